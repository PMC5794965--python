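"""Shared fixtures: the study-condition simulated group and its cleaning.

The heavyweight fixtures are session-scoped so the cross-reference
cleaning of the 6-SAG group (500 kb genome, 2,000 reads/SAG, 15%
chimeric reads, seed 1) is computed once and reused by the property and
acceptance tests.
"""

from __future__ import annotations

import pytest

from ccsag.bridge import TruthAssembler
from ccsag.cleaner import build_cross_reference, run_cleaning
from ccsag.grouping import SagGroup
from ccsag.seqio import ContigSet
from ccsag.simulator import SimParams, simulate_group_data


@pytest.fixture(scope="session")
def study_params() -> SimParams:
    return SimParams(seed=1)  # defaults: 500 kb, 6 SAGs, 2000 reads, 15% chimeras


@pytest.fixture(scope="session")
def study_group(study_params):
    """Simulated group plus per-SAG raw contigs from the stub assembler."""
    data = simulate_group_data(study_params)
    raw_contigs = {}
    for i, sid in enumerate(data.sag_ids):
        asm = TruthAssembler(ContigSet([("genome", data.sag_genomes[i])],
                                       provenance="reference"))
        contigs = ContigSet(asm.assemble([data.reads[sid]]), provenance="raw_sag",
                            sag_ids=(sid,))
        raw_contigs[sid] = contigs.filtered(500)
    group = SagGroup("group01", list(data.sag_ids), contigs=raw_contigs)
    return data, group


@pytest.fixture(scope="session")
def cleaning_results(study_group):
    """run_cleaning output for every SAG of the study group."""
    data, group = study_group
    out = {}
    for sid in data.sag_ids:
        cross = build_cross_reference(group, sid)
        out[sid] = run_cleaning(data.reads[sid], cross, sag_id=sid)
    return out
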