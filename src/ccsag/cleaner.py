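"""Step 2: iterative cross-reference mapping and chimera removal.

Each SAG's reads are mapped onto raw contigs assembled from the *other*
SAGs of its strain group, so amplification artifacts private to one cell
are never self-confirmed. A read is *clean* when complete alignments are
at least as frequent as partial (soft-clipped) ones, *potentially
chimeric* when partial alignments dominate, and *unmapped* otherwise.
Potential chimeras are cut at the boundaries of their best partial
alignment into aligned and unaligned fragments; fragments shorter than
20 bp are discarded and the rest re-enter the next mapping cycle.
Cycles repeat until no potential chimeras remain.

"Complete" tolerates a small total clip (default ≤9 bp, below the 20 bp
fragment floor) because real aligners clip a few terminal bases
spuriously; setting ``max_clip_for_complete=0`` restores the strict
no-soft-clip reading. Frequencies are counts of all alignment records
(primary, secondary, supplementary) against the cross-reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .align import SeedExtendAligner
from .grouping import SagGroup
from .seqio import AlignmentRecord, ContigSet, ReadRecord

log = logging.getLogger(__name__)


@dataclass
class CleanerParams:
    min_fragment_len: int = 20
    max_clip_for_complete: int = 9
    max_cycles: int = 10
    min_cross_ref_contig_len: int = 500

    def __post_init__(self) -> None:
        if self.min_fragment_len < 1:
            raise ValueError("min_fragment_len must be ≥ 1")
        if self.max_clip_for_complete >= self.min_fragment_len:
            raise ValueError("max_clip_for_complete must be < min_fragment_len")


@dataclass
class ReadClass:
    label: str  # clean | potential_chimera | unmapped
    n_complete: int = 0
    n_partial: int = 0


@dataclass
class ClassifiedReadSet:
    """Partition of one SAG's reads for one cleaning cycle."""

    sag_id: str
    cycle: int
    clean: List[ReadRecord] = field(default_factory=list)
    pending: List[ReadRecord] = field(default_factory=list)
    unmapped: List[ReadRecord] = field(default_factory=list)
    discarded_bases: int = 0

    @property
    def counts(self) -> Tuple[int, int, int]:
        return len(self.clean), len(self.pending), len(self.unmapped)


@dataclass
class CycleReport:
    cycle: int
    n_input: int
    n_clean: int
    n_pending: int
    n_unmapped: int
    bases_discarded: int


def build_cross_reference(group: SagGroup, sag_id: str,
                          min_contig_len: int = 500) -> ContigSet:
    """Union of raw contigs (≥ ``min_contig_len``) from all group members
    except ``sag_id``, contig names prefixed by their source SAG."""
    if sag_id not in group.sag_ids:
        raise KeyError(f"{sag_id} not in group {group.group_id}")
    others = [s for s in group.sag_ids if s != sag_id]
    if not others:
        raise ValueError("cross-reference requires ≥2 SAGs in the group")
    contigs = []
    for other in others:
        for name, seq in group.contigs[other].filtered(min_contig_len):
            contigs.append((f"{other}.{name}", seq))
    return ContigSet(contigs, provenance="raw_sag", sag_ids=tuple(others))


def classify_read(alignments: Sequence[AlignmentRecord],
                  params: Optional[CleanerParams] = None) -> ReadClass:
    """Apply the soft-clip frequency rule to one read's alignment records.

    complete := total clip ≤ max_clip_for_complete. Ties go to clean
    ("equally or more frequent"); no alignments means unmapped.
    """
    p = params or CleanerParams()
    mapped = [a for a in alignments if a.is_mapped]
    if len({a.query_id for a in mapped}) > 1:
        raise ValueError("classify_read received alignments of multiple reads")
    n_complete = sum(1 for a in mapped if a.total_clip <= p.max_clip_for_complete)
    n_partial = len(mapped) - n_complete
    if not mapped:
        label = "unmapped"
    elif n_complete >= n_partial and n_complete >= 1:
        label = "clean"
    elif n_partial > n_complete:
        label = "potential_chimera"
    else:  # n_complete == n_partial == 0 cannot happen with mapped records
        label = "unmapped"
    return ReadClass(label, n_complete, n_partial)


def _select_split_template(alignments: Sequence[AlignmentRecord],
                           params: CleanerParams) -> AlignmentRecord:
    partial = [a for a in alignments
               if a.is_mapped and a.total_clip > params.max_clip_for_complete]
    if not partial:
        raise ValueError("split_chimera requires at least one partial alignment")
    # largest aligned query length; ties → leftmost query start, then target id
    partial.sort(key=lambda a: (-a.aligned_query_len, a.query_span[0], a.target_id))
    return partial[0]


def split_chimera(read: ReadRecord, alignments: Sequence[AlignmentRecord],
                  params: Optional[CleanerParams] = None
                  ) -> Tuple[List[ReadRecord], int]:
    """Cut a potential chimera at its best partial alignment's boundaries.

    Yields up to three fragments (left clip, aligned block, right clip);
    pieces shorter than ``min_fragment_len`` are discarded and their bases
    counted. Fragment records carry ``origin`` = (root read id, interval on
    the root read) so truth can be traced through nested splits.
    """
    p = params or CleanerParams()
    template = _select_split_template(alignments, p)
    qs, qe = template.query_span
    cuts = [(0, qs), (qs, qe), (qe, len(read))]
    root_id, root_off = (read.origin[0], read.origin[1]) if read.origin else (read.read_id, 0)
    fragments: List[ReadRecord] = []
    discarded = 0
    quals = list(read.qualities)
    for idx, (a, b) in enumerate(cuts):
        if b - a <= 0:
            continue
        if b - a < p.min_fragment_len:
            discarded += b - a
            continue
        fragments.append(
            ReadRecord(
                read_id=f"{read.read_id}|f{idx}",
                sequence=read.sequence[a:b],
                qualities=quals[a:b],
                sag_id=read.sag_id,
                mate=read.mate,
                origin=(root_id, root_off + a, root_off + b),
            )
        )
    return fragments, discarded


def clean_cycle(reads: Sequence[ReadRecord], aligner,
                params: Optional[CleanerParams] = None,
                sag_id: str = "", cycle: int = 1) -> ClassifiedReadSet:
    """One mapping/classification/splitting pass over ``reads``.

    ``aligner`` is any adapter indexed on the cross-reference exposing
    ``map_read(read, mode="all")``.
    """
    p = params or CleanerParams()
    out = ClassifiedReadSet(sag_id=sag_id, cycle=cycle)
    for read in reads:
        alignments = aligner.map_read(read, mode="all")
        cls = classify_read(alignments, p)
        if cls.label == "clean":
            out.clean.append(read)
        elif cls.label == "unmapped":
            out.unmapped.append(read)
        else:
            fragments, discarded = split_chimera(read, alignments, p)
            out.pending.extend(fragments)
            out.discarded_bases += discarded
    return out


def run_cleaning(sag_reads: Sequence[ReadRecord], cross_ref: ContigSet,
                 aligner=None, params: Optional[CleanerParams] = None,
                 sag_id: str = ""
                 ) -> Tuple[List[ReadRecord], List[ReadRecord], List[CycleReport]]:
    """Iterate cleaning cycles until no potential chimeras remain.

    Returns (clean reads, unmapped reads, per-cycle reports). Every split
    strictly shortens its fragments and sub-threshold pieces are dropped,
    so the loop terminates even without ``max_cycles``; if ``max_cycles``
    is hit anyway, remaining pending fragments are demoted to unmapped
    with a warning.
    """
    p = params or CleanerParams()
    if aligner is None:
        aligner = SeedExtendAligner(cross_ref.filtered(p.min_cross_ref_contig_len))
    clean: List[ReadRecord] = []
    unmapped: List[ReadRecord] = []
    reports: List[CycleReport] = []
    pending = list(sag_reads)
    cycle = 0
    while pending and cycle < p.max_cycles:
        cycle += 1
        n_input = len(pending)
        result = clean_cycle(pending, aligner, p, sag_id=sag_id, cycle=cycle)
        clean.extend(result.clean)
        unmapped.extend(result.unmapped)
        pending = result.pending
        reports.append(CycleReport(
            cycle=cycle,
            n_input=n_input,
            n_clean=len(result.clean),
            n_pending=len(result.pending),
            n_unmapped=len(result.unmapped),
            bases_discarded=result.discarded_bases,
        ))
    if pending:
        log.warning("%s: max_cycles=%d exhausted with %d pending fragments; "
                    "demoting to unmapped", sag_id, p.max_cycles, len(pending))
        unmapped.extend(pending)
    return clean, unmapped, reports


def total_bases(reads: Iterable[ReadRecord]) -> int:
    return sum(len(r) for r in reads)
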