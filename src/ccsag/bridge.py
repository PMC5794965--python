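"""Step 3: co-assembly orchestration and bridging of composite contigs.

Clean reads from all SAGs of a group are co-assembled into *clean
composite* contigs and raw reads into *raw composite* contigs. Raw
composite contigs aligning to clean contigs at ≥99% identity over
≥250 bp can then *bridge* two clean contigs: a raw contig anchored on
the 3' end of clean contig X and the 5' end of clean contig Y (in a
consistent orientation, with non-overlapping raw intervals) proposes the
join X — gap — Y where the gap is the raw sequence between the two
anchor blocks. Clean sequence always takes precedence where both cover a
position; the raw contig contributes only the unanchored gap (and end
extensions). One bridge is accepted per contig end, greedily by total
anchored length, and circular paths are rejected.

Assembly itself is strictly an adapter: the production backend is SPAdes
with single-cell flags; a coverage-truth stub backend serves the test
suite so no external assembler is required.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .align import SeedExtendAligner
from .seqio import (
    AlignmentRecord,
    ContigSet,
    ReadRecord,
    read_fasta,
    revcomp,
    write_fasta,
    write_fastq,
)

log = logging.getLogger(__name__)


@dataclass
class BridgeParams:
    min_bridge_identity: float = 99.0
    min_bridge_alignment_len: int = 250
    min_output_contig_len: int = 500
    #: an anchor must reach this close to the clean contig end to qualify
    end_slack: int = 10


@dataclass
class BridgeCandidate:
    raw_contig_id: str
    clean_contig_id: str
    alignment: AlignmentRecord  # query = raw contig, target = clean contig
    orientation: str            # strand of the raw contig along the clean contig


@dataclass
class BridgeReport:
    joins: List[dict] = field(default_factory=list)
    extensions: List[dict] = field(default_factory=list)
    bases_inserted: int = 0


# ---------------------------------------------------------------------------
# assembler adapters


class SpadesAssembler:
    """SPAdes backend with single-cell flags (--careful --disable-rr --sc)."""

    def __init__(self, binary: str = "spades.py", threads: int = 1) -> None:
        if shutil.which(binary) is None:
            raise RuntimeError(
                f"assembler binary {binary!r} not found on PATH; install SPAdes "
                "or inject a different assembler backend"
            )
        self.binary = binary
        self.threads = threads

    def assemble(self, read_sets: Sequence[Sequence[ReadRecord]]) -> List[Tuple[str, str]]:
        with tempfile.TemporaryDirectory(prefix="ccsag_spades_") as tmp:
            tmp = Path(tmp)
            fq = tmp / "reads.fq"
            write_fastq(fq, [r for rs in read_sets for r in rs])
            cmd = [self.binary, "--careful", "--disable-rr", "--sc",
                   "-s", str(fq), "-t", str(self.threads), "-o", str(tmp / "out")]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(f"SPAdes failed (exit {proc.returncode}): "
                                   f"{proc.stderr[-500:]}")
            return read_fasta(tmp / "out" / "contigs.fasta")


class TruthAssembler:
    """Test/simulation stub: emit read-covered intervals of a known genome.

    Maps each read onto the true genome with the internal aligner and
    returns maximal covered intervals as contigs, merging islands closer
    than ``merge_gap`` (default 1 kb, the amplification-window scale the
    simulator samples at — an idealized assembler reconstructs whole
    amplified windows). A perfect assembler for simulated data, useful
    precisely because assembly quality is not what the cleaning and
    bridging stages are testing.
    """

    def __init__(self, genome: ContigSet, merge_gap: int = 1000) -> None:
        self.genome = genome
        self.merge_gap = merge_gap
        self._aligner = SeedExtendAligner(genome)

    def assemble(self, read_sets: Sequence[Sequence[ReadRecord]]) -> List[Tuple[str, str]]:
        cover: Dict[str, List[Tuple[int, int]]] = {n: [] for n, _ in self.genome}
        for reads in read_sets:
            for read in reads:
                for rec in self._aligner.map_read(read, mode="all"):
                    cover[rec.target_id].append(rec.target_span)
        contigs = []
        i = 0
        for name, seq in self.genome:
            merged: List[List[int]] = []
            for s, e in sorted(cover[name]):
                if merged and s <= merged[-1][1] + self.merge_gap:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for s, e in merged:
                i += 1
                contigs.append((f"contig{i:04d}", seq[s:e]))
        return contigs


class StubAssembler:
    """Injected fixture backend that returns a fixed contig list."""

    def __init__(self, contigs: Sequence[Tuple[str, str]]) -> None:
        self._contigs = list(contigs)

    def assemble(self, read_sets) -> List[Tuple[str, str]]:
        return list(self._contigs)


_PROVENANCE = {"single_sag": "raw_sag", "co_assembly": "raw_composite"}


def run_assembler(read_sets: Sequence[Sequence[ReadRecord]], mode: str,
                  backend, min_contig_len: int = 500,
                  provenance: Optional[str] = None,
                  sag_ids: Tuple[str, ...] = ()) -> ContigSet:
    """Run an assembler backend and collect contigs ≥ ``min_contig_len``."""
    if mode not in _PROVENANCE:
        raise ValueError(f"unknown assembly mode {mode!r}")
    contigs = backend.assemble(read_sets)
    cs = ContigSet(list(contigs), provenance=provenance or _PROVENANCE[mode],
                   sag_ids=sag_ids)
    return cs.filtered(min_contig_len)


# ---------------------------------------------------------------------------
# bridging


def find_bridge_candidates(clean: ContigSet, raw: ContigSet,
                           params: Optional[BridgeParams] = None,
                           aligner=None) -> List[BridgeCandidate]:
    """Local alignments of raw composite contigs onto clean composite
    contigs passing both the identity and length thresholds, both strands."""
    p = params or BridgeParams()
    if not len(clean) or not len(raw):
        return []
    if aligner is None:
        aligner = SeedExtendAligner(clean, min_aln_len=p.min_bridge_alignment_len)
    out = []
    for raw_name, raw_seq in raw:
        for rec in aligner.map_seq(raw_name, raw_seq, mode="all"):
            if (rec.alignment_length >= p.min_bridge_alignment_len
                    and rec.identity_percent >= p.min_bridge_identity):
                out.append(BridgeCandidate(
                    raw_contig_id=raw_name,
                    clean_contig_id=rec.target_id,
                    alignment=rec,
                    orientation=rec.strand,
                ))
    out.sort(key=lambda c: (c.raw_contig_id, c.clean_contig_id,
                            c.alignment.target_span))
    return out


def _anchor_roles(cand: BridgeCandidate, clean_len: int, slack: int) -> Tuple[bool, bool]:
    """(is_left, is_right) roles of an anchor in the raw contig's frame.

    *left*: the oriented clean contig ends at this anchor, so a join can
    continue rightward along the raw contig. *right*: it starts here.
    """
    ts, te = cand.alignment.target_span
    if cand.orientation == "+":
        os_, oe = ts, te
    else:
        os_, oe = clean_len - te, clean_len - ts
    return oe >= clean_len - slack, os_ <= slack


def _end_of(cand: BridgeCandidate, role: str) -> Tuple[str, str]:
    """Physical clean-contig end consumed by an anchor role.

    Ends are named in the contig's own forward orientation: ``head`` is
    the 5' end, ``tail`` the 3' end.
    """
    if role == "left":
        return cand.clean_contig_id, ("tail" if cand.orientation == "+" else "head")
    return cand.clean_contig_id, ("head" if cand.orientation == "+" else "tail")


@dataclass
class _Join:
    score: int
    raw_id: str
    left: BridgeCandidate
    right: BridgeCandidate
    gap: str

    @property
    def e1(self) -> Tuple[str, str]:
        return _end_of(self.left, "left")

    @property
    def e2(self) -> Tuple[str, str]:
        return _end_of(self.right, "right")


def bridge_contigs(clean: ContigSet, candidates: Sequence[BridgeCandidate],
                   raw: ContigSet, params: Optional[BridgeParams] = None
                   ) -> Tuple[ContigSet, BridgeReport]:
    """Join and extend clean composite contigs using anchored raw contigs.

    Proposals (two-anchor joins and single-anchor end extensions) are
    accepted greedily by descending anchored length with deterministic
    tie-breaks; each clean contig end takes at most one proposal and
    circular paths are rejected via union-find. Every clean contig
    survives in the output as an exact substring (possibly
    reverse-complemented) of some emitted contig.
    """
    p = params or BridgeParams()
    clean_seqs = dict(clean.contigs)
    raw_seqs = dict(raw.contigs)
    for c in candidates:
        if c.clean_contig_id not in clean_seqs:
            raise KeyError(f"candidate references unknown clean contig {c.clean_contig_id}")
        if c.raw_contig_id not in raw_seqs:
            raise KeyError(f"candidate references unknown raw contig {c.raw_contig_id}")

    by_raw: Dict[str, List[BridgeCandidate]] = {}
    for c in candidates:
        by_raw.setdefault(c.raw_contig_id, []).append(c)

    joins: List[_Join] = []
    # extension proposals: (score, raw_id, clean_id, end, outward sequence)
    exts: List[Tuple[int, str, str, Tuple[str, str], str]] = []
    for raw_name in sorted(by_raw):
        cands = sorted(by_raw[raw_name], key=lambda c: c.alignment.query_span)
        raw_seq = raw_seqs[raw_name]
        for c1 in cands:
            L1 = len(clean_seqs[c1.clean_contig_id])
            left1, right1 = _anchor_roles(c1, L1, p.end_slack)
            if left1:
                for c2 in cands:
                    if c2.clean_contig_id == c1.clean_contig_id:
                        continue
                    if c2.alignment.query_span[0] < c1.alignment.query_span[1]:
                        continue
                    L2 = len(clean_seqs[c2.clean_contig_id])
                    if not _anchor_roles(c2, L2, p.end_slack)[1]:
                        continue
                    gap = raw_seq[c1.alignment.query_span[1]:c2.alignment.query_span[0]]
                    joins.append(_Join(
                        score=c1.alignment.aligned_query_len + c2.alignment.aligned_query_len,
                        raw_id=raw_name, left=c1, right=c2, gap=gap))
                if c1.alignment.query_span[1] < len(raw_seq):
                    # raw contig overhangs the oriented 3' end: extension
                    extra = raw_seq[c1.alignment.query_span[1]:]
                    exts.append((c1.alignment.aligned_query_len, raw_name,
                                 c1.clean_contig_id, _end_of(c1, "left"), extra))
            if right1 and c1.alignment.query_span[0] > 0:
                extra = revcomp(raw_seq[:c1.alignment.query_span[0]])
                exts.append((c1.alignment.aligned_query_len, raw_name,
                             c1.clean_contig_id, _end_of(c1, "right"), extra))

    proposals: List[Tuple] = [
        (-j.score, 0, j.raw_id, j.left.clean_contig_id, j.right.clean_contig_id, j)
        for j in joins
    ] + [
        (-score, 1, raw_id, clean_id, end[1], (end, extra, raw_id, score))
        for score, raw_id, clean_id, end, extra in exts
    ]
    proposals.sort(key=lambda x: x[:5])

    used_ends: set = set()
    parent: Dict[str, str] = {n: n for n, _ in clean.contigs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edge: Dict[Tuple[str, str], _Join] = {}
    ext_out: Dict[Tuple[str, str], str] = {}  # end -> sequence reading outward
    report = BridgeReport()
    for prop in proposals:
        if prop[1] == 0:
            j: _Join = prop[5]
            if "N" in j.gap:
                continue  # never emit N runs that were not observed
            if j.e1 in used_ends or j.e2 in used_ends:
                continue
            a, b = j.left.clean_contig_id, j.right.clean_contig_id
            if find(a) == find(b):
                continue  # would close a circle
            used_ends.update((j.e1, j.e2))
            parent[find(a)] = find(b)
            edge[j.e1] = j
            edge[j.e2] = j
            report.joins.append({
                "raw_contig": j.raw_id, "left": a, "right": b,
                "inserted_bases": len(j.gap),
                "left_identity": round(j.left.alignment.identity_percent, 3),
                "right_identity": round(j.right.alignment.identity_percent, 3),
            })
            report.bases_inserted += len(j.gap)
        else:
            end, extra, raw_id, score = prop[5]
            if "N" in extra or end in used_ends:
                continue
            used_ends.add(end)
            ext_out[end] = extra
            report.extensions.append({
                "raw_contig": raw_id, "contig": end[0], "end": end[1],
                "added_bases": len(extra),
            })

    # --- walk chains: entering a contig at its head reads it forward -------
    def other(end: str) -> str:
        return "head" if end == "tail" else "tail"

    free_ends = sorted(
        (name, e) for name in clean_seqs for e in ("head", "tail")
        if (name, e) not in edge
    )
    emitted: set = set()
    out_contigs: List[Tuple[str, str]] = []
    merged_i = 0
    for start in free_ends:
        if start[0] in emitted:
            continue
        chain: List[Tuple[str, str]] = []
        pieces: List[str] = []
        if start in ext_out:
            pieces.append(revcomp(ext_out[start]))
        cur, entry = start
        while True:
            orient = "+" if entry == "head" else "-"
            chain.append((cur, orient))
            seq = clean_seqs[cur]
            pieces.append(seq if orient == "+" else revcomp(seq))
            emitted.add(cur)
            exit_end = (cur, other(entry))
            j = edge.get(exit_end)
            if j is None:
                if exit_end in ext_out:
                    pieces.append(ext_out[exit_end])
                break
            if exit_end == j.e1:
                pieces.append(j.gap)
                cur, entry = j.e2
            else:
                pieces.append(revcomp(j.gap))
                cur, entry = j.e1
        if len(chain) == 1 and len(pieces) == 1:
            out_contigs.append((chain[0][0], clean_seqs[chain[0][0]]))
        else:
            merged_i += 1
            name = f"bridged{merged_i:04d}|" + "+".join(c for c, _ in chain)
            out_contigs.append((name, "".join(pieces)))

    result = ContigSet(
        [(n, s) for n, s in out_contigs if len(s) >= p.min_output_contig_len],
        provenance="bridged_composite",
        sag_ids=clean.sag_ids,
    )
    return result, report


def run_step3(clean_reads_per_sag: Dict[str, Sequence[ReadRecord]],
              raw_reads_per_sag: Dict[str, Sequence[ReadRecord]],
              assembler, params: Optional[BridgeParams] = None
              ) -> Tuple[ContigSet, ContigSet, ContigSet, BridgeReport]:
    """Co-assemble raw and clean reads for a group, then bridge.

    Returns (raw_composite, clean_composite, bridged_composite, report).
    SAGs whose clean read set is empty are skipped with a warning.
    """
    p = params or BridgeParams()
    if len(raw_reads_per_sag) < 2:
        raise ValueError("co-assembly requires ≥2 SAGs (cross-reference cleaning "
                         "is impossible for a singleton group)")
    clean_sets = []
    for sag in sorted(clean_reads_per_sag):
        if not clean_reads_per_sag[sag]:
            log.warning("SAG %s has no clean reads; skipping", sag)
            continue
        clean_sets.append(clean_reads_per_sag[sag])
    raw_sets = [raw_reads_per_sag[s] for s in sorted(raw_reads_per_sag)]
    sag_ids = tuple(sorted(raw_reads_per_sag))
    raw_comp = run_assembler(raw_sets, "co_assembly", assembler,
                             p.min_output_contig_len, provenance="raw_composite",
                             sag_ids=sag_ids)
    clean_comp = run_assembler(clean_sets, "co_assembly", assembler,
                               p.min_output_contig_len, provenance="clean_composite",
                               sag_ids=sag_ids)
    candidates = find_bridge_candidates(clean_comp, raw_comp, p)
    bridged, report = bridge_contigs(clean_comp, candidates, raw_comp, p)
    return raw_comp, clean_comp, bridged, report
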