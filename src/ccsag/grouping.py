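"""Step 1: read quality control and grouping of SAGs from the same strain.

SAGs are grouped when their 16S rRNA V3-V4 fragments are ≥99% identical
AND the average nucleotide identity (ANI) between their raw contigs
exceeds 95%, computed over local alignments of at least 500 bp. Grouping
uses single-linkage over the pairs passing both thresholds — the most
permissive reading consistent with threshold-based grouping. A SAG whose
partial assembly lacks a recoverable 16S fragment (rRNA operons are often
missing from SAGs) is grouped on ANI alone and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .align import SeedExtendAligner
from .seqio import ContigSet, ReadRecord, revcomp

# Standard V3-V4 primers (341F / 805R), IUPAC-degenerate.
PRIMER_341F = "CCTACGGGNGGCWGCAG"
PRIMER_805R = "GACTACHVGGGTATCTAATCC"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class QcParams:
    """Read QC thresholds.

    A read is discarded when ≥``low_quality_fraction`` of its bases are
    below ``low_quality_phred``; 3'-terminal bases below ``trim_phred``
    are trimmed stepwise; reads shorter than ``min_read_len`` or with an
    N fraction ≥ ``max_n_fraction`` are discarded; the mate of any
    discarded read is discarded too.
    """

    low_quality_phred: int = 25
    low_quality_fraction: float = 0.50
    trim_phred: int = 20
    min_read_len: int = 20
    max_n_fraction: float = 0.01


@dataclass
class GroupingParams:
    min_16s_identity: float = 99.0   # inclusive
    min_ani: float = 95.0            # exclusive
    min_ani_alignment_len: int = 500
    min_contig_len: int = 500


@dataclass
class QcReport:
    n_input: int = 0
    n_output: int = 0
    removed_low_quality: int = 0
    removed_short: int = 0
    removed_n_content: int = 0
    removed_unpaired_mate: int = 0
    bases_trimmed: int = 0

    @property
    def n_removed(self) -> int:
        return (self.removed_low_quality + self.removed_short
                + self.removed_n_content + self.removed_unpaired_mate)


@dataclass
class SagGroup:
    group_id: str
    sag_ids: List[str]
    pairwise_16s: Optional[np.ndarray] = None
    pairwise_ani: Optional[np.ndarray] = None
    contigs: Dict[str, ContigSet] = field(default_factory=dict)
    no_16s: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# QC


def _qc_single(read: ReadRecord, p: QcParams, report: QcReport) -> Optional[ReadRecord]:
    quals = list(read.qualities)
    n = len(quals)
    if n == 0 or sum(1 for q in quals if q < p.low_quality_phred) >= p.low_quality_fraction * n:
        report.removed_low_quality += 1
        return None
    end = n
    while end > 0 and quals[end - 1] < p.trim_phred:
        end -= 1
    if end < n:
        report.bases_trimmed += n - end
        read = ReadRecord(read.read_id, read.sequence[:end], quals[:end],
                          sag_id=read.sag_id, mate=read.mate, truth=read.truth)
    if len(read) < p.min_read_len:
        report.removed_short += 1
        return None
    if read.sequence.count("N") >= p.max_n_fraction * len(read):
        report.removed_n_content += 1
        return None
    return read


def qc_reads(pairs: Iterable, params: Optional[QcParams] = None):
    """Filter and trim reads; returns (list of surviving reads, QcReport).

    ``pairs`` may mix (r1, r2) tuples and single reads. Rule order is
    fixed: low-quality discard, 3' trim, length, N content; then the mate
    of any discarded read is discarded as well.
    """
    p = params or QcParams()
    report = QcReport()
    out: List[ReadRecord] = []
    for item in pairs:
        if isinstance(item, tuple):
            r1, r2 = item
            report.n_input += 2
            if r1.qualities is None or r2.qualities is None:
                raise ValueError("qc_reads requires per-base qualities")
            k1 = _qc_single(r1, p, report)
            k2 = _qc_single(r2, p, report)
            if k1 is not None and k2 is not None:
                out.extend([k1, k2])
            elif k1 is not None or k2 is not None:
                report.removed_unpaired_mate += 1
        else:
            report.n_input += 1
            kept = _qc_single(item, p, report)
            if kept is not None:
                out.append(kept)
    report.n_output = len(out)
    return out, report


# ---------------------------------------------------------------------------
# 16S V3-V4 extraction


def _primer_mismatches(primer: str, window: str) -> int:
    mm = 0
    for p, b in zip(primer, window):
        if b not in _IUPAC.get(p, p):
            mm += 1
    return mm


def _scan_primer(seq: str, primer: str, max_mm: int) -> List[Tuple[int, int]]:
    """All (position, mismatches) where primer matches seq with ≤ max_mm."""
    out = []
    k = len(primer)
    for i in range(len(seq) - k + 1):
        mm = _primer_mismatches(primer, seq[i:i + k])
        if mm <= max_mm:
            out.append((i, mm))
    return out


def extract_16s_v3v4(
    contigs: ContigSet,
    fwd_primer: str = PRIMER_341F,
    rev_primer: str = PRIMER_805R,
    max_mismatches: int = 2,
    amplicon_range: Tuple[int, int] = (350, 550),
) -> Optional[str]:
    """Extract the inter-primer V3-V4 fragment from contigs, if present.

    Both orientations are searched; the best primer-pair hit (fewest total
    mismatches, then longest amplicon within ``amplicon_range``) wins.
    Returns the forward-oriented insert, or None when no pair is found —
    absence is a value, not an error.
    """
    best = None  # (total_mm, -insert_len, insert)
    rc_rev = revcomp(rev_primer)
    for _, contig in contigs:
        for seq in (contig.upper(), revcomp(contig.upper())):
            fwd_hits = _scan_primer(seq, fwd_primer, max_mismatches)
            if not fwd_hits:
                continue
            rev_hits = _scan_primer(seq, rc_rev, max_mismatches)
            for fpos, fmm in fwd_hits:
                start = fpos + len(fwd_primer)
                for rpos, rmm in rev_hits:
                    amplicon = (rpos + len(rev_primer)) - fpos
                    if not amplicon_range[0] <= amplicon <= amplicon_range[1]:
                        continue
                    insert = seq[start:rpos]
                    key = (fmm + rmm, -len(insert))
                    if best is None or key < best[0]:
                        best = (key, insert)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# identity / ANI


def seq_identity(a: str, b: str) -> float:
    """Percent identity of a global alignment with unit mismatch/gap costs.

    100 · matches / alignment_columns, computed from the edlib traceback;
    symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("seq_identity requires nonempty sequences")
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    matches = 0
    columns = 0
    for n, op in _parse_extended_cigar(res["cigar"]):
        columns += n
        if op == "=":
            matches += n
    return 100.0 * matches / columns


def _parse_extended_cigar(cigar: str) -> Iterator[Tuple[int, str]]:
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


def pairwise_ani(
    a: ContigSet,
    b: ContigSet,
    params: Optional[GroupingParams] = None,
    aligner_factory=SeedExtendAligner,
) -> float:
    """ANI between two contig sets: length-weighted mean identity of local
    alignments ≥ ``min_ani_alignment_len``, symmetrized as the mean of the
    A→B and B→A directions. NaN when no qualifying alignment survives."""
    p = params or GroupingParams()
    fa = a.filtered(p.min_contig_len)
    fb = b.filtered(p.min_contig_len)
    vals = []
    for query, target in ((fa, fb), (fb, fa)):
        if not len(query) or not len(target):
            vals.append(float("nan"))
            continue
        aligner = aligner_factory(target, min_aln_len=p.min_ani_alignment_len)
        wsum = 0.0
        lsum = 0
        for name, seq in query:
            for rec in aligner.map_seq(name, seq, mode="all"):
                if rec.alignment_length >= p.min_ani_alignment_len:
                    wsum += rec.identity_percent * rec.alignment_length
                    lsum += rec.alignment_length
        vals.append(wsum / lsum if lsum else float("nan"))
    vals = [v for v in vals if v == v]  # drop NaN
    return sum(vals) / len(vals) if vals else float("nan")


# ---------------------------------------------------------------------------
# grouping


def group_sags(
    sags: Sequence[Tuple[str, Optional[str], ContigSet]],
    params: Optional[GroupingParams] = None,
    aligner_factory=SeedExtendAligner,
) -> List[SagGroup]:
    """Single-linkage grouping of (sag_id, 16S sequence or None, contigs).

    An edge joins two SAGs when 16S identity ≥ ``min_16s_identity`` (the
    comparison is skipped, i.e. treated as passing, when either lacks a
    16S fragment) AND ANI > ``min_ani``. Deterministic group ids ordered
    by smallest member sag_id.
    """
    p = params or GroupingParams()
    n = len(sags)
    ids = [s[0] for s in sags]
    sim16 = np.full((n, n), np.nan)
    ani = np.full((n, n), np.nan)
    np.fill_diagonal(sim16, 100.0)
    np.fill_diagonal(ani, 100.0)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            s16_i, s16_j = sags[i][1], sags[j][1]
            if s16_i and s16_j:
                sim16[i, j] = sim16[j, i] = seq_identity(s16_i, s16_j)
                pass16 = sim16[i, j] >= p.min_16s_identity
            else:
                pass16 = True  # fall back to ANI alone
            if not pass16:
                continue
            ani[i, j] = ani[j, i] = pairwise_ani(
                sags[i][2], sags[j][2], p, aligner_factory=aligner_factory
            )
            if ani[i, j] == ani[i, j] and ani[i, j] > p.min_ani:
                parent[find(i)] = find(j)

    clusters: Dict[int, List[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(clusters.values(), key=lambda idx: min(ids[i] for i in idx))
    groups = []
    for gi, idx in enumerate(ordered):
        idx = sorted(idx, key=lambda i: ids[i])
        sub = np.ix_(idx, idx)
        groups.append(
            SagGroup(
                group_id=f"group{gi + 1:02d}",
                sag_ids=[ids[i] for i in idx],
                pairwise_16s=sim16[sub],
                pairwise_ani=ani[sub],
                contigs={ids[i]: sags[i][2] for i in idx},
                no_16s=[ids[i] for i in idx if not sags[i][1]],
            )
        )
    return groups
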