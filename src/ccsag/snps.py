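"""Within-strain SNP detection against the composite single-cell genome.

Each SAG's cleaned reads are mapped onto the composite contigs (or their
coding sequences, when a CDS annotation is supplied) and every site is
classified per SAG: with a coverage depth of at least 5 reads, a SAG is
*unmatched* at a site when ≥99.9% of its reads disagree with the
reference AND all disagreeing reads carry one identical base, *matched*
when ≥99.9% agree, and *no-call* otherwise. A site is reported as a SNP
when both multiple (≥2) matched SAGs and multiple (≥2) unmatched SAGs
sharing the same alternate base are present — sites where every SAG
disagrees indicate an assembly error, not a polymorphism. Note that at
depths below 1000 the 99.9% threshold means literally every read, which
is the operative regime at depth ≥5; this is what places the rule above
the sequence error frequency of amplification and sequencing artifacts.

Base qualities are not consulted; reads contribute equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from .seqio import AlignmentRecord, ContigSet, ReadRecord, revcomp

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class SnpParams:
    min_depth: int = 5
    min_mismatch_fraction: float = 0.999  # inclusive
    min_matched_sags: int = 2
    min_unmatched_sags: int = 2


@dataclass
class PileupSite:
    contig_id: str
    position: int  # 0-based
    ref_base: str
    per_sag_counts: Dict[str, Dict[str, int]]

    def depth(self, sag_id: str) -> int:
        return sum(self.per_sag_counts.get(sag_id, {}).values())


@dataclass
class SnpCall:
    contig_id: str
    position: int  # 0-based
    ref_base: str
    alt_base: str
    matched_sags: List[str]
    unmatched_sags: List[str]
    codon_effect: Optional[str] = None


class Pileup:
    """Per-contig, per-SAG base-count arrays against the composite.

    Counts are accumulated from ungapped alignment blocks; clipped read
    ends and deletions contribute nothing, insertions are ignored.
    """

    def __init__(self, composite: ContigSet,
                 regions: Optional[Dict[str, List[Tuple[int, int]]]] = None) -> None:
        self.composite = composite
        self.regions = regions
        self._ref: Dict[str, np.ndarray] = {}
        self._mask: Dict[str, np.ndarray] = {}
        self.counts: Dict[str, Dict[str, np.ndarray]] = {}
        for name, seq in composite:
            enc = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
            ref = np.full(len(seq), -1, dtype=np.int8)
            for b, i in _BASE_IDX.items():
                ref[enc == ord(b)] = i
            self._ref[name] = ref
            mask = np.zeros(len(seq), dtype=bool)
            if regions is None or name not in regions:
                mask[:] = True
            else:
                for s, e in regions[name]:
                    mask[s:e] = True
            self._mask[name] = mask
            self.counts[name] = {}

    def add_alignment(self, sag_id: str, read_seq: str, rec: AlignmentRecord) -> None:
        if rec.target_id not in self._ref:
            raise KeyError(f"alignment target {rec.target_id!r} absent from composite")
        arr = self.counts[rec.target_id].setdefault(
            sag_id, np.zeros((4, len(self._ref[rec.target_id])), dtype=np.int32))
        oriented = read_seq.upper() if rec.strand == "+" else revcomp(read_seq.upper())
        n = len(read_seq)
        for qs, ts, length in rec.blocks:
            if rec.strand == "-":
                # blocks carry original-read offsets; convert to oriented frame
                oq = n - (qs + length)
            else:
                oq = qs
            seg = np.frombuffer(oriented[oq:oq + length].encode(), dtype=np.uint8)
            pos = np.arange(ts, ts + length)
            for b, i in _BASE_IDX.items():
                sel = seg == ord(b)
                if sel.any():
                    np.add.at(arr[i], pos[sel], 1)

    def add_sag(self, sag_id: str, reads: Sequence[ReadRecord], aligner) -> None:
        """Map each read (best alignment only) and accumulate its bases."""
        for read in reads:
            recs = aligner.map_read(read, mode="best")
            if recs:
                self.add_alignment(sag_id, read.sequence, recs[0])

    # -- site iteration ----------------------------------------------------

    def candidate_positions(self, contig_id: str) -> np.ndarray:
        """Positions (within regions) where any SAG shows any non-reference
        base — the only sites that can possibly yield a SNP call."""
        ref = self._ref[contig_id]
        any_mismatch = np.zeros(len(ref), dtype=bool)
        valid = ref >= 0
        for sag, arr in self.counts[contig_id].items():
            total = arr.sum(axis=0)
            refcnt = np.where(valid, arr[np.clip(ref, 0, 3), np.arange(len(ref))], 0)
            any_mismatch |= (total - refcnt) > 0
        return np.nonzero(any_mismatch & self._mask[contig_id] & valid)[0]

    def site(self, contig_id: str, pos: int) -> PileupSite:
        ref = self._ref[contig_id][pos]
        per_sag = {}
        for sag, arr in self.counts[contig_id].items():
            col = arr[:, pos]
            if col.sum():
                per_sag[sag] = {b: int(col[i]) for b, i in _BASE_IDX.items()}
        return PileupSite(contig_id, int(pos), _BASES[ref] if ref >= 0 else "N", per_sag)

    def sites(self, candidates_only: bool = True) -> Iterator[PileupSite]:
        for name, _ in self.composite:
            if candidates_only:
                positions = self.candidate_positions(name)
            else:
                positions = np.nonzero(self._mask[name])[0]
            for pos in positions:
                yield self.site(name, pos)


def build_pileup(per_sag_alignments: Dict[str, Iterable[Tuple[ReadRecord, AlignmentRecord]]],
                 composite: ContigSet,
                 regions: Optional[Dict[str, List[Tuple[int, int]]]] = None) -> Pileup:
    """Accumulate a pileup from precomputed (read, alignment) pairs per SAG."""
    pileup = Pileup(composite, regions)
    for sag_id, pairs in per_sag_alignments.items():
        for read, rec in pairs:
            if rec.is_mapped:
                pileup.add_alignment(sag_id, read.sequence, rec)
    return pileup


def classify_sag_site(counts: Dict[str, int], ref_base: str,
                      params: Optional[SnpParams] = None) -> Tuple[str, Optional[str]]:
    """Classify one SAG at one site: ('matched'|'unmatched'|'no_call', alt).

    depth < min_depth → no_call; all-but-0.1% mismatching with one
    homogeneous alternate base → unmatched(alt); all-but-0.1% matching →
    matched; anything mixed → no_call.
    """
    p = params or SnpParams()
    depth = sum(counts.values())
    if depth < p.min_depth:
        return "no_call", None
    ref_n = counts.get(ref_base, 0)
    mismatch_n = depth - ref_n
    if mismatch_n / depth >= p.min_mismatch_fraction:
        nonref = {b: c for b, c in counts.items() if b != ref_base and c > 0}
        if len(nonref) == 1:  # homogeneous alternate
            return "unmatched", next(iter(nonref))
        return "no_call", None
    if ref_n / depth >= p.min_mismatch_fraction:
        return "matched", None
    return "no_call", None


def call_snps(sites: Iterable[PileupSite],
              params: Optional[SnpParams] = None) -> List[SnpCall]:
    """Apply the per-SAG site rule across SAGs and emit SNP calls.

    A call requires ≥ ``min_matched_sags`` matched SAGs and
    ≥ ``min_unmatched_sags`` unmatched SAGs agreeing on one alternate
    base; disagreement among unmatched SAGs suppresses the call. Output
    is sorted by (contig, position) and invariant to SAG input order.
    """
    p = params or SnpParams()
    calls = []
    for site in sites:
        matched, unmatched = [], {}
        for sag in sorted(site.per_sag_counts):
            label, alt = classify_sag_site(site.per_sag_counts[sag], site.ref_base, p)
            if label == "matched":
                matched.append(sag)
            elif label == "unmatched":
                unmatched.setdefault(alt, []).append(sag)
        if len(matched) < p.min_matched_sags or not unmatched:
            continue
        if len(unmatched) != 1:
            continue  # unmatched SAGs disagree on the alternate base
        alt, carriers = next(iter(unmatched.items()))
        if len(carriers) < p.min_unmatched_sags:
            continue
        calls.append(SnpCall(site.contig_id, site.position, site.ref_base,
                             alt, matched, carriers))
    calls.sort(key=lambda c: (c.contig_id, c.position))
    return calls


_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


def annotate_codon_effect(call: SnpCall, cds_start: int, cds_end: int,
                          strand: str, contig_seq: str) -> SnpCall:
    """Attach the amino-acid effect of a SNP inside a CDS (standard code).

    CDS coordinates are 0-based half-open on the contig; ``strand`` is
    '+' or '-'. Raises when the position lies outside the CDS.
    """
    if not cds_start <= call.position < cds_end:
        raise ValueError(f"position {call.position} outside CDS [{cds_start},{cds_end})")
    cds = contig_seq[cds_start:cds_end].upper()
    if strand == "+":
        off = call.position - cds_start
        ref_b, alt_b = call.ref_base, call.alt_base
    else:
        cds = revcomp(cds)
        off = cds_end - 1 - call.position
        ref_b, alt_b = revcomp(call.ref_base), revcomp(call.alt_base)
    codon_i = off // 3
    codon = list(cds[codon_i * 3:codon_i * 3 + 3])
    if len(codon) < 3:
        raise ValueError("CDS length not a multiple of 3 at variant codon")
    if codon[off % 3] != ref_b:
        raise ValueError(
            f"reference base mismatch in CDS: expected {ref_b}, found {codon[off % 3]}")
    ref_aa = str(Seq("".join(codon)).translate())
    codon[off % 3] = alt_b
    alt_aa = str(Seq("".join(codon)).translate())
    if ref_aa == alt_aa:
        effect = "synonymous"
    else:
        effect = f"{_AA3.get(ref_aa, ref_aa)}->{_AA3.get(alt_aa, alt_aa)}"
    call.codon_effect = effect
    return call


def write_snp_tsv(path, calls: Sequence[SnpCall]) -> None:
    """VCF-like TSV: contig, 1-based position, ref, alt, SAG lists, effect."""
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tmatched_sags\tunmatched_sags\teffect\n")
        for c in calls:
            fh.write(f"{c.contig_id}\t{c.position + 1}\t{c.ref_base}\t{c.alt_base}\t"
                     f"{','.join(c.matched_sags)}\t{','.join(c.unmatched_sags)}\t"
                     f"{c.codon_effect or '.'}\n")


def write_vcf(path, calls: Sequence[SnpCall], composite: ContigSet) -> None:
    """Minimal VCF 4.2 output of the SNP calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in composite:
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=MS,Number=.,Type=String,Description="Matched SAGs">\n')
        fh.write('##INFO=<ID=US,Number=.,Type=String,Description="Unmatched SAGs">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = f"MS={','.join(c.matched_sags)};US={','.join(c.unmatched_sags)}"
            if c.codon_effect:
                info += f";EFF={c.codon_effect}"
            fh.write(f"{c.contig_id}\t{c.position + 1}\t.\t{c.ref_base}\t{c.alt_base}"
                     f"\t.\tPASS\t{info}\n")
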