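"""Evaluation layer: read partition against a trusted reference, chimeric
reads per Mb, genome fraction, N50/NG50 and misassembly counting.

These are the quantities used to judge what cleaning and co-assembly did:
they require a trusted reference (the simulation truth genome, or a
published genome), and are never part of the cleaning itself — the
pipeline proper never sees the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .align import SeedExtendAligner
from .seqio import AlignmentRecord, ContigSet, ReadRecord


@dataclass
class ReadEvalParams:
    min_arm_len: int = 20
    max_concordant_gap: int = 1000
    clip_tolerance: int = 9


@dataclass
class MisassemblyParams:
    breakpoint_distance: int = 1000
    min_block_len: int = 500


@dataclass
class ReadPartition:
    fully_mapped: int = 0
    chimeric: int = 0
    unmapped: int = 0
    total_read_bases: int = 0

    @property
    def total(self) -> int:
        return self.fully_mapped + self.chimeric + self.unmapped

    @property
    def chimeric_per_mb(self) -> float:
        """Chimeric reads per megabase of read sequence processed."""
        if self.total_read_bases == 0:
            return 0.0
        return self.chimeric / (self.total_read_bases / 1e6)


def _is_discordant(a: AlignmentRecord, b: AlignmentRecord, gap: int) -> bool:
    if a.target_id != b.target_id:
        return True
    if a.strand != b.strand:
        return True
    dist = max(b.target_span[0] - a.target_span[1],
               a.target_span[0] - b.target_span[1], 0)
    return dist > gap


def partition_reads_vs_reference(
    read_alignments: Iterable[Tuple[ReadRecord, Sequence[AlignmentRecord]]],
    params: Optional[ReadEvalParams] = None,
) -> ReadPartition:
    """Partition reads into fully mapped / chimeric / unmapped.

    A read is *fully mapped* when some alignment leaves a total clip
    ≤ ``clip_tolerance``; *chimeric* when, instead, at least two partial
    alignments with arms ≥ ``min_arm_len`` land at discordant loci
    (different reference sequence, distance > ``max_concordant_gap``, or
    opposite strands); *unmapped* otherwise.
    """
    p = params or ReadEvalParams()
    out = ReadPartition()
    for read, alignments in read_alignments:
        out.total_read_bases += len(read)
        mapped = [a for a in alignments if a.is_mapped]
        if any(a.total_clip <= p.clip_tolerance for a in mapped):
            out.fully_mapped += 1
            continue
        arms = [a for a in mapped if a.aligned_query_len >= p.min_arm_len]
        chimeric = False
        for i in range(len(arms)):
            for j in range(i + 1, len(arms)):
                # arms must cover distinct parts of the read
                qi, qj = arms[i].query_span, arms[j].query_span
                overlap = min(qi[1], qj[1]) - max(qi[0], qj[0])
                if overlap > min(qi[1] - qi[0], qj[1] - qj[0]) / 2:
                    continue
                if _is_discordant(arms[i], arms[j], p.max_concordant_gap):
                    chimeric = True
                    break
            if chimeric:
                break
        if chimeric:
            out.chimeric += 1
        else:
            out.unmapped += 1
    return out


def genome_fraction(query: ContigSet, reference: ContigSet,
                    aligner=None, min_identity: float = 95.0,
                    min_block_len: int = 500, as_reads: bool = False) -> float:
    """Percent of reference positions covered by ≥1 qualifying alignment.

    Contigs qualify at identity ≥ ``min_identity`` over ≥ ``min_block_len``;
    with ``as_reads=True`` any mapped base counts.
    """
    if not len(reference):
        raise ValueError("genome_fraction requires a nonempty reference")
    if aligner is None:
        aligner = SeedExtendAligner(
            reference, min_aln_len=(20 if as_reads else min_block_len))
    covered = {name: np.zeros(len(seq), dtype=bool) for name, seq in reference}
    for name, seq in query:
        for rec in aligner.map_seq(name, seq, mode="all"):
            if not as_reads:
                if (rec.alignment_length < min_block_len
                        or rec.identity_percent < min_identity):
                    continue
            covered[rec.target_id][rec.target_span[0]:rec.target_span[1]] = True
    total = sum(len(v) for v in covered.values())
    return 100.0 * sum(int(v.sum()) for v in covered.values()) / total


def reads_genome_fraction(reads: Sequence[ReadRecord], reference: ContigSet,
                          aligner=None) -> float:
    """Genome fraction covered by reads (any mapped base qualifies)."""
    query = ContigSet([(r.read_id, r.sequence) for r in reads])
    return genome_fraction(query, reference, aligner=aligner, as_reads=True)


def nx_ngx(contig_lengths: Sequence[int], half_target: float) -> int:
    """Largest L such that contigs ≥ L sum to at least ``half_target``.

    ``half_target`` is total_length/2 for N50 and genome_size/2 for NG50;
    returns 0 when the target is unreachable (e.g. NG50 of an incomplete
    assembly) or the list is empty.
    """
    if not contig_lengths:
        return 0
    if any(l <= 0 for l in contig_lengths):
        raise ValueError("contig lengths must be positive")
    acc = 0
    for length in sorted(contig_lengths, reverse=True):
        acc += length
        if acc >= half_target:
            return length
    return 0


def n50(contig_lengths: Sequence[int]) -> int:
    return nx_ngx(contig_lengths, sum(contig_lengths) / 2)


def ng50(contig_lengths: Sequence[int], genome_size: int) -> int:
    return nx_ngx(contig_lengths, genome_size / 2)


@dataclass
class Breakpoint:
    contig_id: str
    query_pos: int
    kind: str  # relocation | inversion | translocation


def count_misassemblies(contigs: ContigSet, reference: ContigSet,
                        params: Optional[MisassemblyParams] = None,
                        aligner=None) -> Tuple[int, List[Breakpoint]]:
    """Count misassembled contigs by ordering reference-alignment blocks.

    Adjacent blocks (≥ ``min_block_len``) along a contig that map
    > ``breakpoint_distance`` apart on the reference are a relocation,
    on opposite strands an inversion, on different reference sequences a
    translocation — mirroring the extensive-misassembly convention of
    standard assembly evaluators. A contig with ≥1 breakpoint counts as
    misassembled.
    """
    p = params or MisassemblyParams()
    if aligner is None:
        aligner = SeedExtendAligner(reference, min_aln_len=p.min_block_len)
    breakpoints: List[Breakpoint] = []
    bad_contigs = set()
    for name, seq in contigs:
        blocks = [r for r in aligner.map_seq(name, seq, mode="all")
                  if r.aligned_query_len >= p.min_block_len]
        blocks.sort(key=lambda r: (r.query_span, r.target_id, r.target_span))
        # keep a non-redundant tiling along the query
        tiling: List[AlignmentRecord] = []
        for b in blocks:
            if tiling:
                prev = tiling[-1]
                overlap = prev.query_span[1] - b.query_span[0]
                if overlap > (b.aligned_query_len / 2):
                    continue
            tiling.append(b)
        for a, b in zip(tiling, tiling[1:]):
            if a.target_id != b.target_id:
                kind = "translocation"
            elif a.strand != b.strand:
                kind = "inversion"
            else:
                dist = max(b.target_span[0] - a.target_span[1],
                           a.target_span[0] - b.target_span[1], 0)
                if dist <= p.breakpoint_distance:
                    continue
                kind = "relocation"
            breakpoints.append(Breakpoint(name, b.query_span[0], kind))
            bad_contigs.add(name)
    return len(bad_contigs), breakpoints


def assembly_report(assembly: ContigSet, reference: Optional[ContigSet] = None,
                    genome_size: Optional[int] = None) -> Dict[str, object]:
    """Table-style metrics for one assembly (counts, N50/NG50, length,
    misassemblies and genome fraction when a reference is supplied)."""
    lengths = sorted((len(s) for _, s in assembly), reverse=True)
    rep: Dict[str, object] = {
        "contigs_ge_500bp": sum(1 for l in lengths if l >= 500),
        "contigs_ge_2kb": sum(1 for l in lengths if l >= 2000),
        "largest_contig": lengths[0] if lengths else 0,
        "total_length": sum(lengths),
        "n50": n50(lengths),
    }
    if genome_size:
        rep["ng50"] = ng50(lengths, genome_size)
    if reference is not None and len(assembly):
        n_mis, _ = count_misassemblies(assembly, reference)
        rep["misassemblies"] = n_mis
        rep["genome_fraction"] = round(genome_fraction(assembly, reference), 3)
    return rep
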