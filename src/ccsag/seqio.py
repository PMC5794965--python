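"""Sequence and alignment I/O primitives shared by every pipeline stage.

FASTA/FASTQ records, SAM-derived alignment records, and the CIGAR clip
geometry that the chimera classifier inspects. Coordinates are 0-based
half-open throughout; SAM's 1-based positions are converted at the parser
boundary. Quality encoding is fixed to Phred+33 — Phred+64 input is
rejected, never guessed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Tuple

import pysam

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_VALID_BASES = frozenset("ACGTN")

#: CIGAR operations that consume query bases.
_CONSUMES_QUERY = frozenset("MIS=X")
#: CIGAR operations that consume target (reference) bases.
_CONSUMES_TARGET = frozenset("MDN=X")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMP)[::-1]


class CigarError(ValueError):
    """Raised for CIGAR strings that do not conform to the SAM grammar."""


@dataclass
class ReadRecord:
    """One sequencing read, possibly quality-trimmed or a split fragment.

    ``origin`` tracks, for fragments produced by chimera splitting, the
    root read id and the half-open interval of the root read this record
    derives from; whole reads leave it as ``None``.
    """

    read_id: str
    sequence: str
    qualities: Sequence[int]
    sag_id: str = ""
    mate: int = 0  # 1, 2 or 0 (unpaired)
    truth: Optional[object] = None
    origin: Optional[Tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        bad = set(self.sequence.upper()) - _VALID_BASES
        if bad:
            raise ValueError(f"{self.read_id}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def root_id(self) -> str:
        return self.origin[0] if self.origin else self.read_id


@dataclass
class AlignmentRecord:
    """One mapping of a query segment onto a target sequence.

    ``query_span`` is given in the coordinates of the query string as
    provided to the aligner (for SAM input: as stored in the record), and
    ``left_clip``/``right_clip`` are the unaligned bases before/after the
    aligned block in the same frame. ``blocks`` lists ungapped
    (query_start, target_start, length) match blocks for pileup use.
    """

    query_id: str
    target_id: str = ""
    strand: str = "+"
    query_span: Tuple[int, int] = (0, 0)
    target_span: Tuple[int, int] = (0, 0)
    left_clip: int = 0
    right_clip: int = 0
    matches: int = 0
    alignment_length: int = 0
    is_mapped: bool = True
    blocks: Tuple[Tuple[int, int, int], ...] = ()

    @property
    def identity_percent(self) -> float:
        if self.alignment_length == 0:
            return 0.0
        return 100.0 * self.matches / self.alignment_length

    @property
    def aligned_query_len(self) -> int:
        return self.query_span[1] - self.query_span[0]

    @property
    def total_clip(self) -> int:
        return self.left_clip + self.right_clip

    @classmethod
    def unmapped(cls, query_id: str) -> "AlignmentRecord":
        return cls(query_id=query_id, is_mapped=False, strand="+")


@dataclass
class ContigSet:
    """Named contigs with a provenance tag.

    provenance ∈ {raw_sag, raw_composite, clean_composite,
    bridged_composite, reference}.
    """

    contigs: list  # list of (name, sequence)
    provenance: str = "raw_sag"
    sag_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(names) != len(set(names)):
            raise ValueError("contig names must be unique within a set")

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)

    def names(self) -> list:
        return [n for n, _ in self.contigs]

    def get(self, name: str) -> str:
        for n, s in self.contigs:
            if n == name:
                return s
        raise KeyError(name)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def filtered(self, min_len: int) -> "ContigSet":
        return ContigSet(
            [(n, s) for n, s in self.contigs if len(s) >= min_len],
            provenance=self.provenance,
            sag_ids=self.sag_ids,
        )


# ---------------------------------------------------------------------------
# CIGAR geometry


def tokenize_cigar(cigar: str) -> list:
    """Split a CIGAR string into (length, op) tuples, validating the grammar."""
    if cigar == "*":
        return []
    pos = 0
    out = []
    for m in _CIGAR_TOKEN.finditer(cigar):
        if m.start() != pos:
            raise CigarError(f"malformed CIGAR near {cigar[pos:pos + 8]!r}")
        out.append((int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(cigar):
        raise CigarError(f"malformed CIGAR near {cigar[pos:pos + 8]!r}")
    if not out:
        raise CigarError(f"malformed CIGAR {cigar!r}")
    return out


def parse_cigar(cigar: str, read_len: int) -> Tuple[int, int, int]:
    """Clip geometry (left_clip, aligned_query_len, right_clip) of a CIGAR.

    Soft (S) and hard (H) clips both count as clipped bases: both mark
    read ends excluded from the aligned block, and supplementary records
    report the same geometry with H. ``"*"`` yields (0, 0, 0): unmapped,
    no clips, no aligned bases.
    """
    tokens = tokenize_cigar(cigar)
    if not tokens:
        return 0, 0, 0
    left = 0
    i = 0
    while i < len(tokens) and tokens[i][1] in "SH":
        left += tokens[i][0]
        i += 1
    right = 0
    j = len(tokens) - 1
    while j >= i and tokens[j][1] in "SH":
        right += tokens[j][0]
        j -= 1
    aligned = sum(n for n, op in tokens[i:j + 1] if op in _CONSUMES_QUERY)
    for n, op in tokens[i:j + 1]:
        if op in "SH":
            raise CigarError(f"internal clip in CIGAR {cigar!r}")
    return left, aligned, right


def cigar_blocks(cigar: str, query_start: int, target_start: int):
    """Ungapped (query_start, target_start, length) blocks of a CIGAR walk."""
    q, t = query_start, target_start
    blocks = []
    for n, op in tokenize_cigar(cigar):
        if op in "M=X":
            blocks.append((q, t, n))
            q += n
            t += n
        elif op in "IS":
            q += n
        elif op in "DN":
            t += n
        # H and P consume nothing here
    return blocks


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list:
    """Read a FASTA file into a list of (name, sequence) tuples."""
    out = []
    name = None
    chunks: list = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out.append((name, "".join(chunks)))
    return out


def write_fasta(path, records: Iterable[Tuple[str, str]], width: int = 80) -> None:
    """Write (name, sequence) records as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)

_MAX_PHRED33 = 74  # 'J' = Q41; anything above strongly suggests Phred+64


def _decode_quals(qual: str, read_id: str) -> list:
    scores = [ord(c) - 33 for c in qual]
    if scores and min(ord(c) for c in qual) >= 64 and max(ord(c) for c in qual) > _MAX_PHRED33:
        raise ValueError(
            f"{read_id}: quality string looks Phred+64 encoded; only Phred+33 is accepted"
        )
    if any(s < 0 for s in scores):
        raise ValueError(f"{read_id}: quality character below '!' (Phred+33)")
    return scores


def encode_quals(scores: Sequence[int]) -> str:
    return "".join(chr(min(s, 41) + 33) for s in scores)


def _strip_mate_suffix(read_id: str) -> str:
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    return read_id


def read_fastq(path, sag_id: str = "", mate: int = 0) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a 4-line FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not seq:
                raise ValueError(f"{path}: truncated FASTQ record at {header.strip()!r}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record at {header.strip()!r}")
            rid = header[1:].split()[0]
            yield ReadRecord(
                read_id=_strip_mate_suffix(rid),
                sequence=seq.upper(),
                qualities=_decode_quals(qual, rid),
                sag_id=sag_id,
                mate=mate,
            )


def read_fastq_paired(path_r1, path_r2, sag_id: str = "") -> Iterator[Tuple[ReadRecord, ReadRecord]]:
    """Stream synchronized mate pairs from two FASTQ files.

    Ids are normalized (``/1``, ``/2`` suffixes stripped); a mate-id
    mismatch or unequal record counts raise with the offending id.
    """
    it1 = read_fastq(path_r1, sag_id=sag_id, mate=1)
    it2 = read_fastq(path_r2, sag_id=sag_id, mate=2)
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            lone = r1 or r2
            raise ValueError(f"desynchronized mates: unpaired record {lone.read_id!r}")
        if r1.read_id != r2.read_id:
            raise ValueError(f"desynchronized mates: {r1.read_id!r} vs {r2.read_id!r}")
        yield r1, r2


def write_fastq(path, reads: Iterable[ReadRecord]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{encode_quals(r.qualities)}\n")


# ---------------------------------------------------------------------------
# SAM

def read_sam(path) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM (or BAM) file, including secondary
    (0x100) and supplementary (0x800) records; FLAG 4 yields unmapped records.

    Identity is taken from the NM tag when present; otherwise matches are
    assumed equal to the aligned length.
    """
    with pysam.AlignmentFile(str(path), check_sq=True) as fh:
        if not fh.header.get("SQ"):
            raise ValueError(f"{path}: SAM header has no @SQ lines")
        for aln in fh:
            if aln.is_unmapped:
                yield AlignmentRecord.unmapped(aln.query_name)
                continue
            cigar = aln.cigarstring or "*"
            seq_len = aln.infer_read_length() or (len(aln.query_sequence or ""))
            left, aligned, right = parse_cigar(cigar, seq_len)
            blocks = tuple(cigar_blocks(cigar, 0, aln.reference_start))
            # shift query offsets so they are absolute in the stored sequence
            blocks = tuple((q, t, n) for q, t, n in blocks)
            aln_cols = sum(n for n, op in tokenize_cigar(cigar) if op in "M=XID")
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            matches = max(aln_cols - nm, 0)
            yield AlignmentRecord(
                query_id=aln.query_name,
                target_id=aln.reference_name,
                strand="-" if aln.is_reverse else "+",
                query_span=(left, left + aligned),
                target_span=(aln.reference_start, aln.reference_end),
                left_clip=left,
                right_clip=right,
                matches=matches,
                alignment_length=aln_cols,
                blocks=blocks,
            )


def write_sam(path, records: Iterable[Tuple[ReadRecord, AlignmentRecord]], targets: ContigSet) -> None:
    """Minimal SAM writer for aligner-adapter output (ungapped records)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in targets:
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for read, rec in records:
            if not rec.is_mapped:
                fh.write(f"{read.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t"
                         f"{read.sequence}\t{encode_quals(read.qualities)}\n")
                continue
            flag = 16 if rec.strand == "-" else 0
            seq = read.sequence if rec.strand == "+" else revcomp(read.sequence)
            quals = read.qualities if rec.strand == "+" else list(read.qualities)[::-1]
            qs, qe = rec.query_span
            if rec.strand == "-":
                qs, qe = len(seq) - rec.query_span[1], len(seq) - rec.query_span[0]
            parts = []
            if qs:
                parts.append(f"{qs}S")
            parts.append(f"{qe - qs}M")
            if len(seq) - qe:
                parts.append(f"{len(seq) - qe}S")
            fh.write(
                f"{read.read_id}\t{flag}\t{rec.target_id}\t{rec.target_span[0] + 1}\t60\t"
                f"{''.join(parts)}\t*\t0\t0\t{seq}\t{encode_quals(quals)}\n"
            )
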