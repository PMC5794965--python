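"""Aligner adapters.

The cleaning, bridging, ANI and evaluation stages all consume the same
adapter contract: an object indexed on a target :class:`~ccsag.seqio.ContigSet`
whose ``map_seq`` returns :class:`~ccsag.seqio.AlignmentRecord` lists.

Two backends are provided:

* :class:`SeedExtendAligner` — an internal exact-seed, ungapped x-drop
  extension aligner (15-mer seeds every 4 bp plus the final offset, so any
  window of ≥20 bp contains a seed). It reports all distinct local matches
  on both strands, which is what the soft-clip frequency classifier needs,
  and it makes the whole test suite runnable with no external binaries.
  It models substitutions only — adequate for short-read data without
  indel errors, and deliberately so: the chimera model it serves is a
  junction between ungapped segments.
* :class:`BwaMemAligner` — a thin subprocess wrapper around ``bwa mem``
  producing SAM parsed back through :func:`ccsag.seqio.read_sam`, for use
  on real data.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from .seqio import (
    AlignmentRecord,
    ContigSet,
    ReadRecord,
    read_sam,
    revcomp,
    write_fasta,
    write_fastq,
)


class SeedExtendAligner:
    """Exact k-mer seed + ungapped x-drop extension against a contig set.

    Scoring: match +1, mismatch -``mismatch_penalty``; extension stops when
    the running score drops ``xdrop`` below its maximum, and the reported
    segment is trimmed to the score maximum in each direction, so alignments
    end at the last base that improves the score. Alignments shorter than
    ``min_aln_len`` or below ``min_identity`` are dropped; one alignment is
    kept per (target, strand, diagonal).
    """

    def __init__(
        self,
        targets: ContigSet,
        k: int = 15,
        seed_step: int = 4,
        max_hits_per_seed: int = 100,
        mismatch_penalty: int = 3,
        xdrop: int = 12,
        min_aln_len: int = 20,
        min_identity: float = 90.0,
    ) -> None:
        self.targets = targets
        self.k = k
        self.seed_step = seed_step
        self.max_hits = max_hits_per_seed
        self.mismatch_penalty = mismatch_penalty
        self.xdrop = xdrop
        self.min_aln_len = min_aln_len
        self.min_identity = min_identity
        self._names: List[str] = []
        self._seqs: List[str] = []
        self._index: Dict[str, list] = {}
        for ci, (name, seq) in enumerate(targets):
            self._names.append(name)
            self._seqs.append(seq.upper())
        for ci, seq in enumerate(self._seqs):
            idx = self._index
            for pos in range(0, len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                if "N" in kmer:
                    continue
                hits = idx.get(kmer)
                if hits is None:
                    idx[kmer] = [(ci, pos)]
                elif len(hits) < max_hits_per_seed:
                    hits.append((ci, pos))

    # -- extension ---------------------------------------------------------

    def _extend(self, q: str, t: str, qpos: int, tpos: int) -> Tuple[int, int, int, int]:
        """Extend a seed match on one diagonal; returns (qs, qe, ts, matches)."""
        pen, drop = self.mismatch_penalty, self.xdrop
        # right
        i, j = qpos + self.k, tpos + self.k
        score = best = 0
        qe = qpos + self.k
        nq, nt = len(q), len(t)
        while i < nq and j < nt:
            score += 1 if q[i] == t[j] else -pen
            i += 1
            j += 1
            if score > best:
                best = score
                qe = i
            elif best - score >= drop:
                break
        # left
        i, j = qpos - 1, tpos - 1
        score = best = 0
        qs = qpos
        while i >= 0 and j >= 0:
            score += 1 if q[i] == t[j] else -pen
            if score > best:
                best = score
                qs = i
            elif best - score >= drop:
                break
            i -= 1
            j -= 1
        ts = tpos - (qpos - qs)
        matches = sum(1 for a, b in zip(q[qs:qe], t[ts:ts + (qe - qs)]) if a == b)
        return qs, qe, ts, matches

    def _seed_offsets(self, n: int) -> list:
        if n < self.k:
            return []
        offs = list(range(0, n - self.k + 1, self.seed_step))
        last = n - self.k
        if offs[-1] != last:
            offs.append(last)
        return offs

    def map_seq(self, query_id: str, seq: str, mode: str = "all") -> List[AlignmentRecord]:
        """Map one sequence; ``mode="all"`` reports every distinct local hit,
        ``mode="best"`` returns the single best record (early exit on a
        full-length match), and ``[]`` means unmapped."""
        seq = seq.upper()
        n = len(seq)
        found: Dict[Tuple[int, str, int], Tuple[int, int, int, int]] = {}
        best_full = None
        for strand in ("+", "-"):
            q = seq if strand == "+" else revcomp(seq)
            for off in self._seed_offsets(n):
                kmer = q[off:off + self.k]
                hits = self._index.get(kmer)
                if not hits:
                    continue
                for ci, pos in hits:
                    key = (ci, strand, pos - off)
                    prev = found.get(key)
                    if prev is not None and prev[0] <= off < prev[1]:
                        continue  # this diagonal already covers the seed
                    qs, qe, ts, matches = self._extend(q, self._seqs[ci], off, pos)
                    if prev is None or (qe - qs) > (prev[1] - prev[0]):
                        found[key] = (qs, qe, ts, matches)
                    if mode == "best" and qs == 0 and qe == n and matches >= n - 2:
                        best_full = (key, (qs, qe, ts, matches))
                        break
                if best_full:
                    break
            if best_full:
                break

        records = []
        items = [best_full] if best_full else sorted(found.items())
        for (ci, strand, _diag), (qs, qe, ts, matches) in items:
            length = qe - qs
            if length < self.min_aln_len:
                continue
            if 100.0 * matches / length < self.min_identity:
                continue
            if strand == "+":
                q_span = (qs, qe)
            else:  # convert back to original read coordinates
                q_span = (n - qe, n - qs)
            records.append(
                AlignmentRecord(
                    query_id=query_id,
                    target_id=self._names[ci],
                    strand=strand,
                    query_span=q_span,
                    target_span=(ts, ts + length),
                    left_clip=q_span[0],
                    right_clip=n - q_span[1],
                    matches=matches,
                    alignment_length=length,
                    blocks=((q_span[0], ts, length),),
                )
            )
        if mode == "best" and records:
            records.sort(key=lambda r: (-r.matches, r.target_id, r.target_span))
            return records[:1]
        records.sort(key=lambda r: (r.target_id, r.strand, r.target_span, r.query_span))
        return records

    def map_read(self, read: ReadRecord, mode: str = "all") -> List[AlignmentRecord]:
        return self.map_seq(read.read_id, read.sequence, mode=mode)


class BwaMemAligner:
    """``bwa mem`` adapter: index the targets once, map FASTQ batches to SAM.

    Secondary alignments are requested (``-a``) because the soft-clip
    frequency rule counts all records against the cross-reference.
    """

    def __init__(self, targets: ContigSet, binary: str = "bwa", threads: int = 1) -> None:
        if shutil.which(binary) is None:
            raise RuntimeError(
                f"external mapper binary {binary!r} not found on PATH; "
                "install bwa or use the internal aligner"
            )
        self.binary = binary
        self.threads = threads
        self._dir = tempfile.TemporaryDirectory(prefix="ccsag_bwa_")
        self.ref = Path(self._dir.name) / "ref.fa"
        write_fasta(self.ref, list(targets))
        self._run([binary, "index", str(self.ref)])

    def _run(self, cmd, **kw):
        proc = subprocess.run(cmd, capture_output=True, text=True, **kw)
        if proc.returncode != 0:
            raise RuntimeError(
                f"{cmd[0]} failed (exit {proc.returncode}): {proc.stderr[-500:]}"
            )
        return proc

    def map_reads(self, reads: Sequence[ReadRecord]) -> Dict[str, List[AlignmentRecord]]:
        fq = Path(self._dir.name) / "reads.fq"
        sam = Path(self._dir.name) / "out.sam"
        write_fastq(fq, reads)
        proc = self._run(
            [self.binary, "mem", "-a", "-t", str(self.threads), str(self.ref), str(fq)]
        )
        sam.write_text(proc.stdout)
        out: Dict[str, List[AlignmentRecord]] = {r.read_id: [] for r in reads}
        for rec in read_sam(sam):
            if rec.is_mapped:
                out.setdefault(rec.query_id, []).append(rec)
        return out


def make_aligner(targets: ContigSet, backend: str = "internal", **kw):
    """Aligner factory used by the CLI (``internal`` or ``bwa``)."""
    if backend == "internal":
        return SeedExtendAligner(targets, **kw)
    if backend == "bwa":
        return BwaMemAligner(targets, **kw)
    raise ValueError(f"unknown aligner backend {backend!r}")
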