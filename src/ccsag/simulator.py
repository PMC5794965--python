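"""Synthetic multi-SAG read sets with MDA-like pathologies and full truth.

Multiple displacement amplification (MDA) of a single cell produces
strong locus-to-locus coverage bias, complete dropout of some loci, and
chimeric molecules joining noncontiguous (possibly inverted) genomic
segments. The generator models this with per-1 kb-window lognormal
amplification weights drawn independently per SAG, a fraction of windows
zeroed (dropout), two-arm chimeric reads with optional inversion of the
second arm, uniform substitution errors, contaminant reads from a second
genome, and strain-internal SNPs carried by a fixed subset of SAGs.
Every read carries a truth label (arm intervals, strands, contaminant
flag) so downstream stages can be scored exactly.

It makes no claim of mechanistic MDA fidelity: the lognormal-window model
simply reproduces the 50–80% single-SAG coverage regime with a tunable σ.
Default parameters correspond to the study conditions used throughout the
test suite: a 500 kb genome, 6 SAGs, 2,000 reads per SAG, 15% chimeric
reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .seqio import ContigSet, ReadRecord, revcomp, write_fasta, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: constant base quality of simulated reads; error positions get Q20 so
#: QC behaviour can be exercised with explicit fixtures instead.
_Q_GOOD = 35
_Q_ERR = 20


@dataclass
class SimParams:
    genome_len: int = 500_000
    gc_content: float = 0.5
    n_sags: int = 6
    reads_per_sag: int = 2000
    read_len: int = 300
    paired: bool = False
    insert_mean: int = 400
    insert_sd: int = 40
    window: int = 1000
    amp_bias_sigma: float = 0.8
    dropout_fraction: float = 0.2
    chimera_fraction: float = 0.15
    inversion_prob: float = 0.5
    min_arm_len: int = 20
    error_rate: float = 0.0
    contam_fraction: float = 0.0
    contam_genome_len: int = 100_000
    n_strain_snps: int = 0
    snp_sag_fraction: float = 0.375
    per_site_carriers: bool = False
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("gc_content", "dropout_fraction", "chimera_fraction",
                     "inversion_prob", "error_rate", "contam_fraction",
                     "snp_sag_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.genome_len < 10 * self.read_len:
            raise ValueError("genome_len must be ≥ 10 × read_len")


@dataclass
class TruthLabel:
    read_id: str
    is_chimeric: bool = False
    arm_intervals: List[Tuple[Tuple[int, int], str]] = field(default_factory=list)
    is_contaminant: bool = False
    source_sag: str = ""
    snps_overlapped: List[int] = field(default_factory=list)


def make_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random i.i.d. genome with P(G)+P(C) = ``gc``; deterministic per seed."""
    if length < 1:
        raise ValueError("length must be ≥ 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def plant_strain_snps(genome: str, n_snps: int, n_sags: int,
                      snp_sag_fraction: float, seed: int = 0,
                      per_site_carriers: bool = False
                      ) -> Tuple[List[str], List[dict]]:
    """Derive per-SAG genomes carrying planted strain SNPs.

    ``n_snps`` positions are chosen without replacement, each with an
    alternate base distinct from the reference. A fixed subset of
    ⌈fraction·n_sags⌉ SAGs carries the alternate allele at every site
    (or a per-site random subset with ``per_site_carriers``). Returns the
    SAG genome strings and a truth table of dicts (position, ref, alt,
    carrier indices).
    """
    if n_snps > len(genome) // 1000:
        raise ValueError("n_snps too dense: at most one per kb")
    rng = np.random.default_rng(seed)
    n_carriers = int(np.ceil(snp_sag_fraction * n_sags)) if n_snps else 0
    positions = sorted(rng.choice(len(genome), size=n_snps, replace=False)) if n_snps else []
    fixed_carriers = sorted(rng.permutation(n_sags)[:n_carriers].tolist())
    table = []
    alt_at: Dict[int, str] = {}
    carriers_at: Dict[int, List[int]] = {}
    for pos in positions:
        ref = genome[pos]
        alt = ref
        while alt == ref:
            alt = "ACGT"[rng.integers(4)]
        carriers = (sorted(rng.permutation(n_sags)[:n_carriers].tolist())
                    if per_site_carriers else fixed_carriers)
        alt_at[pos] = alt
        carriers_at[pos] = carriers
        table.append({"position": int(pos), "ref": ref, "alt": alt,
                      "carrier_sags": carriers})
    genomes = []
    for s in range(n_sags):
        g = list(genome)
        for pos in positions:
            if s in carriers_at[pos]:
                g[pos] = alt_at[pos]
        genomes.append("".join(g))
    return genomes, table


def _window_weights(genome_len: int, p: SimParams, rng) -> np.ndarray:
    n_win = max(1, genome_len // p.window)
    w = (rng.lognormal(mean=0.0, sigma=p.amp_bias_sigma, size=n_win)
         if p.amp_bias_sigma > 0 else np.ones(n_win))
    drop = rng.random(n_win) < p.dropout_fraction
    w[drop] = 0.0
    if not w.sum():
        raise ValueError("no amplifiable genome: all windows dropped")
    return w


def _draw_start(weights: np.ndarray, p: SimParams, genome_len: int,
                seg_len: int, rng) -> int:
    win = rng.choice(len(weights), p=weights / weights.sum())
    start = win * p.window + rng.integers(p.window)
    return int(min(start, genome_len - seg_len))


def _apply_errors(seq: str, quals: List[int], p: SimParams, rng) -> Tuple[str, List[int]]:
    if p.error_rate <= 0:
        return seq, quals
    n_err = rng.binomial(len(seq), p.error_rate)
    if not n_err:
        return seq, quals
    s = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        alt = s[pos]
        while alt == s[pos]:
            alt = "ACGT"[rng.integers(4)]
        s[pos] = alt
        quals[pos] = _Q_ERR
    return "".join(s), quals


def simulate_sag_reads(sag_genome: str, params: SimParams, sag_id: str = "sag00",
                       seed: Optional[int] = None,
                       contam_genome: Optional[str] = None) -> List[ReadRecord]:
    """Simulate one SAG's read set with truth labels.

    Read start positions follow the SAG's amplification-weight profile;
    a ``chimera_fraction`` of reads concatenate two independently placed
    arms (each ≥ ``min_arm_len``), the second arm reverse-complemented
    with probability ``inversion_prob``.
    """
    p = params
    rng = np.random.default_rng(p.seed if seed is None else seed)
    weights = _window_weights(len(sag_genome), p, rng)
    reads: List[ReadRecord] = []
    for i in range(p.reads_per_sag):
        rid = f"{sag_id}.r{i:06d}"
        u = rng.random()
        if contam_genome is not None and u < p.contam_fraction:
            start = int(rng.integers(len(contam_genome) - p.read_len + 1))
            seq = contam_genome[start:start + p.read_len]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            truth = TruthLabel(rid, is_contaminant=True, source_sag=sag_id)
        elif u < p.contam_fraction + p.chimera_fraction:
            arm1 = int(rng.integers(p.min_arm_len, p.read_len - p.min_arm_len + 1))
            arm2 = p.read_len - arm1
            s1 = _draw_start(weights, p, len(sag_genome), arm1, rng)
            s2 = _draw_start(weights, p, len(sag_genome), arm2, rng)
            strand1 = "+" if rng.random() < 0.5 else "-"
            invert = rng.random() < p.inversion_prob
            strand2 = ("-" if strand1 == "+" else "+") if invert else strand1
            seg1 = sag_genome[s1:s1 + arm1]
            seg2 = sag_genome[s2:s2 + arm2]
            if strand1 == "-":
                seg1 = revcomp(seg1)
            if strand2 == "-":
                seg2 = revcomp(seg2)
            seq = seg1 + seg2
            truth = TruthLabel(
                rid, is_chimeric=True, source_sag=sag_id,
                arm_intervals=[((s1, s1 + arm1), strand1), ((s2, s2 + arm2), strand2)],
            )
        else:
            start = _draw_start(weights, p, len(sag_genome), p.read_len, rng)
            seq = sag_genome[start:start + p.read_len]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            truth = TruthLabel(
                rid, source_sag=sag_id,
                arm_intervals=[((start, start + p.read_len), strand)],
            )
        quals = [_Q_GOOD] * len(seq)
        seq, quals = _apply_errors(seq, quals, p, rng)
        reads.append(ReadRecord(rid, seq, quals, sag_id=sag_id, truth=truth))
    return reads


@dataclass
class SimulatedGroup:
    """In-memory result of one group simulation."""

    params: SimParams
    base_genome: str
    sag_genomes: List[str]
    sag_ids: List[str]
    reads: Dict[str, List[ReadRecord]]
    snp_table: List[dict]
    contam_genome: Optional[str] = None

    def genome_contigs(self) -> ContigSet:
        return ContigSet([("genome", self.base_genome)], provenance="reference")


def simulate_group_data(params: SimParams) -> SimulatedGroup:
    """Simulate a complete multi-SAG group in memory."""
    if params.n_sags < 2:
        raise ValueError("a group needs n_sags ≥ 2")
    base = make_genome(params.genome_len, params.gc_content, seed=params.seed)
    contam = (make_genome(params.contam_genome_len, params.gc_content,
                          seed=params.seed + 999_983)
              if params.contam_fraction > 0 else None)
    sag_genomes, snp_table = plant_strain_snps(
        base, params.n_strain_snps, params.n_sags, params.snp_sag_fraction,
        seed=params.seed + 101, per_site_carriers=params.per_site_carriers)
    sag_ids = [f"sag{i:02d}" for i in range(params.n_sags)]
    reads = {}
    for i, sid in enumerate(sag_ids):
        reads[sid] = simulate_sag_reads(
            sag_genomes[i], params, sag_id=sid,
            seed=params.seed * 1_000 + i + 1, contam_genome=contam)
    return SimulatedGroup(params, base, sag_genomes, sag_ids, reads, snp_table,
                          contam_genome=contam)


def simulate_group(params: SimParams, out_dir) -> Path:
    """Write a complete on-disk fixture: per-SAG FASTQ, truth JSON, genome
    FASTA and a manifest recording the parameters and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_group_data(params)
    write_fasta(out / "genome.fasta", [("genome", data.base_genome)])
    write_fasta(out / "sag_genomes.fasta",
                [(sid, g) for sid, g in zip(data.sag_ids, data.sag_genomes)])
    if data.contam_genome:
        write_fasta(out / "contaminant.fasta", [("contaminant", data.contam_genome)])
    truth: Dict[str, dict] = {"schema_version": 1, "snps": data.snp_table, "reads": {}}
    for sid in data.sag_ids:
        write_fastq(out / f"{sid}.fastq", data.reads[sid])
        for r in data.reads[sid]:
            t = r.truth
            truth["reads"][r.read_id] = {
                "is_chimeric": t.is_chimeric,
                "is_contaminant": t.is_contaminant,
                "arms": [[list(iv), strand] for iv, strand in t.arm_intervals],
                "source_sag": t.source_sag,
            }
    (out / "truth.json").write_text(json.dumps(truth))
    manifest = {"tool": "ccsag simulate", "seed": params.seed,
                "params": asdict(params), "sags": data.sag_ids}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out
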