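"""End-to-end orchestration: QC → grouping → cleaning → co-assembly →
bridging → metrics → SNPs, with a run manifest for reproducibility.

The pipeline is deterministic: re-running with an identical configuration
produces byte-identical manifest-tracked outputs. In ``internal`` mode the
aligner is the built-in seed-and-extend backend and the assembler is the
coverage-truth stub (which requires the simulation's genome FASTA in the
input directory); ``external`` mode switches to bwa and SPAdes for real
data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from .align import SeedExtendAligner, make_aligner
from .bridge import BridgeParams, SpadesAssembler, TruthAssembler, run_step3
from .cleaner import CleanerParams, build_cross_reference, run_cleaning, total_bases
from .grouping import GroupingParams, QcParams, group_sags, qc_reads
from .metrics import assembly_report, genome_fraction
from .seqio import ContigSet, read_fasta, read_fastq, write_fasta, write_fastq
from .snps import Pileup, SnpParams, call_snps, write_snp_tsv, write_vcf

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters plus paths; defaults are the published
    thresholds (Q25/50%, Q20 trim, 20 bp, 16S ≥99%, ANI >95% over ≥500 bp,
    clip ≤9, ≥99%/≥250 bp bridging, depth ≥5, 99.9% mismatch)."""

    input_dir: str = ""
    output_dir: str = ""
    mode: str = "internal"  # internal | external
    seed: int = 1
    threads: int = 1
    qc: QcParams = field(default_factory=QcParams)
    grouping: GroupingParams = field(default_factory=GroupingParams)
    cleaner: CleanerParams = field(default_factory=CleanerParams)
    bridge: BridgeParams = field(default_factory=BridgeParams)
    snp: SnpParams = field(default_factory=SnpParams)

    def to_dict(self) -> dict:
        return asdict(self)


def _discover_sags(input_dir: Path) -> List[str]:
    return sorted(p.stem for p in input_dir.glob("*.fastq"))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on a SAG directory and return the output directory.

    Expects ``<input_dir>/<sag_id>.fastq`` per SAG; internal mode also
    expects ``genome.fasta`` (the simulation truth) for the stub
    assembler. Outputs: filtered reads, grouping TSV, per-cycle cleaning
    TSVs, the three composite FASTAs, metrics JSON, SNP TSV/VCF and a
    manifest tying them together.
    """
    inp = Path(config.input_dir)
    out = Path(config.output_dir)
    if not inp.is_dir():
        raise FileNotFoundError(f"input directory {inp} does not exist")
    sag_ids = _discover_sags(inp)
    if len(sag_ids) < 2:
        raise ValueError("pipeline requires ≥2 SAG FASTQ files")
    out.mkdir(parents=True, exist_ok=True)
    # paths are omitted from the recorded config so that identical runs in
    # different directories remain byte-identical
    recorded = {k: v for k, v in config.to_dict().items()
                if k not in ("input_dir", "output_dir")}
    manifest: Dict[str, object] = {
        "tool": "ccsag", "version": __version__, "seed": config.seed,
        "config": recorded, "stages": {}, "outputs": [],
    }

    def track(path: Path) -> Path:
        manifest["outputs"].append(str(path.relative_to(out)))
        return path

    # stage 1a: QC
    raw_reads, qc_reports = {}, {}
    for sid in sag_ids:
        reads = list(read_fastq(inp / f"{sid}.fastq", sag_id=sid))
        kept, report = qc_reads(reads, config.qc)
        raw_reads[sid] = kept
        qc_reports[sid] = report
    with open(track(out / "qc_report.tsv"), "w") as fh:
        fh.write("sag_id\tn_input\tn_output\tlow_quality\tshort\tn_content"
                 "\tunpaired\tbases_trimmed\n")
        for sid in sag_ids:
            r = qc_reports[sid]
            fh.write(f"{sid}\t{r.n_input}\t{r.n_output}\t{r.removed_low_quality}"
                     f"\t{r.removed_short}\t{r.removed_n_content}"
                     f"\t{r.removed_unpaired_mate}\t{r.bases_trimmed}\n")
    manifest["stages"]["qc"] = {sid: qc_reports[sid].n_output for sid in sag_ids}

    # stage 1b: per-SAG raw contigs + grouping
    if config.mode == "internal":
        genome = ContigSet(read_fasta(inp / "genome.fasta"), provenance="reference")
        assembler = TruthAssembler(genome)
    else:
        assembler = SpadesAssembler(threads=config.threads)
    raw_contigs: Dict[str, ContigSet] = {}
    for sid in sag_ids:
        contigs = ContigSet(assembler.assemble([raw_reads[sid]]),
                            provenance="raw_sag", sag_ids=(sid,))
        raw_contigs[sid] = contigs.filtered(config.grouping.min_contig_len)
        write_fasta(track(out / f"{sid}.raw_contigs.fasta"), list(raw_contigs[sid]))
    groups = group_sags([(sid, None, raw_contigs[sid]) for sid in sag_ids],
                        config.grouping)
    with open(track(out / "grouping.tsv"), "w") as fh:
        fh.write("sag_id\tgroup_id\tbest_ani\n")
        for g in groups:
            for i, sid in enumerate(g.sag_ids):
                row = [v for j, v in enumerate(g.pairwise_ani[i]) if j != i and v == v]
                best = f"{max(row):.3f}" if row else "NA"
                fh.write(f"{sid}\t{g.group_id}\t{best}\n")
    manifest["stages"]["grouping"] = {g.group_id: g.sag_ids for g in groups}

    # stages 2+3 per group of ≥2 SAGs
    group = max(groups, key=lambda g: len(g.sag_ids))
    if len(group.sag_ids) < 2:
        raise ValueError("no group with ≥2 SAGs; cross-reference cleaning impossible")
    clean_reads, unmapped_reads, cycle_rows = {}, {}, []
    for sid in group.sag_ids:
        cross = build_cross_reference(group, sid, config.grouping.min_contig_len)
        if config.mode == "internal":
            aligner = SeedExtendAligner(cross)
        else:
            aligner = _BwaReadMapper(cross)
        clean, unmapped, reports = run_cleaning(
            raw_reads[sid], cross, aligner=aligner, params=config.cleaner, sag_id=sid)
        clean_reads[sid] = clean
        unmapped_reads[sid] = unmapped
        write_fastq(track(out / f"{sid}.clean.fastq"), clean)
        write_fastq(track(out / f"{sid}.unmapped.fastq"), unmapped)
        for r in reports:
            cycle_rows.append((sid, r))
    with open(track(out / "cleaning_cycles.tsv"), "w") as fh:
        fh.write("sag_id\tcycle\tn_input\tn_clean\tn_pending\tn_unmapped"
                 "\tbases_discarded\n")
        for sid, r in cycle_rows:
            fh.write(f"{sid}\t{r.cycle}\t{r.n_input}\t{r.n_clean}\t{r.n_pending}"
                     f"\t{r.n_unmapped}\t{r.bases_discarded}\n")
    manifest["stages"]["cleaning"] = {
        sid: {"clean": len(clean_reads[sid]), "unmapped": len(unmapped_reads[sid])}
        for sid in group.sag_ids}

    raw_comp, clean_comp, bridged, breport = run_step3(
        {s: clean_reads[s] for s in group.sag_ids},
        {s: raw_reads[s] for s in group.sag_ids},
        assembler, config.bridge)
    write_fasta(track(out / "raw_composite.fasta"), list(raw_comp))
    write_fasta(track(out / "clean_composite.fasta"), list(clean_comp))
    write_fasta(track(out / "bridged_composite.fasta"), list(bridged))
    with open(track(out / "bridging.tsv"), "w") as fh:
        fh.write("kind\traw_contig\tleft\tright\tbases\n")
        for j in breport.joins:
            fh.write(f"join\t{j['raw_contig']}\t{j['left']}\t{j['right']}"
                     f"\t{j['inserted_bases']}\n")
        for e in breport.extensions:
            fh.write(f"extension\t{e['raw_contig']}\t{e['contig']}\t{e['end']}"
                     f"\t{e['added_bases']}\n")
    manifest["stages"]["coassembly"] = {
        "raw_composite": len(raw_comp), "clean_composite": len(clean_comp),
        "bridged_composite": len(bridged), "joins": len(breport.joins)}

    # metrics (self-referential: bridged composite is the working reference)
    metrics = {
        "raw_composite": assembly_report(raw_comp),
        "clean_composite": assembly_report(clean_comp),
        "bridged_composite": assembly_report(bridged),
    }
    track(out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    manifest["stages"]["metrics"] = metrics

    # SNPs: cleaned reads per SAG vs the bridged composite
    pileup = Pileup(bridged)
    snp_aligner = SeedExtendAligner(bridged)
    for sid in group.sag_ids:
        pileup.add_sag(sid, clean_reads[sid], snp_aligner)
    calls = call_snps(pileup.sites(), config.snp)
    write_snp_tsv(track(out / "snps.tsv"), calls)
    write_vcf(track(out / "snps.vcf"), calls, bridged)
    manifest["stages"]["snps"] = {"n_calls": len(calls)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


class _BwaReadMapper:
    """map_read adapter over the bwa backend for external mode."""

    def __init__(self, cross_ref: ContigSet) -> None:
        from .align import BwaMemAligner
        self._bwa = BwaMemAligner(cross_ref)

    def map_read(self, read, mode="all"):
        return self._bwa.map_reads([read]).get(read.read_id, [])


def report(output_dir) -> str:
    """Render a human-readable markdown summary of a pipeline run."""
    out = Path(output_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    lines = ["# ccsag run summary", ""]
    grouping = manifest["stages"]["grouping"]
    lines.append(f"SAG groups: {len(grouping)}")
    for gid, sids in sorted(grouping.items()):
        lines.append(f"- {gid}: {', '.join(sids)}")
    lines.append("")
    cleaning = manifest["stages"]["cleaning"]
    lines.append("## Cleaning (reads)")
    lines.append("sag | clean | unmapped")
    lines.append("--- | --- | ---")
    for sid, c in sorted(cleaning.items()):
        lines.append(f"{sid} | {c['clean']} | {c['unmapped']}")
    lines.append("")
    lines.append("## Assemblies")
    lines.append("assembly | contigs ≥0.5 kb | largest | total | N50")
    lines.append("--- | --- | --- | --- | ---")
    for name, m in sorted(manifest["stages"]["metrics"].items()):
        lines.append(f"{name} | {m['contigs_ge_500bp']} | {m['largest_contig']}"
                     f" | {m['total_length']} | {m['n50']}")
    lines.append("")
    n_snps = manifest["stages"]["snps"]["n_calls"]
    lines.append("## SNPs")
    lines.append(f"{n_snps} site(s) detected" if n_snps else "none detected")
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text
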