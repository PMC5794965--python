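"""Cross-reference chimera classification, splitting and cycle iteration."""

import pytest

from ccsag.align import SeedExtendAligner
from ccsag.cleaner import (
    CleanerParams,
    build_cross_reference,
    classify_read,
    clean_cycle,
    run_cleaning,
    split_chimera,
    total_bases,
)
from ccsag.grouping import SagGroup
from ccsag.seqio import AlignmentRecord, ContigSet, ReadRecord, revcomp
from ccsag.simulator import SimParams, make_genome, simulate_group_data


def _aln(clip_left, aligned, clip_right, query_id="r", target_id="t"):
    n = clip_left + aligned + clip_right
    return AlignmentRecord(
        query_id=query_id, target_id=target_id,
        query_span=(clip_left, clip_left + aligned),
        target_span=(0, aligned), left_clip=clip_left, right_clip=clip_right,
        matches=aligned, alignment_length=aligned,
    )


class TestClassifyRead:
    @pytest.mark.parametrize(
        "n_complete,n_partial,label",
        [(2, 1, "clean"), (1, 1, "clean"), (0, 3, "potential_chimera"),
         (0, 0, "unmapped"), (1, 0, "clean"), (3, 5, "potential_chimera")],
    )
    def test_frequency_rule(self, n_complete, n_partial, label):
        alns = [_aln(0, 100, 0) for _ in range(n_complete)]
        alns += [_aln(40, 60, 0) for _ in range(n_partial)]
        assert classify_read(alns).label == label

    def test_small_clips_count_as_complete(self):
        # total clip 9 ≤ default tolerance
        assert classify_read([_aln(4, 91, 5)]).label == "clean"
        # strict reading restored with tolerance 0
        strict = CleanerParams(max_clip_for_complete=0, min_fragment_len=20)
        assert classify_read([_aln(4, 91, 5)], strict).label == "potential_chimera"

    def test_mixed_query_ids_rejected(self):
        with pytest.raises(ValueError):
            classify_read([_aln(0, 100, 0, "a"), _aln(0, 100, 0, "b")])


class TestSplitChimera:
    def _read(self, n, rid="r"):
        return ReadRecord(rid, "A" * n, [35] * n)

    def test_two_fragment_split(self):
        read = self._read(150)
        frags, discarded = split_chimera(read, [_aln(30, 120, 0)])
        assert sorted(len(f) for f in frags) == [30, 120]
        assert discarded == 0

    def test_short_piece_discarded(self):
        read = self._read(100)
        frags, discarded = split_chimera(read, [_aln(15, 85, 0)])
        assert [len(f) for f in frags] == [85]
        assert discarded == 15

    def test_double_clip_split(self):
        read = self._read(100)
        frags, discarded = split_chimera(read, [_aln(10, 80, 10)])
        assert [len(f) for f in frags] == [80]
        assert discarded == 20

    def test_template_is_largest_partial(self):
        read = self._read(150)
        frags, _ = split_chimera(read, [_aln(100, 50, 0), _aln(30, 120, 0)])
        assert sorted(len(f) for f in frags) == [30, 120]

    def test_origin_spans_partition_read(self):
        read = self._read(150)
        frags, discarded = split_chimera(read, [_aln(30, 120, 0)])
        spans = sorted((f.origin[1], f.origin[2]) for f in frags)
        covered = sum(e - s for s, e in spans)
        assert covered + discarded == 150
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # non-overlapping

    def test_requires_partial_alignment(self):
        with pytest.raises(ValueError):
            split_chimera(self._read(100), [_aln(0, 100, 0)])

    def test_qualities_sliced_with_sequence(self):
        read = ReadRecord("r", "ACGT" * 30, list(range(40)) * 3)
        frags, _ = split_chimera(read, [_aln(40, 80, 0)])
        for f in frags:
            s, e = f.origin[1], f.origin[2]
            assert list(f.qualities) == (list(range(40)) * 3)[s:e]


class TestCrossReference:
    def _group(self):
        g = make_genome(3000, 0.5, seed=1)
        contigs = {s: ContigSet([(f"c_{s}", g)], provenance="raw_sag")
                   for s in ("A", "B", "C")}
        return SagGroup("g1", ["A", "B", "C"], contigs=contigs)

    def test_excludes_own_contigs(self):
        cross = build_cross_reference(self._group(), "A")
        assert all(n.startswith(("B.", "C.")) for n in cross.names())

    def test_two_member_group(self):
        group = self._group()
        group.sag_ids = ["A", "B"]
        cross = build_cross_reference(group, "B")
        assert all(n.startswith("A.") for n in cross.names())

    def test_singleton_rejected(self):
        group = self._group()
        group.sag_ids = ["A"]
        with pytest.raises(ValueError, match="≥2 SAGs"):
            build_cross_reference(group, "A")


class TestCleaningCycles:
    def test_error_free_reads_all_clean(self):
        g = make_genome(20_000, 0.5, seed=2)
        cross = ContigSet([("c", g)])
        reads = [ReadRecord(f"r{i}", g[i * 150:(i + 1) * 150], [35] * 150)
                 for i in range(40)]
        clean, unmapped, reports = run_cleaning(reads, cross)
        assert len(clean) == 40 and not unmapped
        assert len(reports) == 1

    def test_foreign_reads_all_unmapped(self):
        cross = ContigSet([("c", make_genome(20_000, 0.5, seed=3))])
        other = make_genome(10_000, 0.5, seed=4)
        reads = [ReadRecord(f"r{i}", other[i * 150:(i + 1) * 150], [35] * 150)
                 for i in range(20)]
        clean, unmapped, _ = run_cleaning(reads, cross)
        assert not clean and len(unmapped) == 20

    def test_two_arm_chimera_resolved_in_two_cycles(self):
        g = make_genome(50_000, 0.5, seed=5)
        cross = ContigSet([("c", g)])
        read = ReadRecord("chim", g[1000:1060] + g[30000:30090], [35] * 150)
        aligner = SeedExtendAligner(cross)
        cycle1 = clean_cycle([read], aligner)
        assert len(cycle1.pending) == 2
        cycle2 = clean_cycle(cycle1.pending, aligner)
        assert len(cycle2.clean) == 2 and not cycle2.pending

    def test_three_arm_chimera_recovered(self):
        g = make_genome(60_000, 0.5, seed=6)
        cross = ContigSet([("c", g)])
        read = ReadRecord(
            "chim3", g[1000:1050] + g[20000:20060] + revcomp(g[40000:40040]),
            [35] * 150)
        clean, unmapped, reports = run_cleaning([read], cross)
        assert len(clean) == 3 and not unmapped
        assert sorted(len(r) for r in clean) == [40, 50, 60]
        assert 2 <= len(reports) <= 3

    def test_base_conservation_and_termination(self):
        p = SimParams(genome_len=60_000, n_sags=2, reads_per_sag=300,
                      chimera_fraction=0.2, seed=9)
        data = simulate_group_data(p)
        cross = ContigSet([("g", data.sag_genomes[1])])
        reads = data.reads["sag00"]
        clean, unmapped, reports = run_cleaning(reads, cross)
        discarded = sum(r.bases_discarded for r in reports)
        assert total_bases(reads) == total_bases(clean) + total_bases(unmapped) + discarded
        assert len(reports) <= 300 // 20  # termination bound

    def test_idempotence_on_clean_output(self):
        p = SimParams(genome_len=60_000, n_sags=2, reads_per_sag=200,
                      chimera_fraction=0.2, seed=10)
        data = simulate_group_data(p)
        cross = ContigSet([("g", data.sag_genomes[1])])
        aligner = SeedExtendAligner(cross)
        clean1, _, _ = run_cleaning(data.reads["sag00"], cross, aligner=aligner)
        clean2, unmapped2, _ = run_cleaning(clean1, cross, aligner=aligner)
        assert [r.read_id for r in clean2] == [r.read_id for r in clean1]
        assert [r.sequence for r in clean2] == [r.sequence for r in clean1]
        assert not unmapped2

    def test_determinism(self):
        p = SimParams(genome_len=60_000, n_sags=2, reads_per_sag=200,
                      chimera_fraction=0.2, seed=11)
        data = simulate_group_data(p)
        cross = ContigSet([("g", data.sag_genomes[1])])
        out1 = run_cleaning(data.reads["sag00"], cross)
        out2 = run_cleaning(data.reads["sag00"], cross)
        assert [(r.read_id, r.sequence) for r in out1[0]] == \
               [(r.read_id, r.sequence) for r in out2[0]]
        assert out1[2] == out2[2]

    def test_truth_recovery_rates(self):
        """≥99% of simulated chimeras flagged in cycle 1; ≤1% of clean reads
        flagged (error-free, arms ≥20 bp, exact internal aligner)."""
        p = SimParams(genome_len=200_000, n_sags=2, reads_per_sag=500,
                      chimera_fraction=0.3, amp_bias_sigma=0.0,
                      dropout_fraction=0.0, seed=12)
        data = simulate_group_data(p)
        aligner = SeedExtendAligner(ContigSet([("g", data.sag_genomes[1])]))
        flagged_chim = flagged_ok = n_chim = n_ok = 0
        for read in data.reads["sag00"]:
            label = classify_read(aligner.map_read(read)).label
            if read.truth.is_chimeric:
                n_chim += 1
                flagged_chim += label == "potential_chimera"
            else:
                n_ok += 1
                flagged_ok += label == "potential_chimera"
        assert flagged_chim / n_chim >= 0.99
        assert flagged_ok / n_ok <= 0.01
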