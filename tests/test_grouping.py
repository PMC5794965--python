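"""Read QC, 16S extraction, identity/ANI and SAG grouping."""

import math

import numpy as np
import pytest

from ccsag.grouping import (
    GroupingParams,
    PRIMER_341F,
    PRIMER_805R,
    QcParams,
    extract_16s_v3v4,
    group_sags,
    pairwise_ani,
    qc_reads,
    seq_identity,
)
from ccsag.seqio import ContigSet, ReadRecord, revcomp
from ccsag.simulator import make_genome


def _read(seq, quals, rid="r"):
    return ReadRecord(rid, seq, quals)


class TestQcRules:
    def test_low_quality_read_discarded(self):
        # 50 of 100 bases below Phred 25 → rule 1
        read = _read("A" * 100, [24] * 50 + [30] * 50)
        kept, rep = qc_reads([read])
        assert kept == [] and rep.removed_low_quality == 1

    def test_three_prime_trim(self):
        read = _read("A" * 100, [30] * 95 + [19] * 5)
        kept, rep = qc_reads([read])
        assert len(kept[0]) == 95
        assert rep.bases_trimmed == 5

    def test_short_after_trim_discarded(self):
        read = _read("A" * 25, [30] * 19 + [10] * 6)
        kept, rep = qc_reads([read])
        assert kept == [] and rep.removed_short == 1

    def test_n_content_discarded(self):
        read = _read("N" + "A" * 99, [30] * 100)  # 1% N
        kept, rep = qc_reads([read])
        assert kept == [] and rep.removed_n_content == 1

    def test_perfect_pair_passes_unchanged(self):
        pair = (_read("ACGT" * 25, [38] * 100, "p"), _read("TGCA" * 25, [38] * 100, "p"))
        kept, rep = qc_reads([pair])
        assert [r.sequence for r in kept] == [pair[0].sequence, pair[1].sequence]
        assert rep.n_removed == 0

    def test_mate_of_discarded_read_discarded(self):
        good = _read("ACGT" * 25, [38] * 100, "p")
        bad = _read("A" * 100, [10] * 100, "p")
        kept, rep = qc_reads([(good, bad)])
        assert kept == []
        assert rep.removed_unpaired_mate == 1

    def test_counts_balance(self):
        reads = [
            _read("A" * 100, [24] * 60 + [30] * 40, "bad1"),
            _read("A" * 100, [38] * 100, "ok"),
            _read("N" * 50 + "A" * 50, [38] * 100, "bad2"),
        ]
        kept, rep = qc_reads(reads)
        assert rep.n_input - rep.n_output == rep.n_removed

    def test_never_lengthens(self):
        rng = np.random.default_rng(0)
        for i in range(50):
            n = int(rng.integers(20, 150))
            quals = rng.integers(2, 41, size=n).tolist()
            read = _read("A" * n, quals, f"r{i}")
            kept, _ = qc_reads([read])
            for k in kept:
                assert len(k) <= n


class TestSeqIdentity:
    def test_identity_cases(self):
        a = make_genome(400, 0.5, seed=1)
        assert seq_identity(a, a) == 100.0
        b = list(a)
        for pos in (10, 110, 210, 310):
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        assert seq_identity(a, "".join(b)) == pytest.approx(99.0)

    def test_against_brute_force_dp(self):
        # exhaustive DP oracle (unit costs) on tiny strings
        def dp_identity(a, b):
            import itertools
            n, m = len(a), len(b)
            # maximize matches over global alignments; track columns via costs
            best = -1.0
            # enumerate alignments by DP on (matches, columns) pairs
            table = {(0, 0): {(0, 0)}}
            for i in range(n + 1):
                for j in range(m + 1):
                    if (i, j) == (0, 0):
                        continue
                    opts = set()
                    if i > 0 and j > 0:
                        inc = 1 if a[i - 1] == b[j - 1] else 0
                        opts |= {(mm + inc, cc + 1) for mm, cc in table[(i - 1, j - 1)]}
                    if i > 0:
                        opts |= {(mm, cc + 1) for mm, cc in table[(i - 1, j)]}
                    if j > 0:
                        opts |= {(mm, cc + 1) for mm, cc in table[(i, j - 1)]}
                    table[(i, j)] = opts
            return max(100.0 * mm / cc for mm, cc in table[(n, m)])

        for a, b in [("ACGT", "TGCA"), ("ACGT", "ACGT"), ("AAAA", "AATA"),
                     ("ACGTAC", "ACTAC")]:
            assert seq_identity(a, b) <= dp_identity(a, b) + 1e-9
            assert seq_identity(a, b) == pytest.approx(seq_identity(b, a), abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            seq_identity("", "ACGT")


class Test16sExtraction:
    def _contig_with_amplicon(self, insert):
        pad1 = make_genome(200, 0.5, seed=5)
        pad2 = make_genome(200, 0.5, seed=6)
        # concrete realizations of the degenerate primers
        fwd = PRIMER_341F.replace("N", "A").replace("W", "A")
        rev = PRIMER_805R.replace("H", "A").replace("V", "C")
        return pad1 + fwd + insert + revcomp(rev) + pad2

    def test_plus_strand_extraction(self):
        insert = make_genome(430, 0.55, seed=7)
        contigs = ContigSet([("c", self._contig_with_amplicon(insert))])
        assert extract_16s_v3v4(contigs) == insert

    def test_minus_strand_extraction(self):
        insert = make_genome(430, 0.55, seed=8)
        contigs = ContigSet([("c", revcomp(self._contig_with_amplicon(insert)))])
        assert extract_16s_v3v4(contigs) == insert

    def test_absent_is_none(self):
        contigs = ContigSet([("c", make_genome(1000, 0.5, seed=9))])
        assert extract_16s_v3v4(contigs) is None


class TestAni:
    def test_identical_sets(self):
        cs = ContigSet([("a", make_genome(2000, 0.5, seed=11))])
        assert pairwise_ani(cs, cs) == pytest.approx(100.0)

    def test_known_divergence(self):
        a = make_genome(1000, 0.5, seed=12)
        b = list(a)
        rng = np.random.default_rng(13)
        for pos in rng.choice(1000, size=20, replace=False):
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        ani = pairwise_ani(ContigSet([("a", a)]), ContigSet([("b", "".join(b))]))
        assert ani == pytest.approx(98.0, abs=0.2)

    def test_short_overlap_is_nan(self):
        g = make_genome(2000, 0.5, seed=14)
        u1 = make_genome(400, 0.5, seed=15)
        u2 = make_genome(400, 0.5, seed=16)
        a = ContigSet([("a", u1 + g[0:300] + u2)])
        b = ContigSet([("b", g[0:300] + make_genome(700, 0.5, seed=17))])
        assert math.isnan(pairwise_ani(a, b))

    def test_symmetry(self):
        g = make_genome(3000, 0.5, seed=18)
        a = ContigSet([("a", g[:2000])])
        b = ContigSet([("b", g[1000:])])
        assert pairwise_ani(a, b) == pytest.approx(pairwise_ani(b, a), abs=1e-9)


class TestGroupSags:
    def test_all_pairs_pass_one_group(self):
        g = make_genome(3000, 0.5, seed=20)
        s16 = make_genome(430, 0.55, seed=21)
        sags = [(f"s{i}", s16, ContigSet([(f"c{i}", g)])) for i in range(3)]
        groups = group_sags(sags)
        assert len(groups) == 1 and groups[0].sag_ids == ["s0", "s1", "s2"]

    def test_low_ani_separates(self):
        s16 = make_genome(430, 0.55, seed=22)
        sags = [
            ("a", s16, ContigSet([("ca", make_genome(3000, 0.5, seed=23))])),
            ("b", s16, ContigSet([("cb", make_genome(3000, 0.5, seed=24))])),
        ]
        groups = group_sags(sags)  # unrelated genomes → no qualifying ANI
        assert [g.sag_ids for g in groups] == [["a"], ["b"]]

    def test_single_linkage_transitivity(self):
        ga = make_genome(2000, 0.5, seed=25)
        gc = make_genome(2000, 0.5, seed=26)
        sags = [
            ("a", None, ContigSet([("ca", ga)])),
            ("b", None, ContigSet([("cb", ga[:1000] + gc[:1000])])),  # bridges a and c
            ("c", None, ContigSet([("cc", gc)])),
        ]
        groups = group_sags(sags)
        assert len(groups) == 1 and groups[0].sag_ids == ["a", "b", "c"]

    def test_16s_threshold_blocks_edge(self):
        g = make_genome(3000, 0.5, seed=27)
        s16a = make_genome(430, 0.55, seed=28)
        s16b = list(s16a)
        rng = np.random.default_rng(29)
        for pos in rng.choice(430, size=9, replace=False):  # ~97.9% identity
            s16b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s16b[pos]]
        sags = [("a", s16a, ContigSet([("ca", g)])),
                ("b", "".join(s16b), ContigSet([("cb", g)]))]
        groups = group_sags(sags)
        assert [g.sag_ids for g in groups] == [["a"], ["b"]]

    def test_unrelated_genomes_never_cogroup(self):
        """SAGs from genomes with no qualifying shared alignment never land
        in one group (100 random trials)."""
        for trial in range(100):
            sags = [
                ("a", None, ContigSet([("ca", make_genome(1500, 0.5, seed=1000 + trial))])),
                ("b", None, ContigSet([("cb", make_genome(1500, 0.5, seed=5000 + trial))])),
            ]
            assert len(group_sags(sags)) == 2

    def test_same_strain_sags_cogroup(self, study_group):
        data, group = study_group
        sags = [(sid, None, group.contigs[sid]) for sid in data.sag_ids]
        groups = group_sags(sags)
        assert len(groups) == 1
        assert groups[0].sag_ids == data.sag_ids
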