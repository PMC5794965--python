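"""Pileup construction and the per-site SNP rule."""

import pytest

from ccsag.align import SeedExtendAligner
from ccsag.seqio import AlignmentRecord, ContigSet, ReadRecord
from ccsag.simulator import make_genome, plant_strain_snps
from ccsag.snps import (
    Pileup,
    PileupSite,
    SnpCall,
    SnpParams,
    annotate_codon_effect,
    call_snps,
    classify_sag_site,
    write_snp_tsv,
    write_vcf,
)


class TestClassifySagSite:
    @pytest.mark.parametrize(
        "counts,ref,expected",
        [
            ({"C": 4}, "A", ("no_call", None)),          # below depth 5
            ({"C": 5}, "A", ("unmatched", "C")),         # 5/5 = 100% ≥ 99.9%
            ({"C": 9, "A": 1}, "A", ("no_call", None)),  # 0.9 < 0.999
            ({"C": 3, "G": 3}, "A", ("no_call", None)),  # not homogeneous
            ({"A": 7}, "A", ("matched", None)),
            ({"A": 6, "C": 1}, "A", ("no_call", None)),  # mixed
        ],
    )
    def test_rule(self, counts, ref, expected):
        assert classify_sag_site(counts, ref) == expected

    def test_monotone_in_alt_depth(self):
        """Adding reads of the established alternate base never flips an
        unmatched call."""
        counts = {"C": 5}
        for extra in range(1, 50):
            label, alt = classify_sag_site({"C": 5 + extra}, "A")
            assert (label, alt) == ("unmatched", "C")


def _site(per_sag, ref="A"):
    return PileupSite("ctg", 10, ref, per_sag)


class TestCallSnps:
    def test_multiple_matched_and_unmatched(self):
        per_sag = {f"s{i}": {"A": 6} for i in range(5)}
        per_sag.update({f"v{i}": {"C": 6} for i in range(3)})
        (call,) = call_snps([_site(per_sag)])
        assert (call.ref_base, call.alt_base) == ("A", "C")
        assert call.unmatched_sags == ["v0", "v1", "v2"]

    def test_single_unmatched_not_called(self):
        per_sag = {f"s{i}": {"A": 6} for i in range(7)}
        per_sag["v0"] = {"C": 6}
        assert call_snps([_site(per_sag)]) == []

    def test_all_unmatched_is_assembly_error(self):
        per_sag = {f"v{i}": {"C": 6} for i in range(8)}
        assert call_snps([_site(per_sag)]) == []

    def test_disagreeing_alts_suppress_call(self):
        per_sag = {f"s{i}": {"A": 6} for i in range(4)}
        per_sag.update({"v0": {"C": 6}, "v1": {"C": 6}, "v2": {"G": 6}, "v3": {"G": 6}})
        assert call_snps([_site(per_sag)]) == []

    def test_order_invariance(self):
        per_sag = {"b": {"A": 9}, "a": {"A": 7}, "d": {"C": 8}, "c": {"C": 5}}
        calls1 = call_snps([_site(dict(sorted(per_sag.items())))])
        calls2 = call_snps([_site(dict(sorted(per_sag.items(), reverse=True)))])
        assert [(c.matched_sags, c.unmatched_sags) for c in calls1] == \
               [(c.matched_sags, c.unmatched_sags) for c in calls2]


class TestPileup:
    def test_counts_and_depth(self):
        comp = ContigSet([("c", "ACGTACGTAC" * 10)])
        pileup = Pileup(comp)
        rec = AlignmentRecord("r", "c", "+", (0, 10), (0, 10), 0, 0, 10, 10,
                              blocks=((0, 0, 10),))
        for i in range(7):
            pileup.add_alignment("sag1", "ACGTACGTAC", rec)
        site = pileup.site("c", 0)
        assert site.per_sag_counts["sag1"]["A"] == 7
        assert site.depth("sag1") == 7

    def test_clipped_ends_contribute_nothing(self):
        comp = ContigSet([("c", "A" * 100)])
        pileup = Pileup(comp)
        # alignment covers target 10..40 only; clips elsewhere
        rec = AlignmentRecord("r", "c", "+", (20, 50), (10, 40), 20, 0, 30, 30,
                              blocks=((20, 10, 30),))
        pileup.add_alignment("s", "C" * 20 + "A" * 30, rec)
        assert pileup.site("c", 5).per_sag_counts == {}
        assert pileup.site("c", 10).depth("s") == 1

    def test_unknown_target_rejected(self):
        pileup = Pileup(ContigSet([("c", "ACGT" * 100)]))
        rec = AlignmentRecord("r", "ghost", "+", (0, 4), (0, 4), 0, 0, 4, 4,
                              blocks=((0, 0, 4),))
        with pytest.raises(KeyError):
            pileup.add_alignment("s", "ACGT", rec)

    def test_per_sag_depth_matches_truth(self):
        genome = make_genome(5000, 0.5, seed=50)
        comp = ContigSet([("g", genome)])
        aligner = SeedExtendAligner(comp)
        pileup = Pileup(comp)
        starts = {"s1": [100, 400], "s2": [100, 100, 100], "s3": [2000]}
        for sag, ss in starts.items():
            reads = [ReadRecord(f"{sag}.{i}", genome[s:s + 300], [35] * 300)
                     for i, s in enumerate(ss)]
            pileup.add_sag(sag, reads, aligner)
        site = pileup.site("g", 150)
        assert site.depth("s1") == 1 and site.depth("s2") == 3
        assert "s3" not in site.per_sag_counts

    def test_minus_strand_bases_complemented(self):
        from ccsag.seqio import revcomp
        genome = make_genome(2000, 0.5, seed=51)
        comp = ContigSet([("g", genome)])
        aligner = SeedExtendAligner(comp)
        pileup = Pileup(comp)
        read = ReadRecord("r", revcomp(genome[500:800]), [35] * 300)
        pileup.add_sag("s", [read], aligner)
        site = pileup.site("g", 600)
        assert site.per_sag_counts["s"][genome[600]] == 1


class TestCodonEffect:
    def test_asp_to_ala(self):
        # GAT (Asp) -> GCT (Ala): change at codon position 2 (middle base)
        contig = "TTT" + "GAT" + "TTT"
        call = SnpCall("c", 4, "A", "C", ["s1", "s2"], ["v1", "v2"])
        out = annotate_codon_effect(call, 3, 9, "+", contig)
        assert out.codon_effect == "Asp->Ala"

    def test_synonymous_third_position(self):
        contig = "ATG" + "GGA" + "TAA"
        call = SnpCall("c", 5, "A", "G", ["s1", "s2"], ["v1", "v2"])
        out = annotate_codon_effect(call, 0, 9, "+", contig)
        assert out.codon_effect == "synonymous"

    def test_minus_strand_cds(self):
        from ccsag.seqio import revcomp
        cds_fwd = "ATG" + "GAT" + "TAA"  # Met-Asp-Stop
        contig = revcomp(cds_fwd)
        # variant at the middle base of GAT; on the contig it is a T->G
        pos = len(contig) - 1 - 4
        call = SnpCall("c", pos, "T", "G", ["s1", "s2"], ["v1", "v2"])
        out = annotate_codon_effect(call, 0, 9, "-", contig)
        assert out.codon_effect == "Asp->Ala"

    def test_outside_cds_rejected(self):
        call = SnpCall("c", 50, "A", "C", [], [])
        with pytest.raises(ValueError):
            annotate_codon_effect(call, 0, 9, "+", "ATGGATTAA" + "A" * 60)


class TestPlantedSnpRecovery:
    def test_planted_snps_recovered_exactly(self):
        """Strain SNPs carried by 3 of 8 SAGs at uniform depth are recovered
        with no spurious sites (error-free)."""
        genome = make_genome(30_000, 0.5, seed=60)
        genomes, table = plant_strain_snps(genome, 10, 8, 0.375, seed=61)
        comp = ContigSet([("g", genome)])
        aligner = SeedExtendAligner(comp)
        pileup = Pileup(comp)
        for i in range(8):
            reads = [ReadRecord(f"s{i}.r{j}", genomes[i][s:s + 300], [35] * 300)
                     for j, s in enumerate(range(0, 29_700, 50))]
            pileup.add_sag(f"s{i:02d}", reads, aligner)
        calls = call_snps(pileup.sites())
        assert {c.position for c in calls} == {t["position"] for t in table}
        carriers = {f"s{i:02d}" for i in table[0]["carrier_sags"]}
        for c in calls:
            assert set(c.unmatched_sags) == carriers


def test_writers_produce_expected_columns(tmp_path):
    calls = [SnpCall("ctg", 9, "A", "C", ["s1", "s2"], ["v1", "v2"], "Asp->Ala")]
    comp = ContigSet([("ctg", "A" * 50)])
    tsv = tmp_path / "s.tsv"
    vcf = tmp_path / "s.vcf"
    write_snp_tsv(tsv, calls)
    write_vcf(vcf, calls, comp)
    assert "ctg\t10\tA\tC\ts1,s2\tv1,v2\tAsp->Ala" in tsv.read_text()
    body = [l for l in vcf.read_text().splitlines() if not l.startswith("#")]
    assert body[0].startswith("ctg\t10\t.\tA\tC")
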