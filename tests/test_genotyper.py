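"""Band-pattern -> genotype calling with tolerance, detection limit, multiplexing."""

import itertools
import random

import pytest

from rflpsim.genotyper import (AMBIGUOUS, NO_CALL, GelModel, SNPAssay,
                               call_genotype, call_lane, expected_bands)
from rflpsim.fixtures import make_template
from rflpsim.rflp import diploid_band_set

STRICT = GelModel(size_tolerance=0, min_detectable=0)


class TestAssayDefinitions:
    def test_expected_band_table(self, assays):
        assert expected_bands(assays["rs1801133"], "CT") == {248, 130, 118}
        assert expected_bands(assays["rs2070744"], "TT") == {137, 41}
        assert expected_bands(assays["rs1799983"], "GG") == {371}

    def test_unknown_genotype_rejected(self, assays):
        with pytest.raises(KeyError, match="unknown genotype"):
            expected_bands(assays["rs1801133"], "GG")

    def test_heterozygote_is_union_of_homozygotes(self, assays):
        for assay in assays.values():
            het = assay.heterozygote
            homs = [g for g in assay.genotype_bands if g != het]
            assert expected_bands(assay, het) == \
                expected_bands(assay, homs[0]) | expected_bands(assay, homs[1])

    def test_cut_allele_bands_conserve_amplicon_length(self, assays):
        for assay in assays.values():
            hom_cut = assay.cut_allele * 2
            assert sum(assay.genotype_bands[hom_cut]) == assay.amplicon_length

    def test_banii_published_row_carried_with_flag(self, assays):
        assay = assays["rs1799983"]
        assert assay.published_bands["TT"] == {223, 139}
        assert sum(assay.published_bands["TT"]) != assay.amplicon_length
        assert "139" in assay.published_note

    def test_inconsistent_definition_rejected(self):
        with pytest.raises(ValueError, match="union"):
            SNPAssay(snp_id="x", locus_label="x", forward_primer="f",
                     reverse_primer="r", amplicon_length=100, enzyme_name="e",
                     alleles=("A", "B"), cut_allele="B",
                     genotype_bands={"AA": frozenset({100}),
                                     "AB": frozenset({100, 60}),
                                     "BB": frozenset({60, 40})})


class TestCallGenotype:
    def test_tolerant_match(self, assays):
        call = call_genotype(assays["rs1801133"], [247, 131, 119],
                             GelModel(size_tolerance=5, min_detectable=0))
        assert call.genotype == "CT" and call.is_clean

    def test_detection_limit_drops_small_band(self, assays):
        call = call_genotype(assays["rs2070744"], [137],
                             GelModel(size_tolerance=5, min_detectable=45))
        assert call.genotype == "TT"
        assert any("41" in f and "below detection" in f for f in call.flags)

    def test_empty_lane_is_no_call(self, assays):
        call = call_genotype(assays["rs1801133"], [])
        assert call.genotype == NO_CALL

    def test_unexplained_band_blocks_call(self, assays):
        call = call_genotype(assays["rs1801133"], [248, 130, 118, 500])
        assert call.genotype == NO_CALL
        assert call.unexplained_bands

    def test_ambiguous_when_several_genotypes_fit(self, assays):
        # a huge detection limit erases every distinguishing band
        gel = GelModel(size_tolerance=5, min_detectable=1000)
        call = call_genotype(assays["rs1801133"], [], gel)
        assert call.genotype == AMBIGUOUS

    def test_negative_band_rejected(self, assays):
        with pytest.raises(ValueError):
            call_genotype(assays["rs1801133"], [-5])

    def test_round_trip_all_nine_genotypes(self, assays):
        for assay in assays.values():
            for genotype in assay.genotype_bands:
                obs = sorted(expected_bands(assay, genotype))
                assert call_genotype(assay, obs, STRICT).genotype == genotype

    def test_order_invariance(self, assays):
        assay = assays["rs1801133"]
        for perm in itertools.permutations([248, 130, 118]):
            assert call_genotype(assay, list(perm)).genotype == "CT"


class TestCallLane:
    def test_multiplex_lane_partition(self, assays):
        calls = call_lane(list(assays.values()), [371, 248, 178, 130, 118],
                          GelModel(size_tolerance=5, min_detectable=45))
        by_snp = {c.snp_id: c for c in calls}
        # per the band table, 248+130+118 is the MTHFR heterozygote
        assert by_snp["rs1801133"].genotype == "CT"
        assert by_snp["rs1799983"].genotype == "GG"
        assert by_snp["rs2070744"].genotype == "CC"

    def test_undigested_lane_calls_uncut_genotypes(self, assays):
        calls = call_lane(list(assays.values()), [248, 371, 178])
        genotypes = {c.snp_id: c.genotype for c in calls}
        assert genotypes == {"rs1801133": "CC", "rs1799983": "GG",
                             "rs2070744": "CC"}

    def test_empty_lane_three_no_calls(self, assays):
        calls = call_lane(list(assays.values()), [])
        assert [c.genotype for c in calls] == [NO_CALL] * 3

    def test_shared_band_flagged(self, assays):
        # 133 bp sits within 5 bp of both MTHFR 130 and eNOS-786 137
        calls = call_lane(list(assays.values()), [133])
        flagged = [c for c in calls if any("multiple assays" in f for f in c.flags)]
        assert flagged

    def test_indistinguishable_panel_rejected(self, assays):
        a = assays["rs1801133"]
        clone = SNPAssay(snp_id="clone", locus_label=a.locus_label,
                         forward_primer=a.forward_primer,
                         reverse_primer=a.reverse_primer,
                         amplicon_length=a.amplicon_length,
                         enzyme_name=a.enzyme_name, alleles=a.alleles,
                         cut_allele=a.cut_allele,
                         genotype_bands=dict(a.genotype_bands))
        with pytest.raises(ValueError, match="indistinguishable"):
            call_lane([a, clone], [248])


class TestEndToEnd:
    def test_pipeline_recovers_planted_genotype(self, assays, panel, enzymes):
        """fixture -> virtual PCR -> digestion -> calling, all 9 combinations."""
        from rflpsim.amplify import predict_amplicons

        recovered = 0
        for assay in assays.values():
            enzyme = enzymes[assay.enzyme_name]
            for genotype in assay.genotype_bands:
                t = make_template(assay, genotype, seed=11)
                for allele_seq in t.allele_sequences:
                    amps = predict_amplicons(allele_seq, panel)
                    assert [a.length for a in amps] == [assay.amplicon_length]
                bands = diploid_band_set(t.allele_amplicons(), enzyme)
                call = call_genotype(assay, sorted(bands.lengths), STRICT)
                assert call.genotype == genotype
                recovered += 1
        assert recovered == 9
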