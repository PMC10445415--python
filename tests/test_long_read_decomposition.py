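"""Profiles, segmentation, discovery, phasing and consensus."""

import numpy as np
import pytest

from rfc1 import (
    ErrorModel,
    Motif,
    composition_profile,
    consensus_allele,
    decompose_sample,
    discover_motifs,
    expand_allele,
    extract_tract,
    motif_density_profile,
    parse_structure,
    phase_reads,
    segment_sequence,
    simulate_long_reads,
)
from rfc1.long_read_decomposition import InsufficientReadsError

KNOWN4 = [Motif(m) for m in ("AAAAG", "AAAGG", "AAGGG", "ACAGG")]


class TestCompositionProfile:
    def test_pure_aagac_interior_fractions(self):
        tract = expand_allele(parse_structure("(AAGAC)270"))
        prof = composition_profile(tract, window_bp=50)
        mid = len(tract) // 2
        assert prof.values["A"][mid] == pytest.approx(0.6)
        assert prof.values["G"][mid] == pytest.approx(0.2)
        assert prof.values["C"][mid] == pytest.approx(0.2)
        assert prof.values["T"][mid] == pytest.approx(0.0)

    def test_pure_aaaag_interior_fractions(self):
        tract = expand_allele(parse_structure("(AAAAG)30"))
        prof = composition_profile(tract, window_bp=50)
        assert prof.values["A"][75] == pytest.approx(0.8)
        assert prof.values["G"][75] == pytest.approx(0.2)

    def test_step_at_block_boundary(self):
        tract = expand_allele(parse_structure("(AAGAC)250(AAAAG)30"))
        prof = composition_profile(tract, window_bp=50)
        assert prof.values["A"][600] == pytest.approx(0.6)
        assert prof.values["A"][1300] == pytest.approx(0.8)
        # the step is localized around the boundary at 1250 bp
        assert 0.6 < prof.values["A"][1250] < 0.8

    def test_fractions_sum_to_one_everywhere(self):
        tract = expand_allele(parse_structure("(AAGGG)50(AGGGG)50"))
        prof = composition_profile(tract, window_bp=50)
        total = sum(prof.values[b] for b in "ACGT")
        assert np.allclose(total, 1.0)

    def test_short_tract_rejected(self):
        with pytest.raises(ValueError):
            composition_profile("AAGGG", window_bp=50)


class TestMotifDensityProfile:
    def test_pure_tract_density(self):
        tract = expand_allele(parse_structure("(AAGGG)100"))
        prof = motif_density_profile(tract, [Motif("AAGGG"), Motif("AAAAG")])
        mid = len(tract) // 2
        assert prof.values["AAGGG"][mid] == pytest.approx(1.0)
        assert prof.values["AAAAG"][mid] == pytest.approx(0.0)

    def test_density_falls_in_second_block(self):
        tract = expand_allele(parse_structure("(AAGGG)50(AGGGG)50"))
        prof = motif_density_profile(tract, [Motif("AAGGG")])
        assert prof.values["AAGGG"][100] == pytest.approx(1.0)
        assert prof.values["AAGGG"][400] < 0.1

    def test_densities_within_unit_interval(self):
        tract = expand_allele(parse_structure("(AAGGG)20(AAAAG)20"))
        prof = motif_density_profile(tract, KNOWN4)
        for values in prof.values.values():
            assert values.min() >= 0.0 and values.max() <= 1.0


class TestSegmentation:
    @pytest.mark.parametrize(
        "text",
        ["(AAAGG)20(AAGGG)500(AAAGG)10",
         "(AAAAG)12(AAGAC)258",
         "(AAAGG)12(AAAGGG)36(AAGGG)12",
         "(AAGGG)100(AGGGG)30",
         "(AAGGG)60[30:(AAAAG)1]"],
    )
    def test_round_trip_zero_error(self, motifs, text):
        s = parse_structure(text)
        assert segment_sequence(expand_allele(s), motifs) == s

    def test_single_unit_interruption_recovered(self, motifs):
        s = parse_structure("(AAGGG)60[30:(AAAAG)1]")
        back = segment_sequence(expand_allele(s), motifs)
        assert back.segments == s.segments
        assert back.interruptions == s.interruptions

    def test_rotation_phase_does_not_matter(self, motifs):
        tract = expand_allele(parse_structure("(AAGGG)60"))
        shifted = tract[2:] + tract[:2]
        back = segment_sequence(shifted, motifs)
        assert [seg.motif.canonical for seg in back.segments] == ["AAGGG"]
        assert back.segments[0].copies == 60

    def test_empty_tract_rejected(self, motifs):
        with pytest.raises(ValueError):
            segment_sequence("", motifs)


class TestDiscoverMotifs:
    def test_aagac_discovered(self):
        tract = expand_allele(parse_structure("(AAGAC)270"))
        assert [m.canonical for m in discover_motifs(tract, KNOWN4)] == ["AAGAC"]

    def test_hexamer_discovered(self):
        tract = expand_allele(parse_structure("(AAAGGG)60"))
        assert [m.canonical for m in discover_motifs(tract, KNOWN4)] == ["AAAGGG"]

    def test_known_tract_yields_nothing(self):
        tract = expand_allele(parse_structure("(AAAAG)100"))
        assert discover_motifs(tract, KNOWN4) == []

    def test_never_returns_known_motif_any_rotation(self):
        tract = expand_allele(parse_structure("(AAGAC)100(AGGGA)0(AAGGG)100"
                                              .replace("(AGGGA)0", "")))
        found = discover_motifs(tract, KNOWN4)
        known = {m.canonical for m in KNOWN4}
        assert all(m.canonical not in known for m in found)

    def test_novel_block_inside_known_context(self):
        tract = expand_allele(parse_structure("(AAAAG)50(AGGGG)40(AAAAG)50"))
        found = discover_motifs(tract, KNOWN4)
        assert [m.canonical for m in found] == ["AGGGG"]


class TestPhaseReads:
    def test_two_clear_clusters(self):
        lengths = [2000] * 30 + [350] * 30
        k, labels = phase_reads(lengths)
        assert k == 2
        # cluster 0 is the longer allele
        assert all(labels[i] == 0 for i in range(30))
        assert all(labels[i] == 1 for i in range(30, 60))

    def test_homozygous_merge(self):
        k, labels = phase_reads([2000] * 60)
        assert k == 1 and set(labels) == {0}

    def test_merge_within_tolerance(self):
        k, _ = phase_reads([1000] * 20 + [1040] * 20)
        assert k == 1

    def test_insufficient_reads(self):
        with pytest.raises(InsufficientReadsError):
            phase_reads([500, 510])

    def test_noisy_lengths_zero_misassignment(self):
        rng = np.random.default_rng(0)
        a = rng.normal(2000, 30, size=25)
        b = rng.normal(430, 15, size=25)
        k, labels = phase_reads(np.concatenate([a, b]).astype(int).tolist())
        assert k == 2
        assert all(l == 0 for l in labels[:25])
        assert all(l == 1 for l in labels[25:])


class TestConsensus:
    def test_exact_recovery_from_error_free_cluster(self, motifs):
        tract = expand_allele(parse_structure("(AAAAG)125"))
        result = consensus_allele([tract] * 6, motifs)
        assert result.structure == parse_structure("(AAAAG)125")
        assert result.copy_count_estimate == 125
        assert result.spread == 0.0
        assert not result.low_confidence

    def test_single_read_cluster_flagged(self, motifs):
        tract = expand_allele(parse_structure("(AAGGG)80"))
        result = consensus_allele([tract], motifs)
        assert result.structure == parse_structure("(AAGGG)80")
        assert result.spread is None
        assert any("single supporting read" in n for n in result.notes)

    def test_novel_motif_propagates(self):
        tract = expand_allele(parse_structure("(AAAAG)12(AAGAC)100"))
        result = consensus_allele([tract] * 5, KNOWN4)
        assert [m.canonical for m in result.novel_motifs] == ["AAGAC"]
        assert result.structure == parse_structure("(AAAAG)12(AAGAC)100")

    def test_empty_cluster_rejected(self, motifs):
        with pytest.raises(ValueError):
            consensus_allele([], motifs)


class TestTractExtraction:
    def test_exact_extraction(self, locus):
        tract = expand_allele(parse_structure("(AAGGG)100"))
        read = locus.left_flank + tract + locus.right_flank
        assert extract_tract(read, locus) == tract

    def test_fuzzy_extraction_with_errors(self, locus, make_genotype):
        g = make_genotype("(AAGGG)100", "(AAGGG)100")
        reads = simulate_long_reads(g, locus, coverage=5, error=ErrorModel(), seed=3)
        extracted = [extract_tract(x.sequence, locus) for x in reads]
        recovered = [t for t in extracted if t is not None]
        assert len(recovered) >= 8
        for t in recovered:
            assert abs(len(t) - 500) < 50

    def test_non_spanning_read_dropped(self, locus):
        assert extract_tract(locus.left_flank + "AAGGG" * 40, locus) is None


class TestDecomposeSample:
    def test_heterozygote_fully_resolved(self, locus, motifs, make_genotype):
        g = make_genotype("(AAGGG)400", "(AAAGG)12(AAAGGG)46(AAGGG)12")
        reads = simulate_long_reads(g, locus, coverage=6, error=ErrorModel.exact())
        sample = decompose_sample([x.sequence for x in reads], locus, motifs)
        assert len(sample.results) == 2
        structures = {a.to_string() for a in sample.alleles}
        assert structures == {g.allele1.to_string(), g.allele2.to_string()}

    def test_colength_heterozygote_split_by_order(self, locus, motifs, make_genotype):
        # 625 bp vs 650 bp tracts: inseparable by length, distinct by order
        g = make_genotype("(AAAAG)125", "(AAGGG)100(AGGGG)30")
        reads = simulate_long_reads(g, locus, coverage=6, error=ErrorModel.exact())
        sample = decompose_sample([x.sequence for x in reads], locus, motifs)
        structures = {a.to_string() for a in sample.alleles}
        assert structures == {g.allele1.to_string(), g.allele2.to_string()}

    def test_homozygote_single_result(self, locus, motifs, make_genotype):
        g = make_genotype("(AAGGG)300", "(AAGGG)300")
        reads = simulate_long_reads(g, locus, coverage=5, error=ErrorModel.exact())
        sample = decompose_sample([x.sequence for x in reads], locus, motifs)
        assert len(sample.results) == 1
        assert sample.alleles[0] == sample.alleles[1] == g.allele1
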