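"""Flanking-PCR and RP-PCR simulation and interpretation."""

import pytest

from rfc1 import (
    AssayConfig,
    Motif,
    amplicon_length,
    flanking_pcr,
    interpret_traces,
    parse_structure,
    rp_panel,
    rp_pcr_trace,
    screen_flanking,
)
from rfc1.pcr_assays import AssayTrace, traces_from_frame, traces_to_frame

CFG = AssayConfig()


class TestAmpliconLength:
    @pytest.mark.parametrize(
        "text, expected",
        [("(AAAAG)8", 340), ("(AAAAG)11", 355), ("(AAAAG)14", 370),
         ("(AAAGG)30", 450), ("(AAAGGG)8", 348)],
    )
    def test_lengths(self, text, expected):
        assert amplicon_length(parse_structure(text), CFG) == expected

    @pytest.mark.parametrize("text", ["(AAGGG)400", "(AAAAG)51", "(ACAGG)800"])
    def test_no_product_beyond_cap(self, text):
        assert amplicon_length(parse_structure(text), CFG) is None

    def test_interruptions_count_toward_cap_and_length(self):
        s = parse_structure("(AAAAG)10[5:(AAGGG)2]")
        assert amplicon_length(s, CFG) == 300 + 60


class TestFlankingScreen:
    def test_homozygote_single_peak_double_height(self, make_genotype):
        trace = flanking_pcr(make_genotype("(AAAAG)11", "(AAAAG)11"), CFG)
        assert trace.peaks == ((355.0, 2.0),)
        assert screen_flanking(trace, CFG).excluded

    def test_het_carrier_shows_reference_peak_only(self, make_genotype):
        trace = flanking_pcr(make_genotype("(AAAAG)11", "(AAGGG)1000"), CFG)
        assert trace.peaks == ((355.0, 1.0),)
        assert screen_flanking(trace, CFG).excluded

    def test_biallelic_expansion_gives_empty_trace(self, make_genotype):
        trace = flanking_pcr(make_genotype("(AAGGG)1000", "(ACAGG)800"), CFG)
        assert trace.peaks == ()
        result = screen_flanking(trace, CFG)
        assert result.suspected_biallelic and not result.excluded

    def test_intermediate_allele_warns(self, make_genotype):
        trace = flanking_pcr(make_genotype("(AAAAG)30", "(AAGGG)1000"), CFG)
        result = screen_flanking(trace, CFG)
        assert result.suspected_biallelic and result.warning

    def test_rejects_rp_trace(self):
        with pytest.raises(ValueError):
            screen_flanking(AssayTrace("rp:AAGGG", ()), CFG)


class TestRpPcr:
    def test_pure_allele_ladders_every_unit(self, make_genotype):
        g = make_genotype("(AAAAG)125", "(AAAAG)125")
        trace = rp_pcr_trace(g, Motif("AAAAG"), CFG)
        assert len(trace.peaks) == 125
        sizes = trace.sizes
        assert sizes[0] == CFG.rp_anchor_bp + 5
        assert all(b - a == 5 for a, b in zip(sizes, sizes[1:]))

    def test_ladder_caps_at_detection_limit(self, make_genotype):
        g = make_genotype("(AAAAG)500", "(AAAAG)500")
        trace = rp_pcr_trace(g, Motif("AAAAG"), CFG)
        assert len(trace.peaks) == CFG.rp_detection_limit_units

    def test_off_motif_assay_is_silent(self, make_genotype):
        g = make_genotype("(AAGGG)400", "(AAGGG)400")
        assert rp_pcr_trace(g, Motif("AAAAG"), CFG).peaks == ()

    def test_maori_aaggg_ladder_starts_after_5prime_block(self, make_genotype):
        g = make_genotype("(AAAGG)20(AAGGG)500(AAAGG)10", "(AAGGG)600")
        trace = rp_pcr_trace(g, Motif("AAGGG"), CFG)
        # second allele ladders from unit 1; the Maori allele joins at unit 21
        assert trace.sizes[0] == CFG.rp_anchor_bp + 5
        solo = rp_pcr_trace(
            make_genotype("(AAAGG)20(AAGGG)500(AAAGG)10",
                          "(AAAGG)20(AAGGG)500(AAAGG)10"),
            Motif("AAGGG"), CFG)
        assert solo.sizes[0] == CFG.rp_anchor_bp + 20 * 5 + 5

    def test_heights_decay_along_ladder(self, make_genotype):
        g = make_genotype("(AAGGG)100", "(AAGGG)100")
        trace = rp_pcr_trace(g, Motif("AAGGG"), CFG)
        heights = [h for _, h in trace.peaks]
        assert heights == sorted(heights, reverse=True)


class TestInterpretTraces:
    def test_biallelic_pure_aaggg(self, make_genotype):
        g = make_genotype("(AAGGG)700", "(AAGGG)900")
        call = interpret_traces(rp_panel(g, CFG), CFG)
        assert {m.canonical for m in call.motifs_present} == {"AAGGG"}
        assert not call.gap_flag and not call.no_product

    def test_interruption_detected_as_short_run(self, make_genotype):
        g = make_genotype("(AAGGG)100[50:(AAAAG)3]", "(AAGGG)100[50:(AAAAG)3]")
        call = interpret_traces(rp_panel(g, CFG), CFG)
        assert {m.canonical for m in call.motifs_present} == {"AAGGG"}
        assert {m.canonical for m in call.interruption_motifs} == {"AAAAG"}

    def test_presence_and_interruption_sets_disjoint(self, make_genotype):
        g = make_genotype("(AAAAG)60[20:(AAGGG)2]", "(AAGGG)300")
        call = interpret_traces(rp_panel(g, CFG), CFG)
        assert not (call.motifs_present & call.interruption_motifs)
        assert {m.canonical for m in call.motifs_present} == {"AAAAG", "AAGGG"}

    def test_hp220149_gap_on_standard_panel(self, make_genotype):
        g = make_genotype(
            "(AAAAG)12(AAGAC)258", "(AAAGG)12(AAAGGG)36(AAGGG)12"
        )
        call = interpret_traces(rp_panel(g, CFG), CFG)
        assert call.gap_flag

    def test_hp220149_resolved_on_extended_panel(self, make_genotype):
        g = make_genotype(
            "(AAAAG)12(AAGAC)258", "(AAAGG)12(AAAGGG)36(AAGGG)12"
        )
        call = interpret_traces(rp_panel(g, CFG, extended=True), CFG)
        present = {m.canonical for m in call.motifs_present}
        assert {"AAGAC", "AAAGGG"} <= present
        assert not call.gap_flag

    def test_no_product_flag(self, make_genotype):
        # no panel motif occurs within the detection limit
        g = make_genotype("(AAGAC)270", "(AAGAC)270")
        call = interpret_traces(rp_panel(g, CFG), CFG)
        assert call.no_product

    def test_mismatched_samples_rejected(self, make_genotype):
        t1 = rp_panel(make_genotype("(AAGGG)100", "(AAGGG)100", "A"), CFG)
        t2 = rp_panel(make_genotype("(AAGGG)100", "(AAGGG)100", "B"), CFG)
        with pytest.raises(ValueError):
            interpret_traces(t1[:2] + t2[2:], CFG)

    @pytest.mark.parametrize(
        "text, expected_present",
        [("(AAGGG)400", {"AAGGG"}),
         ("(AAAAG)125", {"AAAAG"}),
         ("(AAAGG)20(AAGGG)500(AAAGG)10", {"AAAGG", "AAGGG"}),
         ("(ACAGG)800", {"ACAGG"}),
         ("(AAGGG)5(AAAAG)60", {"AAAAG"})],
    )
    def test_presence_iff_run_of_ten_in_first_160_units(
        self, make_genotype, text, expected_present
    ):
        """Oracle: direct inspection of the structure's unit runs."""
        g = make_genotype(text, text)
        call = interpret_traces(rp_panel(g, CFG), CFG)
        assert {m.canonical for m in call.motifs_present} == expected_present

    def test_invariant_to_reserialization(self, make_genotype):
        from rfc1 import parse_structure

        g1 = make_genotype("(AAAGG)20(AAGGG)500(AAAGG)10", "(AAGGG)600")
        reparsed = parse_structure(g1.allele1.to_string())
        g2 = make_genotype(reparsed.to_string(), "(AAGGG)600")
        for t1, t2 in zip(rp_panel(g1, CFG), rp_panel(g2, CFG)):
            assert t1.peaks == t2.peaks


class TestTraceTsv:
    def test_round_trip_including_empty_traces(self, make_genotype):
        g = make_genotype("(AAGGG)400", "(AAGGG)400", "T1")
        traces = rp_panel(g, CFG) + [flanking_pcr(g, CFG)]
        frame = traces_to_frame(traces)
        again = {t.assay: t for t in traces_from_frame(frame)}
        assert set(again) == {t.assay for t in traces}
        for t in traces:
            assert again[t.assay].peaks == t.peaks
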