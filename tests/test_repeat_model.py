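"""Motif algebra, allele structures and locus definition."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfc1 import (
    AlleleSegment,
    AlleleStructure,
    GenomicInterval,
    Interruption,
    LocusDefinition,
    Motif,
    MotifLabel,
    MotifRegistry,
    canonical_rotation,
    classify_motif,
    expand_allele,
    matches_maori_pattern,
    motif_composition,
    parse_structure,
)
from rfc1.repeat_model import InvalidAlphabetError, StructureError, rotations

units = st.text(alphabet="ACGT", min_size=1, max_size=8)
motif_units = st.text(alphabet="ACGT", min_size=5, max_size=6).filter(
    lambda s: len(s) in (5, 6)
)


class TestCanonicalRotation:
    @pytest.mark.parametrize(
        "unit, expected",
        [("AGGGA", "AAGGG"), ("AAAAG", "AAAAG"), ("GGGAA", "AAGGG"),
         ("GGGAAA", "AAAGGG"), ("ACAGG", "ACAGG"), ("GACAG", "ACAGG")],
    )
    def test_examples(self, unit, expected):
        assert canonical_rotation(unit) == expected

    @settings(max_examples=200, derandomize=True)
    @given(units)
    def test_idempotent_and_rotation_invariant(self, unit):
        canon = canonical_rotation(unit)
        assert canonical_rotation(canon) == canon
        for rot in rotations(unit):
            assert canonical_rotation(rot) == canon
        assert canon in rotations(unit)

    def test_rejects_bad_alphabet(self):
        with pytest.raises(InvalidAlphabetError):
            canonical_rotation("AAGNX")
        with pytest.raises(InvalidAlphabetError):
            canonical_rotation("")


class TestMotif:
    def test_identity_up_to_rotation(self):
        assert Motif("AGGGA") == Motif("AAGGG")
        assert hash(Motif("AGGGA")) == hash(Motif("AAGGG"))
        assert Motif("AAGGG") != Motif("AAAGG")

    @pytest.mark.parametrize("bad", ["ACGT", "AAGGGGG", "AAGNG"])
    def test_length_and_alphabet_guards(self, bad):
        with pytest.raises(ValueError):
            Motif(bad)

    @pytest.mark.parametrize(
        "unit, key, value",
        [("AAGAC", "A", 0.6), ("AAGAC", "G", 0.2), ("AAGAC", "C", 0.2),
         ("AAGAC", "T", 0.0), ("AAAAG", "A", 0.8), ("AAAAG", "G", 0.2),
         ("AGGGG", "GC", 0.8), ("AAAGGG", "GC", 0.5)],
    )
    def test_composition(self, unit, key, value):
        assert motif_composition(Motif(unit))[key] == pytest.approx(value)

    @settings(max_examples=100, derandomize=True)
    @given(motif_units)
    def test_composition_sums_to_one(self, unit):
        comp = motif_composition(unit)
        assert sum(comp[b] for b in "ACGT") == pytest.approx(1.0)


class TestRegistry:
    def test_default_labels(self, registry):
        assert classify_motif(Motif("AAGGG"), registry) is MotifLabel.PATHOGENIC
        assert classify_motif(Motif("ACAGG"), registry) is MotifLabel.PATHOGENIC
        assert classify_motif(Motif("AAAAG"), registry) is MotifLabel.REFERENCE
        assert classify_motif(Motif("AAAGG"), registry) is MotifLabel.BENIGN
        assert classify_motif(Motif("AAGAG"), registry) is MotifLabel.UNDETERMINED
        # absent from the registry entirely
        assert classify_motif(Motif("AACCC"), registry) is MotifLabel.NOVEL

    def test_lookup_is_rotation_invariant(self, registry):
        assert classify_motif(Motif("GAAGG"), registry) is MotifLabel.PATHOGENIC

    def test_keys_are_canonical(self, registry):
        for key in registry.entries:
            assert canonical_rotation(key) == key

    def test_with_entry_does_not_mutate(self, registry):
        updated = registry.with_entry("CCCCC"[:5].replace("C", "T", 1), MotifLabel.BENIGN)
        assert len(updated.entries) == len(registry.entries) + 1


class TestAlleleStructure:
    def test_expand_lengths(self):
        assert expand_allele(parse_structure("(AAAAG)11")) == "AAAAG" * 11
        assert len(expand_allele(parse_structure("(AAAGG)15(AAGGG)100(AAAGG)10"))) == 625
        assert len(expand_allele(parse_structure("(AAAGGG)60"))) == 360

    def test_expand_splices_interruptions(self):
        s = parse_structure("(AAGGG)4[2:(AAAAG)1]")
        assert expand_allele(s) == "AAGGG" * 2 + "AAAAG" + "AAGGG" * 2
        assert s.length_bp == 25
        assert s.total_units == 5

    def test_interruption_bounds(self):
        with pytest.raises(StructureError):
            Interruption(0, Motif("AAAAG"), 10)
        with pytest.raises(StructureError):
            Interruption(0, Motif("AAAAG"), 0)
        with pytest.raises(StructureError):
            AlleleStructure(
                (AlleleSegment(Motif("AAGGG"), 5),),
                (Interruption(6, Motif("AAAAG"), 1),),
            )

    @pytest.mark.parametrize(
        "text",
        ["(AAAAG)11", "(AAAGG)20(AAGGG)500(AAAGG)10",
         "(AAGGG)30[15:(AAAAG)2]", "(AAAAG)12(AAGAC)258[3:(AAGGG)1]"],
    )
    def test_string_round_trip(self, text):
        assert parse_structure(text).to_string() == text

    def test_json_round_trip(self):
        s = parse_structure("(AAGGG)30[15:(AAAAG)2]")
        assert AlleleStructure.from_dict(s.to_dict()) == s

    def test_parse_rejects_garbage(self):
        with pytest.raises(StructureError):
            parse_structure("AAGGGx30")
        with pytest.raises(StructureError):
            parse_structure("")

    def test_composition_of_pure_expansion_matches_motif(self):
        tract = expand_allele(parse_structure("(AAGAC)40"))
        comp = motif_composition(Motif("AAGAC"))
        for base in "ACGT":
            assert tract.count(base) / len(tract) == pytest.approx(comp[base])


class TestMaoriPattern:
    @pytest.mark.parametrize(
        "text, expected",
        [("(AAAGG)20(AAGGG)500(AAAGG)10", True),
         ("(AAAGG)15(AAGGG)50(AAAGG)12", True),
         ("(AAGGG)500", False),
         ("(AAAGG)5(AAGGG)500(AAAGG)10", False),
         ("(AAAGG)20(AAGGG)500(AAAGG)20", False),
         ("(AAAGG)20(AAGGG)10(AAAGG)10", False)],
    )
    def test_examples(self, text, expected):
        assert matches_maori_pattern(parse_structure(text)) is expected

    def test_configurable_floor(self):
        s = parse_structure("(AAAGG)20(AAGGG)30(AAAGG)10")
        assert not matches_maori_pattern(s)
        assert matches_maori_pattern(s, expansion_floor=30)


class TestLocusDefinition:
    def test_reference_allele_in_normal_window(self, locus, assay_cfg):
        length = assay_cfg.flank_constant_bp + locus.reference_allele.length_bp
        lo, hi = assay_cfg.normal_window_bp
        assert lo <= length <= hi

    def test_yaml_round_trip(self, locus):
        again = LocusDefinition.from_yaml(locus.to_yaml())
        assert again == locus

    def test_bed_export_is_zero_based_half_open(self, locus):
        lines = locus.to_bed().strip().splitlines()
        chrom, start, end, name = lines[0].split("\t")
        assert (chrom, name) == ("chr4", "RFC1_repeat")
        assert int(start) == locus.repeat_region.start - 1
        assert int(end) == locus.repeat_region.end
        assert len(lines) == 1 + len(locus.probe_intervals)

    def test_flanks_are_deterministic(self, locus):
        from rfc1 import default_locus

        assert default_locus().left_flank == locus.left_flank

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr4", 10, 5)
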