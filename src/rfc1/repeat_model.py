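"""Core domain model for the RFC1 pentanucleotide repeat locus.

The RFC1 short tandem repeat (intron 2 of *RFC1*, chr4:39348425-39348485 on
GRCh38) is a pentanucleotide locus whose reference allele is (AAAAG)11.
Biallelic expansions of particular motifs (AAGGG, ACAGG, and the complex
"Maori" configuration (AAAGG)15-25(AAGGG)exp(AAAGG)10) cause CANVAS
(cerebellar ataxia, neuropathy and vestibular areflexia syndrome), while
other motifs at the same locus are benign or of undetermined significance.

This module defines the motif algebra (canonical rotations, composition),
allele structures (ordered motif blocks plus short interruptions), the locus
definition, and the registry of known motifs with pathogenicity labels.
Everything downstream — assay simulation, read decomposition, the diagnostic
workflow — is phrased in these types.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import yaml

_ALPHABET = frozenset("ACGT")

__all__ = [
    "Motif",
    "MotifLabel",
    "MotifRegistry",
    "AlleleSegment",
    "Interruption",
    "AlleleStructure",
    "GenomicInterval",
    "LocusDefinition",
    "DiploidGenotype",
    "PhenotypeGroup",
    "canonical_rotation",
    "rotations",
    "motif_composition",
    "classify_motif",
    "expand_allele",
    "matches_maori_pattern",
    "parse_structure",
    "default_registry",
    "default_locus",
    "core_motifs",
]


class InvalidAlphabetError(ValueError):
    """A sequence contained characters outside {A, C, G, T}."""


class StructureError(ValueError):
    """An allele structure violated its invariants."""


def _check_alphabet(seq: str) -> None:
    if not seq:
        raise InvalidAlphabetError("empty sequence")
    bad = set(seq) - _ALPHABET
    if bad:
        raise InvalidAlphabetError(f"non-ACGT characters: {sorted(bad)}")


def canonical_rotation(unit: str) -> str:
    """Lexicographically smallest cyclic rotation of ``unit``.

    Phase-shifted descriptions of the same repeat (AAGGG, AGGGA, GGGAA, ...)
    collapse onto a single identity. Idempotent.
    """
    _check_alphabet(unit)
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def rotations(unit: str) -> list[str]:
    """All cyclic rotations of ``unit`` (length == len(unit), may repeat)."""
    return [unit[i:] + unit[:i] for i in range(len(unit))]


@dataclass(frozen=True, order=True)
class Motif:
    """A 5- or 6-base repeat unit, identified up to cyclic rotation.

    Identity is rotation-only: motifs are reported on the plus strand of the
    locus and reverse complements are *not* merged.
    """

    unit: str

    def __post_init__(self) -> None:
        _check_alphabet(self.unit)
        if len(self.unit) not in (5, 6):
            raise ValueError(f"motif length must be 5 or 6, got {len(self.unit)}")

    @property
    def canonical(self) -> str:
        return canonical_rotation(self.unit)

    def __len__(self) -> int:
        return len(self.unit)

    def rotations(self) -> list[str]:
        return rotations(self.unit)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Motif):
            return self.canonical == other.canonical
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.canonical)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.unit


def motif_composition(motif: Motif | str) -> dict[str, float]:
    """Base fractions of a motif over {A, C, G, T}; sums to 1.

    The GC fraction is exposed as key ``"GC"`` on top of the four bases
    (e.g. AGGGG has GC fraction 0.8).
    """
    unit = motif.unit if isinstance(motif, Motif) else motif
    _check_alphabet(unit)
    n = len(unit)
    comp = {b: unit.count(b) / n for b in "ACGT"}
    comp["GC"] = comp["G"] + comp["C"]
    return comp


class MotifLabel(str, Enum):
    REFERENCE = "reference"
    BENIGN = "benign"
    PATHOGENIC = "pathogenic"
    UNDETERMINED = "undetermined"
    NOVEL = "novel"  # returned for motifs absent from the registry


@dataclass
class MotifRegistry:
    """Canonical-motif -> pathogenicity label map.

    Keys are stored canonically; lookups canonicalize first, so any rotation
    of a registered motif resolves to the same label. Motifs not present
    resolve to :attr:`MotifLabel.NOVEL`.
    """

    entries: dict[str, MotifLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fixed = {}
        for key, label in self.entries.items():
            canon = canonical_rotation(key)
            fixed[canon] = MotifLabel(label)
        self.entries = fixed

    def label(self, motif: Motif | str) -> MotifLabel:
        canon = motif.canonical if isinstance(motif, Motif) else canonical_rotation(motif)
        return self.entries.get(canon, MotifLabel.NOVEL)

    def __contains__(self, motif: Motif | str) -> bool:
        canon = motif.canonical if isinstance(motif, Motif) else canonical_rotation(motif)
        return canon in self.entries

    def motifs(self) -> list[Motif]:
        return [Motif(m) for m in sorted(self.entries)]

    def with_entry(self, motif: Motif | str, label: MotifLabel) -> "MotifRegistry":
        new = dict(self.entries)
        canon = motif.canonical if isinstance(motif, Motif) else canonical_rotation(motif)
        new[canon] = label
        return MotifRegistry(new)


def default_registry() -> MotifRegistry:
    """Registry of motifs reported at the RFC1 locus.

    AAAAG is the reference motif; AAAGG is an established benign expansion;
    AAGAG and AGAGG have been observed but their pathogenicity is
    undetermined; AAGGG and ACAGG are pathogenic; AAGAC, AGGGG and AAAGGG
    are recently described motifs of undetermined significance, as are the
    rarer motifs seen in population-scale short-read data.
    """
    lab = MotifLabel
    entries: dict[str, MotifLabel] = {
        "AAAAG": lab.REFERENCE,
        "AAAGG": lab.BENIGN,
        "AAGAG": lab.UNDETERMINED,
        "AGAGG": lab.UNDETERMINED,
        "AAGGG": lab.PATHOGENIC,
        "ACAGG": lab.PATHOGENIC,
        "AAGAC": lab.UNDETERMINED,
        "AGGGG": lab.UNDETERMINED,
        "AAAGGG": lab.UNDETERMINED,
    }
    # additional motifs observed in population short-read data
    for unit in (
        "AAAAA", "AAAAC", "AAACG", "AACAG", "AACGG", "AAGGC", "AAGGT",
        "ACGGG", "AGGGC", "AGGTG", "AAAAAG", "AAAAGG",
    ):
        entries.setdefault(canonical_rotation(unit), lab.UNDETERMINED)
    return MotifRegistry(entries)


def core_motifs() -> list[Motif]:
    """The motif panel used for long-read decomposition: reference, benign,
    pathogenic and the recurrent undetermined motifs seen in expanded
    alleles (rarer population motifs are left to novel-motif discovery)."""
    return [
        Motif(m)
        for m in (
            "AAAAG", "AAAGG", "AAGAG", "AGAGG", "AAGGG", "ACAGG",
            "AAGAC", "AGGGG", "AAAGGG",
        )
    ]


def classify_motif(motif: Motif | str, registry: MotifRegistry) -> MotifLabel:
    """Registry label of a motif's canonical form; NOVEL when absent."""
    return registry.label(motif)


@dataclass(frozen=True)
class AlleleSegment:
    """A block of ``copies`` tandem copies of one motif."""

    motif: Motif
    copies: int

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise StructureError(f"segment copies must be >= 1, got {self.copies}")

    @property
    def length_bp(self) -> int:
        return self.copies * len(self.motif)


@dataclass(frozen=True)
class Interruption:
    """1-9 copies of a foreign motif spliced inside the segment sequence.

    ``index`` is the repeat-unit offset (0-based, counted over the segment
    units only) at which the interruption is inserted. The 1-9 bound is the
    operational definition used when reading repeat-primed PCR traces: one
    to nine continuous peaks of an off-block motif.
    """

    index: int
    motif: Motif
    copies: int

    def __post_init__(self) -> None:
        if not 1 <= self.copies <= 9:
            raise StructureError(
                f"interruption copies must be in [1, 9], got {self.copies}"
            )
        if self.index < 0:
            raise StructureError("interruption index must be >= 0")


@dataclass(frozen=True)
class AlleleStructure:
    """Ordered 5'->3' motif blocks plus interruptions on the plus strand."""

    segments: tuple[AlleleSegment, ...]
    interruptions: tuple[Interruption, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "interruptions", tuple(self.interruptions))
        total = self.segment_units
        for intr in self.interruptions:
            if intr.index > total:
                raise StructureError(
                    f"interruption index {intr.index} beyond {total} segment units"
                )

    # -- size accounting ---------------------------------------------------
    @property
    def segment_units(self) -> int:
        return sum(s.copies for s in self.segments)

    @property
    def total_units(self) -> int:
        """Total repeat units including interruption copies."""
        return self.segment_units + sum(i.copies for i in self.interruptions)

    @property
    def length_bp(self) -> int:
        return sum(s.length_bp for s in self.segments) + sum(
            i.copies * len(i.motif) for i in self.interruptions
        )

    def motifs(self) -> list[Motif]:
        seen: list[Motif] = []
        for seg in self.segments:
            if seg.motif not in seen:
                seen.append(seg.motif)
        return seen

    def all_motifs(self) -> list[Motif]:
        out = self.motifs()
        for intr in self.interruptions:
            if intr.motif not in out:
                out.append(intr.motif)
        return out

    @property
    def is_complex(self) -> bool:
        """True when the allele holds more than one segment motif."""
        return len({s.motif for s in self.segments}) > 1

    def unit_sequence(self) -> list[Motif]:
        """Per-unit motif labels, 5'->3', with interruptions spliced in."""
        base: list[Motif] = []
        for seg in self.segments:
            base.extend([seg.motif] * seg.copies)
        for intr in sorted(self.interruptions, key=lambda i: i.index, reverse=True):
            base[intr.index:intr.index] = [intr.motif] * intr.copies
        return base

    # -- serialization -----------------------------------------------------
    def to_string(self) -> str:
        """Compact text form ``(MOTIF)n...`` with ``[i:(MOTIF)c]`` suffixes
        for interruptions; round-trips through :func:`parse_structure`."""
        out = "".join(f"({s.motif.unit}){s.copies}" for s in self.segments)
        for intr in self.interruptions:
            out += f"[{intr.index}:({intr.motif.unit}){intr.copies}]"
        return out

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"motif": s.motif.unit, "copies": s.copies} for s in self.segments
            ],
            "interruptions": [
                {"index": i.index, "motif": i.motif.unit, "copies": i.copies}
                for i in self.interruptions
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "AlleleStructure":
        return cls(
            segments=tuple(
                AlleleSegment(Motif(s["motif"]), int(s["copies"]))
                for s in payload["segments"]
            ),
            interruptions=tuple(
                Interruption(int(i["index"]), Motif(i["motif"]), int(i["copies"]))
                for i in payload.get("interruptions", ())
            ),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def __str__(self) -> str:
        return self.to_string()


_SEG_RE = re.compile(r"\(([ACGT]+)\)(\d+)")
_INT_RE = re.compile(r"\[(\d+):\(([ACGT]+)\)(\d+)\]")


def parse_structure(text: str) -> AlleleStructure:
    """Parse the compact ``(MOTIF)n...[i:(MOTIF)c]`` allele notation."""
    text = text.strip()
    body, _, _ = text.partition("[")
    consumed = "".join(f"({m}){c}" for m, c in _SEG_RE.findall(body))
    if consumed != body.replace(" ", ""):
        raise StructureError(f"cannot parse structure string: {text!r}")
    segments = tuple(
        AlleleSegment(Motif(m), int(c)) for m, c in _SEG_RE.findall(body)
    )
    if not segments:
        raise StructureError(f"no segments in structure string: {text!r}")
    interruptions = tuple(
        Interruption(int(i), Motif(m), int(c))
        for i, m, c in _INT_RE.findall(text[len(body):])
    )
    return AlleleStructure(segments=segments, interruptions=interruptions)


def expand_allele(structure: AlleleStructure, seed: int | None = None) -> str:
    """Concatenate the structure's repeat units into the tract sequence.

    Deterministic; ``seed`` is accepted for interface symmetry with the
    stochastic generators and ignored. Length equals
    ``structure.length_bp`` exactly.
    """
    return "".join(m.unit for m in structure.unit_sequence())


_MAORI_5P = Motif("AAAGG")
_MAORI_EXP = Motif("AAGGG")


def matches_maori_pattern(
    structure: AlleleStructure,
    expansion_floor: int = 50,
    three_prime_copies: int = 10,
    three_prime_tolerance: int = 2,
) -> bool:
    """True for the Maori configuration (AAAGG)15-25(AAGGG)exp(AAAGG)~10.

    The AAGGG block must reach ``expansion_floor`` copies; the 3' AAAGG
    block must be within ``three_prime_tolerance`` of ``three_prime_copies``.
    """
    segs = structure.segments
    if len(segs) != 3:
        return False
    a, b, c = segs
    return (
        a.motif == _MAORI_5P
        and 15 <= a.copies <= 25
        and b.motif == _MAORI_EXP
        and b.copies >= expansion_floor
        and c.motif == _MAORI_5P
        and abs(c.copies - three_prime_copies) <= three_prime_tolerance
    )


# ---------------------------------------------------------------------------
# Locus definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval (as printed in genome browsers)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("interval end before start")

    def to_bed(self) -> tuple[str, int, int]:
        """0-based half-open BED coordinates."""
        return (self.chrom, self.start - 1, self.end)


def _pseudo_random_flank(length: int, rng: np.random.Generator) -> str:
    """Fixed non-repetitive flank sequence drawn base-by-base.

    Rejects draws that would create a mononucleotide run >= 4 so flanks
    never mimic the A-rich repeat and anchor matching stays unambiguous.
    """
    bases = "ACGT"
    out: list[str] = []
    while len(out) < length:
        b = bases[rng.integers(4)]
        if len(out) >= 3 and out[-1] == out[-2] == out[-3] == b:
            continue
        out.append(b)
    return "".join(out)


REFERENCE_STRUCTURE = AlleleStructure((AlleleSegment(Motif("AAAAG"), 11),))


@dataclass(frozen=True)
class LocusDefinition:
    """The repeat locus: coordinates, flank sequences, reference allele."""

    name: str
    repeat_region: GenomicInterval
    left_flank: str
    right_flank: str
    reference_allele: AlleleStructure = REFERENCE_STRUCTURE
    probe_intervals: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.left_flank or not self.right_flank:
            raise ValueError("flank sequences must be non-empty")
        _check_alphabet(self.left_flank)
        _check_alphabet(self.right_flank)

    @property
    def reference_tract(self) -> str:
        return expand_allele(self.reference_allele)

    def haplotype_sequence(self, allele: AlleleStructure) -> str:
        """Full plus-strand haplotype: left flank + tract + right flank."""
        return self.left_flank + expand_allele(allele) + self.right_flank

    def to_bed(self) -> str:
        rows = [self.repeat_region.to_bed() + (f"{self.name}_repeat",)]
        for k, probe in enumerate(self.probe_intervals, 1):
            rows.append(probe.to_bed() + (f"{self.name}_probe{k}",))
        return "\n".join("\t".join(map(str, r)) for r in rows) + "\n"

    def to_yaml(self) -> str:
        payload = {
            "name": self.name,
            "coordinate_convention": "1-based inclusive",
            "repeat_region": {
                "chrom": self.repeat_region.chrom,
                "start": self.repeat_region.start,
                "end": self.repeat_region.end,
            },
            "left_flank": self.left_flank,
            "right_flank": self.right_flank,
            "reference_allele": self.reference_allele.to_string(),
            "probe_intervals": [
                {"chrom": p.chrom, "start": p.start, "end": p.end}
                for p in self.probe_intervals
            ],
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "LocusDefinition":
        payload = yaml.safe_load(text)
        return cls(
            name=payload["name"],
            repeat_region=GenomicInterval(**payload["repeat_region"]),
            left_flank=payload["left_flank"],
            right_flank=payload["right_flank"],
            reference_allele=parse_structure(payload["reference_allele"]),
            probe_intervals=tuple(
                GenomicInterval(**p) for p in payload.get("probe_intervals", ())
            ),
        )


def default_locus(flank_bp: int = 1000, seed: int = 20230425) -> LocusDefinition:
    """RFC1 locus with synthetic non-repetitive flanks.

    The published amplicon flank sequences are not available, so flanks are
    fixed pseudo-random sequence derived from ``seed``; they serve as
    anchors for read placement and tract extraction.
    """
    rng = np.random.default_rng(seed)
    left = _pseudo_random_flank(flank_bp, rng)
    right = _pseudo_random_flank(flank_bp, rng)
    return LocusDefinition(
        name="RFC1",
        repeat_region=GenomicInterval("chr4", 39348425, 39348485),
        left_flank=left,
        right_flank=right,
        reference_allele=REFERENCE_STRUCTURE,
        probe_intervals=(
            GenomicInterval("chr4", 39348349, 39348469),
            GenomicInterval("chr4", 39348370, 39348490),
        ),
    )


class PhenotypeGroup(str, Enum):
    ATAXIA = "ataxia"
    NEUROPATHY = "neuropathy"
    ATAXIA_NEUROPATHY = "ataxia_neuropathy"
    SUSPECTED_CANVAS = "suspected_CANVAS"
    OTHER = "other"


@dataclass(frozen=True)
class DiploidGenotype:
    """Two allele structures plus sample metadata."""

    allele1: AlleleStructure
    allele2: AlleleStructure
    sample_id: str = ""
    phenotype_group: PhenotypeGroup = PhenotypeGroup.OTHER

    @property
    def alleles(self) -> tuple[AlleleStructure, AlleleStructure]:
        return (self.allele1, self.allele2)
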