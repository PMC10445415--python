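"""Synthetic inputs for every pipeline stage.

No sequencing data for this locus is publicly deposited, so the pipeline is
exercised end-to-end on simulated material: diploid genotypes drawn from the
published genotype-class counts, noisy long reads spanning the whole repeat
(targeted-capture style), and short panel reads over the locus region.

The generator's defaults are the study conditions: a 242-sample cohort with
37 biallelic-pathogenic samples (30 biallelic AAGGG, 2 biallelic Maori,
2 Maori/AAGGG, 2 biallelic ACAGG, 1 ACAGG/AAGGG), 45 biallelic
non-pathogenic samples of which 44 carry complex alleles, 160 samples with
at least one reference-range allele, and phenotype subgroups of
105/50/45/42 (ataxia / neuropathy / ataxia+neuropathy / suspected CANVAS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .repeat_model import (
    AlleleSegment,
    AlleleStructure,
    DiploidGenotype,
    LocusDefinition,
    Motif,
    PhenotypeGroup,
    parse_structure,
)

__all__ = [
    "ErrorModel",
    "SimulatedRead",
    "CohortSpec",
    "CONSENSUS_SHAPES",
    "simulate_long_reads",
    "simulate_short_reads",
    "simulate_cohort",
    "cohort_to_frame",
    "cohort_from_frame",
    "reads_to_fastq",
    "reads_to_fasta",
    "truth_table",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base substitution/insertion/deletion rates.

    Defaults approximate nanopore long-read noise; the indel-heavy profile
    deliberately stresses the G-rich motif ambiguity that makes this locus
    hard to decompose. Use :meth:`exact` for noise-free simulation.
    """

    substitution_rate: float = 0.02
    insertion_rate: float = 0.03
    deletion_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.2:
                raise ValueError(f"{name} must be in [0, 0.2], got {rate}")

    @classmethod
    def exact(cls, seed: int = 0) -> "ErrorModel":
        return cls(0.0, 0.0, 0.0, seed)

    @classmethod
    def short_read(cls, seed: int = 0) -> "ErrorModel":
        """Illumina-like: rare substitutions, no indels."""
        return cls(0.001, 0.0, 0.0, seed)

    @property
    def is_exact(self) -> bool:
        return (
            self.substitution_rate == 0
            and self.insertion_rate == 0
            and self.deletion_rate == 0
        )

    def apply(self, sequence: str, rng: np.random.Generator) -> str:
        """Corrupt ``sequence`` base-by-base under the model."""
        if self.is_exact:
            return sequence
        raw = np.frombuffer(sequence.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.int64)
        lut[ord("A")], lut[ord("C")], lut[ord("G")], lut[ord("T")] = 0, 1, 2, 3
        idx = lut[raw]
        n = idx.size
        keep = rng.random(n) >= self.deletion_rate
        sub = rng.random(n) < self.substitution_rate
        ins = rng.random(n) < self.insertion_rate
        # offsets 1..3 guarantee a substituted base differs from the original
        subbed = np.where(sub, (idx + rng.integers(1, 4, size=n)) % 4, idx)
        # slot 2i holds the (possibly substituted) base, slot 2i+1 a random
        # insertion after it; masked slots vanish
        slots = np.empty(2 * n, dtype=np.int64)
        mask = np.empty(2 * n, dtype=bool)
        slots[0::2] = subbed
        slots[1::2] = rng.integers(0, 4, size=n)
        mask[0::2] = keep
        mask[1::2] = ins
        return "".join(_BASES[slots[mask]])


@dataclass(frozen=True)
class SimulatedRead:
    """A simulated read with generator truth labels retained."""

    read_id: str
    sequence: str
    truth_haplotype: int  # 1 or 2
    spans_repeat: bool
    offset: int  # start position on the generating haplotype sequence


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_long_reads(
    genotype: DiploidGenotype,
    locus: LocusDefinition,
    coverage: int = 30,
    error: ErrorModel = ErrorModel(),
    seed: int | None = None,
) -> list[SimulatedRead]:
    """Full-length spanning reads: flank + tract + flank per haplotype.

    Targeted long-read capture of this locus yields reads that span the
    whole expansion, so every read covers both flanks by construction;
    ``coverage`` reads are emitted per haplotype. Deterministic for a fixed
    seed (``seed`` overrides ``error.seed``).
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = np.random.default_rng(error.seed if seed is None else seed)
    reads: list[SimulatedRead] = []
    for hap, allele in ((1, genotype.allele1), (2, genotype.allele2)):
        template = locus.haplotype_sequence(allele)
        for k in range(coverage):
            seq = error.apply(template, rng)
            reads.append(
                SimulatedRead(
                    read_id=f"{genotype.sample_id or 'sample'}_h{hap}_lr{k}",
                    sequence=seq,
                    truth_haplotype=hap,
                    spans_repeat=True,
                    offset=0,
                )
            )
    return reads


def simulate_short_reads(
    genotype: DiploidGenotype,
    locus: LocusDefinition,
    read_length: int = 150,
    coverage: int = 50,
    error: ErrorModel = ErrorModel.short_read(),
    seed: int | None = None,
    span_margin: int = 20,
) -> list[SimulatedRead]:
    """Short reads sampled uniformly over each haplotype sequence.

    ``spans_repeat`` is geometric truth: the read covers the entire repeat
    tract plus ``span_margin`` anchor bases on both sides (impossible once
    the tract outgrows ``read_length - 2 * span_margin``).
    """
    ref_span = len(locus.reference_tract)
    if read_length <= ref_span:
        raise ValueError(
            f"read_length {read_length} must exceed the reference repeat span "
            f"({ref_span} bp) for spanning-read logic to be meaningful"
        )
    rng = np.random.default_rng(error.seed if seed is None else seed)
    flank = len(locus.left_flank)
    reads: list[SimulatedRead] = []
    for hap, allele in ((1, genotype.allele1), (2, genotype.allele2)):
        template = locus.haplotype_sequence(allele)
        tract_len = allele.length_bp
        n_reads = int(np.ceil(coverage * len(template) / read_length))
        starts = rng.integers(0, len(template) - read_length + 1, size=n_reads)
        for k, start in enumerate(sorted(starts.tolist())):
            fragment = template[start:start + read_length]
            spans = (
                start <= flank - span_margin
                and start + read_length >= flank + tract_len + span_margin
            )
            reads.append(
                SimulatedRead(
                    read_id=f"{genotype.sample_id or 'sample'}_h{hap}_sr{k}",
                    sequence=error.apply(fragment, rng),
                    truth_haplotype=hap,
                    spans_repeat=spans,
                    offset=int(start),
                )
            )
    return reads


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _pure(motif: str, copies: int) -> AlleleStructure:
    return AlleleStructure((AlleleSegment(Motif(motif), copies),))


#: Consensus allele configurations recovered by targeted long-read
#: sequencing of three patient samples; used as the default menu of complex
#: non-pathogenic alleles. Copy counts are fixed at the reported approximate
#: values with every block comfortably above the 10-unit segment threshold.
CONSENSUS_SHAPES: dict[str, tuple[AlleleStructure, AlleleStructure]] = {
    "HP220149": (
        parse_structure("(AAAAG)12(AAGAC)258"),
        parse_structure("(AAAGG)12(AAAGGG)36(AAGGG)12"),
    ),
    "HP220160": (
        parse_structure("(AAGGG)400"),
        parse_structure("(AAAGG)12(AAAGGG)46(AAGGG)12"),
    ),
    "HP220123": (
        parse_structure("(AAAAG)125"),
        parse_structure("(AAGGG)100(AGGGG)30"),
    ),
}

_COMPLEX_MENU: tuple[tuple[AlleleStructure, AlleleStructure], ...] = tuple(
    CONSENSUS_SHAPES.values()
)


@dataclass(frozen=True)
class CohortSpec:
    """Genotype-class and phenotype-subgroup counts for cohort simulation.

    Defaults reproduce the screened Australasian cohort: 242 samples, 82 of
    which carry biallelic expansions (37 pathogenic + 45 non-pathogenic).
    """

    n_biallelic_aaggg: int = 30
    n_biallelic_maori: int = 2
    n_maori_aaggg: int = 2
    n_biallelic_acagg: int = 2
    n_acagg_aaggg: int = 1
    n_benign_biallelic: int = 45
    n_benign_complex: int = 44
    n_ataxia: int = 105
    n_neuropathy: int = 50
    n_ataxia_neuropathy: int = 45
    n_suspected_canvas: int = 42
    n_total: int = 242
    #: two-allele genotype shapes for complex samples; complex alleles
    #: paired with long pure ladders can be invisible to RP-PCR, so the
    #: menu keeps the reported allele pairings intact
    complex_menu: tuple[tuple[AlleleStructure, AlleleStructure], ...] = _COMPLEX_MENU

    def __post_init__(self) -> None:
        if self.n_benign_complex > self.n_benign_biallelic:
            raise ValueError("complex count exceeds benign-biallelic count")
        if self.n_expanded > self.n_total:
            raise ValueError("genotype-class counts exceed cohort size")
        groups = (
            self.n_ataxia
            + self.n_neuropathy
            + self.n_ataxia_neuropathy
            + self.n_suspected_canvas
        )
        if groups != self.n_total:
            raise ValueError(
                f"phenotype subgroups sum to {groups}, expected {self.n_total}"
            )

    @property
    def n_pathogenic(self) -> int:
        return (
            self.n_biallelic_aaggg
            + self.n_biallelic_maori
            + self.n_maori_aaggg
            + self.n_biallelic_acagg
            + self.n_acagg_aaggg
        )

    @property
    def n_expanded(self) -> int:
        """Samples with biallelic expansions (no reference-range allele)."""
        return self.n_pathogenic + self.n_benign_biallelic

    @property
    def n_reference_range(self) -> int:
        return self.n_total - self.n_expanded


def _maori(rng: np.random.Generator) -> AlleleStructure:
    return AlleleStructure(
        (
            AlleleSegment(Motif("AAAGG"), int(rng.integers(15, 26))),
            AlleleSegment(Motif("AAGGG"), int(rng.integers(300, 701))),
            AlleleSegment(Motif("AAAGG"), 10),
        )
    )


def _aaggg_exp(rng: np.random.Generator) -> AlleleStructure:
    return _pure("AAGGG", int(rng.integers(400, 1001)))


def _acagg_exp(rng: np.random.Generator) -> AlleleStructure:
    return _pure("ACAGG", int(rng.integers(600, 901)))


def _benign_exp(rng: np.random.Generator) -> AlleleStructure:
    if rng.random() < 0.5:
        return _pure("AAAAG", int(rng.integers(60, 201)))
    return _pure("AAAGG", int(rng.integers(60, 151)))


def _ref_range(rng: np.random.Generator) -> AlleleStructure:
    return _pure("AAAAG", int(rng.integers(8, 15)))


def _jitter_blocks(
    structure: AlleleStructure, rng: np.random.Generator, frac: float = 0.1
) -> AlleleStructure:
    """Vary large blocks (>= 30 units) by +/- ``frac`` so complex samples
    are not carbon copies; small blocks stay at their reported sizes."""
    segs = []
    for seg in structure.segments:
        copies = seg.copies
        if copies >= 30:
            lo, hi = int(copies * (1 - frac)), int(copies * (1 + frac))
            copies = int(rng.integers(lo, hi + 1))
        segs.append(AlleleSegment(seg.motif, copies))
    return AlleleStructure(tuple(segs), structure.interruptions)


def simulate_cohort(
    spec: CohortSpec = CohortSpec(), seed: int = 0
) -> list[DiploidGenotype]:
    """Draw a cohort matching ``spec`` exactly; reproducible under ``seed``.

    Phenotype-subgroup labels are assigned independently of genotype class
    (no joint cross-tabulation is specified for the study cohort), by a
    seeded shuffle.
    """
    rng = np.random.default_rng(seed)
    genotypes: list[tuple[AlleleStructure, AlleleStructure]] = []

    for _ in range(spec.n_biallelic_aaggg):
        genotypes.append((_aaggg_exp(rng), _aaggg_exp(rng)))
    for _ in range(spec.n_biallelic_maori):
        genotypes.append((_maori(rng), _maori(rng)))
    for _ in range(spec.n_maori_aaggg):
        genotypes.append((_maori(rng), _aaggg_exp(rng)))
    for _ in range(spec.n_biallelic_acagg):
        genotypes.append((_acagg_exp(rng), _acagg_exp(rng)))
    for _ in range(spec.n_acagg_aaggg):
        genotypes.append((_acagg_exp(rng), _aaggg_exp(rng)))

    menu = spec.complex_menu
    for k in range(spec.n_benign_complex):
        a1, a2 = menu[k % len(menu)]
        genotypes.append((_jitter_blocks(a1, rng), _jitter_blocks(a2, rng)))
    for _ in range(spec.n_benign_biallelic - spec.n_benign_complex):
        a = _pure("AAAAG", int(rng.integers(100, 151)))
        b = _pure("AAAGG", int(rng.integers(60, 101)))
        genotypes.append((a, b))

    for _ in range(spec.n_reference_range):
        allele1 = _ref_range(rng)
        u = rng.random()
        if u < 0.60:
            allele2 = _ref_range(rng)
        elif u < 0.80:
            allele2 = _aaggg_exp(rng)  # pathogenic carrier
        else:
            allele2 = _benign_exp(rng)
        genotypes.append((allele1, allele2))

    groups = (
        [PhenotypeGroup.ATAXIA] * spec.n_ataxia
        + [PhenotypeGroup.NEUROPATHY] * spec.n_neuropathy
        + [PhenotypeGroup.ATAXIA_NEUROPATHY] * spec.n_ataxia_neuropathy
        + [PhenotypeGroup.SUSPECTED_CANVAS] * spec.n_suspected_canvas
    )
    groups = groups[: len(genotypes)] + [PhenotypeGroup.OTHER] * max(
        0, len(genotypes) - len(groups)
    )
    order = rng.permutation(len(groups))
    return [
        DiploidGenotype(
            allele1=a1,
            allele2=a2,
            sample_id=f"S{k:04d}",
            phenotype_group=groups[order[k]],
        )
        for k, (a1, a2) in enumerate(genotypes)
    ]


# ---------------------------------------------------------------------------
# Tabular / sequence-file output
# ---------------------------------------------------------------------------

def cohort_to_frame(cohort: Sequence[DiploidGenotype]) -> pd.DataFrame:
    """Cohort table: sample_id, phenotype_group, allele1, allele2."""
    return pd.DataFrame(
        {
            "sample_id": [g.sample_id for g in cohort],
            "phenotype_group": [g.phenotype_group.value for g in cohort],
            "allele1": [g.allele1.to_string() for g in cohort],
            "allele2": [g.allele2.to_string() for g in cohort],
        }
    )


def cohort_from_frame(frame: pd.DataFrame) -> list[DiploidGenotype]:
    return [
        DiploidGenotype(
            allele1=parse_structure(row.allele1),
            allele2=parse_structure(row.allele2),
            sample_id=str(row.sample_id),
            phenotype_group=PhenotypeGroup(row.phenotype_group),
        )
        for row in frame.itertuples()
    ]


def reads_to_fastq(
    reads: Iterable[SimulatedRead], handle, quality: int = 20
) -> None:
    """Write reads as FASTQ with a constant quality score."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(read.sequence)
        records.append(rec)
    SeqIO.write(records, handle, "fastq")


def reads_to_fasta(reads: Iterable[SimulatedRead], handle) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in reads),
        handle,
        "fasta",
    )


def truth_table(reads: Sequence[SimulatedRead]) -> pd.DataFrame:
    """Sidecar truth labels: read_id, haplotype, spans_repeat, offset."""
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "haplotype": [r.truth_haplotype for r in reads],
            "spans_repeat": [r.spans_repeat for r in reads],
            "offset": [r.offset for r in reads],
        }
    )
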