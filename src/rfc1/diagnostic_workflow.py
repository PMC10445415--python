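"""The multi-step diagnostic decision tree for biallelic expansions.

Stages mirror diagnostic practice for this locus:

1. **Screen** — short-read panel (preferred when available) or flanking
   PCR. A reference-range allele excludes biallelic expansion: negative
   report.
2. **RP-PCR panel** — motif presence / interruption / gap interpretation.
   Presence of only pathogenic motifs with no gaps supports a positive
   report without sequencing; only reference/benign motifs and no gaps is
   a negative-with-caveat (RP-PCR cannot phase alleles or see past ~160
   units). Anything mixed, gapped or empty routes to long reads.
3. **Targeted long-read sequencing** — decomposition into per-haplotype
   allele structures, then structural genotype classification.

Every report carries its evidence chain and a caveat list, including the
points at which testing for other repeat-expansion disorders or RFC1
loss-of-function variants is recommended rather than performed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .long_read_decomposition import (
    SampleDecomposition,
    SegmentationParams,
    decompose_sample,
)
from .pcr_assays import (
    AssayConfig,
    AssayTrace,
    FlankingScreen,
    TraceCall,
    flanking_pcr,
    interpret_traces,
    rp_panel,
    screen_flanking,
)
from .repeat_model import (
    AlleleStructure,
    DiploidGenotype,
    LocusDefinition,
    Motif,
    MotifLabel,
    MotifRegistry,
    core_motifs,
    default_locus,
    default_registry,
    matches_maori_pattern,
)
from .short_read_screen import ScreenParams, ScreenResult, screen_sample
from .synthetic_data import ErrorModel, SimulatedRead, simulate_long_reads

__all__ = [
    "PathogenicityClass",
    "DiagnosticReport",
    "WorkflowConfig",
    "WorkflowInput",
    "is_pathogenic_allele",
    "classify_genotype",
    "run_workflow",
    "run_cohort",
]

REPORT_SCHEMA_VERSION = "1.0"


class PathogenicityClass(str, Enum):
    BIALLELIC_PATHOGENIC = "biallelic_pathogenic"
    CARRIER_SINGLE_PATHOGENIC = "carrier_single_pathogenic"
    BIALLELIC_BENIGN_OR_UNDETERMINED = "biallelic_benign_or_undetermined"
    REFERENCE_PRESENT_NEGATIVE = "reference_present_negative"
    NOVEL_MOTIF_UNDETERMINED = "novel_motif_undetermined"
    INDETERMINATE = "indeterminate"


_PATHOGENIC_PURE = {"AAGGG", "ACAGG"}


def is_pathogenic_allele(
    structure: AlleleStructure,
    expansion_floor: int = 50,
    max_interruption_units: int = 9,
) -> bool:
    """True for the three disease-associated allele types.

    A pure AAGGG or ACAGG expansion of at least ``expansion_floor`` units
    (tolerating interruptions totalling <= ``max_interruption_units``), or
    the Maori configuration. No size threshold is established for disease
    causation; the floor is an operational default surfaced on reports.
    """
    if matches_maori_pattern(structure, expansion_floor=expansion_floor):
        return True
    motifs = {s.motif.canonical for s in structure.segments}
    if len(motifs) != 1 or motifs.pop() not in _PATHOGENIC_PURE:
        return False
    if sum(i.copies for i in structure.interruptions) > max_interruption_units:
        return False
    return structure.segment_units >= expansion_floor


def classify_genotype(
    genotype: DiploidGenotype | tuple[AlleleStructure | None, AlleleStructure | None],
    registry: MotifRegistry | None = None,
    expansion_floor: int = 50,
) -> PathogenicityClass:
    """Classify a resolved genotype by the structural rules.

    Order of precedence: biallelic pathogenic; any non-expanded allele
    (reference-range or intermediate, i.e. below the expansion floor) is a
    negative; one pathogenic plus one non-pathogenic expansion is a
    carrier; expansions carrying undetermined or unregistered segment
    motifs are undetermined-novel; otherwise biallelic benign. Interruption
    motifs do not enter classification (1-9 units are tolerated).
    """
    registry = registry or default_registry()
    alleles = (
        genotype.alleles if isinstance(genotype, DiploidGenotype) else tuple(genotype)
    )
    if any(a is None for a in alleles):
        return PathogenicityClass.INDETERMINATE
    path = [is_pathogenic_allele(a, expansion_floor) for a in alleles]
    if all(path):
        return PathogenicityClass.BIALLELIC_PATHOGENIC
    if any(a.total_units < expansion_floor for a in alleles):
        return PathogenicityClass.REFERENCE_PRESENT_NEGATIVE
    if any(path):
        return PathogenicityClass.CARRIER_SINGLE_PATHOGENIC
    labels = {
        registry.label(s.motif) for a in alleles for s in a.segments
    }
    if labels & {MotifLabel.NOVEL, MotifLabel.UNDETERMINED}:
        return PathogenicityClass.NOVEL_MOTIF_UNDETERMINED
    return PathogenicityClass.BIALLELIC_BENIGN_OR_UNDETERMINED


# ---------------------------------------------------------------------------
# Workflow orchestration
# ---------------------------------------------------------------------------

@dataclass
class WorkflowConfig:
    locus: LocusDefinition = field(default_factory=default_locus)
    registry: MotifRegistry = field(default_factory=default_registry)
    assay: AssayConfig = field(default_factory=AssayConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    expansion_floor: int = 50
    extended_panel: bool = False
    decomposition_motifs: list[Motif] = field(default_factory=core_motifs)
    long_read_coverage: int = 6
    long_read_error: ErrorModel = field(default_factory=ErrorModel.exact)
    seed: int = 0


@dataclass
class WorkflowInput:
    """Per-sample inputs; anything missing is simulated from ``genotype``.

    At least one of short reads / flanking trace (or a genotype to simulate
    them from) plus RP-PCR traces (or genotype) must be available.
    """

    sample_id: str
    genotype: DiploidGenotype | None = None
    short_reads: Sequence[SimulatedRead] | None = None
    flanking_trace: AssayTrace | None = None
    rp_traces: Sequence[AssayTrace] | None = None
    long_read_sequences: Sequence[str] | None = None

    @classmethod
    def from_genotype(cls, genotype: DiploidGenotype) -> "WorkflowInput":
        return cls(sample_id=genotype.sample_id, genotype=genotype)


@dataclass
class DiagnosticReport:
    sample_id: str
    pathogenicity_class: PathogenicityClass
    final_genotype: tuple[AlleleStructure | None, AlleleStructure | None]
    stage_results: list[tuple[str, dict]] = field(default_factory=list)
    caveats: list[str] = field(default_factory=list)
    schema_version: str = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "sample_id": self.sample_id,
            "pathogenicity_class": self.pathogenicity_class.value,
            "final_genotype": [
                a.to_string() if a is not None else None for a in self.final_genotype
            ],
            "stage_results": [
                {"stage": name, **payload} for name, payload in self.stage_results
            ],
            "caveats": self.caveats,
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


_LIMITATIONS = (
    "RP-PCR reports at most the first ~160 repeat units and cannot phase "
    "alleles; include the limitations of testing on the report"
)
_STAR_POINT = (
    "recommend testing for additional repeat-expansion disorders to exclude "
    "alternative causes"
)
_LOF_NOTE = (
    "RFC1 loss-of-function variants in trans with a single expanded allele "
    "are not assessed by this workflow"
)


def _sample_seed(sample_id: str, base_seed: int) -> int:
    return (zlib.crc32(sample_id.encode()) ^ base_seed) & 0x7FFFFFFF


def _trace_call_payload(call: TraceCall) -> dict:
    return {
        "motifs_present": sorted(m.canonical for m in call.motifs_present),
        "interruption_motifs": sorted(m.canonical for m in call.interruption_motifs),
        "gap_flag": call.gap_flag,
        "no_product": call.no_product,
    }


def run_workflow(
    sample: WorkflowInput, config: WorkflowConfig = WorkflowConfig()
) -> DiagnosticReport:
    """Execute the staged decision tree for one sample."""
    report = DiagnosticReport(
        sample_id=sample.sample_id,
        pathogenicity_class=PathogenicityClass.INDETERMINATE,
        final_genotype=(None, None),
    )
    report.caveats.append(
        f"expansion floor for pathogenic calls: {config.expansion_floor} repeat "
        "units (no disease-causing size threshold is established)"
    )
    report.caveats.append(_LOF_NOTE)

    # ---- stage 1: screen (short-read panel preferred over flanking PCR)
    screen_call: str | None = None
    flank_screen: FlankingScreen | None = None
    if sample.short_reads is not None:
        result: ScreenResult = screen_sample(
            sample.short_reads, config.locus, config.screen
        )
        screen_call = result.call
        report.stage_results.append(
            ("short_read_screen", result.to_row())
        )
    flanking = sample.flanking_trace
    if flanking is None and sample.genotype is not None:
        flanking = flanking_pcr(sample.genotype, config.assay)
    if flanking is not None:
        flank_screen = screen_flanking(flanking, config.assay)
        report.stage_results.append(
            (
                "flanking_pcr",
                {
                    "peaks_bp": list(flanking.sizes),
                    "excluded": flank_screen.excluded,
                    "suspected_biallelic": flank_screen.suspected_biallelic,
                    "warning": flank_screen.warning,
                },
            )
        )
    if screen_call is not None and flank_screen is not None:
        ngs_negative = screen_call == "reference_present"
        pcr_negative = flank_screen.excluded
        if ngs_negative != pcr_negative and screen_call != "indeterminate":
            report.caveats.append(
                "contradictory screening evidence (NGS vs flanking PCR)"
            )
            report.pathogenicity_class = PathogenicityClass.INDETERMINATE
            return report
    if screen_call is None and flank_screen is None:
        report.caveats.append("no screening input available")
        return report
    negative = screen_call == "reference_present" or (
        flank_screen is not None and flank_screen.excluded
    )
    if negative:
        report.pathogenicity_class = PathogenicityClass.REFERENCE_PRESENT_NEGATIVE
        report.caveats.append(_STAR_POINT)
        return report
    if flank_screen is not None and flank_screen.warning:
        report.caveats.append(
            "flanking product outside the normal window: possible amplifiable "
            "intermediate allele"
        )

    # ---- stage 2: RP-PCR panel
    traces = sample.rp_traces
    if traces is None and sample.genotype is not None:
        traces = rp_panel(sample.genotype, config.assay, config.extended_panel)
    call: TraceCall | None = None
    if traces is not None:
        call = interpret_traces(traces, config.assay)
        report.stage_results.append(("rp_pcr", _trace_call_payload(call)))
        if not call.gap_flag and not call.no_product and call.motifs_present:
            labels = {config.registry.label(m) for m in call.motifs_present}
            if labels <= {MotifLabel.PATHOGENIC}:
                report.pathogenicity_class = PathogenicityClass.BIALLELIC_PATHOGENIC
                report.caveats.append(_LIMITATIONS)
                return report
            if labels <= {MotifLabel.REFERENCE, MotifLabel.BENIGN}:
                report.pathogenicity_class = (
                    PathogenicityClass.BIALLELIC_BENIGN_OR_UNDETERMINED
                )
                report.caveats.append(_LIMITATIONS)
                report.caveats.append(_STAR_POINT)
                return report
        # gapped, empty, or mixed benign/pathogenic/undetermined: long reads

    # ---- stage 3: targeted long-read sequencing
    sequences = sample.long_read_sequences
    if sequences is None and sample.genotype is not None:
        reads = simulate_long_reads(
            sample.genotype,
            config.locus,
            coverage=config.long_read_coverage,
            error=config.long_read_error,
            seed=_sample_seed(sample.sample_id, config.seed),
        )
        sequences = [r.sequence for r in reads]
    if sequences is None:
        report.caveats.append(
            "unresolved by PCR stages and no long-read data available"
        )
        return report
    decomposition: SampleDecomposition = decompose_sample(
        sequences,
        config.locus,
        config.decomposition_motifs,
        params=config.segmentation,
    )
    report.stage_results.append(
        (
            "long_read_decomposition",
            {
                "n_reads": decomposition.n_reads,
                "n_dropped": decomposition.n_dropped,
                "haplotypes": [r.to_dict() for r in decomposition.results],
            },
        )
    )
    alleles = decomposition.alleles
    report.final_genotype = alleles
    novel = sorted(
        {m.canonical for r in decomposition.results for m in r.novel_motifs}
    )
    if novel:
        report.caveats.append(
            "novel repeat motifs observed: " + ", ".join(novel)
        )
    report.pathogenicity_class = classify_genotype(
        alleles, config.registry, config.expansion_floor
    )
    if report.pathogenicity_class in (
        PathogenicityClass.REFERENCE_PRESENT_NEGATIVE,
        PathogenicityClass.BIALLELIC_BENIGN_OR_UNDETERMINED,
        PathogenicityClass.NOVEL_MOTIF_UNDETERMINED,
    ):
        report.caveats.append(_STAR_POINT)
    return report


def run_cohort(
    cohort: Sequence[DiploidGenotype],
    config: WorkflowConfig = WorkflowConfig(),
) -> list[DiagnosticReport]:
    """Batch mode: one report per cohort sample, simulated from genotypes."""
    return [
        run_workflow(WorkflowInput.from_genotype(g), config) for g in cohort
    ]
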