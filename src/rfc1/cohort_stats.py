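"""Cohort-level aggregation of diagnostic outcomes.

Headline quantities for a screened cohort: overall and per-phenotype-
subgroup prevalence of biallelic pathogenic expansions, prevalence of each
repeat motif among samples with biallelic expansions, and the fraction of
biallelic-expansion samples carrying complex (multi-motif) alleles.

Because RP-PCR cannot phase alleles, motif prevalence is counted per
patient sample, not per allele, and the denominator is the set of samples
with biallelic expansions (pathogenic or not). All percentages are
100 * count / denominator rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .diagnostic_workflow import DiagnosticReport, PathogenicityClass
from .pcr_assays import TraceCall

__all__ = [
    "pct",
    "CohortSummary",
    "summarize_cohort",
    "motif_prevalence",
]

_EXPANDED_CLASSES = {
    PathogenicityClass.BIALLELIC_PATHOGENIC,
    PathogenicityClass.CARRIER_SINGLE_PATHOGENIC,
    PathogenicityClass.BIALLELIC_BENIGN_OR_UNDETERMINED,
    PathogenicityClass.NOVEL_MOTIF_UNDETERMINED,
}


def pct(count: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (the printing convention
    that reproduces every published figure checked)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    value = Decimal(100) * Decimal(count) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    n_total: int
    n_biallelic_pathogenic: int
    pct_biallelic_pathogenic: float
    subgroups: dict[str, tuple[int, int, float]]  # name -> (n, n_positive, pct)
    n_biallelic_expansion: int
    n_complex: int
    pct_complex: float
    motif_prevalence: dict[str, tuple[int, float]]  # canonical -> (n, pct)

    def __post_init__(self) -> None:
        if sum(n for n, _, _ in self.subgroups.values()) != self.n_total:
            raise ValueError("subgroup sizes must sum to the cohort total")
        if not (
            self.n_biallelic_pathogenic
            <= self.n_biallelic_expansion
            <= self.n_total
        ):
            raise ValueError("count ordering violated")

    @classmethod
    def from_counts(
        cls,
        n_total: int,
        n_biallelic_pathogenic: int,
        subgroup_counts: Mapping[str, tuple[int, int]],
        n_biallelic_expansion: int,
        n_complex: int,
        motif_counts: Mapping[str, int],
    ) -> "CohortSummary":
        """Build a summary directly from tabulated counts."""
        return cls(
            n_total=n_total,
            n_biallelic_pathogenic=n_biallelic_pathogenic,
            pct_biallelic_pathogenic=pct(n_biallelic_pathogenic, n_total),
            subgroups={
                name: (n, k, pct(k, n)) for name, (n, k) in subgroup_counts.items()
            },
            n_biallelic_expansion=n_biallelic_expansion,
            n_complex=n_complex,
            pct_complex=(
                pct(n_complex, n_biallelic_expansion)
                if n_biallelic_expansion
                else 0.0
            ),
            motif_prevalence={
                m: (k, pct(k, n_biallelic_expansion))
                for m, k in motif_counts.items()
            },
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": "biallelic_pathogenic",
                "group": "overall",
                "n": self.n_biallelic_pathogenic,
                "denominator": self.n_total,
                "pct": self.pct_biallelic_pathogenic,
            }
        ]
        for name, (n, k, p) in self.subgroups.items():
            rows.append(
                {
                    "metric": "biallelic_pathogenic",
                    "group": name,
                    "n": k,
                    "denominator": n,
                    "pct": p,
                }
            )
        rows.append(
            {
                "metric": "complex_alleles",
                "group": "biallelic_expansion",
                "n": self.n_complex,
                "denominator": self.n_biallelic_expansion,
                "pct": self.pct_complex,
            }
        )
        for motif, (k, p) in sorted(self.motif_prevalence.items()):
            rows.append(
                {
                    "metric": f"motif:{motif}",
                    "group": "biallelic_expansion",
                    "n": k,
                    "denominator": self.n_biallelic_expansion,
                    "pct": p,
                }
            )
        return pd.DataFrame(rows)


def motif_prevalence(
    trace_calls: Sequence[TraceCall],
) -> dict[str, tuple[int, float]]:
    """Per-motif (count, percentage) over biallelic-expansion samples.

    A sample counts once per motif it shows at presence level (>= 10
    continuous peaks) regardless of how many alleles carry it.
    """
    if not trace_calls:
        raise ValueError("empty denominator: no biallelic-expansion samples")
    counts: dict[str, int] = {}
    for call in trace_calls:
        for motif in call.motifs_present:
            counts[motif.canonical] = counts.get(motif.canonical, 0) + 1
    n = len(trace_calls)
    return {m: (k, pct(k, n)) for m, k in sorted(counts.items())}


def _is_complex_sample(report: DiagnosticReport) -> bool:
    """Complex = any reported allele with more than one segment motif;
    when alleles are unresolved (PCR-only positive/negative), fall back to
    the trace evidence: a gap flag or an uncharacteristic multi-motif
    pattern with interruptions."""
    if any(a is not None and a.is_complex for a in report.final_genotype):
        return True
    if all(a is None for a in report.final_genotype):
        for stage, payload in report.stage_results:
            if stage == "rp_pcr":
                if payload["gap_flag"] or payload["interruption_motifs"]:
                    return True
    return False


def summarize_cohort(
    reports: Sequence[DiagnosticReport],
    cohort_table: pd.DataFrame,
) -> CohortSummary:
    """Aggregate per-sample reports against the cohort table.

    ``cohort_table`` must carry ``sample_id`` and ``phenotype_group``
    columns (one row per report); percentages follow the published
    denominators: overall for prevalence, subgroup size per subgroup, and
    biallelic-expansion samples for motif prevalence and the complex
    fraction.
    """
    if not len(reports):
        raise ValueError("empty cohort")
    ids = [r.sample_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id among reports")
    table = cohort_table.set_index("sample_id")
    missing = set(ids) - set(table.index)
    if missing:
        raise ValueError(f"reports without cohort rows: {sorted(missing)[:5]}")

    n_total = len(reports)
    positive = {
        r.sample_id
        for r in reports
        if r.pathogenicity_class == PathogenicityClass.BIALLELIC_PATHOGENIC
    }
    expanded = [r for r in reports if r.pathogenicity_class in _EXPANDED_CLASSES]
    n_exp = len(expanded)

    subgroup_counts: dict[str, tuple[int, int]] = {}
    for group, sub in table.loc[ids].groupby("phenotype_group", sort=False):
        members = set(sub.index)
        subgroup_counts[str(group)] = (
            len(members),
            len(members & positive),
        )

    motif_counts: dict[str, int] = {}
    for r in expanded:
        seen: set[str] = set()
        for stage, payload in r.stage_results:
            if stage == "rp_pcr":
                seen.update(payload["motifs_present"])
        for a in r.final_genotype:
            if a is not None:
                seen.update(s.motif.canonical for s in a.segments)
        for m in seen:
            motif_counts[m] = motif_counts.get(m, 0) + 1

    n_complex = sum(_is_complex_sample(r) for r in expanded)
    return CohortSummary.from_counts(
        n_total=n_total,
        n_biallelic_pathogenic=len(positive),
        subgroup_counts=subgroup_counts,
        n_biallelic_expansion=n_exp,
        n_complex=n_complex,
        motif_counts=motif_counts,
    )
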