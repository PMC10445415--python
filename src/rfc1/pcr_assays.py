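"""Forward simulation and interpretation of the locus PCR assays.

Two assay families are modelled as they are read out on a capillary
fragment analyser:

* **Flanking PCR** amplifies across the whole repeat with primers in unique
  flanking sequence. Product length is a constant (combined flank/primer
  footprint) plus the repeat tract length; alleles beyond an amplification
  cap yield no product, so an empty trace flags a suspected biallelic
  expansion. Samples with at least one peak in the normal window
  (340-370 bp, ~8-14 repeat units) are screened out.

* **Repeat-primed PCR (RP-PCR)** pairs a flanking primer with a primer
  annealing inside the repeat, producing a ladder with one peak per repeat
  unit that matches the assayed motif. A motif is called *present* at >= 10
  consecutive peaks; runs of 1-9 peaks are *interruptions*; stretches with
  no peak in any assay of the panel, flanked by peaks on both sides, raise
  a gap flag (possible unassayed/novel motif). The ladder reports at most
  the first ~160 repeat units of each allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .repeat_model import (
    AlleleStructure,
    DiploidGenotype,
    Motif,
)

__all__ = [
    "AssayConfig",
    "AssayTrace",
    "FlankingScreen",
    "TraceCall",
    "amplicon_length",
    "flanking_pcr",
    "screen_flanking",
    "rp_pcr_trace",
    "rp_panel",
    "interpret_traces",
    "traces_to_frame",
    "traces_from_frame",
]

_STANDARD_PANEL = ("AAAAG", "AAAGG", "AAGGG", "ACAGG")
_EXTENDED_EXTRA = ("AAGAC", "AAAGGG")


@dataclass(frozen=True)
class AssayConfig:
    """Tunable assay parameters.

    ``flank_constant_bp`` is the non-repeat portion of the flanking
    amplicon. It is derived from the printed normal window: peaks at
    340-370 bp correspond to ~8-14 pentamer units, and 340 - 8*5 =
    370 - 14*5 = 300 is the unique constant consistent with both endpoints.
    """

    flank_constant_bp: int = 300
    normal_window_bp: tuple[int, int] = (340, 370)
    amplification_cap_units: int = 50
    rp_detection_limit_units: int = 160
    rp_anchor_bp: int = 80
    gap_threshold_units: int = 10
    presence_min_peaks: int = 10
    max_interruption_peaks: int = 9
    ladder_decay_units: float = 60.0
    rp_assay_motifs: tuple[str, ...] = _STANDARD_PANEL
    extended_assay_motifs: tuple[str, ...] = _STANDARD_PANEL + _EXTENDED_EXTRA

    def __post_init__(self) -> None:
        lo, hi = self.normal_window_bp
        if not (lo <= self.flank_constant_bp + 5 * 8 and
                self.flank_constant_bp + 5 * 14 <= hi):
            raise ValueError(
                "normal window inconsistent with flank constant + 8..14 pentamers"
            )

    def panel(self, extended: bool = False) -> tuple[Motif, ...]:
        names = self.extended_assay_motifs if extended else self.rp_assay_motifs
        return tuple(Motif(m) for m in names)


@dataclass(frozen=True)
class AssayTrace:
    """A capillary peak train: (size in bp, height) pairs, sizes increasing.

    ``assay`` is ``"flanking"`` or ``"rp:<canonical motif>"``.
    """

    assay: str
    peaks: tuple[tuple[float, float], ...]
    sample_id: str = ""

    def __post_init__(self) -> None:
        sizes = [s for s, _ in self.peaks]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("peak sizes must be strictly increasing")

    @property
    def sizes(self) -> tuple[float, ...]:
        return tuple(s for s, _ in self.peaks)

    @property
    def is_rp(self) -> bool:
        return self.assay.startswith("rp:")

    @property
    def motif(self) -> Motif:
        if not self.is_rp:
            raise ValueError("flanking traces have no assay motif")
        return Motif(self.assay.split(":", 1)[1])


# ---------------------------------------------------------------------------
# Flanking PCR
# ---------------------------------------------------------------------------

def amplicon_length(allele: AlleleStructure, cfg: AssayConfig = AssayConfig()) -> int | None:
    """Flanking-PCR product size in bp, or None when the allele is too
    large to amplify (total repeat units above the amplification cap)."""
    if allele.total_units > cfg.amplification_cap_units:
        return None
    return cfg.flank_constant_bp + allele.length_bp


def flanking_pcr(
    genotype: DiploidGenotype, cfg: AssayConfig = AssayConfig()
) -> AssayTrace:
    """Fragment-analysis trace of the flanking assay for one sample.

    Identical allele lengths merge to a single peak of doubled height.
    """
    sizes: dict[int, float] = {}
    for allele in genotype.alleles:
        length = amplicon_length(allele, cfg)
        if length is not None:
            sizes[length] = sizes.get(length, 0.0) + 1.0
    peaks = tuple(sorted((float(s), h) for s, h in sizes.items()))
    return AssayTrace("flanking", peaks, sample_id=genotype.sample_id)


@dataclass(frozen=True)
class FlankingScreen:
    """Screen outcome: normal-window peak => excluded from further testing;
    empty trace => suspected biallelic expansion. A non-empty trace whose
    peaks all fall outside the normal window is treated as suspected
    biallelic with a warning (amplifiable intermediate allele)."""

    excluded: bool
    suspected_biallelic: bool
    warning: bool = False


def screen_flanking(
    trace: AssayTrace, cfg: AssayConfig = AssayConfig()
) -> FlankingScreen:
    if trace.assay != "flanking":
        raise ValueError("screen_flanking expects a flanking trace")
    lo, hi = cfg.normal_window_bp
    in_window = any(lo <= s <= hi for s in trace.sizes)
    if in_window:
        return FlankingScreen(excluded=True, suspected_biallelic=False)
    if not trace.peaks:
        return FlankingScreen(excluded=False, suspected_biallelic=True)
    return FlankingScreen(excluded=False, suspected_biallelic=True, warning=True)


# ---------------------------------------------------------------------------
# Repeat-primed PCR
# ---------------------------------------------------------------------------

def _allele_peak_bp(
    allele: AlleleStructure, assay: Motif, cfg: AssayConfig
) -> list[int]:
    """bp offsets (from the anchor) of ladder peaks for one allele.

    The repeat primer anneals from the 5' flank; unit *i* yields a peak at
    the cumulative bp length of units 1..i when that unit's motif matches
    (up to rotation) the assay motif. Only the first
    ``rp_detection_limit_units`` units ladder.
    """
    out: list[int] = []
    pos = 0
    for k, unit_motif in enumerate(allele.unit_sequence()):
        if k >= cfg.rp_detection_limit_units:
            break
        pos += len(unit_motif)
        if unit_motif == assay:
            out.append(pos)
    return out


def rp_pcr_trace(
    genotype: DiploidGenotype,
    assay_motif: Motif,
    cfg: AssayConfig = AssayConfig(),
) -> AssayTrace:
    """RP-PCR ladder for one assay motif; the two alleles superimpose."""
    merged: dict[int, float] = {}
    for allele in genotype.alleles:
        for bp in _allele_peak_bp(allele, assay_motif, cfg):
            units = bp / len(assay_motif)
            height = math.exp(-units / cfg.ladder_decay_units)
            size = cfg.rp_anchor_bp + bp
            merged[size] = merged.get(size, 0.0) + height
    peaks = tuple(sorted((float(s), h) for s, h in merged.items()))
    return AssayTrace(
        f"rp:{assay_motif.canonical}", peaks, sample_id=genotype.sample_id
    )


def rp_panel(
    genotype: DiploidGenotype,
    cfg: AssayConfig = AssayConfig(),
    extended: bool = False,
) -> list[AssayTrace]:
    """One RP-PCR trace per panel assay (standard 4-plex or extended 6-plex)."""
    return [rp_pcr_trace(genotype, m, cfg) for m in cfg.panel(extended)]


@dataclass(frozen=True)
class TraceCall:
    """Panel-level interpretation of a sample's RP-PCR traces."""

    motifs_present: frozenset[Motif]
    interruption_motifs: frozenset[Motif]
    gap_flag: bool
    no_product: bool

    def __post_init__(self) -> None:
        if self.motifs_present & self.interruption_motifs:
            raise ValueError("presence and interruption sets must be disjoint")


def _peak_runs(sizes: Sequence[float], period: int) -> list[int]:
    """Lengths of maximal runs of consecutive unit-spaced peaks."""
    runs: list[int] = []
    current = 0
    prev: float | None = None
    for s in sizes:
        if prev is not None and abs((s - prev) - period) < 0.5:
            current += 1
        else:
            if current:
                runs.append(current)
            current = 1
        prev = s
    if current:
        runs.append(current)
    return runs


def interpret_traces(
    traces: Sequence[AssayTrace], cfg: AssayConfig = AssayConfig()
) -> TraceCall:
    """Apply the presence / interruption / gap rules to a sample's panel.

    Presence: a run of >= ``presence_min_peaks`` consecutive peaks spaced by
    one repeat unit. Interruption: only runs of 1-9 peaks. Gap: an internal
    stretch of at least ``gap_threshold_units`` repeat-unit positions
    (pentamer-equivalent bp) covered by no assay in the panel, with panel
    peaks on both sides.
    """
    rp = [t for t in traces if t.is_rp]
    if not rp:
        raise ValueError("no RP-PCR traces supplied")
    ids = {t.sample_id for t in traces if t.sample_id}
    if len(ids) > 1:
        raise ValueError(f"traces from different samples: {sorted(ids)}")

    present: set[Motif] = set()
    interrupted: set[Motif] = set()
    covered: list[tuple[float, float]] = []
    for trace in rp:
        period = len(trace.motif)
        runs = _peak_runs(trace.sizes, period)
        if any(r >= cfg.presence_min_peaks for r in runs):
            present.add(trace.motif)
        elif any(1 <= r <= cfg.max_interruption_peaks for r in runs):
            interrupted.add(trace.motif)
        for s in trace.sizes:
            covered.append((s - cfg.rp_anchor_bp - period, s - cfg.rp_anchor_bp))

    gap_flag = False
    if covered:
        covered.sort()
        merged: list[list[float]] = [list(covered[0])]
        for lo, hi in covered[1:]:
            if lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        threshold_bp = cfg.gap_threshold_units * 5
        for (_, hi), (lo, _) in zip(merged, merged[1:]):
            if lo - hi >= threshold_bp:
                gap_flag = True
                break

    interrupted -= present
    return TraceCall(
        motifs_present=frozenset(present),
        interruption_motifs=frozenset(interrupted),
        gap_flag=gap_flag,
        no_product=not covered,
    )


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def traces_to_frame(traces: Iterable[AssayTrace]) -> pd.DataFrame:
    materialized = list(traces)
    rows = [
        {"sample_id": t.sample_id, "assay": t.assay, "size_bp": s, "height": h}
        for t in materialized
        for s, h in t.peaks
    ]
    # emit a NaN row for empty traces so the round-trip keeps them
    rows += [
        {"sample_id": t.sample_id, "assay": t.assay, "size_bp": float("nan"),
         "height": float("nan")}
        for t in materialized
        if not t.peaks
    ]
    return pd.DataFrame(rows, columns=["sample_id", "assay", "size_bp", "height"])


def traces_from_frame(frame: pd.DataFrame) -> list[AssayTrace]:
    out: list[AssayTrace] = []
    for (sample_id, assay), grp in frame.groupby(["sample_id", "assay"], sort=False):
        grp = grp.dropna(subset=["size_bp"])
        peaks = tuple(
            sorted((float(s), float(h)) for s, h in zip(grp.size_bp, grp.height))
        )
        out.append(AssayTrace(assay=assay, peaks=peaks, sample_id=str(sample_id)))
    return out
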