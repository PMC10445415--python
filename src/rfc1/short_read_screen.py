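"""First-pass screening of the locus from targeted short-read panels.

A capture panel with probes over the repeat region lets every sample be
screened for biallelic expansions without extra wet-lab work: reads that
span the whole repeat plus both flanks imply a non-expanded allele, while
biallelic expansions leave no spanning reads and a drop in aligned coverage
across the repeat region.

The module emulates what an aligner + IGV session shows without performing
genome alignment: reads are placed on the locus reference (flank + reference
tract + flank) by a unique 20-mer seed, extended base-by-base, and clipped
where local identity collapses — so reads composed of non-reference repeat
contribute no coverage inside the repeat region, reproducing the coverage
drop. Because the visual IGV criterion is qualitative, the quantitative
surrogates used here (minimum spanning-read count, flank/repeat depth-drop
ratio) are reported in the result metadata.

A second pass enumerates the repeat motifs visible in flank-anchored reads,
the strategy used to inventory non-reference motifs at this locus in
population-scale short-read data. It is intrinsically limited to motifs
close to the flanks: a motif deeper into the expansion than a read length
can never be observed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .repeat_model import LocusDefinition, canonical_rotation
from .synthetic_data import SimulatedRead

__all__ = ["ScreenParams", "ScreenResult", "screen_sample", "detect_locus_motifs"]


class NoReadsError(ValueError):
    pass


@dataclass(frozen=True)
class ScreenParams:
    """Quantitative surrogates for the visual screen."""

    min_spanning: int = 3
    drop_ratio: float = 2.0
    flank_window_bp: int = 200
    seed_bp: int = 20
    #: implied tract lengths (bp) treated as a reference-range allele;
    #: matches the flanking-PCR normal window of ~8-14 pentamer units
    ref_tract_window_bp: tuple[int, int] = (40, 70)
    #: clip extension when >2 mismatches accumulate in a 15-base window
    #: (an AAAGG allele mismatches the AAAAG reference 3 times per 15 bp)
    clip_window: int = 15
    clip_max_mismatches: int = 2
    #: a mismatch-clip boundary within this distance of a flank/repeat
    #: junction counts as junction soft-clip evidence of an expansion
    junction_tolerance_bp: int = 5
    min_repeat_bp: int = 25
    purity: float = 0.8


@dataclass
class ScreenResult:
    sample_id: str
    spanning_ref_reads: int
    coverage_profile: np.ndarray  # depth per reference position
    call: str  # reference_present | biallelic_expansion_suspected | indeterminate
    motif_evidence: dict[str, int]
    depth_drop_ratio: float
    metadata: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            "call": self.call,
            "spanning_ref_reads": self.spanning_ref_reads,
            "depth_drop_ratio": round(self.depth_drop_ratio, 2),
            "motifs": ";".join(
                f"{m}:{c}" for m, c in sorted(self.motif_evidence.items())
            ),
        }
        row.update(self.metadata)
        return row


def _unique_seed_position(seq: str, reference: str, seed_bp: int) -> tuple[int, int] | None:
    """(read_offset, reference_position) of a uniquely-placing seed, trying
    the read start then the read end. Ambiguous (repeat-derived) seeds do
    not place, like MAPQ-0 alignments."""
    for off in (0, len(seq) - seed_bp):
        seed = seq[off:off + seed_bp]
        pos = reference.find(seed)
        if pos >= 0 and reference.find(seed, pos + 1) < 0:
            return off, pos
    return None


def _clipped_extent(
    read: np.ndarray, ref: np.ndarray, read_off: int, ref_pos: int,
    params: ScreenParams,
) -> tuple[int, int, bool, bool]:
    """Reference interval [lo, hi) the read covers after clipping where
    local identity collapses, extending outward from the seed; the two
    flags report whether each side was clipped by mismatches (True) rather
    than ending with the read."""
    start = ref_pos - read_off  # reference coordinate of read base 0
    lo_r = max(0, -start)
    hi_r = min(read.size, ref.size - start)
    mism = read[lo_r:hi_r] != ref[start + lo_r:start + hi_r]
    w, mmax = params.clip_window, params.clip_max_mismatches
    seed_i = read_off - lo_r  # index into mism at seed start

    def _extend(indices: Iterable[int]) -> tuple[int, bool]:
        bad: list[int] = []
        last_good = seed_i
        clipped = False
        for i in indices:
            if mism[i]:
                bad.append(i)
                recent = [b for b in bad if abs(i - b) < w]
                if len(recent) > mmax:
                    clipped = True
                    break
            last_good = i
        return last_good, clipped

    right, clip_r = _extend(range(seed_i, mism.size))
    left, clip_l = _extend(range(seed_i, -1, -1))
    return start + lo_r + left, start + lo_r + right + 1, clip_l, clip_r


def screen_sample(
    reads: Sequence[SimulatedRead],
    locus: LocusDefinition,
    params: ScreenParams = ScreenParams(),
) -> ScreenResult:
    """Screen one sample's short reads for presence of a non-expanded allele.

    ``reference_present``: at least ``min_spanning`` reads span the repeat
    with a reference-range implied tract. ``biallelic_expansion_suspected``:
    no such read and the flank/repeat depth ratio reaches ``drop_ratio``.
    Anything else is ``indeterminate`` (triggers follow-up testing).
    """
    if not reads:
        raise NoReadsError("no reads overlapping the locus")
    reference = locus.left_flank + locus.reference_tract + locus.right_flank
    ref_arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    flank = len(locus.left_flank)
    ref_span = len(locus.reference_tract)
    depth = np.zeros(len(reference), dtype=np.int32)

    left_anchor = locus.left_flank[-params.seed_bp:]
    right_anchor = locus.right_flank[:params.seed_bp]
    spanning_ref = 0
    spanning_other = 0
    junction_clips = 0
    for read in reads:
        seq = read.sequence
        a = seq.find(left_anchor)
        if a >= 0:
            b = seq.find(right_anchor, a + params.seed_bp)
            if b >= 0:
                implied = b - (a + params.seed_bp)
                lo, hi = params.ref_tract_window_bp
                if lo <= implied <= hi:
                    spanning_ref += 1
                else:
                    spanning_other += 1
        placed = _unique_seed_position(seq, reference, params.seed_bp)
        if placed is None:
            continue
        read_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        lo, hi, clip_l, clip_r = _clipped_extent(
            read_arr, ref_arr, placed[0], placed[1], params
        )
        depth[lo:hi] += 1
        # reads clipped by mismatch right at a flank/repeat junction are the
        # soft-clip pileup an aligner shows for an expanded allele
        for clipped, boundary in ((clip_l, lo), (clip_r, hi)):
            if clipped and (
                abs(boundary - flank) <= params.junction_tolerance_bp
                or abs(boundary - (flank + ref_span))
                <= params.junction_tolerance_bp
            ):
                junction_clips += 1
                break

    wf = params.flank_window_bp
    flank_depth = float(
        np.concatenate(
            [depth[max(0, flank - wf):flank], depth[flank + ref_span:flank + ref_span + wf]]
        ).mean()
    )
    repeat_depth = float(depth[flank:flank + ref_span].mean())
    ratio = flank_depth / repeat_depth if repeat_depth > 0 else float("inf")

    if spanning_ref >= params.min_spanning:
        call = "reference_present"
    elif (
        spanning_ref == 0
        and spanning_other == 0
        and (ratio >= params.drop_ratio or junction_clips >= params.min_spanning)
    ):
        call = "biallelic_expansion_suspected"
    else:
        call = "indeterminate"

    return ScreenResult(
        sample_id=reads[0].read_id.rsplit("_", 2)[0],
        spanning_ref_reads=spanning_ref,
        coverage_profile=depth,
        call=call,
        motif_evidence=detect_locus_motifs(reads, locus, params),
        depth_drop_ratio=ratio,
        metadata={
            "min_spanning": params.min_spanning,
            "drop_ratio_threshold": params.drop_ratio,
            "spanning_nonref_reads": spanning_other,
            "junction_clipped_reads": junction_clips,
        },
    )


def _tandem_runs(segment: str, min_run_bp: int) -> list[tuple[str, int]]:
    """(canonical motif, run bp) for maximal period-5/6 tandem runs.

    Period 5 is scanned first and claimed bases are masked before the
    period-6 scan, so a pentamer run is never double-reported as a hexamer.
    """
    n = len(segment)
    arr = np.frombuffer(segment.encode(), dtype=np.uint8)
    claimed = np.zeros(n, dtype=bool)
    out: list[tuple[str, int]] = []
    for p in (5, 6):
        if n <= p:
            continue
        eq = arr[:-p] == arr[p:]
        j = 0
        while j < eq.size:
            if not eq[j]:
                j += 1
                continue
            k = j
            while k < eq.size and eq[k]:
                k += 1
            span = (k - j) + p
            if span >= min_run_bp and not claimed[j:j + span].any():
                canon = canonical_rotation(segment[j:j + p])
                if len(set(canon)) > 1:
                    out.append((canon, span))
                    claimed[j:j + span] = True
            j = k + 1
    return out


def detect_locus_motifs(
    reads: Sequence[SimulatedRead],
    locus: LocusDefinition,
    params: ScreenParams = ScreenParams(),
) -> dict[str, int]:
    """Count reads supporting each repeat motif adjacent to a flank.

    A read contributes when it is anchored in a flank (exact 20-mer at the
    flank/repeat junction) and extends at least ``min_repeat_bp`` into the
    tract; the repeat-adjacent bases are decomposed into period-5/6 tandem
    runs and each motif with a run of >= ``min_repeat_bp`` bp is credited
    once per read, provided the runs explain >= ``purity`` of the segment.
    """
    left_anchor = locus.left_flank[-params.seed_bp:]
    right_anchor = locus.right_flank[:params.seed_bp]
    counts: Counter[str] = Counter()
    for read in reads:
        seq = read.sequence
        segments: list[str] = []
        a = seq.find(left_anchor)
        b = seq.find(right_anchor, a + params.seed_bp if a >= 0 else 0)
        if a >= 0:
            segments.append(seq[a + params.seed_bp: b if b >= 0 else len(seq)])
        elif b >= 0:
            segments.append(seq[:b])
        motifs_here: set[str] = set()
        for segment in segments:
            if len(segment) < params.min_repeat_bp:
                continue
            runs = _tandem_runs(segment, params.min_repeat_bp)
            explained = sum(bp for _, bp in runs)
            if explained < params.purity * len(segment):
                continue
            motifs_here.update(canon for canon, _ in runs)
        for canon in motifs_here:
            counts[canon] += 1
    return dict(counts)
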