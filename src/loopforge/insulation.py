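"""Insulation scores, boundary detection, TAD calling and cross-condition matching.

The insulation score of bin i aggregates balanced contact frequencies crossing
that bin: the sum over the w/2 x w/2 rectangle of pixels joining the w/2 bins
upstream with the w/2 bins downstream (default window 1 Mb).  Local minima of
the profile mark domain boundaries; consecutive boundaries delimit TADs.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field
from scipy.signal import find_peaks

from .contact import ContactMap, BalancingWeights, balanced_dense
from .intervals import GenomicInterval

__all__ = [
    "InsulationTrack",
    "TadSet",
    "insulation_score",
    "detect_boundaries",
    "call_tads",
    "match_tads",
]

MIN_TAD_BINS = 3


@dataclass
class InsulationTrack:
    chrom: str
    resolution: int
    window: int
    scores: np.ndarray  # NaN within window/2 of the ends and at masked bins


@dataclass
class TadSet:
    tads: list[GenomicInterval] = field(default_factory=list)
    boundary_bins: list[int] = field(default_factory=list)
    boundary_insulation: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.tads)


def insulation_score(cmap: ContactMap, weights: BalancingWeights,
                     window: int = 1_000_000, use_raw: bool = False) -> InsulationTrack:
    """Sliding-window insulation profile.

    I_i sums balanced values over the square spanning bins
    (i-w/2 .. i-1) x (i .. i+w/2-1) where w = window / resolution.  NaN where
    the square leaves the matrix or bin i is masked; masked pixels inside the
    square contribute 0.  ``use_raw`` sums raw counts instead (the alternative
    reading of "normalized contact frequencies").
    """
    if window % cmap.resolution != 0:
        raise ValueError("window must be a multiple of the resolution")
    w = window // cmap.resolution
    if w < 2:
        raise ValueError("window must span >= 2 bins")
    n = cmap.n_bins
    half = w // 2
    if w > n:
        raise ValueError(f"window of {w} bins exceeds chromosome ({n} bins)")
    if use_raw:
        B = cmap.dense_symmetric().astype(float)
    else:
        B = balanced_dense(cmap, weights)
    B = np.nan_to_num(B, nan=0.0)
    # summed-area table for O(1) rectangle sums
    S = np.zeros((n + 1, n + 1))
    S[1:, 1:] = B.cumsum(axis=0).cumsum(axis=1)
    scores = np.full(n, np.nan)
    for i in range(half, n - half + 1):
        if i >= n:
            break
        r0, r1 = i - half, i          # rows i-half .. i-1
        c0, c1 = i, i + half          # cols i .. i+half-1
        if c1 > n:
            continue
        scores[i] = S[r1, c1] - S[r0, c1] - S[r1, c0] + S[r0, c0]
    scores[weights.mask] = np.nan
    # guard tiny negative round-off; balanced values are non-negative
    scores[scores < 0] = 0.0
    return InsulationTrack(cmap.chrom, cmap.resolution, window, scores)


def detect_boundaries(track: InsulationTrack,
                      prominence_fraction: float = 0.1) -> list[int]:
    """Local minima of the insulation profile with prominence above threshold.

    Threshold = prominence_fraction x median of the finite scores.  Bins at
    chromosome ends (or adjacent to NaN stretches at the ends) never qualify.
    """
    s = np.asarray(track.scores, dtype=float)
    finite = np.isfinite(s)
    if not finite.any():
        raise ValueError("all-NaN insulation track")
    med = float(np.median(s[finite]))
    prom = prominence_fraction * med if med > 0 else 0.0
    boundaries: list[int] = []
    # handle NaN gaps by searching each finite run independently
    idx = np.flatnonzero(finite)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    for run in runs:
        if len(run) < 3:
            continue
        seg = s[run]
        peaks, _ = find_peaks(-seg, prominence=max(prom, 0.0) or None)
        boundaries.extend(int(run[p]) for p in peaks)
    return sorted(b for b in boundaries if 0 < b < len(s) - 1)


def call_tads(boundaries: list[int], chrom_extent: tuple[str, int, int],
              resolution: int,
              insulation: np.ndarray | None = None) -> TadSet:
    """Consecutive boundary bins become TADs; spans < MIN_TAD_BINS bins are dropped."""
    chrom, _start, _end = chrom_extent
    bset = sorted(boundaries)
    tads, bb, bi = [], [], []
    for a, b in zip(bset[:-1], bset[1:]):
        if b - a < MIN_TAD_BINS:
            continue
        tads.append(GenomicInterval(chrom, a * resolution, b * resolution))
        bb.append(a)
        bi.append(float(insulation[a]) if insulation is not None else float("nan"))
    return TadSet(tads, bset, [float(insulation[b]) if insulation is not None
                               else float("nan") for b in bset])


def _boundary_regions(tads: list[GenomicInterval], chrom_span: tuple[int, int]):
    """Gaps between consecutive TADs plus the flanks, as intervals (may be
    zero-length when TADs touch; represented as (pos, pos))."""
    lo, hi = chrom_span
    regions = []
    prev = lo
    for t in sorted(tads, key=lambda t: t.start):
        regions.append((prev, t.start))
        prev = t.end
    regions.append((prev, hi))
    return regions


def _regions_overlap(r1: tuple[int, int], r2: tuple[int, int]) -> bool:
    """Overlap for possibly zero-length boundary regions (touching counts)."""
    a0, a1 = r1
    b0, b1 = r2
    return max(a0, b0) <= min(a1, b1)


def match_tads(tads_control: TadSet, tads_ko: TadSet,
               chrom_span: tuple[int, int] | None = None):
    """Partition TADs into (common, control_specific, ko_specific).

    A Control TAD is common iff it overlaps exactly one KO TAD, that KO TAD
    overlaps exactly one Control TAD, and the flanking boundary regions (the
    gap or touch point between a TAD and its neighbours) overlap between
    conditions.  Everything else is condition-specific.
    """
    ctrl = sorted(tads_control.tads, key=lambda t: t.start)
    ko = sorted(tads_ko.tads, key=lambda t: t.start)
    if chrom_span is None:
        ends = [t.end for t in ctrl + ko] or [0]
        starts = [t.start for t in ctrl + ko] or [0]
        chrom_span = (min(starts), max(ends))
    ctrl_regions = _boundary_regions(ctrl, chrom_span)
    ko_regions = _boundary_regions(ko, chrom_span)

    def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
        return a.start < b.end and b.start < a.end

    ctrl_hits = [[j for j, t in enumerate(ko) if overlaps(c, t)] for c in ctrl]
    ko_hits = [[i for i, c in enumerate(ctrl) if overlaps(c, t)] for t in ko]

    common_ctrl, common_ko = set(), set()
    for i, hits in enumerate(ctrl_hits):
        if len(hits) != 1:
            continue
        j = hits[0]
        if len(ko_hits[j]) != 1 or ko_hits[j][0] != i:
            continue
        # flanking boundary regions: region k and k+1 around TAD k
        if (_regions_overlap(ctrl_regions[i], ko_regions[j])
                and _regions_overlap(ctrl_regions[i + 1], ko_regions[j + 1])):
            common_ctrl.add(i)
            common_ko.add(j)
    common = [ctrl[i] for i in sorted(common_ctrl)]
    control_specific = [c for i, c in enumerate(ctrl) if i not in common_ctrl]
    ko_specific = [t for j, t in enumerate(ko) if j not in common_ko]
    return common, control_specific, ko_specific
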