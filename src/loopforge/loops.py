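"""Focal-enrichment chromatin loop calling and loop-set algebra.

A pixel (i, j) of the balanced contact map is a loop candidate when its value
exceeds, by at least 50%, the local expectation derived from each of four
neighborhoods — lower-left, horizontal (left/right), vertical (above/below)
and a donut — and each enrichment is significant under a Poisson upper-tail
test with BH correction per neighborhood (FDR < 10% by default).  Enriched
pixels cluster into contiguous interaction regions (8-connectivity); each
cluster is reported as one loop at its highest-O/E "peak pixel", whose two
bins are the loop anchors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .contact import (ContactMap, BalancingWeights, ExpectedProfile,
                      balanced_dense)
from .intervals import GenomicInterval

log = logging.getLogger(__name__)

NEIGHBORHOODS = ("lowerleft", "horizontal", "vertical", "donut")

__all__ = [
    "LoopCall",
    "LoopSet",
    "LoopCallParams",
    "neighborhood_offsets",
    "neighborhood_expectations",
    "test_pixel",
    "call_loops",
    "merge_overlapping_loops",
    "nonredundant_union",
    "quantify_loops",
    "loop_fold_changes",
]


@dataclass
class LoopCall:
    chrom: str
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    resolution: int
    peak_pixel: tuple[int, int]
    intensity_by_condition: dict = field(default_factory=dict)
    fdr_q: float = float("nan")
    cluster_size: int = 1

    def __post_init__(self):
        i, j = self.peak_pixel
        if not i < j:
            raise ValueError(f"peak pixel must satisfy i < j, got {self.peak_pixel}")
        if self.anchor1.start > self.anchor2.start:
            raise ValueError("anchor1 must be upstream of anchor2")

    @property
    def intensity(self) -> float:
        """Intensity in the condition the loop was called in (max when several)."""
        vals = [v for v in self.intensity_by_condition.values() if np.isfinite(v)]
        return max(vals) if vals else float("nan")


@dataclass
class LoopSet:
    loops: list[LoopCall] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)


@dataclass
class LoopCallParams:
    fdr: float = 0.10
    ratio: float = 1.5            # "at least 50% more contacts than expected"
    peak_radius: int = 1          # p, inner exclusion radius in bins
    donut_radius: int = 3         # w, outer radius in bins (at 25 kb)
    singleton_fdr: float = 0.01
    max_distance: int = 10_000_000  # bp, tested-pixel upper bound
    min_distance_bins: int = 2


# ---------------------------------------------------------------------------
# neighborhood geometry


def neighborhood_offsets(p: int = 1, w: int = 3) -> dict[str, list[tuple[int, int]]]:
    """Pixel offset sets for the four neighborhoods.

    donut: the (2w+1)^2 square minus the (2p+1)^2 core;
    lowerleft: the w x w block down-left of the pixel minus its p x p corner;
    horizontal: rows within +/-p, columns p < |dj| <= w;
    vertical: transpose of horizontal.
    """
    donut, lowerleft, horizontal, vertical = [], [], [], []
    for di in range(-w, w + 1):
        for dj in range(-w, w + 1):
            if di == 0 and dj == 0:
                continue
            in_core = abs(di) <= p and abs(dj) <= p
            if not in_core:
                donut.append((di, dj))
            if 1 <= di <= w and -w <= dj <= -1 and not (di <= p and -dj <= p):
                lowerleft.append((di, dj))
            if abs(di) <= p and p < abs(dj) <= w:
                horizontal.append((di, dj))
            if abs(dj) <= p and p < abs(di) <= w:
                vertical.append((di, dj))
    return {"lowerleft": lowerleft, "horizontal": horizontal,
            "vertical": vertical, "donut": donut}


def _kernels(p: int, w: int) -> dict[str, np.ndarray]:
    out = {}
    for name, offs in neighborhood_offsets(p, w).items():
        k = np.zeros((2 * w + 1, 2 * w + 1))
        for di, dj in offs:
            k[w + di, w + dj] = 1.0
        out[name] = k
    return out


class _Field:
    """Precomputed per-map arrays shared by the per-pixel and vectorized paths."""

    def __init__(self, cmap: ContactMap, weights: BalancingWeights,
                 expected: ExpectedProfile, p: int, w: int):
        self.cmap = cmap
        self.weights = weights
        self.expected = expected
        self.p, self.w = p, w
        n = cmap.n_bins
        B = balanced_dense(cmap, weights)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        E = expected.values[d]
        valid = np.isfinite(B) & np.isfinite(E) & (E > 0)
        self.valid = valid
        self.B0 = np.where(valid, B, 0.0)
        self.E0 = np.where(valid, E, 0.0)
        self.E = E
        self.B = B
        kernels = _kernels(p, w)
        self.num = {k: ndimage.correlate(self.B0, kern, mode="constant", cval=0.0)
                    for k, kern in kernels.items()}
        self.den = {k: ndimage.correlate(self.E0, kern, mode="constant", cval=0.0)
                    for k, kern in kernels.items()}

    def lam(self, name: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.E * self.num[name] / self.den[name]


def neighborhood_expectations(cmap: ContactMap, weights: BalancingWeights,
                              expected: ExpectedProfile, i: int, j: int,
                              p: int = 1, w: int = 3) -> dict[str, float]:
    """Local expected balanced value lambda for each of the four neighborhoods.

    lambda = E(|i-j|) * (sum of balanced values over the neighborhood /
    sum of distance-expected values over the same pixels); masked or
    off-matrix pixels are excluded from both sums.
    """
    if j - i < 2 * w + 1:
        raise ValueError(f"pixel ({i},{j}) too close to the diagonal for w={w}")
    if weights.mask[i] or weights.mask[j]:
        raise ValueError(f"pixel ({i},{j}) is masked")
    n = cmap.n_bins
    B = balanced_dense(cmap, weights)
    dmat = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    E = expected.values[dmat]
    out = {}
    for name, offs in neighborhood_offsets(p, w).items():
        num = den = 0.0
        used = 0
        for di, dj in offs:
            a, b = i + di, j + dj
            if not (0 <= a < n and 0 <= b < n):
                continue
            if not np.isfinite(B[a, b]) or not np.isfinite(E[a, b]) or E[a, b] <= 0:
                continue
            num += B[a, b]
            den += E[a, b]
            used += 1
        if used == 0 or den == 0:
            raise ValueError(f"neighborhood {name} fully masked at ({i},{j})")
        out[name] = float(expected.values[j - i]) * num / den
    return out


def test_pixel(cmap: ContactMap, weights: BalancingWeights,
               expected: ExpectedProfile, i: int, j: int,
               params: LoopCallParams | None = None) -> dict:
    """Enrichment ratios and Poisson p-values of one pixel vs its neighborhoods.

    The Poisson test runs on the raw-count scale: the balanced local
    expectation lambda is de-scaled by 1/(w_i w_j) and compared with the raw
    observed count via an upper-tail test.  A pixel is enriched when the
    ratio is >= params.ratio for ALL four neighborhoods and all four
    (BH-adjusted, at the call level) p-values pass; this function reports the
    raw per-neighborhood p-values.
    """
    params = params or LoopCallParams()
    p, w = params.peak_radius, params.donut_radius
    lam = neighborhood_expectations(cmap, weights, expected, i, j, p, w)
    wi, wj = weights.weights[i], weights.weights[j]
    o_raw = float(cmap.counts[min(i, j), max(i, j)])
    b_obs = wi * o_raw * wj
    out = {"observed_raw": o_raw, "observed_balanced": b_obs}
    for name, lam_b in lam.items():
        lam_raw = lam_b / (wi * wj)
        ratio = b_obs / lam_b if lam_b > 0 else np.inf
        pval = float(stats.poisson.sf(o_raw - 1, lam_raw)) if lam_raw > 0 else 1.0
        out[name] = {"lambda": lam_b, "ratio": ratio, "p": pval}
    out["enriched_ratio"] = all(out[k]["ratio"] >= params.ratio for k in NEIGHBORHOODS)
    return out


# ---------------------------------------------------------------------------
# loop calling


def _call_one_resolution(cmap: ContactMap, weights: BalancingWeights,
                         expected: ExpectedProfile,
                         params: LoopCallParams) -> list[LoopCall]:
    n = cmap.n_bins
    res = cmap.resolution
    p = params.peak_radius
    w = params.donut_radius
    f = _Field(cmap, weights, expected, p, w)

    ii, jj = np.triu_indices(n, k=max(params.min_distance_bins, 2 * w + 1))
    dist_ok = (jj - ii) * res <= params.max_distance
    ii, jj = ii[dist_ok], jj[dist_ok]
    ok = f.valid[ii, jj]
    ii, jj = ii[ok], jj[ok]
    if ii.size == 0:
        warnings.warn("no testable pixels", stacklevel=2)
        return []

    W = f.weights.weights
    o_raw = np.asarray(cmap.counts[ii, jj]).ravel()
    b_obs = W[ii] * o_raw * W[jj]

    ratios, qvals = {}, {}
    for name in NEIGHBORHOODS:
        lam_b = f.lam(name)[ii, jj]
        den = f.den[name][ii, jj]
        defined = (den > 0) & np.isfinite(lam_b) & (lam_b > 0)
        lam_raw = np.where(defined, lam_b / (W[ii] * W[jj]), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(defined, b_obs / lam_b, np.nan)
        pv = np.ones(ii.size)
        pv[defined] = stats.poisson.sf(o_raw[defined] - 1, lam_raw[defined])
        q = np.ones(ii.size)
        if defined.any():
            q[defined] = multipletests(pv[defined], method="fdr_bh")[1]
        ratios[name] = ratio
        qvals[name] = q
        n_undef = int((~defined).sum())
        if n_undef:
            log.info("%s: %d pixels with undefined %s neighborhood skipped",
                     cmap.chrom, n_undef, name)

    ratio_ok = np.ones(ii.size, dtype=bool)
    q_ok = np.ones(ii.size, dtype=bool)
    q_min = np.ones(ii.size)
    for name in NEIGHBORHOODS:
        with np.errstate(invalid="ignore"):
            ratio_ok &= ratios[name] >= params.ratio
        q_ok &= qvals[name] < params.fdr
        q_min = np.minimum(q_min, qvals[name])
    # the q of a call is the min adjusted p over neighborhoods; singletons
    # must additionally pass it at the stricter singleton FDR
    q_strict = q_min < params.singleton_fdr
    ratio_ok &= np.all([np.isfinite(ratios[name]) for name in NEIGHBORHOODS], axis=0)
    enriched = ratio_ok & q_ok

    grid = np.zeros((n, n), dtype=bool)
    grid[ii[enriched], jj[enriched]] = True
    labels, n_clusters = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))

    qmin_grid = np.full((n, n), np.nan)
    qmin_grid[ii, jj] = q_min
    strict_grid = np.zeros((n, n), dtype=bool)
    strict_grid[ii[q_strict], jj[q_strict]] = True

    oe = np.where(f.valid, np.divide(f.B, f.E, out=np.full_like(f.B, np.nan),
                                     where=f.E > 0), np.nan)
    loops: list[LoopCall] = []
    for lab in range(1, n_clusters + 1):
        ri, rj = np.nonzero(labels == lab)
        vals = oe[ri, rj]
        best = np.nanmax(vals)
        cand = np.flatnonzero(vals == best)
        # deterministic tie-break: smallest (i, then j)
        order = np.lexsort((rj[cand], ri[cand]))
        k = cand[order[0]]
        pi, pj = int(ri[k]), int(rj[k])
        if len(ri) == 1 and not strict_grid[pi, pj]:
            continue  # singleton clusters need the stricter FDR
        loops.append(LoopCall(
            chrom=cmap.chrom,
            anchor1=GenomicInterval(cmap.chrom, pi * res, (pi + 1) * res),
            anchor2=GenomicInterval(cmap.chrom, pj * res, (pj + 1) * res),
            resolution=res,
            peak_pixel=(pi, pj),
            intensity_by_condition={"called": float(oe[pi, pj])},
            fdr_q=float(qmin_grid[pi, pj]),
            cluster_size=int(len(ri)),
        ))
    loops.sort(key=lambda L: L.peak_pixel)
    return loops


def _scaled_params(params: LoopCallParams, resolution: int) -> LoopCallParams:
    """Donut geometry scales inversely with resolution (x2.5 at 10 kb, x5 at 5 kb)."""
    scale = {25000: 1.0, 10000: 2.5, 5000: 5.0}.get(resolution, 25000 / resolution)
    return replace(params,
                   peak_radius=max(1, round(params.peak_radius * scale)),
                   donut_radius=max(2, round(params.donut_radius * scale)))


def call_loops(maps_by_resolution: dict[int, tuple[ContactMap, BalancingWeights,
                                                   ExpectedProfile]],
               params: LoopCallParams | None = None,
               condition: str = "called") -> LoopSet:
    """Call, cluster, and cross-resolution merge loops.

    ``maps_by_resolution`` maps resolution (bp) to (map, weights, expected).
    Resolutions are merged preferring the finest: a coarser call is kept only
    when its anchors overlap no finer-resolution loop.
    """
    params = params or LoopCallParams()
    per_res: dict[int, list[LoopCall]] = {}
    for res in sorted(maps_by_resolution):
        cmap, wts, exp = maps_by_resolution[res]
        scaled = _scaled_params(params, res)
        calls = _call_one_resolution(cmap, wts, exp, scaled)
        calls = merge_overlapping_loops(calls).loops
        per_res[res] = calls

    merged: list[LoopCall] = []
    for res in sorted(per_res):  # finest first
        for loop in per_res[res]:
            if not any(_both_anchors_overlap(loop, kept) for kept in merged):
                merged.append(loop)
    merged.sort(key=lambda L: (L.anchor1.start, L.anchor2.start))
    for L in merged:
        if condition != "called" and "called" in L.intensity_by_condition:
            L.intensity_by_condition[condition] = L.intensity_by_condition.pop("called")
    return LoopSet(merged, provenance={
        "condition": condition,
        "resolutions": sorted(per_res),
        "params": vars(params).copy(),
    })


# ---------------------------------------------------------------------------
# loop-set algebra


def _both_anchors_overlap(a: LoopCall, b: LoopCall) -> bool:
    return (a.anchor1.overlaps(b.anchor1) and a.anchor2.overlaps(b.anchor2))


def merge_overlapping_loops(loop_list) -> LoopSet:
    """Collapse connected components of the both-anchors-overlap relation.

    Each component is represented by its member with the highest called
    intensity (ties: smallest peak pixel).  Idempotent.
    """
    loops = list(loop_list)
    n = len(loops)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i in range(n):
        for j in range(i + 1, n):
            if _both_anchors_overlap(loops[i], loops[j]):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    out = []
    for members in groups.values():
        best = min(members,
                   key=lambda k: (-_nan_to_neginf(loops[k].intensity),
                                  loops[k].peak_pixel))
        out.append(loops[best])
    out.sort(key=lambda L: (L.chrom, L.anchor1.start, L.anchor2.start))
    return LoopSet(out)


def _nan_to_neginf(x: float) -> float:
    return x if np.isfinite(x) else -np.inf


def nonredundant_union(primary_set: LoopSet, secondary_set: LoopSet) -> LoopSet:
    """All primary loops plus secondary loops overlapping (both anchors) none of them.

    |result| = |primary| + |secondary loops with no primary overlap|.
    """
    out = list(primary_set.loops)
    for loop in secondary_set.loops:
        if not any(_both_anchors_overlap(loop, p) for p in primary_set.loops):
            out.append(loop)
    out.sort(key=lambda L: (L.chrom, L.anchor1.start, L.anchor2.start))
    return LoopSet(out, provenance={
        "primary": primary_set.provenance, "secondary": secondary_set.provenance})


# ---------------------------------------------------------------------------
# quantification


def quantify_loops(loop_set: LoopSet, cmap: ContactMap, weights: BalancingWeights,
                   expected: ExpectedProfile, condition: str) -> LoopSet:
    """Measure O/E intensity of a fixed loop list on one condition's map.

    When the map resolution differs from the calling resolution, the peak
    pixel is re-localized to the max O/E within +/-1 bin (absorbs the
    re-binning shift); at the calling resolution the stored pixel is used
    as is, so both conditions are read at the same pixel.  Masked peak
    pixels yield NaN and a log line.
    """
    n = cmap.n_bins
    B = balanced_dense(cmap, weights)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    E = expected.values[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(np.isfinite(E) & (E > 0), B / E, np.nan)

    for loop in loop_set.loops:
        ci = (loop.anchor1.start + loop.anchor1.end) // 2 // cmap.resolution
        cj = (loop.anchor2.start + loop.anchor2.end) // 2 // cmap.resolution
        r = 0 if cmap.resolution == loop.resolution else 1
        best = np.nan
        for a in range(max(0, ci - r), min(n, ci + r + 1)):
            for b in range(max(0, cj - r), min(n, cj + r + 1)):
                lo, hi = min(a, b), max(a, b)
                if lo == hi:
                    continue
                v = oe[lo, hi]
                if np.isfinite(v) and (not np.isfinite(best) or v > best):
                    best = v
        if not np.isfinite(best):
            log.info("loop %s:%d-%d at masked pixel -> NaN intensity",
                     loop.chrom, loop.anchor1.start, loop.anchor2.start)
        loop.intensity_by_condition[condition] = float(best)
    return loop_set


def loop_fold_changes(loop_set: LoopSet, cond_num: str = "KO",
                      cond_den: str = "Control") -> np.ndarray:
    """Per-loop intensity fold change cond_num / cond_den.

    Pseudocount = 0.5 x the minimum positive O/E across the loop list (both
    conditions), added to numerator and denominator.
    """
    num = np.array([L.intensity_by_condition.get(cond_num, np.nan)
                    for L in loop_set.loops])
    den = np.array([L.intensity_by_condition.get(cond_den, np.nan)
                    for L in loop_set.loops])
    pool = np.concatenate([num, den])
    pos = pool[np.isfinite(pool) & (pool > 0)]
    pc = 0.5 * pos.min() if pos.size else 0.5
    with np.errstate(invalid="ignore", divide="ignore"):
        return (num + pc) / (den + pc)
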