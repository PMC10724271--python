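"""Differential peak dynamics: normalized signal, Up/Neutral/Down classes, stats.

CTCF peaks merged across conditions are classified by the KO/Control signal
fold change at the 1.5 threshold: Up (FC > 1.5), Down (FC < 1/1.5), Neutral
otherwise (the boundary values themselves are Neutral).  Promoter enrichment,
group expression tests and SE/TE ATAC normalization follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, Peak

KLASSES = ("Up", "Neutral", "Down")
FC_THRESHOLD = 1.5

__all__ = [
    "PeakDynamics",
    "EnhancerRecord",
    "CoverageTrack",
    "peak_signal",
    "rpgc_normalize",
    "classify_fold_change",
    "classify_peak_dynamics",
    "class_counts",
    "promoter_enrichment",
    "group_log2fc_test",
    "enhancer_normalized_signal",
]


@dataclass
class PeakDynamics:
    peak: Peak
    signal_ctrl: float
    signal_ko: float
    fold_change: float
    klass: str

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValueError("fold change must be > 0")
        if self.klass not in KLASSES:
            raise ValueError(f"unknown class {self.klass!r}")


@dataclass
class EnhancerRecord:
    interval: GenomicInterval
    enhancer_class: str  # SE | TE
    mean_signal: float
    normalized_signal: float

    def __post_init__(self):
        if self.normalized_signal < 0:
            raise ValueError("normalized signal must be >= 0")


@dataclass
class CoverageTrack:
    """Per-bin coverage over one chromosome (uniform bin size)."""

    chrom: str
    bin_size: int
    values: np.ndarray

    @property
    def length(self) -> int:
        return len(self.values) * self.bin_size


def rpgc_normalize(track: CoverageTrack) -> CoverageTrack:
    """Scale so the genome-wide mean coverage is 1 (RPGC-style)."""
    mean = float(np.mean(track.values))
    if mean <= 0:
        raise ValueError("cannot RPGC-normalize an all-zero track")
    return CoverageTrack(track.chrom, track.bin_size,
                         np.asarray(track.values, dtype=float) / mean)


def peak_signal(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Length-weighted mean of per-bin values over the interval."""
    if interval.chrom != track.chrom:
        raise ValueError(f"interval on {interval.chrom}, track on {track.chrom}")
    if interval.start < 0 or interval.end > track.length:
        raise ValueError(f"interval {interval.start}-{interval.end} outside "
                         f"track [0, {track.length})")
    bs = track.bin_size
    total = 0.0
    for b in range(interval.start // bs, (interval.end - 1) // bs + 1):
        lo = max(interval.start, b * bs)
        hi = min(interval.end, (b + 1) * bs)
        total += track.values[b] * (hi - lo)
    return total / len(interval)


def classify_fold_change(fc: float, threshold: float = FC_THRESHOLD) -> str:
    """Up iff FC > threshold; Down iff FC < 1/threshold; boundaries are Neutral."""
    if fc > threshold:
        return "Up"
    if fc < 1.0 / threshold:
        return "Down"
    return "Neutral"


def classify_peak_dynamics(merged_peaks, pseudocount: float | None = None,
                           conditions: tuple[str, str] = ("Control", "KO"),
                           threshold: float = FC_THRESHOLD) -> list[PeakDynamics]:
    """Classify merged two-condition peaks into Up/Neutral/Down.

    Default pseudocount: the 1st percentile of positive signals pooled over
    both conditions (guards zero-signal peaks; the classes are otherwise
    determined solely by FC vs the 1.5 thresholds).
    """
    ctrl_name, ko_name = conditions
    sc = np.array([p.signal_by_condition.get(ctrl_name, 0.0) for p in merged_peaks])
    sk = np.array([p.signal_by_condition.get(ko_name, 0.0) for p in merged_peaks])
    if np.any(sc < 0) or np.any(sk < 0):
        raise ValueError("negative signal")
    if pseudocount is None:
        pos = np.concatenate([sc[sc > 0], sk[sk > 0]])
        pseudocount = float(np.percentile(pos, 1)) if pos.size else 1.0
    out = []
    for p, a, b in zip(merged_peaks, sc, sk):
        fc = (b + pseudocount) / (a + pseudocount)
        out.append(PeakDynamics(p, float(a), float(b), float(fc),
                                classify_fold_change(fc, threshold)))
    return out


def class_counts(dynamics) -> dict[str, int]:
    out = {k: 0 for k in KLASSES}
    for d in dynamics:
        out[d.klass] += 1
    out["total"] = sum(out[k] for k in KLASSES)
    return out


def promoter_enrichment(dynamics, comparator: str = "up_vs_down"):
    """Promoter-fraction enrichment of Up peaks, log2Ratio + chi-square p.

    log2Ratio = log2[(promoter fraction among Up) / (promoter fraction among
    the comparator: Down peaks by default, or all peaks with
    comparator='up_vs_background')].  Zero cells get a Haldane 0.5 continuity
    correction in the ratio (flagged); the chi-square runs on the raw 2x2.
    """
    ups = [d for d in dynamics if d.klass == "Up"]
    if comparator == "up_vs_down":
        others = [d for d in dynamics if d.klass == "Down"]
    elif comparator == "up_vs_background":
        others = list(dynamics)
    else:
        raise ValueError(f"unknown comparator {comparator!r}")
    if not ups or not others:
        raise ValueError("empty comparison group")

    def split(group):
        prom = sum(1 for d in group if d.peak.annotation == "promoter-TSS")
        return prom, len(group) - prom

    a, b = split(ups)      # promoter / non-promoter among Up
    c, d = split(others)
    flagged = 0 in (a, b, c, d)
    aa, bb, cc, dd = ((x + 0.5) for x in (a, b, c, d)) if flagged else (a, b, c, d)
    log2ratio = float(np.log2((aa / (aa + bb)) / (cc / (cc + dd))))
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        chi2, p = float("nan"), float("nan")
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"log2ratio": log2ratio, "chi2": float(chi2), "p": float(p),
            "table": [[a, b], [c, d]], "continuity_corrected": flagged}


def group_log2fc_test(log2fc_values) -> dict:
    """Two-sided one-sample t-test of a group's expression log2FC against 0."""
    x = np.asarray(list(log2fc_values), dtype=float)
    if len(x) < 2:
        raise ValueError(f"need n >= 2 values, got {len(x)}")
    mean = float(np.mean(x))
    if np.std(x) == 0:
        return {"n": len(x), "mean": mean, "t": float("nan"),
                "p": 1.0 if mean == 0 else 0.0, "zero_variance": True}
    t, p = stats.ttest_1samp(x, 0.0)
    return {"n": len(x), "mean": mean, "t": float(t), "p": float(p),
            "zero_variance": False}


def enhancer_normalized_signal(enhancers, atac_track: CoverageTrack) -> list[EnhancerRecord]:
    """Length-scaled ATAC signal: mean signal x enhancer length / 1000 (bp -> kb)."""
    out = []
    for iv, klass in enhancers:
        if len(iv) == 0:
            raise ValueError(f"zero-length enhancer at {iv.chrom}:{iv.start}")
        mean = peak_signal(atac_track, iv)
        out.append(EnhancerRecord(iv, klass, mean, mean * len(iv) / 1000.0))
    return out
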