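"""A/B compartments from the leading eigenvector of the O/E correlation matrix.

The plaid pattern of a normalized contact map is summarized by computing the
Pearson correlation between every pair of matrix columns and taking the first
eigenvector of that correlation matrix.  Its sign per bin separates active (A,
positive after orientation) from inactive (B) chromatin; the sign is oriented
so the track correlates positively with a reference density (gene density by
default), since the eigen-solver's sign is arbitrary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats

__all__ = [
    "CompartmentTrack",
    "DegenerateSpectrumWarning",
    "correlation_matrix",
    "compartment_eigenvector",
    "orient_sign",
    "correlate_tracks",
    "write_track",
    "read_track",
]


class DegenerateSpectrumWarning(UserWarning):
    """Top eigenvalues tie; the compartment eigenvector is not unique."""


class SignOrientationWarning(UserWarning):
    """Sign reference uninformative; eigenvector sign left as computed."""


@dataclass
class CompartmentTrack:
    chrom: str
    resolution: int
    values: np.ndarray          # per-bin eigenvector entries, NaN at masked bins
    sign_reference: str | None = None

    def ab_calls(self) -> np.ndarray:
        """Per-bin labels: 'A' where value > 0, 'B' where value < 0, '' at NaN/0."""
        out = np.full(self.values.shape, "", dtype=object)
        out[self.values > 0] = "A"
        out[self.values < 0] = "B"
        return out


def correlation_matrix(oe: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation between columns of the O/E matrix (masked bins dropped).

    Returns an m x m matrix over the unmasked bins with unit diagonal.  Bins
    whose O/E column has zero variance are treated as masked by the caller
    (their rows come back NaN and should be excluded before eigen-analysis).
    """
    oe = np.asarray(oe, dtype=float)
    if mask is None:
        mask = np.all(~np.isfinite(oe), axis=0)
    keep = np.flatnonzero(~mask)
    if keep.size < 3:
        raise ValueError(f"need >= 3 unmasked bins, got {keep.size}")
    sub = oe[np.ix_(keep, keep)]
    sub = np.nan_to_num(sub, nan=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.corrcoef(sub, rowvar=False)
    np.fill_diagonal(X, 1.0)
    return X


def compartment_eigenvector(X: np.ndarray, rel_tie_tol: float = 1e-9) -> np.ndarray:
    """Unit-norm eigenvector of X for the largest eigenvalue.

    Deterministic up to sign: the returned vector has a non-negative entry of
    largest magnitude.  Warns when the top two eigenvalues tie (degenerate
    spectrum, e.g. X = I), in which case the vector is not meaningful.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("correlation matrix contains non-finite entries")
    vals, vecs = scipy.linalg.eigh(X)
    lead, second = vals[-1], vals[-2] if len(vals) > 1 else -np.inf
    if len(vals) > 1 and abs(lead - second) <= rel_tie_tol * max(1.0, abs(lead)):
        warnings.warn("largest eigenvalue is degenerate; eigenvector not unique",
                      DegenerateSpectrumWarning, stacklevel=2)
    e = vecs[:, -1]
    k = int(np.argmax(np.abs(e)))
    if e[k] < 0:
        e = -e
    return e


def embed_track(e: np.ndarray, mask: np.ndarray, chrom: str, resolution: int,
                sign_reference: str | None = None) -> CompartmentTrack:
    """Re-insert NaN at masked bins so the track aligns with the map binning."""
    values = np.full(mask.shape, np.nan)
    values[~mask] = e
    return CompartmentTrack(chrom, resolution, values, sign_reference)


def orient_sign(track: CompartmentTrack, reference_density: np.ndarray,
                reference_name: str = "gene_density") -> CompartmentTrack:
    """Flip the eigenvector so it correlates non-negatively with the reference.

    A compartment := oriented value > 0.  Zero-variance or orthogonal
    references leave the sign as computed (flagged with a warning).
    """
    ref = np.asarray(reference_density, dtype=float)
    if np.any(ref[np.isfinite(ref)] < 0):
        raise ValueError("reference density must be non-negative")
    ok = np.isfinite(track.values) & np.isfinite(ref)
    vals = track.values
    if ok.sum() < 3 or np.std(ref[ok]) == 0 or np.std(vals[ok]) == 0:
        warnings.warn("sign reference uninformative; sign left as computed",
                      SignOrientationWarning, stacklevel=2)
        return CompartmentTrack(track.chrom, track.resolution, vals.copy(),
                                reference_name)
    r = float(np.corrcoef(vals[ok], ref[ok])[0, 1])
    if r == 0:
        warnings.warn("eigenvector orthogonal to reference; sign left as computed",
                      SignOrientationWarning, stacklevel=2)
        flipped = vals.copy()
    else:
        flipped = vals.copy() if r > 0 else -vals
    return CompartmentTrack(track.chrom, track.resolution, flipped, reference_name)


def correlate_tracks(track_a: np.ndarray, track_b: np.ndarray,
                     method: str = "pearson") -> float:
    """Pearson R or Spearman rho over pairwise-complete (finite) bins."""
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks must share binning")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 complete pairs, got {int(ok.sum())}")
    if method == "pearson":
        return float(stats.pearsonr(a[ok], b[ok]).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a[ok], b[ok]).statistic)
    raise ValueError(f"unknown method {method!r}")


def write_track(track_values: np.ndarray, chrom: str, resolution: int, path) -> None:
    """bedGraph-style TSV chrom,start,end,value (NaN bins written as 'nan')."""
    with open(path, "w") as fh:
        for i, v in enumerate(np.asarray(track_values, dtype=float)):
            fh.write(f"{chrom}\t{i * resolution}\t{(i + 1) * resolution}"
                     f"\t{float(v)!r}\n")


def read_track(path) -> tuple[str, int, np.ndarray]:
    chroms, starts, ends, vals = [], [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.rstrip("\n").split("\t")[:4]
            chroms.append(c)
            starts.append(int(s))
            ends.append(int(e))
            vals.append(float(v))
    if len(set(chroms)) != 1:
        raise ValueError(f"track {path} must cover one chromosome")
    resolution = ends[0] - starts[0]
    return chroms[0], resolution, np.asarray(vals, dtype=float)
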