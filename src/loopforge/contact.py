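"""Binned cis contact matrices: construction, Knight-Ruiz balancing, O/E.

A ContactMap stores raw observed counts O for one chromosome as an
upper-triangular sparse matrix.  Balancing produces per-bin weights w_i such
that the balanced matrix B_ij = w_i O_ij w_j has constant row sums (fixed to
1, which makes downstream values deterministic).  The expected profile E(d)
is the per-diagonal mean of B over unmasked bin pairs, and the O/E ratio
B_ij / E(|i-j|) is the "loop intensity" used throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

SUPPORTED_RESOLUTIONS = (5000, 10000, 25000)

__all__ = [
    "ContactMap",
    "BalancingWeights",
    "ExpectedProfile",
    "BalanceError",
    "bin_pairs",
    "read_pairs",
    "read_matrix",
    "write_matrix",
    "mask_bins",
    "kr_balance",
    "balanced_dense",
    "expected_by_distance",
    "oe_value",
    "oe_matrix",
]


class BalanceError(RuntimeError):
    def __init__(self, message: str, convergence_error: float):
        super().__init__(message)
        self.convergence_error = convergence_error


@dataclass
class ContactMap:
    chrom: str
    resolution: int
    n_bins: int
    counts: sp.csr_matrix  # upper triangle incl. diagonal

    @classmethod
    def from_coo(cls, chrom, resolution, n_bins, rows, cols, vals) -> "ContactMap":
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        vals = np.asarray(vals, dtype=np.float64)
        lower = rows > cols
        rows2 = np.where(lower, cols, rows)
        cols2 = np.where(lower, rows, cols)
        m = sp.coo_matrix((vals, (rows2, cols2)), shape=(n_bins, n_bins)).tocsr()
        m.sum_duplicates()
        return cls(chrom, int(resolution), int(n_bins), m)

    def dense_symmetric(self) -> np.ndarray:
        u = self.counts.toarray()
        return u + np.triu(u, 1).T

    def marginals(self) -> np.ndarray:
        d = self.dense_symmetric()
        return d.sum(axis=1)

    @property
    def total_pairs(self) -> float:
        return float(self.counts.sum())


@dataclass
class BalancingWeights:
    weights: np.ndarray          # NaN at masked bins
    convergence_error: float
    mask: np.ndarray             # boolean, True = masked

    def __post_init__(self):
        ok = ~self.mask
        if np.any(self.weights[ok] <= 0):
            raise ValueError("weights must be > 0 at unmasked bins")


@dataclass
class ExpectedProfile:
    values: np.ndarray  # E(d), d = 0 .. n_bins-1; NaN where no unmasked pair

    def __call__(self, d: int) -> float:
        return float(self.values[d])


# ---------------------------------------------------------------------------
# construction and I/O


def bin_pairs(pairs, chrom_length: int, resolution: int, chrom: str = "chrS") -> ContactMap:
    """Aggregate (pos1, pos2) cis read pairs into a binned ContactMap.

    Each pair increments exactly one upper-triangular pixel, so the total
    matrix mass equals the number of pairs.
    """
    n_bins = math.ceil(chrom_length / resolution)
    p = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs,
                   dtype=np.int64)
    if p.size == 0:
        return ContactMap(chrom, resolution, n_bins,
                          sp.csr_matrix((n_bins, n_bins)))
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("pairs must be an iterable of (pos1, pos2)")
    bad = np.flatnonzero((p < 0).any(axis=1) | (p >= chrom_length).any(axis=1))
    if bad.size:
        raise ValueError(
            f"pair record {bad[0]} out of range [0, {chrom_length}): {p[bad[0]]}")
    b1 = p[:, 0] // resolution
    b2 = p[:, 1] // resolution
    return ContactMap.from_coo(chrom, resolution, n_bins, b1, b2,
                               np.ones(len(p), dtype=np.float64))


def read_pairs(path) -> tuple[str, np.ndarray]:
    """3-column TSV chrom,pos1,pos2 (one chromosome per file)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos1", "pos2"], comment="#")
    chroms = df["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError(f"pairs file {path} spans multiple chromosomes: {chroms}")
    return str(chroms[0]), df[["pos1", "pos2"]].to_numpy(dtype=np.int64)


def read_matrix(path_matrix, path_bins) -> ContactMap:
    """HiC-Pro-style raw matrix (bin-id COO TSV) + abs-bin BED."""
    bins = []
    chroms = set()
    resolution = None
    with open(path_bins) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, bid = line.rstrip("\n").split("\t")[:4]
            chroms.add(chrom)
            bins.append((int(bid), int(start), int(end)))
            resolution = max(resolution or 0, int(end) - int(start))
    if len(chroms) != 1:
        raise ValueError(f"bin table {path_bins} must cover one chromosome, got {chroms}")
    bin_ids = {bid for bid, _, _ in bins}
    offset = min(bin_ids)
    n_bins = len(bins)

    rows, cols, vals = [], [], []
    seen = set()
    dup = False
    with open(path_matrix) as fh:
        for line in fh:
            if not line.strip():
                continue
            a, b, c = line.split("\t")[:3]
            ia, ib = int(a), int(b)
            if ia not in bin_ids or ib not in bin_ids:
                raise ValueError(f"bin id {ia if ia not in bin_ids else ib} "
                                 f"not in bin table {path_bins}")
            key = (min(ia, ib), max(ia, ib))
            if key in seen:
                dup = True
            seen.add(key)
            rows.append(ia - offset)
            cols.append(ib - offset)
            vals.append(float(c))
    if dup:
        warnings.warn("duplicate COO triples summed", stacklevel=2)
    return ContactMap.from_coo(chroms.pop(), resolution, n_bins, rows, cols, vals)


def write_matrix(cmap: ContactMap, path_matrix, path_bins) -> None:
    with open(path_bins, "w") as fh:
        for i in range(cmap.n_bins):
            start = i * cmap.resolution
            fh.write(f"{cmap.chrom}\t{start}\t{start + cmap.resolution}\t{i + 1}\n")
    coo = cmap.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path_matrix, "w") as fh:
        for k in order:
            v = coo.data[k]
            vstr = str(int(v)) if float(v).is_integer() else repr(float(v))
            fh.write(f"{coo.row[k] + 1}\t{coo.col[k] + 1}\t{vstr}\n")


# ---------------------------------------------------------------------------
# balancing


def mask_bins(cmap: ContactMap, percentile: float = 2.0) -> np.ndarray:
    """Mask bins with zero marginal or marginal below the given percentile of
    nonzero marginals.  KR is unstable on near-empty rows."""
    marg = cmap.marginals()
    nonzero = marg[marg > 0]
    if nonzero.size == 0:
        return np.ones(cmap.n_bins, dtype=bool)
    cut = np.percentile(nonzero, percentile)
    return (marg == 0) | (marg < cut)


def _kr_core(A: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, float]:
    """Knight-Ruiz inner-outer Newton iteration for x with diag(x) A diag(x) e = e.

    Translation of the bnewt algorithm (inexact Newton with CG inner solves).
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5

    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout

    MVP = 0
    while rout > stop_tol * stop_tol:  # outer iteration
        k = 0
        y = e.copy()
        innertol = max(eta * eta * rout, stop_tol * stop_tol)
        rho_km2 = rho_km1
        while rho_km1 > innertol:  # inner CG
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k + MVP > max_iter:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        MVP += k + 1
        if MVP > max_iter:
            break
        rat = rout / rold
        rold = rout
        res_norm = math.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o * eta_o > 0.1:
            eta = max(eta, g * eta_o * eta_o)
        eta = max(min(eta, etamax), stop_tol / res_norm)

    err = float(np.max(np.abs(x * (A @ x) - 1.0)))
    return x, err


def kr_balance(cmap: ContactMap, tol: float = 1e-6, max_iter: int = 3000,
               mask: np.ndarray | None = None,
               mask_percentile: float = 2.0) -> BalancingWeights:
    """Knight-Ruiz balance the map so unmasked row sums of w_i O_ij w_j equal 1.

    Raises BalanceError (carrying the final deviation) on non-convergence.
    """
    if cmap.counts.nnz == 0:
        raise ValueError("cannot balance an empty map")
    if mask is None:
        mask = mask_bins(cmap, mask_percentile)
    keep = np.flatnonzero(~mask)
    if keep.size < 2:
        raise BalanceError("fewer than 2 unmasked bins", float("inf"))
    A = cmap.dense_symmetric()[np.ix_(keep, keep)]
    x, err = _kr_core(A, tol, max_iter)
    if err > tol:
        raise BalanceError(
            f"KR did not converge (max row-sum deviation {err:.3g} > tol {tol:g})", err)
    w = np.full(cmap.n_bins, np.nan)
    w[keep] = x
    return BalancingWeights(weights=w, convergence_error=err, mask=mask.copy())


def balanced_dense(cmap: ContactMap, weights: BalancingWeights) -> np.ndarray:
    """Dense symmetric balanced matrix; NaN rows/cols at masked bins."""
    w = weights.weights
    return cmap.dense_symmetric() * np.outer(w, w)


# ---------------------------------------------------------------------------
# expected profile and O/E


def expected_by_distance(cmap: ContactMap, weights: BalancingWeights) -> ExpectedProfile:
    """E(d) = mean balanced value over unmasked pairs (i, i+d), zeros included."""
    if weights.mask.all():
        raise ValueError("all bins masked")
    B = balanced_dense(cmap, weights)
    n = cmap.n_bins
    ok = ~weights.mask
    vals = np.full(n, np.nan)
    for d in range(n):
        i = np.arange(n - d)
        pair_ok = ok[i] & ok[i + d]
        if pair_ok.any():
            vals[d] = B[i[pair_ok], i[pair_ok] + d].mean()
    return ExpectedProfile(vals)


def oe_value(cmap: ContactMap, weights: BalancingWeights,
             expected: ExpectedProfile, i: int, j: int) -> float:
    """O/E ratio (loop intensity) at pixel (i, j); symmetric in its arguments."""
    if weights.mask[i] or weights.mask[j]:
        raise ValueError(f"pixel ({i},{j}) involves a masked bin")
    d = abs(i - j)
    e = expected.values[d]
    if not np.isfinite(e) or e <= 0:
        raise ValueError(f"expected value undefined or zero at distance {d}")
    lo, hi = min(i, j), max(i, j)
    o = cmap.counts[lo, hi]
    return float(weights.weights[i] * o * weights.weights[j] / e)


def oe_matrix(cmap: ContactMap, weights: BalancingWeights,
              expected: ExpectedProfile) -> np.ndarray:
    """Dense symmetric O/E matrix; NaN at masked bins / undefined distances."""
    B = balanced_dense(cmap, weights)
    n = cmap.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    e = expected.values[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = B / e
    out[~np.isfinite(e) | (e <= 0)] = np.nan
    return out
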