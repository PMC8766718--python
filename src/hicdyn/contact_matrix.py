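"""Binned contact matrices and the expected-count model.

Observed read pairs are binned into a symmetric genome-wide contact
matrix.  The expected count for a bin pair follows

    e_ij = f(i - j) * n*_i * n*_j / N*

where ``f`` is the expected read count as a function of linear distance
(tabulated per bin-distance and smoothed to be non-increasing), ``N*``
is the library total and ``n*_i`` the inferred effective read total of
bin i, estimated by a multiplicative hill-climbing scheme that matches
model marginals to observed marginals (absorbing coverage and
accessibility bias).  Trans pairs use a constant distance term (the
trans floor) chosen so that the expected trans mass equals the observed
trans mass.  From the model we derive the observed/expected
(normalized) matrix and the Pearson correlation matrix of log2 ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import matmul_toeplitz
from sklearn.isotonic import IsotonicRegression

from .genome import Genome, GenomeBins, genome_bins

log = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "DecayCurve",
    "ExpectedModel",
    "bin_pairs",
    "estimate_decay",
    "infer_bin_totals",
    "fit_expected_model",
    "expected_count",
    "expected_matrix",
    "normalized_matrix",
    "correlation_matrix",
    "CorrelationMatrix",
]

DEFAULT_MASK_FRACTION = 0.2  # mask bins with < 20% of the median positive marginal


@dataclass
class ContactMatrix:
    """Symmetric binned observed counts plus a low-coverage bin mask."""

    bins: GenomeBins
    observed: sp.csr_matrix  # full symmetric
    mask: np.ndarray  # True = masked (excluded from all statistics)

    @property
    def bin_size(self) -> int:
        return self.bins.bin_size

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    def marginals(self) -> np.ndarray:
        """Per-bin total observed reads (diagonal counted once)."""
        return np.asarray(self.observed.sum(axis=1)).ravel()

    def mass(self) -> float:
        """Total read pairs in the matrix (upper triangle + diagonal)."""
        return float((self.observed.sum() + self.observed.diagonal().sum()) / 2)

    def dense(self) -> np.ndarray:
        return np.asarray(self.observed.todense(), dtype=float)


def bin_pairs(
    pairs: pd.DataFrame,
    genome: Genome,
    bin_size: int,
    mask_fraction: float = DEFAULT_MASK_FRACTION,
) -> ContactMatrix:
    """Bin retained pairs into a symmetric contact matrix.

    Entry (i, j) counts pairs with one mate in bin i and the other in
    bin j; total upper-triangle + diagonal mass equals the pair count.
    Bins whose marginal is below ``mask_fraction`` times the median
    positive marginal (or zero) are masked.
    """
    bins = genome_bins(genome, bin_size)
    B = bins.n_bins
    if len(pairs):
        gi = bins.locate(pairs["chrom1"].to_numpy(), pairs["pos1"].to_numpy())
        gj = bins.locate(pairs["chrom2"].to_numpy(), pairs["pos2"].to_numpy())
        lo = np.minimum(gi, gj)
        hi = np.maximum(gi, gj)
        key, counts = np.unique(lo * B + hi, return_counts=True)
        iu = (key // B).astype(np.int64)
        ju = (key % B).astype(np.int64)
        upper = sp.coo_matrix((counts.astype(np.float64), (iu, ju)), shape=(B, B)).tocsr()
        observed = upper + upper.T - sp.diags(upper.diagonal())
    else:
        observed = sp.csr_matrix((B, B), dtype=np.float64)
    marg = np.asarray(observed.sum(axis=1)).ravel()
    pos = marg[marg > 0]
    thresh = mask_fraction * np.median(pos) if pos.size else 0.0
    mask = marg < max(thresh, 1e-12) if pos.size else np.ones(B, dtype=bool)
    return ContactMatrix(bins=bins, observed=observed.tocsr(), mask=mask)


@dataclass
class DecayCurve:
    """Non-increasing tabulated expected reads per cis bin pair vs distance.

    ``edges[k] <= d < edges[k+1]`` maps distance d (in bins) to
    ``values[k]``; distances beyond the last edge take the last value.
    """

    edges: np.ndarray  # stratum left edges, ascending, edges[0] == 0
    values: np.ndarray  # non-increasing

    def eval(self, d) -> np.ndarray:
        d = np.asarray(d)
        idx = np.clip(np.searchsorted(self.edges, d, side="right") - 1, 0, len(self.values) - 1)
        return self.values[idx]


def _cis_distance_sums(matrix: ContactMatrix):
    """(sum of observed, number of unmasked bin pairs) per cis bin distance."""
    bins = matrix.bins
    coo = sp.triu(matrix.observed).tocoo()
    chrom_code = bins.chrom_of()
    unmasked = ~matrix.mask
    max_d = max(bins.n_bins_per_chrom.values())
    sums = np.zeros(max_d, dtype=np.float64)
    cnts = np.zeros(max_d, dtype=np.float64)
    keep = (
        (chrom_code[coo.row] == chrom_code[coo.col]) & unmasked[coo.row] & unmasked[coo.col]
    )
    d = (coo.col - coo.row)[keep]
    np.add.at(sums, d, coo.data[keep])
    for name in bins.genome.names:
        o = bins.offsets[name]
        n = bins.n_bins_per_chrom[name]
        u = unmasked[o : o + n].astype(np.float64)
        if u.sum() == 0:
            continue
        ac = np.correlate(u, u, mode="full")[n - 1 :]  # lag 0..n-1
        cnts[: len(ac)] += ac
    return sums, cnts


def estimate_decay(
    matrix: ContactMatrix,
    log_pooling: bool | None = None,
    min_stratum_count: float = 50.0,
) -> DecayCurve:
    """Mean observed count per cis bin pair as a function of bin distance.

    Pooled over chromosomes, optionally in log-spaced distance strata
    (merged until each holds at least ``min_stratum_count`` observed
    reads — used at fine resolution to stabilize the sparse tail), then
    smoothed to be non-increasing by isotonic regression.  ``f(0)``
    covers the diagonal.
    """
    if (~matrix.mask).sum() < 2:
        raise ValueError("need at least 2 unmasked bins to estimate decay")
    if log_pooling is None:
        log_pooling = matrix.bin_size < 10_000
    sums, cnts = _cis_distance_sums(matrix)
    max_d = len(sums)
    if max_d < 2 or cnts[1:].sum() == 0:
        # single-bin chromosomes only: the diagonal is all there is
        if cnts[0] == 0:
            raise ValueError("no cis bin pairs available")
        return DecayCurve(edges=np.array([0]), values=np.array([sums[0] / cnts[0]]))
    # the diagonal (within-bin separations, below one bin) is its own
    # stratum, exempt from the monotone constraint that applies at d >= 1
    if log_pooling:
        raw = np.unique(np.concatenate(([1, 2], np.geomspace(1, max_d, 60).astype(np.int64))))
        edges = [1]
        acc = 0.0
        for left, right in zip(raw[:-1], raw[1:]):
            acc += sums[left:right].sum()
            if acc >= min_stratum_count:
                edges.append(int(right))
                acc = 0.0
        stratum_edges = np.array(edges if len(edges) > 1 else [1, max_d], dtype=np.int64)
    else:
        stratum_edges = np.arange(1, max_d + 1, dtype=np.int64)
    left = stratum_edges[:-1]
    right = np.append(stratum_edges[1:-1], max_d)
    if left.size == 0:
        left = np.array([1], dtype=np.int64)
        right = np.array([max_d], dtype=np.int64)
    s_sum = np.array([sums[l:r].sum() for l, r in zip(left, right)])
    s_cnt = np.array([cnts[l:r].sum() for l, r in zip(left, right)])
    ok = s_cnt > 0
    if not ok.any():
        raise ValueError("no cis bin pairs available")
    centers = (left + np.maximum(right - 1, left)) / 2.0
    mean = s_sum[ok] / s_cnt[ok]
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    fitted = np.asarray(iso.fit_transform(centers[ok], mean, sample_weight=s_cnt[ok]), dtype=float)
    diag_mean = sums[0] / cnts[0] if cnts[0] > 0 else 0.0
    return DecayCurve(
        edges=np.concatenate(([0], left[ok])).astype(np.int64),
        values=np.concatenate(([diag_mean], fitted)),
    )


@dataclass
class ExpectedModel:
    """Fitted expected-count model e_ij = f(|i-j|) n*_i n*_j / N*."""

    bins: GenomeBins
    f: DecayCurve
    n_star: np.ndarray
    N_star: float
    trans_floor: float
    mask: np.ndarray
    objective_history: list = field(default_factory=list)

    @property
    def resolution(self) -> int:
        return self.bins.bin_size


def _expected_marginals(matrix: ContactMatrix, f: DecayCurve, n: np.ndarray, N: float, t: float):
    """Model marginal per bin: cis Toeplitz product + constant trans term."""
    bins = matrix.bins
    exp_marg = np.zeros(bins.n_bins)
    S = n.sum()
    for name in bins.genome.names:
        o = bins.offsets[name]
        nb = bins.n_bins_per_chrom[name]
        nc = n[o : o + nb]
        ftab = f.eval(np.arange(nb))
        if nb == 1:
            y = ftab[0] * nc
        else:
            y = matmul_toeplitz((ftab, ftab), nc)
        y = np.asarray(y).ravel()
        exp_marg[o : o + nb] = nc * y / N + t * nc * (S - nc.sum()) / N
    return exp_marg


def _trans_totals(matrix: ContactMatrix, n: np.ndarray):
    """(observed trans mass, sum over trans pairs of n_i n_j) on unmasked bins."""
    bins = matrix.bins
    chrom_code = bins.chrom_of()
    coo = sp.triu(matrix.observed).tocoo()
    keep = (
        (chrom_code[coo.row] != chrom_code[coo.col])
        & ~matrix.mask[coo.row]
        & ~matrix.mask[coo.col]
    )
    obs_trans = float(coo.data[keep].sum())
    S = n.sum()
    S_c = np.array(
        [n[bins.offsets[c] : bins.offsets[c] + bins.n_bins_per_chrom[c]].sum() for c in bins.genome.names]
    )
    pair_nn = (S * S - float((S_c**2).sum())) / 2.0
    return obs_trans, pair_nn


def infer_bin_totals(
    matrix: ContactMatrix,
    f: DecayCurve,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> tuple[np.ndarray, float]:
    """Hill-climb the inferred per-bin totals n*.

    Coordinate-wise multiplicative update n*_i <- n*_i * (observed
    marginal_i / model marginal_i), driving the squared marginal
    residual down; converged when no n* changes by more than ``tol``
    relatively, errors out if the objective rises for 5 consecutive
    iterations.  N* is fixed at the total retained read count.
    """
    model = _fit_totals(matrix, f, max_iter, tol)
    return model.n_star, model.N_star


def _fit_totals(matrix, f, max_iter, tol) -> ExpectedModel:
    unmasked = ~matrix.mask
    if unmasked.sum() == 0:
        raise ValueError("all bins are masked")
    obs_marg = matrix.marginals()
    N = matrix.mass()
    n = obs_marg.astype(float).copy()
    n[~unmasked] = 0.0
    history: list[float] = []
    rising = 0
    for _ in range(max_iter):
        obs_trans, pair_nn = _trans_totals(matrix, n)
        t = (obs_trans * N / pair_nn) if pair_nn > 0 else 0.0
        exp_marg = _expected_marginals(matrix, f, n, N, t)
        resid = obs_marg[unmasked] - exp_marg[unmasked]
        obj = float(resid @ resid)
        if history and obj > history[-1] * (1 + 1e-12):
            rising += 1
            if rising >= 5:
                raise RuntimeError(
                    f"hill climb diverged: objective rose 5 consecutive iterations "
                    f"(last {history[-1]:.6g} -> {obj:.6g})"
                )
        else:
            rising = 0
        history.append(obj)
        ratio = np.ones_like(n)
        good = unmasked & (exp_marg > 0)
        ratio[good] = obs_marg[good] / exp_marg[good]
        # square-root damping: n enters the model bilinearly, so the raw
        # multiplicative update overshoots by exactly a factor two in log
        # space (2-cycle on symmetric data); the damped step is monotone
        n_new = n * np.sqrt(ratio)
        delta = np.abs(n_new - n)[unmasked & (n > 0)] / n[unmasked & (n > 0)]
        n = n_new
        if delta.size == 0 or delta.max() < tol:
            break
    obs_trans, pair_nn = _trans_totals(matrix, n)
    t = (obs_trans * N / pair_nn) if pair_nn > 0 else 0.0
    return ExpectedModel(
        bins=matrix.bins,
        f=f,
        n_star=n,
        N_star=N,
        trans_floor=t,
        mask=matrix.mask.copy(),
        objective_history=history,
    )


def fit_expected_model(
    matrix: ContactMatrix,
    log_pooling: bool | None = None,
    min_stratum_count: float = 50.0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> ExpectedModel:
    """Estimate the decay curve, then the inferred bin totals and trans floor."""
    f = estimate_decay(matrix, log_pooling=log_pooling, min_stratum_count=min_stratum_count)
    return _fit_totals(matrix, f, max_iter, tol)


def expected_count(i, j, model: ExpectedModel):
    """Expected reads for bin pair (i, j): cis f(|i-j|) n*_i n*_j / N*,
    trans t n*_i n*_j / N*.  Masked bins yield NaN."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    chrom_code = model.bins.chrom_of()
    same = chrom_code[i] == chrom_code[j]
    dist_term = np.where(same, model.f.eval(np.abs(j - i)), model.trans_floor)
    e = dist_term * model.n_star[i] * model.n_star[j] / model.N_star
    e = np.where(model.mask[i] | model.mask[j], np.nan, e)
    if e.ndim == 0:
        return float(e)
    return e


def expected_matrix(model: ExpectedModel) -> np.ndarray:
    """Dense expected matrix (intended for coarse resolutions)."""
    B = model.bins.n_bins
    i, j = np.meshgrid(np.arange(B), np.arange(B), indexing="ij")
    return np.asarray(expected_count(i.ravel(), j.ravel(), model)).reshape(B, B)


def normalized_matrix(matrix: ContactMatrix, model: ExpectedModel) -> np.ndarray:
    """Observed/expected ratio matrix (dense, NaN where masked).

    Zero expected with zero observed maps to 1 (no information); zero
    expected with positive observed is masked with a warning.
    """
    if model.bins.bin_size != matrix.bin_size or model.bins.n_bins != matrix.n_bins:
        raise ValueError("model was fitted at a different binning")
    obs = matrix.dense()
    exp = expected_matrix(model)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = obs / exp
    both_zero = (exp == 0) & (obs == 0)
    ratio[both_zero] = 1.0
    bad = (exp == 0) & (obs > 0)
    if bad.any():
        log.warning("%d bin pairs with observed reads but zero expected; masked", int(bad.sum()))
        ratio[bad] = np.nan
    ratio[matrix.mask, :] = np.nan
    ratio[:, matrix.mask] = np.nan
    return ratio


@dataclass
class CorrelationMatrix:
    """Pearson correlation of bins' normalized contact profiles."""

    bins: GenomeBins
    values: np.ndarray
    mask: np.ndarray


def correlation_matrix(norm: np.ndarray, bins: GenomeBins | None = None) -> CorrelationMatrix:
    """Pearson r between rows i and j of log2(obs/exp), computed over the
    columns where both rows are finite, excluding columns i and j.

    Bins whose profile is constant or all-NaN are masked (NaN row/col);
    the diagonal is 1 for unmasked bins.
    """
    norm = np.asarray(norm, dtype=float)
    B = norm.shape[0]
    if norm.shape[0] != norm.shape[1]:
        raise ValueError("normalized matrix must be square")
    if B < 3:
        raise ValueError("need at least 3 bins")
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.log2(norm)
    L[~np.isfinite(L)] = np.nan
    out = np.full((B, B), np.nan)
    row_ok = np.zeros(B, dtype=bool)
    for i in range(B):
        v = L[i]
        fin = np.isfinite(v)
        row_ok[i] = fin.sum() >= 3 and np.nanstd(v) > 0
    for i in range(B):
        if not row_ok[i]:
            continue
        out[i, i] = 1.0
        for j in range(i + 1, B):
            if not row_ok[j]:
                continue
            cols = np.isfinite(L[i]) & np.isfinite(L[j])
            cols[i] = False
            cols[j] = False
            if cols.sum() < 3:
                continue
            x, y = L[i, cols], L[j, cols]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            out[i, j] = out[j, i] = r
    return CorrelationMatrix(
        bins=bins, values=out, mask=~row_ok
    )
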