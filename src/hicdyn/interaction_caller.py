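"""Significant-interaction calling via the cumulative binomial model.

Each unordered locus pair at fine resolution (default 1 kb tiles) is
scored by the upper-tail cumulative binomial probability of seeing at
least the observed read count given N* total reads and per-pair success
probability e_ij / N* from the fitted expected-count model; pairs with
p <= alpha (default 0.05, uncorrected, mirroring standard practice) and
at least ``min_observed`` reads are reported, classified cis/trans,
with descriptive statistics (cis/trans split, median cis distance,
distance-decay profile).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .genome import Genome
from .io_formats import InteractionSet, INTERACTION_COLUMNS
from .contact_matrix import ContactMatrix, ExpectedModel, bin_pairs, expected_count

__all__ = [
    "CallerConfig",
    "InteractionSet",
    "binomial_pvalue",
    "call_interactions",
    "classify_cis_trans",
    "cis_trans_percentages",
    "median_cis_distance",
    "decay_profile",
    "CisTransSummary",
]


@dataclass(frozen=True)
class CallerConfig:
    """Calling parameters.

    resolution: anchor tile width in bp.  alpha: raw p-value cutoff.
    min_observed: minimum reads for a pair to be reported.  min_distance:
    minimum cis separation in bp (None -> 2 * resolution, excluding
    adjacent-tile artifacts).  fdr: apply Benjamini-Hochberg before the
    alpha cut (off by default; the standard analysis uses raw p-values).
    """

    resolution: int = 1000
    alpha: float = 0.05
    min_observed: int = 5
    min_distance: int | None = None
    fdr: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def min_distance_bp(self) -> int:
        return 2 * self.resolution if self.min_distance is None else self.min_distance


def binomial_pvalue(k, n, p) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, p).

    Numerically stable for very large n (regularized incomplete beta
    under the hood); k = 0 returns exactly 1.
    """
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    p_arr = np.asarray(p)
    if np.any(k_arr < 0) or np.any(k_arr > n_arr):
        raise ValueError("need 0 <= k <= n")
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("need 0 <= p <= 1")
    out = stats.binom.sf(k_arr - 1, n_arr, p_arr)
    if out.ndim == 0:
        return float(out)
    return out


def _tested_pair_count(matrix: ContactMatrix, mask: np.ndarray, min_dist_bins: int) -> int:
    """Unmasked candidate pairs: cis at >= min_dist_bins separation + all trans."""
    bins = matrix.bins
    unmasked = ~mask
    n_cis = 0
    for name in bins.genome.names:
        o = bins.offsets[name]
        nb = bins.n_bins_per_chrom[name]
        u = unmasked[o : o + nb].astype(np.float64)
        if u.sum() < 2:
            continue
        ac = np.correlate(u, u, mode="full")[nb - 1 :]
        n_cis += int(ac[min_dist_bins:].sum())
    U = float(unmasked.sum())
    U_c = np.array(
        [
            unmasked[bins.offsets[c] : bins.offsets[c] + bins.n_bins_per_chrom[c]].sum()
            for c in bins.genome.names
        ],
        dtype=float,
    )
    n_trans = int(round((U * U - float((U_c**2).sum())) / 2.0))
    return n_cis + n_trans


def call_interactions(
    pairs: pd.DataFrame,
    genome: Genome,
    model: ExpectedModel,
    config: CallerConfig = CallerConfig(),
    condition: str = "condition",
) -> InteractionSet:
    """Call significant interactions from retained read pairs.

    The model must be fitted at ``config.resolution``.  Every unordered
    unmasked locus pair at >= min_distance cis separation (or trans) is
    a candidate; pairs with observed >= min_observed and cumulative
    binomial p <= alpha are reported with anchors as half-open
    resolution-sized tiles.  ``n_tested`` on the returned set counts all
    candidates (for empirical type-I rates).
    """
    if model.resolution != config.resolution:
        raise ValueError(
            f"model resolution {model.resolution} != caller resolution {config.resolution}"
        )
    matrix = bin_pairs(pairs, genome, config.resolution)
    if matrix.n_bins != model.bins.n_bins:
        raise ValueError("model binning does not match the genome")
    mask = model.mask
    min_dist_bins = max(0, -(-config.min_distance_bp // config.resolution))
    n_tested = _tested_pair_count(matrix, mask, min_dist_bins)

    coo = sp.triu(matrix.observed).tocoo()
    chrom_code = model.bins.chrom_of()
    same = chrom_code[coo.row] == chrom_code[coo.col]
    far = (coo.col - coo.row) >= min_dist_bins
    keep = (
        (coo.data >= config.min_observed)
        & ~mask[coo.row]
        & ~mask[coo.col]
        & (~same | far)
    )
    i = coo.row[keep]
    j = coo.col[keep]
    obs = coo.data[keep]
    exp = np.atleast_1d(expected_count(i, j, model))
    N = int(round(model.N_star))
    p_pair = np.clip(exp / model.N_star, 0.0, 1.0)
    with np.errstate(invalid="ignore"):
        pvals = stats.binom.sf(obs - 1, N, p_pair)
    if config.fdr and pvals.size:
        pvals = stats.false_discovery_control(pvals)
    sig = pvals <= config.alpha
    table = model.bins.table()
    a = table.iloc[i[sig]].reset_index(drop=True)
    b = table.iloc[j[sig]].reset_index(drop=True)
    df = pd.DataFrame(
        {
            "chrom1": a["chrom"],
            "start1": a["start"],
            "end1": a["end"],
            "chrom2": b["chrom"],
            "start2": b["start"],
            "end2": b["end"],
            "observed": obs[sig].astype(np.int64),
            "expected": exp[sig],
            "p_value": pvals[sig],
            "class": np.where(same[keep][sig], "cis", "trans"),
        }
    )[INTERACTION_COLUMNS]
    return InteractionSet(condition=condition, df=df.reset_index(drop=True), config=config, n_tested=n_tested)


class CisTransSummary(NamedTuple):
    cis: int
    trans: int
    cis_pct: float
    trans_pct: float


def cis_trans_percentages(cis: int, trans: int) -> tuple[float, float]:
    """Percentages of a cis/trans partition, rounded to 1 decimal."""
    total = cis + trans
    if total == 0:
        return (float("nan"), float("nan"))
    return (round(100.0 * cis / total, 1), round(100.0 * trans / total, 1))


def classify_cis_trans(iset: InteractionSet) -> CisTransSummary:
    """Counts and percentages of intra- vs inter-chromosomal interactions.

    An interaction is cis iff both anchors lie on the same chromosome.
    Percentages are NaN for an empty set.
    """
    cls = iset.df["class"] if "class" in iset.df else (iset.df["chrom1"] == iset.df["chrom2"]).map(
        {True: "cis", False: "trans"}
    )
    cis = int((cls == "cis").sum())
    trans = int((cls == "trans").sum())
    cis_pct, trans_pct = cis_trans_percentages(cis, trans)
    return CisTransSummary(cis, trans, cis_pct, trans_pct)


def _cis_midpoint_distances(df: pd.DataFrame) -> np.ndarray:
    cis = df[df["chrom1"] == df["chrom2"]]
    midA = (cis["start1"] + cis["end1"]).to_numpy() / 2.0
    midB = (cis["start2"] + cis["end2"]).to_numpy() / 2.0
    return np.abs(midB - midA)


def median_cis_distance(iset: InteractionSet) -> float:
    """Median |anchor midpoint separation| over cis interactions, in bp."""
    d = _cis_midpoint_distances(iset.df)
    if d.size == 0:
        raise ValueError("no cis interactions")
    return float(np.median(d))


def decay_profile(source, n_strata: int = 30) -> tuple[pd.DataFrame, bool]:
    """Contact frequency per log-spaced cis distance stratum.

    ``source`` is a read-pair DataFrame (mate separation) or an
    :class:`InteractionSet` (anchor midpoint separation).  Frequencies
    are normalized to sum to 1; the second return value reports whether
    the per-bp contact density is monotonically decreasing across
    occupied strata.
    """
    if isinstance(source, InteractionSet):
        d = _cis_midpoint_distances(source.df)
    else:
        cis = source[source["chrom1"] == source["chrom2"]]
        d = np.abs(cis["pos2"].to_numpy() - cis["pos1"].to_numpy()).astype(float)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("no cis data with positive distance")
    lo, hi = d.min(), d.max()
    if lo == hi:
        edges = np.array([lo, hi + 1.0])
    else:
        edges = np.geomspace(lo, hi * (1 + 1e-9), n_strata + 1)
    counts, _ = np.histogram(d, bins=edges)
    freq = counts / counts.sum()
    density = counts / np.diff(edges)  # per-bp, for the monotonicity check
    occupied = density[counts > 0]
    monotone = bool(np.all(np.diff(occupied) <= 1e-12)) if occupied.size > 1 else True
    profile = pd.DataFrame(
        {"distance_lo": edges[:-1], "distance_hi": edges[1:], "frequency": freq}
    )
    return profile, monotone
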