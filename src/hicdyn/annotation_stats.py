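"""Epigenetic-state assignment, same-state preference, GWAS-SNP density
and motif-region sequence export for called interactions.

Each interaction anchor is assigned the epigenetic state with maximal
base-pair overlap (ties toward the lower state label); the tendency of
both anchors of an interaction to share a state is tested against a
permutation null built from randomized control interactions that
preserve record count, anchor lengths, cis/trans split and the observed
cis-distance distribution.  GWAS-SNP density (unique SNPs per bp) is
compared between the interacting genome, a matched random control drawn
from the non-interacting complement, and the genome-wide background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .genome import Genome, merge_intervals, intervals_length, complement_intervals
from .io_formats import InteractionSet

log = logging.getLogger(__name__)

__all__ = [
    "PreferenceTestResult",
    "GwasEnrichmentResult",
    "primary_state",
    "state_distribution",
    "random_control_interactions",
    "es_preference_test",
    "snp_frequency",
    "gwas_enrichment",
    "export_motif_regions",
]

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# epigenetic-state assignment
# ---------------------------------------------------------------------------


class _ESIndex:
    """Per-chromosome sorted segment arrays for fast overlap queries.

    Segments may overlap (published chromatin-state maps do); the
    candidate window is bounded by the longest segment per chromosome.
    """

    def __init__(self, es: pd.DataFrame):
        self.by_chrom = {}
        for chrom, grp in es.sort_values(["chrom", "start"]).groupby("chrom"):
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
            states = grp["state"].to_numpy()
            self.by_chrom[chrom] = (starts, ends, states, int((ends - starts).max()))


def _candidate_overlaps(index: _ESIndex, anchors: pd.DataFrame) -> pd.DataFrame:
    """Long table (anchor row index, state, overlap bp) for all anchor/segment
    overlaps."""
    frames = []
    for chrom, grp in anchors.groupby("chrom"):
        entry = index.by_chrom.get(chrom)
        if entry is None:
            continue
        starts, ends, states, max_len = entry
        a_start = grp["start"].to_numpy(np.int64)
        a_end = grp["end"].to_numpy(np.int64)
        lo = np.searchsorted(starts, a_start - max_len, side="left")
        hi = np.searchsorted(starts, a_end, side="left")
        cnt = hi - lo
        if cnt.sum() == 0:
            continue
        rows = np.repeat(grp.index.to_numpy(), cnt)
        intra = np.concatenate([np.arange(c) for c in cnt]) if cnt.sum() else np.array([], dtype=int)
        seg = np.repeat(lo, cnt) + intra
        ov = np.minimum(ends[seg], np.repeat(a_end, cnt)) - np.maximum(
            starts[seg], np.repeat(a_start, cnt)
        )
        keep = ov > 0
        frames.append(
            pd.DataFrame({"anchor": rows[keep], "state": states[seg[keep]], "overlap": ov[keep]})
        )
    if not frames:
        return pd.DataFrame(columns=["anchor", "state", "overlap"])
    return pd.concat(frames, ignore_index=True)


def _primary_of(cand: pd.DataFrame, n_anchors: int) -> np.ndarray:
    """Primary state per anchor: max overlap, ties toward the lower label."""
    out = np.full(n_anchors, None, dtype=object)
    if len(cand):
        best = cand.sort_values(
            ["anchor", "overlap", "state"], ascending=[True, False, True]
        ).drop_duplicates("anchor")
        out[best["anchor"].to_numpy()] = best["state"].to_numpy()
    return out


def primary_state(anchor: tuple, es: pd.DataFrame):
    """(primary state, set of all overlapping states) for one anchor.

    The primary state is the one with maximal overlap length, ties
    broken toward the lower state label; an anchor touching no segment
    yields ('unassigned', empty set).
    """
    chrom, start, end = anchor
    anchors = pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})
    cand = _candidate_overlaps(_ESIndex(es), anchors)
    prim = _primary_of(cand, 1)[0]
    overlap_set = set(cand["state"]) if len(cand) else set()
    return (prim if prim is not None else UNASSIGNED), overlap_set


def _record_anchor_frame(iset: InteractionSet) -> pd.DataFrame:
    """Both anchors of every record, anchor index = 2*record + side."""
    df = iset.df
    a = df[["chrom1", "start1", "end1"]].set_axis(["chrom", "start", "end"], axis=1)
    b = df[["chrom2", "start2", "end2"]].set_axis(["chrom", "start", "end"], axis=1)
    out = pd.concat([a, b], ignore_index=True)
    return out


def _anchor_states(iset: InteractionSet, index: _ESIndex) -> np.ndarray:
    anchors = _record_anchor_frame(iset)
    cand = _candidate_overlaps(index, anchors)
    return _primary_of(cand, len(anchors))


def state_distribution(
    iset: InteractionSet, es: pd.DataFrame, multi: bool = False
) -> tuple[pd.Series, int]:
    """Percentage of interacting regions per epigenetic state.

    Each anchor contributes its primary state (or, with ``multi``,
    every overlapping state once); percentages are over assigned
    contributions and sum to 100.  Returns (percentages, number of
    unassigned anchors).
    """
    if len(iset) == 0:
        raise ValueError("empty interaction set")
    index = _ESIndex(es)
    anchors = _record_anchor_frame(iset)
    cand = _candidate_overlaps(index, anchors)
    if multi:
        contrib = cand.drop_duplicates(["anchor", "state"])["state"]
        assigned_anchors = cand["anchor"].nunique()
    else:
        prim = _primary_of(cand, len(anchors))
        contrib = pd.Series([s for s in prim if s is not None])
        assigned_anchors = int(sum(s is not None for s in prim))
    unassigned = len(anchors) - assigned_anchors
    counts = contrib.value_counts().sort_index()
    pct = 100.0 * counts / counts.sum()
    return pct, unassigned


# ---------------------------------------------------------------------------
# randomized control interactions
# ---------------------------------------------------------------------------


def random_control_interactions(
    iset: InteractionSet, genome: Genome, seed: int, max_retries: int = 100
) -> InteractionSet:
    """Randomized interactions preserving record count, anchor lengths,
    cis/trans split and (for cis) the observed midpoint-distance
    distribution (resampled with replacement); positions uniform over
    valid placements; fully seeded."""
    rng = np.random.default_rng(seed)
    df = iset.df
    n = len(df)
    len1 = (df["end1"] - df["start1"]).to_numpy(np.int64)
    len2 = (df["end2"] - df["start2"]).to_numpy(np.int64)
    is_cis = (df["chrom1"] == df["chrom2"]).to_numpy()
    cis_d = np.abs(
        (df["start2"] + df["end2"]).to_numpy() / 2.0 - (df["start1"] + df["end1"]).to_numpy() / 2.0
    )[is_cis]
    names = genome.names
    lengths = np.array([genome.lengths[c] for c in names], dtype=np.int64)
    rows = []
    for k in range(n):
        l1, l2 = int(len1[k]), int(len2[k])
        if is_cis[k]:
            placed = False
            for _ in range(max_retries):
                d = float(cis_d[rng.integers(len(cis_d))]) if cis_d.size else float(l1)
                # valid chromosomes: need midA in [l1/2, L - d - l2/2]
                room = lengths - d - l2 / 2.0 - l1 / 2.0
                ok = np.flatnonzero(room > 1)
                if ok.size == 0:
                    continue
                ci = int(ok[rng.integers(ok.size)] if ok.size > 1 else ok[0])
                midA = l1 / 2.0 + rng.random() * room[ci]
                midB = midA + d
                s1 = int(round(midA - l1 / 2.0))
                s2 = int(round(midB - l2 / 2.0))
                rows.append((names[ci], s1, s1 + l1, names[ci], s2, s2 + l2, "cis"))
                placed = True
                break
            if not placed:
                raise RuntimeError("could not place a cis control record (genome too small)")
        else:
            c1, c2 = rng.choice(len(names), size=2, replace=False, p=lengths / lengths.sum())
            s1 = int(rng.integers(0, max(1, lengths[c1] - l1)))
            s2 = int(rng.integers(0, max(1, lengths[c2] - l2)))
            a = (names[c1], s1, s1 + l1)
            b = (names[c2], s2, s2 + l2)
            if (b[0], b[1]) < (a[0], a[1]):
                a, b = b, a
            rows.append((*a, *b, "trans"))
    out = pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "class"]
    )
    out["observed"] = 0
    out["expected"] = 0.0
    out["p_value"] = 1.0
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "observed", "expected", "p_value", "class"]
    return InteractionSet(condition=f"{iset.condition}_control", df=out[cols])


@dataclass
class PreferenceTestResult:
    """Same-state preference vs randomized control interactions."""

    observed: float
    null_fractions: np.ndarray
    null_mean: float
    p_permutation: float
    p_normal: float
    replicates: int
    seed: int


def _same_state_fraction(iset: InteractionSet, index: _ESIndex, mode: str) -> float:
    n = len(iset)
    anchors = _record_anchor_frame(iset)
    cand = _candidate_overlaps(index, anchors)
    if mode == "primary":
        prim = _primary_of(cand, 2 * n)
        a, b = prim[:n], prim[n:]
        ok = np.array([x is not None and y is not None for x, y in zip(a, b)])
        if ok.sum() == 0:
            return float("nan")
        same = np.array([x == y for x, y in zip(a, b)]) & ok
        return float(same.sum() / ok.sum())
    # any shared state between the two anchors' overlap sets
    sets = [set() for _ in range(2 * n)]
    for anchor, state in zip(cand["anchor"], cand["state"]):
        sets[anchor].add(state)
    ok = np.array([bool(sets[k]) and bool(sets[k + n]) for k in range(n)])
    if ok.sum() == 0:
        return float("nan")
    shared = np.array([bool(sets[k] & sets[k + n]) for k in range(n)]) & ok
    return float(shared.sum() / ok.sum())


def es_preference_test(
    iset: InteractionSet,
    es: pd.DataFrame,
    K: int = 1000,
    seed: int = 0,
    genome: Genome | None = None,
    mode: str = "primary",
) -> PreferenceTestResult:
    """Permutation test of same-state preference.

    observed = fraction of interactions whose anchors share a primary
    state (``mode='any'`` instead counts any non-empty intersection of
    the anchors' overlapping-state sets); the null statistic is computed
    on K independent randomized control draws; the permutation p-value
    is (1 + #{null >= observed}) / (K + 1), alongside a
    normal-approximation p from the null mean and sd.
    """
    if len(iset) == 0:
        raise ValueError("empty interaction set")
    if K < 1:
        raise ValueError("need K >= 1 replicates")
    if genome is None:
        chrom_max = (
            pd.concat(
                [
                    iset.df.groupby("chrom1")["end1"].max(),
                    iset.df.groupby("chrom2")["end2"].max(),
                    es.groupby("chrom")["end"].max(),
                ]
            )
            .groupby(level=0)
            .max()
        )
        genome = Genome(chromosomes=tuple((c, int(v)) for c, v in chrom_max.items()))
    index = _ESIndex(es)
    observed = _same_state_fraction(iset, index, mode)
    rng = np.random.default_rng(seed)
    null = np.empty(K)
    for k in range(K):
        ctrl = random_control_interactions(iset, genome, seed=int(rng.integers(2**31 - 1)))
        null[k] = _same_state_fraction(ctrl, index, mode)
    null = null[np.isfinite(null)]
    p_perm = (1.0 + float((null >= observed).sum())) / (len(null) + 1.0)
    sd = null.std(ddof=1) if len(null) > 1 else float("nan")
    if sd and np.isfinite(sd) and sd > 0:
        z = (observed - null.mean()) / sd
        p_normal = float(_stats.norm.sf(z))
    else:
        p_normal = float("nan")
    return PreferenceTestResult(
        observed=observed,
        null_fractions=null,
        null_mean=float(null.mean()),
        p_permutation=p_perm,
        p_normal=p_normal,
        replicates=K,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# GWAS SNP density
# ---------------------------------------------------------------------------


def snp_frequency(regions: pd.DataFrame, snps: pd.DataFrame) -> float:
    """Unique SNPs falling in the union of the regions, per bp of union."""
    if len(regions) == 0:
        raise ValueError("empty region list")
    merged = merge_intervals(regions)
    total = intervals_length(merged)
    if total == 0:
        raise ValueError("zero-length region union")
    uniq = snps.drop_duplicates(["chrom", "pos"])
    count = 0
    for chrom, grp in merged.groupby("chrom"):
        s = uniq[uniq["chrom"] == chrom]["pos"].to_numpy(np.int64)
        if s.size == 0:
            continue
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        idx = np.searchsorted(starts, s, side="right") - 1
        ok = idx >= 0
        count += int((s[ok] < ends[idx[ok]]).sum())
    return count / total


def _anchor_union(iset: InteractionSet) -> pd.DataFrame:
    return merge_intervals(_record_anchor_frame(iset))


def _sample_control_regions(
    union: pd.DataFrame, genome: Genome, seed: int, max_retries: int = 100
) -> pd.DataFrame:
    """Random interval set of equal total length and matched piece-length
    distribution, drawn from the complement of the interacting union
    (a control piece never touches the union)."""
    comp = complement_intervals(union, genome)
    comp = comp[(comp["end"] - comp["start"]) > 0].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    seg_chrom = comp["chrom"].to_numpy()
    seg_start = comp["start"].to_numpy(np.int64)
    seg_end = comp["end"].to_numpy(np.int64)
    seg_len = seg_end - seg_start
    placed: list[tuple[str, int, int]] = []
    taken: dict[int, list[tuple[int, int]]] = {}
    for piece in (union["end"] - union["start"]).sort_values(ascending=False):
        piece = int(piece)
        fits = np.flatnonzero(seg_len >= piece)
        if fits.size == 0:
            raise RuntimeError("complement too small to place a control piece")
        weights = (seg_len[fits] - piece + 1).astype(float)
        ok = False
        for _ in range(max_retries):
            si = int(fits[rng.choice(fits.size, p=weights / weights.sum())])
            start = int(seg_start[si] + rng.integers(0, seg_len[si] - piece + 1))
            end = start + piece
            clash = any(start < e and s < end for s, e in taken.get(si, []))
            if not clash:
                taken.setdefault(si, []).append((start, end))
                placed.append((seg_chrom[si], start, end))
                ok = True
                break
        if not ok:
            raise RuntimeError("could not place non-overlapping control pieces")
    return pd.DataFrame(placed, columns=["chrom", "start", "end"])


@dataclass
class GwasEnrichmentResult:
    """Unique-SNP-per-bp frequencies and the control/interacting ratio."""

    freq_interacting: float
    freq_control: float
    freq_background: float
    ratio: float
    control_regions: pd.DataFrame


def gwas_enrichment(
    iset: InteractionSet, snps: pd.DataFrame, genome: Genome, seed: int = 0
) -> GwasEnrichmentResult:
    """SNP density in the interacting genome vs matched control vs background.

    The interacting genome is the union of all anchors; the control is a
    seeded random interval set of equal total length and piece-length
    distribution drawn entirely outside that union; the background is
    all unique SNPs over the genome length.  ``ratio`` is
    freq_control / freq_interacting (> 1 indicates SNP depletion inside
    interacting regions).
    """
    union = _anchor_union(iset)
    control = _sample_control_regions(union, genome, seed)
    f_int = snp_frequency(union, snps)
    f_ctrl = snp_frequency(control, snps)
    f_bg = len(snps.drop_duplicates(["chrom", "pos"])) / genome.total_length
    ratio = f_ctrl / f_int if f_int > 0 else float("inf")
    return GwasEnrichmentResult(
        freq_interacting=f_int,
        freq_control=f_ctrl,
        freq_background=f_bg,
        ratio=ratio,
        control_regions=control,
    )


# ---------------------------------------------------------------------------
# motif-region export
# ---------------------------------------------------------------------------


def export_motif_regions(
    iset: InteractionSet,
    genes: pd.DataFrame,
    genome_fasta,
    out_fasta,
    width: int = 1000,
) -> pd.DataFrame:
    """Write non-redundant width-bp windows around gene-linked anchors.

    For every interaction with at least one anchor overlapping a
    protein-coding gene, each qualifying anchor contributes the
    ``width``-bp window centered on its midpoint, clipped to chromosome
    bounds; identical windows are emitted once.  Returns the region
    table that was written.
    """
    from pyfaidx import Fasta

    coding = genes[genes.get("biotype", "protein_coding") == "protein_coding"]
    merged = merge_intervals(coding[["chrom", "start", "end"]]) if len(coding) else None
    fa = Fasta(str(genome_fasta))
    regions = []
    for rec in iset.df.itertuples(index=False):
        for side in ((rec.chrom1, rec.start1, rec.end1), (rec.chrom2, rec.start2, rec.end2)):
            chrom, s, e = side
            if merged is None:
                continue
            grp = merged[merged["chrom"] == chrom]
            if grp.empty:
                continue
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
            lo = np.searchsorted(ends, s, side="right")
            hi = np.searchsorted(starts, e, side="left")
            if hi <= lo:
                continue
            mid = (s + e) // 2
            chrom_len = len(fa[chrom])
            w_start = max(0, mid - width // 2)
            w_end = min(chrom_len, w_start + width)
            w_start = max(0, w_end - width)
            regions.append((chrom, int(w_start), int(w_end)))
    uniq = pd.DataFrame(sorted(set(regions)), columns=["chrom", "start", "end"])
    with open(out_fasta, "w") as fh:
        for r in uniq.itertuples(index=False):
            seq = fa[r.chrom][r.start : r.end].seq
            fh.write(f">{r.chrom}:{r.start}-{r.end}\n{seq}\n")
    return uniq
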