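"""Cross-condition interaction dynamics and their relation to expression.

Interactions from two or more conditions are matched by anchor overlap
(>= 1 bp on both anchors, orientation-free), yielding pairwise-shared,
k-way-common and per-condition-exclusive counts.  Expression of
interacting genes is compared against equal-sized seeded random samples
of non-interacting genes with a two-sided rank-sum test, and classified
into up / down / unchanged by log2 fold-change on pseudocounted FPKM.
At coarse resolution, interactions are collapsed to fixed-width blocks
and per-block cumulative gene expression is compared between common and
condition-unique blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Genome, genome_bins, merge_intervals
from .io_formats import InteractionSet

log = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "ExpressionComparison",
    "interactions_match",
    "overlap_counts",
    "log2fc",
    "classify_expression",
    "compare_groups",
    "sample_control_genes",
    "interacting_genes",
    "block_expression",
]


# ---------------------------------------------------------------------------
# interaction matching
# ---------------------------------------------------------------------------


def _anchor_overlaps(s1, e1, s2, e2, min_frac: float = 0.0) -> np.ndarray:
    ov = np.minimum(e1, e2) - np.maximum(s1, s2)
    if min_frac <= 0.0:
        return ov > 0
    need = min_frac * np.minimum(e1 - s1, e2 - s2)
    return ov >= np.maximum(need, 1)


def interactions_match(a, b, min_overlap_frac: float = 0.0) -> bool:
    """True iff the two records' anchors overlap pairwise in either
    orientation (>= 1 bp per anchor, same chromosome)."""
    def ov(c1, s1, e1, c2, s2, e2):
        return c1 == c2 and bool(
            _anchor_overlaps(np.int64(s1), np.int64(e1), np.int64(s2), np.int64(e2), min_overlap_frac)
        )

    direct = ov(a["chrom1"], a["start1"], a["end1"], b["chrom1"], b["start1"], b["end1"]) and ov(
        a["chrom2"], a["start2"], a["end2"], b["chrom2"], b["start2"], b["end2"]
    )
    swapped = ov(a["chrom1"], a["start1"], a["end1"], b["chrom2"], b["start2"], b["end2"]) and ov(
        a["chrom2"], a["start2"], a["end2"], b["chrom1"], b["start1"], b["end1"]
    )
    return direct or swapped


def _grouped(df: pd.DataFrame) -> dict:
    """Records grouped by unordered chromosome pair for fast matching."""
    groups = {}
    for key, grp in df.groupby(["chrom1", "chrom2"], sort=False):
        groups[key] = {
            "s1": grp["start1"].to_numpy(np.int64),
            "e1": grp["end1"].to_numpy(np.int64),
            "s2": grp["start2"].to_numpy(np.int64),
            "e2": grp["end2"].to_numpy(np.int64),
        }
    return groups


def _match_any(df_ref: pd.DataFrame, other_groups: dict, min_frac: float) -> np.ndarray:
    """Per reference record: does any record of the other set match it?"""
    out = np.zeros(len(df_ref), dtype=bool)
    for idx, rec in enumerate(df_ref.itertuples(index=False)):
        grp = other_groups.get((rec.chrom1, rec.chrom2))
        if grp is not None:
            hit = _anchor_overlaps(rec.start1, rec.end1, grp["s1"], grp["e1"], min_frac) & _anchor_overlaps(
                rec.start2, rec.end2, grp["s2"], grp["e2"], min_frac
            )
            if hit.any():
                out[idx] = True
                continue
        if rec.chrom1 == rec.chrom2:
            grp = other_groups.get((rec.chrom1, rec.chrom2))
            if grp is not None:
                hit = _anchor_overlaps(rec.start1, rec.end1, grp["s2"], grp["e2"], min_frac) & _anchor_overlaps(
                    rec.start2, rec.end2, grp["s1"], grp["e1"], min_frac
                )
                out[idx] |= bool(hit.any())
        else:
            grp = other_groups.get((rec.chrom2, rec.chrom1))
            if grp is not None:
                hit = _anchor_overlaps(rec.start1, rec.end1, grp["s2"], grp["e2"], min_frac) & _anchor_overlaps(
                    rec.start2, rec.end2, grp["s1"], grp["e1"], min_frac
                )
                out[idx] |= bool(hit.any())
    return out


@dataclass
class OverlapResult:
    """Overlap bookkeeping from the viewpoint of one reference condition.

    ``pairwise_shared[c]`` counts reference records matching >= 1 record
    of condition c; ``common`` counts reference records matching in
    every other condition; ``exclusive[c]`` counts records of condition
    c (as its own reference) matching no other condition.  ``matched``
    maps each reference record to its per-condition match flag.
    """

    reference: str
    totals: dict
    pairwise_shared: dict
    common: int
    exclusive: dict
    matched: pd.DataFrame

    def __post_init__(self):
        ref_total = self.totals[self.reference]
        matched_any = int(self.matched.any(axis=1).sum()) if len(self.matched) else 0
        assert self.exclusive[self.reference] + matched_any == ref_total


def overlap_counts(
    sets: list[InteractionSet],
    reference: str,
    min_overlap_frac: float = 0.0,
) -> OverlapResult:
    """Shared / common / exclusive interaction counts across conditions."""
    if len(sets) < 2:
        raise ValueError("need at least two interaction sets")
    by_name = {s.condition: s for s in sets}
    if reference not in by_name:
        raise ValueError(f"reference {reference!r} not among sets")
    groups = {name: _grouped(s.df) for name, s in by_name.items()}
    ref = by_name[reference]
    others = [n for n in by_name if n != reference]
    matched = pd.DataFrame(
        {n: _match_any(ref.df, groups[n], min_overlap_frac) for n in others},
        index=ref.df.index,
    )
    pairwise = {n: int(matched[n].sum()) for n in others}
    common = int(matched.all(axis=1).sum()) if others else 0
    exclusive = {}
    for name, s in by_name.items():
        flags = [
            _match_any(s.df, groups[m], min_overlap_frac) for m in by_name if m != name
        ]
        any_match = np.logical_or.reduce(flags) if flags else np.zeros(len(s.df), dtype=bool)
        exclusive[name] = int((~any_match).sum())
    return OverlapResult(
        reference=reference,
        totals={n: len(s) for n, s in by_name.items()},
        pairwise_shared=pairwise,
        common=common,
        exclusive=exclusive,
        matched=matched,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def log2fc(fpkm_treated, fpkm_control, pseudocount: float = 1.0):
    """log2((treated + pseudocount) / (control + pseudocount))."""
    t = np.asarray(fpkm_treated, dtype=float)
    c = np.asarray(fpkm_control, dtype=float)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if np.any(t < 0) or np.any(c < 0):
        raise ValueError("FPKM must be non-negative")
    out = np.log2((t + pseudocount) / (c + pseudocount))
    return float(out) if out.ndim == 0 else out


@dataclass
class ExpressionComparison:
    """Fold-change classification of a gene group."""

    per_gene: pd.DataFrame  # gene_id, log2fc, class
    tallies: dict
    percentages: dict
    missing: list = field(default_factory=list)


def classify_expression(
    genes: list[str],
    control: pd.DataFrame,
    treated: pd.DataFrame,
    lfc_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> ExpressionComparison:
    """Classify genes as up / down / unchanged by log2 fold-change.

    up if log2FC >= threshold, down if <= -threshold, else unchanged.
    Genes absent from either table are reported and excluded.
    """
    ctrl = control.set_index("gene_id")["fpkm"]
    trt = treated.set_index("gene_id")["fpkm"]
    present = [g for g in genes if g in ctrl.index and g in trt.index]
    missing = [g for g in genes if g not in present]
    if missing:
        log.warning("%d genes missing from expression tables; excluded", len(missing))
    lfc = log2fc(trt.loc[present].to_numpy(), ctrl.loc[present].to_numpy(), pseudocount)
    lfc = np.atleast_1d(lfc)
    cls = np.where(lfc >= lfc_threshold, "up", np.where(lfc <= -lfc_threshold, "down", "unchanged"))
    per_gene = pd.DataFrame({"gene_id": present, "log2fc": lfc, "class": cls})
    tallies = {k: int((cls == k).sum()) for k in ("up", "down", "unchanged")}
    n = max(len(present), 1)
    pct = {k: round(100.0 * v / n, 1) for k, v in tallies.items()}
    return ExpressionComparison(per_gene=per_gene, tallies=tallies, percentages=pct, missing=missing)


def compare_groups(expr_a, expr_b) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney U) comparison of two expression
    distributions.  Groups smaller than 3 yield (nan, nan) with a warning."""
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size < 3 or b.size < 3:
        log.warning("group size < 3: rank-sum p-value undefined")
        return (float("nan"), float("nan"))
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return (float(res.statistic), float(res.pvalue))


def sample_control_genes(all_genes: list[str], interacting: set, n: int, seed: int) -> list[str]:
    """Seeded equal-size sample of non-interacting genes."""
    pool = sorted(g for g in all_genes if g not in interacting)
    if n > len(pool):
        raise ValueError("not enough non-interacting genes for a control sample")
    rng = np.random.default_rng(seed)
    return list(rng.choice(pool, size=n, replace=False))


def interacting_genes(iset: InteractionSet, genes: pd.DataFrame) -> list[str]:
    """Genes whose body overlaps (>= 1 bp) any anchor of the set."""
    hits: set[str] = set()
    for side in ("1", "2"):
        anchors = iset.df[[f"chrom{side}", f"start{side}", f"end{side}"]]
        anchors = anchors.set_axis(["chrom", "start", "end"], axis=1)
        for chrom, grp in anchors.groupby("chrom"):
            g = genes[genes["chrom"] == chrom]
            if g.empty:
                continue
            gs = g["start"].to_numpy()
            ge = g["end"].to_numpy()
            for s, e in zip(grp["start"], grp["end"]):
                m = (gs < e) & (ge > s)
                if m.any():
                    hits.update(g["gene_id"].to_numpy()[m])
    return sorted(hits)


# ---------------------------------------------------------------------------
# coarse blocks
# ---------------------------------------------------------------------------


def _blocks_of(iset: InteractionSet, genome: Genome, block_size: int) -> set:
    bins = genome_bins(genome, block_size)
    blocks: set[int] = set()
    for side in ("1", "2"):
        chrom = iset.df[f"chrom{side}"].to_numpy()
        start = iset.df[f"start{side}"].to_numpy(np.int64)
        end = iset.df[f"end{side}"].to_numpy(np.int64)
        first = bins.locate(chrom, start)
        last = bins.locate(chrom, np.maximum(start, end - 1))
        for a, b in zip(first, last):
            blocks.update(range(int(a), int(b) + 1))
    return blocks


def block_expression(
    sets: list[InteractionSet],
    genes: pd.DataFrame,
    tables: dict,
    genome: Genome,
    block_size: int = 200_000,
) -> pd.DataFrame:
    """Cumulative per-block gene expression for common and unique blocks.

    Interactions are collapsed to ``block_size`` tiles touched by any
    anchor; tiles touched in every condition are 'common', tiles touched
    in exactly one are 'unique_<condition>'.  Each block row carries the
    summed FPKM of its member genes per condition table; blocks without
    genes are excluded (logged).
    """
    if len(sets) < 2:
        raise ValueError("need at least two conditions")
    bins = genome_bins(genome, block_size)
    table = bins.table()
    per_cond = {s.condition: _blocks_of(s, genome, block_size) for s in sets}
    all_blocks = sorted(set().union(*per_cond.values()))
    fpkm_by_cond = {c: t.set_index("gene_id")["fpkm"] for c, t in tables.items()}
    rows = []
    n_empty = 0
    for blk in all_blocks:
        info = table.iloc[blk]
        in_conds = [c for c, s in per_cond.items() if blk in s]
        if len(in_conds) == len(sets):
            group = "common"
        elif len(in_conds) == 1:
            group = f"unique_{in_conds[0]}"
        else:
            group = "partial"
        g = genes[
            (genes["chrom"] == info["chrom"])
            & (genes["start"] < info["end"])
            & (genes["end"] > info["start"])
        ]
        if g.empty:
            n_empty += 1
            continue
        row = {"chrom": info["chrom"], "start": int(info["start"]), "end": int(info["end"]), "group": group}
        for cond, fpkm in fpkm_by_cond.items():
            member = fpkm.reindex(g["gene_id"]).dropna()
            row[f"cum_fpkm_{cond}"] = float(member.sum())
        rows.append(row)
    if n_empty:
        log.info("%d blocks without genes excluded", n_empty)
    return pd.DataFrame(rows)
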