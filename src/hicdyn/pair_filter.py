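"""Removal of uninformative Hi-C read pairs.

A Hi-C library contains, besides true proximity-ligation products,
pairs that carry no 3D information: self-ligation/dangling ends (both
mates in one restriction fragment), re-ligation products (mates in
adjacent fragments), un-digested continuous genomic fragments
(same-chromosome inward-facing pairs closer than the size-selection
window) and pairs whose reads do not face a restriction site within the
estimated insert length.  Each pair is removed under exactly the first
matching category, so the QC report is a partition of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import FragmentMap

__all__ = ["QCReport", "assign_fragment", "filter_pairs", "removal_categories"]

DEFAULT_INSERT_WINDOW = 500  # bp; typical Hi-C size-selection scale

_CATEGORY_NAMES = np.array(
    [
        "retained",
        "removed_duplicate",
        "removed_same_fragment",
        "removed_religation",
        "removed_continuous",
        "removed_no_site",
    ]
)


@dataclass(frozen=True)
class QCReport:
    """Partition of the input pairs by removal category."""

    input_pairs: int
    removed_duplicate: int
    removed_same_fragment: int
    removed_religation: int
    removed_continuous: int
    removed_no_site: int
    retained: int

    def __post_init__(self):
        total = (
            self.removed_duplicate
            + self.removed_same_fragment
            + self.removed_religation
            + self.removed_continuous
            + self.removed_no_site
            + self.retained
        )
        if total != self.input_pairs:
            raise ValueError("QC counts must partition the input")

    def to_dict(self) -> dict:
        return {
            "input_pairs": self.input_pairs,
            "removed_duplicate": self.removed_duplicate,
            "removed_same_fragment": self.removed_same_fragment,
            "removed_religation": self.removed_religation,
            "removed_continuous": self.removed_continuous,
            "removed_no_site": self.removed_no_site,
            "retained": self.retained,
        }


def assign_fragment(chrom: str, pos: int, fragmap: FragmentMap) -> int:
    """Index of the half-open restriction fragment containing ``pos``.

    A position sitting exactly on a site belongs to the downstream
    fragment.  Binary search over the site array.
    """
    length = fragmap.genome.lengths.get(chrom)
    if length is None:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if not 0 <= pos < length:
        raise ValueError(f"position {pos} outside {chrom} (length {length})")
    return int(np.searchsorted(fragmap.sites[chrom], pos, side="right"))


def _fragments_vec(chrom, pos, fragmap: FragmentMap) -> np.ndarray:
    out = np.empty(len(pos), dtype=np.int64)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    for name, length in fragmap.genome.chromosomes:
        m = chrom == name
        if not m.any():
            continue
        p = pos[m]
        if p.min() < 0 or p.max() >= length:
            raise ValueError(f"position outside chromosome {name}")
        out[m] = np.searchsorted(fragmap.sites[name], p, side="right")
    return out


def _has_downstream_site(chrom, pos, strand, fragmap: FragmentMap, window: int) -> np.ndarray:
    """True where a restriction site lies within ``window`` bp downstream of
    the read (in strand direction, inclusive of both ends)."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    plus = np.asarray(strand) == "+"
    lo = np.where(plus, pos, pos - window)
    hi = np.where(plus, pos + window, pos)
    out = np.zeros(len(pos), dtype=bool)
    for name, _ in fragmap.genome.chromosomes:
        m = chrom == name
        if not m.any():
            continue
        sites = fragmap.sites[name]
        left = np.searchsorted(sites, lo[m], side="left")
        right = np.searchsorted(sites, hi[m], side="right")
        out[m] = right > left
    return out


def _categorize(pairs: pd.DataFrame, fragmap, insert_window: int, remove_duplicates: bool) -> np.ndarray:
    df = pairs.reset_index(drop=True)
    n = len(df)
    dup = np.zeros(n, dtype=bool)
    if remove_duplicates:
        dup = df.duplicated(
            subset=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"], keep="first"
        ).to_numpy()
    f1 = _fragments_vec(df["chrom1"], df["pos1"], fragmap)
    f2 = _fragments_vec(df["chrom2"], df["pos2"], fragmap)
    same_chrom = (df["chrom1"] == df["chrom2"]).to_numpy()
    same_frag = same_chrom & (f1 == f2)
    religation = same_chrom & (np.abs(f1 - f2) == 1)

    pos1 = df["pos1"].to_numpy(dtype=np.int64)
    pos2 = df["pos2"].to_numpy(dtype=np.int64)
    s1 = df["strand1"].to_numpy()
    s2 = df["strand2"].to_numpy()
    left_strand = np.where(pos1 <= pos2, s1, s2)
    right_strand = np.where(pos1 <= pos2, s2, s1)
    inward = (left_strand == "+") & (right_strand == "-")
    continuous = same_chrom & inward & (np.abs(pos2 - pos1) < insert_window)

    no_site = ~(
        _has_downstream_site(df["chrom1"], pos1, s1, fragmap, insert_window)
        | _has_downstream_site(df["chrom2"], pos2, s2, fragmap, insert_window)
    )

    cat = np.zeros(n, dtype=np.int8)
    cat[dup] = 1
    remaining = ~dup
    for code, mask in ((2, same_frag), (3, religation), (4, continuous), (5, no_site)):
        take = remaining & mask
        cat[take] = code
        remaining &= ~mask
    return cat


def filter_pairs(
    pairs: pd.DataFrame,
    fragmap: FragmentMap,
    insert_window: int = DEFAULT_INSERT_WINDOW,
    remove_duplicates: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Remove uninformative pairs; returns (retained pairs, QC report).

    Removal precedence (each pair counted once, first match wins):
    PCR duplicates (identical coordinates+strands, on by default), then
    same-fragment pairs, adjacent-fragment pairs, same-chromosome
    inward-facing pairs closer than ``insert_window``, and finally pairs
    where *neither* mate has a restriction site within ``insert_window``
    downstream of its 3' end.  Filtering is idempotent and
    order-invariant on the retained multiset.
    """
    if insert_window <= 0:
        raise ValueError("insert_window must be positive")
    n_input = len(pairs)
    if n_input == 0:
        return pairs.copy(), QCReport(0, 0, 0, 0, 0, 0, 0)
    cat = _categorize(pairs, fragmap, insert_window, remove_duplicates)
    retained = pairs.reset_index(drop=True)[cat == 0].reset_index(drop=True)
    report = QCReport(
        input_pairs=n_input,
        removed_duplicate=int((cat == 1).sum()),
        removed_same_fragment=int((cat == 2).sum()),
        removed_religation=int((cat == 3).sum()),
        removed_continuous=int((cat == 4).sum()),
        removed_no_site=int((cat == 5).sum()),
        retained=int((cat == 0).sum()),
    )
    return retained, report


def removal_categories(
    pairs: pd.DataFrame,
    fragmap: FragmentMap,
    insert_window: int = DEFAULT_INSERT_WINDOW,
    remove_duplicates: bool = True,
) -> np.ndarray:
    """Per-pair category name ('retained' or 'removed_*'), aligned with the
    input row order; used by recovery tests against generator truth labels."""
    if len(pairs) == 0:
        return np.array([], dtype="U32")
    return _CATEGORY_NAMES[_categorize(pairs, fragmap, insert_window, remove_duplicates)]


#: QC category expected for each generator truth label
CATEGORY_OF_TRUTH = {
    "self_ligation": "removed_same_fragment",
    "re_ligation": "removed_religation",
    "informative": "retained",
}
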