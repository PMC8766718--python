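"""Genome coordinate primitives shared across the pipeline.

All coordinates are 0-based, half-open.  A :class:`Genome` is an ordered
set of named chromosomes; a :class:`FragmentMap` stores the internal
restriction-site positions per chromosome (fragments are the half-open
intervals between consecutive sites, tiling each chromosome exactly);
:class:`GenomeBins` is a genome-wide fixed-width tiling used by the
contact-matrix and interaction-calling stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "FragmentMap",
    "GenomeBins",
    "genome_bins",
    "merge_intervals",
    "intervals_length",
    "complement_intervals",
]


@dataclass(frozen=True)
class Genome:
    """Ordered list of (name, length-in-bp) chromosomes."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


@dataclass(frozen=True)
class FragmentMap:
    """Internal restriction-site positions per chromosome.

    ``sites[chrom]`` is a strictly increasing int array with
    ``0 < site < chromosome length``; the implied fragments are
    ``[0, s1), [s1, s2), ..., [sk, L)``.
    """

    genome: Genome
    sites: dict[str, np.ndarray]

    def __post_init__(self):
        for chrom, length in self.genome.chromosomes:
            s = np.asarray(self.sites[chrom])
            if s.size and (np.any(np.diff(s) <= 0) or s[0] <= 0 or s[-1] >= length):
                raise ValueError(f"sites on {chrom} must be strictly increasing within (0, length)")

    def n_fragments(self, chrom: str) -> int:
        return len(self.sites[chrom]) + 1

    def fragment_boundaries(self, chrom: str) -> np.ndarray:
        """[0, s1, ..., sk, L] — fragments tile the chromosome exactly."""
        return np.concatenate(([0], self.sites[chrom], [self.genome.lengths[chrom]]))


@dataclass(frozen=True)
class GenomeBins:
    """Genome-wide fixed-width binning with a global bin index."""

    genome: Genome
    bin_size: int
    offsets: dict[str, int] = field(default_factory=dict)  # first global bin per chrom
    n_bins_per_chrom: dict[str, int] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_per_chrom.values())

    def chrom_of(self) -> np.ndarray:
        """Integer chromosome code per global bin (order of genome.names)."""
        codes = np.empty(self.n_bins, dtype=np.int32)
        for i, name in enumerate(self.genome.names):
            o = self.offsets[name]
            codes[o : o + self.n_bins_per_chrom[name]] = i
        return codes

    def locate(self, chrom: np.ndarray | pd.Series, pos: np.ndarray | pd.Series) -> np.ndarray:
        """Global bin index per (chrom, pos); raises if a position is outside the genome."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.empty(len(pos), dtype=np.int64)
        for name, length in self.genome.chromosomes:
            m = chrom == name
            if not m.any():
                continue
            p = pos[m]
            if p.min() < 0 or p.max() >= length:
                raise ValueError(f"position outside chromosome {name}")
            out[m] = self.offsets[name] + p // self.bin_size
        known = np.isin(chrom, self.genome.names)
        if not known.all():
            bad = sorted(set(chrom[~known]))
            raise ValueError(f"unknown chromosome(s): {bad}")
        return out

    def table(self) -> pd.DataFrame:
        """chrom/start/end per global bin, in global-index order."""
        rows = []
        for name, length in self.genome.chromosomes:
            starts = np.arange(0, length, self.bin_size, dtype=np.int64)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def labels(self) -> list[str]:
        t = self.table()
        return [f"{c}:{s}-{e}" for c, s, e in zip(t["chrom"], t["start"], t["end"])]


def genome_bins(genome: Genome, bin_size: int) -> GenomeBins:
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    offsets, counts, off = {}, {}, 0
    for name, length in genome.chromosomes:
        n = -(-length // bin_size)
        offsets[name] = off
        counts[name] = n
        off += n
    return GenomeBins(genome=genome, bin_size=bin_size, offsets=offsets, n_bins_per_chrom=counts)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals (columns chrom/start/end)."""
    if len(df) == 0:
        return df.iloc[:0][["chrom", "start", "end"]].copy()
    out = []
    for chrom, grp in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def intervals_length(df: pd.DataFrame) -> int:
    """Total bp covered by the union of the intervals."""
    m = merge_intervals(df)
    return int((m["end"] - m["start"]).sum())


def complement_intervals(df: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Genome minus the union of the intervals."""
    merged = merge_intervals(df)
    out = []
    for chrom, length in genome.chromosomes:
        prev = 0
        grp = merged[merged["chrom"] == chrom]
        for s, e in zip(grp["start"], grp["end"]):
            if s > prev:
                out.append((chrom, prev, s))
            prev = max(prev, e)
        if prev < length:
            out.append((chrom, prev, length))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])
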