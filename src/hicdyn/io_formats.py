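"""Readers and writers for every external format the pipeline touches.

Internal coordinates are uniformly 0-based half-open: BED is native,
GFF3 (1-based inclusive) is converted on read/write.  Strand is parsed
and preserved but ignored by all downstream statistics.  All writers
are deterministic and all reader/writer pairs are mutual inverses on
valid files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "PairFormatError",
    "InteractionSet",
    "read_pairs",
    "write_pairs",
    "read_bed",
    "write_bed",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_fpkm",
    "write_fpkm",
    "read_bedpe",
    "write_bedpe",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_truth_json",
]

PAIR_COLUMNS = ["name", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]

INTERACTION_COLUMNS = [
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "observed",
    "expected",
    "p_value",
    "class",
]


class PairFormatError(ValueError):
    """Malformed pair file; the message names the offending line."""


@dataclass
class InteractionSet:
    """Called interactions for one condition.

    ``df`` columns: chrom1/start1/end1/chrom2/start2/end2, observed,
    expected, p_value, class ('cis'/'trans'); anchors are stored ordered
    by (chrom, start); unordered anchor pairs are unique.  ``n_tested``
    is the number of candidate locus pairs the caller examined (used for
    empirical type-I rates).
    """

    condition: str
    df: pd.DataFrame
    config: object | None = None
    n_tested: int | None = None

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# read pairs (7-column TSV)
# ---------------------------------------------------------------------------


def read_pairs(path) -> pd.DataFrame:
    """Read a 7-column tab-separated pair file.

    Columns: readname, chrom1, pos1, strand1, chrom2, pos2, strand2.
    Malformed lines raise :class:`PairFormatError` naming the 1-based
    line number.  An empty file yields an empty frame.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=PAIR_COLUMNS, dtype=str, comment="#"
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=PAIR_COLUMNS).astype({"pos1": np.int64, "pos2": np.int64})
    except pd.errors.ParserError as err:
        raise PairFormatError(f"{path}: {err}") from err
    bad = df.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise PairFormatError(f"{path}: line {line}: expected 7 tab-separated columns")
    for col in ("strand1", "strand2"):
        ok = df[col].isin(["+", "-"])
        if not ok.all():
            line = int(np.flatnonzero(~ok.to_numpy())[0]) + 1
            raise PairFormatError(f"{path}: line {line}: bad strand symbol {df[col].iloc[line - 1]!r}")
    for col in ("pos1", "pos2"):
        try:
            df[col] = df[col].astype(np.int64)
        except ValueError as err:
            raise PairFormatError(f"{path}: non-integer value in column {col}") from err
        neg = df[col] < 0
        if neg.any():
            line = int(np.flatnonzero(neg.to_numpy())[0]) + 1
            raise PairFormatError(f"{path}: line {line}: negative position")
    return df


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Write the 7 public pair columns as TSV (hidden columns dropped)."""
    pairs[PAIR_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED / GFF3 / FPKM
# ---------------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """BED3+ intervals; column 4, when present, becomes ``label``.

    Input need not be sorted; output is sorted by (chrom, start).
    Overlapping intervals are allowed.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", names=range(12))
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = df.dropna(axis=1, how="all")
    ncol = df.shape[1]
    if ncol < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    cols = ["chrom", "start", "end"] + (["label"] if ncol >= 4 else [])
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: invalid BED interval (need 0 <= start < end)")
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + [c for c in ("label", "state") if c in df.columns][:1]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gff3_genes(path, feature_types: tuple[str, ...] = ("gene",)) -> pd.DataFrame:
    """Gene records from GFF3, converted to 0-based half-open intervals.

    Returns chrom/start/end/strand/gene_id/biotype (biotype from the
    ``biotype`` or ``gene_biotype`` attribute, defaulting to
    'protein_coding' when absent, as in minimal gene-model files).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in feature_types:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            gene_id = attr.get("ID", attr.get("gene_id", f"{chrom}:{start}-{end}"))
            rows.append(
                (
                    chrom,
                    int(start) - 1,  # GFF3 is 1-based inclusive
                    int(end),
                    strand,
                    gene_id.removeprefix("gene:"),
                    attr.get("biotype", attr.get("gene_biotype", "protein_coding")),
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "gene_id", "biotype"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)


def write_gff3_genes(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples(index=False):
            attrs = f"ID={r.gene_id};biotype={getattr(r, 'biotype', 'protein_coding')}"
            fh.write(
                f"{r.chrom}\thicdyn\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


def read_fpkm(path) -> pd.DataFrame:
    """TSV with a header line: gene_id, fpkm."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "fpkm"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_id and fpkm")
    if (df["fpkm"] < 0).any():
        raise ValueError(f"{path}: negative FPKM")
    return df[["gene_id", "fpkm"]]


def write_fpkm(table: pd.DataFrame, path) -> None:
    table[["gene_id", "fpkm"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BEDPE interactions
# ---------------------------------------------------------------------------

_BEDPE_COLS = [
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "name",
    "score",
    "strand1",
    "strand2",
    "observed",
    "expected",
    "p_value",
    "class",
]


def order_anchors(df: pd.DataFrame, warn: bool = False) -> pd.DataFrame:
    """Normalize so that (chrom1, start1) <= (chrom2, start2)."""
    keyA = list(zip(df["chrom1"], df["start1"]))
    keyB = list(zip(df["chrom2"], df["start2"]))
    swap = np.array([a > b for a, b in zip(keyA, keyB)])
    if swap.any():
        if warn:
            log.warning("%d BEDPE records had unordered anchors; normalized", int(swap.sum()))
        df = df.copy()
        for a, b in (("chrom1", "chrom2"), ("start1", "start2"), ("end1", "end2")):
            df.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()
    return df


def write_bedpe(iset: InteractionSet, path) -> None:
    """BEDPE with score = -log10(p) and observed/expected/p/class extras."""
    df = iset.df.copy()
    with np.errstate(divide="ignore"):
        score = -np.log10(df["p_value"].to_numpy(dtype=float))
    df["score"] = np.where(np.isfinite(score), np.round(score, 6), 300.0)
    df["name"] = [f"{iset.condition}_{i}" for i in range(len(df))]
    df["strand1"] = "."
    df["strand2"] = "."
    df[_BEDPE_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path, condition: str | None = None) -> InteractionSet:
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_BEDPE_COLS)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_BEDPE_COLS)
    cond = condition
    if cond is None:
        cond = str(df["name"].iloc[0]).rsplit("_", 1)[0] if len(df) else "unknown"
    df = order_anchors(df, warn=True)
    out = df[INTERACTION_COLUMNS].copy()
    for c in ("start1", "end1", "start2", "end2", "observed"):
        out[c] = out[c].astype(np.int64)
    return InteractionSet(condition=cond, df=out.reset_index(drop=True))


# ---------------------------------------------------------------------------
# matrix TSV
# ---------------------------------------------------------------------------


def write_matrix_tsv(matrix: np.ndarray, labels: list[str], path) -> None:
    """Square symmetric matrix with bin-coordinate headers; masked (NaN)
    entries serialized as NA; values kept to 6 significant digits."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(labels):
        raise ValueError("matrix must be square and match the label list")
    pd.DataFrame(m, index=labels, columns=labels).to_csv(
        path, sep="\t", na_rep="NA", float_format="%.6g"
    )


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise ValueError(f"{path}: not a square labelled matrix")
    m = df.to_numpy(dtype=float)
    both_nan = np.isnan(m) & np.isnan(m.T)
    if not np.allclose(np.where(both_nan, 0.0, m), np.where(both_nan, 0.0, m.T), rtol=1e-5, equal_nan=True):
        raise ValueError(f"{path}: matrix is not symmetric")
    return m, list(df.index)


def write_truth_json(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
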