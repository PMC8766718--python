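"""Synthetic Hi-C study generator with known ground truth.

Generates every input the pipeline consumes — a multi-chromosome genome
with restriction sites, aligned read pairs drawn from a power-law
distance-decay contact model with multiplicative per-bin biases and
planted enriched locus pairs, self-/re-ligation contaminants, an
epigenetic-state track, GWAS-like SNPs with planted depletion, gene
models and lognormal FPKM tables with a treated-effect subset — so that
filtering, normalization, interaction calling, condition comparison and
annotation statistics can all be tested against a :class:`TruthSet`.

The contact model: an informative read pair falls in the unordered bin
pair (i, j) with probability proportional to

    bias_i * bias_j * kernel(d_ij)

where ``kernel(d) = max(d, distance_floor)**-decay_exponent`` for cis
pairs (d = linear bin separation in bp) and a constant trans floor
otherwise; planted pairs multiply this weight by their enrichment fold.
Mates are placed adjacent to a restriction site on the strand facing it,
mimicking real Hi-C ligation-junction geometry, so that informative
pairs survive the 3'-end restriction-site QC rule while labelled
contaminants (same-fragment and adjacent-fragment mates) do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import Genome, FragmentMap, GenomeBins, genome_bins, merge_intervals

__all__ = [
    "TruthSet",
    "make_genome",
    "make_truth",
    "simulate_pairs",
    "make_es_track",
    "make_snps",
    "make_genes",
    "make_expression",
    "write_genome_fasta",
    "simulate_study",
]

#: read 5' positions are offset 1..MAX_READ_OFFSET bp from their restriction
#: site, on the strand facing it; kept below the default 500 bp QC window.
MAX_READ_OFFSET = 400

PAIR_COLUMNS = ["name", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


@dataclass
class TruthSet:
    """Ground truth of a simulated study.

    planted_pairs are (global binA, global binB, enrichment fold > 1) at
    ``bin_size`` resolution; bin_biases are per-global-bin multiplicative
    factors (> 0); depleted_regions carry SNP density reduced by
    ``depletion_factor`` (in (0, 1]); effect_genes are (gene_id, true
    log2 fold-change) pairs for the expression tables.
    """

    bin_size: int
    decay_exponent: float
    bin_biases: np.ndarray
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    depleted_regions: pd.DataFrame | None = None
    depletion_factor: float = 1.0
    effect_genes: list[tuple[str, float]] = field(default_factory=list)
    distance_floor: int = 1000
    trans_floor_frac: float = 0.05
    trans_ref_distance: int = 100_000

    def __post_init__(self):
        if np.any(np.asarray(self.bin_biases) <= 0):
            raise ValueError("bin biases must be positive")
        if any(fold <= 1 for _, _, fold in self.planted_pairs):
            raise ValueError("planted enrichment fold must exceed 1")
        if not 0 < self.depletion_factor <= 1:
            raise ValueError("depletion_factor must be in (0, 1]")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["bin_biases"] = np.asarray(self.bin_biases).tolist()
        d["planted_pairs"] = [list(p) for p in self.planted_pairs]
        if self.depleted_regions is not None:
            d["depleted_regions"] = self.depleted_regions.to_dict(orient="records")
        d["effect_genes"] = [list(g) for g in self.effect_genes]
        return d


def make_genome(
    n_chrom: int,
    chrom_length: int,
    site_spacing_mean: float,
    seed: int,
) -> tuple[Genome, FragmentMap]:
    """Toy genome with exponential restriction-site spacing.

    Emulates a reference genome digested by a 6-cutter (HindIII-like
    mean spacing ~4 kb); deterministic for a fixed seed.
    """
    if n_chrom < 1 or chrom_length <= 0 or site_spacing_mean <= 0:
        raise ValueError("n_chrom, chrom_length and site_spacing_mean must be positive")
    if site_spacing_mean >= chrom_length * 10:
        # guard against degenerate requests; a spacing above the chromosome
        # length is allowed (it yields fragment == chromosome)
        pass
    rng = np.random.default_rng(seed)
    chroms = tuple((f"chr{i + 1}", int(chrom_length)) for i in range(n_chrom))
    genome = Genome(chromosomes=chroms)
    sites = {}
    for name, length in chroms:
        n_draw = max(8, int(3 * length / site_spacing_mean))
        gaps = rng.exponential(site_spacing_mean, size=n_draw)
        pos = np.unique(np.cumsum(gaps).astype(np.int64))
        while pos.size == 0 or pos[-1] < length:
            more = rng.exponential(site_spacing_mean, size=n_draw)
            start = pos[-1] if pos.size else 0
            pos = np.unique(np.concatenate([pos, start + np.cumsum(more).astype(np.int64)]))
        sites[name] = pos[(pos > 0) & (pos < length)]
    return genome, FragmentMap(genome=genome, sites=sites)


def make_truth(
    genome: Genome,
    bin_size: int = 10_000,
    decay_exponent: float = 1.0,
    bias_sigma: float = 0.3,
    n_planted: int = 0,
    planted_fold: float = 10.0,
    planted_distance: tuple[int, int] = (10_000, 40_000),
    depleted_regions: pd.DataFrame | None = None,
    depletion_factor: float = 1.0,
    effect_genes: list[tuple[str, float]] | None = None,
    fragmap: FragmentMap | None = None,
    seed: int = 0,
) -> TruthSet:
    """Draw a ground-truth parameterization for :func:`simulate_pairs`.

    Biases are lognormal (sigma on the natural-log scale, default 0.3);
    planted cis pairs are placed uniformly at linear separations inside
    ``planted_distance``.  When a fragment map is given, planted pairs
    are restricted to bins containing a restriction site (bins without a
    site cannot receive reads, which matters at fine bin sizes).
    """
    rng = np.random.default_rng(seed)
    bins = genome_bins(genome, bin_size)
    biases = rng.lognormal(mean=0.0, sigma=bias_sigma, size=bins.n_bins)
    has_site = np.ones(bins.n_bins, dtype=bool)
    if fragmap is not None:
        has_site = np.zeros(bins.n_bins, dtype=bool)
        for name, _ in genome.chromosomes:
            s = fragmap.sites[name]
            if s.size:
                idx = bins.offsets[name] + s // bin_size
                has_site[idx] = True
    planted: list[tuple[int, int, float]] = []
    if n_planted:
        lo = max(1, planted_distance[0] // bin_size)
        hi = max(lo, planted_distance[1] // bin_size)
        chosen: set[tuple[int, int]] = set()
        chrom_names = genome.names
        attempts = 0
        while len(planted) < n_planted:
            attempts += 1
            if attempts > 100_000:
                raise RuntimeError("could not place the requested planted pairs")
            name = chrom_names[rng.integers(len(chrom_names))]
            off = bins.offsets[name]
            nb = bins.n_bins_per_chrom[name]
            d = int(rng.integers(lo, hi + 1))
            if d >= nb:
                continue
            i = int(rng.integers(0, nb - d))
            key = (off + i, off + i + d)
            if key in chosen or not (has_site[key[0]] and has_site[key[1]]):
                continue
            chosen.add(key)
            planted.append((key[0], key[1], float(planted_fold)))
    return TruthSet(
        bin_size=bin_size,
        decay_exponent=decay_exponent,
        bin_biases=biases,
        planted_pairs=planted,
        depleted_regions=depleted_regions,
        depletion_factor=depletion_factor,
        effect_genes=list(effect_genes or []),
    )


# ---------------------------------------------------------------------------
# read-pair simulation
# ---------------------------------------------------------------------------


def _sites_by_bin(genome: Genome, fragmap: FragmentMap, bins: GenomeBins):
    """Concatenated site array + per-bin [offset, count) into it, plus the
    global chromosome-relative site index and chrom code per site."""
    all_sites, site_chrom_code, site_local_idx = [], [], []
    for code, (name, _) in enumerate(genome.chromosomes):
        s = fragmap.sites[name]
        all_sites.append(s)
        site_chrom_code.append(np.full(s.size, code, dtype=np.int32))
        site_local_idx.append(np.arange(s.size, dtype=np.int64))
    sites = np.concatenate(all_sites) if all_sites else np.array([], dtype=np.int64)
    chrom_code = np.concatenate(site_chrom_code)
    local_idx = np.concatenate(site_local_idx)
    # global bin per site
    chrom_names = np.array(genome.names)
    gbin = bins.locate(chrom_names[chrom_code], sites)
    order = np.argsort(gbin, kind="stable")
    sites, chrom_code, local_idx, gbin = sites[order], chrom_code[order], local_idx[order], gbin[order]
    counts = np.bincount(gbin, minlength=bins.n_bins)
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return sites, chrom_code, local_idx, offsets, counts


def _pair_weights(bins: GenomeBins, truth: TruthSet, has_site: np.ndarray):
    """Enumerate all unordered bin pairs (i <= j) with their sampling weight."""
    B = bins.n_bins
    chrom_code = bins.chrom_of()
    bias = np.asarray(truth.bin_biases, dtype=np.float64).copy()
    bias[~has_site] = 0.0  # reads can only be placed next to a site
    iu, ju = np.triu_indices(B)
    iu = iu.astype(np.int32)
    ju = ju.astype(np.int32)
    same = chrom_code[iu] == chrom_code[ju]
    d_bp = (ju.astype(np.int64) - iu) * bins.bin_size
    kernel = np.empty(iu.size, dtype=np.float64)
    alpha = truth.decay_exponent
    kernel[same] = np.maximum(d_bp[same], truth.distance_floor) ** (-alpha)
    # contacts are modelled between distinct bins; sub-bin-scale ligation
    # structure is not simulated (within-bin separations sit below the
    # decay floor and cannot be placed on non-adjacent fragments reliably)
    kernel[same & (d_bp == 0)] = 0.0
    kernel[~same] = truth.trans_floor_frac * float(truth.trans_ref_distance) ** (-alpha)
    w = bias[iu] * bias[ju] * kernel
    if truth.planted_pairs:
        # map (i, j) -> flat upper-triangle position: i*(2B-i-1)/2 + j
        for a, b, fold in truth.planted_pairs:
            a, b = (a, b) if a <= b else (b, a)
            flat = a * (2 * B - a - 1) // 2 + b
            w[flat] *= fold
    return iu, ju, w


def _place_mates(rng, gbins_drawn, sites, offsets, counts):
    """Place one mate per drawn global bin: pick a site in the bin, a side,
    and an offset; read faces the site (site lies downstream of the 5' end)."""
    n = gbins_drawn.size
    k = (rng.random(n) * counts[gbins_drawn]).astype(np.int64)
    site = sites[offsets[gbins_drawn] + k]
    right_of_site = rng.random(n) < 0.5
    off = rng.integers(1, MAX_READ_OFFSET + 1, size=n)
    pos = np.where(right_of_site, site + off, site - off)
    strand = np.where(right_of_site, "-", "+")
    site_idx = offsets[gbins_drawn] + k
    return pos, strand, site_idx


def simulate_pairs(
    genome: Genome,
    fragmap: FragmentMap,
    truth: TruthSet,
    n_pairs: int,
    contaminant_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n_pairs`` aligned read-pair records.

    Returns a DataFrame with the 7 public pair columns plus a hidden
    ``truth`` label per record ('informative', 'self_ligation' or
    're_ligation') used only by QC recovery tests.  Exactly ``n_pairs``
    records are emitted; the contaminant count is Binomial(n_pairs,
    contaminant_fraction).
    """
    if not genome.chromosomes:
        raise ValueError("empty genome")
    if not 0 <= contaminant_fraction < 1:
        raise ValueError("contaminant_fraction must be in [0, 1)")
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    rng = np.random.default_rng(seed)
    bins = genome_bins(genome, truth.bin_size)
    if bins.n_bins != len(truth.bin_biases):
        raise ValueError("truth.bin_biases does not match the genome binning")

    sites, site_chrom, site_local, offsets, counts = _sites_by_bin(genome, fragmap, bins)
    has_site = counts > 0
    iu, ju, w = _pair_weights(bins, truth, has_site)
    if w.sum() <= 0:
        raise ValueError("no placeable bin pair (no restriction sites?)")
    p = w / w.sum()

    n_contam = int(rng.binomial(n_pairs, contaminant_fraction)) if contaminant_fraction else 0
    n_inf = n_pairs - n_contam

    chrom_names = np.array(genome.names)
    lengths = np.array([length for _, length in genome.chromosomes], dtype=np.int64)

    # --- informative pairs -------------------------------------------------
    draw = rng.choice(iu.size, size=n_inf, p=p)
    bin1 = iu[draw].astype(np.int64)
    bin2 = ju[draw].astype(np.int64)
    pos1 = np.zeros(n_inf, dtype=np.int64)
    pos2 = np.zeros(n_inf, dtype=np.int64)
    strand1 = np.empty(n_inf, dtype="U1")
    strand2 = np.empty(n_inf, dtype="U1")
    chrom_code_bins = bins.chrom_of()

    def _true_fragments(codes, pos):
        out = np.empty(pos.size, dtype=np.int64)
        for code, (name, _) in enumerate(genome.chromosomes):
            m = codes == code
            if m.any():
                out[m] = np.searchsorted(fragmap.sites[name], np.clip(pos[m], 0, None), side="right")
        return out

    todo = np.arange(n_inf)
    for attempt in range(30):
        if todo.size == 0:
            break
        p1, s1, si1 = _place_mates(rng, bin1[todo], sites, offsets, counts)
        p2, s2, si2 = _place_mates(rng, bin2[todo], sites, offsets, counts)
        c1 = chrom_code_bins[bin1[todo]]
        c2 = chrom_code_bins[bin2[todo]]
        in_bounds = (p1 >= 0) & (p1 < lengths[c1]) & (p2 >= 0) & (p2 < lengths[c2])
        f1 = _true_fragments(c1, p1)
        f2 = _true_fragments(c2, p2)
        # a genuine ligation product: distinct non-adjacent fragments and a
        # separation no smaller than the decay floor (so QC distance rules
        # cannot misclassify an informative pair)
        ok = in_bounds & (
            (c1 != c2)
            | ((np.abs(f1 - f2) >= 2) & (np.abs(p1 - p2) >= truth.distance_floor))
        )
        idx_ok = todo[ok]
        pos1[idx_ok], pos2[idx_ok] = p1[ok], p2[ok]
        strand1[idx_ok], strand2[idx_ok] = s1[ok], s2[ok]
        todo = todo[~ok]
        if attempt >= 2 and todo.size:
            # stubborn bin pairs (e.g. a same-bin pair around a lone site)
            # are redrawn from the contact model
            redraw = rng.choice(iu.size, size=todo.size, p=p)
            bin1[todo] = iu[redraw]
            bin2[todo] = ju[redraw]
    if todo.size:  # pragma: no cover - essentially unreachable
        pos1[todo], pos2[todo] = sites[offsets[bin1[todo]]], sites[offsets[bin2[todo]]]
        strand1[todo] = "+"
        strand2[todo] = "+"

    chrom_code = bins.chrom_of()
    rec_chrom1 = chrom_names[chrom_code[bin1]]
    rec_chrom2 = chrom_names[chrom_code[bin2]]
    inf = pd.DataFrame(
        {
            "chrom1": rec_chrom1,
            "pos1": pos1,
            "strand1": strand1,
            "chrom2": rec_chrom2,
            "pos2": pos2,
            "strand2": strand2,
            "truth": "informative",
        }
    )

    # --- contaminants ------------------------------------------------------
    frames = [inf]
    if n_contam:
        n_self = int(rng.binomial(n_contam, 0.5))
        n_relig = n_contam - n_self
        frames.append(_contaminants(rng, genome, fragmap, n_self, adjacent=False))
        frames.append(_contaminants(rng, genome, fragmap, n_relig, adjacent=True))
    df = pd.concat(frames, ignore_index=True)
    df = df.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31 - 1))).reset_index(
        drop=True
    )
    df.insert(0, "name", [f"R{i:08d}" for i in range(len(df))])
    return df[PAIR_COLUMNS + ["truth"]]


def _contaminants(rng, genome: Genome, fragmap: FragmentMap, n: int, adjacent: bool) -> pd.DataFrame:
    """Same-fragment (self-ligation) or adjacent-fragment (re-ligation) pairs."""
    if n == 0:
        return pd.DataFrame(columns=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "truth"])
    # choose chromosomes proportional to fragment count
    nfrag = np.array([fragmap.n_fragments(c) for c in genome.names])
    probs = nfrag / nfrag.sum()
    chosen = rng.choice(len(genome.names), size=n, p=probs)
    rows = {k: [] for k in ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]}
    strands = np.array(["+", "-"])
    for code in range(len(genome.names)):
        m = chosen == code
        cnt = int(m.sum())
        if cnt == 0:
            continue
        name = genome.names[code]
        bounds = fragmap.fragment_boundaries(name)
        nf = len(bounds) - 1
        if adjacent and nf < 2:
            adjacent_here = False
        else:
            adjacent_here = adjacent
        f1 = rng.integers(0, nf - 1 if adjacent_here else nf, size=cnt)
        f2 = f1 + 1 if adjacent_here else f1
        u1 = rng.random(cnt)
        u2 = rng.random(cnt)
        p1 = (bounds[f1] + u1 * (bounds[f1 + 1] - bounds[f1])).astype(np.int64)
        p2 = (bounds[f2] + u2 * (bounds[f2 + 1] - bounds[f2])).astype(np.int64)
        rows["chrom1"].extend([name] * cnt)
        rows["chrom2"].extend([name] * cnt)
        rows["pos1"].extend(p1.tolist())
        rows["pos2"].extend(p2.tolist())
        rows["strand1"].extend(strands[rng.integers(0, 2, size=cnt)].tolist())
        rows["strand2"].extend(strands[rng.integers(0, 2, size=cnt)].tolist())
    out = pd.DataFrame(rows)
    out["truth"] = "re_ligation" if adjacent else "self_ligation"
    return out


# ---------------------------------------------------------------------------
# annotation tracks, SNPs, genes, expression
# ---------------------------------------------------------------------------


def make_es_track(
    genome: Genome,
    n_states: int,
    mean_seg_len: float,
    state_weights,
    seed: int,
) -> pd.DataFrame:
    """Contiguous epigenetic-state segments tiling each chromosome.

    Segment lengths are exponential with the given mean; state labels
    (integers 1..n_states) are drawn independently per segment with the
    given weights.  Stand-in for the nine published chromatin states.
    """
    weights = np.asarray(state_weights, dtype=float)
    if len(weights) != n_states:
        raise ValueError("state_weights length must equal n_states")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("state_weights must sum to 1")
    if n_states < 1:
        raise ValueError("need at least one state")
    rng = np.random.default_rng(seed)
    rows = []
    for name, length in genome.chromosomes:
        pos = 0
        while pos < length:
            seg = max(1, int(np.ceil(rng.exponential(mean_seg_len))))
            end = min(length, pos + seg)
            state = int(rng.choice(n_states, p=weights)) + 1
            rows.append((name, pos, end, state))
            pos = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def make_snps(
    genome: Genome,
    n_snps: int,
    depleted_regions: pd.DataFrame | None,
    depletion_factor: float,
    seed: int,
) -> pd.DataFrame:
    """Unique SNP positions, uniformly dense outside ``depleted_regions``
    and ``depletion_factor`` times as dense inside (rejection sampling)."""
    if n_snps > genome.total_length:
        raise ValueError("more SNPs requested than genome positions")
    if not 0 < depletion_factor <= 1:
        raise ValueError("depletion_factor must be in (0, 1]")
    rng = np.random.default_rng(seed)
    lengths = np.array([length for _, length in genome.chromosomes], dtype=np.int64)
    cuml = np.concatenate(([0], np.cumsum(lengths)))
    names = np.array(genome.names)
    merged = (
        merge_intervals(depleted_regions)
        if depleted_regions is not None and len(depleted_regions)
        else None
    )
    starts_by, ends_by = {}, {}
    if merged is not None:
        for chrom, grp in merged.groupby("chrom"):
            starts_by[chrom] = grp["start"].to_numpy()
            ends_by[chrom] = grp["end"].to_numpy()
    seen: set[tuple[int, int]] = set()
    out_chrom, out_pos = [], []
    while len(out_pos) < n_snps:
        batch = max(1024, 2 * (n_snps - len(out_pos)))
        g = rng.integers(0, cuml[-1], size=batch)
        ci = np.searchsorted(cuml, g, side="right") - 1
        pos = g - cuml[ci]
        keep = np.ones(batch, dtype=bool)
        if merged is not None and depletion_factor < 1:
            inside = np.zeros(batch, dtype=bool)
            for code, chrom in enumerate(names):
                m = ci == code
                if not m.any() or chrom not in starts_by:
                    continue
                idx = np.searchsorted(starts_by[chrom], pos[m], side="right") - 1
                ok = idx >= 0
                ins = np.zeros(int(m.sum()), dtype=bool)
                ins[ok] = pos[m][ok] < ends_by[chrom][idx[ok]]
                inside[m] = ins
            keep[inside] = rng.random(int(inside.sum())) < depletion_factor
        for c, p_ in zip(ci[keep], pos[keep]):
            key = (int(c), int(p_))
            if key not in seen:
                seen.add(key)
                out_chrom.append(names[c])
                out_pos.append(int(p_))
                if len(out_pos) == n_snps:
                    break
    df = pd.DataFrame({"chrom": out_chrom, "pos": out_pos})
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def make_genes(
    genome: Genome,
    n_genes: int,
    mean_len: float = 2000.0,
    coding_fraction: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene models (chrom/start/end/strand/gene_id/biotype)."""
    rng = np.random.default_rng(seed)
    lengths = np.array([length for _, length in genome.chromosomes], dtype=np.int64)
    probs = lengths / lengths.sum()
    ci = rng.choice(len(lengths), size=n_genes, p=probs)
    glen = np.maximum(200, rng.exponential(mean_len, size=n_genes).astype(np.int64))
    starts = (rng.random(n_genes) * np.maximum(1, lengths[ci] - glen)).astype(np.int64)
    ends = np.minimum(starts + glen, lengths[ci])
    names = np.array(genome.names)
    df = pd.DataFrame(
        {
            "chrom": names[ci],
            "start": starts,
            "end": ends,
            "strand": np.where(rng.random(n_genes) < 0.5, "+", "-"),
            "gene_id": [f"G{i:05d}" for i in range(n_genes)],
            "biotype": np.where(
                rng.random(n_genes) < coding_fraction, "protein_coding", "ncRNA"
            ),
        }
    )
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def make_expression(
    genes,
    effect_genes: list[tuple[str, float]],
    true_lfc: float | None = None,
    seed: int = 0,
    noise_sd_log2: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lognormal FPKM tables for a control and a treated condition.

    ``effect_genes`` may carry per-gene true log2 fold-changes; if
    ``true_lfc`` is given it overrides them all.  Non-effect genes are
    unshifted.  Returns (control, treated) tables (gene_id, fpkm).
    """
    if isinstance(genes, pd.DataFrame):
        gene_ids = genes["gene_id"].tolist()
    else:
        gene_ids = list(genes)
    if effect_genes and isinstance(effect_genes[0], str):
        effect = {g: (true_lfc if true_lfc is not None else 0.0) for g in effect_genes}
    else:
        effect = {g: (true_lfc if true_lfc is not None else l) for g, l in effect_genes}
    missing = set(effect) - set(gene_ids)
    if missing:
        raise ValueError(f"effect genes not in gene list: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    n = len(gene_ids)
    base_log2 = rng.normal(3.3, 2.0, size=n)
    lfc = np.array([effect.get(g, 0.0) for g in gene_ids])
    ctrl = 2.0 ** (base_log2 + rng.normal(0, noise_sd_log2, size=n))
    trt = 2.0 ** (base_log2 + lfc + rng.normal(0, noise_sd_log2, size=n))
    control = pd.DataFrame({"gene_id": gene_ids, "fpkm": ctrl})
    treated = pd.DataFrame({"gene_id": gene_ids, "fpkm": trt})
    return control, treated


def write_genome_fasta(genome: Genome, path, seed: int = 0, line_width: int = 70) -> None:
    """Random nucleotide sequence for the toy genome (for motif-region export)."""
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f">{name}\n")
            seq = alphabet[rng.integers(0, 4, size=length)].tobytes().decode()
            for i in range(0, length, line_width):
                fh.write(seq[i : i + line_width] + "\n")


def simulate_study(
    seed: int,
    n_chrom: int = 3,
    chrom_length: int = 2_000_000,
    site_spacing_mean: float = 4000.0,
    bin_size: int = 10_000,
    n_pairs: int = 500_000,
    contaminant_fraction: float = 0.1,
    n_planted: int = 20,
    planted_fold: float = 10.0,
    n_states: int = 9,
    mean_seg_len: float = 20_000.0,
    n_snps: int = 20_000,
    depletion_factor: float = 0.5,
    n_genes: int = 2000,
    n_effect_genes: int = 100,
    true_lfc: float = 2.0,
) -> dict:
    """One call producing a coherent synthetic study (all pipeline inputs).

    SNP depletion is planted inside the neighbourhoods of the planted
    interaction pairs so that the GWAS stage has a recoverable signal.
    """
    rng = np.random.default_rng(seed)
    genome, fragmap = make_genome(n_chrom, chrom_length, site_spacing_mean, seed=int(rng.integers(2**31 - 1)))
    bins = genome_bins(genome, bin_size)
    table = bins.table()
    truth = make_truth(
        genome,
        bin_size=bin_size,
        n_planted=n_planted,
        planted_fold=planted_fold,
        fragmap=fragmap,
        seed=int(rng.integers(2**31 - 1)),
    )
    # depleted regions: the planted pairs' bins
    planted_bins = sorted({b for i, j, _ in truth.planted_pairs for b in (i, j)})
    depleted = table.iloc[planted_bins][["chrom", "start", "end"]].reset_index(drop=True)
    truth.depleted_regions = depleted
    truth.depletion_factor = depletion_factor
    pairs = simulate_pairs(
        genome, fragmap, truth, n_pairs, contaminant_fraction, seed=int(rng.integers(2**31 - 1))
    )
    weights = np.full(n_states, 1.0 / n_states)
    es = make_es_track(genome, n_states, mean_seg_len, weights, seed=int(rng.integers(2**31 - 1)))
    snps = make_snps(genome, n_snps, depleted, depletion_factor, seed=int(rng.integers(2**31 - 1)))
    genes = make_genes(genome, n_genes, seed=int(rng.integers(2**31 - 1)))
    eff = genes["gene_id"].sample(n_effect_genes, random_state=np.random.RandomState(seed % (2**31 - 1))).tolist()
    truth.effect_genes = [(g, true_lfc) for g in eff]
    control, treated = make_expression(genes, truth.effect_genes, seed=int(rng.integers(2**31 - 1)))
    return {
        "genome": genome,
        "fragmap": fragmap,
        "truth": truth,
        "pairs": pairs,
        "es": es,
        "snps": snps,
        "genes": genes,
        "fpkm_control": control,
        "fpkm_treated": treated,
    }
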