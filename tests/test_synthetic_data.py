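"""Generator behaviour: determinism, conservation, and that planted
signals (decay law, enrichment, depletion, expression effects) are
actually present in the emitted data."""

import numpy as np
import pandas as pd
import pytest

from hicdyn import synthetic_data as sd
from hicdyn.genome import genome_bins, intervals_length, merge_intervals


def test_make_genome_fragments_tile_each_chromosome():
    genome, fragmap = sd.make_genome(1, 1000, 10_000, seed=3)
    for name, length in genome.chromosomes:
        b = fragmap.fragment_boundaries(name)
        assert b[0] == 0 and b[-1] == length
        assert np.all(np.diff(b) > 0)


def test_make_genome_site_density_matches_spacing():
    genome, fragmap = sd.make_genome(2, 2_000_000, 4000, seed=7)
    expect = 2_000_000 / 4000
    for name in genome.names:
        n = len(fragmap.sites[name])
        assert abs(n - expect) < 3 * np.sqrt(expect)


def test_make_genome_rejects_bad_arguments():
    with pytest.raises(ValueError):
        sd.make_genome(0, 1000, 100, seed=0)
    with pytest.raises(ValueError):
        sd.make_genome(1, -5, 100, seed=0)


def test_generators_are_deterministic(toy_genome):
    genome, fragmap = toy_genome
    g1, f1 = sd.make_genome(2, 100_000, 4000, seed=5)
    g2, f2 = sd.make_genome(2, 100_000, 4000, seed=5)
    assert g1 == g2
    for c in g1.names:
        assert np.array_equal(f1.sites[c], f2.sites[c])
    truth = sd.make_truth(genome, bin_size=10_000, seed=9)
    p1 = sd.simulate_pairs(genome, fragmap, truth, 2000, 0.1, seed=13)
    p2 = sd.simulate_pairs(genome, fragmap, truth, 2000, 0.1, seed=13)
    pd.testing.assert_frame_equal(p1, p2)
    e1 = sd.make_es_track(genome, 3, 5000, [0.2, 0.3, 0.5], seed=4)
    e2 = sd.make_es_track(genome, 3, 5000, [0.2, 0.3, 0.5], seed=4)
    pd.testing.assert_frame_equal(e1, e2)
    s1 = sd.make_snps(genome, 500, None, 1.0, seed=6)
    s2 = sd.make_snps(genome, 500, None, 1.0, seed=6)
    pd.testing.assert_frame_equal(s1, s2)


def test_simulate_pairs_conservation_and_contaminant_share(toy_genome):
    genome, fragmap = toy_genome
    truth = sd.make_truth(genome, bin_size=10_000, seed=9)
    n = 20_000
    frac = 0.2
    pairs = sd.simulate_pairs(genome, fragmap, truth, n, frac, seed=14)
    assert len(pairs) == n
    share = (pairs["truth"] != "informative").mean()
    se = np.sqrt(frac * (1 - frac) / n)
    assert abs(share - frac) < 4 * se


def test_simulate_pairs_no_contaminants_means_no_same_fragment(toy_genome):
    from hicdyn.pair_filter import removal_categories

    genome, fragmap = toy_genome
    truth = sd.make_truth(genome, bin_size=10_000, seed=9)
    pairs = sd.simulate_pairs(genome, fragmap, truth, 5000, 0.0, seed=15)
    cats = removal_categories(pairs, fragmap)
    assert not np.any(cats == "removed_same_fragment")


def test_simulate_pairs_rejects_bad_input(toy_genome):
    genome, fragmap = toy_genome
    truth = sd.make_truth(genome, bin_size=10_000, seed=9)
    with pytest.raises(ValueError):
        sd.simulate_pairs(genome, fragmap, truth, 100, 1.5, seed=0)


def test_contact_distance_decay_slope(bias_study):
    """Empirical mean count per bin pair vs distance follows the planted
    power law (|slope + alpha| < 0.15) on log-log axes."""
    genome = bias_study["genome"]
    truth = bias_study["truth"]
    pairs = bias_study["pairs"]
    bins = genome_bins(genome, truth.bin_size)
    cis = pairs[pairs["chrom1"] == pairs["chrom2"]]
    d = np.abs(cis["pos2"].to_numpy() - cis["pos1"].to_numpy())
    # mean count per bin pair at distance stratum = counts / n_pairs_at_d
    bin_d = d // truth.bin_size
    max_d = 150
    counts = np.bincount(bin_d[bin_d < max_d], minlength=max_d).astype(float)
    pairs_at_d = np.zeros(max_d)
    for name in genome.names:
        nb = bins.n_bins_per_chrom[name]
        pairs_at_d += np.maximum(nb - np.arange(max_d), 0)
    use = np.arange(2, 60)
    mean = counts[use] / pairs_at_d[use]
    slope = np.polyfit(np.log(use * truth.bin_size), np.log(mean), 1)[0]
    assert abs(slope + truth.decay_exponent) < 0.15


def test_planted_pair_exceeds_equidistant_mean(toy_genome):
    genome, fragmap = toy_genome
    truth = sd.make_truth(
        genome, bin_size=10_000, n_planted=1, planted_fold=10.0, fragmap=fragmap, seed=33
    )
    pairs = sd.simulate_pairs(genome, fragmap, truth, 200_000, 0.0, seed=34)
    bins = genome_bins(genome, 10_000)
    gi = bins.locate(pairs["chrom1"].to_numpy(), pairs["pos1"].to_numpy())
    gj = bins.locate(pairs["chrom2"].to_numpy(), pairs["pos2"].to_numpy())
    lo, hi = np.minimum(gi, gj), np.maximum(gi, gj)
    a, b, fold = truth.planted_pairs[0]
    planted_count = int(((lo == a) & (hi == b)).sum())
    chrom_code = bins.chrom_of()
    dist = b - a
    same = chrom_code[lo] == chrom_code[hi]
    equidistant = same & ((hi - lo) == dist) & ~((lo == a) & (hi == b))
    n_equi_pairs = sum(max(bins.n_bins_per_chrom[c] - dist, 0) for c in genome.names) - 1
    baseline = equidistant.sum() / n_equi_pairs
    assert planted_count > 3 * baseline


def test_es_track_tiles_and_matches_weights(wide_genome):
    genome, _ = wide_genome
    weights = [0.2, 0.3, 0.5]
    es = sd.make_es_track(genome, 3, 1000, weights, seed=4)
    for name, length in genome.chromosomes:
        grp = es[es["chrom"] == name]
        assert grp["start"].iloc[0] == 0 and grp["end"].iloc[-1] == length
        assert np.array_equal(grp["start"].to_numpy()[1:], grp["end"].to_numpy()[:-1])
    share = es.assign(bp=es["end"] - es["start"]).groupby("state")["bp"].sum() / genome.total_length
    for state, w in zip((1, 2, 3), weights):
        assert abs(share[state] - w) < 0.02


def test_es_track_single_state_covers_genome(toy_genome):
    genome, _ = toy_genome
    es = sd.make_es_track(genome, 1, 5000, [1.0], seed=2)
    assert set(es["state"]) == {1}
    assert intervals_length(es[["chrom", "start", "end"]]) == genome.total_length


def test_es_track_weight_mismatch_rejected(toy_genome):
    genome, _ = toy_genome
    with pytest.raises(ValueError):
        sd.make_es_track(genome, 3, 5000, [0.5, 0.5], seed=0)


def test_snps_unique_in_bounds_and_depleted(wide_genome):
    genome, _ = wide_genome
    depleted = pd.DataFrame(
        {"chrom": ["chr1", "chr2"], "start": [0, 500_000], "end": [1_000_000, 1_500_000]}
    )
    snps = sd.make_snps(genome, 20_000, depleted, 0.5, seed=8)
    assert len(snps) == 20_000
    assert not snps.duplicated(["chrom", "pos"]).any()
    for name, length in genome.chromosomes:
        p = snps[snps["chrom"] == name]["pos"]
        if len(p):
            assert p.min() >= 0 and p.max() < length
    inside_bp = intervals_length(depleted)
    outside_bp = genome.total_length - inside_bp
    merged = merge_intervals(depleted)
    inside = 0
    for chrom, grp in merged.groupby("chrom"):
        pos = snps[snps["chrom"] == chrom]["pos"].to_numpy()
        for s, e in zip(grp["start"], grp["end"]):
            inside += int(((pos >= s) & (pos < e)).sum())
    ratio = (inside / inside_bp) / ((len(snps) - inside) / outside_bp)
    assert abs(ratio - 0.5) < 0.1


def test_snps_no_depletion_ratio_one(wide_genome):
    genome, _ = wide_genome
    depleted = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000]})
    snps = sd.make_snps(genome, 20_000, depleted, 1.0, seed=8)
    inside = ((snps["chrom"] == "chr1") & (snps["pos"] < 1_000_000)).sum()
    dens_in = inside / 1_000_000
    dens_out = (len(snps) - inside) / (genome.total_length - 1_000_000)
    assert abs(dens_in / dens_out - 1.0) < 0.1


def test_snps_more_than_genome_rejected():
    genome, _ = sd.make_genome(1, 100, 50, seed=0)
    with pytest.raises(ValueError):
        sd.make_snps(genome, 200, None, 1.0, seed=0)


def test_expression_effect_recovery(toy_genome):
    genome, _ = toy_genome
    genes = sd.make_genes(genome, 2000, seed=13)
    effect = [(g, 2.0) for g in genes["gene_id"].iloc[:100]]
    ctrl, trt = sd.make_expression(genes, effect, seed=14)
    assert (ctrl["fpkm"] >= 0).all() and (trt["fpkm"] >= 0).all()
    lfc = np.log2(trt["fpkm"].iloc[:100].to_numpy() / ctrl["fpkm"].iloc[:100].to_numpy())
    assert abs(lfc.mean() - 2.0) < 0.2
    other = np.log2(trt["fpkm"].iloc[100:].to_numpy() / ctrl["fpkm"].iloc[100:].to_numpy())
    assert abs(other.mean()) < 0.1


def test_expression_zero_effect(toy_genome):
    genome, _ = toy_genome
    genes = sd.make_genes(genome, 200, seed=13)
    ctrl, trt = sd.make_expression(genes, [(g, 0.0) for g in genes["gene_id"][:50]], seed=15)
    lfc = np.log2(trt["fpkm"].to_numpy() / ctrl["fpkm"].to_numpy())
    assert abs(lfc.mean()) < 0.1
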