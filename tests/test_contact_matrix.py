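"""Contact binning, decay estimation, bin-total inference and the
derived normalized/correlation matrices, with parameter-recovery checks
against the generator's ground truth."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hicdyn.genome import Genome, genome_bins
from hicdyn import contact_matrix as cm
from hicdyn.contact_matrix import DecayCurve, ExpectedModel


def _pairs_df(rows):
    return pd.DataFrame(
        rows, columns=["name", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    )


@pytest.fixture()
def small_genome():
    return Genome(chromosomes=(("chr1", 100_000), ("chr2", 60_000)))


def test_bin_pairs_placement_and_symmetry(small_genome):
    rows = [("r0", "chr1", 500, "+", "chr1", 900, "-")]
    rows += [(f"r{k}", "chr1", 25_000, "+", "chr1", 55_000, "-") for k in range(1, 11)]
    mat = cm.bin_pairs(_pairs_df(rows), small_genome, 10_000, mask_fraction=0.0)
    dense = mat.dense()
    assert dense[0, 0] == 1
    assert dense[2, 5] == 10 and dense[5, 2] == 10
    assert np.allclose(dense, dense.T)
    assert mat.mass() == 11


def test_bin_pairs_mass_conservation(bias_study):
    assert bias_study["matrix"].mass() == len(bias_study["retained"])


def test_bin_pairs_rejects_out_of_genome(small_genome):
    rows = [("r0", "chr1", 500, "+", "chr3", 900, "-")]
    with pytest.raises(ValueError):
        cm.bin_pairs(_pairs_df(rows), small_genome, 10_000)


def _uniform_matrix(B=30, c=4.0):
    genome = Genome(chromosomes=(("chr1", B * 1000),))
    bins = genome_bins(genome, 1000)
    obs = sp.csr_matrix(np.full((B, B), c))
    return cm.ContactMatrix(bins=bins, observed=obs, mask=np.zeros(B, dtype=bool))


def test_estimate_decay_constant_matrix():
    mat = _uniform_matrix(c=4.0)
    f = cm.estimate_decay(mat, log_pooling=False)
    d = np.arange(30)
    assert np.allclose(f.eval(d), 4.0)


def test_estimate_decay_nonincreasing_beyond_diagonal(bias_study):
    f = bias_study["model"].f
    vals = f.eval(np.arange(1, 150))
    assert np.all(np.diff(vals) <= 1e-9)
    assert np.all(f.eval(np.arange(150)) >= 0)


def test_estimate_decay_recovers_power_law(bias_study):
    truth = bias_study["truth"]
    f = bias_study["model"].f
    d = np.arange(2, 51)
    slope = np.polyfit(np.log(d * truth.bin_size), np.log(f.eval(d)), 1)[0]
    assert abs(slope + truth.decay_exponent) < 0.15


def test_estimate_decay_all_masked_errors():
    mat = _uniform_matrix()
    mat.mask[:] = True
    with pytest.raises(ValueError):
        cm.estimate_decay(mat)


def test_infer_bin_totals_uniform_matrix_gives_equal_totals():
    mat = _uniform_matrix(B=30, c=4.0)
    f = cm.estimate_decay(mat, log_pooling=False)
    n_star, N_star = cm.infer_bin_totals(mat, f)
    assert N_star == mat.mass()
    assert np.all(np.abs(n_star / n_star.mean() - 1) < 0.02)


def test_infer_bin_totals_recovers_planted_biases(bias_study):
    model = bias_study["model"]
    truth = bias_study["truth"]
    u = ~model.mask
    r = np.corrcoef(model.n_star[u], np.asarray(truth.bin_biases)[u])[0, 1]
    assert r >= 0.9


def test_expected_marginals_match_observed(bias_study):
    from hicdyn.contact_matrix import _expected_marginals

    mat, model = bias_study["matrix"], bias_study["model"]
    em = _expected_marginals(mat, model.f, model.n_star, model.N_star, model.trans_floor)
    obs = mat.marginals()
    u = ~model.mask & (obs > 0)
    rel = np.abs(em[u] - obs[u]) / obs[u]
    assert np.quantile(rel, 0.99) < 0.05


def test_global_conservation(bias_study):
    from hicdyn.contact_matrix import _expected_marginals

    mat, model = bias_study["matrix"], bias_study["model"]
    u = ~model.mask
    em = _expected_marginals(mat, model.f, model.n_star, model.N_star, model.trans_floor)
    idx = np.arange(mat.n_bins)[u]
    diag = cm.expected_count(idx, idx, model)
    exp_total = (em[u].sum() + np.nansum(diag)) / 2
    coo = sp.triu(mat.observed).tocoo()
    keep = u[coo.row] & u[coo.col]
    obs_total = coo.data[keep].sum()
    assert abs(exp_total - obs_total) / obs_total < 0.005


def _toy_model(B=10, f_val=8.0, n_val=100.0):
    genome = Genome(chromosomes=(("chr1", B * 1000),))
    bins = genome_bins(genome, 1000)
    return ExpectedModel(
        bins=bins,
        f=DecayCurve(edges=np.array([0]), values=np.array([f_val])),
        n_star=np.full(B, n_val),
        N_star=1000.0,
        trans_floor=0.0,
        mask=np.zeros(B, dtype=bool),
    )


def test_expected_count_direct_substitution():
    model = _toy_model(f_val=8.0)
    model.n_star[2] = 100.0
    model.n_star[5] = 50.0
    assert cm.expected_count(2, 5, model) == pytest.approx(40.0)
    model.n_star[3] = 0.0
    assert cm.expected_count(3, 5, model) == 0.0
    model2 = _toy_model(f_val=5.0, n_val=10.0)
    model2.N_star = 100.0
    assert cm.expected_count(1, 7, model2) == pytest.approx(5.0)


def test_normalized_matrix_uniform_is_one():
    mat = _uniform_matrix(B=30, c=4.0)
    model = cm.fit_expected_model(mat, log_pooling=False)
    norm = cm.normalized_matrix(mat, model)
    assert np.nanmax(np.abs(norm - 1.0)) < 0.05
    assert np.allclose(norm, norm.T, equal_nan=True)


def test_normalized_matrix_highlights_planted_pair(toy_genome):
    import hicdyn as H
    from hicdyn import synthetic_data as sd

    genome, fragmap = toy_genome
    truth = sd.make_truth(
        genome, bin_size=10_000, n_planted=1, planted_fold=10.0, fragmap=fragmap, seed=51
    )
    pairs = sd.simulate_pairs(genome, fragmap, truth, 300_000, 0.0, seed=52)
    retained, _ = H.filter_pairs(pairs, fragmap)
    mat = cm.bin_pairs(retained, genome, 10_000)
    model = cm.fit_expected_model(mat)
    norm = cm.normalized_matrix(mat, model)
    a, b, fold = truth.planted_pairs[0]
    d = b - a
    chrom_code = mat.bins.chrom_of()
    vals = []
    for i in range(mat.n_bins - d):
        if chrom_code[i] == chrom_code[i + d] and not (i == a):
            v = norm[i, i + d]
            if np.isfinite(v):
                vals.append(v)
    assert norm[a, b] > np.mean(vals) + 5 * np.std(vals)


def test_scale_invariance_of_normalization(bias_study):
    mat = bias_study["matrix"]
    model1 = cm.fit_expected_model(mat, tol=1e-8)
    norm1 = cm.normalized_matrix(mat, model1)
    mat3 = cm.ContactMatrix(bins=mat.bins, observed=mat.observed * 3.0, mask=mat.mask.copy())
    model3 = cm.fit_expected_model(mat3, tol=1e-8)
    norm3 = cm.normalized_matrix(mat3, model3)
    rel = np.abs(norm3 - norm1) / np.maximum(np.abs(norm1), 1e-9)
    assert np.nanmax(rel) < 1e-6


def test_chromosome_permutation_permutes_outputs():
    rng = np.random.default_rng(0)
    gA = Genome(chromosomes=(("chr1", 20_000), ("chr2", 30_000)))
    gB = Genome(chromosomes=(("chr2", 30_000), ("chr1", 20_000)))
    rows = []
    for k in range(500):
        c = "chr1" if rng.random() < 0.4 else "chr2"
        L = 20_000 if c == "chr1" else 30_000
        rows.append((f"r{k}", c, int(rng.integers(L)), "+", c, int(rng.integers(L)), "-"))
    pairs = _pairs_df(rows)
    matA = cm.bin_pairs(pairs, gA, 10_000, mask_fraction=0.0)
    matB = cm.bin_pairs(pairs, gB, 10_000, mask_fraction=0.0)
    dA, dB = matA.dense(), matB.dense()
    # chr1 occupies bins 0-1 in A and bins 3-4 in B
    perm = np.array([3, 4, 0, 1, 2])
    assert np.allclose(dA, dB[np.ix_(perm, perm)])


def test_correlation_checkerboard_blocks():
    B = 12
    block = np.array([i < B // 2 for i in range(B)])
    norm = np.where(np.equal.outer(block, block), 2.0, 0.5)
    res = cm.correlation_matrix(norm)
    v = res.values
    assert np.allclose(np.diag(v), 1.0)
    within = v[0, 1:5]
    between = v[0, B // 2 :]
    assert np.all(within > 0) and np.all(between < 0)


def test_correlation_duplicate_rows_and_mask():
    rng = np.random.default_rng(1)
    norm = np.exp(rng.normal(0, 0.5, size=(8, 8)))
    norm = (norm + norm.T) / 2
    norm[3] = norm[2]
    norm[:, 3] = norm[:, 2]
    res = cm.correlation_matrix(norm)
    assert res.values[2, 3] == pytest.approx(1.0, abs=1e-9)
    flat = np.full((8, 8), 2.0)
    flat[np.diag_indices(8)] = 2.0
    res2 = cm.correlation_matrix(flat)
    assert np.all(res2.mask)
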