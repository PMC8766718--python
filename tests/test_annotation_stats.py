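"""Epigenetic-state assignment and preference testing, SNP density and
planted-depletion recovery, and motif-region sequence export."""

import numpy as np
import pandas as pd
import pytest

from hicdyn import annotation_stats as an
from hicdyn import synthetic_data as sd
from hicdyn.genome import Genome, intervals_length
from hicdyn.io_formats import InteractionSet
from conftest import toy_interactions

COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "observed", "expected", "p_value", "class",
]


def _es(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def test_primary_state_max_overlap_and_ties():
    es = _es([("chr1", 0, 600, 8), ("chr1", 600, 1000, 9)])
    state, overlap_set = an.primary_state(("chr1", 0, 1000), es)
    assert state == 8 and overlap_set == {8, 9}
    es_tie = _es([("chr1", 0, 500, 7), ("chr1", 500, 1000, 3)])
    state, _ = an.primary_state(("chr1", 0, 1000), es_tie)
    assert state == 3  # tie broken toward the lower label
    es_far = _es([("chr2", 0, 100, 1)])
    state, overlap_set = an.primary_state(("chr1", 0, 1000), es_far)
    assert state == an.UNASSIGNED and overlap_set == set()


def test_primary_state_fully_inside_segment():
    es = _es([("chr1", 0, 10_000, 9)])
    state, _ = an.primary_state(("chr1", 2000, 3000), es)
    assert state == 9


def test_state_distribution_sums_to_100_and_recovers_planting(toy_genome):
    genome, _ = toy_genome
    es = sd.make_es_track(genome, 3, 20_000, [0.25, 0.25, 0.5], seed=81)
    iset = toy_interactions(genome, 300, 400_000, seed=82)
    pct, unassigned = an.state_distribution(iset, es)
    assert pct.sum() == pytest.approx(100.0)
    assert unassigned == 0
    # plant 70% of anchors into a single state-1 mega-segment
    es_planted = _es([("chr1", 0, 2_000_000, 1), ("chr2", 0, 2_000_000, 2),
                      ("chr3", 0, 2_000_000, 2)])
    rng = np.random.default_rng(83)
    rows = []
    for k in range(500):
        chrom = "chr1" if rng.random() < 0.7 else "chr2"
        s1 = int(rng.integers(0, 1_000_000))
        rows.append((chrom, s1, s1 + 1000, chrom, s1 + 500_000, s1 + 501_000,
                     5, 1.0, 0.01, "cis"))
    planted = InteractionSet("planted", pd.DataFrame(rows, columns=COLS))
    pct2, _ = an.state_distribution(planted, es_planted)
    assert abs(pct2[1] - 70.0) < 5.0


def test_random_control_preserves_structure(toy_genome):
    genome, _ = toy_genome
    iset = toy_interactions(genome, 400, 300_000, seed=84)
    ctrl = an.random_control_interactions(iset, genome, seed=85)
    assert len(ctrl) == len(iset)
    assert (ctrl.df["class"] == "cis").sum() == (iset.df["class"] == "cis").sum()
    lengths = (ctrl.df["end1"] - ctrl.df["start1"]).unique()
    assert list(lengths) == [1000]
    ctrl2 = an.random_control_interactions(iset, genome, seed=85)
    pd.testing.assert_frame_equal(ctrl.df, ctrl2.df)


def test_random_control_matches_cis_distance_distribution(toy_genome):
    from scipy.stats import ks_2samp

    genome, _ = toy_genome
    rng = np.random.default_rng(86)
    rows = []
    for _ in range(1000):
        d = int(rng.integers(20_000, 800_000))
        c = genome.names[rng.integers(3)]
        s1 = int(rng.integers(0, 2_000_000 - d - 2000))
        rows.append((c, s1, s1 + 1000, c, s1 + d, s1 + d + 1000, 5, 1.0, 0.01, "cis"))
    iset = InteractionSet("x", pd.DataFrame(rows, columns=COLS))
    ctrl = an.random_control_interactions(iset, genome, seed=87)
    d_src = (iset.df["start2"] - iset.df["start1"]).to_numpy()
    d_ctrl = (ctrl.df["start2"] - ctrl.df["start1"]).to_numpy()
    assert ks_2samp(d_src, d_ctrl).pvalue > 0.01


def test_es_preference_observed_one_for_same_state_pairs(toy_genome):
    genome, _ = toy_genome
    es = _es([("chr1", 0, 2_000_000, 5), ("chr2", 0, 2_000_000, 5),
              ("chr3", 0, 2_000_000, 5)])
    iset = toy_interactions(genome, 50, 100_000, seed=88)
    res = an.es_preference_test(iset, es, K=20, seed=89, genome=genome)
    assert res.observed == 1.0
    assert res.p_permutation >= 1.0 / 21


def test_es_preference_null_mean_is_sum_of_squared_weights(toy_genome):
    """For random controls at distances far above the segment length the
    same-state probability is Sum_s w_s^2 over bp shares."""
    genome, _ = toy_genome
    weights = [0.2, 0.3, 0.5]
    es = sd.make_es_track(genome, 3, 5000, weights, seed=90)
    share = es.assign(bp=es["end"] - es["start"]).groupby("state")["bp"].sum() / genome.total_length
    expect = float((share**2).sum())
    iset = toy_interactions(genome, 400, 600_000, seed=91)
    res = an.es_preference_test(iset, es, K=200, seed=92, genome=genome)
    assert abs(res.null_mean - expect) < 0.03


def test_snp_frequency_counting():
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
    snps = pd.DataFrame({"chrom": ["chr1"] * 11, "pos": list(range(0, 1000, 100)) + [500]})
    assert an.snp_frequency(regions, snps) == pytest.approx(0.01)  # duplicate 500 counted once
    with pytest.raises(ValueError):
        an.snp_frequency(regions.iloc[:0], snps)


def test_snp_frequency_split_invariance():
    snps = pd.DataFrame({"chrom": ["chr1"] * 20, "pos": np.arange(0, 2000, 100)})
    whole = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2000]})
    split = pd.DataFrame({"chrom": ["chr1"] * 4, "start": [0, 500, 1000, 1500],
                          "end": [500, 1000, 1500, 2000]})
    assert an.snp_frequency(whole, snps) == an.snp_frequency(split, snps)


def test_gwas_ratio_near_one_for_uniform_snps(toy_genome):
    genome, _ = toy_genome
    iset = toy_interactions(genome, 300, 300_000, seed=93)
    snps = sd.make_snps(genome, 20_000, None, 1.0, seed=94)
    res = an.gwas_enrichment(iset, snps, genome, seed=95)
    assert abs(res.ratio - 1.0) < 0.25
    assert abs(res.freq_control / res.freq_background - 1.0) < 0.10


def test_gwas_recovers_planted_depletion(toy_genome):
    genome, _ = toy_genome
    iset = toy_interactions(genome, 300, 300_000, seed=96)
    union = an._anchor_union(iset)
    snps = sd.make_snps(genome, 20_000, union, 0.5, seed=97)
    res = an.gwas_enrichment(iset, snps, genome, seed=98)
    assert abs(res.ratio - 2.0) <= 0.4


def test_export_motif_regions(tmp_path, toy_genome):
    genome, _ = toy_genome
    small = Genome(chromosomes=(("chr1", 100_000),))
    fasta = tmp_path / "g.fa"
    sd.write_genome_fasta(small, fasta, seed=1)
    genes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 50_000],
            "end": [12_000, 52_000],
            "strand": ["+", "-"],
            "gene_id": ["g1", "g2"],
            "biotype": ["protein_coding", "ncRNA"],
        }
    )
    rows = [
        # anchor A overlaps coding gene g1; anchor B overlaps nothing
        ("chr1", 11_000, 12_000, "chr1", 80_000, 81_000, 5, 1.0, 0.01, "cis"),
        # shares anchor A with the previous record (must dedupe)
        ("chr1", 11_000, 12_000, "chr1", 90_000, 91_000, 5, 1.0, 0.01, "cis"),
        # anchor near g2 only, which is non-coding: contributes nothing
        ("chr1", 50_500, 51_500, "chr1", 95_000, 96_000, 5, 1.0, 0.01, "cis"),
        # anchor at the chromosome start: window clipped to bounds
        ("chr1", 0, 300, "chr1", 70_000, 71_000, 5, 1.0, 0.01, "cis"),
    ]
    genes.loc[2] = ["chr1", 0, 200, "+", "g3", "protein_coding"]
    iset = InteractionSet("x", pd.DataFrame(rows, columns=COLS))
    out = tmp_path / "motifs.fa"
    regions = an.export_motif_regions(iset, genes, fasta, out, width=1000)
    assert len(regions) == 2  # deduped anchor + clipped start anchor
    text = out.read_text()
    seqs = [s.splitlines()[1] for s in text.split(">")[1:]]
    assert all(len(s) == 1000 for s in seqs)
    headers = [s.splitlines()[0] for s in text.split(">")[1:]]
    assert "chr1:0-1000" in headers  # clipped window keeps full width within bounds
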