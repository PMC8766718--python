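"""Shared fixtures: synthetic studies at the scales the recovery tests need.

Heavy simulations are session-scoped so that unit and acceptance tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import hicdyn as H
from hicdyn import synthetic_data as sd, contact_matrix as cm, interaction_caller as ic
from hicdyn.genome import genome_bins


@pytest.fixture(scope="session")
def toy_genome():
    """3 x 2 Mb genome with HindIII-like 4 kb restriction spacing."""
    return sd.make_genome(3, 2_000_000, 4000, seed=7)


@pytest.fixture(scope="session")
def wide_genome():
    """5 x 2 Mb genome for track/SNP statistics that want ~10 Mb."""
    return sd.make_genome(5, 2_000_000, 4000, seed=17)


@pytest.fixture(scope="session")
def bias_study(toy_genome):
    """1M unbiased-contaminant pairs at 10 kb truth bins with lognormal
    biases; filtered, binned and fitted.  Drives bias/decay recovery."""
    genome, fragmap = toy_genome
    truth = sd.make_truth(genome, bin_size=10_000, seed=1)
    pairs = sd.simulate_pairs(genome, fragmap, truth, 1_000_000, 0.0, seed=3)
    retained, report = H.filter_pairs(pairs, fragmap)
    matrix = cm.bin_pairs(retained, genome, 10_000)
    model = cm.fit_expected_model(matrix)
    return {
        "genome": genome,
        "fragmap": fragmap,
        "truth": truth,
        "pairs": pairs,
        "retained": retained,
        "report": report,
        "matrix": matrix,
        "model": model,
    }


@pytest.fixture(scope="session")
def qc_study(toy_genome):
    """100k pairs with 20% labelled contaminants for QC recovery."""
    genome, fragmap = toy_genome
    truth = sd.make_truth(genome, bin_size=10_000, seed=41)
    pairs = sd.simulate_pairs(genome, fragmap, truth, 100_000, 0.2, seed=42)
    return {"genome": genome, "fragmap": fragmap, "pairs": pairs}


@pytest.fixture(scope="session")
def null_1kb(toy_genome):
    """2M pairs with no planted enrichment, modelled and called at 1 kb."""
    genome, fragmap = toy_genome
    truth = sd.make_truth(genome, bin_size=1000, fragmap=fragmap, seed=11)
    pairs = sd.simulate_pairs(genome, fragmap, truth, 2_000_000, 0.0, seed=12)
    retained, _ = H.filter_pairs(pairs, fragmap)
    matrix = cm.bin_pairs(retained, genome, 1000)
    model = cm.fit_expected_model(matrix)
    called = ic.call_interactions(retained, genome, model, ic.CallerConfig(), condition="null")
    return {
        "genome": genome,
        "fragmap": fragmap,
        "truth": truth,
        "retained": retained,
        "model": model,
        "called": called,
    }


@pytest.fixture(scope="session")
def planted_1kb(toy_genome):
    """4M pairs with 20 cis pairs planted at 10x enrichment, called at 1 kb."""
    genome, fragmap = toy_genome
    truth = sd.make_truth(
        genome, bin_size=1000, n_planted=20, planted_fold=10.0, fragmap=fragmap, seed=21
    )
    pairs = sd.simulate_pairs(genome, fragmap, truth, 4_000_000, 0.0, seed=22)
    retained, _ = H.filter_pairs(pairs, fragmap)
    matrix = cm.bin_pairs(retained, genome, 1000)
    model = cm.fit_expected_model(matrix)
    called = ic.call_interactions(retained, genome, model, ic.CallerConfig(), condition="planted")
    return {
        "genome": genome,
        "truth": truth,
        "retained": retained,
        "model": model,
        "called": called,
    }


def called_bin_pairs(iset, genome, resolution):
    """Set of global (i, j) bin-index pairs of a called set."""
    bins = genome_bins(genome, resolution)
    if len(iset) == 0:
        return set()
    i = bins.locate(iset.df["chrom1"].to_numpy(), iset.df["start1"].to_numpy())
    j = bins.locate(iset.df["chrom2"].to_numpy(), iset.df["start2"].to_numpy())
    return set(zip(np.minimum(i, j), np.maximum(i, j)))


def toy_interactions(genome, n, distance, seed, anchor=1000, condition="test"):
    """Random cis interaction records at a fixed midpoint distance."""
    rng = np.random.default_rng(seed)
    rows = []
    names = genome.names
    for _ in range(n):
        c = names[rng.integers(len(names))]
        length = genome.lengths[c]
        s1 = int(rng.integers(0, length - distance - 2 * anchor))
        s2 = s1 + distance
        rows.append((c, s1, s1 + anchor, c, s2, s2 + anchor, 10, 1.0, 0.001, "cis"))
    df = pd.DataFrame(
        rows,
        columns=[
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
        ],
    )
    return H.InteractionSet(condition, df)
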