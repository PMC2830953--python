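"""Synthetic-data generators: determinism, mixtures, stationarity."""

import numpy as np
import pytest

from phyloselect.codon import (CodonModelSpec, codon_codes,
                               empirical_codon_frequencies)
from phyloselect.quality import composition_bias_test
from phyloselect.simulate import (SimulationRecipe, mammal_tree,
                                  simulate_codon_alignment,
                                  simulate_features,
                                  simulate_protein_alignment)
from phyloselect.substmodels import SubstitutionModelSpec
from phyloselect.trees import PhyloTree


def test_codon_class_fractions_concentrate():
    tree = mammal_tree().prune_to(["Human", "Macaque", "Mouse", "Cow"])
    recipe = SimulationRecipe(
        tree=tree, model=CodonModelSpec("M3k2"),
        params={"kappa": 2.0, "p0": 0.7, "omega0": 0.1, "omega1": 4.0},
        n_sites=1000, seed=1)
    _, labels = simulate_codon_alignment(recipe)
    assert abs((labels == 0).mean() - 0.7) < 0.03


def test_zero_length_tree_copies_root():
    tree = PhyloTree.from_newick("(A:0.0,B:0.0,C:0.0);")
    aln, _ = simulate_codon_alignment(SimulationRecipe(
        tree=tree, model=CodonModelSpec("M0"),
        params={"kappa": 2.0, "omega": 1.0}, n_sites=50, seed=2))
    assert aln.rows[0] == aln.rows[1] == aln.rows[2]


def test_fixed_seed_reproducible():
    tree = mammal_tree()
    r = SimulationRecipe(tree=tree, model=CodonModelSpec("M0"),
                         params={"kappa": 2.0, "omega": 0.5},
                         n_sites=100, seed=7)
    a1, l1 = simulate_codon_alignment(r)
    a2, l2 = simulate_codon_alignment(SimulationRecipe(
        tree=tree, model=CodonModelSpec("M0"),
        params={"kappa": 2.0, "omega": 0.5}, n_sites=100, seed=7))
    assert a1.rows == a2.rows and (l1 == l2).all()
    p1 = simulate_protein_alignment(SimulationRecipe(
        tree=tree, model=SubstitutionModelSpec(plus_G=True), n_sites=80,
        seed=9))
    p2 = simulate_protein_alignment(SimulationRecipe(
        tree=tree, model=SubstitutionModelSpec(plus_G=True), n_sites=80,
        seed=9))
    assert p1.rows == p2.rows


def test_long_simulation_reaches_stationarity():
    """Empirical codon frequencies converge to the model's stationary
    distribution (total variation < 0.02 at 50k sites)."""
    tree = PhyloTree.from_newick("(A:0.4,B:0.4,C:0.4);")
    rng = np.random.default_rng(3)
    freqs = rng.dirichlet(np.ones(61) * 5)
    aln, _ = simulate_codon_alignment(SimulationRecipe(
        tree=tree, model=CodonModelSpec("M0"),
        params={"kappa": 2.0, "omega": 0.5, "codon_freqs": freqs},
        n_sites=50_000, seed=4))
    codes = codon_codes(aln).ravel()
    emp = np.bincount(codes, minlength=61) / codes.size
    assert 0.5 * np.abs(emp - freqs).sum() < 0.02


def test_lba_scale_lengthens_named_branches():
    tree = mammal_tree()
    rec = SimulationRecipe(tree=tree, model=SubstitutionModelSpec(),
                           n_sites=200, seed=5,
                           lba_scale={"Macaque": 10.0})
    aln = simulate_protein_alignment(rec)
    # the scaled taxon accumulates far more differences from Human
    diff_mac = sum(a != b for a, b in zip(aln.row("Macaque"),
                                          aln.row("Human")))
    diff_chimp = sum(a != b for a, b in zip(aln.row("Chimp"),
                                            aln.row("Human")))
    assert diff_mac > 2 * diff_chimp


def test_bias_taxon_fails_composition_screen():
    tree = mammal_tree()
    rec = SimulationRecipe(
        tree=tree, model=SubstitutionModelSpec(plus_G=True),
        n_sites=300, seed=6, bias_taxa={"Mouse": "A"}, bias_fraction=0.4)
    aln = simulate_protein_alignment(rec)
    results = {r.taxon: r for r in composition_bias_test(aln, "aa")}
    assert not results["Mouse"].passed


def test_unbiased_simulation_passes_composition_screen():
    tree = mammal_tree()
    ok = 0
    for seed in range(10):
        aln = simulate_protein_alignment(SimulationRecipe(
            tree=tree, model=SubstitutionModelSpec(plus_G=True),
            n_sites=300, seed=600 + seed))
        results = composition_bias_test(aln, "aa")
        ok += all(r.passed for r in results)
    assert ok >= 9


def test_feature_placement():
    features, sites = simulate_features(1464, 99, 11, seed=8)
    assert len(features.positions) == 99
    assert len(sites) == 11
    assert all(1 <= s <= 1464 for s in sites)
    full, _ = simulate_features(50, 50, 0, seed=1)
    from phyloselect.annotate import nearest_feature
    assert all(nearest_feature(s, full)[1] == 0 for s in range(1, 51))
    with pytest.raises(ValueError):
        simulate_features(10, 9, 2)


def test_clustered_sites_score_small_p():
    from phyloselect.annotate import proximity_randomization
    features, sites = simulate_features(
        1000, 30, 10, placement="clustered", cluster_width=2, seed=12)
    rep = proximity_randomization(sites, features, mode="exact")
    assert np.median([r.p_value for r in rep.records]) < 0.1
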