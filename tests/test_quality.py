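"""Composition-bias chi-square test and likelihood mapping."""

import numpy as np
import pytest

from phyloselect.alignments import ProteinAlignment
from phyloselect.quality import (QuartetMap, assign_region, classify_signal,
                                 composition_bias_test, likelihood_map)
from phyloselect.simulate import (SimulationRecipe, mammal_tree,
                                  simulate_protein_alignment, star_tree)
from phyloselect.substmodels import SubstitutionModelSpec
from phyloselect.trees import PhyloTree


def test_identical_composition_all_pass():
    row = "ARNDCQEGHILKMFPSTWYV" * 5
    aln = ProteinAlignment([f"t{i}" for i in range(10)], [row] * 10)
    results = composition_bias_test(aln, "aa")
    assert all(r.passed for r in results)
    assert all(r.p_value > 0.99 for r in results)


def test_single_residue_row_fails():
    rng = np.random.default_rng(0)
    rows = ["".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 300))
            for _ in range(9)]
    rows.append("A" * 300)
    aln = ProteinAlignment([f"t{i}" for i in range(10)], rows)
    results = composition_bias_test(aln, "aa")
    assert not results[-1].passed
    # the biased row is by far the worst offender
    assert results[-1].chi2_stat == max(r.chi2_stat for r in results)


def test_chi2_hand_computed_two_symbol_case():
    # pooled frequencies are 50/50 over {A,R}; the first taxon observes
    # (30, 70), so chi2 = (30-50)^2/50 + (70-50)^2/50 = 16 with dof 1
    rows = ["A" * 30 + "R" * 70, "A" * 70 + "R" * 30,
            "A" * 50 + "R" * 50, "A" * 50 + "R" * 50]
    aln = ProteinAlignment(["w", "x", "y", "z"], rows)
    res = composition_bias_test(aln, "aa")[0]
    assert res.chi2_stat == pytest.approx(16.0)
    assert res.dof == 1
    assert not res.passed


def test_composition_invariant_to_row_and_column_order():
    rng = np.random.default_rng(1)
    rows = ["".join(rng.choice(list("ARND"), 80)) for _ in range(5)]
    aln = ProteinAlignment([f"t{i}" for i in range(5)], rows)
    base = {r.taxon: r.chi2_stat for r in composition_bias_test(aln, "aa")}
    perm = rng.permutation(80)
    shuffled = ProteinAlignment(
        list(reversed(aln.taxa)),
        ["".join(r[i] for i in perm) for r in reversed(rows)])
    again = {r.taxon: r.chi2_stat for r in composition_bias_test(shuffled, "aa")}
    assert base == pytest.approx(again)


def test_composition_needs_4_taxa():
    aln = ProteinAlignment(["a", "b"], ["AR", "AR"])
    with pytest.raises(ValueError):
        composition_bias_test(aln, "aa")


@pytest.mark.parametrize("weights,region", [
    ((1.0, 0.0, 0.0), "corner_1"),
    ((0.1, 0.8, 0.1), "corner_2"),
    ((0.45, 0.45, 0.10), "edge_12"),
    ((1 / 3, 1 / 3, 1 / 3), "center"),
])
def test_region_assignment(weights, region):
    assert assign_region(np.array(weights)) == region


def _qmap(corner, center, n=100):
    edge = n - corner - center
    return QuartetMap(n, {
        "corner_1": corner, "corner_2": 0, "corner_3": 0,
        "edge_12": edge, "edge_13": 0, "edge_23": 0, "center": center})


def test_classify_signal_rules():
    assert classify_signal(_qmap(95, 2)).category == 1
    assert classify_signal(_qmap(75, 10)).category == 2
    assert classify_signal(_qmap(40, 30)).category == 3
    with pytest.raises(ValueError):
        classify_signal(_qmap(95, 2), c1=0.5, c2=0.9)


def test_likelihood_map_resolved_tree_hits_corners():
    tree = mammal_tree().prune_to(
        ["Human", "Macaque", "Mouse", "Rat", "Cow", "Opossum"])
    aln = simulate_protein_alignment(SimulationRecipe(
        tree=tree, model=SubstitutionModelSpec(plus_G=True, alpha=1.0),
        n_sites=500, seed=2))
    qmap = likelihood_map(aln, n_quartets=None, seed=0)
    assert qmap.n_quartets == 15
    assert sum(qmap.region_counts.values()) == qmap.n_quartets
    assert qmap.corner_fraction > 0.9
    assert classify_signal(qmap).category == 1


def test_likelihood_map_star_tree_loses_corners():
    taxa = ["A", "B", "C", "D", "E", "F"]
    aln = simulate_protein_alignment(SimulationRecipe(
        tree=star_tree(taxa, tip_length=0.15),
        model=SubstitutionModelSpec(plus_G=True, alpha=1.0),
        n_sites=500, seed=3))
    qmap = likelihood_map(aln, n_quartets=None, seed=0)
    # without internal branches the corners empty out into edges/center
    assert qmap.corner_fraction < 0.5
    assert qmap.center_fraction + qmap.edge_fraction > 0.5
    assert classify_signal(qmap).category == 3


def test_likelihood_map_requires_4_taxa():
    aln = ProteinAlignment(["a", "b", "c"], ["AR", "AR", "AR"])
    with pytest.raises(ValueError):
        likelihood_map(aln)
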