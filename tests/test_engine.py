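"""Amino-acid likelihood engine: oracles, optimization, site rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from phyloselect.alignments import ProteinAlignment
from phyloselect.engine import (aa_codes, assign_site_rates, estimate_alpha,
                                log_likelihood, make_likelihood, nj_tree,
                                optimize_tree)
from phyloselect.gencode import AMINO_ACIDS
from phyloselect.likelihood import optimize_branch_lengths
from phyloselect.simulate import (SimulationRecipe, mammal_tree,
                                  simulate_protein_alignment)
from phyloselect.substmodels import (JTT_FREQS, SubstitutionModelSpec,
                                     TransitionMatrices, build_rate_matrix,
                                     discrete_gamma_rates)
from phyloselect.trees import PhyloTree


def gamma_slice_means_oracle(alpha, k):
    """Numeric-integration oracle for the equal-probability discretization."""
    dist = stats.gamma(a=alpha, scale=1 / alpha)
    bounds = np.concatenate([[0], dist.ppf(np.arange(1, k) / k), [np.inf]])
    means = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        val, _ = integrate.quad(lambda x: x * dist.pdf(x), lo, hi)
        means.append(val * k)
    return np.array(means)


@pytest.mark.parametrize("alpha,k", [(1.0, 4), (0.5, 8), (2.3, 5)])
def test_discrete_gamma_matches_integration(alpha, k):
    got = discrete_gamma_rates(alpha, k)
    want = gamma_slice_means_oracle(alpha, k)
    assert np.allclose(got, want / want.mean(), atol=1e-6)
    assert got.mean() == pytest.approx(1.0, abs=1e-9)


def test_discrete_gamma_edge_cases():
    assert discrete_gamma_rates(5.0, 1).tolist() == [1.0]
    with pytest.raises(ValueError):
        discrete_gamma_rates(-1.0, 4)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(0.05, 30.0), st.integers(1, 16))
def test_discrete_gamma_mean_always_one(alpha, k):
    assert discrete_gamma_rates(alpha, k).mean() == pytest.approx(1, abs=1e-9)


def test_two_taxon_zero_branch_identity():
    t = PhyloTree.from_newick("(A:0.0,B:0.0);")
    aln = ProteinAlignment(["A", "B"], ["A", "A"])
    lnl = log_likelihood(t, aln, SubstitutionModelSpec())
    assert lnl == pytest.approx(np.log(JTT_FREQS[0]), abs=1e-10)


def _enumeration_lnl(tree_lengths, rows, rates=None, weights=None):
    """Brute-force sum over all internal-state pairs of a 4-taxon tree."""
    la, lb, lv, lc, ld = tree_lengths
    tm = TransitionMatrices(build_rate_matrix(JTT_FREQS), JTT_FREQS)
    rates = [1.0] if rates is None else rates
    weights = [1.0] if weights is None else weights
    codes = [[AMINO_ACIDS.index(c) for c in row] for row in rows]
    total = 0.0
    for col in range(len(rows[0])):
        site = 0.0
        for r, w in zip(rates, weights):
            pa, pb, pv, pc, pd = (tm.probability(r * t)
                                  for t in (la, lb, lv, lc, ld))
            a, b, c, d = (codes[k][col] for k in range(4))
            s = 0.0
            for u in range(20):
                for v in range(20):
                    s += (JTT_FREQS[u] * pa[u, a] * pb[u, b] * pv[u, v]
                          * pc[v, c] * pd[v, d])
            site += w * s
        total += np.log(site)
    return total


@pytest.fixture(scope="module")
def random_quartet_alignment():
    rng = np.random.default_rng(42)
    rows = ["".join(rng.choice(list(AMINO_ACIDS), 10)) for _ in range(4)]
    return ProteinAlignment(["A", "B", "C", "D"], rows)


def test_pruning_matches_enumeration(random_quartet_alignment):
    t = PhyloTree.from_newick("((A:0.12,B:0.31):0.08,(C:0.2,D:0.05):0.08);")
    # the unrooted internal edge is the sum of the two rooted-child edges
    lnl = log_likelihood(t, random_quartet_alignment, SubstitutionModelSpec())
    want = _enumeration_lnl([0.12, 0.31, 0.16, 0.2, 0.05],
                            random_quartet_alignment.rows)
    assert lnl == pytest.approx(want, abs=1e-8)


def test_pruning_matches_enumeration_with_gamma(random_quartet_alignment):
    model = SubstitutionModelSpec(plus_G=True, alpha=0.7, k_rates=4)
    t = PhyloTree.from_newick("((A:0.1,B:0.3):0.05,(C:0.2,D:0.1):0.05);")
    lnl = log_likelihood(t, random_quartet_alignment, model)
    rates = discrete_gamma_rates(0.7, 4)
    want = _enumeration_lnl([0.1, 0.3, 0.1, 0.2, 0.1],
                            random_quartet_alignment.rows,
                            rates, np.full(4, 0.25))
    assert lnl == pytest.approx(want, abs=1e-8)


def test_likelihood_invariant_under_rerooting(random_quartet_alignment):
    model = SubstitutionModelSpec(plus_G=True, alpha=1.2, k_rates=4)
    t1 = PhyloTree.from_newick("((A:0.1,B:0.3):0.16,C:0.2,D:0.05);")
    t2 = PhyloTree.from_newick("((C:0.2,D:0.05):0.16,A:0.1,B:0.3);")
    assert log_likelihood(t1, random_quartet_alignment, model) == \
        pytest.approx(log_likelihood(t2, random_quartet_alignment, model),
                      abs=1e-9)


def test_likelihood_invariant_to_column_order(random_quartet_alignment):
    model = SubstitutionModelSpec()
    t = PhyloTree.from_newick("((A:0.1,B:0.3):0.1,(C:0.2,D:0.1):0.1);")
    base = log_likelihood(t, random_quartet_alignment, model)
    perm = np.random.default_rng(0).permutation(10)
    shuffled = random_quartet_alignment.select_columns(list(perm))
    assert log_likelihood(t, shuffled, model) == pytest.approx(base, abs=1e-9)


def test_taxa_mismatch_lists_difference(random_quartet_alignment):
    t = PhyloTree.from_newick("((A:0.1,B:0.3):0.1,(C:0.2,E:0.1):0.1);")
    with pytest.raises(ValueError, match="E"):
        log_likelihood(t, random_quartet_alignment, SubstitutionModelSpec())


def test_nj_recovers_additive_tree():
    # distances from an additive tree are recovered exactly by NJ
    true = PhyloTree.from_newick(
        "(((A:0.08,B:0.1):0.06,C:0.12):0.05,(D:0.07,E:0.09):0.04,F:0.2);")
    rec = SimulationRecipe(tree=true,
                           model=SubstitutionModelSpec(plus_G=True, alpha=1.0),
                           n_sites=3000, seed=8)
    aln = simulate_protein_alignment(rec)
    tree = nj_tree(aln, SubstitutionModelSpec(plus_G=True, alpha=1.0))
    assert tree.same_unrooted_topology(true)


def test_nj_invariant_to_taxa_order():
    true = PhyloTree.from_newick(
        "((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05,E:0.15);")
    aln = simulate_protein_alignment(SimulationRecipe(
        tree=true, model=SubstitutionModelSpec(), n_sites=800, seed=3))
    t1 = nj_tree(aln)
    rev = ProteinAlignment(aln.taxa[::-1], aln.rows[::-1])
    t2 = nj_tree(rev)
    assert t1.same_unrooted_topology(t2)


@pytest.fixture(scope="module")
def six_taxon_sim():
    true = PhyloTree.from_newick(
        "(((A:0.09,B:0.11):0.05,C:0.14):0.04,(D:0.1,E:0.12):0.05,F:0.18);")
    aln = simulate_protein_alignment(SimulationRecipe(
        tree=true, model=SubstitutionModelSpec(plus_G=True, alpha=1.0),
        n_sites=2000, seed=21))
    return true, aln


def test_ml_search_recovers_true_topology(six_taxon_sim):
    true, aln = six_taxon_sim
    fit = optimize_tree(aln, SubstitutionModelSpec(plus_G=True, alpha=1.0),
                        search="nni")
    assert fit.tree.same_unrooted_topology(true)


def test_bl_only_improves_lnl(six_taxon_sim):
    true, aln = six_taxon_sim
    model = SubstitutionModelSpec(plus_G=True, alpha=1.0)
    start_lnl = log_likelihood(true, aln, model)
    fit = optimize_tree(aln, model, start=true, search="bl_only")
    assert fit.lnl >= start_lnl - 1e-6


def test_nni_fixes_one_swap_perturbation(six_taxon_sim):
    true, aln = six_taxon_sim
    model = SubstitutionModelSpec(plus_G=True, alpha=1.0)
    wrong = true.nni_neighbors()[0]
    fit = optimize_tree(aln, model, start=wrong, search="nni")
    assert fit.tree.same_unrooted_topology(true)


def test_alpha_recovery_median_within_30pct():
    true_alpha = 0.5
    tree = mammal_tree().prune_to(
        ["Human", "Chimp", "Macaque", "Mouse", "Rat", "Dog", "Cow",
         "Opossum"])
    model = SubstitutionModelSpec(plus_G=True, alpha=true_alpha, k_rates=8)
    estimates = []
    for seed in range(10):
        aln = simulate_protein_alignment(SimulationRecipe(
            tree=tree, model=model, n_sites=1000, seed=300 + seed))
        estimates.append(estimate_alpha(aln, tree, model))
    assert abs(np.median(estimates) - true_alpha) <= 0.3 * true_alpha


def test_site_rate_categories():
    tree = mammal_tree().prune_to(
        ["Human", "Chimp", "Macaque", "Mouse", "Rat", "Dog", "Cow",
         "Opossum", "GuineaPig", "Rabbit"])
    model = SubstitutionModelSpec(plus_G=True, alpha=0.7, k_rates=8)
    aln = simulate_protein_alignment(SimulationRecipe(
        tree=tree, model=model, n_sites=60, seed=5))
    rows = [r + "A" * 3 for r in aln.rows]  # append constant columns
    # and one saturated column: a different residue in every taxon
    rows = [r + AMINO_ACIDS[i] for i, r in enumerate(rows)]
    aln2 = ProteinAlignment(aln.taxa, rows)
    prof = assign_site_rates(aln2, tree, model)
    assert np.allclose(prof.posteriors.sum(axis=1), 1.0, atol=1e-9)
    assert all(prof.map_category[-4:-1] == 1)  # constant columns -> slowest
    assert prof.map_category[-1] == 8          # saturated column -> fastest
    assert np.all(np.diff(prof.category_rates) > 0)
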