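"""Codon models: generator structure, likelihood oracle, fits, LRTs, EB."""

import numpy as np
import pytest

from phyloselect.alignments import CodonAlignment
from phyloselect.codon import (CodonModelSpec, LRT_REGISTRY,
                               build_codon_matrix, beta_bin_means,
                               class_structure, codon_codes,
                               codon_log_likelihood,
                               empirical_codon_frequencies, fit_model,
                               mean_rate, run_lrt, site_posteriors)
from phyloselect.gencode import codon_index, sense_codons
from phyloselect.simulate import (SimulationRecipe, mammal_tree,
                                  simulate_codon_alignment)
from phyloselect.substmodels import TransitionMatrices
from phyloselect.trees import PhyloTree

EQ = np.full(61, 1 / 61)


def test_generator_rows_sum_to_zero():
    q = build_codon_matrix(2.3, 0.7, EQ)
    assert np.allclose(q.sum(axis=1), 0.0, atol=1e-14)


def test_generator_parameter_collapse_symmetry():
    # omega = kappa = 1 with equal frequencies: time-reversible and
    # pi-weighted symmetric, synonymous and nonsynonymous rates equal
    q = build_codon_matrix(1.0, 1.0, EQ)
    flow = EQ[:, None] * q
    assert np.allclose(flow, flow.T, atol=1e-15)


def test_generator_single_entries():
    idx = codon_index()
    q = build_codon_matrix(3.0, 0.4, EQ)
    # TTT->TTC: synonymous (Phe) transition: kappa, no omega
    assert q[idx["TTT"], idx["TTC"]] == pytest.approx(EQ[0] * 3.0)
    # TTT->GTT: nonsynonymous (Phe->Val) transversion: omega only
    assert q[idx["TTT"], idx["GTT"]] == pytest.approx(EQ[0] * 0.4)
    # two-nucleotide changes are forbidden
    assert q[idx["TTT"], idx["GGT"]] == 0.0


def test_stationarity_preserved():
    rng = np.random.default_rng(0)
    f = rng.dirichlet(np.ones(61))
    q = build_codon_matrix(2.0, 0.5, f)
    q /= mean_rate(q, f)
    tm = TransitionMatrices(q, f)
    p = tm.probability(0.7)
    assert np.allclose(f @ p, f, atol=1e-10)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)


def test_codon_pruning_matches_enumeration():
    """3-taxon, 5-codon alignments: pruning equals the exhaustive sum over
    the single internal node's 61 states."""
    tree = PhyloTree.from_newick("(A:0.2,B:0.3,C:0.1);")
    rng = np.random.default_rng(5)
    cods = sense_codons()
    rows = ["".join(cods[i] for i in rng.integers(0, 61, 5))
            for _ in range(3)]
    aln = CodonAlignment(["A", "B", "C"], rows)
    spec = CodonModelSpec("M0", codon_frequencies="equal")
    params = {"kappa": 2.5, "omega": 0.4}
    got = codon_log_likelihood(tree, aln, spec, params)
    q = build_codon_matrix(2.5, 0.4, EQ)
    q /= mean_rate(q, EQ)
    tm = TransitionMatrices(q, EQ)
    pa, pb, pc = tm.probability(0.2), tm.probability(0.3), tm.probability(0.1)
    idx = codon_index()
    want = 0.0
    for col in range(5):
        a, b, c = (idx[rows[k][3 * col:3 * col + 3]] for k in range(3))
        want += np.log((EQ * pa[:, a] * pb[:, b] * pc[:, c]).sum())
    assert got == pytest.approx(want, abs=1e-8)


def test_m8_with_tiny_p1_degenerates_to_m7():
    tree = mammal_tree().prune_to(["Human", "Macaque", "Mouse", "Cow"])
    aln, _ = simulate_codon_alignment(SimulationRecipe(
        tree=tree, model=CodonModelSpec("M7"),
        params={"kappa": 2.0, "p": 0.5, "q": 1.0}, n_sites=100, seed=2))
    params7 = {"kappa": 2.0, "p": 0.4, "q": 0.9}
    l7 = codon_log_likelihood(tree, aln, CodonModelSpec("M7"), params7)
    l8 = codon_log_likelihood(
        tree, aln, CodonModelSpec("M8"),
        {**params7, "p0": 1 - 1e-6, "omega_s": 4.0})
    assert l8 == pytest.approx(l7, abs=1e-3)


def test_beta_bins_cover_unit_interval():
    means = beta_bin_means(0.4, 0.6, 10)
    assert means.shape == (10,)
    assert np.all(np.diff(means) > 0)
    assert 0 < means[0] and means[-1] < 1
    assert means.mean() == pytest.approx(0.4, abs=1e-6)


@pytest.mark.parametrize("stat,dof,p", [
    (0.0, 2, 1.0), (5.991, 2, 0.0500), (3.841, 1, 0.0500)])
def test_lrt_chi2_examples(stat, dof, p):
    """Critical chi-square values map to p = 0.05 at the registered dof."""
    from scipy.stats import chi2
    assert chi2.sf(stat, dof) == pytest.approx(p, abs=5e-4)


def test_run_lrt_and_registry():
    class Dummy:
        def __init__(self, name, lnl):
            self.name, self.lnl = name, lnl
    null, alt = Dummy("M7", -1000.0), Dummy("M8", -997.0045)
    res = run_lrt(null, alt)
    assert res.stat == pytest.approx(5.991, abs=1e-3)
    assert res.dof == 2
    assert res.p_value == pytest.approx(0.05, abs=5e-4)
    same = run_lrt(Dummy("M1", -50.0), Dummy("M2", -50.0))
    assert same.stat == 0.0 and same.p_value == 1.0
    with pytest.raises(ValueError, match="registered"):
        run_lrt(Dummy("M0", -1.0), Dummy("M8", -1.0))


def test_registered_dofs():
    assert LRT_REGISTRY[("M8a", "M8")] == 1
    assert LRT_REGISTRY[("M1", "ModelA")] == 2
    assert LRT_REGISTRY[("M3k2", "ModelB")] == 2


@pytest.fixture(scope="module")
def m0_sim():
    tree = mammal_tree().prune_to(
        ["Human", "Chimp", "Macaque", "Mouse", "Rat", "Dog", "Cow",
         "Opossum"])
    aln, _ = simulate_codon_alignment(SimulationRecipe(
        tree=tree, model=CodonModelSpec("M0"),
        params={"kappa": 2.0, "omega": 0.5}, n_sites=400, seed=9))
    return tree, aln


def test_m0_single_seed_recovery(m0_sim):
    tree, aln = m0_sim
    fit = fit_model(aln, tree, CodonModelSpec("M0"), n_restarts=1,
                    branch_lengths="given")
    assert 0.35 <= fit.params["omega"] <= 0.65
    assert 1.4 <= fit.kappa_hat <= 2.8


def test_nested_models_never_lose_likelihood(m0_sim):
    tree, aln = m0_sim
    m0 = fit_model(aln, tree, CodonModelSpec("M0"), n_restarts=1,
                   branch_lengths="given")
    m3 = fit_model(aln, tree, CodonModelSpec("M3k2"), n_restarts=1,
                   branch_lengths="given",
                   init={"kappa": m0.kappa_hat,
                         "omega0": max(0.05, m0.params["omega"] * 0.8),
                         "omega1": m0.params["omega"] * 1.2})
    assert m3.lnl >= m0.lnl - 1e-6
    lrt = run_lrt(m0, m3)
    assert lrt.stat < 10  # data generated under the null


def test_no_variation_is_unidentifiable():
    tree = mammal_tree().prune_to(["Human", "Macaque", "Mouse", "Cow"])
    aln = CodonAlignment(["Human", "Macaque", "Mouse", "Cow"],
                         ["ATGGCT"] * 4)
    with pytest.raises(ValueError, match="unidentifiable"):
        fit_model(aln, tree, CodonModelSpec("M0"), branch_lengths="given")


def test_branch_site_requires_marks(m0_sim):
    tree, aln = m0_sim
    with pytest.raises(ValueError, match="foreground"):
        fit_model(aln, tree, CodonModelSpec("ModelA"),
                  branch_lengths="given")


@pytest.fixture(scope="module")
def m8_fit_with_selection():
    tree = mammal_tree().prune_to(
        ["Human", "Chimp", "Macaque", "Mouse", "Rat", "GuineaPig", "Rabbit",
         "Dog", "Cow", "Opossum", "Horse", "Opossum"][:10])
    truth = {"kappa": 2.0, "p0": 0.85, "p": 0.4, "q": 0.6, "omega_s": 8.0}
    aln, labels = simulate_codon_alignment(SimulationRecipe(
        tree=tree, model=CodonModelSpec("M8"), params=truth,
        n_sites=300, seed=13))
    fit = fit_model(aln, tree, CodonModelSpec("M8"), n_restarts=1,
                    branch_lengths="given")
    return tree, aln, labels, fit


def test_neb_flags_strongly_selected_sites(m8_fit_with_selection):
    _, aln, labels, fit = m8_fit_with_selection
    calls = site_posteriors(fit, aln, method="NEB")
    selected = labels == 10  # the omega_s class of the simulator
    # strong-signal sites should mostly be recovered at the 0.5 threshold
    hits = np.mean(calls.posterior[selected] > 0.5)
    assert hits > 0.6
    # conserved columns never favor the selected class
    codes = codon_codes(aln)
    constant = (codes.max(axis=0) == codes.min(axis=0))
    if constant.any():
        assert calls.posterior[constant].max() < 0.5


def test_call_thresholds_are_nested(m8_fit_with_selection):
    _, aln, _, fit = m8_fit_with_selection
    for method in ("NEB", "BEB"):
        calls = site_posteriors(fit, aln, method=method, grid_points=5)
        assert set(calls.calls[0.99]) <= set(calls.calls[0.95])
        assert set(calls.calls[0.95]) <= set(calls.calls[0.50])
        assert np.all((calls.posterior >= 0) & (calls.posterior <= 1))


def test_beb_agrees_broadly_with_neb(m8_fit_with_selection):
    _, aln, labels, fit = m8_fit_with_selection
    neb = site_posteriors(fit, aln, method="NEB")
    beb = site_posteriors(fit, aln, method="BEB", grid_points=5)
    # same ranking on the clearly selected vs clearly neutral extremes
    top_neb = np.argsort(neb.posterior)[-10:]
    assert np.median(beb.posterior[top_neb]) > 0.5


def test_beb_rejected_for_unsupported_model(m0_sim):
    tree, aln = m0_sim
    m3 = fit_model(aln, tree, CodonModelSpec("M3k2"), n_restarts=1,
                   branch_lengths="given")
    with pytest.raises(ValueError, match="BEB"):
        site_posteriors(m3, aln, method="BEB")


def test_f3x4_frequencies_sum_to_one(m0_sim):
    _, aln = m0_sim
    for scheme in ("F3x4", "F1x4", "F61", "equal"):
        f = empirical_codon_frequencies(aln, scheme)
        assert f.shape == (61,)
        assert f.sum() == pytest.approx(1.0)
        assert (f > 0).all()


def test_class_structure_weights_sum_to_one():
    for name, params in [
        ("M1", {"p0": 0.7, "omega0": 0.2}),
        ("M2", {"p0": 0.6, "p1": 0.3, "omega0": 0.2, "omega2": 3.0}),
        ("M8", {"p0": 0.9, "p": 0.5, "q": 1.0, "omega_s": 2.0}),
        ("ModelA", {"p0": 0.6, "p1": 0.3, "omega0": 0.1, "omega2": 4.0}),
        ("ModelB", {"p0": 0.6, "p1": 0.3, "omega0": 0.1, "omega1": 1.5,
                    "omega2": 4.0}),
    ]:
        cs = class_structure(CodonModelSpec(name), {"kappa": 2.0, **params})
        assert cs.weights.sum() == pytest.approx(1.0)
        assert (cs.weights >= 0).all()
        assert (cs.omega_bg >= 0).all() and (cs.omega_fg >= 0).all()


def test_model_a_foreground_background_structure():
    cs = class_structure(
        CodonModelSpec("ModelA"),
        {"kappa": 2.0, "p0": 0.6, "p1": 0.3, "omega0": 0.1, "omega2": 4.0})
    assert cs.omega_bg.tolist() == [0.1, 1.0, 0.1, 1.0]
    assert cs.omega_fg.tolist() == [0.1, 1.0, 4.0, 4.0]
    null = class_structure(
        CodonModelSpec("ModelAnull"),
        {"kappa": 2.0, "p0": 0.6, "p1": 0.3, "omega0": 0.1})
    assert null.omega_fg.tolist() == [0.1, 1.0, 1.0, 1.0]


class TestBranchSiteScan:
    """Power at a published lineage regime and the scan interface."""

    def test_rodent_stem_selection_detected(self):
        # ~2% of sites at foreground omega = 72.73 on the rodent stem,
        # the strongest published lineage regime this package emulates
        tree = mammal_tree().prune_to(
            ["Human", "Chimp", "Macaque", "Mouse", "Rat", "Dog", "Cow",
             "Opossum"])
        tree.mark_foreground(["Mouse", "Rat"])
        truth = {"kappa": 2.0, "p0": 0.6843, "p1": 0.2940,
                 "omega0": 0.013, "omega2": 72.73}
        sig, psel = 0, []
        for seed in range(10):
            aln, _ = simulate_codon_alignment(SimulationRecipe(
                tree=tree, model=CodonModelSpec("ModelA"), params=truth,
                n_sites=600, seed=200 + seed))
            m1 = fit_model(aln, tree, CodonModelSpec("M1"), n_restarts=1,
                           branch_lengths="given")
            ma = fit_model(aln, tree, CodonModelSpec("ModelA"),
                           n_restarts=1, branch_lengths="given",
                           init={"kappa": m1.kappa_hat,
                                 "omega0": m1.params["omega0"],
                                 "p0": m1.params["p0"] * 0.95, "p1": 0.04})
            sig += run_lrt(m1, ma).significant
            psel.append(ma.class_weights[2] + ma.class_weights[3])
        assert sig >= 7
        assert 0.005 <= np.median(psel) <= 0.06

    def test_two_disjoint_foregrounds_independent_rows(self):
        from phyloselect.codon import branch_site_scan
        tree = mammal_tree().prune_to(
            ["Human", "Macaque", "Mouse", "Rat", "Cow", "Opossum"])
        aln, _ = simulate_codon_alignment(SimulationRecipe(
            tree=tree, model=CodonModelSpec("M0"),
            params={"kappa": 2.0, "omega": 0.3}, n_sites=100, seed=3))
        res = branch_site_scan(
            aln, tree, {"Macaque": ["Macaque"],
                        "Rodents": ["Mouse", "Rat"]},
            seed=1, n_restarts=1, branch_lengths="given")
        assert set(res) == {"Macaque", "Rodents"}
        for row in (res["Macaque"].summary_row(),
                    res["Rodents"].summary_row()):
            assert {"foreground", "ModelA_v_M1_p", "ModelB_v_M3k2_p",
                    "P_percent", "fwd_omega", "bck_omega"} <= set(row)
        # the shared site models are fit once and reused
        assert res["Macaque"].fits["M1"] is res["Rodents"].fits["M1"]
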