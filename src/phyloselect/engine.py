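"""Amino-acid maximum-likelihood engine.

Provides the JTT-family likelihood, NJ starting trees from ML pairwise
distances, branch-length and NNI topology optimization, gamma-shape
estimation, and the 8-category site-rate assignment used by the slow-fast
long-branch-attraction scan.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .alignments import ProteinAlignment, residue_counts
from .likelihood import (FlatTree, MixtureLikelihood, compress_patterns,
                         optimize_branch_lengths)
from .substmodels import (SubstitutionModelSpec, TransitionMatrices,
                          aa_index, build_rate_matrix)
from .trees import PhyloTree

MAX_ML_DISTANCE = 10.0


def aa_codes(aln: ProteinAlignment) -> np.ndarray:
    """(n_taxa, n_sites) state codes; gaps and X become missing (-1)."""
    out = np.full((aln.n_taxa, aln.length_aa), -1, dtype=int)
    for r, row in enumerate(aln.rows):
        for c, ch in enumerate(row):
            i = aa_index(ch)
            if i is not None:
                out[r, c] = i
    return out


def resolve_model(aln: ProteinAlignment,
                  model: SubstitutionModelSpec) -> SubstitutionModelSpec:
    """Attach empirical (+F) frequencies from the data when requested."""
    if model.plus_F and model.frequencies is None:
        return model.with_frequencies_from(residue_counts(aln))
    return model


def make_likelihood(tree: PhyloTree, aln: ProteinAlignment,
                    model: SubstitutionModelSpec) -> MixtureLikelihood:
    model = resolve_model(aln, model)
    freqs = model.freqs()
    tm = TransitionMatrices(build_rate_matrix(freqs), freqs)
    rates, weights = model.rate_mixture()
    flat = FlatTree(tree, aln.taxa)
    patterns, pweights, _ = compress_patterns(aa_codes(aln))
    tms = [{0: tm} for _ in rates]
    return MixtureLikelihood(flat, patterns, pweights, tms, weights, rates)


def log_likelihood(tree: PhyloTree, aln: ProteinAlignment,
                   model: SubstitutionModelSpec) -> float:
    return make_likelihood(tree, aln, model).lnl()


# ---------------------------------------------------------------------------
# pairwise ML distances and neighbor joining

def _pair_distance(codes_i: np.ndarray, codes_j: np.ndarray,
                   tm: TransitionMatrices, rates: np.ndarray,
                   weights: np.ndarray, freqs: np.ndarray) -> float:
    both = (codes_i >= 0) & (codes_j >= 0)
    a, b = codes_i[both], codes_j[both]
    if a.size == 0:
        return MAX_ML_DISTANCE

    def neg(t: float) -> float:
        lik = np.zeros(a.size)
        for r, w in zip(rates, weights):
            lik += w * tm.probability(t * r)[a, b]
        return -float(np.log(np.clip(freqs[a] * lik, 1e-300, None)).sum())

    res = minimize_scalar(neg, bounds=(1e-8, MAX_ML_DISTANCE),
                          method="bounded", options={"xatol": 1e-6})
    d = float(res.x)
    if d > 0.98 * MAX_ML_DISTANCE:
        warnings.warn("saturated pair: ML distance capped at maximum")
        return MAX_ML_DISTANCE
    return d


def ml_distance_matrix(aln: ProteinAlignment,
                       model: SubstitutionModelSpec) -> np.ndarray:
    model = resolve_model(aln, model)
    freqs = model.freqs()
    tm = TransitionMatrices(build_rate_matrix(freqs), freqs)
    rates, weights = model.rate_mixture()
    codes = aa_codes(aln)
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_distance(
                codes[i], codes[j], tm, rates, weights, freqs)
    return d


def nj_tree(aln: ProteinAlignment,
            model: SubstitutionModelSpec | None = None) -> PhyloTree:
    """Neighbor-joining tree on ML pairwise distances (negative lengths -> 0)."""
    if aln.n_taxa < 3:
        raise ValueError("need >= 3 taxa for NJ")
    model = model or SubstitutionModelSpec(plus_G=True, alpha=1.0)
    d = ml_distance_matrix(aln, model)
    buf = io.StringIO()
    buf.write("," + ",".join(aln.taxa) + "\n")
    for i, t in enumerate(aln.taxa):
        buf.write(t + "," + ",".join(f"{x:.8f}" for x in d[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    dtree = pdm.nj_tree()
    return PhyloTree.from_newick(dtree.as_string(schema="newick"))


# ---------------------------------------------------------------------------
# tree optimization

@dataclass
class TreeFitResult:
    tree: PhyloTree
    lnl: float
    converged: bool = True
    n_nni_accepted: int = 0


def _optimized_bl_lnl(tree: PhyloTree, aln: ProteinAlignment,
                      model: SubstitutionModelSpec, tol: float = 1e-6,
                      max_passes: int = 8,
                      xatol: float = 1e-5) -> tuple[PhyloTree, float]:
    lik = make_likelihood(tree, aln, model)
    lnl = optimize_branch_lengths(lik, tol=tol, max_passes=max_passes,
                                  xatol=xatol)
    lik.flat.push_lengths()
    return tree, lnl


def optimize_tree(aln: ProteinAlignment, model: SubstitutionModelSpec,
                  start: PhyloTree | None = None, search: str = "nni",
                  max_rounds: int = 30) -> TreeFitResult:
    """ML tree search: branch lengths always; NNI swaps when ``search='nni'``.

    NNI candidates are screened with current branch lengths; the most
    promising are re-scored with full branch-length optimization and a swap
    is kept only when it improves lnL by at least 1e-4.
    """
    model = resolve_model(aln, model)
    tree = (start or nj_tree(aln, model)).copy()
    if search == "bl_only":
        tree, lnl = _optimized_bl_lnl(tree, aln, model)
        return TreeFitResult(tree, lnl)
    if search != "nni":
        raise ValueError("search must be 'bl_only' or 'nni'")
    # quick passes during the search; full 1e-6 polish on the final tree
    tree, lnl = _optimized_bl_lnl(tree, aln, model, tol=1e-4, max_passes=4,
                                  xatol=1e-4)
    accepted = 0
    converged = False
    for _ in range(max_rounds):
        neighbors = tree.nni_neighbors()
        screened = sorted(
            ((log_likelihood(t, aln, model), t) for t in neighbors),
            key=lambda pair: -pair[0])
        improved = False
        for _, cand in screened[:2]:
            cand, cand_lnl = _optimized_bl_lnl(cand, aln, model, tol=1e-4,
                                               max_passes=4, xatol=1e-4)
            if cand_lnl - lnl >= 1e-4:
                tree, lnl = cand, cand_lnl
                accepted += 1
                improved = True
                break
        if not improved:
            converged = True
            break
    tree, lnl = _optimized_bl_lnl(tree, aln, model)
    return TreeFitResult(tree, lnl, converged=converged, n_nni_accepted=accepted)


# ---------------------------------------------------------------------------
# rate-parameter estimation

def estimate_alpha(aln: ProteinAlignment, tree: PhyloTree,
                   model: SubstitutionModelSpec,
                   bounds: tuple[float, float] = (0.05, 20.0)) -> float:
    """ML gamma shape with branch lengths held fixed."""

    def neg(log_alpha: float) -> float:
        m = SubstitutionModelSpec(
            plus_I=model.plus_I, p_inv=model.p_inv, plus_G=True,
            alpha=float(np.exp(log_alpha)), k_rates=model.k_rates,
            plus_F=model.plus_F, frequencies=model.frequencies)
        return -log_likelihood(tree, aln, m)

    res = minimize_scalar(neg, bounds=np.log(bounds), method="bounded",
                          options={"xatol": 1e-4})
    return float(np.exp(res.x))


def fit_rate_model(aln: ProteinAlignment, tree: PhyloTree,
                   model: SubstitutionModelSpec,
                   n_rounds: int = 2) -> tuple[SubstitutionModelSpec, PhyloTree, float]:
    """Alternate branch-length and rate-parameter optimization."""
    model = resolve_model(aln, model)
    tree = tree.copy()
    lnl = -np.inf
    for _ in range(n_rounds):
        if model.plus_G:
            alpha = estimate_alpha(aln, tree, model)
            model = SubstitutionModelSpec(
                plus_I=model.plus_I, p_inv=model.p_inv, plus_G=True,
                alpha=alpha, k_rates=model.k_rates, plus_F=model.plus_F,
                frequencies=model.frequencies)
        if model.plus_I:
            def neg(p: float) -> float:
                m = SubstitutionModelSpec(
                    plus_I=True, p_inv=p, plus_G=model.plus_G,
                    alpha=model.alpha, k_rates=model.k_rates,
                    plus_F=model.plus_F, frequencies=model.frequencies)
                return -log_likelihood(tree, aln, m)
            res = minimize_scalar(neg, bounds=(0.0, 0.8), method="bounded",
                                  options={"xatol": 1e-3})
            model = SubstitutionModelSpec(
                plus_I=True, p_inv=float(res.x), plus_G=model.plus_G,
                alpha=model.alpha, k_rates=model.k_rates,
                plus_F=model.plus_F, frequencies=model.frequencies)
        tree, lnl = _optimized_bl_lnl(tree, aln, model)
    return model, tree, lnl


def model_aic(lnl: float, model: SubstitutionModelSpec,
              n_branches: int) -> float:
    return 2.0 * (model.n_free_params() + n_branches) - 2.0 * lnl


def select_model(aln: ProteinAlignment, tree: PhyloTree,
                 candidates: list[SubstitutionModelSpec] | None = None
                 ) -> tuple[SubstitutionModelSpec, dict[str, float]]:
    """AIC model choice among JTT [+I][+G][+F] combinations.

    Branch lengths are optimized once under JTT+G and shared across
    candidates; each candidate optimizes only its own rate parameters.
    """
    if candidates is None:
        candidates = [
            SubstitutionModelSpec(),
            SubstitutionModelSpec(plus_G=True),
            SubstitutionModelSpec(plus_G=True, plus_F=True),
            SubstitutionModelSpec(plus_I=True, p_inv=0.1, plus_G=True),
            SubstitutionModelSpec(plus_I=True, p_inv=0.1, plus_G=True,
                                  plus_F=True),
        ]
    base = SubstitutionModelSpec(plus_G=True, alpha=1.0)
    _, bl_tree, _ = fit_rate_model(aln, tree, base, n_rounds=1)
    n_branches = sum(1 for n in bl_tree.d if n.parent_node is not None)
    scores: dict[str, float] = {}
    best, best_aic = None, np.inf
    for cand in candidates:
        cand = resolve_model(aln, cand)
        fitted = cand
        if cand.plus_G:
            alpha = estimate_alpha(aln, bl_tree, cand)
            fitted = SubstitutionModelSpec(
                plus_I=cand.plus_I, p_inv=cand.p_inv, plus_G=True,
                alpha=alpha, k_rates=cand.k_rates, plus_F=cand.plus_F,
                frequencies=cand.frequencies)
        lnl = log_likelihood(bl_tree, aln, fitted)
        aic = model_aic(lnl, fitted, n_branches)
        scores[fitted.name] = aic
        if aic < best_aic:
            best, best_aic = fitted, aic
    return best, scores


# ---------------------------------------------------------------------------
# site-rate categories

@dataclass
class SiteRateProfile:
    """Per-column rate-category assignment, 1 = slowest ... k = fastest."""

    map_category: np.ndarray  # (n_sites,), values 1..k
    posteriors: np.ndarray    # (n_sites, k)
    category_rates: np.ndarray

    @property
    def k(self) -> int:
        return self.category_rates.size

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({
            "column_1based": np.arange(1, self.map_category.size + 1),
            "map_category": self.map_category,
            "top_posterior": self.posteriors.max(axis=1),
        })


def assign_site_rates(aln: ProteinAlignment, tree: PhyloTree,
                      model: SubstitutionModelSpec) -> SiteRateProfile:
    """Posterior rate-category membership per column under +G (k categories).

    Ties in the MAP category break toward the slower category (argmax takes
    the first maximum and categories are sorted by increasing rate).
    """
    if not model.plus_G:
        raise ValueError("site-rate assignment requires a +G model")
    model = resolve_model(aln, model)
    lik = make_likelihood(tree, aln, model)
    cls = lik.class_pattern_loglik()  # (k, n_patterns)
    logw = np.log(lik.class_weights)[:, None]
    post = cls + logw
    post -= post.max(axis=0)
    post = np.exp(post)
    post /= post.sum(axis=0)
    _, _, site_to_pat = compress_patterns(aa_codes(aln))
    post_sites = post[:, site_to_pat].T  # (n_sites, k)
    rates = lik.rates
    # with +I the invariant class is merged into the slowest gamma category
    if model.plus_I and model.p_inv > 0:
        post_sites = np.hstack([
            (post_sites[:, 0] + post_sites[:, 1])[:, None], post_sites[:, 2:]])
        rates = rates[1:]
    map_cat = post_sites.argmax(axis=1) + 1
    return SiteRateProfile(map_cat, post_sites, rates)
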