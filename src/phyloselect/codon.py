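"""Codon substitution models and selection inference.

Implements the Goldman-Yang-style 61-state codon model with
transition/transversion ratio kappa and selection parameter omega = dN/dS,
the standard site-class mixtures (M0, M1, M2, M3 k=2/3, M7, M8, M8a), the
branch-site models A, A-null and B, the registered likelihood-ratio tests,
and NEB/BEB empirical-Bayes identification of positively selected sites.

Site classes share one generator scale computed from the mixture-average
substitution rate, so branch lengths are expected substitutions per codon
site under the full model.  For branch-site models the scale uses the
background-branch mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from .alignments import CodonAlignment
from .gencode import codon_index, is_transition, sense_codons
from .likelihood import (FlatTree, MixtureLikelihood, compress_patterns,
                         optimize_branch_lengths)
from .substmodels import TransitionMatrices
from .trees import PhyloTree

N_STATES = 61
OMEGA_REPORT_CLAMP = 999.0

SITE_MODELS = ("M0", "M1", "M2", "M3k2", "M3k3", "M7", "M8", "M8a")
BRANCH_SITE_MODELS = ("ModelA", "ModelAnull", "ModelB")

# free parameters beyond branch lengths (kappa included)
N_PARAMS = {
    "M0": 2, "M1": 3, "M2": 5, "M3k2": 4, "M3k3": 6,
    "M7": 3, "M8": 5, "M8a": 4,
    "ModelA": 5, "ModelAnull": 4, "ModelB": 6,
}

LRT_REGISTRY = {
    ("M0", "M3k2"): 2,
    ("M0", "M3k3"): 4,
    ("M1", "M2"): 2,
    ("M7", "M8"): 2,
    ("M8a", "M8"): 1,
    ("M1", "ModelA"): 2,
    ("ModelAnull", "ModelA"): 1,
    ("M3k2", "ModelB"): 2,
}


# ---------------------------------------------------------------------------
# state coding and codon frequencies

def codon_codes(aln: CodonAlignment) -> np.ndarray:
    """(n_taxa, n_codons) sense-codon indices; any gap/N codon is missing."""
    idx = codon_index()
    out = np.full((aln.n_taxa, aln.n_codons), -1, dtype=int)
    for r, row in enumerate(aln.rows):
        for c in range(aln.n_codons):
            out[r, c] = idx.get(row[3 * c:3 * c + 3], -1)
    return out


def empirical_codon_frequencies(aln: CodonAlignment,
                                scheme: str = "F3x4") -> np.ndarray:
    """Codon equilibrium frequencies from the data (F3x4, F1x4, F61, equal)."""
    codons = sense_codons()
    if scheme == "equal":
        return np.full(N_STATES, 1.0 / N_STATES)
    nt = "ACGT"
    lut = {c: i for i, c in enumerate(nt)}
    if scheme in ("F3x4", "F1x4"):
        counts = np.full((3, 4), 0.5)  # light pseudocount: no zero states
        for row in aln.rows:
            for i in range(0, len(row), 3):
                cod = row[i:i + 3]
                for pos, ch in enumerate(cod):
                    if ch in lut:
                        counts[pos, lut[ch]] += 1
        if scheme == "F1x4":
            counts = np.tile(counts.sum(axis=0), (3, 1))
        pos_freq = counts / counts.sum(axis=1, keepdims=True)
        f = np.array([
            pos_freq[0, lut[c[0]]] * pos_freq[1, lut[c[1]]] * pos_freq[2, lut[c[2]]]
            for c in codons])
        return f / f.sum()
    if scheme == "F61":
        idx = codon_index()
        counts = np.zeros(N_STATES)
        for row in aln.rows:
            for i in range(0, len(row), 3):
                j = idx.get(row[i:i + 3])
                if j is not None:
                    counts[j] += 1
        if (counts == 0).any():
            warnings.warn("F61: zero-count codons given a 0.1 pseudocount")
            counts = counts + 0.1
        return counts / counts.sum()
    raise ValueError(f"unknown codon frequency scheme {scheme!r}")


# ---------------------------------------------------------------------------
# generator construction

def _single_step_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(neighbor mask, transition mask, nonsynonymous mask) over 61x61."""
    codons = sense_codons()
    from .gencode import translate_codon
    aas = [translate_codon(c) for c in codons]
    n = len(codons)
    nb = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)
    ns = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(codons[i], codons[j]) if a != b]
            if len(diffs) != 1:
                continue
            nb[i, j] = True
            ts[i, j] = is_transition(*diffs[0])
            ns[i, j] = aas[i] != aas[j]
    return nb, ts, ns


_NB, _TS, _NS = _single_step_tables()


def build_codon_matrix(kappa: float, omega: float, codon_freqs: np.ndarray,
                       scale: float | None = None) -> np.ndarray:
    """GY-style codon generator; rate i->j = pi_j * kappa^[ts] * omega^[nonsyn].

    Multi-nucleotide changes are forbidden.  With ``scale`` the generator is
    divided so that branch lengths are in the caller's intended units;
    callers fitting mixtures compute one scale over the whole mixture.
    """
    q = np.where(_NB, codon_freqs[None, :], 0.0)
    q = np.where(_TS, q * kappa, q)
    q = np.where(_NS, q * omega, q)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale is not None:
        q = q / scale
    return q


def mean_rate(q: np.ndarray, freqs: np.ndarray) -> float:
    return float(-(freqs * np.diag(q)).sum())


# ---------------------------------------------------------------------------
# model specifications and class structures

@dataclass
class CodonModelSpec:
    """Named codon model plus shared nuisance choices."""

    name: str
    codon_frequencies: str = "F3x4"
    n_beta_bins: int = 10
    legacy_m1_omega0_zero: bool = False

    def __post_init__(self) -> None:
        if self.name not in SITE_MODELS + BRANCH_SITE_MODELS:
            raise ValueError(f"unknown codon model {self.name!r}")

    @property
    def is_branch_site(self) -> bool:
        return self.name in BRANCH_SITE_MODELS

    @property
    def n_params(self) -> int:
        return N_PARAMS[self.name]


def beta_bin_means(p: float, q: float, k: int) -> np.ndarray:
    """Means of the k equal-probability slices of Beta(p, q)."""
    bounds = stats.beta.ppf(np.arange(1, k) / k, p, q)
    upper = stats.beta.cdf(np.concatenate([bounds, [1.0]]), p + 1, q)
    lower = stats.beta.cdf(np.concatenate([[0.0], bounds]), p + 1, q)
    means = (upper - lower) * k * (p / (p + q))
    return np.clip(means, 1e-8, 1.0)


@dataclass
class ClassStructure:
    """Mixture classes: weights plus background/foreground omega per class."""

    weights: np.ndarray
    omega_bg: np.ndarray
    omega_fg: np.ndarray


def class_structure(spec: CodonModelSpec, params: dict[str, float]
                    ) -> ClassStructure:
    name, k = spec.name, spec.n_beta_bins
    w0 = 0.0 if spec.legacy_m1_omega0_zero else params.get("omega0", 0.0)
    if name == "M0":
        om = np.array([params["omega"]])
        return ClassStructure(np.ones(1), om, om)
    if name == "M1":
        p0 = params["p0"]
        om = np.array([w0, 1.0])
        return ClassStructure(np.array([p0, 1 - p0]), om, om)
    if name == "M2":
        p0, p1 = params["p0"], params["p1"]
        om = np.array([w0, 1.0, params["omega2"]])
        return ClassStructure(np.array([p0, p1, 1 - p0 - p1]), om, om)
    if name == "M3k2":
        p0 = params["p0"]
        om = np.array([params["omega0"], params["omega1"]])
        return ClassStructure(np.array([p0, 1 - p0]), om, om)
    if name == "M3k3":
        p0, p1 = params["p0"], params["p1"]
        om = np.array([params["omega0"], params["omega1"], params["omega2"]])
        return ClassStructure(np.array([p0, p1, 1 - p0 - p1]), om, om)
    if name == "M7":
        om = beta_bin_means(params["p"], params["q"], k)
        return ClassStructure(np.full(k, 1.0 / k), om, om)
    if name in ("M8", "M8a"):
        p0 = params["p0"]
        omega_s = 1.0 if name == "M8a" else params["omega_s"]
        om = np.concatenate([beta_bin_means(params["p"], params["q"], k),
                             [omega_s]])
        w = np.concatenate([np.full(k, p0 / k), [1 - p0]])
        return ClassStructure(w, om, om)
    if name in ("ModelA", "ModelAnull", "ModelB"):
        p0, p1 = params["p0"], params["p1"]
        rest = max(1.0 - p0 - p1, 0.0)
        denom = max(p0 + p1, 1e-12)
        w = np.array([p0, p1, rest * p0 / denom, rest * p1 / denom])
        omega1 = params["omega1"] if name == "ModelB" else 1.0
        omega2 = 1.0 if name == "ModelAnull" else params["omega2"]
        bg = np.array([params["omega0"], omega1, params["omega0"], omega1])
        fg = np.array([params["omega0"], omega1, omega2, omega2])
        return ClassStructure(w, bg, fg)
    raise AssertionError(name)


# default starting points for the optimizer
_DEFAULT_INIT = {
    "M0": {"kappa": 2.0, "omega": 0.3},
    "M1": {"kappa": 2.0, "p0": 0.7, "omega0": 0.2},
    "M2": {"kappa": 2.0, "p0": 0.6, "p1": 0.3, "omega0": 0.2, "omega2": 2.5},
    "M3k2": {"kappa": 2.0, "p0": 0.7, "omega0": 0.2, "omega1": 1.2},
    "M3k3": {"kappa": 2.0, "p0": 0.5, "p1": 0.3, "omega0": 0.1,
             "omega1": 0.8, "omega2": 2.5},
    "M7": {"kappa": 2.0, "p": 0.5, "q": 1.0},
    "M8": {"kappa": 2.0, "p0": 0.9, "p": 0.5, "q": 1.0, "omega_s": 2.5},
    "M8a": {"kappa": 2.0, "p0": 0.9, "p": 0.5, "q": 1.0},
    "ModelA": {"kappa": 2.0, "p0": 0.7, "p1": 0.2, "omega0": 0.2,
               "omega2": 2.5},
    "ModelAnull": {"kappa": 2.0, "p0": 0.7, "p1": 0.2, "omega0": 0.2},
    "ModelB": {"kappa": 2.0, "p0": 0.7, "p1": 0.2, "omega0": 0.2,
               "omega1": 1.2, "omega2": 2.5},
}

# transform kinds: log (positive), logit (0..1), ge1 (>= 1), stick0/stick1
# (p0, p1 with p0 + p1 <= 1 via stick breaking)
_PARAM_KINDS = {
    "kappa": "log", "omega": "log", "omega1": "log", "omega_s": "ge1",
    "omega0": "logit", "p": "logbeta", "q": "logbeta",
    "omega2": "ge1",
}


def _param_layout(spec: CodonModelSpec) -> list[tuple[str, str]]:
    names = list(_DEFAULT_INIT[spec.name])
    layout: list[tuple[str, str]] = []
    for n in names:
        if n == "p0":
            kind = "stick0" if "p1" in names else "logit"
        elif n == "p1":
            kind = "stick1"
        else:
            kind = _PARAM_KINDS[n]
        if spec.name == "M2" and n == "omega2":
            kind = "ge1"
        if spec.name in ("M3k2", "M3k3") and n in ("omega1", "omega2"):
            kind = "log"
        layout.append((n, kind))
    if spec.legacy_m1_omega0_zero and spec.name == "M1":
        layout = [pl for pl in layout if pl[0] != "omega0"]
    return layout


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-np.clip(x, -35, 35))))


def _pack(spec: CodonModelSpec, params: dict[str, float]) -> np.ndarray:
    x = []
    p0 = params.get("p0", 0.5)
    for name, kind in _param_layout(spec):
        v = params[name]
        if kind == "log":
            x.append(np.log(max(v, 1e-8)))
        elif kind == "logbeta":
            x.append(np.log(np.clip(v, 5e-3, 99.0)))
        elif kind == "logit":
            x.append(_logit(v))
        elif kind == "ge1":
            x.append(np.log(max(v - 1.0, 1e-6)))
        elif kind == "stick0":
            x.append(_logit(v))
        elif kind == "stick1":
            x.append(_logit(v / max(1.0 - p0, 1e-9)))
    return np.array(x)


def _unpack(spec: CodonModelSpec, x: np.ndarray) -> dict[str, float]:
    params: dict[str, float] = {}
    p0 = None
    for (name, kind), v in zip(_param_layout(spec), x):
        if kind == "log":
            params[name] = float(np.exp(np.clip(v, -18, 9)))
        elif kind == "logbeta":
            params[name] = float(np.clip(np.exp(v), 5e-3, 99.0))
        elif kind == "logit":
            params[name] = _expit(v)
        elif kind == "ge1":
            params[name] = 1.0 + float(np.exp(np.clip(v, -18, 9)))
        elif kind == "stick0":
            p0 = _expit(v)
            params[name] = p0
        elif kind == "stick1":
            params[name] = _expit(v) * (1.0 - (p0 or 0.0))
    if spec.legacy_m1_omega0_zero and spec.name == "M1":
        params["omega0"] = 0.0
    return params


# ---------------------------------------------------------------------------
# likelihood assembly

def _mixture_likelihood(flat: FlatTree, patterns: np.ndarray,
                        pweights: np.ndarray, freqs: np.ndarray,
                        cs: ClassStructure, kappa: float) -> MixtureLikelihood:
    q_bg = [build_codon_matrix(kappa, om, freqs) for om in cs.omega_bg]
    scale = sum(w * mean_rate(q, freqs) for w, q in zip(cs.weights, q_bg))
    tms: list[dict[int, TransitionMatrices]] = []
    branch_site = not np.array_equal(cs.omega_bg, cs.omega_fg)
    for ci in range(cs.weights.size):
        d = {0: TransitionMatrices(q_bg[ci] / scale, freqs)}
        if branch_site:
            q_fg = build_codon_matrix(kappa, cs.omega_fg[ci], freqs)
            d[1] = TransitionMatrices(q_fg / scale, freqs)
        tms.append(d)
    return MixtureLikelihood(flat, patterns, pweights, tms, cs.weights)


def codon_likelihood(tree: PhyloTree, aln: CodonAlignment,
                     spec: CodonModelSpec, params: dict[str, float],
                     freqs: np.ndarray | None = None) -> MixtureLikelihood:
    """Build the mixture likelihood for a codon model at given parameters."""
    if freqs is None:
        freqs = empirical_codon_frequencies(aln, spec.codon_frequencies)
    flat = FlatTree(tree, aln.taxa)
    patterns, pweights, _ = compress_patterns(codon_codes(aln))
    cs = class_structure(spec, params)
    return _mixture_likelihood(flat, patterns, pweights, freqs, cs,
                               params["kappa"])


def codon_log_likelihood(tree: PhyloTree, aln: CodonAlignment,
                         spec: CodonModelSpec, params: dict[str, float],
                         freqs: np.ndarray | None = None) -> float:
    return codon_likelihood(tree, aln, spec, params, freqs).lnl()


# ---------------------------------------------------------------------------
# fitting

@dataclass
class ModelFit:
    spec: CodonModelSpec
    lnl: float
    n_params: int
    params: dict[str, float]
    omega_by_class: np.ndarray
    class_weights: np.ndarray
    kappa_hat: float
    converged: bool
    n_restarts_used: int
    tree: PhyloTree = field(repr=False, default=None)
    freqs: np.ndarray = field(repr=False, default=None)

    @property
    def name(self) -> str:
        return self.spec.name

    def report_omega(self, omega: float) -> float:
        return min(omega, OMEGA_REPORT_CLAMP)

    def summary_row(self) -> dict:
        cs = class_structure(self.spec, self.params)
        return {
            "model": self.name, "lnL": self.lnl, "n_params": self.n_params,
            "kappa": self.kappa_hat,
            **{k: v for k, v in self.params.items() if k != "kappa"},
            "class_weights": np.round(cs.weights, 5).tolist(),
            "omega_bg": [self.report_omega(o) for o in np.round(cs.omega_bg, 5)],
            "omega_fg": [self.report_omega(o) for o in np.round(cs.omega_fg, 5)],
        }


def fit_m0_with_branch_lengths(aln: CodonAlignment, tree: PhyloTree,
                               codon_frequencies: str = "F3x4",
                               n_rounds: int = 2) -> tuple[PhyloTree, dict[str, float], float]:
    """Joint M0 fit: (kappa, omega) by Nelder-Mead alternated with
    coordinate-wise branch-length optimization.  Returns the tree with
    optimized lengths, the M0 parameter estimates and the final lnL."""
    spec = CodonModelSpec("M0", codon_frequencies=codon_frequencies)
    freqs = empirical_codon_frequencies(aln, codon_frequencies)
    tree = tree.copy()
    params = dict(_DEFAULT_INIT["M0"])
    lnl = -np.inf
    for _ in range(n_rounds):
        def neg(x: np.ndarray) -> float:
            return -codon_log_likelihood(tree, aln, spec, _unpack(spec, x), freqs)

        res = minimize(neg, _pack(spec, params), method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-5, "maxfev": 300})
        params = _unpack(spec, res.x)
        lik = codon_likelihood(tree, aln, spec, params, freqs)
        lnl = optimize_branch_lengths(lik, tol=1e-5, max_passes=4)
        lik.flat.push_lengths()
    return tree, params, lnl


def fit_model(aln: CodonAlignment, tree: PhyloTree, spec: CodonModelSpec,
              n_restarts: int = 3, seed: int = 0,
              branch_lengths: str = "m0",
              freqs: np.ndarray | None = None,
              init: dict[str, float] | None = None,
              maxfev: int | None = None) -> ModelFit:
    """Maximum-likelihood fit of a codon model.

    branch_lengths: 'm0' re-optimizes lengths under M0 and fixes them (the
    default protocol), 'given' uses the tree's lengths as supplied, 'joint'
    alternates length and parameter optimization under the target model.
    """
    codes = codon_codes(aln)
    if np.all(codes.max(axis=0) == codes.min(axis=0)):
        raise ValueError("omega unidentifiable: alignment has no variation")
    if spec.is_branch_site and tree.foreground_edges() == 0:
        raise ValueError(f"{spec.name} requires foreground branch marks")
    if freqs is None:
        freqs = empirical_codon_frequencies(aln, spec.codon_frequencies)
    if branch_lengths == "m0":
        tree, _, _ = fit_m0_with_branch_lengths(
            aln, tree, spec.codon_frequencies)
    elif branch_lengths not in ("given", "joint"):
        raise ValueError("branch_lengths must be 'm0', 'given' or 'joint'")
    tree = tree.copy()

    def neg(x: np.ndarray) -> float:
        return -codon_log_likelihood(tree, aln, spec, _unpack(spec, x), freqs)

    rng = np.random.default_rng(seed)
    base = dict(_DEFAULT_INIT[spec.name])
    if init:
        base.update({k: v for k, v in init.items() if k in base})
    x0 = _pack(spec, base)
    best = None
    n_used = 0
    fev = maxfev or (150 * max(len(x0), 2))
    for r in range(n_restarts):
        start = x0 if r == 0 else x0 + rng.normal(scale=0.7, size=x0.size)
        res = minimize(neg, start, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxfev": fev})
        n_used = r + 1
        if best is None or res.fun < best.fun:
            best = res
    params = _unpack(spec, best.x)
    lnl = -float(best.fun)
    if branch_lengths == "joint":
        for _ in range(2):
            lik = codon_likelihood(tree, aln, spec, params, freqs)
            lnl = optimize_branch_lengths(lik, tol=1e-5, max_passes=3)
            lik.flat.push_lengths()
            res = minimize(neg, _pack(spec, params), method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6,
                                    "maxfev": fev})
            params = _unpack(spec, res.x)
            lnl = -float(res.fun)
    cs = class_structure(spec, params)
    return ModelFit(
        spec=spec, lnl=lnl, n_params=spec.n_params, params=params,
        omega_by_class=cs.omega_fg, class_weights=cs.weights,
        kappa_hat=params["kappa"], converged=bool(best.success),
        n_restarts_used=n_used, tree=tree, freqs=freqs)


# ---------------------------------------------------------------------------
# likelihood ratio tests

@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    stat: float
    dof: int
    p_value: float
    significant: bool


def run_lrt(null_fit: ModelFit, alt_fit: ModelFit,
            alpha: float = 0.05) -> LRTResult:
    pair = (null_fit.name, alt_fit.name)
    if pair not in LRT_REGISTRY:
        raise ValueError(
            f"unregistered nested pair {pair}; registered tests: "
            f"{sorted(LRT_REGISTRY)}")
    stat = 2.0 * (alt_fit.lnl - null_fit.lnl)
    if stat < 0:
        if stat < -0.1:
            warnings.warn(
                f"LRT {pair}: alternative lnL below null by {-stat/2:.3f}; "
                "optimizer convergence is suspect. Clamping statistic to 0.")
        stat = 0.0
    dof = LRT_REGISTRY[pair]
    p = float(stats.chi2.sf(stat, dof))
    return LRTResult(null_fit.name, alt_fit.name, float(stat), dof, p,
                     p < alpha)


# ---------------------------------------------------------------------------
# empirical Bayes site identification

CALL_THRESHOLDS = (0.50, 0.95, 0.99)


@dataclass
class SiteCallSet:
    method: str
    posterior: np.ndarray  # per-site P(omega > 1 class)
    calls: dict[float, list[int]]  # threshold -> 1-based alignment columns
    reference_positions: dict[int, int | None] | None = None

    def n_calls(self) -> dict[float, int]:
        return {t: len(v) for t, v in self.calls.items()}


def _selected_class_mask(spec: CodonModelSpec,
                         cs: ClassStructure) -> np.ndarray:
    """Which mixture classes count as the positively-selected class.

    Structural for models with a dedicated free class (M2's and M8's last
    class; the branch-site models' foreground classes 2a/2b); by the
    fitted omega for M3, whose classes are unconstrained.
    """
    k = cs.weights.size
    mask = np.zeros(k, dtype=bool)
    if spec.name in ("M2", "M8", "M8a"):
        mask[-1] = True
    elif spec.name in ("ModelA", "ModelAnull", "ModelB"):
        mask[2] = mask[3] = True
    else:
        mask = cs.omega_fg > 1.0
    return mask


def _posterior_to_calls(post: np.ndarray) -> dict[float, list[int]]:
    return {t: [int(i) + 1 for i in np.flatnonzero(post > t)]
            for t in CALL_THRESHOLDS}


def site_posteriors(fit: ModelFit, aln: CodonAlignment, method: str = "NEB",
                    reference_taxon: str | None = None,
                    grid_points: int = 10) -> SiteCallSet:
    """Per-site posterior membership in the omega>1 class(es).

    NEB evaluates the class posterior at the MLEs; BEB (M8 and ModelA only)
    averages over a uniform grid prior on the mixture parameters.
    """
    cs = class_structure(fit.spec, fit.params)
    if method == "BEB":
        if fit.spec.name not in ("M8", "ModelA"):
            raise ValueError("BEB is supported for M8 and ModelA only")
        post = _beb_posterior(fit, aln, grid_points)
    elif method == "NEB":
        if not _selected_class_mask(fit.spec, cs).any():
            raise ValueError(
                f"model {fit.name} has no omega>1 class to call sites from")
        post = _neb_posterior(fit, aln)
    else:
        raise ValueError("method must be 'NEB' or 'BEB'")
    refmap = None
    if reference_taxon is not None:
        from .annotate import map_to_reference
        refmap = map_to_reference(aln, reference_taxon,
                                  list(range(1, aln.n_codons + 1)))
    return SiteCallSet(method, post, _posterior_to_calls(post), refmap)


def _neb_posterior(fit: ModelFit, aln: CodonAlignment) -> np.ndarray:
    lik = codon_likelihood(fit.tree, aln, fit.spec, fit.params, fit.freqs)
    cls = lik.class_pattern_loglik()
    logw = np.log(np.clip(lik.class_weights, 1e-300, None))[:, None]
    post = cls + logw
    post -= post.max(axis=0)
    post = np.exp(post)
    post /= post.sum(axis=0)
    sel = _selected_class_mask(fit.spec, class_structure(fit.spec, fit.params))
    _, _, site_to_pat = compress_patterns(codon_codes(aln))
    return post[sel].sum(axis=0)[site_to_pat]


class _OmegaCurve:
    """Per-pattern site likelihoods as a function of omega, interpolated.

    Pruning is run once per omega grid node (single-class likelihood);
    intermediate omegas use linear interpolation of log-likelihood in omega.
    ``mark_omega`` fixes the foreground omega on marked branches (ModelA).
    """

    def __init__(self, fit: ModelFit, aln: CodonAlignment,
                 fg: bool = False) -> None:
        self.flat = FlatTree(fit.tree, aln.taxa)
        self.patterns, self.pweights, _ = compress_patterns(codon_codes(aln))
        self.fit = fit
        self.fg = fg

    def _single(self, omega_bg: float, omega_fg: float) -> np.ndarray:
        freqs = self.fit.freqs
        kappa = self.fit.params["kappa"]
        # scale must match the fitted model's mixture scale
        cs = class_structure(self.fit.spec, self.fit.params)
        q_bg_classes = [build_codon_matrix(kappa, om, freqs)
                        for om in cs.omega_bg]
        scale = sum(w * mean_rate(q, freqs)
                    for w, q in zip(cs.weights, q_bg_classes))
        tm = {0: TransitionMatrices(
            build_codon_matrix(kappa, omega_bg, freqs) / scale, freqs)}
        if self.fg:
            tm[1] = TransitionMatrices(
                build_codon_matrix(kappa, omega_fg, freqs) / scale, freqs)
        lik = MixtureLikelihood(self.flat, self.patterns, self.pweights,
                                [tm], np.ones(1))
        return lik.class_pattern_loglik()[0]


def _beb_posterior(fit: ModelFit, aln: CodonAlignment,
                   g: int) -> np.ndarray:
    if fit.spec.name == "M8":
        return _beb_m8(fit, aln, g)
    return _beb_model_a(fit, aln, g)


def _mid(lo: float, hi: float, g: int) -> np.ndarray:
    return lo + (np.arange(g) + 0.5) * (hi - lo) / g


def _beb_m8(fit: ModelFit, aln: CodonAlignment, g: int) -> np.ndarray:
    curve = _OmegaCurve(fit, aln)
    omega_nodes = np.concatenate([np.linspace(1e-6, 1.0, 21),
                                  np.linspace(1.25, 12.0, 12)])
    node_ll = np.stack([curve._single(om, om) for om in omega_nodes])
    n_pat = node_ll.shape[1]

    def ll_at(omegas: np.ndarray) -> np.ndarray:
        """(len(omegas), n_patterns) interpolated log site-likelihoods."""
        out = np.empty((omegas.size, n_pat))
        for i, om in enumerate(np.clip(omegas, omega_nodes[0], omega_nodes[-1])):
            j = np.searchsorted(omega_nodes, om)
            j = min(max(j, 1), omega_nodes.size - 1)
            w = (om - omega_nodes[j - 1]) / (omega_nodes[j] - omega_nodes[j - 1])
            out[i] = (1 - w) * node_ll[j - 1] + w * node_ll[j]
        return out

    p0_grid = _mid(0.0, 1.0, g)
    pq_grid = np.clip(_mid(0.0, 2.0, g), 5e-3, None)
    ws_grid = _mid(1.0, 11.0, g)
    pw = curve.pweights
    k = fit.spec.n_beta_bins
    log_marg = []
    sel_post = []
    for p in pq_grid:
        for q in pq_grid:
            bll = ll_at(beta_bin_means(p, q, k))  # (k, n_pat)
            for p0 in p0_grid:
                for ws in ws_grid:
                    sll = ll_at(np.array([ws]))  # (1, n_pat)
                    cls = np.vstack([bll, sll])
                    logw = np.log(np.concatenate(
                        [np.full(k, p0 / k), [1 - p0]]))[:, None]
                    joint = cls + logw
                    m = joint.max(axis=0)
                    mix = np.log(np.exp(joint - m).sum(axis=0)) + m
                    log_marg.append(float(mix @ pw))
                    sel_post.append(np.exp(joint[-1] - mix))
    log_marg = np.array(log_marg)
    log_marg -= log_marg.max()
    grid_post = np.exp(log_marg)
    grid_post /= grid_post.sum()
    post_pat = np.einsum("g,gp->p", grid_post, np.array(sel_post))
    _, _, site_to_pat = compress_patterns(codon_codes(aln))
    return post_pat[site_to_pat]


def _beb_model_a(fit: ModelFit, aln: CodonAlignment, g: int) -> np.ndarray:
    curve = _OmegaCurve(fit, aln, fg=True)
    w0_grid = _mid(0.0, 1.0, g)
    w2_grid = _mid(1.0, 11.0, g)
    u_grid = _mid(0.0, 1.0, g)
    # class site-likelihood tables
    ll_c0 = np.stack([curve._single(w0, w0) for w0 in w0_grid])
    ll_c1 = curve._single(1.0, 1.0)[None, :]
    ll_c2a = np.stack([[curve._single(w0, w2) for w2 in w2_grid]
                       for w0 in w0_grid])  # (g, g, n_pat)
    ll_c2b = np.stack([curve._single(1.0, w2) for w2 in w2_grid])
    pw = curve.pweights
    log_marg = []
    sel_post = []
    for i0, w0 in enumerate(w0_grid):
        for i2, w2 in enumerate(w2_grid):
            cls = np.vstack([ll_c0[i0], ll_c1, ll_c2a[i0, i2][None, :],
                             ll_c2b[i2][None, :]])
            for u0 in u_grid:
                for u1 in u_grid:
                    p0, p1 = u0, (1 - u0) * u1
                    rest = 1 - p0 - p1
                    denom = max(p0 + p1, 1e-12)
                    w = np.array([p0, p1, rest * p0 / denom,
                                  rest * p1 / denom])
                    logw = np.log(np.clip(w, 1e-300, None))[:, None]
                    joint = cls + logw
                    m = joint.max(axis=0)
                    mix = np.log(np.exp(joint - m).sum(axis=0)) + m
                    log_marg.append(float(mix @ pw))
                    sel_post.append(np.exp(joint[2] - mix) +
                                    np.exp(joint[3] - mix))
    log_marg = np.array(log_marg)
    log_marg -= log_marg.max()
    grid_post = np.exp(log_marg)
    grid_post /= grid_post.sum()
    post_pat = np.einsum("g,gp->p", grid_post, np.array(sel_post))
    _, _, site_to_pat = compress_patterns(codon_codes(aln))
    return post_pat[site_to_pat]


# ---------------------------------------------------------------------------
# branch-site scan

@dataclass
class ForegroundResult:
    foreground: str
    fits: dict[str, ModelFit]
    lrts: dict[str, LRTResult]
    sites: SiteCallSet | None

    def summary_row(self) -> dict:
        fit = self.fits["ModelA"]
        cs = class_structure(fit.spec, fit.params)
        p_sel = float(cs.weights[2] + cs.weights[3])
        return {
            "foreground": self.foreground,
            "ModelA_v_M1_p": self.lrts["ModelA_v_M1"].p_value,
            "ModelB_v_M3k2_p": self.lrts["ModelB_v_M3k2"].p_value,
            "P_percent": 100.0 * p_sel,
            "fwd_omega": fit.report_omega(fit.params["omega2"]),
            "bck_omega": f"{fit.params['omega0']:.3g}/1",
        }


def branch_site_scan(aln: CodonAlignment, tree: PhyloTree,
                     foregrounds: dict[str, list[str]],
                     seed: int = 0, n_restarts: int = 2,
                     codon_frequencies: str = "F3x4",
                     branch_lengths: str = "m0",
                     site_method: str = "BEB") -> dict[str, ForegroundResult]:
    """Branch-site selection scan over named foreground lineages.

    ``foregrounds`` maps a lineage name to the tip set whose stem branch is
    the foreground (a single tip marks that terminal branch).  Site models
    M1 and M3k2 are shared across foregrounds; Model A / A-null / B are fit
    per foreground with the two LRT ladders (ModelA v M1, ModelB v M3k2).
    """
    base = tree.copy()
    base.clear_marks()
    if branch_lengths == "m0":
        base, _, _ = fit_m0_with_branch_lengths(aln, base, codon_frequencies)
        branch_lengths = "given"
    m1 = fit_model(aln, base, CodonModelSpec("M1", codon_frequencies),
                   n_restarts=n_restarts, seed=seed,
                   branch_lengths=branch_lengths)
    m3 = fit_model(aln, base, CodonModelSpec("M3k2", codon_frequencies),
                   n_restarts=n_restarts, seed=seed + 1,
                   branch_lengths=branch_lengths)
    out: dict[str, ForegroundResult] = {}
    for name, tips in foregrounds.items():
        marked = base.copy()
        marked.clear_marks()
        marked.mark_foreground(tips)
        fits = {"M1": m1, "M3k2": m3}
        warm_a = {"p0": m1.params["p0"] * 0.95, "p1": 0.05,
                  "omega0": m1.params["omega0"], "omega2": 2.0,
                  "kappa": m1.params["kappa"]}
        fits["ModelA"] = fit_model(
            aln, marked, CodonModelSpec("ModelA", codon_frequencies),
            n_restarts=n_restarts, seed=seed + 2, branch_lengths="given",
            init=warm_a)
        fits["ModelAnull"] = fit_model(
            aln, marked, CodonModelSpec("ModelAnull", codon_frequencies),
            n_restarts=n_restarts, seed=seed + 3, branch_lengths="given",
            init=warm_a)
        warm_b = {"p0": m3.params["p0"] * 0.95, "p1": 0.05,
                  "omega0": min(m3.params["omega0"], 0.95),
                  "omega1": m3.params["omega1"], "omega2": 2.0,
                  "kappa": m3.params["kappa"]}
        fits["ModelB"] = fit_model(
            aln, marked, CodonModelSpec("ModelB", codon_frequencies),
            n_restarts=n_restarts, seed=seed + 4, branch_lengths="given",
            init=warm_b)
        lrts = {
            "ModelA_v_M1": run_lrt(m1, fits["ModelA"]),
            "ModelA_v_ModelAnull": run_lrt(fits["ModelAnull"], fits["ModelA"]),
            "ModelB_v_M3k2": run_lrt(m3, fits["ModelB"]),
        }
        sites = None
        if lrts["ModelA_v_M1"].significant:
            sites = site_posteriors(fits["ModelA"], aln, method=site_method)
        out[name] = ForegroundResult(name, fits, lrts, sites)
    return out
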