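"""Alignment quality screens: composition bias and likelihood mapping.

The composition test compares each sequence's residue (or base) composition
to the pooled frequencies of the whole alignment by chi-square.  Likelihood
mapping scores phylogenetic signal by dropping every sampled quartet onto
the standard three-topology probability simplex: quartets near a corner
support one resolved topology, edge quartets are torn between two, and
central quartets carry no signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .alignments import CodonAlignment, ProteinAlignment
from .engine import aa_codes, make_likelihood, resolve_model
from .likelihood import optimize_branch_lengths
from .substmodels import SubstitutionModelSpec
from .trees import PhyloTree

AA_SYMBOLS = "ARNDCQEGHILKMFPSTWYV"
NT_SYMBOLS = "ACGT"


@dataclass
class CompositionTestResult:
    taxon: str
    chi2_stat: float
    dof: int
    p_value: float
    passed: bool


def _symbol_counts(rows: list[str], symbols: str) -> np.ndarray:
    lut = {s: i for i, s in enumerate(symbols)}
    counts = np.zeros((len(rows), len(symbols)))
    for r, row in enumerate(rows):
        for ch in row:
            i = lut.get(ch)
            if i is not None:
                counts[r, i] += 1
    return counts


def _merge_small_expected(obs: np.ndarray, exp: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Merge categories with expected count < 1 into the nearest-frequency one."""
    obs, exp = obs.copy(), exp.copy()
    while exp.size > 1 and exp.min() < 1.0:
        i = int(exp.argmin())
        others = np.delete(np.arange(exp.size), i)
        j = others[int(np.abs(exp[others] - exp[i]).argmin())]
        obs[j] += obs[i]
        exp[j] += exp[i]
        obs, exp = np.delete(obs, i), np.delete(exp, i)
    return obs, exp


def composition_bias_test(aln: ProteinAlignment | CodonAlignment,
                          level: str | None = None
                          ) -> list[CompositionTestResult]:
    """Per-taxon chi-square composition test against pooled frequencies.

    ``level`` is 'aa' for protein alignments, 'nt' for codon alignments
    (all three codon positions pooled, dof = 3); inferred when omitted.
    """
    if level is None:
        level = "nt" if isinstance(aln, CodonAlignment) else "aa"
    symbols = NT_SYMBOLS if level == "nt" else AA_SYMBOLS
    if aln.n_taxa < 4:
        raise ValueError("composition test needs >= 4 taxa")
    counts = _symbol_counts(aln.rows, symbols)
    pooled = counts.sum(axis=0)
    pooled_freq = pooled / pooled.sum()
    out = []
    for r, taxon in enumerate(aln.taxa):
        n = counts[r].sum()
        if n == 0:
            raise ValueError(f"taxon {taxon!r} has no unambiguous symbols")
        obs, exp = _merge_small_expected(counts[r], pooled_freq * n)
        stat = float(((obs - exp) ** 2 / exp).sum())
        dof = obs.size - 1
        p = float(stats.chi2.sf(stat, dof))
        out.append(CompositionTestResult(taxon, stat, dof, p, p >= 0.05))
    return out


# ---------------------------------------------------------------------------
# likelihood mapping

REGIONS = ("corner_1", "corner_2", "corner_3",
           "edge_12", "edge_13", "edge_23", "center")


@dataclass
class QuartetMap:
    n_quartets: int
    region_counts: dict[str, int]
    seed: int = 0

    @property
    def corner_fraction(self) -> float:
        return sum(self.region_counts[f"corner_{i}"] for i in (1, 2, 3)) \
            / self.n_quartets

    @property
    def edge_fraction(self) -> float:
        return sum(self.region_counts[k] for k in
                   ("edge_12", "edge_13", "edge_23")) / self.n_quartets

    @property
    def center_fraction(self) -> float:
        return self.region_counts["center"] / self.n_quartets


def assign_region(weights: np.ndarray) -> str:
    """Map posterior topology weights (3-vector) to one of the 7 regions."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    order = np.argsort(w)[::-1]
    if w[order[0]] > 2.0 / 3.0:
        return f"corner_{order[0] + 1}"
    if w[order[2]] < 1.0 / 3.0:
        a, b = sorted((order[0] + 1, order[1] + 1))
        return f"edge_{a}{b}"
    return "center"


def _quartet_weights(aln: ProteinAlignment, quartet: tuple[int, ...],
                     model: SubstitutionModelSpec) -> np.ndarray:
    i, j, k, l = (aln.taxa[q] for q in quartet)
    sub = ProteinAlignment([i, j, k, l],
                           [aln.rows[q] for q in quartet])
    topos = [f"(({i}:0.1,{j}:0.1):0.05,({k}:0.1,{l}:0.1):0.05);",
             f"(({i}:0.1,{k}:0.1):0.05,({j}:0.1,{l}:0.1):0.05);",
             f"(({i}:0.1,{l}:0.1):0.05,({j}:0.1,{k}:0.1):0.05);"]
    lnls = np.empty(3)
    for t_i, nwk in enumerate(topos):
        lik = make_likelihood(PhyloTree.from_newick(nwk), sub, model)
        lnls[t_i] = optimize_branch_lengths(lik, tol=1e-4, max_passes=4)
    w = np.exp(lnls - lnls.max())
    return w / w.sum()


def likelihood_map(aln: ProteinAlignment,
                   model: SubstitutionModelSpec | None = None,
                   n_quartets: int | None = 200, seed: int = 0) -> QuartetMap:
    """ML likelihood mapping over sampled (or all) quartets.

    Quartets are enumerated exhaustively when C(n,4) <= n_quartets, else
    sampled without replacement with the given seed.
    """
    if aln.n_taxa < 4:
        raise ValueError("likelihood mapping needs >= 4 taxa")
    model = resolve_model(aln, model or SubstitutionModelSpec(plus_G=True))
    all_quartets = list(combinations(range(aln.n_taxa), 4))
    if n_quartets is None or len(all_quartets) <= n_quartets:
        chosen = all_quartets
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(all_quartets), size=n_quartets, replace=False)
        chosen = [all_quartets[i] for i in sorted(idx)]
    counts = {r: 0 for r in REGIONS}
    for quartet in chosen:
        counts[assign_region(_quartet_weights(aln, quartet, model))] += 1
    return QuartetMap(len(chosen), counts, seed=seed)


@dataclass
class SignalCategory:
    category: int
    thresholds: dict[str, float] = field(default_factory=dict)


def classify_signal(qmap: QuartetMap, c1: float = 0.9, z1: float = 0.05,
                    c2: float = 0.7) -> SignalCategory:
    """Three-way phylogenetic-signal gate.

    Category 1 (strong): corner fraction >= c1 and center fraction <= z1;
    category 3 (low/none): corner fraction < c2; otherwise category 2.
    """
    if not (0.0 <= c2 <= c1 <= 1.0):
        raise ValueError("thresholds must satisfy 0 <= c2 <= c1 <= 1")
    thresholds = {"c1": c1, "z1": z1, "c2": c2}
    if qmap.corner_fraction >= c1 and qmap.center_fraction <= z1:
        return SignalCategory(1, thresholds)
    if qmap.corner_fraction < c2:
        return SignalCategory(3, thresholds)
    return SignalCategory(2, thresholds)
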