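"""Tree-to-tree comparison: nodal-distance RMSD and the SH test.

The nodal distance counts edges on the unrooted tip-to-tip path; RMSD of
the two trees' path matrices is 0 iff the matrices agree.  The
Shimodaira-Hasegawa test compares candidate topologies on one alignment via
per-site log-likelihoods and RELL bootstrap of centered differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignments import ProteinAlignment
from .engine import aa_codes, make_likelihood, resolve_model
from .likelihood import compress_patterns, optimize_branch_lengths
from .substmodels import SubstitutionModelSpec
from .trees import PhyloTree


@dataclass
class NodalComparison:
    rmsd: float
    n_pairs: int
    pruned_taxa: list[str]


def nodal_rmsd(t1: PhyloTree, t2: PhyloTree) -> NodalComparison:
    """RMSD between unrooted tip-pair path-length (edge count) matrices.

    Trees are pruned to their shared taxa; polytomies simply shorten paths.
    Symmetric in argument order; 0 iff the path matrices are identical.
    """
    shared = sorted(set(t1.taxa) & set(t2.taxa))
    if len(shared) < 4:
        raise ValueError(
            f"need >= 4 shared taxa for nodal RMSD, got {len(shared)}")
    pruned = sorted((set(t1.taxa) | set(t2.taxa)) - set(shared))
    a = t1.prune_to(shared) if set(t1.taxa) != set(shared) else t1
    b = t2.prune_to(shared) if set(t2.taxa) != set(shared) else t2
    pa, pb = a.path_edge_counts(), b.path_edge_counts()
    diffs = np.array([pa[pair] - pb[pair] for pair in pa])
    return NodalComparison(float(np.sqrt(np.mean(diffs ** 2.0))),
                           len(diffs), pruned)


@dataclass
class SHResult:
    p_gene: float
    p_ideal: float
    best_fit: str  # {"gene", "ideal", "NS"}
    n_rell: int
    seed: int
    lnl_gene: float = 0.0
    lnl_ideal: float = 0.0


def _site_logliks(tree: PhyloTree, aln: ProteinAlignment,
                  model: SubstitutionModelSpec) -> tuple[np.ndarray, float]:
    lik = make_likelihood(tree, aln, model)
    lnl = optimize_branch_lengths(lik, tol=1e-4, max_passes=5, xatol=1e-4)
    per_pattern = lik.pattern_loglik()
    _, _, site_to_pat = compress_patterns(aa_codes(aln))
    return per_pattern[site_to_pat], lnl


def sh_test(aln: ProteinAlignment, trees: list[PhyloTree],
            model: SubstitutionModelSpec | None = None,
            n_rell: int = 1000, seed: int = 0, alpha: float = 0.05) -> SHResult:
    """Shimodaira-Hasegawa test of two or more topologies on one alignment.

    Branch lengths are re-optimized per tree; one-sided p-values per tree
    against the best tree come from an RELL bootstrap of centered per-site
    log-likelihood sums.  The best tree's p is 1 by the centering convention;
    best_fit is "NS" when no tree is rejected at ``alpha``.
    """
    if len(trees) < 2:
        raise ValueError("need at least two trees")
    taxa_sets = {frozenset(t.taxa) for t in trees}
    if len(taxa_sets) != 1:
        raise ValueError("trees have different taxon sets")
    if taxa_sets.pop() != set(aln.taxa):
        raise ValueError("trees do not span the alignment's taxa")
    model = resolve_model(aln, model or SubstitutionModelSpec(plus_G=True))
    site_l = []
    totals = []
    for tree in trees:
        sl, lnl = _site_logliks(tree.copy(), aln, model)
        site_l.append(sl)
        totals.append(lnl)
    site_l = np.asarray(site_l)          # (n_trees, n_sites)
    totals = site_l.sum(axis=1)
    best = int(np.argmax(totals))
    delta = totals[best] - totals        # observed lnL deficits, >= 0
    rng = np.random.default_rng(seed)
    n_sites = site_l.shape[1]
    idx = rng.integers(0, n_sites, size=(n_rell, n_sites))
    boot = site_l[:, idx].sum(axis=2)    # (n_trees, n_rell)
    centered = boot - boot.mean(axis=1, keepdims=True)
    dmax = centered.max(axis=0)          # (n_rell,)
    p = ((dmax[None, :] - centered) >= delta[:, None]).mean(axis=1)
    p[best] = 1.0
    names = ["gene", "ideal"] + [f"tree_{i}" for i in range(2, len(trees))]
    if p.min() >= alpha:
        best_fit = "NS"
    else:
        best_fit = names[best]
    return SHResult(float(p[0]), float(p[1]), best_fit, n_rell, seed,
                    lnl_gene=float(totals[0]), lnl_ideal=float(totals[1]))
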