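"""Felsenstein pruning over an arbitrary finite state space.

One engine serves the 20-state amino-acid models and the 61-state codon
models, including rate/omega mixtures and branch-class (foreground vs
background) transition matrices.  Columns are pattern-compressed; per-node
rescaling keeps partial likelihoods in range on deep trees.
"""

from __future__ import annotations

import numpy as np

from .substmodels import TransitionMatrices
from .trees import PhyloTree

MISSING = -1


class FlatTree:
    """Indexed postorder view of a PhyloTree tied to an alignment's taxa order."""

    def __init__(self, tree: PhyloTree, taxa: list[str]) -> None:
        taxon_row = {t: i for i, t in enumerate(taxa)}
        tree_taxa = set(tree.taxa)
        if tree_taxa != set(taxa):
            raise ValueError(
                "tree/alignment taxa mismatch; only in tree: "
                f"{sorted(tree_taxa - set(taxa))}, only in alignment: "
                f"{sorted(set(taxa) - tree_taxa)}")
        self.tree = tree
        nodes = list(tree.d.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root = self.n_nodes - 1
        self.children: list[list[int]] = [
            [self.index[id(c)] for c in n.child_nodes()] for n in nodes]
        self.lengths = np.array([
            n.edge.length if n.parent_node is not None else 0.0 for n in nodes])
        self.marks = np.array([
            getattr(n.edge, "phyloselect_mark", 0) if n.parent_node is not None
            else 0 for n in nodes], dtype=int)
        self.tip_row = np.array([
            taxon_row[n.taxon.label] if n.is_leaf() else -1 for n in nodes],
            dtype=int)
        self._nodes = nodes

    def push_lengths(self) -> None:
        """Write the (possibly optimizer-modified) lengths back to the tree."""
        for i, n in enumerate(self._nodes):
            if n.parent_node is not None:
                n.edge.length = float(self.lengths[i])


def compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse identical columns.

    codes: (n_taxa, n_sites) integer states with MISSING for gaps/ambiguity.
    Returns (patterns (n_taxa, n_patterns), weights, site_to_pattern).
    """
    cols, inverse, counts = np.unique(
        codes.T, axis=0, return_inverse=True, return_counts=True)
    return cols.T.copy(), counts.astype(float), inverse


class MixtureLikelihood:
    """Mixture pruning likelihood with cached per-edge transition matrices.

    ``tms[c]`` maps a branch mark to the TransitionMatrices of mixture class
    ``c`` (mark 0 = background; branch-site models add mark 1).
    ``rates[c]`` multiplies branch lengths for class ``c``.
    """

    def __init__(self, flat: FlatTree, patterns: np.ndarray,
                 pattern_weights: np.ndarray,
                 tms: list[dict[int, TransitionMatrices]],
                 class_weights: np.ndarray,
                 class_rates: np.ndarray | None = None) -> None:
        self.flat = flat
        self.patterns = patterns
        self.pattern_weights = pattern_weights
        self.tms = tms
        self.class_weights = np.asarray(class_weights, dtype=float)
        self.n_classes = len(tms)
        self.rates = (np.ones(self.n_classes) if class_rates is None
                      else np.asarray(class_rates, dtype=float))
        self.n_states = tms[0][0].freqs.size
        self.n_patterns = patterns.shape[1]
        # one batched-eigen path when every class shares one background TM
        # (amino-acid rate mixtures); otherwise per-class updates
        self._shared_tm = (
            all(len(d) == 1 and 0 in d for d in tms)
            and len({id(d[0]) for d in tms}) == 1)
        # P^T with an appended all-ones row so missing tips index row S
        self._pt = np.ones(
            (self.n_classes, flat.n_nodes, self.n_states + 1, self.n_states))
        self._freqs = np.stack([d[0].freqs for d in tms])
        self.refresh()
        self._tip_idx = np.where(patterns < 0, self.n_states, patterns)

    def _update_edge(self, e: int) -> None:
        flat = self.flat
        t = float(flat.lengths[e])
        if self._shared_tm:
            tm = self.tms[0][0]
            ew = np.exp(np.outer(self.rates * t, tm._w))  # (c, S)
            p = (tm._left[None, :, :] * ew[:, None, :]) @ tm._right[None]
            np.clip(p, 1e-300, None, out=p)
            self._pt[:, e, :self.n_states, :] = p.transpose(0, 2, 1)
            return
        for c in range(self.n_classes):
            tm = self.tms[c].get(int(flat.marks[e]), self.tms[c][0])
            p = tm.probability(t * float(self.rates[c]))
            self._pt[c, e, :self.n_states, :] = p.T

    def set_length(self, e: int, t: float) -> None:
        self.flat.lengths[e] = t
        self._update_edge(e)

    def refresh(self) -> None:
        for e in range(self.flat.n_nodes):
            if e != self.flat.root:
                self._update_edge(e)

    def class_pattern_loglik(self) -> np.ndarray:
        """(n_classes, n_patterns) log P(pattern | class)."""
        flat = self.flat
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros((self.n_classes, self.n_patterns))
        for v in range(flat.n_nodes):
            kids = flat.children[v]
            if not kids:
                continue
            acc: np.ndarray | None = None
            for ch in kids:
                pt = self._pt[:, ch]
                if flat.tip_row[ch] >= 0:
                    factor = pt[:, self._tip_idx[flat.tip_row[ch]], :]
                else:
                    factor = partials.pop(ch) @ pt[:, :self.n_states, :]
                acc = factor if acc is None else acc * factor
            m = acc.max(axis=2)
            m[m == 0.0] = 1.0
            acc /= m[:, :, None]
            logscale += np.log(m)
            partials[v] = acc
        site = np.einsum("cps,cs->cp", partials[flat.root], self._freqs)
        return np.log(np.clip(site, 1e-300, None)) + logscale

    def pattern_loglik(self) -> np.ndarray:
        cls = self.class_pattern_loglik()
        m = cls.max(axis=0)
        mix = np.log(
            (self.class_weights[:, None] * np.exp(cls - m)).sum(axis=0)) + m
        return mix

    def lnl(self) -> float:
        return float(self.pattern_loglik() @ self.pattern_weights)


def optimize_branch_lengths(lik: MixtureLikelihood, tol: float = 1e-6,
                            max_passes: int = 8, max_length: float = 25.0,
                            min_length: float = 1e-8,
                            xatol: float = 1e-5) -> float:
    """Coordinate-wise Brent over branch lengths; >= 2 full passes.

    Returns the final log-likelihood; the optimized lengths live in
    ``lik.flat.lengths`` (call ``lik.flat.push_lengths()`` to write back).
    """
    from scipy.optimize import minimize_scalar

    edges = [e for e in range(lik.flat.n_nodes) if e != lik.flat.root]
    current = lik.lnl()
    for sweep in range(max_passes):
        before = current
        for e in edges:
            t0 = lik.flat.lengths[e]

            def neg(t: float, _e: int = e) -> float:
                lik.set_length(_e, t)
                return -lik.lnl()

            res = minimize_scalar(
                neg, bounds=(min_length, max_length), method="bounded",
                options={"xatol": xatol})
            if -res.fun >= current:
                lik.set_length(e, float(res.x))
                current = -res.fun
            else:  # numerical non-improvement: keep the old length
                lik.set_length(e, t0)
        if sweep >= 1 and current - before < tol:
            break
    return current
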