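"""Synthetic data generators.

Simulates codon alignments under site and branch-site omega-mixtures,
protein alignments under JTT+G (with optional exaggerated long branches and
per-taxon composition bias), and feature/site placements for calibrating
the proximity randomization test.  All generators are deterministic given
(recipe, seed).

The default demonstration tree is a 12-taxon mammal topology at the
paper-scale taxon count, with fixed branch lengths in the 0.02-0.3 range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignments import CodonAlignment, ProteinAlignment
from .codon import (ClassStructure, CodonModelSpec, build_codon_matrix,
                    class_structure, mean_rate)
from .gencode import sense_codons
from .substmodels import (JTT_FREQS, SubstitutionModelSpec,
                          TransitionMatrices, build_rate_matrix)
from .likelihood import FlatTree
from .trees import PhyloTree, star_tree  # star_tree re-exported for recipes
from .gencode import AMINO_ACIDS

MAMMAL_TREE_NEWICK = (
    "(((((Human:0.02,Chimp:0.02):0.03,Macaque:0.06):0.05,"
    "((Mouse:0.15,Rat:0.14):0.08,GuineaPig:0.2):0.06):0.03,"
    "(Rabbit:0.18,Pika:0.2):0.05):0.04,"
    "((Dog:0.11,Cow:0.13):0.03,Horse:0.1):0.04,Opossum:0.3);"
)


def mammal_tree() -> PhyloTree:
    return PhyloTree.from_newick(MAMMAL_TREE_NEWICK)


# Six-taxon balanced topology with short internal branches: the stock
# scenario for long-branch attraction, with the A and C terminal branches
# lengthened via lba_scale in the recipes that exercise it.
LBA_FIXTURE_NEWICK = ("((A:0.06,B:0.06):0.015,(C:0.06,D:0.06):0.015,"
                      "(E:0.06,F:0.06):0.015);")


def lba_fixture_tree() -> PhyloTree:
    return PhyloTree.from_newick(LBA_FIXTURE_NEWICK)


@dataclass
class SimulationRecipe:
    """Everything needed to regenerate a dataset byte-for-byte."""

    tree: PhyloTree
    model: CodonModelSpec | SubstitutionModelSpec
    params: dict = field(default_factory=dict)
    n_sites: int = 300
    seed: int = 0
    lba_scale: dict[str, float] = field(default_factory=dict)
    bias_taxa: dict[str, str] = field(default_factory=dict)
    bias_fraction: float = 0.5

    def describe(self) -> str:
        model = getattr(self.model, "name", str(self.model))
        return (f"model={model} params={self.params} n_sites={self.n_sites} "
                f"seed={self.seed} lba_scale={self.lba_scale} "
                f"bias_taxa={self.bias_taxa}")


def _scaled_tree(tree: PhyloTree, lba_scale: dict[str, float]) -> PhyloTree:
    t = tree.copy()
    for name, factor in lba_scale.items():
        node = t.d.find_node_with_taxon_label(name)
        if node is None:
            raise ValueError(f"lba_scale names unknown taxon {name!r}")
        node.edge.length *= factor
    return t


def _evolve(flat: FlatTree, root_states: np.ndarray,
            p_per_edge: list, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Propagate states from the root down every edge; returns tip states."""
    n_sites = root_states.size
    states = {flat.root: root_states}
    order = list(range(flat.n_nodes - 1, -1, -1))  # preorder-ish (parents first)
    tips: dict[int, np.ndarray] = {}
    for v in order:
        for ch in flat.children[v]:
            p = p_per_edge[ch]  # (n_sites_classesless) transition matrices
            parent_states = states[v]
            u = rng.random(n_sites)
            cdf = p[parent_states].cumsum(axis=1)
            child = (u[:, None] > cdf).sum(axis=1)
            states[ch] = child
            if flat.tip_row[ch] >= 0:
                tips[int(flat.tip_row[ch])] = child
    return tips


def simulate_codon_alignment(recipe: SimulationRecipe
                             ) -> tuple[CodonAlignment, np.ndarray]:
    """Simulate codons under a site/branch-site omega mixture.

    Per site a mixture class is drawn; the root codon comes from the
    stationary frequencies; evolution runs along each branch under the
    class's (branch-specific, for foreground marks) transition matrix.
    Returns the alignment and the true per-site class labels.
    """
    if not isinstance(recipe.model, CodonModelSpec):
        raise TypeError("codon simulation needs a CodonModelSpec")
    rng = np.random.default_rng(recipe.seed)
    freqs = recipe.params.get("codon_freqs")
    if freqs is None:
        freqs = np.full(61, 1.0 / 61)
    cs: ClassStructure = class_structure(recipe.model, recipe.params)
    kappa = recipe.params["kappa"]
    tree = _scaled_tree(recipe.tree, recipe.lba_scale)
    flat = FlatTree(tree, tree.taxa)
    q_bg = [build_codon_matrix(kappa, om, freqs) for om in cs.omega_bg]
    scale = sum(w * mean_rate(q, freqs) for w, q in zip(cs.weights, q_bg))
    labels = rng.choice(cs.weights.size, size=recipe.n_sites, p=cs.weights)
    root = rng.choice(61, size=recipe.n_sites, p=freqs / freqs.sum())
    tip_states = {r: np.empty(recipe.n_sites, dtype=int)
                  for r in range(len(tree.taxa))}
    for c in np.unique(labels):
        sites = np.flatnonzero(labels == c)
        tm_bg = TransitionMatrices(q_bg[c] / scale, freqs)
        tm_fg = TransitionMatrices(
            build_codon_matrix(kappa, cs.omega_fg[c], freqs) / scale, freqs)
        p_per_edge = [
            (tm_fg if flat.marks[e] else tm_bg).probability(flat.lengths[e])
            for e in range(flat.n_nodes)]
        tips = _evolve(flat, root[sites], p_per_edge,
                       np.random.default_rng(rng.integers(2 ** 31)))
        for r, st in tips.items():
            tip_states[r][sites] = st
    codons = sense_codons()
    taxa = tree.taxa
    rows = ["".join(codons[s] for s in tip_states[r])
            for r in range(len(taxa))]
    return CodonAlignment(list(taxa), rows, id=recipe.describe()), labels


def simulate_protein_alignment(recipe: SimulationRecipe) -> ProteinAlignment:
    """Simulate residues under JTT(+G), with optional LBA and bias perturbations.

    ``lba_scale`` multiplies the named taxa's terminal branch lengths.
    ``bias_taxa`` maps a taxon to a residue whose frequency is inflated by
    resampling a ``bias_fraction`` of that row's sites toward it.
    """
    model = recipe.model
    if not isinstance(model, SubstitutionModelSpec):
        raise TypeError("protein simulation needs a SubstitutionModelSpec")
    rng = np.random.default_rng(recipe.seed)
    freqs = model.freqs() if not model.plus_F else JTT_FREQS
    tm = TransitionMatrices(build_rate_matrix(freqs), freqs)
    rates, weights = model.rate_mixture()
    tree = _scaled_tree(recipe.tree, recipe.lba_scale)
    flat = FlatTree(tree, tree.taxa)
    site_rates = rates[rng.choice(rates.size, size=recipe.n_sites, p=weights)]
    root = rng.choice(20, size=recipe.n_sites, p=freqs)
    tip_states = {r: np.empty(recipe.n_sites, dtype=int)
                  for r in range(len(tree.taxa))}
    for rate in np.unique(site_rates):
        sites = np.flatnonzero(site_rates == rate)
        p_per_edge = [tm.probability(rate * flat.lengths[e])
                      for e in range(flat.n_nodes)]
        tips = _evolve(flat, root[sites], p_per_edge,
                       np.random.default_rng(rng.integers(2 ** 31)))
        for r, st in tips.items():
            tip_states[r][sites] = st
    taxa = tree.taxa
    rows = []
    for r, taxon in enumerate(taxa):
        states = tip_states[r]
        if taxon in recipe.bias_taxa:
            target = AMINO_ACIDS.index(recipe.bias_taxa[taxon])
            n_flip = int(recipe.bias_fraction * recipe.n_sites)
            flip = rng.choice(recipe.n_sites, size=n_flip, replace=False)
            states = states.copy()
            states[flip] = target
        rows.append("".join(AMINO_ACIDS[s] for s in states))
    return ProteinAlignment(list(taxa), rows, id=recipe.describe())


def mask_gaps(aln: ProteinAlignment, fraction: float,
              seed: int = 0) -> ProteinAlignment:
    """Uniformly replace a fraction of residues with gaps (I/O testing only)."""
    rng = np.random.default_rng(seed)
    rows = []
    for row in aln.rows:
        chars = np.array(list(row))
        mask = rng.random(chars.size) < fraction
        chars[mask] = "-"
        rows.append("".join(chars))
    return ProteinAlignment(list(aln.taxa), rows, id=aln.id)


def simulate_features(reference_length: int, n_features: int, n_sites: int,
                      placement: str = "uniform", cluster_width: int = 2,
                      seed: int = 0):
    """Place feature positions and candidate sites on a reference sequence.

    uniform: both sets drawn uniformly without replacement (the null of the
    proximity test).  clustered: sites placed within ``cluster_width``
    residues of randomly chosen features (the power scenario).
    Returns (FeatureSet, sites list), both 1-based.
    """
    from .annotate import FeatureSet
    if n_features + n_sites > reference_length:
        raise ValueError("more features+sites than reference positions")
    rng = np.random.default_rng(seed)
    positions = rng.choice(reference_length, size=n_features, replace=False) + 1
    features = FeatureSet(
        reference_length=reference_length,
        features=[(int(p), f"feat{i}", "simulated")
                  for i, p in enumerate(sorted(positions))])
    if placement == "uniform":
        sites = rng.choice(reference_length, size=n_sites, replace=False) + 1
    elif placement == "clustered":
        centers = rng.choice(positions, size=n_sites, replace=True)
        offsets = rng.integers(-cluster_width, cluster_width + 1, size=n_sites)
        sites = np.clip(centers + offsets, 1, reference_length)
    else:
        raise ValueError("placement must be 'uniform' or 'clustered'")
    return features, sorted(int(s) for s in sites)
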