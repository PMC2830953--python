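"""Phylogenetic tree container built on dendropy.

Trees are kept in unrooted form (the seed node is a basal multifurcation
after derooting).  Foreground branch marks use the ``#1`` Newick dialect on
tips or internal nodes and are preserved through parsing and writing.
"""

from __future__ import annotations

import re

import dendropy

_MARK_RE = re.compile(r"#(\d+)$")


class TreeError(ValueError):
    pass


class PhyloTree:
    """Unrooted tree with branch lengths, optional polytomies and marks.

    Foreground marks live on edges; ``node.edge.phyloselect_mark`` is an int
    (0 = background).
    """

    def __init__(self, dtree: dendropy.Tree) -> None:
        dtree.is_rooted = False
        if len(dtree.seed_node.child_nodes()) == 2 and len(dtree.leaf_nodes()) > 2:
            dtree.deroot()
        self.d = dtree
        for node in self.d:
            if not hasattr(node.edge, "phyloselect_mark"):
                node.edge.phyloselect_mark = 0
            if node.edge.length is None:
                node.edge.length = 0.0
            node.edge.length = max(0.0, float(node.edge.length))

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True)
        marks: list[tuple[dendropy.Node, int]] = []
        for node in dtree:
            label = node.taxon.label if node.taxon else node.label
            if label:
                m = _MARK_RE.search(label)
                if m:
                    marks.append((node, int(m.group(1))))
                    stripped = label[:m.start()]
                    if node.taxon:
                        node.taxon.label = stripped
                    else:
                        node.label = stripped or None
        tree = cls(dtree)
        for node, mark in marks:
            node.edge.phyloselect_mark = mark
        return tree

    @classmethod
    def from_file(cls, path: str) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, lengths: bool = True, marks: bool = True) -> str:
        def node_repr(node: dendropy.Node) -> str:
            if node.is_leaf():
                s = node.taxon.label
            else:
                s = "(" + ",".join(node_repr(c) for c in node.child_nodes()) + ")"
            mark = getattr(node.edge, "phyloselect_mark", 0)
            if marks and mark:
                s += f"#{mark}"
            if lengths and node.parent_node is not None:
                s += f":{node.edge.length:.10g}"
            return s

        return node_repr(self.d.seed_node) + ";"

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def copy(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick())

    # -- basic queries -----------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.d.leaf_node_iter()]

    @property
    def n_taxa(self) -> int:
        return len(self.d.leaf_nodes())

    def total_length(self) -> float:
        return sum(n.edge.length for n in self.d if n.parent_node is not None)

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions as frozensets of tip labels (smaller side)."""
        all_taxa = frozenset(self.taxa)
        out: set[frozenset[str]] = set()
        for node in self.d.postorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(below) < len(all_taxa) - 1:
                other = all_taxa - below
                if (len(below), tuple(sorted(below))) <= \
                        (len(other), tuple(sorted(other))):
                    out.add(below)
                else:
                    out.add(other)
        return out

    def same_unrooted_topology(self, other: "PhyloTree") -> bool:
        if set(self.taxa) != set(other.taxa):
            return False
        return self.splits() == other.splits()

    # -- editing -----------------------------------------------------------
    def prune_to(self, taxa: list[str]) -> "PhyloTree":
        keep = set(taxa)
        missing = keep - set(self.taxa)
        if missing:
            raise TreeError(f"taxa absent from tree: {sorted(missing)}")
        t = self.copy()
        t.d.retain_taxa_with_labels(sorted(keep))
        return PhyloTree(t.d)

    def mark_foreground(self, tips: list[str], mark: int = 1) -> None:
        """Mark the branch above the MRCA of ``tips`` (the clade stem).

        A single tip name marks that terminal branch.
        """
        missing = set(tips) - set(self.taxa)
        if missing:
            raise TreeError(f"foreground taxa absent from tree: {sorted(missing)}")
        if len(tips) == 1:
            node = self.d.find_node_with_taxon_label(tips[0])
        else:
            node = self.d.mrca(taxon_labels=tips)
            if node is self.d.seed_node:
                raise TreeError(
                    f"clade {sorted(tips)} spans the (unrooted) root; "
                    "cannot identify a stem branch")
        node.edge.phyloselect_mark = mark

    def clear_marks(self) -> None:
        for node in self.d:
            node.edge.phyloselect_mark = 0

    def foreground_edges(self) -> int:
        return sum(1 for n in self.d if getattr(n.edge, "phyloselect_mark", 0))

    # -- metrics -----------------------------------------------------------
    def path_edge_counts(self) -> dict[frozenset[str], int]:
        """Unrooted tip-pair path lengths counted in edges."""
        leaves = self.d.leaf_nodes()
        # node -> {leaf_label: depth} accumulated postorder
        out: dict[frozenset[str], int] = {}
        below: dict[dendropy.Node, dict[str, int]] = {}
        for node in self.d.postorder_node_iter():
            if node.is_leaf():
                below[node] = {node.taxon.label: 0}
                continue
            groups = [
                {lab: d + 1 for lab, d in below.pop(c).items()}
                for c in node.child_nodes()
            ]
            merged: dict[str, int] = {}
            for gi, g in enumerate(groups):
                for gj in range(gi + 1, len(groups)):
                    for la, da in g.items():
                        for lb, db in groups[gj].items():
                            out[frozenset((la, lb))] = da + db
                merged.update(g)
            below[node] = merged
        assert len(out) == len(leaves) * (len(leaves) - 1) // 2
        return out

    # -- NNI ---------------------------------------------------------------
    def nni_neighbors(self) -> list["PhyloTree"]:
        """All distinct one-NNI rearrangements around internal edges."""
        seen: set[frozenset[frozenset[str]]] = {frozenset(self.splits())}
        out: list[PhyloTree] = []
        n_internal = sum(
            1 for n in self.d.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None)
        for edge_i in range(n_internal):
            for swap_a in range(4):  # upper bound on (child_c x child_p) combos
                t = self.copy()
                internal = [
                    n for n in t.d.preorder_node_iter()
                    if not n.is_leaf() and n.parent_node is not None]
                c = internal[edge_i]
                p = c.parent_node
                c_children = c.child_nodes()
                p_children = [x for x in p.child_nodes() if x is not c]
                ai, bi = divmod(swap_a, 2)
                if ai >= len(c_children) or bi >= len(p_children):
                    continue
                a, b = c_children[ai], p_children[bi]
                c.remove_child(a, suppress_unifurcations=False)
                p.remove_child(b, suppress_unifurcations=False)
                c.add_child(b)
                p.add_child(a)
                t = PhyloTree(t.d)
                key = frozenset(t.splits())
                if key not in seen:
                    seen.add(key)
                    out.append(t)
        return out


def star_tree(taxa: list[str], tip_length: float = 0.1) -> PhyloTree:
    newick = "(" + ",".join(f"{t}:{tip_length}" for t in taxa) + ");"
    return PhyloTree.from_newick(newick)
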