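"""Unrooted expression trees: Newick I/O, bipartitions, bootstrap supports.

Trees produced by the expression-phylogeny stage are small (one leaf per
species) unrooted trees with branch lengths in expression-distance units and
integer percent bootstrap supports attached to internal edges. Storage and
Newick serialisation are delegated to :mod:`dendropy`; this module adds the
bipartition bookkeeping the bootstrap needs.
"""

from __future__ import annotations

import dendropy

__all__ = ["ExpressionTree", "read_newick", "write_newick"]


def _canonical(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Canonical representative of the bipartition {side, complement}."""
    comp = all_leaves - side
    if len(side) < len(comp):
        return frozenset(side)
    if len(comp) < len(side):
        return frozenset(comp)
    return frozenset(min(side, comp, key=lambda s: tuple(sorted(s))))


class ExpressionTree:
    """Unrooted phylogeny with branch lengths and per-edge bootstrap support.

    Wraps a :class:`dendropy.Tree`. Leaf labels are species names and must
    be unique; supports (integer percent, 0-100) live on internal edges and
    are serialised as internal node labels in Newick.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = False
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 leaves")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate leaf names: {sorted(labels)}")
        self._tree = tree

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(lf.taxon.label for lf in self._tree.leaf_node_iter())

    def _leafset(self, node) -> frozenset:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def _internal_nodes(self):
        """Internal non-root nodes, skipping a redundant degree-2 root child."""
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root or node.is_leaf():
                continue
            yield node

    def bipartitions(self, nontrivial_only: bool = True) -> set:
        """Set of canonical bipartitions (frozensets of leaf labels)."""
        leaves = self.leaf_labels
        out = set()
        for node in self._internal_nodes():
            side = self._leafset(node)
            if nontrivial_only and (len(side) < 2 or len(leaves - side) < 2):
                continue
            out.add(_canonical(side, leaves))
        if not nontrivial_only:
            for lf in self._tree.leaf_node_iter():
                out.add(_canonical(frozenset([lf.taxon.label]), leaves))
        return out

    def set_supports(self, supports: dict) -> None:
        """Attach integer percent supports, keyed by canonical bipartition."""
        leaves = self.leaf_labels
        for node in self._internal_nodes():
            key = _canonical(self._leafset(node), leaves)
            if key in supports:
                val = supports[key]
                if not (0 <= val <= 100):
                    raise ValueError(f"support {val} outside [0, 100]")
                node.label = str(int(round(val)))

    def supports(self) -> dict:
        """Bipartition -> integer support for labelled internal edges."""
        leaves = self.leaf_labels
        out = {}
        for node in self._internal_nodes():
            if node.label is not None and node.label != "":
                side = self._leafset(node)
                if len(side) >= 2 and len(leaves - side) >= 2:
                    out[_canonical(side, leaves)] = int(round(float(node.label)))
        return out

    def branch_lengths(self) -> dict:
        """Canonical bipartition (incl. trivial) -> branch length."""
        leaves = self.leaf_labels
        out = {}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            key = _canonical(self._leafset(node), leaves)
            length = node.edge.length or 0.0
            out[key] = out.get(key, 0.0) + length
        return out

    def as_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        )
        return s.strip()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.as_newick()


def write_newick(tree: ExpressionTree, path) -> None:
    """Write a tree as Newick with branch lengths and support labels."""
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


def read_newick(path) -> ExpressionTree:
    """Read a Newick tree; internal node labels are bootstrap supports."""
    t = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return ExpressionTree(t)
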