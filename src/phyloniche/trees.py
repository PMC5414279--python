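"""Rooted phylogenies: Newick I/O, Brownian-motion covariance, independent contrasts.

The comparative methods downstream (PGLS, contrast regression) assume trait
evolution by Brownian motion on a rooted tree with branch lengths.  Two
primitives encode that assumption:

* :func:`brownian_covariance` — the expected trait covariance between two tips
  is proportional to the branch length shared on their root paths, i.e. the
  depth of their most recent common ancestor.
* :func:`pic` — Felsenstein's pruning algorithm, which converts ``n`` tip
  values into ``n - 1`` standardized, phylogenetically independent contrasts.

Newick reading/writing is delegated to :mod:`dendropy`; :class:`PhyloTree`
is a thin wrapper that enforces the invariants the contrast algorithm needs
(unique tip labels, branch lengths present, bifurcating where required).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "ContrastSet",
    "NewickParseError",
    "TreeStructureError",
    "read_newick",
    "brownian_covariance",
    "pic",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or lacks branch lengths."""


class TreeStructureError(ValueError):
    """Raised when a tree violates a structural precondition (e.g. polytomy)."""


class PhyloTree:
    """A rooted phylogeny with branch lengths and uniquely labelled tips.

    Wraps a :class:`dendropy.Tree`. Construct with :meth:`from_newick` /
    :func:`read_newick`, or from a dendropy tree directly.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise NewickParseError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeStructureError(f"duplicate tip labels: {dupes}")
        self._tip_labels = labels

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy error messages carry line/column offsets
            if "Duplicate taxon labels" in str(exc):
                raise TreeStructureError(f"duplicate tip labels: {exc}") from exc
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        seedlings = tree.seed_node.child_nodes()
        if not seedlings:
            raise NewickParseError("tree has no tips")
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            if node.edge.length is None:
                where = node.taxon.label if node.taxon else "an internal node"
                raise NewickParseError(
                    f"missing branch length above {where!r}; "
                    "contrasts and PGLS require branch lengths"
                )
            if node.edge.length < 0:
                raise TreeStructureError("negative branch length")
        return cls(tree)

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True,
                                 unquoted_underscores=True)
        return s.strip()

    # -- basic structure ---------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in the (deterministic) order they appear in the Newick."""
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def is_binary(self) -> bool:
        """True iff every internal node has exactly two children."""
        return all(
            len(n.child_nodes()) == 2
            for n in self._tree.preorder_internal_node_iter()
        )

    def has_positive_lengths(self) -> bool:
        return all(
            n.edge.length is not None and n.edge.length > 0
            for n in self._tree.preorder_node_iter()
            if n is not self._tree.seed_node
        )

    def retain_tips(self, labels: Iterable[str]) -> "PhyloTree":
        """Prune to the given tip labels, merging branch lengths through
        suppressed degree-2 nodes."""
        keep = list(labels)
        unknown = [l for l in keep if l not in set(self._tip_labels)]
        if unknown:
            raise KeyError(f"labels not in tree: {unknown}")
        if len(keep) < 2:
            raise TreeStructureError("cannot prune a tree below 2 tips")
        sub = self._tree.extract_tree_with_taxa_labels(
            labels=keep, suppress_unifurcations=True
        )
        return PhyloTree(sub)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_tips={self.n_tips})"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths required) into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


@dataclass(frozen=True)
class ContrastSet:
    """Standardized independent contrasts of one trait.

    ``node_ids`` identify the internal node each contrast was taken at, in a
    deterministic postorder; ``values`` are the standardized contrasts.  For a
    binary tree with ``n`` tips there are exactly ``n - 1`` contrasts.
    """

    trait: str
    node_ids: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.node_ids) != len(self.values):
            raise ValueError("node_ids and values must align")

    def __len__(self) -> int:
        return len(self.values)


def brownian_covariance(
    tree: PhyloTree, tip_order: Sequence[str] | None = None
) -> np.ndarray:
    """Brownian-motion covariance structure implied by a rooted tree.

    ``C[i, j]`` is the branch length shared on the root paths of tips ``i``
    and ``j`` — the depth of their most recent common ancestor — and
    ``C[i, i]`` the root-to-tip distance.  Under Brownian motion the trait
    covariance is proportional to this matrix, which is symmetric positive
    semi-definite by construction.
    """
    if tip_order is None:
        tip_order = tree.tip_labels
    known = set(tree.tip_labels)
    unknown = [lbl for lbl in tip_order if lbl not in known]
    if unknown:
        raise KeyError(f"labels not in tree: {unknown}")
    if len(set(tip_order)) != len(tip_order):
        raise ValueError("tip_order contains duplicates")

    dtree = tree.dendropy_tree
    # Depth of every node, then MRCA depth per tip pair via ancestor paths.
    depth: dict[int, float] = {id(dtree.seed_node): 0.0}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    paths: dict[str, list[int]] = {}
    for leaf in dtree.leaf_node_iter():
        chain = []
        node = leaf
        while node is not None:
            chain.append(id(node))
            node = node.parent_node
        paths[leaf.taxon.label] = chain[::-1]  # root ... tip

    n = len(tip_order)
    C = np.zeros((n, n))
    for i, a in enumerate(tip_order):
        pa = paths[a]
        C[i, i] = depth[pa[-1]]
        for j in range(i + 1, n):
            pb = paths[tip_order[j]]
            mrca = None
            for x, y in zip(pa, pb):
                if x != y:
                    break
                mrca = x
            C[i, j] = C[j, i] = depth[mrca] if mrca is not None else 0.0
    return C


def pic(tree: PhyloTree, x: Mapping[str, float], trait: str = "trait") -> ContrastSet:
    """Felsenstein's phylogenetically independent contrasts.

    At each internal node with daughter values ``x1, x2`` and (adjusted)
    daughter branch lengths ``v1, v2``:

    * contrast ``= (x1 - x2) / sqrt(v1 + v2)``
    * ancestral value ``= (x1/v1 + x2/v2) / (1/v1 + 1/v2)``
    * the node's own parent branch is lengthened by ``v1*v2 / (v1 + v2)``.

    Contrast sign follows child order in the input Newick; contrasts are
    returned in postorder, so output order is deterministic.

    Raises
    ------
    TreeStructureError
        If the tree contains a polytomy (resolve it before calling) or a
        zero branch length enters a contrast denominator.
    KeyError
        If a tip has no trait value.
    """
    missing = [lbl for lbl in tree.tip_labels if lbl not in x]
    if missing:
        raise KeyError(f"trait {trait!r} missing values for tips: {missing}")

    dtree = tree.dendropy_tree
    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    for node in dtree.preorder_node_iter():
        if node is not dtree.seed_node:
            lengths[id(node)] = float(node.edge.length)

    contrasts: list[float] = []
    node_ids: list[int] = []
    counter = 0
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            values[id(node)] = float(x[node.taxon.label])
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise TreeStructureError(
                f"polytomy with {len(children)} children encountered; "
                "resolve the tree to a bifurcating topology before computing contrasts"
            )
        c1, c2 = children
        v1, v2 = lengths[id(c1)], lengths[id(c2)]
        if v1 + v2 <= 0 or v1 < 0 or v2 < 0 or v1 == 0 or v2 == 0:
            raise TreeStructureError(
                "zero branch length in a contrast denominator; "
                "contrasts are undefined on zero-length branches"
            )
        x1, x2 = values[id(c1)], values[id(c2)]
        contrasts.append((x1 - x2) / math.sqrt(v1 + v2))
        node_ids.append(counter)
        counter += 1
        values[id(node)] = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        if node is not dtree.seed_node:
            lengths[id(node)] += v1 * v2 / (v1 + v2)

    return ContrastSet(trait=trait, node_ids=tuple(node_ids),
                       values=np.asarray(contrasts))
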