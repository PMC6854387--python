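"""Rooted phylogenies: Newick I/O, branch-length schemes, and node dating.

The analyses in this package operate on two kinds of trees: a dated host-plant
tree whose branch lengths are divergence times (millions of years, my), and an
undated herbivore tree whose branch lengths must be assigned by convention —
either all branches equal to 1.0 ("unit") or Grafen's arbitrary lengths, in
which each node is placed at a height proportional to a power of the number of
tips it subtends.

:class:`Phylogeny` is a thin, validated wrapper around a rooted
:class:`dendropy.Tree`.  It refuses to silently resolve polytomies: trees with
multifurcations carry a flag and must be resolved explicitly (the field data
behind this method were resolved by expert opinion, not algorithmically).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy


class TreeError(ValueError):
    """Invalid tree structure or an operation unsupported on this tree."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


@dataclass(frozen=True)
class BranchLengthScheme:
    """Convention for assigning branch lengths to an undated tree.

    Parameters
    ----------
    kind : {"unit", "grafen"}
        ``unit`` sets every branch to 1.0.  ``grafen`` places each internal
        node at height ``((tips below − 1)/(total tips − 1)) ** power`` with
        tips at height 0, so the root sits at height 1.
    power : float
        Exponent applied to Grafen's relative node heights (rho); must be
        positive.  Ignored for ``unit``.
    """

    kind: str = "unit"
    power: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("unit", "grafen"):
            raise ValueError(f"unknown branch-length scheme {self.kind!r}; "
                             "expected 'unit' or 'grafen'")
        if not self.power > 0:
            raise ValueError("grafen power must be > 0")


def _min_tip_label(node: dendropy.Node) -> str:
    labels = [lf.taxon.label for lf in node.leaf_iter()]
    return min(labels)


class Phylogeny:
    """A rooted tree with uniquely labeled tips.

    Wraps a :class:`dendropy.Tree`; the underlying tree is available as
    ``.tree`` for interoperability but should be treated as read-only.
    """

    def __init__(self, tree: dendropy.Tree, tree_id: str | None = None):
        self.tree = tree
        self.tree.is_rooted = True
        self.tree_id = tree_id
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, tree_id: str | None = None) -> "Phylogeny":
        """Parse a rooted Newick string.

        Branch lengths are kept exactly as encoded (absent lengths stay
        unset).  Polytomies are preserved; see :attr:`has_polytomies`.
        """
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick",
                rooting="force-rooted",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parser errors
            raise NewickParseError(f"could not parse Newick: {exc}") from exc
        return cls(tree, tree_id=tree_id)

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1), tree_id=self.tree_id)

    def _validate(self) -> None:
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(labels) < 2:
            raise TreeError("tree must have at least 2 tips")
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise TreeError(f"duplicate tip labels: {dupes}")

    # -- basic structure --------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def has_polytomies(self) -> bool:
        return any(
            len(nd.child_nodes()) > 2
            for nd in self.tree.preorder_internal_node_iter()
        )

    @property
    def is_binary(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2
            for nd in self.tree.preorder_internal_node_iter()
        )

    @property
    def total_branch_length(self) -> float:
        """Sum of all branch lengths below the root (unset lengths error)."""
        total = 0.0
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            if nd.edge.length is None:
                raise TreeError("tree has unset branch lengths")
            total += nd.edge.length
        return total

    def require_binary(self) -> None:
        if not self.is_binary:
            raise TreeError(
                "tree contains polytomies; resolve them explicitly with "
                "resolve_polytomies() before this operation"
            )

    # -- manipulation -----------------------------------------------------

    def resolve_polytomies(self, order: Sequence[str] | None = None) -> "Phylogeny":
        """Return a binary copy with polytomies resolved.

        ``order`` is an explicit tip-label priority: at each multifurcation
        the children are sorted by the position of their smallest-ranked
        descendant tip and folded left-to-right into cherries joined by
        zero-length branches.  With ``order=None`` the tips' lexicographic
        order is used.  The resolution is deterministic either way.
        """
        rank = {lab: i for i, lab in enumerate(order)} if order is not None else None
        new = self.copy()

        def child_key(nd: dendropy.Node):
            labs = [lf.taxon.label for lf in nd.leaf_iter()]
            if rank is None:
                return min(labs)
            missing = [l for l in labs if l not in rank]
            if missing:
                raise TreeError(f"resolution order missing tips: {sorted(missing)}")
            return min(rank[l] for l in labs)

        for nd in list(new.tree.preorder_internal_node_iter()):
            kids = nd.child_nodes()
            while len(kids) > 2:
                kids = sorted(kids, key=child_key)
                a, b = kids[0], kids[1]
                nd.remove_child(a)
                nd.remove_child(b)
                joint = dendropy.Node()
                joint.edge.length = 0.0
                joint.add_child(a)
                joint.add_child(b)
                nd.add_child(joint)
                kids = nd.child_nodes()
        return Phylogeny(new.tree, tree_id=self.tree_id)

    def with_branch_lengths(self, scheme: BranchLengthScheme) -> "Phylogeny":
        """Return a copy with branch lengths assigned by ``scheme``.

        Requires a binary tree (polytomies must be resolved first, matching
        how the underlying comparative method expects its input).
        """
        self.require_binary()
        new = self.copy()
        if scheme.kind == "unit":
            for nd in new.tree.preorder_node_iter():
                if nd.parent_node is not None:
                    nd.edge.length = 1.0
            return new
        # Grafen: height = ((n_desc_tips - 1)/(N - 1)) ** power, tips at 0
        n_total = new.n_tips
        height: dict[dendropy.Node, float] = {}
        for nd in new.tree.postorder_node_iter():
            if nd.is_leaf():
                height[nd] = 0.0
            else:
                k = sum(1 for _ in nd.leaf_iter())
                height[nd] = ((k - 1) / (n_total - 1)) ** scheme.power
        for nd in new.tree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = height[nd.parent_node] - height[nd]
        return new

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Return the induced subtree on ``labels`` (unifurcations collapsed,
        branch lengths summed through removed degree-2 nodes)."""
        keep = sorted(set(labels))
        unknown = sorted(set(keep) - set(self.tip_labels))
        if unknown:
            raise TreeError(f"unknown tip labels: {unknown}")
        if len(keep) < 2:
            raise TreeError("pruning needs at least 2 tips to keep")
        new = self.copy()
        new.tree.retain_taxa_with_labels(keep)
        return Phylogeny(new.tree, tree_id=self.tree_id)

    def mrca(self, labels: Iterable[str]) -> dendropy.Node:
        labels = list(labels)
        node = self.tree.mrca(taxon_labels=labels)
        if node is None:
            raise TreeError(f"no common ancestor found for {labels}")
        return node

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover
        tid = f" id={self.tree_id!r}" if self.tree_id else ""
        return f"<Phylogeny{tid} tips={self.n_tips} binary={self.is_binary}>"


def parse_tree(newick_text: str, tree_id: str | None = None) -> Phylogeny:
    """Parse Newick text into a :class:`Phylogeny` (convenience wrapper)."""
    return Phylogeny.from_newick(newick_text, tree_id=tree_id)


def date_undated_node(parent_age: float, tip_age: float = 0.0) -> float:
    """Midpoint age for a node whose own age is unknown.

    Places the node equidistant between its dated parent and the tip level,
    the convention used to date the one unresolved split of the host tree
    (parent at 34 my, tips at 0 → node at 17 my).
    """
    if not parent_age > tip_age:
        raise ValueError(
            f"parent age ({parent_age}) must exceed tip age ({tip_age})"
        )
    if tip_age < 0:
        raise ValueError("tip age must be nonnegative")
    return (parent_age + tip_age) / 2.0
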