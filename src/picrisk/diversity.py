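"""Host phylodiversity: Faith-style phylogenetic diversity of a host set.

A herbivore's diet breadth is summarized as the total branch length (in
millions of years, when the host tree is dated) of the minimal subtree
connecting its recorded host plants — larger values mean a more phylogenetically
dispersed, i.e. more generalized, diet.  By default the subtree extends only to
the hosts' most recent common ancestor; setting ``include_root=True`` adds the
path from that ancestor up to the tree root (the convention used by some
phylogenetic-diversity implementations).  A monophagous species (one host) has
zero phylodiversity under the default convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .tree import Phylogeny, TreeError


@dataclass(frozen=True)
class HostPhylodiversity:
    species: str | None
    hosts: frozenset[str]
    value: float
    include_root: bool

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("phylodiversity cannot be negative")


def host_phylodiversity(
    host_tree: Phylogeny,
    hosts: Iterable[str],
    include_root: bool = False,
    species: str | None = None,
) -> HostPhylodiversity:
    """Total branch length linking ``hosts`` on ``host_tree``.

    Parameters
    ----------
    host_tree : Phylogeny
        Tree with branch lengths set (my for a dated tree).
    hosts : iterable of str
        Tip labels of the recorded host plants; must be nonempty and all
        present on the tree.  Order and duplicates are irrelevant.
    include_root : bool
        If True, add the branch lengths on the path from the hosts' MRCA to
        the tree root.
    species : str, optional
        Herbivore species id carried through to the result for bookkeeping.

    Returns
    -------
    HostPhylodiversity
        With ``value`` = sum over the union of root-ward paths from each host
        tip to the MRCA (each branch counted once).
    """
    host_set = frozenset(hosts)
    if not host_set:
        raise ValueError("host set is empty")
    known = set(host_tree.tip_labels)
    unknown = sorted(host_set - known)
    if unknown:
        raise TreeError(f"hosts not on the tree: {unknown}")

    mrca = host_tree.mrca(host_set)
    leaves = {
        lf.taxon.label: lf
        for lf in host_tree.tree.leaf_node_iter()
        if lf.taxon.label in host_set
    }

    seen: set[int] = set()
    total = 0.0
    for leaf in leaves.values():
        nd = leaf
        while nd is not mrca:
            if id(nd) in seen:
                break
            seen.add(id(nd))
            if nd.edge.length is None:
                raise TreeError("host tree has unset branch lengths")
            total += nd.edge.length
            nd = nd.parent_node

    if include_root:
        nd = mrca
        while nd.parent_node is not None:
            if nd.edge.length is None:
                raise TreeError("host tree has unset branch lengths")
            total += nd.edge.length
            nd = nd.parent_node

    return HostPhylodiversity(
        species=species, hosts=host_set, value=total, include_root=include_root
    )


def compute_hpd(
    host_tree: Phylogeny,
    hosts: Iterable[str],
    include_root: bool = False,
    species: str | None = None,
) -> HostPhylodiversity:
    """Alias of :func:`host_phylodiversity` (field shorthand: HPD)."""
    return host_phylodiversity(host_tree, hosts, include_root, species)
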