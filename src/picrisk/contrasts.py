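"""Felsenstein's phylogenetically independent contrasts (PICs).

Species trait values are not independent observations: close relatives
resemble each other.  Under a Brownian-motion model of trait change, the
difference between the values of two sister lineages, scaled by the square
root of its expected variance (the sum of the branch lengths separating them),
is a draw from N(0, sigma^2) independent of every other such contrast.  The
pruning recursion below computes one contrast per internal node, so a binary
tree with n tips yields n − 1 independent values.

At an internal node with child values x_i, x_j on (adjusted) branch lengths
v_i, v_j:

    raw contrast   u = x_i − x_j
    variance       V = v_i + v_j
    standardized   u / sqrt(V)
    node value     (x_i/v_i + x_j/v_j) / (1/v_i + 1/v_j)
    node's branch  v + v_i v_j / (v_i + v_j)

The subtraction order is arbitrary in the method; here it is fixed
deterministically (the child whose smallest descendant tip label sorts first
is the minuend) so repeated runs and different traits align sign conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .tree import Phylogeny, TreeError


@dataclass
class ContrastSet:
    """Standardized contrasts for one trait on one tree.

    ``table`` has one row per internal node (postorder, deterministic), with
    columns ``node`` (id built from the smallest descendant tip label of each
    child), ``raw``, ``variance`` and ``standardized``.
    """

    trait: str | None
    tree_id: str | None
    table: pd.DataFrame

    @property
    def standardized(self) -> np.ndarray:
        return self.table["standardized"].to_numpy()

    @property
    def raw(self) -> np.ndarray:
        return self.table["raw"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def independent_contrasts(
    tree: Phylogeny,
    tip_values: Mapping[str, float],
    trait: str | None = None,
) -> ContrastSet:
    """Compute standardized independent contrasts for one trait.

    Parameters
    ----------
    tree : Phylogeny
        Binary rooted tree with strictly positive branch lengths.
    tip_values : mapping of tip label -> value
        Must cover every tip of the tree.
    trait : str, optional
        Name recorded in the result.

    Raises
    ------
    TreeError
        On polytomies, missing tip values, or nonpositive branch lengths.
    """
    tree.require_binary()
    tips = tree.tip_labels
    missing = sorted(set(tips) - set(tip_values))
    if missing:
        raise TreeError(f"missing trait values for tips: {missing}")

    value: dict[int, float] = {}
    adj_len: dict[int, float] = {}
    min_lab: dict[int, str] = {}
    rows = []

    for nd in tree.tree.postorder_node_iter():
        if nd.parent_node is not None:
            bl = nd.edge.length
            if bl is None or bl <= 0:
                raise TreeError(
                    "independent contrasts require positive branch lengths; "
                    f"found {bl!r}"
                )
        if nd.is_leaf():
            lab = nd.taxon.label
            value[id(nd)] = float(tip_values[lab])
            adj_len[id(nd)] = float(nd.edge.length)
            min_lab[id(nd)] = lab
            continue
        a, b = nd.child_nodes()
        # deterministic subtraction order: child with the lexicographically
        # smallest descendant tip is the minuend
        if min_lab[id(b)] < min_lab[id(a)]:
            a, b = b, a
        va, vb = adj_len[id(a)], adj_len[id(b)]
        xa, xb = value[id(a)], value[id(b)]
        raw = xa - xb
        var = va + vb
        rows.append({
            "node": f"{min_lab[id(a)]}|{min_lab[id(b)]}",
            "raw": raw,
            "variance": var,
            "standardized": raw / math.sqrt(var),
        })
        value[id(nd)] = (xa / va + xb / vb) / (1.0 / va + 1.0 / vb)
        own = nd.edge.length if nd.parent_node is not None else 0.0
        adj_len[id(nd)] = float(own) + va * vb / (va + vb)
        min_lab[id(nd)] = min(min_lab[id(a)], min_lab[id(b)])

    table = pd.DataFrame(rows, columns=["node", "raw", "variance", "standardized"])
    return ContrastSet(trait=trait, tree_id=tree.tree_id, table=table)


def compute_pics(tree: Phylogeny, tip_values: Mapping[str, float],
                 trait: str | None = None) -> ContrastSet:
    """Alias of :func:`independent_contrasts`."""
    return independent_contrasts(tree, tip_values, trait=trait)


class IndependentContrasts(TransformerMixin, BaseEstimator):
    """Transformer turning species trait columns into standardized contrasts.

    Parameters
    ----------
    tree : Phylogeny
        Binary rooted tree with positive branch lengths; its tips define the
        required row index of the input.
    scaled : bool, default True
        If True, emit standardized contrasts (raw / sqrt(variance)); if
        False, emit raw contrasts.

    Attributes
    ----------
    node_ids_ : list of str
        Internal-node identifiers, one per output row, in the deterministic
        postorder used by every transform.
    variances_ : ndarray of shape (n_tips - 1,)
        Contrast variances (summed adjusted branch lengths); identical for
        every trait on a fixed tree.

    Examples
    --------
    >>> from picrisk.tree import parse_tree
    >>> t = parse_tree("((A:1,B:1):1,C:1);")
    >>> X = pd.DataFrame({"z": [2.0, 0.0, 1.0]}, index=["A", "B", "C"])
    >>> IndependentContrasts(t).fit_transform(X)["z"].round(4).tolist()
    [1.4142, 0.0]
    """

    def __init__(self, tree: Phylogeny, scaled: bool = True):
        self.tree = tree
        self.scaled = scaled

    def fit(self, X: pd.DataFrame, y=None) -> "IndependentContrasts":
        X = self._check_input(X)
        probe = independent_contrasts(
            self.tree, {t: 0.0 for t in self.tree.tip_labels}
        )
        self.node_ids_ = probe.table["node"].tolist()
        self.variances_ = probe.table["variance"].to_numpy()
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "node_ids_"):
            raise AttributeError("IndependentContrasts is not fitted yet")
        X = self._check_input(X)
        col = "standardized" if self.scaled else "raw"
        out = {}
        for name in X.columns:
            cs = independent_contrasts(
                self.tree, X[name].to_dict(), trait=str(name)
            )
            out[name] = cs.table[col].to_numpy()
        return pd.DataFrame(out, index=pd.Index(self.node_ids_, name="node"))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_in_, dtype=object)

    def _check_input(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "IndependentContrasts expects a DataFrame indexed by tip label"
            )
        tips = self.tree.tip_labels
        missing = sorted(set(tips) - set(X.index))
        if missing:
            raise TreeError(f"rows missing for tips: {missing}")
        if X[X.index.isin(tips)].isna().any().any():
            bad = X.columns[X[X.index.isin(tips)].isna().any()].tolist()
            raise ValueError(f"NaN trait values in columns {bad}")
        return X.loc[tips]
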