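"""Synthetic trees, traits and exclusion-experiment counts with known truth.

The generator emulates the data structure of the field study end to end:

1. a rooted binary tree for the herbivore species (random Yule splitting
   order or a balanced shape), branch lengths by the unit or Grafen scheme;
2. species traits co-evolving along the tree under correlated multivariate
   Brownian motion (root state 0);
3. a paired-branch exclusion experiment: per branch and species, the
   exclusion-arm count is Poisson(lambda0 * area) and the control-arm count is
   Poisson(lambda0 * area * exp(beta . z)), where z are the species' traits
   standardized across species — so a species' true log response ratio is
   exactly beta . z, on the same standardized-coefficient scale the analysis
   estimates.  Bird strata get independent branch sets and optionally
   stratum-specific beta.

Defaults mirror the study's scale: 20 species, 280 branches per arm within
each of two bird strata (about 560 per arm overall), a baseline density of
0.05 caterpillars per m^2 of foliage, and effect sizes around +/-0.4 on the
standardized scale.  Everything is driven by one ``numpy`` Generator, so a
fixed seed reproduces every table byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import effects as eff
from .tree import BranchLengthScheme, Phylogeny

TRAIT_NAMES = ("hpd", "fbr", "mobility", "length", "abundance")


def _default_cov() -> np.ndarray:
    # unit variances; diet breadth and behavioral responsiveness co-evolve
    cov = np.eye(5)
    cov[0, 1] = cov[1, 0] = 0.5
    return cov


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic study.

    ``beta`` links standardized traits to the log control/exclusion density
    ratio; the default (+0.39 diet breadth, +0.41 behavioral response, 0, 0,
    −0.42 abundance) reproduces the magnitude and signs of the effects the
    method is designed to detect.
    """

    n_species: int = 20
    tree_model: str = "yule"
    branch_lengths: BranchLengthScheme = field(
        default_factory=BranchLengthScheme)
    trait_names: tuple[str, ...] = TRAIT_NAMES
    trait_cov: np.ndarray = field(default_factory=_default_cov)
    beta: np.ndarray = field(
        default_factory=lambda: np.array([0.39, 0.41, 0.0, 0.0, -0.42]))
    lambda0: float = 0.05
    abundance_spread: float = 0.8
    branches_per_arm: int = 280
    area_mean: float = 1.5
    area_sd: float = 0.5
    bird_strata: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.trait_cov = np.asarray(self.trait_cov, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        p = len(self.trait_names)
        if self.trait_cov.shape != (p, p):
            raise ValueError("trait covariance shape mismatch")
        if not np.allclose(self.trait_cov, self.trait_cov.T):
            raise ValueError("trait covariance must be symmetric")
        if np.linalg.eigvalsh(self.trait_cov).min() < -1e-10:
            raise ValueError("trait covariance must be positive semidefinite")
        if len(self.beta) != p:
            raise ValueError("beta length must match trait dimension")
        if not self.lambda0 > 0:
            raise ValueError("lambda0 must be > 0")


def simulate_tree(
    n: int,
    model: str = "yule",
    seed: int | np.random.Generator = 0,
    scheme: BranchLengthScheme | None = None,
    label_prefix: str = "sp",
) -> Phylogeny:
    """Random rooted binary tree with ``n`` labeled tips.

    ``yule`` splits a uniformly chosen extant lineage at each step (random
    topology); ``balanced`` builds the most balanced bifurcating shape.
    Branch lengths are then assigned by ``scheme`` (unit lengths by default).
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    if model not in ("yule", "balanced"):
        raise ValueError(f"unknown tree model {model!r}")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    scheme = scheme or BranchLengthScheme("unit")

    tree = dendropy.Tree()
    leaves: list[dendropy.Node] = []
    if model == "yule":
        leaves = [tree.seed_node.new_child(), tree.seed_node.new_child()]
        while len(leaves) < n:
            nd = leaves.pop(int(rng.integers(len(leaves))))
            leaves.extend([nd.new_child(), nd.new_child()])
    else:
        def split(node: dendropy.Node, size: int) -> None:
            if size == 1:
                leaves.append(node)
                return
            left = size - size // 2
            split(node.new_child(), left)
            split(node.new_child(), size - left)
        split(tree.seed_node, n)

    width = max(2, len(str(n)))
    for i, leaf in enumerate(leaves):
        leaf.taxon = tree.taxon_namespace.new_taxon(
            label=f"{label_prefix}{i + 1:0{width}d}")
    return Phylogeny(tree).with_branch_lengths(scheme)


def alternative_topology(
    tree: Phylogeny, seed: int | np.random.Generator = 0,
    scheme: BranchLengthScheme | None = None,
) -> Phylogeny:
    """A second topology differing from ``tree`` by one nearest-neighbor
    interchange at a random internal edge (emulating a single uncertain
    clade placement); branch lengths reassigned by ``scheme``."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    scheme = scheme or BranchLengthScheme("unit")
    new = tree.copy()
    internal = [
        nd for nd in new.tree.preorder_internal_node_iter()
        if nd.parent_node is not None and nd.parent_node.parent_node is not None
    ]
    if not internal:
        raise ValueError("tree too small for a topology variant")
    nd = internal[int(rng.integers(len(internal)))]
    parent = nd.parent_node
    sibling = next(c for c in parent.child_nodes() if c is not nd)
    child = nd.child_nodes()[int(rng.integers(2))]
    # swap one child of nd with nd's sibling
    parent.remove_child(sibling)
    nd.remove_child(child)
    nd.add_child(sibling)
    parent.add_child(child)
    return Phylogeny(new.tree, tree_id=(tree.tree_id or "tree") + "_alt"
                     ).with_branch_lengths(scheme)


def simulate_bm_traits(
    tree: Phylogeny,
    covariance: np.ndarray,
    seed: int | np.random.Generator = 0,
    trait_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Correlated Brownian tip traits: each branch of length t adds a
    MVN(0, t * covariance) increment; root state is 0 (immaterial to
    contrasts).  Returns a tips x traits DataFrame."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    cov = np.asarray(covariance, dtype=float)
    p = cov.shape[0]
    if cov.shape != (p, p) or not np.allclose(cov, cov.T):
        raise ValueError("covariance must be square symmetric")
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-10:
        raise ValueError("covariance must be positive semidefinite")
    L = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    names = tuple(trait_names) if trait_names else tuple(
        f"trait{i}" for i in range(p))
    if len(names) != p:
        raise ValueError("trait_names length mismatch")

    state: dict[int, np.ndarray] = {id(tree.tree.seed_node): np.zeros(p)}
    rows = {}
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is not None:
            bl = nd.edge.length
            if bl is None or bl <= 0:
                raise ValueError("tree must have positive branch lengths")
            step = math.sqrt(bl) * (L @ rng.standard_normal(p))
            state[id(nd)] = state[id(nd.parent_node)] + step
        if nd.is_leaf():
            rows[nd.taxon.label] = state[id(nd)]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(names))
    return out.sort_index()


def _standardize_columns(traits: pd.DataFrame) -> pd.DataFrame:
    z = traits - traits.mean()
    sd = traits.std(ddof=1)
    return z / sd.replace(0.0, 1.0)


def true_log_ratios(traits: pd.DataFrame, beta: np.ndarray) -> pd.Series:
    """Each species' true LRR, beta . z on the standardized trait scale."""
    z = _standardize_columns(traits)
    return pd.Series(z.to_numpy() @ np.asarray(beta, dtype=float),
                     index=traits.index, name="true_lrr")


def simulate_experiment(
    tip_traits: pd.DataFrame,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    stratum_beta: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Poisson branch-level counts for a paired control/exclusion design.

    Returns a wide branch-sample table (one row per branch, one count column
    per species) matching :mod:`picrisk.effects`' schema.  With
    ``stratum_beta`` the control-arm trait effect differs between bird
    strata, creating a true trait x treatment interaction.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed) \
        if not isinstance(seed, np.random.Generator) else seed
    species = list(tip_traits.index)
    if len(config.beta) != tip_traits.shape[1]:
        raise ValueError("beta length must match trait dimension")
    strata = ["bird_access", "bird_excluded"] if config.bird_strata else ["bird_access"]

    eta = {}
    for stratum in strata:
        b = (stratum_beta or {}).get(stratum, config.beta)
        eta[stratum] = true_log_ratios(tip_traits, b)

    # Heterogeneous baseline densities: species differ in how common they
    # are independently of the predation effect, driven by the latent
    # abundance trait (record counts then span a realistic ~25x range).
    z = _standardize_columns(tip_traits)
    if "abundance" in tip_traits.columns and config.abundance_spread:
        base = config.lambda0 * np.exp(
            config.abundance_spread * z["abundance"].to_numpy())
    else:
        base = np.full(len(species), config.lambda0)

    sites = ["siteA", "siteB", "siteC"]
    hosts = [f"host{i+1}" for i in range(8)]
    rows = []
    bid = 0
    for stratum in strata:
        bird = "access" if stratum == "bird_access" else "excluded"
        for arm in eff.ANT_ARMS:
            for j in range(config.branches_per_arm):
                area = max(0.1, rng.normal(config.area_mean, config.area_sd))
                if bird == "access":
                    year = 2011 if j % 2 == 0 else 2012
                else:
                    year = 2011 if j % 5 else 2016
                mu_base = base * area
                row = {
                    "branch_id": f"b{bid:05d}",
                    "site": sites[j % 3],
                    "block": j % 6 + 1,
                    "year": year,
                    "tree_species": hosts[j % 8],
                    "ant_treatment": arm,
                    "bird_treatment": bird,
                    "area_m2": area,
                }
                mult = (np.exp(eta[stratum].to_numpy())
                        if arm == "control" else np.ones(len(species)))
                counts = rng.poisson(mu_base * mult)
                row.update(dict(zip(species, counts.tolist())))
                rows.append(row)
                bid += 1
    return pd.DataFrame(rows)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def build_species_table(
    tip_traits: pd.DataFrame,
    samples: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Species-level trait table in the supplementary-table schema.

    LRRs and record counts are pooled from the simulated experiment through
    the real effect-size code path; latent Brownian traits are mapped to
    observable scales (phylodiversity in my, proportions via a logistic
    squash that preserves rank order, body length in mm).
    """
    from .traits import abundance_metric

    z = _standardize_columns(tip_traits)
    core = samples[samples["year"].isin(eff.CORE_YEARS)]
    rows = []
    for sp in tip_traits.index:
        rec: dict[str, float | str | None] = {"species": sp}
        for stratum, col in (("all", "lrr_all"),
                             ("bird_access", "lrr_bird_access"),
                             ("bird_excluded", "lrr_bird_excluded")):
            if stratum != "all" and not (samples["bird_treatment"] == (
                    "access" if stratum == "bird_access" else "excluded")).any():
                rec[col] = np.nan
                rec[f"n_{stratum}"] = 0
                continue
            c, e, n = eff.pool_densities(samples, sp, stratum)
            try:
                rec[col] = eff.log_response_ratio(c, e)
            except eff.UndefinedEffectError:
                rec[col] = np.nan
            rec[f"n_{stratum}"] = n
        n_core = int(core[sp].sum())
        rec["n_records"] = n_core
        rec["abundance"] = (abundance_metric(n_core) if n_core >= 1
                            else np.nan)
        rec["hpd"] = float(np.clip(90.0 + 45.0 * z.loc[sp, "hpd"], 0.0, 250.0))
        rec["fbr"] = float(_logistic(1.2 * z.loc[sp, "fbr"]))
        rec["ff"] = float(_logistic(
            0.9 * z.loc[sp, "hpd"] + 0.5 * rng.standard_normal()))
        rec["mobility"] = float(_logistic(1.2 * z.loc[sp, "mobility"]))
        rec["length_mm"] = float(np.clip(
            20.0 + 6.0 * z.loc[sp, "length"], 3.0, 60.0))
        rows.append(rec)
    cols = ["species", "lrr_all", "lrr_bird_access", "lrr_bird_excluded",
            "hpd", "fbr", "ff", "mobility", "length_mm", "abundance",
            "n_records", "n_bird_access", "n_bird_excluded"]
    return pd.DataFrame(rows)[cols]


def generate_fixture_table(
    config: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Emit a complete synthetic study to ``outdir``.

    Writes ``species_traits.tsv`` (the species-level table), ``tree1.nwk``
    and ``tree2.nwk`` (two topologies differing by one rearrangement), and
    ``metadata.json`` recording the seed, configuration and ground truth
    (true LRR per species).  Same config, same bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    tree1 = simulate_tree(config.n_species, config.tree_model, rng,
                          config.branch_lengths)
    tree1.tree_id = "tree1"
    tree2 = alternative_topology(tree1, rng, config.branch_lengths)
    tree2.tree_id = "tree2"
    traits = simulate_bm_traits(tree1, config.trait_cov, rng,
                                config.trait_names)
    samples = simulate_experiment(traits, config, rng)
    table = build_species_table(traits, samples, rng)

    paths = {
        "table": outdir / "species_traits.tsv",
        "tree1": outdir / "tree1.nwk",
        "tree2": outdir / "tree2.nwk",
        "metadata": outdir / "metadata.json",
    }
    table.to_csv(paths["table"], sep="\t", index=False, float_format="%.10g")
    paths["tree1"].write_text(tree1.as_newick() + "\n")
    paths["tree2"].write_text(tree2.as_newick() + "\n")
    meta = {
        "seed": config.seed,
        "config": {
            k: (v.tolist() if isinstance(v, np.ndarray)
                else dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "true_lrr": true_log_ratios(traits, config.beta).round(10).to_dict(),
    }
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths


def simulate_contrast_regression(
    n_contrasts: int,
    beta: dict[str, float],
    sigma: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Directly simulated contrast-level regression data.

    Predictor contrasts are i.i.d. standard normal and the response is
    ``X beta + N(0, sigma^2)`` — the sampling model under which the
    through-origin machinery is exactly correct.  Used for calibration
    studies (CI coverage, RVI ranking) where tree simulation would only add
    an equivalent layer of noise.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    names = list(beta)
    X = pd.DataFrame(rng.standard_normal((n_contrasts, len(names))),
                     columns=names)
    y = X.to_numpy() @ np.array([beta[k] for k in names]) \
        + sigma * rng.standard_normal(n_contrasts)
    return X, y
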