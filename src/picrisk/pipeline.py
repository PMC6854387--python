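"""End-to-end comparative analysis of a species-level trait table.

Given a species table (one row per herbivore species: predation-risk log
response ratios overall and per bird stratum, host phylodiversity, behavioral
metrics, body length, abundance, record counts) and one or two tree
topologies, :func:`run_analysis` reproduces the full analysis chain:

1. select the main species set (record count strictly above the main
   threshold, all predictors present), prune the tree to it;
2. compute standardized independent contrasts of the response and the five
   predictors; z-score the predictor contrasts (the response is left on its
   own scale);
3. two-stage AICc screen: RVI over all 32 subsets of the five predictors,
   then all-subsets inference and model averaging over the top three;
4. bird-treatment contingency: per-stratum contrasts (each stratum's species
   set is those with at least the stratum threshold of records there),
   stacked ANCOVA per top predictor, per-stratum through-origin regressions,
   and the joint two-predictor model on the bird-access stratum;
5. Pearson correlations between the behavioral-response and diet-breadth
   contrasts, and between fleeing and diet breadth where the fleeing assay
   has data.

Every fitted table is keyed by tree so alternative topologies are compared
side by side.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ancova import ContrastAncova, make_stacked_table, pic_pearson, stratum_regression
from .contrasts import IndependentContrasts
from .modelsel import TwoStageModelSelection, standardize
from .tree import BranchLengthScheme, Phylogeny

logger = logging.getLogger(__name__)

PREDICTORS = ("hpd", "fbr", "mobility", "length_mm", "abundance")
RESPONSE = "lrr_all"
STRATA = {"bird_access": "lrr_bird_access", "bird_excluded": "lrr_bird_excluded"}


@dataclass
class AnalysisConfig:
    predictors: tuple[str, ...] = PREDICTORS
    response: str = RESPONSE
    branch_lengths: BranchLengthScheme = field(
        default_factory=BranchLengthScheme)
    top_k: int = 3
    min_records_main: int = 10      # strict: species need > 10 records
    min_records_stratum: int = 5    # inclusive: >= 5 records in the stratum
    conditional_average: bool = True
    include_root: bool = False      # host-phylodiversity convention flag
    abundance_log_base: float = float(np.e)
    standardize_response: bool = False


def _prepare_contrasts(
    tree: Phylogeny, table: pd.DataFrame, config: AnalysisConfig,
    response: str, species: pd.Index,
) -> tuple[pd.DataFrame, np.ndarray]:
    sub = table.loc[species]
    cols = [response, *config.predictors]
    pruned = tree.prune_to(species).with_branch_lengths(config.branch_lengths)
    pics = IndependentContrasts(pruned).fit_transform(sub[cols])
    X = pd.DataFrame(
        {p: standardize(pics[p].to_numpy()) for p in config.predictors},
        index=pics.index,
    )
    y = pics[response].to_numpy()
    if config.standardize_response:
        y = standardize(y)
    return X, y


def main_species_set(table: pd.DataFrame, config: AnalysisConfig) -> pd.Index:
    """Species entering the multimodel analysis: record count strictly above
    the main threshold, response and all predictors present."""
    need = [config.response, *config.predictors]
    ok = (
        (table["n_records"] > config.min_records_main)
        & table[need].notna().all(axis=1)
    )
    return table.index[ok]


def stratum_species_set(
    table: pd.DataFrame, stratum: str, config: AnalysisConfig
) -> pd.Index:
    resp = STRATA[stratum]
    ok = (
        (table[f"n_{stratum}"] >= config.min_records_stratum)
        & table[resp].notna()
        & table[list(config.predictors)].notna().all(axis=1)
    )
    return table.index[ok]


def run_analysis(
    table: pd.DataFrame,
    trees: dict[str, Phylogeny],
    config: AnalysisConfig | None = None,
) -> dict:
    """Run the full comparative pipeline on every supplied tree topology.

    ``table`` must be indexed by species (or carry a ``species`` column).
    Returns a nested dict: per tree, the stage-1 RVI table, the stage-2
    model-comparison and model-averaging tables, ANCOVA tables per top
    predictor, per-stratum regressions, the joint bird-access model, and the
    contrast correlations; plus run metadata.
    """
    config = config or AnalysisConfig()
    if "species" in table.columns:
        table = table.set_index("species")
    results: dict = {"metadata": {
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_species_input": int(len(table)),
    }}

    main_set = main_species_set(table, config)
    logger.info("main species set: %d of %d species", len(main_set), len(table))
    results["metadata"]["n_species_main"] = int(len(main_set))

    for tree_id, tree in trees.items():
        res: dict = {}
        X, y = _prepare_contrasts(tree, table, config, config.response, main_set)
        screen = TwoStageModelSelection(
            top_k=config.top_k, conditional=config.conditional_average
        ).fit(X, y)
        res["rvi"] = screen.stage1_rvi_.rename_axis("predictor").reset_index()
        res["models"] = screen.selection_.table_.drop(columns="predictors")
        res["averaged"] = screen.selection_.averaged_.reset_index()
        res["top_predictors"] = list(screen.top_predictors_)

        # --- bird-treatment contingency -------------------------------
        strat_pics: dict[str, pd.DataFrame] = {}
        for stratum, resp in STRATA.items():
            sset = stratum_species_set(table, stratum, config)
            if len(sset) < 4:
                logger.warning("%s: only %d species with >=%d records; "
                               "stratified analyses skipped",
                               stratum, len(sset), config.min_records_stratum)
                continue
            sub = table.loc[sset]
            pruned = tree.prune_to(sset).with_branch_lengths(
                config.branch_lengths)
            pics = IndependentContrasts(pruned).fit_transform(
                sub[[resp, *config.predictors]])
            strat_pics[stratum] = pics.rename(columns={resp: "lrr"})
            results["metadata"][f"n_species_{stratum}"] = int(len(sset))

        if len(strat_pics) == 2:
            ancova_tables = {}
            for pred in screen.top_predictors_:
                stacked = make_stacked_table({
                    g: (p["lrr"].to_numpy(), p[pred].to_numpy())
                    for g, p in strat_pics.items()
                })
                ancova_tables[pred] = ContrastAncova().fit(stacked).anova_
            res["ancova"] = ancova_tables

            reg_rows = []
            for stratum, pics in strat_pics.items():
                for pred in ("hpd", "fbr"):
                    if pred not in pics.columns:
                        continue
                    slope, adj_r2, p = stratum_regression(
                        pics["lrr"].to_numpy(), pics[pred].to_numpy())
                    reg_rows.append({"stratum": stratum, "predictor": pred,
                                     "slope": slope, "adj_r2": adj_r2, "p": p})
            res["stratum_regressions"] = pd.DataFrame(reg_rows)

            if "bird_access" in strat_pics:
                pics = strat_pics["bird_access"]
                from .modelsel import OriginRegression
                jm = OriginRegression().fit(
                    pics[["hpd", "fbr"]].to_numpy(), pics["lrr"].to_numpy())
                jt = jm.slope_test()
                jt.insert(0, "predictor", ["hpd", "fbr"])
                res["joint_bird_access_model"] = jt

        # --- trait correlations on contrasts --------------------------
        corr_rows = []
        c = pic_pearson(X["fbr"].to_numpy(), X["hpd"].to_numpy())
        corr_rows.append({"pair": "fbr~hpd", "n": len(X) + 1, "r": c.r,
                          "t": c.t, "df": c.df, "p": c.p})
        if "ff" in table.columns:
            ff_set = table.index[
                table[["ff", "hpd"]].notna().all(axis=1)
                & table.index.isin(main_set)]
            if len(ff_set) >= 4:
                sub = table.loc[ff_set]
                pruned = tree.prune_to(ff_set).with_branch_lengths(
                    config.branch_lengths)
                pics = IndependentContrasts(pruned).fit_transform(
                    sub[["ff", "hpd"]])
                c = pic_pearson(pics["ff"].to_numpy(), pics["hpd"].to_numpy())
                corr_rows.append({"pair": "ff~hpd", "n": len(ff_set),
                                  "r": c.r, "t": c.t, "df": c.df, "p": c.p})
        res["correlations"] = pd.DataFrame(corr_rows)
        results[tree_id] = res

    return results


def write_results(results: dict, outdir: str | Path) -> None:
    """Flatten a :func:`run_analysis` result into delimited tables plus a
    JSON metadata record."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = dict(results.get("metadata", {}))
    for tree_id, res in results.items():
        if tree_id == "metadata":
            continue
        for name, obj in res.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(outdir / f"{tree_id}_{name}.csv",
                           index=bool(obj.index.name))
            elif isinstance(obj, dict):
                for sub, df in obj.items():
                    df.to_csv(outdir / f"{tree_id}_{name}_{sub}.csv")
            else:
                meta[f"{tree_id}_{name}"] = obj
    import picrisk
    meta["picrisk_version"] = picrisk.__version__
    (outdir / "run_metadata.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True, default=str))
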