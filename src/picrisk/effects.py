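"""Predator-exclusion effect sizes: pooled densities and log response ratios.

The exclusion experiment pairs control branches (predators free to forage)
with exclusion branches (a sticky barrier keeps ants off), optionally crossed
with a bird-exclusion treatment (mesh bags).  Counts of each herbivore species
are pooled across branches and years into a single density per treatment arm
(individuals per m^2 of foliage), and the ant effect on a species is the log
response ratio

    LRR = ln(control density / exclusion density),

negative when ants suppress the species.  No small-sample bias correction is
applied: a single pooled LRR per species has no within-species variance from
which to correct, so an arm with zero counts simply yields a missing effect.

Branch samples are rows of a wide DataFrame: the metadata columns in
``META_COLUMNS`` plus one nonnegative integer count column per species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = [
    "branch_id", "site", "block", "year", "tree_species",
    "ant_treatment", "bird_treatment", "area_m2",
]

ANT_ARMS = ("control", "excluded")
BIRD_STRATA = ("all", "bird_access", "bird_excluded")

#: Years whose samples enter abundance (the supplemental year oversampled a
#: few host species and is excluded from the abundance metric, but its counts
#: do enter LRR pooling).
CORE_YEARS = (2011, 2012)


class UndefinedEffectError(ValueError):
    """LRR requested where one treatment arm has zero pooled density."""


@dataclass(frozen=True)
class SpeciesEffect:
    species: str
    stratum: str
    control_density: float
    exclusion_density: float
    n_records: int
    lrr: float | None

    def __post_init__(self) -> None:
        if self.control_density < 0 or self.exclusion_density < 0:
            raise ValueError("densities must be nonnegative")
        if self.stratum not in BIRD_STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")


def validate_branch_samples(samples: pd.DataFrame) -> list[str]:
    """Check the branch-sample schema; return the species (count) columns."""
    missing = [c for c in META_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"branch samples missing columns: {missing}")
    species = [c for c in samples.columns if c not in META_COLUMNS]
    if not species:
        raise ValueError("no species count columns found")
    if (samples["area_m2"] <= 0).any():
        raise ValueError("foliage area must be > 0 on every branch")
    bad_arm = set(samples["ant_treatment"]) - set(ANT_ARMS)
    if bad_arm:
        raise ValueError(f"unknown ant treatments: {sorted(bad_arm)}")
    bad_bird = set(samples["bird_treatment"]) - {"access", "excluded"}
    if bad_bird:
        raise ValueError(f"unknown bird treatments: {sorted(bad_bird)}")
    counts = samples[species]
    if (counts.to_numpy() < 0).any() or not np.allclose(
        counts.to_numpy(), np.round(counts.to_numpy())
    ):
        raise ValueError("species counts must be nonnegative integers")
    return species


def _stratum_mask(samples: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=samples.index)
    if stratum == "bird_access":
        return samples["bird_treatment"] == "access"
    if stratum == "bird_excluded":
        return samples["bird_treatment"] == "excluded"
    raise ValueError(f"unknown stratum {stratum!r}")


def pool_densities(
    samples: pd.DataFrame, species: str, stratum: str = "all"
) -> tuple[float, float, int]:
    """Pool one species' counts into per-arm densities.

    Returns ``(control density, exclusion density, n_records)`` where each
    density is (summed counts)/(summed foliage area, m^2) over the selected
    branches, and ``n_records`` is the species' total individuals there.
    """
    validate_branch_samples(samples)
    if species not in samples.columns:
        raise KeyError(f"species {species!r} has no count column")
    sub = samples[_stratum_mask(samples, stratum)]
    if sub.empty:
        raise ValueError(f"no branches in stratum {stratum!r}")
    out = {}
    for arm in ANT_ARMS:
        arm_rows = sub[sub["ant_treatment"] == arm]
        if arm_rows.empty:
            raise ValueError(f"no {arm} branches in stratum {stratum!r}")
        out[arm] = arm_rows[species].sum() / arm_rows["area_m2"].sum()
    n = int(sub[species].sum())
    return float(out["control"]), float(out["excluded"]), n


def log_response_ratio(control_density: float, exclusion_density: float) -> float:
    """ln(control density / exclusion density); requires both > 0."""
    if control_density <= 0 or exclusion_density <= 0:
        raise UndefinedEffectError(
            "log response ratio undefined with a zero-density arm "
            f"(control={control_density}, exclusion={exclusion_density}); "
            "no continuity correction is applied"
        )
    return math.log(control_density / exclusion_density)


def percent_density_reduction(lrr: float) -> float:
    """(1 − exp(LRR)) × 100: the percentage by which predator access reduces
    density (negative values mean an increase)."""
    if not math.isfinite(lrr):
        raise ValueError("LRR must be finite")
    return (1.0 - math.exp(lrr)) * 100.0


def species_effects(
    samples: pd.DataFrame,
    stratum: str = "all",
    species: list[str] | None = None,
) -> list[SpeciesEffect]:
    """Pooled densities and LRR for each species in one bird stratum.

    Species with a zero-density arm get ``lrr=None`` and a logged warning
    (they are dropped from that stratum's analyses, not imputed).
    """
    cols = validate_branch_samples(samples)
    species = cols if species is None else species
    effects = []
    for sp in species:
        c, e, n = pool_densities(samples, sp, stratum)
        try:
            lrr = log_response_ratio(c, e)
        except UndefinedEffectError:
            lrr = None
            logger.warning(
                "species %s: zero-density arm in stratum %s; effect undefined",
                sp, stratum,
            )
        effects.append(SpeciesEffect(sp, stratum, c, e, n, lrr))
    return effects


def filter_species(
    effects: list[SpeciesEffect], min_records: int, strict: bool = True
) -> list[SpeciesEffect]:
    """Retain species by record count: ``> min_records`` when strict (the
    main analysis set uses strict > 10), ``>= min_records`` otherwise (the
    per-stratum sets use >= 5)."""
    if strict:
        return [e for e in effects if e.n_records > min_records]
    return [e for e in effects if e.n_records >= min_records]
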