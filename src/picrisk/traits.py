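"""Species-level predictors from individual behavior and observation records.

Three behavioral assays feed the comparative analysis, each scored as a
per-species proportion:

* **FBR** (frequency of behavioral response): fraction of individuals showing
  any active response (thrash, bite, regurgitate, hold on, drop, evade) to a
  simulated attack with forceps; "still" is the absence of response.  Needs
  five or more tested individuals.
* **FF** (frequency of fleeing): fraction of staged ant encounters ending in
  drop, evade, or rappelling on a silk line.  Needs more than five records —
  note the deliberately different threshold from FBR.
* **Mobility**: fraction of field observations in which the animal was
  locomoting or rappelling rather than resting or feeding.

Two further predictors: mean body length (mm, exclusion-arm individuals from
the core years only, so lengths are not censored by predation) and abundance
(natural log of a species' record count in the core-year experiment).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

ASSAY_VOCABULARY = {
    "simulated_attack": {
        "thrash", "bite", "regurgitate", "hold_on", "drop", "evade", "still",
    },
    "ant_encounter": {
        "thrash", "bite", "regurgitate", "hold_on", "drop", "evade", "still",
        "rappel",
    },
    "field_observation": {"resting", "feeding", "locomoting", "rappelling"},
}

RESPONSE_OUTCOMES = {"thrash", "bite", "regurgitate", "hold_on", "drop", "evade"}
FLEEING_OUTCOMES = {"drop", "evade", "rappel"}
MOBILE_OUTCOMES = {"locomoting", "rappelling"}

#: Record-count minima, preserved exactly as the assays define them:
#: FBR requires >= 5, FF requires > 5.
FBR_MIN_RECORDS = 5
FF_MIN_RECORDS = 5


class InsufficientRecords(ValueError):
    """Raised when a species has too few records for a metric; callers treat
    the metric as missing rather than zero."""


@dataclass(frozen=True)
class BehaviorRecord:
    species: str
    assay: str
    outcome: str
    year: int | None = None

    def __post_init__(self) -> None:
        vocab = ASSAY_VOCABULARY.get(self.assay)
        if vocab is None:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.outcome not in vocab:
            raise ValueError(
                f"outcome {self.outcome!r} not in vocabulary of {self.assay}"
            )


def _outcomes(records: Iterable[BehaviorRecord | str], assay: str) -> list[str]:
    out = []
    for r in records:
        if isinstance(r, BehaviorRecord):
            if r.assay != assay:
                raise ValueError(f"expected {assay} records, got {r.assay}")
            out.append(r.outcome)
        else:
            BehaviorRecord("?", assay, r)  # vocabulary check
            out.append(r)
    return out


def frequency_of_behavioral_response(records: Iterable) -> float:
    """FBR: responders / tested, over simulated-attack records.

    Raises :class:`InsufficientRecords` with fewer than five records.
    """
    outcomes = _outcomes(records, "simulated_attack")
    if len(outcomes) < FBR_MIN_RECORDS:
        raise InsufficientRecords(
            f"FBR needs >= {FBR_MIN_RECORDS} records, got {len(outcomes)}"
        )
    responders = sum(o in RESPONSE_OUTCOMES for o in outcomes)
    return responders / len(outcomes)


def frequency_of_fleeing(records: Iterable) -> float:
    """FF: (drop + evade + rappel) / observations, over ant encounters.

    Raises :class:`InsufficientRecords` unless there are more than five
    records (strictly more — this assay's threshold differs from FBR's).
    """
    outcomes = _outcomes(records, "ant_encounter")
    if len(outcomes) <= FF_MIN_RECORDS:
        raise InsufficientRecords(
            f"FF needs > {FF_MIN_RECORDS} records, got {len(outcomes)}"
        )
    fleeing = sum(o in FLEEING_OUTCOMES for o in outcomes)
    return fleeing / len(outcomes)


def mobility(records: Iterable) -> float:
    """(locomoting + rappelling) / observations, over field observations."""
    outcomes = _outcomes(records, "field_observation")
    if not outcomes:
        raise InsufficientRecords("mobility needs at least one observation")
    mobile = sum(o in MOBILE_OUTCOMES for o in outcomes)
    return mobile / len(outcomes)


def abundance_metric(record_count: int, base: float = math.e) -> float:
    """Log-transformed record count (core experiment years only).

    The log base defaults to natural log and is configurable; because the
    predictors are standardized before modeling, the base cannot change any
    fitted model, only the raw tabulated values.
    """
    if record_count < 1:
        raise ValueError("abundance needs a record count >= 1")
    return math.log(record_count) / math.log(base)


def mean_body_length(
    lengths_mm: Sequence[float],
    arms: Sequence[str] | None = None,
    years: Sequence[int] | None = None,
) -> float:
    """Mean body length in mm, filtered to exclusion-arm core-year records.

    If ``arms``/``years`` are given (aligned with ``lengths_mm``), only
    entries with arm ``"excluded"`` and year in the core years are averaged;
    otherwise the caller is trusted to have filtered already.
    """
    from .effects import CORE_YEARS

    vals = list(lengths_mm)
    if arms is not None:
        if len(arms) != len(vals):
            raise ValueError("arms must align with lengths")
        vals = [v for v, a in zip(vals, arms) if a == "excluded"]
        if years is not None:
            yrs = [y for y, a in zip(years, arms) if a == "excluded"]
            vals = [v for v, y in zip(vals, yrs) if y in CORE_YEARS]
    elif years is not None:
        if len(years) != len(list(lengths_mm)):
            raise ValueError("years must align with lengths")
        vals = [v for v, y in zip(vals, years) if y in CORE_YEARS]
    if not vals:
        raise InsufficientRecords("no usable length records")
    return float(sum(vals) / len(vals))


def outcome_frequencies(records: Iterable, assay: str) -> dict[str, float]:
    """Per-outcome relative frequencies (diagnostic helper)."""
    outcomes = _outcomes(records, assay)
    if not outcomes:
        raise InsufficientRecords("no records")
    counts = Counter(outcomes)
    n = len(outcomes)
    return {k: v / n for k, v in sorted(counts.items())}
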