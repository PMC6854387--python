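"""Treatment-contingency analyses on stacked contrasts.

To ask whether a predictor's effect on the predation-risk contrasts depends on
the bird treatment, contrasts are computed separately within each bird stratum
(each stratum's species set prunes its own copy of the tree), stacked, and fit
with a no-intercept ANCOVA

    y = x + group + x:group

whose design columns are [x, 1{group A}, 1{group B}, x·1{group B}].  Because
there is no intercept, the treatment term absorbs two degrees of freedom (both
group indicators).  Terms are tested with sequential (type-I) F tests in that
order, residual df = n − 4.  Per-stratum through-origin regressions and
ordinary Pearson correlations between contrast sets (df = n − 2) complete the
module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .modelsel import OriginRegression


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def make_stacked_table(groups: dict[str, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Build a stacked contrast table from ``{group: (y_contrasts, x_contrasts)}``."""
    rows = []
    for g, (y, x) in groups.items():
        y = np.asarray(y, dtype=float).ravel()
        x = np.asarray(x, dtype=float).ravel()
        if len(y) != len(x):
            raise ValueError(f"group {g!r}: y and x lengths differ")
        for i, (yi, xi) in enumerate(zip(y, x)):
            rows.append({"contrast_id": f"{g}:{i}", "group": g, "y": yi, "x": xi})
    return pd.DataFrame(rows)


class ContrastAncova(BaseEstimator):
    """No-intercept ANCOVA of y-contrasts on x-contrasts crossed with a
    two-level treatment, with sequential (type-I) sums of squares.

    Attributes
    ----------
    anova_ : DataFrame
        Rows predictor / treatment / interaction / residual with columns
        ss, df, F, p (F and p empty for the residual row).
    groups_ : list of str
        The two group labels, sorted; the second indexes the interaction
        column (the F tests are invariant to which one does).
    """

    def fit(self, table: pd.DataFrame) -> "ContrastAncova":
        required = {"group", "y", "x"}
        if not required.issubset(table.columns):
            raise ValueError(f"stacked table needs columns {sorted(required)}")
        groups = sorted(table["group"].unique())
        if len(groups) != 2:
            raise ValueError(f"exactly two groups required, got {groups}")
        for g in groups:
            if (table["group"] == g).sum() < 3:
                raise ValueError(f"group {g!r} has < 3 contrasts")

        y = table["y"].to_numpy(dtype=float)
        x = table["x"].to_numpy(dtype=float)
        g2 = (table["group"] == groups[1]).to_numpy(dtype=float)
        g1 = 1.0 - g2
        design = np.column_stack([x, g1, g2, x * g2])
        n = len(y)
        if n - 4 <= 0:
            raise ValueError("not enough contrasts for the full model")

        # Sequential RSS path: x | x+group | x+group+interaction
        def rss(cols: np.ndarray) -> float:
            beta, *_ = np.linalg.lstsq(cols, y, rcond=None)
            r = y - cols @ beta
            return float(r @ r)

        tss = float(y @ y)
        rss1 = rss(design[:, :1])
        rss2 = rss(design[:, :3])
        rss3 = rss(design)
        ss = {
            "predictor": tss - rss1,
            "treatment": rss1 - rss2,
            "interaction": rss2 - rss3,
        }
        dfs = {"predictor": 1, "treatment": 2, "interaction": 1}
        df_res = n - 4
        ms_res = rss3 / df_res
        rows = []
        for term in ("predictor", "treatment", "interaction"):
            F = (ss[term] / dfs[term]) / ms_res if ms_res > 0 else math.inf
            F = max(F, 0.0) if math.isfinite(F) else F
            p = float(stats.f.sf(F, dfs[term], df_res)) if math.isfinite(F) else 0.0
            rows.append({"term": term, "ss": ss[term], "df": dfs[term],
                         "df_resid": df_res, "F": F, "p": p})
        rows.append({"term": "residual", "ss": rss3, "df": df_res,
                     "df_resid": df_res, "F": math.nan, "p": math.nan})
        self.anova_ = pd.DataFrame(rows).set_index("term")
        self.groups_ = groups
        self.n_ = n
        return self


def ancova_on_contrasts(table: pd.DataFrame) -> pd.DataFrame:
    """Fit the treatment-contingency ANCOVA; returns the anova table."""
    return ContrastAncova().fit(table).anova_


def stratum_regression(y, x) -> tuple[float, float, float]:
    """Through-origin simple regression of y-contrasts on x-contrasts.

    Returns ``(slope, adjusted R^2, p)`` with the slope's two-sided t-test
    p-value (df = n − 1).
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need aligned contrast vectors of length >= 3")
    if np.allclose(x, 0):
        raise ValueError("degenerate predictor contrasts (all zero)")
    m = OriginRegression().fit(x[:, None], y)
    test = m.slope_test()
    return float(m.coef_[0]), float(m.adj_r2_), float(test["p"].iloc[0])


def pic_pearson(a, b) -> CorrelationResult:
    """Ordinary Pearson correlation between two contrast sets.

    The t statistic is r sqrt((n−2)/(1−r²)) on df = n − 2.  A perfectly
    collinear pair is reported as |r| = 1 with infinite t and p flagged 0.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need aligned contrast vectors of length >= 3")
    r = float(stats.pearsonr(a, b).statistic)
    n = len(a)
    df = n - 2
    if abs(r) >= 1.0 - 1e-15:
        return CorrelationResult(r=math.copysign(1.0, r),
                                 t=math.copysign(math.inf, r),
                                 df=df, p=0.0, degenerate=True)
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, t=t, df=df, p=p)
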