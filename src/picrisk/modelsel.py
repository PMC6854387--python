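"""Through-origin regression on contrasts and AICc multimodel inference.

Regressions on independent contrasts are constrained through the origin:
a contrast has an arbitrary sign, so any model relating contrasts must map
(0, 0) to itself and an intercept would be meaningless.  Model comparison
uses the small-sample Akaike information criterion

    AICc = −2 ln L + 2k + 2k(k + 1)/(n − k − 1),

with the Gaussian log-likelihood evaluated at the maximum-likelihood residual
variance (RSS/n) and k counting the regression slopes plus one for that
variance (the null, slope-free model has k = 1).  Akaike weights
w_i ∝ exp(−ΔAICc/2) give each model's relative support; the relative variable
importance (RVI) of a predictor is the summed weight of the models containing
it, and coefficients are model-averaged over the containing models with
weights renormalized, using the unconditional (between-model) standard error
of Buckland et al.:

    SE = Σ w'_i sqrt(var(β_i) + (β_i − β̄)²).

The two-stage screen fits all subsets of the full predictor pool, ranks
predictors by RVI (by rank, not by any RVI cutoff), and refits all subsets of
the top three, which is the final inference set.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

_TIE_TOL = 1e-12


def standardize(values: Sequence[float]) -> np.ndarray:
    """Center to mean 0 and scale to sample standard deviation 1 (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize needs a 1-d array of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize values with zero spread")
    return (x - x.mean()) / sd


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample AIC: −2 lnL + 2k + 2k(k+1)/(n − k − 1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (needs n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("empty model set")
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()


def all_subsets(predictors: Sequence[str]) -> list[tuple[str, ...]]:
    """Every subset of the predictor pool (including the empty, null model),
    ordered by size then by predictor position — deterministic."""
    preds = list(predictors)
    if not 1 <= len(preds) <= 8:
        raise ValueError("predictor pool must have 1-8 names")
    if len(set(preds)) != len(preds):
        raise ValueError("predictor names must be unique")
    out: list[tuple[str, ...]] = []
    for r in range(len(preds) + 1):
        out.extend(itertools.combinations(preds, r))
    return out


class OriginRegression(RegressorMixin, BaseEstimator):
    """Least squares through the origin with information-criterion bookkeeping.

    Accepts a design with zero columns (the null model, which predicts 0
    everywhere).  The coefficient sampling variances use the unbiased
    residual variance RSS/(n − p); the log-likelihood uses the ML plug-in
    RSS/n, the convention under which the AICc values of nested contrast
    models reproduce published model-comparison tables.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
    rss_ : float
    loglik_ : float
        Gaussian log-likelihood at sigma^2 = RSS/n (+inf for an exact fit).
    k_ : int
        Parameter count, p + 1 (slopes plus the residual variance).
    aicc_ : float
    r2_, adj_r2_ : float
        Uncentered R^2 = 1 − RSS/Σy² and its adjustment by n/(n − p);
        both defined as 0.0 for the null model.
    coef_var_ : ndarray of shape (p,)
        Sampling variance of each slope.
    """

    def __init__(self, compute_aicc: bool = True):
        self.compute_aicc = compute_aicc

    def fit(self, X, y) -> "OriginRegression":
        y = np.asarray(y, dtype=float).ravel()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.size == 0:
            X = X.reshape(len(y), 0)
        n, p = X.shape
        if n != len(y):
            raise ValueError("X and y lengths differ")
        if not n > p + 1:
            raise ValueError(f"need n > p + 1 contrasts (n={n}, p={p})")
        if p > 0 and np.linalg.matrix_rank(X) < p:
            raise ValueError("rank-deficient design (collinear predictors)")

        tss = float(y @ y)
        if p > 0:
            xtx = X.T @ X
            coef = np.linalg.solve(xtx, X.T @ y)
            resid = y - X @ coef
            rss = float(resid @ resid)
            rss = max(rss, 0.0)
            sigma2_hat = rss / (n - p)
            self.coef_var_ = sigma2_hat * np.diag(np.linalg.inv(xtx))
        else:
            coef = np.empty(0)
            rss = tss
            self.coef_var_ = np.empty(0)

        self.coef_ = coef
        self.n_ = n
        self.k_ = p + 1
        self.rss_ = rss
        sigma2_ml = rss / n
        if sigma2_ml > 0:
            self.loglik_ = -0.5 * n * (math.log(2 * math.pi * sigma2_ml) + 1.0)
        else:
            self.loglik_ = math.inf
        if p > 0 and tss > 0:
            self.r2_ = 1.0 - rss / tss
            self.adj_r2_ = 1.0 - (rss / tss) * (n / (n - p))
        else:
            # Null model: uncentered R^2 is identically 0 by construction.
            self.r2_ = 0.0
            self.adj_r2_ = 0.0
        if self.compute_aicc:
            self.aicc_ = (aicc(self.loglik_, self.k_, n)
                          if n - self.k_ - 1 > 0 else math.nan)
        self.n_features_in_ = p
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.n_features_in_ == 0:
            return np.zeros(X.shape[0])
        return X @ self.coef_

    def slope_test(self) -> pd.DataFrame:
        """Wald t-test per slope (df = n − p), two-sided p-values."""
        from scipy import stats

        p = self.n_features_in_
        se = np.sqrt(self.coef_var_)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, self.coef_ / se, np.inf * np.sign(self.coef_))
        df = self.n_ - p
        pval = 2.0 * stats.t.sf(np.abs(t), df)
        return pd.DataFrame({"beta": self.coef_, "se": se, "t": t,
                             "df": df, "p": pval})


def fit_origin_ols(y, X, predictors: Sequence[str] | None = None) -> OriginRegression:
    """Thin functional wrapper over :class:`OriginRegression`."""
    model = OriginRegression().fit(np.asarray(X, dtype=float), y)
    model.predictors_ = tuple(predictors) if predictors is not None else None
    return model


def _model_label(predictors: tuple[str, ...]) -> str:
    return " + ".join(predictors) if predictors else "Null"


class AICcModelSelection(BaseEstimator):
    """All-subsets AICc model selection over a fixed predictor pool.

    Parameters
    ----------
    conditional : bool, default True
        Average coefficients over the models containing each predictor with
        renormalized weights (the convention matching "averaged across all
        models in which each parameter appeared").  If False, use full-set
        shrinkage averaging (absent models contribute a zero coefficient).
    ci_multiplier : float, default 1.96
        Normal multiplier for the 95% confidence bounds on averaged slopes.

    Attributes
    ----------
    table_ : DataFrame
        One row per model sorted by AICc: model, k, loglik, AICc, delta,
        weight, adj_r2.
    rvi_ : Series
        Relative variable importance per predictor, descending.
    averaged_ : DataFrame
        Model-averaged beta, unconditional SE, CI bounds and RVI per
        predictor.
    """

    def __init__(self, conditional: bool = True, ci_multiplier: float = 1.96):
        self.conditional = conditional
        self.ci_multiplier = ci_multiplier

    def fit(self, X: pd.DataFrame, y) -> "AICcModelSelection":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
        names = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=float).ravel()
        Xv = X.to_numpy(dtype=float)
        specs = all_subsets(names)
        fits: dict[tuple[str, ...], OriginRegression] = {}
        rows = []
        for spec in specs:
            idx = [names.index(s) for s in spec]
            m = OriginRegression().fit(Xv[:, idx], y)
            fits[spec] = m
            rows.append({
                "model": _model_label(spec), "predictors": spec, "k": m.k_,
                "loglik": m.loglik_, "aicc": m.aicc_, "adj_r2": m.adj_r2_,
            })
        tab = pd.DataFrame(rows)
        tab["weight"] = akaike_weights(tab["aicc"].to_numpy())
        tab["delta"] = tab["aicc"] - tab["aicc"].min()
        tab = tab.sort_values(["aicc", "model"], kind="mergesort",
                              ignore_index=True)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.fits_ = fits
        self.table_ = tab[["model", "predictors", "k", "loglik", "aicc",
                           "delta", "weight", "adj_r2"]]
        self.rvi_ = pd.Series(
            {nm: self.variable_importance(nm) for nm in names}, name="rvi"
        ).sort_values(ascending=False, kind="mergesort")
        self.averaged_ = pd.DataFrame(
            [dict(zip(("beta", "se", "ci_lower", "ci_upper"),
                      self.average_coefficient(nm)),
                  rvi=self.rvi_[nm])
             for nm in names],
            index=pd.Index(names, name="predictor"),
        ).sort_values("rvi", ascending=False, kind="mergesort")
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "table_"):
            raise AttributeError("model selection is not fitted yet")

    def variable_importance(self, predictor: str) -> float:
        """RVI: summed Akaike weight of the models containing ``predictor``."""
        self._check_fitted()
        if predictor not in self.feature_names_in_:
            raise KeyError(f"unknown predictor {predictor!r}")
        mask = self.table_["predictors"].apply(lambda s: predictor in s)
        return float(self.table_.loc[mask, "weight"].sum())

    def average_coefficient(self, predictor: str) -> tuple[float, float, float, float]:
        """Model-averaged slope: (beta, unconditional SE, CI lower, CI upper)."""
        self._check_fitted()
        if predictor not in self.feature_names_in_:
            raise KeyError(f"unknown predictor {predictor!r}")
        betas, variances, weights = [], [], []
        for _, row in self.table_.iterrows():
            spec = row["predictors"]
            if predictor in spec:
                m = self.fits_[spec]
                j = spec.index(predictor)
                betas.append(m.coef_[j])
                variances.append(m.coef_var_[j])
                weights.append(row["weight"])
            elif not self.conditional:
                betas.append(0.0)
                variances.append(0.0)
                weights.append(row["weight"])
        if not betas:
            raise ValueError(f"{predictor!r} appears in no fitted model")
        w = np.asarray(weights)
        if self.conditional:
            w = w / w.sum()
        b = np.asarray(betas)
        v = np.asarray(variances)
        beta_bar = float(w @ b)
        se = float(w @ np.sqrt(v + (b - beta_bar) ** 2))
        half = self.ci_multiplier * se
        return beta_bar, se, beta_bar - half, beta_bar + half

    def best_model(self) -> OriginRegression:
        self._check_fitted()
        return self.fits_[self.table_.iloc[0]["predictors"]]


def relative_variable_importance(selection: AICcModelSelection,
                                 predictor: str) -> float:
    return selection.variable_importance(predictor)


def model_average(selection: AICcModelSelection,
                  predictor: str) -> tuple[float, float, float]:
    """(averaged beta, CI lower, CI upper) for one predictor."""
    beta, _, lo, hi = selection.average_coefficient(predictor)
    return beta, lo, hi


class TwoStageModelSelection(BaseEstimator):
    """RVI screen over the full pool, then all-subsets inference on the top k.

    Stage 1 fits every subset of the full predictor pool and ranks predictors
    by RVI (descending; ties broken by name with a loud warning — the screen
    is by rank, not by an RVI threshold).  Stage 2 refits all subsets of the
    ``top_k`` ranked predictors; that selection object carries the final
    AICc table, RVI values and model-averaged coefficients.

    Attributes
    ----------
    stage1_rvi_ : Series
        Full-pool RVI ranking.
    top_predictors_ : list of str
    selection_ : AICcModelSelection
        The fitted stage-2 model set.
    """

    def __init__(self, top_k: int = 3, conditional: bool = True,
                 ci_multiplier: float = 1.96):
        self.top_k = top_k
        self.conditional = conditional
        self.ci_multiplier = ci_multiplier

    def fit(self, X: pd.DataFrame, y) -> "TwoStageModelSelection":
        stage1 = AICcModelSelection(conditional=self.conditional,
                                    ci_multiplier=self.ci_multiplier).fit(X, y)
        rvi = stage1.rvi_
        order = sorted(rvi.index, key=lambda nm: (-rvi[nm], nm))
        ranked = rvi.loc[order]
        vals = ranked.to_numpy()
        if np.any(np.abs(np.diff(vals)) < _TIE_TOL):
            warnings.warn(
                "RVI ties in stage-1 ranking; broken by predictor name order",
                UserWarning, stacklevel=2,
            )
        self.stage1_ = stage1
        self.stage1_rvi_ = ranked
        self.top_predictors_ = order[: self.top_k]
        self.selection_ = AICcModelSelection(
            conditional=self.conditional, ci_multiplier=self.ci_multiplier
        ).fit(X[self.top_predictors_], y)
        return self


def two_stage_screen(y, X: pd.DataFrame, top_k: int = 3) -> TwoStageModelSelection:
    """Thin functional wrapper over :class:`TwoStageModelSelection`."""
    return TwoStageModelSelection(top_k=top_k).fit(X, y)
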