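"""Empirical transpiration-rate (E) modelling and bootstrap evaluation.

Models are trained on ordered-quantile-normalised data: each variable is
mapped onto normal scores through its ranks, new values are transformed by
monotone interpolation of the fitted map, and predictions are inverted
back to the original E scale before any error metric is computed.  The
model suite spans single-index linear models, stepwise AIC selection,
LASSO, random forest and PLSR; accuracy is summarised as the median
out-of-bag RMSE / R-squared / MAPE over bootstrap resamples, and the
final full-data model can be applied unchanged to other genotypes to
measure transferability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import KFold, LeaveOneOut

import statsmodels.api as sm


class ConstantInputError(ValueError):
    """Ordered quantile normalisation needs spread in its input."""


class OrderNorm:
    """Ordered quantile (rank-based) normalisation with an invertible map.

    Training values of rank r (average ranks for ties) map to
    ``Phi^-1((r - 0.5) / n)``.  New values are transformed by monotone
    linear interpolation between the training (value, score) knots with
    linear extrapolation beyond the training range; the inverse map uses
    the same knots the other way round.
    """

    def __init__(self, scale: float = 1.0):
        self.scale = scale
        self.x_: np.ndarray | None = None
        self.s_: np.ndarray | None = None

    def fit(self, values) -> "OrderNorm":
        x = np.asarray(values, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 5:
            raise ValueError("ordered quantile normalisation needs >= 5 values")
        if np.ptp(x) == 0:
            raise ConstantInputError("input has no spread")
        ranks = stats.rankdata(x, method="average")
        scores = stats.norm.ppf((ranks - 0.5) / x.size) * self.scale
        order = np.argsort(x, kind="stable")
        xs, ss = x[order], scores[order]
        # collapse ties: equal values share their (equal) average-rank score
        ux, idx = np.unique(xs, return_index=True)
        self.x_, self.s_ = ux, ss[idx]
        return self

    def _interp(self, v, xp, fp):
        v = np.asarray(v, dtype=float)
        out = np.interp(v, xp, fp)
        if xp.size >= 2:
            lo_slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
            hi_slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
            out = np.where(v < xp[0], fp[0] + (v - xp[0]) * lo_slope, out)
            out = np.where(v > xp[-1], fp[-1] + (v - xp[-1]) * hi_slope, out)
        return out

    def transform(self, values):
        if self.x_ is None:
            raise RuntimeError("OrderNorm is not fitted")
        out = self._interp(values, self.x_, self.s_)
        return float(out) if out.ndim == 0 else out

    def inverse_transform(self, scores):
        if self.x_ is None:
            raise RuntimeError("OrderNorm is not fitted")
        out = self._interp(scores, self.s_, self.x_)
        return float(out) if out.ndim == 0 else out


class _Identity:
    """Stand-in transformer for predictors without spread."""

    def transform(self, values):
        return np.asarray(values, dtype=float)

    def inverse_transform(self, scores):
        return np.asarray(scores, dtype=float)


# ---------------------------------------------------------------------------
# metrics


def mape(actual, predicted) -> float:
    """Mean absolute percent error, ``mean(|(A - F) / A|) * 100``.

    Observations with A = 0 are excluded with a warning (the ratio is
    undefined there).
    """
    a = np.asarray(actual, dtype=float)
    f = np.asarray(predicted, dtype=float)
    nz = a != 0
    if not np.all(nz):
        warnings.warn(f"excluding {int((~nz).sum())} zero-valued observations from MAPE", stacklevel=2)
    if not np.any(nz):
        return np.nan
    return float(np.mean(np.abs((a[nz] - f[nz]) / a[nz])) * 100.0)


def rmse(actual, predicted) -> float:
    a = np.asarray(actual, dtype=float)
    f = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((a - f) ** 2)))


def r_squared(actual, predicted, kind: str = "corr") -> float:
    """R-squared: squared Pearson correlation (``corr``, the primary form)
    or ``1 - SSE/SST`` (``ss``).  NaN when the actual values are constant."""
    a = np.asarray(actual, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if np.ptp(a) == 0:
        return np.nan
    if kind == "corr":
        if np.ptp(f) == 0:
            return np.nan
        return float(np.corrcoef(a, f)[0, 1] ** 2)
    if kind == "ss":
        return float(1.0 - np.sum((a - f) ** 2) / np.sum((a - a.mean()) ** 2))
    raise ValueError("kind must be 'corr' or 'ss'")


def evaluation_metrics(actual, predicted) -> dict:
    """All evaluation metrics on the original E scale."""
    return {
        "rmse": rmse(actual, predicted),
        "r2": r_squared(actual, predicted, "corr"),
        "r2_ss": r_squared(actual, predicted, "ss"),
        "mape": mape(actual, predicted),
    }


# ---------------------------------------------------------------------------
# model fitting


LINEAR_METHODS = ("linear", "linear_index", "linear_index_env", "linear_index_env_hyp")
METHODS = LINEAR_METHODS + ("stepwise", "lasso", "rf", "plsr")


@dataclass
class ModelSpec:
    """Which method to fit on which feature columns."""

    method: str
    columns: list
    transform_predictors: bool = True
    transform_response: bool = True
    rf_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")


def _stepwise_aic(X: np.ndarray, y: np.ndarray, columns: list) -> list:
    """Greedy forward-backward AIC selection on OLS fits."""

    def aic_of(cols):
        if not cols:
            Xc = np.ones((len(y), 1))
        else:
            idx = [columns.index(c) for c in cols]
            Xc = sm.add_constant(X[:, idx])
        return sm.OLS(y, Xc).fit().aic

    selected: list = []
    current = aic_of(selected)
    improved = True
    while improved:
        improved = False
        candidates = []
        for c in columns:
            if c not in selected and len(selected) + 2 < len(y):
                candidates.append((aic_of(selected + [c]), "add", c))
        for c in selected:
            candidates.append((aic_of([s for s in selected if s != c]), "drop", c))
        if not candidates:
            break
        best = min(candidates)
        if best[0] < current - 1e-9:
            current = best[0]
            if best[1] == "add":
                selected.append(best[2])
            else:
                selected.remove(best[2])
            improved = True
    return selected


class EPredictor:
    """A fitted E prediction model including its frozen transformations."""

    def __init__(self, spec: ModelSpec, response: str = "E", seed: int = 0):
        self.spec = spec
        self.response = response
        self.seed = seed
        self.selected_variables: list = []
        self._estimator = None
        self._x_transformers: dict = {}
        self._y_transformer: OrderNorm | None = None

    def _transform_X(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for c in self.spec.columns:
            cols.append(self._x_transformers[c].transform(df[c].to_numpy(dtype=float)))
        return np.column_stack(cols)

    def fit(self, df: pd.DataFrame) -> "EPredictor":
        df = df.dropna(subset=[self.response] + list(self.spec.columns))
        y_raw = df[self.response].to_numpy(dtype=float)
        self._y_transformer = OrderNorm().fit(y_raw) if self.spec.transform_response else _Identity()
        y = self._y_transformer.transform(y_raw)
        for c in self.spec.columns:
            if self.spec.transform_predictors:
                try:
                    self._x_transformers[c] = OrderNorm().fit(df[c].to_numpy(dtype=float))
                except ConstantInputError:
                    self._x_transformers[c] = _Identity()
            else:
                self._x_transformers[c] = _Identity()
        X = self._transform_X(df)
        n, p = X.shape
        method = self.spec.method
        if method in LINEAR_METHODS:
            if p >= n:
                raise ValueError(
                    "more predictors than observations for an unpenalised linear fit; "
                    "use lasso or plsr"
                )
            self._estimator = LinearRegression().fit(X, y)
            self.selected_variables = list(self.spec.columns)
        elif method == "stepwise":
            self.selected_variables = _stepwise_aic(X, y, list(self.spec.columns))
            idx = [self.spec.columns.index(c) for c in self.selected_variables]
            self._stepwise_idx = idx
            Xs = X[:, idx] if idx else np.zeros((n, 0))
            self._estimator = LinearRegression().fit(Xs if idx else np.ones((n, 1)) * 0, y)
        elif method == "lasso":
            cv = LeaveOneOut() if n <= 120 else KFold(10, shuffle=True, random_state=self.seed)
            path = LassoCV(cv=cv, random_state=self.seed, max_iter=20000).fit(X, y)
            # one-standard-error rule: the sparsest penalty whose CV error is
            # within one SE of the minimum (the usual glmnet-style choice)
            mean_mse = path.mse_path_.mean(axis=1)
            se_mse = path.mse_path_.std(axis=1) / np.sqrt(path.mse_path_.shape[1])
            best = int(np.argmin(mean_mse))
            cutoff = mean_mse[best] + se_mse[best]
            ok = np.flatnonzero(mean_mse <= cutoff)
            alpha = float(path.alphas_[ok.min()])  # alphas_ is decreasing
            self._estimator = Lasso(alpha=alpha, max_iter=20000).fit(X, y)
            self._cv_alpha = alpha
            self.selected_variables = [
                c for c, coef in zip(self.spec.columns, self._estimator.coef_) if coef != 0
            ]
        elif method == "rf":
            params = {"n_estimators": 300, "min_samples_leaf": 2}
            params.update(self.spec.rf_params)
            self._estimator = RandomForestRegressor(random_state=self.seed, **params).fit(X, y)
            imp = self._estimator.feature_importances_
            self.selected_variables = [c for c, i in zip(self.spec.columns, imp) if i > 0]
        elif method == "plsr":
            max_comp = max(1, min(10, p, n - 2))
            best = (np.inf, 1)
            kf = KFold(n_splits=min(5, n), shuffle=True, random_state=self.seed)
            for k in range(1, max_comp + 1):
                errs = []
                for tr, te in kf.split(X):
                    m = PLSRegression(n_components=k).fit(X[tr], y[tr])
                    errs.append(np.mean((m.predict(X[te]).ravel() - y[te]) ** 2))
                score = float(np.mean(errs))
                if score < best[0]:
                    best = (score, k)
            self._n_components = best[1]
            self._estimator = PLSRegression(n_components=best[1]).fit(X, y)
            self.selected_variables = list(self.spec.columns)
        return self

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predict E on the original scale."""
        X = self._transform_X(df)
        if self.spec.method == "stepwise":
            X = X[:, self._stepwise_idx] if self._stepwise_idx else np.zeros((len(X), 1))
        yhat = np.asarray(self._estimator.predict(X)).ravel()
        return np.asarray(self._y_transformer.inverse_transform(yhat))


def fit_model(spec: ModelSpec, table: pd.DataFrame, response: str = "E", seed: int = 0) -> EPredictor:
    """Fit one E prediction model; see :class:`ModelSpec` for the methods."""
    return EPredictor(spec, response=response, seed=seed).fit(table)


def nested_model_chi2(
    table: pd.DataFrame, small: list, big: list, response: str = "E"
) -> dict:
    """Likelihood-ratio chi-square test for adding predictors to a linear model."""
    if not set(small) <= set(big):
        raise ValueError("small model terms must nest inside the big model")
    df = table.dropna(subset=[response] + list(big))
    y = df[response].to_numpy(dtype=float)

    def llf(cols):
        X = sm.add_constant(df[list(cols)].to_numpy(dtype=float)) if cols else np.ones((len(y), 1))
        return sm.OLS(y, X).fit().llf

    lr = 2.0 * (llf(big) - llf(small))
    ddf = len(big) - len(small)
    return {"chi2": float(lr), "df": ddf, "p": float(stats.chi2.sf(lr, ddf))}


# ---------------------------------------------------------------------------
# bootstrap evaluation and transfer


@dataclass
class ModelEvaluation:
    """Bootstrap evaluation of one model specification."""

    label: str
    per_boot: pd.DataFrame
    medians: dict
    final_model: EPredictor
    selected_variables: list
    n_redrawn: int = 0


def bootstrap_evaluate(
    spec: ModelSpec,
    table: pd.DataFrame,
    n_boot: int = 100,
    seed: int = 0,
    response: str = "E",
    label: str | None = None,
    block_col: str | None = None,
) -> ModelEvaluation:
    """Out-of-bag bootstrap evaluation of an E prediction model.

    For each resample the model (including its normalisation maps) is
    refitted on the resampled rows and scored on the out-of-bag rows on
    the original E scale; the per-metric medians summarise accuracy.  A
    resample leaving no out-of-bag rows is redrawn.  ``block_col`` switches
    the resampling unit from rows to blocks (e.g. plants).

    A final model is fitted on the whole table for transfer evaluation.
    """
    table = table.dropna(subset=[response] + list(spec.columns)).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(table)
    rows = []
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            if block_col is None:
                idx = rng.integers(0, n, n)
                oob = np.setdiff1d(np.arange(n), idx)
            else:
                blocks = table[block_col].unique()
                chosen = rng.choice(blocks, size=len(blocks), replace=True)
                idx = np.concatenate(
                    [np.flatnonzero(table[block_col].to_numpy() == blk) for blk in chosen]
                )
                oob = np.flatnonzero(~table[block_col].isin(chosen).to_numpy())
            if oob.size > 0:
                break
            n_redrawn += 1
        model = EPredictor(spec, response=response, seed=seed + b).fit(table.iloc[idx])
        pred = model.predict(table.iloc[oob])
        m = evaluation_metrics(table.iloc[oob][response].to_numpy(dtype=float), pred)
        m["boot"] = b
        rows.append(m)
    per_boot = pd.DataFrame(rows)
    medians = {k: float(per_boot[k].median()) for k in ("rmse", "r2", "r2_ss", "mape")}
    final = EPredictor(spec, response=response, seed=seed).fit(table)
    return ModelEvaluation(
        label=label or spec.method,
        per_boot=per_boot,
        medians=medians,
        final_model=final,
        selected_variables=final.selected_variables,
        n_redrawn=n_redrawn,
    )


def evaluate_transfer(
    final_model: EPredictor,
    table: pd.DataFrame,
    genotype_col: str = "genotype",
    response: str = "E",
) -> pd.DataFrame:
    """Apply a frozen model to each genotype's rows and report the metrics.

    Genotypes with constant E get NaN R-squared (flagged) but finite RMSE.
    """
    rows = []
    for genotype, g in table.groupby(genotype_col):
        g = g.dropna(subset=[response] + list(final_model.spec.columns))
        if g.empty:
            continue
        pred = final_model.predict(g)
        m = evaluation_metrics(g[response].to_numpy(dtype=float), pred)
        m[genotype_col] = genotype
        m["n"] = len(g)
        rows.append(m)
    return pd.DataFrame(rows)


def select_features_by_importance(
    table: pd.DataFrame,
    columns: list,
    response: str = "E",
    seed: int = 0,
    n_splits: int = 5,
    rf_params: dict | None = None,
) -> list:
    """Importance-ranked feature subset selection for the random forest.

    Features are ranked by permutation importance of a forest fitted on
    all candidates; nested prefixes of the ranking are scored by K-fold
    cross-validated MSE and the smallest prefix whose error is within one
    standard error of the best prefix is returned.
    """
    from sklearn.inspection import permutation_importance

    df = table.dropna(subset=[response] + list(columns)).reset_index(drop=True)
    X = df[list(columns)].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    params = {"n_estimators": 200, "min_samples_leaf": 2}
    params.update(rf_params or {})
    forest = RandomForestRegressor(random_state=seed, **params).fit(X, y)
    imp = permutation_importance(forest, X, y, n_repeats=5, random_state=seed)
    order = np.argsort(-imp.importances_mean, kind="stable")
    ranked = [columns[i] for i in order]
    kf = KFold(n_splits=min(n_splits, len(df)), shuffle=True, random_state=seed)
    scores = []
    for k in range(1, len(ranked) + 1):
        idx = order[:k]
        errs = []
        for tr, te in kf.split(X):
            m = RandomForestRegressor(random_state=seed, **params).fit(X[tr][:, idx], y[tr])
            errs.append(np.mean((m.predict(X[te][:, idx]) - y[te]) ** 2))
        scores.append((float(np.mean(errs)), float(np.std(errs) / np.sqrt(len(errs)))))
    best_k = int(np.argmin([s[0] for s in scores]))
    cutoff = scores[best_k][0] + scores[best_k][1]
    for k, (mean_err, _) in enumerate(scores):
        if mean_err <= cutoff:
            return ranked[: k + 1]
    return ranked
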