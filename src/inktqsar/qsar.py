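"""Structure–immune regression models: stepwise MLR and PLS with Q².

D-values (or log relative responses) are regressed on autoscaled chemical
descriptors.  Two model families are provided:

* **Stepwise multiple linear regression.**  Forward steps add the candidate
  descriptor with the smallest partial-F probability; backward steps remove
  any included descriptor whose partial-F probability exceeds the removal
  threshold; iterate to a fixed point.  The entry/removal thresholds are
  probabilities of F (defaults 0.05 / 0.10).  Because the forward step
  scans many candidates, the default entry test compares the *smallest*
  candidate p-value after Bonferroni adjustment for the number of
  candidates, holding the per-step false-entry rate at ``p_enter``; set
  ``adjust="none"`` for the classical per-candidate rule.

* **Partial least squares.**  Latent-component regression (NIPALS) on
  autoscaled descriptors, appropriate when descriptors are many and
  collinear.  Predictive ability is estimated by k-fold (default
  seven-fold) cross-validation: Q² = 1 − PRESS/SS_tot, with each fold
  predicted by a model fit on the remaining folds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

__all__ = ["MLRModel", "PLSModel", "stepwise_mlr_fit", "pls_fit", "kfold_q2",
           "choose_pls_components", "predict_desirability", "model_report"]


def _complete_case(X: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    y = pd.Series(y).astype(float)
    X, y = X.align(y, join="inner", axis=0)
    keep = y.notna() & X.notna().all(axis=1)
    return X.loc[keep], y.loc[keep]


@dataclass
class MLRModel:
    """Stepwise-selected linear model on autoscaled descriptors."""

    selected: list
    coefficients: pd.Series        # per unit of scaled descriptor
    intercept: float
    r2: float
    trace: list = field(repr=False)
    x_mean: pd.Series = field(repr=False, default=None)
    x_std: pd.Series = field(repr=False, default=None)
    q2: float | None = None

    @property
    def descriptor_names(self) -> list:
        return list(self.selected)

    def predict(self, X_new: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.selected if c not in X_new.columns]
        if missing:
            raise KeyError(f"descriptor column(s) missing from input: {missing}")
        if not self.selected:
            return pd.Series(self.intercept, index=X_new.index)
        Z = (X_new[self.selected] - self.x_mean[self.selected]) / self.x_std[self.selected]
        return Z @ self.coefficients[self.selected] + self.intercept

    def to_json(self) -> str:
        return json.dumps({
            "kind": "mlr",
            "selected": list(self.selected),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "intercept": float(self.intercept),
            "r2": float(self.r2),
            "q2": None if self.q2 is None else float(self.q2),
            "x_mean": {k: float(self.x_mean[k]) for k in self.selected},
            "x_std": {k: float(self.x_std[k]) for k in self.selected},
            "trace": self.trace,
        }, ensure_ascii=False, indent=1)


def _ols_rss(Xs: np.ndarray, y: np.ndarray, idx: list[int]):
    """RSS, coefficients and rank of an intercept + columns[idx] fit."""
    n = y.shape[0]
    A = np.column_stack([np.ones(n)] + [Xs[:, j] for j in idx])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), coef, rank


def stepwise_mlr_fit(X: pd.DataFrame, y: pd.Series, p_enter: float = 0.05,
                     p_remove: float = 0.10, adjust: str = "bonferroni",
                     max_steps: int = 200) -> MLRModel:
    """Forward/backward stepwise regression on partial-F probabilities.

    Candidates whose addition would make the design rank-deficient
    (perfect collinearity with already-selected descriptors) are skipped.
    Ties break to the earliest column.  If nothing passes entry, an
    intercept-only model is returned with a warning.
    """
    if not p_enter < p_remove:
        raise ValueError("require p_enter < p_remove")
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjust {adjust!r}")
    X, y = _complete_case(X, y)
    n = len(y)
    if n < 10:
        raise ValueError(f"need >= 10 complete-case rows, have {n}")

    stds = X.std(axis=0, ddof=1)
    usable = [c for c in X.columns if stds[c] > 0]
    x_mean, x_std = X[usable].mean(axis=0), X[usable].std(axis=0, ddof=1)
    Xs = ((X[usable] - x_mean) / x_std).to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("response has zero variance")

    selected: list[int] = []
    trace: list[dict] = []
    rss_cur, coef_cur, _ = _ols_rss(Xs, yv, selected)

    def partial_p(rss_small: float, rss_big: float, k_big: int) -> float:
        df2 = n - k_big - 1
        if df2 <= 0:
            return 1.0
        if rss_big <= 0:
            return 0.0
        F = (rss_small - rss_big) / (rss_big / df2)
        return float(stats.f.sf(max(F, 0.0), 1, df2))

    for _ in range(max_steps):
        changed = False
        # forward: best single addition
        candidates = [j for j in range(len(usable)) if j not in selected]
        best_j, best_p, best_rss = None, np.inf, None
        for j in candidates:
            rss_j, _, rank = _ols_rss(Xs, yv, selected + [j])
            if rank < len(selected) + 2:   # collinear with current model
                continue
            p = partial_p(rss_cur, rss_j, len(selected) + 1)
            if p < best_p:
                best_j, best_p, best_rss = j, p, rss_j
        if best_j is not None:
            p_eff = best_p * len(candidates) if adjust == "bonferroni" else best_p
            if p_eff < p_enter:
                selected.append(best_j)
                rss_cur, coef_cur, _ = _ols_rss(Xs, yv, selected)
                trace.append({"step": len(trace) + 1, "action": "add",
                              "descriptor": usable[best_j], "p": best_p,
                              "p_adjusted": p_eff})
                changed = True
        # backward: drop the worst included descriptor, repeatedly
        while len(selected) > 0:
            worst_i, worst_p = None, -1.0
            for pos, j in enumerate(selected):
                reduced = selected[:pos] + selected[pos + 1:]
                rss_red, _, _ = _ols_rss(Xs, yv, reduced)
                p = partial_p(rss_red, rss_cur, len(selected))
                if p > worst_p:
                    worst_i, worst_p = pos, p
            if worst_p > p_remove:
                dropped = selected.pop(worst_i)
                rss_cur, coef_cur, _ = _ols_rss(Xs, yv, selected)
                trace.append({"step": len(trace) + 1, "action": "remove",
                              "descriptor": usable[dropped], "p": worst_p})
                changed = True
            else:
                break
        if not changed:
            break

    if not selected:
        warnings.warn("stepwise selection admitted no descriptor; "
                      "returning intercept-only model", stacklevel=2)
    names = [usable[j] for j in selected]
    coefficients = pd.Series(coef_cur[1:], index=names, dtype=float)
    r2 = 1.0 - rss_cur / ss_tot
    return MLRModel(selected=names, coefficients=coefficients,
                    intercept=float(coef_cur[0]), r2=float(r2), trace=trace,
                    x_mean=x_mean, x_std=x_std)


@dataclass
class PLSModel:
    """PLS regression model (autoscaled descriptors, centered response)."""

    n_components: int
    descriptor_names: list
    coefficients: pd.Series        # original descriptor scale
    intercept: float
    r2: float
    x_scores: np.ndarray = field(repr=False, default=None)
    x_weights: np.ndarray = field(repr=False, default=None)
    x_loadings: np.ndarray = field(repr=False, default=None)
    q2: float | None = None
    _sk: PLSRegression = field(repr=False, default=None)

    def predict(self, X_new: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.descriptor_names if c not in X_new.columns]
        if missing:
            raise KeyError(f"descriptor column(s) missing from input: {missing}")
        yhat = self._sk.predict(X_new[self.descriptor_names].to_numpy(dtype=float))
        return pd.Series(np.ravel(yhat), index=X_new.index)

    def to_json(self) -> str:
        return json.dumps({
            "kind": "pls",
            "n_components": int(self.n_components),
            "descriptors": list(self.descriptor_names),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "intercept": float(self.intercept),
            "r2": float(self.r2),
            "q2": None if self.q2 is None else float(self.q2),
        }, ensure_ascii=False, indent=1)


def pls_fit(X: pd.DataFrame, y: pd.Series, n_components: int = 2) -> PLSModel:
    """Fit a PLS regression with ``n_components`` latent components.

    Descriptors are autoscaled and the response centered inside the fit;
    reported coefficients are back-transformed to the input scale.
    Zero-variance descriptor columns are dropped before fitting.
    """
    X, y = _complete_case(X, y)
    n, p = X.shape
    if float(y.std(ddof=0)) == 0:
        raise ValueError("response has zero variance")
    stds = X.std(axis=0, ddof=1)
    usable = [c for c in X.columns if stds[c] > 0]
    if not 1 <= n_components <= min(n - 1, len(usable)):
        raise ValueError(f"n_components must be in [1, {min(n - 1, len(usable))}]")
    sk = PLSRegression(n_components=n_components, scale=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sk.fit(X[usable].to_numpy(dtype=float), y.to_numpy(dtype=float))
    yhat = np.ravel(sk.predict(X[usable].to_numpy(dtype=float)))
    yv = y.to_numpy(dtype=float)
    r2 = 1.0 - np.sum((yv - yhat) ** 2) / np.sum((yv - yv.mean()) ** 2)
    coefficients = pd.Series(np.ravel(sk.coef_), index=usable, dtype=float)
    intercept = float(np.ravel(sk.intercept_)[0])
    return PLSModel(n_components=n_components, descriptor_names=usable,
                    coefficients=coefficients, intercept=intercept, r2=float(r2),
                    x_scores=sk.x_scores_, x_weights=sk.x_weights_,
                    x_loadings=sk.x_loadings_, _sk=sk)


def kfold_q2(X: pd.DataFrame, y: pd.Series, fit, k: int = 7,
             seed: int = 0) -> tuple[float, list[float]]:
    """Cross-validated Q² = 1 − PRESS/SS_tot for an arbitrary model factory.

    ``fit(X_train, y_train)`` must return an object with
    ``predict(X_test)``.  Fold assignment is a deterministic shuffle of the
    rows under ``seed``; SS_tot is taken about the full-data mean.
    """
    X, y = _complete_case(X, y)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    yv = y.to_numpy(dtype=float)
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    press_per_fold = []
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True,
                                     random_state=int(seed)).split(X):
        model = fit(X.iloc[train_idx], y.iloc[train_idx])
        pred = np.asarray(model.predict(X.iloc[test_idx]), dtype=float).ravel()
        press_per_fold.append(float(np.sum((yv[test_idx] - pred) ** 2)))
    q2 = 1.0 - sum(press_per_fold) / ss_tot
    return float(q2), press_per_fold


def choose_pls_components(X: pd.DataFrame, y: pd.Series, max_components: int = 10,
                          k: int = 7, seed: int = 0,
                          min_gain: float = 0.01) -> tuple[int, list[float]]:
    """Pick the PLS component count by cross-validated Q².

    Components are added while Q² improves by at least ``min_gain``;
    returns the chosen count and the Q² sequence actually evaluated.
    """
    X, y = _complete_case(X, y)
    stds = X.std(axis=0, ddof=1)
    usable = [c for c in X.columns if stds[c] > 0]
    limit = max(1, min(max_components, len(usable)))
    q2s: list[float] = []
    best = 1
    for a in range(1, limit + 1):
        try:
            q2, _ = kfold_q2(X, y, lambda Xt, yt, a=a: pls_fit(Xt, yt, a), k=k,
                             seed=seed)
        except ValueError:
            break
        q2s.append(q2)
        if a > 1 and q2 < q2s[best - 1] + min_gain:
            break
        if q2 >= q2s[best - 1]:
            best = a
    return best, q2s


def predict_desirability(model, X_new: pd.DataFrame, clip: bool = False,
                         d_min: float = 0.1, d_max: float = 0.9) -> pd.Series:
    """Predict D-values for new compounds; optionally clip to [d_min, d_max]."""
    pred = model.predict(X_new)
    if clip:
        pred = pred.clip(d_min, d_max)
    return pred


def model_report(model, title: str = "") -> str:
    """Human-readable descriptor → coefficient listing."""
    lines = []
    if title:
        lines.append(title)
    kind = "MLR" if isinstance(model, MLRModel) else "PLS"
    lines.append(f"model: {kind}")
    if isinstance(model, PLSModel):
        lines.append(f"components: {model.n_components}")
    lines.append(f"R2 = {model.r2:.4f}")
    if model.q2 is not None:
        lines.append(f"Q2 = {model.q2:.4f}")
    lines.append(f"intercept = {model.intercept:.6g}")
    for name, coef in model.coefficients.items():
        lines.append(f"  {name:<16} {coef:+.6g}")
    return "\n".join(lines)
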