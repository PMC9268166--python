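"""Single-response partial least squares (PLS1) and validation statistics.

PLS extracts a small number of latent variables (LVs) — directions in
descriptor space of maximal covariance with the response — and regresses
the response on them, which remains stable when descriptors are many and
highly collinear.  Extraction uses the NIPALS recursion on autoscaled X
(mean 0, unit sample SD) and mean-centered y; with as many LVs as the
rank of centered X the fit coincides with ordinary least squares.

External validation follows the standard QSAR battery: training R^2,
leave-one-out Q^2 and RMSE_CV, and on a held-out test set the Q^2_F1,
Q^2_F2 and Q^2_F3 determination coefficients (differing in the reference
sum of squares: training mean, external mean, per-n variance
normalization), RMSEP, and Lin's concordance correlation coefficient
(CCC), which penalizes both imprecision and location/scale shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSModel",
    "pls_fit",
    "pls_predict",
    "q2_loo",
    "ValidationStats",
    "validation_stats",
    "PLSRegression",
    "PLSResults",
]


@dataclass
class PLSModel:
    """Fitted PLS1 state on the autoscaled/centered training frame."""

    n_components: int
    feature_names: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    x_weights: np.ndarray    # p x a   (NIPALS w)
    x_loadings: np.ndarray   # p x a   (p)
    y_loadings: np.ndarray   # a       (q)
    coef_scaled: np.ndarray  # p       coefficients on autoscaled X, centered y
    coef_: np.ndarray        # p       coefficients on the original X scale
    intercept_: float
    training_ids: list | None = None


def _design(X) -> tuple[np.ndarray, list[str], list | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns], list(X.index)
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])], None


def pls_fit(X, y, n_components: int) -> PLSModel:
    """Fit a PLS1 model with ``n_components`` latent variables (NIPALS)."""
    Xa, names, ids = _design(X)
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if ya.size != n:
        raise ValueError("X and y have different numbers of rows")
    if n < n_components + 2:
        raise ValueError("too few samples for the requested number of LVs")
    if not (np.all(np.isfinite(Xa)) and np.all(np.isfinite(ya))):
        raise ValueError("non-finite values in X or y")
    x_mean = Xa.mean(axis=0)
    x_std = Xa.std(axis=0, ddof=1)
    dead = np.flatnonzero(x_std == 0)
    if dead.size:
        raise ValueError(f"zero-variance descriptor: {names[dead[0]]!r}")
    E = (Xa - x_mean) / x_std
    rank = np.linalg.matrix_rank(E)
    if not 1 <= n_components <= rank:
        raise ValueError(f"n_components must be in [1, rank(X)={rank}]")
    y_mean = float(ya.mean())
    f = ya - y_mean

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    for a in range(n_components):
        w = E.T @ f
        w_norm = np.linalg.norm(w)
        if w_norm == 0:
            raise ValueError("residual X carries no covariance with y; reduce LVs")
        w /= w_norm
        t = E @ w
        tt = float(t @ t)
        p_a = E.T @ t / tt
        q_a = float(f @ t) / tt
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a

    coef_scaled = W @ np.linalg.solve(P.T @ W, q)
    coef = coef_scaled / x_std
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(n_components, names, x_mean, x_std, y_mean, W, P, q,
                    coef_scaled, coef, intercept, ids)


def pls_predict(model: PLSModel, X_new) -> np.ndarray:
    """Predict the response for new compounds."""
    if isinstance(X_new, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in X_new.columns]
        if missing:
            raise ValueError(f"missing descriptor column: {missing[0]!r}")
        arr = X_new[model.feature_names].to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(X_new, dtype=float))
        if arr.shape[1] != len(model.feature_names):
            raise ValueError("wrong number of descriptor columns")
    return arr @ model.coef_ + model.intercept_


def q2_loo(X, y, n_components: int) -> tuple[float, float]:
    """Leave-one-out Q^2 and RMSE_CV.

    Each compound is held out in turn, the model refit on the rest and
    the held-out response predicted.  Q^2 = 1 - PRESS/TSS with TSS about
    the full-training mean; RMSE_CV = sqrt(PRESS/n).
    """
    Xa, _, _ = _design(X)
    ya = np.asarray(y, dtype=float).ravel()
    n = len(ya)
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out")
    press = 0.0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        m = pls_fit(Xa[mask], ya[mask], n_components)
        press += float((pls_predict(m, Xa[i:i + 1])[0] - ya[i]) ** 2)
        mask[i] = True
    tss = float(((ya - ya.mean()) ** 2).sum())
    return 1.0 - press / tss, float(np.sqrt(press / n))


@dataclass
class ValidationStats:
    """Training and external-validation figures of merit.

    A statistic whose reference sum of squares degenerates to zero is set
    to NaN and listed in ``undefined`` rather than reported as infinite.
    """

    r2: float
    q2_f1: float
    q2_f2: float
    q2_f3: float
    rmse_p: float
    ccc: float
    n_tr: int
    n_ext: int
    q2_loo: float | None = None
    rmse_cv: float | None = None
    undefined: tuple[str, ...] = ()

    def summary(self) -> str:
        parts = [f"R2={self.r2:.3f}"]
        if self.q2_loo is not None:
            parts += [f"Q2loo={self.q2_loo:.3f}", f"RMSEcv={self.rmse_cv:.3f}"]
        parts += [
            f"RMSEP={self.rmse_p:.3f}", f"Q2F1={self.q2_f1:.3f}",
            f"Q2F2={self.q2_f2:.3f}", f"Q2F3={self.q2_f3:.3f}",
            f"CCC={self.ccc:.3f}", f"nTR={self.n_tr}", f"nEXT={self.n_ext}",
        ]
        return "  ".join(parts)


def validation_stats(y_obs_tr, y_pred_tr, y_obs_ext, y_pred_ext) -> ValidationStats:
    """Compute R^2, Q^2_F1/F2/F3, RMSEP and CCC from observed/predicted pairs."""
    yt = np.asarray(y_obs_tr, dtype=float).ravel()
    pt = np.asarray(y_pred_tr, dtype=float).ravel()
    ye = np.asarray(y_obs_ext, dtype=float).ravel()
    pe = np.asarray(y_pred_ext, dtype=float).ravel()
    if yt.size == 0 or ye.size == 0 or yt.size != pt.size or ye.size != pe.size:
        raise ValueError("observed/predicted vectors empty or mismatched")
    n_tr, n_ext = yt.size, ye.size
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return np.nan
        return num / den

    ss_tr = float(((yt - pt) ** 2).sum())
    tss_tr = float(((yt - yt.mean()) ** 2).sum())
    r2 = 1.0 - ratio(ss_tr, tss_tr, "r2")

    ss_ext = float(((ye - pe) ** 2).sum())
    ss_about_tr = float(((ye - yt.mean()) ** 2).sum())
    ss_about_ext = float(((ye - ye.mean()) ** 2).sum())
    q2_f1 = 1.0 - ratio(ss_ext, ss_about_tr, "q2_f1")
    q2_f2 = 1.0 - ratio(ss_ext, ss_about_ext, "q2_f2")
    q2_f3 = 1.0 - ratio(ss_ext / n_ext, tss_tr / n_tr, "q2_f3")
    rmse_p = float(np.sqrt(ss_ext / n_ext))

    s_obs = float(((ye - ye.mean()) ** 2).sum())
    s_pred = float(((pe - pe.mean()) ** 2).sum())
    cov = float(((ye - ye.mean()) * (pe - pe.mean())).sum())
    den = s_obs + s_pred + n_ext * (ye.mean() - pe.mean()) ** 2
    ccc = ratio(2.0 * cov, den, "ccc")
    return ValidationStats(r2, q2_f1, q2_f2, q2_f3, rmse_p, ccc,
                           n_tr, n_ext, undefined=tuple(undefined))


class PLSRegression:
    """Model-style wrapper: ``PLSRegression(X, y, n_components).fit()``."""

    def __init__(self, X, y, n_components: int = 3):
        self.X = X
        self.y = y
        self.n_components = n_components

    def fit(self) -> "PLSResults":
        model = pls_fit(self.X, self.y, self.n_components)
        fitted = pls_predict(model, self.X)
        return PLSResults(self, model, fitted)


@dataclass
class PLSResults:
    model_spec: PLSRegression
    model: PLSModel
    fittedvalues: np.ndarray
    _loo: tuple[float, float] | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        s = pd.Series(self.model.coef_, index=self.model.feature_names)
        s["(intercept)"] = self.model.intercept_
        return s

    @property
    def rsquared(self) -> float:
        y = np.asarray(self.model_spec.y, dtype=float).ravel()
        return 1.0 - float(((y - self.fittedvalues) ** 2).sum()
                           / ((y - y.mean()) ** 2).sum())

    def loo(self) -> tuple[float, float]:
        if self._loo is None:
            self._loo = q2_loo(self.model_spec.X, self.model_spec.y,
                               self.model.n_components)
        return self._loo

    def predict(self, X_new) -> np.ndarray:
        return pls_predict(self.model, X_new)

    def summary(self) -> str:
        q2, rmse_cv = self.loo()
        lines = [
            f"PLS1 regression, {self.model.n_components} latent variable(s), "
            f"{len(self.model.feature_names)} descriptors",
            f"  R2 = {self.rsquared:.4f}   Q2loo = {q2:.4f}   "
            f"RMSEcv = {rmse_cv:.4f}",
            "  coefficients (original scale):",
        ]
        for name, val in self.params.items():
            lines.append(f"    {name:<20}{val: .5f}")
        return "\n".join(lines)
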