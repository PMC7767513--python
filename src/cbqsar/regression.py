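"""Linear QSAR model fitting: OLS, forward-selection MLR, VIF, NIPALS PLS1.

Two regression families operate on the standardized descriptor matrix:

* :class:`ForwardSelectionMLR` — ordinary least squares with greedy
  forward feature selection driven by adjusted R², the classical recipe
  when the training set is tiny and descriptors are collinear.
* :class:`PLS1Regression` — NIPALS partial least squares for a single
  response.  Each component extracts a weight vector w maximizing the
  covariance of the X-score t = X w with the (deflated) response, then
  deflates X by t pᵀ and y by q t.  The score/weight/loading matrices
  collapse to an ordinary coefficient vector, which is the prediction
  contract; at full rank the collapsed model reproduces OLS.

Both produce a :class:`~cbqsar.models.LinearModel` whose intercept is
the training mean response (a consequence of centered predictors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .models import LinearModel
from .validation import adjusted_r_squared, r_squared

__all__ = [
    "ols_fit",
    "vif",
    "SelectionStep",
    "SelectionTrace",
    "ForwardSelectionMLR",
    "PLS1Regression",
    "ComponentScan",
    "scan_components",
]


def _frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def ols_fit(Z, y, *, condition_threshold: float = 1e10) -> LinearModel:
    """Ordinary least squares on standardized predictors.

    Solves the normal equations beta = (Z'Z)^-1 Z'y on internally
    centered predictors; for standardized input the intercept equals
    mean(y) and residuals are orthogonal to every predictor.

    Raises on n <= p and on designs whose condition number exceeds
    ``condition_threshold`` (collinearity).
    """
    Z = _frame(Z)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Z.shape
    if y.shape[0] != n:
        raise ValueError("Z rows and y length differ")
    if n <= p:
        raise ValueError(f"need n > p for OLS; got n={n}, p={p}")
    Xc = Z.to_numpy(dtype=float)
    col_means = Xc.mean(axis=0)
    Xc = Xc - col_means
    cond = np.linalg.cond(Xc)
    if not np.isfinite(cond) or cond > condition_threshold:
        raise ValueError(
            f"singular or ill-conditioned design (cond={cond:.3g}); "
            f"columns: {list(Z.columns)}"
        )
    ybar = float(y.mean())
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - ybar))
    # for standardized predictors col_means ~ 0, so intercept == mean(y)
    intercept = ybar - float(col_means @ beta)
    return LinearModel(
        feature_names=tuple(Z.columns),
        coefficients=tuple(beta),
        intercept=intercept,
        provenance="ols",
    )


def vif(Z, features: Optional[Sequence[str]] = None) -> dict:
    """Variance inflation factors, VIF_j = 1 / (1 - R²_j).

    R²_j comes from regressing descriptor j on the remaining
    descriptors (with intercept).  Perfect collinearity reports
    ``inf`` for the implicated features.
    """
    Z = _frame(Z)
    if features is not None:
        Z = Z.loc[:, list(features)]
    if Z.shape[1] < 2:
        raise ValueError("VIF needs at least 2 features")
    out = {}
    X = Z.to_numpy(dtype=float)
    for j, name in enumerate(Z.columns):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        sst = float(((yj - yj.mean()) ** 2).sum())
        if sst == 0:
            raise ValueError(f"zero-variance feature {name!r}")
        r2_j = 1.0 - float((resid ** 2).sum()) / sst
        out[name] = float("inf") if 1.0 - r2_j < 1e-12 else 1.0 / (1.0 - r2_j)
    return out


@dataclass
class SelectionStep:
    feature: str
    adjusted_r2: float
    accepted: bool


@dataclass
class SelectionTrace:
    steps: List[SelectionStep] = field(default_factory=list)

    @property
    def accepted_features(self) -> List[str]:
        return [s.feature for s in self.steps if s.accepted]

    def validate(self) -> None:
        accepted = [s.adjusted_r2 for s in self.steps if s.accepted]
        if any(b <= a for a, b in zip(accepted, accepted[1:])):
            raise ValueError("accepted steps must strictly increase adjusted R²")


class ForwardSelectionMLR(RegressorMixin, BaseEstimator):
    """Greedy forward-selected multiple linear regression.

    At each round every unselected descriptor is trial-added and the
    one giving the highest adjusted R² wins (ties broken by higher
    absolute correlation with the response, then lexicographic name).
    Selection stops when the best candidate fails to *strictly*
    increase adjusted R², when ``max_features`` is reached, or when
    another feature would exhaust the residual degrees of freedom.

    Attributes (after fit)
    ----------------------
    selected_features_ : list of str
    trace_ : SelectionTrace
    model_ : LinearModel (provenance "forward_mlr")
    coef_, intercept_ : collapsed parameters for sklearn interop
    """

    def __init__(self, max_features: Optional[int] = None,
                 condition_threshold: float = 1e10):
        self.max_features = max_features
        self.condition_threshold = condition_threshold

    def fit(self, X, y):
        X = _frame(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[1] < 1:
            raise ValueError("need at least one candidate feature")
        n = X.shape[0]
        limit = self.max_features if self.max_features is not None else X.shape[1]
        # tie-break key: |r(feature, y)| descending, then name ascending
        abs_r = {}
        yc = y - y.mean()
        ynorm = float(np.sqrt((yc ** 2).sum()))
        for name in X.columns:
            xc = X[name].to_numpy(dtype=float)
            xc = xc - xc.mean()
            xnorm = float(np.sqrt((xc ** 2).sum()))
            abs_r[name] = abs(float(xc @ yc) / (xnorm * ynorm)) if xnorm and ynorm else 0.0

        selected: List[str] = []
        trace = SelectionTrace()
        best_adj = -np.inf
        while len(selected) < limit and n - (len(selected) + 1) - 1 > 0:
            candidates = [c for c in X.columns if c not in selected]
            if not candidates:
                break
            scored = []
            for name in candidates:
                cols = selected + [name]
                try:
                    model = ols_fit(X[cols], y,
                                    condition_threshold=self.condition_threshold)
                except ValueError:
                    continue  # collinear with already-selected features
                yhat = model.predict(X[cols])
                r2 = r_squared(y, yhat)
                adj = adjusted_r_squared(r2, n, len(cols))
                scored.append((adj, abs_r[name], name))
            if not scored:
                break
            # highest adjusted R2; ties -> larger |r|; ties -> earlier name
            scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
            adj, _, name = scored[0]
            if adj > best_adj:
                trace.steps.append(SelectionStep(name, adj, True))
                selected.append(name)
                best_adj = adj
            else:
                trace.steps.append(SelectionStep(name, adj, False))
                break
        trace.validate()
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.selected_features_ = selected
        self.trace_ = trace
        if selected:
            base = ols_fit(X[selected], y,
                           condition_threshold=self.condition_threshold)
        else:
            base = LinearModel((), (), float(y.mean()), "ols")
        self.model_ = LinearModel(base.feature_names, base.coefficients,
                                  base.intercept, "forward_mlr")
        self.coef_ = np.asarray(self.model_.coefficients, dtype=float)
        self.intercept_ = self.model_.intercept
        self.adjusted_r2_ = best_adj if selected else float("nan")
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = _frame(X)
        if self.selected_features_:
            return self.model_.predict(X[self.selected_features_])
        return np.full(X.shape[0], self.intercept_)


class PLS1Regression(RegressorMixin, BaseEstimator):
    """NIPALS partial least squares regression with a univariate response.

    Per component k on the running residual matrices (X_res, y_res):

        w_k = X_res' y_res / ||X_res' y_res||      (weights)
        t_k = X_res w_k                            (X scores)
        p_k = X_res' t_k / (t_k' t_k)              (X loadings)
        q_k = y_res' t_k / (t_k' t_k)              (y loading)
        X_res -= t_k p_k';  y_res -= q_k t_k       (deflation)

    giving the decomposition X = T P' + X_res with mutually orthogonal
    score columns.  The collapsed coefficient vector
    ``b = W (P' W)^-1 q`` maps centered predictors straight to
    predictions, so downstream code sees an ordinary linear model.

    Attributes (after fit)
    ----------------------
    x_scores_ (n, l), x_weights_ (m, l), x_loadings_ (m, l),
    y_loadings_ (l,), x_variance_explained_ (l,) fractions of total
    X variance, coef_ (m,), intercept_ : float.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = _frame(X)
        y = np.asarray(y, dtype=float).ravel()
        n, m = X.shape
        if y.shape[0] != n:
            raise ValueError("X rows and y length differ")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        X0 = X.to_numpy(dtype=float)
        self._x_mean = X0.mean(axis=0)
        Xc = X0 - self._x_mean
        self._y_mean = float(y.mean())
        yc = y - self._y_mean
        rank = np.linalg.matrix_rank(Xc)
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds rank {rank}"
            )
        total_xvar = float((Xc ** 2).sum())
        Xr, yr = Xc.copy(), yc.copy()
        W, T, P, q, xvar = [], [], [], [], []
        for _ in range(self.n_components):
            w = Xr.T @ yr
            wnorm = float(np.linalg.norm(w))
            if wnorm < 1e-12 * max(1.0, float(np.linalg.norm(yc))):
                raise ValueError(
                    "response fully deflated before reaching n_components"
                )
            w = w / wnorm
            t = Xr @ w
            tt = float(t @ t)
            if tt <= 0:
                raise ValueError("degenerate zero-variance score")
            p = Xr.T @ t / tt
            qk = float(yr @ t) / tt
            Xr = Xr - np.outer(t, p)
            yr = yr - qk * t
            W.append(w); T.append(t); P.append(p); q.append(qk)
            xvar.append(tt * float(p @ p) / total_xvar if total_xvar else 0.0)
        self.x_weights_ = np.column_stack(W)
        self.x_scores_ = np.column_stack(T)
        self.x_loadings_ = np.column_stack(P)
        self.y_loadings_ = np.asarray(q)
        self.x_variance_explained_ = np.asarray(xvar)
        self.coef_ = self.x_weights_ @ np.linalg.solve(
            self.x_loadings_.T @ self.x_weights_, self.y_loadings_
        )
        self.intercept_ = self._y_mean - float(self._x_mean @ self.coef_)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = m
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = _frame(X)
        missing = [n for n in self.feature_names_in_ if n not in X.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        mat = X.loc[:, list(self.feature_names_in_)].to_numpy(dtype=float)
        return self.intercept_ + mat @ self.coef_

    def to_linear_model(self) -> LinearModel:
        check_is_fitted(self, "coef_")
        return LinearModel(
            feature_names=tuple(self.feature_names_in_),
            coefficients=tuple(self.coef_),
            intercept=self.intercept_,
            provenance="plsr_collapsed",
        )


@dataclass
class ComponentScan:
    """R² and leave-one-out Q² per candidate component count."""

    n_components: List[int]
    r2: List[float]
    q2: List[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_components": self.n_components, "r2": self.r2, "q2": self.q2}
        )

    @property
    def best_by_q2(self) -> int:
        """Component count maximizing Q² (first maximum on ties)."""
        return self.n_components[int(np.argmax(self.q2))]


def scan_components(X, y, max_components: int, *, standardize: bool = True
                    ) -> ComponentScan:
    """Fit PLS1 at 1..max_components, reporting R² and leave-one-out Q².

    Every leave-one-out fold refits the whole procedure, including the
    per-fold standardization when ``standardize`` is true, so Q² never
    sees the held-out row during preprocessing.
    """
    from .preprocessing import DescriptorStandardizer
    from .validation import q2_loo

    X = _frame(X)
    y = np.asarray(y, dtype=float).ravel()

    def procedure_for(ncomp):
        def fit(Xtr, ytr):
            if standardize:
                std = DescriptorStandardizer().fit(Xtr)
                Ztr = std.transform(Xtr)
            else:
                std, Ztr = None, Xtr
            pls = PLS1Regression(n_components=ncomp).fit(Ztr, ytr)
            def predict(Xnew):
                Znew = std.transform(Xnew) if std is not None else Xnew
                return pls.predict(Znew)
            return predict
        return fit

    counts, r2s, q2s = [], [], []
    for ncomp in range(1, max_components + 1):
        predictor = procedure_for(ncomp)(X, y)
        r2s.append(r_squared(y, predictor(X)))
        q2s.append(q2_loo(X, y, procedure_for(ncomp)))
        counts.append(ncomp)
    return ComponentScan(counts, r2s, q2s)
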