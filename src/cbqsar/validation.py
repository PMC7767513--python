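"""Model-quality statistics for QSAR regression.

Implements the standard internal/external validation battery: R² and
adjusted R², RMSE, leave-one-out Q² (full-procedure refits per fold),
predictive R² on an external set referenced to the training mean,
Y-randomization with the cRp² coefficient, a two-sided single-outlier
Grubbs test, normal Q-Q data for residual diagnostics, and the Pearson
correlation coefficient.

Conventions that matter:

* Predictive R² uses the *squared* deviation of test responses about
  the training mean in its denominator.
* cRp² = R · sqrt(max(0, R² − R̄r²)) where R is the original model's
  correlation between fitted and observed responses and R̄r is the mean
  correlation of the permuted-response models; a model passes when
  cRp² > 0.5.
* Leave-one-out Q² refits the complete procedure (including any
  standardization) on each reduced training set, with the total sum of
  squares about the full training mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "r_squared",
    "c_rp2",
    "adjusted_r_squared",
    "rmse",
    "q2_loo",
    "r2_pred",
    "pearson_r",
    "YRandomizationReport",
    "y_randomization",
    "GrubbsResult",
    "grubbs_test",
    "QQData",
    "qq_points",
    "FitReport",
]

FitProcedure = Callable[[object, np.ndarray], Callable[[object], np.ndarray]]
"""A fit procedure maps (X_train, y_train) to a predict(X) callable.

It must encapsulate *everything* refit under cross-validation or
permutation — standardization included — so held-out rows never leak
into preprocessing.
"""


def _pair(y_obs, y_pred):
    yo = np.asarray(y_obs, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yo.shape != yp.shape:
        raise ValueError("observed and predicted lengths differ")
    return yo, yp


def r_squared(y_obs, y_pred, reference_mean: Optional[float] = None) -> float:
    """Coefficient of determination 1 - SSres/SStot.

    ``reference_mean`` fixes the mean the total sum of squares is taken
    about (the training mean when scoring external data); defaults to
    mean(y_obs).
    """
    yo, yp = _pair(y_obs, y_pred)
    if yo.size < 2:
        raise ValueError("need at least 2 observations")
    mean = float(np.mean(yo)) if reference_mean is None else float(reference_mean)
    sstot = float(((yo - mean) ** 2).sum())
    if sstot == 0:
        raise ValueError("zero total sum of squares about the reference mean")
    return 1.0 - float(((yo - yp) ** 2).sum()) / sstot


def adjusted_r_squared(r2: float, n: int, p: int) -> float:
    """Adjusted R² = 1 - (1 - R²)(N - 1)/(N - p - 1)."""
    if n - p - 1 <= 0:
        raise ValueError(f"adjusted R² undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rmse(y_obs, y_pred) -> float:
    """Root mean square error with denominator n."""
    yo, yp = _pair(y_obs, y_pred)
    if yo.size < 1:
        raise ValueError("need at least 1 observation")
    return float(np.sqrt(np.mean((yo - yp) ** 2)))


def r2_pred(y_obs_test, y_pred_test, train_mean: float) -> float:
    """Predictive R² of an external set about the training-set mean.

    1 - sum((y_test - yhat)²) / sum((y_test - train_mean)²).
    """
    yo, yp = _pair(y_obs_test, y_pred_test)
    if yo.size < 1:
        raise ValueError("need at least 1 test observation")
    denom = float(((yo - float(train_mean)) ** 2).sum())
    if denom == 0:
        raise ValueError("test responses identical to the training mean")
    return 1.0 - float(((yo - yp) ** 2).sum()) / denom


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.shape != yv.shape:
        raise ValueError("length mismatch")
    if xv.size < 3:
        raise ValueError("need at least 3 pairs")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    nx = float(np.sqrt((xc ** 2).sum()))
    ny = float(np.sqrt((yc ** 2).sum()))
    if nx == 0 or ny == 0:
        raise ValueError("zero variance input")
    return float((xc @ yc) / (nx * ny))


def _rows(X, idx):
    if isinstance(X, pd.DataFrame):
        return X.iloc[idx]
    return np.asarray(X)[idx]


def q2_loo(X, y, fit_procedure: FitProcedure) -> float:
    """Leave-one-out cross-validated Q² = 1 - PRESS/SStot.

    Each fold refits ``fit_procedure`` on the remaining n-1 rows and
    predicts the held-out row; SStot is about the *full* training mean.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 rows for leave-one-out")
    press = 0.0
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        try:
            predictor = fit_procedure(_rows(X, rest), y[rest])
            yhat_i = float(np.asarray(predictor(_rows(X, [i]))).ravel()[0])
        except Exception as exc:
            raise RuntimeError(f"leave-one-out refit failed at fold {i}") from exc
        press += (y[i] - yhat_i) ** 2
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot == 0:
        raise ValueError("zero total sum of squares")
    return 1.0 - press / sstot


@dataclass
class YRandomizationReport:
    """Outcome of the permuted-response robustness test."""

    n_permutations: int
    seed: Optional[int]
    r2_original: float
    r_original: float
    r2_random: List[float]
    r_random: List[float]
    rr_mean: float
    c_rp2: float
    passed: bool

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "r2_original": self.r2_original,
            "r_original": self.r_original,
            "r2_random": list(self.r2_random),
            "r_random": list(self.r_random),
            "rr_mean": self.rr_mean,
            "c_rp2": self.c_rp2,
            "passed": self.passed,
        }


def c_rp2(r_original: float, r2_original: float, rr_mean: float) -> float:
    """Y-randomization coefficient cRp² = R · sqrt(max(0, R² − R̄r²)).

    Collapses to 0 when the random models correlate as well as the
    original (R̄r = R with R² = R²) and to R² when R̄r = 0.
    """
    return r_original * float(np.sqrt(max(0.0, r2_original - rr_mean ** 2)))


def y_randomization(X, y, fit_procedure: FitProcedure,
                    n_permutations: int = 25, seed: Optional[int] = None,
                    permutations: Optional[Sequence[np.ndarray]] = None
                    ) -> YRandomizationReport:
    """Y-randomization test: refit on shuffled responses, X unchanged.

    cRp² = R · sqrt(max(0, R² − R̄r²)) with R the original model's
    fitted-vs-observed correlation and R̄r the mean correlation of the
    permuted models (each sign-preserving, fitted vs its permuted
    response).  The model passes when cRp² > 0.5.

    ``permutations`` overrides the seeded shuffles with an explicit
    list of index arrays (a deterministic test hook).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 rows for Y-randomization")
    idx_all = list(range(n))
    predictor = fit_procedure(_rows(X, idx_all), y)
    fitted = np.asarray(predictor(_rows(X, idx_all))).ravel()
    r_orig = pearson_r(fitted, y)
    r2_orig = r_squared(y, fitted)

    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = [rng.permutation(n) for _ in range(n_permutations)]
    else:
        permutations = [np.asarray(p, dtype=int) for p in permutations]
        n_permutations = len(permutations)

    r2_rand, r_rand = [], []
    for k, perm in enumerate(permutations):
        y_p = y[perm]
        try:
            pred_k = fit_procedure(_rows(X, idx_all), y_p)
            fitted_k = np.asarray(pred_k(_rows(X, idx_all))).ravel()
        except Exception as exc:
            raise RuntimeError(f"refit failed at permutation {k}") from exc
        r_rand.append(pearson_r(fitted_k, y_p))
        r2_rand.append(r_squared(y_p, fitted_k))
    rr_mean = float(np.mean(r_rand))
    coeff = c_rp2(r_orig, r2_orig, rr_mean)
    return YRandomizationReport(
        n_permutations=n_permutations, seed=seed,
        r2_original=r2_orig, r_original=r_orig,
        r2_random=r2_rand, r_random=r_rand,
        rr_mean=rr_mean, c_rp2=coeff, passed=coeff > 0.5,
    )


@dataclass
class GrubbsResult:
    flagged_value: Optional[float]
    flagged_index: Optional[int]
    statistic: float
    critical: float
    alpha: float


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test.

    G = max|x_i - mean| / sd (sample sd); the critical value derives
    from the Student t distribution,
    G_crit = (n-1)/sqrt(n) * sqrt(t² / (n - 2 + t²)) with
    t = t_{1 - alpha/(2n), n-2}.  The extreme value is flagged iff
    G > G_crit.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation")
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = float(dev[i]) / sd
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    crit = (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))
    flagged = g > crit
    return GrubbsResult(
        flagged_value=float(x[i]) if flagged else None,
        flagged_index=i if flagged else None,
        statistic=g, critical=float(crit), alpha=alpha,
    )


@dataclass
class QQData:
    """Paired normal-quantile data for a residual Q-Q plot."""

    theoretical: np.ndarray
    sample: np.ndarray
    normality_r: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"theoretical_quantile": self.theoretical,
             "sample_quantile": self.sample}
        )


def qq_points(residuals, plotting_offset: float = 0.5) -> QQData:
    """Standardized residual quantiles vs standard-normal quantiles.

    Plotting positions are (i - plotting_offset)/n; residuals are
    standardized with the sample sd.  ``normality_r`` is the Pearson
    correlation of the paired quantiles — near 1 for normal residuals.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    n = r.size
    if n < 3:
        raise ValueError("need at least 3 residuals")
    sd = float(r.std(ddof=1))
    if sd == 0:
        raise ValueError("zero residual variance")
    z = np.sort((r - r.mean()) / sd)
    probs = (np.arange(1, n + 1) - plotting_offset) / n
    theo = stats.norm.ppf(probs)
    return QQData(theoretical=theo, sample=z,
                  normality_r=pearson_r(theo, z))


@dataclass
class FitReport:
    """Aggregate training/test quality metrics for one fitted model."""

    r2: float
    adjusted_r2: Optional[float]
    q2_loo: Optional[float]
    r2_pred: Optional[float]
    rmse_train: float
    rmse_test: Optional[float]
    n_train: int
    n_test: int
    n_params: int

    def __post_init__(self):
        if self.r2 > 1 + 1e-12:
            raise ValueError("R² cannot exceed 1")
        if self.rmse_train < 0 or (self.rmse_test is not None and self.rmse_test < 0):
            raise ValueError("RMSE must be non-negative")

    def to_dict(self) -> dict:
        return {
            "r2": self.r2, "adjusted_r2": self.adjusted_r2,
            "q2_loo": self.q2_loo, "r2_pred": self.r2_pred,
            "rmse_train": self.rmse_train, "rmse_test": self.rmse_test,
            "n_train": self.n_train, "n_test": self.n_test,
            "n_params": self.n_params,
        }
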