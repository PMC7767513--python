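"""Descriptor standardization and the three-stage feature-filtering chain.

Small QSAR training sets (here, 11 compounds against hundreds of
computed descriptors) require aggressive unsupervised pruning before
any regression is attempted.  The chain applied, in fixed order:

1. near-zero-variance filter — drops constant columns and columns whose
   value distribution is dominated by a single value;
2. pairwise-correlation pruning — greedily removes one member of every
   descriptor pair with absolute Pearson correlation above a cutoff
   (default 0.9), preferring to drop the member more correlated with
   everything else;
3. response-correlation keep — retains only descriptors whose absolute
   Pearson correlation with the response exceeds a threshold (default
   0.3, strict).

All three filters are fit on training rows only; test rows never
influence which columns survive.  Each stage records a
:class:`FilterTrace` for audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FilterTrace",
    "DescriptorStandardizer",
    "NearZeroVarianceFilter",
    "CorrelationPruner",
    "ResponseCorrelationFilter",
    "FeatureSelectionChain",
    "select_features",
]


@dataclass
class FilterTrace:
    """Audit record of one filtering stage."""

    stage: str
    n_in: int
    n_out: int
    removed: List[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.n_out != self.n_in - len(self.removed):
            raise ValueError(
                f"trace inconsistent: {self.n_in} in, {self.n_out} out, "
                f"{len(self.removed)} removed"
            )

    def to_json_line(self) -> str:
        return json.dumps(
            {"stage": self.stage, "in": self.n_in, "out": self.n_out,
             "removed": self.removed}
        )


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


class DescriptorStandardizer(TransformerMixin, BaseEstimator):
    """Column-wise z-scoring with the sample (N-1) standard deviation.

    Unlike :class:`sklearn.preprocessing.StandardScaler`, the scale uses
    the N-1 denominator, matching the convention of standard statistical
    software; a zero-variance column is an error naming the column (the
    filter chain should have removed it).  Test rows are transformed
    with the training means and scales, never their own.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to standardize")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        dead = list(X.columns[(sd <= 0) | ~np.isfinite(sd)])
        if dead:
            raise ValueError(f"zero-variance columns cannot be standardized: {dead}")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.mean_ = mean.to_numpy()
        self.scale_ = sd.to_numpy()
        return self

    def _aligned(self, X) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        names = list(self.feature_names_in_)
        if isinstance(X, pd.DataFrame):
            missing = [n for n in names if n not in X.columns]
            extra = [c for c in X.columns if c not in names]
            if missing or extra:
                raise ValueError(
                    f"column mismatch: missing {missing}, unexpected {extra}"
                )
            return X.loc[:, names]
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(names):
            raise ValueError(f"expected {len(names)} columns, got {X.shape[1]}")
        return pd.DataFrame(X, columns=names)

    def transform(self, X):
        frame = self._aligned(X)
        Z = (frame - self.mean_) / self.scale_
        return Z if isinstance(X, pd.DataFrame) else Z.to_numpy()

    def inverse_transform(self, Z):
        frame = self._aligned(Z)
        X = frame * self.scale_ + self.mean_
        return X if isinstance(Z, pd.DataFrame) else X.to_numpy()

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "mean_")
        return np.asarray(self.feature_names_in_, dtype=object)


class _ColumnSelector(TransformerMixin, BaseEstimator):
    """Shared transform/trace machinery for the filter stages."""

    _stage = "filter"

    def _finalize(self, X: pd.DataFrame, removed: List[dict]):
        keep = [c for c in X.columns if c not in {r["name"] for r in removed}]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.selected_features_ = list(keep)
        self.trace_ = FilterTrace(
            stage=self._stage, n_in=X.shape[1], n_out=len(keep), removed=removed
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        frame = _as_frame(X)
        missing = [c for c in self.selected_features_ if c not in frame.columns]
        if missing:
            raise ValueError(f"columns absent from input: {missing}")
        out = frame.loc[:, self.selected_features_]
        return out if isinstance(X, pd.DataFrame) else out.to_numpy()

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "selected_features_")
        return np.asarray(self.selected_features_, dtype=object)


class NearZeroVarianceFilter(_ColumnSelector):
    """Drop constant and almost-constant descriptor columns.

    A column is dropped when its variance is exactly zero, or when the
    ratio of its most frequent value count to its second most frequent
    value count is at least ``freq_cut`` *and* its percentage of
    distinct values is at most ``unique_cut``.

    Parameters
    ----------
    freq_cut : float, default 19.0
        Frequency-ratio threshold (19 corresponds to a 95/5 split).
    unique_cut : float, default 10.0
        Percent-distinct threshold.
    """

    _stage = "near_zero_variance"

    def __init__(self, freq_cut: float = 19.0, unique_cut: float = 10.0):
        self.freq_cut = freq_cut
        self.unique_cut = unique_cut

    def fit(self, X, y=None):
        X = _as_frame(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows")
        removed = []
        n = X.shape[0]
        for name in X.columns:
            col = X[name].to_numpy(dtype=float)
            counts = pd.Series(col).value_counts().to_numpy()
            if len(counts) == 1:
                removed.append({"name": name, "reason": "zero_variance"})
                continue
            freq_ratio = counts[0] / counts[1]
            pct_unique = 100.0 * len(counts) / n
            if freq_ratio >= self.freq_cut and pct_unique <= self.unique_cut:
                removed.append({"name": name, "reason": "near_zero_variance"})
        return self._finalize(X, removed)


class CorrelationPruner(_ColumnSelector):
    """Greedy removal of highly inter-correlated descriptor pairs.

    While any pair of remaining columns has absolute Pearson correlation
    above ``cutoff``, the pair with the largest |r| is located and the
    member with the larger mean absolute correlation to all other
    remaining columns is removed.  Ties keep the lexicographically
    earlier column name.  The result is deterministic given column
    order, and no surviving pair exceeds the cutoff.
    """

    _stage = "correlation_prune"

    def __init__(self, cutoff: float = 0.9):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        X = _as_frame(X)
        sd = X.std(axis=0, ddof=1)
        if (sd <= 0).any():
            raise ValueError(
                f"zero-variance columns present: {list(X.columns[sd <= 0])}; "
                "apply NearZeroVarianceFilter first"
            )
        corr = X.corr().abs()
        cols = list(X.columns)
        removed = []
        while len(cols) > 1:
            sub = corr.loc[cols, cols].to_numpy(copy=True)
            np.fill_diagonal(sub, 0.0)
            worst = float(sub.max())
            if worst <= self.cutoff:
                break
            i, j = np.unravel_index(int(np.argmax(sub)), sub.shape)
            a, b = cols[min(i, j)], cols[max(i, j)]
            mean_abs = {
                c: float(np.mean([sub[cols.index(c), k]
                                  for k in range(len(cols))
                                  if cols[k] != c]))
                for c in (a, b)
            }
            if mean_abs[a] > mean_abs[b]:
                drop = a
            elif mean_abs[b] > mean_abs[a]:
                drop = b
            else:
                drop = max(a, b)  # keep the lexicographically earlier name
            cols.remove(drop)
            removed.append(
                {"name": drop, "reason": "pairwise_correlation",
                 "partner": b if drop == a else a, "abs_r": worst}
            )
        return self._finalize(X, removed)


class ResponseCorrelationFilter(_ColumnSelector):
    """Keep descriptors with |Pearson r| to the response above a threshold.

    The inequality is strict: a descriptor with |r| exactly equal to
    ``min_abs_r`` is dropped.
    """

    _stage = "response_correlation"

    def __init__(self, min_abs_r: float = 0.3):
        self.min_abs_r = min_abs_r

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X rows and y length differ")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 training rows for correlation")
        yc = y - y.mean()
        ynorm = np.sqrt((yc ** 2).sum())
        removed = []
        self.response_correlations_ = {}
        for name in X.columns:
            col = X[name].to_numpy(dtype=float)
            xc = col - col.mean()
            xnorm = np.sqrt((xc ** 2).sum())
            r = 0.0 if xnorm == 0 or ynorm == 0 else float((xc @ yc) / (xnorm * ynorm))
            self.response_correlations_[name] = r
            if not abs(r) > self.min_abs_r:
                removed.append(
                    {"name": name, "reason": "weak_response_correlation", "r": r}
                )
        return self._finalize(X, removed)


class FeatureSelectionChain(TransformerMixin, BaseEstimator):
    """The full three-stage filter chain as one fitted transformer."""

    def __init__(self, freq_cut: float = 19.0, unique_cut: float = 10.0,
                 corr_cutoff: float = 0.9, min_abs_r: float = 0.3):
        self.freq_cut = freq_cut
        self.unique_cut = unique_cut
        self.corr_cutoff = corr_cutoff
        self.min_abs_r = min_abs_r

    def fit(self, X, y):
        X = _as_frame(X)
        nzv = NearZeroVarianceFilter(self.freq_cut, self.unique_cut).fit(X)
        X1 = nzv.transform(X)
        prune = CorrelationPruner(self.corr_cutoff).fit(X1)
        X2 = prune.transform(X1)
        resp = ResponseCorrelationFilter(self.min_abs_r).fit(X2, y)
        self.stages_ = [nzv, prune, resp]
        self.traces_ = [s.trace_ for s in self.stages_]
        self.selected_features_ = list(resp.selected_features_)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "stages_")
        frame = _as_frame(X)
        out = frame.loc[:, self.selected_features_]
        return out if isinstance(X, pd.DataFrame) else out.to_numpy()

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "stages_")
        return np.asarray(self.selected_features_, dtype=object)


def select_features(X, y, freq_cut: float = 19.0, unique_cut: float = 10.0,
                    corr_cutoff: float = 0.9, min_abs_r: float = 0.3):
    """Run the filter chain on training data; return (filtered X, traces)."""
    chain = FeatureSelectionChain(freq_cut, unique_cut, corr_cutoff, min_abs_r)
    chain.fit(X, y)
    return chain.transform(X), chain.traces_
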