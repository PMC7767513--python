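"""Euclidean-distance applicability domain.

A QSAR model is only trustworthy near its training data.  This domain
definition collects all pairwise Euclidean distances among the
(standardized) training rows, keeps the subset strictly below their
mean, and sets the threshold

    APD = <d> + Z * sigma

where <d> and sigma are the mean and sample standard deviation of that
below-average subset and Z is a cutoff (default 0.5).  A query is
inside the domain when its distance to the *nearest* training row is
at most the threshold.

Degenerate conventions (all pairwise distances equal, so the strict
subset is empty): <d> is the common distance and sigma is 0; a
single-element subset likewise has sigma 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = ["EuclideanApplicabilityDomain"]


class EuclideanApplicabilityDomain(BaseEstimator):
    """Nearest-neighbor Euclidean applicability domain.

    Parameters
    ----------
    z : float, default 0.5
        Cutoff multiplier on the spread of below-average training
        distances.

    Attributes (after fit)
    ----------------------
    d_mean_, d_sigma_ : mean and sample sd of the below-average
        pairwise-distance subset.
    threshold_ : d_mean_ + z * d_sigma_.
    reference_ : the training rows queries are compared against.
    """

    def __init__(self, z: float = 0.5):
        self.z = z

    def fit(self, X, y=None):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            np.atleast_2d(np.asarray(X, dtype=float))
        )
        if frame.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        d = pdist(frame.to_numpy(dtype=float), metric="euclidean")
        mean_all = float(d.mean())
        below = d[d < mean_all]
        if below.size == 0:
            # all pairwise distances equal
            d_mean, d_sigma = mean_all, 0.0
        elif below.size == 1:
            d_mean, d_sigma = float(below[0]), 0.0
        else:
            d_mean = float(below.mean())
            d_sigma = float(below.std(ddof=1))
        self.reference_ = frame.copy()
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        self.d_mean_ = d_mean
        self.d_sigma_ = d_sigma
        self.threshold_ = d_mean + self.z * d_sigma
        return self

    def _query_matrix(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        if isinstance(X, pd.DataFrame):
            names = list(self.feature_names_in_)
            missing = [n for n in names if n not in X.columns]
            if missing:
                raise ValueError(f"query missing columns: {missing}")
            return X.loc[:, names].to_numpy(dtype=float)
        if isinstance(X, pd.Series):
            return self._query_matrix(X.to_frame().T)
        mat = np.atleast_2d(np.asarray(X, dtype=float))
        if mat.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {mat.shape[1]} columns, domain has "
                f"{self.n_features_in_}"
            )
        return mat

    def distance(self, X) -> np.ndarray:
        """Euclidean distance from each query row to its nearest training row."""
        mat = self._query_matrix(X)
        return cdist(mat, self.reference_.to_numpy(dtype=float)).min(axis=1)

    def within(self, X) -> np.ndarray:
        """Boolean mask: nearest-neighbor distance <= threshold."""
        return self.distance(X) <= self.threshold_

    def check(self, row):
        """Screen a single query row; returns (distance, within)."""
        d = float(self.distance(row)[0])
        return d, bool(d <= self.threshold_)

    def predict(self, X) -> np.ndarray:
        """sklearn-style outlier convention: +1 inside the domain, -1 outside."""
        return np.where(self.within(X), 1, -1)

    def to_dict(self) -> dict:
        check_is_fitted(self, "threshold_")
        return {
            "z": self.z,
            "d_mean": self.d_mean_,
            "d_sigma": self.d_sigma_,
            "threshold": self.threshold_,
            "reference_ids": [str(i) for i in self.reference_.index],
        }
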