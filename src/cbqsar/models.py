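"""Linear model container shared by MLR, collapsed PLSR, and bundled fixtures.

A :class:`LinearModel` holds named coefficients on the *standardized*
descriptor scale plus an intercept.  Because every predictor is centered
and scaled before fitting, the intercept of any least-squares fit equals
the training-set mean response, and a prediction at the all-zero
standardized vector returns exactly that intercept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["LinearModel"]

_PROVENANCES = frozenset({"ols", "forward_mlr", "plsr_collapsed", "fixture"})


@dataclass(frozen=True)
class LinearModel:
    """Named linear predictor on standardized descriptors.

    Parameters
    ----------
    feature_names : sequence of str
        Descriptor names, in coefficient order.
    coefficients : sequence of float
        One coefficient per feature, standardized-predictor scale.
    intercept : float
        Constant term; equals the training mean response for any
        least-squares fit on standardized predictors.
    provenance : str
        One of ``{"ols", "forward_mlr", "plsr_collapsed", "fixture"}``.
    """

    feature_names: tuple = field(default=())
    coefficients: tuple = field(default=())
    intercept: float = 0.0
    provenance: str = "ols"

    def __post_init__(self):
        names = tuple(str(n) for n in self.feature_names)
        coefs = tuple(float(c) for c in self.coefficients)
        if len(names) != len(coefs):
            raise ValueError(
                f"{len(names)} feature names but {len(coefs)} coefficients"
            )
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in model")
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "coefficients", coefs)
        object.__setattr__(self, "intercept", float(self.intercept))

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def predict(self, Z) -> np.ndarray:
        """Evaluate intercept + sum(coef_j * z_j) on standardized rows.

        ``Z`` may be a DataFrame (columns matched by name; extra columns
        ignored), a Series or mapping for a single row, or a 2-D array
        whose columns are already in ``feature_names`` order.
        """
        coefs = np.asarray(self.coefficients, dtype=float)
        if isinstance(Z, pd.DataFrame):
            missing = [n for n in self.feature_names if n not in Z.columns]
            if missing:
                raise KeyError(f"missing model features: {missing}")
            mat = Z.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        elif isinstance(Z, (pd.Series, Mapping)):
            try:
                mat = np.asarray(
                    [[float(Z[n]) for n in self.feature_names]]
                )
            except KeyError as exc:
                raise KeyError(f"missing model feature: {exc}") from exc
        else:
            mat = np.atleast_2d(np.asarray(Z, dtype=float))
            if mat.shape[1] != self.n_features:
                raise ValueError(
                    f"expected {self.n_features} columns, got {mat.shape[1]}"
                )
        return self.intercept + mat @ coefs

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "features": list(self.feature_names),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "provenance": self.provenance,
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearModel":
        return cls(
            feature_names=tuple(d["features"]),
            coefficients=tuple(d["coefficients"]),
            intercept=d["intercept"],
            provenance=d.get("provenance", "fixture"),
        )

    @classmethod
    def from_json(cls, source) -> "LinearModel":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
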