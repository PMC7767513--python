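"""Seeded synthetic descriptor/activity generator.

Real molecular-descriptor tables have a characteristic pathology mix:
blocks of strongly collinear descriptors (many descriptors measure the
same underlying size/lipophilicity/polarity axes), exact duplicates
(renamed or rescaled re-implementations), irrelevant noise columns,
and constant columns.  The generator reproduces that structure with
fully seeded randomness so every pipeline stage can be tested offline
against planted ground truth:

* informative columns load on a small number of shared latent factors
  plus idiosyncratic noise, inducing block correlation;
* duplicate columns are exact copies of informative columns;
* junk columns are i.i.d. standard normal, independent of the response;
* constant columns have zero variance.

The response follows a linear model on the *standardized* informative
columns with Gaussian noise, optionally with one planted response
outlier.  Column names encode their role (``info_*``, ``dup_*``,
``junk_*``, ``const_*``) so tests can verify filter behavior without
re-deriving statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import validate_activity_table

__all__ = ["SyntheticSpec", "generate_descriptors", "generate_response",
           "generate_dataset", "reference_like_benchmark"]

# fixed latent-factor mixing weights; informative column j draws its
# factor loading from this cycle so blocks are reproducible across runs
_LOADINGS = (0.9, 0.8, 0.7, 0.85, 0.75)
_IDIO_SD = 0.4  # idiosyncratic noise sd within an informative block
_BASELINE = 6.0  # intercept on the pKi-like scale


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic descriptor/activity dataset."""

    n_compounds: int = 50
    n_informative: int = 2
    n_latent: int = 2
    n_duplicates: int = 0
    n_junk: int = 10
    n_constant: int = 0
    beta: Tuple[float, ...] = (0.8, -0.4)
    noise_sd: float = 0.1
    outlier_offset: Optional[float] = None
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_compounds, self.n_informative, self.n_latent) < 1:
            raise ValueError("n_compounds, n_informative, n_latent must be >= 1")
        if min(self.n_duplicates, self.n_junk, self.n_constant) < 0:
            raise ValueError("column counts must be >= 0")
        if self.n_duplicates > self.n_informative:
            raise ValueError("cannot duplicate more columns than exist")
        if len(self.beta) != self.n_informative:
            raise ValueError("beta must have one entry per informative column")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # independent deterministic streams per purpose (PCG64 via default_rng)
    return np.random.default_rng([spec.seed, stream])


def generate_descriptors(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate the descriptor matrix for ``spec`` (deterministic per seed)."""
    rng = _rng(spec, 1)
    n = spec.n_compounds
    factors = rng.standard_normal((n, spec.n_latent))
    cols = {}
    for j in range(spec.n_informative):
        load = _LOADINGS[j % len(_LOADINGS)]
        factor = factors[:, j % spec.n_latent]
        cols[f"info_{j:02d}"] = load * factor + _IDIO_SD * rng.standard_normal(n)
    for j in range(spec.n_duplicates):
        cols[f"dup_{j:02d}_of_info_{j:02d}"] = cols[f"info_{j:02d}"].copy()
    for j in range(spec.n_junk):
        cols[f"junk_{j:02d}"] = rng.standard_normal(n)
    for j in range(spec.n_constant):
        cols[f"const_{j:02d}"] = np.full(n, float(j))
    ids = [f"C{i:03d}" for i in range(n)]
    return pd.DataFrame(cols, index=pd.Index(ids, name="compound_id"))


def generate_response(X: pd.DataFrame, spec: SyntheticSpec,
                      outlier_role: str = "train") -> pd.DataFrame:
    """Generate the activity table for a descriptor matrix.

    y = baseline + sum_j beta_j z_j + eps with eps ~ N(0, noise_sd²) on
    the standardized (N-1 sd) informative columns.  Roles come from a
    seeded 80/20-style split.  When ``outlier_offset`` is set, the
    first training compound's response is shifted by it; the planted
    compound keeps ``outlier_role`` (default ``"train"`` so a
    downstream outlier screen can find it; pass ``"excluded_outlier"``
    to mark it pre-excluded).
    """
    info_cols = [f"info_{j:02d}" for j in range(spec.n_informative)]
    missing = [c for c in info_cols if c not in X.columns]
    if missing:
        raise ValueError(f"descriptor matrix lacks informative columns {missing}")
    if X.shape[0] != spec.n_compounds:
        raise ValueError("descriptor matrix rows do not match spec")
    rng = _rng(spec, 2)
    Z = (X[info_cols] - X[info_cols].mean()) / X[info_cols].std(ddof=1)
    y = _BASELINE + Z.to_numpy() @ np.asarray(spec.beta) \
        + spec.noise_sd * rng.standard_normal(spec.n_compounds)

    n = spec.n_compounds
    order = rng.permutation(n)
    n_test = max(1, round(spec.test_fraction * n)) if n > 2 else 0
    roles = np.array(["train"] * n, dtype=object)
    roles[order[:n_test]] = "test"
    act = pd.DataFrame({"role": roles, "pki": y}, index=X.index)

    if spec.outlier_offset is not None:
        train_ids = act.index[act["role"] == "train"]
        planted = train_ids[0]
        act.loc[planted, "pki"] += spec.outlier_offset
        act.loc[planted, "role"] = outlier_role
        act.attrs["planted_outlier"] = str(planted)
    validate_activity_table(act)
    return act


def generate_dataset(spec: SyntheticSpec, outlier_role: str = "train"):
    """Convenience: (descriptors, activity) for one spec."""
    X = generate_descriptors(spec)
    return X, generate_response(X, spec, outlier_role=outlier_role)


def reference_like_benchmark(seed: int = 0, large: bool = False):
    """Benchmark datasets shaped like a small-molecule QSAR study.

    The small variant mirrors the bundled CB1 study's scale: 15
    compounds, ~286 raw descriptor columns, an 11 train / 3 test split
    and one pre-excluded response outlier.  The large variant keeps the
    same column structure at n = 100 (no outlier) so statistics such as
    Q² and cRp² are stable enough to assert on.
    """
    if large:
        spec = SyntheticSpec(
            n_compounds=100, n_informative=8, n_latent=3, n_duplicates=6,
            n_junk=60, n_constant=20,
            beta=(0.9, -0.6, 0.7, 0.45, -0.5, 0.55, 0.4, -0.45),
            noise_sd=0.3, outlier_offset=None, seed=seed,
        )
        return generate_dataset(spec)
    X = generate_descriptors(
        SyntheticSpec(
            n_compounds=15, n_informative=8, n_latent=3, n_duplicates=8,
            n_junk=220, n_constant=20,
            beta=(0.9, -0.6, 0.7, 0.45, -0.5, 0.55, 0.4, -0.45),
            noise_sd=0.3, seed=seed,
        )
    )
    # widen the duplicate blocks to reach the raw-descriptor scale (~286)
    extra = {}
    for k in range(30):
        src = f"info_{k % 8:02d}"
        extra[f"dup_x{k:02d}_of_{src}"] = X[src].to_numpy().copy()
    X = pd.concat([X, pd.DataFrame(extra, index=X.index)], axis=1)
    resp_spec = SyntheticSpec(
        n_compounds=15, n_informative=8, n_latent=3, n_duplicates=8,
        n_junk=220, n_constant=20,
        beta=(0.9, -0.6, 0.7, 0.45, -0.5, 0.55, 0.4, -0.45),
        noise_sd=0.3, outlier_offset=-4.0, test_fraction=3 / 14, seed=seed,
    )
    act = generate_response(X, resp_spec, outlier_role="excluded_outlier")
    return X, act
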