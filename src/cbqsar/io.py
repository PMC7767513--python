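"""Descriptor and activity table I/O plus the Ki -> pKi unit conversion.

Conventions
-----------
Descriptor CSV: header ``compound_id,<name1>,<name2>,...``; UTF-8; decimal
point; every cell after the id column must parse as a real number.  Missing
or non-numeric cells are a hard load error (no imputation).

Activity CSV: header ``compound_id,role,ki_nM`` or ``compound_id,role,pki``
with role in {train, test, excluded_outlier, external}.

In memory, a descriptor matrix is a pandas DataFrame indexed by
``compound_id`` with float columns; an activity table is a DataFrame
indexed by ``compound_id`` with columns ``role`` and ``pki``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "ki_to_pki",
    "load_descriptor_table",
    "write_descriptor_table",
    "load_activity_table",
    "write_activity_table",
    "validate_activity_table",
]

ROLES = ("train", "test", "excluded_outlier", "external")


def ki_to_pki(ki_nanomolar):
    """Convert an inhibition constant Ki in nM to pKi = -log10(Ki in mol/L).

    Equivalent to ``9 - log10(ki_nanomolar)``; 1 nM maps to 9.0.
    """
    ki = np.asarray(ki_nanomolar, dtype=float)
    if np.any(~np.isfinite(ki)) or np.any(ki <= 0):
        raise ValueError("Ki must be finite and strictly positive (nM)")
    out = 9.0 - np.log10(ki)
    return float(out) if out.ndim == 0 else out


def load_descriptor_table(path, **read_csv_kwargs) -> pd.DataFrame:
    """Load a descriptor CSV into a DataFrame indexed by compound_id.

    Raises on duplicate compound ids, duplicate descriptor names,
    non-numeric / missing cells (reported with row and column), and
    empty tables.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, **read_csv_kwargs)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: need a compound_id column plus descriptors")
    if raw.shape[0] == 0:
        raise ValueError(f"{path}: empty descriptor table")
    id_col = raw.columns[0]
    ids = raw[id_col].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate compound_id {list(dup)}")
    names = list(raw.columns[1:])
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"{path}: duplicate descriptor names {dups}")
    values = np.empty((raw.shape[0], len(names)), dtype=float)
    for j, name in enumerate(names):
        col = pd.to_numeric(raw[name], errors="coerce")
        bad = col.index[col.isna()]
        if len(bad):
            i = int(bad[0])
            raise ValueError(
                f"{path}: non-numeric cell {raw[name].iloc[i]!r} at "
                f"row {i + 2} (compound {ids.iloc[i]!r}), column {name!r}"
            )
        values[:, j] = col.to_numpy()
    X = pd.DataFrame(values, index=pd.Index(ids, name="compound_id"), columns=names)
    return X


def write_descriptor_table(X: pd.DataFrame, path) -> None:
    X.to_csv(path, index_label="compound_id")


def load_activity_table(path) -> pd.DataFrame:
    """Load an activity CSV; Ki columns are converted to pKi on load."""
    raw = pd.read_csv(path, dtype={0: str})
    cols = {c.lower(): c for c in raw.columns}
    if "compound_id" not in cols or "role" not in cols:
        raise ValueError(f"{path}: need compound_id and role columns")
    ids = raw[cols["compound_id"]].astype(str)
    if ids.duplicated().any():
        raise ValueError(
            f"{path}: duplicate compound_id "
            f"{list(ids[ids.duplicated()].unique())}"
        )
    if "pki" in cols:
        pki = pd.to_numeric(raw[cols["pki"]], errors="raise").astype(float)
    elif "ki_nm" in cols:
        pki = pd.Series(ki_to_pki(raw[cols["ki_nm"]].to_numpy(dtype=float)))
    else:
        raise ValueError(f"{path}: need a pki or ki_nM column")
    act = pd.DataFrame(
        {"role": raw[cols["role"]].astype(str).str.strip().to_numpy(),
         "pki": pki.to_numpy()},
        index=pd.Index(ids, name="compound_id"),
    )
    validate_activity_table(act)
    return act


def write_activity_table(act: pd.DataFrame, path) -> None:
    act.to_csv(path, index_label="compound_id")


def validate_activity_table(act: pd.DataFrame) -> None:
    bad_roles = sorted(set(act["role"]) - set(ROLES))
    if bad_roles:
        raise ValueError(f"unknown roles {bad_roles}; allowed: {ROLES}")
    pki = act["pki"].to_numpy(dtype=float)
    if np.any(~np.isfinite(pki)):
        bad = act.index[~np.isfinite(pki)][0]
        raise ValueError(f"non-finite pKi for compound {bad!r}")
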