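"""Bundled CB1 synthetic-cannabinoid reference dataset.

The package ships the published reference data this toolkit was built
around: measured CB1 receptor binding affinities (pKi) for THC and 14
synthetic cannabinoids (naphthoylindoles, benzoylindoles,
naphthoylnaphthalenes, cyclohexylphenols), the reference PLSR
predictions and applicability-domain distances for each compound, and
the two published regression equations (a 2-descriptor forward-selected
MLR and a 16-descriptor 2-component PLSR) on the standardized
descriptor scale.  The raw descriptor values behind those equations
were never published, so the coefficient vectors are usable only for
prediction on externally standardized descriptors and for checking
summary statistics; refitting requires user-supplied descriptors.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
from sklearn.utils import Bunch

from .io import validate_activity_table
from .models import LinearModel

__all__ = ["load_cb1_reference"]


def _data_path(name: str):
    return resources.files("cbqsar.data").joinpath(name)


def load_cb1_reference() -> Bunch:
    """Load the bundled CB1 synthetic-cannabinoid reference dataset.

    Returns
    -------
    Bunch with fields
        activity : DataFrame indexed by compound_id with ``role`` (11
            train, 3 test, 1 excluded_outlier) and ``pki`` (observed).
        predictions : DataFrame with observed pKi, reference PLSR
            predicted pKi and applicability-domain distance for the 14
            modeled compounds.
        mlr : LinearModel, the published 2-descriptor MLR equation
            (XLogP, ATSc4; standardized scale).
        plsr : LinearModel, the published 16-descriptor collapsed PLSR
            equation (standardized scale).
    """
    with _data_path("cb1_reference.csv").open("r", encoding="utf-8") as fh:
        table = pd.read_csv(fh, dtype={"compound_id": str}).set_index("compound_id")
    activity = pd.DataFrame(
        {"role": table["role"], "pki": table["pki_observed"].astype(float)},
        index=table.index,
    )
    validate_activity_table(activity)
    modeled = table[table["role"].isin(["train", "test"])]
    predictions = pd.DataFrame(
        {
            "role": modeled["role"],
            "pki_observed": modeled["pki_observed"].astype(float),
            "pki_predicted": modeled["pki_predicted"].astype(float),
            "apd_distance": modeled["apd_distance"].astype(float),
        },
        index=modeled.index,
    )
    with _data_path("cb1_mlr_model.json").open("r", encoding="utf-8") as fh:
        mlr = LinearModel.from_json(fh)
    with _data_path("cb1_plsr_model.json").open("r", encoding="utf-8") as fh:
        plsr = LinearModel.from_json(fh)
    return Bunch(activity=activity, predictions=predictions, mlr=mlr, plsr=plsr)
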