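"""End-to-end QSAR workflow orchestration.

The pipeline runs the full modeling recipe in a fixed stage order:

1. response-outlier screen (Grubbs, two-sided, single outlier) on the
   training responses, with exclusion;
2. three-stage descriptor filter chain, fit on training rows only;
3. standardization fit on train, applied to test;
4. model fitting per config: forward-selection MLR and/or NIPALS PLS1
   (component count fixed or chosen by a leave-one-out Q² scan);
5. validation: R², adjusted R², RMSE, leave-one-out Q², predictive R²,
   Y-randomization;
6. Euclidean applicability domain fit on the standardized training
   rows, with per-test-compound screening;
7. serialized reports.

Everything is deterministic for a fixed config and seed; no stage
reads test-set responses before the final evaluation step.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .datasets import load_cb1_reference
from .domain import EuclideanApplicabilityDomain
from .models import LinearModel
from .preprocessing import DescriptorStandardizer, FeatureSelectionChain
from .regression import (ComponentScan, ForwardSelectionMLR, PLS1Regression,
                         scan_components, vif)
from .validation import (FitReport, YRandomizationReport, adjusted_r_squared,
                         grubbs_test, q2_loo, r2_pred, r_squared, rmse,
                         y_randomization)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "report_predictions", "write_reports", "reference_check"]


@dataclass
class PipelineConfig:
    """All tunable settings of the workflow; round-trips through JSON."""

    freq_cut: float = 19.0
    unique_cut: float = 10.0
    corr_cutoff: float = 0.9
    min_abs_r: float = 0.3
    model: str = "both"                       # mlr | plsr | both
    n_components: Union[int, str] = "scan"    # integer or "scan"
    max_scan_components: int = 5
    max_forward_features: Optional[int] = None
    y_randomization_n: int = 25
    apd_z: float = 0.5
    outlier_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("mlr", "plsr", "both"):
            raise ValueError("model must be mlr, plsr or both")
        if not (0 < self.corr_cutoff <= 1):
            raise ValueError("corr_cutoff must be in (0, 1]")
        if not (0 <= self.min_abs_r < 1):
            raise ValueError("min_abs_r must be in [0, 1)")
        if not (0 < self.outlier_alpha < 1):
            raise ValueError("outlier_alpha must be in (0, 1)")
        if isinstance(self.n_components, str) and self.n_components != "scan":
            raise ValueError("n_components must be an integer or 'scan'")

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text(encoding="utf-8")
        return cls(**json.loads(text))


@dataclass
class PipelineResult:
    config: PipelineConfig
    models: Dict[str, LinearModel]
    fit_reports: Dict[str, FitReport]
    y_randomization: Dict[str, YRandomizationReport]
    component_scan: Optional[ComponentScan]
    vif: Dict[str, float]
    apd: EuclideanApplicabilityDomain
    predictions: pd.DataFrame
    filter_traces: list
    excluded_outliers: List[str]
    selected_features: List[str]
    log: List[str] = field(default_factory=list)


def _procedure(feature_names, make_model):
    """Refittable procedure (standardize + model) for CV/permutation."""
    def fit(Xtr, ytr):
        std = DescriptorStandardizer().fit(Xtr[feature_names])
        model = make_model().fit(std.transform(Xtr[feature_names]), ytr)
        def predict(Xnew):
            return model.predict(std.transform(Xnew[feature_names]))
        return predict
    return fit


def run_pipeline(descriptors: pd.DataFrame, activities: pd.DataFrame,
                 config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the full workflow; see the module docstring for stage order."""
    config = config or PipelineConfig()
    log: List[str] = []
    log.append(f"[config] {config.to_json()}")

    # -- join ---------------------------------------------------------
    modeled = activities[activities["role"].isin(["train", "test"])]
    missing = [i for i in modeled.index if i not in descriptors.index]
    if missing:
        raise ValueError(f"[join] compounds lack descriptor rows: {missing}")
    pre_excluded = list(activities.index[activities["role"] == "excluded_outlier"])
    for cid in pre_excluded:
        log.append(f"[outlier] {cid!r} pre-excluded by its role")

    train = modeled[modeled["role"] == "train"]
    test = modeled[modeled["role"] == "test"]

    # -- stage 1: Grubbs outlier screen on training responses ---------
    excluded = list(pre_excluded)
    g = grubbs_test(train["pki"].to_numpy(), alpha=config.outlier_alpha)
    if g.flagged_index is not None:
        cid = train.index[g.flagged_index]
        log.append(
            f"[outlier] Grubbs flagged {cid!r} (pKi={g.flagged_value}, "
            f"G={g.statistic:.3f} > crit={g.critical:.3f}); excluded"
        )
        excluded.append(str(cid))
        train = train.drop(index=cid)
    else:
        log.append(
            f"[outlier] Grubbs flagged none "
            f"(G={g.statistic:.3f} <= crit={g.critical:.3f})"
        )
    if train.shape[0] < 4:
        raise ValueError("[outlier] fewer than 4 training compounds remain")

    X_train = descriptors.loc[train.index]
    y_train = train["pki"].to_numpy()
    X_test = descriptors.loc[test.index]
    y_test = test["pki"].to_numpy()

    # -- stage 2: feature selection on training rows ------------------
    chain = FeatureSelectionChain(config.freq_cut, config.unique_cut,
                                  config.corr_cutoff, config.min_abs_r)
    chain.fit(X_train, y_train)
    features = list(chain.selected_features_)
    for t in chain.traces_:
        log.append(f"[filter] {t.stage}: {t.n_in} -> {t.n_out}")
    if not features:
        raise ValueError("[filter] no descriptors survive the filter chain")

    # -- stage 3: standardization fit on train ------------------------
    std = DescriptorStandardizer().fit(X_train[features])
    Z_train = std.transform(X_train[features])
    Z_test = std.transform(X_test[features]) if len(test) else X_test[features]
    log.append(f"[standardize] {len(features)} descriptors, train-fit scales")

    train_mean = float(y_train.mean())
    models: Dict[str, LinearModel] = {}
    reports: Dict[str, FitReport] = {}
    yrand: Dict[str, YRandomizationReport] = {}
    vifs: Dict[str, float] = {}
    scan: Optional[ComponentScan] = None
    predictions_by_model: Dict[str, Dict[str, np.ndarray]] = {}

    def validate(name, model_obj, yhat_train, yhat_test, n_params, make_model):
        proc = _procedure(features, make_model)
        r2 = r_squared(y_train, yhat_train)
        adj = None
        if y_train.size - n_params - 1 > 0:
            adj = adjusted_r_squared(r2, y_train.size, n_params)
        q2 = q2_loo(X_train, y_train, proc)
        rep = FitReport(
            r2=r2, adjusted_r2=adj, q2_loo=q2,
            r2_pred=(r2_pred(y_test, yhat_test, train_mean)
                     if len(y_test) else None),
            rmse_train=rmse(y_train, yhat_train),
            rmse_test=rmse(y_test, yhat_test) if len(y_test) else None,
            n_train=int(y_train.size), n_test=int(len(y_test)),
            n_params=n_params,
        )
        yr = y_randomization(X_train, y_train, proc,
                             n_permutations=config.y_randomization_n,
                             seed=config.seed)
        reports[name] = rep
        yrand[name] = yr
        log.append(
            f"[validate] {name}: R2={r2:.3f} Q2={q2:.3f} cRp2={yr.c_rp2:.3f}"
        )

    # -- stage 4/5: MLR ----------------------------------------------
    if config.model in ("mlr", "both"):
        fwd = ForwardSelectionMLR(max_features=config.max_forward_features)
        fwd.fit(Z_train, y_train)
        models["mlr"] = fwd.model_
        sel = fwd.selected_features_
        log.append(f"[fit] forward-MLR selected {sel}")
        if len(sel) >= 2:
            vifs = vif(Z_train, sel)
            log.append(f"[fit] VIF: { {k: round(v, 3) for k, v in vifs.items()} }")
        yhat_tr = fwd.predict(Z_train)
        yhat_te = fwd.predict(Z_test) if len(test) else np.array([])
        predictions_by_model["mlr"] = {"train": yhat_tr, "test": yhat_te}
        max_feat = config.max_forward_features
        validate("mlr", fwd, yhat_tr, yhat_te, max(1, len(sel)),
                 lambda: ForwardSelectionMLR(max_features=max_feat))

    # -- stage 4/5: PLSR ----------------------------------------------
    if config.model in ("plsr", "both"):
        rank = int(np.linalg.matrix_rank(
            Z_train.to_numpy() - Z_train.to_numpy().mean(axis=0)))
        if config.n_components == "scan":
            scan = scan_components(
                X_train[features], y_train,
                max_components=min(config.max_scan_components, rank),
            )
            ncomp = scan.best_by_q2
            log.append(
                f"[fit] component scan Q2={ [round(q, 3) for q in scan.q2] }; "
                f"chose {ncomp}"
            )
        else:
            ncomp = int(config.n_components)
            log.append(f"[fit] PLSR components pinned to {ncomp}")
        pls = PLS1Regression(n_components=ncomp).fit(Z_train, y_train)
        models["plsr"] = pls.to_linear_model()
        yhat_tr = pls.predict(Z_train)
        yhat_te = pls.predict(Z_test) if len(test) else np.array([])
        predictions_by_model["plsr"] = {"train": yhat_tr, "test": yhat_te}
        validate("plsr", pls, yhat_tr, yhat_te, ncomp,
                 lambda: PLS1Regression(n_components=ncomp))

    # -- stage 6: applicability domain --------------------------------
    apd = EuclideanApplicabilityDomain(z=config.apd_z).fit(Z_train)
    log.append(f"[apd] threshold={apd.threshold_:.4f} (z={config.apd_z})")

    # -- stage 7: prediction table ------------------------------------
    primary = "plsr" if "plsr" in models else "mlr"
    rows = []
    for subset, frame, Z in (("train", train, Z_train), ("test", test, Z_test)):
        if not len(frame):
            continue
        yhat = predictions_by_model[primary][subset]
        dist = apd.distance(Z)
        within = dist <= apd.threshold_
        for k, cid in enumerate(frame.index):
            obs = float(frame["pki"].iloc[k])
            rows.append({
                "compound_id": cid, "role": subset, "pki_observed": obs,
                "pki_predicted": float(yhat[k]),
                "residual": obs - float(yhat[k]),
                "apd_distance": float(dist[k]),
                "within_apd": bool(within[k]),
            })
    predictions = pd.DataFrame(rows).set_index("compound_id")

    return PipelineResult(
        config=config, models=models, fit_reports=reports,
        y_randomization=yrand, component_scan=scan, vif=vifs, apd=apd,
        predictions=predictions, filter_traces=list(chain.traces_),
        excluded_outliers=excluded, selected_features=features, log=log,
    )


def report_predictions(result: PipelineResult) -> pd.DataFrame:
    """Per-compound table: role, observed, predicted, residual, APD."""
    return result.predictions.copy()


def write_reports(result: PipelineResult, outdir) -> None:
    """Write model.json / validation.json / predictions.csv / filter_trace.jsonl."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model_payload = {name: m.to_dict() for name, m in result.models.items()}
    (outdir / "model.json").write_text(
        json.dumps(model_payload, indent=2) + "\n", encoding="utf-8")
    validation = {
        "config": dataclasses.asdict(result.config),
        "excluded_outliers": result.excluded_outliers,
        "selected_features": result.selected_features,
        "vif": result.vif,
        "fit_reports": {k: v.to_dict() for k, v in result.fit_reports.items()},
        "y_randomization": {k: v.to_dict()
                            for k, v in result.y_randomization.items()},
        "component_scan": (result.component_scan.to_frame().to_dict("list")
                           if result.component_scan else None),
        "apd": result.apd.to_dict(),
        "log": result.log,
    }
    (outdir / "validation.json").write_text(
        json.dumps(validation, indent=2) + "\n", encoding="utf-8")
    result.predictions.to_csv(outdir / "predictions.csv")
    with open(outdir / "filter_trace.jsonl", "w", encoding="utf-8") as fh:
        for t in result.filter_traces:
            fh.write(t.to_json_line() + "\n")


def reference_check() -> dict:
    """Recompute the bundled CB1 reference study's summary statistics.

    Works purely from the shipped observed/predicted pKi table and
    coefficient vectors (the underlying descriptor values were never
    published, so no refit is possible): training R² and RMSE, test
    RMSE and predictive R², per-compound residuals, the observed-pKi
    spread of the modeled compounds, the Grubbs outlier screen of all
    15 measured values, and the intercept property of the standardized
    PLSR equation.
    """
    ref = load_cb1_reference()
    pred = ref.predictions
    tr = pred[pred["role"] == "train"]
    te = pred[pred["role"] == "test"]
    train_mean = float(tr["pki_observed"].mean())

    residuals = (pred["pki_observed"] - pred["pki_predicted"]).to_dict()
    g = grubbs_test(ref.activity["pki"].to_numpy())
    flagged_id = (ref.activity.index[g.flagged_index]
                  if g.flagged_index is not None else None)
    zero_row = {name: 0.0 for name in ref.plsr.feature_names}
    return {
        "train_r2": r_squared(tr["pki_observed"], tr["pki_predicted"],
                              reference_mean=train_mean),
        "train_rmse": rmse(tr["pki_observed"], tr["pki_predicted"]),
        "test_rmse": rmse(te["pki_observed"], te["pki_predicted"]),
        "r2_pred": r2_pred(te["pki_observed"], te["pki_predicted"], train_mean),
        "residuals": residuals,
        "observed_spread": float(pred["pki_observed"].max()
                                 - pred["pki_observed"].min()),
        "train_mean": train_mean,
        "plsr_intercept_at_zero": float(ref.plsr.predict(zero_row)[0]),
        "mlr_intercept_at_zero": float(ref.mlr.predict(
            {n: 0.0 for n in ref.mlr.feature_names})[0]),
        "grubbs_flagged_compound": (str(flagged_id)
                                    if flagged_id is not None else None),
        "grubbs_flagged_value": g.flagged_value,
        "grubbs_statistic": g.statistic,
        "grubbs_critical": g.critical,
        "n_flagged": int(g.flagged_index is not None),
    }
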