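"""Accuracy metrics, report tables, and the full analysis pipeline.

``run_full_analysis`` reproduces the study design end to end on any
(records, assessments, participants) triple:

1. window and featurise every NPI assessment (assessments with empty
   windows are dropped and logged);
2. Stage 1: fit stepwise LR and RF on the training half of the first
   recruitment wave, evaluate LR, RF and the equal-weight ensemble (EM) on
   the held-out half; Stage 2: same on the second wave;
3. keep the features ranked in the RF top-k (default 6) of *both* stages;
4. refit on the selected features and evaluate under patientwise k-fold
   cross-validation (pooled out-of-fold predictions) and under the
   Pocock-Simon minimization train/test allocation.

Accuracy is mean absolute error, root-mean-square error and the Pearson
correlation (with its two-sided t-approximation p-value) between predicted
and observed NPI totals; Spearman is available behind a config flag since
the NPI is ordinal-like.
"""

from __future__ import annotations

import json
import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .features import FEATURE_NAMES, features_dataframe
from .models import (
    ModelBundle,
    ensemble_predict,
    fit_rf_with_ranking,
    fit_stepwise_lr,
    predict_with_clamp,
    select_common_top_k,
)
from .splits import (
    SplitPlan,
    minimization_split_plan,
    patientwise_kfold,
    two_stage_split,
)

logger = logging.getLogger(__name__)

MODELS = ("EM", "LR", "RF")
PROTOCOLS = ("stage1", "stage2", "patientwise", "minimization")


def error_metrics(pred, true) -> tuple[float, float]:
    """(MAE, RMSE) between predictions and observations; lower is better."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size == 0:
        raise ValueError("empty evaluation set")
    err = pred - true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    assert rmse >= mae - 1e-12, "RMSE < MAE should be impossible"
    return mae, rmse


def correlation(pred, true, method: str = "pearson") -> tuple[float, float]:
    """Correlation between predictions and observations, with its p-value."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size < 3:
        raise ValueError("correlation needs >= 3 paired observations")
    if np.std(pred) == 0 or np.std(true) == 0:
        raise ValueError("degenerate correlation input: zero variance")
    if method == "spearman":
        res = stats.spearmanr(pred, true)
    else:
        res = stats.pearsonr(pred, true)
    return float(res.statistic), float(res.pvalue)


def case_label(i: int) -> str:
    """A, B, ..., Z, AA, AB, ... — Table-style case labels."""
    letters = string.ascii_uppercase
    label = ""
    i = int(i)
    while True:
        label = letters[i % 26] + label
        i = i // 26 - 1
        if i < 0:
            return label


def build_prediction_table(
    cases: list[str],
    true,
    lr_preds,
    rf_preds,
    participant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-case table of true scores and the three model predictions.

    The EM column is always recomputed from the (unrounded) LR and RF
    columns rather than stored independently.
    """
    if len(cases) == 0:
        raise ValueError("empty case list")
    if len(set(cases)) != len(cases):
        raise ValueError("duplicate case labels")
    lr_preds = np.asarray(lr_preds, dtype=float)
    rf_preds = np.asarray(rf_preds, dtype=float)
    table = pd.DataFrame(
        {
            "case": cases,
            "true_npi": np.asarray(true, dtype=float),
            "EM": ensemble_predict(lr_preds, rf_preds),
            "LR": lr_preds,
            "RF": rf_preds,
        }
    )
    if participant_ids is not None:
        table.insert(1, "participant_id", participant_ids)
    return table


def format_prediction_table(table: pd.DataFrame, style: str = "stage1") -> pd.DataFrame:
    """Report formatting: 3 significant figures (stage1) or integers (stage2)."""
    out = table.copy()
    cols = ["EM", "LR", "RF"]
    if style == "stage2":
        out[cols] = out[cols].round(0).astype(int)
        out["true_npi"] = out["true_npi"].astype(int)
    else:
        out[cols] = out[cols].map(
            lambda v: float(f"{v:.3g}") if v != 0 else 0.0
        )
    return out


def _evaluate_models(
    table: pd.DataFrame, method: str = "pearson"
) -> dict[str, dict[str, float]]:
    """MAE/RMSE/r for every model column of a prediction table."""
    out: dict[str, dict[str, float]] = {}
    true = table["true_npi"].to_numpy()
    for model in MODELS:
        pred = table[model].to_numpy()
        mae, rmse = error_metrics(pred, true)
        try:
            r, p = correlation(pred, true, method=method)
        except ValueError as exc:
            logger.warning("correlation undefined for %s: %s", model, exc)
            r, p = float("nan"), float("nan")
        out[model] = {"mae": mae, "rmse": rmse, "r": r, "r_pvalue": p}
    _check_ensemble_bounds(out)
    return out


def _check_ensemble_bounds(metrics: dict[str, dict[str, float]]) -> None:
    # Triangle/Minkowski guarantees; violation indicates a pipeline bug.
    for m in ("mae", "rmse"):
        bound = (metrics["LR"][m] + metrics["RF"][m]) / 2
        assert metrics["EM"][m] <= bound + 1e-9, (
            f"ensemble {m} exceeded the LR/RF average: "
            f"{metrics['EM'][m]} > {bound}"
        )


@dataclass
class EvalReport:
    """Everything one pipeline run produced."""

    metrics: pd.DataFrame  # tidy: protocol, model, mae, rmse, r, r_pvalue, n_test
    tables: dict[str, pd.DataFrame]
    selected_features: list[str]
    stage_rankings: dict[str, dict[str, int]]
    stage_lr_terms: dict[str, list[dict]]
    dropped_windows: list[str]
    seed: int
    config_hash: str
    split_plans: dict[str, SplitPlan] = field(default_factory=dict)

    def metric(self, protocol: str, model: str, name: str) -> float:
        row = self.metrics[
            (self.metrics["protocol"] == protocol) & (self.metrics["model"] == model)
        ]
        return float(row[name].iloc[0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config_hash": self.config_hash,
                "selected_features": self.selected_features,
                "stage_rankings": self.stage_rankings,
                "stage_lr_terms": self.stage_lr_terms,
                "dropped_windows": self.dropped_windows,
                "metrics": self.metrics.to_dict(orient="records"),
                "tables": {
                    k: v.to_dict(orient="records") for k, v in self.tables.items()
                },
            },
            indent=2,
        )


def coefficient_report(report: EvalReport) -> pd.DataFrame:
    """Stage-wise stepwise coefficients and RF importance ranks per feature.

    Features dropped by the stepwise selection are reported as absent
    ("N.A."), matching the convention of a coefficient table.
    """
    rows = []
    for feat in FEATURE_NAMES:
        row: dict[str, object] = {"feature": feat}
        for stage in ("stage1", "stage2"):
            terms = {t["name"]: t for t in report.stage_lr_terms[stage]}
            if feat in terms:
                t = terms[feat]
                row[f"{stage}_beta"] = round(t["beta"], 3)
                row[f"{stage}_se"] = round(t["se"], 3)
                row[f"{stage}_pvalue"] = round(t["pvalue"], 4)
            else:
                row[f"{stage}_beta"] = "N.A."
                row[f"{stage}_se"] = "N.A."
                row[f"{stage}_pvalue"] = "N.A."
            row[f"{stage}_rf_rank"] = report.stage_rankings[stage][feat]
        rows.append(row)
    return pd.DataFrame(rows)


def _fit_and_predict(
    train: pd.DataFrame,
    test: pd.DataFrame,
    candidates: list[str],
    config: RunConfig,
    rf_seed: int,
    alpha_enter: float | None = None,
):
    lr = fit_stepwise_lr(
        train,
        train["npi_total"],
        candidates=candidates,
        alpha_enter=alpha_enter if alpha_enter is not None else config.alpha_enter,
        alpha_remove=config.alpha_remove,
    )
    rf = fit_rf_with_ranking(
        train,
        train["npi_total"],
        candidates=candidates,
        n_trees=config.n_trees,
        seed=rf_seed,
        use_permutation_importance=config.use_permutation_importance,
    )
    lr_pred = predict_with_clamp(lr, test)
    rf_pred = predict_with_clamp(rf, test)
    return lr, rf, lr_pred, rf_pred


def run_full_analysis(
    records: pd.DataFrame,
    assessments: pd.DataFrame,
    participants: pd.DataFrame,
    config: RunConfig | None = None,
) -> EvalReport:
    """Run the complete two-stage + final-model pipeline.

    Deterministic given ``config.seed``; all derived seeds come from one
    generator seeded with it.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    child = lambda: int(rng.integers(2**31))  # noqa: E731

    feats, dropped = features_dataframe(
        records,
        assessments,
        window_days=config.window_days,
        aggregate_daily=config.aggregate_daily,
        normalize=config.normalize_features,
    )
    if feats.empty:
        raise ValueError("no assessment has facial-expression data in its window")
    candidates = [c for c in FEATURE_NAMES if c in feats.columns]

    pid_order = list(participants["participant_id"])
    stage1_pids = pid_order[: config.stage1_size]
    stage2_pids = pid_order[config.stage1_size :]

    plans = two_stage_split(feats, stage1_pids, stage2_pids, seed=child())
    metrics_rows: list[dict] = []
    tables: dict[str, pd.DataFrame] = {}
    stage_rankings: dict[str, dict[str, int]] = {}
    stage_lr_terms: dict[str, list[dict]] = {}
    split_plans: dict[str, SplitPlan] = dict(plans)

    case_counter = 0
    for stage in ("stage1", "stage2"):
        plan = plans[stage]
        train = feats.loc[plan.members("train")]
        test = feats.loc[plan.members("test")]
        if len(test) == 0:
            raise ValueError(f"{stage} test half is empty")
        lr, rf, lr_pred, rf_pred = _fit_and_predict(
            train, test, candidates, config, rf_seed=child()
        )
        stage_rankings[stage] = rf.ranking
        stage_lr_terms[stage] = [
            {"name": t.name, "beta": t.beta, "se": t.se, "pvalue": t.pvalue}
            for t in lr.terms
        ]
        cases = [case_label(case_counter + i) for i in range(len(test))]
        case_counter += len(test)
        table = build_prediction_table(
            cases,
            test["npi_total"],
            lr_pred,
            rf_pred,
            participant_ids=list(test["participant_id"]),
        )
        tables[stage] = table
        for model, m in _evaluate_models(table, config.correlation_method).items():
            metrics_rows.append(
                {"protocol": stage, "model": model, **m, "n_test": len(test)}
            )

    selected = sorted(
        select_common_top_k(
            stage_rankings["stage1"], stage_rankings["stage2"], k=config.top_k
        ),
        key=FEATURE_NAMES.index,
    )
    logger.info("cross-stage selected features: %s", selected)

    # --- final models under patientwise k-fold CV (pooled out-of-fold) ---
    cv_plan = patientwise_kfold(
        feats, k=config.n_folds, seed=child(), mild_max=config.npi_mild_max
    )
    split_plans["patientwise"] = cv_plan
    parts = []
    for fold in cv_plan.groups():
        test_ids = cv_plan.members(fold)
        train = feats.drop(index=test_ids)
        test = feats.loc[test_ids]
        if len(test) == 0:
            continue
        _, _, lr_pred, rf_pred = _fit_and_predict(
            train, test, selected, config, rf_seed=child()
        )
        parts.append(
            pd.DataFrame(
                {
                    "sample_id": test_ids,
                    "participant_id": test["participant_id"],
                    "true_npi": test["npi_total"].astype(float),
                    "LR": lr_pred,
                    "RF": rf_pred,
                }
            )
        )
    pooled = pd.concat(parts, ignore_index=True)
    table = build_prediction_table(
        [case_label(i) for i in range(len(pooled))],
        pooled["true_npi"],
        pooled["LR"],
        pooled["RF"],
        participant_ids=list(pooled["participant_id"]),
    )
    tables["patientwise"] = table
    for model, m in _evaluate_models(table, config.correlation_method).items():
        metrics_rows.append(
            {"protocol": "patientwise", "model": model, **m, "n_test": len(table)}
        )

    # --- final models under the minimization train/test allocation ---
    min_plan = minimization_split_plan(
        feats,
        participants,
        test_fraction=config.test_fraction,
        seed=child(),
        mild_max=config.npi_mild_max,
        cut=config.age_cut,
        biased_coin_p=config.biased_coin_p,
    )
    split_plans["minimization"] = min_plan
    train = feats.loc[min_plan.members("train")]
    test = feats.loc[min_plan.members("test")]
    if len(test) == 0:
        raise ValueError("minimization allocation produced an empty test arm")
    _, _, lr_pred, rf_pred = _fit_and_predict(
        train, test, selected, config, rf_seed=child()
    )
    table = build_prediction_table(
        [case_label(i) for i in range(len(test))],
        test["npi_total"],
        lr_pred,
        rf_pred,
        participant_ids=list(test["participant_id"]),
    )
    tables["minimization"] = table
    for model, m in _evaluate_models(table, config.correlation_method).items():
        metrics_rows.append(
            {"protocol": "minimization", "model": model, **m, "n_test": len(test)}
        )

    return EvalReport(
        metrics=pd.DataFrame(metrics_rows),
        tables=tables,
        selected_features=selected,
        stage_rankings=stage_rankings,
        stage_lr_terms=stage_lr_terms,
        dropped_windows=dropped,
        seed=config.seed,
        config_hash=config.config_hash(),
        split_plans=split_plans,
    )


def fit_final_bundle(
    feats: pd.DataFrame, selected: list[str], config: RunConfig, rf_seed: int = 0
) -> ModelBundle:
    """Fit the selected-feature LR + RF pair on a full feature table."""
    lr = fit_stepwise_lr(
        feats,
        feats["npi_total"],
        candidates=selected,
        alpha_enter=config.alpha_enter,
        alpha_remove=config.alpha_remove,
    )
    rf = fit_rf_with_ranking(
        feats,
        feats["npi_total"],
        candidates=selected,
        n_trees=config.n_trees,
        seed=rf_seed,
    )
    return ModelBundle(
        lr=lr, rf=rf, selected_features=set(selected), config_hash=config.config_hash()
    )
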