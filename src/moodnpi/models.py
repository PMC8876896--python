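"""Prediction models over windowed mood features.

Three models target the NPI total:

* **stepwise linear regression** — bidirectional p-value stepwise selection:
  repeatedly add the most significant excluded candidate whose t-test
  p-value is below ``alpha_enter``, then drop any included term whose
  p-value exceeds ``alpha_remove``, until a fixed point.  Candidates whose
  entry would make the design matrix rank deficient (e.g. the exact sum
  ``freq_negative = freq_sadness + freq_anger`` once both addends are in)
  are permanently barred instead of crashing the fit;
* **random-forest regression** with an importance ranking (impurity-based by
  default, permutation importance behind a flag), rank 1 = most important,
  ties broken by the canonical feature order;
* the **equal-weight ensemble** ``EM = (LR + RF) / 2`` of the two clamped
  predictions.

Predictions are clamped to the NPI instrument range [0, 144] (12 domains x
frequency 4 x severity 3).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

NPI_BOUNDS = (0.0, 144.0)
_MAX_STEPWISE_ITER = 100


@dataclass(frozen=True)
class LinearTerm:
    name: str
    beta: float
    se: float
    pvalue: float


@dataclass
class StepwiseModel:
    """Result of a bidirectional stepwise linear-regression fit."""

    intercept: float
    terms: list[LinearTerm]
    candidates: list[str]
    barred_collinear: list[str] = field(default_factory=list)
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10

    @property
    def selected(self) -> list[str]:
        return [t.name for t in self.terms]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        _require_columns(X, self.selected)
        yhat = np.full(len(X), self.intercept, dtype=float)
        for term in self.terms:
            yhat += term.beta * X[term.name].to_numpy(dtype=float)
        return yhat


@dataclass
class ForestModel:
    """Random-forest regressor plus its feature-importance ranking."""

    estimator: RandomForestRegressor
    feature_names: list[str]
    importances: dict[str, float]
    ranking: dict[str, int]  # 1 = most important
    n_trees: int
    seed: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        _require_columns(X, self.feature_names)
        return self.estimator.predict(X[self.feature_names].to_numpy(dtype=float))


def _require_columns(X: pd.DataFrame, names: list[str]) -> None:
    missing = [n for n in names if n not in X.columns]
    if missing:
        raise KeyError(f"feature columns missing from input: {missing}")


def _ols_fit(X: pd.DataFrame, y: np.ndarray, cols: list[str]):
    design = sm.add_constant(
        X[cols].to_numpy(dtype=float), has_constant="add", prepend=True
    )
    return sm.OLS(np.asarray(y, dtype=float), design).fit()


def _pvalue(res, position: int) -> float:
    p = float(res.pvalues[position])
    return 1.0 if np.isnan(p) else p


def cap_candidates(X: pd.DataFrame, y, candidates: list[str], n_max: int) -> list[str]:
    """Univariate |correlation| screen keeping at most ``n_max`` candidates."""
    if len(candidates) <= n_max:
        return list(candidates)
    yv = np.asarray(y, dtype=float)
    scores = {}
    for name in candidates:
        x = X[name].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(yv) == 0:
            scores[name] = 0.0
        else:
            scores[name] = abs(float(np.corrcoef(x, yv)[0, 1]))
    kept = sorted(candidates, key=lambda n: (-scores[n], candidates.index(n)))[:n_max]
    logger.info(
        "capped stepwise candidates from %d to %d (n too small): kept %s",
        len(candidates), n_max, kept,
    )
    return [c for c in candidates if c in kept]  # preserve canonical order


def fit_stepwise_lr(
    X: pd.DataFrame,
    y,
    candidates: list[str] | None = None,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> StepwiseModel:
    """Bidirectional p-value stepwise OLS.

    ``candidates`` defaults to the canonical ten features present in ``X``.
    If the sample is too small for the candidate pool (fewer than
    ``len(candidates) + 2`` rows), the pool is capped by a univariate
    correlation screen and the cap is logged.
    """
    if candidates is None:
        candidates = [c for c in FEATURE_NAMES if c in X.columns]
    _require_columns(X, candidates)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if np.isnan(X[candidates].to_numpy(dtype=float)).any() or np.isnan(y).any():
        raise ValueError("stepwise input contains missing values")
    n_max = max(1, len(X) - 2)
    candidates = cap_candidates(X, y, candidates, n_max)

    if np.std(y) == 0:  # no signal: any nonzero fit is floating-point noise
        return StepwiseModel(
            intercept=float(np.mean(y)),
            terms=[],
            candidates=list(candidates),
            alpha_enter=alpha_enter,
            alpha_remove=alpha_remove,
        )

    included: list[str] = []
    barred: list[str] = []
    for _ in range(_MAX_STEPWISE_ITER):
        changed = False
        # forward step: most significant admissible candidate
        best_name, best_p = None, np.inf
        for name in candidates:
            if name in included or name in barred:
                continue
            cols = included + [name]
            design = np.column_stack(
                [np.ones(len(X)), X[cols].to_numpy(dtype=float)]
            )
            if np.linalg.matrix_rank(design) < design.shape[1]:
                logger.info("barring collinear candidate %r from entry", name)
                barred.append(name)
                continue
            res = _ols_fit(X, y, cols)
            p = _pvalue(res, len(cols))  # the new term is the last column
            if p < best_p:
                best_name, best_p = name, p
        if best_name is not None and best_p < alpha_enter:
            included.append(best_name)
            changed = True
        # backward steps: drop the worst term while it exceeds alpha_remove
        while included:
            res = _ols_fit(X, y, included)
            pvals = {name: _pvalue(res, i + 1) for i, name in enumerate(included)}
            worst = max(pvals, key=lambda n: pvals[n])
            if pvals[worst] > alpha_remove:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    else:
        logger.warning("stepwise selection hit the iteration cap; result may cycle")

    if included:
        res = _ols_fit(X, y, included)
        terms = [
            LinearTerm(
                name=name,
                beta=float(res.params[i + 1]),
                se=float(res.bse[i + 1]),
                pvalue=_pvalue(res, i + 1),
            )
            for i, name in enumerate(included)
        ]
        intercept = float(res.params[0])
    else:
        terms = []
        intercept = float(np.mean(y))
    return StepwiseModel(
        intercept=intercept,
        terms=terms,
        candidates=list(candidates),
        barred_collinear=barred,
        alpha_enter=alpha_enter,
        alpha_remove=alpha_remove,
    )


def fit_rf_with_ranking(
    X: pd.DataFrame,
    y,
    candidates: list[str] | None = None,
    n_trees: int = 500,
    seed: int = 0,
    use_permutation_importance: bool = False,
) -> ForestModel:
    """Random-forest regression with a deterministic importance ranking."""
    if candidates is None:
        candidates = [c for c in FEATURE_NAMES if c in X.columns]
    _require_columns(X, candidates)
    y = np.asarray(y, dtype=float)
    est = RandomForestRegressor(n_estimators=n_trees, random_state=int(seed))
    est.fit(X[candidates].to_numpy(dtype=float), y)
    if use_permutation_importance:
        perm = permutation_importance(
            est,
            X[candidates].to_numpy(dtype=float),
            y,
            n_repeats=10,
            random_state=int(seed),
        )
        raw = perm.importances_mean
    else:
        raw = est.feature_importances_
    importances = {name: float(v) for name, v in zip(candidates, raw)}
    canonical = {name: i for i, name in enumerate(FEATURE_NAMES)}
    order = sorted(
        candidates,
        key=lambda n: (-importances[n], canonical.get(n, len(canonical)), n),
    )
    ranking = {name: rank for rank, name in enumerate(order, start=1)}
    return ForestModel(
        estimator=est,
        feature_names=list(candidates),
        importances=importances,
        ranking=ranking,
        n_trees=n_trees,
        seed=int(seed),
    )


def select_common_top_k(
    rank_stage1: dict[str, int], rank_stage2: dict[str, int], k: int = 6
) -> set[str]:
    """Features ranked in the top ``k`` of *both* stage importance rankings."""
    for label, ranking in (("stage 1", rank_stage1), ("stage 2", rank_stage2)):
        ranks = sorted(ranking.values())
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"{label} ranking is not a bijection onto 1..n: {ranking}")
    if set(rank_stage1) != set(rank_stage2):
        raise ValueError("stage rankings cover different feature sets")
    top1 = {n for n, r in rank_stage1.items() if r <= k}
    top2 = {n for n, r in rank_stage2.items() if r <= k}
    common = top1 & top2
    if not common:
        raise ValueError(
            f"no feature ranked in the top {k} of both stages; increase k"
        )
    return common


def predict_with_clamp(
    model: StepwiseModel | ForestModel,
    X: pd.DataFrame,
    bounds: tuple[float, float] = NPI_BOUNDS,
) -> np.ndarray:
    """Model prediction clipped to the NPI instrument range."""
    return np.clip(model.predict(X), bounds[0], bounds[1])


def ensemble_predict(lr_pred, rf_pred):
    """Equal-weight ensemble: the arithmetic mean of the two predictions."""
    lr_pred = np.asarray(lr_pred, dtype=float)
    rf_pred = np.asarray(rf_pred, dtype=float)
    if not (np.isfinite(lr_pred).all() and np.isfinite(rf_pred).all()):
        raise ValueError("ensemble inputs must be finite")
    out = (lr_pred + rf_pred) / 2.0
    return float(out) if out.ndim == 0 else out


@dataclass
class ModelBundle:
    """The fitted per-stage models plus the cross-stage feature selection."""

    lr: StepwiseModel
    rf: ForestModel
    selected_features: set[str]
    clamp_bounds: tuple[float, float] = NPI_BOUNDS
    config_hash: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "lr": {
                    "intercept": self.lr.intercept,
                    "terms": [
                        {"name": t.name, "beta": t.beta, "se": t.se, "pvalue": t.pvalue}
                        for t in self.lr.terms
                    ],
                    "alpha_enter": self.lr.alpha_enter,
                    "alpha_remove": self.lr.alpha_remove,
                    "barred_collinear": self.lr.barred_collinear,
                },
                "rf": {
                    "n_trees": self.rf.n_trees,
                    "seed": self.rf.seed,
                    "importances": self.rf.importances,
                    "ranking": self.rf.ranking,
                },
                "selected_features": sorted(self.selected_features),
                "clamp_bounds": list(self.clamp_bounds),
                "config_hash": self.config_hash,
            },
            indent=2,
        )
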