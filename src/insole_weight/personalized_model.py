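"""Per-participant regression models, evaluation metrics, experiment runner.

Every participant gets their own regressor: individual load distributions
("gait patterns") mean two people with similar sensor ranges can have very
different weights, so a pooled model cannot separate them.  Training uses
one or more experimental iterations (80/20 train/validation split,
stratified by carried-weight class, plus k-fold CV on the training split);
a held-out iteration is used for testing.  Reports carry MAE, MSE, RMSE,
R^2, and MAPE (stored as a fraction), plus a per-carried-weight MAE
breakdown.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.model_selection import KFold, cross_val_score, train_test_split

from . import schema
from .adaptive_bias import BiasMode, BiasTable, WeightClass, compute_bias
from .moticon_io import DatasetInventory, select_participants
from .windowed_features import LABEL_COLUMN, build_feature_matrix

logger = logging.getLogger(__name__)

LEARNERS = ("extra_trees", "lightgbm", "catboost")


@dataclass(frozen=True)
class ModelConfig:
    learner: str = "extra_trees"
    train_fraction: float = 0.8
    cv_folds: int = 5
    n_estimators: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"learner must be one of {LEARNERS}, got {self.learner!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def make_estimator(config: ModelConfig):
    """Instantiate the configured regressor (gradient-boosting backends are
    optional extras)."""
    if config.learner == "extra_trees":
        return ExtraTreesRegressor(
            n_estimators=config.n_estimators, random_state=config.seed, n_jobs=1
        )
    if config.learner == "lightgbm":
        try:
            from lightgbm import LGBMRegressor
        except ImportError as exc:
            raise ImportError(
                "learner 'lightgbm' requires the optional lightgbm package "
                "(pip install insole-weight[boosting])"
            ) from exc
        return LGBMRegressor(n_estimators=config.n_estimators,
                             random_state=config.seed, verbosity=-1)
    if config.learner == "catboost":
        try:
            from catboost import CatBoostRegressor
        except ImportError as exc:
            raise ImportError(
                "learner 'catboost' requires the optional catboost package "
                "(pip install insole-weight[boosting])"
            ) from exc
        return CatBoostRegressor(iterations=config.n_estimators,
                                 random_seed=config.seed, verbose=False)
    raise AssertionError(config.learner)


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class EvalReport:
    """Five-metric evaluation summary (MAPE stored as a fraction)."""

    mae: float
    mse: float
    rmse: float
    r2: float
    mape: float
    n: int
    per_weight_mae: dict[int, float] | None = None

    def as_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "mse": self.mse, "rmse": self.rmse,
                "r2": self.r2, "mape": self.mape}


def evaluate(
    y_true: Sequence[float] | np.ndarray,
    y_pred: Sequence[float] | np.ndarray,
    carried_weights: Sequence[int] | np.ndarray | None = None,
) -> EvalReport:
    """Compute MAE, MSE, RMSE, R^2, and MAPE from prediction errors.

    Errors are ``e_i = y_i - yhat_i``; R^2 normalizes by the spread of the
    ground truths around their mean and is NaN (with a warning) when the
    ground truths have zero variance.  ``y_true`` must be nonzero for MAPE.
    When ``carried_weights`` is given, a per-carried-weight MAE breakdown is
    attached.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    if np.any(y_true == 0):
        raise ValueError("y_true must be nonzero for MAPE")

    e = y_true - y_pred
    mae = float(np.mean(np.abs(e)))
    mse = float(np.mean(e**2))
    rmse = float(np.sqrt(mse))
    mape = float(np.mean(np.abs(e / y_true)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("zero-variance ground truth: R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(e**2)) / ss_tot

    per_weight = None
    if carried_weights is not None:
        cw = np.asarray(carried_weights)
        per_weight = {
            int(w): float(np.mean(np.abs(e[cw == w]))) for w in np.unique(cw)
        }
    return EvalReport(mae, mse, rmse, r2, mape, n=y_true.size, per_weight_mae=per_weight)


def aggregate_reports(reports: Sequence[EvalReport]) -> EvalReport:
    """Unweighted arithmetic mean of each metric across participants."""
    if not reports:
        raise ValueError("need at least one report to aggregate")
    per_weight: dict[int, float] | None = None
    weights = sorted({w for r in reports if r.per_weight_mae for w in r.per_weight_mae})
    if weights:
        per_weight = {
            w: float(np.mean([r.per_weight_mae[w] for r in reports
                              if r.per_weight_mae and w in r.per_weight_mae]))
            for w in weights
        }
    return EvalReport(
        mae=float(np.mean([r.mae for r in reports])),
        mse=float(np.mean([r.mse for r in reports])),
        rmse=float(np.mean([r.rmse for r in reports])),
        r2=float(np.mean([r.r2 for r in reports])),
        mape=float(np.mean([r.mape for r in reports])),
        n=len(reports),
        per_weight_mae=per_weight,
    )


# ---------------------------------------------------------------------------
# Training / prediction


@dataclass
class ParticipantModel:
    participant_id: str
    estimator: object
    feature_names: tuple[str, ...]
    importances: np.ndarray
    cv_mae: np.ndarray              # per-fold MAE on the training split
    validation_mae: float           # MAE on the held-out 20% split
    config: ModelConfig
    bias_table: BiasTable | None = None


def train_participant(
    features_train: pd.DataFrame,
    config: ModelConfig,
    participant_id: str = "",
    bias_table: BiasTable | None = None,
) -> ParticipantModel:
    """Fit one participant's regressor on their training feature matrix.

    The matrix is split 80/20 (stratified on the carried-weight class when
    every class has at least two rows); k-fold CV MAE is measured on the
    training split and the model refit on it.  Deterministic given the
    config seed.
    """
    X = features_train[list(schema.MODEL_COLUMNS)]
    y = features_train[LABEL_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("cannot learn a weight mapping from a single label value")
    if len(y) < config.cv_folds * 2:
        raise ValueError(
            f"need at least {config.cv_folds * 2} rows, got {len(y)}"
        )

    strata = features_train["carried_weight"].to_numpy()
    stratify = strata if np.min(np.bincount(pd.factorize(strata)[0])) >= 2 else None
    if stratify is None:
        warnings.warn("some carried-weight class has < 2 rows; split unstratified",
                      stacklevel=2)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, train_size=config.train_fraction,
        random_state=config.seed, stratify=stratify,
    )

    est = make_estimator(config)
    cv = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    cv_mae = -cross_val_score(est, X_tr, y_tr, cv=cv,
                              scoring="neg_mean_absolute_error", n_jobs=1)
    est.fit(X_tr, y_tr)
    validation_mae = float(np.mean(np.abs(y_val - est.predict(X_val))))
    importances = np.asarray(getattr(est, "feature_importances_"))
    return ParticipantModel(
        participant_id=participant_id,
        estimator=est,
        feature_names=tuple(schema.MODEL_COLUMNS),
        importances=importances,
        cv_mae=np.asarray(cv_mae, dtype=float),
        validation_mae=validation_mae,
        config=config,
        bias_table=bias_table,
    )


def predict(model: ParticipantModel, features: pd.DataFrame) -> np.ndarray:
    """Predict total weight (lbs) for each feature-matrix row."""
    missing = set(model.feature_names) - set(features.columns)
    if missing:
        raise ValueError(f"feature matrix is missing model columns: {sorted(missing)}")
    X = features[list(model.feature_names)]
    out = np.asarray(model.estimator.predict(X), dtype=float)
    if not np.all(np.isfinite(out)):
        raise ValueError("model produced non-finite predictions")
    return out


# ---------------------------------------------------------------------------
# End-to-end experiment


@dataclass(frozen=True)
class Protocol:
    """Which experimental iterations train the model and which one tests it."""

    train_iterations: tuple[int, ...] = (1,)
    test_iteration: int = 2

    def __post_init__(self) -> None:
        if not self.train_iterations:
            raise ValueError("need at least one training iteration")
        if self.test_iteration in self.train_iterations:
            raise ValueError("test iteration must be disjoint from training iterations")


@dataclass(frozen=True)
class PipelineParams:
    """Pre-processing and model knobs for one experiment run."""

    bias_mode: BiasMode = BiasMode.FAB
    l_samples: int = 100
    olap_init: float = 0.2
    alpha: float = 15.0
    model: ModelConfig = field(default_factory=ModelConfig)
    on_all_zero: str = "zero"


@dataclass
class ParticipantResult:
    participant_id: str
    report: EvalReport
    model: ParticipantModel
    n_train_rows: int
    n_test_rows: int


@dataclass
class ExperimentResult:
    per_participant: dict[str, ParticipantResult]
    cohort: EvalReport
    params: PipelineParams
    protocol: Protocol
    skipped: list[str] = field(default_factory=list)

    @property
    def n_train_rows(self) -> int:
        return sum(r.n_train_rows for r in self.per_participant.values())


def _load_iteration(inventory: DatasetInventory, pid: str, iteration: int):
    return [
        inventory.get(pid, iteration, w).load()
        for w in inventory.weights(pid, iteration)
    ]


def run_experiment(
    inventory: DatasetInventory,
    ground_truth: Mapping[str, float],
    protocol: Protocol,
    params: PipelineParams,
    participants: Sequence[str] | None = None,
) -> ExperimentResult:
    """Run the full per-participant pipeline and evaluate held-out iterations.

    For each eligible participant: fit the bias table on the training
    iterations only, build corrected/windowed feature matrices, train that
    participant's model, predict the test iteration, and evaluate.
    Participants missing a protocol iteration (or absent from the
    ground-truth table) are skipped with a warning.
    """
    if participants is None:
        participants = select_participants(inventory, min_iterations=2)
    if not participants:
        raise ValueError("no eligible participants in the inventory")

    results: dict[str, ParticipantResult] = {}
    skipped: list[str] = []
    needed = set(protocol.train_iterations) | {protocol.test_iteration}
    for pid in participants:
        have = set(inventory.iterations(pid))
        if not needed <= have:
            warnings.warn(f"{pid}: missing iterations {sorted(needed - have)}; skipped",
                          stacklevel=2)
            skipped.append(pid)
            continue
        if pid not in ground_truth:
            warnings.warn(f"{pid}: no ground-truth body weight; skipped", stacklevel=2)
            skipped.append(pid)
            continue
        body_weight = ground_truth[pid]

        train_recs = [
            rec for it in protocol.train_iterations
            for rec in _load_iteration(inventory, pid, it)
        ]
        test_recs = _load_iteration(inventory, pid, protocol.test_iteration)

        weight_class = WeightClass(tuple(sorted({r.key.carried_weight for r in train_recs})))

        bias_table = None
        if params.bias_mode is not BiasMode.NONE:
            pools = {
                w: pd.concat(
                    [r.data[list(schema.RAW_MODEL_COLUMNS)]
                     for r in train_recs if r.key.carried_weight == w],
                    ignore_index=True,
                )
                for w in weight_class.weights
            }
            bias_table = compute_bias(pools, weight_class, on_all_zero=params.on_all_zero)

        fm_train = build_feature_matrix(
            train_recs, bias_table, params.bias_mode, params.l_samples,
            params.olap_init, params.alpha, body_weight, participant_id=pid,
        )
        fm_test = build_feature_matrix(
            test_recs, bias_table, params.bias_mode, params.l_samples,
            params.olap_init, params.alpha, body_weight, participant_id=pid,
        )
        assert set(fm_train["participant"]) == {pid} == set(fm_test["participant"])

        model = train_participant(fm_train, params.model, participant_id=pid,
                                  bias_table=bias_table)
        y_pred = predict(model, fm_test)
        report = evaluate(fm_test[LABEL_COLUMN].to_numpy(), y_pred,
                          carried_weights=fm_test["carried_weight"].to_numpy())
        results[pid] = ParticipantResult(pid, report, model,
                                         n_train_rows=len(fm_train),
                                         n_test_rows=len(fm_test))
        logger.info("%s: %d train rows, %d test rows, test MAE %.3f lbs",
                    pid, len(fm_train), len(fm_test), report.mae)

    if not results:
        raise ValueError("every participant was skipped; nothing to evaluate")
    cohort = aggregate_reports([r.report for r in results.values()])
    return ExperimentResult(results, cohort, params, protocol, skipped)


def run_ablation(
    inventory: DatasetInventory,
    ground_truth: Mapping[str, float],
    protocol: Protocol,
    base_params: PipelineParams,
    bias_modes: Sequence[BiasMode | str] = (BiasMode.FAB,),
    l_samples_grid: Sequence[int] = (100,),
    alpha_grid: Sequence[float] = (15.0,),
    participants: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Grid ablation over bias mode x sample length x alpha.

    Returns one row per grid cell with the cohort metrics and the total
    training-instance count.
    """
    if not (bias_modes and l_samples_grid and alpha_grid):
        raise ValueError("ablation grid must be non-empty in every dimension")
    rows = []
    for mode in bias_modes:
        for ls in l_samples_grid:
            for alpha in alpha_grid:
                params = replace(base_params, bias_mode=BiasMode(mode),
                                 l_samples=int(ls), alpha=float(alpha))
                result = run_experiment(inventory, ground_truth, protocol, params,
                                        participants=participants)
                rows.append({
                    "bias_mode": BiasMode(mode).value,
                    "l_samples": int(ls),
                    "alpha": float(alpha),
                    "n_train_rows": result.n_train_rows,
                    **result.cohort.as_dict(),
                })
    return pd.DataFrame(rows)
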