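"""End-to-end moisture-content diagnosis.

Chain: decompose each AE record (ACMD) -> summarize into a feature vector
-> split records 8:2 into train/test -> tune the boosted-tree
hyperparameters with the improved grey wolf optimizer (objective: k-fold
cross-validated RMSE on the training split) -> fit on the full training
split -> report RMSE / MAE / MAPE / R^2 on the test split.

"Accuracy" for the continuous MC target is defined as ``100 - MAPE`` (MC is
itself a percentage, so the mean absolute percentage error is directly a
percentage-point miss).  An optional ROC-AUC is computed only when a binary
wet/dry threshold on MC is configured (default convention: 30%, around the
fiber saturation point).

A decomposition ablation compares the ACMD-feature front end against
decomposition-free waveform/hit features under identical seeds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .acmd import ACMDConfig, acmd_decompose
from .ae_features import (detect_hits, feature_names, features_from_modes,
                          raw_feature_names, raw_features)
from .gbt import (DEFAULT_SEARCH_SPACE, GBTModel, Hyperparameters, fit_gbt)
from .optimizer import RunResult, StrategyConfig, optimize
from .signal_sim import Record

__all__ = [
    "Dataset", "MetricsReport", "TuneResult", "PipelineConfig",
    "split_train_test", "evaluate", "tune", "build_dataset",
    "run_diagnosis", "decomposition_ablation",
]


# ---------------------------------------------------------------------------
# Dataset container

@dataclass
class Dataset:
    """Feature matrix with MC targets, record ids and train/test labels."""

    X: np.ndarray                          # (n, d)
    y: np.ndarray                          # (n,) percent MC
    ids: np.ndarray                        # (n,) record identifiers
    feature_names: list[str]
    split: np.ndarray | None = None        # 'train'/'test' per row, or None

    def __post_init__(self) -> None:
        if len({self.X.shape[0], self.y.size, self.ids.size}) != 1:
            raise ValueError("X, y and ids must agree in length")
        if np.unique(self.ids).size != self.ids.size:
            raise ValueError("record ids must be unique")

    @property
    def n(self) -> int:
        return self.y.size

    def subset(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        if self.split is None:
            raise ValueError("dataset has not been split yet")
        mask = self.split == label
        return self.X[mask], self.y[mask]


def split_train_test(ds: Dataset, ratio: float = 0.8,
                     seed: int | None = 0) -> Dataset:
    """Seeded 8:2 split by record id.

    Rows are ordered canonically by id before the seeded shuffle, so the
    split assignment depends only on the id set and the seed — presenting
    the records in a different order yields the same partition.  The first
    ``ceil(ratio * n)`` shuffled records become the training split.
    """
    if ds.n < 5:
        raise ValueError("need at least 5 records to split")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    canonical = np.argsort(ds.ids, kind="stable")
    rng = np.random.default_rng(seed)
    perm = canonical[rng.permutation(ds.n)]
    n_train = math.ceil(ratio * ds.n)
    labels = np.empty(ds.n, dtype=object)
    labels[perm[:n_train]] = "train"
    labels[perm[n_train:]] = "test"
    return Dataset(X=ds.X, y=ds.y, ids=ds.ids,
                   feature_names=ds.feature_names, split=labels)


# ---------------------------------------------------------------------------
# Metrics

@dataclass
class MetricsReport:
    """RMSE / MAE / MAPE / R^2 plus derived accuracy for a prediction set."""

    rmse: float                            # percent MC
    mae: float                             # percent MC
    mape: float                            # percent
    r2: float
    accuracy: float                        # 100 - MAPE
    auc: float | None = None

    def to_dict(self) -> dict:
        d = {"rmse": self.rmse, "mae": self.mae, "mape": self.mape,
             "r2": self.r2, "accuracy": self.accuracy}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def evaluate(y_true: np.ndarray, y_pred: np.ndarray,
             wet_threshold: float | None = None) -> MetricsReport:
    """Standard regression metrics; accuracy = 100 - MAPE.

    Zero targets are excluded from the MAPE with a warning (the relative
    error is undefined there).  ROC-AUC is computed against the binary
    label ``y_true >= wet_threshold`` using the prediction as score, and
    only when a threshold is supplied and both classes are present.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("prediction set must be non-empty and consistent")
    err = y_pred - y_true
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    nz = y_true != 0
    if not nz.all():
        warnings.warn("zero targets excluded from MAPE", RuntimeWarning,
                      stacklevel=2)
    mape = float(np.mean(np.abs(err[nz] / y_true[nz])) * 100) if nz.any() else float("nan")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    sse = float(np.sum(err**2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    auc = None
    if wet_threshold is not None:
        labels = y_true >= wet_threshold
        if labels.any() and not labels.all():
            auc = _roc_auc(labels, y_pred)
        else:
            warnings.warn("only one wet/dry class present; AUC omitted",
                          RuntimeWarning, stacklevel=2)
    return MetricsReport(rmse=rmse, mae=mae, mape=mape, r2=r2,
                         accuracy=100.0 - mape, auc=auc)


def _roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney form of the ROC area (ties counted half)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# Hyperparameter tuning (IGWO over the boosting knobs)

@dataclass
class TuneResult:
    best_hp: Hyperparameters
    best_objective: float                  # mean CV RMSE at best_hp
    run: RunResult
    converged_at: int


def _decode(position: np.ndarray,
            space: Mapping[str, tuple[float, float, bool]]) -> Hyperparameters:
    kwargs = {}
    for val, (name, (lo, hi, is_int)) in zip(position, space.items()):
        v = float(np.clip(val, lo, hi))
        kwargs[name] = int(round(v)) if is_int else v
    return Hyperparameters(**kwargs)


def _cv_rmse(X: np.ndarray, y: np.ndarray, hp: Hyperparameters,
             folds: int, seed: int) -> float:
    """Mean validation RMSE over seeded folds; degenerate folds are skipped."""
    n = y.size
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    parts = np.array_split(perm, folds)
    scores = []
    for k, val_idx in enumerate(parts):
        train_idx = np.setdiff1d(perm, val_idx)
        if np.ptp(y[train_idx]) == 0 or val_idx.size == 0:
            warnings.warn(f"fold {k} degenerate (constant target); skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        model = fit_gbt(X[train_idx], y[train_idx], hp, seed=seed + k)
        pred = model.predict(X[val_idx])
        scores.append(float(np.sqrt(np.mean((pred - y[val_idx]) ** 2))))
    if not scores:
        return float("inf")
    return float(np.mean(scores))


def tune(
    X: np.ndarray,
    y: np.ndarray,
    space: Mapping[str, tuple[float, float, bool]] | None = None,
    strategies: StrategyConfig = StrategyConfig(),
    n_wolves: int = 8,
    tmax: int = 10,
    seed: int = 0,
    folds: int = 3,
) -> TuneResult:
    """Search the hyperparameter box with (I)GWO.

    Optimizer positions live in the per-hyperparameter boxes of ``space``
    (integer knobs are rounded on decode); the fitness of a position is the
    mean validation RMSE over ``folds`` seeded folds of (X, y).  The fold
    partition and the per-fold fit seeds depend only on ``seed``, so the
    objective is deterministic and the reported best value equals its
    re-evaluation at the best position.
    """
    space = dict(space) if space is not None else dict(DEFAULT_SEARCH_SPACE)
    lb = np.array([lo for lo, _, _ in space.values()], dtype=float)
    ub = np.array([hi for _, hi, _ in space.values()], dtype=float)

    # integer rounding on decode makes revisits exact: memoize per decoded hp
    cache: dict[tuple, float] = {}

    def objective(pos: np.ndarray) -> float:
        hp = _decode(pos, space)
        key = tuple(sorted(vars(hp).items()))
        if key not in cache:
            cache[key] = _cv_rmse(X, y, hp, folds, seed)
        return cache[key]

    res = optimize(objective, (lb, ub), strategies=strategies, n=n_wolves,
                   tmax=tmax, seed=seed)
    best_hp = _decode(res.best_x, space)
    return TuneResult(best_hp=best_hp,
                      best_objective=_cv_rmse(X, y, best_hp, folds, seed),
                      run=res, converged_at=res.converged_at)


# ---------------------------------------------------------------------------
# Full diagnosis

@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; defaults are desk-scale."""

    acmd: ACMDConfig = field(default_factory=lambda: ACMDConfig(max_modes=3))
    front_end: str = "acmd"                # 'acmd' | 'raw'
    hit_threshold: float = 0.05
    hit_hdt: float = 0.02                  # s
    split_ratio: float = 0.8
    space: Mapping[str, tuple[float, float, bool]] | None = None
    strategies: StrategyConfig = field(default_factory=StrategyConfig)
    n_wolves: int = 8
    tmax: int = 10
    folds: int = 3
    seed: int = 0
    wet_threshold: float | None = None     # e.g. 30.0 to get ROC-AUC


def _record_features(rec: Record, cfg: PipelineConfig) -> np.ndarray | None:
    hits = detect_hits(rec.waveform, cfg.hit_threshold, cfg.hit_hdt)
    if cfg.front_end == "raw":
        return raw_features(rec.waveform, hits)
    try:
        comps, _ = acmd_decompose(rec.waveform, cfg.acmd)
    except Exception as exc:               # decomposition failure: drop record
        warnings.warn(f"record {rec.id}: decomposition failed ({exc}); dropped",
                      RuntimeWarning, stacklevel=2)
        return None
    return features_from_modes(comps, hits, cfg.acmd.max_modes,
                               rec.waveform.rate)


def build_dataset(records: Sequence[Record], cfg: PipelineConfig) -> Dataset:
    """Per-record feature extraction into an unsplit Dataset."""
    rows, ys, ids = [], [], []
    for rec in records:
        feats = _record_features(rec, cfg)
        if feats is None:
            continue
        rows.append(feats)
        ys.append(rec.mc)
        ids.append(rec.id)
    names = (raw_feature_names() if cfg.front_end == "raw"
             else feature_names(cfg.acmd.max_modes))
    # canonical id order: downstream folds/splits see the same rows no
    # matter how the records were presented
    ids = np.asarray(ids)
    order = np.argsort(ids, kind="stable")
    return Dataset(X=np.asarray(rows)[order], y=np.asarray(ys)[order],
                   ids=ids[order], feature_names=names)


def run_diagnosis(
    records: Sequence[Record], cfg: PipelineConfig | None = None
) -> tuple[GBTModel, MetricsReport, TuneResult, Dataset]:
    """Decompose, featurize, split, tune, fit, and score on the test split."""
    cfg = cfg if cfg is not None else PipelineConfig()
    if len(records) < 25:
        raise ValueError("need at least 25 records for a meaningful 8:2 + CV run")
    ds = build_dataset(records, cfg)
    ds = split_train_test(ds, ratio=cfg.split_ratio, seed=cfg.seed)
    X_tr, y_tr = ds.subset("train")
    X_te, y_te = ds.subset("test")
    tuned = tune(X_tr, y_tr, space=cfg.space, strategies=cfg.strategies,
                 n_wolves=cfg.n_wolves, tmax=cfg.tmax, seed=cfg.seed,
                 folds=cfg.folds)
    model = fit_gbt(X_tr, y_tr, tuned.best_hp, seed=cfg.seed)
    report = evaluate(y_te, model.predict(X_te), wet_threshold=cfg.wet_threshold)
    return model, report, tuned, ds


def decomposition_ablation(
    records: Sequence[Record],
    cfg: PipelineConfig | None = None,
    arms: Sequence[str] = ("raw", "acmd"),
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Run the diagnosis once per feature front end under identical seeds.

    Returns a one-row-per-arm metrics table and, per arm, the signed
    per-record test errors (prediction minus truth).
    """
    cfg = cfg if cfg is not None else PipelineConfig()
    rows = []
    errors: dict[str, np.ndarray] = {}
    for arm in arms:
        arm_cfg = replace(cfg, front_end=arm)
        model, report, tuned, ds = run_diagnosis(records, arm_cfg)
        X_te, y_te = ds.subset("test")
        errors[arm] = model.predict(X_te) - y_te
        rows.append({"arm": arm, **report.to_dict(),
                     "tune_iterations": tuned.converged_at})
    return pd.DataFrame(rows), errors
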