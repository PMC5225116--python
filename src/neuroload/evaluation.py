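"""Blocked cross-validation, metrics, and feature-subset experiments.

Trials are never shuffled: each task block is split into k contiguous
partitions and fold i holds out partition i of every block.  Any
held-out trial within ``buffer`` trials (within-block index distance) of
a training trial is dropped from the *test* set only, so short-timescale
carry-over cannot leak across the split while the training-set size
stays constant.

Metrics: standardized MSE (mean squared error divided by the population
variance of the true test values, so a constant mean predictor scores
exactly 1), Pearson r, and a discretized classification accuracy
obtained by rounding each continuous prediction to the nearest training
label (ties to the smaller label).  Pooled metrics concatenate the
(truth, prediction) pairs of all folds; per-fold values are also kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import gpr as _gpr
from .baselines import fit_mlr, predict_mlr
from .features import FeatureMatrix, apply_normalizer, fit_normalizer
from .montage import resolve_channel_subset

log = logging.getLogger(__name__)

BLOCK_KEY_COLUMNS = ("participant", "mode", "level", "block")


@dataclass
class CVFold:
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class CVPlan:
    k: int
    buffer: int
    folds: list[CVFold]


def _partition_sizes(length: int, k: int) -> list[int]:
    # Earlier partitions absorb the remainder (deterministic layout).
    base, rem = divmod(length, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def make_cv_plan(labels: pd.DataFrame, k: int = 5, buffer: int = 5) -> CVPlan:
    """Blocked k-fold plan with a leakage buffer.

    ``labels`` must carry the block-key columns (participant, mode,
    level, block) and a within-block ``trial`` index.  Every block is
    split into k contiguous near-equal partitions; fold i tests
    partition i of every block, trains on the rest, and removes from the
    test set any trial within ``buffer`` positions of a training trial
    of the same block.  Blocks in different breaks are never buffered
    against each other.  Blocks shorter than k trials are rejected.
    """
    for col in BLOCK_KEY_COLUMNS + ("trial",):
        if col not in labels.columns:
            raise ValueError(f"labels missing required column {col!r}")
    folds = [CVFold(train_idx=[], test_idx=[]) for _ in range(k)]
    for _, group in labels.groupby(list(BLOCK_KEY_COLUMNS), sort=False):
        group = group.sort_values("trial")
        rows = group.index.to_numpy()
        n = len(rows)
        if n < k:
            raise ValueError(f"block of {n} trials shorter than k={k}")
        sizes = _partition_sizes(n, k)
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        pos = np.arange(n)
        for i in range(k):
            test_mask = (pos >= bounds[i]) & (pos < bounds[i + 1])
            train_pos = pos[~test_mask]
            test_pos = pos[test_mask]
            dist = np.abs(test_pos[:, None] - train_pos[None, :]).min(axis=1)
            retained = test_pos[dist > buffer]
            folds[i].train_idx.append(rows[train_pos])
            folds[i].test_idx.append(rows[retained])
    folds = [
        CVFold(train_idx=np.concatenate(f.train_idx),
               test_idx=(np.concatenate(f.test_idx) if f.test_idx
                         else np.array([], dtype=int)))
        for f in folds
    ]
    return CVPlan(k=k, buffer=buffer, folds=folds)


def smse(truth: np.ndarray, predictions: np.ndarray) -> float:
    """Mean squared error / population variance of the true values.

    0 = perfect; exactly 1 for a model that always predicts the mean of
    the truth.  NaN (flagged missing) when the truth does not vary.
    """
    truth = np.asarray(truth, dtype=float).ravel()
    predictions = np.asarray(predictions, dtype=float).ravel()
    if len(truth) < 2 or len(truth) != len(predictions):
        raise ValueError("need >= 2 aligned (truth, prediction) pairs")
    var = float(np.var(truth))  # population variance (divide by n)
    if var == 0.0:
        log.warning("zero truth variance; sMSE undefined")
        return float("nan")
    return float(np.mean((truth - predictions) ** 2) / var)


def pearson_r(truth: np.ndarray, predictions: np.ndarray) -> float:
    """Product-moment correlation; NaN when either input is constant."""
    truth = np.asarray(truth, dtype=float).ravel()
    predictions = np.asarray(predictions, dtype=float).ravel()
    if len(truth) != len(predictions) or len(truth) < 2:
        raise ValueError("need >= 2 aligned (truth, prediction) pairs")
    if np.std(truth) == 0 or np.std(predictions) == 0:
        log.warning("constant input; Pearson r undefined")
        return float("nan")
    return float(np.corrcoef(truth, predictions)[0, 1])


def discretize_predictions(predictions: np.ndarray,
                           training_labels) -> np.ndarray:
    """Round each continuous prediction to the nearest training label.

    A prediction of 2.4 with labels {1, 2, 3} becomes 2; distance ties
    go to the smaller label.
    """
    labels = np.unique(np.asarray(training_labels, dtype=float))
    if labels.size == 0:
        raise ValueError("training label set is empty")
    predictions = np.asarray(predictions, dtype=float).ravel()
    diffs = np.abs(predictions[:, None] - labels[None, :])
    return labels[np.argmin(diffs, axis=1)]  # argmin -> first (smaller) label


def classification_accuracy(truth: np.ndarray, labels: np.ndarray) -> float:
    truth = np.asarray(truth, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if len(truth) != len(labels) or len(truth) == 0:
        raise ValueError("need aligned nonempty truth/label vectors")
    return float(np.mean(truth == labels))


@dataclass
class MetricReport:
    smse: float
    pearson_r: float
    accuracy: float
    n_trials: int
    per_fold: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {"smse": self.smse, "pearson_r": self.pearson_r,
               "accuracy": self.accuracy, "n_trials": self.n_trials}
        if self.per_fold is not None:
            out["per_fold"] = self.per_fold.to_dict(orient="records")
        return out


@dataclass
class CVResult:
    method: str
    label_kind: str
    records: pd.DataFrame          # row, fold, truth, prediction, variance, discrete
    report: MetricReport
    models: list = field(default_factory=list)
    normalizers: list = field(default_factory=list)
    plan: CVPlan | None = None
    feature_names: list[str] | None = None


def _labels_vector(features: FeatureMatrix, label_kind: str) -> np.ndarray:
    if label_kind == "level":
        return features.labels["level"].to_numpy(dtype=float)
    if label_kind == "subjective":
        y = features.labels["subjective"].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError("subjective ratings missing for some trials")
        return y
    raise ValueError(f"unknown label kind {label_kind!r}")


def _pooled_report(records: pd.DataFrame,
                   per_fold: pd.DataFrame | None = None) -> MetricReport:
    truth = records["truth"].to_numpy()
    pred = records["prediction"].to_numpy()
    disc = records["discrete"].to_numpy()
    return MetricReport(
        smse=smse(truth, pred),
        pearson_r=pearson_r(truth, pred),
        accuracy=classification_accuracy(truth, disc),
        n_trials=len(records),
        per_fold=per_fold,
    )


def run_cv(
    features: FeatureMatrix,
    plan: CVPlan,
    method: str = "gpr",
    label_kind: str = "level",
    gpr_options: dict | None = None,
) -> CVResult:
    """Cross-validated fit/predict with per-fold train-only normalization.

    Per fold: z-scoring statistics are fit on the training rows and
    applied to both sets, the model (GP or MLR) is trained, and the
    retained test trials are predicted.  Pooled metrics are computed on
    the concatenated prediction records of all folds; per-fold metrics
    are reported alongside.  Folds with an empty retained test set are
    skipped with a warning.
    """
    if method not in ("gpr", "mlr"):
        raise ValueError(f"unknown method {method!r}")
    gpr_options = dict(gpr_options or {})
    y_all = _labels_vector(features, label_kind)
    values = features.values
    rec_frames = []
    fold_rows = []
    models, normalizers = [], []
    for fold_i, fold in enumerate(plan.folds):
        if fold.test_idx.size == 0:
            log.warning("fold %d has no retained test trials; skipped", fold_i)
            models.append(None)
            normalizers.append(None)
            continue
        stats = fit_normalizer(values[fold.train_idx])
        Xtr = apply_normalizer(values[fold.train_idx], stats)
        Xte = apply_normalizer(values[fold.test_idx], stats)
        ytr = y_all[fold.train_idx]
        yte = y_all[fold.test_idx]
        if method == "gpr":
            init = gpr_options.get("init_hyper")
            model = _gpr.train_gpr(
                Xtr, ytr, init_hyper=init,
                max_function_evals=gpr_options.get(
                    "max_function_evals", _gpr.DEFAULT_MAX_FUNCTION_EVALS),
                feature_names=features.feature_names,
            )
            pred = _gpr.predict(model, Xte)
            mean, var = pred.mean, pred.var_observed
        else:
            model = fit_mlr(Xtr, ytr)
            mean = predict_mlr(model, Xte)
            var = np.full(len(yte), np.nan)
        disc = discretize_predictions(mean, ytr)
        models.append(model)
        normalizers.append(stats)
        rec_frames.append(pd.DataFrame({
            "row": fold.test_idx, "fold": fold_i, "truth": yte,
            "prediction": mean, "variance": var, "discrete": disc,
        }))
        fold_rows.append({
            "fold": fold_i,
            "smse": smse(yte, mean),
            "pearson_r": pearson_r(yte, mean),
            "accuracy": classification_accuracy(yte, disc),
            "n_trials": len(yte),
        })
    if not rec_frames:
        raise ValueError("every fold had an empty retained test set")
    records = pd.concat(rec_frames, ignore_index=True)
    report = _pooled_report(records, per_fold=pd.DataFrame(fold_rows))
    return CVResult(method=method, label_kind=label_kind, records=records,
                    report=report, models=models, normalizers=normalizers,
                    plan=plan, feature_names=features.feature_names)


def _subset_records(features: FeatureMatrix, cv_result: CVResult,
                    retained: np.ndarray, refit: bool = False) -> pd.DataFrame:
    """Re-predict every fold's retained test rows using a feature subset."""
    y_all = _labels_vector(features, cv_result.label_kind)
    frames = []
    for fold_i, fold in enumerate(cv_result.plan.folds):
        model = cv_result.models[fold_i]
        stats = cv_result.normalizers[fold_i]
        if model is None or fold.test_idx.size == 0:
            continue
        Xte = apply_normalizer(features.values[fold.test_idx], stats)
        pred = _gpr.predict_with_feature_subset(model, Xte, retained,
                                                refit=refit)
        yte = y_all[fold.test_idx]
        disc = discretize_predictions(pred.mean, y_all[fold.train_idx])
        frames.append(pd.DataFrame({
            "row": fold.test_idx, "fold": fold_i, "truth": yte,
            "prediction": pred.mean, "variance": pred.var_observed,
            "discrete": disc,
        }))
    return pd.concat(frames, ignore_index=True)


def feature_sweep(
    features: FeatureMatrix,
    cv_result: CVResult,
    percents: Sequence[int] = tuple(range(1, 101)),
    refit: bool = False,
) -> pd.DataFrame:
    """Pooled sMSE as a function of the retained-feature percentage.

    For each percentage, every fold keeps that fraction of features with
    the shortest trained length scales (ranked on training data only)
    and re-predicts its retained test trials.  Percentages that round
    down to zero features are skipped.  The 100% point coincides with
    the full model.
    """
    if cv_result.method != "gpr":
        raise ValueError("feature sweep requires a GPR cross-validation result")
    n_feat = features.n_features
    orders = {}
    for fold_i, model in enumerate(cv_result.models):
        if model is not None:
            orders[fold_i] = np.argsort(model.hyper.length_scales,
                                        kind="stable")
    rows = []
    y_all = _labels_vector(features, cv_result.label_kind)
    for pct in percents:
        n_keep = int(np.floor(pct * n_feat / 100.0))
        if n_keep == 0:
            continue
        frames = []
        for fold_i, fold in enumerate(cv_result.plan.folds):
            model = cv_result.models[fold_i]
            if model is None or fold.test_idx.size == 0:
                continue
            retained = orders[fold_i][:n_keep]
            stats = cv_result.normalizers[fold_i]
            Xte = apply_normalizer(features.values[fold.test_idx], stats)
            pred = _gpr.predict_with_feature_subset(model, Xte, retained,
                                                    refit=refit)
            frames.append(pd.DataFrame({
                "truth": y_all[fold.test_idx], "prediction": pred.mean}))
        pooled = pd.concat(frames, ignore_index=True)
        rows.append({
            "percent": pct, "n_features": n_keep,
            "smse": smse(pooled["truth"], pooled["prediction"]),
        })
    return pd.DataFrame(rows)


def ranked_subset_eval(
    features: FeatureMatrix,
    cv_result: CVResult,
    fraction: float,
    ranking: str = "ard",
    refit: bool = False,
) -> MetricReport:
    """Evaluate the top ``fraction`` of features ranked per fold.

    ``ranking='ard'`` keeps the shortest trained length scales;
    ``'anova'`` keeps the largest one-way F for task level, computed on
    that fold's training rows only.
    """
    from .baselines import anova_f_per_feature

    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n_keep = max(1, int(np.floor(fraction * features.n_features)))
    y_all = _labels_vector(features, cv_result.label_kind)
    frames = []
    for fold_i, fold in enumerate(cv_result.plan.folds):
        model = cv_result.models[fold_i]
        stats = cv_result.normalizers[fold_i]
        if model is None or fold.test_idx.size == 0:
            continue
        if ranking == "ard":
            order = np.argsort(model.hyper.length_scales, kind="stable")
        elif ranking == "anova":
            Xtr = apply_normalizer(features.values[fold.train_idx], stats)
            levels = features.labels["level"].to_numpy()[fold.train_idx]
            f = anova_f_per_feature(Xtr, levels).f_values
            order = np.argsort(-f, kind="stable")
        else:
            raise ValueError(f"unknown ranking {ranking!r}")
        retained = order[:n_keep]
        Xte = apply_normalizer(features.values[fold.test_idx], stats)
        pred = _gpr.predict_with_feature_subset(model, Xte, retained,
                                                refit=refit)
        disc = discretize_predictions(pred.mean, y_all[fold.train_idx])
        frames.append(pd.DataFrame({
            "row": fold.test_idx, "fold": fold_i,
            "truth": y_all[fold.test_idx], "prediction": pred.mean,
            "variance": pred.var_observed, "discrete": disc,
        }))
    records = pd.concat(frames, ignore_index=True)
    return _pooled_report(records)


def montage_subset_eval(
    features: FeatureMatrix,
    cv_result: CVResult,
    channel_subset,
    refit: bool = False,
) -> MetricReport:
    """Evaluate a named or explicit channel subset (all bands retained).

    The full per-fold models are kept; prediction restricts the kernel
    to the subset's features, emulating a reduced montage at test time.
    """
    channels = resolve_channel_subset(channel_subset,
                                      montage=features.channels)
    retained = features.feature_indices_for_channels(channels)
    records = _subset_records(features, cv_result, retained, refit=refit)
    return _pooled_report(records)


def cross_variant_eval(
    features: FeatureMatrix,
    plan: CVPlan,
    method: str = "gpr",
    label_kind: str = "level",
    gpr_options: dict | None = None,
) -> pd.DataFrame:
    """3x3 pooled-sMSE matrix over (train variant, test variant) pairs.

    For each ordered pair, fold i trains on the fold's training rows of
    the train variant only and tests on the fold's retained test rows of
    the test variant; the diagonal is the matched-variant case.
    Normalization statistics come from each cell's training rows.
    """
    gpr_options = dict(gpr_options or {})
    modes = list(dict.fromkeys(features.labels["mode"]))
    y_all = _labels_vector(features, label_kind)
    mode_col = features.labels["mode"].to_numpy()
    matrix = pd.DataFrame(index=modes, columns=modes, dtype=float)
    for train_mode in modes:
        fold_models = []
        for fold in plan.folds:
            tr = fold.train_idx[mode_col[fold.train_idx] == train_mode]
            stats = fit_normalizer(features.values[tr])
            Xtr = apply_normalizer(features.values[tr], stats)
            ytr = y_all[tr]
            if method == "gpr":
                model = _gpr.train_gpr(
                    Xtr, ytr,
                    max_function_evals=gpr_options.get(
                        "max_function_evals",
                        _gpr.DEFAULT_MAX_FUNCTION_EVALS))
            else:
                model = fit_mlr(Xtr, ytr)
            fold_models.append((model, stats))
        for test_mode in modes:
            truths, preds = [], []
            for fold, (model, stats) in zip(plan.folds, fold_models):
                te = fold.test_idx[mode_col[fold.test_idx] == test_mode]
                if te.size == 0:
                    continue
                Xte = apply_normalizer(features.values[te], stats)
                if method == "gpr":
                    mean = _gpr.predict(model, Xte).mean
                else:
                    mean = predict_mlr(model, Xte)
                truths.append(y_all[te])
                preds.append(mean)
            matrix.loc[train_mode, test_mode] = smse(
                np.concatenate(truths), np.concatenate(preds))
    matrix.index.name = "train_variant"
    matrix.columns.name = "test_variant"
    return matrix
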