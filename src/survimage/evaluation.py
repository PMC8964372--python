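"""Repeated train/test evaluation with optimal-threshold metrics.

The protocol mirrors an imbalanced-cohort study design: 50 stratified
80/20 train-test splits (one per random seed), minority-class SMOTE
oversampling of the training fold, AUC on the test fold, a Youden-optimal
classification threshold chosen on the test ROC (J = TPR - FPR, Eqs. below),
thresholded accuracy/precision/recall/F1 with the positive class being
death within the horizon, and mean +- SD aggregation over the repeats.

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Everything fitted (gene selection, image layout, Min-Max scaler, clinical
standardization, SMOTE, model weights, threshold) is refit per repeat on
that repeat's training fold by default; ``paper_mode=True`` instead fits
selection, scaler and ordering once on all labeled samples, reproducing the
original single-fit protocol and its optimistic bias.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neighbors import NearestNeighbors

from .annotation_io import (
    AnnotationAssets,
    assign_groups_from_hierarchy,
    assign_groups_from_pathways,
)
from .cohort_data import LabeledCohort
from .feature_selection import mi_scores, select_top_k, variance_filter
from .image_builder import GeneImageLayout, build_layout, fit_minmax, render_images
from .survival_model import (
    IMAGE_INPUTS,
    ModelConfig,
    TrainSettings,
    assemble_architecture,
    train,
)

__all__ = [
    "SplitRepeat",
    "SplitPlan",
    "ConfusionCounts",
    "MetricSet",
    "ExperimentResult",
    "SplitArtifacts",
    "make_splits",
    "smote_oversample",
    "youden_threshold",
    "thresholded_metrics",
    "fit_split_artifacts",
    "build_model_inputs",
    "run_protocol",
]


@dataclass(frozen=True)
class SplitRepeat:
    seed: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass
class SplitPlan:
    repeats: list[SplitRepeat]


def make_splits(
    sample_ids: Sequence[str],
    labels: Mapping[str, int],
    n_repeats: int = 50,
    test_fraction: float = 0.2,
    base_seed: int = 0,
    seeds: Sequence[int] | None = None,
) -> SplitPlan:
    """Stratified shuffled train/test splits, one per seed.

    Each repeat shuffles with its own seed then splits so that the test
    fold holds ``ceil(test_fraction * n)`` samples with both classes
    represented in train and test.  Deterministic per seed.
    """
    ids = list(sample_ids)
    y = np.array([labels[s] for s in ids])
    if len(ids) < 5:
        raise ValueError("need at least 5 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if seeds is None:
        seeds = [base_seed + i for i in range(n_repeats)]
    repeats = []
    for seed in seeds:
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=test_fraction, random_state=seed
        )
        train_idx, test_idx = next(splitter.split(np.zeros(len(ids)), y))
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(f"a class is absent from the training set (seed {seed})")
        repeats.append(
            SplitRepeat(
                seed=seed,
                train_ids=tuple(ids[i] for i in train_idx),
                test_ids=tuple(ids[i] for i in test_idx),
            )
        )
    return SplitPlan(repeats)


def smote_oversample(
    features: np.ndarray,
    labels: Sequence[int],
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to exact class balance.

    Each synthetic point is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``
    and ``x_nn`` one of the k nearest minority neighbors of ``x`` (Euclidean
    on the flattened feature vectors).  Originals are preserved and come
    first.  Applies to training data only (caller's responsibility).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, d) aligned with labels")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE expects exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class must have at least 2 samples")
    Xmin = X[y == minority]
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    _, neighbor_idx = nn.kneighbors(Xmin)  # first neighbor is the point itself

    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    u = rng.random(n_new)
    anchors = Xmin[base]
    partners = Xmin[neighbor_idx[base, pick]]
    synthetic = anchors + u[:, None] * (partners - anchors)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority)])
    return X_out, y_out


def youden_threshold(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """Threshold maximizing Youden's J = TPR - FPR; ties -> smallest.

    Candidate thresholds are the midpoints between consecutive distinct
    scores plus one below the minimum and the maximum score itself, under
    the classification rule ``score > threshold -> predicted positive``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    candidates = np.concatenate(
        [[max(uniq[0] / 2, 0.0)], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1]]]
    )
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = s > t
        tpr = (pred & (y == 1)).sum() / n_pos
        fpr = (pred & (y == 0)).sum() / n_neg
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t), float(best_j)


@dataclass(frozen=True)
class ConfusionCounts:
    """Positive class = death within horizon (label 1)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    auc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "threshold": self.threshold,
        }


def thresholded_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
) -> tuple[MetricSet, ConfusionCounts]:
    """Confusion counts and metrics at a threshold (rule: score > threshold).

    Precision, recall and F1 are defined as 0 when their denominators
    vanish.  AUC is threshold-free and computed from the raw scores.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = (s > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    counts = ConfusionCounts(tp, fp, tn, fn)
    accuracy = (tp + tn) / counts.total if counts.total else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    auc = float(roc_auc_score(y, s)) if len(np.unique(y)) > 1 else 0.0
    return MetricSet(auc, accuracy, precision, recall, f1, threshold), counts


@dataclass
class ExperimentResult:
    per_repeat: list[MetricSet]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.per_repeat and not self.mean:
            frame = self.to_frame()
            self.mean = frame.mean().to_dict()
            self.sd = frame.std(ddof=0).to_dict()  # population SD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.as_dict() for m in self.per_repeat])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})

    def write_tsv(self, path: str | Path) -> None:
        self.summary_frame().to_csv(path, sep="\t", index_label="metric")


@dataclass
class SplitArtifacts:
    """Everything fitted on one training fold."""

    selected_genes: list[str]
    layouts: dict[str, GeneImageLayout]  # keyed by image input name
    clinical_mean: np.ndarray
    clinical_sd: np.ndarray
    fingerprint: str = ""


def _fingerprint(genes: Sequence[str], *arrays) -> str:
    h = hashlib.sha256("\n".join(genes).encode())
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def fit_split_artifacts(
    cohort: LabeledCohort,
    annotation: AnnotationAssets,
    train_ids: Sequence[str],
    k: int = 1000,
    candidate_genes: Sequence[str] | None = None,
    variance_threshold: float = 10.0,
    seed: int = 0,
    paper_mode: bool = False,
) -> SplitArtifacts:
    """Fit gene selection, scalers and both image layouts on a training fold.

    ``candidate_genes`` may carry a precomputed variance-filter result (the
    filter runs on all samples regardless of mode); otherwise it is computed
    here.  With ``paper_mode`` the MI selection, Min-Max scaler and ordering
    means use all labeled samples instead of the training fold.
    """
    all_ids = cohort.labeled_sample_ids
    expr_all = cohort.expression.subset_samples(all_ids)
    if candidate_genes is None:
        candidate_genes = variance_filter(expr_all, variance_threshold)
    if not candidate_genes:
        raise ValueError("variance filter removed every gene")
    fit_ids = list(all_ids) if paper_mode else list(train_ids)
    expr_fit = cohort.expression.subset_genes(candidate_genes).subset_samples(fit_ids)
    table = mi_scores(expr_fit, cohort.label_array(fit_ids), seed=seed)
    selected = select_top_k(table, k=k)

    expr_sel_fit = expr_fit.subset_genes(selected)
    scaler = fit_minmax(expr_sel_fit)
    means = dict(zip(selected, expr_sel_fit.values.mean(axis=1)))

    brite_assignment = assign_groups_from_hierarchy(
        annotation.hierarchy, annotation.annotation_to_gene, selected
    )
    pathway_assignment = assign_groups_from_pathways(annotation.pathways, selected)
    layouts = {
        "image_brite": build_layout(brite_assignment, means, scaler),
        "image_pathway": build_layout(pathway_assignment, means, scaler),
    }

    clin = cohort.clinical_matrix(fit_ids)
    clinical_mean = clin.mean(axis=0)
    clinical_sd = clin.std(axis=0)
    clinical_sd[clinical_sd == 0] = 1.0

    fp = _fingerprint(
        selected,
        scaler.x_min,
        scaler.x_max,
        clinical_mean,
        clinical_sd,
    )
    return SplitArtifacts(selected, layouts, clinical_mean, clinical_sd, fp)


def build_model_inputs(
    cohort: LabeledCohort,
    artifacts: SplitArtifacts,
    sample_ids: Sequence[str],
    enabled_inputs: Sequence[str],
) -> dict[str, np.ndarray]:
    """Render images and standardized clinical scalars for a sample list."""
    expr = cohort.expression.subset_genes(artifacts.selected_genes).subset_samples(
        list(sample_ids)
    )
    inputs: dict[str, np.ndarray] = {}
    for name in IMAGE_INPUTS:
        if name in enabled_inputs:
            inputs[name] = render_images(artifacts.layouts[name], expr)
    if "age" in enabled_inputs or "stage" in enabled_inputs:
        clin = cohort.clinical_matrix(list(sample_ids))
        z = (clin - artifacts.clinical_mean) / artifacts.clinical_sd
        if "age" in enabled_inputs:
            inputs["age"] = z[:, 0]
        if "stage" in enabled_inputs:
            inputs["stage"] = z[:, 1]
    return inputs


def _flatten_inputs(
    inputs: Mapping[str, np.ndarray], enabled: Sequence[str]
) -> tuple[np.ndarray, list[tuple[str, tuple]]]:
    parts, shapes = [], []
    for name in enabled:
        arr = np.asarray(inputs[name])
        shapes.append((name, arr.shape[1:]))
        parts.append(arr.reshape(arr.shape[0], -1))
    return np.concatenate(parts, axis=1), shapes


def _unflatten_inputs(
    flat: np.ndarray, shapes: list[tuple[str, tuple]]
) -> dict[str, np.ndarray]:
    out = {}
    offset = 0
    for name, shape in shapes:
        width = int(np.prod(shape)) if shape else 1
        block = flat[:, offset : offset + width]
        out[name] = block.reshape(len(flat), *shape) if shape else block[:, 0]
        offset += width
    return out


def run_protocol(
    cohort: LabeledCohort,
    annotation: AnnotationAssets,
    config: ModelConfig,
    plan: SplitPlan,
    k: int = 1000,
    variance_threshold: float = 10.0,
    train_settings: TrainSettings | None = None,
    paper_mode: bool = False,
    smote_k_neighbors: int = 5,
) -> ExperimentResult:
    """Run the full repeated-split protocol and aggregate mean +- SD.

    Per repeat: fit selection/layouts/scalers on the training fold (or once
    on all samples in ``paper_mode``), SMOTE-balance the flattened training
    inputs, train the model, score the test fold, choose the Youden-optimal
    threshold on the test ROC, and compute the thresholded metrics.
    """
    base_settings = train_settings or TrainSettings()
    all_ids = cohort.labeled_sample_ids
    expr_all = cohort.expression.subset_samples(all_ids)
    candidate_genes = variance_filter(expr_all, variance_threshold)
    if not candidate_genes:
        raise ValueError("variance filter removed every gene")

    shared_artifacts = None
    if paper_mode:
        shared_artifacts = fit_split_artifacts(
            cohort,
            annotation,
            all_ids,
            k=k,
            candidate_genes=candidate_genes,
            seed=base_settings.seed,
            paper_mode=True,
        )

    per_repeat: list[MetricSet] = []
    for repeat in plan.repeats:
        try:
            artifacts = shared_artifacts or fit_split_artifacts(
                cohort,
                annotation,
                repeat.train_ids,
                k=k,
                candidate_genes=candidate_genes,
                seed=repeat.seed,
            )
            enabled = config.enabled_inputs
            train_inputs = build_model_inputs(
                cohort, artifacts, repeat.train_ids, enabled
            )
            y_train = cohort.label_array(repeat.train_ids)
            if base_settings.oversample:
                flat, shapes = _flatten_inputs(train_inputs, enabled)
                flat_bal, y_train = smote_oversample(
                    flat, y_train, k_neighbors=smote_k_neighbors, seed=repeat.seed
                )
                train_inputs = _unflatten_inputs(flat_bal, shapes)
                for name in IMAGE_INPUTS:
                    if name in train_inputs:
                        train_inputs[name] = np.clip(train_inputs[name], 0.0, 1.0)

            side = next(
                (artifacts.layouts[n].side for n in IMAGE_INPUTS if n in enabled), 4
            )
            description = assemble_architecture(config, side)
            settings = TrainSettings(
                epochs=base_settings.epochs,
                batch_size=base_settings.batch_size,
                early_stop_patience=base_settings.early_stop_patience,
                seed=repeat.seed,
                oversample=base_settings.oversample,
            )
            predictor = train(
                description, {**train_inputs, "labels": y_train}, settings
            )

            test_inputs = build_model_inputs(
                cohort, artifacts, repeat.test_ids, enabled
            )
            scores = predictor.predict(test_inputs)
            y_test = cohort.label_array(repeat.test_ids)
            threshold, _ = youden_threshold(scores, y_test)
            metrics, counts = thresholded_metrics(scores, y_test, threshold)
            if counts.total != len(repeat.test_ids):
                raise RuntimeError("confusion counts do not cover the test fold")
            per_repeat.append(metrics)
        except Exception as exc:
            raise RuntimeError(f"repeat with seed {repeat.seed} failed: {exc}") from exc
    return ExperimentResult(per_repeat)
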