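"""Supervised gene selection: variance filter then mutual-information ranking.

The gene universe is first reduced by an unsupervised variance filter
(default threshold 10 on log-scale expression), then the surviving genes are
ranked by estimated mutual information

    I(X; Y) = sum_{x,y} p(x, y) * ln[ p(x, y) / (p(x) p(y)) ]

between each gene's expression X (continuous) and the binary outcome Y,
computed on the training split only, and the top K genes are kept
(default K = 1000).  MI is zero exactly when the gene is independent of the
outcome.  The continuous-feature / discrete-target MI is estimated with the
nearest-neighbor estimator (3 neighbors, seeded jitter);
:func:`plugin_mutual_information` gives the exact plug-in value for discrete
data and serves as the analytic reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif

from .cohort_data import ExpressionMatrix

__all__ = [
    "GeneScoreTable",
    "variance_filter",
    "plugin_mutual_information",
    "mi_scores",
    "select_top_k",
]


@dataclass
class GeneScoreTable:
    """Aligned per-gene variance and (optionally) MI scores."""

    gene_ids: list[str]
    variance: np.ndarray
    mi_score: np.ndarray | None = None

    def __post_init__(self):
        self.variance = np.asarray(self.variance, dtype=float)
        if len(self.gene_ids) != len(self.variance):
            raise ValueError("gene_ids and variance misaligned")
        if self.mi_score is not None:
            self.mi_score = np.asarray(self.mi_score, dtype=float)
            if len(self.mi_score) != len(self.gene_ids):
                raise ValueError("gene_ids and mi_score misaligned")
            if np.any(self.mi_score < 0):
                raise ValueError("mi_score must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene_id": self.gene_ids, "variance": self.variance})
        if self.mi_score is not None:
            df["mi_score"] = self.mi_score
        return df

    def write_tsv(self, path: str | Path, selected: Sequence[str] | None = None) -> None:
        """Write gene_id, variance, mi_score, rank; rank by descending MI."""
        df = self.to_frame()
        if self.mi_score is not None:
            order = sorted(
                range(len(self.gene_ids)),
                key=lambda i: (-self.mi_score[i], self.gene_ids[i]),
            )
            rank = np.empty(len(order), dtype=int)
            rank[order] = np.arange(1, len(order) + 1)
            df["rank"] = rank
        if selected is not None:
            df = df[df["gene_id"].isin(set(selected))]
        df.to_csv(path, sep="\t", index=False)


def variance_filter(m: ExpressionMatrix, threshold: float = 10.0) -> list[str]:
    """Genes whose unbiased sample variance (across samples) is >= threshold.

    Input gene order is preserved.  Undefined for a single-sample matrix.
    """
    if m.n_samples < 2:
        raise ValueError("variance undefined with fewer than 2 samples")
    var = m.values.var(axis=1, ddof=1)
    return [g for g, v in zip(m.gene_ids, var) if v >= threshold]


def plugin_mutual_information(x: Sequence, y: Sequence) -> float:
    """Exact plug-in mutual information (nats) of two discrete samples.

    Direct summation over the empirical joint distribution:
    sum p(x,y) ln[p(x,y) / (p(x)p(y))].  Zero exactly when the empirical
    joint factorizes.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = len(x)
    joint: dict[tuple, int] = {}
    px: dict = {}
    py: dict = {}
    for xi, yi in zip(x.tolist(), y.tolist()):
        joint[(xi, yi)] = joint.get((xi, yi), 0) + 1
        px[xi] = px.get(xi, 0) + 1
        py[yi] = py.get(yi, 0) + 1
    mi = 0.0
    for (xi, yi), c in joint.items():
        pxy = c / n
        mi += pxy * np.log(pxy * n * n / (px[xi] * py[yi]))
    return max(mi, 0.0)


def mi_scores(
    m: ExpressionMatrix,
    labels: Sequence[int],
    seed: int = 0,
    n_neighbors: int = 3,
) -> GeneScoreTable:
    """Nearest-neighbor MI estimate between each gene and the binary label.

    Deterministic given ``seed`` (the estimator adds seeded jitter to break
    expression ties).  Scores are clipped at zero.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) != m.n_samples:
        raise ValueError("labels misaligned with samples")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    X = m.values.T  # samples x genes
    scores = mutual_info_classif(
        X, y, discrete_features=False, n_neighbors=n_neighbors, random_state=seed
    )
    scores = np.clip(scores, 0.0, None)
    variance = m.values.var(axis=1, ddof=1) if m.n_samples > 1 else np.zeros(m.n_genes)
    return GeneScoreTable(list(m.gene_ids), variance, scores)


def select_top_k(t: GeneScoreTable, k: int = 1000) -> list[str]:
    """The k genes with highest MI score; ties broken by ascending gene ID.

    If fewer than k genes are available, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if t.mi_score is None:
        raise ValueError("MI scores not computed")
    order = sorted(
        range(len(t.gene_ids)), key=lambda i: (-t.mi_score[i], t.gene_ids[i])
    )
    if k > len(order):
        warnings.warn(
            f"requested k={k} but only {len(order)} genes available; returning all",
            stacklevel=2,
        )
        k = len(order)
    return [t.gene_ids[i] for i in order[:k]]
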