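"""Gene expression vectors to 2-D images via multi-index sorting.

Each selected gene is Min-Max scaled to [0, 1] with per-gene minima and
maxima fitted on a reference cohort:

    x_scaled = (x - x_min) / (x_max - x_min)        (clipped to [0, 1])

Genes are then ordered primarily by their annotation group (hierarchy
subclass or pathway, in the group order fixed by the assignment), and within
each group by descending mean expression over the ordering cohort, ties by
ascending gene ID.  The ordered values fill a square grid row-major; the
side is ceil(sqrt(K)) and the trailing cells beyond K are zero padding.

The fitted :class:`GeneImageLayout` is a serializable recipe: rendering a
sample's image depends only on the layout and that sample's vector.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation_io import GeneGroupAssignment
from .cohort_data import ExpressionMatrix

__all__ = [
    "MinMaxScaler",
    "GeneImageLayout",
    "GeneImage",
    "fit_minmax",
    "apply_minmax",
    "build_layout",
    "render_image",
    "render_images",
    "save_png",
]


@dataclass
class MinMaxScaler:
    """Per-gene min/max on the fitting-cohort scale."""

    gene_ids: list[str]
    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self):
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if not (len(self.gene_ids) == len(self.x_min) == len(self.x_max)):
            raise ValueError("scaler arrays misaligned")
        if np.any(self.x_min > self.x_max):
            raise ValueError("x_min must be <= x_max per gene")


def fit_minmax(m: ExpressionMatrix) -> MinMaxScaler:
    """Per-gene minimum and maximum over the fitting samples."""
    if m.n_samples < 1:
        raise ValueError("need at least one fitting sample")
    return MinMaxScaler(
        list(m.gene_ids), m.values.min(axis=1), m.values.max(axis=1)
    )


def apply_minmax(s: MinMaxScaler, m: ExpressionMatrix) -> np.ndarray:
    """Scale a matrix to [0, 1] with fitted ranges (genes x samples).

    Out-of-range values (e.g. a new cohort) are clipped; genes with zero
    fitted range map to 0.  The gene sets must match exactly.
    """
    if set(m.gene_ids) != set(s.gene_ids):
        unknown = sorted(set(m.gene_ids) - set(s.gene_ids))
        missing = sorted(set(s.gene_ids) - set(m.gene_ids))
        raise KeyError(
            f"gene set mismatch: unknown to scaler {unknown[:5]}, absent {missing[:5]}"
        )
    pos = {g: i for i, g in enumerate(s.gene_ids)}
    rows = [pos[g] for g in m.gene_ids]
    lo = s.x_min[rows][:, None]
    hi = s.x_max[rows][:, None]
    span = hi - lo
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(span > 0, (m.values - lo) / span, 0.0)
    return np.clip(scaled, 0.0, 1.0)


@dataclass
class GeneImageLayout:
    """Fitted recipe turning one sample's vector into a square image."""

    ordered_genes: list[str]
    side: int
    scaler: MinMaxScaler
    group_boundaries: list[tuple[str, int, int]]  # (group, start, end exclusive)

    def __post_init__(self):
        k = len(self.ordered_genes)
        if self.side != math.ceil(math.sqrt(k)):
            raise ValueError(f"side {self.side} != ceil(sqrt({k}))")
        if sorted(self.ordered_genes) != sorted(self.scaler.gene_ids):
            raise ValueError("ordered_genes must be a permutation of scaler genes")

    @property
    def n_genes(self) -> int:
        return len(self.ordered_genes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ordered_genes": self.ordered_genes,
            "side": self.side,
            "group_boundaries": [list(b) for b in self.group_boundaries],
            "scaler": {
                "gene_ids": self.scaler.gene_ids,
                "x_min": self.scaler.x_min.tolist(),
                "x_max": self.scaler.x_max.tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneImageLayout":
        p = json.loads(Path(path).read_text())
        scaler = MinMaxScaler(
            p["scaler"]["gene_ids"],
            np.array(p["scaler"]["x_min"]),
            np.array(p["scaler"]["x_max"]),
        )
        return cls(
            p["ordered_genes"],
            p["side"],
            scaler,
            [tuple(b) for b in p["group_boundaries"]],
        )


@dataclass
class GeneImage:
    pixels: np.ndarray  # (side, side), values in [0, 1]
    sample_id: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square matrix")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")


def build_layout(
    assignment: GeneGroupAssignment,
    mean_expression: Mapping[str, float],
    scaler: MinMaxScaler,
) -> GeneImageLayout:
    """Multi-index sort of the selected genes into a square grid.

    Primary key: group position in ``assignment.group_order``; secondary:
    mean expression over the ordering cohort, descending; ties by ascending
    gene ID.  The assignment must cover exactly the scaler's gene set.
    """
    genes = assignment.genes
    if set(genes) != set(scaler.gene_ids):
        raise ValueError("assignment must cover exactly the selected (scaler) genes")
    missing = [g for g in genes if g not in mean_expression]
    if missing:
        raise ValueError(f"mean expression missing for genes: {missing[:5]}")
    group_pos = {g: i for i, g in enumerate(assignment.group_order)}
    ordered = sorted(
        genes,
        key=lambda g: (
            group_pos[assignment.gene_to_group[g]],
            -float(mean_expression[g]),
            g,
        ),
    )
    side = math.ceil(math.sqrt(len(ordered)))
    boundaries: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(ordered) + 1):
        if (
            i == len(ordered)
            or assignment.gene_to_group[ordered[i]]
            != assignment.gene_to_group[ordered[start]]
        ):
            boundaries.append((assignment.gene_to_group[ordered[start]], start, i))
            start = i
    return GeneImageLayout(ordered, side, scaler, boundaries)


def _scale_vector(layout: GeneImageLayout, vector: Mapping[str, float]) -> np.ndarray:
    missing = [g for g in layout.ordered_genes if g not in vector]
    if missing:
        raise KeyError(f"missing gene values: {missing[:5]}")
    pos = {g: i for i, g in enumerate(layout.scaler.gene_ids)}
    values = np.empty(layout.n_genes)
    for i, g in enumerate(layout.ordered_genes):
        j = pos[g]
        lo, hi = layout.scaler.x_min[j], layout.scaler.x_max[j]
        if hi > lo:
            values[i] = min(max((float(vector[g]) - lo) / (hi - lo), 0.0), 1.0)
        else:
            values[i] = 0.0
    return values


def render_image(layout: GeneImageLayout, vector: Mapping[str, float], sample_id: str = "") -> GeneImage:
    """Render one sample: pixel (r, c) holds ordered gene r*side + c, pad 0."""
    values = _scale_vector(layout, vector)
    grid = np.zeros(layout.side * layout.side)
    grid[: layout.n_genes] = values
    return GeneImage(grid.reshape(layout.side, layout.side), sample_id)


def render_images(layout: GeneImageLayout, m: ExpressionMatrix) -> np.ndarray:
    """Render all samples of a matrix at once -> (n_samples, side, side)."""
    sub = m.subset_genes(layout.ordered_genes)
    scaler_in_order = MinMaxScaler(
        layout.ordered_genes,
        layout.scaler.x_min[
            [layout.scaler.gene_ids.index(g) for g in layout.ordered_genes]
        ],
        layout.scaler.x_max[
            [layout.scaler.gene_ids.index(g) for g in layout.ordered_genes]
        ],
    )
    scaled = apply_minmax(scaler_in_order, sub)  # genes x samples, ordered
    n = m.n_samples
    grid = np.zeros((layout.side * layout.side, n))
    grid[: layout.n_genes] = scaled
    return grid.T.reshape(n, layout.side, layout.side)


def save_png(image: GeneImage, path: str | Path) -> None:
    """Lossless grayscale export for inspection: pixel = round(255 * value)."""
    from PIL import Image

    arr = np.round(255 * image.pixels).astype("uint8")
    Image.fromarray(arr, mode="L").save(path)
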