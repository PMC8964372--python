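"""Expression and clinical cohort handling.

Loads the genes-by-samples expression table and the per-sample clinical
table, derives the binary long-term survival label (death within a 60-month
overall-survival horizon vs survival beyond it), encodes the ordinal AJCC
stage covariate, and intersects gene universes across cohorts.

Labeling rule (horizon ``h`` in months):

* ``os_time > h``                      -> label 0 (long-term survivor)
* ``os_time <= h`` and ``os_event = 1`` -> label 1 (died within horizon)
* ``os_time <= h`` and ``os_event = 0`` -> EXCLUDED (censored too early to label)

Samples missing age, stage, survival fields, or an expression column are
likewise excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUDED",
    "STAGE_CODES",
    "ExpressionMatrix",
    "ClinicalRecord",
    "LabeledCohort",
    "load_expression",
    "load_clinical",
    "derive_label",
    "encode_stage",
    "intersect_genes",
    "build_labeled_cohort",
]

#: Sentinel label for samples that cannot be assigned a 60-month outcome.
EXCLUDED = "EXCLUDED"

#: Ordinal AJCC stage codes: +5 per stage group across the 7-group ladder.
STAGE_CODES: dict[str, int] = {
    "i": 5,
    "ia": 5,
    "ib": 10,
    "ii": 15,
    "iia": 15,
    "iib": 20,
    "iii": 25,
    "iiia": 25,
    "iiib": 30,
    "iv": 35,
}

CLINICAL_COLUMNS = ("sample_id", "age", "stage", "os_time", "os_event")


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix with aligned identifier lists."""

    values: np.ndarray  # shape (n_genes, n_samples)
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(self.values[rows], list(genes), self.sample_ids)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(self.values[:, cols], self.gene_ids, list(samples))

    def sample_vector(self, sample_id: str) -> dict[str, float]:
        j = self.sample_ids.index(sample_id)
        return dict(zip(self.gene_ids, self.values[:, j]))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Load a genes-as-rows TSV: first column gene IDs, header row sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression table")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene IDs {dupes[:5]}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[~df[col].apply(lambda v: isinstance(v, (int, float)))]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row!r}")
    return ExpressionMatrix.from_frame(df.astype(float))


@dataclass
class ClinicalRecord:
    sample_id: str
    age_at_diagnosis: float  # years
    stage_label: str
    os_time: float  # months
    os_event: int  # 1 = death observed

    def __post_init__(self):
        if self.os_event not in (0, 1):
            raise ValueError(f"os_event must be 0 or 1, got {self.os_event}")
        if self.os_time < 0:
            raise ValueError(f"os_time must be >= 0, got {self.os_time}")


def load_clinical(path: str | Path) -> pd.DataFrame:
    """Load the clinical table (TSV or CSV) with the required columns.

    Required columns: sample_id, age, stage, os_time, os_event.  Missing age
    or stage values are preserved as NaN/empty and lead to exclusion during
    labeling, not to a load error.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "stage": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing clinical columns {missing}")
    return df


def derive_label(
    record: ClinicalRecord | None = None,
    horizon: float = 60.0,
    *,
    os_time: float | None = None,
    os_event: int | None = None,
):
    """Binary 60-month outcome for one sample: 0, 1, or ``EXCLUDED``.

    Accepts either a :class:`ClinicalRecord` or explicit ``os_time`` /
    ``os_event`` keywords.
    """
    if record is not None:
        os_time, os_event = record.os_time, record.os_event
    if os_time is None or os_event is None:
        raise ValueError("need a record or os_time and os_event")
    if os_time > horizon:
        return 0
    if os_event == 1:
        return 1
    return EXCLUDED


def encode_stage(stage_label: str) -> int:
    """Ordinal code for an AJCC stage label: +5 per stage group.

    ``Stage I`` -> 5, ``Stage IB`` -> 10, ... ``Stage IV`` -> 35.  Stage
    groups (I|IA), IB, (II|IIA), IIB, (III|IIIA), IIIB, IV share codes within
    a group.  Case-insensitive; a leading "Stage " prefix is tolerated.
    """
    if not isinstance(stage_label, str):
        raise ValueError(f"stage label must be text, got {stage_label!r}")
    key = stage_label.strip().lower()
    if key.startswith("stage"):
        key = key[len("stage"):].strip()
    if key not in STAGE_CODES:
        accepted = sorted(set(STAGE_CODES), key=lambda s: (STAGE_CODES[s], s))
        raise ValueError(
            f"unrecognized stage label {stage_label!r}; accepted (with or without "
            f"'Stage ' prefix): {accepted}"
        )
    return STAGE_CODES[key]


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the shared gene set, in ``a``'s gene order."""
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not shared:
        raise ValueError("gene intersection is empty")
    return a.subset_genes(shared), b.subset_genes(shared)


@dataclass
class LabeledCohort:
    """Expression + clinical records + derived labels for one cohort."""

    expression: ExpressionMatrix
    clinical: list[ClinicalRecord]
    labels: dict[str, int]  # sample_id -> {0, 1}
    excluded: list[str]

    def __post_init__(self):
        clinical_ids = {r.sample_id for r in self.clinical}
        if set(self.labels) | set(self.excluded) != clinical_ids:
            raise ValueError("labels and excluded must partition the clinical samples")
        expr_ids = set(self.expression.sample_ids)
        missing = [s for s in self.labels if s not in expr_ids]
        if missing:
            raise ValueError(f"labeled samples without expression: {missing[:5]}")

    @property
    def labeled_sample_ids(self) -> list[str]:
        return [s for s in self.expression.sample_ids if s in self.labels]

    def label_array(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.labeled_sample_ids if sample_ids is None else sample_ids
        return np.array([self.labels[s] for s in ids], dtype=int)

    def clinical_matrix(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """(n, 2) array of [age, stage code] per sample."""
        ids = self.labeled_sample_ids if sample_ids is None else sample_ids
        rec = {r.sample_id: r for r in self.clinical}
        return np.array(
            [
                [rec[s].age_at_diagnosis, encode_stage(rec[s].stage_label)]
                for s in ids
            ],
            dtype=float,
        )

    def survival_arrays(
        self, sample_ids: Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Full follow-up (times, events) for the given samples."""
        rec = {r.sample_id: r for r in self.clinical}
        times = np.array([rec[s].os_time for s in sample_ids], dtype=float)
        events = np.array([rec[s].os_event for s in sample_ids], dtype=int)
        return times, events

    def write_labels_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.labels), "label": list(self.labels.values())}
        ).to_csv(path, sep="\t", index=False)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and not value.strip():
        return True
    return False


def build_labeled_cohort(
    expression: ExpressionMatrix,
    clinical: pd.DataFrame,
    horizon: float = 60.0,
) -> LabeledCohort:
    """Derive labels and assemble a :class:`LabeledCohort`.

    Exclusions: censored before the horizon; missing age/stage/survival
    fields; unrecognized stage label; no expression column for the sample.
    """
    records: list[ClinicalRecord] = []
    labels: dict[str, int] = {}
    excluded: list[str] = []
    expr_ids = set(expression.sample_ids)
    for row in clinical.itertuples(index=False):
        sid = str(row.sample_id)
        if any(
            _is_missing(v)
            for v in (row.age, row.stage, row.os_time, row.os_event)
        ):
            records.append(
                ClinicalRecord(sid, 0.0, "", 0.0, 0)
            )
            excluded.append(sid)
            continue
        rec = ClinicalRecord(
            sid, float(row.age), str(row.stage), float(row.os_time), int(row.os_event)
        )
        records.append(rec)
        label = derive_label(rec, horizon)
        if label == EXCLUDED or sid not in expr_ids:
            excluded.append(sid)
            continue
        try:
            encode_stage(rec.stage_label)
        except ValueError:
            excluded.append(sid)
            continue
        labels[sid] = label
    return LabeledCohort(expression, records, labels, excluded)
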