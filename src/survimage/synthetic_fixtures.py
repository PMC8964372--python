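"""Synthetic cohorts and annotation fixtures.

Generates every input the pipeline consumes — a log-scale expression matrix
with planted outcome-associated genes, censored survival times with
class-dependent exponential hazards, clinical covariates (age, AJCC stage)
with mild outcome association, a small annotation hierarchy in the flat-text
dialect the real parser reads, a three-namespace gene ID mapping chain, and
a pathway-membership table — so the whole method is testable without any
download.

The survival generator draws a latent risk class (high with probability
``p_high``), an exponential survival time whose median is ~20 months for
high-risk and ~240 months for low-risk samples, and uniform censoring on a
``censor_rate`` fraction of samples; with the defaults the labeled cohort
lands near the 74/26 died-within-horizon vs long-term-survivor imbalance of
a typical lung-cancer cohort.  Signal genes receive a mean shift of
``effect_size`` baseline standard deviations between outcome classes, with
alternating sign across genes; noise genes are pure Gaussian.

Everything is reproducible from ``SimulationSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import (
    AnnotationAssets,
    AnnotationHierarchy,
    GeneIdMap,
    PathwayMembership,
    compose_id_maps,
    parse_hierarchy,
)
from .cohort_data import EXCLUDED, ExpressionMatrix, derive_label

__all__ = [
    "SimulationSpec",
    "SyntheticAnnotation",
    "simulate_cohort",
    "simulate_annotation",
    "write_fixture_files",
    "gene_id",
]

STAGE_LABELS = (
    "Stage IA",
    "Stage IB",
    "Stage IIA",
    "Stage IIB",
    "Stage IIIA",
    "Stage IIIB",
    "Stage IV",
)
# stage sampling weights per outcome class (mild association)
_STAGE_W_SURVIVOR = np.array([0.30, 0.28, 0.14, 0.12, 0.10, 0.04, 0.02])
_STAGE_W_DEAD = np.array([0.14, 0.22, 0.12, 0.17, 0.18, 0.08, 0.09])


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions of the synthetic cohort."""

    n_samples: int = 300
    n_genes: int = 500
    n_signal_genes: int = 20
    effect_size: float = 2.0  # mean shift in baseline-SD units between classes
    baseline_mean: float = 5.0  # log-scale expression level
    baseline_sd: float = 1.0
    n_groups: int = 25
    n_pathways: int = 30
    censor_rate: float = 0.15
    horizon: float = 60.0  # months
    seed: int = 0
    p_high_risk: float = 0.82
    median_survival_high: float = 20.0  # months
    median_survival_low: float = 240.0  # months

    def __post_init__(self):
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes must be <= n_genes")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def gene_id(i: int) -> str:
    """Stable-gene-ID-style identifier shared by cohort and annotation."""
    return f"ENSG{i:011d}"


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, list[str]]:
    """Expression matrix, clinical table and the planted signal-gene list.

    The clinical table has columns sample_id, age, stage, os_time, os_event.
    Samples censored before the horizon carry no label; their expression
    shift uses the latent risk class so the matrix stays fully defined.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [gene_id(i) for i in range(spec.n_genes)]
    signal_idx = np.arange(spec.n_signal_genes)
    signal_genes = [gene_ids[i] for i in signal_idx]

    high = rng.random(n) < spec.p_high_risk
    rate = np.where(
        high,
        np.log(2) / spec.median_survival_high,
        np.log(2) / spec.median_survival_low,
    )
    true_time = rng.exponential(1.0 / rate)
    censored = rng.random(n) < spec.censor_rate
    censor_time = rng.uniform(0, 2 * spec.horizon, size=n)
    os_time = np.where(censored, np.minimum(true_time, censor_time), true_time)
    os_event = np.where(censored & (censor_time < true_time), 0, 1).astype(int)

    labels = np.array(
        [
            derive_label(os_time=t, os_event=e, horizon=spec.horizon)
            for t, e in zip(os_time, os_event)
        ],
        dtype=object,
    )
    # outcome class driving the expression shift; latent class for unlabelable
    shift_class = np.where(
        labels == EXCLUDED, high.astype(int), labels
    ).astype(int)

    values = rng.normal(
        spec.baseline_mean, spec.baseline_sd, size=(spec.n_genes, n)
    )
    signs = np.where(signal_idx % 2 == 0, 1.0, -1.0)
    shift = spec.effect_size * spec.baseline_sd
    values[signal_idx, :] += (
        signs[:, None] * shift * shift_class[None, :]
    )

    age = np.clip(
        rng.normal(67.0, 9.0, size=n) + 1.5 * shift_class, 30, 90
    ).round(1)
    stage = np.array(
        [
            rng.choice(
                STAGE_LABELS,
                p=(_STAGE_W_DEAD if c == 1 else _STAGE_W_SURVIVOR)
                / (_STAGE_W_DEAD if c == 1 else _STAGE_W_SURVIVOR).sum(),
            )
            for c in shift_class
        ]
    )

    expression = ExpressionMatrix(values, gene_ids, sample_ids)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": age,
            "stage": stage,
            "os_time": np.round(os_time, 2),
            "os_event": os_event,
        }
    )
    return expression, clinical, signal_genes


@dataclass
class SyntheticAnnotation:
    """Generated annotation fixtures plus their on-disk text forms."""

    hierarchy: AnnotationHierarchy
    pathways: PathwayMembership
    id_maps: list[GeneIdMap]  # annotation -> kegg -> symbol -> stable gene ID
    brite_text: str

    def assets(self) -> AnnotationAssets:
        return AnnotationAssets(
            hierarchy=self.hierarchy,
            annotation_to_gene=compose_id_maps(self.id_maps),
            pathways=self.pathways,
        )


def simulate_annotation(
    n_genes: int,
    n_groups: int = 25,
    n_pathways: int = 30,
    seed: int = 0,
) -> SyntheticAnnotation:
    """Hierarchy, pathway table and a three-namespace ID chain.

    Every gene appears in at least one hierarchy leaf subclass; ~10% of
    genes get a second annotation ID in another subclass (exercising the
    first-occurrence assignment rule through ID-map fan-in); ~20% of genes
    belong to two or more pathways and ~10% to none.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [gene_id(i) for i in range(n_genes)]

    # ID chain: annotation (brite) -> organism gene -> symbol -> stable ID
    kegg_ids = [f"hsa:{10000 + i}" for i in range(n_genes)]
    symbols = [f"GENE{i}" for i in range(n_genes)]
    primary_brite = [f"K{i:05d}" for i in range(n_genes)]

    group_of_gene = rng.integers(0, n_groups, size=n_genes)
    # ensure no empty subclass when possible
    for g in range(min(n_groups, n_genes)):
        group_of_gene[g] = g
    members: dict[int, list[str]] = {g: [] for g in range(n_groups)}
    brite_pairs: list[tuple[str, str]] = []
    for i in range(n_genes):
        members[group_of_gene[i]].append(primary_brite[i])
        brite_pairs.append((primary_brite[i], kegg_ids[i]))
    extra_count = 0
    for i in range(n_genes):
        if rng.random() < 0.10 and n_groups > 1:
            other = int(rng.integers(0, n_groups))
            if other == group_of_gene[i]:
                other = (other + 1) % n_groups
            extra = f"K9{extra_count:04d}"
            extra_count += 1
            members[other].append(extra)
            brite_pairs.append((extra, kegg_ids[i]))

    n_branches = max(1, min(3, n_groups))
    lines = ["A  Genes and Proteins"]
    for b in range(n_branches):
        lines.append(f"B  Branch {b + 1:02d}")
        for g in range(b, n_groups, n_branches):
            lines.append(f"C  Subclass {g + 1:02d}")
            for ann in members[g]:
                lines.append(f"D  {ann}  annotation {ann}")
    brite_text = "\n".join(lines) + "\n"
    hierarchy = parse_hierarchy(brite_text)

    id_maps = [
        GeneIdMap(frozenset(brite_pairs), "brite", "kegg"),
        GeneIdMap(frozenset(zip(kegg_ids, symbols)), "kegg", "symbol"),
        GeneIdMap(frozenset(zip(symbols, genes)), "symbol", "ensembl"),
    ]

    pathway_ids = [f"hsa{(j + 1) * 10:05d}" for j in range(n_pathways)]
    entries: set[tuple[str, str]] = set()
    for i, g in enumerate(genes):
        r = rng.random()
        if r < 0.10:
            continue  # pathway-less gene
        n_member = 2 + int(rng.integers(0, 2)) if r < 0.30 else 1
        for p in rng.choice(n_pathways, size=min(n_member, n_pathways), replace=False):
            entries.add((pathway_ids[int(p)], g))
    labels = {pid: f"pathway {pid}" for pid in pathway_ids}
    pathways = PathwayMembership(frozenset(entries), labels)

    return SyntheticAnnotation(hierarchy, pathways, id_maps, brite_text)


def write_fixture_files(outdir: str | Path, spec: SimulationSpec) -> dict[str, Path]:
    """Write all fixtures in the exact dialects the real parsers read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expression, clinical, signal = simulate_cohort(spec)
    annotation = simulate_annotation(
        spec.n_genes, spec.n_groups, spec.n_pathways, seed=spec.seed
    )
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "brite": outdir / "brite.txt",
        "map_brite_kegg": outdir / "map_brite_to_kegg.tsv",
        "map_kegg_symbol": outdir / "map_kegg_to_symbol.tsv",
        "map_symbol_gene": outdir / "map_symbol_to_gene.tsv",
        "pathways": outdir / "pathways.tsv",
        "signal_genes": outdir / "signal_genes.txt",
    }
    expression.write_tsv(paths["expression"])
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    paths["brite"].write_text(annotation.brite_text)
    for key, id_map in zip(
        ("map_brite_kegg", "map_kegg_symbol", "map_symbol_gene"), annotation.id_maps
    ):
        pd.DataFrame(sorted(id_map.pairs)).to_csv(
            paths[key], sep="\t", header=False, index=False
        )
    pd.DataFrame(
        sorted(
            (pid, gid, annotation.pathways.pathway_labels[pid])
            for pid, gid in annotation.pathways.entries
        )
    ).to_csv(paths["pathways"], sep="\t", header=False, index=False)
    paths["signal_genes"].write_text("\n".join(signal) + "\n")
    return paths
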