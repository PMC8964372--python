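"""Functional-annotation inputs for gene-image construction.

Three kinds of annotation are consumed:

* a hierarchical gene-function classification distributed as an indented
  flat-text file whose lines begin with single-letter depth prefixes
  (``A`` root section, ``B``/``C``/... nested subclasses, deepest lines
  carrying annotation IDs) — the KEGG BRITE dialect;
* chains of two-column gene ID mapping tables (annotation ID -> organism
  gene ID -> gene symbol -> stable gene ID) that bridge annotation IDs to
  the identifiers used in the expression matrix;
* a pathway-membership table (pathway ID -> gene ID, optional label).

The output of this module is a :class:`GeneGroupAssignment`: a deterministic
mapping of every gene to exactly one ordered annotation group.  Group order
and within-group membership drive the multi-index sorting that gives the
2-D gene expression image its spatial structure.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "UNASSIGNED_GROUP",
    "AnnotationParseError",
    "HierarchyNode",
    "AnnotationHierarchy",
    "GeneIdMap",
    "PathwayMembership",
    "GeneGroupAssignment",
    "AnnotationAssets",
    "parse_hierarchy",
    "format_hierarchy",
    "compose_id_maps",
    "assign_groups_from_hierarchy",
    "assign_groups_from_pathways",
]

#: Reserved group ID for genes without any annotation; always last in group_order.
UNASSIGNED_GROUP = "UNASSIGNED"

_TAG_RE = re.compile(r"<[^>]+>")
_DECORATION_PREFIXES = ("#", "!", "+", "%", "<")


class AnnotationParseError(ValueError):
    """Structured parse failure carrying the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass
class HierarchyNode:
    """One node of the annotation hierarchy.

    ``annotation_id`` is set only on leaves (deepest lines), where the line
    content is split on the first whitespace run into ID and label.
    """

    depth: int
    label: str
    annotation_id: str | None = None
    children: list["HierarchyNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class AnnotationHierarchy:
    root: HierarchyNode

    @property
    def root_label(self) -> str:
        return self.root.label

    def iter_leaves(self) -> Iterator[HierarchyNode]:
        """Depth-first (file-order) enumeration of leaves, excluding the root."""

        def walk(node: HierarchyNode) -> Iterator[HierarchyNode]:
            for child in node.children:
                if child.is_leaf:
                    yield child
                else:
                    yield from walk(child)

        return walk(self.root)

    def leaf_annotation_ids(self) -> list[str]:
        return [leaf.annotation_id for leaf in self.iter_leaves()]

    def leaf_subclasses(self) -> list[tuple[str, list[str]]]:
        """Leaf-level subclasses in depth-first file order.

        A subclass is an internal node with at least one leaf child; it is
        the unit of grouping for image construction.  Returns
        ``(subclass label, [annotation IDs of its leaf children])`` pairs.
        Duplicate subclass labels are disambiguated with ``#2``, ``#3``, ...
        suffixes so group IDs stay unique.
        """
        groups: list[tuple[str, list[str]]] = []
        seen: dict[str, int] = {}

        def walk(node: HierarchyNode) -> None:
            leaf_ids = [c.annotation_id for c in node.children if c.is_leaf]
            if leaf_ids:
                count = seen.get(node.label, 0)
                seen[node.label] = count + 1
                label = node.label if count == 0 else f"{node.label}#{count + 1}"
                groups.append((label, leaf_ids))
            for child in node.children:
                if not child.is_leaf:
                    walk(child)

        walk(self.root)
        return groups


def parse_hierarchy(flat_text: str) -> AnnotationHierarchy:
    """Parse indented flat-text annotation into an :class:`AnnotationHierarchy`.

    Lines start with an uppercase level letter (``A`` = root, ``B`` one level
    deeper, ...).  Sibling order follows file order.  The deepest lines are
    leaves; their content is split on the first whitespace run into
    ``(annotation ID, label)``.  Decoration lines (``#``, ``!``, ``+``, ``%``
    or markup) are skipped with a warning; inline markup tags are stripped.

    Raises
    ------
    AnnotationParseError
        On empty input, a line nested deeper than its parent's depth + 1,
        multiple root sections, or duplicate leaf annotation IDs.
    """
    entries: list[tuple[int, int, str]] = []  # (line number, depth, content)
    for lineno, raw in enumerate(flat_text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        head = line[0]
        if head in _DECORATION_PREFIXES or not head.isupper() or not head.isalpha():
            warnings.warn(
                f"skipping decoration line {lineno}: {line[:40]!r}", stacklevel=2
            )
            continue
        depth = ord(head) - ord("A")
        content = _TAG_RE.sub("", line[1:]).strip()
        entries.append((lineno, depth, content))

    if not entries:
        raise AnnotationParseError("empty annotation text")

    first_lineno, first_depth, first_content = entries[0]
    if first_depth != 0:
        raise AnnotationParseError(
            f"first entry must be at level A, got level {chr(first_depth + ord('A'))}",
            first_lineno,
        )
    root = HierarchyNode(depth=0, label=first_content)
    stack = [root]
    for lineno, depth, content in entries[1:]:
        if depth == 0:
            raise AnnotationParseError(
                "multiple root (level A) sections; extract one section first", lineno
            )
        if depth > stack[-1].depth + 1:
            raise AnnotationParseError(
                f"level jump: depth {depth} under parent at depth {stack[-1].depth}",
                lineno,
            )
        while stack[-1].depth >= depth:
            stack.pop()
        node = HierarchyNode(depth=depth, label=content)
        stack[-1].children.append(node)
        stack.append(node)

    hierarchy = AnnotationHierarchy(root=root)
    seen_ids: set[str] = set()
    for leaf in hierarchy.iter_leaves():
        parts = re.split(r"\s+", leaf.label, maxsplit=1)
        leaf.annotation_id = parts[0]
        leaf.label = parts[1] if len(parts) > 1 else ""
        if leaf.annotation_id in seen_ids:
            raise AnnotationParseError(
                f"duplicate leaf annotation ID {leaf.annotation_id!r}"
            )
        seen_ids.add(leaf.annotation_id)
    return hierarchy


def format_hierarchy(h: AnnotationHierarchy) -> str:
    """Serialize a hierarchy back to the flat-text dialect (round-trip safe)."""
    lines: list[str] = []

    def walk(node: HierarchyNode) -> None:
        letter = chr(node.depth + ord("A"))
        if node.is_leaf and node.annotation_id is not None:
            content = f"{node.annotation_id}  {node.label}".rstrip()
        else:
            content = node.label
        lines.append(f"{letter}  {content}" if content else letter)
        for child in node.children:
            walk(child)

    walk(h.root)
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class GeneIdMap:
    """A binary relation between two gene-identifier namespaces."""

    pairs: frozenset[tuple[str, str]]
    source_namespace: str
    target_namespace: str

    def __post_init__(self):
        if not self.source_namespace or not self.target_namespace:
            raise ValueError("namespaces must be non-empty")
        object.__setattr__(self, "pairs", frozenset(self.pairs))

    @classmethod
    def read_tsv(
        cls, path: str | Path, source_namespace: str, target_namespace: str
    ) -> "GeneIdMap":
        """Read a headerless two-column TSV of (source ID, target ID) pairs."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
        pairs = frozenset(zip(df.iloc[:, 0], df.iloc[:, 1]))
        return cls(pairs, source_namespace, target_namespace)

    def targets_of(self, source_id: str) -> list[str]:
        return sorted(t for s, t in self.pairs if s == source_id)

    def as_dict(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, t in sorted(self.pairs):
            out.setdefault(s, []).append(t)
        return out


def compose_id_maps(maps: Sequence[GeneIdMap]) -> GeneIdMap:
    """Relation composition of a chain of ID maps.

    One-to-many fan-out is preserved: if ``a`` maps to both ``b1`` and ``b2``
    and each maps onward, all reachable endpoints are kept as pairs.
    Adjacent namespaces must match.
    """
    if not maps:
        raise ValueError("need at least one map to compose")
    result = maps[0]
    for nxt in maps[1:]:
        if result.target_namespace != nxt.source_namespace:
            raise ValueError(
                "namespace mismatch in composition: "
                f"{result.target_namespace!r} != {nxt.source_namespace!r}"
            )
        forward: dict[str, list[str]] = {}
        for s, t in nxt.pairs:
            forward.setdefault(s, []).append(t)
        composed = frozenset(
            (a, c) for a, b in result.pairs for c in forward.get(b, ())
        )
        result = GeneIdMap(composed, result.source_namespace, nxt.target_namespace)
    return result


@dataclass(frozen=True)
class PathwayMembership:
    """Pathway -> gene membership; a gene may occur in many pathways."""

    entries: frozenset[tuple[str, str]]
    pathway_labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "entries", frozenset(self.entries))
        labels = dict(self.pathway_labels)
        for pid, _ in self.entries:
            labels.setdefault(pid, "")
        object.__setattr__(self, "pathway_labels", labels)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PathwayMembership":
        """Read a TSV of (pathway ID, gene ID[, pathway label]) rows, no header."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected at least two columns")
        entries = frozenset(zip(df.iloc[:, 0], df.iloc[:, 1]))
        labels: dict[str, str] = {}
        if df.shape[1] >= 3:
            for pid, lab in zip(df.iloc[:, 0], df.iloc[:, 2]):
                if isinstance(lab, str):
                    labels[pid] = lab
        return cls(entries, labels)

    def genes_of(self, pathway_id: str) -> list[str]:
        return sorted(g for p, g in self.entries if p == pathway_id)


@dataclass
class GeneGroupAssignment:
    """Each gene assigned to exactly one group; groups carry a fixed order."""

    group_order: list[str]
    gene_to_group: dict[str, str]
    unassigned_group_id: str = UNASSIGNED_GROUP

    def __post_init__(self):
        groups_used = set(self.gene_to_group.values())
        missing = groups_used - set(self.group_order)
        if missing:
            raise ValueError(f"groups used but absent from group_order: {missing}")
        if (
            self.unassigned_group_id in self.group_order
            and self.group_order[-1] != self.unassigned_group_id
        ):
            raise ValueError("unassigned group must be last in group_order")

    @property
    def genes(self) -> list[str]:
        return list(self.gene_to_group)

    def members(self, group_id: str) -> list[str]:
        return [g for g, grp in self.gene_to_group.items() if grp == group_id]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group_order": self.group_order,
            "gene_to_group": self.gene_to_group,
            "unassigned_group_id": self.unassigned_group_id,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneGroupAssignment":
        payload = json.loads(Path(path).read_text())
        return cls(
            payload["group_order"],
            payload["gene_to_group"],
            payload.get("unassigned_group_id", UNASSIGNED_GROUP),
        )


def assign_groups_from_hierarchy(
    h: AnnotationHierarchy, id_map: GeneIdMap, genes: Sequence[str]
) -> GeneGroupAssignment:
    """Assign genes to leaf-level hierarchy subclasses.

    Group order is the depth-first (file) order of subclasses.  Each gene is
    mapped through ``id_map`` (annotation ID -> gene ID) and assigned to the
    FIRST subclass containing it in that order; a gene reachable from no
    annotation ID goes to the trailing unassigned group.  Empty groups are
    dropped.  Unmapped genes are not an error.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    gene_set = set(genes)
    ann_to_genes = id_map.as_dict()

    gene_to_group: dict[str, str] = {}
    group_order: list[str] = []
    for group_label, ann_ids in h.leaf_subclasses():
        members: list[str] = []
        for ann_id in ann_ids:
            for gid in ann_to_genes.get(ann_id, ()):
                if gid in gene_set and gid not in gene_to_group:
                    members.append(gid)
        if members:
            group_order.append(group_label)
            for gid in members:
                gene_to_group[gid] = group_label

    unassigned = [g for g in genes if g not in gene_to_group]
    if unassigned:
        group_order.append(UNASSIGNED_GROUP)
        for gid in unassigned:
            gene_to_group[gid] = UNASSIGNED_GROUP
    # preserve input gene iteration order in the mapping
    ordered = {g: gene_to_group[g] for g in genes}
    return GeneGroupAssignment(group_order, ordered)


def assign_groups_from_pathways(
    p: PathwayMembership, genes: Sequence[str]
) -> GeneGroupAssignment:
    """Assign genes to pathways, ordered by ascending pathway ID.

    A gene belonging to several pathways goes to the one with the smallest
    pathway ID; pathway-less genes go to the trailing unassigned group.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    gene_set = set(genes)
    gene_pathways: dict[str, list[str]] = {}
    for pid, gid in p.entries:
        if gid in gene_set:
            gene_pathways.setdefault(gid, []).append(pid)

    gene_to_group: dict[str, str] = {}
    for gid in genes:
        pids = gene_pathways.get(gid)
        gene_to_group[gid] = min(pids) if pids else UNASSIGNED_GROUP

    used = set(gene_to_group.values())
    group_order = sorted(used - {UNASSIGNED_GROUP})
    if UNASSIGNED_GROUP in used:
        group_order.append(UNASSIGNED_GROUP)
    return GeneGroupAssignment(group_order, gene_to_group)


@dataclass
class AnnotationAssets:
    """Bundle of fitted annotation inputs used by the evaluation pipeline."""

    hierarchy: AnnotationHierarchy
    annotation_to_gene: GeneIdMap  # composed chain, annotation ID -> expression gene ID
    pathways: PathwayMembership
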