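"""Pseudotime stage binning and stage-to-stage chromatin dynamics.

Cells arrive with a pseudotime in [0, 1] and a lineage label (from an
external trajectory tool or the synthetic generator); this module bins
them into developmental stages along a rooted stage tree, then calls
differentially accessible peaks between each stage and its ancestor
(opening vs closing) and between sibling branches, using the same
one-sided Fisher + Benjamini-Hochberg machinery as the cell-type
specificity caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StageGraph:
    """Rooted tree of developmental stages (ancestor -> descendant edges)."""

    edges: tuple[tuple[str, str], ...]
    lineages: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def validate(self) -> None:
        children: dict[str, list[str]] = {}
        parent: dict[str, str] = {}
        for u, v in self.edges:
            children.setdefault(u, []).append(v)
            if v in parent:
                raise ValueError(f"stage {v} has more than one ancestor")
            parent[v] = u
        nodes = self.nodes()
        roots = [n for n in nodes if n not in parent]
        if len(roots) != 1:
            raise ValueError(f"stage graph must have exactly one root, got {roots}")
        # cycle check via DFS from root
        seen: set[str] = set()
        stack = [roots[0]]
        while stack:
            n = stack.pop()
            if n in seen:
                raise ValueError("stage graph contains a cycle")
            seen.add(n)
            stack.extend(children.get(n, []))
        if seen != set(nodes):
            raise ValueError("stage graph is not connected")

    def nodes(self) -> list[str]:
        out: list[str] = []
        for u, v in self.edges:
            for n in (u, v):
                if n not in out:
                    out.append(n)
        return out

    @property
    def root(self) -> str:
        has_parent = {v for _, v in self.edges}
        for n in self.nodes():
            if n not in has_parent:
                return n
        raise ValueError("no root found")

    def parent_of(self, stage: str) -> str | None:
        for u, v in self.edges:
            if v == stage:
                return u
        return None

    def children_of(self, stage: str) -> list[str]:
        return [v for u, v in self.edges if u == stage]

    def subtree(self, stage: str) -> set[str]:
        out = {stage}
        stack = [stage]
        while stack:
            for c in self.children_of(stack.pop()):
                out.add(c)
                stack.append(c)
        return out

    def depths(self) -> dict[str, int]:
        d = {self.root: 0}
        stack = [self.root]
        while stack:
            n = stack.pop()
            for c in self.children_of(n):
                d[c] = d[n] + 1
                stack.append(c)
        return d

    def topological_order(self) -> list[str]:
        order: list[str] = []
        stack = [self.root]
        while stack:
            n = stack.pop(0)
            order.append(n)
            stack.extend(self.children_of(n))
        return order

    def lineage_of(self, stage: str) -> str:
        for lin, stages in self.lineages:
            if stage in stages:
                return lin
        return stage

    def stages_per_lineage(self) -> dict[str, list[str]]:
        return {lin: list(stages) for lin, stages in self.lineages}


def default_kidney_graph() -> StageGraph:
    """The 15-stage nephron differentiation tree.

    Nephron progenitors (NP0-3) give rise to podocytes (Podo1-3) and to
    an intermediate stage (IM1-2) that splits into proximal tubule
    (PT1-3) and the loop of Henle / distal tubule arm (LOH1-2 -> DCT).
    """
    edges = (
        ("NP0", "NP1"), ("NP1", "NP2"), ("NP2", "NP3"),
        ("NP3", "Podo1"), ("Podo1", "Podo2"), ("Podo2", "Podo3"),
        ("NP3", "IM1"), ("IM1", "IM2"),
        ("IM2", "PT1"), ("PT1", "PT2"), ("PT2", "PT3"),
        ("IM2", "LOH1"), ("LOH1", "LOH2"), ("LOH2", "DCT"),
    )
    lineages = (
        ("NP", ("NP0", "NP1", "NP2", "NP3")),
        ("Podo", ("Podo1", "Podo2", "Podo3")),
        ("IM", ("IM1", "IM2")),
        ("PT", ("PT1", "PT2", "PT3")),
        ("LOH", ("LOH1", "LOH2")),
        ("DCT", ("DCT",)),
    )
    return StageGraph(edges, lineages)


# ----------------------------------------------------------------------
# stage binning
# ----------------------------------------------------------------------

@dataclass
class StageAssignment:
    """Barcode -> stage labels plus reported per-lineage stage boundaries."""

    stage: dict[str, str]
    boundaries: dict[str, list[float]] = field(default_factory=dict)

    def to_frame(
        self,
        pseudotime: Mapping[str, float] | None = None,
        lineage: Mapping[str, str] | None = None,
    ) -> pd.DataFrame:
        rows = []
        for bc, st in sorted(self.stage.items()):
            rows.append(
                {
                    "barcode": bc,
                    "stage": st,
                    "lineage": None if lineage is None else lineage[bc],
                    "pseudotime": None if pseudotime is None else pseudotime[bc],
                }
            )
        return pd.DataFrame(rows)


def bin_cells_into_stages(
    pseudotime: Mapping[str, float],
    lineage: Mapping[str, str],
    graph: StageGraph,
    stages_per_lineage: Mapping[str, Sequence[str]] | None = None,
) -> StageAssignment:
    """Split each lineage's cells into equal-count pseudotime bins.

    Each lineage segment is divided into as many stages as it owns in
    the graph; within a lineage, cells are ranked by pseudotime and cut
    into equal-count bins (sizes differ by at most one cell). Boundary
    pseudotimes are reported so alternative binning rules can be
    compared.
    """
    graph.validate()
    per_lineage = dict(stages_per_lineage) if stages_per_lineage else graph.stages_per_lineage()
    if not per_lineage:
        raise ValueError("no stage-per-lineage mapping available")
    n_stages = sum(len(v) for v in per_lineage.values())
    if n_stages != len(graph.nodes()):
        raise ValueError(
            f"stage mapping covers {n_stages} stages but graph has {len(graph.nodes())}"
        )

    assignment: dict[str, str] = {}
    boundaries: dict[str, list[float]] = {}
    cells_by_lineage: dict[str, list[str]] = {}
    for bc in pseudotime:
        cells_by_lineage.setdefault(lineage[bc], []).append(bc)

    for lin, stages in per_lineage.items():
        cells = cells_by_lineage.get(lin, [])
        if len(cells) < len(stages):
            raise ValueError(
                f"lineage {lin} has {len(cells)} cells for {len(stages)} stages"
            )
        cells.sort(key=lambda bc: (pseudotime[bc], bc))
        splits = np.array_split(np.arange(len(cells)), len(stages))
        bounds = []
        for stage_label, idxs in zip(stages, splits):
            for i in idxs:
                assignment[cells[i]] = stage_label
            bounds.append(float(pseudotime[cells[idxs[-1]]]))
        boundaries[lin] = bounds
    return StageAssignment(assignment, boundaries)


# ----------------------------------------------------------------------
# stage-to-stage and branch-vs-branch DAPs
# ----------------------------------------------------------------------

@dataclass
class StageTransitionDap:
    """Opened/closed peaks across one ancestor -> descendant edge."""

    edge: tuple[str, str]
    opened: list[int]
    closed: list[int]
    opened_padj: np.ndarray | None = None
    closed_padj: np.ndarray | None = None


def _directional_daps(
    acc_a: np.ndarray, n_a: int, acc_b: np.ndarray, n_b: int, alpha: float
) -> tuple[list[int], list[int], np.ndarray, np.ndarray]:
    """Two one-sided Fisher screens with BH per direction.

    Returns (enriched_in_b, enriched_in_a, padj_b, padj_a): peaks more
    accessible in group b (opened when b is the descendant) and in a.
    """
    from .dap import bh_adjust, fisher_greater_vec

    p_open = fisher_greater_vec(acc_b, n_b - acc_b, acc_a, n_a - acc_a)
    p_close = fisher_greater_vec(acc_a, n_a - acc_a, acc_b, n_b - acc_b)
    padj_open = bh_adjust(p_open)
    padj_close = bh_adjust(p_close)
    opened = np.flatnonzero(padj_open < alpha)
    closed = np.flatnonzero(padj_close < alpha)
    return list(map(int, opened)), list(map(int, closed)), padj_open, padj_close


def stage_transition_daps(
    matrix,
    assignment: StageAssignment | Mapping[str, str],
    graph: StageGraph,
    alpha: float = 0.05,
) -> list[StageTransitionDap]:
    """DAPs between each stage and its ancestral stage.

    For every edge, each peak is tested in both directions with the
    one-sided Fisher machinery and BH correction per direction across
    peaks: opened = significantly more accessible in the descendant,
    closed = in the ancestor. The root produces no record.
    """
    graph.validate()
    stage_map = assignment.stage if isinstance(assignment, StageAssignment) else dict(assignment)
    acc, sizes = _per_group_accessible(matrix, stage_map)
    out: list[StageTransitionDap] = []
    for u, v in graph.edges:
        for st in (u, v):
            if sizes.get(st, 0) == 0:
                raise ValueError(f"stage {st} has no cells")
        opened, closed, padj_o, padj_c = _directional_daps(
            acc[u], sizes[u], acc[v], sizes[v], alpha
        )
        out.append(StageTransitionDap((u, v), opened, closed, padj_o, padj_c))
    return out


def branch_divergence_daps(
    matrix,
    assignment: StageAssignment | Mapping[str, str],
    branch_a: Iterable[str],
    branch_b: Iterable[str],
    alpha: float = 0.05,
) -> tuple[list[int], list[int]]:
    """Peaks differentially accessible between two pooled descendant branches.

    Returns (enriched_in_a, enriched_in_b). Branch stage sets must be
    disjoint and non-empty.
    """
    a, b = set(branch_a), set(branch_b)
    if not a or not b:
        raise ValueError("branches must be non-empty")
    if a & b:
        raise ValueError(f"branches overlap: {sorted(a & b)}")
    stage_map = assignment.stage if isinstance(assignment, StageAssignment) else dict(assignment)
    pooled = {}
    for bc, st in stage_map.items():
        if st in a:
            pooled[bc] = "branch_a"
        elif st in b:
            pooled[bc] = "branch_b"
    acc, sizes = _per_group_accessible(matrix, pooled)
    if sizes.get("branch_a", 0) == 0 or sizes.get("branch_b", 0) == 0:
        raise ValueError("a branch has no cells in the assignment")
    in_b, in_a, _, _ = _directional_daps(
        acc["branch_a"], sizes["branch_a"], acc["branch_b"], sizes["branch_b"], alpha
    )
    return in_a, in_b


def _per_group_accessible(matrix, groups: Mapping[str, str]):
    """Per-group accessible-cell counts per peak from a binary matrix."""
    bc_index = {bc: i for i, bc in enumerate(matrix.barcodes)}
    acc: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    members: dict[str, list[int]] = {}
    for bc, g in groups.items():
        if bc in bc_index:
            members.setdefault(g, []).append(bc_index[bc])
    X = matrix.X.tocsc() if hasattr(matrix.X, "tocsc") else matrix.X
    for g, rows in members.items():
        sub = X[np.array(rows, dtype=np.int64), :]
        s = np.asarray(sub.sum(axis=0)).ravel()
        acc[g] = s.astype(np.int64)
        sizes[g] = len(rows)
    return acc, sizes
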