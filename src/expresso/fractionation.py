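"""Fractionation of orthogroups into expresso-groups.

Each orthogroup is viewed as a complete weighted bipartite graph: nodes are
its genes (species A on one side, species B on the other), every
interspecific pair carries its Expression Score as edge weight. Removing the
edges whose weight does not exceed the threshold (0.5 by default; a score at
exactly the threshold counts as negative) splits the graph into connected
components — the expresso-groups. A gene left without partners becomes a
singleton expresso-group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .classifier import ESTable
from .core import GenePair, OrthoGroup
from .errors import CoverageError

__all__ = [
    "WeightedBipartiteGraph",
    "ExpressoGroup",
    "FractionationSummary",
    "build_graph",
    "cut_and_components",
    "fractionate",
    "summarize_patterns",
    "groups_to_frame",
]


@dataclass(frozen=True)
class WeightedBipartiteGraph:
    """Complete weighted bipartite graph of one orthogroup."""

    group_id: str
    nodes_a: frozenset[str]
    nodes_b: frozenset[str]
    edges: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a not in self.nodes_a or b not in self.nodes_b:
                raise ValueError(f"edge ({a}, {b}) does not connect A to B")
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"edge weight {w} outside [0, 1]")


@dataclass(frozen=True)
class ExpressoGroup:
    """One connected component after the threshold cut."""

    orthogroup_id: str
    members_a: frozenset[str]
    members_b: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members_a) + len(self.members_b)

    @property
    def is_singleton(self) -> bool:
        return self.size == 1


def build_graph(group: OrthoGroup, es: ESTable | Mapping[GenePair, float]) -> WeightedBipartiteGraph:
    """Attach an ES weight to every interspecific pair of the orthogroup."""
    lookup = es.final_score if isinstance(es, ESTable) else lambda p: es[p]
    edges: dict[tuple[str, str], float] = {}
    missing: list[GenePair] = []
    for pair in group.all_pairs():
        if pair in es:
            edges[(pair.gene_a, pair.gene_b)] = float(lookup(pair))
        else:
            missing.append(pair)
    if missing:
        raise CoverageError(
            f"orthogroup {group.group_id!r} has {len(missing)} unscored pair(s): "
            f"{missing[:5]}"
        )
    return WeightedBipartiteGraph(
        group_id=group.group_id,
        nodes_a=group.genes_a,
        nodes_b=group.genes_b,
        edges=edges,
    )


def cut_and_components(
    graph: WeightedBipartiteGraph, threshold: float = 0.5
) -> list[ExpressoGroup]:
    """Remove edges with weight <= threshold and return connected components.

    Isolated genes come back as singleton expresso-groups; every gene of the
    orthogroup appears in exactly one output group. Nodes are tagged by
    species side so identical gene IDs in both species cannot collide.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    G = nx.Graph()
    G.add_nodes_from(("A", g) for g in graph.nodes_a)
    G.add_nodes_from(("B", g) for g in graph.nodes_b)
    for (a, b), w in graph.edges.items():
        if w > threshold:
            G.add_edge(("A", a), ("B", b))
    out = []
    for comp in nx.connected_components(G):
        out.append(
            ExpressoGroup(
                orthogroup_id=graph.group_id,
                members_a=frozenset(g for side, g in comp if side == "A"),
                members_b=frozenset(g for side, g in comp if side == "B"),
            )
        )
    # deterministic order: by sorted member tuple
    out.sort(key=lambda eg: (sorted(eg.members_a), sorted(eg.members_b)))
    return out


def fractionate(
    groups: Sequence[OrthoGroup],
    es: ESTable | Mapping[GenePair, float],
    threshold: float = 0.5,
) -> dict[str, list[ExpressoGroup]]:
    """Fractionate every orthogroup; mapping orthogroup ID -> its components."""
    return {
        g.group_id: cut_and_components(build_graph(g, es), threshold) for g in groups
    }


@dataclass
class FractionationSummary:
    """Retention patterns and singleton statistics over all orthogroups.

    ``patterns_1x2``/``patterns_1x3`` count, for orthogroups with one gene on
    one side and two (three) co-orthologs on the other, how many co-orthologs
    stayed connected to the single partner. ``retention_1x2``/``retention_1x3``
    are the corresponding fractions of retained co-orthologs.
    """

    n_orthogroups: int
    n_genes: int
    n_singletons: int
    component_size_histogram: dict[int, int]
    patterns_1x2: dict[int, int] = field(default_factory=dict)
    patterns_1x3: dict[int, int] = field(default_factory=dict)

    @property
    def singleton_fraction(self) -> float:
        return self.n_singletons / self.n_genes if self.n_genes else float("nan")

    def _retention(self, patterns: dict[int, int], fan: int) -> float:
        total_groups = sum(patterns.values())
        if total_groups == 0:
            return float("nan")
        retained = sum(k * c for k, c in patterns.items())
        return retained / (fan * total_groups)

    @property
    def retention_1x2(self) -> float:
        return self._retention(self.patterns_1x2, 2)

    @property
    def retention_1x3(self) -> float:
        return self._retention(self.patterns_1x3, 3)


def _retained_count(
    group: OrthoGroup, components: Iterable[ExpressoGroup]
) -> int:
    """For a 1 x n (or n x 1) orthogroup: co-orthologs sharing a component
    with the single partner gene."""
    if len(group.genes_a) == 1:
        single_side, single_gene = "A", next(iter(group.genes_a))
    else:
        single_side, single_gene = "B", next(iter(group.genes_b))
    for comp in components:
        members = comp.members_a if single_side == "A" else comp.members_b
        if single_gene in members:
            partners = comp.members_b if single_side == "A" else comp.members_a
            return len(partners)
    raise ValueError(f"gene {single_gene!r} missing from components")


def summarize_patterns(
    groups: Sequence[OrthoGroup],
    fractionation_result: Mapping[str, Sequence[ExpressoGroup]],
) -> FractionationSummary:
    """Summaries across all fractionated orthogroups.

    Singletons are genes whose expresso-group contains no gene of the other
    species. Pattern counts cover the 1x2 and 1x3 shapes (either orientation).
    """
    size_hist: Counter[int] = Counter()
    n_genes = 0
    n_singletons = 0
    p12: Counter[int] = Counter()
    p13: Counter[int] = Counter()
    for group in groups:
        comps = fractionation_result[group.group_id]
        n_genes += len(group.genes_a) + len(group.genes_b)
        for comp in comps:
            size_hist[comp.size] += 1
            if not comp.members_a or not comp.members_b:
                n_singletons += comp.size
        shape = tuple(sorted(group.shape))
        if shape == (1, 2):
            p12[_retained_count(group, comps)] += 1
        elif shape == (1, 3):
            p13[_retained_count(group, comps)] += 1
    return FractionationSummary(
        n_orthogroups=len(groups),
        n_genes=n_genes,
        n_singletons=n_singletons,
        component_size_histogram=dict(size_hist),
        patterns_1x2=dict(p12),
        patterns_1x3=dict(p13),
    )


def groups_to_frame(
    fractionation_result: Mapping[str, Sequence[ExpressoGroup]],
    species_a: str = "A",
    species_b: str = "B",
) -> pd.DataFrame:
    """Long-format table: orthogroup_id, expresso_group_index, gene, species."""
    rows = []
    for gid in fractionation_result:
        for idx, comp in enumerate(fractionation_result[gid]):
            for g in sorted(comp.members_a):
                rows.append((gid, idx, g, species_a))
            for g in sorted(comp.members_b):
                rows.append((gid, idx, g, species_b))
    return pd.DataFrame(
        rows, columns=["orthogroup_id", "expresso_group_index", "gene", "species"]
    )
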