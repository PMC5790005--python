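"""Condition-specific map construction.

Seed proteins curated for one condition (degeneration-like or
protection-like) are expanded over the background interactome into a
condition map: the induced subgraph on the seeds plus their k-hop
neighbourhood.  Map statistics (node count, average links per node)
mirror the summary numbers such screens report for their maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .types import Interactome, SeedSet

logger = logging.getLogger(__name__)

__all__ = ["ExpansionPolicy", "ConditionMap", "MapStats", "expand_map", "map_stats", "map_overlap"]


@dataclass(frozen=True)
class ExpansionPolicy:
    """How to grow a seed list into a condition map.

    ``k`` — neighbourhood radius in hops over the undirected view (k=0
    keeps only the seeds).  ``min_weight`` — edges below this confidence
    do not contribute to traversal (the induced map keeps all edges).
    ``method`` — ``"khop"`` or ``"shortest_path"`` (union of nodes on
    shortest paths between every seed pair).  ``keep_lwcc`` — prune to
    the largest weakly connected component, always retaining seeds.
    """

    k: int = 1
    min_weight: float | None = None
    method: str = "khop"
    keep_lwcc: bool = True

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.method not in ("khop", "shortest_path"):
            raise ValueError(f"unknown expansion method {self.method!r}")


@dataclass(frozen=True)
class ConditionMap:
    """A condition-specific subnetwork: seeds plus their expansion.

    ``graph`` is exactly the interactome subgraph induced on the map's
    node set (signs and weights preserved).  Seeds missing from the
    interactome are reported in ``missing_seeds``, never silently dropped.
    """

    condition: str
    graph: nx.DiGraph
    seed_nodes: frozenset[str]
    motives: dict[str, tuple[str, ...]] = field(default_factory=dict)
    missing_seeds: tuple[str, ...] = ()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class MapStats:
    n_nodes: int
    n_edges: int
    avg_links_per_node: float
    n_seeds: int
    n_motives: int

    def __str__(self) -> str:  # printed at one decimal, as such maps are reported
        return (
            f"{self.n_nodes} nodes, {self.n_edges} links, "
            f"average links per node {self.avg_links_per_node:.1f}, "
            f"{self.n_seeds} seeds in {self.n_motives} motives"
        )


def _traversal_graph(interactome: Interactome, min_weight: float | None) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(interactome.graph.nodes)
    for u, v, data in interactome.graph.edges(data=True):
        if min_weight is None or data["weight"] >= min_weight:
            g.add_edge(u, v)
    return g


def expand_map(
    interactome: Interactome, seed_set: SeedSet, policy: ExpansionPolicy = ExpansionPolicy()
) -> ConditionMap:
    """Expand a seed set over the interactome into a condition map.

    Raises if no seed is present in the interactome.  The result is the
    interactome subgraph induced on the expanded node set; with
    ``keep_lwcc`` the node set is pruned to the largest weakly connected
    component plus all present seeds.
    """
    present = sorted(seed_set.proteins & set(interactome.graph.nodes))
    missing = tuple(sorted(seed_set.proteins - set(interactome.graph.nodes)))
    if not present:
        raise ValueError(
            f"no seed of condition {seed_set.condition!r} is present in the interactome"
        )
    if missing:
        logger.warning(
            "condition %s: %d seed(s) absent from the interactome: %s",
            seed_set.condition,
            len(missing),
            ", ".join(missing),
        )

    trav = _traversal_graph(interactome, policy.min_weight)
    nodes: set[str] = set(present)
    if policy.method == "khop":
        frontier = set(present)
        for _ in range(policy.k):
            nxt: set[str] = set()
            for n in frontier:
                nxt.update(trav.neighbors(n))
            nxt -= nodes
            nodes |= nxt
            frontier = nxt
            if not frontier:
                break
    else:  # shortest_path closure among seeds
        for i, a in enumerate(present):
            for b in present[i + 1 :]:
                try:
                    nodes.update(nx.shortest_path(trav, a, b))
                except nx.NetworkXNoPath:
                    continue

    sub = interactome.graph.subgraph(nodes)
    if policy.keep_lwcc and sub.number_of_nodes() > 0:
        components = sorted(nx.weakly_connected_components(sub), key=lambda c: (-len(c), sorted(c)))
        keep = set(components[0]) | set(present)
        sub = interactome.graph.subgraph(keep)

    motives: dict[str, tuple[str, ...]] = {}
    for e in seed_set.entries:
        if e.protein in sub:
            motives.setdefault(e.protein, ())
            motives[e.protein] = tuple(sorted(set(motives[e.protein]) | {e.motive}))

    return ConditionMap(
        condition=seed_set.condition,
        graph=nx.DiGraph(sub),
        seed_nodes=frozenset(n for n in present if n in sub),
        motives=motives,
        missing_seeds=missing,
    )


def map_stats(condition_map: ConditionMap) -> MapStats:
    """Node/edge counts and average links per node (undirected collapse).

    Reciprocal directed edges count once, matching the "links per node"
    convention; an empty map yields all-zero stats.
    """
    n = condition_map.graph.number_of_nodes()
    links = {frozenset((u, v)) for u, v in condition_map.graph.edges()}
    e = len(links)
    avg = 2.0 * e / n if n else 0.0
    all_motives = {m for ms in condition_map.motives.values() for m in ms}
    return MapStats(
        n_nodes=n,
        n_edges=e,
        avg_links_per_node=avg,
        n_seeds=len(condition_map.seed_nodes),
        n_motives=len(all_motives),
    )


def map_overlap(map_a: ConditionMap, map_b: ConditionMap) -> int:
    """Number of proteins shared by two condition maps (symmetric)."""
    return len(set(map_a.graph.nodes) & set(map_b.graph.nodes))
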