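"""Anchoring chains into genetic linkage groups and merging the male and
female maps into consensus per-chromosome scaffold orders.

Each chain (super-scaffold) is assigned to the linkage group holding a
qualified majority of its markers, both maps pooled.  Within a linkage
group, each map ranks its chains by mean marker cM and contributes
precedence edges between consecutive ranks; the two maps' constraints are
merged in one directed graph, conflicting edges are removed (weakest
support first), and a topological sort yields the consensus order.  Only
ordinal positions are reported — recombination distances between scaffolds
are not estimated.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .adjacency import Chain
from .errors import CycleError, DataError, InconsistentChainsError
from .formats import LinkageMap

EDGE_KIND_MAP = "map"
EDGE_KIND_CHAIN = "chain_internal"

_MAJORITY_TOL = 1e-9


@dataclass
class Anchoring:
    """Chain -> linkage-group assignment with per-chain marker tallies."""

    placements: dict[str, str] = field(default_factory=dict)
    tallies: dict[str, dict[str, int]] = field(default_factory=dict)
    unplaced: list[tuple[str, str]] = field(default_factory=list)
    chains: dict[str, Chain] = field(default_factory=dict)
    n_skipped_markers: int = 0

    def placed_scaffolds(self) -> set[str]:
        return {
            sid
            for chain_id in self.placements
            for sid in self.chains[chain_id].scaffolds
        }


@dataclass
class ConstraintGraph:
    """Per linkage group, a precedence multigraph on placed chains.

    Edge data: ``kind`` ("map" or "chain_internal"), ``map_id``, ``support``
    (markers backing the edge), ``gap`` (cM).  Node data: ``chain`` and
    ``mean_cm`` (mean marker position over both maps, +inf without markers).
    """

    graphs: dict[str, nx.MultiDiGraph] = field(default_factory=dict)


@dataclass
class ConsensusOrder:
    """Per linkage group, the ordered scaffolds with orientations ("?" when
    no orientation evidence exists, i.e. singleton chains)."""

    orders: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def anchor_chains(
    maps: Sequence[LinkageMap], chains: Sequence[Chain], majority: float = 2 / 3
) -> Anchoring:
    """Assign each chain to a linkage group by qualified marker majority.

    A chain's tally pools both maps over its member scaffolds; it is placed
    on the group holding at least ``majority`` of its markers, otherwise it
    is unplaced ("ambiguous"; "no_markers" when the tally is empty).
    """
    if not (0.5 < majority <= 1.0):
        raise ValueError(f"majority must be in (0.5, 1.0], got {majority}")
    scaffold_chain: dict[str, str] = {}
    chain_index: dict[str, Chain] = {}
    for chain in chains:
        chain_index[chain.id] = chain
        for sid in chain.scaffolds:
            scaffold_chain[sid] = chain.id

    tallies: dict[str, dict[str, int]] = {cid: {} for cid in chain_index}
    n_skipped = 0
    for lmap in maps:
        for entry in lmap.entries:
            chain_id = scaffold_chain.get(entry.scaffold_id)
            if chain_id is None:
                n_skipped += 1
                continue
            tally = tallies[chain_id]
            tally[entry.lg_id] = tally.get(entry.lg_id, 0) + 1

    anchoring = Anchoring(chains=chain_index, n_skipped_markers=n_skipped)
    anchoring.tallies = tallies
    for chain_id in sorted(chain_index):
        tally = tallies[chain_id]
        total = sum(tally.values())
        if total == 0:
            anchoring.unplaced.append((chain_id, "no_markers"))
            continue
        best_lg, best_count = min(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        if best_count / total >= majority - _MAJORITY_TOL:
            anchoring.placements[chain_id] = best_lg
        else:
            anchoring.unplaced.append((chain_id, "ambiguous"))
    return anchoring


# ---------------------------------------------------------------------------
# constraint graph
# ---------------------------------------------------------------------------

def _chain_marker_positions(
    lmap: LinkageMap, chain: Chain, lg_id: str
) -> list[float]:
    members = set(chain.scaffolds)
    return [
        e.position_cm
        for e in lmap.entries
        if e.lg_id == lg_id and e.scaffold_id in members
    ]


def build_constraint_graph(
    anchoring: Anchoring, maps: Sequence[LinkageMap], chains: Sequence[Chain]
) -> ConstraintGraph:
    """Build the per-linkage-group precedence graph from both maps.

    Per map and group, placed chains with at least one marker in that map are
    ranked by mean marker cM; edges run between consecutive *distinct* mean
    values (every chain of the earlier value to every chain of the next).
    Equal means produce no edge.  Edge provenance records the map, the
    smaller of the two chains' marker counts, and the cM gap.
    """
    cg = ConstraintGraph()
    by_lg: dict[str, list[str]] = {}
    for chain_id, lg in anchoring.placements.items():
        by_lg.setdefault(lg, []).append(chain_id)

    for lg, chain_ids in by_lg.items():
        graph = nx.MultiDiGraph()
        for chain_id in sorted(chain_ids):
            chain = anchoring.chains[chain_id]
            positions = [
                p
                for lmap in maps
                for p in _chain_marker_positions(lmap, chain, lg)
            ]
            mean_cm = sum(positions) / len(positions) if positions else math.inf
            graph.add_node(chain_id, chain=chain, mean_cm=mean_cm)
        for lmap in maps:
            ranked: list[tuple[float, int, str]] = []
            for chain_id in sorted(chain_ids):
                positions = _chain_marker_positions(
                    lmap, anchoring.chains[chain_id], lg
                )
                if positions:
                    ranked.append(
                        (sum(positions) / len(positions), len(positions), chain_id)
                    )
            ranked.sort(key=lambda t: (t[0], t[2]))
            groups: list[list[tuple[float, int, str]]] = []
            for item in ranked:
                if groups and math.isclose(
                    groups[-1][0][0], item[0], abs_tol=_MAJORITY_TOL
                ):
                    groups[-1].append(item)
                else:
                    groups.append([item])
            for earlier, later in zip(groups, groups[1:]):
                for mean_u, count_u, u in earlier:
                    for mean_v, count_v, v in later:
                        graph.add_edge(
                            u,
                            v,
                            kind=EDGE_KIND_MAP,
                            map_id=lmap.map_id,
                            support=min(count_u, count_v),
                            gap=mean_v - mean_u,
                        )
        cg.graphs[lg] = graph
    return cg


# ---------------------------------------------------------------------------
# cycle resolution
# ---------------------------------------------------------------------------

def resolve_cycles(
    cg: ConstraintGraph,
) -> tuple[ConstraintGraph, list[dict]]:
    """Remove map edges until every linkage-group graph is acyclic.

    From each cycle found, the removable edge with the lowest supporting
    marker count is dropped (ties: smallest cM gap, then lexicographic
    endpoints).  Chain-internal edges are never removed; a cycle made solely
    of them raises :class:`InconsistentChainsError`.
    """
    resolved = ConstraintGraph(
        graphs={lg: g.copy() for lg, g in cg.graphs.items()}
    )
    removals: list[dict] = []
    for lg in sorted(resolved.graphs):
        graph = resolved.graphs[lg]
        while True:
            try:
                cycle = nx.find_cycle(graph, orientation="original")
            except nx.NetworkXNoCycle:
                break
            removable = [
                (u, v, key)
                for u, v, key, _ in cycle
                if graph.edges[u, v, key].get("kind") != EDGE_KIND_CHAIN
            ]
            if not removable:
                raise InconsistentChainsError(
                    f"{lg}: cycle of chain-internal edges only: "
                    + " -> ".join(u for u, _, _, _ in cycle)
                )
            u, v, key = min(
                removable,
                key=lambda e: (
                    graph.edges[e]["support"],
                    graph.edges[e]["gap"],
                    (e[0], e[1]),
                ),
            )
            data = dict(graph.edges[u, v, key])
            graph.remove_edge(u, v, key)
            removals.append(
                {
                    "lg": lg,
                    "from": u,
                    "to": v,
                    "map_id": data.get("map_id"),
                    "support": data.get("support"),
                    "gap": data.get("gap"),
                }
            )
    return resolved, removals


# ---------------------------------------------------------------------------
# consensus order
# ---------------------------------------------------------------------------

def topological_consensus(cg: ConstraintGraph) -> ConsensusOrder:
    """Kahn-style topological sort per linkage group.

    Among simultaneously available chains, the one with the smallest mean cM
    over both maps is emitted first (ties: lexicographic chain id).  Chains
    are flattened to their member scaffolds; singleton chains, which carry no
    orientation evidence, are reported with orientation "?".
    """
    consensus = ConsensusOrder()
    for lg in sorted(cg.graphs):
        graph = cg.graphs[lg]
        indegree = {n: graph.in_degree(n) for n in graph.nodes}
        heap = [
            (graph.nodes[n]["mean_cm"], n) for n in graph.nodes if indegree[n] == 0
        ]
        heapq.heapify(heap)
        emitted: list[str] = []
        while heap:
            _, node = heapq.heappop(heap)
            emitted.append(node)
            for succ in set(graph.successors(node)):
                indegree[succ] -= graph.number_of_edges(node, succ)
                if indegree[succ] == 0:
                    heapq.heappush(heap, (graph.nodes[succ]["mean_cm"], succ))
        if len(emitted) != graph.number_of_nodes():
            raise CycleError(f"{lg}: constraint graph is cyclic; resolve first")
        order: list[tuple[str, str]] = []
        for chain_id in emitted:
            chain: Chain = graph.nodes[chain_id]["chain"]
            if len(chain) == 1:
                order.append((chain.members[0][0], "?"))
            else:
                order.extend(chain.members)
        consensus.orders[lg] = order
    return consensus


def order_violations(
    cg: ConstraintGraph, consensus: ConsensusOrder
) -> list[tuple[str, str, str]]:
    """Edges of the (resolved) graph not respected by the consensus order.

    An edge u -> v is respected when every scaffold of chain u precedes every
    scaffold of chain v.  Returns (lg, u, v) triples; empty when consistent.
    """
    violations: list[tuple[str, str, str]] = []
    for lg, graph in cg.graphs.items():
        position = {
            sid: i for i, (sid, _) in enumerate(consensus.orders.get(lg, []))
        }
        for u, v in set(graph.edges()):
            u_max = max(position[s] for s in graph.nodes[u]["chain"].scaffolds)
            v_min = min(position[s] for s in graph.nodes[v]["chain"].scaffolds)
            if not u_max < v_min:
                violations.append((lg, u, v))
    return violations


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def lg_coverage(
    anchoring: Anchoring, lengths: dict[str, int], total_assembly_bases: int
) -> float:
    """Percent of assembly bases in chains placed on a linkage group,
    reported to 0.1 %."""
    if total_assembly_bases <= 0:
        raise ValueError("total_assembly_bases must be positive")
    placed = anchoring.placed_scaffolds()
    total = 0
    for sid in placed:
        if sid not in lengths:
            raise DataError(f"scaffold {sid!r} missing from length table")
        total += lengths[sid]
    return round(100.0 * total / total_assembly_bases, 1)
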