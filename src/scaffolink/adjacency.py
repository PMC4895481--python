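"""Scaffold-join inference from conserved gene adjacencies.

The breakpoint-graph formalism: every gene has a *head* and a *tail*
endpoint; on a chromosome, consecutive genes meet through an *adjacency*,
the unordered pair of the facing endpoints.  For an occurrence ``+g`` the
right-facing endpoint is ``g.head`` and the left-facing one ``g.tail``;
signs swap the two.

A fragmented target scaffold exposes one endpoint at each of its two
extremities (5p exposes the left endpoint of its first occurrence, 3p the
right endpoint of its last).  When two exposed endpoints form an adjacency
in a related genome, that genome is evidence that the two scaffolds were
neighbours before fragmentation.  Evidence is weighted by phylogenetic
proximity (1 / patristic distance to the target), candidate joins are
filtered by a multi-genome witness rule, and a conflict-free set is chosen
by maximum-weight matching on scaffold extremities.  Accepted links are
stitched into oriented chains (super-scaffolds).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import networkx as nx

from .errors import DataError
from .gene_orders import GeneOrder, Occurrence

_WEIGHT_TOL = 1e-9


# ---------------------------------------------------------------------------
# endpoints and extremities
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Endpoint:
    """One end of a gene family: ``side`` is ``"head"`` or ``"tail"``."""

    family: str
    side: str

    def __post_init__(self) -> None:
        if self.side not in ("head", "tail"):
            raise DataError(f"bad endpoint side {self.side!r}")

    def __str__(self) -> str:
        return f"{self.family}.{self.side}"


def right_endpoint(occ: Occurrence) -> Endpoint:
    """The endpoint of ``occ`` facing right along the sequence."""
    return Endpoint(occ.family, "head" if occ.sign > 0 else "tail")


def left_endpoint(occ: Occurrence) -> Endpoint:
    """The endpoint of ``occ`` facing left along the sequence."""
    return Endpoint(occ.family, "tail" if occ.sign > 0 else "head")


@dataclass(frozen=True)
class Extremity:
    """A scaffold end: ``side`` is ``"5p"`` (start) or ``"3p"`` (end);
    ``exposed`` is the outward-facing endpoint of the terminal occurrence."""

    scaffold_id: str
    side: str
    exposed: Endpoint | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.scaffold_id, self.side)

    def __str__(self) -> str:
        return f"{self.scaffold_id}:{self.side}"


def other_side(side: str) -> str:
    return "3p" if side == "5p" else "5p"


@dataclass
class CandidateLink:
    """A candidate join between two scaffold extremities with per-genome
    support weights.  ``ext_a.key < ext_b.key`` by construction."""

    ext_a: Extremity
    ext_b: Extremity
    support: dict[str, float] = field(default_factory=dict)

    @property
    def total_weight(self) -> float:
        return sum(self.support.values())

    @property
    def n_genomes(self) -> int:
        return len(self.support)

    @property
    def pair_key(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return (self.ext_a.key, self.ext_b.key)

    def extremity_frozenset(self) -> frozenset[tuple[str, str]]:
        return frozenset((self.ext_a.key, self.ext_b.key))


@dataclass(frozen=True)
class Chain:
    """An oriented path of scaffolds (a super-scaffold).  ``members`` is a
    tuple of ``(scaffold_id, "+"|"-")``; ``internal_links`` realise the
    consecutive pairs."""

    members: tuple[tuple[str, str], ...]
    internal_links: tuple[CandidateLink, ...] = ()

    @property
    def id(self) -> str:
        return "_".join(sorted(sid for sid, _ in self.members))

    @property
    def scaffolds(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.members)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# phylogenetic weights
# ---------------------------------------------------------------------------

def genome_weights(
    tree: dendropy.Tree, target_id: str, ref_ids: list[str]
) -> dict[str, float]:
    """Weight each reference genome by 1 / patristic distance to the target.

    If any branch length is missing, every genome gets weight 1.0 (the method
    stays usable on topology-only trees).
    """
    labels = {t.label for t in tree.taxon_namespace}
    for gid in [target_id, *ref_ids]:
        if gid not in labels:
            raise DataError(f"genome {gid!r} is not a leaf of the tree")
    has_lengths = all(
        e.length is not None
        for e in tree.preorder_edge_iter()
        if e.tail_node is not None
    )
    if not has_lengths:
        return {gid: 1.0 for gid in ref_ids}
    pdm = tree.phylogenetic_distance_matrix()
    target_taxon = tree.taxon_namespace.get_taxon(target_id)
    weights: dict[str, float] = {}
    for gid in ref_ids:
        dist = pdm.patristic_distance(target_taxon, tree.taxon_namespace.get_taxon(gid))
        if dist <= 0:
            raise DataError(f"non-positive patristic distance to {gid!r}")
        weights[gid] = 1.0 / dist
    return weights


# ---------------------------------------------------------------------------
# adjacencies and candidates
# ---------------------------------------------------------------------------

def reference_adjacencies(projected_ref: GeneOrder) -> set[frozenset[Endpoint]]:
    """The set of endpoint adjacencies of one (projected) genome: for each
    sequence ``[x1..xn]``, the pairs {right(xi), left(xi+1)}."""
    adjacencies: set[frozenset[Endpoint]] = set()
    for occs in projected_ref.orders.values():
        for a, b in itertools.pairwise(occs):
            adjacencies.add(frozenset((right_endpoint(a), left_endpoint(b))))
    return adjacencies


def scaffold_extremities(
    target: GeneOrder, window: int = 1
) -> dict[tuple[str, str], list[tuple[Endpoint, int]]]:
    """Outward-facing endpoints at each target scaffold extremity.

    With terminal window ``k``, each extremity exposes the endpoints of its
    outermost ``min(k, len)`` occurrences, each tagged with its offset from
    the scaffold end (0 = terminal).
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    exposed: dict[tuple[str, str], list[tuple[Endpoint, int]]] = {}
    for sid, occs in target.orders.items():
        if not occs:
            continue
        k = min(window, len(occs))
        exposed[(sid, "5p")] = [(left_endpoint(occs[o]), o) for o in range(k)]
        exposed[(sid, "3p")] = [(right_endpoint(occs[-1 - o]), o) for o in range(k)]
    return exposed


def candidate_links(
    target: GeneOrder,
    refs: list[tuple[str, set[frozenset[Endpoint]]]],
    weights: dict[str, float],
    window: int = 1,
    decay: float = 0.5,
) -> list[CandidateLink]:
    """Score all scaffold-extremity pairs against reference adjacencies.

    For each pair of extremities of *different* scaffolds whose exposed
    endpoints form an adjacency of a reference genome, that genome supports
    the pair with ``weight * decay**(offset_a + offset_b)``; a genome counts
    at most once per pair (its best-decay occurrence pair).  Pairs with zero
    support are omitted.  Output sorted by (-total_weight, extremity pair).
    """
    exposed = scaffold_extremities(target, window=window)
    # endpoint -> [(extremity key, offset)]
    index: dict[Endpoint, list[tuple[tuple[str, str], int]]] = {}
    for ext_key, endpoints in exposed.items():
        for endpoint, offset in endpoints:
            index.setdefault(endpoint, []).append((ext_key, offset))

    best: dict[tuple, dict[str, float]] = {}
    for genome_id, adjacencies in refs:
        weight = weights.get(genome_id)
        if weight is None:
            raise DataError(f"no weight for genome {genome_id!r}")
        for adjacency in adjacencies:
            endpoints = tuple(adjacency)
            if len(endpoints) == 1:  # palindromic adjacency (x.head-x.head)
                hits_a = hits_b = index.get(endpoints[0], [])
            else:
                hits_a = index.get(endpoints[0], [])
                hits_b = index.get(endpoints[1], [])
            if not hits_a or not hits_b:
                continue
            for (key_a, off_a), (key_b, off_b) in itertools.product(hits_a, hits_b):
                if key_a[0] == key_b[0]:
                    continue  # never circularize a scaffold
                pair = tuple(sorted((key_a, key_b)))
                contribution = weight * decay ** (off_a + off_b)
                genome_support = best.setdefault(pair, {})
                if contribution > genome_support.get(genome_id, 0.0):
                    genome_support[genome_id] = contribution

    terminal = {key: eps[0][0] for key, eps in exposed.items()}
    links = [
        CandidateLink(
            ext_a=Extremity(*pair[0], exposed=terminal.get(pair[0])),
            ext_b=Extremity(*pair[1], exposed=terminal.get(pair[1])),
            support=dict(sorted(support.items())),
        )
        for pair, support in best.items()
    ]
    links.sort(key=lambda l: (-l.total_weight, l.pair_key))
    return links


# ---------------------------------------------------------------------------
# conflict resolution: maximum-weight matching
# ---------------------------------------------------------------------------

def _matching_weight(graph: nx.Graph) -> float:
    matching = nx.max_weight_matching(graph)
    return sum(graph[u][v]["weight"] for u, v in matching)


def select_links(
    candidates: list[CandidateLink],
    min_genomes: int = 2,
    min_weight: float = 0.0,
) -> list[CandidateLink]:
    """Filter candidates, then pick a conflict-free set of maximum total
    weight (each extremity in at most one accepted link).

    Ties between equal-weight matchings are broken by preferring the
    lexicographically smallest sorted edge list, realised by greedily forcing
    edges in lexicographic order and checking that the optimum is preserved.
    """
    if min_genomes < 1:
        raise ValueError(f"min_genomes must be >= 1, got {min_genomes}")
    if min_weight < 0:
        raise ValueError(f"min_weight must be >= 0, got {min_weight}")
    surviving = [
        c
        for c in candidates
        if c.n_genomes >= min_genomes and c.total_weight >= min_weight - _WEIGHT_TOL
    ]
    if not surviving:
        return []

    graph = nx.Graph()
    by_pair: dict[tuple, CandidateLink] = {}
    for cand in surviving:
        a, b = cand.pair_key
        if graph.has_edge(a, b):
            raise DataError(f"duplicate candidate for extremity pair {a}-{b}")
        graph.add_edge(a, b, weight=cand.total_weight)
        by_pair[(a, b)] = cand

    accepted: list[CandidateLink] = []
    for component in nx.connected_components(graph):
        sub = graph.subgraph(component).copy()
        optimum = _matching_weight(sub)
        edges = sorted(tuple(sorted(e)) for e in sub.edges)
        chosen: list[tuple] = []
        used: set = set()
        forced_weight = 0.0
        for a, b in edges:
            if a in used or b in used:
                continue
            residual = sub.copy()
            residual.remove_nodes_from(used | {a, b})
            if (
                forced_weight
                + sub[a][b]["weight"]
                + _matching_weight(residual)
                >= optimum - _WEIGHT_TOL
            ):
                chosen.append((a, b))
                used.update((a, b))
                forced_weight += sub[a][b]["weight"]
        accepted.extend(by_pair[e] for e in chosen)
    accepted.sort(key=lambda l: l.pair_key)
    return accepted


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

def _reverse_complement(
    members: tuple[tuple[str, str], ...]
) -> tuple[tuple[str, str], ...]:
    flip = {"+": "-", "-": "+"}
    return tuple((sid, flip[o]) for sid, o in reversed(members))


def build_chains(
    accepted: list[CandidateLink], all_scaffolds: list[str]
) -> list[Chain]:
    """Stitch accepted links into oriented chains.

    The accepted links must form a matching on extremities.  Cycles are broken
    at their lowest-weight link (tie: lexicographic extremity pair).  Chain
    orientations satisfy every internal link; the canonical form of a chain is
    the lexicographically smaller of itself and its reverse-complement.
    Unlinked scaffolds become singleton chains oriented "+".
    """
    ext_link: dict[tuple[str, str], CandidateLink] = {}
    for link in accepted:
        for key in (link.ext_a.key, link.ext_b.key):
            if key in ext_link:
                raise DataError(
                    f"links do not form a matching: extremity {key} used twice"
                )
            ext_link[key] = link

    # connected components of scaffolds through links
    comp_graph = nx.MultiGraph()
    comp_graph.add_nodes_from(all_scaffolds)
    for link in accepted:
        comp_graph.add_edge(
            link.ext_a.scaffold_id, link.ext_b.scaffold_id, link=link
        )
        for sid in (link.ext_a.scaffold_id, link.ext_b.scaffold_id):
            if sid not in comp_graph:
                raise DataError(f"link references unknown scaffold {sid!r}")

    chains: list[Chain] = []
    for component in nx.connected_components(comp_graph):
        scaffolds = sorted(component)
        links = {
            data["link"].extremity_frozenset(): data["link"]
            for _, _, data in comp_graph.subgraph(component).edges(data=True)
        }
        if len(links) == len(scaffolds) and len(scaffolds) >= 1 and links:
            # every scaffold has both extremities matched: a cycle; chromosomes
            # are linear, so drop the least-supported link
            weakest = min(
                links.values(), key=lambda l: (l.total_weight, l.pair_key)
            )
            del links[weakest.extremity_frozenset()]
            del ext_link[weakest.ext_a.key]
            del ext_link[weakest.ext_b.key]
        if not links:
            chains.extend(Chain(members=((sid, "+"),)) for sid in scaffolds)
            continue

        free = [
            (sid, side)
            for sid in scaffolds
            for side in ("5p", "3p")
            if (sid, side) not in ext_link
        ]
        start = min(free)
        members: list[tuple[str, str]] = []
        internal: list[CandidateLink] = []
        current: tuple[str, str] | None = start
        while current is not None:
            sid, entry_side = current
            members.append((sid, "+" if entry_side == "5p" else "-"))
            exit_key = (sid, other_side(entry_side))
            link = ext_link.get(exit_key)
            if link is None:
                current = None
            else:
                internal.append(link)
                partner = (
                    link.ext_b if link.ext_a.key == exit_key else link.ext_a
                )
                current = partner.key
        forward = tuple(members)
        backward = _reverse_complement(forward)
        if backward < forward:
            chains.append(
                Chain(members=backward, internal_links=tuple(reversed(internal)))
            )
        else:
            chains.append(Chain(members=forward, internal_links=tuple(internal)))
    chains.sort(key=lambda c: c.id)
    return chains
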