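"""Gene-order evolution simulator with fragmentation and noisy linkage maps.

Emulates the study design the scaffolder targets: a set of fish genomes
diverged by chromosomal rearrangements and gene gain/loss along a known
phylogeny, a target genome fragmented into scaffolds, and two (male/female)
partially overlapping genetic maps with marker dropout, positional noise and
occasional local order swaps.  Every stage records ground truth so link
inference and consensus ordering can be scored without external data.

Defaults mirror a teleost-scale problem cut to desk size: seven leaves
(one target + six references), 19 chromosomes, ~1,000 gene families,
~150 scaffolds.  Event rates are Poisson per unit branch length; a tree
without branch lengths treats every branch as length 1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from . import formats
from .adjacency import CandidateLink
from .formats import Gene, LinkageMap, MapEntry
from .gene_orders import GeneOrder, Occurrence

# Fish-like 7-leaf topology: coelacanth outgroup, the (eel-like) target basal
# among the teleosts, pufferfishes sister to medaka+stickleback.
DEFAULT_TREE = (
    "(Coelacanth:0.45,(Target:0.32,(Zebrafish:0.30,((Fugu:0.17,Tetraodon:0.17)"
    ":0.09,(Medaka:0.23,Stickleback:0.22):0.05):0.05):0.04):0.05);"
)

_GENE_SPAN = 2_000
_GENE_PITCH = 10_000
_RETRIES = 10


@dataclass
class EventRates:
    """Rearrangement/indel/duplication rates, events per unit branch length."""

    inversion: float = 16.0
    translocation: float = 3.0
    fusion: float = 0.4
    fission: float = 0.4
    deletion: float = 6.0
    insertion: float = 6.0
    duplication: float = 6.0

    @classmethod
    def zero(cls) -> "EventRates":
        return cls(0, 0, 0, 0, 0, 0, 0)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass
class SimParams:
    """Study conditions for one simulated scaffolding problem."""

    tree_newick: str = DEFAULT_TREE
    target_id: str = "Target"
    families: int = 1000
    chromosomes: int = 19
    rates: EventRates = field(default_factory=EventRates)
    max_deletion_span: int = 3
    max_duplication_span: int = 3
    max_insertion_size: int = 2
    breaks_per_chromosome: float = 7.0
    markers_per_scaffold: int = 2
    dropout: float = 0.25
    cm_spacing: float = 1.0
    noise_sd: float = 0.4
    swap_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.families < self.chromosomes:
            raise ValueError("need at least one family per chromosome")
        for name in ("dropout", "swap_prob"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if any(v < 0 for v in self.rates.as_dict().values()):
            raise ValueError("event rates must be non-negative")


@dataclass
class SimTruth:
    """Ground truth: broken adjacencies as (scaffold, side) pairs, scaffold ->
    chromosome membership, true scaffold order per chromosome, event log."""

    adjacencies: set[frozenset] = field(default_factory=set)
    chrom_of: dict[str, str] = field(default_factory=dict)
    order: dict[str, list[str]] = field(default_factory=dict)
    event_log: list[dict] = field(default_factory=list)


@dataclass
class SimGenomes:
    genomes: dict[str, GeneOrder]
    event_log: list[dict]
    lineages: dict[str, list[str]]  # leaf -> branch labels on its root path


@dataclass
class LinkEvaluation:
    precision: float | None
    recall: float | None
    n_correct: int
    n_inferred: int
    n_truth: int


# ---------------------------------------------------------------------------
# genome evolution
# ---------------------------------------------------------------------------

def _root_genome(params: SimParams, rng: np.random.Generator) -> dict[str, list]:
    """Single-copy signed families spread near-evenly over the chromosomes."""
    width = len(str(params.families))
    fams = [f"fam{i:0{width}d}" for i in range(1, params.families + 1)]
    signs = rng.choice([-1, 1], size=params.families)
    bounds = np.linspace(0, params.families, params.chromosomes + 1).astype(int)
    chroms: dict[str, list] = {}
    for c in range(params.chromosomes):
        name = f"chr{c + 1:02d}"
        chroms[name] = [
            (fams[i], int(signs[i])) for i in range(bounds[c], bounds[c + 1])
        ]
    return chroms


def _pick_chrom(chroms: dict, rng: np.random.Generator, min_genes: int = 1) -> str | None:
    eligible = sorted(c for c, genes in chroms.items() if len(genes) >= min_genes)
    if not eligible:
        return None
    sizes = np.array([len(chroms[c]) for c in eligible], dtype=float)
    return eligible[rng.choice(len(eligible), p=sizes / sizes.sum())]


def _apply_event(
    kind: str,
    chroms: dict[str, list],
    params: SimParams,
    rng: np.random.Generator,
    state: dict,
) -> dict | None:
    """Apply one event in place; return its log details or None if impossible."""
    if kind == "inversion":
        c = _pick_chrom(chroms, rng)
        if c is None:
            return None
        genes = chroms[c]
        i, j = sorted(rng.integers(0, len(genes), size=2))
        j += 1
        genes[i:j] = [(f, -s) for f, s in reversed(genes[i:j])]
        return {"chrom": c, "start": int(i), "end": int(j), "delta": 0}
    if kind == "translocation":
        if len(chroms) < 2:
            return None
        src = _pick_chrom(chroms, rng)
        genes = chroms[src]
        i, j = sorted(rng.integers(0, len(genes), size=2))
        j += 1
        segment = genes[i:j]
        del genes[i:j]
        dests = sorted(c for c in chroms if c != src)
        dest = dests[rng.integers(0, len(dests))]
        if rng.random() < 0.5:
            segment = [(f, -s) for f, s in reversed(segment)]
        at = int(rng.integers(0, len(chroms[dest]) + 1))
        chroms[dest][at:at] = segment
        if not genes:
            del chroms[src]
        return {"chrom": src, "dest": dest, "span": len(segment), "delta": 0}
    if kind == "fusion":
        if len(chroms) < 2:
            return None
        a, b = sorted(
            np.array(sorted(chroms))[rng.choice(len(chroms), size=2, replace=False)]
        )
        tail = chroms.pop(b)
        if rng.random() < 0.5:
            tail = [(f, -s) for f, s in reversed(tail)]
        chroms[a].extend(tail)
        return {"chrom": a, "merged": b, "delta": 0}
    if kind == "fission":
        c = _pick_chrom(chroms, rng, min_genes=2)
        if c is None:
            return None
        genes = chroms[c]
        cut = int(rng.integers(1, len(genes)))
        state["chrom_counter"] += 1
        new = f"nc{state['chrom_counter']:03d}"
        chroms[new] = genes[cut:]
        chroms[c] = genes[:cut]
        return {"chrom": c, "new": new, "cut": cut, "delta": 0}
    if kind == "deletion":
        c = _pick_chrom(chroms, rng)
        if c is None:
            return None
        genes = chroms[c]
        span = int(rng.integers(1, min(params.max_deletion_span, len(genes)) + 1))
        i = int(rng.integers(0, len(genes) - span + 1))
        del genes[i : i + span]
        if not genes:
            del chroms[c]
        return {"chrom": c, "span": span, "delta": -span}
    if kind == "insertion":
        c = _pick_chrom(chroms, rng)
        if c is None:
            return None
        size = int(rng.integers(1, params.max_insertion_size + 1))
        novel = []
        for _ in range(size):
            state["novel_counter"] += 1
            novel.append((f"nov{state['novel_counter']:04d}", int(rng.choice([-1, 1]))))
        at = int(rng.integers(0, len(chroms[c]) + 1))
        chroms[c][at:at] = novel
        return {"chrom": c, "span": size, "delta": size}
    if kind == "duplication":
        c = _pick_chrom(chroms, rng)
        if c is None:
            return None
        genes = chroms[c]
        span = int(rng.integers(1, min(params.max_duplication_span, len(genes)) + 1))
        i = int(rng.integers(0, len(genes) - span + 1))
        genes[i + span : i + span] = list(genes[i : i + span])  # tandem copy
        return {"chrom": c, "span": span, "delta": span}
    raise ValueError(f"unknown event kind {kind!r}")


def _to_gene_order(genome_id: str, chroms: dict[str, list]) -> GeneOrder:
    orders: dict[str, list[Occurrence]] = {}
    counter = 0
    for chrom in sorted(chroms):
        occs = []
        for family, sign in chroms[chrom]:
            counter += 1
            occs.append(Occurrence(family, sign, f"{genome_id}_g{counter:05d}"))
        orders[chrom] = occs
    return GeneOrder(genome_id=genome_id, orders=orders)


def simulate_genomes(params: SimParams) -> SimGenomes:
    """Evolve leaf genomes from a common ancestor along the tree.

    Per branch, the event count is Poisson(total rate x branch length); event
    types are drawn proportionally to their rates.  An event impossible in the
    current state (e.g. fission of a one-gene genome) is resampled, with
    bounded retries, then skipped with a log entry.
    """
    rng = np.random.default_rng(params.seed)
    tree = dendropy.Tree.get(
        data=params.tree_newick, schema="newick", preserve_underscores=True
    )
    rates = params.rates.as_dict()
    kinds = sorted(rates)
    rate_vec = np.array([rates[k] for k in kinds])
    total_rate = float(rate_vec.sum())
    state = {"chrom_counter": 0, "novel_counter": 0}

    event_log: list[dict] = []
    genomes: dict[str, GeneOrder] = {}
    lineages: dict[str, list[str]] = {}
    node_genome: dict[int, dict] = {}
    node_path: dict[int, list[str]] = {}

    for idx, node in enumerate(tree.preorder_node_iter()):
        if node.parent_node is None:
            node_genome[id(node)] = _root_genome(params, rng)
            node_path[id(node)] = []
            continue
        label = node.taxon.label if node.taxon else f"node{idx}"
        chroms = {c: list(g) for c, g in node_genome[id(node.parent_node)].items()}
        blen = node.edge.length if node.edge.length is not None else 1.0
        n_events = int(rng.poisson(total_rate * blen)) if total_rate > 0 else 0
        for _ in range(n_events):
            details = None
            for _attempt in range(_RETRIES):
                kind = kinds[rng.choice(len(kinds), p=rate_vec / total_rate)]
                details = _apply_event(kind, chroms, params, rng, state)
                if details is not None:
                    break
            if details is None:
                event_log.append({"branch": label, "type": "skipped", "delta": 0})
            else:
                event_log.append({"branch": label, "type": kind, **details})
        node_genome[id(node)] = chroms
        node_path[id(node)] = node_path[id(node.parent_node)] + [label]
        if node.is_leaf():
            genomes[label] = _to_gene_order(label, chroms)
            lineages[label] = node_path[id(node)]
    return SimGenomes(genomes=genomes, event_log=event_log, lineages=lineages)


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

def fragment_target(
    target: GeneOrder, params: SimParams, rng: np.random.Generator | None = None
) -> tuple[GeneOrder, SimTruth]:
    """Split each target chromosome at random inter-gene positions.

    Scaffolds are named SC0001, SC0002, ... in chromosome order; the truth
    records each broken adjacency as the pair {(left scaffold, 3p),
    (right scaffold, 5p)} plus membership and true order per chromosome.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1_000_003)
    truth = SimTruth()
    orders: dict[str, list[Occurrence]] = {}
    counter = 0
    for chrom in sorted(target.orders):
        occs = target.orders[chrom]
        n = len(occs)
        k = min(int(rng.poisson(params.breaks_per_chromosome)), max(n - 1, 0))
        if k > 0:
            cuts = np.sort(rng.choice(np.arange(1, n), size=k, replace=False))
        else:
            cuts = np.array([], dtype=int)
        bounds = [0, *cuts.tolist(), n]
        chrom_scaffolds: list[str] = []
        for a, b in zip(bounds, bounds[1:]):
            counter += 1
            sid = f"SC{counter:04d}"
            orders[sid] = list(occs[a:b])
            truth.chrom_of[sid] = chrom
            chrom_scaffolds.append(sid)
        for left, right in zip(chrom_scaffolds, chrom_scaffolds[1:]):
            truth.adjacencies.add(frozenset(((left, "3p"), (right, "5p"))))
        truth.order[chrom] = chrom_scaffolds
    scaffolded = GeneOrder(genome_id=target.genome_id, orders=orders)
    return scaffolded, truth


def rejoin_scaffolds(scaffolded: GeneOrder, truth: SimTruth) -> GeneOrder:
    """Reconstruct the pre-fragmentation gene order from the truth (used to
    verify that the recorded adjacencies are complete and consistent)."""
    orders = {
        chrom: [
            occ for sid in truth.order[chrom] for occ in scaffolded.orders[sid]
        ]
        for chrom in truth.order
    }
    return GeneOrder(genome_id=scaffolded.genome_id, orders=orders)


def scaffold_lengths(scaffolded: GeneOrder) -> dict[str, int]:
    """Deterministic synthetic base-pair lengths: genes sit on a fixed pitch,
    so a scaffold's length grows linearly with its gene count."""
    return {
        sid: len(occs) * _GENE_PITCH + _GENE_SPAN
        for sid, occs in scaffolded.orders.items()
    }


def gene_order_to_genes(order: GeneOrder) -> list[Gene]:
    """Materialise synthetic coordinates for a gene order (for GFF3 output)."""
    genes: list[Gene] = []
    for seq_id in sorted(order.orders):
        for i, occ in enumerate(order.orders[seq_id]):
            start = 1_000 + i * _GENE_PITCH
            genes.append(
                Gene(
                    gene_id=occ.gene_id,
                    family=occ.family,
                    seq_id=seq_id,
                    start=start,
                    end=start + _GENE_SPAN,
                    strand="+" if occ.sign > 0 else "-",
                )
            )
    return genes


# ---------------------------------------------------------------------------
# linkage maps
# ---------------------------------------------------------------------------

def simulate_maps(
    truth: SimTruth, params: SimParams, rng: np.random.Generator | None = None
) -> list[LinkageMap]:
    """Two maps (male, female) over the true scaffold orders.

    Marker positions are true ordinal x spacing plus truncated-Gaussian noise;
    each marker survives with probability 1 - dropout per map; adjacent marker
    pairs swap positions with the stated probability.  Linkage-group ids equal
    the true chromosome ids.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 2_000_003)
    maps: list[LinkageMap] = []
    for map_id in ("male", "female"):
        entries: list[MapEntry] = []
        for chrom in sorted(truth.order):
            markers: list[tuple[str, str, float]] = []
            ordinal = 0
            for sid in truth.order[chrom]:
                for j in range(params.markers_per_scaffold):
                    ordinal += 1
                    dropped = rng.random() < params.dropout
                    noise = (
                        rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
                    )
                    if dropped:
                        continue
                    pos = max(0.0, ordinal * params.cm_spacing + noise)
                    markers.append((f"{map_id}.{chrom}.{sid}.{j}", sid, pos))
            for i in range(len(markers) - 1):
                if rng.random() < params.swap_prob:
                    ma, mb = markers[i], markers[i + 1]
                    markers[i] = (ma[0], ma[1], mb[2])
                    markers[i + 1] = (mb[0], mb[1], ma[2])
            entries.extend(
                MapEntry(map_id, chrom, mid, sid, pos) for mid, sid, pos in markers
            )
        entries.sort(key=lambda e: (e.lg_id, e.position_cm, e.marker_id))
        maps.append(LinkageMap(map_id=map_id, entries=entries))
    return maps


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_links(
    inferred: list[CandidateLink], truth: SimTruth
) -> LinkEvaluation:
    """Precision/recall of inferred links against the true broken adjacencies
    (orientation-aware: the (scaffold, side) pairs must match exactly)."""
    truth_set = truth.adjacencies
    correct = sum(
        1 for link in inferred if link.extremity_frozenset() in truth_set
    )
    n_inf, n_tru = len(inferred), len(truth_set)
    return LinkEvaluation(
        precision=correct / n_inf if n_inf else None,
        recall=correct / n_tru if n_tru else None,
        n_correct=correct,
        n_inferred=n_inf,
        n_truth=n_tru,
    )


def consensus_accuracy(orders: dict[str, list[tuple[str, str]]], truth: SimTruth) -> float:
    """Mean pairwise order agreement between consensus and true scaffold order.

    Per linkage group, the fraction of scaffold pairs (among scaffolds present
    in the consensus for their true group) ordered as in the truth; groups
    with fewer than two comparable scaffolds are skipped.  1.0 = perfect.
    """
    scores: list[float] = []
    for chrom, true_order in truth.order.items():
        consensus = [sid for sid, _ in orders.get(chrom, [])]
        rank = {sid: i for i, sid in enumerate(consensus)}
        present = [sid for sid in true_order if sid in rank]
        if len(present) < 2:
            continue
        good = total = 0
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                total += 1
                if rank[present[i]] < rank[present[j]]:
                    good += 1
        scores.append(good / total)
    return float(np.mean(scores)) if scores else float("nan")


# ---------------------------------------------------------------------------
# one-call study orchestration + on-disk study
# ---------------------------------------------------------------------------

@dataclass
class SimStudy:
    params: SimParams
    genomes: dict[str, GeneOrder]
    target_scaffolded: GeneOrder
    truth: SimTruth
    maps: list[LinkageMap]
    lengths: dict[str, int]
    event_log: list[dict]
    lineages: dict[str, list[str]]

    @property
    def references(self) -> dict[str, GeneOrder]:
        return {
            gid: order
            for gid, order in self.genomes.items()
            if gid != self.params.target_id
        }


def simulate_study(params: SimParams) -> SimStudy:
    """Run the three simulation stages with one seed: evolve genomes,
    fragment the target, and draw both linkage maps."""
    sim = simulate_genomes(params)
    if params.target_id not in sim.genomes:
        raise ValueError(f"target {params.target_id!r} is not a leaf of the tree")
    rng = np.random.default_rng(params.seed + 1_000_003)
    scaffolded, truth = fragment_target(sim.genomes[params.target_id], params, rng)
    truth.event_log = sim.event_log
    maps = simulate_maps(truth, params, rng)
    return SimStudy(
        params=params,
        genomes=sim.genomes,
        target_scaffolded=scaffolded,
        truth=truth,
        maps=maps,
        lengths=scaffold_lengths(scaffolded),
        event_log=sim.event_log,
        lineages=sim.lineages,
    )


def write_study(study: SimStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a study as the file set the pipeline consumes: per-genome GFF3s,
    one family table, the tree, the two maps, scaffold lengths, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    families: dict[str, str] = {}
    target_genes = gene_order_to_genes(study.target_scaffolded)
    paths["target_gff"] = out / "target.gff3"
    formats.write_gff_genes(target_genes, paths["target_gff"])
    for g in target_genes:
        families[g.gene_id] = g.family
    for gid in sorted(study.references):
        genes = gene_order_to_genes(study.references[gid])
        path = out / f"ref_{gid}.gff3"
        formats.write_gff_genes(genes, path)
        paths[f"ref_{gid}"] = path
        for g in genes:
            families[g.gene_id] = g.family

    paths["families"] = out / "families.tsv"
    formats.write_family_table(families, paths["families"])
    paths["tree"] = out / "tree.nwk"
    paths["tree"].write_text(study.params.tree_newick + "\n")
    paths["lengths"] = out / "lengths.tsv"
    formats.write_sequence_lengths(study.lengths, paths["lengths"])
    paths["maps"] = out / "maps.tsv"
    formats.write_linkage_maps(study.maps, paths["maps"])
    paths["truth"] = out / "truth.json"
    write_truth(study.truth, paths["truth"])
    return paths


def write_truth(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "adjacencies": sorted(
            sorted([list(p) for p in adj]) for adj in truth.adjacencies
        ),
        "chrom_of": truth.chrom_of,
        "order": truth.order,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_truth(path: str | Path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    return SimTruth(
        adjacencies={
            frozenset(tuple(p) for p in adj) for adj in payload["adjacencies"]
        },
        chrom_of=payload["chrom_of"],
        order=payload["order"],
    )
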