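"""One-shot pipeline: annotations + tree + maps in, ordered scaffolds out.

Stage order: read inputs -> build signed gene orders -> drop scaffolds with
no homologous genes -> project references onto the target's family content ->
phylogenetic weights -> candidate links -> maximum-weight selection ->
chains -> anchor chains into linkage groups -> precedence graph -> cycle
resolution -> topological consensus -> coverage.  Every stage count is
logged and written to a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, adjacency, formats, gene_orders, linkage

logger = logging.getLogger("scaffolink")


@dataclass
class PipelineConfig:
    target_gff: Path
    refs: list[tuple[str, Path]]
    families: Path
    tree: Path
    lengths: Path
    maps: Path
    out_dir: Path
    feature_type: str = "gene"
    min_genomes: int = 2
    min_weight: float = 0.0
    window: int = 1
    decay: float = 0.5
    max_copy: int = 10
    gap_size: int = 100
    majority: float = 2 / 3
    target_id: str = "Target"
    seed: int = 0

    def input_paths(self) -> list[Path]:
        return [
            self.target_gff,
            *[p for _, p in self.refs],
            self.families,
            self.tree,
            self.lengths,
            self.maps,
        ]


@dataclass
class PipelineResult:
    counts: dict = field(default_factory=dict)
    artifacts: dict[str, Path] = field(default_factory=dict)
    chains: list = field(default_factory=list)
    accepted: list = field(default_factory=list)
    consensus: linkage.ConsensusOrder | None = None
    anchoring: linkage.Anchoring | None = None


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(
        {
            k: str(v)
            for k, v in dataclasses.asdict(config).items()
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    for path in config.input_paths():
        if not Path(path).exists():
            raise formats.DataError(f"input file not found: {path}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    counts = result.counts

    # --- read + gene orders -------------------------------------------------
    target_read = formats.read_gff_genes(
        config.target_gff, config.families, config.target_id, config.feature_type
    )
    target_order = gene_orders.build_gene_order(target_read.genes, config.target_id)
    counts["target_genes"] = len(target_read.genes)
    counts["target_genes_dropped"] = target_read.n_dropped
    counts["target_scaffolds_in"] = target_order.n_sequences
    target_order, removed = gene_orders.filter_empty_scaffolds(target_order)
    counts["target_scaffolds_filtered"] = removed
    counts["target_scaffolds"] = target_order.n_sequences
    logger.info(
        "target: %d genes on %d scaffolds (%d empty scaffolds filtered)",
        counts["target_genes"], counts["target_scaffolds"], removed,
    )

    target_families = target_order.families()
    tree = formats.read_newick_tree(config.tree)
    weights = adjacency.genome_weights(
        tree, config.target_id, [gid for gid, _ in config.refs]
    )

    refs: list[tuple[str, set]] = []
    for genome_id, path in config.refs:
        read = formats.read_gff_genes(
            path, config.families, genome_id, config.feature_type
        )
        order = gene_orders.build_gene_order(read.genes, genome_id)
        order, _ = gene_orders.filter_empty_scaffolds(order)
        projected = gene_orders.restrict_to_shared(
            order, target_families, config.max_copy
        )
        refs.append((genome_id, adjacency.reference_adjacencies(projected)))
        logger.info(
            "reference %s: %d genes, %d projected adjacencies, weight %.3g",
            genome_id, len(read.genes), len(refs[-1][1]), weights[genome_id],
        )

    # --- link inference -----------------------------------------------------
    candidates = adjacency.candidate_links(
        target_order, refs, weights, window=config.window, decay=config.decay
    )
    counts["candidate_links"] = len(candidates)
    accepted = adjacency.select_links(
        candidates, min_genomes=config.min_genomes, min_weight=config.min_weight
    )
    counts["accepted_links"] = len(accepted)
    result.accepted = accepted
    chains = adjacency.build_chains(accepted, sorted(target_order.orders))
    counts["chains"] = len(chains)
    result.chains = chains
    logger.info(
        "%d candidate links -> %d accepted -> %d chains",
        len(candidates), len(accepted), len(chains),
    )

    lengths = formats.read_sequence_lengths(config.lengths)
    result.artifacts["links"] = out_dir / "links.tsv"
    formats.write_links_tsv(accepted, result.artifacts["links"])
    result.artifacts["agp"] = out_dir / "super_scaffolds.agp"
    formats.write_agp(chains, lengths, result.artifacts["agp"], config.gap_size)

    # --- linkage integration ------------------------------------------------
    maps = formats.read_linkage_maps(config.maps)
    anchoring = linkage.anchor_chains(maps, chains, config.majority)
    result.anchoring = anchoring
    counts["placed_chains"] = len(anchoring.placements)
    counts["unplaced_chains"] = len(anchoring.unplaced)

    graph = linkage.build_constraint_graph(anchoring, maps, chains)
    resolved, removals = linkage.resolve_cycles(graph)
    counts["removed_edges"] = len(removals)
    consensus = linkage.topological_consensus(resolved)
    result.consensus = consensus

    total_bases = sum(lengths.values())
    coverage = linkage.lg_coverage(anchoring, lengths, total_bases)
    counts["coverage_pct"] = coverage
    mapped_scaffolds = {
        e.scaffold_id for m in maps for e in m.entries if e.scaffold_id in lengths
    }
    counts["coverage_baseline_pct"] = round(
        100.0 * sum(lengths[s] for s in mapped_scaffolds) / total_bases, 1
    )
    logger.info(
        "placed %d/%d chains; linkage-group coverage %.1f%% (markers alone: %.1f%%)",
        counts["placed_chains"], counts["chains"],
        coverage, counts["coverage_baseline_pct"],
    )

    # --- artifacts ----------------------------------------------------------
    result.artifacts["anchoring"] = out_dir / "anchoring.tsv"
    with open(result.artifacts["anchoring"], "w") as fh:
        fh.write("chain\tlg\ttally\tstatus\n")
        unplaced = dict(anchoring.unplaced)
        for chain_id in sorted(anchoring.chains):
            tally = ";".join(
                f"{lg}:{n}" for lg, n in sorted(anchoring.tallies[chain_id].items())
            )
            if chain_id in anchoring.placements:
                fh.write(f"{chain_id}\t{anchoring.placements[chain_id]}\t{tally}\tplaced\n")
            else:
                fh.write(f"{chain_id}\t.\t{tally}\t{unplaced[chain_id]}\n")

    result.artifacts["removed_edges"] = out_dir / "removed_edges.tsv"
    with open(result.artifacts["removed_edges"], "w") as fh:
        fh.write("lg\tfrom\tto\tmap_id\tsupport\tgap\n")
        for r in removals:
            fh.write(
                f"{r['lg']}\t{r['from']}\t{r['to']}\t{r['map_id']}\t"
                f"{r['support']}\t{r['gap']:.6g}\n"
            )

    result.artifacts["map_text"] = out_dir / "consensus_map.txt"
    formats.write_map_text(consensus.orders, result.artifacts["map_text"])

    result.artifacts["manifest"] = out_dir / "run_manifest.json"
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": {k: str(v) for k, v in dataclasses.asdict(config).items()},
        "counts": counts,
    }
    result.artifacts["manifest"].write_text(json.dumps(manifest, indent=1) + "\n")
    return result
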