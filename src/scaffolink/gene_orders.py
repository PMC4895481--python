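"""Signed gene orders: genomes as per-sequence lists of oriented family symbols.

A genome is reduced to, per scaffold/chromosome, the coordinate-ordered list
of its gene-family occurrences with a sign taken from the strand.  This is the
substrate of breakpoint-style adjacency analysis: reference genomes are
projected onto the target's family content (tolerating gene insertions,
deletions and duplications) before adjacencies are extracted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .formats import Gene


@dataclass(frozen=True)
class Occurrence:
    """One signed gene-family occurrence; ``sign`` is +1 or -1."""

    family: str
    sign: int
    gene_id: str = ""

    def __str__(self) -> str:  # e.g. "+fam0001"
        return ("+" if self.sign > 0 else "-") + self.family


@dataclass
class GeneOrder:
    """A genome as per-sequence ordered lists of signed family occurrences."""

    genome_id: str
    orders: dict[str, list[Occurrence]] = field(default_factory=dict)

    def families(self) -> set[str]:
        return {occ.family for occs in self.orders.values() for occ in occs}

    def family_counts(self) -> Counter:
        return Counter(occ.family for occs in self.orders.values() for occ in occs)

    @property
    def n_sequences(self) -> int:
        return len(self.orders)

    @property
    def n_occurrences(self) -> int:
        return sum(len(v) for v in self.orders.values())


def build_gene_order(genes: Iterable[Gene], genome_id: str) -> GeneOrder:
    """Turn a gene list into a signed gene order.

    Per sequence, occurrences are sorted by start; genes sharing a start are
    ordered longer-first, then by gene id, so the output is deterministic.
    """
    per_seq: dict[str, list[Gene]] = {}
    for gene in genes:
        per_seq.setdefault(gene.seq_id, []).append(gene)
    orders: dict[str, list[Occurrence]] = {}
    for seq_id, seq_genes in per_seq.items():
        seq_genes.sort(key=lambda g: (g.start, -(g.end - g.start), g.gene_id))
        orders[seq_id] = [
            Occurrence(g.family, +1 if g.strand == "+" else -1, g.gene_id)
            for g in seq_genes
        ]
    return GeneOrder(genome_id=genome_id, orders=dict(sorted(orders.items())))


def filter_empty_scaffolds(order: GeneOrder) -> tuple[GeneOrder, int]:
    """Drop sequences with zero occurrences; return (filtered, removed count)."""
    kept = {sid: occs for sid, occs in order.orders.items() if occs}
    return GeneOrder(order.genome_id, kept), len(order.orders) - len(kept)


def restrict_to_shared(
    ref: GeneOrder, target_families: set[str], max_copy: int = 10
) -> GeneOrder:
    """Project a reference order onto the target's family content.

    Occurrences of families absent from the target are deleted (tolerating
    lineage-specific insertions/deletions).  Families whose total copy number
    in this reference exceeds ``max_copy`` are removed entirely (damping
    repeat-like duplications).  Survivors keep their relative order and signs,
    so the result is a subsequence of the input — the operation is idempotent.
    """
    if max_copy < 1:
        raise ValueError(f"max_copy must be >= 1, got {max_copy}")
    counts = ref.family_counts()
    orders = {
        sid: [
            occ
            for occ in occs
            if occ.family in target_families and counts[occ.family] <= max_copy
        ]
        for sid, occs in ref.orders.items()
    }
    return GeneOrder(ref.genome_id, orders)
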