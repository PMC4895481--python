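"""Shared fixtures: tiny hand-checkable instances and file writers."""

from __future__ import annotations

from pathlib import Path

import pytest

from scaffolink.adjacency import reference_adjacencies
from scaffolink.formats import LinkageMap, MapEntry
from scaffolink.gene_orders import GeneOrder, Occurrence, restrict_to_shared


def make_order(genome_id: str, seqs: dict[str, list[str]]) -> GeneOrder:
    """Build a GeneOrder from signed family tokens like '+a' / '-b'."""
    orders = {}
    for seq_id, tokens in seqs.items():
        occs = []
        for i, tok in enumerate(tokens):
            sign = 1 if tok[0] == "+" else -1
            occs.append(Occurrence(tok[1:], sign, f"{genome_id}.{seq_id}.{i}"))
        orders[seq_id] = occs
    return GeneOrder(genome_id, orders)


def make_map(map_id: str, rows: list[tuple[str, str, str, float]]) -> LinkageMap:
    """rows: (lg_id, marker_id, scaffold_id, position_cM)."""
    entries = [MapEntry(map_id, lg, m, s, p) for lg, m, s, p in rows]
    entries.sort(key=lambda e: (e.lg_id, e.position_cm, e.marker_id))
    return LinkageMap(map_id, entries)


@pytest.fixture
def toy1():
    """The three-scaffold worked example: two strong links, one chain."""
    target = make_order(
        "T", {"S1": ["+a", "+b"], "S2": ["+c", "+d"], "S3": ["+e"]}
    )
    r1 = make_order("R1", {"c1": ["+a", "+b", "+c", "+d", "+e"]})
    r2 = make_order("R2", {"c1": ["+a", "+b", "+x", "+c", "+d", "+e"]})
    r3 = make_order("R3", {"c1": ["+a", "+b", "-d", "-c", "+e"]})
    families = target.families()
    refs = [
        (g.genome_id, reference_adjacencies(restrict_to_shared(g, families)))
        for g in (r1, r2, r3)
    ]
    weights = {"R1": 1.0, "R2": 1.0, "R3": 1.0}
    return target, refs, weights


@pytest.fixture
def toy_gff(tmp_path: Path):
    """A two-gene GFF3 with a family table, on disk."""
    gff = tmp_path / "two.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "s1\ttest\tgene\t100\t200\t.\t+\t.\tID=g1\n"
        "s1\ttest\tgene\t300\t400\t.\t-\t.\tID=g2\n"
    )
    fam = tmp_path / "families.tsv"
    fam.write_text("g1\ta\ng2\tb\n")
    return gff, fam
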