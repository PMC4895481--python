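"""Readers and writers for every on-disk representation the scaffolder touches.

All genomic coordinates are 0-based half-open in memory; GFF3 and AGP keep
their native 1-based inclusive convention on disk.  Dialects:

* GFF3 v3 gene annotations (read, via :mod:`gffutils`);
* gene-family table: 2-column TSV ``gene_id<TAB>family_id``, header optional;
* scaffold lengths: FASTA ``.fai`` index or 2-column TSV ``seq_id<TAB>length``;
* linkage maps: TSV with header ``map_id lg_id marker_id scaffold_id
  position_cM``; one file may carry several maps (e.g. male and female);
* phylogenetic tree: newick (read, via :mod:`dendropy`);
* scaffold links: TSV ``ext_a ext_b weight genomes`` with extremities written
  ``SCAFFOLD:5p`` / ``SCAFFOLD:3p`` and supporting genomes semicolon-joined;
* super-scaffolds: AGP v2.1 (write and read back);
* per-linkage-group map text: one block per group, ordinal + scaffold per line.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import gffutils

from .errors import DataError

AGP_GAP_TYPE = "scaffold"
AGP_EVIDENCE = "align_genus"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """A gene occurrence with a family assignment.

    Coordinates are 0-based half-open; ``strand`` is ``"+"`` or ``"-"``.
    """

    gene_id: str
    family: str
    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.family:
            raise DataError(f"gene {self.gene_id!r}: empty family id")
        if not self.start < self.end:
            raise DataError(
                f"gene {self.gene_id!r}: start {self.start} not < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneReadResult:
    genome_id: str
    genes: list[Gene]
    n_dropped: int


@dataclass(frozen=True)
class MapEntry:
    map_id: str
    lg_id: str
    marker_id: str
    scaffold_id: str
    position_cm: float


@dataclass
class LinkageMap:
    """One genetic map (e.g. the male or the female map): cM-positioned
    markers grouped by linkage group, each marker tied to a scaffold."""

    map_id: str
    entries: list[MapEntry] = field(default_factory=list)

    def by_lg(self) -> dict[str, list[MapEntry]]:
        groups: dict[str, list[MapEntry]] = {}
        for e in self.entries:
            groups.setdefault(e.lg_id, []).append(e)
        return groups

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# lengths
# ---------------------------------------------------------------------------

def read_sequence_lengths(path: str | Path) -> dict[str, int]:
    """Read a seq_id -> length table from a FASTA .fai or a 2-column TSV.

    A .fai has five tab-separated columns; only the first two are used.
    """
    path = Path(path)
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(f"{path}:{lineno}: expected at least 2 columns")
            seq_id, text = fields[0], fields[1]
            if lineno == 1 and not text.lstrip("-").isdigit():
                continue  # header row
            try:
                value = int(text)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: bad length {text!r}") from exc
            if value <= 0:
                raise DataError(f"{path}:{lineno}: non-positive length for {seq_id}")
            if seq_id in lengths:
                raise DataError(f"{path}:{lineno}: duplicate seq id {seq_id!r}")
            lengths[seq_id] = value
    return lengths


def write_sequence_lengths(lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id in sorted(lengths):
            fh.write(f"{seq_id}\t{lengths[seq_id]}\n")


# ---------------------------------------------------------------------------
# family table + GFF3
# ---------------------------------------------------------------------------

_FAMILY_HEADER_TOKENS = {"gene_id", "gene", "id", "family", "family_id", "fam"}


def read_family_table(path: str | Path) -> dict[str, str]:
    """Read the gene -> family TSV.  A header row is tolerated; a gene id
    mapped to two different families is an error."""
    path = Path(path)
    families: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(f"{path}:{lineno}: expected 2 columns")
            gene_id, family = fields[0].strip(), fields[1].strip()
            if lineno == 1 and gene_id.lower() in _FAMILY_HEADER_TOKENS:
                continue
            if gene_id in families and families[gene_id] != family:
                raise DataError(
                    f"{path}:{lineno}: gene {gene_id!r} assigned to conflicting "
                    f"families {families[gene_id]!r} and {family!r}"
                )
            families[gene_id] = family
    return families


def write_family_table(families: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfamily_id\n")
        for gene_id in sorted(families):
            fh.write(f"{gene_id}\t{families[gene_id]}\n")


def _locate_malformed_gff_line(path: Path) -> int | None:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(">"):
                continue
            if len(line.split("\t")) != 9:
                return lineno
    return None


def read_gff_genes(
    gff3_path: str | Path,
    family_table: str | Path,
    genome_id: str,
    feature_type: str = "gene",
) -> GeneReadResult:
    """Read genes of ``feature_type`` from a GFF3 file and attach families.

    Genes with no family assignment (or no usable strand) are dropped and
    counted.  GFF3 1-based inclusive coordinates become 0-based half-open.
    Output is sorted by (seq_id, start) and stable across runs.
    """
    gff3_path = Path(gff3_path)
    families = read_family_table(family_table)
    with open(gff3_path) as fh:
        has_features = any(
            line.strip() and not line.startswith(("#", ">")) for line in fh
        )
    if not has_features:
        return GeneReadResult(genome_id=genome_id, genes=[], n_dropped=0)
    bad_line = _locate_malformed_gff_line(gff3_path)
    if bad_line is not None:
        raise DataError(f"{gff3_path}: unparseable GFF line {bad_line}")
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        lineno = _locate_malformed_gff_line(gff3_path)
        if lineno is not None:
            raise DataError(f"{gff3_path}: unparseable GFF line {lineno}") from exc
        raise DataError(f"{gff3_path}: failed to parse GFF3: {exc}") from exc

    genes: list[Gene] = []
    n_dropped = 0
    for feature in db.features_of_type(feature_type):
        gene_id = feature.attributes.get("ID", [feature.id])[0]
        family = families.get(gene_id)
        if family is None or feature.strand not in ("+", "-"):
            n_dropped += 1
            continue
        genes.append(
            Gene(
                gene_id=gene_id,
                family=family,
                seq_id=feature.seqid,
                start=feature.start - 1,
                end=feature.end,
                strand=feature.strand,
            )
        )
    genes.sort(key=lambda g: (g.seq_id, g.start, -(g.end - g.start), g.gene_id))
    return GeneReadResult(genome_id=genome_id, genes=genes, n_dropped=n_dropped)


def write_gff_genes(genes: Iterable[Gene], path: str | Path, source: str = "scaffolink") -> None:
    """Write genes as GFF3 ``gene`` features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.seq_id}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# linkage maps
# ---------------------------------------------------------------------------

_MAP_COLUMNS = ["map_id", "lg_id", "marker_id", "scaffold_id", "position_cM"]


def read_linkage_maps(path: str | Path) -> list[LinkageMap]:
    """Read linkage maps from the TSV dialect; one :class:`LinkageMap` per
    distinct map id, entries grouped by linkage group and sorted by cM."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MAP_COLUMNS:
            raise DataError(
                f"{path}: expected header {_MAP_COLUMNS}, found {header}"
            )
        rows: list[MapEntry] = []
        seen: set[tuple[str, str]] = set()
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise DataError(f"{path}:{lineno}: expected 5 columns")
            map_id, lg_id, marker_id, scaffold_id, pos_text = fields
            try:
                pos = float(pos_text)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: bad cM {pos_text!r}") from exc
            if not math.isfinite(pos) or pos < 0:
                raise DataError(f"{path}:{lineno}: negative or non-finite cM {pos}")
            key = (map_id, marker_id)
            if key in seen:
                raise DataError(
                    f"{path}:{lineno}: duplicate marker {marker_id!r} in map {map_id!r}"
                )
            seen.add(key)
            rows.append(MapEntry(map_id, lg_id, marker_id, scaffold_id, pos))

    maps: dict[str, list[MapEntry]] = {}
    for entry in rows:
        maps.setdefault(entry.map_id, []).append(entry)
    result = []
    for map_id in sorted(maps):
        entries = sorted(
            maps[map_id], key=lambda e: (e.lg_id, e.position_cm, e.marker_id)
        )
        result.append(LinkageMap(map_id=map_id, entries=entries))
    return result


def write_linkage_maps(maps: Sequence[LinkageMap], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MAP_COLUMNS) + "\n")
        for m in maps:
            for e in m.entries:
                fh.write(
                    f"{e.map_id}\t{e.lg_id}\t{e.marker_id}\t{e.scaffold_id}\t"
                    f"{e.position_cm:g}\n"
                )


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def read_newick_tree(path: str | Path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise DataError(f"{path}: failed to parse newick: {exc}") from exc


# ---------------------------------------------------------------------------
# links TSV
# ---------------------------------------------------------------------------

def format_extremity(scaffold_id: str, side: str) -> str:
    return f"{scaffold_id}:{side}"


def parse_extremity(text: str) -> tuple[str, str]:
    scaffold_id, _, side = text.rpartition(":")
    if side not in ("5p", "3p") or not scaffold_id:
        raise DataError(f"bad extremity {text!r}")
    return scaffold_id, side


def write_links_tsv(links, path: str | Path) -> None:
    """Write accepted/candidate links (``CandidateLink`` objects)."""
    with open(path, "w") as fh:
        fh.write("ext_a\text_b\tweight\tgenomes\n")
        for link in links:
            fh.write(
                f"{format_extremity(link.ext_a.scaffold_id, link.ext_a.side)}\t"
                f"{format_extremity(link.ext_b.scaffold_id, link.ext_b.side)}\t"
                f"{link.total_weight:.6g}\t"
                f"{';'.join(sorted(link.support))}\n"
            )


def read_links_tsv(path: str | Path) -> list[dict]:
    """Read a links TSV into plain dicts (extremity pairs, weight, genomes)."""
    path = Path(path)
    out: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["ext_a", "ext_b", "weight", "genomes"]:
            raise DataError(f"{path}: bad links header {header}")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise DataError(f"{path}:{lineno}: expected 4 columns")
            out.append(
                {
                    "ext_a": parse_extremity(fields[0]),
                    "ext_b": parse_extremity(fields[1]),
                    "weight": float(fields[2]),
                    "genomes": fields[3].split(";") if fields[3] else [],
                }
            )
    return out


# ---------------------------------------------------------------------------
# AGP 2.1
# ---------------------------------------------------------------------------

def chain_object_name(members: Sequence[tuple[str, str]]) -> str:
    """Deterministic AGP object name: sorted member scaffold ids joined."""
    return "_".join(sorted(sid for sid, _ in members))


def write_agp(
    chains,
    lengths: dict[str, int],
    out: str | Path,
    gap_size: int = 100,
) -> None:
    """Write chains as AGP v2.1 objects.

    Component lines are type W with the chain's orientations; inter-scaffold
    gaps are type U (size ``gap_size``, gap_type "scaffold", linkage "yes",
    evidence "align_genus").  Object coordinates are 1-based and contiguous.
    """
    if gap_size < 0:
        raise DataError(f"gap_size must be >= 0, got {gap_size}")
    lines: list[str] = ["##agp-version\t2.1"]
    for chain in sorted(chains, key=lambda c: chain_object_name(c.members)):
        obj = chain_object_name(chain.members)
        pos = 1
        part = 1
        for idx, (sid, orient) in enumerate(chain.members):
            if idx > 0 and gap_size > 0:
                lines.append(
                    f"{obj}\t{pos}\t{pos + gap_size - 1}\t{part}\tU\t{gap_size}\t"
                    f"{AGP_GAP_TYPE}\tyes\t{AGP_EVIDENCE}"
                )
                pos += gap_size
                part += 1
            if sid not in lengths:
                raise DataError(f"scaffold {sid!r} missing from length table")
            length = lengths[sid]
            lines.append(
                f"{obj}\t{pos}\t{pos + length - 1}\t{part}\tW\t{sid}\t1\t{length}\t{orient}"
            )
            pos += length
            part += 1
    Path(out).write_text("\n".join(lines) + "\n")


def read_agp(path: str | Path):
    """Parse an AGP file back into chains (ids, order, orientations).

    Returns a list of :class:`scaffolink.adjacency.Chain` with empty
    internal-link lists (AGP does not carry the supporting evidence).
    """
    from .adjacency import Chain

    path = Path(path)
    objects: dict[str, list[tuple[int, str, str]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise DataError(f"{path}:{lineno}: expected 9 AGP columns")
            obj, _, _, part, ctype = fields[0], fields[1], fields[2], fields[3], fields[4]
            if ctype in ("N", "U"):
                continue
            if ctype != "W":
                raise DataError(f"{path}:{lineno}: unsupported component type {ctype!r}")
            if obj not in objects:
                objects[obj] = []
                order.append(obj)
            objects[obj].append((int(part), fields[5], fields[8]))
    chains = []
    for obj in order:
        parts = sorted(objects[obj])
        members = tuple((sid, orient) for _, sid, orient in parts)
        chains.append(Chain(members=members, internal_links=()))
    return chains


# ---------------------------------------------------------------------------
# map text
# ---------------------------------------------------------------------------

def write_map_text(orders: dict[str, list[tuple[str, str]]], path: str | Path) -> None:
    """Write per-linkage-group consensus orders as plain text: a block per
    group headed by the group id, then one ``ordinal<TAB>scaffold`` per line.
    Only the putative order is represented; inter-scaffold distances are not."""
    with open(path, "w") as fh:
        first = True
        for lg in sorted(orders):
            if not first:
                fh.write("\n")
            first = False
            fh.write(f"{lg}\n")
            for ordinal, (sid, _orient) in enumerate(orders[lg], 1):
                fh.write(f"{ordinal}\t{sid}\n")
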