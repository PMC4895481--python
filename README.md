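# scaffolink

Comparative scaffolding for draft genome assemblies: infer which scaffolds
were neighbours before fragmentation from conserved gene adjacencies in
related genomes, anchor the resulting super-scaffolds into male/female
genetic linkage maps, and merge both maps into a consensus per-chromosome
scaffold order by topological sort.

Fragmented fish assemblies (the motivating case is a draft teleost genome
with thousands of scaffolds and partial SNP-based linkage maps) carry two
complementary sources of long-range information that sequence data alone
does not: gene order conserved across related species, and recombination
maps. `scaffolink` combines both, and ships a rearrangement simulator so the
whole pipeline can be exercised and scored against ground truth with no
external downloads.

## Method

Each genome is reduced to **signed gene orders**: per chromosome or
scaffold, the coordinate-ordered list of gene-family symbols, signed by
strand. In breakpoint-graph notation a gene *g* has two extremities,
*g*<sup>h</sup> (head) and *g*<sup>t</sup> (tail); on a chromosome
consecutive genes meet in an **adjacency** {right(*x<sub>i</sub>*),
left(*x<sub>i+1</sub>*)} with right(+*g*) = *g*<sup>h</sup>, left(+*g*) =
*g*<sup>t</sup>, and signs swapping the two.

* Reference orders are **projected** onto the target's family content:
  families absent from the target are deleted (insertion/deletion
  tolerance), and families exceeding a copy cap (default 10) in a reference
  are removed from it entirely (duplication damping). No unique-gene-content
  filtering is needed.
* A target scaffold exposes one gene endpoint at each end (5′ and 3′). When
  two exposed endpoints of different scaffolds form an adjacency in
  reference genome *G*, that is a candidate join supported by *G* with
  weight 1/*d*(target, *G*), the inverse patristic distance on the input
  phylogeny (weight 1.0 everywhere if branch lengths are absent).
* Candidates seen in at least `min_genomes` references (default 2) enter a
  **maximum-weight matching** on scaffold extremities — each extremity joins
  at most one link — which resolves all conflicts globally and
  deterministically. Accepted links are stitched into oriented chains;
  cycles are broken at their weakest link.
* Chains are assigned to the linkage group holding a ≥ 2/3 majority of
  their pooled male+female markers. Per map and group, chains are ranked by
  mean marker cM; consecutive ranks contribute precedence edges to a
  directed graph. Conflicting edges are removed (lowest marker support
  first), and Kahn's **topological sort** — tie-broken by mean cM — emits
  the consensus scaffold order. Only ordinal positions are reported, since
  no evidence fixes inter-scaffold distances.

Assembly quality metrics (N50/N90 as the standard cumulative-sum
definitions, length-composition tables) are included under `stats`.

## Worked example

Simulate a study (seven genomes on a fish-like phylogeny, 19 chromosomes,
~1,000 gene families, ~150 scaffolds, noisy partially-overlapping maps),
run the full pipeline, and score it against the recorded truth:

```
$ scaffolink simulate --out-dir study --seed 7
simulated 154 scaffolds, 135 true adjacencies -> study

$ scaffolink run --target-gff study/target.gff3 \
    --refs study/ref_Fugu.gff3 --refs study/ref_Tetraodon.gff3 \
    --refs study/ref_Medaka.gff3 --refs study/ref_Stickleback.gff3 \
    --refs study/ref_Zebrafish.gff3 --refs study/ref_Coelacanth.gff3 \
    --families study/families.tsv --tree study/tree.nwk \
    --lengths study/lengths.tsv --maps study/maps.tsv --out-dir out
target_scaffolds        154
candidate_links         136
accepted_links          133
chains                  21
placed_chains           21
coverage_pct            100.0

$ scaffolink evaluate --links out/links.tsv --truth study/truth.json
inferred        133
truth           135
correct         133
precision       1.0000
recall          0.9852
```

Of the 135 scaffold adjacencies destroyed by fragmentation, 133 are
recovered with no false joins: every accepted link is a true pre-breakage
neighbour pair, and the two missed ones lost their flanking-gene evidence to
simulated rearrangements. The 154 scaffolds collapse into 21 chains, all
placed into linkage groups; `out/consensus_map.txt` lists the consensus
order per group, `out/super_scaffolds.agp` the joined super-scaffolds
(AGP 2.1), and `out/run_manifest.json` the per-stage counts.

Inputs are standard formats: GFF3 annotations, a two-column gene→family
TSV, newick, a five-column linkage-map TSV and a lengths TSV or FASTA
`.fai`. `infer-links`, `anchor` and `order` run the stages separately;
`scaffolink run --config run.cfg` reads `key = value` configuration with
flags taking precedence.

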