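# Methods

## Model and assumptions

`scaffolink` treats scaffolding as an inference on gene orders. The only
homology input is a gene→family table; the package never infers orthology
itself. Genomes become signed sequences of family symbols per
chromosome/scaffold ("decided by scaffold boundaries": each scaffold is its
own sequence, so adjacencies never span an assembly gap). Evidence for a
join between two scaffold ends is the existence, in a related genome, of an
adjacency between the two gene endpoints those ends expose. The working
assumptions are:

* rearrangement breakpoints are approximately random relative to assembly
  breakpoints, so a conserved adjacency across independent lineages is far
  likelier to reflect the ancestral (and target) state than convergent
  rearrangement;
* gene content differences (insertions, deletions, low-copy duplications)
  are common and must be tolerated, which projection plus the copy cap
  handles without discarding multi-copy families outright;
* chromosomes are linear (cyclic join sets are always broken).

## Stages and rules

**Projection.** A reference occurrence survives if its family occurs in the
target and its family's total copy number in that reference is ≤
`max_copy` (default 10). Projection preserves order and signs, and is
idempotent. The copy cap, rather than a unique-content filter, keeps
low-copy paralogs as evidence while suppressing repeat-like families; the
cutoff of 10 marks the scale at which a family stops being positionally
informative.

**Phylogenetic weights.** A reference genome supports a candidate with
weight 1/(patristic distance to the target). Closer genomes have had less
time to rearrange, so their adjacencies are stronger evidence. If any
branch length is missing the weights fall back to 1.0 uniformly, keeping
the method usable on topology-only trees.

**Candidates.** With terminal window *k* (default 1), each scaffold end
exposes the outward-facing endpoints of its outermost min(*k*, len)
occurrences; a match at offsets (*o*<sub>a</sub>, *o*<sub>b</sub>)
contributes weight·δ^(*o*<sub>a</sub>+*o*<sub>b</sub>) with δ = 0.5. A
genome counts at most once per candidate (its best-decay match). *k* = 1 is
the strict breakpoint-formalism default; *k* > 1 is an opt-in robustness
knob for scaffolds whose terminal gene is target-specific. Candidates
joining the two ends of one scaffold are excluded — they would circularize
it.

**Selection.** Candidates need support from at least `min_genomes` = 2
genomes (one genome's adjacency can be a lineage-specific rearrangement;
two independent witnesses is the weakest multi-witness rule) and weight ≥
`min_weight` = 0. The surviving conflict graph (vertices = scaffold
extremities, edges = candidates) gets a maximum-total-weight matching. Ties
between equal-weight matchings resolve to the lexicographically smallest
sorted edge list, computed exactly: edges are forced greedily in
lexicographic order, keeping each one only if a maximum matching of the
residual graph still attains the optimum (networkx `max_weight_matching`
per connected component; equality tolerance 1e-9).

**Chains.** Accepted links plus scaffolds form paths and possibly cycles;
each cycle loses its lowest-weight link (tie: lexicographic extremity
pair). Orientation propagates from the entry side (entering via 5′ = "+");
the canonical form of a chain is the lexicographically smaller of itself
and its reverse-complement. Unlinked scaffolds become singleton chains.

**Anchoring.** A chain's marker tally pools both maps over its member
scaffolds; it is placed on a linkage group holding ≥ 2/3 of its markers
(tolerates one stray marker on small tallies without accepting 50/50
conflicts), else unplaced as "ambiguous", or "no_markers" when empty.

**Ordering.** Per map and linkage group, placed chains with ≥ 1 marker in
that map are ranked by mean marker cM; consecutive distinct mean values
contribute directed edges (provenance: map, min marker count of the two
chains, cM gap). Equal means contribute nothing. Consecutive-rank edges
only — the transitive closure is the same as all-pairs, the graph is
smaller, and removal provenance stays attributable. Cycles (male/female
disagreements) are resolved by repeatedly removing, from some cycle, the
edge with the lowest marker support, then smallest cM gap, then
lexicographic endpoints; chain-internal edges are never removable, and a
cycle consisting only of them is an error (the chains themselves are
inconsistent). Kahn's algorithm with a (mean cM over both maps, chain id)
priority emits a deterministic consensus; chains flatten to member
scaffolds, singletons with orientation "?" since nothing orients them.
Output positions are ordinals only: nothing in the inputs measures the
physical or genetic distance between consecutive scaffolds.

**Coverage.** Linkage-group coverage = 100 × (bases in placed chains) /
(total assembly bases), to 0.1 %. The pipeline also logs the baseline
covered by marker-bearing scaffolds alone, so the gain contributed by
homology joins is visible.

**Metrics.** N50/N90 use the standard convention: sort descending, return
the first length at which the cumulative sum reaches the fraction
(ties inclusive). Lengths below the first composition-bin edge are reported
in an explicit underflow bin, never dropped.

## Simulator

The generator emulates the study design end to end: a root genome of
single-copy signed families on 19 chromosomes evolves along a seven-leaf
fish-like tree (one target + six references; coelacanth outgroup, target
basal among the teleosts) by Poisson-distributed events per branch —
inversion, translocation, fusion, fission, deletion, insertion of novel
families, tandem duplication. The target leaf is fragmented at random
inter-gene positions (Poisson(7) breaks per chromosome, ≈ 150 scaffolds at
the default 1,000 families), recording every broken adjacency as ground
truth. Two maps ("male", "female") place `markers_per_scaffold` = 2 markers
per scaffold at true-ordinal × 1 cM spacing, with per-map dropout 0.25,
Gaussian positional noise (sd 0.4 cM, truncated at 0) and adjacent-pair
swaps with probability 0.05. Default event rates (per unit branch length:
inversion 16, translocation 3, deletion/insertion/duplication 6 each,
fusion/fission 0.4) give a typical branch (~0.25 substitutions-equivalent)
a handful of events. A fixed seed reproduces every stage bit-for-bit.

Synthetic coordinates put genes on a fixed 10 kb pitch, so scaffold length
is linear in gene count. What the simulator does **not** emulate: gene-free
scaffolds and unequal gene density, dispersed (non-tandem) duplication,
assembly chimerism, marker genotyping error that moves a marker across
linkage groups, and real recombination-rate heterogeneity. Passing tests
therefore demonstrate algorithmic correctness and robustness to the modeled
noise, not performance on any particular real assembly.

## Verification design and problem sizes

Tests check each stage against independent oracles: the matching against
exhaustive enumeration over matchings (200 random instances of ≤ 12
extremities), Nx statistics against a brute-force scan (500 random
multisets), candidate/chain construction against hand-unrolled examples,
and the whole pipeline against simulator truth. The no-divergence,
noise-free limit must recover links at precision = recall = 1.0 and the
exact true order per linkage group. The moderate-divergence regression
test (expected 5 inversions + 1 translocation + 2 indels per branch, 20
seeds at 1,000 families / 19 chromosomes) was calibrated once at those
generator conditions; its bounds are mean precision ≥ 0.95, mean recall ≥
0.90, per-seed standard deviations ≤ 0.05 (measured: 0.993 ± 0.010 and
0.966 ± 0.015). The acceptance script uses 10 seeds at the default
conditions, sizes chosen so the whole suite runs in seconds while keeping
≈ 150 scaffolds per instance — large enough for every conflict type to
occur.

## Numerical and degenerate-case choices

* Weight comparisons use an absolute tolerance of 1e-9 (weights are sums of
  inverse distances, magnitude ~1–10).
* Equal mean-cM values are tied with the same tolerance and produce no
  precedence edge.
* Genes sharing a start coordinate order longer-first, then by id;
  all other ties throughout break lexicographically, making every artifact
  byte-reproducible.
* Empty inputs are legal wherever a tally can be zero (empty GFF3 → empty
  gene list; full marker dropout → empty maps); Nx metrics of an empty set
  are an error.
* Palindromic reference adjacencies (x.head–x.head) are supported; a
  candidate may pair two extremities exposing the same endpoint.

## Known limitations

* Link inference sees only terminal genes (window 1 by default); a scaffold
  whose end is annotation-poor contributes no evidence.
* The copy cap is per reference genome and global per family; a family both
  repeat-like in one genome and informative in another is only dropped
  where it is inflated, but within one genome no positional subsetting is
  attempted.
* Map integration orders chains, not scaffolds-within-unlinked-chains:
  scaffolds of one chain always stay contiguous even if markers hint at an
  interleaving (chain evidence is deliberately trusted over weak map
  edges).
* Coverage percentages depend on the lengths table covering the whole
  assembly; scaffolds absent from it are an error, not silently skipped.
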