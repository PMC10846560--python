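# Methods

## Problem setting and assumptions

The pipeline ranks proteins by their likelihood of mediating crosstalk
between two disease categories on an undirected, simple PPI network. It
rests on the guilt-by-association premise: proteins associated with a
phenotype cluster in network neighborhoods, so propagating a seed signal
outward ranks plausible new associations. Three further assumptions are
baked in: the interactome is treated as a single static graph (no tissue
or condition specificity), node identifiers are opaque gene symbols (one
symbol = one node; no isoform or cross-database resolution), and seed
lists are trusted as curated positives with uniform weight 1.

## Propagation algorithms

The four ranking algorithms follow the GUILD family of topology-based
prioritizers. The published descriptions name the algorithms but not their
update equations, so the rules below are explicit, standardized surrogates
written for testability — this package is a reimplementation, not the
original C++ binaries, and makes no claim of bit-identical numerics.

With s₀ the seed indicator and N(v) the neighbors of v:

* **netshort** — edge weight w(u,v) = 1/(1 + s₀(u) + s₀(v)); raw score
  raw(v) = Σ over seeds t ≠ v of 1/d_w(v, t), where d_w is the weighted
  shortest-path distance and unreachable seeds contribute 0. Every seed is
  then pinned to the maximum raw score: a phenotype must not rank its own
  curated seeds below its predictions (relevant for small seed sets, where
  a seed's own raw score counts only the *other* seeds).
* **netzcore** — raw(v) after i synchronous rounds of
  s_{k+1}(v) = mean_{u∈N(v)} s_k(u) (isolated nodes keep s₀), z-scored
  per node against the same statistic on R degree-preserving rewired
  replicates: z(v) = (raw − μ_null)/σ_null, with z = 0 wherever σ_null = 0
  (a rigid null carries no information; avoiding the division keeps such
  nodes neutral rather than infinite). The replicates are generated by
  repeated double-edge swaps and depend only on topology, so one ensemble
  is shared across all phenotypes of a run.
* **netscore** — within each of r repetitions, i rounds of
  s_{k+1}(v) = (1−λ)·s_base(v) + λ·Σ_{u∈N(v)} s_k(u)/deg(u); after each
  repetition the accumulated scores are min–max rescaled and become the
  new base. Re-anchoring lets information travel beyond i hops without
  the geometric blow-up of an undamped walk.
* **netcombo** — each component table standardized to zero mean and unit
  variance (a constant table contributes a zero vector), averaged
  elementwise, min–max rescaled. This is the consensus score used by the
  pipeline (`score_phenotype`).

Every final table is min–max scaled to [0, 1]; an all-equal table maps to
a uniform 0.5 so that downstream thresholds behave sanely in degenerate
cases.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `repetitions` (r) | 3 | netscore outer repetitions |
| `iterations` (i) | 2 | message-passing rounds per repetition / netzcore rounds |
| `damping` (λ) | 0.5 | netscore mixing weight, dimensionless in [0, 1] |
| `null_replicates` (R) | 100 | rewired replicates in the netzcore null |
| `rewire_swaps_per_edge` | 10 | double-edge swaps attempted per edge |
| `rng_seed` | required | no silent default; every run names its seed |

r·i = 6 effective hops cover the diameter scale of a scale-free
interactome; R = 100 keeps the null mean/std stable to a few percent;
10 swaps per edge is the conventional mixing budget for degree-preserving
randomization.

## Subnetwork extraction

A phenotype network contains the seeds, the ⌈f·|V|⌉ top-scoring nodes
(f = 0.02 by default, counted over the full node set — seeds compete in
the same pool), and the linkers: nodes outside that selection adjacent to
**at least two** selected nodes. "At least two" rather than "exactly two"
is deliberate: linkers are connectors, and an exact-2 rule would
arbitrarily drop better-connected ones. Role precedence is
seed > top > linker. An optional `max_linkers` cap keeps only the
highest-scoring linkers. Ties anywhere are broken by lexicographic protein
id so every selection is deterministic.

## Overlap crosstalk

The overlap of two phenotype networks lives on the intersection of their
node sets; a shared protein's overlap score is the mean of its two parent
scores. The overlap edge set is the union of the parents' edges restricted
to shared nodes (a connected view; an intersection variant is exposed).
Candidates exclude proteins that are seeds in *either* parent — seeds are
literature-curated, and the ranking is after novelty. Because propagation
scores every node, the overlap score extends network-wide:
`pairwise_score_ranking` ranks all non-seed proteins of the interactome by
the pairwise mean score, which is the statistic used for recovery
benchmarks (the extracted overlap subnetworks at synthetic scale hold only
a handful of candidates, too few for stable rank statistics).

## Global Network and dual scoring

Merging takes set-theoretic unions of nodes and edges, records each
protein's originating phenotypes, and projects them to a category label
("CVD", "CD&OS", "CVD&CD&OS", …, joined in canonical CVD, CD, OS order;
multiplicity within a category is ignored). Centralities are normalized:
degree deg(v)/(n−1), betweenness scaled by 2/((n−1)(n−2)), so values are
comparable across network sizes. Central proteins are the union of the
per-group top-k lists (k = 5) by degree and by betweenness over the
OS-containing category groups — the union reading matches reporting the
two measures as parallel columns.

The dual score per protein uses the per-category maxima:
cvd_max, cd_max, os; os_excluded = (cvd_max + cd_max)/2;
os_included = (cvd_max + cd_max + os)/3. Algebraically
Δ = os_included − os_excluded = (os − os_excluded)/3, hence |Δ| ≤ 1/3 for
scores in [0, 1]. Central proteins with |Δ| ≥ 0.1 (inclusive — the weakest
faithful reading of "affected by 0.1", configurable) are the refined,
stress-sensitive set. Interactors of the centrals are classified from
their origin categories as cvd_only / cd_only / both; neighbors appearing
only in the OS network are reported as os_only rather than silently
merged. Topology is summarized by the unweighted average shortest path on
the largest connected component and the mean local clustering coefficient
(degree < 2 nodes contribute 0); an edgeless graph reports path length 0
with a warning.

## Enrichment

Over-representation is the one-sided hypergeometric upper tail
P(X ≥ overlap) of the query against each gene set (sets intersected with
the universe; sets with < 3 surviving members are skipped), corrected by
Benjamini–Hochberg step-up. BH is a deliberate substitution for web-tool
multiple-testing schemes whose thresholds are not reproducible offline;
the scientific claim — *which* sets are enriched — is robust to that
choice. The default universe is the Global Network node set (the scored
context in which the interactors were classified); the full interactome
can be passed instead. The three settings enrich the refined centrals
together with their cvd_only, cd_only, and both-interactors respectively.

## Synthetic data: what it emulates, and what it does not

The generator produces a preferential-attachment backbone (n = 1000,
m = 3 by default, giving mean degree ≈ 6, typical of a filtered PPI
network), one dense module per phenotype (size 40, intra-module density
0.3 reached by *adding* edges — planting never rewires, so the scale-free
backbone is preserved), seeds sampled as 40% of each module, and 10
crosstalk bridges: free nodes wired with 2 edges into one CVD module and 2
into one CD module. Bridge edges target the module's *seed* members —
seeds are guaranteed to be in the extracted selection, which is what makes
a bridge an eligible linker of both phenotypes by construction; wiring to
arbitrary members leaves linker eligibility to chance. Module membership
overlaps between categories at a controllable rate (0.1 by default), and
the OS module, planted last, draws its overlap from both disease
categories, mimicking stress-related proteins straddling the comorbidity.
Two layouts are canned: `headline` (2 CVD + 1 CD + 1 OS) and
`paper_shaped` (5 CVD + 2 CD + 1 OS, the 8-phenotype design with its
10 + 7 = 17 overlap pairs).

Passing tests on this fixture show that the pipeline recovers planted
structure of the kind guilt-by-association assumes; they do not show
performance on real interactomes, whose literature-derived seed lists are
biased toward well-studied proteins, whose edges carry study-ascertainment
artifacts, and whose disease modules are far less cleanly delimited than
planted cliques-with-noise. Absolute topology statistics (path length,
clustering) are properties of whichever interactome is analyzed and are
not comparable across data sets.

## Numerical and reproducibility choices

* All randomness flows from one explicit seed; derived child seeds are
  drawn below 2³¹ and recorded in the run manifest.
* Graphs are written with sorted node/edge insertion and TSV rows sorted
  lexicographically, so identical runs produce byte-identical files; the
  manifest stores a sha256 checksum per output and no timestamps.
* Ties in every selection (top fraction, candidate ranking, centrality
  lists) break by lexicographic protein id.
* Degenerate inputs: constant score tables scale to uniform 0.5; rigid
  null ensembles give z = 0; graphs admitting no double-edge swap are
  returned unchanged with a warning; empty overlaps are valid empty
  networks.
* Benchmark problem sizes: oracle-equivalence checks run on exhaustive
  small-graph families (all connected graphs up to 6 nodes for the
  shortest-path scorer, random graphs up to 12 nodes for centralities and
  linkers); end-to-end recovery runs on the n = 1000 fixtures above, and
  the determinism check on an n = 400 variant of the same design.

## Known limitations

* The propagation rules are faithful surrogates of the published
  algorithm descriptions, not a port; rankings can differ from the
  original implementation in detail.
* No tissue filtering, edge confidence weights, or directionality.
* The per-category maximum in the dual score makes the refinement
  sensitive to a single high-scoring phenotype; with many phenotypes per
  category the maxima saturate.
* Enrichment treats gene sets as flat lists; no ontology topology or
  redundancy reduction.
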