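# crosstalk

Disease-crosstalk prioritization on protein–protein interaction (PPI)
networks.

`crosstalk` is for computational biologists who want to find proteins that
mediate comorbidity between two disease categories — the motivating case is
the interplay between cardiovascular disease (CVD) phenotypes and cognitive
dysfunction (CD) phenotypes under oxidative stress (OS), as in vascular
cognitive impairment — starting from nothing more than an interactome edge
list and per-phenotype seed gene lists. Everything is reproducible from a
single RNG seed, and a synthetic-interactome generator with planted ground
truth lets you validate the whole pipeline without any proprietary database
snapshot.

## Method

1. **Seed propagation (guilt-by-association).** Each phenotype's curated
   seed proteins are initialized at s₀(v) = 1 (0 elsewhere) and every node
   of the interactome G = (V, E) is scored by four ranking algorithms:
   - *netshort*: edges are cheapened near seeds, w(u,v) = 1/(1 + s₀(u) + s₀(v)),
     and raw(v) = Σ_{seeds t≠v} 1/d_w(v,t) over weighted shortest-path
     distances;
   - *netzcore*: synchronous neighbor averaging of s₀, z-scored against the
     same averaging on degree-preserving rewired null networks;
   - *netscore*: damped message passing s ← (1−λ)·s_base + λ·A D⁻¹ s with
     periodic re-anchoring of s_base;
   - *netcombo*: the consensus — standardize the three tables, average,
     rescale. All final tables are min–max scaled to [0, 1].
2. **Subnetwork extraction.** A phenotype network is the induced subgraph
   over its seeds, the top 2% of nodes by score, and the *linkers* — nodes
   adjacent to ≥ 2 selected nodes.
3. **Overlap crosstalk.** For each CVD×CD (and ×OS) pair, shared proteins
   are scored by the mean of their two phenotype scores (the *overlap
   score*) and non-seed candidates are ranked by it.
4. **Global Network.** All phenotype networks are merged; nodes are labeled
   by originating categories (CVD, CD, OS and "&"-combinations), ranked by
   normalized degree and betweenness centrality per category group, and
   given a dual score: os_excluded = (cvd_max + cd_max)/2 versus
   os_included = (cvd_max + cd_max + os)/3. The shift
   Δ = os_included − os_excluded (|Δ| ≤ 1/3) refines the central proteins
   to the stress-sensitive ones at |Δ| ≥ 0.1.
5. **Enrichment.** The refined centrals are tested with their CVD, CD and
   shared interactors against GMT gene sets (hypergeometric upper tail,
   Benjamini–Hochberg FDR).

See `docs/methods.md` for formulas, defaults and design rationale.

## Worked example

Run the full pipeline on the 8-phenotype synthetic study design (a
1000-node scale-free interactome with 5 CVD + 2 CD + 1 OS planted modules
of 40 proteins and 10 planted crosstalk bridges):

```python
from crosstalk import RunConfig, run_pipeline
from crosstalk.config import SyntheticConfig

config = RunConfig(
    rng_seed=1,
    out_dir="scratch/demo",
    synthetic=SyntheticConfig(preset="paper_shaped"),
)
result = run_pipeline(config)
print(f"phenotype networks: {len(result.networks)}")
print(f"overlap networks:   {len(result.overlaps)}")
t = result.topology
print(f"Global Network:     {t.node_count} nodes, {t.edge_count} edges")
print(f"  avg shortest path (LCC): {t.average_shortest_path_length:.2f}")
print(f"  avg clustering:          {t.average_clustering_coefficient:.2f}")
print(f"central proteins:   {len(result.central_proteins)} "
      f"-> refined by |delta| >= 0.1: {len(result.refined_proteins)}")
```

prints

```
phenotype networks: 8
overlap networks:   17
Global Network:     369 nodes, 2180 edges
  avg shortest path (LCC): 3.30
  avg clustering:          0.27
central proteins:   19 -> refined by |delta| >= 0.1: 12
```

The 17 overlap networks are the 10 CVD×CD pairs plus the 7 pairings of
each disease phenotype with oxidative stress. The 19 central proteins are
the union of the per-group top-5 lists by degree and by betweenness among
the OS-related category groups; 12 of them shift by at least 0.1 when the
OS score enters the average — these are the stress-sensitive crosstalk
hubs, which the pipeline then carries into enrichment. Every output
(scores, GraphML networks, candidate tables, manifest with checksums) is
written under `out_dir`, and rerunning with the same seed reproduces the
files byte for byte.

The same pipeline is available from the shell:

```bash
crosstalk run --config run.yaml          # full pipeline from YAML
crosstalk simulate --seed 7 --out fix/   # synthetic fixture bundle
crosstalk score --edges fix/edges.tsv --seeds fix/seeds.tsv \
    --categories fix/categories.tsv --phenotype CVD1 --seed 7 --out CVD1.tsv
crosstalk subnetwork --edges fix/edges.tsv --scores CVD1.tsv --out CVD1.graphml
```

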