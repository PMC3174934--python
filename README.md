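# gtlinker

Post-process functional-enrichment output into non-redundant,
significance-ranked **metagroups** of genes and co-annotated biological
terms.

Enrichment tools emit long, redundant lists of *GeneTerm-sets* — elements
`E = (G, A, p)` pairing a set of genes `G` with the terms `A` they are all
annotated with and the enrichment p-value `p`. `gtlinker` condenses such
lists in four deterministic steps:

1. **Generic-term filter** — per annotation space, terms whose gene count
   exceeds `mean + n·σ` (default `n = 4`) are tagged as generic
   (promiscuous); elements annotated *only* with generic terms are dropped.
2. **Reciprocal clustering** — each element becomes a gene-occurrence 1/0
   vector over the query list plus a p-value component weighted by the query
   size `M`; cosine distances are clustered with Ward linkage, the tree is
   cut at 20% of its depth (escalating in 10% steps until a metagroup
   forms), and clusters sharing non-generic terms are greedily merged.
3. **Complete cover** — inside each metagroup, elements are visited from the
   least significant and removed when their genes *and* terms are already
   covered by the remaining elements; the union of genes and terms is
   preserved exactly.
4. **Scoring** — each metagroup gets a hypergeometric p-value on its union
   genes (BH-FDR adjusted across metagroups), a silhouette width, a diameter
   and a similarity coefficient (gene-only distances); output is ranked by
   adjusted p, then silhouette.

The package also ships the enrichment front-end (singular SEA and
closed-itemset concurrent MEA over GMT annotation catalogs), pair-based
evaluation statistics (Rand accuracy, Jaccard coefficient,
precision/recall/F-score, noise injection), and a seeded synthetic
benchmark generator with planted gene modules so everything is testable
offline.

## CLI

```bash
# generate a synthetic benchmark (GMT spaces, query list, reference GMT)
gtlinker simulate --seed 4 --noise 0.2 --out-prefix sim

# enrichment only: GeneTerm-set TSV from a query gene list
gtlinker enrich --query sim.query.txt --spaces sim.spaces.gmt \
    --mode mea --out elements.tsv

# full pipeline (query list or precomputed GeneTerm-set TSV as --input)
gtlinker link --input sim.query.txt --spaces sim.spaces.gmt \
    --out-prefix result --json

# compare a found grouping against a reference partition
gtlinker evaluate --found result_groups.gmt --reference sim.reference.gmt

# everything from a YAML config
gtlinker run --config config.yaml
```

`link` writes `<prefix>.metagroups.tsv` (one row per metagroup: id, gene
and element counts, adjusted p, silhouette, diameter, similarity
coefficient, member genes and source-prefixed terms) and
`<prefix>.elements.tsv` (long-format element table). Reports are
byte-identical across reruns.

Annotation catalogs are GMT files; set ids of the form `GO-BP::GO:0007165`
declare the annotation source (one space per source). A two-column
`gene<TAB>term` loader and a plain-text universe file (one gene per line)
are also supported.

## Python API

```python
from gtlinker import (
    SyntheticDesign, generate_space, inject_noise,
    QueryContext, concurrent_enrichment, link_elements,
)
from gtlinker.annotation_space import generic_policies

design = SyntheticDesign(n_universe=600, modules=((12, 6),) * 5, seed=1)
spaces, reference, truth = generate_space(design)
genes = sorted(set().union(*reference.groups.values()))
query = QueryContext.from_genes(
    inject_noise(genes, reference.universe, 0.2, seed=1), design.n_universe
)
elements = concurrent_enrichment(query, spaces)
metagroups, counts = link_elements(
    elements, query, spaces, generic_policies(spaces)
)
```
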