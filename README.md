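# condmap

Analysis pipeline for **conditional genetic-interaction screens**: quantitative
interaction (S-score) screens run under untreated and perturbed (DNA-damaging)
conditions, scored for interactions that *change* with the condition.

The package covers the full path from replicate-level scores to a
condition-specific interaction network:

- **io_formats** — long-format score TSVs, curated interaction tables,
  term→gene annotation tables, SIF / edge-table network export.
- **synthetic_data** — a screen simulator with planted condition-specific
  effects and a confusion-matrix scorer, so every stage is testable without
  external data.
- **differential_scoring** — concentration pooling (3+3 → 6 replicates),
  per-cell mean S-scores, differential scores `D = S_drug − S_untreated`,
  per-batch standardization to Z, two-sided p-values under a theoretical or
  robust empirical (median/MAD) null, Benjamini–Hochberg q-values, and strict
  `q < 0.05` interaction calling. Fixed S-score thresholds (−2.4 / 2.0) are
  available for per-condition summaries.
- **profile_analysis** — pairwise-complete Pearson correlation of
  (query, condition) profiles, agglomerative clustering on `1 − r`, and
  two-sided two-sample Kolmogorov–Smirnov comparisons.
- **network_analysis** — network construction with drug/direction-annotated
  edges, incidence counts, per-query interaction sets, three-way
  shared/exclusive partitions, and one-sided Fisher (hypergeometric
  upper-tail) overlap tests against the 1536-gene screened universe.
- **enrichment** — hypergeometric term enrichment against the screened
  background with Benjamini–Hochberg correction.
- **cli** — `condmap` command-line front end.

A curated table of 569 significant conditional interactions for the
`RTT107`/`SLX4`/`HRQ1` screens ships with the package
(`condmap/data/conditional_interactions.tsv`) and backs the network and
overlap analyses out of the box.

## Command line

```sh
# simulate a screen with planted effects, then call conditional interactions
condmap simulate --seed 7 --n-arrays 1536 --out runs/sim
condmap call --scores runs/sim/scores.tsv --out runs/calls

# differential table (D, Z, p, q) only
condmap score --scores runs/sim/scores.tsv --out runs/scored

# network, counts and overlap tests from the packaged curated table
condmap network --out runs/network

# profile correlations, dendrogram, KS tests
condmap correlate --scores runs/sim/scores.tsv --out runs/corr

# term enrichment against a custom background
condmap enrich --genes genes.txt --annotations ann.tsv --background bg.txt --out runs/enr
```

Every stage writes TSV outputs plus a `manifest.json` (config echo, input
checksums, package version). Defaults — `alpha=0.05`, static thresholds
−2.4/2.0, universe 1536, per-batch standardization, experiment-wide
empirical-null FDR — can be overridden with a YAML config file via
`--config`.

## Python API

```python
import condmap as cm

cfg = cm.SimulationConfig(n_queries=3, n_arrays=1536, planted_fraction=0.01, seed=3)
tensor, truth = cm.generate_screen(cfg)
means = cm.mean_scores(cm.merge_concentrations(tensor))
table = cm.build_differential_table(means)          # D, Z, p, q per (query, array, drug)
calls = cm.call_significant(table, alpha=0.05)
print(cm.truth_confusion(calls, truth, n_triples_tested=len(table)))

net = cm.build_network(cm.read_interaction_calls())  # packaged curated table
print(cm.count_summary(net).total)                   # 569
```
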