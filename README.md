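# tcrconv

Convergence-cluster analysis of TCRβ repertoires, as a tested, reusable
pipeline:

- **repertoire_io** — VDJtools-style tab-delimited clonotype tables; singleton
  removal, seeded down-sampling (multivariate hypergeometric), pooling.
- **generative_model** — a D-less V(D)J recombination model (trimmed V +
  N-insert + trimmed J, productive = in-frame, stop-free, C…F/W) serving as
  Monte-Carlo null, exact-enumeration oracle on toy configurations, and
  synthetic-data generator (null repertoires, planted convergent clusters,
  paired DP/non-DP subsets, replicate count matrices).
- **alice_stat** — the neighbor-enrichment test: observed same-V/J,
  same-length Hamming-≤1 neighbor counts vs. a Poisson expectation from the
  recombination null; Benjamini–Hochberg correction (α = 0.001 default).
- **cluster_graph** — CDR3 similarity graphs (equal length, Hamming ≤ 1;
  V/J-agnostic edges), connected-component clusters, cluster weights,
  composite multi-sample graphs, GML export.
- **annotation** — three-rule specificity matching (exact CDR3 or one central
  same-group substitution; HLA-restriction compatibility), cluster-level
  label propagation, cumulative specific frequencies (bulk vs.
  cluster-related).
- **repertoire_stats** — clonality (1 − normalized Shannon–Wiener),
  top-N cross-repertoire clonotype matching.
- **expansion** — replicate-based differential clonotype expansion: a
  self-contained negative-binomial exact test (median-of-ratios
  normalization, method-of-moments dispersion with trended shrinkage),
  calling at FDR < 0.01 and log2FC > 1.
- **synthetic_data** — one-call synthetic study with complete ground truth.
- **pipeline / cli** — `tcrconv` CLI chaining prep → alice → cluster →
  annotate → stats → expand with a YAML config and a reproducibility
  manifest.

## CLI

```sh
# synthetic study with ground truth (deterministic from the seed)
tcrconv make-study --seed 1 --out-dir study/

# individual stages
tcrconv prep study/FFT.txt --remove-singletons --out prepped.tsv
tcrconv alice prepped.tsv --model study/model.yaml --n-sim 100000 --out hits.tsv
tcrconv cluster prepped.tsv --hits hits.tsv --node-set hits+neighbors \
    --gml clusters.gml --out clusters.tsv
tcrconv annotate clusters.tsv prepped.tsv --db study/specificity_db.tsv \
    --hla "A*02:01,A*26:01" --out labeled.tsv
tcrconv stats prepped.tsv --out stats.tsv
tcrconv expand study/counts.tsv --design study/design.tsv \
    --focal-condition IL21combo --out expansion.tsv

# or everything from one config
tcrconv run config.yaml
```

A minimal `config.yaml`:

```yaml
samples:
  - {path: study/DP.txt, sample_id: DP, subset: DP}
  - {path: study/nonDP.txt, sample_id: nonDP, subset: non-DP}
model_path: study/model.yaml
db_path: study/specificity_db.tsv
counts_path: study/counts.tsv
design_path: study/design.tsv
focal_condition: IL21combo
out_dir: run/
n_sim: 100000
seed: 1
```

Defaults follow the analysis conventions: α = 0.001, n_sim = 5,000,000 per
VJ pair in 20 batches, FDR < 0.01 with log2FC > 1, singleton removal on.
Scale `n_sim` down for quick runs.

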