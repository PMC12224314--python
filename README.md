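# duomics

Substrate-discriminant screening and cross-omic association for **unpaired**
proteome / microbiome experiments.

Salivary-pellicle proteomes (LFQ intensities with detection-limit
missingness) and oral-microbiome ASV tables (zero-inflated, right-skewed
counts) are measured in *separate* experiments on shared substrates
(dentine, enamel, titanium). This package implements the statistical
pipeline that links them:

- **Preprocessing** — a single global imputation constant for below-detection
  protein intensities, chosen to minimize |Pearson's second skewness
  coefficient| of the pooled distribution (bisection on `mean − median` when
  it changes sign, bounded search otherwise); the offset-log transform
  `x → log10(α + x)` with the closed-form offset
  `α = 10^(⌊log10(min nonzero)⌋ − 1)`; proportion scaling; annotation-label
  aggregation; replicate averaging.
- **Discriminant screening** — per-feature Kruskal–Wallis tests (midranks,
  tie correction, chi-square tail), strict p-threshold screening (0.05 for
  proteins, 0.01 for microbes), canonical LDA with shrinkage-regularized
  within-scatter (handles 110 features × 9 cases), standardized
  coefficients, biplot coordinates, and complete-linkage heatmap ordering.
- **Association** — substrate-matched Cartesian "bootstrap" pairing of the
  unpaired experiments, all-pairs Pearson correlation and plug-in mutual
  information on equal-frequency bins, ridge-regularized CCA with
  interset/intraset structure correlations, thresholded chord-diagram edge
  lists, top-k signed correlations, and 2h→24h microbe–microbe association.
- **Diversity** — Shannon index, Bray–Curtis dissimilarity, PCoA, and the
  per-taxon log2 median-proportion differential.
- **Synthetic data** — a generator with planted substrate effects, signed
  protein→microbe couplings, detection-limit censoring, and zero-inflated
  negative-binomial counts, with full ground truth for parameter-recovery
  tests.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle agreement,
parameter recovery across 25 seeded runs, end-to-end determinism), one test
per criterion.

## CLI

```bash
# write a synthetic fixture (tables, designs, annotation, ground truth)
duomics simulate --seed 1 --outdir fixtures/

# full pipeline on a simulated fixture (or on file inputs via --config)
duomics run-all --seed 1 --outdir results/run1

# individual stages
duomics impute --protein fixtures/protein.tsv --design fixtures/protein_design.tsv --out imputed.tsv
duomics screen --table imputed.tsv --design fixtures/protein_design.tsv --threshold 0.05 --out kw.tsv
duomics associate --x-table imputed.tsv --x-design fixtures/protein_design.tsv \
    --y-table fixtures/asv_2h.tsv --y-design fixtures/asv_2h_design.tsv --out assoc.tsv
```

`run-all` writes a deterministic report bundle (detection summary,
imputation/offset JSON, KW tables, LDA models and biplot coordinates for
both the three-substrate and the natural-vs-artificial grouping, heatmap
orders, association/edge/top-3 tables, CCA models with interset/intraset
coordinates, diversity outputs, and a manifest). The bundle is
byte-identical across repeats at a fixed seed.

A YAML config can replace the defaults; all thresholds (0.05, 0.01, 0.7,
0.8, 0.5, top-3) live in the config, never in stage code:

```yaml
simulate:
  n_proteins: 200
  n_asvs: 100
thresholds:
  kw_protein: 0.05
  kw_microbe: 0.01
  corr_high: 0.7
transform:
  skewness_scale: raw       # or log10
  alpha_bracket: floor      # or round
seed: 1
```

## Layout

```
src/duomics/
  data_model.py   typed tables, designs, TSV I/O, detection summaries
  synthetic.py    ground-truth generator
  preprocess.py   imputation, offset-log, scaling, aggregation
  screen.py       Kruskal-Wallis, LDA, biplots, heatmap ordering
  association.py  pairing, Pearson/MI, CCA, edge lists
  diversity.py    Shannon, Bray-Curtis, PCoA, log2 median differential
  pipeline.py     run-all orchestration and report bundle
  cli.py          click-based CLI
```
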