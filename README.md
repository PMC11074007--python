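# pepset

Competitive peptide set testing for differential protein expression,
directly from peptide-level quantitation.

Bottom-up proteomics measures proteins indirectly through peptides.
Instead of collapsing peptides into protein abundances before testing,
`pepset` asks, per protein, whether the moderated t-statistics of its
peptides differ from those of the rest of the peptidome — a competitive
set test that accounts for inter-peptide correlation through a variance
inflation factor, `VIF = 1 + (m − 1)·ρ`. The package provides:

- **`pepset.io`** — wide peptide TSV ingestion (MaxQuant `peptides.txt`
  or generic dialect), contaminant/reverse filtering, the 70% missingness
  rule, log2 transform, and per-sample median centering.
- **`pepset.linmod`** — per-peptide OLS for a two-group contrast and
  empirical-Bayes moderated t-statistics (moment matching of log
  variances, optional lowess trend on a covariate).
- **`pepset.correlation`** — the common within-protein inter-peptide
  correlation ρ̂ = σr²/(σr² + σe²) from a REML-fitted mixed model with a
  random sample intercept (closed form on complete data, profiled
  likelihood with missing cells), plus the Wu-style standardized
  residual-mean estimator as a complete-data alternative.
- **`pepset.settest`** — the competitive set test itself: set mean vs
  background mean of peptide t-statistics, SD or 1.4826-scaled-MAD
  background scale, VIF-inflated set variance, BH/BY adjustment. With
  ρ = 0 and the SD scale it reduces exactly to the ordinary pooled
  two-sample t-test.
- **`pepset.aggregate`** — comparator workflows: summed-intensity and
  robust-regression (Huber IRLS) peptide→protein rollups followed by a
  protein-level moderated t-test, optionally with a log-peptide-count
  variance trend.
- **`pepset.simulate`** — block-equicorrelated synthetic peptidomes and a
  factorial harness reporting Type I error, power, FDR and TPR per
  method with Monte-Carlo standard errors.

## CLI

Run the set test on a peptide table plus a design file
(`sample<TAB>group` TSV):

```sh
pepset test --peptides peptides.tsv --design design.tsv \
    --contrast treated,control \
    --dialect generic --min-frac 0.7 --normalize median_center \
    --cor-method mixed --scale mad --adjust BH \
    --out results.tsv
```

Defaults (`mixed` correlation, `mad` scale, `BH` adjustment) correspond
to the recommended variant. `--dialect maxquant` reads MaxQuant
`peptides.txt` directly and drops `CON__`/`REV__` hits. Every run writes
a `*.manifest.json` with parameters, input checksums and the seed.

Run a simulation scenario from YAML:

```sh
pepset simulate --config scenario.yaml --out metrics.tsv
```

```yaml
# scenario.yaml
proteome: [[1400, 3], [360, 10], [40, 30]]
rho: 0.05
n_samples: 30
de_fraction: 0.05
effect: 0.5
n_reps: 200
seed: 7
methods: [pepsettest_mad, sum_limma, robust_limma]
alpha: 0.05
```

## Library use

```python
from pepset import (read_peptide_table, read_design, filter_missing,
                    normalize_columns, run_pepsettest, results_to_frame)

table = normalize_columns(filter_missing(
    read_peptide_table("peptides.txt", dialect="maxquant"), 0.7))
design = read_design("design.tsv", contrast=("treated", "control"))
results = run_pepsettest(table, design)   # mixed rho, MAD scale, BH
print(results_to_frame(results).head())
```
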