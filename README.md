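# tspminimax

Individualized two-class tumor classification from gene-expression data.
The pipeline has two stages:

1. **Feature selection** — *k* top-scoring gene pairs (k-TSP): pairs are
   scored by the between-class difference of the relative frequency that one
   gene's intensity falls below the other's, with a rank-based tie-break,
   and the top *k* gene-disjoint pairs define a *k*-dimensional
   pair-difference feature space.
2. **Local minimax kernel prediction** — for each queried patient, a
   contextual Tikhonov (kernel-ridge) estimator is fit on an optimally
   chosen neighborhood of nearest training points.  It returns a
   probability-of-cancer estimate, a finite-sample root-MSE bound, a
   one-sided 90% confidence interval, and a **confident-predictability
   (CP)** decision: the patient is CP at level *p* when the interval lies
   entirely inside [0, p] or [1 − p, 1].  The bound and interval width
   depend only on predictor geometry, never on training labels.

A 3-nearest-neighbor baseline with an asymptotic CP rule (unanimous
neighbors), a leave-one-out cross-validation driver with per-fold feature
re-selection, and synthetic-data generators (planted-pair cohorts and
model-class probability functions for bound/coverage validation) are
included.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
interval endpoints, dual-path algebraic equivalence, Monte-Carlo bound
validity and interval coverage, label-independence of uncertainty,
brute-force selection equivalence, and a planted-signal end-to-end run).

## CLI

Expression matrices are plain delimited text (header = sample ids, first
column = gene ids) or GCT v1.2; labels are a two-column file
(`sample_id<TAB>0|1`).

```sh
# select a 10-pair model
tspminimax select --expr expr.tsv --labels labels.tsv --k 10 --out model.json

# predict one patient against the remaining cohort
tspminimax predict --expr expr.tsv --labels labels.tsv --query S42 \
    --sigma-fraction 0.5 --alpha 0.5 --beta 0.10 --p 0.35 --e 0.0

# leave-one-out cross-validation (kernel or knn)
tspminimax loocv --expr expr.tsv --labels labels.tsv --method kernel \
    --sigma-fraction 0.5 --p 0.35 --e 0.0 --out report.tsv

# bandwidth sweep, cohort-wide or per patient
tspminimax sweep --expr expr.tsv --labels labels.tsv --grid 0.2:1.4:0.1 \
    --out curve.tsv
tspminimax sweep --expr expr.tsv --labels labels.tsv --query S42 \
    --grid 0.2:1.4:0.1 --out patient_curve.tsv

# synthetic data
tspminimax simulate --scenario cohort  --seed 1 --out sim/
tspminimax simulate --scenario pkalpha --seed 1 --out sim/
```

## Notes on conventions

- Value ties count as "not less" in pair frequencies; ranks are per gene
  across patients with average ranks on ties.
- Selected pairs are oriented so the class-0 frequency is the larger one;
  candidate ordering breaks exact score ties lexicographically by gene ids.
- Normal quantiles are computed exactly (the 90% one-sided multiplier is
  `sqrt(1 + z_0.10^2) ≈ 1.6255`).
- The confidence interval is formed around the *unclipped* adjusted
  estimate, then clipped to [0, 1]; class calls always use the unadjusted
  estimate at threshold 0.5.
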