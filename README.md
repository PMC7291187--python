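# sice

Missing-data imputation for mixed-type tables: a chained-equations engine
with pluggable univariate methods, and **single-dataset pooling** of the
multiple imputations — mode pooling for categorical columns, mean pooling
for numeric ones.

## The problem

Health records, surveys and registry extracts routinely arrive with holes.
Deleting incomplete rows wastes data and biases estimates; filling every
hole with the column mean or mode (*single imputation*) understates the
uncertainty of the filled values and shrinks variances. *Multiple
imputation by chained equations* (MICE) fixes the bias by drawing *m*
plausible values per missing cell — each incomplete variable is regressed
on all the others and re-imputed in turn, cycling until *m* completed
datasets are produced — but then the analyst must carry and analyse *m*
datasets, which is impractical on large tables.

This package implements the hybrid: run the chained-equations engine to get
the stack of *m* candidate values x_i^1, …, x_i^m per missing cell *i*,
then collapse the stack back to **one** completed dataset,

- categorical column: x_i ← mode(x_i^1, …, x_i^m) — the most frequent of
  the *m* draws (ties broken toward the level more frequent among the
  observed values, then by schema level order);
- numeric column: x_i ← (1/m) Σ_j x_i^j — the arithmetic mean of the draws.

Mean pooling comes with a guarantee: because the root-mean-square error is
a norm, RMSE(pooled) ≤ (1/m) Σ_j RMSE(chain j) — the pooled prediction is
never worse than the average chain, on any data.

Six univariate kernels are provided for the chained engine: predictive mean
matching (`pmm`, imputations confined to observed values), Bayesian linear
regression (`blr`, posterior-predictive draws), binary logistic regression
(`logreg`), multinomial logistic regression (`polyreg`), linear
discriminant analysis (`lda`) and a regression/classification tree with
leaf sampling (`cart`), plus the single-imputation baselines `mean`,
`median`, `mode` and `random`.

The benchmark loop that quantifies all of this is included: **amputation**
(mask `floor(rate·n)` cells of a fully observed column completely at
random, keeping the truth), imputation, and scoring of the masked cells —
RMSE for numeric targets, confusion-matrix metrics (accuracy, balanced
accuracy, sensitivity, precision, specificity, F-measure) for categorical
ones — together with a generator of synthetic mixed-type health-like
tables with planted, recoverable structure.

## Worked example

```python
from sice import GeneratorConfig, generate_health_like, run_experiment

# 2000-row table: sex (binary), district & diagnosis (nominal), age (numeric);
# age carries a planted linear signal on the nominal columns (R² ≈ 0.5).
table = generate_health_like(GeneratorConfig(n_rows=2000, seed=1))

for method in ("pmm", "blr", "mean"):
    r = run_experiment(table, "age", method, rate=0.10, m=7, seed=1)
    chain = sum(c["rmse"] for c in r.per_chain) / len(r.per_chain)
    print(f"{method:>4}  pooled RMSE = {r.pooled['rmse']:.2f}   "
          f"mean per-chain RMSE = {chain:.2f}   ({r.n_masked} masked cells)")
```

prints

```
 pmm  pooled RMSE = 10.64   mean per-chain RMSE = 13.91   (200 masked cells)
 blr  pooled RMSE = 9.82   mean per-chain RMSE = 12.91   (200 masked cells)
mean  pooled RMSE = 14.84   mean per-chain RMSE = 14.84   (200 masked cells)
```

200 cells (10% of 2000) of the `age` column were masked and re-imputed.
Mean pooling of seven chained-equations draws cuts the per-chain error by
roughly a quarter (10.6 vs 13.9 years for PMM) and beats the
mean-imputation baseline (14.8) by a wide margin; for the deterministic
`mean` kernel pooling changes nothing, as expected. The same loop on the
binary `sex` column with mode pooling gives accuracy 0.805 and F-measure
0.785 against ~0.5 for majority-class filling.

## Command line

```bash
sice ampute data.csv holes.csv --schema schema.yaml --target age \
     --rate 0.1 --seed 7 --mask-out truth.csv
sice impute holes.csv completed --schema schema.yaml --method pmm \
     --m 7 --seed 7                    # writes completed.csv (pooled)
sice evaluate --truth truth.csv --imputed completed.csv \
     --schema schema.yaml --target age
sice benchmark --n 2000 --method pmm --method mean --replicates 20 \
     --seed 7 --out report.csv
```

Tables are plain CSV (missing cells empty or `NA`); the schema sidecar is
YAML mapping each column to `binary`/`nominal`/`ordinal`/`numeric` with its
ordered level list. `--seed` is mandatory for stochastic subcommands and
every run is bit-reproducible from it.

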