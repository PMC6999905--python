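# nof1serial

Serial t-tests for N-of-1 (single-case) trials with first-order
autoregressive (AR(1)) serial correlation.

Repeated measurements from one individual are rarely independent. This
package implements four t-tests — paired and 2-sample versions for
level-change and rate-change — that account for lag-1 serial correlation
through closed-form variance/bias kernels, effective sample sizes, and
Student-t inference on fractional degrees of freedom. It also provides:

- the bias-corrected lag-1 correlation estimator
  `r = rho_hat + (1 - rho_hat^2)/(m - 1)` with length-weighted pooling
  for 2-sample designs,
- study-planning calculators: expected confidence-interval margin of
  error and detectable effect size at a given power (noncentral-t with
  fractional sample sizes),
- stationary AR(1) and cross-correlated paired AR(1) data generators plus
  Monte Carlo experiments for Type I error, realized-vs-theoretical
  effect sizes, and confidence-interval margin factors,
- the classical ("usual") t-test analogues for comparison, and a small
  set of packaged worked-example datasets.

## Layout

| module | contents |
| --- | --- |
| `nof1serial.ar1_kernels` | closed-form c(rho), b(rho), effective sample size m', and a dense matrix-algebra oracle (test-only) |
| `nof1serial.correlation` | residual construction, lag-1 MLE, bias-corrected estimator, pooling |
| `nof1serial.serial_tests` | the four serial t-tests, usual analogues, Bonferroni change screen |
| `nof1serial.planning` | expected margin, detectable effect size, planning grids |
| `nof1serial.simulation` | AR(1) generators and Monte Carlo experiments |
| `nof1serial.cli_io` | `nof1` command-line interface, CSV readers, report rendering |
| `nof1serial.fixtures` | packaged worked-example series and their published reference values |

## Command line

```sh
# a paired serial level-change test on a CSV of within-pair differences
nof1 test --design paired-level --input diffs.csv --direction greater

# planning: 90% CI margin at m=8, rho=0.4, or the full rho x m grid
nof1 plan --design paired-level --m 8 --rho 0.4 --mode margin
nof1 plan --mode delta --table

# Monte Carlo Type I error for the 2-sample level test
nof1 simulate --design two-sample-level --experiment type1 --m 10 --rho 0.33 --seed 1

# run every applicable test on a packaged example
nof1 fixtures --name patient_1390 --run-all
```

Series CSVs are long format: columns `time` (1..m, gap-free), `series`
(`A`, `B`, or `diff`) and `value`; `--wide` accepts one column per
series. Missing or unequally spaced observations are rejected.

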