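# gpflm

Scalar-on-function regression for a binary (or other quasi-likelihood)
response with several functional predictors and scalar covariates.  The
pipeline is: functional principal component analysis (FPCA) of each densely
observed predictor, variance-threshold (or fixed) truncation, quasi-likelihood
estimation of the truncated model by iteratively reweighted least squares, and
asymptotic inference built on a generalized auto-covariance metric —
including simultaneous confidence bands for the coefficient functions.  A
simulation module generates synthetic data from a fully specified design and
runs Monte-Carlo studies.

## Layout

| module              | contents |
|---------------------|----------|
| `gpflm.fpca`        | `CurveSet`, trapezoidal quadrature, weighted FPCA, truncation selection, scores |
| `gpflm.model`       | link families, design assembly, quasi-score IWLS fit, coefficient-curve reconstruction, pseudo-R², GCV |
| `gpflm.inference`   | generalized covariance `Lambda` and kernel `G`, the `d_G²` metric (coefficient and integral forms), standardized statistics, `nu`-based standard errors, simultaneous bands |
| `gpflm.simulation`  | synthetic-data generator, per-replicate runner, Monte-Carlo study driver |
| `gpflm.io` / `gpflm.cli` | long-format CSV readers/writers, JSON artifacts, `gpflm` command |

## Command line

```bash
# generate a synthetic dataset
gpflm simulate --n 200 --seed 1 --out data/

# fit: FPCA -> truncate -> quasi-likelihood -> bands
gpflm fit --curves data/curves1.csv --curves data/curves2.csv \
          --scalars data/scalars.csv --response data/response.csv \
          --var-threshold 0.9 --alpha 0.05 --ridge 1e-8 --out fit/

# fixed truncation instead of a variance threshold
gpflm fit ... --p 3 --p 5 --out fit/

# Monte-Carlo study (profiles: paper = per-size fixed truncation,
# full = retain all simulated components, threshold = 90% rule)
gpflm study --reps 100 --sizes 50,500,1000 --profile paper --seed 1 --out study/
```

Exit codes: `0` success, `2` input error, `3` non-convergence (suppress with
`--allow-nonconverged`).  Every flag can also be supplied via `--config
config.yaml`; explicit flags win.  All randomness flows from `--seed`.

Functional predictors are long-format CSV (`subject_id,t,value`) with every
subject observed on the same grid; scalar and response tables are CSV keyed
by `subject_id`.  Alignment across files is by id, never by row order.

## A note on the simulation coefficients

The generating coefficient rules are exposed as two constant sets:
`B*_QUADRATIC` (`b_1k = 2k²`, `b_2k = k²`) and `B*_SUMMABLE`
(`b_1k = 2/k²`, `b_2k = 1/k²`).  The quadratic rule, taken literally, breaks
square-summability of the coefficient expansion and produces a linear
predictor with sd ≈ 150 — perfectly separable binary data under which no
finite estimate exists.  The summable rule keeps the design well posed and
closely reproduces the published scalar-coefficient summaries, so it is the
default for `SimConfig`; either can be selected explicitly.
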