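# effcov

Variance estimation and confidence intervals for **effective coverage** of
health services — the product of a service-coverage proportion and a
facility-readiness measure estimated from two independent samples — plus a
Monte-Carlo harness for studying how often each interval method actually
covers the truth.

## The problem

Health-system analyses increasingly report *effective* (quality-adjusted)
coverage: not just the proportion of people in need who contact a service,
but the proportion who contact a service that is ready to deliver it.  With
a household survey for the individuals and a facility assessment for
readiness, the estimate within one stratum (a region × facility-type cell)
is a product of two independent sample proportions,

    p_rf = p_x,rf · p_y,rf ,

aggregated as p_r = Σ_f p_rf within a region and P = Σ_r w_r p_r nationally
(weights w_r proportional to each region's denominator population).  A
product of two noisy proportions is an atypical target for variance
estimation, and naive intervals misbehave near the 0/1 boundary.  `effcov`
implements three methods:

- **Exact (Goodman) method** — for independent Z, M the identity
  `Var(ZM) = (Var Z + (EZ)²)(Var M + (EM)²) − (EZ·EM)²` holds exactly;
  plugging in p(1−p)/n gives a variance estimate, and the CI is the
  symmetric Wald interval p ± 1.96·s.  Bounds can cross 0 or 1 (*invalid*
  intervals); they are reported unclipped and flagged.
- **Delta method** — the estimate is mapped to the logit scale,
  F = logit(p), Var(F) is obtained by a first-order expansion in the logit
  intercepts b = log(n₁/n₀) of the two samples (s_b = √(1/n₀ + 1/n₁)), and
  the interval antilogit(F ∓ 1.96·√Var F) is asymmetric and always strictly
  inside (0, 1).  Undefined when any count cell is empty or full.
- **Parametric bootstrap** — B pairs of Binomial(n_x, p_x)/n_x ×
  Binomial(n_y, p_y)/n_y resamples; the CI is the (2.5, 97.5) percentile
  pair of the products.

Both binary and continuous (bounded-score) readiness measures are
supported; continuous scores contribute Var(ȳ) = s²/n_y on the natural
scale and are resampled from a moment-matched Beta law in the bootstrap.

## Worked example

Generate a small synthetic stratum table (2 regions × 2 facility types,
400 women and 60 facilities per stratum) and estimate national effective
coverage with the exact and delta methods:

```bash
effcov fixtures --regions 2 --facility-types 2 --seed 7 \
    --output strata.csv --n-x 400 --n-y 60
effcov estimate --input strata.csv --output results.csv \
    --methods exact,delta --level national
```

`results.csv` then contains:

```
level,region_id,facility_type,method,point,variance,lower,upper,status
national,,,delta,0.5735816504653004,0.00902426599284608,0.5275438284807672,0.6183785876141985,valid
national,,,exact,0.5735816504653005,0.0005405473049336212,0.5280122909500188,0.6191510099805823,valid
```

Both methods agree on the point estimate — about 57.4% of the population in
need is covered by a ready facility — and give nearly identical 95%
intervals (roughly 52.8%–61.9%) because the estimate is far from the
boundary and the samples are moderately large.  The delta row's `variance`
is on the logit scale, the exact row's on the proportion scale.  Near 0 or 1
the two methods diverge: the exact interval can cross the boundary (status
`invalid_bounds`) while the delta interval stays inside (0, 1) but becomes
strongly asymmetric.

A coverage-probability simulation for a single setting:

```bash
effcov simulate --output grid.csv --reps 10000 --seed 1 \
    --methods exact,delta --config sim.yaml
```

where `sim.yaml` restricts the grid (e.g. `p_x_grid: [0.5]`,
`p_y_grid: [0.5]`, `sample_size_pairs: [[500, 500]]`); the output table
reports, per method, the estimated coverage probability, the number of
removed (degenerate/undefined) iterations and, for the exact method, the
count of invalid intervals.

## Layout

| module          | contents                                              |
|-----------------|-------------------------------------------------------|
| `estimands`     | stratum/region/national point estimates, data types   |
| `exact`         | Goodman variance, Wald CIs, validity classification   |
| `delta`         | logit intercepts, chain-rule gradients, back-transformed CIs |
| `bootstrap`     | parametric percentile bootstrap                       |
| `simulation`    | vectorized Monte-Carlo coverage study                 |
| `io`, `cli`, `fixtures` | delimited-text I/O, `effcov` command, synthetic tables |

See `docs/methods.md` for the statistical details and design choices.
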