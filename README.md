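# netnonind

Monte-Carlo evaluation of statistical corrections for **network
nonindependence arising from social influence**.

## The problem

Health-services and social-network studies routinely regress one node
trait on another — a physician's prescribing rate on their exposure to
continuing education, say — across the members of a social network.  When
traits spread by social influence (each node's value is pulled toward the
values of its direct contacts), the observations are not independent: the
error terms are correlated along network ties.  Influence of this kind
leaves slope estimates unbiased *on average* but makes them far more
variable than i.i.d. theory predicts, so naive tests produce false
positives at several times the nominal rate.  A variety of corrections
are used in the applied literature; this package measures which of them
actually work, under conditions where the network is known exactly and
influence is the only complication.

## The model

Traits start as i.i.d. Gaussian draws per node and take one influence
step toward the neighborhood mean,

&nbsp;&nbsp;&nbsp;&nbsp;*x*ᵢ ← *x*ᵢ + *s*·(mean<sub>j∈N(i)</sub> *x*ⱼ − *x*ᵢ),&nbsp;&nbsp;*s* = 0.5,

sweeping nodes in order, on networks grown by linear preferential
attachment.  Every correction strategy then estimates the slope β in
*y* = *X*β + *e* and tests it at α = 0.05:

| strategy | handles dependence by |
|---|---|
| naive OLS | nothing (baseline) |
| robust (HC1) SEs | heteroscedasticity-consistent sandwich |
| Conley-style SEs | spatial-HAC sandwich on a 2-D network embedding |
| embedding covariates | 5 nonmetric-MDS components as fixed effects |
| community random effects | random intercept per walktrap community |
| network autocorrelation | ML spatial-error model *e* = ρ*We* + υ |
| tree GLS (Pagel's λ) | GLS on a hierarchical-clustering tree |
| dyadic regression | pairwise distances + crossed node random effects |
| subsampling 10/30/50% | OLS on a sparse random node sample |

Under the null every trait diffuses independently, so each method's
rejection rate estimates its Type I error; with trait pairs constructed
at exact correlation *r* (then diffused) it estimates power.

## Worked example

```python
import numpy as np
from netnonind import (generate_pa_network, make_null_dataset, fit_ols,
                       fit_lnam, fit_subsample)

net = generate_pa_network(100, seed=7)          # 100-node PA tree
data = make_null_dataset(net, n_traits=2, seed=7)  # two independent diffused traits
y, x = data.column(0), data.column(1)

for fit in (fit_ols(y, x),
            fit_lnam(y, x, net.adjacency),
            fit_subsample(y, x, 0.1, seed=7)):
    print(f"{fit.method:>12}  slope={fit.slope:+.3f}  se={fit.se:.3f}  p={fit.p_value:.3f}")
```

```
         ols  slope=+0.019  se=0.104  p=0.854
        lnam  slope=-0.022  se=0.104  p=0.832
subsample_10  slope=-0.658  se=0.358  p=0.104
```

The two traits are unrelated by construction; all three methods correctly
fail to reject here, and the 10-node subsample's much larger standard
error (0.358 vs 0.104) shows the power price of subsampling.  Single fits
say little — the interesting quantities are rejection *rates* over many
replications:

```bash
netnonind reproduce table2 --reps 50 --out-dir out/     # scaled-down demo
```

```
        Statistical Correction Applied  Observed Slope Bias    SE  Empirical SD Type I Error
                     Simple Linear Reg               -0.020 0.098         0.142        20.0%
            H-W Robust Standard Errors               -0.020 0.098         0.142        20.0%
                Conley Standard Errors               -0.020 0.097         0.142        20.0%
      Principal Components for Network               -0.022 0.101         0.138        20.0%
Random Effects for Network Communities               -0.025 0.099         0.145        18.0%
                Network Autoregression               -0.007 0.098         0.121        12.0%
           Phylogenetic Autoregression               -0.016 0.097         0.138        16.0%
                     Dyadic Regression                0.007 0.014         0.029        12.0%
                  Subsample Random 10%               -0.034 0.317         0.395         4.0%
                  Subsample Random 30%               -0.054 0.183         0.220         4.0%
                  Subsample Random 50%               -0.025 0.141         0.158        10.0%
```

Slopes are centered on zero (no bias), the estimated SEs (~0.10)
understate the empirical slope SD (~0.14) for every full-data method —
that gap *is* the nonindependence — and only the sparse subsample reaches
a near-nominal Type I error.  At the full 500 replications
(`--reps 500`, the default) the rates stabilize to within about ±2
percentage points.

`netnonind simulate --config cfg.yaml` runs custom experiments from a
YAML config (network size, replication count, methods, diffusion
strength, power correlations); `netnonind network`/`netnonind traits`
generate and convert the underlying files.  Every run writes a
`manifest.json` with the config snapshot and master seed for exact
replay.

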