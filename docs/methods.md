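# Methods

`netnonind` is a Monte-Carlo testbed for a specific statistical failure
mode: **regression between traits that spread by social influence on a
network**.  When a node's trait value is pulled toward the values of its
network neighbors, observations are no longer independent.  Slopes remain
unbiased on average, but their sampling variability is understated by
i.i.d. formulas, so naive tests reject true nulls far more often than the
nominal level.  The package generates data with exactly this structure,
applies eleven correction strategies, and measures each one's slope bias,
standard error, Type I error, and power.

## The data-generating process

**Networks.**  Synthetic networks grow by linear preferential attachment
(Barabási–Albert): each arriving node attaches `edges_per_step` ties
(default 1) to existing nodes with probability proportional to degree.
With one edge per step the network is a random tree — connected, with a
heavy-tailed degree distribution dominated by hubs, the salient features
of real collaboration and referral networks.  Default sizes are 100 nodes
for the main study and 50/914 for the power grid; 914 emulates the scale
of a large regional physician network.  External networks load from
two-column edge-list TSV or GraphML.

**Traits.**  Each trait starts as an i.i.d. standard-normal draw per node.
One influence step then moves every node `step_fraction` (default 0.5) of
the way toward the mean of its direct neighbors.  The default update is an
**in-place sweep in node-index order**: the loop updates node 0, then node
1 using node 0's already-updated value, and so on — the behavior of a
plain scripted loop over nodes, and the reading of the influence rule that
reproduces the published operating characteristics of the naive test (a
false-positive rate of roughly three times nominal on 100-node networks).
A strictly synchronous variant (`update_mode="synchronous"`), in which all
neighbor means use pre-step values, is retained; it induces somewhat
stronger dependence (OLS Type I error ~20% rather than ~14% under
otherwise identical conditions).  Mathematically the synchronous step is
`x ← x + s·(D⁻¹A − I)x`; it preserves the trait mean exactly on regular
graphs and both variants contract the trait variance toward local means.
One step is the default (`n_steps` is configurable).

**Null vs. power conditions.**  Under the null, every trait diffuses
independently, so the true regression slope between any two traits is 0
and every rejection is a false positive.  For power, a trait pair is
constructed with an *exact* realized Pearson correlation `r`
(orthogonalize-and-rotate, so `r` is hit to machine precision rather than
in expectation), then both columns diffuse by the same rule.  Diffusion
applies the same linear smoother to both columns, so the expected
cross-correlation is essentially preserved.

## The eleven strategies

All strategies regress outcome trait `y` on predictor trait `x` and test
the slope two-sided.

1. **Naive OLS** — classical t test, df n−2.  The uncorrected baseline.
2. **Robust (HC1) SEs** — OLS slope with the heteroscedasticity-consistent
   sandwich, small-sample factor n/(n−k); t test.
3. **Spatial-HAC (Conley-style) SEs** — the network is embedded in the
   plane by 2-component nonmetric MDS of geodesic distances; the sandwich
   sums score cross-products of pairs within a distance cutoff, Bartlett
   taper by default.  The default cutoff is the **median nearest-neighbor
   embedded distance**.  This bandwidth choice matters: HAC variance
   estimates are consistent only when the kernel neighborhood is small
   relative to the sample extent, and a generous cutoff (e.g. the median
   of *all* pairwise distances, which covers half the pairs) makes the
   variance estimate noisy enough to reject 10–25% of true nulls even on
   fully independent data, with frequent negative-variance degeneracies.
4. **Embedding components as covariates** — 5-component nonmetric MDS
   coordinates enter the regression as fixed covariates; t test, df n−7.
5. **Community random effects** — walktrap communities (walk length 4, cut
   at maximum modularity) define a random intercept per community; REML
   linear mixed model, Wald z on the slope.
6. **Network autocorrelation (spatial-error) model** — `y = Xβ + e`,
   `e = ρWe + υ` with `W` the raw binary adjacency.  Profile maximum
   likelihood over ρ inside its spectral bounds `(1/λ_min, 1/λ_max)`;
   log-likelihood uses `log|I − ρW| = Σ log(1 − ρλ_i)` from a single
   symmetric eigendecomposition.  Slope SE from the observed information
   (central-difference Hessian over intercept, slope, ρ, σ²); Wald z.
   Row-normalized `W` is available as a sensitivity option.
7. **Tree-based GLS (Pagel's λ)** — the network is collapsed to an
   ultrametric tree by complete-linkage clustering; shared dendrogram
   depth defines a baseline correlation `C₀`, and λ ∈ [0, 1] scales its
   off-diagonal part, `C(λ) = (1−λ)I + λC₀`.  λ is estimated by profile
   ML; the slope is tested by GLS t with df n−2.  λ = 0 recovers OLS
   exactly.  The default dissimilarity fed to the clustering is the
   **Euclidean distance between adjacency rows** (tie profiles) — what a
   distance-then-cluster pipeline produces when handed the tie matrix
   directly; geodesic distances are available
   (`tree_dissimilarity="geodesic"`) and yield a tree that tracks the
   diffusion clusters more closely, hence a lower Type I error (~10% vs
   ~13% under the default study conditions).
8. **Dyadic regression** — every unordered node pair contributes a row
   with `|y_i − y_j|`, `|x_i − x_j|` and a tie indicator; the mixed model
   adds crossed random intercepts for the two member nodes with one shared
   variance.  Because every node pair shares exactly one dyad, the
   incidence Gram matrix is `(n−2)I + J` with closed-form eigenvalues, so
   the profile likelihood over the variance ratio is evaluated exactly in
   O(n²) via the Woodbury identity (no iterative mixed-model solver).
   Wald z on the distance slope.
9-11. **Node subsampling (10/30/50%)** — OLS on a simple random sample of
   `round(f·n)` nodes.  Sparse subsamples contain almost no directly tied
   pairs, restoring approximate independence at a steep cost in power.
   With f = 1 the estimator reproduces OLS bit-for-bit.

Methods 5 and 8 test with Wald z because the underlying mixed-model
machinery provides no exact reference distribution; all simple-regression
methods use t.

## The Monte-Carlo harness

One replication = one network + one trait pair + one fit per method.  For
generated networks a fresh network is drawn per replication (replications
are then fully independent); a file-loaded network is reused, matching the
empirical single-network condition, and trait pairs are taken as disjoint
columns (2k, 2k+1) of one 1000-trait dataset.  Defaults: 500 replications,
α = 0.05.  Per method the summary reports the mean slope (bias against the
true 0), the mean estimated SE, the empirical SD of slopes, and the
rejection proportion (Type I error or power).  Fits that are degenerate,
non-converged, or at a parameter bound are excluded from the rejection
denominator and counted separately; a method failing >5% of replications
is flagged.

Seeding is hierarchical (`SeedSequence`): the master seed spawns one
sequence per replication, which spawns named child seeds (network, traits,
embedding, one per subsample fraction).  Results are bit-reproducible, and
removing methods from a run does not perturb the remaining methods'
replication stream.

## Numerical choices

- ρ, λ and the dyadic variance ratio are optimized by bounded Brent search
  (tolerance 1e−6; 1e−8 for the variance ratio), with endpoint snapping
  when a boundary value is at least as likely.
- Non-positive-definite `C(λ)` candidates are penalized out of the λ
  search; the baseline `C₀` of an ultrametric tree is itself PSD (it is a
  Brownian-motion correlation on the tree).
- Nonmetric MDS starts from the classical (Torgerson) solution and runs
  SMACOF for at most 150 iterations with relative tolerance 1e−5 — with
  the classical start this is converged for 100-node networks while
  keeping a 500-replication study fast; ties in the distance ranks are
  handled by the solver's isotonic regression (average ranks).
- Disconnected node pairs (absent under default tree networks) get
  geodesic distance diameter + 1 before embedding or clustering.
- A perfect fit (zero residual SE) is flagged `degenerate` and reported
  with statistic ±∞, p = 0.
- Subsample sizes round half-up; sampled indices are sorted so the f = 1
  case is arithmetically identical to full-data OLS.

## What the synthetic data does and does not capture

The generator reproduces the features the study isolates: a connected
heavy-tailed network known without error, pure influence (trait values
literally move toward neighbors'), no homophily, no confounding, Gaussian
traits, a single influence step.  Real provider networks add tie
measurement error, homophilous tie formation, unmeasured confounders,
non-Gaussian and longitudinal traits — all absent here by design.  Passing
tests therefore certify the *statistical mechanics* of the corrections
under clean social influence, not their adequacy on any empirical
network; the direction of the published conclusion (only sparse
subsampling achieves near-nominal false-positive rates, at a large power
cost) is what the acceptance checks verify.

## Known limitations

- The community random-effects strategy absorbs genuine community-level
  variance here (communities are detected on the very network the traits
  diffused on), yielding Type I ≈ 11–13% under the default conditions —
  lower, i.e. more favorable to the method, than the published 16.2%,
  which is statistically indistinguishable from that study's naive-OLS
  row.  The discrepancy is documented rather than tuned away.
- The dyadic distance regression carries a small structural positive
  slope bias under diffusion (unequal node variances make both traits'
  pairwise distances co-vary); it is visible as the only positive entry
  in the bias column, here (+0.0035) as in the published table (+0.002).
- Spatial-HAC results are sensitive to the cutoff; only the local
  (nearest-neighbor-scale) bandwidth is calibrated under independence.
- Wald z tests are mildly anticonservative at n = 100 relative to any
  finite-sample reference; df-adjusted alternatives are not implemented.
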