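# Methods

## The prevalence recursion

The deterministic core tracks a single quantity, the prevalence `p_t` of a
maternally inherited symbiont among adults of a host with non-overlapping
generations.  One generation composes two maps.  Vertical transmission with
cytoplasmic incompatibility (CI) and a fecundity effect gives the offspring
prevalence `k` as a rational function of `p_t` (see README for the
formula); a phoretic-vector step then adds `w k (1 − k)` new infections,
i.e. `w` new cases per infected host scaled by the availability of
uninfected hosts.  The model has no sex structure: males and females are
assumed equally likely to be visited by the vector and to transmit or
acquire the infection, so one prevalence suffices.  `w` is interpreted as
the *effective* horizontal-transmission rate — the raw number of new cases
discounted by any reduction in vertical transmission among horizontally
infected females.

Parameters, units and defaults:

| parameter | meaning | range | notes |
|---|---|---|---|
| `μ` | fraction of uninfected ova from infected mothers | [0, 1) | scenario default 0.03 |
| `F` | relative fecundity of infected females | > 0 | 1 = neutral; 1.05 = benefit scenario |
| `H` | relative hatch rate of incompatible crosses | [0, 1] | 1 = no CI; 0.1 = CI scenario |
| `w` | new cases per infected host per generation | ≥ 0 | scenarios use 0, 0.01, 0.06 |

`s_f = 1 − F` and `s_h = 1 − H` are derived on access, never stored, so a
fitness benefit (`F > 1`, negative `s_f`) needs no special casing.  The map
sends [0, 1] into itself for all parameters in these ranges with `w ≤ 1`
(property-tested); for very large `w` the horizontal step could exceed 1,
in which case the value is clipped to 1 with a warning rather than raised —
this keeps sweeps over `w` robust, and the biologically motivated range is
far below the clip.

Numerical conventions: a trajectory is "converged" when successive iterates
differ by less than 1e-10 and "lost" when prevalence falls below 1e-6; the
scenario runner defaults to 1,000 generations (the qualitative outcomes are
insensitive to this; equilibrium-accuracy checks in the tests use 10,000).

## Equilibria and invasion

Clearing the denominator of `step(p) = p` yields a degree-5 polynomial
whose real roots in [0, 1] are the equilibria; roots are polished by Newton
steps on the polynomial, verified against `|step(p) − p| < 1e-10`, merged
when closer than 1e-8, and classified by the central finite-difference
derivative of the map (step 1e-6, clamped to [0, 1] at the edges):
|derivative| < 1 stable, > 1 unstable, within 1e-6 of 1 neutral.  If
polynomial root-finding fails verification the code falls back to bisection
on sign changes over a 10,000-point grid.  The identity map (`μ = 0, F = 1,
H = 1, w = 0`) fixes every point and is reported as a single `degenerate`
fixed point.  With complete incompatibility (`H = 0`) fixation `p = 1` is a
genuine equilibrium and is reported as such.

The invasion growth factor `λ = (1 + w)(1 − μ)F` is the exact
linearisation of the composed map at `p = 0`; CI enters only at order
`p²`, so `λ` is independent of `H`.  `ci_threshold` solves the interior
fixed-point quadratic for `w = 0` analytically and returns its smaller root
— the classical CI invasion threshold — when it lies in [0, 1).

## The individual-based vector model

The mechanism behind `w` is simulated explicitly: each generation a single
effective wasp probes every host independently with probability `v` in a
random order.  Probing an infected host contaminates the wasp; the
contamination lasts for a configurable number of subsequent visits (default
1 — only the next host, matching the observation that the bacterium is
lost when an uninfected host is probed) and a contaminated probe of an
uninfected host establishes infection with probability `τ`.  Only probed
hosts that survive (probability `σ`) reproduce.  By default the vector
never kills its host and survival is folded into establishment (`τσ` per
contaminated probe); a `kill_hosts` mode instead removes probed
non-survivors before reproduction.  Hosts infected within a phase are not
yet contagious during that phase — their titre is still negligible — which
makes the expected number of new cases from a single infected host exactly
`v τ σ` and is what `estimate_w` measures by Monte Carlo.

Within a generation the cohort first reproduces (a binomial draw around the
vertical-map expectation, adding demographic stochasticity) and is then
exposed to the wasp, so the conditional expectation of the recorded
prevalence is exactly `horizontal(vertical(p))`, the deterministic `step`.
Agreement between the ABM mean trajectory and the recursion run at
`w = estimate_w(...)` is assessed pointwise in units of Monte-Carlo
standard error; because the `w` estimate is itself noisy, its standard
error is propagated through the trajectory's finite-difference sensitivity
`∂p_t/∂w` before standardising.  The maximum of ~40 correlated |z| values
is a heavy-tailed diagnostic; the mean |z| is reported alongside it.

## Experiment statistics

*Proportions.*  Point estimates are raw proportions; 95% intervals are
symmetric on the logit scale (`logit(p̂) ± 1.96·√(1/x + 1/(n−x))`) and
back-transformed, which reproduces the asymmetric intervals appropriate for
proportions near the boundary.  Counts of 0 or n have no logit SE and fall
back to exact Clopper–Pearson intervals, flagged `boundary`.  Percentages
are reported to one decimal.

*Heterogeneity LRT.*  Prevalence heterogeneity across groups (generations)
is tested by twice the log-likelihood difference between a per-group and a
common-probability binomial model, each with a replicate-level random
intercept integrated by 15-node adaptive Gauss–Hermite quadrature (the
integrand is re-centred and re-scaled at its Laplace mode per replicate).
df = groups − 1.  When the variance estimate hits zero — the usual case
for truly binomial data — the statistic collapses exactly to the
closed-form fixed-effects G statistic (verified in tests).  At the
persistence-experiment sizes (5 groups × 40 trials, prevalence 0.875) the
chi-square reference is known to be slightly anti-conservative; the
calibration checks measure the realised type-I error directly.

*Trend test.*  The decay of wasp infectivity is tested by a binomial GLM
(logit link) of infected/total on hours since contamination, fitted by
IRLS (statsmodels) with deviance tolerance 1e-8; the Wald z of the slope
is reported and its estimate is cross-checked in tests against a direct
likelihood maximiser.  Complete separation (or an all-boundary fit) sets a
`separation` flag instead of returning a spurious z.

*Fitness comparisons.*  Gaussian traits (development time, fecundity) are
tested by a two-sample t on per-cage means; in the balanced 4+4-cage design
this is the exact likelihood reduction of the linear mixed model with a
replicate random intercept, and gives df = 6.  Ratio traits (immature
survival, offspring sex ratio) use a binomial GLM with arm effect and a
Pearson-based over-dispersion scale (Wald z).  Longevity uses a Cox partial
likelihood stratified by replicate *index* — the contemporaneous infected
and uninfected cages sharing a replicate number form a stratum — with
Breslow handling of ties (the generator's exponential lifetimes are
tie-free in practice); this is a deliberate simplification of a shared
frailty model that preserves the arm contrast without estimating a random
effect.  Stratifying on the eight distinct cages instead would leave the
arm constant within every stratum and the effect inestimable.  All tests
are two-sided at a fixed 95% confidence level.

## Synthetic data

Generators draw one dataset per seeded numpy Generator, so identical
configurations export byte-identical CSVs.  Defaults mirror the laboratory
designs: 106 visited nymphs with outcome probabilities 0.358/0.340/0.302
and infection probability 0.938 among survivors; 5 generations × 4
replicate lines × 10 tested at a constant prevalence 0.875 (midpoint of the
observed 85–90% range — per-generation values are not tabulated, so a
constant is assumed); transmission at 24/48/72/96 h × 4 replicates × 10
with a logistic time course anchored at 0.9 (24 h) and 0.1 (96 h),
reflecting efficient transmission only in the first two days; and 4 cages ×
10 pairs per infection arm for fitness.  Fitness effect sizes are realistic
magnitudes for whitefly at 26 °C, not published values: development 19 d
with infected 1 d faster, fecundity 150 eggs with no arm effect, longevity
exponential (mean 15 d, infected hazard ratio 0.6), immature survival 0.8,
a slight female bias among infected offspring, and replicate-level logit
jitter (SD 0.3) to induce over-dispersion in the ratio traits.

What the generators do *not* emulate: within-cage temporal correlation,
measurement error in infection screening (PCR false negatives), non-logistic
decay shapes, censored lifetimes, and any dependence between traits within
a pair.  Passing calibration on these generators therefore shows the
estimators are correct under their assumed sampling models, not that those
models capture every feature of real cage data.

## Problem sizes used in checks

Calibration experiments use 2,000 simulated persistence experiments for the
type-I error of the heterogeneity LRT, 500 decay experiments for slope
recovery, and 500 fitness experiments for interval coverage; the ABM
agreement check uses 10,000 hosts × 32 replicates × 40 generations with a
60,000-replicate `w` estimate.  Equilibrium accuracy checks iterate the
recursion for 10,000 generations.

## Known limitations

Single strain, no sex or spatial structure, no wasp population dynamics or
host-instar preference, no interspecific transmission.  The heterogeneity
GLMM integrates a single random intercept only; crossed or nested designs
beyond one replicate level are out of scope.  The Cox comparison does not
estimate a frailty variance.  Reported equilibria and thresholds are
model-derived quantities; the underlying experiments published no numeric
equilibria to compare against.
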