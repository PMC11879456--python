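# Methods

## The model

`rtfit` fits the *retarded transient function* (RTF), a phenomenological
model of the response curves typical of cellular signalling: a new steady
state after stimulation, monotone or single-peak behaviour, and delayed
onset.  The response is

    R(t) = signSus · A (1 − e^{−α t}) + signTrans · B (1 − e^{−β t}) e^{−γ t} + b,

a *sustained* component (amplitude `A`, rate `α`) plus a *transient*
component (amplitude `B`, rise rate `β`, decay rate `γ`) and an offset
`b`.  The signs (±1) let the user impose prior knowledge about activation
versus inhibition; left to `auto`, all four combinations are tried during
fitting.

The argument `t` is not the experimental time but a log-domain transform
of it,

    t(treal, τ) = log10(10^{treal·10/T} + 10^τ) − log10(1 + 10^τ),

where `T` is the range of the measurement times.  The transform maps 0 to
0 exactly, approaches the linear rescaling `treal·10/T` as `τ → −∞`, and
produces a delayed, retarded onset for larger `τ`.  Rates therefore act on
the transformed axis, whose range is about [0, 10] regardless of the units
of `treal`; this convention is fixed throughout the package.  The
transform is evaluated in log-sum-exp form, so large `treal·10/T` cannot
overflow.

### Dose dependence

For dose-resolved data each kinetic parameter becomes a Hill function of
the dose, `H(d) = M d^h / (K^h + d^h)`, with maximum `M`, Hill coefficient
`h`, and half-maximal dose (EC50) `K`.  `A, B, α, β, γ` increase with
dose.  The delay `τ` decreases with dose; since no canonical decreasing
form exists, the package uses the *reversed* Hill

    τ(d) = M_τ · K^h / (K^h + d^h),

which keeps the same (M, h, K) semantics, equals `M_τ` at dose 0, `M_τ/2`
at `d = K`, and decays to 0 at saturating dose.  This choice is an
assumption of this package, made once and kept.  A dose of zero makes all
amplitudes zero; the rates, which the Hill expansion would also send to
zero, are clamped to a floor of 1e−10 to preserve positivity (the
response is unaffected because the amplitudes vanish).

## Likelihood and optimization

The objective is twice the negative Gaussian log-likelihood,
`−2 ln L = Σ [ln(2π σ_i²) + Δ_i²/σ_i²]`, with residuals
`Δ_i = y_i − R(t_i)`.  When the data table carries a known per-point
standard error (`sigmaExp`) it is used directly; otherwise a single noise
parameter σ is estimated jointly with the kinetic parameters.

Each local search runs in two stages.  First, a trust-region reflective
least-squares solve over the kinetic parameters with the analytic model
Jacobian; when σ is free it is profiled analytically — for a single free
σ the joint optimum of the likelihood satisfies `σ̂² = mean(Δ²)` exactly,
so the profiled solution *is* the joint ML solution.  Second, a bounded
quasi-Newton (L-BFGS-B) refinement of the full joint objective with the
analytic gradient, which also sharpens convergence when σ̂ hits its
bounds.  The two-stage design was adopted because a quasi-Newton search
alone, started from random points, frequently terminates in shallow local
minima of this model's characteristically sloppy likelihood surface; the
trust-region stage reaches the global basin far more reliably, which
shows up directly in the waterfall plot as a wider plateau at the best
objective.

Multi-start: the first start is a cheap data-driven guess (offset from
the data floor, amplitudes from the net and peak excursions, unit rates,
no retardation); the rest are Latin-hypercube draws inside the bounds,
log10-uniform for positive scale-spanning parameters (rates, σ, Hill `h`
and `K`, the `M` of rate parameters).  With `auto` signs the four sign
combinations split the start budget equally.  All randomness derives from
one seed through a CRC-based derivation, so identical inputs and seed
give bit-identical results.  A previous fit can be passed back in
(`res_old`) and its starts join the comparison, so continuation never
worsens the best value.

### Default bounds

Scale-free in the data's units, with `ry = max(y) − min(y)`: amplitudes
in [0, 2·ry]; rates in [1e−2, 1e2] (log10); τ in [−2, max(t)·10/T];
offset in [min(y) − ry, max(y) + ry]; σ in [1e−4·ry, ry] (log10).  Hill
maxima inherit the bounds of the parameter they modulate (`M_τ` in
[0, max(t)·10/T], since the reversed Hill keeps τ non-negative); `h` in
[0.1, 10] and `K` spanning [min positive dose/10, 10·max dose], both
log10.  All of these are user-overridable per parameter.

## Model reduction

Backward elimination by likelihood-ratio tests: each candidate
simplification is refit (warm-started from the current best fit plus
fresh starts) and compared with the current model by an upper-tail χ²
probability of the increase in −2 ln L.  If any candidate reaches
p ≥ α (default 0.05) the least significant one is accepted and the loop
repeats; ties prefer fewer pinned parameters.  Candidates remove whole
components together with the rates they render unidentifiable — transient
(`B→0` with `β, γ` pinned, df 3), sustained (`A→0` with `α` pinned,
df 2), retardation (`τ→0`, df 1), offset (`b→0`, df 1); dose-dependent
models additionally allow `h→1` per Hill triple and pin every triple a
removed component owns.  Pinned rates are set to the neutral value 1, so
reduced parameter vectors are canonical and comparable across fits.  σ
(or a supplied `sigmaExp`) is never a candidate.  `α ≥ 1` acts as the
limiting "always eliminate" setting.

Two caveats a user should know.  First, the χ² reference treats the
pinned rates as regular parameters, but under e.g. `B = 0` the rates
`β, γ` vanish from the model — the classical situation of nuisance
parameters absent under the null — and at small n (≈20 points) the
observed null distribution of the statistic is somewhat heavier-tailed
than χ²₃, so the realized type-I rate at nominal α = 0.05 is closer to
10% than 5%.  Second, the test statistic uses the profiled-σ likelihood;
no small-sample (Bartlett-type) correction is applied.

## Low-dimensional representation

`lowdimensional_rtf` fits every time course of a collection independently
(single-dose mode, shared options, the same seeded start set for every
course so identical data gives identical rows), assembles the fitted
parameters into a courses × parameters matrix (including the two resolved
signs as ±1 columns), standardizes it, embeds it in 2-D with UMAP
(neighbours = min(15, n−1), min-dist 0.1, seeded) and clusters it with
k-means.  Clustering operates on the standardized parameter matrix, not
on the 2-D coordinates: clusters then reflect the parameters and the
embedding is display-only.  If `k` is not given it is chosen in
2..min(10, n−1) by mean silhouette.  Cluster summaries report per-cluster
per-parameter 25th/50th/75th percentiles (linear interpolation), plus the
member curves unscaled and min-max scaled to [0, 1] (constant curves map
to 0.5).  `condition_shift` reports, per paired entity across two
conditions, the 2-D displacement and its length, sorted descending — the
ranked list of entities whose dynamics changed most.  We call the
perturbed class "ranked above" the unperturbed one when its median
displacement exceeds theirs.

Two design choices here depart from the most naive pipeline, both forced
by the model's practical non-identifiability:

1. **Per-course reduction (default on).**  A plain ML fit of, say, a
   sustained-only course routinely carries a full-sized spurious
   transient (amplitude ~1–2, arbitrary rates, sometimes a flipped sign)
   that improves −2 ln L by only a few units: near-degenerate directions
   of the RTF family let a slowly decaying transient impersonate part of
   the sustained component.  Those arbitrary values differ between noise
   draws and swamp every distance computed from the matrix.  Each
   course's fit is therefore simplified by the package's own
   likelihood-ratio reduction before entering the matrix, with pinned
   parameters at canonical null values and the sign of a zeroed amplitude
   canonicalized to +1.  Switch off with `reduce=False` to embed raw fits.

2. **Reliability-weighted standardization.**  Columns are z-scored (rates
   on the log10 axis) and then weighted by
   `max(0, 1 − median(se²)/var)`, where the per-course standard errors
   come from the observed Fisher information at each best fit.  A column
   whose between-course variance is pure fit uncertainty (often τ and b
   in a homogeneous collection) would otherwise be inflated to unit
   variance and drown the real differences in dynamics; the weight sends
   such columns smoothly to zero.  The median (not mean) of se² is used
   because an occasional near-singular fit has exploding standard errors
   along its sloppy direction.  Without uncertainties, `standardize`
   falls back to plain z-scores.

## The synthetic-data generator

`simulate` draws i.i.d. Gaussian noise around an exact RTF (or
dose-expanded RTF) evaluation; everything is reproducible from the spec's
seed, and the generating truth is returned next to the table.  Defaults:
single-dose truth `A=1, B=1, α=1, β=2, γ=0.5, τ=0.5, b=0.2`, 21 equally
spaced times on [0, 10], noise sd 0.02 — visible sustained-plus-transient
structure at a realistic signal-to-noise; dose-dependent truth with Hill
maxima equal to the single-dose values, `h = 2`, EC50 5 on the dose grid
{1.25, 2.5, 5, 10, 20}, 11 time points per dose.
`simulate_collection` builds labelled multi-class, optionally
two-condition paired collections; its defaults (101 time points, noise sd
0.002) emulate densely sampled, essentially noise-free simulated ODE
trajectories — the typical input of the embedding workflow — rather than
sparse noisy measurements.  The condition effect is a multiplicative
perturbation of named parameters applied to a subset of classes.

What the generator does *not* emulate: replicate structure and
per-point heteroscedastic errors, non-Gaussian noise, missing values,
and model misspecification (real data are never exactly an RTF).  Tests
passing on these fixtures therefore demonstrate correctness of the
machinery and calibration under the model, not robustness to violations
of it.

## What is — and is not — statistically attainable at the default sizes

The default single-dose study (n = 21, noise 1–2% of amplitude) is
*structurally* identifiable: at noise 1e−6 the ML fit recovers every
parameter to <0.1%.  It is not *practically* identifiable: the Cramér–Rao
bound computed from the analytic Jacobian at the default truth with
σ = 0.01 gives asymptotic relative standard deviations of roughly 1.2%
for A and 5% for b, but ~40% for γ, ~165–180% for B, α, β, and ±0.30 for
τ — the transient parameters trade off along sloppy directions.  Point
estimates of those parameters at this design are therefore not
individually meaningful (though the fitted *curve* is reproduced to
within the noise), and the same holds, more strongly, for most Hill
parameters of the dose-dependent model at 5 doses × 11 points.  The test
suite contains recovery tests at exactly these conditions; the ones that
demand tight per-parameter recovery where the information bound forbids
it fail, and are retained as an honest record of that limit.  Profile
likelihood uncertainties, which would quantify this per fit, are not
implemented.

## Problem sizes used in the shipped studies

Unit and statistical tests run at the generator defaults above; the
replicated studies use 20 replicates (100 for the null-calibration study
at 10 starts each), 50 starts for single-course recovery fits, 20 for
reduction studies, and 4 starts per course (plus reduction refits with a
single fresh start) for 40-course collections.  These sizes are the
package's chosen defaults for its own validation studies.
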