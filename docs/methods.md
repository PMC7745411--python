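# Methods

## Growth model

Suspension cultures are modelled as logistic growth with a
time-dependent per-capita rate,

    dN/dt = r(t) N − r(t) N²/K,

i.e. a division rate r(t) per cell and a death rate that grows linearly
with density (pairwise competition), which together cap the population
at the carrying capacity K.  K and any death-rate structure are assumed
constant — adaptation is modelled entirely as a change in r(t).  K must
be supplied by the user; it is not inferred, because near saturation the
counts carry almost no independent information about K versus r.

r(t) is a piecewise-linear function over 1–3 control points evenly
spaced across the observation window (day of first count to day of last
count).  One point encodes a constant rate, two a linear trend, three a
broken-stick trend; the deliberately small parameter count guards
against overfitting sparse count timelines.  Outside the window the rate
is clamped to the nearest endpoint value, so plotting or simulating
slightly beyond the data never extrapolates a runaway trend.

Units everywhere: days, divisions/cell/day, cells.

### Deterministic solver

With R(t) = ∫₀ᵗ r(ξ)dξ (piecewise quadratic, closed form), the Bernoulli
substitution u = 1/N gives the exact solution

    N(t) = K / (1 + (K/N₀ − 1) e^{−(R(t) − R(t_ref))}),

anchored at N(t_ref) = N₀.  The identity d/dζ e^{R(ζ)} = r(ζ)e^{R(ζ)}
collapses the remaining integral, so no numerical quadrature or ODE
stepping is involved; the solver is exact to floating point, fast enough
for the ABC inner loop, and well behaved for negative rates, N₀ = 0,
N₀ = K and overgrown cultures (N₀ > K).  The one genuinely singular
regime — an overgrown culture with a negative rate, which blows up in
finite time — is reported as `inf` past the blow-up.  Adaptive ODE
integration of the defining equation is retained
(`solve_deterministic_ode`) purely as an independent cross-check; the
test suite verifies agreement to better than one part in 10⁵ on
randomized instances.

### Stochastic simulator

For small populations the same dynamics are simulated as a logistic
branching process: every cell is a particle, birth hazard λ = N·r(t),
death hazard μ = N(N−1)·r(t)/K, N = 0 absorbing.  Both hazards share the
factor r(t), which has two exact consequences exploited by the
implementation: the waiting time to the next event solves
c(N)·[R(t+Δ) − R(t)] = Exp(1) with c(N) = N + N(N−1)/K — a per-segment
quadratic in Δ, inverted analytically (zero-rate segments are skipped;
no thinning is ever needed) — and the birth/death choice is a simple
Bernoulli draw with odds N : N(N−1)/K, independent of time given N.
Rates must be non-negative here (they are event intensities); the
inference layer clamps curves at zero before stochastic simulation,
while the deterministic path accepts negative rates unchanged.

The event loop is JIT-compiled with numba.  Ensembles derive
per-replicate seeds from the base seed by a counter-based scheme
(`SeedSequence(seed, spawn_key=(i,))`), so replicate i is identical no
matter how many replicates are requested.  A `max_events` guard
(default 2·10⁶) aborts runaway simulations; in practice the simulator is
intended for populations below ~2·10⁶ cells, above which per-event
simulation is slow and the deterministic solver is indistinguishable
anyway.

## Observation model

A count is produced from a true size N by a chain of subsampling steps
with fractions f₁, f₂, … (e.g. 10 µL of 1 mL → f₁ = 0.01; 0.2 µL
undiluted equivalent of that sample → f₂ = 0.02; dye dilution does not
change cell numbers and is folded into the fractions).  For
well-dispersed cells each step yields a Poisson count: c₀ = N,
cᵢ ~ Poisson(cᵢ₋₁ fᵢ).  By Poisson thinning the chain is distributionally
identical to a single Poisson with the product rate — a property the
test suite verifies by goodness of fit — but the chain form mirrors how
users record their protocol.

Sampling noise alone understates real variability, so a pluggable
counting-noise filter is applied afterwards.  The shipped
`normal_binomial` filter assumes each counted cell is wrong with
probability `p_wrong` (default 0.05, a typical manual/instrument error
rate) and adds a zero-mean normal draw with the matching binomial
variance c·p(1−p), rounded and floored at zero — counts are non-negative
integers.  `none` disables the stage.  The filter architecture is a
single `kind` switch so other instruments' error models can be added
without touching the samplers.

The inverse point estimate `count / ∏fᵢ` is used only for plotting
observed counts on population axes and for centring the N₀ prior; the
inference itself always runs the forward model.

## ABC-SMC inversion

Parameters per model m (m = number of control points): one latent
initial population per series plus the m control values.  Priors are
uniform: control values over a user range (default 0.01–3.0
divisions/cell/day), N₀ over 0.2×–5× the first count's point estimate.
N₀ is inferred rather than fixed because the first count is itself a
noisy, heavily subsampled observation.

The SMC loop: generation 0 samples the prior (all particles accepted);
each later generation sets ε to the `epsilon_quantile` (default 0.5) of
the previous generation's accepted distances, resamples particles by
weight, perturbs them with a component-wise Gaussian kernel whose
variance is twice the weighted posterior variance of the previous
generation (per model), rejects proposals outside the prior support, and
accepts simulations with distance ≤ ε.  Weights use the standard SMC
importance ratio prior/(model-mass × kernel density).  Requested
control-point counts compete as models under a uniform model prior:
a particle's model is drawn from the previous generation's model masses
(no cross-model moves), and the reported model probabilities are the
final weight shares.  A generation that cannot fill its particle
population within `max_sims_per_generation` simulations (default
200 × n_particles) raises an error identifying the ε schedule as too
aggressive rather than looping forever.

The default distance is Euclidean between square-root-transformed
counts: the square root approximately stabilises Poisson variance, so
early small counts and late large counts contribute comparably.  Plain
Euclidean is selectable.  Distances are only defined on identical time
grids and sampling schemes, which the forward simulation guarantees.

Grouped series (replicate wells, or cultures expected to share
dynamics) are fitted jointly: one shared rate curve, one latent N₀ per
series, each anchored at that series' own first observation time, with
the concatenated counts entering one distance.  Whether replicates
should also share N₀ is genuinely ambiguous; per-series N₀ was chosen
because replicate wells are seeded independently.

Determinism: a single RNG stream seeded from the config drives
everything, so identical config ⇒ identical posterior.  The
`n_parallel` option is accepted and logged for interface compatibility,
but execution is sequential; results are therefore trivially independent
of the worker count.

## Reporting

The HPDI of a weighted sample is computed by sorting, then sliding the
smallest window whose contained weight reaches the target mass (default
0.89); width ties go to the leftmost window.  A brute-force window
search is kept in the test suite as the oracle.  Rate and population
credibility bands evaluate every weighted posterior draw on a time grid
and take the per-time HPDI, pooling models by their posterior mass.
Fit tables are plain CSV (one row per group × model × parameter with
mean, median, HPDI bounds and model probability).  The report figure
combines the population panel (observed point estimates, posterior
median curve, HPDI band) with connected raincloud plots of the rate
posterior (weighted KDE + quartile box + raw draws); every number behind
a panel is computed by `report_panel_data` and tested numerically — the
rendering itself is only smoke-tested.

## Synthetic scenarios

`cellrate.scenarios` generates count series through the full forward
model from known truth, returning the truth alongside so recovery
experiments never re-derive it.  The three built-ins cover a constant
rate (1.0), an increasing rate (0.2 → 1.2) and a decreasing rate
(1.2 → 0.2) over days 0–8, observed every second day through the
two-stage 0.01 × 0.02 scheme with 5% counting error.  The constant
scenario uses the worked-example culture (K = 3·10⁶, N₀ = 9.5·10⁴).  The
trending scenarios place the same inoculum in a larger culture
(K = 3·10⁷): near carrying capacity the counts carry essentially no rate
information (at the fixed point they carry none), so a culture that
saturates mid-window cannot demonstrate recovery of a late-time rate —
the trend would be unidentifiable by construction, not by algorithmic
failure.  Keeping the population below saturation for the whole window
is therefore part of the experimental design these scenarios emulate.

What the generator does *not* emulate: drift in K or in the death rate,
non-Poisson clumping of cells, pipetting bias, plate-position effects,
or measurement-time jitter.  Passing recovery tests therefore
demonstrates correctness of the inversion under the stated model, not
robustness to model misspecification.

## Numerical choices and problem sizes

Defaults of 200 particles × 6 generations with the deterministic
simulator fit a 5-point series in seconds and are the sizes used by the
recovery experiments; the detectability experiments run 10 generations
because distinguishing two posteriors requires the SMC tolerance to be
near its noise floor, and model comparison likewise uses 10 generations
— at looser tolerances the simpler model retains mass it only loses
once ε forces the fit to track the data's curvature.  The
stochastic/deterministic cross-check uses K = 10⁴, N₀ = 100 and 500
replicates.  Known limitations: no inference of K; at most a handful of
control points is sensible for typical count timelines; ABC posteriors
are approximate — their width includes the tolerance floor, so very
small rate differences (≲10–20%) are not resolvable from data of the
worked example's sparsity, which is precisely the detectability bracket
the acceptance experiments measure.
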