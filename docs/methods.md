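# Methods

This note documents the models, estimators and numerical choices behind
`lamvar`, and what the synthetic benchmark does and does not establish.

## Data model and conventions

Spike times are stimulus-locked milliseconds (onset = 0); every trial covers a
[−400, 0) ms baseline and a [0, 500) ms stimulus epoch.  Counting windows are
half-open `[start, end)`.  Two stimulus analysis windows exist — [50, 450) ms
(the default) and [50, 350) ms (the averaging window used for display-style
summaries and for the responsiveness gate) — and a run configuration must name
one; neither is silently preferred.  Layer labels come from the fixed
vocabulary {SG, G, IG, unassigned}.  Sessions serialize to an HDF5 container
(spike times at 0.1 ms resolution, stored as integer ticks so round trips are
lossless) or to a flat CSV count table.

## Generator

Counts are doubly stochastic Poisson.  On a trial at diameter `s`, unit `u`
fires `N ~ Poisson(mu_u(s) T g h)` where `g = exp(sigma_u(s) eps − sigma²/2)`
is a private mean-one log-normal gain and `h = exp(lambda_u(s) z − lambda²/2)`
couples all units of a penetration through one standard-normal latent per
trial.  Closed forms used as oracles throughout:

* `E[N] = m = mu T`
* `Var[N] = m + m²(e^{sigma²+lambda²} − 1)`, so `FF = 1 + (e^{sigma²+lambda²} − 1) m`
* `Cov[N_u, N_v] = m_u m_v (e^{lambda_u lambda_v} − 1)` for `u ≠ v`; with equal
  loadings the implied single-factor shared variance is exactly
  `m²(e^{lambda²} − 1)`.

Rate curves are ratio-of-Gaussians with parameters drawn per unit (RF near
1°, SI ≈ 0.35–0.65, peak rates 20–40 Hz, baseline 3.5–6.5 Hz).  The
variability ground truth is specified as a *target Fano-factor profile* pinned
at {smallest size, RF, 2×RF, 26°} and interpolated monotonically in log
diameter (PCHIP); inverting the FF formula yields the total excess
log-variance at each size, which is then split between the shared latent and
the private gain by a layer-dependent fraction.  Defaults (chosen once, as the
study conditions of the benchmark):

* all layers: FF falls from the smallest sizes to a minimum at the RF
  (FF(RF) = 2.2 by default against a baseline FF of 3.0, matching the high
  variability of anesthetized cortex); 65% of units are "amplifiers" whose
  small-stimulus FF exceeds their baseline FF;
* SG: the far-surround FF knot grows with the unit's suppression index
  (`1.4 + 1.0·SI`), reproducing the positive correlation between far-surround
  variability amplification and suppression strength, and the shared fraction
  rises from 0.5 to 0.95 toward 26° — far-surround stimulation amplifies both
  FF and shared variance;
* G: FF flat beyond the RF, constant shared fraction 0.6;
* IG: FF knots 0.65/0.72 at 2RF/26° (near-surround quenching), shared
  fraction dropping to 0.35 beyond the RF.

Because count variance scales with the rate squared, strong surround
suppression shrinks shared variance in count² units even at a constant
loading; the layer profiles above are expressed as fractions of the excess
variance so the intended laminar sign pattern survives this rate confound.
Effect magnitudes are deliberately stronger than a typical cortical dataset so
that sign recovery is resolvable at desk scale; signs, not magnitudes, mirror
the laminar physiology.

Spike times are placed uniformly within their epoch — only counts matter to
the downstream statistics — and all randomness flows from one explicit seed
(no global state); a session is bit-for-bit reproducible.

Raw-signal fixtures: `simulate_voltage` inserts a biphasic waveform into
Gaussian noise at known times (detector ground truth); `simulate_laminar_lfp`
builds a potential with a positive Gaussian depth-bump at the sink channel and
a negative one at the source, an alpha-function time course, and white noise,
so the second spatial derivative has a negative extremum at the sink (known
dipole for the CSD stage).

## Variability estimators

* **Fano-factor**: unbiased variance over mean + 1e-7 (guards empty units).
* **Bootstrap SD**: trial resampling, 1000 resamples by default.
* **Zero-median bootstrap** (population % changes): the sample is shifted to
  zero median, resampled with replacement (default B = 9999), and the p-value
  is the fraction of resample medians at least as extreme as the observed
  median, floored at 1/(B+1).  The resampling is *smoothed* with a Gaussian
  kernel of bandwidth `2·sd·n^{-1/5}`: the plain bootstrap distribution of a
  median carries large atoms at the central order statistics and rejects a
  true null at ~2.5× the nominal rate; the smoothed version holds the 5%
  level in Gaussian null simulations across the sample sizes that occur here
  (n ≈ 8–41) and is conservative for skewed nulls.
* **Amplifier/quencher classification**: per diameter, the distribution of
  FF(stim) − FF(baseline) is rebuilt from 3000 trial resamples, mean-centred,
  and the observed difference is called a significant increase (decrease)
  above the 95th (below the 5th) percentile.  Trials, not precomputed
  differences, are resampled.  Amplifier = at least one significant increase
  and one decrease; quencher = decreases only.
* **% changes**: `100(b − a)/a`; units with |change| > 500% (near-zero
  denominators) are excluded from population medians.
* **Mean matching**: per condition, each point (unit) contributes a mean
  count and an FF; means are binned (1 spike), the bin-wise minimum histogram
  across conditions is the common target, and per repetition (50) points are
  randomly discarded to match it before averaging FF over retained points.
  Empty common histograms fail loudly, naming the bins.
* **MAD outlier rule**: drop points ≥ 2.5 absolute median deviations from the
  median; a zero MAD with non-identical values keeps everything with a
  warning.

## Size-tuning fits

The RoG form is `R(s) = r0 + k_c L(s,w_c)/(1 + k_s L(s,w_s))`,
`L = erf(s/w)²`.  Rate curves: bounded least squares (trust-region reflective
with analytic Jacobian, non-negativity bounds), multi-started from a
data-driven initial guess plus seeded log-normal perturbations (default 20
restarts), lowest SSE kept.  Fano and shared-variance curves: the sum of two
independent RoG components under per-parameter upper bounds
(k: 100, w_c: 30°, w_s: 60°, r0: 20) and a width floor of 0.3°; with ten
parameters on a dozen points an unconstrained width lets a narrow hump slip
between sample diameters, and the floor keeps fitted curves smooth at the
stimulus grid's resolution.  The "basin-hopping analog" is 50 seeded restarts
(data-driven start, perturbations, occasional log-uniform draws) + bounded
local optimization.

Derived quantities operate on a 2000-point log-spaced grid over 0.01–26°:

* **RF diameter** = grid argmax; ties/plateaus resolve to the smallest
  diameter; curves still at their peak at 26° (within 0.5% of the modulation
  depth) or with < 1% relative modulation are flagged "RF undefined".
* **Per-neuron surround**: on the grid above the RF, find the most negative
  slope, then scan toward larger diameters for the first slope ≥ min_slope +
  0.10·|min_slope|.  The rule is anchored at the minimum-slope location
  because anchoring at the RF would fire immediately at slope ≈ 0.  Curves
  with SI < 0.05 get "surround undefined" (26° is reported).
* **SI** = (R_RF − R_26°)/R_RF.
* **Canonical sizes** {s_min, RF, 2RF, 4RF, 8RF, 26°} (multiples clipped at
  26° and flagged), values normalized by the value at the RF; population
  averages use the geometric mean with a bootstrap SD over units.

## Factor analysis

EM on the sample covariance of (trials × units) counts from a single 300 ms
window — [50, 350) ms within the stimulus, [−350, −50) ms for the baseline —
fitted separately per penetration, layer and diameter.  Psi is floored at
1e-6 (no Heywood collapse), the stopping rule is a log-likelihood gain below
1e-8 per trial, at most 5000 iterations, and the log-likelihood is
non-decreasing across iterations by construction (asserted in tests).  Shared
variance per unit is `diag(Lambda Lambda')`; it is invariant to unit order and
to the latent's sign.

When the data carry no shared structure, the ML solution is nearly flat along
a ridge that splits one unit's variance arbitrarily between loading and
private variance; `prune=True` removes loading rows whose likelihood
contribution is within what chance covariance-fitting earns (LR check at the
0.999 level with q·(p−1) degrees of freedom).  Pruning is off by default:
at the pipeline's trial counts genuinely shared but weak structure is
statistically indistinguishable from the ridge, and the study-style estimator
reports the plain ML diagonal.

Leave-neuron-out cross-validation (5 folds over trials) predicts each held-out
unit from the others via the Gaussian conditional expectation under the
fitted model; the chosen dimensionality is the smallest q not significantly
worse (paired t-test over folds) than the best q.

At 20–50 trials and ~8 units per cell, the FA shared-variance estimate has an
upward sampling bias of order `total_variance · p/n`; the generator's default
loadings are sized so the true shared variance dominates it.  Users applying
the pipeline to weakly correlated data should expect per-cell estimates to be
noisy and rely on medians across units and sizes, as the pipeline does.

## Preprocessing

Noise SD is `median(|x|)/0.6745` — the median absolute signal of a zero-mean
trace, scaled to a Gaussian SD; the literal median of a signed trace would be
≈ 0.  Events are detected on the 300–5000 Hz band-passed trace (the band is a
declared default; it is not dictated by the recording) at 4× that SD, on
negative excursions by the extracellular convention (configurable), one event
per contiguous excursion at its absolute peak, 1 ms refractory.

CSD: band-pass (1–100 Hz), trial-average, second spatial difference across
channels, cubic-spline interpolation to a 10 µm depth grid, and per-depth
Z-scoring against the 200 ms pre-stimulus baseline.  On stimulus-locked traces
shorter than twice the high-pass period the high-pass is dropped (low-pass
only): a zero-phase 1 Hz filter on a sub-second trace smears the evoked
transient across the baseline and corrupts the Z reference.  A baseline SD at
numerical-noise level is floored relative to the profile scale.  Layer
assignment anchors on the most negative post-stimulus deflection (single-
sample threshold crossings are baseline-level noise), averages the profile in
a ±20 ms window around it, and requires a sustained sink ≤ −2 Z; the top of
the contiguous sink region is the SG/G boundary and the first sink→source
zero crossing below it is the G/IG boundary.  No sustained sink →
`UnassignableLaminarProfile`, never a silent default.

Gates: a unit is visually responsive if its best diameter evokes ≥ 3 spikes
above the duration-matched baseline mean in the [50, 350) ms window (mean per
trial, not summed), and size-tuned if a one-way fixed-effects ANOVA on raw
stimulus-window counts gives p < 0.05.  Gated-out units stay in the data
files with a flag and are excluded from population statistics.

## Pipeline and reporting

`run_full_analysis` executes gating → Fano curves (+bootstrap SDs) → rate RoG
fits (RF, surround, SI) → amplifier/quencher census → double-RoG Fano fits →
canonical % changes (RF vs baseline; 2RF, per-neuron surround and 26° vs RF)
→ per-cell factor analysis and per-unit shared-variance fits → per-layer
medians with bootstrap SDs and zero-median bootstrap p-values → summary JSON
and per-unit CSV.  All bootstrap seeds derive deterministically from the run
seed, floats are rounded to six significant digits on output, and a summary
with a matching configuration hash is reused instead of recomputed.  Reports
print raw p-values per layer/contrast (with per-analysis n always explicit)
plus clearly-labelled Benjamini–Hochberg-adjusted columns as an extension.

`layer_sign_summary` compares the per-layer medians against the generator's
sign pattern: SG far-surround FF and shared-variance medians positive, IG
near-surround medians negative, and the G-layer far-surround FF median
"flat", operationalized as lying within 2.5 bootstrap standard errors of
zero (a calibrated reading of "no change" that scales with the layer's n).

## Problem sizes

The generator's defaults are the study conditions (5 penetrations × 24
channels, 0.1–26°, 500/400 ms epochs, ~30 trials per diameter).  The repeated
end-to-end studies (the 50-session sign-recovery benchmark in the acceptance
suite and script) run a reduced per-session size chosen as this package's
own benchmark configuration: 2 penetrations × 24 channels, 10 diameters, 40
trials per diameter, 4 rate-fit and 2 double-fit restarts, ≈ 8 s per session.
Single-session analyses and the examples use the full configuration or
near-full reductions as noted in each script.

## What the benchmark does and does not show

The generator produces exactly the covariance structure the estimators
assume: log-normal gains, a single shared latent, stationary rates within the
window, no spike-sorting contamination, no slow drift, no eye movements, no
cross-penetration structure.  Passing tests therefore demonstrate estimator
correctness and pipeline wiring — not robustness to the ways real laminar
recordings violate these assumptions.  Known limitations: double-RoG fits on
~10 noisy points are variance-limited (medians across units are the reliable
quantity); FA shared variance is biased upward at small trial counts (see
above); the CSD layer assignment assumes a single dominant sink; and the
mean-matching procedure needs overlapping mean-count distributions to have
any common histogram.
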