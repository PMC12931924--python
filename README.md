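# lamvar

Laminar size tuning of neural response variability and shared variability.

`lamvar` implements the analysis chain used to ask how trial-to-trial spike-count
variability (the Fano-factor) and the variability *shared* across simultaneously
recorded units are tuned by visual stimulus size across the layers of primary
visual cortex (supragranular SG, granular G, infragranular IG), together with a
synthetic laminar session generator that makes every stage of the chain
verifiable against closed-form ground truth.  It is written for systems
neuroscientists analyzing laminar-array size-tuning experiments, and for anyone
who wants a tested reference implementation of these estimators.

## The statistics at the core

**Fano-factor.** For spike counts over repeated identical trials,
`FF = Var[N] / (E[N] + 1e-7)` with the unbiased sample variance; `FF = 1` for a
Poisson process.  Analyses use stimulus-locked count windows (default
[50, 450) ms; pre-stimulus baseline [−400, 0) ms), bootstrap SDs, a smoothed
zero-median bootstrap for population medians of % changes, and a 3000-resample
percentile test to flag per-diameter FF increases/decreases vs baseline
("amplifier" units show both a significant increase and decrease across sizes;
"quenchers" only decreases).

**Size-tuning model.** Mean rates follow a ratio of Gaussians,
`R(s) = r0 + k_c L(s, w_c) / (1 + k_s L(s, w_s))` with `L(s, w) = erf(s/w)^2`;
the RF diameter is the curve's peak, the suppression index is
`SI = (R_RF − R_26°)/R_RF`, and the per-neuron surround diameter comes from a
slope-recovery rule on the fitted curve.  Non-monotonic Fano and
shared-variance curves are fitted with the sum of two independent RoG
components under box bounds.

**Shared variability.** A single-factor factor analysis per (penetration,
layer, diameter) on 300 ms counts decomposes the trial-to-trial covariance as
`Lambda Lambda' + Psi`; the per-unit shared variance is `diag(Lambda Lambda')`,
the private variance is `Psi`.  Latent dimensionality is checked by fivefold
leave-neuron-out cross-validation.

**Generator.** Counts are doubly stochastic Poisson:
`N ~ Poisson(mu(s) · T · g · h)` with mean-one log-normal private gain `g`
(SD parameter `sigma(s)`) and shared gain `h = exp(lambda(s) z − lambda²/2)`
coupling units through one latent `z ~ N(0,1)` per trial.  This gives exact
moment oracles: `FF = 1 + (e^{sigma²+lambda²} − 1) mu T` and
`Cov(N_u, N_v) = m_u m_v (e^{lambda_u lambda_v} − 1)`.  Defaults emulate the
study conditions (5 penetrations × 24 channels at 100 µm spacing, gratings
0.1–26°, 500 ms stimulus / 400 ms baseline per trial) with layer-dependent
ground truth: SG far-surround variability increase, IG near-surround decrease,
G flat beyond the RF.

## Worked example

```bash
python examples/05_full_pipeline.py
```

runs the full pipeline (gating → Fano → tuning fits → factor analysis →
per-layer report) on a 2-penetration synthetic session and prints, among
others:

```
Units: 40/48 passed gating (responsive, size-tuned, layer-assigned)

=== Layer SG (n = 14) ===
contrast            median %   boot sd    p(two)    n
FF rf_vs_baseline      -21.5       5.2    0.0024   14
FF far_vs_rf            25.0      18.0    0.2432   14
SV far_vs_rf            61.3      44.0    0.5601   13
...
=== Layer IG (n = 18) ===
FF rf_vs_baseline      -28.8       4.8    0.0001   18
SV near_vs_rf          -36.9       8.6    0.0001   18
```

Read: in every layer an RF-sized grating quenches variability relative to the
pre-stimulus baseline (−21% to −29%); far-surround stimulation *amplifies*
variability and shared variability in SG (+25% / +61%), while near-surround
stimulation quenches shared variability in IG (−37%) — the laminar sign
pattern built into the generator's ground truth.  `layer_sign_summary`
compares the recovered pattern with that truth session by session.

The other examples (`examples/01`–`04`) cover the generator, single-unit
Fano size tuning, factor analysis + dimensionality selection, and spike
detection / CSD laminar assignment.  A thin CLI mirrors the stages:
`lamvar simulate | fano | tuning | sharedvar | report | all`.

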