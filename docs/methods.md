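# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `timeddm`, in the spirit of the methods sections of
simulation and statistics packages. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Drift-diffusion model of switch response times

The model is an Ornstein–Uhlenbeck-type accumulator
dx = (F − x) D dt + σ dξ, x(0) = b, with an absorbing-style readout at
the threshold T(F, b) = (1 − b/4) F + (b/4)(1 − F). The packaged
parameter sets are the published intact and disrupted values
(intact D2: F=1, b=0.52, D=0.135, σ=0.052, hence T=0.87; intact D1:
F=0, b=0.48, D=0.141, σ=0.052, hence T=0.12; disrupted variants lower
D and σ together).

Numerics:

* **Integration.** Euler–Maruyama with Δt = 0.1 s (the published
  step), 25-s horizon, 500 trials per batch, vectorised across trials.
  Paths continue to evolve after their first crossing so that full
  trajectories are available to the ensemble generator.
* **Crossing detection.** First grid step at-or-beyond T in the drift
  direction, with the direction inferred from sign(T − b); t\* is the
  step index times Δt. A start exactly on threshold reports t\* = 0
  and is flagged degenerate. With σ = 0 the crossing converges to the
  closed form t\* = (1/D) ln(|F − b| / |F − T|) with O(Δt) error,
  which serves as the integrator's analytic oracle in the tests.
* **Censoring.** Trials that never reach threshold within the horizon
  (≈0.3–0.8% at published parameters) are flagged and excluded from
  gamma fits and summary statistics; a batch that censors every trial
  is an error. Scoring censored trials at the horizon instead was
  evaluated and discarded: it systematically drags the fitted gamma
  shape below the published intact-D2 value, whereas exclusion
  reproduces it.
* **Gamma fitting.** Two-parameter maximum likelihood
  (`scipy.stats.gamma.fit` with the location pinned at zero), reported
  in the rate parameterisation. ML was chosen over least-squares
  density fitting and method of moments because it reproduces the
  published intact-D2 fit essentially exactly at large n, which the
  alternatives do not.
* **Goodness of fit.** `gamma_sample_r2` reports 1 − SS_res/SS_tot
  either between the empirical CDF and the fitted gamma CDF at bin
  edges (`method="cdf"`, the default) or between the sample's
  normalised histogram density and the gamma density at bin centres
  (`method="pdf"`), with 0.5-s bins on [0, 25] s. The CDF comparison
  is the default because distribution-function overlays are the form
  in which such fits are displayed and assessed; at 500 trials the
  histogram-density statistic is dominated by bin noise (it plateaus
  near 0.9 regardless of fit quality) while the CDF statistic
  approaches 1 for a correct model.
* **Parameter selection.** `summary_stats` repeats the 500-trial
  "experiment" (default 10 times) and takes group medians of the
  per-repeat sample mean and CV; `fit_errors` applies the inclusive
  acceptance rule E^μ ≤ 0.05 and E^cv ≤ 0.02 against gamma-implied
  targets μ_M = α_M/β_M, CV_M = 1/√α_M. `grid_search_params` evaluates
  the error surfaces over a default grid D ∈ [0.05, 0.25] (step 0.002)
  × σ ∈ [0.02, 0.10] (step 0.002), deriving each cell's seed
  deterministically from (base seed, cell index) so surfaces are
  reproducible regardless of evaluation order. An empty accepted
  region is a valid result. Tests and the acceptance script exercise
  the machinery on small sub-grids; the full default grid is a
  CLI-scale computation.

A note on the intact-D1 gamma shape: under this pipeline the
large-sample ML shape of the simulated intact-D1 model is ≈6.25
(rate ≈0.71), about one 500-trial-batch standard deviation above the
published single-batch fit of 5.89, while the intact-D2 shape
reproduces the published 6.08 to within 0.1%. The corresponding
acceptance test asserts the published value and is expected to flag
this discrepancy rather than hide it.

Likewise, the simulated switch-time distribution is only approximately
gamma: its sample CV at intact-D2 parameters (≈0.424) sits slightly
above the value implied by the ML shape (1/√6.08 ≈ 0.406), so E^cv at
the published parameters has expectation ≈0.018 — inside the 0.02
bound, but close enough that single selection experiments straddle it.
The acceptance test replicates the selection experiment over ten base
seeds and asserts the median errors.

## Synthetic behavior

`SynthBehaviorSpec` draws switch times i.i.d. from gamma(6.08, 0.69/s)
— the model-derived distribution, mean ≈8.8 s — for the 50% of trials
that are 18-s switch trials; 6-s trials are generated but flagged
`short` and excluded downstream, mirroring the task's unanalysed
trials. Event logs follow the task grammar: trial start at time zero,
an optional earlier first-nosepoke bout (probability 0.3), a final
bout whose exit is exactly the switch time (bout duration log-normal,
median 1.2 s), a second-nosepoke entry after a log-normal traversal
gap (median 1 s), and a reward at max(18 s, second entry). The
traversal and nosepoke-duration forms are free modelling choices
(positive, right-skewed); their medians are configuration knobs. An
optional laser condition adds a constant shift to laser-on switch
times for effect-size testing. Switch-time extraction inverts the
generator exactly (a round-trip test enforces this).

Switch extraction uses the rule "last first-nosepoke exit preceding
the first second-nosepoke entry", the most literal reading of
departing the first nosepoke before arriving at the second when
multiple bouts are allowed; trials without that pattern are error
trials and yield no record.

## Synthetic units and ensembles

Single units are inhomogeneous Poisson processes: baseline rate
0.5–20 Hz, plus a linear ramp (slope in spikes/s per s, sign encoding
up/down, at the scale of the reported per-unit GLM slopes) gated to
the 0–6 s interval of each trial, a multiplicative log-normal
per-trial gain (SD 0.1), and rates clipped at zero. Sampling is by
thinning against the session rate maximum, exact for piecewise-linear
rates; a test checks empirical rates against the specified profile.
Opto-tagging responses add one light-evoked spike per pulse at a
positive-truncated normal latency. Blockade is emulated by shrinking
ramp slopes toward flat.

The DDM-linked ensemble is the construction behind the trial-by-trial
readout result. For each non-censored trial the generator forms an
accumulation signal

    y(t) = 0.5 · ((1 − m) · p(t) + m · min(t/t*, 1.15))^q

from the threshold progress p(t) = (x(t) − b)/(T − b) of the realised
trajectory blended (m = 0.5) with the trial's normalised elapsed-time
ramp and squared (q = 2), smoothed (Gaussian, 0.5 s), pinned to equal
0.5 exactly at t\*, and then *deconvolved* against the readout kernel
on the simulation grid. Unit rates are a_j + c_j·h(t) with mixed-sign
gains (|c| = 20 Hz, baselines spanning roughly 1–18 Hz so session-mean
rates stay in the MSN band), and the generator's weights β solve
β·c = 1, β·a = 0 with minimum norm. By construction the expected
β-weighted, kernel-convolved ensemble activity equals y(t) on the grid
and crosses 0.5 at the trial's switch time (a test bounds the median
crossing error by two grid steps).

The ramp component is deliberate: with rates purely affine in the
instantaneous trajectory, slow trials whose paths hover just below
threshold for seconds are undecodable in principle — a near-miss and a
crossing look identical to any causal readout — and no physiological
rate scaling recovers the published >90% regime. Real MSN ramps are
time-locked as well as state-locked; the blend encodes that while
keeping the trajectory's trial-to-trial fluctuations in the signal.

Poisson surrogates replace each unit's spikes on each trial with a
homogeneous train at that unit's observed trial-average rate,
destroying within-trial temporal structure while matching rates — the
control showing the readout uses timing, not excitability.

## Ephys analyses

* **Unit selection**: mean session rate within [0.5, 20] Hz,
  inclusive.
* **MSN/FSI separation**: Ward hierarchical clustering of standardised
  (peak-to-trough ratio, half-peak width); the wider-waveform cluster
  is labelled MSN, since fast-spiking interneurons are narrow by
  convention.
* **Tagging**: mean first-spike latency within a 0–10 ms post-pulse
  search window; tagged iff latency ≤ 5 ms (inclusive, with a 1e-9
  epsilon against floating-point representation) and
  evoked-to-spontaneous waveform correlation > 0.9 (1.0 assumed when
  waveforms are absent, as in synthetic mode).
* **PETHs**: spikes aligned to trial start, binned at 0.2 s over
  (−4, 22) s (130 bins), averaged across trials, converted to rate,
  then smoothed with a Gaussian kernel of SD 1 s — the default reading
  of a KDE bandwidth of 1 in time-axis units, applied after averaging.
  z-scoring is over the full window per unit. Raw binned counts are
  retained so smoothing provably conserves in-window spike counts.
* **PCA**: units are observations, the 0–6 s PETH bins variables. Each
  component's sign is fixed so its linear trend over the interval is
  non-positive; with a down-trending PC1, up-ramping (D2-like) units
  score negative and down-ramping (D1-like) units positive. The PC1
  explained fraction is compared against an empirical null in which
  every unit's spikes are replaced by uniform random session
  timestamps with identical counts and the full PETH+PCA pipeline is
  re-run (default 1000 iterations; tests use ~100 for runtime and a
  calibration check confirms the null p is uniform-ish when the
  observed data are themselves random).
* **GLM ramp slopes**: pooled (trial, bin) firing rates over 0–6 s
  regressed on time and per-bin nosepoke counts with an identity-link
  Gaussian model — the reported slopes carry spikes/s-per-s units,
  which a log link would not. The nosepoke regressor is dropped when
  no nosepokes fall in the interval. Sensitivity variants refit after
  excluding observations outside the 95% prediction interval, or end
  each trial's observations at its switch time.

## Decoding

The naive Bayes decoder bins ensemble spikes at 0.5 s over (−6, 24) s
(6-s pads against edge effects), requires more than 20 trials per unit
(configurable), and, for each held-out trial under leave-one-out
cross-validation, scores each observed bin against every candidate bin
by a product of per-unit Poisson likelihoods with training-mean counts
floored at 0.1 spikes/bin (the floor prevents zero-likelihood
lockouts); the prediction is the posterior-argmax bin centre under a
uniform prior. Performance is the per-trial squared Pearson
correlation between objective and predicted times within the 0–6,
6–12, and 12–18 s epochs, treated as independent; constant predictions
within an epoch are reported as R² = 0 and flagged. The shuffle
control permutes each trial's bin order (one permutation per trial,
shared across units) before decoding.

The readout's logistic fit is pooled across trials (the per-trial
alternative is under-determined at one crossing per trial) and uses a
small ridge penalty (C = 100) because noise-free synthetic ensembles
separate perfectly and the unpenalised MLE diverges. Readout fitting
is in-sample by default, matching a descriptive fit to observed switch
times; a leave-one-trial-out mode is provided. The ±1-s accuracy
window reads "within a 1-s window" lenient-side; the stricter ±0.5 s
reading is a configuration option.

## Pipeline and reproducibility

All randomness flows through explicit integer seeds;
`numpy.random.default_rng` generators are created at use sites, and
stage seeds derive from the root seed via a CRC of the stage name, so
stage-level results do not depend on execution order. The pipeline
writes plain delimited text plus a manifest of output SHA-256 hashes;
re-running with an identical configuration reproduces byte-identical
artifacts (tested).

## Problem sizes

Defaults mirror the study's scales: 500-trial DDM batches, 10-repeat
selection experiments, 130-bin PETHs, 16-unit/40-trial ensembles. The
test suite and acceptance script run the same code at those scales,
except that grid searches use small sub-grids and the PC1 null uses
~100 iterations — the package's choice of desk-scale defaults for
routine verification; the full-resolution settings remain available
through configuration.

## What passing tests do and do not show

The synthetic generators emulate the *statistical structure* the
analyses assume — gamma switch times, trial-gated linear ramps,
Poisson spiking, short-latency tagging, threshold-crossing ensembles —
not the recordings themselves. Real MSN data add slow drifts,
correlated noise across units, behavioral covariates (movement,
motivation), imperfect spike sorting, and session-to-session
heterogeneity that these generators deliberately omit. Passing tests
therefore validate the implementation and the internal consistency of
the modelling chain (parameter recovery, invariances, orderings,
controls), and reproduce the published model-side quantities; they do
not re-establish the empirical findings that require the original
recordings (the mouse-data PC1 variance, decoding R², behavioral
medians, and drug/laser effect sizes).

## Known limitations

* The DDM readout is first-passage on a discrete grid; crossing times
  are quantised at Δt and biased upward by at most one step.
* The ML gamma fit summarises a distribution that is not exactly
  gamma; shape/rate should be read as descriptive, and derived CV
  differs from the sample CV by ~4% at published parameters.
* The naive Bayes decoder assumes Poisson counts independent across
  units given time; synthetic data satisfy this by construction, real
  data do not.
* `classify_msn_fsi` assumes exactly two waveform clusters and labels
  by width ordering; pathological feature sets (a single cluster)
  raise instead of guessing.
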