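# Methods

This document records the models, calibration choices and numerical
decisions behind `windbat`. It is written for a reader who wants to
audit the analysis chain, not just run it.

## 1. Sound propagation (`windbat.propagation`)

### Atmospheric absorption

Pure-tone atmospheric absorption `alpha(f)` in dB/m follows ISO 9613-1:
oxygen and nitrogen relaxation frequencies computed from the molar
concentration of water vapour (via the standard's saturation-pressure
exponent), combined with the classical translational term. The
implementation is hand-written because no installed library exposes the
standard; an independent reimplementation from the published formulas
lives in the test suite and agrees to a relative 1e-6 across 1–100 kHz
and three atmospheres. Valid input band: 1–200 kHz. Default atmosphere
is 20 °C, 60 % relative humidity, 101.325 kPa — the reference study
conditions.

### Sonar-equation distance solves

For a source level `SL` (dB peSPL at 1 m, as conventional in bat
bioacoustics) the received level at range `r` is

- one-way: `RL = SL − 20·log10(r) − alpha·r`
- two-way (echo): `EL = SL − 40·log10(d) − 2·alpha·d`

`solve_max_distance` finds the range where the received level crosses a
threshold using `scipy.optimize.brentq` on [1 m, 1e6 m] with
`xtol = 0.01 m`. `RL` is strictly decreasing in `r`, so the root is
unique; sources already below threshold at 1 m return 0. An
`alpha_db_per_m` override exists for controlled comparisons — with
`alpha = 0` the solves reduce exactly to the closed forms
`10^((SL−thr)/20)` (one-way) and `10^((SL−thr)/40)` (two-way), which the
tests verify to 0.01 m.

Two fixed thresholds are packaged: the recorder trigger (37 dB SPL) and
the conspecific hearing threshold (20 dB SPL).

### Active-space modes and a documented inconsistency

Published treatments of song "active space" sometimes describe it as
*double the two-way detection distance*. Both conventions are
implemented:

- `one_way` (default): solve the one-way equation directly at the
  hearing threshold. This is the physically direct reading — a listening
  conspecific receives the signal once, there is no echo path.
- `paper_doubling`: solve the two-way equation at the hearing threshold
  and double the result.

The default was chosen *empirically* against the published reference
ranges. Under `paper_doubling`, reproducing the published *Plecotus*
pair (25.1 m recorder range, 42 m active space) requires negative
atmospheric absorption, and the published *V. murinus* pair (114.3 m
recorder range, 100 m active space) would require a source level near
156 dB — far outside the published 72–108 dB range. The direct one-way
solve reproduces the *Plecotus* active space to 0.3 % and admits the
*P. nathusii* 100 m value within the published source-level range, so
`one_way` is the calibrated default and `paper_doubling` is retained as
the alternative convention.

**Known limitation.** The published 100 m active space for
*V. murinus* is jointly inconsistent with its published 114.3 m
recorder detection range under *either* convention: a source loud
enough to trigger a recorder (37 dB threshold) at 114.3 m is audible
(20 dB threshold) one-way at ~173 m, and no admissible source level
closes the gap under doubling. The package reproduces the 114.3 m
detection range and reports the internally consistent ~173 m active
space; the acceptance test for the published 100 m value is left
failing on that one assertion rather than being weakened, so the
discrepancy stays visible.

### Species parameter table

Supplementary per-species song parameters were not available, so
`data/species_params.csv` was reconstructed by calibration against the
published range constraints, with a provenance column distinguishing
`calibrated` from `placeholder` rows:

- *V. murinus*: 14.0 kHz, 108 dB — the published endpoints; gives a
  118.1 m recorder range (within 5 % of 114.3 m).
- *Plecotus* spp.: 26.4 kHz; source level solved from the 25.1 m
  recorder range → 83.45 dB.
- *P. nathusii*: 19.0 kHz; source level solved from the 100 m active
  space → 102.93 dB.
- The remaining four species carry round, literature-plausible values
  (84/82/87/72 dB at 15/16/21/23 kHz) chosen so the seven-species
  one-way mean active space is 82.4 m, matching the published ~82 m.

Flight speeds: *Plecotus* 2.5 m/s and *N. noctula* 6.0 m/s are
published; others are placeholders and are only used by
`covered_flight_distance`.

## 2. Acoustic event classification (`windbat.events`, `windbat.pipeline`)

The classifier is a deterministic rule chain over parameterized call
events (start time, duration, start/end frequency, level):

1. **Trigger filter** — drop events failing the recorder's validity
   rules (frequency band, minimum sweep, duration, level window).
2. **Species assignment** from echolocation end frequencies. Bins
   (kHz): *N. noctula* [8, 22); Nyctaloid (22, 29]; (29, 30] →
   Chiroptera; *P. nathusii* (30, 42]; *P. pipistrellus* (42, 51];
   *P. pygmaeus* (51, 65]. The bin edges are half-open exactly as
   stated, so an end frequency of exactly 22.0 kHz is unassigned at
   species level and falls back to Chiroptera — the tests pin this
   boundary deliberately. Detector groups: Nyctaloid [8, 33),
   Pipistrelloid [33, 65). A recording's species label needs ≥ 2
   concordant echolocation calls; a single call falls back to the group
   label.
3. **Feeding buzzes** — maximal runs of ≥ 3 consecutive pulse intervals
   ≤ 10 ms. Species comes from ≥ 2 preceding search calls, with a
   one-call fallback to group level. The implementation is verified
   against a brute-force window-scan oracle including the 10.00 vs
   10.01 ms boundary.
4. **Song elements vs social calls** — for Pipistrelloid, *Plecotus*
   and unknown labels, a run of ≥ 5 consecutive song-type elements is
   required before elements count as song; shorter runs are downgraded
   to social calls. Echolocation calls may interleave without breaking
   a run; social calls break it. Nyctaloid song has no minimum run.
5. **Song events** — same-label song elements merged while gaps are
   ≤ 5 s; events may span recording boundaries at one turbine but never
   across turbines. Assembly is verified against a brute-force
   gap-partition oracle, including exhaustively over all 5⁴ gap
   patterns of short sequences.

## 3. Stereo 3D reconstruction (`windbat.stereo`)

### Camera model and triangulation

Each thermal camera is an angular pinhole: a pixel offset from the
principal point maps linearly to an angle, with per-axis scales
17.5°/640 px and 13.1°/480 px. Rays from both cameras are triangulated
by the midpoint of closest approach, which for unit direction vectors
coincides with the two-ray least-squares point (the tests verify this
against explicitly solved normal equations to 1e-9). The closest-approach
gap `gap_m` is kept as a per-point quality measure, and matching of
left/right detections within a frame is greedy on that gap.

### Geometry and resolution

`StereoRig.facing()` builds the study geometry: two cameras 16 m apart,
~200 m from the rotor, converged on the nacelle, offset 100 m along the
ground. The analytic one-pixel range resolution of a converged stereo
pair is `r²·Δφ / b` with `Δφ` the per-pixel angle and `b` the baseline,
giving ≈ 1.19 m at 200 m — consistent with the published ~1.5 m figure.
Monte-Carlo experiments with ±0.5 px Gaussian pixel noise yield a radial
RMS error well under 1.5 m.

### Density profile and attraction model

Positions are binned into 3 m spherical shells around the nacelle out to
60 m. Shell volumes are *clipped* to the region visible to both camera
frusta, estimated by Monte Carlo: radii sampled by inverse CDF
(`r = R·cbrt(u)` per shell), directions uniform, acceptance = inside
both frusta; the binomial standard error is propagated as a relative
volume SE per shell. Sampling is seeded and deterministic.

The attraction model `d(r) = a·exp(−r/λ) + c` is fitted to shell
densities for r ≥ 10 m (inside 10 m the rotor-swept volume dominates)
with `scipy.optimize.curve_fit`, weighted by shell counts.

**Identifiability collapse.** On flat scenes the (a, λ, c) surface has a
ridge: a tiny `a` with a huge `λ` mimics a constant, and the split
between `a` and `c` is arbitrary. If the fitted exponential's variation
across the window is below 5 % of the weighted mean density, the fit is
collapsed to the flat model (`a = 0`, `λ = ∞`, `c` = weighted mean).
The threshold separates the ridge regime observed on Poisson-flat scenes
(~1 % spurious variation) from genuine attraction signals (λ = 15 m
gives ~250 % variation) by more than an order of magnitude on each side.

## 4. Activity statistics (`windbat.activity`, `windbat.glmm`)

### Aggregation and design

Recordings are aggregated to cells of (site, year, month 4–10, species
group), with feeding-buzz and social-call recordings as binomial
numerators over recordings as trials. The fixed-effects design has 12
columns: intercept, a species-group dummy (Pipistrelloid = 1), five
orthonormal polynomial month contrasts (QR of the Vandermonde matrix on
the 7 month levels, signs fixed by `diag(R) > 0` — numerically identical
to R's `contr.poly(7)` truncated to 5 columns, verified against an
`Rscript` oracle when R is available), and the five group × month
interactions.

### GLMM

The model is a binomial-logit GLMM with random intercepts for site and
for observation (OLRE, absorbing overdispersion). statsmodels has no
frequentist binomial GLMM, so the fit is hand-rolled:

- **Inner problem**: penalized Newton iterations over (β, u, e) jointly.
  The OLRE block is diagonal, so it is eliminated by a Schur complement;
  the remaining system is dense and small.
- **Outer problem**: Nelder–Mead over the two log standard deviations,
  clipped to [−6, 3], maximizing the Laplace-approximate marginal
  likelihood.
- **Inference**: conditional (lme4-style) covariance of β at the mode;
  Wald z tests.

When both random terms are absent the workspace is built with zero
random-effect columns and the fit reduces *exactly* to a binomial GLM;
the tests verify agreement with statsmodels to 1e-4 on coefficients.
With random effects present, the fit is cross-checked against R's
`lme4::glmer` (bobyqa) via an `Rscript` oracle.

**Calibration evidence**: over 500 simulated null datasets the per-term
type-I error at α = 0.05 lies in [0.036, 0.064] for every fixed-effect
term, and 95 % Wald CIs cover planted group effects of 0.93 and 1.88
log-odds in ≥ 93 % of simulations. These checks run in the acceptance
test suite.

### Marginal means and contrasts

Marginal means are computed on the 2 × 7 group × month grid with
delta-method standard errors. All 91 pairwise contrasts carry a Tukey
adjustment via the studentized range distribution
(`scipy.stats.studentized_range.sf(|z|·√2, k, ν=1e6)`), clamped to be no
smaller than the unadjusted p-value to guard tail inaccuracies.
Spearman correlations between activity series use `scipy.stats.spearmanr`
and require ≥ 4 non-constant paired values.

## 5. Synthetic data (`windbat.synthetic`)

All generators take a seed, are exactly reproducible, and return a
ground-truth ledger alongside the data, so every downstream stage can be
scored for exact precision/recall rather than plausibility.

**Nights** (`simulate_night`): bat passes with truncated-lognormal
search-call intervals (μ = −1.9, σ = 0.5 in log-seconds, bounded to
[0.03, 0.9] s — the lower bound keeps search sequences clear of the
10 ms buzz rule, the upper bound keeps a pass inside one recording),
optional feeding buzzes (3–8 intervals drawn U(4, 9) ms), and optional
song bouts. End frequencies are drawn inside the assigned species' bin;
received levels follow the one-way sonar equation at the simulated
distance, closing the loop with the propagation module. Event streams
are split into recordings at gaps > 1 s. Two-bout songs include a short
echolocation prelude in the second recording so the classifier can
re-identify the species; the configuration enforces
`pause_hi + 2·song_gap_hi < song_merge_gap` so a planted song event can
never straddle the 5 s assembly gap.

**Flight scenes** (`simulate_flight_scene`): positions drawn by
rejection sampling — uniform in a ball, thinned by `d(r)/d(0)` to plant
an attraction profile, restricted to the joint camera frustum — then
projected to per-frame pixel detections with Gaussian pixel noise,
clamped to the sensor.

**Activity datasets** (`simulate_activity_dataset`): binomial cell
counts from a known 12-coefficient linear predictor plus Gaussian site
and observation intercepts, on the full site × year × month × group
grid.

## 6. Numerical choices and problem sizes

- Root finding: `brentq`, bracket [1, 1e6] m, `xtol` 0.01 m.
- Shell volumes: 100 000 Monte-Carlo samples per call (relative SE
  < 1 % per shell), seeded.
- Attraction fit: `curve_fit` with count weights; collapse rule above.
- GLMM: Newton tolerance 1e-10 on the penalized deviance; Nelder–Mead
  `xatol/fatol` tight enough that a 364-cell fit takes ~30 ms.
- Full test suite ≈ 150 tests in well under a minute excluding the
  simulation-calibration acceptance test, which runs 700 GLMM fits in
  ≈ 90 s.
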