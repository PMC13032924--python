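# windbat

Acoustic and 3D-thermal analysis of bat activity at wind turbines.

Bats are attracted to wind turbines, and some species perform **song
flights** around the nacelle during autumn courtship — a behavior that
puts them directly into the rotor-swept zone. `windbat` implements the
quantitative toolchain needed to study this from nacelle-height acoustic
monitoring and ground-based stereo thermal imaging:

- **Acoustic event classification** (`windbat.events`, `windbat.pipeline`)
  — a rule-based chain over parameterized call-event streams: a trigger
  filter, species(-group) identification from echolocation end
  frequencies, feeding-buzz detection (pulse intervals ≤ 10 ms), and
  separation of social calls from song elements, which are then merged
  into song events (gap ≤ 5 s, may span recordings).
- **Sound propagation** (`windbat.propagation`) — ISO 9613-1 pure-tone
  atmospheric absorption and sonar-equation distance solves: how far a
  nacelle recorder detects a song (trigger 37 dB SPL) and how far
  conspecifics can hear it (active space, hearing threshold 20 dB SPL).
- **Stereo 3D reconstruction** (`windbat.stereo`) — an angular pinhole
  model for two synchronized 640 × 480 px thermal cameras (17.5° × 13.1°
  field of view, 16 m base line, ~200 m stand-off), midpoint
  triangulation, nacelle-referenced density in 3 m spherical shells with
  Monte-Carlo frustum-clipped volumes, and a weighted fit of the
  attraction model d(r) = a·exp(−r/λ) + c.
- **Activity statistics** (`windbat.activity`, `windbat.glmm`) — monthly
  feeding/social activity proportions per species group, analysed with a
  hand-rolled Laplace-approximated binomial-logit GLMM (random intercepts
  for site and observation), orthogonal polynomial month contrasts,
  Tukey-adjusted marginal-mean contrasts and Spearman correlations.
- **Synthetic data** (`windbat.synthetic`) — seeded generators with
  ground-truth ledgers for every stage, so the whole chain is testable
  offline: call-event nights with planted buzzes and songs, 3D flight
  scenes with a known attraction profile, and activity datasets from a
  known mixed model.

## Worked example

Detection range and active space of bat song under study conditions
(20 °C, 60 % relative humidity):

```python
from windbat import default_profiles, song_active_space

profiles = default_profiles()
res = song_active_space(profiles["Plecotus spp."])
print(res.detection_range_m)   # ~25.1 m  (recorder trigger, 37 dB SPL)
print(res.active_space_m)      # ~42 m    (conspecific hearing, 20 dB SPL)

res = song_active_space(profiles["Vespertilio murinus"])
print(res.detection_range_m)   # ~114-118 m: loud 14 kHz song carries far
```

Simulate a night, classify it, and score against the planted truth:

```python
from windbat.synthetic import simulate_night
from windbat.pipeline import classify_recordings

recordings, truth = simulate_night(seed=1)
result = classify_recordings(recordings)
print(result["manifest"])          # counts + rules hash
print(len(result["buzzes"]), "buzzes detected,",
      len(truth.buzzes), "planted")   # identical by construction
```

Reconstruct a stereo scene and recover the attraction length scale:

```python
import numpy as np
from windbat.stereo import (StereoRig, match_and_triangulate, shell_edges,
                            shell_volumes, density_profile, fit_attraction_model)
from windbat.synthetic import simulate_flight_scene, FlightSimConfig

scene = simulate_flight_scene(FlightSimConfig(n_positions=2000, lambda_m=15.0), seed=1)
positions = match_and_triangulate(scene.rig, scene.detections)
edges = shell_edges()                      # 3 m shells out to 60 m
vol, se = shell_volumes(scene.rig, np.zeros(3), edges, seed=0)
fit = fit_attraction_model(density_profile(positions, edges, vol, se))
print(fit.lambda_m)                        # ~15 m
```

Fit the activity GLMM:

```python
from windbat.synthetic import simulate_activity_dataset, ActivitySimConfig
from windbat.activity import fit_activity_glmm, marginal_means_and_contrasts

cells, truth = simulate_activity_dataset(
    ActivitySimConfig(beta=(-4.0, 0.93) + (0.0,) * 10), seed=1)
fit = fit_activity_glmm(cells, response="feeding")
print(fit.summary_frame().head(2))         # recovers the 0.93 group effect
emm, contrasts = marginal_means_and_contrasts(fit)
```

## Command line

```bash
windbat propagate                          # per-species ranges table
windbat simulate night --seed 1 --out ev.csv
windbat classify ev.csv --out-dir out/
windbat simulate activity --seed 1 --out cells.csv
windbat glmm cells.csv --response feeding
windbat density --seed 1 --n-positions 2000
```

## Reproduction

```bash
pytest                                      # full suite incl. acceptance tests
python scripts/acceptance.py --seed 1 --out results.json
```

`scripts/acceptance.py` recomputes the headline quantities (per-species
detection ranges and active spaces, stereo resolution and triangulation
error, attraction-model recovery, classifier precision/recall, GLMM
effect recovery) and writes them to JSON.

One acceptance test is expected to fail: the published 100 m active space
for *V. murinus* is mutually inconsistent with its published 114.3 m
recorder detection range under any propagation convention (see
`docs/methods.md`); the test asserts the published value unweakened
rather than papering over the discrepancy.

## Documentation

Model assumptions, calibration methodology and numerical design choices
are documented in [`docs/methods.md`](docs/methods.md).
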