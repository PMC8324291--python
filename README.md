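# itlearn

Simulation of unsupervised, temporal-contiguity-driven plasticity in
inferior temporal (IT) cortex and its predicted consequences for human
size-tolerant object discrimination.

## The scientific problem

The ventral visual stream supports object recognition that tolerates image
transformations such as size changes. One long-standing hypothesis is that
this tolerance is learned — and continuously maintained — from the temporal
statistics of natural viewing: images that follow each other closely in
time usually belong to the same object, so neurons that associate
temporally contiguous images will come to respond similarly to different
views of one object. Exposing observers to *swapped* temporal pairings
(object A at one size followed by object B at another) should therefore
gradually **break** size tolerance, while normal *non-swapped* pairings
should **build** it.

`itlearn` implements an end-to-end computational chain that turns this
hypothesis into quantitative behavioral predictions:

1. **Generative IT model** (`itlearn.stats`, `itlearn.population`) — each
   simulated site is a draw from a multi-dimensional Gaussian over a
   64-object preference space (block category covariance), multiplied by a
   size-tuning kernel from a pool; responses to concrete images add cached
   per-exemplar clutter offsets and Poisson-like repetition noise, all in
   normalized response units (nru, ≈ 23 spikes/s each).
2. **Plasticity rule** (`itlearn.plasticity`) — after each exposure event
   (leading then lagging image), ΔFR_leading = α (FR_lagging − FR_leading)
   with α = 0.0016 nru/event; includes the single-site swap-design
   replication and grid-search calibration of α against reference
   selectivity trajectories, Δ(P−N)/(P−N).
3. **IT-to-behavior linking model** (`itlearn.decoder`) — 2AFC choices by
   Pearson correlation of the evoked population vector with frozen
   class-mean templates (defaults: n = 260 sites, m = 20 training images);
   lapse rate λ injects random guesses (accuracy ceiling 1 − λ/2);
   performance is pooled d′ = Z(TPR) − Z(FPR) with ε = 1e-4 clipping
   (|d′| ≤ 7.4), plus trial bootstrap for SEs and p-values.
4. **Experiment driver** (`itlearn.experiment`) — alternates 200-trial test
   phases with 400-event exposure epochs (designs u1 = break,
   u2 = build, u3 = build-then-break; plus a single-epoch 800-event
   difficulty sweep across a task bank), and reports learning effects
   (target-minus-control Δd′ at the exposed size) over run ensembles.

It is intended for computational neuroscientists who want a tested,
reusable and fully synthetic (no data downloads) version of this model
chain for exploration, calibration experiments, and extension.

## Worked example

```python
import itlearn as il

stats = il.generate_population_statistics(seed=1)      # synthetic IT statistics
ens = il.average_model_runs(                            # 25 simulated subjects
    il.ExperimentDesign.u1(), stats, n_runs=25, base_seed=42
)
print("pre-exposure pooled d' (target @ big):",
      round(ens.pooled_dprime_curve(('target', il.BIG))[0], 2))
for ev, eff, se in zip(ens.events, ens.mean_effect, ens.se_effect):
    print(f"{ev:6.0f} events: learning effect {eff:+.2f} +/- {se:.2f}")
```

prints

```
pre-exposure pooled d' (target @ big): 2.35
     0 events: learning effect +0.00 +/- 0.00
   400 events: learning effect -1.45 +/- 0.37
   800 events: learning effect -2.32 +/- 0.41
  1200 events: learning effect -4.13 +/- 0.54
  1600 events: learning effect -5.03 +/- 0.61
```

The target pair starts in the human-typical difficulty range (pooled
d′ ≈ 2.4 at the exposed size). Swapped exposure (u1) drives the learning
effect — the d′ change for exposed objects minus the change for unexposed
control objects — increasingly negative with exposure dose: size tolerance
is being "broken", while control tasks and the non-exposed size stay flat.
`ExperimentDesign.u2()` shows the opposite (building) direction and
`ExperimentDesign.u3()` builds then reverses. See `docs/methods.md` for the
model's assumptions, calibration, and limitations.

A thin CLI wraps the same library calls:

```bash
itlearn simulate-population --n-sites 260 --seed 1 --out out/pop
itlearn calibrate-alpha --alpha-true 0.0016 --seed 0 --out out/alpha
itlearn run-experiment --design u1 --runs 25 --seed 0 --out out/u1
itlearn sweep-difficulty --lapse 0 --lapse 0.09 --seed 0 --out out/sweep
```

Every run writes a `manifest.json` (seeds, config, version) sufficient to
reproduce its outputs bit-for-bit.

## Optional recorded-data adapter

`itlearn.load_recorded_statistics(path)` builds the same statistics object
from a CSV of recorded trial-level responses with columns
`site, object, size, exemplar, rep, response` (responses on the z-score/nru
scale; sizes coded 0/1/2). If such a table (plus a reference distance
matrix and plasticity trajectories) is placed under `data/archive/`, the
opt-in tests in `tests/test_archive_optional.py` compare the generative
model against the recordings; without the data they skip.

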