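# Methods

## Overview

`itlearn` simulates how unsupervised visual experience — temporally
contiguous pairs of images — changes the responses of inferior temporal (IT)
cortex neurons, and how those neural changes translate into measurable
changes in human size-tolerant object discrimination. The model has three
locked components and a driver:

1. a **generative IT population model** (multi-dimensional Gaussian over
   object preferences, times a size-tuning kernel per site),
2. an **IT-to-behavior linking model** (correlation readout of 260 sites
   against frozen class-mean templates built from 20 training images per
   object, with an optional lapse rate),
3. an **unsupervised plasticity rule** with one parameter, the rate
   α = 0.0016 nru per exposure event,
4. an **experiment driver** that alternates 200-trial test phases with
   400-event exposure epochs and reports learning effects as changes in
   pooled d′.

## Units

Responses are expressed in normalized response units (nru): the z-score
scale of a site's across-object response distribution. The default
conversion is 1 nru ≈ 23 spikes/s around a 90 spikes/s mean multi-unit
rate, so the default plasticity rate corresponds to ≈ 0.037 spikes/s of
firing-rate change per exposure event for a 1-nru response gap
(`rate_to_spikes`).

## Generative IT model

Each simulated site draws a 64-element object-preference vector from a
multivariate Gaussian whose covariance has a block category structure:
8 categories of 8 objects, with within-category correlations graded from
0.998 (nearly collinear, subordinate/face-like discriminations) down to
0.75, and 0.20 between categories. The preference vector is multiplied
(outer product) by a 3-point size-tuning kernel drawn from a pool of 168
kernels mixing flat, monotone, and medium-peaked shapes — the mixture is
tilted toward baseline(medium)-size-preferring tuning (mean gains ≈ 0.9 /
1.2 / 0.6 for small / medium / big), as in recorded IT populations that were
characterized at the baseline size. Initialization is therefore exactly
separable (rank-1 object × size response matrix): perfect size tolerance
before any exposure.

Image-level variability has two sources:

* **clutter variance** σ²_clutter: an additive offset per
  (object, size, exemplar) condition, drawn once per condition and cached
  (exemplar identity is stable across test phases), with per-object
  variances drawn from a Gamma(2, ·) distribution with mean 0.25 nru²;
* **repetition noise** σ²_repeats: Poisson-like trial noise whose variance
  equals the underlying firing rate on the spikes/s scale (fano = 1),
  mapped back to nru².

### Calibration of the generator defaults

The linking model's hyperparameters (n = 260 sites, m = 20 training images)
are fixed by prior work; matching initial behavioral performance at those
hyperparameters is part of the model specification. The generator defaults
above were therefore calibrated once, before any learning simulations were
interpreted, so that at (260, 20) the within-category pairs span the
human-behavior range (pooled initial d′ ≈ 0.1–3, with the default
target pair near d′ ≈ 2.5) and between-category ("basic-level") pairs are
saturated (d′ at the measurement bound), mirroring the subordinate vs.
basic-level split of the behavioral task bank. They were not revisited
afterwards.

What the generator does **not** emulate: image-computable encoding (images
are abstract (object, size, exemplar) tuples), position/pose tuning,
correlated (shared) trial-to-trial noise across sites, non-Gaussian
preference distributions, and any non-stationarity of the recording. A
passing simulation therefore shows internal consistency of the model chain,
not fidelity to any particular recorded population.

## Plasticity rule

After each exposure event (leading image then lagging image, both clean —
no clutter term),

    ΔFR_leading = α (FR_lagging − FR_leading)

applied to every site's clean mean response to the leading condition only.
The rule is temporally asymmetric; since the leading/lagging order is
randomized ~50/50 across events, both paired conditions drift toward each
other over a session. Under strict alternation the pair's response gap
contracts exactly by (1 − α) per event — this closed form is used as an
oracle in the tests. Decoder templates are frozen before exposure and never
updated; clutter offsets are re-applied unchanged around the updated means
at test time.

### Single-site exposure-design replication and rate calibration

`replicate_neural_exposure_design` reproduces the classic single-electrode
design: for each site, its preferred (P) and non-preferred (N) objects are
chosen from the size-averaged responses and frozen; four interleaved arrow
types (P@medium↔N@swap-size, N@medium↔P@swap-size, P@medium↔P@non-swap,
N@medium↔N@non-swap) deliver 400 events each (1600 total; 200/arrow
available via argument, since the source descriptions differ). The summary
statistic per condition (swapped / medium / non-swapped size) is the change
in the mean P-vs-N response over P>N-selective sites, normalized by the
initial mean gap. We deliberately normalize the mean rather than averaging
per-site ratios: sites with near-zero initial gaps make the per-site ratio
heavy-tailed, and the mean-level normalization is what makes the rate fit
identifiable at the grid resolution used.

The default size roles swap at the small size and keep the big size
non-swapped: with the medium-peaked kernel pool the big size has clear
headroom below its medium-anchored steady state, producing the positive
("building") non-swapped trajectory alongside the negative swapped one.

`fit_plasticity_rate` grid-searches α (default log grid 1e-4…1e-2 plus
0.0016) minimizing the unweighted MSE between simulated and reference mean
trajectories across the three conditions jointly. Synthetic references
generated at α = 0.0016 with 500 sites are recovered exactly on grids
containing the true value for typical seeds; identifiability is limited by
the sampling noise of a single 500-site reference experiment, so grids finer
than ~8% around the optimum are not meaningfully resolved.

A caveat found in simulation: the *magnitude* of the non-swapped (building)
trajectory is not monotone in α at fixed event count — at 4× the calibrated
rate the build overshoots and reverses within 1600 events because the
medium-size hub itself degrades. Swapped and medium-condition magnitudes
are monotone in α.

## Linking model (decoder and psychophysics)

A 2AFC task between objects A and B is decided by Pearson correlation of
the evoked 260-site population vector with each object's frozen template
(mean response to m = 20 generated training images, sizes drawn uniformly
over the three levels; test images are never used in training). Exact ties
break by a seeded fair coin. Lapses replace the choice with a fair coin on
a fraction λ of trials, capping measurable accuracy at 1 − λ/2 (95.5% at
λ = 0.09, 90% at λ = 0.20). Performance is the pooled
d′ = Z(TPR) − Z(FPR) with rates clipped to [1e-4, 1 − 1e-4], bounding |d′|
at 2·Z(0.9999) ≈ 7.44 (reported as ±7.4). Bootstrap SEs and p-values
resample trials with replacement (1000 resamples by default); p-values are
two-sided tail fractions of the resampled change distribution against zero.

Because templates are estimated from 20 noisy training images, individual
frozen decoders can be strongly biased toward one choice; this is a real
property of the linking model at these hyperparameters, washes out across
model runs, and is the reason per-run d′ values are noisy while pooled
(across-run) confusion matrices are stable. Learning curves therefore
report both the run-average of Δd′ (with SE over runs) and the
pooled-confusion d′.

## Experiments

One simulated subject = one fresh 260-site population + frozen decoders for
the target and control pairs. A test phase holds 200 trials — per object:
10 small + 10 big size tests, 5 medium baselines, 25 cover trials (cover
trials are generated and classified but excluded from analysis, and test
phases cause no plasticity). Six size-specific sub-tasks exist (2 pairs ×
3 sizes); three are analyzed: target@exposed-size, control@exposed-size,
target@non-exposed-size. The learning effect is
Δd′(target@exposed) − Δd′(control@exposed) relative to the first test
phase.

Designs: u1 = four swapped 400-event epochs (medium↔big), u2 = four
non-swapped epochs, u3 = two non-swapped then two swapped epochs, and a
difficulty sweep using a single 800-event swapped epoch bracketed by two
test phases. Ensembles average 25 independent runs by default in the tests
and acceptance script (the full-scale reference is 100 runs; 25 keeps the
suite fast while leaving the run-level t-tests well powered for the default
conditions). Exposure events alternate between the two pairings of the
flavor in a fully shuffled order with randomized leading/lagging direction.

The sweep task bank contains six subordinate (within-category) tasks from
the tightest categories plus three basic-level (between-category) tasks,
mirroring the face/basic-level composition of the behavioral bank: the
subordinate tasks span near-chance to clearly-discriminable, and the
basic-level tasks are far above the lapse ceiling, which is what produces
the inverted-U of measurable learning effects under a 9% lapse rate (large
underlying changes at high initial d′ are hidden by the ceiling).

In u3 the breaking epochs overshoot: the effect ends below zero rather than
returning to it, as in the measured human build-then-break curves; the
package asserts the rise-then-fall shape, not a literal return toward zero.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.SeedSequence` spawning; any
  top-level seed reproduces every artifact bit-for-bit.
* PSD checks tolerate eigenvalues ≥ −1e-8 × trace; empirical covariances
  from the data adapter are eigenvalue-clipped to PSD.
* Selectivity (P − N)/(P + N) uses an ε = 1e-6 denominator and flags the
  size degenerate when P + N ≈ 0 or P = N; on the zero-mean nru scale this
  ratio is ill-conditioned, so subgroup selection thresholds the raw nru
  gap by default.
* Constant population vectors yield zero correlations with a warning, both
  in distance matrices and in the consistency metric.
* Trial-level responses are not rectified (the nru scale is centered).

## Limitations

* The synthetic statistics are a structural stand-in, not a fit to any
  recorded dataset; quantities that depend on the archived recordings
  (representational similarity to real IT, the 24-task behavioral
  consistency, the absolute decoder crossing point) are only checked for
  internal consistency unless the archive adapter is given real data.
* Homeostatic or weight-level plasticity mechanisms, attention, adaptation,
  and per-subject lapse estimation are out of scope.
* With 20 analysis trials per sub-task per phase, single-run d′ is heavily
  quantized by the ε-clipping; inference should use run ensembles or pooled
  confusions, as the acceptance script does.
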