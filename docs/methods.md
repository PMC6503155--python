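# Methods

`isobold` implements a complete event-related fMRI analysis chain for
comparing BOLD responses to painful (laser) and tactile (electrical)
stimuli whose *perceived* intensities have been matched trial by trial,
together with a synthetic cohort generator that reproduces the statistical
structure the analyses assume. This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
validation does and does not demonstrate.

## Study design emulated by the generator

Each subject completes two sessions of 24 trials. A trial lasts 25 s:
a 2-s lead-in, a 10-s stimulation window containing exactly one brief
stimulus at a uniformly random time (jitter), a 3-s gap, and a 10-s rating
period in which the subject reports perceived intensity on a 0–10 visual
analogue scale. Trials come in six alternating same-modality blocks of
four (two low + two high physical intensity, randomly ordered); the
starting modality alternates across sessions and subjects. Volumes are
acquired every TR = 0.8 s, giving 750 scans per session. The stimulus→
rating lag is therefore 3–13 s, which is why stimulus- and rating-evoked
responses overlap and must be disentangled (see template removal).

Perceived-intensity ratings are truncated Gaussians on [0, 10] with
per-(modality, level) pre-truncation moments

| condition     | mean | SD   |
|---------------|------|------|
| pain, low     | 2.76 | 1.54 |
| pain, high    | 5.59 | 1.51 |
| tactile, low  | 3.06 | 1.14 |
| tactile, high | 5.65 | 1.26 |

Moment checks compare sample means against the *truncated* distribution's
exact mean (the truncation shifts the pain-low mean by ≈ +0.06). The
observed moments conflate between- and within-subject variance; no split
is modelled because none is available.

## Regional response model

Every voxel of region *g* carries the region signal

    s_g(t) = Σ_trials A · h_d(t − onset − δ_pain) + rating response + noise,
    A = amp_modality(g) + slope(g) · (rating − 5)

where `h_d` is the canonical double-gamma HRF convolved with a boxcar of
neural duration `duration_s` (0 = impulse), `δ_pain = peak_shift_s` delays
pain responses only, and amplitudes are centred at the mid-scale rating 5
so `amp_*` is the response at a middling percept. Pain's later, longer
response is expressed through `peak_shift_s` and `duration_s` rather than a
different kernel family — two interpretable knobs. The rating period adds a
common 10-s boxcar response (`rating_amp`, default 0.5 a.u.) in every
region.

Default effect sizes (chosen once as a plausible single-event BOLD
scenario, ~1% signal-change-scale units against unit noise): preferential
regions respond 1.0 vs 0.5 a.u. (pain-preferential ones additionally with
1-s peak delay and 2-s duration), null regions 0.7 vs 0.7; intensity slope
0.15 a.u. per rating unit. Noise is AR(1) (innovation SD 1.0 a.u., ρ = 0.3)
plus slow cosine drifts (amplitudes 1.0 and 0.5 over periods ≥ the session
length, removable by the high-pass set) and optional leakage of six smooth
random-walk motion parameters (off by default, but the motion covariate
path is always exercised). All randomness is drawn from streams keyed by
(seed, subject index), so cohorts are reproducible and subjects
independent.

The generator and the GLM share one regressor-sampling routine (microtime
convolution, below), so noiseless data lie exactly in the design span and
parameter recovery is exact to numerical precision; independent brute-force
convolution oracles in the test suite guard against the two paths drifting
together.

## Trial matching

For each painful trial with rating *r*, taken in chronological order, the
not-yet-paired tactile trial with the closest rating inside the closed
interval [r − 0.5, r + 0.5] is selected (ties → earliest tactile onset); no
candidate leaves the painful trial unmatched. Matching is one-to-one:
reusing a tactile trial would double-count it in the event partition of the
five-condition GLM. Greedy order effects are bounded — a maximal matching
is at least half the maximum bipartite matching — and the observed deficit
against the exact maximum (SciPy's Hopcroft–Karp) is logged by the test
suite; it is typically 0–3 pairs on 24-trial tables.

The median split pools all of a subject's ratings; strictly above the
pooled median is "high", strictly below "low", and ties at the median are
dropped (the labels are defined only by strict inequality). Count
equalization removes trials nearest the median (ties → earliest onset) from
the larger group only.

## First-level GLM

The canonical HRF is a difference of gamma densities (peak delay 6 s,
undershoot delay 16 s, dispersions 1, ratio 1/6, 32-s support) normalised
to peak 1. Regressors are built at microtime resolution (16 bins per TR)
and sampled at the middle bin of each scan (a deterministic stand-in for
slice timing, which is out of scope). Stimulus events are impulses
(duration 0; configurable), rating periods 10-s boxcars.

The five-condition design models matched pain, matched tactile, remaining
pain, remaining tactile and the rating period per session, each with its
temporal derivative (finite-difference kernel derivative, not
orthogonalised against its parent; amplitude contrasts use canonical
columns only), plus six motion parameters, a discrete-cosine high-pass set
with K = ⌊2·T/128 s⌋ columns, and a session mean. The parametric design
collapses all stimuli into one regressor plus a modulator whose impulse
heights are session-mean-centred ratings (centred, not otherwise
orthogonalised — centring alone makes its beta the intensity slope; full
orthogonalisation is exposed as a config choice but off by default).
Empty conditions (e.g. no unmatched pain trials) drop their column with a
logged warning; contrasts addressing a dropped column raise an error
naming it.

Fitting is per-voxel OLS through a single SVD; rank-deficient designs fall
back to the pseudoinverse with degrees of freedom from the rank. No
prewhitening: second-level inference is by permutation and does not rely on
first-level whiteness. Contrasts are specified by condition name and
averaged across sessions (equal session weights). t-maps use
t = w'β / √(σ̂² · w'(X'X)⁺w).

## Second-level permutation inference

One-sample tests on subject effect maps flip the sign of whole subject
maps (one sign per subject per permutation), valid under symmetric errors.
Family-wise error control uses the max-statistic null: the maximum |t| (or
signed t, per tail) over the mask for voxel-level FWE, and the maximum
suprathreshold cluster size for cluster-level FWE with a cluster-defining
threshold of p < 0.001 (Student-t quantile at n−1 dof, one-tailed for
directional tests). Clusters are formed with 18-connectivity by default
(6 and 26 are available; the choice is not dictated by anything in the
data, so it is configuration). p-values use the (b+1)/(m+1) estimator, so
they are valid and never below 1/(n_perm+1). With n ≤ 12 subjects and
2ⁿ ≤ n_perm all sign assignments are enumerated exactly; the exhaustive
path doubles as the oracle for the sampled path in the tests. Defaults:
5000 permutations, α = 0.05.

The modality analysis tests pain and tactile activation maps against zero
over the whole mask (one-tailed), forms the union of the two thresholded
maps, and tests the difference contrast one-tailed in both directions
*inside the union mask* — the union restricts both the statistic image and
the max-statistic null — plus a conjunction (intersection) map. Region-wise
paired comparisons (AUC analyses) use the same machinery on subject×region
matrices with the max statistic taken across regions.

## Model-free time-course analysis

A trial course is the spatial mean of a region's raw BOLD over
[−1.6 s, +20 s] around the stimulus, sampled at the nearest volume (no
interpolation — at TR 0.8 s the grid is fine and interpolation would bias
the AUC), minus the mean of the two pre-stimulus samples. The 20-s window
covers the HRF return plus the prolonged pain response; the exact extent is
a documented choice, not given by the source material.

Because the rating act (button presses) evokes its own response 3–13 s
after the stimulus, an average rating-locked course per region is
subtracted from each stimulus-locked course, aligned by the trial's actual
stimulus→rating lag (per-trial alignment is the only choice consistent
with the jittered lag). Pre-stimulus samples are never altered. Two
refinements make the subtraction consistent when rating responses outlast
the trial pace (with 25-s trials a 10-s rating boxcar convolved with a
32-s kernel reaches well into the next trial): the template is extracted
on a window long enough to cover both the longest lag before its onset and
one full trial pace after it, and each post-stimulus sample is corrected
using the template aligned to the *most recent* rating onset, re-referenced
to the template's own value over that trial's pre-stimulus baseline phase.
Because rating onsets recur at the fixed trial pace, the rating-locked
average already contains the neighbouring responses at their correct
phases, so this single subtraction removes the previous trial's bleed-in
between the stimulus and the current rating onset as well — exactly so in
the stationary interior of a session. Limitation: session-edge trials
break stationarity (the first trial has no predecessor), leaving a small
edge residual (~7% of the template peak under the 25-s design, <2% when
trials are spaced so responses do not overlap); the template-removal
validation uses the spaced configuration (32-s lead-in, same 3–13 s lag
structure) to verify the mechanics without the edge effect.

The AUC is the signed trapezoidal integral of the corrected course from
stimulus onset to the window end (a.u.·s; a rectified variant is
available). Subject×region×condition AUCs of trial-mean courses feed the
paired sign-flip test; by linearity the trial-mean-then-AUC and
AUC-then-mean orders agree exactly. Per-timepoint paired t-tests on the
group mean courses are reported uncorrected as descriptive annotation;
inference rests on the AUC permutation test.

The intensity-mismatch analysis compares, in pain-preferential regions,
low-perceived-intensity pain against high-perceived-intensity touch (and
symmetrically for tactile-preferential regions), after the pooled median
split and count equalization. When the intensity slope dominates the
modality amplitude gap the comparison reverses — intensity, not modality,
drives the response — and with slope 0 the preference persists; both
regimes are checked in simulation.

## Numerical and validation choices

- Gaussian smoothing (σ = FWHM/√(8 ln 2), reflective boundaries) is an
  optional stage, default off: the generator produces pre-aligned,
  unsmoothed data, and smoothing belongs to preprocessing.
- Event tables round-trip bitwise (%.17g writing, round-trip float
  parsing); with a fixed seed the whole pipeline is byte-reproducible.
- Validation experiment sizes (see `isobold.experiments`): matching fuzz on
  100 tables; noiseless recovery on a 12³ grid with 2×750 scans;
  permutation exactness at n = 8 (256 exhaustive flips vs 5000 samples);
  FWER calibration over 200 null cohorts of 16 subjects on 10³ voxels with
  500 permutations; preference recovery over 25 cohorts of 30 subjects
  with 50 regions (1000 permutations); mismatch regimes over 20 cohorts of
  8 subjects. These sizes keep each experiment in the minutes range on one
  CPU while leaving the binomial/Monte-Carlo intervals tight enough to be
  informative.

## What the synthetic validation does not show

The generator omits physiological noise (cardiac/respiratory),
susceptibility artifacts, anatomical variability, head-motion-induced
signal (unless leakage is enabled) and HRF variability across regions and
subjects. Recovery and calibration results on synthetic cohorts therefore
demonstrate correctness of the procedures under the stated model, not
performance on real data; in particular the GLM's power advantage over the
model-free AUC route partly reflects that the generator's HRF matches the
analysis HRF exactly.
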