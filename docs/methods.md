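# Methods

This note documents the models, conventions and design choices behind
fearphot's pipeline: what each stage assumes, which knobs matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Session designs

The generator reproduces a four-day differential aversive-conditioning
protocol. All CS are 20-s tones; the US is a 2-s footshock whose onset
coincides exactly with the paired CS+ offset; both channels are sampled at
10 Hz on one shared timebase.

| day | trials | ITI mean |
|---|---|---|
| habituation | 30 CS− | 30 s |
| conditioning | 5 CS− + 5 CS+→US | 90 s |
| extinction | 5 CS− + 30 CS+ | 70 s |
| retrieval | 5 CS− + 10 CS+ | 70 s |
| opto extinction / retrieval | 30 / 6 CS+ | 70 s |

Two layout details are not fixed by the protocol and are explicit
conventions here: ITIs are drawn uniformly on [mean − 20, mean + 20] s
(simple, mean-correct, bounded), and CS types are interleaved by seeded
rejection sampling with at most two consecutive same-type trials. The
two-in-a-row cap is combinatorially impossible for the majority type when
30 CS+ share a session with 5 CS− (at most 2·(5+1) = 12 majority trials
could be placed), so on such days the cap applies to the minority type
only. Optogenetic "inhibition" sessions attach one laser epoch per CS from
400 ms before onset to 3 s after offset; "activation" sessions span the CS.

## Fluorescence forward model

```
signal(t)  = B_s·bleach(t) + Σ transients + g_s·M(t) + ε_s(t)
control(t) = B_c·bleach(t)                + g_c·M(t) + ε_c(t)
```

* `bleach(t) = 1 − f·(1 − e^(−t/τ))`, defaults τ = 600 s, f = 0.2 —
  a slow exponential approach shared in shape by both channels.
* `M(t)` is one shared motion process: a Gaussian random walk low-pass
  filtered at 0.5 Hz and standardized to SD 3 a.u. Default gains are
  proportional to the channel baselines (g_s/B_s = g_c/B_c), i.e. the
  artifact is multiplicative. This is the regime single-regressor
  isosbestic correction is built for: one OLS slope then removes bleach
  and motion jointly.
* Transients use a peak-normalized difference of exponentials
  `A·(e^(−t/τ_d) − e^(−t/τ_r))`, defaults rise 0.5 s, decay 3 s; the
  closed-form window integral serves as the oracle in tests. CS+ onset
  amplitudes are scaled per-trial by a learning curve (the extinction
  profile uses e^(−trial/5), prominent over the first ~5 trials); the
  post-offset suppression amplitude is applied unscaled, so the biphasic
  shape persists across extinction while the onset component decays — the
  planted structure the phase statistics are expected to resolve.
* White noise (SD 1 a.u.) is independent per channel. With a ~100 a.u.
  baseline this makes planted amplitudes read approximately in z units
  after normalization (exactly, when the control channel is noise-free).

What the generator does **not** emulate: spike-to-fluorescence dynamics,
hemodynamic or wavelength-specific artifacts, non-shared bleaching,
sensor nonlinearity, or inter-subject response heterogeneity beyond seed
variation. Passing recovery tests therefore demonstrates correctness of
the analysis chain under the stated artifact structure, not robustness to
every artifact real recordings can contain.

## Preprocessing

Motion correction fits the signal channel on the control channel by
session-wide OLS and subtracts the fit. Subtraction (rather than division
or ΔF/F) suffices because all downstream quantification uses baseline
z-scores, which are invariant to affine rescaling of the corrected trace;
this invariance is property-tested. A per-trial fit variant was
considered and rejected: the session-wide fit is the simplest contract
consistent with a single artifact process, and trials supply too few
samples for stable slopes. The acquisition nominally labels the control
LED 415 nm and its isosbestic point 410 nm; the module treats the control
channel generically, as nothing in the computation depends on the exact
wavelength. Channels arrive on one shared timebase in this data model; an
acquisition that timestamps channels separately would need the control
interpolated onto the signal clock before the fit.

Z-scoring uses the 20 s strictly preceding each CS onset (CS− trials
included, same rule) and rejects trials with zero baseline SD or
insufficient pre/post data, naming the trial. The aligned window is
[−20, +45] s at the session rate.

## Quantification

Windows are fixed relative to CS onset for a 20-s CS: onset10 [0, 10] s,
late10 [10, 20] s, offset5 [20, 25] s, evaluated on the nominal schedule
(schedules are ground truth here, so measured tone end is not used). Both
the trapezoidal integral (z·s) and the window mean z are stored per trial;
the integral is the default reported value since figure-caption usage of
"AUC" vs "mean z" varies. Windows are closed on the grid, so the [0, 20]
integral equals onset10 + late10 exactly at shared nodes. Population
traces average trials within subject first, then mean ± SEM across
subjects, matching SEM-across-subjects reporting.

## Statistics

* **Exact Wilcoxon signed-rank.** Zero differences dropped, midranks on
  ties, W = Σ sign·rank (can be negative). The exact two-sided p is
  P(|W*| ≥ |W|) under the equiprobable sign-flip null, computed by
  integer convolution over doubled ranks — algebraically identical to
  enumerating all 2ⁿ patterns (the test oracle does exactly that) but
  polynomial-time. n > 25 is refused rather than approximated; no
  large-sample mode is provided.
* **Greenhouse–Geisser.** Box's ε̂ from the within-subject contrast
  covariance, clipped to [1/(k−1), 1]; no Huynh–Feldt option. Correction
  is applied a priori to every RM ANOVA p-value, with ε and both df pairs
  reported. In the two-way fully-within design each effect is tested
  against its own effect×subject mean square with its own ε computed from
  Kronecker-structured orthonormal contrasts.
* **Calibration.** The null type-I suite uses cohorts of 30 subjects × 3
  conditions for the ANOVA (and n = 7 pairs for the t test, matching the
  study scale). At very small n Box's ε̂ is noisy and the corrected test
  is conservative — measured ≈ 0.03 at n = 7, k = 3 versus ≈ 0.048 at
  n = 30 — a known property of the estimator, not an implementation
  artifact; the calibration cohort size is chosen where the estimator is
  approximately unbiased so the check measures the implementation.
* **Gated selection.** Shapiro–Wilk (scipy's routine) on the paired
  differences gates at α = 0.05 between paired t and exact Wilcoxon; the
  gate p is logged but never reported as a result.
* **Not implemented.** REML mixed-effects models for unbalanced designs
  are out of scope; the tracing group comparison runs the balanced RM
  ANOVA on complete (synthetic) per-section tables instead — a documented
  deviation from what unbalanced real cell counts would require.

## Behavior

The freezing rule — boxcar-smoothed motion energy (displacement × frame
rate, default 0.1-s smoothing at 30 Hz) below a threshold (default
15 px/s) for at least 1 s — is the field-standard immobility criterion;
threshold, minimum bout and smoothing are explicit configuration, since
no canonical classifier is defined for tracked-centroid input. The
defaults were calibrated once against the generator's motion scales
(~75 px/s moving, ~2 px/s frozen) and sit two orders of magnitude above
the frozen-state energy, so recovered boundaries land within half a
smoothing window (≤ 2 frames) of planted epoch edges. Percentages are
per-CS interval intersections; the session baseline uses the 20 s before
the first CS−.

## Tracing

Midline-distance statistics are per-label mean ± SEM (single-cell groups
flagged degenerate with SEM 0); AP profiles use half-open bins with
edge cells assigned upward. The overlap ratio counts double-labeled cells
against all target-projecting cells (single + Both) by default —
"projecting to the target" naturally includes double-labeled neurons — with
a flag for the single-labeled-only denominator. In the generator,
`both_fraction` is the per-cell probability that a labeled neuron is
double-labeled, which makes single-cluster recovery exactly binomial.

## Numerical choices and degenerate inputs

* CSV writers use 17-significant-digit floats and readers parse with
  round-trip precision, so write→read is bit-exact; deinterleaved channel
  tables with unequal lengths (dropped frames) are refused, as are NaN
  samples (named by row), non-monotone timebases, unknown event kinds and
  unknown projection labels.
* ANOVA sums of squares are clamped to zero below 1e−12 of the total SS so
  exactly additive tables yield F = 0 rather than 0/0 noise; an exact fit
  (zero error SS with zero effect SS) reports F = 0, p = 1.
* RM ANOVA epsilon falls back to 1 when the contrast variance vanishes.
* Seeded cohort generation derives per-subject seeds from a
  `numpy.random.SeedSequence`, keeping every derived seed below 2³¹.

## Problem sizes used in checks

The recovery and calibration suites run at sizes chosen to make the
checks statistically decisive while remaining quick on one CPU: 2,000
null replicates for type-I error, 20 simulated cohorts of 7 subjects for
the biphasic power check, 20 subjects for the null-bias bound, 200–500
cells per cluster for tracing recovery, and 4–5 seeded sessions per
planted freezing fraction.
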