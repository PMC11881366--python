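# fearphot

Analysis pipeline for dual-wavelength fiber-photometry, freezing behavior,
and retrograde-tracing data from Pavlovian aversive conditioning and
extinction experiments — the kind of study that records bulk calcium
activity from projection-defined thalamic neurons (e.g. nucleus reuniens or
mediodorsal thalamus neurons projecting to ventromedial prefrontal cortex)
while mice learn that one tone (CS+) predicts a footshock (US) and another
(CS−) does not, and then extinguish that memory.

It is written for systems-neuroscience labs who want the full analysis
chain — from raw two-channel fluorescence to corrected, trial-aligned
statistics — as tested, reusable library code rather than one-off scripts,
plus a synthetic-data generator that emulates the session designs so every
stage can be validated against planted ground truth.

## What it computes

**Preprocessing.** The calcium-dependent channel (~470 nm) is corrected
with the isosbestic control channel (~410–415 nm) by session-wide ordinary
least squares,

```
corrected(t) = F470(t) − (β̂·Fiso(t) + α̂),
```

which removes motion (and proportionally shared bleaching) artifacts. Each
20-s CS trial is z-scored against the mean μ and SD σ of the 20 s
preceding its onset: `z(t) = (corrected(t) − μ)/σ`.

**Quantification.** Three peri-onset windows summarize the biphasic CS
response: onset [0, 10] s, late CS [10, 20] s, and post-offset [20, 25] s.
Each trial yields the trapezoidal AUC (z·s) and mean z; extinction trials
are blocked into CS−, early CS+ (first 5 trials) and late CS+ (last 5).

**Statistics** (implemented in-package, not wrapped): paired t;
exact Wilcoxon signed-rank with `W = Σ sign(dᵢ)·rank|dᵢ|` and a two-sided
p by full enumeration of the 2ⁿ sign-flip null; one- and two-way
repeated-measures ANOVA with a-priori Greenhouse–Geisser correction using
Box's ε̂ = tr(CSC′)²/[(k−1)·tr((CSC′)²)]; Šidák and Tukey
(studentized-range) post-hoc adjustment; and Shapiro–Wilk-gated selection
between the parametric and rank tests.

**Behavior and anatomy.** Freezing is scored as smoothed motion energy
below a threshold for ≥ 1 s, reported as percent of each CS period;
retrograde-tracing cell tables yield per-label midline-distance statistics,
anterior–posterior profiles, and dual-projection overlap ratios.

**Synthetic data.** `fearphot.simulate` generates the four-day session
design (habituation, conditioning, extinction, retrieval, plus optogenetic
variants), two-channel fluorescence with bleaching, shared motion artifact
and programmed CS/US transients, random-walk trajectories with planted
immobility, and Gaussian projection-labeled cell maps.

## Worked example

One command simulates an extinction cohort of 7 mice carrying a planted
biphasic CS+ response (onset excitation +1.5 z decaying over trials,
post-offset suppression −1.0 z) and runs the full chain:

```
$ fearphot demo --seed 7
onset10: phase RM-ANOVA          F/t/W=  11.2522 df=(1.401,8.4061) p=0.006383
late10: phase RM-ANOVA           F/t/W=   2.4083 df=(1.2641,7.5844) p=0.1608
offset5: phase RM-ANOVA          F/t/W= 113.9666 df=(1.417,8.5021) p=1e-06
freezing: {'CS_MINUS': 19.719, 'CS_PLUS': 69.748}
outputs in demo_out/
```

Reading the numbers: the onset-window ANOVA (fractional df are the
GG-corrected values) detects the early-trial CS+ excitation; the Tukey
table in `demo_out/report.json` shows CS− vs early-CS+ significant but
CS− vs late-CS+ not — the response extinguishes. The offset window shows
strong suppression in both CS+ phases, and the late-CS window shows no
effect. Freezing percentages recover the planted 20% / 70% immobility.
The same steps are available piecewise from Python; see `examples/`
(one narrative script per capability) and the `fearphot` subcommands
`simulate`, `preprocess`, `quantify`, `freezing`, `tracing`, `run`.

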