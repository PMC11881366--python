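"""Extinction-phase statistics on a simulated 7-mouse cohort.

For each window the per-trial AUCs are blocked into CS-, early CS+ (first
5 trials) and late CS+ (last 5 trials) phases, then compared with a
Greenhouse-Geisser-corrected one-way repeated-measures ANOVA and Tukey
post-hoc contrasts — the analysis that shows onset excitation confined to
early extinction and offset suppression throughout.
"""

from fearphot import pipeline

cohort = pipeline.simulate_cohort("extinction", n_subjects=7, profile="biphasic", seed=7)
df, _ = pipeline.quantify_cohort(cohort, session_name="extinction")
results = pipeline.analyze_extinction(df)

for window, res in results.items():
    a = res["anova"]
    print(f"{window}: F({a.df[0]:.2f}, {a.df[1]:.2f}) = {a.statistic:.2f}, "
          f"p = {a.p:.4g} (GG epsilon {a.epsilon:.3f})")
    for contrast, p in res["tukey"].items():
        print(f"    {contrast}: p = {p:.4g}")
# Expected pattern: onset10 CS- vs CS+E significant but CS- vs CS+L not
# (the onset response extinguishes); offset5 suppressed for both CS+ phases.
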