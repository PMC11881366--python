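"""Conditioning-day statistics on a simulated 7-mouse cohort.

The battery mirrors the acquisition-session analysis: a normality-gated
paired comparison (Shapiro-Wilk chooses paired t or the exact Wilcoxon
signed-rank test) of CS+ vs CS- AUCs, and a 2 CS-type x 5 trial two-way
repeated-measures ANOVA testing whether the CS+ response develops over
learning (the interaction term, uncorrected df (4, 24) with 7 subjects).
"""

from fearphot import pipeline

cohort = pipeline.simulate_cohort(
    "conditioning", n_subjects=7, profile="conditioning", seed=11
)
df, _ = pipeline.quantify_cohort(cohort, session_name="conditioning")
res = pipeline.analyze_conditioning(df)

for window in ("onset10", "offset5"):
    r = res[window]["paired"]
    stat = "t" if r.test == "paired_t" else "W"
    print(f"{window} CS+ vs CS-: {r.test}, {stat} = {r.statistic:.2f}, "
          f"p = {r.p:.4g}  [{r.note}]")

tc = res["trial_course"]
for label, r in (("CS type", tc.main_a), ("trial", tc.main_b),
                 ("interaction", tc.interaction)):
    print(f"trial-course {label}: F({r.df[0]:.2f}, {r.df[1]:.2f}) = "
          f"{r.statistic:.2f}, p = {r.p:.4g}")
# offset5 contains the shock-evoked transient on CS+ trials, so the paired
# comparison there reflects the US response; the interaction tests whether
# CS+ onset responses grow across the five pairings.
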