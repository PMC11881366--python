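"""Repeated-measures statistical battery for small-n within-subject designs.

Implemented here rather than wrapped: paired t, exact Wilcoxon signed-rank
by enumeration over sign flips, one- and two-way repeated-measures ANOVA
with the Box (Greenhouse-Geisser) sphericity correction applied a priori,
Sidak and Tukey (studentized-range) post-hoc adjustment, and Shapiro-Wilk-
gated selection between the parametric and rank tests. Only distribution
CDFs (t, F, studentized range) and the Shapiro-Wilk statistic come from
scipy.stats.

Conventions
-----------
* Wilcoxon W is the sum of signed ranks (negative when most differences are
  negative); zero differences are dropped; ties receive midranks; the exact
  two-sided p is P(|W*| >= |W|) under the 2^n equiprobable sign-flip null.
* Greenhouse-Geisser epsilon is Box's estimator
  eps = tr(C S C')^2 / (d * tr((C S C')^2)) for an orthonormal contrast
  basis C with d rows, clipped to [1/d, 1]; corrected df = eps * df.
* In the two-way fully-within design, every effect is tested against its
  own effect-by-subject interaction mean square, with its own epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import StatResult, ValidationError

__all__ = [
    "paired_t",
    "wilcoxon_signed_rank_exact",
    "signed_rank_distribution",
    "gg_epsilon",
    "rm_anova_one_way",
    "rm_anova_two_way",
    "TwoWayRMResult",
    "sidak_adjust",
    "tukey_rm",
    "select_test",
]


# ---------------------------------------------------------------- paired t

def paired_t(x, y) -> StatResult:
    """Two-sided paired t test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired samples must be 1-D and equal length")
    n = len(x)
    if n < 2:
        raise ValidationError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValidationError("degenerate: all differences identical")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2 * sps.t.sf(abs(t), df))
    return StatResult(test="paired_t", statistic=t, p=p, df=(float(df),),
                      df_uncorrected=(df,))


# ------------------------------------------------ exact Wilcoxon signed rank

def _midranks(a: np.ndarray) -> np.ndarray:
    """Ranks of |a| with ties assigned the mean of the tied positions."""
    order = np.argsort(a, kind="stable")
    ranks = np.empty(len(a), dtype=float)
    i = 0
    sorted_a = a[order]
    while i < len(a):
        j = i
        while j + 1 < len(a) and sorted_a[j + 1] == sorted_a[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # mean of 1-based positions
        i = j + 1
    return ranks


def signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W = sum(s_i * r_i), s_i = +/-1 equiprobable.

    Ranks are doubled to integers (midranks are multiples of 1/2), and the
    distribution of the positive-rank sum is built by polynomial
    convolution — algebraically identical to full 2^n enumeration but
    O(n * sum(r)) instead of O(2^n). Returns ``(support, counts)`` where
    ``support`` holds the achievable W values (on the original scale) and
    ``counts`` the number of the 2^n sign patterns achieving each.
    """
    r2 = np.rint(2 * np.asarray(ranks, dtype=float)).astype(int)
    if not np.allclose(2 * np.asarray(ranks, float), r2):
        raise ValidationError("midranks must be multiples of 1/2")
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:  # convolve with (1 + x^r): include rank in the positive set or not
        counts[r:] += counts[:-r].copy() if r > 0 else counts
    support2 = 2 * np.arange(total + 1) - total  # W2 = 2*Wplus2 - total
    return support2 / 2.0, counts


def wilcoxon_signed_rank_exact(d) -> StatResult:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    W is the sum of signed ranks; p = P(|W*| >= |W|) by exact enumeration
    of the sign-flip null. Zero differences are dropped before ranking.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1:
        raise ValidationError("differences must be 1-D")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValidationError("all differences are zero")
    if n > 25:
        raise ValidationError(
            "n > 25: exact enumeration refused; a large-sample mode is not provided"
        )
    ranks = _midranks(np.abs(d))
    w = float(np.sum(np.sign(d) * ranks))
    support, counts = signed_rank_distribution(ranks)
    p = float(counts[np.abs(support) >= abs(w) - 1e-9].sum() / 2.0**n)
    return StatResult(test="wilcoxon_signed_rank_exact", statistic=w, p=min(p, 1.0),
                      note=f"n={n} after dropping zeros")


# -------------------------------------------- Greenhouse-Geisser epsilon

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal basis of the contrast space (Helmert rows)."""
    c = np.zeros((k - 1, k))
    for i in range(1, k):
        c[i - 1, :i] = 1.0
        c[i - 1, i] = -i
        c[i - 1] /= np.linalg.norm(c[i - 1])
    return c


def gg_epsilon(S, contrasts: np.ndarray | None = None) -> float:
    """Box's sphericity epsilon from a k x k condition covariance matrix.

    eps = tr(M)^2 / (d * tr(M^2)) with M = C S C' for an orthonormal
    contrast basis C (d = rows of C, k-1 by default), clipped to [1/d, 1].
    Equals 1 exactly under compound symmetry and always when k = 2.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValidationError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValidationError("S must be symmetric")
    k = S.shape[0]
    if k < 2:
        raise ValidationError("need k >= 2 conditions")
    C = _orthonormal_contrasts(k) if contrasts is None else np.asarray(contrasts, float)
    d = C.shape[0]
    M = C @ S @ C.T
    tr2 = np.trace(M) ** 2
    denom = d * np.trace(M @ M)
    if denom <= 0:
        return 1.0  # zero contrast variance: sphericity trivially holds
    return float(np.clip(tr2 / denom, 1.0 / d, 1.0))


# -------------------------------------------------- repeated-measures ANOVA

def rm_anova_one_way(scores, posthoc: str | None = None) -> StatResult:
    """One-way repeated-measures ANOVA with a priori GG correction.

    ``scores`` is a complete balanced subjects x conditions table.
    F = MS_condition / MS_(condition x subject); uncorrected df
    (k-1, (k-1)(n-1)); the p-value uses eps-scaled df. ``posthoc="tukey"``
    appends all pairwise comparisons via the studentized range.
    """
    Y = np.asarray(scores, dtype=float)
    if Y.ndim != 2:
        raise ValidationError("scores must be subjects x conditions")
    if np.isnan(Y).any():
        raise ValidationError("missing cells: balanced complete data required")
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValidationError("need n >= 2 subjects and k >= 2 conditions")
    grand = Y.mean()
    cond_means = Y.mean(axis=0)
    subj_means = Y.mean(axis=1)
    ss_cond = n * float(((cond_means - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((Y - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    tol = 1e-12 * max(ss_total, 1.0)
    ss_cond = 0.0 if ss_cond < tol else ss_cond
    ss_err = 0.0 if ss_err < tol else ss_err
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        # all residual variation vanished; F is 0/0 or inf — treat exact fit
        f = 0.0 if ms_cond == 0 else np.inf
        p = 1.0 if ms_cond == 0 else 0.0
        eps = 1.0
    else:
        f = float(ms_cond / ms_err)
        eps = gg_epsilon(np.cov(Y, rowvar=False, ddof=1))
        p = float(sps.f.sf(f, eps * df1, eps * df2))
    result = StatResult(
        test="rm_anova_one_way", statistic=f, p=p,
        df=(eps * df1, eps * df2), df_uncorrected=(df1, df2), epsilon=eps,
    )
    if posthoc == "tukey":
        ph = tukey_rm(cond_means, ms_err, df2, n)
        result = StatResult(**{**result.__dict__, "posthoc": ph})
    return result


@dataclass(frozen=True)
class TwoWayRMResult:
    """Effects of a fully within-subject two-factor design."""

    main_a: StatResult
    main_b: StatResult | None
    interaction: StatResult | None


def _effect_test(ss: float, df: int, ss_err: float, df_err: int,
                 eps: float, name: str) -> StatResult:
    ms, ms_err = ss / df, ss_err / df_err
    if ms_err <= 0:
        f = 0.0 if ms == 0 else np.inf
        p = 1.0 if ms == 0 else 0.0
        eps = 1.0
    else:
        f = float(ms / ms_err)
        p = float(sps.f.sf(f, eps * df, eps * df_err))
    return StatResult(test=name, statistic=f, p=p, df=(eps * df, eps * df_err),
                      df_uncorrected=(df, df_err), epsilon=eps)


def rm_anova_two_way(scores) -> TwoWayRMResult:
    """Two-way fully within-subject ANOVA with per-effect GG correction.

    ``scores`` has shape (subjects, levels_a, levels_b); every effect is
    tested against its own effect-by-subject mean square. With a single
    level of factor B the main effect of A reduces exactly to the one-way
    repeated-measures result and B/interaction are returned as None.
    """
    Y = np.asarray(scores, dtype=float)
    if Y.ndim != 3:
        raise ValidationError("scores must be subjects x levels_a x levels_b")
    if np.isnan(Y).any():
        raise ValidationError("missing cells: balanced complete data required")
    n, a, b = Y.shape
    if n < 2 or a < 2:
        raise ValidationError("need n >= 2 subjects and a >= 2 levels of factor A")

    if b == 1:
        return TwoWayRMResult(
            main_a=rm_anova_one_way(Y[:, :, 0]), main_b=None, interaction=None
        )

    grand = Y.mean()
    m_a = Y.mean(axis=(0, 2))            # (a,)
    m_b = Y.mean(axis=(0, 1))            # (b,)
    m_ab = Y.mean(axis=0)                # (a, b)
    m_s = Y.mean(axis=(1, 2))            # (n,)
    m_sa = Y.mean(axis=2)                # (n, a)
    m_sb = Y.mean(axis=1)                # (n, b)

    ss_a = n * b * float(((m_a - grand) ** 2).sum())
    ss_b = n * a * float(((m_b - grand) ** 2).sum())
    ss_ab = n * float(((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_s = a * b * float(((m_s - grand) ** 2).sum())
    ss_as = b * float(((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum())
    ss_bs = a * float(((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_total = float(((Y - grand) ** 2).sum())
    ss_abs = ss_total - (ss_a + ss_b + ss_ab + ss_s + ss_as + ss_bs)
    tol = 1e-12 * max(ss_total, 1.0)
    ss_a, ss_b, ss_ab = (0.0 if s < tol else s for s in (ss_a, ss_b, ss_ab))
    ss_as, ss_bs, ss_abs = (0.0 if s < tol else s for s in (ss_as, ss_bs, ss_abs))

    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_as, df_bs, df_abs = df_a * (n - 1), df_b * (n - 1), df_ab * (n - 1)

    # per-effect contrast covariances on the flattened (a*b) condition scores
    cells = Y.reshape(n, a * b)
    S = np.cov(cells, rowvar=False, ddof=1)
    Ka, Kb = _orthonormal_contrasts(a), _orthonormal_contrasts(b)
    ja = np.full((1, a), 1 / np.sqrt(a))
    jb = np.full((1, b), 1 / np.sqrt(b))
    C_a = np.kron(Ka, jb)
    C_b = np.kron(ja, Kb)
    C_ab = np.kron(Ka, Kb)
    eps_a = gg_epsilon(S, C_a)
    eps_b = gg_epsilon(S, C_b)
    eps_ab = gg_epsilon(S, C_ab)

    return TwoWayRMResult(
        main_a=_effect_test(ss_a, df_a, ss_as, df_as, eps_a, "rm_anova_two_way:A"),
        main_b=_effect_test(ss_b, df_b, ss_bs, df_bs, eps_b, "rm_anova_two_way:B"),
        interaction=_effect_test(ss_ab, df_ab, ss_abs, df_abs, eps_ab,
                                 "rm_anova_two_way:AxB"),
    )


# ------------------------------------------------------------- post-hoc

def sidak_adjust(p, m: int | None = None) -> list[float]:
    """Sidak family-wise adjustment: p_adj = 1 - (1 - p)^m, capped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < 1:
        raise ValidationError("m must be >= 1")
    return [float(min(1.0, 1.0 - (1.0 - pi) ** m)) for pi in p]


def tukey_rm(cond_means, ms_error: float, df_error: float, n: int) -> list[dict]:
    """All-pairs Tukey HSD on repeated-measures condition means.

    q_ij = |m_i - m_j| / sqrt(MS_error / n); the adjusted p comes from the
    studentized range distribution with k groups and df_error error df.
    """
    means = np.asarray(cond_means, dtype=float)
    k = len(means)
    if k < 2:
        raise ValidationError("need at least 2 condition means")
    if ms_error <= 0:
        raise ValidationError("MS_error must be positive")
    se = np.sqrt(ms_error / n)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            q = float(abs(means[i] - means[j]) / se)
            p = float(sps.studentized_range.sf(q, k, df_error))
            out.append({"contrast": (i, j), "statistic": q, "p_adj": min(p, 1.0)})
    return out


# ------------------------------------------------------ gated test choice

def select_test(x, y, alpha_norm: float = 0.05) -> StatResult:
    """Normality-gated paired comparison.

    Shapiro-Wilk is run on the paired differences; if its p >= ``alpha_norm``
    the paired t test is used, otherwise the exact Wilcoxon signed-rank test.
    The gate's p-value is recorded in ``note`` but never reported as the
    result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired samples must be 1-D and equal length")
    if len(x) < 3:
        raise ValidationError("Shapiro-Wilk needs n >= 3")
    d = x - y
    if np.ptp(d) == 0:
        raise ValidationError("degenerate: all differences identical")
    sw_stat, sw_p = sps.shapiro(d)
    if sw_p >= alpha_norm:
        result = paired_t(x, y)
    else:
        result = wilcoxon_signed_rank_exact(d)
    note = f"shapiro_p={sw_p:.4g} -> {result.test}"
    return StatResult(**{**result.__dict__, "note": note})
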