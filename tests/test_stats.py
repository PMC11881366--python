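"""Statistical battery: every test statistic is checked against an
independent oracle (brute-force enumeration, from-scratch sums of squares,
eigenvalue identities, or pingouin as a third-party cross-check)."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h
from scipy import stats as sps

from fearphot.core import ValidationError
from fearphot import stats as st


# ---------------------------------------------------------------- oracles

def wilcoxon_brute_force(d):
    """Independent exact signed-rank p: enumerate all 2^n sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = np.sum(np.sign(d) * ranks)
    hits = 0
    for signs in itertools.product((-1.0, 1.0), repeat=len(d)):
        if abs(np.dot(signs, ranks)) >= abs(w_obs) - 1e-9:
            hits += 1
    return w_obs, hits / 2.0 ** len(d)


def one_way_ss_oracle(Y):
    """From-scratch sums-of-squares F for the one-way RM design."""
    n, k = Y.shape
    grand = Y.mean()
    ss_cond = sum(n * (Y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (Y[i].mean() - grand) ** 2 for i in range(n))
    ss_err = sum(
        (Y[i, j] - Y[i].mean() - Y[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


def box_epsilon_eigen(S):
    """Epsilon via eigenvalues of the double-centered covariance."""
    k = S.shape[0]
    H = np.eye(k) - np.ones((k, k)) / k
    lam = np.linalg.eigvalsh(H @ S @ H)
    lam = lam[lam > 1e-12]
    return float(np.clip(lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum()),
                         1 / (k - 1), 1))


# ---------------------------------------------------------------- paired t

def test_paired_t_hand_computation():
    # d = (1, 2, 3): mean 2, sd 1, t = 2 / (1/sqrt(3)) = 2*sqrt(3)
    res = st.paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-9)
    assert res.df_uncorrected == (2,)
    # quadrature oracle for the two-sided p under t(2)
    from scipy.integrate import quad
    dens = lambda x: sps.t.pdf(x, 2)
    p_oracle = 2 * quad(dens, abs(res.statistic), np.inf)[0]
    assert res.p == pytest.approx(p_oracle, rel=1e-8)


def test_paired_t_df_seven_subjects(rng):
    x = rng.normal(size=7)
    res = st.paired_t(x, x + rng.normal(size=7))
    assert res.df_uncorrected == (6,)


def test_paired_t_constant_shift_degenerate():
    x = np.arange(5.0)
    with pytest.raises(ValidationError, match="degenerate"):
        st.paired_t(x + 3.0, x)


# ---------------------------------------------------- exact signed rank

def test_signed_rank_one_signed_seven():
    """Seven one-signed distinct differences: W = 28, p = 2/128."""
    res = st.wilcoxon_signed_rank_exact([0.3, 1.1, 2.0, 0.7, 5.0, 3.3, 0.9])
    assert res.statistic == 28.0
    assert res.p == pytest.approx(0.015625, abs=1e-12)


def test_signed_rank_smallest_opposite_seven():
    """Flip the smallest-magnitude difference: W = 26, p = 4/128."""
    res = st.wilcoxon_signed_rank_exact([-0.3, 1.1, 2.0, 0.7, 5.0, 3.3, 0.9])
    assert res.statistic == 26.0
    assert res.p == pytest.approx(0.03125, abs=1e-12)


def test_signed_rank_sign_convention_negative_w():
    res = st.wilcoxon_signed_rank_exact([-1.0, -2.0, -3.0, 0.5])
    assert res.statistic < 0


def test_signed_rank_zero_and_overflow_guards():
    with pytest.raises(ValidationError, match="zero"):
        st.wilcoxon_signed_rank_exact(np.zeros(5))
    with pytest.raises(ValidationError, match="n > 25"):
        st.wilcoxon_signed_rank_exact(np.arange(1.0, 28.0))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st_h.lists(
        st_h.floats(min_value=-9, max_value=9, allow_nan=False).filter(
            lambda v: abs(v) > 1e-6
        ),
        min_size=1, max_size=12,
    )
)
def test_signed_rank_matches_brute_force(d):
    """Convolution-based enumeration equals the 2^n brute force exactly,
    including tied magnitudes via midranks."""
    d = np.round(np.asarray(d), 1)  # induce ties
    d = d[d != 0]
    if len(d) == 0:
        return
    res = st.wilcoxon_signed_rank_exact(d)
    w_oracle, p_oracle = wilcoxon_brute_force(d)
    assert res.statistic == pytest.approx(w_oracle, abs=1e-9)
    assert res.p == pytest.approx(p_oracle, abs=1e-12)


def test_signed_rank_matches_scipy_exact(rng):
    """Third-party cross-check: scipy's exact mode on tie-free data."""
    for _ in range(10):
        d = rng.normal(size=9)
        res = st.wilcoxon_signed_rank_exact(d)
        p_sp = sps.wilcoxon(d, mode="exact").pvalue
        assert res.p == pytest.approx(p_sp, abs=1e-12)


# ------------------------------------------------------------ GG epsilon

def test_gg_epsilon_compound_symmetry_and_k2():
    S = 0.6 * np.eye(4) + 0.4 * np.ones((4, 4))
    assert st.gg_epsilon(S) == pytest.approx(1.0, abs=1e-12)
    assert st.gg_epsilon(np.array([[2.0, 0.3], [0.3, 1.0]])) == 1.0


def test_gg_epsilon_eigen_oracle(rng):
    for _ in range(200):
        k = int(rng.integers(2, 7))
        A = rng.normal(size=(k, k + 2))
        S = A @ A.T
        eps = st.gg_epsilon(S)
        assert eps == pytest.approx(box_epsilon_eigen(S), abs=1e-10)
        assert 1 / (k - 1) - 1e-12 <= eps <= 1 + 1e-12


def test_gg_epsilon_rejects_asymmetric():
    with pytest.raises(ValidationError, match="symmetric"):
        st.gg_epsilon(np.array([[1.0, 0.5], [0.0, 1.0]]))


# ------------------------------------------------------------- RM ANOVA

def test_one_way_identical_conditions_f_zero(rng):
    base = rng.normal(size=7)
    Y = np.tile(base[:, None], (1, 3))
    res = st.rm_anova_one_way(Y)
    assert res.statistic == 0.0
    assert res.p == 1.0


def test_one_way_df_formula(rng):
    res = st.rm_anova_one_way(rng.normal(size=(7, 3)))
    assert res.df_uncorrected == (2, 12)
    assert res.df[0] == pytest.approx(res.epsilon * 2)
    assert res.df[1] == pytest.approx(res.epsilon * 12)


def test_one_way_matches_ss_oracle(rng):
    Y = rng.normal(size=(9, 4)) + np.linspace(0, 1, 4)
    res = st.rm_anova_one_way(Y)
    assert res.statistic == pytest.approx(one_way_ss_oracle(Y), abs=1e-10)


def test_one_way_matches_pingouin(rng):
    import pandas as pd
    import pingouin as pg

    Y = rng.normal(size=(8, 4)) + np.array([0.0, 0.2, 0.5, 1.0])
    n, k = Y.shape
    long = pd.DataFrame({
        "y": Y.ravel(),
        "subj": np.repeat(np.arange(n), k),
        "cond": np.tile(np.arange(k), n),
    })
    ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj",
                      correction=True).iloc[0]
    res = st.rm_anova_one_way(Y)
    assert res.statistic == pytest.approx(ref["F"], rel=1e-9)
    assert res.epsilon == pytest.approx(ref["eps"], rel=1e-9)
    assert res.p == pytest.approx(ref["p_GG_corr"], rel=1e-6)


def test_two_way_interaction_df_2x5x7(rng):
    res = st.rm_anova_two_way(rng.normal(size=(7, 2, 5)))
    assert res.interaction.df_uncorrected == (4, 24)
    assert res.main_a.df_uncorrected == (1, 6)


def test_two_way_additive_table_zero_interaction(rng):
    n, a, b = 6, 3, 4
    subj = rng.normal(size=n)
    ea = np.array([0.0, 1.0, 2.0])
    eb = np.array([0.0, 0.5, 1.0, 1.5])
    Y = subj[:, None, None] + ea[None, :, None] + eb[None, None, :]
    Y = Y + rng.normal(scale=0.0, size=Y.shape)
    res = st.rm_anova_two_way(Y)
    assert res.interaction.statistic == pytest.approx(0.0, abs=1e-18)


def test_two_way_matches_pingouin(rng):
    import pandas as pd
    import pingouin as pg

    Y = rng.normal(size=(7, 2, 5))
    Y[:, 1, :] += np.linspace(0, 1, 5)
    n, a, b = Y.shape
    long = pd.DataFrame({
        "y": Y.ravel(),
        "subj": np.repeat(np.arange(n), a * b),
        "a": np.tile(np.repeat(np.arange(a), b), n),
        "b": np.tile(np.arange(b), n * a),
    })
    ref = pg.rm_anova(data=long, dv="y", within=["a", "b"], subject="subj",
                      correction=True)
    mine = st.rm_anova_two_way(Y)
    for row, res in zip(ref.itertuples(), (mine.main_a, mine.main_b, mine.interaction)):
        assert res.statistic == pytest.approx(row.F, rel=1e-9)
        assert res.epsilon == pytest.approx(row.eps, rel=1e-9)
        assert res.p == pytest.approx(row.p_GG_corr, rel=1e-6)


def test_two_way_single_level_collapses_to_one_way(rng):
    Y = rng.normal(size=(7, 4))
    two = st.rm_anova_two_way(Y[:, :, None])
    one = st.rm_anova_one_way(Y)
    assert two.main_b is None and two.interaction is None
    assert two.main_a.statistic == pytest.approx(one.statistic, rel=1e-12)
    assert two.main_a.p == pytest.approx(one.p, rel=1e-12)


def test_rm_anova_rejects_missing_cells(rng):
    Y = rng.normal(size=(5, 3))
    Y[2, 1] = np.nan
    with pytest.raises(ValidationError, match="missing"):
        st.rm_anova_one_way(Y)


# --------------------------------------------------------------- post-hoc

def test_sidak_arithmetic():
    assert st.sidak_adjust([0.0], 3) == [0.0]
    assert st.sidak_adjust([0.05], 1) == [pytest.approx(0.05)]
    assert st.sidak_adjust([0.01], 3)[0] == pytest.approx(1 - 0.99 ** 3, abs=1e-12)
    assert st.sidak_adjust([0.9], 5)[0] == pytest.approx(1 - 0.1 ** 5, abs=1e-12)
    assert st.sidak_adjust([1.0], 2) == [1.0]


def test_tukey_equal_means_p_one():
    ph = st.tukey_rm([1.0, 1.0, 1.0], ms_error=2.0, df_error=12, n=7)
    assert all(d["statistic"] == 0.0 and d["p_adj"] == 1.0 for d in ph)


def test_tukey_k2_equals_t_relation(rng):
    """With two groups q = t*sqrt(2) and the studentized-range p equals the
    two-sided t probability."""
    Y = rng.normal(size=(8, 2))
    Y[:, 1] += 1.0
    res = st.rm_anova_one_way(Y, posthoc="tukey")
    q = res.posthoc[0]["statistic"]
    d = Y[:, 0] - Y[:, 1]
    t = abs(d.mean() / (d.std(ddof=1) / np.sqrt(len(d))))
    assert q == pytest.approx(t * np.sqrt(2), rel=1e-9)
    assert res.posthoc[0]["p_adj"] == pytest.approx(2 * sps.t.sf(t, 7), rel=1e-6)


def test_tukey_matches_range_cdf_quadrature():
    """Adjusted p equals direct numerical integration of the studentized
    range density."""
    from scipy.integrate import quad

    k, df, q = 3, 12, 3.2
    p_num = quad(lambda x: sps.studentized_range.pdf(x, k, df), q, np.inf,
                 limit=200)[0]
    ph = st.tukey_rm([0.0, 0.0, q * np.sqrt(2.0 / 7)], ms_error=2.0,
                     df_error=df, n=7)
    worst = max(d["p_adj"] for d in ph if d["statistic"] > 1e-9)
    assert worst == pytest.approx(p_num, rel=1e-5)


def test_tukey_rejects_bad_ms():
    with pytest.raises(ValidationError):
        st.tukey_rm([0.0, 1.0], ms_error=0.0, df_error=10, n=5)


# -------------------------------------------------------- gated selection

def test_select_test_gaussian_picks_t(rng):
    x = rng.normal(size=50)
    y = x + rng.normal(size=50)
    res = st.select_test(x, y)
    assert res.test == "paired_t"
    assert "shapiro" in res.note


def test_select_test_heavy_tails_pick_wilcoxon():
    picked = 0
    for seed in range(100):
        r = np.random.default_rng(seed)
        d = r.standard_cauchy(size=25)
        res = st.select_test(d, np.zeros_like(d))
        if res.test == "wilcoxon_signed_rank_exact":
            picked += 1
    assert picked >= 95


def test_select_test_too_small():
    with pytest.raises(ValidationError):
        st.select_test([1.0, 2.0], [0.0, 1.0])
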