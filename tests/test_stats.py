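import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pupilhint import stats as st
from pupilhint.io import MICROPHONES, NOISE_CONFIGURATIONS


def make_long(y, subjects=None, configs=NOISE_CONFIGURATIONS, mics=MICROPHONES):
    """Long table from y[subject, config, mic]."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    subjects = subjects or [f"s{i}" for i in range(n)]
    rows = []
    for i, s in enumerate(subjects):
        for j, c in enumerate(configs):
            for k, m in enumerate(mics):
                rows.append((s, m, c, y[i, j, k], 0.05, 20))
    return pd.DataFrame(rows, columns=["subject", "microphone", "configuration",
                                       "snr_db", "ppd_au", "n_epochs"])


# ---------------------------------------------------------------------------
# one-way repeated measures

def test_oneway_zero_between_level_variance_gives_F_zero():
    rng = np.random.default_rng(0)
    subj = rng.normal(0, 1, 6)
    y = np.tile(subj[:, None, None], (1, 3, 3))  # identical across levels
    tab, _ = st.rm_anova_oneway(make_long(y), "snr_db", "configuration")
    assert tab["F"].iloc[0] == 0.0


def test_oneway_matches_handmade_sum_of_squares():
    """3 subjects x 3 levels: direct SS arithmetic, computed independently."""
    y = np.array([[1.0, 2.0, 4.0],
                  [0.0, 3.0, 5.0],
                  [2.0, 2.0, 3.0]])  # subject x level
    n, k = y.shape
    grand = y.mean()
    ss_factor = n * sum((y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subject = k * sum((y[i].mean() - grand) ** 2 for i in range(n))
    ss_total = ((y - grand) ** 2).sum()
    ss_error = ss_total - ss_factor - ss_subject
    expected_F = (ss_factor / (k - 1)) / (ss_error / ((k - 1) * (n - 1)))

    long = make_long(np.repeat(y[:, :, None], 3, axis=2))
    tab, _ = st.rm_anova_oneway(long, "snr_db", "configuration")
    assert tab["F"].iloc[0] == pytest.approx(expected_F, rel=1e-12)
    assert (tab["num_df"].iloc[0], tab["den_df"].iloc[0]) == (2, 4)


def test_oneway_agrees_with_statsmodels_anovarm():
    from statsmodels.stats.anova import AnovaRM
    rng = np.random.default_rng(42)
    for _ in range(10):
        y = rng.normal(0, 1, (8, 3, 3)) + rng.normal(0, 1, (8, 1, 1))
        long = make_long(y)
        means = long.groupby(["subject", "configuration"], as_index=False)["snr_db"].mean()
        ref = AnovaRM(means, "snr_db", "subject", within=["configuration"]).fit()
        tab, _ = st.rm_anova_oneway(long, "snr_db", "configuration")
        assert tab["F"].iloc[0] == pytest.approx(
            float(ref.anova_table["F Value"].iloc[0]), rel=1e-6)
        assert tab["p"].iloc[0] == pytest.approx(
            float(ref.anova_table["Pr > F"].iloc[0]), abs=1e-6)


def test_oneway_incomplete_crossing_rejected():
    y = np.zeros((3, 3, 3))
    long = make_long(y)
    long = long[~((long["subject"] == "s0") & (long["configuration"] == "S0N0"))]
    with pytest.raises(ValueError, match="missing cell"):
        st.rm_anova_oneway(long, "snr_db", "configuration")


def test_oneway_type_one_error_calibrated():
    """Exchangeable normal null: rejection rate ~ alpha (vectorised core)."""
    rng = np.random.default_rng(3)
    y = rng.normal(0, 1, (4000, 8, 3)) + rng.normal(0, 1, (4000, 8, 1))
    _, p, *_ = st._rm_oneway_core(y)
    rate = float(np.mean(p < 0.05))
    assert 0.035 < rate < 0.065


# ---------------------------------------------------------------------------
# two-way interaction model

def test_twoway_constant_response_gives_zero_F():
    y = np.full((8, 3, 3), 2.5)
    tab, _ = st.rm_anova_twoway_interaction(make_long(y), "snr_db")
    factor_rows = tab[tab["term"] != "(Intercept)"]
    assert (factor_rows["F"] == 0.0).all()


def test_twoway_df_layout_for_eight_subjects():
    rng = np.random.default_rng(1)
    tab, _ = st.rm_anova_twoway_interaction(make_long(rng.normal(0, 1, (8, 3, 3))),
                                            "snr_db")
    by_term = dict(zip(tab["term"], zip(tab["num_df"], tab["den_df"])))
    assert by_term["(Intercept)"] == (1, 56)
    assert by_term["Sound configuration"] == (2, 56)
    assert by_term["Microphone"] == (2, 56)
    assert by_term["Configuration/microphone"] == (4, 56)


def test_twoway_agrees_with_statsmodels_ols_blocks():
    """Pooled-residual F's equal the subject-blocked OLS decomposition."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm
    rng = np.random.default_rng(7)
    for _ in range(10):
        y = rng.normal(0, 1, (8, 3, 3)) + rng.normal(0, 2, (8, 1, 1))
        long = make_long(y)
        fit = smf.ols(
            "snr_db ~ C(subject) + C(configuration) * C(microphone)", long).fit()
        ref = anova_lm(fit, typ=2)
        tab, _ = st.rm_anova_twoway_interaction(long, "snr_db")
        by_term = dict(zip(tab["term"], tab["F"]))
        assert by_term["Sound configuration"] == pytest.approx(
            ref.loc["C(configuration)", "F"], rel=1e-6)
        assert by_term["Microphone"] == pytest.approx(
            ref.loc["C(microphone)", "F"], rel=1e-6)
        assert by_term["Configuration/microphone"] == pytest.approx(
            ref.loc["C(configuration):C(microphone)", "F"], rel=1e-6)
        assert int(ref.loc["Residual", "df"]) == 56


def test_twoway_detects_planted_configuration_effect():
    """A +3 dB configuration shift is found; no spurious interaction."""
    rng = np.random.default_rng(11)
    hits, inter = 0, 0
    n_sim = 200
    for _ in range(n_sim):
        y = rng.normal(0, 1.5, (8, 3, 3)) + rng.normal(0, 2, (8, 1, 1))
        y[:, 1, :] += 3.0
        tab, _ = st.rm_anova_twoway_interaction(make_long(y), "snr_db")
        by_term = dict(zip(tab["term"], tab["p"]))
        hits += by_term["Sound configuration"] < 0.05
        inter += by_term["Configuration/microphone"] < 0.05
    assert hits / n_sim >= 0.8
    assert inter / n_sim < 0.12


def test_subject_offset_leaves_factor_F_unchanged():
    rng = np.random.default_rng(5)
    y = rng.normal(0, 1, (8, 3, 3))
    offsets = rng.normal(0, 10, (8, 1, 1))
    t1, _ = st.rm_anova_twoway_interaction(make_long(y), "snr_db")
    t2, _ = st.rm_anova_twoway_interaction(make_long(y + offsets), "snr_db")
    f1 = t1[t1["term"] != "(Intercept)"]["F"].to_numpy()
    f2 = t2[t2["term"] != "(Intercept)"]["F"].to_numpy()
    np.testing.assert_allclose(f1, f2, rtol=1e-9)


# ---------------------------------------------------------------------------
# Shapiro-Wilk

def test_shapiro_on_normal_scores_is_high():
    # perfect normal quantile sequence, n=20
    q = sps.norm.ppf((np.arange(1, 21) - 0.5) / 20)
    w, p = st.shapiro_wilk(q)
    assert w > 0.99


def test_shapiro_power_against_bimodal():
    rng = np.random.default_rng(2)
    rejections = 0
    for _ in range(200):
        x = np.concatenate([rng.normal(-3, 0.3, 25), rng.normal(3, 0.3, 25)])
        _, p = st.shapiro_wilk(x)
        rejections += p < 0.05
    assert rejections / 200 >= 0.95


def test_shapiro_rejects_constant_and_bad_n():
    with pytest.raises(ValueError):
        st.shapiro_wilk(np.ones(10))
    with pytest.raises(ValueError):
        st.shapiro_wilk([1.0, 2.0])


# ---------------------------------------------------------------------------
# Games-Howell

def gh_bruteforce(groups):
    """Direct textbook formulas, independent of the implementation."""
    out = []
    k = len(groups)
    for (i, a), (j, b) in itertools.combinations(enumerate(groups), 2):
        a, b = np.asarray(a, float), np.asarray(b, float)
        vi, vj = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        diff = a.mean() - b.mean()
        se = np.sqrt(vi + vj)
        df = (vi + vj) ** 2 / (vi ** 2 / (len(a) - 1) + vj ** 2 / (len(b) - 1))
        p = sps.studentized_range.sf(abs(diff) / se * np.sqrt(2), k, df)
        out.append((i, j, diff, se, df, p))
    return out


def test_games_howell_identical_groups():
    g = np.arange(10.0)
    tab = st.games_howell([g, g.copy()])
    assert tab["mean_diff"].iloc[0] == 0.0
    assert tab["p_adjusted"].iloc[0] == pytest.approx(1.0)


def test_games_howell_matches_formula_oracle():
    rng = np.random.default_rng(8)
    groups = [rng.normal(0, 1, 12), rng.normal(0.8, 2.5, 17), rng.normal(-0.5, 0.5, 9)]
    tab = st.games_howell(groups)
    ref = gh_bruteforce(groups)
    for row, (i, j, diff, se, df, p) in zip(tab.itertuples(), ref):
        assert row.mean_diff == pytest.approx(diff, rel=1e-9)
        assert row.se == pytest.approx(se, rel=1e-9)
        assert row.df == pytest.approx(df, rel=1e-9)
        assert row.p_adjusted == pytest.approx(p, abs=1e-6)


def test_games_howell_agrees_with_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(9)
    vals = np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 3, 20),
                           rng.normal(-1, 0.5, 12)])
    labels = np.repeat(["a", "b", "c"], [15, 20, 12])
    ref = pg.pairwise_gameshowell(
        data=pd.DataFrame({"y": vals, "g": labels}), dv="y", between="g")
    tab = st.games_howell([vals[labels == g] for g in ("a", "b", "c")])
    np.testing.assert_allclose(tab["mean_diff"], ref["diff"], rtol=1e-9)
    np.testing.assert_allclose(tab["df"], ref["df"], rtol=1e-6)
    np.testing.assert_allclose(tab["p_adjusted"], ref["pval"], atol=1e-6)


def test_games_howell_symmetric_in_group_order():
    rng = np.random.default_rng(10)
    groups = [rng.normal(0, 1, 10), rng.normal(1, 2, 14), rng.normal(2, 3, 8)]
    tab_fwd = st.games_howell(groups)
    tab_rev = st.games_howell(groups[::-1])
    assert sorted(np.round(tab_fwd["p_adjusted"], 10)) == pytest.approx(
        sorted(np.round(tab_rev["p_adjusted"], 10)))


def test_games_howell_rejects_tiny_group():
    with pytest.raises(ValueError, match="fewer than 2"):
        st.games_howell([[1.0], [1.0, 2.0]])


def test_studentized_range_crit_matches_ppf():
    dfs = np.array([5.0, 17.3, 56.0, 90.0])
    crit = st.studentized_range_crit(3, dfs, 0.05)
    ref = sps.studentized_range.ppf(0.95, 3, dfs)
    np.testing.assert_allclose(crit, ref, rtol=2e-3)


# ---------------------------------------------------------------------------
# Bonferroni, Spearman, PTA

@pytest.mark.parametrize("alpha,m,expected",
                         [(0.05, 3, 0.05 / 3), (0.05, 1, 0.05), (0.01, 4, 0.0025)])
def test_bonferroni_threshold(alpha, m, expected):
    assert st.bonferroni_threshold(alpha, m) == pytest.approx(expected)


def test_spearman_monotone_is_plus_minus_one():
    x = np.array([1.0, 2.5, 3.0, 7.0, 9.0, 12.0])
    rho, p = st.spearman(x, np.exp(x))
    assert rho == pytest.approx(1.0)
    rho_r, _ = st.spearman(x, -np.exp(x))
    assert rho_r == pytest.approx(-1.0)


def test_spearman_exact_p_matches_enumeration_n5():
    """n=5 exact permutation p equals brute-force enumeration of 120 orders."""
    x = np.array([0.3, 1.2, 2.2, 3.1, 4.9])
    y = np.array([1.0, 0.2, 3.3, 2.8, 4.1])
    rho, p = st.spearman(x, y)
    rx = sps.rankdata(x)
    count = 0
    total = 0
    for perm in itertools.permutations(sps.rankdata(y)):
        r = np.corrcoef(rx, perm)[0, 1]
        count += abs(r) >= abs(rho) - 1e-12
        total += 1
    assert total == 120
    assert p == pytest.approx(count / total)


def test_spearman_large_n_uses_t_approximation():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 40)
    y = 0.5 * x + rng.normal(0, 1, 40)
    rho, p = st.spearman(x, y)
    ref_rho, ref_p = sps.spearmanr(x, y)
    assert rho == pytest.approx(ref_rho, rel=1e-9)
    assert p == pytest.approx(ref_p, rel=1e-2)


def test_spearman_ties_use_midranks():
    x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0]
    y = [1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0]
    rho, _ = st.spearman(x, y)
    ref_rho, _ = sps.spearmanr(x, y)
    assert rho == pytest.approx(ref_rho, rel=1e-9)


def test_spearman_requires_three_pairs():
    with pytest.raises(ValueError):
        st.spearman([1.0, 2.0], [1.0, 2.0])


@pytest.mark.parametrize("thresholds,expected",
                         [((40, 40, 40, 40), 40.0), ((35, 45, 40, 60), 45.0),
                          ((30, 40, 50, 60), 45.0)])
def test_pure_tone_average(thresholds, expected):
    assert st.pure_tone_average(thresholds) == pytest.approx(expected)


def test_pure_tone_average_requires_four_values():
    with pytest.raises(ValueError):
        st.pure_tone_average([40, 40, 40])
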