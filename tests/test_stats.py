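import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import gaitsync as gs
from gaitsync.errors import DegenerateDataError, ValidationError

rng = np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# independent enumeration oracles


def oracle_wilcoxon_exact_p(d):
    """Two-sided exact p by enumerating every sign pattern of |d| ranks."""
    d = np.asarray(d, float)
    d = d[d != 0]
    r = sps.rankdata(np.abs(d))
    n = len(d)
    mean = n * (n + 1) / 4.0
    obs = np.sum(r[d > 0])
    count = 0
    for bits in range(2**n):
        w = sum(r[i] for i in range(n) if bits >> i & 1)
        if abs(w - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / 2**n


def oracle_mann_whitney_exact_p(x, y):
    """Two-sided exact p by enumerating every group labeling of pooled ranks."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    mean = n1 * n2 / 2.0
    obs_u = n1 * n2 + n1 * (n1 + 1) / 2.0 - np.sum(ranks[:n1])
    hits = total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = n1 * n2 + n1 * (n1 + 1) / 2.0 - sum(ranks[i] for i in comb)
        total += 1
        if abs(u - mean) >= abs(obs_u - mean) - 1e-12:
            hits += 1
    return hits / total


def oracle_friedman_chi2(m):
    """Hand rank computation: 12/(nk(k+1)) sum R_j^2 - 3n(k+1) (no ties)."""
    m = np.asarray(m, float)
    n, k = m.shape
    R = np.vstack([sps.rankdata(row) for row in m]).sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3.0 * n * (k + 1)


# ---------------------------------------------------------------------------


class TestFriedman:
    def test_identical_columns_gives_zero(self):
        m = np.tile([[3.0, 3.0, 3.0]], (4, 1))
        res = gs.friedman(m)
        assert res.statistic_value == 0.0
        assert res.p_value == 1.0

    def test_perfectly_ordered_3x3(self):
        res = gs.friedman([[1, 2, 3]] * 3)
        assert res.statistic_value == pytest.approx(6.0)
        assert res.df == 2

    def test_matches_hand_formula_without_ties(self):
        for _ in range(10):
            m = rng.normal(size=(6, 4))
            assert gs.friedman(m).statistic_value == pytest.approx(oracle_friedman_chi2(m))

    def test_matches_scipy_with_and_without_ties(self):
        m = rng.integers(0, 4, size=(7, 3)).astype(float)  # plenty of ties
        ours = gs.friedman(m)
        ref_stat, ref_p = sps.friedmanchisquare(*m.T)
        assert ours.statistic_value == pytest.approx(ref_stat)
        assert ours.p_value == pytest.approx(ref_p)

    def test_chi2_p_tracks_exact_permutation_null(self):
        m = rng.normal(size=(4, 3))
        res = gs.friedman(m)
        perms = list(itertools.permutations(range(3)))
        null = []
        for combo in itertools.product(perms, repeat=4):
            mm = np.array([m[i, list(p)] for i, p in enumerate(combo)])
            null.append(gs.friedman(mm).statistic_value)
        p_exact = np.mean(np.asarray(null) >= res.statistic_value - 1e-12)
        assert res.p_value == pytest.approx(p_exact, abs=0.2)  # chi2 approx at n=4

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValidationError):
            gs.friedman(m)


class TestWilcoxon:
    def test_uniform_shift_gives_minimal_w_and_negative_z(self):
        x = rng.normal(size=10)
        res = gs.wilcoxon_signed_rank(x, x + 3.0)
        assert res.statistic_value == 0.0  # no positive differences
        assert res.z < 0

    def test_swapping_samples_flips_z(self):
        x, y = rng.normal(size=12), rng.normal(size=12)
        a = gs.wilcoxon_signed_rank(x, y)
        b = gs.wilcoxon_signed_rank(y, x)
        assert a.z == pytest.approx(-b.z)
        assert a.p_value == pytest.approx(b.p_value)

    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_exact_p_matches_enumeration_oracle(self, n):
        for _ in range(5):
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = gs.wilcoxon_signed_rank(x, y)
            assert "exact" in res.method
            assert res.p_value == pytest.approx(oracle_wilcoxon_exact_p(x - y))

    def test_exact_p_matches_scipy_without_ties(self):
        x, y = rng.normal(size=7), rng.normal(size=7)
        ours = gs.wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, mode="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_normal_approximation_matches_scipy(self):
        x, y = rng.normal(size=20), rng.normal(size=20)
        ours = gs.wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, mode="approx", correction=True)
        assert "approx" in ours.method
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_all_zero_differences_degenerate(self):
        x = np.arange(6.0)
        with pytest.raises(DegenerateDataError):
            gs.wilcoxon_signed_rank(x, x)


class TestBonferroni:
    @pytest.mark.parametrize("fam,m,expected", [(0.05, 10, 0.005), (0.05, 1, 0.05), (1.0, 4, 0.25)])
    def test_division(self, fam, m, expected):
        assert gs.bonferroni_alpha(fam, m) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            gs.bonferroni_alpha(0.0, 3)
        with pytest.raises(ValidationError):
            gs.bonferroni_alpha(0.05, 0)


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        res = gs.mann_whitney([10, 11, 12, 13], [1, 2, 3, 4])
        assert res.statistic_value == 0.0

    def test_min_convention_symmetric_under_swap(self):
        x, y = rng.normal(size=6), rng.normal(1.0, 1.0, size=9)
        a = gs.mann_whitney(x, y)
        b = gs.mann_whitney(y, x)
        assert a.statistic_value == pytest.approx(b.statistic_value)
        assert a.p_value == pytest.approx(b.p_value)

    @pytest.mark.parametrize("n1,n2", [(4, 4), (5, 7), (8, 8)])
    def test_exact_p_matches_enumeration_oracle(self, n1, n2):
        x, y = rng.normal(size=n1), rng.normal(0.8, 1.0, size=n2)
        res = gs.mann_whitney(x, y)
        assert "exact" in res.method
        assert res.p_value == pytest.approx(oracle_mann_whitney_exact_p(x, y))

    def test_exact_p_matches_scipy_without_ties(self):
        x, y = rng.normal(size=6), rng.normal(size=7)
        ours = gs.mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_normal_approximation_against_scipy(self):
        x, y = rng.normal(size=12), rng.normal(0.7, 1.0, size=11)
        ours = gs.mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert "approx" in ours.method
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)
        assert ours.effect_size == pytest.approx(ours.z**2 / ours.n)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        assert gs.spearman(x, np.exp(x)).statistic_value == pytest.approx(1.0)
        assert gs.spearman(x, -(x**3)).statistic_value == pytest.approx(-1.0)

    def test_matches_rank_formula_without_ties(self):
        x, y = rng.normal(size=5), rng.normal(size=5)
        d = sps.rankdata(x) - sps.rankdata(y)
        expected = 1.0 - 6.0 * np.sum(d**2) / (5 * (25 - 1))
        assert gs.spearman(x, y).statistic_value == pytest.approx(expected)

    def test_matches_scipy(self):
        x, y = rng.normal(size=30), rng.normal(size=30)
        ours = gs.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.statistic_value == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateDataError):
            gs.spearman(np.ones(5), rng.normal(size=5))


class TestKsNormality:
    def test_normal_samples_rarely_rejected(self):
        flags = [
            gs.ks_normality(np.random.default_rng(s).normal(size=1000)).p_value > 0.05
            for s in range(40)
        ]
        assert np.mean(flags) >= 0.95

    def test_uniform_samples_reliably_rejected(self):
        flags = [
            gs.ks_normality(np.random.default_rng(s).uniform(size=200)).p_value < 0.05
            for s in range(40)
        ]
        assert np.mean(flags) >= 0.95

    def test_statistic_matches_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors

        x = rng.normal(size=161)
        ours = gs.ks_normality(x)
        d_ref, p_ref = lilliefors(x, dist="norm", pvalmethod="table")
        assert ours.statistic_value == pytest.approx(d_ref)
        assert ours.p_value == pytest.approx(p_ref)

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateDataError):
            gs.ks_normality(np.full(10, 2.5))


class TestRmAnovaLinear:
    def test_perfectly_linear_rows_give_unit_r2(self):
        scores = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        m = np.tile(scores, (6, 1)) + rng.normal(size=(6, 1))  # subject offsets only
        _, contrast = gs.rm_anova_linear(m, scores)
        assert contrast.effect_size == pytest.approx(1.0)

    def test_constant_rows_give_zero_omnibus(self):
        m = np.tile(rng.normal(size=(5, 1)), (1, 4))
        omni, _ = gs.rm_anova_linear(m, [1.0, 2.0, 3.0, 4.0])
        assert omni.statistic_value == pytest.approx(0.0, abs=1e-20)

    def test_omnibus_matches_direct_ss_decomposition(self):
        m = rng.normal(size=(5, 3))
        scores = np.array([0.0, 1.0, 2.0])
        omni, contrast = gs.rm_anova_linear(m, scores)
        # independent sums-of-squares oracle
        n, k = m.shape
        gm = m.mean()
        ss_cond = n * ((m.mean(0) - gm) ** 2).sum()
        ss_subj = k * ((m.mean(1) - gm) ** 2).sum()
        ss_err = ((m - gm) ** 2).sum() - ss_cond - ss_subj
        f_ref = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        assert omni.statistic_value == pytest.approx(f_ref)
        # contrast oracle: per-subject contrast values, one-sample F
        c = scores - scores.mean()
        L = m @ c
        f_con = n * L.mean() ** 2 / (np.sum((L - L.mean()) ** 2) / (n - 1))
        assert contrast.statistic_value == pytest.approx(f_con)

    def test_omnibus_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        m = rng.normal(size=(8, 5))
        omni, _ = gs.rm_anova_linear(m, np.arange(5.0))
        df = pd.DataFrame(m, columns=[f"c{j}" for j in range(5)])
        df["subject"] = np.arange(8)
        long = df.melt(id_vars="subject", var_name="cond", value_name="y")
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject")
        assert omni.statistic_value == pytest.approx(float(ref["F"][0]))
        assert omni.p_value == pytest.approx(float(ref["p_unc"][0]))

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValidationError):
            gs.rm_anova_linear(m, [0.0, 1.0])


def _metric_frame(values):
    """participants x conditions entrainment matrix -> tidy metric table."""
    n, shifts = values.shape[0], list(gs.SHIFTS)
    rows = []
    for i in range(n):
        for j, s in enumerate(shifts):
            rows.append(
                {"participant_id": f"P{i:02d}", "shift_pct": s,
                 "entrainment_pct": values[i, j], "rpe": 13}
            )
    return pd.DataFrame(rows)


class TestBasinAnalysis:
    def test_all_identical_values_flag_nothing(self):
        df = _metric_frame(np.full((8, 11), 50.0))
        result = gs.basin_analysis(df)
        assert not any(result.significant.values())
        assert not any(result.flagged_lower.values())

    def test_bonferroni_level_is_005(self):
        df = _metric_frame(np.full((8, 11), 50.0))
        assert gs.basin_analysis(df).bonferroni_alpha == pytest.approx(0.005)

    def test_clearly_depressed_edges_are_flagged(self):
        base = 70.0 + rng.normal(0, 3.0, size=(16, 11))
        shifts = np.array(gs.SHIFTS)
        base[:, np.abs(shifts) >= 2.5] -= 45.0
        result = gs.basin_analysis(_metric_frame(base))
        for s in (-3.0, -2.5, 2.5, 3.0):
            assert result.flagged_lower[s]
        for s in (-1.0, 1.0):
            assert not result.flagged_lower[s]

    def test_flags_monotone_under_stochastic_dominance(self):
        base = 70.0 + rng.normal(0, 3.0, size=(16, 11))
        shifts = np.array(gs.SHIFTS)
        base[:, shifts == 2.5] -= 30.0
        base[:, shifts == 3.0] = base[:, shifts == 2.5] - 5.0  # dominated column
        result = gs.basin_analysis(_metric_frame(base))
        if result.flagged_lower[2.5]:
            assert result.flagged_lower[3.0]

    def test_incomplete_grid_rejected(self):
        df = _metric_frame(np.full((4, 11), 50.0)).iloc[:-1]
        with pytest.raises(ValidationError):
            gs.basin_analysis(df)


class TestGenderContrastDirection:
    def test_female_entrainment_exceeds_male_in_most_seeds(self):
        # stronger coupling for women (0.16 vs 0.09) must surface as a
        # higher median per-participant entrainment in >= 90 % of cohorts
        wins = 0
        seeds = range(10)
        for seed in seeds:
            ds = gs.simulate_cohort(gs.CohortConfig(seed=seed), synth_traces=False)
            m = gs.compute_metrics(ds, use_detected=False)
            pf = ds.profile_frame()
            per = m.groupby("participant_id")["entrainment_pct"].mean()
            f = np.median(per[pf.loc[pf.gender == "female", "id"]])
            ml = np.median(per[pf.loc[pf.gender == "male", "id"]])
            wins += f > ml
        assert wins >= 0.9 * len(list(seeds))
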