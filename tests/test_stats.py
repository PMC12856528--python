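"""Mixed ANOVA, post hocs, resampling/permutation inference, LMM, correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sulcprofile.stats import (
    assumption_checks,
    balanced_resample_anova,
    lmm_random_intercept,
    mixed_anova_3way,
    pearson_correlation,
    permutation_anova,
    posthoc_paired_t,
)


def make_long(cells, groups, seed=0, sd=0.0):
    """Long table from per-subject 2x2 cell values.

    ``cells``: array (n_subjects, 4) ordered (A1B1, A1B2, A2B1, A2B2);
    ``groups``: between-factor level per subject.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s, (vals, g) in enumerate(zip(np.atleast_2d(cells), groups)):
        for (a, b), v in zip ([("I", "left"), ("I", "right"), ("II", "left"), ("II", "right")], vals):
            rows.append(
                {
                    "subject_id": f"s{s:03d}",
                    "feature": a,
                    "hemisphere": b,
                    "sex": g,
                    "y": v + rng.normal(0, sd),
                }
            )
    return pd.DataFrame(rows)


def oracle_balanced_mixed_anova(df):
    """Direct sums-of-squares decomposition for the balanced 2x2xG design."""
    y = df.set_index(["subject_id", "feature", "hemisphere"])["y"]
    subjects = sorted(df["subject_id"].unique())
    group = df.groupby("subject_id")["sex"].first()
    glevels = sorted(group.unique())
    A = sorted(df["feature"].unique())
    B = sorted(df["hemisphere"].unique())
    gm = df["y"].mean()
    n_per_g = {g: sum(group[s] == g for s in subjects) for g in glevels}
    N = len(subjects)

    m_s = {s: np.mean([y[s, a, b] for a in A for b in B]) for s in subjects}
    m_g = {g: np.mean([m_s[s] for s in subjects if group[s] == g]) for g in glevels}
    m_a = {a: np.mean([y[s, a, b] for s in subjects for b in B]) for a in A}
    m_b = {b: np.mean([y[s, a, b] for s in subjects for a in A]) for b in B}
    m_ag = {(a, g): np.mean([y[s, a, b] for s in subjects if group[s] == g for b in B]) for a in A for g in glevels}
    m_bg = {(b, g): np.mean([y[s, a, b] for s in subjects if group[s] == g for a in A]) for b in B for g in glevels}
    m_ab = {(a, b): np.mean([y[s, a, b] for s in subjects]) for a in A for b in B}
    m_abg = {
        (a, b, g): np.mean([y[s, a, b] for s in subjects if group[s] == g])
        for a in A for b in B for g in glevels
    }
    m_as = {(a, s): np.mean([y[s, a, b] for b in B]) for a in A for s in subjects}
    m_bs = {(b, s): np.mean([y[s, a, b] for a in A]) for b in B for s in subjects}

    ss_g = 4 * sum(n_per_g[g] * (m_g[g] - gm) ** 2 for g in glevels)
    ss_subj = 4 * sum((m_s[s] - m_g[group[s]]) ** 2 for s in subjects)
    ss_a = 2 * N * sum((m_a[a] - gm) ** 2 for a in A)
    ss_ag = 2 * sum(n_per_g[g] * (m_ag[a, g] - m_a[a] - m_g[g] + gm) ** 2 for a in A for g in glevels)
    ss_as = 2 * sum((m_as[a, s] - m_s[s] - m_ag[a, group[s]] + m_g[group[s]]) ** 2 for a in A for s in subjects)
    ss_b = 2 * N * sum((m_b[b] - gm) ** 2 for b in B)
    ss_bg = 2 * sum(n_per_g[g] * (m_bg[b, g] - m_b[b] - m_g[g] + gm) ** 2 for b in B for g in glevels)
    ss_bs = 2 * sum((m_bs[b, s] - m_s[s] - m_bg[b, group[s]] + m_g[group[s]]) ** 2 for b in B for s in subjects)
    ss_ab = N * sum((m_ab[a, b] - m_a[a] - m_b[b] + gm) ** 2 for a in A for b in B)
    ss_abg = sum(
        n_per_g[g]
        * (m_abg[a, b, g] - m_ab[a, b] - m_ag[a, g] - m_bg[b, g] + m_a[a] + m_b[b] + m_g[g] - gm) ** 2
        for a in A for b in B for g in glevels
    )
    ss_abs = sum(
        (
            y[s, a, b]
            - m_as[a, s]
            - m_bs[b, s]
            + m_s[s]
            - m_abg[a, b, group[s]]
            + m_ag[a, group[s]]
            + m_bg[b, group[s]]
            - m_g[group[s]]
        )
        ** 2
        for a in A for b in B for s in subjects
    )
    dfe = N - len(glevels)
    return {
        "feature": ss_a / (ss_as / dfe),
        "hemisphere": ss_b / (ss_bs / dfe),
        "sex": ss_g / (ss_subj / dfe),
        "feature:hemisphere": ss_ab / (ss_abs / dfe),
        "feature:sex": ss_ag / (ss_as / dfe),
        "hemisphere:sex": ss_bg / (ss_bs / dfe),
        "feature:hemisphere:sex": ss_abg / (ss_abs / dfe),
    }


class TestMixedAnova:
    def test_constant_response_gives_zero_F(self):
        df = make_long(np.full((6, 4), 3.0), ["male"] * 3 + ["female"] * 3)
        res = mixed_anova_3way(df, "y")
        assert all(res.F[e] == 0.0 for e in res.effects)

    def test_balanced_design_matches_ss_oracle(self):
        rng = np.random.default_rng(8)
        cells = rng.normal(0, 1, (8, 4)) + np.array([0.5, 0.0, -0.3, 0.2])
        df = make_long(cells, ["male"] * 4 + ["female"] * 4)
        res = mixed_anova_3way(df, "y")
        oracle = oracle_balanced_mixed_anova(df)
        for e, f_exp in oracle.items():
            assert res.F[e] == pytest.approx(f_exp, abs=1e-10), e
            assert res.df_num[e] == 1 and res.df_den[e] == 6

    def test_unbalanced_between_factor_matches_regression_route(self):
        """Independent route: OLS on the per-subject contrast scores with
        sum-to-zero coding reproduces every type-3 F as a squared t."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(9)
        n1, n2 = 11, 5  # deliberately unbalanced
        cells = rng.normal(0, 1, (n1 + n2, 4))
        df = make_long(cells, ["male"] * n1 + ["female"] * n2)
        res = mixed_anova_3way(df, "y")

        wide = df.pivot_table(index="subject_id", columns=["feature", "hemisphere"], values="y")
        scores = pd.DataFrame(
            {
                "m": wide.mean(axis=1),
                "sA": (wide[("I", "left")] + wide[("I", "right")] - wide[("II", "left")] - wide[("II", "right")]) / 2,
                "sB": (wide[("I", "left")] - wide[("I", "right")] + wide[("II", "left")] - wide[("II", "right")]) / 2,
                "sAB": (wide[("I", "left")] - wide[("I", "right")] - wide[("II", "left")] + wide[("II", "right")]) / 2,
                "g": df.groupby("subject_id")["sex"].first(),
            }
        )
        for col, main, inter in (
            ("m", None, "sex"),
            ("sA", "feature", "feature:sex"),
            ("sB", "hemisphere", "hemisphere:sex"),
            ("sAB", "feature:hemisphere", "feature:hemisphere:sex"),
        ):
            fit = smf.ols(f"{col} ~ C(g, Sum)", data=scores).fit()
            t_int, t_grp = fit.tvalues.iloc[0], fit.tvalues.iloc[1]
            if main is not None:
                assert res.F[main] == pytest.approx(t_int**2, rel=1e-10)
            assert res.F[inter] == pytest.approx(t_grp**2, rel=1e-10)

    def test_incomplete_subject_dropped_and_reported(self):
        df = make_long(np.random.default_rng(0).normal(size=(5, 4)), ["male"] * 3 + ["female"] * 2)
        df = df[~((df["subject_id"] == "s000") & (df["hemisphere"] == "right") & (df["feature"] == "I"))]
        res = mixed_anova_3way(df, "y")
        assert res.n_subjects == 4
        assert res.dropped_subjects == ["s000"]

    def test_empty_between_level_is_error(self):
        df = make_long(np.random.default_rng(0).normal(size=(4, 4)), ["male"] * 4)
        with pytest.raises(ValueError, match="levels"):
            mixed_anova_3way(df, "y")


class TestPostHoc:
    def test_identical_pairs(self):
        x = np.arange(10.0)
        res = posthoc_paired_t([("same", x, x.copy())])
        row = res.table.iloc[0]
        assert row["delta"] == 0.0 and row["t"] == 0.0 and row["p"] == 1.0

    def test_constant_shift_degenerate(self):
        x = np.arange(10.0)
        res = posthoc_paired_t([("shift", x + 2.0, x)])
        row = res.table.iloc[0]
        assert row["degenerate"]
        assert row["delta"] == pytest.approx(2.0)
        assert np.isnan(row["t"])

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(0, 1, 40), rng.normal(0.3, 1, 40)
        res = posthoc_paired_t([("ab", x, y)])
        row = res.table.iloc[0]
        t_ref, p_ref = sps.ttest_rel(x, y)
        assert row["t"] == pytest.approx(t_ref, abs=1e-12)
        assert row["p"] == pytest.approx(p_ref, abs=1e-12)
        d = x - y
        sem = d.std(ddof=1) / np.sqrt(40)
        tc = sps.t.ppf(0.975, 39)
        assert row["ci_low"] == pytest.approx(d.mean() - tc * sem, abs=1e-12)
        assert row["ci_high"] == pytest.approx(d.mean() + tc * sem, abs=1e-12)
        assert row["ci_low"] <= row["delta"] <= row["ci_high"]

    def test_bonferroni_threshold(self):
        rng = np.random.default_rng(1)
        comps = [(f"c{i}", rng.normal(size=10), rng.normal(size=10)) for i in range(4)]
        res = posthoc_paired_t(comps)
        assert res.p_crit == pytest.approx(0.0125)


def _handed_table(oldfields, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s, v in enumerate(oldfields):
        base = rng.normal(0, 1) + (effect if v > 0 else 0.0)
        for a in ("I", "II"):
            for b in ("left", "right"):
                rows.append(
                    {
                        "subject_id": f"s{s:03d}",
                        "feature": a,
                        "hemisphere": b,
                        "oldfield": v,
                        "handedness": "left_handed" if v < 0 else "right_handed",
                        "y": base + rng.normal(0, 0.5),
                    }
                )
    return pd.DataFrame(rows)


class TestBalancedResampling:
    def test_exact_mirrored_pairing_single_iteration(self):
        df = _handed_table([-10, -20, 10, 20, 100])
        res = balanced_resample_anova(df, "y", iterations=1, seed=0)
        assert res.n_matched == 4
        assert res.unmatched_warnings == 0
        assert set(res.median_F) == {
            "feature", "hemisphere", "handedness", "feature:hemisphere",
            "feature:handedness", "hemisphere:handedness", "feature:hemisphere:handedness",
        }

    def test_nearest_index_fallback_counts_warning(self):
        df = _handed_table([-10, -20, 15, 25])
        res = balanced_resample_anova(df, "y", iterations=1, seed=0)
        assert res.unmatched_warnings >= 1

    def test_reproducible_from_seed(self):
        df = _handed_table([-10, -20, -5, 10, 20, 5, 100, 55], seed=2)
        a = balanced_resample_anova(df, "y", iterations=20, seed=7)
        b = balanced_resample_anova(df, "y", iterations=20, seed=7)
        assert a.median_F == b.median_F and a.median_p == b.median_p

    def test_null_handedness_p_centred(self):
        olds = [-5 * k for k in range(1, 7)] + [5 * k for k in range(1, 25)]
        df = _handed_table(olds, seed=3, effect=0.0)
        res = balanced_resample_anova(df, "y", iterations=100, seed=1)
        assert 0.05 < res.median_p["handedness"] < 0.95

    def test_too_few_left_handers_is_error(self):
        df = _handed_table([-10, 10, 20, 30])
        with pytest.raises(ValueError):
            balanced_resample_anova(df, "y", iterations=1, seed=0)


class TestPermutation:
    def test_empirical_p_formula(self):
        from sulcprofile.stats import PermutationResult

        assert PermutationResult("e", 1.0, 10_000, 0).p_empirical == pytest.approx(1 / 10_001)
        assert PermutationResult("e", 1.0, 100, 100).p_empirical == 1.0

    def test_strong_effect_small_p(self):
        olds = [-5 * (k % 20 + 1) for k in range(15)] + [5 * (k % 20 + 1) for k in range(15)]
        df = _handed_table(olds, seed=4, effect=5.0)
        res = permutation_anova(df, "y", iterations=199, seed=0, between="handedness")
        assert res["handedness"].p_empirical == pytest.approx(1 / 200)

    def test_reproducible_and_in_unit_interval(self):
        df = _handed_table([-5, -10, -15, 5, 10, 15], seed=5)
        a = permutation_anova(df, "y", iterations=99, seed=3, between="handedness")
        b = permutation_anova(df, "y", iterations=99, seed=3, between="handedness")
        for e in a:
            assert a[e].p_empirical == b[e].p_empirical
            assert 0.0 < a[e].p_empirical <= 1.0


class TestLmm:
    def test_zero_intercept_variance_boundary(self):
        """Subject means forced identical: the intercept variance estimate sits
        on the zero boundary and fixed effects collapse to ordinary least squares."""
        rng = np.random.default_rng(6)
        df = _handed_table([-5 * k for k in range(1, 16)] + [5 * k for k in range(1, 16)], seed=6)
        df["y"] = rng.normal(0, 1, len(df))
        df["y"] -= df.groupby("subject_id")["y"].transform("mean")  # zero subject means
        df["hand"] = np.where(df["oldfield"] < 0, "L", "R")
        res = lmm_random_intercept(df, "y", fixed="feature * hemisphere * hand")
        assert res.boundary
        assert res.var_intercept == pytest.approx(0.0, abs=1e-4)
        import statsmodels.formula.api as smf

        ols = smf.ols("y ~ feature * hemisphere * hand", data=df).fit()
        # within-subject contrasts carry no intercept-variance shrinkage and
        # must match OLS; the pure between-subject terms are degenerate under
        # the exact centering used to force the boundary
        within = [k for k in res.params.index if "feature" in k or "hemisphere" in k]
        np.testing.assert_allclose(
            res.params[within].to_numpy(), ols.params[within].to_numpy(), atol=1e-4
        )

    def test_between_wald_agrees_with_mixed_anova_on_balanced_data(self):
        """With a balanced design the subject-stratum ANOVA F for the between
        factor and the LMM Wald t^2 coincide."""
        rng = np.random.default_rng(7)
        n = 60
        rows = []
        for s in range(n):
            hand = "L" if s < n // 2 else "R"
            u = rng.normal(0, 1.2)
            for a in ("I", "II"):
                for b in ("left", "right"):
                    rows.append(
                        {
                            "subject_id": f"s{s}",
                            "feature": a,
                            "hemisphere": b,
                            "handedness": hand,
                            "y": 0.6 * (hand == "R") + u + rng.normal(0, 0.8),
                        }
                    )
        df = pd.DataFrame(rows)
        anova = mixed_anova_3way(df, "y", between="handedness")
        df["hand"] = df["handedness"]
        # sum coding so the coefficient is the marginal (main) handedness effect
        lmm = lmm_random_intercept(
            df, "y", fixed="C(hand, Sum) * C(feature, Sum) * C(hemisphere, Sum)"
        )
        t_hand = [v for k, v in lmm.tvalues.items() if k == "C(hand, Sum)[S.L]"][0]
        assert t_hand**2 == pytest.approx(anova.F["handedness"], rel=0.05)


class TestCorrelationAndChecks:
    def test_perfect_linear_relation(self):
        x = np.linspace(0, 1, 50)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_two_tailed < 1e-10

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(12)
        res = pearson_correlation(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(res.r) < 0.05

    def test_zero_variance_flagged(self):
        res = pearson_correlation(np.ones(10), np.arange(10.0))
        assert res.degenerate and np.isnan(res.r)

    def test_equal_variances_levene_null(self):
        rng = np.random.default_rng(13)
        groups = {f"g{i}": rng.normal(0, 1, 500) for i in range(4)}
        rep = assumption_checks(groups)
        lev = rep[rep["test"] == "levene"].iloc[0]
        assert lev["p"] > 0.05

    def test_skewed_group_fails_shapiro(self):
        rng = np.random.default_rng(14)
        rep = assumption_checks({"skew": rng.exponential(1.0, 200), "norm": rng.normal(0, 1, 200)})
        sh = rep[(rep["group"] == "skew") & (rep["test"] == "shapiro")].iloc[0]
        assert sh["p"] < 0.01

    def test_constant_and_tiny_groups_skipped(self):
        rep = assumption_checks({"const": np.ones(50), "tiny": np.array([1.0, 2.0])})
        notes = rep.set_index("group")["note"]
        assert "constant" in notes["const"]
        assert "n < 3" in notes["tiny"]
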