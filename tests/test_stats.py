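"""Repeated-measures correlation, mixed models, individual fits, stratification."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chijva import stats as cst
from chijva.pipeline import simulate_common_slope_table


def rmcorr_oracle(df, x="csa", y="jva"):
    """Independent oracle via within-participant centering (FWL theorem).

    Demeaning both variables within participant removes the participant
    intercepts; the common slope and correlation follow from the centered
    cross-products, with df = N_obs - N_participants - 1.
    """
    g = df.groupby("participant")
    xc = df[x] - g[x].transform("mean")
    yc = df[y] - g[y].transform("mean")
    sxx = float((xc**2).sum())
    sxy = float((xc * yc).sum())
    syy = float((yc**2).sum())
    slope = sxy / sxx
    r = sxy / np.sqrt(sxx * syy)
    dof = len(df) - df["participant"].nunique() - 1
    from scipy import stats as sps

    f = r**2 / (1 - r**2) * dof
    return r, slope, dof, float(sps.f.sf(f, 1, dof))


def random_instance(rng, n_part, k):
    rows = []
    for i in range(n_part):
        x = rng.uniform(0, 1, k)
        y = rng.uniform(0.3, 0.8) + rng.normal(0, 0.3) * x + 0.1 * rng.standard_normal(k)
        for j in range(k):
            rows.append(
                {"participant": f"P{i}", "sex": "M", "condition": "LBNP",
                 "level": float(-10 * j), "csa": x[j], "jva": y[j]}
            )
    return pd.DataFrame(rows)


class TestRmcorr:
    def test_identical_slopes_give_unit_magnitude(self):
        rows = []
        for i, intercept in enumerate((0.2, 0.5, 0.9)):
            for j, x in enumerate((0.1, 0.4, 0.7)):
                rows.append({"participant": f"P{i}", "sex": "F", "condition": "HDT",
                             "level": float(-3 * j), "csa": x, "jva": intercept + 0.3 * x})
        df = pd.DataFrame(rows)
        res = cst.rmcorr(df)
        assert res.r_rm == pytest.approx(1.0)
        assert res.common_slope == pytest.approx(0.3)
        neg = df.assign(jva=-df["jva"])
        res_neg = cst.rmcorr(neg)
        assert res_neg.r_rm == pytest.approx(-1.0)

    def test_matches_centering_oracle_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(60):
            df = random_instance(rng, int(rng.integers(2, 9)), int(rng.integers(3, 7)))
            res = cst.rmcorr(df)
            r, slope, dof, p = rmcorr_oracle(df)
            assert res.r_rm == pytest.approx(r, abs=1e-10)
            assert res.common_slope == pytest.approx(slope, abs=1e-10)
            assert res.df == dof
            assert res.p == pytest.approx(p, rel=1e-8, abs=1e-12)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        df = random_instance(np.random.default_rng(3), 6, 4)
        res = cst.rmcorr(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pg.rm_corr(data=df, x="csa", y="jva", subject="participant")
        assert res.r_rm == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.df == int(ref["dof"].iloc[0])
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_sign_equivariance_under_y_negation(self):
        df = random_instance(np.random.default_rng(4), 5, 4)
        a = cst.rmcorr(df)
        b = cst.rmcorr(df.assign(jva=-df["jva"]))
        assert b.r_rm == pytest.approx(-a.r_rm, abs=1e-12)
        assert b.p == pytest.approx(a.p, rel=1e-10)

    def test_constant_covariate_participant_excluded_with_warning(self):
        df = random_instance(np.random.default_rng(5), 4, 4)
        extra = pd.DataFrame(
            [{"participant": "PX", "sex": "M", "condition": "LBNP", "level": float(-10 * j),
              "csa": 0.5, "jva": 0.6 + 0.01 * j} for j in range(4)]
        )
        with pytest.warns(UserWarning, match="constant"):
            res = cst.rmcorr(pd.concat([df, extra], ignore_index=True))
        assert res.n_participants == 4

    def test_ci_brackets_estimate(self):
        res = cst.rmcorr(random_instance(np.random.default_rng(6), 6, 4))
        assert res.ci_low <= res.r_rm <= res.ci_high
        assert -1.0 <= res.ci_low <= res.ci_high <= 1.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_effect_size_property(self, seed):
        df = random_instance(np.random.default_rng(seed), 4, 4)
        res = cst.rmcorr(df)
        assert -1.0 <= res.r_rm <= 1.0
        assert 0.0 <= res.p <= 1.0


class TestIndividualFits:
    def test_exact_line(self):
        df = pd.DataFrame(
            [{"participant": "P0", "sex": "M", "condition": "HDT", "level": float(-3 * j),
              "csa": x, "jva": 2 * x + 1} for j, x in enumerate((0.1, 0.3, 0.6))]
        )
        fits = cst.individual_fits(df)
        assert len(fits) == 1
        assert fits[0].slope == pytest.approx(2.0)
        assert fits[0].r == pytest.approx(1.0)
        assert fits[0].delta_csa == pytest.approx(0.5)

    def test_median_iqr_quantile_rule(self):
        slopes = np.array([0.1, 0.2, 0.3])
        assert np.median(slopes) == pytest.approx(0.2)
        q25, q75 = np.percentile(slopes, [25, 75])
        assert (q25, q75) == (pytest.approx(0.15), pytest.approx(0.25))
        fits = [
            cst.IndividualFit("P%d" % i, "M", "HDT", s, 0.0, 0.9, 3, 0.2)
            for i, s in enumerate(slopes)
        ]
        summary = cst.summarize_fits(fits)
        assert summary["slope_median"].iloc[0] == pytest.approx(0.2)
        assert summary["slope_q25"].iloc[0] == pytest.approx(0.15)
        assert summary["slope_q75"].iloc[0] == pytest.approx(0.25)

    def test_constant_covariate_omitted(self):
        df = pd.DataFrame(
            [{"participant": "P0", "sex": "M", "condition": "HDT", "level": float(-3 * j),
              "csa": 0.5, "jva": 0.6} for j in range(3)]
        )
        assert cst.individual_fits(df) == []

    def test_too_few_points_omitted(self):
        df = pd.DataFrame(
            [{"participant": "P0", "sex": "M", "condition": "HDT", "level": float(-3 * j),
              "csa": 0.1 * j, "jva": 0.6 + 0.1 * j} for j in range(2)]
        )
        assert cst.individual_fits(df) == []


class TestCompareSlopes:
    def test_exact_fully_separated_3v3(self):
        stat, p = cst.compare_slopes([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_give_p_one(self):
        _, p = cst.compare_slopes([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_in_group_order(self):
        a = [0.1, 0.5, 0.9, 1.3]
        b = [0.2, 0.4, 1.1]
        _, p1 = cst.compare_slopes(a, b)
        _, p2 = cst.compare_slopes(b, a)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cst.compare_slopes([], [1.0])


def balanced_table(rng, n_per_sex=6, levels=(0.0, -20.0, -30.0, -40.0),
                   sex_effect=0.1, level_effect=0.02, interaction=0.0,
                   subject_sd=0.0, noise_sd=0.0):
    rows = []
    for s, sex in enumerate(("F", "M")):
        for i in range(n_per_sex):
            pid = f"{sex}{i}"
            a_i = rng.normal(0, subject_sd) if subject_sd else 0.0
            for j, lv in enumerate(levels):
                y = (
                    0.5 + a_i + sex_effect * (0.5 if sex == "M" else -0.5)
                    + level_effect * j
                    + interaction * j * (0.5 if sex == "M" else -0.5)
                    + (rng.normal(0, noise_sd) if noise_sd else 0.0)
                )
                rows.append({"participant": pid, "sex": sex, "condition": "LBNP",
                             "level": lv, "jva": y, "csa": 0.5, "baseline_csa": 0.5})
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_matches_ols_when_no_subject_variance(self):
        """With zero between-participant variance the GLS fit collapses to OLS."""
        rng = np.random.default_rng(7)
        df = balanced_table(rng, noise_sd=0.01)
        res = cst.fit_lmm(df, response="jva")
        import statsmodels.formula.api as smf

        df2 = df.copy()
        df2["level_f"] = pd.Categorical(
            df2["level"].astype(str),
            categories=[str(l) for l in sorted(df2["level"].unique(), key=abs)],
            ordered=True,
        )
        df2["sex_e"] = np.where(df2["sex"] == "M", 0.5, -0.5)
        ols = smf.ols("jva ~ C(level_f, Sum) * sex_e", df2).fit()
        for name in res.fixed_effects.index:
            assert res.fixed_effects[name] == pytest.approx(ols.params[name], abs=1e-6)

    def test_recovers_additive_effects_exactly(self):
        rng = np.random.default_rng(8)
        df = balanced_table(rng, sex_effect=0.12, level_effect=0.03)
        res = cst.fit_lmm(df, response="jva")
        assert res.fixed_effects["sex_e"] == pytest.approx(0.12, abs=1e-6)
        interaction = [n for n in res.fixed_effects.index if ":" in n]
        assert np.allclose(res.fixed_effects[interaction], 0.0, atol=1e-8)
        # Balanced design: EMMs equal cell means.
        cell = df[(df["sex"] == "M") & (df["level"] == -40.0)]["jva"].mean()
        got = res.emm[(res.emm["sex"] == "M") & (res.emm["level"] == -40.0)]["emm"].iloc[0]
        assert got == pytest.approx(cell, abs=1e-6)

    def test_sex_invariant_response_gives_null_sex_test(self):
        """No true sex effect: the sex p-value is null-distributed (large),
        while the level effect is detected."""
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(20):
            df = balanced_table(rng, n_per_sex=10, sex_effect=0.0, level_effect=0.05,
                                subject_sd=0.02, noise_sd=0.01)
            res = cst.fit_lmm(df, response="jva")
            pvals.append(res.p_values["sex"])
            assert res.p_values["level"] < 1e-6
        assert np.mean(np.asarray(pvals) > 0.05) >= 0.8
        assert np.mean(pvals) > 0.3

    def test_interaction_detected_when_present(self):
        rng = np.random.default_rng(10)
        df = balanced_table(rng, n_per_sex=10, interaction=0.05, subject_sd=0.01,
                            noise_sd=0.005)
        res = cst.fit_lmm(df, response="jva")
        assert res.p_values["sex_x_level"] < 0.01

    def test_tukey_contrasts_monotone_in_effect(self):
        rng = np.random.default_rng(11)
        df = balanced_table(rng, n_per_sex=8, sex_effect=0.2, subject_sd=0.01,
                            noise_sd=0.01)
        res = cst.fit_lmm(df, response="jva")
        assert (res.contrasts["estimate_m_minus_f"] > 0).all()
        assert (res.contrasts["p_tukey"] < 0.05).all()
        assert (res.contrasts["p_tukey"] >= 0).all()

    def test_baseline_covariate_model_runs(self):
        rng = np.random.default_rng(12)
        df = balanced_table(rng, noise_sd=0.01)
        base = {pid: rng.uniform(0.3, 0.8) for pid in df["participant"].unique()}
        df["baseline_csa"] = df["participant"].map(base)
        res = cst.fit_lmm(df, response="jva", include_baseline_csa=True)
        assert "baseline_csa" in res.p_values

    def test_single_sex_rejected(self):
        rng = np.random.default_rng(13)
        df = balanced_table(rng)
        with pytest.raises(ValueError):
            cst.fit_lmm(df[df["sex"] == "M"], response="jva")


class TestStratifyReliability:
    def _fit(self, r, delta):
        return cst.IndividualFit("P", "M", "HDT", 0.1, 0.0, r, 3, delta)

    def test_all_high_flags_empty_low_stratum(self):
        fits = [self._fit(0.9, 0.5), self._fit(0.8, 0.4)]
        out = cst.stratify_reliability(fits)
        assert out["n_low"] == 0
        assert any("low" in f for f in out["flags"])

    def test_zero_threshold_puts_all_high(self):
        fits = [self._fit(0.9, 0.01), self._fit(0.8, 0.02)]
        out = cst.stratify_reliability(fits, threshold=0.0)
        assert out["n_high"] == 2 and out["n_low"] == 0

    def test_widths_computed_per_stratum(self):
        fits = [self._fit(r, 0.05) for r in (-0.5, 0.2, 0.9)] + [
            self._fit(r, 0.4) for r in (0.85, 0.9, 0.95)
        ]
        out = cst.stratify_reliability(fits)
        assert out["iqr_width_low"] > out["iqr_width_high"]


class TestAnthropometric:
    def test_identity_gives_unit_correlation(self):
        rng = np.random.default_rng(14)
        thick = rng.uniform(0.6, 1.4, 20)
        tab = pd.DataFrame({
            "jva_baseline": thick, "scm_thickness": thick,
            "ijv_depth": rng.uniform(1.0, 1.8, 20),
        })
        out = cst.anthropometric_correlations(tab)
        assert out["scm_thickness"]["r"] == pytest.approx(1.0)

    def test_permuted_jva_decorrelates(self):
        rng = np.random.default_rng(15)
        thick = rng.uniform(0.6, 1.4, 200)
        jva = 0.4 + 0.1 * thick + 0.01 * rng.standard_normal(200)
        tab = pd.DataFrame({
            "jva_baseline": rng.permutation(jva), "scm_thickness": thick,
            "ijv_depth": rng.uniform(1.0, 1.8, 200),
        })
        out = cst.anthropometric_correlations(tab)
        assert abs(out["scm_thickness"]["r"]) < 0.2

    def test_zero_variance_rejected(self):
        tab = pd.DataFrame({
            "jva_baseline": [0.5, 0.5, 0.5], "scm_thickness": [0.8, 0.9, 1.0],
            "ijv_depth": [1.1, 1.2, 1.3],
        })
        with pytest.raises(ValueError):
            cst.anthropometric_correlations(tab)


class TestSmallHelpers:
    def test_percent_difference_arithmetic(self):
        assert cst.percent_difference(0.61, 0.51) == pytest.approx(100 * 0.10 / 0.51)

    def test_students_t_reduces_to_standard_formula(self):
        """Hand-computed pooled-variance two-sample t."""
        m = np.array([1.0, 2.0, 3.0])
        f = np.array([2.0, 4.0, 6.0])
        cohort = pd.DataFrame({
            "sex": ["M"] * 3 + ["F"] * 3, "bsa": np.concatenate([m, f]),
        })
        t, p = cst.demographics_ttest(cohort, "bsa")
        sp2 = (m.var(ddof=1) * 2 + f.var(ddof=1) * 2) / 4
        expected = (m.mean() - f.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(expected, abs=1e-12)


class TestSlopeRecovery:
    def test_known_common_slope_recovered(self):
        ests = [
            cst.rmcorr(simulate_common_slope_table(10, 4, slope=0.1, seed=s)).common_slope
            for s in range(40)
        ]
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.1) <= 3 * se
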