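import math

import numpy as np
import pandas as pd
import pytest

import pitnet_ith as pi
from pitnet_ith.cohort_stats import categorical_test, records_to_frame


def _record(**kw):
    base = dict(
        patient_id="p", age=40.0, sex="M", surgery_approach="ETS",
        ihc_class="GH-only", gh_preop=5.0, gh_post24h=1.0, tumor_volume=5.0,
        residual_volume=1.0, residual_present=True,
    )
    base.update(kw)
    return pi.PatientRecord(**base)


class TestRemissionRules:
    @pytest.mark.parametrize(
        "gh,limit,expected", [(0.5, 2.0, True), (2.0, 2.0, False), (3.7, 2.0, False)]
    )
    def test_center_rule_strict_below(self, gh, limit, expected):
        assert pi.classify_remission_center(gh, limit) is expected

    def test_center_rule_requires_limit(self):
        with pytest.raises(ValueError):
            pi.classify_remission_center(1.0, None)

    @pytest.mark.parametrize(
        "rand,nadir,igf,expected",
        [
            (0.8, None, True, True),
            (None, 0.3, True, True),
            (0.8, None, False, False),
            (1.0, None, True, False),  # random GH branch is strict <1
            (None, 0.4, True, False),  # nadir branch is strict <0.4
        ],
    )
    def test_consensus_rule(self, rand, nadir, igf, expected):
        assert pi.classify_remission_consensus(rand, nadir, igf) is expected

    def test_consensus_rule_needs_a_measurement(self):
        with pytest.raises(ValueError):
            pi.classify_remission_consensus(None, None, True)


class TestDerivedCategories:
    @pytest.mark.parametrize(
        "gh,expected", [(10.0, "<=10"), (10.1, "10-30"), (30.0, "10-30"), (35.0, ">30")]
    )
    def test_gh_bins(self, gh, expected):
        assert pi.categorize_record(_record(gh_preop=gh))["gh_preop_bin"] == expected

    @pytest.mark.parametrize(
        "pct,expected", [(0.0, "0"), (15.0, "0-30"), (30.0, "0-30"), (40.0, "30-50"), (55.0, ">50")]
    )
    def test_encasement_categories(self, pct, expected):
        got = pi.categorize_record(_record(ica_encasement_pct=pct))
        assert got["ica_encasement_cat"] == expected

    @pytest.mark.parametrize(
        "kw,expected",
        [
            (dict(knosp_grade=3), True),
            (dict(knosp_grade=2), False),
            (dict(hardy_grade="III"), True),
            (dict(hardy_stage="C"), True),
            (dict(hardy_stage="B"), False),
        ],
    )
    def test_invasiveness_rule(self, kw, expected):
        assert pi.categorize_record(_record(**kw))["invasive"] is expected

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            _record(gh_preop=-1.0)
        with pytest.raises(ValueError):
            _record(residual_volume=9.0, tumor_volume=5.0)
        with pytest.raises(ValueError):
            _record(ica_encasement_pct=130.0)


class TestDiscordance:
    def test_all_concordant_is_zero(self):
        assert pi.discordance_rate([True, False], [True, False]) == 0.0

    def test_half_discordant(self):
        assert pi.discordance_rate([True, True], [True, False]) == 50.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pi.discordance_rate([], [])


class TestUnivariate:
    def test_chi_square_reproduces_published_2x2_tables(self):
        # intrasellar residual (yes/no x nonremission/remission)
        test, stat, p = categorical_test(np.array([[15, 68], [4, 57]]).T)
        assert test == "chi_square"
        assert stat == pytest.approx(4.07, abs=0.005)
        assert p == pytest.approx(0.044, abs=0.002)
        # suprasellar residual
        test, _, p = categorical_test(np.array([[29, 54], [25, 36]]).T)
        assert test == "chi_square"
        assert p == pytest.approx(0.459, abs=0.002)

    def test_fisher_triggered_by_small_expected_counts(self):
        test, _, p = categorical_test(np.array([[2, 1], [1, 20]]))
        assert test == "fisher"
        assert 0 <= p <= 1

    def test_monte_carlo_fisher_on_larger_table_tracks_chi_square(self):
        table = np.array([[3, 1, 0], [2, 15, 12], [1, 12, 30]])
        rng = np.random.default_rng(0)
        test, _, p = categorical_test(table, rng)
        assert test == "fisher"
        from scipy.stats import chi2_contingency

        p_chi = chi2_contingency(table, correction=False)[1]
        assert p == pytest.approx(p_chi, abs=0.05)

    def test_gate_routes_normal_and_skewed_factors(self):
        rng = np.random.default_rng(2)
        n = 120
        df = pd.DataFrame(
            {
                "outcome": np.repeat([False, True], n // 2),
                "gaussian": rng.normal(0, 1, n),
                "skewed": rng.lognormal(0, 1.5, n),
            }
        )
        res = {r.factor: r for r in pi.univariate_tests(df, "outcome", ["gaussian", "skewed"])}
        assert res["gaussian"].test == "t"
        assert res["skewed"].test == "mann_whitney"

    def test_identical_groups_null_p(self):
        x = np.tile(np.arange(10.0), 2) + np.random.default_rng(0).normal(0, 1e-6, 20)
        df = pd.DataFrame({"outcome": np.repeat([False, True], 10), "v": x})
        res = pi.univariate_tests(df, "outcome", ["v"])[0]
        assert res.p_value > 0.9


class TestLogistic:
    def test_single_binary_covariate_matches_cross_product_ratio(self):
        # 2x2: exposed 30/10, unexposed 20/40 -> OR = (30*40)/(10*20) = 6
        rows = (
            [(1, 1)] * 30 + [(1, 0)] * 10 + [(0, 1)] * 20 + [(0, 0)] * 40
        )
        df = pd.DataFrame(rows, columns=["x", "y"])
        df["x"] = df["x"].astype(bool)
        df["y"] = df["y"].astype(bool)
        res = pi.fit_multivariate_logistic(df, "y", ["x"])
        assert res["x"].odds_ratio == pytest.approx(6.0, rel=1e-4)

    def test_categorical_reference_coding(self):
        rng = np.random.default_rng(5)
        lvl = rng.choice(["a", "b", "c"], 300)
        logit = -0.2 + 1.0 * (lvl == "b") + 0.3 * (lvl == "c")
        y = rng.random(300) < 1 / (1 + np.exp(-logit))
        df = pd.DataFrame({"g": lvl, "y": y})
        res = pi.fit_multivariate_logistic(df, "y", ["g"], reference_levels={"g": "a"})
        names = [t.term for t in res.terms]
        assert names == ["g[b]", "g[c]"]
        assert res.reference_levels["g"] == "a"

    def test_planted_or_recovered(self):
        ests, cover = [], 0
        n_rep = 20
        for rep in range(n_rep):
            spec = pi.CohortSpec(
                n_patients=2000, intercept=-0.5, beta_gh_10_30=0, beta_gh_gt30=0,
                beta_resection=0, beta_ith=0, beta_intrasellar_direct=math.log(3.0),
                p_intrasellar=0.5, mediator_slope=0.0, seed=900 + rep,
            )
            recs, truth = pi.simulate_cohort(spec)
            df = records_to_frame(recs)
            df["remission"] = truth["remission"]
            t = pi.fit_multivariate_logistic(df, "remission", ["residual_intrasellar"])[
                "residual_intrasellar"
            ]
            ests.append(t.odds_ratio)
            cover += t.ci_low <= 3.0 <= t.ci_high
        assert 2.5 <= np.mean(ests) <= 3.6
        assert cover >= 0.9 * n_rep

    def test_binary_outcome_required(self):
        df = pd.DataFrame({"y": [True] * 10, "x": np.arange(10.0)})
        with pytest.raises(ValueError):
            pi.fit_multivariate_logistic(df, "y", ["x"])


class TestMediation:
    def _full_mediation_cohort(self, seed=5):
        spec = pi.CohortSpec(
            n_patients=1000, intercept=-2.5, beta_gh_10_30=0, beta_gh_gt30=0,
            beta_resection=4.0, beta_ith=0, beta_intrasellar_direct=0.0,
            p_intrasellar=0.5, mediator_slope=-0.3, seed=seed,
        )
        recs, truth = pi.simulate_cohort(spec)
        df = records_to_frame(recs)
        df["remission"] = truth["remission"]
        return df

    def test_full_mediation_signature(self):
        df = self._full_mediation_cohort()
        med = pi.mediation_analysis(
            df, "residual_intrasellar", "resection_rate", "remission", n_sim=1000, seed=3
        )
        assert med.acme_ci[0] <= med.acme <= med.acme_ci[1]
        assert not (med.acme_ci[0] <= 0 <= med.acme_ci[1])  # indirect effect real
        assert med.ade_ci[0] <= 0 <= med.ade_ci[1]  # no direct effect
        assert med.total_effect == pytest.approx(med.acme + med.ade, abs=1e-9)

    def test_null_exposure_acme_covers_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "x": rng.random(800) < 0.5,
                "m": rng.normal(0, 1, 800),
                "y": rng.random(800) < 0.4,
            }
        )
        med = pi.mediation_analysis(df, "x", "m", "y", n_sim=500, seed=1)
        assert med.acme_ci[0] <= 0 <= med.acme_ci[1]

    def test_determinism_same_seed(self):
        df = self._full_mediation_cohort()
        a = pi.mediation_analysis(df, "residual_intrasellar", "resection_rate", "remission", n_sim=300, seed=9)
        b = pi.mediation_analysis(df, "residual_intrasellar", "resection_rate", "remission", n_sim=300, seed=9)
        assert a.acme == b.acme and a.ade == b.ade

    def test_agrees_with_statsmodels_mediation(self):
        """Independent cross-check: statsmodels' quasi-Bayesian mediation on
        the same cohort gives compatible ACME/ADE point estimates."""
        import statsmodels.api as sm
        from statsmodels.stats.mediation import Mediation

        df = self._full_mediation_cohort()
        ours = pi.mediation_analysis(
            df, "residual_intrasellar", "resection_rate", "remission", n_sim=1000, seed=3
        )
        df2 = df.assign(
            x=df["residual_intrasellar"].astype(float),
            m=df["resection_rate"].astype(float),
            y=df["remission"].astype(float),
        )
        out_model = sm.GLM.from_formula("y ~ x + m", df2, family=sm.families.Binomial())
        med_model = sm.OLS.from_formula("m ~ x", df2)
        np.random.seed(42)
        sm_res = Mediation(out_model, med_model, "x", "m").fit(n_rep=500)
        sm_acme = sm_res.summary().loc["ACME (average)", "Estimate"]
        sm_ade = sm_res.summary().loc["ADE (average)", "Estimate"]
        assert ours.acme == pytest.approx(sm_acme, abs=0.03)
        assert ours.ade == pytest.approx(sm_ade, abs=0.03)


class TestConfig:
    def test_yaml_config_roundtrip_and_validation(self, tmp_path):
        from pitnet_ith.cohort_stats import load_analysis_config

        p = tmp_path / "cfg.yaml"
        p.write_text("gh_upper_normal: 2.0\nseed: 7\n")
        cfg = load_analysis_config(p)
        assert cfg["gh_upper_normal"] == 2.0 and cfg["seed"] == 7 and cfg["n_sim"] == 1000
        p.write_text("nope: 1\n")
        with pytest.raises(KeyError):
            load_analysis_config(p)


class TestCohortSummary:
    def test_published_proportions(self):
        df = pd.DataFrame({"residual": [True] * 144 + [False] * 314})
        s = pi.cohort_summary(df)
        assert s["overall"]["residual"]["True"]["pct"] == pytest.approx(31.44, abs=0.005)
        df = pd.DataFrame({"remission": [True] * 61 + [False] * 83})
        s = pi.cohort_summary(df)
        assert s["overall"]["remission"]["True"]["pct"] == pytest.approx(42.36, abs=0.005)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"cat": rng.choice(list("abcd"), 97)})
        s = pi.cohort_summary(df)
        assert sum(v["pct"] for v in s["overall"]["cat"].values()) == pytest.approx(100.0, abs=0.01)

    def test_stratified_and_degenerate(self):
        df = pd.DataFrame({"g": [True, True, False], "v": [1.0, 2.0, 3.0]})
        s = pi.cohort_summary(df, stratifier="g")
        assert s["g=True"]["n"] == 2
        single = pi.cohort_summary(pd.DataFrame({"v": [1.0]}))
        assert single["overall"]["v"]["sd_defined"] is False
        with pytest.raises(KeyError):
            pi.cohort_summary(df, stratifier="nope")
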