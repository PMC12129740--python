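"""Mixed models, smooths, ANCOVA, Holm and the analysis suite."""

import numpy as np
import pandas as pd
import pytest

from mtlnet.stats import (
    ModelSpec, SuiteConfig, ancova_pairwise, fit_gam_ranked, fit_lmm, holm,
    rank_groups, run_analysis_suite,
)
from mtlnet.synthgen import CohortConfig, generate_cohort


def brute_force_holm(pvals, alpha=0.05):
    """Literal step-down procedure as an independent oracle."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [None] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * pvals[idx]))
        adjusted[idx] = running
    reject = [None] * m
    # sequential rejection: stop at the first non-rejected hypothesis
    stopped = False
    for rank, idx in enumerate(order):
        if stopped or pvals[idx] >= alpha / (m - rank):
            stopped = True
            reject[idx] = False
        else:
            reject[idx] = True
    return adjusted, reject


class TestHolm:
    def test_single_pvalue_unchanged(self):
        adj, rej = holm([0.03])
        assert adj[0] == pytest.approx(0.03) and rej[0]

    def test_hand_stepped_examples(self):
        adj, rej = holm([0.01, 0.04])
        np.testing.assert_allclose(adj, [0.02, 0.04])
        assert rej.all()
        adj, rej = holm([0.03, 0.04])
        np.testing.assert_allclose(adj, [0.06, 0.06])
        assert not rej.any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = int(rng.integers(1, 9))
            p = rng.uniform(size=m)
            adj, rej = holm(p)
            adj_o, rej_o = brute_force_holm(list(p))
            np.testing.assert_allclose(adj, adj_o, atol=1e-12)
            np.testing.assert_array_equal(rej, rej_o)

    def test_never_rejects_less_than_bonferroni(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(2, 9)))
            _, rej = holm(p)
            bonf = p < 0.05 / len(p)
            assert np.all(rej | ~bonf)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            holm([0.2, 1.3])


class TestRankGroups:
    def test_extreme_groups(self):
        out = rank_groups(["CU-young", "AD"])
        assert list(out) == [1.0, 6.0]

    def test_order_free_coding(self):
        a = rank_groups(["MCI", "CU-oldneg", "AD"])
        b = rank_groups(["AD", "MCI", "CU-oldneg"])
        assert sorted(a) == sorted(b) == [3.0, 5.0, 6.0]

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="unknown group"):
            rank_groups(["CU-young", "HC"])

    def test_constant_labels_warn(self):
        with pytest.warns(UserWarning, match="identical"):
            rank_groups(["MCI", "MCI"])


def _longitudinal_table(n_subj=60, seed=0, slope=0.5, noise=1.0, tau=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subj):
        b = rng.normal(0, tau)
        x0 = rng.uniform(0, 10)
        for v in range(rng.integers(1, 4)):
            x = x0 + v
            rows.append(dict(subject_id=f"s{i}", x=x,
                             z=rng.normal(),
                             y=1.0 + slope * x + b + rng.normal(0, noise)))
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_matches_statsmodels_mixedlm(self):
        table = _longitudinal_table(seed=3)
        fit = fit_lmm(table, ModelSpec(outcome="y", fixed_terms=["x", "z"]))
        import statsmodels.formula.api as smf
        ref = smf.mixedlm("y ~ x + z", table,
                          groups=table["subject_id"]).fit(reml=True)
        for term in ("Intercept", "x", "z"):
            got = fit.coef(term)
            assert got["beta"] == pytest.approx(ref.params[term], abs=1e-5)
            assert got["se"] == pytest.approx(ref.bse[term], rel=1e-3)
        assert fit.sigma2 == pytest.approx(ref.scale, rel=1e-3)

    def test_one_observation_per_subject_matches_ols_anova(self):
        """With no replication the random intercept vanishes and the
        Satterthwaite F-tests must reduce to OLS ANOVA."""
        rng = np.random.default_rng(4)
        n = 80
        table = pd.DataFrame(dict(
            subject_id=[f"s{i}" for i in range(n)],
            x=rng.uniform(0, 1, n), z=rng.normal(size=n)))
        table["y"] = 2.0 + 0.8 * table["x"] + rng.normal(0, 0.5, n)
        fit = fit_lmm(table, ModelSpec(outcome="y", fixed_terms=["x", "z"]))
        assert fit.tau2 <= 1e-6 * fit.sigma2 + 1e-12
        import statsmodels.formula.api as smf
        ols = smf.ols("y ~ x + z", table).fit()
        for term in ("x", "z"):
            frow = fit.f_tests.set_index("term").loc[term]
            t_ols = ols.tvalues[term]
            assert frow["F"] == pytest.approx(t_ols**2, rel=1e-3)
            assert frow["df_den"] == pytest.approx(ols.df_resid, rel=1e-6)

    def test_planted_slope_recovered_within_ci(self):
        table = _longitudinal_table(n_subj=120, seed=5, slope=0.5)
        fit = fit_lmm(table, ModelSpec(outcome="y", fixed_terms=["x"]))
        c = fit.coef("x")
        assert c["ci_lo"] < 0.5 < c["ci_hi"]

    def test_degenerate_zero_outcome_flagged(self):
        table = _longitudinal_table(seed=6)
        table["y"] = 0.0
        fit = fit_lmm(table, ModelSpec(outcome="y", fixed_terms=["x"]))
        assert fit.degenerate
        assert (fit.coefficients["beta"] == 0).all()

    def test_interaction_requires_type_three(self):
        with pytest.raises(ValueError, match="Type III"):
            ModelSpec(outcome="y", fixed_terms=["x*z"],
                      ftest_type="II").resolved_type()

    def test_missing_column_named(self):
        table = _longitudinal_table(seed=7)
        with pytest.raises(KeyError, match="nope"):
            fit_lmm(table, ModelSpec(outcome="y", fixed_terms=["nope"]))

    def test_interaction_f_test_detects_planted_moderation(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(80):
            g = "a" if i % 2 else "b"
            b = rng.normal(0, 0.3)
            for v in range(2):
                x = rng.uniform(0, 4)
                slope = 1.0 if g == "a" else 2.0
                rows.append(dict(subject_id=f"s{i}", grp=g, x=x,
                                 y=slope * x + b + rng.normal(0, 0.3)))
        table = pd.DataFrame(rows)
        fit = fit_lmm(table, ModelSpec(outcome="y",
                                       fixed_terms=["x*C(grp)"],
                                       ftest_type="III"))
        frow = fit.f_tests.set_index("term").loc["x:C(grp)"]
        assert frow["p"] < 1e-6


class TestFitGamRanked:
    def _table(self, f, n_per=40, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        ranks = np.repeat(np.arange(1.0, 7.0), n_per)
        y = f(ranks) + rng.normal(0, noise, ranks.size)
        return pd.DataFrame(dict(group_rank=ranks, y=y))

    def test_linear_truth_gives_edf_near_one(self):
        fit = fit_gam_ranked(self._table(lambda r: 0.1 * r), "y")
        assert 1.0 <= fit.edf <= 1.2

    def test_quadratic_truth_gives_larger_edf(self):
        fit = fit_gam_ranked(self._table(lambda r: 0.05 * (r - 3.5) ** 2,
                                         noise=0.005), "y")
        assert fit.edf > 1.5

    def test_constant_outcome_is_flat(self):
        fit = fit_gam_ranked(self._table(lambda r: 0.0 * r, noise=0.02), "y")
        assert fit.edf <= 1.3
        fitted = fit.extra["fitted"]
        assert np.ptp(fitted) < 0.05

    def test_needs_three_distinct_ranks(self):
        tab = pd.DataFrame(dict(group_rank=[1.0, 2.0] * 10,
                                y=np.random.default_rng(0).normal(size=20)))
        with pytest.raises(ValueError, match="distinct rank"):
            fit_gam_ranked(tab, "y")


class TestAncovaPairwise:
    def _table(self, offset=0.0, n_per=25, sd=0.03, seed=0, confounded=False):
        rng = np.random.default_rng(seed)
        rows = []
        for g, shift in (("ctrl", 0.0), ("pat", offset)):
            for i in range(n_per):
                cov = rng.uniform(0, 1) + (1.0 if confounded and g == "pat" else 0.0)
                y = 0.2 + shift + (0.5 * cov if confounded else 0.0) \
                    + rng.normal(0, sd)
                rows.append(dict(group=g, y=y, cov=cov))
        return pd.DataFrame(rows)

    def test_identical_groups_give_null_contrast(self):
        res = ancova_pairwise(self._table(0.0), "y", covariates=["cov"])
        con = res.contrasts.iloc[0]
        assert abs(con["estimate"]) < 3 * con["se"]

    def test_planted_offset_recovered(self):
        hits = 0
        for seed in range(20):
            res = ancova_pairwise(self._table(0.04, seed=seed), "y",
                                  covariates=["cov"])
            con = res.contrasts.iloc[0]
            if abs(abs(con["estimate"]) - 0.04) <= 2 * con["se"]:
                hits += 1
        assert hits >= 17

    def test_confounded_offset_explained_by_covariate(self):
        # the group offset is carried entirely by the covariate
        res = ancova_pairwise(self._table(0.0, confounded=True, sd=0.01,
                                          n_per=80), "y", covariates=["cov"])
        con = res.contrasts.iloc[0]
        assert abs(con["estimate"]) < 4 * con["se"] + 0.01

    def test_small_groups_rejected(self):
        tab = pd.DataFrame(dict(group=["a", "a", "b"], y=[1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="fewer than 2"):
            ancova_pairwise(tab, "y")

    def test_singular_design_lists_alias(self):
        tab = self._table(0.1)
        tab["cov2"] = tab["cov"]
        with pytest.raises(ValueError, match="singular"):
            ancova_pairwise(tab, "y", covariates=["cov", "cov2"])


class TestAnalysisSuite:
    def test_association_family_has_ten_members(self, default_cohort):
        table, _ = default_cohort
        _fits, results = run_analysis_suite(table, SuiteConfig())
        fam = results[results["family"] == "associations"]
        assert len(fam) == 10
        assert fam["p_holm"].notna().all()

    def test_disabling_variants_runs_core_only(self, default_cohort):
        table, _ = default_cohort
        fits, _ = run_analysis_suite(table, SuiteConfig(
            stage_models=False, ranked_models=False, converter_models=False,
            association_models=False))
        assert set(fits) == {"age_AT", "age_PM"}

    def test_fd_and_both_network_variants_add_designs(self, default_cohort):
        table, _ = default_cohort
        fits, _ = run_analysis_suite(table, SuiteConfig(
            fd_adjusted=True, both_networks=True, stage_models=False,
            ranked_models=False, converter_models=False,
            association_models=False))
        assert "both_networks_age" in fits
        age_fit = fits["age_AT"]
        assert "mean_fd" in list(age_fit.coefficients["term"])

    def test_missing_column_names_design(self, default_cohort):
        table, _ = default_cohort
        broken = table.drop(columns=["amyloid_suvr"])
        with pytest.raises(KeyError, match="assoc_AT_amyloid_suvr"):
            run_analysis_suite(broken, SuiteConfig())

    def test_null_effects_rarely_rejected_after_holm(self):
        """With all planted effects zero, the Holm-corrected association
        family should reject (almost) nowhere."""
        null_effects = {"intercept_at": 0.2, "intercept_pm": 0.35}
        reject_free = 0
        n_rep = 12
        for seed in range(n_rep):
            cfg = CohortConfig(effects=null_effects)
            table, _ = generate_cohort(cfg, seed=900 + seed)
            _fits, results = run_analysis_suite(table, SuiteConfig(
                age_models=False, stage_models=False, ranked_models=False,
                converter_models=False))
            fam = results[results["family"] == "associations"]
            reject_free += bool((fam["p_holm"] >= 0.05).all())
        assert reject_free >= n_rep - 2

    def test_recovers_planted_age_and_stage_signals(self, default_cohort):
        table, _ = default_cohort
        fits, results = run_analysis_suite(table, SuiteConfig())
        age_pm = fits["age_PM"].coef("age_years")
        assert age_pm["beta"] < 0 and age_pm["p"] < 0.01
        gam = fits["ranked_gam_AT"]
        assert gam.edf >= 1.0
        conv = fits["converter_AT"].coef("months_to_dementia")
        assert conv["beta"] < 0

    def test_sign_recovery_across_replicates(self):
        """Planted signs are recovered consistently at cohort scale."""
        wrong = 0
        for seed in range(10):
            table, _ = generate_cohort(CohortConfig(), seed=500 + seed)
            fits, _ = run_analysis_suite(table, SuiteConfig(
                stage_models=False, ranked_models=False,
                converter_models=False, association_models=False))
            if fits["age_PM"].coef("age_years")["beta"] >= 0:
                wrong += 1
            if fits["age_AT"].coef("age_years")["beta"] <= 0:
                wrong += 1
        assert wrong == 0
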