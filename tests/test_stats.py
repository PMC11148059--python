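"""Normality-gated two-group tests, correlations and the multivariable model."""

import numpy as np
import pandas as pd
import pytest

from octachorio.stats import (compare_groups, compare_sex, comparison_table,
                              correlate, correlation_table, multivariable_fit,
                              normality_gate, regression_table)
from octachorio.synthetic import default_cohort_config, generate_cohort

from _oracles import ols_normal_equations, two_sample_t_power
from conftest import two_group_frame


class TestNormalityGate:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(0)
        assert normality_gate(rng.normal(size=25), rng.normal(size=25))

    def test_lognormal_sample_fails(self):
        rng = np.random.default_rng(0)
        assert not normality_gate(rng.lognormal(0.0, 1.0, size=25))

    def test_constant_values_not_computable(self):
        with pytest.raises(ValueError):
            normality_gate(np.full(10, 3.0))

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            normality_gate(np.array([1.0, 2.0]))


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        # exact normal quantiles, so the gate routes to the t-test
        from scipy.stats import norm
        values = norm.ppf((np.arange(30) + 0.5) / 30)
        frame = two_group_frame(values, values)
        res = compare_groups(frame, "value")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)
        assert res.group_means["pop1"] == res.group_means["pop2"]

    def test_routes_to_mann_whitney_for_skewed_data(self):
        rng = np.random.default_rng(2)
        frame = two_group_frame(rng.lognormal(0, 1, 40), rng.lognormal(0.5, 1, 40))
        assert compare_groups(frame, "value").test == "mann-whitney"

    def test_mann_whitney_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(0, 1, 30)
        b = rng.lognormal(0.8, 1, 30)
        p_raw = compare_groups(two_group_frame(a, b), "value")
        p_cubed = compare_groups(two_group_frame(a**3, b**3), "value")
        assert p_raw.test == p_cubed.test == "mann-whitney"
        assert p_raw.p_value == pytest.approx(p_cubed.p_value, rel=1e-12)

    def test_amt6s_group_difference_power(self):
        """At the configured group means/SDs and n = 25/25, the two-group
        comparison of aMT6s is significant in ~96% of replicates; the
        Monte-Carlo rejection rate must agree with the analytic t-test power
        (the oracle) within 3 binomial SEs and exceed 0.9."""
        base = default_cohort_config()
        spec = base.variables["amt6s_pg_ml"]
        config = base.with_(variables={"amt6s_pg_ml": spec},
                            correlations_amt6s={})
        n_rep = 200
        hits = 0
        for i in range(n_rep):
            table = generate_cohort(config.with_(seed=10_000 + i))
            if compare_groups(table, "amt6s_pg_ml").p_value < 0.05:
                hits += 1
        rate = hits / n_rep
        power = two_sample_t_power(spec.mean["pop1"], spec.sd["pop1"],
                                   spec.mean["pop2"], spec.sd["pop2"], n=25)
        se = np.sqrt(power * (1 - power) / n_rep)
        assert power >= 0.95
        assert abs(rate - power) <= 3 * se
        assert rate > 0.9

    def test_sex_chi_square(self):
        frame = pd.DataFrame({"group": ["pop1"] * 20 + ["pop2"] * 20,
                              "sex": ["M", "F"] * 10 + ["M"] * 18 + ["F"] * 2})
        res = compare_sex(frame)
        assert res.test == "chi-square"
        assert res.p_value < 0.05


class TestCorrelate:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        frame = pd.DataFrame({"amt6s_pg_ml": x, "y": 2 * x + 1})
        res = correlate(frame, "y")
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p_value < 1e-10

    def test_pearson_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        y = x + rng.normal(scale=0.5, size=60)
        base = correlate(pd.DataFrame({"amt6s_pg_ml": x, "y": y}), "y",
                         method="pearson")
        scaled = correlate(pd.DataFrame({"amt6s_pg_ml": 3 * x + 7,
                                         "y": 0.1 * y - 2}), "y",
                           method="pearson")
        assert scaled.r == pytest.approx(base.r, rel=1e-12)

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=60)
        y = x + rng.normal(scale=0.5, size=60)
        base = correlate(pd.DataFrame({"amt6s_pg_ml": x, "y": y}), "y",
                         method="spearman")
        warped = correlate(pd.DataFrame({"amt6s_pg_ml": np.exp(x),
                                         "y": y**3}), "y", method="spearman")
        assert warped.r == pytest.approx(base.r, rel=1e-12)

    def test_gate_selects_spearman_for_lognormal(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(0, 1, 50)
        frame = pd.DataFrame({"amt6s_pg_ml": x,
                              "y": x + rng.normal(size=50)})
        assert correlate(frame, "y").method == "spearman"

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame({"amt6s_pg_ml": rng.normal(size=10_000),
                              "y": rng.normal(size=10_000)})
        assert abs(correlate(frame, "y").r) < 0.03

    def test_constant_variable_rejected(self):
        frame = pd.DataFrame({"amt6s_pg_ml": np.ones(10),
                              "y": np.arange(10.0)})
        with pytest.raises(ValueError):
            correlate(frame, "y")

    def test_too_few_pairs_rejected(self):
        frame = pd.DataFrame({"amt6s_pg_ml": [1.0, 2, 3], "y": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            correlate(frame, "y")


class TestMultivariableFit:
    def make_table(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "age": rng.normal(30, 3, n),
            "al_mm": rng.normal(24, 0.7, n),
            "ser_D": rng.normal(-0.4, 0.7, n),
            "amt6s_pg_ml": rng.normal(180, 75, n),
        })

    def test_pure_exposure_effect_recovered_exactly(self):
        table = self.make_table()
        table["outcome"] = 3.0 * table.amt6s_pg_ml
        res = multivariable_fit(table, "outcome")
        assert res.coefficients["amt6s_pg_ml"] == pytest.approx(3.0, abs=1e-10)
        for term in ("age", "al_mm", "ser_D", "intercept"):
            assert res.coefficients[term] == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        table = self.make_table(n=10, seed=3)
        rng = np.random.default_rng(4)
        table["outcome"] = (0.5 * table.age - 2.0 * table.al_mm
                            + 0.8 * table.ser_D + 0.01 * table.amt6s_pg_ml
                            + rng.normal(size=10))
        res = multivariable_fit(table, "outcome")
        beta = ols_normal_equations(
            table[["age", "al_mm", "ser_D", "amt6s_pg_ml"]].to_numpy(),
            table.outcome.to_numpy())
        fitted = [res.coefficients[t] for t in
                  ("intercept", "age", "al_mm", "ser_D", "amt6s_pg_ml")]
        np.testing.assert_allclose(fitted, beta, atol=1e-8)

    def test_rank_deficiency_rejected(self):
        table = self.make_table()
        table["ser_D"] = 2.0 * table.age  # collinear
        table["outcome"] = table.amt6s_pg_ml
        with pytest.raises(ValueError, match="rank"):
            multivariable_fit(table, "outcome")

    def test_exposure_only_effect_selective_significance(self):
        """Outcome driven by aMT6s alone: across replicates the exposure is
        significant and each null covariate is non-significant ≥90% of the
        time."""
        n_rep = 200
        sig_exposure = 0
        nonsig = {"age": 0, "al_mm": 0, "ser_D": 0}
        for i in range(n_rep):
            table = self.make_table(n=50, seed=100 + i)
            rng = np.random.default_rng(500 + i)
            table["outcome"] = 0.05 * table.amt6s_pg_ml + rng.normal(0, 5, 50)
            res = multivariable_fit(table, "outcome")
            sig_exposure += res.p_values["amt6s_pg_ml"] < 0.05
            for term in nonsig:
                nonsig[term] += res.p_values[term] > 0.05
        assert sig_exposure / n_rep >= 0.9
        for term, count in nonsig.items():
            assert count / n_rep >= 0.9, term


class TestReportTables:
    def test_tables_well_formed_on_default_cohort(self):
        table = generate_cohort(default_cohort_config(seed=0))
        comp = comparison_table(table, ["amt6s_pg_ml", "ct_fovea"])
        assert set(comp.variable) == {"amt6s_pg_ml", "ct_fovea"}
        assert ((comp.p >= 0) & (comp.p <= 1)).all()
        corr = correlation_table(table, ["ct_fovea", "cvi_3S"])
        assert ((corr.r >= -1) & (corr.r <= 1)).all()
        reg = regression_table(table, ["ct_fovea"])
        assert set(reg.term) == {"intercept", "age", "al_mm", "ser_D",
                                 "amt6s_pg_ml"}

    def test_bonferroni_inflates_p(self):
        table = generate_cohort(default_cohort_config(seed=1))
        raw = correlation_table(table, ["ct_fovea", "ct_2I", "ct_2T"])
        adj = correlation_table(table, ["ct_fovea", "ct_2I", "ct_2T"],
                                bonferroni=True)
        assert (adj.p >= raw.p - 1e-15).all()
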