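"""Synthetic cohort generator: marginals, outcomes, judgement, missingness."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import riskvalid as rv
from riskvalid.cohort import (
    CohortSpecError,
    apply_missingness,
    generate_judgement,
    generate_outcomes,
    generate_predictors,
    stage_rng,
)


@pytest.fixture(scope="module")
def big_predictors():
    spec = rv.default_cohort_spec(n=100_000, seed=101)
    return spec, generate_predictors(spec)


class TestPredictors:
    def test_male_marginal_recovered_at_large_n(self, big_predictors):
        _, table = big_predictors
        assert table["male"].mean() == pytest.approx(0.60, abs=0.005)

    def test_all_marginals_within_three_mc_standard_errors(self):
        spec = rv.default_cohort_spec(n=10_000, seed=55)
        table = generate_predictors(spec)
        for name, p in spec.predictor_marginals.items():
            se = np.sqrt(p * (1 - p) / spec.n)
            assert abs(table[name].mean() - p) <= 3 * se + 1e-12, name

    def test_age_moments_and_range(self, big_predictors):
        _, table = big_predictors
        age = table["age"]
        assert age.mean() == pytest.approx(25.0, abs=0.2)
        assert age.std() == pytest.approx(10.0, abs=0.2)
        assert age.min() >= 14.0 and age.max() <= 65.0

    def test_identity_correlation_gives_independence(self):
        spec = dataclasses.replace(
            rv.default_cohort_spec(n=50_000, seed=7), latent_correlation=None
        )
        table = generate_predictors(spec)
        corr = table[["previous_violent_crime", "previous_drug_misuse"]].corr().iloc[0, 1]
        assert abs(corr) < 0.02

    def test_block_correlation_induces_positive_association(self):
        spec = rv.default_cohort_spec(n=50_000, seed=7)
        table = generate_predictors(spec)
        corr = table[["previous_violent_crime", "previous_drug_misuse"]].corr().iloc[0, 1]
        assert corr > 0.05

    def test_zero_prevalence_gives_all_zeros(self):
        spec = rv.default_cohort_spec(n=500, seed=1)
        marg = dict(spec.predictor_marginals)
        marg["previous_violent_crime"] = 0.0
        spec = dataclasses.replace(spec, predictor_marginals=marg, latent_correlation=None)
        table = generate_predictors(spec)
        assert (table["previous_violent_crime"] == 0).all()

    def test_non_psd_correlation_rejected(self):
        spec = rv.default_cohort_spec(n=100, seed=1)
        k = len(spec.predictor_marginals) + 1
        bad = -np.ones((k, k)) + 2 * np.eye(k)  # eigenvalue k-2 on -1 vector side
        spec = dataclasses.replace(spec, latent_correlation=bad)
        with pytest.raises(CohortSpecError, match="positive semi-definite"):
            generate_predictors(spec)


class TestSolveIntercept:
    def test_closed_form_when_all_coefficients_zero(self):
        m = rv.RiskModel(
            predictors=(rv.PredictorDef("x", "binary", 0.0),), constant=0.0
        )
        table = pd.DataFrame({"x": np.zeros(100)})
        alpha = rv.solve_intercept(m, table, 0.11)
        assert alpha == pytest.approx(float(logit(0.11)), abs=1e-6)
        assert alpha == pytest.approx(-2.0907, abs=1e-4)

    def test_symmetric_predictors_give_zero_intercept(self):
        m = rv.RiskModel(
            predictors=(rv.PredictorDef("x", "continuous", 1.0),), constant=0.3
        )
        x = np.concatenate([np.linspace(-3, 3, 2001)])
        alpha = rv.solve_intercept(m, pd.DataFrame({"x": x}), 0.5)
        assert alpha == pytest.approx(0.0, abs=1e-8)

    def test_realised_prevalence_matches_target(self, model):
        spec = rv.default_cohort_spec(n=10_000, seed=31)
        table = generate_predictors(spec)
        alpha = rv.solve_intercept(model, table, 0.11)
        truth = dataclasses.replace(model, constant=alpha)
        y = generate_outcomes(truth, table, stage_rng(31, "outcome"))
        assert y.mean() == pytest.approx(0.11, abs=0.01)

    def test_invalid_target_rejected(self, model):
        table = pd.DataFrame({p.name: [0, 1] for p in model.predictors})
        with pytest.raises(ValueError):
            rv.solve_intercept(model, table, 1.5)


class TestOutcomes:
    def test_probability_zero_gives_no_events(self):
        m = rv.RiskModel(
            predictors=(rv.PredictorDef("x", "binary", 0.0),), constant=-1e3
        )
        table = pd.DataFrame({"x": np.zeros(500)})
        y = generate_outcomes(m, table, np.random.default_rng(0))
        assert (y == 0).all()

    def test_fair_coin_prevalence(self):
        m = rv.RiskModel(
            predictors=(rv.PredictorDef("x", "binary", 0.0),), constant=0.0
        )
        table = pd.DataFrame({"x": np.zeros(10_000)})
        y = generate_outcomes(m, table, np.random.default_rng(12))
        assert y.mean() == pytest.approx(0.5, abs=0.015)


class TestJudgement:
    def test_perfect_judgement_reproduces_outcome(self):
        y = np.array([0, 1, 1, 0, 1])
        flag = generate_judgement(y, 1.0, 1.0, np.random.default_rng(0))
        assert np.array_equal(flag, y)

    def test_zero_sensitivity_perfect_specificity_flags_nothing(self):
        y = np.array([0, 1] * 50)
        flag = generate_judgement(y, 0.0, 1.0, np.random.default_rng(0))
        assert (flag == 0).all()

    def test_flagged_fraction_matches_total_probability(self):
        # P(flag) = sens*prev + (1-spec)*(1-prev) = 0.40*0.11 + 0.11*0.89
        rng = np.random.default_rng(77)
        y = (rng.random(100_000) < 0.11).astype(int)
        flag = generate_judgement(y, 0.40, 0.89, np.random.default_rng(78))
        expected = 0.40 * y.mean() + 0.11 * (1 - y.mean())
        assert flag.mean() == pytest.approx(expected, abs=0.01)
        assert flag.mean() == pytest.approx(0.142, abs=0.01)


class TestMissingness:
    def test_zero_rates_leave_table_unchanged(self, small_cohort):
        full = small_cohort.table.drop(columns=["id"]).dropna()
        out = apply_missingness(full, {}, np.random.default_rng(0))
        pd.testing.assert_frame_equal(out, full)

    @pytest.mark.parametrize(
        "variable,rate",
        [("parent_violent_crime", 0.43), ("lower_secondary_education", 0.14)],
    )
    def test_realised_missing_fraction_matches_target(self, model, variable, rate):
        spec = rv.default_cohort_spec(n=30_000, seed=19)
        table = generate_predictors(spec)
        table["outcome"] = generate_outcomes(
            dataclasses.replace(model, constant=rv.solve_intercept(model, table, 0.11)),
            table,
            stage_rng(19, "outcome"),
        )
        masked = apply_missingness(table, {variable: rate}, stage_rng(19, "missingness"))
        assert masked[variable].isna().mean() == pytest.approx(rate, abs=0.01)

    def test_outcome_rate_rejected(self, small_cohort):
        full = small_cohort.table.dropna()
        with pytest.raises(CohortSpecError):
            apply_missingness(full, {"outcome": 0.1}, np.random.default_rng(0))

    def test_missingness_is_mar_given_drivers(self, model):
        """Masking must not depend on the masked value beyond the drivers:
        regressing the missingness indicator on the generator-truth value
        plus the drivers shows no effect of the value."""
        import statsmodels.api as sm

        spec = rv.default_cohort_spec(n=20_000, seed=43)
        table = generate_predictors(spec)
        table["outcome"] = generate_outcomes(
            dataclasses.replace(model, constant=rv.solve_intercept(model, table, 0.11)),
            table,
            stage_rng(43, "outcome"),
        )
        truth = table["previous_drug_misuse"].to_numpy(dtype=float)
        masked = apply_missingness(
            table, {"previous_drug_misuse": 0.3}, stage_rng(43, "missingness")
        )
        miss = masked["previous_drug_misuse"].isna().astype(float).to_numpy()
        X = sm.add_constant(
            np.column_stack(
                [
                    truth,
                    table["male"].to_numpy(dtype=float),
                    table["age"].to_numpy(dtype=float),
                    table["outcome"].to_numpy(dtype=float),
                ]
            )
        )
        fit = sm.GLM(miss, X, family=sm.families.Binomial()).fit()
        assert abs(fit.tvalues[1]) < 3.0  # truth column has no detectable effect


class TestDeterminismAndIO:
    def test_same_spec_and_seed_byte_identical_csv(self, tmp_path):
        spec = rv.default_cohort_spec(n=300, seed=9)
        for name in ("a.csv", "b.csv"):
            rv.write_cohort(rv.generate_cohort(spec), tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_roundtrip_preserves_values_and_missingness(self, tmp_path, small_cohort):
        rv.write_cohort(small_cohort, tmp_path / "c.csv")
        again = rv.read_cohort(tmp_path / "c.csv")
        assert len(again.table) == small_cohort.n
        for col in small_cohort.table.columns:
            a = small_cohort.table[col]
            b = again.table[col]
            assert a.isna().equals(b.isna()), col
            np.testing.assert_allclose(
                a.dropna().to_numpy(dtype=float),
                b.dropna().to_numpy(dtype=float),
                atol=1e-6,
            )
        assert (tmp_path / "c.provenance.json").exists()

    def test_ids_unique(self, small_cohort):
        assert small_cohort.table["id"].is_unique

    def test_outcome_and_judgement_never_missing(self, small_cohort):
        assert not small_cohort.table["outcome"].isna().any()
        assert not small_cohort.table["judgement"].isna().any()
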