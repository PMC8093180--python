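"""FIML estimation: likelihood correctness, recovery, SEs, invariances."""

import math

import numpy as np
import pandas as pd
import pytest

from pgsnurture import (
    FitSpec,
    GeneticNurtureModel,
    ModelParams,
    closed_form_model0,
    equilibrium_state,
    fit_assumed_a,
    implied_covariance,
)
from pgsnurture.estimate import loglik_from_cov

M2_TRUTH = ModelParams(delta=0.3, a=0.55, f=0.12, r_mate=0.3, V_eps=0.4)


def implied_cov(params, model, with_parents=False):
    state = equilibrium_state(params, model=model)
    return implied_covariance(state, params, with_parents=with_parents).cov


class TestLoglik:
    def test_truth_beats_perturbed_f(self, no_am_table):
        model = GeneticNurtureModel(no_am_table, model="m0", se_method="none")
        truth = ModelParams(delta=0.5, f=0.2, V_eps=0.545)
        worse = ModelParams(delta=0.5, f=0.3, V_eps=0.545)
        assert model.loglik(truth) > model.loglik(worse)

    def test_single_variable_record_is_univariate_normal(self):
        df = pd.DataFrame(
            {"T_p": [np.nan] * 4, "NT_p": np.nan, "T_m": np.nan, "NT_m": np.nan,
             "Y_o": [1.0, -1.0, 2.0, -2.0]}
        )
        model = GeneticNurtureModel(df, model="m0", se_method="none")
        p = ModelParams(delta=0.5, f=0.0, V_eps=0.5)
        vy = equilibrium_state(p, model="m0").V_Y
        y = df.Y_o - df.Y_o.mean()
        expected = sum(
            -0.5 * (math.log(2 * math.pi * vy) + yi**2 / vy) for yi in y
        )
        assert model.loglik(p) == pytest.approx(expected, rel=1e-12)

    def test_covariance_entry_point_matches_records(self, no_am_table):
        sub = no_am_table.head(2000)
        rec = GeneticNurtureModel(sub, model="m0", se_method="none")
        X = sub[list(rec.variables)].to_numpy()
        Xc = X - X.mean(0)
        S = Xc.T @ Xc / len(Xc)
        spec = FitSpec(model="m0", se_method="none")
        for f in (0.1, 0.25):
            p = ModelParams(delta=0.5, f=f, V_eps=0.545)
            assert loglik_from_cov(p, S, len(Xc), spec) == pytest.approx(
                rec.loglik(p), rel=1e-12
            )

    def test_invalid_region_returns_minus_inf(self, no_am_table):
        model = GeneticNurtureModel(no_am_table, model="m0", se_method="none")
        assert model.loglik(ModelParams(delta=0.5, f=0.9, V_eps=0.5)) == -np.inf


class TestExactMomentRecovery:
    """Fitting the model-implied covariance itself must return the truth."""

    @pytest.mark.parametrize(
        "model, params, with_parents",
        [
            ("m0", ModelParams(delta=0.5, f=0.2, V_eps=0.545), False),
            ("m1", ModelParams(delta=0.6, f=0.15, r_mate=0.25, V_eps=0.5), False),
            ("m2", M2_TRUTH, True),
        ],
    )
    def test_recovery(self, model, params, with_parents):
        S = implied_cov(params, model, with_parents)
        m = GeneticNurtureModel.from_covariance(
            S, 20_000, model=model, se_method="none",
            use_parental_phenotypes=with_parents,
        )
        res = m.fit()
        assert res.params["delta"] == pytest.approx(params.delta, abs=2e-3)
        assert res.params["f"] == pytest.approx(params.f, abs=2e-3)
        assert res.params["V_eps"] == pytest.approx(params.V_eps, abs=2e-3)
        if model != "m0":
            assert res.params["r_mate"] == pytest.approx(params.r_mate or 0.0, abs=2e-3)
        if model == "m2":
            assert res.params["a"] == pytest.approx(params.a, abs=5e-3)
        truth_state = equilibrium_state(params, model=model)
        assert res.derived["V_F"] == pytest.approx(truth_state.V_F, abs=2e-3)

    def test_assumed_a_with_correct_h2_matches_full_fit(self):
        # PGS-partial heritability; base h2 = delta^2 + a^2 under base scaling
        S5 = implied_cov(M2_TRUTH, "m2", with_parents=False)
        h2 = M2_TRUTH.delta**2 + M2_TRUTH.a**2
        m = GeneticNurtureModel.from_covariance(
            S5, 20_000, model="m2", assumed_base_h2=h2,
            use_parental_phenotypes=False, se_method="none",
        )
        res = m.fit()
        truth_state = equilibrium_state(M2_TRUTH, model="m2")
        assert res.params["delta"] == pytest.approx(M2_TRUTH.delta, abs=3e-3)
        assert res.params["a"] == pytest.approx(M2_TRUTH.a, abs=5e-3)
        assert res.derived["V_F"] == pytest.approx(truth_state.V_F, abs=3e-3)

    def test_assumed_a_too_high_biases_vf_down(self):
        S5 = implied_cov(M2_TRUTH, "m2", with_parents=False)
        h2 = M2_TRUTH.delta**2 + M2_TRUTH.a**2
        truth_vf = equilibrium_state(M2_TRUTH, model="m2").V_F
        m = GeneticNurtureModel.from_covariance(
            S5, 20_000, model="m2", assumed_base_h2=min(h2 + 0.1, 0.99),
            use_parental_phenotypes=False, se_method="none",
        )
        res = m.fit()
        assert res.derived["V_F"] < truth_vf  # sign of bias, not magnitude

    def test_assumed_a_reduces_to_m1_without_latent(self):
        p1 = ModelParams(delta=0.6, f=0.15, r_mate=0.25, V_eps=0.5)
        S = implied_cov(p1, "m1")
        res = GeneticNurtureModel.from_covariance(
            S, 20_000, model="m2", assumed_base_h2=p1.delta**2,
            use_parental_phenotypes=False, se_method="none",
        ).fit()
        res1 = GeneticNurtureModel.from_covariance(
            S, 20_000, model="m1", se_method="none"
        ).fit()
        assert res.params["a"] == pytest.approx(0.0, abs=0.02)
        assert res.derived["V_F"] == pytest.approx(res1.derived["V_F"], abs=2e-3)


class TestSimulatedDataFits:
    def test_model0_matches_closed_form(self, no_am_table):
        res = GeneticNurtureModel(no_am_table, model="m0", se_method="none").fit()
        th_nt = np.cov(no_am_table.Y_o, no_am_table.NT_p)[0, 1] + \
            np.cov(no_am_table.Y_o, no_am_table.NT_m)[0, 1]
        th_t = np.cov(no_am_table.Y_o, no_am_table.T_p)[0, 1] + \
            np.cov(no_am_table.Y_o, no_am_table.T_m)[0, 1]
        cf = closed_form_model0(th_nt, th_t, no_am_table.Y_o.var())
        # just-identified model: ML equals the moment solution
        assert res.params["f"] == pytest.approx(cf.f, abs=5e-3)
        assert res.derived["w"] == pytest.approx(cf.w, abs=5e-3)
        assert res.derived["V_F"] == pytest.approx(cf.V_F, abs=5e-3)

    def test_model0_recovers_truth_within_3se(self, no_am_table):
        res = GeneticNurtureModel(no_am_table, model="m0").fit()
        assert abs(res.params["f"] - 0.2) < 3 * res.bse["f"]
        truth_vf = equilibrium_state(
            ModelParams(delta=0.5, f=0.2, V_eps=0.545), model="m0"
        ).V_F
        assert abs(res.derived["V_F"] - truth_vf) < 3 * res.derived_bse["V_F"]

    def test_model2_unbiased_model1_biased_with_partial_pgs(self, am_m2_table):
        truth = equilibrium_state(M2_TRUTH, model="m2")
        res2 = GeneticNurtureModel(am_m2_table, model="m2").fit()
        assert abs(res2.derived["V_F"] - truth.V_F) < 3 * res2.derived_bse["V_F"]
        res1 = GeneticNurtureModel(am_m2_table, model="m1", se_method="none").fit()
        assert res1.derived["V_F"] > truth.V_F  # upward bias from unmodelled i

    def test_scaling_convention_invariance(self, am_m2_pops):
        from pgsnurture import extract_family_table

        base = extract_family_table(am_m2_pops, scaling="base_standardized")
        full = extract_family_table(am_m2_pops, scaling="full_pgs_standardized_now")
        res_b = GeneticNurtureModel(base, model="m2", scaling="base_standardized",
                                    se_method="none").fit()
        res_f = GeneticNurtureModel(full, model="m2",
                                    scaling="full_pgs_standardized_now",
                                    se_method="none").fit()
        # f, V_F, V_A are scale-free; delta is not
        assert res_f.params["f"] == pytest.approx(res_b.params["f"], rel=0.02)
        assert res_f.derived["V_F"] == pytest.approx(res_b.derived["V_F"], rel=0.05, abs=5e-3)
        assert res_f.derived["V_A"] == pytest.approx(res_b.derived["V_A"], rel=0.02)


class TestStandardErrors:
    def test_se_of_vf_grows_as_delta_shrinks(self):
        """Lower PGS predictive power inflates the V_F standard error."""
        ses = []
        for delta in (0.6, 0.4, 0.2):
            p = ModelParams(delta=delta, f=0.2, V_eps=1.0 - 2 * delta**2 * 0.5)
            S = implied_cov(p, "m0")
            res = GeneticNurtureModel.from_covariance(S, 10_000, model="m0").fit()
            ses.append(res.derived_bse["V_F"])
        assert ses[0] < ses[1] < ses[2]

    def test_bootstrap_and_hessian_agree(self, no_am_table):
        sub = no_am_table.head(8000)
        res = GeneticNurtureModel(sub, model="m0", n_boot=80, seed=7).fit()
        hess = res.bse.copy()
        res._compute_se("bootstrap")
        boot = res.bse
        for name in hess.index:
            assert boot[name] == pytest.approx(hess[name], rel=0.35)

    def test_zero_variance_input_rejected(self):
        df = pd.DataFrame({
            "T_p": np.zeros(100), "NT_p": np.random.default_rng(0).normal(size=100),
            "T_m": np.random.default_rng(1).normal(size=100),
            "NT_m": np.random.default_rng(2).normal(size=100),
            "Y_o": np.random.default_rng(3).normal(size=100),
        })
        with pytest.raises(ValueError, match="zero variance"):
            GeneticNurtureModel(df, model="m0")


class TestSpecValidation:
    def test_m2_without_parents_needs_h2(self):
        with pytest.raises(ValueError, match="assumed_base_h2"):
            FitSpec(model="m2", use_parental_phenotypes=False)

    def test_parents_only_for_m2(self, no_am_table):
        with pytest.raises(ValueError, match="Model 2"):
            GeneticNurtureModel(no_am_table, model="m0", use_parental_phenotypes=True)

    def test_assumed_h2_too_low_raises(self, am_m2_table):
        from pgsnurture.estimate import FitError

        with pytest.raises((FitError, ValueError)):
            fit_assumed_a(am_m2_table, base_h2=0.05, se_method="none")


def test_summary_and_dict_roundtrip(no_am_table):
    res = GeneticNurtureModel(no_am_table.head(3000), model="m0", se_method="none").fit()
    text = res.summary()
    assert "delta" in text and "V_F" in text
    d = res.to_dict()
    assert d["model"] == "m0"
    assert set(d["estimates"]) == {"delta", "f", "V_eps"}
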