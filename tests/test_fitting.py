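import math

import numpy as np
import pytest

from rnakinetics import (
    ConfigurationError,
    DomainError,
    ExpressionProfile,
    FitError,
    Form,
    KineticModel,
    NoiseModel,
    RateFunction,
    RegulatoryClass,
    chi_squared,
    confidence_intervals,
    fit,
    goodness_of_fit,
    random_model,
    refine,
    select_model,
    simulate_profile,
)
from rnakinetics.fitting import OPTIMIZER_TOL, embed_model

from conftest import exact_profile


class TestRegulatoryClass:
    def test_field_codes(self):
        # "sd": variable synthesis, constant processing, variable degradation
        cls = RegulatoryClass(Form.SIGMOID, Form.CONSTANT, Form.SIGMOID)
        assert cls.code == "sd"
        # "sp": variable synthesis and processing, constant degradation
        assert RegulatoryClass(Form.SIGMOID, Form.SIGMOID, Form.CONSTANT).code == "sp"
        assert RegulatoryClass(Form.CONSTANT, Form.CONSTANT, Form.CONSTANT).code == "no-reg"

    def test_from_code_round_trip(self):
        for code in ("no-reg", "s", "p", "d", "sp", "sd", "pd", "spd"):
            assert RegulatoryClass.from_code(code).code == code

    def test_from_code_with_impulse(self):
        cls = RegulatoryClass.from_code("sd", variable_form="impulse")
        assert cls.forms == (Form.IMPULSE, Form.CONSTANT, Form.IMPULSE)
        assert cls.n_free_params == 13

    @pytest.mark.parametrize("bad", ["ds", "x", "ss", "sdp"])
    def test_invalid_codes_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            RegulatoryClass.from_code(bad)

    def test_embedding_preserves_time_course(self):
        model = KineticModel(
            RateFunction.sigmoid(2.0, 6.0, 4.0, 1.0),
            RateFunction.constant(1.0),
            RateFunction.constant(0.5),
        )
        target = RegulatoryClass(Form.IMPULSE, Form.SIGMOID, Form.CONSTANT)
        emb = embed_model(model, target, 0.0, 16.0)
        ts = np.linspace(0, 16, 50)
        for orig, new in zip(model.rates, emb.rates):
            np.testing.assert_allclose(new(ts), orig(ts), rtol=1e-12)


class TestChiSquared:
    def test_perfect_fit_is_zero(self, const_model, grid):
        prof = exact_profile(const_model, grid)
        assert chi_squared(const_model, prof) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_off_by_one_sd_of_mean(self, const_model):
        # steady state P=2, M=4, S=2; premature observed 1 sd-of-mean low
        sd, n_rep = 0.4, 4
        prof = ExpressionProfile(
            times=[0.0],
            premature_mean=[2.0 - sd / math.sqrt(n_rep)],
            premature_sd=[sd],
            mature_mean=[4.0],
            mature_sd=[0.4],
            synthesis_mean=[2.0],
            synthesis_sd=[0.2],
            n_replicates=n_rep,
        )
        assert chi_squared(const_model, prof) == pytest.approx(1.0, rel=1e-9)

    def test_hand_summed_toy_profile(self, const_model):
        # predictions are flat (P=2, M=4); sum the weighted residuals by hand
        prof = ExpressionProfile(
            times=[0.0, 1.0, 2.0],
            premature_mean=[1.8, 2.0, 2.4],
            premature_sd=[0.2, 0.2, 0.4],
            mature_mean=[4.4, 3.6, 4.0],
            mature_sd=[0.4, 0.8, 0.4],
            n_replicates=2,
        )
        expected = (
            2 * ((0.2 / 0.2) ** 2 + 0.0 + (0.4 / 0.4) ** 2)  # premature
            + 2 * ((0.4 / 0.4) ** 2 + (0.4 / 0.8) ** 2 + 0.0)  # mature
        )
        assert chi_squared(const_model, prof) == pytest.approx(expected, rel=1e-9)

    def test_invariant_under_joint_rescaling(self, grid):
        # scaling k1 scales all species linearly; rescaled data+model match
        scale = 7.3
        base = KineticModel(
            RateFunction.sigmoid(2.0, 4.0, 4.0, 1.0),
            RateFunction.constant(1.0),
            RateFunction.constant(0.5),
        )
        scaled = KineticModel(
            RateFunction.sigmoid(2.0 * scale, 4.0 * scale, 4.0, 1.0),
            RateFunction.constant(1.0),
            RateFunction.constant(0.5),
        )
        prof, _ = simulate_profile(base, times=grid, seed=5)
        prof_scaled = ExpressionProfile(
            times=prof.times,
            premature_mean=prof.premature_mean * scale,
            premature_sd=prof.premature_sd * scale,
            mature_mean=prof.mature_mean * scale,
            mature_sd=prof.mature_sd * scale,
            synthesis_mean=prof.synthesis_mean * scale,
            synthesis_sd=prof.synthesis_sd * scale,
            n_replicates=prof.n_replicates,
        )
        assert chi_squared(scaled, prof_scaled) == pytest.approx(
            chi_squared(base, prof), rel=1e-9
        )


class TestGoodnessOfFit:
    def test_p_near_maximum_at_the_chi2_median(self):
        # independent CDF: numerically integrate the chi-squared density
        dof, x0 = 10, 9.34
        x = np.linspace(1e-9, x0, 200001)
        dens = x ** (dof / 2 - 1) * np.exp(-x / 2) / (2 ** (dof / 2) * math.gamma(dof / 2))
        F_ref = np.trapezoid(dens, x)
        assert 0.4 < F_ref < 0.6  # x0 is near the distribution's median
        p, _ = goodness_of_fit(x0, dof, 3)
        assert p == pytest.approx(2 * min(F_ref, 1 - F_ref), rel=1e-4)
        assert p > 0.5

    def test_too_good_fit_is_flagged(self):
        p, _ = goodness_of_fit(0.0, 5, 3)
        assert p == 0.0

    def test_aic_penalizes_extra_parameters(self):
        # same chi2, constant (1 param) vs sigmoid (4 params) on one rate
        _, aic_const = goodness_of_fit(10.0, 20, 1 + 1 + 1)
        _, aic_sig = goodness_of_fit(10.0, 17, 4 + 1 + 1)
        assert aic_sig - aic_const == pytest.approx(6.0)

    def test_dof_below_one_rejected(self):
        with pytest.raises(DomainError):
            goodness_of_fit(1.0, 0, 3)


class TestFit:
    def test_steady_state_inversion_is_exact(self):
        prof = ExpressionProfile(
            times=[0.0],
            premature_mean=[2.5],
            premature_sd=[0.2],
            mature_mean=[10.0],
            mature_sd=[0.5],
            synthesis_mean=[4.0],
            synthesis_sd=[0.3],
            n_replicates=3,
        )
        res = fit(prof, RegulatoryClass.from_code("no-reg"))
        assert res.parameters["k1.h0"] == 4.0
        assert res.parameters["k2.h0"] == 4.0 / 2.5
        assert res.parameters["k3.h0"] == 4.0 / 10.0
        assert res.objective == 0.0

    def test_noise_free_constant_recovery_to_four_significant_digits(self, grid):
        truth = KineticModel(
            RateFunction.constant(3.0),
            RateFunction.constant(1.2),
            RateFunction.constant(0.4),
        )
        prof = exact_profile(truth, grid)
        res = fit(prof, RegulatoryClass.from_code("no-reg"), seed=0)
        assert res.objective < 1e-6
        for name, true_val in (("k1.h0", 3.0), ("k2.h0", 1.2), ("k3.h0", 0.4)):
            assert res.parameters[name] == pytest.approx(true_val, rel=1e-4)

    def test_sp_model_recovery_with_noise(self, grid):
        truth = KineticModel(
            RateFunction.sigmoid(2.0, 6.0, 4.0, 1.0),
            RateFunction.sigmoid(1.0, 3.0, 6.0, 1.0),
            RateFunction.constant(0.5),
        )
        prof, _ = simulate_profile(
            truth, times=grid, noise=NoiseModel(level=0.05), seed=11
        )
        res = fit(prof, RegulatoryClass.from_code("sp"), seed=11)
        for name, true_val in (
            ("k1.h0", 2.0), ("k1.h1", 6.0), ("k2.h0", 1.0), ("k2.h1", 3.0), ("k3.h0", 0.5),
        ):
            assert res.parameters[name] == pytest.approx(true_val, rel=0.15)

    def test_too_many_parameters_for_data(self):
        prof = ExpressionProfile(
            times=[0.0, 1.0],
            premature_mean=[1.0, 1.0],
            premature_sd=[0.1, 0.1],
            mature_mean=[1.0, 1.0],
            mature_sd=[0.1, 0.1],
        )
        with pytest.raises(FitError, match="too complex"):
            fit(prof, RegulatoryClass.from_code("spd"))

    def test_same_seed_gives_bit_identical_results(self, grid):
        truth = random_model(RegulatoryClass.from_code("s"), seed=3)
        prof, _ = simulate_profile(truth, times=grid, seed=4)
        a = fit(prof, RegulatoryClass.from_code("s"), seed=9)
        b = fit(prof, RegulatoryClass.from_code("s"), seed=9)
        assert a.objective == b.objective
        assert a.parameters == b.parameters


class TestRefine:
    @pytest.fixture
    def converged(self, grid, const_model):
        prof = exact_profile(const_model, grid)
        return prof, fit(prof, RegulatoryClass.from_code("no-reg"), seed=0)

    def test_refining_a_converged_fit_is_a_fixed_point(self, converged):
        prof, res = converged
        res2 = refine(res, prof, extra_iter=500)
        assert abs(res2.objective - res.objective) < 1e-10

    def test_zero_extra_iterations_is_a_no_op(self, converged):
        prof, res = converged
        assert refine(res, prof, extra_iter=0) is res

    def test_under_iterated_fit_improves(self, grid):
        truth = KineticModel(
            RateFunction.sigmoid(2.0, 6.0, 4.0, 1.0),
            RateFunction.constant(1.0),
            RateFunction.constant(0.5),
        )
        prof, _ = simulate_profile(truth, times=grid, noise=NoiseModel(level=0.05), seed=2)
        rough = fit(prof, RegulatoryClass.from_code("s"), max_iter=10, n_starts=2, seed=2)
        polished = refine(rough, prof, extra_iter=3000)
        assert polished.objective < rough.objective

    def test_class_mismatch_rejected(self, converged):
        prof, res = converged
        with pytest.raises(ConfigurationError):
            refine(res, prof, cls=RegulatoryClass.from_code("s"))


class TestSelectModel:
    def test_true_class_ranks_first_on_noise_free_data(self, grid):
        truth = KineticModel(
            RateFunction.sigmoid(3.0, 9.0, 4.0, 1.0),
            RateFunction.constant(1.0),
            RateFunction.sigmoid(0.5, 1.5, 6.0, 1.0),
        )
        prof = exact_profile(truth, grid)
        classes = [RegulatoryClass.from_code(c) for c in
                   ("no-reg", "s", "p", "d", "sp", "sd", "pd", "spd")]
        ranked = select_model(prof, classes, seed=1, n_starts=3)
        assert ranked[0].regulatory_class.code == "sd"

    def test_nested_chi2_dominance(self, grid):
        truth = random_model(RegulatoryClass.from_code("s"), seed=6)
        prof, _ = simulate_profile(truth, times=grid, seed=7)
        chain = [RegulatoryClass.from_code(c) for c in ("no-reg", "s", "sp", "spd")]
        ranked = select_model(prof, chain, seed=8, n_starts=3)
        by_k = sorted(ranked, key=lambda r: r.n_free_params)
        for simpler, richer in zip(by_k[:-1], by_k[1:]):
            assert richer.objective <= simpler.objective + OPTIMIZER_TOL

    def test_duplicate_candidates_tie_break_deterministically(self, grid, const_model):
        prof = exact_profile(const_model, grid)
        cls = RegulatoryClass.from_code("no-reg")
        ranked = select_model(prof, [cls, cls], seed=0)
        assert len(ranked) == 2
        assert ranked[0].aic == ranked[1].aic
        assert ranked[0].parameters == ranked[1].parameters


class TestConfidenceIntervals:
    def test_noise_free_intervals_collapse(self, grid, const_model):
        # effectively noise-free: many replicates shrink the sd of the mean
        prof = exact_profile(const_model, grid, rel_sd=0.01, n_replicates=10000)
        res = fit(prof, RegulatoryClass.from_code("no-reg"), seed=0)
        ci = confidence_intervals(res, prof)
        for name, interval in ci.items():
            est = res.parameters[name]
            assert (interval.upper - interval.lower) / est < 1e-3
            assert interval.lower <= est <= interval.upper

    def test_flat_likelihood_flagged_unbounded(self, grid, const_model):
        # gigantic variances: no parameter is constrained by the data
        prof = exact_profile(const_model, grid, rel_sd=1e6, n_replicates=2)
        res = fit(prof, RegulatoryClass.from_code("no-reg"), seed=0)
        ci = confidence_intervals(res, prof, parameters=["k1.h0"])
        interval = ci["k1.h0"]
        assert not interval.lower_bounded
        assert not interval.upper_bounded

    def test_non_converged_fit_refused(self, grid, const_model):
        prof = exact_profile(const_model, grid)
        res = fit(prof, RegulatoryClass.from_code("no-reg"), seed=0)
        res.converged = False
        with pytest.raises(FitError):
            confidence_intervals(res, prof)
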