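"""Objective algebra, MAP priors, criteria identities, and fit recovery."""

import numpy as np
import pandas as pd
import pytest

import il10pkpd as m
from il10pkpd import reference as R
from il10pkpd.estimation import (
    Prior,
    TimeCourseModel,
    half_life_from_lifespan,
    map_objective,
    neg2ll,
    turnover_half_life,
    weights,
)
from il10pkpd.models import MonkeyIL18Model, MouseIL18Model
from il10pkpd.synthetic import (
    gen_monkey_studies,
    gen_mouse_pkpd_study,
    monkey_study_design,
    mouse_ct26_design,
)
from il10pkpd.dosing import SimGrid

from conftest import single_ip_regimen


class TestNeg2LL:
    def test_equal_residuals_match_hand_formula(self):
        y = np.array([10.0, 12.0, 9.0, 11.0, 13.0])
        r = 0.5
        value = neg2ll(y - r, y, "equal")
        n = y.size
        assert value == pytest.approx(n * np.log(2 * np.pi * r**2) + n)

    def test_perfect_fit_is_floored_not_infinite(self):
        y = np.linspace(1, 5, 5)
        value = neg2ll(y, y, "equal")
        assert np.isfinite(value) and value < -1000.0

    def test_inv_y2_scaling_identity(self):
        """Scaling data and predictions by c shifts the 1/y^2 objective by
        exactly 2 n ln c (the profiled variance term is scale-invariant),
        so parameter estimates are unchanged by unit changes."""
        rng = np.random.default_rng(0)
        y = rng.uniform(1, 10, 20)
        yhat = y * rng.uniform(0.9, 1.1, 20)
        c = 37.0
        base = neg2ll(yhat, y, "inv_y2")
        scaled = neg2ll(c * yhat, c * y, "inv_y2")
        assert scaled - base == pytest.approx(2 * y.size * np.log(c), rel=1e-9)

    def test_zero_observation_rejected_for_inverse_weighting(self):
        y = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            neg2ll(y, y, "inv_y")

    def test_weight_schemes(self):
        y = np.array([2.0, 4.0])
        assert np.allclose(weights(y, "equal"), [1, 1])
        assert np.allclose(weights(y, "inv_y"), [0.5, 0.25])
        assert np.allclose(weights(y, "inv_y2"), [0.25, 0.0625])
        with pytest.raises(ValueError):
            weights(y, "1/y")


class TestMAPObjective:
    def test_no_priors_equals_neg2ll(self):
        assert map_objective(12.3, {"a": 1.0}, ()) == 12.3

    def test_estimate_at_prior_mean_adds_nothing(self):
        pr = Prior("kout", 0.043, 0.022)
        assert map_objective(5.0, {"kout": 0.043}, [pr]) == 5.0

    def test_one_sd_deviation_adds_one(self):
        pr = Prior("kout", 0.043, 0.022)
        assert map_objective(5.0, {"kout": 0.065}, [pr]) == pytest.approx(6.0)

    def test_prior_on_unknown_parameter_raises(self):
        with pytest.raises(KeyError):
            map_objective(0.0, {"a": 1.0}, [Prior("b", 0.0, 1.0)])


class TestHalfLives:
    @pytest.mark.parametrize("kout, expected", [
        (0.064, 10.83), (0.014, 49.5), (0.693, 1.0),
    ])
    def test_turnover_half_life(self, kout, expected):
        assert turnover_half_life(kout) == pytest.approx(expected, rel=1e-2)

    def test_nonpositive_kout_raises(self):
        with pytest.raises(ValueError):
            turnover_half_life(0.0)

    def test_lifespan_conversion(self):
        assert half_life_from_lifespan(6.5) == pytest.approx(4.5045)


class _LineModel(TimeCourseModel):
    """y = a + b t; cheap model for optimizer/criteria plumbing tests."""

    def predict(self, params):
        t = self.data["time_h"].to_numpy()
        return params["a"] + params["b"] * t


def _line_data(a=2.0, b=0.5, n=20, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 10, n)
    y = a + b * t + rng.normal(0, noise, n)
    return pd.DataFrame({"time_h": t, "value": y})


class TestFitMachinery:
    def test_criteria_identities(self):
        data = _line_data()
        model = _LineModel(data, {"a": 1.0, "b": 1.0}, ["a", "b"])
        res = model.fit(n_starts=2)
        assert res.aic == pytest.approx(res.neg2ll + 2 * 2, abs=1e-12)
        assert res.sbic == pytest.approx(res.neg2ll + 2 * np.log(res.nobs), abs=1e-12)

    def test_trace_is_monotone_decreasing(self):
        model = _LineModel(_line_data(), {"a": 1.0, "b": 1.0}, ["a", "b"])
        res = model.fit(n_starts=2)
        assert np.all(np.diff(res.trace) <= 0)

    def test_tight_prior_pins_estimate(self):
        prior = Prior("b", 0.9, 1e-7)
        model = _LineModel(_line_data(), {"a": 1.0, "b": 1.0}, ["a", "b"],
                           priors=[prior])
        res = model.fit(n_starts=2)
        assert res.params["b"] == pytest.approx(0.9, abs=1e-4)

    def test_prior_on_fixed_parameter_rejected(self):
        with pytest.raises(ValueError):
            _LineModel(_line_data(), {"a": 1.0, "b": 1.0}, ["a"],
                       priors=[Prior("b", 1.0, 1.0)])

    def test_free_parameter_without_start_rejected(self):
        with pytest.raises(ValueError):
            _LineModel(_line_data(), {"a": 1.0}, ["a", "b"])

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            _LineModel(_line_data().iloc[:0], {"a": 1.0}, ["a"])

    def test_summary_lists_free_and_fixed(self):
        model = _LineModel(_line_data(), {"a": 1.0, "b": 0.5}, ["a"])
        res = model.fit(n_starts=1)
        text = res.summary()
        assert "a" in text and "(fixed)" in text and "-2LL" in text

    def test_standard_errors_scale_with_noise(self):
        se = []
        for noise in (0.05, 0.5):
            model = _LineModel(_line_data(noise=noise, seed=1),
                               {"a": 1.0, "b": 1.0}, ["a", "b"])
            se.append(model.fit(n_starts=1).bse["b"])
        assert se[1] > 3 * se[0]


class TestRecovery:
    def test_noise_free_monkey_il18_recovery(
        self, monkey_il18, monkey_repeat_pk_forcing
    ):
        """Fitting the five cIL-18 parameters to noise-free synthetic data
        recovers all of them to well within 0.1%."""
        design = monkey_study_design(
            seed=0, il18_sd=0.0, pk_cv=0.0, platelet_sd=0.0, hct_sd=0.0
        )
        df = gen_monkey_studies(
            R.monkey_pk_reference(), monkey_il18,
            R.platelet_reference(), R.hematocrit_reference(), design,
        )
        obs = df[df.endpoint == "il18"]
        start = dict(baseline_predose=25.0, slope=-0.02, emax=40.0,
                     ec50=0.15, kout=0.02)
        model = MonkeyIL18Model(obs, monkey_repeat_pk_forcing, start,
                                free=list(start))
        res = model.fit(n_starts=2)
        truth = dict(baseline_predose=20.0, slope=-0.013, emax=57.0,
                     ec50=0.082, kout=0.014)
        for name, value in res.params.items():
            assert value == pytest.approx(truth[name], rel=1e-3), name

    def test_reduction_factors_satisfy_prior_consistency(self, monkey_pk):
        """Dose-reduction factors are weakly identified from sparse
        post-dose sampling; with Cmax-ratio prior means and 50% CV the
        posterior mode must land within 2 prior SDs."""
        from il10pkpd.models import MonkeyPKModel
        from il10pkpd.synthetic import gen_monkey_studies, monkey_study_design
        from conftest import q2w_iv_regimen

        design = monkey_study_design(seed=11)
        df = gen_monkey_studies(
            monkey_pk, R.monkey_il18_reference(), R.platelet_reference(),
            R.hematocrit_reference(), design,
        )
        obs = df[(df.endpoint == "pk") & (df.arm == "rd-0.06")]
        start = dict(
            vc=monkey_pk.vc, k12=monkey_pk.k12, k21=monkey_pk.k21,
            k13=monkey_pk.k13, k31=monkey_pk.k31,
            kel_non_target=monkey_pk.kel_non_target,
            km_target=monkey_pk.km_target, vmax_target=monkey_pk.vmax_target,
        )
        priors, free = [], []
        for k, mean in ((2, 3.0), (3, 4.9)):
            name = f"rf_rd-0.06_{k}"
            start[name] = mean
            free.append(name)
            priors.append(Prior(name, mean, 0.5 * mean))
        model = MonkeyPKModel(
            obs,
            regimens={"rd-0.06": q2w_iv_regimen(0.06)},
            start=start, free=free, priors=priors, grid_step=0.5,
        )
        res = model.fit(n_starts=1)
        for pr in priors:
            assert abs(res.params[pr.parameter] - pr.mean) < 2 * pr.sd

    def test_information_criteria_select_generating_model(self, mouse_pk):
        """The anti-PD-1 interaction model beats its nested no-interaction
        reduction on data generated with a 4.4-fold interaction, in at
        least 90% of replicates at the study noise level."""
        design = mouse_ct26_design()
        grid = SimGrid(0.0, 528.0 + 24.0, 0.25)
        pk_03 = m.simulate_mouse_pk(
            R.mouse_pk_reference(0.036), single_ip_regimen(0.3), grid
        )
        # monotherapy arm pins Emax; the combination arm then exposes the
        # anti-PD-1 interaction multiplier (4.4-fold in the truth)
        pk_by_arm = {"mono-0.3": pk_03, "combo-0.3": pk_03}
        start = dict(baseline_predose=113.0, slope=0.15, slope_combo=0.19,
                     emax=126.0, ec50=2.4, kout=0.064, combo_fold=3.0)
        wins = 0
        n_rep = 12
        for seed in range(n_rep):
            df = gen_mouse_pkpd_study(
                R.mouse_pk_reference(0.036), R.mouse_il18_reference(),
                design, seed=seed,
            )
            obs = df[df.endpoint == "il18"]
            obs = obs[obs.arm.isin(pk_by_arm)]
            fits = {}
            for label, free, start_k in (
                ("interaction", ["emax", "ec50", "combo_fold"], start),
                ("no_interaction", ["emax", "ec50"], dict(start, combo_fold=1.0)),
            ):
                model = MouseIL18Model(
                    obs, pk_by_arm, start_k, free=free,
                    combo_arms=("combo-0.3",),
                )
                fits[label] = model.fit(n_starts=2, seed=seed)
            if (
                fits["interaction"].aic < fits["no_interaction"].aic
                and fits["interaction"].sbic < fits["no_interaction"].sbic
            ):
                wins += 1
        assert wins >= 0.9 * n_rep
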