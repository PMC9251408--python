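"""IL-18 indirect-response model tests against closed-form solutions."""

import dataclasses

import numpy as np
import pytest

import il10pkpd as m
from il10pkpd import reference as R
from il10pkpd.dosing import SimGrid
from il10pkpd.profiles import Profile
from il10pkpd.response import (
    IL18Params,
    control_il18,
    efficacy_correlation,
    fold_induction_auc,
    fold_induction_cmax,
    minimal_folds_for_efficacy,
    simulate_il18,
)

from conftest import single_ip_regimen, q2w_iv_regimen, zero_profile


def drift_closed_form(b0, s, kout, t):
    """No-drug trajectory: C(t) = b0 + s t - (s/kout)(1 - e^(-kout t))."""
    return b0 + s * t - (s / kout) * (1 - np.exp(-kout * t))


class TestTurnoverDynamics:
    def test_constant_baseline_is_exact_steady_state(self, monkey_il18):
        p = dataclasses.replace(monkey_il18, slope=0.0)
        prof = simulate_il18(p, zero_profile(500.0), SimGrid(0, 500, 0.5))
        assert np.allclose(prof.values, p.baseline_predose, rtol=1e-12)

    @pytest.mark.parametrize("slope", [0.15, -0.013])
    def test_drifting_control_matches_closed_form(self, slope):
        p = IL18Params(
            baseline_predose=113.0 if slope > 0 else 20.0,
            slope=slope, emax=0.0, ec50=1.0, kout=0.064,
        )
        grid = SimGrid(0.0, 504.0, 0.5)
        prof = simulate_il18(p, zero_profile(504.0), grid)
        expected = drift_closed_form(p.baseline_predose, slope, p.kout, prof.times)
        assert np.allclose(prof.values, expected, rtol=1e-9, atol=1e-9)

    def test_control_helper_strips_drug_term(self, monkey_il18):
        grid = SimGrid(0.0, 336.0, 0.5)
        a = control_il18(monkey_il18, grid).values
        expected = drift_closed_form(
            monkey_il18.baseline_predose, monkey_il18.slope, monkey_il18.kout,
            grid.times(),
        )
        assert np.allclose(a, expected, rtol=1e-9)

    def test_combo_fold_one_reproduces_monotherapy(self, mouse_pk, mouse_il18):
        grid = SimGrid(0.0, 504.0, 0.5)
        pk = m.simulate_mouse_pk(mouse_pk, single_ip_regimen(0.3), grid)
        combo1 = dataclasses.replace(mouse_il18, combo_fold=1.0)
        a = simulate_il18(mouse_il18, pk, grid).values
        b = simulate_il18(combo1, pk, grid).values
        assert np.array_equal(a, b)

    def test_fast_turnover_tracks_quasi_steady_state(self, monkey_pk):
        """At kout = 10/h the response follows baseline + stimulation."""
        p = IL18Params(baseline_predose=13.0, slope=0.0, emax=57.0,
                       ec50=0.082, kout=10.0)
        grid = SimGrid(0.0, 336.0, 0.02)
        pk = m.simulate_monkey_pk(monkey_pk, q2w_iv_regimen(0.06, n_doses=1), grid)
        prof = simulate_il18(p, pk, grid)
        qss = p.baseline_predose + p.emax * pk.values / (p.ec50 + pk.values)
        later = grid.times() > 2.0  # after the initial relaxation
        assert np.allclose(prof.values[later], qss[later], rtol=0.01)

    def test_lag_shifts_only_the_forcing(self, mouse_pk, mouse_il18):
        """Before the lag elapses the trajectory equals the control arm."""
        grid = SimGrid(0.0, 504.0, 0.5)
        pk = m.simulate_mouse_pk(mouse_pk, single_ip_regimen(0.3), grid)
        treated = simulate_il18(mouse_il18, pk, grid)
        ctrl = control_il18(mouse_il18, grid)
        pre_lag = treated.times <= mouse_il18.lag
        assert np.allclose(
            treated.values[pre_lag], ctrl.at(treated.times[pre_lag]), rtol=1e-9
        )
        assert treated.values[-1] > ctrl.values[-1]

    def test_short_window_warns(self, mouse_il18):
        with pytest.warns(RuntimeWarning):
            simulate_il18(mouse_il18, zero_profile(48.0), SimGrid(0, 48, 0.5))

    def test_negative_baseline_floored_with_warning(self):
        p = IL18Params(baseline_predose=20.0, slope=-0.05, emax=0.0,
                       ec50=1.0, kout=0.014)
        with pytest.warns(RuntimeWarning):
            prof = simulate_il18(p, zero_profile(1000.0), SimGrid(0, 1000, 0.5))
        assert prof.values.min() >= 0.0


class TestFoldInduction:
    def _pair(self, treated_vals, control_vals):
        t = np.linspace(0, 28 * 24.0, treated_vals.size)
        return (
            Profile(times=t, values=treated_vals, unit="pg/ml"),
            Profile(times=t, values=control_vals, unit="pg/ml"),
        )

    def test_identical_profiles_give_one(self):
        tr, ct = self._pair(np.full(100, 50.0), np.full(100, 50.0))
        assert fold_induction_cmax(tr, ct) == pytest.approx(1.0)
        assert fold_induction_auc(tr, ct, 14) == pytest.approx(1.0)

    def test_doubled_profile_gives_two(self):
        base = np.linspace(40, 60, 100)
        tr, ct = self._pair(2 * base, base)
        assert fold_induction_cmax(tr, ct) == pytest.approx(2.0)

    def test_cmax_uses_control_at_peak_time(self):
        ctrl = np.full(100, 130.0)
        treated = ctrl.copy()
        treated[40] = 260.0
        tr, ct = self._pair(treated, ctrl)
        assert fold_induction_cmax(tr, ct) == pytest.approx(2.0)

    def test_constant_offset_rectangle(self):
        b, delta = 13.0, 6.5
        tr, ct = self._pair(np.full(200, b + delta), np.full(200, b))
        assert fold_induction_auc(tr, ct, 14) == pytest.approx(1 + delta / b)

    def test_nonpositive_control_raises(self):
        tr, ct = self._pair(np.full(10, 5.0), np.zeros(10))
        with pytest.raises(ValueError):
            fold_induction_cmax(tr, ct)
        with pytest.raises(ValueError):
            fold_induction_auc(tr, ct, 14)

    def test_fold_monotone_in_dose(self, monkey_pk, monkey_il18):
        p = dataclasses.replace(monkey_il18, baseline_predose=13.0, slope=0.0)
        folds = []
        grid = SimGrid(0.0, 14 * 24.0 + 1, 0.5)
        ctrl = control_il18(p, grid)
        for dose in (0.005, 0.02, 0.06, 0.2):
            pk = m.simulate_monkey_pk(monkey_pk, q2w_iv_regimen(dose, 1), grid)
            treated = simulate_il18(p, pk, grid)
            folds.append(fold_induction_auc(treated, ctrl, 14))
        assert np.all(np.diff(folds) > 0)


class TestEfficacyCorrelation:
    def test_table_layout_and_threshold_flagging(self):
        table = efficacy_correlation(
            arms=["a", "b", "c"],
            doses_mgkg=[0.1, 0.3, 1.0],
            fold_cmax=[1.2, 1.8, 2.4],
            fold_auc_by_window={14: [1.1, 1.6, 2.0], 28: [1.05, 1.3, 1.6]},
            pct_tumor_free=[5.0, 65.0, 95.0],
        )
        assert list(table.columns) == [
            "arm", "dose_mgkg", "fold_cmax", "fold_auc_14d", "fold_auc_28d",
            "pct_tumor_free",
        ]
        mins = minimal_folds_for_efficacy(table, threshold_pct=80.0)
        assert mins == {"fold_cmax": 2.4, "fold_auc_14d": 2.0, "fold_auc_28d": 1.6}

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            efficacy_correlation(["a"], [0.1, 0.3], [1.0], {}, [5.0])

    def test_no_arm_reaching_threshold_raises(self):
        table = efficacy_correlation(["a"], [0.1], [1.2], {}, [40.0])
        with pytest.raises(ValueError):
            minimal_folds_for_efficacy(table, 80.0)

    def test_simulated_mouse_folds_recover_efficacy_thresholds(self, mouse_pk):
        """Simulating every efficacy-study arm (both tumor models, 5-week
        window) and flagging the minimal AUC folds among arms with >= 80%
        tumor-free mice yields the 1.6 / 1.4 / 1.3 thresholds over
        2 / 3 / 4 weeks."""
        grid = SimGrid(0.0, 35 * 24.0, 0.25)
        arms, doses, cmax, pct = [], [], [], []
        auc_folds = {14: [], 21: [], 28: []}
        studies = [
            (R.MC38_MONOTHERAPY_EFFICACY, False),
            (R.CT26_COMBINATION_EFFICACY, True),
        ]
        for observed, combo in studies:
            params = R.mouse_il18_reference(combo=combo)
            ctrl = control_il18(params, grid)
            for dose, tumor_free in observed.items():
                pk = m.simulate_mouse_pk(mouse_pk, single_ip_regimen(dose), grid)
                treated = simulate_il18(params, pk, grid)
                arms.append(f"{'combo' if combo else 'mono'}-{dose}")
                doses.append(dose)
                cmax.append(fold_induction_cmax(treated, ctrl))
                for w in auc_folds:
                    auc_folds[w].append(fold_induction_auc(treated, ctrl, w))
                pct.append(tumor_free)
        table = efficacy_correlation(arms, doses, cmax, auc_folds, pct)
        mins = minimal_folds_for_efficacy(table, threshold_pct=80.0)
        assert round(mins["fold_auc_14d"], 1) == 1.6
        assert round(mins["fold_auc_21d"], 1) == 1.4
        assert round(mins["fold_auc_28d"], 1) == 1.3
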