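"""Concrete fit models for each endpoint.

Fitting mirrors the sequential strategy of the source analysis: PK is
fitted (or fixed from reference estimates) first, and each PD/toxicity
endpoint is then fitted conditional on the fixed PK forcing.  Every
class is a :class:`~il10pkpd.estimation.TimeCourseModel`: construct from
an observation table, call ``fit()``, read the results object.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dosing import DoseEvent, DoseRegimen, SimGrid
from .estimation import Prior, TimeCourseModel
from .hematology import (
    HematocritParams,
    PlateletParams,
    simulate_hematocrit,
    simulate_platelets,
)
from .pk import (
    MonkeyPKParams,
    MousePKParams,
    simulate_monkey_pk,
    simulate_mouse_pk,
)
from .profiles import Profile
from .response import IL18Params, simulate_il18

__all__ = [
    "MousePKModel",
    "MonkeyPKModel",
    "MouseIL18Model",
    "MonkeyIL18Model",
    "PlateletModel",
    "HematocritModel",
]

_MOUSE_PK_FIELDS = (
    "vc_apparent", "ka", "k12", "k21", "kel_non_target", "km_target", "vmax_target",
)
_MONKEY_PK_FIELDS = (
    "vc", "k12", "k21", "k13", "k31", "kel_non_target", "km_target", "vmax_target",
)
_IL18_FIELDS = ("baseline_predose", "slope", "emax", "ec50", "kout")
_TOX_FIELDS = ("predose", "ic50", "kout")


def _arm_grid(times: np.ndarray, step: float, lag: float = 0.0) -> SimGrid:
    t_end = float(times.max()) + step
    return SimGrid(0.0, max(t_end, lag + step), step)


class _ArmwiseModel(TimeCourseModel):
    """Shared plumbing: observations grouped by arm, one simulation per arm."""

    def __init__(self, data: pd.DataFrame, *args, grid_step: float = 0.25, **kwargs):
        super().__init__(data, *args, **kwargs)
        self.grid_step = grid_step
        self._arm_slices = {
            arm: (
                np.asarray(idx, dtype=int),
                self.data.loc[idx, "time_h"].to_numpy(dtype=float),
            )
            for arm, idx in self.data.groupby("arm").groups.items()
        }

    def _predict_arm(self, arm: str, params: Mapping[str, float], t: np.ndarray):
        raise NotImplementedError

    def predict(self, params: Mapping[str, float]) -> np.ndarray:
        out = np.empty(len(self.data))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for arm, (idx, t) in self._arm_slices.items():
                out[idx] = self._predict_arm(arm, params, t)
        return out


class MousePKModel(_ArmwiseModel):
    """Mouse IP TMDD PK fitted to concentration data (1/y weighting).

    Typical use fixes every parameter except ``vc_apparent`` (the scalar
    that absorbs between-study exposure differences); per-arm volume
    overrides are expressed by fitting arms separately.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        regimens: Mapping[str, DoseRegimen],
        start: Mapping[str, float],
        free: Sequence[str] = ("vc_apparent",),
        priors: Sequence[Prior] = (),
        weighting: str = "inv_y",
        grid_step: float = 0.25,
    ) -> None:
        self.regimens = dict(regimens)
        super().__init__(
            data, dict(start), list(free), priors, weighting, grid_step=grid_step
        )

    def _predict_arm(self, arm, params, t):
        p = MousePKParams(**{k: params[k] for k in _MOUSE_PK_FIELDS})
        prof = simulate_mouse_pk(p, self.regimens[arm], _arm_grid(t, self.grid_step))
        return prof.at(t)


class MonkeyPKModel(_ArmwiseModel):
    """Monkey IV TMDD PK fitted to concentration data (1/y^2 weighting).

    ADA exposure loss is parameterised by per-dose reduction factors
    named ``rf_<arm>_<k>`` (k = 1-based dose index); factors not listed
    in ``start`` stay at 1.  Reduction factors are typically given
    Cmax-ratio initial values as prior means with 50% CV.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        regimens: Mapping[str, DoseRegimen],
        start: Mapping[str, float],
        free: Sequence[str],
        priors: Sequence[Prior] = (),
        weighting: str = "inv_y2",
        grid_step: float = 0.25,
    ) -> None:
        self.regimens = dict(regimens)
        super().__init__(
            data, dict(start), list(free), priors, weighting, grid_step=grid_step
        )

    def _regimen_with_factors(self, arm: str, params: Mapping[str, float]):
        base = self.regimens[arm]
        events = []
        for k, ev in enumerate(base.events, start=1):
            rf = params.get(f"rf_{arm}_{k}", ev.reduction_factor)
            events.append(
                DoseEvent(ev.time, ev.amount, ev.route, max(rf, 1.0))
            )
        return DoseRegimen(events=tuple(events), mw=base.mw)

    def _predict_arm(self, arm, params, t):
        p = MonkeyPKParams(**{k: params[k] for k in _MONKEY_PK_FIELDS})
        regimen = self._regimen_with_factors(arm, params)
        prof = simulate_monkey_pk(p, regimen, _arm_grid(t, self.grid_step))
        return prof.at(t)


class _ForcedPDModel(_ArmwiseModel):
    """PD endpoint driven by fixed per-arm PK forcing profiles."""

    def __init__(
        self,
        data: pd.DataFrame,
        pk_by_arm: Mapping[str, Profile],
        start: Mapping[str, float],
        free: Sequence[str],
        priors: Sequence[Prior] = (),
        weighting: str = "equal",
        grid_step: float = 0.25,
    ) -> None:
        self.pk_by_arm = dict(pk_by_arm)
        super().__init__(
            data, dict(start), list(free), priors, weighting, grid_step=grid_step
        )


class MonkeyIL18Model(_ForcedPDModel):
    """cIL-18 turnover model (no lag, declining baseline).

    Free parameters among: baseline_predose, slope, emax, ec50, kout.
    ``slope`` is signed (negative for the declining monkey baseline) and
    is fitted without a positivity constraint.
    """

    lag = 0.0
    combo_by_arm: Mapping[str, float] = {}

    def _predict_arm(self, arm, params, t):
        p = IL18Params(
            baseline_predose=params["baseline_predose"],
            slope=params["slope"],
            emax=params["emax"],
            ec50=params["ec50"],
            kout=params["kout"],
            lag=self.lag,
            combo_fold=float(self.combo_by_arm.get(arm, 1.0)),
        )
        pk = self.pk_by_arm[arm]
        prof = simulate_il18(p, pk, _arm_grid(t, self.grid_step, self.lag))
        return prof.at(t)


class MouseIL18Model(MonkeyIL18Model):
    """mIL-18 turnover model with the 72-h induction lag.

    Combination arms (anti-PD-1) multiply Emax by the free parameter
    ``combo_fold``; arm membership is given by ``combo_arms``.  Control
    arms may use a different baseline slope via ``slope_combo`` when it
    is included in ``start``/``free``.
    """

    lag = 72.0

    def __init__(
        self,
        data: pd.DataFrame,
        pk_by_arm: Mapping[str, Profile],
        start: Mapping[str, float],
        free: Sequence[str],
        combo_arms: Sequence[str] = (),
        priors: Sequence[Prior] = (),
        weighting: str = "equal",
        grid_step: float = 0.25,
    ) -> None:
        self.combo_arms = set(combo_arms)
        super().__init__(data, pk_by_arm, start, free, priors, weighting,
                         grid_step=grid_step)

    def _predict_arm(self, arm, params, t):
        combo = arm in self.combo_arms
        slope = params.get("slope_combo", params["slope"]) if combo else params["slope"]
        p = IL18Params(
            baseline_predose=params["baseline_predose"],
            slope=slope,
            emax=params["emax"],
            ec50=params["ec50"],
            kout=params["kout"],
            lag=self.lag,
            combo_fold=params.get("combo_fold", 1.0) if combo else 1.0,
        )
        prof = simulate_il18(
            p, self.pk_by_arm[arm], _arm_grid(t, self.grid_step, self.lag)
        )
        return prof.at(t)


class PlateletModel(_ForcedPDModel):
    """Platelet precursor-pool model; free among predose, ic50, kout."""

    def _predict_arm(self, arm, params, t):
        p = PlateletParams(**{k: params[k] for k in _TOX_FIELDS})
        prof = simulate_platelets(
            p, self.pk_by_arm[arm], _arm_grid(t, self.grid_step)
        )
        return prof.at(t)


class HematocritModel(_ForcedPDModel):
    """Hematocrit turnover model; free among predose, ic50, kout."""

    def _predict_arm(self, arm, params, t):
        p = HematocritParams(**{k: params[k] for k in _TOX_FIELDS})
        prof = simulate_hematocrit(
            p, self.pk_by_arm[arm], _arm_grid(t, self.grid_step)
        )
        return prof.at(t)
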