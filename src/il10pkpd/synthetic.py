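"""Synthetic study generation with the designs of the two source studies.

The generator emulates:

* the mouse CT26 PK/PD study: 6 arms x 6 mice (isotype control,
  anti-PD-1 control, 0.1 and 0.3 mg/kg IP as monotherapy and combined
  with anti-PD-1), composite sparse sampling (independent animals per
  time point, so independent noise draws and no between-animal random
  effects — the source analysis modeled average data);
* the monkey studies: single IV doses of 0.005/0.05/0.5 mg/kg (n = 1)
  for PK, and the repeat-dose study (0.06 and 0.18 mg/kg IV Q2W x 3,
  n = 3, plus vehicle) with ADA-driven exposure loss expressed through
  per-dose reduction factors, measuring PK, cIL-18, platelet counts and
  hematocrit.

Default residual noise (configurable; the source study reports no
residual-error magnitudes): proportional log-normal with 15% CV for PK,
additive Gaussian at 10% of the predose baseline for IL-18 and 5% for
platelets and hematocrit — typical bioanalytical / hematology precision.
Observations below the LLOQ are censored (dropped), as in the source
figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dosing import (
    MW_MONKEY_CONSTRUCT,
    MW_MOUSE_CONSTRUCT,
    Route,
    SimGrid,
    build_regimen,
)
from .hematology import (
    HematocritParams,
    PlateletParams,
    simulate_hematocrit,
    simulate_platelets,
)
from .pk import MonkeyPKParams, MousePKParams, simulate_monkey_pk, simulate_mouse_pk
from .profiles import Profile
from .response import IL18Params, control_il18, simulate_il18

__all__ = [
    "Arm",
    "EndpointNoise",
    "StudyDesign",
    "mouse_ct26_design",
    "monkey_study_design",
    "gen_mouse_pkpd_study",
    "gen_monkey_studies",
    "apply_dilution_correction",
]

_UNITS = {"pk": "nM", "il18": "pg/ml", "platelet": "1e3/uL", "hematocrit": "%"}


def apply_dilution_correction(measured: float, factor: float = 17.36):
    """Correct a diluted-sample concentration to the undiluted value.

    The mouse blood micro-sampling protocol dilutes samples by a
    theoretical factor of 17.36.
    """
    if factor < 0:
        raise ValueError(f"dilution factor must be non-negative, got {factor}")
    arr = np.asarray(measured, dtype=float)
    if np.any(arr < 0):
        raise ValueError("measured concentration must be non-negative")
    out = arr * factor
    return float(out) if np.isscalar(measured) else out


@dataclass(frozen=True)
class EndpointNoise:
    """Residual-error model for one endpoint.

    ``proportional_lognormal``: magnitude is a CV fraction;
    ``additive_gaussian``: magnitude is an absolute SD in endpoint units.
    """

    model: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.model not in ("proportional_lognormal", "additive_gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.magnitude < 0:
            raise ValueError("noise magnitude must be >= 0")

    def apply(self, truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        truth = np.asarray(truth, dtype=float)
        if self.magnitude == 0:
            return truth.copy()
        if self.model == "proportional_lognormal":
            sigma = np.sqrt(np.log1p(self.magnitude**2))
            return truth * rng.lognormal(-0.5 * sigma**2, sigma, truth.shape)
        return np.clip(truth + rng.normal(0.0, self.magnitude, truth.shape), 0.0, None)


@dataclass(frozen=True)
class Arm:
    """One treatment arm: label, dose, subjects, endpoints measured."""

    label: str
    dose_mgkg: float
    n_subjects: int = 6
    combo: bool = False
    reduction_factors: tuple[float, ...] = ()
    endpoints: tuple[str, ...] = ("pk", "il18")

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.dose_mgkg < 0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """Arms, per-endpoint sampling times (h), noise models and LLOQs."""

    species: str
    arms: tuple[Arm, ...]
    sampling_times: dict[str, tuple[float, ...]]
    noise: dict[str, EndpointNoise]
    lloq: dict[str, float] = field(default_factory=dict)
    n_doses: int = 1
    interval_days: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in ("mouse", "monkey"):
            raise ValueError(f"species must be mouse or monkey, got {self.species!r}")


def mouse_ct26_design(seed: int = 0, pk_cv: float = 0.15,
                      il18_sd: float = 11.3) -> StudyDesign:
    """The 6-arm, 6-mice CT26 PK/PD study design.

    IL-18 additive noise defaults to 10% of the 113 pg/ml predose
    baseline; PK proportional CV 15%.
    """
    arms = (
        Arm("isotype", 0.0, endpoints=("il18",)),
        Arm("anti-pd1", 0.0, combo=True, endpoints=("il18",)),
        Arm("mono-0.1", 0.1),
        Arm("mono-0.3", 0.3),
        Arm("combo-0.1", 0.1, combo=True),
        Arm("combo-0.3", 0.3, combo=True),
    )
    return StudyDesign(
        species="mouse",
        arms=arms,
        sampling_times={
            "pk": (6.0, 24.0, 72.0),
            "il18": (0.0, 48.0, 96.0, 168.0, 240.0, 336.0, 408.0, 504.0),
        },
        noise={
            "pk": EndpointNoise("proportional_lognormal", pk_cv),
            "il18": EndpointNoise("additive_gaussian", il18_sd),
        },
        lloq={"pk": 0.05},
        seed=seed,
    )


def monkey_study_design(seed: int = 0, pk_cv: float = 0.15,
                        il18_sd: float = 2.0, platelet_sd: float = 18.95,
                        hct_sd: float = 2.15) -> StudyDesign:
    """Single-dose (0.005/0.05/0.5 mg/kg, n=1) plus repeat-dose
    (0.06/0.18 mg/kg Q2W x 3, n=3, vehicle) monkey study designs.

    Additive SDs default to 10% of the 20 pg/ml cIL-18 baseline and 5%
    of the platelet (379) and hematocrit (43) predose levels.
    """
    pd_endpoints = ("pk", "il18", "platelet", "hematocrit")
    per_dose = (1.0, 8.0, 24.0, 72.0, 168.0, 240.0, 336.0)
    pk_times = tuple(
        round(d * 336.0 + off, 6) for d in range(3) for off in per_dose
    )
    # hematology: early post-dose days around each dose (nadirs develop
    # within days) plus weekly washout follow-up
    hem_days = sorted(
        {d * 14 + off for d in range(3) for off in (0, 1, 2, 3, 5, 7, 10)}
        | {42, 49, 56, 63, 70}
    )
    hematology = tuple(24.0 * d for d in hem_days)
    arms = (
        Arm("sd-0.005", 0.005, n_subjects=1, endpoints=("pk",)),
        Arm("sd-0.05", 0.05, n_subjects=1, endpoints=("pk",)),
        Arm("sd-0.5", 0.5, n_subjects=1, endpoints=("pk",)),
        Arm("vehicle", 0.0, n_subjects=3, endpoints=("il18", "platelet", "hematocrit")),
        Arm("rd-0.06", 0.06, n_subjects=3,
            reduction_factors=(1.0, 3.0, 4.9), endpoints=pd_endpoints),
        Arm("rd-0.18", 0.18, n_subjects=3,
            reduction_factors=(1.0, 2530.0, 380.0), endpoints=pd_endpoints),
    )
    return StudyDesign(
        species="monkey",
        arms=arms,
        sampling_times={
            "pk": pk_times,
            "il18": tuple(sorted(set((0.0, 24.0, 48.0) + pk_times))),
            "platelet": hematology,
            "hematocrit": hematology,
        },
        noise={
            "pk": EndpointNoise("proportional_lognormal", pk_cv),
            "il18": EndpointNoise("additive_gaussian", il18_sd),
            "platelet": EndpointNoise("additive_gaussian", platelet_sd),
            "hematocrit": EndpointNoise("additive_gaussian", hct_sd),
        },
        lloq={"pk": 0.02},
        n_doses=3,
        interval_days=14.0,
        seed=seed,
    )


def _rows(arm, endpoint, times, truth, design, rng):
    noise = design.noise[endpoint]
    lloq = design.lloq.get(endpoint, 0.0)
    rows = []
    for t, v in zip(times, truth):
        vals = noise.apply(np.full(arm.n_subjects, v), rng)
        for j, obs in enumerate(vals):
            rows.append(
                {
                    "arm": arm.label,
                    "endpoint": endpoint,
                    "time_h": t,
                    "value": float(obs),
                    "unit": _UNITS[endpoint],
                    "subject": j + 1,
                    "censored": bool(obs < lloq),
                }
            )
    return rows


def _finalize(rows, drop_censored=True) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    if drop_censored:
        df = df[~df["censored"]].drop(columns="censored").reset_index(drop=True)
    return df


def gen_mouse_pkpd_study(
    pk_params: MousePKParams,
    il18_params: IL18Params,
    design: StudyDesign,
    seed: int | None = None,
    combo_fold: float = 4.4,
    slope_combo: float = 0.19,
    drop_censored: bool = True,
) -> pd.DataFrame:
    """Simulate the mouse study and return an observation table.

    ``il18_params`` are the monotherapy PD parameters; combination arms
    apply ``combo_fold`` and the anti-PD-1 control-arm baseline slope.
    Deterministic for a given seed (defaults to the design's seed).
    """
    if design.species != "mouse":
        raise ValueError("design.species must be 'mouse'")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    t_max = max(max(v) for v in design.sampling_times.values())
    grid = SimGrid(0.0, t_max + 24.0, 0.25)
    rows = []
    for arm in design.arms:
        pd_params = replace(
            il18_params,
            slope=slope_combo if arm.combo else il18_params.slope,
            combo_fold=combo_fold if arm.combo else 1.0,
        )
        if arm.dose_mgkg > 0:
            regimen = build_regimen(
                arm.dose_mgkg, design.interval_days, design.n_doses,
                Route.IP_FIRST_ORDER, mw=MW_MOUSE_CONSTRUCT,
            )
            pk = simulate_mouse_pk(pk_params, regimen, grid)
            il18 = simulate_il18(pd_params, pk, grid)
        else:
            pk = None
            il18 = control_il18(pd_params, grid)
        for endpoint in arm.endpoints:
            times = design.sampling_times[endpoint]
            prof = {"pk": pk, "il18": il18}[endpoint]
            if prof is None:
                continue
            rows.extend(_rows(arm, endpoint, times, prof.at(np.array(times)), design, rng))
    return _finalize(rows, drop_censored)


def gen_monkey_studies(
    pk_params: MonkeyPKParams,
    il18_params: IL18Params,
    platelet_params: PlateletParams,
    hct_params: HematocritParams,
    design: StudyDesign,
    seed: int | None = None,
    drop_censored: bool = True,
) -> pd.DataFrame:
    """Simulate the monkey single- and repeat-dose studies.

    Per-dose reduction factors in each arm are applied to the generating
    PK, so the 2nd/3rd-dose exposure loss from ADA is present in the
    truth before noise.
    """
    if design.species != "monkey":
        raise ValueError("design.species must be 'monkey'")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    t_max = max(max(v) for v in design.sampling_times.values())
    grid = SimGrid(0.0, t_max + 24.0, 0.25)
    rows = []
    for arm in design.arms:
        if arm.dose_mgkg > 0:
            n_doses = design.n_doses if arm.reduction_factors else 1
            regimen = build_regimen(
                arm.dose_mgkg, design.interval_days, n_doses, Route.IV_BOLUS,
                reduction_factors=arm.reduction_factors, mw=MW_MONKEY_CONSTRUCT,
            )
            pk = simulate_monkey_pk(pk_params, regimen, grid)
        else:
            pk = Profile(times=grid.times(), values=np.zeros(grid.times().size),
                         unit="nM", name="Cp")
        sims = {
            "pk": lambda g: pk,
            "il18": lambda g: simulate_il18(il18_params, pk, g),
            "platelet": lambda g: simulate_platelets(platelet_params, pk, g),
            "hematocrit": lambda g: simulate_hematocrit(hct_params, pk, g),
        }
        for endpoint in arm.endpoints:
            times = design.sampling_times[endpoint]
            # each endpoint is simulated only over its own sampling span
            sub = SimGrid(0.0, max(times) + 1.0, grid.step)
            prof = sims[endpoint](sub)
            rows.extend(_rows(arm, endpoint, times, prof.at(np.array(times)),
                              design, rng))
    return _finalize(rows, drop_censored)
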