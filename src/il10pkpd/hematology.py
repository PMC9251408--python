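"""Semimechanistic hematotoxicity models, adverse-event grading, and MTD search.

Thrombocytopenia uses a precursor-pool turnover model: drug inhibits the
transfer from a precursor pool into circulating platelets, both pools
sharing the turnover rate ``kout``.  Inhibition lets the precursor pool
accumulate, which produces the observed post-washout platelet rebound
above the predose level.  Anemia (hematocrit) uses a plain
inhibition-of-production turnover model; its much slower turnover makes
the hematocrit nadir schedule-sensitive while the platelet nadir is not.

Adverse-event grades are assigned from the fraction of the predose
baseline reached at nadir.  The grade-line percentages are a required
configuration input (`GradeScale`); the defaults derive CTCAE v5
absolute cut-offs normalised by the human lower limit of normal
(platelets: 75/50/25 of LLN 150 -> 0.5/0.333/0.167 would be G2/G3/G4;
the three boundaries stored are G1/G2/G3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .dosing import Route, SimGrid, build_regimen
from .pk import IntegrationError, MonkeyPKParams, simulate_monkey_pk
from .profiles import Profile
from .response import _turnover_exact

__all__ = [
    "PlateletParams",
    "HematocritParams",
    "GradeScale",
    "DEFAULT_PLATELET_SCALE",
    "DEFAULT_HEMATOCRIT_SCALE",
    "simulate_platelets",
    "simulate_hematocrit",
    "grade_profile",
    "find_mtd",
]


@dataclass(frozen=True)
class PlateletParams:
    """Platelet precursor-pool model parameters.

    predose 10^3 cells/uL; imax fraction (fixed 1.0 in the reference
    fit); ic50 nM; kout 1/h (shared by precursor and platelet pools).
    """

    predose: float
    ic50: float
    kout: float
    imax: float = 1.0

    def __post_init__(self) -> None:
        if self.predose <= 0:
            raise ValueError("predose must be > 0")
        if not 0 < self.imax <= 1:
            raise ValueError("imax must be in (0, 1]")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")
        if self.kout <= 0:
            raise ValueError("kout must be > 0")


@dataclass(frozen=True)
class HematocritParams:
    """Hematocrit turnover model parameters (predose in percent)."""

    predose: float
    ic50: float
    kout: float
    imax: float = 1.0

    def __post_init__(self) -> None:
        if self.predose <= 0:
            raise ValueError("predose must be > 0")
        if not 0 < self.imax <= 1:
            raise ValueError("imax must be in (0, 1]")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")
        if self.kout <= 0:
            raise ValueError("kout must be > 0")


@dataclass(frozen=True)
class GradeScale:
    """Fraction-of-baseline grade boundaries (G1, G2, G3), decreasing.

    A value strictly below boundary ``b_g`` scores at least grade ``g``;
    a nadir exactly on a boundary takes the less severe grade.
    """

    endpoint: str
    boundaries: tuple[float, float, float]

    def __post_init__(self) -> None:
        b = self.boundaries
        if not (1.0 > b[0] > b[1] > b[2] > 0.0):
            raise ValueError(
                f"boundaries must satisfy 1 > b1 > b2 > b3 > 0, got {b}"
            )

    @property
    def scale_id(self) -> str:
        return f"{self.endpoint}:" + "/".join(f"{b:.3f}" for b in self.boundaries)


DEFAULT_PLATELET_SCALE = GradeScale("platelet", (0.667, 0.50, 1 / 3))
DEFAULT_HEMATOCRIT_SCALE = GradeScale("hematocrit", (11 / 12, 10 / 12, 8 / 12))


def _inhibition(params, cp: np.ndarray) -> np.ndarray:
    return 1.0 - params.imax * cp / (params.ic50 + cp)


def simulate_platelets(
    params: PlateletParams, pk: Profile, grid: SimGrid
) -> Profile:
    """Circulating platelet count (10^3/uL) under a PK forcing profile.

    Two-state system; precursor and platelet pools both start at the
    predose level (required for a constant no-drug baseline).
    """
    t_out = grid.times()

    def rhs(t, y):
        cp = np.interp(t, pk.times, pk.values)
        r = 1.0 - params.imax * cp / (params.ic50 + cp)
        prec, plat = y
        inflow = params.kout * r * prec
        return (params.predose * params.kout - inflow, inflow - params.kout * plat)

    sol = solve_ivp(
        rhs,
        (t_out[0], t_out[-1]),
        (params.predose, params.predose),
        method="LSODA",
        rtol=1e-8,
        atol=1e-8,
        dense_output=True,
        max_step=4.0,  # forcing changes abruptly at bolus times
    )
    if not sol.success:
        raise IntegrationError(f"platelet integration failed: {sol.message}")
    return Profile(
        times=t_out, values=sol.sol(t_out)[1], unit="1e3/uL", name="platelets"
    )


def simulate_hematocrit(
    params: HematocritParams, pk: Profile, grid: SimGrid
) -> Profile:
    """Hematocrit (%) under a PK forcing profile (inhibition of production)."""
    t_out = grid.times()
    cp = pk.at(t_out)
    f = params.predose * _inhibition(params, cp)
    hct = _turnover_exact(t_out, f, params.kout, params.predose)
    return Profile(times=t_out, values=hct, unit="%", name="hematocrit")


def grade_profile(profile: Profile, scale: GradeScale, baseline: float | None = None) -> int:
    """Worst adverse-event grade over the profile (0-3).

    Grade g is scored when value/baseline falls strictly below the g-th
    boundary, so a nadir exactly on a boundary takes the lower grade.
    ``baseline`` defaults to the profile's first value.
    """
    base = profile.values[0] if baseline is None else baseline
    if base <= 0:
        raise ValueError("profile baseline must be positive")
    nadir_frac = float(np.min(profile.values)) / base
    grade = 0
    for g, b in enumerate(scale.boundaries, start=1):
        if nadir_frac < b:
            grade = g
    return grade


def _tox_profile(tox_params, pk: Profile, grid: SimGrid) -> Profile:
    if isinstance(tox_params, PlateletParams):
        return simulate_platelets(tox_params, pk, grid)
    if isinstance(tox_params, HematocritParams):
        return simulate_hematocrit(tox_params, pk, grid)
    raise TypeError(f"unsupported toxicity parameter type {type(tox_params)!r}")


def worst_grade_at_dose(
    pk_params: MonkeyPKParams,
    tox_params,
    scale: GradeScale,
    dose_mgkg: float,
    interval_days: float,
    n_doses: int = 3,
    washout_days: float = 42.0,
    step: float = 0.25,
) -> int:
    """Worst grade over an n-dose regimen plus washout (no ADA loss)."""
    regimen = build_regimen(dose_mgkg, interval_days, n_doses, Route.IV_BOLUS)
    horizon = max(12 * 7 * 24.0, regimen.times[-1] + washout_days * 24.0)
    grid = SimGrid(0.0, horizon, step)
    pk = simulate_monkey_pk(pk_params, regimen, grid)
    prof = _tox_profile(tox_params, pk, grid)
    return grade_profile(prof, scale, baseline=tox_params.predose)


def find_mtd(
    pk_params: MonkeyPKParams,
    tox_params,
    scale: GradeScale,
    interval_days: float,
    dose_grid: np.ndarray | None = None,
    n_doses: int = 3,
    max_grade: int = 2,
    refine_to: float | None = None,
) -> float | None:
    """Largest dose on the grid whose simulated worst grade stays <= 2.

    The default grid is 0.02-0.40 mg/kg at 0.02 mg/kg resolution, the
    resolution at which the source study's dose range was simulated; the
    grid (not a continuous bisection) is the primary definition of the
    MTD, with optional bisection refinement via ``refine_to``.  Drug
    exposure is assumed unaltered on repeat dosing (no ADA).  Returns
    ``None`` when even the lowest grid dose exceeds the grade limit.
    """
    if dose_grid is None:
        dose_grid = np.round(np.arange(0.02, 0.40001, 0.02), 10)
    dose_grid = np.asarray(dose_grid, dtype=float)
    if dose_grid.size == 0 or np.any(np.diff(dose_grid) <= 0):
        raise ValueError("dose_grid must be non-empty and increasing")

    def ok(dose: float) -> bool:
        return (
            worst_grade_at_dose(
                pk_params, tox_params, scale, dose, interval_days, n_doses
            )
            <= max_grade
        )

    mtd = None
    for dose in dose_grid:
        if ok(dose):
            mtd = float(dose)
        else:
            break
    if mtd is None or refine_to is None:
        return mtd
    # bisection between the last passing and first failing grid dose
    lo = mtd
    idx = int(np.searchsorted(dose_grid, mtd))
    hi = float(dose_grid[idx + 1]) if idx + 1 < dose_grid.size else lo
    if hi <= lo:
        return mtd
    while hi - lo > refine_to:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return lo
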