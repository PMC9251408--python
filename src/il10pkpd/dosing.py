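"""Dose units, dosing regimens, and simulation grids.

Internal canonical units throughout the package: time in hours,
concentration in nM, amounts in nmol per kg body weight, volumes in L/kg.
Doses are entered in mg/kg and converted with the construct's molecular
mass; body-weight scaling is implicit because every rate constant and
volume is expressed per kg.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Route",
    "DoseEvent",
    "DoseRegimen",
    "SimGrid",
    "mgkg_to_nmolkg",
    "build_regimen",
    "regimen_from_config",
]

#: molecular masses (Da) of the two Fc-fusion constructs
MW_MOUSE_CONSTRUCT = 91_004.0  # mFc-mIL-10
MW_MONKEY_CONSTRUCT = 90_815.0  # hFc-hIL-10


class Route(str, Enum):
    """Administration route: IV bolus or first-order IP absorption."""

    IV_BOLUS = "iv_bolus"
    IP_FIRST_ORDER = "ip_first_order"


def mgkg_to_nmolkg(amount_mgkg: float, mw_da: float) -> float:
    """Convert a mg/kg dose to nmol/kg using the molecular mass in Da.

    nmol/kg = mg/kg * 1e6 / MW.  Linear in the dose amount.
    """
    if mw_da <= 0:
        raise ValueError(f"molecular mass must be positive, got {mw_da}")
    if amount_mgkg < 0:
        raise ValueError(f"dose amount must be non-negative, got {amount_mgkg}")
    return amount_mgkg * 1e6 / mw_da


@dataclass(frozen=True)
class DoseEvent:
    """A single dose: time (h since first dose), amount (mg/kg), route,
    and an ADA exposure-loss divisor (``reduction_factor`` >= 1; 1 = no loss)."""

    time: float
    amount: float
    route: Route = Route.IV_BOLUS
    reduction_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.reduction_factor < 1:
            raise ValueError(
                f"reduction factor must be >= 1, got {self.reduction_factor}"
            )


@dataclass(frozen=True)
class DoseRegimen:
    """An ordered sequence of dose events plus the construct molecular mass."""

    events: tuple[DoseEvent, ...]
    mw: float = MW_MONKEY_CONSTRUCT

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"molecular mass must be positive, got {self.mw}")
        times = [e.time for e in self.events]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("dose events must be strictly increasing in time")

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(e.time for e in self.events)

    def amounts_nmolkg(self) -> tuple[float, ...]:
        """Per-event administered amounts in nmol/kg, after reduction factors."""
        return tuple(
            mgkg_to_nmolkg(e.amount, self.mw) / e.reduction_factor
            for e in self.events
        )


@dataclass(frozen=True)
class SimGrid:
    """Output time grid; dose times are inserted as exact breakpoints."""

    t_start: float = 0.0
    t_end: float = 24.0 * 70
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.step <= 0:
            raise ValueError("step must be positive")

    def times(self, breakpoints: Sequence[float] = ()) -> np.ndarray:
        """Grid points from t_start to t_end with breakpoints merged in."""
        t = np.arange(self.t_start, self.t_end, self.step)
        extra = [self.t_end] + [
            b for b in breakpoints if self.t_start <= b <= self.t_end
        ]
        t = np.union1d(t, np.asarray(extra, dtype=float))
        return t


def build_regimen(
    amount_mgkg: float,
    interval_days: float,
    n_doses: int,
    route: Route = Route.IV_BOLUS,
    reduction_factors: Sequence[float] = (),
    mw: float = MW_MONKEY_CONSTRUCT,
    start_h: float = 0.0,
) -> DoseRegimen:
    """Build an equally spaced regimen (Q2W = 14-day interval, etc.).

    ``reduction_factors`` must be empty (all 1) or one factor per dose.
    """
    if n_doses < 1:
        raise ValueError(f"n_doses must be >= 1, got {n_doses}")
    if reduction_factors and len(reduction_factors) != n_doses:
        raise ValueError(
            f"got {len(reduction_factors)} reduction factors for {n_doses} doses"
        )
    factors = list(reduction_factors) if reduction_factors else [1.0] * n_doses
    events = tuple(
        DoseEvent(
            time=start_h + i * interval_days * 24.0,
            amount=amount_mgkg,
            route=route,
            reduction_factor=factors[i],
        )
        for i in range(n_doses)
    )
    return DoseRegimen(events=events, mw=mw)


def regimen_from_config(cfg: dict) -> DoseRegimen:
    """Build a regimen from a config block.

    Keys: ``dose_mgkg``, ``interval_days``, ``n_doses``, ``route``
    (``iv_bolus`` or ``ip_first_order``), ``reduction_factors``, ``mw_da``.
    """
    return build_regimen(
        amount_mgkg=float(cfg["dose_mgkg"]),
        interval_days=float(cfg.get("interval_days", 14.0)),
        n_doses=int(cfg.get("n_doses", 1)),
        route=Route(cfg.get("route", "iv_bolus")),
        reduction_factors=cfg.get("reduction_factors") or (),
        mw=float(cfg.get("mw_da", MW_MONKEY_CONSTRUCT)),
    )
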