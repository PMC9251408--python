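"""Time-series container and trapezoidal AUC."""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Profile", "auc"]


@dataclass(frozen=True)
class Profile:
    """A simulated or observed time course of one quantity.

    times are hours, strictly increasing; values carry the stated unit.
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    def at(self, t) -> np.ndarray:
        """Linear interpolation at time(s) ``t`` (h); constant outside range."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, "value": self.values})

    def to_csv(self, path) -> None:
        """Two-column CSV (`time_h`, `value`) with a unit header comment."""
        with open(path, "w") as fh:
            fh.write(f"# name: {self.name}\n# unit: {self.unit}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Profile":
        name, unit = "", ""
        with open(path) as fh:
            text = fh.read()
        body = []
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                if key.strip() == "name":
                    name = val.strip()
                elif key.strip() == "unit":
                    unit = val.strip()
            else:
                body.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body)))
        return cls(
            times=df["time_h"].to_numpy(),
            values=df["value"].to_numpy(),
            unit=unit,
            name=name,
        )


def auc(profile: Profile, t0: float, t1: float) -> float:
    """Linear-trapezoid AUC of a profile over [t0, t1], in unit·day.

    Window endpoints inside the profile range are linearly interpolated.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    lo, hi = profile.times[0], profile.times[-1]
    if t0 < lo - 1e-9 or t1 > hi + 1e-9:
        raise ValueError(
            f"AUC window [{t0}, {t1}] outside profile range [{lo}, {hi}]"
        )
    t = profile.times
    inner = t[(t > t0) & (t < t1)]
    tt = np.concatenate(([t0], inner, [t1]))
    vv = profile.at(tt)
    return float(np.trapezoid(vv, tt)) / 24.0
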