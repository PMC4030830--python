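"""Glucose-unit (GU) calibration of HPLC retention times.

A ladder of PA-derivatized isomalto-oligosaccharides (glucose polymers,
degree of polymerization 1-20) is run on each column; a peak's retention
time is then expressed in glucose units by piecewise-linear interpolation
against the ladder. GU below DP 1 or above the last ladder point comes from
linear extrapolation of the terminal segment and is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GUCalibration",
    "GUResult",
    "CalibrationError",
    "fit_calibration",
    "time_to_gu",
    "gu_to_time",
    "load_ladder_csv",
]


class CalibrationError(ValueError):
    """Invalid calibration ladder."""


class GUResult(NamedTuple):
    value: float
    extrapolated: bool


def _interp_linear(x: float, xs: np.ndarray, ys: np.ndarray) -> float:
    """Piecewise-linear interpolation with terminal-segment extrapolation.

    ``xs`` strictly increasing.
    """
    if x <= xs[0]:
        i = 0
    elif x >= xs[-1]:
        i = len(xs) - 2
    else:
        i = int(np.searchsorted(xs, x, side="right")) - 1
    x0, x1 = xs[i], xs[i + 1]
    y0, y1 = ys[i], ys[i + 1]
    return float(y0 + (y1 - y0) * (x - x0) / (x1 - x0))


@dataclass(frozen=True)
class GUCalibration:
    """Monotone retention-time <-> GU mapping for one column run."""

    column: str
    dp: Tuple[float, ...]
    rt_min: Tuple[float, ...]

    def __post_init__(self) -> None:
        dp = np.asarray(self.dp, dtype=float)
        rt = np.asarray(self.rt_min, dtype=float)
        if dp.size < 2:
            raise CalibrationError("calibration ladder needs at least 2 points")
        if np.unique(dp).size != dp.size:
            raise CalibrationError("duplicate degree-of-polymerization values in ladder")
        order = np.argsort(dp)
        dp, rt = dp[order], rt[order]
        diffs = np.diff(rt)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise CalibrationError("ladder retention times are not strictly monotone in DP")
        object.__setattr__(self, "dp", tuple(dp))
        object.__setattr__(self, "rt_min", tuple(rt))

    @property
    def increasing(self) -> bool:
        return self.rt_min[1] > self.rt_min[0]

    def _axes_time(self) -> Tuple[np.ndarray, np.ndarray]:
        rt = np.asarray(self.rt_min)
        dp = np.asarray(self.dp)
        if not self.increasing:
            rt, dp = rt[::-1], dp[::-1]
        return rt, dp

    def time_to_gu(self, t: float, with_flag: bool = False):
        """Convert a retention time (min) to glucose units."""
        rt, dp = self._axes_time()
        gu = _interp_linear(float(t), rt, dp)
        extrapolated = not (rt[0] <= t <= rt[-1])
        if extrapolated:
            warnings.warn(
                f"retention time {t:g} min outside calibrated range of the "
                f"{self.column} ladder; GU extrapolated",
                stacklevel=2,
            )
        return GUResult(gu, extrapolated) if with_flag else gu

    def gu_to_time(self, gu: float, with_flag: bool = False):
        """Convert glucose units back to a retention time (min)."""
        dp = np.asarray(self.dp)
        rt = np.asarray(self.rt_min)
        t = _interp_linear(float(gu), dp, rt)
        extrapolated = not (dp[0] <= gu <= dp[-1])
        if extrapolated:
            warnings.warn(
                f"GU {gu:g} outside calibrated DP range of the {self.column} ladder; "
                "retention time extrapolated",
                stacklevel=2,
            )
        return GUResult(t, extrapolated) if with_flag else t


def fit_calibration(
    ladder: Iterable[Sequence[float]], column: str = "amide"
) -> GUCalibration:
    """Build a calibration from ``(dp, retention time)`` pairs."""
    pairs = [(float(n), float(t)) for n, t in ladder]
    return GUCalibration(
        column=column,
        dp=tuple(p[0] for p in pairs),
        rt_min=tuple(p[1] for p in pairs),
    )


def time_to_gu(cal: GUCalibration, t: float, with_flag: bool = False):
    return cal.time_to_gu(t, with_flag=with_flag)


def gu_to_time(cal: GUCalibration, gu: float, with_flag: bool = False):
    return cal.gu_to_time(gu, with_flag=with_flag)


def load_ladder_csv(path) -> list:
    """Read a ladder CSV with header columns ``dp`` and ``rt_min``."""
    df = pd.read_csv(Path(path))
    missing = {"dp", "rt_min"} - set(df.columns)
    if missing:
        raise CalibrationError(f"ladder CSV missing columns: {sorted(missing)}")
    return list(zip(df["dp"].astype(float), df["rt_min"].astype(float)))
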