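"""Arterial input function construction.

The metabolite-corrected plasma input is built in three steps: (1) the
continuous whole-blood detector curve is cross-calibrated against manual
arterial samples with a single multiplicative factor; (2) the parent
(unmetabolized) fraction measured in the manual samples is fitted with a
three-parameter Hill-type sigmoid PF(t) = 1 - a*t^b/(t^b + c), anchored at
PF(0) = 1; (3) the parent plasma curve is C_p(t) = C_wb(t) * R(t) * PF(t),
where R(t) is the plasma-to-whole-blood ratio interpolated through the
manual samples.
"""
from __future__ import annotations

import dataclasses
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .data import BloodSampleSet


@dataclasses.dataclass(frozen=True)
class HillParams:
    """Parent-fraction sigmoid: PF(t) = 1 - a*t^b/(t^b + c).

    ``a`` is the asymptotic metabolized fraction (plateau = 1 - a), ``b`` the
    steepness, ``c`` (units min^b) sets the half-conversion time c^(1/b).
    """

    a: float
    b: float
    c: float

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0):
            raise ValueError("a must lie in [0, 1]")
        if self.b <= 0 or self.c <= 0:
            raise ValueError("b and c must be positive")

    def parent_fraction(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tb = np.where(t > 0, t, 0.0) ** self.b
        return 1.0 - self.a * tb / (tb + self.c)


def evaluate_parent_fraction(hill: HillParams, t) -> np.ndarray:
    """Parent fraction at time(s) t (minutes, >= 0)."""
    return hill.parent_fraction(t)


def fit_parent_fraction(times, fractions, bounds=None, n_starts: int = 6) -> HillParams:
    """Bounded least-squares fit of the Hill sigmoid to measured parent fractions.

    PF(0)=1 is structural (built into the model), not an extra data point.
    Multi-started over a spread of steepness values; best residual wins.
    """
    times = np.asarray(times, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 parent-fraction samples")
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("parent fractions must lie in [0, 1]")
    lo, hi = bounds if bounds is not None else ((0.0, 1e-6, 1e-6), (1.0, 10.0, 1e6))

    def resid(x):
        return HillParams(*np.clip(x, lo, hi)).parent_fraction(times) - fractions

    tmid = float(np.median(times))
    best = None
    for b0 in np.geomspace(0.5, 8.0, n_starts):
        x0 = np.clip([1.0 - float(np.min(fractions)), b0, tmid**b0], lo, hi)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e-2 * times.size:
        raise RuntimeError("Hill fit did not converge")
    return HillParams(*best.x)


def calibrate_continuous_blood(
    continuous_time, continuous_activity, manual: BloodSampleSet
) -> tuple[float, np.ndarray]:
    """Single multiplicative cross-calibration of the detector curve.

    Returns the factor f minimizing sum (f*C_cont(t_j) - C_manual_j)^2 over the
    manual samples inside the detector's time span (closed form f =
    sum(x*y)/sum(x^2)), plus the per-sample residuals of the calibrated curve.
    """
    t = np.asarray(continuous_time, dtype=float)
    c = np.asarray(continuous_activity, dtype=float)
    inside = (manual.sample_time >= t[0]) & (manual.sample_time <= t[-1])
    if not np.any(inside):
        raise ValueError("no manual samples fall inside the continuous curve's span")
    x = np.interp(manual.sample_time[inside], t, c)
    y = manual.whole_blood_activity[inside]
    denom = float(np.sum(x * x))
    if denom == 0:
        raise ValueError("continuous curve is zero at all manual sample times")
    f = float(np.sum(x * y) / denom)
    if f <= 0:
        raise ValueError(f"non-positive calibration factor {f}")
    return f, f * x - y


class InputFunction:
    """Calibrated whole-blood and metabolite-corrected plasma curves.

    Both curves live on a shared sample grid (minutes) and are evaluated by
    piecewise-linear interpolation: zero before the first sample (the curves
    start at injection), constant after the last.
    """

    def __init__(self, times, whole_blood, parent_plasma, hill: HillParams,
                 ratio_times=None, ratio_values=None):
        self.times = np.asarray(times, dtype=float)
        self.whole_blood = np.asarray(whole_blood, dtype=float)
        self.parent_plasma = np.asarray(parent_plasma, dtype=float)
        self.hill = hill
        self.ratio_times = None if ratio_times is None else np.asarray(ratio_times, float)
        self.ratio_values = None if ratio_values is None else np.asarray(ratio_values, float)
        if self.times.shape != self.whole_blood.shape or self.times.shape != self.parent_plasma.shape:
            raise ValueError("times, whole_blood, parent_plasma must have equal shapes")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("input-function sample times must be strictly increasing")

    def plasma(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.parent_plasma, left=0.0)

    def blood(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.whole_blood, left=0.0)

    def ratio(self, t) -> np.ndarray:
        if self.ratio_times is None:
            return np.ones_like(np.asarray(t, dtype=float))
        return np.interp(t, self.ratio_times, self.ratio_values)

    @cached_property
    def _cum_plasma(self) -> np.ndarray:
        # leading triangle from (0, 0) to the first sample when it is not at 0
        lead = 0.5 * self.times[0] * self.parent_plasma[0]
        return lead + cumulative_trapezoid(self.parent_plasma, self.times, initial=0.0)

    @cached_property
    def _cum_blood(self) -> np.ndarray:
        lead = 0.5 * self.times[0] * self.whole_blood[0]
        return lead + cumulative_trapezoid(self.whole_blood, self.times, initial=0.0)

    @cached_property
    def _dbl_cum_plasma(self) -> np.ndarray:
        return cumulative_trapezoid(self._cum_plasma, self.times, initial=0.0)

    def cumulative_plasma(self, t) -> np.ndarray:
        """Integral of C_p from 0 to t (piecewise-linear-exact on the grid)."""
        return np.interp(t, self.times, self._cum_plasma, left=0.0)

    def cumulative_blood(self, t) -> np.ndarray:
        return np.interp(t, self.times, self._cum_blood, left=0.0)

    def double_cumulative_plasma(self, t) -> np.ndarray:
        """Integral from 0 to t of the running plasma integral."""
        return np.interp(t, self.times, self._dbl_cum_plasma, left=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "C_wb": self.whole_blood,
                "C_p": self.parent_plasma,
                "parent_fraction": self.hill.parent_fraction(self.times),
                "plasma_ratio": self.ratio(self.times),
            }
        )


def build_input(
    times,
    calibrated_whole_blood,
    manual: BloodSampleSet,
    hill: HillParams,
) -> InputFunction:
    """Assemble C_p(t) = C_wb(t) * R(t) * PF(t) on the detector grid.

    R(t) is the plasma-to-whole-blood ratio interpolated linearly through the
    manual samples with constant extrapolation outside their span.
    """
    times = np.asarray(times, dtype=float)
    cwb = np.asarray(calibrated_whole_blood, dtype=float)
    ratio = np.interp(times, manual.sample_time, manual.plasma_to_wholeblood_ratio)
    pf = hill.parent_fraction(times)
    return InputFunction(
        times, cwb, cwb * ratio * pf, hill,
        ratio_times=manual.sample_time, ratio_values=manual.plasma_to_wholeblood_ratio,
    )


def interpolate_input(inp: InputFunction, t) -> tuple[np.ndarray, np.ndarray]:
    """(C_p, C_wb) at time(s) t by the input's interpolation rule."""
    return inp.plasma(t), inp.blood(t)
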