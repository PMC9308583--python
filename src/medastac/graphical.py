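"""Linearized estimators (Patlak, Logan, MLAIR1/2) and SUV.

All four linearizations operate on the frame-midpoint samples of the TAC.
For an irreversible two-tissue system with blood volume the operational
MLAIR equations follow from integrating the tissue ODEs twice:

    MLAIR1: C_pet(T) = P1 C_wb(T) + P2 int C_wb + P3 int C_p
                        + P4 iint C_p + P5 int C_pet,       Ki = -P4/P5
    MLAIR2: int C_pet = b1 C_wb(T) + b2 int C_wb + b3 int C_p
                        + b4 iint C_p + b5 C_pet(T),        Ki = b4

with P1 = V_B, P5 = -(k2+k3), P4 = (1-V_B) Ki (k2+k3).  The reported Ki is
the apparent coefficient and therefore absorbs the (1-V_B) factor; pass
``vb`` to divide it out.  MLAIR2 reads Ki directly as a coefficient, which
is why it stays stable at voxel-level noise where the MLAIR1 ratio -P4/P5
becomes erratic.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats as sps
from scipy.integrate import cumulative_trapezoid

from .data import SubjectMeta, TimeActivityCurve
from .input_function import InputFunction


@dataclasses.dataclass
class GraphicalResult:
    method: str
    estimate: float          # Ki (patlak/mlair) or VT (logan)
    intercept: float | None
    coefficients: np.ndarray | None
    tstar: float | None
    n_points: int
    r2: float
    low_confidence: bool = False
    diverging: bool = False


@dataclasses.dataclass
class SuvValue:
    interval: tuple[float, float]
    suv: float  # g/cm^3


def cumulative_integral(values, grid) -> np.ndarray:
    """Running trapezoidal integral with a leading triangle from (0, 0).

    The first sample (t0, v0) contributes t0*v0/2, i.e. the signal is taken
    to rise linearly from zero at injection.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    lead = 0.5 * grid[0] * values[0]
    return lead + cumulative_trapezoid(values, grid, initial=0.0)


def frame_cumulative(tac: TimeActivityCurve) -> np.ndarray:
    """Cumulative tissue integral to each frame midpoint, frame-aware.

    TAC values are frame averages, so the integral to the end of frame i is
    exactly sum(avg_j * dt_j); the half-frame from start to midpoint
    contributes avg_i * dt_i / 2 (exact for a locally linear curve).  This is
    materially more accurate than midpoint trapezoids around the early
    5-10 s frames.
    """
    a = tac.activity
    d = tac.schedule.frame_duration
    ends = np.cumsum(a * d)
    return np.concatenate([[0.0], ends[:-1]]) + a * d / 2.0


def patlak(tac: TimeActivityCurve, inp: InputFunction, tstar: float = 20.0) -> GraphicalResult:
    """Patlak plot: C_pet(T)/C_p(T) vs int_0^T C_p / C_p(T); slope = Ki.

    Only frames with midpoint >= tstar enter the regression (equilibrium
    assumption); fewer than 3 such points flags the result low-confidence.
    """
    t = tac.schedule.midpoints
    use = t >= tstar
    if np.count_nonzero(use) < 2:
        raise ValueError(f"fewer than 2 frames with midpoint >= tstar={tstar}")
    cp = inp.plasma(t[use])
    if np.any(cp <= 0):
        raise ValueError("plasma activity must be positive over the Patlak window")
    x = inp.cumulative_plasma(t[use]) / cp
    y = tac.activity[use] / cp
    fit = sps.linregress(x, y)
    return GraphicalResult(
        "patlak", float(fit.slope), float(fit.intercept), None, tstar,
        int(np.count_nonzero(use)), float(fit.rvalue**2),
        low_confidence=np.count_nonzero(use) < 3,
    )


def logan(tac: TimeActivityCurve, inp: InputFunction, tstar: float = 20.0) -> GraphicalResult:
    """Logan plot: int C_pet/C_pet(T) vs int C_p/C_pet(T); slope = V_T.

    Flags divergence (no finite V_T) when the late slope still trends upward,
    as for an irreversible tracer.
    """
    t = tac.schedule.midpoints
    use = t >= tstar
    if np.count_nonzero(use) < 2:
        raise ValueError(f"fewer than 2 frames with midpoint >= tstar={tstar}")
    if np.any(tac.activity[use] <= 0):
        raise ValueError("tissue activity must be positive over the Logan window")
    cum_t = frame_cumulative(tac)
    x = inp.cumulative_plasma(t[use]) / tac.activity[use]
    y = cum_t[use] / tac.activity[use]
    fit = sps.linregress(x, y)
    diverging = False
    k = np.count_nonzero(use)
    if k >= 4:  # split-window slope comparison
        half = k // 2
        s1 = sps.linregress(x[:half], y[:half]).slope
        s2 = sps.linregress(x[half:], y[half:]).slope
        diverging = s2 > 1.05 * s1
    return GraphicalResult(
        "logan", float(fit.slope), float(fit.intercept), None, tstar,
        k, float(fit.rvalue**2), low_confidence=k < 3, diverging=diverging,
    )


def _mlair_design(tac, inp, include_blood_integral=True):
    t = tac.schedule.midpoints
    cpet = tac.activity
    cwb = inp.blood(t)
    icwb = inp.cumulative_blood(t)
    icp = inp.cumulative_plasma(t)
    iicp = inp.double_cumulative_plasma(t)
    icpet = frame_cumulative(tac)
    return t, cpet, icpet, cwb, icwb, icp, iicp


def mlair1(tac: TimeActivityCurve, inp: InputFunction,
           include_blood_integral: bool = True, vb: float | None = None) -> GraphicalResult:
    """Multilinear irreversible estimator using all frames; Ki = -P4/P5."""
    t, cpet, icpet, cwb, icwb, icp, iicp = _mlair_design(tac, inp)
    cols = [cwb, icwb, icp, iicp, icpet] if include_blood_integral else [cwb, icp, iicp, icpet]
    X = np.column_stack(cols)
    if t.size < X.shape[1]:
        raise ValueError("fewer frames than regressors")
    beta, *_ = np.linalg.lstsq(X, cpet, rcond=None)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient MLAIR1 design matrix")
    p4, p5 = beta[-2], beta[-1]
    if p5 == 0:
        raise ZeroDivisionError("P5 = 0: Ki undefined")
    ki = -p4 / p5
    if vb is not None:
        ki /= 1.0 - vb
    pred = X @ beta
    ss = np.sum((cpet - cpet.mean()) ** 2)
    r2 = 1.0 - float(np.sum((cpet - pred) ** 2)) / ss if ss > 0 else float("nan")
    return GraphicalResult("mlair1", float(ki), None, beta, None, t.size, r2)


def mlair2(tac: TimeActivityCurve, inp: InputFunction,
           include_blood_integral: bool = True, vb: float | None = None) -> GraphicalResult:
    """Rearranged multilinear estimator; Ki is the iint C_p coefficient itself."""
    t, cpet, icpet, cwb, icwb, icp, iicp = _mlair_design(tac, inp)
    cols = [cwb, icwb, icp, iicp, cpet] if include_blood_integral else [cwb, icp, iicp, cpet]
    X = np.column_stack(cols)
    if t.size < X.shape[1]:
        raise ValueError("fewer frames than regressors")
    beta, *_ = np.linalg.lstsq(X, icpet, rcond=None)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient MLAIR2 design matrix")
    ki = beta[-2]
    if vb is not None:
        ki /= 1.0 - vb
    pred = X @ beta
    ss = np.sum((icpet - icpet.mean()) ** 2)
    r2 = 1.0 - float(np.sum((icpet - pred) ** 2)) / ss if ss > 0 else float("nan")
    return GraphicalResult("mlair2", float(ki), None, beta, None, t.size, r2)


def suv(tac: TimeActivityCurve, interval: tuple[float, float], meta: SubjectMeta) -> SuvValue:
    """Standardized uptake value over a time window.

    Duration-weighted mean concentration (kBq/mL) over the window divided by
    net injected dose (kBq) per body weight (g); frames partially inside the
    window contribute their overlapping portion.
    """
    start, end = float(interval[0]), float(interval[1])
    sched = tac.schedule
    if start >= end:
        raise ValueError("interval start must precede end")
    if start < sched.frame_start[0] - 1e-9 or end > sched.frame_end[-1] + 1e-9:
        raise ValueError("interval not covered by the scan")
    edges = np.concatenate([sched.frame_start, sched.frame_end[-1:]])
    if not (np.any(np.isclose(edges, start, atol=1e-9)) and np.any(np.isclose(edges, end, atol=1e-9))):
        warnings.warn("SUV interval not aligned to frame boundaries; integrating partial frames")
    overlap = np.minimum(sched.frame_end, end) - np.maximum(sched.frame_start, start)
    overlap = np.clip(overlap, 0.0, None)
    mean_conc = float(np.sum(overlap * tac.activity) / np.sum(overlap))
    dose_kbq = meta.net_injected_dose_mbq * 1e3
    weight_g = meta.body_weight_kg * 1e3
    return SuvValue((start, end), mean_conc / (dose_kbq / weight_g))


def parametric_map(method: str, voxel_tacs: np.ndarray, schedule, inp: InputFunction,
                   meta: SubjectMeta | None = None, interval=(40.0, 50.0), **kw) -> np.ndarray:
    """Apply an estimator voxelwise to a (..., n_frames) array of TACs.

    Voxels that are all-NaN, or where the estimator fails, map to NaN.
    """
    arr = np.asarray(voxel_tacs, dtype=float)
    if arr.shape[-1] != schedule.n_frames:
        raise ValueError("last axis must match the number of frames")
    flat = arr.reshape(-1, schedule.n_frames)
    out = np.full(flat.shape[0], np.nan)
    for i, vox in enumerate(flat):
        if not np.all(np.isfinite(vox)):
            continue
        try:
            tac = TimeActivityCurve(schedule, vox, region_label=f"voxel{i}")
            if method == "mlair2":
                out[i] = mlair2(tac, inp, **kw).estimate
            elif method == "suv":
                out[i] = suv(tac, interval, meta).suv
            else:
                raise ValueError(f"unsupported voxel method {method!r}")
        except ValueError as exc:
            if "unsupported voxel method" in str(exc):
                raise
        except (np.linalg.LinAlgError, ZeroDivisionError):
            pass
    return out.reshape(arr.shape[:-1])
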