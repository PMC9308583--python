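"""Compartment-model simulation and weighted nonlinear fitting.

Models: the reversible one-tissue model (1T2k: K1, k2), the irreversible
(2T3k: K1, k2, k3) and reversible (2T4k: K1, k2, k3, k4) two-tissue models,
each with a fractional blood volume V_B.  The measured signal is

    C_pet(t) = (1 - V_B) * C_t(t) + V_B * C_wb(t)

and the tissue response is the standard sum of exponentials convolved with
the plasma input:

    1T2k:  C_t = K1 e^{-k2 t} (x) C_p
    2T:    C_t = K1/(th1-th2) [ (th1-k3-k4) e^{-th1 t} + (k3+k4-th2) e^{-th2 t} ] (x) C_p

with th1, th2 the roots of s^2 - (k2+k3+k4) s + k2 k4.  For k4 = 0 the slow
root is 0 and the exponential degenerates to the running plasma integral,
giving the familiar 2T3k form with net influx rate Ki = K1 k3/(k2+k3).

All convolutions are evaluated exactly for a piecewise-linear input, and the
predicted frame values are exact frame averages (time integral of C_pet over
the frame divided by its duration), not midpoint samples: the 5-10 s frames
around the blood peak make midpoint sampling materially biased.
"""
from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .data import FrameSchedule, TimeActivityCurve, TissueClass
from .input_function import InputFunction

log = logging.getLogger(__name__)

#: carbon-11 decay constant, min^-1
LAMBDA_C11 = math.log(2.0) / 20.34

MODELS = ("1T2k", "2T3k", "2T4k")
_MODEL_RATES = {"1T2k": ("K1", "k2"), "2T3k": ("K1", "k2", "k3"), "2T4k": ("K1", "k2", "k3", "k4")}
_PARAM_ORDER = ("K1", "k2", "k3", "k4", "VB")

DEFAULT_INIT = {"K1": 0.1, "k2": 0.1, "k3": 0.05, "k4": 0.01, "VB": 0.05}
DEFAULT_BOUNDS = {
    "K1": (1e-6, 2.0), "k2": (1e-6, 2.0), "k3": (1e-6, 2.0), "k4": (1e-6, 2.0),
    "VB": (0.0, 0.2),
}


@dataclasses.dataclass(frozen=True)
class KineticParams:
    """Rate constants; unused rates are zero for the reduced topologies."""

    K1: float  # mL cm^-3 min^-1
    k2: float  # min^-1
    k3: float = 0.0
    k4: float = 0.0
    VB: float = 0.0

    def __post_init__(self):
        for name in _PARAM_ORDER:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.VB >= 1:
            raise ValueError("VB must be < 1")

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in _PARAM_ORDER}


@dataclasses.dataclass(frozen=True)
class MacroParams:
    """Macroparameters; entries are None where the topology does not define them."""

    Ki: float | None = None      # K1 k3/(k2+k3), mL cm^-3 min^-1
    VT: float | None = None      # volume of distribution, mL cm^-3
    BPND: float | None = None    # k3/k4

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, v in dataclasses.asdict(self).items() if v is not None}


def macro_params(model: str, params: KineticParams) -> MacroParams:
    """Ki / V_T / BP_ND as defined by each model topology."""
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    if model == "1T2k":
        if k2 == 0:
            raise ZeroDivisionError("VT undefined for k2 = 0")
        return MacroParams(VT=K1 / k2)
    if model == "2T3k":
        if k2 + k3 == 0:
            raise ZeroDivisionError("Ki undefined for k2 + k3 = 0")
        return MacroParams(Ki=K1 * k3 / (k2 + k3))
    if model == "2T4k":
        if k4 == 0 or k2 == 0:
            raise ZeroDivisionError("VT/BPND undefined for k2 = 0 or k4 = 0")
        return MacroParams(
            Ki=K1 * k3 / (k2 + k3) if k2 + k3 > 0 else None,
            VT=(K1 / k2) * (1.0 + k3 / k4),
            BPND=k3 / k4,
        )
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Exact piecewise-linear convolution machinery

def _phi(theta: float, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """phi1 = int_0^h e^{-theta(h-u)} du, phi2 = int_0^h e^{-theta(h-u)} u du."""
    x = theta * h
    small = x < 1e-4
    with np.errstate(over="ignore"):
        p1 = np.where(small, h * (1 - x / 2 + x * x / 6 - x**3 / 24), -np.expm1(-x) / theta)
        p2 = np.where(
            small,
            h * h * (0.5 - x / 6 + x * x / 24 - x**3 / 120),
            (h - p1) / theta,
        )
    return p1, p2


def exp_conv(theta: float, t: np.ndarray, c: np.ndarray) -> np.ndarray:
    """E(t_k) = int_0^{t_k} e^{-theta (t_k - s)} c(s) ds for piecewise-linear c.

    Exact per segment; evaluated at every grid point.  theta = 0 reduces to
    the cumulative trapezoid.
    """
    if theta < 1e-12:
        return cumulative_trapezoid(c, t, initial=0.0)
    h = np.diff(t)
    c0 = c[:-1]
    b = np.diff(c) / h
    p1, p2 = _phi(theta, h)
    seg = c0 * p1 + b * p2  # exact contribution of segment j at its right end
    w = theta * t[1:]
    if w[-1] < 600.0:
        E1 = np.exp(-w) * np.cumsum(seg * np.exp(w))
    else:  # chunked renormalization for extreme theta*t
        E1 = np.empty_like(seg)
        acc = 0.0
        decay = np.exp(-theta * h)
        for j in range(seg.size):
            acc = acc * decay[j] + seg[j]
            E1[j] = acc
    return np.concatenate([[0.0], E1])


class PreparedInput:
    """Input curves resampled on the union of their grid and frame boundaries.

    Precomputes everything fit iterations reuse: segment geometry, cumulative
    integrals at frame boundaries, and the whole-blood frame averages.
    """

    def __init__(self, inp: InputFunction, schedule: FrameSchedule):
        t_end = float(schedule.frame_end[-1])
        bounds = np.concatenate([schedule.frame_start, [t_end]])
        knots = inp.times[(inp.times >= 0.0) & (inp.times <= t_end + 1e-12)]
        grid = np.union1d(np.union1d(knots, bounds), [0.0])
        if grid[-1] < t_end - 1e-9:
            raise ValueError("input function does not span the scan")
        self.t = grid
        self.cp = inp.plasma(grid)
        self.cwb = inp.blood(grid)
        self.h = np.diff(grid)
        self.durations = schedule.frame_duration
        self.i_lo = np.searchsorted(grid, schedule.frame_start)
        self.i_hi = np.searchsorted(grid, schedule.frame_end)
        self.cp_cum = cumulative_trapezoid(self.cp, grid, initial=0.0)
        cwb_cum = cumulative_trapezoid(self.cwb, grid, initial=0.0)
        self.cwb_frame_avg = (cwb_cum[self.i_hi] - cwb_cum[self.i_lo]) / self.durations
        # cumulative double integral of cp: exact for piecewise-linear cp
        c0 = self.cp[:-1]
        b = np.diff(self.cp) / self.h
        d = self.cp_cum[:-1] * self.h + c0 * self.h**2 / 2.0 + b * self.h**3 / 6.0
        self.cp_dblcum = np.concatenate([[0.0], np.cumsum(d)])

    def _frame_int_conv(self, theta: float) -> np.ndarray:
        """Frame integrals of E_theta = e^{-theta t} (x) C_p (exact)."""
        if theta < 1e-12:
            return self.cp_dblcum[self.i_hi] - self.cp_dblcum[self.i_lo]
        E = exp_conv(theta, self.t, self.cp)
        # dE/dt = C_p - theta E  =>  int E = (int C_p - dE) / theta
        d_cp = self.cp_cum[self.i_hi] - self.cp_cum[self.i_lo]
        d_e = E[self.i_hi] - E[self.i_lo]
        return (d_cp - d_e) / theta

    def tissue_frame_avg(self, model: str, K1: float, k2: float, k3: float, k4: float) -> np.ndarray:
        """Frame-averaged tissue response C_t (no blood-volume term)."""
        if model == "1T2k" or (k3 == 0.0 and k4 == 0.0):
            return K1 * self._frame_int_conv(k2) / self.durations
        s = k2 + k3 + k4
        disc = s * s - 4.0 * k2 * k4
        root = math.sqrt(max(disc, 0.0))
        th1 = 0.5 * (s + root)
        th2 = 0.5 * (s - root)
        if th1 - th2 < 1e-8 * max(th1, 1e-12):
            # repeated eigenvalue: symmetric split approximates the confluent
            # t*e^{-theta t} limit with ~1e-12 relative formula error
            delta = 1e-6 * max(th1, 1e-6)
            th1, th2 = th1 + delta, max(th2 - delta, 0.0)
        a1 = K1 * (th1 - k3 - k4) / (th1 - th2)
        a2 = K1 * (k3 + k4 - th2) / (th1 - th2)
        out = a1 * self._frame_int_conv(th1) + a2 * self._frame_int_conv(th2)
        return out / self.durations

    def pet_frame_avg(self, model: str, p: KineticParams) -> np.ndarray:
        ct = self.tissue_frame_avg(model, p.K1, p.k2, p.k3, p.k4)
        return (1.0 - p.VB) * ct + p.VB * self.cwb_frame_avg


def model_tissue_curve(
    model: str,
    params: KineticParams,
    inp: InputFunction | PreparedInput,
    schedule: FrameSchedule,
    region_label: str = "model",
    tissue_class: TissueClass = TissueClass.OTHER,
) -> TimeActivityCurve:
    """Simulate a frame-averaged PET TAC for the given model and parameters."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    prep = inp if isinstance(inp, PreparedInput) else PreparedInput(inp, schedule)
    return TimeActivityCurve(schedule, prep.pet_frame_avg(model, params), region_label, tissue_class)


# ---------------------------------------------------------------------------
# Weighted nonlinear fitting

def frame_weights(schedule: FrameSchedule, mode: str = "decay_duration") -> np.ndarray:
    """Per-frame fit weights, normalized to mean 1.

    ``decay_duration``: w_i proportional to dt_i * exp(-lambda * t_mid,i),
    the count-statistics weighting for decay-corrected frames of a C-11 scan.
    """
    if mode == "uniform":
        w = np.ones(schedule.n_frames)
    elif mode == "decay_duration":
        w = schedule.frame_duration * np.exp(-LAMBDA_C11 * schedule.midpoints)
    else:
        raise ValueError(f"unknown weights mode {mode!r}")
    return w / w.mean()


def aic(n: int, wrss: float, m: int) -> float:
    """Akaike information criterion n*ln(wrss/n) + 2m (no small-sample term)."""
    if n <= m:
        raise ValueError("need n > m")
    if wrss < 0:
        raise ValueError("wrss must be non-negative")
    if wrss == 0:
        warnings.warn("wrss = 0: AIC is -inf")
        return -math.inf
    return n * math.log(wrss / n) + 2 * m


@dataclasses.dataclass
class FitResult:
    model: str
    params: KineticParams
    fixed: dict[str, float]
    macro: MacroParams
    se: dict[str, float]
    se_percent: dict[str, float]
    wrss: float
    r2: float
    aic: float
    n_frames: int
    n_free: int
    success: bool
    k1k2_ratio: float | None = None


def percent_se(fit: FitResult, which: str) -> float:
    """100 * SE / |estimate| for a free parameter or macroparameter."""
    if which not in fit.se_percent:
        raise KeyError(f"{which!r} is not a free parameter or macroparameter of this fit")
    return fit.se_percent[which]


def _macro_vector(model: str, params: KineticParams) -> dict[str, float]:
    try:
        return macro_params(model, params).as_dict()
    except ZeroDivisionError:
        return {}


def fit_model(
    tac: TimeActivityCurve,
    inp: InputFunction | PreparedInput,
    model: str = "2T3k",
    fixed: dict[str, float] | None = None,
    weights_mode: str = "decay_duration",
    init: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    k1k2_ratio: float | None = None,
    n_starts: int = 5,
    jitter_seed: int = 0,
) -> FitResult:
    """Bounded weighted nonlinear least-squares fit of a compartment model.

    ``fixed`` pins named parameters (e.g. ``{"VB": 0.02}``).  ``k1k2_ratio``
    reparameterizes with K1 free and k2 = K1/ratio (the "K1/k2 fixed to the
    whole-brain white-matter value" mode).  Standard errors come from the
    scaled inverse Gauss-Newton Hessian at the optimum; macroparameter SEs by
    the first-order delta method.  Multi-start with jittered initials guards
    against local minima; a singular information matrix yields infinite SEs
    rather than a failure.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    fixed = dict(fixed or {})
    schedule = tac.schedule
    prep = inp if isinstance(inp, PreparedInput) else PreparedInput(inp, schedule)
    w = frame_weights(schedule, weights_mode)
    sw = np.sqrt(w)
    y = tac.activity

    names = list(_MODEL_RATES[model]) + ["VB"]
    if k1k2_ratio is not None:
        if "k2" in fixed or k1k2_ratio <= 0:
            raise ValueError("k1k2_ratio must be positive and k2 not otherwise fixed")
        names.remove("k2")
    free_names = [n for n in names if n not in fixed]
    if schedule.n_frames < len(free_names) + 1:
        raise ValueError("fewer frames than free parameters + 1")

    init_all = {**DEFAULT_INIT, **(init or {})}
    bounds_all = {**DEFAULT_BOUNDS, **(bounds or {})}
    lo = np.array([bounds_all[n][0] for n in free_names])
    hi = np.array([bounds_all[n][1] for n in free_names])
    x0 = np.clip([init_all[n] for n in free_names], lo, hi)

    def unpack(x) -> KineticParams:
        d = {n: 0.0 for n in _PARAM_ORDER}
        d.update(fixed)
        d.update(dict(zip(free_names, x)))
        if k1k2_ratio is not None:
            d["k2"] = d["K1"] / k1k2_ratio
        return KineticParams(**d)

    def resid(x):
        return sw * (prep.pet_frame_avg(model, unpack(x)) - y)

    rng = np.random.default_rng(jitter_seed)
    best = None
    for start in range(max(1, n_starts)):
        xs = x0 if start == 0 else np.clip(x0 * rng.lognormal(0.0, 0.6, x0.size), lo, hi)
        try:
            sol = least_squares(resid, xs, bounds=(lo, hi), method="trf", x_scale=np.maximum(x0, 1e-3))
        except Exception as exc:  # pragma: no cover - defensive
            log.debug("fit start %d failed: %s", start, exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"{model} fit failed to converge from any start")

    x = best.x
    params = unpack(x)
    pred = prep.pet_frame_avg(model, params)
    res = pred - y
    wrss = float(np.sum(w * res * res))
    n, m = schedule.n_frames, len(free_names)

    # covariance of the free parameters from the weighted Jacobian
    J = best.jac
    dof = max(n - m, 1)
    s2 = wrss / dof
    jtj = J.T @ J
    u, sv, vt = np.linalg.svd(jtj)
    tol = sv.max() * max(jtj.shape) * np.finfo(float).eps if sv.size else 0.0
    rank_ok = sv > tol
    inv = vt.T @ np.diag(np.where(rank_ok, 1.0 / np.where(rank_ok, sv, 1.0), 0.0)) @ u.T
    cov = s2 * inv
    se = {}
    for i, name in enumerate(free_names):
        if np.all(rank_ok):
            se[name] = float(np.sqrt(max(cov[i, i], 0.0)))
        else:
            se[name] = math.inf

    macro = macro_params(model, params) if _macro_vector(model, params) else MacroParams()
    macro_se: dict[str, float] = {}
    base_macro = _macro_vector(model, params)
    if base_macro and np.all(np.isfinite(list(se.values()) or [0.0])):
        # delta method: numerical gradient of each macroparameter w.r.t. x
        grads = {k: np.zeros(m) for k in base_macro}
        for i in range(m):
            step = 1e-6 * max(abs(x[i]), 1e-6)
            e = step * np.eye(m)[i]
            xp = np.clip(x + e, lo, hi)  # stay inside bounds at the edges
            xm = np.clip(x - e, lo, hi)
            denom = xp[i] - xm[i]
            if denom == 0:
                continue
            mp = _macro_vector(model, unpack(xp))
            mm = _macro_vector(model, unpack(xm))
            for k in base_macro:
                if k in mp and k in mm:
                    grads[k][i] = (mp[k] - mm[k]) / denom
        for k, g in grads.items():
            macro_se[k] = float(np.sqrt(max(g @ cov @ g, 0.0)))
    elif base_macro:
        macro_se = {k: math.inf for k in base_macro}

    def pct(est, sd):
        if not math.isfinite(sd):
            return math.inf
        return math.inf if est == 0 else 100.0 * sd / abs(est)

    se_percent = {nme: pct(getattr(params, nme), sd) for nme, sd in se.items()}
    for k, v in base_macro.items():
        se_percent[k] = pct(v, macro_se.get(k, math.inf))
        se[k] = macro_se.get(k, math.inf)

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res * res)) / ss_tot if ss_tot > 0 else float("nan")
    return FitResult(
        model=model,
        params=params,
        fixed=fixed,
        macro=macro,
        se=se,
        se_percent=se_percent,
        wrss=wrss,
        r2=r2,
        aic=aic(n, wrss, m) if wrss > 0 else -math.inf,
        n_frames=n,
        n_free=m,
        success=bool(best.success),
        k1k2_ratio=k1k2_ratio,
    )
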