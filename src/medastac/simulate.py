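"""Synthetic dynamic-PET studies with known ground truth.

The generator emulates the study conditions of a 60-min, 26-frame dynamic
brain acquisition of a fast-metabolizing C-11 tracer with arterial sampling:

* a tri-exponential (Feng-type) arterial whole-blood curve sampled densely
  (1 s) over the first 5 min and at 5 s afterwards, mimicking the two-speed
  withdrawal of an online detector;
* five manual samples at 10/20/30/45/60 min carrying the whole-blood
  activity, the plasma-to-whole-blood ratio, and the parent fraction;
* a Hill-type parent fraction falling to ~19% at 10 min and plateauing
  near 5%;
* per-region kinetic truths drawn from log-normal class distributions whose
  net influx rates are anchored to the reported whole-brain means
  (GM Ki 0.064 +/- 0.018, WM 0.113 +/- 0.031 mL min^-1 cm^-3) and lesion
  class means (BH 0.072, DM 0.079, PM 0.085, RM 0.102);
* frame noise with variance proportional to activity, decay, and inverse
  frame duration, the standard count-statistics model.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from . import kinetics
from .data import (
    DEFAULT_FRAMING,
    BloodSampleSet,
    FrameSchedule,
    StudyDataset,
    SubjectData,
    SubjectMeta,
    TimeActivityCurve,
    TissueClass,
    parse_frame_schedule,
)
from .input_function import HillParams, InputFunction, build_input
from .kinetics import LAMBDA_C11, KineticParams, PreparedInput
from .stats import MYELIN_ORDER, LesionClass

GENERATOR_VERSION = "1.0"


@dataclasses.dataclass(frozen=True)
class InputModelParams:
    """Tri-exponential arterial model: fast spike plus two washout terms."""

    A1: float = 600.0   # kBq mL^-1 min^-1
    A2: float = 12.0    # kBq mL^-1
    A3: float = 16.0    # kBq mL^-1
    l1: float = 4.0     # min^-1
    l2: float = 0.25    # min^-1
    l3: float = 0.012   # min^-1
    delay: float = 0.5  # minutes

    def __post_init__(self):
        if not (self.l1 > self.l2 > self.l3 > 0):
            raise ValueError("need l1 > l2 > l3 > 0")


def feng_input(p: InputModelParams, grid) -> np.ndarray:
    """C(t) = (A1 (t-tau) - A2 - A3) e^{-l1 (t-tau)} + A2 e^{-l2 (t-tau)} + A3 e^{-l3 (t-tau)}.

    Zero for t <= tau; continuous at the arrival time tau by construction.
    """
    t = np.asarray(grid, dtype=float) - p.delay
    t = np.where(t > 0, t, 0.0)
    c = (
        (p.A1 * t - p.A2 - p.A3) * np.exp(-p.l1 * t)
        + p.A2 * np.exp(-p.l2 * t)
        + p.A3 * np.exp(-p.l3 * t)
    )
    return np.where(np.asarray(grid, dtype=float) > p.delay, c, 0.0)


#: Default Hill parameters: parent fraction 0.194 at 10 min, 0.055 at 60 min.
DEFAULT_HILL = HillParams(a=0.95, b=2.0, c=17.86)

#: Plasma-to-whole-blood ratio (no reported value; constant is typical for
#: tracers without strong cell uptake kinetics).
DEFAULT_PLASMA_RATIO = 1.1

MANUAL_SAMPLE_TIMES = np.array([10.0, 20.0, 30.0, 45.0, 60.0])


def generate_blood_data(
    p: InputModelParams = InputModelParams(),
    hill: HillParams = DEFAULT_HILL,
    ratio: float = DEFAULT_PLASMA_RATIO,
    detector_noise: float = 0.0,
    miscalibration: float = 0.9,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, BloodSampleSet]:
    """Continuous detector curve plus the five manual arterial samples.

    The continuous curve is the true whole-blood curve scaled by
    ``miscalibration`` (detector vs well-counter cross-calibration error), so
    the calibration step has real work to do; the manual samples are exact
    (well-counter) unless ``detector_noise`` adds relative Gaussian noise to
    the continuous curve.
    """
    rng = np.random.default_rng(seed)
    grid = np.concatenate([np.arange(0.0, 5.0, 1.0 / 60.0), np.arange(5.0, 60.0 + 1e-9, 5.0 / 60.0)])
    wb_true = feng_input(p, grid)
    continuous = miscalibration * wb_true
    if detector_noise > 0:
        continuous = continuous + detector_noise * np.abs(continuous) * rng.standard_normal(grid.size)
    samples = BloodSampleSet(
        MANUAL_SAMPLE_TIMES,
        feng_input(p, MANUAL_SAMPLE_TIMES),
        np.full(MANUAL_SAMPLE_TIMES.size, ratio),
        hill.parent_fraction(MANUAL_SAMPLE_TIMES),
    )
    return grid, continuous, samples


def true_input_function(
    p: InputModelParams = InputModelParams(),
    hill: HillParams = DEFAULT_HILL,
    ratio: float = DEFAULT_PLASMA_RATIO,
) -> InputFunction:
    """Noise-free, correctly calibrated input function (for oracles and truth)."""
    grid, continuous, samples = generate_blood_data(p, hill, ratio, 0.0, 1.0, 0)
    return build_input(grid, continuous, samples, hill)


def add_noise(tac: TimeActivityCurve, alpha: float, seed: int = 0) -> TimeActivityCurve:
    """Frame noise: sd_i = alpha * sqrt(max(C_i,0) e^{lambda t_mid}/dt_i).

    Variance grows for short frames and late (decay-weighted) times, the
    qualitative structure of decay-corrected PET frames.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        return TimeActivityCurve(tac.schedule, tac.activity.copy(), tac.region_label, tac.tissue_class)
    rng = np.random.default_rng(seed)
    sched = tac.schedule
    sd = noise_sd(tac.activity, sched, alpha)
    noisy = tac.activity + sd * rng.standard_normal(sched.n_frames)
    return TimeActivityCurve(sched, noisy, tac.region_label, tac.tissue_class)


def noise_sd(activity, schedule: FrameSchedule, alpha: float) -> np.ndarray:
    return alpha * np.sqrt(
        np.maximum(np.asarray(activity, float), 0.0)
        * np.exp(LAMBDA_C11 * schedule.midpoints)
        / schedule.frame_duration
    )


def alpha_for_cv(tac: TimeActivityCurve, target_cv: float) -> float:
    """Alpha giving a duration-weighted mean relative noise of target_cv
    over the frames after the first minute (where the TAC is established)."""
    sched = tac.schedule
    late = sched.midpoints >= 1.0
    sd1 = noise_sd(tac.activity, sched, 1.0)[late]
    c = np.abs(tac.activity[late])
    w = sched.frame_duration[late]
    mean_rel = float(np.sum(w * sd1 / np.maximum(c, 1e-12)) / np.sum(w))
    return target_cv / mean_rel


# --------------------------------------------------------------------------
# Cohort-level truth distributions

@dataclasses.dataclass(frozen=True)
class ClassKinetics:
    """Log-normal hyperparameters (mean, sd on the natural scale) for one
    tissue class.  k3 is derived from the drawn Ki, K1, k2 via
    k3 = Ki k2 / (K1 - Ki), so the class Ki distribution hits its anchor."""

    ki_mean: float
    ki_sd: float
    k1_mean: float
    k1_sd: float
    k2_mean: float
    k2_sd: float
    vb_mean: float
    vb_sd: float
    k4_mean: float = 0.0  # only used when the truth model is 2T4k


DEFAULT_CLASS_KINETICS: dict[str, ClassKinetics] = {
    # GM: high influx, fast washout; WM: lower influx, slow washout with
    # strong trapping (myelin binding).  Ki anchors from the whole-brain
    # GM/WM means; lesion classes from the lesion-vs-NAWM table.
    "GM": ClassKinetics(0.064, 0.018, 0.40, 0.06, 0.50, 0.08, 0.05, 0.010),
    "WM": ClassKinetics(0.113, 0.031, 0.25, 0.04, 0.18, 0.03, 0.02, 0.005),
    "NAWM": ClassKinetics(0.105, 0.045, 0.25, 0.04, 0.18, 0.03, 0.02, 0.005),
    "BH": ClassKinetics(0.072, 0.035, 0.25, 0.04, 0.18, 0.03, 0.02, 0.005),
    "DM": ClassKinetics(0.079, 0.038, 0.25, 0.04, 0.18, 0.03, 0.02, 0.005),
    "PM": ClassKinetics(0.085, 0.042, 0.25, 0.04, 0.18, 0.03, 0.02, 0.005),
    "RM": ClassKinetics(0.102, 0.054, 0.25, 0.04, 0.18, 0.03, 0.02, 0.005),
}

#: reported lesion-class sizes (black holes / demyelinated / partial / remyelinated)
DEFAULT_LESION_COUNTS = {"BH": 105, "DM": 111, "PM": 69, "RM": 7}

_CLASS_TO_TISSUE = {
    "GM": TissueClass.GM, "WM": TissueClass.WM, "NAWM": TissueClass.NAWM,
    "BH": TissueClass.LESION, "DM": TissueClass.LESION,
    "PM": TissueClass.LESION, "RM": TissueClass.LESION,
}
_CLASS_TO_LESION = {
    "BH": LesionClass.BLACK_HOLE, "DM": LesionClass.DEMYELINATED,
    "PM": LesionClass.PARTIALLY_MYELINATED, "RM": LesionClass.REMYELINATED,
}
# descriptor templates consistent with each class (volumes in mL from the
# reported per-class averages)
_DESCRIPTOR_TEMPLATE = {
    "BH": dict(t1_class="iso_to_CSF", vol_ratio=1.0, mean_vol=0.17),
    "DM": dict(t1_class="hypointense", vol_ratio=1.0, mean_vol=0.34),
    "PM": dict(t1_class="hypointense", vol_ratio=0.5, mean_vol=0.10),
    "RM": dict(t1_class="iso_to_NAWM", vol_ratio=1.0, mean_vol=0.04),
}


@dataclasses.dataclass
class CohortSpec:
    n_hc: int = 6
    n_ms: int = 9
    class_kinetics: Mapping[str, ClassKinetics] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_KINETICS))
    lesion_counts: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LESION_COUNTS))
    n_gm_regions: int = 5
    n_wm_regions: int = 5
    noise_alpha: float = 0.3
    truth_model: str = "2T3k"   # or 1T2k / 2T4k, for model-selection tests
    framing: str = DEFAULT_FRAMING
    seed: int = 0

    def __post_init__(self):
        if self.n_hc < 0 or self.n_ms < 0 or self.noise_alpha < 0:
            raise ValueError("counts and noise_alpha must be non-negative")
        if self.truth_model not in kinetics.MODELS:
            raise ValueError(f"unknown truth model {self.truth_model}")


def _lognormal(rng, mean, sd, size=None):
    """Draws with the given natural-scale mean and sd."""
    if sd == 0:
        return np.full(size, mean) if size is not None else mean
    s2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), size)


def draw_class_params(rng, ck: ClassKinetics, truth_model: str = "2T3k") -> tuple[KineticParams, float]:
    """One region's kinetic truth; returns (params, true Ki)."""
    k1 = float(_lognormal(rng, ck.k1_mean, ck.k1_sd))
    k2 = float(_lognormal(rng, ck.k2_mean, ck.k2_sd))
    vb = float(np.clip(_lognormal(rng, ck.vb_mean, ck.vb_sd), 0.0, 0.15))
    if truth_model == "1T2k":
        return KineticParams(K1=k1, k2=k2, VB=vb), 0.0
    ki = float(_lognormal(rng, ck.ki_mean, ck.ki_sd))
    ki = min(ki, 0.7 * k1)  # keep k3 finite; clips <~2 sigma tails
    k3 = ki * k2 / (k1 - ki)
    k4 = 0.0
    if truth_model == "2T4k":
        k4 = float(_lognormal(rng, max(ck.k4_mean, 0.02), max(ck.k4_mean, 0.02) * 0.3))
    return KineticParams(K1=k1, k2=k2, k3=k3, k4=k4, VB=vb), ki


def generate_subject(
    spec: CohortSpec,
    subject_index: int,
    cohort: str = "HC",
    seed: int | None = None,
) -> tuple[SubjectData, pd.DataFrame]:
    """One subject's dataset (blood + region/lesion TACs) and its truth table."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng([seed, subject_index, 0 if cohort == "HC" else 1])
    schedule = parse_frame_schedule(spec.framing)

    if cohort == "HC":
        dose = float(np.clip(rng.normal(203.0, 46.0), 80.0, 400.0))
    else:
        dose = float(np.clip(rng.normal(209.0, 35.0), 80.0, 400.0))
    weight = float(np.clip(rng.normal(75.0, 12.0), 45.0, 120.0))
    meta = SubjectMeta(dose, weight, cohort, f"{cohort}{subject_index:02d}")

    # subject-specific arterial curve: blood concentration scales with the
    # injected dose per body size, with residual physiological jitter in the
    # amplitudes (cardiovascular throughput, clearance) and arrival delay
    base = InputModelParams()
    amp = (dose / 203.0) / (weight / 75.0)
    l2 = float(_lognormal(rng, base.l2, base.l2 * 0.15))
    l3 = float(_lognormal(rng, base.l3, base.l3 * 0.15))
    p = InputModelParams(
        A1=float(_lognormal(rng, amp * base.A1, amp * base.A1 * 0.15)),
        A2=float(_lognormal(rng, amp * base.A2, amp * base.A2 * 0.15)),
        A3=float(_lognormal(rng, amp * base.A3, amp * base.A3 * 0.15)),
        l1=base.l1, l2=min(l2, 0.9 * base.l1), l3=min(l3, 0.9 * l2),
        delay=float(rng.uniform(0.3, 0.7)),
    )
    # subject-level metabolism spread: the half-conversion scale c varies so
    # that the 10-min parent fraction spreads ~0.19 +/- 0.07 across subjects
    hill = HillParams(DEFAULT_HILL.a, DEFAULT_HILL.b,
                      float(_lognormal(rng, DEFAULT_HILL.c, 0.5 * DEFAULT_HILL.c)))
    miscal = float(rng.uniform(0.8, 1.2))
    grid, continuous, samples = generate_blood_data(
        p, hill, DEFAULT_PLASMA_RATIO, 0.0, miscal, int(rng.integers(2**31)))
    truth_inp = build_input(grid, feng_input(p, grid), samples, hill)
    prep = PreparedInput(truth_inp, schedule)

    regions: list[tuple[str, str]] = [("whole_brain_GM", "GM"), ("whole_brain_WM", "WM")]
    regions += [(f"GM_region_{i}", "GM") for i in range(1, spec.n_gm_regions)]
    regions += [(f"WM_region_{i}", "WM") for i in range(1, spec.n_wm_regions)]
    lesion_rows = []
    if cohort == "MS":
        for cls, n_total in spec.lesion_counts.items():
            n_here = int(round(n_total / max(spec.n_ms, 1)))
            for j in range(n_here):
                regions.append((f"{cls}_lesion_{j}", cls))
                regions.append((f"NAWM_for_{cls}_{j}", "NAWM"))
                tmpl = _DESCRIPTOR_TEMPLATE[cls]
                vol_flair = float(_lognormal(rng, tmpl["mean_vol"], tmpl["mean_vol"] * 0.6))
                lesion_rows.append({
                    "lesion_id": f"{meta.subject_id}_{cls}_{j}",
                    "region": f"{cls}_lesion_{j}",
                    "flair_hyper": True,
                    "t1_class": tmpl["t1_class"],
                    "gd_hyper": False,
                    "vol_t1_ml": vol_flair * tmpl["vol_ratio"],
                    "vol_flair_ml": vol_flair,
                    "max_diam_mm": float(rng.uniform(4.0, 15.0)),
                    "nawm_region": f"NAWM_for_{cls}_{j}",
                    "true_class": _CLASS_TO_LESION[cls].value,
                })

    tacs, truth = [], []
    for label, cls in regions:
        params, ki = draw_class_params(rng, spec.class_kinetics[cls], spec.truth_model)
        clean = TimeActivityCurve(
            schedule, prep.pet_frame_avg(spec.truth_model, params), label, _CLASS_TO_TISSUE[cls])
        noisy = add_noise(clean, spec.noise_alpha, int(rng.integers(2**31)))
        tacs.append(noisy)
        truth.append({
            "subject": meta.subject_id, "region": label, "tissue_class": cls,
            "model": spec.truth_model, **params.as_dict(), "Ki": ki,
        })
    subject = SubjectData(
        meta, tacs, grid, continuous, samples,
        lesions=pd.DataFrame(lesion_rows) if lesion_rows else None,
    )
    return subject, pd.DataFrame(truth)


def generate_cohort(spec: CohortSpec) -> tuple[StudyDataset, pd.DataFrame]:
    """Full study: n_hc healthy controls and n_ms patients, plus truth table."""
    subjects, truths = {}, []
    for i in range(spec.n_hc):
        s, t = generate_subject(spec, i, "HC")
        subjects[s.meta.subject_id] = s
        truths.append(t)
    for i in range(spec.n_ms):
        s, t = generate_subject(spec, i, "MS")
        subjects[s.meta.subject_id] = s
        truths.append(t)
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    ds = StudyDataset(subjects, provenance={"seed": spec.seed, "generator": GENERATOR_VERSION})
    return ds, truth
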