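"""Core containers and table I/O for dynamic PET time-activity data.

Internal conventions: time is in minutes, rate constants in min^-1, activity
concentration in kBq/mL decay-corrected to injection time.  Frame schedules
are carried in seconds in files (as scanners print them) and converted to
minutes at parse time.  Frames are half-open intervals [start, start+dur).
"""
from __future__ import annotations

import dataclasses
import enum
import json
import logging
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: 26-frame, 60-min acquisition used throughout: durations in seconds.
DEFAULT_FRAMING = "1x10,10x5,1x10,2x30,3x60,2x150,4x300,3x600"


class TissueClass(str, enum.Enum):
    GM = "GM"
    WM = "WM"
    LESION = "lesion"
    PERI_LESION = "peri-lesion"
    NAWM = "NAWM"
    WHOLE_BLOOD = "whole-blood"
    OTHER = "other"


@dataclasses.dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping frame timing of a dynamic scan (minutes)."""

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or start.shape != dur.shape or start.size < 1:
            raise ValueError("frame_start and frame_duration must be equal-length 1-D arrays with >= 1 frame")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1], rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def midpoints(self) -> np.ndarray:
        return self.frame_start + self.frame_duration / 2.0

    @property
    def total_duration(self) -> float:
        return float(self.frame_end[-1] - self.frame_start[0])

    @classmethod
    def from_spec(cls, spec: str, start: float = 0.0) -> "FrameSchedule":
        """Parse a ``"NxS,NxS,..."`` framing string (durations in seconds)."""
        durations_s: list[float] = []
        for token in spec.split(","):
            m = re.fullmatch(r"\s*(\d+)\s*x\s*([0-9.]+)\s*", token)
            if not m:
                raise ValueError(f"malformed framing token {token!r}")
            n, dur = int(m.group(1)), float(m.group(2))
            if n < 1 or dur <= 0:
                raise ValueError(f"framing token {token!r} must have count >= 1 and duration > 0")
            durations_s.extend([dur] * n)
        dur_min = np.asarray(durations_s) / 60.0
        starts = start + np.concatenate([[0.0], np.cumsum(dur_min)[:-1]])
        return cls(starts, dur_min)

    def to_spec(self) -> str:
        """Serialize back to the ``NxS`` grammar (seconds, run-length encoded)."""
        dur_s = np.round(self.frame_duration * 60.0, 9)
        parts: list[str] = []
        i = 0
        while i < dur_s.size:
            j = i
            while j + 1 < dur_s.size and dur_s[j + 1] == dur_s[i]:
                j += 1
            parts.append(f"{j - i + 1}x{dur_s[i]:g}")
            i = j + 1
        return ",".join(parts)


def parse_frame_schedule(spec: str) -> FrameSchedule:
    """Parse a framing string like ``"1x10,10x5,..."`` (seconds) into minutes."""
    return FrameSchedule.from_spec(spec)


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    return schedule.midpoints


@dataclasses.dataclass
class TimeActivityCurve:
    """Decay-corrected activity concentration per frame for one region."""

    schedule: FrameSchedule
    activity: np.ndarray
    region_label: str = ""
    tissue_class: TissueClass = TissueClass.OTHER

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"activity length {self.activity.size} != n_frames {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity values must be finite")
        if np.any(self.activity < 0):
            # Low-count early frames can legitimately go negative after
            # scatter correction; retain but flag.
            log.warning("TAC %r contains negative frame values (retained)", self.region_label)

    @property
    def has_negative_frames(self) -> bool:
        return bool(np.any(self.activity < 0))


@dataclasses.dataclass
class BloodSampleSet:
    """Manual arterial samples: whole-blood activity, plasma ratio, parent fraction."""

    sample_time: np.ndarray
    whole_blood_activity: np.ndarray
    plasma_to_wholeblood_ratio: np.ndarray
    parent_fraction: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.sample_time, dtype=float)
        self.sample_time = t
        self.whole_blood_activity = np.asarray(self.whole_blood_activity, dtype=float)
        self.plasma_to_wholeblood_ratio = np.asarray(self.plasma_to_wholeblood_ratio, dtype=float)
        self.parent_fraction = np.asarray(self.parent_fraction, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.plasma_to_wholeblood_ratio <= 0):
            raise ValueError("plasma-to-whole-blood ratios must be positive")
        pf = self.parent_fraction
        if np.any((pf < 0) | (pf > 1)):
            raise ValueError("parent fractions must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.sample_time.size


@dataclasses.dataclass
class SubjectMeta:
    """Dose/weight metadata needed for SUV normalization."""

    net_injected_dose_mbq: float
    body_weight_kg: float
    cohort: str = "HC"
    subject_id: str = ""

    def __post_init__(self):
        if self.net_injected_dose_mbq <= 0:
            raise ValueError("net injected dose must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.cohort not in ("HC", "MS"):
            raise ValueError("cohort must be 'HC' or 'MS'")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "SubjectMeta":
        return cls(**json.loads(Path(path).read_text()))


@dataclasses.dataclass
class SubjectData:
    """Everything the pipeline needs for one subject."""

    meta: SubjectMeta
    tacs: list[TimeActivityCurve]
    continuous_time: np.ndarray  # minutes
    continuous_blood: np.ndarray  # kBq/mL, pre-calibration
    samples: BloodSampleSet
    lesions: pd.DataFrame | None = None  # lesion descriptor table (MS only)


@dataclasses.dataclass
class StudyDataset:
    subjects: dict[str, SubjectData]
    provenance: dict = dataclasses.field(default_factory=dict)


# ---------------------------------------------------------------------------
# Table I/O.  All tables are plain delimited text; '#'-prefixed header lines
# carry key: value metadata (units, subject id).

_UNIT_SCALE = {"kBq/mL": 1.0, "Bq/mL": 1e-3, "MBq/mL": 1e3}


def _read_commented_csv(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    return df, meta


def read_tac_table(path) -> list[TimeActivityCurve]:
    """Read a TAC table: columns ``frame_start_s, frame_duration_s, <region>...``.

    One TAC per region column, all sharing one schedule.  A ``# units:`` header
    converts Bq/mL or MBq/mL to the internal kBq/mL.
    """
    df, meta = _read_commented_csv(path)
    for col in ("frame_start_s", "frame_duration_s"):
        if col not in df.columns:
            raise ValueError(f"TAC table {path} missing column {col!r}")
    scale = _UNIT_SCALE[meta.get("units", "kBq/mL")]
    schedule = FrameSchedule(
        df["frame_start_s"].to_numpy() / 60.0, df["frame_duration_s"].to_numpy() / 60.0
    )
    classes = {}
    if "tissue_classes" in meta:
        for part in meta["tissue_classes"].split(";"):
            name, _, cls = part.partition("=")
            classes[name.strip()] = TissueClass(cls.strip())
    tacs = []
    for col in df.columns:
        if col in ("frame_start_s", "frame_duration_s"):
            continue
        tacs.append(
            TimeActivityCurve(
                schedule,
                df[col].to_numpy() * scale,
                region_label=col,
                tissue_class=classes.get(col, TissueClass.OTHER),
            )
        )
    return tacs


def write_tac_table(path, tacs: Sequence[TimeActivityCurve], subject_id: str = "") -> None:
    """Write TACs sharing one schedule; values as <= 9 significant digit text."""
    schedule = tacs[0].schedule
    for tac in tacs[1:]:
        if tac.schedule.n_frames != schedule.n_frames or not np.allclose(
            tac.schedule.frame_start, schedule.frame_start
        ):
            raise ValueError("all TACs in one table must share a schedule")
    df = pd.DataFrame(
        {
            "frame_start_s": schedule.frame_start * 60.0,
            "frame_duration_s": schedule.frame_duration * 60.0,
        }
    )
    for tac in tacs:
        df[tac.region_label] = tac.activity
    with open(path, "w") as fh:
        fh.write("# units: kBq/mL\n")
        if subject_id:
            fh.write(f"# subject: {subject_id}\n")
        cls = ";".join(f"{t.region_label}={t.tissue_class.value}" for t in tacs)
        fh.write(f"# tissue_classes: {cls}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def write_blood_tables(continuous_path, samples_path, t_min, wb, samples: BloodSampleSet) -> None:
    pd.DataFrame(
        {"time_s": np.asarray(t_min) * 60.0, "whole_blood_kBq_ml": wb}
    ).to_csv(continuous_path, index=False, float_format="%.9g")
    pd.DataFrame(
        {
            "time_s": samples.sample_time * 60.0,
            "whole_blood_kBq_ml": samples.whole_blood_activity,
            "plasma_ratio": samples.plasma_to_wholeblood_ratio,
            "parent_fraction": samples.parent_fraction,
        }
    ).to_csv(samples_path, index=False, float_format="%.9g")


def read_blood_tables(continuous_path, samples_path) -> tuple[np.ndarray, np.ndarray, BloodSampleSet]:
    cont = pd.read_csv(continuous_path, comment="#")
    man = pd.read_csv(samples_path, comment="#")
    samples = BloodSampleSet(
        man["time_s"].to_numpy() / 60.0,
        man["whole_blood_kBq_ml"].to_numpy(),
        man["plasma_ratio"].to_numpy(),
        man["parent_fraction"].to_numpy(),
    )
    return cont["time_s"].to_numpy() / 60.0, cont["whole_blood_kBq_ml"].to_numpy(), samples
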