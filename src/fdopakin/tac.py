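"""Frame schedules, time–activity curves, SUV and SUVr.

A dynamic PET acquisition is reconstructed into contiguous time frames; a
time–activity curve (TAC) is the region-mean radioactivity concentration
(kBq/mL) per frame.  SUV normalises activity by injected dose per body
weight; SUVr is the target/reference SUV ratio, which for a trapped tracer
approaches a late-scan pseudo-equilibrium plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "F18_HALF_LIFE_S",
    "STUDY_FRAME_DURATIONS_S",
    "FrameSchedule",
    "TimeActivityCurve",
    "SubjectMeta",
    "SUVCurve",
    "build_schedule",
    "decay_correct",
    "decay_uncorrect",
    "cumulative_integral",
    "compute_suv",
    "suv_ratio",
    "find_pseudo_equilibrium",
]

#: Physical half-life of fluorine-18, seconds (109.77 min).
F18_HALF_LIFE_S = 109.77 * 60.0

#: The 2 h acquisition: 6 x 30 s, 3 x 60 s, 2 x 120 s, 22 x 300 s.
STUDY_FRAME_DURATIONS_S = (30.0,) * 6 + (60.0,) * 3 + (120.0,) * 2 + (300.0,) * 22

GENOTYPES = ("WT", "G51D/+", "G51D/G51D")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class FrameSchedule:
    """Start times and durations (seconds from injection) of dynamic frames.

    Frames must be non-overlapping with strictly increasing starts; mid-frame
    times are the standard abscissa for frame-averaged data.
    """

    frame_starts: np.ndarray
    frame_durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.frame_starts, dtype=float)
        durs = np.asarray(self.frame_durations, dtype=float)
        object.__setattr__(self, "frame_starts", starts)
        object.__setattr__(self, "frame_durations", durs)
        if starts.ndim != 1 or durs.shape != starts.shape or starts.size == 0:
            raise ValidationError("frame_starts and frame_durations must be equal-length 1-D, non-empty")
        if np.any(durs <= 0):
            raise ValidationError("all frame durations must be > 0")
        if np.any(np.diff(starts) <= 0):
            raise ValidationError("frame starts must be strictly increasing")
        if np.any(starts[1:] < (starts + durs)[:-1] - 1e-9):
            raise ValidationError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return self.frame_starts.size

    @property
    def mid_times(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations / 2.0

    @property
    def frame_ends(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations

    @property
    def total_duration(self) -> float:
        """Scan length in seconds (end of last frame)."""
        return float(self.frame_ends[-1])

    def same_grid(self, other: "FrameSchedule") -> bool:
        return (
            self.n_frames == other.n_frames
            and np.allclose(self.frame_starts, other.frame_starts)
            and np.allclose(self.frame_durations, other.frame_durations)
        )


def build_schedule(durations_s) -> FrameSchedule:
    """Contiguous frame schedule starting at t = 0 from a list of durations."""
    durs = np.asarray(durations_s, dtype=float)
    if durs.size == 0:
        raise ValidationError("need at least one frame duration")
    if np.any(durs <= 0):
        raise ValidationError("all frame durations must be > 0")
    starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
    return FrameSchedule(starts, durs)


def study_schedule() -> FrameSchedule:
    """The 33-frame, 7200 s schedule used throughout this package's defaults."""
    return build_schedule(STUDY_FRAME_DURATIONS_S)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Region activity concentration (kBq/mL) per frame.

    ``decay_corrected`` records whether values are referred back to a common
    time (scanner convention); negative values are legal so that additive
    noise stays symmetric and does not bias graphical slopes.
    """

    schedule: FrameSchedule
    activity: np.ndarray
    region_label: str = ""
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.shape != (self.schedule.n_frames,):
            raise ValidationError(
                f"activity length {act.size} != {self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(act)):
            raise ValidationError("activity values must be finite")

    def __add__(self, other: "TimeActivityCurve") -> "TimeActivityCurve":
        if not self.schedule.same_grid(other.schedule):
            raise ValidationError("TACs live on different frame schedules")
        return replace(self, activity=self.activity + other.activity)

    def __sub__(self, other: "TimeActivityCurve") -> "TimeActivityCurve":
        if not self.schedule.same_grid(other.schedule):
            raise ValidationError("TACs live on different frame schedules")
        return replace(
            self,
            activity=self.activity - other.activity,
            region_label=f"{self.region_label}-{other.region_label}",
        )


@dataclass(frozen=True)
class SubjectMeta:
    """Per-animal metadata needed for SUV: dose decay-corrected to injection."""

    subject_id: str
    genotype: str
    age_months: float
    weight_kg: float
    injected_dose_MBq: float

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"genotype {self.genotype!r} not in {GENOTYPES}")
        if not self.weight_kg > 0:
            raise ValidationError("weight_kg must be > 0")
        if not self.injected_dose_MBq > 0:
            raise ValidationError("injected_dose_MBq must be > 0")


@dataclass(frozen=True)
class SUVCurve:
    schedule: FrameSchedule
    suv: np.ndarray = field(repr=False)
    region_label: str = ""

    def __post_init__(self) -> None:
        suv = np.asarray(self.suv, dtype=float)
        object.__setattr__(self, "suv", suv)
        if suv.shape != (self.schedule.n_frames,):
            raise ValidationError("suv length must equal frame count")


def decay_correct(
    tac: TimeActivityCurve, half_life_s: float = F18_HALF_LIFE_S, to_time_s: float = 0.0
) -> TimeActivityCurve:
    """Refer activities back to ``to_time_s`` by undoing physical decay.

    Each frame is scaled by ``2**((mid - to_time)/half_life)``.  Applying the
    correction to an already-corrected TAC raises.
    """
    if half_life_s <= 0:
        raise ValidationError("half_life_s must be > 0")
    if tac.decay_corrected:
        raise ValidationError("TAC is already decay-corrected; refusing to double-correct")
    factor = 2.0 ** ((tac.schedule.mid_times - to_time_s) / half_life_s)
    return replace(tac, activity=tac.activity * factor, decay_corrected=True)


def decay_uncorrect(
    tac: TimeActivityCurve, half_life_s: float = F18_HALF_LIFE_S, to_time_s: float = 0.0
) -> TimeActivityCurve:
    """Inverse of :func:`decay_correct` (reinstates physical decay)."""
    if half_life_s <= 0:
        raise ValidationError("half_life_s must be > 0")
    if not tac.decay_corrected:
        raise ValidationError("TAC is not decay-corrected")
    factor = 2.0 ** (-(tac.schedule.mid_times - to_time_s) / half_life_s)
    return replace(tac, activity=tac.activity * factor, decay_corrected=False)


def cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Running integral of the TAC (kBq·s/mL) evaluated at each mid-time.

    Trapezoid on mid-times with a zero-anchored first segment — exact for
    piecewise-linear curves, the standard grid for graphical analyses.
    """
    mids = tac.schedule.mid_times
    t = np.concatenate([[0.0], mids])
    y = np.concatenate([[0.0], tac.activity])
    return np.cumsum(np.diff(t) * (y[1:] + y[:-1]) / 2.0)


def compute_suv(tac: TimeActivityCurve, meta: SubjectMeta) -> SUVCurve:
    """SUV (g/mL) = activity (kBq/mL) / (injected dose (MBq) / weight (kg))."""
    scale = meta.injected_dose_MBq / meta.weight_kg
    return SUVCurve(tac.schedule, tac.activity / scale, region_label=tac.region_label)


def suv_ratio(target: SUVCurve, reference: SUVCurve) -> np.ndarray:
    """Elementwise target/reference SUV (unitless SUVr per frame).

    Frames with a non-positive reference are returned as NaN with a warning
    rather than silently divided.
    """
    if not target.schedule.same_grid(reference.schedule):
        raise ValidationError("SUV curves live on different frame schedules")
    bad = reference.suv <= 0
    out = np.full(target.suv.shape, np.nan)
    np.divide(target.suv, reference.suv, out=out, where=~bad)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} frame(s) with non-positive reference SUV set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def find_pseudo_equilibrium(
    suvr: np.ndarray, schedule: FrameSchedule, slope_tol_per_min: float = 0.005
):
    """Longest late-scan window where SUVr is flat, or ``None``.

    A frame qualifies when the magnitude of the local SUVr slope (central
    difference on mid-times, per minute) is at most ``slope_tol_per_min``;
    the longest contiguous run of >= 3 qualifying frames is returned as
    ``(start_s, end_s)`` spanning from the first frame's start to the last
    frame's end.
    """
    suvr = np.asarray(suvr, dtype=float)
    if suvr.size < 3:
        raise ValidationError("need at least 3 frames")
    mids_min = schedule.mid_times / 60.0
    slope = np.gradient(suvr, mids_min)
    ok = np.abs(slope) <= slope_tol_per_min
    best = None  # (length, i0, i1)
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j + 1 < ok.size and ok[j + 1]:
                j += 1
            if j - i + 1 >= 3 and (best is None or j - i > best[2] - best[1]):
                best = (j - i + 1, i, j)
            i = j + 1
        else:
            i += 1
    if best is None:
        return None
    _, i0, i1 = best
    return float(schedule.frame_starts[i0]), float(schedule.frame_ends[i1])
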