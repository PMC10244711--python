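"""Reference-tissue graphical analyses: Patlak Ki, Logan DVR, EDVR.

All three are linearisations of compartmental kinetics fitted by ordinary
least squares over a late-scan window [t*, end]:

* Patlak (irreversible trapping): C_T/C_R against ∫C_R/C_R; the slope is the
  net influx rate constant Ki relative to the reference region.
* Logan (reversible uptake): ∫C_T/C_T against ∫C_R/C_T; the slope is the
  distribution volume ratio (DVR) of target to reference.
* EDVR: the reference TAC is subtracted from the target TAC first, isolating
  the specific (trapped) signal, and the Logan slope of that difference
  against the reference is the effective DVR.  Its inverse estimates
  effective dopamine turnover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tac import FrameSchedule, TimeActivityCurve, ValidationError, cumulative_integral

__all__ = [
    "GraphicalFit",
    "PatlakResult",
    "LoganResult",
    "EDVRResult",
    "fit_window_frames",
    "patlak_reference",
    "logan_reference",
    "edvr",
]

# Study defaults: Patlak on 60 min of data with t* = 10 min; Logan (and the
# EDVR variant) on the full 120 min with t* = 30 min.
PATLAK_T_STAR_S = 600.0
PATLAK_END_S = 3600.0
LOGAN_T_STAR_S = 1800.0
LOGAN_END_S = 7200.0


@dataclass(frozen=True)
class GraphicalFit:
    """OLS fit of a graphical transform: slope, intercept, R², window and points."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    t_star_s: float
    end_s: float
    x: np.ndarray
    y: np.ndarray


@dataclass(frozen=True)
class PatlakResult:
    fit: GraphicalFit
    Ki_per_min: float


@dataclass(frozen=True)
class LoganResult:
    fit: GraphicalFit
    DVR: float


@dataclass(frozen=True)
class EDVRResult:
    fit: GraphicalFit
    EDVR: float

    @property
    def effective_turnover(self) -> float:
        """Effective dopamine turnover, the inverse of EDVR."""
        return 1.0 / self.EDVR


def fit_window_frames(schedule: FrameSchedule, t_star_s: float, end_s: float) -> np.ndarray:
    """Indices of frames whose mid-time lies in [t_star_s, end_s] (inclusive)."""
    if not t_star_s < end_s:
        raise ValidationError("t_star_s must be < end_s")
    mids = schedule.mid_times
    idx = np.nonzero((mids >= t_star_s) & (mids <= end_s))[0]
    if idx.size == 0:
        raise ValidationError(
            f"no frame mid-times inside [{t_star_s}, {end_s}] s "
            f"(scan spans 0–{schedule.total_duration:g} s)"
        )
    return idx


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Unweighted least squares; returns (slope, intercept, r_squared)."""
    xm, ym = x.mean(), y.mean()
    dx, dy = x - xm, y - ym
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ValidationError("degenerate fit: transform abscissa is constant")
    slope = float(dx @ dy) / sxx
    intercept = ym - slope * xm
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(dy @ dy)
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return slope, intercept, min(1.0, r2)


def _check_pair(target: TimeActivityCurve, reference: TimeActivityCurve) -> None:
    if not target.schedule.same_grid(reference.schedule):
        raise ValidationError("target and reference TACs must share a frame schedule")


def patlak_reference(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    t_star_s: float = PATLAK_T_STAR_S,
    end_s: float = PATLAK_END_S,
) -> PatlakResult:
    """Patlak reference-tissue influx: slope of C_T/C_R vs ∫C_R/C_R.

    Valid for irreversibly trapped tracers once the exchangeable pools have
    equilibrated (after t*).  Ki is reported in 1/min.
    """
    _check_pair(target, reference)
    idx = fit_window_frames(target.schedule, t_star_s, end_s)
    if idx.size < 2:
        raise ValidationError("need at least 2 frames in the Patlak window")
    ref = reference.activity
    nonpos = idx[ref[idx] <= 0]
    if nonpos.size:
        raise ValidationError(
            f"reference TAC non-positive inside the fit window at frame(s) {nonpos.tolist()}"
        )
    int_ref = cumulative_integral(reference)
    x = int_ref[idx] / ref[idx]          # seconds
    y = target.activity[idx] / ref[idx]  # unitless
    slope, intercept, r2 = _ols(x, y)
    fit = GraphicalFit(slope, intercept, r2, idx.size, t_star_s, end_s, x, y)
    return PatlakResult(fit=fit, Ki_per_min=slope * 60.0)


def logan_reference(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    t_star_s: float = LOGAN_T_STAR_S,
    end_s: float = LOGAN_END_S,
    k2_prime_per_min: float | None = None,
) -> LoganResult:
    """Logan reference-tissue DVR: slope of ∫C_T/C_T vs ∫C_R/C_T.

    The plain two-term form is the default; passing ``k2_prime_per_min``
    (reference-region efflux rate) adds the standard C_R/(k2'·C_T) term to
    the abscissa for tracers where reference equilibration is slow.
    """
    _check_pair(target, reference)
    idx = fit_window_frames(target.schedule, t_star_s, end_s)
    if idx.size < 2:
        raise ValidationError("need at least 2 frames in the Logan window")
    tgt = target.activity
    nonpos = idx[tgt[idx] <= 0]
    if nonpos.size:
        raise ValidationError(
            f"target TAC non-positive inside the fit window at frame(s) {nonpos.tolist()}"
        )
    int_tgt = cumulative_integral(target)
    int_ref = cumulative_integral(reference)
    x = int_ref[idx] / tgt[idx]
    if k2_prime_per_min is not None:
        if k2_prime_per_min <= 0:
            raise ValidationError("k2_prime_per_min must be > 0")
        x = x + reference.activity[idx] / (k2_prime_per_min / 60.0) / tgt[idx]
    y = int_tgt[idx] / tgt[idx]
    slope, intercept, r2 = _ols(x, y)
    fit = GraphicalFit(slope, intercept, r2, idx.size, t_star_s, end_s, x, y)
    return LoganResult(fit=fit, DVR=slope)


def edvr(
    striatum: TimeActivityCurve,
    cerebellum: TimeActivityCurve,
    t_star_s: float = LOGAN_T_STAR_S,
    end_s: float = LOGAN_END_S,
) -> EDVRResult:
    """Effective DVR: Logan analysis of (striatum − cerebellum) vs cerebellum.

    Subtracting the reference TAC removes the free/non-specific signal, so
    the slope approximates the specific-compartment distribution volume
    relative to the reference.  Early frames of the difference may be
    negative (pre-equilibrium); only frames inside the fit window must be
    positive.
    """
    _check_pair(striatum, cerebellum)
    specific = striatum - cerebellum
    idx = fit_window_frames(striatum.schedule, t_star_s, end_s)
    if np.all(specific.activity[idx] <= 0):
        raise ValidationError(
            "striatum minus cerebellum is non-positive across the whole fit window: "
            "no specific binding signal"
        )
    logan = logan_reference(specific, cerebellum, t_star_s=t_star_s, end_s=end_s)
    return EDVRResult(fit=logan.fit, EDVR=logan.DVR)
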