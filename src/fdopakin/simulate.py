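"""Compartment-model synthetic-data generator with closed-form oracles.

The tracer model is the standard irreversible-with-slow-loss description of
striatal F-DOPA kinetics.  A tri-exponential bolus plasma input C_p(t)
drives, in the target (striatum),

    dC_f/dt = K1·C_p − (k2 + k3)·C_f        (free + precursor pool)
    dC_s/dt = k3·C_f − k_loss·C_s           (decarboxylated, vesicular pool)

with measured tissue activity C_T = C_f + C_s, and in the reference
(cerebellum, no AADC) a one-tissue model

    dC_r/dt = K1r·C_p − k2r·C_r.

Because the input is a sum of (a·t + b)·e^(−λt) terms and the system is
linear, every solution is again a finite sum of such terms; curves and their
frame averages are evaluated in closed form, so simulation is exact and
bit-deterministic.  Closed-form steady-state expressions for the Patlak,
Logan and EDVR endpoints serve as independent oracles for parameter
recovery.

A cohort generator emulates a longitudinal cross-sectional design — three
genotypes by three ages, n animals per cell — with log-normal inter-subject
variability, group-level effects on dopamine turnover (k_loss) and a
left–right turnover asymmetry, plus count-statistics-like frame noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .tac import (
    GENOTYPES,
    FrameSchedule,
    SubjectMeta,
    TimeActivityCurve,
    ValidationError,
    F18_HALF_LIFE_S,
)

__all__ = [
    "PlasmaInput",
    "TissueKinetics",
    "ReferenceKinetics",
    "GroupEffect",
    "CohortDesign",
    "SimulatedSubject",
    "CohortDataset",
    "default_plasma_input",
    "default_tissue_kinetics",
    "default_reference_kinetics",
    "plasma_input_curve",
    "simulate_region",
    "add_noise",
    "analytic_targets",
    "simulate_cohort",
    "default_effect_map",
]

AGES_MONTHS = (5, 11, 16)
REGIONS = ("left_striatum", "right_striatum", "cerebellum")

# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class PlasmaInput:
    """Feng-type bolus input: (A1·s − A2 − A3)e^(−λ1·s) + A2·e^(−λ2·s) + A3·e^(−λ3·s),
    s = t − delay (zero before the delay).  Rates in 1/min, time in minutes,
    amplitudes chosen so tissue activities land in the tens of kBq/mL."""

    A1: float = 600.0      # kBq/mL/min
    A2: float = 30.0       # kBq/mL
    A3: float = 25.0       # kBq/mL
    lambda1: float = 4.0   # 1/min
    lambda2: float = 0.5   # 1/min
    lambda3: float = 0.008 # 1/min
    delay_min: float = 0.5

    def __post_init__(self) -> None:
        if not (self.lambda1 > self.lambda2 > self.lambda3 > 0):
            raise ValidationError("require lambda1 > lambda2 > lambda3 > 0")
        if self.delay_min < 0:
            raise ValidationError("delay_min must be >= 0")
        t = np.linspace(0.0, 240.0, 4801)
        if np.any(plasma_input_curve(self, t, _validate=False) < -1e-9):
            raise ValidationError("plasma input goes negative on the scan interval")

    @property
    def terms(self) -> list[tuple[float, float, float]]:
        """(a, b, lam) triples meaning (a·s + b)·e^(−lam·s) in the delayed frame."""
        return [
            (self.A1, -(self.A2 + self.A3), self.lambda1),
            (0.0, self.A2, self.lambda2),
            (0.0, self.A3, self.lambda3),
        ]


@dataclass(frozen=True)
class TissueKinetics:
    """Two-tissue rates, 1/min: K1 delivery, k2 efflux, k3 AADC trapping,
    k_loss egress from the specific (vesicular) compartment."""

    K1: float = 0.1
    k2: float = 0.3
    k3: float = 0.03
    k_loss: float = 0.01

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3, self.k_loss) < 0:
            raise ValidationError("rate constants must be >= 0")
        if self.k2 + self.k3 <= 0:
            raise ValidationError("k2 + k3 must be > 0")


@dataclass(frozen=True)
class ReferenceKinetics:
    """One-tissue cerebellum rates, 1/min."""

    K1r: float = 0.1
    k2r: float = 0.3

    def __post_init__(self) -> None:
        if self.K1r <= 0 or self.k2r <= 0:
            raise ValidationError("reference rates must be > 0")


def default_plasma_input() -> PlasmaInput:
    return PlasmaInput()


def default_tissue_kinetics() -> TissueKinetics:
    return TissueKinetics()


def default_reference_kinetics() -> ReferenceKinetics:
    return ReferenceKinetics()


# --------------------------------------------------------------------------
# exponential-polynomial algebra: terms are (a, b, lam) == (a·s + b)·e^(−lam·s)

_RATE_EPS = 1e-10
_NUDGE = 1e-8


def _eval_terms(terms, s: np.ndarray) -> np.ndarray:
    out = np.zeros_like(s, dtype=float)
    for a, b, lam in terms:
        out += (a * s + b) * np.exp(-lam * s)
    return out


def _convolve_exp(terms, k: float) -> list[tuple[float, float, float]]:
    """Convolve a term sum with e^(−k·s); result is again a term sum.

    Coincident rates are split by a deterministic 1e-8 nudge, keeping the
    polynomial degree at one; the induced error is ~1e-8 relative.
    """
    out: list[tuple[float, float, float]] = []
    for a, b, lam in terms:
        if abs(lam - k) < _RATE_EPS:
            lam = lam + _NUDGE
        d = lam - k
        if b:
            out.append((0.0, b / d, k))
            out.append((0.0, -b / d, lam))
        if a:
            out.append((0.0, a / d**2, k))
            out.append((0.0, -a / d**2, lam))
            out.append((-a / d, 0.0, lam))
    return out


def _integral_terms(terms, s0: float, s1: float) -> float:
    """∫ over [s0, s1] of the term sum, in closed form."""
    total = 0.0
    for a, b, lam in terms:
        if abs(lam) < _RATE_EPS:
            f = lambda s: a * s * s / 2.0 + b * s
        else:
            f = lambda s: np.exp(-lam * s) * (-(a * s + b) / lam - a / lam**2)
        total += f(s1) - f(s0)
    return total


def plasma_input_curve(params: PlasmaInput, t_min, _validate: bool = True) -> np.ndarray:
    """Plasma activity (kBq/mL) at times ``t_min`` (minutes post injection)."""
    t = np.asarray(t_min, dtype=float)
    if _validate and np.any(t < 0):
        raise ValidationError("t_min must be >= 0")
    s = t - params.delay_min
    out = np.where(s >= 0, _eval_terms(params.terms, np.maximum(s, 0.0)), 0.0)
    return np.maximum(out, 0.0)


def _solution_terms(kin, params: PlasmaInput):
    """Closed-form tissue solution as exp-polynomial terms (delayed frame)."""
    cp = params.terms
    if isinstance(kin, ReferenceKinetics):
        cf = [(a * kin.K1r, b * kin.K1r, lam) for a, b, lam in _convolve_exp(cp, kin.k2r)]
        return cf
    cf = _convolve_exp(cp, kin.k2 + kin.k3)
    cf = [(a * kin.K1, b * kin.K1, lam) for a, b, lam in cf]
    cs = _convolve_exp(cf, kin.k_loss)
    cs = [(a * kin.k3, b * kin.k3, lam) for a, b, lam in cs]
    return cf + cs


def simulate_region(
    kin, input_params: PlasmaInput, schedule: FrameSchedule, region_label: str = ""
) -> TimeActivityCurve:
    """Noise-free frame-averaged TAC for a target or reference region.

    Frame values are the exact mean of the continuous solution over each
    frame (closed-form integrals), not point samples.
    """
    terms = _solution_terms(kin, input_params)
    starts_min = schedule.frame_starts / 60.0
    ends_min = schedule.frame_ends / 60.0
    act = np.empty(schedule.n_frames)
    for i, (t0, t1) in enumerate(zip(starts_min, ends_min)):
        s0 = max(t0 - input_params.delay_min, 0.0)
        s1 = max(t1 - input_params.delay_min, 0.0)
        if s1 <= s0:
            act[i] = 0.0
        else:
            act[i] = _integral_terms(terms, s0, s1) / (t1 - t0)
    return TimeActivityCurve(schedule, act, region_label=region_label, decay_corrected=True)


def add_noise(
    tac: TimeActivityCurve,
    noise_scale: float,
    half_life_s: float = F18_HALF_LIFE_S,
    seed=None,
) -> TimeActivityCurve:
    """Frame noise mimicking count statistics on decay-corrected data.

    Per-frame SD = noise_scale · sqrt(max(A,0) · 2^(t_mid/T_half) / duration):
    variance grows with physical decay and shrinks with frame duration, as
    for reconstructed PET counts.  ``seed`` may be an int or a Generator.
    """
    if noise_scale < 0:
        raise ValidationError("noise_scale must be >= 0")
    if noise_scale == 0:
        return tac
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mids = tac.schedule.mid_times
    sd = noise_scale * np.sqrt(
        np.maximum(tac.activity, 0.0) * 2.0 ** (mids / half_life_s) / tac.schedule.frame_durations
    )
    return replace(tac, activity=tac.activity + rng.normal(0.0, 1.0, tac.activity.shape) * sd)


def analytic_targets(kin: TissueKinetics, ref: ReferenceKinetics) -> dict:
    """Closed-form steady-state endpoints used as parameter-recovery oracles.

    * Ki_ref = K1·k3·k2r / ((k2 + k3)·K1r)  — net influx relative to the
      reference (meaningful as the Patlak slope when k_loss = 0);
    * DVR = K1/(k2 + k3)·(1 + k3/k_loss)·k2r/K1r — target:reference
      distribution volume ratio (the Logan asymptote), the target DV being
      the sum of the precursor-pool DV K1/(k2 + k3) and the specific-pool
      DV K1·k3/((k2 + k3)·k_loss);
    * EDVR = (k3/k_loss)·k2/(k2 + k3) — specific:precursor distribution
      volume ratio reduced by the precursor partition factor k2/(k2 + k3),
      assuming the reference DV matches the target's non-specific DV K1/k2;
      its inverse is the effective dopamine turnover.
    """
    if kin.k2 == 0:
        raise ValidationError("k2 = 0: EDVR is undefined")
    out = {"Ki_ref": kin.K1 * kin.k3 * ref.k2r / ((kin.k2 + kin.k3) * ref.K1r)}
    if kin.k_loss == 0:
        raise ValidationError("k_loss = 0: DVR and EDVR are unbounded (fully trapped tracer)")
    out["DVR"] = (
        kin.K1 / (kin.k2 + kin.k3) * (1.0 + kin.k3 / kin.k_loss) * ref.k2r / ref.K1r
    )
    out["EDVR"] = (kin.k3 / kin.k_loss) * kin.k2 / (kin.k2 + kin.k3)
    return out


# --------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class GroupEffect:
    """Group-level modifiers applied on top of the base kinetics.

    ``edvr_multiplier`` scales the bilateral EDVR by dividing k_loss (lower
    EDVR = faster turnover); ``left_right_k_loss_ratio`` > 1 raises k_loss on
    the left relative to the right, lowering left EDVR (positive asymmetry
    under the contralateral=right convention)."""

    edvr_multiplier: float = 1.0
    left_right_k_loss_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.edvr_multiplier <= 0 or self.left_right_k_loss_ratio <= 0:
            raise ValidationError("effect multipliers must be > 0")


def default_effect_map() -> dict:
    """Effects emulating the study phenotype: reduced EDVR in aged
    homozygotes and a left-dominant turnover asymmetry in homozygotes at the
    youngest and oldest ages."""
    eff = {(g, a): GroupEffect() for g in GENOTYPES for a in AGES_MONTHS}
    eff[("G51D/G51D", 5)] = GroupEffect(left_right_k_loss_ratio=1.2)
    eff[("G51D/G51D", 16)] = GroupEffect(edvr_multiplier=0.7, left_right_k_loss_ratio=1.3)
    return eff


@dataclass(frozen=True)
class CohortDesign:
    """Study design: genotypes × ages with n animals per cell.

    Inter-subject variability is log-normal on the kinetic rates
    (``inter_subject_cv``); delivery (K1) and efflux (k2) draws are shared
    between striatum and cerebellum within a subject, because the
    reference-tissue methods assume a common non-specific distribution
    volume.  ``side_cv`` is extra left/right k_loss variability within a
    subject."""

    genotypes: tuple = GENOTYPES
    ages_months: tuple = AGES_MONTHS
    n_per_cell: int = 4
    effect_map: dict = field(default_factory=default_effect_map)
    noise_scale: float = 0.1
    inter_subject_cv: float = 0.1
    side_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValidationError("n_per_cell must be >= 1")

    @property
    def n_subjects(self) -> int:
        return len(self.genotypes) * len(self.ages_months) * self.n_per_cell


@dataclass(frozen=True)
class SimulatedSubject:
    meta: SubjectMeta
    tacs: dict  # region label -> TimeActivityCurve
    true_kinetics: dict  # side -> TissueKinetics, plus "reference" -> ReferenceKinetics


@dataclass(frozen=True)
class CohortDataset:
    design: CohortDesign
    schedule: FrameSchedule
    input_params: PlasmaInput
    subjects: list


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(rng.normal(-sigma * sigma / 2.0, sigma)))


def simulate_cohort(
    design: CohortDesign,
    base_kinetics: TissueKinetics | None = None,
    base_reference: ReferenceKinetics | None = None,
    input_params: PlasmaInput | None = None,
    schedule: FrameSchedule | None = None,
) -> CohortDataset:
    """Simulate left striatum, right striatum and cerebellum TACs for every
    subject of the design; deterministic for a fixed design seed."""
    from .tac import study_schedule

    kin0 = base_kinetics or default_tissue_kinetics()
    ref0 = base_reference or default_reference_kinetics()
    inp = input_params or default_plasma_input()
    sched = schedule or study_schedule()
    rng = np.random.default_rng(design.seed)
    subjects = []
    for genotype in design.genotypes:
        for age in design.ages_months:
            effect = design.effect_map.get((genotype, age), GroupEffect())
            for i in range(design.n_per_cell):
                cv = design.inter_subject_cv
                gK1 = _lognormal_factor(rng, cv)   # shared delivery
                gk2 = _lognormal_factor(rng, cv)   # shared efflux
                gk3 = _lognormal_factor(rng, cv)
                gkl = _lognormal_factor(rng, cv)
                k_loss = kin0.k_loss * gkl / effect.edvr_multiplier
                lr = effect.left_right_k_loss_ratio
                sides = {}
                for side, side_mult in (("left", np.sqrt(lr)), ("right", 1.0 / np.sqrt(lr))):
                    jitter = _lognormal_factor(rng, design.side_cv)
                    sides[side] = TissueKinetics(
                        K1=kin0.K1 * gK1,
                        k2=kin0.k2 * gk2,
                        k3=kin0.k3 * gk3,
                        k_loss=k_loss * side_mult * jitter,
                    )
                ref = ReferenceKinetics(K1r=ref0.K1r * gK1, k2r=ref0.k2r * gk2)
                weight = max(0.2, rng.normal(0.37, 0.03))
                dose = max(2.0, rng.normal(18.5, 7.1))
                meta = SubjectMeta(
                    subject_id=f"{genotype.replace('/', '')}_{age}m_{i + 1:02d}",
                    genotype=genotype,
                    age_months=age,
                    weight_kg=round(weight, 4),
                    injected_dose_MBq=round(dose, 4),
                )
                tacs = {}
                for region, kin in (
                    ("left_striatum", sides["left"]),
                    ("right_striatum", sides["right"]),
                    ("cerebellum", ref),
                ):
                    clean = simulate_region(kin, inp, sched, region_label=region)
                    tacs[region] = add_noise(clean, design.noise_scale, seed=rng)
                subjects.append(
                    SimulatedSubject(
                        meta=meta,
                        tacs=tacs,
                        true_kinetics={**sides, "reference": ref},
                    )
                )
    return CohortDataset(design=design, schedule=sched, input_params=inp, subjects=subjects)
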