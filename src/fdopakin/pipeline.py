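"""Study pipeline: per-subject kinetic endpoints and group statistics.

Per subject, the whole-striatum Ki (Patlak), DVR (Logan) and EDVR, per-side
EDVR and the left–right asymmetry index are computed from the three region
TACs; group statistics mirror the study design — per age, a one-way ANOVA
with Tukey HSD across genotypes for each endpoint, a paired t test on
left-vs-right EDVR per genotype and age, and Q–Q normality points per
endpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import graphical
from .graphical import edvr, logan_reference, patlak_reference
from .io import read_cohort_tacs, subject_meta_from_row
from .simulate import CohortDataset
from .stats import anova_tukey, asymmetry_index, paired_t, qq_points
from .tac import TimeActivityCurve, ValidationError, F18_HALF_LIFE_S

log = logging.getLogger("fdopakin")

ENDPOINT_COLUMNS = [
    "subject_id",
    "genotype",
    "age_months",
    "region",
    "Ki_per_min",
    "DVR",
    "EDVR",
    "turnover",
    "asymmetry",
]


@dataclass(frozen=True)
class Window:
    t_star_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.t_star_s < self.end_s:
            raise ValidationError("window requires t_star_s < end_s")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis parameters; defaults follow the study (Patlak: 60 min of
    data, t* 10 min; Logan and EDVR: 120 min of data, t* 30 min)."""

    patlak: Window = field(default_factory=lambda: Window(graphical.PATLAK_T_STAR_S, graphical.PATLAK_END_S))
    logan: Window = field(default_factory=lambda: Window(graphical.LOGAN_T_STAR_S, graphical.LOGAN_END_S))
    edvr: Window = field(default_factory=lambda: Window(graphical.LOGAN_T_STAR_S, graphical.LOGAN_END_S))
    half_life_s: float = F18_HALF_LIFE_S
    side_convention: str = "contralateral=right"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.side_convention not in ("contralateral=right", "contralateral=left"):
            raise ValidationError("side_convention must be 'contralateral=right' or 'contralateral=left'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(open(path)) or {}
        kwargs = {}
        for name in ("patlak", "logan", "edvr"):
            if name in doc:
                kwargs[name] = Window(**doc[name])
        for name in ("half_life_s", "side_convention", "alpha", "seed"):
            if name in doc:
                kwargs[name] = doc[name]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def whole_striatum_tac(left: TimeActivityCurve, right: TimeActivityCurve) -> TimeActivityCurve:
    """Equal-weight mean of the side TACs (equal-volume VOIs assumed)."""
    if not left.schedule.same_grid(right.schedule):
        raise ValidationError("left/right TACs on different schedules")
    return TimeActivityCurve(
        left.schedule, (left.activity + right.activity) / 2.0, region_label="whole_striatum"
    )


def fit_subject(tacs: dict, config: PipelineConfig | None = None) -> tuple[dict, list]:
    """Endpoints for one subject from its region TACs.

    Returns ``(endpoints, model_records)`` where endpoints has Ki/DVR/EDVR
    for the whole striatum, per-side EDVR, turnover and the asymmetry index,
    and model_records are per-fit JSON-ready dicts (slope, intercept, R²,
    window).
    """
    config = config or PipelineConfig()
    for region in ("left_striatum", "right_striatum", "cerebellum"):
        if region not in tacs:
            raise ValidationError(f"missing TAC for region {region!r}")
    cer = tacs["cerebellum"]
    left, right = tacs["left_striatum"], tacs["right_striatum"]
    whole = tacs.get("whole_striatum") or whole_striatum_tac(left, right)

    records = []

    def record(model, region, fit, **extra):
        records.append(
            {
                "region": region,
                "model": model,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "t_star_s": fit.t_star_s,
                "end_s": fit.end_s,
                **extra,
            }
        )

    pk = patlak_reference(whole, cer, config.patlak.t_star_s, config.patlak.end_s)
    record("patlak", "whole_striatum", pk.fit, Ki_per_min=pk.Ki_per_min)
    lg = logan_reference(whole, cer, config.logan.t_star_s, config.logan.end_s)
    record("logan", "whole_striatum", lg.fit, DVR=lg.DVR)
    ed = {}
    for region, tac in (("whole_striatum", whole), ("left_striatum", left), ("right_striatum", right)):
        res = edvr(tac, cer, config.edvr.t_star_s, config.edvr.end_s)
        ed[region] = res
        record("edvr", region, res.fit, EDVR=res.EDVR, effective_turnover=res.effective_turnover)

    if config.side_convention == "contralateral=right":
        contra, ipsi = ed["right_striatum"].EDVR, ed["left_striatum"].EDVR
    else:
        contra, ipsi = ed["left_striatum"].EDVR, ed["right_striatum"].EDVR
    endpoints = {
        "Ki_per_min": pk.Ki_per_min,
        "DVR": lg.DVR,
        "EDVR_whole": ed["whole_striatum"].EDVR,
        "EDVR_left": ed["left_striatum"].EDVR,
        "EDVR_right": ed["right_striatum"].EDVR,
        "turnover": ed["whole_striatum"].effective_turnover,
        "asymmetry": asymmetry_index(contra, ipsi),
        "side_convention": config.side_convention,
    }
    return endpoints, records


def _endpoint_rows(subject_id, genotype, age, ep) -> list:
    rows = []
    for region, edvr_key in (
        ("whole_striatum", "EDVR_whole"),
        ("left_striatum", "EDVR_left"),
        ("right_striatum", "EDVR_right"),
    ):
        rows.append(
            {
                "subject_id": subject_id,
                "genotype": genotype,
                "age_months": float(age),
                "region": region,
                "Ki_per_min": ep["Ki_per_min"] if region == "whole_striatum" else np.nan,
                "DVR": ep["DVR"] if region == "whole_striatum" else np.nan,
                "EDVR": ep[edvr_key],
                "turnover": 1.0 / ep[edvr_key],
                "asymmetry": ep["asymmetry"] if region == "whole_striatum" else np.nan,
            }
        )
    return rows


def fit_cohort(cohort, config: PipelineConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """Fit every subject of a cohort (a :class:`CohortDataset` or a cohort
    directory path); subjects with missing regions are skipped with a
    warning and counted in the summary."""
    config = config or PipelineConfig()
    if isinstance(cohort, CohortDataset):
        subjects = [(s.meta, s.tacs) for s in cohort.subjects]
    else:
        manifest, tac_map = read_cohort_tacs(cohort)
        if manifest.empty:
            raise ValidationError(f"cohort manifest in {cohort} lists no subjects")
        subjects = [
            (subject_meta_from_row(row), tac_map.get(row["subject_id"], {}))
            for _, row in manifest.iterrows()
        ]
    rows, per_subject, skipped = [], {}, []
    for meta, tacs in subjects:
        try:
            ep, records = fit_subject(tacs, config)
        except ValidationError as err:
            log.warning("skipping subject %s: %s", meta.subject_id, err)
            skipped.append(meta.subject_id)
            continue
        rows.extend(_endpoint_rows(meta.subject_id, meta.genotype, meta.age_months, ep))
        per_subject[meta.subject_id] = records
    table = pd.DataFrame(rows, columns=ENDPOINT_COLUMNS)
    summary = {
        "n_subjects": len(subjects),
        "n_fitted": len(per_subject),
        "n_skipped": len(skipped),
        "skipped": skipped,
        "per_subject": per_subject,
        "config": config.to_dict(),
    }
    return table, summary


def report_groups(endpoints: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Group statistics mirroring the study figures: per-age ANOVA + Tukey
    across genotypes for Ki, DVR and EDVR (whole striatum), per
    genotype-and-age paired t on left-vs-right EDVR, and Q–Q points per
    endpoint.  Under-sized groups are listed, not fatal."""
    config = config or PipelineConfig()
    whole = endpoints[endpoints["region"] == "whole_striatum"]
    if whole["genotype"].nunique() < 2:
        raise ValidationError("need at least 2 genotype groups to compare")
    report = {"config": config.to_dict(), "anova": {}, "paired_t": {}, "qq": {}, "insufficient": []}
    metrics = {"Ki_per_min": "Ki_per_min", "DVR": "DVR", "EDVR": "EDVR"}
    for age, by_age in whole.groupby("age_months"):
        age_block = {}
        for name, col in metrics.items():
            groups, labels = [], []
            for genotype, g in by_age.groupby("genotype", sort=False):
                vals = g[col].dropna().to_numpy()
                if vals.size >= 2:
                    groups.append(vals)
                    labels.append(genotype)
                else:
                    report["insufficient"].append(
                        {"age_months": age, "metric": name, "genotype": genotype, "n": int(vals.size)}
                    )
            if len(groups) < 2:
                continue
            gc = anova_tukey(groups, labels=labels, alpha=config.alpha)
            age_block[name] = {
                "F": gc.F_statistic,
                "p": gc.p_value,
                "significant": gc.p_value < config.alpha,
                "pairwise": [
                    {
                        "pair": list(p.pair),
                        "mean_difference": p.mean_difference,
                        "p_adjusted": p.p_adjusted,
                        "significant": p.significant,
                    }
                    for p in gc.pairwise
                ],
            }
        report["anova"][str(age)] = age_block

    sides = endpoints[endpoints["region"].isin(["left_striatum", "right_striatum"])]
    for (genotype, age), g in sides.groupby(["genotype", "age_months"], sort=False):
        piv = g.pivot_table(index="subject_id", columns="region", values="EDVR")
        piv = piv.dropna()
        if len(piv) < 2 or piv.shape[1] < 2:
            report["insufficient"].append(
                {"age_months": age, "metric": "EDVR_left_right", "genotype": genotype, "n": int(len(piv))}
            )
            continue
        try:
            pt = paired_t(piv["left_striatum"].to_numpy(), piv["right_striatum"].to_numpy())
        except ValidationError as err:
            report["insufficient"].append(
                {"age_months": age, "metric": "EDVR_left_right", "genotype": genotype, "error": str(err)}
            )
            continue
        report["paired_t"][f"{genotype}|{age:g}"] = {
            "t": pt.t_statistic,
            "df": pt.degrees_of_freedom,
            "p": pt.p_value,
            "significant": pt.p_value < config.alpha,
        }

    for name, col in metrics.items():
        vals = whole[col].dropna().to_numpy()
        if vals.size >= 3:
            theo, ordered = qq_points(vals)
            report["qq"][name] = {"theoretical": theo.tolist(), "ordered": ordered.tolist()}
    return report
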