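"""On-disk interchange: TAC CSVs, cohort manifests, design JSON, endpoints.

A cohort directory is self-contained: one TAC CSV per subject (long format,
one row per frame per region), a manifest CSV of subject metadata, and a
design JSON echoing every simulation input including the seed, so the whole
downstream pipeline can be re-run from disk.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import (
    CohortDataset,
    CohortDesign,
    GroupEffect,
    PlasmaInput,
    SimulatedSubject,
)
from .tac import FrameSchedule, SubjectMeta, TimeActivityCurve

TAC_COLUMNS = [
    "frame_start_s",
    "frame_duration_s",
    "mid_time_s",
    "activity_kBq_per_mL",
    "region",
    "subject_id",
]
MANIFEST_COLUMNS = ["subject_id", "genotype", "age_months", "weight_kg", "injected_dose_MBq"]


def tacs_to_frame(tacs: dict, subject_id: str) -> pd.DataFrame:
    rows = []
    for region, tac in tacs.items():
        s = tac.schedule
        rows.append(
            pd.DataFrame(
                {
                    "frame_start_s": s.frame_starts,
                    "frame_duration_s": s.frame_durations,
                    "mid_time_s": s.mid_times,
                    "activity_kBq_per_mL": tac.activity,
                    "region": region,
                    "subject_id": subject_id,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[TAC_COLUMNS]


def frame_to_tacs(df: pd.DataFrame) -> dict:
    """Inverse of :func:`tacs_to_frame` for a single subject."""
    out = {}
    for region, grp in df.groupby("region", sort=False):
        grp = grp.sort_values("frame_start_s")
        schedule = FrameSchedule(
            grp["frame_start_s"].to_numpy(float), grp["frame_duration_s"].to_numpy(float)
        )
        out[region] = TimeActivityCurve(
            schedule, grp["activity_kBq_per_mL"].to_numpy(float), region_label=str(region)
        )
    return out


def write_cohort(cohort: CohortDataset, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for subj in cohort.subjects:
        m = subj.meta
        tacs_to_frame(subj.tacs, m.subject_id).to_csv(
            directory / f"{m.subject_id}_tac.csv", index=False, float_format="%.10g"
        )
        manifest.append([m.subject_id, m.genotype, m.age_months, m.weight_kg, m.injected_dose_MBq])
    pd.DataFrame(manifest, columns=MANIFEST_COLUMNS).to_csv(
        directory / "cohort_manifest.csv", index=False, float_format="%.10g"
    )
    design = cohort.design
    design_doc = {
        "genotypes": list(design.genotypes),
        "ages_months": list(design.ages_months),
        "n_per_cell": design.n_per_cell,
        "effect_map": {
            f"{g}|{a}": asdict(e) for (g, a), e in sorted(design.effect_map.items())
        },
        "noise_scale": design.noise_scale,
        "inter_subject_cv": design.inter_subject_cv,
        "side_cv": design.side_cv,
        "seed": design.seed,
        "plasma_input": asdict(cohort.input_params),
        "frame_durations_s": cohort.schedule.frame_durations.tolist(),
    }
    (directory / "design.json").write_text(json.dumps(design_doc, indent=2) + "\n")
    return directory


def read_cohort_design(directory) -> CohortDesign:
    doc = json.loads((Path(directory) / "design.json").read_text())
    effect_map = {}
    for key, eff in doc["effect_map"].items():
        genotype, age = key.rsplit("|", 1)
        effect_map[(genotype, int(age))] = GroupEffect(**eff)
    return CohortDesign(
        genotypes=tuple(doc["genotypes"]),
        ages_months=tuple(doc["ages_months"]),
        n_per_cell=doc["n_per_cell"],
        effect_map=effect_map,
        noise_scale=doc["noise_scale"],
        inter_subject_cv=doc["inter_subject_cv"],
        side_cv=doc["side_cv"],
        seed=doc["seed"],
    )


def read_cohort_tacs(directory) -> tuple[pd.DataFrame, dict]:
    """Load a cohort directory: (manifest DataFrame, {subject_id: {region: TAC}})."""
    directory = Path(directory)
    manifest_path = directory / "cohort_manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no cohort_manifest.csv in {directory}")
    manifest = pd.read_csv(manifest_path)
    tacs = {}
    for subject_id in manifest["subject_id"]:
        path = directory / f"{subject_id}_tac.csv"
        if path.exists():
            tacs[subject_id] = frame_to_tacs(pd.read_csv(path))
    return manifest, tacs


def subject_meta_from_row(row) -> SubjectMeta:
    return SubjectMeta(
        subject_id=str(row["subject_id"]),
        genotype=str(row["genotype"]),
        age_months=float(row["age_months"]),
        weight_kg=float(row["weight_kg"]),
        injected_dose_MBq=float(row["injected_dose_MBq"]),
    )
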