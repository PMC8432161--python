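"""Cohort-level summary tallies and end-to-end pipeline orchestration."""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from . import classifier as clf
from . import synthetic_data as synth
from .clustering import (DEFAULT_MIN_AREA_MM2, extract_clusters, rank_clusters,
                         write_cluster_manifest)
from .planning import (PlanningConfig, PowerConfig, count_extra_electrodes,
                       filter_clusters_for_planning, power_min_cohort)
from .seeg import assess_colocalization, classify_patient
from .surface_io import PatientRecord, ValidationError

FCD_HISTOLOGIES = ("FCD IIA", "FCD IIB", "FCD II")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class CohortSummary:
    n_total: int
    n_focal: int
    n_mtle: int
    n_diffuse_or_likely: int
    n_focal_concordant: int
    focal_concordance_pct: int
    n_fcd_histology: int
    n_fcd_concordant: int
    fcd_concordance_pct: int
    n_focal_surgery: int
    cluster_mean: float
    cluster_sd: float
    cluster_range: tuple
    n_focal_not_seizure_free_with_clusters: int
    # audit extras
    n_focal_not_seizure_free: int = 0
    n_focal_surgery_seizure_free: int = 0
    flags: list = field(default_factory=list)


def tally_cohort(records: Sequence[PatientRecord]) -> CohortSummary:
    """Aggregate a cohort table into the summary counts.

    Percentages are rounded to the nearest integer (halves away from zero);
    the cluster spread is the sample (n-1) standard deviation.
    """
    if not records:
        raise ValidationError("cannot tally an empty cohort")
    focal = [r for r in records if r.seeg_outcome == "focal"]
    mtle = [r for r in records if r.seeg_outcome == "mTLE"]
    other = [r for r in records if r.seeg_outcome in ("diffuse", "likely-focal")]
    focal_concordant = [r for r in focal if r.concordance == "yes"]
    fcd = [r for r in focal if r.histology in FCD_HISTOLOGIES]
    fcd_concordant = [r for r in fcd if r.concordance == "yes"]
    focal_surgery = [r for r in focal if r.surgery == "yes"]
    counts = np.array([r.n_clusters for r in records], dtype=float)
    not_free = [r for r in focal if r.seizure_free == "no"]
    not_free_with_clusters = [r for r in not_free if r.n_clusters >= 1]
    surgery_free = [r for r in focal_surgery if r.seizure_free == "yes"]

    def pct(num, den):
        return round_half_away(100.0 * num / den) if den else 0

    summary = CohortSummary(
        n_total=len(records),
        n_focal=len(focal),
        n_mtle=len(mtle),
        n_diffuse_or_likely=len(other),
        n_focal_concordant=len(focal_concordant),
        focal_concordance_pct=pct(len(focal_concordant), len(focal)),
        n_fcd_histology=len(fcd),
        n_fcd_concordant=len(fcd_concordant),
        fcd_concordance_pct=pct(len(fcd_concordant), len(fcd)),
        n_focal_surgery=len(focal_surgery),
        cluster_mean=float(counts.mean()),
        cluster_sd=float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        cluster_range=(int(counts.min()), int(counts.max())),
        n_focal_not_seizure_free_with_clusters=len(not_free_with_clusters),
        n_focal_not_seizure_free=len(not_free),
        n_focal_surgery_seizure_free=len(surgery_free),
    )
    if summary.n_focal_not_seizure_free != summary.n_focal_not_seizure_free_with_clusters:
        summary.flags.append("some non-seizure-free focal patients have 0 clusters")
    return summary


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

PIPELINE_KEYS = {
    "seed", "n_patients", "n_controls", "subdivision", "lesion_radius_mm",
    "lesion_effects", "min_area_mm2", "distance_threshold_mm", "top_k",
    "power_target", "power_confidence", "power_cohorts", "out_dir",
}


def validate_pipeline_config(config: dict) -> dict:
    unknown = set(config) - PIPELINE_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return config


def run_pipeline(config: dict) -> dict:
    """Synthetic end-to-end run: simulate -> features -> LOOCV -> cluster ->
    colocalize -> plan -> report. Deterministic for a fixed seed.

    Returns the summary dictionary; per-patient cluster manifests and the
    JSON summary are written to ``out_dir`` when given.
    """
    validate_pipeline_config(config)
    seed = int(config.get("seed", 0))
    spec = synth.SyntheticCohortSpec(
        n_patients=int(config.get("n_patients", 8)),
        n_controls=int(config.get("n_controls", 10)),
        subdivision=int(config.get("subdivision", 4)),
        lesion_radius_mm=config.get("lesion_radius_mm", 11.0),
        lesion_effects=config.get("lesion_effects",
                                  dict(synth.DEFAULT_LESION_EFFECTS)),
        seed=seed)
    min_area = float(config.get("min_area_mm2", DEFAULT_MIN_AREA_MM2))
    plan_cfg = PlanningConfig(
        top_k=int(config.get("top_k", 3)),
        distance_threshold_mm=float(config.get("distance_threshold_mm", 10.0)))

    cohort = synth.make_cohort(spec)
    patients, controls, _stats = synth.prepare_classifier_data(cohort)
    control_matrix = np.vstack([m for c in controls for m in c.matrices.values()])
    hidden = clf.select_hidden_size(control_matrix)

    cv = clf.loocv(patients, hidden, seed=seed, min_area_mm2=min_area)

    ts = clf.assemble_training_set(patients, seed=seed)
    model = clf.train_network(ts, hidden, seed=seed)
    model.decision_threshold = clf.youden_threshold(
        clf.predict_vertices(model, ts.X).values, ts.y)
    n_false, specificity = clf.control_specificity(model, controls,
                                                   min_area_mm2=min_area)

    mid = {h: cohort.surfaces[h]["mid"] for h in cohort.surfaces}
    per_patient = []
    n_extra_total = 0
    n_colocalized = 0
    for subject, patient in zip(patients, cohort.patients):
        clusters = []
        for hemi, matrix in subject.matrices.items():
            scores = clf.predict_vertices(model, matrix)
            clusters += extract_clusters(mid[hemi], scores,
                                         model.decision_threshold, min_area)
        clusters = rank_clusters(clusters)
        conc = assess_colocalization(clusters, mid, patient.electrodes,
                                     plan_cfg.distance_threshold_mm)
        filtered = filter_clusters_for_planning(
            clusters, patient.electrodes.implant_laterality, plan_cfg)
        extra = count_extra_electrodes(filtered, patient.electrodes, mid, plan_cfg)
        n_extra_total += extra
        if conc.colocalized:
            n_colocalized += 1
        per_patient.append({
            "subject_id": subject.subject_id,
            "n_clusters": len(clusters),
            "colocalized": conc.colocalized,
            "concordance": classify_patient(conc, "focal"),
            "extra_electrodes": extra,
            "clusters": clusters,
        })

    p_contrib = n_colocalized / len(patients)
    power_n = None
    if p_contrib > 0:
        power_n = power_min_cohort(PowerConfig(
            contribution_probability=p_contrib,
            target_successes=int(config.get("power_target", 10)),
            confidence=float(config.get("power_confidence", 0.90)),
            n_cohorts=int(config.get("power_cohorts", 1000)),
            seed=seed))

    summary = {
        "seed": seed,
        "parameters": {"hidden_size": hidden, "min_area_mm2": min_area,
                       "threshold": model.decision_threshold,
                       "distance_threshold_mm": plan_cfg.distance_threshold_mm},
        "loocv_sensitivity": cv.sensitivity,
        "control_specificity": specificity,
        "false_positive_clusters": n_false,
        "n_colocalized": n_colocalized,
        "contribution_probability": p_contrib,
        "extra_electrodes_total": n_extra_total,
        "power_min_cohort": power_n,
        "patients": [{k: v for k, v in p.items() if k != "clusters"}
                     for p in per_patient],
    }

    out_dir = config.get("out_dir")
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        for p in per_patient:
            write_cluster_manifest(
                os.path.join(out_dir, f"{p['subject_id']}_clusters.csv"),
                p["clusters"])
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary


def summary_to_dict(summary: CohortSummary) -> dict:
    d = asdict(summary)
    d["cluster_range"] = list(d["cluster_range"])
    return d
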