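"""End-to-end pipeline: simulate -> features -> scores -> SBR cutoffs -> report.

Deterministic for a fixed config: all randomness derives from the master seed,
and every stage logs the artefacts it writes.  Outputs land under the
configured directory; inputs are never mutated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_analysis, kinematics, scoring, synthetic_data
from .config import RunConfig
from .io import write_features, write_scores

logger = logging.getLogger("fluokin.pipeline")

#: metrics whose SBR dependence is scanned for a cutoff, and whether the
#: breakpoint fit runs on SBR-binned means (counts) or raw values
CUTOFF_METRICS = [
    ("HE", True),
    ("t_task_s", False),
    ("s_m", False),
    ("t_firefly_s", False),
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def extract_cohort_features(records, config: RunConfig) -> pd.DataFrame:
    """Kinematic feature table of a list of exercise records."""
    feats = [
        kinematics.extract_features(
            rec.track,
            exercise_id=rec.exercise_id,
            handling_errors=rec.handling_errors,
            sbr_min=min(rec.target_sbrs),
            window=config.smoothing_window,
            polyorder=config.smoothing_polyorder,
            jerk_threshold=config.jerk_threshold,
        )
        for rec in records
    ]
    return kinematics.features_to_frame(feats)


def run_pipeline(config: RunConfig, write_figures: bool = True) -> dict:
    """Run the full analysis and return the report dict.

    Stages: cohort simulation, kinematic feature extraction, scoring
    (dexterity / decision making / performance / proficiency), per-metric SBR
    cutoff detection and the feature correlation map.  Raises with the stage
    name and exercise id on failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    logger.info("stage simulate: %d exercises", config.n_exercises)
    records = synthetic_data.generate_cohort(
        config.n_exercises,
        config=config.trial,
        intensity_range=config.intensity_range,
        out_dir=out / "tracks",
        master_seed=config.seed,
    )

    logger.info("stage features")
    try:
        features = extract_cohort_features(records, config)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc
    features_path = out / "features.csv"
    write_features(features, features_path)

    logger.info("stage score")
    try:
        scores, score_meta = scoring.score_cohort(
            features,
            step=config.weight_grid_step,
            normalize_dm=config.normalize_dm,
            pca_method=config.pca_method,
            z=config.z_multiplier,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'score' failed: {exc}") from exc
    scores_path = out / "scores.csv"
    write_scores(scores, scores_path)

    logger.info("stage cutoff")
    sbr = features["sbr_min"].to_numpy(float)
    cutoffs = {}
    for metric, binned in CUTOFF_METRICS:
        try:
            res = cohort_analysis.detect_cutoff(
                features[metric].to_numpy(float), sbr,
                metric_name=metric, bin_counts=binned,
                grid_step=config.breakpoint_grid_step,
                bin_width=config.sbr_bin_width,
            )
            cutoffs[metric] = {
                "breakpoint": res.breakpoint,
                "r_squared": res.r_squared,
                "method": res.method,
                "no_clear_cutoff": res.no_clear_cutoff,
            }
        except ValueError as exc:
            cutoffs[metric] = {"error": str(exc)}
    valid_bps = [c["breakpoint"] for c in cutoffs.values() if "breakpoint" in c]
    mean_cutoff = cohort_analysis.average_cutoffs(valid_bps) if valid_bps else None
    with open(out / "cutoffs.json", "w", encoding="utf-8") as fh:
        json.dump({"per_metric": cutoffs, "mean_cutoff": mean_cutoff}, fh, indent=2)

    logger.info("stage correlation")
    corr, order = cohort_analysis.correlation_cluster(
        features,
        columns=["sbr_min", "s_m", "t_task_s", "t_firefly_s", "v_mps", "a_mps2",
                 "J", "n_J_extr", "ST", "Cr", "AD", "HE"],
    )
    corr.to_csv(out / "correlation_matrix.csv", float_format="%.6g")

    if write_figures:
        cohort_analysis.plot_correlation_heatmap(corr, str(out / "correlation_heatmap.png"))
        dens, xe, ye = kinematics.position_density(
            records[0].track, bin_size_mm=config.density_bin_mm
        )
        np.savetxt(out / "density_ex0.csv", dens, delimiter=",", fmt="%.6g")
        kinematics.plot_position_density(dens, xe, ye, str(out / "density_ex0.png"))

    report = {
        "config": config.to_dict(),
        "n_exercises": len(records),
        "scoring": score_meta,
        "cutoffs": cutoffs,
        "mean_cutoff": mean_cutoff,
        "artifacts": {
            p.name: _sha256(p)
            for p in [features_path, scores_path, out / "cutoffs.json"]
        },
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    logger.info("run complete: %s", out)
    return report
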