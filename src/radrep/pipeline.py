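"""End-to-end orchestration: simulate -> segment -> filter -> extract -> icc -> cluster.

``run_pipeline`` drives a full synthetic repeatability study from one config
and writes every stage product (cohort manifest, tidy feature tables, per-VOI
ICC tables, summaries, cluster composition) under a run directory.  Rerunning
with the same config and seed reproduces all CSV outputs bitwise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import icc as icc_mod
from .features import DEFAULT_BIN_WIDTH, feature_names, variant_feature_vector
from .filters import DEFAULT_LOG_SIGMAS_MM, image_variants, variant_names
from .grid import GridImage
from .phantom import CohortSpec, CohortSubject, GroupSpec, simulate_cohort
from .segmentation import (
    SUVCalibration,
    auto_contour_tbr,
    mirrored_center,
    sphere_mask,
    to_suv,
    tumor_sphere_series,
)

__all__ = ["PipelineConfig", "run_pipeline", "cohort_feature_tables", "segment_subject"]

log = logging.getLogger(__name__)

DEFAULT_DIAMETERS_MM = (10.0, 16.0, 20.0, 24.0, 30.0, 35.0, 40.0)


@dataclass
class PipelineConfig:
    """All knobs of a synthetic repeatability run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    tbr_threshold: float = 1.6
    background_diameter_mm: float = 30.0
    tumor_diameters_mm: tuple[float, ...] = DEFAULT_DIAMETERS_MM
    bin_width: float = DEFAULT_BIN_WIDTH
    log_sigmas_mm: tuple[float, ...] = DEFAULT_LOG_SIGMAS_MM
    wavelet: str = "coif1"
    icc_alpha: float = 0.05
    n_clusters: int = 2
    n_permutations: int = 1000
    injected_dose_mbq: float = 210.0
    body_weight_kg: float = 70.0
    suv_scale_to_background: bool = True
    cluster_condition: str = "test"  # which half feeds the clustering
    write_images: bool = False
    seed: int = 0

    # ------------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            cd = dict(d["cohort"])
            if "groups" in cd:
                cd["groups"] = [
                    GroupSpec(**{**g, "volume_range_ml": tuple(g.get("volume_range_ml", (1.4, 33.0)))})
                    if isinstance(g, dict)
                    else g
                    for g in cd["groups"]
                ]
            for key in ("shape", "spacing"):
                if key in cd:
                    cd[key] = tuple(cd[key])
            d["cohort"] = CohortSpec(**cd)
        for key in ("tumor_diameters_mm", "log_sigmas_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# --------------------------------------------------------------------- segmentation
def segment_subject(
    reference: GridImage, config: PipelineConfig
) -> dict[str, object]:
    """Define all VOIs for one subject on a reference image.

    The background sphere is mirrored across the axis-0 midline from the
    global-maximum voxel (a stand-in for manual contralateral placement); the
    tumor contour is the TBR auto-contour; the sphere series is centered on
    the tumor's maximum-uptake voxel.  Masks are then reused voxel-for-voxel
    on both halves.
    """
    vals = np.asarray(reference.values)
    peak = np.unravel_index(int(np.argmax(vals)), vals.shape)
    axes = reference.axis_coordinates()
    peak_mm = tuple(float(axes[ax][peak[ax]]) for ax in range(3))
    bg_center = mirrored_center(reference, peak_mm, axis=0)
    background = sphere_mask(
        reference, bg_center, config.background_diameter_mm, label="background_sphere"
    )
    tumor = auto_contour_tbr(reference, background, threshold=config.tbr_threshold)
    spheres = tumor_sphere_series(reference, tumor, config.tumor_diameters_mm)
    return {"background": background, "tumor": tumor, "spheres": spheres}


def _suv_images(subject: CohortSubject, config: PipelineConfig) -> tuple[GridImage, GridImage, GridImage]:
    """SUV-normalized test, retest and reference (mean of halves) images."""
    cal = SUVCalibration(config.injected_dose_mbq, config.body_weight_kg)
    if config.suv_scale_to_background:
        # simulation shortcut: activity is already in SUV-like units
        test, retest = subject.test, subject.retest
    else:
        test, retest = to_suv(subject.test, cal), to_suv(subject.retest, cal)
    reference = test.with_values(0.5 * (np.asarray(test.values) + np.asarray(retest.values)))
    return test, retest, reference


# ------------------------------------------------------------------- feature tables
def cohort_feature_tables(
    subjects: list[CohortSubject], config: PipelineConfig
) -> dict[str, dict[str, pd.DataFrame]]:
    """Extract the full feature bank for every subject and VOI.

    Returns ``tables[voi_label][condition]`` as subjects x features frames.
    VOI labels are ``tumor``, ``background`` and ``sphere_<d>mm`` per series
    diameter.
    """
    columns = feature_names(variant_names(config.log_sigmas_mm))
    rows: dict[str, dict[str, dict[str, dict[str, float]]]] = {}
    for subject in subjects:
        test, retest, reference = _suv_images(subject, config)
        vois = segment_subject(reference, config)
        voi_map = {"tumor": vois["tumor"], "background": vois["background"]}
        for d, sphere in zip(config.tumor_diameters_mm, vois["spheres"]):
            voi_map[f"sphere_{d:g}mm"] = sphere
        test_variants = image_variants(test, config.log_sigmas_mm, config.wavelet)
        retest_variants = image_variants(retest, config.log_sigmas_mm, config.wavelet)
        for label, voi in voi_map.items():
            ft = variant_feature_vector(
                test, voi, config.bin_width, variants=test_variants
            )
            fr = variant_feature_vector(
                retest, voi, config.bin_width, variants=retest_variants
            )
            rows.setdefault(label, {}).setdefault("test", {})[subject.subject_id] = ft
            rows.setdefault(label, {}).setdefault("retest", {})[subject.subject_id] = fr
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for label, conditions in rows.items():
        out[label] = {
            cond: pd.DataFrame.from_dict(data, orient="index")[columns]
            for cond, data in conditions.items()
        }
    return out


# ------------------------------------------------------------------------ pipeline
def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis and write all products under ``out_dir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    log.info("simulating cohort (%d groups)", len(config.cohort.groups))
    subjects = simulate_cohort(config.cohort)
    manifest_rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "genotype": s.genotype,
            "true_volume_mL": s.true_volume_ml,
        }
        if config.write_images:
            img_dir = out / "images"
            img_dir.mkdir(exist_ok=True)
            tpath = img_dir / f"{s.subject_id}_test.nii.gz"
            rpath = img_dir / f"{s.subject_id}_retest.nii.gz"
            s.test.save(tpath)
            s.retest.save(rpath)
            row["test_path"] = str(tpath)
            row["retest_path"] = str(rpath)
        manifest_rows.append(row)
    cohort_df = pd.DataFrame(manifest_rows)
    cohort_df.to_csv(out / "cohort.csv", index=False)

    log.info("extracting features for %d subjects", len(subjects))
    tables = cohort_feature_tables(subjects, config)
    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    for label, conds in tables.items():
        for cond, frame in conds.items():
            tidy = frame.reset_index(names="subject_id")
            tidy.insert(1, "condition", cond)
            tidy.insert(2, "voi_label", label)
            tidy.to_csv(feat_dir / f"{label}_{cond}.csv", index=False)

    log.info("scoring repeatability")
    icc_dir = out / "icc"
    icc_dir.mkdir(exist_ok=True)
    icc_tables: dict[str, pd.DataFrame] = {}
    summaries: dict[str, dict] = {}
    for label, conds in tables.items():
        table = icc_mod.icc_table(conds["test"], conds["retest"], alpha=config.icc_alpha)
        icc_tables[label] = table
        table.to_csv(icc_dir / f"{label}.csv")
        summaries[label] = icc_mod.repeatability_report(table)
    with open(out / "repeatability_summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2, default=str)

    log.info("clustering on repeatable tumor features")
    genotype = cohort_df.set_index("subject_id")["genotype"]
    cluster_payload: dict[str, object] = {"performed": False}
    tumor_icc = icc_tables["tumor"]
    if (tumor_icc["label"] == "repeatable").any():
        features = cluster_mod.select_repeatable_features(
            tables["tumor"][config.cluster_condition], tumor_icc
        )
        z = cluster_mod.zscore_features(features)
        result = cluster_mod.ward_cluster(z, n_clusters=config.n_clusters)
        composition = cluster_mod.genotype_composition(result, genotype)
        null = cluster_mod.purity_permutation_null(
            result, genotype, n_permutations=config.n_permutations, seed=config.seed
        )
        result.assignments.to_csv(out / "cluster_assignments.csv")
        composition.to_csv(out / "cluster_composition.csv")
        cluster_payload = {
            "performed": True,
            "n_repeatable_features": int(features.shape[1]),
            "composition": composition.to_dict(orient="index"),
            "permutation": null,
        }
    else:
        log.warning("no repeatable tumor features; skipping clustering")

    manifest = {
        "seed": config.seed,
        "n_subjects": len(subjects),
        "n_feature_columns": int(len(feature_names(variant_names(config.log_sigmas_mm)))),
        "voi_labels": sorted(tables.keys()),
        "overall_tumor": summaries["tumor"]["overall"],
        "cluster": cluster_payload,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
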