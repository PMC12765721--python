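"""End-to-end orchestration: simulate, measure, statistics.

A *study directory* holds one sub-directory per subject with per-tooth
files (``<tooth>_t0.ply``, ``<tooth>_t4.ply``, ``<tooth>_roi.json``,
``<tooth>_disclosed.png`` + ``<tooth>_mask.png``, optionally
``<tooth>_labels.png`` sparse annotations), a study-level ``scores.csv``
(TMQHPlI sites) and, for synthetic studies, ``truth.csv``.

Processing is fail-soft per surface and fail-hard per study: a surface
that errors at any stage is marked failed in the manifest and the run
continues; the run itself fails only when every surface does. All
randomness hangs off one root seed, and reruns on the same inputs and
seed are byte-identical (records CSV and stats JSON).
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

from . import clinical, io, planimetry, projection, registration, stats, synthetic, volumetry
from .core import SurfaceMesh, ValidationError

log = logging.getLogger(__name__)

RESULTS_SCHEMA_VERSION = "1"

RECORD_COLUMNS = [
    "subject_id", "tooth_id", "status",
    "roi_area_mm2", "vpi", "avpi", "covered_fraction", "plani_volmap",
    "plani_tot", "plani_dark", "plani_light", "rel_dark", "rel_light",
    "tmqhpli_tdp_mean", "tmqhpli_tdp_rounded", "tmqhpli_ddp_mean", "tmqhpli_ddp_rounded",
    "alignment_mad_mm", "alignment_sd_mm", "alignment_iterations", "alignment_converged",
]


@dataclass
class RunConfig:
    study_dir: Path = Path(".")
    output_dir: Path = Path("results")
    detection_limit: float = volumetry.DETECTION_LIMIT_MM
    trim_fraction: float = 0.6
    pixel_size: float = projection.DEFAULT_PIXEL_SIZE_MM
    seed: int = 0
    stat_config: stats.StatConfig = field(default_factory=stats.StatConfig)
    signed_volume: bool = False
    two_pass_planimetry: bool = False
    min_component_px: int = planimetry.MIN_COMPONENT_PX

    def __post_init__(self) -> None:
        self.study_dir = Path(self.study_dir)
        self.output_dir = Path(self.output_dir)
        if not (0 < self.trim_fraction <= 1):
            raise ValidationError("trim_fraction must be in (0, 1]")
        if self.detection_limit <= 0 or self.pixel_size <= 0:
            raise ValidationError("detection_limit and pixel_size must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        stat_kwargs = doc.pop("stat_config", {})
        cfg = cls(**{k: v for k, v in doc.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if stat_kwargs:
            cfg.stat_config = stats.StatConfig(**stat_kwargs)
        return cfg


# -- simulate --------------------------------------------------------------


def simulate_study(
    out_dir: str | Path,
    n_subjects: int = 3,
    teeth_per_subject: int = 3,
    seed: int = 0,
    edge_length: float = 0.25,
    n_label_surfaces: int = 2,
) -> Path:
    """Write a complete synthetic study directory (meshes, ROIs, images, scores).

    The first ``n_label_surfaces`` surfaces also get sparse annotation
    rasters (indexed PNG, 255 = unannotated) so the pixel classifier can
    be trained from the directory alone.
    """
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = synthetic.SyntheticSpec(edge_length=edge_length)
    surfaces = synthetic.generate_cohort(n_subjects, teeth_per_subject, seed=seed, base_spec=base)
    label_rng = np.random.default_rng(seed + 977)

    score_rows = []
    truth_rows = []
    for k, s in enumerate(surfaces):
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        io.save_mesh(s.mesh_t0, sdir / f"{s.tooth_id}_t0.ply")
        io.save_mesh(s.mesh_t4, sdir / f"{s.tooth_id}_t4.ply")
        roi_t0 = io.ROIMask(s.tooth_id, s.roi.vertex_ids, "T0")
        roi_t4 = io.ROIMask(s.tooth_id, s.roi.vertex_ids, "T4")
        io.save_roi([roi_t0, roi_t4], sdir / f"{s.tooth_id}_roi.json")
        Image.fromarray(s.image.rgb).save(sdir / f"{s.tooth_id}_disclosed.png")
        Image.fromarray((s.image.roi_pixel_mask * 255).astype(np.uint8), mode="L").save(
            sdir / f"{s.tooth_id}_mask.png"
        )
        if k < n_label_surfaces:
            lab = synthetic.labels_from_truth(s.truth_classes, s.image.roi_pixel_mask, label_rng)
            Image.fromarray(np.where(lab < 0, 255, lab).astype(np.uint8), mode="L").save(
                sdir / f"{s.tooth_id}_labels.png"
            )
        for variant, sites in (("TDP", s.tdp_sites), ("DDP", s.ddp_sites)):
            for site, score in zip(io.SITES, sites):
                score_rows.append(
                    {"subject_id": s.subject_id, "tooth_id": s.tooth_id, "variant": variant,
                     "site": site, "score": score}
                )
        gt = s.ground_truth
        truth_rows.append(
            {"subject_id": s.subject_id, "tooth_id": s.tooth_id,
             "true_volume_mm3": gt.true_volume, "true_area_mm2": gt.true_area,
             "true_coverage_fraction": gt.true_coverage_fraction,
             "true_dark_fraction": gt.true_dark_fraction}
        )
    pd.DataFrame(score_rows).to_csv(out / "scores.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False, float_format="%.10g")
    return out


# -- measure ---------------------------------------------------------------


def measure_surface(
    mesh_t0: SurfaceMesh,
    mesh_t4: SurfaceMesh,
    roi_t0: io.ROIMask,
    roi_t4: io.ROIMask,
    cfg: RunConfig,
) -> dict:
    """Volumetric measurement of one surface: align, field, indices, map."""
    sub_t0, _ = mesh_t0.submesh(roi_t0.vertex_ids)
    sub_t4, _ = mesh_t4.submesh(roi_t4.vertex_ids)
    init = registration.pre_align(sub_t4, sub_t0)
    report = registration.best_fit_roi(sub_t4, sub_t0, init=init, trim_fraction=cfg.trim_fraction)
    aligned_t4 = sub_t4.transformed(report.transform.rotation, report.transform.translation)
    fieldv = volumetry.signed_distance_field(
        sub_t0, aligned_t4, detection_limit=cfg.detection_limit, tooth_id=roi_t0.tooth_id
    )
    indices = volumetry.compute_vpi(fieldv, signed_volume=cfg.signed_volume)
    spec = projection.ProjectionSpec.for_roi(sub_t0, pixel_size=cfg.pixel_size)
    bool_map = projection.render_thickness_map(sub_t0, fieldv, spec, mode="boolean", cutoff=cfg.detection_limit)
    pvm = projection.planivolmap(bool_map)
    return {
        "roi_area_mm2": indices.roi_area,
        "vpi": indices.vpi,
        "avpi": indices.avpi,
        "covered_fraction": indices.covered_fraction,
        "plani_volmap": pvm,
        "alignment_mad_mm": report.mean_abs_distance,
        "alignment_sd_mm": report.sd_distance,
        "alignment_iterations": report.iterations,
        "alignment_converged": report.converged,
        "_field": fieldv,
        "_submesh_t0": sub_t0,
        "_bool_map": bool_map,
        "_transform": report.transform,
    }


def _load_image(sdir: Path, tooth: str) -> planimetry.DisclosedImage | None:
    from PIL import Image

    img_path = sdir / f"{tooth}_disclosed.png"
    mask_path = sdir / f"{tooth}_mask.png"
    if not img_path.exists() or not mask_path.exists():
        return None
    rgb = np.asarray(Image.open(img_path).convert("RGB"))
    mask = np.asarray(Image.open(mask_path).convert("L")) > 127
    return planimetry.DisclosedImage(rgb=rgb, roi_pixel_mask=mask, tooth_id=tooth)


def _train_study_classifier(cfg: RunConfig) -> planimetry.PixelClassifier | None:
    from PIL import Image

    images, labels = [], []
    for lab_path in sorted(cfg.study_dir.glob("*/*_labels.png")):
        tooth = lab_path.name.replace("_labels.png", "")
        img = _load_image(lab_path.parent, tooth)
        if img is None:
            continue
        raw = np.asarray(Image.open(lab_path).convert("L")).astype(np.int16)
        labels.append(np.where(raw == 255, -1, raw))
        images.append(img)
    if not images:
        return None
    try:
        return planimetry.train_classifier(images, labels, seed=cfg.seed)
    except ValidationError as exc:
        log.warning("classifier training skipped: %s", exc)
        return None


def run_study(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Process every surface of a study directory, then run the statistics.

    Returns (records, stats report) and writes ``records.csv``,
    ``stats.json`` and ``manifest.json`` to the output directory.
    """
    t_start = time.time()
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    clf = _train_study_classifier(cfg)

    scores_path = cfg.study_dir / "scores.csv"
    clinical_frame = None
    if scores_path.exists():
        records = clinical.summarize_scores(io.load_scores(scores_path))
        clinical_frame = clinical.records_to_frame(records).set_index(["subject_id", "tooth_id"])

    rows = []
    manifest = []
    subject_dirs = sorted(d for d in cfg.study_dir.iterdir() if d.is_dir())
    for sdir in subject_dirs:
        subject = sdir.name
        for roi_path in sorted(sdir.glob("*_roi.json")):
            tooth = roi_path.name.replace("_roi.json", "")
            entry = {"subject_id": subject, "tooth_id": tooth}
            try:
                mesh_t0 = io.load_mesh(sdir / f"{tooth}_t0.ply")
                mesh_t4 = io.load_mesh(sdir / f"{tooth}_t4.ply")
                rois = io.load_roi(roi_path)
                roi_t0 = next(r for r in rois if r.timepoint == "T0")
                roi_t4 = next(r for r in rois if r.timepoint == "T4")
                row = measure_surface(mesh_t0, mesh_t4, roi_t0, roi_t4, cfg)
                projection.save_map_png(row.pop("_bool_map"), cfg.output_dir / f"{subject}_{tooth}_boolmap.png")
                io.save_mesh(
                    row.pop("_submesh_t0"),
                    cfg.output_dir / f"{subject}_{tooth}_field.ply",
                    scalars=row["_field"].d,
                )
                (cfg.output_dir / f"{subject}_{tooth}_transform.json").write_text(
                    json.dumps(row.pop("_transform").as_matrix().tolist())
                )
                row.pop("_field")
                img = _load_image(sdir, tooth)
                if img is not None and clf is not None:
                    seg = planimetry.segment(img, clf, min_component_px=cfg.min_component_px)
                    fn = planimetry.indices_two_pass if cfg.two_pass_planimetry else planimetry.planimetric_indices
                    idx = fn(seg, img.roi_pixel_mask)
                    row.update(
                        plani_tot=idx.plani_tot, plani_dark=idx.plani_dark, plani_light=idx.plani_light,
                        rel_dark=idx.rel_dark, rel_light=idx.rel_light,
                    )
                entry.update(status="ok")
                rows.append({**entry, **row})
            except (ValidationError, IOError, StopIteration) as exc:
                log.error("surface %s/%s failed: %s", subject, tooth, exc)
                entry.update(status="failed", error=str(exc))
                rows.append({"subject_id": subject, "tooth_id": tooth, "status": "failed"})
            manifest.append(entry)

    if not manifest:
        raise ValidationError(f"no surfaces found in study directory {cfg.study_dir}")
    if all(e["status"] == "failed" for e in manifest):
        raise ValidationError("all surfaces failed")

    records_df = pd.DataFrame(rows)
    if clinical_frame is not None:
        records_df = records_df.join(clinical_frame, on=["subject_id", "tooth_id"])
    for col in RECORD_COLUMNS:
        if col not in records_df.columns:
            records_df[col] = np.nan
    records_df = records_df[RECORD_COLUMNS].sort_values(["subject_id", "tooth_id"]).reset_index(drop=True)

    csv_path = cfg.output_dir / "records.csv"
    with open(csv_path, "w", newline="") as fh:
        fh.write(f"# plaquemetry records schema v{RESULTS_SCHEMA_VERSION}\n")
        records_df.to_csv(fh, index=False, float_format="%.10g")

    report = run_stats(csv_path, cfg)
    manifest_doc = {
        "n_surfaces": len(manifest),
        "n_failed": sum(e["status"] == "failed" for e in manifest),
        "surfaces": manifest,
        "elapsed_s": round(time.time() - t_start, 2),
        "parameters": {
            "detection_limit_mm": cfg.detection_limit,
            "trim_fraction": cfg.trim_fraction,
            "pixel_size_mm": cfg.pixel_size,
            "seed": cfg.seed,
        },
    }
    (cfg.output_dir / "manifest.json").write_text(json.dumps(manifest_doc, sort_keys=True, indent=1))
    return records_df, report


def run_stats(records_csv: str | Path, cfg: RunConfig) -> dict:
    """Statistics from the records CSV alone (reproducible from the CSV)."""
    df = pd.read_csv(records_csv, comment="#", dtype={"subject_id": str, "tooth_id": str})
    ok = df[df["status"] == "ok"] if "status" in df.columns else df
    n_subjects = ok["subject_id"].nunique()
    if n_subjects < 2:
        log.warning("fewer than 2 subjects: statistics skipped")
        report = {"n_surfaces": int(len(ok)), "skipped": "fewer than 2 subjects"}
    else:
        report = stats.full_report(ok, cfg.stat_config, seed=cfg.seed)
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    (cfg.output_dir / "stats.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report
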