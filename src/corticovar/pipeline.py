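"""End-to-end orchestration: simulate -> thickness GLM -> covariance
deviation -> functional connectivity, with per-stage TSV outputs and
JSON audits.  Rerunning with an identical config and seed reproduces
byte-identical tables: all randomness flows from the config seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import covariance, fc, surface, synthetic
from .config import PipelineConfig
from .datatypes import meta_frame

__all__ = ["run_pipeline", "motion_screen"]

log = logging.getLogger(__name__)

_VERSION = "0.1.0"


def _audit(path: Path, stage: str, config: PipelineConfig, **extra) -> None:
    payload = {"stage": stage, "version": _VERSION, "seed": config.seed,
               "thresholds": {
                   "fwhm_surface": config.fwhm_surface,
                   "p_thresh": config.p_thresh,
                   "min_area": config.min_area,
                   "ci_level": config.ci_level,
                   "iters": config.iters,
                   "alpha_patient": config.alpha_patient,
                   "voxel_alpha": config.voxel_alpha,
                   "cluster_alpha": config.cluster_alpha,
                   "mask_alpha": config.mask_alpha,
               }}
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)


def motion_screen(runs, max_mm: float = 2.5, max_deg: float = 2.5):
    """Exclude runs whose motion exceeds the translation/rotation limits."""
    kept, excluded = [], []
    for run in runs:
        m = np.asarray(run.motion)
        if np.abs(m[:, :3]).max() > max_mm or np.abs(m[:, 3:]).max() > max_deg:
            excluded.append(run.subject.id)
        else:
            kept.append(run)
    if excluded:
        log.warning("motion screening excluded: %s", excluded)
    return kept, excluded


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on a synthetic cohort; return the report bundle.

    Writes cluster/covdev/FC tables as TSV plus one JSON audit per
    stage under ``out_dir``.  The returned dict holds the in-memory
    DataFrames keyed by stage name.
    """
    from .io import write_tsv

    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    bundle: dict = {}

    # --- simulate -------------------------------------------------------
    meta_thick = synthetic.make_cohort_meta(config.n_patients,
                                            config.n_controls_thickness,
                                            seed=seed)
    mesh = synthetic.make_toy_surface(config.mesh_subdivisions,
                                      config.mesh_radius)
    rng = np.random.default_rng(seed + 1)
    patch_center = int(rng.integers(mesh.n_vertices))
    d = np.linalg.norm(mesh.vertices - mesh.vertices[patch_center], axis=1)
    patch = np.where(d < 0.25 * config.mesh_radius)[0]
    thickness = synthetic.simulate_thickness_dataset(
        mesh, meta_thick, effect_patches=[(patch, 0.45)], noise_sd=0.15,
        seed=seed + 2)
    table = synthetic.simulate_region_table(meta_thick, seed=seed + 3)
    write_tsv(meta_frame(meta_thick), out / "subjects.tsv")

    # --- thickness GLM --------------------------------------------------
    stats = surface.vertex_group_glm(thickness, fwhm=config.fwhm_surface)
    clusters = surface.find_surface_clusters(stats, config.p_thresh,
                                             config.min_area)
    report = surface.cluster_report(clusters, thickness,
                                    fwhm=config.fwhm_surface)
    write_tsv(report, out / "thickness_clusters.tsv")
    _audit(out / "thickness_audit.json", "thickness_glm", config,
           n_clusters=len(clusters), injected_patch_center=patch_center)
    bundle["thickness_clusters"] = report

    # --- covariance deviation ------------------------------------------
    covdev = covariance.deviation_report(table, iters=config.iters,
                                         level=config.ci_level,
                                         alpha_patient=config.alpha_patient,
                                         seed=seed + 4,
                                         bonferroni=config.bonferroni)
    write_tsv(covdev, out / "covdev.tsv")
    _audit(out / "covdev_audit.json", "covariance_deviation", config,
           n_flagged=int(covdev["flagged"].sum()),
           redraws={str(k): v for k, v in
                    covariance.bootstrap_control_cis.last_redraws.items()})
    bundle["covdev"] = covdev

    # --- functional connectivity ---------------------------------------
    meta_fc = synthetic.make_cohort_meta(config.n_patients,
                                         config.n_controls_fc, seed=seed)
    runs = synthetic.simulate_bold_cohort(
        meta_fc, grid=config.grid, n_volumes=config.n_volumes, tr=config.tr,
        seed=seed + 5)
    runs, excluded = motion_screen(runs, config.motion_exclusion_mm,
                                   config.motion_exclusion_deg)
    roi_center = synthetic.default_roi_centers(config.grid)[0]
    zmaps_p, zmaps_c = [], []
    for run in runs:
        pre = fc.preprocess_bold(run, discard=config.discard,
                                 smooth_fwhm=config.smooth_fwhm,
                                 global_signal=config.global_signal)
        series = fc.extract_sphere_roi(pre, roi_center, config.roi_radius)
        zm = fc.subject_fc_zmap(pre, series, roi_name="seed")
        (zmaps_p if run.subject.group == "patient" else zmaps_c).append(zm)
    res = fc.group_fc_inference(
        zmaps_p, zmaps_c, mask=runs[0].mask, affine=runs[0].affine,
        voxel_alpha=config.voxel_alpha, cluster_alpha=config.cluster_alpha,
        mask_alpha=config.mask_alpha, mask_rule=config.mask_rule,
        correction=config.correction, n_perm=config.n_perm, seed=seed + 6)
    write_tsv(res.cluster_table, out / "fc_clusters.tsv")
    _audit(out / "fc_audit.json", "fc_inference", config,
           excluded_subjects=excluded,
           geometry=None if res.geometry is None else {
               "fwhm_mm": list(res.geometry.fwhm),
               "resels": res.geometry.resels},
           n_clusters=len(res.clusters))
    bundle["fc_clusters"] = res.cluster_table
    return bundle
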