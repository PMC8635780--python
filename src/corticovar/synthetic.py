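"""Synthetic cohorts for every pipeline stage.

Generates toy cortical surfaces with per-subject thickness maps,
region x subject thickness tables with group-specific covariance, and
BOLD-like 4-D runs with injected ROI-to-block connectivity plus drift,
motion-coupled and tissue nuisance components.  Every generator is a
pure function of its parameters and a seed.

The defaults emulate the study conditions the pipeline targets: 11
patients vs 24 sighted controls for thickness (15 controls for the
functional runs), six regions whose group means/sds follow the group
cluster table, 240 volumes at TR 2.25 s, and a patient-specific
covariance structure built from a one-factor model with the left
lingual gyrus as hub so the three reported deviant pairs (-0.71, -0.67,
+0.71) are present in the patient population but not in the controls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import trimesh

from .datatypes import (
    BoldRun,
    RegionThicknessTable,
    SubjectMeta,
    SurfaceMesh,
    ThicknessDataset,
)

__all__ = [
    "TABLE_REGIONS",
    "default_corr_patient",
    "default_corr_control",
    "make_cohort_meta",
    "make_toy_surface",
    "default_roi_centers",
    "default_block_centers",
    "simulate_thickness_dataset",
    "simulate_region_table",
    "simulate_bold_cohort",
]

# Six regions with group mean (sd) thickness in mm and peak MNI coordinates.
TABLE_REGIONS = pd.DataFrame(
    [
        ("lingual_L", "L", -35, -43, -14, 2.27, 0.33, 2.76, 0.38),
        ("calcarine_L", "L", -7, -85, 20, 1.64, 0.10, 1.48, 0.14),
        ("calcarine_R", "R", 19, -83, 13, 1.74, 0.23, 1.58, 0.11),
        ("inferior_frontal_R", "R", 54, 36, -7, 2.89, 0.20, 2.58, 0.23),
        ("lateral_orbital_R", "R", 46, 26, 1, 2.37, 0.17, 2.68, 0.22),
        ("occipital_pole_R", "R", 19, -98, 22, 2.41, 0.18, 2.03, 0.31),
    ],
    columns=[
        "name", "hemisphere", "peak_x", "peak_y", "peak_z",
        "mean_patient", "sd_patient", "mean_control", "sd_control",
    ],
)

# One-factor loadings: corr(i, j) = loading_i * loading_j off-diagonal,
# guaranteeing positive semi-definiteness.  The patient loadings place a
# hub on the lingual gyrus so that lingual x calcarine_L = -0.71,
# lingual x calcarine_R = -0.67 and lingual x IFG = +0.71.
_PATIENT_LOADINGS = np.array([0.95, -0.71 / 0.95, -0.67 / 0.95, 0.71 / 0.95,
                              0.30, 0.30])
_CONTROL_LOADINGS = np.full(6, np.sqrt(0.2))


def _factor_corr(loadings: np.ndarray) -> np.ndarray:
    c = np.outer(loadings, loadings)
    np.fill_diagonal(c, 1.0)
    return c


def default_corr_patient() -> np.ndarray:
    """Default patient inter-region correlation matrix (hub structure)."""
    return _factor_corr(_PATIENT_LOADINGS)


def default_corr_control() -> np.ndarray:
    """Default control inter-region correlation matrix (uniform 0.2)."""
    return _factor_corr(_CONTROL_LOADINGS)


def make_cohort_meta(n_patients: int = 11, n_controls: int = 24,
                     seed: int = 0) -> list[SubjectMeta]:
    """Subject metadata for a matched cohort.

    Patients receive a deprivation duration drawn from a triangular
    distribution on [65, 283] days (mode near the low end, mean ~138)
    and a decimal visual acuity log-uniform in [0.16, 1.0] (20/125 to
    20/20).  Each control is age-matched within +/-2 years and
    sex-matched to a patient, cycling over patients when there are more
    controls.
    """
    rng = np.random.default_rng(seed)
    sexes = ["F", "M"]
    patients = []
    for i in range(n_patients):
        age = float(rng.uniform(18, 32))
        patients.append(SubjectMeta(
            id=f"pat{i:02d}", group="patient", age=age,
            sex=sexes[int(rng.integers(2))],
            deprivation_days=float(rng.triangular(65, 66, 283)),
            acuity=float(np.exp(rng.uniform(np.log(0.16), np.log(1.0)))),
        ))
    controls = []
    for j in range(n_controls):
        if patients:
            ref = patients[j % n_patients]
            age = float(np.clip(ref.age + rng.uniform(-2, 2), 18, 35))
            sex = ref.sex
        else:
            age = float(rng.uniform(18, 32))
            sex = sexes[int(rng.integers(2))]
        controls.append(SubjectMeta(id=f"ctl{j:02d}", group="control",
                                    age=age, sex=sex))
    return patients + controls


def make_toy_surface(subdivisions: int = 3, radius: float = 50.0) -> SurfaceMesh:
    """Subdivided icosahedral sphere standing in for a cortical surface."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(vertices=np.asarray(ico.vertices, dtype=float),
                       triangles=np.asarray(ico.faces, dtype=np.int64))


def simulate_thickness_dataset(
    mesh: SurfaceMesh,
    meta: list[SubjectMeta],
    effect_patches: list[tuple[np.ndarray, float]] | None = None,
    age_slope: float = -0.01,
    sex_shift: float = 0.05,
    noise_sd: float = 0.15,
    smoothness_fwhm: float = 12.0,
    baseline: float = 2.5,
    seed: int = 0,
) -> ThicknessDataset:
    """Per-vertex thickness maps with group/age/sex effects + smooth noise.

    ``effect_patches`` is a list of ``(vertex_index_array, shift_mm)``
    pairs; the shift is added for patients only (patient minus control
    difference).  Noise is white Gaussian smoothed on the mesh with the
    same diffusion smoother the analysis uses, then rescaled to
    ``noise_sd`` per vertex, giving the spatial autocorrelation that
    cluster-based inference presumes.
    """
    from .surface import smooth_surface   # local import avoids cycle at import time

    if not meta:
        raise ValueError("subject list is empty")
    rng = np.random.default_rng(seed)
    n_vert = mesh.n_vertices
    ages = np.array([s.age for s in meta])
    mean_age = ages.mean()
    thick = np.empty((len(meta), n_vert))
    for i, s in enumerate(meta):
        base = np.full(n_vert, baseline)
        base += age_slope * (s.age - mean_age)
        base += sex_shift * (1.0 if s.sex == "M" else 0.0)
        if s.group == "patient" and effect_patches:
            for verts, shift in effect_patches:
                verts = np.asarray(verts, dtype=np.int64)
                if verts.min(initial=0) < 0 or verts.max(initial=-1) >= n_vert:
                    raise ValueError("effect patch outside the mesh")
                base[verts] += shift
        if noise_sd > 0:
            noise = rng.standard_normal(n_vert)
            if smoothness_fwhm > 0:
                noise = smooth_surface(mesh, noise, smoothness_fwhm)
            sd = noise.std()
            if sd > 0:
                noise *= noise_sd / sd
            base = base + noise
        thick[i] = np.maximum(base, 1e-3)
    return ThicknessDataset(mesh=mesh, subjects=list(meta), thickness=thick)


def simulate_region_table(
    meta: list[SubjectMeta],
    means_patient=None,
    sds_patient=None,
    means_control=None,
    sds_control=None,
    corr_patient: np.ndarray | None = None,
    corr_control: np.ndarray | None = None,
    regions: pd.DataFrame | None = None,
    seed: int = 0,
) -> RegionThicknessTable:
    """Region-mean thickness table from group-specific multivariate Gaussians.

    Defaults reproduce the six-region group cluster table's means/sds
    and the default hub/uniform correlation structures.
    """
    regions = TABLE_REGIONS if regions is None else regions
    n_regions = len(regions)
    means_patient = np.asarray(
        regions["mean_patient"] if means_patient is None else means_patient, float)
    sds_patient = np.asarray(
        regions["sd_patient"] if sds_patient is None else sds_patient, float)
    means_control = np.asarray(
        regions["mean_control"] if means_control is None else means_control, float)
    sds_control = np.asarray(
        regions["sd_control"] if sds_control is None else sds_control, float)
    if corr_patient is None:
        corr_patient = default_corr_patient() if n_regions == 6 \
            else _factor_corr(np.full(n_regions, np.sqrt(0.2)))
    else:
        corr_patient = np.asarray(corr_patient, float)
    if corr_control is None:
        corr_control = _factor_corr(np.full(n_regions, np.sqrt(0.2)))
    else:
        corr_control = np.asarray(corr_control, float)

    rng = np.random.default_rng(seed)
    rows = np.empty((len(meta), n_regions))
    chol = {}
    for grp, corr in (("patient", corr_patient), ("control", corr_control)):
        _check_corr(corr, n_regions, grp)
        # tiny jitter keeps the factorization stable for exactly singular inputs
        chol[grp] = np.linalg.cholesky(corr + 1e-10 * np.eye(n_regions))
    for i, s in enumerate(meta):
        z = rng.standard_normal(n_regions)
        if s.group == "patient":
            rows[i] = means_patient + (chol["patient"] @ z) * sds_patient
        else:
            rows[i] = means_control + (chol["control"] @ z) * sds_control
    rows = np.maximum(rows, 1e-3)
    return RegionThicknessTable(subjects=list(meta),
                                regions=regions.reset_index(drop=True),
                                values=rows)


def _check_corr(corr: np.ndarray, n: int, label: str) -> None:
    if corr.shape != (n, n):
        raise ValueError(f"{label} correlation matrix must be {n}x{n}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError(f"{label} correlation matrix is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError(f"{label} correlation matrix diagonal is not 1")
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValueError(f"{label} correlation matrix is not positive "
                         "semi-definite")


def _mni_like_affine(grid: tuple[int, int, int], voxel: float = 3.0) -> np.ndarray:
    aff = np.diag([voxel, voxel, voxel, 1.0])
    aff[:3, 3] = -voxel * (np.asarray(grid) - 1) / 2.0
    return aff


def default_roi_centers(grid: tuple[int, int, int] = (12, 14, 12)) -> list[tuple]:
    """Default seed-ROI world coordinate, at the lower-quarter voxel."""
    aff = _mni_like_affine(grid)
    ijk = np.array([g // 4 for g in grid], dtype=float)
    return [tuple((aff[:3, :3] @ ijk + aff[:3, 3]).tolist())]


def default_block_centers(grid: tuple[int, int, int] = (12, 14, 12)) -> list[tuple]:
    """Default connected-block world coordinate, at the upper-quarter voxel."""
    aff = _mni_like_affine(grid)
    ijk = np.array([(3 * g) // 4 for g in grid], dtype=float)
    return [tuple((aff[:3, :3] @ ijk + aff[:3, 3]).tolist())]


def _ar1(rng, t, rho=0.5):
    x = rng.standard_normal(t)
    for i in range(1, t):
        x[i] = rho * x[i - 1] + np.sqrt(1 - rho ** 2) * x[i]
    return x


def simulate_bold_cohort(
    meta: list[SubjectMeta],
    grid: tuple[int, int, int] = (12, 14, 12),
    n_volumes: int = 240,
    tr: float = 2.25,
    roi_centers: list[tuple[float, float, float]] | None = None,
    block_centers: list[tuple[float, float, float]] | None = None,
    connectivity: dict[str, np.ndarray] | None = None,
    block_radius_vox: int = 1,
    motion_sd: float = 0.05,
    drift_slope: float = 0.2,
    noise_sd: float = 1.0,
    nuisance_amp: float = 0.3,
    seed: int = 0,
) -> list[BoldRun]:
    """BOLD-like cohort with injected ROI-to-block connectivity.

    Each ROI k carries a latent unit-variance signal.  Voxels in target
    block b receive the mixture ``sum_k c[k, b] * s_k`` plus white noise
    scaled so the population correlation with s_k equals ``c[k, b]``
    (requires ``sum_k c[k, b]^2 < 1``, else the structure is infeasible
    and an error is raised).  ``connectivity`` maps group name to an
    (n_roi, n_block) matrix.  All voxels additionally receive a linear
    drift, a motion-coupled component and WM/CSF nuisance contributions;
    the global series is the mean over the mask of the assembled data.
    """
    grid = tuple(int(g) for g in grid)
    affine = _mni_like_affine(grid)
    if roi_centers is None:
        roi_centers = default_roi_centers(grid)
    if block_centers is None:
        block_centers = default_block_centers(grid)
    n_roi, n_block = len(roi_centers), len(block_centers)
    if connectivity is None:
        connectivity = {"patient": np.full((n_roi, n_block), 0.5),
                        "control": np.zeros((n_roi, n_block))}
    inv = np.linalg.inv(affine)

    def world_to_ijk(xyz):
        hom = np.r_[np.asarray(xyz, float), 1.0]
        return np.round((inv @ hom)[:3]).astype(int)

    shape = np.array(grid)
    mask = np.ones(grid, dtype=bool)
    for c in roi_centers + block_centers:
        ijk = world_to_ijk(c)
        if np.any(ijk < 0) or np.any(ijk >= shape):
            raise ValueError(f"center {c} falls outside the grid")

    def sphere_voxels(center_ijk, radius_vox):
        idx = np.indices(grid).reshape(3, -1).T
        d2 = ((idx - center_ijk) ** 2).sum(axis=1)
        return idx[d2 <= radius_vox ** 2]

    roi_vox = [sphere_voxels(world_to_ijk(c), 1) for c in roi_centers]
    block_vox = [sphere_voxels(world_to_ijk(c), block_radius_vox)
                 for c in block_centers]

    master = np.random.SeedSequence(seed)
    runs = []
    for s, child in zip(meta, master.spawn(len(meta))):
        rng = np.random.default_rng(child)
        c_mat = np.asarray(connectivity[s.group], dtype=float)
        if c_mat.shape != (n_roi, n_block):
            raise ValueError("connectivity matrix must be (n_roi, n_block)")
        resid_var = 1.0 - (c_mat ** 2).sum(axis=0)
        if np.any(resid_var <= 0):
            raise ValueError("infeasible connectivity: column sum of squares "
                             ">= 1 (non-PSD mixing)")
        t = n_volumes
        signals = rng.standard_normal((n_roi, t))
        data = noise_sd * rng.standard_normal(grid + (t,))
        for k, vox in enumerate(roi_vox):
            for i, j, l in vox:
                data[i, j, l] = signals[k] + 0.1 * rng.standard_normal(t)
        for b, vox in enumerate(block_vox):
            mix = c_mat[:, b] @ signals          # (t,)
            sd_e = np.sqrt(resid_var[b])
            for i, j, l in vox:
                data[i, j, l] = mix + sd_e * rng.standard_normal(t)
        # nuisance structure shared across voxels
        time = np.arange(t) / t
        drift = drift_slope * (time - time.mean())
        motion = np.cumsum(motion_sd * rng.standard_normal((t, 6)), axis=0)
        wm = _ar1(rng, t)
        csf = _ar1(rng, t)
        coup = nuisance_amp * rng.standard_normal(grid + (3,))
        data += drift
        data += (coup[..., 0, None] * motion[:, 0]
                 + coup[..., 1, None] * wm
                 + coup[..., 2, None] * csf)
        global_signal = data[mask].mean(axis=0)
        runs.append(BoldRun(subject=s, data=data, tr=tr, affine=affine,
                            mask=mask, motion=motion, wm=wm, csf=csf,
                            global_signal=global_signal))
    return runs
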