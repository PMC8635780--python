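"""Seed-based resting-state functional-connectivity group inference.

Preprocessing residualizes each voxel's series on an intercept, a
linear trend, the Friston-24 motion expansion and WM/CSF/global-mean
nuisance series (after discarding initial volumes), then smooths
volumes with a 3-D Gaussian kernel.  Subject-level connectivity is the
Fisher-z map of Pearson correlations between a 3 mm spherical seed mean
series and every voxel.  Group inference follows the two-stage scheme:
one-sample t-tests per group define where connectivity exists at all,
and the patient-control two-sample t-test is evaluated only inside that
mask, with cluster-level random-field (or permutation) correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import rft as rft_mod
from .core_stats import fisher_z
from .datatypes import BoldRun, ClusterRecord

__all__ = [
    "FcZMap",
    "FcGroupResult",
    "friston24_expand",
    "preprocess_bold",
    "extract_sphere_roi",
    "subject_fc_zmap",
    "group_fc_inference",
]

log = logging.getLogger(__name__)


@dataclass
class FcZMap:
    """One subject's Fisher-z connectivity map for one seed ROI."""

    subject_id: str
    roi: str
    z: np.ndarray                   # (X, Y, Z); NaN outside mask/degenerate
    n_degenerate: int = 0


@dataclass
class FcGroupResult:
    """Group-level FC inference for one seed ROI."""

    roi: str
    t_onesample_patient: np.ndarray
    t_onesample_control: np.ndarray
    significance_mask: np.ndarray   # bool (X, Y, Z)
    t_twosample: np.ndarray         # NaN outside significance_mask
    clusters: list[ClusterRecord] = field(default_factory=list)
    geometry: rft_mod.RftGeometry | None = None
    cluster_table: pd.DataFrame | None = None


def friston24_expand(motion: np.ndarray) -> np.ndarray:
    """Friston-24 motion regressors: [m, m^2, m_{t-1}, m_{t-1}^2].

    The lagged block's first row is zero-filled.  Input is the (T, 6)
    realignment table; output is (T, 24).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise ValueError("motion table must be (T >= 2, 6)")
    lag = np.vstack([np.zeros(6), motion[:-1]])
    return np.hstack([motion, motion ** 2, lag, lag ** 2])


def _nuisance_design(run: BoldRun, global_signal: bool) -> tuple[np.ndarray, list[str]]:
    t = run.n_volumes
    trend = np.arange(t, dtype=float)
    trend = (trend - trend.mean()) / t
    cols = [np.ones(t), trend]
    names = ["intercept", "trend"]
    f24 = friston24_expand(run.motion)
    cols.extend(f24.T)
    names.extend(f"friston24_{i}" for i in range(24))
    cols.extend([run.wm, run.csf])
    names.extend(["wm", "csf"])
    if global_signal:
        cols.append(run.global_signal)
        names.append("global")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in
               np.where(diag <= diag.max() * max(X.shape) * np.finfo(float).eps)[0]]
        raise np.linalg.LinAlgError(
            f"rank-deficient nuisance design; dependent columns: {bad}")
    return X, names


def preprocess_bold(run: BoldRun, discard: int = 10, smooth_fwhm: float = 6.0,
                    global_signal: bool = True) -> BoldRun:
    """Discard initial volumes, residualize nuisance structure, smooth.

    Per voxel, the residual of OLS on [intercept, linear trend,
    Friston-24, WM, CSF, (global mean)] replaces the series; volumes are
    then smoothed with a Gaussian of ``smooth_fwhm`` mm.  The returned
    run keeps the truncated nuisance series, so re-residualizing with
    ``discard=0, smooth_fwhm=0`` is a no-op (residuals are orthogonal to
    every regressor).
    """
    t = run.n_volumes
    if t - discard < 20:
        raise ValueError("fewer than 20 volumes would remain after discard")
    sl = slice(discard, None)
    trimmed = BoldRun(subject=run.subject, data=run.data[..., sl], tr=run.tr,
                      affine=run.affine, mask=run.mask,
                      motion=np.asarray(run.motion)[sl],
                      wm=np.asarray(run.wm)[sl], csf=np.asarray(run.csf)[sl],
                      global_signal=np.asarray(run.global_signal)[sl])
    X, _ = _nuisance_design(trimmed, global_signal)
    shape = trimmed.data.shape
    Y = trimmed.data.reshape(-1, shape[-1]).T          # (T, voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T.reshape(shape)
    if smooth_fwhm > 0:
        voxel = np.abs(np.diag(np.asarray(trimmed.affine))[:3])
        sigma = smooth_fwhm / np.sqrt(8.0 * np.log(2.0)) / voxel
        resid = ndimage.gaussian_filter(resid, sigma=(*sigma, 0.0))
    return BoldRun(subject=run.subject, data=resid, tr=run.tr,
                   affine=run.affine, mask=run.mask, motion=trimmed.motion,
                   wm=trimmed.wm, csf=trimmed.csf,
                   global_signal=trimmed.global_signal)


def extract_sphere_roi(run: BoldRun, center_world, radius: float = 3.0) -> np.ndarray:
    """Mean series over mask voxels whose centers lie within ``radius`` mm.

    ``radius=0`` selects the single nearest mask voxel.  An empty
    intersection is an error that reports the nearest mask voxel centre.
    """
    shape = run.data.shape[:3]
    ijk = np.indices(shape).reshape(3, -1).T
    world = run.voxel_to_world(ijk)
    d = np.linalg.norm(world - np.asarray(center_world, float), axis=1)
    inmask = run.mask.reshape(-1)
    if radius <= 0:
        d_masked = np.where(inmask, d, np.inf)
        sel = np.array([int(np.argmin(d_masked))])
    else:
        sel = np.where((d <= radius + 1e-9) & inmask)[0]
        if sel.size == 0:
            nearest = world[np.argmin(np.where(inmask, d, np.inf))]
            raise ValueError(
                f"no mask voxel within {radius} mm of {tuple(center_world)}; "
                f"nearest mask voxel centre is {tuple(np.round(nearest, 1))}")
    flat = run.data.reshape(-1, run.data.shape[-1])
    return flat[sel].mean(axis=0)


def subject_fc_zmap(run: BoldRun, roi_series: np.ndarray,
                    roi_name: str = "roi") -> FcZMap:
    """Fisher-z map of voxelwise correlation with the seed series.

    Correlations are clipped to +/-(1 - 1e-7) before atanh so seed
    voxels map to a large finite z.  Zero-variance voxels are set to NaN
    and counted.
    """
    roi_series = np.asarray(roi_series, dtype=float)
    if roi_series.shape[0] != run.n_volumes:
        raise ValueError("ROI series length does not match the run")
    shape = run.data.shape[:3]
    Y = run.data.reshape(-1, run.n_volumes)
    s = roi_series - roi_series.mean()
    sn = np.sqrt(s @ s)
    if sn == 0:
        raise ValueError("seed series has zero variance")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    yn = np.sqrt(np.einsum("ij,ij->i", Yc, Yc))
    degenerate = yn == 0
    yn = np.where(degenerate, 1.0, yn)
    r = (Yc @ s) / (yn * sn)
    z = fisher_z(r, clip=True)
    z[degenerate] = np.nan
    z = z.reshape(shape)
    z[~run.mask] = np.nan
    n_deg = int((degenerate.reshape(shape) & run.mask).sum())
    if n_deg:
        log.info("%d zero-variance voxels set missing in z-map", n_deg)
    return FcZMap(subject_id=run.subject.id, roi=roi_name, z=z,
                  n_degenerate=n_deg)


def _stack(zmaps: list[FcZMap]) -> np.ndarray:
    return np.stack([m.z for m in zmaps], axis=0)


def group_fc_inference(
    zmaps_patients: list[FcZMap],
    zmaps_controls: list[FcZMap],
    mask: np.ndarray,
    affine: np.ndarray,
    voxel_alpha: float = 0.001,
    cluster_alpha: float = 0.05,
    mask_alpha: float = 0.001,
    mask_rule: str = "union",
    correction: str = "rft",
    n_perm: int = 1000,
    seed: int = 0,
    roi_name: str = "roi",
) -> FcGroupResult:
    """Two-stage group inference on Fisher-z connectivity maps.

    One-sample t-tests within each group (two-tailed ``mask_alpha``)
    define the significance mask — by default the union, so a
    connection present in either group is testable.  Inside it, the
    pooled two-sample t-map is z-converted, thresholded at two-tailed
    ``voxel_alpha``, and sign-homogeneous 18-connected clusters receive
    corrected p-values from Gaussian random-field theory (smoothness
    estimated from the two-sample model residuals) or from a group-label
    permutation oracle.  Only clusters with corrected p below
    ``cluster_alpha`` are reported; each carries the group-mean z (and
    back-transformed r) at its peak.
    """
    if len(zmaps_patients) < 3 or len(zmaps_controls) < 3:
        raise ValueError("need at least 3 subjects per group")
    if mask_rule not in ("union", "intersection"):
        raise ValueError("mask_rule must be 'union' or 'intersection'")
    zp = _stack(zmaps_patients)
    zc = _stack(zmaps_controls)
    mask = np.asarray(mask, dtype=bool)
    valid = mask & np.isfinite(zp).all(axis=0) & np.isfinite(zc).all(axis=0)

    def one_sample(z):
        res = stats.ttest_1samp(z, popmean=0.0, axis=0)
        return res.statistic, res.pvalue

    tp, pp = one_sample(zp)
    tc, pc = one_sample(zc)
    sig_p = valid & (pp < mask_alpha)
    sig_c = valid & (pc < mask_alpha)
    sig = (sig_p | sig_c) if mask_rule == "union" else (sig_p & sig_c)

    result = FcGroupResult(roi=roi_name, t_onesample_patient=tp,
                           t_onesample_control=tc, significance_mask=sig,
                           t_twosample=np.full(mask.shape, np.nan))
    if not sig.any():
        log.warning("empty significance mask for ROI %s; no group test run",
                    roi_name)
        result.cluster_table = _cluster_table([], zp, zc, affine)
        return result

    n1, n2 = len(zp), len(zc)
    df = n1 + n2 - 2
    t2 = rft_mod._two_sample_t_map(np.nan_to_num(
        np.concatenate([zp, zc]), nan=0.0),
        np.arange(n1 + n2) < n1)
    t_in = np.where(sig, t2, np.nan)
    result.t_twosample = t_in

    zstat = rft_mod.t_to_z(np.nan_to_num(t2, nan=0.0), df)
    zthr = stats.norm.isf(voxel_alpha / 2.0)
    comps = rft_mod.label_clusters(zstat, zthr, sig)

    voxel = np.abs(np.diag(np.asarray(affine))[:3])
    stack_all = np.nan_to_num(np.concatenate([zp, zc]), nan=0.0)
    group_means = np.where(np.arange(n1 + n2)[:, None, None, None] < n1,
                           stack_all[:n1].mean(axis=0),
                           stack_all[n1:].mean(axis=0))
    resid = np.moveaxis(stack_all - group_means, 0, -1)
    geometry = rft_mod.estimate_fwhm(resid, valid, tuple(voxel))
    result.geometry = geometry

    if correction == "permutation":
        perm = rft_mod.permutation_cluster_p(zp, zc, sig,
                                             voxel_alpha=voxel_alpha,
                                             n_perm=n_perm, seed=seed)
        # permutation clusters are labelled identically (same threshold rule
        # up to the t vs z scale, which is monotone), so align by extent order
        pmap = {e: p for e, p in zip(perm.extents, perm.p)}
    clusters = []
    for vox in comps:
        extent = len(vox)
        if correction == "rft":
            cp = rft_mod.cluster_p(extent, voxel_alpha, geometry, df=df)
        else:
            cp = pmap.get(extent, 1.0)
        if cp >= cluster_alpha:
            continue
        tt = np.abs(t2[tuple(vox.T)])
        k = int(np.argmax(tt))
        peak = vox[k]
        hom = np.r_[peak.astype(float), 1.0]
        world = tuple(float(x) for x in (np.asarray(affine) @ hom)[:3])
        sgn = int(np.sign(t2[tuple(peak)]))
        clusters.append(ClusterRecord(
            peak_index=int(np.ravel_multi_index(peak, mask.shape)),
            peak_world=world, extent=float(extent),
            peak_p=float(2 * stats.t.sf(tt[k], df)), peak_t=float(t2[tuple(peak)]),
            sign=sgn, members=vox, corrected_p=float(cp)))
    result.clusters = clusters
    result.cluster_table = _cluster_table(clusters, zp, zc, affine)
    return result


def _cluster_table(clusters, zp, zc, affine) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        peak = np.unravel_index(cl.peak_index, zp.shape[1:])
        mz_p = float(np.nanmean(zp[(slice(None),) + peak]))
        mz_c = float(np.nanmean(zc[(slice(None),) + peak]))
        x, y, z = cl.peak_world
        rows.append({
            "peak_mni": f"{x:.0f}, {y:.0f}, {z:.0f}",
            "extent_voxels": int(cl.extent),
            "peak_t": cl.peak_t,
            "corrected_p": cl.corrected_p,
            "sign": cl.sign,
            "patient_mean_z": mz_p,
            "control_mean_z": mz_c,
            # group-mean z back-transformed to r, as printed on the figures
            "patient_mean_r": float(np.tanh(mz_p)),
            "control_mean_r": float(np.tanh(mz_c)),
        })
    return pd.DataFrame(rows, columns=["peak_mni", "extent_voxels", "peak_t",
                                       "corrected_p", "sign",
                                       "patient_mean_z", "control_mean_z",
                                       "patient_mean_r", "control_mean_r"])
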