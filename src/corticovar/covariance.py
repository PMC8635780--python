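"""Thickness-covariance deviation testing.

The statistic: a patient-group inter-regional Pearson correlation is
"deviant" when it (a) falls outside the bootstrapped confidence interval
of the same correlation in controls — resampling control subjects with
replacement at the patient sample size, 1000 iterations, 99% central
interval by default — and (b) is itself significantly nonzero at
``alpha_patient``.  Both conditions are reported for every pair; the
flag is their conjunction.  No multiplicity correction is applied by
default (an optional Bonferroni switch is provided for comparison).

Randomness policy: a master seed expands to an independent stream per
region pair via ``SeedSequence`` spawn keys, so adding or removing a
region never perturbs the other pairs' intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_stats import CorrResult, PercentileCI, correlation_p, percentile_ci
from .datatypes import RegionThicknessTable

__all__ = [
    "PairCorrelations",
    "CovDevReport",
    "SeedProfile",
    "CovariateResult",
    "patient_pair_correlations",
    "bootstrap_control_cis",
    "flag_deviations",
    "deviation_report",
    "seed_profile",
    "covariate_correlation",
]


@dataclass
class PairCorrelations:
    """Symmetric matrix of patient-group correlations with significance."""

    regions: list[str]
    r: np.ndarray                   # (R, R), unit diagonal
    p: np.ndarray                   # (R, R), 1.0 on diagonal
    n: int
    degenerate: np.ndarray          # (R,) bool, zero-variance columns

    def pairs(self):
        nr = len(self.regions)
        for i in range(nr):
            for j in range(i + 1, nr):
                yield i, j


@dataclass(frozen=True)
class CovDevReport:
    """Deviation verdict for one region pair."""

    pair: tuple[str, str]
    r_patient: float
    p_patient: float
    ci_lo: float
    ci_hi: float
    flagged: bool
    n_boot: int
    level: float
    seed: int
    degenerate: bool = False


@dataclass
class SeedProfile:
    """Deviation reports of one seed region against every other parcel."""

    seed_region: str
    entries: list[CovDevReport] = field(default_factory=list)


def _corr_matrix(values: np.ndarray):
    """Correlation matrix tolerant of zero-variance columns."""
    v = values - values.mean(axis=0)
    norm = np.sqrt((v ** 2).sum(axis=0))
    degenerate = norm == 0
    norm = np.where(degenerate, 1.0, norm)
    r = (v / norm).T @ (v / norm)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0), degenerate


def patient_pair_correlations(table: RegionThicknessTable) -> PairCorrelations:
    """Pearson correlations among all region pairs in the patient group."""
    vals = table.group_values("patient")
    n = vals.shape[0]
    if n < 3:
        raise ValueError("need at least 3 patients")
    r, degenerate = _corr_matrix(vals)
    nr = r.shape[0]
    p = np.ones((nr, nr))
    for i in range(nr):
        for j in range(i + 1, nr):
            if degenerate[i] or degenerate[j]:
                continue
            p[i, j] = p[j, i] = correlation_p(r[i, j], n)
    return PairCorrelations(regions=table.region_names, r=r, p=p, n=n,
                            degenerate=degenerate)


def _bootstrap_pair(x: np.ndarray, y: np.ndarray, n_draw: int, iters: int,
                    rng: np.random.Generator, max_redraw_frac: float = 0.5):
    """Bootstrap correlations for one pair; degenerate resamples redrawn."""
    n = len(x)
    rs = np.empty(iters)
    filled = 0
    redraws = 0
    while filled < iters:
        todo = iters - filled
        idx = rng.integers(0, n, size=(todo, n_draw))
        xs, ys = x[idx], y[idx]
        xs = xs - xs.mean(axis=1, keepdims=True)
        ys = ys - ys.mean(axis=1, keepdims=True)
        sx = np.sqrt((xs ** 2).sum(axis=1))
        sy = np.sqrt((ys ** 2).sum(axis=1))
        ok = (sx > 0) & (sy > 0)
        r = np.einsum("ij,ij->i", xs[ok], ys[ok]) / (sx[ok] * sy[ok])
        rs[filled:filled + r.size] = np.clip(r, -1.0, 1.0)
        filled += r.size
        redraws += todo - r.size
        if redraws > max_redraw_frac * iters:
            raise ValueError("more than half of bootstrap resamples were "
                             "degenerate; data unusable")
    return rs, redraws


def bootstrap_control_cis(
    table: RegionThicknessTable,
    n_draw: int | None = None,
    iters: int = 1000,
    level: float = 0.99,
    seed: int = 0,
    pairs: list[tuple[int, int]] | None = None,
) -> dict[tuple[int, int], PercentileCI]:
    """Per-pair bootstrap CIs of control-group correlations.

    Controls are resampled with replacement at size ``n_draw``
    (defaulting to the patient count) ``iters`` times per pair; the CI
    is the central ``level`` percentile interval of the resampled
    correlations.  Returns ``{(i, j): PercentileCI}`` over unordered
    pairs; redraw counts are stored on the function attribute
    ``bootstrap_control_cis.last_redraws`` for audit.
    """
    ctl = table.group_values("control")
    if ctl.shape[0] < 2:
        raise ValueError("need at least 2 controls to bootstrap")
    if iters < 100:
        raise ValueError("need at least 100 bootstrap iterations")
    if n_draw is None:
        n_draw = sum(1 for s in table.subjects if s.group == "patient")
        if n_draw == 0:
            n_draw = ctl.shape[0]
    nr = ctl.shape[1]
    if pairs is None:
        pairs = [(i, j) for i in range(nr) for j in range(i + 1, nr)]
    cis: dict[tuple[int, int], PercentileCI] = {}
    redraw_log: dict[tuple[int, int], int] = {}
    for (i, j) in pairs:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, j)))
        rs, redraws = _bootstrap_pair(ctl[:, i], ctl[:, j], n_draw, iters, rng)
        cis[(i, j)] = percentile_ci(rs, level)
        redraw_log[(i, j)] = redraws
    bootstrap_control_cis.last_redraws = redraw_log
    return cis


bootstrap_control_cis.last_redraws = {}


def flag_deviations(
    patient: PairCorrelations,
    cis: dict[tuple[int, int], PercentileCI],
    alpha_patient: float = 0.05,
    seed: int = 0,
    bonferroni: bool = False,
) -> list[CovDevReport]:
    """Conjunction rule: outside the control CI AND patient p < alpha.

    ``bonferroni=True`` divides ``alpha_patient`` by the number of pairs
    (off by default; the reference procedure is uncorrected).
    Degenerate pairs are reported but never flagged.
    """
    alpha = alpha_patient / len(cis) if (bonferroni and cis) else alpha_patient
    reports = []
    for (i, j), ci in sorted(cis.items()):
        r = float(patient.r[i, j])
        p = float(patient.p[i, j])
        degen = bool(patient.degenerate[i] or patient.degenerate[j])
        outside = (r < ci.lo) or (r > ci.hi)
        flagged = bool(outside and p < alpha and not degen)
        reports.append(CovDevReport(
            pair=(patient.regions[i], patient.regions[j]),
            r_patient=r, p_patient=p, ci_lo=ci.lo, ci_hi=ci.hi,
            flagged=flagged, n_boot=ci.n_samples, level=ci.level,
            seed=seed, degenerate=degen))
    return reports


def deviation_report(table: RegionThicknessTable, iters: int = 1000,
                     level: float = 0.99, alpha_patient: float = 0.05,
                     seed: int = 0, bonferroni: bool = False) -> pd.DataFrame:
    """End-to-end pairwise deviation analysis as a tidy table."""
    pc = patient_pair_correlations(table)
    cis = bootstrap_control_cis(table, iters=iters, level=level, seed=seed)
    reports = flag_deviations(pc, cis, alpha_patient=alpha_patient, seed=seed,
                              bonferroni=bonferroni)
    return pd.DataFrame([{
        "region_a": r.pair[0], "region_b": r.pair[1],
        "r_patient": r.r_patient, "p_patient": r.p_patient,
        "ci_lo": r.ci_lo, "ci_hi": r.ci_hi, "flagged": r.flagged,
    } for r in reports])


def seed_profile(table: RegionThicknessTable, seed_region: str,
                 iters: int = 1000, level: float = 0.99,
                 alpha_patient: float = 0.05, seed: int = 0) -> SeedProfile:
    """Deviation test of one seed region against every other parcel.

    Mirrors the pairwise machinery with the pair set restricted to
    (seed, parcel); the seed itself is excluded.
    """
    names = table.region_names
    if seed_region not in names:
        raise KeyError(f"unknown seed region {seed_region!r}; available: "
                       f"{', '.join(names)}")
    s = names.index(seed_region)
    pc = patient_pair_correlations(table)
    pairs = [tuple(sorted((s, j))) for j in range(len(names)) if j != s]
    cis = bootstrap_control_cis(table, iters=iters, level=level, seed=seed,
                                pairs=pairs)
    entries = flag_deviations(pc, cis, alpha_patient=alpha_patient, seed=seed)
    return SeedProfile(seed_region=seed_region, entries=entries)


@dataclass
class CovariateResult:
    """Correlation of regional thickness with a clinical covariate."""

    result: CorrResult
    loo_r: list[float]              # leave-one-out correlations, n entries
    n_used: int
    n_missing: int


def covariate_correlation(values, covariate,
                          drop_index: int | None = None) -> CovariateResult:
    """Thickness vs covariate correlation with leave-one-out sensitivity.

    Missing covariate entries are handled pairwise-complete (the count
    is reported).  ``drop_index`` removes one subject before the main
    estimate, matching sensitivity re-analyses on n-1 subjects; the
    leave-one-out list always refers to the full (complete-case) sample.
    """
    from .core_stats import pearson_r

    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if values.shape != covariate.shape:
        raise ValueError("values and covariate must have equal length")
    ok = np.isfinite(values) & np.isfinite(covariate)
    n_missing = int((~ok).sum())
    v, c = values[ok], covariate[ok]
    keep = np.arange(len(v))
    if drop_index is not None:
        keep = np.delete(keep, drop_index)
    if len(keep) < 3:
        raise ValueError("fewer than 3 complete cases after dropping")
    main = pearson_r(v[keep], c[keep])
    loo = [pearson_r(np.delete(v, k), np.delete(c, k)).r for k in range(len(v))]
    return CovariateResult(result=main, loo_r=loo, n_used=len(keep),
                           n_missing=n_missing)
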