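"""Elementary statistical kernels shared by every pipeline stage.

Pearson correlation with Student-t significance, the Fisher
variance-stabilizing transform, empirical percentile confidence
intervals, a least-squares GLM with contrast t-tests, and the pooled
two-sample t-test.  All kernels are pure functions of their arguments:
no RNG, no I/O, no global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrResult",
    "GlmFit",
    "PercentileCI",
    "pearson_r",
    "correlation_p",
    "fisher_z",
    "percentile_ci",
    "ols_glm",
    "two_sample_t",
]

#: clip bound applied to correlations before atanh when building z-maps;
#: voxels inside a seed ROI correlate at exactly 1 with the seed mean.
FISHER_CLIP = 1.0 - 1e-7


class DegenerateInputError(ValueError):
    """Raised when an input has no variance (or is otherwise unusable)."""


@dataclass(frozen=True)
class CorrResult:
    """A Pearson correlation with its two-tailed significance.

    Attributes
    ----------
    r : float
        Sample correlation coefficient, in [-1, 1].
    n : int
        Number of paired observations (subjects).
    p : float
        Two-tailed probability under the t reference distribution.
    df : int
        Degrees of freedom, ``n - 2``.
    degenerate : bool
        True when ``|r| >= 1`` so the t statistic is unbounded and the
        returned ``p`` of 0 should not be over-interpreted.
    """

    r: float
    n: int
    p: float
    df: int
    degenerate: bool = False


@dataclass(frozen=True)
class PercentileCI:
    """Empirical percentile confidence interval over a resample set."""

    lo: float
    hi: float
    level: float
    n_samples: int


@dataclass(frozen=True)
class GlmFit:
    """Least-squares fit of many responses on one design, with one contrast.

    ``betas`` has shape (k, n_targets); ``residuals`` (n_obs, n_targets);
    ``contrast_t`` and ``contrast_p`` have one entry per target.
    """

    betas: np.ndarray
    residuals: np.ndarray
    df_resid: int
    contrast_t: np.ndarray
    contrast_p: np.ndarray


def pearson_r(x, y) -> CorrResult:
    """Sample Pearson correlation between two vectors, with significance.

    Parameters
    ----------
    x, y : array-like
        Paired observations, equal length >= 3, each with nonzero variance.

    Raises
    ------
    DegenerateInputError
        If either vector is constant (a silent NaN would propagate into
        the bootstrap machinery undetected).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(dx @ dx)
    sy = np.sqrt(dy @ dy)
    if sx == 0 or sy == 0:
        raise DegenerateInputError("zero-variance input to pearson_r")
    r = float(np.clip((dx @ dy) / (sx * sy), -1.0, 1.0))
    p, degenerate = _corr_p_impl(r, n, tails=2)
    return CorrResult(r=r, n=n, p=p, df=n - 2, degenerate=degenerate)


def _corr_p_impl(r: float, n: int, tails: int) -> tuple[float, bool]:
    if abs(r) >= 1.0:
        return 0.0, True
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = tails * float(stats.t.sf(abs(t), df))
    return min(p, 1.0), False


def correlation_p(r: float, n: int, tails: int = 2) -> float:
    """Tail probability of a Pearson correlation of ``r`` at sample size ``n``.

    Uses the exact null distribution via ``t = r*sqrt(n-2)/sqrt(1-r^2)``
    referred to Student's t with ``n - 2`` degrees of freedom.  Two-tailed
    by default; symmetric in the sign of ``r``.  ``|r| >= 1`` returns 0
    (the statistic is unbounded); ``n < 3`` is an error.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 to test a correlation, got {n}")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    p, _ = _corr_p_impl(float(r), int(n), tails)
    return p


def fisher_z(r, clip: bool = False):
    """Fisher z-transform ``z = atanh(r) = 0.5*ln((1+r)/(1-r))``.

    With ``clip=True`` the input is first clipped to ``+/-(1 - 1e-7)`` so
    perfectly correlated voxels (e.g. inside the seed sphere) map to a
    large finite z rather than infinity.  Without clipping, ``|r| >= 1``
    is an error.  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -FISHER_CLIP, FISHER_CLIP)
    elif np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| >= 1 requires clip=True")
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def percentile_ci(samples, level: float = 0.99) -> PercentileCI:
    """Empirical central CI over a vector of (bootstrap) samples.

    Quantiles use linear interpolation between order statistics (the
    "type 7" rule, numpy's default), so the interval is continuous in
    the data and reproducible bit-for-bit.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if samples.size < 2:
        raise ValueError("need at least 2 finite samples for a percentile CI")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return PercentileCI(lo=float(lo), hi=float(hi), level=level,
                        n_samples=int(samples.size))


def _collinear_columns(X: np.ndarray) -> list[int]:
    # QR: columns with negligible R diagonal lie in the span of earlier ones
    _, Rm = np.linalg.qr(X)
    diag = np.abs(np.diag(Rm))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [int(j) for j in np.where(diag <= tol)[0]]


def ols_glm(Y, X, contrast) -> GlmFit:
    """Mass-univariate ordinary least squares with a single contrast t-test.

    Fits every column of ``Y`` (obs x targets) on the shared design ``X``
    (obs x k) and tests ``contrast @ beta = 0`` with
    ``t = c'b / sqrt(c'(X'X)^-1 c * sigma^2)`` on ``n - k`` degrees of
    freedom, two-tailed.

    Raises
    ------
    np.linalg.LinAlgError
        If the design is rank deficient; the message names the dependent
        columns.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = X.shape
    if Y.shape[0] != n:
        raise ValueError("Y and X disagree on the number of observations")
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != (k,):
        raise ValueError(f"contrast must have length {k}")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        bad = _collinear_columns(X)
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {k} columns); "
            f"collinear column indices: {bad}")
    if n <= k:
        raise ValueError("need more observations than design columns")
    xtx_inv = np.linalg.inv(X.T @ X)
    betas, *_ = np.linalg.lstsq(X, Y, rcond=None)   # QR/SVD solve, (k, m)
    resid = Y - X @ betas
    df = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    cvar = float(contrast @ xtx_inv @ contrast)
    se = np.sqrt(cvar * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (contrast @ betas) / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return GlmFit(betas=betas, residuals=resid, df_resid=df,
                  contrast_t=t, contrast_p=p)


def two_sample_t(a, b) -> tuple[float, float, int]:
    """Pooled-variance two-sample t-test (equal-variance, not Welch).

    Equivalent to the group contrast of :func:`ols_glm` with an
    intercept + group-indicator design, which is the formulation the
    standard vertex/voxel GLM packages use.  Returns ``(t, p, df)`` with
    ``df = n_a + n_b - 2`` and two-tailed ``p``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    df = na + nb - 2
    ssa = np.sum((a - a.mean()) ** 2)
    ssb = np.sum((b - b.mean()) ** 2)
    sp2 = (ssa + ssb) / df
    if sp2 == 0:
        raise DegenerateInputError("zero pooled variance in two_sample_t")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), min(p, 1.0), df
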