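"""Cohort-level statistics for precision-stepping summaries.

Implements the study's statistical layer: two-tailed Pearson correlations
of behavior with age, partial correlations controlling covariates (e.g.
intracranial volume or age) via double residualization, a repeated-measures
ANCOVA over the four ARD conditions with age as a continuous
between-subject covariate and Greenhouse-Geisser (GG) correction of the
within-subject degrees of freedom, Benjamini-Hochberg FDR over an
explicitly supplied family of p values, and permutation p values for
Pearson correlations.

The RM-ANCOVA follows the classic univariate mixed-model form: the
between-subject covariate is tested on subject means with df (1, n-2);
within-subject effects are tested on orthonormal within-subject contrasts
with uncorrected dfs (k-1, (k-1)(n-2)), multiplied by the GG epsilon
estimated from the residual covariance of the contrasts (after removing
the covariate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "EffectTest",
    "RmAncovaResult",
    "FdrResult",
    "pearson_corr",
    "partial_corr",
    "rm_ancova",
    "fdr_bh",
    "permutation_pearson",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    df: int  # n - 2 - (#partialled covariates)
    p: float  # two-tailed
    n_covariates: int = 0
    p_perm: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r={self.r} outside [-1, 1]")


@dataclass(frozen=True)
class EffectTest:
    F: float
    df1: float
    df2: float
    p: float
    epsilon: float | None = None  # GG epsilon; None for between-subject tests
    df1_uncorrected: float | None = None
    df2_uncorrected: float | None = None


@dataclass(frozen=True)
class RmAncovaResult:
    n: int
    k: int
    age: EffectTest  # between-subject covariate, df (1, n-2)
    ard: EffectTest  # within-subject factor, GG-corrected
    interaction: EffectTest  # ARD x age, GG-corrected


@dataclass(frozen=True)
class FdrResult:
    reject: np.ndarray
    adjusted: np.ndarray
    q: float


def _validate_xy(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    return x, y


def pearson_corr(x, y) -> CorrelationResult:
    """Bivariate product-moment correlation with a two-tailed t-based p."""
    x, y = _validate_xy(x, y)
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), n=x.size, df=x.size - 2, p=float(res.pvalue)
    )


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_corr(x, y, covariates) -> CorrelationResult:
    """Correlation of x and y after linearly removing ``covariates`` from both.

    ``covariates`` is (n,) or (n, c).  The p value uses a t test with
    df = n - 2 - c.  Collinear covariates or zero residual variance raise
    ValueError.
    """
    x, y = _validate_xy(x, y)
    Z = np.asarray(covariates, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != x.size:
        raise ValueError("covariates must have one row per observation")
    c = Z.shape[1]
    n = x.size
    if n <= 2 + c:
        raise ValueError(f"need n > 2 + {c} covariates, got n={n}")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero residual variance after removing covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - c
    tstat = r * np.sqrt(df / max(1.0 - r * r, np.finfo(float).tiny))
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    return CorrelationResult(r=r, n=n, df=df, p=p, n_covariates=c)


def _gg_epsilon(S: np.ndarray, k: int) -> float:
    """Greenhouse-Geisser epsilon from a (k-1)x(k-1) contrast covariance."""
    tr = float(np.trace(S))
    tr2 = float(np.trace(S @ S))
    eps = tr * tr / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_ancova(per_condition, age) -> RmAncovaResult:
    """Repeated-measures ANCOVA: within factor (k conditions) x age covariate.

    ``per_condition`` is a complete (n, k) matrix of one measure per subject
    and condition; ``age`` is the continuous between-subject covariate
    (centered internally).  Missing cells raise ValueError (no imputation).
    """
    Y = np.asarray(per_condition, float)
    age = np.asarray(age, float)
    if Y.ndim != 2:
        raise ValueError("per_condition must be an (n, k) matrix")
    n, k = Y.shape
    if age.shape != (n,):
        raise ValueError("age must have one value per subject")
    if not np.isfinite(Y).all() or not np.isfinite(age).all():
        raise ValueError("missing or non-finite cells; no imputation is done")
    if n < 5:
        raise ValueError(f"need at least 5 subjects, got {n}")
    if k < 2:
        raise ValueError("need at least 2 within-subject conditions")
    xc = age - age.mean()
    Sxx = float(xc @ xc)
    if Sxx == 0:
        raise ValueError("age has zero variance")

    # between-subject covariate test on subject means, df (1, n-2)
    m = Y.mean(axis=1)
    b = float(xc @ (m - m.mean())) / Sxx
    fitted = m.mean() + b * xc
    ss_age = float(b * b * Sxx)
    sse_b = float(np.sum((m - fitted) ** 2))
    F_age = ss_age / (sse_b / (n - 2))
    age_test = EffectTest(
        F=F_age, df1=1.0, df2=float(n - 2), p=float(stats.f.sf(F_age, 1, n - 2))
    )

    # within-subject effects on orthonormal contrasts
    C = np.linalg.svd(np.eye(k) - np.ones((k, k)) / k)[0][:, : k - 1]
    Z = Y @ C  # (n, k-1)
    X = np.column_stack([np.ones(n), xc])
    B, *_ = np.linalg.lstsq(X, Z, rcond=None)
    E = Z - X @ B
    S = E.T @ E
    sse_w = float(np.trace(S))
    df1_u = float(k - 1)
    df2_u = float((k - 1) * (n - 2))
    mse = sse_w / df2_u
    eps = _gg_epsilon(S, k)

    def within_test(ss: float) -> EffectTest:
        F = (ss / df1_u) / mse
        d1, d2 = eps * df1_u, eps * df2_u
        return EffectTest(
            F=float(F),
            df1=float(d1),
            df2=float(d2),
            p=float(stats.f.sf(F, d1, d2)),
            epsilon=eps,
            df1_uncorrected=df1_u,
            df2_uncorrected=df2_u,
        )

    ss_ard = float(n * np.sum(B[0] ** 2))
    ss_int = float(Sxx * np.sum(B[1] ** 2))
    return RmAncovaResult(
        n=n,
        k=k,
        age=age_test,
        ard=within_test(ss_ard),
        interaction=within_test(ss_int),
    )


def fdr_bh(pvals, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up FDR control at level ``q``.

    Returns the rejection mask and monotone adjusted p values; an empty
    input yields empty outputs.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return FdrResult(
            reject=np.zeros(0, bool), adjusted=np.zeros(0, float), q=q
        )
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return FdrResult(reject=reject, adjusted=adjusted, q=q)


def permutation_pearson(
    x, y, n_perm: int = 5000, seed: int | np.random.Generator | None = None
) -> CorrelationResult:
    """Two-sided permutation p value for the Pearson correlation.

    ``p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)`` over random
    permutations of ``y``.
    """
    x, y = _validate_xy(x, y, min_n=5)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    n = x.size
    r_obs = float(xz @ yz) / n
    count = 0
    for _ in range(n_perm):
        r_p = float(xz @ rng.permutation(yz)) / n
        if abs(r_p) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    base = pearson_corr(x, y)
    return CorrelationResult(
        r=base.r,
        n=base.n,
        df=base.df,
        p=base.p,
        p_perm=float(p),
        n_perm=int(n_perm),
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )
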