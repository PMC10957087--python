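"""Shared inferential machinery.

Group inference throughout the package is permutation-based: paired
comparisons use sign-flip permutation t-tests (default 20,000
permutations, exhaustive enumeration whenever feasible), one-sample
model-correlation tests use classical right-tailed t-tests, and
multiple testing is controlled with Benjamini-Hochberg FDR.  Partial
Spearman correlation (rank, residualize on covariate ranks, Pearson on
residuals) backs the TRF-fMRI fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_N_PERM = 20_000


@dataclass
class TestResult:
    statistic: float
    p: float
    df: float
    tail: str  # {"two", "right"}
    q: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    flagged: bool = False


def _paired_t(d: np.ndarray) -> float:
    """t statistic of mean(d) against 0; ±inf for zero-variance nonzero d."""
    n = d.size
    sd = d.std(ddof=1)
    m = d.mean()
    if sd == 0:
        return 0.0 if m == 0 else np.sign(m) * np.inf
    return m / (sd / np.sqrt(n))


def permutation_paired_ttest(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> TestResult:
    """Two-sided sign-flip permutation paired t-test.

    The p-value is the proportion of sign-flip permutations (including
    the identity) whose |t| meets or exceeds the observed |t|.  When
    ``2**n <= n_perm`` all sign patterns are enumerated and the p-value
    is exact; otherwise ``n_perm`` random flips are drawn (the identity
    flip is always included).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be matched 1-D samples")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    t_obs = _paired_t(d)
    exhaustive = 2**n <= n_perm
    if exhaustive:
        # all sign patterns via the bits of 0..2^n-1
        codes = np.arange(2**n, dtype=np.int64)
        signs = 1 - 2 * ((codes[:, None] >> np.arange(n)) & 1)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1, 1], size=(n_perm, n))
        signs[0] = 1  # identity flip always in the reference distribution
    flipped = signs * d
    m = flipped.mean(axis=1)
    sd = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = m / (sd / np.sqrt(n))
        t_perm = np.where(sd == 0,
                          np.where(m == 0, 0.0, np.sign(m) * np.inf), t_perm)
    p = float(np.mean(np.abs(t_perm) >= np.abs(t_obs) - 1e-12))
    return TestResult(
        statistic=float(t_obs), p=p, df=n - 1, tail="two",
        n_perm=int(signs.shape[0]), seed=None if exhaustive else seed,
    )


def fdr_bh(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(q, reject)``: monotone adjusted p-values and the
    rejection mask at level ``alpha``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return q.reshape(p.shape), reject.reshape(p.shape)


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | list[np.ndarray] | None = None,
) -> float:
    """Partial Spearman correlation of ``x`` and ``y`` given covariates.

    All vectors are rank-transformed (average ranks for ties); the
    ranks of ``x`` and ``y`` are each regressed on the covariate ranks
    (with intercept) and the residuals are Pearson-correlated.  With no
    covariates this reduces to the plain Spearman correlation.  Returns
    NaN for constant inputs.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if covariates is None:
        covariates = []
    elif isinstance(covariates, np.ndarray) and covariates.ndim == 1:
        covariates = [covariates]
    covs = [np.asarray(c, dtype=float).ravel() for c in covariates]
    n = x.size
    if y.size != n or any(c.size != n for c in covs):
        raise ValueError("all vectors must have the same length")
    if n < len(covs) + 3:
        raise ValueError("too few observations for the requested covariates")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if covs:
        Z = np.column_stack([np.ones(n)] + [stats.rankdata(c) for c in covs])
        ss_rank = np.sum((np.arange(n) - (n - 1) / 2.0) ** 2)
        rx = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
        ry = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
        # a vector fully explained by the covariates carries no partial
        # association; treat numerically-zero residuals as exactly zero
        if (rx @ rx) < 1e-12 * ss_rank or (ry @ ry) < 1e-12 * ss_rank:
            return 0.0
    denom = np.sqrt((rx - rx.mean()) @ (rx - rx.mean())
                    * ((ry - ry.mean()) @ (ry - ry.mean())))
    if denom == 0:
        return np.nan
    return float((rx - rx.mean()) @ (ry - ry.mean()) / denom)


def right_tailed_onesample_t(x: np.ndarray, mu0: float = 0.0) -> TestResult:
    """Classical one-sample t-test with a right-tail alternative."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if x.std(ddof=1) == 0:
        m = x.mean() - mu0
        t = 0.0 if m == 0 else np.sign(m) * np.inf
        p = 1.0 if m <= 0 else 0.0
        return TestResult(statistic=float(t), p=p, df=x.size - 1,
                          tail="right", flagged=True)
    res = stats.ttest_1samp(x, mu0, alternative="greater")
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      df=x.size - 1, tail="right")


def orthogonal_poly_contrasts(k: int) -> np.ndarray:
    """Linear and quadratic orthogonal polynomial contrasts over k levels.

    Rows are the contrasts (each zero-sum, unit-norm); the linear row
    increases with level, the quadratic row is U-shaped (positive at
    the extremes).
    """
    levels = np.arange(k, dtype=float)
    V = np.vander(levels, 3, increasing=True)  # 1, x, x^2
    Q, _ = np.linalg.qr(V)
    contrasts = Q[:, 1:3].T
    # fix signs: linear ascending, quadratic positive at the ends
    if contrasts[0, -1] < contrasts[0, 0]:
        contrasts[0] *= -1
    if contrasts[1, 0] < 0:
        contrasts[1] *= -1
    return contrasts
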