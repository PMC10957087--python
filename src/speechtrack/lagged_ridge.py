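"""Time-lagged ridge regression: forward TRFs and backward reconstruction.

A temporal response function (TRF) is the per-channel lagged linear
kernel mapping the speech envelope to the EEG; conceptually an ERP to a
continuous regressor.  The forward model uses lags -200..800 ms and a
ridge parameter of 1e5; the backward (reconstruction) model predicts
the envelope from all channels jointly at lags -200..0 ms with a ridge
parameter of 1e4.  Both are fitted with leave-one-trial-out
cross-validation, pooling the lines of one subject x stream x condition
cell, and evaluated on held-out trials.

Conventions (fixed here, unit-tested via impulse examples):

* forward lag tau means EEG at time t is predicted from the envelope at
  t - tau; backward lags in [-200, 0] ms mean the envelope at t is
  predicted from EEG in [t, t + 200 ms];
* lagged design columns are zero-padded at the epoch edges (all epochs
  keep their full length);
* within each training fold, predictor columns are z-scored and targets
  centred; the ridge penalty is lambda times the identity in that
  scaled space.  Reported TRF weights are rescaled back to original
  predictor units.  Absolute TRF amplitude is therefore
  convention-dependent; every downstream statistic (correlations, RDMs)
  is invariant to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

DEFAULT_FORWARD_LAMBDA = 1e5
DEFAULT_BACKWARD_LAMBDA = 1e4
FORWARD_LAGS_MS = (-200.0, 800.0)
BACKWARD_LAGS_MS = (-200.0, 0.0)

_EPS = 1e-12


@dataclass(frozen=True)
class LagSpec:
    """Contiguous integer lag set derived from a millisecond window."""

    t_min_ms: float
    t_max_ms: float
    rate: float

    def __post_init__(self) -> None:
        if self.t_min_ms > self.t_max_ms:
            raise ValueError("t_min_ms must not exceed t_max_ms")

    @property
    def lag_samples(self) -> np.ndarray:
        lo = int(round(self.t_min_ms * self.rate / 1000.0))
        hi = int(round(self.t_max_ms * self.rate / 1000.0))
        return np.arange(lo, hi + 1)

    @property
    def lag_times_ms(self) -> np.ndarray:
        return self.lag_samples * 1000.0 / self.rate

    @property
    def n_lags(self) -> int:
        return self.lag_samples.size


@dataclass
class TRF:
    """Per-channel lagged kernel for one condition cell and stream.

    With a multi-input stimulus (e.g. both speech streams fitted
    jointly) ``weights`` concatenates the per-input kernels
    input-major; :meth:`input_weights` slices one input's kernel.
    """

    weights: np.ndarray  # [n_channels x (n_inputs * n_lags)], original units
    lags_ms: np.ndarray
    rate: float
    lam: float
    n_inputs: int = 1
    stream: str | None = None
    condition_index: int | None = None

    def input_weights(self, i: int = 0) -> np.ndarray:
        """Kernel of input ``i``, shape [n_channels x n_lags]."""
        n_lags = self.lags_ms.size
        return self.weights[:, i * n_lags:(i + 1) * n_lags]

    def nonnegative(self, i: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Weights and times restricted to lags >= 0 (the causal part)."""
        mask = self.lags_ms >= 0
        return self.input_weights(i)[:, mask], self.lags_ms[mask]


def build_lag_matrix(x: np.ndarray, spec: LagSpec) -> np.ndarray:
    """Lagged design matrix [n_samples x (n_inputs * n_lags)].

    Column ``(i, j)`` holds input ``i`` delayed by ``lag_samples[j]``:
    ``X[t, i * n_lags + j] = x[i, t - lag_j]``, zero-padded at the
    edges.  Column order is input-major, lag-minor.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    lags = spec.lag_samples
    if lags.size == 0:
        raise ValueError("empty lag set")
    n_inputs, n_samples = x.shape
    X = np.zeros((n_samples, n_inputs * lags.size))
    for i in range(n_inputs):
        for j, lag in enumerate(lags):
            col = i * lags.size + j
            if lag >= 0:
                X[lag:, col] = x[i, : n_samples - lag] if lag < n_samples else 0.0
            else:
                X[:lag, col] = x[i, -lag:]
    return X


def fit_ridge(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge solution ``argmin ||Y - Xw||^2 + lam ||w||^2``.

    ``X`` is used as given — callers are responsible for any column
    scaling convention.  Solved from the normal equations with a
    Cholesky-backed positive-definite solve (exact for lam > 0).
    """
    if lam < 0:
        raise ValueError("ridge parameter must be non-negative")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    A = X.T @ X + lam * np.eye(X.shape[1])
    b = X.T @ Y
    try:
        return linalg.solve(A, b, assume_a="pos")
    except linalg.LinAlgError:
        return linalg.lstsq(A, b)[0]


def standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score columns; returns (scaled X, means, stds). Constant columns
    keep std 1 so they scale to exactly zero."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < _EPS, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally shaped 2-D arrays."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / denom
    return np.where(denom < _EPS, np.nan, r)


class _LooRidge:
    """Leave-one-trial-out ridge with per-trial Gram accumulation.

    Per-fold sufficient statistics (X'X, X'Y, column sums/sums of
    squares) are obtained by subtracting the held-out trial's
    contribution from the totals, which makes the exact within-fold
    z-scoring affordable for many folds.
    """

    def __init__(self, X_trials: list[np.ndarray], Y_trials: list[np.ndarray],
                 lam: float):
        self.X_trials = X_trials
        self.Y_trials = []
        for i, y in enumerate(Y_trials):
            y = np.asarray(y, dtype=float)
            if y.ndim == 1:
                y = y[:, None]
            if y.shape[0] != X_trials[i].shape[0]:
                raise ValueError("X and Y sample counts differ within a trial")
            self.Y_trials.append(y)
        self.lam = lam
        self.xtx = [x.T @ x for x in X_trials]
        self.xty = [x.T @ y for x, y in zip(X_trials, self.Y_trials)]
        self.xsum = [x.sum(axis=0) for x in X_trials]
        self.x2sum = [(x * x).sum(axis=0) for x in X_trials]
        self.ysum = [y.sum(axis=0) for y in self.Y_trials]
        self.ns = [x.shape[0] for x in X_trials]
        self.tot_xtx = sum(self.xtx)
        self.tot_xty = sum(self.xty)
        self.tot_xsum = sum(self.xsum)
        self.tot_x2sum = sum(self.x2sum)
        self.tot_ysum = sum(self.ysum)
        self.tot_n = sum(self.ns)

    def fold(self, held_out: int) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                           np.ndarray, float]:
        """Scaled-space ridge weights and scaling for one training fold."""
        n = self.tot_n - self.ns[held_out]
        xsum = self.tot_xsum - self.xsum[held_out]
        x2sum = self.tot_x2sum - self.x2sum[held_out]
        ysum = self.tot_ysum - self.ysum[held_out]
        xtx = self.tot_xtx - self.xtx[held_out]
        xty = self.tot_xty - self.xty[held_out]
        mu = xsum / n
        var = np.maximum(x2sum / n - mu * mu, 0.0)
        sd = np.where(var < _EPS, 1.0, np.sqrt(var))
        ymean = ysum / n
        # centred/scaled normal equations
        cxtx = (xtx - n * np.outer(mu, mu)) / np.outer(sd, sd)
        cxty = (xty - np.outer(mu, ymean) * n) / sd[:, None]
        A = cxtx + self.lam * np.eye(cxtx.shape[0])
        try:
            w = linalg.solve(A, cxty, assume_a="pos")
        except linalg.LinAlgError:
            w = linalg.lstsq(A, cxty)[0]
        return w, mu, sd, ymean, n

    def predict(self, held_out: int) -> np.ndarray:
        w, mu, sd, ymean, _ = self.fold(held_out)
        Xs = (self.X_trials[held_out] - mu) / sd
        return Xs @ w + ymean

    def fold_weights_original_units(self, held_out: int) -> np.ndarray:
        w, _, sd, _, _ = self.fold(held_out)
        return w / sd[:, None]


def estimate_trf(
    envelopes: list[np.ndarray],
    eegs: list[np.ndarray],
    rate: float,
    lam: float = DEFAULT_FORWARD_LAMBDA,
    t_min_ms: float = FORWARD_LAGS_MS[0],
    t_max_ms: float = FORWARD_LAGS_MS[1],
) -> tuple[TRF, np.ndarray]:
    """Estimate a forward TRF for one condition cell.

    Fits leave-one-trial-out: each fold trains on all-but-one line and
    predicts the held-out line's EEG.  The returned TRF is the mean of
    the per-fold weight matrices; the second return value holds the
    held-out per-channel prediction correlations, shape
    ``[n_trials x n_channels]``.  Each envelope may be a single series
    or an ``[n_inputs x n_samples]`` stack (e.g. both streams jointly);
    the kernels are then concatenated input-major in ``weights``.
    """
    if len(envelopes) < 2:
        raise ValueError("leave-one-out needs >=2 trials")
    if len(envelopes) != len(eegs):
        raise ValueError("envelope and EEG trial counts differ")
    n_channels = np.atleast_2d(eegs[0]).shape[0]
    for e in eegs:
        if np.atleast_2d(e).shape[0] != n_channels:
            raise ValueError("channel count mismatch across trials")
    n_inputs = np.atleast_2d(envelopes[0]).shape[0]
    spec = LagSpec(t_min_ms, t_max_ms, rate)
    X_trials = [build_lag_matrix(env, spec) for env in envelopes]
    Y_trials = [np.atleast_2d(e).T for e in eegs]
    loo = _LooRidge(X_trials, Y_trials, lam)
    n_trials = len(envelopes)
    weights = np.zeros((n_channels, n_inputs * spec.n_lags))
    fold_r = np.zeros((n_trials, n_channels))
    for k in range(n_trials):
        weights += loo.fold_weights_original_units(k).T / n_trials
        pred = loo.predict(k)
        fold_r[k] = _pearson_rows(pred.T, Y_trials[k].T)
    trf = TRF(weights=weights, lags_ms=spec.lag_times_ms, rate=rate, lam=lam,
              n_inputs=n_inputs)
    return trf, fold_r


def reconstruct_envelope(
    eegs: list[np.ndarray],
    envelopes: list[np.ndarray],
    rate: float,
    lam: float = DEFAULT_BACKWARD_LAMBDA,
    t_min_ms: float = BACKWARD_LAGS_MS[0],
    t_max_ms: float = BACKWARD_LAGS_MS[1],
) -> tuple[list[np.ndarray], np.ndarray]:
    """Backward model: reconstruct the envelope from all channels jointly.

    Trained leave-one-trial-out; returns each trial's held-out
    reconstruction and the held-out reconstruction correlations.
    """
    if len(eegs) < 2:
        raise ValueError("leave-one-out needs >=2 trials")
    n_channels = np.atleast_2d(eegs[0]).shape[0]
    for e in eegs:
        if np.atleast_2d(e).shape[0] != n_channels:
            raise ValueError("channel count mismatch across trials")
    spec = LagSpec(t_min_ms, t_max_ms, rate)
    X_trials = [build_lag_matrix(np.atleast_2d(e), spec) for e in eegs]
    Y_trials = [np.asarray(env, dtype=float)[:, None] for env in envelopes]
    loo = _LooRidge(X_trials, Y_trials, lam)
    recons = []
    r = np.zeros(len(eegs))
    for k in range(len(eegs)):
        pred = loo.predict(k)[:, 0]
        recons.append(pred)
        r[k] = _pearson_rows(pred[None, :], Y_trials[k].T)[0]
    return recons, r
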