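"""Representational dissimilarity analysis and TRF-fMRI fusion.

TRF RDMs: at each post-stimulus time point, the across-channel TRF
value vectors of the 16 conditions are pairwise correlated (Spearman by
default) and dissimilarity is 1 - r, giving a 16x16 RDM per time point
(100 points spanning 0-800 ms at the 128 Hz TRF step).  fMRI RDMs hold
pairwise leave-one-run-out decoding accuracies per ROI.  Model RDMs are
binary contrast matrices for the factorial design's main effects and
interactions.

Fusion correlates the subject-averaged TRF RDM time series with each
fMRI subject's ROI RDMs using partial Spearman correlation, controlling
for the attentional-task model RDM and the opposite stream's TRF RDM at
the same time point, then tests the mean correlation against zero
(right-tailed t across fMRI subjects) with one joint BH/FDR family over
time points x ROIs x streams.

All RDMs are indexed in the canonical condition order; rank-scaling is
for display only and never enters statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from . import group_stats
from .data_model import (
    ALL_CONDITIONS,
    FACTORS,
    N_CONDITIONS,
    factor_signs,
)

#: number of post-stimulus TRF time points entering RDM analyses
N_TIME_POINTS = 100


@dataclass
class RdmSeries:
    """One RDM per TRF time point, canonical condition order."""

    values: np.ndarray  # [n_times x 16 x 16]
    times_ms: np.ndarray
    subject: str = "group-mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (N_CONDITIONS,
                                                              N_CONDITIONS):
            raise ValueError("RDM series must be [n_times x 16 x 16]")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("time axis must be strictly increasing")


@dataclass
class FusionResult:
    """Tidy time x ROI x stream partial-correlation map with statistics."""

    table: pd.DataFrame
    alpha: float = 0.05
    fdr_family: str = "joint"

    def peak_latency_ms(self, roi: str, stream: str) -> float:
        sub = self.table[(self.table["roi"] == roi)
                         & (self.table["stream"] == stream)]
        return float(sub.loc[sub["mean_r"].idxmax(), "time_ms"])


def lower_triangle(rdm: np.ndarray) -> np.ndarray:
    """Vectorize the strictly-lower triangle (the RSA comparison space)."""
    rdm = np.asarray(rdm)
    idx = np.tril_indices(rdm.shape[0], k=-1)
    return rdm[idx]


def check_rdm(rdm: np.ndarray, lo: float = 0.0, hi: float = 2.0) -> None:
    """Validate symmetry, zero diagonal, and value range."""
    rdm = np.asarray(rdm)
    if rdm.shape[0] != rdm.shape[1]:
        raise ValueError("RDM must be square")
    if not np.allclose(rdm, rdm.T, atol=1e-10):
        raise ValueError("RDM must be symmetric")
    if not np.allclose(np.diag(rdm), 0, atol=1e-10):
        raise ValueError("RDM diagonal must be zero")
    if rdm.min() < lo - 1e-9 or rdm.max() > hi + 1e-9:
        raise ValueError(f"RDM values outside [{lo}, {hi}]")


def rank_scale(rdm: np.ndarray) -> np.ndarray:
    """Rank-scale an RDM to [0, 1] for display (never for statistics)."""
    tri = lower_triangle(rdm)
    ranks = (stats.rankdata(tri) - 1) / max(tri.size - 1, 1)
    out = np.zeros_like(np.asarray(rdm, dtype=float))
    idx = np.tril_indices(rdm.shape[0], k=-1)
    out[idx] = ranks
    return out + out.T


# ---------------------------------------------------------------------------
# RDM construction
# ---------------------------------------------------------------------------


def trf_rdm_series(
    weights: np.ndarray,
    lags_ms: np.ndarray,
    n_points: int = N_TIME_POINTS,
    method: str = "spearman",
    subject: str = "group-mean",
) -> RdmSeries:
    """Condition x condition dissimilarity per TRF time point.

    ``weights`` is ``[16 conditions x n_channels x n_lags]`` in
    canonical condition order.  Non-negative lags are kept and the
    first ``n_points`` used (103 non-negative samples exist at 128 Hz
    for a -200..800 ms window; the first 100 honour the 0-800 ms
    convention).  At each time point, entry (i, j) is
    ``1 - corr`` between the two conditions' across-channel TRF value
    vectors (Spearman by default, Pearson optional).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 3 or weights.shape[0] != N_CONDITIONS:
        raise ValueError("weights must be [16 x n_channels x n_lags]")
    if weights.shape[1] < 2:
        raise ValueError("need >=2 channels to correlate across channels")
    lags_ms = np.asarray(lags_ms, dtype=float)
    keep = np.flatnonzero(lags_ms >= 0)[:n_points]
    if keep.size == 0:
        raise ValueError("no non-negative lags available")
    times = lags_ms[keep]
    rdms = np.zeros((keep.size, N_CONDITIONS, N_CONDITIONS))
    for out_t, t in enumerate(keep):
        vectors = weights[:, :, t]  # [16 x n_channels]
        if method == "spearman":
            rho = stats.spearmanr(vectors.T).statistic
        elif method == "pearson":
            rho = np.corrcoef(vectors)
        else:
            raise ValueError("method must be 'spearman' or 'pearson'")
        rho = np.asarray(rho)
        rdm = 1.0 - rho
        np.fill_diagonal(rdm, 0.0)
        rdms[out_t] = np.clip((rdm + rdm.T) / 2.0, 0.0, 2.0)
    return RdmSeries(values=rdms, times_ms=times, subject=subject)


def model_rdm(term: str) -> np.ndarray:
    """Binary model RDM for a main effect or interaction of the design.

    ``term`` is a factor name (task, coherence, auditory, visual) or a
    colon-joined interaction (e.g. ``task:auditory``).  With ±1 factor
    codings, the term code of a condition is the product of its factor
    codes; entry (i, j) is 1 when the two conditions' term codes
    differ.
    """
    names = [t.strip() for t in term.split(":") if t.strip()]
    if not names:
        raise ValueError("empty model term")
    for name in names:
        if name not in FACTORS:
            raise ValueError(f"unknown factor {name!r}; choose from {FACTORS}")
    codes = np.array([
        np.prod([factor_signs(c)[name] for name in names])
        for c in ALL_CONDITIONS
    ])
    return (codes[:, None] != codes[None, :]).astype(float)


def pairwise_decoding_rdm(
    patterns: np.ndarray,
    C: float = 1.0,
) -> np.ndarray:
    """Pairwise leave-one-run-out decoding accuracy RDM for one ROI.

    ``patterns`` is ``[16 conditions x n_runs x n_exemplars x
    n_features]`` (exemplars are lines, features are voxels).  For each
    condition pair a linear SVM (C=1) is trained on all runs but one
    and tested on the held-out run; entry (i, j) is the mean held-out
    accuracy over folds.  Tie predictions at the margin resolve toward
    the lower canonical index (the SVM decision function's sign
    convention with class labels {i, j}).
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 4 or patterns.shape[0] != N_CONDITIONS:
        raise ValueError("patterns must be [16 x n_runs x n_exemplars x n_features]")
    n_runs = patterns.shape[1]
    if n_runs < 2:
        raise ValueError("need >=2 runs for leave-one-run-out")
    rdm = np.zeros((N_CONDITIONS, N_CONDITIONS))
    for i, j in combinations(range(N_CONDITIONS), 2):
        accs = []
        for test_run in range(n_runs):
            train_runs = [r for r in range(n_runs) if r != test_run]
            X_train = np.concatenate([
                patterns[c, r] for c in (i, j) for r in train_runs
            ])
            y_train = np.concatenate([
                np.full(patterns[c, r].shape[0], c)
                for c in (i, j) for r in train_runs
            ])
            X_test = np.concatenate([patterns[c, test_run] for c in (i, j)])
            y_test = np.concatenate([
                np.full(patterns[c, test_run].shape[0], c) for c in (i, j)
            ])
            clf = SVC(kernel="linear", C=C)
            clf.fit(X_train, y_train)
            accs.append(float(np.mean(clf.predict(X_test) == y_test)))
        rdm[i, j] = rdm[j, i] = float(np.mean(accs))
    return rdm


# ---------------------------------------------------------------------------
# Model correlations and fusion
# ---------------------------------------------------------------------------


def rdm_model_correlation(
    series_per_subject: list[RdmSeries],
    model: np.ndarray,
    alpha: float = 0.05,
    apply_fdr: bool = True,
) -> pd.DataFrame:
    """Time course of RDM-model Spearman correlation with group stats.

    For every subject and time point the lower triangles of the data
    RDM and the model RDM are Spearman-correlated; the mean correlation
    is tested against zero with a right-tailed one-sample t-test per
    time point, BH-corrected across time points.
    """
    if len(series_per_subject) < 2:
        raise ValueError("need >=2 subjects")
    times = series_per_subject[0].times_ms
    model_tri = lower_triangle(model)
    r = np.full((len(series_per_subject), times.size), np.nan)
    for s, series in enumerate(series_per_subject):
        if not np.array_equal(series.times_ms, times):
            raise ValueError("subjects must share the RDM time axis")
        for t in range(times.size):
            r[s, t] = group_stats.partial_spearman(
                lower_triangle(series.values[t]), model_tri)
    rows = []
    for t in range(times.size):
        vals = r[:, t]
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            rows.append({"time_ms": times[t], "mean_r": np.nan, "t": np.nan,
                         "p": np.nan, "n": int(ok.sum())})
            continue
        test = group_stats.right_tailed_onesample_t(vals[ok])
        rows.append({"time_ms": times[t], "mean_r": float(np.mean(vals[ok])),
                     "t": test.statistic, "p": test.p, "n": int(ok.sum())})
    table = pd.DataFrame(rows)
    if apply_fdr:
        ok = table["p"].notna()
        q = np.full(len(table), np.nan)
        rej = np.zeros(len(table), dtype=bool)
        if ok.any():
            q[ok], rej[ok] = group_stats.fdr_bh(table.loc[ok, "p"].to_numpy(),
                                                alpha)
        table["q"] = q
        table["significant"] = rej
    return table


def average_series(series_list: list[RdmSeries]) -> RdmSeries:
    """Subject-average of RDM series sharing one time axis."""
    times = series_list[0].times_ms
    for s in series_list[1:]:
        if not np.array_equal(s.times_ms, times):
            raise ValueError("mismatched time axes")
    mean = np.mean([s.values for s in series_list], axis=0)
    return RdmSeries(values=mean, times_ms=times, subject="group-mean")


def fuse(
    trf_series: dict[str, RdmSeries],
    fmri_rdms: dict[str, np.ndarray],
    task_model: np.ndarray | None = None,
    control_opposite: bool = True,
    alpha: float = 0.05,
) -> FusionResult:
    """Partial-correlation TRF-fMRI fusion.

    Parameters
    ----------
    trf_series
        ``{"dialogue": RdmSeries, "background": RdmSeries}`` —
        group-mean (EEG-subject-averaged) TRF RDM series per stream.
    fmri_rdms
        ROI label -> ``[n_fmri_subjects x 16 x 16]`` RDM stack.
    task_model
        Attentional-task model RDM controlled for in every correlation
        (defaults to :func:`model_rdm` of the task factor).  Pass
        ``task_model=None`` with ``control_opposite=False`` for plain
        Spearman fusion.

    For each stream, time point, ROI, and fMRI subject the lower
    triangles are partially Spearman-correlated, controlling the task
    model and the opposite stream's group TRF RDM at the same time
    point; mean correlations are tested right-tailed across fMRI
    subjects and BH-corrected over the joint family time x ROI x
    stream.
    """
    streams = sorted(trf_series)
    times = trf_series[streams[0]].times_ms
    for s in streams[1:]:
        if not np.array_equal(trf_series[s].times_ms, times):
            raise ValueError("mismatched time axes between streams")
    if task_model is None and control_opposite is not False:
        task_model = model_rdm("task")
    task_tri = lower_triangle(task_model) if task_model is not None else None

    tri_by_stream = {
        s: np.stack([lower_triangle(trf_series[s].values[t])
                     for t in range(times.size)])
        for s in streams
    }
    rows = []
    for stream in streams:
        opposite = [s for s in streams if s != stream]
        opp_tri = tri_by_stream[opposite[0]] if (opposite and control_opposite) \
            else None
        for roi, stack in fmri_rdms.items():
            stack = np.asarray(stack, dtype=float)
            if stack.ndim != 3 or stack.shape[1:] != (N_CONDITIONS, N_CONDITIONS):
                raise ValueError(f"ROI {roi}: RDM stack must be [n_subj x 16 x 16]")
            subj_tri = np.stack([lower_triangle(m) for m in stack])
            for t in range(times.size):
                covs = []
                if task_tri is not None:
                    covs.append(task_tri)
                if opp_tri is not None:
                    covs.append(opp_tri[t])
                r = np.array([
                    group_stats.partial_spearman(tri_by_stream[stream][t],
                                                 subj_tri[k], covs)
                    for k in range(subj_tri.shape[0])
                ])
                ok = np.isfinite(r)
                if ok.sum() >= 2:
                    test = group_stats.right_tailed_onesample_t(r[ok])
                    rows.append({"stream": stream, "roi": roi,
                                 "time_ms": float(times[t]),
                                 "mean_r": float(np.mean(r[ok])),
                                 "t": test.statistic, "p": test.p,
                                 "n": int(ok.sum())})
                else:
                    rows.append({"stream": stream, "roi": roi,
                                 "time_ms": float(times[t]), "mean_r": np.nan,
                                 "t": np.nan, "p": np.nan, "n": int(ok.sum())})
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    q = np.full(len(table), np.nan)
    rej = np.zeros(len(table), dtype=bool)
    if ok.any():
        q[ok], rej[ok] = group_stats.fdr_bh(table.loc[ok, "p"].to_numpy(), alpha)
    table["q"] = q
    table["significant"] = rej
    return FusionResult(table=table, alpha=alpha, fdr_family="joint")
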