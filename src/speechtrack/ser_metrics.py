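"""Speech-envelope-reconstruction (SER) accuracy metrics.

Tracking of a stream is quantified with the correlation-difference
score Δr: the Pearson correlation of a stream's reconstruction with
its own envelope minus its correlation with the opposite stream's
envelope.  Δr is computed per line and, for temporal profiling, per
quarter segment of the line.  The module also provides attention
classification from the four reconstruction correlations, the
two-level performance-Δr association, temporal trend contrasts across
lines and segments, and the partial-eta-squared effect-size formula
F*df1 / (F*df1 + df2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from . import group_stats
from .envelopes import split_segments

_EPS = 1e-12

#: Δr pairing conventions.  "reconstruction" holds one reconstruction
#: fixed and correlates it with both envelopes (the default);
#: "envelope" holds one envelope fixed and correlates it with both
#: reconstructions.  The two agree in their diagnostic intent but not
#: numerically; both are provided.
PAIRINGS = ("reconstruction", "envelope")


@dataclass
class SerScore:
    """Direct, cross, and Δr correlations for one trial (or segment)."""

    stream: str
    r_direct: float
    r_cross: float
    segment: int = 0  # 0 = whole line, 1..4 = quarter
    valid: bool = True

    @property
    def delta_r(self) -> float:
        return self.r_direct - self.r_cross


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() < _EPS or b.std() < _EPS:
        return np.nan, False
    return float(np.corrcoef(a, b)[0, 1]), True


def ser_scores(
    recon_dialogue: np.ndarray,
    recon_background: np.ndarray,
    env_dialogue: np.ndarray,
    env_background: np.ndarray,
    per_segment: bool = False,
    pairing: str = "reconstruction",
) -> dict[str, list[SerScore]]:
    """Δr scores for both streams of one trial.

    With ``pairing="reconstruction"`` (default), stream ``s`` scores
    ``r_direct = r(recon_s, env_s)`` and
    ``r_cross = r(recon_s, env_other)``.  With ``pairing="envelope"``
    the cross term is ``r(recon_other, env_s)`` instead.  Zero-variance
    inputs yield NaN scores flagged invalid, which downstream
    aggregation excludes.

    Returns ``{"dialogue": [...], "background": [...]}`` with one score
    per trial (or four per-segment scores when ``per_segment``).
    """
    if pairing not in PAIRINGS:
        raise ValueError(f"pairing must be one of {PAIRINGS}")
    recon = {"dialogue": np.asarray(recon_dialogue, dtype=float),
             "background": np.asarray(recon_background, dtype=float)}
    env = {"dialogue": np.asarray(env_dialogue, dtype=float),
           "background": np.asarray(env_background, dtype=float)}
    lengths = {x.size for x in (*recon.values(), *env.values())}
    if len(lengths) != 1:
        raise ValueError("reconstructions and envelopes must share length")

    def score(stream: str, seg_slices) -> list[SerScore]:
        other = "background" if stream == "dialogue" else "dialogue"
        out = []
        for seg_idx, sl in seg_slices:
            rd, ok1 = _pearson(recon[stream][sl], env[stream][sl])
            if pairing == "reconstruction":
                rc, ok2 = _pearson(recon[stream][sl], env[other][sl])
            else:
                rc, ok2 = _pearson(recon[other][sl], env[stream][sl])
            out.append(SerScore(stream=stream, r_direct=rd, r_cross=rc,
                                segment=seg_idx, valid=ok1 and ok2))
        return out

    n = next(iter(lengths))
    if per_segment:
        seg_len = n // 4
        slices = [(k + 1, slice(k * seg_len, (k + 1) * seg_len)) for k in range(4)]
    else:
        slices = [(0, slice(None))]
    return {s: score(s, slices) for s in ("dialogue", "background")}


# ---------------------------------------------------------------------------
# Attention classification from the four reconstruction correlations
# ---------------------------------------------------------------------------


def classify_attention(
    features: np.ndarray,
    labels: np.ndarray,
    runs: np.ndarray,
    C: float = 1.0,
    n_iterations: int = 1,
    seed: int | None = None,
) -> float:
    """Leave-one-run-out linear SVM attention classification accuracy.

    ``features`` is the per-trial 4-vector (r_dd, r_db, r_bb, r_bd) of
    direct and cross reconstruction correlations; ``labels`` the binary
    task; ``runs`` the run index of each trial.  A linear max-margin
    classifier with unit regularization constant is trained on all
    runs but one and tested on the held-out run; fold accuracies are
    averaged.  When ``n_iterations > 1`` the training set is randomly
    subsampled to balanced classes in each iteration and accuracies
    averaged over iterations.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    runs = np.asarray(runs)
    unique_runs = np.unique(runs)
    if unique_runs.size < 2:
        raise ValueError("leave-one-run-out needs >=2 runs")
    rng = np.random.default_rng(seed)
    fold_acc = []
    for run in unique_runs:
        test = runs == run
        train = ~test
        y_train = labels[train]
        classes = np.unique(y_train)
        if classes.size < 2:
            raise ValueError(f"training fold for run {run} has a single class")
        accs = []
        for _ in range(n_iterations):
            idx = np.flatnonzero(train)
            if n_iterations > 1:
                n_min = min((y_train == c).sum() for c in classes)
                keep = []
                for c in classes:
                    c_idx = idx[labels[idx] == c]
                    keep.append(rng.choice(c_idx, size=n_min, replace=False))
                idx = np.concatenate(keep)
            clf = SVC(kernel="linear", C=C)
            clf.fit(features[idx], labels[idx])
            accs.append(float(np.mean(clf.predict(features[test]) == labels[test])))
        fold_acc.append(float(np.mean(accs)))
    return float(np.mean(fold_acc))


# ---------------------------------------------------------------------------
# Two-level performance association
# ---------------------------------------------------------------------------


def performance_association_first_level(
    trials: pd.DataFrame,
) -> pd.DataFrame:
    """Per-subject, per-line OLS of Δr on response correctness.

    ``trials`` needs columns subject, line, delta_r, correct (0/1) and
    the three binary confounds coherence, auditory, visual (any 0/1 or
    two-level coding).  For each subject x line cell with both correct
    and incorrect trials, Δr is regressed on correctness plus the
    confounds; the correctness beta is returned.  Cells without
    response variability are skipped and reported with ``skipped``.
    """
    rows = []
    for (subject, line), grp in trials.groupby(["subject", "line"]):
        correct = grp["correct"].to_numpy(dtype=float)
        skipped = correct.min() == correct.max()
        beta = np.nan
        if not skipped:
            X = np.column_stack([
                np.ones(len(grp)),
                correct,
                pd.factorize(grp["coherence"])[0],
                pd.factorize(grp["auditory"])[0],
                pd.factorize(grp["visual"])[0],
            ])
            y = grp["delta_r"].to_numpy(dtype=float)
            beta = float(np.linalg.lstsq(X, y, rcond=None)[0][1])
        rows.append({"subject": subject, "line": line, "beta": beta,
                     "skipped": bool(skipped)})
    return pd.DataFrame(rows)


def performance_association_second_level(
    betas: pd.DataFrame,
    trim: float = 0.05,
    n_perm: int = group_stats.DEFAULT_N_PERM,
    seed: int | None = None,
) -> dict:
    """Line-wise trimmed means of the first-level betas plus a trend test.

    The per-line group value is the symmetrically ``trim``-per-tail
    trimmed mean of subject betas; the line effect is tested with the
    linear orthogonal contrast per subject and a sign-flip permutation
    t-test.
    """
    usable = betas[~betas["skipped"]]
    lines = np.sort(usable["line"].unique())
    trimmed = {
        int(line): float(stats.trim_mean(
            usable.loc[usable["line"] == line, "beta"], trim))
        for line in lines
    }
    wide = usable.pivot_table(index="subject", columns="line", values="beta")
    wide = wide.dropna()
    result = {"trimmed_means": trimmed, "n_subjects": int(len(wide)),
              "n_skipped_cells": int(betas["skipped"].sum())}
    if len(wide) >= 2 and wide.shape[1] >= 3:
        contrast = group_stats.orthogonal_poly_contrasts(wide.shape[1])[0]
        scores = wide.to_numpy() @ contrast
        test = group_stats.permutation_paired_ttest(
            scores, np.zeros_like(scores), n_perm=n_perm, seed=seed)
        result["linear_trend"] = test
    return result


# ---------------------------------------------------------------------------
# Temporal profiles of Δr
# ---------------------------------------------------------------------------


def profile_contrasts(
    table: pd.DataFrame,
    axis: str,
    n_perm: int = group_stats.DEFAULT_N_PERM,
    seed: int | None = None,
) -> dict:
    """Linear and quadratic trend tests of Δr across lines or segments.

    ``table`` needs columns subject, ``axis`` (line or segment) and
    delta_r; values are averaged per subject x level, projected on the
    orthogonal polynomial contrasts, and each contrast is tested
    against zero with a sign-flip permutation t-test.  Returns the
    per-level group means, per-subject contrast scores, and tests.
    """
    wide = table.pivot_table(index="subject", columns=axis, values="delta_r")
    wide = wide.dropna()
    k = wide.shape[1]
    if k < 3:
        raise ValueError(f"need >=3 {axis} levels for trend contrasts")
    contrasts = group_stats.orthogonal_poly_contrasts(k)
    values = wide.to_numpy()
    out = {
        "levels": [int(c) for c in wide.columns],
        "group_means": values.mean(axis=0).tolist(),
        "n_subjects": int(values.shape[0]),
    }
    for name, c in zip(("linear", "quadratic"), contrasts):
        scores = values @ c
        out[f"{name}_scores"] = scores
        out[f"{name}_test"] = group_stats.permutation_paired_ttest(
            scores, np.zeros_like(scores), n_perm=n_perm, seed=seed)
    return out


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Effect-size approximation partial η² = F·df1 / (F·df1 + df2)."""
    if F < 0:
        raise ValueError("F must be non-negative")
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    return F * df1 / (F * df1 + df2)


def segment_scores_from_arrays(recon_d, recon_b, env_d, env_b, pairing="reconstruction"):
    """Convenience wrapper: per-segment Δr using the quarter-split rule."""
    # segments are defined by the same floor(n/4) rule as split_segments
    split_segments(env_d)  # validates length
    return ser_scores(recon_d, recon_b, env_d, env_b,
                      per_segment=True, pairing=pairing)
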