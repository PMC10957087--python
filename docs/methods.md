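# Methods

This note documents the models, estimators, and simulation assumptions
behind `speechtrack`, and the design choices made where several
reasonable options existed.

## Design and data model

The experiment is a 2×2×2×2 within-subject factorial: Attentional Task
(attend the audiovisual dialogue / ignore all speech), Semantic
Coherence (coherent / incoherent), Auditory Quality (good / poor
noise-vocoding) and Visual Quality (good / poor masking). A trial is
one 6.5 s line of a dialogue (7 lines per dialogue, 3 runs), paired
with the simultaneous 6.5 s window of the continuously running
background audiobook. The background stream has no line structure of
its own; the simultaneous-window convention is the only sensible
alignment and is used throughout.

The 16 design cells are frozen in one canonical order — the eight
attend cells first, then the eight ignore cells, each block ordered
co-gv-ga, inco-gv-ga, co-pv-ga, inco-pv-ga, co-gv-pa, inco-gv-pa,
co-pv-pa, inco-pv-pa — and every RDM, classifier and model matrix
indexes conditions only through `canonical_condition_index`. A single
ordering bug would silently corrupt every RSA result, so the mapping
is bijective by construction and property-tested. Internal indexing is
0-based; user-facing line/run numbers are 1-based.

On-disk exchange uses one HDF5 container
(`/subjects/<id>/trials/<uid>/{eeg, env_dialogue, env_background}`
with rate/run/line/condition attributes); round trips are bit-lossless
and a trial missing either stream envelope is rejected.

## Envelopes

The stimulus feature is the slow amplitude envelope: magnitude of the
analytic signal (Hilbert transform), low-pass filtered at 10 Hz with a
zero-phase Hamming-window FIR, then polyphase-resampled to 128 Hz (TRF
analyses) or 64 Hz (reconstruction). The nominal band is 0–10 Hz; a
0 Hz high-pass edge is a no-op, so only the low-pass is implemented.
Filtering precedes resampling to avoid aliasing. The filter is up to
0.5 s of taps, shortened for brief inputs so zero-phase edge padding
stays valid; family and order are exposed in the function signature
since no specific design is canonical. Lines are split into 4 equal
segments of `floor(n/4)` samples; up to three trailing samples are
dropped (the remainder rule is undocumented in the source analyses;
dropping is the simplest deterministic choice).

## Lagged ridge regression

Both estimators share one lagged design: column (i, τ) of the design
matrix holds input *i* delayed by τ samples, zero-padded at epoch
edges (padding, rather than trimming, keeps every epoch full length
for the epoch-wise correlations downstream). Forward lag τ means the
EEG at time *t* is predicted from the envelope at *t − τ*; the
backward window τ ∈ [−200, 0] ms therefore predicts the envelope at
*t* from EEG over *t*…*t* + 200 ms. Both conventions are pinned by
impulse-response unit tests.

Within each training fold, predictor columns are z-scored and targets
centred; the penalty is λ·I in that standardized space, solved in
closed form from the normal equations (Cholesky). The standard λ
values (10⁵ forward, 10⁴ backward) are the defaults under this
convention and are configurable; since the scaling convention of any
particular toolbox is not part of the contract, absolute TRF
amplitudes are convention-dependent, and every downstream statistic
(correlations, RDMs) is invariant to them.

Models are fitted leave-one-trial-out per subject × stream ×
condition cell, pooling that cell's lines; the reported TRF is the
mean of per-fold weights and all accuracies are computed on held-out
predictions. Whether per-line quantities should come from per-line
models or from per-cell models evaluated per line is ambiguous in the
source description; the per-cell variant is implemented (more data per
fit) and per-line evaluation happens on the held-out scores. The
leave-one-out loop uses per-trial Gram-matrix accumulation (fold
statistics by subtraction), which makes exact within-fold z-scoring
affordable at many folds.

## Δr and its profiles

For stream *s*, Δr = r(recon_s, env_s) − r(recon_s, env_other): one
reconstruction correlated against both envelopes. The opposite pairing
(one envelope against both reconstructions) is also implemented behind
a `pairing` flag because the two appear interchangeably in informal
descriptions of the method; the reconstruction-centred pairing is the
default. Zero-variance inputs yield flagged-invalid scores that all
aggregations exclude.

Temporal profiles: per-subject mean Δr per line (1–7) or segment
(1–4), projected on orthogonal polynomial contrasts (linear,
quadratic), each tested with a sign-flip permutation t-test. This
permutation machinery replaces mixed-model inference (out of scope
here); it is assumption-light and exactly valid under subject
exchangeability.

Attention decoding uses the four per-trial reconstruction
correlations (direct and cross, both streams) as features in a linear
SVM (C = 1) with leave-one-run-out cross-validation; optional
iterations subsample the training set to balanced classes.

The two-level performance association regresses per-trial Δr on
response correctness (plus the three binary quality/coherence
confounds) per subject and line, then takes 5% symmetrically trimmed
means of the betas per line across subjects with a permutation trend
test. Trimming sidedness was unspecified; symmetric trimming is the
`scipy.stats.trim_mean` convention.

Partial η² = F·df₁ / (F·df₁ + df₂) is provided as the effect-size
approximation for fixed effects.

## Group statistics

Sign-flip permutation paired t-tests (default 20,000 permutations)
enumerate all 2ⁿ sign patterns when 2ⁿ ≤ n_perm, making p-values
exact; the identity flip is always in the reference distribution.
Benjamini–Hochberg FDR is delegated to
`statsmodels.stats.multitest.multipletests`. Partial Spearman
correlation ranks all vectors (average ranks at ties), residualizes
the ranks of x and y on the covariate ranks with an intercept, and
Pearson-correlates the residuals; a vector fully explained by the
covariates gives partial r = 0, a constant input gives NaN (flagged).

## RSA and fusion

TRF RDMs are `1 − Spearman` across channels per time point (Pearson
optional); at 128 Hz a −200…800 ms lag window has 103 non-negative
samples and the first 100 are used, honouring the 0–800 ms, 100-point
convention. Model RDMs code each factor ±1; a term's code is the
product over its factors, and the RDM entry is 1 where two conditions'
codes differ. fMRI RDMs are pairwise leave-one-run-out linear-SVM
(C = 1) decoding accuracies at ROI level; voxelwise searchlight and
atlas geometry are out of scope (ROIs are opaque labels).

Fusion averages TRF RDMs across EEG subjects, then for each time
point, ROI, and fMRI subject computes the partial Spearman correlation
with that subject's ROI RDM, controlling (i) the attentional-task
model RDM and (ii) the opposite stream's group TRF RDM at the same
time point. Group inference is a right-tailed one-sample t across
fMRI subjects with one flat BH family over time × ROI × stream;
"models" in the FDR family is read as the two streams (configurable).
The EEG and fMRI cohorts are distinct, mirroring the two-sample design
the method was built for. RDMs are rank-scaled only for display.

## Synthetic-data generator

The generator is first-class, tested code; it emulates the statistical
structure the analyses assume, at a desk scale that runs in minutes.

Per trial it draws two independent envelopes (rectified Gaussian noise
low-passed at 9 Hz, unit variance; >99% of power below 10 Hz). EEG is
envelope ⊛ kernel per stream plus 1/f-shaped noise band-limited to
the 0.5–10 Hz analysis band. Kernels per condition and channel are

    K(c, ch, t) = g(c) · [ base(ch)·k0(t)
                           + s_task(c)·p_task(ch)·k_task(t)·0.3
                           + 0.55·idio(c, ch, t) ]

where k0 is a difference of gamma bumps (positive peak ≈ 90 ms,
negative ≈ 280 ms), k_task peaks at 120 and 300 ms (loosely matching
early and late attention effects), `base` is a signed (dipolar)
topography, `p_task` flips sign between tasks, and `idio` is a smooth
(σ = 35 ms) condition-specific Gaussian random field windowed over
0–700 ms. The idiosyncratic fields make the representational geometry
time-varying, which is what fusion latency recovery rests on; their
smoothness keeps the kernels inside the envelope's identifiable band
(content above the envelope bandwidth cannot be estimated from a
band-limited regressor). Kernels and patterns are drawn independently
per subject — subjects are random effects; sharing one kernel draw
across subjects would turn draw-specific condition asymmetries into a
systematic group effect and invalidate type-I-error calibration.

Condition gains: the attend-task dialogue gain is
`attended_gain_ratio` (default 2) times the ignore-task gain, with
mild degradations for poor auditory (×0.9), poor visual (×0.95) and
incoherent (×0.97) input; the background stream has gain 0.8, slightly
boosted (×1.15) during the attend task, echoing the finding that
actively suppressed speech is not simply attenuated. The attend-task
dialogue drive additionally declines linearly within the line
(`within_line_decay` = 0.3 across the epoch) and is modulated across
the 7 lines by an inverted-U profile (peak ×1.4 at line 4). The decay
and profile amplitudes are qualitative emulations — no quantitative
effect sizes exist to copy — chosen salient enough that the contrast
analyses they exist to validate are identifiable at desk scale.

Noise is fixed per subject: its power is the subject's unit-gain
(baseline) response power divided by `snr` (default 1). Referencing
noise to the baseline rather than to each trial keeps sensor noise a
property of the recording, so condition gains translate into genuine
SNR differences — a per-trial reference would silently cancel the
attention effect it is supposed to carry.

fMRI ROI RDMs are rank-preserving noisy copies of the group-mean TRF
RDM at an assigned latency per ROI (per-subject Gaussian noise on the
lower triangle at 0.25 of the template spread; chosen so that
averaging over the default 8 fMRI subjects leaves the template ranks
dominant) or, for "null" ROIs, pure symmetric noise. The default map
has six structured ROIs (dialogue at 100/250/400/600 ms, background at
150/300 ms) and two null ROIs.

Default scale: 8 subjects, 16 channels, 128 Hz, 7 lines per condition
cell (one full dialogue per cell, so every line position occurs once
and the temporal-profile analyses are estimable), SNR 1, 8 ROIs. The
temporal-profile validation uses 14 lines per cell (two dialogues) and
8 channels; the type-I calibration uses a reduced 8-subject, 4-channel,
64 Hz, 2-line configuration with every task-dependent mechanism
switched off (gain ratio 1, no decay, flat profile, no background
boost), at which size all 256 sign-flip permutations are enumerated and
the attainable 0.05-level rejection rate (12/256 ≈ 0.047) sits at the
nominal level. These problem sizes were chosen so each validation is
identifiable and runs in minutes on one CPU.

## What the simulations do and do not show

Passing the recovery checks shows the estimators and statistics are
correct under the generative model they assume: linear time-invariant
envelope-to-EEG kernels, stationary band-limited noise, exchangeable
subjects, and ROI RDMs that literally contain a TRF RDM. Real data
violate all of these to some degree — nonlinear and adaptive neural
responses, artifacts, inter-subject latency differences, fMRI RDMs
only indirectly related to electrophysiological geometry — so
synthetic performance (e.g. Δr ≈ 0.5 attended) is systematically
cleaner than empirical values, and no synthetic number should be read
as a prediction for real recordings. What carries over is the
validity of the machinery: sign conventions, cross-validation
hygiene, calibrated nulls, and correct multiple-testing behaviour.

## Numerical choices and degenerate inputs

* Exact within-fold standardization via per-trial Gram accumulation;
  constant columns scale to exactly zero rather than dividing by zero.
* Noiseless identifiability of kernels is demonstrated with a joint
  two-stream fit at light regularization (λ = 10²): fitting streams
  separately leaves a finite-sample cross-stream interference floor
  (two 6.5 s envelopes are only uncorrelated in expectation), and
  heavy regularization biases kernel shape toward the envelope
  autocorrelation.
* Permutation p-values compare |t| with a 1e-12 tolerance so the
  identity permutation always counts; zero-variance difference vectors
  give t = 0 (all-equal) or ±∞.
* Spearman RDMs are symmetrized and clipped to [0, 2] against
  floating-point drift; decoding RDM ties resolve toward the lower
  canonical index via the SVM decision-function sign convention.
* The config hash covers every analysis-relevant field and excludes
  the documented cosmetic ones (output directory, stage list, log
  level); identical (container, config) runs produce byte-identical
  tables.

## Known limitations

* No raw-EEG artifact pipeline (ICA, interpolation) and no raw fMRI
  GLM: the package starts from epoched band-passed EEG and ROI-level
  patterns or RDMs.
* Group inference is permutation/t-based; covariance-structured mixed
  models are deliberately not replicated.
* The generator's fMRI model is at the RDM level only — no
  hemodynamics, no spatial structure.
* Envelope extraction assumes PCM WAV input; compressed audio is out
  of scope.
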