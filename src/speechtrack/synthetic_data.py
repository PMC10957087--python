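"""Synthetic cocktail-party fixtures with known ground truth.

The generator emulates the statistical structure the analyses assume,
at a configurable desk scale:

* two mutually uncorrelated slow (<10 Hz) amplitude envelopes per
  trial (dialogue and background stream);
* EEG per channel as envelope ⊛ kernel per stream plus 1/f-shaped,
  band-limited noise at a configurable SNR.  Kernels are
  difference-of-gamma waveforms (early positive deflection near 90 ms,
  late negative near 280 ms) with condition-dependent gain: the
  attended (attend-task) dialogue stream carries
  ``attended_gain_ratio`` times the ignored-task gain, declines
  linearly within the line (``within_line_decay``) and is modulated
  across the 7 lines by a quadratic profile peaking mid-dialogue;
* condition-specific across-channel patterns: a task pattern with its
  own time course plus smooth idiosyncratic per-condition pattern time
  courses, so the representational geometry of the TRFs varies over
  time (this is what fusion latency recovery rests on);
* fMRI ROI RDMs as rank-preserving noisy copies of the group TRF RDM
  at an assigned latency per ROI ("null" ROIs are pure noise).

Kernels and channel patterns are drawn independently per subject
(subjects are random effects: each has its own topographies and
idiosyncratic kernel fields) on top of per-trial envelope and noise
realizations.  Every dataset is reproducible from (config, seed)
alone, and ground truth is returned alongside for parameter-recovery
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .data_model import (
    Dataset,
    EegEpoch,
    SpeechEnvelope,
    TrialKey,
    ALL_CONDITIONS,
    N_CONDITIONS,
    N_LINES,
    N_RUNS,
    canonical_condition_index,
    epoch_samples,
)
from .rsa_fusion import RdmSeries, lower_triangle

#: default 7-line gain profile of the attended stream: quadratic with
#: the peak at line 4, mirroring tracking that builds up early in the
#: dialogue and abates towards the end (1 + 0.4*(1 - ((line-4)/3)^2))
DEFAULT_LINE_PROFILE = (1.0, 1.222, 1.356, 1.4, 1.356, 1.222, 1.0)

DEFAULT_ROI_MAP: dict[str, tuple[str, float, float] | str] = {
    "roi-dial-100": ("dialogue", 100.0, 0.25),
    "roi-dial-250": ("dialogue", 250.0, 0.25),
    "roi-dial-400": ("dialogue", 400.0, 0.25),
    "roi-dial-600": ("dialogue", 600.0, 0.25),
    "roi-back-150": ("background", 150.0, 0.25),
    "roi-back-300": ("background", 300.0, 0.25),
    "roi-null-1": "null",
    "roi-null-2": "null",
}


@dataclass
class SynthConfig:
    """Study-scale parameters of the generator.

    ``n_lines_per_condition`` is the number of line epochs per subject
    and condition cell; line numbers cycle 1..7, so with the default 7
    every line position occurs once per cell and the temporal-profile
    analyses are estimable.  ``snr`` is the power ratio between the
    unit-gain (baseline) kernel response and the sensor noise; the
    noise level is fixed per subject, so condition gains translate
    into genuine SNR differences between conditions.
    """

    n_subjects: int = 8
    n_channels: int = 16
    rate: float = 128.0
    n_lines_per_condition: int = 7
    attended_gain_ratio: float = 2.0
    within_line_decay: float = 0.3
    line_profile: tuple[float, ...] = DEFAULT_LINE_PROFILE
    snr: float = 1.0
    background_gain: float = 0.8
    background_attend_boost: float = 1.15
    kernel_length_ms: float = 700.0
    task_pattern_scale: float = 0.3
    idiosyncratic_scale: float = 0.55
    roi_map: dict = field(default_factory=lambda: dict(DEFAULT_ROI_MAP))
    n_fmri_subjects: int = 8
    n_runs: int = N_RUNS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.line_profile) != N_LINES:
            raise ValueError(f"line_profile needs exactly {N_LINES} multipliers")
        if any(g <= 0 for g in self.line_profile):
            raise ValueError("line-profile gains must be positive")
        if self.snr <= 0 or self.attended_gain_ratio <= 0:
            raise ValueError("snr and attended_gain_ratio must be positive")


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the injected structure."""

    #: subject -> stream -> [16 x n_channels x n_taps]; kernels are drawn
    #: independently per subject (random-effects structure)
    kernels: dict[str, dict[str, np.ndarray]]
    kernel_times_ms: np.ndarray
    condition_gains: dict[str, np.ndarray]  # stream -> [16]
    trial_gains: pd.DataFrame
    roi_map: dict
    config: SynthConfig


def _gamma_bump(t_ms: np.ndarray, peak_ms: float, width_ms: float) -> np.ndarray:
    """Unit-peak gamma-shaped bump with given mode and spread."""
    shape = max((peak_ms / width_ms) ** 2, 1.1)
    scale = peak_ms / (shape - 1)
    y = stats.gamma.pdf(t_ms, shape, scale=scale)
    return y / y.max()


def _smooth_time(x: np.ndarray, rate: float, sigma_ms: float = 35.0) -> np.ndarray:
    """Gaussian smoothing along the last axis."""
    sigma = sigma_ms / 1000.0 * rate
    half = int(np.ceil(3 * sigma))
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    kern /= kern.sum()
    pad = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(half, half)], mode="reflect")
    return np.apply_along_axis(lambda v: np.convolve(v, kern, mode="valid"),
                               -1, pad)


def one_over_f_noise(shape: tuple[int, ...], rate: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Band-limited 1/f-shaped Gaussian noise, unit variance per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    amp = 1.0 / np.sqrt(np.maximum(freqs, 0.5))
    amp *= np.exp(-((freqs / 10.0) ** 4))  # soft 10 Hz low-pass edge
    amp[0] = 0.0
    shaped = np.fft.irfft(spec * amp, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    return shaped / np.where(sd == 0, 1.0, sd)


def simulate_envelope_pair(
    duration: float,
    rate: float,
    rng: np.random.Generator,
    cutoff: float = 9.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent slow amplitude envelopes (unit variance).

    Rectified Gaussian noise is low-pass filtered well below 10 Hz, so
    essentially all spectral power sits in the envelope band; the two
    streams are generated from independent noise and are uncorrelated
    in expectation.
    """
    n = int(round(duration * rate))
    pad = int(rate)  # filter warm-up, cropped after filtering
    taps = signal.firwin(int(2 * rate) | 1, cutoff, fs=rate)
    out = []
    for _ in range(2):
        raw = np.abs(rng.standard_normal(n + 2 * pad))
        env = signal.filtfilt(taps, [1.0], raw)[pad:pad + n]
        sd = env.std()
        out.append(env / (sd if sd > 0 else 1.0))
    return out[0], out[1]


def _condition_gains(cfg: SynthConfig) -> dict[str, np.ndarray]:
    """Scalar tracking gain per condition and stream."""
    gains = {"dialogue": np.zeros(N_CONDITIONS),
             "background": np.zeros(N_CONDITIONS)}
    for c in ALL_CONDITIONS:
        i = canonical_condition_index(c)
        g_d = cfg.attended_gain_ratio if c.task == "attend" else 1.0
        # degraded input weakens tracking of the dialogue stream
        g_d *= 0.9 if c.auditory == "poor" else 1.0
        g_d *= 0.95 if c.visual == "poor" else 1.0
        g_d *= 0.97 if c.coherence == "incoherent" else 1.0
        gains["dialogue"][i] = g_d
        g_b = cfg.background_gain
        g_b *= cfg.background_attend_boost if c.task == "attend" else 1.0
        gains["background"][i] = g_b
    return gains


def make_kernels(cfg: SynthConfig,
                 rng: np.random.Generator) -> tuple[dict[str, np.ndarray],
                                                    np.ndarray,
                                                    dict[str, np.ndarray]]:
    """Ground-truth kernels [16 x n_channels x n_taps] per stream."""
    n_taps = int(round(cfg.kernel_length_ms / 1000.0 * cfg.rate))
    t_ms = np.arange(n_taps) * 1000.0 / cfg.rate
    k0 = _gamma_bump(t_ms, 90.0, 45.0) - 0.5 * _gamma_bump(t_ms, 280.0, 90.0)
    k_task = 0.7 * _gamma_bump(t_ms, 120.0, 50.0) + _gamma_bump(t_ms, 300.0, 80.0)
    window = signal.windows.tukey(n_taps, alpha=0.3)
    gains = _condition_gains(cfg)
    kernels: dict[str, np.ndarray] = {}
    for stream in ("dialogue", "background"):
        # signed (dipolar) channel topography; streams drawn independently
        base = rng.standard_normal(cfg.n_channels)
        base /= np.sqrt(np.mean(base**2))
        p_task = rng.standard_normal(cfg.n_channels)
        p_task /= np.linalg.norm(p_task) / np.sqrt(cfg.n_channels)
        K = np.zeros((N_CONDITIONS, cfg.n_channels, n_taps))
        for c in ALL_CONDITIONS:
            i = canonical_condition_index(c)
            sign = 1.0 if c.task == "attend" else -1.0
            idio = _smooth_time(rng.standard_normal((cfg.n_channels, n_taps)),
                                cfg.rate)
            idio /= np.abs(idio).max()
            K[i] = (base[:, None] * k0[None, :]
                    + sign * cfg.task_pattern_scale * p_task[:, None]
                    * k_task[None, :]
                    + cfg.idiosyncratic_scale * idio * window[None, :])
            K[i] *= gains[stream][i]
        kernels[stream] = K
    return kernels, t_ms, gains


def simulate_eeg_dataset(config: SynthConfig) -> tuple[Dataset, GroundTruth]:
    """Generate the EEG dataset and its ground truth.

    Per trial, each channel is the sum over streams of the (gain-
    modulated) envelope convolved with that condition's kernel, plus
    1/f noise scaled so the per-trial signal-to-noise power ratio
    equals ``config.snr``.  The within-line decay and line profile act
    multiplicatively on the attend-task dialogue stream.
    """
    cfg = config
    n_samples = epoch_samples(cfg.rate)
    master = np.random.default_rng(cfg.seed)
    dataset = Dataset()
    gain_rows = []
    all_kernels: dict[str, dict[str, np.ndarray]] = {}
    cond_gains = _condition_gains(cfg)
    channel_names = [f"ch{i:03d}" for i in range(cfg.n_channels)]
    decay_ramp = 1.0 - cfg.within_line_decay * np.linspace(0.0, 1.0, n_samples)
    t_ms = None
    for s_idx in range(cfg.n_subjects):
        subject = f"sub{s_idx + 1:02d}"
        rng = np.random.default_rng(master.integers(2**31))
        # each subject gets an independent brain: own topographies,
        # task pattern, and idiosyncratic kernel fields
        kernels, t_ms, _ = make_kernels(cfg, rng)
        all_kernels[subject] = kernels
        if t_ms.size > n_samples:
            raise ValueError("kernel longer than the 6.5 s epoch")
        trials = []
        baseline_powers = []
        ramp_ms = float(np.mean(decay_ramp**2))
        for cond in ALL_CONDITIONS:
            ci = canonical_condition_index(cond)
            for rep in range(cfg.n_lines_per_condition):
                line = rep % N_LINES + 1
                run = rep % cfg.n_runs + 1
                key = TrialKey(subject_id=subject, run=run,
                               dialogue_id=f"d{ci:02d}x{rep // N_LINES}",
                               line=line, condition=cond)
                env_d, env_b = simulate_envelope_pair(
                    n_samples / cfg.rate, cfg.rate, rng)
                signal_sum = np.zeros((cfg.n_channels, n_samples))
                p_base = 0.0
                for stream, env in (("dialogue", env_d), ("background", env_b)):
                    drive = env
                    line_gain = 1.0
                    ramped = False
                    if stream == "dialogue" and cond.task == "attend":
                        line_gain = cfg.line_profile[line - 1]
                        drive = env * decay_ramp
                        ramped = True
                    drive = drive * line_gain
                    conv = signal.fftconvolve(
                        drive[None, :], kernels[stream][ci], axes=1)[:, :n_samples]
                    signal_sum += conv
                    # power this stream would carry at unit condition gain
                    # and no within-line modulation
                    g2 = (cond_gains[stream][ci] * line_gain) ** 2
                    g2 *= ramp_ms if ramped else 1.0
                    p_base += np.mean(conv**2) / g2
                    gain_rows.append({
                        "subject": subject, "condition_index": ci,
                        "stream": stream, "line": line, "run": run,
                        "gain": cond_gains[stream][ci] * line_gain,
                    })
                trials.append((key, env_d, env_b, signal_sum))
                baseline_powers.append(p_base)
        # sensor noise is a fixed property of the recording, not of the
        # stimulus: one noise level per subject, referenced to the
        # unit-gain (baseline) response power so `snr` names the
        # signal-to-noise ratio of an unmodulated response
        noise_scale = np.sqrt(np.mean(baseline_powers) / cfg.snr)
        for key, env_d, env_b, signal_sum in trials:
            noise = one_over_f_noise((cfg.n_channels, n_samples),
                                     cfg.rate, rng)
            eeg = EegEpoch(signal_sum + noise * noise_scale,
                           channel_names, cfg.rate, key)
            dataset.add_trial(
                eeg,
                SpeechEnvelope(env_d, cfg.rate, key, "dialogue"),
                SpeechEnvelope(env_b, cfg.rate, key, "background"),
            )
    truth = GroundTruth(
        kernels=all_kernels, kernel_times_ms=t_ms, condition_gains=cond_gains,
        trial_gains=pd.DataFrame(gain_rows), roi_map=dict(cfg.roi_map),
        config=cfg,
    )
    return dataset, truth


def simulate_fmri_rdms(
    config: SynthConfig,
    trf_series: dict[str, RdmSeries],
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-subject ROI RDM stacks from the group TRF RDM series.

    Structured ROIs copy the designated stream's group-mean TRF RDM at
    the assigned latency and add independent symmetric noise per fMRI
    subject (scaled to ``noise`` times the spread of the template's
    lower triangle, so ranks are largely preserved); ``"null"`` ROIs
    are pure symmetric noise.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out: dict[str, np.ndarray] = {}
    n_subj = config.n_fmri_subjects
    for roi, spec in config.roi_map.items():
        stack = np.zeros((n_subj, N_CONDITIONS, N_CONDITIONS))
        if spec == "null":
            for k in range(n_subj):
                tri = 0.5 + 0.08 * rng.standard_normal(N_CONDITIONS * 15 // 2)
                stack[k] = _from_triangle(np.clip(tri, 0, 1))
        else:
            stream, latency_ms, noise = spec
            series = trf_series[stream]
            if not (series.times_ms.min() <= latency_ms <= series.times_ms.max()):
                raise ValueError(
                    f"ROI {roi}: latency {latency_ms} ms outside the TRF axis")
            t_idx = int(np.argmin(np.abs(series.times_ms - latency_ms)))
            tri0 = lower_triangle(series.values[t_idx])
            scale = noise * tri0.std()
            for k in range(n_subj):
                stack[k] = _from_triangle(
                    tri0 + scale * rng.standard_normal(tri0.size))
        out[roi] = stack
    return out


def _from_triangle(tri: np.ndarray) -> np.ndarray:
    m = np.zeros((N_CONDITIONS, N_CONDITIONS))
    idx = np.tril_indices(N_CONDITIONS, k=-1)
    m[idx] = tri
    return m + m.T


def reduced_null_config(seed: int) -> SynthConfig:
    """Small equal-gain configuration for type-I-error simulations.

    All task-dependent generator mechanisms are switched off (gain
    ratio 1, no within-line decay, flat line profile, no background
    task boost), so the attend and ignore cells are exchangeable.
    Eight subjects keep the exhaustive sign-flip null distribution
    fine-grained enough that the attainable 0.05-level rejection rate
    (12/256) sits at the nominal level.
    """
    return SynthConfig(
        n_subjects=8, n_channels=4, rate=64.0, n_lines_per_condition=2,
        attended_gain_ratio=1.0, within_line_decay=0.0,
        background_attend_boost=1.0,
        line_profile=(1.0,) * N_LINES, seed=seed,
    )
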