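"""Canonical types, condition ordering, and HDF5 container I/O.

The experiment is a 2x2x2x2 within-subject design: Attentional Task
(attend / ignore the audiovisual dialogue), Semantic Coherence
(coherent / incoherent), Auditory Quality (good / poor noise-vocoding)
and Visual Quality (good / poor masking).  Every analysis downstream —
RDMs, classifiers, model matrices — indexes the 16 cells exclusively
through :func:`canonical_condition_index`, so the ordering is frozen
here and nowhere else:

    attend block first (indices 0-7), then ignore (8-15); within a
    task block the order is co-gv-ga, inco-gv-ga, co-pv-ga, inco-pv-ga,
    co-gv-pa, inco-gv-pa, co-pv-pa, inco-pv-pa.

Each trial is one 6.5 s line of a dialogue, accompanied by the
simultaneous window of the continuously running background stream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np

TASKS = ("attend", "ignore")
COHERENCE_LEVELS = ("coherent", "incoherent")
QUALITY_LEVELS = ("good", "poor")
STREAMS = ("dialogue", "background")
FACTORS = ("task", "coherence", "auditory", "visual")

#: duration of one dialogue line epoch, seconds
EPOCH_SECONDS = 6.5
#: supported epoch sampling rates (Hz); 128 for TRFs, 64 for reconstruction
EPOCH_RATES = (64, 128)

N_CONDITIONS = 16
N_LINES = 7
N_RUNS = 3
N_SEGMENTS = 4


class ContainerError(RuntimeError):
    """Raised when an on-disk container violates the layout contract."""


class IncompleteTrialError(ContainerError):
    """A trial is missing one of its two stream envelopes."""


class RateMismatchError(ContainerError):
    """EEG and envelope sampling rates disagree within a trial."""


def epoch_samples(rate: float) -> int:
    """Number of samples in a 6.5 s epoch at ``rate`` Hz."""
    return int(round(EPOCH_SECONDS * rate))


@dataclass(frozen=True, order=True)
class ConditionLabel:
    """One cell of the factorial design."""

    task: str
    coherence: str
    auditory: str
    visual: str

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.coherence not in COHERENCE_LEVELS:
            raise ValueError(f"coherence must be one of {COHERENCE_LEVELS}")
        if self.auditory not in QUALITY_LEVELS:
            raise ValueError(f"auditory must be one of {QUALITY_LEVELS}")
        if self.visual not in QUALITY_LEVELS:
            raise ValueError(f"visual must be one of {QUALITY_LEVELS}")

    @property
    def code(self) -> str:
        """8-character serialization, e.g. ``att-co-gv-ga``."""
        task = "att" if self.task == "attend" else "ign"
        co = "co" if self.coherence == "coherent" else "inco"
        vis = "gv" if self.visual == "good" else "pv"
        aud = "ga" if self.auditory == "good" else "pa"
        return f"{task}-{co}-{vis}-{aud}"

    @classmethod
    def from_code(cls, code: str) -> "ConditionLabel":
        task_c, co, vis, aud = code.split("-")
        return cls(
            task={"att": "attend", "ign": "ignore"}[task_c],
            coherence={"co": "coherent", "inco": "incoherent"}[co],
            auditory={"ga": "good", "pa": "poor"}[aud],
            visual={"gv": "good", "pv": "poor"}[vis],
        )


def canonical_condition_index(label: ConditionLabel) -> int:
    """Map a condition label to its frozen position 0..15.

    Attend conditions occupy 0-7, ignore 8-15; within a task block the
    order iterates auditory quality slowest, then visual quality, then
    coherence (co-gv-ga, inco-gv-ga, co-pv-ga, inco-pv-ga, co-gv-pa,
    inco-gv-pa, co-pv-pa, inco-pv-pa).
    """
    return (
        8 * (label.task == "ignore")
        + 4 * (label.auditory == "poor")
        + 2 * (label.visual == "poor")
        + 1 * (label.coherence == "incoherent")
    )


def condition_from_index(index: int) -> ConditionLabel:
    """Inverse of :func:`canonical_condition_index`."""
    if not 0 <= index <= 15:
        raise ValueError(f"condition index must be in 0..15, got {index}")
    return ConditionLabel(
        task="ignore" if index & 8 else "attend",
        coherence="incoherent" if index & 1 else "coherent",
        auditory="poor" if index & 4 else "good",
        visual="poor" if index & 2 else "good",
    )


#: all 16 conditions in canonical order
ALL_CONDITIONS = tuple(condition_from_index(i) for i in range(N_CONDITIONS))


def factor_signs(label: ConditionLabel) -> dict[str, int]:
    """±1 coding of the four factors (first level of each factor is +1)."""
    return {
        "task": 1 if label.task == "attend" else -1,
        "coherence": 1 if label.coherence == "coherent" else -1,
        "auditory": 1 if label.auditory == "good" else -1,
        "visual": 1 if label.visual == "good" else -1,
    }


@dataclass(frozen=True, order=True)
class TrialKey:
    """Identity of one trial: one line of one dialogue for one subject.

    ``run`` and ``line`` are 1-based, as reported to users; internal
    arrays are always 0-based.
    """

    subject_id: str
    run: int
    dialogue_id: str
    line: int
    condition: ConditionLabel

    def __post_init__(self) -> None:
        if not 1 <= self.line <= N_LINES:
            raise ValueError(f"line must be in 1..{N_LINES}, got {self.line}")
        if not 1 <= self.run <= N_RUNS:
            raise ValueError(f"run must be in 1..{N_RUNS}, got {self.run}")

    @property
    def uid(self) -> str:
        return f"{self.subject_id}_r{self.run}_{self.dialogue_id}_l{self.line}"


@dataclass
class SpeechEnvelope:
    """Low-pass amplitude envelope of one stream, epoched to 6.5 s."""

    values: np.ndarray
    rate: float
    key: TrialKey
    stream: str = "dialogue"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stream not in STREAMS:
            raise ValueError(f"stream must be one of {STREAMS}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope values must be finite")
        expected = epoch_samples(self.rate)
        if self.values.shape != (expected,):
            raise ValueError(
                f"envelope must have {expected} samples at {self.rate} Hz, "
                f"got shape {self.values.shape}"
            )


@dataclass
class EegEpoch:
    """One 6.5 s multichannel EEG epoch (µV, 0.5-10 Hz band)."""

    data: np.ndarray
    channel_names: list[str]
    rate: float
    key: TrialKey

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG epoch must be [n_channels x n_samples]")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG values must be finite")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        expected = epoch_samples(self.rate)
        if self.data.shape[1] != expected:
            raise ValueError(
                f"epoch must have {expected} samples at {self.rate} Hz, "
                f"got {self.data.shape[1]}"
            )


@dataclass
class Dataset:
    """A collection of epochs with both stream envelopes per trial."""

    epochs: list[EegEpoch] = field(default_factory=list)
    envelopes: dict[tuple[str, str], SpeechEnvelope] = field(default_factory=dict)
    design: tuple[ConditionLabel, ...] = ALL_CONDITIONS

    def add_trial(
        self,
        epoch: EegEpoch,
        env_dialogue: SpeechEnvelope,
        env_background: SpeechEnvelope,
    ) -> None:
        self.epochs.append(epoch)
        self.envelopes[(epoch.key.uid, "dialogue")] = env_dialogue
        self.envelopes[(epoch.key.uid, "background")] = env_background

    def envelope(self, key: TrialKey, stream: str) -> SpeechEnvelope:
        return self.envelopes[(key.uid, stream)]

    @property
    def subjects(self) -> list[str]:
        return sorted({e.key.subject_id for e in self.epochs})

    def subject_epochs(self, subject_id: str) -> list[EegEpoch]:
        return [e for e in self.epochs if e.key.subject_id == subject_id]

    def validate(self) -> None:
        """Check the stream-completeness and rate invariants."""
        for epoch in self.epochs:
            for stream in STREAMS:
                env = self.envelopes.get((epoch.key.uid, stream))
                if env is None:
                    raise IncompleteTrialError(
                        f"incomplete trial: {epoch.key.uid} lacks its "
                        f"{stream}-stream envelope"
                    )
                if env.rate != epoch.rate:
                    raise RateMismatchError(
                        f"rate mismatch in trial {epoch.key.uid}: EEG at "
                        f"{epoch.rate} Hz, {stream} envelope at {env.rate} Hz"
                    )


# ---------------------------------------------------------------------------
# HDF5 container
#
# Layout: /subjects/<id>/trials/<trial_uid>/{eeg, env_dialogue,
# env_background} with attributes rate, run, line, dialogue_id,
# condition_index, channel_names on the trial group.
# ---------------------------------------------------------------------------


def write_container(dataset: Dataset, path) -> str:
    """Write a :class:`Dataset` to the documented HDF5 layout."""
    dataset.validate()
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "speechtrack-container"
        f.attrs["version"] = 1
        subjects = f.create_group("subjects")
        for epoch in dataset.epochs:
            key = epoch.key
            sub = subjects.require_group(key.subject_id)
            trials = sub.require_group("trials")
            grp = trials.create_group(key.uid)
            grp.create_dataset("eeg", data=epoch.data)
            for stream in STREAMS:
                env = dataset.envelope(key, stream)
                grp.create_dataset(f"env_{stream}", data=env.values)
            grp.attrs["rate"] = epoch.rate
            grp.attrs["run"] = key.run
            grp.attrs["line"] = key.line
            grp.attrs["dialogue_id"] = key.dialogue_id
            grp.attrs["condition_index"] = canonical_condition_index(key.condition)
            grp.attrs["channel_names"] = [str(c) for c in epoch.channel_names]
    return str(path)


def read_container(path) -> Dataset:
    """Read a container written by :func:`write_container`.

    The round trip is lossless: arrays are bit-identical and keys are
    reconstructed exactly.
    """
    dataset = Dataset()
    with h5py.File(path, "r") as f:
        subjects = f.get("subjects")
        if subjects is None:
            raise ContainerError(f"{path} is not a speechtrack container")
        for subject_id in sorted(subjects):
            trials = subjects[subject_id].get("trials", {})
            for uid in sorted(trials):
                grp = trials[uid]
                for stream in STREAMS:
                    if f"env_{stream}" not in grp:
                        raise IncompleteTrialError(
                            f"incomplete trial: {uid} lacks its "
                            f"{stream}-stream envelope"
                        )
                rate = float(grp.attrs["rate"])
                key = TrialKey(
                    subject_id=subject_id,
                    run=int(grp.attrs["run"]),
                    dialogue_id=str(grp.attrs["dialogue_id"]),
                    line=int(grp.attrs["line"]),
                    condition=condition_from_index(int(grp.attrs["condition_index"])),
                )
                channel_names = [str(c) for c in grp.attrs["channel_names"]]
                epoch = EegEpoch(grp["eeg"][()], channel_names, rate, key)
                envs = {
                    stream: SpeechEnvelope(grp[f"env_{stream}"][()], rate, key, stream)
                    for stream in STREAMS
                }
                dataset.add_trial(epoch, envs["dialogue"], envs["background"])
    dataset.validate()
    return dataset
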