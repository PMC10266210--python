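"""Core in-memory containers shared by every pipeline stage.

An :class:`EEGRecording` is a channels-by-time array with its sampling rate,
channel names, a domain tag ("source"/"target" or any string) and an attached
:class:`LabelSeries`.  A :class:`Segment` is one training sample: a fixed-size
window cut from a recording together with one interpolated fatigue-index
label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "LabelAccessError",
    "LabelSeries",
    "EEGRecording",
    "Segment",
    "INDEX_ANCHORS",
    "REACTION_TIMES",
]

INDEX_ANCHORS = "index_anchors"
REACTION_TIMES = "reaction_times"
_MODALITIES = (INDEX_ANCHORS, REACTION_TIMES)


class LabelAccessError(RuntimeError):
    """Raised when evaluation-only labels are requested for training."""


@dataclass
class LabelSeries:
    """Anchor times and values of a fatigue annotation.

    ``modality`` is either ``"index_anchors"`` (values are a bounded [0, 1]
    vigilance index, e.g. PERCLOS-like) or ``"reaction_times"`` (values are
    per-event reaction times in seconds, to be mapped to a drowsiness index
    before use).  Anchor times are strictly increasing seconds; ``span_end``
    marks the end of the interval covered by the last anchor (defaults to the
    last anchor time plus the median anchor spacing).
    """

    anchor_times: np.ndarray
    values: np.ndarray
    modality: str = INDEX_ANCHORS
    tau0: float = 1.0
    span_start: float | None = None
    span_end: float | None = None

    def __post_init__(self) -> None:
        self.anchor_times = np.asarray(self.anchor_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.anchor_times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("anchor_times and values must be 1-D")
        if self.anchor_times.shape != self.values.shape:
            raise ValueError("anchor_times and values must have equal length")
        if self.modality not in _MODALITIES:
            raise ValueError(
                f"unknown label modality {self.modality!r}; "
                f"expected one of {_MODALITIES}"
            )
        if self.anchor_times.size:
            if np.any(np.diff(self.anchor_times) <= 0):
                raise ValueError("anchor_times must be strictly increasing")
            if self.modality == INDEX_ANCHORS:
                if self.values.min() < 0 or self.values.max() > 1:
                    raise ValueError("index values must lie in [0, 1]")
            else:
                if self.values.min() <= 0:
                    raise ValueError("reaction times must be positive")
        if self.anchor_times.size:
            if self.span_start is None:
                self.span_start = float(self.anchor_times[0])
            elif self.span_start > self.anchor_times[0]:
                raise ValueError("span_start must not exceed the first anchor")
            if self.span_end is None:
                if self.anchor_times.size > 1:
                    step = float(np.median(np.diff(self.anchor_times)))
                else:
                    step = 1.0
                self.span_end = float(self.anchor_times[-1] + step)

    @property
    def n_anchors(self) -> int:
        return int(self.anchor_times.size)

    def copy(self) -> "LabelSeries":
        return LabelSeries(
            self.anchor_times.copy(),
            self.values.copy(),
            modality=self.modality,
            tau0=self.tau0,
            span_start=self.span_start,
            span_end=self.span_end,
        )


@dataclass
class EEGRecording:
    """A multichannel EEG recording with its annotation.

    ``labels_eval_only`` marks recordings whose labels exist for assessment
    but must not be seen by training (the unlabeled target domain).  Training
    code goes through :meth:`training_labels`, which enforces the contract;
    evaluation uses :meth:`assessment_labels`.
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    domain: str = "source"
    labels: LabelSeries | None = None
    labels_eval_only: bool = False
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x time 2-D array")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def training_labels(self) -> LabelSeries:
        """Labels for supervised training; refuses evaluation-only labels."""
        if self.labels is None:
            raise LabelAccessError(f"recording {self.recording_id!r} is unlabeled")
        if self.labels_eval_only:
            raise LabelAccessError(
                f"labels of recording {self.recording_id!r} are evaluation-only "
                "and may not be used for training"
            )
        return self.labels

    def assessment_labels(self) -> LabelSeries:
        """Labels for evaluation; always available when present."""
        if self.labels is None:
            raise LabelAccessError(f"recording {self.recording_id!r} is unlabeled")
        return self.labels

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        return replace(self, data=data, fs=self.fs if fs is None else fs)


@dataclass
class Segment:
    """One training sample: a C x T window with a scalar fatigue index."""

    window: np.ndarray
    label: float
    domain: str = "source"
    source_recording: str = ""
    start_sample: int = 0
    label_eval_only: bool = False

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=float)
        if self.window.ndim != 2:
            raise ValueError("segment window must be 2-D (channels x time)")
        if not (0.0 <= self.label <= 1.0):
            raise ValueError(f"segment label {self.label} outside [0, 1]")

    @property
    def n_channels(self) -> int:
        return int(self.window.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.window.shape[1])


def stack_windows(segments: Sequence[Segment]) -> np.ndarray:
    """Stack segment windows into a batch x C x T array."""
    return np.stack([s.window for s in segments]).astype(np.float64)


def stack_labels(segments: Sequence[Segment], *, training: bool = False) -> np.ndarray:
    """Stack segment labels; with ``training=True`` eval-only labels raise."""
    if training:
        locked = [s.source_recording for s in segments if s.label_eval_only]
        if locked:
            raise LabelAccessError(
                f"segments from {sorted(set(locked))} carry evaluation-only labels"
            )
    return np.array([s.label for s in segments], dtype=float)
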