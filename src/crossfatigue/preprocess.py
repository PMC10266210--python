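"""Signal conditioning and segmentation.

Covers the standard conditioning chain applied to both domains — zero-phase
FIR band-pass (1–50 Hz), anti-aliased downsampling to 128 Hz, montage
matching between datasets with different channel sets — plus the two
label-side operations specific to this pipeline:

* ``rt_to_di``: the bounded monotone transform from a reaction time tau to
  the drowsiness index DI = max(0, (1 - e^-(tau - tau0)) / (1 + e^-(tau - tau0))),
  with tau0 = 1 s by default;
* ``interpolate_label``: overlap-fraction-weighted averaging of
  piecewise-constant anchor labels over an arbitrary segment span, so that
  segments cut at a random offset still receive a consistent index label.

Segmentation draws one uniform random offset in {0..T-1} per call and tiles
non-overlapping C x T windows from it, re-drawable every training epoch.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import signal

from .types import (
    EEGRecording,
    INDEX_ANCHORS,
    LabelSeries,
    REACTION_TIMES,
    Segment,
)

__all__ = [
    "ChannelMap",
    "fir_bandpass",
    "resample_to",
    "match_channels",
    "load_alias_table",
    "rt_to_di",
    "to_index_series",
    "interpolate_label",
    "random_offset_segments",
    "normalize",
]


# ---------------------------------------------------------------------------
# filtering and resampling
# ---------------------------------------------------------------------------

def fir_bandpass(rec: EEGRecording, hp: float = 1.0, lp: float = 50.0) -> EEGRecording:
    """Zero-phase windowed-sinc (Hamming) band-pass filter.

    The filter order targets a ~1 Hz transition band and is capped so
    forward-backward filtering stays valid for short recordings.
    """
    nyq = rec.fs / 2.0
    if not (0 < hp < lp):
        raise ValueError("require 0 < hp < lp")
    if lp >= nyq:
        raise ValueError(f"low-pass edge {lp} Hz >= Nyquist {nyq} Hz")
    numtaps = int(3.3 * rec.fs / 1.0)  # ~1 Hz transition width
    numtaps = min(numtaps, rec.n_samples // 3 - 1)
    numtaps = max(numtaps | 1, 11)  # odd, sensible floor
    taps = signal.firwin(numtaps, [hp, lp], pass_zero=False, fs=rec.fs,
                         window="hamming")
    out = signal.filtfilt(taps, [1.0], rec.data, axis=1)
    return rec.with_data(out)


def resample_to(rec: EEGRecording, fs_out: float = 128.0) -> EEGRecording:
    """Polyphase anti-aliased downsampling; upsampling is out of scope."""
    if fs_out > rec.fs:
        raise ValueError(f"upsampling {rec.fs} -> {fs_out} Hz not supported")
    if fs_out == rec.fs:
        return rec.with_data(rec.data.copy())
    from fractions import Fraction

    frac = Fraction(fs_out / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    rec2 = rec.with_data(out, fs=fs_out)
    return rec2


# ---------------------------------------------------------------------------
# channel matching
# ---------------------------------------------------------------------------

@dataclass
class ChannelMap:
    """One-to-one channel pairing; ordered by the smaller montage."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("channel map is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def names_a(self) -> list[str]:
        return [a for a, _ in self.pairs]

    def names_b(self) -> list[str]:
        return [b for _, b in self.pairs]


def load_alias_table(path: str | None = None) -> list[tuple[str, str]]:
    """Montage synonym pairs (editable CSV; default covers 10-20 synonyms
    and the nearest-electrode pairings between the two emulated montages)."""
    if path is None:
        ref = resources.files("crossfatigue.data") / "montage_aliases.csv"
        text = ref.read_text().splitlines()
    else:
        with open(path) as fh:
            text = fh.read().splitlines()
    rows = list(csv.DictReader(text))
    return [(r["name_a"].strip().upper(), r["name_b"].strip().upper()) for r in rows]


def match_channels(names_a, names_b,
                   aliases: list[tuple[str, str]] | None = None) -> ChannelMap:
    """Pair channels across two montages by the one-to-one correspondence
    principle: the montage with fewer channels drives the matching; exact
    (case-insensitive) name matches are taken first, then alias-table
    equivalences.  Unmatchable channels are dropped."""
    if not names_a or not names_b:
        raise ValueError("both channel lists must be non-empty")
    if aliases is None:
        aliases = load_alias_table()
    alias_of: dict[str, set[str]] = {}
    for x, y in aliases:
        alias_of.setdefault(x, set()).add(y)
        alias_of.setdefault(y, set()).add(x)

    swap = len(names_b) < len(names_a)
    small, big = (names_b, names_a) if swap else (names_a, names_b)
    big_upper = {n.upper(): n for n in big}
    used: set[str] = set()
    pairs: list[tuple[str, str]] = []
    # exact matches first so aliases never steal a channel's exact partner
    exact: dict[str, str] = {}
    for name in small:
        u = name.upper()
        if u in big_upper and u not in used:
            exact[name] = big_upper[u]
            used.add(u)
    for name in small:
        if name in exact:
            pairs.append((name, exact[name]))
            continue
        for cand in sorted(alias_of.get(name.upper(), ())):
            if cand in big_upper and cand not in used:
                pairs.append((name, big_upper[cand]))
                used.add(cand)
                break
    if not pairs:
        raise ValueError(
            "no matching channels between montages "
            f"{list(names_a)} and {list(names_b)}"
        )
    if swap:
        pairs = [(b, a) for a, b in pairs]
    return ChannelMap(pairs)


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def rt_to_di(tau, tau0: float = 1.0):
    """Drowsiness index DI = max(0, (1 - e^-(tau-tau0)) / (1 + e^-(tau-tau0))).

    Maps a positive reaction time to [0, 1); exactly 0 for tau <= tau0 and
    monotone non-decreasing in tau.  Accepts scalars or arrays.
    """
    arr = np.asarray(tau, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("reaction times must be positive")
    e = np.exp(-(arr - tau0))
    di = np.maximum(0.0, (1.0 - e) / (1.0 + e))
    return float(di) if np.isscalar(tau) or arr.ndim == 0 else di


def to_index_series(labels: LabelSeries) -> LabelSeries:
    """Unify both modalities to a [0, 1] index series (reaction times go
    through :func:`rt_to_di`)."""
    if labels.modality == INDEX_ANCHORS:
        return labels
    values = rt_to_di(labels.values, labels.tau0)
    return LabelSeries(labels.anchor_times.copy(), values,
                       modality=INDEX_ANCHORS,
                       span_start=labels.span_start, span_end=labels.span_end)


def interpolate_label(labels: LabelSeries, start_s: float, end_s: float) -> float:
    """Overlap-weighted average of piecewise-constant anchor values.

    Each anchor's value is held constant over its interval
    [t_i, t_{i+1}) — the first interval starts at ``labels.span_start`` and
    the last extends to ``labels.span_end`` — and the returned label is the
    average over [start_s, end_s) weighted by overlap fraction, the discrete
    form of integrating the stepwise label over the segment.
    """
    if end_s <= start_s:
        raise ValueError("require end_s > start_s")
    if labels.modality != INDEX_ANCHORS:
        labels = to_index_series(labels)
    times = labels.anchor_times
    if times.size == 0:
        raise ValueError("label series is empty")
    edges = np.concatenate([[labels.span_start], times[1:], [labels.span_end]])
    span_lo, span_hi = edges[0], edges[-1]
    lo = max(start_s, span_lo)
    hi = min(end_s, span_hi)
    if hi <= lo:
        raise ValueError(
            f"segment [{start_s}, {end_s}) lies outside the annotated span "
            f"[{span_lo}, {span_hi})"
        )
    overlaps = np.maximum(
        0.0, np.minimum(hi, edges[1:]) - np.maximum(lo, edges[:-1])
    )
    total = overlaps.sum()
    return float(np.dot(overlaps, labels.values) / total)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def random_offset_segments(rec: EEGRecording, T: int = 1024,
                           rng: np.random.Generator | int = 0,
                           offset: int | None = None) -> list[Segment]:
    """Cut non-overlapping C x T windows starting at one random offset.

    A single offset is drawn uniformly from {0..T-1} per call (re-drawn on
    each call, so successive training epochs see different windows); a
    trailing partial window is discarded.  Each window's label is the
    overlap-weighted interpolation of the recording's annotation.
    """
    if rec.n_samples < 2 * T:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than 2*T={2 * T}"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if offset is None:
        offset = int(rng.integers(0, T))
    elif not (0 <= offset < T):
        raise ValueError("offset must lie in {0..T-1}")
    labels = to_index_series(rec.assessment_labels())
    segments = []
    for start in range(offset, rec.n_samples - T + 1, T):
        start_s = start / rec.fs
        end_s = (start + T) / rec.fs
        label = interpolate_label(labels, start_s, end_s)
        segments.append(
            Segment(
                window=rec.data[:, start : start + T].copy(),
                label=float(np.clip(label, 0.0, 1.0)),
                domain=rec.domain,
                source_recording=rec.recording_id,
                start_sample=start,
                label_eval_only=rec.labels_eval_only,
            )
        )
    return segments


def normalize(segment: Segment) -> Segment:
    """Per-channel z-score within the segment; constant channels map to 0."""
    w = segment.window
    mean = w.mean(axis=1, keepdims=True)
    sd = w.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    out = (w - mean) / sd
    from dataclasses import replace

    return replace(segment, window=out)


def rms_normalize(segment: Segment) -> Segment:
    """Whole-segment RMS scaling (mean removed per channel).

    Unlike the per-channel z-score, this keeps the *relative* channel
    amplitudes — the spatial gain pattern that distinguishes recording
    setups — while removing absolute units; it is the default segment
    scaling in the training pipeline.
    """
    w = segment.window
    w = w - w.mean(axis=1, keepdims=True)
    r = np.sqrt((w**2).mean())
    from dataclasses import replace

    return replace(segment, window=w / (r if r > 0 else 1.0))
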