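"""On-disk interchange: EDF recordings, CSV label sidecars, JSON manifests,
and an ``.npz`` segment container.

Recordings are written as standard 16-bit EDF (one file per recording,
channel names in the signal headers, amplitudes in microvolts) with a CSV
sidecar holding the label anchors (columns ``time_s, value, modality``) and
a per-directory ``manifest.json`` listing domain membership.  Reading goes
through MNE's EDF reader; the writer here is a minimal EDF implementation
(integer-second data records, physical range fitted per channel).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EEGRecording, LabelSeries, Segment

__all__ = [
    "write_edf",
    "read_edf",
    "write_recording",
    "read_recording",
    "write_domain_dir",
    "read_domain_dir",
    "save_segments",
    "load_segments",
]


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: EEGRecording) -> Path:
    """Write a recording as 16-bit EDF (µV).  Requires an integer sampling
    rate; trailing samples beyond the last whole second are dropped."""
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = rec.n_samples // fs
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_rec * fs]
    ns = rec.n_channels

    # round the physical range outward to what the 8-char header can carry,
    # and digitize against the rounded values so read-back scaling matches
    pmin = np.floor(data.min(axis=1) * 100) / 100
    pmax = np.ceil(data.max(axis=1) * 100) / 100
    flat = pmax - pmin < 1e-2
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    header = b"".join([
        _ascii(0, 8),
        _ascii("X", 80),
        _ascii(rec.recording_id or "X", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (ns + 1), 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii(1, 8),
        _ascii(ns, 4),
    ])
    sig = b"".join([
        b"".join(_ascii(name, 16) for name in rec.channel_names),
        b"".join(_ascii("", 80) for _ in range(ns)),
        b"".join(_ascii("uV", 8) for _ in range(ns)),
        b"".join(_ascii(f"{v:.2f}"[:8], 8) for v in pmin),
        b"".join(_ascii(f"{v:.2f}"[:8], 8) for v in pmax),
        b"".join(_ascii(dmin, 8) for _ in range(ns)),
        b"".join(_ascii(dmax, 8) for _ in range(ns)),
        b"".join(_ascii("", 80) for _ in range(ns)),
        b"".join(_ascii(fs, 8) for _ in range(ns)),
        b"".join(_ascii("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # records: for each second, all channels' samples sequentially
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
    return path


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file via MNE; returns (data in µV, fs, channel names)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


def _labels_path(edf_path: Path) -> Path:
    return edf_path.with_suffix(".labels.csv")


def write_recording(dirpath: str | Path, rec: EEGRecording) -> dict:
    """Write one recording (EDF + label CSV); returns its manifest entry."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    edf = dirpath / f"{rec.recording_id}.edf"
    write_edf(edf, rec)
    entry = {
        "recording_id": rec.recording_id,
        "edf": edf.name,
        "domain": rec.domain,
        "labels_eval_only": rec.labels_eval_only,
        "fs": rec.fs,
    }
    if rec.labels is not None:
        lab = rec.labels
        pd.DataFrame({
            "time_s": lab.anchor_times,
            "value": lab.values,
            "modality": lab.modality,
        }).to_csv(_labels_path(edf), index=False)
        entry["labels"] = _labels_path(edf).name
        entry["tau0"] = lab.tau0
        entry["span_start"] = lab.span_start
        entry["span_end"] = lab.span_end
    return entry


def read_recording(dirpath: str | Path, entry: dict) -> EEGRecording:
    dirpath = Path(dirpath)
    data, fs, names = read_edf(dirpath / entry["edf"])
    labels = None
    if "labels" in entry:
        df = pd.read_csv(dirpath / entry["labels"])
        labels = LabelSeries(
            df["time_s"].to_numpy(),
            df["value"].to_numpy(),
            modality=str(df["modality"].iloc[0]),
            tau0=float(entry.get("tau0", 1.0)),
            span_start=entry.get("span_start"),
            span_end=entry.get("span_end"),
        )
    return EEGRecording(
        data=data,
        fs=fs,
        channel_names=names,
        domain=entry["domain"],
        labels=labels,
        labels_eval_only=bool(entry.get("labels_eval_only", False)),
        recording_id=entry["recording_id"],
    )


def write_domain_dir(dirpath: str | Path, source: list[EEGRecording],
                     target: list[EEGRecording]) -> Path:
    """Write a simulated domain pair plus a manifest listing membership."""
    dirpath = Path(dirpath)
    entries = [write_recording(dirpath, r) for r in source + target]
    manifest = dirpath / "manifest.json"
    manifest.write_text(json.dumps({"recordings": entries}, indent=2))
    return manifest


def read_domain_dir(dirpath: str | Path) -> tuple[list[EEGRecording], list[EEGRecording]]:
    dirpath = Path(dirpath)
    manifest = json.loads((dirpath / "manifest.json").read_text())
    source, target = [], []
    for entry in manifest["recordings"]:
        rec = read_recording(dirpath, entry)
        (source if rec.domain == "source" else target).append(rec)
    return source, target


def save_segments(path: str | Path, segments: list[Segment]) -> Path:
    """Segment tensors in an .npz container with a JSON manifest inside."""
    path = Path(path)
    windows = np.stack([s.window for s in segments]).astype(np.float32)
    meta = {
        "labels": [s.label for s in segments],
        "domains": [s.domain for s in segments],
        "recordings": [s.source_recording for s in segments],
        "starts": [s.start_sample for s in segments],
        "eval_only": [s.label_eval_only for s in segments],
    }
    np.savez_compressed(path, windows=windows, manifest=json.dumps(meta))
    return path


def load_segments(path: str | Path) -> list[Segment]:
    with np.load(path, allow_pickle=False) as npz:
        windows = npz["windows"]
        meta = json.loads(str(npz["manifest"]))
    return [
        Segment(
            window=windows[i].astype(float),
            label=float(meta["labels"][i]),
            domain=meta["domains"][i],
            source_recording=meta["recordings"][i],
            start_sample=int(meta["starts"][i]),
            label_eval_only=bool(meta["eval_only"][i]),
        )
        for i in range(windows.shape[0])
    ]
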