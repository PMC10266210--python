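"""Synthetic multi-domain EEG with a latent fatigue trajectory.

The generator stands in for a pair of driving-vigilance EEG datasets so the
whole pipeline is testable offline.  Each recording is a sum of band-limited
oscillators (delta/theta/alpha/beta at 2/6/10/20 Hz, random phase per
channel) plus 1/f ("pink") noise.  The classic fatigue signature is built
in: theta and alpha amplitudes rise and beta amplitude falls monotonically
with the latent fatigue index f(t), a clipped mean-reverting
(Ornstein-Uhlenbeck-style) random walk in [0, 1].

Two annotation modalities emulate the two real-world labelling schemes:

* ``index_anchors`` — the latent index sampled on a fixed grid (every 8 s by
  default) plus clipped Gaussian noise, like a PERCLOS series;
* ``reaction_times`` — event times with reaction times
  tau = tau0 + ln((1 + f)/(1 - f)) + noise, chosen so the standard
  drowsiness-index transform inverts it exactly at zero noise.

``shift`` scales every cross-domain difference (per-channel gains, noise
level, spectral tilt, oscillator base amplitudes); at ``shift=0`` the two
domains follow the same generative law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import EEGRecording, INDEX_ANCHORS, LabelSeries, REACTION_TIMES

__all__ = [
    "SynthConfig",
    "LatentFatigue",
    "simulate_latent",
    "simulate_recording",
    "make_domain_pair",
    "DEFAULT_CHANNELS",
]

# 17 channels matching the posterior + temporal montage shared by the two
# emulated datasets (the 18th, POZ, has no partner and is dropped).
DEFAULT_CHANNELS = (
    "CP1", "CPZ", "CP2", "P1", "PZ", "P2", "PO3", "PO4",
    "O1", "OZ", "O2", "FT7", "FT8", "T7", "T8", "TP7", "TP8",
)

_BANDS = {  # name -> (center Hz, base amplitude uV)
    "delta": (2.0, 8.0),
    "theta": (6.0, 6.0),
    "alpha": (10.0, 6.0),
    "beta": (20.0, 4.0),
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic domain pair."""

    n_channels: int = 17
    fs: float = 128.0
    duration: float = 64.0
    n_recordings_per_domain: int = 4
    shift: float = 1.0
    label_modality: str = INDEX_ANCHORS
    anchor_interval: float = 8.0
    label_noise_sd: float = 0.02
    rt_event_interval: float = 6.0  # mean spacing of lane-departure events, s
    tau0: float = 1.0
    noise_amp: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if self.anchor_interval <= 0:
            raise ValueError("anchor_interval must be positive")
        if self.label_modality not in (INDEX_ANCHORS, REACTION_TIMES):
            raise ValueError(f"unknown label modality {self.label_modality!r}")

    def channel_names(self) -> list[str]:
        base = list(DEFAULT_CHANNELS)
        if self.n_channels <= len(base):
            return base[: self.n_channels]
        return base + [f"X{i}" for i in range(self.n_channels - len(base))]


@dataclass
class LatentFatigue:
    """A smooth latent fatigue trajectory on a regular time grid."""

    t: np.ndarray
    f_t: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f_t = np.asarray(self.f_t, dtype=float)
        if self.t.shape != self.f_t.shape:
            raise ValueError("t and f_t must have the same shape")
        if self.f_t.size and (self.f_t.min() < 0 or self.f_t.max() > 1):
            raise ValueError("latent fatigue must lie in [0, 1]")

    def at(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of the trajectory at arbitrary times."""
        return np.interp(times, self.t, self.f_t)

    @property
    def duration(self) -> float:
        return float(self.t[-1]) if self.t.size else 0.0


def simulate_latent(duration: float, fs_label: float = 4.0,
                    seed: int | np.random.Generator = 0,
                    *, mean: float = 0.5, reversion: float = 0.01,
                    volatility: float = 0.03) -> LatentFatigue:
    """Clipped mean-reverting random walk in [0, 1].

    ``reversion`` (1/s) pulls toward ``mean``; ``volatility`` (1/sqrt(s))
    sets the step noise.  The defaults drift on the minutes timescale that
    vigilance changes on — nearly constant within one 8-s annotation
    interval, but sweeping a wide range of the [0, 1] index over a session.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs_label))
    if n == 0:
        return LatentFatigue(np.empty(0), np.empty(0))
    dt = 1.0 / fs_label
    t = np.arange(n) * dt
    f = np.empty(n)
    f[0] = np.clip(rng.normal(mean, 0.25), 0.0, 1.0)
    steps = rng.normal(0.0, volatility * np.sqrt(dt), size=n - 1)
    for k in range(1, n):
        drift = reversion * (mean - f[k - 1]) * dt
        f[k] = np.clip(f[k - 1] + drift + steps[k - 1], 0.0, 1.0)
    return LatentFatigue(t, f)


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                tilt: float = 0.0) -> np.ndarray:
    """1/f-shaped Gaussian noise; ``tilt`` > 0 shifts power toward high
    frequencies (the spectral component of the domain shift)."""
    white = rng.normal(size=(n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-0.5 + tilt)
    shape[0] = 0.0
    out = np.fft.irfft(spec * shape[None, :], n=n, axis=1)
    sd = out.std()
    return out / sd if sd > 0 else out


def _domain_params(cfg: SynthConfig, domain: str, rng: np.random.Generator) -> dict:
    """Deterministic per-domain generative parameters, scaled by cfg.shift.

    The source domain uses the reference law; the target domain deviates in
    per-channel gain, noise level, spectral tilt and oscillator amplitude by
    amounts proportional to ``shift``.
    """
    shifted = domain != "source"
    s = cfg.shift if shifted else 0.0
    gain_rng = np.random.default_rng(cfg.seed + 7919)  # fixed per config
    gains = 1.0 + s * 0.25 * gain_rng.standard_normal(cfg.n_channels)
    gains = np.clip(gains, 0.1, None)
    return {
        "gains": gains,
        "noise_scale": 1.0 + 0.4 * s,
        "tilt": 0.12 * s,
        "amp_scale": 1.0 + 0.15 * s,
    }


def simulate_recording(cfg: SynthConfig, domain: str, latent: LatentFatigue,
                       rng: np.random.Generator | int | None = None,
                       recording_id: str = "") -> EEGRecording:
    """Render one EEG recording from a latent fatigue trajectory."""
    if latent.duration + 1.0 / 4.0 < cfg.duration:
        raise ValueError("latent trajectory does not cover the recording duration")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    f = latent.at(t)  # (n,)
    par = _domain_params(cfg, domain, rng)

    data = np.zeros((cfg.n_channels, n))
    for name, (freq, base_amp) in _BANDS.items():
        if name in ("theta", "alpha"):
            amp_t = base_amp * (0.5 + f)          # increases with fatigue
        elif name == "beta":
            amp_t = base_amp * (1.5 - f)          # decreases with fatigue
        else:
            amp_t = np.full(n, base_amp)
        phases = rng.uniform(0, 2 * np.pi, size=cfg.n_channels)
        # band rhythms are only partially phase-coherent: let each channel's
        # phase diffuse (~0.8 rad/sqrt(s)) so no stable inter-channel phase
        # fingerprint identifies a recording
        drift = np.cumsum(
            rng.normal(0.0, 0.8 / np.sqrt(cfg.fs), size=(cfg.n_channels, n)),
            axis=1,
        )
        osc = np.sin(2 * np.pi * freq * t[None, :] + phases[:, None] + drift)
        data += par["amp_scale"] * amp_t[None, :] * osc
    data += cfg.noise_amp * par["noise_scale"] * _pink_noise(
        rng, cfg.n_channels, n, cfg.fs, tilt=par["tilt"]
    )
    data *= par["gains"][:, None]

    labels = _make_labels(cfg, f, t, rng)
    return EEGRecording(
        data=data,
        fs=cfg.fs,
        channel_names=cfg.channel_names(),
        domain=domain,
        labels=labels,
        recording_id=recording_id or f"{domain}-rec",
    )


def _make_labels(cfg: SynthConfig, f: np.ndarray, t: np.ndarray,
                 rng: np.random.Generator) -> LabelSeries:
    if cfg.label_modality == INDEX_ANCHORS:
        anchors = np.arange(0.0, cfg.duration, cfg.anchor_interval)
        vals = np.interp(anchors, t, f)
        vals = np.clip(vals + rng.normal(0, cfg.label_noise_sd, size=vals.size), 0, 1)
        return LabelSeries(anchors, vals, modality=INDEX_ANCHORS,
                           span_start=0.0, span_end=float(cfg.duration))
    # reaction-time events at jittered times; tau chosen so the DI transform
    # recovers f exactly when label_noise_sd == 0
    n_ev = max(2, int(round(cfg.duration / cfg.rt_event_interval)))
    times = np.sort(rng.uniform(0.0, cfg.duration, size=n_ev))
    times = np.unique(times)
    while times.size < 2:  # pragma: no cover - vanishingly unlikely
        times = np.sort(rng.uniform(0.0, cfg.duration, size=n_ev))
        times = np.unique(times)
    fv = np.clip(np.interp(times, t, f), 0.0, 0.999)
    tau = cfg.tau0 + np.log((1.0 + fv) / (1.0 - fv))
    tau = np.maximum(tau + rng.normal(0, cfg.label_noise_sd, size=tau.size), 1e-3)
    return LabelSeries(times, tau, modality=REACTION_TIMES, tau0=cfg.tau0,
                       span_start=0.0, span_end=float(cfg.duration))


def make_domain_pair(cfg: SynthConfig) -> tuple[list[EEGRecording], list[EEGRecording]]:
    """A labeled source-like and an evaluation-only target-like domain.

    Source recordings carry index-anchor labels; target recordings carry
    reaction-time labels flagged evaluation-only, so training can never read
    them (the target domain is unlabeled from the learner's point of view).
    """
    if cfg.n_recordings_per_domain < 1:
        raise ValueError("n_recordings_per_domain must be >= 1")
    from dataclasses import replace

    rng = np.random.default_rng(cfg.seed)
    source, target = [], []
    for domain, bucket in (("source", source), ("target", target)):
        for i in range(cfg.n_recordings_per_domain):
            modality = INDEX_ANCHORS if domain == "source" else REACTION_TIMES
            dom_cfg = replace(cfg, label_modality=modality)
            latent = simulate_latent(cfg.duration + 1.0, seed=rng)
            rec = simulate_recording(
                dom_cfg, domain, latent, rng=rng,
                recording_id=f"{domain}-{i:02d}",
            )
            if domain == "target":
                rec.labels_eval_only = True
            bucket.append(rec)
    return source, target
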