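"""Synthetic two-class motor-imagery EEG with planted ERD/ERS.

Each trial is a superposition, per channel, of

* 1/f**alpha background noise (broadband, task independent),
* a mu rhythm (band-limited noise, 8-13 Hz by default) and
* a beta rhythm (13-30 Hz by default),

where during the imagery cue interval the mu/beta amplitude of the channel
contralateral to the imagined hand is attenuated (event-related
desynchronization) and the ipsilateral channel enhanced (event-related
synchronization).  "Left" imagery therefore attenuates C4 and enhances C3;
"right" is the mirror image.  Cz carries task-independent rhythms.  Gains
are ramped with a raised cosine at the cue edges so no step artifacts leak
into wavelet subbands.

Rhythms are band-limited noise rather than pure tones so that subband
energies are non-degenerate.  The default geometry mirrors a classic
three-channel cued-imagery protocol: 128 Hz sampling, 9 s trials, cue from
3 s on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _sig

__all__ = ["SimConfig", "TrialSet", "generate_trials",
           "write_trialset", "read_trialset"]

CLASSES = ("left", "right")


@dataclass
class SimConfig:
    """Generator settings; defaults define the reference study conditions."""

    n_trials: int = 200
    fs: float = 128.0
    duration_s: float = 9.0
    cue_interval: tuple = (3.0, 7.0)
    mu_band: tuple = (8.0, 13.0)
    beta_band: tuple = (13.0, 30.0)
    # per-channel rhythm amplitudes (standard deviations, microvolts)
    mu_amp: dict = field(default_factory=lambda: {"C3": 1.0, "Cz": 0.5,
                                                  "C4": 1.0})
    beta_amp: dict = field(default_factory=lambda: {"C3": 0.7, "Cz": 0.35,
                                                    "C4": 0.7})
    erd_factor: float = 0.5    # multiplicative power attenuation, (0, 1]
    ers_factor: float = 1.2    # ipsilateral power enhancement, >= 1
    noise_exponent: float = 1.0
    noise_amp: float = 1.0
    ramp_s: float = 0.25
    rng_seed: int = 0

    def validate(self):
        if self.n_trials < 0:
            raise ValueError("n_trials must be nonnegative")
        if self.fs < 64:
            raise ValueError("fs must be >= 64 Hz so the beta band is "
                             "representable")
        for name, (lo, hi) in (("mu_band", self.mu_band),
                               ("beta_band", self.beta_band)):
            if lo >= hi:
                raise ValueError(f"{name}: low edge must be below high edge")
            if hi > self.fs / 2:
                raise ValueError(f"{name} extends beyond Nyquist "
                                 f"({self.fs / 2} Hz)")
        if not 0 < self.erd_factor <= 1:
            raise ValueError("erd_factor must lie in (0, 1]")
        if self.ers_factor < 1:
            raise ValueError("ers_factor must be >= 1")
        lo, hi = self.cue_interval
        if not 0 <= lo < hi <= self.duration_s:
            raise ValueError("cue_interval must lie within the trial")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration_s must be an integer sample count")

    @property
    def n_samples(self):
        return int(round(self.fs * self.duration_s))


@dataclass
class TrialSet:
    """Trials x channels x samples EEG block with per-trial class labels."""

    data: np.ndarray           # (n_trials, n_channels, n_samples), microvolts
    labels: np.ndarray         # per-trial, 'left' / 'right'
    fs: float
    channels: list
    trial_window: tuple        # (cue start, cue end) seconds from trial onset

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel count mismatch")
        if not {"C3", "C4"} <= set(self.channels):
            raise ValueError("channels must include C3 and C4")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or Inf")

    @property
    def n_trials(self):
        return self.data.shape[0]

    @property
    def n_samples(self):
        return self.data.shape[2]

    def channel(self, name):
        return self.data[:, self.channels.index(name), :]

    def subset(self, idx):
        return TrialSet(self.data[idx], self.labels[idx], self.fs,
                        list(self.channels), self.trial_window)


def _pink_noise(rng, n, exponent):
    """FFT-shaped 1/f**exponent noise, unit standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(rng, n, fs, band):
    """Band-limited Gaussian noise, unit standard deviation."""
    sos = _sig.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, rng.standard_normal(n + 4 * int(fs)))
    x = x[2 * int(fs): 2 * int(fs) + n]     # drop filter warm-up
    sd = x.std()
    return x / sd if sd > 0 else x


def _gain_curve(cfg, power_factor):
    """Amplitude gain over time: sqrt(power_factor) inside the cue interval,
    1 outside, raised-cosine ramps at the edges."""
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    g = np.ones(n)
    lo, hi = cfg.cue_interval
    amp = np.sqrt(power_factor)
    ramp = max(cfg.ramp_s, 1.0 / cfg.fs)
    rise = np.clip((t - lo) / ramp, 0, 1)
    fall = np.clip((hi - t) / ramp, 0, 1)
    envelope = 0.5 * (1 - np.cos(np.pi * rise)) * 0.5 * (1 - np.cos(np.pi * fall))
    return g + (amp - 1.0) * envelope


def generate_trials(cfg: SimConfig) -> TrialSet:
    """Generate a balanced two-class synthetic trial set.

    Deterministic for a given config (labels alternate left/right; all noise
    draws come from ``cfg.rng_seed``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    channels = ["C3", "Cz", "C4"]
    n = cfg.n_samples
    labels = np.array([CLASSES[i % 2] for i in range(cfg.n_trials)])

    g_erd = _gain_curve(cfg, cfg.erd_factor)
    g_ers = _gain_curve(cfg, cfg.ers_factor)
    g_flat = np.ones(n)

    data = np.empty((cfg.n_trials, len(channels), n))
    for i, lab in enumerate(labels):
        # contralateral channel to the imagined hand desynchronizes
        contra = "C4" if lab == "left" else "C3"
        ipsi = "C3" if lab == "left" else "C4"
        for c, ch in enumerate(channels):
            gain = {contra: g_erd, ipsi: g_ers}.get(ch, g_flat)
            bg = cfg.noise_amp * _pink_noise(rng, n, cfg.noise_exponent)
            mu = cfg.mu_amp[ch] * _band_noise(rng, n, cfg.fs, cfg.mu_band)
            beta = cfg.beta_amp[ch] * _band_noise(rng, n, cfg.fs,
                                                  cfg.beta_band)
            data[i, c] = bg + gain * (mu + beta)
    return TrialSet(data, labels, cfg.fs, channels, tuple(cfg.cue_interval))


def write_trialset(ts: TrialSet, path):
    """Write one delimited matrix (trials x samples) per channel plus a JSON
    metadata sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if ts.n_trials == 0:
        raise ValueError("empty dataset")
    for c, ch in enumerate(ts.channels):
        np.savetxt(path / f"{ch}.csv", ts.data[:, c, :], fmt="%.17e",
                   delimiter=",")
    meta = {"fs": ts.fs, "labels": list(map(str, ts.labels)),
            "channels": list(ts.channels),
            "trial_window": list(ts.trial_window)}
    (path / "trialset.json").write_text(json.dumps(meta, indent=1))


def read_trialset(path) -> TrialSet:
    path = Path(path)
    sidecar = path / "trialset.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    mats = []
    for ch in meta["channels"]:
        f = path / f"{ch}.csv"
        if not f.exists():
            raise FileNotFoundError(f"channel matrix missing for {ch!r}")
        m = np.loadtxt(f, delimiter=",", ndmin=2)
        mats.append(m)
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"channel matrices disagree in shape: {shapes}")
    data = np.stack(mats, axis=1)
    if data.shape[0] == 0:
        raise ValueError("empty dataset")
    return TrialSet(data, np.array(meta["labels"]), float(meta["fs"]),
                    list(meta["channels"]), tuple(meta["trial_window"]))
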