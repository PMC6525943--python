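"""ERD/ERS feature extraction: average power curves, optimal time block,
sliding-window normalized subband energies, and the channel-difference
high-dimensional vectors fed to the manifold embedding.

All internal indices are 0-based half-open [start, stop); an inclusive
sample pair [min, max] supplied as an override is converted at the boundary
(stop = max + 1), so the sequence-length conventions of the energy features
(window of 2*fs samples sliding one sample at a time giving
stop - start - 2*fs + 1 windows) hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import TrialSet
from .dtcwt import decompose_subbands

__all__ = ["PowerSpectrum", "TimeBlock", "EnergyFeature", "HighDimFeature",
           "average_power_spectrum", "select_time_block", "sliding_energy",
           "average_energy_feature", "select_waves", "build_highdim_feature",
           "trial_subbands"]


@dataclass
class PowerSpectrum:
    """Across-trial mean squared amplitude per sample, one channel/class."""

    power: np.ndarray        # (n_samples,), microvolt^2
    channel: str
    class_label: str
    n_trials: int


@dataclass
class TimeBlock:
    """Selected analysis window, 0-based half-open sample indices."""

    start: int
    stop: int
    fs: float

    @property
    def seconds(self):
        return (self.start / self.fs, (self.stop - 1) / self.fs)

    @property
    def n_samples(self):
        return self.stop - self.start

    def slice(self):
        return slice(self.start, self.stop)


@dataclass
class EnergyFeature:
    """Normalized-energy summary of one trial: F1 = [AE_alpha, AE_beta]."""

    ae_alpha: float
    ae_beta: float
    sequences: dict          # (wave, channel) -> normalized energy sequence

    @property
    def f1(self):
        return np.array([self.ae_alpha, self.ae_beta])


@dataclass
class HighDimFeature:
    """C3-minus-C4 subband differences over the time block, per trial."""

    matrix: np.ndarray       # (feature_dim, n_trials), column per trial
    waves: list              # wave tags concatenated, in order

    @property
    def n_trials(self):
        return self.matrix.shape[1]


def average_power_spectrum(ts: TrialSet, channel, class_label) -> PowerSpectrum:
    """Mean over same-class trials of the squared j-th sample, per sample j."""
    if channel not in ts.channels:
        raise ValueError(f"unknown channel {channel!r}")
    mask = ts.labels == class_label
    if not mask.any():
        raise ValueError(f"no trials with label {class_label!r}")
    d = ts.channel(channel)[mask]
    return PowerSpectrum((d ** 2).mean(axis=0), channel, str(class_label),
                         int(mask.sum()))


def _smooth(x, width):
    width = max(int(width), 1)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def select_time_block(ts: TrialSet, *, window_s=4.0, search_interval=None,
                      override=None, smooth_frac=0.25) -> TimeBlock:
    """Choose the analysis window with the strongest class contrast.

    The automated rule slides a window of ``window_s`` seconds over the
    post-cue interval and maximizes the integrated contrast
    ``sum_j |(P_left^C3 - P_left^C4) - (P_right^C3 - P_right^C4)|(j)``
    computed on moving-average-smoothed power curves; ties go to the
    earliest start.  An explicit ``override`` always wins: a pair of floats
    is read as seconds, a pair of ints as inclusive sample indices.
    """
    fs = ts.fs
    n = ts.n_samples
    if override is not None:
        lo, hi = override
        if isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer)):
            start, stop = int(lo), int(hi) + 1
        else:
            start, stop = int(round(lo * fs)), int(round(hi * fs)) + 1
        if not 0 <= start < stop <= n:
            raise ValueError(f"override block [{start}, {stop}) outside "
                             f"signal of {n} samples")
        if stop - start <= 2 * fs:
            raise ValueError("time block must exceed two seconds' worth of "
                             "samples (2*fs) so a sliding window fits")
        return TimeBlock(start, stop, fs)

    w = int(round(window_s * fs))
    if w <= 2 * fs:
        raise ValueError("window_s must exceed 2 s so a sliding window fits")
    if search_interval is None:
        search_interval = (ts.trial_window[0], n / fs)
    s0 = int(round(search_interval[0] * fs))
    s1 = min(n, int(round(search_interval[1] * fs)))
    if s1 - s0 < w:
        raise ValueError("no candidate window of the required length")

    width = max(int(fs * smooth_frac), 1)
    curves = {}
    for ch in ("C3", "C4"):
        for lab in ("left", "right"):
            curves[ch, lab] = _smooth(
                average_power_spectrum(ts, ch, lab).power, width)
    contrast = np.abs((curves["C3", "left"] - curves["C4", "left"])
                      - (curves["C3", "right"] - curves["C4", "right"]))
    csum = np.concatenate([[0.0], np.cumsum(contrast)])
    starts = np.arange(s0, s1 - w + 1)
    scores = csum[starts + w] - csum[starts]
    best = int(starts[np.argmax(scores)])    # argmax ties -> earliest
    return TimeBlock(best, best + w, fs)


def sliding_energy(subband_signals, fs) -> np.ndarray:
    """Normalized sliding-window energies of all subbands of one channel.

    subband_signals: (n_subbands, block_len) array over the time block.
    A window of 2*fs samples slides one sample at a time; each window's
    energies are normalized to sum to 1 across subbands.  Returns an
    (n_subbands, block_len - 2*fs + 1) array.
    """
    S = np.atleast_2d(np.asarray(subband_signals, float))
    win = 2 * int(fs)
    n = S.shape[1]
    if n < win:
        raise ValueError(f"time block ({n} samples) shorter than the "
                         f"sliding window ({win})")
    sq = S ** 2
    csum = np.concatenate([np.zeros((S.shape[0], 1)), np.cumsum(sq, axis=1)],
                          axis=1)
    E = csum[:, win:] - csum[:, :-win]        # (n_subbands, n - win + 1)
    total = E.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        En = np.where(total > 0, E / total, 1.0 / S.shape[0])
    return En


def average_energy_feature(sub_c3, sub_c4, fs, tags) -> EnergyFeature:
    """Average normalized-energy difference C3 - C4 for the alpha and beta
    subbands (the 2-D energy feature F1).

    sub_c3 / sub_c4: (n_subbands, block_len) subband signals over the time
    block; tags: wave tag per subband row.
    """
    for wv in ("alpha", "beta"):
        if wv not in tags:
            raise ValueError(f"no subband tagged {wv!r}")
    e3 = sliding_energy(sub_c3, fs)
    e4 = sliding_energy(sub_c4, fs)
    seqs, ae = {}, {}
    for wv in ("alpha", "beta"):
        i = tags.index(wv)
        seqs[wv, "C3"], seqs[wv, "C4"] = e3[i], e4[i]
        ae[wv] = float(e3[i].mean() - e4[i].mean())
    return EnergyFeature(ae["alpha"], ae["beta"], seqs)


def fisher_ratio(values, labels):
    """Between-class over within-class variance of a scalar feature."""
    values = np.asarray(values, float)
    a = values[labels == "left"]
    b = values[labels == "right"]
    denom = a.var(ddof=1) + b.var(ddof=1)
    if denom == 0:
        return np.inf if a.mean() != b.mean() else 0.0
    return float((a.mean() - b.mean()) ** 2 / denom)


def select_waves(ae_per_band, labels, tags, *, fraction=0.8, override=None):
    """Subject-adaptive subband choice by Fisher ratio of the per-trial
    average-energy difference.

    ae_per_band: (n_subbands, n_trials) array of AE values on training
    trials.  Returns the wave tags whose score reaches ``fraction`` of the
    best score (ties resolved toward lower frequency, i.e. earlier subband).
    ``override`` (list of tags) always wins.
    """
    if override is not None:
        unknown = [wv for wv in override if wv not in tags]
        if unknown:
            raise ValueError(f"override waves {unknown} not among {tags}")
        return list(override), None
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("wave selection needs trials from both classes")
    scores = np.array([fisher_ratio(row, labels) for row in ae_per_band])
    best = scores.max()
    if best == 0:
        return [tags[0]], scores          # non-discriminative; deterministic
    chosen = [tags[i] for i in range(len(tags))
              if scores[i] >= fraction * best]
    return chosen, scores


def build_highdim_feature(subs_c3, subs_c4, tags, waves, block: TimeBlock
                          ) -> HighDimFeature:
    """Per-trial C3-minus-C4 difference vectors of the selected subbands.

    subs_c3 / subs_c4: (n_trials, n_subbands, n_samples) full-length subband
    signals; the block is applied here.  With several selected waves the
    per-wave difference vectors are concatenated.
    """
    if not waves:
        raise ValueError("at least one wave required")
    if block.stop > subs_c3.shape[2]:
        raise ValueError("time block outside signal bounds")
    cols = []
    for wv in waves:
        i = tags.index(wv)
        d = subs_c3[:, i, block.slice()] - subs_c4[:, i, block.slice()]
        cols.append(d)
    return HighDimFeature(np.hstack(cols).T, list(waves))


def trial_subbands(ts: TrialSet, J, fb, channels=("C3", "C4")):
    """Dual-tree subband signals for every trial of the given channels.

    Returns (arrays, tags): arrays maps channel -> (n_trials, J+1, n_samples)
    and tags is the wave tag per subband row.
    """
    arrays = {}
    tags = None
    for ch in channels:
        d = ts.channel(ch)
        out = np.empty((ts.n_trials, J + 1, ts.n_samples))
        for i in range(ts.n_trials):
            ss = decompose_subbands(d[i], J, fb, ts.fs)
            out[i] = ss.signals
            tags = ss.tags
        arrays[ch] = out
    return arrays, tags
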