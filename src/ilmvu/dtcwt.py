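"""1-D dual-tree complex wavelet transform: analysis, synthesis, and
single-subband signal reconstruction.

Two parallel real discrete wavelet transforms are run with periodized
boundary handling; the first tree supplies the real part of each complex
coefficient and the second (offset by one input sample at level 1, time
reversed Q-shift filters afterwards) the imaginary part.  Because each tree
is individually a perfect-reconstruction filter bank, inversion averages the
two trees' reconstructions, and zeroing all but one level before inversion
yields that level's subband signal; the J+1 subband signals sum exactly to
the input.

Inputs whose length is not a multiple of 2**J are extended by symmetric
reflection at the right edge and trimmed after inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .filterbanks import FilterBank

__all__ = ["DtcwtCoefficients", "SubbandSet", "dtcwt_forward", "dtcwt_inverse",
           "reconstruct_subband", "subband_frequency_ranges", "wave_tags",
           "decompose_subbands"]

# canonical EEG wave bands (Hz); gamma is open ended
_WAVES = [("delta", 0.0, 4.0), ("theta", 4.0, 8.0), ("alpha", 8.0, 13.0),
          ("beta", 13.0, 30.0), ("gamma", 30.0, np.inf)]


@dataclass
class DtcwtCoefficients:
    """Complex dual-tree coefficients of a real 1-D signal.

    details[j-1] holds level-j detail coefficients d_j (tree A + i tree B),
    finest level first (j = 1); scaling holds the level-J approximation.
    """

    details: list            # complex arrays, levels 1..J
    scaling: np.ndarray      # complex array, level J
    length: int              # original signal length
    padded_length: int
    J: int

    def zeroed_copy(self, keep):
        """Coefficients with every level except ``keep`` set to zero.

        keep: 'A' (or 'A{J}') for the approximation, 'D{j}' or int j for
        detail level j.
        """
        lev = _parse_selector(keep, self.J)
        details = [d.copy() if (lev == j) else np.zeros_like(d)
                   for j, d in enumerate(self.details, start=1)]
        scaling = (self.scaling.copy() if lev == 0
                   else np.zeros_like(self.scaling))
        return DtcwtCoefficients(details, scaling, self.length,
                                 self.padded_length, self.J)


@dataclass
class SubbandSet:
    """Reconstructed subband signals A_J, Dt_J, ..., Dt_1 of one signal."""

    names: list                      # e.g. ['A4', 'D4', 'D3', 'D2', 'D1']
    signals: np.ndarray              # (J+1, n_samples), same order as names
    frequency_ranges: list           # (lo, hi) Hz per subband
    tags: list                       # canonical wave tag per subband
    fs: float

    def by_tag(self, tag):
        """Signal of the subband carrying the given wave tag."""
        try:
            return self.signals[self.tags.index(tag)]
        except ValueError:
            raise KeyError(f"no subband tagged {tag!r}; tags: {self.tags}")


def _parse_selector(keep, J):
    """0 for the approximation, j for detail level j."""
    if keep is None or (isinstance(keep, str) and not keep.strip()):
        raise ValueError("empty subband selector")
    if isinstance(keep, (int, np.integer)):
        lev = int(keep)
        if not 1 <= lev <= J:
            raise ValueError(f"detail level {lev} outside 1..{J}")
        return lev
    s = str(keep).strip().upper()
    if s in ("A", f"A{J}"):
        return 0
    if s.startswith("D"):
        lev = int(s[1:])
        if not 1 <= lev <= J:
            raise ValueError(f"detail level {lev} outside 1..{J}")
        return lev
    raise ValueError(f"unrecognized subband selector {keep!r}")


def _pad(x, J):
    block = 2 ** J
    n = len(x)
    rem = (-n) % block
    if rem == 0:
        return x
    # symmetric reflection at the right edge (repeat as needed for short x)
    tail = []
    need = rem
    src = x
    while need > 0:
        chunk = src[::-1][:need]
        tail.append(chunk)
        need -= len(chunk)
    return np.concatenate([x] + tail)


def dtcwt_forward(signal, J, fb: FilterBank) -> DtcwtCoefficients:
    """J-level dual-tree analysis of a real 1-D signal."""
    x = np.asarray(signal, float).ravel()
    if J < 1:
        raise ValueError("J must be >= 1")
    if len(x) < max(2 ** J, fb.min_signal_length):
        raise ValueError(
            f"signal of length {len(x)} too short for J={J} with this bank")
    xp = _pad(x, J)
    a_a, a_b = xp, np.roll(xp, 1)
    details = []
    for j in range(1, J + 1):
        wav_a = fb.level1 if j == 1 else fb.tree_a
        wav_b = fb.level1 if j == 1 else fb.tree_b
        a_a, d_a = pywt.dwt(a_a, wav_a, mode="periodization")
        a_b, d_b = pywt.dwt(a_b, wav_b, mode="periodization")
        details.append(d_a + 1j * d_b)
    return DtcwtCoefficients(details, a_a + 1j * a_b, len(x), len(xp), J)


def _inverse_tree(coeffs: DtcwtCoefficients, fb, part):
    take = np.real if part == "a" else np.imag
    a = take(coeffs.scaling).copy()
    for j in range(coeffs.J, 0, -1):
        wav = fb.level1 if j == 1 else (fb.tree_a if part == "a" else fb.tree_b)
        a = pywt.idwt(a, take(coeffs.details[j - 1]), wav, mode="periodization")
    return a if part == "a" else np.roll(a, -1)


def dtcwt_inverse(coeffs: DtcwtCoefficients, fb: FilterBank) -> np.ndarray:
    """Synthesis: average of the two trees' reconstructions."""
    if len(coeffs.details) != coeffs.J:
        raise ValueError("coefficient levels do not match J")
    expect = coeffs.padded_length // 2 ** coeffs.J
    if len(coeffs.scaling) != expect:
        raise ValueError("scaling coefficient length inconsistent with J")
    xa = _inverse_tree(coeffs, fb, "a")
    xb = _inverse_tree(coeffs, fb, "b")
    return (0.5 * (xa + xb))[: coeffs.length]


def reconstruct_subband(coeffs: DtcwtCoefficients, keep, fb: FilterBank):
    """Signal of a single subband (all other levels zeroed before synthesis)."""
    return dtcwt_inverse(coeffs.zeroed_copy(keep), fb)


def subband_frequency_ranges(fs, J):
    """Nominal dyadic band edges (Hz) for A_J, Dt_J, ..., Dt_1."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    if J < 1:
        raise ValueError("J must be >= 1")
    edges = [(0.0, fs / 2 ** (J + 1))]
    for j in range(J, 0, -1):
        edges.append((fs / 2 ** (j + 1), fs / 2 ** j))
    return edges


def wave_tags(fs, J):
    """Canonical wave tag per subband, by greatest frequency overlap."""
    tags = []
    for lo, hi in subband_frequency_ranges(fs, J):
        best, best_ov = None, -1.0
        for name, wlo, whi in _WAVES:
            ov = max(0.0, min(hi, whi) - max(lo, wlo))
            if ov > best_ov:
                best, best_ov = name, ov
        tags.append(best)
    return tags


def decompose_subbands(signal, J, fb: FilterBank, fs) -> SubbandSet:
    """All J+1 subband signals of one signal, with band edges and wave tags."""
    coeffs = dtcwt_forward(signal, J, fb)
    names = [f"A{J}"] + [f"D{j}" for j in range(J, 0, -1)]
    sigs = np.vstack([reconstruct_subband(coeffs, name, fb) for name in names])
    return SubbandSet(names, sigs, subband_frequency_ranges(fs, J),
                      wave_tags(fs, J), float(fs))
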