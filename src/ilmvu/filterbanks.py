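"""Filter-bank catalogue for the 1-D dual-tree complex wavelet transform.

The dual tree needs two kinds of banks:

* a *first-level* biorthogonal bank (odd length, linear phase).  Both trees
  use the same filters at level 1; the imaginary tree is offset by one input
  sample, which at the decimated rate is the required half-sample shift.
* a *Q-shift* orthonormal bank for levels >= 2.  The real tree's scaling
  filter has group delay (L-1)/2 - 1/4; the imaginary tree uses its time
  reverse, whose delay is (L-1)/2 + 1/4, so the two low-pass filters differ
  by approximately half a sample - the property that makes the combined
  complex wavelet nearly analytic and the transform nearly shift invariant.

Antonini (CDF 9/7) and LeGall (CDF 5/3) come from PyWavelets; the
near-symmetric and Q-shift banks are in-house designs shipped as plain-text
resources (see scripts/design_filters.py for the design procedure).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _ir

import numpy as np
import pywt

__all__ = ["FilterBank", "load_filter_bank", "first_level_names",
           "later_level_names", "half_sample_delay_offset"]

_FIRST_LEVEL = {
    "antonini": ("pywt", "bior4.4"),
    "legall": ("pywt", "bior2.2"),
    "near_sym_a": ("resource", "firstlevel_near_sym_a.txt"),
    "near_sym_b": ("resource", "firstlevel_near_sym_b.txt"),
}
_LATER_LEVEL = {
    "qshift_06": "qshift_06.txt",
    "qshift_a": "qshift_a.txt",
    "qshift_b": "qshift_b.txt",
    "qshift_c": "qshift_c.txt",
    "qshift_d": "qshift_d.txt",
}


def first_level_names():
    return ["Antonini", "LeGall", "Near_Sym_a", "Near_Sym_b"]


def later_level_names():
    return ["Qshift_06", "Qshift_a", "Qshift_b", "Qshift_c", "Qshift_d"]


def _read_resource(fname):
    with _ir.files("ilmvu.resources").joinpath(fname).open("r") as fh:
        return np.loadtxt(fh)


def _orthonormal_wavelet(g):
    """pywt Wavelet from an orthonormal scaling filter g (sum sqrt2)."""
    g = np.asarray(g, float)
    n = np.arange(len(g))
    rec_lo = g
    dec_lo = g[::-1]
    rec_hi = ((-1.0) ** n) * g[::-1]
    dec_hi = rec_hi[::-1]
    return pywt.Wavelet("qshift", filter_bank=[dec_lo, dec_hi, rec_lo, rec_hi])


def _trim(f):
    f = np.asarray(f, float)
    nz = np.flatnonzero(f)
    return f[nz[0]: nz[-1] + 1] if nz.size else f[:0]


@dataclass(frozen=True)
class FilterBank:
    """A first-level + Q-shift filter pairing for the dual-tree transform."""

    first_level_name: str
    later_level_name: str
    level1: pywt.Wavelet        # both trees at level 1 (tree B: 1-sample delay)
    tree_a: pywt.Wavelet        # levels >= 2, real tree
    tree_b: pywt.Wavelet        # levels >= 2, imaginary tree (time reverse)
    qshift_lo: np.ndarray       # tree-A scaling filter

    @property
    def first_level_taps(self):
        """(analysis low-pass, analysis high-pass) tap counts."""
        return (_trim(self.level1.dec_lo).size, _trim(self.level1.dec_hi).size)

    @property
    def later_level_taps(self):
        n = self.qshift_lo.size
        return (n, n)

    @property
    def min_signal_length(self):
        return max(len(self.level1.dec_lo), len(self.qshift_lo))


def load_filter_bank(first_level_name="Antonini", later_level_name="Qshift_c"):
    """Build a :class:`FilterBank` from the catalogue names.

    Defaults to Antonini + Qshift_c, the combination used for the
    single-subject motor-imagery benchmark this pipeline targets.
    """
    f_key = str(first_level_name).lower()
    l_key = str(later_level_name).lower()
    if f_key not in _FIRST_LEVEL:
        raise ValueError(
            f"unknown first-level filter bank {first_level_name!r}; "
            f"choose from {first_level_names()}")
    if l_key not in _LATER_LEVEL:
        raise ValueError(
            f"unknown later-level filter bank {later_level_name!r}; "
            f"choose from {later_level_names()}")

    kind, src = _FIRST_LEVEL[f_key]
    if kind == "pywt":
        level1 = pywt.Wavelet(src)
    else:
        cols = _read_resource(src)
        level1 = pywt.Wavelet(f_key, filter_bank=[cols[:, i] for i in range(4)])

    g = _read_resource(_LATER_LEVEL[l_key])
    tree_a = _orthonormal_wavelet(g)
    tree_b = _orthonormal_wavelet(g[::-1])
    return FilterBank(first_level_name, later_level_name,
                      level1, tree_a, tree_b, g)


def half_sample_delay_offset(fb: FilterBank) -> float:
    """Cross-correlation peak offset (samples) between the two trees'
    Q-shift low-pass filters; approximately 0.5 by design."""
    h = fb.qshift_lo
    xc = np.correlate(h, h[::-1], "full")
    i = int(np.argmax(xc))
    num = 0.5 * (xc[i - 1] - xc[i + 1])
    den = xc[i - 1] - 2 * xc[i] + xc[i + 1]
    return abs(i + num / den - (len(h) - 1))
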