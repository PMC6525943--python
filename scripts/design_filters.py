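"""Generate the wavelet filter-bank resource files shipped with ilmvu.

Two filter families are produced:

* First-level biorthogonal banks (odd-length, applied at level 1 of the dual
  tree).  Antonini (CDF 9/7) and LeGall (CDF 5/3) are the classic JPEG2000
  wavelets and are taken from PyWavelets (bior4.4 / bior2.2).  The
  near-symmetric 5,7- and 13,19-tap pairs are designed here by spectral
  factorization of maximum-flat half-band product filters: the half-band
  P(z) = 2 [(1+z)(1+z^-1)/4]^K R(y), y = (2-z-z^-1)/4, is split into two
  symmetric low-pass factors by assigning its zeros at z=-1 and the
  reciprocal root groups of R to the two filters at the catalogued tap
  counts.  Perfect reconstruction is verified through PyWavelets before the
  coefficients are written.

* Q-shift orthonormal banks (even-length, levels >= 2).  Each scaling filter
  is parametrized by a two-channel paraunitary lattice (rotation angles), so
  orthonormality - and hence perfect reconstruction - holds exactly by
  construction.  The angles are optimized for (a) approximately linear
  passband phase with group delay (L-1)/2 - 1/4 (the quarter-sample shift
  that makes the two trees' low-pass filters differ by half a sample), and
  (b) stopband attenuation, subject to one vanishing moment.  The per-bank
  seeds and objective weights below are the frozen design choices.

Run from the repository root:  python scripts/design_filters.py
The output files under src/ilmvu/resources/ are committed; re-running is
only needed if the designs change.
"""

import itertools
from math import comb
from pathlib import Path

import numpy as np
import pywt
from scipy.optimize import minimize

RES = Path(__file__).resolve().parent.parent / "src" / "ilmvu" / "resources"


# ----------------------------------------------------------------------
# Q-shift design: paraunitary lattice
# ----------------------------------------------------------------------

def lattice_filters(thetas):
    """Low/high-pass orthonormal pair from lattice rotation angles."""
    c, s = np.cos(thetas[0]), np.sin(thetas[0])
    E = [[np.array([c]), np.array([s])], [np.array([-s]), np.array([c])]]
    for th in thetas[1:]:
        E[1][0] = np.concatenate([[0.0], E[1][0]])
        E[1][1] = np.concatenate([[0.0], E[1][1]])
        L = len(E[1][0])
        E[0][0] = np.concatenate([E[0][0], np.zeros(L - len(E[0][0]))])
        E[0][1] = np.concatenate([E[0][1], np.zeros(L - len(E[0][1]))])
        c, s = np.cos(th), np.sin(th)
        E = [[c * E[0][0] - s * E[1][0], c * E[0][1] - s * E[1][1]],
             [s * E[0][0] + c * E[1][0], s * E[0][1] + c * E[1][1]]]
    deg = len(E[0][0])
    h0 = np.zeros(2 * deg)
    h0[0::2], h0[1::2] = E[0][0], E[0][1]
    h1 = np.zeros(2 * deg)
    h1[0::2], h1[1::2] = E[1][0], E[1][1]
    return h0, h1


def _freqz(h, w):
    n = np.arange(len(h))
    return (h[None, :] * np.exp(-1j * np.outer(w, n))).sum(1)


def design_qshift(L, seed, wd, ws, trials, n_pass=0.40, n_stop=0.60):
    K = L // 2
    tau = (L - 1) / 2 - 0.25
    wpass = np.linspace(0, n_pass * np.pi, 50)
    wstop = np.linspace(n_stop * np.pi, np.pi, 80)

    def obj(th):
        h0, _ = lattice_filters(th)
        Hp = _freqz(h0, wpass)
        phase_err = np.imag(Hp * np.exp(1j * tau * wpass))
        mag_err = np.abs(Hp) - np.sqrt(2)
        stop = np.abs(_freqz(h0, wstop))
        return (wd * (phase_err ** 2).sum() + 0.2 * (mag_err ** 2).sum()
                + ws * (stop ** 2).sum())

    def con(th):
        h0, h1 = lattice_filters(th)
        n = np.arange(L)
        return np.array([h1.sum(), (((-1.0) ** n) * (n - tau) * h0).sum()])

    best = None
    rng = np.random.default_rng(seed)
    for _ in range(trials):
        x0 = rng.uniform(-np.pi, np.pi, K)
        res = minimize(obj, x0, constraints=[{"type": "eq", "fun": con}],
                       method="SLSQP", options={"maxiter": 800, "ftol": 1e-15})
        if not res.success:
            continue
        h0, _ = lattice_filters(res.x)
        if h0.sum() < 0:
            continue
        if best is None or res.fun < best[0]:
            best = (res.fun, h0)
    return best[1]


# frozen per-bank design choices: length, rng seed, phase weight, stop weight,
# number of multistarts
QSHIFT_SPECS = {
    "qshift_06": (10, 11, 2.0, 2.0, 15),
    "qshift_a": (10, 23, 4.0, 2.0, 12),
    "qshift_b": (14, 31, 2.0, 1.0, 15),
    "qshift_c": (16, 41, 2.0, 4.0, 15),
    "qshift_d": (18, 51, 2.0, 4.0, 15),
}


# ----------------------------------------------------------------------
# Near-symmetric biorthogonal design: half-band factorization
# ----------------------------------------------------------------------

def _r_yroots(K):
    coeffs = [float(comb(K - 1 + j, j)) for j in range(K)]
    return np.roots(coeffs[::-1])


def _z_pair(y):
    b = 2 - 4 * y
    disc = np.sqrt(complex(b * b - 4))
    z1, z2 = (b + disc) / 2, (b - disc) / 2
    return (z1, z2) if abs(z1) <= abs(z2) else (z2, z1)


def _poly(roots):
    p = np.array([1.0 + 0j])
    for r in roots:
        p = np.convolve(p, [1.0, -r])
    assert np.abs(p.imag).max() < 1e-9
    return p.real


def build_biorth_pair(K, n_pi_h, picks):
    """Split the maxflat half-band of order K into two low-pass factors.

    picks assigns each reciprocal root group of the remainder R(y) to the
    analysis filter ('in'/'out' = the group's inside/outside-circle half,
    'both' = whole group, 'none' = all to the synthesis filter).
    """
    yr = _r_yroots(K)
    units, used = [], np.zeros(len(yr), bool)
    for i, y in enumerate(yr):
        if used[i]:
            continue
        if abs(y.imag) < 1e-9:
            units.append(("real", y.real))
            used[i] = True
        else:
            j = int(np.argmin(np.abs(yr - np.conj(y))))
            used[i] = used[j] = True
            units.append(("cplx", y))
    h_roots, g_roots = [], []
    for (kind, y), pick in zip(units, picks):
        zi, zo = _z_pair(y)
        if kind == "real":
            inside, outside = (zi,), (zo,)
        else:
            zi2, zo2 = _z_pair(np.conj(y))
            inside, outside = (zi, zi2), (zo, zo2)
        if pick == "in":
            h_roots += list(inside); g_roots += list(outside)
        elif pick == "out":
            h_roots += list(outside); g_roots += list(inside)
        elif pick == "both":
            h_roots += list(inside) + list(outside)
        else:
            g_roots += list(inside) + list(outside)
    h0, g0 = _poly(h_roots), _poly(g_roots)
    for _ in range(n_pi_h):
        h0 = np.convolve(h0, [1.0, 1.0])
    for _ in range(2 * K - n_pi_h):
        g0 = np.convolve(g0, [1.0, 1.0])
    return h0 * np.sqrt(2) / h0.sum(), g0 * np.sqrt(2) / g0.sum()


def align_bank(h0, g0, max_pad=6):
    """Zero-pad (h0, g0) into a pywt filter bank with perfect reconstruction.

    The relative alignment of the analysis/synthesis low-pass filters inside
    pywt's even-length convention is a pure bookkeeping choice; it is found
    by searching small pad offsets and checking reconstruction error.
    """
    rng = np.random.default_rng(0)
    x = rng.standard_normal(256)
    best = None
    for pad_h, pad_g in itertools.product(range(max_pad), repeat=2):
        dl = np.concatenate([np.zeros(pad_h), h0])
        rl = np.concatenate([np.zeros(pad_g), g0])
        L = max(len(dl), len(rl))
        L += L % 2
        dl = np.concatenate([dl, np.zeros(L - len(dl))])
        rl = np.concatenate([rl, np.zeros(L - len(rl))])
        n = np.arange(L)
        rh = ((-1.0) ** n) * dl
        dh = -((-1.0) ** n) * rl
        try:
            w = pywt.Wavelet("c", filter_bank=[dl, dh, rl, rh])
            xr = pywt.waverec(pywt.wavedec(x, w, mode="periodization", level=3),
                              w, mode="periodization")
            err = float(np.abs(xr - x).max())
        except Exception:
            continue
        if best is None or err < best[0]:
            best = (err, [dl, dh, rl, rh])
    assert best is not None and best[0] < 1e-9, f"no PR alignment found ({best})"
    return best[1]


def main():
    RES.mkdir(parents=True, exist_ok=True)

    # first-level banks
    banks = {
        "antonini": pywt.Wavelet("bior4.4").filter_bank,   # CDF 9/7
        "legall": pywt.Wavelet("bior2.2").filter_bank,     # CDF 5/3
        "near_sym_a": align_bank(*build_biorth_pair(3, 4, ["none"])),
        "near_sym_b": align_bank(*build_biorth_pair(8, 6, ["both", "none",
                                                           "both", "none"])),
    }
    for name, fb in banks.items():
        fb = [np.asarray(f, float) for f in fb]
        cols = np.column_stack(fb)
        hdr = ("first-level biorthogonal bank: columns dec_lo dec_hi rec_lo "
               "rec_hi (pywt convention, zero-padded)")
        np.savetxt(RES / f"firstlevel_{name}.txt", cols, fmt="%+.17e",
                   header=hdr)
        dl, rl = fb[0], fb[2]
        taps = (np.flatnonzero(dl).size, np.flatnonzero(rl).size)
        print(f"{name}: {taps[0]},{taps[1]}-tap pair written")

    # q-shift banks
    for name, (L, seed, wd, ws, trials) in QSHIFT_SPECS.items():
        h0 = design_qshift(L, seed, wd, ws, trials)
        err = max(abs(np.dot(h0[: L - 2 * k], h0[2 * k:]))
                  for k in range(1, L // 2))
        assert err < 1e-12, err
        hdr = ("q-shift orthonormal scaling filter (tree A; tree B is the "
               "time reverse)")
        np.savetxt(RES / f"{name}.txt", h0, fmt="%+.17e", header=hdr)
        print(f"{name}: {L}-tap scaling filter written (orth err {err:.1e})")


if __name__ == "__main__":
    main()
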