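"""Log-barrier interior-point solver for small linear semidefinite programs.

Solves problems of the form

    maximize    <C, M>
    subject to  v_p^T M v_p <= b_p   (p = 1..P)
                M  symmetric positive semidefinite (q x q)

by path following on the standard logarithmic barrier

    f_t(M) = -t <C, M> - log det M - sum_p log(b_p - v_p^T M v_p),

with damped Newton steps taken in the full vec(M) coordinates (the Newton
direction is automatically symmetric because the Hessian preserves the
symmetric subspace).  Iterates are strictly feasible throughout, so the
returned solution satisfies every inequality with nonnegative slack and is
positive definite up to the barrier's analytic-center offset, which shrinks
as 1/t.

This is deliberately a dense, deterministic solver for desk-scale problems
(q up to a few tens); each Newton step costs O(q^6 + P q^4) at worst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve


class SdpError(RuntimeError):
    """Raised when the interior-point iteration cannot make progress."""


@dataclass
class SdpResult:
    M: np.ndarray          # optimal matrix (q x q, symmetric PSD)
    objective: float       # <C, M>
    gap: float             # barrier duality-gap bound at termination
    newton_steps: int
    max_slack_violation: float  # most negative slack (>= 0 means feasible)


def solve_psd_max(C, V_rows, b, tol=1e-8, mu=10.0, max_newton=600):
    """Maximize <C, M> over PSD M subject to v_p^T M v_p <= b_p.

    Parameters
    ----------
    C : (q, q) symmetric objective matrix.
    V_rows : (P, q) array; row p gives the constraint vector v_p.
    b : (P,) positive right-hand sides.
    tol : relative duality-gap target.
    """
    C = np.asarray(C, float)
    V_rows = np.atleast_2d(np.asarray(V_rows, float))
    b = np.asarray(b, float)
    q = C.shape[0]
    if q == 0:
        return SdpResult(np.zeros((0, 0)), 0.0, 0.0, 0, 0.0)
    P = len(b)
    if P == 0:
        raise SdpError("unconstrained maximization is unbounded")
    if np.any(b <= 0):
        raise SdpError("right-hand sides must be strictly positive")

    # scale distances to O(1); M scales linearly with b
    bscale = float(b.max())
    b = b / bscale

    A = np.einsum("pi,pj->pij", V_rows, V_rows).reshape(P, q * q)
    c = C.reshape(-1)
    cnorm = max(np.linalg.norm(c), 1e-300)

    aii = np.einsum("pi,pi->p", V_rows, V_rows)
    if np.any(aii <= 0):
        raise SdpError("zero constraint vector")
    M = np.eye(q) * (0.5 * float(np.min(b / aii)))

    nu = q + P
    t = max(1.0, nu / cnorm)
    steps = 0
    stalled = False
    while True:
        for _ in range(100):
            if steps >= max_newton:
                stalled = True
                break
            Mi = np.linalg.inv(M)
            s = b - A @ M.reshape(-1)
            g = -t * c - Mi.reshape(-1) + A.T @ (1.0 / s)
            H = np.kron(Mi, Mi) + (A.T * (1.0 / s ** 2)) @ A
            d = None
            hdiag = np.abs(np.diag(H)).max()
            for damp in (0.0, 1e-12, 1e-9, 1e-6):
                try:
                    cf = cho_factor(H + damp * hdiag * np.eye(q * q),
                                    lower=True)
                    d = cho_solve(cf, -g)
                    break
                except np.linalg.LinAlgError:
                    continue
            if d is None or not np.isfinite(d).all():
                stalled = True   # Newton system at machine precision
                break
            D = d.reshape(q, q)
            D = 0.5 * (D + D.T)
            lam2 = float(-g @ d)
            steps += 1
            if lam2 <= 0:
                break
            f0 = (-t * (c @ M.reshape(-1))
                  - np.linalg.slogdet(M)[1] - np.log(s).sum())
            alpha, accepted = 1.0, False
            while alpha > 1e-13:
                Mn = M + alpha * D
                sn = b - A @ Mn.reshape(-1)
                if (sn > 0).all():
                    try:
                        np.linalg.cholesky(Mn)
                    except np.linalg.LinAlgError:
                        alpha *= 0.5
                        continue
                    fn = (-t * (c @ Mn.reshape(-1))
                          - np.linalg.slogdet(Mn)[1] - np.log(sn).sum())
                    if fn <= f0 - 0.25 * alpha * lam2:
                        accepted = True
                        break
                alpha *= 0.5
            if not accepted:
                break  # at numerical precision for this t
            M = M + alpha * D
            if lam2 / 2 < 1e-11:
                break
        obj = float(c @ M.reshape(-1))
        if nu / t < tol * max(1.0, abs(obj)):
            break
        if stalled:
            # accept a stall only once the gap bound is already small
            if nu / t < 1e-4 * max(1.0, abs(obj)):
                break
            raise SdpError(
                f"interior-point iteration stalled at duality gap "
                f"{nu / t:.2e} (objective {obj:.3e}, {steps} Newton steps)")
        t *= mu

    M = 0.5 * (M + M.T) * bscale
    slack = (b * bscale) - A @ (M.reshape(-1))
    return SdpResult(M, float(c @ M.reshape(-1)), nu / t * bscale,
                     steps, float(slack.min()))
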