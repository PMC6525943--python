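"""Landmark maximum variance unfolding (L-MVU).

Training proceeds in five steps: (1) locally linear reconstruction weights W
over each sample's r nearest neighbors; (2) the landmark transform Q built
from Lambda = (I - W)^T (I - W), whose non-landmark block minimizes the
reconstruction functional tr(Y Lambda Y^T) given the landmark embeddings;
(3) a semidefinite program over the m x m landmark kernel L that maximizes
the unfolded variance trace(Q L Q^T) subject to local isometry constraints
on k-nearest-neighbor pairs and global centering; (4) eigendecomposition of
L giving landmark coordinates sqrt(lambda_k) v_k; (5) propagation of all
samples through Q.

The centering constraint sum_ij (Q L Q^T)_ij = 0 forces q = Q^T 1 into the
null space of any feasible PSD kernel, so the SDP is solved over the
subspace orthogonal to q (and to any zero-distance constraint directions),
where a strictly feasible interior exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._sdp import SdpError, solve_psd_max

__all__ = ["MvuParams", "EmbeddingModel", "knn_graph", "reconstruction_weights",
           "landmark_transform", "solve_landmark_sdp", "embed_landmarks",
           "embed_all", "fit_lmvu"]

#: ridge regularization scale for near-singular local Gram systems
RIDGE = 1e-3
#: conditioning threshold beyond which the ridge is applied
COND_MAX = 1e10


@dataclass
class MvuParams:
    """Free parameters of the embedding.

    r : neighbors for the locally linear reconstruction weights.
    m : number of landmarks (the SDP size).
    d : target (intrinsic) dimension.
    k : neighbors generating SDP distance constraints.

    Defaults follow the reference motor-imagery configuration; ``clamped``
    shrinks them to legal values for a dataset of n samples.
    """

    r: int = 52
    m: int = 14
    d: int = 5
    k: int = 24

    def clamped(self, n):
        r = min(self.r, n - 1)
        k = min(self.k, n - 1)
        m = min(self.m, n)
        d = min(self.d, m - 1) if m > 1 else 1
        return MvuParams(r=r, m=m, d=d, k=k)

    def validate(self, n):
        if not 1 <= self.r < n:
            raise ValueError(f"need 1 <= r < n (r={self.r}, n={n})")
        if not 1 <= self.k < n:
            raise ValueError(f"need 1 <= k < n (k={self.k}, n={n})")
        if not self.d < self.m <= n:
            raise ValueError(f"need d < m <= n (d={self.d}, m={self.m}, n={n})")


@dataclass
class EmbeddingModel:
    """Fitted L-MVU model; X and Y are retained for the incremental
    out-of-sample mapping."""

    X: np.ndarray                  # (D, n) training samples, column-major
    W: np.ndarray                  # (n, n) reconstruction weights
    Q: np.ndarray                  # (n, m) landmark transform
    L: np.ndarray                  # (m, m) landmark kernel
    eigenvalues: np.ndarray        # all eigenvalues of L, descending
    eigenvectors: np.ndarray       # (m, m), columns matching eigenvalues
    Y: np.ndarray                  # (d, n) embedding
    params: MvuParams
    landmarks: np.ndarray          # indices of the landmark samples
    sdp_info: dict = field(default_factory=dict)

    @property
    def n_samples(self):
        return self.X.shape[1]

    @property
    def landmark_embedding(self):
        return self.Y[:, self.landmarks]


def _pairwise_sq(X):
    G = X.T @ X
    sq = np.diag(G)
    return np.maximum(sq[:, None] - 2 * G + sq[None, :], 0.0)


def _neighbor_order(d2_row, i):
    """Indices sorted by distance then index; the sample itself excluded."""
    keys = d2_row.copy()
    keys[i] = np.inf
    return np.argsort(keys, kind="stable")


def knn_graph(X, k):
    """Symmetrized (union) k-nearest-neighbor indicator matrix.

    eta[i, j] is True iff j is among i's k nearest by Euclidean distance or
    vice versa; distance ties break toward the smaller index; the diagonal
    is False.
    """
    X = np.asarray(X, float)
    n = X.shape[1]
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n (k={k}, n={n})")
    d2 = _pairwise_sq(X)
    eta = np.zeros((n, n), bool)
    for i in range(n):
        eta[i, _neighbor_order(d2[i], i)[:k]] = True
    return eta | eta.T


def _solve_local_weights(xi, neighbors):
    """Sum-to-one least-squares reconstruction of xi from neighbor columns."""
    diff = neighbors - xi[:, None]          # (D, r)
    G = diff.T @ diff
    r = G.shape[0]
    # an (effectively) coincident neighbor is the exact zero-residual
    # minimizer; the ridge below would smear weight off it
    dd = np.diag(G)
    if dd.min() <= 1e-14 * max(dd.max(), 1e-300):
        w = np.zeros(r)
        w[int(np.argmin(dd))] = 1.0
        return w
    # ridge when the local Gram is (near-)singular, e.g. r > local rank
    tr = np.trace(G)
    eigbound = np.linalg.norm(G, 2) if r > 1 else G[0, 0]
    smallest = np.linalg.eigvalsh(G)[0] if r > 1 else G[0, 0]
    if smallest <= 0 or (eigbound / max(smallest, 1e-300)) > COND_MAX:
        G = G + np.eye(r) * (RIDGE * (tr / r) if tr > 0 else RIDGE)
    w = np.linalg.solve(G, np.ones(r))
    return w / w.sum()


def reconstruction_weights(X, r):
    """Row-stochastic locally linear reconstruction weights (n x n).

    Row i solves min ||x_i - sum_j W_ij x_j||^2 over its r nearest neighbors
    with sum_j W_ij = 1; all other entries are exactly zero.
    """
    X = np.asarray(X, float)
    n = X.shape[1]
    if not 1 <= r < n:
        raise ValueError(f"need 1 <= r < n (r={r}, n={n})")
    d2 = _pairwise_sq(X)
    W = np.zeros((n, n))
    for i in range(n):
        nb = _neighbor_order(d2[i], i)[:r]
        W[i, nb] = _solve_local_weights(X[:, i], X[:, nb])
    return W


def landmark_transform(W, m, landmark_indices=None):
    """Linear transform Q (n x m) from landmark embeddings to all samples.

    Landmark rows of Q form the identity; the remaining rows minimize the
    reconstruction functional over the Lambda = (I-W)^T (I-W) partition,
    i.e. Q_rest = -Lambda_22^{-1} Lambda_21 in the ordering [landmarks,
    rest].  Defaults to the first m samples as landmarks.
    """
    W = np.asarray(W, float)
    n = W.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m <= n (m={m}, n={n})")
    if landmark_indices is None:
        landmark_indices = np.arange(m)
    lm = np.asarray(landmark_indices, int)
    if len(lm) != m or len(np.unique(lm)) != m:
        raise ValueError("landmark_indices must hold m distinct indices")
    rest = np.setdiff1d(np.arange(n), lm)
    IW = np.eye(n) - W
    Lam = IW.T @ IW
    Q = np.zeros((n, m))
    Q[lm, np.arange(m)] = 1.0
    if rest.size:
        L22 = Lam[np.ix_(rest, rest)]
        L21 = Lam[np.ix_(rest, lm)]
        try:
            cond = np.linalg.cond(L22)
        except np.linalg.LinAlgError:
            cond = np.inf
        if not np.isfinite(cond) or cond > COND_MAX:
            warnings.warn("non-landmark block ill-conditioned; applying "
                          "ridge regularization", RuntimeWarning)
            L22 = L22 + np.eye(rest.size) * (RIDGE * np.trace(L22) / rest.size)
        Q[rest] = -np.linalg.solve(L22, L21)
    return Q


def _null_basis(m, null_vectors):
    """Orthonormal basis of the subspace orthogonal to the given vectors."""
    N = np.array(null_vectors).reshape(len(null_vectors), m)
    U, s, Vt = np.linalg.svd(N, full_matrices=True)
    rank = int((s > max(m, len(null_vectors)) * np.finfo(float).eps
                * (s[0] if s.size else 0)).sum())
    return Vt[rank:].T                      # (m, m - rank)


def solve_landmark_sdp(X, Q, eta, tol=1e-8):
    """Landmark kernel L maximizing trace(Q L Q^T).

    Constraints: for every neighbor pair (eta[i, j]), the embedded squared
    distance (Q L Q^T)_ii - 2 (Q L Q^T)_ij + (Q L Q^T)_jj may not exceed the
    input squared distance; the total sum of Q L Q^T is zero; L is PSD.
    Returns (L, info) where info reports solver diagnostics.  Raises
    :class:`~ilmvu._sdp.SdpError` if the interior-point method fails.
    """
    X = np.asarray(X, float)
    Q = np.asarray(Q, float)
    n, m = Q.shape
    d2 = _pairwise_sq(X)
    iu, ju = np.where(np.triu(eta, 1))
    if iu.size == 0:
        raise ValueError("neighbor graph has no edges")
    U = Q[iu] - Q[ju]                       # (P, m) constraint directions
    b = d2[iu, ju]

    scale = float(d2.max())
    null_vecs = [Q.sum(axis=0)]             # centering: q^T L q = 0
    zero_mask = b <= 1e-12 * max(scale, 1.0)
    for v in U[zero_mask]:
        null_vecs.append(v)                 # duplicate points: u^T L u = 0
    V = _null_basis(m, null_vecs)
    if V.shape[1] == 0:
        info = {"objective": 0.0, "gap": 0.0, "newton_steps": 0,
                "min_slack": 0.0, "reduced_dim": 0}
        return np.zeros((m, m)), info

    QV = Q @ V
    C = QV.T @ QV
    rows = U[~zero_mask] @ V
    keep = np.einsum("pi,pi->p", rows, rows) > 0
    res = solve_psd_max(C, rows[keep], b[~zero_mask][keep], tol=tol)
    L = V @ res.M @ V.T
    L = 0.5 * (L + L.T)
    K = Q @ L @ Q.T
    kdiag = np.diag(K)
    emb_d2 = kdiag[iu] - 2 * K[iu, ju] + kdiag[ju]
    info = {
        "objective": float(np.trace(K)),
        "gap": res.gap,
        "newton_steps": res.newton_steps,
        "min_slack": res.max_slack_violation,
        "max_violation": float((emb_d2 - b).max()),
        "centering": float(abs(K.sum())),
        "reduced_dim": V.shape[1],
        "n_constraints": int(iu.size),
    }
    return L, info


def embed_landmarks(L, d, tol=1e-6):
    """Landmark coordinates sqrt(lambda_k) v_k for the d largest eigenpairs.

    Eigenvalues are sorted descending; each eigenvector's sign is fixed so
    its largest-magnitude component is positive (first such index on ties).
    Raises if L has an eigenvalue below -tol * max(|lambda|).
    """
    L = np.asarray(L, float)
    m = L.shape[0]
    if not 1 <= d <= m:
        raise ValueError(f"need 1 <= d <= m (d={d}, m={m})")
    w, V = np.linalg.eigh(0.5 * (L + L.T))
    w, V = w[::-1], V[:, ::-1]
    lead = max(abs(w[0]), 1.0) if w.size else 1.0
    if w.size and w[-1] < -tol * lead:
        raise ValueError(f"kernel not PSD (min eigenvalue {w[-1]:.3e})")
    w = np.maximum(w, 0.0)
    for j in range(m):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    Ylm = (np.sqrt(w[:d])[:, None]) * V[:, :d].T
    return Ylm, w, V


def embed_all(Q, landmark_embedding):
    """Embed every sample: Y = Y_landmarks Q^T (d x n)."""
    Q = np.asarray(Q, float)
    Ylm = np.asarray(landmark_embedding, float)
    if Ylm.shape[1] != Q.shape[1]:
        raise ValueError("landmark embedding and Q are not conformable")
    return Ylm @ Q.T


def fit_lmvu(X, params: MvuParams = None, landmark_indices=None,
             sdp_tol=1e-9) -> EmbeddingModel:
    """Run the full L-MVU chain on the columns of X (D x n)."""
    X = np.asarray(X, float)
    n = X.shape[1]
    params = (params or MvuParams()).clamped(n)
    params.validate(n)
    W = reconstruction_weights(X, params.r)
    Q = landmark_transform(W, params.m, landmark_indices)
    if landmark_indices is None:
        landmark_indices = np.arange(params.m)
    eta = knn_graph(X, params.k)
    L, info = solve_landmark_sdp(X, Q, eta, tol=sdp_tol)
    Ylm, w, V = embed_landmarks(L, params.d)
    Y = embed_all(Q, Ylm)
    return EmbeddingModel(X=X, W=W, Q=Q, L=L, eigenvalues=w, eigenvectors=V,
                          Y=Y, params=params,
                          landmarks=np.asarray(landmark_indices, int),
                          sdp_info=info)
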