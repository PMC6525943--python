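"""Landmark-MVU core: neighbor graphs, reconstruction weights, the landmark
transform, the kernel SDP, and the eigen-embedding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from ilmvu import (MvuParams, embed_all, embed_landmarks, fit_lmvu,
                   knn_graph, landmark_transform, reconstruction_weights,
                   solve_landmark_sdp)
from ilmvu._sdp import SdpError, solve_psd_max
from ilmvu.mvu import _pairwise_sq

from conftest import curled_arc, procrustes_residual


# ------------------------------------------------------------- knn graph

def test_collinear_points_k1():
    X = np.array([[0.0, 1.0, 4.0]])
    eta = knn_graph(X, 1)
    assert eta[1, 0] and eta[0, 1]          # middle linked to nearer endpoint
    assert eta[2, 1] and eta[1, 2]          # symmetrization links far endpoint
    assert not eta[0, 2]
    assert not eta.diagonal().any()


def test_complete_graph_when_k_is_n_minus_1(rng):
    X = rng.standard_normal((3, 7))
    eta = knn_graph(X, 6)
    assert eta.sum() == 7 * 6


def test_knn_matches_brute_force(rng):
    X = rng.standard_normal((4, 20))
    k = 5
    eta = knn_graph(X, k)
    d2 = ((X[:, :, None] - X[:, None, :]) ** 2).sum(0)
    expect = np.zeros((20, 20), bool)
    for i in range(20):
        order = sorted(j for j in range(20) if j != i)
        order.sort(key=lambda j: d2[i, j])
        for j in order[:k]:
            expect[i, j] = expect[j, i] = True
    assert np.array_equal(eta, expect)


def test_k_out_of_range(rng):
    with pytest.raises(ValueError):
        knn_graph(rng.standard_normal((2, 5)), 5)


# ----------------------------------------------------- reconstruction weights

def test_barycentric_weights_on_line():
    X = np.array([[1.0, 2.0, 4.0]])
    W = reconstruction_weights(X, 2)
    # x=2 reconstructed from neighbors {1, 4}: weights (2/3, 1/3) up to the
    # ridge applied to the rank-deficient 1-D local Gram
    assert abs(W[1, 0] - 2 / 3) < 2e-3 and abs(W[1, 2] - 1 / 3) < 2e-3
    assert abs(X @ W[1] - 2.0) < 1e-3
    assert np.allclose(W.sum(axis=1), 1.0, atol=1e-10)


def test_duplicate_neighbor_attracts_weight():
    X = np.array([[1.0, 2.0, 2.0, 5.0]])
    W = reconstruction_weights(X, 2)
    assert W[1, 2] > 0.99                  # duplicate of x_1 dominates
    recon = X @ W[1]
    assert abs(recon - 2.0) < 1e-3


@settings(derandomize=True, max_examples=15, deadline=None)
@given(seed=st.integers(0, 10 ** 6))
def test_weight_rows_are_stochastic(seed):
    X = np.random.default_rng(seed).standard_normal((6, 15))
    W = reconstruction_weights(X, 4)
    assert np.allclose(W.sum(axis=1), 1.0, atol=1e-10)
    for i in range(15):
        assert (W[i] != 0).sum() <= 4


def lagrange_weights(xi, nb):
    """Brute-force sum-to-one least squares via the bordered KKT system."""
    r = nb.shape[1]
    G = nb.T @ nb
    K = np.zeros((r + 1, r + 1))
    K[:r, :r] = 2 * G
    K[:r, r] = 1
    K[r, :r] = 1
    rhs = np.concatenate([2 * nb.T @ xi, [1.0]])
    sol = np.linalg.solve(K, rhs)
    return sol[:r]


def test_weights_match_brute_force_constrained_solver(rng):
    """50 random instances: the local Gram solve equals an independent
    Lagrange-elimination solution to 1e-8."""
    for _ in range(50):
        X = rng.standard_normal((15, 30))
        W = reconstruction_weights(X, 5)
        d2 = _pairwise_sq(X)
        i = int(rng.integers(30))
        nb = np.argsort(np.where(np.arange(30) == i, np.inf, d2[i]),
                        kind="stable")[:5]
        expect = lagrange_weights(X[:, i], X[:, nb])
        assert np.abs(W[i, nb] - expect).max() < 1e-8
        err_pkg = np.linalg.norm(X[:, i] - X[:, nb] @ W[i, nb])
        err_ora = np.linalg.norm(X[:, i] - X[:, nb] @ expect)
        assert abs(err_pkg - err_ora) < 1e-8


# --------------------------------------------------------- landmark transform

def test_all_samples_landmarks_gives_identity(rng):
    W = reconstruction_weights(rng.standard_normal((3, 8)), 3)
    assert np.array_equal(landmark_transform(W, 8), np.eye(8))


def test_landmark_rows_are_identity(rng):
    W = reconstruction_weights(rng.standard_normal((3, 9)), 3)
    Q = landmark_transform(W, 4)
    assert np.array_equal(Q[:4], np.eye(4))


def test_landmark_transform_minimizes_reconstruction(rng):
    """The non-landmark block is the unconstrained minimizer of
    tr(Q^T Lambda Q): perturbing it only increases the functional."""
    W = reconstruction_weights(rng.standard_normal((3, 10)), 3)
    IW = np.eye(10) - W
    Lam = IW.T @ IW
    Q = landmark_transform(W, 4)
    base = np.trace(Q.T @ Lam @ Q)
    for _ in range(5):
        Qp = Q.copy()
        Qp[4:] += 1e-3 * rng.standard_normal(Qp[4:].shape)
        assert np.trace(Qp.T @ Lam @ Qp) >= base - 1e-12


# ------------------------------------------------------------------- SDP

def test_sdp_identical_points_give_zero_kernel():
    X = np.ones((3, 6))
    W = reconstruction_weights(X, 2)
    Q = landmark_transform(W, 6)
    eta = np.ones((6, 6), bool) ^ np.eye(6, dtype=bool)
    L, info = solve_landmark_sdp(X, Q, eta)
    assert np.abs(L).max() == 0
    assert info["reduced_dim"] == 0


def test_sdp_solver_rejects_nonpositive_rhs():
    with pytest.raises(SdpError):
        solve_psd_max(np.eye(2), np.eye(2), np.array([1.0, -1.0]))


def test_sdp_solver_simple_box():
    """max tr(M) s.t. e_i^T M e_i <= 1 has optimum M = I."""
    q = 4
    res = solve_psd_max(np.eye(q), np.eye(q), np.ones(q))
    assert np.abs(res.M - np.eye(q)).max() < 1e-4
    assert res.max_slack_violation >= -1e-12


def test_arc_unfolds_to_line_full_mvu():
    """10 points on a tightly curled arc with every point a landmark: the
    kernel is essentially rank one and neighbor distances are preserved."""
    X, s = curled_arc(10, angle=1.5 * np.pi)
    model = fit_lmvu(X, MvuParams(r=2, m=10, d=2, k=2))
    w = model.eigenvalues
    assert w[1] / w[0] < 0.05
    assert info_feasible(model, X)


def info_feasible(model, X, rel=1e-5):
    d2max = _pairwise_sq(X).max()
    info = model.sdp_info
    return (info["max_violation"] <= rel * d2max
            and info["centering"] <= 1e-5 * max(1.0, d2max))


def test_arc_with_landmarks_never_stretches_neighbor_distances():
    """m=5 landmark solve: the distance inequality is one sided, so every
    embedded neighbor distance is preserved or shrunk - never stretched -
    and most are preserved nearly exactly.  (Some chords shrink by tens of
    percent: the kernel is confined to the landmark transform's span.)"""
    X, s = curled_arc(10, angle=1.5 * np.pi)
    perm = np.random.default_rng(1).permutation(10)
    X = X[:, perm]
    model = fit_lmvu(X, MvuParams(r=3, m=5, d=2, k=2))
    d2 = _pairwise_sq(X)
    e2 = _pairwise_sq(model.Y)
    eta = knn_graph(X, 2)
    iu, ju = np.where(np.triu(eta, 1))
    ratios = np.sqrt(e2[iu, ju] / d2[iu, ju])
    assert ratios.max() <= 1 + 1e-5
    assert np.median(ratios) >= 0.95


def test_unfolding_rank_correlation():
    """The d=1 embedding of an arbitrarily ordered curled arc orders the
    points exactly by arc length."""
    X, s = curled_arc(30, angle=1.5 * np.pi)
    perm = np.random.default_rng(0).permutation(30)
    X, s = X[:, perm], s[perm]
    model = fit_lmvu(X, MvuParams(r=2, m=10, d=1, k=3))
    rho = spearmanr(model.Y[0], s).statistic
    assert abs(rho) == 1.0
    assert info_feasible(model, X)


def full_mvu_embedding(X, k, d):
    """Independent full-kernel formulation: solve for K (n x n) directly
    with the centering null space handled explicitly, then eigen-embed."""
    n = X.shape[1]
    d2 = _pairwise_sq(X)
    eta = knn_graph(X, k)
    ones = np.ones(n) / np.sqrt(n)
    Vb = np.linalg.svd(np.eye(n) - np.outer(ones, ones))[0][:, : n - 1]
    iu, ju = np.where(np.triu(eta, 1))
    rows = Vb.T[:, iu].T - Vb.T[:, ju].T
    res = solve_psd_max(Vb.T @ Vb, rows, d2[iu, ju], tol=1e-9)
    K = Vb @ res.M @ Vb.T
    w, V = np.linalg.eigh(K)
    w, V = w[::-1][:d], V[:, ::-1][:, :d]
    return (np.sqrt(np.maximum(w, 0))[:, None] * V.T)


@pytest.mark.parametrize("n", [8, 12])
def test_lmvu_with_all_landmarks_equals_full_mvu(n):
    """With m = n the landmark chain must reproduce plain maximum variance
    unfolding (independent full-kernel solve) up to rotation/reflection."""
    X, _ = curled_arc(n, angle=1.2 * np.pi, noise=0.02, seed=4)
    model = fit_lmvu(X, MvuParams(r=3, m=n, d=2, k=3), sdp_tol=1e-9)
    oracle = full_mvu_embedding(X, k=3, d=2)
    assert procrustes_residual(oracle, model.Y) < 1e-3


# ------------------------------------------------------------ eigen-embed

def test_eigen_embedding_closed_form():
    Ylm, w, V = embed_landmarks(np.diag([4.0, 1.0]), 1)
    assert np.allclose(np.abs(Ylm), [[2.0, 0.0]])
    assert np.allclose(w, [4.0, 1.0])


def test_gram_identity_full_dimension(rng):
    A = rng.standard_normal((6, 6))
    L = A.T @ A
    Ylm, _, _ = embed_landmarks(L, 6)
    assert np.abs(Ylm.T @ Ylm - L).max() < 1e-8


def test_zero_kernel_embeds_to_zero():
    Ylm, _, _ = embed_landmarks(np.zeros((4, 4)), 2)
    assert np.all(Ylm == 0)


def test_indefinite_kernel_rejected():
    with pytest.raises(ValueError, match="not PSD"):
        embed_landmarks(np.diag([1.0, -0.5]), 1)


def test_eigen_sign_convention_deterministic(rng):
    A = rng.standard_normal((5, 5))
    L = A.T @ A
    Y1, _, V1 = embed_landmarks(L, 3)
    Y2, _, V2 = embed_landmarks(L.copy(), 3)
    assert np.array_equal(Y1, Y2)
    for j in range(V1.shape[1]):
        i = int(np.argmax(np.abs(V1[:, j])))
        assert V1[i, j] > 0


# -------------------------------------------------------------- embed_all

def test_embed_all_is_matrix_product(rng):
    Q = rng.standard_normal((9, 4))
    Ylm = rng.standard_normal((2, 4))
    Y = embed_all(Q, Ylm)
    expect = np.array([[Ylm[r] @ Q[i] for i in range(9)] for r in range(2)])
    assert np.abs(Y - expect).max() < 1e-12


def test_landmark_columns_equal_landmark_embedding(rng):
    X = rng.standard_normal((3, 12))
    model = fit_lmvu(X, MvuParams(r=4, m=5, d=2, k=4))
    assert np.allclose(model.Y[:, :5], model.landmark_embedding)


def test_dimension_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        embed_all(rng.standard_normal((5, 3)), rng.standard_normal((2, 4)))


# --------------------------------------------------------------- fit_lmvu

def test_params_clamped_to_small_n(rng):
    X = rng.standard_normal((4, 10))
    model = fit_lmvu(X)                     # defaults r=52, m=14, d=5, k=24
    p = model.params
    assert p.r == 9 and p.k == 9 and p.m == 10 and p.d == 5
    assert model.Y.shape == (5, 10)
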