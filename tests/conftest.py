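import numpy as np
import pytest

from ilmvu import SimConfig, generate_trials, load_filter_bank


@pytest.fixture(scope="session")
def default_bank():
    return load_filter_bank("Antonini", "Qshift_c")


@pytest.fixture(scope="session")
def alt_bank():
    return load_filter_bank("LeGall", "Qshift_b")


@pytest.fixture(scope="session")
def small_trialset():
    """60 trials with a strong planted ERD; enough for feature checks."""
    return generate_trials(SimConfig(n_trials=60, erd_factor=0.3, rng_seed=7))


@pytest.fixture(scope="session")
def null_trialset():
    """No planted effect: the two classes are distributionally identical."""
    return generate_trials(SimConfig(n_trials=60, erd_factor=1.0,
                                     ers_factor=1.0, rng_seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def curled_arc(n, angle=1.5 * np.pi, noise=0.0, seed=0, radius=1.0):
    """Points on a circular arc embedded in 3-D; arc length is the latent
    coordinate that maximum variance unfolding should recover."""
    s = np.linspace(0.0, angle, n)
    X = np.vstack([radius * np.cos(s), radius * np.sin(s), np.zeros(n)])
    if noise:
        X = X + noise * np.random.default_rng(seed).standard_normal(X.shape)
    return X, s * radius


def procrustes_residual(Y_ref, Y_other):
    """Relative residual after optimal rotation/reflection alignment of two
    d x n embeddings (both centered first)."""
    from scipy.linalg import orthogonal_procrustes
    A = Y_other - Y_other.mean(axis=1, keepdims=True)
    B = Y_ref - Y_ref.mean(axis=1, keepdims=True)
    R, _ = orthogonal_procrustes(A.T, B.T)
    return float(np.linalg.norm(R.T @ A - B) / max(np.linalg.norm(B), 1e-300))
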