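"""Constant-time out-of-sample extension of a fitted L-MVU embedding.

A new sample is embedded by finding its w nearest neighbors among the
retained training samples, solving the same sum-to-one locally linear
reconstruction as at training time, and carrying the weights to the
low-dimensional coordinates: y_new = sum_j IW_j y_j.  No semidefinite
program is touched at test time - that is the point of the incremental
extension: the training-stage solve is amortized over every future sample.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .mvu import EmbeddingModel, MvuParams, _solve_local_weights

__all__ = ["DEFAULT_W", "incremental_weights", "transform", "transform_batch",
           "save_model", "load_model"]

#: default number of incremental neighbors; accuracy is nearly flat in w
DEFAULT_W = 4


def incremental_weights(x_new, model: EmbeddingModel, w=DEFAULT_W):
    """Neighbor set and sum-to-one reconstruction weights for one new sample.

    Returns (ns, iw): indices of the w nearest training samples (distance
    ties toward the smaller index) and the weights minimizing
    ||x_new - sum_j iw_j x_j||^2 with sum_j iw_j = 1.
    """
    X = model.X
    n = X.shape[1]
    if n == 0:
        raise ValueError("model has no training samples")
    if not 1 <= w <= n:
        raise ValueError(f"need 1 <= w <= n (w={w}, n={n})")
    x_new = np.asarray(x_new, float).ravel()
    if x_new.size != X.shape[0]:
        raise ValueError(f"sample dimension {x_new.size} != model "
                         f"dimension {X.shape[0]}")
    d2 = ((X - x_new[:, None]) ** 2).sum(axis=0)
    order = np.argsort(d2, kind="stable")
    ns = order[:w]
    iw = _solve_local_weights(x_new, X[:, ns])
    return ns, iw


def transform(model: EmbeddingModel, x_new, w=DEFAULT_W):
    """Embed one out-of-sample vector; the model is never refitted."""
    ns, iw = incremental_weights(x_new, model, w)
    return model.Y[:, ns] @ iw


def transform_batch(model: EmbeddingModel, X_new, w=DEFAULT_W):
    """Columnwise :func:`transform` of X_new (D x n_new) -> (d x n_new)."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    return np.column_stack([transform(model, X_new[:, i], w)
                            for i in range(X_new.shape[1])])


_MATS = ("X", "W", "Q", "L", "Y", "eigenvalues", "eigenvectors")


def save_model(model: EmbeddingModel, path):
    """Persist all matrices (full-precision text) and parameters (JSON)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in _MATS:
        np.savetxt(path / f"{name}.csv", np.atleast_2d(getattr(model, name)),
                   fmt="%.17e", delimiter=",")
    meta = {"params": vars(model.params),
            "landmarks": model.landmarks.tolist(),
            "sdp_info": model.sdp_info}
    (path / "model.json").write_text(json.dumps(meta, indent=1))


def load_model(path) -> EmbeddingModel:
    path = Path(path)
    meta_file = path / "model.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"missing model parameter file {meta_file}")
    meta = json.loads(meta_file.read_text())
    mats = {}
    for name in _MATS:
        f = path / f"{name}.csv"
        if not f.exists():
            raise FileNotFoundError(f"missing model matrix {f}")
        mats[name] = np.loadtxt(f, delimiter=",", ndmin=2)
    mats["eigenvalues"] = mats["eigenvalues"].ravel()
    return EmbeddingModel(params=MvuParams(**meta["params"]),
                          landmarks=np.asarray(meta["landmarks"], int),
                          sdp_info=meta.get("sdp_info", {}), **mats)
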