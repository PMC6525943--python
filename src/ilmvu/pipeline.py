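"""End-to-end two-class motor-imagery pipeline and its evaluation layer.

For each cross-validation fold the full chain is fitted on training trials
only - time-block selection, subject-adaptive wave selection, dual-tree
subband decomposition, the 2-D average-energy feature F1, the
high-dimensional C3-C4 difference vectors, and the landmark-MVU embedding
F2 - and test trials are embedded through the incremental out-of-sample map
(the landmark SDP is never re-solved for a test trial).  Features are fused
as F = [100 F1 ; F2] (the energy features are two orders of magnitude
smaller than the embedding coordinates) and classified with regularized
two-class LDA.  Accuracy, Cohen's kappa and a pooled-variance two-sample
t-test complete the evaluation layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as _stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .features import (build_highdim_feature, select_time_block,
                       select_waves, sliding_energy, trial_subbands)
from .filterbanks import load_filter_bank
from .incremental import DEFAULT_W, transform_batch
from .mvu import MvuParams, fit_lmvu
from .synthetic import TrialSet

__all__ = ["PipelineConfig", "CvResult", "TTestResult", "fuse_features",
           "train_lda", "predict", "kappa", "two_sample_ttest",
           "cross_validate", "run_ilmd", "w_sensitivity"]

_LABELS = ("left", "right")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; defaults follow the reference setup."""

    first_level: str = "Antonini"
    later_level: str = "Qshift_c"
    levels: int = 4
    mvu: MvuParams = field(default_factory=MvuParams)
    w: int = DEFAULT_W
    time_block: tuple = None        # None = automatic contrast criterion
    waves: list = None              # None = automatic Fisher-ratio choice
    wave_fraction: float = 0.8
    window_s: float = 4.0
    f1_scale: float = 100.0
    selection_on_full_set: bool = False   # leakage switch; keep False
    classifier_factory: object = None     # callable returning an estimator

    def to_report(self):
        rep = asdict(self)
        rep["mvu"] = vars(self.mvu)
        rep.pop("classifier_factory")
        return rep


@dataclass
class CvResult:
    fold_accuracies: np.ndarray    # percent, one per fold
    mean_accuracy: float           # percent
    confusion: np.ndarray          # pooled 2x2, rows true / cols predicted
    kappa: float
    seed: int
    fold_assignment: np.ndarray    # fold index per trial
    details: list = field(default_factory=list)


@dataclass
class TTestResult:
    t: float
    p: float
    alpha: float
    reject: bool
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    n_a: int
    n_b: int


def fuse_features(f1, f2, scale=100.0):
    """F = [scale * F1 ; F2]; F2 may be empty (energy-only mode)."""
    f1 = np.asarray(f1, float).ravel()
    f2 = np.asarray(f2, float).ravel()
    if f1.size != 2:
        raise ValueError(f"F1 must have length 2, got {f1.size}")
    return np.concatenate([scale * f1, f2])


def train_lda(F, labels, shrinkage_cond=1e8):
    """Two-class LDA with equal priors and pooled within-class covariance.

    When the pooled covariance is ill-conditioned the estimate is shrunk
    toward a scaled identity (Ledoit-Wolf-style, with a small fixed
    coefficient so the regularization never degenerates to zero).
    """
    F = np.asarray(F, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    resid = np.vstack([F[labels == c] - F[labels == c].mean(axis=0)
                       for c in classes])
    pooled = resid.T @ resid / max(len(F) - classes.size, 1)
    cond = np.linalg.cond(pooled) if pooled.size else 1.0
    if not np.isfinite(cond) or cond > shrinkage_cond:
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-3,
                                         priors=[0.5, 0.5])
    else:
        clf = LinearDiscriminantAnalysis(solver="svd", priors=[0.5, 0.5])
    return clf.fit(F, labels)


def predict(clf, F):
    return clf.predict(np.asarray(F, float))


def kappa(confusion):
    """Cohen's kappa of a 2x2 confusion matrix (rows true, cols predicted)."""
    c = np.asarray(confusion, float)
    if c.shape != (2, 2) or (c < 0).any() or c.sum() == 0:
        raise ValueError("confusion must be a nonnegative 2x2 matrix with "
                         "positive total")
    total = c.sum()
    po = np.trace(c) / total
    pe = float((c.sum(axis=0) * c.sum(axis=1)).sum()) / total ** 2
    if pe >= 1.0:
        warnings.warn("degenerate confusion matrix (chance agreement 1); "
                      "kappa defined as 0", RuntimeWarning)
        return 0.0
    return float((po - pe) / (1 - pe))


def two_sample_ttest(results_a, results_b, alpha=0.05, two_sided=False):
    """Pooled-variance two-sample t-test, t = (mean_b - mean_a) / s_pooled.

    With ``two_sided`` False the p-value is the upper tail
    P{T > t} at n_a + n_b - 2 degrees of freedom (is sample b larger?);
    otherwise both tails.  Zero pooled variance with equal means gives
    t = 0 and no rejection.
    """
    a = np.asarray(results_a, float)
    b = np.asarray(results_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = na + nb - 2
    pooled = ((nb - 1) * vb + (na - 1) * va) / df * (1 / na + 1 / nb)
    if pooled == 0:
        t = 0.0 if b.mean() == a.mean() else np.inf * np.sign(b.mean() - a.mean())
    else:
        t = float((b.mean() - a.mean()) / np.sqrt(pooled))
    if two_sided:
        p = float(2 * _stats.t.sf(abs(t), df))
    else:
        p = float(_stats.t.sf(t, df))
    return TTestResult(t=t, p=p, alpha=alpha, reject=bool(p <= alpha),
                       mean_a=float(a.mean()), mean_b=float(b.mean()),
                       var_a=float(va), var_b=float(vb), n_a=na, n_b=nb)


# ----------------------------------------------------------------------
# pipeline fitting
# ----------------------------------------------------------------------

class _FittedFold:
    """Everything fitted on one fold's training trials."""

    def __init__(self, block, waves, wave_scores, model, clf, tags,
                 train_idx, f1_scale):
        self.block = block
        self.waves = waves
        self.wave_scores = wave_scores
        self.model = model
        self.clf = clf
        self.tags = tags
        self.train_idx = np.asarray(train_idx)
        self.f1_scale = f1_scale


def _ae_matrix(subs, tags, block, fs, idx):
    """Per-trial average normalized-energy difference C3 - C4, per subband.

    Returns (n_subbands, len(idx)).
    """
    out = np.empty((subs["C3"].shape[1], len(idx)))
    for col, i in enumerate(idx):
        e3 = sliding_energy(subs["C3"][i][:, block.slice()], fs)
        e4 = sliding_energy(subs["C4"][i][:, block.slice()], fs)
        out[:, col] = e3.mean(axis=1) - e4.mean(axis=1)
    return out


def _fit_fold(ts, subs, tags, train_idx, config) -> _FittedFold:
    sel_idx = (np.arange(ts.n_trials) if config.selection_on_full_set
               else train_idx)
    ts_sel = ts.subset(sel_idx)
    block = select_time_block(ts_sel, window_s=config.window_s,
                              override=config.time_block)
    ae_sel = _ae_matrix(subs, tags, block, ts.fs, sel_idx)
    waves, scores = select_waves(ae_sel, ts.labels[sel_idx], tags,
                                 fraction=config.wave_fraction,
                                 override=config.waves)
    ae_train = (_ae_matrix(subs, tags, block, ts.fs, train_idx)
                if config.selection_on_full_set or len(sel_idx) != len(train_idx)
                or not np.array_equal(sel_idx, train_idx) else ae_sel)
    ia, ib = tags.index("alpha"), tags.index("beta")
    f1_train = ae_train[[ia, ib]].T                     # (n_train, 2)
    hd = build_highdim_feature(subs["C3"][train_idx], subs["C4"][train_idx],
                               tags, waves, block)
    model = fit_lmvu(hd.matrix, config.mvu)
    F_train = np.column_stack([config.f1_scale * f1_train, model.Y.T])
    clf = train_lda(F_train, ts.labels[train_idx])
    return _FittedFold(block, waves, scores, model, clf, tags, train_idx,
                       config.f1_scale)


def _test_features(ts, subs, fold: _FittedFold, test_idx, w):
    ae = _ae_matrix(subs, fold.tags, fold.block, ts.fs, test_idx)
    ia, ib = fold.tags.index("alpha"), fold.tags.index("beta")
    f1 = ae[[ia, ib]].T
    hd = build_highdim_feature(subs["C3"][test_idx], subs["C4"][test_idx],
                               fold.tags, fold.waves, fold.block)
    f2 = transform_batch(fold.model, hd.matrix, w)
    return np.column_stack([fold.f1_scale * f1, f2.T])


def cross_validate(ts: TrialSet, config: PipelineConfig = None, folds=10,
                   seed=1, _return_folds=False):
    """Stratified k-fold evaluation of the full pipeline.

    Every selection and fit happens on the training trials of each fold;
    test trials only pass through the incremental embedding and the trained
    classifier.
    """
    config = config or PipelineConfig()
    if ts.n_trials < folds:
        raise ValueError(f"need at least {folds} trials for {folds}-fold CV")
    fb = load_filter_bank(config.first_level, config.later_level)
    subs, tags = trial_subbands(ts, config.levels, fb)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(ts.n_trials, int)
    accs, details, fitted = [], [], []
    confusion = np.zeros((2, 2), int)
    for f, (tr, te) in enumerate(skf.split(np.zeros(ts.n_trials), ts.labels)):
        if len(set(ts.labels[tr])) < 2 or len(set(ts.labels[te])) < 2:
            raise ValueError(f"fold {f} is single-class; re-seed or "
                             "rebalance the data")
        assignment[te] = f
        fold = _fit_fold(ts, subs, tags, tr, config)
        F_te = _test_features(ts, subs, fold, te, config.w)
        pred = predict(fold.clf, F_te)
        truth = ts.labels[te]
        accs.append(100.0 * float((pred == truth).mean()))
        for t, p in zip(truth, pred):
            confusion[_LABELS.index(t), _LABELS.index(p)] += 1
        details.append({"fold": f,
                        "time_block_s": list(fold.block.seconds),
                        "waves": list(fold.waves),
                        "n_train": len(tr), "n_test": len(te),
                        "accuracy": accs[-1]})
        if _return_folds:
            fitted.append((fold, te))
    accs = np.asarray(accs)
    result = CvResult(fold_accuracies=accs, mean_accuracy=float(accs.mean()),
                      confusion=confusion, kappa=kappa(confusion), seed=seed,
                      fold_assignment=assignment, details=details)
    return (result, fitted, subs) if _return_folds else result


def run_ilmd(ts: TrialSet, config: PipelineConfig = None, folds=10, seed=1):
    """Cross-validate and assemble a JSON-serializable report."""
    config = config or PipelineConfig()
    res = cross_validate(ts, config, folds=folds, seed=seed)
    report = {
        "config": config.to_report(),
        "folds": folds,
        "seed": seed,
        "fold_accuracies": res.fold_accuracies.tolist(),
        "mean_accuracy": res.mean_accuracy,
        "kappa": res.kappa,
        "confusion": res.confusion.tolist(),
        "fold_details": res.details,
    }
    return res, report


def w_sensitivity(ts: TrialSet, config: PipelineConfig = None,
                  w_values=range(2, 13), folds=10, seed=1):
    """Mean CV accuracy as a function of the incremental neighbor count w.

    The fold models and classifiers do not depend on w, so each fold is
    fitted once and only the out-of-sample embedding is recomputed.
    """
    config = config or PipelineConfig()
    _, fitted, subs = cross_validate(ts, config, folds=folds, seed=seed,
                                     _return_folds=True)
    out = {}
    for w in w_values:
        accs = []
        for fold, te in fitted:
            F_te = _test_features(ts, subs, fold, te, w)
            pred = predict(fold.clf, F_te)
            accs.append(100.0 * float((pred == ts.labels[te]).mean()))
        out[int(w)] = float(np.mean(accs))
    return out
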