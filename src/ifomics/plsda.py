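"""PLS-DA and repeated double cross-validation (rdCV) with permutation tests.

The classifier is PLS2 on an indicator-coded class matrix, fitted by
NIPALS with training-only centering and unit-variance scaling.  Model
validation follows the rdCV scheme: an inner cross-validation loop tunes
the number of latent components, an outer loop predicts held-out samples,
and the whole procedure is repeated over many random stratified splits so
that each sample accrues one class assignment per repetition.  Class
"probabilities" are assignment frequencies across repetitions; accuracy is
correctly predicted samples over total samples.  A label-permutation test
provides the significance gate.

`PLSDA` is a model object in the statsmodels style: construct from data,
``fit()`` returns a results object carrying the factors and a ``predict``
method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLSDA",
    "PLSDAResults",
    "RdcvConfig",
    "RdcvResult",
    "PermutationResult",
    "plsda_fit",
    "plsda_predict",
    "rdcv_run",
    "permutation_test",
    "predictive_accuracy",
]


# ---------------------------------------------------------------- core NIPALS

def _nipals_pls2(X: np.ndarray, Y: np.ndarray, n_components: int,
                 tol: float = 1e-9, max_iter: int = 500):
    """NIPALS PLS2 on pre-centered/scaled X and centered indicator Y.

    Returns (W, T, P, Q, n_fit).  Each weight vector has unit norm and the
    sign convention that its largest-|value| coordinate is positive.  For a
    two-class Y (rank 1) the inner loop converges in a single pass.
    """
    n, p = X.shape
    A = int(n_components)
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    Q = np.zeros((Y.shape[1], A))
    Xa, Ya = X.copy(), Y.copy()
    n_fit = 0
    for a in range(A):
        ynorms = (Ya ** 2).sum(axis=0)
        if ynorms.max() <= 1e-24 or (Xa ** 2).sum() <= 1e-24:
            break  # rank exhausted
        u = Ya[:, int(np.argmax(ynorms))]
        for _ in range(max_iter):
            w = Xa.T @ u
            wn = np.linalg.norm(w)
            if wn == 0:
                break
            w /= wn
            t = Xa @ w
            tt = t @ t
            if tt == 0:
                break
            q = Ya.T @ t / tt
            u_new = Ya @ q / (q @ q)
            if np.max(np.abs(u_new - u)) < tol * max(1.0, np.max(np.abs(u_new))):
                u = u_new
                break
            u = u_new
        if wn == 0 or tt == 0:
            break
        # deterministic sign: largest-|w| coordinate positive
        k = int(np.argmax(np.abs(w)))
        if w[k] < 0:
            w, t, q = -w, -t, -q
        pvec = Xa.T @ t / tt
        Xa -= np.outer(t, pvec)
        Ya -= np.outer(t, q)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, pvec, q
        n_fit += 1
    return W[:, :n_fit], T[:, :n_fit], P[:, :n_fit], Q[:, :n_fit], n_fit


def _coef(W, P, Q, a):
    """Regression coefficients using the first ``a`` components."""
    Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:, :a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)


def _scale_train(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _indicator(y, classes):
    Y = np.zeros((len(y), len(classes)))
    for c, cls in enumerate(classes):
        Y[np.asarray(y) == cls, c] = 1.0
    return Y


# -------------------------------------------------------------- model object

class PLSDA:
    """PLS discriminant analysis model.

    Parameters
    ----------
    X : array-like, samples x features
    y : array-like of class labels (two or more classes)
    scale : bool
        Unit-variance scaling of features (training statistics only).
    """

    def __init__(self, X, y, scale: bool = True):
        self.feature_ids = list(X.columns) if isinstance(X, pd.DataFrame) else None
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.classes_ = np.unique(self.y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        self.scale = scale

    def fit(self, n_components: int = 2, tol: float = 1e-9,
            max_iter: int = 500) -> "PLSDAResults":
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        Xs, mu, sd = _scale_train(self.X) if self.scale else (
            self.X - self.X.mean(axis=0), self.X.mean(axis=0),
            np.ones(self.X.shape[1]))
        Y = _indicator(self.y, self.classes_)
        ymean = Y.mean(axis=0)
        W, T, P, Q, n_fit = _nipals_pls2(Xs, Y - ymean, n_components, tol, max_iter)
        if n_fit < n_components:
            warnings.warn(
                f"rank limited: fitted {n_fit} of {n_components} requested components"
            )
        return PLSDAResults(self, W, T, P, Q, mu, sd, ymean, n_fit)


@dataclass
class PLSDAResults:
    """Fitted PLS-DA factors plus training preprocessing parameters."""

    model: PLSDA
    weights: np.ndarray      # features x A, unit-norm columns
    scores: np.ndarray       # samples x A, mutually orthogonal
    x_loadings: np.ndarray   # features x A
    y_loadings: np.ndarray   # classes x A
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    n_components: int

    @property
    def classes_(self):
        return self.model.classes_

    def predict(self, X_new, n_components: int | None = None):
        """Predicted indicator, class probabilities and assignments.

        Probabilities are a softmax-free normalization of the predicted
        indicator row (shifted to be non-negative); the assignment is the
        argmax column, ties broken toward the first class in class order.
        """
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != self.x_mean.size:
            raise ValueError("feature mismatch with the fitted model")
        a = self.n_components if n_components is None else min(
            n_components, self.n_components)
        Xs = (X_new - self.x_mean) / self.x_std
        yhat = Xs @ _coef(self.weights, self.x_loadings, self.y_loadings, a) + self.y_mean
        shifted = yhat - yhat.min(axis=1, keepdims=True)
        denom = shifted.sum(axis=1, keepdims=True)
        probs = np.where(denom > 0, shifted / np.where(denom == 0, 1, denom),
                         1.0 / yhat.shape[1])
        assignments = self.classes_[np.argmax(yhat, axis=1)]
        return yhat, probs, assignments

    def summary(self) -> str:
        lines = [
            "PLS-DA results",
            f"  classes:      {list(self.classes_)}",
            f"  components:   {self.n_components}",
            f"  samples:      {self.scores.shape[0]}",
            f"  features:     {self.weights.shape[0]}",
        ]
        expl = (self.scores ** 2).sum(axis=0)
        for a in range(self.n_components):
            lines.append(f"  score SS component {a + 1}: {expl[a]:.4f}")
        return "\n".join(lines)


def plsda_fit(X, labels, n_components: int = 2, scale: bool = True) -> PLSDAResults:
    """Functional wrapper: fit a PLS-DA model."""
    return PLSDA(X, labels, scale=scale).fit(n_components)


def plsda_predict(result: PLSDAResults, X_new):
    """Functional wrapper: class probabilities and assignments."""
    _, probs, assignments = result.predict(X_new)
    return probs, assignments


# ----------------------------------------------------------------- rdCV loop

@dataclass
class RdcvConfig:
    """Settings of the repeated double cross-validation loop."""

    outer_folds: int = 7
    inner_folds: int = 6
    repetitions: int = 200
    max_components: int = 3
    stratified: bool = True
    fitness: str = "balanced"   # or "plain" misclassification
    seed: int = 0

    def __post_init__(self):
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")
        if self.fitness not in ("balanced", "plain"):
            raise ValueError("fitness must be 'balanced' or 'plain'")


@dataclass
class RdcvResult:
    """Per-sample per-repetition assignments and aggregated accuracy."""

    sample_ids: list
    classes: np.ndarray
    labels: np.ndarray
    assignments: np.ndarray          # samples x repetitions (class indices)
    probabilities: pd.DataFrame      # samples x classes (assignment frequency)
    predicted: np.ndarray            # consensus class per sample
    misclassified: list
    accuracy: float
    components_per_model: np.ndarray  # repetitions x outer_folds
    consensus_components: int
    config: RdcvConfig = field(repr=False, default=None)

    def summary(self) -> str:
        return "\n".join([
            "rdCV-PLS-DA result",
            f"  samples:               {len(self.sample_ids)}",
            f"  repetitions:           {self.assignments.shape[1]}",
            f"  accuracy:              {self.accuracy:.4f}",
            f"  misclassified:         {self.misclassified}",
            f"  consensus components:  {self.consensus_components}",
        ])


def _stratified_folds(y_codes: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Fold index per sample; classes spread round-robin after shuffling."""
    folds = np.empty(y_codes.size, dtype=np.int64)
    for c in np.unique(y_codes):
        idx = np.flatnonzero(y_codes == c)
        idx = rng.permutation(idx)
        start = int(rng.integers(n_folds))
        folds[idx] = (np.arange(idx.size) + start) % n_folds
    return folds


def _misclass_cost(y_true_codes, y_pred_codes, n_classes, balanced):
    if balanced:
        errs = []
        for c in range(n_classes):
            mask = y_true_codes == c
            if mask.any():
                errs.append(np.mean(y_pred_codes[mask] != c))
        return float(np.mean(errs))
    return float(np.mean(y_pred_codes != y_true_codes))


def rdcv_run(X, labels, config: RdcvConfig | None = None, **overrides) -> RdcvResult:
    """Repeated double cross-validation of PLS-DA.

    Per repetition: a stratified outer split; per outer fold, an inner CV
    over 1..max_components picks the component count with minimal
    (balanced) misclassification (ties favor fewer components); the tuned
    model then predicts the outer test fold.  Assignments are pooled over
    repetitions into per-sample class frequencies; the reported accuracy is
    correctly predicted samples / total samples under the consensus
    (frequency-argmax) assignment.
    """
    if config is None:
        config = RdcvConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    sample_ids = list(X.index) if isinstance(X, pd.DataFrame) else list(
        range(np.asarray(X).shape[0]))
    Xm = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes, y_codes = np.unique(y, return_inverse=True)
    n, n_classes = y.size, classes.size
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(y_codes)
    if counts.min() < config.outer_folds:
        warnings.warn(
            "smallest class has fewer samples than outer_folds; "
            "stratification relaxed to available samples"
        )
    A = min(config.max_components, Xm.shape[1])
    balanced = config.fitness == "balanced"

    assignments = np.empty((n, config.repetitions), dtype=np.int64)
    comp_choice = np.empty((config.repetitions, config.outer_folds), dtype=np.int64)
    root = np.random.SeedSequence(config.seed)
    for r, child in enumerate(root.spawn(config.repetitions)):
        rng = np.random.default_rng(child)
        outer = _stratified_folds(y_codes, config.outer_folds, rng)
        for k in range(config.outer_folds):
            test = outer == k
            train = ~test
            y_tr = y_codes[train]
            if np.unique(y_tr).size < n_classes:
                raise ValueError(
                    f"stratification failure: class missing from outer "
                    f"training set (repetition {r}, fold {k})"
                )
            X_tr = Xm[train]
            a_star = _inner_select(X_tr, y_tr, n_classes, A, config, rng, balanced)
            comp_choice[r, k] = a_star
            pred = _fit_predict_codes(X_tr, y_tr, n_classes, a_star, Xm[test])
            assignments[test, r] = pred
    freqs = np.stack([
        (assignments == c).mean(axis=1) for c in range(n_classes)
    ], axis=1)
    predicted_codes = np.argmax(freqs, axis=1)
    mis = [sample_ids[i] for i in np.flatnonzero(predicted_codes != y_codes)]
    accuracy = 1.0 - len(mis) / n
    consensus = int(np.bincount(comp_choice.ravel()).argmax())
    return RdcvResult(
        sample_ids=sample_ids,
        classes=classes,
        labels=y,
        assignments=assignments,
        probabilities=pd.DataFrame(freqs, index=sample_ids, columns=list(classes)),
        predicted=classes[predicted_codes],
        misclassified=mis,
        accuracy=accuracy,
        components_per_model=comp_choice,
        consensus_components=consensus,
        config=config,
    )


def _fit_predict_codes(X_tr, y_tr_codes, n_classes, a, X_te):
    """Fit on training rows only (scaling included) and predict codes."""
    Xs, mu, sd = _scale_train(X_tr)
    Y = _indicator(y_tr_codes, np.arange(n_classes))
    ymean = Y.mean(axis=0)
    W, T, P, Q, n_fit = _nipals_pls2(Xs, Y - ymean, a)
    a_eff = max(1, n_fit)
    B = _coef(W, P, Q, a_eff)
    yhat = ((X_te - mu) / sd) @ B + ymean
    return np.argmax(yhat, axis=1)


def _inner_select(X_tr, y_tr_codes, n_classes, A, config, rng, balanced):
    """Inner CV over component counts; returns the tuned count."""
    if A == 1:
        return 1
    inner = _stratified_folds(y_tr_codes, config.inner_folds, rng)
    costs = np.zeros(A)
    weights = np.zeros(A)
    for k in range(config.inner_folds):
        val = inner == k
        tr = ~val
        if np.unique(y_tr_codes[tr]).size < n_classes or not val.any():
            continue
        Xs, mu, sd = _scale_train(X_tr[tr])
        Y = _indicator(y_tr_codes[tr], np.arange(n_classes))
        ymean = Y.mean(axis=0)
        W, T, P, Q, n_fit = _nipals_pls2(Xs, Y - ymean, A)
        Xv = (X_tr[val] - mu) / sd
        for a in range(1, A + 1):
            a_eff = min(a, max(1, n_fit))
            yhat = Xv @ _coef(W, P, Q, a_eff) + ymean
            pred = np.argmax(yhat, axis=1)
            costs[a - 1] += _misclass_cost(y_tr_codes[val], pred, n_classes, balanced)
            weights[a - 1] += 1
    if weights.max() == 0:
        return 1
    mean_cost = costs / np.maximum(weights, 1)
    return int(np.argmin(mean_cost)) + 1  # argmin takes the first (fewest) on ties


def predictive_accuracy(result: RdcvResult) -> float:
    """Correct / total under the repetition-averaged class assignment."""
    correct = (result.predicted == result.labels).sum()
    return correct / len(result.sample_ids)


# --------------------------------------------------------- permutation gate

@dataclass
class PermutationResult:
    observed_accuracy: float
    permuted_accuracies: np.ndarray
    p_empirical: float
    p_parametric: float
    n_permutations: int
    seed: int

    def summary(self) -> str:
        return "\n".join([
            "rdCV permutation test",
            f"  observed accuracy:  {self.observed_accuracy:.4f}",
            f"  permutations:       {self.n_permutations}",
            f"  permuted mean:      {self.permuted_accuracies.mean():.4f}",
            f"  empirical p:        {self.p_empirical:.4g}",
            f"  parametric p (t):   {self.p_parametric:.4g}",
        ])


def permutation_test(X, labels, config: RdcvConfig | None = None,
                     n_permutations: int = 1000, seed: int | None = None,
                     perm_repetitions: int = 1,
                     observed: RdcvResult | None = None) -> PermutationResult:
    """Label-permutation null for the rdCV accuracy.

    Each permutation shuffles the class labels and refits a reduced-cost
    rdCV (``perm_repetitions`` outer repetitions, default 1).  Empirical
    p = (1 + #{perm >= obs}) / (1 + n); a one-sided t-test of the observed
    accuracy against the permuted distribution is reported alongside.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if config is None:
        config = RdcvConfig()
    if seed is None:
        seed = config.seed
    if observed is None:
        observed = rdcv_run(X, labels, config)
    y = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9e3779]))
    perm_acc = np.empty(n_permutations)
    for b in range(n_permutations):
        y_perm = rng.permutation(y)
        res = rdcv_run(
            X, y_perm,
            replace(config, repetitions=perm_repetitions,
                    seed=int(rng.integers(2 ** 31))),
        )
        perm_acc[b] = res.accuracy
    ge = int((perm_acc >= observed.accuracy - 1e-12).sum())
    p_emp = (1 + ge) / (1 + n_permutations)
    if np.std(perm_acc, ddof=1) == 0:
        p_par = 1.0 if perm_acc.mean() >= observed.accuracy else 0.0
    else:
        p_par = float(stats.ttest_1samp(
            perm_acc, observed.accuracy, alternative="less").pvalue)
    return PermutationResult(observed.accuracy, perm_acc, p_emp, p_par,
                             n_permutations, seed)
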