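"""L2-regularized logistic regression with nested cross-validation.

This is the estimation engine behind both the kinematic encoding model
(predicting the true stimulus configuration from single-trial kinematic
differences) and the per-observer readout model (predicting the observer's
choice from the same differences):

    P(y = 1 | x) = sigma(x . beta + b),    yhat = H(sigma(x . beta + b) - 1/2)

with sigma the logistic sigmoid and H the Heaviside step.  The tie
P = 1/2 is resolved deterministically as class 0 ("large first").

Fits minimize  -loglik + (lam / 2) * ||beta||^2  (intercept unpenalized) by
damped Newton iterations.  The ridge penalty ``lam`` is selected by inner
stratified cross-validation over a fixed grid; predictive accuracy is
estimated by an outer stratified k-fold, optionally grouped so that trials
sharing a stimulus pair never straddle a train/test split.

Everything is deterministic given the seed.  Problems here are tiny
(<=30 trials, <=96 predictors) but fitted tens of thousands of times in
permutation nulls, hence the dedicated dense Newton solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

#: Default ridge-penalty grid searched by inner CV (documented contract).
DEFAULT_LAMBDA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


def _fit_augmented(
    Xa: np.ndarray,
    y: np.ndarray,
    ridge: np.ndarray,
    w0: np.ndarray | None,
    max_iter: int,
    tol: float,
) -> np.ndarray:
    """Damped-Newton solver on the intercept-augmented design matrix."""
    w = np.zeros(Xa.shape[1]) if w0 is None else w0.copy()
    eta = Xa @ w
    obj = float(np.sum(np.logaddexp(0.0, eta) - y * eta)
                + 0.5 * np.sum(ridge * w * w))
    for _ in range(max_iter):
        mu = expit(eta)
        grad = Xa.T @ (mu - y) + ridge * w
        if np.max(np.abs(grad)) < tol:
            break
        s = np.maximum(mu * (1.0 - mu), 1e-10)
        H = (Xa * s[:, None]).T @ Xa
        H[np.diag_indices_from(H)] += ridge + 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / np.max(np.abs(np.diag(H)))
        # backtracking line search keeps the objective monotone
        t = 1.0
        for _ in range(30):
            w_new = w - t * step
            eta_new = Xa @ w_new
            obj_new = float(np.sum(np.logaddexp(0.0, eta_new) - y * eta_new)
                            + 0.5 * np.sum(ridge * w_new * w_new))
            if obj_new <= obj + 1e-14:
                break
            t *= 0.5
        if obj_new > obj:
            break
        w, obj, eta = w_new, obj_new, eta_new
    return w


def fit_l2_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    max_iter: int = 50,
    tol: float = 1e-9,
    w0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Fit the penalized logistic model; returns (beta, intercept).

    ``lam`` may be 0 only on strictly non-separable data (the MLE must
    exist); use a small positive value otherwise.  ``w0`` (beta + intercept,
    intercept last) warm-starts the Newton iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xa = np.hstack([X, np.ones((n, 1))])
    ridge = np.full(p + 1, float(lam))
    ridge[-1] = 0.0  # intercept unpenalized
    w = _fit_augmented(Xa, y, ridge, w0, max_iter, tol)
    return w[:-1], float(w[-1])


def predict_proba(X: np.ndarray, beta: np.ndarray, intercept: float) -> np.ndarray:
    return expit(np.asarray(X, dtype=float) @ beta + intercept)


def predict_class(X: np.ndarray, beta: np.ndarray, intercept: float) -> np.ndarray:
    """Heaviside decision rule; the tie P = 0.5 predicts class 0."""
    return (predict_proba(X, beta, intercept) > 0.5).astype(int)


def stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deterministic stratified k-fold: class-wise shuffle then round-robin.

    Classes are processed in a label-flip-invariant order (the class of the
    first trial first), so globally flipping all labels yields identical
    folds — the interval-swap symmetry of the 2AFC design is then exact.
    """
    y = np.asarray(y).astype(int)
    k = min(k, max(2, np.min(np.bincount(y, minlength=2))))
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    ref = int(y[0])
    for c in (ref, 1 - ref):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(int(i))
        offset += len(idx) % k
    return [np.asarray(sorted(f), dtype=int) for f in folds if len(f) > 0]


def grouped_stratified_folds(
    y: np.ndarray, groups: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Stratified folds keeping all trials of a group in the same fold.

    Groups are shuffled, sorted by size (stable), then greedily assigned to
    the fold with the fewest trials (ties: fewest of the group's majority
    class, then lowest fold index).
    """
    y = np.asarray(y).astype(int)
    groups = np.asarray(groups)
    uniq, inv = np.unique(groups, return_inverse=True)
    order = rng.permutation(len(uniq))
    sizes = np.bincount(inv)
    order = order[np.argsort(-sizes[order], kind="stable")]
    k = min(k, len(uniq))
    fold_n = np.zeros(k, dtype=int)
    fold_c = np.zeros((k, 2), dtype=int)
    assign = np.empty(len(uniq), dtype=int)
    ref = int(y[0])  # label-flip-invariant class coding (see stratified_folds)
    yc = (y != ref).astype(int)
    for g in order:
        members = np.flatnonzero(inv == g)
        maj = int(np.round(np.mean(yc[members])))
        cost = fold_n * 1000 + fold_c[:, maj]
        f = int(np.argmin(cost))
        assign[g] = f
        fold_n[f] += len(members)
        for c in (0, 1):
            fold_c[f, c] += int(np.sum(yc[members] == c))
    folds = [np.flatnonzero(np.isin(inv, np.flatnonzero(assign == f)))
             for f in range(k)]
    return [f for f in folds if len(f) > 0]


def select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    lam_grid: tuple[float, ...],
    inner_k: int,
    rng: np.random.Generator,
) -> float:
    """Pick the penalty maximizing inner-CV accuracy; ties go to the larger
    (more regularized) value for determinism and stability."""
    lam_grid = tuple(sorted(lam_grid))
    if len(lam_grid) == 1:
        return lam_grid[0]
    folds = stratified_folds(y, inner_k, rng)
    if len(folds) < 2:
        return lam_grid[-1]
    n, p = X.shape
    Xa = np.hstack([X, np.ones((n, 1))])
    yf = y.astype(float)
    correct = np.zeros(len(lam_grid))
    ridge = np.empty(p + 1)
    for f in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[f] = False
        if len(np.unique(y[mask])) < 2:
            continue
        Xtr, ytr = Xa[mask], yf[mask]
        w = None
        # fit the ridge path from strongest to weakest penalty, warm-started
        for li in range(len(lam_grid) - 1, -1, -1):
            ridge[:] = lam_grid[li]
            ridge[-1] = 0.0
            # looser tolerance: only the held-out sign matters here
            w = _fit_augmented(Xtr, ytr, ridge, w, 50, 1e-6)
            pred = (Xa[f] @ w) > 0.0
            correct[li] += np.sum(pred == (y[f] == 1))
    best = np.flatnonzero(correct == correct.max())
    return lam_grid[int(best[-1])]


@dataclass
class CVResult:
    """Outer-CV summary of a penalized logistic fit."""

    cv_accuracy: float
    cv_sem: float
    fold_accuracies: np.ndarray
    fold_assignments: np.ndarray  # fold index per trial
    heldout_proba: np.ndarray  # per-trial held-out P(y=1)
    heldout_pred: np.ndarray  # per-trial held-out Heaviside prediction
    beta: np.ndarray  # full-data fit at the full-data selected penalty
    intercept: float
    penalty: float


def cv_logistic(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    outer_k: int = 10,
    inner_k: int = 5,
    lam_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    groups: np.ndarray | None = None,
) -> CVResult:
    """Nested-CV accuracy plus a full-data fit.

    The penalty is re-selected inside every outer training set (so the outer
    accuracy is unbiased) and once more on the full data for the reported
    coefficients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if not np.any(np.abs(X) > 0):
        raise ValueError("degenerate all-zero feature matrix")
    rng = np.random.default_rng(seed)
    if groups is not None:
        folds = grouped_stratified_folds(y, groups, outer_k, rng)
    else:
        folds = stratified_folds(y, outer_k, rng)
    n = len(y)
    fold_assign = np.full(n, -1, dtype=int)
    proba = np.full(n, np.nan)
    accs = []
    for fi, f in enumerate(folds):
        fold_assign[f] = fi
        mask = np.ones(n, dtype=bool)
        mask[f] = False
        if len(np.unique(y[mask])) < 2:
            proba[f] = np.mean(y[mask])
            accs.append(float(np.mean((proba[f] > 0.5).astype(int) == y[f])))
            continue
        lam = select_lambda(X[mask], y[mask], lam_grid, inner_k, rng)
        beta, b = fit_l2_logistic(X[mask], y[mask], lam)
        proba[f] = predict_proba(X[f], beta, b)
        accs.append(float(np.mean((proba[f] > 0.5).astype(int) == y[f])))
    accs = np.asarray(accs)
    lam_full = select_lambda(X, y, lam_grid, inner_k, rng)
    beta, b = fit_l2_logistic(X, y, lam_full)
    sem = float(np.std(accs, ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0
    return CVResult(
        cv_accuracy=float(np.mean(accs)),
        cv_sem=sem,
        fold_accuracies=accs,
        fold_assignments=fold_assign,
        heldout_proba=proba,
        heldout_pred=(proba > 0.5).astype(int),
        beta=beta,
        intercept=float(b),
        penalty=float(lam_full),
    )
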