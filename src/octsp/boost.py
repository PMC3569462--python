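"""LogitBoost two-class classifier with decision-stump base learners.

Additive logistic regression fitted by stagewise weighted least squares:
starting from ``F = 0`` and ``p = 1/2``, each iteration computes the
working response ``z_i = (y*_i - p_i) / (p_i (1 - p_i))`` with
``y* in {0, 1}`` and weights ``w_i = p_i (1 - p_i)``, fits a weighted
least-squares regression stump, and updates ``F <- F + nu * f``,
``p = 1 / (1 + exp(-2 F))``.  Standard numerical safeguards: the working
response is clipped to ``|z| <= 4`` and weights floored at ``2e-6``.

The classifier score is the additive stump sum: negative for the healthy
class, positive for disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Z_MAX = 4.0
W_MIN = 2e-6


@dataclass(frozen=True)
class Stump:
    feature: int
    threshold: float
    left: float  # value for x[feature] <= threshold
    right: float


@dataclass
class BoostModel:
    stumps: list[Stump]
    n_iter: int
    shrinkage: float
    n_features: int


def _fit_stump(X: np.ndarray, z: np.ndarray, w: np.ndarray) -> tuple[Stump, float]:
    """Weighted least-squares stump over all features and thresholds.

    Thresholds are midpoints of sorted distinct feature values; ties in
    the loss are broken toward the smaller threshold (and smaller feature
    index).  Returns the stump and its weighted SSE.
    """
    n, d = X.shape
    sw = w.sum()
    swz = (w * z).sum()
    swz2 = (w * z * z).sum()
    best = None
    best_sse = np.inf
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ws = w[order]
        zs = z[order]
        cw = np.cumsum(ws)
        cwz = np.cumsum(ws * zs)
        # candidate split after position i (0-based), where value changes
        change = np.flatnonzero(xs[1:] > xs[:-1])
        if change.size == 0:
            continue
        wl, wzl = cw[change], cwz[change]
        wr, wzr = sw - wl, swz - wzl
        with np.errstate(invalid="ignore", divide="ignore"):
            sse = swz2 - np.where(wl > 0, wzl**2 / wl, 0.0) - np.where(
                wr > 0, wzr**2 / wr, 0.0
            )
        i = int(np.argmin(sse))  # argmin takes the first -> smaller threshold
        if sse[i] < best_sse - 1e-15:
            thr = 0.5 * (xs[change[i]] + xs[change[i] + 1])
            wl_i, wzl_i = wl[i], wzl[i]
            left = wzl_i / wl_i if wl_i > 0 else 0.0
            right = (swz - wzl_i) / (sw - wl_i) if sw - wl_i > 0 else 0.0
            best = Stump(j, float(thr), float(left), float(right))
            best_sse = float(sse[i])
    if best is None:  # all features constant: fit the weighted mean
        c = swz / sw if sw > 0 else 0.0
        best = Stump(0, np.inf, float(c), float(c))
        best_sse = float(swz2 - sw * c * c)
    return best, best_sse


def logitboost_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 100,
    shrinkage: float = 0.1,
) -> BoostModel:
    """Fit LogitBoost on binary labels (0 = healthy, 1 = disease)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2D")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes present")
    ystar = (y == classes.max()).astype(float)
    n = len(ystar)
    F = np.zeros(n)
    p = np.full(n, 0.5)
    stumps: list[Stump] = []
    for _ in range(n_iter):
        w = np.maximum(p * (1.0 - p), W_MIN)
        z = np.clip((ystar - p) / w, -Z_MAX, Z_MAX)
        stump, _ = _fit_stump(X, z, w)
        stumps.append(stump)
        f = np.where(X[:, stump.feature] <= stump.threshold, stump.left, stump.right)
        F = F + shrinkage * f
        p = 1.0 / (1.0 + np.exp(-2.0 * F))
    return BoostModel(
        stumps=stumps, n_iter=n_iter, shrinkage=shrinkage, n_features=X.shape[1]
    )


def predict_score(model: BoostModel, X: np.ndarray) -> np.ndarray:
    """Additive stump sum (x shrinkage); no thresholding applied."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError("column count differs from training data")
    F = np.zeros(len(X))
    for s in model.stumps:
        F += model.shrinkage * np.where(
            X[:, s.feature] <= s.threshold, s.left, s.right
        )
    return F


def training_loss(model: BoostModel, X: np.ndarray, y: np.ndarray) -> list[float]:
    """Negative binomial log-likelihood after each boosting iteration."""
    X = np.asarray(X, float)
    classes = np.unique(y)
    ystar = (np.asarray(y) == classes.max()).astype(float)
    F = np.zeros(len(ystar))
    losses = []
    for s in model.stumps:
        F += model.shrinkage * np.where(X[:, s.feature] <= s.threshold, s.left, s.right)
        p = 1.0 / (1.0 + np.exp(-2.0 * F))
        eps = 1e-12
        losses.append(float(-np.mean(ystar * np.log(p + eps) + (1 - ystar) * np.log(1 - p + eps))))
    return losses


def stratified_folds(
    y: np.ndarray,
    n_folds: int,
    seed: int,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic stratified fold assignment, optionally group-aware.

    With ``groups`` (e.g. subject ids), all samples of a group land in the
    same fold; groups are dealt round-robin per class of their first
    member after a seeded shuffle.
    """
    y = np.asarray(y)
    n = len(y)
    rng = np.random.default_rng(seed)
    fold = np.empty(n, int)
    if groups is None:
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            fold[idx] = np.arange(len(idx)) % n_folds
    else:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        rng.shuffle(uniq)
        gclass = {g: y[groups == g][0] for g in uniq}
        counter: dict = {}
        for g in uniq:
            c = gclass[g]
            k = counter.get(c, 0)
            fold[groups == g] = k % n_folds
            counter[c] = k + 1
    return fold


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    n_iter: int = 100,
    shrinkage: float = 0.1,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Out-of-fold LogitBoost scores: each sample scored exactly once by a
    model that never saw it (stratified folds, deterministic given seed)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if len(y) < n_folds:
        raise ValueError("fewer samples than folds")
    for attempt in range(20):
        fold = stratified_folds(y, n_folds, seed + attempt, groups)
        ok = all(
            len(np.unique(y[fold != f])) == 2 for f in range(n_folds)
        )
        if ok:
            break
    else:
        raise ValueError("cannot stratify: a fold is missing a class")
    scores = np.empty(len(y))
    for f in range(n_folds):
        test = fold == f
        if not test.any():
            continue
        model = logitboost_fit(X[~test], y[~test], n_iter, shrinkage)
        scores[test] = predict_score(model, X[test])
    return scores
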