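"""Latent-variable class discrimination: PLS-DA, VIP scores, metrics.

Partial least squares discriminant analysis (PLS-DA) projects the
autoscaled feature matrix X onto a small number of latent components
chosen to maximize covariance with a class indicator y in {0, 1}. The
components are computed by the NIPALS sequence: for each component the
weight vector is proportional to X'y (unit norm), scores are t = X w,
and X is deflated by the rank-one score/loading product before the next
component. With a single binary response each component's inner loop
converges in one step, so the sequence is direct.

Variable importance in projection (VIP) summarizes each variable's
contribution to the explained class variance across components; the
mean of squared VIP over variables is exactly 1 by construction, so
VIP >= 1 marks above-average importance.

Model quality is reported as R2X / R2Y (fraction of X / y variance
captured by the components) and Q2(cum) = 1 - PRESS/SS from stratified
cross-validation with refitting; AUC / PPV / NPV / accuracy gauge
classification of continuous predicted responses at a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold


class ModelError(ValueError):
    """Raised for invalid model inputs (single class, rank deficits...)."""


def autoscale(X: np.ndarray):
    """Center to zero mean and scale to unit sample variance per column.

    Returns ``(scaled, centers, spreads)`` with ``spreads`` the ddof=1
    standard deviations. A constant column cannot be autoscaled and
    raises :class:`ModelError` naming its index (the caller may drop it).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ModelError("autoscale needs a 2-D matrix with at least 2 rows")
    centers = X.mean(axis=0)
    spreads = X.std(axis=0, ddof=1)
    constant = np.flatnonzero(spreads == 0)
    if constant.size:
        raise ModelError(f"constant column(s) at index {constant.tolist()}")
    return (X - centers) / spreads, centers, spreads


def unscale(X_scaled: np.ndarray, centers: np.ndarray, spreads: np.ndarray):
    """Inverse of :func:`autoscale`."""
    return np.asarray(X_scaled) * spreads + centers


@dataclass
class PLSModel:
    """A fitted NIPALS PLS-DA model (binary response).

    Matrices follow the usual conventions: ``weights`` W (variables x
    components, unit-norm columns), ``x_loadings`` P, ``x_scores`` T
    (samples x components), ``y_loadings`` c (per component), and
    regression ``coefficients`` b mapping autoscaled X to the centered
    response. ``scale_center``/``scale_spread`` are the training
    autoscaling parameters, ``y_mean`` the training class-indicator
    mean.
    """

    n_components: int
    weights: np.ndarray
    x_loadings: np.ndarray
    x_scores: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    scale_center: np.ndarray
    scale_spread: np.ndarray
    y_mean: float
    ssy_per_component: np.ndarray
    r2x_per_component: np.ndarray
    r2y_per_component: np.ndarray
    r2x_cum: float = field(init=False)
    r2y_cum: float = field(init=False)

    def __post_init__(self) -> None:
        self.r2x_cum = float(np.sum(self.r2x_per_component))
        self.r2y_cum = float(np.sum(self.r2y_per_component))

    @property
    def n_variables(self) -> int:
        return self.weights.shape[0]


def fit_plsda(X: np.ndarray, y: np.ndarray, n_components: int = 4) -> PLSModel:
    """Fit a PLS-DA model on raw X (autoscaled internally) and y in {0,1}."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ModelError("X and y disagree on sample count")
    classes = np.unique(y)
    if classes.size != 2:
        raise ModelError(f"need exactly 2 classes, got {classes.tolist()}")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ModelError(f"n_components={n_components} exceeds rank {rank}")

    Xs, centers, spreads = autoscale(X)
    y_mean = float(y.mean())
    yc = y - y_mean

    n, p = Xs.shape
    E = Xs.copy()
    f = yc.copy()
    ssx_total = float(np.sum(Xs**2))
    ssy_total = float(np.sum(yc**2))

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    c = np.zeros(n_components)
    ssy_comp = np.zeros(n_components)
    r2x_comp = np.zeros(n_components)
    r2y_comp = np.zeros(n_components)

    for a in range(n_components):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ModelError(f"component {a + 1}: degenerate weight vector")
        w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt == 0:
            raise ModelError(f"component {a + 1}: zero score vector")
        p_a = E.T @ t / tt
        c_a = float(f @ t / tt)
        ssx_before = float(np.sum(E**2))
        ssy_before = float(np.sum(f**2))
        E = E - np.outer(t, p_a)
        f = f - c_a * t
        W[:, a], P[:, a], T[:, a], c[a] = w, p_a, t, c_a
        ssy_comp[a] = c_a**2 * tt  # Y variance captured by component a
        r2x_comp[a] = (ssx_before - float(np.sum(E**2))) / ssx_total
        r2y_comp[a] = (ssy_before - float(np.sum(f**2))) / ssy_total

    # b = W (P'W)^-1 c reconstructs the fitted response from scaled X
    coefficients = W @ np.linalg.solve(P.T @ W, c)

    return PLSModel(
        n_components=n_components,
        weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=c,
        coefficients=coefficients,
        scale_center=centers,
        scale_spread=spreads,
        y_mean=y_mean,
        ssy_per_component=ssy_comp,
        r2x_per_component=r2x_comp,
        r2y_per_component=r2y_comp,
    )


def predict_scores(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Continuous predicted response for new samples (training scaling)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_variables:
        raise ModelError(
            f"expected {model.n_variables} variables, got {X_new.shape[1]}"
        )
    Xs = (X_new - model.scale_center) / model.scale_spread
    return model.y_mean + Xs @ model.coefficients


def predict_classes(model: PLSModel, X_new: np.ndarray, threshold: float = 0.5):
    """Class call at the response threshold (0.5 for {0,1} dummy coding)."""
    return (predict_scores(model, X_new) >= threshold).astype(int)


def vip_scores(model: PLSModel, upto_component: int | None = None) -> np.ndarray:
    """Cumulative VIP over components ``1..upto_component``.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ); the
    squared scores average to 1 over variables.
    """
    a = model.n_components if upto_component is None else int(upto_component)
    if not 1 <= a <= model.n_components:
        raise ModelError(f"upto_component must be in [1, {model.n_components}]")
    W = model.weights[:, :a]
    ssy = model.ssy_per_component[:a]
    wnorm2 = (W**2) / np.sum(W**2, axis=0, keepdims=True)
    p = model.n_variables
    return np.sqrt(p * (wnorm2 @ ssy) / np.sum(ssy))


def vip_per_component(model: PLSModel, component: int) -> np.ndarray:
    """Single-component VIP (the per-component importance profile)."""
    if not 1 <= component <= model.n_components:
        raise ModelError(f"component must be in [1, {model.n_components}]")
    w = model.weights[:, component - 1]
    p = model.n_variables
    return np.sqrt(p * w**2 / np.sum(w**2))


@dataclass
class BinaryMetrics:
    """Classification quality of continuous scores at a threshold."""

    auc: float
    ppv: float
    npv: float
    accuracy: float
    threshold: float


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by positive/negative pair counting with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ModelError("both classes must be present for AUC")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def binary_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> BinaryMetrics:
    """AUC plus PPV/NPV/accuracy of the threshold classifier.

    PPV (NPV) is NaN when no sample is called positive (negative).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    auc = auc_mann_whitney(scores, labels)
    called = (scores >= threshold).astype(int)
    tp = int(np.sum((called == 1) & (labels == 1)))
    fp = int(np.sum((called == 1) & (labels == 0)))
    tn = int(np.sum((called == 0) & (labels == 0)))
    fn = int(np.sum((called == 0) & (labels == 1)))
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    accuracy = (tp + tn) / labels.size
    return BinaryMetrics(auc=auc, ppv=ppv, npv=npv, accuracy=accuracy, threshold=threshold)


def model_metrics(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 4,
    cv_folds: int = 7,
    seed: int = 0,
):
    """(R2X cum, R2Y cum, Q2 cum) for a PLS-DA fit of ``X`` against ``y``.

    Q2(cum) = 1 - PRESS/SS over stratified ``cv_folds``-fold
    cross-validation with refitting in every fold; SS is taken about the
    training-fold response mean. Negative Q2 means the model predicts
    worse than the mean response.
    """
    if cv_folds < 2:
        raise ModelError("cv_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    model = fit_plsda(X, y, n_components)

    counts = np.bincount(y.astype(int))
    folds = min(cv_folds, counts.min())
    if folds < 2:
        raise ModelError("too few samples per class for cross-validation")
    press = ss = 0.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        sub = fit_plsda(X[train_idx], y[train_idx], min(n_components, len(train_idx) - 1))
        pred = predict_scores(sub, X[test_idx])
        press += float(np.sum((y[test_idx] - pred) ** 2))
        ss += float(np.sum((y[test_idx] - y[train_idx].mean()) ** 2))
    q2 = 1.0 - press / ss
    return model.r2x_cum, model.r2y_cum, float(q2)
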