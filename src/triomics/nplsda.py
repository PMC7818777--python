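"""N-way partial least squares discriminant analysis (NPLS-DA).

Trilinear PLS2 in the style of Bro: each component h finds the rank-1
feature x timepoint weight pair (w_j, w_k), both unit norm, that maximizes
the covariance between the tensor's mode-1 projection and the (residual)
response — obtained from the SVD of the covariance unfolding Z = X_(1)' Y.
Subject scores are t_h = X_(1) (w_j (x) w_k).  Only the response is
deflated (by regression of Y on the accumulated scores); the predictor
tensor is left intact, so scores are exact tensor contractions with the
weights at every component.

The discriminant layer is linear discriminant analysis (LDA) on the mode-1
scores; the inner PLS regression with a 0.5 cutoff on the dummy response is
available as an alternative rule.  R2Y and the cross-validated Q^2
(1 - PRESS/TSS) are computed on the continuous dummy response, and the
classification rate is reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

__all__ = ["NPLSDAModel", "CVResult", "fit_nplsda", "predict", "cross_validate"]


def _unfold1(x: np.ndarray) -> np.ndarray:
    return x.reshape(x.shape[0], -1)


def _dummy(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    if classes.size > 2:
        raise ValueError("only binary case/control labels are supported")
    y = np.column_stack([(labels == c).astype(float) for c in classes])
    return y, classes


@dataclass
class NPLSDAModel:
    """Fitted NPLS-DA model (weights, scores, inner regression, LDA rule)."""

    n_components: int
    mode1_scores: np.ndarray          # I x H
    mode2_weights: np.ndarray         # J x H, unit columns
    mode3_weights: np.ndarray         # K x H, unit columns
    response_weights: np.ndarray      # M x H (right singular vectors per component)
    coef: np.ndarray                  # H x M inner regression of Y on scores
    classes: np.ndarray
    x_mean: np.ndarray                # J x K centering offsets
    y_mean: np.ndarray
    r2x: float
    r2y: float
    component_r2y: np.ndarray         # per-component incremental explained Y SS
    ssy_explained: np.ndarray         # per-component explained response SS (for VIP)
    discriminant: str = "lda"
    lda: LinearDiscriminantAnalysis | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mode2_weights.shape[0], self.mode3_weights.shape[0]


def _component_weights(z: np.ndarray, J: int, K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best rank-1 (w_j, w_k, v) from the covariance unfolding Z (JK x M)."""
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    zvec = u[:, 0]
    v = vt[0]
    wj_mat = zvec.reshape(J, K)
    uj, sj, vjt = np.linalg.svd(wj_mat, full_matrices=False)
    w_j = uj[:, 0]
    w_k = vjt[0]
    # sign convention: largest-magnitude entries of w_k then w_j positive;
    # the joint flip keeps the rank-1 product, the w_j-only flip is absorbed
    # by the inner regression.  With K=1 this reduces scores and weights to
    # exactly those of two-way PLS with the same convention.
    if w_k[np.argmax(np.abs(w_k))] < 0:
        w_j, w_k = -w_j, -w_k
    if w_j[np.argmax(np.abs(w_j))] < 0:
        w_j = -w_j
    return w_j, w_k, v


def fit_nplsda(
    tensor_values: np.ndarray,
    labels: np.ndarray,
    n_components: int = 2,
    discriminant: str = "lda",
) -> NPLSDAModel:
    """Fit NPLS-DA on a complete I x J x K tensor with binary labels."""
    x = np.asarray(tensor_values, dtype=float)
    if x.ndim != 3:
        raise ValueError("predictor must be a 3-way array")
    labels = np.asarray(labels)
    I, J, K = x.shape
    if labels.shape[0] != I:
        raise ValueError("labels length must match the subject mode")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > I - 1:
        raise ValueError("n_components must be below the subject count")
    y, classes = _dummy(labels)

    x_mean = x.mean(axis=0)
    xc = _unfold1(x - x_mean)                # I x JK
    y_mean = y.mean(axis=0)
    yc = y - y_mean
    tss_y = float(np.sum(yc * yc))
    tss_x = float(np.sum(xc * xc))

    T = np.zeros((I, n_components))
    WJ = np.zeros((J, n_components))
    WK = np.zeros((K, n_components))
    V = np.zeros((y.shape[1], n_components))
    comp_r2y = np.zeros(n_components)
    ssy_exp = np.zeros(n_components)
    y_res = yc.copy()
    prev_res_ss = tss_y
    for h in range(n_components):
        z = xc.T @ y_res                      # JK x M covariance unfolding
        w_j, w_k, v = _component_weights(z, J, K)
        WJ[:, h] = w_j
        WK[:, h] = w_k
        V[:, h] = v
        T[:, h] = xc @ np.kron(w_j, w_k)
        # deflate the response by regression on all scores so far
        Th = T[:, : h + 1]
        coef_h, *_ = np.linalg.lstsq(Th, yc, rcond=None)
        y_res = yc - Th @ coef_h
        res_ss = float(np.sum(y_res * y_res))
        ssy_exp[h] = max(prev_res_ss - res_ss, 0.0)
        comp_r2y[h] = ssy_exp[h] / tss_y if tss_y > 0 else 0.0
        prev_res_ss = res_ss
    coef, *_ = np.linalg.lstsq(T, yc, rcond=None)
    r2y = 1.0 - float(np.sum((yc - T @ coef) ** 2)) / tss_y if tss_y > 0 else 0.0
    # X variance captured by projecting X onto the score space
    tt = T.T @ T
    proj = T @ np.linalg.solve(tt, T.T @ xc)
    r2x = 1.0 - float(np.sum((xc - proj) ** 2)) / tss_x if tss_x > 0 else 0.0

    lda = None
    if discriminant == "lda":
        lda = LinearDiscriminantAnalysis()
        lda.fit(T, labels)
    elif discriminant != "inner":
        raise ValueError("discriminant must be 'lda' or 'inner'")
    return NPLSDAModel(
        n_components=n_components,
        mode1_scores=T,
        mode2_weights=WJ,
        mode3_weights=WK,
        response_weights=V,
        coef=coef,
        classes=classes,
        x_mean=x_mean,
        y_mean=y_mean,
        r2x=r2x,
        r2y=r2y,
        component_r2y=comp_r2y,
        ssy_explained=ssy_exp,
        discriminant=discriminant,
        lda=lda,
    )


def _project(model: NPLSDAModel, tensor_values: np.ndarray) -> np.ndarray:
    x = np.asarray(tensor_values, dtype=float)
    if x.ndim != 3:
        raise ValueError("predictor must be a 3-way array")
    J, K = model.shape
    if x.shape[1] != J:
        raise ValueError(f"feature mode mismatch: model has {J}, data has {x.shape[1]}")
    if x.shape[2] != K:
        raise ValueError(f"timepoint mode mismatch: model has {K}, data has {x.shape[2]}")
    xc = _unfold1(x - model.x_mean)
    W = np.column_stack(
        [
            np.kron(model.mode2_weights[:, h], model.mode3_weights[:, h])
            for h in range(model.n_components)
        ]
    )
    return xc @ W


def predict(
    model: NPLSDAModel, tensor_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project new subjects and classify.

    Returns (class labels, mode-1 scores, class probabilities).  Ties in
    posterior probability resolve to the first class in sorted label order.
    """
    T = _project(model, tensor_values)
    if model.discriminant == "lda" and model.lda is not None:
        proba = model.lda.predict_proba(T)
    else:
        y_hat = T @ model.coef + model.y_mean
        # clip the continuous dummy prediction into a probability simplex
        p = np.clip(y_hat, 1e-9, None)
        proba = p / p.sum(axis=1, keepdims=True)
    # argmax takes the first class on exact ties; classes are sorted
    labels = model.classes[np.argmax(proba, axis=1)]
    return labels, T, proba


def predict_response(model: NPLSDAModel, tensor_values: np.ndarray) -> np.ndarray:
    """Continuous dummy-response prediction (for PRESS/Q^2)."""
    T = _project(model, tensor_values)
    return T @ model.coef + model.y_mean


@dataclass
class CVResult:
    scheme: str
    n_repeats: int
    r2_mean: float
    q2_mean: float
    q2_sd: float
    accuracy: float
    predictions: np.ndarray  # repeats x subjects predicted labels


def _fold_indices(
    scheme: str,
    labels: np.ndarray,
    rng: np.random.Generator,
    pair_ids: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(test, train) index pairs.

    With ``pair_ids`` the matched set is the exchangeable unit: after
    within-set normalization a subject's profile is determined by its
    partners', so partners of a held-out subject are always excluded from
    training.  LOO still performs one fit per subject; k-fold assigns whole
    sets to folds (each set holds both classes, keeping folds stratified).
    """
    n = labels.shape[0]
    all_idx = np.arange(n)
    if scheme == "loo":
        tests = [np.array([i]) for i in range(n)]
        if pair_ids is None:
            return [(t, np.setdiff1d(all_idx, t)) for t in tests]
        return [
            (t, np.flatnonzero(pair_ids != pair_ids[t[0]])) for t in tests
        ]
    k = {"5fold": 5, "kfold5": 5, "10fold": 10, "kfold10": 10}.get(scheme)
    if k is None:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    if pair_ids is not None:
        pairs = np.unique(pair_ids)
        if k > pairs.size:
            raise ValueError(f"{k}-fold CV needs at least {k} matched sets")
        order = rng.permutation(pairs)
        folds = np.array_split(order, k)
        out = []
        for f in folds:
            test = np.flatnonzero(np.isin(pair_ids, f))
            out.append((test, np.setdiff1d(all_idx, test)))
        return out
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(f"{k}-fold CV needs at least {k} samples per class")
    skf = StratifiedKFold(
        n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    return [
        (test, np.setdiff1d(all_idx, test))
        for _, test in skf.split(np.zeros(n), labels)
    ]


def cross_validate(
    tensor_values: np.ndarray,
    labels: np.ndarray,
    n_components: int = 2,
    scheme: str = "loo",
    n_repeats: int = 1,
    seed: int = 0,
    discriminant: str = "lda",
    pair_ids: np.ndarray | None = None,
) -> CVResult:
    """Cross-validated R^2, Q^2 and classification accuracy.

    Q^2 = 1 - PRESS/TSS on the centered dummy response, pooling held-out
    predictions over folds.  LOO is deterministic (one fit per subject and
    no repeat randomness); k-fold schemes are stratified by class and
    averaged over ``n_repeats`` random fold assignments.  When ``pair_ids``
    are given, a held-out subject's matched partners never enter its
    training fold: after within-set normalization partners carry each
    other's profiles, and splitting a set across folds leaks the label.
    """
    x = np.asarray(tensor_values, dtype=float)
    labels = np.asarray(labels)
    y, _ = _dummy(labels)
    tss = float(np.sum((y - y.mean(axis=0)) ** 2))
    rng = np.random.default_rng(seed)
    if scheme == "loo":
        n_repeats = 1
    q2s, r2s, accs = [], [], []
    all_preds = []
    for _ in range(n_repeats):
        folds = _fold_indices(scheme, labels, rng, pair_ids)
        press = 0.0
        preds = np.empty(labels.shape, dtype=labels.dtype)
        fold_r2 = []
        for test, train in folds:
            model = fit_nplsda(
                x[train], labels[train], n_components, discriminant=discriminant
            )
            fold_r2.append(model.r2y)
            y_hat = predict_response(model, x[test])
            press += float(np.sum((y[test] - y_hat) ** 2))
            preds[test], _, _ = predict(model, x[test])
        q2s.append(1.0 - press / tss)
        r2s.append(float(np.mean(fold_r2)))
        accs.append(float(np.mean(preds == labels)))
        all_preds.append(preds)
    return CVResult(
        scheme=scheme,
        n_repeats=n_repeats,
        r2_mean=float(np.mean(r2s)),
        q2_mean=float(np.mean(q2s)),
        q2_sd=float(np.std(q2s)),
        accuracy=float(np.mean(accs)),
        predictions=np.array(all_preds),
    )
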