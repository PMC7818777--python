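"""Permutation-based model validation and per-timepoint LDA validation.

Two permutation modes assess the selected feature set:

* ``random_features`` — the observed R^2/Q^2 of the VIP-selected set are
  compared against models refit on random feature sets of the same size.
* ``permuted_labels`` — case/control roles are flipped within matched pairs
  (the exchangeable unit under the paired design), the model refit, and the
  resulting null R^2/Q^2 recorded.

p = (1 + #{null >= observed}) / (n_permutations + 1), one-sided.

Subjects excluded from model building (fewer than 3 observed timepoints)
cannot enter the 3-way model; they are classified per timepoint by an LDA
trained on the analysis subjects' selected-feature slice at that timepoint,
with shrinkage when features outnumber samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .nplsda import cross_validate, fit_nplsda

__all__ = ["PermutationResult", "TimepointValidation", "permutation_test", "timepoint_validate"]


@dataclass
class PermutationResult:
    mode: str
    n_permutations: int
    observed_r2: float
    observed_q2: float
    null_r2: np.ndarray
    null_q2: np.ndarray
    p_r2: float
    p_q2: float


@dataclass
class TimepointValidation:
    timepoints: list[int]
    n_samples: list[int]
    accuracy: list[float]          # NaN where not evaluable
    predictions: dict[int, np.ndarray]


def _model_stats(
    x: np.ndarray,
    labels: np.ndarray,
    cols: np.ndarray,
    n_components: int,
    cv_scheme: str,
    seed: int,
    pair_ids: np.ndarray | None = None,
) -> tuple[float, float]:
    sub = x[:, cols, :]
    H = min(n_components, max(1, len(cols)))
    model = fit_nplsda(sub, labels, H)
    cv = cross_validate(sub, labels, H, scheme=cv_scheme, seed=seed, pair_ids=pair_ids)
    return model.r2y, cv.q2_mean


def permutation_test(
    tensor_values: np.ndarray,
    labels: np.ndarray,
    feature_ids: list[str],
    selected_ids: list[str],
    mode: str = "random_features",
    n_permutations: int = 100,
    n_components: int = 2,
    cv_scheme: str = "5fold",
    seed: int = 0,
    pair_ids: np.ndarray | None = None,
    paired: bool = True,
) -> PermutationResult:
    """One-sided permutation p-values for R^2 and Q^2 of the selected set."""
    if not selected_ids:
        raise ValueError("selected_ids is empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(tensor_values, dtype=float)
    labels = np.asarray(labels)
    f_index = {f: j for j, f in enumerate(feature_ids)}
    sel_cols = np.array(sorted(f_index[f] for f in selected_ids))
    J = x.shape[1]
    if mode == "random_features" and sel_cols.size >= J:
        raise ValueError("selected set covers the feature universe; nothing to randomize")
    rng = np.random.default_rng(seed)

    obs_r2, obs_q2 = _model_stats(
        x, labels, sel_cols, n_components, cv_scheme, seed, pair_ids
    )

    null_r2 = np.empty(n_permutations)
    null_q2 = np.empty(n_permutations)
    for b in range(n_permutations):
        if mode == "random_features":
            cols = rng.choice(J, size=sel_cols.size, replace=False)
            perm_labels = labels
        elif mode == "permuted_labels":
            cols = sel_cols
            perm_labels = _permute_labels(labels, pair_ids, paired, rng)
        else:
            raise ValueError(f"unknown permutation mode {mode!r}")
        null_r2[b], null_q2[b] = _model_stats(
            x, perm_labels, np.sort(cols), n_components, cv_scheme,
            int(rng.integers(2**31 - 1)), pair_ids,
        )
    p_r2 = (1.0 + np.sum(null_r2 >= obs_r2)) / (n_permutations + 1.0)
    p_q2 = (1.0 + np.sum(null_q2 >= obs_q2)) / (n_permutations + 1.0)
    return PermutationResult(
        mode, n_permutations, obs_r2, obs_q2, null_r2, null_q2, float(p_r2), float(p_q2)
    )


def _permute_labels(
    labels: np.ndarray,
    pair_ids: np.ndarray | None,
    paired: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    out = labels.copy()
    if paired and pair_ids is not None:
        for pid in np.unique(pair_ids):
            idx = np.flatnonzero(pair_ids == pid)
            if rng.random() < 0.5:
                # flip the case/control roles within the set
                is_case = labels[idx] == "case"
                out[idx[is_case]] = "control"
                ctl = idx[~is_case]
                if ctl.size:
                    out[ctl[int(rng.integers(ctl.size))]] = "case"
    else:
        out = rng.permutation(labels)
    return out


def timepoint_validate(
    train_values: np.ndarray,
    train_labels: np.ndarray,
    feature_ids: list[str],
    selected_ids: list[str],
    val_values: np.ndarray,
    val_mask: np.ndarray,
    val_labels: np.ndarray,
    timepoints: list[int],
    train_timepoint: int | None = None,
) -> TimepointValidation:
    """Per-timepoint LDA validation on subjects outside the model build.

    For each timepoint an LDA is trained on the analysis subjects'
    selected-feature slice (at ``train_timepoint`` if given, supporting
    cross-timepoint prediction; otherwise at the same timepoint) and applied
    to the validation subjects observed there.  Training values are
    typically within-set normalized while validation subjects, lacking
    complete pairs, are raw, so both slices are mean-centered per feature
    to put them on a common scale.  Timepoints with fewer than two
    evaluable samples or a single observed class are reported as NaN.
    """
    f_index = {f: j for j, f in enumerate(feature_ids)}
    cols = np.array(sorted(f_index[f] for f in selected_ids))
    accs: list[float] = []
    ns: list[int] = []
    preds: dict[int, np.ndarray] = {}
    for k, tp in enumerate(timepoints):
        k_train = k if train_timepoint is None else timepoints.index(train_timepoint)
        x_tr = train_values[:, cols, k_train]
        obs = val_mask[:, :, k].any(axis=1)
        idx = np.flatnonzero(obs)
        if idx.size < 2 or np.unique(val_labels[idx]).size < 2:
            accs.append(float("nan"))
            ns.append(int(idx.size))
            continue
        n, p = x_tr.shape
        if p >= n:
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        else:
            lda = LinearDiscriminantAnalysis()
        lda.fit(x_tr - x_tr.mean(axis=0), train_labels)
        x_val = val_values[idx][:, cols, k]
        yhat = lda.predict(x_val - x_val.mean(axis=0))
        preds[tp] = yhat
        accs.append(float(np.mean(yhat == val_labels[idx])))
        ns.append(int(idx.size))
    return TimepointValidation(list(timepoints), ns, accs, preds)
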