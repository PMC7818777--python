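"""Tucker3 decomposition, DIFFIT rank selection, and model-based imputation.

Tucker3 factors a 3-way array X (I x J x K) into a small core G (P x Q x R)
and three column-orthonormal loading matrices A (I x P), B (J x Q), C (K x R)
so that X ~ G x1 A x2 B x3 C.  Fitting is by higher-order orthogonal
iteration (alternating least squares from an HOSVD start), which makes the
explained sum of squares non-decreasing across iterations.

Missing cells are imputed by the classic fill-fit-replace loop: initialize
missing cells with the observed mean, fit a Tucker3 model, replace the
missing cells with the model reconstruction, and iterate until the imputed
values stop moving (relative change below ``tol``, default 1e-7).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .tensors import OmicsTensor

logger = logging.getLogger(__name__)

__all__ = [
    "Tucker3Model",
    "ImputationReport",
    "tucker3_fit",
    "diffit_select",
    "impute_missing",
]


def unfold(x: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding (mode becomes rows, remaining modes in C order)."""
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def multi_mode_dot(core: np.ndarray, mats: list[np.ndarray]) -> np.ndarray:
    """core x1 mats[0] x2 mats[1] x3 mats[2]."""
    out = core
    for mode, m in enumerate(mats):
        out = np.moveaxis(np.tensordot(m, out, axes=(1, mode)), 0, mode)
    return out


@dataclass
class Tucker3Model:
    core: np.ndarray
    loadings: tuple[np.ndarray, np.ndarray, np.ndarray]
    ranks: tuple[int, int, int]
    fit: float
    n_iterations: int
    converged: bool
    fit_history: list[float] = None

    def reconstruct(self) -> np.ndarray:
        return multi_mode_dot(self.core, list(self.loadings))


@dataclass
class ImputationReport:
    n_imputed_cells: int
    fraction_imputed: float
    iterations: int
    final_change: float
    converged: bool
    ranks: tuple[int, int, int]


def _leading_left_sv(x: np.ndarray, r: int) -> np.ndarray:
    u, _, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :r]


def tucker3_fit(
    values: np.ndarray,
    ranks: tuple[int, int, int],
    tol: float = 1e-8,
    max_iter: int = 200,
) -> Tucker3Model:
    """Fit a Tucker3 model by HOOI (ALS) from an HOSVD start.

    ``fit`` is the fraction of the total sum of squares explained,
    ||G||^2 / ||X||^2, which with orthonormal loadings equals
    1 - ||X - Xhat||^2 / ||X||^2.  The fit sequence is non-decreasing; the
    loop stops when its relative change drops below ``tol``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected a 3-way array")
    for mode, r in enumerate(ranks):
        if not (1 <= r <= x.shape[mode]):
            raise ValueError(
                f"rank {r} invalid for mode {mode} of dimension {x.shape[mode]}"
            )
    total_ss = float(np.sum(x * x))
    if total_ss == 0.0:
        raise ValueError("zero tensor: Tucker3 fit undefined")

    # HOSVD initialization: leading singular vectors of each unfolding
    mats = [_leading_left_sv(unfold(x, m), r) for m, r in enumerate(ranks)]

    fit_prev = -np.inf
    fit = 0.0
    converged = False
    it = 0
    history: list[float] = []
    for it in range(1, max_iter + 1):
        for mode in range(3):
            others = [m for m in range(3) if m != mode]
            y = x
            for m in others:
                y = np.moveaxis(
                    np.tensordot(mats[m].T, y, axes=(1, m)), 0, m
                )
            mats[mode] = _leading_left_sv(unfold(y, mode), ranks[mode])
        core = multi_mode_dot(x, [m.T for m in mats])
        fit = float(np.sum(core * core) / total_ss)
        history.append(fit)
        if fit + 1e-10 < fit_prev:
            raise RuntimeError("ALS fit decreased; numerical failure")
        if fit_prev > -np.inf and (fit - fit_prev) <= tol * max(fit_prev, 1e-300):
            converged = True
            break
        fit_prev = fit
    core = multi_mode_dot(x, [m.T for m in mats])
    return Tucker3Model(
        core=core,
        loadings=tuple(mats),
        ranks=tuple(ranks),
        fit=min(fit, 1.0),
        n_iterations=it,
        converged=converged,
        fit_history=history,
    )


def diffit_select(
    values: np.ndarray,
    max_total_rank: int = 9,
    min_salience: float = 1e-4,
    elbow_ratio: float = 3.0,
) -> tuple[int, int, int]:
    """Choose Tucker3 ranks by the difference-in-fit (DIFFIT) heuristic.

    All rank triples with P+Q+R <= ``max_total_rank`` are fitted; for every
    total rank s the best fit is kept.  With dif(s) = fit(s) - fit(s-1)
    (dif(3) = fit(1,1,1) against the zero model), the selected s maximizes
    dif(s) relative to the largest gain achievable at any higher total —
    a sharp elbow means every later gain is small, which is robust to the
    occasional flat ALS step that can zero out a single dif value.  Two
    guards keep the rule parsimonious on structureless data: totals with
    gain below ``min_salience`` of the total sum of squares are not
    candidates, and if no candidate's elbow statistic reaches
    ``elbow_ratio`` (noise-like smoothly decaying gains), the minimal
    triple (1,1,1) is returned.  Ties break toward the smaller total rank.
    """
    x = np.asarray(values, dtype=float)
    if max_total_rank < 3:
        raise ValueError("max_total_rank must be at least 3")
    dims = x.shape
    best_fit: dict[int, float] = {}
    best_triple: dict[int, tuple[int, int, int]] = {}
    for p, q, r in itertools.product(
        range(1, dims[0] + 1), range(1, dims[1] + 1), range(1, dims[2] + 1)
    ):
        s = p + q + r
        if s > max_total_rank:
            continue
        # a Tucker3 rank cannot usefully exceed the product of the others
        if p > q * r or q > p * r or r > p * q:
            continue
        fit = tucker3_fit(x, (p, q, r)).fit
        if fit > best_fit.get(s, -1.0) + 1e-12:
            best_fit[s] = fit
            best_triple[s] = (p, q, r)
    totals = sorted(best_fit)
    # enforce monotone best-fit sequence (ALS local optima can dent it)
    for a, b in zip(totals, totals[1:]):
        best_fit[b] = max(best_fit[b], best_fit[a])
    dif = {totals[0]: best_fit[totals[0]]}
    for a, b in zip(totals, totals[1:]):
        dif[b] = best_fit[b] - best_fit[a]
    floor = 1e-9
    best_s = totals[0]
    best_ratio = -np.inf
    for i, s in enumerate(totals[:-1]):
        if dif[s] < min_salience:
            continue
        later = max(dif[t] for t in totals[i + 1 :])
        ratio = dif[s] / max(later, floor)
        if ratio > best_ratio + 1e-12:
            best_ratio = ratio
            best_s = s
    if best_ratio < elbow_ratio:
        return best_triple[totals[0]]
    return best_triple[best_s]


def impute_missing(
    tensor: OmicsTensor,
    ranks: tuple[int, int, int] | str = "diffit",
    tol: float = 1e-7,
    max_iter: int = 200,
    max_total_rank: int = 9,
) -> tuple[OmicsTensor, ImputationReport]:
    """Impute missing cells by iterative Tucker3 fill-fit-replace.

    Missing cells start at the mean of the observed cells; at each iteration
    a Tucker3 model is fitted to the filled tensor and the missing cells are
    replaced with the model reconstruction.  Convergence when the relative
    change in the sum of squared differences of the imputed cells between
    successive iterations drops below ``tol`` (default 1e-7).  Observed
    cells are never altered; the output mask still marks imputed cells False.
    """
    missing = ~tensor.mask
    n_missing = int(missing.sum())
    frac = n_missing / tensor.values.size
    if n_missing == 0:
        report = ImputationReport(0, 0.0, 0, 0.0, True, (0, 0, 0))
        return tensor, report

    filled = tensor.values.copy()
    obs_mean = float(tensor.values[tensor.mask].mean())
    filled[missing] = obs_mean

    if ranks == "diffit":
        use_ranks = diffit_select(filled, max_total_rank=max_total_rank)
    else:
        use_ranks = tuple(ranks)  # type: ignore[arg-type]

    change = np.inf
    converged = False
    it = 0
    prev_imputed = filled[missing].copy()
    for it in range(1, max_iter + 1):
        model = tucker3_fit(filled, use_ranks)
        new_imputed = model.reconstruct()[missing]
        filled[missing] = new_imputed
        denom = float(np.sum(new_imputed * new_imputed)) or 1.0
        change = float(np.sum((new_imputed - prev_imputed) ** 2)) / denom
        prev_imputed = new_imputed.copy()
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"imputation did not converge in {max_iter} iterations "
            f"(last relative change {change:.3g})",
            RuntimeWarning,
        )
    out = OmicsTensor(
        values=filled,
        mask=tensor.mask.copy(),
        subject_ids=list(tensor.subject_ids),
        feature_ids=list(tensor.feature_ids),
        timepoints=list(tensor.timepoints),
        block=tensor.block,
    )
    report = ImputationReport(
        n_imputed_cells=n_missing,
        fraction_imputed=frac,
        iterations=it,
        final_change=change,
        converged=converged,
        ranks=tuple(use_ranks),
    )
    return out, report
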