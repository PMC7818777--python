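"""Variable importance for projection (VIP) and combinatorial selection.

Wold's VIP for a PLS model with unit-norm per-component weights w_h and
per-component explained response sum of squares SSY_h:

    VIP_j = sqrt( p * sum_h SSY_h * w_jh^2 / sum_h SSY_h )

so that sum_j VIP_j^2 = p (the number of predictor variables).  Three data
arrangements are supported:

* ``vip2d`` — the 3-way array is matricized to subjects x (features x
  timepoints) and standard two-way VIP computed, giving one value per
  variable per timepoint; the per-variable score collapses over timepoints
  (max by default, mean optional).
* ``vip3d_model1`` — the time mode is constrained: only the mode-2 (feature)
  weights of the trilinear model enter, giving one VIP per variable.
* ``vip3d_model2`` — VIP is computed per variable per timepoint per
  component from the Kronecker element w_jh * w_kh, then summed over
  timepoints and averaged over components.

Selected variables are those strictly above a per-block percentile of the
VIP distribution (99th for gene expression, 95th for metabolomics in the
default setup); the union/intersection search refits candidate feature sets
and keeps the one with the best cross-validated Q^2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .nplsda import NPLSDAModel, cross_validate, fit_nplsda

__all__ = [
    "VIPSelection",
    "compute_vip",
    "select_by_percentile",
    "search_best_set",
]

STRATEGIES = ("vip2d", "vip3d_model1", "vip3d_model2")


@dataclass
class VIPSelection:
    strategy: str
    feature_ids: list[str]
    vip_values: np.ndarray                       # one score per variable
    per_timepoint: np.ndarray | None = None      # J x K (vip2d / model2)
    percentile_threshold: float | None = None
    selected_ids: list[str] = field(default_factory=list)
    candidate_provenance: str = ""
    r2: float | None = None
    q2: float | None = None


def _two_way_vip(weights: np.ndarray, ssy: np.ndarray) -> np.ndarray:
    """Wold VIP for a two-way model: weights p x H (unit columns), ssy H."""
    p = weights.shape[0]
    denom = ssy.sum()
    if denom <= 0:
        return np.zeros(p)
    return np.sqrt(p * (weights**2 @ ssy) / denom)


def compute_vip(
    model: NPLSDAModel | None,
    tensor_values: np.ndarray,
    labels: np.ndarray,
    feature_ids: list[str],
    strategy: str = "vip3d_model1",
    n_components: int | None = None,
    collapse_2d: str = "max",
) -> VIPSelection:
    """Compute VIP values per variable under one of the three arrangements."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown VIP strategy {strategy!r}")
    x = np.asarray(tensor_values, dtype=float)
    I, J, K = x.shape
    if len(feature_ids) != J:
        raise ValueError("feature_ids length must match the feature mode")

    if strategy == "vip2d":
        # matricize: each feature x timepoint column is its own variable,
        # modelled as a single-timepoint tensor (equivalent to two-way PLS)
        flat = x.reshape(I, J * K, 1)
        H = n_components or (model.n_components if model else 2)
        m2 = fit_nplsda(flat, labels, H)
        vip_flat = _two_way_vip(m2.mode2_weights, m2.ssy_explained)  # J*K
        per_tp = vip_flat.reshape(J, K)
        if collapse_2d == "max":
            per_var = per_tp.max(axis=1)
        elif collapse_2d == "mean":
            per_var = per_tp.mean(axis=1)
        else:
            raise ValueError("collapse_2d must be 'max' or 'mean'")
        return VIPSelection(strategy, list(feature_ids), per_var, per_timepoint=per_tp)

    if model is None:
        model = fit_nplsda(x, labels, n_components or 2)
    ssy = model.ssy_explained
    if strategy == "vip3d_model1":
        # time mode constrained: feature weights only, normalized over J
        per_var = _two_way_vip(model.mode2_weights, ssy)
        return VIPSelection(strategy, list(feature_ids), per_var)

    # vip3d_model2: per variable per timepoint per component from the
    # Kronecker weight element, summed over time, mean over components
    denom = ssy.sum()
    Hn = model.n_components
    per_tp_comp = np.zeros((J, K, Hn))
    for h in range(Hn):
        w = np.outer(model.mode2_weights[:, h], model.mode3_weights[:, h])
        if denom > 0:
            per_tp_comp[:, :, h] = np.sqrt(J * K * ssy[h] * w**2 / denom)
    per_var = per_tp_comp.sum(axis=1).mean(axis=1)
    return VIPSelection(
        strategy, list(feature_ids), per_var, per_timepoint=per_tp_comp.mean(axis=2)
    )


def select_by_percentile(selection: VIPSelection, percentile: float) -> VIPSelection:
    """Keep variables with VIP strictly greater than the given percentile.

    The percentile is computed by linear interpolation over the selection's
    own VIP distribution; ties at the threshold are excluded.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must lie in (0, 100)")
    vips = selection.vip_values
    if vips.size == 0:
        raise ValueError("empty VIP value vector")
    cut = float(np.percentile(vips, percentile))
    keep = vips > cut
    selection.percentile_threshold = percentile
    selection.selected_ids = [f for f, k in zip(selection.feature_ids, keep) if k]
    return selection


def search_best_set(
    selections: list[VIPSelection],
    tensor_values: np.ndarray,
    labels: np.ndarray,
    feature_ids: list[str],
    n_components: int = 2,
    cv_scheme: str = "5fold",
    seed: int = 0,
    pair_ids: np.ndarray | None = None,
) -> tuple[VIPSelection, list[dict]]:
    """Evaluate per-strategy sets and their unions/intersections.

    Candidates are the (non-empty, deduplicated) base sets plus all pairwise
    and three-way unions and intersections.  Each candidate is refit and
    cross-validated; the winner has the highest Q^2, ties broken by higher
    R^2 and then by smaller set size.  Returns the winning selection and the
    full candidate log.
    """
    x = np.asarray(tensor_values, dtype=float)
    f_index = {f: j for j, f in enumerate(feature_ids)}
    base = {s.strategy: frozenset(s.selected_ids) for s in selections}
    candidates: dict[frozenset, str] = {}
    for name, ids in base.items():
        if ids:
            candidates.setdefault(ids, name)
    for a, b in itertools.combinations(base, 2):
        for op, ids in (("|", base[a] | base[b]), ("&", base[a] & base[b])):
            if ids:
                candidates.setdefault(ids, f"{a}{op}{b}")
    if len(base) == 3:
        names = list(base)
        u3 = base[names[0]] | base[names[1]] | base[names[2]]
        i3 = base[names[0]] & base[names[1]] & base[names[2]]
        if u3:
            candidates.setdefault(u3, "union_all")
        if i3:
            candidates.setdefault(i3, "intersection_all")
    if not candidates:
        raise ValueError("all candidate feature sets are empty")

    log: list[dict] = []
    best: tuple | None = None
    for ids, prov in candidates.items():
        cols = sorted(f_index[f] for f in ids)
        H = min(n_components, max(1, len(cols)))
        cv = cross_validate(
            x[:, cols, :], labels, n_components=H, scheme=cv_scheme, seed=seed,
            pair_ids=pair_ids,
        )
        entry = {
            "set": prov,
            "size": len(cols),
            "r2": cv.r2_mean,
            "q2": cv.q2_mean,
            "features": sorted(ids),
        }
        log.append(entry)
        key = (cv.q2_mean, cv.r2_mean, -len(cols))
        if best is None or key > best[0]:
            best = (key, ids, prov, cv)
    _, ids, prov, cv = best
    winner = VIPSelection(
        strategy="search",
        feature_ids=list(feature_ids),
        vip_values=np.zeros(len(feature_ids)),
        selected_ids=sorted(ids),
        candidate_provenance=prov,
        r2=cv.r2_mean,
        q2=cv.q2_mean,
    )
    return winner, log
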