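"""Time-window partial-correlation networks over the selected signature.

Disease-progression dynamics are captured by differencing normalized case
profiles between consecutive timepoints, yielding four windows (12to9,
9to6, 6to3, 3to0 months before seroconversion).  Within each window an
elastic-net bootstrap selects high-variability features, full-order partial
correlations are computed from a (shrunk) precision matrix, edges with
|pcor| above a threshold (default 0.7) form the network, and windows are
compared by excess kurtosis and two-sample Kolmogorov-Smirnov tests on
their correlation-value distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.covariance import LedoitWolf
from sklearn.linear_model import LogisticRegression

__all__ = [
    "DeltaWindow",
    "PcorNetwork",
    "delta_profiles",
    "elastic_net_select",
    "partial_correlations",
    "build_network",
    "compare_windows",
]


@dataclass
class DeltaWindow:
    label: str
    matrix: np.ndarray            # subjects x features, later minus earlier
    feature_ids: list[str]
    subject_ids: list[str]
    from_tp: int
    to_tp: int
    #: subjects with either endpoint unobserved before imputation
    incomplete_subjects: list[str] = field(default_factory=list)


@dataclass
class PcorNetwork:
    window: str
    threshold: float
    graph: nx.Graph

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def delta_profiles(
    values: np.ndarray,
    mask: np.ndarray,
    subject_ids: list[str],
    feature_ids: list[str],
    timepoints: list[int],
    labels: np.ndarray | None = None,
    subjects: str = "cases",
    feature_cols: list[int] | None = None,
) -> list[DeltaWindow]:
    """Consecutive-timepoint difference profiles (later minus earlier).

    Timepoints are ordered by descending MBSC, so window ``12to9`` is
    values at 9 MBSC minus values at 12 MBSC: the change as the subject
    moves toward seroconversion.  By default only case subjects' normalized
    values are used.
    """
    if len(timepoints) < 5:
        raise ValueError("delta profiles require the full 5-timepoint design")
    x = np.asarray(values, dtype=float)
    if subjects == "cases":
        if labels is None:
            raise ValueError("labels required to restrict to cases")
        rows = np.flatnonzero(np.asarray(labels) == "case")
    else:
        rows = np.arange(x.shape[0])
    cols = np.arange(x.shape[1]) if feature_cols is None else np.asarray(feature_cols)
    windows = []
    for k in range(len(timepoints) - 1):
        earlier, later = timepoints[k], timepoints[k + 1]
        delta = x[np.ix_(rows, cols, [k + 1])][:, :, 0] - x[np.ix_(rows, cols, [k])][:, :, 0]
        incomplete = [
            subject_ids[i]
            for i in rows
            if not (mask[i, :, k].any() and mask[i, :, k + 1].any())
        ]
        windows.append(
            DeltaWindow(
                label=f"{earlier}to{later}",
                matrix=delta,
                feature_ids=[feature_ids[j] for j in cols],
                subject_ids=[subject_ids[i] for i in rows],
                from_tp=earlier,
                to_tp=later,
                incomplete_subjects=incomplete,
            )
        )
    return windows


def elastic_net_select(
    window: DeltaWindow,
    response: np.ndarray,
    alpha_grid: np.ndarray | None = None,
    n_tune: int = 100,
    n_final: int = 1000,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[list[str], float]:
    """Bootstrap elastic-net feature selection within one window.

    For each mixing value alpha in the ridge-to-lasso grid, ``n_tune``
    logistic elastic-net fits on bootstrap resamples are scored by deviance
    on the out-of-bootstrap samples; the alpha with the best mean deviance
    wins.  ``n_final`` bootstrap fits at the winning alpha then collect
    every feature with a nonzero coefficient in at least one fit.

    Returns (selected feature ids, winning alpha).
    """
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.0, 1.01, 0.1), 2)
    X = window.matrix
    keep = X.std(axis=0) > 0
    if not keep.all():
        import warnings

        warnings.warn(
            f"window {window.label}: dropping {int((~keep).sum())} constant features"
        )
    X = X[:, keep]
    feat = [f for f, k in zip(window.feature_ids, keep) if k]
    y = np.asarray(response)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("elastic-net response must be binary")
    y01 = (y == classes[1]).astype(int)
    rng = np.random.default_rng(seed)
    n = X.shape[0]

    def _fit(alpha: float, rows: np.ndarray) -> LogisticRegression | None:
        if np.unique(y01[rows]).size < 2:
            return None
        lr = LogisticRegression(
            solver="saga", l1_ratio=float(alpha), C=C, max_iter=2000, tol=1e-4,
            random_state=int(rng.integers(2**31 - 1)),
        )
        lr.fit(X[rows], y01[rows])
        return lr

    mean_dev = []
    for alpha in alpha_grid:
        devs = []
        for _ in range(n_tune):
            rows = rng.integers(n, size=n)
            oob = np.setdiff1d(np.arange(n), rows)
            lr = _fit(alpha, rows)
            if lr is None or oob.size == 0 or np.unique(y01[oob]).size < 2:
                continue
            p = np.clip(lr.predict_proba(X[oob])[:, 1], 1e-12, 1 - 1e-12)
            devs.append(-2.0 * np.mean(y01[oob] * np.log(p) + (1 - y01[oob]) * np.log(1 - p)))
        mean_dev.append(np.mean(devs) if devs else np.inf)
    winning_alpha = float(alpha_grid[int(np.argmin(mean_dev))])

    hit = np.zeros(X.shape[1], dtype=bool)
    for _ in range(n_final):
        rows = rng.integers(n, size=n)
        lr = _fit(winning_alpha, rows)
        if lr is not None:
            hit |= np.abs(lr.coef_[0]) > 1e-10
    return [f for f, h in zip(feat, hit) if h], winning_alpha


def partial_correlations(matrix: np.ndarray, shrink: str = "auto") -> np.ndarray:
    """Full-order partial correlations from the (shrunk) precision matrix.

    pcor(i, j) = -P_ij / sqrt(P_ii * P_jj) with unit diagonal.  When the
    sample size does not comfortably exceed the number of variables
    (n <= p + 10), the covariance is shrunk toward its scaled identity with
    the Ledoit-Wolf analytic intensity before inversion; otherwise the
    empirical covariance is inverted directly (``shrink='never'`` forces
    the unregularized route, ``'always'`` forces shrinkage).
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if p < 3:
        raise ValueError("partial correlations need at least 3 variables")
    if n < 4:
        raise ValueError("partial correlations need at least 4 samples")
    corr = np.corrcoef(X, rowvar=False)
    off = np.abs(corr - np.eye(p))
    if off.max() > 1 - 1e-12:
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            f"perfectly collinear feature pair (columns {i}, {j}): "
            "precision matrix is singular"
        )
    use_shrink = {"auto": n <= p + 10, "always": True, "never": False}[shrink]
    if use_shrink:
        cov = LedoitWolf(assume_centered=False).fit(X).covariance_
    else:
        cov = np.cov(X, rowvar=False)
    P = np.linalg.pinv(cov)
    d = np.sqrt(np.diag(P))
    pcor = -P / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip((pcor + pcor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def build_network(
    pcor: np.ndarray,
    feature_ids: list[str],
    threshold: float = 0.7,
    kinds: dict[str, str] | None = None,
    node_values: dict[str, float] | None = None,
    window: str = "",
    keep_isolated: bool = True,
) -> PcorNetwork:
    """Threshold a partial-correlation matrix into an annotated graph.

    Edges keep pairs with |pcor| strictly greater than ``threshold`` and are
    annotated with the correlation sign; nodes carry their molecule kind
    (gene / metabolite / vitamin) and the mean normalized case value at the
    window's first timepoint, whose sign encodes up/down regulation.
    """
    pcor = np.asarray(pcor)
    if pcor.shape[0] != pcor.shape[1] or not np.allclose(pcor, pcor.T, atol=1e-8):
        raise ValueError("expected a square symmetric matrix")
    g = nx.Graph()
    for f in feature_ids:
        val = (node_values or {}).get(f, 0.0)
        g.add_node(
            f,
            kind=(kinds or {}).get(f, "gene"),
            mean_case_value=float(val),
            regulation="up" if val > 0 else ("down" if val < 0 else "flat"),
        )
    p = len(feature_ids)
    for i in range(p):
        for j in range(i + 1, p):
            w = float(pcor[i, j])
            if abs(w) > threshold:
                g.add_edge(
                    feature_ids[i],
                    feature_ids[j],
                    weight=w,
                    sign="positive" if w > 0 else "negative",
                )
    if not keep_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    else:
        for nd in g.nodes:
            g.nodes[nd]["isolated"] = g.degree[nd] == 0
    return PcorNetwork(window=window, threshold=threshold, graph=g)


def compare_windows(
    pcor_values: dict[str, np.ndarray],
) -> tuple[dict[str, float], list[dict]]:
    """Excess kurtosis per window and KS tests between consecutive windows.

    ``pcor_values`` maps window label to its off-diagonal partial
    correlation values.  Excess kurtosis is 0 for a normal distribution
    (negative = platykurtic, positive = leptokurtic).
    """
    if len(pcor_values) < 2:
        raise ValueError("need at least two windows to compare")
    kurt = {}
    for label, vals in pcor_values.items():
        vals = np.asarray(vals)
        if vals.size < 20:
            raise ValueError(f"window {label}: need >= 20 values, got {vals.size}")
        k = float(stats.kurtosis(vals, fisher=True, bias=True))
        kurt[label] = k
    ks_rows = []
    labels = list(pcor_values)
    for a, b in zip(labels, labels[1:]):
        stat, p = stats.ks_2samp(pcor_values[a], pcor_values[b])
        ks_rows.append(
            {"window_a": a, "window_b": b, "ks_stat": float(stat), "ks_p": float(p)}
        )
    return kurt, ks_rows


def kurtosis_label(excess_kurtosis: float) -> str:
    """Shape label from the sign of excess kurtosis."""
    if excess_kurtosis < 0:
        return "platykurtic"
    if excess_kurtosis > 0:
        return "leptokurtic"
    return "mesokurtic"
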