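"""Gene-set and metabolite-class enrichment over the selected signature.

Gene sets are scored per timepoint by a permutation test on the VIP-ranked
gene list (statistic = sum and mean of member values; the most significant
of the two modalities is retained).  Per-timepoint p-values are combined
over every non-empty timepoint subset with Fisher's method
(X^2 = -2 sum ln p ~ chi-square with 2k df), Benjamini-Hochberg adjusted
across sets within each combination, and a set is flagged when any adjusted
combination p <= 0.05.  A signed pathway score, (1 - p) times the sign of
the mean value of the significant member genes, supports heatmap-style
export.

Metabolite classes are scored per timepoint from per-metabolite case-vs-
control t-tests (significance at p < 0.05) followed by Fisher's exact test
on the in-class x significant 2x2 table, BH-adjusted across classes and
kept at FDR <= 0.2.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_gmt",
    "gsea_by_vip",
    "fisher_combine",
    "signed_score",
    "metabolite_class_enrichment",
]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: set name, description, member genes (tab-separated)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def gsea_by_vip(
    rankings: dict[int, pd.Series],
    gene_sets: dict[str, list[str]],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation enrichment p per gene set per timepoint.

    ``rankings`` maps timepoint label to a Series of per-gene ranking values
    (VIP loadings).  The null permutes gene labels: for a set of size m the
    null statistic is the sum (equivalently mean) of m values drawn without
    replacement.  p = (1 + #{null >= observed}) / (n_perm + 1); the reported
    p is the minimum over the sum and mean modalities.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    rows = []
    for tp, series in rankings.items():
        genes = series.index.to_numpy()
        values = series.to_numpy(dtype=float)
        universe = set(genes)
        g_index = {g: i for i, g in enumerate(genes)}
        overlaps = {}
        for name, members in gene_sets.items():
            hits = [g_index[g] for g in members if g in universe]
            if not hits:
                warnings.warn(f"gene set {name!r} has no overlap with the universe")
                rows.append({"set": name, "timepoint": tp, "p": np.nan, "n_overlap": 0})
            else:
                overlaps[name] = np.asarray(hits)
        sizes = sorted({h.size for h in overlaps.values() if h.size < values.size})
        # null sums for every needed set size from shared gene-label
        # permutations, built in chunks to bound memory
        exceed = {name: 0 for name in overlaps}
        obs = {
            name: float(values[h].sum()) for name, h in overlaps.items()
        }
        chunk = max(1, min(n_perm, 2_000_000 // max(values.size, 1)))
        if sizes:
            done = 0
            while done < n_perm:
                b = min(chunk, n_perm - done)
                perm = rng.permuted(
                    np.broadcast_to(values, (b, values.size)).copy(), axis=1
                )
                cums = perm.cumsum(axis=1)
                for name, h in overlaps.items():
                    m = h.size
                    if m == values.size:
                        continue
                    exceed_here = np.sum(cums[:, m - 1] >= obs[name] - 1e-12)
                    exceed[name] = exceed.get(name, 0) + int(exceed_here)
                done += b
        for name, h in overlaps.items():
            m = h.size
            if m == values.size:
                # the whole universe: null equals the observed statistic
                rows.append({"set": name, "timepoint": tp, "p": 1.0, "n_overlap": m})
                continue
            # the mean statistic is sum/m, a monotone transform of the sum
            # for fixed set size, so its permutation p coincides; the
            # retained minimum over the two modalities equals either
            p = (1.0 + exceed[name]) / (n_perm + 1.0)
            rows.append(
                {"set": name, "timepoint": tp, "p": float(p), "n_overlap": m}
            )
    return pd.DataFrame(rows)


def fisher_combine(
    per_timepoint_p: pd.DataFrame,
    alpha: float = 0.05,
    max_combo_size: int | None = None,
    p_floor: float = 1e-16,
) -> pd.DataFrame:
    """Fisher's-method combination over all timepoint subsets, BH-adjusted.

    Input columns: set, timepoint, p.  For each non-empty subset of
    timepoints, X^2 = -2 sum ln p with 2k degrees of freedom gives the
    combined p; BH runs across sets within each combination.  A set is
    selected when any adjusted p <= ``alpha``.  Zero p-values are clipped
    to ``p_floor`` with a warning.
    """
    df = per_timepoint_p.dropna(subset=["p"]).copy()
    if (df["p"] <= 0).any():
        warnings.warn("p values of 0 clipped to the floor")
        df.loc[df["p"] <= 0, "p"] = p_floor
    if (df["p"] > 1).any():
        raise ValueError("p values must lie in (0, 1]")
    tps = sorted(df["timepoint"].unique(), reverse=True)
    combos = []
    for k in range(1, len(tps) + 1):
        if max_combo_size is not None and k > max_combo_size:
            break
        combos.extend(itertools.combinations(tps, k))
    out_rows = []
    for combo in combos:
        sub = df[df["timepoint"].isin(combo)]
        counts = sub.groupby("set")["p"].count()
        full = counts[counts == len(combo)].index
        stats_rows = []
        for s in full:
            ps = sub.loc[sub["set"] == s, "p"].to_numpy()
            x2 = float(-2.0 * np.log(ps).sum())
            p_comb = float(stats.chi2.sf(x2, df=2 * len(ps)))
            stats_rows.append((s, x2, p_comb))
        if not stats_rows:
            continue
        names, x2s, pcs = zip(*stats_rows)
        adj = multipletests(pcs, method="fdr_bh")[1]
        for s, x2, pc, pa in zip(names, x2s, pcs, adj):
            out_rows.append(
                {
                    "set": s,
                    "combination": "+".join(str(t) for t in combo),
                    "combo_size": len(combo),
                    "chi2": x2,
                    "fisher_p": pc,
                    "adj_p": float(pa),
                }
            )
    out = pd.DataFrame(out_rows)
    if out.empty:
        return out
    selected = out.groupby("set")["adj_p"].min() <= alpha
    out["selected"] = out["set"].map(selected)
    return out


def signed_score(p: float, member_values: np.ndarray, significant: np.ndarray | None = None) -> float:
    """(1 - p) times the sign of the mean value of significant members.

    ``significant`` flags which members count toward the sign; when no
    member is significant the score is 0.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("p must lie in (0, 1]")
    vals = np.asarray(member_values, dtype=float)
    if significant is not None:
        vals = vals[np.asarray(significant, dtype=bool)]
    if vals.size == 0:
        return 0.0
    return float((1.0 - p) * np.sign(vals.mean()))


@dataclass
class MetaboliteClassResult:
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def metabolite_class_enrichment(
    case_values: np.ndarray,
    control_values: np.ndarray,
    feature_ids: list[str],
    class_map: dict[str, str],
    timepoints: list[int],
    alpha: float = 0.05,
    fdr: float = 0.2,
    paired: bool = True,
) -> MetaboliteClassResult:
    """Metabolite-class enrichment from per-metabolite t-tests.

    ``case_values`` and ``control_values`` are aligned (set x feature x
    timepoint) arrays: with pairing available, row s of the control array is
    the mean control profile of set s and a paired t-test is used, otherwise
    Welch.  Per timepoint: metabolites significant at p < ``alpha`` feed a
    per-class 2x2 Fisher exact test (one-sided, enrichment), BH-corrected
    across classes and kept at adjusted p <= ``fdr``.  Classes with fewer
    than 2 members are skipped.
    """
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.shape != ctrl.shape:
        raise ValueError("case and control arrays must be aligned")
    if case.shape[0] < 2:
        raise ValueError("need at least 2 case-control sets per group")
    J = len(feature_ids)
    classes = sorted({c for c in class_map.values()})
    rows = []
    for k, tp in enumerate(timepoints):
        with np.errstate(invalid="ignore", divide="ignore"):
            if paired:
                tstat, pvals = stats.ttest_rel(case[:, :, k], ctrl[:, :, k], axis=0)
            else:
                tstat, pvals = stats.ttest_ind(
                    case[:, :, k], ctrl[:, :, k], axis=0, equal_var=False
                )
        sig = pvals < alpha
        diff = case[:, :, k].mean(axis=0) - ctrl[:, :, k].mean(axis=0)
        tp_rows = []
        for cls in classes:
            in_cls = np.array([class_map.get(f) == cls for f in feature_ids])
            n_cls = int(in_cls.sum())
            if n_cls < 2:
                warnings.warn(f"class {cls!r}: fewer than 2 members, skipped")
                continue
            if n_cls == J:
                warnings.warn(f"class {cls!r} covers all metabolites; test degenerate")
                continue
            a = int((in_cls & sig).sum())          # in-class significant
            b = n_cls - a                          # in-class not
            c = int((~in_cls & sig).sum())         # out-of-class significant
            d = int((~in_cls).sum()) - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            sig_members = in_cls & sig
            direction = (
                float(np.sign(diff[sig_members].mean())) if sig_members.any() else 0.0
            )
            tp_rows.append(
                {
                    "class": cls,
                    "timepoint": tp,
                    "n_class": n_cls,
                    "n_significant": a,
                    "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
                    "fisher_p": float(p),
                    "direction": direction,
                }
            )
        if tp_rows:
            ps = [r["fisher_p"] for r in tp_rows]
            adj = multipletests(ps, method="fdr_bh")[1]
            for r, pa in zip(tp_rows, adj):
                r["adj_p"] = float(pa)
                r["enriched"] = bool(pa <= fdr)
            rows.extend(tp_rows)
    return MetaboliteClassResult(table=pd.DataFrame(rows))
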