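"""End-to-end workflow: simulate -> bin -> split -> impute -> normalize ->
per-block NPLS-DA -> VIP selection -> integrated model -> validation ->
networks -> enrichment, with every stage writing plain-text artifacts and a
manifest of content hashes for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import networks as net
from . import validation as val
from .enrichment import fisher_combine, gsea_by_vip, metabolite_class_enrichment, read_gmt
from .nplsda import cross_validate, fit_nplsda
from .synthetic import BlockSpec, CohortConfig, generate_cohort, write_fixture
from .tensors import (
    DEFAULT_BIN_SPEC,
    OmicsTensor,
    bin_to_tensor,
    filter_and_split,
    within_normalize,
    write_tensor_bundle,
)
from .tucker import impute_missing
from .vip import STRATEGIES, compute_vip, search_best_set

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "triomics_run"
    seed: int = 0
    # synthetic cohort (used when no input tables are given)
    n_pairs: int = 40
    n_validation_pairs: int = 6
    effect_size: float = 2.0
    missing_rate: float = 0.1
    block_specs: tuple = (
        BlockSpec("gene_expression", 120, 1),
        BlockSpec("metabolomics", 60, 3),
        BlockSpec("dietary_biomarkers", 8, 3),
    )
    n_informative_per_block: int = 6
    measurements_path: str | None = None
    design_path: str | None = None
    # preprocessing
    normalize_before_impute: bool = False
    imputation_ranks: str | tuple = "diffit"
    imputation_tol: float = 1e-7
    # model
    n_components: int = 2
    cv_scheme: str = "loo"
    cv_repeats: int = 1
    # selection
    percentile_gene: float = 99.0
    percentile_metab: float = 95.0
    # validation
    n_permutations: int = 30
    # networks
    pcor_threshold: float = 0.7
    en_n_tune: int = 10
    en_n_final: int = 50
    # enrichment
    gmt_path: str | None = None
    gsea_n_perm: int = 1000
    class_map_path: str | None = None

    def derive_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _percentile_for(block: str, cfg: PipelineConfig) -> float:
    return cfg.percentile_gene if "gene" in block else cfg.percentile_metab


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full workflow; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "artifacts": {}}

    def save_df(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        return p

    def record(stage: str, **info):
        manifest["stages"][stage] = info
        logger.info("stage %s: %s", stage, info)

    # ------------------------------------------------------------- simulate
    if cfg.measurements_path is None:
        cc = CohortConfig(
            n_pairs=cfg.n_pairs,
            n_validation_pairs=cfg.n_validation_pairs,
            block_specs=tuple(cfg.block_specs),
            n_informative_per_block=cfg.n_informative_per_block,
            effect_size=cfg.effect_size,
            missing_rate=cfg.missing_rate,
            seed=cfg.derive_seed("simulate"),
        )
        measurements, design, truth = generate_cohort(cc)
        write_fixture(measurements, design, truth, out / "cohort")
        record("simulate", n_pairs=cfg.n_pairs, seed=cc.seed)
    else:
        measurements = pd.read_csv(cfg.measurements_path, sep="\t")
        design = pd.read_csv(cfg.design_path, sep="\t")
        truth = None
        record("load", measurements=cfg.measurements_path)

    blocks = sorted(measurements["block"].unique())
    analysis: dict[str, OmicsTensor] = {}
    validation: dict[str, OmicsTensor] = {}
    reports = {}
    for block in blocks:
        tensor = bin_to_tensor(measurements, DEFAULT_BIN_SPEC, block)
        ana, vali = filter_and_split(tensor, design)
        if cfg.normalize_before_impute:
            ana = within_normalize(ana, design)
        filled, report = impute_missing(
            ana, ranks=cfg.imputation_ranks, tol=cfg.imputation_tol
        )
        if not cfg.normalize_before_impute:
            # imputed cells are data for normalization purposes; the
            # imputed-cell mask is restored afterwards
            from dataclasses import replace as _replace

            complete = _replace(filled, mask=np.ones_like(filled.mask))
            normalized = within_normalize(complete, design)
            filled = _replace(
                normalized, mask=filled.mask.copy(), values=normalized.values
            )
        analysis[block] = filled
        validation[block] = vali
        reports[block] = asdict(report)
        write_tensor_bundle(filled, out / f"tensor_{block}")
    (out / "imputation_reports.json").write_text(json.dumps(reports, indent=1))
    record("prep_impute", blocks=blocks, reports=reports)

    # align subjects across blocks on the case axis: per-block models use
    # their own subjects; the integrated model uses normalized case deltas
    # from each block's matched sets (cases are shared across blocks)
    labels_of = {}
    pairs_of = {}
    design_idx = design.set_index("subject_id")
    for block, tensor in analysis.items():
        labels_of[block] = np.array(
            [design_idx.loc[s, "role"] for s in tensor.subject_ids]
        )
        pairs_of[block] = np.array(
            [design_idx.loc[s, "pair_id"] for s in tensor.subject_ids]
        )

    # ------------------------------------------------- per-block NPLS + VIP
    selected: dict[str, list[str]] = {}
    block_model_stats = {}
    vip_rankings: dict[str, dict[int, pd.Series]] = {}
    for block, tensor in analysis.items():
        labels = labels_of[block]
        seed_b = cfg.derive_seed(f"vip:{block}")
        sels = []
        for strat in STRATEGIES:
            s = compute_vip(
                None, tensor.values, labels, tensor.feature_ids,
                strategy=strat, n_components=cfg.n_components,
            )
            from .vip import select_by_percentile

            select_by_percentile(s, _percentile_for(block, cfg))
            sels.append(s)
        winner, log = search_best_set(
            sels, tensor.values, labels, tensor.feature_ids,
            n_components=cfg.n_components, cv_scheme="5fold", seed=seed_b,
            pair_ids=pairs_of[block],
        )
        selected[block] = winner.selected_ids
        block_model_stats[block] = {
            "r2": winner.r2, "q2": winner.q2,
            "n_selected": len(winner.selected_ids),
            "provenance": winner.candidate_provenance,
        }
        save_df(pd.DataFrame(log).drop(columns=["features"]), f"vip_search_{block}.tsv")
        rows = []
        for s in sels:
            for f, v in zip(s.feature_ids, s.vip_values):
                rows.append(
                    {
                        "feature_id": f,
                        "block": block,
                        "strategy": s.strategy,
                        "vip": v,
                        "selected": f in s.selected_ids,
                    }
                )
        save_df(pd.DataFrame(rows), f"vip_values_{block}.tsv")
        # per-timepoint VIP rankings for enrichment
        s2 = compute_vip(
            None, tensor.values, labels, tensor.feature_ids,
            strategy="vip2d", n_components=cfg.n_components,
        )
        vip_rankings[block] = {
            tp: pd.Series(s2.per_timepoint[:, k], index=tensor.feature_ids)
            for k, tp in enumerate(tensor.timepoints)
        }
    record("vip_select", **block_model_stats)

    # ------------------------------------------------------ integrated model
    # feature-wise concatenation of the selected features of each block on
    # the shared case subjects plus (for 1:1 blocks) their control; blocks
    # are scaled to unit total SS so no block dominates the covariance
    base_block = blocks[0]
    shared = None
    for block, tensor in analysis.items():
        subs = set(tensor.subject_ids)
        shared = subs if shared is None else (shared & subs)
    shared = sorted(shared)
    if len(shared) < 8:
        raise RuntimeError("too few shared subjects for the integrated model")
    parts, part_ids, part_blocks = [], [], []
    for block, tensor in analysis.items():
        cols = [tensor.feature_ids.index(f) for f in selected[block]]
        if not cols:
            continue
        rows = [tensor.subject_ids.index(s) for s in shared]
        sub = tensor.values[np.ix_(rows, cols, range(tensor.shape[2]))]
        ss = float(np.sum(sub * sub)) or 1.0
        parts.append(sub / np.sqrt(ss))
        part_ids.extend(f"{block}:{f}" for f in selected[block])
        part_blocks.extend([block] * len(cols))
    integrated = np.concatenate(parts, axis=1)
    int_labels = np.array([design_idx.loc[s, "role"] for s in shared])
    int_tensor = OmicsTensor(
        integrated, np.ones_like(integrated, dtype=bool), shared, part_ids,
        analysis[base_block].timepoints, "integrated",
    )
    write_tensor_bundle(int_tensor, out / "tensor_integrated")
    int_model = fit_nplsda(integrated, int_labels, cfg.n_components)
    int_pairs = np.array([design_idx.loc[s, "pair_id"] for s in shared])
    cv = cross_validate(
        integrated, int_labels, cfg.n_components, scheme=cfg.cv_scheme,
        n_repeats=cfg.cv_repeats, seed=cfg.derive_seed("cv"),
        pair_ids=int_pairs,
    )
    record(
        "integrated_model",
        r2x=int_model.r2x, r2y=int_model.r2y,
        q2=cv.q2_mean, accuracy=cv.accuracy, scheme=cfg.cv_scheme,
    )
    save_df(
        pd.DataFrame(
            {
                "subject_id": shared,
                "label": int_labels,
                **{
                    f"t{h + 1}": int_model.mode1_scores[:, h]
                    for h in range(cfg.n_components)
                },
            }
        ),
        "integrated_scores.tsv",
    )

    # ------------------------------------------------------------ validation
    # significance of the VIP selection: the selected set of the largest
    # block is compared against random same-size draws from its universe
    perm_block = max(blocks, key=lambda b: len(analysis[b].feature_ids))
    perm = None
    if selected[perm_block] and len(selected[perm_block]) < len(
        analysis[perm_block].feature_ids
    ):
        tb = analysis[perm_block]
        perm = val.permutation_test(
            tb.values, labels_of[perm_block], tb.feature_ids, selected[perm_block],
            mode="random_features", n_permutations=cfg.n_permutations,
            n_components=cfg.n_components, seed=cfg.derive_seed("perm"),
            pair_ids=pairs_of[perm_block],
        )
    if perm:
        (out / "permutation_result.json").write_text(
            json.dumps(
                {
                    "mode": perm.mode,
                    "observed_r2": perm.observed_r2,
                    "observed_q2": perm.observed_q2,
                    "p_r2": perm.p_r2,
                    "p_q2": perm.p_q2,
                    "null_r2": perm.null_r2.tolist(),
                    "null_q2": perm.null_q2.tolist(),
                },
                indent=1,
            )
        )
        record("permutation", p_q2=perm.p_q2, p_r2=perm.p_r2)

    # per-timepoint validation on the held-out sparse subjects (first block)
    vali = validation[base_block]
    if vali.subject_ids:
        ana0 = analysis[base_block]
        tv = val.timepoint_validate(
            ana0.values, labels_of[base_block], ana0.feature_ids,
            selected[base_block] or ana0.feature_ids[:5],
            vali.values, vali.mask,
            np.array([design_idx.loc[s, "role"] for s in vali.subject_ids]),
            ana0.timepoints,
        )
        save_df(
            pd.DataFrame(
                {"timepoint": tv.timepoints, "n": tv.n_samples, "accuracy": tv.accuracy}
            ),
            "timepoint_validation.tsv",
        )
        record("timepoint_validation", accuracy=tv.accuracy)

    # -------------------------------------------------------------- networks
    kinds = {}
    for fid, blk in zip(part_ids, part_blocks):
        kinds[fid] = (
            "gene" if "gene" in blk else ("vitamin" if "diet" in blk else "metabolite")
        )
    tps = analysis[base_block].timepoints
    full_mask = np.ones_like(integrated, dtype=bool)
    # elastic-net selection runs on all normalized subjects with the
    # case/control outcome as response; partial correlations use cases only
    windows_all = net.delta_profiles(
        integrated, full_mask, shared, part_ids, tps, subjects="all"
    )
    windows_cases = net.delta_profiles(
        integrated, full_mask, shared, part_ids, tps,
        labels=int_labels, subjects="cases",
    )
    pcor_values = {}
    net_stats = {}
    for w_all, w in zip(windows_all, windows_cases):
        lbl = {s: l for s, l in zip(shared, int_labels)}
        sel_feats, alpha = net.elastic_net_select(
            w_all,
            response=np.array([lbl[s] for s in w_all.subject_ids]),
            n_tune=cfg.en_n_tune, n_final=cfg.en_n_final,
            seed=cfg.derive_seed(f"en:{w.label}"),
        )
        if w.matrix.shape[1] < 3 or w.matrix.shape[0] < 4:
            continue
        # partial correlations over the full signature; the network displays
        # only the elastic-net-selected features of this window
        pcor_full = net.partial_correlations(w.matrix)
        use = sel_feats if len(sel_feats) >= 3 else w.feature_ids
        cols = [w.feature_ids.index(f) for f in use]
        pcor = pcor_full[np.ix_(cols, cols)]
        # node sign: mean normalized case value at the window's first timepoint
        k_first = tps.index(w.from_tp)
        case_rows_int = np.flatnonzero(int_labels == "case")
        node_vals = {
            f: float(
                integrated[case_rows_int, part_ids.index(f), k_first].mean()
            )
            for f in use
        }
        g = net.build_network(
            pcor, use, threshold=cfg.pcor_threshold, kinds=kinds,
            node_values=node_vals, window=w.label,
        )
        nx_path = out / f"network_{w.label}.graphml"
        import networkx as nx

        nx.write_graphml(g.graph, nx_path)
        _write_sif(g, out / f"network_{w.label}.sif")
        iu = np.triu_indices(pcor_full.shape[0], k=1)
        pcor_values[w.label] = pcor_full[iu]
        net_stats[w.label] = {
            "n_nodes": g.graph.number_of_nodes(),
            "n_edges": g.n_edges,
            "winning_alpha": alpha,
            "n_selected": len(sel_feats),
        }
    if len(pcor_values) >= 2 and all(v.size >= 20 for v in pcor_values.values()):
        kurt, ks_rows = net.compare_windows(pcor_values)
        stats_df = pd.DataFrame(
            [{"window": k, "kurtosis": v} for k, v in kurt.items()]
        )
        save_df(stats_df, "window_kurtosis.tsv")
        save_df(pd.DataFrame(ks_rows), "window_ks.tsv")
        record("networks", kurtosis=kurt, **net_stats)
    else:
        record("networks", **net_stats)

    # ------------------------------------------------------------ enrichment
    gene_block = next((b for b in blocks if "gene" in b), None)
    if gene_block is not None:
        if cfg.gmt_path:
            gene_sets = read_gmt(cfg.gmt_path)
        else:
            # built-in demonstration sets: random slices of the universe
            rng = np.random.default_rng(cfg.derive_seed("gmt"))
            universe = analysis[gene_block].feature_ids
            gene_sets = {
                f"SET_{i:02d}": list(
                    rng.choice(universe, size=min(15, len(universe)), replace=False)
                )
                for i in range(8)
            }
            if truth is not None:
                gene_sets["PLANTED"] = truth.informative_features.get(gene_block, [])[:15]
        gsea = gsea_by_vip(
            vip_rankings[gene_block], gene_sets,
            n_perm=max(100, cfg.gsea_n_perm), seed=cfg.derive_seed("gsea"),
        )
        save_df(gsea, "gsea_per_timepoint.tsv")
        combined = fisher_combine(gsea, max_combo_size=3)
        if not combined.empty:
            save_df(combined, "gsea_combined.tsv")
            record(
                "enrichment",
                n_selected_sets=int(
                    combined.groupby("set")["selected"].first().sum()
                ),
            )

    metab_block = next((b for b in blocks if "metab" in b), None)
    if metab_block is not None:
        tensor = analysis[metab_block]
        labels_m = labels_of[metab_block]
        case_rows = np.flatnonzero(labels_m == "case")
        # mean control profile per set, aligned with its case
        pair_of = {s: design_idx.loc[s, "pair_id"] for s in tensor.subject_ids}
        ctl_means = []
        for ci in case_rows:
            pid = pair_of[tensor.subject_ids[ci]]
            rows = [
                i
                for i, s in enumerate(tensor.subject_ids)
                if pair_of[s] == pid and labels_m[i] == "control"
            ]
            ctl_means.append(tensor.values[rows].mean(axis=0))
        class_map = (
            _read_class_map(cfg.class_map_path)
            if cfg.class_map_path
            else {
                f: f"class_{j % 4}" for j, f in enumerate(tensor.feature_ids)
            }
        )
        mce = metabolite_class_enrichment(
            tensor.values[case_rows], np.array(ctl_means), tensor.feature_ids,
            class_map, tensor.timepoints,
        )
        if not mce.table.empty:
            save_df(mce.table, "metabolite_classes.tsv")
            record(
                "metabolite_enrichment",
                n_enriched=int(mce.table["enriched"].sum()),
            )

    # --------------------------------------------------------------- manifest
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_sif(network: net.PcorNetwork, path: Path) -> None:
    lines = []
    for a, b, d in network.graph.edges(data=True):
        rel = "pp" if d.get("sign") == "positive" else "pn"
        lines.append(f"{a}\t{rel}\t{b}")
    for nd in network.graph.nodes:
        if network.graph.degree[nd] == 0:
            lines.append(nd)
    path.write_text("\n".join(lines) + "\n")


def _read_class_map(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
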