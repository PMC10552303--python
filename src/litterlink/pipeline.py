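"""Per-tissue orchestration: routes -> ORA hits -> combined score -> rank.

The prioritization logic: each metabolite feature in the analysis set
(significantly more abundant in SPF in at least one tissue, or undetectable
in GF) accumulates gene sets through three evidence routes — direct Spearman
pairs, linked hierarchical clusters, and shared plaid biclusters. Each route
gene set is scored by the number of significant ORA terms; features are
ranked within each route by descending hit count (average ranks for ties)
and the combined score is the sum of the three route ranks, smaller = more
strongly prioritized. Rank aggregation keeps the routes scale-free; a
sum-of-counts alternative is available in config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    Bicluster,
    ClusterSet,
    classify_dependency,
    hierarchical_clusters,
    link_clusters,
    plaid_biclustering,
    select_top_biclusters,
    spearman_matrix,
    spearman_screen,
)
from .config import PipelineConfig
from .enrichment import ora, ora_for_route
from .io import (
    GeneSetCollection,
    OmicsMatrix,
    read_de_table,
    read_gmt,
    read_matrix,
    read_metadata,
    subset_metadata,
    write_de_table,
)
from .screening import (
    LitterMatrix,
    average_litters,
    classify_metabolites,
    de_standin,
    normalize_counts,
    prefilter_genes,
    twin_similarity_test,
)

logger = logging.getLogger("litterlink")

ROUTE_NAMES = ("direct", "cluster", "bicluster")


def _tissue_key(tissue: str) -> int:
    """Stable per-tissue seed component (process-independent, < 2**16)."""
    return int.from_bytes(hashlib.sha256(tissue.encode()).digest()[:2], "big")


# ---------------------------------------------------------------------------
# Route gene sets and scoring


def route_gene_sets(
    feature_id: str,
    pairs: pd.DataFrame,
    links: pd.DataFrame,
    gene_clusters: ClusterSet | None,
    feature_clusters: ClusterSet | None,
    top_biclusters: list[Bicluster],
) -> dict[str, set[str]]:
    """Assemble the three per-feature gene sets from the route outputs.

    direct: genes with a retained direct pair with the feature;
    cluster: union of member genes of gene clusters linked to the feature's
    cluster; bicluster: union of gene members of selected biclusters that
    contain the feature. Sets may be empty.
    """
    if feature_clusters is not None and feature_id not in feature_clusters.labels.index:
        raise KeyError(f"feature {feature_id!r} is not in the analysis set")
    direct = set(pairs.loc[pairs["feature_id"] == feature_id, "gene_id"])
    cluster: set[str] = set()
    if feature_clusters is not None and gene_clusters is not None and len(links):
        fc = feature_clusters.labels[feature_id]
        for gc in links.loc[links["feature_cluster"] == fc, "gene_cluster"]:
            cluster.update(gene_clusters.members(gc))
    bicluster: set[str] = set()
    for b in top_biclusters:
        if feature_id in b.row_ids:
            bicluster.update(b.col_ids)
    return {"direct": direct, "cluster": cluster, "bicluster": bicluster}


def score_features(hits: pd.DataFrame, aggregation: str = "rank_sum") -> pd.DataFrame:
    """Combined score and final rank from per-route significant-hit counts.

    ``hits``: one row per analysis-set feature (index = feature_id), one
    column per route with the count of significant ORA terms. Within-route
    ranks are by descending hits with average ranks for ties; the combined
    score is the rank sum (or minus the total hit count under ``hit_sum``).
    Final order: ascending combined score, ties by descending total hits,
    then feature id.
    """
    if hits.empty:
        raise ValueError("no features to score")
    hits = hits.copy()
    hits.index = hits.index.astype(str)
    ranks = hits.rank(ascending=False, method="average")
    total = hits.sum(axis=1)
    if aggregation == "rank_sum":
        combined = ranks.sum(axis=1)
    elif aggregation == "hit_sum":
        combined = -total.astype(float)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    out = pd.DataFrame(
        {
            **{f"hits_{r}": hits[r] for r in hits.columns},
            **{f"rank_{r}": ranks[r] for r in hits.columns},
            "combined_score": combined,
            "total_hits": total,
        }
    )
    out.index.name = "feature_id"
    out = out.reset_index()
    out = out.sort_values(
        by=["combined_score", "total_hits", "feature_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out


def summarize_de(de_table: pd.DataFrame, n_prefiltered: int, alpha: float = 0.05) -> dict:
    """Down/up-regulated counts and rounded percentages of prefiltered genes.

    Percentages follow the reporting convention of the summary tables this
    mirrors: one decimal at >= 1%, two decimals below 1%.
    """
    if n_prefiltered <= 0:
        raise ValueError("n_prefiltered must be positive")
    sig = de_table["p_adj"] < alpha
    n_down = int((sig & (de_table["log2_fold_change"] < 0)).sum())
    n_up = int((sig & (de_table["log2_fold_change"] > 0)).sum())

    def pct(n: int) -> float:
        value = 100.0 * n / n_prefiltered
        return round(value, 1) if value >= 1.0 else round(value, 2)

    return {
        "n_prefiltered": int(n_prefiltered),
        "n_down": n_down,
        "n_up": n_up,
        "pct_down": pct(n_down),
        "pct_up": pct(n_up),
    }


# ---------------------------------------------------------------------------
# Tissue-level run


@dataclasses.dataclass
class TissueResult:
    tissue: str
    n_prefiltered: int = 0
    feature_status: pd.DataFrame | None = None
    de_table: pd.DataFrame | None = None
    de_summary: dict | None = None
    qc: dict | None = None
    pairs: pd.DataFrame | None = None
    gene_clusters: ClusterSet | None = None
    feature_clusters: ClusterSet | None = None
    links: pd.DataFrame | None = None
    biclusters: list[Bicluster] = dataclasses.field(default_factory=list)
    top_biclusters: list[Bicluster] = dataclasses.field(default_factory=list)
    route_hits: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None
    dependency: pd.DataFrame | None = None
    detailed_ora: pd.DataFrame | None = None
    error: str | None = None


@dataclasses.dataclass
class StudyResult:
    tissues: dict[str, TissueResult]
    analysis_features: list[str]
    manifest: dict


def _classify_all_tissues(intensities, metadata, config) -> dict[str, pd.DataFrame]:
    status = {}
    for tissue in sorted(metadata["tissue"].unique()):
        md = subset_metadata(metadata, tissue=tissue, assay="metabolome")
        sub = intensities.subset_samples(list(md["sample_id"]))
        status[tissue] = classify_metabolites(
            sub, md, alpha=config.alpha, test=config.metabolite_test
        )
    return status


def run_tissue(
    tissue: str,
    config: PipelineConfig,
    counts: OmicsMatrix,
    intensities: OmicsMatrix,
    metadata: pd.DataFrame,
    gene_sets: GeneSetCollection,
    feature_status: pd.DataFrame,
    analysis_features: list[str],
    de_table: pd.DataFrame | None = None,
) -> TissueResult:
    """One tissue end-to-end: prefilter -> DE -> routes -> ORA -> ranking."""
    cfg = config.for_tissue(tissue)
    res = TissueResult(tissue=tissue, feature_status=feature_status)

    tx_md = subset_metadata(metadata, tissue=tissue, assay="transcriptome")
    mb_md = subset_metadata(metadata, tissue=tissue, assay="metabolome")
    counts_t = counts.subset_samples(list(tx_md["sample_id"]))
    intens_t = intensities.subset_samples(list(mb_md["sample_id"]))

    filtered = prefilter_genes(counts_t, cfg.prefilter_min_reads, cfg.prefilter_min_samples)
    res.n_prefiltered = filtered.shape[0]
    normalized, size_factors = normalize_counts(filtered)
    if de_table is None:
        de_table = de_standin(normalized, tx_md)
    else:
        de_table = de_table[de_table["gene_id"].isin(filtered.feature_ids)].copy()
    res.de_table = de_table
    res.de_summary = summarize_de(de_table, res.n_prefiltered, alpha=cfg.alpha)

    tkey = _tissue_key(tissue)
    qc_tx = twin_similarity_test(counts_t, tx_md, n_perm=cfg.n_perm,
                                 seed=(cfg.seed, tkey, 1))
    qc_mb = twin_similarity_test(intens_t, mb_md, n_perm=cfg.n_perm,
                                 seed=(cfg.seed, tkey, 2))
    res.qc = {"transcriptome": qc_tx.to_dict(), "metabolome": qc_mb.to_dict()}

    # genes entering the association routes
    if cfg.gene_selection == "de_significant":
        selected = list(de_table.loc[de_table["p_adj"] < cfg.alpha, "gene_id"])
        selected = [g for g in selected if g in normalized.data.index]
    else:
        selected = filtered.feature_ids
    feats = [f for f in analysis_features if f in intens_t.data.index]
    if len(selected) < 2 or len(feats) < 2:
        res.error = (
            f"too little signal for association routes "
            f"({len(selected)} selected genes, {len(feats)} analysis features)"
        )
        logger.warning("tissue %s: %s", tissue, res.error)
        return res

    gene_litter_all = average_litters(normalized.subset_features(selected), tx_md)
    feat_litter_all = average_litters(intens_t.subset_features(feats), mb_md)
    spf_dams = sorted(subset_metadata(metadata, tissue=tissue, group="SPF")["dam_id"].unique())
    gene_litter = gene_litter_all.restrict_dams(
        [d for d in gene_litter_all.dam_ids if d in spf_dams])
    feat_litter = feat_litter_all.restrict_dams(
        [d for d in feat_litter_all.dam_ids if d in spf_dams])

    routes = set(cfg.routes)
    pairs = (
        spearman_screen(feat_litter, gene_litter, cfg.rho_pair, cfg.use_absolute_rho)
        if "direct" in routes
        else pd.DataFrame(columns=["feature_id", "gene_id", "rho", "route"])
    )
    res.pairs = pairs

    # feature clustering is needed for route membership bookkeeping even
    # when only reporting; build it whenever the cluster route is enabled
    links = pd.DataFrame(columns=["feature_cluster", "gene_cluster", "mean_rho", "n_pairs"])
    if "cluster" in routes:
        res.gene_clusters = hierarchical_clusters(gene_litter, cfg.target_cluster_genes,
                                                  kind="gene")
        res.feature_clusters = hierarchical_clusters(
            feat_litter, cfg.target_cluster_features, kind="feature")
        links = link_clusters(
            res.gene_clusters, res.feature_clusters, gene_litter, feat_litter,
            threshold=cfg.rho_cluster, use_absolute=cfg.cluster_link_absolute,
        )
    res.links = links

    if "bicluster" in routes:
        rho = spearman_matrix(feat_litter.data.to_numpy(), gene_litter.data.to_numpy())
        ok_rows = ~np.isnan(rho).all(axis=1)
        ok_cols = ~np.isnan(rho).any(axis=0)
        corr_abs = pd.DataFrame(
            np.abs(np.nan_to_num(rho[np.ix_(ok_rows, ok_cols)])),
            index=np.asarray(feat_litter.feature_ids)[ok_rows],
            columns=np.asarray(gene_litter.feature_ids)[ok_cols],
        )
        if corr_abs.shape[0] >= 2 and corr_abs.shape[1] >= 2:
            res.biclusters = plaid_biclustering(
                corr_abs, cfg, seed=(cfg.seed, tkey, 3))
            res.top_biclusters = select_top_biclusters(
                res.biclusters, cfg.bicluster_top_fraction)

    # per-feature ORA hit counts
    universe = filtered.feature_ids
    hit_rows = []
    feature_order = sorted(feat_litter.feature_ids)
    for f in feature_order:
        sets_f = route_gene_sets(f, pairs, links, res.gene_clusters,
                                 res.feature_clusters, res.top_biclusters)
        row = {"feature_id": f}
        for route in ROUTE_NAMES:
            if route in routes:
                _, _, n_sig = ora_for_route(
                    f, route, sets_f[route], universe, gene_sets,
                    alpha=cfg.alpha, min_overlap=cfg.ora_min_overlap,
                )
                row[route] = n_sig
        hit_rows.append(row)
    hits = pd.DataFrame(hit_rows).set_index("feature_id")
    res.route_hits = hits
    res.scores = score_features(hits, aggregation=cfg.score_aggregation)

    # dependency labels on direct pairs, using per-group normalized means
    grp = subset_metadata(metadata, tissue=tissue, assay="transcriptome")
    grp = grp.set_index("sample_id").loc[normalized.sample_ids, "group"]
    gene_group_means = normalized.data.T.groupby(grp).mean().T
    res.dependency = classify_dependency(pairs, gene_group_means, feature_status)

    # detailed ORA report for the top features (direct route)
    detail_rows = []
    for f in res.scores.head(cfg.top_n_detailed)["feature_id"]:
        genes_f = route_gene_sets(f, pairs, links, res.gene_clusters,
                                  res.feature_clusters, res.top_biclusters)["direct"]
        if not genes_f:
            continue
        try:
            tab = ora(genes_f, universe, gene_sets, alpha=cfg.alpha,
                      min_overlap=cfg.ora_min_overlap)
        except ValueError:
            continue
        tab = tab[tab["significant"]]
        for _, r in tab.iterrows():
            detail_rows.append({"feature_id": f, **r.to_dict()})
    res.detailed_ora = pd.DataFrame(detail_rows)
    return res


# ---------------------------------------------------------------------------
# Whole-study run


def run_study(
    config: PipelineConfig,
    counts: OmicsMatrix,
    intensities: OmicsMatrix,
    metadata: pd.DataFrame,
    gene_sets: GeneSetCollection,
    de_tables: dict[str, pd.DataFrame] | None = None,
    tissues: list[str] | None = None,
    outdir: str | None = None,
    input_digests: dict[str, str] | None = None,
) -> StudyResult:
    """Run the full per-tissue pipeline; a failing tissue does not stop others."""
    de_tables = de_tables or {}
    all_tissues = sorted(metadata["tissue"].unique())
    tissues = [t for t in (tissues or all_tissues)]
    unknown = set(tissues) - set(all_tissues)
    if unknown:
        raise ValueError(f"tissues not in metadata: {sorted(unknown)}")

    status_by_tissue = _classify_all_tissues(intensities, metadata, config)
    analysis_features = sorted(
        set().union(
            *(
                set(st.loc[st["status"] != "unchanged", "feature_id"])
                for st in status_by_tissue.values()
            )
        )
    )
    logger.info("analysis set: %d features qualify in >= 1 tissue", len(analysis_features))

    results: dict[str, TissueResult] = {}
    for tissue in tissues:
        try:
            results[tissue] = run_tissue(
                tissue, config, counts, intensities, metadata, gene_sets,
                status_by_tissue[tissue], analysis_features,
                de_tables.get(tissue),
            )
        except Exception as exc:  # noqa: BLE001 - other tissues proceed
            logger.error("tissue %s failed: %s", tissue, exc)
            results[tissue] = TissueResult(tissue=tissue, error=str(exc))

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "tissues": tissues,
        "n_analysis_features": len(analysis_features),
        "input_digests": input_digests or {},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "per_tissue": {
            t: {
                "n_prefiltered": r.n_prefiltered,
                "de_summary": r.de_summary,
                "n_pairs": None if r.pairs is None else int(len(r.pairs)),
                "n_links": None if r.links is None else int(len(r.links)),
                "n_biclusters": len(r.biclusters),
                "error": r.error,
            }
            for t, r in results.items()
        },
    }
    study = StudyResult(results, analysis_features, manifest)
    if outdir is not None:
        write_study_outputs(study, outdir)
    return study


def write_study_outputs(study: StudyResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    for tissue, res in study.tissues.items():
        tdir = os.path.join(outdir, tissue)
        os.makedirs(tdir, exist_ok=True)
        if res.feature_status is not None:
            res.feature_status.to_csv(os.path.join(tdir, "feature_status.tsv"),
                                      sep="\t", index=False)
        if res.de_table is not None:
            write_de_table(res.de_table, os.path.join(tdir, "de_table.tsv"))
        if res.pairs is not None:
            res.pairs.to_csv(os.path.join(tdir, "direct_pairs.tsv"), sep="\t", index=False)
        if res.links is not None:
            res.links.to_csv(os.path.join(tdir, "cluster_links.tsv"), sep="\t", index=False)
        for name, cs in (("gene_clusters", res.gene_clusters),
                         ("feature_clusters", res.feature_clusters)):
            if cs is not None:
                cs.labels.rename("cluster").rename_axis("item_id").to_csv(
                    os.path.join(tdir, f"{name}.tsv"), sep="\t")
        with open(os.path.join(tdir, "biclusters.json"), "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "accepted": [b.to_dict() for b in res.biclusters],
                    "selected": [b.to_dict() for b in res.top_biclusters],
                },
                fh, indent=1,
            )
        if res.route_hits is not None:
            res.route_hits.to_csv(os.path.join(tdir, "route_hits.tsv"), sep="\t")
        if res.scores is not None:
            res.scores.to_csv(os.path.join(tdir, "scores.tsv"), sep="\t", index=False)
        if res.dependency is not None:
            res.dependency.to_csv(os.path.join(tdir, "dependency_labels.tsv"),
                                  sep="\t", index=False)
        if res.detailed_ora is not None:
            res.detailed_ora.to_csv(os.path.join(tdir, "top_feature_ora.tsv"),
                                    sep="\t", index=False)
        if res.qc is not None:
            with open(os.path.join(tdir, "qc.json"), "w", encoding="utf-8") as fh:
                json.dump(res.qc, fh, indent=1)
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(study.manifest, fh, indent=1)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    counts_path: str,
    intensities_path: str,
    metadata_path: str,
    gene_sets_path: str,
    de_table_paths: dict[str, str] | None = None,
    tissues: list[str] | None = None,
    outdir: str = "litterlink_out",
) -> StudyResult:
    """File-level entry point: read standard inputs, run, write outputs."""
    counts = read_matrix(counts_path, "counts")
    intensities = read_matrix(intensities_path, "intensities")
    metadata = read_metadata(metadata_path)
    gene_sets = read_gmt(gene_sets_path)
    de_tables = {
        tissue: read_de_table(path) for tissue, path in (de_table_paths or {}).items()
    }
    digests = {
        os.path.basename(p): _digest(p)
        for p in [counts_path, intensities_path, metadata_path, gene_sets_path,
                  *(de_table_paths or {}).values()]
    }
    return run_study(
        config, counts, intensities, metadata, gene_sets, de_tables,
        tissues=tissues, outdir=outdir, input_digests=digests,
    )
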