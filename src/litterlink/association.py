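"""The three metabolite-gene association routes on SPF dam-level means.

1. direct: all-pairs Spearman screen at |rho| > 0.9;
2. cluster: complete-linkage hierarchical clustering of genes and of
   metabolite features on 1 - Spearman dissimilarity, linking cluster pairs
   whose mean member-pair rho exceeds 0.7 (0.6 for brain);
3. bicluster: plaid-model biclustering of the |Spearman| feature x gene
   correlation matrix with constant layer means (the y ~ m model), layers
   accepted only when their importance beats permuted copies.

All correlations use the SPF dams only (six data points at the default
design), which is why the routes refuse to run with fewer than four dams.
A dependency classifier flags pairs whose GF expression shift contradicts
the linear extrapolation of the within-SPF correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .config import PipelineConfig
from .screening import LitterMatrix

logger = logging.getLogger("litterlink")

__all__ = [
    "spearman_matrix", "spearman_screen", "hierarchical_clusters",
    "link_clusters", "plaid_biclustering", "select_top_biclusters",
    "classify_dependency", "ClusterSet", "Bicluster",
]


def spearman_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row Spearman correlations between two matrices.

    Rows are variables, columns are matched observations (dams). Ties get
    average ranks. Rows with zero rank variance (constant vectors) yield
    NaN, mirroring the undefined correlation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("observation counts differ")
    ra = stats.rankdata(a, axis=1)
    rb = stats.rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    na = np.sqrt((ra**2).sum(axis=1))
    nb = np.sqrt((rb**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ra @ rb.T) / np.outer(na, nb)
    return np.clip(rho, -1.0, 1.0)


def _check_dam_means(feature_litter: LitterMatrix, gene_litter: LitterMatrix) -> None:
    if feature_litter.dam_ids != gene_litter.dam_ids:
        raise ValueError(
            "mismatched dam sets between feature and gene litter matrices: "
            f"{feature_litter.dam_ids} vs {gene_litter.dam_ids}"
        )
    if len(gene_litter.dam_ids) < 4:
        raise ValueError(
            "fewer than 4 dams: Spearman ranks on dam means would be meaningless"
        )


# ---------------------------------------------------------------------------
# Route 1: direct pair screen


def spearman_screen(
    feature_litter: LitterMatrix,
    gene_litter: LitterMatrix,
    threshold: float = 0.9,
    use_absolute: bool = True,
) -> pd.DataFrame:
    """All feature x gene Spearman pairs passing the screen threshold.

    Retains rho > threshold, or |rho| > threshold when ``use_absolute``
    (the default, so the negative dose-response associations the screen is
    meant to surface are kept; the sign is reported either way). Constant
    vectors have undefined rho and are excluded with a log entry.
    """
    _check_dam_means(feature_litter, gene_litter)
    rho = spearman_matrix(feature_litter.data.to_numpy(), gene_litter.data.to_numpy())
    n_const = int(np.isnan(rho).all(axis=1).sum() + np.isnan(rho).all(axis=0).sum())
    if np.isnan(rho).any():
        logger.info("spearman_screen: %d constant vectors excluded", n_const)
    crit = np.abs(rho) > threshold if use_absolute else rho > threshold
    crit &= ~np.isnan(rho)
    fi, gi = np.nonzero(crit)
    out = pd.DataFrame(
        {
            "feature_id": np.asarray(feature_litter.feature_ids)[fi],
            "gene_id": np.asarray(gene_litter.feature_ids)[gi],
            "rho": rho[fi, gi],
            "route": "direct",
        }
    )
    logger.info(
        "spearman_screen: %d pairs pass %s%.2f over %d dams",
        len(out), "|rho|>" if use_absolute else "rho>", threshold,
        len(gene_litter.dam_ids),
    )
    return out


# ---------------------------------------------------------------------------
# Route 2: hierarchical clusters + links


@dataclass
class ClusterSet:
    """A partition of items from complete-linkage clustering on 1 - rho."""

    labels: pd.Series  # item_id -> cluster label (int)
    kind: str  # 'gene' | 'feature'
    cut_height: float
    target_range: tuple[int, int]
    achieved_mean_size: float

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def hierarchical_clusters(
    litter: LitterMatrix,
    target_size_range: tuple[int, int],
    kind: str = "gene",
) -> ClusterSet:
    """Complete-linkage clustering on 1 - Spearman, cut to a target mean size.

    The upstream analysis reports only the resulting average cluster sizes
    (16-43 genes, 7-15 features per cluster); the tree is therefore cut at
    the height whose mean cluster size falls inside that range, or at the
    closest achievable mean size (with a warning) when no height does.
    Constant vectors are undefined under rank correlation and become
    singleton clusters.
    """
    if litter.data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    values = litter.data.to_numpy(dtype=float)
    ranks_spread = np.ptp(values, axis=1)
    const_mask = ranks_spread == 0
    ids = np.asarray(litter.feature_ids)
    if const_mask.any():
        logger.warning(
            "%d constant %s vectors assigned singleton clusters", const_mask.sum(), kind
        )
    work_ids = ids[~const_mask]
    labels = pd.Series(0, index=pd.Index(ids, name="item_id"), dtype=int)
    cut_height = 0.0
    achieved = float(len(ids))
    if len(work_ids) >= 2:
        rho = spearman_matrix(values[~const_mask], values[~const_mask])
        dis = 1.0 - rho
        np.fill_diagonal(dis, 0.0)
        dis = np.clip((dis + dis.T) / 2.0, 0.0, 2.0)
        z = linkage(squareform(dis, checks=False), method="complete")
        n = len(work_ids)
        lo, hi = target_size_range
        mid = (lo + hi) / 2.0
        best_k, best_cost = 1, np.inf
        for k in range(1, n + 1):
            mean_size = n / k
            in_range = lo <= mean_size <= hi
            cost = (0.0 if in_range else 1e6) + abs(mean_size - mid)
            if cost < best_cost:
                best_k, best_cost = k, cost
        if best_cost >= 1e6:
            logger.warning(
                "%s clustering: no cut reaches mean size in %s; using closest (%.1f)",
                kind, target_size_range, n / best_k,
            )
        flat = fcluster(z, t=best_k, criterion="maxclust")
        labels.loc[work_ids] = flat
        achieved = n / len(np.unique(flat))
        merge_heights = z[:, 2]
        n_merges_done = n - len(np.unique(flat))
        cut_height = float(merge_heights[n_merges_done - 1]) if n_merges_done > 0 else 0.0
    elif len(work_ids) == 1:
        labels.loc[work_ids] = 1
    # singleton clusters for constant items
    next_label = int(labels.max()) + 1
    for i, item in enumerate(ids[const_mask]):
        labels.loc[item] = next_label + i
    logger.info(
        "%s clustering: %d clusters, mean size %.1f (target %s)",
        kind, labels.nunique(), achieved, target_size_range,
    )
    return ClusterSet(labels, kind, cut_height, tuple(target_size_range), achieved)


def link_clusters(
    gene_clusters: ClusterSet,
    feature_clusters: ClusterSet,
    gene_litter: LitterMatrix,
    feature_litter: LitterMatrix,
    threshold: float = 0.7,
    use_absolute: bool = False,
) -> pd.DataFrame:
    """Cluster pairs whose mean member-pair Spearman exceeds the threshold.

    The mean is over all member gene x member feature pairs, signed by
    default (mean rho > threshold as reported); an absolute-value variant
    is available for symmetric screening.
    """
    _check_dam_means(feature_litter, gene_litter)
    rho = spearman_matrix(feature_litter.data.to_numpy(), gene_litter.data.to_numpy())
    feat_pos = {f: i for i, f in enumerate(feature_litter.feature_ids)}
    gene_pos = {g: i for i, g in enumerate(gene_litter.feature_ids)}
    records = []
    for fc in sorted(feature_clusters.labels.unique()):
        f_idx = [feat_pos[f] for f in feature_clusters.members(fc) if f in feat_pos]
        if not f_idx:
            logger.warning("feature cluster %s empty in litter matrix; skipped", fc)
            continue
        for gc in sorted(gene_clusters.labels.unique()):
            g_idx = [gene_pos[g] for g in gene_clusters.members(gc) if g in gene_pos]
            if not g_idx:
                continue
            block = rho[np.ix_(f_idx, g_idx)]
            if np.isnan(block).all():
                continue
            mean_rho = float(np.nanmean(np.abs(block) if use_absolute else block))
            if mean_rho > threshold:
                records.append(
                    {
                        "feature_cluster": fc,
                        "gene_cluster": gc,
                        "mean_rho": mean_rho,
                        "n_pairs": len(f_idx) * len(g_idx),
                    }
                )
    out = pd.DataFrame(records, columns=["feature_cluster", "gene_cluster",
                                         "mean_rho", "n_pairs"])
    logger.info("link_clusters: %d links above mean rho %.2f", len(out), threshold)
    return out


# ---------------------------------------------------------------------------
# Route 3: plaid biclustering


@dataclass
class Bicluster:
    """One accepted plaid layer on the |Spearman| feature x gene matrix."""

    row_ids: tuple[str, ...]  # features
    col_ids: tuple[str, ...]  # genes
    background: float  # mu0
    layer_mean: float  # mu_k
    importance: float  # sum of squared fitted effects = |rows|*|cols|*mu_k^2
    mean_internal_corr: float  # mean |rho| over member feature x gene pairs
    layer_index: int

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_ids), len(self.col_ids))

    def to_dict(self) -> dict:
        return {
            "row_ids": list(self.row_ids),
            "col_ids": list(self.col_ids),
            "background": self.background,
            "layer_mean": self.layer_mean,
            "importance": self.importance,
            "mean_internal_corr": self.mean_internal_corr,
            "layer_index": self.layer_index,
        }


def _fit_layer(z: np.ndarray, rng: np.random.Generator, iterations: int,
               row_release: float, col_release: float, n_starts: int = 8):
    """Fit one constant-mean layer on the residual matrix.

    Runs ``n_starts`` candidate fits and keeps the one with the largest
    importance: one start from random binary memberships, the rest seeded
    from a random pivot row's strongest columns. Pivot seeding matters on
    rank-correlation matrices, whose heavy-tailed background pushes a
    random start into a broad shallow layer instead of a sharp block.
    Only layers with a positive mean are retained: the input is a
    similarity matrix, and a negative layer (a block *less* correlated
    than background) is not an association bicluster.
    Returns (rows, cols, mu) with boolean masks; empty masks mean no layer.
    """
    best = (np.zeros(z.shape[0], dtype=bool), np.zeros(z.shape[1], dtype=bool), 0.0)
    best_imp = -1.0
    for start in range(max(1, n_starts)):
        cand = _fit_layer_once(z, rng, iterations, row_release, col_release,
                               pivot_init=start > 0)
        if cand[2] <= 0.0:
            continue
        imp = _layer_importance(*cand)
        if imp > best_imp:
            best, best_imp = cand, imp
    return best


def _fit_layer_once(z: np.ndarray, rng: np.random.Generator, iterations: int,
                    row_release: float, col_release: float, pivot_init: bool):
    n, m = z.shape
    empty = (np.zeros(n, dtype=bool), np.zeros(m, dtype=bool), 0.0)
    if pivot_init:
        pivot = int(rng.integers(n))
        cols = z[pivot] >= np.quantile(z[pivot], 0.75)
        if not cols.any():
            cols = z[pivot] >= z[pivot].max()
        mu0 = z[:, cols].mean()
        rows = z[:, cols].mean(axis=1) > mu0
        rows[pivot] = True
    else:
        rows = rng.random(n) < 0.5
        cols = rng.random(m) < 0.5
    if not rows.any():
        rows[rng.integers(n)] = True
    if not cols.any():
        cols[rng.integers(m)] = True
    for _ in range(iterations):
        nr, nc = int(rows.sum()), int(cols.sum())
        if nr == 0 or nc == 0:
            return empty
        mu = z[np.ix_(rows, cols)].mean()
        if mu == 0.0:
            return empty
        rgain = 2.0 * mu * z[:, cols].sum(axis=1) - nc * mu * mu
        cgain = 2.0 * mu * z[rows, :].sum(axis=0) - nr * mu * mu
        new_rows = rgain > 0
        new_cols = cgain > 0
        if np.array_equal(new_rows, rows) and np.array_equal(new_cols, cols):
            break
        rows, cols = new_rows, new_cols
    if not rows.any() or not cols.any():
        return empty
    # iterated release: a member's contribution is its squared-error
    # reduction (proportional to mean residual minus mu/2); members below
    # the release fraction of the strongest member's contribution are
    # pruned, the mean is re-estimated (it rises once weak members leave),
    # and the step repeats to a fixed point. Relative release keeps a
    # layer a coherent block rather than a halo of weak correlates,
    # independent of the background scale.
    for _ in range(iterations):
        mu = z[np.ix_(rows, cols)].mean()
        if mu == 0.0:
            return empty
        sign = np.sign(mu)
        row_contrib = z[:, cols].mean(axis=1) * sign - abs(mu) / 2.0
        col_contrib = z[rows, :].mean(axis=0) * sign - abs(mu) / 2.0
        best_row = row_contrib[rows].max()
        best_col = col_contrib[cols].max()
        new_rows = rows & (row_contrib >= row_release * best_row)
        new_cols = cols & (col_contrib >= col_release * best_col)
        if not new_rows.any() or not new_cols.any():
            return empty
        if np.array_equal(new_rows, rows) and np.array_equal(new_cols, cols):
            break
        rows, cols = new_rows, new_cols
    mu = z[np.ix_(rows, cols)].mean()
    return rows, cols, float(mu)


def _layer_importance(rows: np.ndarray, cols: np.ndarray, mu: float) -> float:
    return float(rows.sum() * cols.sum() * mu * mu)


def _shuffle_residual(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute entries within each row, then within each column.

    Destroys any coherent block while approximately preserving row and
    column marginal distributions, so a candidate layer must beat the
    matrix's marginal heterogeneity, not just its global value spread.
    """
    zs = np.take_along_axis(z, rng.random(z.shape).argsort(axis=1), axis=1)
    zs = np.take_along_axis(zs, rng.random(zs.shape).argsort(axis=0), axis=0)
    return zs


def plaid_biclustering(
    corr_abs: pd.DataFrame,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> list[Bicluster]:
    """Plaid biclustering with constant layer means on a |rho| matrix.

    The matrix is modelled as a background mean plus up to ``max_layers``
    overlapping layers, each a constant ``mu_k`` over its member rows
    (features) and columns (genes) — the y ~ m plaid model. Layers are fit
    greedily on the residual; a layer is accepted only if its importance
    (sum of squared fitted effects) exceeds the best importance achieved on
    ``n_shuffles`` permuted copies of the residual, and fitting stops at
    the first rejection.
    """
    cfg = config or PipelineConfig()
    y = corr_abs.to_numpy(dtype=float)
    if y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("plaid needs at least a 2 x 2 matrix")
    if np.isnan(y).any() or (y < 0).any() or (y > 1).any():
        raise ValueError("plaid input must be |rho| values in [0, 1]")
    rng = np.random.default_rng(seed)
    mu0 = float(y.mean())
    z = y - mu0
    iters = cfg.iter_startup + cfg.iter_layer
    row_ids = np.asarray(corr_abs.index)
    col_ids = np.asarray(corr_abs.columns)
    layers: list[Bicluster] = []
    for k in range(cfg.max_layers):
        rows, cols, mu = _fit_layer(z, rng, iters, cfg.row_release, cfg.col_release)
        imp = _layer_importance(rows, cols, mu)
        null_best = 0.0
        for _ in range(cfg.n_shuffles):
            zs = _shuffle_residual(z, rng)
            r0, c0, m0 = _fit_layer(zs, rng, iters, cfg.row_release, cfg.col_release)
            null_best = max(null_best, _layer_importance(r0, c0, m0))
        if imp <= null_best or imp == 0.0:
            logger.info(
                "plaid: layer %d rejected (importance %.3g <= permuted %.3g); stopping",
                k, imp, null_best,
            )
            break
        block = y[np.ix_(rows, cols)]
        layers.append(
            Bicluster(
                row_ids=tuple(row_ids[rows]),
                col_ids=tuple(col_ids[cols]),
                background=mu0,
                layer_mean=mu,
                importance=imp,
                mean_internal_corr=float(block.mean()),
                layer_index=k,
            )
        )
        z[np.ix_(rows, cols)] -= mu
        logger.info(
            "plaid: accepted layer %d: %d x %d, mu=%.3f, importance %.3g",
            k, int(rows.sum()), int(cols.sum()), mu, imp,
        )
    return layers


def select_top_biclusters(
    biclusters: list[Bicluster],
    top_fraction: float = 0.5,
    n_top: int | None = None,
    merge_col_jaccard: float = 0.5,
) -> list[Bicluster]:
    """Biclusters with the strongest mean internal correlations.

    Sorted by mean internal |rho| descending; the top half is retained
    (minimum one), unless an explicit count is given. Ties break by larger
    area (rows x cols), then lexicographic row ids.

    Greedy plaid fitting can emit several layers over essentially the same
    column (gene) space: the dominant block first, then residual "echo"
    variants built from weaker rows. Before ranking, layers whose column
    sets overlap an earlier-fitted layer at Jaccard > ``merge_col_jaccard``
    are dropped as refits of the same bicluster, so echoes neither occupy
    selection slots nor displace distinct biclusters.
    """
    if not biclusters:
        return []
    if n_top is None:
        n_top = max(1, int(len(biclusters) * top_fraction))
    primaries: list[Bicluster] = []
    for cand in sorted(biclusters, key=lambda b: b.layer_index):
        is_echo = False
        for k in primaries:
            cset, kset = set(cand.col_ids), set(k.col_ids)
            if len(cset & kset) / len(cset | kset) > merge_col_jaccard:
                is_echo = True
                break
        if not is_echo:
            primaries.append(cand)
    ordered = sorted(
        primaries,
        key=lambda b: (-b.mean_internal_corr, -(b.shape[0] * b.shape[1]), b.row_ids),
    )
    return ordered[:n_top]


# ---------------------------------------------------------------------------
# Nonlinear dependency classification

LABEL_CONSISTENT = "linear_consistent"
LABEL_DISCORDANT = "nonlinear_discordant"


def classify_dependency(
    pairs: pd.DataFrame,
    gene_group_means: pd.DataFrame,
    feature_status: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label pairs as linear-consistent or nonlinear-discordant.

    The screened metabolites are lowest (or absent) in GF, so linear
    extrapolation of the within-SPF correlation predicts the GF expression
    shift: rho < 0 predicts GF > SPF expression and rho > 0 predicts
    GF < SPF. Agreement is ``linear_consistent``; disagreement (e.g. a
    negatively correlated gene that is nevertheless *down* in GF) is
    ``nonlinear_discordant``. A zero GF shift counts as consistent with a
    zero-effect flag. Pairs with undefined rho are excluded.

    ``gene_group_means`` must have gene ids as index and GF / SPF columns;
    ``feature_status`` (optional) restricts pairs to gf_absent/spf_higher
    features.
    """
    pairs = pairs.dropna(subset=["rho"]).copy()
    if feature_status is not None:
        eligible = set(
            feature_status.loc[feature_status["status"] != "unchanged", "feature_id"]
        )
        pairs = pairs[pairs["feature_id"].isin(eligible)].copy()
    delta = (
        gene_group_means.loc[pairs["gene_id"], "GF"].to_numpy()
        - gene_group_means.loc[pairs["gene_id"], "SPF"].to_numpy()
    )
    gf_direction = np.sign(delta).astype(int)
    rho_sign = np.sign(pairs["rho"].to_numpy()).astype(int)
    predicted = -rho_sign
    zero_effect = gf_direction == 0
    label = np.where(
        zero_effect | (gf_direction == predicted), LABEL_CONSISTENT, LABEL_DISCORDANT
    )
    out = pairs[["feature_id", "gene_id"]].copy()
    out["rho_spf"] = pairs["rho"].to_numpy()
    out["gf_direction"] = gf_direction
    out["label"] = label
    out["zero_effect"] = zero_effect
    return out.reset_index(drop=True)
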