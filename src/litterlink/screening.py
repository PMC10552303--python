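"""Per-tissue preprocessing: prefilter, normalization, DE stand-in,
metabolite status classification, litter averaging, and twin-similarity QC.

The gene prefilter and the per-dam averaging mirror the upstream study
conditions: genes must show >= 5 reads in >= 12 fetuses (11 for brain), and
because transcriptomics and metabolomics were performed on *different*
fetuses of each litter, all cross-omics association is computed on the
per-dam mean of the two fetuses. The twin-similarity permutation test
verifies the premise that littermates are more alike than unrelated
fetuses, which is what justifies that averaging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsMatrix, make_de_table

logger = logging.getLogger("litterlink")

STATUS_GF_ABSENT = "gf_absent"
STATUS_SPF_HIGHER = "spf_higher"
STATUS_UNCHANGED = "unchanged"


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


# ---------------------------------------------------------------------------
# Gene prefilter and normalization


def prefilter_genes(counts: OmicsMatrix, min_reads: int, min_samples: int) -> OmicsMatrix:
    """Retain genes with >= min_reads in >= min_samples samples (order kept)."""
    if counts.kind != "counts":
        raise ValueError("prefilter_genes requires a counts matrix")
    n_samples = counts.shape[1]
    if min_samples > n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {n_samples} samples present"
        )
    keep = (counts.data.to_numpy() >= min_reads).sum(axis=1) >= min_samples
    out = OmicsMatrix(counts.data.loc[keep].copy(), "counts")
    logger.info(
        "prefilter: kept %d/%d genes (>=%d reads in >=%d samples)",
        out.shape[0], counts.shape[0], min_reads, min_samples,
    )
    return out


def normalize_counts(counts: OmicsMatrix) -> tuple[OmicsMatrix, pd.Series]:
    """Median-of-ratios size-factor normalization.

    The reference is the per-gene geometric mean across samples, computed
    over genes with all-positive counts; each sample's size factor is the
    median count/reference ratio over those genes, and normalized values
    are counts divided by the sample's size factor.
    """
    if counts.kind != "counts":
        raise ValueError("normalize_counts requires a counts matrix")
    values = counts.data.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; a pseudo-reference "
            "(e.g. adding a pseudocount) would be needed for these data"
        )
    logref = np.log(values[all_positive]).mean(axis=1)
    ratios = np.log(values[all_positive]) - logref[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    normalized = pd.DataFrame(
        values / size_factors[None, :],
        index=counts.data.index, columns=counts.data.columns,
    )
    sf = pd.Series(size_factors, index=counts.data.columns, name="size_factor")
    logger.info(
        "normalize: %d reference genes, size factors %.3f-%.3f",
        int(all_positive.sum()), sf.min(), sf.max(),
    )
    return OmicsMatrix(normalized, "intensities"), sf


# ---------------------------------------------------------------------------
# DE stand-in


def de_standin(norm_counts: OmicsMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Simple two-group DE stand-in: OLS on log2(normalized+1), sex-adjusted.

    Per gene, fit y = b0 + b1*GF + b2*male and test b1 (two-sided t on
    n-3 df), then BH-adjust. log2_fold_change is b1, i.e. GF minus SPF, so
    negative values mean downregulated in GF. This is a clearly flagged
    stand-in (source='standin') for an externally supplied DE table from a
    dedicated count-model tool; it exists so synthetic runs are
    self-contained.
    """
    md = metadata.set_index("sample_id").loc[norm_counts.sample_ids]
    for group in ("GF", "SPF"):
        if (md["group"] == group).sum() < 2:
            raise ValueError(f"group {group} has fewer than 2 samples")
    for sex in ("F", "M"):
        if (md["sex"] == sex).sum() < 1:
            raise ValueError(f"sex {sex} absent; the stand-in adjusts for sex")

    y = np.log2(norm_counts.data.to_numpy(dtype=float) + 1.0)  # genes x samples
    n = y.shape[1]
    x = np.column_stack(
        [
            np.ones(n),
            (md["group"] == "GF").to_numpy(dtype=float),
            (md["sex"] == "M").to_numpy(dtype=float),
        ]
    )
    xtx_inv = np.linalg.inv(x.T @ x)
    hat = xtx_inv @ x.T  # 3 x n
    beta = y @ hat.T  # genes x 3
    resid = y - beta @ x.T
    df_resid = n - 3
    s2 = (resid**2).sum(axis=1) / df_resid
    zero_var = np.ptp(y, axis=1) == 0
    se = np.sqrt(np.maximum(s2, 0.0) * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, 1] / se
    p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    p = np.where(se == 0, np.where(beta[:, 1] == 0, 1.0, 0.0), p)
    p[zero_var] = 1.0
    p_adj = bh_adjust(p)
    return make_de_table(norm_counts.feature_ids, beta[:, 1], p, p_adj,
                         source="standin", zero_variance=zero_var)


# ---------------------------------------------------------------------------
# Metabolite status


def classify_metabolites(
    intensities: OmicsMatrix,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    test: str = "welch",
) -> pd.DataFrame:
    """Classify each feature as gf_absent, spf_higher, or unchanged.

    gf_absent: zero GF detections and detection in at least half of the SPF
    samples (the quorum guards against calling a near-universally absent
    feature microbially derived). Otherwise a Welch t-test (or rank-sum) on
    log2(intensity+1) with BH control: spf_higher when p_adj < alpha with a
    higher SPF mean.
    """
    md = metadata.set_index("sample_id").loc[intensities.sample_ids]
    tissues = md["tissue"].unique()
    if len(tissues) != 1:
        raise ValueError(f"expected samples from one tissue, got {list(tissues)}")
    tissue = tissues[0]
    gf_cols = md.index[md["group"] == "GF"]
    spf_cols = md.index[md["group"] == "SPF"]
    if len(gf_cols) < 3 or len(spf_cols) < 3:
        raise ValueError(
            f"tissue {tissue!r}: need >= 3 samples per group "
            f"(got GF={len(gf_cols)}, SPF={len(spf_cols)})"
        )

    data = intensities.data
    detected = data.notna() & (data > 0)
    filled = data.fillna(0.0)
    n_detect_gf = detected[gf_cols].sum(axis=1)
    n_detect_spf = detected[spf_cols].sum(axis=1)
    quorum = int(np.ceil(len(spf_cols) / 2))
    gf_absent = (n_detect_gf == 0) & (n_detect_spf >= quorum)

    log_gf = np.log2(filled[gf_cols].to_numpy(dtype=float) + 1.0)
    log_spf = np.log2(filled[spf_cols].to_numpy(dtype=float) + 1.0)
    direction = np.sign(log_spf.mean(axis=1) - log_gf.mean(axis=1)).astype(int)

    tested = ~gf_absent.to_numpy()
    p = np.full(len(data), np.nan)
    if tested.any():
        if test == "welch":
            with np.errstate(divide="ignore", invalid="ignore"):
                res = stats.ttest_ind(log_spf[tested], log_gf[tested], axis=1,
                                      equal_var=False)
            p_t = np.asarray(res.pvalue, dtype=float)
        elif test == "ranksum":
            p_t = np.array(
                [
                    stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                    if not np.array_equal(a, b) else 1.0
                    for a, b in zip(log_spf[tested], log_gf[tested])
                ]
            )
        else:
            raise ValueError(f"unknown metabolite test {test!r}")
        p_t = np.where(np.isnan(p_t), 1.0, p_t)  # zero variance in both groups
        p[tested] = p_t
    p_adj = np.full(len(data), np.nan)
    if tested.any():
        p_adj[tested] = bh_adjust(p[tested])

    status = np.where(
        gf_absent,
        STATUS_GF_ABSENT,
        np.where((p_adj < alpha) & (direction > 0), STATUS_SPF_HIGHER, STATUS_UNCHANGED),
    )
    out = pd.DataFrame(
        {
            "feature_id": data.index,
            "tissue": tissue,
            "status": status,
            "n_detect_gf": n_detect_gf.to_numpy(),
            "n_detect_spf": n_detect_spf.to_numpy(),
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
        }
    ).reset_index(drop=True)
    logger.info(
        "classify_metabolites[%s]: %d gf_absent, %d spf_higher, %d unchanged",
        tissue,
        int((out["status"] == STATUS_GF_ABSENT).sum()),
        int((out["status"] == STATUS_SPF_HIGHER).sum()),
        int((out["status"] == STATUS_UNCHANGED).sum()),
    )
    return out


# ---------------------------------------------------------------------------
# Litter averaging


@dataclass
class LitterMatrix:
    """Per-dam means of a features x samples matrix (one tissue, one assay)."""

    data: pd.DataFrame  # features x dams
    n_fetuses: pd.Series  # dam -> number of averaged fetuses

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def dam_ids(self) -> list[str]:
        return list(self.data.columns)

    def restrict_dams(self, dams) -> "LitterMatrix":
        return LitterMatrix(self.data.loc[:, list(dams)].copy(),
                            self.n_fetuses.loc[list(dams)].copy())

    def restrict_features(self, features) -> "LitterMatrix":
        return LitterMatrix(self.data.loc[list(features)].copy(), self.n_fetuses.copy())


def average_litters(matrix: OmicsMatrix, metadata: pd.DataFrame) -> LitterMatrix:
    """Arithmetic per-dam mean over each dam's fetuses; dams ordered by id."""
    md = metadata.set_index("sample_id").loc[matrix.sample_ids]
    if md["tissue"].nunique() > 1 or md["assay"].nunique() > 1:
        raise ValueError("average_litters expects samples from one tissue and one assay")
    dam_of = md["dam_id"]
    means = matrix.data.astype(float).T.groupby(dam_of).mean().T
    means = means.sort_index(axis=1)
    n_fetuses = dam_of.value_counts().sort_index()
    singles = n_fetuses.index[n_fetuses == 1]
    if len(singles):
        logger.warning("singleton litters: %s", list(singles))
    return LitterMatrix(means, n_fetuses)


# ---------------------------------------------------------------------------
# Twin-similarity QC


@dataclass
class TwinSimilarityResult:
    within_range: tuple[float, float]
    between_range: tuple[float, float]
    within_mean: float
    between_mean: float
    statistic: float
    p_perm: float
    n_perm: int

    def to_dict(self) -> dict:
        return {
            "within_range": list(self.within_range),
            "between_range": list(self.between_range),
            "within_mean": self.within_mean,
            "between_mean": self.between_mean,
            "statistic": self.statistic,
            "p_perm": self.p_perm,
            "n_perm": self.n_perm,
        }


def _sample_spearman(matrix: OmicsMatrix) -> np.ndarray:
    """Sample x sample Spearman similarity (average ranks; NaN as 0)."""
    vals = matrix.data.fillna(0.0).to_numpy(dtype=float).T  # samples x features
    ranks = stats.rankdata(vals, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = (ranks @ ranks.T) / np.outer(norms, norms)
    return np.clip(sim, -1.0, 1.0)


def twin_similarity_test(
    matrix: OmicsMatrix,
    metadata: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> TwinSimilarityResult:
    """Within- vs between-litter sample similarity, with a permutation p.

    statistic = mean within-litter pairwise Spearman - mean between-litter
    pairwise Spearman. The null reassigns fetuses to dams at random with
    litter sizes preserved (both groups permuted together); the one-sided p
    uses the +1 correction p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: permutation p is coarse", stacklevel=2)
    md = metadata.set_index("sample_id").loc[matrix.sample_ids]
    litter_sizes = md["dam_id"].value_counts()
    if (litter_sizes >= 2).sum() < 2:
        raise ValueError("need >= 2 dams with >= 2 fetuses for the twin test")

    sim = _sample_spearman(matrix)
    n = sim.shape[0]
    iu = np.triu_indices(n, k=1)
    pair_sim = sim[iu]
    dams = md["dam_id"].to_numpy()

    def stat(labels: np.ndarray) -> float:
        within = labels[iu[0]] == labels[iu[1]]
        if np.isnan(pair_sim).all() or not within.any() or within.all():
            return 0.0
        return float(np.nanmean(pair_sim[within]) - np.nanmean(pair_sim[~within]))

    within_mask = dams[iu[0]] == dams[iu[1]]
    within_vals = pair_sim[within_mask]
    between_vals = pair_sim[~within_mask]
    finite = pair_sim[~np.isnan(pair_sim)]
    if finite.size == 0 or np.allclose(finite, 1.0):
        # all expression profiles identical: no separation is measurable
        observed = 0.0
        p_perm = 1.0
    else:
        observed = stat(dams)
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            exceed += stat(rng.permutation(dams)) >= observed
        p_perm = (1 + exceed) / (1 + n_perm)
    def _safe(fn, vals):
        vals = vals[~np.isnan(vals)]
        return float(fn(vals)) if vals.size else float("nan")

    return TwinSimilarityResult(
        within_range=(_safe(np.min, within_vals), _safe(np.max, within_vals)),
        between_range=(_safe(np.min, between_vals), _safe(np.max, between_vals)),
        within_mean=_safe(np.mean, within_vals),
        between_mean=_safe(np.mean, between_vals),
        statistic=float(observed),
        p_perm=float(p_perm),
        n_perm=n_perm,
    )
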