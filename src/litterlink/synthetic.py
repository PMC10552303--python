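"""Twin-litter GF/SPF multi-omics simulator with known planted structure.

The generator emulates the study design this package analyses: 6 germ-free
(GF) and 6 specific-pathogen-free (SPF) pregnant dams, with 4 fetuses
sampled per dam — two for transcriptomics and two for metabolomics — across
three tissues. Litters are the unit of biological replication: fetuses of a
dam share a per-gene/per-feature dam random effect (log scale), which makes
twins far more similar than unrelated fetuses and motivates the per-dam
averaging the downstream pipeline performs.

Planted structure, all recorded in :class:`SyntheticTruth`:

* a subset of metabolite features absent in every GF sample (microbially
  derived compounds) and a subset significantly less abundant in GF;
* ``n_driver_features`` driver metabolites, each heading a small family of
  co-varying companion features (one compound observed as several LC-MS
  molecular features, or a chemically related family such as aryl sulfates).
  Each SPF dam carries a latent exposure per driver; the driver's family
  tracks it in the metabolome and the driver's linked genes track it in the
  transcriptome, producing within-SPF dam-level dose-response correlations;
* discordant pairs: linked genes coupled negatively to their driver within
  SPF yet additionally suppressed in GF, violating linear extrapolation
  (the pattern reported for e.g. carnitine-shuttle genes vs aryl sulfates);
* gene sets enriched for each driver's linked genes (many small overlapping
  subsets, so ORA hit counts grade with evidence), plus background sets;
* background differentially expressed genes and sex-effect genes, so the
  DE stand-in's group and sex terms both have work to do.

Counts are negative-binomial (gene baseline x dam effect x sex effect x
group/coupling effect); intensities are log-normal with a detection floor.
All randomness flows from one integer seed; the same seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    GeneSetCollection,
    OmicsMatrix,
    validate_metadata,
    write_gmt,
    write_matrix,
    write_metadata,
)

__all__ = ["SimConfig", "SyntheticTruth", "generate_synthetic_study",
           "generate_null_study", "write_study"]

# Log-scale coupling slope of linked genes on the standardized dam exposure.
# Large enough that the planted dose-response dominates the dam random effect
# and counting noise on well-expressed genes (see docs/methods.md).
_BETA = 1.5
# Log-intensity scale of the dam exposure in driver/companion features.
_EXPOSURE_SCALE = 1.0
# Extra exposure noise of driver features themselves (near-faithful reporters).
_DRIVER_NOISE_SD = 0.05


class SimulationError(ValueError):
    """The simulation configuration is invalid or internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design and generative-model parameters (defaults = study layout)."""

    n_dams_per_group: int = 6
    fetuses_per_dam_per_assay: int = 2
    tissues: tuple[str, ...] = ("intestine", "brain", "placenta")
    n_genes: int = 2000
    n_features: int = 500
    n_driver_features: int = 5
    genes_per_driver: int = 30
    n_gene_sets: int = 100
    gene_set_size_range: tuple[int, int] = (10, 80)
    frac_gf_absent: float = 0.05
    frac_spf_higher: float = 0.15
    litter_sd: float = 0.3
    sex_effect_genes: int = 50
    nb_dispersion: tuple[float, float] = (0.05, 0.5)
    detection_limit: float = 500.0
    coupling_strength: float = 0.95
    n_discordant_pairs: int = 20
    seed: int = 0
    # family / effect-size parameters (package's own minimal assumptions)
    companions_per_driver: int = 4
    companion_noise_sd: float = 1.0
    enriched_sets_per_driver: int = 16
    n_background_de_genes: int = 100
    background_de_effect: float = 1.0  # natural-log GF offset of background DE genes
    sex_effect_size: float = 0.5  # natural-log male offset
    gf_offset: float = 2.0  # natural-log GF shift of driver-linked genes
    spf_fold_change: float = 4.0  # SPF / GF intensity ratio of spf_higher features
    gene_baseline_logmean: float = math.log(200.0)
    gene_baseline_logsd: float = 1.5
    feature_baseline_logmean: float = math.log(1e5)
    feature_baseline_logsd: float = 1.0
    fetus_intensity_sd: float = 0.2
    nondetect_as_nan: bool = False
    duplicate_male_exception: bool = False

    @property
    def family_size(self) -> int:
        return 1 + self.companions_per_driver

    def validate(self) -> "SimConfig":
        if self.n_dams_per_group < 3:
            raise SimulationError(
                "n_dams_per_group must be >= 3: Spearman association on dam "
                "means is meaningless with fewer litters per group"
            )
        if self.genes_per_driver * self.n_driver_features > self.n_genes:
            raise SimulationError(
                "genes_per_driver * n_driver_features exceeds n_genes"
            )
        for name in ("fetuses_per_dam_per_assay", "n_genes", "n_features",
                     "n_gene_sets", "sex_effect_genes"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be a positive count")
        for name in ("frac_gf_absent", "frac_spf_higher"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.coupling_strength <= 1:
            raise SimulationError("coupling_strength must be in (0, 1]")
        if self.litter_sd < 0 or self.fetus_intensity_sd < 0:
            raise SimulationError("standard deviations must be non-negative")
        lo, hi = self.gene_set_size_range
        if lo < 1 or hi < lo:
            raise SimulationError("gene_set_size_range must be an increasing pair")
        if self.n_driver_features > 0:
            n_absent = round(self.frac_gf_absent * self.n_features)
            n_higher = round(self.frac_spf_higher * self.n_features)
            n_absent_fams = (self.n_driver_features + 1) // 2
            n_higher_fams = self.n_driver_features - n_absent_fams
            if (n_absent_fams * self.family_size > n_absent
                    or n_higher_fams * self.family_size > n_higher):
                raise SimulationError(
                    "driver families do not fit inside the gf_absent / "
                    "spf_higher fractions; increase the fractions or shrink "
                    "the families"
                )
        return self


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, for recovery tests."""

    driver_feature_ids: list[str] = field(default_factory=list)
    gf_absent_feature_ids: list[str] = field(default_factory=list)
    spf_higher_feature_ids: list[str] = field(default_factory=list)
    linked_pairs: list[tuple[str, str]] = field(default_factory=list)
    enriched_set_ids: dict[str, list[str]] = field(default_factory=dict)
    discordant_pairs: list[tuple[str, str]] = field(default_factory=list)
    de_gene_ids: dict[str, int] = field(default_factory=dict)  # gene -> sign of GF-SPF
    sex_effect_gene_ids: list[str] = field(default_factory=list)
    dam_latent_exposures: pd.DataFrame | None = None  # dams x drivers
    family_feature_ids: dict[str, list[str]] = field(default_factory=dict)

    def linked_genes_of(self, driver: str) -> list[str]:
        return [g for f, g in self.linked_pairs if f == driver]

    def to_json(self, path) -> None:
        payload = {
            "driver_feature_ids": self.driver_feature_ids,
            "gf_absent_feature_ids": self.gf_absent_feature_ids,
            "spf_higher_feature_ids": self.spf_higher_feature_ids,
            "linked_pairs": [list(p) for p in self.linked_pairs],
            "enriched_set_ids": self.enriched_set_ids,
            "discordant_pairs": [list(p) for p in self.discordant_pairs],
            "de_gene_ids": self.de_gene_ids,
            "sex_effect_gene_ids": self.sex_effect_gene_ids,
            "dam_latent_exposures": (
                None if self.dam_latent_exposures is None
                else {
                    "dams": list(self.dam_latent_exposures.index),
                    "drivers": list(self.dam_latent_exposures.columns),
                    "values": self.dam_latent_exposures.to_numpy().tolist(),
                }
            ),
            "family_feature_ids": self.family_feature_ids,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        exposures = d.get("dam_latent_exposures")
        if exposures is not None:
            exposures = pd.DataFrame(
                np.asarray(exposures["values"], dtype=float),
                index=exposures["dams"], columns=exposures["drivers"],
            )
        return cls(
            driver_feature_ids=d["driver_feature_ids"],
            gf_absent_feature_ids=d["gf_absent_feature_ids"],
            spf_higher_feature_ids=d["spf_higher_feature_ids"],
            linked_pairs=[tuple(p) for p in d["linked_pairs"]],
            enriched_set_ids=d["enriched_set_ids"],
            discordant_pairs=[tuple(p) for p in d["discordant_pairs"]],
            de_gene_ids={k: int(v) for k, v in d["de_gene_ids"].items()},
            sex_effect_gene_ids=d["sex_effect_gene_ids"],
            dam_latent_exposures=exposures,
            family_feature_ids=d["family_feature_ids"],
        )


def _coupling_noise_sd(config: SimConfig) -> float:
    """Latent exposure noise targeting the configured within-SPF |rho|.

    Uses the bivariate-normal rank-correlation relation rho_S ~= (6/pi)
    asin(r/2): the Pearson r needed for the target Spearman is 2 sin(pi *
    rho_S / 6), and for y = beta*(z + eps) vs z we need total noise sd
    sigma with 1/sqrt(1 + sigma^2) = r. The dam random effect (litter_sd,
    scaled by the slope) spends part of that budget; counting noise on the
    dam-mean counts takes the remaining slack (calibrated on seeds 1-10 so
    realized dam-level |rho| concentrates at the target; docs/methods.md).
    """
    r = min(2.0 * math.sin(math.pi * config.coupling_strength / 6.0), 0.999999)
    sigma_total_sq = 1.0 / (r * r) - 1.0
    dam_part = (config.litter_sd / _BETA) ** 2
    return math.sqrt(max(sigma_total_sq - dam_part, 0.0025))


def _orthogonal_exposures(n_dams: int, n_drivers: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-driver dose orderings with low mutual rank correlation.

    Each driver's dam exposures are a permutation of evenly spaced normal
    quantiles. Orderings are chosen greedily so pairwise |Spearman| between
    drivers stays small; with only six litters, uncontrolled random
    orderings collide often enough to merge unrelated metabolite families.
    """
    quantiles = stats.norm.ppf((np.arange(n_dams) + 0.5) / n_dams)
    ranks = (np.argsort(np.argsort(quantiles)) + 1).astype(float)
    chosen: list[np.ndarray] = []
    for _ in range(n_drivers):
        best, best_cost = None, np.inf
        for _ in range(200):
            cand = rng.permutation(n_dams)
            cand_ranks = ranks[cand]
            cost = max(
                (abs(float(np.corrcoef(cand_ranks, ranks[c])[0, 1])) for c in chosen),
                default=0.0,
            )
            if cost < best_cost:
                best, best_cost = cand, cost
            if best_cost == 0.0:
                break
        chosen.append(best)
    return np.column_stack([quantiles[c] for c in chosen])


def _build_metadata(config: SimConfig) -> pd.DataFrame:
    dams_gf = [f"GF{i+1}" for i in range(config.n_dams_per_group)]
    dams_spf = [f"SPF{i+1}" for i in range(config.n_dams_per_group)]
    rows = []
    for tissue in config.tissues:
        for assay, tag in (("transcriptome", "t"), ("metabolome", "m")):
            for group, dams in (("GF", dams_gf), ("SPF", dams_spf)):
                for d_idx, dam in enumerate(dams):
                    for k in range(config.fetuses_per_dam_per_assay):
                        sex = ("F", "M")[k % 2]
                        if (config.duplicate_male_exception and assay == "metabolome"
                                and d_idx == 0):
                            sex = "M"
                        rows.append(
                            {
                                "sample_id": f"{dam}_{tissue}_{tag}{k+1}",
                                "dam_id": dam,
                                "group": group,
                                "sex": sex,
                                "tissue": tissue,
                                "assay": assay,
                            }
                        )
    return validate_metadata(pd.DataFrame(rows))


def _generate(config: SimConfig, null: bool):
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_genes, n_features = config.n_genes, config.n_features
    gene_ids = np.array([f"g{i:04d}" for i in range(n_genes)])
    feature_ids = np.array([f"m{i:04d}" for i in range(n_features)])
    dams_gf = [f"GF{i+1}" for i in range(config.n_dams_per_group)]
    dams_spf = [f"SPF{i+1}" for i in range(config.n_dams_per_group)]
    all_dams = dams_gf + dams_spf

    metadata = _build_metadata(config)
    truth = SyntheticTruth()

    # --- gene-level parameters -------------------------------------------
    base_log = rng.normal(config.gene_baseline_logmean, config.gene_baseline_logsd,
                          n_genes)
    disp = rng.uniform(config.nb_dispersion[0], config.nb_dispersion[1], n_genes)

    beta = np.zeros(n_genes)  # coupling slope on the driver exposure
    driver_of_gene = np.full(n_genes, -1)  # driver index per linked gene
    gf_gene_offset = np.zeros(n_genes)  # natural-log GF shift
    sex_offset = np.zeros(n_genes)

    n_drivers = 0 if null else config.n_driver_features
    linked_idx = np.empty(0, dtype=int)
    if n_drivers > 0:
        # plant couplings on well-expressed, low-dispersion genes so the
        # dose-response signal is not drowned by counting noise
        eligible = np.flatnonzero(base_log >= np.median(base_log))
        linked_idx = rng.choice(eligible, n_drivers * config.genes_per_driver,
                                replace=False)
        disp[linked_idx] = config.nb_dispersion[0]
        signs = rng.choice([-1.0, 1.0], size=linked_idx.size)
        beta[linked_idx] = _BETA * signs
        for d in range(n_drivers):
            block = linked_idx[d * config.genes_per_driver:(d + 1) * config.genes_per_driver]
            driver_of_gene[block] = d
        # discordant pairs: negative coupling AND GF suppression
        n_disc = min(config.n_discordant_pairs, linked_idx.size)
        disc_idx = rng.choice(linked_idx, n_disc, replace=False)
        beta[disc_idx] = -_BETA
        # consistent linked genes follow linear extrapolation (metabolite is
        # lowest in GF): negative slope -> gene up in GF, positive -> down
        gf_gene_offset[linked_idx] = -np.sign(beta[linked_idx]) * config.gf_offset
        gf_gene_offset[disc_idx] = -config.gf_offset
    else:
        disc_idx = np.empty(0, dtype=int)

    remaining = np.setdiff1d(np.arange(n_genes), linked_idx)
    if not null and config.n_background_de_genes > 0:
        bg_idx = rng.choice(remaining, min(config.n_background_de_genes, remaining.size),
                            replace=False)
        gf_gene_offset[bg_idx] = (rng.choice([-1.0, 1.0], bg_idx.size)
                                  * config.background_de_effect)
        remaining = np.setdiff1d(remaining, bg_idx)
    if not null and config.sex_effect_genes > 0:
        sex_idx = rng.choice(remaining, min(config.sex_effect_genes, remaining.size),
                             replace=False)
        sex_offset[sex_idx] = (rng.choice([-1.0, 1.0], sex_idx.size)
                               * config.sex_effect_size)
        truth.sex_effect_gene_ids = sorted(gene_ids[sex_idx])

    # --- feature-level parameters ----------------------------------------
    feat_base = rng.normal(config.feature_baseline_logmean,
                           config.feature_baseline_logsd, n_features)
    absent_mask = np.zeros(n_features, dtype=bool)
    higher_mask = np.zeros(n_features, dtype=bool)
    family_of_feature = np.full(n_features, -1)
    feature_noise = np.zeros(n_features)

    exposures = pd.DataFrame(0.0, index=all_dams,
                             columns=[f"driver{d}" for d in range(n_drivers)])
    driver_feat_idx = np.empty(0, dtype=int)
    if not null:
        n_absent = round(config.frac_gf_absent * n_features)
        n_higher = round(config.frac_spf_higher * n_features)
        perm = rng.permutation(n_features)
        fam = config.family_size
        fam_feats = [perm[d * fam:(d + 1) * fam] for d in range(n_drivers)]
        driver_feat_idx = np.array([f[0] for f in fam_feats], dtype=int)
        pool = perm[n_drivers * fam:]
        # alternate whole families between the absent and higher classes,
        # then pad each class with non-family features
        absent_members = [m for d, f in enumerate(fam_feats) if d % 2 == 0 for m in f]
        higher_members = [m for d, f in enumerate(fam_feats) if d % 2 == 1 for m in f]
        n_extra_absent = n_absent - len(absent_members)
        n_extra_higher = n_higher - len(higher_members)
        absent_members.extend(pool[:n_extra_absent])
        higher_members.extend(pool[n_extra_absent:n_extra_absent + n_extra_higher])
        absent_mask[np.asarray(absent_members, dtype=int)] = True
        higher_mask[np.asarray(higher_members, dtype=int)] = True

        for d, members in enumerate(fam_feats):
            family_of_feature[members] = d
            feature_noise[members] = config.companion_noise_sd
            feature_noise[members[0]] = _DRIVER_NOISE_SD

        # dose levels spread evenly across SPF litters (shuffled normal
        # quantiles): maternal exposures act as a dose design, and even
        # spacing keeps dam-level rank structure identifiable with only
        # six litters; drivers get mutually near-orthogonal orderings so
        # distinct metabolite families stay distinguishable
        if n_drivers > 0:
            z = _orthogonal_exposures(config.n_dams_per_group, n_drivers, rng)
            exposures.loc[dams_spf, :] = z

        # record truth
        truth.driver_feature_ids = [str(feature_ids[i]) for i in driver_feat_idx]
        truth.gf_absent_feature_ids = sorted(feature_ids[absent_mask])
        truth.spf_higher_feature_ids = sorted(feature_ids[higher_mask])
        truth.family_feature_ids = {
            str(feature_ids[driver_feat_idx[d]]): [str(feature_ids[i]) for i in fam_feats[d]]
            for d in range(n_drivers)
        }
        truth.linked_pairs = [
            (str(feature_ids[driver_feat_idx[driver_of_gene[g]]]), str(gene_ids[g]))
            for g in linked_idx
        ]
        truth.discordant_pairs = [
            (str(feature_ids[driver_feat_idx[driver_of_gene[g]]]), str(gene_ids[g]))
            for g in disc_idx
        ]
        de_sign = {}
        for g in np.flatnonzero(gf_gene_offset != 0):
            de_sign[str(gene_ids[g])] = int(np.sign(gf_gene_offset[g]))
        truth.de_gene_ids = de_sign
    truth.dam_latent_exposures = exposures

    sigma_c = _coupling_noise_sd(config)

    # --- counts ----------------------------------------------------------
    tx_md = metadata[metadata["assay"] == "transcriptome"]
    count_cols: dict[str, np.ndarray] = {}
    for tissue in config.tissues:
        md_t = tx_md[tx_md["tissue"] == tissue]
        dam_eff = rng.normal(0.0, config.litter_sd, (n_genes, len(all_dams)))
        dam_pos = {dam: i for i, dam in enumerate(all_dams)}
        # per-gene, per-dam latent coupling noise (dam-level biology, shared
        # by both fetuses of the dam)
        eps = rng.normal(0.0, sigma_c, (linked_idx.size, len(all_dams)))
        sample_order = list(md_t["sample_id"])
        log_mu = np.empty((n_genes, len(sample_order)))
        for s_pos, (_, row) in enumerate(md_t.iterrows()):
            dam = row["dam_id"]
            j = dam_pos[dam]
            col = base_log + dam_eff[:, j]
            if row["sex"] == "M":
                col = col + sex_offset
            if row["group"] == "GF":
                col = col + gf_gene_offset
            elif linked_idx.size:
                zd = exposures.loc[dam].to_numpy()
                col = col.copy()
                col[linked_idx] += beta[linked_idx] * (
                    zd[driver_of_gene[linked_idx]] + eps[:, j]
                )
            log_mu[:, s_pos] = col
        mu = np.exp(log_mu)
        r = 1.0 / disp[:, None]
        counts = rng.negative_binomial(r, r / (r + mu))
        for s_pos, sid in enumerate(sample_order):
            count_cols[sid] = counts[:, s_pos]
    counts_df = pd.DataFrame(count_cols, index=gene_ids)
    counts_matrix = OmicsMatrix(counts_df, "counts")

    # --- intensities ------------------------------------------------------
    mb_md = metadata[metadata["assay"] == "metabolome"]
    feat_cols: dict[str, np.ndarray] = {}
    ln_fold = math.log(config.spf_fold_change)
    for tissue in config.tissues:
        md_t = mb_md[mb_md["tissue"] == tissue]
        dam_eff = rng.normal(0.0, config.litter_sd, (n_features, len(all_dams)))
        # for exposure-driven features the dam latent exposure IS the dam
        # effect; an additional independent dam effect would scramble the
        # dose ranks the family is meant to report
        dam_eff[family_of_feature >= 0, :] = 0.0
        dam_pos = {dam: i for i, dam in enumerate(all_dams)}
        # per-feature, per-dam exposure reporting noise
        eps_f = rng.normal(0.0, 1.0, (n_features, len(all_dams))) * feature_noise[:, None]
        dam_log = np.empty((n_features, len(all_dams)))
        for dam, j in dam_pos.items():
            col = feat_base + dam_eff[:, j]
            is_gf = dam.startswith("GF")
            if not null:
                if is_gf:
                    col = col - higher_mask * ln_fold
                else:
                    in_family = family_of_feature >= 0
                    zd = exposures.loc[dam].to_numpy()
                    col = col.copy()
                    col[in_family] += _EXPOSURE_SCALE * (
                        zd[family_of_feature[in_family]] + eps_f[in_family, j]
                    )
                if is_gf:
                    col = np.where(absent_mask, -np.inf, col)
            dam_log[:, j] = col
        for _, row in md_t.iterrows():
            j = dam_pos[row["dam_id"]]
            vals = np.exp(dam_log[:, j]
                          + rng.normal(0.0, config.fetus_intensity_sd, n_features))
            below = vals < config.detection_limit
            vals = np.where(below, np.nan if config.nondetect_as_nan else 0.0, vals)
            feat_cols[row["sample_id"]] = vals
    intensities_df = pd.DataFrame(feat_cols, index=feature_ids)
    intensities_matrix = OmicsMatrix(intensities_df, "intensities")

    # --- gene sets --------------------------------------------------------
    collection = GeneSetCollection()
    set_counter = 0
    if not null:
        # overlapping planted subsets of varying size, imitating the nested
        # granularity of real ontology terms: a query covering most of a
        # driver's linked genes hits nearly all of them, a partial query
        # proportionally fewer, so hit counts grade with evidence strength
        for d in range(n_drivers):
            block = linked_idx[d * config.genes_per_driver:(d + 1) * config.genes_per_driver]
            driver_id = str(feature_ids[driver_feat_idx[d]])
            truth.enriched_set_ids[driver_id] = []
            for _ in range(config.enriched_sets_per_driver):
                set_counter += 1
                term = f"GS{set_counter:03d}"
                lo = min(5, block.size)
                hi = max(lo + 1, min(11, block.size + 1))
                size = int(rng.integers(lo, hi))
                part = rng.choice(block, size=size, replace=False)
                fillers = rng.choice(
                    np.setdiff1d(np.arange(n_genes), block),
                    size=2, replace=False,
                )
                collection.add(term, f"planted set for {driver_id}",
                               list(gene_ids[part]) + list(gene_ids[fillers]))
                truth.enriched_set_ids[driver_id].append(term)
    while set_counter < config.n_gene_sets:
        set_counter += 1
        size = int(rng.integers(config.gene_set_size_range[0],
                                config.gene_set_size_range[1] + 1))
        members = rng.choice(n_genes, size=min(size, n_genes), replace=False)
        collection.add(f"GS{set_counter:03d}", "background set",
                       list(gene_ids[members]))

    return counts_matrix, intensities_matrix, metadata, collection, truth


def generate_synthetic_study(config: SimConfig):
    """Generate (counts, intensities, metadata, gene sets, truth).

    Same config and seed always produce byte-identical outputs.
    """
    return _generate(config, null=False)


def generate_null_study(config: SimConfig):
    """Same generative model with every systematic effect removed.

    Group effects, drivers, couplings, absent/higher features AND sex
    effects are all zero, so fetuses are exchangeable across dams apart
    from the litter random effect; truth lists are empty. This is the
    type-I-error harness for the screening and QC statistics.
    """
    import dataclasses

    null_config = dataclasses.replace(config, n_driver_features=0,
                                      n_discordant_pairs=0)
    return _generate(null_config, null=True)


def write_study(dataset, outdir) -> dict[str, str]:
    """Write a generated study to the standard pipeline input files."""
    counts, intensities, metadata, collection, truth = dataset
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "counts": os.path.join(outdir, "counts.tsv"),
        "intensities": os.path.join(outdir, "intensities.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "gene_sets": os.path.join(outdir, "gene_sets.gmt"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_matrix(counts, paths["counts"])
    write_matrix(intensities, paths["intensities"])
    write_metadata(metadata, paths["metadata"])
    write_gmt(collection, paths["gene_sets"])
    truth.to_json(paths["truth"])
    return paths
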