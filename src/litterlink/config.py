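"""Pipeline configuration: thresholds, plaid settings, and tissue overrides.

Defaults encode the analysis conditions of the germ-free vs SPF fetal study
design this package reimplements: a Spearman pair screen at |rho| > 0.9 on
SPF dam means, cluster links at mean rho > 0.7 (0.6 for brain, where far
fewer genes are differentially expressed), BH significance at p.adj < 0.05,
and the gene prefilter of >= 5 reads in >= 12 fetuses (11 for brain, one
sample having been excluded there).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import yaml

logger = logging.getLogger("litterlink")

ROUTES = ("direct", "cluster", "bicluster")


class ConfigError(ValueError):
    """A configuration file contained an unknown key or out-of-range value."""


@dataclass(frozen=True)
class PipelineConfig:
    # association thresholds
    rho_pair: float = 0.9
    rho_cluster: float = 0.7
    rho_cluster_brain: float = 0.6
    use_absolute_rho: bool = True
    cluster_link_absolute: bool = False
    # significance
    alpha: float = 0.05
    # gene prefilter
    prefilter_min_reads: int = 5
    prefilter_min_samples: int = 12
    prefilter_min_samples_brain: int = 11
    # plaid biclustering
    max_layers: int = 10
    row_release: float = 0.7
    col_release: float = 0.7
    n_shuffles: int = 3
    iter_startup: int = 5
    iter_layer: int = 10
    bicluster_top_fraction: float = 0.5
    # enrichment
    ora_min_overlap: int = 2
    # hierarchical clustering calibration (mean members per cluster)
    target_cluster_genes: tuple[int, int] = (16, 43)
    target_cluster_features: tuple[int, int] = (7, 15)
    # permutation QC
    n_perm: int = 1000
    seed: int = 0
    # which tissues receive the brain overrides
    brain_tissues: tuple[str, ...] = ("brain",)
    # which genes enter the association routes
    gene_selection: str = "de_significant"  # or "all_prefiltered"
    metabolite_test: str = "welch"  # or "ranksum"
    score_aggregation: str = "rank_sum"  # or "hit_sum"
    routes: tuple[str, ...] = ROUTES
    top_n_detailed: int = 20

    def validate(self) -> "PipelineConfig":
        for name in ("rho_pair", "rho_cluster", "rho_cluster_brain"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in (
            "prefilter_min_reads", "prefilter_min_samples", "prefilter_min_samples_brain",
            "max_layers", "n_shuffles", "iter_startup", "iter_layer",
            "ora_min_overlap", "n_perm", "top_n_detailed",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        for name in ("row_release", "col_release", "bicluster_top_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        for name in ("target_cluster_genes", "target_cluster_features"):
            rng = getattr(self, name)
            if len(rng) != 2 or rng[0] < 1 or rng[1] < rng[0]:
                raise ConfigError(f"{name} must be an increasing pair of counts, got {rng}")
        if self.gene_selection not in ("de_significant", "all_prefiltered"):
            raise ConfigError(f"unknown gene_selection {self.gene_selection!r}")
        if self.metabolite_test not in ("welch", "ranksum"):
            raise ConfigError(f"unknown metabolite_test {self.metabolite_test!r}")
        if self.score_aggregation not in ("rank_sum", "hit_sum"):
            raise ConfigError(f"unknown score_aggregation {self.score_aggregation!r}")
        unknown_routes = set(self.routes) - set(ROUTES)
        if unknown_routes or not self.routes:
            raise ConfigError(f"routes must be a non-empty subset of {ROUTES}")
        return self

    def for_tissue(self, tissue: str) -> "PipelineConfig":
        """Apply per-tissue overrides (brain: lower cluster rho, n-1 prefilter)."""
        if tissue in self.brain_tissues:
            return dataclasses.replace(
                self,
                rho_cluster=self.rho_cluster_brain,
                prefilter_min_samples=self.prefilter_min_samples_brain,
            )
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d


_TUPLE_FIELDS = {
    "target_cluster_genes": int,
    "target_cluster_features": int,
    "brain_tissues": str,
    "routes": str,
}


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML key-value file plus overrides.

    Unset keys take the dataclass defaults; unknown keys raise ConfigError so
    typos never pass silently. The full effective configuration is echoed to
    the log.
    """
    data: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: expected a mapping of keys to values")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    for key, elem_type in _TUPLE_FIELDS.items():
        if key in data:
            if not isinstance(data[key], (list, tuple)):
                raise ConfigError(f"{key} must be a list")
            data[key] = tuple(elem_type(v) for v in data[key])
    cfg = PipelineConfig(**data).validate()
    logger.info("effective config: %s", cfg.to_dict())
    return cfg
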