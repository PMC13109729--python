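"""End-to-end demultiplexing workflow and its configuration.

``run_demux`` wires the stages together in the canonical order:

    local CLR -> k-medoids (optional select_k) -> core cells -> cluster
    labels -> pooled covariance + pseudoinverse -> Mahalanobis distances ->
    initial classification -> outlier split -> doublet identities ->
    mRNA reclassification -> optional weak-hashtag rescue

Every tunable lives in :class:`RunConfig`; defaults are the method's
recommended settings. The configuration plus the seed reproduce a run bit
for bit on one platform.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields

from . import classification as cls
from . import clustering, mahalanobis, normalization
from .dataset import HashingDataset
from .errors import ConfigurationError

__all__ = ["RunConfig", "PipelineArtifacts", "run_demux"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of the demultiplexing workflow.

    Defaults: pseudo-count 1 in the CLR proportion; k = N clusters (one per
    hashtag); core quantile 0.9; medoid-based cluster labelling; chi-square
    distance cutoff at p = 0.975 with df = N-1, which adapts to the outlier
    fraction (the empirical 0.95-quantile alternative caps the outlier rate
    at 5% by construction);
    antimode split needs >= 10 outliers; mRNA reclassification on whenever
    library sizes are attached.
    """

    pseudo_count: float = 1.0
    k: int | None = None  # None -> number of hashtags
    k2: int | None = None  # enables select_k when set
    lfc_threshold: float = 1.0
    cluster_mode: str = "auto"
    core_quantile: float = 0.9
    label_method: str = "medoid"
    negative_clusters: tuple[int, ...] = field(default_factory=tuple)
    cutoff_mode: str = "chisq"
    cutoff_q: float = 0.95
    chisq_p: float = 0.975
    min_outliers: int = 10
    mrna_reclass: bool = True
    rescue_hashtag: str | None = None
    rescue_min_log_count: float | None = None
    rescue_min_clr_margin: float | None = None
    rank_tolerance: float = 1e-10
    seed: int = 0

    def validate(self) -> None:
        if self.pseudo_count <= 0:
            raise ConfigurationError("pseudo_count must be positive")
        if not 0 < self.core_quantile <= 1:
            raise ConfigurationError("core_quantile must be in (0, 1]")
        if not 0 < self.cutoff_q < 1:
            raise ConfigurationError("cutoff_q must be in (0, 1)")
        if not 0 < self.chisq_p < 1:
            raise ConfigurationError("chisq_p must be in (0, 1)")
        if self.cutoff_mode not in ("quantile", "chisq"):
            raise ConfigurationError(f"unknown cutoff_mode {self.cutoff_mode!r}")
        if self.cluster_mode not in ("auto", "pam", "clara"):
            raise ConfigurationError(f"unknown cluster_mode {self.cluster_mode!r}")
        if self.label_method not in ("medoid", "average"):
            raise ConfigurationError(f"unknown label_method {self.label_method!r}")
        if self.min_outliers < 0:
            raise ConfigurationError("min_outliers must be >= 0")
        if self.rescue_hashtag is not None and (
            self.rescue_min_log_count is None or self.rescue_min_clr_margin is None
        ):
            raise ConfigurationError(
                "rescue_hashtag requires rescue_min_log_count and "
                "rescue_min_clr_margin"
            )

    @classmethod
    def from_dict(cls, values: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "negative_clusters" in values and values["negative_clusters"] is not None:
            values = dict(values)
            values["negative_clusters"] = tuple(
                int(v) for v in values["negative_clusters"]
            )
        cfg = cls(**values)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["negative_clusters"] = list(d["negative_clusters"])
        return d


@dataclass
class PipelineArtifacts:
    """Intermediate objects of a run, kept for diagnostics and plots."""

    clr: normalization.ClrMatrix
    model: clustering.ClusterModel
    cov: mahalanobis.CovarianceModel
    distances: mahalanobis.DistanceMatrix
    k_used: int


def run_demux(
    data: HashingDataset, config: RunConfig | None = None
) -> tuple[cls.DemuxResult, PipelineArtifacts]:
    """Demultiplex a hashing dataset; returns the result and intermediates."""
    config = config or RunConfig()
    config.validate()

    clr = normalization.local_clr(data, pseudo_count=config.pseudo_count)
    logger.info("local CLR computed for %d droplets x %d hashtags",
                clr.n_droplets, clr.n_hashtags)

    k = config.k if config.k is not None else data.n_hashtags
    if config.k2 is not None:
        k = clustering.select_k(
            clr, k, config.k2,
            lfc_threshold=config.lfc_threshold,
            mode=config.cluster_mode,
            seed=config.seed,
        )
        logger.info("select_k chose k=%d", k)
    model = clustering.kmedoids_cluster(
        clr, k, mode=config.cluster_mode, seed=config.seed
    )
    model = clustering.flag_core_cells(model, clr, quantile=config.core_quantile)
    model = clustering.label_clusters(
        model,
        clr,
        data.hashtag_names,
        method=config.label_method,
        hto_library_size=data.hto_library_size,
        forced_negative=set(config.negative_clusters),
    )
    logger.info("cluster labels: %s; negative clusters: %s",
                model.label_map, sorted(model.negative_cluster_ids))

    cov = mahalanobis.pooled_covariance(
        clr, model, rank_tolerance=config.rank_tolerance
    )
    distances = mahalanobis.mahalanobis_distances(clr, model, cov)

    result = cls.initial_classify(
        distances, model, data,
        cutoff_mode=config.cutoff_mode,
        q=config.cutoff_q,
        chisq_p=config.chisq_p,
    )
    result = cls.split_outliers(result, data, min_outliers=config.min_outliers)
    result = cls.doublet_identities(result)
    if config.mrna_reclass:
        result = cls.mrna_reclassify(result, data)
    if config.rescue_hashtag is not None:
        result = cls.rescue_weak_hashtag(
            result, clr, data,
            target_hashtag=config.rescue_hashtag,
            min_log_count=config.rescue_min_log_count,
            min_clr_margin=config.rescue_min_clr_margin,
        )
    logger.info("final category counts: %s", result.counts())
    return result, PipelineArtifacts(
        clr=clr, model=model, cov=cov, distances=distances, k_used=k
    )
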