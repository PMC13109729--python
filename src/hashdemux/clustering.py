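"""K-medoids clustering of droplets in local CLR space.

Droplets sharing a hashtag form a cluster in CLR space, so the default
number of clusters is k = N (one per hashtag). Medoids — actual droplets —
serve as centroids, which keeps the centroid on the data manifold and
robust to doublet/negative outliers. On top of the raw clustering this
module provides:

* ``select_k`` — a log-fold-change heuristic comparing the top-cluster
  median CLR of every hashtag between two candidate k values, for data
  where an extra cluster (e.g. of empty droplets) hides a hashtag at k = N;
* ``flag_core_cells`` — per-cluster distance-quantile partition into core
  cells (used later for covariance estimation) and non-core cells;
* ``label_clusters`` — the hashtag <-> cluster correspondence, by medoid
  CLR or core-median CLR, with automatic fallback when two hashtags claim
  one cluster, and identification of candidate negative (unclaimed,
  low-library-size) clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kmedoids import assign_to_medoids, clara, pam
from .errors import ConflictError, DegenerateInputError
from .normalization import ClrMatrix

__all__ = [
    "ClusterModel",
    "kmedoids_cluster",
    "select_k",
    "flag_core_cells",
    "label_clusters",
]

logger = logging.getLogger(__name__)

#: above this many droplets, mode="auto" switches from exact PAM to CLARA
PAM_MAX_CELLS = 10_000


@dataclass
class ClusterModel:
    """A fitted k-medoids partition of the droplets.

    ``assignment`` uses 1-based cluster ids; ``centroids`` are the CLR
    profiles of the medoids. ``label_map`` (hashtag name -> cluster id) and
    ``negative_cluster_ids`` are filled by :func:`label_clusters`;
    ``core_flag`` by :func:`flag_core_cells` (initially all True).
    """

    k: int
    assignment: np.ndarray
    medoid_indices: np.ndarray
    centroids: np.ndarray
    core_flag: np.ndarray
    negative_cluster_ids: set[int] = field(default_factory=set)
    label_map: dict[str, int] = field(default_factory=dict)
    core_quantile: float = 0.9

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster_id)

    @property
    def labelled_cluster_ids(self) -> list[int]:
        return list(self.label_map.values())


def kmedoids_cluster(
    clr: ClrMatrix, k: int, mode: str = "auto", seed: int = 0
) -> ClusterModel:
    """Cluster droplets by Euclidean k-medoids on local CLR values.

    ``mode="pam"`` runs the exact build+swap algorithm, ``"clara"`` the
    subsampled variant; ``"auto"`` picks PAM below 10 000 droplets. The
    result is deterministic for a fixed seed (the seed only matters for
    clara subsampling).
    """
    if mode not in ("auto", "pam", "clara"):
        raise ValueError(f"unknown clustering mode {mode!r}")
    x = clr.values
    c = x.shape[0]
    if not 2 <= k <= c:
        raise ValueError(f"k={k} must be in [2, {c}]")
    n_distinct = np.unique(x, axis=0).shape[0]
    if k > n_distinct:
        raise DegenerateInputError(
            f"k={k} exceeds the {n_distinct} distinct droplet profiles"
        )
    if mode == "auto":
        mode = "pam" if c < PAM_MAX_CELLS else "clara"
    if mode == "pam":
        medoids = pam(x, k)
    else:
        medoids = clara(x, k, rng=np.random.default_rng(seed))
    assignment = assign_to_medoids(x, x[medoids]) + 1
    # guarantee each medoid stays in its own cluster even under ties
    assignment[medoids] = np.arange(1, k + 1)
    return ClusterModel(
        k=k,
        assignment=assignment,
        medoid_indices=medoids,
        centroids=x[medoids].copy(),
        core_flag=np.ones(c, dtype=bool),
    )


def _top_cluster_medians(clr: ClrMatrix, model: ClusterModel) -> np.ndarray:
    """Per hashtag: the maximum over clusters of the within-cluster median CLR."""
    meds = np.empty((model.k, clr.n_hashtags))
    for l in range(1, model.k + 1):
        meds[l - 1] = np.median(clr.values[model.members(l)], axis=0)
    return meds.max(axis=0)


def select_k(
    clr: ClrMatrix,
    k1: int,
    k2: int,
    lfc_threshold: float = 1.0,
    mode: str = "auto",
    seed: int = 0,
) -> int:
    """Choose between two candidate cluster counts.

    For each hashtag i, compute the median CLR within its best cluster at k1
    and at k2; the difference f_i is the log fold-change gained by the finer
    clustering. If any hashtag gains more than ``lfc_threshold``, the finer
    k2 is recommended — typically because its singlets were buried inside a
    larger cluster at k1.
    """
    if not k1 < k2:
        raise ValueError(f"need k1 < k2, got k1={k1}, k2={k2}")
    top1 = _top_cluster_medians(clr, kmedoids_cluster(clr, k1, mode=mode, seed=seed))
    top2 = _top_cluster_medians(clr, kmedoids_cluster(clr, k2, mode=mode, seed=seed))
    f = top2 - top1
    logger.info("select_k: per-hashtag top-cluster median gain %s", np.round(f, 3))
    return k2 if float(f.max()) > lfc_threshold else k1


def flag_core_cells(
    model: ClusterModel, clr: ClrMatrix, quantile: float = 0.9
) -> ClusterModel:
    """Mark the fraction of each cluster nearest its centroid as core.

    Within each non-negative cluster the Euclidean distances to the cluster
    medoid are ranked; droplets at or below the empirical ``quantile``
    (linear interpolation, ties inclusive) are core. Droplets of negative
    clusters are always non-core. Core cells alone feed the covariance
    estimate, so outliers near cluster edges cannot inflate it.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    core = np.zeros(clr.n_droplets, dtype=bool)
    for l in range(1, model.k + 1):
        idx = model.members(l)
        if l in model.negative_cluster_ids:
            continue
        d = np.linalg.norm(clr.values[idx] - model.centroids[l - 1], axis=1)
        # inverted-CDF quantile: the smallest observed distance with at least
        # a `quantile` fraction of droplets at or below it, so the core
        # fraction is always >= quantile (ties inclusive)
        thr = np.quantile(d, quantile, method="inverted_cdf")
        core[idx] = d <= thr
    model.core_flag = core
    model.core_quantile = quantile
    return model


def _resolve_labels(scores: np.ndarray, hashtag_names: list[str]) -> dict[str, int]:
    """scores[i, l]: affinity of hashtag i for cluster l (0-based); argmax
    with ties to the lowest cluster id. Raises on non-injective maps."""
    claims = scores.argmax(axis=1)
    label_map = {h: int(l) + 1 for h, l in zip(hashtag_names, claims)}
    seen: dict[int, str] = {}
    clashing: list[str] = []
    for h, l in label_map.items():
        if l in seen:
            clashing.extend([seen[l], h])
        seen.setdefault(l, h)
    if clashing:
        raise ConflictError(
            f"hashtags {sorted(set(clashing))} claim the same cluster",
            hashtags=sorted(set(clashing)),
        )
    return label_map


def label_clusters(
    model: ClusterModel,
    clr: ClrMatrix,
    hashtag_names: list[str],
    method: str = "medoid",
    hto_library_size: np.ndarray | None = None,
    forced_negative: set[int] | frozenset[int] = frozenset(),
) -> ClusterModel:
    """Assign each hashtag to the cluster where its CLR signal peaks.

    ``method="medoid"`` compares each hashtag's CLR value across cluster
    medoids; ``"average"`` compares the median CLR over core cells of each
    cluster (non-core cells excluded first). If the medoid map is not
    injective the average map is tried automatically; a persistent conflict
    raises :class:`ConflictError` naming the hashtags.

    Clusters claimed by no hashtag become negative-cluster candidates when
    their median HTO library size is below the global median (both
    conditions logged); ``forced_negative`` ids are always negative. All
    droplets of a negative cluster are marked non-core.
    """
    if method not in ("medoid", "average"):
        raise ValueError(f"unknown labelling method {method!r}")

    def medoid_scores() -> np.ndarray:
        return model.centroids.T  # (N, k): h_{i, medoid(l)}

    def average_scores() -> np.ndarray:
        scores = np.full((clr.n_hashtags, model.k), -np.inf)
        for l in range(1, model.k + 1):
            idx = model.members(l)
            core_idx = idx[model.core_flag[idx]]
            use = core_idx if core_idx.size else idx
            scores[:, l - 1] = np.median(clr.values[use], axis=0)
        return scores

    if method == "medoid":
        try:
            label_map = _resolve_labels(medoid_scores(), hashtag_names)
        except ConflictError as exc:
            logger.warning(
                "medoid labelling conflict (%s); retrying with average method",
                ", ".join(exc.hashtags),
            )
            label_map = _resolve_labels(average_scores(), hashtag_names)
    else:
        label_map = _resolve_labels(average_scores(), hashtag_names)

    negatives = set(int(l) for l in forced_negative)
    unclaimed = set(range(1, model.k + 1)) - set(label_map.values())
    if unclaimed and hto_library_size is not None:
        lib = np.asarray(hto_library_size, dtype=float)
        global_median = float(np.median(lib))
        for l in sorted(unclaimed):
            cluster_median = float(np.median(lib[model.members(l)]))
            low = cluster_median < global_median
            logger.info(
                "cluster %d unclaimed by any hashtag; median HTO library size "
                "%.1f vs global %.1f -> %snegative candidate",
                l, cluster_median, global_median, "" if low else "not a ",
            )
            if low:
                negatives.add(l)
    elif unclaimed:
        logger.info(
            "clusters %s unclaimed but no HTO library sizes given; "
            "not flagging as negative", sorted(unclaimed),
        )

    model.label_map = label_map
    model.negative_cluster_ids = negatives
    if negatives:
        neg_mask = np.isin(model.assignment, sorted(negatives))
        model.core_flag = model.core_flag & ~neg_mask
    return model
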