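"""Singlet / doublet / negative calls from the Mahalanobis distance matrix.

Classification proceeds in stages:

1. ``initial_classify`` — each droplet takes the hashtag whose labelled
   cluster is nearest in Mahalanobis distance. Droplets whose minimum
   distance exceeds a cutoff (an empirical quantile of the observed minimum
   distances, or a chi-square(N-1) quantile) are outliers; droplets of
   negative clusters are outliers regardless.
2. ``split_outliers`` — outliers are either negatives (too little hashtag
   material) or doublets (two cells' worth), so their log HTO library sizes
   are bimodal. The antimode of a kernel density estimate splits the pool:
   below -> Negative, at/above -> Doublet.
3. ``doublet_identities`` — each doublet is annotated with the hashtags of
   its two nearest clusters, its most plausible donor pair.
4. ``mrna_reclassify`` — with a paired transcriptome, droplets whose mRNA
   library size contradicts the call (a "negative" with more mRNA than the
   median singlet, a "doublet" with less) are rescued as singlets of their
   best hashtag.
5. ``rescue_weak_hashtag`` — explicit opt-in recovery of singlets of a
   hashtag so weakly labelled that its cells land among the negatives.

All ties break on hashtag input order; every comparison rule is strict or
inclusive exactly as documented, so runs are reproducible bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterModel
from .dataset import HashingDataset
from .errors import ConfigurationError
from .mahalanobis import DistanceMatrix
from .normalization import ClrMatrix

__all__ = [
    "DemuxResult",
    "initial_classify",
    "split_outliers",
    "doublet_identities",
    "mrna_reclassify",
    "rescue_weak_hashtag",
    "NEGATIVE",
    "DOUBLET",
]

logger = logging.getLogger(__name__)

NEGATIVE = "Negative"
DOUBLET = "Doublet"


@dataclass
class DemuxResult:
    """Per-droplet demultiplexing calls and their provenance.

    ``category`` holds the hashtag name for singlets, or ``"Negative"`` /
    ``"Doublet"``. ``best_hashtag`` / ``second_hashtag`` are the hashtags of
    the nearest and second-nearest labelled clusters and are always
    populated, whatever the category. Outliers that have not yet been split
    are provisionally ``"Negative"``; ``split_outliers`` refines them.
    """

    barcodes: list[str]
    hashtag_names: list[str]
    category: np.ndarray
    best_hashtag: np.ndarray
    second_hashtag: np.ndarray
    min_md: np.ndarray
    second_md: np.ndarray
    is_outlier_initial: np.ndarray
    reclassified_by_mrna: np.ndarray
    doublet_first: np.ndarray
    doublet_second: np.ndarray
    cutoff_used: float
    cutoff_mode: str
    antimode: float | None = None
    split_done: bool = field(default=False)

    @property
    def md_ratio(self) -> np.ndarray:
        """min_md / second_md in [0, 1]; defined as 1 when both are zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(self.second_md > 0, self.min_md / self.second_md, 1.0)
        return r

    @property
    def n_droplets(self) -> int:
        return len(self.barcodes)

    def is_singlet(self) -> np.ndarray:
        return ~np.isin(self.category, (NEGATIVE, DOUBLET))

    def counts(self) -> dict[str, int]:
        cats, n = np.unique(self.category, return_counts=True)
        return dict(zip(cats.tolist(), n.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "category": self.category,
                "doublet_first": self.doublet_first,
                "doublet_second": self.doublet_second,
                "min_md": self.min_md,
                "second_md": self.second_md,
                "md_ratio": self.md_ratio,
                "reclassified_by_mrna": self.reclassified_by_mrna,
            }
        )


def initial_classify(
    md: DistanceMatrix,
    model: ClusterModel,
    data: HashingDataset,
    cutoff_mode: str = "quantile",
    q: float = 0.95,
    chisq_p: float = 0.975,
) -> DemuxResult:
    """Assign singlets by minimum Mahalanobis distance; flag outliers.

    The minimum runs over labelled clusters only. The cutoff is either the
    empirical ``q``-quantile of the observed minimum distances (default) or
    the ``chisq_p`` quantile of a chi-square distribution on N-1 degrees of
    freedom. Comparison is strict: min_md < cutoff -> singlet of the best
    hashtag, otherwise outlier. Droplets in negative clusters bypass the
    cutoff and are outliers directly.
    """
    if cutoff_mode not in ("quantile", "chisq"):
        raise ValueError(f"unknown cutoff mode {cutoff_mode!r}")
    hashtags = data.hashtag_names
    missing = [h for h in hashtags if h not in model.label_map]
    if missing:
        raise ConfigurationError(f"hashtags without a labelled cluster: {missing}")

    cols = [model.label_map[h] - 1 for h in hashtags]
    md_h = md.md[:, cols]  # (C, N) distance to each hashtag's cluster
    order = np.argsort(md_h, axis=1, kind="stable")  # ties -> hashtag order
    c_idx = np.arange(md_h.shape[0])
    best_i, second_i = order[:, 0], order[:, 1]
    min_md = md_h[c_idx, best_i]
    second_md = md_h[c_idx, second_i]

    if cutoff_mode == "quantile":
        if not 0 < q < 1:
            raise ConfigurationError(f"cutoff quantile must be in (0,1), got {q}")
        cutoff = float(np.quantile(min_md, q))
    else:
        if not 0 < chisq_p < 1:
            raise ConfigurationError(f"chisq_p must be in (0,1), got {chisq_p}")
        cutoff = float(stats.chi2.ppf(chisq_p, df=len(hashtags) - 1))

    outlier = min_md >= cutoff
    if model.negative_cluster_ids:
        outlier |= np.isin(model.assignment, sorted(model.negative_cluster_ids))

    names = np.array(hashtags, dtype=object)
    category = names[best_i].copy()
    category[outlier] = NEGATIVE  # provisional until split_outliers
    c = md_h.shape[0]
    logger.info(
        "initial classification: cutoff=%.4g (%s), %d/%d outliers",
        cutoff, cutoff_mode, int(outlier.sum()), c,
    )
    return DemuxResult(
        barcodes=list(data.barcodes),
        hashtag_names=list(hashtags),
        category=category,
        best_hashtag=names[best_i].copy(),
        second_hashtag=names[second_i].copy(),
        min_md=min_md.astype(float),
        second_md=second_md.astype(float),
        is_outlier_initial=outlier,
        reclassified_by_mrna=np.zeros(c, dtype=bool),
        doublet_first=np.full(c, "", dtype=object),
        doublet_second=np.full(c, "", dtype=object),
        cutoff_used=cutoff,
        cutoff_mode=cutoff_mode,
    )


def _kde_antimode(values: np.ndarray) -> float | None:
    """Antimode of a 1-D sample by Gaussian KDE (Silverman bandwidth).

    Density on a 512-point grid over the data range; modes are local maxima.
    With >= 2 modes, returns the grid argmin strictly between the two
    highest-density modes; returns None when the density is unimodal or the
    KDE cannot be formed (e.g. zero variance).
    """
    try:
        kde = stats.gaussian_kde(values, bw_method="silverman")
    except np.linalg.LinAlgError:
        return None
    grid = np.linspace(values.min(), values.max(), 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    mode_idx = np.flatnonzero(interior) + 1
    if dens[0] > dens[1]:
        mode_idx = np.r_[0, mode_idx]
    if dens[-1] > dens[-2]:
        mode_idx = np.r_[mode_idx, 511]
    if mode_idx.size < 2:
        return None
    top_two = mode_idx[np.argsort(dens[mode_idx], kind="stable")[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    if hi - lo < 2:
        return None
    between = slice(lo + 1, hi)
    return float(grid[between][np.argmin(dens[between])])


def split_outliers(
    result: DemuxResult, data: HashingDataset, min_outliers: int = 10
) -> DemuxResult:
    """Split initial outliers into negatives and doublets by HTO library size.

    The split point is the KDE antimode of log(HTO_+ + 1) over outliers;
    below -> Negative, at/above -> Doublet. With fewer than ``min_outliers``
    outliers, or when no bimodal structure is found, the fallback boundary
    is the median singlet log HTO library size.
    """
    out = np.flatnonzero(result.is_outlier_initial)
    result.split_done = True
    if out.size == 0:
        return result
    log_lib = np.log(data.hto_library_size + 1.0)
    antimode: float | None = None
    if out.size >= min_outliers:
        antimode = _kde_antimode(log_lib[out])
    if antimode is None:
        singlets = result.is_singlet() & ~result.is_outlier_initial
        if singlets.any():
            antimode = float(np.median(log_lib[singlets]))
            logger.warning(
                "no bimodal outlier library-size structure; falling back to "
                "median singlet log HTO library size %.3f", antimode,
            )
        else:
            antimode = float(np.median(log_lib))
            logger.warning(
                "no singlets available; outlier split falls back to the "
                "global median log HTO library size %.3f", antimode,
            )
    is_neg = log_lib[out] < antimode
    result.category[out[is_neg]] = NEGATIVE
    result.category[out[~is_neg]] = DOUBLET
    result.antimode = antimode
    logger.info(
        "outlier split at log library size %.3f: %d negatives, %d doublets",
        antimode, int(is_neg.sum()), int((~is_neg).sum()),
    )
    return result


def doublet_identities(result: DemuxResult) -> DemuxResult:
    """Annotate every doublet with its (best, second-best) hashtag pair."""
    dbl = result.category == DOUBLET
    result.doublet_first[dbl] = result.best_hashtag[dbl]
    result.doublet_second[dbl] = result.second_hashtag[dbl]
    result.doublet_first[~dbl] = ""
    result.doublet_second[~dbl] = ""
    return result


def mrna_reclassify(result: DemuxResult, data: HashingDataset) -> DemuxResult:
    """Rescue outlier calls contradicted by the transcriptome.

    Threshold T = median log(L_c + 1) over current singlets. A Negative with
    log mRNA library size strictly above T, or a Doublet strictly below T,
    becomes a singlet of its best hashtag. Skipped (with a log message) when
    no mRNA library sizes are attached or no singlets exist.
    """
    if data.mrna_library_size is None:
        logger.info("no mRNA library sizes attached; skipping reclassification")
        return result
    singlet = result.is_singlet()
    if not singlet.any():
        logger.warning("no singlets present; skipping mRNA reclassification")
        return result
    log_l = np.log(np.asarray(data.mrna_library_size, dtype=float) + 1.0)
    threshold = float(np.median(log_l[singlet]))
    neg_up = (result.category == NEGATIVE) & (log_l > threshold)
    dbl_down = (result.category == DOUBLET) & (log_l < threshold)
    for mask in (neg_up, dbl_down):
        result.category[mask] = result.best_hashtag[mask]
        result.reclassified_by_mrna[mask] = True
        result.doublet_first[mask] = ""
        result.doublet_second[mask] = ""
    logger.info(
        "mRNA reclassification at T=%.3f: %d negatives and %d doublets "
        "became singlets", threshold, int(neg_up.sum()), int(dbl_down.sum()),
    )
    return result


def rescue_weak_hashtag(
    result: DemuxResult,
    clr: ClrMatrix,
    data: HashingDataset,
    target_hashtag: str,
    min_log_count: float,
    min_clr_margin: float,
) -> DemuxResult:
    """Opt-in recovery of singlets from a weakly labelled hashtag.

    A hashtag that barely binds yields counts too low to clear the
    Mahalanobis cutoff, so its cells sink into the negative pool. A Negative
    droplet is rescued as Singlet(target) when (a) its log(count+1) of the
    target is at least ``min_log_count`` and (b) the target's CLR value
    exceeds the droplet's second-highest CLR by at least ``min_clr_margin``.
    Both thresholds are explicit: sensible values depend on the dataset and
    should be read off the CLR distributions.
    """
    if target_hashtag not in data.hashtag_names:
        raise ValueError(f"unknown hashtag {target_hashtag!r}")
    j = data.hashtag_names.index(target_hashtag)
    log_count = np.log(data.hto_counts[:, j] + 1.0)
    clr_t = clr.values[:, j]
    others = np.delete(clr.values, j, axis=1)
    margin = clr_t - others.max(axis=1)
    rescue = (
        (result.category == NEGATIVE)
        & (log_count >= min_log_count)
        & (margin >= min_clr_margin)
    )
    result.category[rescue] = target_hashtag
    n = int(rescue.sum())
    if n:
        logger.info(
            "rescued %d negatives as %s singlets (log count >= %.2f, "
            "CLR margin >= %.2f)", n, target_hashtag, min_log_count, min_clr_margin,
        )
    return result
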