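"""Metrics for demultiplexing results, with and without a reference labelling.

With a reference (e.g. a SNP-based genotype demultiplexer), agreement is
summarized by per-category and overall concordance, and by micro-averaged
precision, recall, F1 and Matthews correlation computed from one-vs-rest
confusion totals pooled over categories. Without a reference, the separation
of the claimed singlet donors is quantified by the exact silhouette score,
the Calinski-Harabasz, Davies-Bouldin and Dunn indices on log-transformed
raw hashing counts. Library-size ratio diagnostics express the expectation
that doublets carry more material than any singlet donor, and every singlet
donor more than the negatives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import davies_bouldin_score, silhouette_samples

__all__ = [
    "ConfusionSummary",
    "MicroMetrics",
    "ClusteringIndices",
    "concordance",
    "micro_metrics",
    "library_size_ratios",
    "clustering_indices",
]

logger = logging.getLogger(__name__)

_MISSING = {"", "NA", "nan", "None"}


def _clean(pred, truth):
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.size} vs {truth.size}")
    ok = np.array(
        [t is not None and str(t) not in _MISSING and t == t for t in truth],
        dtype=bool,
    )
    return pred[ok], truth[ok], int((~ok).sum())


@dataclass
class ConfusionSummary:
    """One-vs-rest confusion counts per category and their pooled totals."""

    per_category: dict[str, tuple[int, int, int, int]]  # TP, TN, FP, FN
    ttp: int
    ttn: int
    tfp: int
    tfn: int

    @classmethod
    def from_labels(cls, pred, truth, categories) -> "ConfusionSummary":
        per = {}
        for cat in categories:
            p = pred == cat
            t = truth == cat
            tp = int(np.sum(p & t))
            tn = int(np.sum(~p & ~t))
            fp = int(np.sum(p & ~t))
            fn = int(np.sum(~p & t))
            per[cat] = (tp, tn, fp, fn)
        totals = np.array(list(per.values())).sum(axis=0)
        return cls(per, *(int(v) for v in totals))


@dataclass
class MicroMetrics:
    precision: float
    recall: float
    f1: float
    mcc: float


def concordance(pred, truth) -> dict:
    """Fraction of droplets assigned the same label by both methods.

    Per category C: |{pred = truth = C}| / n_compared; the overall value is
    the sum over categories, i.e. the plain agreement fraction. Missing
    truth labels are excluded from the denominator and counted.
    """
    pred, truth, n_missing = _clean(pred, truth)
    if pred.size == 0:
        raise ValueError("no comparable droplets (all truth labels missing)")
    total = pred.size
    cats = sorted({str(c) for c in truth} | {str(c) for c in pred})
    per = {c: float(np.sum((pred == c) & (truth == c))) / total for c in cats}
    return {
        "per_category": per,
        "overall": float(np.sum(pred == truth)) / total,
        "n_compared": total,
        "n_missing": n_missing,
    }


def micro_metrics(pred, truth, exclude_negatives: bool = False) -> MicroMetrics:
    """Micro-averaged precision, recall, F1 and MCC over one-vs-rest totals.

    Categories are the union of labels seen in either vector; with
    ``exclude_negatives`` the "Negative" category is dropped from the
    one-vs-rest set before pooling. P = TTP/(TTP+TFP), R = TTP/(TTP+TFN),
    F1 their harmonic mean, and MCC the binary Matthews coefficient of the
    pooled totals.
    """
    pred, truth, _ = _clean(pred, truth)
    cats = sorted({str(c) for c in truth} | {str(c) for c in pred})
    if exclude_negatives:
        cats = [c for c in cats if c != "Negative"]
    if not cats:
        raise ValueError("no categories to evaluate")
    summary = ConfusionSummary.from_labels(pred, truth, cats)
    return metrics_from_totals(summary.ttp, summary.ttn, summary.tfp, summary.tfn)


def metrics_from_totals(ttp: int, ttn: int, tfp: int, tfn: int) -> MicroMetrics:
    """P/R/F1/MCC from pooled confusion totals (zero denominators -> 0)."""
    p = ttp / (ttp + tfp) if ttp + tfp else 0.0
    r = ttp / (ttp + tfn) if ttp + tfn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    denom = np.sqrt(
        float(ttp + tfp) * (ttp + tfn) * (ttn + tfp) * (ttn + tfn)
    )
    mcc = (ttn * ttp - tfn * tfp) / denom if denom else 0.0
    return MicroMetrics(precision=p, recall=r, f1=f1, mcc=float(mcc))


def library_size_ratios(categories, sizes) -> dict:
    """Median library-size ratios: doublets vs singlets, singlets vs negatives.

    doublet_singlet = median(doublets) / max over donors of the donor's
    singlet median; singlet_negative = min donor median / median(negatives).
    A good demultiplexing shows both ratios comfortably above 1. A ratio
    whose categories are empty is reported as None with a flag.
    """
    categories = np.asarray(categories, dtype=object)
    sizes = np.asarray(sizes, dtype=float)
    if categories.shape != sizes.shape:
        raise ValueError("categories and sizes must have equal length")
    dbl = sizes[categories == "Doublet"]
    neg = sizes[categories == "Negative"]
    donors = sorted(
        {str(c) for c in categories} - {"Doublet", "Negative"}
    )
    donor_medians = {d: float(np.median(sizes[categories == d])) for d in donors}

    out: dict[str, float | None | dict] = {"donor_medians": donor_medians}
    if dbl.size and donor_medians:
        out["doublet_singlet_ratio"] = float(np.median(dbl)) / max(
            donor_medians.values()
        )
    else:
        out["doublet_singlet_ratio"] = None
        logger.warning("doublet/singlet ratio undefined (empty category)")
    if neg.size and donor_medians and np.median(neg) > 0:
        out["singlet_negative_ratio"] = min(donor_medians.values()) / float(
            np.median(neg)
        )
    else:
        out["singlet_negative_ratio"] = None
        logger.warning("singlet/negative ratio undefined (empty category or zero)")
    return out


@dataclass
class ClusteringIndices:
    silhouette_median: float
    silhouette_by_donor: dict[str, float]
    calinski_harabasz: float
    davies_bouldin: float
    dunn: float


def clustering_indices(values: np.ndarray, singlet_labels) -> ClusteringIndices:
    """Separation of singlet donors in log-count space (Euclidean distance).

    ``values`` are the raw hashing counts of singlets only (the caller
    excludes doublets and negatives); they are log(x+1)-transformed here.
    Silhouette is the exact per-droplet formula, summarized by per-donor
    and overall medians; donors with a single droplet are excluded from the
    silhouette with a warning. Calinski-Harabasz is between-group over
    within-group dispersion (+inf when within is zero), Davies-Bouldin the
    usual average worst-pair similarity, and Dunn the minimum inter-cluster
    distance over the maximum cluster diameter.
    """
    labels = np.asarray(singlet_labels, dtype=object)
    x = np.log(np.asarray(values, dtype=float) + 1.0)
    if x.shape[0] != labels.size:
        raise ValueError("values and labels must have equal length")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 donor labels among singlets")

    # silhouette: exclude donors represented by a single droplet
    singletons = set(uniq[counts < 2].tolist())
    if singletons:
        warnings.warn(
            f"donors {sorted(map(str, singletons))} have a single singlet; "
            "excluded from silhouette", RuntimeWarning, stacklevel=2,
        )
    sil_mask = ~np.isin(labels, sorted(singletons))
    sil_by_donor: dict[str, float] = {}
    sil_median = float("nan")
    if np.unique(labels[sil_mask]).size >= 2:
        sil = silhouette_samples(x[sil_mask], labels[sil_mask].astype(str))
        lab = labels[sil_mask]
        sil_by_donor = {
            str(d): float(np.median(sil[lab == d])) for d in np.unique(lab)
        }
        sil_median = float(np.median(sil))

    # Calinski-Harabasz with an explicit +inf for perfectly tight clusters
    overall = x.mean(axis=0)
    within = 0.0
    between = 0.0
    for d in uniq:
        xd = x[labels == d]
        mu = xd.mean(axis=0)
        within += float(((xd - mu) ** 2).sum())
        between += xd.shape[0] * float(((mu - overall) ** 2).sum())
    n, k = x.shape[0], uniq.size
    if within == 0.0:
        ch = float("inf")
    else:
        ch = (between / (k - 1)) / (within / (n - k))

    db = float(davies_bouldin_score(x, labels.astype(str)))

    d = squareform(pdist(x))
    max_diam = 0.0
    for lab in uniq:
        idx = np.flatnonzero(labels == lab)
        if idx.size > 1:
            max_diam = max(max_diam, float(d[np.ix_(idx, idx)].max()))
    min_inter = np.inf
    for i, a in enumerate(uniq):
        ia = np.flatnonzero(labels == a)
        for b in uniq[i + 1 :]:
            ib = np.flatnonzero(labels == b)
            min_inter = min(min_inter, float(d[np.ix_(ia, ib)].min()))
    dunn = float("inf") if max_diam == 0.0 else min_inter / max_diam

    return ClusteringIndices(
        silhouette_median=sil_median,
        silhouette_by_donor=sil_by_donor,
        calinski_harabasz=ch,
        davies_bouldin=db,
        dunn=dunn,
    )
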