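"""Pooled covariance of CLR profiles and Mahalanobis distances to centroids.

The distance that classifies a droplet is the quadratic form

    MD_{c,l} = (h_c - M^{(l)})^T  Gamma^+  (h_c - M^{(l)})

where h_c is the droplet's local CLR profile, M^{(l)} the medoid of cluster
l, and Gamma the covariance of CLR deviations pooled over the core cells of
all non-negative clusters:

    Gamma_{i,i'} = sum_l sum_{c in core(l)} (h_{i,c} - M_i^{(l)})(h_{i',c} - M_{i'}^{(l)}) / sum_l n_l

with n_l the number of core cells in cluster l (no Bessel correction).
Because every CLR profile sums to zero, Gamma is singular by construction
(rank <= N-1), so its Moore-Penrose pseudoinverse Gamma^+ — computed by SVD
with small singular values truncated — replaces the ordinary inverse. MD is
kept on the squared scale: under a Gaussian working model it is compared
against a chi-square distribution on N-1 degrees of freedom downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .clustering import ClusterModel
from .errors import InsufficientDataError
from .normalization import ClrMatrix

__all__ = [
    "CovarianceModel",
    "DistanceMatrix",
    "pooled_covariance",
    "pseudo_inverse",
    "mahalanobis_distances",
]

logger = logging.getLogger(__name__)


@dataclass
class CovarianceModel:
    """Pooled core-cell covariance, its pseudoinverse and SVD spectrum."""

    gamma: np.ndarray
    gamma_pinv: np.ndarray
    singular_values: np.ndarray
    rank_tolerance: float
    n_core_used: int

    @property
    def rank(self) -> int:
        s = self.singular_values
        if s.size == 0 or s[0] == 0:
            return 0
        return int(np.sum(s > self.rank_tolerance * s[0]))


@dataclass
class DistanceMatrix:
    """Squared Mahalanobis distances, droplets x clusters."""

    md: np.ndarray


def pseudo_inverse(
    gamma: np.ndarray, rank_tolerance: float = 1e-10, n_core_used: int = 0
) -> CovarianceModel:
    """Moore-Penrose pseudoinverse of a symmetric PSD matrix via SVD.

    Singular values below ``rank_tolerance`` times the largest are treated
    as exact zeros and excluded from inversion. If every singular value
    falls below the tolerance the pseudoinverse is the zero matrix (with a
    warning) — every Mahalanobis distance then degenerates to zero.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
        raise ValueError("gamma must be square")
    if not np.allclose(gamma, gamma.T, atol=1e-8):
        raise ValueError("gamma must be symmetric")
    u, s, vt = np.linalg.svd(gamma, hermitian=True)
    cutoff = rank_tolerance * (s[0] if s.size else 0.0)
    keep = s > cutoff
    if not keep.any():
        warnings.warn(
            "covariance matrix is numerically zero; pseudoinverse set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        pinv = np.zeros_like(gamma)
    else:
        inv_s = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
        pinv = (vt.T * inv_s) @ u.T
        pinv = (pinv + pinv.T) / 2  # enforce exact symmetry
    return CovarianceModel(
        gamma=gamma,
        gamma_pinv=pinv,
        singular_values=s,
        rank_tolerance=rank_tolerance,
        n_core_used=n_core_used,
    )


def pooled_covariance(
    clr: ClrMatrix, model: ClusterModel, rank_tolerance: float = 1e-10
) -> CovarianceModel:
    """Estimate Gamma from core-cell deviations around their cluster medoid.

    Negative clusters contribute nothing (all their droplets are non-core).
    Requires at least N+1 core cells overall.
    """
    n = clr.n_hashtags
    core = np.flatnonzero(model.core_flag)
    if core.size < n + 1:
        raise InsufficientDataError(
            f"covariance needs at least {n + 1} core cells, have {core.size}"
        )
    dev = clr.values[core] - model.centroids[model.assignment[core] - 1]
    gamma = dev.T @ dev / core.size
    logger.info("pooled covariance from %d core cells", core.size)
    return pseudo_inverse(gamma, rank_tolerance=rank_tolerance, n_core_used=core.size)


def mahalanobis_distances(
    clr: ClrMatrix, model: ClusterModel, cov: CovarianceModel
) -> DistanceMatrix:
    """Squared Mahalanobis distance of every droplet to every cluster medoid."""
    if cov.gamma_pinv.shape != (clr.n_hashtags, clr.n_hashtags):
        raise ValueError("covariance dimension does not match CLR matrix")
    if model.centroids.shape[1] != clr.n_hashtags:
        raise ValueError("centroid dimension does not match CLR matrix")
    dev = clr.values[:, None, :] - model.centroids[None, :, :]  # (C, k, N)
    md = np.einsum("ckn,nm,ckm->ck", dev, cov.gamma_pinv, dev, optimize=True)
    # the quadratic form of a PSD pseudoinverse; clamp rounding noise
    np.maximum(md, 0.0, out=md)
    return DistanceMatrix(md=md)
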