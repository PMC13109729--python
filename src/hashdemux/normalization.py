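"""Centred log-ratio (CLR) normalization of hashtag counts.

HTO counts are compositional within a droplet: what matters for identifying
the droplet's sample of origin is which hashtag dominates relative to the
others, not the absolute depth. The *local* (within-cell) CLR transform

    pi_{i,c} = (HTO_{i,c} + 1) / (HTO_{+,c} + N)
    h_{i,c}  = log( pi_{i,c} / GM(pi_{.,c}) )

first library-size-normalizes the counts of droplet c with a pseudo-count,
then centres the log values on the droplet's geometric mean. Every droplet's
CLR profile therefore sums to exactly zero, which makes the pooled CLR
covariance singular — the reason the classifier downstream uses a
Moore-Penrose pseudoinverse.

A *global* (across-cell, per-hashtag) CLR is provided for comparison with
threshold-based demultiplexers; the classifier never uses it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import HashingDataset

__all__ = ["ClrMatrix", "local_clr", "global_clr"]


@dataclass
class ClrMatrix:
    """Local-CLR-normalized values, droplets x hashtags, sum-zero per droplet."""

    values: np.ndarray
    pseudo_count: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CLR values must be finite")

    @property
    def n_droplets(self) -> int:
        return self.values.shape[0]

    @property
    def n_hashtags(self) -> int:
        return self.values.shape[1]


def local_clr(data: HashingDataset, pseudo_count: float = 1.0) -> ClrMatrix:
    """Within-cell CLR of the HTO counts (natural log, pseudo-count 1).

    The pseudo-count enters exactly as in the proportion above: +pseudo per
    entry in the numerator, +N*pseudo in the denominator. Each row of the
    result sums to zero up to rounding.
    """
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    counts = data.hto_counts
    n = data.n_hashtags
    if n < 2:
        raise ValueError("local CLR is undefined for fewer than 2 hashtags")
    lib = counts.sum(axis=1, keepdims=True)
    log_pi = np.log(counts + pseudo_count) - np.log(lib + n * pseudo_count)
    h = log_pi - log_pi.mean(axis=1, keepdims=True)
    return ClrMatrix(values=h, pseudo_count=pseudo_count)


def global_clr(data: HashingDataset, pseudo_count: float = 1.0) -> np.ndarray:
    """Across-cell CLR: each hashtag column centred on its own geometric mean.

    ``h'_{i,c} = log((HTO_{i,c}+pseudo) / GM_c(HTO_{i,.}+pseudo))``. Column
    sums are zero; rows are not. Comparison utility only — the demultiplexer
    works exclusively in local CLR space.
    """
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    logx = np.log(data.hto_counts + pseudo_count)
    return logx - logx.mean(axis=0, keepdims=True)
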