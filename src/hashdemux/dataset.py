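"""The central dataset container for hashing experiments.

A :class:`HashingDataset` holds the raw hashtag-oligo (HTO) count matrix for
one multiplexed single-cell capture: C droplets (rows) by N hashtags
(columns), together with droplet barcodes, hashtag names, and optionally the
per-droplet mRNA library size from a paired gene-expression matrix.

Orientation contract: droplets are ALWAYS rows internally. File readers that
consume the 10x-style features-by-barcodes layout transpose on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

__all__ = ["HashingDataset"]


@dataclass
class HashingDataset:
    """Raw HTO counts per droplet plus identifiers.

    Parameters
    ----------
    hto_counts
        Non-negative integer matrix, shape ``(C, N)`` = droplets x hashtags.
    hashtag_names
        N unique hashtag identifiers.
    barcodes
        C unique droplet barcodes, in input order (order is preserved by the
        whole pipeline; nothing ever sorts droplets).
    mrna_library_size
        Optional length-C vector of total gene-expression counts per droplet
        (``L_c``), used only by the mRNA reclassification step.
    """

    hto_counts: np.ndarray
    hashtag_names: list[str]
    barcodes: list[str]
    mrna_library_size: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        counts = np.asarray(self.hto_counts)
        if counts.ndim != 2:
            raise FormatError("hto_counts must be a 2-D matrix (droplets x hashtags)")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("HTO counts must be integers")
            counts = np.round(counts).astype(np.int64)
        if counts.min(initial=0) < 0:
            raise ValueError("HTO counts must be non-negative")
        self.hto_counts = counts.astype(np.int64, copy=False)

        self.hashtag_names = [str(h) for h in self.hashtag_names]
        self.barcodes = [str(b) for b in self.barcodes]
        c, n = self.hto_counts.shape
        if n < 2:
            raise FormatError(f"need at least 2 hashtags, got {n}")
        if c < n:
            raise FormatError(f"need at least as many droplets ({c}) as hashtags ({n})")
        if len(self.hashtag_names) != n:
            raise FormatError("hashtag_names length does not match matrix columns")
        if len(self.barcodes) != c:
            raise FormatError("barcodes length does not match matrix rows")
        if len(set(self.hashtag_names)) != n:
            raise FormatError("hashtag names must be unique")
        if len(set(self.barcodes)) != c:
            raise FormatError("barcodes must be unique")
        if self.mrna_library_size is not None:
            sizes = np.asarray(self.mrna_library_size, dtype=float)
            if sizes.shape != (c,):
                raise FormatError(
                    f"mrna_library_size has length {sizes.size}, expected {c}"
                )
            if np.any(sizes < 0) or not np.all(np.isfinite(sizes)):
                raise ValueError("mRNA library sizes must be finite and >= 0")
            self.mrna_library_size = sizes

    @property
    def n_droplets(self) -> int:
        return self.hto_counts.shape[0]

    @property
    def n_hashtags(self) -> int:
        return self.hto_counts.shape[1]

    @property
    def hto_library_size(self) -> np.ndarray:
        """Total HTO count per droplet, ``HTO_{+,c} = sum_i HTO_{i,c}``."""
        return self.hto_counts.sum(axis=1)
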