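"""Synthetic hashing-data generator with ground-truth labels.

Emulates the recurring quality regimes of real cell-hashing experiments so
every pipeline stage can be validated against known droplet identities:

* ``standard`` — clean bimodal hashtags: high counts on the true label,
  low background elsewhere;
* ``weak_signal`` — one hashtag binds poorly, its signal mean shrunk
  toward the background (left-shifted distribution);
* ``strong_signal`` — one over-labelled hashtag with inflated signal AND
  background (right-shifted distribution that bleeds into other hashtags);
* ``contaminated`` — a fraction of droplets show moderate counts on every
  hashtag (ambient contamination);
* ``empty_cluster`` — a fraction of droplets are empty, with only faint
  background counts, forming a distinct low-library-size cluster;
* ``low_input`` — all means scaled down (shallow sequencing / low input).

Counts are negative binomial (mean m, size r, variance m + m^2/r), the
standard dispersion model for UMI data. A doublet's profile is the sum of
two independent singlet profiles, so doublets carry roughly twice the
hashtag material of singlets — the property the library-size antimode
split relies on. mRNA library sizes are log-normal for singlets, a sum of
two draws for doublets and a scaled-down draw for negatives, giving the
Negative < Singlet < Doublet median ordering the mRNA reclassification
step exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import HashingDataset

__all__ = ["SimConfig", "SimTruth", "simulate", "archetype_suite", "ARCHETYPES"]

ARCHETYPES = (
    "standard",
    "weak_signal",
    "strong_signal",
    "contaminated",
    "empty_cluster",
    "low_input",
)


@dataclass
class SimConfig:
    """Generator settings; defaults describe a typical clean experiment."""

    n_cells: int = 3000
    n_hashtags: int = 4
    background_mean: float = 10.0
    signal_mean: float = 300.0
    dispersion: float = 5.0
    doublet_rate: float = 0.08
    negative_rate: float = 0.05
    archetype: str = "standard"
    # archetype knobs
    weak_factor: float = 0.1
    strong_factor: float = 10.0
    contamination_fraction: float = 0.2
    empty_fraction: float = 0.15
    empty_scale: float = 0.2
    low_input_factor: float = 0.1
    # mRNA library-size model
    mrna_meanlog: float = 8.0
    mrna_sdlog: float = 0.4
    mrna_negative_scale: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.n_hashtags < 2:
            raise ValueError("need at least 2 hashtags")
        if not (0 <= self.doublet_rate < 1 and 0 <= self.negative_rate < 1):
            raise ValueError("rates must be in [0, 1)")
        if self.doublet_rate + self.negative_rate >= 1:
            raise ValueError("doublet_rate + negative_rate must be < 1")
        for name in ("background_mean", "signal_mean", "dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimTruth:
    """Ground-truth labels for a simulated dataset.

    ``category`` matches the result convention: hashtag name for singlets,
    ``"Doublet"`` / ``"Negative"`` otherwise. Doublet donor pairs are stored
    in hashtag input order. Flags record which droplets were overwritten by
    the contamination / empty-droplet mechanisms.
    """

    category: np.ndarray
    doublet_first: np.ndarray
    doublet_second: np.ndarray
    is_contaminated: np.ndarray
    is_empty: np.ndarray


def _nb(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate(config: SimConfig) -> tuple[HashingDataset, SimTruth]:
    """Draw one dataset + ground truth; deterministic for a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    c, n = cfg.n_cells, cfg.n_hashtags

    background = np.full(n, cfg.background_mean)
    signal = np.full(n, cfg.signal_mean)
    if cfg.archetype == "weak_signal":
        signal = signal.copy()
        signal[0] *= cfg.weak_factor
    elif cfg.archetype == "strong_signal":
        signal = signal.copy()
        background = background.copy()
        signal[0] *= cfg.strong_factor
        background[0] *= cfg.strong_factor
    elif cfg.archetype == "low_input":
        signal = signal * cfg.low_input_factor
        background = background * cfg.low_input_factor

    p_singlet = 1.0 - cfg.doublet_rate - cfg.negative_rate
    kind = rng.choice(3, size=c, p=[p_singlet, cfg.doublet_rate, cfg.negative_rate])
    hashtags = np.array([f"HTO{i + 1}" for i in range(n)], dtype=object)

    # per-droplet mean matrix for the first (or only) cell in the droplet
    donor1 = rng.integers(0, n, size=c)
    means = np.tile(background, (c, 1))
    singlet_or_dbl = kind != 2
    means[singlet_or_dbl, donor1[singlet_or_dbl]] = signal[donor1[singlet_or_dbl]]
    counts = _nb(rng, means, cfg.dispersion)

    # doublets: add a second, independent singlet profile of another donor
    dbl = np.flatnonzero(kind == 1)
    donor2 = np.full(c, -1)
    if dbl.size:
        shift = rng.integers(1, n, size=dbl.size)
        donor2[dbl] = (donor1[dbl] + shift) % n
        means2 = np.tile(background, (dbl.size, 1))
        means2[np.arange(dbl.size), donor2[dbl]] = signal[donor2[dbl]]
        counts[dbl] += _nb(rng, means2, cfg.dispersion)

    category = np.empty(c, dtype=object)
    category[kind == 0] = hashtags[donor1[kind == 0]]
    category[kind == 1] = "Doublet"
    category[kind == 2] = "Negative"
    pair_lo = np.minimum(donor1, donor2)
    pair_hi = np.maximum(donor1, donor2)
    doublet_first = np.where(kind == 1, hashtags[pair_lo], "").astype(object)
    doublet_second = np.where(kind == 1, hashtags[pair_hi], "").astype(object)

    is_contaminated = np.zeros(c, dtype=bool)
    if cfg.archetype == "contaminated" and cfg.contamination_fraction > 0:
        n_cont = int(round(cfg.contamination_fraction * c))
        idx = rng.choice(c, size=n_cont, replace=False)
        inter = np.sqrt(cfg.background_mean * cfg.signal_mean)
        counts[idx] = _nb(rng, np.full((n_cont, n), inter), cfg.dispersion)
        is_contaminated[idx] = True

    is_empty = np.zeros(c, dtype=bool)
    if cfg.archetype == "empty_cluster" and cfg.empty_fraction > 0:
        n_empty = int(round(cfg.empty_fraction * c))
        idx = rng.choice(c, size=n_empty, replace=False)
        counts[idx] = _nb(
            rng,
            np.tile(background * cfg.empty_scale, (n_empty, 1)),
            cfg.dispersion,
        )
        is_empty[idx] = True
        category[idx] = "Negative"
        doublet_first[idx] = ""
        doublet_second[idx] = ""

    # mRNA library sizes keyed to the *final* truth category
    base = rng.lognormal(cfg.mrna_meanlog, cfg.mrna_sdlog, size=c)
    extra = rng.lognormal(cfg.mrna_meanlog, cfg.mrna_sdlog, size=c)
    mrna = base.copy()
    dbl_mask = category == "Doublet"
    neg_mask = category == "Negative"
    mrna[dbl_mask] += extra[dbl_mask]
    mrna[neg_mask] *= cfg.mrna_negative_scale

    data = HashingDataset(
        hto_counts=counts.astype(np.int64),
        hashtag_names=list(hashtags),
        barcodes=[f"BC{i:06d}" for i in range(c)],
        mrna_library_size=mrna,
    )
    truth = SimTruth(
        category=category,
        doublet_first=doublet_first,
        doublet_second=doublet_second,
        is_contaminated=is_contaminated,
        is_empty=is_empty,
    )
    return data, truth


def archetype_suite(
    seed: int = 0, n_cells: int = 3000, n_hashtags: int = 4
) -> list[tuple[SimConfig, HashingDataset, SimTruth]]:
    """One simulated instance per archetype at canonical test sizes."""
    out = []
    for offset, archetype in enumerate(ARCHETYPES):
        cfg = SimConfig(
            n_cells=n_cells,
            n_hashtags=n_hashtags,
            archetype=archetype,
            seed=seed + offset,
        )
        data, truth = simulate(cfg)
        out.append((cfg, data, truth))
    return out


def truth_frame(truth: SimTruth, barcodes: list[str]):
    """Ground truth as a DataFrame (for the simulate CLI's truth CSV)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "barcode": barcodes,
            "category": truth.category,
            "doublet_first": truth.doublet_first,
            "doublet_second": truth.doublet_second,
            "is_contaminated": truth.is_contaminated,
            "is_empty": truth.is_empty,
        }
    )
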