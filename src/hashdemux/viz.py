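"""Diagnostic tables and plots for inspecting demultiplexing calls.

The droplet-check table gathers, per droplet, the quantities that separate
singlets, doublets and negatives into distinct regions: log HTO library
size, log mRNA library size (when available), the second-smallest
Mahalanobis distance and the first-to-second distance ratio. Suspicious
barcodes can be highlighted to see where they fall. Every rendered figure
has a machine-readable CSV twin so downstream checks never parse images;
plotting problems are logged and never abort a run.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import DemuxResult
from .clustering import ClusterModel
from .dataset import HashingDataset
from .normalization import ClrMatrix

__all__ = ["build_check_table", "render_plots", "cluster_boxplot_table"]

logger = logging.getLogger(__name__)

CATEGORY_COLOURS = {"Negative": "#7f7f7f", "Doublet": "#d62728"}
_SINGLET_CYCLE = ("#1f77b4", "#2ca02c", "#9467bd", "#ff7f0e",
                  "#17becf", "#8c564b", "#e377c2", "#bcbd22")


def build_check_table(
    result: DemuxResult,
    data: HashingDataset,
    highlight_barcodes: list[str] | tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-droplet diagnostic table; unknown highlight barcodes warn."""
    table = pd.DataFrame(
        {
            "barcode": result.barcodes,
            "log_hto_library_size": np.log(data.hto_library_size + 1.0),
            "second_md": result.second_md,
            "md_ratio": result.md_ratio,
            "category": result.category,
        }
    )
    if data.mrna_library_size is not None:
        table.insert(
            2,
            "log_mrna_library_size",
            np.log(np.asarray(data.mrna_library_size, dtype=float) + 1.0),
        )
    wanted = set(highlight_barcodes)
    unknown = wanted - set(result.barcodes)
    if unknown:
        warnings.warn(
            f"{len(unknown)} highlight barcodes not in the dataset "
            f"(e.g. {sorted(unknown)[:3]})", RuntimeWarning, stacklevel=2,
        )
    table["highlight"] = table["barcode"].isin(wanted)
    return table


def _colours(categories: pd.Series) -> list[str]:
    singlets = sorted(set(categories) - set(CATEGORY_COLOURS))
    lut = dict(CATEGORY_COLOURS)
    for i, s in enumerate(singlets):
        lut[s] = _SINGLET_CYCLE[i % len(_SINGLET_CYCLE)]
    return [lut[c] for c in categories]


def cluster_boxplot_table(model: ClusterModel, clr: ClrMatrix,
                          hashtag_names: list[str]) -> pd.DataFrame:
    """Median (and quartile) CLR of each hashtag within each cluster — the
    numeric backing of the per-cluster boxplot used for select-k inspection."""
    rows = []
    for l in range(1, model.k + 1):
        vals = clr.values[model.members(l)]
        for i, h in enumerate(hashtag_names):
            q1, med, q3 = np.percentile(vals[:, i], [25, 50, 75])
            rows.append(
                {"cluster": l, "hashtag": h, "q1": q1, "median": med, "q3": q3}
            )
    return pd.DataFrame(rows)


def render_plots(
    table: pd.DataFrame,
    out_dir: str | Path,
    mode: str = "both",
    model: ClusterModel | None = None,
    clr: ClrMatrix | None = None,
    hashtag_names: list[str] | None = None,
    min_md: np.ndarray | None = None,
    cutoff: float | None = None,
) -> list[Path]:
    """Write droplet-check figures (and CSV twins) into ``out_dir``.

    ``mode="2d"`` draws pairwise scatter panels of the check-table axes;
    ``"3d"`` a static 3-axis scatter (log HTO size, log mRNA size, MD
    ratio — second MD replaces the mRNA axis when absent); ``"both"`` draws
    both. Given ``min_md``/``cutoff``, the minimum-distance histogram with
    its cutoff line is added; given ``model``/``clr``, the per-cluster
    hashtag-CLR boxplot. Returns the files written.
    """
    if mode not in ("2d", "3d", "both"):
        raise ValueError(f"unknown plot mode {mode!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = out / "check_table.csv"
    table.to_csv(csv_path, index=False)
    written.append(csv_path)

    has_mrna = "log_mrna_library_size" in table.columns
    axes_cols = ["log_hto_library_size"]
    if has_mrna:
        axes_cols.append("log_mrna_library_size")
    else:
        logger.info("no mRNA library sizes; mRNA axes omitted from plots")
    axes_cols += ["second_md", "md_ratio"]
    colours = _colours(table["category"])

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if mode in ("2d", "both"):
            pairs = [
                (a, b)
                for i, a in enumerate(axes_cols)
                for b in axes_cols[i + 1 :]
            ]
            ncol = 3
            nrow = -(-len(pairs) // ncol)
            fig, axs = plt.subplots(
                nrow, ncol, figsize=(4 * ncol, 3.2 * nrow), squeeze=False
            )
            for ax, (a, b) in zip(axs.ravel(), pairs):
                ax.scatter(table[a], table[b], c=colours, s=6, alpha=0.6, lw=0)
                hl = table[table["highlight"]]
                if len(hl):
                    ax.scatter(hl[a], hl[b], facecolors="none",
                               edgecolors="black", s=40)
                ax.set_xlabel(a)
                ax.set_ylabel(b)
            for ax in axs.ravel()[len(pairs):]:
                ax.axis("off")
            fig.tight_layout()
            p = out / "check_2d.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)

        if mode in ("3d", "both"):
            zcol = "log_mrna_library_size" if has_mrna else "second_md"
            fig = plt.figure(figsize=(6, 5))
            ax = fig.add_subplot(projection="3d")
            ax.scatter(
                table["log_hto_library_size"], table[zcol], table["md_ratio"],
                c=colours, s=6, alpha=0.6, lw=0,
            )
            hl = table[table["highlight"]]
            if len(hl):
                ax.scatter(hl["log_hto_library_size"], hl[zcol], hl["md_ratio"],
                           facecolors="none", edgecolors="black", s=40)
            ax.set_xlabel("log HTO library size")
            ax.set_ylabel(zcol)
            ax.set_zlabel("MD ratio")
            p = out / "check_3d.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)

        if min_md is not None:
            hist_df = pd.DataFrame({"min_md": np.asarray(min_md, dtype=float)})
            hp = out / "min_md_histogram.csv"
            hist_df.to_csv(hp, index=False)
            written.append(hp)
            fig, ax = plt.subplots(figsize=(5, 3.5))
            ax.hist(hist_df["min_md"], bins=60, color="#1f77b4")
            if cutoff is not None:
                ax.axvline(cutoff, color="red", ls="--", label=f"cutoff {cutoff:.3g}")
                ax.legend()
            ax.set_xlabel("minimum Mahalanobis distance")
            ax.set_ylabel("droplets")
            fig.tight_layout()
            p = out / "min_md_histogram.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)

        if model is not None and clr is not None and hashtag_names is not None:
            box = cluster_boxplot_table(model, clr, hashtag_names)
            bp = out / "cluster_clr_boxplot.csv"
            box.to_csv(bp, index=False)
            written.append(bp)
            fig, axs = plt.subplots(
                1, model.k, figsize=(3 * model.k, 3.2), squeeze=False
            )
            for l, ax in zip(range(1, model.k + 1), axs.ravel()):
                vals = clr.values[model.members(l)]
                ax.boxplot([vals[:, i] for i in range(len(hashtag_names))],
                           tick_labels=hashtag_names)
                ax.set_title(f"cluster {l}")
                ax.tick_params(axis="x", rotation=45)
            fig.tight_layout()
            p = out / "cluster_clr_boxplot.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)
    except Exception:  # plots are advisory; the CSV twins are authoritative
        logger.exception("figure rendering failed; CSV outputs were still written")
    return written
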