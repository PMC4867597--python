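"""Figure helpers: metagene curves, occupancy profiles and MA plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .annotation import REGIONS

_REGION_LABEL = {"utr5": "5'-UTR", "cds": "CDS", "utr3": "3'-UTR"}


def plot_metagene(profile, path: str, title: str = "Metagene peak density") -> None:
    """Per-bin peak density across the 5'-UTR/CDS/3'-UTR axis."""
    n = profile.scheme.n_bins
    dens = profile.density
    fig, ax = plt.subplots(figsize=(8, 3))
    x0 = 0
    for r in REGIONS:
        x = np.arange(x0, x0 + n)
        ax.plot(x, dens[r], drawstyle="steps-mid", label=_REGION_LABEL[r])
        x0 += n
        if r != "utr3":
            ax.axvline(x0 - 0.5, color="grey", lw=0.8)
    ax.set_xlabel("region bin")
    ax.set_ylabel("features per kb")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_occupancy(curves: list, path: str, title: str = "Relative ribosome density") -> None:
    """Overlay relative occupancy curves (one line per condition/gene class)."""
    fig, ax = plt.subplots(figsize=(8, 3))
    for c in curves:
        y = c.concatenated()
        label = c.condition + (f" ({c.gene_class})" if c.gene_class != "all" else "")
        ax.plot(np.arange(len(y)), y, drawstyle="steps-mid", label=label)
    n = curves[0].scheme.n_bins
    for k in (1, 2):
        ax.axvline(k * n - 0.5, color="grey", lw=0.8)
    ax.set_xlabel("bin (5'-UTR | CDS | 3'-UTR)")
    ax.set_ylabel("relative density")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ma(ma_df, targets: set[str], path: str, title: str = "MA plot") -> None:
    """Log-ratio versus abundance with target genes highlighted."""
    is_t = ma_df.gene_id.isin(targets)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ma_df.A[~is_t], ma_df.M[~is_t], s=5, c="grey", alpha=0.5, label="non-target")
    ax.scatter(ma_df.A[is_t], ma_df.M[is_t], s=8, c="crimson", label="target")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("A = mean log2 abundance")
    ax.set_ylabel("M = log2 fold change")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
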