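"""Figure helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def density_plot(summary: pd.DataFrame, out_path: str,
                 cgi_cut: float = 0.24, backbone_cut: float = 0.78) -> None:
    """2-D density of avg_backbone (x) vs avg_cgi (y) with class cutoffs.

    Mirrors the classic joint view of genome-wide average methylation:
    normals cluster near (0.80, 0.21); tumors spread toward the
    hypermethylated-CGI (up) and demethylated-backbone (left) quadrants.
    """
    df = summary.dropna(subset=["avg_cgi", "avg_backbone"])
    fig, ax = plt.subplots(figsize=(5, 5))
    hb = ax.hexbin(df["avg_backbone"], df["avg_cgi"], gridsize=40,
                   extent=(0, 1, 0, 1), cmap="viridis", mincnt=1)
    ax.axhline(cgi_cut, ls="--", lw=0.8, color="red")
    ax.axvline(backbone_cut, ls="--", lw=0.8, color="red")
    ax.set_xlabel("average backbone methylation")
    ax.set_ylabel("average CGI methylation")
    fig.colorbar(hb, ax=ax, label="samples")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
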