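"""Sliding-window methylation tracks and LAD inside/outside contrasts.

Windows of a fixed bin size tile each chromosome from position 0 at a fixed
step (defaults: 2 Mb bin, 1 Mb step, so consecutive windows half-overlap
and a probe typically contributes to two windows). The final partial window
is retained. Window membership is half-open. These tracks visualize the
megabase-scale demethylation blocks that coincide with partially methylated
domains, lamina-associated domains (LADs) and late-replicating regions.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .intervals import Genome, RegionSet

WINDOW_BIN = 2_000_000
WINDOW_STEP = 1_000_000


def sliding_window_means(
    values: pd.Series,
    manifest: pd.DataFrame,
    genome: Genome,
    bin_size: int = WINDOW_BIN,
    step: int = WINDOW_STEP,
) -> pd.DataFrame:
    """Mean of per-probe values within each sliding window.

    `values` is indexed by probe_id (beta or delta-beta, per sample or
    cohort-aggregated); probes contribute to every window overlapping their
    position. Windows with no probes carry NaN. Returns a DataFrame with
    chrom, start, end, value, n_probes.
    """
    if bin_size <= 0 or step <= 0:
        raise ValueError("bin and step must be positive")
    info = manifest.set_index("probe_id").loc[values.index, ["chrom", "pos"]]
    rows = []
    for chrom, length in genome.items():
        n_windows = int(np.floor((length - 1) / step)) + 1 if length > 0 else 0
        sums = np.zeros(n_windows)
        counts = np.zeros(n_windows, dtype=np.int64)
        here = info["chrom"] == chrom
        pos = info.loc[here, "pos"].to_numpy()
        val = values[here].to_numpy(dtype=float)
        ok = ~np.isnan(val)
        pos, val = pos[ok], val[ok]
        # window k covers [k*step, k*step + bin); probe at pos is in windows
        # k with (pos - bin)/step < k <= pos/step
        k_max = np.minimum(pos // step, n_windows - 1).astype(np.int64)
        k_min = np.maximum((pos - bin_size) // step + 1, 0).astype(np.int64)
        for p, v, lo, hi in zip(pos, val, k_min, k_max):
            sums[lo:hi + 1] += v
            counts[lo:hi + 1] += 1
        starts = np.arange(n_windows) * step
        ends = np.minimum(starts + bin_size, length)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "value": means, "n_probes": counts,
        }))
    return pd.concat(rows, ignore_index=True)


def delta_vs_normal(
    betas, tumor_samples, normal_mean: pd.Series
) -> pd.Series:
    """Cohort-mean delta-beta (tumor − normal mean) per probe."""
    vals = betas.masked_values()[pd.Index(tumor_samples)]
    return vals.sub(normal_mean, axis=0).mean(axis=1, skipna=True)


def lad_contrast(
    delta: pd.Series,
    manifest: pd.DataFrame,
    lads: RegionSet,
    assignment: pd.DataFrame,
    classes: Tuple[str, ...] = ("backbone", "cgi"),
) -> pd.DataFrame:
    """Mean per-probe delta-beta inside vs outside LADs, per region class.

    `delta` is indexed by probe_id (delta-beta against the normal mean when
    normals exist, raw beta otherwise). Raises if no probe falls inside the
    LAD set. Outside means are NaN when LADs cover every probe.
    """
    info = manifest.set_index("probe_id").loc[delta.index, ["chrom", "pos"]]
    inside = np.zeros(len(info), dtype=bool)
    for chrom, grp in info.groupby("chrom", sort=False):
        hit = lads.contains(chrom, grp["pos"].to_numpy())
        inside[info.index.get_indexer(grp.index)] = hit
    if not inside.any():
        raise ValueError("no probes inside the LAD set")
    inside = pd.Series(inside, index=delta.index)
    rows = []
    for cls in classes:
        in_cls = assignment.reindex(delta.index)[cls].fillna(False).astype(bool)
        d_in = delta[in_cls & inside]
        d_out = delta[in_cls & ~inside]
        rows.append({
            "region_class": cls,
            "mean_inside": d_in.mean() if len(d_in) else np.nan,
            "mean_outside": d_out.mean() if len(d_out) else np.nan,
            "n_inside": int(len(d_in)),
            "n_outside": int(len(d_out)),
        })
    out = pd.DataFrame(rows).set_index("region_class")
    out["inside_minus_outside"] = out["mean_inside"] - out["mean_outside"]
    return out
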