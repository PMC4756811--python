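"""Per-sample compartment averages, HC/NC × LB/NB classification, and
array-vs-WGBS concordance.

Each sample is summarized by the arithmetic mean beta over its unmasked
CpG-island probes (avg_cgi) and over its unmasked backbone probes
(avg_backbone). Samples are then classified against fixed cutoffs derived
from the normal-tissue ranges: high CGI methylation (HC) when avg_cgi >
0.24 versus normal (NC, <= 0.24), and low backbone methylation (LB) when
avg_backbone < 0.78 versus normal (NB, >= 0.78) — boundaries belong to the
normal classes.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix
from .probe_qc import probes_in_class

CGI_CUT = 0.24
BACKBONE_CUT = 0.78
MIN_PROBES = 100


def average_region_methylation(
    betas: BetaMatrix,
    assignment: pd.DataFrame,
    region_class: str,
    min_probes: int = MIN_PROBES,
) -> Tuple[pd.Series, pd.Series]:
    """Mean unmasked beta over the probes of one region class, per sample.

    Averaging is pairwise-complete: cells masked in a sample contribute
    nothing to that sample's mean. Samples with fewer than `min_probes`
    usable probes get NaN (flagged as unreliable).

    Returns (means, n_used) indexed by sample.
    """
    ids = probes_in_class(assignment, region_class)
    sub = betas.subset_probes(ids)
    vals = sub.masked_values()
    n_used = vals.notna().sum(axis=0)
    means = vals.mean(axis=0, skipna=True)
    means[n_used < min_probes] = np.nan
    return means, n_used.astype(int)


def classify(
    avg_cgi: float, avg_backbone: float,
    cgi_cut: float = CGI_CUT, backbone_cut: float = BACKBONE_CUT,
) -> Tuple[Optional[str], Optional[str]]:
    """Classify one sample on both axes; NaN averages give None."""
    cgi_class = None if pd.isna(avg_cgi) else ("HC" if avg_cgi > cgi_cut else "NC")
    bb_class = None if pd.isna(avg_backbone) else (
        "LB" if avg_backbone < backbone_cut else "NB"
    )
    return cgi_class, bb_class


def summarize_samples(
    betas: BetaMatrix,
    assignment: pd.DataFrame,
    sample_info: Optional[pd.DataFrame] = None,
    cgi_cut: float = CGI_CUT,
    backbone_cut: float = BACKBONE_CUT,
    min_probes: int = MIN_PROBES,
    cgi_class_label: str = "cgi",
    backbone_class_label: str = "backbone",
) -> pd.DataFrame:
    """Build the per-sample summary table.

    sample_info may carry `tissue` ({tumor, normal}) and `tumor_type`
    columns indexed by sample id; absent info is reported as NA.
    """
    avg_cgi, n_cgi = average_region_methylation(
        betas, assignment, cgi_class_label, min_probes
    )
    avg_bb, n_bb = average_region_methylation(
        betas, assignment, backbone_class_label, min_probes
    )
    rows = []
    for sample in betas.samples:
        cgi_class, bb_class = classify(
            avg_cgi[sample], avg_bb[sample], cgi_cut, backbone_cut
        )
        rows.append({
            "sample_id": sample,
            "avg_cgi": avg_cgi[sample],
            "avg_backbone": avg_bb[sample],
            "n_cgi": n_cgi[sample],
            "n_backbone": n_bb[sample],
            "cgi_class": cgi_class,
            "backbone_class": bb_class,
        })
    summary = pd.DataFrame(rows).set_index("sample_id")
    if sample_info is not None:
        summary = summary.join(sample_info[["tissue", "tumor_type"]], how="left")
    else:
        summary["tissue"] = pd.NA
        summary["tumor_type"] = pd.NA
    cols = ["tissue", "tumor_type", "avg_cgi", "avg_backbone",
            "n_cgi", "n_backbone", "cgi_class", "backbone_class"]
    return summary[cols]


def calibrate_thresholds(normal_summary: pd.DataFrame) -> Tuple[float, float]:
    """Re-derive cutoffs from a normal cohort, as the original thresholds
    were derived from observed normal ranges: the CGI cutoff is the maximum
    normal avg_cgi and the backbone cutoff the minimum normal avg_backbone.
    """
    cgi = normal_summary["avg_cgi"].dropna()
    bb = normal_summary["avg_backbone"].dropna()
    if cgi.empty or bb.empty:
        raise ValueError("normal cohort has no usable averages")
    return float(cgi.max()), float(bb.min())


def concordance(
    array_summary: pd.DataFrame,
    other_summary: pd.DataFrame,
    pairs: Optional[Sequence[str]] = None,
) -> Dict[str, float]:
    """Pearson correlation between array and WGBS-derived per-sample averages.

    Cross-platform check: both summaries carry avg_cgi / avg_backbone columns
    indexed by sample. Reports the pooled correlation (both axes stacked, as
    in a joint cross-platform scatter) and per-axis correlations. Requires at
    least 3 complete pairs.
    """
    if pairs is None:
        pairs = array_summary.index.intersection(other_summary.index)
    pairs = pd.Index(pairs)
    a = array_summary.loc[pairs, ["avg_cgi", "avg_backbone"]]
    b = other_summary.loc[pairs, ["avg_cgi", "avg_backbone"]]
    complete = a.notna().all(axis=1) & b.notna().all(axis=1)
    a, b = a[complete], b[complete]
    if len(a) < 3:
        raise ValueError(f"need >= 3 paired samples, got {len(a)}")
    pooled_a = np.concatenate([a["avg_cgi"], a["avg_backbone"]])
    pooled_b = np.concatenate([b["avg_cgi"], b["avg_backbone"]])
    out = {
        "r_pooled": float(stats.pearsonr(pooled_a, pooled_b)[0]),
        "r_cgi": float(stats.pearsonr(a["avg_cgi"], b["avg_cgi"])[0]),
        "r_backbone": float(stats.pearsonr(a["avg_backbone"], b["avg_backbone"])[0]),
        "n_pairs": int(len(a)),
    }
    return out
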