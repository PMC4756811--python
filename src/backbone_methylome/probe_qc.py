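"""Probe masking and region assignment for methylation-array data.

Masking rules applied across all samples: probes with a common SNP within
10 bp of the interrogated CpG, probes whose 15 bp neighbourhood overlaps a
repeat element, and probes on sex chromosomes are dropped. Per-sample,
cells whose detection p-value exceeds 0.05 are masked (strictly greater:
p = 0.05 is kept). Retained probes are then assigned to every compartment
class whose intervals contain their CpG coordinate; probes inside no
functional class and no repeat fall in the backbone.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Mapping

import numpy as np
import pandas as pd

from .intervals import RegionSet
from .io import BetaMatrix

DEFAULT_SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})

SNP_WINDOW_BP = 10
REPEAT_WINDOW_BP = 15
DETECTION_P_CUT = 0.05


def apply_global_masks(
    manifest: pd.DataFrame,
    sex_chroms: Iterable[str] = DEFAULT_SEX_CHROMS,
    snp_window: int = SNP_WINDOW_BP,
) -> pd.DataFrame:
    """Return the manifest rows that survive the sample-independent filters.

    A probe is removed when its nearest common SNP is within `snp_window` bp
    (distance <= snp_window; a missing distance means no nearby SNP), when
    its repeat-overlap flag is set, or when it lies on a sex chromosome.
    """
    sex = set(sex_chroms)
    snp = manifest["snp_dist"].notna() & (manifest["snp_dist"] <= snp_window)
    rep = manifest["repeat_within_15bp"].astype(bool)
    sexchrom = manifest["chrom"].isin(sex)
    return manifest.loc[~(snp | rep | sexchrom)].copy()


def apply_detection_mask(
    betas: BetaMatrix, detection_p: pd.DataFrame, p_cut: float = DETECTION_P_CUT
) -> BetaMatrix:
    """Mask cells whose detection p-value is strictly greater than `p_cut`.

    Masking is monotone: already-masked cells stay masked.
    """
    if detection_p.shape != betas.values.shape:
        raise ValueError(
            f"detection_p shape {detection_p.shape} != beta shape {betas.values.shape}"
        )
    dp = detection_p.reindex(index=betas.probes, columns=betas.samples)
    if dp.isna().values.any():
        raise ValueError("detection_p index/columns do not match beta matrix")
    new_mask = betas.mask | (dp > p_cut)
    return BetaMatrix(betas.values, new_mask)


def assign_regions(
    manifest: pd.DataFrame, regions: Mapping[str, RegionSet]
) -> pd.DataFrame:
    """Assign each probe to the region classes containing its CpG coordinate.

    `regions` maps class label -> normalized RegionSet and should include a
    "backbone" entry built by the partition so that non-functional probes are
    labelled. Membership is half-open: pos in [start, end). Returns a
    DataFrame indexed by probe_id with one boolean column per class plus an
    "unannotated" column for probes matching no class (e.g. on a chromosome
    absent from every track).
    """
    labels = sorted(regions)
    out = pd.DataFrame(False, index=manifest["probe_id"].values, columns=labels)
    out.index.name = "probe_id"
    for chrom, grp in manifest.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        ids = grp["probe_id"].to_numpy()
        for label in labels:
            hit = regions[label].contains(chrom, pos)
            if hit.any():
                out.loc[ids[hit], label] = True
    out["unannotated"] = ~out[labels].any(axis=1)
    return out


def probes_in_class(assignment: pd.DataFrame, region_class: str) -> pd.Index:
    if region_class not in assignment.columns:
        raise KeyError(f"unknown region class {region_class!r}")
    return assignment.index[assignment[region_class]]


def class_counts(assignment: pd.DataFrame) -> pd.Series:
    """Number of retained probes per region class (reported for QC)."""
    return assignment.sum(axis=0).astype(int)


def assignment_to_frame(assignment: pd.DataFrame) -> pd.DataFrame:
    """Tidy long-format view: probe_id, region_class rows for TSV export."""
    stacked = assignment.stack()
    tidy = stacked[stacked].reset_index()
    tidy.columns = ["probe_id", "region_class", "_member"]
    return tidy[["probe_id", "region_class"]]


def assignment_from_frame(tidy: pd.DataFrame) -> pd.DataFrame:
    wide = pd.crosstab(tidy["probe_id"], tidy["region_class"]).astype(bool)
    wide.index.name = "probe_id"
    return wide
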