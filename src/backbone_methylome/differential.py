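"""Per-sample differential methylation calls and TF-binding-site enrichment.

A CpG is differentially methylated in a tumor sample when its beta deviates
from the mean of the normal tissues by more than 0.2 (strict), hyper- or
hypomethylated by sign. For each transcription factor, the enrichment rate
contrasts the differentially methylated fraction inside the factor's
binding sites with the fraction outside:

    rate = (dm_in / total_in) / (dm_out / total_out)

so rate = 1 means no enrichment, and a polycomb-like factor whose sites
attract tumor hypermethylation shows rate >> 1 for the hyper direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Set

import numpy as np
import pandas as pd

from .io import BetaMatrix

logger = logging.getLogger(__name__)

DM_THRESHOLD = 0.2
MIN_NORMALS = 2


@dataclass
class DifferentialCalls:
    sample_id: str
    hyper: Set[str]
    hypo: Set[str]
    universe: Set[str]  # probes unmasked in the sample and with a normal mean

    def __post_init__(self):
        assert not (self.hyper & self.hypo), "hyper/hypo sets must be disjoint"


@dataclass
class EnrichmentResult:
    tf: str
    direction: str  # {hyper, hypo}
    dm_in: int
    total_in: int
    dm_out: int
    total_out: int
    rate: Optional[float]


def normal_mean_per_probe(betas: BetaMatrix, normal_samples) -> pd.Series:
    """Mean unmasked beta per probe across the normal cohort.

    Probes usable in fewer than MIN_NORMALS normals get NaN and are excluded
    from the differential universe.
    """
    normals = pd.Index(normal_samples)
    missing = normals.difference(betas.samples)
    if len(missing):
        raise KeyError(f"normal samples absent from beta matrix: {list(missing)[:5]}")
    vals = betas.masked_values()[normals]
    n = vals.notna().sum(axis=1)
    mean = vals.mean(axis=1, skipna=True)
    mean[n < MIN_NORMALS] = np.nan
    return mean


def call_differential(
    betas: BetaMatrix,
    sample_id: str,
    normal_mean: pd.Series,
    threshold: float = DM_THRESHOLD,
) -> DifferentialCalls:
    """Call hyper/hypomethylated probes for one sample against the normal mean.

    Strict threshold: a change of exactly `threshold` is not called.
    """
    vals = betas.masked_values()[sample_id]
    nm = normal_mean.reindex(vals.index)
    usable = vals.notna() & nm.notna()
    delta = vals[usable] - nm[usable]
    hyper = set(delta.index[delta > threshold])
    hypo = set(delta.index[delta < -threshold])
    return DifferentialCalls(sample_id, hyper, hypo, set(delta.index))


def enrichment_rate(
    dm_in: int, total_in: int, dm_out: int, total_out: int
) -> Optional[float]:
    """The inside/outside differential-methylation fraction ratio.

    Undefined (None) when there are no outside calls — the ratio would be
    infinite — or when either universe side is empty.
    """
    if total_in <= 0 or total_out <= 0:
        raise ValueError("total_in and total_out must be positive")
    if dm_in < 0 or dm_in > total_in or dm_out < 0 or dm_out > total_out:
        raise ValueError("counts out of range")
    if dm_out == 0:
        return None
    return (dm_in / total_in) / (dm_out / total_out)


def tf_enrichment_profile(
    calls: DifferentialCalls,
    tf_membership: pd.DataFrame,
) -> List[EnrichmentResult]:
    """Enrichment rates for every TF, both directions, for one sample.

    `tf_membership` is a boolean DataFrame indexed by probe_id with one
    column per factor (probe CpG inside that factor's binding sites). The
    probe universe is the calls' universe (retained, annotated probes).
    Factors with zero member probes in the universe are skipped.
    """
    universe = pd.Index(sorted(calls.universe))
    member = tf_membership.reindex(universe).fillna(False).astype(bool)
    results: List[EnrichmentResult] = []
    for direction, dm_set in (("hyper", calls.hyper), ("hypo", calls.hypo)):
        dm = universe.isin(dm_set)
        for tf in member.columns:
            inside = member[tf].to_numpy()
            total_in = int(inside.sum())
            total_out = int((~inside).sum())
            if total_in == 0 or total_out == 0:
                logger.info("skipping TF %s (%s): empty side of the universe",
                            tf, direction)
                continue
            dm_in = int((dm & inside).sum())
            dm_out = int((dm & ~inside).sum())
            results.append(EnrichmentResult(
                tf, direction, dm_in, total_in, dm_out, total_out,
                enrichment_rate(dm_in, total_in, dm_out, total_out),
            ))
    return results


def tf_membership_from_sets(
    manifest: pd.DataFrame, tf_sets: Mapping[str, "object"]
) -> pd.DataFrame:
    """Probe × factor membership matrix from per-factor RegionSets."""
    out = pd.DataFrame(
        False, index=manifest["probe_id"].values, columns=sorted(tf_sets)
    )
    out.index.name = "probe_id"
    for chrom, grp in manifest.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        ids = grp["probe_id"].to_numpy()
        for tf, rs in tf_sets.items():
            hit = rs.contains(chrom, pos)
            if hit.any():
                out.loc[ids[hit], tf] = True
    return out


def enrichment_to_frame(results: List[EnrichmentResult], sample_id: str) -> pd.DataFrame:
    rows = [{
        "sample_id": sample_id, "tf": r.tf, "direction": r.direction,
        "dm_in": r.dm_in, "total_in": r.total_in,
        "dm_out": r.dm_out, "total_out": r.total_out,
        "rate": np.nan if r.rate is None else r.rate,
    } for r in results]
    return pd.DataFrame(rows)
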