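"""End-to-end orchestration: simulate -> partition -> QC -> summarize ->
differential/enrichment -> windows/LAD contrast -> associations.

Every stage is a pure function of (inputs, config, seed); a run directory
receives the stage outputs plus a JSON manifest recording the config hash,
seed and per-stage row counts, so identical configs reproduce identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import associations as assoc
from . import differential as diff
from . import metrics, probe_qc, windows
from .io import (BetaMatrix, write_bed, write_bedgraph, write_genome,
                 write_manifest, write_matrix, write_named_bed)
from .simulate import CohortSpec, generate_annotations, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Numeric thresholds of the whole pipeline (defaults = published values)."""

    out_dir: str = "run"
    seed: int = 1
    cgi_cut: float = 0.24
    backbone_cut: float = 0.78
    dm_threshold: float = 0.2
    detection_p_cut: float = 0.05
    snp_window: int = 10
    repeat_window: int = 15
    shore_flank: int = 2000
    promoter_length: int = 1500
    body_fraction: float = 0.1
    window_bin: int = 2_000_000
    window_step: int = 1_000_000
    min_probes: int = 100
    min_normals_for_differential: int = 10

    def __post_init__(self):
        for name in ("dm_threshold", "detection_p_cut", "snp_window",
                     "repeat_window", "shore_flank", "promoter_length",
                     "body_fraction", "window_bin", "window_step",
                     "cgi_cut", "backbone_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig,
                 spec: Optional[CohortSpec] = None) -> Dict[str, object]:
    """Run the full analysis on a simulated cohort; return the run manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: Dict[str, object] = {
        "config": asdict(config), "config_hash": config.digest(),
        "seed": config.seed, "stages": {},
    }

    def record(stage: str, **info):
        manifest["stages"][stage] = info
        logger.info("stage %s: %s", stage, info)

    spec = spec if spec is not None else CohortSpec(seed=config.seed)
    ann = generate_annotations(spec)
    cohort = generate_cohort(spec, ann)
    record("simulate", n_probes=len(ann.manifest),
           n_samples=len(cohort.betas.samples))

    # stage: regions + QC
    retained = probe_qc.apply_global_masks(ann.manifest,
                                           snp_window=config.snp_window)
    betas = cohort.betas.subset_probes(retained["probe_id"])
    dp = cohort.detection_p.loc[betas.probes]
    betas = probe_qc.apply_detection_mask(betas, dp, config.detection_p_cut)
    region_classes = {k: v for k, v in ann.region_sets.items() if k != "lad"}
    assignment = probe_qc.assign_regions(retained, region_classes)
    record("qc", n_retained=len(retained),
           counts=probe_qc.class_counts(assignment).to_dict())

    # stage: summaries + classification
    summary = metrics.summarize_samples(
        betas, assignment, cohort.clinical, config.cgi_cut,
        config.backbone_cut, config.min_probes)
    summary_path = os.path.join(config.out_dir, "summary.tsv")
    summary.to_csv(summary_path, sep="\t", float_format="%.6g")
    record("summarize", n_samples=len(summary), path=summary_path)

    normals = summary.index[summary["tissue"] == "normal"]
    tumors = summary.index[summary["tissue"] == "tumor"]

    # stage: differential calls + TF enrichment (needs enough normals)
    enrich_path = None
    if len(normals) >= config.min_normals_for_differential:
        nm = diff.normal_mean_per_probe(betas, normals)
        tf_member = diff.tf_membership_from_sets(retained, ann.tf_sets)
        frames = []
        for sid in tumors:
            calls = diff.call_differential(betas, sid, nm, config.dm_threshold)
            frames.append(diff.enrichment_to_frame(
                diff.tf_enrichment_profile(calls, tf_member), sid))
        enrich = pd.concat(frames, ignore_index=True)
        enrich_path = os.path.join(config.out_dir, "tf_enrichment.tsv")
        enrich.to_csv(enrich_path, sep="\t", index=False, float_format="%.6g")
        record("enrichment", n_rows=len(enrich), path=enrich_path)
    else:
        record("enrichment", skipped="insufficient normals")

    # stage: windows + LAD contrast on cohort-mean delta-beta
    nm = diff.normal_mean_per_probe(betas, normals)
    delta = windows.delta_vs_normal(betas, tumors, nm)
    track = windows.sliding_window_means(delta, retained, ann.genome,
                                         config.window_bin, config.window_step)
    track_path = os.path.join(config.out_dir, "delta_windows.bedgraph")
    write_bedgraph(track, track_path)
    contrast = windows.lad_contrast(delta, retained, ann.region_sets["lad"],
                                    assignment)
    contrast_path = os.path.join(config.out_dir, "lad_contrast.tsv")
    contrast.to_csv(contrast_path, sep="\t", float_format="%.6g")
    record("windows", n_windows=len(track), track=track_path,
           lad_contrast=contrast_path)

    # stage: association battery on tumors
    results = []
    tsum = summary.loc[tumors]
    for axis in ("avg_cgi", "avg_backbone"):
        y = tsum[axis]
        for var in ("stage", "grade", "msi", "smoking"):
            r = assoc.adjusted_clinical_association(y, cohort.clinical, var)
            r.variable = f"{axis}:{var}"
            results.append(r)
        for gene in cohort.mutations.columns:
            r = assoc.molecular_association(y, cohort.mutations[gene].loc[tumors],
                                            "binary", f"{axis}:mut_{gene}")
            results.append(r)
    assoc.attach_q(results)
    assoc_path = os.path.join(config.out_dir, "associations.tsv")
    assoc.results_to_frame(results).to_csv(assoc_path, sep="\t", index=False,
                                           float_format="%.6g")
    record("associations", n_tests=len(results), path=assoc_path)

    # stage: per-tumor-type SCNA scan + cross-type percentiles
    scans = {}
    for ttype, grp in tsum.groupby("tumor_type"):
        scan = assoc.scna_scan(grp["avg_backbone"],
                               cohort.scna.loc[grp.index], cohort.scna_coords)
        scans[ttype] = scan
    if len(scans) >= 2:
        pct = assoc.cross_tumor_percentiles(scans)
        pct_path = os.path.join(config.out_dir, "scna_percentiles.tsv")
        pct.to_csv(pct_path, sep="\t", index=False, float_format="%.6g")
        record("scna", n_types=len(scans), path=pct_path)

    manifest_path = os.path.join(config.out_dir, "run_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["manifest_path"] = manifest_path
    manifest["summary"] = summary
    return manifest


def export_simulation(spec: CohortSpec, out_dir: str) -> None:
    """Write a simulated data set in the file formats the CLI stages read."""
    os.makedirs(out_dir, exist_ok=True)
    ann = generate_annotations(spec)
    cohort = generate_cohort(spec, ann)
    write_genome(ann.genome, os.path.join(out_dir, "genome.txt"))
    for name, rs in ann.region_sets.items():
        write_bed(rs, os.path.join(out_dir, f"{name}.bed"))
    write_named_bed(ann.tf_sets, os.path.join(out_dir, "tf_sites.bed"))
    write_manifest(ann.manifest, os.path.join(out_dir, "manifest.tsv"))
    cohort.betas.to_files(os.path.join(out_dir, "betas.tsv"))
    write_matrix(cohort.detection_p, os.path.join(out_dir, "detection_p.tsv"))
    cohort.clinical.to_csv(os.path.join(out_dir, "clinical.tsv"), sep="\t")
    cohort.mutations.to_csv(os.path.join(out_dir, "mutations.tsv"), sep="\t")
    cohort.scna.to_csv(os.path.join(out_dir, "scna.tsv"), sep="\t")
    cohort.scna_coords.to_csv(os.path.join(out_dir, "scna_genes.tsv"),
                              sep="\t", index=False)
    cohort.wgbs.to_csv(os.path.join(out_dir, "wgbs.tsv"), sep="\t")
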