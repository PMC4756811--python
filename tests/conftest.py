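import numpy as np
import pandas as pd
import pytest

from backbone_methylome import (
    CohortSpec, TumorBlock, apply_detection_mask, apply_global_masks,
    assign_regions, simulate, summarize_samples,
)


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition cohort (seed 1): 100 normals + three tumor blocks."""
    return simulate(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def default_qc(default_sim):
    """QC'd betas, region assignment and sample summary for the default cohort."""
    ann, cohort = default_sim
    retained = apply_global_masks(ann.manifest)
    betas = cohort.betas.subset_probes(retained["probe_id"])
    betas = apply_detection_mask(betas, cohort.detection_p.loc[betas.probes])
    regions = {k: v for k, v in ann.region_sets.items() if k != "lad"}
    assignment = assign_regions(retained, regions)
    summary = summarize_samples(betas, assignment, cohort.clinical)
    return {"retained": retained, "betas": betas, "assignment": assignment,
            "summary": summary}


def small_spec(seed=7, **kwargs):
    """A reduced cohort for fast pipeline-level tests."""
    defaults = dict(
        seed=seed,
        genome={"chr1": 6_000_000, "chr2": 4_000_000, "chrX": 1_000_000},
        n_genes=120, n_intergenic_cgi=25, n_sites_per_random_tf=80,
        n_dnase=80, n_enhancer=40, n_repeats=200,
        lad_length_range=(600_000, 1_200_000),
        n_cgi_probes=600, n_backbone_probes=800, n_other_probes=300,
        n_flagged_probes=60, n_normal=25,
        tumor_blocks=(TumorBlock("TS", n_tumors=25, cgi_shift=0.06,
                                 backbone_shift=0.05),),
    )
    defaults.update(kwargs)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_spec())
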