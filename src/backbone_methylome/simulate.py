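"""Self-contained synthetic cohorts with the statistical structure the
analysis assumes.

The generator emits a toy genome annotation (genes, CpG islands, shores,
TF-binding sites with one polycomb-like factor concentrated at islands,
DNase sites, enhancers, repeats, LADs and the derived backbone), an
array-style probe manifest, and a cohort of normal and tumor samples.

Noise model. Per-probe baseline means are drawn from Beta distributions
centered at the normal compartment levels (CGI 0.21, backbone 0.80 — the
midpoints of the observed normal ranges 0.18–0.24 and 0.78–0.82); each
sample adds a small compartment-level random effect (sd 0.005) so normal
cohorts stay inside those ranges; each cell draws a Beta value with
concentration kappa around its mean, so values live in [0, 1] and the mean
is preserved exactly. Tumor blocks shift CGI probe means up by delta_C
(concentrated at polycomb-like TF-site islands) and backbone probe means
down by delta_B (amplified inside LADs); both weightings are normalized to
be mean-preserving so the planted delta equals the expected cohort-level
change. Planted clinical slopes, mutation effects and copy-number
couplings enter through the per-sample compartment effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel, Genome, RegionSet, build_backbone, build_gene_region_sets,
    genome_regions, shore_of, union_all,
)
from .io import BetaMatrix


@dataclass(frozen=True)
class TumorBlock:
    """One tumor type's planted parameters."""

    name: str
    n_tumors: int = 50
    cgi_shift: float = 0.0          # mean increase of CGI probe methylation
    backbone_shift: float = 0.0     # mean decrease of backbone probe methylation
    lad_extra_shift: float = 0.0    # additional decrease inside LADs (additive)
    polycomb_factor: float = 2.0    # CGI-shift concentration at polycomb sites
    lad_factor: float = 1.5         # backbone-shift concentration inside LADs
    age_slope_backbone: float = -0.0004   # per year, centered at age 55
    stage_slope_cgi: float = 0.0          # per stage unit, centered at 2.5
    # gene -> (axis in {cgi, backbone}, effect on the axis, carrier prevalence)
    mutation_effects: Mapping[str, Tuple[str, float, float]] = field(
        default_factory=dict)
    # gene -> (axis, target Kendall tau of log2ratio vs the axis average)
    scna_couplings: Mapping[str, Tuple[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated cohort."""

    seed: int = 1
    genome: Mapping[str, int] = field(default_factory=lambda: {
        "chr1": 12_000_000, "chr2": 8_000_000, "chrX": 2_000_000})
    sex_chroms: Tuple[str, ...] = ("chrX", "chrY")
    n_genes: int = 250
    cgi_at_promoter_fraction: float = 0.6
    n_intergenic_cgi: int = 50
    polycomb_tf: str = "SUZ12"
    polycomb_cgi_fraction: float = 0.4
    random_tfs: Tuple[str, ...] = ("CTCF", "IKZF1", "BATF")
    n_sites_per_random_tf: int = 150
    n_dnase: int = 150
    n_enhancer: int = 80
    n_repeats: int = 400
    n_lads_per_chrom: int = 2
    lad_length_range: Tuple[int, int] = (1_000_000, 2_000_000)
    n_cgi_probes: int = 2000
    n_backbone_probes: int = 2000
    n_other_probes: int = 1000
    n_flagged_probes: int = 150   # split between SNP, repeat and sex-chromosome
    n_normal: int = 100
    tumor_blocks: Tuple[TumorBlock, ...] = (
        TumorBlock("TTA", n_tumors=40),                       # NC-NB like
        TumorBlock("TTB", n_tumors=40, cgi_shift=0.10,        # HC-NB like
                   backbone_shift=0.01),
        TumorBlock("TTC", n_tumors=40, cgi_shift=0.08,        # HC-LB like
                   backbone_shift=0.10,
                   mutation_effects={"TP53": ("backbone", -0.04, 0.4)},
                   scna_couplings={"NSD1": ("backbone", 0.4)}),
    )
    cgi_normal_mean: float = 0.21
    backbone_normal_mean: float = 0.80
    other_normal_mean: float = 0.50
    probe_mean_concentration: float = 60.0   # spread of per-probe baselines
    kappa: float = 300.0                     # per-cell Beta concentration
    sample_sd: float = 0.005                 # per-sample compartment effect sd
    detection_fail_rate: float = 0.002
    n_background_mut_genes: int = 3
    n_scna_genes: int = 60
    wgbs_n_paired: int = 14
    wgbs_noise_sd: float = 0.01


@dataclass
class SimulatedAnnotations:
    genome: Genome
    genes: List[GeneModel]
    region_sets: Dict[str, RegionSet]   # incl. cgi, shore, ..., repeat, backbone, lad
    tf_sets: Dict[str, RegionSet]
    manifest: pd.DataFrame


@dataclass
class SimulatedCohort:
    betas: BetaMatrix
    detection_p: pd.DataFrame
    clinical: pd.DataFrame         # indexed by sample_id
    mutations: pd.DataFrame        # samples x genes, 0/1
    scna: pd.DataFrame             # samples x genes, log2 ratio
    scna_coords: pd.DataFrame      # gene, chrom, start, end
    wgbs: pd.DataFrame             # paired per-sample averages
    truth: Dict[str, object]       # ground truth for parameter-recovery tests


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _autosomes(spec: CohortSpec) -> List[str]:
    return [c for c in spec.genome if c not in spec.sex_chroms]


def generate_annotations(spec: CohortSpec) -> SimulatedAnnotations:
    """Deterministic toy annotation for the spec's genome (seeded by spec.seed)."""
    rng = np.random.default_rng([spec.seed, 101])
    genome = dict(spec.genome)
    autosomes = _autosomes(spec)
    total_auto = sum(genome[c] for c in autosomes)
    if total_auto < 4_000_000:
        raise ValueError("genome too small to place the requested features")

    # genes: sequential placement with random gaps, proportional per chromosome
    genes: List[GeneModel] = []
    gid = 0
    for chrom in autosomes:
        n_here = int(round(spec.n_genes * genome[chrom] / total_auto))
        pos = int(rng.integers(50_000, 120_000))
        for _ in range(n_here):
            length = int(rng.integers(5_000, 40_000))
            if pos + length > genome[chrom] - 50_000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 7))
            starts = np.sort(rng.choice(
                np.arange(pos, pos + length - 200, 200), n_ex, replace=False))
            exons = tuple(
                (int(s), int(min(s + int(rng.integers(100, 1500)), pos + length)))
                for s in starts)
            gid += 1
            genes.append(GeneModel(f"G{gid:04d}", chrom, pos, pos + length,
                                   strand, exons))
            pos += length + int(rng.integers(15_000, 60_000))
    if len(genes) < 20:
        raise ValueError("genome too small to place the requested features")

    # CpG islands: around a subset of TSSs plus intergenic ones
    cgi_ivs: List[Tuple[str, int, int]] = []
    for g in genes:
        if rng.random() < spec.cgi_at_promoter_fraction:
            tss = g.start if g.strand == "+" else g.end
            half = int(rng.integers(300, 900))
            cgi_ivs.append((g.chrom, max(0, tss - half), tss + half))
    for _ in range(spec.n_intergenic_cgi):
        chrom = autosomes[int(rng.integers(len(autosomes)))]
        s = int(rng.integers(0, genome[chrom] - 2000))
        cgi_ivs.append((chrom, s, s + int(rng.integers(500, 2000))))
    cgi = RegionSet("cgi", cgi_ivs)

    # TF sites: polycomb-like factor blankets a fraction of islands
    tf_sets: Dict[str, RegionSet] = {}
    poly_ivs = []
    for iv in cgi.intervals():
        if rng.random() < spec.polycomb_cgi_fraction:
            poly_ivs.append((iv.chrom, max(0, iv.start - 200),
                             min(genome[iv.chrom], iv.end + 200)))
    tf_sets[spec.polycomb_tf] = RegionSet(spec.polycomb_tf, poly_ivs)
    for tf in spec.random_tfs:
        ivs = []
        for _ in range(spec.n_sites_per_random_tf):
            chrom = autosomes[int(rng.integers(len(autosomes)))]
            s = int(rng.integers(0, genome[chrom] - 1200))
            ivs.append((chrom, s, s + int(rng.integers(200, 1000))))
        tf_sets[tf] = RegionSet(tf, ivs)

    def scatter(name: str, n: int, lo: int, hi: int) -> RegionSet:
        ivs = []
        for _ in range(n):
            chrom = autosomes[int(rng.integers(len(autosomes)))]
            length = int(rng.integers(lo, hi))
            s = int(rng.integers(0, genome[chrom] - length))
            ivs.append((chrom, s, s + length))
        return RegionSet(name, ivs)

    dnase = scatter("dnase", spec.n_dnase, 200, 1000)
    enhancer = scatter("enhancer", spec.n_enhancer, 500, 2000)
    repeats = scatter("repeat", spec.n_repeats, 200, 3000)

    # LADs: a few megabase blocks per autosome, non-overlapping
    lad_ivs = []
    for chrom in autosomes:
        slots = np.sort(rng.choice(
            np.arange(0, genome[chrom] - spec.lad_length_range[1],
                      spec.lad_length_range[1] + 200_000),
            min(spec.n_lads_per_chrom, 2), replace=False))
        for s in slots:
            length = int(rng.integers(*spec.lad_length_range))
            lad_ivs.append((chrom, int(s), int(s) + length))
    lads = RegionSet("lad", lad_ivs)

    gene_sets = build_gene_region_sets(genes, genome)
    shore = shore_of(cgi, genome)
    functional = [cgi, shore, gene_sets["promoter"], gene_sets["five_prime_body"],
                  gene_sets["exon"], dnase, union_all(list(tf_sets.values()), "tf"),
                  enhancer]
    backbone = build_backbone(genome, functional, repeats)

    region_sets = {
        "cgi": cgi, "shore": shore, "promoter": gene_sets["promoter"],
        "five_prime_body": gene_sets["five_prime_body"],
        "exon": gene_sets["exon"], "dnase": dnase,
        "tf": union_all(list(tf_sets.values()), "tf"), "enhancer": enhancer,
        "repeat": repeats, "backbone": backbone, "lad": lads,
    }

    manifest = _generate_manifest(spec, rng, genome, region_sets)
    return SimulatedAnnotations(genome, genes, region_sets, tf_sets, manifest)


def _sample_positions(rs: RegionSet, n: int, rng) -> List[Tuple[str, int]]:
    """Sample probe positions uniformly over the bases a RegionSet covers."""
    chroms, arrs, lens = [], [], []
    for chrom in rs.chroms:
        arr = rs.arrays(chrom)
        if len(arr):
            chroms.append(chrom)
            arrs.append(arr)
            lens.append((arr[:, 1] - arr[:, 0]))
    flat_len = np.concatenate(lens)
    cum = np.concatenate([[0], np.cumsum(flat_len)])
    total = cum[-1]
    starts = np.concatenate([a[:, 0] for a in arrs])
    chrom_of = np.concatenate([[c] * len(a) for c, a in zip(chroms, arrs)])
    u = rng.integers(0, total, size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    pos = starts[idx] + (u - cum[idx])
    return [(chrom_of[i], int(p)) for i, p in zip(idx, pos)]


def _generate_manifest(spec, rng, genome, region_sets) -> pd.DataFrame:
    rows = []
    cgi, backbone = region_sets["cgi"], region_sets["backbone"]
    other = union_all([region_sets[k] for k in
                       ("shore", "promoter", "five_prime_body", "exon",
                        "dnase", "tf", "enhancer")], "other").subtract(cgi)
    for compartment, rs, n in (("cgi", cgi, spec.n_cgi_probes),
                               ("backbone", backbone, spec.n_backbone_probes),
                               ("other", other, spec.n_other_probes)):
        for chrom, pos in _sample_positions(rs, n, rng):
            rows.append({"chrom": chrom, "pos": pos, "snp_dist": np.nan,
                         "repeat_within_15bp": 0, "compartment": compartment})
    # probes the global masks must remove: SNP-near, repeat-near, sex-chromosome
    n_each = spec.n_flagged_probes // 3
    whole = genome_regions({c: l for c, l in genome.items()
                            if c not in spec.sex_chroms})
    for chrom, pos in _sample_positions(whole, n_each, rng):
        rows.append({"chrom": chrom, "pos": pos,
                     "snp_dist": int(rng.integers(0, 11)),
                     "repeat_within_15bp": 0, "compartment": "flagged"})
    for chrom, pos in _sample_positions(whole, n_each, rng):
        rows.append({"chrom": chrom, "pos": pos, "snp_dist": np.nan,
                     "repeat_within_15bp": 1, "compartment": "flagged"})
    sex_present = [c for c in spec.sex_chroms if c in genome]
    if sex_present:
        sexg = genome_regions({c: genome[c] for c in sex_present})
        for chrom, pos in _sample_positions(sexg, n_each, rng):
            rows.append({"chrom": chrom, "pos": pos, "snp_dist": np.nan,
                         "repeat_within_15bp": 0, "compartment": "flagged"})
    df = pd.DataFrame(rows)
    # unflagged probes sit comfortably away from SNPs
    unflagged = df["snp_dist"].isna() & (df["compartment"] != "flagged")
    df.loc[unflagged, "snp_dist"] = rng.integers(50, 5000, size=int(unflagged.sum()))
    df.insert(0, "probe_id", [f"cg{i:07d}" for i in range(len(df))])
    df["type"] = np.where(rng.random(len(df)) < 0.7, "II", "I")
    return df[["probe_id", "chrom", "pos", "snp_dist", "repeat_within_15bp",
               "type", "compartment"]]


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _probe_shift_weights(spec, ann, block: TumorBlock) -> np.ndarray:
    """Per-probe mean shift for one tumor block (mean-preserving weighting)."""
    m = ann.manifest
    shift = np.zeros(len(m))
    pos_by_chrom = {c: g for c, g in m.groupby("chrom", sort=False)}

    def membership(rs) -> np.ndarray:
        out = np.zeros(len(m), dtype=bool)
        for chrom, grp in pos_by_chrom.items():
            out[grp.index] = rs.contains(chrom, grp["pos"].to_numpy())
        return out

    is_cgi = (m["compartment"] == "cgi").to_numpy()
    is_bb = (m["compartment"] == "backbone").to_numpy()
    if block.cgi_shift and is_cgi.any():
        in_poly = membership(ann.tf_sets[spec.polycomb_tf]) & is_cgi
        w = np.where(in_poly, block.polycomb_factor, 1.0)
        w = w / w[is_cgi].mean()
        shift[is_cgi] += block.cgi_shift * w[is_cgi]
    if (block.backbone_shift or block.lad_extra_shift) and is_bb.any():
        in_lad = membership(ann.region_sets["lad"]) & is_bb
        w = np.where(in_lad, block.lad_factor, 1.0)
        w = w / w[is_bb].mean()
        shift[is_bb] -= block.backbone_shift * w[is_bb]
        shift[in_lad] -= block.lad_extra_shift
    return shift


def generate_cohort(spec: CohortSpec, ann: SimulatedAnnotations) -> SimulatedCohort:
    """Simulate betas, detection p, clinical and molecular tables."""
    rng = np.random.default_rng([spec.seed, 202])
    m = ann.manifest
    n_probes = len(m)

    # per-probe baseline means by compartment
    comp_mean = {"cgi": spec.cgi_normal_mean, "backbone": spec.backbone_normal_mean,
                 "other": spec.other_normal_mean, "flagged": spec.other_normal_mean}
    nu = spec.probe_mean_concentration
    base = np.empty(n_probes)
    for comp, mean in comp_mean.items():
        sel = (m["compartment"] == comp).to_numpy()
        base[sel] = rng.beta(mean * nu, (1 - mean) * nu, size=int(sel.sum()))
    base = np.clip(base, 0.02, 0.98)

    # sample roster
    sample_ids, tissues, ttypes, block_of = [], [], [], []
    for i in range(spec.n_normal):
        sample_ids.append(f"N{i + 1:04d}")
        tissues.append("normal")
        ttypes.append("NORMAL")
        block_of.append(None)
    for block in spec.tumor_blocks:
        for i in range(block.n_tumors):
            sample_ids.append(f"{block.name}_{i + 1:04d}")
            tissues.append("tumor")
            ttypes.append(block.name)
            block_of.append(block)
    n_samples = len(sample_ids)

    # clinical covariates
    age = rng.uniform(30, 80, n_samples)
    sex = np.where(rng.random(n_samples) < 0.5, "F", "M")
    stage = rng.integers(1, 5, n_samples).astype(float)
    grade = rng.integers(1, 4, n_samples).astype(float)
    msi = rng.choice([0, 1, 2], n_samples, p=[0.7, 0.15, 0.15]).astype(float)
    smoking = rng.choice([0, 1, 2], n_samples, p=[0.5, 0.3, 0.2]).astype(float)

    # mutation table
    mut_genes = sorted({g for b in spec.tumor_blocks for g in b.mutation_effects})
    mut_genes += [f"BG{i + 1}" for i in range(spec.n_background_mut_genes)]
    mutations = pd.DataFrame(0, index=sample_ids, columns=mut_genes, dtype=int)

    # per-sample compartment effects
    c_cgi = rng.normal(0, spec.sample_sd, n_samples)
    c_bb = rng.normal(0, spec.sample_sd, n_samples)
    c_other = rng.normal(0, spec.sample_sd, n_samples)
    for i, block in enumerate(block_of):
        if block is None:
            continue
        c_bb[i] += block.age_slope_backbone * (age[i] - 55.0)
        c_cgi[i] += block.stage_slope_cgi * (stage[i] - 2.5)
        for gene, (axis, delta, prev) in block.mutation_effects.items():
            if rng.random() < prev:
                mutations.loc[sample_ids[i], gene] = 1
                if axis == "cgi":
                    c_cgi[i] += delta
                else:
                    c_bb[i] += delta
        for gene in mut_genes:
            if gene.startswith("BG") and rng.random() < 0.2:
                mutations.loc[sample_ids[i], gene] = 1

    # per-probe per-sample means and Beta draws
    is_cgi = (m["compartment"] == "cgi").to_numpy()
    is_bb = (m["compartment"] == "backbone").to_numpy()
    is_other = ~(is_cgi | is_bb)
    shifts = {b.name: _probe_shift_weights(spec, ann, b) for b in spec.tumor_blocks}
    mean_mat = np.empty((n_probes, n_samples))
    for j, (sid, block) in enumerate(zip(sample_ids, block_of)):
        mu = base.copy()
        if block is not None:
            mu = mu + shifts[block.name]
        mu[is_cgi] += c_cgi[j]
        mu[is_bb] += c_bb[j]
        mu[is_other] += c_other[j]
        if (mu < 0.001).any() or (mu > 0.999).any():
            warnings.warn(f"sample {sid}: planted shifts pushed "
                          f"{int(((mu < 0.001) | (mu > 0.999)).sum())} probe "
                          "means outside [0, 1]; clipped", stacklevel=2)
        mean_mat[:, j] = np.clip(mu, 0.001, 0.999)
    betas_arr = rng.beta(mean_mat * spec.kappa, (1 - mean_mat) * spec.kappa)
    values = pd.DataFrame(betas_arr, index=m["probe_id"].values, columns=sample_ids)
    values.index.name = "probe_id"
    betas = BetaMatrix(values, None)

    detection = rng.uniform(0, 0.04, size=(n_probes, n_samples))
    fail = rng.random((n_probes, n_samples)) < spec.detection_fail_rate
    detection[fail] = rng.uniform(0.051, 0.5, size=int(fail.sum()))
    detection_p = pd.DataFrame(detection, index=values.index, columns=sample_ids)

    clinical = pd.DataFrame({
        "tissue": tissues, "tumor_type": ttypes, "age": age, "sex": sex,
        "stage": stage, "grade": grade, "msi": msi, "smoking": smoking,
    }, index=pd.Index(sample_ids, name="sample_id"))

    # copy-number table: null genes plus planted couplings, at gene coordinates
    scna_gene_pool = [g.gene_id for g in ann.genes[: spec.n_scna_genes]]
    planted = sorted({g for b in spec.tumor_blocks for g in b.scna_couplings})
    scna_genes = planted + [g for g in scna_gene_pool
                            if g not in planted][: spec.n_scna_genes - len(planted)]
    coords_rows = []
    gene_by_id = {g.gene_id: g for g in ann.genes}
    for k, gname in enumerate(scna_genes):
        ref = gene_by_id.get(gname, ann.genes[k % len(ann.genes)])
        coords_rows.append({"gene": gname, "chrom": ref.chrom,
                            "start": ref.start, "end": ref.end})
    scna_coords = pd.DataFrame(coords_rows)
    scna = pd.DataFrame(rng.normal(0, 0.3, size=(n_samples, len(scna_genes))),
                        index=pd.Index(sample_ids, name="sample_id"),
                        columns=scna_genes)
    scna.loc[[t == "normal" for t in tissues]] = 0.0
    for block in spec.tumor_blocks:
        rows = [j for j, b in enumerate(block_of) if b is block]
        for gene, (axis, tau) in block.scna_couplings.items():
            z = c_cgi[rows] if axis == "cgi" else c_bb[rows]
            z = (z - z.mean()) / max(z.std(), 1e-12)
            rho = np.sin(np.pi * tau / 2)  # Kendall tau of a bivariate Gaussian
            eps = rng.normal(0, 1, len(rows))
            scna.iloc[rows, scna.columns.get_loc(gene)] = 0.3 * (
                rho * z + np.sqrt(1 - rho ** 2) * eps)

    # paired WGBS-like averages: true per-sample compartment means + noise
    true_cgi = mean_mat[is_cgi].mean(axis=0)
    true_bb = mean_mat[is_bb].mean(axis=0)
    paired_idx = np.linspace(0, n_samples - 1, min(spec.wgbs_n_paired, n_samples))
    paired_idx = np.unique(paired_idx.astype(int))
    wgbs = pd.DataFrame({
        "avg_cgi": true_cgi[paired_idx] + rng.normal(0, spec.wgbs_noise_sd,
                                                     len(paired_idx)),
        "avg_backbone": true_bb[paired_idx] + rng.normal(0, spec.wgbs_noise_sd,
                                                         len(paired_idx)),
    }, index=pd.Index([sample_ids[i] for i in paired_idx], name="sample_id"))

    truth = {
        "base_means": pd.Series(base, index=values.index),
        "probe_shifts": {k: pd.Series(v, index=values.index)
                         for k, v in shifts.items()},
        "sample_cgi_effect": pd.Series(c_cgi, index=sample_ids),
        "sample_backbone_effect": pd.Series(c_bb, index=sample_ids),
        "true_avg_cgi": pd.Series(true_cgi, index=sample_ids),
        "true_avg_backbone": pd.Series(true_bb, index=sample_ids),
    }
    return SimulatedCohort(betas, detection_p, clinical, mutations, scna,
                           scna_coords, wgbs, truth)


def simulate(spec: Optional[CohortSpec] = None,
             seed: Optional[int] = None) -> Tuple[SimulatedAnnotations, SimulatedCohort]:
    """Convenience: annotations + cohort from one spec (optionally reseeded)."""
    spec = spec or CohortSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    ann = generate_annotations(spec)
    cohort = generate_cohort(spec, ann)
    return ann, cohort
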