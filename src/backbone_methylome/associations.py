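"""Association battery between methylation averages and clinical/molecular
variables.

Clinical variables are tested inside a linear model controlling age and sex
(the coefficient's two-sided p is reported); molecular variables use the
scale-appropriate rank test — Wilcoxon rank-sum for binary, Kruskal–Wallis
for categorical, Kendall rank correlation (tau-b) for continuous. Families
of tests are corrected by Benjamini–Hochberg step-up with an explicitly
declared family size, so a genome-wide scan can correct by the total number
of genes attempted rather than the number that returned a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

# Editable ordinal coding tables: clinical text categories -> monotone codes.
ORDINAL_CODES: Dict[str, Dict[str, float]] = {
    "stage": {"I": 1, "II": 2, "III": 3, "IV": 4},
    "msi": {"MSS": 0, "MSI-I": 1, "MSI-H": 2},
    "smoking": {"never": 0, "former": 1, "current": 2},
    "response": {"CR": 1, "PR": 2, "SD": 3, "PD": 4},
}


@dataclass
class AssociationResult:
    variable: str
    test: str  # {wilcoxon, kruskal_wallis, kendall, linear_adjusted}
    statistic: Optional[float]
    p: Optional[float]
    q: Optional[float]
    n: int
    effect_sign: Optional[float]
    note: str = ""

    @property
    def missing(self) -> bool:
        return self.p is None or not np.isfinite(self.p)


def encode_ordinal(values: pd.Series, table: Mapping[str, float]) -> pd.Series:
    """Map text categories through an ordinal coding table (unknown -> NaN)."""
    return values.map(table).astype(float)


def dummy_code(values: pd.Series, prefix: str) -> pd.DataFrame:
    return pd.get_dummies(values, prefix=prefix, dtype=float)


def adjusted_clinical_association(
    y: pd.Series,
    clinical: pd.DataFrame,
    variable: str,
    age_col: str = "age",
    sex_col: str = "sex",
) -> AssociationResult:
    """Linear model of a methylation average on (variable, age, sex).

    Sex is dummy-coded and dropped in single-sex cohorts ("wherever
    applicable"). The reported p is the two-sided p of the variable's
    coefficient. Degenerate designs (constant variable, collinearity with
    the covariates) return a missing result with a diagnostic note.
    """
    df = clinical.loc[clinical.index.intersection(y.index)].copy()
    yv = y.loc[df.index]
    x = pd.to_numeric(df[variable], errors="coerce")
    design = pd.DataFrame({"var": x, "age": pd.to_numeric(df[age_col], errors="coerce")})
    sexes = df[sex_col].dropna().unique()
    if len(sexes) > 1:
        design["sex"] = (df[sex_col] == sorted(map(str, sexes))[-1]).astype(float)
    keep = design.notna().all(axis=1) & yv.notna()
    design, yv = design[keep], yv[keep]
    n = int(len(yv))
    if n < 4 or design["var"].nunique() < 2:
        return AssociationResult(variable, "linear_adjusted", None, None, None, n,
                                 None, "constant variable or too few samples")
    X = sm.add_constant(design.astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        return AssociationResult(variable, "linear_adjusted", None, None, None, n,
                                 None, "collinear design (variable vs covariates)")
    fit = sm.OLS(yv.astype(float), X).fit()
    coef = float(fit.params["var"])
    p = float(fit.pvalues["var"])
    return AssociationResult(variable, "linear_adjusted", float(fit.tvalues["var"]),
                             p, None, n, float(np.sign(coef)) or None)


def molecular_association(
    y: pd.Series, values: pd.Series, scale: str, variable: str = ""
) -> AssociationResult:
    """Rank test between a methylation average and one molecular variable.

    scale: "binary" -> Wilcoxon rank-sum, "categorical" -> Kruskal–Wallis,
    "continuous" -> Kendall tau-b.
    """
    variable = variable or (values.name or "variable")
    common = y.index.intersection(values.index)
    yv = y.loc[common]
    xv = values.loc[common]
    keep = yv.notna() & xv.notna()
    yv, xv = yv[keep], xv[keep]
    n = int(len(yv))
    if scale == "binary":
        g0, g1 = yv[xv == 0], yv[xv != 0]
        if len(g0) < 2 or len(g1) < 2:
            return AssociationResult(variable, "wilcoxon", None, None, None, n,
                                     None, "group with < 2 samples")
        stat, p = stats.mannwhitneyu(g1, g0, alternative="two-sided")
        sign = float(np.sign(g1.median() - g0.median())) or None
        return AssociationResult(variable, "wilcoxon", float(stat), float(p),
                                 None, n, sign)
    if scale == "categorical":
        groups = [grp.to_numpy() for _, grp in yv.groupby(xv) if len(grp) >= 2]
        if len(groups) < 2:
            return AssociationResult(variable, "kruskal_wallis", None, None, None,
                                     n, None, "fewer than 2 usable groups")
        try:
            with np.errstate(invalid="ignore"):
                stat, p = stats.kruskal(*groups)
        except ValueError:
            stat, p = np.nan, np.nan
        if not np.isfinite(stat):  # every observation tied: no evidence
            stat, p = 0.0, 1.0
        return AssociationResult(variable, "kruskal_wallis", float(stat), float(p),
                                 None, n, None)
    if scale == "continuous":
        if n < 3 or xv.nunique() < 2 or yv.nunique() < 2:
            return AssociationResult(variable, "kendall", None, None, None, n,
                                     None, "constant input")
        tau, p = stats.kendalltau(xv, yv)
        return AssociationResult(variable, "kendall", float(tau), float(p), None,
                                 n, float(np.sign(tau)) or None)
    raise ValueError(f"unknown scale {scale!r}")


def bh_adjust(pvalues: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values over one declared family.

    `m` is the family size used in the correction; by default the number of
    non-missing p-values, but a scan may declare the total number of tests
    attempted (the "correction by the number of comparisons" convention).
    Missing (NaN) entries propagate as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    k = int(ok.sum())
    if k == 0:
        return q
    m_eff = int(m) if m is not None else k
    if m_eff < k:
        raise ValueError("family size m smaller than the number of p-values")
    pv = p[ok]
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m_eff / np.arange(1, k + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(k)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


def attach_q(results: Sequence[AssociationResult],
             m: Optional[int] = None) -> None:
    """BH-adjust one family of AssociationResults in place."""
    p = [r.p if r.p is not None else np.nan for r in results]
    q = bh_adjust(p, m=m)
    for r, qi in zip(results, q):
        r.q = None if not np.isfinite(qi) else float(qi)


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variable": r.variable, "test": r.test, "statistic": r.statistic,
        "p": r.p, "q": r.q, "n": r.n, "effect_sign": r.effect_sign,
        "note": r.note,
    } for r in results])


def scna_scan(
    y: pd.Series,
    gene_log2: pd.DataFrame,
    gene_coords: pd.DataFrame,
    family_m: Optional[int] = None,
) -> pd.DataFrame:
    """Gene-level copy-number vs methylation scan for one cohort.

    Kendall tau-b between each gene's log2 copy ratio (samples × genes) and
    the per-sample methylation average, BH-corrected across the scan (family
    size defaults to the total number of genes attempted, mirroring the
    genome-wide correction convention). Output is sorted by chromosome and
    position; genes with a constant log2 ratio report missing p.
    """
    results = []
    for gene in gene_log2.columns:
        r = molecular_association(y, gene_log2[gene], "continuous", variable=gene)
        results.append(r)
    m = family_m if family_m is not None else len(gene_log2.columns)
    n_ok = sum(not r.missing for r in results)
    attach_q(results, m=max(m, n_ok))
    out = results_to_frame(results).rename(columns={"variable": "gene",
                                                    "statistic": "tau"})
    coords = gene_coords.set_index("gene") if "gene" in gene_coords.columns else gene_coords
    out = out.join(coords[["chrom", "start", "end"]], on="gene")
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def cross_tumor_percentiles(
    scans: Mapping[str, pd.DataFrame],
    percentiles: Sequence[float] = (10, 20, 30, 40),
    value_col: str = "q",
) -> pd.DataFrame:
    """Per-gene percentiles of corrected p-values across tumor types.

    For each gene present in >= 2 tumor-type scans, the requested
    percentiles (linear interpolation between closest ranks) of its
    corrected p across types, for positional plotting of recurrently
    associated loci. Genes in fewer than 2 types are dropped.
    """
    if len(scans) < 2:
        raise ValueError("need scans from >= 2 tumor types")
    per_gene: Dict[str, list] = {}
    coords = {}
    for ttype, scan in scans.items():
        for _, row in scan.iterrows():
            v = row[value_col]
            if pd.notna(v):
                per_gene.setdefault(row["gene"], []).append(float(v))
                coords[row["gene"]] = (row.get("chrom"), row.get("start"))
    rows = []
    for gene, vals in per_gene.items():
        if len(vals) < 2:
            continue
        pct = np.percentile(vals, percentiles, method="linear")
        row = {"gene": gene, "chrom": coords[gene][0], "start": coords[gene][1],
               "n_types": len(vals)}
        row.update({f"p{int(q)}": v for q, v in zip(percentiles, pct)})
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return out


def body_methylation_expression_correlation(
    body_beta: pd.DataFrame,
    expression: pd.DataFrame,
    method: str = "spearman",
) -> Dict[str, object]:
    """Per-gene rank correlation between gene-body backbone methylation and
    expression across paired samples.

    Both inputs are genes × samples; genes with constant expression report
    NaN. Returns the per-gene correlations plus a distribution summary.
    """
    samples = body_beta.columns.intersection(expression.columns)
    if len(samples) < 3:
        raise ValueError("need >= 3 paired samples")
    corrs = {}
    for gene in body_beta.index.intersection(expression.index):
        b = body_beta.loc[gene, samples].astype(float)
        e = expression.loc[gene, samples].astype(float)
        keep = b.notna() & e.notna()
        if keep.sum() < 3 or e[keep].nunique() < 2 or b[keep].nunique() < 2:
            corrs[gene] = np.nan
            continue
        if method == "spearman":
            corrs[gene] = float(stats.spearmanr(b[keep], e[keep])[0])
        elif method == "kendall":
            corrs[gene] = float(stats.kendalltau(b[keep], e[keep])[0])
        else:
            raise ValueError(f"unknown method {method!r}")
    series = pd.Series(corrs, name="correlation")
    valid = series.dropna()
    return {
        "per_gene": series,
        "median": float(valid.median()) if len(valid) else np.nan,
        "mean": float(valid.mean()) if len(valid) else np.nan,
        "n_genes": int(len(valid)),
    }
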