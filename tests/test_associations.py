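"""The clinical/molecular association battery and the SCNA scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from backbone_methylome.associations import (
    adjusted_clinical_association, bh_adjust, body_methylation_expression_correlation,
    cross_tumor_percentiles, encode_ordinal, molecular_association, scna_scan,
    ORDINAL_CODES,
)


class TestBH:
    def test_hand_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04], m=4)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_and_all_ones(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_declared_family_larger_than_observed(self):
        # the genome-wide convention: correct by the total tests attempted
        q = bh_adjust([0.001, 0.5], m=100)
        assert q[0] == pytest.approx(0.1)

    def test_family_smaller_than_observed_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2, 0.3], m=2)

    def test_nan_propagates_without_entering_family(self):
        q = bh_adjust([0.02, np.nan, 0.04])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], bh_adjust([0.02, 0.04]))

    def test_matches_statsmodels_and_is_monotone(self):
        rng = np.random.default_rng(51)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1).all() and (q >= p - 1e-12).all()


class TestAdjustedLinear:
    @staticmethod
    def simulate_cohort(rng, n=200, slope=0.02, noise=0.02):
        age = rng.uniform(30, 80, n)
        sex = rng.choice(["M", "F"], n)
        stage = rng.integers(1, 5, n).astype(float)
        y = 0.2 + slope * stage - 0.0005 * (age - 55) + rng.normal(0, noise, n)
        idx = [f"s{i}" for i in range(n)]
        clinical = pd.DataFrame({"age": age, "sex": sex, "stage": stage},
                                index=idx)
        return pd.Series(y, index=idx), clinical

    def test_planted_stage_effect_recovered(self):
        rng = np.random.default_rng(61)
        hits, close = 0, 0
        for _ in range(100):
            y, clinical = self.simulate_cohort(rng)
            r = adjusted_clinical_association(y, clinical, "stage")
            assert r.test == "linear_adjusted"
            if r.p < 0.01:
                hits += 1
            # re-fit to inspect the coefficient directly
            import statsmodels.api as sm
            X = sm.add_constant(pd.DataFrame({
                "var": clinical["stage"], "age": clinical["age"],
                "sex": (clinical["sex"] == "M").astype(float)}))
            coef = sm.OLS(y, X).fit().params["var"]
            if abs(coef - 0.02) < 0.01:
                close += 1
        assert hits >= 90
        assert close >= 90

    def test_constant_variable_is_missing(self):
        rng = np.random.default_rng(62)
        y, clinical = self.simulate_cohort(rng, n=50)
        clinical["flat"] = 1.0
        r = adjusted_clinical_association(y, clinical, "flat")
        assert r.missing and "constant" in r.note

    def test_collinear_design_is_missing_with_diagnostic(self):
        rng = np.random.default_rng(63)
        y, clinical = self.simulate_cohort(rng, n=50)
        clinical["age_copy"] = clinical["age"]
        r = adjusted_clinical_association(y, clinical, "age_copy")
        assert r.missing and "collinear" in r.note

    def test_single_sex_cohort_drops_sex_covariate(self):
        rng = np.random.default_rng(64)
        y, clinical = self.simulate_cohort(rng, n=80)
        clinical["sex"] = "F"
        r = adjusted_clinical_association(y, clinical, "stage")
        assert not r.missing


class TestMolecular:
    def test_wilcoxon_power_on_planted_shift(self):
        rng = np.random.default_rng(71)
        hits = 0
        for _ in range(20):
            mut = pd.Series([0] * 50 + [1] * 50,
                            index=[f"s{i}" for i in range(100)])
            y = pd.Series(np.concatenate([
                rng.normal(0.20, 0.02, 50), rng.normal(0.30, 0.02, 50)]),
                index=mut.index)
            r = molecular_association(y, mut, "binary")
            if r.p < 1e-5:
                hits += 1
        assert hits >= 19

    def test_wilcoxon_group_too_small_is_missing(self):
        y = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        mut = pd.Series([0, 0, 0, 1], index=list("abcd"))
        assert molecular_association(y, mut, "binary").missing

    def test_kendall_perfect_concordance(self):
        y = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        r = molecular_association(y, x, "continuous")
        assert r.statistic == pytest.approx(1.0)

    def test_kruskal_identical_groups(self):
        y = pd.Series([0.5] * 9, index=[f"s{i}" for i in range(9)])
        g = pd.Series([0, 1, 2] * 3, index=y.index)
        r = molecular_association(y, g, "categorical")
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_rank_tests_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(72)
        idx = [f"s{i}" for i in range(60)]
        y = pd.Series(rng.uniform(0.1, 0.9, 60), index=idx)
        mut = pd.Series(rng.integers(0, 2, 60), index=idx)
        x = pd.Series(rng.normal(size=60), index=idx)
        y2 = np.exp(3 * y)  # strictly monotone transform
        for scale, v in (("binary", mut), ("continuous", x)):
            r1 = molecular_association(y, v, scale)
            r2 = molecular_association(y2, v, scale)
            assert r1.p == pytest.approx(r2.p, rel=1e-9)

    def test_ordinal_coding_tables_are_monotone(self):
        coded = encode_ordinal(pd.Series(["MSS", "MSI-I", "MSI-H", "weird"]),
                               ORDINAL_CODES["msi"])
        assert coded.tolist()[:3] == [0, 1, 2]
        assert np.isnan(coded.iloc[3])


def planted_scan(rng, n=100, n_genes=80, tau=0.4):
    idx = [f"s{i}" for i in range(n)]
    y = pd.Series(rng.normal(0.75, 0.03, n), index=idx)
    z = (y - y.mean()) / y.std()
    rho = np.sin(np.pi * tau / 2)
    log2 = pd.DataFrame(rng.normal(0, 0.3, (n, n_genes)), index=idx,
                        columns=[f"g{j}" for j in range(n_genes)])
    log2["g0"] = 0.3 * (rho * z + np.sqrt(1 - rho ** 2) * rng.normal(size=n))
    coords = pd.DataFrame({
        "gene": log2.columns,
        "chrom": ["chr1"] * (n_genes // 2) + ["chr2"] * (n_genes - n_genes // 2),
        "start": np.arange(n_genes) * 100_000,
        "end": np.arange(n_genes) * 100_000 + 50_000})
    return y, log2, coords


class TestScnaScan:
    def test_planted_coupling_detected_null_genes_quiet(self):
        rng = np.random.default_rng(81)
        y, log2, coords = planted_scan(rng)
        scan = scna_scan(y, log2, coords)
        planted_q = scan.loc[scan["gene"] == "g0", "q"].iloc[0]
        assert planted_q < 0.05
        null_q = scan.loc[scan["gene"] != "g0", "q"]
        assert (null_q >= 0.05).mean() >= 0.95

    def test_shuffled_labels_kill_the_signal(self):
        rng = np.random.default_rng(82)
        y, log2, coords = planted_scan(rng)
        y_perm = pd.Series(rng.permutation(y.values), index=y.index)
        scan = scna_scan(y_perm, log2, coords)
        assert scan.loc[scan["gene"] == "g0", "q"].iloc[0] >= 0.05

    def test_constant_gene_is_missing_and_output_position_sorted(self):
        rng = np.random.default_rng(83)
        y, log2, coords = planted_scan(rng, n_genes=10)
        log2["g5"] = 0.0
        scan = scna_scan(y, log2, coords)
        assert np.isnan(scan.loc[scan["gene"] == "g5", "p"].iloc[0])
        assert (scan.groupby("chrom")["start"].apply(
            lambda s: s.is_monotonic_increasing)).all()

    def test_single_gene_reduces_to_continuous_association(self):
        rng = np.random.default_rng(84)
        y, log2, coords = planted_scan(rng, n_genes=1)
        scan = scna_scan(y, log2[["g0"]], coords.iloc[:1])
        direct = molecular_association(y, log2["g0"], "continuous")
        assert scan["p"].iloc[0] == pytest.approx(direct.p)
        assert scan["tau"].iloc[0] == pytest.approx(direct.statistic)


class TestPercentiles:
    @staticmethod
    def scans_from_pvals(per_type_p, gene="gA"):
        return {
            f"T{i}": pd.DataFrame({"gene": [gene], "chrom": ["chr1"],
                                   "start": [0], "q": [p]})
            for i, p in enumerate(per_type_p)}

    def test_identical_values_give_flat_percentiles(self):
        out = cross_tumor_percentiles(self.scans_from_pvals([0.3] * 21))
        row = out.iloc[0]
        assert row[["p10", "p20", "p30", "p40"]].tolist() == [0.3] * 4

    def test_linear_interpolation_matches_order_statistics(self):
        vals = (np.arange(1, 22) / 21.0).tolist()
        out = cross_tumor_percentiles(self.scans_from_pvals(vals))
        expected = np.percentile(vals, [10, 20, 30, 40], method="linear")
        assert np.allclose(
            out.iloc[0][["p10", "p20", "p30", "p40"]].astype(float), expected)

    def test_one_small_p_spread(self):
        # a hit in a few tumor types shows at the low percentile only
        vals = [1e-8] * 3 + [1.0] * 18
        out = cross_tumor_percentiles(self.scans_from_pvals(vals))
        assert out.iloc[0]["p10"] < 0.01
        assert out.iloc[0]["p40"] == pytest.approx(1.0)

    def test_gene_in_fewer_than_two_types_dropped(self):
        scans = self.scans_from_pvals([0.5, 0.6])
        scans["T1"] = pd.DataFrame({"gene": ["gB"], "chrom": ["chr1"],
                                    "start": [0], "q": [0.6]})
        out = cross_tumor_percentiles(scans)
        assert out.empty
        with pytest.raises(ValueError):
            cross_tumor_percentiles({"T0": scans["T0"]})


class TestBodyExpression:
    @staticmethod
    def paired(rng, n_genes=60, n=100, rho=0.5):
        genes = [f"g{j}" for j in range(n_genes)]
        samples = [f"s{i}" for i in range(n)]
        body = pd.DataFrame(rng.uniform(0.4, 0.9, (n_genes, n)),
                            index=genes, columns=samples)
        noise = rng.normal(0, 1, (n_genes, n))
        z = (body - body.mean(axis=1).values[:, None])
        z = z / z.std(axis=1).values[:, None]
        expr = pd.DataFrame(rho * z.values + np.sqrt(1 - rho ** 2) * noise,
                            index=genes, columns=samples)
        return body, expr

    def test_planted_positive_correlation_recovered(self):
        rng = np.random.default_rng(91)
        body, expr = self.paired(rng)
        out = body_methylation_expression_correlation(body, expr)
        assert out["median"] > 0.3

    def test_independent_expression_near_zero(self):
        rng = np.random.default_rng(92)
        body, expr = self.paired(rng, rho=0.0)
        out = body_methylation_expression_correlation(body, expr)
        assert abs(out["median"]) < 0.05

    def test_noiseless_monotone_pairing_gives_one(self):
        body = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["g0"],
                            columns=list("abcd"))
        expr = pd.DataFrame([[1.0, 4.0, 9.0, 16.0]], index=["g0"],
                            columns=list("abcd"))
        out = body_methylation_expression_correlation(body, expr)
        assert out["per_gene"]["g0"] == pytest.approx(1.0)

    def test_constant_expression_is_missing(self):
        body = pd.DataFrame([[0.1, 0.2, 0.3]], index=["g0"],
                            columns=list("abc"))
        expr = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g0"],
                            columns=list("abc"))
        out = body_methylation_expression_correlation(body, expr)
        assert np.isnan(out["per_gene"]["g0"])
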