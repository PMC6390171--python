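"""cis-window assignment, nominal engine, permutation empirical p-values."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from nephroage.containers import OmicsMatrix, VariantSet
from nephroage.qtl import (
    CisWindowConfig,
    assign_cis_variants,
    map_cis_nominal,
    permutation_pass,
    select_best_variant,
    signed_distance,
)
from nephroage.simulate import CohortParams, Effect, simulate_cohort


def _variant_set(positions, dosage, samples=None):
    positions = list(positions)
    ann = pd.DataFrame(
        {
            "feature_id": [f"v{j}" for j in range(len(positions))],
            "chrom": "chr1",
            "start": positions,
            "end": [p + 1 for p in positions],
            "strand": ".",
            "kind": "variant",
        }
    )
    samples = samples or [f"s{j}" for j in range(dosage.shape[1])]
    return VariantSet(ann, dosage, samples)


def _gene(start=1_000_000, end=1_010_000):
    return pd.DataFrame(
        [("geneA", "chr1", start, end, "+", "gene")],
        columns=["feature_id", "chrom", "start", "end", "strand", "kind"],
    )


class TestCisAssignment:
    def test_signed_distance_convention(self):
        assert signed_distance(1_005_000, 1_000_000, 1_010_000) == 0
        assert signed_distance(999_000, 1_000_000, 1_010_000) == -1000
        assert signed_distance(1_012_000, 1_000_000, 1_010_000) == 1_012_000 - 1_009_999

    def test_half_open_window_boundary(self, rng):
        dosage = rng.binomial(2, 0.3, size=(2, 50)).astype(float)
        vs = _variant_set([2_009_999, 2_010_000], dosage)
        mapping = assign_cis_variants(_gene(), vs, CisWindowConfig(window=10**6))
        ids = set(mapping["geneA"]["variant_id"])
        assert ids == {"v0"}

    def test_window_zero_keeps_only_overlap(self, rng):
        dosage = rng.binomial(2, 0.3, size=(3, 50)).astype(float)
        vs = _variant_set([999_999, 1_000_000, 1_009_999], dosage)
        mapping = assign_cis_variants(_gene(), vs, CisWindowConfig(window=0))
        assert list(mapping["geneA"]["variant_id"]) == ["v1", "v2"]
        assert list(mapping["geneA"]["distance"]) == [0, 0]

    def test_missing_chromosome_gives_empty_list(self, rng):
        gene = _gene().assign(chrom="chrX")
        vs = _variant_set([1_000_500], rng.binomial(2, 0.3, (1, 30)).astype(float))
        mapping = assign_cis_variants(gene, vs, CisWindowConfig())
        assert len(mapping["geneA"]) == 0

    def test_maf_filter(self):
        dosage = np.zeros((2, 100))
        dosage[0, :2] = 1.0  # MAF 0.01
        dosage[1, :60] = 1.0  # MAF 0.3
        vs = _variant_set([1_000_100, 1_000_200], dosage)
        mapping = assign_cis_variants(_gene(), vs, CisWindowConfig(maf_min=0.05))
        assert list(mapping["geneA"]["variant_id"]) == ["v1"]


class TestNominal:
    def _setup(self, rng, beta=0.3, n=400):
        dosage = rng.binomial(2, 0.3, size=(4, n)).astype(float)
        y = beta * dosage[1] + rng.normal(scale=1.0, size=n)
        pheno = OmicsMatrix(
            pd.DataFrame(y[None, :], index=["geneA"],
                         columns=[f"s{j}" for j in range(n)]),
            "normalized",
        )
        vs = _variant_set([1_000_100, 1_000_200, 1_000_300, 1_000_400], dosage)
        cov = pd.DataFrame({"c1": rng.normal(size=n)}, index=pheno.sample_ids)
        mapping = assign_cis_variants(_gene(), vs, CisWindowConfig())
        return pheno, vs, cov, mapping

    def test_recovers_planted_effect(self, rng):
        pheno, vs, cov, mapping = self._setup(rng, beta=0.3, n=5000)
        res = map_cis_nominal(pheno, vs, cov, mapping)
        row = res[res["variant_id"] == "v1"].iloc[0]
        assert row["beta"] == pytest.approx(0.3, abs=0.05)
        assert row["p"] < 1e-10

    def test_agrees_with_statsmodels_including_covariates(self, rng):
        pheno, vs, cov, mapping = self._setup(rng)
        res = map_cis_nominal(pheno, vs, cov, mapping)
        X = sm.add_constant(np.column_stack([vs.dosage[2], cov["c1"]]))
        fit = sm.OLS(pheno.values[0], X).fit()
        row = res[res["variant_id"] == "v2"].iloc[0]
        assert row["beta"] == pytest.approx(fit.params[1], abs=1e-8)
        assert row["se"] == pytest.approx(fit.bse[1], abs=1e-8)
        assert row["p"] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_permuted_phenotype_nominal_p_uniform(self, rng):
        n = 200
        dosage = rng.binomial(2, 0.3, size=(40, n)).astype(float)
        positions = 1_000_000 + 100 * np.arange(40)
        vs = _variant_set(positions, dosage)
        y = rng.normal(size=(50, n))
        pheno = OmicsMatrix(
            pd.DataFrame(y, index=[f"f{i}" for i in range(50)],
                         columns=vs.sample_ids),
            "normalized",
        )
        genes = pd.DataFrame(
            [(f"f{i}", "chr1", 1_000_000, 1_004_000, "+", "gene") for i in range(50)],
            columns=["feature_id", "chrom", "start", "end", "strand", "kind"],
        )
        mapping = assign_cis_variants(genes, vs, CisWindowConfig(window=10_000))
        res = map_cis_nominal(pheno, vs, None, mapping)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_monomorphic_variant_skipped(self, rng):
        dosage = rng.binomial(2, 0.3, size=(2, 100)).astype(float)
        dosage[0] = 1.0
        vs = _variant_set([1_000_100, 1_000_200], dosage)
        y = rng.normal(size=100)
        pheno = OmicsMatrix(
            pd.DataFrame(y[None, :], index=["geneA"], columns=vs.sample_ids),
            "normalized",
        )
        mapping = assign_cis_variants(_gene(), vs, CisWindowConfig(maf_min=0.0))
        res = map_cis_nominal(pheno, vs, None, mapping)
        assert res[res["variant_id"] == "v0"].iloc[0]["status"] == "monomorphic"


class TestBestVariant:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["feature_id", "variant_id", "distance", "beta",
                           "se", "t", "df", "p", "n", "status"]
        )

    def test_unique_minimum(self):
        res = self._frame(
            [("g", "a", 10, 1, 1, 1, 10, 0.5, 50, "ok"),
             ("g", "b", 10, 1, 1, 1, 10, 0.01, 50, "ok")]
        )
        assert select_best_variant(res).iloc[0]["variant_id"] == "b"

    def test_p_tie_broken_by_distance(self):
        res = self._frame(
            [("g", "far", 5000, 1, 1, 1, 10, 0.01, 50, "ok"),
             ("g", "near", 500, 1, 1, 1, 10, 0.01, 50, "ok")]
        )
        assert select_best_variant(res).iloc[0]["variant_id"] == "near"

    def test_full_tie_broken_lexicographically(self):
        res = self._frame(
            [("g", "zz", 500, 1, 1, 1, 10, 0.01, 50, "ok"),
             ("g", "aa", -500, 1, 1, 1, 10, 0.01, 50, "ok")]
        )
        assert select_best_variant(res).iloc[0]["variant_id"] == "aa"


class TestPermutation:
    def test_empirical_p_floor_and_formula(self, rng):
        params = CohortParams(
            n_samples=200, n_genes=5, n_cpgs=2, n_variants=10, ld_block_size=2,
            seed=4, effects=[Effect("variant:rs000000", "gene:gene_0000", 1.5)],
        )
        bundle = simulate_cohort(params)
        cfg = CisWindowConfig(window=10**6, B=99, seed=9)
        genes = bundle.annotations.query("kind == 'gene'")
        expr = bundle.expression.with_values(
            np.log2(bundle.expression.values), kind="expression_log"
        )
        mapping = assign_cis_variants(genes, bundle.genotypes, cfg)
        res = permutation_pass(expr, bundle.genotypes, None, mapping, cfg)
        res = res.set_index("feature_id")
        # saturated signal: no permutation beats the observed statistic
        assert res.loc["gene_0000", "perm_p"] == pytest.approx(1 / 100)
        assert res.loc["gene_0000", "k"] == 0
        # formula holds everywhere and the floor is 1/(B+1), never 0
        ok = res[res["status"] == "ok"]
        np.testing.assert_allclose(ok["perm_p"], (ok["k"] + 1) / (cfg.B + 1))
        assert (ok["perm_p"] >= 1 / (cfg.B + 1)).all()

    def test_deterministic_given_seed(self, small_bundle):
        genes = small_bundle.annotations.query(
            "kind == 'gene' and feature_id == 'gene_0000'"
        )
        expr = small_bundle.expression.with_values(
            np.log2(small_bundle.expression.values), kind="expression_log"
        )
        cfg = CisWindowConfig(window=10**6, B=50, seed=21)
        mapping = assign_cis_variants(genes, small_bundle.genotypes, cfg)
        a = permutation_pass(expr, small_bundle.genotypes, None, mapping, cfg)
        b = permutation_pass(expr, small_bundle.genotypes, None, mapping, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_no_cis_variants_reported(self, rng):
        gene = _gene().assign(chrom="chrX")
        vs = _variant_set([1_000_100], rng.binomial(2, 0.3, (1, 50)).astype(float))
        y = rng.normal(size=50)
        pheno = OmicsMatrix(
            pd.DataFrame(y[None, :], index=["geneA"], columns=vs.sample_ids),
            "normalized",
        )
        cfg = CisWindowConfig(B=9)
        mapping = assign_cis_variants(gene, vs, cfg)
        res = permutation_pass(pheno, vs, None, mapping, cfg)
        assert res.iloc[0]["status"] == "no_cis_variants"
        assert np.isnan(res.iloc[0]["perm_p"])

    def test_null_empirical_p_uniform(self, rng):
        # many null features sharing one cis-variant panel
        n, n_feat, B = 150, 300, 200
        dosage = rng.binomial(2, 0.3, size=(8, n)).astype(float)
        positions = 1_000_000 + 200 * np.arange(8)
        vs = _variant_set(positions, dosage)
        y = rng.normal(size=(n_feat, n))
        pheno = OmicsMatrix(
            pd.DataFrame(y, index=[f"f{i}" for i in range(n_feat)],
                         columns=vs.sample_ids),
            "normalized",
        )
        genes = pd.DataFrame(
            [(f"f{i}", "chr1", 1_000_000, 1_002_000, "+", "gene")
             for i in range(n_feat)],
            columns=["feature_id", "chrom", "start", "end", "strand", "kind"],
        )
        cfg = CisWindowConfig(window=10_000, B=B, seed=3)
        mapping = assign_cis_variants(genes, vs, cfg)
        res = permutation_pass(pheno, vs, None, mapping, cfg)
        assert stats.kstest(res["perm_p"], "uniform").pvalue > 0.01
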