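"""Mediation, instrument selection, MR estimators, triangulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nephroage.causal import (
    TriangulationConfig,
    mediate,
    mr_egger,
    mr_ivw,
    mr_weighted_median,
    run_triangulation,
    select_instruments,
    weighted_median,
)
from nephroage.containers import ValidationError, VariantSet
from nephroage.simulate import (
    CohortParams,
    Effect,
    promoter_methylation_scenario,
    simulate_cohort,
)


class TestMediate:
    def test_noiseless_chain_decomposition(self, rng):
        x = np.arange(20.0)
        m = 2.0 * x + 1e-9 * rng.normal(size=20)  # jitter breaks collinearity
        y = 3.0 * m
        res = mediate(x, m, y, n_boot=199, seed=0)
        assert res.acme == pytest.approx(6.0, abs=1e-5)
        assert res.ade == pytest.approx(0.0, abs=1e-5)
        assert res.prop_mediated == pytest.approx(1.0, abs=1e-5)

    def test_total_equals_acme_plus_ade(self, rng):
        n = 200
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.4 * m + 0.3 * x + rng.normal(size=n)
        cov = rng.normal(size=(n, 2))
        res = mediate(x, m, y, cov, n_boot=199, seed=1)
        assert res.total == pytest.approx(res.acme + res.ade, abs=1e-8)
        assert res.ci[0] <= res.acme <= res.ci[1]

    def test_null_mediator_path_covers_zero(self, rng):
        n = 300
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)  # b = 0
        res = mediate(x, m, y, n_boot=499, seed=2)
        assert res.ci[0] <= 0.0 <= res.ci[1]

    def test_parameter_errors(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(ValidationError, match="constant"):
            mediate(x, np.zeros(50), x, n_boot=199)
        with pytest.raises(ValidationError, match="n_boot"):
            mediate(x, x + rng.normal(size=50), x, n_boot=100)


class TestInstrumentSelection:
    def _qtl_frame(self, ids, ps):
        return pd.DataFrame(
            {
                "feature_id": "cpg",
                "variant_id": ids,
                "distance": 0,
                "beta": 0.2,
                "se": 0.05,
                "t": 4.0,
                "df": 100,
                "p": ps,
                "n": 100,
                "status": "ok",
            }
        )

    def _variants(self, dosage):
        ann = pd.DataFrame(
            {
                "feature_id": [f"v{j}" for j in range(dosage.shape[0])],
                "chrom": "chr1",
                "start": 100 * np.arange(dosage.shape[0]),
                "end": 100 * np.arange(dosage.shape[0]) + 1,
                "strand": ".",
                "kind": "variant",
            }
        )
        return VariantSet(ann, dosage, [f"s{j}" for j in range(dosage.shape[1])])

    def test_perfectly_correlated_pair_keeps_smaller_p(self, rng):
        g = rng.binomial(2, 0.3, size=100).astype(float)
        vs = self._variants(np.vstack([g, g]))
        out = select_instruments(
            self._qtl_frame(["v0", "v1"], [0.01, 0.001]), vs, r2_max=0.1, p_max=0.05
        )
        assert list(out["variant_id"]) == ["v1"]

    def test_independent_instruments_all_retained(self, rng):
        dosage = rng.binomial(2, 0.3, size=(4, 2000)).astype(float)
        vs = self._variants(dosage)
        out = select_instruments(
            self._qtl_frame([f"v{j}" for j in range(4)], [1e-4] * 4),
            vs, r2_max=0.1, p_max=0.05,
        )
        assert len(out) == 4

    def test_planted_instruments_recovered_exactly(self):
        params = promoter_methylation_scenario(
            n_samples=600, n_genes=20, seed=6, ld_block_size=1, ld_decay=0.0,
        )
        bundle = simulate_cohort(params)
        from nephroage.qtl import CisWindowConfig, assign_cis_variants, map_cis_nominal

        cpg = bundle.annotations.query("feature_id == 'cpg_0000'")
        cfg = CisWindowConfig(window=33_172, maf_min=0.05)
        mapping = assign_cis_variants(cpg, bundle.genotypes, cfg)
        nominal = map_cis_nominal(bundle.methylation, bundle.genotypes, None, mapping)
        out = select_instruments(nominal, bundle.genotypes, r2_max=0.1, p_max=0.05)
        from nephroage.simulate import scenario_instrument_ids

        assert sorted(out["variant_id"]) == scenario_instrument_ids(params)

    def test_no_survivors_errors(self, rng):
        g = rng.binomial(2, 0.3, size=100).astype(float)
        vs = self._variants(g[None, :])
        with pytest.raises(ValidationError, match="instruments"):
            select_instruments(self._qtl_frame(["v0"], [0.9]), vs, p_max=1e-8)


def _instr(bx, by, sey, sex=None):
    frame = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(len(bx))],
            "beta_x": bx,
            "beta_y": by,
            "se_y": sey,
        }
    )
    if sex is not None:
        frame["se_x"] = sex
    return frame


class TestIvw:
    def test_single_instrument_is_wald_ratio(self):
        res = mr_ivw(_instr([0.5], [-0.25], [0.1]))
        assert res.theta == pytest.approx(-0.5)
        assert res.se == pytest.approx(0.2)

    def test_three_instrument_worked_example(self):
        res = mr_ivw(_instr([0.4, 0.5, 0.2], [0.2, 0.3, 0.05], [0.1, 0.1, 0.2]))
        # weights (16, 25, 1), ratios (0.5, 0.6, 0.25)
        assert res.theta == pytest.approx(23.25 / 42.0, abs=1e-10)
        assert res.theta == pytest.approx(0.5536, abs=1e-4)
        assert res.se == pytest.approx(42.0**-0.5, abs=1e-10)
        assert res.se == pytest.approx(0.1543, abs=1e-4)

    def test_proportional_instruments_recover_theta_exactly(self, rng):
        bx = rng.uniform(0.2, 0.8, size=5)
        res = mr_ivw(_instr(bx, 0.7 * bx, rng.uniform(0.05, 0.2, size=5)))
        assert res.theta == pytest.approx(0.7, abs=1e-12)

    def test_sign_flip_invariance(self):
        base = _instr([0.4, 0.5, 0.2], [0.2, 0.3, 0.05], [0.1, 0.1, 0.2])
        flipped = base.copy()
        flipped.loc[1, ["beta_x", "beta_y"]] *= -1
        assert mr_ivw(flipped).theta == pytest.approx(mr_ivw(base).theta)

    def test_zero_beta_x_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="beta_x"):
            res = mr_ivw(_instr([0.0, 0.5], [0.1, 0.25], [0.1, 0.1]))
        assert res.n_instruments == 1


class TestWeightedMedian:
    def test_midpoint_median_identity(self):
        assert weighted_median(np.array([1.0, 2.0, 10.0]), np.ones(3)) == 2.0

    def test_breakdown_resistance(self, rng):
        # 5 valid instruments at theta=1, 2 pleiotropic outliers (<50% weight)
        bx = np.concatenate([rng.uniform(0.3, 0.6, 5), rng.uniform(0.3, 0.4, 2)])
        by = np.concatenate([bx[:5] * 1.0, bx[5:] * 1.0 + 0.8])
        sey = np.full(7, 0.02)
        estimates = [
            mr_weighted_median(
                _instr(
                    rng.normal(bx, 0.01), rng.normal(by, 0.02), sey,
                    sex=np.full(7, 0.01),
                ),
                seed=i,
            ).theta
            for i in range(30)
        ]
        assert np.mean(estimates) == pytest.approx(1.0, abs=0.1)

    def test_identical_ratios_and_vanishing_se(self):
        bx = np.array([0.3, 0.5, 0.7])
        res = mr_weighted_median(
            _instr(bx, 2.0 * bx, np.full(3, 1e-8), sex=np.full(3, 1e-8)), seed=0
        )
        assert res.theta == pytest.approx(2.0)
        assert res.se < 1e-6

    def test_requires_three_instruments(self):
        with pytest.raises(ValidationError, match="3 instruments"):
            mr_weighted_median(_instr([0.5, 0.4], [0.2, 0.2], [0.1, 0.1]))


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        res = mr_egger(_instr(bx, 0.1 + 0.5 * bx, np.full(4, 0.1)))
        assert res.theta == pytest.approx(0.5, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-10)

    def test_intercept_type_one_error_calibrated(self, rng):
        rejections = 0
        reps = 500
        for _ in range(reps):
            bx = rng.uniform(0.2, 0.8, size=50)
            sey = np.full(50, 0.05)
            by = 0.5 * bx + rng.normal(0.0, sey)
            if mr_egger(_instr(bx, by, sey)).egger_intercept_p < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_detects_planted_directional_pleiotropy(self, rng):
        detected = 0
        reps = 100
        for _ in range(reps):
            bx = rng.uniform(0.2, 0.8, size=50)
            sey = np.full(50, 0.05)
            by = 0.2 + 0.5 * bx + rng.normal(0.0, sey)
            if mr_egger(_instr(bx, by, sey)).egger_intercept_p < 0.05:
                detected += 1
        assert detected / reps > 0.8


class TestTriangulation:
    def test_planted_scenario_flagged_end_to_end(self):
        params = promoter_methylation_scenario(n_samples=260, seed=8)
        bundle = simulate_cohort(params)
        cfg = TriangulationConfig(B=300, n_boot=299, seed=8)
        rep = run_triangulation(bundle, "gene_0000", "cpg_0000", cfg)
        eq = rep["eqtl"].set_index("feature_id")
        mq = rep["mqtl"].set_index("feature_id")
        assert eq.loc["gene_0000", "perm_p"] < 0.05
        assert mq.loc["cpg_0000", "perm_p"] < 0.05
        med = rep["mediation_age"]
        assert med.ci[1] < 0  # CI excludes zero, negative indirect path
        assert rep["mr"]["ivw"].theta < 0
        assert rep["mr"]["weighted_median"].theta < 0
        assert rep["mr"]["egger"].egger_intercept_p > 0.05
        assert len(rep["esnp_msnp_overlap"]) > 0

    def test_direct_snp_to_gene_path_has_null_acme(self):
        params = CohortParams(
            n_samples=400, n_genes=20, n_cpgs=5, n_variants=120, ld_block_size=2,
            seed=9,
            effects=[Effect("variant:rs000000", "gene:gene_0000", 0.6)],
        )
        bundle = simulate_cohort(params)
        cfg = TriangulationConfig(B=100, n_boot=299, seed=9,
                                  instrument_p_max=1.0)
        rep = run_triangulation(bundle, "gene_0000", "cpg_0000", cfg)
        med = rep["mediation_snp"]
        assert med.ci[0] <= 0.0 <= med.ci[1]

    def test_empty_instrument_set_marks_mr_not_run(self):
        params = CohortParams(
            n_samples=150, n_genes=10, n_cpgs=3, n_variants=40, ld_block_size=2,
            seed=10,
        )
        bundle = simulate_cohort(params)
        cfg = TriangulationConfig(B=50, n_boot=199, instrument_p_max=1e-30)
        rep = run_triangulation(bundle, "gene_0000", "cpg_0000", cfg)
        assert rep["mr_status"].startswith("not_run")
        assert rep["mr"] == {}

    def test_unknown_target_names_stage(self, small_bundle):
        with pytest.raises(ValidationError, match="stage eqtl"):
            run_triangulation(small_bundle, "nope", "cpg_0000")
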