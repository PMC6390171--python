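"""Inverse-variance meta-analysis, FDR control, replication, specificity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nephroage.meta import (
    bh_fdr,
    estimate_pi0,
    inverse_variance_meta,
    replicate_in_families,
    replication_filter,
    sensitivity_overlap,
    storey_qvalue,
)


def _study(betas, ses, fids=None):
    fids = fids or [f"g{i}" for i in range(len(betas))]
    return pd.DataFrame(
        {
            "feature_id": fids,
            "predictor": "age",
            "beta": betas,
            "se": ses,
            "t": np.array(betas) / np.array(ses),
            "df": 100,
            "p": 0.5,
            "n": 100,
            "status": "ok",
        }
    )


class TestInverseVarianceMeta:
    def test_single_study_is_identity(self):
        res = inverse_variance_meta([_study([0.3], [0.1])])
        row = res.iloc[0]
        assert row["beta_meta"] == pytest.approx(0.3)
        assert row["se_meta"] == pytest.approx(0.1)
        assert row["p"] == pytest.approx(2 * stats.norm.sf(3.0))

    def test_two_study_worked_example(self):
        res = inverse_variance_meta(
            [_study([0.2], [0.1]), _study([0.4], [0.2])]
        )
        row = res.iloc[0]
        # weights (100, 25): beta = (20+10)/125 = 0.24, SE = 125^-0.5
        assert row["beta_meta"] == pytest.approx(0.24, abs=1e-12)
        assert row["se_meta"] == pytest.approx(0.08944, abs=1e-5)
        assert row["z"] == pytest.approx(2.683, abs=1e-3)
        assert row["p"] == pytest.approx(0.00729, abs=1e-4)

    def test_equal_se_studies_average(self):
        res = inverse_variance_meta([_study([0.1], [0.05]), _study([0.5], [0.05])])
        assert res.iloc[0]["beta_meta"] == pytest.approx(0.3)

    def test_k_equal_se_studies_shrink_se_by_sqrt_k(self):
        k = 4
        res = inverse_variance_meta([_study([0.2], [0.1])] * k)
        assert res.iloc[0]["se_meta"] == pytest.approx(0.1 / np.sqrt(k))

    def test_meta_beta_convex_and_direction_flag(self, rng):
        betas = rng.normal(size=20)
        res = inverse_variance_meta(
            [
                _study(betas, np.full(20, 0.1)),
                _study(betas + rng.normal(scale=0.01, size=20), np.full(20, 0.2)),
            ]
        )
        for _, row in res.iterrows():
            assert min(row["study_betas"]) - 1e-12 <= row["beta_meta"] <= max(row["study_betas"]) + 1e-12
        res2 = inverse_variance_meta([_study([0.2], [0.1]), _study([-0.2], [0.1])])
        assert not res2.iloc[0]["direction_concordant"]


class TestBhFdr:
    def test_worked_stepup(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04]).q
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.2]).q[0] == pytest.approx(0.2)

    def test_agrees_with_bruteforce_stepup_oracle(self, rng):
        for _ in range(20):
            m = int(rng.integers(1, 50))
            p = rng.uniform(1e-6, 1, size=m)
            q = bh_fdr(p).q
            # brute force: q_i = min_{j: p_j >= p_i} p_j * m / rank(p_j)
            order = np.argsort(p)
            ranks = np.empty(m, dtype=int)
            ranks[order] = np.arange(1, m + 1)
            oracle = np.array(
                [
                    min(
                        min(p[j] * m / ranks[j] for j in range(m) if ranks[j] >= ranks[i]),
                        1.0,
                    )
                    for i in range(m)
                ]
            )
            np.testing.assert_allclose(q, oracle, atol=1e-12)

    def test_controls_fdp_on_mixture(self, rng):
        fdps = []
        for _ in range(200):
            null_p = rng.uniform(size=1600)
            alt_p = 2 * stats.norm.sf(np.abs(rng.normal(3.5, 1, size=400)))
            p = np.concatenate([null_p, np.clip(alt_p, 1e-300, 1)])
            is_null = np.arange(2000) < 1600
            q = bh_fdr(p).q
            sig = q < 0.05
            fdps.append(np.sum(sig & is_null) / max(sig.sum(), 1))
        assert np.mean(fdps) <= 0.07


class TestStorey:
    def test_pi0_near_one_on_uniform(self, rng):
        p = rng.uniform(size=5000)
        res = storey_qvalue(p)
        assert res.pi0 == pytest.approx(1.0, abs=0.05)

    def test_forced_pi0_scales_bh(self, rng):
        p = rng.uniform(size=200)
        bh = bh_fdr(p).q
        st = storey_qvalue(p, pi0=0.5).q
        np.testing.assert_allclose(st, np.minimum(bh * 0.5, 1.0), atol=1e-12)

    def test_signal_mixture_gives_smaller_q_than_bh(self, rng):
        null_p = rng.uniform(size=1600)
        alt_p = 2 * stats.norm.sf(np.abs(rng.normal(4, 1, size=400)))
        p = np.concatenate([null_p, np.clip(alt_p, 1e-300, 1)])
        st = storey_qvalue(p)
        assert st.pi0 < 1.0
        assert np.all(st.q <= bh_fdr(p).q + 1e-12)

    def test_all_tiny_p_hits_lower_bound_with_warning(self):
        with pytest.warns(UserWarning):
            pi0, _ = estimate_pi0(np.full(500, 1e-8))
        assert pi0 == pytest.approx(1 / 500)


class TestReplication:
    def _discovery(self):
        return pd.DataFrame(
            {"feature_id": ["a", "b", "c"], "beta_meta": [0.5, 0.4, -0.3]}
        )

    def test_same_direction_significant_replicates(self):
        rep = pd.DataFrame(
            {"feature_id": ["a"], "beta": [0.2], "p": [0.001]}
        )
        out = replication_filter(self._discovery(), rep)
        assert out.set_index("feature_id").loc["a", "status"] == "replicated"

    def test_opposite_direction_fails_despite_significance(self):
        rep = pd.DataFrame({"feature_id": ["a"], "beta": [-0.2], "p": [1e-6]})
        out = replication_filter(self._discovery(), rep)
        assert (
            out.set_index("feature_id").loc["a", "status"]
            == "not_replicated_direction"
        )

    def test_absent_feature_marked_unavailable(self):
        rep = pd.DataFrame({"feature_id": ["a"], "beta": [0.2], "p": [0.001]})
        out = replication_filter(self._discovery(), rep).set_index("feature_id")
        assert out.loc["b", "status"] == "unavailable"
        assert out.loc["c", "status"] == "unavailable"

    def test_family_union(self):
        families = {
            "cortex": pd.DataFrame({"feature_id": ["a"], "beta": [0.2], "p": [0.001]}),
            "medulla": pd.DataFrame({"feature_id": ["b"], "beta": [0.3], "p": [0.002]}),
        }
        out = replicate_in_families(self._discovery(), families).set_index("feature_id")
        assert out.loc["a", "status"] == "replicated"
        assert out.loc["b", "status"] == "replicated"
        assert out.loc["c", "status"] == "unavailable"


class TestSensitivityOverlap:
    def test_primary_scenario_specificity(self):
        out = sensitivity_overlap(
            {"A", "B", "C"},
            {"primary": {"t1": {"A"}, "t2": set()}},
            "primary",
        ).set_index("feature_id")
        assert out.loc["A", "label"] == "ubiquitous"
        assert out.loc["B", "label"] == "specific_all_scenarios"
        assert out.loc["C", "specific_primary"]

    def test_absent_everywhere_is_specific_all(self):
        out = sensitivity_overlap(
            {"G"},
            {"primary": {"t": {"X"}}, "alt": {"t": {"Y"}}},
            "primary",
        ).set_index("feature_id")
        assert out.loc["G", "label"] == "specific_all_scenarios"

    def test_hit_in_nonprimary_scenario_only(self):
        out = sensitivity_overlap(
            {"G"},
            {"primary": {"t": set()}, "alt": {"t": {"G"}}},
            "primary",
        ).set_index("feature_id")
        assert out.loc["G", "label"] == "specific_primary"
        assert out.loc["G", "specific_primary"]
        assert not out.loc["G", "specific_all_scenarios"]
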