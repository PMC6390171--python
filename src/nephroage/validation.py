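"""Calibration and recovery studies for the pipeline's estimators.

Each function runs one self-contained simulation experiment at the study
conditions the pipeline is designed for (discovery cohorts of 160 + 100
samples, ages spanning roughly 28-87 years, B = 2000 permutations, six
independent methylation instruments) and returns the measured quantities.
They power both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from nephroage import association, causal, meta, preprocess, qtl as qtl_mod
from nephroage.pipeline import run_pipeline
from nephroage.simulate import (
    CohortParams,
    Effect,
    promoter_methylation_scenario,
    simulate_cohort,
)


def permutation_floor(seed: int = 0, B: int = 2000, n_samples: int = 260) -> dict:
    """Empirical p-value of a saturated cis signal at B permutations.

    A planted eQTL strong enough that no permutation beats the observed
    statistic pins the empirical p at its floor 1/(B+1)."""
    params = CohortParams(
        n_samples=n_samples, n_genes=5, n_cpgs=2, n_variants=10, ld_block_size=2,
        seed=seed, effects=[Effect("variant:rs000000", "gene:gene_0000", 1.5)],
    )
    bundle = simulate_cohort(params)
    cfg = qtl_mod.CisWindowConfig(window=10**6, B=B, seed=seed + 1)
    genes = bundle.annotations.query("kind == 'gene' and feature_id == 'gene_0000'")
    expr = bundle.expression.with_values(
        np.log2(bundle.expression.values), kind="expression_log"
    )
    mapping = qtl_mod.assign_cis_variants(genes, bundle.genotypes, cfg)
    res = qtl_mod.permutation_pass(expr, bundle.genotypes, None, mapping, cfg)
    p = float(res.iloc[0]["perm_p"])
    return {"perm_p": p, "printed": f"{p:.2E}", "B": B, "k": int(res.iloc[0]["k"])}


def age_scan_type1(seed: int = 0, n_genes: int = 2000, n_samples: int = 160) -> dict:
    """Rejection fraction at alpha = 0.05 for null genes regressed on age
    after the full normalization stack."""
    params = CohortParams(
        n_samples=n_samples, n_genes=n_genes, n_cpgs=2, n_variants=30,
        ld_block_size=3, seed=seed, effects=[],
    )
    bundle = simulate_cohort(params)
    norm = preprocess.log_quantile_rbint(bundle.expression)
    covariates = bundle.covariates[["sex"]]
    # the cohort carries hidden technical factors; the analysis controls
    # for their estimates, as in the main pipeline
    factors = preprocess.estimate_hidden_factors(
        norm, covariates, params.n_hidden_factors
    )
    covariates = pd.concat([covariates, factors.scores], axis=1)
    res = association.fit_feature_associations(
        norm, bundle.covariates["age"], covariates, "age"
    )
    ok = res[res["status"] == "ok"]
    rate = float((ok["p"] < 0.05).mean())
    return {"rate": rate, "n_genes": len(ok), "n_samples": n_samples}


def fdr_calibration(seed: int = 0, m: int = 2000, reps: int = 200) -> dict:
    """Realized false-discovery proportion of BH at q < 0.05 on an 80%-null
    mixture, and Storey's pi0 on pure nulls."""
    rng = np.random.default_rng(seed)
    n_null = int(0.8 * m)
    fdps = []
    for _ in range(reps):
        null_p = rng.uniform(size=n_null)
        alt_p = 2 * stats.norm.sf(np.abs(rng.normal(3.5, 1.0, size=m - n_null)))
        p = np.concatenate([null_p, np.clip(alt_p, 1e-300, 1.0)])
        q = meta.bh_fdr(p).q
        sig = q < 0.05
        fdps.append(np.sum(sig[:n_null]) / max(sig.sum(), 1))
    pi0 = meta.storey_qvalue(rng.uniform(size=5000)).pi0
    return {"mean_fdp": float(np.mean(fdps)), "pi0_null": float(pi0), "reps": reps}


def ols_oracle_agreement(seed: int = 0, n_designs: int = 100) -> dict:
    """Max |difference| between the scan engine and explicit normal-equation
    solutions over random small designs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_designs):
        n = int(rng.integers(8, 21))
        n_cov = int(rng.integers(0, 3))
        x = rng.normal(size=n)
        cov = rng.normal(size=(n, n_cov)) if n_cov else None
        y = rng.normal(size=(2, n))
        mine = association.ols_scan(y, ["a", "b"], x, cov)
        X = np.column_stack(
            [np.ones(n), x] + ([cov] if cov is not None else [])
        )
        xtx_inv = np.linalg.inv(X.T @ X)
        for i, fid in enumerate(["a", "b"]):
            beta = xtx_inv @ X.T @ y[i]
            resid = y[i] - X @ beta
            df = n - X.shape[1]
            se = np.sqrt(resid @ resid / df * xtx_inv[1, 1])
            row = mine[mine["feature_id"] == fid].iloc[0]
            worst = max(worst, abs(row["beta"] - beta[1]), abs(row["se"] - se))
    return {"max_abs_diff": float(worst), "n_designs": n_designs}


def ivw_worked_example() -> dict:
    """Three-instrument IVW hand check plus the single-instrument Wald
    ratio identity."""
    three = causal.mr_ivw(
        pd.DataFrame(
            {"beta_x": [0.4, 0.5, 0.2], "beta_y": [0.2, 0.3, 0.05],
             "se_y": [0.1, 0.1, 0.2]}
        )
    )
    single = causal.mr_ivw(
        pd.DataFrame({"beta_x": [0.5], "beta_y": [-0.25], "se_y": [0.1]})
    )
    return {
        "theta": three.theta,
        "se": three.se,
        "single_theta": single.theta,
        "single_se": single.se,
    }


def mr_recovery(
    seed: int = 0,
    reps: int = 200,
    n_samples: int = 500,
    true_effect: float = -0.6,
) -> dict:
    """Bias of IVW and weighted-median estimates on cohorts with a planted
    CpG -> gene effect and six independent methylation instruments."""
    ivw_thetas, wm_thetas = [], []
    for rep in range(reps):
        params = promoter_methylation_scenario(
            n_samples=n_samples, seed=seed * 100_000 + rep,
            cpg_gene_effect=true_effect,
        )
        bundle = simulate_cohort(params)
        ann = bundle.annotations
        cpg_ann = ann[(ann["kind"] == "cpg") & (ann["feature_id"] == "cpg_0000")]
        gene_ann = ann[(ann["kind"] == "gene") & (ann["feature_id"] == "gene_0000")]
        cov = bundle.covariates[["sex"]]
        m_map = qtl_mod.assign_cis_variants(
            cpg_ann, bundle.genotypes, qtl_mod.CisWindowConfig(window=33_172)
        )
        m_nom = qtl_mod.map_cis_nominal(bundle.methylation, bundle.genotypes, cov, m_map)
        e_map = qtl_mod.assign_cis_variants(
            gene_ann, bundle.genotypes, qtl_mod.CisWindowConfig(window=10**6)
        )
        expr = bundle.expression.with_values(
            np.log2(bundle.expression.values), kind="expression_log"
        )
        e_nom = qtl_mod.map_cis_nominal(
            expr, bundle.genotypes, cov, e_map
        ).set_index("variant_id")
        instr = causal.select_instruments(m_nom, bundle.genotypes, r2_max=0.1)
        instr["beta_y"] = [float(e_nom.loc[v, "beta"]) for v in instr["variant_id"]]
        instr["se_y"] = [float(e_nom.loc[v, "se"]) for v in instr["variant_id"]]
        ivw_thetas.append(causal.mr_ivw(instr).theta)
        if len(instr) >= 3:
            wm_thetas.append(causal.mr_weighted_median(instr, seed=rep).theta)
    ivw_mean = float(np.mean(ivw_thetas))
    wm_mean = float(np.mean(wm_thetas))
    return {
        "true_effect": true_effect,
        "ivw_mean": ivw_mean,
        "wm_mean": wm_mean,
        "ivw_rel_bias": abs(ivw_mean - true_effect) / abs(true_effect),
        "wm_rel_bias": abs(wm_mean - true_effect) / abs(true_effect),
        "reps": reps,
    }


def egger_calibration(
    seed: int = 0, reps_null: int = 500, reps_power: int = 200, J: int = 50
) -> dict:
    """Egger intercept test: type-I error with no pleiotropy and power
    against a planted directional-pleiotropy intercept of 0.2."""
    rng = np.random.default_rng(seed)

    def run(intercept: float, reps: int) -> float:
        hits = 0
        for _ in range(reps):
            bx = rng.uniform(0.2, 0.8, size=J)
            sey = np.full(J, 0.05)
            by = intercept + 0.5 * bx + rng.normal(0.0, sey)
            frame = pd.DataFrame({"beta_x": bx, "beta_y": by, "se_y": sey})
            if causal.mr_egger(frame).egger_intercept_p < 0.05:
                hits += 1
        return hits / reps

    return {
        "null_rejection_rate": run(0.0, reps_null),
        "power": run(0.2, reps_power),
        "J": J,
    }


def mediation_coverage(
    seed: int = 0, reps: int = 500, n: int = 500, n_boot: int = 499
) -> dict:
    """Coverage of the ACME bootstrap CI: a = 0.5, b = 0.4, direct = 0.3,
    unit noise (true ACME 0.2); and a direct-only negative control (b = 0,
    true ACME 0)."""

    def run(b: float, target: float) -> float:
        covered = 0
        for rep in range(reps):
            rng = np.random.default_rng(seed * 100_000 + rep + int(b * 1000))
            x = rng.normal(size=n)
            m = 0.5 * x + rng.normal(size=n)
            y = b * m + 0.3 * x + rng.normal(size=n)
            res = causal.mediate(x, m, y, n_boot=n_boot, seed=rep)
            covered += res.ci[0] <= target <= res.ci[1]
        return covered / reps

    return {
        "coverage": run(0.4, 0.2),
        "null_coverage": run(0.0, 0.0),
        "reps": reps,
    }


def end_to_end_demo(seed: int = 1, outdir=None) -> dict:
    """Seeded pipeline run on the planted promoter-methylation scenario;
    reports whether the target gene is flagged at every stage."""
    import tempfile

    config = {
        "seed": seed,
        "qtl": {"B": 1000, "seed": seed + 10},
        "mediation": {"n_boot": 999, "seed": seed + 11},
        "mr": {"seed": seed + 12},
    }
    if outdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            results = run_pipeline(config, tmp)
    else:
        results = run_pipeline(config, outdir)
    target = "gene_0000"
    eq = results["eqtl"].set_index("feature_id")
    tri = results["triangulation"]
    mq = tri["mqtl"].set_index("feature_id")
    med = tri["mediation_age"]
    flags = {
        "age_associated": target in results["age_genes"],
        "replicated": target in results["replicated_genes"],
        "eqtl_perm_p": float(eq.loc[target, "perm_p"]),
        "mqtl_perm_p": float(mq.loc["cpg_0000", "perm_p"]),
        "acme": med.acme,
        "acme_ci": med.ci,
        "mediation_significant": med.ci[1] < 0.0,
        "mr_ivw_theta": tri["mr"]["ivw"].theta,
        "mr_wm_theta": tri["mr"]["weighted_median"].theta,
        "egger_intercept_p": tri["mr"]["egger"].egger_intercept_p,
    }
    flags["all_stages_flag_target"] = bool(
        flags["age_associated"]
        and flags["replicated"]
        and flags["eqtl_perm_p"] < 0.05
        and flags["mqtl_perm_p"] < 0.05
        and flags["mediation_significant"]
        and flags["mr_ivw_theta"] < 0
        and flags["mr_wm_theta"] < 0
    )
    return flags
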