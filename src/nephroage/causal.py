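"""Causal mediation analysis and summary-statistic Mendelian randomization.

Mediation uses the product-of-coefficients estimator under the linear
no-interaction model: with ``M ~ X + C`` giving the exposure-mediator path
``a`` and ``Y ~ X + M + C`` giving the mediator-outcome path ``b`` and the
direct effect, the average causal mediation effect is ``ACME = a * b`` and
the identity ``total = ACME + ADE`` holds exactly for the point estimates.
Uncertainty comes from a nonparametric bootstrap (samples resampled with
replacement) with percentile intervals.

Mendelian randomization operates on per-instrument summary statistics
(beta_X, SE_X) for the exposure and (beta_Y, SE_Y) for the outcome:

* IVW: ratio estimates beta_Y/beta_X combined with first-order weights
  w = beta_X^2 / SE_Y^2 (fixed effect); a single instrument reduces to the
  Wald ratio.
* Weighted median: consistent when instruments carrying at least half the
  weight are valid; SE by parametric bootstrap.
* MR-Egger: weighted regression of beta_Y on beta_X with an intercept that
  measures average directional pleiotropy (t-test with J - 2 df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from nephroage import association, preprocess, qtl as qtl_mod
from nephroage.containers import OmicsMatrix, ValidationError, VariantSet
from nephroage.meta import bh_fdr

# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    a: float
    b: float
    acme: float
    ade: float
    total: float
    prop_mediated: float
    ci: tuple[float, float]
    p: float
    n_boot: int
    seed: int
    n: int


def _coef(y: np.ndarray, columns: list[np.ndarray]) -> np.ndarray:
    X = np.column_stack([np.ones_like(y)] + columns)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def mediate(
    exposure: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 1999,
    seed: int = 0,
) -> MediationResult:
    """Product-of-coefficients mediation with bootstrap percentile CI.

    ``p`` is the two-sided bootstrap sign probability,
    ``2 * min(P(ACME* <= 0), P(ACME* >= 0))``, floored at ``2/(n_boot+1)``.
    """
    x = np.asarray(exposure, float)
    m = np.asarray(mediator, float)
    y = np.asarray(outcome, float)
    if n_boot < 199:
        raise ValidationError("n_boot must be >= 199")
    if np.ptp(m) == 0:
        raise ValidationError("mediator is constant")
    if not (x.size == m.size == y.size):
        raise ValidationError("exposure, mediator and outcome lengths differ")
    cov_cols = []
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov_cols = [cov]

    def fit(idx: np.ndarray) -> tuple[float, float, float, float]:
        xs, ms, ys = x[idx], m[idx], y[idx]
        cc = [c[idx] for c in cov_cols]
        a = _coef(ms, [xs] + cc)[1]
        full = _coef(ys, [xs, ms] + cc)
        ade, b = full[1], full[2]
        total = _coef(ys, [xs] + cc)[1]
        return a, b, ade, total

    all_idx = np.arange(x.size)
    a, b, ade, total = fit(all_idx)
    acme = a * b
    rng = np.random.default_rng(seed)
    # batched bootstrap: solve the two normal-equation systems for all
    # resamples at once
    n = x.size
    cov_mat = cov_cols[0] if cov_cols else np.empty((n, 0))
    Xm = np.column_stack([np.ones(n), x, cov_mat])  # mediator model design
    Xy = np.column_stack([np.ones(n), x, m, cov_mat])  # outcome model design
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.empty(n_boot)
    for start in range(0, n_boot, 256):
        block = idx[start : start + 256]
        Xmb = Xm[block]  # (B, n, p)
        Xyb = Xy[block]
        mb = m[block]
        yb = y[block]
        # pinv (not solve) so the rare degenerate resample of a discrete
        # exposure cannot abort the whole bootstrap
        a_b = np.matmul(
            np.linalg.pinv(np.einsum("bni,bnj->bij", Xmb, Xmb)),
            np.einsum("bni,bn->bi", Xmb, mb)[..., None],
        )[:, 1, 0]
        b_b = np.matmul(
            np.linalg.pinv(np.einsum("bni,bnj->bij", Xyb, Xyb)),
            np.einsum("bni,bn->bi", Xyb, yb)[..., None],
        )[:, 2, 0]
        boots[start : start + len(block)] = a_b * b_b
    lo, hi = np.percentile(boots, [2.5, 97.5])
    p = 2.0 * min(np.mean(boots <= 0.0), np.mean(boots >= 0.0))
    p = min(max(p, 2.0 / (n_boot + 1.0)), 1.0)
    prop = acme / total if total != 0 else np.nan
    return MediationResult(
        a=float(a),
        b=float(b),
        acme=float(acme),
        ade=float(ade),
        total=float(total),
        prop_mediated=float(prop),
        ci=(float(lo), float(hi)),
        p=float(p),
        n_boot=n_boot,
        seed=seed,
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# instrument selection


def select_instruments(
    exposure_qtl: pd.DataFrame,
    genotypes: VariantSet,
    r2_max: float = 0.1,
    p_max: float | None = None,
) -> pd.DataFrame:
    """Greedy LD pruning of exposure-associated variants.

    Candidates are nominal-``ok`` rows with ``p <= p_max`` (default: the
    BH-significant set at q < 0.05 within the supplied table), walked in
    order of increasing p; a variant is kept when its squared dosage
    correlation with every already-kept variant is at most ``r2_max``.
    Returns per-instrument ``(variant_id, beta_x, se_x, p_x)``.
    """
    ok = exposure_qtl[exposure_qtl["status"] == "ok"].copy()
    if p_max is None:
        fdr = bh_fdr(ok["p"].to_numpy())
        ok = ok[fdr.q < 0.05]
    else:
        ok = ok[ok["p"] <= p_max]
    ok = ok.sort_values(["p", "variant_id"], kind="mergesort")
    if ok.empty:
        raise ValidationError("no candidate instruments survive the p filter")
    dosage = genotypes.dosage
    lookup = {v: i for i, v in enumerate(genotypes.variant_ids)}
    col_mean = np.nanmean(dosage, axis=1, keepdims=True)
    filled = np.where(np.isnan(dosage), col_mean, dosage)
    kept_rows: list[int] = []
    kept: list[pd.Series] = []
    for _, row in ok.iterrows():
        r = lookup[row["variant_id"]]
        g = filled[r]
        independent = True
        for kr in kept_rows:
            rho = np.corrcoef(g, filled[kr])[0, 1]
            if rho * rho > r2_max:
                independent = False
                break
        if independent:
            kept_rows.append(r)
            kept.append(row)
    out = pd.DataFrame(kept).rename(
        columns={"beta": "beta_x", "se": "se_x", "p": "p_x"}
    )[["variant_id", "beta_x", "se_x", "p_x"]]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mendelian randomization estimators


@dataclass
class MRResult:
    method: str
    theta: float
    se: float
    ci: tuple[float, float]
    p: float
    n_instruments: int
    instruments: list[str] = field(default_factory=list)
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None


def _check_instruments(instr: pd.DataFrame, minimum: int, method: str) -> pd.DataFrame:
    needed = {"beta_x", "beta_y", "se_y"}
    missing = needed - set(instr.columns)
    if missing:
        raise ValidationError(f"instrument table lacks columns {sorted(missing)}")
    nonzero = instr["beta_x"] != 0
    if not nonzero.all():
        warnings.warn("dropping instruments with beta_x = 0", stacklevel=2)
        instr = instr[nonzero]
    if len(instr) < minimum:
        raise ValidationError(
            f"{method} needs at least {minimum} instruments, have {len(instr)}"
        )
    return instr


def mr_ivw(instruments: pd.DataFrame) -> MRResult:
    """Fixed-effect IVW of per-instrument Wald ratios, first-order weights."""
    instr = _check_instruments(instruments, 1, "IVW")
    bx = instr["beta_x"].to_numpy(float)
    by = instr["beta_y"].to_numpy(float)
    sey = instr["se_y"].to_numpy(float)
    w = bx**2 / sey**2
    ratios = by / bx
    theta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = theta / se
    return MRResult(
        method="ivw",
        theta=theta,
        se=se,
        ci=(theta - 1.96 * se, theta + 1.96 * se),
        p=float(2.0 * stats.norm.sf(abs(z))),
        n_instruments=len(instr),
        instruments=list(instr.get("variant_id", pd.Series(dtype=str))),
    )


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with midpoint cumulative weights and linear
    interpolation between neighbouring order statistics."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0
    if 0.5 <= s[0]:
        return float(v[0])
    if s[-1] <= 0.5:
        return float(v[-1])
    j = int(np.searchsorted(s, 0.5))
    if s[j] == 0.5:
        return float(v[j])
    return float(v[j - 1] + (0.5 - s[j - 1]) * (v[j] - v[j - 1]) / (s[j] - s[j - 1]))


def mr_weighted_median(
    instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Weighted-median MR; SE by seeded parametric bootstrap of the
    per-instrument summary statistics (the estimator has no closed form)."""
    instr = _check_instruments(instruments, 3, "weighted median")
    bx = instr["beta_x"].to_numpy(float)
    by = instr["beta_y"].to_numpy(float)
    sex = instr.get("se_x", pd.Series(np.zeros(len(instr)))).to_numpy(float)
    sey = instr["se_y"].to_numpy(float)
    w = bx**2 / sey**2
    theta = weighted_median(by / bx, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sex)
        bys = rng.normal(by, sey)
        ws = bxs**2 / sey**2
        with np.errstate(divide="ignore", invalid="ignore"):
            boots[i] = weighted_median(bys / bxs, ws)
    se = float(np.std(boots, ddof=1))
    z = theta / se if se > 0 else np.inf
    return MRResult(
        method="weighted_median",
        theta=float(theta),
        se=se,
        ci=(theta - 1.96 * se, theta + 1.96 * se),
        p=float(2.0 * stats.norm.sf(abs(z))),
        n_instruments=len(instr),
        instruments=list(instr.get("variant_id", pd.Series(dtype=str))),
    )


def mr_egger(instruments: pd.DataFrame) -> MRResult:
    """MR-Egger: WLS of beta_Y on beta_X (instruments oriented so
    beta_X > 0) with an intercept capturing directional pleiotropy."""
    instr = _check_instruments(instruments, 3, "MR-Egger")
    bx = instr["beta_x"].to_numpy(float).copy()
    by = instr["beta_y"].to_numpy(float).copy()
    sey = instr["se_y"].to_numpy(float)
    flip = bx < 0
    bx[flip] *= -1.0
    by[flip] *= -1.0
    w = 1.0 / sey**2
    X = np.column_stack([np.ones_like(bx), bx])
    wsq = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * wsq[:, None], by * wsq, rcond=None)
    resid = by - X @ coef
    dof = len(bx) - 2
    if dof <= 0:
        raise ValidationError("MR-Egger needs more than 2 instruments")
    sigma2 = np.sum(w * resid**2) / dof
    xtwx_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    ses = np.sqrt(sigma2 * np.diag(xtwx_inv))
    intercept, slope = coef
    se_int, se_slope = ses
    t_slope = slope / se_slope
    t_int = intercept / se_int
    return MRResult(
        method="egger",
        theta=float(slope),
        se=float(se_slope),
        ci=(float(slope - 1.96 * se_slope), float(slope + 1.96 * se_slope)),
        p=float(2.0 * stats.t.sf(abs(t_slope), dof)),
        n_instruments=len(instr),
        instruments=list(instr.get("variant_id", pd.Series(dtype=str))),
        egger_intercept=float(intercept),
        egger_intercept_se=float(se_int),
        egger_intercept_p=float(2.0 * stats.t.sf(abs(t_int), dof)),
    )


# ---------------------------------------------------------------------------
# triangulation


@dataclass
class TriangulationConfig:
    eqtl_window: int = 1_000_000
    mqtl_window: int = 33_172
    B: int = 2000
    maf_min: float = 0.05
    r2_max: float = 0.1
    instrument_p_max: float | None = None
    n_boot: int = 1999
    n_hidden_factors: int = 2
    n_genotype_pcs: int = 3
    # pseudo-count for the log2 outcome scale; 0 keeps strictly positive
    # TPM matrices on the exact log scale, 1 is the safe choice for sparse
    # real data (at the price of attenuating low-expression effects)
    outcome_pseudo_count: float = 0.0
    seed: int = 0


def run_triangulation(
    bundle,
    target_gene: str,
    target_cpg: str,
    config: TriangulationConfig | None = None,
) -> dict:
    """End-to-end genotype/methylation/expression triangulation for one
    gene-CpG pair: cis-eQTL and cis-mQTL with permutations, eSNP/mSNP
    overlap, mediation in both orientations (age -> M -> Y and
    SNP -> M -> Y) and all three MR estimators.

    Mediation and MR run on log2 expression and beta-scale methylation so
    effects stay on the generative scales.
    """
    config = config or TriangulationConfig()
    ann = bundle.annotations
    if target_gene not in set(ann.loc[ann["kind"] == "gene", "feature_id"]):
        raise ValidationError(f"stage eqtl: unknown gene {target_gene!r}")
    if target_cpg not in set(ann.loc[ann["kind"] == "cpg", "feature_id"]):
        raise ValidationError(f"stage mqtl: unknown CpG {target_cpg!r}")

    covariates = bundle.covariates[["sex"]].copy()
    pcs = preprocess.compute_genotype_pcs(bundle.genotypes, config.n_genotype_pcs)
    covariates = pd.concat([covariates, pcs], axis=1)
    shifted = bundle.expression.values + config.outcome_pseudo_count
    if np.any(shifted <= 0):
        raise ValidationError(
            "expression has zeros; set outcome_pseudo_count > 0"
        )
    expr_log = bundle.expression.with_values(
        np.log2(shifted), kind="expression_log"
    )
    if config.n_hidden_factors > 0:
        factors = preprocess.estimate_hidden_factors(
            expr_log, covariates, config.n_hidden_factors
        )
        covariates = pd.concat([covariates, factors.scores], axis=1)

    gene_ann = ann[(ann["kind"] == "gene") & (ann["feature_id"] == target_gene)]
    cpg_ann = ann[(ann["kind"] == "cpg") & (ann["feature_id"] == target_cpg)]

    eqtl_cfg = qtl_mod.CisWindowConfig(
        window=config.eqtl_window, maf_min=config.maf_min, B=config.B, seed=config.seed
    )
    mqtl_cfg = qtl_mod.CisWindowConfig(
        window=config.mqtl_window, maf_min=config.maf_min, B=config.B,
        seed=config.seed + 1,
    )
    eqtl_map = qtl_mod.assign_cis_variants(gene_ann, bundle.genotypes, eqtl_cfg)
    mqtl_map = qtl_mod.assign_cis_variants(cpg_ann, bundle.genotypes, mqtl_cfg)
    eqtl_nominal = qtl_mod.map_cis_nominal(
        expr_log, bundle.genotypes, covariates, eqtl_map
    )
    mqtl_nominal = qtl_mod.map_cis_nominal(
        bundle.methylation, bundle.genotypes, covariates, mqtl_map
    )
    eqtl_perm = qtl_mod.permutation_pass(
        expr_log, bundle.genotypes, covariates, eqtl_map, eqtl_cfg, eqtl_nominal
    )
    mqtl_perm = qtl_mod.permutation_pass(
        bundle.methylation, bundle.genotypes, covariates, mqtl_map, mqtl_cfg,
        mqtl_nominal,
    )

    def significant_set(nominal: pd.DataFrame) -> set[str]:
        ok = nominal[nominal["status"] == "ok"]
        if ok.empty:
            return set()
        q = bh_fdr(ok["p"].to_numpy()).q
        return set(ok.loc[q < 0.05, "variant_id"])

    esnps = significant_set(eqtl_nominal)
    msnps = significant_set(mqtl_nominal)

    cov_arr = covariates.to_numpy(float)
    age = bundle.covariates["age"].to_numpy(float)
    m_values = bundle.methylation.data.loc[target_cpg].to_numpy(float)
    y_values = expr_log.data.loc[target_gene].to_numpy(float)
    mediation_age = mediate(
        age, m_values, y_values, cov_arr, n_boot=config.n_boot, seed=config.seed + 2
    )
    best_msnp = (
        mqtl_perm.loc[mqtl_perm["feature_id"] == target_cpg, "best_variant"].iloc[0]
        if (mqtl_perm["status"] == "ok").any()
        else None
    )
    mediation_snp = None
    if best_msnp is not None:
        snp_row = bundle.genotypes.variant_ids.index(best_msnp)
        dosage = bundle.genotypes.dosage[snp_row]
        mediation_snp = mediate(
            dosage, m_values, y_values, cov_arr,
            n_boot=config.n_boot, seed=config.seed + 3,
        )

    report: dict = {
        "target_gene": target_gene,
        "target_cpg": target_cpg,
        "eqtl": eqtl_perm,
        "mqtl": mqtl_perm,
        "eqtl_nominal": eqtl_nominal,
        "mqtl_nominal": mqtl_nominal,
        "esnps": sorted(esnps),
        "msnps": sorted(msnps),
        "esnp_msnp_overlap": sorted(esnps & msnps),
        "mediation_age": mediation_age,
        "mediation_snp": mediation_snp,
        "mr": {},
        "mr_status": "ok",
        "seed": config.seed,
    }

    try:
        instruments = select_instruments(
            mqtl_nominal[mqtl_nominal["feature_id"] == target_cpg],
            bundle.genotypes,
            r2_max=config.r2_max,
            p_max=config.instrument_p_max,
        )
    except ValidationError as exc:
        report["mr_status"] = f"not_run: {exc}"
        return report

    # outcome associations for the same instruments
    outcome_rows = eqtl_nominal.set_index("variant_id")
    by, sey = [], []
    usable = []
    for _, inst in instruments.iterrows():
        vid = inst["variant_id"]
        if vid in outcome_rows.index and outcome_rows.loc[vid, "status"] == "ok":
            usable.append(inst)
            by.append(float(outcome_rows.loc[vid, "beta"]))
            sey.append(float(outcome_rows.loc[vid, "se"]))
    if not usable:
        report["mr_status"] = "not_run: no instrument has outcome statistics"
        return report
    instr = pd.DataFrame(usable).reset_index(drop=True)
    instr["beta_y"] = by
    instr["se_y"] = sey
    report["instruments"] = instr
    report["mr"]["ivw"] = mr_ivw(instr)
    if len(instr) >= 3:
        report["mr"]["weighted_median"] = mr_weighted_median(
            instr, seed=config.seed + 4
        )
        report["mr"]["egger"] = mr_egger(instr)
    return report
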