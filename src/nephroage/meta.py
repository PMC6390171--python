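"""Fixed-effect meta-analysis, FDR control, replication and specificity.

Per-cohort regression summaries are combined with inverse-variance weights
(w_i = 1/SE_i^2, beta_meta = sum(w b)/sum(w), SE_meta = sum(w)^(-1/2)) under
a fixed-effect model; Cochran's Q and I^2 are reported for heterogeneity but
do not gate anything.  False-discovery control is available as
Benjamini-Hochberg step-up q-values or Storey q-values with pi0 estimated on
a lambda grid.  Replication follows the two-part rule: significant within
the replication family's own multiple-testing correction AND concordant in
direction with the discovery effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from nephroage.containers import ValidationError

META_COLUMNS = [
    "feature_id",
    "predictor",
    "beta_meta",
    "se_meta",
    "z",
    "p",
    "n_studies",
    "study_betas",
    "direction_concordant",
    "q_het",
    "i2",
]


def inverse_variance_meta(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance combination of per-study association
    results (as produced by :mod:`nephroage.association`).

    Features are matched on ``(feature_id, predictor)``; studies where a
    feature is missing or has non-finite SE simply do not contribute.
    """
    if not studies:
        raise ValidationError("no studies to combine")
    frames = []
    for i, study in enumerate(studies):
        sub = study[study["status"] == "ok"][["feature_id", "predictor", "beta", "se"]]
        sub = sub.assign(study=i)
        frames.append(sub)
    stacked = pd.concat(frames, ignore_index=True)
    stacked = stacked[np.isfinite(stacked["se"]) & (stacked["se"] > 0)]
    if stacked.empty:
        raise ValidationError("no finite standard errors to combine")
    rows = []
    for (fid, pred), group in stacked.groupby(["feature_id", "predictor"], sort=False):
        w = 1.0 / group["se"].to_numpy() ** 2
        b = group["beta"].to_numpy()
        beta_meta = float(np.sum(w * b) / np.sum(w))
        se_meta = float(np.sum(w) ** -0.5)
        z = beta_meta / se_meta
        p = 2.0 * stats.norm.sf(abs(z))
        q_het = float(np.sum(w * (b - beta_meta) ** 2))
        dof = len(b) - 1
        i2 = float(max(0.0, (q_het - dof) / q_het)) if q_het > 0 and dof > 0 else 0.0
        rows.append(
            (
                fid,
                pred,
                beta_meta,
                se_meta,
                z,
                p,
                len(b),
                list(b),
                bool(len(set(np.sign(b))) <= 1),
                q_het,
                i2,
            )
        )
    return pd.DataFrame(rows, columns=META_COLUMNS)


@dataclass
class FdrResult:
    method: str
    p: np.ndarray
    q: np.ndarray
    pi0: float | None = None
    lambda_grid: np.ndarray | None = None


def bh_fdr(p: np.ndarray | list[float]) -> FdrResult:
    """Benjamini-Hochberg step-up q-values, q_i = min_{j>=rank(i)} p_j m/j."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return FdrResult(method="bh", p=p, q=q)


def estimate_pi0(
    p: np.ndarray, lambda_grid: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Storey's pi0 on a lambda grid with cubic smoothing, evaluated at the
    largest lambda and capped at 1."""
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    m = p.size
    pi0_raw = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in lambda_grid]
    )
    if np.all(pi0_raw == 0):
        warnings.warn(
            "all p-values below the smallest lambda; pi0 set to its lower bound",
            stacklevel=2,
        )
        return 1.0 / m, lambda_grid
    # cubic least-squares smoother over the grid, read off at max lambda
    coefs = np.polyfit(lambda_grid, pi0_raw, deg=3)
    pi0 = float(np.polyval(coefs, lambda_grid.max()))
    pi0 = min(pi0, 1.0)
    pi0 = max(pi0, 1.0 / m)
    return pi0, lambda_grid


def storey_qvalue(
    p: np.ndarray | list[float],
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
) -> FdrResult:
    """Storey q-values: pi0 times the BH step-up quantity.

    A forced ``pi0`` bypasses estimation (used for calibration checks).
    Fewer than ~100 tests give an unstable pi0 and trigger a warning.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if p.size < 100:
        warnings.warn("Storey pi0 is unreliable below ~100 tests", stacklevel=2)
    if pi0 is None:
        pi0, lambda_grid = estimate_pi0(p, lambda_grid)
    q = np.minimum(pi0 * multipletests(p, method="fdr_bh")[1], 1.0)
    return FdrResult(method="storey", p=p, q=q, pi0=pi0, lambda_grid=lambda_grid)


def attach_q(results: pd.DataFrame, method: str = "bh", p_column: str = "p") -> pd.DataFrame:
    """Append a ``q`` column to a result table over its finite p-values."""
    out = results.copy()
    out["q"] = np.nan
    mask = np.isfinite(out[p_column].to_numpy(dtype=float))
    if mask.any():
        pvals = out.loc[mask, p_column].to_numpy(dtype=float)
        fdr = bh_fdr(pvals) if method == "bh" else storey_qvalue(pvals)
        out.loc[mask, "q"] = fdr.q
    return out


REPLICATION_STATUSES = (
    "replicated",
    "not_replicated_direction",
    "not_replicated_q",
    "unavailable",
)


def replication_filter(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    q_threshold: float = 0.05,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Label each discovery feature by the replication outcome.

    ``discovery`` needs ``feature_id`` and ``beta_meta`` (or ``beta``);
    ``replication`` needs ``feature_id``, an effect column and ``p``.  The
    replication q-values are computed within the replication table itself
    (its own multiple-testing family).  A feature replicates iff its
    replication q is below the threshold AND the effect signs agree;
    features absent from the replication table are ``unavailable`` and
    excluded from the replication denominator.
    """
    def effect_col(frame):
        return "beta_meta" if "beta_meta" in frame.columns else "beta"

    rep = replication[np.isfinite(replication["p"].astype(float))].copy()
    rep = attach_q(rep, method=fdr_method)
    rep_lookup = rep.set_index("feature_id")
    rows = []
    for _, row in discovery.iterrows():
        fid = row["feature_id"]
        if fid not in rep_lookup.index:
            rows.append((fid, "unavailable", np.nan, np.nan))
            continue
        rrow = rep_lookup.loc[fid]
        q = float(rrow["q"])
        same_sign = np.sign(row[effect_col(discovery)]) == np.sign(
            rrow[effect_col(rep)]
        )
        if q >= q_threshold:
            status = "not_replicated_q"
        elif not same_sign:
            status = "not_replicated_direction"
        else:
            status = "replicated"
        rows.append((fid, status, float(rrow[effect_col(rep)]), q))
    return pd.DataFrame(
        rows, columns=["feature_id", "status", "replication_beta", "replication_q"]
    )


def replicate_in_families(
    discovery: pd.DataFrame,
    families: dict[str, pd.DataFrame],
    q_threshold: float = 0.05,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Run :func:`replication_filter` per family (e.g. renal cortex and
    medulla as separate multiple-testing families) and take the union:
    a feature replicates if it replicates in any family."""
    per_family = {
        name: replication_filter(discovery, frame, q_threshold, fdr_method)
        for name, frame in families.items()
    }
    rows = []
    for fid in discovery["feature_id"]:
        statuses = {
            name: frame.set_index("feature_id").loc[fid, "status"]
            for name, frame in per_family.items()
        }
        if any(s == "replicated" for s in statuses.values()):
            overall = "replicated"
        elif all(s == "unavailable" for s in statuses.values()):
            overall = "unavailable"
        else:
            overall = "not_replicated"
        rows.append((fid, overall, statuses))
    return pd.DataFrame(rows, columns=["feature_id", "status", "family_status"])


def sensitivity_overlap(
    kidney_features: set[str],
    scenario_tissue_sets: dict[str, dict[str, set[str]]],
    primary_scenario: str,
) -> pd.DataFrame:
    """Tissue-specificity labels for kidney age-associated features.

    ``specific_primary``: absent from every non-renal tissue's significant
    set under the primary scenario; ``specific_all_scenarios``: absent under
    every scenario; otherwise ``ubiquitous``.
    """
    if primary_scenario not in scenario_tissue_sets:
        raise ValidationError(f"unknown primary scenario {primary_scenario!r}")
    rows = []
    for fid in sorted(kidney_features):
        in_primary = any(
            fid in tissue_set
            for tissue_set in scenario_tissue_sets[primary_scenario].values()
        )
        in_any = any(
            fid in tissue_set
            for scenario in scenario_tissue_sets.values()
            for tissue_set in scenario.values()
        )
        if not in_any:
            label = "specific_all_scenarios"
        elif not in_primary:
            label = "specific_primary"
        else:
            label = "ubiquitous"
        rows.append((fid, label, not in_primary, not in_any))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "label", "specific_primary", "specific_all_scenarios"],
    )
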