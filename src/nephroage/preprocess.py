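"""Normalization and latent-structure estimation.

Expression matrices are prepared for association testing by the standard
three-step recipe: ``log2(TPM + pseudo-count)``, quantile normalization
across samples, then a per-feature rank-based inverse normal transformation
(RBINT) with the Blom offset, ``value -> Phi^-1((rank - c) / (n - 2c + 1))``.

Hidden technical structure is estimated by singular value decomposition of
the standardized residual matrix after regressing out known covariates —
a PCA-style latent-factor estimator whose interface (k factors, sample
scores used as covariates) matches how residual-factor methods are used in
expression QTL practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from nephroage.containers import OmicsMatrix, ValidationError, VariantSet


@dataclass
class NormalizationConfig:
    pseudo_count: float = 1.0
    blom_c: float = 0.375

    def validate(self) -> None:
        if self.pseudo_count <= 0:
            raise ValidationError("pseudo_count must be > 0")
        if not (0.0 <= self.blom_c < 0.5):
            raise ValidationError("blom_c must be in [0, 0.5)")


@dataclass
class HiddenFactors:
    """Top-k latent factor scores (samples x k) with variance explained."""

    k: int
    scores: pd.DataFrame  # samples x k, columns factor_1..k
    variance_explained: np.ndarray


def _average_ranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def rank_inverse_normal(values: np.ndarray, c: float = 0.375) -> np.ndarray:
    """Blom-offset RBINT of one vector; ties share their average rank.

    A constant vector maps to all zeros (degenerate; callers should exclude
    such features downstream)."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0.0:
        warnings.warn("constant feature mapped to zeros by RBINT", stacklevel=2)
        return np.zeros_like(values)
    n = values.size
    ranks = _average_ranks(values)
    return stats.norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile normalization across samples (columns) of a features x
    samples matrix: each column's sorted values are replaced by the
    cross-sample means at each rank; ties receive the average of their
    would-be rank means."""
    n_features, _ = values.shape
    order = np.argsort(values, axis=0, kind="mergesort")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        ranks = _average_ranks(values[:, j])  # 1..n, ties averaged
        # interpolate rank means at (possibly fractional) average ranks
        out[:, j] = np.interp(ranks, np.arange(1, n_features + 1), rank_means)
    return out


def log_quantile_rbint(
    matrix: OmicsMatrix, config: NormalizationConfig | None = None
) -> OmicsMatrix:
    """log2(TPM + pseudo-count) -> quantile normalization -> per-feature
    RBINT.  Output features have mean ~0 and unit-normal marginals."""
    config = config or NormalizationConfig()
    config.validate()
    if matrix.kind != "expression_tpm":
        raise ValidationError(
            f"log_quantile_rbint expects expression_tpm, got {matrix.kind}"
        )
    if matrix.n_samples < 3:
        raise ValidationError("need at least 3 samples to normalize")
    logged = np.log2(matrix.values + config.pseudo_count)
    qn = quantile_normalize(logged)
    out = np.vstack([rank_inverse_normal(row, config.blom_c) for row in qn])
    return matrix.with_values(out, kind="normalized")


def residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Project each row of a features x samples matrix off the column space
    of [1, covariates]."""
    n = values.shape[1]
    design = np.ones((n, 1))
    if covariates is not None and covariates.size:
        design = np.column_stack([design, covariates])
    coef, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    return values - (design @ coef).T


def estimate_hidden_factors(
    matrix: OmicsMatrix,
    covariates: pd.DataFrame | None,
    k: int,
) -> HiddenFactors:
    """SVD-based latent factors of the covariate-residualized, per-feature
    standardized matrix.  Scores are the top-k right singular vectors
    (orthonormal over samples)."""
    if k <= 0:
        raise ValidationError("k must be positive")
    if k >= min(matrix.n_features, matrix.n_samples):
        raise ValidationError("k must be < min(features, samples)")
    cov = None
    if covariates is not None and covariates.shape[1]:
        cov = covariates.loc[matrix.sample_ids].to_numpy(dtype=float)
    resid = residualize(matrix.values, cov)
    sd = resid.std(axis=1, ddof=1)
    keep = sd > 0
    standardized = resid[keep] / sd[keep, None]
    _, singular, vt = np.linalg.svd(standardized, full_matrices=False)
    scores = pd.DataFrame(
        vt[:k].T,
        index=matrix.sample_ids,
        columns=[f"factor_{i + 1}" for i in range(k)],
    )
    variance = singular**2 / np.sum(singular**2)
    return HiddenFactors(k=k, scores=scores, variance_explained=variance[:k])


def compute_genotype_pcs(variants: VariantSet, n_pcs: int = 3) -> pd.DataFrame:
    """Principal component scores of the centered, variance-scaled dosage
    matrix (population-structure covariates; top 3 by default)."""
    maf = variants.maf()
    poly = np.isfinite(maf) & (maf > 0)
    if poly.sum() < n_pcs:
        raise ValidationError(
            f"need at least {n_pcs} polymorphic variants, have {int(poly.sum())}"
        )
    dosage = variants.dosage[poly]
    # mean-impute the (rare) missing entries before decomposition
    col_mean = np.nanmean(dosage, axis=1, keepdims=True)
    filled = np.where(np.isnan(dosage), col_mean, dosage)
    centered = filled - filled.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, ddof=1)
    scaled = centered[sd > 0] / sd[sd > 0, None]
    u, s, vt = np.linalg.svd(scaled, full_matrices=False)
    scores = (vt[:n_pcs] * s[:n_pcs, None]).T
    return pd.DataFrame(
        scores,
        index=variants.sample_ids,
        columns=[f"pc{i + 1}" for i in range(n_pcs)],
    )


def methylation_to_mvalue(matrix: OmicsMatrix, eps: float = 1e-6) -> OmicsMatrix:
    """Beta -> M-value transform, M = log2(m / (1 - m)), with beta values
    clamped to [eps, 1 - eps]."""
    if matrix.kind != "methylation_beta":
        raise ValidationError("methylation_to_mvalue expects methylation_beta")
    beta = np.clip(matrix.values, eps, 1.0 - eps)
    return matrix.with_values(np.log2(beta / (1.0 - beta)), kind="methylation_mvalue")


def mvalue_to_beta(matrix: OmicsMatrix) -> OmicsMatrix:
    m = matrix.values
    return matrix.with_values(2.0**m / (1.0 + 2.0**m), kind="methylation_beta")
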