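"""Synthetic multi-omic cohort generator.

Generates genotype, CpG-methylation and gene-expression data for a cohort
under a configurable linear-Gaussian causal graph:

* dosages are Hardy-Weinberg draws with first-order haplotype-copying LD
  inside blocks (an allele is copied from the previous variant with
  probability ``ld_decay``, else drawn fresh at that variant's MAF),
* logit-methylation is linear in age, sex, assigned SNP dosages and hidden
  factors, returned on the beta scale through the inverse logit,
* log2-expression is linear in methylation (beta scale), dosages, age, sex
  and hidden factors, returned on a TPM-like scale via ``2**x``; most genes
  carry no effect and form the null background,
* optional traits: eGFR declining linearly in age, and ordinal 0-3
  histology scores obtained by thresholding a latent Gaussian score at
  fixed cumulative proportions.

Effects are declared as ``(source, target, size)`` triples where sources are
``"age"``, ``"sex"``, ``"variant:<id>"``, ``"cpg:<id>"`` or ``"gene:<id>"``
and targets are ``"cpg:<id>"``, ``"gene:<id>"`` or ``"trait:<name>"``.
Effect sizes are on the transformed analysis scales (logit methylation,
log2 expression), so downstream linear estimators are consistent for the
recorded truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from nephroage.containers import (
    ANNOTATION_COLUMNS,
    OmicsMatrix,
    ValidationError,
    VariantSet,
)

HISTOLOGY_TRAITS = (
    "glomerulosclerosis",
    "interstitial_fibrosis",
    "tubular_atrophy",
    "arterial_narrowing",
)

# cumulative proportions of Remuzzi grades 0..2 (grade 3 takes the rest),
# mirroring the discovery cohort's 0/1/2/3 histology counts
_HISTOLOGY_CUTS = {
    "glomerulosclerosis": (0.383, 0.916, 1.0),
    "interstitial_fibrosis": (0.455, 0.909, 1.0),
    "tubular_atrophy": (0.435, 0.883, 0.994),
    "arterial_narrowing": (0.097, 0.708, 0.961),
}


class ConfigurationError(ValueError):
    """Raised when cohort parameters are inconsistent."""


@dataclass(frozen=True)
class Effect:
    """One directed edge of the generative graph, on the transformed scale."""

    source: str
    target: str
    size: float


@dataclass
class TraitSpec:
    """Generative coefficients for eGFR and histology scores.

    eGFR is in ml/min per 1.73 m^2; the default slope reproduces the
    canonical decline of ~8 ml/min per decade from mid-life onward.
    Histology latent scores rise with age and are cut at fixed cumulative
    proportions to give a 0-3 ordinal grade.
    """

    egfr_intercept: float = 120.0
    egfr_age_slope: float = -0.8
    egfr_noise_sd: float = 12.0
    histology_age_coef: float = 0.05
    histology_noise_sd: float = 1.0


@dataclass
class CohortParams:
    """Full parameterization of one synthetic cohort."""

    n_samples: int = 260
    age_range: tuple[float, float] = (28.0, 87.0)
    sex_fraction: float = 0.65
    n_genes: int = 200
    n_cpgs: int = 20
    n_variants: int = 60
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_decay: float = 0.3
    n_hidden_factors: int = 2
    effects: list[Effect] = field(default_factory=list)
    noise_sd_expression: float = 0.5
    noise_sd_methylation: float = 0.5
    trait_spec: TraitSpec | None = None
    seed: int = 0
    # cohorts that should share feature-level baselines (intercepts, factor
    # loadings, MAFs) while drawing independent samples set a common
    # biology_seed and distinct seeds; None ties biology to ``seed``
    biology_seed: int | None = None
    # feature-level baselines; zero-variance settings give the degenerate
    # configurations used in contract tests
    gene_intercept_mean: float = 4.0
    gene_intercept_sd: float = 1.0
    cpg_intercept_mean: float = -1.0
    cpg_intercept_sd: float = 0.5
    hf_loading_sd_expression: float = 0.3
    hf_loading_sd_methylation: float = 0.15
    sample_prefix: str = "S"

    # ---- layout ----------------------------------------------------------
    def gene_ids(self) -> list[str]:
        return [f"gene_{i:04d}" for i in range(self.n_genes)]

    def cpg_ids(self) -> list[str]:
        return [f"cpg_{i:04d}" for i in range(self.n_cpgs)]

    def variant_ids(self) -> list[str]:
        return [f"rs{i:06d}" for i in range(self.n_variants)]

    def sample_ids(self) -> list[str]:
        return [f"{self.sample_prefix}{i:04d}" for i in range(self.n_samples)]

    def gene_span(self, i: int) -> tuple[int, int]:
        start = 1_000_000 + i * 200_000
        return start, start + 10_000

    def cpg_position(self, j: int) -> int:
        gene = j % self.n_genes
        tier = j // self.n_genes
        return self.gene_span(gene)[0] - 200 - 50 * tier

    def variant_position(self, v: int) -> int:
        block = v // self.ld_block_size
        within = v % self.ld_block_size
        gene = block % self.n_genes
        tier = block // self.n_genes
        return self.gene_span(gene)[0] - 15_000 + tier * 8_000 + within * 500

    def annotations(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.gene_ids()):
            start, end = self.gene_span(i)
            rows.append((g, "chr1", start, end, "+", "gene"))
        for j, c in enumerate(self.cpg_ids()):
            pos = self.cpg_position(j)
            rows.append((c, "chr1", pos, pos + 1, ".", "cpg"))
        for v, r in enumerate(self.variant_ids()):
            pos = self.variant_position(v)
            rows.append((r, "chr1", pos, pos + 1, ".", "variant"))
        frame = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
        var = frame[frame["kind"] == "variant"]
        if var["start"].duplicated().any():
            raise ConfigurationError(
                "variant layout produced colliding positions; reduce "
                "ld_block_size or n_variants per gene"
            )
        return frame

    # ---- validation ------------------------------------------------------
    def validate(self) -> None:
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ConfigurationError(
                f"maf_range must lie within (0, 0.5], got {self.maf_range}"
            )
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.noise_sd_expression < 0 or self.noise_sd_methylation < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ConfigurationError("ld_decay must be in [0, 1)")
        if not (0.0 <= self.sex_fraction <= 1.0):
            raise ConfigurationError("sex_fraction must be a probability")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must be (low, high) with low < high")
        declared = {
            "gene": set(self.gene_ids()),
            "cpg": set(self.cpg_ids()),
            "variant": set(self.variant_ids()),
        }
        for eff in self.effects:
            self._check_node(eff.source, declared, role="source")
            self._check_node(eff.target, declared, role="target")

    @staticmethod
    def _check_node(node: str, declared: dict, role: str) -> None:
        if node in ("age", "sex"):
            if role == "target":
                raise ConfigurationError(f"{node!r} cannot be an effect target")
            return
        if ":" not in node:
            raise ConfigurationError(f"malformed effect {role} {node!r}")
        kind, name = node.split(":", 1)
        if kind == "trait":
            if role == "source":
                raise ConfigurationError("traits cannot be effect sources")
            if name != "egfr" and name not in HISTOLOGY_TRAITS:
                raise ConfigurationError(f"unknown trait {name!r}")
            return
        if kind not in declared or name not in declared[kind]:
            raise ConfigurationError(
                f"effect {role} {node!r} references an undeclared feature"
            )


@dataclass
class CohortBundle:
    """All components of one simulated cohort, sample-aligned by construction."""

    expression: OmicsMatrix
    methylation: OmicsMatrix
    genotypes: VariantSet
    covariates: pd.DataFrame
    annotations: pd.DataFrame
    truth: dict

    def save(self, outdir) -> None:
        from pathlib import Path

        from nephroage import io as nio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nio.write_matrix(self.expression, outdir / "expression_tpm.tsv")
        nio.write_matrix(self.methylation, outdir / "methylation_beta.tsv")
        nio.write_vcf(self.genotypes, outdir / "genotypes.vcf")
        nio.write_sample_table(self.covariates, outdir / "covariates.tsv")
        for kind in ("gene", "cpg", "variant"):
            sub = self.annotations[self.annotations["kind"] == kind]
            nio.write_bed(sub, outdir / f"{kind}s.bed")
        with open(outdir / "truth.json", "w") as handle:
            json.dump(self.truth, handle, indent=2)


# ---------------------------------------------------------------------------
# component simulators


def _rng(params: CohortParams, stream: int) -> np.random.Generator:
    """Per-sample randomness (ages, haplotypes, noise)."""
    return np.random.default_rng([params.seed, stream])


def _bio_rng(params: CohortParams, stream: int) -> np.random.Generator:
    """Feature-level randomness (intercepts, loadings, MAFs) shared across
    cohorts that declare the same biology_seed."""
    bio = params.seed if params.biology_seed is None else params.biology_seed
    return np.random.default_rng([bio, 100 + stream])


def simulate_covariates(params: CohortParams) -> pd.DataFrame:
    """Sample table: age (years, uniform over the cohort range), sex
    (1 = male), and standard-normal hidden technical factors ``hf_1..k``."""
    params.validate()
    rng = _rng(params, 0)
    n = params.n_samples
    table = {
        "age": rng.uniform(*params.age_range, size=n),
        "sex": (rng.random(n) < params.sex_fraction).astype(float),
    }
    for k in range(params.n_hidden_factors):
        table[f"hf_{k + 1}"] = rng.standard_normal(n)
    return pd.DataFrame(table, index=params.sample_ids())


def simulate_genotypes(params: CohortParams) -> VariantSet:
    """Hardy-Weinberg dosages with block LD by first-order haplotype copying."""
    params.validate()
    rng = _rng(params, 1)
    n, v = params.n_samples, params.n_variants
    mafs = _bio_rng(params, 1).uniform(
        params.maf_range[0], params.maf_range[1], size=v
    )
    haplotypes = np.zeros((2, v, n), dtype=np.int8)
    for j in range(v):
        fresh = (rng.random((2, n)) < mafs[j]).astype(np.int8)
        if j % params.ld_block_size == 0:
            haplotypes[:, j] = fresh
        else:
            copy = rng.random((2, n)) < params.ld_decay
            haplotypes[:, j] = np.where(copy, haplotypes[:, j - 1], fresh)
    dosage = haplotypes.sum(axis=0).astype(float)
    ann = params.annotations()
    variants = ann[ann["kind"] == "variant"].reset_index(drop=True)
    vs = VariantSet(variants, dosage, params.sample_ids())
    vs.true_maf = mafs  # recorded for the truth ledger
    return vs


def _centered_source_values(*args, **kwargs) -> np.ndarray:
    """Effect sources enter centered at their sample mean, so declared
    intercepts stay the population means and effect sizes are slopes."""
    values = _source_values(*args, **kwargs)
    return values - values.mean()


def _source_values(
    source: str,
    covariates: pd.DataFrame,
    genotypes: VariantSet | None,
    methylation: OmicsMatrix | None,
    expression_log: pd.DataFrame | None = None,
) -> np.ndarray:
    if source in ("age", "sex"):
        return covariates[source].to_numpy()
    kind, name = source.split(":", 1)
    if kind == "variant":
        if genotypes is None:
            raise ConfigurationError("variant effect requires genotypes")
        idx = genotypes.variant_ids.index(name)
        return genotypes.dosage[idx]
    if kind == "cpg":
        if methylation is None:
            raise ConfigurationError("cpg effect requires methylation")
        return methylation.data.loc[name].to_numpy()
    if kind == "gene":
        if expression_log is None:
            raise ConfigurationError("gene effect requires expression")
        return expression_log.loc[name].to_numpy()
    raise ConfigurationError(f"unknown effect source {source!r}")


def simulate_methylation(
    genotypes: VariantSet,
    covariates: pd.DataFrame,
    params: CohortParams,
) -> OmicsMatrix:
    """Beta-value methylation matrix from the linear logit model."""
    params.validate()
    if list(covariates.index) != genotypes.sample_ids:
        raise ConfigurationError("covariates and genotypes are not sample-aligned")
    rng = _rng(params, 2)
    bio = _bio_rng(params, 2)
    n, m = params.n_samples, params.n_cpgs
    cpgs = params.cpg_ids()
    logit = np.tile(
        bio.normal(params.cpg_intercept_mean, params.cpg_intercept_sd, size=m)[:, None],
        (1, n),
    )
    for k in range(params.n_hidden_factors):
        loadings = bio.normal(0.0, params.hf_loading_sd_methylation, size=m)
        logit += loadings[:, None] * covariates[f"hf_{k + 1}"].to_numpy()[None, :]
    index = {c: i for i, c in enumerate(cpgs)}
    for eff in params.effects:
        if not eff.target.startswith("cpg:"):
            continue
        row = index[eff.target.split(":", 1)[1]]
        logit[row] += eff.size * _centered_source_values(eff.source, covariates, genotypes, None)
    logit += rng.normal(0.0, params.noise_sd_methylation, size=(m, n))
    beta = 1.0 / (1.0 + np.exp(-logit))
    frame = pd.DataFrame(beta, index=cpgs, columns=genotypes.sample_ids)
    return OmicsMatrix(frame, "methylation_beta")


def simulate_expression(
    methylation: OmicsMatrix,
    genotypes: VariantSet,
    covariates: pd.DataFrame,
    params: CohortParams,
) -> OmicsMatrix:
    """TPM-like expression from the linear log2 model (null background for
    genes with no declared effect)."""
    params.validate()
    if methylation.sample_ids != genotypes.sample_ids:
        raise ConfigurationError("methylation and genotypes are not sample-aligned")
    rng = _rng(params, 3)
    bio = _bio_rng(params, 3)
    n, g = params.n_samples, params.n_genes
    genes = params.gene_ids()
    log2x = np.tile(
        bio.normal(params.gene_intercept_mean, params.gene_intercept_sd, size=g)[:, None],
        (1, n),
    )
    for k in range(params.n_hidden_factors):
        loadings = bio.normal(0.0, params.hf_loading_sd_expression, size=g)
        log2x += loadings[:, None] * covariates[f"hf_{k + 1}"].to_numpy()[None, :]
    index = {gid: i for i, gid in enumerate(genes)}
    for eff in params.effects:
        if not eff.target.startswith("gene:"):
            continue
        row = index[eff.target.split(":", 1)[1]]
        log2x[row] += eff.size * _centered_source_values(
            eff.source, covariates, genotypes, methylation
        )
    log2x += rng.normal(0.0, params.noise_sd_expression, size=(g, n))
    frame = pd.DataFrame(2.0 ** log2x, index=genes, columns=genotypes.sample_ids)
    return OmicsMatrix(frame, "expression_tpm")


def simulate_traits(
    covariates: pd.DataFrame,
    expression: OmicsMatrix,
    params: CohortParams,
) -> pd.DataFrame:
    """eGFR and ordinal histology grades; grades come from age-driven latent
    scores cut at the fixed cumulative proportions of a 0-3 Remuzzi-like
    distribution."""
    spec = params.trait_spec or TraitSpec()
    rng = _rng(params, 4)
    n = len(covariates)
    age = covariates["age"].to_numpy()
    log2x = np.log2(expression.values + 1.0)

    def extra(trait: str) -> np.ndarray:
        total = np.zeros(n)
        for eff in params.effects:
            if eff.target != f"trait:{trait}":
                continue
            total += eff.size * _centered_source_values(
                eff.source, covariates, None, None, expression_log=pd.DataFrame(
                    log2x, index=expression.feature_ids, columns=expression.sample_ids
                )
            )
        return total

    out = pd.DataFrame(index=covariates.index)
    out["egfr"] = (
        spec.egfr_intercept
        + spec.egfr_age_slope * age
        + extra("egfr")
        + rng.normal(0.0, spec.egfr_noise_sd, size=n)
    )
    for trait in HISTOLOGY_TRAITS:
        latent = (
            spec.histology_age_coef * age
            + extra(trait)
            + rng.normal(0.0, spec.histology_noise_sd, size=n)
        )
        cuts = np.quantile(latent, _HISTOLOGY_CUTS[trait])
        out[trait] = np.searchsorted(cuts, latent, side="left").astype(int)
    return out


def simulate_cohort(params: CohortParams, with_traits: bool = False) -> CohortBundle:
    """Compose genotypes, methylation, expression (and optional traits)
    into a sample-aligned bundle with a truth record."""
    params.validate()
    covariates = simulate_covariates(params)
    genotypes = simulate_genotypes(params)
    methylation = simulate_methylation(genotypes, covariates, params)
    expression = simulate_expression(methylation, genotypes, covariates, params)
    if with_traits or params.trait_spec is not None:
        traits = simulate_traits(covariates, expression, params)
        covariates = pd.concat([covariates, traits], axis=1)
    truth = {
        "seed": params.seed,
        "effects": [asdict(e) for e in params.effects],
        "noise_sd_expression": params.noise_sd_expression,
        "noise_sd_methylation": params.noise_sd_methylation,
        "n_hidden_factors": params.n_hidden_factors,
        "true_maf": [float(x) for x in genotypes.true_maf],
        "trait_spec": asdict(params.trait_spec) if params.trait_spec else None,
    }
    return CohortBundle(
        expression=expression,
        methylation=methylation,
        genotypes=genotypes,
        covariates=covariates,
        annotations=params.annotations(),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# canonical scenarios


def promoter_methylation_scenario(
    n_samples: int = 260,
    seed: int = 0,
    n_genes: int = 150,
    cpg_gene_effect: float = -3.0,
    age_cpg_effect: float = 0.08,
    snp_cpg_effects: tuple[float, ...] = (0.8, 0.7, 0.9, 0.6, 0.75, 0.85),
    ld_block_size: int = 3,
    ld_decay: float = 0.4,
    **overrides,
) -> CohortParams:
    """Cohort in which one gene's age-related expression decline is driven
    by promoter hypermethylation that is itself under genetic control.

    Gene ``gene_0000`` receives no direct age or SNP effect: age raises
    methylation of ``cpg_0000`` (promoter CpG), independent SNPs near the
    CpG shift its methylation, and the CpG represses the gene.  This is the
    planted ground truth for the end-to-end mediation / Mendelian
    randomization demonstration.
    """
    n_instruments = len(snp_cpg_effects)
    n_variants = n_genes * ld_block_size * n_instruments
    params = CohortParams(
        n_samples=n_samples,
        n_genes=n_genes,
        n_cpgs=max(10, n_genes // 4),
        n_variants=n_variants,
        ld_block_size=ld_block_size,
        ld_decay=ld_decay,
        seed=seed,
        **overrides,
    )
    # one instrument SNP per tier-block anchored at gene 0; blocks are
    # independent, so the instruments are mutually unlinked
    effects = [Effect("age", "cpg:cpg_0000", age_cpg_effect)]
    for tier, size in enumerate(snp_cpg_effects):
        variant_index = tier * n_genes * ld_block_size  # first variant of block
        effects.append(
            Effect(f"variant:rs{variant_index:06d}", "cpg:cpg_0000", size)
        )
    effects.append(Effect("cpg:cpg_0000", "gene:gene_0000", cpg_gene_effect))
    params.effects = effects
    params.validate()
    return params


def concat_cohorts(*bundles: CohortBundle) -> CohortBundle:
    """Column-concatenate cohorts that share the same feature layout (same
    biology_seed); sample ids must be disjoint.  A ``cohort`` indicator
    column is added to the covariates."""
    first = bundles[0]
    ids: set[str] = set()
    for b in bundles:
        overlap = ids & set(b.expression.sample_ids)
        if overlap:
            raise ConfigurationError(
                f"cohorts share sample ids (e.g. {sorted(overlap)[0]!r}); "
                "use distinct sample_prefix values"
            )
        ids |= set(b.expression.sample_ids)
        if b.expression.feature_ids != first.expression.feature_ids:
            raise ConfigurationError("cohorts have different gene layouts")
    expr = OmicsMatrix(
        pd.concat([b.expression.data for b in bundles], axis=1), "expression_tpm"
    )
    meth = OmicsMatrix(
        pd.concat([b.methylation.data for b in bundles], axis=1), "methylation_beta"
    )
    geno = VariantSet(
        first.genotypes.annotations,
        np.concatenate([b.genotypes.dosage for b in bundles], axis=1),
        [s for b in bundles for s in b.genotypes.sample_ids],
        ref=first.genotypes.ref,
        alt=first.genotypes.alt,
    )
    cov_frames = []
    for i, b in enumerate(bundles):
        frame = b.covariates.copy()
        frame["cohort"] = i
        cov_frames.append(frame)
    covariates = pd.concat(cov_frames, axis=0)
    return CohortBundle(
        expression=expr,
        methylation=meth,
        genotypes=geno,
        covariates=covariates,
        annotations=first.annotations,
        truth=first.truth,
    )


def scenario_instrument_ids(params: CohortParams) -> list[str]:
    """Variant ids of the planted methylation instruments in a scenario
    built by :func:`promoter_methylation_scenario`."""
    return sorted(
        {
            e.source.split(":", 1)[1]
            for e in params.effects
            if e.source.startswith("variant:") and e.target.startswith("cpg:")
        }
    )
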