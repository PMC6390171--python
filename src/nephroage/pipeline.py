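"""Configuration-driven orchestration of the full analysis.

A YAML config describes one run: either simulate cohorts (discovery pair,
replication families, non-renal comparison tissues) from a named scenario,
or point at on-disk matrices; then normalize, run per-cohort age
associations, meta-analyze, control FDR, apply the replication and
tissue-specificity logic, map cis-eQTL/mQTL with permutations, and finish
with mediation and Mendelian randomization for the configured gene-CpG
target.  Every stage output is a TSV stamped with the config hash and seed;
a JSONL event log records per-stage feature counts.  Identical config +
seeds give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nephroage import association, causal, meta, preprocess, qtl as qtl_mod
from nephroage.containers import ValidationError
from nephroage.simulate import (
    CohortBundle,
    TraitSpec,
    concat_cohorts,
    promoter_methylation_scenario,
    simulate_cohort,
)

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {
        "scenario": "promoter_methylation",
        "n_genes": 150,
        "discovery_sizes": [160, 100],
        "replication_families": {"cortex": 150, "medulla": 150},
        "tissue_scenarios": {"primary": 2, "alternative": 3},
        "n_tissues": 2,
        "tissue_size": 120,
        "target_gene": "gene_0000",
        "target_cpg": "cpg_0000",
        "with_traits": True,
    },
    "preprocess": {
        "pseudo_count": 1.0,
        "blom_c": 0.375,
        "n_hidden_factors": 2,
        "n_genotype_pcs": 3,
    },
    "fdr": {"method": "bh", "threshold": 0.05},
    "replication": {"q_threshold": 0.05},
    "qtl": {
        "eqtl_window": 1_000_000,
        "mqtl_window": 33_172,
        "B": 1000,
        "maf_min": 0.05,
        "seed": 11,
    },
    "mediation": {"n_boot": 999, "seed": 12},
    "mr": {"r2_max": 0.1, "p_max": None, "seed": 13},
}


def load_config(path: str | Path) -> dict:
    with open(path) as handle:
        return yaml.safe_load(handle)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def validate_config(config: dict) -> list[str]:
    """Schema / range / cross-stage checks; returns a list of error strings
    (empty when valid)."""
    errors: list[str] = []
    known = set(DEFAULT_CONFIG) | {"inputs", "output_dir"}
    for key in config:
        if key not in known:
            errors.append(f"unknown stage {key!r}")
    if "seed" not in config:
        errors.append("missing top-level key 'seed'")
    fdr = config.get("fdr", {})
    threshold = fdr.get("threshold", 0.05)
    if not (0.0 < threshold < 1.0):
        errors.append(f"fdr.threshold must be in (0, 1), got {threshold}")
    if fdr.get("method", "bh") not in ("bh", "storey"):
        errors.append("fdr.method must be 'bh' or 'storey'")
    qtl_cfg = config.get("qtl", {})
    for key in ("eqtl_window", "mqtl_window"):
        if qtl_cfg.get(key, 0) < 0:
            errors.append(f"qtl.{key} must be >= 0, got {qtl_cfg[key]}")
    if qtl_cfg.get("B", 1) < 1:
        errors.append("qtl.B must be >= 1")
    for stage in ("qtl", "mediation", "mr"):
        if stage in config and "seed" not in config[stage]:
            errors.append(f"missing key {stage}.seed (stochastic stage)")
    repl = config.get("replication", {})
    if not (0.0 < repl.get("q_threshold", 0.05) < 1.0):
        errors.append("replication.q_threshold must be in (0, 1)")
    med = config.get("mediation", {})
    if med.get("n_boot", 999) < 199:
        errors.append("mediation.n_boot must be >= 199")
    sim = config.get("simulate")
    if sim is None and "inputs" not in config:
        errors.append("either 'simulate' or 'inputs' must be present")
    if "inputs" in config:
        for key, path in config["inputs"].items():
            if not Path(path).exists():
                errors.append(f"inputs.{key}: path {path!r} does not exist")
    return errors


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            out[key] = _merge(base[key], value)
        else:
            out[key] = value
    return out


class Pipeline:
    """One configured run; ``run()`` executes stages in dependency order."""

    def __init__(self, config: dict, outdir: str | Path):
        self.config = _merge(DEFAULT_CONFIG, config)
        errors = validate_config(self.config)
        if errors:
            raise ValidationError("invalid config: " + "; ".join(errors))
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.hash = config_hash(self.config)
        self._log_path = self.outdir / "events.jsonl"
        self.results: dict = {}

    # -- plumbing ---------------------------------------------------------
    def _log(self, stage: str, **fields) -> None:
        event = {"stage": stage, **fields}
        with open(self._log_path, "a") as handle:
            handle.write(json.dumps(event, default=str) + "\n")

    def _write(self, name: str, frame: pd.DataFrame) -> None:
        path = self.outdir / f"{name}.tsv"
        with open(path, "w") as handle:
            handle.write(
                f"# config_hash={self.hash} seed={self.config['seed']}\n"
            )
            frame.to_csv(handle, sep="\t", index=False, float_format="%.10g")

    # -- cohorts ----------------------------------------------------------
    def _scenario_params(self, n_samples, seed, prefix, **overrides):
        sim = self.config["simulate"]
        if sim["scenario"] != "promoter_methylation":
            raise ValidationError(f"unknown scenario {sim['scenario']!r}")
        params = promoter_methylation_scenario(
            n_samples=n_samples,
            seed=seed,
            n_genes=sim["n_genes"],
            sample_prefix=prefix,
            **overrides,
        )
        params.biology_seed = self.config["seed"]
        if sim.get("with_traits"):
            params.trait_spec = TraitSpec()
        return params

    def simulate(self) -> None:
        sim = self.config["simulate"]
        base = self.config["seed"]
        discovery = []
        for i, n in enumerate(sim["discovery_sizes"]):
            params = self._scenario_params(n, base * 1000 + i, f"D{i}_")
            discovery.append(simulate_cohort(params, with_traits=True))
        replication = {}
        for j, (family, n) in enumerate(sim["replication_families"].items()):
            params = self._scenario_params(n, base * 1000 + 100 + j, f"R{j}_")
            replication[family] = simulate_cohort(params)
        # non-renal tissues: same layout, no planted effects on the target
        tissues: dict[str, dict[str, CohortBundle]] = {}
        for s, (scenario, _k) in enumerate(sim["tissue_scenarios"].items()):
            tissues[scenario] = {}
            for t in range(sim["n_tissues"]):
                params = self._scenario_params(
                    sim["tissue_size"], base * 1000 + 200 + 10 * s + t, f"T{s}{t}_"
                )
                params.effects = []  # null tissues: age does not act there
                tissues[scenario][f"tissue_{t}"] = simulate_cohort(params)
        self.results["discovery"] = discovery
        self.results["replication"] = replication
        self.results["tissues"] = tissues
        self.results["combined_discovery"] = concat_cohorts(*discovery)
        self._log(
            "simulate",
            discovery_sizes=[b.expression.n_samples for b in discovery],
            replication={f: b.expression.n_samples for f, b in replication.items()},
        )

    # -- per-cohort association ------------------------------------------
    def _cohort_age_scan(self, bundle: CohortBundle, k: int | None = None) -> pd.DataFrame:
        pp = self.config["preprocess"]
        norm = preprocess.log_quantile_rbint(
            bundle.expression,
            preprocess.NormalizationConfig(pp["pseudo_count"], pp["blom_c"]),
        )
        covs = [bundle.covariates[["sex"]]]
        covs.append(
            preprocess.compute_genotype_pcs(bundle.genotypes, pp["n_genotype_pcs"])
        )
        k = pp["n_hidden_factors"] if k is None else k
        if k > 0:
            factors = preprocess.estimate_hidden_factors(
                norm, pd.concat(covs, axis=1), k
            )
            covs.append(factors.scores)
        covariates = pd.concat(covs, axis=1)
        return association.fit_feature_associations(
            norm, bundle.covariates["age"], covariates, "age"
        )

    def discover(self) -> None:
        fdr_cfg = self.config["fdr"]
        studies = [self._cohort_age_scan(b) for b in self.results["discovery"]]
        for i, study in enumerate(studies):
            self._write(f"discovery_cohort{i}_age", study)
        combined = meta.inverse_variance_meta(studies)
        combined = meta.attach_q(combined, method=fdr_cfg["method"])
        self._write("discovery_meta_age", combined.drop(columns=["study_betas"]))
        significant = combined[combined["q"] < fdr_cfg["threshold"]]
        self.results["meta_age"] = combined
        self.results["age_genes"] = list(significant["feature_id"])
        self._log(
            "discovery",
            n_features=len(combined),
            n_significant=len(significant),
        )

    def replicate(self) -> None:
        discovery = self.results["meta_age"]
        hits = discovery[discovery["feature_id"].isin(self.results["age_genes"])]
        families = {
            name: meta.attach_q(self._cohort_age_scan(bundle))
            for name, bundle in self.results["replication"].items()
        }
        outcome = meta.replicate_in_families(
            hits,
            families,
            q_threshold=self.config["replication"]["q_threshold"],
            fdr_method=self.config["fdr"]["method"],
        )
        self._write(
            "replication", outcome.assign(family_status=outcome["family_status"].astype(str))
        )
        self.results["replicated_genes"] = list(
            outcome.loc[outcome["status"] == "replicated", "feature_id"]
        )
        self._log("replication", n_replicated=len(self.results["replicated_genes"]))

    def specificity(self) -> None:
        sim = self.config["simulate"]
        fdr_cfg = self.config["fdr"]
        scenario_sets: dict[str, dict[str, set]] = {}
        for scenario, k in sim["tissue_scenarios"].items():
            scenario_sets[scenario] = {}
            for tissue, bundle in self.results["tissues"][scenario].items():
                scan = meta.attach_q(
                    self._cohort_age_scan(bundle, k=k), method=fdr_cfg["method"]
                )
                scenario_sets[scenario][tissue] = set(
                    scan.loc[scan["q"] < fdr_cfg["threshold"], "feature_id"]
                )
        labels = meta.sensitivity_overlap(
            set(self.results["replicated_genes"]),
            scenario_sets,
            primary_scenario=next(iter(sim["tissue_scenarios"])),
        )
        self._write("specificity", labels)
        self.results["specificity"] = labels
        self._log("specificity", n_features=len(labels))

    def traits(self) -> None:
        bundle = self.results["discovery"][0]  # traits live in the first cohort
        trait_cols = [
            c for c in bundle.covariates.columns
            if c in ("egfr", "glomerulosclerosis", "interstitial_fibrosis",
                     "tubular_atrophy", "arterial_narrowing")
        ]
        if not trait_cols:
            return
        pp = self.config["preprocess"]
        norm = preprocess.log_quantile_rbint(bundle.expression)
        pcs = preprocess.compute_genotype_pcs(bundle.genotypes, pp["n_genotype_pcs"])
        covariates = pd.concat([bundle.covariates[["sex"]], pcs], axis=1)
        scan = association.trait_association_scan(
            norm, bundle.covariates[trait_cols], covariates
        )
        adjusted = association.trait_association_scan(
            norm, bundle.covariates[trait_cols], covariates,
            adjust_age=True, age=bundle.covariates["age"],
        )
        self._write("trait_associations", scan)
        self._write("trait_associations_age_adjusted", adjusted)
        self.results["trait_scan"] = scan
        self.results["trait_scan_age_adjusted"] = adjusted
        self._log("traits", n_tests=len(scan))

    def qtl_and_causal(self) -> None:
        sim = self.config["simulate"]
        qtl_cfg = self.config["qtl"]
        bundle = self.results["combined_discovery"]
        target_gene = sim["target_gene"]
        target_cpg = sim["target_cpg"]
        genes = self.results.get("replicated_genes") or [target_gene]
        ann = bundle.annotations
        gene_ann = ann[(ann["kind"] == "gene") & ann["feature_id"].isin(genes)]
        pp = self.config["preprocess"]
        config = causal.TriangulationConfig(
            eqtl_window=qtl_cfg["eqtl_window"],
            mqtl_window=qtl_cfg["mqtl_window"],
            B=qtl_cfg["B"],
            maf_min=qtl_cfg["maf_min"],
            r2_max=self.config["mr"]["r2_max"],
            instrument_p_max=self.config["mr"]["p_max"],
            n_boot=self.config["mediation"]["n_boot"],
            n_hidden_factors=pp["n_hidden_factors"],
            n_genotype_pcs=pp["n_genotype_pcs"],
            seed=qtl_cfg["seed"],
        )
        # genome-wide-style eQTL scan over the replicated genes
        cis_cfg = qtl_mod.CisWindowConfig(
            window=qtl_cfg["eqtl_window"], maf_min=qtl_cfg["maf_min"],
            B=qtl_cfg["B"], seed=qtl_cfg["seed"],
        )
        pcs = preprocess.compute_genotype_pcs(bundle.genotypes, pp["n_genotype_pcs"])
        covariates = pd.concat([bundle.covariates[["sex", "cohort"]], pcs], axis=1)
        expr_log = bundle.expression.with_values(
            np.log2(bundle.expression.values), kind="expression_log"
        )
        mapping = qtl_mod.assign_cis_variants(gene_ann, bundle.genotypes, cis_cfg)
        nominal = qtl_mod.map_cis_nominal(expr_log, bundle.genotypes, covariates, mapping)
        perm = qtl_mod.permutation_pass(
            expr_log, bundle.genotypes, covariates, mapping, cis_cfg, nominal
        )
        ok = perm[perm["status"] == "ok"].copy()
        if len(ok):
            perm = perm.merge(
                meta.attach_q(ok, p_column="perm_p")[["feature_id", "q"]],
                on="feature_id", how="left",
            )
        self._write("eqtl_best_per_gene", perm)
        self.results["eqtl"] = perm

        # methylation-expression associations around the replicated genes
        pairs = association.build_cpg_gene_pairs(ann, 1000, genes)
        me = association.methylation_expression_assoc(
            bundle.methylation, expr_log, pairs, covariates
        )
        self._write("methylation_expression", meta.attach_q(me))
        self.results["methylation_expression"] = me

        report = causal.run_triangulation(bundle, target_gene, target_cpg, config)
        self.results["triangulation"] = report
        summary_rows = []
        for method, res in report["mr"].items():
            summary_rows.append(
                (method, res.theta, res.se, res.ci[0], res.ci[1], res.p,
                 res.n_instruments, res.egger_intercept, res.egger_intercept_p)
            )
        mr_frame = pd.DataFrame(
            summary_rows,
            columns=["method", "theta", "se", "ci_low", "ci_high", "p",
                     "n_instruments", "egger_intercept", "egger_intercept_p"],
        )
        self._write("mendelian_randomization", mr_frame)
        med = report["mediation_age"]
        med_frame = pd.DataFrame(
            [
                ("age", med.a, med.b, med.acme, med.ade, med.total,
                 med.prop_mediated, med.ci[0], med.ci[1], med.p),
            ]
            + (
                [
                    ("best_msnp", report["mediation_snp"].a, report["mediation_snp"].b,
                     report["mediation_snp"].acme, report["mediation_snp"].ade,
                     report["mediation_snp"].total, report["mediation_snp"].prop_mediated,
                     report["mediation_snp"].ci[0], report["mediation_snp"].ci[1],
                     report["mediation_snp"].p)
                ]
                if report["mediation_snp"] is not None
                else []
            ),
            columns=["exposure", "a", "b", "acme", "ade", "total",
                     "prop_mediated", "ci_low", "ci_high", "p"],
        )
        self._write("mediation", med_frame)
        self._log(
            "qtl_causal",
            n_egenes=int((perm.get("q", pd.Series(dtype=float)) < self.config["fdr"]["threshold"]).sum()),
            mr_status=report["mr_status"],
        )

    def run(self) -> dict:
        start = time.time()
        self._log("start", config_hash=self.hash)
        self.simulate()
        self.discover()
        self.replicate()
        self.specificity()
        self.traits()
        self.qtl_and_causal()
        self._log("done", seconds=round(time.time() - start, 2))
        return self.results


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    if not isinstance(config, dict):
        config = load_config(config)
    return Pipeline(config, outdir).run()
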