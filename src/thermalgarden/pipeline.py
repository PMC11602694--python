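"""End-to-end orchestration of the multi-year heat-stress analysis.

Runs, from one config: (optional) synthetic-data generation → phenotype
descriptors / PCA fitness / response models / variance partition →
population genetics (F_ST, DAPC, sMLH, heterosis vs nec-int) → thermal
regime (climatology, MHW/MHS, summer stats) → genotype-by-environment
sensitivity with its randomization null → field-survey ANOVA, and writes
per-stage CSV artifacts plus one consolidated JSON report.  Fully
deterministic under a fixed seed: all stage seeds derive from the global
one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gxe, phenotype, popgen, thermal
from .simulate import SimConfig, simulate_field_survey, simulate_genotypes, \
    simulate_necrosis_panel, simulate_temperature_series

log = logging.getLogger("thermalgarden")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Single-file configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "thermalgarden_out"
    simulate: dict | None = None          # SimConfig kwargs, or None
    inputs: dict | None = None            # paths: necrosis, genepop, temperature, survey
    trim_before_day: int = 10
    n_permutations: int = 1000
    n_randomizations: int = 10000
    max_k: int = 3
    max_pcs: int = 100
    t_threshold: float = 23.0
    min_mhw_duration: int = 5
    baseline: tuple[int, int] | None = None
    refit_env: bool = True

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'simulate' or 'inputs'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "baseline" in raw and raw["baseline"] is not None:
            raw["baseline"] = tuple(raw["baseline"])
        return cls(**raw)


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2 ** 31))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (pd.Timestamp,)):
        return str(obj.date())
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def _load_inputs(config: PipelineConfig):
    paths = config.inputs
    panel = pd.read_csv(paths["necrosis"])
    genotypes = popgen.read_genepop(paths["genepop"]) if paths.get("genepop") else None
    temperature = pd.read_csv(paths["temperature"], parse_dates=["date"]) \
        if paths.get("temperature") else None
    survey = pd.read_csv(paths["survey"]) if paths.get("survey") else None
    return panel, genotypes, temperature, survey, {}


def _simulate_inputs(config: PipelineConfig):
    sim = SimConfig(seed=config.seed, **(config.simulate or {}))
    nec = simulate_necrosis_panel(sim)
    gen = simulate_genotypes(sim)
    temp = simulate_temperature_series(sim)
    surv = simulate_field_survey(sim)
    truth = {"necrosis": nec.truth, "genotypes": gen.truth,
             "temperature": temp.truth, "survey": surv.truth}
    return nec.panel, gen.matrix, temp.series, surv.table, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the consolidated report bundle."""
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "seed": config.seed}
    if config.simulate is not None:
        panel, genotypes, temperature, survey, truth = _simulate_inputs(config)
        report["ground_truth"] = truth
    else:
        panel, genotypes, temperature, survey, truth = _load_inputs(config)
    artifacts: dict[str, pd.DataFrame] = {"necrosis_panel": panel}
    log.info("inputs: %d necrosis rows, %s genotypes, %s temperature days",
             len(panel), genotypes.n_individuals if genotypes else 0,
             len(temperature) if temperature is not None else 0)

    # --- phenotype stage ---
    panel = phenotype.apply_inclusion_rule(phenotype.validate_panel(panel))
    descriptors = phenotype.compute_daily_descriptors(panel)
    fitness = phenotype.fit_fitness_pca(panel, config.trim_before_day)
    bc = phenotype.boxcox_transform(fitness.scores)
    comparison, nec_int = phenotype.fit_response_models(bc.scores)
    comparison.boxcox_lambda = bc.lmbda
    partition = phenotype.variance_partition(bc.scores)
    artifacts["daily_descriptors"] = descriptors
    artifacts["fitness_scores"] = bc.scores
    artifacts["variance_partition"] = partition.contributions
    report["phenotype"] = {
        "n_cases": len(fitness.scores),
        "exploratory_pc1_pct": fitness.exploratory_variance_explained[0],
        "trimmed_pc1_pct": fitness.variance_explained[0],
        "boxcox_lambda": bc.lmbda,
        "boxcox_shift": bc.shift,
        "shapiro_p": bc.shapiro_p,
        "levene_p": bc.levene_p,
        "models": comparison.models,
        "lrt": {"chi2": comparison.lrt_chi2, "df": comparison.lrt_df,
                "p": comparison.lrt_p},
        "fixed_factor_tests": comparison.fixed_factor_tests,
        "tukey_year": comparison.tukey_year,
        "preferred_model": comparison.preferred,
        "variance_partition": {
            r.factor: r.contribution_pct
            for r in partition.contributions.itertuples()
        },
    }
    log.info("phenotype: PC1 %.1f%% (trimmed), lambda=%.2f, year share %.1f%%",
             fitness.variance_explained[0], bc.lmbda,
             report["phenotype"]["variance_partition"].get("year", np.nan))

    # --- population genetics stage ---
    if genotypes is not None:
        fst = popgen.wc_fst(genotypes, config.n_permutations,
                            seed=_stage_seed(config.seed, 1))
        dapc = popgen.dapc_clusters(genotypes, config.max_k, config.max_pcs,
                                    seed=_stage_seed(config.seed, 2))
        smlh = popgen.compute_smlh(genotypes)
        heterosis = popgen.heterosis_test(
            nec_int, smlh, n_perm=config.n_randomizations,
            seed=_stage_seed(config.seed, 3))
        diversity = popgen.diversity_summary(genotypes)
        artifacts["diversity_summary"] = diversity
        artifacts["fst_pairwise"] = fst.pairwise.reset_index(names="population")
        artifacts["dapc_memberships"] = dapc.memberships.reset_index(names="colony_id")
        artifacts["smlh"] = smlh.rename_axis("colony_id").reset_index()
        mean_membership = {
            c: float(dapc.memberships.loc[dapc.assignments == c, c].mean())
            for c in dapc.memberships.columns
        }
        report["popgen"] = {
            "global_fst": fst.global_theta,
            "population_isolation": popgen.population_isolation_summary(fst),
            "global_fst_p": fst.global_p,
            "pairwise_fst": fst.pairwise,
            "pairwise_fst_p": fst.pairwise_p,
            "n_permutations": fst.n_permutations,
            "dapc_chosen_k": dapc.chosen_k,
            "dapc_bic": dapc.bic_curve,
            "dapc_mean_membership": mean_membership,
            "smlh_range": [float(smlh.min()), float(smlh.max())],
            "heterosis": {"slope": heterosis.observed_slope,
                          "p": heterosis.p_value,
                          "n_permutations": heterosis.n_permutations,
                          "n": heterosis.n_individuals},
        }
        log.info("popgen: global FST=%.4f, K=%d, heterosis p=%.3f",
                 fst.global_theta, dapc.chosen_k, heterosis.p_value)
    else:
        report["popgen"] = None

    # --- thermal stage ---
    if temperature is not None:
        clim = thermal.build_climatology(temperature, baseline=config.baseline)
        events = thermal.detect_thermal_events(
            temperature, clim, min_mhw_duration=config.min_mhw_duration)
        summer = thermal.summer_statistics(temperature, events,
                                           t_threshold=config.t_threshold)
        artifacts["climatology"] = clim.table
        artifacts["thermal_events"] = thermal.events_to_frame(events)
        artifacts["summer_stats"] = summer
        report["thermal"] = {
            "n_events": len(events),
            "events": thermal.events_to_frame(events),
            "summer_stats": summer,
        }
        log.info("thermal: %d events detected", len(events))
    else:
        report["thermal"] = None

    # --- genotype-by-environment stage ---
    env = gxe.environmental_values(bc.scores)
    profiles = gxe.sensitivity_slopes(bc.scores, env)
    null = gxe.null_slope_distribution(
        bc.scores, env, n_randomizations=config.n_randomizations,
        seed=_stage_seed(config.seed, 4), refit_env=config.refit_env)
    profiles = gxe.classify_sensitivity(profiles, null.central_interval)
    artifacts["sensitivity_profiles"] = profiles
    report["gxe"] = {
        "environmental_values": env.values,
        "n_common_genotypes": len(env.common_genotypes),
        "mean_slope": float(profiles["slope"].mean()),
        "slope_range": [float(profiles["slope"].min()),
                        float(profiles["slope"].max())],
        "null_mean": null.mean,
        "null_central_interval": list(null.central_interval),
        "exceedance_pct": 100.0 * null.exceedance_fraction,
        "n_randomizations": null.n_randomizations,
        "categories": profiles["category"].value_counts().to_dict(),
    }
    log.info("gxe: mean slope %.4f, exceedance %.1f%%",
             report["gxe"]["mean_slope"], report["gxe"]["exceedance_pct"])

    # --- field-survey stage ---
    if survey is not None:
        anova = phenotype.survey_anova(survey)
        artifacts["survey"] = survey
        report["survey"] = {
            "f_stat": anova.f_stat,
            "p": anova.p_value,
            "group_stats": anova.group_stats,
            "tukey": anova.tukey,
        }
        log.info("survey: F=%.3f p=%.4f", anova.f_stat, anova.p_value)
    else:
        report["survey"] = None

    return {"report": report, "artifacts": artifacts}


def write_report(bundle: dict, outdir) -> Path:
    """Write the consolidated JSON report and per-stage CSV artifacts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle["artifacts"].items():
        df.to_csv(out / f"{name}.csv", index=False)
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(_jsonable(bundle["report"]), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
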