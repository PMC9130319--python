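"""End-to-end orchestration: exclusions, model battery, reports.

``run_pipeline`` reproduces the full analysis battery on one cohort
(simulated or read from files):

* PRS scoring, z-standardisation, quintile categories;
* smoking-status and pack-year categories;
* documented exclusion filters with a per-rule audit log;
* genetic-risk models (Model 1: covariate adjustment only; Model 2: plus
  smoking status; Model 3: plus pack-year categories), smoking models
  (Model 1; Model 2 adds the continuous PRS), 3x3 and 3x4 joint-category
  models with the low-genetic/never (or no pack-years) cell as reference,
  smoking models stratified by genetic risk;
* trend tests, PRS-by-smoking interaction tests, Schoenfeld
  proportional-hazards diagnostics, a restricted-cubic-spline dose-response
  for the PRS, ROC AUCs, Kaplan-Meier cumulative incidence;
* attributable fractions: case-load and prevalence PAFs, the quit-scenario
  generalized impact fraction, genetic-risk-stratified PAFs and externally
  standardised PAFs, all with bootstrap intervals.

Reports are plain TSV/JSON under a run directory and are byte-identical
across runs with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    FLOAT_FMT,
    read_exposure_distributions,
    read_phenotypes,
    read_plink_raw,
    read_vcf,
    read_weight_table,
)
from .paf import (
    ExposureDistribution,
    PAFResult,
    generalized_impact_fraction,
    paf_confidence_interval,
    stratified_paf,
)
from .prs import (
    GENETIC_RISK_LEVELS,
    PACKYEAR_LEVELS,
    SMOKING_STATUS_LEVELS,
    ValidationError,
    categorize_smoking,
    harmonize_genotypes,
    score_cohort,
)
from .survival import (
    CategoricalTerm,
    ContinuousTerm,
    CoxFit,
    ModelSpec,
    cumulative_incidence,
    fit_cox,
    group_summaries,
    hazard_ratios,
    interaction_test,
    rcs_basis,
    roc_auc,
    schoenfeld_ph_test,
    trend_test,
)
from .synthetic import SimulationConfig, inject_mismatch, simulate_cohort

log = logging.getLogger(__name__)

TIME, EVENT = "follow_up_years", "event"


@dataclasses.dataclass
class ExclusionRules:
    """Sensitivity filters, applied in the documented order:
    missing covariates -> prior cancer flag -> relatedness flag -> events in
    the first ``early_event_years`` -> never-smoker/pack-year mismatch.
    A rule whose column is absent raises, never silently passes."""

    missing_covariates: bool = True
    prior_cancer: bool = False
    relatedness: bool = False
    early_events: bool = False
    early_event_years: float = 2.0
    smoking_mismatch: bool = True


@dataclasses.dataclass
class PipelineConfig:
    """Either file inputs or a simulation config, plus run options."""

    simulation: SimulationConfig | None = None
    weights_path: str | None = None
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    external_distributions_path: str | None = None
    exclusions: ExclusionRules = dataclasses.field(default_factory=ExclusionRules)
    mismatch_fraction: float = 0.0027
    adjustment: tuple[str, ...] = ("age", "sex", "tdi", "bmi", "pc1", "pc2", "pc3", "pc4")
    n_boot: int = 1000
    seed: int = 0
    output_dir: str = "prscox_run"

    def validate(self) -> None:
        file_mode = self.phenotypes_path is not None
        sim_mode = self.simulation is not None
        if file_mode == sim_mode:
            raise ValidationError(
                "provide exactly one of (input paths, simulation config)"
            )
        if file_mode and (self.weights_path is None or self.genotypes_path is None):
            raise ValidationError("file input needs weights, genotypes and phenotypes")


@dataclasses.dataclass
class ReportBundle:
    """All tables of one run, with provenance."""

    table1: pd.DataFrame
    genetic_risk_table: pd.DataFrame
    smoking_table: pd.DataFrame
    stratified_table: pd.DataFrame
    joint_table: pd.DataFrame
    cumulative_incidence: pd.DataFrame
    spline: pd.DataFrame
    interaction: dict
    ph_diagnostics: pd.DataFrame
    auc: dict
    paf: dict
    exclusion_log: pd.DataFrame
    provenance: dict
    fits: dict[str, CoxFit] = dataclasses.field(default_factory=dict)


def apply_exclusions(
    data: pd.DataFrame, rules: ExclusionRules
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply enabled filters in order; return (filtered data, audit log)."""
    df = data
    log_rows = []

    def record(rule: str, before: int, after: int):
        log_rows.append({"rule": rule, "removed": before - after, "remaining": after})

    if rules.missing_covariates:
        before = len(df)
        df = df.dropna()
        record("missing_covariates", before, len(df))
    for flag_rule, col in (("prior_cancer", "prior_cancer"), ("relatedness", "related")):
        if getattr(rules, flag_rule):
            if col not in df.columns:
                raise ValidationError(f"exclusion rule {flag_rule!r} needs column {col!r}")
            before = len(df)
            df = df[~df[col].astype(bool)]
            record(flag_rule, before, len(df))
    if rules.early_events:
        before = len(df)
        early = (df[EVENT] == 1) & (df[TIME] <= rules.early_event_years)
        df = df[~early]
        record("early_events", before, len(df))
    if rules.smoking_mismatch:
        if "smoking_mismatch" not in df.columns:
            raise ValidationError("mismatch rule needs the smoking_mismatch column")
        before = len(df)
        df = df[~df["smoking_mismatch"].astype(bool)]
        record("smoking_mismatch", before, len(df))
    audit = pd.DataFrame(log_rows, columns=["rule", "removed", "remaining"])
    return df.reset_index(drop=True), audit


def _load_cohort(config: PipelineConfig) -> pd.DataFrame:
    """Return the analysis table (phenotypes + raw PRS columns merged)."""
    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation)
        if config.mismatch_fraction > 0:
            cohort = inject_mismatch(cohort, config.mismatch_fraction, config.seed + 1)
        pheno = cohort.phenotypes.copy()
        genotypes, panel = cohort.genotypes, cohort.truth.variant_panel
    else:
        panel = read_weight_table(config.weights_path)
        gpath = str(config.genotypes_path)
        gm = read_vcf(gpath) if gpath.endswith(".vcf") else read_plink_raw(gpath)
        genotypes, panel = harmonize_genotypes(gm, panel)
        pheno = read_phenotypes(config.phenotypes_path)
        missing = set(pheno["sample_id"]) ^ set(genotypes.sample_ids)
        if missing:
            raise ValidationError(
                f"sample IDs inconsistent between phenotype and genotype files: "
                f"{sorted(missing)[:5]}"
            )
        pheno = pheno.set_index("sample_id").loc[genotypes.sample_ids].reset_index()
        cats = categorize_smoking(pheno["smoking_status"], pheno["pack_years"])
        pheno[["smoking_status", "packyear_category", "smoking_mismatch"]] = cats[
            ["smoking_status", "packyear_category", "smoking_mismatch"]
        ].to_numpy()
    scores = score_cohort(genotypes, panel)
    scores.index = pheno.index
    return pd.concat([pheno, scores[["prs_raw"]]], axis=1)


def _rescore(df: pd.DataFrame) -> pd.DataFrame:
    """(Re-)standardise and categorise the PRS on the post-exclusion cohort."""
    from .prs import categorize_prs, standardize_prs

    z = standardize_prs(df["prs_raw"])
    cats = categorize_prs(z)
    out = df.copy()
    out["prs_z"] = z
    out["prs_quintile"] = cats["quintile"]
    out["genetic_risk"] = cats["genetic_risk"]
    return out


def _summary_frame(df, group_col, order) -> pd.DataFrame:
    gs = {g.group: g for g in group_summaries(df, group_col)}
    rows = []
    for lv in order:
        g = gs.get(lv)
        if g is None:
            continue
        rows.append(
            {
                "group": lv,
                "n": g.n,
                "events": g.events,
                "event_pct": 100.0 * g.events / g.n,
                "person_years": g.person_years,
                "ir_per_1000": g.ir_per_1000,
            }
        )
    return pd.DataFrame(rows)


def _attach_model(table, df, group_col, order, model_name, adjustment, extra_terms=()):
    """Fit one categorical model and merge HR columns into the group table.

    A divergent fit (sparse cells, e.g. within a small stratum) leaves the
    HR columns as NaN and is reported through the fit's warnings rather
    than aborting the run.
    """
    spec = ModelSpec(
        TIME, EVENT,
        exposures=(CategoricalTerm(group_col, reference=order[0], levels=tuple(order[1:])),)
        + tuple(extra_terms),
        adjustment=tuple(adjustment),
    )
    fit = fit_cox(df, spec)
    for col in (f"{model_name}_hr", f"{model_name}_ci_low", f"{model_name}_ci_high", f"{model_name}_p"):
        table[col] = np.nan
    if not fit.converged:
        log.warning("%s on %s did not converge: %s", model_name, group_col, fit.warnings)
        table[f"{model_name}_p_trend"] = np.nan
        return fit
    hr = hazard_ratios(fit)
    p_trend = trend_test(df, spec, group_col)
    table.loc[table["group"] == order[0], f"{model_name}_hr"] = 1.0
    for lv in order[1:]:
        key = f"{group_col}[{lv}]"
        if key not in hr.index:
            continue
        row = table["group"] == lv
        table.loc[row, f"{model_name}_hr"] = hr.loc[key, "hr"]
        table.loc[row, f"{model_name}_ci_low"] = hr.loc[key, "ci_low"]
        table.loc[row, f"{model_name}_ci_high"] = hr.loc[key, "ci_high"]
        table.loc[row, f"{model_name}_p"] = hr.loc[key, "p"]
    table[f"{model_name}_p_trend"] = p_trend
    return fit


def _baseline_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    n = len(df)
    for col, order in (
        ("smoking_status", SMOKING_STATUS_LEVELS),
        ("packyear_category", PACKYEAR_LEVELS),
        ("genetic_risk", GENETIC_RISK_LEVELS),
    ):
        counts = df[col].astype(str).value_counts()
        for lv in order:
            c = int(counts.get(lv, 0))
            rows.append({"characteristic": col, "level": lv, "n": c, "pct": 100.0 * c / n})
    for col in ("age", "bmi", "prs_z"):
        if col in df.columns:
            rows.append(
                {
                    "characteristic": f"{col}_mean_sd",
                    "level": "",
                    "n": n,
                    "pct": np.nan,
                    "mean": float(df[col].mean()),
                    "sd": float(df[col].std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the whole battery; see the module docstring for stages."""
    config.validate()
    stage = "load"
    try:
        raw = _load_cohort(config)
        stage = "exclusions"
        df, audit = apply_exclusions(raw, config.exclusions)
        stage = "scoring"
        df = _rescore(df)
        adjustment = tuple(c for c in config.adjustment if c in df.columns)
        fits: dict[str, CoxFit] = {}

        # --- genetic-risk table (three nested models)
        stage = "genetic_risk_models"
        gtab = _summary_frame(df, "genetic_risk", GENETIC_RISK_LEVELS)
        fits["genetic_m1"] = _attach_model(
            gtab, df, "genetic_risk", GENETIC_RISK_LEVELS, "m1", adjustment
        )
        fits["genetic_m2"] = _attach_model(
            gtab, df, "genetic_risk", GENETIC_RISK_LEVELS, "m2", adjustment,
            extra_terms=(CategoricalTerm("smoking_status", "never", ("former", "current")),),
        )
        fits["genetic_m3"] = _attach_model(
            gtab, df, "genetic_risk", GENETIC_RISK_LEVELS, "m3", adjustment,
            extra_terms=(
                CategoricalTerm("packyear_category", "no", ("light", "intermediate", "heavy")),
            ),
        )
        # continuous per-SD model (adjusted for smoking status, Model-2 style)
        spec_sd = ModelSpec(
            TIME, EVENT,
            exposures=(
                ContinuousTerm("prs_z"),
                CategoricalTerm("smoking_status", "never", ("former", "current")),
            ),
            adjustment=adjustment,
        )
        fits["per_sd"] = fit_cox(df, spec_sd)
        hr_sd = hazard_ratios(fits["per_sd"]).loc["prs_z"]
        per_sd_row = pd.DataFrame(
            [{
                "group": "per_sd_of_prs", "n": len(df), "events": int(df[EVENT].sum()),
                "event_pct": np.nan, "person_years": float(df[TIME].sum()),
                "ir_per_1000": np.nan,
                "m2_hr": hr_sd["hr"], "m2_ci_low": hr_sd["ci_low"],
                "m2_ci_high": hr_sd["ci_high"], "m2_p": hr_sd["p"],
            }]
        )
        gtab = pd.concat([gtab, per_sd_row], ignore_index=True)

        # --- smoking tables (status and pack-years; Model 2 adds the PRS)
        stage = "smoking_models"
        stab = _summary_frame(df, "smoking_status", SMOKING_STATUS_LEVELS)
        fits["smoking_m1"] = _attach_model(
            stab, df, "smoking_status", SMOKING_STATUS_LEVELS, "m1", adjustment
        )
        fits["smoking_m2"] = _attach_model(
            stab, df, "smoking_status", SMOKING_STATUS_LEVELS, "m2", adjustment,
            extra_terms=(ContinuousTerm("prs_z"),),
        )
        ptab = _summary_frame(df, "packyear_category", PACKYEAR_LEVELS)
        fits["packyear_m1"] = _attach_model(
            ptab, df, "packyear_category", PACKYEAR_LEVELS, "m1", adjustment
        )
        fits["packyear_m2"] = _attach_model(
            ptab, df, "packyear_category", PACKYEAR_LEVELS, "m2", adjustment,
            extra_terms=(ContinuousTerm("prs_z"),),
        )
        stab.insert(0, "exposure", "smoking_status")
        ptab.insert(0, "exposure", "packyear_category")
        smoking_table = pd.concat([stab, ptab], ignore_index=True)

        # --- joint 3x3 and 3x4 categories
        stage = "joint_models"
        df = df.copy()
        df["joint_status"] = (
            df["genetic_risk"].astype(str) + "/" + df["smoking_status"].astype(str)
        )
        df["joint_packyear"] = (
            df["genetic_risk"].astype(str) + "/" + df["packyear_category"].astype(str)
        )
        joint_frames = []
        for col, ref, inner in (
            ("joint_status", "low/never", SMOKING_STATUS_LEVELS),
            ("joint_packyear", "low/no", PACKYEAR_LEVELS),
        ):
            order = [f"{g}/{s}" for g in GENETIC_RISK_LEVELS for s in inner]
            order = [ref] + [o for o in order if o != ref]
            order = [o for o in order if o in set(df[col].astype(str))]
            jt = _summary_frame(df, col, order)
            spec = ModelSpec(
                TIME, EVENT,
                exposures=(CategoricalTerm(col, ref, tuple(order[1:])),),
                adjustment=adjustment,
            )
            fit = fit_cox(df, spec)
            fits[col] = fit
            if fit.converged:
                hr = hazard_ratios(fit)
                jt["hr"] = [
                    1.0 if g == ref else hr.loc[f"{col}[{g}]", "hr"] for g in jt["group"]
                ]
                jt["ci_low"] = [
                    np.nan if g == ref else hr.loc[f"{col}[{g}]", "ci_low"] for g in jt["group"]
                ]
                jt["ci_high"] = [
                    np.nan if g == ref else hr.loc[f"{col}[{g}]", "ci_high"] for g in jt["group"]
                ]
            else:
                log.warning("joint model %s did not converge: %s", col, fit.warnings)
                jt["hr"] = np.nan
                jt["ci_low"] = np.nan
                jt["ci_high"] = np.nan
            jt.insert(0, "classification", col)
            joint_frames.append(jt)
        joint_table = pd.concat(joint_frames, ignore_index=True)

        # --- smoking models stratified by genetic risk
        stage = "stratified_models"
        strat_rows = []
        for g in GENETIC_RISK_LEVELS:
            sub = df[df["genetic_risk"].astype(str) == g]
            tab = _summary_frame(sub, "smoking_status", SMOKING_STATUS_LEVELS)
            fits[f"stratified_{g}"] = _attach_model(
                tab, sub, "smoking_status", SMOKING_STATUS_LEVELS, "m1", adjustment
            )
            tab.insert(0, "genetic_risk", g)
            strat_rows.append(tab)
        stratified_table = pd.concat(strat_rows, ignore_index=True)

        # --- interaction tests (continuous z-PRS x smoking dummies)
        stage = "interaction"
        p_status, _, _ = interaction_test(df, spec_sd, "prs_z", "smoking_status")
        spec_py = ModelSpec(
            TIME, EVENT,
            exposures=(
                ContinuousTerm("prs_z"),
                CategoricalTerm("packyear_category", "no", ("light", "intermediate", "heavy")),
            ),
            adjustment=adjustment,
        )
        p_py, _, _ = interaction_test(df, spec_py, "prs_z", "packyear_category")
        interaction = {
            "prs_x_smoking_status_p": p_status,
            "prs_x_packyear_p": p_py,
        }

        # --- proportional hazards diagnostic on the per-SD model
        stage = "schoenfeld"
        ph = schoenfeld_ph_test(fits["per_sd"], df)

        # --- spline dose-response for the PRS
        stage = "spline"
        basis, knots = rcs_basis(df["prs_z"], n_knots=4)
        spl = df.copy()
        for c in basis.columns:
            spl[c] = basis[c]
        spec_spl = ModelSpec(
            TIME, EVENT,
            exposures=tuple(ContinuousTerm(c) for c in basis.columns),
            adjustment=adjustment,
        )
        fits["spline"] = fit_cox(spl, spec_spl)
        grid = np.linspace(df["prs_z"].quantile(0.01), df["prs_z"].quantile(0.99), 101)
        gb, _ = rcs_basis(grid, knots=knots)
        beta_spl = fits["spline"].beta[list(basis.columns)].to_numpy()
        log_hr_curve = gb.to_numpy() @ beta_spl
        log_hr_curve -= np.interp(0.0, grid, log_hr_curve)  # HR 1 at the mean PRS
        spline = pd.DataFrame({"prs_z": grid, "log_hr": log_hr_curve})

        # --- discrimination
        stage = "auc"
        y = df[EVENT].to_numpy()
        auc = {
            "prs_only": roc_auc(y, df["prs_z"].to_numpy()),
            "smoking_only": roc_auc(y, fits["smoking_m1"].linear_predictor(df).to_numpy()),
            "combined": roc_auc(y, fits["per_sd"].linear_predictor(df).to_numpy()),
        }

        # --- cumulative incidence curves
        stage = "cumulative_incidence"
        cum_frames = []
        for col in ("genetic_risk", "smoking_status", "packyear_category"):
            ci = cumulative_incidence(df, col)
            ci.insert(0, "classification", col)
            cum_frames.append(ci)
        cum_inc = pd.concat(cum_frames, ignore_index=True)

        # --- attributable fractions
        stage = "paf"
        paf_section = _paf_section(df, fits["smoking_m2"], config, adjustment)

        stage = "report"
        provenance = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_input": len(raw),
            "n_analysed": len(df),
            "n_events": int(df[EVENT].sum()),
        }
        return ReportBundle(
            table1=_baseline_table(df),
            genetic_risk_table=gtab,
            smoking_table=smoking_table,
            stratified_table=stratified_table,
            joint_table=joint_table,
            cumulative_incidence=cum_inc,
            spline=spline,
            interaction=interaction,
            ph_diagnostics=ph.reset_index(),
            auc=auc,
            paf=paf_section,
            exclusion_log=audit,
            provenance=provenance,
            fits=fits,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _paf_section(df, smoking_fit, config, adjustment) -> dict:
    hr_cols = {
        "former": "smoking_status[former]",
        "current": "smoking_status[current]",
    }
    cases = df[df[EVENT] == 1]
    case_counts = {
        lv: int((cases["smoking_status"].astype(str) == lv).sum())
        for lv in SMOKING_STATUS_LEVELS
    }
    cohort_counts = {
        lv: int((df["smoking_status"].astype(str) == lv).sum())
        for lv in SMOKING_STATUS_LEVELS
    }
    out: dict = {}
    out["case_load"] = dataclasses.asdict(
        paf_confidence_interval(
            "case_load", case_counts, "never", smoking_fit, hr_cols,
            n_boot=config.n_boot, seed=config.seed + 10,
        )
    )
    out["prevalence"] = dataclasses.asdict(
        paf_confidence_interval(
            "prevalence", cohort_counts, "never", smoking_fit, hr_cols,
            n_boot=config.n_boot, seed=config.seed + 11,
        )
    )
    # quit scenario: current smokers become former, former remain
    p = ExposureDistribution.from_counts(cohort_counts, "never")
    quit_dist = ExposureDistribution(
        p.levels,
        (p.proportions[0], p.proportions[1] + p.proportions[2], 0.0),
        "never",
    )
    out["quit_scenario_gif"] = dataclasses.asdict(
        paf_confidence_interval(
            "impact_fraction", cohort_counts, "never", smoking_fit, hr_cols,
            counterfactual=quit_dist, n_boot=config.n_boot, seed=config.seed + 12,
        )
    )
    # stratified by genetic risk, stratum-specific unadjusted-by-PRS fits
    def strat_fit(sub):
        return fit_cox(
            sub,
            ModelSpec(
                TIME, EVENT,
                exposures=(CategoricalTerm("smoking_status", "never", ("former", "current")),),
                adjustment=tuple(adjustment),
            ),
        )

    out["stratified"] = {
        k: dataclasses.asdict(v)
        for k, v in stratified_paf(
            df, "genetic_risk", "smoking_status", "never", strat_fit, hr_cols,
            method="case_load", n_boot=config.n_boot, seed=config.seed + 13,
        ).items()
    }
    # external standardisation (packaged synthetic placeholder distributions)
    if config.external_distributions_path:
        dists = read_exposure_distributions(config.external_distributions_path)
    else:
        with importlib.resources.as_file(
            importlib.resources.files("prscox.data").joinpath(
                "synthetic_external_smoking_distributions.tsv"
            )
        ) as p:
            dists = read_exposure_distributions(p)
    out["external"] = {}
    hrs = {
        lv: float(np.exp(smoking_fit.beta[col])) for lv, col in hr_cols.items()
    }
    from .paf import paf_prevalence

    for name, dist in dists.items():
        out["external"][name] = {
            "estimate": paf_prevalence(dist, hrs),
            "proportions": dict(zip(dist.levels, dist.proportions)),
        }
    return out


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_report(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write every report table under ``outdir``; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def tsv(name: str, frame: pd.DataFrame):
        p = outdir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
        written.append(p)

    def js(name: str, obj):
        p = outdir / f"{name}.json"
        p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")
        written.append(p)

    tsv("table1_baseline", bundle.table1)
    tsv("table2_genetic_risk", bundle.genetic_risk_table)
    tsv("table3_smoking", bundle.smoking_table)
    tsv("table4_stratified", bundle.stratified_table)
    tsv("joint_categories", bundle.joint_table)
    tsv("cumulative_incidence", bundle.cumulative_incidence)
    tsv("spline_dose_response", bundle.spline)
    tsv("ph_diagnostics", bundle.ph_diagnostics)
    tsv("exclusion_log", bundle.exclusion_log)
    js("interaction", bundle.interaction)
    js("auc", bundle.auc)
    js("paf", bundle.paf)
    js("provenance", bundle.provenance)
    fit_summary = {
        name: {
            "beta": fit.beta.to_dict(),
            "se": fit.se.to_dict(),
            "loglik": fit.loglik,
            "n_events": fit.n_events,
            "converged": fit.converged,
            "iterations": fit.iterations,
        }
        for name, fit in bundle.fits.items()
    }
    js("fits", fit_summary)
    return written
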