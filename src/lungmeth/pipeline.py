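"""End-to-end orchestration of the methylation → lung-function inference chain.

``run_full_pipeline`` executes, in order: simulate (or load) → QC → per-cohort
EWAS (combined and sex-stratified) → inverse-variance meta-analysis →
direction-consistency retention → candidate regions → sex-specific and
sex-divergent DMPs → stratified network estimation with differential hubs →
PRS adjustment/robustness/interaction → epigenetic-age association.  Every
stage writes plain TSV/BED/GraphML into the output directory and appends a
record (rows, outputs, parameters) to a JSON manifest, so each filter's
record counts are auditable.  With a fixed configuration and seed the whole
run is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ageaccel, ewas, ggmnet, metaconsist, methio, prsrobust, sexdiff, synthdata

logger = logging.getLogger(__name__)

STAGES = [
    "simulate", "qc", "ewas", "meta", "consistency",
    "regions", "sexdiff", "ggm", "prs", "ageaccel",
]

CHILD_COVARIATES = ["sex", "age", "height", "smoke_exposure",
                    "cell_CD4T", "cell_CD8T", "cell_NK", "cell_Bcell", "cell_Mono"]
BIRTH_COVARIATES = ["sex", "gestational_age", "height", "smoke_exposure",
                    "cell_CD4T", "cell_CD8T", "cell_NK", "cell_Bcell", "cell_Mono"]


class ValidationError(ValueError):
    """Configuration or input validation failed (message lists violations)."""


@dataclass
class RunConfig:
    """Pipeline configuration; defaults encode the three-cohort study design."""

    n_cpgs: int = 500
    cohort_sizes: tuple[int, ...] = (788, 703, 572)
    cohort_ids: tuple[str, ...] = ("CHILD_A", "CHILD_B", "BIRTH")
    birth_cohorts: tuple[str, ...] = ("BIRTH",)
    outcomes: tuple[str, ...] = ("FEV1", "FEV1_FVC")
    frac_causal: float = 0.05
    frac_sex_divergent: float = 0.2
    shared_truth_frac: float = 0.7
    effect_mean: float = 0.5
    effect_sd: float = 0.1
    noise_sd: float = 1.0
    discovery_p: float = 0.05
    fdr: float = 0.05
    rel_tol: float = 0.10
    diff_threshold: float = 0.20
    min_cpgs: int = 4
    max_gap: int = 1000
    min_n: int = 20
    prs_correlation: float = 0.3
    ggm_selection: str = "ebic"
    ggm_min_nodes: int = 8
    seed: int = 0
    qc_max_missing: float = 0.1
    qc_min_sd: float = 1e-6

    def validate(self) -> None:
        problems = []
        for name, lo, hi in (
            ("discovery_p", 0, 1), ("fdr", 0, 1), ("rel_tol", 0, 1),
            ("diff_threshold", 0, 1), ("shared_truth_frac", 0, 1),
            ("frac_causal", 0, 1), ("frac_sex_divergent", 0, 1),
            ("qc_max_missing", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                problems.append(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_cpgs < 1:
            problems.append(f"min_cpgs={self.min_cpgs} must be >= 1")
        if self.max_gap < 1:
            problems.append(f"max_gap={self.max_gap} must be >= 1")
        if len(self.cohort_sizes) != len(self.cohort_ids):
            problems.append("cohort_sizes and cohort_ids differ in length")
        if len(self.cohort_ids) < 2:
            problems.append("need at least two cohorts")
        if self.ggm_selection not in ("ebic", "stars", "fixed"):
            problems.append(f"unknown ggm_selection {self.ggm_selection!r}")
        unknown = [o for o in self.outcomes if o not in methio.OUTCOME_COLUMNS]
        if unknown:
            problems.append(f"unknown outcome(s) {unknown}")
        if problems:
            raise ValidationError("invalid configuration: " + "; ".join(problems))

    def cohort_configs(self) -> list[synthdata.CohortConfig]:
        configs = []
        for i, (cid, n) in enumerate(zip(self.cohort_ids, self.cohort_sizes)):
            birth = cid in self.birth_cohorts
            configs.append(
                synthdata.CohortConfig(
                    cohort_id=cid,
                    n_samples=n,
                    n_cpgs=self.n_cpgs,
                    frac_causal=self.frac_causal,
                    effect_mean=self.effect_mean,
                    effect_sd=self.effect_sd,
                    noise_sd=self.noise_sd,
                    frac_sex_divergent=self.frac_sex_divergent,
                    seed=self.seed * 1000 + i + 1,
                    birth_cohort=birth,
                    effect_attenuation=0.5 if birth else 1.0,
                    target_outcomes=tuple(self.outcomes),
                )
            )
        return configs

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("cohort_sizes", "cohort_ids", "birth_cohorts", "outcomes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def covariates_for(cohort_id: str, config: RunConfig, stratum: str) -> list[str]:
    cov = BIRTH_COVARIATES if cohort_id in config.birth_cohorts else CHILD_COVARIATES
    return [c for c in cov if not (stratum in ("F", "M") and c == "sex")]


# ---------------------------------------------------------------------------
# input validation (path mode)
# ---------------------------------------------------------------------------

def validate_inputs(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
) -> list[str]:
    """Cross-check a loaded cohort; returns the list of fatal violations."""
    violations: list[str] = []
    try:
        methio.validate_beta_matrix(beta)
    except (methio.SchemaError, methio.DomainError) as err:
        violations.append(str(err))
    try:
        methio.validate_sample_table(samples)
    except methio.SchemaError as err:
        violations.append(str(err))
        return violations
    known = set(samples["sample_id"])
    orphans = [s for s in beta.columns if s not in known]
    if orphans:
        violations.append(f"beta-matrix sample(s) absent from sample table: {orphans[:5]}")
    if annotation is not None:
        try:
            methio.validate_annotation(annotation)
            uncovered = [c for c in beta.index if c not in set(annotation["cpg_id"])]
            if uncovered:
                violations.append(f"CpG(s) missing from annotation: {uncovered[:5]}")
        except methio.SchemaError as err:
            violations.append(str(err))
    return violations


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def _write(df: pd.DataFrame, outdir: Path, name: str) -> str:
    path = outdir / name
    methio.write_table(df, path)
    return name


def run_full_pipeline(
    config: RunConfig,
    outdir,
    cohort_data: dict[str, tuple[pd.DataFrame, pd.DataFrame]] | None = None,
    annotation: pd.DataFrame | None = None,
) -> dict:
    """Execute every stage; returns (and writes) the run manifest.

    ``cohort_data`` maps cohort_id -> (beta, samples) to run on user data;
    when omitted, cohorts are simulated from the configuration (and planted
    truth tables are written alongside the data).
    """
    config.validate()
    outdir = methio.ensure_dir(outdir)
    manifest: dict = {
        "package": "lungmeth",
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "cohort_order": list(config.cohort_ids),
        "stages": [],
    }

    def record(stage: str, rows: int, outputs: list[str], **params) -> None:
        manifest["stages"].append({"stage": stage, "rows": int(rows), "outputs": outputs, **params})

    # ---- simulate / load -------------------------------------------------
    truths: dict[str, pd.DataFrame] = {}
    cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    if cohort_data is None:
        triples = synthdata.generate_multi_cohort(config.cohort_configs(), config.shared_truth_frac)
        outputs = []
        for cfg, (beta, samples, truth) in zip(config.cohort_configs(), triples):
            cohorts[cfg.cohort_id] = (beta, samples)
            truths[cfg.cohort_id] = truth
            bname = f"{cfg.cohort_id}_beta.tsv"
            methio.write_matrix(beta, outdir / bname)
            outputs += [bname, _write(samples, outdir, f"{cfg.cohort_id}_samples.tsv"),
                        _write(truth, outdir, f"{cfg.cohort_id}_truth.tsv")]
        if annotation is None:
            annotation = synthdata.generate_annotation(config.n_cpgs, seed=config.seed)
        outputs.append(_write(annotation, outdir, "annotation.tsv"))
        methio.write_annotation_bed(annotation, outdir / "annotation.bed")
        outputs.append("annotation.bed")
        record("simulate", sum(len(b.index) for b, _ in cohorts.values()), outputs,
               shared_truth_frac=config.shared_truth_frac)
    else:
        all_violations = []
        for cid, (beta, samples) in cohort_data.items():
            vio = validate_inputs(beta, samples, annotation)
            all_violations += [f"{cid}: {v}" for v in vio]
            cohorts[cid] = (beta, samples)
        if all_violations:
            raise ValidationError("; ".join(all_violations))
        record("simulate", sum(len(b.index) for b, _ in cohorts.values()), [], mode="loaded")

    # ---- qc --------------------------------------------------------------
    qc_outputs, qc_rows = [], 0
    for cid in list(cohorts):
        beta, samples = cohorts[cid]
        filtered, report = methio.qc_filter(beta, config.qc_max_missing, config.qc_min_sd)
        cohorts[cid] = (filtered, samples)
        qc_outputs.append(_write(report, outdir, f"{cid}_qc_report.tsv"))
        qc_rows += len(filtered)
    record("qc", qc_rows, qc_outputs, max_missing=config.qc_max_missing, min_sd=config.qc_min_sd)

    # ---- ewas ------------------------------------------------------------
    mvals = {cid: methio.beta_to_m(beta) for cid, (beta, _) in cohorts.items()}
    scans: dict[tuple[str, str, str], pd.DataFrame] = {}
    ewas_outputs, ewas_rows = [], 0
    for cid, (beta, samples) in cohorts.items():
        for outcome in config.outcomes:
            for stratum in ("all", "F", "M"):
                tab = ewas.run_ewas(
                    mvals[cid], samples, outcome,
                    covariates_for(cid, config, stratum),
                    stratum=stratum, cohort_id=cid,
                    annotation=annotation, min_n=config.min_n,
                )
                scans[(cid, outcome, stratum)] = tab
                ewas_outputs.append(_write(tab, outdir, f"ewas_{cid}_{outcome}_{stratum}.tsv"))
                ewas_rows += len(tab)
    record("ewas", ewas_rows, ewas_outputs, discovery_p=config.discovery_p, min_n=config.min_n)

    # ---- meta ------------------------------------------------------------
    metas: dict[tuple[str, str], pd.DataFrame] = {}
    meta_outputs, meta_rows = [], 0
    for outcome in config.outcomes:
        for stratum in ("all", "F", "M"):
            tables = {cid: scans[(cid, outcome, stratum)] for cid in config.cohort_ids}
            meta = metaconsist.run_meta(tables, discovery_p=config.discovery_p)
            metas[(outcome, stratum)] = meta
            meta_outputs.append(_write(meta, outdir, f"meta_{outcome}_{stratum}.tsv"))
            meta_rows += len(meta)
    record("meta", meta_rows, meta_outputs, discovery_p=config.discovery_p)

    # ---- consistency tiers ----------------------------------------------
    retained: dict[tuple[str, str, str], pd.DataFrame] = {}
    cons_outputs, cons_rows = [], 0
    for (outcome, stratum), meta in metas.items():
        for tier in metaconsist.TIERS:
            kept = metaconsist.consistency_filter(meta, tier=tier, fdr_threshold=config.fdr)
            retained[(outcome, stratum, tier)] = kept
            cons_outputs.append(_write(kept, outdir, f"retained_{outcome}_{stratum}_{tier}.tsv"))
            cons_rows += len(kept)
    record("consistency", cons_rows, cons_outputs, fdr=config.fdr)

    # ---- multi-trait overlap + regions ------------------------------------
    region_outputs, region_rows = [], 0
    if len(config.outcomes) >= 2:
        overlap = metaconsist.multi_trait_overlap(
            {o: retained[(o, "all", "all_studies")] for o in config.outcomes}
        )
        region_outputs.append(_write(overlap["per_cpg"], outdir, "multi_trait_per_cpg.tsv"))
        region_outputs.append(_write(overlap["at_least"], outdir, "multi_trait_at_least.tsv"))
    for outcome in config.outcomes:
        hits = retained[(outcome, "all", "all_studies")]
        regions = metaconsist.region_filter(
            hits, annotation, max_gap_bp=config.max_gap, min_cpgs=config.min_cpgs
        )
        region_outputs.append(_write(regions, outdir, f"regions_{outcome}.tsv"))
        metaconsist.write_regions_bed(regions, outdir / f"regions_{outcome}.bed")
        region_outputs.append(f"regions_{outcome}.bed")
        region_rows += len(regions)
    record("regions", region_rows, region_outputs,
           max_gap=config.max_gap, min_cpgs=config.min_cpgs)

    # ---- sex-specific and divergent DMPs ----------------------------------
    sex_outputs, divergent_all = [], []
    for outcome in config.outcomes:
        sets = sexdiff.sex_specific_sets(
            retained[(outcome, "F", "two_of_three")], retained[(outcome, "M", "two_of_three")]
        )
        for name in ("female_only", "male_only", "shared"):
            sex_outputs.append(_write(sets[name], outdir, f"sex_{name}_{outcome}.tsv"))
        div = sexdiff.divergent_dmps(
            metas[(outcome, "F")], metas[(outcome, "M")],
            fdr_threshold=config.fdr, min_consistent_studies=2,
        )
        divergent_all.append(div)
        sex_outputs.append(_write(div, outdir, f"divergent_{outcome}.tsv"))
    divergent = pd.concat(divergent_all, ignore_index=True) if divergent_all else pd.DataFrame()
    record("sexdiff", len(divergent), sex_outputs, fdr=config.fdr)

    # ---- stratified GGMs + differential hubs ------------------------------
    node_source = "divergent"
    nodes = sorted(set(divergent["cpg_id"])) if len(divergent) else []
    if len(nodes) < config.ggm_min_nodes:
        # fall back to the strongest combined-meta CpGs so the network stage
        # always runs on something
        node_source = "top_meta"
        pool = pd.concat([metas[(o, "all")] for o in config.outcomes], ignore_index=True)
        pool = pool.reindex(pool["z"].abs().sort_values(ascending=False).index)
        nodes = list(dict.fromkeys(pool["cpg_id"]))[: max(config.ggm_min_nodes, 15)]
    ggm_outputs, flagged_rows = [], 0
    for cid, (beta, samples) in cohorts.items():
        resid = ggmnet.residualize(
            mvals[cid].loc[[n for n in nodes if n in mvals[cid].index]],
            samples,
            [c for c in covariates_for(cid, config, "F") if c != "sex"],
        )
        sex_of = samples.set_index("sample_id")["sex"]
        nets = {}
        for stratum, label in (("F", "female"), ("M", "male")):
            rows = [s for s in resid.index if sex_of.get(s) == stratum]
            nets[label] = ggmnet.estimate_ggm(
                resid.loc[rows], selection=config.ggm_selection, seed=config.seed
            )
            ggm_outputs.append(
                _write(nets[label].edge_list(), outdir, f"ggm_edges_{cid}_{label}.tsv")
            )
            ggmnet.write_graphml(nets[label], outdir / f"ggm_{cid}_{label}.graphml")
            ggm_outputs.append(f"ggm_{cid}_{label}.graphml")
        hubs = ggmnet.differential_hubs(nets["female"], nets["male"], config.diff_threshold)
        ggm_outputs.append(_write(hubs, outdir, f"hub_table_{cid}.tsv"))
        flagged = hubs[hubs["flagged"]]
        ggm_outputs.append(_write(flagged, outdir, f"hub_flagged_{cid}.tsv"))
        flagged_rows += len(flagged)
    record("ggm", max(flagged_rows, len(nodes)), ggm_outputs,
           node_source=node_source, n_nodes=len(nodes),
           selection=config.ggm_selection, diff_threshold=config.diff_threshold)

    # ---- PRS stages (first cohort carries genotype-derived scores) ---------
    prs_cid = config.cohort_ids[0]
    beta0, samples0 = cohorts[prs_cid]
    prs = synthdata.generate_prs(
        samples0, config.prs_correlation, seed=config.seed + 99, outcome=config.outcomes[0]
    )
    prs_outputs = [_write(prs, outdir, f"prs_{prs_cid}.tsv")]
    outcome0 = config.outcomes[0]
    base_scan = scans[(prs_cid, outcome0, "all")]
    adj_scan = prsrobust.prs_adjusted_ewas(
        mvals[prs_cid], samples0, prs, outcome0,
        covariates_for(prs_cid, config, "all"), min_n=config.min_n,
    )
    prs_outputs.append(_write(adj_scan, outdir, f"prs_adjusted_{prs_cid}_{outcome0}.tsv"))
    robust = prsrobust.robustness_compare(base_scan, adj_scan, rel_tol=config.rel_tol)
    prs_outputs.append(_write(robust, outdir, f"prs_robustness_{prs_cid}_{outcome0}.tsv"))
    interaction = prsrobust.interaction_scan(
        mvals[prs_cid], samples0, prs, outcome0,
        covariates_for(prs_cid, config, "all"), min_n=config.min_n,
    )
    prs_outputs.append(_write(interaction, outdir, f"prs_interaction_{prs_cid}_{outcome0}.tsv"))
    record("prs", len(robust), prs_outputs, rel_tol=config.rel_tol,
           prs_correlation=config.prs_correlation)

    # ---- epigenetic age ----------------------------------------------------
    age_rows = []
    age_outputs = []
    for cid, (beta, samples) in cohorts.items():
        birth = cid in config.birth_cohorts
        chron_col = "gestational_age" if birth else "age"
        chron = samples.set_index("sample_id")[chron_col]
        clock = ageaccel.synthetic_clock_from_cohort(
            beta, samples.assign(age=chron.to_numpy()), seed=config.seed + 7
        )
        ageaccel.write_clock(clock, outdir / f"clock_{cid}_synthetic.tsv")
        age_outputs.append(f"clock_{cid}_synthetic.tsv")
        predicted = ageaccel.predict_age(beta, clock)
        accel = ageaccel.age_acceleration(predicted, chron)
        for outcome in config.outcomes:
            res = ageaccel.associate_acceleration(
                accel, samples,
                outcome, [c for c in covariates_for(cid, config, "all") if c != chron_col],
            )
            res["cohort"] = cid
            age_rows.append(res)
    age_tab = pd.DataFrame(age_rows)
    age_outputs.append(_write(age_tab, outdir, "age_acceleration_associations.tsv"))
    record("ageaccel", len(age_tab), age_outputs)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d stages -> %s", len(manifest["stages"]), outdir)
    return manifest
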