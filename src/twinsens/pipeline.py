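"""End-to-end orchestration: simulate -> QC -> discovery -> scores ->
validation -> treatment, from a single seeded config.

Every stage writes its table to the output directory and contributes to a
machine-readable ``metrics.json``; identical config + seed gives
byte-identical metrics.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import discordance, gxe, prs, treatment
from .config import (
    ClumpParameters,
    ConfigError,
    DEFAULT_THRESHOLDS,
    DISCOVERY_QC,
    QcThresholds,
    SimulationConfig,
    TREATMENT_QC,
    validate_thresholds,
)
from .genotypes import GenotypeDataset
from .qc import compute_pcs, snp_qc
from .simulate import (
    cohort_slices,
    draw_truth,
    simulate_genotypes,
    simulate_mz_cohort,
    simulate_treatment_cohort,
    simulate_validation_cohort,
    write_fixture_set,
)


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, schema-validated up front."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    discovery_qc: QcThresholds = field(default_factory=lambda: DISCOVERY_QC)
    treatment_qc: QcThresholds = field(default_factory=lambda: TREATMENT_QC)
    clump: ClumpParameters = field(default_factory=ClumpParameters)
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    k_pcs: int = 10
    headline_threshold: float = 0.05
    output_dir: str = "twinsens_output"
    write_fixtures: bool = False

    def validate(self) -> "PipelineConfig":
        self.sim.validate()
        self.discovery_qc.validate()
        self.treatment_qc.validate()
        self.clump.validate()
        self.thresholds = validate_thresholds(self.thresholds)
        if self.headline_threshold not in self.thresholds:
            raise ConfigError(
                "invalid headline_threshold: not in thresholds")
        if self.k_pcs < 0:
            raise ConfigError("invalid k_pcs: must be >= 0")
        return self

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = SimulationConfig.from_dict(kwargs["sim"])
        for key in ("discovery_qc", "treatment_qc"):
            if key in kwargs:
                kwargs[key] = QcThresholds(**kwargs[key])
        if "clump" in kwargs:
            kwargs["clump"] = ClumpParameters(**kwargs["clump"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = tuple(kwargs["thresholds"])
        try:
            cfg = cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        return cfg.validate()

    def config_hash(self) -> str:
        """Hash of the scientific settings (output location excluded)."""
        d = asdict(self)
        d.pop("output_dir", None)
        d.pop("write_fixtures", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Run outputs: metrics, file list and the run manifest."""

    metrics: dict
    files: list[str]
    output_dir: str


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _save(df: pd.DataFrame, out_dir: str, name: str,
          files: list[str]) -> None:
    path = os.path.join(out_dir, name)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    files.append(path)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages in order and write artifacts + metrics.json."""
    config.validate()
    out_dir = config.output_dir
    os.makedirs(out_dir, exist_ok=True)
    t0 = time.time()
    files: list[str] = []
    metrics: dict = {"seed": config.sim.seed,
                     "config_hash": config.config_hash()}
    sim = config.sim
    headline = np.format_float_positional(config.headline_threshold,
                                          trim="-")

    # ---- stage: simulate --------------------------------------------
    genotypes = simulate_genotypes(sim)
    truth = draw_truth(genotypes, sim)
    twins, _ = simulate_mz_cohort(genotypes, sim, truth=truth)
    validation = simulate_validation_cohort(genotypes, truth, sim)
    records = simulate_treatment_cohort(genotypes, truth, sim)

    slices = cohort_slices(sim)
    disc_geno = genotypes.subset_samples(
        np.arange(slices["pairs"].start, slices["pairs"].stop))
    val_geno = genotypes.subset_samples(
        np.arange(slices["validation"].start, slices["validation"].stop))
    trt_geno = genotypes.subset_samples(
        np.arange(slices["treatment"].start, slices["treatment"].stop))

    if config.write_fixtures:
        write_fixture_set(genotypes,
                          {"twins": twins, "validation": validation,
                           "treatment": records},
                          truth, os.path.join(out_dir, "fixtures"))

    metrics["n_pairs"] = len(twins)
    metrics["n_validation"] = len(validation)
    metrics["n_subjects"] = len(records)
    metrics["n_variants_simulated"] = genotypes.n_variants

    # ---- stage: QC + PCs --------------------------------------------
    disc_geno, disc_report = snp_qc(disc_geno, config.discovery_qc)
    trt_geno_qc, trt_report = snp_qc(trt_geno, config.treatment_qc)
    _save(disc_report.table, out_dir, "qc_discovery.tsv", files)
    _save(trt_report.table, out_dir, "qc_treatment.tsv", files)
    metrics["n_variants_discovery_qc"] = disc_geno.n_variants
    metrics["n_variants_treatment_qc"] = trt_geno_qc.n_variants

    k = config.k_pcs
    disc_pcs = compute_pcs(disc_geno, k) if k else None
    val_pcs = compute_pcs(val_geno, k) if k else None
    trt_pcs = compute_pcs(trt_geno_qc, k) if k else None

    # ---- stage: discovery GWAS --------------------------------------
    outcome = discordance.make_discordance_outcome(twins)
    sumstats = discordance.run_discordance_gwas(disc_geno, outcome,
                                                pcs=disc_pcs)
    sumstats = discordance.flag_hits(sumstats)
    _save(sumstats, out_dir, "discovery_sumstats.tsv", files)
    metrics["n_suggestive"] = int(sumstats["suggestive"].sum())
    metrics["n_genomewide"] = int(sumstats["genomewide"].sum())

    # ---- stage: scores (clumped per target sample) ------------------
    val_retained = prs.clump_variants(sumstats, val_geno, config.clump)
    val_scores = prs.compute_scores(val_geno, sumstats, val_retained,
                                    config.thresholds)
    trt_sumstats = sumstats[sumstats["variant_id"].isin(
        set(trt_geno_qc.variants["variant_id"]))]
    trt_retained = prs.clump_variants(trt_sumstats, trt_geno_qc,
                                      config.clump)
    trt_scores = prs.compute_scores(trt_geno_qc, trt_sumstats,
                                    trt_retained, config.thresholds)
    _save(val_scores.scores.rename_axis("sample_id").reset_index(),
          out_dir, "scores_validation.tsv", files)
    _save(trt_scores.scores.rename_axis("subject_id").reset_index(),
          out_dir, "scores_treatment.tsv", files)
    metrics["n_clumped_validation"] = len(val_retained)
    metrics["n_clumped_treatment"] = len(trt_retained)
    metrics["snp_counts_validation"] = val_scores.snp_counts
    metrics["snp_counts_treatment"] = trt_scores.snp_counts

    # truth is a generative quantity: evaluate it on the pre-QC matrix
    s_val = truth.true_sensitivity(val_geno)
    s_trt = truth.true_sensitivity(trt_geno)
    metrics["score_truth_correlation"] = {
        lab: float(np.corrcoef(val_scores.scores[lab], s_val)[0, 1])
        for lab in val_scores.scores.columns}

    # ---- stage: G x E validation ------------------------------------
    adj = gxe.residualize_phenotype(validation)
    covs = validation[["ses"]].copy()
    if val_pcs is not None:
        covs = pd.concat(
            [covs.reset_index(drop=True),
             val_pcs.as_frame().reset_index(drop=True)], axis=1)
    exposure = validation["parenting_total"].to_numpy()
    sweep = gxe.gxe_threshold_sweep(adj, val_scores.scores, exposure,
                                    covariates=covs)
    _save(sweep, out_dir, "gxe_threshold_sweep.tsv", files)

    last = val_scores.scores.columns[-1]
    inter = sweep[(sweep["term"] == "score_x_exposure")]
    metrics["gxe_interaction"] = {
        row["threshold"]: {"beta": row["beta"], "p": row["p"],
                           "delta_r2_pct": row["delta_r2_pct"]}
        for _, row in inter.iterrows()}

    rge = gxe.test_gene_environment_correlation(
        val_scores.scores[last].to_numpy(),
        validation[["parenting_total", "parenting_positive",
                    "parenting_negative"]],
        covariates=covs)
    _save(rge, out_dir, "rge.tsv", files)
    metrics["rge_p"] = {row["exposure"]: row["p"]
                        for _, row in rge.iterrows()}

    cells = gxe.tertile_cell_means(adj, val_scores.scores[last].to_numpy(),
                                   exposure)
    _save(cells, out_dir, "gxe_tertiles.tsv", files)

    # ---- stage: treatment response ----------------------------------
    records = treatment.attach_scores(records, trt_scores)
    if trt_pcs is not None:
        pc_frame = trt_pcs.as_frame().rename_axis("subject_id")
        records = records.merge(pc_frame.reset_index(), on="subject_id")
        pc_cols = tuple(pc_frame.columns)
    else:
        pc_cols = ()
    table = treatment.build_response_table(records)
    score_cols = [treatment.score_column_name(lab)
                  for lab in trt_scores.scores.columns]
    effects = treatment.score_treatment_effects(table, score_cols,
                                                pc_columns=pc_cols)
    _save(effects.overall, out_dir, "treatment_overall.tsv", files)
    _save(effects.per_arm, out_dir, "treatment_per_arm.tsv", files)
    _save(effects.interactions, out_dir, "treatment_interactions.tsv",
          files)
    metrics["treatment_overall"] = {
        row["threshold"]: {"beta": row["beta"], "p": row["p"],
                           "r2_pct": row["r2_pct"]}
        for _, row in effects.overall.iterrows()}
    metrics["treatment_per_arm"] = {
        f"{row['threshold']}:{row['arm']}": {
            "beta": row["beta"], "p": row["p"], "r2_pct": row["r2_pct"]}
        for _, row in effects.per_arm.iterrows()}
    metrics["treatment_interactions"] = {
        f"{row['threshold']}:{row['contrast']}": {
            "beta": row["beta"], "p": row["p"]}
        for _, row in effects.interactions.iterrows()}

    remit = treatment.remission_table(
        records,
        records[treatment.score_column_name(headline)].to_numpy())
    _save(remit, out_dir, "remission.tsv", files)
    metrics["remission"] = {
        f"{row['arm']}:{row['score_tertile']}": row["remission_rate"]
        for _, row in remit.iterrows()}

    matches = treatment.propensity_match(
        records,
        ["csr_baseline", "age", "primary_diagnosis",
         "comorbid_internalizing", "comorbid_externalizing",
         "parental_psychopathology"])
    bal_rows = []
    for (a, b), m in matches.items():
        blk = m.balance.copy()
        blk.insert(0, "pair", f"{a}_vs_{b}")
        bal_rows.append(blk)
    balance = pd.concat(bal_rows, ignore_index=True)
    _save(balance, out_dir, "matching_balance.tsv", files)
    metrics["matching_max_abs_smd_after"] = float(
        balance["smd_after"].abs().max())
    metrics["matching_n_matched"] = len(
        treatment.matched_subject_ids(matches))

    comorb = treatment.comorbidity_sensitivity(
        table, [treatment.score_column_name(headline)],
        pc_columns=pc_cols)
    _save(comorb.interactions, out_dir,
          "treatment_interactions_comorbidity_adjusted.tsv", files)
    metrics["comorbidity_adjusted_interactions"] = {
        row["contrast"]: {"beta": row["beta"], "p": row["p"]}
        for _, row in comorb.interactions.iterrows()}

    metrics["runtime_seconds"] = round(time.time() - t0, 1)
    metrics = _round_floats(metrics)
    # runtime varies between runs; keep it out of the deterministic blob
    runtime = metrics.pop("runtime_seconds")
    metrics_path = os.path.join(out_dir, "metrics.json")
    with open(metrics_path, "w") as fh:
        json.dump(metrics, fh, sort_keys=True, indent=1)
    files.append(metrics_path)
    metrics["runtime_seconds"] = runtime

    manifest = pd.DataFrame({
        "file": [os.path.basename(p) for p in files],
        "seed": config.sim.seed,
        "config_hash": config.config_hash(),
    })
    _save(manifest, out_dir, "run_manifest.tsv", files)
    return ReportBundle(metrics=metrics, files=files, output_dir=out_dir)


def generate_report(bundle: ReportBundle) -> str:
    """Human-readable summary rendered from the metrics bundle."""
    m = bundle.metrics
    lines = ["# twinsens pipeline report", ""]
    lines.append(f"seed {m.get('seed')}  config {m.get('config_hash')}")
    lines.append(f"pairs {m.get('n_pairs')}, validation "
                 f"{m.get('n_validation')}, subjects {m.get('n_subjects')}")
    lines.append("")

    gxe_m = m.get("gxe_interaction")
    if gxe_m:
        lines.append("## Score x parenting moderation (per threshold)")
        lines.append("threshold\tbeta\tp\tdelta_r2_pct")
        for thr, row in gxe_m.items():
            lines.append(f"{thr}\t{row['beta']}\t{row['p']}"
                         f"\t{row['delta_r2_pct']}")
        lines.append("")
    else:
        lines.append("## Score x parenting moderation: unavailable")
        lines.append("")

    per_arm = m.get("treatment_per_arm")
    if per_arm:
        lines.append("## Score effects on treatment response")
        lines.append("threshold:arm\tbeta\tp\tr2_pct")
        for key, row in per_arm.items():
            lines.append(f"{key}\t{row['beta']}\t{row['p']}"
                         f"\t{row['r2_pct']}")
        lines.append("")
        lines.append("## Arm x score interaction contrasts")
        lines.append("threshold:contrast\tbeta\tp")
        for key, row in m.get("treatment_interactions", {}).items():
            lines.append(f"{key}\t{row['beta']}\t{row['p']}")
        lines.append("")
    else:
        lines.append("## Treatment response: unavailable")
        lines.append("")

    remit = m.get("remission")
    if remit:
        lines.append("## Remission by arm and score tertile")
        lines.append("arm:tertile\trate")
        for key, rate in remit.items():
            lines.append(f"{key}\t{rate}")
        lines.append("")
    return "\n".join(lines)
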