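"""End-to-end orchestration: scores -> per-cohort EWAS (Models 1 and 2) ->
inflation correction -> cross-cohort meta-analysis with Bonferroni/FDR ->
BMI-attenuation classification -> Mendelian randomization of the
Bonferroni-significant CpGs -> category enrichment of the FDR hits.

`analyse_study` drives the pipeline on an in-memory synthetic study;
`run_pipeline` is the file-based entry point that validates every input up
front and writes every stage's table plus a run manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bacon import correct_inflation
from .config import SimulationConfig
from .containers import MethylationMatrix, StudyData
from .enrich import category_overrepresentation, gene_overrepresentation
from .ewas import build_design, estimate_surrogates, fit_ewas, scale_mvalues
from .meta import attenuation as compute_attenuation
from .meta import meta_analyse
from .mr import MRResult, run_mr
from . import io as dio
from . import scores as ds
from . import synthetic

logger = logging.getLogger(__name__)


@dataclass
class MRParams:
    p_max: float = 1e-8
    r2_max: float = 0.8
    palindrome_window: tuple[float, float] = (0.42, 0.58)
    n_boot: int = 500
    seed: int = 0


@dataclass
class PipelineParams:
    scores: tuple[str, ...] = ("DASH", "HPDI", "MMDS")
    models: tuple[str, ...] = ("M1", "M2")
    k_sv: int = 2
    lambda_trigger: float = 1.05
    alpha: float = 0.05
    i2_threshold: float = 0.50
    q_alpha: float = 0.05
    attenuation_threshold: float = 10.0
    energy_bounds: dict = field(
        default_factory=lambda: dict(ds.DEFAULT_ENERGY_BOUNDS))
    standardize_mvalues: bool = True
    sv_max_cpgs: int = 1000
    mr: MRParams = field(default_factory=MRParams)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.i2_threshold <= 1:
            raise ValueError("i2_threshold must lie in [0, 1]")
        unknown = set(self.scores) - set(ds.SCORE_TO_Z)
        if unknown:
            raise ValueError(f"unknown scores: {sorted(unknown)}")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    counts: dict
    created: str

    def identity_hash(self) -> str:
        payload = json.dumps(
            {"config": self.config_hash, "version": self.version,
             "counts": self.counts}, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class StudyResult:
    scores: dict
    ewas: pd.DataFrame
    diagnostics: pd.DataFrame
    meta: dict
    attenuation: pd.DataFrame
    mr_results: list
    mr_table: pd.DataFrame
    enrichment: dict
    manifest: RunManifest


def _cohort_ewas(phenotypes: pd.DataFrame, meth: MethylationMatrix,
                 params: PipelineParams) -> tuple[pd.DataFrame, list[dict]]:
    """Score, fit and inflation-correct one cohort; returns long-format
    records and per-(score, model) diagnostics."""
    cohort = str(phenotypes["cohort"].iloc[0])
    phen = ds.filter_implausible_energy(phenotypes, params.energy_bounds)
    n_excluded = phen.attrs.get("n_energy_excluded", 0)
    values = meth.values.loc[:, phen["participant_id"]]
    if params.standardize_mvalues:
        values = scale_mvalues(values)

    raw = ds.compute_all_scores(phen)
    clustered = phen["cluster_id"].duplicated().any() \
        if "cluster_id" in phen.columns else False

    all_records = []
    diagnostics = []
    for score in params.scores:
        raw_col = ds.SCORE_TO_RAW[score]
        ok = raw[raw_col].notna()
        sub = phen.loc[ok]
        z = ds.standardize_scores(raw.loc[ok])[ds.SCORE_TO_Z[score]]
        vals = values.loc[:, sub["participant_id"]]
        base = build_design(sub, z, model="M1")
        sv = estimate_surrogates(vals, base, params.k_sv,
                                 max_cpgs=params.sv_max_cpgs)
        cluster = sub["cluster_id"] if clustered else None
        for model in params.models:
            design = build_design(sub, z, model=model, surrogates=sv)
            rec = fit_ewas(vals, design, cluster_id=cluster)
            rec, diag = correct_inflation(rec, trigger=params.lambda_trigger)
            rec = rec.reset_index()
            rec.insert(1, "score", score)
            rec.insert(2, "model", model)
            rec.insert(3, "cohort", cohort)
            all_records.append(rec)
            diagnostics.append({
                "cohort": cohort, "score": score, "model": model,
                "n": len(sub), "n_energy_excluded": n_excluded,
                "lambda_raw": diag.lambda_raw, "bias": diag.bias,
                "inflation": diag.inflation,
                "lambda_corrected": diag.lambda_corrected,
                "corrected": diag.corrected,
            })
    return pd.concat(all_records, ignore_index=True), diagnostics


def mr_results_table(results: list[MRResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"cpg": r.cpg, "outcome": r.outcome, "n_snps": r.n_snps,
               "valid": r.valid, "mean_F": r.mean_F,
               "Q_cochran": r.Q_cochran, "p_Qc": r.p_Qc}
        if r.ivw is not None:
            row.update(ivw_beta=r.ivw.beta, ivw_se=r.ivw.se, ivw_p=r.ivw.p)
            if r.binary:
                orr, lo, hi = r.odds_ratio()
                row.update(odds_ratio=orr, or_ci_low=lo, or_ci_high=hi)
        if r.egger is not None:
            row.update(egger_slope=r.egger.slope,
                       egger_intercept=r.egger.intercept,
                       egger_intercept_p=r.egger.intercept_p,
                       p_Qr=r.egger.p_Q_rucker)
        if r.wmedian is not None:
            row.update(wmedian_beta=r.wmedian.beta, wmedian_p=r.wmedian.p)
        for name, val in r.checks.items():
            row[name] = val
        rows.append(row)
    return pd.DataFrame(rows)


def analyse_study(study: StudyData, params: PipelineParams | None = None,
                  gene_sets: dict | None = None,
                  run_mr_stage: bool = True) -> StudyResult:
    """Run the full analysis on an in-memory study."""
    params = params or PipelineParams()
    records = []
    diagnostics = []
    scores_by_cohort = {}
    for name, phen in study.phenotypes.items():
        rec, diags = _cohort_ewas(phen, study.methylation[name], params)
        records.append(rec)
        diagnostics.extend(diags)
        scores_by_cohort[name] = ds.compute_all_scores(phen)
    ewas = pd.concat(records, ignore_index=True)
    diagnostics = pd.DataFrame(diagnostics)

    meta_by_model = {}
    for model in params.models:
        sub = ewas[ewas["model"] == model]
        meta_by_model[model] = meta_analyse(
            sub, i2_threshold=params.i2_threshold, q_alpha=params.q_alpha,
            alpha=params.alpha)

    atten = pd.DataFrame()
    if "M1" in meta_by_model and "M2" in meta_by_model:
        atten = compute_attenuation(meta_by_model["M1"], meta_by_model["M2"],
                                    threshold=params.attenuation_threshold)

    meta_m1 = meta_by_model.get("M1", pd.DataFrame())
    mr_results: list[MRResult] = []
    if run_mr_stage and study.mqtl is not None and not meta_m1.empty:
        hits = sorted(set(meta_m1.loc[meta_m1["bonferroni_hit"], "cpg"]))
        with_instruments = set(study.mqtl["cpg"])
        if isinstance(study.config, SimulationConfig):
            binary = set(study.config.gwas.binary_traits)
        else:
            binary = set(getattr(study.config, "binary_traits", ()))
        for cpg in hits:
            if cpg not in with_instruments:
                logger.info("no instruments for %s", cpg)
                continue
            exposure = study.mqtl[study.mqtl["cpg"] == cpg]
            ld = study.ld.get(cpg) if study.ld else None
            for trait, outcome_stats in (study.gwas or {}).items():
                mr_results.append(run_mr(
                    cpg, trait, exposure, outcome_stats, ld,
                    p_max=params.mr.p_max, r2_max=params.mr.r2_max,
                    palindrome_window=params.mr.palindrome_window,
                    n_boot=params.mr.n_boot, seed=params.mr.seed,
                    binary=trait in binary))
    mr_table = mr_results_table(mr_results)

    enrichment: dict[str, pd.DataFrame] = {}
    if not meta_m1.empty:
        fdr_hits = sorted(set(meta_m1.loc[meta_m1["fdr_q"] < params.alpha, "cpg"]))
        ann = study.universe.annotation
        tested = sorted(set(meta_m1["cpg"]))
        if fdr_hits:
            for cat in ("island_relation", "position_class"):
                enrichment[cat] = category_overrepresentation(
                    ann.loc[fdr_hits, cat], ann.loc[tested, cat])
            if gene_sets:
                fg = sorted({g for g in ann.loc[fdr_hits, "gene"] if g})
                bg = sorted({g for g in ann.loc[tested, "gene"] if g})
                if fg:
                    enrichment["genes"] = gene_overrepresentation(fg, bg, gene_sets)

    counts = {
        "cohorts": len(study.phenotypes),
        "participants": int(sum(len(p) for p in study.phenotypes.values())),
        "participants_energy_excluded": int(
            diagnostics.drop_duplicates("cohort")["n_energy_excluded"].sum()),
        "cpgs_tested": int(meta_m1["cpg"].nunique()) if not meta_m1.empty else 0,
        "m_tests": int(meta_m1.attrs.get("m_tests", 0)) if not meta_m1.empty else 0,
        "bonferroni_hits": int(meta_m1["bonferroni_hit"].sum()) if not meta_m1.empty else 0,
        "fdr_hits": int((meta_m1["fdr_q"] < params.alpha).sum()) if not meta_m1.empty else 0,
        "cpgs_with_instruments": int(len({r.cpg for r in mr_results})),
        "mr_valid_results": int(sum(r.valid for r in mr_results)),
    }
    config_repr = json.dumps(
        study.config.to_dict() if hasattr(study.config, "to_dict")
        else str(study.config), sort_keys=True, default=str)
    params_repr = json.dumps(asdict(params), sort_keys=True, default=str)
    config_hash = hashlib.sha256((config_repr + params_repr).encode()).hexdigest()
    manifest = RunManifest(config_hash, __version__, counts,
                           datetime.now(timezone.utc).isoformat())
    return StudyResult(scores_by_cohort, ewas, diagnostics, meta_by_model,
                       atten, mr_results, mr_table, enrichment, manifest)


def run_synthetic_study(config: SimulationConfig,
                        params: PipelineParams | None = None,
                        **kwargs) -> tuple[StudyData, StudyResult]:
    """Generate a synthetic study and analyse it."""
    study = synthetic.simulate_study(config)
    return study, analyse_study(study, params, **kwargs)


@dataclass
class CohortPaths:
    phenotypes: str
    methylation: str


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (see `run_pipeline`)."""

    cohorts: dict[str, CohortPaths]
    annotation: str
    out_dir: str
    mqtl: str | None = None
    gwas: dict[str, str] = field(default_factory=dict)
    ld_dir: str | None = None
    gene_sets: str | None = None
    binary_traits: tuple[str, ...] = ("T2D", "CHD")
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohorts = {name: CohortPaths(**paths)
                   for name, paths in raw.pop("cohorts").items()}
        params = PipelineParams(**raw.pop("params", {}))
        mr = params.mr
        if isinstance(mr, dict):
            params.mr = MRParams(**mr)
        return cls(cohorts=cohorts, params=params, **raw)


def _load_study(config: PipelineConfig) -> StudyData:
    """Read and validate every input before any computation (fail fast)."""
    paths = [config.annotation]
    for cp in config.cohorts.values():
        paths += [cp.phenotypes, cp.methylation]
    if config.mqtl:
        paths.append(config.mqtl)
    paths += list(config.gwas.values())
    missing = [p for p in paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    annotation = dio.read_annotation(config.annotation)
    phenotypes = {}
    methylation = {}
    for name, cp in config.cohorts.items():
        phen = dio.read_phenotypes(cp.phenotypes)
        values = dio.read_methylation(cp.methylation)
        missing_samples = set(phen["participant_id"]) - set(values.columns)
        if missing_samples:
            raise dio.SchemaError(
                f"{cp.methylation}: missing samples {sorted(missing_samples)[:5]}")
        phenotypes[name] = phen
        batch = phen.set_index("participant_id").get(
            "batch", pd.Series("batch0", index=phen["participant_id"]))
        ann = annotation.reindex(values.index)
        array = "EPIC" if "array" in ann and (ann["array"] == "EPIC").any() else "450K"
        methylation[name] = MethylationMatrix(
            values.loc[:, phen["participant_id"]], ann, batch, array)

    mqtl = dio.read_mqtl(config.mqtl) if config.mqtl else None
    gwas = {t: dio.read_gwas(p) for t, p in config.gwas.items()} or None
    ld = None
    if config.ld_dir and mqtl is not None:
        ld = {}
        for cpg in mqtl["cpg"].unique():
            p = Path(config.ld_dir) / f"ld_{cpg}.tsv"
            if p.exists():
                ld[cpg] = dio.read_ld_matrix(p)

    from .containers import CpGUniverse, GroundTruth
    universe = CpGUniverse(annotation,
                           pd.Series(0.0, index=annotation.index))
    return StudyData(config, phenotypes, methylation, universe, GroundTruth(),
                     mqtl, gwas, ld)


def run_pipeline(config: PipelineConfig) -> StudyResult:
    """File-based end-to-end run; writes every stage table and the manifest."""
    study = _load_study(config)
    gene_sets = dio.read_gmt(config.gene_sets) if config.gene_sets else None
    result = analyse_study(study, config.params, gene_sets=gene_sets)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, sc in result.scores.items():
        dio.write_table(sc, out / f"scores_{name}.tsv")
    dio.write_table(result.ewas, out / "ewas.tsv")
    dio.write_table(result.diagnostics, out / "ewas_diagnostics.tsv")
    for model, df in result.meta.items():
        dio.write_table(df, out / f"meta_{model}.tsv")
    dio.write_table(result.attenuation, out / "attenuation.tsv")
    dio.write_table(result.mr_table, out / "mr_results.tsv")
    for name, df in result.enrichment.items():
        dio.write_table(df, out / f"enrichment_{name}.tsv")
    dio.write_manifest(
        {"config_hash": result.manifest.config_hash,
         "version": result.manifest.version,
         "counts": result.manifest.counts,
         "created": result.manifest.created,
         "identity_hash": result.manifest.identity_hash()},
        out / "manifest.json")
    return result
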