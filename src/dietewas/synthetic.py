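"""Synthetic multi-cohort study generator with known ground truth.

Every downstream stage of the pipeline (scores, EWAS, meta-analysis,
Mendelian randomization) can be tested against planted effects:

* per-person latent healthy-eating factor drives correlated log-scale
  food-group intakes, BMI (negatively) and smoking (on a liability scale);
* methylation M-values carry a per-CpG baseline plus planted diet-score,
  BMI, smoking, cell-fraction and batch effects on top of unit Gaussian
  noise, so planted effects are approximately on the M-value SD scale;
* cis-mQTL instruments with 2-SNP LD blocks and outcome GWAS summary
  statistics generated under known causal effects of methylation.

One global seed yields byte-identical outputs; per-cohort substreams are
derived deterministically from (seed, cohort name).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import (CELL_TYPES, FOOD_GROUPS, INTAKE_LOG_MEANS, INTAKE_LOG_SD,
                     SCORE_NAMES, SimulationConfig)
from .containers import (CpGUniverse, DietCpG, GroundTruth, MethylationMatrix,
                         StudyData)
from . import scores as ds

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
ISLAND_PROBS = (0.31, 0.12, 0.11, 0.05, 0.05, 0.36)
POSITION_CLASSES = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "IGR")
POSITION_PROBS = (0.10, 0.13, 0.12, 0.07, 0.34, 0.04, 0.20)


def cpg_universe(config: SimulationConfig) -> CpGUniverse:
    """Deterministic CpG panel: ids, hg19-style annotation, array membership
    and a bimodal baseline M-value per CpG."""
    rng = config.substream("universe")
    m = config.n_cpgs
    ids = [f"cg{i:08d}" for i in range(1, m + 1)]
    chrom = rng.integers(1, 23, size=m)
    pos = rng.integers(10_000, 240_000_000, size=m)
    gene_idx = rng.integers(1, max(2, m // 2), size=m)
    intergenic = rng.random(m) < 0.15
    gene = np.where(intergenic, "", [f"G{g:05d}" for g in gene_idx])
    island = rng.choice(ISLAND_RELATIONS, size=m, p=ISLAND_PROBS)
    position = rng.choice(POSITION_CLASSES, size=m, p=POSITION_PROBS)
    epic_only = rng.random(m) < config.epic_only_fraction
    array = np.where(epic_only, "EPIC", "450K")
    # bimodal baseline: mostly-unmethylated and mostly-methylated CpGs
    lowmode = rng.random(m) < 0.5
    baseline = np.where(lowmode, rng.normal(-2.0, 0.5, m), rng.normal(2.0, 0.5, m))
    annotation = pd.DataFrame(
        {"chr": chrom, "pos": pos, "gene": gene, "island_relation": island,
         "position_class": position, "array": array},
        index=pd.Index(ids, name="cpg"),
    )
    return CpGUniverse(annotation, pd.Series(baseline, index=annotation.index))


def make_truth(config: SimulationConfig,
               universe: CpGUniverse | None = None) -> GroundTruth:
    """Assign planted diet, smoking and BMI effects to CpGs.

    Diet CpGs are drawn from the 450K-shared panel (so every cohort carries
    them) and assigned round-robin to the three scores; the first
    ``frac_mediated`` share act only through BMI.
    """
    universe = universe or cpg_universe(config)
    rng = config.substream("truth")
    shared = np.asarray(universe.cpgs_for_array("450K"))
    truth = GroundTruth()

    n_diet = config.n_diet_cpgs
    picked = rng.choice(shared, size=n_diet, replace=False) if n_diet else np.array([])
    n_mediated = int(round(config.frac_mediated * n_diet))
    for i, cpg in enumerate(sorted(picked)):
        score = SCORE_NAMES[i % len(SCORE_NAMES)]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if i < n_mediated:
            truth.diet_cpgs[cpg] = DietCpG(score, 0.0, True,
                                           bmi_effect=sign * config.bmi_effect_sd)
        else:
            truth.diet_cpgs[cpg] = DietCpG(score, sign * config.diet_effect_sd, False)

    remaining = np.setdiff1d(np.asarray(universe.annotation.index), picked)
    n_extra = config.n_smoking_cpgs + config.n_bmi_cpgs
    extra = rng.choice(remaining, size=min(n_extra, remaining.size), replace=False)
    for cpg in extra[: config.n_smoking_cpgs]:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        truth.smoking_cpgs[cpg] = sign * config.smoking_effect_sd
    for cpg in extra[config.n_smoking_cpgs:]:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        truth.bmi_cpgs[cpg] = sign * config.bmi_effect_sd

    for cpg in truth.diet_cpgs:
        for trait, theta in config.gwas.theta_per_trait.items():
            truth.causal_theta[(cpg, trait)] = theta
    return truth


def simulate_cohort(config: SimulationConfig, cohort_name: str) -> pd.DataFrame:
    """Phenotype table for one cohort.

    Columns include participant covariates, six cell fractions summing to 1,
    a batch label, a cluster id, all food-group intakes, and the hidden
    ``latent_healthy`` factor (kept for diagnostics and tests).
    """
    spec = config.cohort(cohort_name)
    rng = config.substream("cohort", cohort_name)
    n = spec.n

    latent = rng.standard_normal(n)
    female = rng.random(n) < spec.female_fraction
    sex = np.where(female, "F", "M")
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 20, 95)
    ethnicity = (rng.choice(["white", "nonwhite"], size=n, p=[0.5, 0.5])
                 if spec.multi_ethnic else np.repeat("white", n))

    # smoking on a liability scale coupled to the negated latent factor
    b = config.smoking_latent_beta
    liability = -b * latent + rng.standard_normal(n)
    lsd = np.sqrt(1.0 + b * b)
    current = liability > stats.norm.ppf(0.85) * lsd
    former = (~current) & (liability > stats.norm.ppf(0.55) * lsd)
    smoking = np.where(current, "current", np.where(former, "former", "never"))

    energy = np.exp(rng.normal(np.log(2000.0) + 0.10 * (~female), 0.25, n))
    bmi = np.clip(27.5 - config.bmi_latent_slope * latent
                  + rng.normal(0.0, config.bmi_noise_sd, n), 15, 60)
    cells = rng.dirichlet(config.cell_dirichlet_alpha, size=n)
    batch = np.array([f"batch{i % spec.n_batches}" for i in rng.integers(0, spec.n_batches, n)])
    if spec.clustered:
        cluster = np.array([f"{cohort_name}_fam{i // 2:05d}" for i in range(n)])
    else:
        cluster = np.array([f"{cohort_name}_ind{i:05d}" for i in range(n)])

    table = pd.DataFrame(
        {
            "participant_id": [f"{cohort_name}_{i:05d}" for i in range(n)],
            "cohort": cohort_name,
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
            "smoking": smoking,
            "bmi": bmi,
            "energy": energy,
            "cluster_id": cluster,
            "batch": batch,
            "latent_healthy": latent,
        }
    )
    for j, cell in enumerate(CELL_TYPES):
        table[cell] = cells[:, j]

    for group in FOOD_GROUPS:
        if group == "alcohol_g":
            continue
        loading = config.latent_diet_loading.get(group, 0.0)
        logx = INTAKE_LOG_MEANS[group] + loading * latent \
            + rng.normal(0.0, INTAKE_LOG_SD, n)
        table[group] = np.exp(logx)
    drinker = rng.random(n) < 0.85
    base = np.exp(rng.normal(np.log(8.0) + 0.5 * (~female), 0.8, n))
    table["alcohol_g"] = np.where(drinker, base, 0.0)
    table["alcohol"] = table["alcohol_g"]
    return table


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def simulate_methylation(phenotypes: pd.DataFrame, truth: GroundTruth,
                         config: SimulationConfig,
                         universe: CpGUniverse | None = None) -> MethylationMatrix:
    """M-value matrix for one cohort's phenotype table.

    M = baseline + diet-score effect (direct CpGs) + BMI effect + smoking
    effect + linear cell-fraction effects + batch shift (+ family intercepts
    in clustered cohorts) + Gaussian noise.  EPIC cohorts carry the extra
    EPIC-only CpGs.
    """
    if phenotypes.empty:
        raise ValueError("phenotype table is empty")
    universe = universe or cpg_universe(config)
    cohort_name = str(phenotypes["cohort"].iloc[0])
    spec = config.cohort(cohort_name)
    cpgs = universe.cpgs_for_array(spec.array)
    pos = {c: i for i, c in enumerate(cpgs)}
    m, n = len(cpgs), len(phenotypes)
    rng = config.substream("meth", cohort_name)

    Y = config.noise_sd * rng.standard_normal((m, n))
    Y += universe.baseline.loc[cpgs].to_numpy()[:, None]

    # cell-composition effects: per-CpG coefficients shared across cohorts
    gamma_rng = config.substream("cellgamma")
    gamma_all = config.cell_effect_sd * gamma_rng.standard_normal(
        (config.n_cpgs, len(CELL_TYPES)))
    gamma = gamma_all[universe.annotation.index.get_indexer(cpgs), :]
    cells = phenotypes[list(CELL_TYPES)].to_numpy()
    cells_std = (cells - cells.mean(axis=0)) / np.maximum(cells.std(axis=0, ddof=1), 1e-12)
    Y += gamma @ cells_std.T

    smoke_dose = phenotypes["smoking"].map({"never": 0.0, "former": 0.5,
                                            "current": 1.0}).to_numpy()
    for cpg, eff in truth.smoking_cpgs.items():
        if cpg in pos:
            Y[pos[cpg]] += eff * smoke_dose

    bmi_z = _standardize(phenotypes["bmi"].to_numpy())
    for cpg, eff in truth.bmi_cpgs.items():
        if cpg in pos:
            Y[pos[cpg]] += eff * bmi_z
    for cpg, planted in truth.diet_cpgs.items():
        if planted.mediated and cpg in pos:
            Y[pos[cpg]] += planted.bmi_effect * bmi_z

    if truth.diet_cpgs:
        raw = ds.compute_all_scores(phenotypes)
        z = ds.standardize_scores(raw)
        for cpg, planted in truth.diet_cpgs.items():
            if planted.mediated or cpg not in pos:
                continue
            zcol = z[ds.SCORE_TO_Z[planted.score]].to_numpy()
            Y[pos[cpg]] += planted.effect * np.nan_to_num(zcol)

    batch_labels = phenotypes["batch"].to_numpy()
    batches = np.unique(batch_labels)
    shifts = config.batch_effect_sd * rng.standard_normal((m, len(batches)))
    batch_idx = np.searchsorted(batches, batch_labels)
    Y += shifts[:, batch_idx]

    if spec.clustered and config.family_effect_sd > 0:
        clusters = phenotypes["cluster_id"].to_numpy()
        uniq, cidx = np.unique(clusters, return_inverse=True)
        fam = config.family_effect_sd * rng.standard_normal((m, len(uniq)))
        Y += fam[:, cidx]

    values = pd.DataFrame(Y, index=cpgs, columns=phenotypes["participant_id"].to_numpy())
    annotation = universe.annotation.loc[cpgs]
    batch = pd.Series(batch_labels, index=values.columns, name="batch")
    return MethylationMatrix(values, annotation, batch, spec.array)


_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


def simulate_mqtl_and_gwas(truth: GroundTruth, config: SimulationConfig
                           ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame],
                                      dict[str, pd.DataFrame]]:
    """cis-mQTL instruments and outcome GWAS for every planted diet CpG.

    Per CpG, ``snps_per_cpg`` SNPs are generated in 2-SNP LD blocks with the
    configured r^2; exposure effects get sampling noise from the exposure
    sample size and outcome effects are ``theta * b_true`` plus pleiotropy
    and outcome sampling noise.  A fraction of outcome rows has its alleles
    swapped (with the matching sign/frequency flips) so harmonization has
    real work to do.  Truth is recorded in ``truth.mqtl_effects``.
    """
    traits = list(config.gwas.theta_per_trait)
    if not traits:
        raise ValueError("no outcome traits configured")
    rng = config.substream("mqtl")
    mq = config.mqtl
    snp_counter = 1
    mqtl_rows: list[dict] = []
    gwas_rows: dict[str, list[dict]] = {t: [] for t in traits}
    ld: dict[str, pd.DataFrame] = {}

    for cpg in sorted(truth.diet_cpgs):
        J = mq.snps_per_cpg
        snps = [f"rs{snp_counter + j}" for j in range(J)]
        snp_counter += J
        chrom = int(rng.integers(1, 23))
        base_pos = int(rng.integers(10_000, 240_000_000))
        eaf = rng.uniform(*mq.maf_range, size=J)
        palindromic = rng.random(J) < mq.palindromic_fraction
        alleles = []
        for j in range(J):
            pool = _PALINDROMIC_PAIRS if palindromic[j] else _ALLELE_PAIRS
            alleles.append(pool[rng.integers(0, len(pool))])

        b_true = rng.uniform(*mq.beta_range, size=J) * rng.choice([-1.0, 1.0], size=J)
        r = np.sqrt(mq.ld_block_r2)
        ld_mat = np.eye(J)
        for j in range(0, J - 1, 2):
            if mq.ld_block_r2 > 0:
                # marginal effect of a SNP in LD with the causal partner
                b_true[j + 1] = r * b_true[j]
            ld_mat[j, j + 1] = ld_mat[j + 1, j] = mq.ld_block_r2
        ld[cpg] = pd.DataFrame(ld_mat, index=snps, columns=snps)

        se_exp = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * mq.n_exposure)
        b_exp = b_true + rng.standard_normal(J) * se_exp
        p_exp = 2.0 * stats.norm.sf(np.abs(b_exp / se_exp))
        for j in range(J):
            truth.mqtl_effects[(snps[j], cpg)] = float(b_true[j])
            mqtl_rows.append({
                "snp": snps[j], "cpg": cpg, "chr": chrom,
                "pos": base_pos + 1000 * j,
                "effect_allele": alleles[j][0], "other_allele": alleles[j][1],
                "eaf": eaf[j], "beta": b_exp[j], "se": se_exp[j],
                "p": max(p_exp[j], 5e-324), "n": mq.n_exposure,
            })

        for trait in traits:
            theta = truth.causal_theta[(cpg, trait)]
            se_out = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.gwas.n_outcome)
            pleio = rng.standard_normal(J) * config.gwas.pleiotropy_sd
            b_out = theta * b_true + pleio + rng.standard_normal(J) * se_out
            swap = rng.random(J) < 0.3
            for j in range(J):
                ea, oa = alleles[j]
                beta_j, eaf_j = b_out[j], eaf[j]
                if swap[j]:
                    ea, oa = oa, ea
                    beta_j, eaf_j = -beta_j, 1.0 - eaf_j
                gwas_rows[trait].append({
                    "snp": snps[j], "chr": chrom, "pos": base_pos + 1000 * j,
                    "effect_allele": ea, "other_allele": oa,
                    "eaf": eaf_j, "beta": beta_j, "se": se_out[j],
                    "p": max(2.0 * stats.norm.sf(abs(beta_j / se_out[j])), 5e-324),
                    "n": config.gwas.n_outcome,
                })

    mqtl = pd.DataFrame(mqtl_rows)
    gwas = {t: pd.DataFrame(rows) for t, rows in gwas_rows.items()}
    return mqtl, gwas, ld


def simulate_instruments(seed: int, J: int = 20, theta: float = 0.2,
                         n_exposure: int = 30_000, n_outcome: int = 200_000,
                         pleiotropy_sd: float = 0.0,
                         directional_pleiotropy: float = 0.0) -> pd.DataFrame:
    """Harmonized-format instrument table generated under a known causal
    effect ``theta`` of 1 SD methylation on the outcome.

    True SNP-exposure effects are U(0.05, 0.15) with random sign; observed
    effects carry sampling noise from the two sample sizes.  Balanced
    pleiotropy adds N(0, pleiotropy_sd) to each outcome effect;
    ``directional_pleiotropy`` adds a constant (oriented with the exposure
    effect) that an MR-Egger intercept should recover.
    """
    rng = np.random.default_rng(seed)
    eaf = rng.uniform(0.1, 0.9, J)
    b_true = rng.uniform(0.05, 0.15, J) * rng.choice([-1.0, 1.0], J)
    se_exp = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * n_exposure)
    se_out = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * n_outcome)
    b_exp = b_true + rng.standard_normal(J) * se_exp
    b_out = (theta * b_true + directional_pleiotropy * np.sign(b_true)
             + rng.standard_normal(J) * pleiotropy_sd
             + rng.standard_normal(J) * se_out)
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(J)],
        "beta_exp": b_exp, "se_exp": se_exp,
        "beta_out": b_out, "se_out": se_out, "eaf": eaf,
        "palindromic": np.zeros(J, dtype=bool),
        "F": (b_exp / se_exp) ** 2, "wald_ratio": b_out / b_exp,
    })


def simulate_study(config: SimulationConfig, with_genetics: bool = True) -> StudyData:
    """Generate the complete study: phenotypes and methylation for every
    cohort plus (optionally) mQTL instruments and outcome GWAS tables."""
    universe = cpg_universe(config)
    truth = make_truth(config, universe)
    phenotypes = {c.name: simulate_cohort(config, c.name) for c in config.cohorts}
    methylation = {
        name: simulate_methylation(phen, truth, config, universe)
        for name, phen in phenotypes.items()
    }
    mqtl = gwas = ld = None
    if with_genetics and truth.diet_cpgs:
        mqtl, gwas, ld = simulate_mqtl_and_gwas(truth, config)
    return StudyData(config, phenotypes, methylation, universe, truth, mqtl, gwas, ld)
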