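"""Tab-separated file formats for every pipeline table.

All tables are TSV with a header row; floats are serialized with 10
significant digits so that re-runs are diff-able.  Readers validate the
declared schema and fail fast naming the file, the missing column or the
offending row; extra columns are preserved.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CpGUniverse, DietCpG, GroundTruth, MethylationMatrix

FLOAT_FORMAT = "%.10g"


class SchemaError(ValueError):
    """A table does not match its declared schema."""


PHENOTYPE_COLUMNS = ("participant_id", "cohort", "age", "sex", "smoking",
                     "bmi", "energy")
ANNOTATION_COLUMNS = ("chr", "pos", "gene", "island_relation", "position_class")
EWAS_COLUMNS = ("cpg", "score", "model", "cohort", "beta", "se", "p", "n")
META_COLUMNS = ("cpg", "score", "k", "beta_fixed", "se_fixed", "beta_random",
                "se_random", "Q", "p_Q", "I2", "tau2", "chosen", "beta", "se",
                "p", "bonferroni_hit", "fdr_q")
GWAS_COLUMNS = ("snp", "chr", "pos", "effect_allele", "other_allele", "eaf",
                "beta", "se", "p", "n")
SCORES_COLUMNS = ("participant_id", "mmds_raw", "dash_raw", "hpdi_raw")


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _check_numeric(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{path}: column {col!r} has non-numeric value "
                f"{df[col].iloc[row]!r} at data row {row + 1}")
        df[col] = coerced


def read_table(path, required=(), numeric=(), unique_key: str | None = None,
               auto_numeric: bool = True) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_columns(df, required, path)
    _check_numeric(df, numeric, path)
    if auto_numeric:
        # extra columns (e.g. food-group intakes) come back numeric when
        # every non-missing value parses as a number
        for col in df.columns:
            if col in numeric or df[col].dtype != object:
                continue
            coerced = pd.to_numeric(df[col], errors="coerce")
            if not (coerced.isna() & df[col].notna()).any():
                df[col] = coerced
    if unique_key is not None and df[unique_key].duplicated().any():
        dup = df.loc[df[unique_key].duplicated(), unique_key].iloc[0]
        raise SchemaError(f"{path}: duplicate {unique_key} {dup!r}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_phenotypes(path) -> pd.DataFrame:
    return read_table(path, required=PHENOTYPE_COLUMNS,
                      numeric=("age", "bmi", "energy"),
                      unique_key="participant_id")


def write_phenotypes(df: pd.DataFrame, path) -> None:
    write_table(df, path)


def read_methylation(path) -> pd.DataFrame:
    """M-value matrix: first column 'cpg', remaining columns samples."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "cpg":
        raise SchemaError(f"{path}: first column must be 'cpg'")
    df = df.set_index("cpg")
    if df.index.duplicated().any():
        raise SchemaError(f"{path}: duplicate CpG ids")
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        col = values.columns[values.isna().any()][0]
        row = int(np.flatnonzero(values[col].isna())[0])
        raise SchemaError(f"{path}: non-numeric M-value in column {col!r}, "
                          f"data row {row + 1}")
    return values


def write_methylation(values: pd.DataFrame, path) -> None:
    write_table(values.rename_axis("cpg"), path, index=True)


def read_annotation(path) -> pd.DataFrame:
    df = read_table(path, required=("cpg",) + ANNOTATION_COLUMNS,
                    numeric=("chr", "pos"), unique_key="cpg")
    return df.set_index("cpg")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    write_table(annotation.rename_axis("cpg"), path, index=True)


def read_gwas(path) -> pd.DataFrame:
    return read_table(path, required=GWAS_COLUMNS,
                      numeric=("pos", "eaf", "beta", "se", "p", "n"))


def read_mqtl(path) -> pd.DataFrame:
    return read_table(path, required=("cpg",) + GWAS_COLUMNS,
                      numeric=("pos", "eaf", "beta", "se", "p", "n"))


def read_ewas(path) -> pd.DataFrame:
    return read_table(path, required=EWAS_COLUMNS,
                      numeric=("beta", "se", "p", "n"))


def read_meta(path) -> pd.DataFrame:
    df = read_table(path, required=META_COLUMNS,
                    numeric=("k", "beta_fixed", "se_fixed", "beta_random",
                             "se_random", "Q", "p_Q", "I2", "tau2", "beta",
                             "se", "p", "fdr_q"))
    df["bonferroni_hit"] = df["bonferroni_hit"].astype(str).str.lower() == "true"
    return df


def read_ld_matrix(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise SchemaError(f"{path}: LD matrix must be square with matching ids")
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Gene sets in GMT format: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}: malformed GMT line {lineno}")
            name, _desc, *genes = parts
            if name in sets:
                raise SchemaError(f"{path}: duplicate set name {name!r}")
            sets[name] = {g for g in genes if g}
    return sets


def write_gmt(collection: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, "na"] + sorted(genes)) + "\n")


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "diet_cpgs": {c: {"score": d.score, "effect": d.effect,
                          "mediated": d.mediated, "bmi_effect": d.bmi_effect}
                      for c, d in truth.diet_cpgs.items()},
        "smoking_cpgs": {c: float(e) for c, e in truth.smoking_cpgs.items()},
        "bmi_cpgs": {c: float(e) for c, e in truth.bmi_cpgs.items()},
        "causal_theta": [{"cpg": c, "trait": t, "theta": float(v)}
                         for (c, t), v in truth.causal_theta.items()],
        "mqtl_effects": [{"snp": s, "cpg": c, "beta": float(v)}
                         for (s, c), v in truth.mqtl_effects.items()],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    truth = GroundTruth()
    for c, d in payload.get("diet_cpgs", {}).items():
        truth.diet_cpgs[c] = DietCpG(d["score"], d["effect"], d["mediated"],
                                     d.get("bmi_effect", 0.0))
    truth.smoking_cpgs = dict(payload.get("smoking_cpgs", {}))
    truth.bmi_cpgs = dict(payload.get("bmi_cpgs", {}))
    for rec in payload.get("causal_theta", []):
        truth.causal_theta[(rec["cpg"], rec["trait"])] = rec["theta"]
    for rec in payload.get("mqtl_effects", []):
        truth.mqtl_effects[(rec["snp"], rec["cpg"])] = rec["beta"]
    return truth


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def write_study(study, out_dir) -> None:
    """Serialize a synthetic study to a directory of TSV/YAML files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, phen in study.phenotypes.items():
        write_phenotypes(phen, out / f"phenotypes_{name}.tsv")
    for name, meth in study.methylation.items():
        write_methylation(meth.values, out / f"methylation_{name}.tsv")
    write_annotation(study.universe.annotation, out / "annotation.tsv")
    write_truth(study.truth, out / "truth.yaml")
    if study.mqtl is not None:
        write_table(study.mqtl, out / "mqtl.tsv")
    if study.gwas:
        for trait, df in study.gwas.items():
            write_table(df, out / f"gwas_{trait}.tsv")
    if study.ld:
        for cpg, mat in study.ld.items():
            write_table(mat, out / f"ld_{cpg}.tsv", index=True)
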