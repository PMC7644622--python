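"""Tab-separated file formats for every pipeline table.

Dialect: UTF-8, tab-separated, '.' decimal separator, 'NA' for missing
values.  Schema violations raise with the offending column (and line
where available).  All tables round-trip bit-identically through their
write/read pair.  Formats are documented in docs/formats.md.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (BehaviorTable, ConnectomeSet, GenotypeTable,
                        GroundTruth, SummaryStats)

logger = logging.getLogger(__name__)

NA = "NA"


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA],
                       keep_default_na=False,
                       float_precision="round_trip", **kwargs)


def _require_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header = 1
            raise ValueError(
                f"{path}: column {col!r} has a non-numeric value at line "
                f"{line} (value {df[col][bad].iloc[0]!r}; note the dialect "
                f"uses '.' decimals and 'NA' for missing)")
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees exact float64 round-trips through text
    df.to_csv(path, sep="\t", na_rep=NA, index=index, float_format="%.17g")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# -- genotypes ---------------------------------------------------------------

def write_genotypes(genotypes: GenotypeTable, dosage_path, meta_path) -> None:
    write_table(genotypes.dosages, dosage_path)
    write_table(genotypes.snp_meta, meta_path)


def read_genotypes(dosage_path, meta_path) -> GenotypeTable:
    dosages = _read_tsv(dosage_path, index_col=0)
    dosages.index.name = "subject_id"
    dosages = _require_numeric(dosages, dosages.columns, dosage_path)
    dosages = dosages.astype(float)
    n_missing = int(dosages.isna().to_numpy().sum())
    if n_missing:
        logger.info("read_genotypes: %d missing dosage cells", n_missing)
    meta = _read_tsv(meta_path, index_col=0)
    meta.index.name = "snp_id"
    meta = _require_numeric(meta, ["gwas_p"], meta_path)
    if "maf" in meta.columns:
        meta = _require_numeric(meta, ["maf"], meta_path)
    return GenotypeTable(dosages=dosages, snp_meta=meta)


# -- connectomes -------------------------------------------------------------

def write_connectomes(connectomes: ConnectomeSet, out_dir) -> None:
    """One square TSV per subject plus a manifest (subject_id, file)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s, sid in enumerate(connectomes.subject_ids):
        fname = f"connectome_{sid}.tsv"
        mat = pd.DataFrame(connectomes.matrices[s],
                           index=connectomes.node_labels,
                           columns=connectomes.node_labels)
        mat.to_csv(out / fname, sep="\t", na_rep=NA, float_format="%.17g")
        rows.append((sid, fname))
    manifest = pd.DataFrame(rows, columns=["subject_id", "file"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)


def read_connectomes(in_dir) -> ConnectomeSet:
    in_dir = Path(in_dir)
    manifest = _read_tsv(in_dir / "manifest.tsv")
    mats, subject_ids, node_labels = [], [], None
    for rec in manifest.itertuples(index=False):
        df = _read_tsv(in_dir / rec.file, index_col=0)
        df = _require_numeric(df, df.columns, rec.file)
        if node_labels is None:
            node_labels = list(df.index)
        elif list(df.index) != node_labels:
            raise ValueError(f"{rec.file}: node ordering differs from the "
                             "first connectome")
        mats.append(df.to_numpy(float))
        subject_ids.append(rec.subject_id)
    return ConnectomeSet(subject_ids=subject_ids, node_labels=node_labels,
                         matrices=np.stack(mats))


# -- covariates --------------------------------------------------------------

def write_covariates(covariates: pd.DataFrame, path) -> None:
    write_table(covariates, path)


def read_covariates(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col=0)
    df.index.name = "subject_id"
    numeric = [c for c in df.columns if c != "scanner"]
    df = _require_numeric(df, numeric, path)
    df[numeric] = df[numeric].astype(float)
    return df


# -- behaviors ---------------------------------------------------------------

def write_behaviors(behaviors: BehaviorTable, path) -> None:
    """Values table with a second header row declaring each variable's
    type (continuous | dichotomous)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cols = list(behaviors.values.columns)
    with open(path, "w") as fh:
        fh.write("subject_id\t" + "\t".join(cols) + "\n")
        fh.write("type\t" + "\t".join(behaviors.types[c] for c in cols)
                 + "\n")
        for sid, row in behaviors.values.iterrows():
            cells = [NA if pd.isna(v) else repr(float(v)) for v in row]
            fh.write(str(sid) + "\t" + "\t".join(cells) + "\n")


def read_behaviors(path) -> BehaviorTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        type_row = fh.readline().rstrip("\n").split("\t")
    if type_row[0] != "type":
        raise ValueError(f"{path}: second row must be the 'type' row")
    cols = header[1:]
    types = pd.Series(type_row[1:], index=cols)
    bad = types[~types.isin(["continuous", "dichotomous"])]
    if len(bad):
        raise ValueError(f"{path}: unknown behavior types {dict(bad)}")
    values = _read_tsv(path, skiprows=[1], index_col=0)
    values.index.name = "subject_id"
    values = _require_numeric(values, values.columns, path)
    return BehaviorTable(values=values, types=types,
                         vulnerability_sign=pd.Series(1, index=cols))


# -- summary statistics ------------------------------------------------------

def write_sumstats(sumstats: SummaryStats, path) -> None:
    df = sumstats.table.rename(columns={
        "snp_id": "SNP", "effect_allele": "A1", "beta": "BETA", "p": "P"})
    write_table(df[["SNP", "A1", "BETA", "P"]], path, index=False)


def read_sumstats(path, phenotype: str = "unknown") -> SummaryStats:
    df = _read_tsv(path)
    missing = {"SNP", "A1", "BETA", "P"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = _require_numeric(df, ["BETA", "P"], path)
    table = df.rename(columns={"SNP": "snp_id", "A1": "effect_allele",
                               "BETA": "beta", "P": "p"})
    return SummaryStats(table=table, phenotype=phenotype)


# -- ground truth ------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    write_json({
        "causal_snp_ids": truth.causal_snp_ids,
        "signal_connection_ids": truth.signal_connection_ids,
        "true_genetic_weights": truth.true_genetic_weights,
        "true_connection_effects": truth.true_connection_effects,
        "latent_g": truth.latent_g,
        "latent_m": truth.latent_m,
        "rho": truth.rho,
        "behavior_paths": truth.behavior_paths,
    }, path)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        causal_snp_ids=d["causal_snp_ids"],
        signal_connection_ids=np.asarray(d["signal_connection_ids"], int),
        true_genetic_weights=np.asarray(d["true_genetic_weights"], float),
        true_connection_effects=np.asarray(d["true_connection_effects"],
                                           float),
        latent_g=np.asarray(d["latent_g"], float),
        latent_m=np.asarray(d["latent_m"], float),
        rho=float(d["rho"]),
        behavior_paths={k: tuple(v) for k, v in d["behavior_paths"].items()})


def write_cohort(out_dir, genotypes, connectomes, covariates, behaviors,
                 sumstats, truth) -> None:
    """Write every simulated input under one directory."""
    out = Path(out_dir)
    write_genotypes(genotypes, out / "dosages.tsv", out / "snp_meta.tsv")
    write_connectomes(connectomes, out / "connectomes")
    write_covariates(covariates, out / "covariates.tsv")
    write_behaviors(behaviors, out / "behaviors.tsv")
    write_sumstats(sumstats, out / "sumstats.tsv")
    write_ground_truth(truth, out / "ground_truth.json")
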