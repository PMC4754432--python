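"""Readers and writers for summary statistics, LD tables, and parameter configs.

Canonical table dialect: tab-separated with a header row (gzip transparently
supported by pandas).  Summary statistics carry columns SNP, CHR, POS, A1,
A2, FREQ and either Z or (BETA, SE); LD tables are whitespace-delimited
SNP_A SNP_B R2 (the PLINK --r2 output dialect); fitted parameters are a
flat TOML file with keys pi1, sigma0_sq, sigma_a_sq, sigma_b_sq.
"""

from __future__ import annotations

import json
import logging
import sys
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .empirical import LdTable, StudyInfo, SummaryStatsTable
from .model import ModelParams, heterozygosity

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_table",
    "write_ld_table",
    "read_studies_manifest",
    "write_studies_manifest",
    "read_params",
    "write_params",
    "build_table",
    "write_cohort",
    "log_event",
]

logger = logging.getLogger("gwasmix")

_MANDATORY = ("SNP", "FREQ")


class FormatError(ValueError):
    pass


def read_summary_stats(path) -> pd.DataFrame:
    """One substudy's summary statistics.

    Requires SNP and FREQ plus either Z or (BETA, SE); BETA/SE are converted
    to Z = BETA/SE, and rows with SE <= 0 are rejected (logged).
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.upper() for c in df.columns]
    missing = [c for c in _MANDATORY if c not in df.columns]
    if "Z" not in df.columns and not {"BETA", "SE"}.issubset(df.columns):
        missing.append("Z or (BETA, SE)")
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    if "Z" not in df.columns:
        bad = df["SE"].to_numpy() <= 0
        if bad.any():
            logger.warning("%s: rejecting %d rows with SE <= 0", path, int(bad.sum()))
            df = df[~bad].copy()
        df["Z"] = df["BETA"] / df["SE"]
    return df.reset_index(drop=True)


def write_summary_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ld_table(path) -> LdTable:
    """PLINK .ld dialect: whitespace-delimited SNP_A SNP_B R2."""
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except pd.errors.EmptyDataError:
        return LdTable()
    if len(df) == 0:
        return LdTable()
    df.columns = [c.upper() for c in df.columns]
    for col in ("SNP_A", "SNP_B", "R2"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    r = df["R2"].to_numpy(dtype=float)
    bad = (r < 0) | (r > 1) | ~np.isfinite(r)
    if bad.any():
        logger.warning("%s: rejecting %d rows with r2 outside [0, 1]", path, int(bad.sum()))
        df = df[~bad]
    return LdTable(
        pd.DataFrame(
            {
                "snp_a": df["SNP_A"].astype(str),
                "snp_b": df["SNP_B"].astype(str),
                "r_sq": df["R2"].astype(float),
            }
        )
    )


def write_ld_table(ld: LdTable, path) -> None:
    out = ld.pairs.rename(columns={"snp_a": "SNP_A", "snp_b": "SNP_B", "r_sq": "R2"})
    out.to_csv(path, sep="\t", index=False)


def read_studies_manifest(path) -> list[StudyInfo]:
    """TSV manifest: study_id plus (n_cases, n_controls) or n_quant."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if "study_id" not in df.columns:
        raise FormatError(f"{path}: missing column study_id")
    studies = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        if d.get("n_quant") is not None and not pd.isna(d.get("n_quant")):
            studies.append(StudyInfo(str(d["study_id"]), n_quant=float(d["n_quant"])))
        else:
            studies.append(
                StudyInfo(
                    str(d["study_id"]),
                    n_cases=float(d["n_cases"]),
                    n_controls=float(d["n_controls"]),
                )
            )
    return studies


def write_studies_manifest(studies: list[StudyInfo], path) -> None:
    pd.DataFrame(
        {
            "study_id": [s.study_id for s in studies],
            "n_cases": [s.n_cases for s in studies],
            "n_controls": [s.n_controls for s in studies],
            "n_quant": [s.n_quant for s in studies],
        }
    ).to_csv(path, sep="\t", index=False)


def read_params(path) -> ModelParams:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    try:
        return ModelParams(
            pi1=float(cfg["pi1"]),
            sigma0_sq=float(cfg["sigma0_sq"]),
            sigma_a_sq=float(cfg["sigma_a_sq"]),
            sigma_b_sq=float(cfg["sigma_b_sq"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing parameter key {exc}") from exc


def write_params(params: ModelParams, path) -> None:
    pi1, s0, sa, sb = params.as_sigma_tuple()
    with open(path, "w") as fh:
        fh.write("# two-component mixture parameters (natural scale)\n")
        fh.write(f"pi1 = {params.pi1!r}\n")
        fh.write(f"sigma0_sq = {params.sigma0_sq!r}\n")
        fh.write(f"sigma_a_sq = {params.sigma_a_sq!r}\n")
        fh.write(f"sigma_b_sq = {params.sigma_b_sq!r}\n")
        fh.write(
            f"# sd convention: pi1={pi1:.4g}, sigma0={s0:.4g}, "
            f"sigma_a={sa:.4g}, sigma_b={sb:.4g}\n"
        )


def build_table(frames: dict[str, pd.DataFrame]) -> SummaryStatsTable:
    """Merge per-study frames into one table on the SNP intersection.

    Allele labels, when present, are checked against the first study: a
    swapped (A1, A2) pair flips the z sign; label mismatches drop the SNP
    (logged).  Strand ambiguity (A/T, C/G) is not resolved here.
    """
    if not frames:
        raise ValueError("no study frames given")
    study_ids = list(frames)
    ref_id = study_ids[0]
    ref = frames[ref_id].set_index("SNP")
    common = ref.index
    for sid in study_ids[1:]:
        common = common.intersection(frames[sid].set_index("SNP").index)
    if len(common) == 0:
        raise ValueError("no SNPs shared across all studies")
    ref = ref.loc[common]
    have_alleles = {"A1", "A2"}.issubset(ref.columns)
    z_cols = []
    keep = np.ones(len(common), dtype=bool)
    for sid in study_ids:
        df = frames[sid].set_index("SNP").loc[common]
        z = df["Z"].to_numpy(dtype=float)
        if have_alleles and {"A1", "A2"}.issubset(df.columns):
            same = (df["A1"].to_numpy() == ref["A1"].to_numpy()) & (
                df["A2"].to_numpy() == ref["A2"].to_numpy()
            )
            swapped = (df["A1"].to_numpy() == ref["A2"].to_numpy()) & (
                df["A2"].to_numpy() == ref["A1"].to_numpy()
            )
            z = np.where(swapped, -z, z)
            bad = ~(same | swapped)
            if bad.any():
                logger.warning(
                    "study %s: dropping %d SNPs with mismatched alleles", sid, int(bad.sum())
                )
                keep &= ~bad
        z_cols.append(z)
    if not keep.any():
        raise ValueError("no SNPs left after allele harmonization")
    z = np.column_stack(z_cols)[keep]
    meta = ref.reset_index().loc[keep].reset_index(drop=True)
    snps = pd.DataFrame(
        {
            "snp": meta["SNP"].astype(str),
            "allele_freq": meta["FREQ"].to_numpy(dtype=float),
        }
    )
    for src, dst in (("CHR", "chrom"), ("POS", "pos"), ("A1", "a1"), ("A2", "a2")):
        if src in meta.columns:
            snps[dst] = meta[src].to_numpy()
    snps["het"] = heterozygosity(snps["allele_freq"].to_numpy())
    return SummaryStatsTable(snps, z, study_ids)


def write_cohort(cohort, outdir) -> dict[str, str]:
    """Write a synthetic cohort as per-study TSVs, a manifest, truth, and LD."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = cohort.table
    written = {}
    for k, sid in enumerate(table.study_ids):
        df = pd.DataFrame(
            {
                "SNP": table.snps["snp"],
                "FREQ": table.snps["allele_freq"],
                "Z": table.z[:, k],
            }
        )
        p = outdir / f"sumstats_{sid}.tsv"
        write_summary_stats(df, p)
        written[sid] = str(p)
    write_studies_manifest(cohort.studies, outdir / "studies.tsv")
    written["manifest"] = str(outdir / "studies.tsv")
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    written["truth"] = str(outdir / "truth.tsv")
    if cohort.ld is not None:
        write_ld_table(cohort.ld, outdir / "ld.tsv")
        written["ld"] = str(outdir / "ld.tsv")
    return written


def log_event(stream, **fields) -> None:
    """Line-delimited JSON event log (stderr by default)."""
    stream = stream or sys.stderr
    stream.write(json.dumps(fields, default=str) + "\n")
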