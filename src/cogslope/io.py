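"""Readers and writers for the package's tabular and genetic formats.

Summary statistics travel as TSV (``SNP CHR BP A1 A2 BETA SE P``),
genotypes as dosage TSV (one row per SNP) or VCF with a DS FORMAT field
(via pysam), cohorts as wide CSV (one row per person).  Tabular writers
prepend ``#``-prefixed provenance lines (config hash, seeds) and use a
fixed float format so identical inputs give byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import ParameterError
from .simulate import GenotypeMatrix, SummaryStats

FLOAT_FMT = "%.12g"


def provenance_lines(provenance: dict | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {k}: {provenance[k]}" for k in sorted(provenance)]


def write_table(df: pd.DataFrame, path, provenance: dict | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(provenance):
            fh.write(line + "\n")
        df.to_csv(fh, index=index, float_format=FLOAT_FMT, lineterminator="\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

SUMSTAT_COLUMNS = {"SNP": "snp", "CHR": "chrom", "BP": "pos", "A1": "a1",
                   "A2": "a2", "BETA": "beta", "SE": "se", "P": "p"}


def write_sumstats(ss: SummaryStats, path) -> None:
    out = ss.table.rename(columns={v: k for k, v in SUMSTAT_COLUMNS.items()})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_sumstats(path) -> SummaryStats:
    tab = pd.read_csv(path, sep="\t")
    missing = set(SUMSTAT_COLUMNS) - set(tab.columns)
    if missing:
        raise ParameterError(f"summary-stat file lacks columns {sorted(missing)}")
    return SummaryStats(tab.rename(columns=SUMSTAT_COLUMNS))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def write_dosage_tsv(geno: GenotypeMatrix, path, person_ids=None) -> None:
    """One row per SNP: metadata columns then per-person dosages."""
    ids = list(person_ids) if person_ids is not None else [f"P{i + 1:05d}" for i in range(geno.n)]
    out = geno.snps.copy()
    dos = pd.DataFrame(geno.dosage.T, columns=ids)
    out = pd.concat([out.reset_index(drop=True), dos.reset_index(drop=True)], axis=1)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_dosage_tsv(path) -> tuple[GenotypeMatrix, list[str]]:
    tab = pd.read_csv(path, sep="\t")
    meta_cols = ["snp", "chrom", "pos", "a1", "a2", "maf"]
    missing = set(meta_cols) - set(tab.columns)
    if missing:
        raise ParameterError(f"dosage file lacks columns {sorted(missing)}")
    ids = [c for c in tab.columns if c not in meta_cols]
    dosage = tab[ids].to_numpy(dtype=float).T
    return GenotypeMatrix(dosage, tab[meta_cols].copy()), ids


CONTIG_LENGTH = 250_000_000


def write_vcf(geno: GenotypeMatrix, path, person_ids=None) -> None:
    """Write dosages as an uncompressed VCF with a DS FORMAT field.

    REF is the non-effect allele (a2) and ALT the dosage-counted effect
    allele (a1), so DS counts ALT copies as usual.
    """
    ids = list(person_ids) if person_ids is not None else [f"P{i + 1:05d}" for i in range(geno.n)]
    header = pysam.VariantHeader()
    for c in sorted(set(geno.snps["chrom"])):
        header.contigs.add(str(c), length=CONTIG_LENGTH)
    header.formats.add("DS", 1, "Float", "Estimated alternate allele dosage")
    for pid in ids:
        header.add_sample(pid)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, row in geno.snps.iterrows():
            rec = vcf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(row["a2"], row["a1"]),
                id=row["snp"],
            )
            for s, pid in enumerate(ids):
                rec.samples[pid]["DS"] = float(geno.dosage[s, j])
            vcf.write(rec)


def read_vcf(path) -> tuple[GenotypeMatrix, list[str]]:
    """Read a VCF into a dosage matrix, preferring DS over GT."""
    with pysam.VariantFile(str(path)) as vcf:
        ids = list(vcf.header.samples)
        rows = []
        dosages = []
        for rec in vcf:
            ds = np.empty(len(ids))
            for s, pid in enumerate(ids):
                sample = rec.samples[pid]
                if "DS" in sample and sample["DS"] is not None:
                    ds[s] = float(sample["DS"])
                else:
                    gt = sample.get("GT", (None, None))
                    ds[s] = np.nan if gt[0] is None else float(sum(g for g in gt if g))
            dosages.append(ds)
            af = np.nanmean(ds) / 2.0
            rows.append(
                {
                    "snp": rec.id,
                    "chrom": int(rec.contig),
                    "pos": rec.pos,
                    "a1": rec.alts[0],
                    "a2": rec.ref,
                    "maf": min(af, 1 - af),
                }
            )
    dosage = np.asarray(dosages).T if dosages else np.zeros((len(ids), 0))
    return GenotypeMatrix(dosage, pd.DataFrame(rows)), ids


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def write_cohort(cohort: pd.DataFrame, path, provenance: dict | None = None) -> None:
    truth_cols = [c for c in cohort.columns if c.startswith("true_")]
    write_table(cohort.drop(columns=truth_cols), path, provenance)
    if truth_cols:
        sidecar = Path(path).with_name(Path(path).stem + "_truth.csv")
        write_table(cohort[["person_id"] + truth_cols], sidecar, provenance)


def read_cohort(path) -> pd.DataFrame:
    cohort = read_table(path)
    sidecar = Path(path).with_name(Path(path).stem + "_truth.csv")
    if sidecar.exists():
        truth = read_table(sidecar)
        cohort = cohort.merge(truth, on="person_id", how="left")
    return cohort
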