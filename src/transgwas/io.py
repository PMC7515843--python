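"""File formats: daner summary statistics, dosage VCF, sample tables.

daner tables are whitespace/tab-delimited with columns CHR SNP BP A1 A2
FRQ INFO OR SE P Nca Nco (effect sizes as odds ratios; internal tables
carry BETA = log OR). Cohorts round-trip as VCF with a DS (dosage)
FORMAT field plus a tab-separated sample table (ID, sex, phenotype 1/2,
batch).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simcohort import CohortPanel, ReferencePanel

__all__ = [
    "read_daner",
    "write_daner",
    "write_vcf_dosage",
    "read_vcf_dosage",
    "write_sample_table",
    "read_sample_table",
    "write_population_map",
]

DANER_COLUMNS = ["CHR", "SNP", "BP", "A1", "A2", "FRQ", "INFO", "OR", "SE", "P", "Nca", "Nco"]


def write_daner(stats_df: pd.DataFrame, path: str) -> None:
    """Write an association table in daner layout (OR column, tab-separated)."""
    df = stats_df.copy()
    if "OR" not in df.columns and "BETA" in df.columns:
        df["OR"] = np.exp(df["BETA"])
    cols = [c for c in DANER_COLUMNS if c in df.columns]
    extra = [c for c in ["DIR", "Q", "P_Q", "I2", "P_RE2", "NEFF"] if c in df.columns]
    df[cols + extra].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_daner(path: str) -> pd.DataFrame:
    """Read a daner-style table; derives BETA = log(OR) when absent."""
    df = pd.read_csv(path, sep=r"\s+")
    if "BETA" not in df.columns and "OR" in df.columns:
        df["BETA"] = np.log(df["OR"])
    return df


def write_vcf_dosage(cohort: CohortPanel, path: str) -> None:
    """Write cohort dosages as a VCF with GT-free DS FORMAT records."""
    ids = cohort.samples["ID"].tolist()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        if cohort.info is not None:
            fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        for j in range(cohort.n_snps):
            v = cohort.variants.iloc[j]
            if cohort.info is not None and np.isfinite(cohort.info[j]):
                info = f"INFO={cohort.info[j]:.4f}"
            else:
                info = "."
            ds = "\t".join(
                "." if np.isnan(x) else f"{x:.3f}" for x in cohort.dosages[j]
            )
            fh.write(f"{v['CHR']}\t{v['BP']}\t{v['SNP']}\t{v['A2']}\t{v['A1']}\t.\t.\t{info}\tDS\t{ds}\n")


def read_vcf_dosage(vcf_path: str, sample_table_path: str | None = None) -> CohortPanel:
    """Read a DS-format dosage VCF (optionally joining a sample table)."""
    header = None
    rows = []
    with open(vcf_path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header = line.rstrip("\n").split("\t")
                continue
            rows.append(line.rstrip("\n").split("\t"))
    if header is None:
        raise ValueError(f"no #CHROM header in {vcf_path}")
    ids = header[9:]
    variants = pd.DataFrame(
        {
            "CHR": [r[0] for r in rows],
            "SNP": [r[2] for r in rows],
            "BP": [int(r[1]) for r in rows],
            "A1": [r[4] for r in rows],  # ALT = counted allele
            "A2": [r[3] for r in rows],
        }
    )
    dosages = np.array(
        [[np.nan if x == "." else float(x) for x in r[9:]] for r in rows], dtype=float
    )
    info = np.array(
        [
            float(r[7].split("INFO=")[1].split(";")[0]) if "INFO=" in r[7] else np.nan
            for r in rows
        ]
    )
    if sample_table_path is not None:
        samples = read_sample_table(sample_table_path)
        samples = samples.set_index("ID").loc[ids].reset_index()
    else:
        samples = pd.DataFrame({"ID": ids, "sex": 0, "phenotype": 0, "batch": "NA"})
    return CohortPanel(variants=variants, dosages=dosages, samples=samples, info=info)


def write_sample_table(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_population_map(panel: ReferencePanel, path: str) -> None:
    """TSV mapping reference individuals to population labels."""
    rows = []
    for pop in panel.populations:
        n_ind = panel.haplotypes[pop].shape[0] // 2
        rows.extend({"ID": f"{pop}_{i:04d}", "population": pop} for i in range(n_ind))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
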