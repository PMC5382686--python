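"""Readers and writers for the pipeline's on-disk formats.

Twin phenotypes travel as CSV (one row per pair, empty field = missing);
GWAS summaries and dosage matrices as TSV with PLINK-association-style
column names; genotypes additionally as VCF with genotype calls (written and
read through pysam), where the dosage is the count of the ALT allele and the
ALT allele is the scored effect allele.  Floats are written at 12
significant digits so text round-trips preserve value equality.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .simulate import TWIN_COLUMNS, GenotypePanel

__all__ = [
    "write_twin_csv", "read_twin_csv",
    "write_gwas_tsv", "read_gwas_tsv",
    "write_dosage_tsv", "read_dosage_tsv",
    "write_vcf", "read_vcf",
    "load_config",
]

_FLOAT_FMT = "%.12g"


def write_twin_csv(data: pd.DataFrame, path) -> None:
    data[TWIN_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_twin_csv(path) -> pd.DataFrame:
    data = pd.read_csv(path, dtype={"pair_id": str, "zygosity": str})
    missing = [c for c in TWIN_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return data[TWIN_COLUMNS]


_GWAS_COLS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P"]


def write_gwas_tsv(summary: pd.DataFrame, path) -> None:
    cols = [c for c in _GWAS_COLS + ["MAF"] if c in summary.columns]
    summary[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gwas_tsv(path) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str,
                                             "A1": str, "A2": str})
    missing = [c for c in _GWAS_COLS if c not in out.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return out


def write_dosage_tsv(panel: GenotypePanel, dosage_path, snp_path=None) -> None:
    """Dosage matrix TSV (rows = individuals, columns = SNP ids), plus an
    optional SNP metadata sidecar TSV (id, chrom, pos, a1, a2, maf)."""
    df = pd.DataFrame(panel.dosages, columns=panel.snps["id"])
    df.insert(0, "individual", [f"ind{i + 1:06d}" for i in range(panel.n)])
    df.to_csv(dosage_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    if snp_path is not None:
        panel.snps.to_csv(snp_path, sep="\t", index=False,
                          float_format=_FLOAT_FMT)


def read_dosage_tsv(dosage_path, snp_path=None) -> GenotypePanel:
    df = pd.read_csv(dosage_path, sep="\t")
    ids = [c for c in df.columns if c != "individual"]
    dosages = df[ids].to_numpy(dtype=float)
    if snp_path is not None:
        snps = pd.read_csv(snp_path, sep="\t",
                           dtype={"id": str, "chrom": str, "a1": str, "a2": str})
        snps = snps.set_index("id").loc[ids].reset_index()
    else:
        # metadata-free fallback: synthetic positions, unknown alleles
        maf = dosages.mean(axis=0) / 2.0
        maf = np.minimum(maf, 1 - maf)
        snps = pd.DataFrame({
            "id": ids, "chrom": "1",
            "pos": 1 + np.arange(len(ids)) * 1000,
            "a1": "N", "a2": "N", "maf": maf,
        })
    return GenotypePanel(dosages, snps)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write integer dosages as VCF v4.2 genotype calls (ALT = effect
    allele, dosage = ALT count; non-integer dosages are rejected)."""
    d = panel.dosages
    if not np.allclose(d, np.round(d), atol=1e-9):
        raise ValueError("VCF genotype output requires integer dosages")
    d = np.round(d).astype(int)
    header = pysam.VariantHeader()
    for chrom in pd.unique(panel.snps["chrom"].astype(str)):
        header.contigs.add(chrom, length=2_000_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.info.add("MAF", 1, "Float", "Minor allele frequency")
    samples = [f"ind{i + 1:06d}" for i in range(panel.n)]
    for s in samples:
        header.add_sample(s)
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, row in enumerate(panel.snps.itertuples(index=False)):
            rec = vcf.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1,
                stop=int(row.pos), id=row.id,
                alleles=(row.a2, row.a1))  # REF = other, ALT = effect
            rec.info["MAF"] = float(row.maf)
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = gt_codes[d[i, j]]
            vcf.write(rec)


def read_vcf(path) -> GenotypePanel:
    """Read a GT-based VCF back into a panel (dosage = ALT allele count;
    missing calls become NaN)."""
    ids, chroms, poss, a1s, a2s, mafs, rows = [], [], [], [], [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            ids.append(rec.id)
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            a2s.append(rec.ref)
            a1s.append(rec.alts[0])
            col = np.empty(len(samples))
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                col[i] = np.nan if gt is None or None in gt else sum(gt)
            rows.append(col)
            if "MAF" in rec.info:
                mafs.append(float(rec.info["MAF"]))
            else:
                af = np.nanmean(col) / 2.0
                mafs.append(min(af, 1 - af))
    snps = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss,
                         "a1": a1s, "a2": a2s, "maf": mafs})
    return GenotypePanel(np.column_stack(rows) if rows else
                         np.empty((len(samples), 0)), snps)


def load_config(path, schema: dict) -> dict:
    """Load a flat JSON config, apply defaults from ``schema`` (a mapping of
    key -> default) and reject unknown keys."""
    raw = json.loads(Path(path).read_text())
    unknown = set(raw) - set(schema)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(schema)
    cfg.update(raw)
    missing = [k for k, v in cfg.items() if v is None]
    if missing:
        raise ValueError(f"config keys missing with no default: {missing}")
    return cfg
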