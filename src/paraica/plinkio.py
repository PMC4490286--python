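"""PLINK 1 binary (BED/BIM/FAM) and delimited-text genotype I/O.

The BED writer emits the standard SNP-major layout: three magic bytes
``0x6c 0x1b 0x01`` followed by one row of ``ceil(n_subjects / 4)`` bytes
per SNP, two bits per genotype (00 = homozygous A1, 10 = heterozygous,
11 = homozygous A2, 01 = missing).  A1 is written as the minor (B)
allele, so the additive dosage equals the A1-allele count.

Subject metadata beyond the six FAM columns travels in a sidecar TSV
(``<prefix>.subjects.tsv``) written and read alongside the trio.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import GenotypeTable

__all__ = ["write_plink", "read_plink", "write_dosage_text", "read_dosage_text"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes indexed by dosage 0,1,2; 0b01 is the missing code
_DOSAGE_TO_CODE = np.array([0b11, 0b10, 0b00], dtype=np.uint8)
_CODE_TO_DOSAGE = {0b00: 2.0, 0b10: 1.0, 0b11: 0.0, 0b01: np.nan}

_SEX_CODE = {"M": 1, "F": 2}
_PHENO_CODE = {"control": 1, "case1": 2, "case2": 2}


def write_plink(table: GenotypeTable, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam plus the subject-metadata sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = table.n_subjects

    codes = np.full(table.dosages.shape, 0b01, dtype=np.uint8)  # missing
    called = np.isfinite(table.dosages)
    codes[called] = _DOSAGE_TO_CODE[table.dosages[called].astype(int)]

    # pack 4 genotypes per byte, subject index advancing through bit pairs
    n_bytes = (n + 3) // 4
    padded = np.zeros((table.n_snps, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    shifts = np.tile([0, 2, 4, 6], n_bytes)
    packed = np.bitwise_or.reduce(
        (padded << shifts).reshape(table.n_snps, n_bytes, 4), axis=2
    ).astype(np.uint8)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": table.snps["chrom"],
            "snp_id": table.snps["snp_id"],
            "cm": 0,
            "pos": table.snps["pos"],
            "a1": table.snps["allele_b"],
            "a2": table.snps["allele_a"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    subj = table.subjects
    fam = pd.DataFrame(
        {
            "fid": subj["subject_id"],
            "iid": subj["subject_id"],
            "pat": 0,
            "mat": 0,
            "sex": subj["sex"].map(_SEX_CODE).fillna(0).astype(int),
            "pheno": subj["group"].map(_PHENO_CODE).fillna(-9).astype(int),
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    subj.to_csv(str(prefix) + ".subjects.tsv", sep="\t", index=False)


def read_plink(prefix: str | Path) -> GenotypeTable:
    """Read a BED/BIM/FAM trio (plus sidecar metadata if present)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK BED file")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    # unpack bit pairs
    pairs = np.stack([(body >> s) & 0b11 for s in (0, 2, 4, 6)], axis=2)
    codes = pairs.reshape(m, n_bytes * 4)[:, :n]
    lut = np.full(4, np.nan)
    for c, d in _CODE_TO_DOSAGE.items():
        lut[c] = d
    dosages = lut[codes].T

    sidecar = Path(str(prefix) + ".subjects.tsv")
    if sidecar.exists():
        subjects = pd.read_csv(sidecar, sep="\t")
    else:
        subjects = pd.DataFrame(
            {
                "subject_id": fam["iid"].astype(str),
                "group": fam["pheno"].map({1: "control", 2: "case1"}),
                "age": np.nan,
                "sex": fam["sex"].map({1: "M", 2: "F"}),
                "site": "unknown",
                "ethnicity": "unknown",
            }
        )
    snps = pd.DataFrame(
        {
            "snp_id": bim["snp_id"].astype(str),
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "allele_a": bim["a2"],
            "allele_b": bim["a1"],
        }
    )
    return GenotypeTable(dosages, snps, subjects)


def write_dosage_text(table: GenotypeTable, prefix: str | Path) -> None:
    """Write dosages as TSV (subjects × SNPs) with SNP and subject sidecars."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        table.dosages,
        index=table.subjects["subject_id"],
        columns=table.snps["snp_id"],
    )
    df.to_csv(str(prefix) + ".dosages.tsv", sep="\t")
    table.snps.to_csv(str(prefix) + ".snps.tsv", sep="\t", index=False)
    table.subjects.to_csv(str(prefix) + ".subjects.tsv", sep="\t", index=False)


def read_dosage_text(prefix: str | Path) -> GenotypeTable:
    prefix = Path(prefix)
    df = pd.read_csv(str(prefix) + ".dosages.tsv", sep="\t", index_col=0)
    snps = pd.read_csv(str(prefix) + ".snps.tsv", sep="\t")
    subjects = pd.read_csv(str(prefix) + ".subjects.tsv", sep="\t")
    return GenotypeTable(df.to_numpy(dtype=float), snps, subjects)
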