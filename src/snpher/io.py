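"""Readers/writers for the field's standard flat formats.

PLINK1 BED/BIM/FAM (SNP-major, two bits per genotype), PLINK --pheno/--covar
layout tables (FID IID then columns, missing = "NA"), the GCTA GRM binary
triple (grm.bin / grm.N.bin / grm.id), the ``.l2.ldscore`` TSV dialect and a
(SNP, A1, A2, N, Z) summary-statistics TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MISSING, GenotypePanel

__all__ = [
    "write_plink",
    "read_plink",
    "write_pheno",
    "read_pheno",
    "write_grm_bin",
    "read_grm_bin",
    "write_ldscore",
    "read_ldscore",
    "write_sumstats",
    "read_sumstats",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# PLINK 2-bit codes -> allele1 dosage: 00 hom A1 (2), 10 het (1), 11 hom A2 (0),
# 01 missing
_CODE_FOR_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}
_DOSAGE_FOR_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam (BIM positions 1-based, A1 = counted)."""
    prefix = Path(prefix)
    v = panel.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "snp": v["snp"],
            "cm": 0,
            "pos": v["pos"],
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    sexcode = np.where(panel.sex == "male", 1, 2)
    fam = pd.DataFrame(
        {
            "fid": panel.sample_ids,
            "iid": panel.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": sexcode,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)

    n, m = panel.n_samples, panel.n_variants
    codes = np.empty((n, m), dtype=np.uint8)
    for dos, code in _CODE_FOR_DOSAGE.items():
        codes[panel.dosages == dos] = code
    # pack 4 samples per byte, SNP-major
    n_pad = (-n) % 4
    if n_pad:
        codes = np.vstack([codes, np.zeros((n_pad, m), dtype=np.uint8)])
    c = codes.T.reshape(m, -1, 4)  # (m, ceil(n/4), 4)
    packed = c[..., 0] | (c[..., 1] << 2) | (c[..., 2] << 4) | (c[..., 3] << 6)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK1 fileset written in SNP-major order."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK1 BED file")
    body = raw[3:].reshape(m, -1)
    codes = np.empty((m, body.shape[1] * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _DOSAGE_FOR_CODE[codes[:, :n]].T.copy()

    variants = bim[["chrom", "snp", "pos", "a1", "a2"]].copy()
    obs = dosages != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(obs, dosages, 0).sum(0) / (2.0 * obs.sum(0))
    variants["maf"] = np.minimum(freq, 1 - freq)
    variants["info"] = 1.0
    return GenotypePanel(
        sample_ids=fam["iid"].astype(str).to_numpy(),
        sex=np.where(fam["sex"].to_numpy() == 1, "male", "female"),
        variants=variants.reset_index(drop=True),
        dosages=dosages,
    )


def write_pheno(table: pd.DataFrame, path: str | Path, columns=None) -> None:
    """PLINK --pheno/--covar layout: FID IID then columns, missing = NA."""
    cols = list(columns) if columns is not None else list(table.columns)
    out = pd.DataFrame({"FID": table.index, "IID": table.index})
    for c in cols:
        out[c] = table[c].to_numpy()
    out.to_csv(path, sep=" ", index=False, na_rep="NA")


def read_pheno(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA", "-9"])
    return df.set_index("IID").drop(columns=["FID"])


# ---------------------------------------------------------------------------
# GCTA GRM binary triple


def write_grm_bin(prefix: str | Path, grm_values: np.ndarray, sample_ids, n_snps: int) -> None:
    """Write grm.bin (lower triangle, float32), grm.N.bin and grm.id."""
    prefix = Path(prefix)
    n = grm_values.shape[0]
    tril = np.tril_indices(n)
    grm_values[tril].astype("<f4").tofile(str(prefix) + ".grm.bin")
    np.full(len(tril[0]), n_snps, dtype="<f4").tofile(str(prefix) + ".grm.N.bin")
    pd.DataFrame({"fid": sample_ids, "iid": sample_ids}).to_csv(
        str(prefix) + ".grm.id", sep="\t", header=False, index=False
    )


def write_grm_tsv(path: str | Path, grm_values: np.ndarray, sample_ids) -> None:
    """Plain long-format GRM TSV (id1, id2, relatedness), lower triangle."""
    n = grm_values.shape[0]
    i, j = np.tril_indices(n)
    ids = np.asarray(sample_ids)
    pd.DataFrame(
        {"id1": ids[i], "id2": ids[j], "relatedness": grm_values[i, j]}
    ).to_csv(path, sep="\t", index=False)


def read_grm_bin(prefix: str | Path) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (matrix, sample_ids, n_snps) from a GCTA GRM binary triple."""
    prefix = str(prefix)
    ids = pd.read_csv(prefix + ".grm.id", sep="\t", header=None)[1].astype(str).to_numpy()
    n = len(ids)
    vals = np.fromfile(prefix + ".grm.bin", dtype="<f4").astype(np.float64)
    a = np.zeros((n, n))
    tril = np.tril_indices(n)
    a[tril] = vals
    a = a + a.T - np.diag(np.diag(a))
    nsnp = int(np.fromfile(prefix + ".grm.N.bin", dtype="<f4")[0])
    return a, ids, nsnp


# ---------------------------------------------------------------------------
# LD scores and summary statistics


def write_ldscore(table: pd.DataFrame, path: str | Path, m_total: int | None = None) -> None:
    """Write the ``.l2.ldscore`` TSV dialect (CHR, SNP, BP, L2) and, when
    ``m_total`` is given, an ``.l2.M`` sidecar with the SNP count."""
    out = table.rename(columns={"chrom": "CHR", "snp": "SNP", "pos": "BP", "l2": "L2"})
    out[["CHR", "SNP", "BP", "L2"]].to_csv(path, sep="\t", index=False)
    if m_total is not None:
        Path(str(path) + ".M").write_text(f"{m_total}\n")


def read_ldscore(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"CHR": "chrom", "SNP": "snp", "BP": "pos", "L2": "l2"})


def write_sumstats(table: pd.DataFrame, path: str | Path) -> None:
    """(SNP, A1, A2, N, Z) summary-statistics TSV."""
    table[["SNP", "A1", "A2", "N", "Z"]].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
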