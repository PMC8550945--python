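"""PLINK 1 .bed/.bim/.fam and plain-text dosage I/O.

The .bed format is SNP-major with 2-bit codes per genotype:
00 = hom A1, 10 = het, 11 = hom A2, 01 = missing.  Here A1 is the reference
allele and A2 the counted (alternate) allele, so the stored code maps
directly onto the alternate-allele dosage.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# dosage -> 2-bit code (alt-allele count); 3 stands for missing
_DOS2CODE = np.array([0b00, 0b10, 0b11, 0b01], dtype=np.uint8)
_CODE2DOS = {0b00: 0, 0b10: 1, 0b11: 2, 0b01: -1}


def write_plink(prefix: str, geno: GenotypeMatrix, ped: Pedigree | None = None) -> None:
    n, m = geno.n, geno.m
    dos = geno.dosages.astype(np.int64).copy()
    if geno.mask is not None:
        dos[geno.mask] = 3
    codes = _DOS2CODE[dos]  # n x m
    n_bytes = (n + 3) // 4
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_MAGIC)
        packed = np.zeros((m, n_bytes), dtype=np.uint8)
        for k in range(4):
            sel = codes[k::4, :].T  # m x ceil(n/4)
            packed[:, : sel.shape[1]] |= sel << (2 * k)
        fh.write(packed.tobytes())
    bim = geno.snp_meta
    pd.DataFrame(
        {
            "chrom": bim["chrom"],
            "snp": bim["snp"],
            "cm": 0,
            "pos": bim["pos"],
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    ).to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    if ped is not None:
        ped.to_fam(f"{prefix}.fam")
    else:
        pd.DataFrame(
            {"fid": geno.ids, "iid": geno.ids, "pat": 0, "mat": 0, "sex": 0, "pheno": -9}
        ).to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)


def read_plink(prefix: str) -> GenotypeMatrix:
    fam = pd.read_csv(
        f"{prefix}.fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        f"{prefix}.bim", sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
    )
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        if fh.read(3) != _MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK .bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n + 3) // 4
    raw = raw.reshape(m, n_bytes)
    dos = np.zeros((n, m), dtype=np.int8)
    mask = np.zeros((n, m), dtype=bool)
    lut_dos = np.array([_CODE2DOS[c] for c in range(4)], dtype=np.int8)
    for k in range(4):
        rows = np.arange(k, n, 4)  # individuals occupying bit-pair k of their byte
        codes = (raw[:, rows // 4].T >> (2 * k)) & 0b11  # len(rows) x m
        vals = lut_dos[codes]
        dos[rows, :] = np.where(vals < 0, 0, vals)
        mask[rows, :] = vals < 0
    return GenotypeMatrix(
        ids=fam["iid"].to_numpy(),
        dosages=dos,
        snp_meta=bim[["snp", "chrom", "pos", "a1", "a2"]].reset_index(drop=True),
        mask=mask if mask.any() else None,
    )


def write_dosage_text(path: str, geno: GenotypeMatrix) -> None:
    """Plain-text alternative: header SNP metadata columns then one dosage
    column per individual (PLINK .traw layout)."""
    out = pd.DataFrame(
        {
            "CHR": geno.snp_meta["chrom"],
            "SNP": geno.snp_meta["snp"],
            "POS": geno.snp_meta["pos"],
            "COUNTED": geno.snp_meta["a2"],
            "ALT": geno.snp_meta["a1"],
        }
    )
    dos = geno.dosages.astype(object)
    if geno.mask is not None:
        dos[geno.mask] = "NA"
    cols = pd.DataFrame(dos.T, columns=list(geno.ids))
    pd.concat([out, cols], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_text(path: str) -> GenotypeMatrix:
    tab = pd.read_csv(path, sep="\t")
    meta = pd.DataFrame(
        {
            "snp": tab["SNP"],
            "chrom": tab["CHR"],
            "pos": tab["POS"],
            "a1": tab["ALT"],
            "a2": tab["COUNTED"],
        }
    )
    ids = [c for c in tab.columns if c not in ("CHR", "SNP", "POS", "COUNTED", "ALT")]
    vals = tab[ids].to_numpy().T.astype(float)
    mask = np.isnan(vals)
    dos = np.where(mask, 0, vals).astype(np.int8)
    return GenotypeMatrix(
        ids=np.array(ids), dosages=dos, snp_meta=meta, mask=mask if mask.any() else None
    )
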