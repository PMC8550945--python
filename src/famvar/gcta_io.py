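"""GCTA GRM file formats.

Binary triplet ``prefix.grm.bin`` (lower triangle, float32), ``prefix.grm.N.bin``
(per-pair SNP counts, float32) and ``prefix.grm.id`` (FID IID text), plus the
gzipped text format (i j n value).
"""
from __future__ import annotations

import gzip

import numpy as np
import pandas as pd

from .matrices import RelationshipMatrix


def _tril_indices(n: int):
    return np.tril_indices(n)


def write_grm_bin(prefix: str, mat: RelationshipMatrix, n_snps: int | None = None) -> None:
    n = mat.n
    i, j = _tril_indices(n)
    mat.values[i, j].astype("<f4").tofile(f"{prefix}.grm.bin")
    m = n_snps if n_snps is not None else mat.provenance.get("m_snps", 1)
    np.full(len(i), m, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": mat.ids, "iid": mat.ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm_bin(prefix: str, role: str = "G") -> RelationshipMatrix:
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None, dtype=str)[1].to_numpy()
    n = len(ids)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    i, j = _tril_indices(n)
    if len(vals) != len(i):
        raise ValueError(f"{prefix}.grm.bin has {len(vals)} entries, expected {len(i)}")
    M = np.zeros((n, n))
    M[i, j] = vals
    M[j, i] = vals
    nsnp = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    m = int(nsnp[0]) if len(nsnp) else 0
    return RelationshipMatrix(values=M, ids=ids, role=role, provenance={"m_snps": m})


def write_grm_gz(prefix: str, mat: RelationshipMatrix, n_snps: int | None = None) -> None:
    n = mat.n
    m = n_snps if n_snps is not None else mat.provenance.get("m_snps", 1)
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{m}\t{mat.values[i, j]:.6f}\n")
    pd.DataFrame({"fid": mat.ids, "iid": mat.ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm_gz(prefix: str, role: str = "G") -> RelationshipMatrix:
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None, dtype=str)[1].to_numpy()
    n = len(ids)
    M = np.zeros((n, n))
    with gzip.open(f"{prefix}.grm.gz", "rt") as fh:
        for line in fh:
            i, j, _, v = line.split()
            M[int(i) - 1, int(j) - 1] = M[int(j) - 1, int(i) - 1] = float(v)
    return RelationshipMatrix(values=M, ids=ids, role=role)
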