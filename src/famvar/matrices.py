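"""Relationship matrices for the GKFCS variance decomposition.

G is the genomic relationship matrix (GRM) over standardized SNP dosages;
K captures close-pedigree genetic effects by zeroing sub-threshold GRM
entries; F, C and S are 0/1 indicator matrices for shared nuclear-family,
couple and sibling environments.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

ROLES = ("G", "K", "F", "C", "S")


class MatrixError(ValueError):
    pass


@dataclass
class RelationshipMatrix:
    """Symmetric n x n similarity matrix tagged with its model role."""

    values: np.ndarray
    ids: np.ndarray
    role: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise MatrixError("matrix shape does not match id count")
        if len(set(self.ids)) != n:
            raise MatrixError("ids must be unique")
        if not np.isfinite(self.values).all():
            raise MatrixError("matrix entries must be finite")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise MatrixError("matrix must be symmetric")
        if self.role not in ROLES:
            raise MatrixError(f"role must be one of {ROLES}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reorder(self, new_ids) -> "RelationshipMatrix":
        idx = {iid: i for i, iid in enumerate(self.ids)}
        try:
            perm = np.array([idx[i] for i in new_ids])
        except KeyError as e:  # pragma: no cover
            raise MatrixError(f"unknown id {e.args[0]!r}") from e
        return RelationshipMatrix(
            values=self.values[np.ix_(perm, perm)],
            ids=np.asarray(new_ids),
            role=self.role,
            provenance=dict(self.provenance),
        )


def compute_grm(
    geno: GenotypeMatrix, maf_floor: float = 0.01, dtype=np.float64
) -> RelationshipMatrix:
    """GRM with the standard GREML estimator.

    A_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),
    with allele frequencies p_i estimated from the sample itself.  SNPs with
    minor allele frequency below ``maf_floor`` (or monomorphic) are excluded;
    missing calls are mean-imputed per SNP first.  ``dtype=np.float32``
    halves time and memory on large panels (entry error ~1e-5, ample for
    REML; keep float64 when exact reproducibility of small examples matters).
    """
    if geno.n < 2:
        raise MatrixError("need at least 2 individuals for a GRM")
    p = geno.allele_freq()  # mean-imputation leaves per-SNP frequencies intact
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= max(maf_floor, 1e-12)
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise MatrixError("all SNPs excluded by the MAF floor")
    # accumulate Z Z' in SNP chunks to bound memory at large panels
    keep_idx = np.flatnonzero(keep)
    G = np.zeros((geno.n, geno.n), dtype=dtype)
    for lo in range(0, len(keep_idx), 4000):
        sel = keep_idx[lo: lo + 4000]
        X = geno.dosages[:, sel].astype(dtype)
        if geno.mask is not None:
            X = np.where(geno.mask[:, sel], (2.0 * p[sel]).astype(dtype), X)
        Z = (X - 2.0 * p[sel]) / np.sqrt(2.0 * p[sel] * (1.0 - p[sel]))
        Z = Z.astype(dtype, copy=False)
        G += Z @ Z.T
    G = G.astype(np.float64) / keep.sum()
    G = (G + G.T) / 2.0
    return RelationshipMatrix(
        values=G,
        ids=geno.ids,
        role="G",
        provenance={"m_snps": int(keep.sum()), "maf_floor": maf_floor,
                    "n_excluded": n_excluded},
    )


def threshold_to_kinship(grm: RelationshipMatrix, cutoff: float = 0.025) -> RelationshipMatrix:
    """K matrix: zero all off-diagonal GRM entries below ``cutoff``.

    The diagonal is kept as-is, so K retains each individual's genomic
    self-relatedness while dropping distant-relative noise.
    """
    K = grm.values.copy()
    off = ~np.eye(grm.n, dtype=bool)
    K[off & (K < cutoff)] = 0.0
    prov = dict(grm.provenance)
    prov["kinship_cutoff"] = cutoff
    return RelationshipMatrix(values=K, ids=grm.ids, role="K", provenance=prov)


def pedigree_kinship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Path-counting alternative to the thresholded-GRM K (2 x kinship)."""
    return RelationshipMatrix(
        values=ped.additive_relationship(), ids=ped.ids, role="K",
        provenance={"method": "path_counting"},
    )


def build_env_matrix(ped: Pedigree, couples, role: str) -> RelationshipMatrix:
    """Shared-environment indicator matrix.

    F: entry 1 for parent-offspring, full-sibling and couple pairs;
    S: full siblings (both parents shared); C: couple pairs.  Diagonal 1.
    ``couples`` is an iterable of (id_a, id_b) pairs or CouplePair objects.
    """
    if role not in ("F", "C", "S"):
        raise MatrixError("environmental role must be F, C or S")
    idx = {iid: i for i, iid in enumerate(ped.ids)}
    couple_pairs = []
    for c in couples:
        a, b = (c.id_a, c.id_b) if hasattr(c, "id_a") else (c[0], c[1])
        if a not in idx or b not in idx:
            raise MatrixError(f"couple pair ({a!r}, {b!r}) references unknown id")
        couple_pairs.append((a, b))

    if role == "C":
        pairs = couple_pairs
    elif role == "S":
        pairs = ped.full_sib_pairs()
    else:
        pairs = ped.parent_offspring_pairs() + ped.full_sib_pairs() + couple_pairs

    M = np.eye(ped.n)
    for a, b in pairs:
        i, j = idx[a], idx[b]
        M[i, j] = M[j, i] = 1.0
    if role == "F":
        n_f = int(M.sum() - ped.n) // 2
        n_c = len(set(tuple(sorted(p)) for p in couple_pairs))
        if n_f - n_c < 10:
            warnings.warn(
                "F and C matrices differ by fewer than 10 pairs; the couple "
                "and family components may not be identifiable",
                stacklevel=2,
            )
    return RelationshipMatrix(values=M, ids=ped.ids, role=role, provenance={"n_pairs": len(pairs)})
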