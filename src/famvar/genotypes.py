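"""Genotype container (dosage matrix plus SNP metadata)."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_META_COLUMNS = ["snp", "chrom", "pos", "a1", "a2"]


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """n_individuals x n_snps matrix of alternate-allele dosages in {0,1,2}.

    ``mask`` (optional, same shape, boolean) marks missing calls; masked
    entries are ignored when allele frequencies are computed and are
    mean-imputed by consumers that need complete data.
    """

    ids: np.ndarray
    dosages: np.ndarray
    snp_meta: pd.DataFrame
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise GenotypeError("dosages must be 2-D (individuals x SNPs)")
        n, m = self.dosages.shape
        if len(self.ids) != n:
            raise GenotypeError("ids length does not match dosage rows")
        if len(self.snp_meta) != m:
            raise GenotypeError("snp_meta length does not match dosage columns")
        missing = [c for c in _META_COLUMNS if c not in self.snp_meta.columns]
        if missing:
            raise GenotypeError(f"snp_meta missing columns: {missing}")
        valid = np.isin(self.dosages, (0, 1, 2))
        if self.mask is not None:
            valid |= self.mask
        if not valid.all():
            raise GenotypeError("dosage values must be 0, 1 or 2 (missing via mask)")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP, ignoring masked calls."""
        d = self.dosages.astype(float)
        if self.mask is None:
            return d.mean(axis=0) / 2.0
        d = np.where(self.mask, np.nan, d)
        return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_individuals(self, keep_ids) -> "GenotypeMatrix":
        idx = {iid: i for i, iid in enumerate(self.ids)}
        rows = np.array([idx[i] for i in keep_ids])
        return GenotypeMatrix(
            ids=np.asarray(keep_ids),
            dosages=self.dosages[rows],
            snp_meta=self.snp_meta.reset_index(drop=True),
            mask=None if self.mask is None else self.mask[rows],
        )

    def snp_index(self, snp_id) -> int:
        hits = np.flatnonzero((self.snp_meta["snp"] == snp_id).to_numpy())
        if len(hits) == 0:
            raise KeyError(f"SNP {snp_id!r} not present")
        return int(hits[0])
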