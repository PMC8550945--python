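"""Pedigree container and relationship queries.

A pedigree is a table of individuals with parent links, sex, family id and a
generation label.  It is the substrate for the pedigree-derived relationship
matrices (K via path counting, F/C/S indicator matrices) and for couple
discovery by shared child.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MALE = "M"
FEMALE = "F"

_COLUMNS = ["id", "father_id", "mother_id", "sex", "family_id", "generation"]


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Individuals with parent links.

    ``table`` has columns id, father_id, mother_id, sex, family_id,
    generation.  Missing parents are ``None``/NaN.  Parents must either both
    be present or both be missing for simulated gene dropping.
    """

    table: pd.DataFrame
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        ids = self.table["id"]
        if ids.duplicated().any():
            raise PedigreeError("duplicate individual ids in pedigree")
        self._index = {iid: i for i, iid in enumerate(ids)}
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.table)

    def loc(self, iid) -> int:
        return self._index[iid]

    def validate(self) -> None:
        tab = self.table
        known = set(tab["id"])
        for col in ("father_id", "mother_id"):
            listed = tab[col].dropna()
            unknown = set(listed) - known
            if unknown:
                raise PedigreeError(f"{col} references unknown ids: {sorted(unknown)[:5]}")
        sex = tab.set_index("id")["sex"]
        fathers = tab["father_id"].dropna().unique()
        mothers = tab["mother_id"].dropna().unique()
        if (sex.loc[fathers] != MALE).any():
            raise PedigreeError("a listed father is not male")
        if (sex.loc[mothers] != FEMALE).any():
            raise PedigreeError("a listed mother is not female")
        one_parent = tab["father_id"].isna() != tab["mother_id"].isna()
        if one_parent.any():
            raise PedigreeError("individuals with exactly one known parent are not supported")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn-style peel: repeatedly remove individuals whose parents are
        # already removed; leftovers indicate a cycle / self-ancestry.
        tab = self.table
        placed: set = set()
        pending = list(tab.itertuples(index=False))
        while pending:
            rest = []
            for row in pending:
                f, m = row.father_id, row.mother_id
                if (pd.isna(f) or f in placed) and (pd.isna(m) or m in placed):
                    placed.add(row.id)
                else:
                    rest.append(row)
            if len(rest) == len(pending):
                raise PedigreeError("pedigree contains a cycle (individual is its own ancestor)")
            pending = rest

    # -- relationship queries ----------------------------------------------
    def founders(self) -> np.ndarray:
        tab = self.table
        return tab.loc[tab["father_id"].isna() & tab["mother_id"].isna(), "id"].to_numpy()

    def trios(self) -> pd.DataFrame:
        """Rows (child, father, mother) for every child with known parents."""
        tab = self.table
        kids = tab[tab["father_id"].notna()]
        return kids[["id", "father_id", "mother_id"]].rename(columns={"id": "child_id"})

    def parent_offspring_pairs(self) -> list[tuple]:
        out = []
        for row in self.trios().itertuples(index=False):
            out.append((row.child_id, row.father_id))
            out.append((row.child_id, row.mother_id))
        return out

    def full_sib_pairs(self) -> list[tuple]:
        out = []
        trios = self.trios()
        for (_, _), grp in trios.groupby(["father_id", "mother_id"], sort=False):
            kids = grp["child_id"].tolist()
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    out.append((kids[i], kids[j]))
        return out

    def sibships(self) -> list[list]:
        """Groups of full siblings (shared father and mother), size >= 2."""
        trios = self.trios()
        return [
            grp["child_id"].tolist()
            for _, grp in trios.groupby(["father_id", "mother_id"], sort=False)
            if len(grp) >= 2
        ]

    def nuclear_families(self) -> list[list]:
        """Parent couples with their children (members of one nuclear unit)."""
        out = []
        trios = self.trios()
        for (f, m), grp in trios.groupby(["father_id", "mother_id"], sort=False):
            out.append([f, m] + grp["child_id"].tolist())
        return out

    def extended_components(self) -> list[list]:
        """Connected components of the parent-child graph.

        Families linked by a marriage with children merge into one extended
        component; components are the independent blocks of the pedigree
        relationship matrix.
        """
        parent = {iid: iid for iid in self.ids}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for row in self.trios().itertuples(index=False):
            union(row.child_id, row.father_id)
            union(row.child_id, row.mother_id)
        groups: dict = {}
        for iid in self.ids:
            groups.setdefault(find(iid), []).append(iid)
        return list(groups.values())

    def subset(self, keep_ids) -> "Pedigree":
        """Sub-pedigree on ``keep_ids`` (parents outside the set are cut)."""
        keep = set(keep_ids)
        sub = self.table[self.table["id"].isin(keep)].copy()
        cut = ~(sub["father_id"].isin(keep) & sub["mother_id"].isin(keep))
        sub.loc[cut, ["father_id", "mother_id"]] = np.nan
        return Pedigree(sub.reset_index(drop=True))

    def additive_relationship(self) -> np.ndarray:
        """Expected additive genetic relationship matrix A = 2 x kinship.

        Henderson's tabular recursion over individuals sorted so that parents
        precede offspring.  A_ii = 1 + 0.5*A(father, mother);
        A_ij = 0.5*(A(j, father_i) + A(j, mother_i)).
        """
        order = self._topological_order()
        n = self.n
        pos = {iid: i for i, iid in enumerate(order)}
        tab = self.table.set_index("id")
        A = np.zeros((n, n))
        for iid in order:
            i = pos[iid]
            f, m = tab.at[iid, "father_id"], tab.at[iid, "mother_id"]
            fi = pos[f] if pd.notna(f) else None
            mi = pos[m] if pd.notna(m) else None
            if fi is None and mi is None:
                A[i, i] = 1.0
            else:
                A[i, i] = 1.0 + 0.5 * A[fi, mi]
                row = 0.5 * (A[fi, :i] + A[mi, :i])
                A[i, :i] = row
                A[:i, i] = row
        # reorder back to table order
        perm = np.array([pos[iid] for iid in self.ids])
        return A[np.ix_(perm, perm)]

    def _topological_order(self) -> list:
        tab = self.table
        placed: set = set()
        order: list = []
        pending = list(tab.itertuples(index=False))
        while pending:
            rest = []
            for row in pending:
                f, m = row.father_id, row.mother_id
                if (pd.isna(f) or f in placed) and (pd.isna(m) or m in placed):
                    placed.add(row.id)
                    order.append(row.id)
                else:
                    rest.append(row)
            if len(rest) == len(pending):  # pragma: no cover - validate() guards
                raise PedigreeError("cycle detected")
            pending = rest
        return order

    # -- I/O -----------------------------------------------------------------
    def to_fam(self, path) -> None:
        """Write a PLINK .fam-style file (FID IID PAT MAT SEX PHENO)."""
        tab = self.table
        fam = pd.DataFrame(
            {
                "fid": tab["family_id"],
                "iid": tab["id"],
                "pat": tab["father_id"].fillna("0"),
                "mat": tab["mother_id"].fillna("0"),
                "sex": tab["sex"].map({MALE: 1, FEMALE: 2}),
                "pheno": -9,
            }
        )
        fam.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_fam(cls, path) -> "Pedigree":
        fam = pd.read_csv(
            path, sep=r"\s+", header=None,
            names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
        )
        tab = pd.DataFrame(
            {
                "id": fam["iid"],
                "father_id": fam["pat"].replace("0", np.nan),
                "mother_id": fam["mat"].replace("0", np.nan),
                "sex": fam["sex"].map({"1": MALE, "2": FEMALE}),
                "family_id": fam["fid"],
            }
        )
        tab["generation"] = _infer_generation(tab)
        return cls(tab)


def _infer_generation(tab: pd.DataFrame) -> np.ndarray:
    gen = {}
    pending = list(tab.itertuples(index=False))
    while pending:
        rest = []
        for row in pending:
            f, m = row.father_id, row.mother_id
            if pd.isna(f) and pd.isna(m):
                gen[row.id] = 0
            elif f in gen and m in gen:
                gen[row.id] = max(gen[f], gen[m]) + 1
            else:
                rest.append(row)
        if len(rest) == len(pending):
            raise PedigreeError("cannot infer generations (cycle or missing parent)")
        pending = rest
    return np.array([gen[i] for i in tab["id"]])
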