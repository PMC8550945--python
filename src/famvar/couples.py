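"""Couple identification.

Two discovery routes mirror family-cohort practice: (1) the shared-child
rule on a pedigree (a couple is a father-mother combination appearing on at
least one child), and (2) a household-roster filter cascade (two recruited
individuals sharing a household id, both reporting household size 2 and
living with a husband/wife/partner, with age-gap and matching-parental-age
exclusions to remove mislabelled pairs such as cohabiting siblings).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .pedigree import MALE, Pedigree


class CoupleError(ValueError):
    pass


@dataclass(frozen=True)
class CouplePair:
    id_a: str
    id_b: str
    method: str  # shared_child | household
    sex_composition: str  # opposite | same | unknown
    shared_children: int = 0

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise CoupleError("a couple pair must contain two distinct individuals")

    @property
    def ids(self) -> tuple:
        return (self.id_a, self.id_b)


def find_couples_shared_child(ped: Pedigree, genotyped_ids=None) -> list[CouplePair]:
    """One pair per (father, mother) combination with >=1 shared child.

    Restricted to ``genotyped_ids`` when given.  Individuals appearing in
    several parental combinations (serial partnerships) are reduced to the
    combination with the most shared children, ties broken by id order, so
    each person belongs to at most one pair.
    """
    trios = ped.trios()
    bad = trios["father_id"] == trios["mother_id"]
    if bad.any():
        raise CoupleError("child listing the same individual as both parents")
    counts = (
        trios.groupby(["father_id", "mother_id"], sort=False)
        .size()
        .reset_index(name="shared_children")
    )
    if genotyped_ids is not None:
        keep = set(genotyped_ids)
        counts = counts[
            counts["father_id"].isin(keep) & counts["mother_id"].isin(keep)
        ]
    counts = counts.sort_values(
        ["shared_children", "father_id", "mother_id"],
        ascending=[False, True, True],
        kind="stable",
    )
    used: set = set()
    sex = ped.table.set_index("id")["sex"]
    out = []
    for row in counts.itertuples(index=False):
        if row.father_id in used or row.mother_id in used:
            continue
        used.update((row.father_id, row.mother_id))
        comp = "opposite" if sex[row.father_id] != sex[row.mother_id] else "same"
        out.append(
            CouplePair(
                id_a=row.father_id,
                id_b=row.mother_id,
                method="shared_child",
                sex_composition=comp,
                shared_children=int(row.shared_children),
            )
        )
    return out


_ROSTER_COLUMNS = [
    "id", "household_id", "household_size", "relationship", "age",
    "father_age", "mother_age", "sex",
]


@dataclass
class HouseholdFilterLog:
    """Per-step removal counts of the household cascade."""

    counts: dict = field(default_factory=dict)

    def record(self, step: str, n: int) -> None:
        self.counts[step] = int(n)


def find_couples_household(
    records: pd.DataFrame,
    max_age_gap: float = 10.0,
    require_unrelated: bool = False,
) -> tuple[list[CouplePair], list[CouplePair], HouseholdFilterLog]:
    """Household filter cascade; returns (opposite_sex, same_sex, log).

    Steps, in order: (1) group by household id; (2) keep households with
    exactly two recruited members, both reporting household size 2 and a
    husband/wife/partner relationship; (3) drop pairs with age gap >
    ``max_age_gap`` years; (4) drop pairs whose father ages match or whose
    mother ages match (both non-missing) — the cohabiting-sibling guard;
    (5) optionally require the ancestry/unrelatedness flag.
    """
    if len(records) == 0:
        raise CoupleError("no household records supplied")
    missing = [c for c in _ROSTER_COLUMNS if c not in records.columns]
    if missing:
        raise CoupleError(f"roster missing columns: {missing}")
    if records["id"].duplicated().any():
        raise CoupleError("duplicated individual id across household records")
    log = HouseholdFilterLog()

    usable = records[records["household_id"].notna()]
    grouped = usable.groupby("household_id", sort=False)
    pairs = []
    n_households = grouped.ngroups
    for _, grp in grouped:
        if len(grp) != 2:
            continue
        if not (grp["household_size"] == 2).all():
            continue
        if not (grp["relationship"] == "husband_wife_partner").all():
            continue
        pairs.append(grp.sort_values("id"))
    log.record("households_considered", n_households)
    log.record("pass_size_and_relationship", len(pairs))

    kept = []
    for grp in pairs:
        a, b = grp.iloc[0], grp.iloc[1]
        if abs(a["age"] - b["age"]) > max_age_gap:
            continue
        kept.append(grp)
    log.record("removed_age_gap", len(pairs) - len(kept))
    pairs, kept = kept, []

    for grp in pairs:
        a, b = grp.iloc[0], grp.iloc[1]
        father_match = pd.notna(a["father_age"]) and pd.notna(b["father_age"]) and (
            a["father_age"] == b["father_age"]
        )
        mother_match = pd.notna(a["mother_age"]) and pd.notna(b["mother_age"]) and (
            a["mother_age"] == b["mother_age"]
        )
        if father_match or mother_match:
            continue
        kept.append(grp)
    log.record("removed_parental_age_match", len(pairs) - len(kept))
    pairs, kept = kept, []

    if require_unrelated:
        if "ancestry_unrelated_flag" not in records.columns:
            raise CoupleError("roster lacks ancestry_unrelated_flag")
        for grp in pairs:
            if grp["ancestry_unrelated_flag"].all():
                kept.append(grp)
        log.record("removed_related_or_ancestry", len(pairs) - len(kept))
        pairs = kept

    opposite, same = [], []
    for grp in pairs:
        a, b = grp.iloc[0], grp.iloc[1]
        comp = "opposite" if a["sex"] != b["sex"] else "same"
        pair = CouplePair(
            id_a=str(a["id"]), id_b=str(b["id"]), method="household", sex_composition=comp
        )
        (opposite if comp == "opposite" else same).append(pair)
    log.record("opposite_sex_pairs", len(opposite))
    log.record("same_sex_pairs", len(same))
    return opposite, same, log


def pair_table(
    pairs: list[CouplePair],
    pheno: pd.DataFrame,
    trait: str = "trait",
    sex_col: str = "sex",
) -> pd.DataFrame:
    """One row per couple with both members' trait and covariates.

    Pairs with a member missing from the phenotype table (or with a missing
    trait value) are dropped.  For opposite-sex pairs member A is the male.
    """
    seen: dict = {}
    for p in pairs:
        for iid in p.ids:
            if iid in seen and seen[iid] != p:
                raise CoupleError(f"individual {iid!r} appears in more than one pair")
            seen[iid] = p
    tab = pheno.set_index("id")
    rows = []
    n_dropped = 0
    covars = [c for c in pheno.columns if c not in ("id", trait)]
    for p in pairs:
        a, b = p.id_a, p.id_b
        if a not in tab.index or b not in tab.index:
            n_dropped += 1
            continue
        ra, rb = tab.loc[a], tab.loc[b]
        if pd.isna(ra[trait]) or pd.isna(rb[trait]):
            n_dropped += 1
            continue
        if p.sex_composition == "opposite" and sex_col in tab.columns:
            if rb[sex_col] == MALE and ra[sex_col] != MALE:
                a, b, ra, rb = b, a, rb, ra
        row = {"id_a": a, "id_b": b, "trait_a": ra[trait], "trait_b": rb[trait]}
        for c in covars:
            row[f"{c}_a"] = ra[c]
            row[f"{c}_b"] = rb[c]
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = n_dropped
    return out


def pairs_to_frame(pairs: list[CouplePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "method": p.method,
                "sex_composition": p.sex_composition,
                "shared_children": p.shared_children,
            }
            for p in pairs
        ]
    )


def frame_to_pairs(tab: pd.DataFrame) -> list[CouplePair]:
    return [
        CouplePair(
            id_a=str(r.id_a),
            id_b=str(r.id_b),
            method=getattr(r, "method", "shared_child"),
            sex_composition=getattr(r, "sex_composition", "unknown"),
            shared_children=int(getattr(r, "shared_children", 0)),
        )
        for r in tab.itertuples(index=False)
    ]
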