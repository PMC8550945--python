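"""Synthetic pedigrees, genotypes and phenotypes with known variance fractions.

The generator emulates a family-based cohort: nuclear families of two
founder parents (a couple) and one or more children, biallelic SNPs in HWE
transmitted by Mendelian gene dropping, and a phenotype built explicitly
from the GKFCS components

    Y = Xb + u_G + u_K + u_F + u_C + u_S + eps.

Each component is scaled to its configured share of the phenotypic variance,
so downstream variance-decomposition code can be checked against ground
truth.  Options cover liability-threshold binary traits, ordinal
interval-coded traits, an indirect partner-genotype effect (delta times the
partner's standardized genetic value) and phenotypic or genotypic
assortative mating by rank-matching.

One global seed drives a hierarchical stream (pedigree -> genotypes ->
phenotype), so each stage is reproducible on its own.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from .genotypes import GenotypeMatrix
from .pedigree import FEMALE, MALE, Pedigree

_STAGE_PEDIGREE, _STAGE_GENOTYPES, _STAGE_PHENOTYPE = 0, 1, 2


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Multi-generation families.

    Each family starts as two founder parents (a couple) with 1+ children.
    With ``third_generation`` a ``mate_fraction`` share of those children are
    paired across families and have children of their own, creating the
    grandparental, avuncular and cousin relationships of a family cohort
    (these are what separate close-pedigree genetic sharing from the
    nuclear-family environment in the variance model).
    """
    rng = _stage_rng(config, _STAGE_PEDIGREE)
    lo, hi = config.offspring_range
    n_off = rng.integers(lo, hi + 1, size=config.n_families)
    rows = []
    gen1 = []  # (id, sex, family index)
    for f in range(config.n_families):
        fam = f"fam{f:05d}"
        father, mother = f"{fam}_p1", f"{fam}_p2"
        rows.append((father, None, None, MALE, fam, 0))
        rows.append((mother, None, None, FEMALE, fam, 0))
        for j in range(n_off[f]):
            sex = MALE if rng.random() < 0.5 else FEMALE
            iid = f"{fam}_o{j + 1}"
            rows.append((iid, father, mother, sex, fam, 1))
            gen1.append((iid, sex, f))

    if config.third_generation and config.n_families >= 2 and config.mate_fraction > 0:
        males = [(i, f) for i, s, f in gen1 if s == MALE]
        females = [(i, f) for i, s, f in gen1 if s == FEMALE]
        rng.shuffle(males)
        rng.shuffle(females)
        n_target = int(round(config.mate_fraction * len(gen1) / 2.0))
        n_pairs = 0
        used_f: set = set()
        for m_id, m_fam in males:
            if n_pairs >= n_target:
                break
            pick = next(
                (k for k, (f_id, f_fam) in enumerate(females)
                 if k not in used_f and f_fam != m_fam),
                None,
            )
            if pick is None:
                break
            used_f.add(pick)
            f_id, _ = females[pick]
            fam = f"fam{m_fam:05d}"
            for j in range(rng.integers(lo, hi + 1)):
                sex = MALE if rng.random() < 0.5 else FEMALE
                rows.append((f"{fam}_g{n_pairs}_{j + 1}", m_id, f_id, sex, fam, 2))
            n_pairs += 1

    tab = pd.DataFrame(
        rows, columns=["id", "father_id", "mother_id", "sex", "family_id", "generation"]
    )
    return Pedigree(tab)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _snp_meta(config: SimConfig, freqs: np.ndarray) -> pd.DataFrame:
    m = config.n_snps
    chroms = 1 + (np.arange(m) * 22) // m
    pos = np.empty(m, dtype=int)
    for c in range(1, 23):
        sel = chroms == c
        pos[sel] = 50_000 * (1 + np.arange(sel.sum()))
    return pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(m)],
            "chrom": chroms,
            "pos": pos,
            "a1": "A",  # reference allele
            "a2": "G",  # alternate (counted) allele; non-strand-ambiguous
            "freq": freqs,
        }
    )


def simulate_genotypes(
    ped: Pedigree,
    config: SimConfig,
    founder_dosages: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Founders drawn binomially under HWE; descendants by gene dropping.

    Each transmitted allele is sampled independently from each parent
    (probability dosage/2 of passing the alternate allele), so trios are
    Mendelian-consistent by construction.
    """
    rng = _stage_rng(config, _STAGE_GENOTYPES)
    if freqs is None:
        freqs = rng.uniform(*config.maf_range, size=config.n_snps)
    tab = ped.table
    n, m = ped.n, config.n_snps
    dos = np.zeros((n, m), dtype=np.int8)
    founder_mask = tab["father_id"].isna().to_numpy()
    if founder_dosages is None:
        dos[founder_mask] = rng.binomial(2, freqs, size=(founder_mask.sum(), m)).astype(np.int8)
    else:
        dos[founder_mask] = founder_dosages
    # drop generation by generation so parents are always filled first
    idx = {iid: i for i, iid in enumerate(tab["id"])}
    for gen in sorted(tab.loc[~founder_mask, "generation"].unique()):
        rows = tab[(tab["generation"] == gen) & ~founder_mask]
        child_i = np.array([idx[i] for i in rows["id"]])
        fa_i = np.array([idx[i] for i in rows["father_id"]])
        mo_i = np.array([idx[i] for i in rows["mother_id"]])
        pat = (rng.random((len(rows), m)) < dos[fa_i] / 2.0).astype(np.int8)
        mat = (rng.random((len(rows), m)) < dos[mo_i] / 2.0).astype(np.int8)
        dos[child_i] = pat + mat
    return GenotypeMatrix(ids=ped.ids, dosages=dos, snp_meta=_snp_meta(config, freqs))


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground-truth pieces of a simulated phenotype, keyed by individual."""

    components: pd.DataFrame  # id, u_G, u_K, u_F, u_C, u_S, eps, g_std, partner_id
    causal_effects: pd.DataFrame  # snp, beta
    couples: list  # (father_id, mother_id) per family


def causal_effects(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Causal SNP indices and i.i.d. normal effects on standardized dosages.

    Drawn from a dedicated substream of the phenotype stage so that the same
    effects can be materialized before genotypes exist (needed when mates
    are matched on genetic value).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STAGE_PHENOTYPE, 0))
    )
    causal = np.sort(rng.choice(config.n_snps, size=config.n_causal_snps, replace=False))
    w = rng.normal(size=config.n_causal_snps)
    return causal, w


def genetic_values(geno: GenotypeMatrix, causal: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Unscaled polygenic value: standardized causal dosages times effects."""
    Z = geno.dosages[:, causal].astype(float)
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    return (Z - mu) / sd @ w


def _scaled(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale to the exact target variance (0 -> zero vector)."""
    if target_var <= 0:
        return np.zeros_like(x)
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ConfigError("cannot scale a constant component to positive variance")
    return x * (np.sqrt(target_var) / sd)


def _group_effect(n: int, groups: list[list[int]], rng: np.random.Generator) -> np.ndarray:
    """One N(0,1) draw per group, shared by members; singletons independent."""
    u = rng.normal(size=n)  # default: private draw
    for g in groups:
        u[g] = rng.normal()
    return u


def _family_polygenic(ped: Pedigree, rng: np.random.Generator) -> np.ndarray:
    """Pedigree-structured polygenic draw, cov = additive relationship A.

    Extended-family components are independent, so the draw factorizes into
    per-component blocks of the path-counting A matrix.
    """
    u = np.zeros(ped.n)
    idx = {iid: i for i, iid in enumerate(ped.ids)}
    for comp in ped.extended_components():
        sub = ped.subset(comp)
        A = sub.additive_relationship()
        L = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
        draw = L @ rng.normal(size=len(A))
        u[[idx[i] for i in sub.ids]] = draw
    return u


def _nuclear_env_effect(ped: Pedigree, rng: np.random.Generator) -> np.ndarray:
    """Nuclear-family shared-environment draw.

    Target covariance is the F indicator (1 for parent-offspring, sibling
    and couple pairs).  Within a purely two-generation family that is a
    block of ones — one shared draw.  Across marriage chains the indicator
    is not a valid covariance (it is indefinite), so each extended block is
    projected to its nearest positive-semidefinite matrix (negative
    eigenvalues clipped) before sampling.
    """
    u = np.zeros(ped.n)
    idx = {iid: i for i, iid in enumerate(ped.ids)}
    pair_set = set()
    for a, b in ped.parent_offspring_pairs() + ped.full_sib_pairs():
        pair_set.add((a, b))
    for unit in ped.nuclear_families():
        pair_set.add((unit[0], unit[1]))  # the parent couple
    for comp in ped.extended_components():
        pos = {iid: i for i, iid in enumerate(comp)}
        B = np.eye(len(comp))
        for a, b in pair_set:
            if a in pos and b in pos:
                B[pos[a], pos[b]] = B[pos[b], pos[a]] = 1.0
        vals, vecs = np.linalg.eigh(B)
        vals = np.clip(vals, 0.0, None)
        draw = vecs @ (np.sqrt(vals) * rng.normal(size=len(comp)))
        u[[idx[i] for i in comp]] = draw
    return u


def _covariates(ped: Pedigree, rng: np.random.Generator) -> pd.DataFrame:
    tab = ped.table
    gen = tab["generation"].to_numpy()
    means = np.select([gen == 0, gen == 1], [68.0, 44.0], default=22.0)
    age = rng.normal(means, 6.0)
    age = np.clip(np.round(age), 18, 99)
    center = rng.choice(["centerA", "centerB", "centerC"], size=ped.n)
    pcs = rng.normal(size=(ped.n, 4))
    out = pd.DataFrame({"id": tab["id"], "age": age, "sex": tab["sex"], "center": center})
    for k in range(4):
        out[f"pc{k + 1}"] = pcs[:, k]
    return out


def simulate_phenotype(
    ped: Pedigree,
    geno: GenotypeMatrix,
    config: SimConfig,
    effects: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotype table plus ground truth for the configured GKFCS fractions.

    Every component (including the residual) is rescaled to its exact target
    share of unit phenotypic variance; fixed effects of age, sex and center
    are added on top.  Returns ``(phenotypes, truth)`` where phenotypes has
    columns id, trait, trait_bin, age, sex, center, pc1..pc4.
    """
    if not np.array_equal(ped.ids, geno.ids):
        raise ConfigError("pedigree and genotype ids differ")
    fr = config.fractions
    rng = _stage_rng(config, _STAGE_PHENOTYPE)
    if effects is None:
        effects = causal_effects(config)
    causal, w = effects

    idx = {iid: i for i, iid in enumerate(ped.ids)}
    g_raw = genetic_values(geno, causal, w)
    g_sd = g_raw.std()
    g_std = (g_raw - g_raw.mean()) / (g_sd if g_sd > 0 else 1.0)
    u_G = _scaled(g_raw, fr["G"]) if fr["G"] > 0 else np.zeros(ped.n)
    u_K = _scaled(_family_polygenic(ped, rng), fr["K"])

    couples = [(g[0], g[1]) for g in ped.nuclear_families()]
    couple_groups = [[idx[a], idx[b]] for a, b in couples]
    sib_groups = [[idx[i] for i in g] for g in ped.sibships()]
    u_F = _scaled(_nuclear_env_effect(ped, rng), fr["F"])
    u_C = _scaled(_group_effect(ped.n, couple_groups, rng), fr["C"])
    u_S = _scaled(_group_effect(ped.n, sib_groups, rng), fr["S"])
    eps = _scaled(rng.normal(size=ped.n), config.residual_fraction)

    y = u_G + u_K + u_F + u_C + u_S + eps

    partner = np.full(ped.n, None, dtype=object)
    for a, b in couples:
        partner[idx[a]], partner[idx[b]] = b, a
    if config.partner_effect != 0.0:
        add = np.zeros(ped.n)
        for a, b in couples:
            add[idx[a]] = config.partner_effect * g_std[idx[b]]
            add[idx[b]] = config.partner_effect * g_std[idx[a]]
        y = y + add

    cov = _covariates(ped, rng)
    sex_num = (cov["sex"] == MALE).to_numpy(float)
    center_eff = cov["center"].map({"centerA": -0.05, "centerB": 0.0, "centerC": 0.05})
    y_full = y + 0.01 * (cov["age"].to_numpy() - 45.0) + 0.1 * sex_num + center_eff.to_numpy()

    trait = np.exp(y_full / 2.0) if config.trait_scale == "lognormal" else y_full
    pheno = cov.copy()
    pheno.insert(1, "trait", trait)
    pheno.insert(2, "trait_bin", dichotomize_liability(y_full, config.prevalence))

    truth = SimTruth(
        components=pd.DataFrame(
            {
                "id": ped.ids,
                "u_G": u_G,
                "u_K": u_K,
                "u_F": u_F,
                "u_C": u_C,
                "u_S": u_S,
                "eps": eps,
                "g_std": g_std,
                "partner_id": partner,
            }
        ),
        causal_effects=pd.DataFrame(
            {"snp": geno.snp_meta["snp"].to_numpy()[causal], "beta": w}
        ),
        couples=couples,
    )
    return pheno, truth


# ---------------------------------------------------------------------------
# whole-study orchestrator (handles assortative mating)
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig):
    """Pedigree + genotypes + phenotype in one pass.

    With ``assortment_rho > 0`` mates are re-paired before children are
    generated: each founder gets a matching score (a noisy copy of the
    pre-shared-environment phenotype, or of the genetic value when
    ``assort_on='genetic'``), and males/females are paired by rank so the
    matched quantity correlates ~rho between partners.  Shared-environment
    terms are added only after matching.
    """
    ped = simulate_pedigree(config)
    if config.assortment_rho <= 0:
        geno = simulate_genotypes(ped, config)
        pheno, truth = simulate_phenotype(ped, geno, config)
        return ped, geno, pheno, truth

    grng = _stage_rng(config, _STAGE_GENOTYPES)
    freqs = grng.uniform(*config.maf_range, size=config.n_snps)
    n_founders = 2 * config.n_families
    founder_dos = grng.binomial(2, freqs, size=(n_founders, config.n_snps)).astype(np.int8)

    effects = causal_effects(config)
    founder_ids = ped.founders()
    founder_geno = GenotypeMatrix(
        ids=founder_ids, dosages=founder_dos, snp_meta=_snp_meta(config, freqs)
    )
    g = genetic_values(founder_geno, *effects)
    g = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
    mrng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(3,)))
    fr = config.fractions
    if config.assort_on == "genetic":
        basis = g
    else:
        h2 = fr["G"] + fr["K"]
        own = max(1e-12, h2 + config.residual_fraction)
        basis = np.sqrt(h2 / own) * g + np.sqrt(config.residual_fraction / own) * mrng.normal(
            size=n_founders
        )
    tau = np.sqrt(1.0 / config.assortment_rho - 1.0)
    score = basis + tau * mrng.normal(size=n_founders)

    tab = ped.table
    sex = tab.set_index("id")["sex"]
    males = [i for i in founder_ids if sex[i] == MALE]
    females = [i for i in founder_ids if sex[i] == FEMALE]
    fpos = {iid: k for k, iid in enumerate(founder_ids)}
    males_sorted = sorted(males, key=lambda i: score[fpos[i]])
    females_sorted = sorted(females, key=lambda i: score[fpos[i]])

    # re-pair: the k-th ranked female replaces the mother in the k-th ranked
    # male's family; children keep their father and get the new mother
    new_tab = tab.copy()
    fam_of_male = tab.set_index("id")["family_id"]
    for m_id, f_id in zip(males_sorted, females_sorted):
        fam = fam_of_male[m_id]
        sel = new_tab["father_id"] == m_id
        new_tab.loc[sel, "mother_id"] = f_id
        new_tab.loc[new_tab["id"] == f_id, "family_id"] = fam
    new_ped = Pedigree(new_tab.sort_values(["family_id", "generation", "id"]))

    order = np.array([fpos[i] for i in new_ped.founders()])
    geno = simulate_genotypes(new_ped, config, founder_dosages=founder_dos[order], freqs=freqs)
    pheno, truth = simulate_phenotype(new_ped, geno, config, effects=effects)
    return new_ped, geno, pheno, truth


# ---------------------------------------------------------------------------
# trait transforms
# ---------------------------------------------------------------------------

def dichotomize_liability(y, prevalence: float):
    """Binary trait under a liability-threshold model.

    Cases are the top ``prevalence`` fraction of the liability distribution;
    the realized case fraction is within 1/n of the target.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) == 0:
        raise ValueError("y must be a non-empty 1-D array")
    if np.ptp(y) == 0:
        raise ValueError("liability is constant; no threshold separates cases")
    k = int(round(prevalence * len(y)))
    k = min(max(k, 1), len(y) - 1)
    order = np.argsort(y, kind="stable")
    out = np.zeros(len(y), dtype=int)
    out[order[len(y) - k:]] = 1
    return out


_CPD_EDGES = [1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50]  # codes 2..12 start here
_ONSET_EDGES = [5, 10, 15, 20, 25, 30, 35, 40, 45, 50]  # codes 2..11 start here


def encode_ordinal(value, scheme: str):
    """Interval-code a raw count or age.

    ``cigarettes_per_day``: 0 -> 0, less than daily (0 < value < 1) -> 1,
    1-4 -> 2, 5-9 -> 3, ... 50+ -> 12.
    ``onset_age``: under 5 -> 1, 5-9 -> 2, 10-14 -> 3, ... 50+ -> 11;
    unknown (NaN) stays missing.
    """
    arr = np.asarray(value, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("values must be non-negative")
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    if scheme == "cigarettes_per_day":
        codes = np.searchsorted(_CPD_EDGES, arr[ok], side="right") + 1
        codes[arr[ok] == 0] = 0
        out[ok] = codes
    elif scheme == "onset_age":
        out[ok] = np.searchsorted(_ONSET_EDGES, arr[ok], side="right") + 1
    else:
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    return float(out[0]) if scalar else out
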