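"""Cross-partner association analyses.

Within-couple regressions of standardized traits under three covariate
schemes (none; age+sex; age+sex+center), own-PRS to partner-phenotype and
PRS-PRS regressions, Monte-Carlo permutation tests of couple independence,
and single-SNP contrasts stratified by partner genotype.

For standardized bivariate regressions the reported beta equals the Pearson
correlation and r^2 = beta^2; r^2 is reported as a percentage.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotypes import GenotypeMatrix
from .prs import PRSProfile, PrsError

ADJUSTMENTS = ("baseline", "age_sex", "age_sex_center")


class AssocError(ValueError):
    pass


@dataclass
class AssocResult:
    beta: float  # standardized
    se: float
    p: float
    r2: float  # percentage of variance explained
    n_pairs: int
    adjustment: str = "baseline"
    permutation_p: float | None = None

    def __str__(self) -> str:
        perm = f", perm p = {self.permutation_p:.4g}" if self.permutation_p else ""
        return (
            f"beta = {self.beta:.3f} (S.E. = {self.se:.3f}), p = {self.p:.3g}, "
            f"r2 = {self.r2:.2f}% (n = {self.n_pairs}, {self.adjustment}{perm})"
        )


@dataclass
class StratifiedContrast:
    """Trait means of reference-homozygote individuals split by partner
    carrier status, e.g. GG-G vs GG-A."""

    group_ref: str
    group_alt: str
    n_ref: int
    n_alt: int
    mean_ref: float
    mean_alt: float
    se_ref: float
    se_alt: float
    difference: float  # mean_ref - mean_alt
    p: float
    available: bool = True
    own_carrier_mean: float = np.nan
    own_noncarrier_mean: float = np.nan
    own_p: float = np.nan


def _zscale(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise AssocError("variable has zero variance")
    return (x - x.mean()) / sd


def residualize_trait(
    pheno: pd.DataFrame, trait: str = "trait", scheme: str = "age_sex"
) -> pd.Series:
    """Residuals of the trait under a covariate scheme (baseline = identity)."""
    if scheme not in ADJUSTMENTS:
        raise AssocError(f"scheme must be one of {ADJUSTMENTS}")
    y = pheno[trait].astype(float)
    if scheme == "baseline":
        return y.copy()
    cols = [pheno["age"].astype(float), (pheno["sex"] == "M").astype(float)]
    names = ["age", "sex"]
    if scheme == "age_sex_center":
        dummies = pd.get_dummies(pheno["center"], drop_first=True, dtype=float)
        cols += [dummies[c] for c in dummies.columns]
        names += list(dummies.columns)
    X = pd.concat(cols, axis=1)
    X.columns = names
    keep = [c for c in X.columns if X[c].nunique() > 1]
    if len(keep) < len(X.columns):
        warnings.warn(f"dropping constant covariates: {set(X.columns) - set(keep)}",
                      stacklevel=2)
    X = sm.add_constant(X[keep])
    ok = y.notna()
    res = pd.Series(np.nan, index=y.index)
    fitted = sm.OLS(y[ok], X[ok]).fit()
    res[ok] = y[ok] - fitted.predict(X[ok])
    return res


def _standardized_regression(x, y, adjustment="baseline") -> AssocResult:
    x, y = _zscale(x), _zscale(y)
    n = len(x)
    if n < 3:
        raise AssocError("need at least 3 complete pairs")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params[1])
    return AssocResult(
        beta=beta,
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        r2=float(fit.rsquared * 100.0),
        n_pairs=n,
        adjustment=adjustment,
    )


def couple_regression(pairs: pd.DataFrame, adjustment: str = "baseline") -> AssocResult:
    """Partner trait regressed on own trait, both z-scaled.

    ``pairs`` is a pair table with (already residualized, if applicable)
    ``trait_a``/``trait_b`` columns.  The standardized beta is symmetric to
    member swap.
    """
    tab = pairs.dropna(subset=["trait_a", "trait_b"])
    return _standardized_regression(
        tab["trait_a"].to_numpy(), tab["trait_b"].to_numpy(), adjustment
    )


def prs_partner_regression(
    own_prs: PRSProfile | np.ndarray,
    partner_trait: np.ndarray,
    own_trait: np.ndarray,
    adjustment: str = "baseline",
) -> tuple[AssocResult, AssocResult]:
    """(PRS -> partner trait, PRS -> own trait) standardized regressions."""
    score = own_prs.score if isinstance(own_prs, PRSProfile) else own_prs
    score = np.asarray(score, float)
    if score.std() == 0:
        raise PrsError("score has zero variance")
    partner = _standardized_regression(score, np.asarray(partner_trait, float), adjustment)
    own = _standardized_regression(score, np.asarray(own_trait, float), adjustment)
    return partner, own


def prs_couple_regression(
    prs_a: PRSProfile | np.ndarray,
    prs_b: PRSProfile | np.ndarray,
    adjustment: str = "baseline",
) -> AssocResult:
    """Partner's PRS regressed on own PRS (both standardized)."""
    a = prs_a.score if isinstance(prs_a, PRSProfile) else np.asarray(prs_a, float)
    b = prs_b.score if isinstance(prs_b, PRSProfile) else np.asarray(prs_b, float)
    return _standardized_regression(a, b, adjustment)


def permutation_test(
    x, y, n_resamples: int = 10_000, seed: int | None = None
) -> float:
    """Monte-Carlo permutation p for the independence of a pairing.

    The statistic is the absolute Pearson correlation; member-b values are
    shuffled across couples.  p = (1 + #{|r_perm| >= |r_obs|}) / (B + 1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise AssocError("x and y must be equal-length with n >= 2")
    if np.isnan(x).any() or np.isnan(y).any():
        raise AssocError("permutation test requires complete pairs")
    if n_resamples < 100:
        warnings.warn("fewer than 100 resamplings gives a coarse p-value", stacklevel=2)
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = len(x)
    obs = abs(float(xc @ yc) / n)
    hits = 0
    chunk = max(1, min(n_resamples, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_resamples:
        b = min(chunk, n_resamples - done)
        perms = rng.permuted(np.broadcast_to(yc, (b, n)), axis=1)
        stats_ = np.abs(perms @ xc) / n
        hits += int((stats_ >= obs - 1e-12).sum())
        done += b
    return (1 + hits) / (n_resamples + 1)


def partner_genotype_contrast(
    geno: GenotypeMatrix,
    snp: str,
    pairs: pd.DataFrame,
    trait: pd.Series | dict,
    carrier_allele: str = "alt",
) -> StratifiedContrast:
    """Stratify reference-homozygotes by partner carrier status.

    Individuals homozygous for the non-carrier allele are split by whether
    the partner carries >=1 copy of the carrier allele; trait means are
    compared by a two-sample Welch test.  The own-genotype contrast
    (carriers vs non-carriers, all individuals in pairs) is reported too.
    """
    col = geno.snp_index(snp)
    dos = geno.dosages[:, col].astype(float)
    if geno.mask is not None:
        dos = np.where(geno.mask[:, col], np.nan, dos)
    idx = {iid: i for i, iid in enumerate(geno.ids)}
    tr = trait if isinstance(trait, dict) else dict(zip(trait.index, trait.values))

    ref_vals, alt_vals = [], []  # trait of GG-G vs GG-A individuals
    own_car, own_non = [], []
    for row in pairs.itertuples(index=False):
        for me, partner in ((row.id_a, row.id_b), (row.id_b, row.id_a)):
            if me not in idx or partner not in idx or me not in tr:
                continue
            t = tr[me]
            if pd.isna(t):
                continue
            d_me, d_pa = dos[idx[me]], dos[idx[partner]]
            if np.isnan(d_me) or np.isnan(d_pa):
                continue
            if carrier_allele == "alt":
                me_carrier, pa_carrier = d_me > 0, d_pa > 0
            else:
                me_carrier, pa_carrier = d_me < 2, d_pa < 2
            (own_car if me_carrier else own_non).append(t)
            if not me_carrier:
                (alt_vals if pa_carrier else ref_vals).append(t)

    own_p = np.nan
    if len(own_car) >= 2 and len(own_non) >= 2:
        own_p = float(stats.ttest_ind(own_car, own_non, equal_var=False).pvalue)
    base = dict(
        group_ref="hom-noncarrier partner", group_alt="carrier partner",
        n_ref=len(ref_vals), n_alt=len(alt_vals),
        own_carrier_mean=float(np.mean(own_car)) if own_car else np.nan,
        own_noncarrier_mean=float(np.mean(own_non)) if own_non else np.nan,
        own_p=own_p,
    )
    if len(ref_vals) < 2 or len(alt_vals) < 2:
        return StratifiedContrast(
            mean_ref=np.nan, mean_alt=np.nan, se_ref=np.nan, se_alt=np.nan,
            difference=np.nan, p=np.nan, available=False, **base,
        )
    ref, alt = np.asarray(ref_vals), np.asarray(alt_vals)
    welch = stats.ttest_ind(ref, alt, equal_var=False)
    return StratifiedContrast(
        mean_ref=float(ref.mean()),
        mean_alt=float(alt.mean()),
        se_ref=float(ref.std(ddof=1) / np.sqrt(len(ref))),
        se_alt=float(alt.std(ddof=1) / np.sqrt(len(alt))),
        difference=float(ref.mean() - alt.mean()),
        p=float(welch.pvalue),
        **base,
    )
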