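"""Polygenic scoring: per-SNP association scan, greedy LD clumping,
p-value-threshold scoring over a dense grid, and principal-component
residualization of the chosen score.

Scores follow the clumping + thresholding recipe: approximately independent
index SNPs are selected greedily by p-value within an r^2/distance window,
then for each threshold t the score is the dosage-weighted sum of effects of
clumped SNPs with p <= t, and the threshold maximizing the variance
explained in the target trait is kept.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.round(np.arange(1, 10_001) * 5e-5, 10)  # 0.00005 .. 0.5

_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class PrsError(ValueError):
    pass


@dataclass
class SummaryStats:
    """Per-SNP association results (effect allele = a2, the counted allele)."""

    table: pd.DataFrame  # snp, chrom, pos, a1, a2, beta, se, p
    training_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        req = ["snp", "chrom", "pos", "a1", "a2", "beta", "se", "p"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise PrsError(f"summary stats missing columns: {missing}")
        if self.table["snp"].duplicated().any():
            raise PrsError("duplicate SNP ids in summary stats")
        ok = self.table["p"].dropna()
        if ((ok <= 0) | (ok > 1)).any():
            raise PrsError("p values must lie in (0, 1]")

    def to_tsv(self, path) -> None:
        out = self.table.rename(
            columns={
                "snp": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A2", "a2": "A1",
                "beta": "BETA", "se": "SE", "p": "P",
            }
        )
        out[["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P"]].to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "SummaryStats":
        raw = pd.read_csv(path, sep="\t")
        tab = raw.rename(
            columns={
                "SNP": "snp", "CHR": "chrom", "BP": "pos", "A1": "a2", "A2": "a1",
                "BETA": "beta", "SE": "se", "P": "p",
            }
        )
        return cls(table=tab)


@dataclass
class PRSProfile:
    """Per-individual polygenic score at the selected p-value threshold."""

    ids: np.ndarray
    score: np.ndarray
    threshold: float
    n_snps_in_score: int
    variance_explained: float  # incremental r^2 over covariates at selection
    r2_marginal: float = np.nan
    residualized: bool = False
    snps: list = field(default_factory=list)

    def standardized(self) -> np.ndarray:
        s = np.asarray(self.score, float)
        sd = s.std()
        if sd == 0:
            raise PrsError("score has zero variance")
        return (s - s.mean()) / sd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "score": self.score, "threshold": self.threshold}
        )


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    n = len(y)
    if C is None:
        X = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(C, float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PrsError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def gwas_scan(
    geno: GenotypeMatrix, pheno: np.ndarray, covars: np.ndarray | None = None
) -> SummaryStats:
    """Per-SNP linear association of the covariate-residualized trait.

    The trait is residualized on the covariates (plus intercept) and
    standardized; each SNP is then tested by simple linear regression of
    that residual on dosage.  Binary traits go through the same linear
    scan.  Monomorphic SNPs get missing statistics.
    """
    y = np.asarray(pheno, dtype=float).ravel()
    if y.std() == 0:
        raise PrsError("trait has zero variance")
    y = _residualize(y, covars)
    y = y / y.std()
    n = len(y)
    X = geno.dosages.astype(float)
    if geno.mask is not None:
        p_obs = geno.allele_freq()
        X = np.where(geno.mask, 2.0 * p_obs, X)
    xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    mono = sxx == 0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = (xc.T @ y) / sxx_safe
    syy = float(y @ y)
    rss = np.maximum(syy - beta**2 * sxx_safe, 0.0)
    dof = n - 2
    se = np.sqrt(rss / dof / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    beta[mono] = np.nan
    se[mono] = np.nan
    p[mono] = np.nan
    tab = geno.snp_meta[["snp", "chrom", "pos", "a1", "a2"]].copy()
    tab["beta"] = beta
    tab["se"] = se
    tab["p"] = p
    return SummaryStats(table=tab, training_ids=np.asarray(geno.ids).copy())


def genomic_inflation(stats_: SummaryStats) -> float:
    """Genomic-control lambda: median association chi2 over its null median."""
    p = stats_.table["p"].dropna().to_numpy()
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def align_stats(stats_: SummaryStats, geno: GenotypeMatrix) -> pd.DataFrame:
    """Match summary stats to the genotype panel by SNP id and alleles.

    Betas are flipped when the stats' effect allele is the panel's reference
    allele; strand-ambiguous (A/T, C/G) SNPs and allele mismatches are
    dropped with a log message.  Returns the aligned stats table augmented
    with the genotype column index ``col``.
    """
    meta = geno.snp_meta[["snp", "a1", "a2"]].reset_index().rename(
        columns={"index": "col", "a1": "g_a1", "a2": "g_a2"}
    )
    merged = stats_.table.merge(meta, on="snp", how="inner")
    amb = merged.apply(lambda r: frozenset({r["a1"], r["a2"]}) in _AMBIGUOUS, axis=1)
    if amb.any():
        logger.info("dropping %d strand-ambiguous SNPs", int(amb.sum()))
        merged = merged[~amb]
    same = (merged["a2"] == merged["g_a2"]) & (merged["a1"] == merged["g_a1"])
    flipped = (merged["a2"] == merged["g_a1"]) & (merged["a1"] == merged["g_a2"])
    n_bad = int((~(same | flipped)).sum())
    if n_bad:
        logger.info("dropping %d SNPs with mismatched alleles", n_bad)
    merged = merged[same | flipped].copy()
    merged.loc[flipped[same | flipped], "beta"] *= -1.0
    return merged.drop(columns=["g_a1", "g_a2"])


def clump(
    stats_: SummaryStats,
    geno: GenotypeMatrix,
    r2_max: float = 0.1,
    window_kb: float = 250.0,
) -> list[str]:
    """Greedy p-value clumping.

    Repeatedly take the smallest-p unclaimed SNP as an index SNP and claim
    every unclaimed SNP on the same chromosome within ``window_kb`` whose
    squared dosage correlation with it exceeds ``r2_max``.  Ties in p are
    broken by (chrom, pos).  Returns index SNP ids in selection order.
    """
    aligned = align_stats(stats_, geno)
    usable = aligned.dropna(subset=["p", "pos"])
    n_skip = len(aligned) - len(usable)
    if n_skip:
        logger.info("skipping %d SNPs with missing p or position", n_skip)
    if usable.empty:
        return []
    usable = usable.sort_values(["p", "chrom", "pos"], kind="stable")
    X = geno.dosages.astype(float)
    cols = usable["col"].to_numpy()
    chrom = usable["chrom"].to_numpy()
    pos = usable["pos"].to_numpy(float)
    snps = usable["snp"].to_numpy()
    m = len(usable)
    claimed = np.zeros(m, dtype=bool)
    window = window_kb * 1000.0
    out = []
    for i in range(m):
        if claimed[i]:
            continue
        claimed[i] = True
        out.append(str(snps[i]))
        near = (
            ~claimed
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        if not near.any():
            continue
        xi = X[:, cols[i]]
        xi = xi - xi.mean()
        denom_i = float(xi @ xi)
        if denom_i == 0:
            continue
        Xn = X[:, cols[near]]
        Xn = Xn - Xn.mean(axis=0)
        num = xi @ Xn
        denom = denom_i * np.einsum("ij,ij->j", Xn, Xn)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(denom > 0, num**2 / denom, 0.0)
        idx = np.flatnonzero(near)
        claimed[idx[r2 > r2_max]] = True
    return out


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _incremental_r2(score, y, covars):
    """r^2 of the score added to a covariate-only model (and marginal r^2)."""
    ry = _residualize(np.asarray(y, float), covars)
    rs = _residualize(np.asarray(score, float), covars)
    marg = np.corrcoef(score, y)[0, 1] ** 2 if np.std(score) > 0 else 0.0
    if rs.std() == 0 or ry.std() == 0:
        return 0.0, float(marg)
    return float(np.corrcoef(rs, ry)[0, 1] ** 2), float(marg)


def score_grid(
    geno: GenotypeMatrix,
    stats_: SummaryStats,
    clumped: list[str],
    target_pheno: np.ndarray,
    covars: np.ndarray | None = None,
    thresholds: np.ndarray = DEFAULT_GRID,
) -> PRSProfile:
    """Score at every threshold of the grid and keep the best.

    The grid is swept in one pass over p-sorted clumped SNPs (cumulative
    scores), not by rescanning per threshold.  The chosen threshold
    maximizes the incremental variance explained in the target trait over
    the covariates; if no SNP passes the smallest threshold, the smallest
    non-empty threshold is used and logged.
    """
    if len(clumped) == 0:
        raise PrsError("clumped SNP set is empty")
    if stats_.training_ids is not None:
        overlap = set(map(str, geno.ids)) & set(map(str, stats_.training_ids))
        if overlap:
            raise PrsError(
                f"{len(overlap)} target individuals were in the GWAS training sample"
            )
    aligned = align_stats(stats_, geno)
    sub = aligned[aligned["snp"].isin(set(clumped))].dropna(subset=["p"])
    if sub.empty:
        raise PrsError("no clumped SNPs present in the genotype panel")
    sub = sub.sort_values(["p", "chrom", "pos"], kind="stable")
    X = geno.dosages.astype(float)
    if geno.mask is not None:
        p_obs = geno.allele_freq()
        X = np.where(geno.mask, 2.0 * p_obs, X)
    y = np.asarray(target_pheno, float)

    pvals = sub["p"].to_numpy()
    cols = sub["col"].to_numpy()
    betas = sub["beta"].to_numpy()
    # prefix k = number of SNPs with p <= t; distinct prefixes <= n SNPs
    cut_idx = np.searchsorted(pvals, thresholds, side="right")
    distinct = np.unique(cut_idx[cut_idx > 0])
    if len(distinct) == 0:
        k_min = 1
        logger.info(
            "no SNP passes the smallest threshold %g; using the single best SNP",
            thresholds[0],
        )
        distinct = np.array([k_min])
    score = np.zeros(geno.n)
    best = (-np.inf, None, None, None)  # r2, k, score copy, marginal
    done = 0
    for k in distinct:
        block = X[:, cols[done:k]] @ betas[done:k]
        score = score + block
        done = k
        r2, marg = _incremental_r2(score, y, covars)
        if r2 > best[0]:
            best = (r2, int(k), score.copy(), marg)
    r2, k, best_score, marg = best
    if k is None:
        raise PrsError("threshold selection failed (all scores degenerate)")
    if best_score.std() == 0:
        logger.warning("selected score is constant; weights may all be zero")
    covered = thresholds[cut_idx >= k]
    chosen_t = float(covered.min()) if len(covered) else float(thresholds[-1])
    return PRSProfile(
        ids=np.asarray(geno.ids).copy(),
        score=best_score,
        threshold=chosen_t,
        n_snps_in_score=int(k),
        variance_explained=float(r2),
        r2_marginal=float(marg),
        snps=[str(s) for s in sub["snp"].to_numpy()[:k]],
    )


def score_at_threshold(
    geno: GenotypeMatrix, stats_: SummaryStats, clumped: list[str], threshold: float
) -> np.ndarray:
    """Plain score at one threshold (sum over clumped SNPs with p <= t)."""
    aligned = align_stats(stats_, geno)
    sub = aligned[aligned["snp"].isin(set(clumped)) & (aligned["p"] <= threshold)]
    X = geno.dosages.astype(float)
    return X[:, sub["col"].to_numpy()] @ sub["beta"].to_numpy()


def residualize_on_pcs(profile: PRSProfile, pcs: np.ndarray, k: int = 4) -> PRSProfile:
    """Regress the score on the leading k principal components; keep residuals."""
    pcs = np.atleast_2d(np.asarray(pcs, float))
    if pcs.shape[0] != len(profile.score):
        pcs = pcs.T
    if k > pcs.shape[1]:
        raise PrsError(f"requested {k} components, only {pcs.shape[1]} available")
    resid = _residualize(np.asarray(profile.score, float), pcs[:, :k])
    return PRSProfile(
        ids=profile.ids,
        score=resid,
        threshold=profile.threshold,
        n_snps_in_score=profile.n_snps_in_score,
        variance_explained=profile.variance_explained,
        r2_marginal=profile.r2_marginal,
        residualized=True,
        snps=list(profile.snps),
    )
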