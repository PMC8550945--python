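"""End-to-end convenience pipeline: simulate a family study, build the five
relationship matrices, and fit (or backward-select) the GKFCS model."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import SimConfig
from .couples import find_couples_shared_child
from .matrices import RelationshipMatrix, build_env_matrix, compute_grm, threshold_to_kinship
from .reml import VarianceFit, VarianceModel, backward_select, fit_reml
from .simulate import simulate_study


@dataclass
class StudyFit:
    fit: VarianceFit
    trace: list | None
    n: int
    case_fraction: float | None = None

    def fraction(self, name: str) -> float:
        """Fitted fraction of a component; 0 when it was selected away."""
        return self.fit.fraction(name) if name in self.fit.names else 0.0


def gkfcs_matrices(ped, geno, kinship_cutoff: float = 0.025,
                   maf_floor: float = 0.01) -> dict[str, RelationshipMatrix]:
    """G (GRM), K (thresholded GRM), F, C, S for a pedigree + genotypes."""
    G = compute_grm(geno, maf_floor=maf_floor, dtype=np.float32)
    K = threshold_to_kinship(G, cutoff=kinship_cutoff)
    pairs = find_couples_shared_child(ped)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F = build_env_matrix(ped, pairs, "F")
        C = build_env_matrix(ped, pairs, "C")
        S = build_env_matrix(ped, pairs, "S")
    return {"G": G, "K": K, "F": F, "C": C, "S": S}


def fit_gkfcs_study(
    config: SimConfig,
    binary: bool = False,
    select: bool = False,
    tol: float = 1e-4,
) -> StudyFit:
    """Simulate under ``config`` and fit the five-component model.

    With ``binary`` the liability-threshold 0/1 trait is analysed on the
    observed scale (transform the fractions afterwards with
    :func:`famvar.observed_to_liability`).  With ``select`` backward
    stepwise pruning is applied instead of a single full fit.
    """
    ped, geno, pheno, truth = simulate_study(config)
    mats = gkfcs_matrices(ped, geno)
    y = pheno["trait_bin" if binary else "trait"].to_numpy(float)
    X = np.column_stack(
        [np.ones(ped.n), pheno["age"].to_numpy(float),
         (pheno["sex"] == "M").to_numpy(float)]
    )
    model = VarianceModel(
        y=y, X=X, components=[mats[r] for r in ("G", "K", "F", "C", "S")]
    )
    if select:
        fit, trace = backward_select(model, tol=tol)
    else:
        fit, trace = fit_reml(model, tol=tol), None
    return StudyFit(fit=fit, trace=trace, n=ped.n,
                    case_fraction=float(y.mean()) if binary else None)


UNITS_PER_WEEK = dict(
    n_families=1200, offspring_range=(1, 3), n_snps=20_000, n_causal_snps=1000,
    mate_fraction=0.5, var_fractions={"G": 0.06, "K": 0.12, "F": 0.07, "C": 0.38},
)
"""Study conditions for the alcohol units-per-week variance decomposition:
~6,000 individuals in 1,200 extended families."""

SMOKING_STATUS = dict(
    n_families=1200, offspring_range=(1, 3), n_snps=20_000, n_causal_snps=1000,
    mate_fraction=0.5, prevalence=0.48,
    var_fractions={"G": 0.22, "K": 0.19, "C": 0.29, "S": 0.10},
)
"""Liability-scale study conditions for ever/never smoking (prevalence 48%)."""

CAGE_SCORE = dict(
    n_families=400, offspring_range=(2, 2), n_snps=12_000, n_causal_snps=800,
    mate_fraction=0.5, var_fractions={"G": 0.19, "C": 0.31},
)
"""Two-component (SNP-genetic + couple) conditions for the CAGE misuse score,
at a reduced desk scale (~2,000 individuals)."""
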