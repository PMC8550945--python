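import warnings

import numpy as np
import pytest

from famvar import (
    SimConfig,
    build_env_matrix,
    compute_grm,
    find_couples_shared_child,
    simulate_study,
    threshold_to_kinship,
)


@pytest.fixture(scope="session")
def small_study():
    """A reusable small family study: 120 families, 800 SNPs."""
    cfg = SimConfig(
        n_families=120,
        offspring_range=(1, 3),
        n_snps=800,
        n_causal_snps=200,
        var_fractions={"G": 0.2, "K": 0.1, "F": 0.1, "C": 0.3},
        seed=42,
    )
    ped, geno, pheno, truth = simulate_study(cfg)
    return cfg, ped, geno, pheno, truth


@pytest.fixture(scope="session")
def small_matrices(small_study):
    cfg, ped, geno, pheno, truth = small_study
    G = compute_grm(geno)
    K = threshold_to_kinship(G)
    pairs = find_couples_shared_child(ped)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F = build_env_matrix(ped, pairs, "F")
        C = build_env_matrix(ped, pairs, "C")
        S = build_env_matrix(ped, pairs, "S")
    return {"G": G, "K": K, "F": F, "C": C, "S": S, "pairs": pairs}


def couple_block_matrix(n_pairs: int) -> np.ndarray:
    """Block-diagonal matrix of 2x2 all-ones couple blocks."""
    M = np.eye(2 * n_pairs)
    for i in range(n_pairs):
        M[2 * i, 2 * i + 1] = M[2 * i + 1, 2 * i] = 1.0
    return M
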