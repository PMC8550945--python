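"""Simulation configuration.

``SimConfig`` holds the generative study conditions: pedigree shape, SNP
panel, and the variance fractions of the GKFCS phenotype model

    Y = Xb + u_G + u_K + u_F + u_C + u_S + eps,

where u_G is the SNP-tagged polygenic value, u_K a pedigree-structured
polygenic residual, and u_F/u_C/u_S environmental effects shared by nuclear
families, couples and sibships respectively.  The residual fraction is
implied as 1 minus the sum of the component fractions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import yaml

ROLES = ("G", "K", "F", "C", "S")


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    n_families: int = 100
    offspring_range: tuple[int, int] = (1, 3)
    n_snps: int = 1000
    n_causal_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    var_fractions: dict[str, float] = field(default_factory=dict)
    third_generation: bool = True
    mate_fraction: float = 0.5
    prevalence: float = 0.5
    partner_effect: float = 0.0
    assortment_rho: float = 0.0
    assort_on: str = "phenotype"  # or "genetic"
    trait_scale: str = "gaussian"  # or "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        lo, hi = self.offspring_range
        if not (isinstance(lo, int) and isinstance(hi, int) and 1 <= lo <= hi):
            raise ConfigError(f"invalid offspring_range {self.offspring_range}")
        if self.n_snps < 1 or not (1 <= self.n_causal_snps <= self.n_snps):
            raise ConfigError("need 1 <= n_causal_snps <= n_snps")
        mlo, mhi = self.maf_range
        if not (0.0 < mlo <= mhi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        unknown = set(self.var_fractions) - set(ROLES)
        if unknown:
            raise ConfigError(f"unknown variance roles: {sorted(unknown)}")
        fr = self.fractions
        if any(v < 0 for v in fr.values()):
            raise ConfigError("variance fractions must be >= 0")
        if sum(fr.values()) > 1.0 + 1e-12:
            raise ConfigError("variance fractions sum to more than 1")
        if not (0.0 <= self.mate_fraction <= 1.0):
            raise ConfigError("mate_fraction must be in [0, 1]")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigError("prevalence must be in (0, 1)")
        if not (0.0 <= self.assortment_rho < 1.0):
            raise ConfigError("assortment_rho must be in [0, 1)")
        if self.assort_on not in ("phenotype", "genetic"):
            raise ConfigError("assort_on must be 'phenotype' or 'genetic'")
        if self.trait_scale not in ("gaussian", "lognormal"):
            raise ConfigError("trait_scale must be 'gaussian' or 'lognormal'")

    @property
    def fractions(self) -> dict[str, float]:
        """All five component fractions, defaulting absent roles to 0."""
        return {r: float(self.var_fractions.get(r, 0.0)) for r in ROLES}

    @property
    def residual_fraction(self) -> float:
        return max(0.0, 1.0 - sum(self.fractions.values()))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("offspring_range", "maf_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            "n_families": self.n_families,
            "offspring_range": list(self.offspring_range),
            "n_snps": self.n_snps,
            "n_causal_snps": self.n_causal_snps,
            "maf_range": list(self.maf_range),
            "var_fractions": dict(self.var_fractions),
            "third_generation": self.third_generation,
            "mate_fraction": self.mate_fraction,
            "prevalence": self.prevalence,
            "partner_effect": self.partner_effect,
            "assortment_rho": self.assortment_rho,
            "assort_on": self.assort_on,
            "trait_scale": self.trait_scale,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
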