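"""Synthetic species pools, assemblages and extinction-driver covariates.

The generator emulates the statistical structure the analysis assumes:
a categorical five-trait species pool (271 species by default), per-system
assemblage richness ranges (estuaries 4-57, lakes 3-19, rivers 3-31),
heavy-tailed (lognormal) abundances with a few dominants and a long rare
tail, and per-species vulnerability scores whose rank correlation with
functional distinctiveness is a tunable coupling — the knob that controls
whether "vulnerable species first" scenarios erode function faster than
chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assemblage_data import Assemblage, RIVER_CATEGORIES
from .trait_space import (
    AssemblageTree,
    FunctionalDendrogram,
    TraitSchema,
    TraitTable,
    default_fish_schema,
)

__all__ = ["GeneratorConfig", "generate_species_pool", "generate_assemblages", "assign_extinction_drivers"]

#: Assemblage richness ranges observed per system type.
RICHNESS_RANGES = {"estuary": (4, 57), "lake": (3, 19), "river": (3, 31)}

#: Red List category mix used when none is configured (most pool species are
#: of least concern; threatened classes are progressively rarer).
DEFAULT_IUCN_PROPORTIONS = {"CR": 0.03, "EN": 0.05, "VU": 0.10, "NT": 0.12, "LC": 0.70}


@dataclass
class GeneratorConfig:
    """Tunable parameters of the synthetic study."""

    pool_size: int = 271
    schema: TraitSchema = field(default_factory=default_fish_schema)
    n_sites: dict[str, int] = field(
        default_factory=lambda: {"estuary": 49, "lake": 302, "river": 869}
    )
    richness_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(RICHNESS_RANGES)
    )
    abundance_meanlog: float = 0.0
    abundance_sdlog: float = 1.5
    #: target Spearman correlation between vulnerability and functional
    #: distinctiveness, in [-1, 1]
    coupling: float = 0.0
    iucn_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IUCN_PROPORTIONS)
    )
    #: sizes of groups of species forced to share a full trait vector
    redundancy_blocks: tuple[int, ...] = ()
    #: geometric decay of category frequencies within each trait (1 = uniform)
    category_decay: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 2:
            raise ValueError("pool size must be at least 2")
        if not -1 <= self.coupling <= 1:
            raise ValueError("coupling must lie in [-1, 1]")
        for system, (lo, hi) in self.richness_ranges.items():
            if not 1 <= lo <= hi:
                raise ValueError(f"invalid richness range for {system!r}")
            if self.n_sites.get(system, 0) > 0 and hi > self.pool_size:
                raise ValueError(f"richness range for {system!r} exceeds the pool size")
        total = sum(self.iucn_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("IUCN proportions must sum to 1")
        if sum(self.redundancy_blocks) > self.pool_size:
            raise ValueError("redundancy blocks exceed pool size")


def _species_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"sp{str(i + 1).zfill(width)}" for i in range(n)]


def generate_species_pool(config: GeneratorConfig, rng: np.random.Generator | None = None) -> TraitTable:
    """Draw a species pool with per-trait categorical frequencies.

    Category frequencies decay geometrically within each trait (a few common
    states, several rare ones); ``redundancy_blocks`` forces groups of species
    to share complete trait vectors, creating perfectly redundant species.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.pool_size
    names = _species_names(n)
    data = {}
    for t in config.schema.traits:
        k = len(t.categories)
        w = config.category_decay ** np.arange(k)
        w = w / w.sum()
        data[t.name] = rng.choice(list(t.categories), size=n, p=w)
    df = pd.DataFrame(data, index=names)
    pos = 0
    for size in config.redundancy_blocks:
        block = names[pos : pos + size]
        df.loc[block, :] = df.loc[[block[0]] * size, :].to_numpy()
        pos += size
    return TraitTable(df, config.schema)


def generate_assemblages(
    pool: TraitTable,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> list[Assemblage]:
    """Sample per-site assemblages from the pool.

    Site richness is uniform within its system's range; species are drawn
    without replacement; relative abundances are lognormal, normalised to sum
    to one, so every assemblage has a few dominants and a long rare tail.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    species = np.asarray(pool.species)
    out: list[Assemblage] = []
    for system in ("estuary", "lake", "river"):
        n_sites = config.n_sites.get(system, 0)
        lo, hi = config.richness_ranges[system]
        if hi > len(species):
            raise ValueError(f"richness range for {system!r} exceeds the pool size")
        width = len(str(max(n_sites, 1)))
        for i in range(n_sites):
            richness = int(rng.integers(lo, hi + 1))
            chosen = rng.choice(species, size=richness, replace=False)
            raw = rng.lognormal(config.abundance_meanlog, config.abundance_sdlog, size=richness)
            rel = raw / raw.sum()
            if system == "river":
                category = str(rng.choice(RIVER_CATEGORIES))
            else:
                category = str(rng.choice(["small", "large"]))
            out.append(
                Assemblage(
                    site_id=f"{system}_{str(i + 1).zfill(width)}",
                    system=system,
                    abundances={str(s): float(a) for s, a in zip(chosen, rel)},
                    region=str(rng.choice(["Danubian", "Iberian"])),
                    category=category,
                )
            )
    return out


def functional_distinctiveness(pool: TraitTable, tree: FunctionalDendrogram) -> pd.Series:
    """Leave-one-out FD loss of each species on the full pool dendrogram."""
    atree = AssemblageTree(tree, pool.species)
    n = len(pool.species)
    # column j removes the j-th species (local leaf order == pool order here)
    X = np.ones((n, n)) - np.eye(n)
    losses = atree.fd_full - atree.fd_subsets(X)
    return pd.Series(losses, index=pool.species, name="distinctiveness")


def assign_extinction_drivers(
    pool: TraitTable,
    tree: FunctionalDendrogram,
    coupling: float,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    iucn_proportions: Mapping[str, float] | None = None,
) -> tuple[dict[str, float], dict[str, str]]:
    """Vulnerability scores (0-100) and IUCN categories for the pool.

    The score's rank correlation with functional distinctiveness targets
    ``coupling`` through a Gaussian copula; categories are assigned by
    vulnerability quantiles following the configured proportions (most
    vulnerable species get the most threatened categories).
    """
    if not -1 <= coupling <= 1:
        raise ValueError("coupling must lie in [-1, 1]")
    if iucn_proportions is None:
        iucn_proportions = DEFAULT_IUCN_PROPORTIONS
    rng = np.random.default_rng(seed)
    dist = functional_distinctiveness(pool, tree)
    n = len(dist)
    # Gaussian copula: Pearson rho chosen so the Spearman correlation ~ coupling
    # (exactly +-1 at the endpoints, so ties in distinctiveness stay tied)
    rho = float(np.sign(coupling)) if abs(coupling) == 1 else 2.0 * np.sin(np.pi * coupling / 6.0)
    z_d = sps.norm.ppf(sps.rankdata(dist.to_numpy(), method="average") / (n + 1))
    latent = rho * z_d + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    vuln_rank = sps.rankdata(latent, method="average")
    vulnerability = 100.0 * (vuln_rank - 0.5) / n
    vuln = {s: float(v) for s, v in zip(dist.index, vulnerability)}
    # categories by vulnerability quantile, most threatened at the top
    order = sorted(dist.index, key=lambda s: (-vuln[s], s))
    iucn: dict[str, str] = {}
    boundaries = []
    cum = 0.0
    for cat in ("CR", "EN", "VU", "NT", "LC"):
        cum += iucn_proportions.get(cat, 0.0)
        boundaries.append((cat, int(round(cum * n))))
    pos = 0
    for cat, upto in boundaries:
        for s in order[pos:upto]:
            iucn[s] = cat
        pos = max(pos, upto)
    for s in order[pos:]:  # rounding slack
        iucn[s] = "LC"
    return vuln, iucn
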