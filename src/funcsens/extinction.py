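"""Species-extinction scenarios and functional-loss curves.

Six scenarios are simulated per assemblage: random (999 trajectories, whose
mean AUC is the functional-redundancy index), greedy best- and worst-case,
abundance-based (rarest species first), trait-based (most intrinsically
vulnerable first) and IUCN-based (threat-category clusters, most threatened
first).  Each trajectory yields a loss curve of residual functional-richness
proportion against the proportion of species lost; the area under that curve
(AUC) summarises functional sensitivity, and directional scenarios are scored
against the random null by a standardised effect size (SES).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .assemblage_data import Assemblage
from .trait_space import AssemblageTree, FunctionalDendrogram

__all__ = [
    "Trajectory",
    "LossCurve",
    "ScenarioResult",
    "ExhaustiveSummary",
    "DegenerateAssemblageError",
    "SCENARIOS",
    "IUCN_REMOVAL_ORDER",
    "derive_seed",
    "loss_curve",
    "trapezoid_auc",
    "random_trajectories",
    "random_null_aucs",
    "redundancy_index",
    "greedy_trajectory",
    "score_ranked_trajectory",
    "iucn_cluster_trajectory",
    "random_cluster_trajectories",
    "standardized_effect_size",
    "exhaustive_auc_oracle",
]

SCENARIOS = ("random", "best", "worst", "abundance", "trait", "iucn")

#: IUCN Red List categories in removal order (most threatened first);
#: data-deficient and not-evaluated species are folded into least concern.
IUCN_REMOVAL_ORDER = ("CR", "EN", "VU", "NT", "LC")
IUCN_ALIASES = {"DD": "LC", "NE": "LC"}

#: Loss-curve abscissa conventions.  "span" places the k-th removal at
#: k/(S-1), so the last observable state (one species, FD = 0) sits at x = 1;
#: "per-species" places it at k/S and appends a terminal (1, 0) point.
AXIS_CONVENTIONS = ("span", "per-species")


class DegenerateAssemblageError(ValueError):
    """All species in the assemblage are functionally identical (FD = 0)."""


@dataclass(frozen=True)
class Trajectory:
    """An ordered removal sequence; each step removes one or more species."""

    steps: tuple[tuple[str, ...], ...]
    scenario: str = "custom"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for step in self.steps:
            for sp in step:
                if sp in seen:
                    raise ValueError(f"species {sp!r} removed twice")
                seen.add(sp)

    @property
    def removed(self) -> list[str]:
        return [sp for step in self.steps for sp in step]

    @property
    def is_sequential(self) -> bool:
        return all(len(step) == 1 for step in self.steps)


@dataclass
class LossCurve:
    """Residual FD proportion (y) against proportion of species lost (x)."""

    x: np.ndarray
    y: np.ndarray
    assemblage_id: str = ""
    scenario: str = "custom"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1 or len(self.x) < 2:
            raise ValueError("curve needs matching 1-d x and y with >= 2 points")
        if not (self.x[0] == 0 and abs(self.y[0] - 1) < 1e-9):
            raise ValueError("loss curve must start at (0, 1)")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if abs(self.x[-1] - 1) > 1e-9 or abs(self.y[-1]) > 1e-9:
            raise ValueError("loss curve must end at (1, 0)")
        if self.y.min() < -1e-9 or self.y.max() > 1 + 1e-9:
            raise ValueError("y must lie in [0, 1]")


@dataclass
class ScenarioResult:
    """Per-assemblage outcome of one scenario."""

    assemblage_id: str
    scenario: str
    auc: float
    ses: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    n_random: int | None = None
    seed: int | None = None


def derive_seed(master_seed: int, assemblage_id: str) -> np.random.SeedSequence:
    """Per-assemblage seed derived from the master seed and the site id, so
    results do not depend on processing order."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(assemblage_id.encode())])


# ---------------------------------------------------------------------------
# Loss curves and AUC
# ---------------------------------------------------------------------------


def _as_atree(tree: FunctionalDendrogram | AssemblageTree, assemblage: Assemblage | None) -> AssemblageTree:
    if isinstance(tree, AssemblageTree):
        return tree
    if assemblage is None:
        raise ValueError("an assemblage is required with a pool dendrogram")
    return tree.assemblage_tree(assemblage.species)


def _check_not_degenerate(atree: AssemblageTree) -> None:
    if atree.n_species >= 2 and atree.fd_full <= 0:
        raise DegenerateAssemblageError(
            "assemblage has zero functional richness (functionally identical species)"
        )


def _species_list(obj: Assemblage | Sequence[str]) -> list[str]:
    return obj.species if isinstance(obj, Assemblage) else sorted(obj)


def _curve_from_steps(
    atree: AssemblageTree,
    steps: Sequence[Sequence[str]],
    axis: str,
) -> tuple[np.ndarray, np.ndarray]:
    """x, y arrays of the loss curve for arbitrary removal steps."""
    if axis not in AXIS_CONVENTIONS:
        raise ValueError(f"axis must be one of {AXIS_CONVENTIONS}")
    S = atree.n_species
    remaining = np.ones(S)
    xs = [0.0]
    cols = [remaining.copy()]
    cum = 0
    denom = S - 1 if axis == "span" else S
    for step in steps:
        cum += len(step)
        for sp in step:
            remaining[atree.leaf_local[sp]] = 0.0
        xk = cum / denom
        if xk < 1 - 1e-12:
            xs.append(xk)
            cols.append(remaining.copy())
        if S - cum <= 1 or xk >= 1 - 1e-12:
            break
    if S - cum > 1:
        raise ValueError("trajectory must reduce the assemblage to at most one species")
    fd = atree.fd_subsets(np.column_stack(cols))
    y = np.clip(fd / atree.fd_full, 0.0, 1.0)
    y[0] = 1.0  # intact assemblage by definition
    x = np.append(np.asarray(xs), 1.0)
    y = np.append(y, 0.0)
    return x, y


def loss_curve(
    tree: FunctionalDendrogram | AssemblageTree,
    assemblage: Assemblage | None,
    trajectory: Trajectory,
    axis: str = "span",
) -> LossCurve:
    """Loss curve of a trajectory: FD of the remaining set after each step,
    normalised by the intact assemblage's FD."""
    atree = _as_atree(tree, assemblage)
    _check_not_degenerate(atree)
    if atree.n_species < 2:
        raise ValueError("loss curves need at least two species")
    x, y = _curve_from_steps(atree, trajectory.steps, axis)
    aid = assemblage.site_id if assemblage is not None else ""
    return LossCurve(x=x, y=y, assemblage_id=aid, scenario=trajectory.scenario)


def trapezoid_auc(curve: LossCurve) -> float:
    """Area under the loss curve (trapezoidal rule over x in [0, 1])."""
    return float(np.trapezoid(curve.y, curve.x))


# ---------------------------------------------------------------------------
# Random null
# ---------------------------------------------------------------------------


def random_trajectories(
    assemblage: Assemblage | Sequence[str],
    n: int = 999,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> list[Trajectory]:
    """``n`` uniform-random sequential removal orders (each stops when one
    species remains)."""
    if n < 2:
        raise ValueError("need at least 2 random trajectories")
    species = _species_list(assemblage)
    if len(species) < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        order = rng.permutation(len(species))
        steps = tuple((species[i],) for i in order[:-1])
        out.append(Trajectory(steps=steps, scenario="random"))
    return out


def _sequential_null_aucs(atree: AssemblageTree, n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised AUCs of ``n`` random sequential trajectories (span axis)."""
    S = atree.n_species
    perms = np.argsort(rng.random((n, S)), axis=1)  # n random permutations
    # remaining-set indicators after k = 0..S-2 removals, all replicates at once
    onehot = np.zeros((n, S, S))
    np.put_along_axis(onehot, perms[:, :, None], 1.0, axis=2)
    removed_cum = np.cumsum(onehot, axis=1)
    remaining = 1.0 - removed_cum[:, : S - 1, :]  # (n, S-1, S)
    cols = np.concatenate([np.ones((n, 1, S)), remaining], axis=1)  # k = 0 first
    X = cols.reshape(n * S, S).T
    fd = atree.fd_subsets(X).reshape(n, S)
    y = fd / atree.fd_full
    # trapezoid over x = k/(S-1), k = 0..S-1 (y at k = S-1 is 0 by construction)
    w = np.full(S, 1.0 / (S - 1))
    w[0] = w[-1] = 0.5 / (S - 1)
    return y @ w


def random_null_aucs(
    tree: FunctionalDendrogram | AssemblageTree,
    assemblage: Assemblage | None = None,
    n: int = 999,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> np.ndarray:
    """AUC values of ``n`` random sequential extinction trajectories."""
    if n < 2:
        raise ValueError("need at least 2 random trajectories")
    atree = _as_atree(tree, assemblage)
    _check_not_degenerate(atree)
    if atree.n_species < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)
    return _sequential_null_aucs(atree, n, rng)


def redundancy_index(
    tree: FunctionalDendrogram | AssemblageTree,
    assemblage: Assemblage | None = None,
    n: int = 999,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> float:
    """Functional redundancy: the mean AUC of ``n`` random trajectories."""
    return float(np.mean(random_null_aucs(tree, assemblage, n=n, seed=seed)))


# ---------------------------------------------------------------------------
# Directional scenarios
# ---------------------------------------------------------------------------


def greedy_trajectory(
    tree: FunctionalDendrogram | AssemblageTree,
    assemblage: Assemblage | Sequence[str] | None,
    mode: str,
) -> Trajectory:
    """Best-case (``mode='best'``) or worst-case (``'worst'``) trajectory.

    At each step the FD loss of removing every remaining candidate is
    evaluated and the arg-min (best) or arg-max (worst) is removed; ties are
    broken lexicographically by species identifier.
    """
    if mode not in ("best", "worst"):
        raise ValueError("mode must be 'best' or 'worst'")
    if isinstance(tree, AssemblageTree):
        atree = tree
    else:
        atree = tree.assemblage_tree(_species_list(assemblage))
    _check_not_degenerate(atree)
    S = atree.n_species
    if S < 2:
        raise ValueError("need at least two species")
    order_species = sorted(atree.species)
    idx = np.array([atree.leaf_local[s] for s in order_species])
    remaining = np.ones(S)
    alive = list(range(len(order_species)))  # positions into order_species
    steps: list[tuple[str, ...]] = []
    for _ in range(S - 1):
        cur_fd = atree.fd_subsets(remaining[:, None])[0]
        cols = np.repeat(remaining[:, None], len(alive), axis=1)
        for j, pos in enumerate(alive):
            cols[idx[pos], j] = 0.0
        losses = cur_fd - atree.fd_subsets(cols)
        # ties (within float noise) resolve to the smallest species id, which
        # comes first because candidates are scanned in sorted order
        if mode == "best":
            eligible = losses <= np.min(losses) + 1e-12
        else:
            eligible = losses >= np.max(losses) - 1e-12
        pick = int(np.flatnonzero(eligible)[0])
        pos = alive.pop(pick)
        remaining[idx[pos]] = 0.0
        steps.append((order_species[pos],))
    return Trajectory(steps=tuple(steps), scenario=mode)


def score_ranked_trajectory(
    assemblage: Assemblage | Sequence[str],
    scores: Mapping[str, float],
    direction: str,
    scenario: str = "ranked",
) -> Trajectory:
    """Sequential removal in ``ascending`` or ``descending`` score order.

    The abundance scenario removes in ascending abundance (rarest first); the
    trait scenario in descending intrinsic vulnerability (0-100 scale, most
    vulnerable first).  Score ties are broken lexicographically by species id.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    species = _species_list(assemblage)
    missing = [s for s in species if s not in scores]
    if missing:
        raise KeyError(f"missing scores for species: {missing}")
    sign = 1.0 if direction == "ascending" else -1.0
    ordered = sorted(species, key=lambda s: (sign * scores[s], s))
    steps = tuple((s,) for s in ordered[:-1])
    return Trajectory(steps=steps, scenario=scenario)


def abundance_trajectory(assemblage: Assemblage) -> Trajectory:
    """Rarest-first removal order from the assemblage's own abundances."""
    return score_ranked_trajectory(assemblage, assemblage.abundances, "ascending", scenario="abundance")


def iucn_cluster_trajectory(
    assemblage: Assemblage | Sequence[str],
    iucn_categories: Mapping[str, str],
) -> Trajectory:
    """Cluster removal by Red List category, most threatened first
    (CR > EN > VU > NT > LC); DD/NE fold into LC; empty categories skipped."""
    species = _species_list(assemblage)
    clusters: dict[str, list[str]] = {c: [] for c in IUCN_REMOVAL_ORDER}
    missing = [s for s in species if s not in iucn_categories]
    if missing:
        raise KeyError(f"missing IUCN categories for species: {missing}")
    for s in species:
        cat = iucn_categories[s].upper()
        cat = IUCN_ALIASES.get(cat, cat)
        if cat not in clusters:
            raise ValueError(f"unknown IUCN category {iucn_categories[s]!r} for {s!r}")
        clusters[cat].append(s)
    steps = tuple(tuple(sorted(clusters[c])) for c in IUCN_REMOVAL_ORDER if clusters[c])
    return Trajectory(steps=steps, scenario="iucn")


def random_cluster_trajectories(
    assemblage: Assemblage | Sequence[str],
    cluster_sizes: Sequence[int],
    n: int = 999,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> list[Trajectory]:
    """Random partitions of the assemblage into clusters of the given sizes,
    removed in the given order — the null for the IUCN-based scenario."""
    if n < 2:
        raise ValueError("need at least 2 random trajectories")
    species = _species_list(assemblage)
    if sum(cluster_sizes) != len(species):
        raise ValueError("cluster sizes must sum to the assemblage richness")
    if any(s <= 0 for s in cluster_sizes):
        raise ValueError("cluster sizes must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        perm = rng.permutation(len(species))
        steps = []
        pos = 0
        for size in cluster_sizes:
            steps.append(tuple(species[i] for i in perm[pos : pos + size]))
            pos += size
        out.append(Trajectory(steps=tuple(steps), scenario="random-cluster"))
    return out


def cluster_null_aucs(
    tree: FunctionalDendrogram | AssemblageTree,
    assemblage: Assemblage | None,
    cluster_sizes: Sequence[int],
    n: int = 999,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    axis: str = "span",
) -> np.ndarray:
    """AUCs of ``n`` random cluster trajectories with the given sizes."""
    atree = _as_atree(tree, assemblage)
    _check_not_degenerate(atree)
    sp = atree.species if assemblage is None else assemblage.species
    trajs = random_cluster_trajectories(sp, cluster_sizes, n=n, seed=seed)
    aucs = np.empty(n)
    for i, t in enumerate(trajs):
        x, y = _curve_from_steps(atree, t.steps, axis)
        aucs[i] = np.trapezoid(y, x)
    return aucs


# ---------------------------------------------------------------------------
# Standardised effect size and exact oracle
# ---------------------------------------------------------------------------


def standardized_effect_size(obs_auc: float, random_aucs: Sequence[float], ddof: int = 1) -> float:
    """SES = (observed AUC - null mean) / null SD (sample SD by default).

    Negative values mean the directional scenario erodes functional richness
    faster than random extinction."""
    random_aucs = np.asarray(random_aucs, dtype=float)
    if len(random_aucs) < 2:
        raise ValueError("need at least 2 null AUC values")
    sd = float(np.std(random_aucs, ddof=ddof))
    if sd == 0:
        raise ZeroDivisionError("null SD is zero; SES undefined")
    return float((obs_auc - np.mean(random_aucs)) / sd)


@dataclass
class ExhaustiveSummary:
    """Exact AUC distribution over all removal orders of a small assemblage."""

    aucs: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_population(self) -> float:
        return float(np.std(self.aucs))

    @property
    def sd_sample(self) -> float:
        return float(np.std(self.aucs, ddof=1))

    @property
    def min(self) -> float:
        return float(np.min(self.aucs))

    @property
    def max(self) -> float:
        return float(np.max(self.aucs))


def exhaustive_auc_oracle(
    tree: FunctionalDendrogram | AssemblageTree,
    assemblage: Assemblage | Sequence[str] | None = None,
    max_species: int = 7,
) -> ExhaustiveSummary:
    """Exact AUC mean/SD/min/max over all S! sequential removal orders.

    Refuses S > ``max_species`` (factorial blow-up); intended as a test and
    convergence oracle for the Monte-Carlo null.
    """
    from itertools import permutations

    if isinstance(tree, AssemblageTree):
        atree = tree
    else:
        atree = tree.assemblage_tree(_species_list(assemblage))
    _check_not_degenerate(atree)
    S = atree.n_species
    if S > max_species:
        raise ValueError(f"exhaustive enumeration refused for S = {S} > {max_species}")
    if S < 2:
        raise ValueError("need at least two species")
    species = atree.species
    aucs = []
    for order in permutations(range(S)):
        steps = tuple((species[i],) for i in order[:-1])
        x, y = _curve_from_steps(atree, steps, "span")
        aucs.append(np.trapezoid(y, x))
    return ExhaustiveSummary(aucs=np.asarray(aucs))
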