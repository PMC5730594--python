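"""Functional trait space for fish assemblages.

Species are described by five categorical traits (body size as an ordered
factor; vertical position, trophic group, spawning habitat and swimming mode
as nominal factors).  Pairwise functional dissimilarity is the Gower index,
the functional dendrogram is built by UPGMA (average linkage), and the
functional richness (FD) of any species subset is the total branch length of
the minimal subtree spanning those leaves up to their most recent common
ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

__all__ = [
    "Trait",
    "TraitSchema",
    "TraitTable",
    "DissimilarityMatrix",
    "FunctionalDendrogram",
    "AssemblageTree",
    "default_fish_schema",
    "gower_dissimilarity",
    "build_upgma_dendrogram",
    "cophenetic_correlation",
    "functional_richness",
]

NOMINAL = "nominal"
ORDERED = "ordered"


class SchemaViolationError(ValueError):
    """A trait table does not conform to its declared schema."""


@dataclass(frozen=True)
class Trait:
    """One categorical trait: its name, kind and category list (in order)."""

    name: str
    kind: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in (NOMINAL, ORDERED):
            raise ValueError(f"trait kind must be nominal or ordered, got {self.kind!r}")
        if len(self.categories) == 0:
            raise ValueError(f"trait {self.name!r} has an empty category list")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"trait {self.name!r} has duplicate categories")


@dataclass(frozen=True)
class TraitSchema:
    """An ordered collection of traits defining the functional space."""

    traits: tuple[Trait, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names in schema")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.traits]

    def trait(self, name: str) -> Trait:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)


#: Body size classes are maximum total length (cm); the remaining traits are
#: nominal ecological categories.
def default_fish_schema() -> TraitSchema:
    """The five-trait fish schema used throughout the pipeline."""
    return TraitSchema(
        traits=(
            Trait("size", ORDERED, ("0-8", "8.1-15", "15.1-30", "30.1-50", "50.1-80", ">80.1")),
            Trait("vertical_position", NOMINAL, ("benthic", "non-benthic")),
            Trait(
                "trophic_group",
                NOMINAL,
                (
                    "piscivorous",
                    "omnivorous",
                    "planktivorous",
                    "insectivorous",
                    "herbivorous",
                    "detritivorous",
                    "parasitic",
                ),
            ),
            Trait(
                "spawning_habitat",
                NOMINAL,
                (
                    "lithophilic",
                    "pelagophilic",
                    "phytophilic",
                    "polyphilic",
                    "nest builder",
                    "internal brooder",
                ),
            ),
            Trait(
                "swimming_mode",
                NOMINAL,
                (
                    "carangiform",
                    "sub-carangiform",
                    "diodontiform",
                    "anguilliform",
                    "labriform",
                    "balistiform",
                    "amiiform",
                    "rajiform",
                ),
            ),
        )
    )


class TraitTable:
    """A species x trait table conforming to a :class:`TraitSchema`.

    Parameters
    ----------
    data
        DataFrame indexed by species identifier with one column per trait,
        or a mapping species -> {trait: category}.
    schema
        The trait schema the values must conform to.
    """

    def __init__(self, data: pd.DataFrame | Mapping, schema: TraitSchema) -> None:
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame.from_dict(dict(data), orient="index")
        df = data.copy()
        df.index = df.index.astype(str)
        self.schema = schema
        missing_cols = [n for n in schema.names if n not in df.columns]
        if missing_cols:
            raise SchemaViolationError(f"trait table lacks columns {missing_cols}")
        df = df[schema.names]
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].tolist()
            raise SchemaViolationError(f"duplicate species identifiers: {dup}")
        if df.isna().any().any():
            bad = df.index[df.isna().any(axis=1)].tolist()
            raise SchemaViolationError(f"missing trait values for species {bad}")
        for t in schema.traits:
            bad_vals = set(df[t.name]) - set(t.categories)
            if bad_vals:
                raise SchemaViolationError(
                    f"unknown categories {sorted(bad_vals)} for trait {t.name!r}"
                )
        self.data = df

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, species: Iterable[str]) -> "TraitTable":
        return TraitTable(self.data.loc[list(species)], self.schema)

    @classmethod
    def from_csv(cls, path: str | Path, schema: TraitSchema, sep: str | None = None) -> "TraitTable":
        """Read a trait table from CSV/TSV; first column = species identifier."""
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
        return cls(df, schema)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index_label="species")


@dataclass
class DissimilarityMatrix:
    """Square symmetric matrix of pairwise dissimilarities in [0, 1]."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def gower_dissimilarity(table: TraitTable, schema: TraitSchema | None = None) -> DissimilarityMatrix:
    """Gower dissimilarity over mixed nominal/ordered categorical traits.

    Each trait contributes equally (unweighted mean).  A nominal trait
    contributes 0 on a match and 1 on a mismatch; an ordered trait with L
    levels ranked 1..L contributes ``|rank_a - rank_b| / (L - 1)``.
    """
    if schema is None:
        schema = table.schema
    species = table.species
    n = len(species)
    total = np.zeros((n, n))
    for t in schema.traits:
        col = table.data[t.name]
        if t.kind == ORDERED:
            ranks = col.map({c: r for r, c in enumerate(t.categories, start=1)}).to_numpy(float)
            L = len(t.categories)
            contrib = np.abs(ranks[:, None] - ranks[None, :]) / (L - 1) if L > 1 else np.zeros((n, n))
        else:
            codes = col.map({c: i for i, c in enumerate(t.categories)}).to_numpy()
            contrib = (codes[:, None] != codes[None, :]).astype(float)
        total += contrib
    return DissimilarityMatrix(total / len(schema.traits), species)


# ---------------------------------------------------------------------------
# UPGMA dendrogram
# ---------------------------------------------------------------------------


class FunctionalDendrogram:
    """Rooted ultrametric binary merge tree over a species pool.

    Nodes ``0..n-1`` are leaves (in ``labels`` order); internal nodes are
    appended in merge order, so children always precede parents.  Each node
    carries the height at which its cluster was formed (leaves at 0); the
    branch length above a node is the height difference to its parent.
    """

    def __init__(self, labels: Sequence[str], merges: Sequence[tuple[int, int, float]]):
        n = len(labels)
        if len(merges) != n - 1:
            raise ValueError("a binary tree over n leaves needs n-1 merges")
        self.labels = [str(s) for s in labels]
        self.n_leaves = n
        m = 2 * n - 1
        self.parent = np.full(m, -1, dtype=np.int64)
        self.height = np.zeros(m)
        self.children: list[tuple[int, int] | None] = [None] * m
        self.leaf_index = {s: i for i, s in enumerate(self.labels)}
        for k, (a, b, h) in enumerate(merges):
            node = n + k
            self.parent[a] = node
            self.parent[b] = node
            self.height[node] = h
            self.children[node] = (a, b)
        heights = self.height[n:]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing (ultrametric)")
        # cluster sizes, for the scipy linkage representation
        sizes = np.ones(m, dtype=np.int64)
        for node in range(n, m):
            a, b = self.children[node]  # type: ignore[misc]
            sizes[node] = sizes[a] + sizes[b]
        self._sizes = sizes

    # -- representation / export ------------------------------------------

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def linkage_matrix(self) -> np.ndarray:
        """scipy-style (n-1) x 4 linkage matrix [left, right, height, size]."""
        n = self.n_leaves
        Z = np.zeros((n - 1, 4))
        for node in range(n, 2 * n - 1):
            a, b = self.children[node]  # type: ignore[misc]
            Z[node - n] = [a, b, self.height[node], self._sizes[node]]
        return Z

    def branch_length(self, node: int) -> float:
        """Length of the edge above ``node`` (0 for the root)."""
        p = self.parent[node]
        return 0.0 if p < 0 else float(self.height[p] - self.height[node])

    def total_branch_length(self) -> float:
        p = self.parent[:-1]
        return float(np.sum(self.height[p] - self.height[np.arange(len(p))]))

    def cophenetic_matrix(self) -> np.ndarray:
        """Condensed matrix of LCA heights for all leaf pairs."""
        return sch.cophenet(self.linkage_matrix())

    def to_newick(self) -> str:
        """Newick string with branch lengths (heights converted to edges)."""

        def render(node: int) -> str:
            if self.children[node] is None:
                name = self.labels[node].replace(" ", "_")
                return f"{name}:{self.branch_length(node):.10g}"
            a, b = self.children[node]  # type: ignore[misc]
            return f"({render(a)},{render(b)}):{self.branch_length(node):.10g}"

        return render(self.root) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- functional richness ----------------------------------------------

    def _leaf_ids(self, subset: Iterable[str]) -> np.ndarray:
        ids = []
        for s in subset:
            if s not in self.leaf_index:
                raise KeyError(f"species {s!r} is not a leaf of the dendrogram")
            ids.append(self.leaf_index[s])
        return np.asarray(ids, dtype=np.int64)

    def functional_richness(self, subset: Iterable[str]) -> float:
        """Total branch length spanning ``subset`` up to its most recent
        common ancestor.  Empty and singleton subsets have FD 0."""
        ids = self._leaf_ids(subset)
        if len(set(ids.tolist())) != len(ids):
            raise ValueError("subset contains duplicate species")
        k = len(ids)
        if k <= 1:
            return 0.0
        m = 2 * self.n_leaves - 1
        counts = np.zeros(m, dtype=np.int64)
        counts[ids] = 1
        for node in range(self.n_leaves, m):
            a, b = self.children[node]  # type: ignore[misc]
            counts[node] = counts[a] + counts[b]
        # an edge is spanned iff its subtree holds some but not all subset leaves
        active = (counts > 0) & (counts < k)
        nodes = np.flatnonzero(active)
        return float(np.sum(self.height[self.parent[nodes]] - self.height[nodes]))

    def assemblage_tree(self, species: Iterable[str]) -> "AssemblageTree":
        return AssemblageTree(self, list(species))


def build_upgma_dendrogram(D: DissimilarityMatrix) -> FunctionalDendrogram:
    """UPGMA (average linkage) with deterministic tie-breaking.

    At each step the pair of clusters at minimal average dissimilarity is
    merged; among tied pairs, the pair whose (lexicographically smallest
    member label) pair sorts first is chosen, so the tree is reproducible
    bit-for-bit regardless of input order.
    """
    n = len(D.labels)
    if n < 2:
        raise ValueError("need at least two species to build a dendrogram")
    d = D.values.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(n))  # current cluster node ids
    node_of = {i: i for i in range(n)}  # row index -> tree node id
    sizes = {i: 1 for i in range(n)}
    # representative label for lexicographic tie-breaking: smallest leaf label
    rep = {i: D.labels[i] for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    rows = list(range(n))
    work = d
    next_node = n
    while len(rows) > 1:
        sub = work[np.ix_(rows, rows)]
        h = np.min(sub)
        ii, jj = np.where(np.isclose(sub, h, rtol=0, atol=1e-15))
        pairs = [(rows[a], rows[b]) for a, b in zip(ii, jj) if a < b]
        i, j = min(pairs, key=lambda p: tuple(sorted((rep[p[0]], rep[p[1]]))))
        # average-linkage update of row i; drop row j
        si, sj = sizes[i], sizes[j]
        for r in rows:
            if r in (i, j):
                continue
            val = (si * work[i, r] + sj * work[j, r]) / (si + sj)
            work[i, r] = work[r, i] = val
        merges.append((node_of[i], node_of[j], float(h)))
        node_of[i] = next_node
        sizes[i] = si + sj
        rep[i] = min(rep[i], rep[j])
        rows.remove(j)
        next_node += 1
    return FunctionalDendrogram(D.labels, merges)


def cophenetic_correlation(tree: FunctionalDendrogram, D: DissimilarityMatrix) -> float:
    """Pearson correlation between cophenetic and original dissimilarities.

    A value of 1 means the dendrogram represents the dissimilarities
    perfectly (only possible when they are ultrametric)."""
    if tree.labels != D.labels:
        raise ValueError("tree and matrix species sets differ")
    if tree.n_leaves < 3:
        raise ValueError("cophenetic correlation needs at least 3 species")
    coph = tree.cophenetic_matrix()
    orig = D.condensed()
    if np.std(coph) == 0 or np.std(orig) == 0:
        raise ValueError("cophenetic correlation undefined for constant distances")
    return float(np.corrcoef(coph, orig)[0, 1])


def functional_richness(tree: FunctionalDendrogram, subset: Iterable[str]) -> float:
    """Module-level convenience wrapper for
    :meth:`FunctionalDendrogram.functional_richness`."""
    return tree.functional_richness(subset)


# ---------------------------------------------------------------------------
# Reduced per-assemblage tree for fast repeated FD evaluation
# ---------------------------------------------------------------------------


class AssemblageTree:
    """The pool dendrogram restricted to one assemblage's species.

    Degree-two paths are contracted, so the structure has at most ``2S - 1``
    nodes for S species; FD of any species subset computed here equals the
    value on the full pool tree.  Exposes a vectorised evaluator used by the
    extinction simulations: FD of a subset T is the sum of branch lengths of
    edges whose subtree holds some but not all of T's leaves.
    """

    def __init__(self, tree: FunctionalDendrogram, species: Sequence[str]):
        species = [str(s) for s in species]
        if len(set(species)) != len(species):
            raise ValueError("duplicate species in assemblage")
        self.species = species
        S = len(species)
        if S < 1:
            raise ValueError("assemblage must contain at least one species")
        ids = tree._leaf_ids(species)
        m = 2 * tree.n_leaves - 1
        counts = np.zeros(m, dtype=np.int64)
        counts[ids] = 1
        for node in range(tree.n_leaves, m):
            a, b = tree.children[node]  # type: ignore[misc]
            counts[node] = counts[a] + counts[b]
        lca = int(np.flatnonzero(counts == S)[0]) if S > 1 else int(ids[0])
        # essential nodes: assemblage leaves + branching internal nodes <= LCA
        essential = set(int(i) for i in ids)
        for node in range(tree.n_leaves, lca + 1):
            a, b = tree.children[node]  # type: ignore[misc]
            if counts[a] > 0 and counts[b] > 0 and counts[node] <= S and node <= lca:
                essential.add(node)
        essential.add(lca)
        order = sorted(essential, key=lambda v: (tree.height[v], v))
        local = {v: i for i, v in enumerate(order)}
        M = len(order)
        self.n_species = S
        self.heights = np.array([tree.height[v] for v in order])
        self.parent = np.full(M, -1, dtype=np.int64)
        for v in order:
            if v == lca:
                continue
            p = int(tree.parent[v])
            while p not in essential:
                p = int(tree.parent[p])
            self.parent[local[v]] = local[p]
        self.lengths = np.zeros(M)
        has_parent = self.parent >= 0
        idx = np.flatnonzero(has_parent)
        self.lengths[idx] = self.heights[self.parent[idx]] - self.heights[idx]
        # leaf membership matrix A (M x S): A[v, s] = leaf s under node v
        A = np.zeros((M, S), dtype=np.float64)
        for s, sp_id in enumerate(ids):
            v = local[int(sp_id)]
            while v >= 0:
                A[v, s] = 1.0
                v = self.parent[v]
        self.A = A
        self.leaf_local = {sp: s for s, sp in enumerate(species)}
        self.fd_full = self.fd_subsets(np.ones((S, 1)))[0] if S > 1 else 0.0

    def fd_subsets(self, indicators: np.ndarray) -> np.ndarray:
        """FD for each column of a (S x K) 0/1 subset indicator matrix."""
        counts = self.A @ indicators
        sizes = indicators.sum(axis=0)
        active = (counts > 0.5) & (counts < sizes[None, :] - 0.5)
        return self.lengths @ active

    def fd(self, subset: Iterable[str]) -> float:
        ind = np.zeros((self.n_species, 1))
        for s in subset:
            ind[self.leaf_local[s], 0] = 1.0
        return float(self.fd_subsets(ind)[0])
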