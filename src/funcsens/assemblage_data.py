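"""Site and assemblage data model.

Sites come from three aquatic system types (lakes, rivers, estuaries) in two
biogeographical regions.  Raw survey counts are standardised to densities with
system-specific conventions, pooled across sampling events per site, and
filtered by the study's inclusion rules before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SamplingEvent",
    "SiteRecord",
    "Assemblage",
    "classify_size_category",
    "filter_river_sites",
    "standardize_abundance",
    "pool_samples",
    "read_long_format",
    "read_wide_format",
]

SYSTEMS = ("lake", "river", "estuary")
REGIONS = ("Danubian", "Iberian")
RIVER_CATEGORIES = ("HWS", "MGR", "LLR", "MES")

#: Surface-area thresholds (km^2) separating small from large systems.
LAKE_SIZE_THRESHOLD_KM2 = 0.68
ESTUARY_SIZE_THRESHOLD_KM2 = 25.0

#: River inclusion rule: fished area and pooled catch must exceed these.
MIN_RIVER_FISHED_AREA_M2 = 100.0
MIN_RIVER_INDIVIDUALS = 50

#: Estuarine densities are reported per 1000 m^2; lakes (per m^2 of net per
#: night) and rivers (per m^2) use the raw count/effort ratio.
DENSITY_SCALE = {"estuary": 1000.0, "lake": 1.0, "river": 1.0}


@dataclass
class SamplingEvent:
    """One survey of a site: raw counts per species and the sampling effort.

    Effort is the sampled surface in m^2; for lakes it is net area (m^2)
    multiplied by the number of nights.
    """

    counts: dict[str, float]
    effort: float

    def __post_init__(self) -> None:
        if self.effort <= 0:
            raise ValueError("sampling effort must be positive")
        for sp, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for species {sp!r}")

    @property
    def total_individuals(self) -> float:
        return sum(self.counts.values())


@dataclass
class SiteRecord:
    """A monitored site with its metadata and sampling events."""

    site_id: str
    system: str
    region: str
    samplings: list[SamplingEvent] = field(default_factory=list)
    surface_area_km2: float | None = None  # lakes and estuaries
    fished_area_m2: float | None = None  # rivers
    river_category: str | None = None  # rivers: HWS / MGR / LLR / MES

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown system {self.system!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.system == "river":
            if self.river_category is not None and self.river_category not in RIVER_CATEGORIES:
                raise ValueError(f"unknown river category {self.river_category!r}")
        else:
            if self.surface_area_km2 is not None and self.surface_area_km2 < 0:
                raise ValueError("surface area must be non-negative")

    @property
    def total_individuals(self) -> float:
        return sum(ev.total_individuals for ev in self.samplings)

    @property
    def category(self) -> str:
        """Within-system category: size class, or the river category."""
        if self.system == "river":
            return self.river_category or "unknown"
        if self.surface_area_km2 is None:
            return "unknown"
        return classify_size_category(self.system, self.surface_area_km2)


@dataclass
class Assemblage:
    """One site's species set with standardised abundances (densities > 0)."""

    site_id: str
    system: str
    abundances: dict[str, float]
    region: str = "Danubian"
    category: str = "unknown"

    def __post_init__(self) -> None:
        if not self.abundances:
            raise ValueError(f"assemblage {self.site_id!r} has no species")
        bad = [s for s, a in self.abundances.items() if a <= 0]
        if bad:
            raise ValueError(f"non-positive abundances for {bad} at site {self.site_id!r}")

    @property
    def species(self) -> list[str]:
        return sorted(self.abundances)

    @property
    def richness(self) -> int:
        return len(self.abundances)


def classify_size_category(system: str, surface_area_km2: float) -> str:
    """Small/large classification of lakes and estuaries by surface area.

    Boundary values fall in the ``large`` class.  Rivers are categorised by
    assemblage type, not area, and are rejected here.
    """
    if system == "river":
        raise ValueError("river sites carry a supplied category, not a size class")
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}")
    if surface_area_km2 <= 0:
        raise ValueError("surface area must be positive")
    threshold = LAKE_SIZE_THRESHOLD_KM2 if system == "lake" else ESTUARY_SIZE_THRESHOLD_KM2
    return "large" if surface_area_km2 >= threshold else "small"


def filter_river_sites(records: Iterable[SiteRecord]) -> list[SiteRecord]:
    """Keep river sites with fished area > 100 m^2 and > 50 individuals caught
    (both strict); non-river records pass through unchanged."""
    kept = []
    for rec in records:
        if rec.system != "river":
            kept.append(rec)
            continue
        if rec.fished_area_m2 is None:
            continue
        if rec.fished_area_m2 > MIN_RIVER_FISHED_AREA_M2 and rec.total_individuals > MIN_RIVER_INDIVIDUALS:
            kept.append(rec)
    return kept


def standardize_abundance(counts: float, effort: float, system: str) -> float:
    """Convert a raw count and effort to the system's density convention:
    estuaries individuals / 1000 m^2, lakes individuals / m^2 / night,
    rivers individuals / m^2."""
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}")
    if effort <= 0:
        raise ValueError("effort must be positive")
    if counts < 0:
        raise ValueError("counts must be non-negative")
    return counts / effort * DENSITY_SCALE[system]


def pool_samples(record: SiteRecord) -> Assemblage:
    """Pool a site's sampling events into one assemblage.

    Abundance is the pooled ratio (total counts over total effort, rescaled to
    the system convention), which weights samples by their effort and is
    invariant to splitting a sample into proportional parts.
    """
    if not record.samplings:
        raise ValueError(f"site {record.site_id!r} has no samplings")
    total_effort = sum(ev.effort for ev in record.samplings)
    totals: dict[str, float] = {}
    for ev in record.samplings:
        for sp, c in ev.counts.items():
            totals[sp] = totals.get(sp, 0.0) + c
    abund = {
        sp: standardize_abundance(c, total_effort, record.system)
        for sp, c in totals.items()
        if c > 0
    }
    if not abund:
        raise ValueError(f"site {record.site_id!r} has no individuals")
    return Assemblage(
        site_id=record.site_id,
        system=record.system,
        abundances=abund,
        region=record.region,
        category=record.category,
    )


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_long_format(
    counts_path: str | Path,
    sites_path: str | Path,
) -> list[SiteRecord]:
    """Read survey data from two CSV/TSV tables.

    ``counts_path`` is long format with columns ``site, sampling, species,
    count, effort`` (one row per species per sampling event); ``sites_path``
    has columns ``site, system, region`` and optionally ``surface_area_km2``,
    ``fished_area_m2``, ``river_category``.
    """
    counts = pd.read_csv(counts_path, sep=_sep_for(counts_path))
    sites = pd.read_csv(sites_path, sep=_sep_for(sites_path)).set_index("site")
    records = []
    for site_id, site_rows in counts.groupby("site"):
        meta = sites.loc[site_id]
        samplings = []
        for _, ev_rows in site_rows.groupby("sampling"):
            effort = float(ev_rows["effort"].iloc[0])
            c = {str(r.species): float(r.count) for r in ev_rows.itertuples()}
            samplings.append(SamplingEvent(counts=c, effort=effort))

        def _opt(col: str) -> float | str | None:
            v = meta.get(col)
            return None if v is None or pd.isna(v) else v

        records.append(
            SiteRecord(
                site_id=str(site_id),
                system=str(meta["system"]),
                region=str(meta["region"]),
                samplings=samplings,
                surface_area_km2=_opt("surface_area_km2"),
                fished_area_m2=_opt("fished_area_m2"),
                river_category=_opt("river_category"),
            )
        )
    return records


def read_wide_format(
    matrix_path: str | Path,
    sites_path: str | Path,
    effort_column: str = "effort",
) -> list[SiteRecord]:
    """Read a site x species count matrix (first column = site id) plus the
    site metadata table; each site is treated as a single pooled sampling
    whose effort comes from ``effort_column`` of the metadata table."""
    mat = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0)
    sites = pd.read_csv(sites_path, sep=_sep_for(sites_path)).set_index("site")
    records = []
    for site_id, row in mat.iterrows():
        meta = sites.loc[site_id]
        counts = {str(sp): float(v) for sp, v in row.items() if v > 0}
        ev = SamplingEvent(counts=counts, effort=float(meta[effort_column]))

        def _opt(col: str) -> float | str | None:
            v = meta.get(col)
            return None if v is None or pd.isna(v) else v

        records.append(
            SiteRecord(
                site_id=str(site_id),
                system=str(meta["system"]),
                region=str(meta["region"]),
                samplings=[ev],
                surface_area_km2=_opt("surface_area_km2"),
                fished_area_m2=_opt("fished_area_m2"),
                river_category=_opt("river_category"),
            )
        )
    return records
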