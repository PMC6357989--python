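"""Located synthetic household population from gridded counts and regions.

Starting from gridded person counts (LandScan-style cells), nested
administrative polygons (county containing communes), and per-commune
ethnicity count tables, this module places households on the grid so
that

* every cell's household sizes sum exactly to its person count,
* each commune's Roma person-share tracks its census share via a
  largest-remainder quota (randomized order, exact regional totals),
* household sizes follow per-ethnicity truncated-Poisson distributions
  (defaults calibrated to mean sizes of 5.3 Roma / 4.2 non-Roma),
* member ages are drawn conditional on ethnicity, giving each household
  a three-level age structure (no / some / majority minors).

Everything is deterministic given the inputs and a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import Point, shape

from .survey import AGE_STRUCTURES

MAX_HOUSEHOLD_SIZE = 12


class RegionCoverageError(ValueError):
    """Some grid cells fall outside every commune polygon."""

    def __init__(self, orphans: list[str]):
        self.orphans = orphans
        super().__init__(
            f"{len(orphans)} grid cell(s) not covered by any commune polygon: "
            f"{orphans[:20]}"
        )


@dataclass(slots=True)
class GridCell:
    """One populated grid cell (centroid coordinates, person count)."""

    cell_id: str
    x: float
    y: float
    population: int
    commune_id: str | None = None
    county_id: str | None = None


@dataclass(slots=True, frozen=True)
class RegionEthnicity:
    """Census ethnicity counts for one region."""

    region_id: str
    count_roma: int
    count_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.count_roma <= self.count_total:
            raise ValueError(
                f"region {self.region_id}: need 0 <= roma <= total"
            )

    @property
    def roma_share(self) -> float:
        return self.count_roma / self.count_total if self.count_total else 0.0


@dataclass(slots=True)
class SyntheticHousehold:
    """One located synthetic household."""

    household_id: str
    cell_id: str
    commune_id: str
    county_id: str
    size: int
    ethnicity: str
    age_structure: str
    ages: list[int]


@dataclass(slots=True, frozen=True)
class TruncatedPoissonSizes:
    """Household-size distribution: Poisson conditioned to [1, max_size]."""

    mean: float
    max_size: int = MAX_HOUSEHOLD_SIZE

    def pmf(self) -> np.ndarray:
        k = np.arange(1, self.max_size + 1)
        p = sps.poisson.pmf(k, self.mean)
        return p / p.sum()

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(np.arange(1, self.max_size + 1), size=n, p=self.pmf())


DEFAULT_SIZE_DISTS: dict[str, TruncatedPoissonSizes] = {
    "roma": TruncatedPoissonSizes(mean=5.3),
    "non_roma": TruncatedPoissonSizes(mean=4.2),
}


@dataclass(slots=True, frozen=True)
class AgeModel:
    """Per-member minor probability by ethnicity; ages uniform in band.

    Roma households skew younger than non-Roma ones; one adult (the
    respondent analogue) is always present.
    """

    p_minor: Mapping[str, float] = field(
        default_factory=lambda: {"roma": 0.45, "non_roma": 0.30}
    )

    def sample_ages(
        self, ethnicity: str, size: int, rng: np.random.Generator
    ) -> list[int]:
        ages = [int(rng.integers(18, 81))]  # at least one adult
        p = self.p_minor[ethnicity]
        for _ in range(size - 1):
            if rng.random() < p:
                ages.append(int(rng.integers(0, 18)))
            else:
                ages.append(int(rng.integers(18, 81)))
        return ages


def classify_age_structure(ages: Sequence[int]) -> str:
    n_minor = sum(a < 18 for a in ages)
    if n_minor == 0:
        return "no_minors"
    if n_minor > len(ages) / 2:
        return "majority_minors"
    return "some_minors"


def load_regions(path: str | Path) -> tuple[dict[str, object], dict[str, str]]:
    """Read a regions GeoJSON into (commune_id -> shapely geometry,
    commune_id -> county_id)."""
    with open(path) as fh:
        gj = json.load(fh)
    geoms: dict[str, object] = {}
    county_of: dict[str, str] = {}
    for feat in gj["features"]:
        props = feat["properties"]
        if props.get("level") != "commune":
            continue
        rid = str(props["region_id"])
        geoms[rid] = shape(feat["geometry"])
        county_of[rid] = str(props["county_id"])
    return geoms, county_of


def attach_regions(
    cells: Sequence[GridCell],
    commune_geoms: Mapping[str, object],
    county_of: Mapping[str, str],
) -> list[GridCell]:
    """Label each cell with the commune/county containing its centroid.

    Containment includes polygon boundaries; a centroid on a shared edge
    is assigned to the lexicographically lowest commune id.  Cells not
    covered by any commune raise :class:`RegionCoverageError`.
    """
    ordered = sorted(commune_geoms.items(), key=lambda kv: kv[0])
    orphans: list[str] = []
    out: list[GridCell] = []
    for cell in cells:
        pt = Point(cell.x, cell.y)
        assigned = None
        for rid, geom in ordered:
            if geom.covers(pt):
                assigned = rid
                break
        if assigned is None:
            orphans.append(cell.cell_id)
            continue
        out.append(
            GridCell(
                cell_id=cell.cell_id,
                x=cell.x,
                y=cell.y,
                population=cell.population,
                commune_id=assigned,
                county_id=county_of[assigned],
            )
        )
    if orphans:
        raise RegionCoverageError(orphans)
    return out


def _largest_remainder_roma_count(share: float, n: int) -> int:
    """Largest-remainder apportionment of n households between two groups."""
    exact = share * n
    base = int(np.floor(exact))
    return base + (1 if exact - base >= 0.5 else 0)


def build_households(
    cells: Sequence[GridCell],
    ethnicity: Mapping[str, RegionEthnicity],
    size_dists: Mapping[str, TruncatedPoissonSizes] | None = None,
    age_model: AgeModel | None = None,
    seed: int | np.random.Generator = 0,
) -> list[SyntheticHousehold]:
    """Fill every cell with households summing exactly to its population.

    Per cell: sizes are drawn i.i.d. from the ethnicity mixture implied
    by the commune's Roma share until the cumulative size reaches the
    cell population (last household truncated to fit); ethnicities are
    then assigned by largest-remainder quota against the commune share,
    in an order randomized by the seed.
    """
    size_dists = dict(size_dists or DEFAULT_SIZE_DISTS)
    age_model = age_model or AgeModel()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sizes_support = np.arange(1, MAX_HOUSEHOLD_SIZE + 1)
    households: list[SyntheticHousehold] = []
    hid = 0
    for cell in cells:
        if cell.commune_id is None or cell.county_id is None:
            raise ValueError(f"cell {cell.cell_id} has no region labels")
        if cell.population <= 0:
            continue
        eth_row = ethnicity.get(cell.commune_id)
        if eth_row is None:
            raise ValueError(
                f"commune {cell.commune_id} is populated but has no ethnicity row"
            )
        share = eth_row.roma_share
        mix_pmf = share * size_dists["roma"].pmf() + (1 - share) * size_dists[
            "non_roma"
        ].pmf()
        sizes: list[int] = []
        total = 0
        while total < cell.population:
            s = int(rng.choice(sizes_support, p=mix_pmf))
            if total + s > cell.population:
                s = cell.population - total  # truncate the last household
            sizes.append(s)
            total += s
        n_h = len(sizes)
        n_roma = _largest_remainder_roma_count(share, n_h)
        eth_labels = np.array(["non_roma"] * n_h, dtype=object)
        eth_labels[rng.permutation(n_h)[:n_roma]] = "roma"
        for s, eth in zip(sizes, eth_labels):
            ages = age_model.sample_ages(eth, s, rng)
            households.append(
                SyntheticHousehold(
                    household_id=f"h{hid:07d}",
                    cell_id=cell.cell_id,
                    commune_id=cell.commune_id,
                    county_id=cell.county_id,
                    size=s,
                    ethnicity=str(eth),
                    age_structure=classify_age_structure(ages),
                    ages=ages,
                )
            )
            hid += 1
    return households


def households_to_frame(households: Sequence[SyntheticHousehold]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "household_id": [h.household_id for h in households],
            "cell_id": [h.cell_id for h in households],
            "commune_id": [h.commune_id for h in households],
            "county_id": [h.county_id for h in households],
            "size": [h.size for h in households],
            "ethnicity": [h.ethnicity for h in households],
            "age_structure": [h.age_structure for h in households],
            "ages": [" ".join(map(str, h.ages)) for h in households],
        }
    )


def load_grid(path: str | Path) -> list[GridCell]:
    """Read a grid CSV (cell_id,x,y,population[,commune_id,county_id])."""
    df = pd.read_csv(path, dtype={"cell_id": str})
    cells = []
    for row in df.itertuples(index=False):
        cells.append(
            GridCell(
                cell_id=str(row.cell_id),
                x=float(row.x),
                y=float(row.y),
                population=int(row.population),
                commune_id=str(row.commune_id) if hasattr(row, "commune_id") else None,
                county_id=str(row.county_id) if hasattr(row, "county_id") else None,
            )
        )
    return cells


def load_ethnicity(path: str | Path) -> dict[str, RegionEthnicity]:
    """Read a per-region ethnicity CSV (region_id,count_roma,count_total)."""
    df = pd.read_csv(path, dtype={"region_id": str})
    return {
        str(r.region_id): RegionEthnicity(
            region_id=str(r.region_id),
            count_roma=int(r.count_roma),
            count_total=int(r.count_total),
        )
        for r in df.itertuples(index=False)
    }
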