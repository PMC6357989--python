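"""Synthetic study inputs: landscape, ethnicity tables, and coded surveys.

This generator stands in for the data sources the pipeline was designed
around — gridded person counts, nested administrative regions with
per-region ethnicity censuses, and a small coded needs-assessment
survey — while keeping their statistical structure:

* a rectangular grid of cells with log-normal person counts, tiled into
  rectangular communes nested inside counties;
* a low background Roma share with elevated-share cluster communes
  (recorded as planted ground truth for recovery scoring);
* a five-community survey (default sizes 29/30/30/30/16, 98 Roma / 37
  non-Roma) in which every adverse indicator is Bernoulli with a
  configured non-Roma prevalence p0 and a Roma prevalence solved from a
  target odds ratio:  p1 = OR*q / (1 + OR*q), q = p0 / (1 - p0).

Default indicator prevalences and odds ratios are calibrated to the
published Roma vs non-Roma comparisons the pipeline is meant to
reproduce (e.g. insecure housing p0 = 0.054, OR = 6.65).  All outputs
are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from shapely.geometry import box, mapping

from .survey import SurveyRecord
from .synthpop import GridCell, RegionEthnicity


class ConfigError(ValueError):
    pass


@dataclass(slots=True, frozen=True)
class IndicatorSpec:
    """Adverse-state prevalence p0 (non-Roma) and target Roma/non-Roma OR."""

    p0: float
    odds_ratio: float

    def p1(self) -> float:
        """Roma adverse prevalence implied by the target odds ratio."""
        if not 0.0 <= self.p0 < 1.0:
            raise ConfigError(f"p0={self.p0} must be in [0, 1)")
        if self.odds_ratio <= 0:
            raise ConfigError("target odds ratio must be positive")
        q = self.p0 / (1.0 - self.p0)
        odds1 = self.odds_ratio * q
        return odds1 / (1.0 + odds1)

    def prevalence(self, ethnicity: str) -> float:
        return self.p1() if ethnicity == "roma" else self.p0


#: adverse-direction indicator calibration (non-Roma prevalence, target OR)
DEFAULT_INDICATORS: dict[str, IndicatorSpec] = {
    "indoor_toilet_lacking": IndicatorSpec(0.784, 1.31),
    "indoor_bathroom_lacking": IndicatorSpec(0.784, 1.08),
    "improved_water_lacking": IndicatorSpec(0.919, 0.34),
    "insecure_housing": IndicatorSpec(0.054, 6.65),
    "safe_water_lacking": IndicatorSpec(0.405, 1.47),
    "diarrhea": IndicatorSpec(0.405, 2.04),
    "not_immunized": IndicatorSpec(0.029, 4.65),
    "uninsured": IndicatorSpec(0.109, 1.86),
    "no_pcp_access": IndicatorSpec(0.030, 0.75),
    "electricity_lacking": IndicatorSpec(0.027, 5.51),
    "gas_lacking": IndicatorSpec(0.189, 2.08),
    "severe_poverty": IndicatorSpec(0.432, 1.61),
    "low_education": IndicatorSpec(0.25, 6.0),
    "illiterate": IndicatorSpec(0.026, 23.95),
    "no_property_documents": IndicatorSpec(0.30, 1.50),
    "unemployed": IndicatorSpec(0.676, 1.33),
    "single": IndicatorSpec(0.243, 1.00),
}


@dataclass(slots=True, frozen=True)
class CommunitySpec:
    """One survey community: size, Roma head-count, geography class."""

    community_id: str
    n_households: int
    n_roma: int
    geography_class: str

    def __post_init__(self) -> None:
        if not 0 <= self.n_roma <= self.n_households:
            raise ConfigError(f"{self.community_id}: n_roma outside [0, n]")


#: default five-community layout (98 Roma / 37 non-Roma, three rural,
#: one suburban, one urban community)
DEFAULT_COMMUNITIES: tuple[CommunitySpec, ...] = (
    CommunitySpec("community_1", 29, 28, "rural"),
    CommunitySpec("community_2", 30, 24, "rural"),
    CommunitySpec("community_3", 30, 18, "suburban"),
    CommunitySpec("community_4", 30, 13, "rural"),
    CommunitySpec("community_5", 16, 15, "urban"),
)


@dataclass
class GeneratorConfig:
    """Everything the synthetic-input generator needs.

    The landscape is a ``cells_x`` x ``cells_y`` grid of unit cells,
    tiled into ``counties_x`` x ``counties_y`` counties each holding
    ``communes_x`` x ``communes_y`` communes.
    """

    seed: int
    cells_x: int = 20
    cells_y: int = 20
    counties_x: int = 2
    counties_y: int = 2
    communes_x: int = 5
    communes_y: int = 5
    cell_pop_median: float = 400.0
    cell_pop_sigma: float = 0.3
    base_roma_share: float = 0.05
    cluster_roma_share: float = 0.5
    n_cluster_communes: int = 3
    planted_need_prevalence: float = 0.6
    background_need_prevalence: float = 0.2
    communities: tuple[CommunitySpec, ...] = DEFAULT_COMMUNITIES
    indicators: Mapping[str, IndicatorSpec] = field(
        default_factory=lambda: dict(DEFAULT_INDICATORS)
    )
    household_size_mean_roma: float = 5.3
    household_size_mean_non_roma: float = 4.2
    p_minor: Mapping[str, float] = field(
        default_factory=lambda: {"roma": 0.45, "non_roma": 0.30}
    )
    pct_water_over_1km: Mapping[str, float] = field(
        default_factory=lambda: {"roma": 0.122, "non_roma": 0.108}
    )
    p_male: Mapping[str, float] = field(
        default_factory=lambda: {"roma": 0.51, "non_roma": 0.46}
    )
    age_mean: Mapping[str, float] = field(
        default_factory=lambda: {"roma": 44.8, "non_roma": 52.4}
    )
    age_sd: float = 15.0

    def __post_init__(self) -> None:
        for name, spec in self.indicators.items():
            if not 0 <= spec.p0 < 1:
                raise ConfigError(f"{name}: p0 outside [0, 1)")
            spec.p1()  # raises on impossible OR/p0 combinations
        if not 0 <= self.base_roma_share <= 1 or not 0 <= self.cluster_roma_share <= 1:
            raise ConfigError("roma shares must lie in [0, 1]")
        n_communes = (
            self.counties_x * self.counties_y * self.communes_x * self.communes_y
        )
        if self.n_cluster_communes > n_communes:
            raise ConfigError("more cluster communes than communes in the landscape")
        if self.cells_x % (self.counties_x * self.communes_x) or self.cells_y % (
            self.counties_y * self.communes_y
        ):
            raise ConfigError("commune tiling must divide the cell grid evenly")


def config_from_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "communities" in raw:
        raw["communities"] = tuple(CommunitySpec(**c) for c in raw["communities"])
    if "indicators" in raw:
        raw["indicators"] = {
            k: IndicatorSpec(**v) for k, v in raw["indicators"].items()
        }
    return GeneratorConfig(**raw)


def _commune_layout(config: GeneratorConfig):
    """Yield (commune_id, county_id, x0, y0, x1, y1) rectangles."""
    cw = config.cells_x // (config.counties_x * config.communes_x)
    ch = config.cells_y // (config.counties_y * config.communes_y)
    for cy in range(config.counties_y):
        for cx in range(config.counties_x):
            county_id = f"J{cy * config.counties_x + cx + 1:02d}"
            for my in range(config.communes_y):
                for mx in range(config.communes_x):
                    commune_id = (
                        f"{county_id}-C{my * config.communes_x + mx + 1:02d}"
                    )
                    x0 = (cx * config.communes_x + mx) * cw
                    y0 = (cy * config.communes_y + my) * ch
                    yield commune_id, county_id, x0, y0, x0 + cw, y0 + ch


def plant_truth(config: GeneratorConfig) -> dict:
    """Which communes carry the elevated Roma share / elevated need.

    A seed-chosen anchor commune and its nearest neighbors (by centroid
    distance, ``n_cluster_communes`` in total) form one contiguous
    high-need cluster, emulating a regional concentration; the result
    records them for recovery scoring.
    """
    layout = list(_commune_layout(config))
    communes = [c for c, *_ in layout]
    centroids = np.array(
        [((x0 + x1) / 2.0, (y0 + y1) / 2.0) for _, _, x0, y0, x1, y1 in layout]
    )
    rng = np.random.default_rng(config.seed + 1)
    anchor = int(rng.integers(len(communes)))
    dist = np.linalg.norm(centroids - centroids[anchor], axis=1)
    # ties broken by commune order so the cluster is deterministic
    nearest = np.lexsort((np.arange(len(communes)), dist))
    planted = sorted(communes[i] for i in nearest[: config.n_cluster_communes])
    return {
        "planted_communes": planted,
        "cluster_roma_share": config.cluster_roma_share,
        "planted_need_prevalence": config.planted_need_prevalence,
        "background_need_prevalence": config.background_need_prevalence,
    }


def generate_landscape(
    config: GeneratorConfig,
) -> tuple[list[GridCell], dict, dict[str, RegionEthnicity]]:
    """Generate (grid cells, regions GeoJSON dict, ethnicity table).

    Cells carry log-normal person counts and their commune/county
    labels; ethnicity counts give planted cluster communes the elevated
    Roma share and all others the base share.
    """
    rng = np.random.default_rng(config.seed)
    planted = set(plant_truth(config)["planted_communes"])
    cells: list[GridCell] = []
    features: list[dict] = []
    ethnicity: dict[str, RegionEthnicity] = {}
    county_boxes: dict[str, list[float]] = {}
    for commune_id, county_id, x0, y0, x1, y1 in _commune_layout(config):
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "region_id": commune_id,
                    "level": "commune",
                    "county_id": county_id,
                },
                "geometry": mapping(box(x0, y0, x1, y1)),
            }
        )
        bb = county_boxes.setdefault(county_id, [x0, y0, x1, y1])
        bb[0], bb[1] = min(bb[0], x0), min(bb[1], y0)
        bb[2], bb[3] = max(bb[2], x1), max(bb[3], y1)
        total = 0
        for yy in range(y0, y1):
            for xx in range(x0, x1):
                pop = int(
                    round(
                        float(
                            rng.lognormal(
                                np.log(config.cell_pop_median), config.cell_pop_sigma
                            )
                        )
                    )
                )
                cells.append(
                    GridCell(
                        cell_id=f"c{xx:03d}_{yy:03d}",
                        x=xx + 0.5,
                        y=yy + 0.5,
                        population=pop,
                        commune_id=commune_id,
                        county_id=county_id,
                    )
                )
                total += pop
        share = (
            config.cluster_roma_share
            if commune_id in planted
            else config.base_roma_share
        )
        ethnicity[commune_id] = RegionEthnicity(
            region_id=commune_id,
            count_roma=int(round(share * total)),
            count_total=total,
        )
    for county_id, (x0, y0, x1, y1) in sorted(county_boxes.items()):
        features.append(
            {
                "type": "Feature",
                "properties": {"region_id": county_id, "level": "county"},
                "geometry": mapping(box(x0, y0, x1, y1)),
            }
        )
    regions = {"type": "FeatureCollection", "features": features}
    return cells, regions, ethnicity


def _truncated_poisson(mean: float, rng: np.random.Generator, max_val: int = 12) -> int:
    from scipy import stats as sps

    k = np.arange(1, max_val + 1)
    p = sps.poisson.pmf(k, mean)
    return int(rng.choice(k, p=p / p.sum()))


def generate_survey(config: GeneratorConfig) -> list[SurveyRecord]:
    """Generate the coded five-community survey.

    Each adverse indicator is an independent Bernoulli draw at the
    ethnicity-specific prevalence implied by its configured (p0, OR)
    pair; housing components, education grade, and the protected-well
    flag are drawn conditional on their governing adverse flags so that
    derived quantities (insecure-housing score, safe-water flag,
    low-education flag) hit the calibrated prevalences.
    """
    rng = np.random.default_rng(config.seed + 2)
    ind = config.indicators
    records: list[SurveyRecord] = []

    def adverse(name: str, eth: str) -> bool:
        return bool(rng.random() < ind[name].prevalence(eth))

    for spec in config.communities:
        eths = ["roma"] * spec.n_roma + ["non_roma"] * (
            spec.n_households - spec.n_roma
        )
        for eth in eths:
            size_mean = (
                config.household_size_mean_roma
                if eth == "roma"
                else config.household_size_mean_non_roma
            )
            size = _truncated_poisson(size_mean, rng)
            n_minors = int(rng.binomial(size - 1, config.p_minor[eth])) if size > 1 else 0

            insecure = adverse("insecure_housing", eth)
            if insecure:
                n_def = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
                which = rng.permutation(3)[:n_def]
            else:
                which = np.array([], dtype=int)
            deficient = [i in which for i in range(3)]

            piped = not adverse("improved_water_lacking", eth)
            # draw a protected well only for non-tap households, at the rate
            # that makes the derived safe-water flag hit its calibrated
            # prevalence: P(well | no tap) = (p_safe - p_tap) / (1 - p_tap)
            p_tap = 1.0 - ind["improved_water_lacking"].prevalence(eth)
            p_safe = 1.0 - ind["safe_water_lacking"].prevalence(eth)
            p_well = max(0.0, (p_safe - p_tap) / (1.0 - p_tap)) if p_tap < 1 else 0.0
            well = bool((not piped) and rng.random() < p_well)

            low_ed = adverse("low_education", eth)
            grade = int(rng.integers(6, 9)) if low_ed else int(rng.integers(9, 15))

            p_far = config.pct_water_over_1km[eth]
            dist = float(rng.exponential(-1.0 / np.log(p_far)))
            is_rural = spec.geography_class == "rural"
            ttw = int(min(rng.poisson(1.0 if is_rural else 1.2), 4))

            records.append(
                SurveyRecord(
                    community_id=spec.community_id,
                    geography_class=spec.geography_class,
                    ethnicity=eth,
                    respondent_age=float(
                        np.clip(
                            rng.normal(config.age_mean[eth], config.age_sd), 18, 90
                        )
                    ),
                    respondent_sex="M" if rng.random() < config.p_male[eth] else "F",
                    household_size=size,
                    n_minors=n_minors,
                    education_grade=grade,
                    marital="single" if adverse("single", eth) else "partnership",
                    employment=(
                        "unemployed_or_day_labour"
                        if adverse("unemployed", eth)
                        else "full_time"
                    ),
                    time_to_water=ttw,
                    distance_to_water_km=round(dist, 3),
                    literate=not adverse("illiterate", eth),
                    indoor_toilet=not adverse("indoor_toilet_lacking", eth),
                    indoor_bathroom=not adverse("indoor_bathroom_lacking", eth),
                    piped_tap=piped,
                    protected_well=well,
                    housing_deficient_floor=deficient[0],
                    housing_deficient_walls=deficient[1],
                    housing_deficient_roof=deficient[2],
                    diarrhea_mod_severe=adverse("diarrhea", eth),
                    immunized_any=not adverse("not_immunized", eth),
                    insured=not adverse("uninsured", eth),
                    pcp_access=not adverse("no_pcp_access", eth),
                    electricity=not adverse("electricity_lacking", eth),
                    gas=not adverse("gas_lacking", eth),
                    spends_over_2usd=not adverse("severe_poverty", eth),
                    property_documents=not adverse("no_property_documents", eth),
                )
            )
    return records


def simulate_need_flags(
    households_communes: Sequence[str],
    truth: Mapping,
    seed: int,
) -> np.ndarray:
    """Bernoulli per-household adverse flags with planted prevalences.

    Households in planted communes draw at the planted prevalence, all
    others at the background prevalence — the ground-truth field for
    hot-spot recovery scoring.
    """
    rng = np.random.default_rng(seed)
    planted = set(truth["planted_communes"])
    p_hi = float(truth["planted_need_prevalence"])
    p_lo = float(truth["background_need_prevalence"])
    p = np.array([p_hi if c in planted else p_lo for c in households_communes])
    return (rng.random(len(p)) < p).astype(int)


def recovery_score(
    flagged_communes: Sequence[str], truth: Mapping, all_communes: Sequence[str]
) -> dict[str, float | None]:
    """Sensitivity / specificity of hot-spot recovery against the truth."""
    planted = set(truth["planted_communes"])
    flagged = set(flagged_communes)
    universe = set(all_communes)
    tp = len(planted & flagged)
    fn = len(planted - flagged)
    negatives = universe - planted
    tn = len(negatives - flagged)
    fp = len(negatives & flagged)
    sensitivity = tp / (tp + fn) if planted else None
    specificity = tn / (tn + fp) if negatives else None
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "true_positives": tp,
        "false_positives": fp,
    }
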