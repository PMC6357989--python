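import numpy as np
import pytest

from needscape.simulate import GeneratorConfig, generate_landscape, generate_survey, plant_truth
from needscape.survey import SurveyRecord


def make_record(**overrides) -> SurveyRecord:
    """A fully favorable baseline record; override fields per test."""
    base = dict(
        community_id="community_1",
        geography_class="rural",
        ethnicity="roma",
        respondent_age=40.0,
        respondent_sex="F",
        household_size=4,
        n_minors=1,
        education_grade=10,
        marital="partnership",
        employment="full_time",
        time_to_water=0,
        distance_to_water_km=0.1,
        literate=True,
        indoor_toilet=True,
        indoor_bathroom=True,
        piped_tap=True,
        protected_well=False,
        housing_deficient_floor=False,
        housing_deficient_walls=False,
        housing_deficient_roof=False,
        diarrhea_mod_severe=False,
        immunized_any=True,
        insured=True,
        pcp_access=True,
        electricity=True,
        gas=True,
        spends_over_2usd=True,
        property_documents=True,
    )
    base.update(overrides)
    return SurveyRecord(**base)


@pytest.fixture(scope="session")
def survey_records():
    """A default generated five-community survey (135 rows, 98 Roma)."""
    return generate_survey(GeneratorConfig(seed=123))


@pytest.fixture(scope="session")
def landscape():
    """Default 20x20 landscape: cells, regions GeoJSON, ethnicity, truth."""
    cfg = GeneratorConfig(seed=321)
    cells, regions, ethnicity = generate_landscape(cfg)
    return cfg, cells, regions, ethnicity, plant_truth(cfg)


def rook_lattice(nx: int, ny: int) -> np.ndarray:
    """Unit-spaced lattice points, row-major."""
    return np.array([(i, j) for j in range(ny) for i in range(nx)], dtype=float)
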