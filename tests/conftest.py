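import numpy as np
import pandas as pd
import pytest

from hemilat.core_data import Region, RegionAtlas, load_atlas
from hemilat.simulate import GeneratorConfig, simulate_cross_sectional


@pytest.fixture(scope="session")
def atlas_and_rois():
    return load_atlas("dk84")


@pytest.fixture(scope="session")
def atlas(atlas_and_rois):
    return atlas_and_rois[0]


@pytest.fixture(scope="session")
def rois(atlas_and_rois):
    return {r.name: r for r in atlas_and_rois[1]}


@pytest.fixture(scope="session")
def toy_atlas():
    """Six regions, three per hemisphere, three homotopic pairs."""
    names = ["alpha", "beta", "gamma"]
    regions = [Region(n, "left", "toy", i) for i, n in enumerate(names)]
    regions += [Region(n, "right", "toy", 3 + i) for i, n in enumerate(names)]
    return RegionAtlas(regions)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort at n = 60 for structural tests."""
    return simulate_cross_sectional(GeneratorConfig(seed=42), n=60)


@pytest.fixture(scope="session")
def big_mixture():
    """10,000 subjects, truth columns only, for mixture calibration."""
    return simulate_cross_sectional(GeneratorConfig(seed=7), n=10_000,
                                    include_biomarkers=False).truth


def toy_biomarker_frame():
    rows = []
    for sid in ("s1", "s2"):
        for region in ("alpha", "beta"):
            for hemisphere, suvr in (("left", 1.5), ("right", 1.7)):
                rows.append((sid, 0.0, "tau", region, hemisphere, suvr))
    return pd.DataFrame(rows, columns=[
        "subject_id", "timepoint_years", "tracer", "region_name",
        "hemisphere", "suvr"])


@pytest.fixture()
def toy_biomarkers():
    return toy_biomarker_frame()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)
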