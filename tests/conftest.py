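import numpy as np
import pandas as pd
import pytest

import ntquant as nq


@pytest.fixture(scope="session")
def small_section():
    """One modest simulated section shared by read-only tests."""
    params = nq.SectionSimParams(shape=(256, 256), n_nuclei=100, seed=11)
    label, channels, markers, gt = nq.generate_transverse_section(params)
    return params, label, channels, markers, gt


@pytest.fixture(scope="session")
def small_section_records(small_section):
    params, label, channels, markers, _gt = small_section
    return nq.measure_nuclei(label, channels, markers,
                             excluded_bands=params.excluded_bands)


@pytest.fixture(scope="session")
def small_mosaic():
    params = nq.MosaicSimParams(shape=(300, 300), n_cells=150,
                                constriction_scale=0.5, junction_factor=0.5,
                                seed=7)
    label, junction, gt = nq.generate_apical_mosaic(params)
    return params, label, junction, gt


def random_records(rng: np.random.Generator, n: int = 40) -> pd.DataFrame:
    """Random marker/position tables for rate and restriction oracles."""
    return pd.DataFrame({
        "label": np.arange(1, n + 1),
        "centroid_y": rng.uniform(0, 200, n),
        "centroid_x": rng.uniform(0, 200, n),
        "section_height": 200,
        "region": rng.choice(["included", "excluded"], n, p=[0.9, 0.1]),
        "HuCD": rng.random(n) < 0.3,
        "EdU": rng.random(n) < 0.4,
        "transfected": rng.random(n) < 0.5,
    })
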