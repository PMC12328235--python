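import numpy as np
import pandas as pd
import pytest

from paleoniche.synthetic import (
    NicheDimension,
    SyntheticWorldSpec,
    VariableParams,
    default_niche_spec,
    generate_biome_labels,
    generate_climate_cube,
    generate_world,
    simulate_occurrences,
)


def small_spec(**overrides) -> SyntheticWorldSpec:
    """A fast world: 12x12 grid, 28 slices, mostly land."""
    base = dict(
        lon_min=0.0,
        lon_max=24.0,
        lat_min=-12.0,
        lat_max=12.0,
        cell_size=2.0,
        time_start=120_000.0,
        time_end=66_000.0,
        time_step=2_000.0,
        sea_fraction=0.1,
        seed=7,
    )
    base.update(overrides)
    return SyntheticWorldSpec(**base)


@pytest.fixture(scope="session")
def quiet_cube():
    """Deterministic cube with zero noise and zero trend."""
    params = {
        name: VariableParams(mean=vp.mean, spatial_amplitude=vp.spatial_amplitude,
                             trend_amplitude=0.0, noise_sd=0.0)
        for name, vp in
        __import__("paleoniche.synthetic", fromlist=["x"]).default_variable_params().items()
    }
    return generate_climate_cube(small_spec(variable_params=params))


@pytest.fixture(scope="session")
def labelled_world():
    """Full default world (cube + biomes + occurrences), fixed niche."""
    cube, occ = generate_world(SyntheticWorldSpec(seed=11))
    return cube, occ


@pytest.fixture(scope="session")
def drift_world():
    """World whose bio10 optimum drifts 4 °C across the window."""
    spec = SyntheticWorldSpec(seed=5, niche_spec=default_niche_spec(drift=4.0))
    return generate_world(spec)


@pytest.fixture()
def occurrence_csv(tmp_path):
    path = tmp_path / "occ.csv"
    pd.DataFrame(
        {
            "site_id": ["A", "B", "C"],
            "layer_id": ["1", "1", "2"],
            "lon": [10.0, 20.5, -3.0],
            "lat": [5.0, -8.0, 0.0],
            "method_class": ["radiocarbon", "other_radiometric", "other_radiometric"],
            "age_mean": [30_000.0, 80_000.0, 50_000.0],
            "age_uncertainty": [1_000.0, 5_000.0, 2_000.0],
            "raw_14c_age": [26_000.0, np.nan, np.nan],
            "raw_14c_error": [300.0, np.nan, np.nan],
        }
    ).to_csv(path, index=False)
    return path
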