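import numpy as np
import pandas as pd
import pytest
import shapely

from pfaspest import (
    LandscapeConfig,
    RunConfig,
    build_system_table,
    generate_landscape,
)

SMALL_CONFIG = dict(
    n_systems=150,
    n_block_groups=220,
    regional_population=1_600_000,
    seed=42,
)


@pytest.fixture(scope="session")
def small_landscape():
    return generate_landscape(LandscapeConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_table(small_landscape):
    cfg = RunConfig(landscape=small_landscape.config,
                    seed=small_landscape.config.seed)
    return build_system_table(small_landscape, cfg)


@pytest.fixture()
def square():
    """Unit helper: axis-aligned square of a given side at an origin."""
    def make(x0, y0, side):
        return shapely.box(x0, y0, x0 + side, y0 + side)
    return make


def wells_frame(rows):
    """(well_id, system_id, x, y) tuples -> wells geotable."""
    df = pd.DataFrame(rows, columns=["well_id", "system_id", "x", "y"])
    df["geometry"] = shapely.points(np.c_[df["x"], df["y"]])
    return df
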