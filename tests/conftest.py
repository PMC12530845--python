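import numpy as np
import pytest

import ecoscape as es


def make_lulc(codes, cell_size=1000.0, nodata=0, epoch=""):
    """LULCMap from a literal code matrix (default 1 km cells)."""
    codes = np.asarray(codes, dtype=np.int64)
    grid = es.GridSpec(
        codes.shape[0], codes.shape[1], cell_size, nodata_code=nodata
    )
    return es.LULCMap(grid=grid, codes=codes, epoch_label=epoch)


def random_lulc(rng, shape=(15, 15), cell_size=1000.0, p_nodata=0.05):
    """Random seven-class map with a sprinkle of nodata."""
    codes = rng.integers(1, 8, size=shape)
    codes[rng.random(shape) < p_nodata] = 0
    return make_lulc(codes, cell_size=cell_size)


@pytest.fixture(scope="session")
def landscape():
    """One medium synthetic landscape shared across tests (read-only)."""
    grid = es.GridSpec(96, 96, 30.0)
    spec = es.LandscapeSpec(grid=grid, rng_seed=11)
    t1, drivers, mask = es.generate_landscape(spec)
    t2 = es.generate_change(
        t1, [es.ChangeRule(2, 1, 400, "edge")], drivers, seed=12
    )
    return {"t1": t1, "t2": t2, "drivers": drivers, "mask": mask, "spec": spec}
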