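"""Seed-reproducible synthetic landscapes for end-to-end testing.

Emulates the statistical structure the pipeline assumes without any
download: a mosaic dominated (~90%) by forest with farmland at its
low-elevation edges, small water/construction/shrub/grass/barren fractions,
smooth spatially correlated driver fields (elevation and derivatives,
distance-to-feature layers, population/GDP surfaces declining with
elevation), and a restricted-conversion mask over the forest core.

Class patches come from quantile-thresholding a smoothed Gaussian field
correlated with elevation, so low-suitability classes (water, farmland,
construction) concentrate in the lowlands as they do in mountainous study
areas. Change between epochs is injected by explicit rules (from-class,
to-class, cell count, adjacency bias), making every transition exactly
auditable downstream. None of this claims topographic realism; see the
methods note for what a green test does and does not establish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .allocation import DriverStack
from .grid import CLASS_LABELS, GridSpec, LULCMap

#: Default composition: forest-dominated with expanding-farmland structure.
DEFAULT_FRACTIONS = {
    1: 0.06,   # farmland
    2: 0.90,   # forest
    3: 0.005,  # shrub
    4: 0.005,  # grass
    5: 0.02,   # water
    6: 0.005,  # construction
    7: 0.005,  # barren
}


@dataclass
class ChangeRule:
    """Convert ``n_cells`` from one class to another between epochs."""

    from_class: int
    to_class: int
    n_cells: int
    adjacency: str = "edge"  # "edge" (next to destination, low ground) | "random"

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.adjacency not in ("edge", "random"):
            raise ValueError(f"unknown adjacency mode {self.adjacency!r}")


@dataclass
class LandscapeSpec:
    """Recipe for one synthetic landscape."""

    grid: GridSpec
    class_fractions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    patch_scale: float = 8.0  # correlation length, cells
    change_rules: list[ChangeRule] = field(default_factory=list)
    redline_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class fractions sum to {total}, expected 1")
        if not 0 <= self.redline_fraction <= 1:
            raise ValueError("redline_fraction must lie in [0, 1]")


def _smooth_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Standardised Gaussian random field with correlation length ``scale``."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _random_lines(rng: np.random.Generator, shape, n_lines: int) -> np.ndarray:
    """Binary raster of a few random straight linear features (roads/rivers)."""
    mask = np.zeros(shape, dtype=bool)
    n_rows, n_cols = shape
    for _ in range(n_lines):
        r0, c0 = rng.integers(0, n_rows), rng.integers(0, n_cols)
        r1, c1 = rng.integers(0, n_rows), rng.integers(0, n_cols)
        n = max(abs(int(r1) - int(r0)), max(abs(int(c1) - int(c0)), 1)) + 1
        rr = np.linspace(r0, r1, n).round().astype(int)
        cc = np.linspace(c0, c1, n).round().astype(int)
        mask[rr.clip(0, n_rows - 1), cc.clip(0, n_cols - 1)] = True
    return mask


def generate_landscape(
    spec: LandscapeSpec,
) -> tuple[LULCMap, DriverStack, np.ndarray]:
    """Build (t1 map, driver stack, restricted mask) from a spec, seeded.

    Classes are ordered along a smoothed elevation-correlated field from
    lowlands upward: water, construction, farmland, barren, forest, shrub,
    grass — so the mosaic is patchy and farmland hugs the forest's lower
    edge. The mask covers ``redline_fraction`` of the dominant natural
    class's core (eroded) area, chosen contiguously via a smooth field.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.grid.shape

    elevation = _smooth_field(rng, shape, spec.patch_scale)
    elevation_m = (elevation - elevation.min()) / np.ptp(elevation) * 1800.0

    # class-assignment field: elevation plus independent texture
    texture = _smooth_field(rng, shape, spec.patch_scale / 2)
    u = 0.7 * elevation + 0.5 * texture

    order = [5, 6, 1, 7, 2, 3, 4]  # lowland -> upland occupancy
    fracs = [spec.class_fractions.get(c, 0.0) for c in order]
    qs = np.cumsum(fracs)[:-1]
    edges = np.quantile(u, np.clip(qs, 0, 1))
    codes = np.full(shape, order[-1], dtype=np.int64)
    bins = np.digitize(u, edges)  # 0..len(order)-1
    for k, c in enumerate(order):
        codes[bins == k] = c

    slope_y, slope_x = np.gradient(elevation_m, spec.grid.cell_size)
    slope = np.degrees(np.arctan(np.hypot(slope_x, slope_y)))
    aspect = np.degrees(np.arctan2(slope_y, slope_x)) % 360.0

    cell_km = spec.grid.cell_size / 1000.0
    roads = _random_lines(rng, shape, n_lines=4)
    rails = _random_lines(rng, shape, n_lines=2)
    dist_road = ndimage.distance_transform_edt(~roads) * cell_km
    dist_rail = ndimage.distance_transform_edt(~rails) * cell_km
    water_mask = codes == 5
    if water_mask.any():
        dist_water = ndimage.distance_transform_edt(~water_mask) * cell_km
    else:
        dist_water = np.full(shape, np.hypot(*shape) * cell_km)

    lowland = np.exp(-elevation_m / 500.0)
    population = 1000.0 * lowland * np.exp(_smooth_field(rng, shape, spec.patch_scale))
    gdp = 50.0 * lowland * np.exp(_smooth_field(rng, shape, spec.patch_scale))
    temperature = 24.5 - 6.0 * elevation_m / 1000.0 + 0.3 * _smooth_field(
        rng, shape, spec.patch_scale
    )
    precipitation = 1800.0 + 400.0 * _smooth_field(rng, shape, spec.patch_scale)
    soil = np.digitize(
        _smooth_field(rng, shape, spec.patch_scale), [-0.7, 0.0, 0.7]
    ).astype(np.int64)

    drivers = DriverStack(
        grid=spec.grid,
        layers={
            "elevation": elevation_m,
            "slope": slope,
            "aspect": aspect,
            "dist_road": dist_road,
            "dist_rail": dist_rail,
            "dist_water": dist_water,
            "population": population,
            "gdp": gdp,
            "temperature": temperature,
            "precipitation": precipitation,
            "soil": soil,
        },
        categorical=frozenset({"soil"}),
    )

    # restricted mask: contiguous share of the dominant natural class's core
    dominant = max(
        (c for c in spec.class_fractions if c in {2, 3, 4, 5}),
        key=lambda c: spec.class_fractions[c],
    )
    core = ndimage.binary_erosion((codes == dominant), iterations=2)
    mask = np.zeros(shape, dtype=bool)
    if spec.redline_fraction > 0 and core.any():
        pick = _smooth_field(rng, shape, spec.patch_scale)
        cut = np.quantile(pick[core], 1.0 - spec.redline_fraction)
        mask = core & (pick >= cut)

    lulc = LULCMap(
        grid=spec.grid, codes=codes, class_labels=dict(CLASS_LABELS), epoch_label="t1"
    )
    return lulc, drivers, mask


def generate_change(
    t1: LULCMap,
    rules: list[ChangeRule],
    drivers: DriverStack | None = None,
    seed: int = 0,
) -> LULCMap:
    """Apply change rules to t1, converting exactly ``n_cells`` per rule.

    Edge-biased rules weight source cells adjacent to the destination class
    strongly, and lower-elevation cells more when an elevation driver is
    available — mimicking agricultural encroachment at forest edges. Rules
    are applied in order on the evolving map; a rule short of source cells
    raises.
    """
    rng = np.random.default_rng(seed)
    codes = t1.codes.copy()
    for rule in rules:
        if rule.n_cells == 0:
            continue
        src = (codes == rule.from_class) & t1.valid_mask
        n_src = int(src.sum())
        if n_src < rule.n_cells:
            raise ValueError(
                f"rule {rule.from_class}->{rule.to_class}: needs {rule.n_cells} "
                f"cells, only {n_src} available"
            )
        weights = np.ones(t1.grid.shape)
        if rule.adjacency == "edge":
            near_dest = ndimage.binary_dilation(codes == rule.to_class, iterations=2)
            weights += 20.0 * near_dest
            if drivers is not None and "elevation" in drivers.layers:
                e = drivers.layers["elevation"]
                weights *= np.exp(-(e - e.min()) / max(np.ptp(e), 1e-9) * 3.0)
        p = weights[src] / weights[src].sum()
        flat_idx = np.flatnonzero(src.ravel())
        chosen = rng.choice(flat_idx, size=rule.n_cells, replace=False, p=p)
        r, c = np.unravel_index(chosen, t1.grid.shape)
        codes[r, c] = rule.to_class
    return LULCMap(
        grid=t1.grid,
        codes=codes,
        class_labels=dict(t1.class_labels),
        epoch_label="t2",
    )
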