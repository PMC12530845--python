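"""Patch-generating cellular-automata land allocation.

Three stages mirror the patch-generating land-use simulation workflow:

1. *Expansion sampling* — cells that newly converted to a class between two
   dates are positives; a seeded random background sample supplies
   negatives (land-expansion analysis strategy).
2. *Development probability* — a random-forest classifier on the driver
   stack yields a per-class conversion-suitability surface and normalised
   driver importances.
3. *Allocation* — a multi-seed CA iteratively converts the highest-scoring
   cells toward classes whose projected demand is unmet. The score couples
   development probability, a neighbourhood density term, a seeded
   patch-seeding bonus (so new patches can nucleate away from existing
   ones) and a conversion-cost gate; a global acceptance threshold decays
   whenever an iteration converts nothing. Cells of protected classes
   inside the restricted-conversion mask never change.

Exact behavioural parity with any released desktop implementation is not a
goal; the contract is the documented mechanism and its invariants
(conservation, mask inviolability, demand satisfaction on feasible inputs,
determinism under a fixed seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .grid import GridSpec, LULCMap

logger = logging.getLogger(__name__)

#: Classes protected from conversion inside the restricted mask
#: (forest, shrub, grassland, water).
PROTECTED_CLASSES = frozenset({2, 3, 4, 5})


@dataclass
class DriverStack:
    """Named co-registered driver rasters (continuous or categorical)."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    categorical: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr)
            if arr.shape != self.grid.shape:
                raise ValueError(f"driver {name!r} shape {arr.shape} != grid")
            self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def feature_names(self) -> list[str]:
        """Column names after one-hot expansion of categorical layers."""
        cols = []
        for name in self.names:
            if name in self.categorical:
                for v in np.unique(self.layers[name]):
                    cols.append(f"{name}={v}")
            else:
                cols.append(name)
        return cols

    def feature_matrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Feature rows for the given cell indices; categoricals one-hot."""
        blocks = []
        for name in self.names:
            vals = self.layers[name][rows, cols]
            if name in self.categorical:
                cats = np.unique(self.layers[name])
                blocks.append((vals[:, None] == cats[None, :]).astype(float))
            else:
                blocks.append(np.asarray(vals, dtype=float)[:, None])
        X = np.hstack(blocks)
        if not np.all(np.isfinite(X)):
            raise ValueError("driver features contain non-finite values")
        return X


@dataclass
class ExpansionSamples:
    """Training set for one class's expansion model."""

    target_class: int
    X: np.ndarray
    y: np.ndarray  # 1 = newly converted to target, 0 = background
    feature_names: list[str]
    seed: int


@dataclass
class DevelopmentProbability:
    """Conversion-suitability surface and driver importances for one class."""

    target_class: int
    surface: np.ndarray  # in [0, 1]; NaN on nodata
    importances: pd.Series  # per original driver, sums to 1

    def __post_init__(self) -> None:
        finite = self.surface[~np.isnan(self.surface)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("probability surface outside [0, 1]")


@dataclass
class AllocationConfig:
    """CA controls; defaults suit the synthetic fixtures in this package."""

    neighborhood_radius: int = 1
    neighborhood_weight: dict[int, float] = field(default_factory=dict)  # default 1
    conversion_cost: np.ndarray | None = None  # n×n gate, 1 = allowed
    patch_seed_fraction: float = 0.02
    threshold_decay: float = 0.8
    demand_tolerance: float = 0.0  # km²
    max_iterations: int = 200
    rng_seed: int = 0
    restricted_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.neighborhood_radius < 1:
            raise ValueError("neighborhood_radius must be >= 1")
        if not 0 < self.threshold_decay < 1:
            raise ValueError("threshold_decay must lie in (0, 1)")
        if self.demand_tolerance < 0:
            raise ValueError("demand_tolerance must be non-negative")


@dataclass
class AllocationResult:
    """Simulated map plus convergence diagnostics."""

    lulc: LULCMap
    converged: bool
    n_iterations: int
    n_converted: int
    residuals: pd.Series  # demand − achieved, km², per class

    @property
    def infeasible(self) -> bool:
        return not self.converged


def extract_expansion_samples(
    m1: LULCMap,
    m2: LULCMap,
    drivers: DriverStack,
    target_class: int,
    background_ratio: float = 1.0,
    seed: int = 0,
) -> ExpansionSamples:
    """Mine expansion cells of ``target_class`` and a background sample.

    Positives are every cell with ``m1 != target`` and ``m2 == target``
    (both valid); negatives are ``background_ratio`` times as many cells
    drawn uniformly without replacement from the remaining jointly valid
    cells, with a seeded generator.
    """
    m1.grid.require_match(m2.grid, "epoch rasters")
    m1.grid.require_match(drivers.grid, "drivers")
    both = m1.valid_mask & m2.valid_mask
    pos = both & (m1.codes != target_class) & (m2.codes == target_class)
    n_pos = int(pos.sum())
    names = drivers.feature_names()
    if n_pos == 0:
        warnings.warn(f"no expansion cells for class {target_class}")
        return ExpansionSamples(
            target_class, np.empty((0, len(names))), np.empty(0, dtype=int), names, seed
        )
    bg_pool = both & ~pos
    n_bg = min(int(round(background_ratio * n_pos)), int(bg_pool.sum()))
    rng = np.random.default_rng(seed)
    pool_idx = np.flatnonzero(bg_pool.ravel())
    bg_idx = rng.choice(pool_idx, size=n_bg, replace=False)
    pr, pc = np.nonzero(pos)
    br, bc = np.unravel_index(bg_idx, m1.grid.shape)
    rows = np.concatenate([pr, br])
    cols = np.concatenate([pc, bc])
    X = drivers.feature_matrix(rows, cols)
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_bg, dtype=int)])
    return ExpansionSamples(target_class, X, y, names, seed)


def fit_development_probability(
    samples: ExpansionSamples,
    drivers: DriverStack,
    valid_mask: np.ndarray | None = None,
    seed: int = 0,
    n_estimators: int = 50,
) -> DevelopmentProbability:
    """Fit a seeded random forest and evaluate P(expansion) on every cell.

    One-hot importances are summed back onto their source driver, then
    normalised to sum to 1.
    """
    if samples.X.shape[0] == 0:
        raise ValueError("empty sample set")
    if len(np.unique(samples.y)) < 2:
        raise ValueError("need both positive and background samples")
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    clf.fit(samples.X, samples.y)

    shape = drivers.grid.shape
    if valid_mask is None:
        valid_mask = np.ones(shape, dtype=bool)
    rows, cols = np.nonzero(valid_mask)
    surface = np.full(shape, np.nan)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    # chunked prediction keeps peak memory flat on large grids
    chunk = 200_000
    for s in range(0, rows.size, chunk):
        sl = slice(s, s + chunk)
        X = drivers.feature_matrix(rows[sl], cols[sl])
        surface[rows[sl], cols[sl]] = clf.predict_proba(X)[:, pos_col]

    # fold one-hot columns back onto their driver
    raw = pd.Series(clf.feature_importances_, index=samples.feature_names)
    grouped = raw.groupby(
        raw.index.map(lambda s: s.split("=")[0])
    ).sum().reindex(drivers.names)
    total = grouped.sum()
    importances = grouped / total if total > 0 else grouped
    return DevelopmentProbability(samples.target_class, surface, importances)


def neighborhood_effect(lulc: LULCMap, cls: int, radius: int = 1) -> np.ndarray:
    """Fraction of ``cls`` cells in the (2r+1)² window around each cell.

    Nodata cells are excluded from both numerator and denominator; windows
    truncate at the grid edge. Values lie in [0, 1].
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    size = 2 * radius + 1
    valid = lulc.valid_mask.astype(float)
    hits = ((lulc.codes == cls) & lulc.valid_mask).astype(float)
    kernel = np.ones((size, size))
    num = ndimage.convolve(hits, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(frac, 0.0, 1.0)


def _demand_to_cells(
    demand: pd.Series, labels: list[int], total_cells: int, cell_area: float
) -> dict[int, int]:
    """Largest-remainder rounding of km² demand to integer cell counts."""
    raw = np.array([max(float(demand.get(c, 0.0)), 0.0) for c in labels]) / cell_area
    base = np.floor(raw).astype(int)
    short = total_cells - base.sum()
    if short < 0:
        raise ValueError("demand exceeds total map area")
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return dict(zip(labels, base.tolist()))


def allocate(
    lulc_t: LULCMap,
    demand: pd.Series,
    probs: dict[int, DevelopmentProbability],
    config: AllocationConfig | None = None,
) -> AllocationResult:
    """Iterative multi-seed CA meeting class-area demand.

    Each iteration scores candidate cells per under-demand class as

        score = P_dev × (neighbourhood + seed_bonus) × cost_gate,

    converts the best-scoring cells above the acceptance threshold (donor
    cells must belong to an over-demand class), and decays the threshold
    when nothing converts. Restricted protected cells never change class.
    Terminates when every class is within ``demand_tolerance`` of demand or
    after ``max_iterations``; an unmet demand is reported, not raised.
    """
    config = AllocationConfig() if config is None else config
    grid = lulc_t.grid
    labels = sorted(lulc_t.class_labels)
    idx = {c: k for k, c in enumerate(labels)}
    cell_area = grid.cell_area_km2
    codes = lulc_t.codes.copy()
    valid = lulc_t.valid_mask
    total_cells = int(valid.sum())

    targets = _demand_to_cells(demand, labels, total_cells, cell_area)
    cost = (
        np.ones((len(labels), len(labels)))
        if config.conversion_cost is None
        else np.asarray(config.conversion_cost, dtype=float)
    )
    restricted = (
        np.zeros(grid.shape, dtype=bool)
        if config.restricted_mask is None
        else np.asarray(config.restricted_mask, dtype=bool)
    )
    frozen = restricted & np.isin(codes, sorted(PROTECTED_CLASSES))
    rng = np.random.default_rng(config.rng_seed)

    def counts() -> dict[int, int]:
        c = {cls: 0 for cls in labels}
        vals, ns = np.unique(codes[valid], return_counts=True)
        c.update(dict(zip(vals.tolist(), ns.tolist())))
        return c

    cur = counts()
    _warned_neutral: set[int] = set()
    tol_cells = int(config.demand_tolerance / cell_area)
    threshold = 0.9
    n_converted = 0
    it = 0
    for it in range(1, config.max_iterations + 1):
        deficits = {c: targets[c] - cur[c] for c in labels}
        if all(abs(d) <= tol_cells for d in deficits.values()):
            break
        growing = [c for c in labels if deficits[c] > tol_cells]
        if not growing:
            break
        converted_this_iter = 0
        claimed = np.zeros(grid.shape, dtype=bool)
        # largest unmet demand first gets first pick of cells
        for c in sorted(growing, key=lambda c: -deficits[c]):
            need = targets[c] - cur[c]
            if need <= tol_cells:
                continue
            dp = probs.get(c)
            if dp is None:
                if c not in _warned_neutral:
                    warnings.warn(
                        f"no development probability for growing class {c}; "
                        "using a neutral surface"
                    )
                    _warned_neutral.add(c)
                surface = np.ones(grid.shape)
            else:
                surface = np.nan_to_num(dp.surface, nan=0.0)
            neigh = neighborhood_effect(
                LULCMap(grid, codes, dict(lulc_t.class_labels)), c,
                config.neighborhood_radius,
            ) * config.neighborhood_weight.get(c, 1.0)
            seed_bonus = config.patch_seed_fraction * rng.random(grid.shape)
            gate = np.zeros(grid.shape)
            donors = np.zeros(grid.shape, dtype=bool)
            for src in labels:
                if src == c:
                    continue
                # donors: classes currently above their own target
                if cur[src] - targets[src] > 0 and cost[idx[src], idx[c]] > 0:
                    m = codes == src
                    gate[m] = cost[idx[src], idx[c]]
                    donors |= m
            cand = donors & valid & ~frozen & ~claimed
            if not cand.any():
                continue
            score = surface * (neigh + seed_bonus) * gate
            score[~cand] = -np.inf
            flat = score.ravel()
            # accept cells above the absolute threshold, best first
            above = np.flatnonzero((flat > threshold) & np.isfinite(flat))
            if above.size == 0:
                continue
            order = above[np.argsort(-flat[above])]
            # cap per-donor take so a donor class never drops below its target
            surplus = {
                src: cur[src] - targets[src] for src in labels if src != c
            }
            take_rows, take_cols = np.unravel_index(order, grid.shape)
            n_take = 0
            for r, cc in zip(take_rows, take_cols):
                if n_take >= need:
                    break
                src = int(codes[r, cc])
                if surplus.get(src, 0) <= 0:
                    continue
                codes[r, cc] = c
                claimed[r, cc] = True
                surplus[src] -= 1
                cur[src] -= 1
                cur[c] += 1
                n_take += 1
            converted_this_iter += n_take
        n_converted += converted_this_iter
        if converted_this_iter == 0:
            threshold *= config.threshold_decay
            if threshold < 1e-12:
                threshold = 0.0

    final = counts()
    residual = pd.Series(
        {c: (targets[c] - final[c]) * cell_area for c in labels}, name="residual_km2"
    )
    converged = bool((residual.abs() <= config.demand_tolerance + 1e-9).all())
    if not converged:
        warnings.warn(
            "allocation did not meet demand; residuals (km²): "
            + ", ".join(f"{c}: {v:.3f}" for c, v in residual.items() if abs(v) > 1e-9)
        )
    assert not np.any(lulc_t.codes[frozen] != codes[frozen]), "restricted cell changed"
    out = LULCMap(grid, codes, dict(lulc_t.class_labels), epoch_label="simulated")
    return AllocationResult(out, converged, it, n_converted, residual)
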