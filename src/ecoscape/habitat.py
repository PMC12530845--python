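"""InVEST-style habitat quality and degradation model.

Habitat degradation at a cell accumulates the influence of threat sources
(farmland and construction land in the default parameterisation), each
decaying with distance either linearly,

    i(d) = max(0, 1 - d / d_max),

or exponentially,

    i(d) = exp(-2.99 d / d_max)   (zero beyond d_max),

weighted by the threat weight ω_r (normalised over threats), scaled by the
habitat's sensitivity S_jr to that threat and an accessibility factor β:

    D_x = Σ_r (ω_r / Σ ω) · i_r(x) · β_x · S_{j(x), r}.

Per threat, the influence i_r(x) is taken from the *nearest* source cell —
the screened-threat reading under which a habitat far from every source of
every threat degrades to exactly zero. A ``mean`` aggregation over all
sources within range is available for sensitivity analysis.

Quality discounts the class suitability H_j through a half-saturation
transform:

    Q_x = H_{j(x)} · (1 - D_x² / (D_x² + k²)),

so Q equals H where D = 0 and H/2 where D = k. Quality is then graded into
four levels (low / medium / good / excellent) at fixed cut points, or at cut
points chosen by Jenks natural breaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .grid import GridSpec, LULCMap

logger = logging.getLogger(__name__)

#: Exponential decay reaches exp(-2.99) ≈ 0.05 at d_max.
EXP_DECAY_RATE = 2.99

GRADE_LABELS = {1: "Low", 2: "Medium", 3: "Good", 4: "Excellent"}


@dataclass(frozen=True)
class ThreatSpec:
    """One threat factor: its source class, reach, weight and decay form."""

    name: str
    source_class: int
    d_max: float  # maximum effective distance, km
    weight: float  # ω_r >= 0
    decay: str  # "linear" | "exponential"

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if self.weight < 0:
            raise ValueError("threat weight must be non-negative")
        if self.decay not in ("linear", "exponential"):
            raise ValueError(f"unknown decay form {self.decay!r}")


@dataclass
class SensitivityTable:
    """Per-class habitat suitability H_j and sensitivity S_jr to each threat."""

    suitability: dict[int, float]  # class code -> H_j in [0, 1]
    sensitivity: dict[int, dict[str, float]]  # class code -> threat name -> S_jr

    def __post_init__(self) -> None:
        for c, h in self.suitability.items():
            if not 0 <= h <= 1:
                raise ValueError(f"suitability H[{c}]={h} outside [0, 1]")
        for c, row in self.sensitivity.items():
            for t, s in row.items():
                if not 0 <= s <= 1:
                    raise ValueError(f"sensitivity S[{c},{t}]={s} outside [0, 1]")

    def require_threats(self, threats: list[ThreatSpec]) -> None:
        for t in threats:
            missing = [c for c in self.suitability if t.name not in self.sensitivity.get(c, {})]
            if missing:
                raise KeyError(
                    f"sensitivity table lacks threat {t.name!r} for classes {missing}"
                )

    def to_dataframe(self) -> pd.DataFrame:
        from .grid import CLASS_LABELS

        threats = sorted({t for row in self.sensitivity.values() for t in row})
        rows = []
        for c in sorted(self.suitability):
            row = {
                "code": c,
                "label": CLASS_LABELS.get(c, str(c)),
                "habitat_quality": self.suitability[c],
            }
            row.update({t: self.sensitivity[c].get(t, np.nan) for t in threats})
            rows.append(row)
        return pd.DataFrame(rows).set_index("code")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SensitivityTable":
        threats = [c for c in df.columns if c not in ("label", "habitat_quality")]
        suit = {int(c): float(df.loc[c, "habitat_quality"]) for c in df.index}
        sens = {
            int(c): {t: float(df.loc[c, t]) for t in threats} for c in df.index
        }
        return cls(suitability=suit, sensitivity=sens)


@dataclass
class HabitatConfig:
    """Model constants: half-saturation k, accessibility β, grade cut points,
    and the per-threat source aggregation rule."""

    k: float = 0.5
    beta: float | np.ndarray = 1.0
    thresholds: tuple[float, float, float] = (0.298, 0.698, 0.984)
    aggregation: str = "nearest"  # "nearest" | "mean"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("half-saturation constant k must be positive")
        t = self.thresholds
        if not (0 < t[0] < t[1] < t[2] < 1):
            raise ValueError("thresholds must be strictly increasing within (0, 1)")
        if self.aggregation not in ("nearest", "mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


def default_threats() -> list[ThreatSpec]:
    """Standard two-threat parameterisation: farmland (1 km, linear, ω=0.4)
    and construction land (10 km, exponential, ω=1)."""
    return [
        ThreatSpec("farmland", source_class=1, d_max=1.0, weight=0.4, decay="linear"),
        ThreatSpec(
            "construction", source_class=6, d_max=10.0, weight=1.0, decay="exponential"
        ),
    ]


def default_sensitivity() -> SensitivityTable:
    """Suitability and sensitivity for the seven-class legend."""
    return SensitivityTable(
        suitability={1: 0.3, 2: 1.0, 3: 0.9, 4: 0.7, 5: 0.7, 6: 0.0, 7: 0.2},
        sensitivity={
            1: {"farmland": 0.0, "construction": 0.6},
            2: {"farmland": 0.6, "construction": 0.5},
            3: {"farmland": 0.7, "construction": 0.8},
            4: {"farmland": 0.8, "construction": 0.6},
            5: {"farmland": 0.2, "construction": 0.3},
            6: {"farmland": 0.0, "construction": 0.0},
            7: {"farmland": 0.1, "construction": 0.9},
        },
    )


def threat_presence(lulc: LULCMap, threat: ThreatSpec) -> np.ndarray:
    """Binary intensity raster r_y: 1 where the cell hosts the threat source."""
    if threat.source_class not in lulc.class_labels:
        raise ValueError(f"threat source class {threat.source_class} not in legend")
    return (lulc.codes == threat.source_class).astype(np.uint8)


def decay_weight(d, threat: ThreatSpec):
    """Influence i(d) of a threat at distance ``d`` km from a source.

    Vectorised over ``d``; exactly zero beyond ``d_max`` for both forms.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if threat.decay == "linear":
        w = np.maximum(0.0, 1.0 - d / threat.d_max)
    else:
        w = np.exp(-EXP_DECAY_RATE * d / threat.d_max)
    w = np.where(d > threat.d_max, 0.0, w)
    return w if w.ndim else float(w)


def _nearest_influence(presence: np.ndarray, threat: ThreatSpec, cell_km: float) -> np.ndarray:
    """Decay weight of the nearest source cell, via a Euclidean distance transform."""
    if not presence.any():
        return np.zeros(presence.shape, dtype=float)
    d = ndimage.distance_transform_edt(presence == 0) * cell_km
    return decay_weight(d, threat)


def _mean_influence(presence: np.ndarray, threat: ThreatSpec, cell_km: float) -> np.ndarray:
    """Mean decay weight over all source cells within d_max (FFT convolution)."""
    if not presence.any():
        return np.zeros(presence.shape, dtype=float)
    r = int(np.ceil(threat.d_max / cell_km))
    ax = np.arange(-r, r + 1, dtype=float)
    dist = np.hypot(ax[:, None], ax[None, :]) * cell_km
    kernel = decay_weight(dist, threat)
    reach = (dist <= threat.d_max).astype(float)
    p = presence.astype(float)
    num = signal.fftconvolve(p, kernel, mode="same")
    den = signal.fftconvolve(p, reach, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0.5, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(out, 0.0, 1.0)


def compute_degradation(
    lulc: LULCMap,
    threats: list[ThreatSpec] | None = None,
    sens: SensitivityTable | None = None,
    config: HabitatConfig | None = None,
) -> np.ndarray:
    """Degradation surface D in [0, 1]; NaN on nodata cells.

    D_x = Σ_r (ω_r/Σω) · i_r(x) · β_x · S_{j(x),r} with i_r(x) the influence
    of threat r aggregated over its sources (nearest source by default).
    Distances are Euclidean centre-to-centre in km.
    """
    threats = default_threats() if threats is None else threats
    sens = default_sensitivity() if sens is None else sens
    config = HabitatConfig() if config is None else config
    if not threats:
        raise ValueError("at least one threat required")
    w_total = sum(t.weight for t in threats)
    if w_total <= 0:
        raise ValueError("total threat weight must be positive")
    sens.require_threats(threats)

    cell_km = lulc.grid.cell_size / 1000.0
    agg = _nearest_influence if config.aggregation == "nearest" else _mean_influence
    D = np.zeros(lulc.grid.shape, dtype=float)
    for t in threats:
        influence = agg(threat_presence(lulc, t), t, cell_km)
        s_map = np.zeros_like(D)
        for c in lulc.class_labels:
            s_map[lulc.codes == c] = sens.sensitivity[c][t.name]
        D += (t.weight / w_total) * influence * s_map
    D *= np.asarray(config.beta, dtype=float)
    D = np.clip(D, 0.0, 1.0)
    D[~lulc.valid_mask] = np.nan
    return D


def compute_quality(
    lulc: LULCMap,
    deg: np.ndarray,
    sens: SensitivityTable | None = None,
    config: HabitatConfig | None = None,
) -> np.ndarray:
    """Quality surface Q = H_j · (1 − D²/(D² + k²)); NaN on nodata cells."""
    sens = default_sensitivity() if sens is None else sens
    config = HabitatConfig() if config is None else config
    deg = np.asarray(deg, dtype=float)
    if deg.shape != lulc.grid.shape:
        raise ValueError("degradation surface shape mismatch")
    H = np.full(lulc.grid.shape, np.nan)
    for c in lulc.class_labels:
        H[lulc.codes == c] = sens.suitability[c]
    with np.errstate(invalid="ignore"):
        Q = H * (1.0 - deg**2 / (deg**2 + config.k**2))
    Q[~lulc.valid_mask] = np.nan
    return Q


def classify_quality(
    q: np.ndarray,
    thresholds: tuple[float, float, float] = (0.298, 0.698, 0.984),
) -> np.ndarray:
    """Grade raster 1..4 (Low/Medium/Good/Excellent), 0 where Q is NaN.

    Intervals are lower-bound inclusive: [0, t1) → Low, [t1, t2) → Medium,
    [t2, t3) → Good, [t3, 1] → Excellent (Q = 1 counts as Excellent).
    """
    q = np.asarray(q, dtype=float)
    grades = np.zeros(q.shape, dtype=np.int8)
    valid = ~np.isnan(q)
    qv = q[valid]
    g = np.ones(qv.shape, dtype=np.int8)
    g[qv >= thresholds[0]] = 2
    g[qv >= thresholds[1]] = 3
    g[qv >= thresholds[2]] = 4
    grades[valid] = g
    return grades


def jenks_breaks(values, n_classes: int) -> list[float]:
    """Jenks natural breaks: cut points minimising within-class variance.

    Implements Fisher's exact dynamic programme on the sorted sample, so the
    result is optimal and deterministic. Returns the ``n_classes - 1``
    interior cut points (upper edge of each class but the last), each equal
    to a sample value.

    A degenerate all-equal sample yields a single break at the common value
    with a warning. Complexity is O(k·n²); subsample large rasters first.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    x = x[~np.isnan(x)]
    n = x.size
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    if n < n_classes:
        raise ValueError("need at least n_classes values")
    if x[0] == x[-1]:
        warnings.warn("all values equal; returning a single degenerate break")
        return [float(x[0])]

    # prefix sums for O(1) within-class sum of squared deviations
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def ssd(i: int, j: int) -> float:
        # SSD of x[i:j] (j exclusive)
        m = j - i
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / m

    INF = np.inf
    # cost[k][j]: min total SSD splitting x[:j] into k classes
    prev = np.array([ssd(0, j) if j else 0.0 for j in range(n + 1)])
    choice = np.zeros((n_classes + 1, n + 1), dtype=int)
    for k in range(2, n_classes + 1):
        cur = np.full(n + 1, INF)
        for j in range(k, n + 1):
            best, arg = INF, k - 1
            for i in range(k - 1, j):
                c = prev[i] + ssd(i, j)
                if c < best:
                    best, arg = c, i
            cur[j] = best
            choice[k][j] = arg
        prev = cur

    # backtrack class boundaries
    breaks = []
    j = n
    for k in range(n_classes, 1, -1):
        i = choice[k][j]
        breaks.append(float(x[i - 1]))  # upper edge of class k-1
        j = i
    return sorted(breaks)


def grade_summary(
    grades: np.ndarray,
    q: np.ndarray,
    deg: np.ndarray,
    grid: GridSpec,
) -> pd.DataFrame:
    """Per-grade area/proportion plus the unweighted mean Q and D.

    Means are taken over all valid cells of the grid (every class included)
    and attached to the frame as ``df.attrs['mean_quality']`` /
    ``df.attrs['mean_degradation']``.
    """
    if not (grades.shape == q.shape == deg.shape == grid.shape):
        raise ValueError("grade/quality/degradation shapes must match the grid")
    valid = grades > 0
    total = int(valid.sum())
    rows = []
    for g in sorted(GRADE_LABELS, reverse=True):
        n = int((grades == g).sum())
        rows.append(
            {
                "grade": g,
                "label": GRADE_LABELS[g],
                "area": n * grid.cell_area_km2,
                "proportion": n / total if total else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("grade")
    df.attrs["mean_quality"] = float(np.nanmean(q)) if total else np.nan
    df.attrs["mean_degradation"] = float(np.nanmean(deg)) if total else np.nan
    return df
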