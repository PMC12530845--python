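"""Land-use/land-cover change accounting between two epochs.

The transition matrix S_ij records the area (km²) converted from class i at
the first date to class j at the second; its marginals reproduce the
per-epoch class areas, which feeds both the change summary tables and the
Markov demand estimation. Trajectory coding compresses the same information
into a per-cell raster (``10*i + j``), the standard input for change maps
and Sankey diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec, LULCMap


@dataclass
class TransitionMatrix:
    """Class-by-class converted area S_ij in km² between two dates."""

    areas: np.ndarray
    labels: list[int]
    period: tuple[str, str] = ("t1", "t2")
    cell_area: float = 1.0  # km² per cell

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        n = len(self.labels)
        if self.areas.shape != (n, n):
            raise ValueError("areas must be square and match labels")
        if np.any(self.areas < 0):
            raise ValueError("transition areas must be non-negative")

    @property
    def areas_t1(self) -> np.ndarray:
        """Row sums: class areas at the first date (km²)."""
        return self.areas.sum(axis=1)

    @property
    def areas_t2(self) -> np.ndarray:
        """Column sums: class areas at the second date (km²)."""
        return self.areas.sum(axis=0)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def to_dataframe(self) -> pd.DataFrame:
        from .grid import CLASS_LABELS

        names = [CLASS_LABELS.get(c, str(c)) for c in self.labels]
        return pd.DataFrame(self.areas, index=names, columns=names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label=f"{self.period[0]} \\ {self.period[1]}")


def compute_transition_matrix(m1: LULCMap, m2: LULCMap) -> TransitionMatrix:
    """Cross-tabulate two co-registered maps into an area matrix S_ij.

    Cells that are nodata in *either* epoch are excluded from both marginals
    so that row/column sums stay consistent with per-epoch areas over the
    jointly valid extent.
    """
    m1.grid.require_match(m2.grid, "epoch rasters")
    labels = sorted(set(m1.class_labels) | set(m2.class_labels))
    both = m1.valid_mask & m2.valid_mask
    n = len(labels)
    i = np.searchsorted(labels, m1.codes[both])
    j = np.searchsorted(labels, m2.codes[both])
    counts = np.bincount(i * n + j, minlength=n * n).reshape(n, n)
    return TransitionMatrix(
        areas=counts * m1.grid.cell_area_km2,
        labels=labels,
        period=(m1.epoch_label or "t1", m2.epoch_label or "t2"),
        cell_area=m1.grid.cell_area_km2,
    )


def change_summary(tm: TransitionMatrix) -> pd.DataFrame:
    """Per-class area/proportion table with change rates.

    Columns: ``area_t1``/``area_t2`` (km²), ``proportion_t1``/``proportion_t2``
    (fraction of total valid area), ``delta_area`` (km²) and ``delta_rate``
    (percent of the t1 area; NaN where the class had no t1 area).
    """
    from .grid import CLASS_LABELS

    a1, a2 = tm.areas_t1, tm.areas_t2
    total = tm.total_area
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(a1 > 0, 100.0 * (a2 - a1) / a1, np.nan)
    return pd.DataFrame(
        {
            "code": tm.labels,
            "label": [CLASS_LABELS.get(c, str(c)) for c in tm.labels],
            "area_t1": a1,
            "proportion_t1": a1 / total,
            "area_t2": a2,
            "proportion_t2": a2 / total,
            "delta_area": a2 - a1,
            "delta_rate": rate,
        }
    ).set_index("code")


def transition_shares(tm: TransitionMatrix) -> pd.DataFrame:
    """Each off-diagonal transition's area and share of total valid area."""
    from .grid import CLASS_LABELS

    rows = []
    for i, ci in enumerate(tm.labels):
        for j, cj in enumerate(tm.labels):
            if i == j or tm.areas[i, j] == 0:
                continue
            rows.append(
                {
                    "code": 10 * ci + cj,
                    "from": CLASS_LABELS.get(ci, str(ci)),
                    "to": CLASS_LABELS.get(cj, str(cj)),
                    "area": tm.areas[i, j],
                    "share": tm.areas[i, j] / tm.total_area,
                }
            )
    df = pd.DataFrame(rows, columns=["code", "from", "to", "area", "share"])
    return df.sort_values("area", ascending=False).reset_index(drop=True)


@dataclass
class TrajectoryMap:
    """Per-cell change trajectory: class i at t1, j at t2 encodes ``10*i + j``."""

    grid: GridSpec
    codes: np.ndarray

    @staticmethod
    def encode(i: int, j: int) -> int:
        return 10 * i + j

    @staticmethod
    def decode(code: int) -> tuple[int, int]:
        return divmod(code, 10)


def trajectory_map(m1: LULCMap, m2: LULCMap) -> TrajectoryMap:
    """Encode the (t1, t2) class pair of every cell as ``10*i + j``.

    Unchanged cells therefore carry ``11*i`` (e.g. stable forest = 22);
    a farmland-to-forest cell carries 12. Nodata in either epoch propagates.
    """
    m1.grid.require_match(m2.grid, "epoch rasters")
    both = m1.valid_mask & m2.valid_mask
    codes = np.full(m1.grid.shape, m1.grid.nodata_code, dtype=np.int64)
    codes[both] = 10 * m1.codes[both] + m2.codes[both]
    return TrajectoryMap(grid=m1.grid, codes=codes)
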