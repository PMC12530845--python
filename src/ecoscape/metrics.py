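"""Map-agreement metrics for simulation validation.

Overall accuracy and Cohen's Kappa are computed from the class confusion
matrix; the Figure of Merit (FOM) is the change-focused ratio
B / (A + B + C + D) over the cells involved in observed or simulated
change, with

    A — observed change simulated as persistence (miss),
    B — observed change simulated as the correct new class (hit),
    C — observed change simulated as change to the wrong class,
    D — observed persistence simulated as change (false alarm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import LULCMap


@dataclass
class ConfusionMatrix:
    """Cross-tabulation: reference classes in rows, simulated in columns."""

    counts: np.ndarray
    labels: list[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square and match labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        from .grid import CLASS_LABELS

        names = [CLASS_LABELS.get(c, str(c)) for c in self.labels]
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion_matrix(reference: LULCMap, simulated: LULCMap) -> ConfusionMatrix:
    """Joint class histogram over cells valid in both maps."""
    reference.grid.require_match(simulated.grid, "reference/simulated rasters")
    labels = sorted(set(reference.class_labels) | set(simulated.class_labels))
    both = reference.valid_mask & simulated.valid_mask
    n = len(labels)
    i = np.searchsorted(labels, reference.codes[both])
    j = np.searchsorted(labels, simulated.codes[both])
    counts = np.bincount(i * n + j, minlength=n * n).reshape(n, n)
    return ConfusionMatrix(counts=counts, labels=labels)


def oa_kappa(cm: ConfusionMatrix) -> tuple[float, float]:
    """Overall accuracy and Cohen's Kappa.

    OA = trace/total; Kappa = (OA − p_e)/(1 − p_e) where p_e is the chance
    agreement from the marginals. Kappa is NaN when p_e = 1 (a single class
    on both sides leaves chance-corrected agreement undefined).
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    oa = float(np.trace(cm.counts)) / total
    p_ref = cm.counts.sum(axis=1) / total
    p_sim = cm.counts.sum(axis=0) / total
    p_e = float(p_ref @ p_sim)
    if abs(1.0 - p_e) < 1e-12:
        warnings.warn("degenerate marginals (p_e = 1); Kappa undefined")
        return oa, float("nan")
    return oa, (oa - p_e) / (1.0 - p_e)


def figure_of_merit(
    ref_t1: LULCMap, ref_t2: LULCMap, simulated_t2: LULCMap
) -> float:
    """FOM = hits / (misses + hits + wrong-class change + false alarms).

    NaN (with a warning) when the reference pair shows no change at all.
    """
    ref_t1.grid.require_match(ref_t2.grid, "reference rasters")
    ref_t1.grid.require_match(simulated_t2.grid, "simulated raster")
    ok = ref_t1.valid_mask & ref_t2.valid_mask & simulated_t2.valid_mask
    obs_change = ok & (ref_t1.codes != ref_t2.codes)
    sim_change = ok & (ref_t1.codes != simulated_t2.codes)
    if not obs_change.any():
        warnings.warn("no observed change; FOM undefined")
        return float("nan")
    a = int((obs_change & ~sim_change).sum())
    b = int((obs_change & sim_change & (simulated_t2.codes == ref_t2.codes)).sum())
    c = int((obs_change & sim_change & (simulated_t2.codes != ref_t2.codes)).sum())
    d = int((~obs_change & ok & sim_change).sum())
    return b / (a + b + c + d)
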