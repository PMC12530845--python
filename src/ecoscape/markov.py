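"""Markov-chain land-demand projection with scenario adjustments.

The period transition-probability matrix is the row-normalised transition
area matrix; one Markov step spans the calibration period, so projecting an
equally long horizon is a single step. Scenario presets rescale named
off-diagonal transition probabilities (e.g. under an ecological-priority
scenario, farmland → natural-class probabilities rise by 50% while
forest → non-water losses fall by 60%), absorbing the residual into the
diagonal so rows stay stochastic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transitions import TransitionMatrix

ROW_SUM_TOL = 1e-9


@dataclass
class TransitionProbabilityMatrix:
    """Row-stochastic class transition probabilities over one period."""

    probs: np.ndarray
    labels: list[int]
    period_years: int = 14

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        n = len(self.labels)
        if self.probs.shape != (n, n):
            raise ValueError("probs must be square and match labels")
        if np.any(self.probs < -ROW_SUM_TOL) or np.any(self.probs > 1 + ROW_SUM_TOL):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each row must sum to 1")

    def to_dataframe(self) -> pd.DataFrame:
        from .grid import CLASS_LABELS

        names = [CLASS_LABELS.get(c, str(c)) for c in self.labels]
        return pd.DataFrame(self.probs, index=names, columns=names)


@dataclass
class ScenarioAdjustment:
    """Multiplicative rules on off-diagonal transition probabilities."""

    rules: list[tuple[int, frozenset[int], float]] = field(default_factory=list)
    label: str = "custom"

    def __post_init__(self) -> None:
        for src, targets, mult in self.rules:
            if mult <= 0:
                raise ValueError("multipliers must be positive")
            if src in targets:
                raise ValueError("a rule may not target its own diagonal")


def nd_scenario() -> ScenarioAdjustment:
    """Natural development: historical probabilities unadjusted."""
    return ScenarioAdjustment(rules=[], label="ND")


def ep_scenario() -> ScenarioAdjustment:
    """Ecological priority: boost farmland reversion to natural classes by
    50% and cut losses from forest (×0.4), shrub, grass and water (×0.6)
    toward non-protected destinations."""
    f = frozenset
    return ScenarioAdjustment(
        rules=[
            (1, f({2, 3, 4, 5}), 1.5),   # farmland -> forest/shrub/grass/water
            (2, f({1, 3, 4, 6, 7}), 0.4),  # forest -> all but water
            (3, f({1, 4, 6, 7}), 0.6),     # shrub -> all but water, forest
            (4, f({1, 6, 7}), 0.6),        # grass -> all but water, shrub, forest
            (5, f({1, 6, 7}), 0.6),        # water -> all but shrub, forest, grass
        ],
        label="EP",
    )


SCENARIOS = {"ND": nd_scenario, "EP": ep_scenario}


def estimate_transition_probabilities(
    tm: TransitionMatrix, period_years: int = 14
) -> TransitionProbabilityMatrix:
    """Row-normalise the area matrix: P_ij = S_ij / Σ_j S_ij.

    A class absent at the first date has an undefined row; it gets the
    identity row (the class persists) with a warning.
    """
    S = tm.areas
    if S.sum() == 0:
        raise ValueError("empty transition matrix")
    row = S.sum(axis=1, keepdims=True)
    empty = row[:, 0] == 0
    P = np.divide(S, np.where(row == 0, 1.0, row))
    if empty.any():
        warnings.warn(
            f"classes {[tm.labels[i] for i in np.flatnonzero(empty)]} have no "
            "t1 area; assigned identity rows"
        )
        P[empty] = np.eye(len(tm.labels))[empty]
    return TransitionProbabilityMatrix(
        probs=P, labels=list(tm.labels), period_years=period_years
    )


def apply_scenario(
    P: TransitionProbabilityMatrix, adj: ScenarioAdjustment
) -> TransitionProbabilityMatrix:
    """Apply multiplicative rules and restore row-stochasticity.

    The diagonal (persistence) is reset to 1 − Σ off-diagonal; if the
    boosted off-diagonals exceed 1, they are rescaled proportionally and the
    diagonal is zero.
    """
    idx = {c: k for k, c in enumerate(P.labels)}
    out = P.probs.copy()
    for src, targets, mult in adj.rules:
        if src not in idx or any(t not in idx for t in targets):
            raise KeyError(f"scenario rule references unknown class: {src}->{set(targets)}")
        i = idx[src]
        for t in targets:
            out[i, idx[t]] *= mult
    n = len(P.labels)
    for i in range(n):
        off = out[i].sum() - out[i, i]
        if off <= 1.0:
            out[i, i] = 1.0 - off
        else:
            d = np.eye(n, dtype=bool)[i]
            out[i, ~d] *= 1.0 / off
            out[i, i] = 0.0
    return TransitionProbabilityMatrix(
        probs=out, labels=list(P.labels), period_years=P.period_years
    )


def project_demand(
    P: TransitionProbabilityMatrix,
    areas_t: dict[int, float] | np.ndarray,
    steps: int = 1,
) -> pd.Series:
    """Project class-area demand: demand = areas · Pˢ.

    ``areas_t`` maps class code → km² (or is a vector ordered as P.labels).
    Total area is conserved exactly up to float round-off.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if isinstance(areas_t, dict):
        missing = set(areas_t) - set(P.labels)
        if missing:
            raise KeyError(f"area vector has classes unknown to P: {sorted(missing)}")
        a = np.array([float(areas_t.get(c, 0.0)) for c in P.labels])
    else:
        a = np.asarray(areas_t, dtype=float)
        if a.shape != (len(P.labels),):
            raise ValueError("area vector length must match P labels")
    if np.any(a < 0):
        raise ValueError("areas must be non-negative")
    demand = a @ np.linalg.matrix_power(P.probs, steps)
    return pd.Series(demand, index=P.labels, name="demand_km2")
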