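"""High-level model/results interface.

Two model classes tie the pipeline's stages together the way statistical
packages organise estimation:

* :class:`HabitatQualityModel` — the mechanistic habitat model evaluated on
  a land-cover map; ``fit()`` returns a :class:`HabitatQualityResults`
  holding the degradation and quality surfaces, the grade raster, the grade
  summary and landscape means.
* :class:`LandUseChangeModel` — fitted from two dated maps (plus optional
  drivers); ``fit()`` estimates the transition accounting, the Markov
  transition probabilities and, when drivers are supplied, the per-class
  random-forest development probabilities. The results object projects
  demand under a scenario and simulates the horizon map with the CA
  allocator.

Both results objects expose ``summary()`` returning a plain-text table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import allocation as _alloc
from . import habitat as _hab
from . import markov as _mk
from . import transitions as _tr
from .grid import LULCMap


@dataclass
class HabitatQualityResults:
    """Estimated habitat surfaces and their summaries."""

    lulc: LULCMap
    degradation: np.ndarray
    quality: np.ndarray
    grades: np.ndarray
    grade_table: pd.DataFrame

    @property
    def mean_quality(self) -> float:
        return self.grade_table.attrs["mean_quality"]

    @property
    def mean_degradation(self) -> float:
        return self.grade_table.attrs["mean_degradation"]

    def summary(self) -> str:
        lines = [
            f"Habitat quality summary — epoch {self.lulc.epoch_label or '?'}",
            f"  valid cells: {self.lulc.n_valid}"
            f" ({self.lulc.n_valid * self.lulc.grid.cell_area_km2:.2f} km²)",
            f"  mean quality:     {self.mean_quality:.4f}",
            f"  mean degradation: {self.mean_degradation:.4f}",
            "",
            self.grade_table.to_string(
                float_format=lambda v: f"{v:.4f}", columns=["label", "area", "proportion"]
            ),
        ]
        return "\n".join(lines)


class HabitatQualityModel:
    """Habitat-quality model bound to a land-cover map and parameter tables.

    Parameters default to the standard two-threat setup (farmland 1 km
    linear ω=0.4; construction 10 km exponential ω=1) with the seven-class
    suitability/sensitivity table and fixed grade cut points
    (0.298, 0.698, 0.984).
    """

    def __init__(
        self,
        lulc: LULCMap,
        threats: list[_hab.ThreatSpec] | None = None,
        sensitivity: _hab.SensitivityTable | None = None,
        config: _hab.HabitatConfig | None = None,
    ) -> None:
        self.lulc = lulc
        self.threats = _hab.default_threats() if threats is None else threats
        self.sensitivity = (
            _hab.default_sensitivity() if sensitivity is None else sensitivity
        )
        self.config = _hab.HabitatConfig() if config is None else config

    def fit(self) -> HabitatQualityResults:
        """Evaluate degradation, quality and grades on the bound map."""
        deg = _hab.compute_degradation(
            self.lulc, self.threats, self.sensitivity, self.config
        )
        q = _hab.compute_quality(self.lulc, deg, self.sensitivity, self.config)
        grades = _hab.classify_quality(q, self.config.thresholds)
        table = _hab.grade_summary(grades, q, deg, self.lulc.grid)
        return HabitatQualityResults(self.lulc, deg, q, grades, table)


@dataclass
class SimulationResult:
    """Scenario simulation output: the horizon map and its bookkeeping."""

    scenario: str
    demand: pd.Series
    allocation: _alloc.AllocationResult

    @property
    def lulc(self) -> LULCMap:
        return self.allocation.lulc


@dataclass
class LandUseChangeResults:
    """Fitted change accounting and projection machinery."""

    t1: LULCMap
    t2: LULCMap
    transition_matrix: _tr.TransitionMatrix
    change_table: pd.DataFrame
    transition_probabilities: _mk.TransitionProbabilityMatrix
    development: dict[int, _alloc.DevelopmentProbability] = field(default_factory=dict)
    drivers: _alloc.DriverStack | None = None

    @property
    def importances(self) -> pd.DataFrame | None:
        """Driver importances per expanding class (columns), or None."""
        if not self.development:
            return None
        return pd.DataFrame(
            {c: dp.importances for c, dp in sorted(self.development.items())}
        )

    def scenario_probabilities(
        self, scenario: str | _mk.ScenarioAdjustment = "ND"
    ) -> _mk.TransitionProbabilityMatrix:
        adj = (
            _mk.SCENARIOS[scenario]() if isinstance(scenario, str) else scenario
        )
        return _mk.apply_scenario(self.transition_probabilities, adj)

    def project_demand(
        self, scenario: str | _mk.ScenarioAdjustment = "ND", steps: int = 1
    ) -> pd.Series:
        """Markov class-area demand at the horizon under a scenario."""
        P = self.scenario_probabilities(scenario)
        return _mk.project_demand(P, self.t2.class_areas_km2(), steps=steps)

    def simulate(
        self,
        scenario: str | _mk.ScenarioAdjustment = "ND",
        steps: int = 1,
        config: _alloc.AllocationConfig | None = None,
        restricted_mask: np.ndarray | None = None,
    ) -> SimulationResult:
        """Project demand and allocate it spatially from the t2 map.

        Under the EP scenario the restricted mask (if given) freezes
        protected natural classes; under ND the mask is ignored.
        """
        if not self.development:
            raise ValueError("no development probabilities; fit with drivers")
        label = scenario if isinstance(scenario, str) else scenario.label
        demand = self.project_demand(scenario, steps=steps)
        config = _alloc.AllocationConfig() if config is None else config
        if restricted_mask is not None and label == "EP":
            from dataclasses import replace

            config = replace(config, restricted_mask=restricted_mask)
        result = _alloc.allocate(self.t2, demand, self.development, config)
        return SimulationResult(label, demand, result)

    def summary(self) -> str:
        df = self.change_table
        lines = [
            f"Land-use change {self.transition_matrix.period[0]} → "
            f"{self.transition_matrix.period[1]} "
            f"(total {self.transition_matrix.total_area:.2f} km²)",
            "",
            df.to_string(
                float_format=lambda v: f"{v:.4f}",
                columns=[
                    "label", "area_t1", "proportion_t1", "area_t2",
                    "proportion_t2", "delta_area", "delta_rate",
                ],
            ),
        ]
        if self.development:
            lines += ["", "Driver importances (per expanding class):",
                      self.importances.to_string(float_format=lambda v: f"{v:.3f}")]
        return "\n".join(lines)


class LandUseChangeModel:
    """Land-use change model fitted from two co-registered dated maps.

    ``drivers`` enables the spatial stage: expansion sampling and
    random-forest development probabilities for every class that grew
    between the two dates.
    """

    def __init__(
        self,
        t1: LULCMap,
        t2: LULCMap,
        drivers: _alloc.DriverStack | None = None,
        period_years: int = 14,
        seed: int = 0,
    ) -> None:
        t1.grid.require_match(t2.grid, "epoch rasters")
        self.t1 = t1
        self.t2 = t2
        self.drivers = drivers
        self.period_years = period_years
        self.seed = seed

    def fit(
        self,
        background_ratio: float = 1.0,
        n_estimators: int = 50,
        min_expansion_cells: int = 10,
    ) -> LandUseChangeResults:
        """Estimate accounting, Markov probabilities and (optionally) the
        per-class development-probability surfaces.

        Classes with fewer than ``min_expansion_cells`` expansion cells are
        skipped (too few positives to train on).
        """
        tm = _tr.compute_transition_matrix(self.t1, self.t2)
        table = _tr.change_summary(tm)
        P = _mk.estimate_transition_probabilities(tm, self.period_years)
        development: dict[int, _alloc.DevelopmentProbability] = {}
        if self.drivers is not None:
            valid = self.t2.valid_mask
            for cls in sorted(self.t2.class_labels):
                samples = _alloc.extract_expansion_samples(
                    self.t1, self.t2, self.drivers, cls,
                    background_ratio=background_ratio,
                    seed=self.seed + cls,
                )
                if samples.y.sum() < min_expansion_cells:
                    continue
                development[cls] = _alloc.fit_development_probability(
                    samples, self.drivers, valid_mask=valid,
                    seed=self.seed + cls, n_estimators=n_estimators,
                )
        return LandUseChangeResults(
            self.t1, self.t2, tm, table, P, development, self.drivers
        )
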