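"""Light x nutrient flux scenarios and the scenario result table.

The eight canonical scenarios A-H combine two photon uptake caps (low light
320, high light 800 mmol/(g dw . h)) with two nitrate uptake caps
(nutrient-replete 0.19, nutrient-depleted 0.001 mmol/(g dw . h)).  All fix
the maintenance-ATP drain at 0.92 mmol/(g dw . h).  Scenarios A-D maximize
growth alone, max(mu); E-H additionally maximize the beta-carotene sink in
a second lexicographic stage, max(mu, Car14).

Light and nitrate are capped (0 <= v <= value) by default; maintenance is
equality-fixed.  Under growth maximization the cap binds whenever the
resource limits, so capped and fixed modes coincide where it matters; both
are available via ``bound_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ROLE_BIOMASS,
    ROLE_CAROTENE,
    ROLE_LIGHT,
    ROLE_MAINTENANCE,
    ROLE_NITRATE,
    StoichiometricNetwork,
)
from .fba import FBAResult, FluxBalanceModel, ObjectiveSpec

__all__ = [
    "FluxScenario",
    "ScenarioTable",
    "CANONICAL_LABELS",
    "LOW_LIGHT",
    "HIGH_LIGHT",
    "NITRATE_REPLETE",
    "NITRATE_DEPLETED",
    "MAINTENANCE_ATP",
    "make_scenario",
    "run_scenarios",
    "compare_tables",
]

LOW_LIGHT = 320.0
HIGH_LIGHT = 800.0
NITRATE_REPLETE = 0.19
NITRATE_DEPLETED = 0.001
MAINTENANCE_ATP = 0.92

CANONICAL_LABELS = ("A", "B", "C", "D", "E", "F", "G", "H")

_LIGHT = {"A": LOW_LIGHT, "B": HIGH_LIGHT, "C": LOW_LIGHT, "D": HIGH_LIGHT}
_NITRATE = {"A": NITRATE_REPLETE, "B": NITRATE_REPLETE,
            "C": NITRATE_DEPLETED, "D": NITRATE_DEPLETED}


@dataclass(frozen=True)
class FluxScenario:
    """Exchange-flux constraints plus an ordered objective.

    ``bound_mode`` applies to the driven exchanges (light, nitrate):
    "capped" constrains 0 <= v <= value, "fixed" pins lb = ub = value.
    The maintenance drain is always equality-fixed.
    ``objective_roles`` lists the roles maximized in order; one role is
    plain FBA, two are solved lexicographically.
    """

    label: str
    light_flux: float
    nitrate_flux: float
    maintenance_flux: float = MAINTENANCE_ATP
    objective_roles: tuple[str, ...] = (ROLE_BIOMASS,)
    bound_mode: str = "capped"

    def __post_init__(self) -> None:
        if self.bound_mode not in ("capped", "fixed"):
            raise ValueError("bound_mode must be 'capped' or 'fixed'")
        if not self.objective_roles:
            raise ValueError("scenario needs at least one objective role")

    @property
    def objective_text(self) -> str:
        names = {ROLE_BIOMASS: "mu", ROLE_CAROTENE: "Car14"}
        inner = ",".join(names.get(r, r) for r in self.objective_roles)
        return f"max({inner})"

    def _role_id(self, network: StoichiometricNetwork, role: str) -> str:
        rid = network.role_reaction(role)
        if rid is None:
            raise KeyError(
                f"scenario {self.label!r} needs the network to name role {role!r}"
            )
        return rid

    def bound_overrides(self, network: StoichiometricNetwork) -> dict[str, tuple[float, float]]:
        def driven(value: float) -> tuple[float, float]:
            return (value, value) if self.bound_mode == "fixed" else (0.0, value)

        return {
            self._role_id(network, ROLE_LIGHT): driven(self.light_flux),
            self._role_id(network, ROLE_NITRATE): driven(self.nitrate_flux),
            self._role_id(network, ROLE_MAINTENANCE): (
                self.maintenance_flux, self.maintenance_flux
            ),
        }

    def objective_spec(self, network: StoichiometricNetwork) -> ObjectiveSpec:
        return ObjectiveSpec.maximize(
            *(self._role_id(network, role) for role in self.objective_roles)
        )

    def with_bound_mode(self, mode: str) -> "FluxScenario":
        return replace(self, bound_mode=mode)


def make_scenario(label: str, bound_mode: str = "capped") -> FluxScenario:
    """Build one of the canonical scenarios A-H.

    A/E: low light, nitrate-replete; B/F: high light, replete;
    C/G: low light, depleted; D/H: high light, depleted.  A-D maximize
    growth only; E-H maximize growth then the carotene sink.
    """
    label = label.strip().upper()
    if label not in CANONICAL_LABELS:
        raise ValueError(
            f"unknown scenario {label!r}; valid labels: {', '.join(CANONICAL_LABELS)}"
        )
    base = label if label in "ABCD" else "ABCD"["EFGH".index(label)]
    roles = (ROLE_BIOMASS,) if label in "ABCD" else (ROLE_BIOMASS, ROLE_CAROTENE)
    return FluxScenario(
        label=label,
        light_flux=_LIGHT[base],
        nitrate_flux=_NITRATE[base],
        maintenance_flux=MAINTENANCE_ATP,
        objective_roles=roles,
        bound_mode=bound_mode,
    )


@dataclass
class ScenarioRow:
    label: str
    light_flux: float
    nitrate_flux: float
    objective: str
    status: str
    growth_rate: float = np.nan       # 1/h, full precision
    carotene_flux: float = np.nan     # mmol/(g dw . h)
    stage_values: list[float] = field(default_factory=list)


@dataclass
class ScenarioTable:
    """Per-scenario inputs and FBA outputs, one row per scenario."""

    rows: list[ScenarioRow] = field(default_factory=list)

    def labels(self) -> list[str]:
        return [r.label for r in self.rows]

    def row(self, label: str) -> ScenarioRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(f"no scenario row {label!r}")

    def to_frame(self) -> pd.DataFrame:
        """Wide layout mirroring the printed tables: columns = scenarios."""
        data = {
            "Light (Ex01)": [r.light_flux for r in self.rows],
            "Nutrients (Ex06, NO3-)": [r.nitrate_flux for r in self.rows],
            "Objective function": [r.objective for r in self.rows],
            "Calc. growth rate in 1/h": [r.growth_rate for r in self.rows],
            "Calc. beta-carotene production in mmol/(g dw.h)": [
                r.carotene_flux for r in self.rows
            ],
            "Status": [r.status for r in self.rows],
        }
        return pd.DataFrame(data, index=self.labels()).T

    def summary(self, decimals: int = 4) -> str:
        """Display table with numeric cells rounded to 4 decimals."""
        df = self.to_frame().copy()
        for row in ("Light (Ex01)", "Nutrients (Ex06, NO3-)",
                    "Calc. growth rate in 1/h",
                    "Calc. beta-carotene production in mmol/(g dw.h)"):
            df.loc[row] = [
                "" if (isinstance(v, float) and np.isnan(v)) else f"{float(v):.{decimals}f}"
                for v in df.loc[row]
            ]
        return df.to_string()


def run_scenarios(
    network: StoichiometricNetwork,
    labels: Optional[Iterable[str]] = None,
    scenarios: Optional[Sequence[FluxScenario]] = None,
    bound_mode: str = "capped",
    tie_break: Optional[str] = None,
) -> ScenarioTable:
    """Solve each scenario on the network and assemble a result table.

    Per-scenario solver failures are recorded in the row status and the run
    continues.  Values are stored at full precision; rounding happens only
    in :meth:`ScenarioTable.summary`.
    """
    if scenarios is None:
        labels = list(labels if labels is not None else CANONICAL_LABELS)
        scenarios = [make_scenario(lbl, bound_mode=bound_mode) for lbl in labels]
    table = ScenarioTable()
    for sc in scenarios:
        row = ScenarioRow(
            label=sc.label,
            light_flux=sc.light_flux,
            nitrate_flux=sc.nitrate_flux,
            objective=sc.objective_text,
            status="error",
        )
        try:
            model = FluxBalanceModel(network, scenario=sc, tie_break=tie_break)
            result: FBAResult = model.fit()
            row.status = result.status
            if result.status == "optimal":
                row.growth_rate = result.named_fluxes.get(ROLE_BIOMASS, np.nan)
                row.carotene_flux = result.named_fluxes.get(ROLE_CAROTENE, np.nan)
                row.stage_values = result.stage_values
        except Exception as exc:  # keep going; the row carries the failure
            row.status = f"error: {exc}"
        table.rows.append(row)
    return table


@dataclass
class TableDeviation:
    label: str
    quantity: str
    computed: float
    reference: float
    rel_deviation: float


@dataclass
class ComparisonReport:
    deviations: list[TableDeviation]
    rel_tol: float

    @property
    def max_deviation(self) -> float:
        return max((d.rel_deviation for d in self.deviations), default=0.0)

    @property
    def passed(self) -> bool:
        return all(d.rel_deviation <= self.rel_tol for d in self.deviations)

    def failures(self) -> list[TableDeviation]:
        return [d for d in self.deviations if d.rel_deviation > self.rel_tol]


def compare_tables(
    computed: ScenarioTable, reference: ScenarioTable, rel_tol: float = 1e-3
) -> ComparisonReport:
    """Cell-wise relative deviation between two scenario tables.

    Deviations are relative to max(|reference|, 1e-6), so a zero reference
    cell is compared absolutely at the 1e-6 flux scale instead of blowing
    up on solver round-off.
    """
    if computed.labels() != reference.labels():
        raise ValueError(
            f"label mismatch: {computed.labels()} vs {reference.labels()}"
        )
    devs: list[TableDeviation] = []
    for lbl in computed.labels():
        c, r = computed.row(lbl), reference.row(lbl)
        for attr, pretty in (
            ("growth_rate", "growth rate"),
            ("carotene_flux", "carotene flux"),
        ):
            cv, rv = getattr(c, attr), getattr(r, attr)
            if np.isnan(cv) and np.isnan(rv):
                continue
            denom = max(abs(rv), 1e-6)
            devs.append(TableDeviation(lbl, pretty, cv, rv, abs(cv - rv) / denom))
    return ComparisonReport(devs, rel_tol)
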