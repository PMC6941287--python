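"""Core domain types for compartmentalized stoichiometric networks.

A :class:`StoichiometricNetwork` holds ordered metabolites and reactions and
is the single source of the stoichiometric matrix ``S`` used by the flux
balance machinery.  Conventions:

* Stoichiometric coefficients are negative for substrates and positive for
  products.
* Exchange reactions are single-sided columns (no explicit boundary species
  row); a positive exchange flux means uptake into the system.
* All fluxes are in mmol/(g dw . h).  The biomass reaction flux is read as a
  specific growth rate in 1/h, i.e. biomass composition coefficients are
  scaled to yield 1 g dry weight per unit flux.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np

__all__ = [
    "Compartment",
    "ReactionKind",
    "Metabolite",
    "Reaction",
    "StoichiometricNetwork",
    "BoundsPolicy",
    "ValidationIssue",
    "ValidationReport",
    "NetworkStructureError",
    "build_stoichiometric_matrix",
    "apply_bounds",
    "validate_network",
    "ROLE_BIOMASS",
    "ROLE_LIGHT",
    "ROLE_NITRATE",
    "ROLE_MAINTENANCE",
    "ROLE_CAROTENE",
]

# canonical role keys used throughout the package
ROLE_BIOMASS = "biomass"
ROLE_LIGHT = "light_exchange"
ROLE_NITRATE = "nitrate_exchange"
ROLE_MAINTENANCE = "maintenance"
ROLE_CAROTENE = "carotene_sink"

KNOWN_ROLES = (ROLE_BIOMASS, ROLE_LIGHT, ROLE_NITRATE, ROLE_MAINTENANCE, ROLE_CAROTENE)


class NetworkStructureError(ValueError):
    """Raised when a network references unknown ids or violates invariants."""


class Compartment(str, enum.Enum):
    """Subcellular compartments of the model (plus the external boundary)."""

    CYTOSOL = "cytosol"
    CHLOROPLAST = "chloroplast"
    MITOCHONDRION = "mitochondrion"
    EXTERNAL = "external"


class ReactionKind(str, enum.Enum):
    INTERNAL = "internal"
    TRANSPORT = "transport"
    EXCHANGE = "exchange"
    BIOMASS = "biomass"
    MAINTENANCE = "maintenance"


@dataclass(frozen=True)
class Metabolite:
    """A chemical species located in one compartment."""

    id: str
    name: str = ""
    compartment: Compartment = Compartment.CYTOSOL
    formula: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")
        if not isinstance(self.compartment, Compartment):
            object.__setattr__(self, "compartment", Compartment(self.compartment))


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps metabolite ids to signed coefficients (negative =
    consumed).  Zero coefficients are rejected; an irreversible reaction must
    have a non-negative lower bound.
    """

    id: str
    stoichiometry: Mapping[str, float]
    name: str = ""
    reversible: bool = False
    lower_bound: Optional[float] = None
    upper_bound: Optional[float] = None
    ec_number: Optional[str] = None
    kegg_id: Optional[str] = None
    kind: ReactionKind = ReactionKind.INTERNAL

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r}: stoichiometry must be non-empty")
        stoich = dict(self.stoichiometry)
        for met, coef in stoich.items():
            if coef == 0:
                raise ValueError(
                    f"reaction {self.id!r}: zero coefficient for {met!r} not allowed"
                )
        object.__setattr__(self, "stoichiometry", stoich)
        if not isinstance(self.kind, ReactionKind):
            object.__setattr__(self, "kind", ReactionKind(self.kind))
        if (
            self.lower_bound is not None
            and self.upper_bound is not None
            and self.lower_bound > self.upper_bound
        ):
            raise ValueError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound is not None and self.lower_bound < 0:
            raise ValueError(
                f"reaction {self.id!r}: irreversible reaction with negative lower bound"
            )

    @property
    def has_bounds(self) -> bool:
        return self.lower_bound is not None and self.upper_bound is not None

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        if lower > upper:
            raise ValueError(
                f"reaction {self.id!r}: lower bound {lower} exceeds upper bound {upper}"
            )
        return replace(self, lower_bound=float(lower), upper_bound=float(upper))


@dataclass(frozen=True)
class BoundsPolicy:
    """Default flux bounds applied where a reaction carries no explicit bound.

    Defaults follow the common constraint-based convention for this network:
    irreversible reactions 0..100 mmol/(g dw . h), reversible -100..100.
    """

    irreversible_default: tuple[float, float] = (0.0, 100.0)
    reversible_default: tuple[float, float] = (-100.0, 100.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.irreversible_default, self.reversible_default):
            if lo > hi:
                raise ValueError("bounds policy: lower default exceeds upper default")


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    subject: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, severity: str, code: str, subject: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity, code, subject, message))

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def ok(self) -> bool:
        """True iff the report is empty (all checks passed)."""
        return not self.issues

    def has_errors(self) -> bool:
        return bool(self.errors)


class StoichiometricNetwork:
    """Ordered collection of metabolites and reactions with named roles.

    ``named_roles`` maps functional roles (biomass, light_exchange,
    nitrate_exchange, maintenance, carotene_sink) to reaction ids so the
    scenario layer can drive models regardless of reaction naming.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        named_roles: Optional[Mapping[str, str]] = None,
        name: str = "",
        compartment_ids: Optional[Mapping[Compartment, str]] = None,
    ) -> None:
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.named_roles: dict[str, str] = dict(named_roles or {})
        self.name = name
        # original SBML compartment ids, for round-tripping
        self.compartment_ids: dict[Compartment, str] = dict(compartment_ids or {})
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._check_references()

    def _check_references(self) -> None:
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise NetworkStructureError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
        for role, rid in self.named_roles.items():
            if rid not in self._rxn_index:
                raise NetworkStructureError(
                    f"named role {role!r} references unknown reaction {rid!r}"
                )

    # -- lookup ----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def role_reaction(self, role: str) -> Optional[str]:
        return self.named_roles.get(role)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def balanced_metabolites(self) -> list[Metabolite]:
        """Metabolites subject to steady-state mass balance (non-external)."""
        return [m for m in self.metabolites if m.compartment is not Compartment.EXTERNAL]

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lbs, ubs = [], []
        for r in self.reactions:
            if not r.has_bounds:
                raise ValueError(
                    f"reaction {r.id!r} has no bounds; call apply_bounds first"
                )
            lbs.append(r.lower_bound)
            ubs.append(r.upper_bound)
        return np.asarray(lbs, dtype=float), np.asarray(ubs, dtype=float)

    def replace_reaction(self, rxn: Reaction) -> None:
        self.reactions[self._rxn_index[rxn.id]] = rxn

    def copy(self) -> "StoichiometricNetwork":
        return StoichiometricNetwork(
            self.metabolites,
            self.reactions,
            self.named_roles,
            name=self.name,
            compartment_ids=self.compartment_ids,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<StoichiometricNetwork {self.name!r}: "
            f"{len(self.metabolites)} metabolites, {len(self.reactions)} reactions>"
        )


def build_stoichiometric_matrix(network: StoichiometricNetwork) -> np.ndarray:
    """Assemble ``S`` with rows = balanced metabolites, columns = reactions.

    External (boundary) species are excluded from the rows, so exchange
    reactions appear as unbalanced columns.  Entry ``(i, j)`` is the signed
    coefficient of metabolite ``i`` in reaction ``j``.
    """
    balanced = network.balanced_metabolites
    row_index = {m.id: i for i, m in enumerate(balanced)}
    S = np.zeros((len(balanced), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            if met_id not in network._met_index:
                raise NetworkStructureError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
            i = row_index.get(met_id)
            if i is not None:
                S[i, j] = coef
    return S


def apply_bounds(
    network: StoichiometricNetwork,
    policy: BoundsPolicy = BoundsPolicy(),
    overrides: Optional[Mapping[str, tuple[float, float]]] = None,
) -> StoichiometricNetwork:
    """Return a copy of the network with defaults and overrides applied.

    Reactions lacking explicit bounds receive the policy defaults according
    to reversibility; ``overrides`` replace whatever is there (a fixed flux
    is expressed as ``lb == ub``).  Idempotent for a fixed policy/overrides.
    """
    overrides = dict(overrides or {})
    for rid, (lo, hi) in overrides.items():
        if rid not in network._rxn_index:
            raise NetworkStructureError(f"bound override references unknown reaction {rid!r}")
        if lo > hi:
            raise ValueError(f"override for {rid!r}: lower bound {lo} exceeds upper {hi}")
    out = network.copy()
    for rxn in list(out.reactions):
        if rxn.id in overrides:
            lo, hi = overrides[rxn.id]
            new = replace(
                rxn,
                lower_bound=float(lo),
                upper_bound=float(hi),
                reversible=rxn.reversible or lo < 0,
            )
        elif not rxn.has_bounds:
            lo, hi = (
                policy.reversible_default if rxn.reversible else policy.irreversible_default
            )
            new = rxn.with_bounds(lo, hi)
        else:
            continue
        out.replace_reaction(new)
    return out


def validate_network(network: StoichiometricNetwork) -> ValidationReport:
    """Structural checks: duplicate ids, orphan metabolites, missing roles.

    All findings are report entries; an empty report means every check
    passed.  Zero-coefficient entries cannot be constructed through
    :class:`Reaction` but are re-checked defensively.
    """
    report = ValidationReport()

    seen_rxn: set[str] = set()
    for rxn in network.reactions:
        if rxn.id in seen_rxn:
            report.add("error", "duplicate-reaction-id", rxn.id,
                       f"reaction id {rxn.id!r} occurs more than once")
        seen_rxn.add(rxn.id)
    seen_met: set[str] = set()
    for met in network.metabolites:
        if met.id in seen_met:
            report.add("error", "duplicate-metabolite-id", met.id,
                       f"metabolite id {met.id!r} occurs more than once")
        seen_met.add(met.id)

    used = {m for r in network.reactions for m in r.stoichiometry}
    for met in network.metabolites:
        if met.id not in used:
            report.add("warning", "orphan-metabolite", met.id,
                       f"metabolite {met.id!r} participates in no reaction")

    for rxn in network.reactions:
        for met_id, coef in rxn.stoichiometry.items():
            if coef == 0:
                report.add("error", "zero-coefficient", rxn.id,
                           f"reaction {rxn.id!r} stores a zero coefficient for {met_id!r}")

    # role completeness is only meaningful once the network opts into roles;
    # purely structural toys without any role stay clean
    if network.named_roles:
        for role in KNOWN_ROLES:
            if role not in network.named_roles:
                report.add("warning", "named-role-absent", role,
                           f"named role {role!r} absent from the network")

    return report
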