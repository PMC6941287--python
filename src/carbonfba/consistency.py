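"""Feasibility and structural consistency checks for flux scenarios.

Mirrors the usual constraint-based validation step: a phase-1 LP decides
whether the steady-state system ``S.v = 0, lb <= v <= ub`` admits any flux
at all; blocked reactions and dead-end metabolites flag structural gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import linprog

from .core import (
    StoichiometricNetwork,
    apply_bounds,
    build_stoichiometric_matrix,
)
from .fba import SolverError

__all__ = [
    "FeasibilityResult",
    "check_feasibility",
    "find_blocked_reactions",
    "find_dead_end_metabolites",
]

#: |S.v| tolerance per metabolite row, relative to max(1, ||v||_inf)
FEASIBILITY_TOL = 1e-9
BOUND_TOL = 1e-9


@dataclass
class FeasibilityResult:
    feasible: bool
    witness_flux: Optional[dict[str, float]] = None
    infeasible_subsystem: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.feasible


def _phase1(S: np.ndarray, lb: np.ndarray, ub: np.ndarray):
    res = linprog(
        np.zeros(len(lb)),
        A_eq=S if S.size else None,
        b_eq=np.zeros(S.shape[0]) if S.size else None,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 0:
        return res.x
    if res.status == 2:
        return None
    raise SolverError(f"phase-1 LP failed: status {res.status}: {res.message}")


def check_feasibility(
    network: StoichiometricNetwork,
    scenario=None,
    bound_overrides: Optional[Mapping[str, tuple[float, float]]] = None,
) -> FeasibilityResult:
    """Phase-1 feasibility of a (scenario-constrained) network.

    On success the witness flux satisfies mass balance and all bounds.  On
    infeasibility, fixed-flux constraints (lb == ub != 0) are relaxed one at
    a time greedily; every constraint whose individual removal restores
    feasibility is reported as implicated.  This is a greedy diagnosis, not
    an exact irreducible infeasible subsystem.
    """
    overrides: dict[str, tuple[float, float]] = {}
    if scenario is not None:
        overrides.update(scenario.bound_overrides(network))
    overrides.update(bound_overrides or {})
    net = apply_bounds(network, overrides=overrides)
    S = build_stoichiometric_matrix(net)
    lb, ub = net.bounds_arrays()
    x = _phase1(S, lb, ub)
    if x is not None:
        return FeasibilityResult(
            feasible=True,
            witness_flux={rid: float(v) for rid, v in zip(net.reaction_ids, x)},
        )

    # greedy one-at-a-time relaxation: a reaction's bounds are implicated if
    # fully relaxing them alone restores feasibility (not an exact IIS)
    implicated: list[str] = []
    for j in range(len(lb)):
        lb2, ub2 = lb.copy(), ub.copy()
        lb2[j], ub2[j] = -np.inf, np.inf
        if _phase1(S, lb2, ub2) is not None:
            implicated.append(net.reaction_ids[j])
    return FeasibilityResult(feasible=False, infeasible_subsystem=implicated)


def find_blocked_reactions(
    network: StoichiometricNetwork,
    bound_overrides: Optional[Mapping[str, tuple[float, float]]] = None,
    tol: float = 1e-9,
) -> set[str]:
    """Reactions whose flux is zero in every feasible steady state.

    Determined by per-reaction flux variability: a reaction is blocked iff
    both its maximal and minimal achievable flux vanish.
    """
    net = apply_bounds(network, overrides=bound_overrides or {})
    S = build_stoichiometric_matrix(net)
    lb, ub = net.bounds_arrays()
    n = len(lb)
    bounds = list(zip(lb, ub))
    blocked: set[str] = set()
    for j, rid in enumerate(net.reaction_ids):
        c = np.zeros(n)
        c[j] = 1.0
        extremes = []
        for sign in (-1.0, 1.0):
            res = linprog(sign * c, A_eq=S if S.size else None,
                          b_eq=np.zeros(S.shape[0]) if S.size else None,
                          bounds=bounds, method="highs")
            if res.status == 2:  # infeasible system: nothing carries flux
                return set(net.reaction_ids)
            if res.status == 3:
                extremes.append(np.inf)
                continue
            if res.status != 0:
                raise SolverError(f"FVA LP failed for {rid!r}: {res.message}")
            extremes.append(abs(res.x[j]))
        if max(extremes) <= tol:
            blocked.add(rid)
    return blocked


def find_dead_end_metabolites(network: StoichiometricNetwork) -> set[str]:
    """Metabolites only produced or only consumed, accounting for reversibility.

    A reversible reaction can both produce and consume each of its
    participants, so any metabolite touched by one is never a dead end on
    that side.  External boundary species are not considered.
    """
    producers: set[str] = set()
    consumers: set[str] = set()
    touched: set[str] = set()
    for rxn in network.reactions:
        for met_id, coef in rxn.stoichiometry.items():
            touched.add(met_id)
            if rxn.reversible:
                producers.add(met_id)
                consumers.add(met_id)
            elif coef > 0:
                producers.add(met_id)
            else:
                consumers.add(met_id)
    balanced = {m.id for m in network.balanced_metabolites}
    dead = set()
    for met_id in touched & balanced:
        if (met_id in producers) != (met_id in consumers):
            dead.add(met_id)
    return dead
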