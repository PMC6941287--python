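"""Flux balance analysis: single-objective and lexicographic LP optimization.

The central objects follow the Model/Results convention: a
:class:`FluxBalanceModel` is built from a network (plus an optional flux
scenario and an :class:`ObjectiveSpec`), and :meth:`FluxBalanceModel.fit`
returns an :class:`FBAResult` carrying stage optima, one optimal flux
vector, named fluxes and solver diagnostics.

The LP is::

    max  c . v
    s.t. S . v = 0
         lb <= v <= ub

with ``S`` the stoichiometric matrix over balanced metabolites.  Combined
objectives such as max(mu, Car14) are solved lexicographically: each stage
is maximized with every earlier stage anchored at its optimum by an
equality row.  The optimal *value* per stage is the contract; the returned
flux vector is one vertex of a possibly non-unique optimal face (a
deterministic minimum-L1 tie-break is available via ``tie_break="min_l1"``).

``enumerate_vertices_oracle`` is an independent brute-force check for tiny
instances: it enumerates all basic solutions of the polytope exhaustively
and must agree with the LP to 1e-6.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .core import (
    ROLE_BIOMASS,
    ROLE_CAROTENE,
    ROLE_LIGHT,
    ROLE_MAINTENANCE,
    ROLE_NITRATE,
    BoundsPolicy,
    StoichiometricNetwork,
    apply_bounds,
    build_stoichiometric_matrix,
)

__all__ = [
    "ObjectiveSpec",
    "FBAResult",
    "FluxBalanceModel",
    "SolverError",
    "OracleResult",
    "solve_fba",
    "solve_lexicographic",
    "enumerate_vertices_oracle",
]

#: steady-state residual tolerance for reporting a solution as balanced
STEADY_STATE_TOL = 1e-6
#: bound-violation tolerance
BOUND_TOL = 1e-9
#: agreement tolerance between LP and the vertex-enumeration oracle
ORACLE_TOL = 1e-6


class SolverError(RuntimeError):
    """Numerical solver failure, distinct from genuine infeasibility."""


@dataclass(frozen=True)
class ObjectiveSpec:
    """Ordered linear objectives, each a map reaction-id -> weight, maximized.

    One stage is plain FBA; several stages are solved lexicographically
    (stage i+1 subject to stage i held at its optimum).
    """

    stages: tuple[dict[str, float], ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("objective needs at least one stage")
        object.__setattr__(self, "stages", tuple(dict(s) for s in self.stages))
        for stage in self.stages:
            if not stage:
                raise ValueError("objective stage must reference at least one reaction")

    @classmethod
    def maximize(cls, *reaction_ids: str) -> "ObjectiveSpec":
        """One stage per reaction id, each maximizing that single flux."""
        return cls(tuple({rid: 1.0} for rid in reaction_ids))

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def check_against(self, network: StoichiometricNetwork) -> None:
        for stage in self.stages:
            for rid in stage:
                if not network.has_reaction(rid):
                    raise KeyError(f"objective references unknown reaction {rid!r}")

    def stage_vector(self, network: StoichiometricNetwork, i: int) -> np.ndarray:
        c = np.zeros(len(network.reactions))
        for rid, w in self.stages[i].items():
            c[network.reaction_index(rid)] = w
        return c


@dataclass
class FBAResult:
    """Results of a flux balance optimization.

    Attributes
    ----------
    status : str
        "optimal", "infeasible" or "unbounded".
    stage_values : list of float
        Optimal objective value per stage (growth rate first for the
        canonical max(mu) / max(mu, Car14) objectives).
    flux : dict
        One optimal flux vector, reaction id -> mmol/(g dw . h).
    mu : float or None
        Growth rate in 1/h if the network names a biomass role.
    named_fluxes : dict
        Fluxes of the role reactions (biomass, light, nitrate, maintenance,
        carotene sink) present in the network.
    residual : float
        max_i |(S.v)_i| of the returned vector.
    unbounded_support : list of str
        Reactions carrying flux in an unbounded direction, when status is
        "unbounded".
    """

    status: str
    stage_values: list[float] = field(default_factory=list)
    flux: dict[str, float] = field(default_factory=dict)
    mu: Optional[float] = None
    named_fluxes: dict[str, float] = field(default_factory=dict)
    residual: float = np.nan
    max_bound_violation: float = np.nan
    unbounded_support: list[str] = field(default_factory=list)
    objective_stages: tuple[dict[str, float], ...] = ()
    backend: str = "scipy-highs"

    @property
    def objective_value(self) -> Optional[float]:
        return self.stage_values[0] if self.stage_values else None

    def summary(self) -> str:
        lines = ["Flux balance analysis results", "=" * 33]
        lines.append(f"status:        {self.status}")
        lines.append(f"backend:       {self.backend}")
        for i, val in enumerate(self.stage_values):
            terms = " + ".join(
                (f"{w:g}*{rid}" if w != 1 else rid)
                for rid, w in self.objective_stages[i].items()
            ) if i < len(self.objective_stages) else "?"
            lines.append(f"stage {i + 1} max({terms}): {val:.6g}")
        if self.mu is not None:
            lines.append(f"growth rate mu [1/h]: {self.mu:.6g}")
        for role, v in self.named_fluxes.items():
            lines.append(f"{role:>20s}: {v: .6g} mmol/(g dw.h)")
        if self.status == "optimal":
            lines.append(f"steady-state residual |S.v|_inf: {self.residual:.3g}")
            lines.append(f"max bound violation:             {self.max_bound_violation:.3g}")
        if self.unbounded_support:
            lines.append("unbounded direction support: " + ", ".join(self.unbounded_support))
        return "\n".join(lines)


def _linprog_once(
    c_max: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
) -> tuple[str, Optional[np.ndarray], Optional[float]]:
    """Maximize c.v subject to A_eq v = b_eq, lb <= v <= ub via HiGHS."""
    res = linprog(
        -c_max,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 0:
        return "optimal", res.x, -res.fun
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 3:
        return "unbounded", None, None
    raise SolverError(f"LP solver failed: status {res.status}: {res.message}")


def _unbounded_support(
    c: np.ndarray, S: np.ndarray, lb: np.ndarray, ub: np.ndarray, rxn_ids: Sequence[str]
) -> list[str]:
    """Support of a ray d with S d = 0, c.d = 1, d respecting the recession cone."""
    n = len(c)
    d_lb = np.where(np.isfinite(lb), 0.0, -np.inf)
    d_ub = np.where(np.isfinite(ub), 0.0, np.inf)
    A_eq = np.vstack([S, c[None, :]])
    b_eq = np.concatenate([np.zeros(S.shape[0]), [1.0]])
    res = linprog(
        np.zeros(n), A_eq=A_eq, b_eq=b_eq,
        bounds=list(zip(d_lb, d_ub)), method="highs",
    )
    if res.status != 0 or res.x is None:
        return []
    return [rxn_ids[i] for i in np.flatnonzero(np.abs(res.x) > 1e-9)]


class FluxBalanceModel:
    """Flux balance model over a stoichiometric network.

    Parameters
    ----------
    network : StoichiometricNetwork
        The metabolic network.  Bounds need not be applied yet; the default
        :class:`BoundsPolicy` fills any gaps.
    objective : ObjectiveSpec
        Ordered maximization stages.  Defaults to maximizing the network's
        biomass role reaction.
    scenario : object, optional
        Anything exposing ``bound_overrides(network)`` (a
        :class:`~carbonfba.scenarios.FluxScenario`); its overrides replace
        default bounds before solving.
    bound_overrides : mapping, optional
        Additional reaction-id -> (lb, ub) overrides, applied last.
    method : {"lexicographic", "weighted"}
        How multi-stage objectives are combined.  "weighted" collapses the
        stages into a single weighted sum (sensitivity analysis only).
    tie_break : {None, "min_l1"}
        With "min_l1" the returned flux vector additionally minimizes
        ||v||_1 at the fixed stage optima, giving a reproducible vertex.
    """

    def __init__(
        self,
        network: StoichiometricNetwork,
        objective: Optional[ObjectiveSpec] = None,
        scenario=None,
        bound_overrides: Optional[Mapping[str, tuple[float, float]]] = None,
        bounds_policy: BoundsPolicy = BoundsPolicy(),
        method: str = "lexicographic",
        stage_weights: Optional[Sequence[float]] = None,
        tie_break: Optional[str] = None,
    ) -> None:
        if method not in ("lexicographic", "weighted"):
            raise ValueError("method must be 'lexicographic' or 'weighted'")
        if tie_break not in (None, "min_l1"):
            raise ValueError("tie_break must be None or 'min_l1'")
        overrides: dict[str, tuple[float, float]] = {}
        if scenario is not None:
            overrides.update(scenario.bound_overrides(network))
            if objective is None:
                objective = scenario.objective_spec(network)
        overrides.update(bound_overrides or {})
        if objective is None:
            biomass = network.role_reaction(ROLE_BIOMASS)
            if biomass is None:
                raise ValueError("no objective given and network names no biomass role")
            objective = ObjectiveSpec.maximize(biomass)
        objective.check_against(network)
        self.network = apply_bounds(network, bounds_policy, overrides)
        self.objective = objective
        self.method = method
        self.stage_weights = (
            None if stage_weights is None else np.asarray(stage_weights, dtype=float)
        )
        self.tie_break = tie_break
        self.S = build_stoichiometric_matrix(self.network)
        self.lb, self.ub = self.network.bounds_arrays()

    # ------------------------------------------------------------------
    def fit(self) -> FBAResult:
        """Solve the (staged) LP and return an :class:`FBAResult`."""
        n = len(self.network.reactions)
        rxn_ids = self.network.reaction_ids
        m = self.S.shape[0]

        if self.method == "weighted" and self.objective.n_stages > 1:
            w = (
                self.stage_weights
                if self.stage_weights is not None
                else np.ones(self.objective.n_stages)
            )
            c = sum(
                w[i] * self.objective.stage_vector(self.network, i)
                for i in range(self.objective.n_stages)
            )
            stages = [c]
        else:
            stages = [
                self.objective.stage_vector(self.network, i)
                for i in range(self.objective.n_stages)
            ]

        A_eq = self.S.copy()
        b_eq = np.zeros(m)
        stage_values: list[float] = []
        x = None
        for c in stages:
            status, x, val = _linprog_once(c, A_eq, b_eq, self.lb, self.ub)
            if status == "infeasible":
                return self._result("infeasible", stage_values)
            if status == "unbounded":
                support = _unbounded_support(c, self.S, self.lb, self.ub, rxn_ids)
                res = self._result("unbounded", stage_values)
                res.unbounded_support = support
                return res
            stage_values.append(float(val))
            # anchor this stage at its optimum (equality, not a relaxation)
            A_eq = np.vstack([A_eq, c[None, :]])
            b_eq = np.concatenate([b_eq, [val]])

        if self.tie_break == "min_l1":
            x = self._min_l1_vertex(A_eq, b_eq, x)

        return self._result("optimal", stage_values, x)

    # statsmodels-style alias
    optimize = fit

    def _min_l1_vertex(
        self, A_eq: np.ndarray, b_eq: np.ndarray, x0: np.ndarray
    ) -> np.ndarray:
        """Minimize ||v||_1 over the optimal face (deterministic tie-break)."""
        n = len(self.lb)
        big = np.maximum(np.abs(self.lb), np.abs(self.ub))
        # variables [v, t]; t_i >= |v_i|
        c = np.concatenate([np.zeros(n), np.ones(n)])
        A_eq2 = np.hstack([A_eq, np.zeros((A_eq.shape[0], n))])
        I = np.eye(n)
        A_ub = np.vstack([np.hstack([I, -I]), np.hstack([-I, -I])])
        b_ub = np.zeros(2 * n)
        bounds = list(zip(self.lb, self.ub)) + list(zip(np.zeros(n), big))
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq2, b_eq=b_eq,
                      bounds=bounds, method="highs")
        if res.status != 0 or res.x is None:  # keep the plain vertex on failure
            return x0
        return res.x[:n]

    def _result(
        self, status: str, stage_values: list[float], x: Optional[np.ndarray] = None
    ) -> FBAResult:
        result = FBAResult(
            status=status,
            stage_values=list(stage_values),
            objective_stages=self.objective.stages,
        )
        if x is None:
            return result
        rxn_ids = self.network.reaction_ids
        result.flux = {rid: float(v) for rid, v in zip(rxn_ids, x)}
        result.residual = float(np.max(np.abs(self.S @ x))) if self.S.size else 0.0
        result.max_bound_violation = float(
            max(np.max(self.lb - x, initial=0.0), np.max(x - self.ub, initial=0.0))
        )
        for role in (ROLE_BIOMASS, ROLE_LIGHT, ROLE_NITRATE, ROLE_MAINTENANCE, ROLE_CAROTENE):
            rid = self.network.role_reaction(role)
            if rid is not None:
                result.named_fluxes[role] = result.flux[rid]
        biomass = self.network.role_reaction(ROLE_BIOMASS)
        if biomass is not None:
            result.mu = result.flux[biomass]
        return result


# ---------------------------------------------------------------------------
# functional front ends


def solve_fba(
    network: StoichiometricNetwork,
    scenario=None,
    objective: Optional[ObjectiveSpec] = None,
    **kwargs,
) -> FBAResult:
    """Single-objective FBA (first/only stage of ``objective``)."""
    if objective is not None and objective.n_stages != 1:
        objective = ObjectiveSpec((objective.stages[0],))
    model = FluxBalanceModel(network, objective=objective, scenario=scenario, **kwargs)
    if model.objective.n_stages != 1:
        model.objective = ObjectiveSpec((model.objective.stages[0],))
    return model.fit()


def solve_lexicographic(
    network: StoichiometricNetwork,
    scenario=None,
    objective: Optional[ObjectiveSpec] = None,
    **kwargs,
) -> FBAResult:
    """Ordered multi-objective FBA; stage i+1 solved at stage i's optimum."""
    model = FluxBalanceModel(
        network, objective=objective, scenario=scenario, method="lexicographic", **kwargs
    )
    return model.fit()


# ---------------------------------------------------------------------------
# brute-force vertex enumeration oracle (test-only, <= 12 reactions)

MAX_ORACLE_REACTIONS = 12


@dataclass(frozen=True)
class OracleResult:
    status: str  # "optimal" | "infeasible"
    value: Optional[float]


def _independent_rows(S: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Row basis of S chosen by Gaussian elimination with partial pivoting."""
    A = S.astype(float).copy()
    m, n = A.shape
    rows: list[int] = []
    col = 0
    r = 0
    order = list(range(m))
    while r < m and col < n:
        piv = max(range(r, m), key=lambda i: abs(A[i, col]))
        if abs(A[piv, col]) <= tol:
            col += 1
            continue
        A[[r, piv]] = A[[piv, r]]
        order[r], order[piv] = order[piv], order[r]
        rows.append(order[r])
        A[r + 1:] -= np.outer(A[r + 1:, col] / A[r, col], A[r])
        r += 1
        col += 1
    return S[sorted(rows)] if rows else np.zeros((0, n))


def enumerate_vertices_oracle(
    network: StoichiometricNetwork,
    scenario=None,
    objective: Optional[ObjectiveSpec] = None,
    bound_overrides: Optional[Mapping[str, tuple[float, float]]] = None,
    tol: float = 1e-9,
) -> OracleResult:
    """Exhaustive basic-solution enumeration of {S.v = 0, lb <= v <= ub}.

    Every vertex of the box-bounded polytope has at least ``n - rank(S)``
    coordinates at a bound; the oracle tries all such active sets and
    returns the best feasible objective.  Intended as an independent check
    of the LP path on tiny instances only.
    """
    overrides: dict[str, tuple[float, float]] = {}
    if scenario is not None:
        overrides.update(scenario.bound_overrides(network))
        if objective is None:
            objective = scenario.objective_spec(network)
    overrides.update(bound_overrides or {})
    if objective is None:
        raise ValueError("oracle requires an explicit objective")
    net = apply_bounds(network, overrides=overrides)
    n = len(net.reactions)
    if n > MAX_ORACLE_REACTIONS:
        raise ValueError(
            f"oracle refuses instances with more than {MAX_ORACLE_REACTIONS} reactions "
            f"(got {n}); it is a test-only brute force"
        )
    S_full = build_stoichiometric_matrix(net)
    lb, ub = net.bounds_arrays()
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("oracle requires finite bounds")
    c = objective.stage_vector(net, 0)
    objective.check_against(net)

    R = _independent_rows(S_full)
    r = R.shape[0]
    best: Optional[float] = None
    cols = range(n)
    for basic in itertools.combinations(cols, r):
        B = list(basic)
        N = [j for j in cols if j not in basic]
        RB = R[:, B]
        if r and abs(np.linalg.det(RB)) <= tol:
            continue
        for picks in itertools.product((0, 1), repeat=len(N)):
            v = np.empty(n)
            for j, p in zip(N, picks):
                v[j] = lb[j] if p == 0 else ub[j]
            if r:
                rhs = -R[:, N] @ v[N] if N else np.zeros(r)
                v[B] = np.linalg.solve(RB, rhs)
            feas_tol = 1e-7 * max(1.0, np.max(np.abs(v)))
            if np.any(v < lb - feas_tol) or np.any(v > ub + feas_tol):
                continue
            if S_full.size and np.max(np.abs(S_full @ v)) > feas_tol:
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    if best is None:
        return OracleResult("infeasible", None)
    return OracleResult("optimal", best)
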