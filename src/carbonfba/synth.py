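"""Synthetic networks with known optima.

Two generators back the test surface when the full organism model is not
at hand:

* :func:`make_toy_phototroph` builds a minimal three-compartment
  photoautotroph — photon capture in the chloroplast, nitrate assimilation
  in the cytosol, a maintenance-ATP drain in the mitochondrion, a biomass
  drain and a secondary-carotenoid branch — whose single- and two-stage
  FBA optima have closed forms.
* :func:`make_random_network` draws sparse random stoichiometries with
  small integer coefficients, always feasible (every bound interval
  contains zero), for property tests against the vertex-enumeration
  oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    ROLE_BIOMASS,
    ROLE_CAROTENE,
    ROLE_LIGHT,
    ROLE_MAINTENANCE,
    ROLE_NITRATE,
    Compartment,
    Metabolite,
    Reaction,
    ReactionKind,
    StoichiometricNetwork,
)

__all__ = ["PhototrophParams", "ToyClosedForm", "make_toy_phototroph", "make_random_network"]

#: generous cap for unconstrained internal fluxes of the toy (the intended
#: constraints are the uptake caps and the maintenance drain)
_WIDE = 1.0e4


@dataclass(frozen=True)
class PhototrophParams:
    """Stoichiometric parameters of the toy photoautotroph.

    All quantities are per gram dry weight.  Defaults are sized to a green
    microalga growing photoautotrophically: ~5.6 mmol N and ~35 mmol C per
    g dw of biomass, ~85 mmol ATP-equivalents per g dw of growth demand,
    8 photons per ATP-equivalent (y_E = 0.125), and uptake caps matching
    the low-light, nutrient-replete condition (photons 320, nitrate
    0.19 mmol/(g dw . h)) with a 0.92 mmol/(g dw . h) maintenance drain.

    n_N : mmol nitrate per g dw biomass
    n_C : mmol CO2-derived carbon per g dw biomass
    n_E : mmol ATP-equivalents per g dw biomass
    y_E : ATP-equivalents formed per photon
    m_ATP : maintenance drain, mmol/(g dw . h)
    k_car : ATP-equivalents per mmol carotene
    k_car_c : mmol carbon per mmol carotene
    v_light_max, v_N_max : uptake caps, mmol/(g dw . h)
    """

    n_N: float = 5.6
    n_C: float = 35.0
    n_E: float = 85.0
    y_E: float = 0.125
    m_ATP: float = 0.92
    k_car: float = 50.0
    k_car_c: float = 40.0
    v_light_max: float = 320.0
    v_N_max: float = 0.19

    def __post_init__(self) -> None:
        for name in ("n_N", "n_C", "n_E", "y_E", "m_ATP", "k_car", "k_car_c",
                     "v_light_max", "v_N_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"phototroph parameter {name} must be strictly positive")


@dataclass(frozen=True)
class ToyClosedForm:
    """Analytic optima of the toy phototroph.

    With photon cap L and nitrate cap N, the energy balance gives
    y_E*L = m_ATP + n_E*mu + k_car*car, the nitrogen balance N = n_N*mu,
    hence::

        mu*  = min(N / n_N, (y_E*L - m_ATP) / n_E)
        car* = max(0, (y_E*L - m_ATP - n_E*mu*) / k_car)   at fixed mu*

    car* applies to the two-stage objective; maximizing growth alone
    leaves the carotene branch at zero.  If y_E*L < m_ATP the maintenance
    drain cannot be met and the scenario is infeasible (mu* is None).
    """

    params: PhototrophParams

    def available_energy(self, light: Optional[float] = None) -> float:
        p = self.params
        L = p.v_light_max if light is None else light
        return p.y_E * L - p.m_ATP

    def mu_star(self, light: Optional[float] = None,
                nitrate: Optional[float] = None) -> Optional[float]:
        p = self.params
        N = p.v_N_max if nitrate is None else nitrate
        e = self.available_energy(light)
        if e < 0:
            return None
        return min(N / p.n_N, e / p.n_E)

    def car_star(self, light: Optional[float] = None,
                 nitrate: Optional[float] = None) -> Optional[float]:
        mu = self.mu_star(light, nitrate)
        if mu is None:
            return None
        p = self.params
        return max(0.0, (self.available_energy(light) - p.n_E * mu) / p.k_car)

    def __call__(self, light: Optional[float] = None,
                 nitrate: Optional[float] = None) -> tuple[Optional[float], Optional[float]]:
        return self.mu_star(light, nitrate), self.car_star(light, nitrate)


def make_toy_phototroph(
    params: PhototrophParams = PhototrophParams(),
) -> tuple[StoichiometricNetwork, ToyClosedForm]:
    """Build the 12-reaction, three-compartment toy phototroph.

    Photons enter the chloroplast (Ex01) and are converted to
    ATP-equivalents; nitrate enters the cytosol (Ex06) and is assimilated;
    CO2 enters the chloroplast and is fixed to organic carbon; ATP shuttles
    to the cytosol and mitochondrion, where the maintenance drain (R192) is
    equality-fixed; biomass (mu) drains nitrogen, carbon and energy; the
    carotene branch converts energy and carbon into a pigment exported by
    the Car14 sink.  The CO2 cap is wide so carbon never limits and the
    closed forms in :class:`ToyClosedForm` hold exactly.
    """
    p = params
    c, h, m = Compartment.CYTOSOL, Compartment.CHLOROPLAST, Compartment.MITOCHONDRION
    mets = [
        Metabolite("photon_h", "photon", h),
        Metabolite("atp_h", "ATP-equivalent (chloroplast)", h),
        Metabolite("atp_c", "ATP-equivalent (cytosol)", c),
        Metabolite("atp_m", "ATP-equivalent (mitochondrion)", m),
        Metabolite("no3_c", "nitrate", c),
        Metabolite("norg_c", "organic nitrogen", c),
        Metabolite("co2_h", "CO2", h),
        Metabolite("corg_h", "fixed organic carbon", h),
        Metabolite("car_c", "beta-carotene", c),
    ]
    rxns = [
        Reaction("Ex01", {"photon_h": 1.0}, name="photon uptake",
                 kind=ReactionKind.EXCHANGE, lower_bound=0.0, upper_bound=p.v_light_max),
        Reaction("Ex06", {"no3_c": 1.0}, name="nitrate uptake",
                 kind=ReactionKind.EXCHANGE, lower_bound=0.0, upper_bound=p.v_N_max),
        Reaction("Ex02", {"co2_h": 1.0}, name="CO2 uptake",
                 kind=ReactionKind.EXCHANGE, lower_bound=0.0, upper_bound=_WIDE),
        Reaction("R_light", {"photon_h": -1.0, "atp_h": p.y_E},
                 name="photon capture", lower_bound=0.0, upper_bound=_WIDE),
        Reaction("R_cfix", {"co2_h": -1.0, "corg_h": 1.0},
                 name="carbon fixation", lower_bound=0.0, upper_bound=_WIDE),
        Reaction("R_nassim", {"no3_c": -1.0, "norg_c": 1.0},
                 name="nitrate assimilation", lower_bound=0.0, upper_bound=_WIDE),
        Reaction("T_atp_ch", {"atp_h": -1.0, "atp_c": 1.0}, reversible=True,
                 name="ATP shuttle chloroplast/cytosol", kind=ReactionKind.TRANSPORT,
                 lower_bound=-_WIDE, upper_bound=_WIDE),
        Reaction("T_atp_cm", {"atp_c": -1.0, "atp_m": 1.0}, reversible=True,
                 name="ATP shuttle cytosol/mitochondrion", kind=ReactionKind.TRANSPORT,
                 lower_bound=-_WIDE, upper_bound=_WIDE),
        Reaction("R192", {"atp_m": -1.0}, name="maintenance ATP drain",
                 kind=ReactionKind.MAINTENANCE,
                 lower_bound=p.m_ATP, upper_bound=p.m_ATP),
        Reaction("mu", {"norg_c": -p.n_N, "corg_h": -p.n_C, "atp_c": -p.n_E},
                 name="biomass formation", kind=ReactionKind.BIOMASS,
                 lower_bound=0.0, upper_bound=_WIDE),
        Reaction("R_car", {"atp_c": -p.k_car, "corg_h": -p.k_car_c, "car_c": 1.0},
                 name="carotene synthesis", lower_bound=0.0, upper_bound=_WIDE),
        Reaction("Car14", {"car_c": -1.0}, name="carotene sink",
                 kind=ReactionKind.EXCHANGE, lower_bound=0.0, upper_bound=_WIDE),
    ]
    net = StoichiometricNetwork(
        mets,
        rxns,
        named_roles={
            ROLE_BIOMASS: "mu",
            ROLE_LIGHT: "Ex01",
            ROLE_NITRATE: "Ex06",
            ROLE_MAINTENANCE: "R192",
            ROLE_CAROTENE: "Car14",
        },
        name="toy_phototroph",
    )
    return net, ToyClosedForm(p)


_COMPARTMENT_CYCLE = (Compartment.CYTOSOL, Compartment.CHLOROPLAST, Compartment.MITOCHONDRION)


def make_random_network(
    seed: int,
    n_metabolites: int = 4,
    n_reactions: int = 6,
    p_reversible: float = 0.4,
    max_bound: float = 10.0,
) -> StoichiometricNetwork:
    """Sparse random network, reproducible per seed, always feasible.

    Coefficients are drawn from {-2, -1, +1, +2}; every reaction touches
    one to three metabolites; bounds are (0, U) or (-U, U) with U drawn in
    (1, max_bound], so the zero vector is always feasible.
    """
    if n_metabolites < 1 or n_reactions < 1:
        raise ValueError("sizes must be >= 1")
    if not 0.0 <= p_reversible <= 1.0:
        raise ValueError("p_reversible must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mets = [
        Metabolite(f"M{i + 1}", compartment=_COMPARTMENT_CYCLE[i % 3])
        for i in range(n_metabolites)
    ]
    rxns = []
    for j in range(n_reactions):
        k = int(rng.integers(1, min(3, n_metabolites) + 1))
        members = rng.choice(n_metabolites, size=k, replace=False)
        stoich = {
            f"M{i + 1}": float(rng.choice([-2, -1, 1, 2])) for i in members
        }
        reversible = bool(rng.random() < p_reversible)
        U = float(np.round(rng.uniform(1.0, max_bound), 3))
        rxns.append(
            Reaction(
                f"R{j + 1}",
                stoich,
                reversible=reversible,
                lower_bound=-U if reversible else 0.0,
                upper_bound=U,
            )
        )
    return StoichiometricNetwork(mets, rxns, name=f"random_{seed}")
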