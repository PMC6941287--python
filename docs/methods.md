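# Methods

## Model

`carbonfba` analyses compartmentalized stoichiometric networks of the kind
used for the carbon-core metabolism of the halophilic green microalga
*Dunaliella salina*: metabolites assigned to cytosol, chloroplast or
mitochondrion (plus an external boundary), reactions with signed
stoichiometric coefficients (negative = consumed), and flux bounds in
mmol/(g dw · h).

Flux balance analysis solves the linear program

    max  c·v
    s.t. S·v = 0,  lb ≤ v ≤ ub

where `S` is the stoichiometric matrix over *balanced* (non-external)
metabolites, so exchange reactions appear as single-sided, unbalanced
columns; a positive exchange flux means uptake. The biomass pseudo-reaction
μ drains precursors in measured proportions scaled so that one unit of flux
produces 1 g dry weight; its flux is therefore read as the specific growth
rate in 1/h while every other flux is in mmol/(g dw · h).

### Combined objectives

The combined objective max(μ, Car14) — maximize growth, then β-carotene
export — is implemented *lexicographically*: stage 1 maximizes μ; stage 2
maximizes Car14 with μ anchored at its optimum by an equality row
(`c₁·v = μ*`), not by a relaxed inequality, so no extra tolerance parameter
is introduced. The lexicographic reading is the one consistent with growth
rates being identical between the single-objective and combined-objective
scenario families; a weighted-sum mode (`method="weighted"`) is available
for sensitivity analysis only.

The contract of an optimization is the stage optimum values and the named
role fluxes. The returned flux vector is one vertex of a possibly
non-unique optimal face and depends on solver pivoting; a deterministic
minimum-‖v‖₁ tie-break over the optimal face is available via
`tie_break="min_l1"` when a reproducible flux map matters.

### Solver

The LP backend is HiGHS through `scipy.optimize.linprog`. LPs are
deterministic, so nothing is seeded. Statuses optimal / infeasible /
unbounded are passed through; any other solver status raises a distinct
`SolverError` so numerical failure is never conflated with genuine
infeasibility. For an unbounded objective the support of an unbounded ray
is recovered from a secondary LP over the recession cone.

## Bounds and scenarios

Reactions without explicit bounds receive the defaults 0–100 mmol/(g dw · h)
(irreversible) and −100–100 (reversible); explicit overrides replace
defaults, and a fixed flux is expressed as `lb = ub`.

The eight canonical scenarios combine photon uptake (Ex01 role) of 320
(low light) or 800 (high light) with nitrate uptake (Ex06 role) of 0.19
(replete) or 0.001 (depleted) mmol/(g dw · h); the maintenance-ATP drain
(R192 role) is equality-fixed at 0.92 mmol/(g dw · h) in all of them.
Scenarios A–D maximize μ alone; E–H use the staged max(μ, Car14).
Light and nitrate are *capped* (0 ≤ v ≤ value) by default, since they are
stated as maximal rates; under maximization the cap binds whenever the
resource limits, so capped and equality-fixed modes give the same optimum
where it matters, and `bound_mode="fixed"` is provided for the equality
reading.

## Numerical choices

- Feasibility: phase-1 LP; a witness flux must satisfy |S·v| ≤ 1e−9 ·
  max(1, ‖v‖∞) per row and bounds to 1e−9.
- Infeasibility diagnosis: greedy one-at-a-time relaxation — a reaction's
  bounds are implicated if fully relaxing them alone restores feasibility.
  This is simple and solver-independent; it is not an exact irreducible
  infeasible subsystem (constraints that only jointly cause infeasibility
  are not resolved further).
- Blocked reactions: per-reaction flux variability; blocked iff both the
  maximal and minimal achievable flux are ≤ 1e−9 in magnitude.
- Optimal results report the steady-state residual (required ≤ 1e−6) and
  the maximum bound violation (required ≤ 1e−9).
- Degenerate inputs: a network with no reactions is valid and trivially
  feasible; all-zero bound boxes give the zero optimum; equality-fixed
  fluxes are ordinary bounds with lb = ub.

## The vertex-enumeration oracle

`enumerate_vertices_oracle` is an independent verification route for tiny
instances (≤ 12 reactions, finite bounds): every vertex of
{S·v = 0, lb ≤ v ≤ ub} has at least n − rank(S) coordinates at a bound, so
the oracle enumerates all basic-column subsets and all lower/upper
assignments of the non-basic coordinates, solves the resulting square
systems exactly, filters by feasibility and returns the best objective.
It shares no code with the LP path and must agree with it to 1e−6; the
test suite checks this on over a hundred random networks.

## Synthetic networks

### Toy phototroph

`make_toy_phototroph` builds a 12-reaction, three-compartment skeleton of
photoautotrophic growth: photon uptake and conversion to ATP-equivalents in
the chloroplast, nitrate uptake and assimilation in the cytosol, CO₂
fixation, ATP shuttles into cytosol and mitochondrion, an equality-fixed
maintenance drain, a biomass drain and a carotene branch with an export
sink. Energy and nitrogen balances give closed-form optima

    μ*   = min( v_N_max / n_N , (y_E·v_light_max − m_ATP) / n_E )
    Car* = max( 0, (y_E·v_light_max − m_ATP − n_E·μ*) / k_car )

with Car* attained only by the staged objective; growth maximization alone
leaves the carotene branch at zero because it only consumes resources.

Default parameters are sized to a green microalga under the low-light,
nutrient-replete condition: n_N = 5.6 mmol N/g dw and n_C = 35 mmol C/g dw
(roughly 8 % nitrogen and 42 % carbon by weight), n_E = 85 mmol
ATP-equivalents/g dw growth demand, y_E = 0.125 ATP per photon (≈ 8 photons
per ATP-equivalent), k_car = 50 ATP and k_car_c = 40 C per mmol carotene,
maintenance 0.92 and uptake caps 320 (photons) and 0.19 (nitrate)
mmol/(g dw · h). The CO₂ exchange cap is set wide (10⁴) so carbon never
limits and the closed forms hold exactly.

What the toy emulates: the resource logic behind the scenario tables —
nitrogen-limited growth, an energy budget split between maintenance, growth
and pigment, and the carotene branch acting as a sink for excess captured
light. What it does not emulate: real pathway structure (a single lumped
energy currency instead of ATP/NAD(P)H, no photorespiration, no
photoinhibition or light attenuation, no glycerol cycle, no TAG branch) and
realistic internal flux magnitudes. Passing tests on the toy therefore
validate the optimization machinery and the qualitative scenario logic, not
quantitative predictions for the real organism; those require the published
221-reaction network.

### Random networks

`make_random_network` draws sparse stoichiometries with coefficients in
{±1, ±2} (small integers keep the oracle's square solves well-conditioned),
1–3 participants per reaction, and bound boxes that always contain zero, so
every generated instance is feasible. Seeds are explicit everywhere; there
is no global random state.

Randomized sweeps in the tests sample toy parameters from ranges chosen to
keep the instance well-posed: maintenance below 90 % of the photon energy
supply (otherwise the scenario is correctly infeasible) and carotene/carbon
coefficients such that the wide CO₂ cap never binds.

## I/O conventions

SBML is written as Level 3 Version 1 with fbc-v2 flux-bound parameters and
deterministic element order (two writes are byte-identical). On reading,
both fbc bounds and legacy kinetic-law LOWER_BOUND/UPPER_BOUND parameters
are accepted; explicit boundary species (`boundaryCondition="true"` or an
external compartment) are normalized away so exchanges become single-sided
columns. Arbitrary metabolite/reaction ids (e.g. `glc[c]`) survive the
SBML id restrictions through a reversible character encoding. EC numbers,
KEGG ids, reaction kinds and the named roles (biomass, light, nitrate,
maintenance, carotene sink) round-trip through structured notes.

Reaction tables are delimited text (comma/tab/semicolon auto-detected) with
at least an id and an equation column; equations use `+`-separated terms,
optional numeric coefficients, bracket compartment tags and `->` / `<=>`
arrows. Scenario tables are written with scenarios as columns and numeric
cells at 4 decimal places, matching the precision of the published tables;
comparisons always use full precision.

## Known limitations

- Gene–protein–reaction associations are carried as opaque annotations,
  never evaluated; no thermodynamic constraints.
- The infeasibility diagnosis is greedy, not an exact IIS.
- The oracle requires finite bounds and refuses instances over 12
  reactions by design.
- The problem sizes used in the self-verification sweeps (100 random
  networks for the oracle and round-trip checks, 200 toy parameter sets)
  are the package's standard verification workload; they complete in a few
  seconds.
- Quantitative reproduction of the published scenario tables requires the
  published SBML network placed at `data/dunaliella_carbon_core.sbml`; it
  is not redistributed with this package.
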