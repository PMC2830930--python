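"""Mass-balance-only flux analyses: FBA, FVA classification, duals, trade-offs.

All optimization goes through the HiGHS linear-programming solver behind
``scipy.optimize.linprog``.  The FBA problem is

    max  c'v   s.t.  N v = 0,  lb <= v <= ub

with c selecting the biomass (or any other) reaction.  Flux variability
analysis fixes the objective at its optimum and computes per-reaction flux
ranges, classifying each reaction as essential (its interval excludes
zero), blocked (interval within +/- epsilon of zero) or substitutable.
Shadow prices are the duals of the metabolite mass-balance rows in the
maximization orientation (negative = limiting, matching the convention of
the field's FBA toolchains); reduced costs are the duals of the flux
bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .formulas import parse_formula
from .model import MetabolicModel

__all__ = [
    "FluxSolution",
    "FvaClassification",
    "SensitivityReport",
    "TradeoffCurve",
    "fba",
    "fva_classify",
    "growth_yield",
    "secretion_profile",
    "sensitivity",
    "tradeoff_scan",
]

MASS_BALANCE_TOL = 1e-6
FVA_EPSILON = 1e-9
OBJECTIVE_FIX_SCALE = 1e-9


@dataclass
class FluxSolution:
    objective_id: str
    objective_value: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded
    shadow_prices: dict[str, float] = field(default_factory=dict)
    reduced_costs: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FvaClassification:
    labels: dict[str, str]  # essential | substitutable | blocked
    ranges: dict[str, tuple[float, float]]
    failures: dict[str, str] = field(default_factory=dict)

    def of_class(self, label: str) -> list[str]:
        return sorted(r for r, l in self.labels.items() if l == label)


@dataclass
class SensitivityReport:
    shadow_prices: dict[str, float]
    reduced_costs: dict[str, float]
    basis_caveat: bool = False


@dataclass
class TradeoffCurve:
    biomass: list[float]
    uptake: list[float]  # |exchange flux| at each grid point
    status: list[str]
    mode: str  # maximize | minimize

    def feasible_points(self) -> list[tuple[float, float]]:
        return [(b, u) for b, u, s in zip(self.biomass, self.uptake, self.status) if s == "optimal"]


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve(
    model: MetabolicModel,
    objective: Mapping[str, float],
    sense: str,
    bound_overrides: Optional[Mapping[str, tuple[float, float]]] = None,
    want_duals: bool = False,
) -> FluxSolution:
    N, met_ids, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays(rxn_ids)
    if bound_overrides:
        for rid, (lo, hi) in bound_overrides.items():
            j = rxn_ids.index(rid)
            lb[j], ub[j] = lo, hi
    c = np.zeros(len(rxn_ids))
    for rid, coeff in objective.items():
        c[rxn_ids.index(rid)] = coeff
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=N,
        b_eq=np.zeros(N.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _STATUS.get(res.status, "infeasible")
    obj_id = max(objective, key=lambda r: abs(objective[r]))
    if status != "optimal":
        return FluxSolution(obj_id, 0.0, {}, status)
    fluxes = dict(zip(rxn_ids, res.x))
    value = float(c @ res.x)
    solution = FluxSolution(obj_id, value, fluxes, "optimal")
    if want_duals:
        # linprog minimizes sign*c with marginals d(min obj)/d(b).  The
        # reported price is d(objective)/d(net production b_i) in the
        # problem's own orientation, so a limiting nutrient (which the cell
        # wants to consume, b_i < 0) prices negative under maximization.
        marg = np.asarray(res.eqlin.marginals)
        solution.shadow_prices = dict(zip(met_ids, sign * marg))
        red = np.asarray(res.lower.marginals) + np.asarray(res.upper.marginals)
        solution.reduced_costs = dict(zip(rxn_ids, sign * red))
    return solution


def fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: str = "max",
    want_duals: bool = True,
) -> FluxSolution:
    """Optimize one reaction's flux subject to N v = 0 and the bounds.

    Infeasible and unbounded problems are reported in ``status`` (objective
    value 0), never raised.  The optimal flux vector satisfies
    ``|N v| <= 1e-6`` per metabolite.
    """
    objective = objective or model.biomass_reaction_id
    if objective not in model.reactions:
        raise LookupError(f"objective reaction {objective!r} not in model")
    return _solve(model, {objective: 1.0}, sense, want_duals=want_duals)


def growth_yield(solution: FluxSolution, exchange_id: str, biomass_id: Optional[str] = None) -> Optional[float]:
    """Biomass produced per mmol of substrate taken up (g biomass/mmol).

    Zero biomass yields 0; zero uptake with nonzero biomass is undefined
    and returns ``None``.
    """
    biomass_flux = solution.objective_value if biomass_id is None else solution.fluxes.get(biomass_id, 0.0)
    uptake = solution.fluxes.get(exchange_id, 0.0)
    if biomass_flux <= MASS_BALANCE_TOL:
        return 0.0
    if uptake >= -MASS_BALANCE_TOL:
        return None
    return biomass_flux / abs(uptake)


def _objective_fix_bounds(opt: float) -> tuple[float, float]:
    """Near-equality window around the optimum, scaled to dodge round-off."""
    slack = abs(opt) * OBJECTIVE_FIX_SCALE + 1e-12
    return (opt - slack, opt + slack)


def fva_classify(
    model: MetabolicModel,
    objective: Optional[str] = None,
    epsilon: float = FVA_EPSILON,
    reactions: Optional[Iterable[str]] = None,
) -> FvaClassification:
    """Flux ranges at the fixed optimal objective, with a three-way labeling.

    essential: the flux interval excludes zero (the reaction must run);
    blocked: the interval lies within [-epsilon, epsilon];
    substitutable: anything else.
    """
    objective = objective or model.biomass_reaction_id
    base = fba(model, objective, want_duals=False)
    if not base.optimal:
        raise RuntimeError(f"FVA requires an optimal base solution (got {base.status})")
    fix = {objective: _objective_fix_bounds(base.objective_value)}
    rxn_ids = sorted(reactions) if reactions is not None else sorted(model.reactions)

    labels, ranges, failures = {}, {}, {}
    for rid in rxn_ids:
        lo_sol = _solve(model, {rid: 1.0}, "min", bound_overrides=fix)
        hi_sol = _solve(model, {rid: 1.0}, "max", bound_overrides=fix)
        if not (lo_sol.optimal and hi_sol.optimal):
            failures[rid] = f"min:{lo_sol.status} max:{hi_sol.status}"
            continue
        lo, hi = lo_sol.objective_value, hi_sol.objective_value
        ranges[rid] = (lo, hi)
        if lo > epsilon or hi < -epsilon:
            labels[rid] = "essential"
        elif abs(lo) <= epsilon and abs(hi) <= epsilon:
            labels[rid] = "blocked"
        else:
            labels[rid] = "substitutable"
    return FvaClassification(labels, ranges, failures)


def sensitivity(
    model: MetabolicModel,
    solution: Optional[FluxSolution] = None,
    degeneracy_check: bool = True,
    tol: float = 1e-6,
) -> SensitivityReport:
    """Shadow prices and reduced costs at the FBA optimum.

    When the optimum is dual-degenerate (alternative optimal bases exist,
    detected as any nonzero objective-fixed FVA width), the duals are still
    reported from the returned basis but ``basis_caveat`` is set: only
    their signs and ordering are then meaningful.
    """
    if solution is None or not solution.shadow_prices:
        solution = fba(model, want_duals=True)
    if not solution.optimal:
        raise RuntimeError("sensitivity requires an optimal solution")
    caveat = False
    if degeneracy_check:
        fva = fva_classify(model)
        caveat = any(hi - lo > tol for lo, hi in fva.ranges.values())
    return SensitivityReport(
        shadow_prices=dict(solution.shadow_prices),
        reduced_costs=dict(solution.reduced_costs),
        basis_caveat=caveat,
    )


def tradeoff_scan(
    model: MetabolicModel,
    biomass_grid: Sequence[float],
    uptake_exchange: str,
    mode: str = "maximize",
    objective: Optional[str] = None,
) -> TradeoffCurve:
    """Optimal substrate uptake at each fixed biomass value.

    ``maximize`` finds the largest uptake the network can absorb at that
    growth rate (bioremediation capacity); ``minimize`` the smallest uptake
    that still sustains it (substrate efficiency).  Uptake is reported as a
    magnitude.  Infeasible grid points are flagged in ``status``.
    """
    if mode not in ("maximize", "minimize"):
        raise ValueError("mode must be 'maximize' or 'minimize'")
    objective = objective or model.biomass_reaction_id
    if uptake_exchange not in model.reactions:
        raise LookupError(f"exchange {uptake_exchange!r} not in model")
    biomass, uptake, status = [], [], []
    for b in biomass_grid:
        fix = {objective: (b, b)}
        sense = "min" if mode == "maximize" else "max"  # uptake flux is negative
        sol = _solve(model, {uptake_exchange: 1.0}, sense, bound_overrides=fix)
        biomass.append(float(b))
        status.append(sol.status)
        uptake.append(abs(sol.objective_value) if sol.optimal else math.nan)
    return TradeoffCurve(biomass, uptake, status, mode)


def secretion_profile(
    solution: FluxSolution,
    model: MetabolicModel,
    exclude: Iterable[str] = ("co2", "hco3"),
    tol: float = 1e-6,
) -> list[str]:
    """Carbon compounds excreted at this solution, minus common by-products.

    Returns the exchange reaction ids with positive flux whose metabolite
    contains carbon and is not in the excluded set (default: CO2 and
    bicarbonate).
    """
    exclude = {e.lower() for e in exclude}
    out = []
    for ex_id in model.exchange_reaction_ids:
        flux = solution.fluxes.get(ex_id, 0.0)
        if flux <= tol:
            continue
        met_id = next(iter(model.reactions[ex_id].stoich))
        met = model.metabolites[met_id]
        base = met_id.rsplit("_", 1)[0].lower()
        if base in exclude:
            continue
        if parse_formula(met.formula).get("C", 0) > 0:
            out.append(ex_id)
    return sorted(out)
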