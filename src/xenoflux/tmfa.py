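"""Thermodynamics-based metabolic flux analysis (TMFA).

Mass-balance constraints are augmented with second-law constraints in a
mixed-integer linear program.  Every reaction is split into non-negative
forward/backward directions, each gated by a binary indicator z:

    v_dir <= v_max,dir * z_dir
    dG'_dir <= M * (1 - z_dir)          (reactions with an energy estimate)
    z_fwd + z_bwd <= 1

with the realized reaction energy

    dG'_dir = +/- ( drGm + s + RT * sum_j nu_j (ln a_j - ln a_ref,j) )

where the ln-activity variables a_j range over physiological bounds
(default 1e-5 - 0.02 M; gases bounded by saturation; CO2 1e-4 - 1.4e-3 M;
the xenobiotic and its dihydrodiol 8e-7 - 0.025 M), protons and water
carry no concentration term, and the slack s absorbs up to three standard
errors of the group-contribution estimate.  A reaction can therefore only
carry flux in a direction made exergonic by some admissible activity
profile; reactions with no energy estimate keep their direction binaries
but no energy row.

Solutions are checked by an independent post-hoc validator (mass balance,
bounds, and the second law recomputed from the returned activities), not
trusted from the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .analysis import FvaClassification
from .model import MetabolicModel
from .pathways import Pathway
from .thermo import (
    DEFAULT_REFERENCE_M,
    H2_SATURATION_M,
    O2_SATURATION_M,
    PROTON_WATER,
    RT,
    ReactionEnergy,
)

__all__ = [
    "ThermoConstraintSet",
    "TmfaProblem",
    "TmfaSolution",
    "build_tmfa_problem",
    "default_activity_bounds",
    "reaction_energies_for_model",
    "screen_feasible_pathways",
    "tmfa_fva_classify",
    "tmfa_optimize",
    "validate_solution",
]

BIG_M = 1000.0  # kcal/mol, safely above any |drGm| + concentration swing
DEFAULT_ACTIVITY = (1e-5, 0.02)
CO2_ACTIVITY = (1e-4, 1.4e-3)
GAS_LOWER = 1e-8
EXPANDED_ACTIVITY = (8e-7, 0.025)
FLUX_TOL = 1e-6
DG_TOL = 1e-6


class ThermoConfigError(ValueError):
    """A species participating in an energy constraint lacks activity bounds."""


@dataclass
class ThermoConstraintSet:
    """Per-reaction energies plus per-species activity bounds (molar)."""

    reaction_energies: Mapping[str, ReactionEnergy]
    activity_bounds: Mapping[str, tuple[float, float]]
    reference_activities: Mapping[str, Optional[float]] = field(default_factory=dict)
    slack_sigmas: float = 3.0
    big_M: float = BIG_M

    def __post_init__(self):
        for species, (lo, hi) in self.activity_bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"bad activity bounds for {species}: [{lo}, {hi}]")
        if self.slack_sigmas < 0:
            raise ValueError("slack half-width must be >= 0")

    def reference_activity(self, species: str) -> Optional[float]:
        if species in PROTON_WATER:
            return None
        return self.reference_activities.get(species, DEFAULT_REFERENCE_M)


def reaction_energies_for_model(
    model: MetabolicModel,
    compound_energies: Mapping,
    overrides: Optional[Mapping[str, ReactionEnergy]] = None,
) -> dict[str, ReactionEnergy]:
    """Per-reaction ΔrG'^m for every model reaction from a compound table.

    Exchange and balance-exempt reactions, and any reaction with a species
    missing from the table, are flagged ``no_estimate``.  ``overrides``
    supplies precomputed energies (e.g. for augmented degradation steps
    whose energies were derived on the rule-network side).
    """
    from .thermo import reaction_dGm

    out: dict[str, ReactionEnergy] = {}
    overrides = dict(overrides or {})
    for rid, rxn in model.reactions.items():
        if rid in overrides:
            out[rid] = overrides[rid]
            continue
        if rxn.is_exchange or rxn.balance_exempt:
            out[rid] = ReactionEnergy(rid, None, 0.0, frozenset({"no_estimate"}))
            continue
        out[rid] = reaction_dGm(rid, rxn.stoich, compound_energies)
    return out


def default_activity_bounds(
    model: MetabolicModel,
    xenobiotic_ids: Iterable[str] = (),
    fixed_extracellular: Optional[Mapping[str, float]] = None,
    expanded: bool = True,
) -> dict[str, tuple[float, float]]:
    """Physiological activity windows for every model metabolite.

    ``xenobiotic_ids`` (the seed compound and its dihydrodiol) get the
    expanded window needed to drive the uphill first dioxygenation step;
    per the study design the expansion, once triggered, applies to all
    calculations.  ``fixed_extracellular`` pins medium species to their
    in-silico M9 concentrations (point intervals).
    """
    bounds: dict[str, tuple[float, float]] = {}
    xeno = set(xenobiotic_ids)
    for met in model.metabolites.values():
        base = met.id.rsplit("_", 1)[0].lower()
        if met.id in xeno and expanded:
            bounds[met.id] = EXPANDED_ACTIVITY
        elif base == "o2":
            bounds[met.id] = (GAS_LOWER, O2_SATURATION_M)
        elif base == "h2":
            bounds[met.id] = (GAS_LOWER, H2_SATURATION_M)
        elif base == "co2":
            bounds[met.id] = CO2_ACTIVITY
        else:
            bounds[met.id] = DEFAULT_ACTIVITY
    for species, value in (fixed_extracellular or {}).items():
        bounds[species] = (value, value)
    return bounds


@dataclass
class _Directed:
    rxn_id: str
    forward: bool
    cap: float
    has_energy: bool
    k_const: float = 0.0  # drGm - RT*sum(nu*ln a_ref), forward orientation


@dataclass
class TmfaProblem:
    model: MetabolicModel
    thermo: ThermoConstraintSet
    directed: list[_Directed]
    ln_species: list[str]
    slack_rxns: list[str]
    rxn_ids: list[str]
    met_ids: list[str]

    @property
    def n_directed(self) -> int:
        return len(self.directed)

    def var_layout(self) -> tuple[int, int, int, int]:
        """Offsets of (v, z, ln_a, slack) variable blocks."""
        nd, ns, ne = len(self.directed), len(self.ln_species), len(self.slack_rxns)
        return 0, nd, 2 * nd, 2 * nd + ns

    @property
    def n_vars(self) -> int:
        return 2 * len(self.directed) + len(self.ln_species) + len(self.slack_rxns)

    def variable_names(self) -> list[str]:
        names = []
        for d in self.directed:
            names.append(f"v_{d.rxn_id}_{'f' if d.forward else 'b'}")
        for d in self.directed:
            names.append(f"z_{d.rxn_id}_{'f' if d.forward else 'b'}")
        names += [f"ln_{s}" for s in self.ln_species]
        names += [f"s_{r}" for r in self.slack_rxns]
        return names

    def to_lp_string(self, objective: Optional[str] = None) -> str:
        """CPLEX-LP-format text of the MILP for external-solver audit."""
        objective = objective or self.model.biomass_reaction_id
        A_eq, A_ub, b_ub, lb, ub, integrality, *_ = _assemble(self)
        names = self.variable_names()
        c = _net_objective(self, objective)

        def terms(row):
            sparse = sp.issparse(row)
            cols = row.nonzero()[1] if sparse else np.nonzero(row)[0]
            out = []
            for j in cols:
                coeff = row[0, j] if sparse else row[j]
                out.append(f"{'+' if coeff >= 0 else '-'} {abs(coeff):.12g} {names[j]}")
            return " ".join(out) or "0 " + names[0]

        lines = ["Maximize", " obj: " + terms(c), "Subject To"]
        A_eq = A_eq.tocsr()
        for i in range(A_eq.shape[0]):
            lines.append(f" mb{i}: {terms(A_eq.getrow(i))} = 0")
        A_ub = A_ub.tocsr()
        for i in range(A_ub.shape[0]):
            lines.append(f" c{i}: {terms(A_ub.getrow(i))} <= {b_ub[i]:.12g}")
        lines.append("Bounds")
        for j, name in enumerate(names):
            lines.append(f" {lb[j]:.12g} <= {name} <= {ub[j]:.12g}")
        lines.append("Binaries")
        lines.append(" " + " ".join(n for j, n in enumerate(names) if integrality[j]))
        lines.append("End")
        return "\n".join(lines) + "\n"


@dataclass
class TmfaSolution:
    fluxes: dict[str, float]
    ln_activities: dict[str, float]
    activity_indicators: dict[tuple[str, str], int]
    realized_drG: dict[tuple[str, str], float]
    slacks: dict[str, float]
    objective_value: float
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def build_tmfa_problem(model: MetabolicModel, thermo: ThermoConstraintSet) -> TmfaProblem:
    """Assemble the directed-reaction MILP description.

    Exchange reactions and reactions flagged ``no_estimate`` carry
    direction binaries but no energy constraint; their directionality is
    restricted by the model bounds alone.  A species participating in an
    energy constraint without activity bounds raises
    :class:`ThermoConfigError`.
    """
    _, met_ids, rxn_ids = model.stoichiometric_matrix()
    directed: list[_Directed] = []
    ln_species: list[str] = []
    ln_seen = set()
    slack_rxns: list[str] = []

    for rid in rxn_ids:
        rxn = model.reactions[rid]
        energy = thermo.reaction_energies.get(rid)
        has_energy = (
            energy is not None and energy.drGm is not None and not rxn.is_exchange
        )
        if has_energy:
            k = energy.drGm
            for species, coeff in rxn.stoich.items():
                a_ref = thermo.reference_activity(species)
                if species in PROTON_WATER or a_ref is None:
                    continue
                if species not in thermo.activity_bounds:
                    raise ThermoConfigError(
                        f"species {species!r} in energy-constrained reaction {rid!r} "
                        "has no activity bounds"
                    )
                k -= RT * coeff * math.log(a_ref)
                if species not in ln_seen:
                    ln_seen.add(species)
                    ln_species.append(species)
            slack_rxns.append(rid)
        else:
            k = 0.0
        if rxn.upper_bound > 0:
            directed.append(_Directed(rid, True, rxn.upper_bound, has_energy, k))
        if rxn.lower_bound < 0:
            directed.append(_Directed(rid, False, -rxn.lower_bound, has_energy, k))

    ln_species.sort()
    return TmfaProblem(model, thermo, directed, ln_species, slack_rxns, rxn_ids, met_ids)


def _assemble(problem: TmfaProblem):
    """Matrices, bounds and integrality for the MILP (without objective)."""
    model, thermo = problem.model, problem.thermo
    nd = len(problem.directed)
    ns = len(problem.ln_species)
    ne = len(problem.slack_rxns)
    nvar = problem.n_vars
    off_v, off_z, off_ln, off_s = problem.var_layout()
    ln_index = {s: off_ln + i for i, s in enumerate(problem.ln_species)}
    slack_index = {r: off_s + i for i, r in enumerate(problem.slack_rxns)}
    met_index = {m: i for i, m in enumerate(problem.met_ids)}
    M = thermo.big_M

    # mass balance (equalities)
    rows, cols, data = [], [], []
    for j, d in enumerate(problem.directed):
        sgn = 1.0 if d.forward else -1.0
        for met, coeff in model.reactions[d.rxn_id].stoich.items():
            rows.append(met_index[met])
            cols.append(off_v + j)
            data.append(sgn * coeff)
    A_eq = sp.csr_matrix((data, (rows, cols)), shape=(len(problem.met_ids), nvar))

    # inequalities
    ub_rows: list[tuple[dict[int, float], float]] = []
    by_rxn: dict[str, dict[str, int]] = {}
    for j, d in enumerate(problem.directed):
        by_rxn.setdefault(d.rxn_id, {})["fwd" if d.forward else "bwd"] = j
        # capacity: v_j - cap * z_j <= 0
        ub_rows.append(({off_v + j: 1.0, off_z + j: -d.cap}, 0.0))
        if d.has_energy:
            energy = thermo.reaction_energies[d.rxn_id]
            sgn = 1.0 if d.forward else -1.0
            row = {off_z + j: M, slack_index[d.rxn_id]: sgn}
            for species, coeff in model.reactions[d.rxn_id].stoich.items():
                if species in ln_index:
                    row[ln_index[species]] = row.get(ln_index[species], 0.0) + sgn * RT * coeff
            ub_rows.append((row, M - sgn * d.k_const))
    for rid, dirs in by_rxn.items():
        if len(dirs) == 2:
            ub_rows.append(({off_z + dirs["fwd"]: 1.0, off_z + dirs["bwd"]: 1.0}, 1.0))

    rows, cols, data, b_ub = [], [], [], []
    for i, (row, rhs) in enumerate(ub_rows):
        for j, v in row.items():
            rows.append(i)
            cols.append(j)
            data.append(v)
        b_ub.append(rhs)
    A_ub = sp.csr_matrix((data, (rows, cols)), shape=(len(ub_rows), nvar))

    lb = np.zeros(nvar)
    ub = np.zeros(nvar)
    for j, d in enumerate(problem.directed):
        ub[off_v + j] = d.cap
        ub[off_z + j] = 1.0
    for s, j in ln_index.items():
        lo, hi = thermo.activity_bounds[s]
        lb[j], ub[j] = math.log(lo), math.log(hi)
    for rid, j in slack_index.items():
        half = thermo.slack_sigmas * thermo.reaction_energies[rid].se
        lb[j], ub[j] = -half, half
    integrality = np.zeros(nvar)
    integrality[off_z: off_z + nd] = 1
    return A_eq, A_ub, np.array(b_ub), lb, ub, integrality, ln_index, slack_index


def _net_objective(problem: TmfaProblem, reaction: str) -> np.ndarray:
    off_v, _, _, _ = problem.var_layout()
    c = np.zeros(problem.n_vars)
    for j, d in enumerate(problem.directed):
        if d.rxn_id == reaction:
            c[off_v + j] = 1.0 if d.forward else -1.0
    return c


def _solve_milp(problem: TmfaProblem, c: np.ndarray, sense: str,
                extra_rows: Sequence[tuple[np.ndarray, float, float]] = ()):
    A_eq, A_ub, b_ub, lb, ub, integrality, ln_index, slack_index = _assemble(problem)
    constraints = [
        LinearConstraint(A_eq, 0.0, 0.0),
        LinearConstraint(A_ub, -np.inf, b_ub),
    ]
    for row, lo, hi in extra_rows:
        constraints.append(LinearConstraint(sp.csr_matrix(row), lo, hi))
    sign = -1.0 if sense == "max" else 1.0
    res = milp(
        sign * c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"mip_rel_gap": 1e-9},
    )
    return res, ln_index, slack_index


def _extract(problem: TmfaProblem, res, ln_index, slack_index, c) -> TmfaSolution:
    if res.status != 0 or res.x is None:
        status = {2: "infeasible", 3: "unbounded", 4: "infeasible"}.get(res.status, "failed")
        return TmfaSolution({}, {}, {}, {}, {}, 0.0, status)
    x = res.x
    off_v, off_z, off_ln, off_s = problem.var_layout()
    fluxes: dict[str, float] = {rid: 0.0 for rid in problem.rxn_ids}
    indicators: dict[tuple[str, str], int] = {}
    realized: dict[tuple[str, str], float] = {}
    ln_act = {s: float(x[j]) for s, j in ln_index.items()}
    slacks = {r: float(x[j]) for r, j in slack_index.items()}
    for j, d in enumerate(problem.directed):
        v = float(x[off_v + j])
        key = (d.rxn_id, "fwd" if d.forward else "bwd")
        fluxes[d.rxn_id] += v if d.forward else -v
        indicators[key] = int(round(x[off_z + j]))
        if d.has_energy:
            sgn = 1.0 if d.forward else -1.0
            dg = d.k_const + slacks[d.rxn_id]
            for species, coeff in problem.model.reactions[d.rxn_id].stoich.items():
                if species in ln_act:
                    dg += RT * coeff * ln_act[species]
            realized[key] = sgn * dg
    return TmfaSolution(fluxes, ln_act, indicators, realized, slacks, float(c @ x), "optimal")


def tmfa_optimize(
    problem: TmfaProblem,
    objective: Optional[str] = None,
    sense: str = "max",
) -> TmfaSolution:
    """Solve the TMFA MILP for one objective reaction (net flux)."""
    objective = objective or problem.model.biomass_reaction_id
    if objective not in problem.model.reactions:
        raise LookupError(f"objective {objective!r} not in model")
    c = _net_objective(problem, objective)
    res, ln_index, slack_index = _solve_milp(problem, c, sense)
    return _extract(problem, res, ln_index, slack_index, c)


def validate_solution(
    problem: TmfaProblem,
    solution: TmfaSolution,
    flux_tol: float = FLUX_TOL,
    dg_tol: float = DG_TOL,
) -> list[str]:
    """Independent post-hoc check of a TMFA solution; returns violations.

    Recomputes mass balance from the net fluxes and the second law from
    the returned ln-activities and slacks — nothing is trusted from the
    solver.  An empty list means the solution is clean.
    """
    issues: list[str] = []
    model = problem.model
    # mass balance
    N, met_ids, rxn_ids = model.stoichiometric_matrix()
    v = np.array([solution.fluxes.get(r, 0.0) for r in rxn_ids])
    residual = np.abs(N @ v)
    if residual.size and residual.max() > flux_tol:
        worst = met_ids[int(residual.argmax())]
        issues.append(f"mass balance violated at {worst}: |Nv| = {residual.max():.3g}")
    # bounds
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        flux = solution.fluxes.get(rid, 0.0)
        if flux < rxn.lower_bound - flux_tol or flux > rxn.upper_bound + flux_tol:
            issues.append(f"{rid}: flux {flux:.6g} outside [{rxn.lower_bound}, {rxn.upper_bound}]")
    # activity bounds
    for species, value in solution.ln_activities.items():
        lo, hi = problem.thermo.activity_bounds[species]
        if value < math.log(lo) - 1e-6 or value > math.log(hi) + 1e-6:
            issues.append(f"ln-activity of {species} out of bounds")
    # slack window
    for rid, s in solution.slacks.items():
        half = problem.thermo.slack_sigmas * problem.thermo.reaction_energies[rid].se
        if abs(s) > half + 1e-6:
            issues.append(f"{rid}: slack {s:.3g} exceeds {half:.3g}")
    # second law, recomputed from scratch
    for d in problem.directed:
        if not d.has_energy:
            continue
        flux = solution.fluxes.get(d.rxn_id, 0.0)
        dir_flux = flux if d.forward else -flux
        if dir_flux <= flux_tol:
            continue
        sgn = 1.0 if d.forward else -1.0
        dg = d.k_const + solution.slacks.get(d.rxn_id, 0.0)
        for species, coeff in model.reactions[d.rxn_id].stoich.items():
            if species in solution.ln_activities:
                dg += RT * coeff * solution.ln_activities[species]
        dg *= sgn
        if dg > dg_tol:
            issues.append(
                f"{d.rxn_id} ({'fwd' if d.forward else 'bwd'}): flux {dir_flux:.4g} "
                f"with positive dG' {dg:.4g}"
            )
    # directionality
    seen: dict[str, int] = {}
    for (rid, _), z in solution.activity_indicators.items():
        seen[rid] = seen.get(rid, 0) + z
    for rid, total in seen.items():
        if total > 1:
            issues.append(f"{rid}: both direction indicators active")
    return issues


def tmfa_fva_classify(
    problem: TmfaProblem,
    objective: Optional[str] = None,
    epsilon: float = 1e-9,
    reactions: Optional[Iterable[str]] = None,
) -> FvaClassification:
    """Per-reaction net flux ranges under thermodynamic constraints.

    The objective is fixed at (1 - 1e-9) of the TMFA optimum and each
    reaction's net flux is minimized/maximized by MILP; labels follow the
    essential/substitutable/blocked convention of the mass-balance FVA.
    """
    objective = objective or problem.model.biomass_reaction_id
    base = tmfa_optimize(problem, objective)
    if not base.optimal:
        raise RuntimeError(f"TMFA FVA requires an optimum (got {base.status})")
    c_obj = _net_objective(problem, objective)
    opt = base.objective_value
    fix_lo = opt - abs(opt) * 1e-9 - 1e-12
    rxn_list = sorted(reactions) if reactions is not None else list(problem.rxn_ids)

    labels, ranges, failures = {}, {}, {}
    for rid in rxn_list:
        c = _net_objective(problem, rid)
        extreme = {}
        for sense in ("min", "max"):
            res, ln_index, slack_index = _solve_milp(
                problem, c, sense, extra_rows=[(c_obj, fix_lo, np.inf)]
            )
            sol = _extract(problem, res, ln_index, slack_index, c)
            extreme[sense] = sol
        if not (extreme["min"].optimal and extreme["max"].optimal):
            failures[rid] = f"min:{extreme['min'].status} max:{extreme['max'].status}"
            continue
        lo, hi = extreme["min"].objective_value, extreme["max"].objective_value
        ranges[rid] = (lo, hi)
        if lo > epsilon or hi < -epsilon:
            labels[rid] = "essential"
        elif abs(lo) <= epsilon and abs(hi) <= epsilon:
            labels[rid] = "blocked"
        else:
            labels[rid] = "substitutable"
    return FvaClassification(labels, ranges, failures)


def screen_feasible_pathways(
    pathways: Sequence[Pathway],
    classification: FvaClassification,
) -> list[Pathway]:
    """Drop pathways containing any thermodynamically blocked reaction."""
    out = []
    for p in pathways:
        for rid in p.reactions:
            if rid not in classification.labels:
                raise LookupError(f"pathway reaction {rid!r} is unclassified")
        if all(classification.labels[rid] != "blocked" for rid in p.reactions):
            out.append(p)
    return out
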