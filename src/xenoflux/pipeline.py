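"""End-to-end study orchestration.

``run_pipeline`` drives the whole analysis on one configuration: expand the
rule network from the seed xenobiotic, enumerate and screen pathways to
compounds with known metabolism, classify them by overall reaction, then
for each overall reaction implement it in the host model and quantify
growth-linked degradation (FBA yields, FVA classes, shadow prices,
biomass/uptake trade-offs, by-product secretion), run all overall
reactions simultaneously with reduced-cost analysis, and finally apply
thermodynamic constraints (TMFA) to the distinct pathway reactions of the
leading overall reactions, screening out pathways with thermodynamically
blocked steps.

Outputs are collected in a :class:`ReportBundle` of plain tables that can
be written to a directory as TSV plus one deterministic JSON bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import __version__
from .analysis import (
    FluxSolution,
    fba,
    fva_classify,
    growth_yield,
    secretion_profile,
    sensitivity,
    tradeoff_scan,
    TradeoffCurve,
)
from .fixtures import (
    DEFAULT_SEED,
    KNOWN_ROUTE_CHAIN,
    CATECHOL_ROUTE_CHAIN,
    ToyModelSpec,
    default_media,
    find_route,
    make_network_thermo_table,
    make_toy_model,
    make_toy_rules_and_registry,
)
from .model import (
    DonorSpec,
    MediaSpec,
    MetabolicModel,
    apply_media,
    augment_with_pathway,
)
from .pathways import (
    OverallReaction,
    Pathway,
    PathwayScreenCriteria,
    classify_by_overall,
    enumerate_pathways,
    equation_string,
    overall_reaction,
    screen_pathways,
)
from .rules import CompoundRegistry, ReactionNetwork, expand_network
from .thermo import apply_class_corrections, reaction_dGm
from .tmfa import (
    ThermoConstraintSet,
    build_tmfa_problem,
    default_activity_bounds,
    reaction_energies_for_model,
    screen_feasible_pathways,
    tmfa_fva_classify,
    tmfa_optimize,
    validate_solution,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "compare_carbon_sources"]

#: EC prefixes treated as oxygenases for the free-energy cap
OXYGENASE_EC = ("1.13", "1.14")


@dataclass
class RunConfig:
    """Study configuration; defaults reproduce the shipped fixture study."""

    max_generations: int = 10
    max_path_len: int = 15
    known_route_length: int = len(KNOWN_ROUTE_CHAIN)  # screen: <= known pathway
    require_known_intermediates: bool = True
    require_native_products: bool = True
    seed: int = DEFAULT_SEED
    xenobiotic_uptake: float = 10.0
    donor_uptake: float = 100.0
    oxygenase_cap: float = -25.0
    dioxygenation_drGm: float = 10.6  # planted first-step energy, kcal/mol
    tradeoff_points: int = 6
    tmfa_groups: int = 2  # leading overall-reaction groups taken to TMFA
    output_dir: Optional[str] = None

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """All result tables of one study run (rows are plain dicts)."""

    config: RunConfig
    network_summary: dict
    overall_reactions: list[dict]  # Table-1 style
    growth: list[dict]  # Table-2 style: yields and uptakes
    shadow_prices: list[dict]  # Table-3 style
    reduced_costs: list[dict]  # Table-4 style, simultaneous run
    screen_counts: list[dict]  # Table-5 style
    reducing_equivalents: list[dict]  # figure-2 style pairs
    tradeoffs: dict[str, dict]  # figure-4 style curves per label/mode
    fva_labels: dict[str, dict[str, str]]
    secretion: dict[str, list[str]]
    log: list[str] = field(default_factory=list)

    def to_dir(self, path) -> None:
        import pandas as pd

        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "overall_reactions.tsv": self.overall_reactions,
            "growth.tsv": self.growth,
            "shadow_prices.tsv": self.shadow_prices,
            "reduced_costs.tsv": self.reduced_costs,
            "screen_counts.tsv": self.screen_counts,
            "reducing_equivalents.tsv": self.reducing_equivalents,
        }
        for name, rows in tables.items():
            pd.DataFrame(rows).to_csv(out / name, sep="\t", index=False)
        bundle = {
            "config_digest": self.config.digest(),
            "version": __version__,
            "network": self.network_summary,
            "overall_reactions": self.overall_reactions,
            "growth": self.growth,
            "shadow_prices": self.shadow_prices,
            "reduced_costs": self.reduced_costs,
            "screen_counts": self.screen_counts,
            "reducing_equivalents": self.reducing_equivalents,
            "tradeoffs": self.tradeoffs,
            "fva_labels": self.fva_labels,
            "secretion": self.secretion,
        }
        (out / "bundle.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
        (out / "run.log").write_text("\n".join(self.log) + "\n")


def _media_for(
    model: MetabolicModel,
    carbon_exchange: str,
    carbon_bound: float,
    donor: Optional[DonorSpec],
) -> MediaSpec:
    extra = {}
    if donor is not None and donor.enabled and donor.exchange_id in model.reactions:
        extra[donor.exchange_id] = (donor.uptake_bound, 1000.0)
    return default_media(model, carbon_exchange=carbon_exchange,
                         carbon_bounds=(-carbon_bound, 1000.0)) if not extra else MediaSpec.minimal(
        ("EX_co2_e", "EX_h2o_e", "EX_h_e", "EX_nh4_e"),
        o2_exchange="EX_o2_e",
        carbon_exchange=carbon_exchange,
        carbon_bounds=(-carbon_bound, 1000.0),
        extra=extra,
    )


def _implement_overall(
    base: MetabolicModel,
    ov: OverallReaction,
    registry: CompoundRegistry,
    config: RunConfig,
) -> MetabolicModel:
    donor = DonorSpec(uptake_bound=-config.donor_uptake)
    aug = augment_with_pathway(base, [ov], donor=donor, registry=registry, xenobiotic="tcb_c")
    media = _media_for(aug, "EX_tcb_e", config.xenobiotic_uptake, donor)
    return apply_media(aug, media)


def run_pipeline(config: Optional[RunConfig] = None) -> ReportBundle:
    """Execute every stage of the study on the synthetic fixture inputs."""
    config = config or RunConfig()
    log = [f"xenoflux {__version__} config {config.digest()}"]

    # stage 1: network expansion
    rules, registry, seed_compound = make_toy_rules_and_registry()
    network = expand_network([seed_compound], rules, config.max_generations)
    log.append(f"expand: {len(network.compounds)} compounds, {len(network.reactions)} reactions")

    # stage 2: enumeration and screening
    sinks = [s for s in registry.native_ids() if s in network.compounds]
    pathways = enumerate_pathways(network, seed_compound.id, sinks, config.max_path_len)
    criteria = PathwayScreenCriteria(
        max_length=config.known_route_length,
        require_known_intermediates=config.require_known_intermediates,
        require_native_products=config.require_native_products,
    )
    screened = screen_pathways(pathways, criteria, registry, network)
    log.append(f"enumerate: {len(pathways)} pathways; screened: {len(screened)}")

    # stage 3: classification by overall reaction
    groups = classify_by_overall(screened, network)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0].key()))
    labelled: list[tuple[str, OverallReaction, list[Pathway]]] = []

    def _reference_key(chain):
        try:
            return overall_reaction(find_route(network, chain), network).key()
        except LookupError:  # route truncated by a small generation cap
            return None

    known_key = _reference_key(KNOWN_ROUTE_CHAIN)
    catechol_key = _reference_key(CATECHOL_ROUTE_CHAIN)
    counter = 0
    for ov, members in ordered:
        if ov.key() == known_key:
            label = "K"
        elif ov.key() == catechol_key:
            label = "3"
        else:
            counter += 1
            label = f"N{counter}"
        labelled.append((label, OverallReaction(ov.stoich, label), members))
    log.append(f"classify: {len(labelled)} distinct overall reactions")

    overall_rows = [
        {"label": label, "equation": equation_string(ov),
         "n_pathways": len(members),
         "reducing_equivalents": ov.reducing_equivalents,
         "electrons": ov.electrons, "net_nadph": ov.net_nadph, "o2": ov.o2_consumed}
        for label, ov, members in labelled
    ]

    # stage 4: per-overall-reaction implementation
    base = make_toy_model(ToyModelSpec(seed=config.seed)).model
    growth_rows, re_rows = [], []
    shadow_rows, fva_labels, secretion = [], {}, {}
    tradeoffs: dict[str, dict] = {}
    media_metabolites = ["o2_e", "nh4_e", "h_e", "h2o_e", "co2_e"]
    for label, ov, members in labelled:
        m = _implement_overall(base, ov, registry, config)
        sol = fba(m)
        if not sol.optimal or sol.objective_value <= 1e-9:
            growth_rows.append({"label": label, "biomass": 0.0, "yield": 0.0, "uptake": 0.0})
            continue
        yld = growth_yield(sol, "EX_tcb_e") or 0.0
        uptake = abs(sol.fluxes.get("EX_tcb_e", 0.0))
        growth_rows.append({"label": label, "biomass": sol.objective_value,
                            "yield": yld, "uptake": uptake})
        re_rows.append({"label": label, "reducing_equivalents": ov.reducing_equivalents,
                        "yield": yld})
        sens = sensitivity(m, sol, degeneracy_check=True)
        shadow_rows.append({"label": label, **{
            met: sens.shadow_prices.get(met, 0.0) for met in media_metabolites
        }, "basis_caveat": sens.basis_caveat})
        fva = fva_classify(m)
        fva_labels[label] = fva.labels
        # by-product secretion at sub-optimal biomass
        sub = m.copy()
        sub.reactions["BIOMASS"].lower_bound = 0.5 * sol.objective_value
        sub.reactions["BIOMASS"].upper_bound = 0.5 * sol.objective_value
        sub_sol = _maximize_uptake(sub, "EX_tcb_e")
        secretion[label] = secretion_profile(sub_sol, sub) if sub_sol.optimal else []
        # trade-off curves
        grid = list(np.linspace(0.0, sol.objective_value, config.tradeoff_points))
        for mode in ("maximize", "minimize"):
            curve = tradeoff_scan(m, grid, "EX_tcb_e", mode=mode)
            tradeoffs[f"{label}:{mode}"] = {
                "biomass": curve.biomass, "uptake": curve.uptake, "status": curve.status,
            }
    log.append(f"growth: {len(growth_rows)} overall reactions implemented individually")

    # stage 5: simultaneous implementation with reduced costs
    reduced_rows = _simultaneous_run(base, labelled, registry, config)
    log.append("simultaneous run complete")

    # stage 6: thermodynamics and TMFA screen
    screen_rows = _tmfa_stage(base, network, labelled, registry, config, log)

    bundle = ReportBundle(
        config=config,
        network_summary={
            "compounds": len(network.compounds),
            "reactions": len(network.reactions),
            "max_generation": network.max_generation,
            "pathways_enumerated": len(pathways),
            "pathways_screened": len(screened),
        },
        overall_reactions=overall_rows,
        growth=growth_rows,
        shadow_prices=shadow_rows,
        reduced_costs=reduced_rows,
        screen_counts=screen_rows,
        reducing_equivalents=re_rows,
        tradeoffs=tradeoffs,
        fva_labels=fva_labels,
        secretion=secretion,
        log=log,
    )
    if config.output_dir:
        bundle.to_dir(config.output_dir)
    return bundle


def _maximize_uptake(model: MetabolicModel, exchange: str) -> FluxSolution:
    return fba(model, objective=exchange, sense="min", want_duals=False)


def _simultaneous_run(
    base: MetabolicModel,
    labelled: Sequence[tuple[str, OverallReaction, list]],
    registry: CompoundRegistry,
    config: RunConfig,
) -> list[dict]:
    """Implement every overall reaction at once; report ranges and reduced costs.

    The same exchange bound governs total xenobiotic uptake, so the cell
    chooses among the routes; forcing flux through an off-optimum route
    lowers biomass by its reduced cost.
    """
    donor = DonorSpec(uptake_bound=-config.donor_uptake)
    aug = augment_with_pathway(
        base, [ov for _, ov, _ in labelled], donor=donor, registry=registry, xenobiotic="tcb_c",
    )
    media = _media_for(aug, "EX_tcb_e", config.xenobiotic_uptake, donor)
    m = apply_media(aug, media)
    sol = fba(m)
    if not sol.optimal:
        return []
    ovr_ids = [f"OVR_{label}" for label, _, _ in labelled]
    fva = fva_classify(m, reactions=ovr_ids)
    sens = sensitivity(m, sol, degeneracy_check=False)
    rows = []
    for label, _, _ in labelled:
        rid = f"OVR_{label}"
        lo, hi = fva.ranges.get(rid, (0.0, 0.0))
        rows.append({
            "label": label,
            "flux_min": lo,
            "flux_max": hi,
            "flux": sol.fluxes.get(rid, 0.0),
            "reduced_cost": sens.reduced_costs.get(rid, 0.0),
            "biomass": sol.objective_value,
        })
    return rows


def _tmfa_stage(
    base: MetabolicModel,
    network: ReactionNetwork,
    labelled: Sequence[tuple[str, OverallReaction, list]],
    registry: CompoundRegistry,
    config: RunConfig,
    log: list[str],
) -> list[dict]:
    """Implement the distinct pathway reactions per leading group; TMFA screen."""
    try:
        known = find_route(network, KNOWN_ROUTE_CHAIN)
        planted = {known.reactions[0]: config.dioxygenation_drGm}
    except LookupError:  # truncated network: no step gets pinned uphill
        planted = {}
    net_energies = make_network_thermo_table(network, seed=config.seed,
                                             planted_reactions=planted)
    rows = []
    # leading groups: the known route's group and the catechol group first
    priority = {"K": 0, "3": 1}
    chosen = sorted(labelled, key=lambda t: (priority.get(t[0], 2), t[0]))[: config.tmfa_groups]
    donor = DonorSpec(uptake_bound=-config.donor_uptake)
    for label, ov, members in chosen:
        distinct = sorted({rid for p in members for rid in p.reactions})
        reactions = [network.reactions[rid] for rid in distinct]
        aug = augment_with_pathway(base, reactions, donor=donor, registry=registry,
                                   xenobiotic="tcb_c")
        media = _media_for(aug, "EX_tcb_e", config.xenobiotic_uptake, donor)
        m = apply_media(aug, media)
        mass_sol = fba(m)
        # reaction energies: network-side estimates with oxygenase correction
        overrides = {}
        for rid in distinct:
            rxn = network.reactions[rid]
            energy = reaction_dGm(rid, rxn.stoich, net_energies)
            flags = set()
            rule_ec = rid.split("__")[0]
            for rule_id, prefix in _rule_ec_index(network).items():
                if rid.startswith(rule_id):
                    rule_ec = prefix
                    break
            if any(rule_ec.startswith(p) for p in OXYGENASE_EC):
                flags.add("oxygenase")
            if rule_ec.startswith("1.97"):
                flags.add("reductive_dechlorination")
            from .thermo import cap_strategy

            energy = apply_class_corrections(
                energy, flags, oxygenase_strategy=cap_strategy(config.oxygenase_cap),
            )
            overrides[rid] = energy
        model_energies, _ = _model_thermo(m, config)
        rxn_energies = reaction_energies_for_model(m, model_energies, overrides=overrides)
        dihydrodiol = _mapped_id(m, KNOWN_ROUTE_CHAIN[0][1])
        xeno_ids = ["tcb_c"] + ([dihydrodiol] if dihydrodiol else [])
        bounds = default_activity_bounds(m, xenobiotic_ids=xeno_ids)
        refs = {cid: e.reference_activity for cid, e in model_energies.items()}
        for cid, e in net_energies.items():
            mapped = _mapped_id(m, cid)
            if mapped:
                refs.setdefault(mapped, e.reference_activity)
        tcs = ThermoConstraintSet(rxn_energies, bounds, refs)
        problem = build_tmfa_problem(m, tcs)
        tmfa_sol = tmfa_optimize(problem)
        issues = validate_solution(problem, tmfa_sol) if tmfa_sol.optimal else []
        if issues:
            raise RuntimeError(f"TMFA validation failed for group {label}: {issues[:3]}")
        classification = tmfa_fva_classify(problem, reactions=distinct)
        feasible = screen_feasible_pathways(members, classification)
        tmfa_yield = 0.0
        if tmfa_sol.optimal and tmfa_sol.objective_value > 1e-9:
            uptake = abs(tmfa_sol.fluxes.get("EX_tcb_e", 0.0))
            tmfa_yield = tmfa_sol.objective_value / uptake if uptake > 1e-9 else 0.0
        rows.append({
            "label": label,
            "total_pathways": len(members),
            "met_pathway_screen": len(members),
            "met_tmfa_screen": len(feasible),
            "mass_balance_biomass": mass_sol.objective_value if mass_sol.optimal else 0.0,
            "tmfa_biomass": tmfa_sol.objective_value if tmfa_sol.optimal else 0.0,
            "tmfa_yield": tmfa_yield,
            "blocked_reactions": len(classification.of_class("blocked")),
        })
        log.append(
            f"tmfa[{label}]: {len(distinct)} distinct reactions, "
            f"{len(feasible)}/{len(members)} pathways feasible"
        )
    return rows


def _rule_ec_index(network: ReactionNetwork) -> dict[str, str]:
    # reaction ids embed their rule id; map rule ids to EC prefixes lazily
    from .rules import toy_rule_set

    return {r.rule_id: r.ec_prefix for r in toy_rule_set()}


def _mapped_id(model: MetabolicModel, structure: str) -> Optional[str]:
    from .model import _novel_metabolite_id

    for candidate in (_novel_metabolite_id(structure, "c"), structure):
        if candidate in model.metabolites:
            return candidate
    return None


def _model_thermo(model: MetabolicModel, config: RunConfig):
    from .fixtures import make_thermo_table

    return make_thermo_table(model, seed=config.seed, profile="all_downhill")


def compare_carbon_sources(
    config: Optional[RunConfig] = None,
    alternative_exchange: str = "EX_glc_e",
) -> dict[str, object]:
    """Trade-off comparison: xenobiotic versus a conventional carbon source.

    Returns both maximize-mode curves and whether the alternative source's
    maximum uptake is biomass-independent (flat curve) — the signature of
    a substrate whose assimilation needs no extra reducing power or
    oxygen.
    """
    config = config or RunConfig()
    rules, registry, seed_compound = make_toy_rules_and_registry()
    network = expand_network([seed_compound], rules, config.max_generations)
    # the known route: its own oxygen and reducing-power demand makes the
    # biodegradation/growth competition visible
    route = find_route(network, KNOWN_ROUTE_CHAIN)
    ov = overall_reaction(route, network, label="K")
    base = make_toy_model(ToyModelSpec(seed=config.seed)).model
    xeno_model = _implement_overall(base, ov, registry, config)
    xeno_sol = fba(xeno_model)
    glc_model = apply_media(base, default_media(base, carbon_exchange=alternative_exchange))
    glc_sol = fba(glc_model)

    out: dict[str, object] = {}
    for name, model, sol, exchange in (
        ("xenobiotic", xeno_model, xeno_sol, "EX_tcb_e"),
        ("alternative", glc_model, glc_sol, alternative_exchange),
    ):
        grid = list(np.linspace(0.0, sol.objective_value, config.tradeoff_points))
        curve = tradeoff_scan(model, grid, exchange, mode="maximize")
        ok = [u for u, s in zip(curve.uptake, curve.status) if s == "optimal"]
        out[name] = {"biomass": curve.biomass, "uptake": curve.uptake, "status": curve.status}
        out[f"{name}_flat"] = bool(ok) and (max(ok) - min(ok) < 1e-6)
    return out
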