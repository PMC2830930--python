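"""Thermodynamics-constrained flux analysis: MILP, validator, classification."""

import numpy as np
import pytest

from xenoflux.analysis import fba
from xenoflux.fixtures import (
    ToyModelSpec,
    default_media,
    make_thermo_table,
    make_toy_model,
    make_toy_rules_and_registry,
    find_route,
    KNOWN_ROUTE_CHAIN,
)
from xenoflux.model import (
    DonorSpec,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_media,
    augment_with_pathway,
)
from xenoflux.pathways import Pathway, overall_reaction
from xenoflux.thermo import CompoundEnergy, ReactionEnergy
from xenoflux.tmfa import (
    ThermoConfigError,
    ThermoConstraintSet,
    build_tmfa_problem,
    default_activity_bounds,
    reaction_energies_for_model,
    screen_feasible_pathways,
    tmfa_fva_classify,
    tmfa_optimize,
    validate_solution,
)


def _constraints(model, energies, xeno=("tcb_c",), **kwargs):
    rxn_e = reaction_energies_for_model(model, energies)
    bounds = default_activity_bounds(model, xenobiotic_ids=list(xeno))
    refs = {cid: e.reference_activity for cid, e in energies.items()}
    return ThermoConstraintSet(rxn_e, bounds, refs, **kwargs)


@pytest.fixture(scope="module")
def glucose_model():
    fix = make_toy_model()
    return apply_media(fix.model, default_media(fix.model))


@pytest.fixture(scope="module")
def tcb_known_model(toy_fixture_module):
    """Toy model augmented with the known-route overall reaction, TCB medium."""
    model, ov = toy_fixture_module
    return model


@pytest.fixture(scope="module")
def toy_fixture_module():
    rules, registry, seed = make_toy_rules_and_registry()
    from xenoflux.rules import expand_network

    network = expand_network([seed], rules, 10)
    route = find_route(network, KNOWN_ROUTE_CHAIN)
    ov = overall_reaction(route, network, label="K")
    base = make_toy_model().model
    donor = DonorSpec()
    aug = augment_with_pathway(base, [ov], donor=donor, registry=registry, xenobiotic="tcb_c")
    from xenoflux.model import MediaSpec

    media = MediaSpec.minimal(
        ("EX_co2_e", "EX_h2o_e", "EX_h_e", "EX_nh4_e"),
        o2_exchange="EX_o2_e",
        carbon_exchange="EX_tcb_e",
        extra={"EX_ac_e": (-100.0, 1000.0)},
    )
    return apply_media(aug, media), ov


class TestOptimize:
    def test_all_downhill_recovers_the_fba_optimum(self, glucose_model):
        energies, _ = make_thermo_table(glucose_model, seed=11, profile="all_downhill")
        problem = build_tmfa_problem(glucose_model, _constraints(glucose_model, energies))
        sol = tmfa_optimize(problem)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(
            fba(glucose_model).objective_value, abs=1e-6
        )
        assert validate_solution(problem, sol) == []

    def test_rescuable_uphill_step_keeps_full_biomass(self, toy_fixture_module):
        """A +12.5 kcal/mol step on an essential reaction still runs: the
        activity window buys ~9 kcal/mol and the three-standard-error slack
        (se 1.8 -> +/-5.4 kcal/mol) covers the rest."""
        model, _ = toy_fixture_module
        energies, planted = make_thermo_table(model, seed=3, profile="one_uphill",
                                              uphill_magnitude=12.5, se_range=(0.9, 0.9))
        assert planted == {"SUCDH": 12.5}
        problem = build_tmfa_problem(model, _constraints(model, energies))
        sol = tmfa_optimize(problem)
        reference = fba(model).objective_value
        assert sol.optimal
        assert sol.objective_value == pytest.approx(reference, abs=1e-6)
        assert validate_solution(problem, sol) == []
        assert sol.fluxes["SUCDH"] > 1e-6  # the uphill step actually runs

    def test_unrescuable_uphill_step_blocks_growth(self, toy_fixture_module):
        """+50 kcal/mol with zero standard error exceeds any activity swing."""
        model, _ = toy_fixture_module
        energies, _ = make_thermo_table(model, seed=3, profile="one_uphill",
                                        uphill_magnitude=50.0, se_range=(0.0, 1e-9))
        problem = build_tmfa_problem(model, _constraints(model, energies))
        sol = tmfa_optimize(problem)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_no_estimate_reaction_escapes_the_constraint(self, toy_fixture_module):
        model, _ = toy_fixture_module
        energies, _ = make_thermo_table(model, seed=3, profile="one_uphill",
                                        uphill_magnitude=50.0, se_range=(0.0, 1e-9))
        rxn_e = reaction_energies_for_model(model, energies)
        rxn_e["SUCDH"] = ReactionEnergy("SUCDH", None, 0.0, frozenset({"no_estimate"}))
        bounds = default_activity_bounds(model, xenobiotic_ids=["tcb_c"])
        refs = {cid: e.reference_activity for cid, e in energies.items()}
        problem = build_tmfa_problem(model, ThermoConstraintSet(rxn_e, bounds, refs))
        sol = tmfa_optimize(problem)
        assert sol.objective_value == pytest.approx(fba(model).objective_value, abs=1e-6)

    def test_closed_exchanges_give_zero(self, glucose_model):
        closed = glucose_model.copy()
        for ex in closed.exchange_reaction_ids:
            closed.reactions[ex].lower_bound = 0.0
            closed.reactions[ex].upper_bound = 0.0
        energies, _ = make_thermo_table(closed, seed=5)
        problem = build_tmfa_problem(closed, _constraints(closed, energies))
        sol = tmfa_optimize(problem)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_missing_activity_bounds_is_a_config_error(self, glucose_model):
        energies, _ = make_thermo_table(glucose_model, seed=11)
        rxn_e = reaction_energies_for_model(glucose_model, energies)
        refs = {cid: e.reference_activity for cid, e in energies.items()}
        with pytest.raises(ThermoConfigError):
            build_tmfa_problem(
                glucose_model, ThermoConstraintSet(rxn_e, {"pyr_c": (1e-5, 0.02)}, refs)
            )


class TestDominanceProperty:
    @pytest.mark.parametrize("seed", range(20))
    def test_tmfa_never_exceeds_fba_and_obeys_second_law(self, seed):
        """Across seeded fixtures the TMFA optimum is bounded by FBA and the
        independent validator finds no positive-flux endergonic reaction."""
        rng = np.random.default_rng(10_000 + seed)
        spec = ToyModelSpec(
            seed=seed,
            yield_coefficient=float(rng.uniform(0.03, 0.08)),
            carbon_uptake=float(rng.uniform(5.0, 15.0)),
            include_redundant_branch=bool(rng.integers(0, 2)),
        )
        fix = make_toy_model(spec)
        model = apply_media(fix.model, default_media(fix.model))
        energies, _ = make_thermo_table(model, seed=seed, profile="mixed")
        problem = build_tmfa_problem(model, _constraints(model, energies))
        reference = fba(model).objective_value
        sol = tmfa_optimize(problem)
        assert sol.optimal
        assert sol.objective_value <= reference + 1e-6
        assert validate_solution(problem, sol) == []

    def test_widening_activity_bounds_recovers_fba(self, toy_fixture_module):
        """In the wide-concentration limit the thermodynamic constraints vanish."""
        model, _ = toy_fixture_module
        energies, _ = make_thermo_table(model, seed=3, profile="one_uphill",
                                        uphill_magnitude=50.0, se_range=(0.0, 1e-9))
        rxn_e = reaction_energies_for_model(model, energies)
        wide = {m: (1e-30, 1e30) for m in model.metabolites}
        refs = {cid: e.reference_activity for cid, e in energies.items()}
        problem = build_tmfa_problem(
            model, ThermoConstraintSet(rxn_e, wide, refs, big_M=10000.0)
        )
        sol = tmfa_optimize(problem)
        assert sol.objective_value == pytest.approx(fba(model).objective_value, abs=1e-5)


def _flip_model():
    """EX -> a; direct route r1: a->b; wasteful route r2a: a->c, r2b: c->0.5 b."""
    mets = {m: Metabolite(m, formula="X", charge=0) for m in ("a", "b", "c")}
    rxns = {
        "EX_a": Reaction("EX_a", {"a": -1}, -10.0, 0.0, balance_exempt=True),
        "r1": Reaction("r1", {"a": -1, "b": 1}, 0.0, 1000.0),
        "r2a": Reaction("r2a", {"a": -1, "c": 1}, 0.0, 1000.0),
        "r2b": Reaction("r2b", {"c": -1, "b": 0.5}, 0.0, 1000.0, balance_exempt=True),
        "BIO": Reaction("BIO", {"b": -1}, 0.0, 1000.0, balance_exempt=True),
    }
    return MetabolicModel(mets, rxns, "BIO")


class TestThermoClassification:
    def _problem(self, r1_drGm):
        model = _flip_model()
        energies = {
            "r1": ReactionEnergy("r1", r1_drGm, 0.0),
            "r2a": ReactionEnergy("r2a", -5.0, 0.0),
            "r2b": ReactionEnergy("r2b", -5.0, 0.0),
        }
        bounds = {m: (1e-5, 0.02) for m in model.metabolites}
        refs = {m: 1e-3 for m in model.metabolites}
        return model, build_tmfa_problem(model, ThermoConstraintSet(energies, bounds, refs))

    def test_blocked_reaction_becomes_essential_under_thermo(self):
        """The wasteful branch is blocked by mass balance alone but becomes the
        essential route once the direct step is endergonic beyond rescue."""
        from xenoflux.analysis import fva_classify

        model, problem = self._problem(r1_drGm=+50.0)
        # epsilon above the objective-fixing slack window (~2e-8 here) so the
        # wasteful branch counts as blocked rather than hairline-substitutable
        mass_only = fva_classify(model, epsilon=1e-6)
        assert mass_only.labels["r1"] == "essential"
        assert mass_only.labels["r2a"] == "blocked"

        sol = tmfa_optimize(problem)
        assert sol.objective_value == pytest.approx(5.0, abs=1e-6)  # 10 * 0.5
        thermo = tmfa_fva_classify(problem, epsilon=1e-6)
        assert thermo.labels["r1"] == "blocked"
        assert thermo.labels["r2a"] == "essential"
        assert thermo.labels["r2b"] == "essential"

    def test_all_downhill_classification_matches_mass_balance(self):
        from xenoflux.analysis import fva_classify

        model, problem = self._problem(r1_drGm=-20.0)
        mass_only = fva_classify(model)
        thermo = tmfa_fva_classify(problem)
        assert thermo.labels == mass_only.labels

    def test_rerouting_lowers_the_objective(self):
        _, blocked_problem = self._problem(r1_drGm=+50.0)
        _, free_problem = self._problem(r1_drGm=-20.0)
        assert (
            tmfa_optimize(blocked_problem).objective_value
            < tmfa_optimize(free_problem).objective_value - 1e-6
        )


def test_lp_export_is_complete_and_deterministic(glucose_model):
    """The audit export carries every variable and all LP-format sections."""
    energies, _ = make_thermo_table(glucose_model, seed=11)
    rxn_e = reaction_energies_for_model(glucose_model, energies)
    bounds = default_activity_bounds(glucose_model, xenobiotic_ids=["tcb_c"])
    refs = {cid: e.reference_activity for cid, e in energies.items()}
    problem = build_tmfa_problem(glucose_model, ThermoConstraintSet(rxn_e, bounds, refs))
    text = problem.to_lp_string()
    for section in ("Maximize", "Subject To", "Bounds", "Binaries", "End"):
        assert section in text
    for name in problem.variable_names():
        assert name in text
    assert text == problem.to_lp_string()


class TestPathwayScreen:
    def test_pathway_with_blocked_step_is_dropped(self):
        from xenoflux.analysis import FvaClassification

        classes = FvaClassification(
            labels={"r1": "essential", "r2": "blocked", "r3": "substitutable"},
            ranges={},
        )
        keep = Pathway(("r1", "r3"), "s", ("t",))
        drop = Pathway(("r1", "r2"), "s", ("t",))
        assert screen_feasible_pathways([keep, drop], classes) == [keep]

    def test_unclassified_reaction_raises(self):
        from xenoflux.analysis import FvaClassification

        classes = FvaClassification(labels={"r1": "essential"}, ranges={})
        with pytest.raises(LookupError):
            screen_feasible_pathways([Pathway(("r1", "rX"), "s", ("t",))], classes)

    def test_nothing_blocked_keeps_everything(self):
        from xenoflux.analysis import FvaClassification

        classes = FvaClassification(
            labels={"r1": "essential", "r2": "substitutable"}, ranges={},
        )
        paths = [Pathway(("r1",), "s", ("t",)), Pathway(("r1", "r2"), "s", ("t",))]
        assert screen_feasible_pathways(paths, classes) == paths
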