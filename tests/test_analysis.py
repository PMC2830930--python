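"""FBA, FVA classification, duals, trade-off curves, secretion."""

import numpy as np
import pytest

from xenoflux.analysis import (
    fba,
    fva_classify,
    growth_yield,
    secretion_profile,
    sensitivity,
    tradeoff_scan,
)
from xenoflux.model import MetabolicModel, Metabolite, Reaction

from _oracles import vertex_enumeration_lp


def _model(reactions, biomass="BIO"):
    mets = {}
    for stoich in (r[1] for r in reactions):
        for m in stoich:
            mets.setdefault(m, Metabolite(m, formula="C", charge=0))
    rxns = {}
    for rid, stoich, lb, ub in reactions:
        exempt = len(stoich) == 1 or rid == biomass
        rxns[rid] = Reaction(rid, stoich, lb, ub, balance_exempt=exempt)
    return MetabolicModel(mets, rxns, biomass if biomass in rxns else None)


@pytest.fixture()
def chain_model():
    """EX -> a -> b -> biomass with yield 0.05 per unit of uptake."""
    return _model([
        ("EX_a", {"a": -1}, -10.0, 1000.0),
        ("T", {"a": -1, "b": 1}, 0.0, 1000.0),
        ("BIO", {"b": -20.0}, 0.0, 1000.0),
    ])


@pytest.fixture()
def branch_model():
    """Two parallel equivalent routes plus a dead-end branch."""
    return _model([
        ("EX_a", {"a": -1}, -10.0, 1000.0),
        ("P1", {"a": -1, "b": 1}, 0.0, 1000.0),
        ("P2", {"a": -1, "b": 1}, 0.0, 1000.0),
        ("DEAD", {"c": -1, "d": 1}, 0.0, 1000.0),
        ("MAKE_C", {"b": -1, "c": 1}, 0.0, 0.0),  # closed: c unreachable
        ("BIO", {"b": -1.0}, 0.0, 1000.0),
    ])


class TestFba:
    def test_chain_solution_matches_closed_form(self, chain_model):
        sol = fba(chain_model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.5, abs=1e-8)

    def test_toy_model_matches_recorded_analytic_optimum(self, toy_model, toy_fixture):
        sol = fba(toy_model)
        assert sol.objective_value == pytest.approx(
            toy_fixture.analytic_biomass_optimum, abs=1e-8
        )

    def test_all_bounds_zero_gives_zero(self, chain_model):
        for rxn in chain_model.reactions.values():
            rxn.lower_bound = rxn.upper_bound = 0.0
        assert fba(chain_model).objective_value == pytest.approx(0.0, abs=1e-12)

    def test_unconsumable_uptake_objective_is_zero(self, toy_model):
        # maximizing uptake (minimizing exchange flux) of a secretion-only species
        sol = fba(toy_model, objective="EX_cl_e", sense="min", want_duals=False)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_mass_balance_residual_below_tolerance(self, toy_model):
        sol = fba(toy_model)
        N, met_ids, rxn_ids = toy_model.stoichiometric_matrix()
        v = np.array([sol.fluxes[r] for r in rxn_ids])
        assert np.max(np.abs(N @ v)) <= 1e-6

    @pytest.mark.parametrize("trial", range(8))
    def test_objective_matches_vertex_enumeration_oracle(self, trial):
        """On random <= 10-reaction networks, FBA equals brute-force vertex search."""
        rng = np.random.default_rng(900 + trial)
        n_mets = int(rng.integers(2, 5))
        n_rxns = int(rng.integers(n_mets + 1, 9))
        N = rng.integers(-2, 3, size=(n_mets, n_rxns)).astype(float)
        lb = np.where(rng.random(n_rxns) < 0.4, -rng.integers(1, 10, n_rxns), 0.0).astype(float)
        ub = rng.integers(1, 10, n_rxns).astype(float)
        mets = [f"m{i}" for i in range(n_mets)]
        reactions = []
        for j in range(n_rxns):
            stoich = {mets[i]: N[i, j] for i in range(n_mets) if N[i, j] != 0}
            if not stoich:
                stoich = {mets[0]: 0.0}
            reactions.append((f"r{j}", stoich, lb[j], ub[j]))
        model = _model(reactions, biomass="r0")
        sol = fba(model, objective="r0", want_duals=False)
        c = np.zeros(n_rxns)
        c[0] = 1.0
        # oracle works on the same N the model reports, not the raw draw
        Nm, _, rxn_ids = model.stoichiometric_matrix()
        order = [rxn_ids.index(f"r{j}") for j in range(n_rxns)]
        best, _ = vertex_enumeration_lp(
            Nm.toarray()[:, order], lb, ub, c
        )
        if best is None:
            assert sol.status != "optimal"
        else:
            assert sol.objective_value == pytest.approx(best, abs=1e-8)


class TestGrowthYield:
    def test_printed_style_yield(self):
        sol = fba.__wrapped__ if hasattr(fba, "__wrapped__") else None
        from xenoflux.analysis import FluxSolution

        s = FluxSolution("BIO", 0.2, {"EX_x": -4.2, "BIO": 0.2}, "optimal")
        assert growth_yield(s, "EX_x") == pytest.approx(0.048, abs=5e-4)

    def test_zero_biomass_yields_zero(self):
        from xenoflux.analysis import FluxSolution

        s = FluxSolution("BIO", 0.0, {"EX_x": -4.2}, "optimal")
        assert growth_yield(s, "EX_x") == 0.0

    def test_zero_uptake_with_growth_is_undefined(self):
        from xenoflux.analysis import FluxSolution

        s = FluxSolution("BIO", 0.2, {"EX_x": 0.0}, "optimal")
        assert growth_yield(s, "EX_x") is None

    def test_chain_yield_matches_construction(self, chain_model):
        sol = fba(chain_model)
        assert growth_yield(sol, "EX_a") == pytest.approx(0.05, abs=1e-9)


class TestFvaClassify:
    def test_chain_reactions_are_all_essential(self, chain_model):
        result = fva_classify(chain_model)
        assert all(result.labels[r] == "essential" for r in ("EX_a", "T", "BIO"))

    def test_parallel_branches_are_substitutable(self, branch_model):
        result = fva_classify(branch_model)
        assert result.labels["P1"] == "substitutable"
        assert result.labels["P2"] == "substitutable"

    def test_dead_end_reaction_is_blocked(self, branch_model):
        result = fva_classify(branch_model)
        assert result.labels["DEAD"] == "blocked"

    def test_partition_is_exhaustive_and_exclusive(self, toy_model):
        result = fva_classify(toy_model)
        assert set(result.labels) == set(toy_model.reactions)
        assert set(result.labels.values()) <= {"essential", "substitutable", "blocked"}

    def test_labels_match_cobra_variability_oracle(self, toy_model, tmp_path):
        """Flux ranges agree with an independent FVA implementation."""
        import warnings

        import cobra
        from cobra.flux_analysis import flux_variability_analysis

        from xenoflux.model import write_sbml

        path = tmp_path / "m.xml"
        write_sbml(toy_model, path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = cobra.io.read_sbml_model(str(path))
            cm.objective = "BIOMASS"
            # same objective-fixing convention as ours: optimum scaled by 1-1e-9
            ranges = flux_variability_analysis(cm, fraction_of_optimum=1.0 - 1e-9)
        ours = fva_classify(toy_model)

        def label(lo, hi, eps=1e-6):
            # eps above both solvers' numerical noise so the comparison tests
            # the analysis, not round-off in either backend
            if lo > eps or hi < -eps:
                return "essential"
            if abs(lo) <= eps and abs(hi) <= eps:
                return "blocked"
            return "substitutable"

        for rid in ours.labels:
            theirs = label(ranges.loc[rid, "minimum"], ranges.loc[rid, "maximum"])
            mine = label(*ours.ranges[rid])
            assert mine == theirs, (rid, ours.ranges[rid],
                                    tuple(ranges.loc[rid]))


class TestSensitivity:
    def test_binding_nutrient_prices_negative(self, chain_model):
        report = sensitivity(chain_model)
        assert report.shadow_prices["a"] < 0  # uptake bound is active

    def test_nonbinding_exchange_prices_zero(self, toy_model):
        report = sensitivity(toy_model, degeneracy_check=False)
        assert report.shadow_prices["nh4_e"] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_optimum_sets_the_caveat(self, toy_model):
        # ATPH/ATPM and the aconitase pair guarantee alternative optima
        report = sensitivity(toy_model, degeneracy_check=True)
        assert report.basis_caveat


class TestTradeoff:
    def test_minimize_mode_is_nondecreasing_and_convex(self, toy_model):
        top = fba(toy_model).objective_value
        grid = list(np.linspace(0.0, top, 7))
        curve = tradeoff_scan(toy_model, grid, "EX_glc_e", mode="minimize")
        ok = [u for u, s in zip(curve.uptake, curve.status) if s == "optimal"]
        assert len(ok) == len(grid)
        diffs = np.diff(ok)
        assert np.all(diffs >= -1e-9)
        assert np.all(np.diff(diffs) >= -1e-7)  # convexity: slopes non-decreasing

    def test_zero_biomass_needs_zero_uptake(self, toy_model):
        curve = tradeoff_scan(toy_model, [0.0], "EX_glc_e", mode="minimize")
        assert curve.uptake[0] == pytest.approx(0.0, abs=1e-9)

    def test_maximize_mode_at_top_matches_fba_uptake(self, toy_model):
        sol = fba(toy_model)
        curve = tradeoff_scan(toy_model, [sol.objective_value], "EX_glc_e", mode="maximize")
        assert curve.uptake[0] >= abs(sol.fluxes["EX_glc_e"]) - 1e-6

    def test_infeasible_grid_points_are_flagged(self, toy_model):
        top = fba(toy_model).objective_value
        curve = tradeoff_scan(toy_model, [top * 2.0], "EX_glc_e", mode="minimize")
        assert curve.status[0] == "infeasible"


class TestSecretion:
    def test_optimal_glucose_growth_secretes_no_carbon(self, toy_model):
        sol = fba(toy_model)
        assert secretion_profile(sol, toy_model) == []

    def test_forced_suboptimal_growth_overflows_pyruvate(self, toy_model):
        sol = fba(toy_model)
        sub = toy_model.copy()
        sub.reactions["BIOMASS"].upper_bound = 0.5 * sol.objective_value
        sub.reactions["EX_glc_e"].lower_bound = -10.0
        sub.reactions["EX_glc_e"].upper_bound = -10.0  # force full uptake
        sub_sol = fba(sub)
        secreted = secretion_profile(sub_sol, sub)
        assert secreted, "expected carbon overflow at forced sub-optimal growth"
        assert "EX_co2_e" not in secreted  # common by-products are excluded

    def test_closed_exchanges_secrete_nothing(self, toy_model):
        closed = toy_model.copy()
        for ex in closed.exchange_reaction_ids:
            closed.reactions[ex].lower_bound = 0.0
            closed.reactions[ex].upper_bound = 0.0
        sol = fba(closed)
        assert secretion_profile(sol, closed) == []
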