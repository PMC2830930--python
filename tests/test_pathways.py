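"""Pathway enumeration, screening, and overall-reaction composition."""

import numpy as np
import pytest

from xenoflux.pathways import (
    CompositionError,
    OverallReaction,
    Pathway,
    PathwayScreenCriteria,
    classify_by_overall,
    enumerate_pathways,
    overall_reaction,
    pathways_to_tsv,
    reducing_equivalents,
    screen_pathways,
)
from xenoflux.rules import (
    Compound,
    CompoundRegistry,
    NetworkReaction,
    ReactionNetwork,
    canonicalize_compound,
)

from _oracles import brute_force_pathways, summation_overall

# Table-1 reference stoichiometries (canonical SMILES ids for the organics)
TCB = "Clc1ccc(Cl)c(Cl)c1"
GLYCOLATE = "O=C([O-])CO"
SUCCINATE = "O=C([O-])CCC(=O)[O-]"
CATECHOL = "Oc1ccccc1O"

KNOWN_OVERALL = {
    TCB: -1.0, "O2": -2.0, "NADH": -1.0, "H2O": -3.0, "e-": -2.0,
    "NAD+": 1.0, "Cl-": 3.0, "H+": 3.0, GLYCOLATE: 1.0, SUCCINATE: 1.0,
}
CATECHOL_OVERALL = {
    TCB: -1.0, "H2O": -2.0, "e-": -2.0, "Cl-": 3.0, "H+": 1.0, CATECHOL: 1.0,
}


def _net(reactions, extra_compounds=()):
    compounds = {cid: Compound(cid, cid) for cid in extra_compounds}
    for stoich in reactions.values():
        for cid in stoich:
            if cid not in ("O2", "H2O", "H+", "Cl-", "e-", "NADH", "NAD+"):
                compounds[cid] = Compound(cid, cid)
    rxns = {
        rid: NetworkReaction(rid, stoich, rule_id="hand", generation=1)
        for rid, stoich in reactions.items()
    }
    return ReactionNetwork(compounds, rxns, seed_ids=[], max_generation=1)


# isomer family keeps hand networks balanced without cofactors
HEXANES = ["CCCCCC", "CCCC(C)C", "CCC(C)CC", "CC(C)C(C)C", "CC(C)(C)CC"]
HEX = [canonicalize_compound(s).id for s in HEXANES]
assert len(set(HEX)) == 5


@pytest.fixture()
def chain_network():
    a, b, c, d = HEX[:4]
    return _net({"r1": {a: -1, b: 1}, "r2": {b: -1, c: 1}, "r3": {c: -1, d: 1}}), (a, d)


@pytest.fixture()
def diamond_network():
    s, a, b, t = HEX[:4]
    return _net({
        "r1": {s: -1, a: 1}, "r2": {a: -1, t: 1},
        "r3": {s: -1, b: 1}, "r4": {b: -1, t: 1},
    }), (s, t)


class TestEnumerate:
    def test_linear_chain_has_exactly_one_pathway(self, chain_network):
        net, (src, dst) = chain_network
        paths = enumerate_pathways(net, src, [dst], max_len=3)
        assert len(paths) == 1
        assert paths[0].reactions == ("r1", "r2", "r3")
        assert enumerate_pathways(net, src, [dst], max_len=2) == []

    def test_diamond_gives_two_pathways_and_length_cap_zero(self, diamond_network):
        net, (src, dst) = diamond_network
        assert len(enumerate_pathways(net, src, [dst], max_len=2)) == 2
        assert enumerate_pathways(net, src, [dst], max_len=1) == []

    def test_source_as_sink_yields_nothing(self, diamond_network):
        net, (src, _) = diamond_network
        assert enumerate_pathways(net, src, [src], max_len=3) == []

    def test_missing_source_or_sink_raises(self, chain_network):
        net, (src, dst) = chain_network
        with pytest.raises(LookupError):
            enumerate_pathways(net, "CCCCCCCCCC", [dst], max_len=2)
        with pytest.raises(LookupError):
            enumerate_pathways(net, src, ["CCCCCCCCCC"], max_len=2)

    @pytest.mark.parametrize("trial", range(12))
    def test_counts_match_exhaustive_search_on_random_networks(self, trial):
        rng = np.random.default_rng(500 + trial)
        n_compounds = int(rng.integers(5, 13))
        compounds = HEX + [canonicalize_compound("C" * k).id for k in range(1, 8)]
        compounds = compounds[:n_compounds]
        reactions = {}
        for i in range(int(rng.integers(4, 14))):
            sub, prod = rng.choice(len(compounds), size=2, replace=False)
            stoich = {compounds[sub]: -1.0, compounds[prod]: 1.0}
            if rng.random() < 0.3:  # occasional two-product reaction
                extra = int(rng.integers(0, len(compounds)))
                if compounds[extra] not in stoich:
                    stoich[compounds[extra]] = 1.0
            reactions[f"r{i}"] = stoich
        net = _net(reactions, extra_compounds=compounds)
        source = compounds[0]
        sinks = {str(s) for s in rng.choice(compounds[1:], size=2, replace=False)}
        max_len = int(rng.integers(2, 6))
        got = enumerate_pathways(net, source, sinks, max_len)
        expected = brute_force_pathways(reactions, source, sinks, max_len, cofactors=set())
        assert {p.reactions for p in got} == expected

    def test_ordering_is_deterministic(self, diamond_network):
        net, (src, dst) = diamond_network
        first = [p.reactions for p in enumerate_pathways(net, src, [dst], 2)]
        second = [p.reactions for p in enumerate_pathways(net, src, [dst], 2)]
        assert first == second == sorted(first)


class TestScreen:
    def _pathways(self, lengths):
        return [
            Pathway(tuple(f"r{i}_{j}" for j in range(n)), "src", ("dst",))
            for i, n in enumerate(lengths)
        ]

    def test_length_screen_matches_hand_count(self):
        paths = self._pathways([1, 2, 3, 4, 5])
        kept = screen_pathways(paths, PathwayScreenCriteria(max_length=3))
        assert len(kept) == 3

    def test_tightening_max_length_never_retains_more(self):
        paths = self._pathways([1, 2, 2, 3, 5, 6])
        counts = [
            len(screen_pathways(paths, PathwayScreenCriteria(max_length=k)))
            for k in range(6, 0, -1)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_all_criteria_disabled_returns_input(self):
        paths = self._pathways([2, 9])
        assert screen_pathways(paths, PathwayScreenCriteria()) == paths

    def test_unknown_intermediate_removes_pathway(self, chain_network):
        net, (src, dst) = chain_network
        paths = enumerate_pathways(net, src, [dst], 3)
        registry = CompoundRegistry()
        for cid in net.compounds:
            registry.add(cid, known_registry=(cid != HEX[1]))  # one unknown hop
        criteria = PathwayScreenCriteria(require_known_intermediates=True)
        assert screen_pathways(paths, criteria, registry, net) == []
        registry.add(HEX[1], known_registry=True)
        assert screen_pathways(paths, criteria, registry, net) == paths

    def test_native_product_screen(self, diamond_network):
        net, (src, dst) = diamond_network
        paths = enumerate_pathways(net, src, [dst], 2)
        registry = CompoundRegistry()
        registry.add(dst, native_to_model=False)
        criteria = PathwayScreenCriteria(require_native_products=True)
        assert screen_pathways(paths, criteria, registry, net) == []


class TestOverallReaction:
    def test_known_route_composes_to_reference_stoichiometry(self, full_network, known_route):
        ov = overall_reaction(known_route, full_network)
        assert ov.stoich == pytest.approx(KNOWN_OVERALL)
        assert ov.stoich["Cl-"] == 3.0
        assert ov.stoich["e-"] == -2.0

    def test_catechol_route_composes_to_reference_stoichiometry(self, full_network, catechol_route):
        ov = overall_reaction(catechol_route, full_network)
        assert ov.stoich == pytest.approx(CATECHOL_OVERALL)

    def test_single_reaction_pathway_equals_the_reaction(self, full_network, known_route):
        rid = known_route.reactions[0]
        rxn = full_network.reactions[rid]
        p = Pathway((rid,), known_route.source, tuple(rxn.products()))
        ov = overall_reaction(p, full_network)
        assert ov.stoich == pytest.approx(dict(rxn.stoich))

    def test_composition_matches_independent_summation(self, full_network, known_route):
        ov = overall_reaction(known_route, full_network)
        expected = summation_overall(
            [full_network.reactions[r].stoich for r in known_route.reactions]
        )
        assert ov.stoich == pytest.approx(expected)

    def test_no_internal_intermediate_survives(self, full_network, known_route):
        ov = overall_reaction(known_route, full_network)
        intermediates = set()
        for rid in known_route.reactions[:-1]:
            intermediates.update(full_network.reactions[rid].products())
        intermediates -= set(known_route.terminal_products)
        assert not (intermediates & set(ov.stoich))

    def test_missing_reaction_raises(self, full_network):
        p = Pathway(("nope",), "x", ("y",))
        with pytest.raises(LookupError):
            overall_reaction(p, full_network)


class TestReducingEquivalents:
    def test_known_route_needs_two(self, full_network, known_route):
        ov = overall_reaction(known_route, full_network)
        assert reducing_equivalents(ov) == pytest.approx(2.0)  # 2 e-/2 + 1 NADH

    def test_catechol_route_needs_one(self, full_network, catechol_route):
        ov = overall_reaction(catechol_route, full_network)
        assert reducing_equivalents(ov) == pytest.approx(1.0)  # 2 e-/2 + 0 NADH

    def test_redox_free_overall_is_zero(self):
        ov = OverallReaction({HEX[0]: -1.0, HEX[1]: 1.0})
        assert reducing_equivalents(ov) == 0.0

    def test_invariant_across_group_members(self, full_network, known_route):
        groups = classify_by_overall([known_route, known_route], full_network)
        for ov, members in groups.items():
            values = {reducing_equivalents(overall_reaction(p, full_network))
                      for p in members}
            assert len(values) == 1


class TestClassify:
    def test_fixture_routes_fall_in_distinct_groups(self, full_network, known_route, catechol_route):
        groups = classify_by_overall([known_route, catechol_route], full_network)
        assert len(groups) == 2

    def test_duplicates_stay_in_one_group(self, full_network, known_route):
        groups = classify_by_overall([known_route, known_route], full_network)
        assert len(groups) == 1
        assert len(next(iter(groups.values()))) == 2

    def test_empty_input_gives_empty_mapping(self, full_network):
        assert classify_by_overall([], full_network) == {}


def test_pathway_tsv_export(tmp_path, full_network, known_route):
    out = tmp_path / "paths.tsv"
    pathways_to_tsv([known_route], full_network, out)
    lines = out.read_text().strip().splitlines()
    assert lines[0].startswith("pathway_id")
    assert ";".join(known_route.reactions) in lines[1]
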