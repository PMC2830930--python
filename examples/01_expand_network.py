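"""Expand a biodegradation reaction network from 1,2,4-trichlorobenzene.

The shipped rule set generalizes the enzyme chemistry of chloroaromatic
degradation (dioxygenation, dehydrogenation, ring cleavage, two kinds of
dechlorination, tautomerization, enoate reduction, C-C hydrolysis).
Applying it iteratively to the seed generates every reachable compound,
one generation per wave.
"""

from xenoflux.fixtures import KNOWN_ROUTE_CHAIN, find_route, make_toy_rules_and_registry
from xenoflux.rules import expand_network

rules, registry, seed = make_toy_rules_and_registry()
print(f"seed compound: {seed.name} ({seed.id})")
print(f"{len(rules)} reaction rules, e.g. {rules[0].rule_id} (EC {rules[0].ec_prefix})")

for generations in (2, 5, 10):
    net = expand_network([seed], rules, generations)
    print(f"after {generations:>2} generations: "
          f"{len(net.compounds):>4} compounds, {len(net.reactions):>4} reactions")

net = expand_network([seed], rules, 10)
route = find_route(net, KNOWN_ROUTE_CHAIN)
print(f"\nthe experimentally known degradation route is present: "
      f"{route.length} steps, ending in {', '.join(route.terminal_products)}")
print("(glycolate and succinate are the entry points into central metabolism)")
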