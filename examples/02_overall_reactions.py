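"""Enumerate degradation pathways, screen them, and compose net reactions.

Thousands of raw pathways collapse into a handful of distinct overall
reactions once intermediates are cancelled; the reducing-equivalent count
(electrons/2 + net NAD(P)H) summarizes what each route costs the cell.
"""

from xenoflux.fixtures import make_toy_rules_and_registry
from xenoflux.pathways import (
    PathwayScreenCriteria,
    classify_by_overall,
    enumerate_pathways,
    equation_string,
    screen_pathways,
)
from xenoflux.rules import expand_network

rules, registry, seed = make_toy_rules_and_registry()
network = expand_network([seed], rules, 10)
sinks = [s for s in registry.native_ids() if s in network.compounds]

pathways = enumerate_pathways(network, seed.id, sinks, max_len=15)
print(f"{len(pathways)} simple pathways from the seed to a native sink (<= 15 steps)")

criteria = PathwayScreenCriteria(
    max_length=9,  # no longer than the known route
    require_known_intermediates=True,
    require_native_products=True,
)
screened = screen_pathways(pathways, criteria, registry, network)
print(f"{len(screened)} remain after the catalogued-intermediate and native-product screens")

names = {
    "Clc1ccc(Cl)c(Cl)c1": "1,2,4-TCB",
    "O=C([O-])CO": "glycolate",
    "O=C([O-])CCC(=O)[O-]": "succinate",
    "Oc1ccccc1O": "catechol",
}
print("\ndistinct overall reactions (net stoichiometry of the whole route):")
for overall, members in classify_by_overall(screened, network).items():
    print(f"  [{len(members)} pathway(s)] {equation_string(overall, names)}")
    print(f"     reducing equivalents required: {overall.reducing_equivalents:g} "
          f"(= {overall.electrons:g} e-/2 + {overall.net_nadph:g} NAD(P)H)")
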