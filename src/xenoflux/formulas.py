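"""Elemental composition arithmetic shared across the package.

Compositions are plain ``{element: count}`` dicts.  Alongside real element
symbols we allow single-letter placeholder symbols for conserved cofactor
moieties (``Q`` nicotinamide core, ``Z`` NADP core, ``R`` CoA thiol core,
``A`` adenosine diphosphate core, ``P`` phosphate unit).  These behave like
ordinary elements in balance checks, which keeps toy models and reaction
rules exactly balanceable without carrying full cofactor structures.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Mapping

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: ids treated as electrons: no atoms, formal charge -1
ELECTRON_IDS = frozenset({"e-", "elec", "elec_c", "elec_e", "elec_p"})


def parse_formula(formula: str) -> Counter:
    """Parse ``C6H12O6``-style strings into element counts.

    An empty string (massless species such as the electron or photon) parses
    to an empty composition.
    """
    if formula is None:
        raise ValueError("formula is None")
    formula = formula.strip()
    counts: Counter = Counter()
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if not m or m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        counts[m.group(1)] += int(m.group(2) or 1)
        pos = m.end()
    return counts


def formula_string(counts: Mapping[str, float]) -> str:
    """Render counts back to a Hill-ish formula string (C, H, then others)."""

    def fmt(el: str, n: float) -> str:
        if abs(n - round(n)) < 1e-9:
            n = int(round(n))
        return f"{el}{'' if n == 1 else n}"

    keys = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(fmt(k, counts[k]) for k in keys if abs(counts[k]) > 1e-12)


def smiles_composition(smiles: str) -> tuple[Counter, int]:
    """Element counts (including hydrogens) and net formal charge of a SMILES."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    counts: Counter = Counter()
    charge = 0
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs()
        charge += atom.GetFormalCharge()
    if counts["H"] == 0:
        del counts["H"]
    return counts, charge


def balance_residual(
    stoich: Mapping[str, float],
    composition: Mapping[str, Mapping[str, float]],
    charges: Mapping[str, float],
) -> tuple[Counter, float]:
    """Net element counts and net charge of a reaction.

    ``composition``/``charges`` map species id to its element counts and
    formal charge.  Electrons carry charge -1 and no atoms.  A balanced
    reaction returns an (empty, 0.0) residual.
    """
    residual: Counter = Counter()
    net_charge = 0.0
    for species, coeff in stoich.items():
        comp = composition[species]
        for el, n in comp.items():
            residual[el] += coeff * n
        net_charge += coeff * charges[species]
    residual = Counter({el: n for el, n in residual.items() if abs(n) > 1e-9})
    if abs(net_charge) < 1e-9:
        net_charge = 0.0
    return residual, net_charge


def is_balanced(
    stoich: Mapping[str, float],
    composition: Mapping[str, Mapping[str, float]],
    charges: Mapping[str, float],
) -> bool:
    residual, net_charge = balance_residual(stoich, composition, charges)
    return not residual and net_charge == 0.0
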