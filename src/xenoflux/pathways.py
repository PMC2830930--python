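"""Pathway enumeration, screening, and overall-reaction composition.

A pathway is an ordered sequence of network reactions leading from a seed
xenobiotic to a compound whose intermediary metabolism is known (a "sink").
Summing the member stoichiometries and cancelling every species that is
both produced and consumed internally yields the overall reaction — the
pathway's net stoichiometry — which groups the thousands of enumerated
routes into a handful of distinct net chemistries.

The reducing-equivalent count of an overall reaction is half the number of
electrons consumed plus the net number of NAD(P)H consumed; it is the main
axis along which degradation routes trade biomass yield for reducing power.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .formulas import balance_residual, parse_formula, smiles_composition
from .rules import COFACTORS, CompoundRegistry, NetworkReaction, ReactionNetwork

__all__ = [
    "OverallReaction",
    "Pathway",
    "PathwayScreenCriteria",
    "classify_by_overall",
    "enumerate_pathways",
    "equation_string",
    "overall_reaction",
    "pathways_to_tsv",
    "reducing_equivalents",
    "screen_pathways",
]

#: species never treated as pathway-connecting intermediates
DEFAULT_COFACTOR_IDS = frozenset(COFACTORS)

NADH_IDS = ("NADH", "NADPH")
NAD_IDS = ("NAD+", "NADP+")


class CompositionError(ValueError):
    """Overall reaction failed element/charge balance."""


@dataclass(frozen=True)
class Pathway:
    """Ordered reaction-id sequence from a source compound to a sink."""

    reactions: tuple[str, ...]
    source: str
    terminal_products: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.reactions)


@dataclass(frozen=True)
class PathwayScreenCriteria:
    max_length: Optional[int] = None
    require_known_intermediates: bool = False
    require_native_products: bool = False

    def __post_init__(self):
        if self.max_length is not None and self.max_length < 1:
            raise ValueError("max_length must be >= 1")


@dataclass(frozen=True, eq=False)
class OverallReaction:
    """Net stoichiometry of a pathway after intermediate cancellation.

    Identity (equality/hash) is the canonical sorted stoichiometry, so two
    pathways with the same net chemistry compare equal regardless of label.
    """

    stoich: Mapping[str, float]
    label: Optional[str] = None

    def __eq__(self, other) -> bool:
        return isinstance(other, OverallReaction) and self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    @property
    def electrons(self) -> float:
        """Electrons consumed (0 when electrons are produced or absent)."""
        return max(0.0, -self.stoich.get("e-", 0.0))

    @property
    def net_nadph(self) -> float:
        """Net NAD(P)H consumed."""
        return -sum(self.stoich.get(s, 0.0) for s in NADH_IDS)

    @property
    def o2_consumed(self) -> float:
        return max(0.0, -self.stoich.get("O2", 0.0))

    @property
    def reducing_equivalents(self) -> float:
        return self.electrons / 2.0 + self.net_nadph

    def key(self) -> tuple:
        return tuple(sorted((s, round(c, 9)) for s, c in self.stoich.items()))


def enumerate_pathways(
    network: ReactionNetwork,
    source: str,
    sinks: Iterable[str],
    max_len: int,
    cofactor_ids: frozenset[str] = DEFAULT_COFACTOR_IDS,
) -> list[Pathway]:
    """All simple reaction sequences of length <= ``max_len`` from source to a sink.

    The chain connects through non-cofactor compounds only; no compound is
    revisited (simple paths), and a pathway terminates the first time it
    reaches a sink.  Ordering is deterministic: by length, then by the
    reaction-id sequence.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if source not in network.compounds:
        raise LookupError(f"source {source!r} not in network")
    sinks = set(sinks)
    for s in sinks:
        if s not in network.compounds:
            raise LookupError(f"sink {s!r} not in network")

    consumers: dict[str, list[NetworkReaction]] = {}
    for rxn in sorted(network.reactions.values(), key=lambda r: r.id):
        for cid, coeff in rxn.stoich.items():
            if coeff < 0 and cid not in cofactor_ids:
                consumers.setdefault(cid, []).append(rxn)

    found: list[Pathway] = []

    def walk(current: str, visited: set[str], trail: tuple[str, ...]) -> None:
        if len(trail) >= max_len:
            return
        for rxn in consumers.get(current, ()):
            products = [p for p in rxn.products() if p not in cofactor_ids]
            for nxt in products:
                if nxt in visited:
                    continue
                new_trail = trail + (rxn.id,)
                if nxt in sinks:
                    found.append(Pathway(new_trail, source, tuple(sorted(products))))
                else:
                    walk(nxt, visited | {nxt}, new_trail)

    walk(source, {source}, ())
    found.sort(key=lambda p: (p.length, p.reactions))
    return found


def screen_pathways(
    pathways: Sequence[Pathway],
    criteria: PathwayScreenCriteria,
    registry: Optional[CompoundRegistry] = None,
    network: Optional[ReactionNetwork] = None,
    cofactor_ids: frozenset[str] = DEFAULT_COFACTOR_IDS,
) -> list[Pathway]:
    """Retain pathways meeting every enabled criterion (order-independent)."""
    if (criteria.require_known_intermediates or criteria.require_native_products) and registry is None:
        raise ValueError("registry required for the enabled screens")
    if criteria.require_known_intermediates and network is None:
        raise ValueError("network required to resolve pathway intermediates")

    def passes(p: Pathway) -> bool:
        if criteria.max_length is not None and p.length > criteria.max_length:
            return False
        if criteria.require_known_intermediates:
            for cid in pathway_compounds(p, network, cofactor_ids):
                if not registry.known(cid):
                    return False
        if criteria.require_native_products:
            for cid in p.terminal_products:
                if not registry.native(cid):
                    return False
        return True

    return [p for p in pathways if passes(p)]


def pathway_compounds(
    pathway: Pathway, network: ReactionNetwork,
    cofactor_ids: frozenset[str] = DEFAULT_COFACTOR_IDS,
) -> list[str]:
    """Every non-cofactor compound a pathway touches (source, intermediates, products)."""
    seen: set[str] = set()
    for rid in pathway.reactions:
        for cid in network.reactions[rid].stoich:
            if cid not in cofactor_ids:
                seen.add(cid)
    return sorted(seen)


def overall_reaction(
    pathway: Pathway,
    network: ReactionNetwork,
    label: Optional[str] = None,
    cofactor_ids: frozenset[str] = DEFAULT_COFACTOR_IDS,
) -> OverallReaction:
    """Sum member stoichiometries and cancel internally recycled species.

    The result is element- and charge-balanced; an imbalance (which can only
    come from a corrupted network) raises :class:`CompositionError` naming
    the offending element.
    """
    net: Counter = Counter()
    for rid in pathway.reactions:
        if rid not in network.reactions:
            raise LookupError(f"pathway reaction {rid!r} not in network")
        for cid, coeff in network.reactions[rid].stoich.items():
            net[cid] += coeff
    stoich = {cid: c for cid, c in net.items() if abs(c) > 1e-9}

    comp, charges = {}, {}
    for cid in stoich:
        if cid in COFACTORS:
            formula, charge = COFACTORS[cid]
            comp[cid] = parse_formula(formula)
            charges[cid] = charge
        else:
            comp[cid], charges[cid] = smiles_composition(cid)
    residual, net_charge = balance_residual(stoich, comp, charges)
    if residual:
        element = sorted(residual)[0]
        raise CompositionError(f"overall reaction unbalanced in element {element}: {dict(residual)}")
    if net_charge:
        raise CompositionError(f"overall reaction carries net charge {net_charge}")
    return OverallReaction(stoich=stoich, label=label)


def reducing_equivalents(overall: OverallReaction) -> float:
    """Half the electrons consumed plus the net NAD(P)H consumed."""
    return overall.reducing_equivalents


def classify_by_overall(
    pathways: Sequence[Pathway],
    network: ReactionNetwork,
    cofactor_ids: frozenset[str] = DEFAULT_COFACTOR_IDS,
) -> dict[OverallReaction, list[Pathway]]:
    """Group pathways by identical net stoichiometry (canonical sorted keys)."""
    groups: dict[tuple, list[Pathway]] = {}
    reps: dict[tuple, OverallReaction] = {}
    for p in pathways:
        ov = overall_reaction(p, network, cofactor_ids=cofactor_ids)
        k = ov.key()
        groups.setdefault(k, []).append(p)
        reps.setdefault(k, ov)
    return {reps[k]: groups[k] for k in sorted(groups)}


def equation_string(
    overall: OverallReaction,
    names: Optional[Mapping[str, str]] = None,
) -> str:
    """Human-readable ``A + (2) B -> C`` rendering of an overall reaction."""
    names = names or {}

    def side(items):
        parts = []
        for cid, coeff in items:
            mag = abs(coeff)
            coeff_s = "" if abs(mag - 1) < 1e-9 else f"({mag:g}) "
            parts.append(coeff_s + names.get(cid, cid))
        return " + ".join(parts)

    lhs = sorted(((c, v) for c, v in overall.stoich.items() if v < 0), key=lambda t: t[0])
    rhs = sorted(((c, v) for c, v in overall.stoich.items() if v > 0), key=lambda t: t[0])
    return f"{side(lhs)} -> {side(rhs)}"


def pathways_to_tsv(
    pathways: Sequence[Pathway],
    network: ReactionNetwork,
    path,
    labels: Optional[Mapping[tuple, str]] = None,
) -> None:
    """TSV export: pathway id, ordered reaction ids, length, overall label."""
    labels = labels or {}
    with open(path, "w") as fh:
        fh.write("pathway_id\treactions\tlength\toverall_label\n")
        for i, p in enumerate(pathways):
            ov = overall_reaction(p, network)
            fh.write(f"P{i:05d}\t{';'.join(p.reactions)}\t{p.length}\t{labels.get(ov.key(), '')}\n")
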