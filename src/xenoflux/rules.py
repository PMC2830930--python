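"""Generalized enzyme-reaction rules and iterative network expansion.

A reaction rule is an EC-third-level generalization of an enzymatic
transformation: a substructure pattern, a structure rewrite, and a fixed
cofactor stoichiometry.  Applying the rule set iteratively to a seed
molecule grows a reaction network of hypothetical biodegradation chemistry,
one generation per wave of newly created compounds, until closure or a
generation cap.

Compounds are identified by canonical SMILES, so the same molecule written
two ways deduplicates; reactions deduplicate on their full stoichiometry.
Every generated reaction is element- and charge-balanced by construction
(electrons are a massless bookkeeping species of charge -1), and this is
enforced, not assumed: an imbalanced rewrite raises ``RuleApplicationError``.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .formulas import balance_residual, parse_formula, smiles_composition

__all__ = [
    "COFACTORS",
    "Compound",
    "CompoundRegistry",
    "NetworkReaction",
    "ReactionNetwork",
    "ReactionRule",
    "RegistryEntry",
    "RuleApplicationError",
    "StructureParseError",
    "apply_rule",
    "canonicalize_compound",
    "expand_network",
    "toy_rule_set",
]

#: Auxiliary species matched by fixed id in rule stoichiometries.  Formulas
#: use the placeholder-element convention of :mod:`xenoflux.formulas`.
COFACTORS: dict[str, tuple[str, int]] = {
    "O2": ("O2", 0),
    "H2": ("H2", 0),
    "H2O": ("H2O", 0),
    "H+": ("H", 1),
    "Cl-": ("Cl", -1),
    "e-": ("", -1),
    "NADH": ("QH", 0),
    "NAD+": ("Q", 1),
    "NADPH": ("ZH", 0),
    "NADP+": ("Z", 1),
    "CO2": ("CO2", 0),
    "CoA": ("RH", 0),
    "Pi": ("P", 0),
}


class StructureParseError(ValueError):
    """Raised when a SMILES string does not describe a valid molecule."""

    def __init__(self, structure: str):
        self.structure = structure
        super().__init__(f"unparsable structure: {structure!r}")


class RuleApplicationError(RuntimeError):
    """A rule rewrite produced an invalid or imbalanced reaction."""

    def __init__(self, rule_id: str, site: str, reason: str):
        self.rule_id = rule_id
        self.site = site
        super().__init__(f"rule {rule_id!r} failed on {site!r}: {reason}")


@dataclass(frozen=True)
class Compound:
    """A molecule keyed by its canonical SMILES."""

    id: str
    structure: str
    name: Optional[str] = None

    def __post_init__(self):
        if self.id != self.structure:
            raise ValueError("Compound id must equal its canonical structure")


@dataclass(frozen=True)
class RegistryEntry:
    known_registry: bool = False
    native_to_model: bool = False
    model_metabolite_id: Optional[str] = None
    name: Optional[str] = None


class CompoundRegistry:
    """Canonical-SMILES-keyed flags: catalogued? native? model metabolite?"""

    def __init__(self, entries: Optional[Mapping[str, RegistryEntry]] = None):
        self.entries: dict[str, RegistryEntry] = dict(entries or {})

    def add(self, structure: str, **kwargs) -> None:
        cid = canonicalize_compound(structure).id
        self.entries[cid] = RegistryEntry(**kwargs)

    def get(self, compound_id: str) -> RegistryEntry:
        return self.entries.get(compound_id, RegistryEntry())

    def known(self, compound_id: str) -> bool:
        return self.get(compound_id).known_registry

    def native(self, compound_id: str) -> bool:
        return self.get(compound_id).native_to_model

    def native_ids(self) -> list[str]:
        return sorted(c for c, e in self.entries.items() if e.native_to_model)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("smiles\tname\tknown_registry\tnative_to_model\tmodel_metabolite_id\n")
            for cid in sorted(self.entries):
                e = self.entries[cid]
                fh.write(
                    f"{cid}\t{e.name or ''}\t{int(e.known_registry)}"
                    f"\t{int(e.native_to_model)}\t{e.model_metabolite_id or ''}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "CompoundRegistry":
        reg = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                reg.add(
                    row["smiles"],
                    name=row.get("name") or None,
                    known_registry=bool(int(row.get("known_registry", "0") or 0)),
                    native_to_model=bool(int(row.get("native_to_model", "0") or 0)),
                    model_metabolite_id=row.get("model_metabolite_id") or None,
                )
        return reg


@dataclass
class ReactionRule:
    """EC-third-level reaction rule: pattern rewrite plus cofactor stoichiometry.

    ``smarts`` is an RDKit reaction SMARTS ``pattern>>rewrite`` acting on the
    single organic substrate; ``cofactors`` maps auxiliary species ids to
    signed coefficients (negative = consumed).  ``filter_smarts`` optionally
    restricts application to molecules containing a substructure.
    """

    rule_id: str
    ec_prefix: str
    smarts: str
    cofactors: Mapping[str, float] = field(default_factory=dict)
    reversible: bool = False
    filter_smarts: Optional[str] = None
    name: Optional[str] = None
    _rxn: object = field(default=None, repr=False, compare=False)
    _filter: object = field(default=None, repr=False, compare=False)

    def reaction(self):
        if self._rxn is None:
            from rdkit.Chem import AllChem

            rxn = AllChem.ReactionFromSmarts(self.smarts)
            if rxn is None:
                raise ValueError(f"invalid reaction SMARTS for rule {self.rule_id}")
            object.__setattr__(self, "_rxn", rxn)
        return self._rxn

    def substrate_filter(self):
        if self.filter_smarts and self._filter is None:
            from rdkit import Chem

            object.__setattr__(self, "_filter", Chem.MolFromSmarts(self.filter_smarts))
        return self._filter


@dataclass(frozen=True)
class NetworkReaction:
    """One rule application: signed stoichiometry over compounds + cofactors."""

    id: str
    stoich: Mapping[str, float]
    rule_id: str
    generation: int = 1

    def substrates(self) -> list[str]:
        return sorted(s for s, c in self.stoich.items() if c < 0 and s not in COFACTORS)

    def products(self) -> list[str]:
        return sorted(s for s, c in self.stoich.items() if c > 0 and s not in COFACTORS)

    def signature(self) -> tuple:
        return tuple(sorted((s, round(c, 9)) for s, c in self.stoich.items()))


@dataclass
class ReactionNetwork:
    compounds: dict[str, Compound]
    reactions: dict[str, NetworkReaction]
    seed_ids: list[str]
    max_generation: int

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for species in rxn.stoich:
                if species not in COFACTORS and species not in self.compounds:
                    raise ValueError(f"reaction {rxn.id} references unknown compound {species}")
        sigs = [r.signature() for r in self.reactions.values()]
        if len(sigs) != len(set(sigs)):
            raise ValueError("duplicate reactions in network")

    def consumers_of(self, compound_id: str) -> list[NetworkReaction]:
        return [r for r in sorted(self.reactions.values(), key=lambda r: r.id)
                if r.stoich.get(compound_id, 0) < 0]

    # -- serialization ---------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "seed_ids": sorted(self.seed_ids),
            "max_generation": self.max_generation,
            "compounds": [
                {"id": c.id, "structure": c.structure, "name": c.name}
                for c in sorted(self.compounds.values(), key=lambda c: c.id)
            ],
            "reactions": [
                {
                    "id": r.id,
                    "rule_id": r.rule_id,
                    "generation": r.generation,
                    "stoich": {s: r.stoich[s] for s in sorted(r.stoich)},
                }
                for r in sorted(self.reactions.values(), key=lambda r: r.id)
            ],
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ReactionNetwork":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            try:
                doc = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    doc = json.load(fh)
        compounds = {c["id"]: Compound(c["id"], c["structure"], c.get("name"))
                     for c in doc["compounds"]}
        reactions = {
            r["id"]: NetworkReaction(r["id"], dict(r["stoich"]), r["rule_id"], r["generation"])
            for r in doc["reactions"]
        }
        return cls(compounds, reactions, list(doc["seed_ids"]), doc["max_generation"])

    def compound_smiles(self) -> list[str]:
        return sorted(self.compounds)


def canonicalize_compound(structure: str, name: Optional[str] = None) -> Compound:
    """Canonicalize a SMILES string into a :class:`Compound`.

    Idempotent: canonicalizing an already-canonical structure returns the
    same id.  Unparsable input raises :class:`StructureParseError` naming
    the offending string.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureParseError(structure)
    canonical = Chem.MolToSmiles(mol)
    return Compound(id=canonical, structure=canonical, name=name)


def _check_balance(rule: ReactionRule, substrate: str, stoich: Mapping[str, float]) -> None:
    comp: dict[str, Counter] = {}
    charges: dict[str, float] = {}
    for species in stoich:
        if species in COFACTORS:
            formula, charge = COFACTORS[species]
            comp[species] = parse_formula(formula)
            charges[species] = charge
        else:
            comp[species], charges[species] = smiles_composition(species)
    residual, net_charge = balance_residual(stoich, comp, charges)
    if residual or net_charge:
        raise RuleApplicationError(
            rule.rule_id, substrate,
            f"imbalanced reaction: residual={dict(residual)}, charge={net_charge}",
        )


def _reaction_id(rule_id: str, stoich: Mapping[str, float]) -> str:
    payload = json.dumps(sorted((s, round(c, 9)) for s, c in stoich.items()))
    return f"{rule_id}__{hashlib.sha1(payload.encode()).hexdigest()[:10]}"


def apply_rule(rule: ReactionRule, compound: Compound) -> list[NetworkReaction]:
    """Apply one rule to one compound, returning deduplicated balanced reactions.

    One reaction per distinct product multiset (symmetric sites collapse);
    empty list when the pattern does not match.  A rewrite that yields an
    invalid molecule or an imbalanced stoichiometry raises
    :class:`RuleApplicationError` carrying the rule id and substrate.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(compound.id)
    if mol is None:
        raise StructureParseError(compound.id)
    filt = rule.substrate_filter()
    if filt is not None and not mol.HasSubstructMatch(filt):
        return []

    product_sets: set[tuple[str, ...]] = set()
    failures: list[str] = []
    for prods in rule.reaction().RunReactants((mol,)):
        smis: list[str] = []
        try:
            for prod in prods:
                for frag in Chem.GetMolFrags(prod, asMols=True, sanitizeFrags=True):
                    smis.append(Chem.MolToSmiles(frag))
        except Exception as exc:  # sanitize failure on this site
            failures.append(str(exc))
            continue
        if smis:
            product_sets.add(tuple(sorted(smis)))
    if failures and not product_sets:
        raise RuleApplicationError(rule.rule_id, compound.id, failures[0])

    reactions = []
    for prods in sorted(product_sets):
        stoich: Counter = Counter({compound.id: -1.0})
        for p in prods:
            stoich[p] += 1.0
        for cof, coeff in rule.cofactors.items():
            if cof not in COFACTORS:
                raise RuleApplicationError(rule.rule_id, compound.id, f"unknown cofactor {cof!r}")
            stoich[cof] += float(coeff)
        stoich = {s: c for s, c in stoich.items() if abs(c) > 1e-12}
        if compound.id not in stoich:
            continue  # degenerate rewrite (product == substrate)
        _check_balance(rule, compound.id, stoich)
        reactions.append(NetworkReaction(_reaction_id(rule.rule_id, stoich), stoich, rule.rule_id))
    return reactions


def expand_network(
    seeds: Sequence[Compound],
    rules: Sequence[ReactionRule],
    max_generations: int,
) -> ReactionNetwork:
    """Breadth-first closure of rule applications starting from seed compounds.

    Seeds are generation 0.  A generation-g reaction consumes a compound
    first created in generation g-1; expansion stops at closure or at
    ``max_generations``.  Output is deterministic (canonical ordering) for
    fixed inputs.
    """
    if max_generations < 0:
        raise ValueError("max_generations must be >= 0")
    compounds: dict[str, Compound] = {}
    for seed in seeds:
        compounds[seed.id] = seed
    reactions: dict[tuple, NetworkReaction] = {}
    frontier = sorted(compounds)
    generation = 0
    for generation in range(1, max_generations + 1):
        new_ids: list[str] = []
        for cid in frontier:
            for rule in rules:
                for rxn in apply_rule(rule, compounds[cid]):
                    sig = rxn.signature()
                    if sig in reactions:
                        continue
                    reactions[sig] = replace(rxn, generation=generation)
                    for pid in rxn.products():
                        if pid not in compounds:
                            compounds[pid] = canonicalize_compound(pid)
                            new_ids.append(pid)
        if not new_ids:
            generation -= 1  # nothing new: closure reached in previous wave
            break
        frontier = sorted(set(new_ids))
    network = ReactionNetwork(
        compounds=compounds,
        reactions={r.id: r for r in reactions.values()},
        seed_ids=sorted(s.id for s in seeds),
        max_generation=generation if max_generations else 0,
    )
    network.validate()
    return network


# ---------------------------------------------------------------------------
# rule file I/O and the curated chloroaromatic toy rule set
# ---------------------------------------------------------------------------

def rules_to_json(rules: Iterable[ReactionRule], path=None) -> str:
    doc = [
        {
            "rule_id": r.rule_id,
            "ec_prefix": r.ec_prefix,
            "smarts": r.smarts,
            "cofactors": dict(r.cofactors),
            "reversible": r.reversible,
            "filter_smarts": r.filter_smarts,
            "name": r.name,
        }
        for r in rules
    ]
    text = json.dumps(doc, indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def rules_from_json(source) -> list[ReactionRule]:
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        try:
            doc = json.loads(source)
        except (ValueError, TypeError):
            with open(source) as fh:
                doc = json.load(fh)
    return [
        ReactionRule(
            rule_id=r["rule_id"],
            ec_prefix=r["ec_prefix"],
            smarts=r["smarts"],
            cofactors=r.get("cofactors", {}),
            reversible=r.get("reversible", False),
            filter_smarts=r.get("filter_smarts"),
            name=r.get("name"),
        )
        for r in doc
    ]


def toy_rule_set() -> list[ReactionRule]:
    """Curated rule set for chloroaromatic degradation.

    Ten rules spanning ring dioxygenation, dihydrodiol dehydrogenation,
    intradiol ring cleavage, hydrolytic and reductive dechlorination
    (aromatic and vinylic), enol/keto isomerization, enoate reduction and
    hydrolytic C-C cleavage.  Expansion from 1,2,4-trichlorobenzene
    recreates both the experimentally known route (ending in glycolate +
    succinate) and shorter alternatives ending in catechol.
    """
    return [
        ReactionRule(
            "aromatic_dioxygenation", "1.14.12",
            "[cH:1]1[cH:2][c:3][c:4][c:5][c:6]1>>"
            "[C:1]1([OH])[C:2]([OH])[C:3]=[C:4][C:5]=[C:6]1",
            cofactors={"O2": -1, "NADH": -1, "H+": -1, "NAD+": 1},
            filter_smarts="c[Cl]",
            name="ring-hydroxylating dioxygenase (chloroaromatics)",
        ),
        ReactionRule(
            "dihydrodiol_dehydrogenase", "1.3.1",
            "[C;!$(C=*);H1:1]1([OH:7])[C;!$(C=*);H1:2]([OH:8])[C:3]=[C:4][C:5]=[C:6]1>>"
            "[c:1]1([OH:7])[c:2]([OH:8])[c:3][c:4][c:5][c:6]1",
            cofactors={"NAD+": -1, "NADH": 1, "H+": 1},
            name="cis-dihydrodiol dehydrogenase",
        ),
        ReactionRule(
            "intradiol_ring_cleavage", "1.13.11",
            "[c:1]1([OH:7])[c:2]([OH:8])[c:3][c:4][c:5][c:6]1>>"
            "[C:1](=[OH0:7])([O-])[C:6]=[C:5][C:4]=[C:3][C:2](=[OH0:8])[O-]",
            cofactors={"O2": -1, "H+": 2},
            name="catechol 1,2-dioxygenase (ortho cleavage)",
        ),
        ReactionRule(
            "hydrolytic_dechlorination_aromatic", "3.8.1",
            "[c:1][Cl]>>[c:1][OH]",
            cofactors={"H2O": -1, "Cl-": 1, "H+": 1},
            name="haloarene hydrolase",
        ),
        ReactionRule(
            "hydrolytic_dechlorination_vinylic", "3.8.1",
            "[C:1]([Cl])=[C:2]>>[C:1]([OH])=[C:2]",
            cofactors={"H2O": -1, "Cl-": 1, "H+": 1},
            name="vinyl chloride hydrolase",
        ),
        ReactionRule(
            "reductive_dechlorination_aromatic", "1.97.1",
            "[c:1][Cl]>>[c:1]",
            cofactors={"e-": -2, "H+": -1, "Cl-": 1},
            name="aryl reductive dehalogenase",
        ),
        ReactionRule(
            "reductive_dechlorination_vinylic", "1.97.1",
            "[C:1]([Cl])=[C:2]>>[C:1]=[C:2]",
            cofactors={"e-": -2, "H+": -1, "Cl-": 1},
            name="vinyl reductive dehalogenase",
        ),
        ReactionRule(
            "enol_keto_tautomerase", "5.3.2",
            "[C:1]([OH:3])=[C:2]>>[C:1](=[OH0:3])[C:2]",
            name="enol-keto tautomerase",
        ),
        ReactionRule(
            "enoate_reductase", "1.3.1",
            "[C:1]=[C:2][C:3](=[O:4])[O-:5]>>[C:1][C:2][C:3](=[O:4])[O-:5]",
            cofactors={"NADH": -1, "H+": -1, "NAD+": 1},
            name="2-enoate reductase",
        ),
        ReactionRule(
            "oxoacid_cc_hydrolase", "3.7.1",
            "[C:1](=[O:2])[C:3][C:4](=[O:5])[O-:6]>>"
            "[C:1](=[O:2])[O-].[C:3][C:4](=[O:5])[O-:6]",
            cofactors={"H2O": -1, "H+": 1},
            name="oxoacid C-C hydrolase",
        ),
    ]
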