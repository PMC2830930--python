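"""Constraint-based metabolic model container, SBML I/O, media, augmentation.

The model is the standard stoichiometric object of flux balance analysis:
m metabolites, n reactions, the sparse m x n coefficient matrix N implied
by the reaction stoichiometries, flux bounds, and a biomass objective.
Exchange reactions (single-metabolite boundary reactions) carry the medium:
uptake is a negative exchange flux.

SBML level 3 + fbc is read and written through libsbml; stoichiometry,
bounds, charges and formulas round-trip losslessly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

from .formulas import balance_residual, formula_string, parse_formula, smiles_composition
from .pathways import OverallReaction
from .rules import COFACTORS, CompoundRegistry, NetworkReaction

logger = logging.getLogger(__name__)

__all__ = [
    "DonorSpec",
    "MediaConfigError",
    "MediaSpec",
    "Metabolite",
    "MetabolicModel",
    "ModelParseError",
    "Reaction",
    "SpeciesMappingError",
    "apply_media",
    "augment_with_pathway",
    "check_balance",
    "read_sbml",
    "write_sbml",
]

LOWER_DEFAULT = -1000.0
UPPER_DEFAULT = 1000.0

COMPARTMENTS = ("c", "p", "e")  # cytoplasm, periplasm, extracellular


class ModelParseError(ValueError):
    """Malformed SBML, reported with the offending element path."""


class MediaConfigError(ValueError):
    """A media species has no exchange reaction in the model."""


class SpeciesMappingError(ValueError):
    """Pathway species could not be mapped into the model."""

    def __init__(self, species: Sequence[str]):
        self.species = list(species)
        super().__init__(f"unmapped pathway species: {', '.join(species)}")


@dataclass
class Metabolite:
    id: str
    compartment: str = "c"
    formula: str = ""
    charge: float = 0.0
    name: Optional[str] = None


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lower_bound: float = LOWER_DEFAULT
    upper_bound: float = UPPER_DEFAULT
    name: Optional[str] = None
    balance_exempt: bool = False  # exchange/biomass convention

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        return len(self.stoich) == 1


@dataclass
class MetabolicModel:
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    biomass_reaction_id: Optional[str] = None
    id: str = "model"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(f"{rxn.id}: lower bound exceeds upper bound")
            for met in rxn.stoich:
                if met not in self.metabolites:
                    raise ValueError(f"{rxn.id}: unknown metabolite {met!r}")
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in self.reactions:
            raise ValueError(f"biomass reaction {self.biomass_reaction_id!r} missing")

    @property
    def exchange_reaction_ids(self) -> list[str]:
        return sorted(r.id for r in self.reactions.values() if r.is_exchange)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites={m.id: replace(m) for m in self.metabolites.values()},
            reactions={r.id: replace(r, stoich=dict(r.stoich)) for r in self.reactions.values()},
            biomass_reaction_id=self.biomass_reaction_id,
            id=self.id,
        )

    def stoichiometric_matrix(self) -> tuple[sp.csr_matrix, list[str], list[str]]:
        """The m x n matrix N with its row (metabolite) and column (reaction) ids."""
        met_ids = sorted(self.metabolites)
        rxn_ids = sorted(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        rows, cols, data = [], [], []
        for j, rid in enumerate(rxn_ids):
            for met, coeff in self.reactions[rid].stoich.items():
                rows.append(met_index[met])
                cols.append(j)
                data.append(coeff)
        N = sp.csr_matrix((data, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
        return N, met_ids, rxn_ids

    def bounds_arrays(self, rxn_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([self.reactions[r].lower_bound for r in rxn_ids])
        ub = np.array([self.reactions[r].upper_bound for r in rxn_ids])
        return lb, ub


def check_balance(model: MetabolicModel, atol: float = 1e-9) -> dict[str, tuple]:
    """Element/charge residuals of all non-exempt, non-exchange reactions."""
    comp = {m.id: parse_formula(m.formula) for m in model.metabolites.values()}
    charge = {m.id: m.charge for m in model.metabolites.values()}
    violations = {}
    for rxn in model.reactions.values():
        if rxn.is_exchange or rxn.balance_exempt:
            continue
        residual, net_charge = balance_residual(rxn.stoich, comp, charge)
        if residual or abs(net_charge) > atol:
            violations[rxn.id] = (dict(residual), net_charge)
    return violations


# ---------------------------------------------------------------------------
# media
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediaSpec:
    """Exchange bounds (mmol/gDW/h); uptake is a negative lower bound.

    Unlisted exchange reactions are forced secretion-only
    (``default_secretion``).  Media components follow the in-silico minimal
    medium convention: bulk nutrients at [-100, 1000], O2 uptake capped at
    -18.5, the xenobiotic at -10.
    """

    uptake_bounds: Mapping[str, tuple[float, float]]
    default_secretion: tuple[float, float] = (0.0, 1000.0)

    MEDIA_UPTAKE: tuple[float, float] = (-100.0, 1000.0)
    O2_UPTAKE: tuple[float, float] = (-18.5, 1000.0)
    XENOBIOTIC_UPTAKE: tuple[float, float] = (-10.0, 1000.0)

    @classmethod
    def minimal(
        cls,
        media_exchanges: Iterable[str],
        o2_exchange: str,
        carbon_exchange: Optional[str] = None,
        carbon_bounds: Optional[tuple[float, float]] = None,
        extra: Optional[Mapping[str, tuple[float, float]]] = None,
    ) -> "MediaSpec":
        bounds = {ex: cls.MEDIA_UPTAKE for ex in media_exchanges}
        bounds[o2_exchange] = cls.O2_UPTAKE
        if carbon_exchange is not None:
            bounds[carbon_exchange] = carbon_bounds or cls.XENOBIOTIC_UPTAKE
        if extra:
            bounds.update(extra)
        return cls(uptake_bounds=bounds)


def apply_media(model: MetabolicModel, media: MediaSpec) -> MetabolicModel:
    """Return a copy with exchange bounds set exactly per the media spec."""
    out = model.copy()
    exchanges = set(out.exchange_reaction_ids)
    missing = [ex for ex in media.uptake_bounds if ex not in exchanges]
    if missing:
        raise MediaConfigError(f"media species without exchange reaction: {', '.join(sorted(missing))}")
    for ex in exchanges:
        lb, ub = media.uptake_bounds.get(ex, media.default_secretion)
        rxn = out.reactions[ex]
        rxn.lower_bound, rxn.upper_bound = float(lb), float(ub)
    return out


# ---------------------------------------------------------------------------
# augmentation with degradation pathways
# ---------------------------------------------------------------------------

#: rule-network cofactor ids -> cytoplasmic metabolite ids
DEFAULT_COFACTOR_MAP = {
    "O2": "o2_c",
    "H2": "h2_c",
    "H2O": "h2o_c",
    "H+": "h_c",
    "Cl-": "cl_c",
    "e-": "elec_c",
    "NADH": "nadh_c",
    "NAD+": "nad_c",
    "NADPH": "nadph_c",
    "NADP+": "nadp_c",
    "CO2": "co2_c",
    "CoA": "coa_c",
    "Pi": "pi_c",
}


@dataclass(frozen=True)
class DonorSpec:
    """Cell-side electron supply for degradation steps consuming electrons.

    The default is complete acetate oxidation
    ``ac + 2 h2o -> 2 co2 + 7 h+ + 8 e-`` (8 electrons per acetate); a
    two-electron partial oxidation can be configured instead.  Enabling the
    donor opens its exchange for uptake.
    """

    reaction_id: str = "ACOX"
    stoich: Mapping[str, float] = field(
        default_factory=lambda: {
            "ac_c": -1.0, "h2o_c": -2.0, "co2_c": 2.0, "h_c": 7.0, "elec_c": 8.0,
        }
    )
    exchange_id: str = "EX_ac_e"
    uptake_bound: float = -100.0
    enabled: bool = True


def _novel_metabolite_id(structure: str, compartment: str) -> str:
    return f"nov_{hashlib.sha1(structure.encode()).hexdigest()[:8]}_{compartment}"


def _map_species(
    species: str,
    model: MetabolicModel,
    registry: Optional[CompoundRegistry],
    cofactor_map: Mapping[str, str],
    compartment: str,
    created: dict[str, Metabolite],
    unmapped: list[str],
) -> Optional[str]:
    if species in cofactor_map:
        target = cofactor_map[species]
        if target not in model.metabolites and target not in created:
            formula, charge = COFACTORS.get(species, ("", 0))
            comp = target.rsplit("_", 1)[-1] if "_" in target else compartment
            created[target] = Metabolite(
                target, compartment=comp if comp in COMPARTMENTS else compartment,
                formula=formula, charge=charge, name=species,
            )
        return target
    if species in model.metabolites:
        return species
    if registry is not None:
        entry = registry.get(species)
        if entry.model_metabolite_id:
            if entry.model_metabolite_id not in model.metabolites:
                unmapped.append(species)
                return None
            return entry.model_metabolite_id
    mid = _novel_metabolite_id(species, compartment)
    if mid not in model.metabolites and mid not in created:
        try:
            counts, charge = smiles_composition(species)
        except ValueError:
            unmapped.append(species)
            return None
        created[mid] = Metabolite(
            mid, compartment=compartment, formula=formula_string(counts),
            charge=charge, name=species,
        )
    return mid


def augment_with_pathway(
    model: MetabolicModel,
    reactions: Sequence[Union[NetworkReaction, OverallReaction, Reaction]],
    donor: Optional[DonorSpec] = None,
    registry: Optional[CompoundRegistry] = None,
    xenobiotic: Optional[str] = None,
    xenobiotic_uptake: tuple[float, float] = (0.0, 1000.0),
    compartment: str = "c",
    cofactor_map: Mapping[str, str] = DEFAULT_COFACTOR_MAP,
) -> MetabolicModel:
    """Insert degradation reactions (plus exchange/transport/donor) into a copy.

    Pathway species are mapped to model metabolites through the cofactor
    map, the compound registry, or — for novel intermediates — by creating
    a cytoplasmic metabolite with formula and charge derived from the
    structure.  When any added reaction consumes electrons and a donor is
    enabled, the donor half-reaction is added (if absent) and its exchange
    opened.  The augmented model remains balance-consistent.
    """
    out = model.copy()
    created: dict[str, Metabolite] = {}
    unmapped: list[str] = []
    new_reactions: list[Reaction] = []
    consumes_electrons = False

    for k, rxn in enumerate(reactions):
        if isinstance(rxn, Reaction):
            new_reactions.append(replace(rxn, stoich=dict(rxn.stoich)))
            if rxn.stoich.get(cofactor_map.get("e-", "elec_c"), 0) < 0:
                consumes_electrons = True
            continue
        if isinstance(rxn, OverallReaction):
            rid = f"OVR_{rxn.label or k}"
            stoich_in = rxn.stoich
        else:
            rid = rxn.id
            stoich_in = rxn.stoich
        mapped: dict[str, float] = {}
        for species, coeff in stoich_in.items():
            mid = _map_species(species, out, registry, cofactor_map, compartment, created, unmapped)
            if mid is not None:
                mapped[mid] = mapped.get(mid, 0.0) + coeff
        if stoich_in.get("e-", 0) < 0:
            consumes_electrons = True
        new_reactions.append(Reaction(rid, mapped, 0.0, UPPER_DEFAULT, name=f"degradation step {rid}"))

    if unmapped:
        raise SpeciesMappingError(sorted(set(unmapped)))

    for met in created.values():
        out.metabolites[met.id] = met
    for rxn in new_reactions:
        out.reactions[rxn.id] = rxn

    if xenobiotic is not None:
        if xenobiotic not in out.metabolites:
            raise SpeciesMappingError([xenobiotic])
        base = xenobiotic.rsplit("_", 1)[0]
        met_e = f"{base}_e"
        if met_e not in out.metabolites:
            src = out.metabolites[xenobiotic]
            out.metabolites[met_e] = Metabolite(
                met_e, compartment="e", formula=src.formula, charge=src.charge, name=src.name,
            )
        ex_id, t_id = f"EX_{met_e}", f"{base.upper()}t"
        if ex_id not in out.reactions:
            out.reactions[ex_id] = Reaction(ex_id, {met_e: -1.0}, *xenobiotic_uptake,
                                            name=f"{base} exchange", balance_exempt=True)
        if t_id not in out.reactions:
            out.reactions[t_id] = Reaction(t_id, {met_e: -1.0, xenobiotic: 1.0}, 0.0, UPPER_DEFAULT,
                                           name=f"{base} transport")

    if consumes_electrons and donor is not None and donor.enabled:
        if donor.reaction_id not in out.reactions:
            out.reactions[donor.reaction_id] = Reaction(
                donor.reaction_id, dict(donor.stoich), 0.0, UPPER_DEFAULT,
                name="electron-donor oxidation",
            )
        if donor.exchange_id in out.reactions:
            out.reactions[donor.exchange_id].lower_bound = donor.uptake_bound
    out.validate()
    return out


# ---------------------------------------------------------------------------
# SBML I/O (level 3 version 1 with the fbc package)
# ---------------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    fbc_plugin = sbml_model.getPlugin("fbc")
    fbc_plugin.setStrict(False)

    for comp_id in COMPARTMENTS:
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in sorted(model.metabolites.values(), key=lambda m: m.id):
        sp_ = sbml_model.createSpecies()
        sp_.setId(met.id)
        if met.name:
            sp_.setName(met.name)
        sp_.setCompartment(met.compartment)
        sp_.setHasOnlySubstanceUnits(False)
        sp_.setBoundaryCondition(False)
        sp_.setConstant(False)
        sfbc = sp_.getPlugin("fbc")
        sfbc.setCharge(int(met.charge))
        if met.formula:
            sfbc.setChemicalFormula(met.formula)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bnd_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in sorted(model.reactions.values(), key=lambda r: r.id):
        srxn = sbml_model.createReaction()
        srxn.setId(rxn.id)
        if rxn.name:
            srxn.setName(rxn.name)
        srxn.setFast(False)
        srxn.setReversible(rxn.reversible)
        for met, coeff in sorted(rxn.stoich.items()):
            ref = srxn.createReactant() if coeff < 0 else srxn.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rfbc = srxn.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(rxn.lower_bound))
        rfbc.setUpperFluxBound(bound_param(rxn.upper_bound))

    if model.biomass_reaction_id:
        objective = fbc_plugin.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        fbc_plugin.setActiveObjectiveId("obj")
        flux_obj = objective.createFluxObjective()
        flux_obj.setReaction(model.biomass_reaction_id)
        flux_obj.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


def read_sbml(path) -> MetabolicModel:
    """Parse an SBML model (L2 or L3; fbc bounds when present).

    Models without explicit flux bounds get defaults from the reversibility
    flag ([-1000, 1000] reversible, [0, 1000] irreversible) with a warning.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"SBML parse error at line {err.getLine()}: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"no <model> element in {path}")

    metabolites: dict[str, Metabolite] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp_ = sbml_model.getSpecies(i)
        if sp_.getBoundaryCondition():
            continue
        sfbc = sp_.getPlugin("fbc")
        charge = sfbc.getCharge() if sfbc is not None and sfbc.isSetCharge() else 0
        formula = sfbc.getChemicalFormula() if sfbc is not None and sfbc.isSetChemicalFormula() else ""
        metabolites[sp_.getId()] = Metabolite(
            sp_.getId(), compartment=sp_.getCompartment() or "c",
            formula=formula or "", charge=charge, name=sp_.getName() or None,
        )

    defaulted = []
    reactions: dict[str, Reaction] = {}
    for i in range(sbml_model.getNumReactions()):
        srxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(srxn.getNumReactants()):
            ref = srxn.getReactant(j)
            if ref.getSpecies() in metabolites:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(srxn.getNumProducts()):
            ref = srxn.getProduct(j)
            if ref.getSpecies() in metabolites:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        lb = ub = None
        rfbc = srxn.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            par = sbml_model.getParameter(rfbc.getLowerFluxBound())
            lb = par.getValue() if par is not None else None
        if rfbc is not None and rfbc.isSetUpperFluxBound():
            par = sbml_model.getParameter(rfbc.getUpperFluxBound())
            ub = par.getValue() if par is not None else None
        kinetic = srxn.getKineticLaw()
        if (lb is None or ub is None) and kinetic is not None:
            for pname, setter in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                par = kinetic.getParameter(pname)
                if par is not None:
                    if setter == "lb" and lb is None:
                        lb = par.getValue()
                    elif setter == "ub" and ub is None:
                        ub = par.getValue()
        if lb is None or ub is None:
            defaulted.append(srxn.getId())
            if srxn.getReversible():
                lb, ub = (lb if lb is not None else LOWER_DEFAULT,
                          ub if ub is not None else UPPER_DEFAULT)
            else:
                lb, ub = (lb if lb is not None else 0.0,
                          ub if ub is not None else UPPER_DEFAULT)
        reactions[srxn.getId()] = Reaction(
            srxn.getId(), stoich, lb, ub, name=srxn.getName() or None,
        )

    if defaulted:
        logger.warning(
            "no flux bounds for %d reaction(s); defaults applied from reversibility (%s%s)",
            len(defaulted), ", ".join(defaulted[:5]), "..." if len(defaulted) > 5 else "",
        )

    biomass_id = None
    mfbc = sbml_model.getPlugin("fbc")
    if mfbc is not None and mfbc.getActiveObjective() is not None:
        obj = mfbc.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            biomass_id = obj.getFluxObjective(0).getReaction()
    if biomass_id is None:
        for rid in reactions:
            if "biomass" in rid.lower() or "growth" in rid.lower():
                biomass_id = rid
                break

    for rxn in reactions.values():
        if rxn.is_exchange or (biomass_id and rxn.id == biomass_id):
            rxn.balance_exempt = True
    return MetabolicModel(metabolites, reactions, biomass_id, id=sbml_model.getId() or "model")
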