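"""Deterministic synthetic inputs for the whole pipeline.

Everything the analysis consumes can be generated here without downloads:

* a core metabolic model (glycolytic carbon backbone, TCA cycle, glyoxylate
  shunt, redundant aconitase branch, uncoupled NADH oxidase, acetate
  electron-donor oxidation, catechol funnel, exchanges) whose FBA optimum
  has a recorded closed form: biomass = yield_coefficient x carbon uptake
  bound;
* the curated chloroaromatic rule set together with a compound registry
  and the reference reconstruction of the experimentally known
  1,2,4-trichlorobenzene route (9 steps to glycolate + succinate) plus the
  shorter catechol route;
* internally consistent compound thermodynamic tables produced by solving
  a small LP for formation energies, with optional planted uphill steps of
  chosen magnitude.

Cofactor moieties use placeholder elements (see :mod:`xenoflux.formulas`)
so that every non-exchange, non-biomass reaction is exactly element- and
charge-balanced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import MediaSpec, MetabolicModel, Metabolite, Reaction
from .pathways import Pathway
from .rules import (
    COFACTORS,
    Compound,
    CompoundRegistry,
    ReactionNetwork,
    ReactionRule,
    canonicalize_compound,
    toy_rule_set,
)
from .thermo import (
    DEFAULT_REFERENCE_M,
    O2_SATURATION_M,
    PROTON_WATER,
    RT,
    CompoundEnergy,
)

__all__ = [
    "KNOWN_ROUTE_CHAIN",
    "CATECHOL_ROUTE_CHAIN",
    "ToyModelFixture",
    "ToyModelSpec",
    "default_media",
    "find_route",
    "make_network_thermo_table",
    "make_thermo_table",
    "make_toy_model",
    "make_toy_rules_and_registry",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 1404  # arbitrary package-wide fixture seed


# ---------------------------------------------------------------------------
# toy metabolic model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyModelSpec:
    seed: int = DEFAULT_SEED
    include_glyoxylate_shunt: bool = True
    include_redundant_branch: bool = True
    yield_coefficient: float = 0.05  # g biomass per mmol carbon substrate
    maintenance: float = 0.0  # mmol ATP/gDW/h forced hydrolysis
    carbon_uptake: float = 10.0  # mmol/gDW/h bound on the carbon source

    def __post_init__(self):
        if self.yield_coefficient <= 0:
            raise ValueError("yield_coefficient must be positive")
        if self.carbon_uptake <= 0:
            raise ValueError("carbon_uptake must be positive")
        if self.maintenance < 0:
            raise ValueError("maintenance must be >= 0")


@dataclass
class ToyModelFixture:
    model: MetabolicModel
    spec: ToyModelSpec
    analytic_biomass_optimum: float


_MET_TABLE = [
    # id, compartment, formula, charge, name
    ("glc_c", "c", "C6H12O6", 0, "glucose"),
    ("pyr_c", "c", "C3H3O3", -1, "pyruvate"),
    ("coa_c", "c", "RH", 0, "coenzyme A"),
    ("accoa_c", "c", "C2H3OR", 0, "acetyl-CoA"),
    ("co2_c", "c", "CO2", 0, "carbon dioxide"),
    ("o2_c", "c", "O2", 0, "oxygen"),
    ("h2o_c", "c", "H2O", 0, "water"),
    ("h_c", "c", "H", 1, "proton"),
    ("nad_c", "c", "Q", 1, "NAD+"),
    ("nadh_c", "c", "QH", 0, "NADH"),
    ("nadp_c", "c", "Z", 1, "NADP+"),
    ("nadph_c", "c", "ZH", 0, "NADPH"),
    ("adp_c", "c", "A", 0, "ADP"),
    ("atp_c", "c", "AP", 0, "ATP"),
    ("pi_c", "c", "P", 0, "phosphate"),
    ("oaa_c", "c", "C4H2O5", -2, "oxaloacetate"),
    ("cit_c", "c", "C6H5O7", -3, "citrate"),
    ("icit_c", "c", "C6H5O7", -3, "isocitrate"),
    ("akg_c", "c", "C5H4O5", -2, "2-oxoglutarate"),
    ("succ_c", "c", "C4H4O4", -2, "succinate"),
    ("fum_c", "c", "C4H2O4", -2, "fumarate"),
    ("mal_c", "c", "C4H4O5", -2, "malate"),
    ("glx_c", "c", "C2HO3", -1, "glyoxylate"),
    ("glyclt_c", "c", "C2H3O3", -1, "glycolate"),
    ("ac_c", "c", "C2H3O2", -1, "acetate"),
    ("nh4_c", "c", "H4N", 1, "ammonium"),
    ("cl_c", "c", "Cl", -1, "chloride"),
    ("elec_c", "c", "", -1, "electron"),
    ("tcb_c", "c", "C6H3Cl3", 0, "1,2,4-trichlorobenzene"),
    ("catechol_c", "c", "C6H6O2", 0, "catechol"),
    ("ccmucon_c", "c", "C6H4O4", -2, "cis,cis-muconate"),
    # extracellular
    ("glc_e", "e", "C6H12O6", 0, "glucose"),
    ("o2_e", "e", "O2", 0, "oxygen"),
    ("co2_e", "e", "CO2", 0, "carbon dioxide"),
    ("h2o_e", "e", "H2O", 0, "water"),
    ("h_e", "e", "H", 1, "proton"),
    ("nh4_e", "e", "H4N", 1, "ammonium"),
    ("cl_e", "e", "Cl", -1, "chloride"),
    ("ac_e", "e", "C2H3O2", -1, "acetate"),
    ("glyclt_e", "e", "C2H3O3", -1, "glycolate"),
    ("succ_e", "e", "C4H4O4", -2, "succinate"),
    ("pyr_e", "e", "C3H3O3", -1, "pyruvate"),
    ("catechol_e", "e", "C6H6O2", 0, "catechol"),
    ("tcb_e", "e", "C6H3Cl3", 0, "1,2,4-trichlorobenzene"),
]

#: media components with bulk uptake in the minimal medium
MEDIA_EXCHANGES = ("EX_co2_e", "EX_h2o_e", "EX_h_e", "EX_nh4_e")


def _core_reactions(spec: ToyModelSpec) -> list[Reaction]:
    inv_yield = 1.0 / spec.yield_coefficient

    def rxn(rid, stoich, lb=0.0, ub=1000.0, name=None, exempt=False):
        return Reaction(rid, stoich, lb, ub, name=name, balance_exempt=exempt)

    reactions = [
        # carbon backbone: substrate-level NADH+ATP, pyruvate as hub
        rxn("GLYC", {"glc_c": -1, "nad_c": -2, "adp_c": -2, "pi_c": -2,
                     "pyr_c": 2, "nadh_c": 2, "atp_c": 2, "h_c": 4}, name="glycolytic backbone"),
        rxn("PDH", {"pyr_c": -1, "coa_c": -1, "nad_c": -1,
                    "accoa_c": 1, "co2_c": 1, "nadh_c": 1}, name="pyruvate dehydrogenase"),
        rxn("CS", {"accoa_c": -1, "oaa_c": -1, "h2o_c": -1,
                   "cit_c": 1, "coa_c": 1, "h_c": 1}, name="citrate synthase"),
        rxn("ACONT", {"cit_c": -1, "icit_c": 1}, lb=-1000.0, name="aconitase"),
        rxn("ICDH", {"icit_c": -1, "nadp_c": -1,
                     "akg_c": 1, "co2_c": 1, "nadph_c": 1}, name="isocitrate dehydrogenase"),
        rxn("AKGDH", {"akg_c": -1, "nad_c": -1, "h2o_c": -1, "adp_c": -1, "pi_c": -1,
                      "succ_c": 1, "co2_c": 1, "nadh_c": 1, "atp_c": 1, "h_c": 1},
            name="2-oxoglutarate dehydrogenase (lumped)"),
        rxn("SUCDH", {"succ_c": -1, "nad_c": -1, "fum_c": 1, "nadh_c": 1, "h_c": 1},
            name="succinate dehydrogenase"),
        rxn("FUMH", {"fum_c": -1, "h2o_c": -1, "mal_c": 1}, lb=-1000.0, name="fumarase"),
        rxn("MDH", {"mal_c": -1, "nad_c": -1, "oaa_c": 1, "nadh_c": 1, "h_c": 1},
            lb=-1000.0, name="malate dehydrogenase"),
        rxn("ME", {"mal_c": -1, "nad_c": -1, "pyr_c": 1, "co2_c": 1, "nadh_c": 1},
            name="malic enzyme"),
        rxn("PC", {"pyr_c": -1, "co2_c": -1, "oaa_c": 1, "h_c": 1}, name="pyruvate carboxylase"),
        rxn("GLYCDH", {"glyclt_c": -1, "nad_c": -1, "glx_c": 1, "nadh_c": 1, "h_c": 1},
            name="glycolate dehydrogenase"),
        rxn("THD", {"nadph_c": -1, "nad_c": -1, "nadp_c": 1, "nadh_c": 1},
            name="transhydrogenase"),
        rxn("NADHOX", {"nadh_c": -1, "o2_c": -0.5, "h_c": -1, "nad_c": 1, "h2o_c": 1},
            name="uncoupled NADH oxidase"),
        rxn("ATPH", {"atp_c": -1, "adp_c": 1, "pi_c": 1}, name="uncoupled ATPase"),
        rxn("ATPM", {"atp_c": -1, "adp_c": 1, "pi_c": 1}, lb=spec.maintenance,
            name="ATP maintenance"),
        rxn("CAT12DIOX", {"catechol_c": -1, "o2_c": -1, "ccmucon_c": 1, "h_c": 2},
            name="catechol 1,2-dioxygenase"),
        rxn("MUCDEG", {"ccmucon_c": -1, "coa_c": -1, "h2o_c": -1, "accoa_c": 1, "succ_c": 1},
            name="muconate degradation (lumped beta-ketoadipate)"),
        rxn("ACOX", {"ac_c": -1, "h2o_c": -2, "co2_c": 2, "h_c": 7, "elec_c": 8},
            name="acetate oxidation (electron donor)"),
        rxn("BIOMASS",
            {"pyr_c": -2 * inv_yield, "atp_c": -2, "nh4_c": -0.2, "adp_c": 2, "pi_c": 2},
            name="biomass", exempt=True),
    ]
    if spec.include_redundant_branch:
        reactions.append(rxn("ACONT2", {"cit_c": -1, "icit_c": 1}, name="aconitase (two-step)"))
    if spec.include_glyoxylate_shunt:
        reactions += [
            rxn("ICL", {"icit_c": -1, "succ_c": 1, "glx_c": 1}, name="isocitrate lyase"),
            rxn("MALS", {"glx_c": -1, "accoa_c": -1, "h2o_c": -1,
                         "mal_c": 1, "coa_c": 1, "h_c": 1}, name="malate synthase"),
        ]

    transports = [
        rxn("GLCt", {"glc_e": -1, "glc_c": 1}, name="glucose transport"),
        rxn("O2t", {"o2_e": -1, "o2_c": 1}, lb=-1000.0, name="oxygen diffusion"),
        rxn("CO2t", {"co2_c": -1, "co2_e": 1}, lb=-1000.0, name="CO2 diffusion"),
        rxn("H2Ot", {"h2o_c": -1, "h2o_e": 1}, lb=-1000.0, name="water diffusion"),
        rxn("Ht", {"h_c": -1, "h_e": 1}, lb=-1000.0, name="proton exchange"),
        rxn("NH4t", {"nh4_e": -1, "nh4_c": 1}, lb=-1000.0, name="ammonium transport"),
        rxn("CLt", {"cl_c": -1, "cl_e": 1}, name="chloride efflux"),
        rxn("ACt", {"ac_e": -1, "ac_c": 1}, name="acetate transport"),
        rxn("GLYCLTt", {"glyclt_c": -1, "glyclt_e": 1}, lb=-1000.0, name="glycolate transport"),
        rxn("SUCCt", {"succ_c": -1, "succ_e": 1}, name="succinate efflux"),
        rxn("PYRt", {"pyr_c": -1, "pyr_e": 1}, name="pyruvate overflow"),
        rxn("CATECHOLt", {"catechol_c": -1, "catechol_e": 1}, name="catechol efflux"),
        rxn("TCBt", {"tcb_e": -1, "tcb_c": 1}, name="trichlorobenzene uptake"),
    ]

    exchanges = [
        rxn("EX_glc_e", {"glc_e": -1}, lb=-spec.carbon_uptake, name="glucose exchange", exempt=True),
        rxn("EX_o2_e", {"o2_e": -1}, lb=-18.5, name="oxygen exchange", exempt=True),
        rxn("EX_co2_e", {"co2_e": -1}, lb=-100.0, name="CO2 exchange", exempt=True),
        rxn("EX_h2o_e", {"h2o_e": -1}, lb=-100.0, name="water exchange", exempt=True),
        rxn("EX_h_e", {"h_e": -1}, lb=-100.0, name="proton exchange", exempt=True),
        rxn("EX_nh4_e", {"nh4_e": -1}, lb=-100.0, name="ammonium exchange", exempt=True),
        rxn("EX_cl_e", {"cl_e": -1}, name="chloride exchange", exempt=True),
        rxn("EX_ac_e", {"ac_e": -1}, name="acetate exchange", exempt=True),
        rxn("EX_glyclt_e", {"glyclt_e": -1}, name="glycolate exchange", exempt=True),
        rxn("EX_succ_e", {"succ_e": -1}, name="succinate exchange", exempt=True),
        rxn("EX_pyr_e", {"pyr_e": -1}, name="pyruvate exchange", exempt=True),
        rxn("EX_catechol_e", {"catechol_e": -1}, name="catechol exchange", exempt=True),
        rxn("EX_tcb_e", {"tcb_e": -1}, name="trichlorobenzene exchange", exempt=True),
    ]
    return reactions + transports + exchanges


def make_toy_model(spec: Optional[ToyModelSpec] = None) -> ToyModelFixture:
    """Build the core model; its FBA optimum is yield x carbon uptake bound.

    The closed form holds because pyruvate is the sole biomass precursor
    (two per carbon-six substrate), oxygen demand at full uptake stays
    below the -18.5 bound, and excess ATP/NADH/NADPH drain through
    uncoupled hydrolysis/oxidase reactions.  With ``maintenance`` above
    the ATP supply capacity the model is infeasible and FBA reports
    biomass 0.
    """
    spec = spec or ToyModelSpec()
    metabolites = {
        mid: Metabolite(mid, compartment=comp, formula=formula, charge=charge, name=name)
        for mid, comp, formula, charge, name in _MET_TABLE
    }
    reactions = {r.id: r for r in _core_reactions(spec)}
    model = MetabolicModel(metabolites, reactions, "BIOMASS", id=f"xenoflux_toy_{spec.seed}")
    analytic = spec.yield_coefficient * spec.carbon_uptake
    if spec.maintenance > 2.0 * spec.carbon_uptake:  # ATP capacity: 2 per substrate
        analytic = 0.0
    return ToyModelFixture(model, spec, analytic)


def default_media(
    model: MetabolicModel,
    carbon_exchange: str = "EX_glc_e",
    carbon_bounds: Optional[tuple[float, float]] = None,
) -> MediaSpec:
    """Minimal-medium bounds for the toy model with a chosen carbon source."""
    return MediaSpec.minimal(
        MEDIA_EXCHANGES,
        o2_exchange="EX_o2_e",
        carbon_exchange=carbon_exchange,
        carbon_bounds=carbon_bounds,
    )


# ---------------------------------------------------------------------------
# rules, registry, and the reference routes
# ---------------------------------------------------------------------------

TCB_SMILES = "Clc1ccc(Cl)c(Cl)c1"

#: designed reconstruction of the known route: (rule_id, product SMILES) steps
KNOWN_ROUTE_CHAIN: tuple[tuple[str, str], ...] = (
    ("aromatic_dioxygenation", "OC1C(Cl)=CC(Cl)=C(Cl)C1O"),
    ("dihydrodiol_dehydrogenase", "Oc1c(Cl)cc(Cl)c(Cl)c1O"),
    ("intradiol_ring_cleavage", "O=C([O-])C(Cl)=CC(Cl)=C(Cl)C(=O)[O-]"),
    ("hydrolytic_dechlorination_vinylic", "O=C([O-])C(Cl)=CC(Cl)=C(O)C(=O)[O-]"),
    ("hydrolytic_dechlorination_vinylic", "O=C([O-])C(Cl)=CC(O)=C(O)C(=O)[O-]"),
    ("enol_keto_tautomerase", "O=C([O-])C(Cl)=CC(=O)C(O)C(=O)[O-]"),
    ("reductive_dechlorination_vinylic", "O=C([O-])C=CC(=O)C(O)C(=O)[O-]"),
    ("enoate_reductase", "O=C([O-])CCC(=O)C(O)C(=O)[O-]"),
    ("oxoacid_cc_hydrolase", "O=C([O-])CO"),  # + succinate co-product
)

CATECHOL_ROUTE_CHAIN: tuple[tuple[str, str], ...] = (
    ("hydrolytic_dechlorination_aromatic", "Oc1cc(Cl)ccc1Cl"),
    ("hydrolytic_dechlorination_aromatic", "Oc1ccc(Cl)cc1O"),
    ("reductive_dechlorination_aromatic", "Oc1ccccc1O"),
)

GLYCOLATE_SMILES = "O=C([O-])CO"
SUCCINATE_SMILES = "O=C([O-])CCC(=O)[O-]"
CATECHOL_SMILES = "Oc1ccccc1O"
CCMUCONATE_SMILES = "O=C([O-])C=CC=CC(=O)[O-]"


def make_toy_rules_and_registry() -> tuple[list[ReactionRule], CompoundRegistry, Compound]:
    """Rule set, compound registry, and the canonical seed compound.

    The registry marks the reference-route intermediates as catalogued and
    the central-metabolism entry points (glycolate, succinate, catechol,
    cis,cis-muconate) as native model metabolites.
    """
    rules = toy_rule_set()
    seed = canonicalize_compound(TCB_SMILES, name="1,2,4-trichlorobenzene")
    registry = CompoundRegistry()
    registry.add(TCB_SMILES, known_registry=True, model_metabolite_id="tcb_c",
                 name="1,2,4-trichlorobenzene")
    for _, smiles in KNOWN_ROUTE_CHAIN[:-1]:
        registry.add(smiles, known_registry=True)
    for _, smiles in CATECHOL_ROUTE_CHAIN[:-1]:
        registry.add(smiles, known_registry=True)
    registry.add(GLYCOLATE_SMILES, known_registry=True, native_to_model=True,
                 model_metabolite_id="glyclt_c", name="glycolate")
    registry.add(SUCCINATE_SMILES, known_registry=True, native_to_model=True,
                 model_metabolite_id="succ_c", name="succinate")
    registry.add(CATECHOL_SMILES, known_registry=True, native_to_model=True,
                 model_metabolite_id="catechol_c", name="catechol")
    registry.add(CCMUCONATE_SMILES, known_registry=True, native_to_model=True,
                 model_metabolite_id="ccmucon_c", name="cis,cis-muconate")
    return rules, registry, seed


def find_route(
    network: ReactionNetwork,
    chain: Sequence[tuple[str, str]],
    source_smiles: str = TCB_SMILES,
) -> Pathway:
    """Locate a designed (rule, product) chain inside an expanded network."""
    current = canonicalize_compound(source_smiles).id
    reaction_ids = []
    products: tuple[str, ...] = ()
    for rule_id, product_smiles in chain:
        target = canonicalize_compound(product_smiles).id
        match = None
        for rxn in network.consumers_of(current):
            if rxn.rule_id == rule_id and target in rxn.products():
                match = rxn
                break
        if match is None:
            raise LookupError(f"no {rule_id} reaction from {current} to {target} in network")
        reaction_ids.append(match.id)
        products = tuple(match.products())
        current = target
    source = canonicalize_compound(source_smiles).id
    return Pathway(tuple(reaction_ids), source, products)


# ---------------------------------------------------------------------------
# thermodynamic tables (LP-consistent formation energies)
# ---------------------------------------------------------------------------

_REF_EXCEPT = {"o2_c": O2_SATURATION_M, "o2_e": O2_SATURATION_M, "O2": O2_SATURATION_M}


def _reference_activity(species: str) -> Optional[float]:
    if species in PROTON_WATER:
        return None
    return _REF_EXCEPT.get(species, DEFAULT_REFERENCE_M)


def _solve_formation_energies(
    species: Sequence[str],
    constraints: Sequence[tuple[Mapping[str, float], str, float]],
    rng: np.random.Generator,
    bound: float = 300.0,
) -> dict[str, float]:
    """LP for formation energies: each (stoich, sense, rhs) with sense in {le, eq}.

    The rhs is on the drGm scale; reference-activity constants are folded
    in by the caller.  A seeded random objective picks a reproducible
    vertex.
    """
    index = {s: i for i, s in enumerate(species)}
    A_ub, b_ub, A_eq, b_eq = [], [], [], []
    for stoich, sense, rhs in constraints:
        row = np.zeros(len(species))
        for s, coeff in stoich.items():
            if s in index:
                row[index[s]] += coeff
        if sense == "le":
            A_ub.append(row)
            b_ub.append(rhs)
        else:
            A_eq.append(row)
            b_eq.append(rhs)
    c = rng.uniform(-1.0, 1.0, size=len(species))
    res = linprog(
        c,
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=[(-bound, bound)] * len(species),
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"formation-energy LP infeasible (status {res.status})")
    return {s: float(res.x[i]) for s, i in index.items()}


#: reactions whose planted-uphill equality is provably compatible with the
#: all-downhill background (each has a product confined to few consumers)
UPHILL_MENU = ("SUCDH", "CS", "GLYCDH", "ME", "CAT12DIOX")


def make_thermo_table(
    model: MetabolicModel,
    seed: int = DEFAULT_SEED,
    profile: str = "all_downhill",
    uphill_magnitude: float = 12.5,
    margin: float = 5.0,
    se_range: tuple[float, float] = (0.1, 1.5),
) -> tuple[dict[str, CompoundEnergy], dict[str, float]]:
    """Formation-energy table for the toy model's cytoplasmic species.

    Profiles: ``all_downhill`` (every core reaction drGm <= -margin),
    ``one_uphill`` (SUCDH planted at exactly ``uphill_magnitude``),
    ``mixed`` (one to three menu reactions planted at seeded magnitudes in
    [4, 14] kcal/mol).  Transport and exchange reactions carry no entry
    (they are treated as no-estimate in TMFA); biomass is exempt.
    Deterministic per seed; additivity over pathways holds by construction
    since all energies derive from one potential per compound.
    """
    rng = np.random.default_rng(seed)
    planted: dict[str, float] = {}
    if profile == "one_uphill":
        planted["SUCDH"] = float(uphill_magnitude)
    elif profile == "mixed":
        k = int(rng.integers(1, 4))
        picks = rng.choice(len(UPHILL_MENU), size=k, replace=False)
        for i in sorted(picks):
            planted[UPHILL_MENU[i]] = float(rng.uniform(4.0, 14.0))
    elif profile != "all_downhill":
        raise ValueError(f"unknown profile {profile!r}")

    core = [
        r for r in model.reactions.values()
        if not r.is_exchange and not r.balance_exempt
        and all(model.metabolites[m].compartment == "c" for m in r.stoich)
    ]
    species = sorted({
        m for r in core for m in r.stoich if m not in PROTON_WATER
    })
    constraints = []
    for r in core:
        const = sum(
            coeff * RT * math.log(_reference_activity(m))
            for m, coeff in r.stoich.items()
            if m not in PROTON_WATER and _reference_activity(m) is not None
        )
        if r.id in planted:
            constraints.append((r.stoich, "eq", planted[r.id] - const))
        else:
            constraints.append((r.stoich, "le", -margin - const))
    dfg = _solve_formation_energies(species, constraints, rng)

    energies = {
        s: CompoundEnergy(s, dfg[s], se=float(rng.uniform(*se_range)),
                          reference_activity=_reference_activity(s))
        for s in species
    }
    return energies, planted


def make_network_thermo_table(
    network: ReactionNetwork,
    seed: int = DEFAULT_SEED,
    planted_reactions: Optional[Mapping[str, float]] = None,
    margin: float = 2.0,
    se_range: tuple[float, float] = (0.1, 1.8),
) -> dict[str, CompoundEnergy]:
    """Consistent formation energies for every compound of a rule network.

    All network reactions come out with drGm <= -margin except those in
    ``planted_reactions`` (reaction id -> target drGm), which are pinned
    exactly — e.g. an endergonic first dioxygenation step.  Cofactor ids
    share one table with the organic compounds.
    """
    rng = np.random.default_rng(seed)
    planted_reactions = dict(planted_reactions or {})
    species = sorted(
        set(network.compounds) | {c for c in COFACTORS if c not in PROTON_WATER}
    )
    constraints = []
    for rxn in sorted(network.reactions.values(), key=lambda r: r.id):
        const = sum(
            coeff * RT * math.log(_reference_activity(m))
            for m, coeff in rxn.stoich.items()
            if m not in PROTON_WATER and _reference_activity(m) is not None
        )
        if rxn.id in planted_reactions:
            constraints.append((rxn.stoich, "eq", planted_reactions[rxn.id] - const))
        else:
            constraints.append((rxn.stoich, "le", -margin - const))
    dfg = _solve_formation_energies(species, constraints, rng, bound=2000.0)
    return {
        s: CompoundEnergy(s, dfg[s], se=float(rng.uniform(*se_range)),
                          reference_activity=_reference_activity(s))
        for s in species
    }
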