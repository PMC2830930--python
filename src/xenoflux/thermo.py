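"""Reaction free energies at the millimolar reference state.

Per-compound transformed standard formation energies (ΔfG'°, pH 7, 298 K,
as produced by a group-contribution method and consumed here as an input
table) are combined into per-reaction standard millimolar free energies

    ΔrG'^m = Σ ν_j ΔfG'_j + RT Σ ν_j ln(a_ref,j)

where the reference activity a_ref is 1 mM for every species except:
protons and water, which contribute no concentration term (the transformed
convention absorbs them); and dissolved H2 and O2, whose reference is their
aqueous saturation concentration (3.4e-5 M and 5.5e-5 M).  Standard errors
combine in quadrature.  Reactions transporting charge or protons across the
cytoplasmic membrane gain an electrochemical term from the membrane
potential and the periplasm/cytoplasm pH gradient (7.7 / 7.2).

Two reaction classes get special handling: oxygenases, whose large
uncoupled free-energy release is capped at a configurable exploitable
value, and reductive dechlorinations, which consume two electrons per
chloride released, supplied by a cell-side electron donor selected by
closeness to the Minkevich-Eroshin regularities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

__all__ = [
    "RT",
    "FARADAY_KCAL",
    "H2_SATURATION_M",
    "O2_SATURATION_M",
    "CompoundEnergy",
    "ElectronDonorCriteria",
    "ReactionEnergy",
    "TransportSpec",
    "apply_class_corrections",
    "degree_of_reductance",
    "reaction_dGm",
    "read_thermo_tsv",
    "select_electron_donor",
    "write_energy_report",
    "write_thermo_tsv",
]

R_KCAL = 1.9872e-3  # kcal/mol/K
TEMPERATURE_K = 298.0
RT = R_KCAL * TEMPERATURE_K  # 0.59219 kcal/mol
FARADAY_KCAL = 23.061  # kcal/(V*mol)

H2_SATURATION_M = 3.4e-5
O2_SATURATION_M = 5.5e-5
DEFAULT_REFERENCE_M = 1e-3

#: species whose concentration term is omitted entirely (reference_activity None)
PROTON_WATER = frozenset({"H+", "H2O", "h", "h2o", "h_c", "h_e", "h_p", "h2o_c", "h2o_e", "h2o_p"})


@dataclass(frozen=True)
class CompoundEnergy:
    """Transformed standard formation energy of one compound.

    ``reference_activity`` is the activity (M) defining this compound's
    contribution to the millimolar reference state; ``None`` marks the
    proton/water exemption (no concentration term at all).
    """

    compound_id: str
    dfG_prime: float  # kcal/mol
    se: float = 0.0  # kcal/mol
    reference_activity: Optional[float] = DEFAULT_REFERENCE_M

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be >= 0")
        if self.reference_activity is not None and self.reference_activity <= 0:
            raise ValueError("reference activity must be positive")


@dataclass(frozen=True)
class ReactionEnergy:
    reaction_id: str
    drGm: Optional[float]  # kcal/mol at the millimolar reference state
    se: float = 0.0
    flags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be >= 0")
        if "no_estimate" in self.flags and self.drGm is not None:
            raise ValueError("no_estimate excludes a numeric drGm")

    @property
    def no_estimate(self) -> bool:
        return "no_estimate" in self.flags


@dataclass(frozen=True)
class TransportSpec:
    """Electrochemical bookkeeping for transport across the cytoplasmic membrane."""

    membrane_potential: float = 0.15  # volts, periplasm-positive
    pH_cytoplasm: float = 7.2
    pH_periplasm: float = 7.7
    charge_translocated: float = 0.0  # net charge moved into the cytoplasm
    protons_translocated: float = 0.0  # protons moved into the cytoplasm

    def delta_g(self) -> float:
        """kcal/mol added to the reaction energy by the translocation."""
        electrical = self.charge_translocated * FARADAY_KCAL * self.membrane_potential
        chemical = (
            2.303 * RT * (self.pH_periplasm - self.pH_cytoplasm) * self.protons_translocated
        )
        return electrical + chemical


def reaction_dGm(
    reaction_id: str,
    stoich: Mapping[str, float],
    energies: Mapping[str, CompoundEnergy],
    transport: Optional[TransportSpec] = None,
) -> ReactionEnergy:
    """Combine compound formation energies into a reaction ΔrG'^m with error.

    A species with a nonzero coefficient but no table entry yields a
    ``no_estimate`` flag rather than an exception; protons never require an
    entry.
    """
    total = 0.0
    var = 0.0
    contributing = 0
    flags = set()
    if transport is not None:
        flags.add("transport")
    for species, coeff in stoich.items():
        if abs(coeff) < 1e-12:
            continue
        if species in PROTON_WATER and species not in energies:
            continue  # proton/water convention: absorbed into transformed energies
        entry = energies.get(species)
        if entry is None:
            return ReactionEnergy(reaction_id, None, 0.0, frozenset(flags | {"no_estimate"}))
        contributing += 1
        total += coeff * entry.dfG_prime
        var += (coeff * entry.se) ** 2
        if species not in PROTON_WATER and entry.reference_activity is not None:
            total += coeff * RT * math.log(entry.reference_activity)
    if contributing == 0:
        # nothing but exempt species: no meaningful estimate exists
        return ReactionEnergy(reaction_id, None, 0.0, frozenset(flags | {"no_estimate"}))
    if transport is not None:
        total += transport.delta_g()
    return ReactionEnergy(reaction_id, total, math.sqrt(var), frozenset(flags))


# ---------------------------------------------------------------------------
# reaction-class corrections
# ---------------------------------------------------------------------------

def cap_strategy(cap: float = -25.0) -> Callable[[float], float]:
    """Limit the exploitable free-energy release of an uncoupled oxygenase.

    ``drGm`` values more negative than ``cap`` are truncated to ``cap``;
    endergonic estimates pass through unchanged.
    """

    def apply(drGm: float) -> float:
        return max(drGm, cap)

    return apply


def apply_class_corrections(
    energy: ReactionEnergy,
    class_flags: Iterable[str],
    oxygenase_strategy: Optional[Callable[[float], float]] = None,
) -> ReactionEnergy:
    """Flag-driven adjustment of a reaction energy.

    ``oxygenase``: the uncoupled release correction (default: cap strategy).
    ``reductive_dechlorination``: marked on the energy; the two-electron
    stoichiometry itself lives in the reaction rule (see
    :func:`reductive_dechlorination_electrons`).
    """
    class_flags = set(class_flags)
    if not class_flags:
        return energy
    flags = set(energy.flags) | class_flags
    drGm = energy.drGm
    if "oxygenase" in class_flags and drGm is not None:
        strategy = oxygenase_strategy or cap_strategy()
        drGm = strategy(drGm)
    return replace(energy, drGm=drGm, flags=frozenset(flags))


def reductive_dechlorination_electrons(stoich: Mapping[str, float]) -> dict[str, float]:
    """Ensure a reductive dechlorination consumes two electrons per chloride.

    Returns a corrected stoichiometry; reactions already carrying at least
    the required electrons are returned unchanged.
    """
    chloride = stoich.get("Cl-", 0.0)
    if chloride <= 0:
        return dict(stoich)
    required = -2.0 * chloride
    present = stoich.get("e-", 0.0)
    if present <= required + 1e-9:
        return dict(stoich)
    out = dict(stoich)
    out["e-"] = required
    return out


# ---------------------------------------------------------------------------
# electron-donor selection
# ---------------------------------------------------------------------------

def degree_of_reductance(formula_counts: Mapping[str, float], charge: float = 0.0) -> float:
    """Electrons available per carbon: (4C + H - 2O - 3N - charge)/C."""
    c = formula_counts.get("C", 0)
    if c == 0:
        raise ValueError("degree of reductance undefined for carbon-free compounds")
    electrons = (
        4 * c
        + formula_counts.get("H", 0)
        - 2 * formula_counts.get("O", 0)
        - 3 * formula_counts.get("N", 0)
        - charge
    )
    return electrons / c


@dataclass(frozen=True)
class ElectronDonorCriteria:
    """Candidates scored against the Minkevich-Eroshin regularities.

    ``candidates`` maps candidate id to its (degree-of-reductance,
    free-energy-dissipation) pair.  Defaults follow the classical
    regularity values: reductance of biomass-compatible substrates near
    4.29 and dissipation near 26.95 kcal per electron equivalent.
    """

    candidates: Mapping[str, tuple[float, float]]
    reductance_target: float = 4.291
    dissipation_target: float = 26.95

    def __post_init__(self):
        if not math.isfinite(self.reductance_target) or not math.isfinite(self.dissipation_target):
            raise ValueError("targets must be finite")


def select_electron_donor(
    criteria: ElectronDonorCriteria,
    norm: float = 2.0,
) -> list[tuple[str, float]]:
    """Rank candidates by distance to the regularity targets (ties: lexicographic).

    Returns ``[(candidate, score), ...]`` best first; the score is the
    p-norm distance of (reductance, dissipation) from the targets.
    """
    if not criteria.candidates:
        raise ValueError("no electron-donor candidates supplied")
    scored = []
    for cid in sorted(criteria.candidates):
        red, dis = criteria.candidates[cid]
        score = (
            abs(red - criteria.reductance_target) ** norm
            + abs(dis - criteria.dissipation_target) ** norm
        ) ** (1.0 / norm)
        scored.append((cid, score))
    scored.sort(key=lambda t: (t[1], t[0]))
    return scored


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def write_thermo_tsv(energies: Mapping[str, CompoundEnergy], path) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\tdfG_prime_kcal\tse_kcal\treference_activity_M\n")
        for cid in sorted(energies):
            e = energies[cid]
            ref = "" if e.reference_activity is None else repr(e.reference_activity)
            fh.write(f"{cid}\t{e.dfG_prime!r}\t{e.se!r}\t{ref}\n")


def read_thermo_tsv(path) -> dict[str, CompoundEnergy]:
    energies: dict[str, CompoundEnergy] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            cid = row["compound_id"]
            ref_raw = row.get("reference_activity_M", "")
            ref = float(ref_raw) if ref_raw else None
            energies[cid] = CompoundEnergy(
                cid,
                float(row["dfG_prime_kcal"]),
                float(row.get("se_kcal", 0) or 0),
                ref,
            )
    return energies


def write_energy_report(energies: Sequence[ReactionEnergy], path) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\tdrGm_kcal\tse_kcal\tflags\n")
        for e in energies:
            drgm = "" if e.drGm is None else f"{e.drGm:.6f}"
            fh.write(f"{e.reaction_id}\t{drgm}\t{e.se:.6f}\t{','.join(sorted(e.flags))}\n")
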