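"""Species registry, stoichiometric reactions and the default reaction table.

The reaction scheme couples four groups of chemistry: anodic electrooxidation
(water, H2O2 and protein channels), bulk radical chemistry (recombination,
Haber-Weiss, Fenton), protein oxidation up to the light-emitting species
(singlet oxygen and triplet carbonyls), and cathodic electroreduction.
Electrode reactions carry no mass-action rate constant; their rates are set by
the partitioned electrode current (see :mod:`pefros.pulse_driver`).

The buffered species H2O, H+ and OH- are *fixed*: their concentrations never
change and they are excluded from mass-action products, so shipped rate
constants are effective constants at the working pH (7.2).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "BalanceError",
    "SchemaError",
    "StateError",
    "load_network",
    "load_diffusion_table",
    "mass_action_rate",
    "parse_side",
    "DEFAULT_SPECIES",
    "FIXED_SPECIES",
    "SUPEROXIDE_PKA",
]

#: pKa of the HO2./O2.- acid-base pair
SUPEROXIDE_PKA = 4.8

#: species whose concentration is buffered / clamped during simulation
FIXED_SPECIES = frozenset({"H2O", "H+", "OH-"})


class SchemaError(ValueError):
    """Malformed reaction table or unknown species reference."""


class BalanceError(ValueError):
    """Element or charge imbalance in a small-species reaction."""


class StateError(ValueError):
    """Invalid concentration state (e.g. negative concentration)."""


@dataclass(frozen=True)
class Species:
    id: str
    display: str
    charge: int = 0
    composition: Mapping[str, int] | None = None  # element -> count
    is_macromolecule: bool = False
    is_excited_state: bool = False


def _sp(sid, display, charge=0, comp=None, macro=False, excited=False):
    return Species(sid, display, charge, comp, macro, excited)


#: registry of every species the default table uses
DEFAULT_SPECIES: dict[str, Species] = {
    s.id: s
    for s in [
        _sp("H2O", "H2O", 0, {"H": 2, "O": 1}),
        _sp("3O2", "O2 (triplet ground state)", 0, {"O": 2}),
        _sp("1O2", "O2 (singlet excited state)", 0, {"O": 2}, excited=True),
        _sp("HO.", "hydroxyl radical", 0, {"H": 1, "O": 1}),
        _sp("HO2.", "hydroperoxyl radical", 0, {"H": 1, "O": 2}),
        _sp("O2.-", "superoxide anion", -1, {"O": 2}),
        _sp("H2O2", "hydrogen peroxide", 0, {"H": 2, "O": 2}),
        _sp("HO2-", "hydroperoxide anion", -1, {"H": 1, "O": 2}),
        _sp("H+", "proton", 1, {"H": 1}),
        _sp("OH-", "hydroxide", -1, {"H": 1, "O": 1}),
        _sp("H.", "hydrogen atom", 0, {"H": 1}),
        _sp("H2", "dihydrogen", 0, {"H": 2}),
        _sp("Fe2+", "ferrous iron", 2, {"Fe": 1}),
        _sp("Fe3+", "ferric iron", 3, {"Fe": 1}),
        _sp("BSA", "serum albumin", 0, None, macro=True),
        _sp("BSA.", "albumin radical", 0, None, macro=True),
        _sp("BSAOO.", "albumin peroxyl radical", 0, None, macro=True),
        _sp("BSA_ox", "oxidized albumin", 0, None, macro=True),
        _sp("3RCOR*", "triplet excited carbonyl", 0, None, macro=True,
            excited=True),
        _sp("SOD", "superoxide dismutase", 0, None, macro=True),
        _sp("CAT", "catalase", 0, None, macro=True),
    ]
}

_REACTION_KINDS = frozenset({"bulk", "anodic", "cathodic", "enzymatic",
                             "emission"})


@dataclass(frozen=True)
class Reaction:
    """One stoichiometric reaction of the scheme.

    ``electrons`` is the number of electrons transferred per event for
    electrode reactions (anodic: removed, cathodic: delivered); 0 otherwise.
    ``emission_wavelength_nm`` marks photon-emitting reactions.
    """

    id: str
    reactants: Mapping[str, float]
    products: Mapping[str, float]
    rate_constant: float
    k_units: str = ""
    kind: str = "bulk"
    electrons: int = 0
    emission_wavelength_nm: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise SchemaError(f"reaction {self.id}: negative rate constant")
        if self.kind not in _REACTION_KINDS:
            raise SchemaError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if self.kind in ("anodic", "cathodic") and self.electrons < 1:
            raise SchemaError(
                f"reaction {self.id}: electrode reaction needs electrons >= 1")

    @property
    def is_electrode(self) -> bool:
        return self.kind in ("anodic", "cathodic")

    def net_stoichiometry(self) -> dict[str, float]:
        net: dict[str, float] = {}
        for sid, nu in self.reactants.items():
            net[sid] = net.get(sid, 0.0) - nu
        for sid, nu in self.products.items():
            net[sid] = net.get(sid, 0.0) + nu
        return {k: v for k, v in net.items() if v != 0.0}


def parse_side(text: str) -> dict[str, float]:
    """Parse one side of a reaction, e.g. ``"2 HO. + H2O2"``.

    Terms are separated by ``+`` surrounded by spaces; an optional leading
    numeric coefficient may precede the species id.
    """
    out: dict[str, float] = {}
    text = text.strip()
    if not text:
        return out
    for term in text.split(" + "):
        parts = term.strip().split()
        if len(parts) == 1:
            coeff, sid = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coeff = float(parts[0])
            except ValueError as exc:
                raise SchemaError(f"bad coefficient in term {term!r}") from exc
            sid = parts[1]
        else:
            raise SchemaError(f"cannot parse reaction term {term!r}")
        out[sid] = out.get(sid, 0.0) + coeff
    return out


def format_side(stoich: Mapping[str, float]) -> str:
    parts = []
    for sid, nu in stoich.items():
        if nu == 1:
            parts.append(sid)
        elif nu == int(nu):
            parts.append(f"{int(nu)} {sid}")
        else:
            parts.append(f"{nu:g} {sid}")
    return " + ".join(parts)


def check_balance(reaction: Reaction,
                  species: Mapping[str, Species]) -> None:
    """Element and charge balance for reactions of fully-characterised species.

    Macromolecular (composition-less) participants exempt a reaction from the
    element check; electrode reactions balance charge once the transferred
    electron is counted.
    """
    participants = list(reaction.reactants) + list(reaction.products)
    for sid in participants:
        if sid not in species:
            raise SchemaError(
                f"reaction {reaction.id}: unknown species {sid!r}")
    if any(species[sid].composition is None for sid in participants):
        return
    elements: dict[str, float] = {}
    charge = 0.0
    for sid, nu in reaction.reactants.items():
        for el, n in species[sid].composition.items():
            elements[el] = elements.get(el, 0.0) + nu * n
        charge += nu * species[sid].charge
    for sid, nu in reaction.products.items():
        for el, n in species[sid].composition.items():
            elements[el] = elements.get(el, 0.0) - nu * n
        charge -= nu * species[sid].charge
    if any(abs(v) > 1e-9 for v in elements.values()):
        bad = {k: v for k, v in elements.items() if abs(v) > 1e-9}
        raise BalanceError(
            f"reaction {reaction.id}: element imbalance {bad}")
    # anodic: products carry +z relative to reactants (electron removed);
    # cathodic: -z (electron delivered); otherwise zero.
    expected = 0.0
    if reaction.kind == "anodic":
        expected = -reaction.electrons
    elif reaction.kind == "cathodic":
        expected = reaction.electrons
    if abs(charge - expected) > 1e-9:
        raise BalanceError(
            f"reaction {reaction.id}: charge imbalance "
            f"(net {charge:+g}, expected {expected:+g})")


@dataclass
class ReactionNetwork:
    """Validated collection of species and reactions."""

    species: dict[str, Species]
    reactions: list[Reaction]
    fixed_species: frozenset[str] = FIXED_SPECIES
    ph: float = 7.2

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate reaction ids: {sorted(dupes)}")
        for r in self.reactions:
            check_balance(r, self.species)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def bulk_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if not r.is_electrode]

    @property
    def electrode_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_electrode]

    @property
    def emission_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions
                if r.emission_wavelength_nm is not None]

    def with_rate(self, rid: str, k: float) -> "ReactionNetwork":
        """Copy of the network with one rate constant overridden."""
        new = [replace(r, rate_constant=k) if r.id == rid else r
               for r in self.reactions]
        return ReactionNetwork(self.species, new, self.fixed_species, self.ph)

    def with_branching(self, carbonyl_fraction: float) -> "ReactionNetwork":
        """Set the carbonyl vs singlet-oxygen branching of the peroxyl
        fragmentation step (reaction 17)."""
        if not (0.0 <= carbonyl_fraction <= 1.0):
            raise ValueError("branching fraction must be in [0, 1]")
        r17 = self.reaction("17")
        products = dict(r17.products)
        products["3RCOR*"] = carbonyl_fraction
        products["1O2"] = 1.0 - carbonyl_fraction
        new = [replace(r, products=products) if r.id == "17" else r
               for r in self.reactions]
        return ReactionNetwork(self.species, new, self.fixed_species, self.ph)

    def subnetwork(self, reaction_ids: Iterable[str]) -> "ReactionNetwork":
        keep = [self.reaction(rid) for rid in reaction_ids]
        return ReactionNetwork(self.species, keep, self.fixed_species, self.ph)

    def superoxide_acid_fraction(self) -> float:
        """Equilibrium fraction of the HO2./O2.- pool present as HO2.

        at the clamped pH: 1/(1 + 10^(pH - pKa)).
        """
        return 1.0 / (1.0 + 10.0 ** (self.ph - SUPEROXIDE_PKA))


def mass_action_rate(reaction: Reaction, state: Mapping[str, float],
                     fixed: frozenset[str] = FIXED_SPECIES) -> float:
    """Reaction rate (M s^-1) at ``state`` concentrations (M).

    Mass action over non-fixed reactants; enzymatic reactions use the linear
    second-order form k*[E]*[S] (the kcat/KM regime: substrate far below KM),
    where E is the conserved catalyst and S the first non-fixed substrate.
    """
    for sid, c in state.items():
        if c < 0:
            raise StateError(f"negative concentration for {sid}")
    k = reaction.rate_constant
    if reaction.kind == "enzymatic":
        enzyme = next(sid for sid in reaction.reactants
                      if reaction.products.get(sid) == reaction.reactants[sid])
        substrate = next(sid for sid in reaction.reactants
                         if sid != enzyme and sid not in fixed)
        return k * state.get(enzyme, 0.0) * state.get(substrate, 0.0)
    rate = k
    for sid, nu in reaction.reactants.items():
        if sid in fixed:
            continue
        rate *= state.get(sid, 0.0) ** nu
    return rate


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("pefros").joinpath("data", name))


def load_network(path: str | Path | None = None,
                 ph: float = 7.2) -> ReactionNetwork:
    """Load a reaction-definition TSV (the shipped default when ``path`` is None).

    Columns: ``id, reactants, products, k, k_units, kind, z, band_nm,
    provenance``; ``#`` lines are comments. Duplicate ids, unknown species and
    unbalanced small-species reactions are rejected.
    """
    path = _data_path("reactions.tsv") if path is None else Path(path)
    reactions: list[Reaction] = []
    header: list[str] | None = None
    required = {"id", "reactants", "products", "k", "k_units", "kind"}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                missing = required - set(header)
                if missing:
                    raise SchemaError(f"missing columns: {sorted(missing)}")
                continue
            row = dict(zip(header, cells))
            band = row.get("band_nm", "").strip()
            z = row.get("z", "").strip()
            reactions.append(Reaction(
                id=row["id"].strip(),
                reactants=parse_side(row["reactants"]),
                products=parse_side(row["products"]),
                rate_constant=float(row["k"]),
                k_units=row.get("k_units", "").strip(),
                kind=row["kind"].strip(),
                electrons=int(z) if z else 0,
                emission_wavelength_nm=float(band) if band else None,
                provenance=row.get("provenance", "").strip(),
            ))
    if header is None:
        raise SchemaError(f"empty reaction table: {path}")
    return ReactionNetwork(dict(DEFAULT_SPECIES), reactions, ph=ph)


def load_diffusion_table(path: str | Path | None = None,
                         default: float = 1.0e-9) -> dict[str, float]:
    """Species -> aqueous diffusion coefficient (m^2 s^-1).

    Species absent from the table fall back to ``default``; a zero entry
    disables diffusive exchange for that species.
    """
    path = _data_path("diffusion.tsv") if path is None else Path(path)
    table: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("species"):
                continue
            sid, d = line.split("\t")
            table[sid] = float(d)
    table.setdefault("__default__", default)
    return table
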