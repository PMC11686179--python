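"""Domain types for stoichiometric models and the mass/charge balance check.

Conventions
-----------
* Metabolite ids carry a bracketed compartment suffix, e.g. ``lcts[c]``;
  valid compartment tags are ``c`` (cytosol), ``e`` (extracellular), ``u``
  (community lumen), ``d`` (diet) and ``fe`` (fecal).
* Exchange reactions touch exactly one metabolite; negative flux through an
  exchange is uptake into the system.
* Formulas are Hill-notation strings; pseudo-elements (``R``, ``X``) are
  treated like ordinary elements in balance checks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

COMPARTMENTS = ("c", "e", "u", "d", "fe")

#: Reaction kinds exempt from mass/charge balancing.
EXEMPT_KINDS = frozenset({"exchange", "demand", "sink", "biomass"})

REACTION_KINDS = frozenset(
    {"internal", "transport", "exchange", "biomass", "demand", "sink"}
)

BALANCE_TOL = 1e-9

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_COMPARTMENT_SUFFIX = re.compile(r"\[([a-z]+)\]$")


class ModelError(ValueError):
    """Structural violation in a model, reaction or metabolite."""


class FormulaError(ValueError):
    """Malformed Hill-notation formula."""


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-notation formula into an element -> count map.

    Pseudo-elements such as ``R`` and ``X`` are accepted as ordinary
    one-letter symbols.

    >>> parse_formula("C6H12O6")
    {'C': 6, 'H': 12, 'O': 6}
    """
    if not formula:
        raise FormulaError("empty formula")
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"malformed formula {formula!r}: unexpected character at "
                f"position {pos} ({formula[pos]!r})"
            )
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(
            f"malformed formula {formula!r}: unexpected character at "
            f"position {pos} ({formula[pos]!r})"
        )
    return counts


def split_compartment(met_id: str) -> Tuple[str, str]:
    """Split ``lcts[c]`` into ``("lcts", "c")``."""
    match = _COMPARTMENT_SUFFIX.search(met_id)
    if match is None:
        raise ModelError(f"metabolite id {met_id!r} lacks a [compartment] suffix")
    return met_id[: match.start()], match.group(1)


@dataclass(frozen=True)
class Metabolite:
    """A compartmentalized chemical species."""

    id: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    compartment: str = ""

    def __post_init__(self) -> None:
        base, comp = split_compartment(self.id)
        if not self.compartment:
            object.__setattr__(self, "compartment", comp)
        elif self.compartment != comp:
            raise ModelError(
                f"metabolite {self.id!r}: compartment field "
                f"{self.compartment!r} does not match id suffix {comp!r}"
            )
        if self.formula:
            parse_formula(self.formula)  # fail fast on malformed formulas

    @property
    def base_id(self) -> str:
        """Id without the compartment suffix."""
        return split_compartment(self.id)[0]

    def elements(self) -> Dict[str, int]:
        if not self.formula:
            raise FormulaError(f"metabolite {self.id!r} has no formula")
        return parse_formula(self.formula)


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps metabolite ids to nonzero signed coefficients
    (negative = substrate, positive = product).
    """

    id: str
    stoichiometry: Mapping[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    kind: str = "internal"

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ModelError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        stoich = dict(self.stoichiometry)
        for met_id, coeff in stoich.items():
            if coeff == 0:
                raise ModelError(f"reaction {self.id!r}: zero coefficient for {met_id}")
        if self.kind in ("exchange", "demand", "sink") and len(stoich) != 1:
            raise ModelError(
                f"reaction {self.id!r}: kind {self.kind} must touch exactly one "
                f"metabolite, got {sorted(stoich)}"
            )
        object.__setattr__(self, "stoichiometry", stoich)

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


@dataclass(frozen=True)
class BalanceReport:
    """Outcome of an elemental/charge balance check for one reaction."""

    reaction_id: str
    element_imbalance: Mapping[str, float]
    charge_imbalance: float
    verdict: str  # balanced | unbalanced | exempt

    @property
    def is_clean(self) -> bool:
        return self.verdict in ("balanced", "exempt")


@dataclass
class Taxonomy:
    species: str = ""
    genus: str = ""
    phylum: str = ""


class MetabolicModel:
    """A strain/species-level stoichiometric reconstruction."""

    def __init__(
        self,
        id: str,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        biomass_id: Optional[str] = None,
        taxonomy: Optional[Taxonomy] = None,
        name: str = "",
    ):
        self.id = id
        self.name = name or id
        self.taxonomy = taxonomy or Taxonomy()
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)
        self.biomass_id = biomass_id
        if biomass_id is not None and biomass_id not in self.reactions:
            raise ModelError(f"model {id!r}: biomass reaction {biomass_id!r} missing")

    def add_metabolite(self, met: Metabolite) -> None:
        existing = self.metabolites.get(met.id)
        if existing is not None:
            # names are labels; chemical identity must agree
            same = (
                existing.formula == met.formula
                and existing.charge == met.charge
                and existing.compartment == met.compartment
            )
            if not same:
                raise ModelError(
                    f"metabolite id collision with different chemistry: {met.id}"
                )
            return
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id: {rxn.id}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelError(
                f"reaction {rxn.id!r} references unknown metabolites: "
                f"{sorted(missing)}"
            )
        self.reactions[rxn.id] = rxn

    @property
    def biomass(self) -> Reaction:
        if self.biomass_id is None:
            raise ModelError(f"model {self.id!r} has no biomass reaction")
        return self.reactions[self.biomass_id]

    def copy(self, id: Optional[str] = None) -> "MetabolicModel":
        clone = MetabolicModel(id or self.id, name=self.name)
        clone.taxonomy = replace(self.taxonomy)
        clone.metabolites = dict(self.metabolites)
        clone.reactions = dict(self.reactions)
        clone.biomass_id = self.biomass_id
        return clone

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites>"
        )


def check_balance(
    reaction: Reaction,
    metabolite_db: Mapping[str, Metabolite],
    tol: float = BALANCE_TOL,
) -> BalanceReport:
    """Elemental and charge balance of one reaction against a metabolite db.

    Exchange, demand, sink and biomass reactions are exempt by convention and
    return verdict ``exempt`` without any computation.
    """
    if reaction.kind in EXEMPT_KINDS:
        return BalanceReport(reaction.id, {}, 0.0, "exempt")
    missing = [
        m
        for m in reaction.stoichiometry
        if m not in metabolite_db or not metabolite_db[m].formula
    ]
    if missing:
        raise ModelError(
            f"reaction {reaction.id!r}: no formula for metabolites "
            f"{sorted(missing)}"
        )
    element_imbalance: Dict[str, float] = {}
    charge_imbalance = 0.0
    for met_id, coeff in reaction.stoichiometry.items():
        met = metabolite_db[met_id]
        for element, count in met.elements().items():
            element_imbalance[element] = (
                element_imbalance.get(element, 0.0) + coeff * count
            )
        charge_imbalance += coeff * met.charge
    element_imbalance = {e: v for e, v in element_imbalance.items() if abs(v) > tol}
    balanced = not element_imbalance and abs(charge_imbalance) <= tol
    if abs(charge_imbalance) <= tol:
        charge_imbalance = 0.0
    return BalanceReport(
        reaction.id,
        element_imbalance,
        charge_imbalance,
        "balanced" if balanced else "unbalanced",
    )


def validate_balance(
    model_or_reactions,
    metabolite_db: Optional[Mapping[str, Metabolite]] = None,
    tol: float = BALANCE_TOL,
) -> List[BalanceReport]:
    """Balance reports for all reactions of a model (or explicit collections)."""
    if isinstance(model_or_reactions, MetabolicModel):
        reactions = model_or_reactions.reactions.values()
        metabolite_db = model_or_reactions.metabolites
    else:
        reactions = model_or_reactions
        if metabolite_db is None:
            raise ValueError("metabolite_db required when passing raw reactions")
    return [check_balance(r, metabolite_db, tol=tol) for r in reactions]


def add_reactions(
    model: MetabolicModel,
    new_reactions: Iterable[Reaction],
    new_metabolites: Iterable[Metabolite] = (),
) -> Tuple[MetabolicModel, int]:
    """Merge reactions (and their metabolites) into a copy of ``model``.

    Reactions whose id already exists are skipped if stoichiometrically
    identical, otherwise a conflict is raised. Returns the expanded model and
    the number of reactions actually inserted; calling twice with the same
    arguments is a no-op the second time.
    """
    out = model.copy()
    for met in new_metabolites:
        out.add_metabolite(met)
    n_added = 0
    for rxn in new_reactions:
        existing = out.reactions.get(rxn.id)
        if existing is not None:
            if dict(existing.stoichiometry) != dict(rxn.stoichiometry):
                raise ModelError(
                    f"reaction id collision with different stoichiometry: {rxn.id}"
                )
            continue
        out.add_reaction(rxn)
        n_added += 1
    return out, n_added
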