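"""Stage-specific infant diets: concentrations -> fluxes -> model bounds.

Units: milk component concentrations are g/L or mmol/L; diet fluxes are
mmol/person/day. Uptake through a diet exchange is a *negative* flux
(COBRA convention), so ``apply_diet`` writes lower bound = -flux and closes
secretion into the diet compartment (upper bound 0).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from babybiome.core import MetabolicModel
from babybiome.io import PathLike, _read_tsv

logger = logging.getLogger(__name__)

TIME_POINTS = ("5 days", "1 month", "6 months", "1 year")

#: daily milk consumption per time point, mL/day
DEFAULT_MILK_VOLUMES: Dict[str, float] = {
    "5 days": 480.0,
    "1 month": 720.0,
    "6 months": 1260.0,
    "1 year": 1320.0,
}

FEEDINGS = ("breastfed", "formula", "combined")

DIET_PREFIX = "Diet_EX_"


class DietError(ValueError):
    pass


def concentration_to_flux(
    concentration: float,
    unit: str,
    volume_mL: float,
    mw_g_per_mol: Optional[float] = None,
) -> float:
    """Convert a milk concentration into a daily flux (mmol/person/day).

    g/L: flux = conc * (volume/1000) * 1000 / MW; mmol/L: conc * volume/1000.
    """
    if concentration < 0 or volume_mL < 0:
        raise DietError("concentration and volume must be nonnegative")
    if unit == "g/L":
        if not mw_g_per_mol or mw_g_per_mol <= 0:
            raise DietError("molecular weight required for g/L concentrations")
        return concentration * (volume_mL / 1000.0) * 1000.0 / mw_g_per_mol
    if unit == "mmol/L":
        return concentration * volume_mL / 1000.0
    raise DietError(f"unknown concentration unit {unit!r}")


@dataclass
class ConcentrationTable:
    """Metabolite concentrations of a liquid diet (milk or formula)."""

    rows: Dict[str, Tuple[float, str, Optional[float]]]
    # metabolite -> (concentration, unit, molecular weight or None)

    def __post_init__(self) -> None:
        for met, (conc, unit, mw) in self.rows.items():
            if conc < 0:
                raise DietError(f"negative concentration for {met}")
            if unit == "g/L" and (mw is None or mw <= 0):
                raise DietError(f"metabolite {met}: g/L unit requires MW > 0")

    def fluxes(self, volume_mL: float) -> Dict[str, float]:
        return {
            met: concentration_to_flux(conc, unit, volume_mL, mw)
            for met, (conc, unit, mw) in self.rows.items()
        }


def load_concentration_table(path: PathLike) -> ConcentrationTable:
    rows = {}
    for row in _read_tsv(str(path)):
        mw = float(row["mw"]) if row.get("mw") else None
        rows[row["metabolite"]] = (float(row["concentration"]), row["unit"], mw)
    return ConcentrationTable(rows)


@dataclass
class FeedingRegimen:
    time_point: str
    feeding: str = "breastfed"
    milk_volume: Optional[float] = None  # mL/day; defaults per time point
    solid_items: List[Tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise DietError(f"unknown time point {self.time_point!r}")
        if self.feeding not in FEEDINGS:
            raise DietError(f"unknown feeding type {self.feeding!r}")
        if self.milk_volume is None:
            self.milk_volume = DEFAULT_MILK_VOLUMES[self.time_point]
        if self.solid_items and self.time_point in ("5 days", "1 month"):
            raise DietError(
                f"solid foods are not fed at {self.time_point}: "
                f"{[f for f, _ in self.solid_items]}"
            )


@dataclass
class DietFluxTable:
    """Per-metabolite daily uptake bounds with provenance tags."""

    fluxes: Dict[str, float] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, flux in self.fluxes.items():
            if flux < 0:
                raise DietError(f"negative diet flux for {met}")

    def add(self, met: str, flux: float, source: str) -> None:
        if flux < 0:
            raise DietError(f"negative diet flux for {met}")
        self.fluxes[met] = self.fluxes.get(met, 0.0) + flux
        self.provenance.setdefault(met, source)

    def __getitem__(self, met: str) -> float:
        return self.fluxes[met]

    def __contains__(self, met: str) -> bool:
        return met in self.fluxes

    def write(self, path: PathLike) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["exchange_reaction_id", "flux_mmol_per_person_per_day",
                 "provenance"]
            )
            for met in sorted(self.fluxes):
                writer.writerow(
                    [f"{DIET_PREFIX}{met}[d]", f"{self.fluxes[met]:.10g}",
                     self.provenance.get(met, "")]
                )


def load_diet(path: PathLike) -> DietFluxTable:
    table = DietFluxTable()
    for row in _read_tsv(str(path)):
        rid = row["exchange_reaction_id"]
        met = rid
        if met.startswith(DIET_PREFIX):
            met = met[len(DIET_PREFIX):]
        if met.endswith("[d]"):
            met = met[:-3]
        table.add(
            met,
            float(row["flux_mmol_per_person_per_day"]),
            row.get("provenance", ""),
        )
    return table


def build_stage_diet(
    regimen: FeedingRegimen,
    milk: ConcentrationTable,
    solids: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> DietFluxTable:
    """Milk contribution plus per-gram solid-food fluxes.

    ``solids`` maps food id -> metabolite -> mmol per gram consumed.
    Combined breast/formula feeding uses the breast-milk table upstream (the
    caller selects the milk table; this function is feeding-agnostic).
    """
    table = DietFluxTable()
    for met, flux in sorted(milk.fluxes(regimen.milk_volume).items()):
        if flux > 0:
            table.add(met, flux, "milk")
    for food, grams in regimen.solid_items:
        if solids is None or food not in solids:
            raise DietError(f"unknown solid food id {food!r}")
        if grams < 0:
            raise DietError(f"negative amount for solid food {food!r}")
        for met, per_gram in sorted(solids[food].items()):
            if per_gram * grams > 0:
                table.add(met, per_gram * grams, "solid")
    return table


@dataclass(frozen=True)
class DietConfig:
    """Essential-micronutrient trickle applied to unlisted diet exchanges."""

    micronutrients: Tuple[str, ...] = ()
    trickle_flux: float = 0.1


def apply_diet(
    community: MetabolicModel,
    diet: DietFluxTable,
    config: DietConfig = DietConfig(),
) -> MetabolicModel:
    """Write diet uptake bounds onto a community model's diet exchanges.

    Unlisted diet exchanges are closed, except configured micronutrients
    which are opened at the trickle flux. Diet entries without a matching
    exchange are skipped with a warning; the skipped list is attached to the
    returned model as ``diet_skipped``.
    """
    out = community.copy()
    for attr in ("abundances", "couplings", "species_tags", "config"):
        if hasattr(community, attr):
            setattr(out, attr, getattr(community, attr))
    diet_exchanges = {}
    for rxn in community.reactions.values():
        if rxn.id.startswith(DIET_PREFIX):
            met = rxn.id[len(DIET_PREFIX):]
            if met.endswith("[d]"):
                met = met[:-3]
            diet_exchanges[met] = rxn.id
    if not diet_exchanges:
        raise DietError(f"community {community.id!r} has no diet exchanges")
    for met, rid in diet_exchanges.items():
        if met in diet:
            bounds = (-diet[met], 0.0)
        elif met in config.micronutrients:
            bounds = (-config.trickle_flux, 0.0)
        else:
            bounds = (0.0, 0.0)
        out.reactions[rid] = out.reactions[rid].with_bounds(*bounds)
    skipped = sorted(m for m in diet.fluxes if m not in diet_exchanges)
    if skipped:
        logger.warning(
            "%s: %d diet metabolites without a diet exchange skipped: %s",
            community.id, len(skipped), ", ".join(skipped),
        )
    out.diet_skipped = skipped
    return out
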