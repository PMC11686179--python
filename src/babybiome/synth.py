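"""Synthetic toy universe: guild-structured strain reconstructions, cohort
abundance tables with planted group/time effects, and stage diets.

Everything is deterministic given the config seeds, all generated reactions
are mass/charge balanced against the shared toy chemistry, and every
species model is LP-verified to grow on at least one generated diet.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from babybiome.chemistry import (
    FREE_FORMS,
    METABOLITE_NAMES,
    molecular_weight,
)
from babybiome.community import AbundanceTable
from babybiome.core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    Taxonomy,
    validate_balance,
)
from babybiome.diet import (
    ConcentrationTable,
    DEFAULT_MILK_VOLUMES,
    DietFluxTable,
    FeedingRegimen,
    TIME_POINTS,
)
from babybiome.hmo import HMOCatalog, TraitTable, load_catalog
from babybiome.lp import FluxSolver, InfeasibleError

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")

GUILDS = (
    "hmo_degrader",
    "lactate_producer",
    "butyrate_producer",
    "vitamin_producer",
    "generalist",
)

GUILD_GENUS = {
    "hmo_degrader": "Degradibacter",
    "lactate_producer": "Lactofermentum",
    "butyrate_producer": "Butyrivibrionix",
    "vitamin_producer": "Vitaminophilus",
    "generalist": "Generalibacter",
}

GUILD_PHYLUM = {
    "hmo_degrader": "Actinobacteria",
    "lactate_producer": "Firmicutes",
    "butyrate_producer": "Firmicutes",
    "vitamin_producer": "Proteobacteria",
    "generalist": "Bacteroidetes",
}

#: HMOs present in the toy breast milk and usable by degrader species.
#: All four use proton-symport routes, so no ATP machinery is needed in
#: the toy reconstructions.
UNIVERSE_HMOS = ("3sl", "6sl", "lndfh1", "lnh")


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# universe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniverseConfig:
    n_per_guild: Mapping[str, int] = field(
        default_factory=lambda: {
            "hmo_degrader": 3,
            "lactate_producer": 3,
            "butyrate_producer": 2,
            "vitamin_producer": 2,
            "generalist": 4,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = sorted(set(self.n_per_guild) - set(GUILDS))
        if unknown:
            raise GenerationError(f"unknown guilds in config: {unknown}")


def _met(base: str, comp: str) -> Metabolite:
    formula, charge = FREE_FORMS[base]
    return Metabolite(
        f"{base}[{comp}]",
        name=METABOLITE_NAMES[base],
        formula=formula,
        charge=charge,
        compartment=comp,
    )


def _symport(base: str, rid: str, reversible: bool = True) -> Reaction:
    return Reaction(
        rid,
        {f"{base}[e]": -1, "h[e]": -1, f"{base}[c]": 1, "h[c]": 1},
        name=f"{METABOLITE_NAMES[base]} proton symport",
        lower_bound=-1000.0 if reversible else 0.0,
        upper_bound=1000.0,
        subsystem="Transport, extracellular",
        kind="transport",
    )


def _uniport(base: str, rid: str) -> Reaction:
    return Reaction(
        rid,
        {f"{base}[e]": -1, f"{base}[c]": 1},
        name=f"{METABOLITE_NAMES[base]} uniport",
        lower_bound=-1000.0,
        upper_bound=1000.0,
        subsystem="Transport, extracellular",
        kind="transport",
    )


def _exchange(base: str) -> Reaction:
    return Reaction(
        f"EX_{base}(e)",
        {f"{base}[e]": -1},
        name=f"{METABOLITE_NAMES[base]} exchange",
        lower_bound=-1000.0,
        upper_bound=1000.0,
        subsystem="Exchange/demand reaction",
        kind="exchange",
    )


def _guild_model(species: str, guild: str, index: int) -> MetabolicModel:
    """One toy strain reconstruction for a guild member."""
    genus = GUILD_GENUS[guild]
    model = MetabolicModel(
        species.replace(" ", "_"),
        taxonomy=Taxonomy(species=species, genus=genus,
                          phylum=GUILD_PHYLUM[guild]),
        name=species,
    )
    mets: Dict[str, Metabolite] = {}
    rxns: List[Reaction] = []

    def need(*bases_comps: Tuple[str, str]) -> None:
        for base, comp in bases_comps:
            mets.setdefault(f"{base}[{comp}]", _met(base, comp))

    def both(base: str) -> None:
        need((base, "e"), (base, "c"))

    # shared core: glucose + ammonium uptake, proton balance, biomass
    for base in ("glc_D", "nh4", "h", "h2o"):
        both(base)
    rxns += [
        _exchange("glc_D"), _uniport("glc_D", "GLCt1"),
        _exchange("nh4"), _uniport("nh4", "NH4t"),
        _exchange("h"), _uniport("h", "Ht"),
        _exchange("h2o"), _uniport("h2o", "H2Ot"),
        Reaction(
            "biomass_toy",
            {"glc_D[c]": -0.1, "nh4[c]": -0.02},
            name="toy biomass",
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="Biomass",
            kind="biomass",
        ),
    ]

    def lactose_machinery() -> None:
        both("lcts")
        both("gal")
        rxns.extend([
            _exchange("lcts"), _symport("lcts", "LCTSt2r"),
            Reaction(
                "LACZ",
                {"lcts[c]": -1, "h2o[c]": -1, "glc_D[c]": 1, "gal[c]": 1},
                name="beta-galactosidase", upper_bound=1000.0,
                subsystem="Lactose and galactose metabolism",
            ),
            Reaction(
                "GALCONV", {"gal[c]": -1, "glc_D[c]": 1},
                name="lumped Leloir pathway", upper_bound=1000.0,
                subsystem="Lactose and galactose metabolism",
            ),
            _exchange("gal"), _symport("gal", "GALt2r"),
        ])

    def lactate_machinery() -> None:
        both("lac_L")
        rxns.extend([
            Reaction(
                "GLCFERM", {"glc_D[c]": -1, "lac_L[c]": 2, "h[c]": 2},
                name="homolactic fermentation", upper_bound=1000.0,
                subsystem="Glycolysis/gluconeogenesis",
            ),
            _exchange("lac_L"), _symport("lac_L", "L_LACt2r"),
        ])

    if guild == "hmo_degrader":
        lactose_machinery()
        lactate_machinery()
        for base in ("fuc_L", "acnam", "acgam"):
            both(base)
        rxns.extend([
            _exchange("fuc_L"), _symport("fuc_L", "FUCt2r"),
            _exchange("acnam"), _symport("acnam", "ACNAMt2r"),
            _exchange("acgam"), _symport("acgam", "ACGAMt2r"),
        ])
    elif guild == "lactate_producer":
        lactose_machinery()
        lactate_machinery()
    elif guild == "butyrate_producer":
        both("lac_L")
        both("but")
        both("co2")
        both("h2")
        rxns.extend([
            _exchange("lac_L"), _symport("lac_L", "L_LACt2r"),
            Reaction(
                "BUTFERM",
                {"lac_L[c]": -2, "h[c]": -1, "but[c]": 1, "co2[c]": 2,
                 "h2[c]": 2},
                name="lactate to butyrate fermentation", upper_bound=1000.0,
                subsystem="Butyrate production",
            ),
            _exchange("but"), _symport("but", "BUTt2r"),
            _exchange("co2"), _uniport("co2", "CO2t"),
            _exchange("h2"), _uniport("h2", "H2t"),
        ])
    elif guild == "vitamin_producer":
        both("fol_toy")
        both("rib_toy")
        rxns.extend([
            Reaction(
                "FOLSYN",
                {"glc_D[c]": -1, "nh4[c]": -1, "fol_toy[c]": 1, "h2o[c]": 1},
                name="toy folate synthesis", upper_bound=1000.0,
                subsystem="Folate biosynthesis",
            ),
            Reaction(
                "RIBSYN",
                {"glc_D[c]": -2, "rib_toy[c]": 1, "h2o[c]": 1},
                name="toy riboflavin synthesis", upper_bound=1000.0,
                subsystem="Riboflavin biosynthesis",
            ),
            _exchange("fol_toy"), _uniport("fol_toy", "FOLt"),
            _exchange("rib_toy"), _uniport("rib_toy", "RIBt"),
        ])
    elif guild == "generalist":
        if index % 2 == 0:
            lactose_machinery()

    for met in mets.values():
        model.add_metabolite(met)
    for rxn in rxns:
        model.add_reaction(rxn)
    model.biomass_id = "biomass_toy"
    return model


def _degrader_hmos(index: int) -> List[str]:
    """Deterministic HMO capability subset for degrader number ``index``."""
    k = 2 + (index % (len(UNIVERSE_HMOS) - 1))
    start = index % len(UNIVERSE_HMOS)
    return sorted(
        UNIVERSE_HMOS[(start + j) % len(UNIVERSE_HMOS)] for j in range(k)
    )


def generate_universe(
    config: UniverseConfig = UniverseConfig(),
) -> Tuple[Dict[str, MetabolicModel], pd.DataFrame, TraitTable, HMOCatalog]:
    """Toy strain models, taxonomy table, trait table and the HMO catalog.

    Models and traits are deterministic functions of the config; the catalog
    is the packaged curated catalog.
    """
    catalog = load_catalog(os.path.join(DATA_DIR, "hmo_catalog"))
    models: Dict[str, MetabolicModel] = {}
    taxonomy_rows = []
    trait_rows = []
    hmo_columns = sorted(catalog.routes)
    guild_of: Dict[str, str] = {}
    for guild in GUILDS:
        for i in range(1, config.n_per_guild.get(guild, 0) + 1):
            species = f"{GUILD_GENUS[guild]} species{i}"
            model = _guild_model(species, guild, i)
            bad = [
                r for r in validate_balance(model) if r.verdict == "unbalanced"
            ]
            if bad:
                raise GenerationError(
                    f"{species}: unbalanced reactions "
                    f"{[r.reaction_id for r in bad]}"
                )
            models[species] = model
            guild_of[species] = guild
            taxonomy_rows.append(
                {
                    "species": species,
                    "genus": GUILD_GENUS[guild],
                    "phylum": GUILD_PHYLUM[guild],
                    "guild": guild,
                    "model_id": model.id,
                }
            )
            caps = _degrader_hmos(i) if guild == "hmo_degrader" else []
            row = {
                "strain_id": model.id,
                "species": species,
                "genus": GUILD_GENUS[guild],
                "phylum": GUILD_PHYLUM[guild],
                "level": "strain",
                "monosaccharide_only": False,
                "reference": "synthetic universe" if caps else "",
            }
            for hmo in hmo_columns:
                row[hmo] = hmo in caps
            trait_rows.append(row)
    taxonomy = pd.DataFrame(taxonomy_rows).set_index("species")
    traits = TraitTable(
        df=pd.DataFrame(trait_rows).set_index("strain_id"), hmos=hmo_columns
    )
    _verify_growth(models)
    return models, taxonomy, traits, catalog


def _verify_growth(models: Mapping[str, MetabolicModel]) -> None:
    """Each species must grow on the generated breast-milk diet (LP check)."""
    diet = breast_milk_table().fluxes(DEFAULT_MILK_VOLUMES["5 days"])
    for species, model in models.items():
        solver = FluxSolver(model)
        overrides = {}
        for rxn in model.exchanges():
            base = next(iter(rxn.stoichiometry))[:-3]
            flux = diet.get(base, 0.0)
            overrides[rxn.id] = (-flux, 1000.0)
        try:
            growth = solver.maximize(
                {model.biomass_id: 1.0}, bound_overrides=overrides
            )
        except InfeasibleError:
            growth = 0.0
        if growth < 1e-6:
            raise GenerationError(
                f"species {species!r} cannot grow on the 5-day breast-milk diet"
            )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    n_vd: int = 10
    n_csd: int = 10
    n_maternal: int = 0
    time_points: Tuple[str, ...] = TIME_POINTS
    #: (guild, delivery group, time point) -> abundance multiplier
    effects: Mapping[Tuple[str, str, str], float] = field(default_factory=dict)
    #: expected species count per time point (non-decreasing)
    richness: Tuple[int, ...] = (5, 8, 12, 14)
    maternal_richness: int = 14
    #: relative species-inclusion weights per guild (unlisted guilds: 1.0);
    #: degraders are early colonizers, so infant samples favor them
    inclusion_weights: Mapping[str, float] = field(
        default_factory=lambda: {"hmo_degrader": 4.0}
    )
    maternal_inclusion_weights: Mapping[str, float] = field(
        default_factory=lambda: {"butyrate_producer": 3.0, "generalist": 2.0}
    )
    sigma: float = 0.6  # log-normal dispersion
    formula_fraction: float = 0.2
    antibiotics_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.effects.values()):
            raise GenerationError("effect multipliers must be > 0")
        if len(self.richness) != len(self.time_points):
            raise GenerationError("one richness value per time point required")
        if list(self.richness) != sorted(self.richness):
            raise GenerationError("richness must be non-decreasing over time")


def _sample_abundances(
    rng: np.random.Generator,
    species: Sequence[str],
    guild_of: Mapping[str, str],
    group: str,
    time_point: str,
    richness: int,
    config: CohortConfig,
) -> pd.Series:
    n = min(richness, len(species))
    weight_map = (
        config.maternal_inclusion_weights
        if group == "maternal"
        else config.inclusion_weights
    )
    raw = np.array([weight_map.get(guild_of[s], 1.0) for s in species])
    chosen = rng.choice(
        len(species), size=n, replace=False, p=raw / raw.sum()
    )
    values = pd.Series(0.0, index=species)
    for idx in chosen:
        name = species[idx]
        weight = rng.lognormal(mean=0.0, sigma=config.sigma)
        weight *= config.effects.get(
            (guild_of[name], group, time_point), 1.0
        )
        values[name] = weight
    total = values.sum()
    if total <= 0:
        raise GenerationError("degenerate sample with zero total abundance")
    return values / total


def generate_cohort(
    config: CohortConfig, taxonomy: pd.DataFrame
) -> AbundanceTable:
    """Cohort abundance table with planted group x time effects.

    Per sample: species inclusion by time-point richness, log-normal
    abundances, effect-map multipliers, closure to sum 1. Sub-seeds are
    derived deterministically from the root seed.
    """
    species = list(taxonomy.index)
    guild_of = taxonomy["guild"].to_dict()
    columns: Dict[str, pd.Series] = {}
    metadata_rows = []
    sample_no = 0

    def add_sample(sample_id, group, time_point, richness):
        nonlocal sample_no
        rng = np.random.default_rng([config.seed, sample_no])
        sample_no += 1
        for attempt in range(5):
            try:
                columns[sample_id] = _sample_abundances(
                    rng, species, guild_of, group, time_point, richness,
                    config,
                )
                break
            except GenerationError:
                rng = np.random.default_rng([config.seed, sample_no, attempt])
        feeding = (
            "formula"
            if rng.random() < config.formula_fraction and group != "maternal"
            else "breastfed"
        )
        metadata_rows.append(
            {
                "sample": sample_id,
                "delivery_mode": group,
                "time_point": time_point,
                "feeding": feeding,
                "antibiotics": int(rng.random() < config.antibiotics_fraction),
            }
        )

    for group, count in (("VD", config.n_vd), ("CSD", config.n_csd)):
        for i in range(1, count + 1):
            for t_index, time_point in enumerate(config.time_points):
                add_sample(
                    f"{group}{i:02d}_t{t_index + 1}", group, time_point,
                    config.richness[t_index],
                )
    for i in range(1, config.n_maternal + 1):
        add_sample(f"M{i:02d}", "maternal", "maternal",
                   config.maternal_richness)

    abundances = pd.DataFrame(columns)
    abundances.index.name = "species"
    metadata = pd.DataFrame(metadata_rows).set_index("sample")
    return AbundanceTable(abundances=abundances, metadata=metadata)


# ---------------------------------------------------------------------------
# diets
# ---------------------------------------------------------------------------

def _gpl(base: str, grams_per_liter: float) -> Tuple[float, str, float]:
    return (grams_per_liter, "g/L", molecular_weight(FREE_FORMS[base][0]))


def breast_milk_table() -> ConcentrationTable:
    """Toy breast-milk composition; includes the universe HMOs."""
    from babybiome.chemistry import HMO_COMPOSITIONS, condensed_formula

    rows = {
        "lcts": _gpl("lcts", 70.0),
        "glc_D": _gpl("glc_D", 0.3),
        "nh4": (2.0, "mmol/L", None),
        "h": (10.0, "mmol/L", None),
        "h2o": (52000.0, "mmol/L", None),
    }
    hmo_gpl = {"3sl": 2.0, "6sl": 1.0, "lndfh1": 2.5, "lnh": 2.0}
    for hmo, conc in hmo_gpl.items():
        mw = molecular_weight(condensed_formula(HMO_COMPOSITIONS[hmo]))
        rows[hmo] = (conc, "g/L", mw)
    return ConcentrationTable(rows)


def formula_table() -> ConcentrationTable:
    """Toy formula composition; no HMOs."""
    return ConcentrationTable(
        {
            "lcts": _gpl("lcts", 74.0),
            "glc_D": _gpl("glc_D", 1.5),
            "nh4": (2.5, "mmol/L", None),
            "h": (10.0, "mmol/L", None),
            "h2o": (52000.0, "mmol/L", None),
        }
    )


#: per-gram metabolite fluxes (mmol/g) of toy solid foods
SOLID_FOODS: Dict[str, Dict[str, float]] = {
    "apple_sauce_strained": {"glc_D": 0.05, "h2o": 40.0},
    "chicken_soup": {"nh4": 0.03, "glc_D": 0.01, "h2o": 45.0},
    "banana_apple_pear_blend": {"glc_D": 0.08, "h2o": 35.0},
    "baby_yogurt": {"lcts": 0.02, "glc_D": 0.01, "nh4": 0.01, "h2o": 40.0},
}

STAGE_SOLIDS: Dict[str, List[Tuple[str, float]]] = {
    "5 days": [],
    "1 month": [],
    "6 months": [("apple_sauce_strained", 50.0), ("chicken_soup", 50.0)],
    "1 year": [
        ("banana_apple_pear_blend", 112.0),
        ("baby_yogurt", 122.5),
        ("chicken_soup", 120.0),
    ],
}


def generate_diets(
    time_points: Sequence[str] = TIME_POINTS,
    variants: Sequence[str] = ("breastfed", "formula"),
) -> Dict[Tuple[str, str], Tuple[ConcentrationTable, FeedingRegimen]]:
    """Stage diets keyed by (variant, time point)."""
    tables = {"breastfed": breast_milk_table(), "formula": formula_table()}
    out = {}
    for variant in variants:
        for time_point in time_points:
            regimen = FeedingRegimen(
                time_point=time_point,
                feeding=variant,
                milk_volume=DEFAULT_MILK_VOLUMES[time_point],
                solid_items=list(STAGE_SOLIDS[time_point]),
            )
            out[(variant, time_point)] = (tables[variant], regimen)
    return out


def maternal_diet() -> DietFluxTable:
    """Generic rich adult diet used for maternal samples."""
    table = DietFluxTable()
    for met, flux in (
        ("glc_D", 150.0),
        ("lcts", 20.0),
        ("nh4", 60.0),
        ("h", 40.0),
        ("h2o", 70000.0),
    ):
        table.add(met, flux, "adult-default")
    return table
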