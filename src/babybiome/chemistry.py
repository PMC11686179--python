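"""Self-consistent toy chemistry shared by the HMO catalog and the
synthetic universe.

Formulas are exact: every oligosaccharide formula is derived from its
monomer composition by condensation (one H2O removed per glycosidic bond),
so hydrolysis reactions written from the same composition table balance by
construction. Sialic acid is carried as the anion (charge -1); its release
during hydrolysis is accompanied by one proton.
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

from babybiome.core import parse_formula

# element counts of the *neutral* monomers used for condensation arithmetic
MONOMERS: Dict[str, str] = {
    "glc_D": "C6H12O6",   # D-glucose
    "gal": "C6H12O6",     # D-galactose
    "fuc_L": "C6H12O5",   # L-fucose
    "acgam": "C8H15NO6",  # N-acetyl-D-glucosamine
    "acnam": "C11H19NO9", # N-acetylneuraminate, neutral acid form
}

#: (formula, charge) of free metabolites as they appear in models.
FREE_FORMS: Dict[str, Tuple[str, int]] = {
    "glc_D": ("C6H12O6", 0),
    "gal": ("C6H12O6", 0),
    "fuc_L": ("C6H12O5", 0),
    "acgam": ("C8H15NO6", 0),
    "acnam": ("C11H18NO9", -1),  # anion
    "lcts": ("C12H22O11", 0),    # gal-glc, one bond
    "h2o": ("H2O", 0),
    "h": ("H", 1),
    "atp": ("C10H12N5O13P3", -4),
    "adp": ("C10H12N5O10P2", -3),
    "pi": ("HO4P", -2),
    "lac_L": ("C3H5O3", -1),
    "pyr": ("C3H3O3", -1),
    "12ppd_S": ("C3H8O2", 0),
    "ac": ("C2H3O2", -1),
    "nh4": ("H4N", 1),
    "but": ("C4H7O2", -1),
    "co2": ("CO2", 0),
    "h2": ("H2", 0),
    # toy B-vitamin analogs with formulas chosen to balance against the
    # toy precursors (glc_D + nh4 -> fol_toy + h2o; 2 glc_D -> rib_toy + h2o)
    "fol_toy": ("C6H14NO5", 1),
    "rib_toy": ("C12H22O11", 0),
}

METABOLITE_NAMES: Dict[str, str] = {
    "glc_D": "D-glucose",
    "gal": "D-galactose",
    "fuc_L": "L-fucose",
    "acgam": "N-acetyl-D-glucosamine",
    "acnam": "N-acetylneuraminate",
    "lcts": "lactose",
    "h2o": "water",
    "h": "proton",
    "atp": "ATP",
    "adp": "ADP",
    "pi": "orthophosphate",
    "lac_L": "L-lactate",
    "pyr": "pyruvate",
    "12ppd_S": "(S)-1,2-propanediol",
    "ac": "acetate",
    "nh4": "ammonium",
    "but": "butyrate",
    "co2": "carbon dioxide",
    "h2": "dihydrogen",
    "fol_toy": "toy folate analog",
    "rib_toy": "toy riboflavin analog",
}


def _add(counts: Dict[str, int], formula: str, times: int = 1) -> None:
    for element, n in parse_formula(formula).items():
        counts[element] = counts.get(element, 0) + n * times


def hill_formula(counts: Mapping[str, int]) -> str:
    """Render element counts in Hill order (C, H, then alphabetical)."""
    counts = {e: n for e, n in counts.items() if n}
    order = [e for e in ("C", "H") if e in counts] + sorted(
        e for e in counts if e not in ("C", "H")
    )
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order)


def condensed_formula(composition: Mapping[str, int]) -> str:
    """Formula of an oligosaccharide from its monomer composition."""
    counts: Dict[str, int] = {}
    n_units = 0
    for monomer, n in composition.items():
        _add(counts, MONOMERS[monomer], n)
        n_units += n
    if n_units < 1:
        raise ValueError("empty composition")
    _add(counts, "H2O", -(n_units - 1))
    return hill_formula(counts)


#: HMO id -> monomer composition. 28 full HMO structures.
HMO_COMPOSITIONS: Dict[str, Dict[str, int]] = {
    "2fl":    {"gal": 1, "glc_D": 1, "fuc_L": 1},
    "3fl":    {"gal": 1, "glc_D": 1, "fuc_L": 1},
    "dfl":    {"gal": 1, "glc_D": 1, "fuc_L": 2},
    "3sl":    {"gal": 1, "glc_D": 1, "acnam": 1},
    "6sl":    {"gal": 1, "glc_D": 1, "acnam": 1},
    "dsl":    {"gal": 1, "glc_D": 1, "acnam": 2},
    "lnt":    {"gal": 2, "glc_D": 1, "acgam": 1},
    "lnnt":   {"gal": 2, "glc_D": 1, "acgam": 1},
    "lnfp1":  {"gal": 2, "glc_D": 1, "acgam": 1, "fuc_L": 1},
    "lnfp2":  {"gal": 2, "glc_D": 1, "acgam": 1, "fuc_L": 1},
    "lnfp3":  {"gal": 2, "glc_D": 1, "acgam": 1, "fuc_L": 1},
    "lnfp5":  {"gal": 2, "glc_D": 1, "acgam": 1, "fuc_L": 1},
    "lnfp6":  {"gal": 2, "glc_D": 1, "acgam": 1, "fuc_L": 1},
    "lndfh1": {"gal": 2, "glc_D": 1, "acgam": 1, "fuc_L": 2},
    "lndfh2": {"gal": 2, "glc_D": 1, "acgam": 1, "fuc_L": 2},
    "lsta":   {"gal": 2, "glc_D": 1, "acgam": 1, "acnam": 1},
    "lstb":   {"gal": 2, "glc_D": 1, "acgam": 1, "acnam": 1},
    "lstc":   {"gal": 2, "glc_D": 1, "acgam": 1, "acnam": 1},
    "dslnt":  {"gal": 2, "glc_D": 1, "acgam": 1, "acnam": 2},
    "lnh":    {"gal": 3, "glc_D": 1, "acgam": 2},
    "lnnh":   {"gal": 3, "glc_D": 1, "acgam": 2},
    "flnh1":  {"gal": 3, "glc_D": 1, "acgam": 2, "fuc_L": 1},
    "flnh2":  {"gal": 3, "glc_D": 1, "acgam": 2, "fuc_L": 1},
    "dflnh1": {"gal": 3, "glc_D": 1, "acgam": 2, "fuc_L": 2},
    "dflnh2": {"gal": 3, "glc_D": 1, "acgam": 2, "fuc_L": 2},
    "slnh":   {"gal": 3, "glc_D": 1, "acgam": 2, "acnam": 1},
    "fslnh":  {"gal": 3, "glc_D": 1, "acgam": 2, "acnam": 1, "fuc_L": 1},
    "dslnh":  {"gal": 3, "glc_D": 1, "acgam": 2, "acnam": 2},
}

HMO_NAMES: Dict[str, str] = {
    "2fl": "2'-fucosyllactose",
    "3fl": "3-fucosyllactose",
    "dfl": "difucosyllactose",
    "3sl": "3'-sialyllactose",
    "6sl": "6'-sialyllactose",
    "dsl": "disialyllactose",
    "lnt": "lacto-N-tetraose",
    "lnnt": "lacto-N-neotetraose",
    "lnfp1": "lacto-N-fucopentaose I",
    "lnfp2": "lacto-N-fucopentaose II",
    "lnfp3": "lacto-N-fucopentaose III",
    "lnfp5": "lacto-N-fucopentaose V",
    "lnfp6": "lacto-N-fucopentaose VI",
    "lndfh1": "lacto-N-difucohexaose I",
    "lndfh2": "lacto-N-difucohexaose II",
    "lsta": "sialyllacto-N-tetraose a",
    "lstb": "sialyllacto-N-tetraose b",
    "lstc": "sialyllacto-N-tetraose c",
    "dslnt": "disialyllacto-N-tetraose",
    "lnh": "lacto-N-hexaose",
    "lnnh": "lacto-N-neohexaose",
    "flnh1": "fucosyllacto-N-hexaose I",
    "flnh2": "fucosyllacto-N-hexaose II",
    "dflnh1": "difucosyllacto-N-hexaose I",
    "dflnh2": "difucosyllacto-N-hexaose II",
    "slnh": "sialyllacto-N-hexaose",
    "fslnh": "fucosylsialyllacto-N-hexaose",
    "dslnh": "disialyllacto-N-hexaose",
}

#: molecular weights (g/mol) for diet flux conversion, computed from formulas
ATOMIC_WEIGHTS = {
    "C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06,
}


def molecular_weight(formula: str) -> float:
    return sum(ATOMIC_WEIGHTS[e] * n for e, n in parse_formula(formula).items())
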