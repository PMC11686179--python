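"""Regenerate the packaged HMO catalog and trait-table fixtures.

Writes src/babybiome/data/hmo_catalog/{metabolites,reactions,routes,templates}.tsv
and src/babybiome/data/hmo_traits.tsv. The emitted sheets are deterministic;
run from the repository root:

    python scripts/build_fixtures.py
"""

from __future__ import annotations

import csv
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from babybiome.chemistry import (
    FREE_FORMS,
    HMO_COMPOSITIONS,
    HMO_NAMES,
    METABOLITE_NAMES,
    condensed_formula,
)

DATA_DIR = os.path.join(
    os.path.dirname(__file__), "..", "src", "babybiome", "data"
)

# transport mechanism per HMO; extracellular-hydrolysis HMOs have no
# transporter of the intact structure
ABC = [
    "2fl", "3fl", "dfl", "lnt", "lnnt", "lnfp1", "lnfp2", "lnfp3",
    "lnfp5", "lnfp6", "lsta",
]
SYMPORT = [
    "3sl", "6sl", "dsl", "lndfh1", "lndfh2", "lstb", "lstc", "dslnt",
    "lnh", "flnh1", "slnh",
]
EXTRACELLULAR = ["dflnh1", "dflnh2", "dslnh", "flnh2", "fslnh", "lnnh"]

MET_CLASS = {
    **{h: "HMO" for h in HMO_COMPOSITIONS},
    "lcts": "disaccharide",
    "glc_D": "sugar",
    "gal": "sugar",
    "fuc_L": "sugar",
    "acgam": "sugar",
    "acnam": "sugar",
    "lac_L": "product",
    "pyr": "product",
    "12ppd_S": "product",
    "ac": "product",
    "nh4": "product",
    "h2o": "cofactor",
    "h": "cofactor",
    "atp": "cofactor",
    "adp": "cofactor",
    "pi": "cofactor",
}


def met_row(base: str, comp: str):
    if base in HMO_COMPOSITIONS:
        formula, charge = condensed_formula(HMO_COMPOSITIONS[base]), 0
        name = HMO_NAMES[base]
    else:
        formula, charge = FREE_FORMS[base]
        name = METABOLITE_NAMES[base]
    return [f"{base}[{comp}]", name, formula, charge, comp, MET_CLASS[base]]


def hydrolysis_stoich(hmo: str, comp: str):
    """Lumped hydrolysis; gal1-glc1 cores are released as lactose."""
    composition = dict(HMO_COMPOSITIONS[hmo])
    n_units = sum(composition.values())
    products = {}
    n_bonds = n_units - 1
    if composition.get("gal") == 1 and composition.get("glc_D") == 1:
        products[f"lcts[{comp}]"] = 1
        composition["gal"] -= 1
        composition["glc_D"] -= 1
        n_bonds -= 1  # the lactose core bond is not hydrolyzed
    for monomer, n in composition.items():
        if n == 0:
            continue
        products[f"{monomer}[{comp}]"] = products.get(f"{monomer}[{comp}]", 0) + n
        if monomer == "acnam":
            products[f"h[{comp}]"] = products.get(f"h[{comp}]", 0) + n
    stoich = {f"{hmo}[{comp}]": -1}
    if n_bonds:
        stoich[f"h2o[{comp}]"] = -n_bonds
    stoich.update(products)
    return stoich


def equation(stoich):
    subs = sorted((m, -c) for m, c in stoich.items() if c < 0)
    prods = sorted((m, c) for m, c in stoich.items() if c > 0)
    left = " + ".join(f"{c:g} {m}" for m, c in subs)
    right = " + ".join(f"{c:g} {m}" for m, c in prods)
    return f"{left} -> {right}"


def build_catalog():
    mets = {}

    def need(base, comp):
        mets[(base, comp)] = met_row(base, comp)

    reactions = []  # rows: id, name, equation, lb, ub, subsystem, kind
    routes = []  # hmo_id, mechanism, position, reaction_id
    templates = []  # product_id, position, reaction_id

    def rxn(rid, name, stoich, lb, ub, subsystem, kind):
        for met_id in stoich:
            base, comp = met_id[:-1].rsplit("[", 1)[0], met_id.rsplit("[", 1)[1][:-1]
            need(base, comp)
        reactions.append([rid, name, equation(stoich), f"{lb:g}", f"{ub:g}", subsystem, kind])

    for hmo in sorted(HMO_COMPOSITIONS):
        up = hmo.upper()
        if hmo in EXTRACELLULAR:
            mechanism = "extracellular-hydrolysis"
        elif hmo in ABC:
            mechanism = "ABC"
        else:
            assert hmo in SYMPORT, hmo
            mechanism = "proton-symport"
        route = []
        ex_id = f"EX_{hmo}(e)"
        rxn(ex_id, f"{HMO_NAMES[hmo]} exchange", {f"{hmo}[e]": -1},
            -1000, 1000, "Exchange/demand reaction", "exchange")
        route.append(ex_id)
        if mechanism == "ABC":
            tid = f"{up}abc"
            rxn(tid, f"{HMO_NAMES[hmo]} transport via ABC system",
                {f"{hmo}[e]": -1, "atp[c]": -1, "h2o[c]": -1,
                 f"{hmo}[c]": 1, "adp[c]": 1, "pi[c]": 1, "h[c]": 1},
                0, 1000, "HMO degradation", "transport")
            route.append(tid)
        elif mechanism == "proton-symport":
            tid = f"{up}t2"
            rxn(tid, f"{HMO_NAMES[hmo]} transport via proton symport",
                {f"{hmo}[e]": -1, "h[e]": -1, f"{hmo}[c]": 1, "h[c]": 1},
                0, 1000, "HMO degradation", "transport")
            route.append(tid)
        comp = "e" if mechanism == "extracellular-hydrolysis" else "c"
        hid = f"{up}hy" + ("e" if comp == "e" else "")
        rxn(hid, f"{HMO_NAMES[hmo]} hydrolysis", hydrolysis_stoich(hmo, comp),
            0, 1000, "HMO degradation", "internal")
        route.append(hid)
        for pos, rid in enumerate(route):
            routes.append([hmo, mechanism, pos, rid])

    # --- gap-fill templates (not part of the degradation module proper) ----
    def symport_rev(base, rid):
        rxn(rid, f"{METABOLITE_NAMES[base]} reversible proton symport",
            {f"{base}[e]": -1, "h[e]": -1, f"{base}[c]": 1, "h[c]": 1},
            -1000, 1000, "Transport, extracellular", "transport")

    def uniport_rev(base, rid):
        rxn(rid, f"{METABOLITE_NAMES[base]} reversible uniport",
            {f"{base}[e]": -1, f"{base}[c]": 1},
            -1000, 1000, "Transport, extracellular", "transport")

    def exchange(base):
        rid = f"EX_{base}(e)"
        rxn(rid, f"{METABOLITE_NAMES[base]} exchange", {f"{base}[e]": -1},
            -1000, 1000, "Exchange/demand reaction", "exchange")
        return rid

    rxn("LACZ", "beta-galactosidase",
        {"lcts[c]": -1, "h2o[c]": -1, "glc_D[c]": 1, "gal[c]": 1},
        0, 1000, "Lactose and galactose metabolism", "internal")
    rxn("GALCONV", "galactose to glucose interconversion (lumped Leloir)",
        {"gal[c]": -1, "glc_D[c]": 1},
        0, 1000, "Lactose and galactose metabolism", "internal")
    rxn("GLCFERM", "homolactic fermentation (lumped glycolysis)",
        {"glc_D[c]": -1, "lac_L[c]": 2, "h[c]": 2},
        0, 1000, "Glycolysis/gluconeogenesis", "internal")
    rxn("FUCCAT", "fucose catabolism to pyruvate and propanediol",
        {"fuc_L[c]": -1, "pyr[c]": 1, "12ppd_S[c]": 1, "h[c]": 1},
        0, 1000, "Fucose and rhamnose metabolism", "internal")
    rxn("ACGAMCAT", "N-acetylglucosamine catabolism (lumped)",
        {"acgam[c]": -1, "h2o[c]": -2, "glc_D[c]": 1, "ac[c]": 1, "nh4[c]": 1},
        0, 1000, "Amino sugar metabolism", "internal")
    rxn("ACNAMCAT", "N-acetylneuraminate lyase",
        {"acnam[c]": -1, "acgam[c]": 1, "pyr[c]": 1},
        0, 1000, "Amino sugar metabolism", "internal")

    symport_rev("lcts", "LCTSt2r")
    symport_rev("glc_D", "GLCt2r")
    symport_rev("gal", "GALt2r")
    symport_rev("fuc_L", "FUCt2r")
    symport_rev("acgam", "ACGAMt2r")
    symport_rev("acnam", "ACNAMt2r")
    symport_rev("lac_L", "L_LACt2r")
    symport_rev("pyr", "PYRt2r")
    symport_rev("ac", "ACt2r")
    uniport_rev("12ppd_S", "12PPDt")
    uniport_rev("nh4", "NH4t")
    for base in ["lcts", "glc_D", "gal", "fuc_L", "acgam", "acnam",
                 "lac_L", "pyr", "ac", "12ppd_S", "nh4"]:
        exchange(base)

    groups = {
        "lcts": ["EX_lcts(e)", "LCTSt2r", "LACZ"],
        "gal": ["EX_gal(e)", "GALt2r", "GALCONV"],
        "glc_D": ["EX_glc_D(e)", "GLCt2r", "GLCFERM",
                  "L_LACt2r", "EX_lac_L(e)"],
        "fuc_L": ["EX_fuc_L(e)", "FUCt2r", "FUCCAT", "PYRt2r", "EX_pyr(e)",
                  "12PPDt", "EX_12ppd_S(e)"],
        "acgam": ["EX_acgam(e)", "ACGAMt2r", "ACGAMCAT", "ACt2r", "EX_ac(e)",
                  "NH4t", "EX_nh4(e)"],
        "acnam": ["EX_acnam(e)", "ACNAMt2r", "ACNAMCAT",
                  "PYRt2r", "EX_pyr(e)"],
        "lac_L": ["EX_lac_L(e)", "L_LACt2r"],
        "pyr": ["EX_pyr(e)", "PYRt2r"],
        "12ppd_S": ["EX_12ppd_S(e)", "12PPDt"],
        "ac": ["EX_ac(e)", "ACt2r"],
        "nh4": ["EX_nh4(e)", "NH4t"],
    }
    for product in sorted(groups):
        for pos, rid in enumerate(groups[product]):
            templates.append([product, pos, rid])

    out = os.path.join(DATA_DIR, "hmo_catalog")
    os.makedirs(out, exist_ok=True)

    def write(name, header, rows):
        with open(os.path.join(out, name), "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)

    met_rows = [mets[key] for key in sorted(mets)]
    write("metabolites.tsv",
          ["id", "name", "formula", "charge", "compartment", "class"], met_rows)
    write("reactions.tsv",
          ["id", "name", "equation", "lb", "ub", "subsystem", "kind"],
          sorted(reactions, key=lambda r: r[0]))
    write("routes.tsv", ["hmo_id", "mechanism", "position", "reaction_id"], routes)
    write("templates.tsv", ["product_id", "position", "reaction_id"], templates)


# ---------------------------------------------------------------------------
# trait table
# ---------------------------------------------------------------------------

ALL_HMOS = sorted(HMO_COMPOSITIONS)

BIF_CORE = ["2fl", "3fl", "dfl", "lnt", "lnnt", "lnfp1", "lnfp2", "lnfp3",
            "lnfp5", "lnfp6", "lndfh1", "lndfh2", "lnh", "lnnh", "3sl", "6sl"]
BACTEROIDES = ["2fl", "3fl", "dfl", "3sl", "6sl", "dsl", "lnt", "lnnt",
               "lnfp2", "lnfp3", "lndfh2", "lsta", "lstb", "lstc", "dslnt",
               "lnh", "lnnh", "dflnh1", "dflnh2", "slnh", "fslnh", "dslnh"]

# species, genus, phylum, n_strains, capability set, reference
SPECIES = [
    ("Bifidobacterium longum", "Bifidobacterium", "Actinobacteria", 57,
     BIF_CORE, "Sela et al. 2008; Garrido et al. 2016"),
    ("Bifidobacterium breve", "Bifidobacterium", "Actinobacteria", 28,
     ["2fl", "3fl", "lnt", "lnnt", "lnfp1", "3sl", "6sl"],
     "Ruiz-Moyano et al. 2013"),
    ("Bifidobacterium bifidum", "Bifidobacterium", "Actinobacteria", 25,
     ["2fl", "3fl", "lnt", "lnnt", "lnfp1", "lnfp2", "lnfp3", "lndfh1",
      "lnh", "flnh1", "flnh2"], "Asakuma et al. 2011"),
    ("Bifidobacterium animalis", "Bifidobacterium", "Actinobacteria", 8,
     ["lnt", "3sl"], "Turroni et al. 2010"),
    ("Bifidobacterium pseudocatenulatum", "Bifidobacterium", "Actinobacteria",
     6, ["2fl", "3fl", "lnt"], "Shani et al. 2018"),
    ("Bifidobacterium catenulatum", "Bifidobacterium", "Actinobacteria", 4,
     ["lnt", "lnnt"], "Turroni et al. 2010"),
    ("Bifidobacterium adolescentis", "Bifidobacterium", "Actinobacteria", 6,
     ["lnt", "3sl", "6sl"], "Turroni et al. 2010"),
    ("Bifidobacterium kashiwanohense", "Bifidobacterium", "Actinobacteria", 2,
     ["2fl", "3fl"], "Bunesova et al. 2016"),
    ("Bifidobacterium dentium", "Bifidobacterium", "Actinobacteria", 2,
     ["lnt"], "Turroni et al. 2010"),
    ("Bacteroides fragilis", "Bacteroides", "Bacteroidetes", 12,
     BACTEROIDES, "Marcobal et al. 2010"),
    ("Bacteroides thetaiotaomicron", "Bacteroides", "Bacteroidetes", 10,
     BACTEROIDES, "Marcobal et al. 2011"),
    ("Bacteroides caccae", "Bacteroides", "Bacteroidetes", 4,
     ["2fl", "3sl", "lnt", "lnnt"], "Marcobal et al. 2010"),
    ("Bacteroides ovatus", "Bacteroides", "Bacteroidetes", 6,
     ["lnt", "lnnt", "lnh", "lnnh"], "Marcobal et al. 2010"),
    ("Bacteroides xylanisolvens", "Bacteroides", "Bacteroidetes", 2,
     ["lnt", "lnnt"], "Marcobal et al. 2010"),
    ("Phocaeicola vulgatus", "Phocaeicola", "Bacteroidetes", 8,
     ["2fl", "3fl", "3sl", "6sl", "lnt", "lnnt", "lsta", "lstc"],
     "Marcobal et al. 2010"),
    ("Phocaeicola dorei", "Phocaeicola", "Bacteroidetes", 4,
     ["2fl", "3sl", "lnt"], "Marcobal et al. 2010"),
    ("Akkermansia muciniphila", "Akkermansia", "Verrucomicrobia", 5,
     ["2fl", "3fl", "3sl", "6sl", "lnt"], "Kostopoulos et al. 2020"),
    ("Ruminococcus gnavus", "Mediterraneibacter", "Firmicutes", 4,
     ["2fl", "3sl", "6sl"], "Crost et al. 2013"),
    ("Roseburia inulinivorans", "Roseburia", "Firmicutes", 3,
     ["2fl", "3fl"], "Pichler et al. 2020"),
    ("Roseburia intestinalis", "Roseburia", "Firmicutes", 3,
     ["lnt", "lnnt"], "Pichler et al. 2020"),
    ("Lacticaseibacillus casei", "Lacticaseibacillus", "Firmicutes", 6,
     ["2fl", "3fl", "lnt"], "Bidart et al. 2014"),
    ("Lacticaseibacillus rhamnosus", "Lacticaseibacillus", "Firmicutes", 6,
     ["lnt", "lnnt"], "Bidart et al. 2014"),
    ("Limosilactobacillus fermentum", "Limosilactobacillus", "Firmicutes", 4,
     ["2fl", "3fl"], "Rodriguez-Diaz et al. 2011"),
    ("Lactobacillus acidophilus", "Lactobacillus", "Firmicutes", 5,
     ["2fl", "lnt", "lnnt"], "Thongaram et al. 2017"),
    ("Ligilactobacillus salivarius", "Ligilactobacillus", "Firmicutes", 3,
     ["3sl"], "Thongaram et al. 2017"),
    ("Levilactobacillus brevis", "Levilactobacillus", "Firmicutes", 3,
     ["2fl"], "Thongaram et al. 2017"),
    ("Lactiplantibacillus plantarum", "Lactiplantibacillus", "Firmicutes", 4,
     ["2fl", "3fl"], "Thongaram et al. 2017"),
    ("Streptococcus thermophilus", "Streptococcus", "Firmicutes", 4,
     ["3sl", "6sl"], "Kiyohara et al. 2011"),
    ("Staphylococcus epidermidis", "Staphylococcus", "Firmicutes", 3,
     ["3sl"], "Kiyohara et al. 2011"),
    ("Enterococcus faecalis", "Enterococcus", "Firmicutes", 3,
     ["lnt"], "Thongaram et al. 2017"),
    ("Clostridium perfringens", "Clostridium", "Firmicutes", 2,
     ["lnt", "lnnt"], "Pichler et al. 2020"),
]

# strains supplemented only with monosaccharide pathways
MONO_ONLY = [
    ("Escherichia coli", "Escherichia", "Proteobacteria", 3,
     "Fabich et al. 2008"),
    ("Enterococcus faecium", "Enterococcus", "Firmicutes", 2,
     "Zhang et al. 2017"),
    ("Veillonella parvula", "Veillonella", "Firmicutes", 2,
     "Egan et al. 2014"),
]

INFANTIS = "Bifidobacterium_longum_subsp_infantis_ATCC_15697"


def build_traits():
    rows = []

    def strain_row(strain_id, species, genus, phylum, caps, ref, mono=False):
        row = {
            "strain_id": strain_id,
            "species": species,
            "genus": genus,
            "phylum": phylum,
            "level": "strain",
            "monosaccharide_only": int(mono),
            "reference": ref,
        }
        for hmo in ALL_HMOS:
            row[hmo] = int(hmo in caps)
        rows.append(row)

    total = 0
    for species, genus, phylum, n, caps, ref in SPECIES:
        tag = species.replace(" ", "_")
        for i in range(1, n + 1):
            strain_caps = list(caps)
            # deterministic strain-to-strain variation
            if len(strain_caps) >= 4 and i % 3 == 0:
                strain_caps.pop(i % len(strain_caps))
            strain_row(f"{tag}_STR_{i:02d}", species, genus, phylum,
                       strain_caps, ref)
        total += n
    # the strain with the largest capacity for HMO degradation
    strain_row(INFANTIS, "Bifidobacterium longum", "Bifidobacterium",
               "Actinobacteria", ALL_HMOS, "Sela et al. 2008 (type strain)")
    total += 1
    assert total == 243, total
    assert len(SPECIES) == 31, len(SPECIES)

    mono_total = 0
    for species, genus, phylum, n, ref in MONO_ONLY:
        tag = species.replace(" ", "_")
        for i in range(1, n + 1):
            strain_row(f"{tag}_STR_{i:02d}", species, genus, phylum, [],
                       ref, mono=True)
        mono_total += n
    assert mono_total == 7, mono_total

    os.makedirs(DATA_DIR, exist_ok=True)
    header = ["strain_id", "species", "genus", "phylum", "level",
              "monosaccharide_only", "reference", *ALL_HMOS]
    with open(os.path.join(DATA_DIR, "hmo_traits.tsv"), "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=header, delimiter="\t",
                                lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


if __name__ == "__main__":
    build_catalog()
    build_traits()
    print("fixtures written to", os.path.abspath(DATA_DIR))
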