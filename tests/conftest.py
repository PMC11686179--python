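import pytest

from babybiome.community import CommunityConfig, assemble_community, build_pan_model
from babybiome.core import MetabolicModel, Metabolite, Reaction, Taxonomy
from babybiome.diet import DietFluxTable, apply_diet
from babybiome.synth import DATA_DIR


def met(base: str, comp: str, formula: str = "", charge: int = 0) -> Metabolite:
    return Metabolite(f"{base}[{comp}]", name=base, formula=formula,
                      charge=charge, compartment=comp)


def lactose_fermenter(model_id: str = "S", species: str = "S",
                      genus: str = "G") -> MetabolicModel:
    """Single-species toy: biomass 0.1 lcts -> 1 bio; 1 lcts -> 4 lac."""
    m = MetabolicModel(model_id, taxonomy=Taxonomy(species=species, genus=genus))
    for b in ("lcts", "lac_L"):
        for c in ("e", "c"):
            m.add_metabolite(met(b, c))
    m.add_reaction(Reaction("EX_lcts(e)", {"lcts[e]": -1}, lower_bound=-1000,
                            upper_bound=1000, kind="exchange"))
    m.add_reaction(Reaction("LCTSt", {"lcts[e]": -1, "lcts[c]": 1},
                            upper_bound=1000, kind="transport"))
    m.add_reaction(Reaction("FERM", {"lcts[c]": -1, "lac_L[c]": 4},
                            upper_bound=1000, subsystem="Fermentation"))
    m.add_reaction(Reaction("LACt", {"lac_L[c]": -1, "lac_L[e]": 1},
                            upper_bound=1000, kind="transport"))
    m.add_reaction(Reaction("EX_lac_L(e)", {"lac_L[e]": -1}, lower_bound=-1000,
                            upper_bound=1000, kind="exchange"))
    m.add_reaction(Reaction("bio", {"lcts[c]": -0.1}, upper_bound=1000,
                            kind="biomass"))
    m.biomass_id = "bio"
    return m


def butyrate_converter(model_id: str = "S2", species: str = "S2",
                       genus: str = "G2") -> MetabolicModel:
    """Cross-feeder: 1 lac -> 1 but; biomass 0.1 lac."""
    m = MetabolicModel(model_id, taxonomy=Taxonomy(species=species, genus=genus))
    for b in ("lac_L", "but"):
        for c in ("e", "c"):
            m.add_metabolite(met(b, c))
    m.add_reaction(Reaction("EX_lac_L(e)", {"lac_L[e]": -1}, lower_bound=-1000,
                            upper_bound=1000, kind="exchange"))
    m.add_reaction(Reaction("LACt_in", {"lac_L[e]": -1, "lac_L[c]": 1},
                            upper_bound=1000, kind="transport"))
    m.add_reaction(Reaction("BUT", {"lac_L[c]": -1, "but[c]": 1},
                            upper_bound=1000, subsystem="Butyrate production"))
    m.add_reaction(Reaction("BUTt", {"but[c]": -1, "but[e]": 1},
                            upper_bound=1000, kind="transport"))
    m.add_reaction(Reaction("EX_but(e)", {"but[e]": -1}, lower_bound=-1000,
                            upper_bound=1000, kind="exchange"))
    m.add_reaction(Reaction("bio", {"lac_L[c]": -0.1}, upper_bound=1000,
                            kind="biomass"))
    m.biomass_id = "bio"
    return m


@pytest.fixture
def toy_single_community():
    """Growth fixed at 1.0, lactose diet of 10; net lactate optimum 39.6."""
    pan = build_pan_model([lactose_fermenter()])
    config = CommunityConfig(coupling_factor=None, growth_window=(1.0, 1.0))
    community = assemble_community({"S": pan}, {"S": 1.0}, config,
                                   sample_id="toy")
    diet = DietFluxTable()
    diet.add("lcts", 10.0, "milk")
    return apply_diet(community, diet)


@pytest.fixture
def toy_cross_feeding_community():
    """Two-species chain; growth requirement off; butyrate optimum 40."""
    pans = {
        "S1": build_pan_model([lactose_fermenter("S1", "S1", "G1")]),
        "S2": build_pan_model([butyrate_converter()]),
    }
    config = CommunityConfig(coupling_factor=None, growth_window=(0.0, 1e6))
    community = assemble_community(pans, {"S1": 0.5, "S2": 0.5}, config,
                                   sample_id="toy2")
    diet = DietFluxTable()
    diet.add("lcts", 10.0, "milk")
    return apply_diet(community, diet)


@pytest.fixture(scope="session")
def packaged_catalog():
    from babybiome.hmo import load_catalog
    import os

    return load_catalog(os.path.join(DATA_DIR, "hmo_catalog"))


@pytest.fixture(scope="session")
def packaged_traits():
    from babybiome.hmo import load_trait_table
    import os

    return load_trait_table(os.path.join(DATA_DIR, "hmo_traits.tsv"))


@pytest.fixture(scope="session")
def small_universe():
    from babybiome.synth import UniverseConfig, generate_universe

    return generate_universe(UniverseConfig(seed=7))
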