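import numpy as np
import pandas as pd
import pytest

from babybiome.community import (
    AbundanceTable,
    CommunityConfig,
    MatchError,
    assemble_community,
    build_pan_model,
    load_community,
    match_taxa,
    normalize_abundances,
    save_community,
)
from babybiome.core import MetabolicModel, Metabolite, ModelError, Reaction
from babybiome.diet import DietFluxTable, apply_diet
from babybiome.lp import FluxSolver
from tests.conftest import butyrate_converter, lactose_fermenter, met


# ---------------------------------------------------------------------------
# taxa matching
# ---------------------------------------------------------------------------

class TestMatchTaxa:
    REGISTRY = {
        "pan_Blongum": "Bifidobacterium longum",
        "pan_Rgnavus": "Ruminococcus gnavus",
    }

    def test_underscores_match_spaces(self):
        result = match_taxa(["Bifidobacterium_longum"], self.REGISTRY)
        assert result.mapping == {"Bifidobacterium_longum": "pan_Blongum"}
        assert result.unmatched == []

    def test_bracket_stripping(self):
        result = match_taxa(["[Ruminococcus] gnavus"], self.REGISTRY)
        assert result.mapping == {"[Ruminococcus] gnavus": "pan_Rgnavus"}

    def test_subspecies_qualifier_stripped(self):
        registry = {"pan_inf": "Bifidobacterium longum subsp. infantis"}
        result = match_taxa(
            ["Bifidobacterium longum subspecies infantis"], registry
        )
        assert result.mapping == {
            "Bifidobacterium longum subspecies infantis": "pan_inf"
        }

    def test_unmatched_reported(self):
        result = match_taxa(["Escherichia coli"], self.REGISTRY)
        assert result.mapping == {}
        assert result.unmatched == ["Escherichia coli"]

    def test_no_fuzzy_matching(self):
        result = match_taxa(["Bifidobacterium longus"], self.REGISTRY)
        assert result.unmatched == ["Bifidobacterium longus"]

    def test_ambiguous_inputs_rejected(self):
        with pytest.raises(MatchError, match="both match"):
            match_taxa(
                ["Bifidobacterium longum", "Bifidobacterium_longum"],
                self.REGISTRY,
            )


# ---------------------------------------------------------------------------
# abundance normalization
# ---------------------------------------------------------------------------

def _table(data, samples=("s1",)):
    df = pd.DataFrame(data, index=list(data), columns=list(samples))
    for s in samples:
        df[s] = [data[t] for t in data]
    return AbundanceTable(df, pd.DataFrame(index=list(samples)))


class TestNormalizeAbundances:
    def test_simple_normalization(self):
        table = _table({"A": 30.0, "B": 10.0})
        out = normalize_abundances(table, cutoff=0)
        assert out.abundances["s1"].to_dict() == {"A": 0.75, "B": 0.25}

    def test_cutoff_zeroes_and_renormalizes(self):
        table = _table({"A": 0.9999, "B": 0.00005})
        out = normalize_abundances(table, cutoff=1e-4)
        assert out.abundances["s1"].to_dict() == {"A": 1.0}

    def test_all_below_cutoff_rejected(self):
        table = _table({"A": 1e-6, "B": 2e-6})
        with pytest.raises(ValueError, match="s1"):
            normalize_abundances(table, cutoff=1e-4)

    def test_unclassified_rows_dropped(self):
        table = _table({"A": 0.5, "unclassified": 0.5})
        out = normalize_abundances(table, cutoff=0)
        assert list(out.abundances.index) == ["A"]
        assert out.abundances.loc["A", "s1"] == 1.0

    def test_column_sums_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.random((6, 4)), index=list("ABCDEF"), columns=list("wxyz")
        )
        out = normalize_abundances(
            AbundanceTable(df, pd.DataFrame(index=list("wxyz"))), cutoff=0.1
        )
        assert np.allclose(out.abundances.sum(axis=0), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# pan models
# ---------------------------------------------------------------------------

def _strain(sid, reactions, biomass_stoich, bounds=None):
    m = MetabolicModel(sid)
    for b in ("a", "b", "c"):
        m.add_metabolite(met(b, "c"))
    for rid in reactions:
        lb, ub = (bounds or {}).get(rid, (0, 10))
        m.add_reaction(Reaction(rid, {"a[c]": -1, "b[c]": 1}, lower_bound=lb,
                                upper_bound=ub))
    m.add_reaction(Reaction("bio_" + sid, biomass_stoich, upper_bound=10,
                            kind="biomass"))
    m.biomass_id = "bio_" + sid
    return m


class TestPanModel:
    def test_single_strain_identity(self):
        strain = _strain("S1", ["R1", "R2"], {"a[c]": -0.5})
        pan = build_pan_model([strain])
        assert set(pan.reactions) == {"R1", "R2", "panBiomass"}
        assert dict(pan.biomass.stoichiometry) == {"a[c]": -0.5}
        for rid in ("R1", "R2"):
            assert dict(pan.reactions[rid].stoichiometry) == dict(
                strain.reactions[rid].stoichiometry
            )

    def test_union_of_reactions(self):
        s1 = _strain("S1", ["R1", "R2"], {"a[c]": -0.5})
        s2 = _strain("S2", ["R2", "R3"], {"a[c]": -0.5})
        pan = build_pan_model([s1, s2])
        assert set(pan.reactions) == {"R1", "R2", "R3", "panBiomass"}

    def test_bounds_envelope(self):
        s1 = _strain("S1", ["R2"], {"a[c]": -0.5}, bounds={"R2": (0, 10)})
        s2 = _strain("S2", ["R2"], {"a[c]": -0.5}, bounds={"R2": (-5, 5)})
        pan = build_pan_model([s1, s2])
        assert (pan.reactions["R2"].lower_bound,
                pan.reactions["R2"].upper_bound) == (-5, 10)

    def test_merged_biomass_component_means(self):
        s1 = _strain("S1", ["R1"], {"a[c]": -0.4})
        s2 = _strain("S2", ["R1"], {"a[c]": -0.8, "b[c]": -0.2})
        pan = build_pan_model([s1, s2])
        merged = dict(pan.biomass.stoichiometry)
        assert merged["a[c]"] == pytest.approx(-0.6)  # mean over both strains
        assert merged["b[c]"] == pytest.approx(-0.2)  # only in S2

    def test_conflicting_stoichiometry_rejected(self):
        s1 = _strain("S1", ["R1"], {"a[c]": -0.5})
        s2 = _strain("S2", [], {"a[c]": -0.5})
        s2.add_reaction(Reaction("R1", {"a[c]": -2, "b[c]": 1}, upper_bound=10))
        with pytest.raises(ModelError, match="disagree"):
            build_pan_model([s1, s2])

    def test_random_pairs_union_property(self):
        rng = np.random.default_rng(42)
        pool = [f"R{i}" for i in range(12)]
        for _ in range(25):
            ids1 = list(rng.choice(pool, size=rng.integers(1, 9),
                                   replace=False))
            ids2 = list(rng.choice(pool, size=rng.integers(1, 9),
                                   replace=False))
            s1 = _strain("S1", ids1, {"a[c]": -0.5})
            s2 = _strain("S2", ids2, {"a[c]": -0.5})
            pan = build_pan_model([s1, s2])
            assert set(pan.reactions) == set(ids1) | set(ids2) | {"panBiomass"}


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

def _mini_species(sid="M"):
    """4 reactions, 2 extracellular metabolites (a, b)."""
    m = MetabolicModel(sid)
    for b in ("a", "b"):
        for c in ("e", "c"):
            m.add_metabolite(met(b, c))
    m.add_reaction(Reaction("EX_a(e)", {"a[e]": -1}, lower_bound=-10,
                            upper_bound=10, kind="exchange"))
    m.add_reaction(Reaction("EX_b(e)", {"b[e]": -1}, lower_bound=-10,
                            upper_bound=10, kind="exchange"))
    m.add_reaction(Reaction("At", {"a[e]": -1, "a[c]": 1}, upper_bound=10,
                            kind="transport"))
    m.add_reaction(Reaction("bio", {"a[c]": -0.5}, upper_bound=10,
                            kind="biomass"))
    m.biomass_id = "bio"
    return m


class TestAssembleCommunity:
    def test_reaction_count_single_species(self):
        # 4 tagged + 2 lumen metabolites x 4 chain + 3 biomass-path = 15
        pan = build_pan_model([_mini_species()])
        # pan has EX_a, EX_b, At, panBiomass = 4 reactions, 2 [e] metabolites
        assert len(pan.reactions) == 4
        community = assemble_community(
            {"M": pan}, {"M": 1.0},
            CommunityConfig(coupling_factor=None), sample_id="x",
        )
        assert len(community.reactions) == 15

    def test_closed_form_size(self, small_universe):
        models, _, _, _ = small_universe
        species = sorted(models)[:4]
        pans = {s: build_pan_model([models[s]]) for s in species}
        n = len(species)
        abundances = {s: 1.0 / n for s in species}
        community = assemble_community(
            pans, abundances, CommunityConfig(coupling_factor=None),
            sample_id="x",
        )
        lumen = set()
        for s in species:
            for m in pans[s].metabolites.values():
                if m.compartment == "e":
                    lumen.add(m.base_id)
        expected = sum(len(p.reactions) for p in pans.values()) \
            + 4 * len(lumen) + 3
        assert len(community.reactions) == expected
        assert set(community.lumen_metabolites()) == lumen | {"microbeBiomass"}

    def test_community_biomass_coefficients(self):
        pans = {
            "A": build_pan_model([lactose_fermenter("A", "A")]),
            "B": build_pan_model([butyrate_converter("B", "B")]),
        }
        community = assemble_community(
            pans, {"A": 0.6, "B": 0.4}, CommunityConfig(), sample_id="x"
        )
        stoich = dict(community.reactions["communityBiomass"].stoichiometry)
        assert stoich["A_biomass[c]"] == pytest.approx(-0.6)
        assert stoich["B_biomass[c]"] == pytest.approx(-0.4)
        assert stoich["microbeBiomass[u]"] == 1.0

    def test_single_species_growth_equals_community_growth(self):
        pan = build_pan_model([lactose_fermenter()])
        community = assemble_community(
            {"S": pan}, {"S": 1.0},
            CommunityConfig(coupling_factor=None, growth_window=(0.0, 1000.0)),
            sample_id="x",
        )
        diet = DietFluxTable({"lcts": 10.0})
        community = apply_diet(community, diet)
        solver = FluxSolver(community)
        max_community = solver.maximize({"communityBiomass": 1.0})
        max_species = solver.maximize({"S_panBiomass": 1.0})
        assert max_community == pytest.approx(max_species, abs=1e-6)
        assert max_community == pytest.approx(100.0, abs=1e-6)  # 10 / 0.1

    def test_missing_pan_model_rejected(self):
        pan = build_pan_model([_mini_species()])
        with pytest.raises(ModelError, match="ghost"):
            assemble_community({"M": pan}, {"M": 0.5, "ghost": 0.5},
                               CommunityConfig(), sample_id="x")

    def test_unnormalized_rejected(self):
        pan = build_pan_model([_mini_species()])
        with pytest.raises(ModelError, match="normalized"):
            assemble_community({"M": pan}, {"M": 0.7}, CommunityConfig(),
                               sample_id="x")

    def test_chain_naming_dialect(self):
        pan = build_pan_model([_mini_species()])
        community = assemble_community({"M": pan}, {"M": 1.0},
                                       CommunityConfig(), sample_id="x")
        for base in ("a", "b"):
            for rid in (f"Diet_EX_{base}[d]", f"DUt_{base}", f"UFEt_{base}",
                        f"EX_{base}[fe]", f"M_IEX_{base}[u]"):
                assert rid in community.reactions, rid
        assert "communityBiomass" in community.reactions
        assert "UFEt_microbeBiomass" in community.reactions
        assert "EX_microbeBiomass[fe]" in community.reactions

    def test_coupling_constraints_listed(self):
        pan = build_pan_model([_mini_species()])
        community = assemble_community(
            {"M": pan}, {"M": 1.0},
            CommunityConfig(coupling_factor=400.0), sample_id="x",
        )
        coupled = {rid for rid, _, _ in community.couplings}
        # all tagged reactions except the species biomass itself
        assert coupled == {"M_IEX_a[u]", "M_IEX_b[u]", "M_At"}
        assert all(b == "M_panBiomass" and c == 400.0
                   for _, b, c in community.couplings)

    def test_coupling_relaxes_to_uncoupled(self, toy_single_community):
        from babybiome.simulation import compute_net_secretion

        base = toy_single_community  # coupling off
        relaxed = base.copy()
        relaxed.couplings = [
            (rid, "S_panBiomass", 1e9)
            for rid in base.reactions
            if rid.startswith("S_") and rid != "S_panBiomass"
        ]
        uncoupled = compute_net_secretion(base)
        coupled = compute_net_secretion(relaxed)
        for base_id in uncoupled.index:
            assert coupled[base_id] == pytest.approx(
                uncoupled[base_id], abs=1e-6), base_id

    def test_steady_state_feasibility_random_objectives(self):
        rng = np.random.default_rng(3)
        pans = {
            "A": build_pan_model([lactose_fermenter("A", "A")]),
            "B": build_pan_model([butyrate_converter("B", "B")]),
        }
        community = assemble_community(
            pans, {"A": 0.5, "B": 0.5},
            CommunityConfig(coupling_factor=None, growth_window=(0.0, 10.0)),
            sample_id="x",
        )
        community = apply_diet(community, DietFluxTable({"lcts": 5.0}))
        solver = FluxSolver(community)
        rids = solver.reaction_ids
        for _ in range(5):
            objective = {
                rids[i]: float(rng.normal())
                for i in rng.integers(0, len(rids), size=4)
            }
            solver.maximize(objective)  # must not raise


class TestSaveLoadCommunity:
    def test_roundtrip(self, tmp_path, toy_single_community):
        from babybiome.simulation import compute_net_secretion

        community = toy_single_community
        save_community(community, tmp_path)
        loaded = load_community(str(tmp_path / "toy.xml"))
        assert loaded.abundances == community.abundances
        assert set(loaded.reactions) == set(community.reactions)
        before = compute_net_secretion(community)
        after = compute_net_secretion(loaded)
        assert after["lac_L"] == pytest.approx(before["lac_L"], abs=1e-6)
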