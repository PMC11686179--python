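"""Taxa matching, pan-species models and community model assembly.

Community models follow the mgPipe naming dialect: per-taxon tagged
compartments, lumen metabolites ``m[u]``, diet/fecal transport chains
``Diet_EX_m[d] -> DUt_m -> UFEt_m -> EX_m[fe]``, species shuttles
``<tag>_IEX_m[u]`` and an abundance-weighted ``communityBiomass`` reaction
producing ``microbeBiomass[u]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from babybiome.core import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    Taxonomy,
    split_compartment,
)
from babybiome.lp import Coupling

BIG = 1_000_000.0

PAN_BIOMASS_ID = "panBiomass"
COMMUNITY_BIOMASS_ID = "communityBiomass"
BIOMASS_MET = "biomass"


class MatchError(ValueError):
    pass


# ---------------------------------------------------------------------------
# taxa matching
# ---------------------------------------------------------------------------

@dataclass
class TaxaMapping:
    mapping: Dict[str, str]  # input name -> registry model id
    unmatched: List[str]


_QUALIFIERS = {"subsp.", "subsp", "subspecies"}


def normalize_taxon(name: str) -> str:
    """Case-fold, underscores to spaces, strip bracket characters and
    subspecies qualifiers."""
    text = name.replace("_", " ")
    text = re.sub(r"[\[\]]", "", text)
    tokens = [t for t in text.split() if t.lower() not in _QUALIFIERS]
    return " ".join(tokens).casefold()


def match_taxa(
    names: Sequence[str], registry: Mapping[str, str]
) -> TaxaMapping:
    """Name-match input taxa to a registry of model id -> taxon name.

    Exact equality after normalization only; no fuzzy matching. Two inputs
    resolving to the same registry id is an ambiguity error.
    """
    normalized_registry: Dict[str, str] = {}
    for model_id, taxon in registry.items():
        key = normalize_taxon(taxon)
        if key in normalized_registry and normalized_registry[key] != model_id:
            raise MatchError(
                f"registry taxa {taxon!r} normalize ambiguously to {key!r}"
            )
        normalized_registry[key] = model_id
    mapping: Dict[str, str] = {}
    used: Dict[str, str] = {}
    unmatched: List[str] = []
    for name in names:
        model_id = normalized_registry.get(normalize_taxon(name))
        if model_id is None:
            unmatched.append(name)
            continue
        if model_id in used and used[model_id] != name:
            raise MatchError(
                f"inputs {used[model_id]!r} and {name!r} both match registry "
                f"model {model_id!r}"
            )
        used[model_id] = name
        mapping[name] = model_id
    return TaxaMapping(mapping=mapping, unmatched=unmatched)


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Taxon x sample relative abundances plus sample metadata."""

    abundances: pd.DataFrame  # rows: taxon, columns: sample
    metadata: pd.DataFrame  # indexed by sample id

    def samples(self) -> List[str]:
        return list(self.abundances.columns)


def load_abundance_table(
    abundance_path, metadata_path=None
) -> AbundanceTable:
    df = pd.read_csv(abundance_path, sep="\t", index_col=0)
    meta = (
        pd.read_csv(metadata_path, sep="\t", index_col=0)
        if metadata_path is not None
        else pd.DataFrame(index=df.columns)
    )
    return AbundanceTable(abundances=df, metadata=meta)


def normalize_abundances(
    table: AbundanceTable, cutoff: float = 1e-4
) -> AbundanceTable:
    """Drop unclassified rows, zero out entries below cutoff, renormalize
    each sample column to sum 1."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    df = table.abundances.copy().astype(float)
    keep = [
        t for t in df.index if not str(t).casefold().startswith("unclassified")
    ]
    df = df.loc[keep]
    df[df < cutoff] = 0.0
    sums = df.sum(axis=0)
    dead = [s for s in df.columns if sums[s] <= 0]
    if dead:
        raise ValueError(
            f"samples with no taxa above the abundance cutoff: {dead}"
        )
    df = df / sums
    df = df.loc[(df != 0).any(axis=1)]
    return AbundanceTable(abundances=df, metadata=table.metadata)


# ---------------------------------------------------------------------------
# pan-species models
# ---------------------------------------------------------------------------

def build_pan_model(
    strains: Sequence[MetabolicModel], pan_id: Optional[str] = None
) -> MetabolicModel:
    """Union-of-reactions pan-species model with a merged biomass reaction.

    Duplicate reaction ids must agree stoichiometrically; their bounds are
    widened to the envelope. The merged biomass contains the union of all
    strain biomass components with coefficients averaged over the strains
    containing each component.
    """
    if not strains:
        raise ValueError("at least one strain model required")
    species = strains[0].taxonomy.species or strains[0].id
    pan_id = pan_id or f"pan_{species.replace(' ', '_')}"

    pan = MetabolicModel(pan_id, name=f"pan-species model of {species}")
    pan.taxonomy = replace(strains[0].taxonomy)
    for strain in strains:
        for met in strain.metabolites.values():
            pan.add_metabolite(met)
        for rxn in strain.reactions.values():
            if rxn.id == strain.biomass_id:
                continue
            existing = pan.reactions.get(rxn.id)
            if existing is None:
                pan.add_reaction(rxn)
            else:
                if dict(existing.stoichiometry) != dict(rxn.stoichiometry):
                    raise ModelError(
                        f"strains disagree on stoichiometry of {rxn.id!r}"
                    )
                pan.reactions[rxn.id] = existing.with_bounds(
                    min(existing.lower_bound, rxn.lower_bound),
                    max(existing.upper_bound, rxn.upper_bound),
                )

    # merged biomass: per-component mean over the strains containing it
    component_totals: Dict[str, float] = {}
    component_counts: Dict[str, int] = {}
    lo, hi = float("inf"), float("-inf")
    for strain in strains:
        biomass = strain.biomass
        lo = min(lo, biomass.lower_bound)
        hi = max(hi, biomass.upper_bound)
        for met_id, coeff in biomass.stoichiometry.items():
            component_totals[met_id] = component_totals.get(met_id, 0.0) + coeff
            component_counts[met_id] = component_counts.get(met_id, 0) + 1
    merged = {
        met_id: component_totals[met_id] / component_counts[met_id]
        for met_id in component_totals
    }
    pan.add_reaction(
        Reaction(
            PAN_BIOMASS_ID,
            merged,
            name=f"merged biomass of {species}",
            lower_bound=lo,
            upper_bound=hi,
            subsystem="Biomass",
            kind="biomass",
        )
    )
    pan.biomass_id = PAN_BIOMASS_ID
    return pan


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunityConfig:
    abundance_cutoff: float = 1e-4
    coupling_factor: Optional[float] = 400.0  # None switches coupling off
    growth_window: Tuple[float, float] = (0.4, 1.0)  # 1/day


class CommunityModel(MetabolicModel):
    """Compartmentalized multi-species model with lumen and diet/fecal
    exchange chains."""

    def __init__(self, id: str, **kwargs):
        super().__init__(id, **kwargs)
        self.abundances: Dict[str, float] = {}
        self.couplings: List[Coupling] = []
        self.species_tags: Dict[str, str] = {}
        self.config: CommunityConfig = CommunityConfig()

    def copy(self, id: Optional[str] = None) -> "CommunityModel":
        clone = CommunityModel(id or self.id, name=self.name)
        clone.taxonomy = replace(self.taxonomy)
        clone.metabolites = dict(self.metabolites)
        clone.reactions = dict(self.reactions)
        clone.biomass_id = self.biomass_id
        clone.abundances = dict(self.abundances)
        clone.couplings = list(self.couplings)
        clone.species_tags = dict(self.species_tags)
        clone.config = self.config
        return clone

    def lumen_metabolites(self) -> List[str]:
        return sorted(
            m.base_id for m in self.metabolites.values() if m.compartment == "u"
        )

    def fecal_exchanges(self) -> Dict[str, str]:
        """Metabolite base id -> fecal exchange reaction id."""
        out = {}
        for rid in self.reactions:
            if rid.startswith("EX_") and rid.endswith("[fe]"):
                out[rid[3:-4]] = rid
        return out

    def diet_exchanges(self) -> Dict[str, str]:
        out = {}
        for rid in self.reactions:
            if rid.startswith("Diet_EX_") and rid.endswith("[d]"):
                out[rid[8:-3]] = rid
        return out


def _tag(taxon: str) -> str:
    return re.sub(r"\W+", "_", taxon.strip())


def save_community(community: "CommunityModel", directory: str) -> None:
    """Write a community as SBML plus a JSON sidecar (abundances, coupling)."""
    import json
    import os

    from babybiome.io import write_model

    os.makedirs(directory, exist_ok=True)
    write_model(community, os.path.join(directory, f"{community.id}.xml"),
                "sbml")
    sidecar = {
        "id": community.id,
        "abundances": community.abundances,
        "species_tags": community.species_tags,
        "coupling_factor": community.config.coupling_factor,
        "growth_window": list(community.config.growth_window),
        "abundance_cutoff": community.config.abundance_cutoff,
    }
    with open(os.path.join(directory, f"{community.id}.json"), "w") as handle:
        json.dump(sidecar, handle, indent=2, sort_keys=True)


def load_community(xml_path: str) -> "CommunityModel":
    """Load a community written by :func:`save_community`."""
    import json
    import os

    from babybiome.io import read_model

    base = read_model(xml_path, "sbml")
    with open(os.path.splitext(xml_path)[0] + ".json") as handle:
        sidecar = json.load(handle)
    community = CommunityModel(sidecar["id"], name=base.name)
    community.metabolites = dict(base.metabolites)
    community.reactions = dict(base.reactions)
    community.biomass_id = base.biomass_id or COMMUNITY_BIOMASS_ID
    community.abundances = dict(sidecar["abundances"])
    community.species_tags = dict(sidecar["species_tags"])
    community.config = CommunityConfig(
        abundance_cutoff=sidecar.get("abundance_cutoff", 1e-4),
        coupling_factor=sidecar.get("coupling_factor"),
        growth_window=tuple(sidecar.get("growth_window", (0.4, 1.0))),
    )
    factor = community.config.coupling_factor
    if factor is not None:
        biomass_of = {
            tag: f"{tag}_biomass" for tag in community.species_tags.values()
        }
        # locate each species' tagged biomass reaction
        tagged_biomass = {}
        for rid, rxn in community.reactions.items():
            if rxn.kind != "biomass" or rid == COMMUNITY_BIOMASS_ID:
                continue
            for tag in community.species_tags.values():
                if rid.startswith(f"{tag}_"):
                    tagged_biomass[tag] = rid
        for rid in community.reactions:
            if rid == COMMUNITY_BIOMASS_ID:
                continue
            for tag, bio_id in tagged_biomass.items():
                if rid.startswith(f"{tag}_") and rid != bio_id:
                    community.couplings.append((rid, bio_id, factor))
                    break
    return community


def assemble_community(
    pan_models: Mapping[str, MetabolicModel],
    abundances: Mapping[str, float],
    config: CommunityConfig = CommunityConfig(),
    sample_id: str = "community",
) -> CommunityModel:
    """Join pan-species models through a shared lumen compartment.

    ``abundances`` must be normalized (sum 1); every taxon with positive
    abundance needs a pan model. Abundances serve as the stoichiometric
    coefficients of the community biomass reaction, enforcing growth ratios.
    """
    retained = {t: a for t, a in abundances.items() if a > 0}
    if not retained:
        raise ModelError(f"sample {sample_id!r}: no taxa with abundance > 0")
    total = sum(retained.values())
    if abs(total - 1.0) > 1e-6:
        raise ModelError(
            f"sample {sample_id!r}: abundances not normalized (sum {total:g})"
        )
    missing = sorted(t for t in retained if t not in pan_models)
    if missing:
        raise ModelError(
            f"sample {sample_id!r}: taxa without pan models: {missing}"
        )

    community = CommunityModel(sample_id)
    community.config = config
    community.abundances = dict(retained)
    lumen: Dict[str, Metabolite] = {}

    for taxon in sorted(retained):
        model = pan_models[taxon]
        tag = _tag(taxon)
        community.species_tags[taxon] = tag

        def tagged(met_id: str) -> str:
            base, comp = split_compartment(met_id)
            return f"{tag}_{base}[{comp}]"

        for met in model.metabolites.values():
            community.add_metabolite(
                replace(met, id=tagged(met.id), compartment=met.compartment)
            )
            if met.compartment == "e" and met.base_id not in lumen:
                lumen[met.base_id] = replace(
                    met, id=f"{met.base_id}[u]", compartment="u"
                )
        # species biomass metabolite produced by its biomass reaction
        bio_met = Metabolite(
            f"{tag}_{BIOMASS_MET}[c]", name=f"{taxon} biomass", compartment="c"
        )
        community.add_metabolite(bio_met)

        tagged_biomass_id = None
        for rxn in sorted(model.reactions.values(), key=lambda r: r.id):
            if rxn.kind == "exchange":
                met_id = next(iter(rxn.stoichiometry))
                base = split_compartment(met_id)[0]
                shuttle = Reaction(
                    f"{tag}_IEX_{base}[u]",
                    {tagged(met_id): -1.0, f"{base}[u]": 1.0},
                    name=f"{taxon} lumen shuttle for {base}",
                    lower_bound=-BIG,
                    upper_bound=BIG,
                    subsystem="Microbe exchange",
                    kind="transport",
                )
                if f"{base}[u]" not in community.metabolites:
                    community.add_metabolite(lumen[base])
                community.add_reaction(shuttle)
                continue
            stoich = {tagged(m): c for m, c in rxn.stoichiometry.items()}
            rid = f"{tag}_{rxn.id}"
            if rxn.id == model.biomass_id:
                stoich[bio_met.id] = stoich.get(bio_met.id, 0.0) + 1.0
                tagged_biomass_id = rid
            community.add_reaction(
                Reaction(
                    rid,
                    stoich,
                    name=rxn.name,
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    subsystem=rxn.subsystem,
                    kind=rxn.kind,
                )
            )
        if tagged_biomass_id is None:
            raise ModelError(f"pan model for {taxon!r} lacks a biomass reaction")
        if config.coupling_factor is not None:
            for rxn in sorted(model.reactions.values(), key=lambda r: r.id):
                if rxn.id == model.biomass_id:
                    continue
                if rxn.kind == "exchange":
                    base = split_compartment(next(iter(rxn.stoichiometry)))[0]
                    rid = f"{tag}_IEX_{base}[u]"
                else:
                    rid = f"{tag}_{rxn.id}"
                community.couplings.append(
                    (rid, tagged_biomass_id, config.coupling_factor)
                )

    # make sure all lumen metabolites are present
    for base in sorted(lumen):
        if f"{base}[u]" not in community.metabolites:
            community.add_metabolite(lumen[base])

    # diet / fecal chains: 4 reactions per lumen metabolite
    for base in sorted(lumen):
        met_u = lumen[base]
        met_d = replace(met_u, id=f"{base}[d]", compartment="d")
        met_fe = replace(met_u, id=f"{base}[fe]", compartment="fe")
        community.add_metabolite(met_d)
        community.add_metabolite(met_fe)
        community.add_reaction(
            Reaction(
                f"Diet_EX_{base}[d]",
                {met_d.id: -1.0},
                name=f"diet exchange of {base}",
                lower_bound=-1000.0,
                upper_bound=0.0,
                subsystem="Exchange/demand reaction",
                kind="exchange",
            )
        )
        community.add_reaction(
            Reaction(
                f"DUt_{base}",
                {met_d.id: -1.0, met_u.id: 1.0},
                name=f"diet-to-lumen transport of {base}",
                lower_bound=0.0,
                upper_bound=BIG,
                subsystem="Transport, diet",
                kind="transport",
            )
        )
        community.add_reaction(
            Reaction(
                f"UFEt_{base}",
                {met_u.id: -1.0, met_fe.id: 1.0},
                name=f"lumen-to-feces transport of {base}",
                lower_bound=0.0,
                upper_bound=BIG,
                subsystem="Transport, fecal",
                kind="transport",
            )
        )
        community.add_reaction(
            Reaction(
                f"EX_{base}[fe]",
                {met_fe.id: -1.0},
                name=f"fecal exchange of {base}",
                lower_bound=0.0,
                upper_bound=BIG,
                subsystem="Exchange/demand reaction",
                kind="exchange",
            )
        )

    # community biomass path
    microbe_u = Metabolite("microbeBiomass[u]", name="community biomass",
                           compartment="u")
    microbe_fe = Metabolite("microbeBiomass[fe]", name="community biomass",
                            compartment="fe")
    community.add_metabolite(microbe_u)
    community.add_metabolite(microbe_fe)
    stoich = {
        f"{community.species_tags[t]}_{BIOMASS_MET}[c]": -retained[t]
        for t in sorted(retained)
    }
    stoich[microbe_u.id] = 1.0
    community.add_reaction(
        Reaction(
            COMMUNITY_BIOMASS_ID,
            stoich,
            name="abundance-weighted community biomass",
            lower_bound=config.growth_window[0],
            upper_bound=config.growth_window[1],
            subsystem="Community biomass",
            kind="biomass",
        )
    )
    community.add_reaction(
        Reaction(
            "UFEt_microbeBiomass",
            {microbe_u.id: -1.0, microbe_fe.id: 1.0},
            lower_bound=0.0,
            upper_bound=BIG,
            subsystem="Transport, fecal",
            kind="transport",
        )
    )
    community.add_reaction(
        Reaction(
            "EX_microbeBiomass[fe]",
            {microbe_fe.id: -1.0},
            lower_bound=0.0,
            upper_bound=BIG,
            subsystem="Exchange/demand reaction",
            kind="exchange",
        )
    )
    community.biomass_id = COMMUNITY_BIOMASS_ID
    return community
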