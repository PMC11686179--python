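"""LP interrogation of community models.

Net secretion of a metabolite is the optimum of a single LP maximizing
``v_fecal + v_diet`` (uptake-negative convention, i.e. secretion minus
dietary uptake), clamped at zero. Reaction/subsystem abundances are
abundance-weighted reaction carriage and need no LP. Species contributions
maximize the species' lumen shuttle flux under identical constraints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from babybiome.community import CommunityModel
from babybiome.lp import FluxSolver, InfeasibleError

logger = logging.getLogger(__name__)

OBJECTIVE_TOL = 1e-6


class SimulationError(RuntimeError):
    pass


def _community_solver(community: CommunityModel) -> FluxSolver:
    return FluxSolver(community, couplings=community.couplings)


def compute_net_secretion(
    community: CommunityModel,
    metabolites: Optional[Sequence[str]] = None,
    solver: Optional[FluxSolver] = None,
) -> pd.Series:
    """Net maximal secretion flux (mmol/person/day) per fecal metabolite.

    The diet must already be applied and the community growth window set.
    Raises :class:`SimulationError` if the community cannot grow on the diet.
    """
    solver = solver or _community_solver(community)
    fecal = community.fecal_exchanges()
    diet = community.diet_exchanges()
    targets = sorted(fecal) if metabolites is None else list(metabolites)
    values: Dict[str, float] = {}
    for base in targets:
        if base not in fecal:
            values[base] = 0.0
            continue
        objective = {fecal[base]: 1.0}
        if base in diet:
            objective[diet[base]] = 1.0
        try:
            optimum = solver.maximize(objective)
        except InfeasibleError as exc:
            raise SimulationError(
                f"sample {community.id!r}: community cannot reach the minimum "
                f"growth requirement on this diet"
            ) from exc
        values[base] = max(0.0, optimum)
    series = pd.Series(values, name=community.id)
    series.index.name = "metabolite"
    return series


@dataclass
class ReactionMetrics:
    reaction_abundance: pd.Series  # reaction id -> [0, 1]
    reaction_presence: pd.Series  # reaction id -> {0, 1}
    subsystem_abundance: pd.Series  # subsystem -> summed abundance


def compute_reaction_metrics(
    abundances: Mapping[str, float],
    pan_models: Mapping[str, object],
) -> ReactionMetrics:
    """Abundance-weighted reaction carriage for one sample.

    RA(j) = sum over species s of a_s * [j in reactions(s)]; presence is
    RA > 0; subsystem abundance sums member-reaction abundances.
    """
    ra: Dict[str, float] = {}
    subsystem_of: Dict[str, str] = {}
    for taxon, a in abundances.items():
        if a <= 0:
            continue
        model = pan_models[taxon]
        for rxn in model.reactions.values():
            ra[rxn.id] = ra.get(rxn.id, 0.0) + a
            if rxn.subsystem:
                subsystem_of.setdefault(rxn.id, rxn.subsystem)
    reaction_abundance = pd.Series(ra, dtype=float).sort_index()
    reaction_presence = (reaction_abundance > 0).astype(int)
    sub: Dict[str, float] = {}
    for rid, value in ra.items():
        name = subsystem_of.get(rid)
        if name:
            sub[name] = sub.get(name, 0.0) + value
    subsystem_abundance = pd.Series(sub, dtype=float).sort_index()
    for series in (reaction_abundance, reaction_presence):
        series.index.name = "reaction"
    subsystem_abundance.index.name = "subsystem"
    return ReactionMetrics(reaction_abundance, reaction_presence,
                           subsystem_abundance)


def compute_contributions(
    community: CommunityModel,
    metabolites: Sequence[str],
    growth_required: bool = True,
    solver: Optional[FluxSolver] = None,
) -> pd.DataFrame:
    """Maximal per-species secretion flux into the lumen per metabolite.

    Returns a long-format frame (sample, species, metabolite, flux). Species
    lacking a shuttle for a metabolite contribute 0.
    """
    solver = solver or _community_solver(community)
    overrides = None
    if not growth_required:
        overrides = {community.biomass_id: (0.0, 1_000_000.0)}
    records: List[Tuple[str, str, str, float]] = []
    for taxon in sorted(community.abundances):
        tag = community.species_tags[taxon]
        for base in metabolites:
            shuttle = f"{tag}_IEX_{base}[u]"
            if shuttle not in community.reactions:
                flux = 0.0
            else:
                try:
                    flux = max(
                        0.0,
                        solver.maximize({shuttle: 1.0},
                                        bound_overrides=overrides),
                    )
                except InfeasibleError as exc:
                    raise SimulationError(
                        f"sample {community.id!r}: infeasible under "
                        f"contribution constraints"
                    ) from exc
            records.append((community.id, taxon, base, flux))
    return pd.DataFrame(
        records, columns=["sample", "species", "metabolite", "flux"]
    )


def summarize_contributions(
    table: pd.DataFrame,
    genus_of: Mapping[str, str],
    group_of: Mapping[str, str],
) -> pd.DataFrame:
    """Mean species contribution per stratification group, summed to genus.

    ``table`` is the long-format output of :func:`compute_contributions`
    (possibly concatenated over samples).
    """
    df = table.copy()
    df["group"] = df["sample"].map(group_of)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "sample"].unique())
        raise ValueError(f"samples without a group label: {missing}")
    if not len(df):
        logger.warning("empty contribution table")
        return pd.DataFrame(columns=["genus", "metabolite", "group", "flux"])
    df["genus"] = df["species"].map(
        lambda s: genus_of.get(s, s.split()[0] if s else "")
    )
    species_means = (
        df.groupby(["group", "genus", "species", "metabolite"])["flux"]
        .mean()
        .reset_index()
    )
    genus_table = (
        species_means.groupby(["genus", "metabolite", "group"])["flux"]
        .sum()
        .reset_index()
    )
    empty_groups = [
        g for g in set(group_of.values())
        if g not in set(genus_table["group"])
    ]
    if empty_groups:
        logger.warning("groups without any samples: %s", sorted(empty_groups))
    return genus_table
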