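"""HMO degradation module: trait table, reaction catalog, model expansion.

The catalog is a directory of four TSV sheets:

* ``metabolites.tsv`` — tabular metabolite sheet plus a ``class`` column
  (``HMO`` | ``sugar`` | ``disaccharide`` | ``product`` | ``cofactor``);
* ``reactions.tsv`` — reaction sheet in the tabular model dialect;
* ``routes.tsv`` — per-HMO ordered pathway template
  (``hmo_id, mechanism, position, reaction_id``);
* ``templates.tsv`` — monosaccharide/product gap-fill groups
  (``product_id, position, reaction_id``).

Expansion injects, per trait-enabled HMO, the route's exchange, transport
and hydrolysis reactions, then gap-fills degradation-product dead ends with
catalog templates (greedy, alphabetical product order) until the model can
carry HMO uptake flux.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from babybiome.core import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    add_reactions,
    check_balance,
    split_compartment,
)
from babybiome.io import LoadError, PathLike, _read_tsv, read_metabolites_tsv, read_reactions_tsv
from babybiome.lp import FluxSolver, InfeasibleError

#: currency metabolites are catalog chemistry, not module content
CURRENCY_METS = frozenset({"h2o", "h", "atp", "adp", "pi"})

FEASIBILITY_TOL = 1e-6

TRANSPORT_MECHANISMS = ("ABC", "proton-symport", "extracellular-hydrolysis")


class GapfillError(RuntimeError):
    """No catalog template set can unblock HMO degradation."""


# ---------------------------------------------------------------------------
# trait table
# ---------------------------------------------------------------------------

_META_COLUMNS = (
    "strain_id",
    "species",
    "genus",
    "phylum",
    "level",
    "monosaccharide_only",
    "reference",
)

_TRUE = {"1", "true"}
_FALSE = {"0", "false", ""}


def _parse_bool(raw: str, context: str) -> bool:
    token = raw.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise LoadError(f"{context}: not a boolean: {raw!r}")


@dataclass
class TraitTable:
    """Strain/species x HMO capability flags with per-row references."""

    df: pd.DataFrame  # indexed by strain_id
    hmos: List[str]

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            dups = sorted(self.df.index[self.df.index.duplicated()])
            raise LoadError(f"duplicate strain ids in trait table: {dups}")
        if len(set(self.hmos)) != len(self.hmos):
            raise LoadError("duplicate HMO columns in trait table")
        flagged = self.df[self.hmos].any(axis=1)
        missing_ref = self.df.index[flagged & (self.df["reference"] == "")]
        if len(missing_ref):
            raise LoadError(
                "trait rows with capabilities but no reference: "
                f"{sorted(missing_ref)}"
            )

    @property
    def n_capable(self) -> int:
        """Strains with at least one true HMO flag."""
        return int(self.df[self.hmos].any(axis=1).sum())

    @property
    def capable_strains(self) -> List[str]:
        return sorted(self.df.index[self.df[self.hmos].any(axis=1)])

    @property
    def monosaccharide_only_strains(self) -> List[str]:
        return sorted(self.df.index[self.df["monosaccharide_only"]])

    def traits_for(
        self, strain_id: Optional[str] = None, species: Optional[str] = None
    ) -> Dict[str, bool]:
        """Capability flags, strain-level row overriding the species row."""
        if strain_id is not None and strain_id in self.df.index:
            row = self.df.loc[strain_id]
            return {h: bool(row[h]) for h in self.hmos}
        if species is not None:
            level = self.df.get("level")
            sub = self.df[(self.df["species"] == species)]
            if level is not None:
                species_rows = sub[sub["level"] == "species"]
                if len(species_rows):
                    row = species_rows.iloc[0]
                    return {h: bool(row[h]) for h in self.hmos}
        return {h: False for h in self.hmos}


def load_trait_table(path: PathLike) -> TraitTable:
    raw = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    columns = list(raw.columns)
    if "strain_id" not in columns:
        raise LoadError(f"trait table {path} lacks a strain_id column")
    hmos = [c for c in columns if c not in _META_COLUMNS]
    rows = raw.to_dict("records")
    if not rows:
        df = pd.DataFrame(
            columns=["species", "genus", "phylum", "level",
                     "monosaccharide_only", "reference", *hmos]
        )
        df.index.name = "strain_id"
        df["monosaccharide_only"] = df["monosaccharide_only"].astype(bool)
        for hmo in hmos:
            df[hmo] = df[hmo].astype(bool)
        return TraitTable(df=df, hmos=hmos)
    records = []
    for row in rows:
        rec: Dict[str, object] = {
            "strain_id": row["strain_id"],
            "species": row.get("species", ""),
            "genus": row.get("genus", ""),
            "phylum": row.get("phylum", ""),
            "level": row.get("level", "strain") or "strain",
            "monosaccharide_only": _parse_bool(
                row.get("monosaccharide_only", "0"),
                f"strain {row['strain_id']} monosaccharide_only",
            ),
            "reference": row.get("reference", ""),
        }
        for hmo in hmos:
            rec[hmo] = _parse_bool(row[hmo], f"strain {row['strain_id']} x {hmo}")
        records.append(rec)
    df = pd.DataFrame.from_records(records).set_index("strain_id")
    return TraitTable(df=df, hmos=hmos)


def coverage_matrix(traits: TraitTable) -> Tuple[pd.DataFrame, pd.Series]:
    """Binary strain x HMO matrix (ordered by phylum, species, strain) and
    per-strain capability counts."""
    if not len(traits.df):
        return pd.DataFrame(columns=traits.hmos), pd.Series(dtype=int)
    order = traits.df.assign(_strain=traits.df.index).sort_values(
        ["phylum", "species", "_strain"]
    )
    matrix = order[traits.hmos].astype(int)
    counts = matrix.sum(axis=1)
    counts.name = "n_hmos"
    return matrix, counts


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

@dataclass
class HMOCatalog:
    """Curated HMO reactions plus gap-fill templates."""

    metabolites: Dict[str, Metabolite]
    met_class: Dict[str, str]  # base id -> class
    reactions: Dict[str, Reaction]
    routes: Dict[str, List[str]]  # hmo base id -> ordered reaction ids
    mechanisms: Dict[str, str]  # hmo base id -> transport mechanism tag
    templates: Dict[str, List[str]]  # product base id -> reaction ids

    @property
    def hmo_ids(self) -> List[str]:
        return sorted(self.routes)

    def module_reaction_ids(self) -> List[str]:
        """Unique reaction ids across all per-HMO pathway templates."""
        seen: Dict[str, None] = {}
        for hmo in sorted(self.routes):
            for rid in self.routes[hmo]:
                seen.setdefault(rid)
        return list(seen)

    def module_metabolite_ids(self) -> List[str]:
        """Unique non-currency base metabolite ids referenced by the module."""
        bases: Dict[str, None] = {}
        for rid in self.module_reaction_ids():
            for met_id in self.reactions[rid].stoichiometry:
                base = split_compartment(met_id)[0]
                if base not in CURRENCY_METS:
                    bases.setdefault(base)
        return sorted(bases)

    def hmo_metabolites(self) -> List[str]:
        """Base ids classified as full HMO structures."""
        return sorted(b for b, cls in self.met_class.items() if cls == "HMO")

    def metabolites_for(self, reaction_ids: Iterable[str]) -> List[Metabolite]:
        needed: Dict[str, Metabolite] = {}
        for rid in reaction_ids:
            for met_id in self.reactions[rid].stoichiometry:
                needed[met_id] = self.metabolites[met_id]
        return list(needed.values())

    def validate(self) -> None:
        reports = [
            check_balance(rxn, self.metabolites)
            for rxn in self.reactions.values()
        ]
        bad = [r for r in reports if r.verdict == "unbalanced"]
        if bad:
            details = "; ".join(
                f"{r.reaction_id}: elements {dict(r.element_imbalance)}, "
                f"charge {r.charge_imbalance:+g}"
                for r in bad
            )
            raise LoadError(f"unbalanced catalog reactions: {details}")
        for hmo, route in self.routes.items():
            if not route:
                raise LoadError(f"HMO {hmo!r} has an empty route")
            if self.mechanisms.get(hmo) not in TRANSPORT_MECHANISMS:
                raise LoadError(
                    f"HMO {hmo!r}: unknown transport mechanism "
                    f"{self.mechanisms.get(hmo)!r}"
                )


def load_catalog(path: PathLike) -> HMOCatalog:
    """Load and balance-validate a catalog directory."""
    path = str(path)
    mets = read_metabolites_tsv(os.path.join(path, "metabolites.tsv"))
    met_rows = _read_tsv(os.path.join(path, "metabolites.tsv"))
    met_class: Dict[str, str] = {}
    for row in met_rows:
        base = split_compartment(row["id"])[0]
        cls = row.get("class", "product")
        prev = met_class.setdefault(base, cls)
        if prev != cls:
            raise LoadError(f"metabolite {base!r} has conflicting classes")
    reactions = {r.id: r for r in read_reactions_tsv(os.path.join(path, "reactions.tsv"))}

    routes: Dict[str, List[str]] = {}
    mechanisms: Dict[str, str] = {}
    route_rows = _read_tsv(os.path.join(path, "routes.tsv"))
    for row in sorted(route_rows, key=lambda r: (r["hmo_id"], int(r["position"]))):
        hmo = row["hmo_id"]
        routes.setdefault(hmo, []).append(row["reaction_id"])
        mechanisms[hmo] = row["mechanism"]
        if row["reaction_id"] not in reactions:
            raise LoadError(
                f"route for {hmo!r} references unknown reaction "
                f"{row['reaction_id']!r}"
            )

    templates: Dict[str, List[str]] = {}
    template_path = os.path.join(path, "templates.tsv")
    if os.path.exists(template_path):
        for row in sorted(
            _read_tsv(template_path),
            key=lambda r: (r["product_id"], int(r["position"])),
        ):
            if row["reaction_id"] not in reactions:
                raise LoadError(
                    f"template for {row['product_id']!r} references unknown "
                    f"reaction {row['reaction_id']!r}"
                )
            templates.setdefault(row["product_id"], []).append(row["reaction_id"])

    catalog = HMOCatalog(
        metabolites={m.id: m for m in mets},
        met_class=met_class,
        reactions=reactions,
        routes=routes,
        mechanisms=mechanisms,
        templates=templates,
    )
    catalog.validate()
    return catalog


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------

@dataclass
class ExpansionReport:
    model_id: str
    reactions_added: List[str] = field(default_factory=list)
    gapfilled: List[str] = field(default_factory=list)
    feasibility: Dict[str, bool] = field(default_factory=dict)

    @property
    def n_added(self) -> int:
        return len(self.reactions_added)


def _open_exchange_overrides(model: MetabolicModel) -> Dict[str, Tuple[float, float]]:
    return {r.id: (-1000.0, 1000.0) for r in model.exchanges()}


def _max_uptake(model: MetabolicModel, exchange_id: str) -> float:
    """Maximal uptake flux through an exchange with all exchanges opened."""
    solver = FluxSolver(model)
    overrides = _open_exchange_overrides(model)
    overrides[exchange_id] = (-1000.0, 1000.0)
    try:
        return solver.maximize({exchange_id: -1.0}, bound_overrides=overrides)
    except InfeasibleError:
        return 0.0


def _route_products(
    model: MetabolicModel, route_ids: Iterable[str]
) -> List[str]:
    """Non-currency degradation-product base ids of a route's reactions."""
    products: Dict[str, None] = {}
    for rid in route_ids:
        rxn = model.reactions.get(rid)
        if rxn is None or rxn.kind == "exchange":
            continue
        for met_id, coeff in rxn.stoichiometry.items():
            base = split_compartment(met_id)[0]
            if coeff > 0 and base not in CURRENCY_METS:
                products.setdefault(base)
    return sorted(products)


def _consumers(model: MetabolicModel, base: str, ignore: Iterable[str]) -> int:
    """Count reactions able to drain metabolite ``base`` (any compartment)."""
    skip = set(ignore)
    n = 0
    for rxn in model.reactions.values():
        if rxn.id in skip:
            continue
        for met_id, coeff in rxn.stoichiometry.items():
            if split_compartment(met_id)[0] != base:
                continue
            if coeff < 0 or (rxn.kind == "exchange") or rxn.lower_bound < 0:
                n += 1
                break
    return n


def gapfill_degradation(
    model: MetabolicModel,
    hmo_id: str,
    catalog: HMOCatalog,
    tol: float = FEASIBILITY_TOL,
) -> Tuple[MetabolicModel, List[str]]:
    """Unblock degradation of ``hmo_id`` by adding catalog templates.

    Iterative LP dead-end detection: while the model cannot carry HMO uptake
    flux, the catalog's catabolism template for the alphabetically first
    unconsumable degradation product is added; fails if no completing set
    exists.
    """
    route = catalog.routes[hmo_id]
    exchange_id = route[0]
    added: List[str] = []
    products = _route_products(model, route)
    while _max_uptake(model, exchange_id) < tol:
        dead_ends = [
            p for p in products if _consumers(model, p, ignore=route) == 0
        ]
        candidates = [
            p
            for p in dead_ends
            if p in catalog.templates
            and not all(t in model.reactions for t in catalog.templates[p])
        ]
        if not candidates:
            blocked = dead_ends or products
            raise GapfillError(
                f"cannot complete degradation of {hmo_id!r}: dead-end "
                f"products without catalog templates: {blocked}"
            )
        product = candidates[0]
        template = catalog.templates[product]
        model, _ = add_reactions(
            model,
            [catalog.reactions[t] for t in template],
            catalog.metabolites_for(template),
        )
        added.extend(t for t in template if t not in added)
    return model, added


def expand_model(
    model: MetabolicModel,
    traits_row: Mapping[str, bool],
    catalog: HMOCatalog,
    gapfill: bool = True,
    tol: float = FEASIBILITY_TOL,
) -> Tuple[MetabolicModel, ExpansionReport]:
    """Inject per-HMO exchange/transport/degradation reactions.

    Idempotent: reactions already present are skipped and a second run adds
    nothing. Per-HMO feasibility (positive uptake flux in an LP with open
    exchange bounds) is recorded in the report.
    """
    report = ExpansionReport(model_id=model.id)
    enabled = sorted(h for h, flag in traits_row.items() if flag)
    for hmo in enabled:
        if hmo not in catalog.routes:
            raise ModelError(f"HMO {hmo!r} flagged in traits but absent from catalog")
    expanded = model
    for hmo in enabled:
        route = catalog.routes[hmo]
        before = set(expanded.reactions)
        expanded, _ = add_reactions(
            expanded,
            [catalog.reactions[rid] for rid in route],
            catalog.metabolites_for(route),
        )
        report.reactions_added.extend(
            rid for rid in route if rid not in before
        )
        if gapfill:
            expanded, gap_added = gapfill_degradation(
                expanded, hmo, catalog, tol=tol
            )
            new_gap = [rid for rid in gap_added if rid not in report.gapfilled]
            report.gapfilled.extend(new_gap)
            report.reactions_added.extend(new_gap)
        report.feasibility[hmo] = _max_uptake(expanded, route[0]) >= tol
    return expanded, report
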