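"""End-to-end orchestration: expand -> diet -> build -> simulate -> stats.

A run consumes a workspace of plain-text inputs (SBML models, trait/catalog
TSVs, abundance + metadata TSVs, diet TSVs) and emits CSV result tables plus
a JSON manifest capturing the config snapshot and per-sample model sizes.
Per-sample failures are logged and skipped; a run fails only if no sample
succeeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import platform
import time
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

import babybiome
from babybiome.community import (
    AbundanceTable,
    CommunityConfig,
    assemble_community,
    build_pan_model,
    load_abundance_table,
    match_taxa,
    normalize_abundances,
)
from babybiome.core import MetabolicModel
from babybiome.diet import DietConfig, DietFluxTable, apply_diet, load_diet
from babybiome.hmo import expand_model, load_catalog, load_trait_table
from babybiome.io import read_model
from babybiome.simulation import (
    compute_contributions,
    compute_net_secretion,
    compute_reaction_metrics,
)
from babybiome.stats import compare_features

logger = logging.getLogger(__name__)

SUPPORTED_SOLVERS = ("highs",)

FEATURE_FAMILIES = (
    "net_secretion",
    "reaction_abundance",
    "reaction_presence",
    "subsystem_abundance",
)


@dataclass
class RunConfig:
    models: str
    traits: str
    catalog: str
    abundance: str
    metadata: str
    diets: str
    output: str
    abundance_cutoff: float = 1e-4
    coupling_factor: Optional[float] = 400.0
    growth_window: Tuple[float, float] = (0.4, 1.0)
    micronutrients: Tuple[str, ...] = ()
    trickle_flux: float = 0.1
    contribution_metabolites: Tuple[str, ...] = ()
    solver: str = "highs"
    seed: int = 0
    gapfill: bool = True
    comparisons: Tuple[str, ...] = ()

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


class ConfigError(ValueError):
    pass


def load_config(path: str) -> RunConfig:
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    violations = _violations(raw, base_dir=os.path.dirname(os.path.abspath(path)))
    if violations:
        raise ConfigError("; ".join(violations))
    return _to_config(raw, base_dir=os.path.dirname(os.path.abspath(path)))


def _to_config(raw: Mapping, base_dir: str) -> RunConfig:
    paths = dict(raw.get("paths", {}))
    params = dict(raw.get("parameters", {}))
    resolved = {
        key: os.path.join(base_dir, value) if not os.path.isabs(value) else value
        for key, value in paths.items()
    }
    window = params.get("growth_window", (0.4, 1.0))
    return RunConfig(
        models=resolved["models"],
        traits=resolved["traits"],
        catalog=resolved["catalog"],
        abundance=resolved["abundance"],
        metadata=resolved["metadata"],
        diets=resolved["diets"],
        output=resolved.get("output", os.path.join(base_dir, "results")),
        abundance_cutoff=float(params.get("abundance_cutoff", 1e-4)),
        coupling_factor=(
            None
            if params.get("coupling_factor", 400.0) in (None, "none", "off")
            else float(params.get("coupling_factor", 400.0))
        ),
        growth_window=(float(window[0]), float(window[1])),
        micronutrients=tuple(params.get("micronutrients", ())),
        trickle_flux=float(params.get("trickle_flux", 0.1)),
        contribution_metabolites=tuple(
            params.get("contribution_metabolites", ())
        ),
        solver=str(params.get("solver", "highs")),
        seed=int(params.get("seed", 0)),
        gapfill=bool(params.get("gapfill", True)),
        comparisons=tuple(raw.get("comparisons", ())),
    )


def _violations(raw: Mapping, base_dir: str) -> List[str]:
    problems: List[str] = []
    paths = raw.get("paths", {})
    for key in ("models", "traits", "catalog", "abundance", "metadata", "diets"):
        value = paths.get(key)
        if not value:
            problems.append(f"missing path: {key}")
            continue
        resolved = value if os.path.isabs(value) else os.path.join(base_dir, value)
        if not os.path.exists(resolved):
            problems.append(f"path does not exist: {key} = {value}")
    params = raw.get("parameters", {})
    if float(params.get("abundance_cutoff", 0)) < 0:
        problems.append("abundance cutoff must be >= 0")
    coupling = params.get("coupling_factor", 400.0)
    if coupling not in (None, "none", "off") and float(coupling) <= 0:
        problems.append("coupling factor must be > 0 (or null to disable)")
    window = params.get("growth_window", (0.4, 1.0))
    if len(window) != 2 or float(window[0]) > float(window[1]) or float(window[0]) < 0:
        problems.append("growth window must be 0 <= lower <= upper")
    if float(params.get("trickle_flux", 0.1)) < 0:
        problems.append("trickle flux must be >= 0")
    solver = str(params.get("solver", "highs"))
    if solver not in SUPPORTED_SOLVERS:
        problems.append(
            f"unknown solver {solver!r}; supported: {list(SUPPORTED_SOLVERS)}"
        )
    return problems


def validate_config(path: str) -> List[str]:
    """List of violations; empty means the config is clean."""
    try:
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
    except OSError as exc:
        raise IOError(f"cannot read config {path}: {exc}") from exc
    return _violations(raw, base_dir=os.path.dirname(os.path.abspath(path)))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _load_models(models_dir: str) -> Dict[str, MetabolicModel]:
    models: Dict[str, MetabolicModel] = {}
    for entry in sorted(os.listdir(models_dir)):
        path = os.path.join(models_dir, entry)
        if entry.endswith(".xml"):
            model = read_model(path, "sbml")
        elif os.path.isdir(path):
            model = read_model(path, "tabular")
        else:
            continue
        models[model.id] = model
    if not models:
        raise ConfigError(f"no models found under {models_dir}")
    return models


def _select_diet(diets_dir: str, meta_row: pd.Series) -> DietFluxTable:
    if str(meta_row.get("delivery_mode", "")) == "maternal":
        return load_diet(os.path.join(diets_dir, "maternal.tsv"))
    feeding = str(meta_row.get("feeding", "breastfed"))
    if feeding == "combined":  # combined feeding receives the breastfed diet
        feeding = "breastfed"
    time_point = str(meta_row.get("time_point", "5 days")).replace(" ", "_")
    return load_diet(os.path.join(diets_dir, f"{feeding}_{time_point}.tsv"))


@dataclass
class RunResult:
    n_samples: int
    n_succeeded: int
    failed: List[str] = field(default_factory=list)
    output: str = ""

    @property
    def ok(self) -> bool:
        return self.n_succeeded > 0


def run_pipeline(config: RunConfig) -> RunResult:
    os.makedirs(config.output, exist_ok=True)
    started = time.time()

    models = _load_models(config.models)
    traits = load_trait_table(config.traits)
    catalog = load_catalog(config.catalog)

    expansion_rows = []
    expanded: Dict[str, MetabolicModel] = {}
    for model_id in sorted(models):
        model = models[model_id]
        row = traits.traits_for(
            strain_id=model_id, species=model.taxonomy.species
        )
        new_model, report = expand_model(
            model, row, catalog, gapfill=config.gapfill
        )
        expanded[model_id] = new_model
        expansion_rows.append(
            {
                "model_id": model_id,
                "n_added": report.n_added,
                "gapfilled": ";".join(report.gapfilled),
                "infeasible_hmos": ";".join(
                    sorted(h for h, ok in report.feasibility.items() if not ok)
                ),
            }
        )
    pd.DataFrame(expansion_rows).to_csv(
        os.path.join(config.output, "expansion_report.tsv"),
        sep="\t", index=False,
    )

    # pan-species models over strains grouped by species
    by_species: Dict[str, List[MetabolicModel]] = {}
    for model in expanded.values():
        species = model.taxonomy.species or model.id
        by_species.setdefault(species, []).append(model)
    pan_models = {
        species: build_pan_model(strains)
        for species, strains in sorted(by_species.items())
    }

    table = load_abundance_table(config.abundance, config.metadata)
    registry = {species: species for species in pan_models}
    mapping = match_taxa(list(table.abundances.index), registry)
    if mapping.unmatched:
        logger.warning(
            "%d input taxa unmatched to the model registry: %s",
            len(mapping.unmatched), ", ".join(mapping.unmatched),
        )
    matched = table.abundances.loc[list(mapping.mapping)]
    matched.index = [mapping.mapping[t] for t in matched.index]
    table = normalize_abundances(
        AbundanceTable(matched, table.metadata), cutoff=config.abundance_cutoff
    )

    community_config = CommunityConfig(
        abundance_cutoff=config.abundance_cutoff,
        coupling_factor=config.coupling_factor,
        growth_window=config.growth_window,
    )
    diet_config = DietConfig(
        micronutrients=config.micronutrients, trickle_flux=config.trickle_flux
    )

    secretion_rows: Dict[str, pd.Series] = {}
    reaction_rows: Dict[str, pd.Series] = {}
    presence_rows: Dict[str, pd.Series] = {}
    subsystem_rows: Dict[str, pd.Series] = {}
    contribution_frames: List[pd.DataFrame] = []
    sizes = {}
    failed: List[str] = []

    for sample in table.samples():
        t0 = time.time()
        try:
            column = table.abundances[sample]
            column = column[column > 0]
            community = assemble_community(
                pan_models, column.to_dict(), community_config,
                sample_id=sample,
            )
            meta_row = (
                table.metadata.loc[sample]
                if sample in table.metadata.index
                else pd.Series(dtype=object)
            )
            diet = _select_diet(config.diets, meta_row)
            community = apply_diet(community, diet, diet_config)
            secretion_rows[sample] = compute_net_secretion(community)
            metrics = compute_reaction_metrics(column.to_dict(), pan_models)
            reaction_rows[sample] = metrics.reaction_abundance
            presence_rows[sample] = metrics.reaction_presence
            subsystem_rows[sample] = metrics.subsystem_abundance
            if config.contribution_metabolites:
                contribution_frames.append(
                    compute_contributions(
                        community, list(config.contribution_metabolites)
                    )
                )
            sizes[sample] = {
                "species": int(len(column)),
                "reactions": len(community.reactions),
                "metabolites": len(community.metabolites),
            }
            logger.info("sample %s done in %.2fs", sample, time.time() - t0)
        except Exception as exc:  # per-sample isolation is intentional
            logger.error("sample %s failed: %s", sample, exc)
            failed.append(sample)

    def write_matrix(rows: Dict[str, pd.Series], name: str) -> pd.DataFrame:
        frame = pd.DataFrame(rows).T.fillna(0.0).sort_index()
        frame = frame[sorted(frame.columns)]
        frame.index.name = "sample"
        frame.to_csv(
            os.path.join(config.output, f"{name}.csv"), float_format="%.10g"
        )
        return frame

    features: Dict[str, pd.DataFrame] = {}
    if secretion_rows:
        features["net_secretion"] = write_matrix(secretion_rows, "net_secretion")
        features["reaction_abundance"] = write_matrix(
            reaction_rows, "reaction_abundance"
        )
        features["reaction_presence"] = write_matrix(
            presence_rows, "reaction_presence"
        )
        features["subsystem_abundance"] = write_matrix(
            subsystem_rows, "subsystem_abundance"
        )
    if contribution_frames:
        contributions = pd.concat(contribution_frames, ignore_index=True)
        genus_of = {
            species: pan_models[species].taxonomy.genus
            for species in pan_models
        }
        contributions["genus"] = contributions["species"].map(genus_of)
        contributions = contributions[
            ["sample", "species", "genus", "metabolite", "flux"]
        ]
        contributions.to_csv(
            os.path.join(config.output, "contributions.csv"),
            index=False, float_format="%.10g",
        )

    stats_files = []
    for comparison in config.comparisons:
        for family, frame in features.items():
            try:
                result = compare_features(frame, table.metadata, comparison)
            except Exception as exc:
                logger.error(
                    "comparison %r on %s failed: %s", comparison, family, exc
                )
                continue
            tag = (
                comparison.replace(":", "-").replace("@", "-at-")
                .replace("=", "-").replace(" ", "_")
            )
            filename = f"stats_{family}_{tag}.csv"
            result.to_csv(
                os.path.join(config.output, filename),
                index=False, float_format="%.10g",
            )
            stats_files.append(filename)

    manifest = {
        "package": {"name": "babybiome", "version": babybiome.__version__},
        "python": platform.python_version(),
        "config": config.to_dict(),
        "unmatched_taxa": mapping.unmatched,
        "samples": sizes,
        "failed_samples": failed,
        "stats_files": stats_files,
        "wallclock_seconds": round(time.time() - started, 2),
    }
    with open(os.path.join(config.output, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)

    return RunResult(
        n_samples=len(table.samples()),
        n_succeeded=len(sizes),
        failed=failed,
        output=config.output,
    )
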