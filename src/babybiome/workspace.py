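"""Write a complete ready-to-run synthetic workspace to disk."""

from __future__ import annotations

import os
import shutil
from typing import Dict, Mapping, Optional

import yaml

from babybiome.diet import build_stage_diet
from babybiome.io import write_model
from babybiome.synth import (
    DATA_DIR,
    CohortConfig,
    SOLID_FOODS,
    UniverseConfig,
    generate_cohort,
    generate_diets,
    generate_universe,
    maternal_diet,
)


def write_trait_table(traits, path: str) -> None:
    df = traits.df.copy()
    df["monosaccharide_only"] = df["monosaccharide_only"].astype(int)
    for hmo in traits.hmos:
        df[hmo] = df[hmo].astype(int)
    df.to_csv(path, sep="\t")


def write_workspace(
    path: str,
    universe_config: UniverseConfig = UniverseConfig(),
    cohort_config: CohortConfig = CohortConfig(),
    parameters: Optional[Mapping] = None,
    comparisons: tuple = (),
) -> str:
    """Models, traits, catalog, cohort, diets and a run config under ``path``.

    Returns the path of the written ``config.yaml``.
    """
    os.makedirs(path, exist_ok=True)
    models, taxonomy, traits, _catalog = generate_universe(universe_config)

    models_dir = os.path.join(path, "models")
    os.makedirs(models_dir, exist_ok=True)
    for species in sorted(models):
        model = models[species]
        write_model(model, os.path.join(models_dir, f"{model.id}.xml"), "sbml")

    write_trait_table(traits, os.path.join(path, "traits.tsv"))
    taxonomy.to_csv(os.path.join(path, "taxonomy.tsv"), sep="\t")

    catalog_dir = os.path.join(path, "catalog")
    if os.path.exists(catalog_dir):
        shutil.rmtree(catalog_dir)
    shutil.copytree(os.path.join(DATA_DIR, "hmo_catalog"), catalog_dir)

    cohort = generate_cohort(cohort_config, taxonomy)
    cohort.abundances.to_csv(
        os.path.join(path, "abundance.tsv"), sep="\t", float_format="%.10g"
    )
    cohort.metadata.to_csv(os.path.join(path, "metadata.tsv"), sep="\t")

    diets_dir = os.path.join(path, "diets")
    os.makedirs(diets_dir, exist_ok=True)
    for (variant, time_point), (table, regimen) in generate_diets().items():
        diet = build_stage_diet(regimen, table, SOLID_FOODS)
        name = f"{variant}_{time_point.replace(' ', '_')}.tsv"
        diet.write(os.path.join(diets_dir, name))
    maternal_diet().write(os.path.join(diets_dir, "maternal.tsv"))

    config = {
        "paths": {
            "models": "models",
            "traits": "traits.tsv",
            "catalog": "catalog",
            "abundance": "abundance.tsv",
            "metadata": "metadata.tsv",
            "diets": "diets",
            "output": "results",
        },
        "parameters": dict(parameters or {}),
        "comparisons": list(comparisons),
    }
    config_path = os.path.join(path, "config.yaml")
    with open(config_path, "w") as handle:
        yaml.safe_dump(config, handle, sort_keys=True)
    return config_path
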