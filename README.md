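# babybiome

Personalized constraint-based modeling of infant gut microbiome metabolism.

`babybiome` builds abundance-weighted, compartmentalized community metabolic
models from species-level genome-scale reconstructions, expands those
reconstructions with a curated human milk oligosaccharide (HMO) degradation
module, contextualizes each community with a stage-specific infant diet
(breast milk or formula, plus solid foods at later stages), and interrogates
the models by linear programming:

* **net metabolite secretion** — per metabolite, the maximal fecal secretion
  flux minus dietary uptake (mmol/person/day), from a single LP;
* **reaction / subsystem abundance and presence** — abundance-weighted
  reaction carriage per sample;
* **species contributions** — maximal per-species secretion flux of selected
  metabolites under community constraints;
* **group statistics** — Wilcoxon rank-sum tests with Benjamini–Hochberg
  correction for delivery-mode, time-point and infant-vs-maternal contrasts.

A synthetic-data module generates a toy universe of guild-structured strain
reconstructions (HMO degraders, lactate producers, butyrate cross-feeders,
B-vitamin producers, generalists), cohort abundance tables with planted
delivery-mode and time effects, and stage diets, so the entire pipeline runs
end-to-end without any downloads.

## Quick start

Generate a synthetic workspace with a planted CSD depletion of the
HMO-degrader guild, validate the config, and run the full pipeline:

```bash
babybiome synth --out ws --seed 1 --n-vd 10 --n-csd 10 --csd-depletion 0.1
babybiome validate --config ws/config.yaml
babybiome run --config ws/config.yaml
```

Outputs land in `ws/results/`: `net_secretion.csv`,
`reaction_abundance.csv`, `reaction_presence.csv`,
`subsystem_abundance.csv`, `contributions.csv`, per-comparison
`stats_*.csv` files, an `expansion_report.tsv` and a `manifest.json`
(config snapshot, per-sample model sizes, failures).

Individual stages are also exposed:

```bash
babybiome expand   --models ws/models --traits ws/traits.tsv --catalog ws/catalog --out expanded
babybiome diet     --time-point "6 months" --feeding breastfed --out diet.tsv
babybiome build    --abundance ws/abundance.tsv --models expanded --out communities
babybiome simulate --community communities --diet ws/diets/breastfed_5_days.tsv --out sim
babybiome stats    --features ws/results/net_secretion.csv --metadata ws/metadata.tsv \
                   --compare "delivery_mode:VD_vs_CSD@time_point=5 days" --out stats.csv
```

## Package layout

| module | contents |
| --- | --- |
| `babybiome.core` | `Metabolite`, `Reaction`, `MetabolicModel`, Hill-formula parsing, mass/charge balance checking, reaction merging |
| `babybiome.io` | SBML L3+FBC reader/writer (libsbml) and a two-sheet TSV model dialect |
| `babybiome.hmo` | trait table, HMO reaction catalog, trait-driven model expansion with LP-based gap-filling, coverage matrix |
| `babybiome.diet` | concentration→flux conversion, stage diets, applying diets to community models |
| `babybiome.community` | taxa name-matching, abundance normalization, pan-species models, community assembly (lumen, diet/fecal chains, coupling constraints) |
| `babybiome.simulation` | net secretion, reaction/subsystem metrics, species contributions |
| `babybiome.stats` | rank-sum test (exact/normal), BH adjustment, Spearman, comparison drivers |
| `babybiome.synth` | synthetic universe, cohorts with planted effects, toy diets |
| `babybiome.pipeline` / `babybiome.cli` | YAML config, orchestration, `babybiome` CLI |
| `babybiome/data/` | packaged curated HMO catalog and strain trait-table fixtures |

The packaged fixtures encode the curated HMO degradation module: 78 pathway
reactions over 34 module metabolites (28 full HMO structures plus simple
sugars/disaccharides), a trait table with 243 HMO-utilizing strains from 31
species, and 7 further strains receiving only monosaccharide pathways (250
reconstructions slated for expansion in total). `scripts/build_fixtures.py`
regenerates the fixture TSVs deterministically.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: fixture count
reproduction, hand-solved LP oracle equivalence, 100% balance validation,
pan-model union properties, statistics oracles (full-enumeration Wilcoxon,
brute-force BH), null calibration of the type-I error, planted-effect
recovery through the full pipeline, and byte-level determinism of outputs.

## Conventions

* Metabolite ids carry bracketed compartment suffixes (`lcts[c]`, `glc_D[u]`);
  compartments are `c`/`e` (species), `u` (lumen), `d` (diet), `fe` (fecal).
* Community reactions follow the mgPipe dialect: `Diet_EX_m[d]`, `DUt_m`,
  `<tag>_IEX_m[u]`, `UFEt_m`, `EX_m[fe]`, `communityBiomass`.
* Negative flux through an exchange is uptake; diet exchanges never secrete.
* Coupling constraints |v| ≤ c·v_biomass (default c = 400, configurable or
  off) tie every species reaction to that species' biomass flux.
* Community growth window defaults to [0.4, 1.0] day⁻¹.
* Only LP objective values are reported, never individual flux vectors.
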