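# metabopipe

Chainable post-preprocessing for LC-MS metabolomics in Python: common data
models, isotopologue/adduct grouping into *empirical compounds*, multi-level
annotation, QA/QC, and standardized three-table outputs.

The pipeline picks up where preprocessing (feature detection/alignment) leaves
off. It ingests an aligned feature table (TSV, Asari/XCMS-style), a sample
metadata CSV, and optional reference resources (compound lists, authentic
standard tables, MSP spectral libraries, centroided mzML with MS2 scans), and
produces a curated feature table, a per-(feature, annotation) annotation
table, and a sample metadata table, plus a chained empirical-compound JSON.

## Features

- **Data models** (`metabopipe.models`): spectra, elution peaks, features,
  feature tables, acquisitions, empirical compounds with ordered annotation
  chains, experiments, and metabolic-model carrier types. Lossless,
  byte-stable JSON serialization (schema in `src/metabopipe/schemas/`).
- **Pre-annotation** (`metabopipe.preannotation`): groups co-eluting features
  whose m/z differences match isotope/adduct relations into charge-aware
  isotope × adduct grids, infers neutral masses, and emits one empirical
  compound per grid. Small connected components are resolved optimally
  (verified against an exhaustive oracle in the test suite); the relation
  table is overridable via CSV.
- **Annotation** (`metabopipe.annotation`): level 4 by neutral-mass lookup,
  level 1b by m/z + RT match to authentic standards, levels 2/1a by MS2
  cosine similarity with an interval-tree precursor index. Levels follow the
  spirit of the Schymanski confidence scheme.
- **QA/QC** (`metabopipe.qaqc`): acquisition metrics, failed-injection
  detection by feature-count z-score, median-TIC normalization, blank
  masking, rare-feature removal, half-minimum imputation, parametric
  empirical-Bayes batch correction (self-contained ComBat-style
  implementation), PCA and correlation clustermap summaries.
- **Synthetic fixtures** (`metabopipe.synthetic`): seed-deterministic
  generators with exported ground truth for every pipeline stage, so the full
  workflow is testable offline.

## CLI

Every analysis step is one subcommand over an on-disk experiment directory;
outputs are referenced by name, and every invocation is recorded in the
experiment's command log.

```sh
metabopipe assemble metadata.csv my_experiment/
metabopipe ingest-table my_experiment/ features.tsv --dialect asari --out raw
metabopipe qc-metrics my_experiment/ --table raw
metabopipe detect-outliers my_experiment/ --table raw --drop --out clean
metabopipe blank-mask my_experiment/ --table clean --out masked
metabopipe drop-rare my_experiment/ --table masked --out dense
metabopipe normalize my_experiment/ --table dense --out norm
metabopipe impute my_experiment/ --table norm --out imputed
metabopipe batch-correct my_experiment/ --table imputed --out corrected
metabopipe build-empcpds my_experiment/ --table corrected --out empcpds
metabopipe annotate-l4 my_experiment/ --empcpds empcpds --compounds compounds.csv
metabopipe annotate-l1b my_experiment/ --empcpds empcpds --standards standards.csv
metabopipe map-ms2 my_experiment/ --empcpds empcpds --mzml run_dda.mzML
metabopipe annotate-ms2 my_experiment/ --empcpds empcpds --library mona.msp
metabopipe export my_experiment/ --table corrected --empcpds empcpds
metabopipe report my_experiment/
```

The same steps are available programmatically via
`metabopipe.experiment.run_step` or by calling the module functions directly.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes exhaustive brute-force oracles for grid grouping,
precursor indexing and peak pairing, hypothesis property tests, and a
dedicated acceptance module (`tests/test_acceptance.py`).

## Conventions

- Retention times in seconds everywhere (mzML minute-encoded times converted
  at read); masses in Da; ppm error = 1e6·Δm/m against the reference mass;
  ppm windows are closed intervals.
- Missing feature-table intensities read as 0; imputation is an explicit step.
- All QC operations are pure table→table transforms with provenance tags;
  stored tables are never mutated (copy-on-write naming).
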