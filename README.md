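# humoralkit

A tested, reusable pipeline for humoral-immunity analyses around immune
checkpoint blockade cohorts:

- **repertoire** — immunoglobulin isotype assignment from BCR `c_call`s with
  gene-expression (IGHC UMI) rescue, CDR3-keyed clonotyping within patient,
  clonal-expansion calls (expanded = ≥ 2 cells per clonotype), and tracking
  of clones shared across tissues and timepoints.
- **abundance** — compositional differential abundance by Dirichlet
  regression (log link on concentrations, quasi-Newton ML with analytic
  gradient), likelihood-ratio tests with Benjamini–Hochberg correction, and
  paired tumor-vs-adjacent Wilcoxon enrichment.
- **spatial** — TLS-like community detection on mIHC centroids (CD3/CD8/CD20
  seeds linked within 10 µm), mean-shift centroiding with equal-area
  concentric-ring density profiles, radial-gradient aggregate enrichment
  with union-of-disks areas, and KNN (k = 10) / Leiden plasma-cell
  infiltration scores (MZB1⁺ fraction per community).
- **serology** — ELISA reciprocal-titer interpolation on fourfold titrations
  (1:100–1:6,400; positive above a reciprocal titer of 100), the ELISpot
  "> 50 spots and ≥ 2× background" rule, and seromics (protein-array) hit
  calling with class-stratified counts and group tests.
- **synthetic_data** — seeded generators for every input (cell annotations,
  AIRR rearrangements, IGHC UMIs, spatial centroid fields, ELISA/ELISpot/
  seromics tables) with ground-truth registries for exact scoring. All
  generator distributions are stand-ins: they reproduce the qualitative
  structure the analyses assume, not any published cohort.

No external data are required; the full pipeline runs on synthetic inputs.

## CLI

```bash
# run everything with defaults into ./humoralkit_out
humoralkit all --seed 1 --output-dir out

# individual stages (generate must run first, or point inputs.* at files)
humoralkit generate --seed 1 --output-dir out
humoralkit repertoire --output-dir out
humoralkit abundance --output-dir out
humoralkit spatial --output-dir out
humoralkit serology --output-dir out

# markdown summary from the run manifest
humoralkit report --output-dir out
```

All stages are driven by a YAML config (see `examples/config.yaml`);
`--seed`/`--output-dir` override the file. Every output table carries a
`# schema=... config_hash=... seed=...` header line, and re-running with an
identical config and seed reproduces byte-identical outputs.

## Layout

```
src/humoralkit/
  synthetic_data/   # cohort, tissue and serology generators + validated specs
  repertoire.py     # isotypes, clonotypes, expansion, clone tracking
  abundance.py      # Dirichlet regression, LRT/BH, tumor enrichment
  spatial.py        # TLS communities, ring profiles, infiltration scores
  serology.py       # titers, ELISpot calls, seromics hits
  pipeline.py       # orchestration, manifest, report
  pipeline_cli.py   # click CLI
tests/              # unit + property + acceptance suites
scripts/acceptance.py
```
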