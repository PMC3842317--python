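# hsp90flux

Analysis pipeline for proteome dynamics under Hsp90 inhibition, built
around three assay types and a synthetic-data generator with known ground
truth:

- **SILAC protein-group filtering** (`hsp90flux.silac`) — read wide
  protein-group TSVs (label-swapped replicates re-oriented on load), drop
  contaminant/reverse/lab-list rows, blank single-evidence ratios, apply a
  per-time-point replicate-occurrence rule and a ×1.41 replicate-agreement
  outlier rule, with conserved filter bookkeeping.
- **Significance calling and temporal clustering**
  (`hsp90flux.differential`) — per-time-point one-sample t-tests on log2
  ratios, Benjamini–Hochberg correction, and assignment of each
  significant protein's (0, 6h, 20h) trajectory to one of 12 qualitative
  change templates by maximal Pearson correlation (cluster 13 = no
  significant change, cluster 14 = detected at one time point only); a
  generic hypergeometric term-enrichment test.
- **Pulse-chase turnover kinetics** (`hsp90flux.kinetics`) — first-order
  decomposition of old-pool ("chase") and new-pool ("pulse") signals into
  per-condition decay constants `k_d` (log-linear least squares),
  synthesis rates `V_s` (closed-form linear fit), half-lives `ln2/k_d`,
  condition ratios, global-median adjustment, and category summaries.
- **NanoString nCounter processing** (`hsp90flux.nanostring`) —
  background subtraction (mean + 2 sd of negative controls, floor 1),
  positive-control ratio QC gate (< 3), geNorm reference-gene selection,
  geometric-mean normalization, and log2 fold-changes of condition
  geometric means.
- **Synthetic data** (`hsp90flux.simulate`) — generators for all three
  inputs with planted cluster patterns, lognormal turnover-rate
  distributions (including category presets with distinct half-life
  shifts), and count noise; every generator returns its ground truth.
- **Integration** (`hsp90flux.integrate`) — alignment of tables on
  identical protein-group id sets, network node-attribute export with a
  clamped red-to-blue color scale, and a one-call pipeline runner.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis) and independent brute-force
oracles (`tests/oracles.py`) for the BH step-up, the t-distribution tail,
hypergeometric tails and geNorm M values. `tests/test_acceptance.py`
checks the headline recovery targets on the calibrated presets.

## CLI

```sh
hsp90flux simulate --kind stsilac --out sim.tsv --n-proteins 100 --seed 1
hsp90flux filter --in sim.tsv --out filtered.tsv --label-swap 3 --report report.json
hsp90flux cluster --in filtered.tsv --out clusters.tsv --alpha 0.05
hsp90flux simulate --kind pcsilac --out series.csv --seed 1
hsp90flux kinetics --in series.csv --out fits.tsv
hsp90flux nanostring --counts counts.csv --samples samples.csv --out fc.tsv
hsp90flux align --a clusters.tsv --b fits.tsv --out joint.tsv
hsp90flux report --config pipeline.yaml --out outdir --seed 1
```

`report` takes a YAML config with `stsilac` / `pcsilac` / `nanostring`
sections, each either `simulate: {...}` or `input: <path>`, and writes
every intermediate table plus `run_log.json`.

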