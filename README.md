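# beehex

Flower-color analysis pipeline for a polymorphic plant–pollinator system:
parametric modelling of petal and nectar-guide reflectance spectra, a
bumblebee trichromatic (hexagon color space) vision model with a
discrimination threshold, availability-adjusted visitation statistics,
AICc-based multimodel comparison, and soil–morph association stages — all
exercised end-to-end on a seeded synthetic-data generator, so nothing
needs to be downloaded.

## Modules

| module | what it does |
| --- | --- |
| `beehex.spectra` | petal reflectance model (specular offset + sigmoidal long-pass + Gaussian pigment dip), least-squares fitting, morph classification from dip depth, resampling/averaging |
| `beehex.vision` | receptor templates (peaks 347/424/539 nm), ground-level daylight illuminant (zero below 310 nm), band contributions, von Kries adaptation, hexagon projection, chromatic contrast/distances, pairwise morph tables, spectral locus |
| `beehex.synth` | seeded generator: morph-specific spectra (with the probe-dilution artifact on spots), population censuses, visitation, fitness, plant-size and region-structured soil tables |
| `beehex.stats` | adjusted visitation, fitness summaries, AICc + Akaike weights, five-candidate GLM comparison, Spearman + Benjamini-Hochberg screening, soil PCA |
| `beehex.io` | long-format spectra CSV reading/writing, provenance headers |
| `beehex.cli` | orchestration + `beehex` command line |

Two excitation modes are implemented and always recorded in outputs:
`literal` (the sensitivity- and illuminant-weighted mean reflectance) and
`adapted` (quantum-catch ratio against a green-foliage background with the
hyperbolic transform). The pipeline default is `literal`; switch with
`--mode adapted`.

## Command line

```sh
# generate a synthetic dataset (5 populations by default)
beehex simulate --seed 1 --out runs/ds

# fit the petal model to every spectrum
beehex spectra-fit --spectra runs/ds/spectra.csv --out runs

# hexagon coordinates + pairwise morph distance tables
beehex beevision --spectra runs/ds/spectra.csv --mode literal --out runs

# availability-adjusted visitation rates
beehex visitation --census runs/ds/visitation.csv --out runs

# model selection, soil correlations, PCA, morph frequencies
beehex analyze --data-dir runs/ds --out runs

# everything in one pass
beehex all --seed 1 --out runs/full
```

A documented generator configuration example lives in
`examples/config.yaml` (`--config` on `simulate`/`all`). Every output CSV
starts with `# key: value` provenance lines (seed, config hash, mode,
threshold); readers skip them automatically.

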