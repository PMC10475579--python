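# phenosel

Phenomic selection toolkit for multitemporal canopy-reflectance trials.

The package implements an end-to-end analysis for open-pollinated progeny
trials observed monthly with a five-band multispectral camera (blue 450,
green 560, red 650, red-edge 730, NIR 840 nm):

- **`phenosel.synthdata`** — a synthetic trial generator with known variance
  components: 2 sites x 20 blocks x 20 families in single-tree plots
  (800 trees), exact-count mortality (30% -> 560 survivors), 11 monthly
  observations, genetically correlated spectra and growth, seasonal growth
  dynamics, and the full generating truth retained for recovery tests.
- **`phenosel.vegindices`** — the 15 vegetation indices computed from the
  five bands, assembled into the 20-column per-month feature matrix that
  stands in for a marker matrix.
- **`phenosel.genetics`** — EM-REML estimation of the
  `y = mu + block + family + e` mixed model per trait-month; narrow-sense
  heritability `2.5 * s2_f / (s2_f + s2_b + s2_e)`, genetic correlations via
  the sum-trait identity, family breeding values (BLUPs), rankings, and
  genetic gain at selection fractions.
- **`phenosel.kernels`** — the linear kernel `GB = XX'/p`, the Gaussian
  kernel `GK = exp(-h d^2/q)` with `q` the median off-diagonal squared
  distance, and the constant within-family pedigree kernel `A`.
- **`phenosel.phenopred`** — kernel BLUP with one (MV) or two (MV+pedigree)
  random effects and repeated, seeded 80/20 cross-validation summarized as
  mean +/- SD Pearson correlation.
- **`phenosel.pbwas`** — a GWAS-style association scan with months as
  chromosomes and the 20 feature columns as markers; block/family random
  effects provide the structure correction, hits flagged at P < 1e-3
  (strict, uncorrected).
- **`phenosel.pipeline`** — orchestration, YAML config, seeding, and the
  `phenosel` CLI.

Variance components everywhere are REML-based; the kernel models use exact
eigendecomposition REML for single-kernel fits and numerical restricted
likelihood maximization for two-kernel fits.

## CLI

```sh
phenosel simulate --seed 1 --out ds/                 # synthetic trial
phenosel features --data ds/ --month Jul --out f.csv # 560 x 20 matrix
phenosel genpar   --data ds/ --out gp/               # h2, BLUPs, gains
phenosel kernels  --data ds/ --month Jul --kind GK --h 1.0 --out k.csv
phenosel predict  --data ds/ --month Jul --trait height \
                  --models GB,GK --reps 100 --train-frac 0.8 \
                  --split tree --seed 1 --out cv.csv
phenosel pbwas    --data ds/ --threshold 1e-3 --out pbwas.csv
phenosel run-all  --seed 1 --out report/             # everything
```

`run-all` writes `genpar.csv`, `rg.csv`, `ranking.csv`, `gains.csv`,
`cv_results.csv`, `cv_summary.csv`, `pbwas.csv`, `manhattan.csv` and
`report.json`; every table carries the config hash as a leading comment
line, and identical config + seed reproduce the report byte for byte.

## Notes on conventions

- ARI is implemented literally as `G/NIR` and MARI as `(1/G - 1/E)/NIR`,
  following the source index table rather than the classical forms.
- Degenerate index denominators yield NaN (with a warning), never an
  exception; NaNs are mean-imputed before kernel construction.
- Genetic gain defaults to `mean(top ceil(r*n) BVs) - mean(all BVs)`; a
  `literal_form` flag multiplies the selected mean by `r` instead.
- Feature columns are standardized before both kernels; the GK bandwidth
  `h` (default 1) and pedigree relatedness `rho` (default 0.4 = 1/2.5) are
  exposed as options.
- The association scan estimates variance components once per trait-month
  under the null model and tests each variable by GLS at those estimates
  (the standard two-stage mixed-model GWAS strategy); `--no-structure`
  gives the naive regression for comparison.
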