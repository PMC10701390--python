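# sparsegp

Sparse-testing experimental design and multi-kernel genomic prediction for
NAM-structured (nested association mapping) plant-breeding panels.

The package covers the full pipeline:

1. **`sparsegp.synthetic_nam`** — simulate a NAM panel (many bi-parental
   families sharing one hub parent, three ancestry groups of founders, fully
   inbred RILs) and multi-environment phenotypes from an additive
   variance-component model with genomic, genomic×environment (GE) and
   family×environment (FE) terms.
2. **`sparsegp.sparse_design`** — selection method S1: random base
   allocations assigning each RIL to exactly one environment, systematic
   training-size reduction in nested groups, redistribution of masked RILs
   as overlapping RILs (O-RILs) observed in all environments, exact design
   accounting and a $/plot cost model.
3. **`sparsegp.ssd`** — selection method S2: a supersaturated-design
   exchange algorithm that picks a fixed-size sample maximizing or
   minimizing genetic diversity via the E(S²) criterion
   (trace((X₀′X₀)²), computed through the Gram-matrix identity; an
   off-diagonal-only variant is available).
4. **`sparsegp.gp_models`** — marker QC (missingness/MAF filters,
   mean-imputation, standardization), the genomic relationship matrix
   G = XX′/p, Hadamard-product interaction covariance structures, and a
   Gibbs sampler for the nested models
   M1 (E + L + G), M2 (+GE), M3 (+F + FE) that predicts every unobserved
   RIL-in-environment cell.
5. **`sparsegp.evaluation`** — within-environment predictive ability
   (Pearson r, averaged across environments, optionally post-stratified by
   ancestry group or family), between-environment stability correlations,
   and the replicate × size × composition × model experiment driver.
6. **`sparsegp.io` / `sparsegp.cli`** — plain-text I/O and the `sparsegp`
   command-line umbrella.

## CLI

```bash
sparsegp simulate --config sim.yaml --out out/sim
sparsegp design   --genotype-table out/sim/genotypes.tsv --grid base --replicates 5 --seed 1 --out out/design
sparsegp ssd      --genotype-table out/sim/genotypes.tsv --n 195 --direction max --seed 1 --out out/ssd.json
sparsegp fit      --model M3 --pheno out/sim/phenotypes.csv --geno out/sim/genotypes.tsv \
                  --families out/sim/families.tsv --alloc out/design/base_rep0.json --out out/fit
sparsegp evaluate --pred out/fit/predictions.csv --truth out/sim/phenotypes.csv --out out/ability.csv
sparsegp run      --config run.yaml --out out/run
```

Every stage writes a `provenance.json` (package version, configuration,
seeds) so it can be re-run bit-identically. A master seed deterministically
derives all stage seeds (`sparsegp._seeds`).

### File schemas

| file | format | columns |
|---|---|---|
| genotypes | TSV | `ril_id`, then one column per marker; dosages 0/1/2, `NA` missing |
| markers | TSV | `marker`, `chromosome`, `order` |
| families | TSV | `ril_id`, `family_id`, `ancestry_group` |
| phenotypes | CSV | `ril_id`, `family_id`, `ancestry_group`, `env_id`, `value`, `observed` |
| allocation | JSON | per-environment `no_rils` + `prediction`, shared `o_rils`, `meta` |

### Run configuration (`run.yaml`)

```yaml
seed: 9
simulation:            # SimConfig fields
  n_families_g1: 3
  n_families_g2: 3
  n_families_g3: 3
  rils_per_family: 30
  n_markers: 600
  n_env: 6
grid:                  # composition grid over training sizes
  sizes: [45]
  overlap_step: 5
  min_no: 5
models: [M1, M2, M3]
replicates: 5
mcmc: {n_iter: 800, burn_in: 200, thin: 2}
```

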