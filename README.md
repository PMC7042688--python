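# qfasakit

Quantitative fatty acid signature analysis (QFASA) toolkit: estimate a
predator's diet composition from its adipose fatty acid signature against a
multi-species prey library, check the model with simulation diagnostics, run
distance-based permutation statistics on the resulting diet compositions,
and work through predator energetics arithmetic. A synthetic-data module
generates prey libraries, calibration coefficients and predator cohorts with
known true diets, so the entire pipeline is testable without field data.

## Modules

- `qfasakit.signatures` — compositional data model (signatures, calibration
  coefficients, prey libraries, ice-index tables), validation, zero
  replacement, and delimited-text readers/writers.
- `qfasakit.qfasa_core` — the estimation engine: symmetrized Kullback-Leibler
  distance, prey mixture model, multi-start simplex-constrained optimization,
  and lipid-fraction conversion from fatty-acid-space coefficients (`alpha`)
  to biomass diet proportions (`pi`).
- `qfasakit.diagnostics` — prey-on-prey identification and pseudo-predator
  diet-recovery simulations.
- `qfasakit.comp_stats` — chi-square distance, sequential-SS permutational
  MANOVA (with exact enumeration for small designs), Holm adjustment,
  per-prey and pairwise-class wrappers, Spearman trend tests on annual
  means, and sea-ice covariate models.
- `qfasakit.energetics` — daily intake through annual population prey
  consumption and share of regional prey biomass, with exact and
  display-rounded columns.
- `qfasakit.synthetic_data` — seeded scenario realization (library, CCs,
  cohort, ice table) with named random substreams.

## CLI

```bash
# realize a synthetic scenario into fixture files
qfasakit synth --seed 3 --n-predators 50 --out-dir scratch/demo

# estimate diets
qfasakit estimate --predators scratch/demo/predators.csv \
    --prey scratch/demo/prey.csv --cc scratch/demo/cc.csv \
    --lipids scratch/demo/lipids.csv --seed 0 --out scratch/demo/diet.csv

# model diagnostics
qfasakit prey-on-prey --prey scratch/demo/prey.csv --cc scratch/demo/cc.csv \
    --n-reps 100 --seed 0 --out scratch/demo/pop.csv
qfasakit pseudo-predator --prey scratch/demo/prey.csv --cc scratch/demo/cc.csv \
    --true-diet 0.45,0.2,0.05,0.15,0.15 --n-runs 100 --seed 0 \
    --out scratch/demo/pp.csv

# permutation statistics and trends
qfasakit stats --diet-table scratch/demo/diet.csv \
    --prey ringed_seal,bearded_seal,beluga,bowhead,seabird \
    --ice scratch/demo/ice.csv --n-perm 999 --seed 0 \
    --out scratch/demo/stats.json

# energetics chain
qfasakit energetics
```

Global behaviors: `--seed` controls every source of randomness,
`--lipid-override species=value` reruns lipid sensitivity analyses,
`--fa-subset` restricts the modelled fatty acid set, `--config` supplies a
YAML file of defaults. Output tables carry a `#`-prefixed provenance header
(version, seed, parameters).

## Notes

- Signatures are stored as proportions on the simplex; percent-scale input
  files (rows summing to ~100) are closed automatically on read.
- Zeros are replaced by a small constant (default 1e-5) and renormalized
  before any log-based distance.
- Calibration correction divides predator signatures by the coefficients and
  renormalizes (predator → prey space); the multiplicative direction is used
  when simulating predators.
- Permutation p-values use the add-one convention and free label
  permutation; `exact=True` enumerates all label permutations for small n.
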