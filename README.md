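# cosolv

Cosolvency solubility modeling for drugs in binary solvent mixtures.

The package converts solubility datasets between nine solute/solvent
concentration-unit combinations, fits the Jouyban–Acree log-linear mixing
model by ordinary least squares (with optional significance-based term
pruning), back-calculates solubilities, evaluates five error criteria,
and orchestrates comparative and outlier-sensitivity studies.  A
synthetic-data module generates datasets with known ground truth for all
of it.

## The model

The saturated solubility `x_m` of a solute in a binary mixture at
temperature `T` (kelvin) is modeled as

```
ln x_m(T) = w1·ln x1(T) + w2·ln x2(T) + (w1·w2/T) · Σ_{i=0}^{np} J_i·(w1 − w2)^i
```

where `w1`, `w2 = 1 − w1` are the solute-free solvent fractions, `x1`,
`x2` the measured mono-solvent solubilities, and `J_0…J_np` interaction
coefficients (kelvin) estimated by regressing the excess-log response
`ln x_m − w1·ln x1 − w2·ln x2` on `w1·w2·(w1−w2)^i / T` without an
intercept.  With all `J_i = 0` this reduces to the ideal (Yalkowsky)
log-linear mixing rule.

Unit codes 1–9 combine the solvent-composition basis (mole, mass, volume
fraction → rows) with the solute unit (mole fraction, mol/L, g/L →
columns), numbered row-major.  Conversions between the gravimetric and
volumetric solute scales use the saturated-solution density; volume
fractions use the volume-additive convention from pure-solvent densities.

Error criteria: MRD% (percent mean relative deviation), RMSD and mean
absolute deviation on both the arithmetic (RMSD1, E1) and logarithmic
(RMSD2, E2) scales.  MRD% and the log-scale criteria are invariant under
uniform rescaling of the solubilities, which is why the molar and g/L
codes of the same dataset give identical fits and MRD% while their E1
values differ by exactly the drug's molar mass.  MRD% and E1 use absolute
deviations (signed means would cancel for bias-free fits).

## Library quick start

```python
from cosolv import (
    GeneratorConfig, generate_dataset, run_code_analysis, run_full_study,
    perturb_and_compare, UnitCode,
)

ds = generate_dataset(GeneratorConfig(noise_sigma=0.05, seed=1))
fit, report = run_code_analysis(ds, UnitCode(4), np_index=2, prune=True)
print(fit.coefficients, report.mrd_percent)

summary = run_full_study([ds], codes=range(1, 10))
print(summary.overall_frame())
```

## CLI

```bash
# generate a synthetic dataset from a YAML generator config
cosolv simulate --config config.yaml --out dataset.csv

# fit every dataset in a directory under codes 1-9
cosolv study --datasets data/ --codes 1-9 --np 2 --prune --alpha 0.05 --out results/
# -> summary.csv, overall.csv, per_drug.csv, skew.csv, correlations.csv

# single-record outlier experiment (refit and compare all five criteria)
cosolv perturb --dataset dataset.csv --index 5 --factor 10 --code 4
```

Dataset files are CSV (records table plus a `#`-prefixed JSON metadata
header holding the drug/solvent specs) or JSON; see
`cosolv.datamodel.read_dataset` / `write_dataset`.

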