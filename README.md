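# htgp

Pedigree and genomic prediction of wheat grain yield, with aerial
high-throughput phenotypes — canopy temperature (CT) and the green/red
normalized difference vegetation indices (GNDVI, RNDVI) — used as
*secondary traits* in multi-trait mixed models.

## Who this is for

Breeders and quantitative geneticists who want to predict grain yield (GY)
for selection candidates that cannot yet be yield-tested, but that *can* be
imaged from the air. The package covers the full analysis chain:

1. **Phenotype QC** — within-date repeatability
   `r² = σ²_g / (σ²_g + σ²_e / n_rep)` per trial, Studentized-residual
   outlier removal (two-sided p < 0.001, remove once and refit), overall
   repeatability across measurement dates, and the drop rules for
   low-repeatability dates and trials.
2. **Relationship matrices** — marker QC (missingness ≤ 80%,
   heterozygosity ≤ 20%, MAF ≥ 0.01, marker-mean imputation), the
   allele-frequency-scaled genomic kernel `G = ZZ′ / (2Σ p_j(1−p_j))`, and
   the pedigree numerator relationship `A` (twice the coefficient of
   parentage) by the tabular method.
3. **Genetic values** — per-environment line BLUEs from an alpha-lattice
   mixed model (trial, date, replicate and incomplete block random),
   across-environment BLUEs with everything nested in a random environment
   effect, validation BLUPs of GY, and square-root heritabilities
   `H_plot` and `H_line` on single-plot and line-mean bases.
4. **Prediction** — univariate GBLUP `y = μ + g + e`, `g ~ N(0, Kσ²_g)`,
   and the multi-trait model with genetic covariance `K ⊗ H` and residual
   covariance `I ⊗ R` (`H`, `R` unstructured, REML): GY observed on the
   training set only, secondary traits observed on training *and* test
   lines, per-record weights scaling the residual as `R_tt / w`. A variant
   with `K = I` plus a replicate-within-trait effect predicts total genetic
   value when no relationship information exists.
5. **Validation** — five-fold cross-validation with one shared fold
   assignment, predictive ability `r_p` against validation BLUPs, accuracy
   `r_g = r̄_p / H_line`, `SE = sd(r_p)/(H_line √k)`, and an OLS
   meta-regression of the multivariate-minus-univariate accuracy gain on
   kernel, environment, mean secondary-trait heritability `H̄` and mean
   absolute genetic correlation `|r̄|`.
6. **Simulation** — a generator for the whole stated world: five
   environments (optimal, drought, severe drought, late heat, early heat),
   trials of 30 entries (28 lines + 2 repeated checks) in 3 replicates × 6
   incomplete blocks, 1–5 measurement dates per growth stage, published
   per-environment heritabilities and trait–GY genetic correlations as
   targets, markers dropped through a founder/cross/selfing pedigree.

The REML engines are written here: a univariate engine (EM warm start +
average-information Newton steps on Henderson's mixed-model equations) and
a multi-trait engine (same schedule, eigenvalue bending for `H` and `R`,
masked cells as absent records, kernel handled through its eigen square
root so singular genomic kernels need no inverse).

## Worked example

```python
from htgp import (assign_folds, genomic_relationship, pedigree_relationship,
                  qc_pipeline, scenario_presets, simulate_dataset)
from htgp.pipeline import accuracy_grid, grid_frame, prepare_environment_data

cfg = scenario_presets("early_heat", n_lines=150, n_markers=800,
                       traits=["CT-GF", "GNDVI-GF", "GY", "DTHD"], seed=1)
markers, pedigree, truth, plots = simulate_dataset(cfg)
plots, report = qc_pipeline(plots)

kernels = {"G": genomic_relationship(markers),
           "A": pedigree_relationship(pedigree, markers.line_ids)}
data = prepare_environment_data(plots, "early_heat",
                                secondary_traits=["CT-GF", "GNDVI-GF"])
lines = sorted(s for s in data.gy_blues.table["line"]
               if not s.startswith("CHECK"))
folds = assign_folds(lines, k=5, seed=1)
print(grid_frame(accuracy_grid(data, folds, kernels)).round(3))
```

prints

```
environment kernel secondary_mode  dthd_corrected  scope  r_p_mean  h_line   r_g    se
 early_heat      G           none           False within     0.526   0.903 0.583 0.049
 early_heat      G           1rep           False within     0.694   0.903 0.769 0.038
 early_heat      G           3rep           False within     0.740   0.903 0.819 0.024
 early_heat      A           none           False within     0.486   0.903 0.539 0.082
 early_heat      A           1rep           False within     0.714   0.903 0.791 0.025
 early_heat      A           3rep           False within     0.751   0.903 0.832 0.047
```

Reading the grid: `none` is the univariate model (GY on the training folds
only); `1rep`/`3rep` add CT and GNDVI on every line, with test-set values
from one or three field replicates. Accuracy `r_g` is the mean fold
correlation with the validation BLUPs divided by `H_line` (here 0.903).
Secondary traits raise genomic accuracy from 0.58 to 0.77–0.82 and
pedigree accuracy from 0.54 to 0.79–0.83, with replicated secondary data
worth slightly more than unreplicated — the qualitative result the method
exists to deliver.

A command-line interface mirrors the stages
(`htgp simulate / qc / relmat / blues / herit / corr / cv / gainreg`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end to end — simulation of the early-heat world,
QC, both kernels, and the univariate vs multi-trait cross-validated
accuracy grid — deterministically for the given seed, and writes the
results JSON. See `docs/methods.md` for the model details, numerical
choices and the limits of what the synthetic world can establish.
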