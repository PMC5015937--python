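# Methods

## The problem

In wheat breeding, selection candidates are grown in small plots for seed
increase before any meaningful yield testing is possible, but canopy
temperature (CT) and vegetation indices (GNDVI, RNDVI) can be measured on
them cheaply from the air. Because these secondary traits are heritable
and genetically correlated with grain yield (GY), putting them in a
multi-trait mixed model together with GY records on related, yield-tested
lines sharpens the prediction of each candidate's genetic value. This
package implements that analysis — QC, relationship matrices, REML
mixed models, cross-validation — plus a simulator that generates data with
the same statistical structure so every stage is testable offline.

## Models

**Repeatability (QC).** Per trial and measurement date,
`y = μ + g + r + e` with genotype, replicate and residual random;
`r² = σ²_g/(σ²_g + σ²_e/n_rep)`. Across dates,
`y = μ + g + d + r(d) + gd + e` and
`r²_overall = σ²_g/(σ²_g + σ²_gd/n_date + σ²_e/(n_rep·n_date))`.
Records with externally Studentized residual p < 0.001 (two-sided) are
removed once and the model refit. A date is dropped when its single-date
r² < 0.01 *and* dropping it improves `r²_overall` (worst date first); a
trial is dropped when any trait ends below 0.01. `n_rep` and `n_date` are
the realized counts of the slice, not nominal design values.

**Line BLUEs.** Per environment, genotype is fixed (cell means) with
trial, date, replicate-within-trial-and-date and incomplete block as
independent random effects. Single-measure traits drop the date term;
days-to-heading (DTHD), scored once on one replicate, also drops replicate
and block. Per-replicate BLUEs (test lines grown without replication)
restrict to one replicate and drop replicate/block — estimable only
because repeated checks connect the trials. Across-environment BLUEs add
a random environment effect with every design term nested inside it. Each
BLUE carries a weight equal to its number of underlying plots.

**Heritabilities.** From the BLUE model with genotype switched to random
plus a genotype-by-date term:
`H_plot = √(σ²_g/(σ²_g + σ²_gd/n_date + σ²_e/n_date))` and
`H_line = √(σ²_g/(σ²_g + σ²_gd/n_date + σ²_e/(n_rep·n_date)))`;
single-measure traits use `n_date = 1` without the interaction. For GY in
the lodging-affected environment the lodging covariate is included (the
source leaves this ambiguous; the choice is flagged in the record).

**Prediction.** Univariate: `y_i = μ (+ β·lodging_i) + g_i + e_i` with
`g ~ N(0, Kσ²_g)`, `K` the pedigree `A`, genomic `G`, or identity.
Multi-trait: stacked per-trait records with genetic effects
`a ~ N(0, H ⊗ K)` and residuals `e ~ N(0, R*)`, where records of traits
`s, t` on the same line covary as `R[s,t]/√(w_s w_t)` — i.e. weights enter
the diagonal (and off-diagonal) of `R` inversely, the standard meaning of
"weights in the diagonal of R". GY of test lines is *absent* (not
zero-filled); its genetic value is predicted by the mixed-model equations
from kernel relationships and the correlated secondary records. The
unrelated-lines variant uses per-replicate BLUEs, `K = I`, and a random
replicate-within-trait effect; its predictions are total genetic values.

**Validation.** Five-fold CV with one shared fold assignment (balanced
random partition, reproducible from a seed). Ability `r_p` = Pearson
correlation of predictions with validation BLUPs (genotype random, trial /
replicate / block random, lodging and optionally DTHD fixed). Accuracy
`r_g = r̄_p / H_line`. SE uses `sd(r_p)/(H_line·√k)`; the plain `/k`
convention is available (`se_convention="k"`) because the source formula
is ambiguous between the two — `√k` is the SE of a mean of k values.
When the DTHD covariate is active, validation uses DTHD-corrected BLUPs
(like-with-like). The gain regression is OLS of (multivariate −
univariate) accuracy on kernel (reference: pedigree), environment
(reference: optimal), mean secondary-trait `H̄` (line-mean basis when the
secondary data were replicated, single-plot otherwise) and mean `|r̄|`
with GY.

## REML engines

*Univariate* (`htgp.lmm`): Henderson mixed-model equations, dense; 10 EM
iterations then average-information (AI) Newton steps with step halving so
the restricted likelihood never decreases; convergence at |ΔlogL| < 1e-9
and parameter movement < 1e-6·var(y), cap 200 iterations. Nonnegativity
by projection onto a floor of 1e-10·var(y) with a KKT active set:
a component at the floor whose gradient points down is frozen, anything
else may revive. Kernels enter through their eigen square root
`K = BB′` (rank-truncated at 1e-10·λ_max), so the singular, column-centered
genomic kernel never needs an inverse and the equations stay
well conditioned.

*Multi-trait* (`htgp.multitrait`): same EM (20) + AI schedule on
vech(H), vech(R) and any extra iid variances. H and R are kept positive
definite by eigenvalue bending (floor 1e-6 × mean diagonal); AI
line-search candidates outside the PD cone are rejected (step halved)
rather than bent, so iterates approach a boundary from inside. Starting
values: H₀ = R₀ = half the pairwise-complete phenotypic covariance.
Convergence: |ΔlogL| < 1e-6 with parameter movement < 1e-5, plus a plateau
rule — when the best likelihood stops improving between successive
8-iteration windows (1e-4; 1e-2 after 100 iterations) the fit is accepted.
The plateau rule exists because the restricted likelihood is *unbounded*
as R approaches singularity (a linear combination of residuals explained
exactly); there the eigenvalue floor binds and bending makes the
likelihood oscillate at ~1e-3 scale forever. The reported estimate is the
floored boundary value, as in mainstream REML software. A failed joint
fit in the correlation table falls back to pairwise bivariate models
(flagged), which are far better identified — with seven strongly collinear
traits and a few hundred lines, the 28+28 free covariance parameters of
the joint fit are weakly identified and this fallback is the norm rather
than the exception.

Fixed effects are estimated by GLS inside the same equations; prediction
of masked cells was verified against explicit joint-covariance
conditioning to 1e-15 relative error, and balanced-data REML against
closed-form ANOVA estimators to 1e-12.

## Simulator: what it emulates, and what a green test does not establish

The generator reproduces the *structure* of a five-environment CIMMYT
yield-trial series: trials of 30 entries (28 lines + 2 checks shared by
every trial), 3 replicates × 6 incomplete blocks of 5, the per-environment
measurement-date calendar (e.g. late heat has a single vegetative date),
DTHD on one replicate, lodging in the optimal environment only. True
breeding values are `Z α` with marker effects drawn so each environment's
trait correlation matrix equals its published target and environments
share an exchangeable genetic correlation (default 0.5 — no value is
published; 0.5 produces the expected within > across accuracy ordering).
Per-trait genotype-by-date and residual variances are *solved* from the
published `H_line`/`H_plot` pairs given the date and replicate counts;
when printed rounding makes the pair marginally infeasible (σ²_gd < 0) the
generator matches `H_line` exactly and lets `H_plot` land a rounding step
high. Single-measure traits can only match `H_line`.

Published tables give trait–GY correlations but not the full
secondary×secondary matrix, so a structural default fills it (0.6 within a
trait family across stages, 0.5/0.3 between indices at the same/different
stage, −0.4/−0.25 between CT and indices, ±0.2 for DTHD), bent to the
nearest positive-definite correlation matrix (eigenvalue floor 1e-4; the
largest adjustment across the five presets stays below 0.25 and is
recorded). Defaults for nuisance variances (trial 0.5, date 1.0,
replicate 0.25, block 0.25 × genetic variance) are field-realistic choices,
not published values.

Not emulated: linkage and LD between markers (markers segregate
independently down the pedigree), spatial field trend, selection, and any
technical error structure of the imaging pipeline. A green round-trip test
therefore establishes that the estimation machinery recovers the
parameters of *this* data-generating process — not that the field data
behind the published tables would yield the same numbers, and not that the
headline accuracy-gain percentages transfer, since those depend on the
real 557-line panel and its LD.

## Degenerate inputs and tie-breaks

- Zero-variance traits: the genetic variance lands on the eigenvalue
  floor; correlations involving that trait are reported as NaN (flagged
  undefined) rather than propagated.
- `H_line < 0.05` aborts accuracy scaling rather than dividing by ~0.
- Ties in the date-drop rule are broken by dropping the lowest-r² date
  first, re-evaluating after each drop.
- The QC outlier pass runs exactly once per slice (no iteration), so a
  cascade of removals cannot occur.
- Fold assignment, simulation and the CLI are deterministic given seeds;
  REML itself uses no randomness.

## Scaling of test and acceptance runs

The full stated world (5 environments × 7 traits × 560 lines) runs the
same code but not inside a CI budget. Tests and the acceptance script
scale down the *sizes* only (e.g. 100–200 lines, one environment, 1–2
secondary traits, 5–10 simulation replicates instead of 20) and keep the
published targets and the stated tolerances unchanged; each scaled test
says so in its docstring.
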