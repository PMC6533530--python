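# Methods

## Penalized mixed-model engine (`mycogrid.pmm`)

All spatial analyses reduce to one Gaussian model,

    y = X beta + sum_j Z_j u_j + e,   u_j ~ N(0, sigma2_j I),  e ~ N(0, sigma2_e I),

in which random intercepts enter as indicator blocks with identity penalties
and smoothers enter as quadratic penalties `lambda_j u' P_j u`.  Each penalty
is eigendecomposed; its range space becomes an i.i.d. random-effect block
(columns scaled by the inverse root eigenvalues) and its null space joins the
fixed effects, where aliased columns are dropped deterministically
(first-come-kept, Gram–Schmidt rank test at tolerance 1e-8).  Consequences of
this reparametrization worth knowing: the MRF null space (one constant per
block) is usually absorbed by intercept/run columns, and at
`lambda -> infinity` a smoother's contribution collapses onto its null space,
exactly as the penalty intends.

Fitting is REML.  Fixed effects and the residual variance are profiled
analytically; the restricted likelihood is evaluated through the penalized
normal equations (`M = C'C + diag(0, Lambda)`, one Cholesky per evaluation,
with a relative diagonal guard of 1e-10), giving

    -2 l_R = (n - p)(log(2 pi s2) + 1) + log|M| - log|Lambda|,

which matches Harville's dense-covariance restricted likelihood — a property
the test suite checks to 1e-6 on small problems.  The free log-ratios
`log lambda_j = log(sigma2_e / sigma2_j)` are optimized by a coordinate sweep
over a log-spaced grid (1e-4 to 1e4, 25 points, two sweeps) followed by
Nelder–Mead refinement.  For large designs (more than 600 coefficient
columns) the default switches to a 13-point grid, one sweep, and a looser
Nelder–Mead budget; every fit accepts an `optimizer` dict, and the recovery
tests pass a still lighter one, since slope and field estimates are
insensitive to high-precision smoothing parameters.  The optimizer is
deterministic, so identical data and settings give bit-identical fits.

Reported per fit: coefficients with Wald SEs from `sigma2 * M^-1`;
per-observation component predictions for every term whose sum plus residual
reproduces the (transformed) response exactly (checked to 1e-10); variance
parameters; effective degrees of freedom per term from the influence-matrix
trace `diag(M^-1 C'C)`; and REML/ML log-likelihoods.

**Information criteria.**  AIC/BIC are computed from the marginal Gaussian
likelihood at the fitted variance parameters with parameter count =
identifiable fixed coefficients + variance parameters + 1 (residual); BIC
uses log(n).  Counting effective degrees of freedom *on top of* the marginal
likelihood would double-charge the penalized fields — the marginal
likelihood already integrates them out — and in our simulations makes BIC
reject a Markov-random-field term even when the data contain a strong CAR
field.  The marginal-likelihood/parameter-count form is the one under which
both structure-selection behaviors demanded of the model family (a common
spatial trend chosen when the truth is common; the MRF supported when
spatial dependence is real) are recovered.  Per-term effective degrees of
freedom are still computed and reported.

## Experiment geometry (`mycogrid.geometry`)

Blocks are 17 × 20 lattices (5 cm spacing), three per box along its long
axis, four runs.  The neighborhood is queen (8-cell), matching the
neighbor-mean covariate, and never crosses the dividers between treatment
blocks: a 17 × 20 block has degree histogram {3: 4, 5: 66, 8: 270}.  `edge`
marks the outermost ring; `exterior` marks the subset of that ring along a
physical box wall — the long sides for every block, plus the short box ends
(first row of block 1, last row of block 3).  Missing or dead plants are
dropped from responses and skipped in neighbor means; a plant whose scored
neighbors are all missing gets a missing neighbor mean and is dropped from
the SDW analysis.  Coordinates are 1-based (row, col) within block; the
common spatial trend uses a global coordinate along the box axis
(`(block_order - 1) * rows + row`).

The panel comprises 334 varieties in seven subgroups
(ADMIX 35, AROMATIC 12, AUS 54, IND 63, TEJ 82, TRJ 83, OTHER 5); the six
cells left over in each 340-cell block hold check plants, which participate
in neighbor means and model fits but are excluded from cultivar-level
genetics and GWA.

## The two analyses (`mycogrid.spatial`)

The SDW model uses natural-log SDW (predictions can be reported on both
scales); the neighbor covariate is in grams so slopes are per gram.  The
spline is a tensor-product cubic B-spline, 8 × 8 basis by default, with
second-order difference penalties per margin — any smooth low-rank field
would do; the basis size is a config knob (`spline_k`).  The
treatment-by-variety interaction is one random intercept per
(treatment, variety) with a common variance.  Second-order interactions
among the positional fixed effects can be added (`all_interactions`) and
pruned backward (`select_fixed`), dropping the least significant term with
Wald p ≥ 0.05 one at a time; smoothing parameters are frozen at the
full-model estimates during the sweep and re-estimated once for the final
model.  The treatment-specific neighbor slope is never pruned.  Spatial
scope is selected by fitting the common / per-box / per-block variants and
taking the smallest BIC, ties resolved toward fewer fields.

The colonization model is Gaussian on the percent scale (colonization is
roughly symmetric in the screen's range, so no link function), restricted to
AM-treatment plants, with one MRF field per block sharing a single smoothing
parameter.  The additive and interactive (focal × neighbor SDW) variants are
compared by the signed AIC difference.

Spatial correction subtracts every component except intercept, treatment and
the genotype terms (or an explicit `subtract` list), each centered to mean
zero over the observations so corrected values keep the raw scale; for SDW
the subtraction happens on the log scale before back-transforming.
Correcting already-corrected data subtracts approximately nothing (checked:
each nuisance component's refitted variance below a few percent of its
original).

## Variance partitioning (`mycogrid.quantgen`)

One-way partitions report `R² = SS_group / SS_total` and a plot-level
broad-sense heritability from expected mean squares,
`H² = s2_G / (s2_G + MS_E)` with `s2_G = (MS_G - MS_E) / r_bar` and the
unbalanced replicate coefficient `r_bar = (N - sum n_i² / N) / (k - 1)`,
truncated at zero.  Two-way partitions use Type II sums of squares
(statsmodels), appropriate for unbalanced main-effect shares, normalized so
shares total 100%; EMS-based variance-component shares (both factors random)
are reported alongside, because raw interaction SS shares absorb residual
noise in proportion to their degrees of freedom and overstate small
interaction variances.

## Association mapping (`mycogrid.gwas`)

Kinship is a VanRaden centered/scaled GRM (IBS available as an option),
jittered by 1e-6 on the diagonal and normalized to unit mean diagonal;
p-values are invariant to positive rescaling of K.  The null model is fitted
by spectral REML: one eigendecomposition, a 61-point log-grid over
`delta = sigma2_e / sigma2_g` in [1e-5, 1e5], bounded Brent refinement.
Per-SNP tests reuse the null-model delta (the EMMAX/P3D approximation) in a
vectorized GLS F-test on 1 df; an exact mode re-optimizing delta per SNP
exists for desk-scale cross-checks and agrees closely in simulation.
Missing dosages are mean-imputed per SNP; sites with call rate below 50% or
MAF ≤ the threshold (strict, default 5%) carry no p-value.  BH adjustment is
the standard step-up with monotonicity enforcement, checked exactly against
an independent implementation.

QTL calling: support SNPs (p < 1e-3) are single-linkage clustered per
chromosome at gap ≤ 200 kb; a cluster is a QTL iff it has ≥ 2 members and
≥ 1 seed SNP (p < 1e-4, MAF > 5%, both strict).  The top SNP minimizes p
(ties to the smallest bp) and defines a ± 200 kb candidate window clipped at
position 1.  The caller is deterministic and invariant to row order.  No
merging of QTLs across separate analyses (e.g. subpopulation scans) is
attempted.

## Intersection scoring (`mycogrid.scoring`)

Each root–graticule intersection carries exactly one category with
precedence arbuscule > vesicle > hyphae-only (either structure implies
hyphae are present), so the total hyphal percentage — the sum of the three
positive categories — cannot double-count.

## Synthetic experiments (`mycogrid.synth`)

The generator reproduces the screen's design exactly (runs, boxes, treatment
block orders, shared within-run randomization, check cells).  Log-SDW is the
equilibrium of a simultaneous autoregressive process per block,
`(I - rho_t W)^-1 eta` with row-normalized queen adjacency and
treatment-ordered coupling `rho = (0.12, 0.30, 0.44)`; because the SAR
equilibrium scales a constant mean by `1/(1 - rho)`, each block is recentred
to its intended mean so marginal anchors are preserved while the
neighbor-dependence structure of deviations is kept.  Defaults are anchored
to the screen's marginal summaries: baseline `exp(4.569) ≈ 96 mg`, run
effects spanning roughly 78–125 mg, internal-edge advantage +0.126 log,
exterior offset −0.076 log, variety SD 0.30, genotype-by-treatment SD 0.10,
spatial field SD 0.12 (a smooth sinusoidal surface over global coordinates,
or independent per-block surfaces when `spatial_scope = "per_block"`),
residual SD 0.25.  The rho values are calibrated so fitted neighbor slopes
land near 1–5 per gram, bracketing the magnitudes a real screen shows.

Colonization (AM blocks only) is mean 51% plus subgroup (SD 2), variety
(causal-SNP contributions plus polygenic SD 6), focal-SDW slope 15 %/g,
neighbor-SDW slope 25 %/g, an optional focal × neighbor interaction
(default 0), a conditional-autoregressive field (precision `D - alpha A`,
alpha 0.9, scaled to SD 6) and residual SD 10, truncated to [0, 100] and then
pushed through per-intersection binomial scoring (100 intersections per
plant; positives subdivided arbuscule 0.3 / vesicle 0.2 / rest hyphae-only).
The resulting colonization spans roughly 20–90% with plant-level
heritability near 0.4 raw and 0.5 corrected.

Genotypes are inbred dosages (0/2 with 2% heterozygosity and 1% missing
calls) at 5000 SNPs on 12 chromosomes, arranged in 10-SNP LD blocks (10 kb
spacing within, 400 kb gaps between, so distinct blocks never fall in one
QTL window); within a block each accession's allele copies the previous
SNP's with probability 0.93.  Subgroup allele frequencies follow a
Balding–Nichols model (divergence 0.15).  Eight causal SNPs sit mid-block on
alternating chromosomes: four large (|beta| = 5.5% per dosage unit, each
roughly 10–15% of cultivar-mean variance — the "large-effect" class the
recovery criterion refers to) and four small (|beta| = 1.5) that are not
expected to be individually detectable.  Every drawn effect and parameter is
recorded in a JSON-serializable truth ledger.

What the generator does **not** emulate: realistic rice LD maps or
demography, dose–response or time-course structure, non-Gaussian
colonization error beyond binomial scoring, genotype-dependent neighbor
coupling, or missing-data mechanisms other than uniform plant loss.  Passing
recovery tests therefore show the estimators recover the *statistical*
structure the analysis assumes — not that real greenhouse data satisfy that
structure.

## Problem sizes in the test and acceptance suites

Unit recovery tests run on toy screens (two runs of 8 × 10 or 10 × 12
blocks, 48–100 varieties, 20 seeded replicates) chosen so each penalized fit
takes fractions of a second.  The end-to-end recovery suite runs 20
replicates of a two-run screen (3 × 340 plants per run, ~2040 plants, 5000
SNPs), fitting the full SDW model, correcting colonization, partitioning
variance and running the GWA per replicate.  The expected variety share used
there includes the binomial scoring variance
(`p(1-p) * 100² / n_intersections ≈ 25`) in the non-genetic denominator,
since intersection counting is part of the measurement model.

## Known limitations

- The neighbor-mean covariate is endogenous: each plant's residual enters
  its neighbors' covariate, so Wald SEs on neighbor slopes are
  anti-conservative when residual noise dominates the neighbor signal
  (measured per-slope coverage of a true zero was ~85% instead of 95% in
  that regime at toy scale).  Slope *ordering* and contrasts are robust;
  literal coverage statements require the variety-dominated regime, and the
  null-calibration test runs there.
- The same covariate acts as a per-block-adaptive estimate of any smooth
  field, so spatial-scope selection is only sharply answerable without it
  (the `include_neighbor` switch); with it, BIC correctly prefers the more
  parsimonious common-trend description.
- Wald/F inference throughout is approximate (no smoothing-parameter
  uncertainty propagation); no non-Gaussian families; MRF fields on lattices
  with one observation per cell are only informative for spatial dependence
  that is smooth relative to the nugget noise.
- The EMMAX-style scan reuses the null-model variance ratio; at very large
  per-SNP effects the exact mode gives slightly different (more accurate)
  p-values.
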