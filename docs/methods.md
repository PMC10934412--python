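# Methods

This note documents the models implemented in `polyuptake`, the choices made
where the methodology was genuinely open, and what the synthetic-library
generator does and does not emulate.

## The system

The package analyses a combinatorial library of poly(methyl
methacrylate-*co*-styrene) nanoparticles made by soap-free emulsion
copolymerization: a factorial design of five styrene feed ratios (0, 25, 50,
75, 100 mol %), up to five monomer-concentration factors (0.2–1.0, where
factor 1.0 corresponds to 2.625 mol/L so that factor 0.8 is the 2.10 mmol/mL
condition), and labelled/nonlabelled variants — 48 members after two grid
gaps.  Each member carries the copolymer composition *x* (mol % Sty, NIR
calibration), the number-average molecular weight *M̄n* (GPC, kg/mol), DLS and
SEM diameters (nm), the PdI, the zeta potential *z* (mV, negative), and solid
contents; fluorescence-labelled members additionally carry flow-cytometry
uptake measurements (percent particle-positive cells *U_P*) in phagocytic
RAW264.7 and nonphagocytic HEK cells at nominal loads of 8, 80 and
160 µg/mL.

## Size quality control

DLS reports an intensity-weighted hydrodynamic diameter and is dominated by
aggregates; SEM is number-weighted and blind to solution aggregation.  The
ratio r = d(DLS)/d(SEM) classifies each sample:

* r > 1.2 — aggregated during the DLS measurement,
* r < 0.8 — DLS size over-approximated by broad dispersity,
* 0.8 ≤ r ≤ 1.2 — consistent; missing SEM diameter — unknown.

Thresholds are strict inequalities, so boundary values (a printed r of
exactly 1.2 appears in the reference table without an aggregate footnote)
count as consistent.  Classification uses the full-precision ratio; the
1-decimal presentation uses half-up rounding.  Independently, DLS diameters
below 800 nm (strict) count as single particles.  A sample is excluded from
the size model when it is aggregated or not a single particle; the "large
aggregates above 5000 nm" case is handled by the same aggregated class, as
nothing downstream treats it differently.

A redundancy screen (pairwise Pearson correlation over complete rows,
default threshold |ρ| ≥ 0.7) justifies dropping non-independent variables —
in practice the PdI, which tracks the DLS diameter through aggregation —
before PCA.

## Micellar size model

In soap-free emulsion polymerization each growing chain starts from a
charged persulfate fragment and particles form from micelles of n_poly
chains.  Assuming particle volume ∝ n_poly·M̄n, all charges at the micelle
surface, and surface potential ∝ surface charge density (zeta ∝
n_poly/d²), eliminating n_poly leaves

    d = k · (−z) · M̄n,

with k (nm·mV⁻¹·(kg/mol)⁻¹) absorbing density, packing and the
charge-to-potential conversion.  The exponents on (−z) and M̄n are
configurable (defaults 1) because variant derivations differ in constant
factors and powers; the default is the minimal form implied by the three
assumptions above.  Calibration is least squares through the origin — the
model is a pure proportionality, so no intercept — with the closed form
k = Σdᵢwᵢ/Σwᵢ², wᵢ = (−zᵢ)·M̄nᵢ, over QC-passing samples only.  The
root-mean-square prediction error (RMSPE) is reported on the same subset and
is an in-sample quantity.

## Multivariate analysis

* **Standardization**: mean-centering and scaling by the sample standard
  deviation (ddof = 1 throughout the package), complete-case with logged
  drop counts.  PCA operates on standardized data only.
* **PCA**: eigendecomposition of the correlation matrix; loadings are
  unit-norm eigenvectors in descending eigenvalue order, scores are
  `standardized data @ loadings`, explained fractions sum to one.
  Eigenvector signs are arbitrary, so each component is oriented with its
  largest-|loading| entry positive.  Components beyond the data rank are
  kept, flagged as zero-variance.
* **MLR**: ordinary least squares with intercept on *raw-scale* data
  (statsmodels OLS behind the module surface).  The relative variable impact
  I_v,j = |β_j·s_j| / Σ_m|β_m·s_m| rescales each coefficient by its
  predictor's sample sd, making the impacts unit-free and summing to 1.
  Designs with condition number above 10¹⁰ are rejected.  A `square` option
  replaces a predictor by its square (used for M̄n², the physically motivated
  regressor given d ∝ (−z)·M̄n and the diameter's appearance squared in the
  surface-charge balance).
* **Simple fits**: OLS line with R²; a group-means mode first averages x and
  y within nominal-feed groups, cancelling the complementary influence of
  the other particle parameters.
* **Mean confidence ellipses**: Hotelling T² ellipses for the bivariate
  mean — sample covariance scaled by 1/n with the F-based critical value
  p(n−1)/(n−p)·F_{p,n−p}(level), p = 2.  "Mean confidence ellipse" is read
  as bounding the mean, not the data cloud; this is an interpretation and is
  flagged as such.  The trend sign is the sign of the sample correlation,
  suppressed below |ρ| = 0.1.

## Logarithmic uptake model

Uptake grows degressively with particle load and is modelled as

    U_P = u_S · log10(p̃) + u_L,

with p̃ = (p · solid_measured/solid_theoretical)/p₀ the solid-content-
corrected dimensionless load and p₀ = 1 µg/mL.  The logarithm base is
configurable; base 10 is the default and u_S is then the uptake gain per
decade of load.  Each (sample, cell line) series needs at least three
distinct loads; series with R² < 0.80 (strict) are excluded.  U_P at the
reference load (100 µg/mL nominal, solid-corrected when possible) is capped
into [0, 100] % at reporting time only; the raw value is retained.  For an
exactly constant, exactly fitted series (zero total and zero residual sum of
squares) R² is defined as 1 rather than 0/0.  The expected error Er is the
pooled within-load replicate sd of U_P — the model is linear in U_P, so
replicate scatter propagates to the prediction unchanged to first order —
and is absent without replicates.

The published per-sample uptake-fit table is not invertible to its printed
U_P values under any single fixed load (the per-sample corrected loads are
not printed), so the package never back-computes the published U_P from
(u_S, u_L); cohort summaries use the printed U_P values directly.

## Synthetic-library generator

The generator reproduces the statistical structure the analysis assumes, so
that every downstream stage has a ground truth.  Defaults (units as above):

| parameter | default | emulates |
|---|---|---|
| enrichment ratio r | 7/3 | ideal-copolymerization curve x = 100·r·f/(r·f+1−f); feed 50 → x 70, endpoints pinned |
| Mn trend | 400 + 150·c − 2.0·feed | Mn rising with concentration, falling with Sty feed |
| −z trend | 20 + 10·c | anionic latex, charge magnitude tracking feed concentration |
| k_true | 0.022 | micellar forward model; true diameters ≈ 150–800 nm over the grid |
| x / Mn / −z noise sd | 2 mol % / 25 / 1.5 | NIR characteristic error (±2 mol %); GPC and zeta scatter |
| d_dls noise | lognormal σ = 0.08 | multiplicative DLS error, keeps d > 0 |
| aggregation | prob 0.15, inflation U(1.5, 5) | the observed aggregated-ratio range ~2.9–5.0 at a few samples per library |
| SEM rounding | 50 nm | SEM diameters reported on a 50 nm grid |
| PdI | 0.08 + 0.15·(inflation−1) + noise | PdI coupled to aggregation |
| solid recovery | U(0.75, 1.0) | dialysis losses; measured < theoretical solid content |
| uptake RAW | u_S = 30+0.03x, u_L = 15+0.03x, sd 3 % | high, weakly composition-dependent phagocytic uptake |
| uptake HEK | u_S = 10+0.15x, u_L = 0.15x, sd 3 % | endocytosis rising strongly with styrene content |

A single "enrichment exponent" in a symmetric power-law form cannot move the
feed-50 composition away from 50 %, so the one-parameter ideal
(Mayo–Lewis-shaped, r₁r₂ = 1) curve is used instead.  The uptake parameter
scales are chosen so that U_P stays inside [0, 100] over loads 8–160 µg/mL
with p̃ = p/p₀ (the published fit parameters imply unprinted per-sample load
corrections and are not directly transferable).  Mn/zeta effect sizes are
synthetic choices matching the reported trends, not fitted values.

All randomness descends from one integer seed via
`numpy.random.SeedSequence(seed, spawn_key=(k,))` with k = 0 for
physicochemistry and k = 1 for uptake; identical parameters give
byte-identical tables.  Truth tables (latent diameter, aggregation flag and
inflation, true uptake parameters) are emitted row-aligned with the
observations.  The `noiseless()` preset zeroes every noise source, the
aggregation probability, the solid-recovery spread *and* the SEM rounding
grid, so forward–inverse identities hold exactly.

What the generator does **not** emulate: polymerization kinetics
(conversion–time behaviour, radical balances), labelled-vs-nonlabelled
composition-variance differences, instrument-level artefacts (DLS
correlogram fitting, GPC calibration drift), inter-batch effects, and any
cell-biology covariates beyond the (x → u_S, u_L) maps.  Passing
recovery tests therefore demonstrates the correctness and calibration of
the *analysis*, not the adequacy of these models for any particular real
library.

## Problem sizes and determinism

The test suite and the acceptance script work at the library's native scale:
48-member libraries, 3 loads × 2 cell lines, 100 replicate libraries for
k-recovery, 200 trials for exclusion power, 100 seeded problems for the
PCA/MLR oracles.  Everything runs in seconds.  The exclusion-power check
uses the replicated measurement design (3 replicates × 3 loads): with only
three noise points the sample correlation follows the arcsine law and
exceeds R² = 0.8 about 30 % of the time regardless of implementation, so
exclusion power is a property of the replicated design the experiments
actually used (the published table carries a replicate-sd error column).
k-recovery at default noise is assessed as the relative bias of the
estimator across replicate libraries (plus the median per-library error);
individual libraries can stray a few percent when an aggregate slips past
the ratio QC.

## Known limitations

* All RMSPE/R² values are in-sample; no cross-validation is implemented.
* The micellar model ignores Debye-layer/Henry corrections; k is a lumped
  constant and not decomposable into density or packing factors.
* The redundancy screen is pairwise-linear only.
* The Hotelling-ellipse "mean confidence" reading and the replicate-sd Er
  are documented interpretations of under-specified conventions.
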