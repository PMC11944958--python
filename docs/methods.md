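# Methods

This note documents the models, numerical choices and synthetic-data design
behind `fppid`, a toolkit for formulation–process–product integrated design
of tablets manufactured by high-shear wet granulation and tableting (HSWGT).

## Problem setting

HSWGT turns a powder (drug + excipients) into wet granules, dries and sieves
them, and compresses them into tablets. Two tablet quality attributes are
modeled: the diametral tensile strength TS = 2F/(πDH) (MPa, from the
crushing force F in N and tablet diameter/thickness in mm) and the solid
fraction SF = ρ_app/ρ_true with porosity ε = 1 − SF. The apparent density
comes from the tablet mass and cylinder volume. We deliberately use the
standard convention SF = ρ_app/ρ_true (so SF → 1 at high pressure); solid
fractions slightly above 1 are tolerated up to 1.02 as measurement noise and
rejected beyond that. Tableting forces in kN convert to pressure through the
punch area with full-precision π (1 kN on a 10 mm punch = 12.732 MPa; the
rounded engineering value 12.74 appears in some sources).

## Granulation regime descriptors

Two dimensionless numbers summarize the granulation state:

* **Froude number** Fr = ω²·(2R)/g, with ω the impeller speed in
  revolutions per second and 2R the bowl inner diameter in metres. The rps
  convention is pinned by the endpoints 0.63 (400 rpm) and 2.54 (800 rpm) on
  the default 0.14 m bowl; a rad/s convention would be ~40× larger. The bowl
  diameter default (0.14 m, a 2 L pot) is a configuration constant.
* **Maximum pore saturation** S′max = w·ρ_s·(1 − ε_min)/(ρ_l·ε_min), where
  w is the liquid-to-solid mass ratio, ρ_s the bulk density of the solid,
  ρ_l the liquid density, and ε_min = 1 − ρ_tapped/ρ_true the minimum
  attainable porosity, using the tapped density in place of the generally
  unavailable envelope density. Liquid densities default to water 1.000 and
  95 % (v/v) ethanol 0.8114 g/mL at 20 °C, overridable in configuration.

S′max is physically determined by w and the densities, so the process
sampler *derives* it from the drawn liquid level rather than gridding it
independently.

## Compression behavior classification system (CBCS)

Nine descriptors from six compression equations characterize a powder's
compressibility, compactibility and tabletability. All fits are ordinary
least squares on the linearized coordinates; R² and RMSE are reported on
the linearized response so the R² > 0.9 quality gate is unambiguous.

| model | linearization | descriptors |
|---|---|---|
| Kawakita | P/C vs P (slope 1/a, intercept 1/(ab)) | a, b⁻¹, ab |
| Heckel | ln(1/ε) vs P | P_y = 1/K |
| Shapiro | ln ε vs (P, √P) | f |
| Gurnham | ε vs ln P (slope −1/K) | K |
| Ryshkewitch–Duckworth | ln TS vs ε | k_b |
| power law | ln TS vs ln P | d, g |

The Kawakita degree of compression is C = 1 − (1 − ε₀)/(1 − ε), which
follows from the volume per unit solid mass V ∝ 1/(1 − ε) with ε₀ the
loose-powder porosity obtained from the bulk density. Noisy points whose
measured porosity exceeds ε₀ imply negative compression and are unphysical;
the Kawakita fit trims them and errors only when fewer than three usable
points remain. The Heckel fit uses the full pressure range by default (a
pressure window is configurable); whether a linear-region rule should be
applied is a known open choice. Degenerate designs (constant porosity,
constant pressure, non-positive strength) raise fit errors that identify
the offending points.

## Latent-variable process model

The process model is a two-response PLS regression (PLS2) fitted by NIPALS
on mean-centered, unit-variance (UV, ddof = 1) scaled inputs and outputs.
Inputs are 19 physical powder properties, the CBCS descriptors, and five
process columns (L/S ratio, wet massing time, Fr, S′max, tableting
pressure); outputs are TS and SF. The full layout (M1) carries all 9
descriptors (33 inputs); the reduced layout (M2) drops the three
descriptors with variable importance in projection below 1 in the full
model (the rearrangement index ab, the fragmentation descriptor f, and the
pressure-sensitivity exponent g), giving the fixed 25 + 5 = 30-column
layout used by the design engine.

Numerical conventions:

* NIPALS tolerance 1e-12 on the relative score change, at most 5000
  iterations per component (power iteration converges slowly when the
  leading Y-covariance eigenvalues nearly coincide; 1000 iterations proved
  insufficient on realistic near-symmetric two-response problems).
  Non-convergence raises, naming the component.
* Sign convention: each weight (and PCA loading) vector is flipped so its
  largest-magnitude element is positive, making decompositions
  deterministic and score plots stable.
* Regression coefficients B = W(PᵀW)⁻¹Cᵀ on the scaled spaces; predictions
  are mapped back to original units through the stored scalers.
* R²X and R²Y are cumulative reconstruction fractions on the scaled
  training data. Q² = 1 − PRESS/SS from 7-fold cross-validation with
  deterministic interleaved fold assignment (row i → fold i mod 7); a
  seeded random assignment is available. PRESS and SS are pooled over both
  responses on the full-sample UV scale of Y so responses with different
  units contribute comparably. RMSEE and RMSECV are reported per response
  in original units with an N denominator.
* Component count selection uses the parsimony rule: the smallest A whose
  Q² is within 0.01 of the curve maximum, since the Q² curve is flat past
  the true dimensionality and the raw argmax overfits.
* VIP_j = sqrt(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with
  SSY_a = ‖t_a‖²‖c_a‖², satisfying mean(VIP²) = 1. VIP pruning is a single
  pass: fit, drop features below the threshold, refit with the same number
  of components.
* Hotelling T²_i = Σ_a t_ia²/s²_a with training score variances (n − 1
  denominator); its limit is A(n − 1)/(n − A)·F(A, n − A; 1 − α). At the
  study size (A = 6, n = 735, α = 0.05) this evaluates to 12.75.
* SPE_i is the squared reconstruction residual of an observation on the
  scaled X space. Its limit uses the Jackson–Mudholkar approximation from
  the training residual covariance eigenvalues by default; a χ²
  moment-matching estimator (g·χ²_h with g = v/2m, h = 2m²/v from the SPE
  sample mean and variance) is available behind a switch. Published SPE
  limits computed by unspecified methods (e.g. a reported 3.84) are not
  reproduction targets; both estimators are exposed instead.

Model serialization stores scalers, W/P/C, score variances, training
residuals and metadata in a single JSON file; reloaded models reproduce
predictions, T² and SPE to machine precision.

## Representative material selection

A material library is screened in the 2-D score space of a UV-scaled PCA
over the full feature block (the two optional tabletability-change indexes
participate when present). Boundary materials: the point farthest from the
score centroid, then repeatedly the point maximizing the minimum distance
to those already chosen. Center materials: nearest the centroid. Fill
materials: greedy max–min coverage seeded by everything chosen so far.
Ties break toward the smaller row index, so selection is deterministic and
row-order invariant up to that rule. Manual score-plot selection is thereby
codified into a reproducible procedure; the use of UV scaling and two
components for selection is fixed by convention here since no canonical
rule exists.

## Hybrid experimental design

One block per material. Within a block, `runs_per_block` combinations of
(L/S level ∈ {low, mid, high}, impeller speed ∈ {400, 600, 800} rpm, wet
massing time ∈ {180, 240, 300} s) are chosen from the 27-point candidate
grid by a Fedorov-style exchange with 50 seeded random restarts, maximizing
a determinant objective for a main-effects model (intercept, two L/S
dummies, coded speed and time). With 3 runs and 5 parameters every subset's
p×p information matrix is singular, so the objective is det(X_s X_sᵀ) (the
n×n Gram determinant) when runs < parameters and det(X_sᵀX_s) otherwise —
a documented surrogate for the D-optimal criterion of commercial design
software; any determinant-non-inferior design is acceptable. L/S levels
map to each material's feasible range (low = minimum, high = maximum,
mid = midpoint); the ranges themselves come from wet-mass consistency
("fist test") endpoints recorded per material. Crossing each granulation
run with the six tableting force levels (1–11 kN, step 2) multiplies the
run count exactly: 10 materials × 3 runs × 6 forces = 180 tableting runs.

## Four-step integrated design

1. **Targets.** Minimum TS (default 2.0 MPa), SF window (default
   0.80–0.90; widened windows such as 0.705–0.995 are a configuration
   input, not a computed rule), and significance levels for T²/SPE (0.05).
2. **Formulation simulation.** Each recipe fixes the drug fraction at
   1 − m and draws an excipient support size uniformly from
   {1..max_excipients} (default 5), a uniform support subset, and flat
   Dirichlet weights scaled to m. This samples the bounded-support
   constraint directly, so the requested number of rows is produced
   exactly; a generate-then-filter scheme's yield would be an artifact of
   its unspecified sampler. Mixture properties follow the ideal mixing
   rule AI = A × I (mass-fraction-weighted averages), making every mixture
   property a convex combination of component properties.
3. **Process simulation.** A 3-component UV-scaled PCA of the library's
   28-feature block locates the water- and alcohol-granulated centroids;
   each mixture is assigned the wetting agent of the nearer centroid and
   inherits the L/S range of the single nearest library powder. Process
   levels (impeller speed, liquid volume, wet massing time, tableting
   force) are drawn uniformly from practical grids; the liquid draw is
   restricted to levels whose implied L/S ratio (volume × liquid density /
   batch mass, default 300 g) falls inside the inherited range, and rows
   with no feasible level are flagged infeasible and logged. Fr, S′max
   (from the mixture's ideal-mixed bulk/tapped/true densities — a
   documented approximation) and pressure are derived, never gridded.
4. **Solution generation.** The reduced-layout PLS model predicts TS/SF
   for the concatenated mixture + process matrix; rows survive when they
   meet both targets *and* lie inside the model's validity region (T² and
   SPE below their limits). Per-stage counts are logged and the filter is
   idempotent.

The Monte Carlo sensitivity analysis fixes a material's 25-feature vector,
draws n = 1000 vectors of the five process parameters from independent
uniforms over specified ranges, predicts TS/SF, and reports the Pearson
correlation (PEAR) of each parameter with each predicted response.
Correlations are computed on predictions, so they characterize the fitted
(linear) response surface; degenerate parameter ranges yield PEAR = 0 with
a zero-variance flag.

## Synthetic data design

The generators provide seeded, fully reproducible stand-ins with planted
structure so that every downstream stage has a recoverable ground truth.

* **Material library.** 28 features are driven by 3 standard-normal latent
  factors through fixed loadings, plus independent per-feature noise
  (default 0.7 of one latent unit), then mapped through affine or
  log-affine transforms and clipped to physically sensible ranges.
  Derived features are constructed for internal consistency (ε_p + SF_p =
  1, D₁₀ ≤ D₅₀ ≤ D₉₀, bulk ≤ tapped < true density, Hausner/Carr indexes
  from the densities). The correlation signs mirror real powder libraries:
  densities anticorrelate with the tabletability coefficient d and
  correlate with the compression-resistance and bonding descriptors;
  particle size anticorrelates with flow time; yield pressure
  anticorrelates with Kawakita a. The default noise level places the
  first-two-PC explained variance near 57 % (0.54–0.65 across seeds), the
  regime of published material libraries. Wetting agents are assigned by
  thresholding factor 1; L/S ranges are drawn within 0.15–1.5 g/g. In the
  one-factor zero-noise limit the affine features are near-perfectly
  correlated and PC1 dominates; exact |r| = 1 is broken only by the
  consistency clips on derived ratio features.
* **Tablet observation table.** One row per tablet (4 replicates per
  (run, force) pair; the realized compression force is jittered with
  σ = 0.15 kN to emulate press tolerance). TS and SF are planted linear
  truths on the UV-scaled 30-column input block. The standardized linear
  predictor is scaled by `signal_scale` = 0.19 and perturbed by
  N(0, noise_sd = 0.1), then mapped affinely to physical units
  (TS: 4.5 ± 7.0·r MPa floored at 0.05; SF: 0.80 ± 0.30·r clipped to
  (0.3, 1.0)). The signal-to-noise ratio 1.9 gives a theoretical
  cross-validated Q² of 0.19²/(0.19² + 0.1²) ≈ 0.78, the predictive regime
  (≈0.70–0.85) that latent-variable tablet-quality models reach on real
  material-library data. The planted coefficient signs follow the observed
  physics (pressure positive for both responses, L/S negative for both,
  densities/K/k_b negative for TS, P_y negative and Kawakita a positive
  for SF), and anticorrelated-by-construction features carry
  opposite-signed coefficients so that sign recovery is well defined under
  collinearity.
* **Compression curves.** Exact evaluation of a chosen equation plus
  multiplicative lognormal noise. The combined CBCS series uses a Kawakita
  porosity truth (a = 0.60, b⁻¹ = 25 MPa, ε₀ = 0.65 — substantial
  compression by the lowest pressure level and near-Heckel-linear
  behavior over the 12.7–140 MPa window, as real powders show) and a
  power-law strength truth (d = 0.05, g = 0.9). At 5 % noise on a
  6-level × 4-replicate grid, ~98 % of individual fitted equations clear
  the R² > 0.9 gate, matching the rate observed on real powder/granule
  batches.

**What the generators do not emulate:** granule-scale mechanisms (growth,
breakage, intragranular porosity evolution), nonlinear
material–process interactions, heteroscedastic measurement error, and
material-specific random effects beyond the feature block. Passing tests
therefore demonstrate that the estimators and the design loop recover
*linear latent structure* under realistic noise and collinearity — not
that a linear model suffices for any particular real powder system.

## Pipeline and reproducibility

Each stage (library, design, observations, formulation, process draw, CV,
sensitivity) derives its own seed from the base seed, so stages are
independently reproducible and an end-to-end run is bit-stable: identical
configuration and seed produce byte-identical CSV artifacts. All CSV output
uses a fixed dialect (`%.10g` floats, `\n` line endings) so save→load→save
round-trips are byte-identical.

Default problem sizes (30-material library, 10-material working set, 180
tableting runs, 720 tablet rows, 1566 simulated recipes, 1000 sensitivity
draws) follow the study shape of the underlying workflow and run in
seconds on one CPU.

## Known limitations

* The Heckel fit has no automatic linear-region detection; users fitting
  strongly curved data should set the pressure window.
* The wetting-agent matcher assumes both agent classes are represented in
  the library and that ideal-mixed properties are meaningful for the
  mixture — percolation effects and granule-level interactions are out of
  scope.
* The design engine screens random candidates; it is not a global
  optimizer.
* PEAR-based sensitivity is linear by construction and inherits the PLS
  model's validity region; extrapolation beyond the T²/SPE limits is
  flagged, not prevented.
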