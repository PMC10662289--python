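# Methods

`pollenlra` implements the modelling chain used to estimate and validate
relative pollen productivities (RPPs) from networks of small pollen traps
(moss polsters) with paired vegetation surveys: a Gaussian-plume
dispersal–deposition kernel, Extended R-value (ERV) maximum-likelihood
fitting, the relevant source area of pollen (RSAP), the REVEALS regional
vegetation estimator with delta-method errors, and two validation schemes
(leave-one-out and subregion splitting). Because raw survey data of this
kind are rarely deposited, the package ships a first-class synthetic
landscape generator whose truth record makes every stage testable.

## Dispersal–deposition kernel

Pollen released from vegetation at distance `z` from a point basin deposits
with density

    g(z) = b·γ·z^(γ−1)·exp(−b·z^γ),   γ = n/2,   b = 4·v_g / (n·u·√π·C_z)

where `v_g` is the taxon's fall speed (m/s), `u` the mean wind speed, `n`
Sutton's turbulence parameter and `C_z` the vertical diffusion coefficient.
Defaults are the conventional neutral-atmosphere values `u = 3 m/s`,
`n = 0.25`, `C_z = 0.12`, all overridable per run; fall speeds come from a
per-taxon CSV or from Stokes' law given grain dimensions. `g` has the
closed-form antiderivative `1 − exp(−b·z^γ)`, so ring weights
(`exp(−b·z1^γ) − exp(−b·z2^γ)`), distance-weighted plant abundance (DWPA:
cover × ring weight summed over rings) and REVEALS deposition factors
`K_i = ∫_R^{Zmax} g_i` are all exact. The basin edge sits at 0.5 m (moss
polster) and rings are half-open `[z1, z2)`; distances are metres from the
sampling point. The same point-basin model serves both ERV weighting and
REVEALS deposition because all samples are polsters; lake-basin geometry is
out of scope.

One property worth noting: the *whole-plume* deposition factor
`exp(−b·R^γ)` decreases with fall speed, but a factor truncated at finite
`z_max` need not — a heavy grain's plume concentrates inside the regional
limit. Tests therefore assert monotonicity on the infinite-limit form and
on the survival function at every distance.

## ERV model

For counts `n_ik` (taxon `i`, site `k`) and DWPA `x_ik` truncated at a
distance cutoff, submodel 3 — the primary formulation — sets the expected
pollen proportion to

    e_ik = (α_i·x_ik + ω_i) / Σ_j (α_j·x_jk + ω_j)

with productivities `α_i ≥ 0` and taxon-specific background `ω_i ≥ 0`
representing pollen from beyond the surveyed area. Counts are multinomial
per site; the likelihood is invariant to a common rescaling of all
`(α, ω)`, so identifiability comes solely from pinning the reference taxon
(default Poaceae) at `α = 1`, whose SD is 0 by construction. Submodel 1
(site-normalised DWPA proportions) and submodel 2 (background scaled by the
site's total DWPA) are available as variants behind the same machinery.

Maximisation is by L-BFGS-B on log-parameterised `(α, ω)` (non-negativity
by construction) with an analytic gradient, started from moment-style
initial values plus jittered multi-starts (default 5, seeded). The
multi-start matters: a rare local optimum collapses a low-productivity
taxon's `α` toward zero with the background absorbing its pollen. SDs come
from the inverse observed information at the optimum (central-difference
Hessian of the analytic gradient in natural coordinates). A taxon with zero
DWPA everywhere at the chosen cutoff gets `α = 0` and a warning rather than
aborting the fit.

The log-likelihood–distance curve refits all parameters at every distance
(warm-started from the previous fit). RSAP is located by moving-window
linear regression: windows are anchored at curve points and span a
configurable width (≥ 3 points); the RSAP is the start of the first window
whose slope does not differ from zero at the chosen level (default 0.05)
*and* whose successors all stay non-significant, which prevents premature
asymptote calls; a curve that never flattens is flagged "no asymptote".

## REVEALS

Regional cover fractions from pollen counts, productivities and deposition
factors:

    V̂_i = (n_i / (α_i·K_i)) / Σ_j (n_j / (α_j·K_j)),   K_i = ∫_R^{Zmax} g_i.

The default regional limit is `z_max = 100 km` (configurable 50–150 km).
Delta-method SEs propagate multinomial count covariance and, when supplied,
the variance of `α̂` (taxa treated as independent); the formulas are
cross-validated against Monte Carlo rather than trusted blindly, and the
calibration is asserted to a factor of 2 in the tests. With several small
sites, `mean_of_sites` (default) averages per-site estimates and combines
the mean per-site variance with the between-site variance of the estimates;
`pooled` sums counts first. Because every site yields a fixed count total,
pooling cannot recover absolute loadings — the two modes agree on
homogeneous networks and differ under heterogeneity.

## Validation schemes

*Leave-one-out*: drop one site, fit the ERV model on the rest, run
single-site REVEALS on the held-out site's counts; repeat for every site.
Means and SEs over runs use `Var(mean) = mean within-run variance/S +
between-run variance/S`. Non-convergent runs are excluded, never imputed,
and the exclusion count is reported.

*Subregion splitting*: fit RPPs on one geographic group, apply REVEALS to
the other group's pollen. A warning replicates the stability screen that
disqualifies a fit group when any RPP's SD exceeds the estimate.

`compare` assembles, per taxon, pollen proportions (PP; mean of per-site
proportions by default, pooled optional), REVEALS estimates (RV ± SE) and
observed regional vegetation (OBV) at each buffer radius, with similarity
metrics. The literature's "coefficient of variation" and "fold" wordings
admit several readings, so all three candidates are computed and labelled
explicitly: `cv` = RV standard error ÷ OBV, `ratio_diff` = |RV−OBV|/OBV,
`fold` = max(RV,OBV)/min(RV,OBV); headline metrics use the first buffer
supplied, and `closest_buffer` searches all of them. A zero OBV with
positive RV yields infinite ratio metrics plus a flag.

## Vegetation handling

Braun-Blanquet classes convert to fixed percent covers (present → 0.01,
I → 5, II → 10, III → 25, IV → 50, V → 75). Species tables harmonise to
pollen-morphological taxa by a user mapping (unmapped species are an error
unless explicitly dropped); covers add within a pollen taxon. Taxon
selection keeps taxa present (strictly positive) in ≥ 60% of sites with a
maximum percentage above 1%. Regional OBV is the area-weighted mean of
per-category compositions within a buffer, normalised over the selected
taxa only — category rows are kept as printed (layered vegetation may sum
past 100%) and never renormalised within a category. Normalising over the
selected taxa is required for comparability with RVs, which also sum to 1.

## Synthetic landscapes

The generator emulates the structure of a moss-polster RPP study: 36 sites
(17 + 19 in two subregions), 10 taxa with true RPPs
{27, 12, 9, 5, 2.5, 1.5, 1, 0.9, 0.9, 0.7} (Poaceae ≡ 1) and fall speeds
0.01–0.06 m/s, 1,000-grain multinomial counts per sample, ring surveys to
1,500 m (10-m rings to 100 m, then 50-m rings), and buffers at 75–150 km.

The landscape is a category mosaic: ~12 land-cover categories, each
dominated by one taxon (30–80% cover) with minor associates; the reference
grass is present everywhere but spans 2–60% between closed forest and open
grassland, mirroring the orders-of-magnitude contrast of real composition
tables — a deliberately wide range, because a weakly varying reference
taxon injects a shared error into every RPP ratio. Category weights are
Dirichlet; buffer area tables are those weights times the buffer area (the
primary buffer exactly, others jittered), so the generating regional
composition equals `regional_obv` applied to the emitted tables by
construction.

Around each site, rings draw categories with Markov persistence 0.85
(stationary at the mosaic weights), and each ring averages over
`ring_area / patch_area` independent patches (patch radius 50 m, capped at
50), so wide outer rings mix many stands while the immediate surroundings
stay coherent; mean-one lognormal noise (sd 0.15) models survey error.
Site placement is *stratified* over the mosaic weights (largest-remainder
allocation of home categories), as field campaigns deliberately cover a
region's community types; this keeps the network representative of the
region without sacrificing the between-site contrast the ERV model needs.

Expected loadings follow the submodel-3 structure exactly:

    y_ik = α_i·x_ik + α_i·v_i^reg·K_i(extent, z_max)

with `v^reg` the *unnormalised* area-weighted mean ground cover (the same
units as ring covers, so the local and background terms are
commensurable); counts are multinomial on the normalised loadings. A
Dirichlet-multinomial `perturb` adds between-site overdispersion without
touching the truth record.

What the generator does *not* emulate: directional wind and topography,
temporal mismatch between pollen deposition and surveys, taxa outside the
selected panel, spatial autocorrelation between nearby sites' outer rings,
and map-digitisation error in the OBV. Passing recovery tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to these real-data violations.

## Numerical choices and problem sizes

Ring weights, deposition factors and DWPA are closed-form; quadrature
appears only as an independent oracle in tests (agreement to 1e-8).
Optimiser: L-BFGS-B, `ftol 1e-12`, log-parameter bounds ±40, 5 starts
(jitter sd 0.7); likelihood-curve and leave-one-out refits warm-start and
use fewer starts. The observed-information Hessian uses central differences
with relative step 1e-5; a singular information matrix yields NaN SDs and
a warning. Distance grids for RSAP default to 50-m steps with 500-m
windows at level 0.05.

Test and acceptance runs use the default study conditions (36 sites, 1,000
grains) with 20-seed sweeps for recovery statistics, 500 Monte-Carlo draws
for SE calibration, and reduced landscapes (6–8 sites, 400–600-m surveys)
for unit and CLI tests; a full sweep plus leave-one-out completes in well
under a minute on one core.

Measured under the default conditions, REVEALS recovery from fitted RPPs
reaches a median *mean* absolute deviation of ~0.006 from the true
composition (total deviation ~0.06, against ~1.0 for raw pollen
proportions). The total deviation is dominated by the per-taxon RPP error,
which at 1,000 grains per sample is count-noise-limited at roughly 7%
(median; it shrinks as √n with larger counts), plus the residual
landscape-sampling error of a 36-site network.

## Known limitations

- The ERV background formulation (taxon-specific additive `ω_i` on absolute
  DWPA) is one of several in the literature; submodels 1–2 are provided
  but only smoke-tested.
- Delta-method SEs treat fitted RPPs as independent across taxa; their
  correlation through the shared reference is ignored, which the Monte-
  Carlo calibration shows is acceptable at these problem sizes.
- The RSAP of generated landscapes reflects the generator's kernel-decay
  structure rather than a tunable plateau; the detector itself is validated
  on constructed curves with known onsets.
- `pooled` and `mean_of_sites` REVEALS modes cannot be distinguished by
  count data on homogeneous networks and neither recovers absolute pollen
  loadings.
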