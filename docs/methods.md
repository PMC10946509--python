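# Methods

This note documents the models, the synthetic-data design, the defaults
and the numerical choices behind `serloss`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The species–energy model

Potential species richness per landscape cell is modelled as

    SR_pot ~ quasiPoisson(μ, φ),   log μ = β₀(realm) + β_isl·island + β_npp·NPP_pot

- **Response**: `SR_pot = SR_obs + SR_ext` on wilderness cells — counting
  extinct species alongside extant ones credits losses unrelated to land
  use (e.g. hunting) back to the pristine baseline.
- **Link**: log. The model is described as having a linear effect of NPP
  on the response, but a log link is the standard quasi-Poisson choice
  and is what makes realm intercepts multiplicative and gives ΔSR its
  clean sign behaviour (loss wherever HANPP > 0, gain wherever HANPP < 0,
  exactly zero where HANPP = 0). The identity link would break all three.
- **Dispersion**: φ = Pearson χ²/(n−p). Point estimates are plain Poisson
  maximum likelihood (IRLS via statsmodels; relative deviance tolerance
  10⁻⁸, ≤100 iterations); quasi-likelihood enters only as the √φ scaling
  of standard errors, so quasi-Poisson and Poisson coefficients are
  identical by construction (asserted in tests).
- **Fit summaries**: deviance-based adjusted
  R² = 1 − (D_res/df_res)/(D_null/df_null), and deviance-based partial
  R² = (D_reduced − D_full)/D_reduced from a refit without the term group
  on the identical sample. The R package conventionally used for partial
  R² defaults to a variance-function-based variant; the deviance form is
  implemented here from first principles and can differ numerically.
- **Coding**: treatment contrasts, reference = first kept realm and
  mainland. The coding moves intercepts only, never fitted means.

## Calibration domain and sampling

Wilderness is `footprint == 0` (a strict zero; a tolerance flag exists
but defaults to 0), with the extra requirement of intact-forest
membership where the pristine habitat is forest. Unproductive cells
(NPP_pot below 20 gC·m⁻²·yr⁻¹, a free parameter — the threshold is not a
published constant) are never wilderness and are no-data everywhere.
Realms without any wilderness cell cannot inform the model and are
excluded end to end (their cells project to no-data).

The calibration sample is stratified by realm: 500 cells where a realm
has ≥500 wilderness cells, otherwise round(W/3) (at least 1) — the
one-third rule tempers spatial autocorrelation in wilderness-poor realms.
The wilderness cells holding the global NPP_pot minimum and maximum are
swapped in for random picks of their realms (quotas unchanged), so
projections never extrapolate beyond the sampled predictor range.

## Projection and uncertainty

`SR_pot` and `SR_lu` are exp(η) evaluated with NPP_pot and NPP_eco
respectively; expected counts stay fractional (rounding would be a
presentation choice). `ΔSR = SR_pot − SR_lu` is forced to exact 0 on
wilderness cells (it is already analytically zero there since
NPP_pot = NPP_eco). Uncertainty follows the single-coefficient
convention: only β_npp is varied, by ± one standard error; realm
intercepts and dispersion are not propagated. The hybrid `SR_pot` map
(observed+extinct on wilderness, model elsewhere) and the purely modelled
one are both available.

## Validation protocol

Two comparisons, each on 10 independent without-replacement draws of
5000 cells (all cells if the domain is smaller, which is noted in the
report): `SR_lu` vs `SR_obs` on productive non-wilderness cells of kept
realms, and `ΔSR` vs `SR_thr+ext` additionally restricted to
Red-List-covered cells. Per draw: Pearson r with a two-sided t-test p
(plain p-values despite spatial autocorrelation — a deliberate mirror of
the study protocol; treat them as descriptive). Pooled statistics use
the union of drawn cells, whose size is logged. The OLS regression puts
the projection on the left-hand side, so slope < 1 reads as
under-prediction of the reference map. The SR_lu comparison is *not*
restricted to Red-List coverage; only the ΔSR one is.

## The synthetic-world generator

The generator defines the study conditions; its defaults are fixed once.
It emulates, on an abstract equal-area grid (nominal 20 km cells,
100×100 by default):

- **NPP_pot**: Gaussian-kernel-smoothed white noise (autocorrelation
  length 8 cells) probit-mapped to a uniform marginal on
  [0, 1500] gC·m⁻²·yr⁻¹. Units are fixed at gC·m⁻²·yr⁻¹ throughout; all
  slopes are per that unit. A dynamic global vegetation model is out of
  scope — this field is its statistical stand-in.
- **Realms**: a balanced contiguous partition (k-means on cell
  coordinates, 10 realms). **Islands**: smoothed-noise blobs covering
  ~15% of cells. **Elevation**: smoothed field on [0, 3000] m.
- **Wilderness designates**: per realm, three contiguous patches (grown
  by randomized flood fill) jointly covering ~25% of the realm's
  productive cells; HANPP is identically zero there. Fragmenting the
  designate across a few patches keeps the calibration domain
  representative of each realm — a single blob can sit on a local high
  or low of the species-placement intensity and bias that realm's fitted
  intercept, which then propagates to every projected cell of the realm.
  Realms listed in `zero_wilderness_realms` get no patch (the
  excluded-realm case). The footprint layer is 0 exactly on designates
  and lognormal elsewhere; intact forest is the eroded interior of
  forested designates, so some zero-footprint forest cells are correctly
  *not* wilderness.
- **HANPP**: outside designates, an autocorrelated appropriated fraction
  with mean `hanpp_intensity` (default 0.5) of NPP_pot, split 70/30 into
  HANPP_luc/HANPP_harv. Irrigation pockets (2% of used cells, drawn from
  the arid 40%) get HANPP_luc = −0.3·NPP_pot, so NPP_eco exceeds NPP_pot
  there. All flux layers are quantized to multiples of 2⁻²⁰ gC·m⁻²·yr⁻¹:
  every value then carries at most 32 significand bits, sums and
  differences are exact in double precision, and the conservation
  identity NPP_pot − NPP_eco − HANPP_luc − HANPP_harv = 0 holds bitwise.
- **Habitat and conversion**: six pristine habitat codes (two of them
  forest) from a productivity-correlated mosaic; one code per cell per
  epoch. Conversion is *intensity-graded*: sixteen converted codes
  ordered by conversion intensity, and a cell's current code is the
  intensity bin of its expected richness-loss share
  1 − exp(−c·HANPP), with c = `conversion_energy_coef`. Species tolerate
  a nested prefix of the converted codes up to a uniformly drawn
  threshold, so a converted cell retains, in expectation and with only
  binomial noise, exactly the species share its intensity implies.
  This grading is what makes the generator produce worlds *within the
  fitted model class*: with a single all-or-nothing converted state,
  cell-level observed richness would be bimodal (pristine count or the
  tolerant remnant) and no projection could track it closely.
- **Conversion coefficient**: the default c = 0.0032 per gC·m⁻²·yr⁻¹ is
  the *realized* SER slope of the default species pool (see below), not
  the nominal placement slope — self-consistency requires conversion
  losses and energy-projected losses to follow the same coefficient.
- **Red-List coverage**: a smoothed-noise mask covering 70% of cells.

## The species pool

Ranges are contiguous: grown from a centroid by weighted flood fill, with
both centroid sampling and growth weighted by w = exp(true linear
predictor at NPP_pot); sizes are log-normal (median 80 cells, σ=0.6,
default 3000 species). Because centroid placement and growth weighting
compound, the realized per-cell overlap intensity scales approximately as
a power >1 of w — the *realized* energy slope (≈0.0032 under defaults) is
steeper than the nominal β_npp = 0.0015. This is a property of the
emergent point pattern, not an error: the pipeline calibrates itself on
wilderness counts and all self-consistency statements are about the
realized relationship.

Affiliations: every pristine code holding ≥2% of the range (plus the
modal code); the elevation interval spans the 2nd–98th percentile of the
range's elevations (≥80% coverage is guaranteed by clamping the
parameter). Status is extinct/possibly-extinct with probability 0.05.
Threat flags: a species is threatened in a realm when more than half
(configurable) of its range cells there currently mismatch its habitat —
an emulation of national Red Lists, not a claim about real listing
criteria.

## Replicated studies and problem sizes

- **Parameter recovery**: 200 replicates of 128×128 worlds (10 realms,
  wilderness fraction 0.35), richness simulated from a known truth
  (dispersion 1.5) as a gamma–Poisson mixture with variance φ·μ, quota
  350 per realm → ~3500 sampled cells per replicate. Reported: coverage
  of the 95% Wald interval for β_npp and bias relative to SE. These sizes
  keep a replicate under 200 ms while matching the scale of the original
  sampling design.
- **End-to-end consistency**: 5 seeds of the full default pipeline
  (100×100, 3000 species); seed-averaged pooled r and OLS slope of SR_lu
  on SR_obs, and of ΔSR on SR_thr+ext.

## Numerical conventions

- Grids are row-major, 0-based (row, col). No-data is NaN for float
  layers and −1 for integer/factor layers; both are propagated, never
  treated as 0.
- Factor aggregation (majority resampling) breaks ties toward the lowest
  code; continuous aggregation offers area means (flux-conserving) and
  bilinear interpolation at coarse-cell centers.
- Stage seeds derive from the global seed by hashing the stage name
  (BLAKE2b, 4 bytes, mod 2³¹), so stages are decoupled and reruns
  byte-identical.
- Degenerate inputs raise typed errors: rank-deficient designs, n ≤ p,
  empty validation domains, zero-variance references, realms with no
  wilderness reaching the sampler.

## What passing tests do and do not show

The synthetic worlds share the *statistical* structure of the real
analysis inputs (autocorrelated energy fields, uneven wilderness,
realm-structured richness, conversion coupled to appropriation) but none
of its geometry or biology: no real projections or coastlines, no
climate forcing, one habitat code per cell, range shapes from a flood
fill rather than ecology, and threat flags from a mechanical mismatch
rule. Passing the suite demonstrates that the pipeline's logic,
estimators and protocols are correct and self-consistent — not that the
substantive conclusions transfer to any particular real dataset.
Residual spatial autocorrelation is mitigated only by subsampling, as in
the original protocol, and p-values are not corrected for it.
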