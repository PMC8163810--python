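# Methods

`blowdown` analyses the aboveground-carbon consequences of a wind
disturbance (a *blowdown*: convective-downdraft damage that fells or snaps
trees over a contiguous area) in a forest landscape observed with
discrete-return lidar at two epochs. This note documents the models, the
numerical choices, the synthetic-data generator that stands in for field
data, and the limits of what the test suite demonstrates.

## Canopy rasterization

Point returns carry planar coordinates, elevation, return number and scan
angle. Epoch harmonization follows four rules, each config-gated per epoch
because acquisition platforms differ:

- **First returns only** — the earliest echo per pulse, representing the
  highest intercepted surface; later returns are sensitive to beam
  divergence and detector behaviour.
- **Scan-angle limit** (default ±15°) and **density homogenization**
  (uniform random thinning to a target of 10 pts m⁻²) — applied to the
  denser, wider-swath epoch so the two epochs are comparable.
- **Terrain normalization** — elevation minus bilinearly interpolated
  ground elevation from a DTM; negative heights are clamped to zero, since
  negative canopy height is physically meaningless and the gap machinery
  assumes heights ≥ 0. Points in the half-pixel margin outside the DTM's
  pixel-center grid use edge padding; points outside the DTM extent are an
  error naming the offending count.
- **Vertical bias correction** — a constant per-epoch shift (default
  0.7 m for a known inter-survey bias), supplied by config rather than
  estimated from control surfaces.

Two gridding schemes serve different purposes. The 1.25 m **canopy height
model (CHM)** interpolates a Delaunay TIN of first returns at pixel
centers, so every pixel inside the convex hull has a height (gap detection
cannot tolerate holes); out-of-hull pixels are nodata and excluded
downstream. The 5 m **top-of-canopy height (TCH)** grid is the arithmetic
mean of return heights per half-open pixel footprint
`[x0, x0+res) × [y0, y0+res)` — the half-open convention applies wherever
coordinates meet pixels. Nodata is −9999 in files and NaN in memory.

## Carbon allometry

Plot-mean TCH predicts field AGBD through a power law,

    AGBD = a · TCH^b + ε,   ε ~ N(0, σ²),

fitted by maximum likelihood (equivalently nonlinear least squares in
(a, b) with σ the RMS residual), started from the log–log OLS line and
solved with an analytic Jacobian to tight tolerances, so noise-free data
recover the generating parameters to better than six significant digits.
Carbon is AGBD × 0.47. One shared fit serves both epochs, on the premise
that the height–biomass relationship does not change across the
disturbance.

Predictions are made on square 0.5-ha cells aggregated from the TCH grid.
Exactly 0.5 ha (70.7 m) cannot tile a 5 m grid, so cells are 14 × 14
blocks (70 m, 0.49 ha); the 2% area difference is immaterial because ACD
is a per-hectare density.

**Uncertainty.** A Monte Carlo parametric bootstrap (default 1000 draws)
adds independent N(0, σ) residual noise per cell, truncates at zero (a
deliberate deviation to keep carbon physical), converts to ACD, and takes
2.5/97.5 percentiles per cell and for the landscape mean. Two modes exist:

- *residual-only* (default): only ε is resampled. This quantifies
  prediction scatter, but the landscape-mean interval narrows as
  1/√n_cells while the error of the fitted curve itself does not — so it
  cannot be read as a confidence interval around the true landscape mean.
- *parameter + residual* (`include_parameter_uncertainty=True`): (log a, b)
  are additionally drawn from the delta-method transform of the asymptotic
  MLE covariance (log-scale keeps a positive, which matters at 18-plot
  sample sizes where the raw (a, b) covariance is wide). Coverage checks
  against generating truth use this mode, and the pipeline uses it for its
  reported intervals.

Change maps difference paired draws: parameter draws are shared between
epochs (one shared fit), residual draws are independent. The 17.6%-style
headline statistic is the landscape-mean percent change with percentile
intervals over paired draws.

## Gap size power law

A gap at threshold h is a maximal 8-connected set (diagonals count) of CHM
pixels with height ≤ h; the classic definition uses h = 2 m and the
analysis ladder extends to 20 m in 2 m steps. Gaps touching the raster
edge are included (excluding them in a small window would bias against
large gaps); the minimum gap is a single pixel. Sizes are measured in
pixel counts k, and modelled by the Zeta distribution

    f(k) = k^(−λ) / ζ(λ),  k ≥ 1,  λ > 1,

with ζ the Riemann zeta function (evaluated by `scipy.special.zeta`;
the likelihood reduces to the sufficient statistics (n, Σ log k), one ζ
evaluation per proposal). Smaller λ means relatively more large gaps.

The posterior for λ uses Metropolis–Hastings: uniform prior on
(1.01, 5), normal random-walk proposals with SD 0.1, chain length 100 000,
burn-in 5 000, thinning by 25 — exactly 3 800 retained draws, summarized
by the median and central 95% credible interval. Proposals below 1 are
redrawn from the same density until ≥ 1 (values in [1, 1.01) then die on
the prior). The redraw makes the proposal slightly asymmetric near the
boundary; the sampler reproduces this stated procedure rather than an
idealized corrected version, and its output is cross-checked against an
independent brute-force grid posterior (step 0.001 over the prior
support), with agreement required within 0.02 on the median. Two epochs
are compared at a threshold by Δλ of posterior medians; "significant"
means the two 95% credible intervals do not overlap (the criterion is a
documented interpretation — interval non-overlap is conservative).

## Height-class transitions and equilibrium projection

Paired 5 m rasters are binned into 1 m height classes, class c covering
[c−1, c) m, with the class count set by the ceiling of the tallest pixel
(heights at the top edge fall into the last class). The transition count
a_ij is the number of pixels starting in class j and ending in class i.
Column-normalizing gives a column-stochastic matrix P; the projected
equilibrium height distribution is the dominant right eigenvector
(eigenvalue 1), i.e. the distribution unchanged by the observed dynamics.
The implementation verifies |λ_dom − 1| < 1e−9 and fails loudly rather
than renormalizing; a reducible matrix with several closed class sets has
no unique equilibrium and raises an error listing the blocks. Empty start
classes get uniform columns (with a warning) in the count-based point
estimate. Mean equilibrium height uses class midpoints (c − 0.5 m);
lower-edge weighting is available via the stored class edges.

Each column of transition probabilities is a multinomial parameter, so
with the uniform (uninformative) Dirichlet prior the column posterior is
Dirichlet(counts + 1). Sampling all columns 10 000 times and recomputing
the stationary distribution per draw gives per-class 95% envelopes and an
interval on the equilibrium mean height. The posterior point estimate is
the stationary distribution of the posterior-mean matrix
(counts + 1, column-normalized), which is strictly positive and therefore
always irreducible — sparse count matrices from small rasters often are
not. A departure from steady state is flagged when the observed mean
height falls outside the projected mean's 95% credible interval.

## Optical change detection

Each reflectance pixel is modelled as a linear mixture of three endmember
spectra — photosynthetic vegetation, non-photosynthetic vegetation (NPV)
and shade — and solved per pixel by least squares under the hard equality
constraint that fractions sum to one (KKT system, factored once for all
pixels). Non-negativity is *not* enforced, matching sum-to-one-only
unmixing practice; negative fractions are logged. The package ships a
synthetic six-band endmember set (labelled synthetic in code); measured
sensor endmembers are a config input. ΔNPV = f_NPV(post) − f_NPV(pre)
is tested against zero with a two-sided one-sample t-test (sidedness is
unstated in common usage; two-sided is the conservative documented
choice), and regressed on per-cell ACD loss by OLS. Where the carbon and
reflectance grids differ, pairing uses area-weighted mean resampling onto
the reflectance grid.

## Recovery bookkeeping

Recovery time of the landscape-mean ACD is bracketed by two estimates:

- **long-term**: loss ÷ long-term annual gain (default 0.49 Mg C ha⁻¹ yr⁻¹)
  — an overestimate, because growth accelerates right after disturbance;
- **two-phase**: elevated annual gains for the first 5 years (estimated
  from census records as the mean gains in the 5 years following annual
  losses > 11.5 Mg C ha⁻¹), then the long-term gain — an underestimate,
  because not all of the landscape gets the elevated phase.

Reported years are the integer part of the exact crossing time, with any
positive loss taking at least one year; this floor convention makes the
two approaches ordered (two-phase ≤ long-term whenever elevated gains
dominate the long-term gain) and reproduces, e.g., 17.4/0.49 → 35. The
baseline adjustment adds `gain × years` of pre-event growth (default
0.74 Mg C ha⁻¹ yr⁻¹ × 9 yr) to the loss before either estimate, measuring
recovery against the eve-of-event stock.

## Synthetic data generator

The generator provides every input the pipeline consumes, with the
statistical structure the analysis assumes:

- **Canopy surface**: truncated-at-zero Gaussian heights (default mean
  22.2 m, SD 6 m) smoothed by a moving-average window (5 px) and rescaled
  to preserve the SD, then `n_gaps` disk-shaped patches with
  Zeta(λ = 2)-distributed pixel areas set to a 0.5 m floor. Zeta sampling
  is inverse-CDF on a cumulative table truncated at k_max = 10⁶ with tail
  mass assigned to k_max. Overlapping disks merge, as real coalescing gaps
  do.
- **Disturbance**: additional power-law patches (λ = 1.7) lowered to
  near-ground until a target fraction of total canopy volume (summed
  height) is removed. Because the size law is heavy-tailed, the patch that
  would cross the target is shrunk to the remaining deficit, so the
  realized severity lands within tolerance by construction. True
  per-pixel change and the realized removed fraction are recorded for
  oracles.
- **Plots**: TCH uniform over 14–30 m (the spread of a mixed
  secondary/old-growth landscape; wide enough that 18 plots constrain the
  exponent to ±≈0.07 median error), AGBD = 1.28·TCH^1.6 + N(0, 16),
  truncated at zero. These values give ≈173 Mg ha⁻¹ at 21.5 m and a
  9.2% RMSE — the fit quality of a well-constrained tropical lidar
  allometry. A narrower 18–25 m range (used in one fit-quality test)
  yields r² ≈ 0.74 jointly with that RMSE.
- **Reflectance**: exact linear mixtures of the synthetic endmembers plus
  i.i.d. Gaussian noise; in the demo, the NPV fraction rises inside
  damaged areas in proportion to coarse-grid canopy loss.
- **Point clouds**: uniform planar scatters over the synthetic surface
  with nearest-pixel canopy height, bilinear ground elevation, small
  vertical noise, a second-return fraction and uniform scan angles — a
  geometric fixture, not beam physics.

All randomness flows from one explicit seed per call; identical seeds give
bit-identical outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: real gap geometry (gaps are unions of disks,
not treefall-shaped), vertical canopy structure and occlusion, ground
classification error in the DTM, spatially correlated allometric residuals,
sensor georeferencing error, and atmospheric effects in reflectance. Tests
demonstrate that each estimator recovers the generating process it
assumes, and that the pipeline's qualitative conclusions (carbon loss
bounded by its interval, exponent decrease, equilibrium departure,
positive ΔNPV with weak explanatory power) follow from a disturbance of
known severity.

## Problem sizes and determinism

The packaged experiment uses a 320 m × 320 m landscape (10.24 ha) at the
native grid sizes (1.25 m CHM, 5 m TCH, 70 m carbon cells, 32 m
reflectance pixels, ≈4 pts m⁻² per epoch), a scale at which the full
pipeline — including two 100 000-iteration MCMC chains per threshold,
1000 Monte Carlo carbon draws and 10 000 Dirichlet draws — completes in
about a minute. Statistical-property tests use 20 seeded replicates.
Rerunning any stage with the same seeds reproduces numeric summaries
byte-for-byte.

## Known limitations

- Landscape percent carbon loss in the synthetic experiment (≈25–33% at
  20% volume severity) exceeds the volume severity by construction: ACD is
  convex in TCH (b = 1.6) and disturbance patches are carved to near
  ground.
- The Dirichlet posterior treats pixels as independent multinomial trials;
  spatial autocorrelation of canopy change makes the credible envelopes
  anti-conservative on real data.
- The MH sampler inherits the mild proposal asymmetry of its stated
  redraw rule; the grid-posterior cross-check bounds the induced bias
  below 0.02 at the sample sizes tested.
- LAS/LAZ ingestion is not included; points enter as CSV
  (`x,y,z,return_number,scan_angle`).
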