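# Methods

This note documents the models implemented in `encapquant`, the
numerical choices behind them, and what passing the synthetic-data
tests does and does not demonstrate about real instrument data.

## Capsid geometry

An icosahedral shell on a Caspar–Klug lattice with triangulation number
T = h² + hk + k² (h, k non-negative integers) has 60·T subunits, 12
pentamers at the vertices and 10·(T−1) hexamers, satisfying
12·5 + 6·10·(T−1) = 60·T. Validity of T is checked by exhaustive
search over h, k ≤ 50 (covers T ≤ 2500), which is exact and cheap.

Assembly mass counts each cargo dimer as two monomers:
(240·32.2 + 42·2·22.6) kDa = 9626.4 kDa = 9.63 MDa, which rounds to the
reported 9.6 MDa at two significant figures. Internal-volume
comparisons use outer shell diameters (42/32/24 nm for T = 4/3/1)
because inner diameters are not available; the function returns the
unrounded (d_a/d_b)³ ratio — 535.9% and 226.1% — and leaves any
presentation rounding to the caller. Iron-storage capacity is
`round((π/6)·d³·ρ)` at a requested granularity; the 36-nm shell-limited
core at 3.40 Fe/nm³ gives 83,000 atoms to the nearest thousand.

## Synthetic DualEELS data

`project_sphere` projects a uniform sphere of volumetric density ρ and
diameter d to areal density ρ·2·√(r² − s²) at in-plane distance s,
averaging each pixel over a 4×4 sub-grid so the pixel sum converges to
the closed-form total (π/6)·d³·ρ (within 10⁻⁵ at d/50 sampling).
Pixel centers sit at integer coordinates.

`make_eels_cube` builds, per pixel:

* a low-loss spectrum holding a Gaussian zero-loss peak whose channel
  sum is exactly I₀ (default 10⁸ counts, FWHM 1 eV, ±10 eV window at
  0.25 eV/channel);
* a core-loss spectrum (600–820 eV at 0.25 eV/channel) holding a
  power-law background A·(E/600)^(−r) (default r = 3, 100
  counts/channel at 600 eV per 10⁸ incident — the background is
  dose-proportional, which is what makes the measured density error
  scale as 1/√I₀) plus an Fe-L edge. The edge shape is a sigmoid onset
  of width 2 eV at 708 eV followed by a 60-eV exponential decay,
  normalised so its channel sum over [708, 780] eV equals exactly
  I₀·N·σ with σ = 2664.9 barn = 2.6649×10⁻⁷ nm². Only this integral
  matters for quantification; the line shape itself is a free choice.

Optional Poisson noise is applied channel-wise from a single seeded
generator; identical inputs give bit-identical cubes. Not modelled:
plural scattering and thickness effects (the quantification chain has
no deconvolution step), detector MTF, drift, beam damage, white-line
fine structure, or oxidation-state effects on the edge shape. Passing
round-trip tests therefore shows the analysis chain is unbiased and
correctly normalised for single-scattering data with Poisson
statistics; it does not validate the chain against thickness or
fine-structure artifacts in real spectra.

## EELS quantification

Per pixel (batched across the scan grid by shared-design least squares
plus damped Gauss–Newton refinement, `encapquant._fitting`):

1. **I₀** — a Gaussian is fitted to the zero-loss peak; I₀ is its
   analytic integral divided by the channel width. A raw low-loss
   channel sum is available via `QuantConfig(i0_mode="lowloss_sum")`.
2. **Background** — both candidates are fitted over the pre-edge
   window (default [630, 700] eV, ≥ 10 channels, positive counts
   required): a power law (linear in ln E–ln I) and a first-order
   log-polynomial, read as quadratic in ln E since the power law is
   already linear there. Selection: if the power law fits to rounding
   precision it wins outright; otherwise the quadratic term must pass
   an F-test at a per-pixel level of 10⁻⁴. The small level is
   deliberate — the test runs once per pixel, thousands of times per
   map, and a spuriously fitted curvature term extrapolates
   catastrophically over the 70-eV edge window (single-pixel errors of
   hundreds of atoms/nm² were observed at looser levels). The selected
   model is then refined by unweighted least squares in counts space:
   fitting Poisson data purely in log space underestimates the
   background by E[ln y] − ln E[y] ≈ −1/(2y), which integrates to a
   few-percent bias on particle totals.
3. **Edge integral** — channel sum of (counts − extrapolated
   background) over [708, 780] eV. Negative values on background
   pixels are kept so that empty regions average to zero.
4. **Areal density** — N = I_edge/(I₀·σ), 1 barn = 10⁻¹⁰ nm². The
   statistical error combines window counting statistics with the
   background-extrapolation variance propagated from the fit
   covariance (the dominant term: reported ≈16 atoms/nm² per pixel at
   I₀ = 10⁸, matching the empirical scatter) and the I₀ fit error.
   The 10% relative cross-section uncertainty is tracked separately.

Per-pixel accuracy at the reference dose (I₀ = 10⁸/px) is ~20% of the
peak projected density; accuracy comes from summation. Particle totals
sum N·pixel-area over the mask, add per-pixel statistical errors in
quadrature, and apply the cross-section uncertainty coherently to the
total (it is common to every pixel, so adding it per pixel would
understate it). Pixels failing any stage's preconditions are masked
with a reason, never zeroed.

EDS composition uses the thin-film Cliff–Lorimer relation:
atomic ratio a:b = k_ab·(I_a/I_b), rendered in the conventional "1:x"
form.

## Particle sizing

**Edge-onset diameters** (density or dark-field maps, particle
brighter than background): the local window's histogram is split at
the Otsu threshold; the background level is the lower class's median
and the particle reference level the upper class's 95th percentile —
for a projected sphere the pixel-value density grows linearly toward
the peak projected density, so a high percentile tracks the peak where
a raw histogram mode collapses onto the class boundary under noise. A
window is rejected as containing no particle when its (winsorised)
value skewness is below 0.25; pure symmetric noise stays within ±0.2
while any particle adds a strong positive tail. The threshold sits at
background + f·(particle − background) with f = 0.15 by default:
"edge onset" means just above background, where the projected chord of
a sphere falls to zero, so the crossing lands near the true rim
(geometric bias −(1 − √(1−f²))·d ≈ −1% of d); the midpoint rule
(f = 0.5) is one configuration away but crosses a projected sphere at
0.87·d. The particle is measured along 8 evenly spaced diameters
through the centroid; each chord locates the particle/background
transition on a 1-px-smoothed profile (a crossing requires 2 px
sustained below threshold, suppressing noise spikes) and interpolates
the exact crossing on the raw profile where the rim slope is steep.
Mean and standard deviation of the chords are reported; fewer than 4
valid chords is an error.

**Micrograph route**: global Otsu threshold (dark particles on a
bright field by convention), 8-connected labelling, minimum area 10 px.
The Feret diameter is the maximum pairwise distance between
boundary-pixel centers, computed on the convex hull (which attains the
maximum) with a brute-force fallback for degenerate masks.

Volumetric density is atoms/((π/6)·d³); the ParticleRecord constructor
enforces this identity to 10⁻⁹ relative. For the highest observed core
(23,293 atoms, 23.6 nm) it gives 3.38 Fe/nm³, i.e. 3.4 at two
significant figures.

## Assay curves

**Kinetics model.** The rate law
dP/dt = Vmax·S/(Km + S) + k_auto·S·P^(2/3) with S = S₀ − P combines
Michaelis–Menten enzymatic oxidation with mineral-surface
autocatalysis; the 2/3 exponent is the surface area of a growing
spherical mineral. It is this package's defined model for the
qualitative hyperbolic/sigmoidal dichotomy, not a mechanistic claim.
The autocatalytic term has a fixed point at P = 0, so simulations seed
P(0) = 10⁻⁶·S₀ (configurable; zero seed with zero Vmax stays flat).
Integration uses LSODA at rtol 10⁻⁹; mass conservation holds by
construction of the single-variable ODE.

**Classification** fits P(t) = A·t^h/(t^h + τ^h): h ≤ 1.2 is
hyperbolic, h ≥ 1.5 sigmoidal, between is ambiguous — the explicit
band avoids forced calls near the boundary. The fit is scale-invariant
in time and amplitude. One behaviour matters for interpreting the
labels: a Michaelis–Menten progress curve looks hyperbolic (h ≈ 1.05–
1.2) only in the sub-saturating regime (Km ≳ 2·S₀) observed to partial
conversion; enzyme-saturated curves rise linearly and then cut off,
which the Hill fit reads as h ≈ 2. The generators' "hyperbolic" regime
therefore uses Km = 250 µM at S₀ = 100 µM over a window capturing
~80% conversion — consistent with a flux-limited compartment assay —
and the classification grids sample that regime. Autocatalytic curves
fit h ≈ 3.7 across two decades of k_auto.

**Melt curves** are two-state sigmoids over a 35–95 °C ramp with
linear pre/post baselines; the unfolded fraction has scale
steepness/4 (default 0.5 °C) and the derivative peak sits at Tm by
construction for flat baselines. `fit_tm` first locates the transition
on a lightly smoothed finite-difference derivative and then fits a
degree-7 polynomial in a ±8 °C window around it, taking Tm as the
interior argmax of the polynomial derivative on a 0.01 °C grid. The
window matters: a single degree-7 polynomial across the whole 60 °C
ramp cannot follow a transition a couple of degrees wide and biases Tm
by over 1 °C. Recovery is within 0.15 °C noise-free and within 0.2 °C
at 2% amplitude noise across 50 seeds. A near-constant derivative
(monotone ramp, no transition) or a boundary argmax raises an error.

**Peroxidase calls** are background-subtracted A490 endpoint means;
activity requires the signal to exceed a configurable number (default
3) of blank standard deviations.

## Pipeline study conditions

The default end-to-end run emulates the 22 spectrum-imaged cores:
diameters ~N(23, 3) nm clipped to 18–30 nm, volumetric densities
uniform on 2.8–3.4 Fe/nm³, sampled at 0.75 nm/px with a mapping dose
of I₀ = 10⁹/px. The clipping and dose reflect that cores picked for
spectrum imaging are the larger, well-mineralised ones and that maps
are acquired with enough dose to delineate them (at 10⁸/px the faintest
cores' peak signal is ~3σ of the per-pixel noise and no sizing method
can work); the unselected size distribution is the micrograph
generator's job, and the 10⁸/px reference dose remains the round-trip
test condition. Each phantom draws an independent child seed from the
run seed, so a run is a pure function of its configuration. Under
these conditions every per-particle total lands within ±1.5% of ground
truth and every diameter within ±0.7 px across seeds. The report
summary (max Fe count, max density, mean diameter, capacity
extrapolated to the 36-nm shell-limited core at the highest observed
density) is recomputed from the table and verified on every run.

## Known limitations

* The density map's per-pixel noise is dominated by background
  extrapolation; window choice ([630, 700] eV) trades bias against
  variance and is not optimised per dataset.
* Edge-onset sizing assumes one particle per window and bright-on-dark
  polarity; touching particles are not split (no watershed).
* The skewness-based particle-presence test can reject genuine but
  very faint or very window-filling particles (a particle occupying
  half the window has near-zero skew).
* The kinetics rate law is qualitative; fitted Hill exponents should
  not be read as mechanistic cooperativity.
* Reported per-particle errors assume independent pixels; correlated
  instrumental drift is not modelled or propagated.
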