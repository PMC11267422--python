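# Methods

This note records the models, conventions and numerical choices behind
the package, and what the synthetic fixtures do and do not establish
about real data.

## Monolayer analysis

**Condensation effect.** For a binary film, c = 100·(1 − A₀/(X₁A₁+X₂A₂))
in percent, evaluated by default at 30 mN/m. The formula is written so
that c = 0 exactly at ideal mixing, c > 0 for condensation and c < 0 for
expansion; both A₀ and the pure-film areas come from the same
MMA-extraction path (replicate averaging, then linear interpolation at
the query pressure), so the ideal-zero identity holds to machine
precision.

**Replicate averaging.** Replicates are interpolated linearly onto the
pressure grid of the first replicate restricted to the common range, then
averaged pointwise with the sample standard deviation (ddof = 1). Linear
interpolation (no spline) is adequate because isotherms are densely
sampled and monotone; it also keeps the MMA query monotone-consistent.

**MMA extraction.** Linear interpolation between bracketing samples; no
extrapolation — a query outside the recorded range is an error.
An optional `round_down` mode instead snaps the query to the nearest
recorded pressure at or below the target, mimicking workflows that round
data down to the nearest recorded neighbor before computing condensation
and free energies; it is off by default because interpolation uses
strictly more of the data.

**Excess free energy of mixing.** ΔG_exc(Π*) is the trapezoidal integral
of the excess area ΔA(Π) from the lowest tabulated pressure up to Π*
(interpolating the end point when Π* falls between grid points),
converted with 1 mN/m·Å²/molecule = 1e-23 J/molecule and Avogadro's
number (factor 6.02214 J/mol). No extrapolation to Π = 0 is attempted;
the integration lower bound is recorded in the result (the synthetic
grid starts at 0.5 mN/m). ΔG = 0 is reported for ideal mixing, i.e. the
default omits the ideal entropy term RT(X₁lnX₁+X₂lnX₂); the term is
available behind `include_ideal` (at the film temperature, default
20 °C) for comparison with conventions that include it. The package
reads ΔG = 0 as "ideally mixed", which is only true of the excess part —
hence the excess-only default.

**Uncertainty.** All propagation is first order (delta method) with
independent errors: mole-fraction-weighted quadrature for the ideal
area, analytic partials for c, and quadrature over trapezoid weights for
ΔG. A corollary used as a test invariant: doubling every input sd
exactly doubles every output sd.

**Group comparison.** Each replicate isotherm is reduced to the OLS line
A = β₀ + β₁Π over a configurable window (default 10–30 mN/m, the
near-linear liquid-condensed region of the synthetic films), and groups
are compared by one-way MANOVA on the (β₀, β₁) vectors. Pillai's trace
is the default statistic (robust for small groups); Wilks' lambda is
selectable. Identical replicates give a singular within-group covariance
and raise a degeneracy error rather than a spurious p-value.

## Trajectory analysis

**Frame model.** Planar bilayers with the membrane normal along the
laboratory z axis; no local-normal or undulation correction. Boxes are
orthorhombic; bond vectors (C–H, C24–O3, double-bond pairs) are
unwrapped by minimum image before any angle or midpoint is computed.
Every frame weighs equally (plain averages, no autocorrelation
correction).

**Bilayer centre.** z₀ is the midpoint of the two leaflets' mean
phosphate-anchor z, recomputed per frame. Leaflets are assigned per
residue by the sign of its anchor z (phosphate for phospholipids, O3 for
ring lipids) minus z₀.

**Order parameters.** S_CD = ½⟨3cos²φ−1⟩ per chain carbon, signed (no
absolute value), averaged over C–H bonds, residues, and frames. The
plateau is the arithmetic mean over chain carbons 4–8 (configurable).
Carbon numbering starts at 2 (alpha to the carbonyl), so a Δn bond joins
carbons n and n+1. Hydrogens must be explicit; the chain topology (atom
names per carbon, double-bond position) ships as an editable YAML
registry.

**Histograms.** z-histograms use bin width 0.87 Å anchored at the
bilayer centre and fold the two leaflets onto |z−z₀| by default (the
one-sided convention; an unfolded mode exists). All histograms are
normalized to unit integral. The overlap coefficient is
Σ min(p₁,p₂)·Δz; mismatched binnings are rebinned onto a common grid by
linear mass assignment before comparison.

**Tilt.** The angle between the C24→O3 vector and the outward normal of
the residue's leaflet, so upright molecules score near 0° in both
leaflets; histogrammed on [0°, 180°] (2° bins).

**Voronoi areas.** Reference points are the unweighted centroid of the
C2/C21/C31 glycerol atoms (phospholipids) or the O3 atom (ring lipids),
wrapped into [0, L). Periodicity is handled by tiling the box 3×3 and
keeping the central-copy cells, which are then closed convex polygons;
their areas partition the box (Σ = Lx·Ly, asserted to 1e-6 relative).
Coincident points are separated by a deterministic 1e-6 Å jitter with a
warning.

## Cell assays

Growth rate is the negative OLS slope of OD562 on time, restricted to
measured OD values inside the closed window [0.4, 0.75] — the indicative
range of phenol red. The lysed fraction normalizes each replicate to its
own plate anchors, f = (F_q − F_intact)/(F_lysed − F_intact), taking the
0 % wash-buffer well (pure water) as the full-lysis reference and the
100 % well as intact; this makes f increase with hypoosmotic stress. The
anchor mapping is explicit in the code because plate layouts vary.
Replicates are averaged after normalization (per-plate gain cancels
first); the mean is clamped to [0, 1] with the raw value also reported.
Group comparison is one-way ANOVA with Tukey HSD.

## Synthetic data

The generators define the study conditions for every test:

* **Isotherms** are quadratic in pressure, A(Π) = c0 + c1Π + c2Π² on a
  0.5–40 mN/m grid (0.5 steps), constrained positive and strictly
  compressing, with i.i.d. Gaussian area noise (default sd 0.3 Å², three
  replicates). The reference calibration fixes A(30) at 65.3 / 66.0 /
  64.3 Å²/molecule for the Δ6/Δ9/Δ11 films with a shared compressibility
  shape. The quadratic form is a modelling convenience only — no
  analysis step assumes it.
* **Mixtures** add an injected excess ΔA(Π) (zero, constant, or Gaussian
  hump) to the mole-fraction-weighted pure curves; the implied true
  condensation 100·(−ΔA)/(X₁A₁+X₂A₂) is recorded as ground truth.
* **Toy bilayers** place lipids on a jittered lattice (default 100 per
  leaflet — a reduced-size stand-in for simulation-scale systems of
  roughly 550 per leaflet — in a box sized at 8 Å lattice spacing, 50
  frames by default: seconds-scale to generate yet ample sampling).
  Each carbon's C–H vectors sit at the exact polar angle solving
  ½(3cos²φ−1) = S_target with uniform random azimuth, leaflet-mirrored;
  since the normal is z, the per-bond angle is exact and the recovered
  S_CD is deterministic, not merely unbiased. Methyl groups and
  double-bond midpoints are drawn from prescribed Gaussians in |z|
  (defaults place the Δ9 bond at 8.5 Å coinciding with Dpop's M2 at
  8.5 Å, and the Δ11 bond at 6.5 Å between M3 and M4); ring-lipid tilt
  is fixed or Gaussian. Phosphate anchors are emitted so the centring
  convention is self-consistent.
* **Plate traces** are linear OD decays and anchor-interpolated
  fluorescence with Gaussian noise.

What passing tests show — and do not. The toy bilayer realizes the
*observables* exactly by construction; it contains no conformational
statistics, force-field energetics, collective tilt, or undulations.
Tests against it validate the measurement code (geometry, binning,
periodic boundaries, averaging, normalization), not the physics of real
membranes. Likewise the quadratic isotherms contain no phase
transitions, so the monolayer tests validate the reductions, not an
equation of state.

## Numerical choices and degenerate inputs

* Interpolation is linear everywhere; queries outside tabulated ranges
  are errors, never extrapolated.
* Duplicate pressures in an input isotherm are averaged with a warning;
  small non-monotonicity of area with pressure (noise) warns but does
  not fail.
* S_CD estimates are clamped only by physics: any value outside
  [−0.5, 1] raises, since cos² arithmetic cannot produce it.
* Histogram edges tile outward from the bilayer centre (folded) or
  symmetrically about it (unfolded), so the centre is always a bin edge.
* Zero-length orientation vectors and hydrogen-free carbons are skipped
  with warnings; empty selections are errors.
* All random draws flow from a single `numpy` Generator per call,
  seeded explicitly: identical seeds reproduce outputs bit-for-bit,
  different seeds change noise but not noiseless structure.

## Problem sizes

Default test-suite scales: 100 lipids per leaflet × 50 frames for
order-parameter recovery (tolerance 0.01), 512² pixels for the raster
tessellation oracle on 100-point configurations, and 200 Monte-Carlo
replicates for the ANOVA/MANOVA type-I calibration (acceptance band
0.02–0.09 at α = 0.05, the binomial 95 % region around the nominal
rate). The analysis drivers default to 50–60 lipids per leaflet and
10–20 frames, which already recover the prescribed observables to the
third decimal.

## Known limitations

* The membrane normal is global; curved or undulating membranes are out
  of scope, as are implicit-hydrogen force fields.
* MANOVA assumes multivariate normality of the fit coefficients within
  groups; with two-point coefficient vectors and few replicates the
  Pillai F approximation is conservative.
* The lysis normalization assumes the anchors bracket every sample up to
  noise; gross anchor failures (equal anchors) raise rather than
  silently rescale.
* Trajectory I/O targets text formats (PDB/GRO); compressed binary
  trajectory containers are supported only insofar as MDAnalysis reads
  them alongside a coordinate file.
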