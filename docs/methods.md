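# Methods

This note documents the models and numerical choices behind piezokit.
It states no empirical result that the test suite and
`scripts/acceptance.py` do not themselves compute.

## Membrane-footprint overlap model (`piezokit.footprint`)

A curved membrane protein such as the Piezo1 trimer bends the
surrounding bilayer into a decaying "footprint".  The footprint profile
is taken as the ansatz h(x) = tanh(m0·x) in reduced units (lengths
scaled by the footprint height H), with m0 = tan(α) the membrane slope
at the dome edge for arms inclined at α to the membrane plane.  This is
a stated ansatz, not a solution of Helfrich elasticity: it reproduces
the flat far-field plateau and the "knee" of maximal curvature near the
dome, which sharpens with α.

Two domes separated by D = R/H reduced units have footprints that meet
midway, where each has slope m = m0·sech²(m0·D/2).  The intersection
angle is θ = π − 2·arctan(m): π minus the two local inclination angles.
θ(α; D) is biphasic in α; the separation at which a given α is the
stationary point solves

    tan(α)·D·tanh(tan(α)·D/2) = 1.

The left side is monotone increasing in D, so the root is found by
bracketed Brent/bisection on D ∈ (1e−6, 100] to 1e−10.  The physical
critical dome–dome distance is R_crit = D_crit·H.

Two textual ambiguities in the source material are handled explicitly:

* the slope at the dome edge is tan(α) (the slope of a line inclined at
  α), not arctan(α); both appear in prose but only tan is geometrically
  consistent with the sech² slope formula;
* an alternative "literal" reading of the printed angle formula,
  θ = π − 2·arctan(tan α)·sech²(tan α·D/2), is implemented alongside the
  canonical construction (its stationarity condition is
  D·(1+t²)·arctan(t)·tanh(t·D/2) = 1 with t = tan α).  Both forms give a
  critical D at α = 38° inside the 1.6–2.8 band; the canonical form is
  the default everywhere.

The free-energy balance of pore opening,
ΔG_total = ΔG_protein − (ΔG_memb + ΔG_overlap) − γ·ΔA, converts the
tension work once: 1 mN/m × 1 nm² = 1 zJ, divided by kBT at 310.15 K
(4.2827 zJ).  The temperature is an explicit argument.

## Dome curvature fit (`piezokit.dome`)

Each leaflet's headgroup cloud is fitted with a bivariate Gaussian dome

    g(x, y) = zo + h·exp(−½ (p−μ)ᵀ C⁻¹ (p−μ)),   h < 0,

with C = Rot(θ)·diag(σ₁², σ₂²)·Rot(θ)ᵀ.  The printed source formula has
a positive exponent and no −½ factor, which diverges; the implemented
form is the only one consistent with the companion curvature relation
κᵢ = |h|/σᵢ² (the surface's principal curvatures at the peak; the
reported "mean curvature" is their arithmetic mean — the natural reading
of a peak-curvature plot, adopted here and documented as a choice).

Optimization: BFGS on the sum of squared z-residuals with an analytic
gradient, parameterised as (zo, u, μx, μy, log σ₁, log σ₂, θ) with
h = −exp(u), so positivity/negativity constraints hold by construction.
Maximum 2000 iterations, gradient tolerance 1e−8.  The fitted model is
canonicalized to σ₁ ≥ σ₂ (p1 = major axis) with θ in [0, π), since an
axis orientation is defined modulo π.

Initial guess (percentile recipe): zo = 95th percentile of z; rows
outside the [5th, 95th] z-band are dropped; |h| = z-range of the kept
rows; μ = depth-weighted mean of (x, y) with weight max(zo − z, 0);
principal axes and σ from the eigendecomposition of the depth-weighted
second-moment tensor (the square roots of its eigenvalues serve as σ
guesses — the eigenvalues themselves carry units of length²).  By
default the clipping affects only this initial guess; the least squares
sees every row.  Clipping the fitted data too (`clip=True`) reproduces
the outlier-robust variant, but on clean synthetic clouds it censors the
height noise asymmetrically near the dome peak and biases |h| (hence κ)
low by 10–20 % at noise σ ≈ 1 Å — measurable with this package's own
generator — so it is opt-in, intended for real data with genuine
outliers.

1D planar profiles (xz / yz) use the same machinery in one dimension on
a slab of configurable half-width (default 5 Å) about the axis through
the fitted 2D peak; trough curvature is |h|/σ².  Per-frame series fits
are warm-started from the previous frame and per-frame failures are
flagged rather than fatal.

Degenerate inputs: fewer than 10 points or rank-deficient xy spread
raise before optimization; a perfectly flat cloud drives |h| → 0 and
reports ~zero curvature.

## Pore geometry (`piezokit.geometry`)

* Gate size: distances of the three V2476-like marker atoms to their
  centroid, sorted (min, median, max).
* Dome radius r: mean centroid distance of the outer-helix COM triangle;
  dome–dome distances to the periodic neighbours are box_x − 2r and
  box_y − 2r, with negative values flagged as overlapping rather than
  rejected.
* Arm flattening angle β: angle between a beam's dominant principal axis
  (SVD of the centred atom cloud, oriented from the first to the last
  supplied atom, i.e. pore-proximal to distal) and the internal axis
  from the CTD COM to the cap COM.  The principal-axis construction is a
  documented choice; the alternative (terminal-atom vector) differs only
  for strongly bent beams.
* Cap rotation: least-squares in-plane rotation of pivot-centred
  coordinates projected onto the plane normal to the axis,
  φ = atan2(Σ u×v, Σ u·v).  Positive φ corresponds to the right-handed
  rotation matrix R(+φ) about the +axis (counterclockwise viewed from
  the +axis side); `sign="cw_from_plus"` flips the convention, since the
  viewing direction behind a reported "clockwise" is rarely stated.
* Leaflet area fraction occupied by protein: 1 − n·APL/A_box.  The
  area per lipid is an explicit input, never inferred.
* No minimum-image correction is applied to intra-protein geometry (the
  protein is assumed whole); trajectory-wide summaries take the
  averaging window (e.g. a last-N-ns window) as an explicit parameter.

## Permeation and conductance (`piezokit.permeation`)

The counting region is an axial slab z_lo < z < z_hi intersected with a
cylinder of radius r_cut about the pore axis (defaults 56–66 Å and
35 Å).  A permeation event is an ion entering through one axial boundary
and exiting through the opposite one with every in-slab sample inside
the cylinder (strict containment: an ion that wanders outside the
radius mid-slab has left the pore, so its transit is voided; for a
single-step jump across the whole slab both bracketing samples must be
contained).  Crossing times are assigned sub-frame by linear
interpolation of z.  z is unwrapped first when a periodic box height is
supplied (jumps > box/2).  Bookkeeping: a +z crossing of charge +q and a
−z crossing of −q both transport +q; per-species, per-direction raw
counts are also returned.

Currents:

* counts route: I = (net transported charge in e)/τ, converted via
  e = 1.602177×10⁻¹⁹ C (1 e/ns = 160.2177 pA).  Uncertainty from the
  exact (Garwood) Poisson interval on the event count, via χ²
  quantiles — conservative by construction.
* z-displacement route: I(t) = Σᵢ qᵢ·Δz̃ᵢ/(Δt·L) with z̃ the z clipped
  to the slab, so only in-region motion contributes and a complete
  traversal transports exactly one ion charge (telescoping); L defaults
  to the slab length, as the pore length is not otherwise fixed.
  Uncertainty by moving-block bootstrap of the instantaneous series
  (default block 10 samples, B = 1000, seed mandatory).

The two estimators agree exactly up to ions currently inside the region
(partial traversals), which the tests assert as a hard bound.

Conductance: through-origin least squares G = Σ IᵥVᵥ/Σ Vᵥ² (pA/mV →
×1000 pS), R² against the through-origin model.  For the counts route a
CI is propagated by resampling each voltage's event count from
Poisson(N_obs), rescaling its current and refitting (one admissible
reading of propagating per-voltage Poisson uncertainty into a slope;
the original procedure is not stated).  Selectivity ratios are ratios of
summed event counts; a zero denominator is reported as the one-sided
lower bound N/1 and flagged, since the true selectivity can only be
larger.

## Lipid contacts (`piezokit.contacts`)

The contact cutoff is the first local minimum after the first local
maximum of the probe–headgroup radial distribution function, after a
centred moving-average smoothing (default 5 bins at 0.1 Å).  The RDF
uses minimum-image distances in orthorhombic boxes (triclinic
unsupported — the intended systems are orthorhombic), spherical-shell
normalization and the per-frame instantaneous box volume; r_max beyond
half the smallest box dimension is rejected.  Documented operating
points for Piezo1/PIP₂: 5.7 Å at all-atom resolution (Arg/Lys CZ/CE
probes), 6.5 Å at MARTINI coarse-grained resolution (SC1 beads).

Occupancy is per residue: the fraction of frames in which *any*
designated headgroup atom is within the cutoff of *any* probe atom
(per-atom contact semantics, "at least one lipid").  Hotspots are
residues above both thresholds — 60 % of the coarse-grained and 90 % of
the all-atom trajectory by default — present in both tables; residues
present in only one table are excluded with a warning.

## Synthetic data (`piezokit.synth`)

The generators produce inputs with exactly the statistical structure
each estimator assumes, standing in for microsecond MD trajectories:

* membrane clouds: xy uniform over the box (minus an optional exclusion
  disk mimicking the protein's own area), z = dome model + iid Gaussian
  noise.  Defaults (5000 points, 250 Å box, 1 Å noise) match a
  single-protein bilayer patch at typical headgroup resolution.
* ion traces: Euler–Maruyama drift-diffusion in z
  (Δz = v·Δt + √(2D·Δt)·ξ) with an Ornstein–Uhlenbeck lateral walk
  reflected at the cylinder wall (stationary SD r_cut/4), Poisson
  injection at a reservoir plane 10 Å beyond the upstream boundary and
  removal at walls 10 Å beyond the reservoirs.  Δt is rejected if the
  drift per step exceeds a quarter of the slab (event-skipping risk).
  Defaults (10 Å slab at 56–66 Å, 35 Å cylinder, 0.1 ns sampling,
  100 ns per condition) echo the in-silico patch-clamp geometry.  The
  truth record carries (i) the closed-form expected net crossing rate,
  injection rate × the drift-diffusion splitting probability
  (1 − e^(−v·d₁/D))/(1 − e^(−v·d/D)) from the injection plane to the far
  wall, and (ii) an internal traversal tally computed by a deliberately
  minimal side-of-slab scan, independent of the analysis state machine.
  With `drain=True` ions injected before the cutoff finish their
  journey, making the event count an unbiased Poisson sample of
  rate × p × τ (used in recovery tests); without it, late-injected ions
  are censored at τ.
* contact series: a two-state Markov chain with stay probability
  `persistence` in the contact state and off→on probability chosen so
  the stationary occupancy is p_on; inconsistent pairs (implying
  probabilities outside [0, 1]) are rejected.
* footprint surfaces: the two mirrored tanh profiles tabulated on a
  20001-point grid; the intersection angle measured from
  central-difference slopes at the midpoint is the geometric oracle for
  the closed-form angle (agreement to 1e−4 rad is part of the
  acceptance suite).

What the generators deliberately do not model: electrostatics, lipid
chemistry, protein structure, ion–ion interactions, anisotropic or
non-Gaussian membrane undulations.  Passing tests therefore demonstrate
estimator correctness and calibration under the assumed statistical
structure, not fidelity to any particular force field or real
trajectory.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded per spec;
generators are bit-reproducible per (spec, seed).  The regression suite
uses clouds of 2000–50 000 points, 10 000 random-walk ion traces for the
counting oracle, 20-replicate recovery runs of ~50 ions × 1000 steps per
voltage, and 10 000-draw coverage checks — sizes chosen so the whole
suite completes in well under a minute while leaving the statistical
assertions sharp.

## Known limitations

* The tanh model is one-dimensional in the radial coordinate; true
  footprint overlap between finite-size domes is not axisymmetric.
* The dome fit is a single global Gaussian; membranes with multiple
  deformations or strong undulations violate the model class and are
  reported only through the fit diagnostics.
* The z-displacement current gates ions on their position at the start
  of each step; sub-step boundary crossings are handled by clipping, not
  by interpolating the radial coordinate.
* Occupancy analysis treats frames as exchangeable; it estimates a
  fraction, not binding kinetics (no residence times or rate constants).
* Triclinic boxes are not supported anywhere minimum-image arithmetic is
  used.
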