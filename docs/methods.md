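# Methods

`silkbundle` simulates the tensile mechanics of regenerated silk fibers
(RSFs) modeled as bundles of silk microfibrils (SMFs), and analyzes the
resulting — or externally supplied — stress-strain curves and amide-I
infrared spectra.  This note records the model, its numerical choices,
and the design decisions taken where the problem was genuinely open.

## The coarse-grained bundle model

Each microfibril is a 1D chain of mass beads (mass m = 5.5e-10 g,
matching silk density for a 10 µm fibril segment) at equilibrium spacing
r0 = 7.1 µm along the loading axis.  Three interactions act:

**Morse bonds** between consecutive beads,

    E(r) = D [1 − exp(−α(r − r0))]²,

with D = 1.41e-8 J and α = 2.14e6 m⁻¹.  These values reproduce a
single-fibril Young's modulus of 11.2 GPa (initial slope, with stress =
axial force / (πσ²/4), σ = 10 µm the fibril diameter) and a work to
rupture of 3.0 MJ m⁻³.  The small-strain stiffness is 2Dα² ≈ 1.29e5 N/m,
i.e. E ≈ 2Dα²r0/(πσ²/4) ≈ 11.7 GPa; the Morse tangent softens by ~10%
already at 0.5% strain (αr0 = 15.2), which is why the package fits the
modulus over 0.05–0.15% strain (see below).

**Angular springs** on every bead triple, E(θ) = K_B(θ − π)², carry the
bending stiffness of a solid circular fibril: K_B = E_f·I_t/(2r0) =
E_f·σ⁴/(128·r0) ≈ 1.23e-7 J for E_f = 11.2 GPa.  The potential has no ½
factor; tensile observables are insensitive to this convention because
loading keeps the chains straight.

**Inter-fibril cohesion** acts pairwise between beads of different
fibrils through a 12-6 Lennard-Jones potential with length scale σ,
truncated and shifted at 2.5σ, and a well depth that depends on the
bundle radius R:

    ε(R) = (1/R − 1/R2)·(ε1 − ε2)/(1/R1 − 1/R2) + ε2,

linear in 1/R between (R1 = 0.026 mm, ε1 = 0.6e-8 J) and (R2 = 0.09 mm,
ε2 = ε1/6), clamped to the endpoint values outside the calibration
interval (1/R extrapolation to small R diverges).  This encodes the
reeling-speed physics: thin, fast-reeled bundles cohere strongly.

### Close-packed construction is load-bearing

Fibril centers occupy a triangular lattice of pitch σ.  The axial
registry matters enormously: if all beads are axially aligned, every
adjacent fibril pair sits on a *maximum* of the inter-fibril corrugation
(a half-spacing stagger is lower in energy by ~0.2ε per bead), so the
aligned bundle is mechanically unstable — under any dynamics the fibrils
spontaneously stagger, internal bond strains exceed the rupture strain,
and the bundle self-damages before it is ever loaded.  We verified this
with long overdamped relaxations (the potential energy descends by ~6%
while bonds tear) and consider it a real property of the stated
Hamiltonian, not a numerical artifact.

The package therefore builds bundles genuinely close-packed: the
triangular lattice is 3-colored (color = (i − j) mod 3 in lattice
coordinates, so nearest neighbors always differ) and the color classes
are offset axially by 0, r0/3 and 2r0/3.  Every adjacent pair then rests
at a relative offset of ±r0/3 — a frustration-free equilibrium of the
corrugation with *positive* shear stiffness.  This arrangement is
stable, transfers shear linearly at small strain, and is what the model
needs to reproduce the published brittle/ductile size effect.  An
aligned construction remains available (`staggered=False`).

Two alternative couplings explored during development are retained as
options on `SimulationConfig.pair_mode`: `"junction"` (persistent
sacrificial harmonic junctions with the LJ well curvature 57.15ε/σ² and
detachment when the stored energy reaches ε) and `"contact"`
(mutual-nearest-bead LJ contacts).  Both suppress the stagger
instability but neither reproduces ductile sliding: a sacrificial
interface makes sliding a peel process whose force sqrt(2·k_bond·w)
exceeds the fibril strength even at ε2.  Conservative re-gripping
corrugation — the dense LJ on the staggered lattice — is what makes
thick-bundle sliding cheap and is the default.

### Loading protocol

Following the asymmetric grip scheme that permits sliding, the left
terminal bead of odd-index fibrils is held and the right terminal bead of
even-index fibrils is driven at constant velocity ε̇·L (displacement
control; a constant strain rate is not realizable under force control).
Default strain rate 10 s⁻¹.  For bundles the grips are soft anchor
springs of stiffness 2Dα² rather than rigid constraints — rigid terminal
beads concentrate the transverse lattice relaxation into their first
bond and snap it; the anchor-spring compliance costs < 3% in measured
modulus.  Single-fibril (homogeneous) runs keep rigid grips so the
closed-form modulus cross-check is exact.

The integrator is athermal BAOAB (velocity Verlet with an exponential
friction substep), bit-reproducible at fixed seed.  Thermal noise is
omitted: at these bead masses kT is ~12 orders below the bond energy.
Choices:

* **Time step.**  The reference step 5e-8 s exceeds the bond-oscillator
  stability bound T/20 ≈ 6.5e-10 s at the physical mass, so runs use
  mass scaling (default 1e4, a standard quasistatic device); the run
  refuses a dt above the bound.  Quasistaticity is checked by the
  rate-halving property (< 2% modulus change), not assumed.
* **Damping.**  γ = π·sqrt(2Dα²/m_eff)/n per fibril — critical for the
  fundamental stretch mode.  The resulting drag bias on the measured
  force is a constant ~400 µN offset that cancels in the modulus slope
  and is < 3% of the failure force.
* **Equilibration.**  The lattice is built at pitch σ, on the repulsive
  wall of the LJ (minimum at 1.12σ).  Before loading, the transverse
  lattice is scaled uniformly to its energy optimum and relaxed for 2000
  overdamped steps (critical at the *bond* frequency; an underdamped
  relaxation would release ~ε per bead as kinetic energy — enough to
  break bonds).
* **Rupture.**  A Morse bond never formally breaks, so bonds are deleted
  irreversibly at a strain threshold.  The default, 0.0278, is the
  strain at which the homogeneous fibril has absorbed exactly
  3.0 MJ m⁻³ — the calibrated single-fibril work to rupture.  (The
  peak-force strain ln2/(αr0) ≈ 0.0456 would give 6.3 MJ m⁻³, twice the
  calibrated value.)
* **Initial noise.**  Free beads get Gaussian jitter of 1e-4·r0 — enough
  to seed symmetry breaking, far below the rupture strain.  Replicate
  spread under seed variation is consequently very small; the model is
  nearly deterministic.
* **Termination.**  A run ends at max strain or when the pulling force
  falls below 1% of its running maximum (evaluated once the ramp passes
  a quarter of the rupture strain), which terminates both brittle and
  ductile runs.

### Observables

Stress is the pulled-set constraint force divided by the *nominal* CSA,
n_fibrils·πσ²/4 (solid footprint, no void correction), which makes
single-fibril and bundle stress scales commensurate; strain is
engineering strain of the ramp.  From the curve:

* **Young's modulus**: OLS slope over 0.05–0.15% strain.  The window is
  deliberately small — it reproduces the initial-slope convention and
  stays clear of both the Morse softening (−10% by 0.5% strain) and the
  loading start-up transient (decayed by 0.05% strain at the default
  rate; verified by rate halving).
* **Toughness**: trapezoidal area to the break point, defined as the
  first post-peak sample below 10% of the peak stress (finite and
  insensitive to post-failure ringing for both failure modes);
  1 MPa × unit strain = 1 MJ m⁻³.
* **Failure mode**: brittle when ≥ 80% of the broken bonds lie within
  one axial window of width 5·r0 around the modal break position and the
  mean neighbor-pair sliding is < 20% of the pulled-end displacement;
  ductile when sliding ≥ 20%; mixed otherwise (mixed counts toward
  ductile when bracketing the transition, since it already implies
  substantial sliding).  The thresholds are declared constants; the
  critical CSA is always reported with its bracket so their sensitivity
  is visible.
* **Critical CSA A_c**: midpoint of the bracket between the largest
  majority-brittle and smallest majority-ductile CSA of a replicate
  sweep.

## What the model reproduces, and what it does not

With every printed parameter and the close-packed construction:

* a single fibril gives 11.2 GPa / 3.0 MJ m⁻³ by construction (the
  calibration round-trips through the dynamics);
* the thick bundle (CSA 0.025 mm², ε2 cohesion) slides ductilely —
  zero bond ruptures at the reduced scale — with a ~40–50 MPa sliding
  plateau and toughness 8–17 MJ m⁻³ depending on the strain cap;
* the brittle→ductile flip appears between CSA 0.007 and 0.014 mm² on
  the reduced-scale sort-center sweep, bracketing 0.008 mm²;
* modulus falls and toughness rises monotonically with CSA through the
  transition.

Two quantities fall short of their published values, for identifiable
mechanical reasons rather than numerics:

* **Thin-bundle toughness (and strength).**  With alternating grips,
  only 12 of the 25 fibrils cross the pulled end plane, so those bonds
  carry ~2.1× the mean tension and rupture at ~1% applied strain; the
  measured toughness is ~0.3 MJ m⁻³ against the published 3.3.  A bundle
  toughness *above* the single-fibril value requires the end-plane
  concentration to be absent, which force balance forbids under this
  grip scheme.
* **Moduli under strong shear-lag.**  The thin-bundle modulus measures
  9.3–9.5 GPa (transfer-length compliance of the ε1 interface over
  L = 1000 µm) against 11.2; the reduced-scale thick bundle gives
  5.9 GPa against 8.0, because ductility requires the ε2 transfer length
  (~250 µm) to be comparable to the fibril length, and the same ratio
  depresses the apparent stiffness.  At the full 1000 µm length the
  thick-bundle regime l_t/L ≈ 0.3 would plausibly restore ~8 GPa, but a
  full-size dense run costs hours on one CPU and is not part of the test
  suite.

The corresponding acceptance tests are left red with this analysis; the
failure-mode and transition checks pass.

## Problem sizes

Default runs: fibril length 1000 µm (141 beads), rate 10 s⁻¹, dt 5e-8 s,
mass scaling 1e4.  The thick-bundle and sweep simulations in the test
suite use a length-reduced configuration — 250 µm fibrils, rate 25 s⁻¹
(verified quasistatic at that size; 50 s⁻¹ overshoots the sliding
plateau and breaks grips), dt 5e-7 s with mass scaling 1e6, strain
capped at 20% — chosen so the whole suite completes on one CPU in well
under half an hour.  Because the ductile toughness is integration-capped
at the common max strain, the monotone-toughness property is asserted
strictly through the transition and as "no material regression" between
the two ductile points.

## Synthetic data

The generators exist to validate analysis code by round-trip, not to
imitate instrument quirks.

* **Tensile curves**: linear rise at the target modulus to a 1% yield
  strain, flat plateau, instant break placed so the trapezoidal area
  equals the target toughness exactly (grid error < 0.5%).  Noise is
  multiplicative on stress; break-strain jitter scales the plateau.
  Cohort defaults follow the five CSA sorts (centers 0.002…0.024 mm²,
  modulus 11→8 GPa, toughness 2→14 MJ m⁻³ with the reported spreads);
  intermediate-sort means are interpolated since only the extreme sorts
  are quoted numerically.
* **FTIR spectra**: sums of Gaussians on a 1 cm⁻¹ grid over
  1400–1750 cm⁻¹ with exact area bookkeeping: a β-sheet component at
  1620 cm⁻¹ carrying the requested area fraction, coil (1652) and turn
  (1680) components splitting the remainder 65/35, plus a 1450 cm⁻¹
  methyl reference band so normalization is exercised.  The turn
  component sits 10 cm⁻¹ clear of the 1690 cm⁻¹ β assignment boundary so
  1%-noise center drift cannot flip its class.  Real spectra differ in
  baseline drift, ATR distortion and side-chain bands; passing the
  recovery tests shows the deconvolution arithmetic is right, not that
  real-sample β fractions are accurate to the same tolerance.

## Amide-I deconvolution details

Spectra are normalized at 1450 cm⁻¹, component centers located as minima
of a Savitzky–Golay second derivative (window 21 points, order 3,
prominence ≥ 5% of the strongest minimum, sub-grid parabolic
refinement), and a band is refused when it does not stand ≥ 10× above
the grid noise.  The fit is bounded least squares over amplitudes ≥ 0,
widths in 3–25 cm⁻¹, and centers within ±2 cm⁻¹ of their
second-derivative positions — the derivative defines *which* components
exist and roughly where; the small bounded refinement removes the
area-misallocation bias of grid-quantized centers (up to 5 β-points on
1%-noise synthetics, < 2 points with refinement).  `center_slack=0`
recovers strictly fixed centers.  β fraction = area share of components
whose centers fall in 1600–1640 or 1690–1705 cm⁻¹ (config-overridable);
fits whose residual exceeds 5% of the band area are flagged, not
silently returned.

## Known limitations

* No thermal motion, solvent, or humidity/temperature dependence; no
  notch fracture mechanics; transverse lattice relaxation is uniform
  plus damped dynamics, not a full minimization.
* The anchor-spring grip is an idealization of a clamped fiber end; the
  end-plane stress concentration it preserves is physical for this
  boundary scheme but is the main reason thin-bundle toughness falls
  short of the published value.
* ε(R) is clamped outside [R1, R2]; bundles thinner than R1 all behave
  like the thinnest calibrated fiber.
* Junction and contact pair modes are provided for exploration and are
  not covered by the headline acceptance checks.
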