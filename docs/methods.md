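# Methods

This note documents the models, conventions and numerical choices behind
`hampkin`, and what its synthetic validation does and does not establish
about real trajectory data.

## The synthetic dimer

`bundle_synth.build_dimer_model` assembles a rigid geometric scaffold of
the CpxA cytoplasmic dimer in 4BIV residue numbering. It is a *stand-in for
the crystal structure*, not a model of its energetics: helices are ideal,
loops are omitted, and no covalent connectivity is implied.

**Helix geometry.** Cα atoms are placed parametrically on a right-handed
helix with rise 1.5 Å/residue, twist 100°/residue and Cα radius 2.3 Å —
textbook α-helix values that reproduce the ≈3.8 Å consecutive Cα spacing.
Backbone N, C and O ride companion helices with fixed cylindrical offsets
(radius, phase, axial shift) derived once from ideal internal coordinates
(φ = −57°, ψ = −47°, ω = 180°, standard bond geometry), so that the
dihedral-based secondary-structure assignment scores the default model as
100% α-helical. One consequence of using 4-Cα end means as helix head and
tail: the measured axis `R = R_h − R_t` carries a small radial offset
(≈0.45 Å) unless `(n−4)·twist ≡ 0 (mod 360°)`; all descriptors use that
measured axis consistently, so the offset cancels out of every exactness
claim below.

**Layout.** The four HAMP helices (built 188–204 and 216–234 per chain;
the extra residue 216 gives residue 217 a φ dihedral) form a parallel
square array of side equal to the HAMP inter-monomer distance (default
8.5 Å, the value typical of the associated dimer; the constructor hits a
requested value exactly because chain B is a translated copy of chain A).
Within a chain the N and C helices run antiparallel. DHp helices are built
as 235–268 and 271–299 — the union of the two published DHp residue
conventions, so both the collective-variable set (235–266/272–299) and the
architecture set (240–268/271–298) resolve. The CA domains are rigid
pseudo-domains: ~30 Cα pseudo-atoms on a deterministic Fibonacci sphere
(radius 7 Å), a real gripper helix (420–430) oriented ≈40° to its
companion DHp helix (235–255; CA\* pairs with helix 1A, CA⁻ with 1B), the
C-helix rotation-anchor residues 313/317/321/325, and marker Cα for N360,
D386 and R363. The CA centers are placed by the inscribed-angle
construction so the HAMP–CA–DHp vertex angles equal the requested values
exactly (defaults 116.6° and 105.5°, the crystallographic architecture,
ratio ≈ 1.1), and N360 is placed so the cross-chain N360–H248 distances are
exactly 25 Å (CA⁻ side) and 13 Å (CA\* side), the autokinase-state values.

Because the scaffold is an idealized parallel bundle, it does **not**
reproduce the splayed helix packing of the crystal structure. In
particular, of the published HAMP inter-monomer restraint sets only the
cross-chain 190/219 distances (bounds 7–11 Å) are satisfied by
construction; the mid-helix (2.2–6.2 Å) and bottom (13–17 Å) bounds encode
crystallographic packing the square array does not have, and the restraint
drivers report them as violated. This is a property of the synthetic
geometry, not of the bookkeeping.

**Motions and ground truth.** A `MotionSchedule` holds per-frame absolute
motions (frame 0 is the identity): per-helix pistons and axial rotations,
a chain-B scissor tilt, and per-chain CA swings. Motions are applied to
the base model per frame, in the order tilt → piston/rotation → swing.
Three constructions make the descriptor round trip exact (≤1e-6; in
practice ~1e-13):

* pistons translate along the *measured* helix axis, and rotations turn
  the helix about the measured axis through the measured center;
* an axial rotation carries the helix's four anchor Cα along. The rotation
  descriptor measures the azimuth of the anchor direction about the helix
  axis, so a rotation of the helix with anchors fixed is invisible to it
  (the anchor vector does not move); the carried-anchor motion is the
  relative helix-versus-anchor rotation the descriptor is defined to read.
  The schedule's sign convention matches the descriptor's sign term:
  schedule +φ is a clockwise turn of the helix–anchor unit about the
  head-to-tail axis;
* the C helix is shifted during construction so the segment joining the
  measured N- and C-helix centers is perpendicular to the measured chain
  axis; the chain-B tilt then rotates about that segment, which leaves both
  helix centers fixed (pistons unaffected) and maps the chain axis exactly
  through the requested angle. Pistons and axial rotations preserve every
  per-helix axis vector, so tilt commutes with them exactly.

CA swings rotate a CA domain about the HAMP center toward the HAMP–DHp
axis (monotonically increasing the corresponding vertex angle); they move
the C-helix anchors and are therefore excluded from exact-recovery claims.

Gaussian positional noise (sd `noise_sigma` per coordinate, default 0.3 Å
— fluctuations at the scale seen for the catalytic domains) is added after
the motions, i.i.d. per atom coordinate and frame; this is the simplest
model satisfying the RMSF closed form σ√3 used in validation. Frames are
emitted in the reference lab frame: the HAMP superposition step of the
descriptor pipeline is then the identity and may be skipped (`fit=False`)
for exact recovery; with `fit=True` the descriptors are exactly invariant
under whole-frame rigid motion (the fitted frame is the same whether or
not a rigid transform was applied first).

**What passing these tests shows.** That the descriptor formulas, their
sign conventions and the statistical machinery are implemented correctly.
The generator does not emulate force-field energetics, solvent, anharmonic
fluctuations, helix unfolding or correlated domain dynamics, so agreement
on synthetic data says nothing about the conformational ensemble of the
real protein — only that measurements on such an ensemble would be
computed correctly.

## Descriptor conventions

* Helix **head** = mean of the four N-terminal Cα, **tail** = the four
  C-terminal Cα (the assignment is configurable; only the signs of piston
  and tilt depend on it).
* The rotation reference vector `R_0c = R_r⁰ − R_c⁰` uses reference-frame
  quantities for both points, so every descriptor vanishes at frame 0. The
  two cross products project both vectors off the current axis; no extra
  projection is applied. The angle is evaluated as
  `atan2(|c₁×c₂|, c₁·c₂)` — identical to the arccos of the normalized dot
  product but conditioned well near 0° and 180°.
* For the tilt, within each chain the C-helix axis is flipped into the
  hemisphere of the N-helix axis before averaging heads and tails
  (antiparallel helices would otherwise cancel to a degenerate axis).
* Three HAMP residue presets are shipped verbatim and never unified:
  collective-variable set 188–201/219–234, descriptor set 189–204/217–232,
  distance/helix-content set 189–203/217–231. Rotation anchors are
  chain-matched: 283/287/291/295 for N helices, 313/317/321/325 for C
  helices.
* α-helix assignment: φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°] with a minimum
  run of three consecutive residues; terminal residues lacking a dihedral
  are non-helical. A dihedral rule avoids hydrogen placement.
* Domain centers are unweighted Cα means. Resolution is tolerant — a
  domain uses the Cα present within its stated ranges and errors only when
  a range resolves to nothing — because the synthetic CA domain is a
  sparse pseudo-atom cloud and the architecture span 305–453 exceeds the
  built 306–452.
* "Heavy atoms of the protein backbone" = N, Cα, C, O. Residue numbering
  is 1-based PDB throughout; insertion codes are rejected; alternate
  locations resolve to the highest occupancy. Superpositions are proper
  rotations only. Trajectories without stored times assume 10 ps frame
  spacing.

## Restraints

Flat-bottom harmonic distance restraints: zero inside [lower, upper],
½k(d − bound)² outside the nearest bound — continuous with continuous
first derivative at both bounds. The printed force-constant unit is
interpreted as kcal/(mol·Å²) (dimensional necessity for a harmonic
distance term). Ambiguous groups combine pair distances as
`d_eff = (Σ d_k⁻⁶)^(−1/6)` (standard ambiguous-distance treatment; always
≤ the minimum pair distance; a min-distance mode is available) and count
once per frame in violation statistics. "Interval increased by 10%" widens
each side by 10% of the interval width; a mode scaling each bound by 10%
is available by flag. Dissociation intervals are maximal runs above the
3 Å threshold; runs shorter than `min_duration` are dropped, and a series
with under 5% of frames above threshold and no surviving run is flagged as
showing only isolated dissociation events.

## The sampling engine

Units are kcal/mol, Å and ps; thermal energies are given directly in
kcal/mol (k_B folded in). Physical defaults: κ = 100 kcal/(mol·Å²),
γ = 0.5 ps⁻¹, β⁻¹ = 0.6 kcal/mol (300 K); artificial thermal energies of
15–20 kcal/mol are the acceleration regime.

* The x-equation is integrated with the BAOAB Langevin splitting (stable
  at the 2 fs-equivalent step on the toy systems; velocity equipartition
  holds within ~1%). The z-equation has no inertial term and uses
  Euler–Maruyama.
* The CV friction γ̄ formally carries energy·time/unit²; a value quoted in
  ps⁻¹ is accepted by an implicit unit factor of 1 (kcal·ps²)/(mol·Å²).
  The all-atom calibration outcome 0.02 ps⁻¹ is kept as a preset constant;
  the toy-system default is γ̄ = 50 (double well) or 10 (harmonic
  analyses), chosen so the targets move slowly against each system's
  physical relaxation while still sampling within the run lengths below.
* `calibrate_gamma_bar` reports the running average of the restraining
  force per CV with the targets held fixed, plus the standard deviation of
  its last quarter as a convergence diagnostic; the acceptance threshold
  for "calibrated" is left to the user. For a harmonic well of stiffness
  k_w displaced by δ the limit is −k_w κ δ/(k_w + κ), the closed form used
  in validation.
* `free_energy_estimate` is a histogram inversion, F = −β̄⁻¹ ln p(z) with
  the minimum shifted to zero; empty interior bins are masked with a
  warning. For the harmonic well the marginalized curvature is
  k_w κ/(k_w + κ), recovered within ~10% at the run lengths used.
* Geometric-center collective variables (Jacobian 1/N per member atom) are
  supported natively; `hdc_cv_groups` builds the ten-center H/D/C set of
  the dimer (four HAMP helices, four DHp helices, two CA domains — 30
  scalar components). The coarse elastic-network surrogate (springs
  between Cα pairs within 10 Å of the reference conformation, optional
  flat-bottom restraints) stands in for all-atom dynamics at desk scale;
  it makes no claim of reproducing all-atom sampling.
* Problem sizes: the validation suite uses 10⁶-step double-well runs
  (5 seeds × 2 artificial temperatures), a 6×10⁶-step harmonic variance
  run, 200 ps calibration runs and a 2×10⁶-step free-energy run. These
  lengths put the statistical error of each estimate comfortably inside
  its stated tolerance (e.g. the z-variance estimator decorrelates every
  ~5 ps, giving ~3% sampling error). The 1-D identity-CV systems use a
  scalar fast path of the same integration scheme.

## Joint distributions and maxima

Default density: 2-D histogram with Scott-rule bin counts
(h = 3.5σn^(−1/4) per axis) on a grid covering the data plus 2.5% of the
span on each side; a Gaussian KDE (Scott bandwidth) is optional. Local
maxima are grid cells exceeding all eight neighbors and a prominence floor
(default 0.2 of the global maximum); for histograms the peak search runs
on a one-cell Gaussian smoothing so counting noise does not fragment a
mode, and maxima within one bandwidth are merged, highest kept. The
maxima-trend summary reports the Spearman correlation between the
parameter and ratio coordinates of the maxima; with fewer than three
maxima no trend is claimed. Any prominence threshold is a convention — the
"bullets" of published contour maps are not defined algorithmically.

## Known limitations

* The synthetic scaffold is rigid and idealized: no loops 205–215, no side
  chains beyond marker Cα, no ATP (synthetic ATP contacts are scripted
  pseudo-atom distance series only), no membrane or solvent.
* Trajectory-averaged observables of real all-atom runs (domain RMSDs,
  inter-monomer distance drift, helix unfolding, ATP dissociation times)
  are outside what the generator emulates; the package computes them from
  any trajectory it is given but validates them only on constructions with
  known answers.
* The crystal structure itself is not bundled; the default model carries
  its published architecture parameters by construction, which validates
  the measurement pipeline as a round trip, not the published values.
* The rotation descriptor is undefined (ill-conditioned error) when the
  anchor direction is within ~1e-6 rad of the helix axis.
* Combined schedules mixing chain-B tilt with chain-B axial rotations in
  the same frame are recovered to ~1e-5 deg rather than 1e-13 (the tilted
  axis slightly re-orients the anchor cross products); per-family
  schedules are exact.
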