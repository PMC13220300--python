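# Methods

Units are Å and Å⁻¹ throughout; intensities and spectral amplitudes are in
arbitrary units. All randomness is seeded explicitly; every stochastic
routine is a pure function of (parameters, seed).

## Cross-section model: hard disks with a sheath

Cellulose microfibrils are treated as parallel, infinitely long cylinders;
in cross-section they are disks of physical radius *R* (default 13.5 Å, the
18-chain fibril) carrying a non-penetrating sheath, so that two fibril
surfaces never approach closer than a minimum separation *sep* (default
4.7 Å, roughly one polysaccharide chain thickness). Packing statistics are
therefore those of hard disks of effective radius *R\_e = R + sep/2*
(15.85 Å) at effective area fraction φ\_eff = φ\_phys·(R\_e/R)² (29% →
39.98%). The model assumes no attraction or repulsion beyond the hard core
— positions are an equilibrium hard-disk fluid.

**Monte Carlo protocol.** Random sequential addition seeds the box (side
*L = R\_e·√(nπ/φ)*); above φ\_eff = 0.52 a dilute start plus a gradual
box-compression schedule is used instead, since RSA jams near 0.55. The
packing is then relaxed by Metropolis sweeps (one sweep = *n* single-disk
trial moves, uniform displacement in [−δ, δ]², rejected on any overlap);
δ is auto-tuned every 10 sweeps toward 30–50% acceptance and capped at
*L*/4. Defaults: 2000 disks, 2000 equilibration sweeps, snapshots every
10 sweeps. Overlap tests use periodic minimum-image distances with cell
lists (cells ≥ one diameter wide). All protocol choices are recorded in the
configuration metadata. Hard-disk dynamics have no temperature scale;
acceptance is purely geometric.

**Caveat on snapshot correlation.** Successive snapshots 10 sweeps apart
are well decorrelated at liquid-like densities (typical displacement per
interval ≈ √10·δ ≈ *R\_e*), but in the near-ideal-gas regime δ must first
grow to its cap before the standard-error estimates from snapshot scatter
are honest; the dilute control tests therefore equilibrate longer.

## Structure factor

g(r) is the periodic pair histogram normalised by the ideal-gas expectation
(with the (n−1)/n finite-N factor), averaged over snapshots; the snapshot
scatter provides per-bin standard errors. S(q) follows from 2D liquid-state
theory,

S(q) = 1 + 2πρ ∫₀^rmax (g(r) − 1) J₀(qr) r dr,

with a raised-cosine taper over the outermost 20% of r to suppress
truncation ringing, and q < 2π/L rejected as probing beyond the box. An
independent oracle — direct summation S(q) = ⟨|Σ exp(iq·r)|²⟩/N over
reciprocal-lattice-compatible wave vectors — is used in tests; the two
routes agree within combined statistical errors.

The tabulated S(φ, x = qR\_e) surface is built from one simulation per φ at
*unit* effective radius (so the x axis is dimensionless and one table
serves any *R\_e*), interpolated by a bicubic spline (s = 0: node values
reproduced exactly; lower order automatically when the φ grid is short; a
single-φ table interpolates in x only and accepts only that φ). Queries
outside the grid raise; no extrapolation. The φ = 0 row is the analytic
ideal-gas value 1.

**Tail behaviour.** Pointwise S oscillates around 1 with period ≈ π in x
and amplitude ≈ 3% at x = 20 for φ = 0.40 — genuine hard-disk physics, not
noise. The "S → 1 at large q" acceptance property is therefore asserted on
the tail averaged over one oscillation period, which removes the
oscillation and isolates the decay of correlations.

## Proximity shells

A square lattice (default spacing 1 Å; results identical at 0.5 Å) is laid
over the box; lattice points outside every physical disk form the matrix
phase. For each distance d the reported quantity is the fraction of matrix
points whose distance to the nearest disk *surface* is ≤ d. At the default
geometry the converged values are 41.9% (6 Å) and 66.7% (10 Å), stable
under 5× longer equilibration, finer lattices, doubled system size, and
*R\_e* = 15.85 vs 15.9 Å.

## SAXS fitting

The composite intensity is linear in scale A and background B, so each
candidate radius in the scan needs only an ordinary least-squares solve
(A clipped at 0; B refit alone if clipped). Goodness is the sum of squared
log₁₀-intensity residuals on Lorentz-corrected (I·q) curves over a q window
of 0.05–0.7 Å⁻¹ — the double-log, Lorentz-corrected comparison that
practitioners judge by eye, made numeric. Below 0.05 Å⁻¹ surface scattering
(c·q⁻³) dominates; when the data extend there, c is fitted by closed-form
projection on 0.01–0.05 Å⁻¹ and subtracted before scanning, rather than fit
jointly — the two regimes are physically distinct. No σ-weighting by
default; σ columns are carried through but optional.

On synthetic truth the scan recovers the generating radius exactly without
noise and in ≥95% of seeds at 3% multiplicative noise on the paper-style
grid 13–15.5 Å in 0.5 Å steps. A green recovery test establishes that the
estimator is consistent on data drawn from its own model family — not that
any particular experimental curve is described by that family.

## WAXS analysis

Pseudo-Voigt peaks, amplitude·[η·L + (1−η)·G] with unit-height components
sharing one FWHM, are fitted by bounded nonlinear least squares (η ∈ [0,1]
initialised at 0.5, linear background, window 0.8–2.0 Å⁻¹). Scherrer size
is implemented as L = 2πK/B with B the FWHM in Q-space and K = 0.90. (The
familiar form K·λ/(β·cos θ) reduces to exactly this once widths are
measured in Q; a formula carrying an explicit λ together with a Q-space
width is dimensionally inconsistent, so the wavelength, 1.542 Å, is kept in
metadata only.) d-spacings are 2π/q. Note the Scherrer size of a ~31 Å
crystallite exceeds the fibril diameter expectation; the package computes,
it does not reinterpret.

## NMR quantitation

Trapezoidal integration on the native ppm grid, boundaries by linear
interpolation, no baseline correction by default (the synthetic data are
baseline-free; a per-region linear baseline can be added upstream).
Default regions: reference 0–200, aromatic 110–170, sugar 60–110,
C1 100–110, two-fold C4 80–90 split at 86 ppm into interior (>86) and
surface (<86), methoxy 50–60, acetyl CO 170–180 and CH₃ 15–25 ppm.

Conformer arithmetic: the 2-fold backbone share is C4(80–90)/C1; the
xylan-specific share assumes all cellulose is 2-fold, giving
(overall − cellulose)/(1 − cellulose) — with the default 6:4
glucose:xylose split this yields 0.583, presented as "60%" style rounding
upstream. The acetylation degree divides a configurable xylan residue
fraction (default: C1 × xylan share) by the acetyl fraction; zero acetyl
returns an infinite-degree sentinel rather than raising.

Cross-peak classes: >4% strong, <2% weak, boundaries 2.0% and 4.0%
inclusive to medium (the boundary policy is a stated convention; the class
bands of the generator keep a 0.05-point margin so round trips are
unambiguous). Chord weights 3/2/1 are summed per (source component, sink
component) using an editable site→component map covering interior/surface
cellulose, 2-/3-fold xylan, arabinose, acetyl, and lignin S/G/H/FA/OMe
carbons; unmapped labels raise with the offending list.

Relaxation fits are single exponentials (decay I₀e^(−t/T); inversion
recovery I₀(1−2e^(−t/T)), the convention recorded in diagnostics) via
bounded `curve_fit`; exact on clean data for T ∈ [0.1, 50] s. HSQC S:G:H
proportions halve the S2/6 and H2/6 integrals (two equivalent C–H pairs).

## Wall stoichiometry

Per 18 glucose: xylose and arabinose scale by sugar molar ratios; lignin
monomers from the carbohydrate:lignin mass ratio (65:20 default) at
211 g/mol per C9 unit (1:1 S:G mean — configurable, never printed by
composition assays); water from dry-basis moisture (30%) over the
carbohydrate + lignin mass. The defaults give 12.57 xylose, 1.36
arabinose, 6.94 lignin and 103.6 water. The water count is sensitive to
which dry-mass convention is used (adding the ~15% unassigned wall mass
raises it to ~122); the package states its convention and reports exact
values alongside half-up-rounded presentation integers.

Fibril radius from chain count: area = n·m/(rise·ρ·N\_A) with rise
5.19 Å/residue (half the cellulose Iβ c-axis repeat) and ρ = 1.6 g/cm³ →
13.63 Å for 18 chains, consistent with the 13.5 Å scattering radius at the
0.5 Å scan resolution. Volume fractions use default densities (cellulose
1.6, hemicellulose 1.5, lignin 1.35, water 1.0 g/cm³ — package defaults,
configurable) and always sum to 1.

The schematic layout scatters matrix beads (xylose-equivalent 3 Å, water
1.9 Å) uniformly in the inter-fibril space, rejecting bead–disk overlap
only — it conveys crowding, not a packing. The rendered water count per
fibril (60) is lower than the stoichiometric 110, reflecting water's lower
linear density along the fibril axis; both numbers are kept in the record.

## Synthetic data: what a green test establishes

Generators emulate the statistical structure each stage assumes:
lognormal multiplicative noise for SAXS (decade-spanning counts, double-log
comparison), additive Gaussian for WAXS and NMR (linear plotting). The 1D
spectrum preset is a sum of Gaussian lines whose analytic areas equal the
stated region fractions (aromatic 12%, sugar 76% with C1 12% and two-fold
C4 10% split 38/62, methoxy 4%, acetyl 2+2%, 4% aliphatic filler), with
every line ≥3σ inside its region boundaries (spill < 0.5% of any region).
They do not emulate: baseline drift and phasing errors, peak overlap across
region boundaries, resolution smearing, detector artefacts, or any physics
outside the fitted model family. Round-trip tests therefore establish
estimator correctness and self-consistency, not the validity of the model
for a particular experimental sample.

## Known limitations

* 2D monodisperse hard disks only: no polydispersity, no attractive terms,
  no 3D packing, no event-chain/cluster moves.
* The equilibrium shell fractions at the default geometry (41.9%/66.7%)
  sit about one percentage point below commonly quoted 43%/68% figures for
  this construction; unpublished protocol details (system size, sweep
  budget, lattice) plausibly account for the difference.
* No instrument resolution/smearing in the scattering model; no absolute
  intensity calibration; WAXS background is linear over the fit window.
* NMR quantitation consumes already-extracted 1D profiles and cross-peak
  tables; peak picking and 2D lineshape deconvolution are out of scope.
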