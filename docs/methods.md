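# Methods

`gjpore` analyses ion permeation through gap-junction channels (GJCs):
dodecameric channels built from two docked hexameric hemichannels (HCs)
spanning two apposed membranes. The package takes static structures and
MD trajectories of such channels and computes the quantities a
permeation study reports: axial ion densities, free-energy (PMF)
profiles, permeation-event statistics, pore-radius profiles and
N-terminal-domain (NTD) gate states. Every stage is validated against a
synthetic Brownian-dynamics generator with analytic ground truth.

## Coordinate and unit conventions

Lengths in Å, times in ps, temperature in K, voltage in mV, energies in
kcal/mol. All analyses run in an *axis frame*: origin at the junction
midplane, z along the pore (diffusion) axis, increasing from the HC1
cytosol toward the HC2 cytosol. For a structure, the axis is the
largest-variance principal axis of the atom cloud (a two-membrane
channel is longest along its pore), with the sign fixed by declaring
which chains form HC1; without that declaration the orientation is a
convention and downstream quantities are symmetric in it.

Conversions are centralized in `gjpore.constants`:
R = 1.9872×10⁻³ kcal/(mol·K), 1 e·mV = 2.30605×10⁻² kcal/mol. The
default temperature is 303.15 K (the production-thermostat setting of
the simulations this pipeline targets).

## Constant-field voltage setup

A transjunctional voltage V across a periodic box of axial length L_z
is a uniform field E_z = V/L_z (mV/Å), applied to each ion's charge.
`compute_net_charge` counts Lys/Arg as +1 and Asp/Glu as −1 with His
neutral (neutral-pH protonation), plus ±1 for charged termini. For the
twelve modelled Cx43 chains (two fragments each, residues 2–105 and
151–235; chain-break termini treated as charged by default) this gives
+36 e, matching the 36-anion counterion excess of the solvated system.

## Density grid and axial profiles

Ions of one species within a cylinder of radius 10 Å around the axis
are binned each frame onto a 3D grid with 1 Å voxels (half-open on the
low edge; an ion exactly on the cylinder boundary is included) and
averaged over frames, so the grid total equals the mean in-cylinder ion
count — an invariant asserted in the tests. The axial profile ρ(z) sums
each z-slab. Densities use wrapped coordinates; event detection (below)
uses per-ion minimum-image unwrapped z, which requires per-frame
displacements below box_z/2. Replicates are combined as per-bin mean
and sample SD (n−1) — the "fluctuation" bars; SEM or time-block
alternatives were not used because the replicate count (≥2 per
condition) is the natural unit of independence here.

## Free-energy profiles

Boltzmann inversion: ΔG(z) = −RT ln(ρ(z)/ρ_ref), with ρ_ref the mean
density over a bulk reference band (default: the outer 10 Å at each end
of the profile) so the bulk plateau is zero; the raw logarithm has a
unit-dependent offset and published profiles plateau at zero in bulk.
Bins with ρ = 0 are flagged undefined, never ±∞, and barrier extraction
skips them. The density uncertainty propagates to first order as
σ_ΔG = |RT σ_ρ/ρ|; since σ_ρ is the across-replicate SD, σ_ΔG estimates
the replicate-to-replicate spread of ΔG, which is what the bootstrap
check in the acceptance suite measures. Barriers are the maximum
defined ΔG in a window, ties broken toward smaller |z|.

## Permeation events

Three boundary planes (HC1 cytosolic boundary, midplane, HC2 cytosolic
boundary) split the axis into four stations. Each plane carries a
hysteresis band of half-width h (default 2 Å): an ion is confirmed in a
station only outside every band, so thermal re-crossings inside a band
count nothing. An HC event is a confirmed traversal between the two
planes bounding that hemichannel (either direction); a GJC event is a
continuous cytosol-to-cytosol passage and by construction also contains
one HC1 and one HC2 traversal. Ions that start inside a compartment
produce no event before their first confirmed station. Jumps over more
than one station between samples are expanded at interpolated times, so
coarse sampling cannot silently drop traversals. The event semantics
(full half-channel traversals; both directions counted) are this
package's definition — published event tables rarely state a detector —
and a direction filter is available downstream. Replicate summaries
report mean ± sample SD of per-replicate counts keyed by applied
voltage, compartment and species.

## Pore radius

Two definitions are provided and agree within one voxel on convex
fixtures:

* **Sphere insertion** (static structures): at each z, the radius of
  the largest probe sphere centred in that plane clearing all atom vdW
  spheres, r(z) = max_c min_i (|c − x_i| − vdW_i), maximized by
  deterministic multi-start Nelder–Mead (default 8 seeded starts,
  0.5 Å z-step) with the probe centre confined within 5 Å of the axis —
  an unconstrained ascent escapes the pore laterally at open planes.
  Planes whose optimum reaches 30 Å are capped and flagged unbounded
  (bulk/vestibule), mirroring HOLE's capping. Simulated annealing was
  not needed at this step size.
* **Voxel emptiness** (trajectories): per frame and z-slab, a voxel is
  empty iff no heavy-atom centre lies within its vdW radius of the
  voxel centre (closed boundary: exactly-at-distance occupies). Only
  the empty region 4-connected to the axis counts as lumen; A(z) =
  N·s², r(z) = √(A/π), reported as time mean ± SD. Hydrogens are
  ignored: the grid resolution is 1 Å and deposited models are
  heavy-atom.

vdW radii are Bondi-style per element (H 1.20, C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80, K 2.75, Cl 1.75; generic pseudo-atom X 1.50); unknown
elements raise rather than defaulting silently.

## Superposition and gate states

Kabsch superposition is the closed-form SVD solution restricted to
proper rotations (det +1). Region RMSD "without refitting" superposes
on a global selection and measures the region under that transform (the
rms_cur-style number); homologue comparisons pair residues by
user-supplied ranges and atom name, not automatic alignment. Per-chain
traces fit each frame on a core selection, then measure each chain's
NTD without refitting; states are classified as closed (< 3 Å),
intermediate, open (≥ 6 Å), boundaries to the higher state. The
thresholds are configuration, not measurements — published state
colourings rarely print them — and outputs carry them alongside the
trace. A fragment-based (CE-style) aligner is not implemented;
sequence-order Cα pairing can differ from fragment aligners by design.

## Synthetic generator

Non-interacting ions follow overdamped Langevin (Euler–Maruyama)
dynamics: z ← z + (D/kT)F dt + √(2D dt) ξ with F = −dU/dz + qE_z, pure
diffusion in-plane, a reflecting radial wall, periodic z. Defaults:
D = 0.2 Å²/ps (aqueous K⁺/Cl⁻ scale), dt chosen so √(2D dt) ≲ 0.3 Å
(a warning fires above 1 Å). U(z) is flat or a sum of Gaussian
barriers; the stationary density is the Boltzmann distribution of
U − qE_z·z·(conversion), which makes density, PMF and event stages
testable against analytic truth. `init="equilibrium"` draws starting
positions from that target by rejection sampling so desk-scale runs
need no burn-in; `n_equil` adds explicit burn-in steps otherwise.
Identical seeds give bit-identical trajectories; replicate k uses
seed + k.

What the generator does *not* emulate: ion–ion and ion–protein
electrostatics, explicit water/lipids, protein dynamics (walls are
static; conformational tests use scripted displacements). Passing
tests therefore validate the *analysis* code — binning, inversion,
counting, geometry — not force-field realism.

## Validation problem sizes

Chosen for ≈1 min of total generator time on one CPU: PMF recovery
uses 2000 independent ions for 5000 ps sampled every 50 ps (2×10⁵
ion-frames per barrier; samples 50 ps apart are nearly independent at
D = 0.2 Å²/ps); barrier heights are estimated by density-weighted
projection of the inverted profile onto the known barrier shape, which
uses every informative bin instead of the noise-biased maximum bin.
The error-propagation check uses 18 replicates; the Einstein-drift
check 500 ions for 22.5 ns with 50 ps sampling (shorter strides keep
minimum-image unwrapping exact); field-response monotonicity uses 20
replicates at three field strengths with a one-sided Welch test at 95%.

## Known limitations

* The pore centreline is assumed straight on the symmetry axis; no
  curved/spline centreline.
* The sphere-insertion probe-centre bound (5 Å) must be widened for
  channels whose lumen wanders off-axis.
* Event detection cannot recover paths that alias through the periodic
  boundary between samples (per-interval |Δz| must stay below box_z/2).
* No WHAM/umbrella machinery, conductance estimation, kernel smoothing
  or 2D (r,z) free-energy surfaces.
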