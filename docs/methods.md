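# Methods

## Model

`dipscreen` treats a lipid bilayer as a static random lattice of point
dipoles and a surfactant as a single point dipole on a Stokes sphere
moving through the lattice's conservative field.  The purpose is ranking
— which agent/lipid pairings carry entry barriers, interfacial minima and
net translocation cost — not a Boltzmann-weighted potential of mean
force.  The recorded profile is the engine's energy bookkeeping along a
dynamical path, and is compared with MD free-energy profiles only
qualitatively.

### Membrane generation

For a lateral box lx × ly and area per lipid APL, each leaflet carries
⌊lx·ly/APL⌋ sites (80 × 80 Å at APL 64 Å² gives the 200-lipid reference
bilayer, 100 per leaflet).  Sites sit on a centered square lattice of
spacing √APL; the lattice is identical across seeds so run-to-run
variation isolates the dipole draws.  Per site, each dipole component is
drawn from a normal law with the per-lipid mean and SD (untruncated by
default; clipping at ±1 SD is available).  The lower leaflet's z
component is sign-flipped so the bilayer is mirror-symmetric; a
uniformly-polarized slab (`flip_lower=False`) is available.  The leaflet
planes sit at ±20 Å by default — a typical phosphate-plane distance for
POPC/POPG — and both the dielectric and the viscosity switch at that same
|z| (boundary itself counted as water).

Built-in dipole statistics (Debye, per axis) and agent parameters:

| species | X | Y | Z | other |
|---|---|---|---|---|
| PC  | 0.34 ± 11.29 | −0.37 ± 11.39 | 1.65 ± 8.44  | APL 64 Å² |
| PG  | 0.14 ± 10.17 | 0.29 ± 10.09  | −35.08 ± 8.29 | APL 64 Å² |
| OCT | 0.69 ± 7.08  | 2.12 ± 8.14   | −0.51 ± 12.78 | m = 623.84 g/mol, logP = 9.25 |
| CHX | 2.74 ± 15.46 | 2.21 ± 10.37  | −0.55 ± 10.25 | m = 505.452 g/mol, logP = 5.48 |

The agent uses its per-axis mean vector as a fixed dipole.

### Interaction and media

The pair term is the scalar product form
E = (**μ**ᵢ·**μ**)/(4πε₀ ε_r r³); the orientation factor
−3(**μ**ᵢ·r̂)(**μ**·r̂) of the full tensor is deliberately omitted from
the default model (the agent is treated as a freely tumbling point mass);
the full tensor is implemented behind `orientation_term=True` for
comparison.  ε_r is taken from the agent's z (88 water / 4 membrane), one
value per evaluation.  The patch is finite: no periodic images, so the
default 80 Å box keeps edge effects small.  Energies are SI per molecule
internally and kcal/mol on output.

**Contact clamp.**  The bare 1/r³ term diverges as the agent passes a
lattice site.  Site–agent distances are clamped at 4 Å in all energy and
force evaluations (force zero inside the clamp, where the clamped energy
is flat).  The value is a molecular contact distance — both the agent and
a lipid headgroup are whole molecules, so sub-contact separations are
geometrically meaningless — and it bounds single-site energies to the
few-kcal/mol scale of the physical problem.  With a much smaller clamp
the dynamics ends in an unphysical permanent orbit on the clamp sphere of
the first attractive site, recording energies two orders of magnitude
beyond anything physical.

### Propagation

The two-step recurrence is implemented as printed in its source
formulation: position from rₙ₋₂ and vₙ₋₁, velocity from vₙ₋₁, the force
at the fresh position, and a Stokes drag term −(b/m)v·2Δt with
b = 6πηR (R = 10⁻¹⁴ m nominal — far below molecular size, but it enters
only through the drag magnitude and is kept as given).  One update spans
2Δt; `n_steps` counts updates, so the default Δt = 1 fs, n = 5×10⁵ run
spans 1 ns.  The recurrence is bootstrapped from a single state
(r₋₁ = r₀, v₋₁ = v₀).  In drag-free, cap-free runs the integrator
conserves E_p + KE to ~10⁻⁶ of the energy scale on smooth paths (under
test); near-site passages show the usual bounded leapfrog oscillation.

**Kinetic-energy rule.**  Three modes:

* `cap` — the literal k_BT limit: if mv²/2 > k_BT, rescale the speed to
  √(2k_BT/m).  This only removes energy; starting from rest a capped
  particle can never climb a barrier above k_BT ≈ 0.6 kcal/mol, so a
  membrane with a repulsive mean field (PG against either reference
  agent) is never entered at all.
* `hold` (default) — the speed is rescaled to √(2k_BT/m) every update, up
  or down: a crude isokinetic thermostat.  This is the only rule in the
  model's vocabulary under which every run traverses the bilayer the way
  the engine's published trajectories do (consistent start and end points
  for all four agent/lipid systems, including barrier climbs of ~3
  kcal/mol), and it makes the recorded Hamiltonian exactly
  E_p + k_BT along the path.
* `off` — for integrator checks.

With `hold`, the agent starts at the lateral box center, z = 45 Å, moving
toward the membrane at the thermal speed (89.4 m/s for OCT).  There is no
stochastic force: each trajectory is a deterministic function of the
membrane seed, and all replicate variation comes from membrane
generation.

Runs end after `n_steps` updates, when z ≤ 0 (`stop_at_core`, default
on), or abort with a diagnostic if the agent leaves a 10× box envelope
(e.g. deflected back into bulk, where nothing recalls it); aborted runs
keep their partial trajectory and still contribute their sampled bins.

### Free-energy bookkeeping

H = E_p + min(mv²/2, k_BT); ΔG accumulates H_B − H_A per update from the
start state.  On a water↔membrane crossing, ±ΔH_transfer with
ΔH_transfer = ln(10)·R·T·logP can be added (`transfer_sign = +1/−1`,
antisymmetric so enter-then-exit cancels).  **Default: transfer_sign = 0**
— the crossing term is excluded from the recorded profile and the
transfer enthalpy is reported as a separate scalar.  Rationale: for the
reference agents ΔH_transfer is 12.70 (OCT) and 7.52 (CHX) kcal/mol,
while every published engine profile shows features of at most ~3
kcal/mol, interior minima ~1.3 kcal/mol above bulk, and near-equal net
values for the two agents; a ±7–13 kcal/mol step at the boundary is
arithmetically incompatible with those profiles under either sign.  The
published profiles are therefore reproducible only with the crossing term
absent from the recorded ΔG, and that is the default here.

The cumulative ΔG is binned by agent z (0.2 Å bins, the ABF convention),
bin value = mean of samples in the bin, profile re-zeroed at the bin
containing z_start.  Replicate screens average per bin over the runs that
populated the bin (≥ 2 required), with a per-bin sample SD.  Features are
extracted from the 3-bin-smoothed profile with `scipy.signal.find_peaks`
(prominence ≥ 0.05 kcal/mol to ignore single-bin noise); barrier heights
and minimum values are measured from the bulk reference and positions
reported as |z|.  ΔG_trans = ΔG_core − ΔG_bulk requires a populated bin
within 1 Å of z = 0; otherwise the result is explicitly "core not
reached", never zero.  When a queried region holds no local maximum, the
headline selectors fall back to the region's maximum value above bulk (a
profile that never rises has a ~0 barrier — a measurement, not a missing
value).

## What the generator emulates, and what it does not

Replicate membranes emulate the lipid-dipole disorder seen across MD
snapshots: per-site dipoles fluctuate with the MD-derived SDs, which for
PC are an order of magnitude larger than the means.  The generator does
not emulate lateral lipid diffusion, membrane elasticity or undulations,
explicit water or ions, lipid mixtures, or any response of the membrane
to the agent — the lattice is frozen per run.  Passing tests therefore
show that the engine's bookkeeping and statistics behave as specified on
this idealized ensemble, not that the profiles match experiment.

## Known limitations

* Net translocation values are near zero by construction: the bookkeeping
  telescopes to H(end) − H(start), the mirrored bilayer makes E_p at the
  core nearly cancel, and the isokinetic rule fixes the kinetic term, so
  ΔG_trans measures the small core/bulk field difference (~0.0–0.1
  kcal/mol) rather than the ~1.6–3.5 kcal/mol net costs the engine's
  published runs report.  Those published nets are not derivable from the
  printed bookkeeping equations under any crossing-term sign; this
  implementation keeps the equations and accepts the discrepancy.
* Averaging profiles across seeds flattens barriers whose position varies
  seed-to-seed; per-replicate feature statistics (also exposed in
  `ScreenResult`) run systematically higher than mean-profile features
  and are the better measurement when positions wander.
* Neutral-membrane (PC) runs usually park in the attractive
  carbonyl–glycerol region and are eventually deflected back to bulk;
  interior PC bins are then sampled by a minority of replicates.
* The sharp ε_r step at |z| = h makes energies exactly 22× larger one bin
  inside the boundary than one bin outside; a 2 Å sigmoid switch is
  available (`field` module) but off by default.
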