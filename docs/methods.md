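# Methods

## The model

Passive transport of a single permeant across a symmetric bilayer with
normal z is treated with the inhomogeneous solubility-diffusion (ISD)
model. The permeant's free energy dG(z) and local diffusion
coefficient D(z) vary along the normal (z = 0 at the bilayer center of
mass); the local partition coefficient is K(z) = exp(-dG(z)/RT) with
the bulk-water reference dG = 0, the local resistance is
R(z) = 1/(K(z)·D(z)), and the permeability follows from
1/P = ∫ R(z) dz across the sampled span. With K ≡ 1 and D ≡ D₀ over a
thickness d this reduces to the homogeneous limit P = D₀/d, which the
code reproduces to machine precision and the tests pin down.

Both inputs come from constrained-ensemble force statistics. At each
window (fixed particle–bilayer COM separation z) the recorded
constraint force F(z, t) gives

- the mean force ⟨F⟩(z), integrated (negative sign, trapezoid) to
  dG(z);
- the force-fluctuation autocorrelation, whose time integral gives
  D(z) = (RT)² / ∫₀^∞ ⟨δF(t) δF(0)⟩ dt.

Windows cover one leaflet, 0 ≤ z ≤ z_max; profiles are mirrored about
z = 0 before the permeability integral, reflecting bilayer symmetry.

## Estimators and numerical choices

**Equilibration discard.** Each window drops the leading 60% of its
series by default (the constrained-protocol convention of discarding
120 ns of a 200 ns window), configurable per run.

**Mean-force errors.** Standard errors come from block averaging with
doubling block lengths, stopping at an SE plateau (successive change
< 5%) or when fewer than two blocks would remain. On exact
Ornstein–Uhlenbeck input the block SE reproduces the analytic
√(2σ²τ/T) within 20%.

**dG uncertainties.** Window means are treated as independent; the
trapezoid weights between each grid point and the reference propagate
their SEs exactly.

**ACF integration cutoff.** The autocovariance (biased 1/n estimator,
FFT-based) is integrated by trapezoid up to its first zero crossing.
If no crossing occurs within 10 estimated correlation times (first
1/e crossing of the ACF), the integral is truncated there and closed
with an exponential tail c(t_cut)·τ. This is unbiased for OU-like
fluctuations and robust to noisy tails. Per-window D errors come from
re-estimating D on five contiguous sub-segments. Windows with a
non-positive ACF integral are flagged unusable and their D is filled
by linear interpolation from neighboring windows.

**Quadrature.** Trapezoid everywhere, matching the uniform 0.2 nm
window grid; no spline smoothing. The permeability integral defaults
to the full symmetrized span — for neutral hydrophobic particles much
of the resistance sits in the water phase, so truncating at the
bilayer faces would discard real resistance — with a "bilayer-only"
±d/2 bounds option exposed.

**Permeability uncertainty.** A parametric bootstrap at the window
level: per-window mean forces and diffusion coefficients are resampled
within their standard errors and the entire dG → K → R → P chain is
rebuilt per draw (200 draws by default). The bootstrap label is kept
in the output record since other conventions (block, leaflet
difference) exist.

**Constants.** R = 8.314462618×10⁻³ kJ·mol⁻¹·K⁻¹; T defaults to the
skin temperature 310 K; 1 nm/ps = 10⁵ cm/s.

## Synthetic data: what it emulates and what it does not

Real constraint forces fluctuate around a z-dependent mean with an
approximately exponential memory. The generator reproduces exactly
that structure: a stationary OU process sampled by its exact AR(1)
discretization (coefficient e^(−dt/τ)), so generated autocovariances
are exact at all lags and recovery tests carry no discretization bias.
A window set couples the OU means to an analytic free-energy shape
(mean force = −dG'(z)) and solves each window's variance from a target
diffusion profile via σ² = (RT)²/(D τ) with a single global τ (1 ps
default, 0.1 ps sampling, both stated as package defaults rather than
protocol values), keeping the mapping identifiable.

Window placement follows the pulling protocol: storage every 0.2 nm
from z_max = 8 nm down to and including the bilayer center, giving 40
windows with the first stored window at 7.8 nm.

Three analytic shapes cover the phenomenology: flat (bulk), a Gaussian
interior well (neutral hydrophobic particles), and a headgroup minimum
with a positive interior barrier (charged particles). All are even in
z and tapered smoothly (a (z/z_max)² correction) to vanish exactly at
z_max. Study-condition presets pair deepening wells (70–350 kJ/mol for
2–5 nm-like particles) with bulk diffusivities falling with size
(0.12–0.05 nm²/ps, interior one third of bulk); the charged presets
use a 10 kJ/mol headgroup minimum and a +30 RT interior barrier. These
reproduce the qualitative structure of the physical system — size
ordering of P driven by diffusivity, and a ≥10-order charged/neutral
suppression — not any particular simulation's numerical profiles.

The toy bead configurations are geometric stand-ins only: straight
chain lattices with controllable rigid tilt, sinusoidal whole-chain
undulation and uniform ideal-gas boxes. They carry no force-field
energetics, no thermal disorder and no realistic lipid mixing, so
passing structural-metric tests demonstrates correctness of the
estimators (exact limits, nulls, analytic constructions), not fidelity
to any real membrane.

## Nanoparticle builder

Gold cores are carved from an FCC lattice (conventional-cell constant
0.408 nm by default, configurable) keeping all sites within the
nominal radius; the result is deterministic. Surface beads are those
with coordination < 12 inside a cutoff placed strictly between the
first and second neighbor shells — parameter-light and exact on a
lattice. Dodecanethiol ligands are 4 beads (anchor + 3 tails, 0.47 nm
bonds, a 4:1 heavy-atom mapping) built radially straight outward from
their surface bead; no geometry relaxation is attempted. Anchor sites
are chosen by seeded farthest-point sampling, which empirically beats
the best of 1000 random placements in minimum anchor spacing. Charged
particles put ±1 e on each ligand terminal; the charge density
σ = Ne/S uses the nominal core diameter for S (150 terminals on a
3 nm core give σ ≈ 5.3 e/nm²). Default ligand counts per size
(80/150/280/410 for 2/3/4/5 nm) are adopted as given, not derived
from a grafting-density rule. Assembly removes water within 0.5 nm
(≈ one bead diameter, configurable) of any particle bead and converts
seeded-random water positions into monovalent counter-ions until the
net charge is exactly zero.

## Structural metrics

Projected area per lipid is box-XY area divided by the per-leaflet
lipid count (per-leaflet normalization is recorded in the output
metadata); undulation at fixed true membrane area necessarily shrinks
it. The area-compressibility modulus uses the standard fluctuation
estimator K_A = k_B T ⟨A⟩ / Var(A); a zero variance is flagged
undefined rather than raised. Order parameters use consecutive bond
vectors against the global z axis (not a local normal), giving Sz = 1
for aligned, −0.5 for in-plane and 0 for isotropic bonds; ⟨Sn⟩
averages tail–tail bonds. The RDF is fully 3-D under the minimum-image
convention (KD-tree with periodic boxsize), normalized by ideal-gas
shell counts, and accepts a single reference point (e.g. a particle
COM) against a bead selection.

## Langevin oracle

The ISD integral is cross-checked by simulating the permeant's
overdamped dynamics in the same (dG, D): the Itô update
z ← z + [−D dG'/RT + D'] dt + √(2 D dt) ξ, with the D' spurious-drift
term required for detailed balance under position-dependent diffusion
(central differences on a fine interpolation grid; 0.02 nm spacing).
Construction rejects timesteps whose maximum drift displacement per
step reaches half the profile grid spacing. With an absorbing bottom
boundary and reinjection at the top (source) plane, the steady-state
permeability is absorption flux divided by the source-side
concentration, read from the time-averaged occupancy in a thin window
below the source; since the measured concentration sits at the window
midpoint, the matching ISD integral spans that midpoint to the sink.
Error bars use Poisson counting statistics on the crossing count. A
third, both-walls-reflecting mode provides equilibrium sampling, whose
occupancy histogram is verified against the Boltzmann weight
exp(−dG/RT) (χ² on independent walkers).

## Problem sizes

Desk-scale defaults keep the full validation chain to minutes on one
CPU: 10⁶ force samples per window where recovery accuracy is asserted
(diffusion within 10%, free energy within 2 kJ/mol of ground truth),
2×10⁵ samples per window for the five-preset permeability sweep, and
1500 walkers × 1.5–2.5×10⁵ steps per oracle run (a few thousand
recorded crossings on the flat profile). These sizes are the package's
own defaults and are the ones exercised by `scripts/acceptance.py`.

## Known limitations

- The synthetic generator's exponential-memory, Gaussian-fluctuation
  assumption is idealized; real constraint forces can show multi-scale
  memory, for which the first-zero-crossing cutoff is less accurate.
- Profiles are assumed symmetric and windows uniformly spaced;
  asymmetric bilayers and adaptive grids are out of scope.
- The builder emits geometry only — no bonded/nonbonded topology for
  any MD engine, and no energy minimization.
- The oracle is strictly 1-D and overdamped; it validates the ISD
  arithmetic, not the underlying dimensional reduction of the real
  3-D dynamics.
- Area per lipid is a projected estimate; no Voronoi tessellation or
  curvature tensor analysis is provided.
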