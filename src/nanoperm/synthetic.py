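"""Synthetic stand-ins for the microsecond-scale constrained MD data.

Two families of fixtures are generated here:

1. **Constraint-force time series.** In a constrained simulation the
   force on the permeant fluctuates around a window-dependent mean with
   an approximately exponential autocorrelation. We emulate this with a
   stationary Ornstein--Uhlenbeck (OU) process, sampled exactly by its
   discrete AR(1) form, so that the generated autocovariance
   sigma2 * exp(-t/tau) holds at every lag with no discretization bias.
   A *window set* places one such series at each constrained z position
   and wires the OU parameters to an analytic free-energy shape and a
   target diffusion profile, so the full analysis chain can be checked
   against known ground truth.

2. **Toy bead configurations.** Lamellar two-leaflet chain lattices
   with controllable tilt and undulation, plus uniform ideal-gas boxes,
   for exercising the structural metrics. These are geometric
   stand-ins only; no force-field energetics are implied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .constants import DEFAULT_TEMPERATURE, thermal_energy
from .frames import BilayerFrame
from .isd import ForceWindow
from .profiles import Profile

__all__ = [
    "OUForceSpec",
    "PMFShapeSpec",
    "ToyBilayerSpec",
    "OUDefaults",
    "gen_ou_force",
    "gen_window_set",
    "gen_toy_bilayer",
    "gen_ideal_gas",
    "solvate",
    "preset_conditions",
    "PRESET_NAMES",
]


# ---------------------------------------------------------------------------
# Ornstein--Uhlenbeck force series
# ---------------------------------------------------------------------------

@dataclass
class OUForceSpec:
    """Parameters of one synthetic constraint-force series.

    mean_force in kJ/(mol nm); sigma2 is the stationary variance in
    (kJ/(mol nm))^2; tau the correlation time and dt the sampling
    interval, both in ps.
    """

    mean_force: float
    sigma2: float
    tau: float
    dt: float
    n_steps: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be > 0 (zero only as the noiseless limit)")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.dt >= self.tau:
            raise ValueError("dt must be < tau so sampling resolves the correlation")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


def gen_ou_force(spec: OUForceSpec) -> np.ndarray:
    """Sample a stationary OU force series F(t) = mean + dF(t).

    Exact discrete-time AR(1) update with coefficient rho = exp(-dt/tau)
    and innovation variance sigma2 * (1 - rho^2); the initial
    fluctuation is drawn from the stationary distribution, so the
    series is stationary from the first sample. Reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.sigma2 == 0:
        return np.full(spec.n_steps, spec.mean_force)
    rho = math.exp(-spec.dt / spec.tau)
    sigma = math.sqrt(spec.sigma2)
    x0 = sigma * rng.standard_normal()
    innov = sigma * math.sqrt(1.0 - rho * rho) * rng.standard_normal(spec.n_steps)
    innov[0] = x0  # first output is the stationary draw itself
    fluct, _ = signal.lfilter([1.0], [1.0, -rho], innov, zi=np.array([0.0]))
    return spec.mean_force + fluct


# ---------------------------------------------------------------------------
# Analytic free-energy shapes
# ---------------------------------------------------------------------------

_SHAPES = ("flat", "hydrophobic_well", "headgroup_minimum_interior_barrier")


@dataclass
class PMFShapeSpec:
    """Analytic, even free-energy profile dG(z), zero at |z| = z_max.

    Shapes
    ------
    flat
        dG = 0 everywhere (bulk-like).
    hydrophobic_well
        A Gaussian well of the given ``depth`` centered at z = 0: the
        monotone attraction a neutral hydrophobic particle feels toward
        the bilayer interior.
    headgroup_minimum_interior_barrier
        A shallow minimum of the given ``depth`` at
        |z| = ``headgroup_position`` plus a positive interior barrier
        of the given ``height`` at z = 0: the adsorption-without-
        penetration shape characteristic of charged particles.

    All shapes are corrected by a smooth even taper so the profile is
    exactly zero at |z| = z_max while remaining even and differentiable.
    Energies in kJ/mol, lengths in nm.
    """

    shape_name: str
    depth: float = 0.0
    height: float = 0.0
    headgroup_position: float = 3.0
    z_max: float = 8.0
    width: float = 1.5
    barrier_width: float = 1.5

    def __post_init__(self) -> None:
        if self.shape_name not in _SHAPES:
            raise ValueError(f"shape_name must be one of {_SHAPES}")
        if self.z_max <= 0:
            raise ValueError("z_max must be > 0")
        if self.width <= 0 or self.barrier_width <= 0:
            raise ValueError("widths must be > 0")

    # raw (untapered) shape and derivative ---------------------------------
    def _raw(self, z: np.ndarray) -> np.ndarray:
        if self.shape_name == "flat":
            return np.zeros_like(z)
        if self.shape_name == "hydrophobic_well":
            return -self.depth * np.exp(-(z**2) / (2 * self.width**2))
        zh, w, wb = self.headgroup_position, self.width, self.barrier_width
        wells = np.exp(-((z - zh) ** 2) / (2 * w**2)) + np.exp(
            -((z + zh) ** 2) / (2 * w**2)
        )
        return self.height * np.exp(-(z**2) / (2 * wb**2)) - self.depth * wells

    def _raw_derivative(self, z: np.ndarray) -> np.ndarray:
        if self.shape_name == "flat":
            return np.zeros_like(z)
        if self.shape_name == "hydrophobic_well":
            return self.depth * (z / self.width**2) * np.exp(-(z**2) / (2 * self.width**2))
        zh, w, wb = self.headgroup_position, self.width, self.barrier_width
        d_wells = -((z - zh) / w**2) * np.exp(-((z - zh) ** 2) / (2 * w**2)) - (
            (z + zh) / w**2
        ) * np.exp(-((z + zh) ** 2) / (2 * w**2))
        d_barrier = -self.height * (z / wb**2) * np.exp(-(z**2) / (2 * wb**2))
        return d_barrier - self.depth * d_wells

    # public profile -------------------------------------------------------
    def value(self, z) -> np.ndarray:
        """dG(z) in kJ/mol; even in z and exactly 0 at |z| = z_max."""
        z = np.asarray(z, dtype=float)
        u_edge = self._raw(np.array([self.z_max]))[0]
        return self._raw(z) - u_edge * (z / self.z_max) ** 2

    def derivative(self, z) -> np.ndarray:
        """d(dG)/dz in kJ/(mol nm)."""
        z = np.asarray(z, dtype=float)
        u_edge = self._raw(np.array([self.z_max]))[0]
        return self._raw_derivative(z) - u_edge * 2.0 * z / self.z_max**2


# ---------------------------------------------------------------------------
# Window sets
# ---------------------------------------------------------------------------

@dataclass
class OUDefaults:
    """Fluctuation defaults shared by all windows of a set.

    ``tau`` (ps) is fixed globally; per-window variances are solved
    from the target diffusion profile via sigma2 = (RT)^2 / (D tau).
    """

    tau: float = 1.0
    dt: float = 0.1
    n_steps: int = 200_000
    temperature: float = DEFAULT_TEMPERATURE


def _as_diffusion_function(d_true):
    if isinstance(d_true, Profile):
        return d_true
    if callable(d_true):
        return d_true
    value = float(d_true)
    return lambda z: np.full_like(np.asarray(z, dtype=float), value)


def gen_window_set(
    pmf: PMFShapeSpec,
    d_true,
    ou: OUDefaults | None = None,
    window_spacing: float = 0.2,
    seed: int = 0,
) -> list[ForceWindow]:
    """One constrained window per z, from z_max down to z = 0.

    Mimics the pulling protocol: the particle starts at z_max and a
    configuration is stored at each ``window_spacing`` decrease of the
    COM separation, down to and including the bilayer center. For
    z_max = 8.0 nm and 0.2 nm spacing this yields 40 windows, the first
    at 7.8 nm.

    Each window's mean force is -d(dG)/dz of the analytic shape at its
    z; its OU variance is solved from the target diffusion profile
    ``d_true`` (a scalar, callable or :class:`Profile`, nm^2/ps) so the
    force-autocorrelation estimator recovers D(z).
    """
    if window_spacing <= 0:
        raise ValueError("window_spacing must be > 0")
    ou = ou or OUDefaults()
    dfun = _as_diffusion_function(d_true)
    n_windows = int(math.floor(pmf.z_max / window_spacing + 1e-9))
    zs = pmf.z_max - window_spacing * np.arange(1, n_windows + 1)
    zs[np.abs(zs) < 1e-12] = 0.0
    d_vals = np.asarray(dfun(zs), dtype=float)
    if np.any(d_vals <= 0):
        raise ValueError("d_true must be positive at every window position")

    rt = thermal_energy(ou.temperature)
    children = np.random.SeedSequence(seed).spawn(n_windows)
    windows = []
    for z, d, child in zip(zs, d_vals, children):
        sigma2 = rt**2 / (d * ou.tau)
        spec = OUForceSpec(
            mean_force=float(-pmf.derivative(z)),
            sigma2=sigma2,
            tau=ou.tau,
            dt=ou.dt,
            n_steps=ou.n_steps,
            seed=child,
        )
        windows.append(ForceWindow(z=float(z), forces=gen_ou_force(spec), dt=ou.dt))
    return windows


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("2nm", "3nm", "4nm", "5nm", "3nm_cationic", "3nm_anionic")

#: Interior free-energy depths (kJ/mol) for the neutral hydrophobic
#: particles: the well deepens with particle size, while bulk
#: diffusivity (nm^2/ps) falls roughly with size. Charged 3 nm
#: particles get a shallow headgroup minimum plus a +30 RT interior
#: barrier, the adsorption-without-penetration shape.
_NEUTRAL_DEPTH = {"2nm": 70.0, "3nm": 135.0, "4nm": 250.0, "5nm": 350.0}
_BULK_D = {"2nm": 0.12, "3nm": 0.08, "4nm": 0.06, "5nm": 0.05}


def _sigmoid_diffusion(d_bulk: float, d_interior: float, z_interface: float = 3.0,
                       sharpness: float = 0.5):
    def d_of_z(z):
        z = np.asarray(np.abs(z), dtype=float)
        s = 1.0 / (1.0 + np.exp(-(z - z_interface) / sharpness))
        return d_interior + (d_bulk - d_interior) * s
    return d_of_z


def preset_conditions(name: str, temperature: float = DEFAULT_TEMPERATURE):
    """(PMFShapeSpec, D(z) callable) for one study condition.

    Neutral presets ("2nm".."5nm"): hydrophobic wells of increasing
    depth with bulk diffusivity decreasing with size (interior
    diffusivity one third of bulk). Charged presets ("3nm_cationic",
    "3nm_anionic"): a 10 kJ/mol headgroup minimum plus a +30 RT
    interior barrier at the 3 nm particle's diffusivity.
    """
    rt = thermal_energy(temperature)
    if name in _NEUTRAL_DEPTH:
        pmf = PMFShapeSpec("hydrophobic_well", depth=_NEUTRAL_DEPTH[name], z_max=8.0)
        d_bulk = _BULK_D[name]
    elif name in ("3nm_cationic", "3nm_anionic"):
        pmf = PMFShapeSpec(
            "headgroup_minimum_interior_barrier",
            depth=10.0,
            height=30.0 * rt,
            headgroup_position=3.0,
            z_max=8.0,
        )
        d_bulk = _BULK_D["3nm"]
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return pmf, _sigmoid_diffusion(d_bulk, d_bulk / 3.0)


# ---------------------------------------------------------------------------
# Toy bead configurations
# ---------------------------------------------------------------------------

@dataclass
class ToyBilayerSpec:
    """A lamellar two-leaflet chain lattice with optional tilt/undulation.

    Chains are straight bead strings (head bead at the water-facing
    end) on a square in-plane lattice; ``tilt_angle`` rigidly tilts
    each chain away from z about a random in-plane axis, and the
    undulation displaces whole chains in z by
    amplitude * sin(2 pi x / wavelength). The wavelength must divide
    the box edge Lx so the sinusoid is periodic.
    """

    n_lipids_per_leaflet: int
    beads_per_chain: int = 4
    bond_length: float = 0.47
    tilt_angle: float = 0.0
    undulation_amplitude: float = 0.0
    undulation_wavelength: float = 0.0
    box: tuple[float, float, float] = (12.0, 12.0, 16.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids_per_leaflet < 1:
            raise ValueError("n_lipids_per_leaflet must be >= 1")
        if self.beads_per_chain < 2:
            raise ValueError("beads_per_chain must be >= 2")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be > 0")
        if any(b <= 0 for b in self.box):
            raise ValueError("box edges must be > 0")
        if self.undulation_amplitude != 0:
            if self.undulation_wavelength <= 0:
                raise ValueError("undulation_wavelength must be > 0 when amplitude != 0")
            ratio = self.box[0] / self.undulation_wavelength
            if abs(ratio - round(ratio)) > 1e-6:
                raise ValueError("undulation_wavelength must divide the box edge Lx")


def gen_toy_bilayer(spec: ToyBilayerSpec) -> BilayerFrame:
    """Build the toy bilayer frame described by ``spec``.

    Bead count is 2 * n_lipids_per_leaflet * beads_per_chain; leaflet
    ground-truth labels (+1 upper / -1 lower) are stored on the frame.
    """
    n = spec.n_lipids_per_leaflet
    lx, ly, lz = spec.box
    nx = int(math.ceil(math.sqrt(n)))
    ny = int(math.ceil(n / nx))
    sx, sy = lx / nx, ly / ny
    if min(sx, sy) < spec.bond_length:
        raise ValueError(
            f"box too small: in-plane lattice spacing {min(sx, sy):.3f} nm "
            f"< bond length {spec.bond_length} nm"
        )
    chain_len = (spec.beads_per_chain - 1) * spec.bond_length
    gap = 0.1  # nm clearance between leaflet termini at the midplane
    z_mid = lz / 2.0
    if chain_len + gap / 2.0 + abs(spec.undulation_amplitude) > lz / 2.0:
        raise ValueError("box too small in z for the chain length")

    rng = np.random.default_rng(spec.seed)
    tilt = math.radians(spec.tilt_angle)

    positions = []
    labels = []
    chains = []
    leaflets = []
    bead = 0
    for leaf in (+1, -1):
        for i in range(n):
            ix, iy = i % nx, i // nx
            x = (ix + 0.5) * sx
            y = (iy + 0.5) * sy
            head_z = z_mid + leaf * (gap / 2.0 + chain_len)
            # bond direction: from head toward the midplane
            direction = np.array([0.0, 0.0, -float(leaf)])
            if tilt != 0.0:
                phi = rng.uniform(0, 2 * math.pi)
                axis = np.array([math.cos(phi), math.sin(phi), 0.0])
                direction = _rotate(direction, axis, tilt)
            dz = 0.0
            if spec.undulation_amplitude != 0:
                dz = spec.undulation_amplitude * math.sin(
                    2 * math.pi * x / spec.undulation_wavelength
                )
            head = np.array([x, y, head_z + dz])
            chain_ids = []
            for k in range(spec.beads_per_chain):
                positions.append(head + k * spec.bond_length * direction)
                labels.append("head" if k == 0 else "tail")
                chain_ids.append(bead)
                bead += 1
            chains.append(np.array(chain_ids))
            leaflets.append(leaf)

    pos = np.array(positions)
    box = np.array([lx, ly, lz])
    pos[:, :2] %= box[:2]  # wrap laterally (tilt can push beads across edges)
    return BilayerFrame(
        positions=pos,
        labels=np.array(labels),
        box=box,
        chains=chains,
        leaflets=np.array(leaflets),
    )


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * np.dot(axis, v) * (1 - math.cos(angle))
    )


def gen_ideal_gas(n: int, box, seed: int = 0, label: str = "water") -> BilayerFrame:
    """n beads uniformly distributed in an orthorhombic box (RDF null)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * box
    return BilayerFrame(positions=pos, labels=np.full(n, label), box=box)


def solvate(frame: BilayerFrame, n_water: int, seed: int = 0) -> BilayerFrame:
    """Return a copy of ``frame`` with n_water uniform water beads added."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.0, 1.0, size=(n_water, 3)) * frame.box
    return BilayerFrame(
        positions=np.vstack([frame.positions, w]),
        labels=np.concatenate([frame.labels, np.full(n_water, "water")]),
        box=frame.box.copy(),
        chains=[c.copy() for c in frame.chains],
        leaflets=None if frame.leaflets is None else frame.leaflets.copy(),
        charges=None
        if frame.charges is None
        else np.concatenate([frame.charges, np.zeros(n_water)]),
    )
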