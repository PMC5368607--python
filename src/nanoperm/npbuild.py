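"""Coarse-grained coated gold nanoparticle construction.

Builds a bare FCC gold core of a nominal diameter, flags its surface
beads by coordination number, grafts dodecanethiol-like 4-bead ligand
chains onto distinct surface beads by farthest-point sampling, assigns
terminal charges (cationic/anionic particles), and assembles a
particle with a solvated bilayer box: placement above the bilayer
center of mass, removal of overlapping water, and counter-ion addition
to exact charge neutrality.

No force-field topology is produced; the output is a geometric model
with bead species, charges and masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .frames import BilayerFrame, write_frame

__all__ = [
    "CoreSpec",
    "CoatedNanoparticle",
    "AssembledSystem",
    "carve_fcc_core",
    "flag_surface_beads",
    "graft_ligands",
    "assign_surface_charge",
    "assemble_system",
    "DEFAULT_LIGAND_COUNTS",
    "DEFAULT_COMPOSITION",
    "write_particle",
]

#: Dodecanethiol ligand counts per nominal core diameter (nm).
DEFAULT_LIGAND_COUNTS = {2: 80, 3: 150, 4: 280, 5: 410}

#: Bilayer composition defaults (number of molecules); water counts per
#: particle size reflect the enlarged solvation boxes.
DEFAULT_COMPOSITION = {
    "CER": 832,
    "CHOL": 800,
    "FFA": 832,
    "water": {None: 20480, 2: 30680, 3: 40960, 4: 61440, 5: 61440},
}

#: FCC conventional-cell basis (fractions of the lattice constant).
_FCC_BASIS = np.array(
    [[0.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]
)

#: Nominal bead masses, amu (one Au atom per core bead; a dodecanethiol
#: molecule split over four beads).
AU_BEAD_MASS = 196.97
LIGAND_BEAD_MASS = 50.6

#: Beads per grafted dodecanethiol chain (anchor + 3 tail beads).
BEADS_PER_LIGAND = 4


@dataclass
class CoreSpec:
    """Bare FCC core: nominal diameter and lattice constant, nm."""

    diameter: float
    lattice_constant: float = 0.408

    def __post_init__(self) -> None:
        if self.lattice_constant <= 0:
            raise ValueError("lattice_constant must be > 0")
        if self.diameter <= self.lattice_constant:
            raise ValueError("diameter must exceed the lattice constant")


@dataclass
class CoatedNanoparticle:
    """Core beads, surface flags, grafted ligands and per-bead charges."""

    core_positions: np.ndarray          # (Nc, 3) nm, centered at origin
    surface_mask: np.ndarray            # (Nc,) bool
    ligand_positions: np.ndarray        # (Nl, 4, 3) nm; anchor first
    anchor_parent: np.ndarray           # (Nl,) core index of each anchor's surface bead
    ligand_charges: np.ndarray          # (Nl, 4) e; nonzero only on terminal beads
    diameter: float                     # nominal core diameter, nm
    bond_length: float = 0.47

    @property
    def n_ligands(self) -> int:
        return self.ligand_positions.shape[0]

    @property
    def all_positions(self) -> np.ndarray:
        if self.n_ligands == 0:
            return self.core_positions
        return np.vstack([self.core_positions, self.ligand_positions.reshape(-1, 3)])

    @property
    def all_charges(self) -> np.ndarray:
        return np.concatenate(
            [np.zeros(self.core_positions.shape[0]), self.ligand_charges.ravel()]
        )

    @property
    def total_charge(self) -> float:
        return float(self.all_charges.sum())

    @property
    def total_mass(self) -> float:
        return (
            self.core_positions.shape[0] * AU_BEAD_MASS
            + self.n_ligands * BEADS_PER_LIGAND * LIGAND_BEAD_MASS
        )

    def min_separation(self) -> float:
        pos = self.all_positions
        tree = cKDTree(pos)
        d, _ = tree.query(pos, k=2)
        return float(d[:, 1].min())


def carve_fcc_core(spec: CoreSpec) -> np.ndarray:
    """All FCC lattice sites within diameter/2 of the origin.

    The lattice origin coincides with the core center, so the origin
    site is always included. Output order is deterministic
    (lexicographic sort).
    """
    a = spec.lattice_constant
    r = spec.diameter / 2.0
    nmax = int(math.ceil(r / a)) + 1
    cells = np.arange(-nmax, nmax + 1)
    ii, jj, kk = np.meshgrid(cells, cells, cells, indexing="ij")
    corners = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    sites = (corners[:, None, :] + _FCC_BASIS[None, :, :]).reshape(-1, 3) * a
    keep = np.einsum("ij,ij->i", sites, sites) <= r * r + 1e-12
    sites = sites[keep]
    order = np.lexsort((sites[:, 2], sites[:, 1], sites[:, 0]))
    return sites[order]


def flag_surface_beads(
    core_positions: np.ndarray,
    neighbor_cutoff: float = 0.35,
    lattice_constant: float = 0.408,
) -> np.ndarray:
    """Surface flags: a bead is surface iff its coordination < 12.

    ``neighbor_cutoff`` must fall strictly between the first FCC
    neighbor shell (a/sqrt(2)) and the second (a), so the coordination
    number counts exactly the nearest-neighbor shell.
    """
    a = lattice_constant
    if not (a / math.sqrt(2) < neighbor_cutoff < a):
        raise ValueError(
            f"neighbor_cutoff must lie in (a/sqrt(2), a) = "
            f"({a / math.sqrt(2):.4f}, {a:.4f}) nm"
        )
    pos = np.asarray(core_positions, dtype=float)
    if pos.shape[0] == 1:
        return np.array([True])
    tree = cKDTree(pos)
    coordination = np.array(
        [len(neigh) - 1 for neigh in tree.query_ball_point(pos, neighbor_cutoff)]
    )
    return coordination < 12


def graft_ligands(
    core_positions: np.ndarray,
    n_ligands: int,
    seed: int = 0,
    surface_mask: np.ndarray | None = None,
    bond_length: float = 0.47,
    diameter: float | None = None,
) -> CoatedNanoparticle:
    """Graft ligand chains onto surface beads by farthest-point sampling.

    Anchor sites are chosen greedily: a seeded random surface bead
    starts the set and each subsequent anchor is the surface bead
    farthest from all chosen ones (lowest index on ties, so the result
    is deterministic for a fixed seed). Each ligand is built radially
    outward from its surface bead: four beads (anchor + 3 tails) at
    1..4 bond lengths along the outward normal.
    """
    pos = np.asarray(core_positions, dtype=float)
    if surface_mask is None:
        surface_mask = flag_surface_beads(pos)
    surface_idx = np.nonzero(surface_mask)[0]
    if n_ligands < 0:
        raise ValueError("n_ligands must be >= 0")
    if n_ligands > surface_idx.size:
        raise ValueError(
            f"n_ligands={n_ligands} exceeds the {surface_idx.size} available surface beads"
        )
    if diameter is None:
        diameter = 2.0 * float(np.linalg.norm(pos, axis=1).max())

    chosen: list[int] = []
    if n_ligands > 0:
        rng = np.random.default_rng(seed)
        surf_pos = pos[surface_idx]
        start = int(rng.integers(surface_idx.size))
        chosen = [start]
        min_d2 = np.einsum("ij,ij->i", surf_pos - surf_pos[start], surf_pos - surf_pos[start])
        while len(chosen) < n_ligands:
            nxt = int(np.argmax(min_d2))  # argmax takes the lowest index on ties
            chosen.append(nxt)
            d2 = np.einsum("ij,ij->i", surf_pos - surf_pos[nxt], surf_pos - surf_pos[nxt])
            min_d2 = np.minimum(min_d2, d2)

    anchors = surface_idx[np.array(chosen, dtype=int)] if chosen else np.empty(0, dtype=int)
    lig = np.zeros((n_ligands, BEADS_PER_LIGAND, 3))
    for m, idx in enumerate(anchors):
        normal = pos[idx] / np.linalg.norm(pos[idx])
        for k in range(BEADS_PER_LIGAND):
            lig[m, k] = pos[idx] + (k + 1) * bond_length * normal
    return CoatedNanoparticle(
        core_positions=pos,
        surface_mask=np.asarray(surface_mask, dtype=bool),
        ligand_positions=lig,
        anchor_parent=anchors,
        ligand_charges=np.zeros((n_ligands, BEADS_PER_LIGAND)),
        diameter=float(diameter),
        bond_length=bond_length,
    )


def assign_surface_charge(
    particle: CoatedNanoparticle, charge_per_terminal: float
) -> tuple[CoatedNanoparticle, float]:
    """Charge every ligand terminal bead and return the charge density.

    sigma = N e / S with N the number of charged terminals, e the
    reduced charge per bead, and S the sphere surface area computed
    from the nominal core diameter. Returns (charged particle, sigma in
    e/nm^2).
    """
    if particle.n_ligands == 0:
        raise ValueError("cannot charge a particle with zero ligands")
    charges = np.zeros_like(particle.ligand_charges)
    charges[:, -1] = charge_per_terminal
    surface_area = math.pi * particle.diameter**2
    sigma = particle.n_ligands * charge_per_terminal / surface_area
    return replace(particle, ligand_charges=charges), float(sigma)


@dataclass
class AssembledSystem:
    """Particle + bilayer + water + counter-ions in one periodic box."""

    frame: BilayerFrame
    counts: dict
    n_water_removed: int
    n_ions_added: int

    @property
    def total_charge(self) -> float:
        return float(self.frame.charges.sum())


def assemble_system(
    particle: CoatedNanoparticle,
    frame: BilayerFrame,
    placement_z: float,
    desolvation_cutoff: float = 0.5,
    seed: int = 0,
) -> AssembledSystem:
    """Place a particle above the bilayer and resolvate.

    The particle center of mass (all beads equal-weighted) is moved to
    ``placement_z`` nm above the bilayer center of mass, laterally
    centered in the box. Water beads within ``desolvation_cutoff`` of
    any particle bead are removed, and counter-ions (monovalent, of
    opposite sign) are created at seeded-random water positions --
    preferentially the just-removed ones -- until the total charge is
    exactly zero.
    """
    lipid_mask = np.isin(frame.labels, ("head", "tail"))
    if not lipid_mask.any():
        raise ValueError("frame contains no lipid beads")
    com_bilayer = frame.positions[lipid_mask].mean(axis=0)
    np_pos = particle.all_positions
    target = np.array([frame.box[0] / 2.0, frame.box[1] / 2.0, com_bilayer[2] + placement_z])
    np_pos = np_pos - np_pos.mean(axis=0) + target
    if np.any(np_pos < 0) or np.any(np_pos > frame.box):
        raise ValueError("particle overlaps the box boundary at this placement_z")

    water_mask = frame.labels == "water"
    water_pos = frame.positions[water_mask]
    removed = np.zeros(water_pos.shape[0], dtype=bool)
    if water_pos.size:
        tree = cKDTree(np_pos)
        hit = tree.query_ball_point(water_pos, desolvation_cutoff)
        removed = np.array([len(h) > 0 for h in hit])

    net = particle.total_charge
    n_ions = int(round(abs(net)))
    ion_charge = -1.0 if net > 0 else 1.0
    rng = np.random.default_rng(seed)
    removed_pool = water_pos[removed]
    kept_pool_idx = np.nonzero(~removed)[0]
    ion_positions = []
    take_removed = min(n_ions, removed_pool.shape[0])
    if take_removed:
        pick = rng.choice(removed_pool.shape[0], size=take_removed, replace=False)
        ion_positions.append(removed_pool[pick])
    remaining = n_ions - take_removed
    converted = np.empty(0, dtype=int)
    if remaining:
        if remaining > kept_pool_idx.size:
            raise ValueError("not enough water beads to place counter-ions")
        converted = rng.choice(kept_pool_idx, size=remaining, replace=False)
        ion_positions.append(water_pos[converted])
    ion_pos = np.vstack(ion_positions) if ion_positions else np.empty((0, 3))

    keep_water = ~removed
    keep_water[converted] = False
    water_kept = water_pos[keep_water]

    other_mask = ~water_mask
    positions = np.vstack([frame.positions[other_mask], water_kept, np_pos, ion_pos])
    labels = np.concatenate(
        [
            frame.labels[other_mask],
            np.full(water_kept.shape[0], "water"),
            np.full(np_pos.shape[0], "np"),
            np.full(ion_pos.shape[0], "ion"),
        ]
    )
    charges = np.concatenate(
        [
            np.zeros(other_mask.sum()),
            np.zeros(water_kept.shape[0]),
            particle.all_charges,
            np.full(ion_pos.shape[0], ion_charge) if n_ions else np.empty(0),
        ]
    )
    # remap chain topology onto the new ordering
    old_idx = np.nonzero(other_mask)[0]
    remap = {int(o): i for i, o in enumerate(old_idx)}
    chains = [np.array([remap[int(b)] for b in chain]) for chain in frame.chains]

    out = BilayerFrame(
        positions=positions, labels=labels, box=frame.box.copy(), chains=chains, charges=charges
    )
    counts = {
        "lipid_beads": int(other_mask.sum() - (frame.labels == "np").sum()),
        "water": int(water_kept.shape[0]),
        "np_beads": int(np_pos.shape[0]),
        "ions": n_ions,
    }
    return AssembledSystem(
        frame=out,
        counts=counts,
        n_water_removed=int(removed.sum()),
        n_ions_added=n_ions,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_particle(particle: CoatedNanoparticle, outdir, stem: str = "particle") -> dict:
    """Write GRO/PDB coordinates, a TSV bead index and a composition summary.

    Returns the paths written. Residue names distinguish core (AUC),
    anchor (SAU), ligand tail (CT) beads.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pos = particle.all_positions
    span = pos.max(axis=0) - pos.min(axis=0)
    box = span + 2.0  # 1 nm vacuum margin per side
    shifted = pos - pos.min(axis=0) + 1.0

    nc = particle.core_positions.shape[0]
    species = ["AUC"] * nc
    for _ in range(particle.n_ligands):
        species += ["SAU"] + ["CT"] * (BEADS_PER_LIGAND - 1)
    charges = particle.all_charges
    surface = np.concatenate(
        [particle.surface_mask, np.zeros(particle.n_ligands * BEADS_PER_LIGAND, dtype=bool)]
    )

    labels = np.full(shifted.shape[0], "np")
    frame = BilayerFrame(positions=shifted, labels=labels, box=box, charges=charges)
    paths = {}
    for ext in ("gro", "pdb"):
        p = outdir / f"{stem}.{ext}"
        write_frame(frame, p)
        paths[ext] = p

    index = pd.DataFrame(
        {
            "bead_id": np.arange(shifted.shape[0]),
            "species": species,
            "charge_e": charges,
            "surface": surface.astype(int),
        }
    )
    paths["index"] = outdir / f"{stem}_index.tsv"
    index.to_csv(paths["index"], sep="\t", index=False)

    d_nm = int(round(particle.diameter))
    water = DEFAULT_COMPOSITION["water"].get(d_nm, DEFAULT_COMPOSITION["water"][None])
    summary = outdir / f"{stem}_composition.txt"
    summary.write_text(
        "quantity\tvalue\n"
        f"core_diameter_nm\t{particle.diameter:g}\n"
        f"core_beads\t{nc}\n"
        f"dodecanethiol_ligands\t{particle.n_ligands}\n"
        f"ligand_beads\t{particle.n_ligands * BEADS_PER_LIGAND}\n"
        f"total_charge_e\t{particle.total_charge:g}\n"
        f"total_mass_amu\t{particle.total_mass:.1f}\n"
        f"CER\t{DEFAULT_COMPOSITION['CER']}\n"
        f"CHOL\t{DEFAULT_COMPOSITION['CHOL']}\n"
        f"FFA\t{DEFAULT_COMPOSITION['FFA']}\n"
        f"water\t{water}\n"
    )
    paths["composition"] = summary
    return paths
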