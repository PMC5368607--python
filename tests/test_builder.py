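"""Tests of the coated-nanoparticle construction."""

import itertools

import numpy as np
import pytest

from nanoperm.frames import BilayerFrame
from nanoperm.npbuild import (
    DEFAULT_LIGAND_COUNTS,
    CoreSpec,
    assemble_system,
    assign_surface_charge,
    carve_fcc_core,
    flag_surface_beads,
    graft_ligands,
)
from nanoperm.synthetic import ToyBilayerSpec, gen_toy_bilayer, solvate

A = 0.408  # default lattice constant, nm
NN = A / np.sqrt(2)  # first-shell neighbor distance


def brute_force_fcc_sites(radius, a=A):
    """Independent enumeration of FCC sites within radius of the origin."""
    basis = [(0, 0, 0), (0, 0.5, 0.5), (0.5, 0, 0.5), (0.5, 0.5, 0)]
    n = int(np.ceil(radius / a)) + 2
    sites = []
    for i, j, k in itertools.product(range(-n, n + 1), repeat=3):
        for bx, by, bz in basis:
            p = np.array([i + bx, j + by, k + bz]) * a
            if p @ p <= radius**2 + 1e-12:
                sites.append(p)
    return np.array(sorted(map(tuple, sites)))


class TestCarveCore:
    def test_smallest_core_is_origin_plus_first_shell(self):
        d = 2 * NN + 0.01
        core = carve_fcc_core(CoreSpec(diameter=d))
        oracle = brute_force_fcc_sites(d / 2)
        assert core.shape == oracle.shape
        assert np.allclose(np.array(sorted(map(tuple, core))), oracle)
        assert core.shape[0] == 13  # origin + full 12-neighbor FCC shell

    def test_count_scales_with_volume(self):
        n2 = carve_fcc_core(CoreSpec(diameter=2.0)).shape[0]
        n4 = carve_fcc_core(CoreSpec(diameter=4.0)).shape[0]
        assert 7.0 < n4 / n2 < 9.0

    def test_deterministic_and_on_lattice(self):
        spec = CoreSpec(diameter=3.0)
        a = carve_fcc_core(spec)
        b = carve_fcc_core(spec)
        assert np.array_equal(a, b)
        # every site sits on the FCC lattice: doubled fractional coords are
        # integers of even parity
        frac2 = a / spec.lattice_constant * 2.0
        assert np.allclose(frac2, np.round(frac2), atol=1e-6)
        assert np.all(np.round(frac2).sum(axis=1).astype(int) % 2 == 0)

    def test_too_small_diameter_rejected(self):
        with pytest.raises(ValueError, match="diameter"):
            CoreSpec(diameter=0.3)


class TestSurfaceDetection:
    def test_single_bead_is_surface(self):
        assert flag_surface_beads(np.zeros((1, 3))).tolist() == [True]

    def test_interior_bead_with_full_shell_not_surface(self):
        core = carve_fcc_core(CoreSpec(diameter=3.0))
        surf = flag_surface_beads(core)
        origin = np.flatnonzero(np.all(np.abs(core) < 1e-9, axis=1))[0]
        assert not surf[origin]

    def test_matches_brute_force_coordination_oracle(self):
        core = carve_fcc_core(CoreSpec(diameter=5.0))
        surf = flag_surface_beads(core)
        diff = core[:, None, :] - core[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        coordination = ((dist > 1e-9) & (dist < 0.35)).sum(axis=1)
        assert np.array_equal(surf, coordination < 12)
        # all surface beads sit within one lattice constant of the boundary
        r = np.linalg.norm(core, axis=1)
        assert np.all(r[surf] > 2.5 - A)

    def test_cutoff_outside_shell_gap_rejected(self):
        core = carve_fcc_core(CoreSpec(diameter=2.0))
        for bad in (0.2, 0.5):
            with pytest.raises(ValueError, match="neighbor_cutoff"):
                flag_surface_beads(core, neighbor_cutoff=bad)


class TestGrafting:
    def test_zero_ligands_leaves_bare_particle(self):
        core = carve_fcc_core(CoreSpec(diameter=2.0))
        p = graft_ligands(core, 0, seed=0, diameter=2.0)
        assert p.n_ligands == 0
        assert np.array_equal(p.all_positions, core)

    def test_table_default_for_3nm_particle(self):
        core = carve_fcc_core(CoreSpec(diameter=3.0))
        p = graft_ligands(core, DEFAULT_LIGAND_COUNTS[3], seed=0, diameter=3.0)
        assert p.n_ligands == 150
        assert p.ligand_positions.reshape(-1, 3).shape[0] == 600
        # anchors attach to distinct surface beads
        assert np.unique(p.anchor_parent).size == 150
        assert np.all(p.surface_mask[p.anchor_parent])

    def test_coated_radius_is_core_plus_ligand_length(self):
        core = carve_fcc_core(CoreSpec(diameter=3.0))
        p = graft_ligands(core, 150, seed=1, diameter=3.0)
        rmax = np.linalg.norm(p.all_positions, axis=1).max()
        assert abs(rmax - (1.5 + 4 * p.bond_length)) <= p.bond_length

    def test_grafting_is_deterministic(self):
        core = carve_fcc_core(CoreSpec(diameter=2.0))
        p1 = graft_ligands(core, 80, seed=5, diameter=2.0)
        p2 = graft_ligands(core, 80, seed=5, diameter=2.0)
        assert np.array_equal(p1.ligand_positions, p2.ligand_positions)
        assert np.array_equal(p1.anchor_parent, p2.anchor_parent)

    def test_farthest_point_beats_random_placement(self):
        core = carve_fcc_core(CoreSpec(diameter=3.0))
        surf_idx = np.flatnonzero(flag_surface_beads(core))
        p = graft_ligands(core, 150, seed=0, diameter=3.0)
        anchors = core[p.anchor_parent]

        def min_pairwise(points):
            diff = points[:, None, :] - points[None, :, :]
            d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
            return d[np.triu_indices_from(d, k=1)].min()

        fps_min = min_pairwise(anchors)
        rng = np.random.default_rng(123)
        random_best = max(
            min_pairwise(core[rng.choice(surf_idx, 150, replace=False)])
            for _ in range(1000)
        )
        assert fps_min >= random_best

    def test_too_many_ligands_rejected_with_counts(self):
        core = carve_fcc_core(CoreSpec(diameter=2.0))
        n_surface = int(flag_surface_beads(core).sum())
        with pytest.raises(ValueError, match=str(n_surface)):
            graft_ligands(core, n_surface + 1, diameter=2.0)


@pytest.fixture(scope="module")
def coated_3nm():
    core = carve_fcc_core(CoreSpec(diameter=3.0))
    return graft_ligands(core, 150, seed=0, diameter=3.0)


@pytest.fixture(scope="module")
def solvated_bilayer():
    frame = gen_toy_bilayer(ToyBilayerSpec(n_lipids_per_leaflet=64, box=(16.0, 16.0, 24.0)))
    return solvate(frame, 3000, seed=2)


@pytest.fixture(scope="module")
def charged_particle():
    core = carve_fcc_core(CoreSpec(diameter=2.0))
    p = graft_ligands(core, 80, seed=0, diameter=2.0)
    charged, _ = assign_surface_charge(p, +1.0)
    return charged


class TestSurfaceCharge:
    def test_charge_density_matches_spherical_formula(self, coated_3nm):
        charged, sigma = assign_surface_charge(coated_3nm, +1.0)
        assert sigma == pytest.approx(150 / (np.pi * 9.0))
        assert sigma == pytest.approx(5.0, abs=0.5)
        # charges live only on ligand terminal beads
        assert np.all(charged.ligand_charges[:, -1] == 1.0)
        assert np.all(charged.ligand_charges[:, :-1] == 0.0)
        assert charged.total_charge == pytest.approx(150.0)

    def test_zero_charge_gives_zero_density(self, coated_3nm):
        _, sigma = assign_surface_charge(coated_3nm, 0.0)
        assert sigma == 0.0

    def test_anionic_density_is_sign_flipped(self, coated_3nm):
        _, s_pos = assign_surface_charge(coated_3nm, +1.0)
        _, s_neg = assign_surface_charge(coated_3nm, -1.0)
        assert s_neg == pytest.approx(-s_pos)

    def test_bare_particle_cannot_be_charged(self):
        core = carve_fcc_core(CoreSpec(diameter=2.0))
        bare = graft_ligands(core, 0, diameter=2.0)
        with pytest.raises(ValueError, match="zero ligands"):
            assign_surface_charge(bare, 1.0)


class TestAssembly:
    def test_neutral_particle_adds_no_ions(self, solvated_bilayer):
        core = carve_fcc_core(CoreSpec(diameter=2.0))
        p = graft_ligands(core, 80, seed=0, diameter=2.0)
        sys = assemble_system(p, solvated_bilayer, placement_z=7.0, seed=0)
        assert sys.n_ions_added == 0
        assert sys.total_charge == 0.0

    def test_cationic_particle_neutralized_by_anions(self, solvated_bilayer, charged_particle):
        sys = assemble_system(charged_particle, solvated_bilayer, placement_z=7.0, seed=0)
        assert sys.n_ions_added == 80
        assert sys.total_charge == 0.0
        assert np.all(sys.frame.charges[sys.frame.labels == "ion"] == -1.0)

    def test_removed_water_matches_all_pairs_oracle(self, charged_particle):
        frame = gen_toy_bilayer(ToyBilayerSpec(n_lipids_per_leaflet=16, box=(10, 10, 20)))
        frame = solvate(frame, 400, seed=7)
        cutoff = 0.5
        sys = assemble_system(charged_particle, frame, placement_z=6.0,
                              desolvation_cutoff=cutoff, seed=0)
        # brute-force oracle on the same placement
        np_pos = charged_particle.all_positions
        lipid = np.isin(frame.labels, ("head", "tail"))
        target = np.array([5.0, 5.0, frame.positions[lipid].mean(axis=0)[2] + 6.0])
        np_pos = np_pos - np_pos.mean(axis=0) + target
        water = frame.positions[frame.labels == "water"]
        d = np.linalg.norm(water[:, None, :] - np_pos[None, :, :], axis=2)
        assert sys.n_water_removed == int((d.min(axis=1) <= cutoff).sum())

    def test_out_of_box_placement_rejected(self, solvated_bilayer, charged_particle):
        with pytest.raises(ValueError, match="box boundary"):
            assemble_system(charged_particle, solvated_bilayer, placement_z=15.0)

    def test_chain_topology_survives_assembly(self, solvated_bilayer, charged_particle):
        sys = assemble_system(charged_particle, solvated_bilayer, placement_z=7.0, seed=0)
        assert len(sys.frame.chains) == len(solvated_bilayer.chains)
        for chain in sys.frame.chains:
            assert np.all(np.isin(sys.frame.labels[chain], ("head", "tail")))
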