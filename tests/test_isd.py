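"""Tests of the solubility-diffusion pipeline estimators."""

import numpy as np
import pytest
from scipy import integrate

from nanoperm.constants import CM_PER_S_PER_NM_PER_PS, thermal_energy
from nanoperm.isd import (
    ForceWindow,
    diffusion_from_facf,
    free_energy_profile,
    integrate_mean_force,
    mean_force,
    partition_profile,
    permeability,
    resistance_profile,
    run_isd,
    symmetrize,
)
from nanoperm.profiles import Profile
from nanoperm.synthetic import (
    OUDefaults,
    OUForceSpec,
    PMFShapeSpec,
    gen_ou_force,
    gen_window_set,
)

RT = thermal_energy(310.0)


def ou_window(z=1.0, mean=10.0, sigma2=25.0, tau=1.0, dt=0.1, n=1_000_000, seed=0):
    spec = OUForceSpec(mean_force=mean, sigma2=sigma2, tau=tau, dt=dt, n_steps=n, seed=seed)
    return ForceWindow(z=z, forces=gen_ou_force(spec), dt=dt)


class TestMeanForce:
    def test_constant_series(self):
        w = ForceWindow(z=0.0, forces=np.full(1000, 7.0), dt=0.1)
        res = mean_force(w)
        assert res.value == 7.0
        assert res.se == 0.0

    def test_discard_indexing_keeps_last_forty_percent(self):
        w = ForceWindow(z=0.0, forces=np.arange(200, dtype=float), dt=0.1)
        res = mean_force(w, discard_fraction=0.6)
        assert res.n_used == 80
        assert res.value == pytest.approx(np.arange(120, 200).mean())

    def test_ou_mean_and_block_se_match_analytic(self):
        w = ou_window(mean=10.0, sigma2=25.0, tau=1.0, dt=0.1, n=1_000_000, seed=1)
        res = mean_force(w, discard_fraction=0.6)
        t_total = res.n_used * w.dt
        analytic_se = np.sqrt(2 * 25.0 * 1.0 / t_total)
        assert abs(res.value - 10.0) < 3 * analytic_se
        assert res.se == pytest.approx(analytic_se, rel=0.20)

    def test_too_aggressive_discard_rejected(self):
        w = ForceWindow(z=0.0, forces=np.arange(4, dtype=float), dt=0.1)
        with pytest.raises(ValueError, match="remain"):
            mean_force(w, discard_fraction=0.75)


class TestFreeEnergy:
    def test_zero_forces_give_zero_profile(self):
        ws = [ForceWindow(z=z, forces=np.zeros(10), dt=1.0) for z in (0.0, 0.5, 1.0)]
        prof = free_energy_profile(ws)
        assert np.allclose(prof.values, 0.0)

    def test_constant_force_gives_linear_profile(self):
        f0 = 4.0
        zs = np.arange(0.0, 5.01, 0.5)
        prof = integrate_mean_force(zs, np.full_like(zs, f0), reference_z=5.0)
        assert np.allclose(prof.values, f0 * (5.0 - zs))

    def test_gaussian_well_recovery_within_trapezoid_bound(self):
        pmf = PMFShapeSpec("hydrophobic_well", depth=70.0, width=1.5)
        h = 0.2
        zs = np.arange(0.0, 8.0 + 1e-9, h)
        f = -pmf.derivative(zs)
        prof = integrate_mean_force(zs, f, reference_z=8.0)
        err = np.abs(prof.values - pmf.value(zs))
        zfine = np.linspace(0, 8, 4001)
        d2 = np.gradient(np.gradient(pmf.value(zfine), zfine), zfine)
        bound = h**2 / 12.0 * np.abs(d2).max() * 8.0
        assert err.max() <= bound

    def test_duplicate_windows_rejected(self):
        ws = [ForceWindow(z=1.0, forces=np.zeros(10), dt=1.0) for _ in range(2)]
        with pytest.raises(ValueError, match="duplicate"):
            free_energy_profile(ws)

    def test_error_propagation_grows_away_from_reference(self):
        zs = np.arange(0.0, 2.01, 0.5)
        prof = integrate_mean_force(zs, np.zeros_like(zs), np.ones_like(zs), reference_z=2.0)
        assert prof.errors[-1] == 0.0
        assert np.all(np.diff(prof.errors) <= 1e-12)  # monotone toward z=0


class TestDiffusion:
    def test_ou_window_matches_analytic_integral(self):
        # D = (RT)^2 / (sigma2 tau) = 2.577^2/100 = 0.0664 nm^2/ps
        w = ou_window(sigma2=100.0, tau=1.0, n=1_000_000, seed=2)
        res = diffusion_from_facf(w, temperature=310.0)
        assert res.usable
        assert res.value == pytest.approx(RT**2 / 100.0, rel=0.10)

    @pytest.mark.parametrize("factor_sigma, factor_tau", [(2.0, 1.0), (1.0, 2.0)])
    def test_scaling_halves_diffusion(self, factor_sigma, factor_tau):
        base = diffusion_from_facf(ou_window(sigma2=50.0, tau=1.0, n=400_000, seed=3))
        scaled = diffusion_from_facf(
            ou_window(sigma2=50.0 * factor_sigma, tau=factor_tau, n=400_000, seed=3)
        )
        assert scaled.value / base.value == pytest.approx(0.5, rel=0.12)

    def test_error_bar_brackets_truth(self):
        w = ou_window(sigma2=100.0, tau=1.0, n=400_000, seed=4)
        res = diffusion_from_facf(w)
        assert np.isfinite(res.se) and res.se > 0
        assert abs(res.value - RT**2 / 100.0) < 5 * max(res.se, 0.001 * res.value)


class TestPartition:
    def test_zero_free_energy_gives_unity(self):
        prof = Profile.constant(0.0, np.linspace(0, 1, 5), "dG", "kJ/mol")
        assert np.allclose(partition_profile(prof).values, 1.0)

    def test_minus_rt_gives_e(self):
        prof = Profile.constant(-RT, np.linspace(0, 1, 5), "dG", "kJ/mol")
        assert np.allclose(partition_profile(prof, 310.0).values, np.e)

    def test_ten_kj_barrier(self):
        prof = Profile.constant(10.0, np.linspace(0, 1, 3), "dG", "kJ/mol")
        assert partition_profile(prof, 310.0).values[0] == pytest.approx(
            np.exp(-10.0 / RT), rel=1e-12
        )
        assert partition_profile(prof, 310.0).values[0] == pytest.approx(0.0207, abs=0.0005)


class TestSymmetrize:
    def test_output_is_even_with_doubled_span(self):
        z = np.arange(0.0, 2.01, 0.5)
        prof = Profile(z=z, values=z**2, errors=0.1 * z, quantity="dG")
        sym = symmetrize(prof)
        assert len(sym) == 2 * len(prof) - 1
        assert np.allclose(sym.values, sym.values[::-1])
        assert np.allclose(sym.errors, sym.errors[::-1])
        assert sym.span == (-2.0, 2.0)

    def test_integral_doubles_against_quadrature_oracle(self):
        z = np.linspace(0.0, 3.0, 31)
        prof = Profile(z=z, values=np.cos(z) + 2.0, quantity="R")
        sym = symmetrize(prof)
        half = np.trapezoid(prof.values, prof.z)
        assert np.trapezoid(sym.values, sym.z) == pytest.approx(2 * half, rel=1e-12)

    def test_profile_not_starting_at_zero_rejected(self):
        prof = Profile(z=np.array([0.5, 1.0]), values=np.zeros(2))
        with pytest.raises(ValueError, match="z = 0"):
            symmetrize(prof)


class TestResistance:
    def test_pointwise_reciprocal(self):
        z = np.linspace(0, 1, 5)
        K = Profile.constant(1.0, z, "K")
        D = Profile.constant(0.05, z, "D")
        assert np.allclose(resistance_profile(K, D).values, 20.0)

    def test_deep_well_lowers_resistance_interior_barrier_raises_it(self):
        z = np.linspace(-8, 8, 81)
        D = Profile.constant(0.05, z, "D")
        well = PMFShapeSpec("hydrophobic_well", depth=70.0)
        barrier = PMFShapeSpec(
            "headgroup_minimum_interior_barrier", depth=10.0, height=30 * RT,
            headgroup_position=3.0,
        )
        r_bulk = 20.0
        for pmf, compare in ((well, np.less), (barrier, np.greater)):
            dG = Profile(z=z, values=pmf.value(z), quantity="dG")
            r = resistance_profile(partition_profile(dG), D)
            center = np.argmin(np.abs(z))
            assert compare(r.values[center], r_bulk)

    def test_grid_mismatch_rejected(self):
        K = Profile.constant(1.0, np.linspace(0, 1, 5), "K")
        D = Profile.constant(0.05, np.linspace(0, 1, 6), "D")
        with pytest.raises(ValueError, match="identical z grids"):
            resistance_profile(K, D)


class TestPermeability:
    def test_closed_form_flat_membrane(self):
        # K=1, D=D0 over thickness d: P = D0/d exactly
        z = np.linspace(0.0, 10.0, 51)
        R = Profile.constant(1.0 / 0.05, z, "R", "ps/nm^2")
        res = permeability(R, n_boot=0)
        assert res.P_nm_per_ps == pytest.approx(0.005, rel=1e-9)
        assert res.P == pytest.approx(500.0, rel=1e-9)

    def test_gaussian_barrier_matches_fine_quadrature(self):
        pmf = PMFShapeSpec("headgroup_minimum_interior_barrier", depth=0.0,
                           height=10 * RT, headgroup_position=3.0)
        z = np.linspace(-8, 8, 3201)
        dG = Profile(z=z, values=pmf.value(z), quantity="dG")
        R = resistance_profile(partition_profile(dG), Profile.constant(0.05, z, "D"))
        res = permeability(R, n_boot=0)
        oracle_inv, _ = integrate.quad(
            lambda s: np.exp(pmf.value(s) / RT) / 0.05, -8, 8, limit=400
        )
        assert res.P_nm_per_ps == pytest.approx(1.0 / oracle_inv, rel=1e-3)

    def test_unit_round_trip(self):
        z = np.linspace(0.0, 10.0, 11)
        R = Profile.constant(20.0, z, "R")
        res = permeability(R, n_boot=0)
        assert res.P == res.P_nm_per_ps * CM_PER_S_PER_NM_PER_PS

    def test_empty_range_rejected(self):
        z = np.linspace(0.0, 10.0, 11)
        R = Profile.constant(20.0, z, "R")
        with pytest.raises(ValueError, match="empty integration range"):
            permeability(R, bounds=(5.0, 5.0))

    def test_barrier_monotonically_depresses_permeability(self):
        z = np.linspace(-8, 8, 161)
        D = Profile.constant(0.05, z, "D")
        p_values = []
        for height_rt in (0.0, 5.0, 10.0, 20.0, 30.0):
            pmf = PMFShapeSpec(
                "headgroup_minimum_interior_barrier", depth=0.0,
                height=height_rt * RT, headgroup_position=3.0,
            )
            dG = Profile(z=z, values=pmf.value(z), quantity="dG")
            R = resistance_profile(partition_profile(dG), D)
            p_values.append(permeability(R, n_boot=0).P)
        assert np.all(np.diff(p_values) < 0)


class TestPipeline:
    def test_reference_rechoice_shifts_dg_by_constant_and_preserves_p(self):
        zs = np.arange(0.0, 8.0 + 1e-9, 0.2)
        pmf = PMFShapeSpec("hydrophobic_well", depth=30.0)
        f = -pmf.derivative(zs)
        prof_bulk = integrate_mean_force(zs, f, reference_z=8.0)
        prof_mid = integrate_mean_force(zs, f, reference_z=4.0)
        shift = prof_mid.values - prof_bulk.values
        assert np.allclose(shift, shift[0])
        # re-reference to bulk and the permeabilities coincide exactly
        rezeroed = prof_mid.with_values(prof_mid.values - prof_mid.values[-1])
        D = Profile.constant(0.05, zs, "D")
        p1 = permeability(resistance_profile(partition_profile(prof_bulk), D), n_boot=0).P
        p2 = permeability(resistance_profile(partition_profile(rezeroed), D), n_boot=0).P
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_end_to_end_recovery_from_synthetic_windows(self):
        # moderate-length windows; the tighter large-n recovery bounds are
        # exercised by the acceptance suite
        pmf = PMFShapeSpec("hydrophobic_well", depth=70.0, width=1.5)
        ws = gen_window_set(pmf, 0.05, OUDefaults(n_steps=200_000), 0.2, seed=10)
        res = run_isd(ws, n_boot=50, seed=0)
        assert np.max(np.abs(res.dG.values - pmf.value(np.abs(res.dG.z)))) < 2.0
        assert np.max(np.abs(res.D.values - 0.05) / 0.05) < 0.25
        assert res.perm.P > 0
        assert res.perm.error > 0
        # symmetry of the outputs
        assert np.allclose(res.dG.values, res.dG.values[::-1])
        assert np.allclose(res.R.values, res.R.values[::-1])

    def test_pipeline_determinism(self):
        pmf = PMFShapeSpec("flat")
        ws = gen_window_set(pmf, 0.05, OUDefaults(n_steps=20_000), 0.8, seed=11)
        r1 = run_isd(ws, n_boot=20, seed=5)
        r2 = run_isd(ws, n_boot=20, seed=5)
        assert r1.perm.P == r2.perm.P
        assert r1.perm.error == r2.perm.error
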