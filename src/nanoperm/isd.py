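"""Inhomogeneous solubility-diffusion (ISD) permeability pipeline.

From per-window constrained-force time series to the free-energy
profile dG(z), local diffusion D(z), partition coefficient K(z), local
resistance R(z), and the membrane permeability P.

The chain of estimators, for a permeant whose center-of-mass separation
from the bilayer center is constrained at z:

* mean constraint force  <F>(z), with block-averaged standard error;
* dG(z) = -integral of <F>(z') dz' from a bulk reference (so dG = 0 in
  bulk water);
* D(z) = (RT)^2 / integral_0^inf <dF(z,t) dF(z,0)> dt, the
  force-autocorrelation estimator of the local diffusion coefficient;
* K(z) = exp(-dG(z)/RT);
* R(z) = 1 / (K(z) D(z));
* 1/P = integral R(z) dz across the (symmetrized) bilayer.

All integrals use trapezoid quadrature on the window grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, fft

from .constants import CM_PER_S_PER_NM_PER_PS, DEFAULT_TEMPERATURE, thermal_energy
from .profiles import Profile

__all__ = [
    "ForceWindow",
    "MeanForceResult",
    "DiffusionResult",
    "PermeabilityResult",
    "ISDResult",
    "mean_force",
    "block_averaged_se",
    "integrate_mean_force",
    "free_energy_profile",
    "diffusion_from_facf",
    "partition_profile",
    "symmetrize",
    "resistance_profile",
    "permeability",
    "run_isd",
]

#: Default fraction of each window discarded as equilibration
#: (120 ns of a 200 ns window).
DEFAULT_DISCARD_FRACTION = 0.6


@dataclass
class ForceWindow:
    """One constrained-simulation window.

    Attributes
    ----------
    z
        Permeant--bilayer center-of-mass separation, nm (z >= 0 before
        symmetrization; the bilayer COM defines z = 0).
    forces
        Sampled z-component of the constraint force, kJ/(mol nm).
    dt
        Sampling interval of the force series, ps.
    source
        Originating file name, for provenance.
    """

    z: float
    forces: np.ndarray
    dt: float
    source: str = ""

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 1 or self.forces.size < 2:
            raise ValueError("forces must be a 1-D series with >= 2 samples")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.z < 0:
            raise ValueError("z must be >= 0 before symmetrization")

    def retained(self, discard_fraction: float = DEFAULT_DISCARD_FRACTION) -> np.ndarray:
        """The production segment after discarding leading equilibration."""
        if not 0 <= discard_fraction < 1:
            raise ValueError("discard_fraction must lie in [0, 1)")
        start = int(round(discard_fraction * self.forces.size))
        x = self.forces[start:]
        if x.size < 2:
            raise ValueError(
                f"window at z={self.z}: only {x.size} samples remain after "
                f"discarding {discard_fraction:.0%}"
            )
        return x


@dataclass
class MeanForceResult:
    value: float
    se: float
    n_used: int
    block_length: int


@dataclass
class DiffusionResult:
    value: float
    se: float
    tau_corr: float
    usable: bool


@dataclass
class PermeabilityResult:
    """Permeability with uncertainty and full unit/bounds record."""

    P: float                      # cm/s
    error: float                  # cm/s
    bounds: tuple[float, float]   # nm
    thickness: float              # nm, |bounds[1] - bounds[0]|
    temperature: float            # K
    P_nm_per_ps: float = 0.0

    def __post_init__(self) -> None:
        if self.P <= 0:
            raise ValueError("permeability must be > 0")


# ---------------------------------------------------------------------------
# Mean force
# ---------------------------------------------------------------------------

def block_averaged_se(x: np.ndarray, plateau_rtol: float = 0.05) -> tuple[float, int]:
    """Standard error of the mean of a correlated series by block averaging.

    Block lengths are doubled until the block-averaged SE changes by
    less than ``plateau_rtol`` between successive doublings, or fewer
    than two blocks would remain. Returns ``(se, block_length)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 samples for a standard error")
    prev_se = None
    block = 1
    best = (float(np.std(x, ddof=1) / np.sqrt(n)), 1)
    while n // block >= 2:
        nb = n // block
        means = x[: nb * block].reshape(nb, block).mean(axis=1)
        se = float(np.std(means, ddof=1) / np.sqrt(nb))
        best = (se, block)
        if prev_se is not None and prev_se > 0 and abs(se - prev_se) / prev_se < plateau_rtol:
            return best
        prev_se = se
        block *= 2
    return best


def mean_force(
    window: ForceWindow,
    discard_fraction: float = DEFAULT_DISCARD_FRACTION,
) -> MeanForceResult:
    """Time-averaged constraint force of one window, with block-averaged SE."""
    x = window.retained(discard_fraction)
    if np.allclose(x, x[0]):
        return MeanForceResult(value=float(x[0]), se=0.0, n_used=x.size, block_length=1)
    se, block = block_averaged_se(x)
    return MeanForceResult(value=float(x.mean()), se=se, n_used=x.size, block_length=block)


# ---------------------------------------------------------------------------
# Free energy
# ---------------------------------------------------------------------------

def integrate_mean_force(
    z: np.ndarray,
    f_mean: np.ndarray,
    f_se: np.ndarray | None = None,
    reference_z: float | None = None,
) -> Profile:
    """dG(z) = -int_ref^z <F>(z') dz' on the window grid.

    ``z`` must be strictly increasing; the reference (where dG = 0)
    defaults to the largest z, i.e. bulk water. Uncertainties assume
    independent window means and propagate the trapezoid weights.
    """
    z = np.asarray(z, dtype=float)
    f = np.asarray(f_mean, dtype=float)
    se = np.zeros_like(f) if f_se is None else np.asarray(f_se, dtype=float)
    if z.size != f.size:
        raise ValueError("z and f_mean must have equal length")
    if np.any(np.diff(z) <= 0):
        raise ValueError("z must be strictly increasing with no duplicates")
    if reference_z is None:
        reference_z = float(z[-1])
    iref = int(np.argmin(np.abs(z - reference_z)))
    if abs(z[iref] - reference_z) > 1e-9:
        raise ValueError(f"reference_z={reference_z} is not a grid point")

    cum = np.concatenate(([0.0], integrate.cumulative_trapezoid(f, z)))
    dG = -(cum - cum[iref])

    # trapezoid weights between each point and the reference
    var = np.zeros_like(dG)
    for j in range(z.size):
        lo, hi = min(iref, j), max(iref, j)
        if hi == lo:
            continue
        w = np.zeros(hi - lo + 1)
        dz = np.diff(z[lo : hi + 1])
        w[:-1] += dz / 2.0
        w[1:] += dz / 2.0
        var[j] = float(np.sum((w * se[lo : hi + 1]) ** 2))
    return Profile(z=z, values=dG, errors=np.sqrt(var), quantity="dG", units="kJ/mol")


def free_energy_profile(
    windows: list[ForceWindow],
    reference_z: float | None = None,
    discard_fraction: float = DEFAULT_DISCARD_FRACTION,
) -> Profile:
    """Free-energy profile from a set of constrained windows."""
    if not windows:
        raise ValueError("need at least one window")
    order = np.argsort([w.z for w in windows])
    ws = [windows[i] for i in order]
    zs = np.array([w.z for w in ws])
    if np.any(np.diff(zs) == 0):
        raise ValueError("duplicate window z values")
    results = [mean_force(w, discard_fraction) for w in ws]
    f = np.array([r.value for r in results])
    se = np.array([r.se for r in results])
    return integrate_mean_force(zs, f, se, reference_z)


# ---------------------------------------------------------------------------
# Local diffusion from the force autocorrelation function
# ---------------------------------------------------------------------------

def _autocovariance(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (1/n) autocovariance of ``x`` up to ``max_lag`` via FFT."""
    n = x.size
    d = x - x.mean()
    m = fft.next_fast_len(2 * n)
    f = fft.rfft(d, m)
    acov = fft.irfft(f * np.conj(f), m)[: max_lag + 1] / n
    return acov


def _acf_time_integral(
    acov: np.ndarray, dt: float, cutoff_tau_factor: float = 10.0
) -> tuple[float, float]:
    """Integrate an autocovariance over time.

    Integrates by trapezoid up to the first zero crossing. When no
    crossing occurs within ``cutoff_tau_factor`` estimated correlation
    times, the integral is truncated there and closed with a fitted
    exponential tail. Returns ``(integral, tau_estimate)``.
    """
    if acov[0] <= 0:
        return 0.0, 0.0
    # correlation-time estimate: first lag where ACF drops below 1/e
    below = np.nonzero(acov < acov[0] / np.e)[0]
    tau_est = float(below[0]) * dt if below.size else float(acov.size - 1) * dt
    tau_est = max(tau_est, dt)

    neg = np.nonzero(acov <= 0)[0]
    k_tau = min(int(np.ceil(cutoff_tau_factor * tau_est / dt)), acov.size - 1)
    if neg.size and neg[0] <= k_tau:
        k_cut = int(neg[0])
        return float(np.trapezoid(acov[: k_cut + 1], dx=dt)), tau_est
    # no crossing: integrate to the cutoff, close with an exponential tail
    head = float(np.trapezoid(acov[: k_tau + 1], dx=dt))
    tail = float(acov[k_tau]) * tau_est
    return head + tail, tau_est


def diffusion_from_facf(
    window: ForceWindow,
    temperature: float = DEFAULT_TEMPERATURE,
    discard_fraction: float = DEFAULT_DISCARD_FRACTION,
    n_error_segments: int = 5,
    cutoff_tau_factor: float = 10.0,
) -> DiffusionResult:
    """Local diffusion coefficient D = (RT)^2 / int <dF(t) dF(0)> dt.

    The force-fluctuation autocorrelation is integrated up to its first
    zero crossing (exponential-tail fallback, see
    :func:`_acf_time_integral`). The error is estimated by splitting the
    retained segment into ``n_error_segments`` contiguous pieces and
    taking the SE of the per-segment estimates. Windows whose ACF
    integral is non-positive are flagged unusable.
    """
    rt = thermal_energy(temperature)
    x = window.retained(discard_fraction)
    if x.size < 100:
        warnings.warn(
            f"window at z={window.z}: only {x.size} retained samples; "
            "diffusion estimate will be noisy"
        )
    max_lag = x.size // 2
    acov = _autocovariance(x, max_lag)
    integral, tau_est = _acf_time_integral(acov, window.dt, cutoff_tau_factor)
    if integral <= 0:
        return DiffusionResult(value=np.nan, se=np.nan, tau_corr=tau_est, usable=False)
    d_value = rt**2 / integral

    # segment resampling for the error bar
    seg_estimates = []
    seg_len = x.size // n_error_segments
    if seg_len >= 50:
        for i in range(n_error_segments):
            seg = x[i * seg_len : (i + 1) * seg_len]
            sacov = _autocovariance(seg, seg.size // 2)
            s_int, _ = _acf_time_integral(sacov, window.dt, cutoff_tau_factor)
            if s_int > 0:
                seg_estimates.append(rt**2 / s_int)
    if len(seg_estimates) >= 2:
        se = float(np.std(seg_estimates, ddof=1) / np.sqrt(len(seg_estimates)))
    else:
        se = np.nan
    return DiffusionResult(value=float(d_value), se=se, tau_corr=tau_est, usable=True)


# ---------------------------------------------------------------------------
# Partition, symmetrization, resistance, permeability
# ---------------------------------------------------------------------------

def partition_profile(dG: Profile, temperature: float = DEFAULT_TEMPERATURE) -> Profile:
    """K(z) = exp(-dG(z)/RT); K = 1 wherever dG = 0 (bulk reference)."""
    rt = thermal_energy(temperature)
    k = np.exp(-dG.values / rt)
    err = k * dG.errors / rt  # first-order propagation
    return Profile(z=dG.z.copy(), values=k, errors=err, quantity="K", units="1")


def symmetrize(profile: Profile) -> Profile:
    """Mirror a one-leaflet profile on [0, z_max] about z = 0.

    The bilayer is treated as symmetric: the value and uncertainty at
    -z equal those at +z. The output spans [-z_max, +z_max] with the
    center point shared.
    """
    if abs(profile.z[0]) > 1e-9:
        raise ValueError("profile must start at z = 0 to be symmetrized")
    z = np.concatenate((-profile.z[::-1], profile.z[1:]))
    v = np.concatenate((profile.values[::-1], profile.values[1:]))
    e = np.concatenate((profile.errors[::-1], profile.errors[1:]))
    return Profile(z=z, values=v, errors=e, quantity=profile.quantity, units=profile.units)


def resistance_profile(K: Profile, D: Profile) -> Profile:
    """Local resistance R(z) = 1 / (K(z) D(z)), in ps/nm^2.

    ``K`` and ``D`` must share the same z grid. Points with
    non-positive D are flagged with a warning and given NaN resistance
    (they are excluded from any subsequent integration).
    """
    if K.z.size != D.z.size or not np.allclose(K.z, D.z, atol=1e-9):
        raise ValueError("K and D must be tabulated on identical z grids")
    bad = ~(D.values > 0)
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} grid points with non-positive D excluded")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(bad, np.nan, 1.0 / (K.values * D.values))
        rel = np.zeros_like(r)
        ok = ~bad
        kv, dv = K.values[ok], D.values[ok]
        rel_ok = np.sqrt((K.errors[ok] / kv) ** 2 + (D.errors[ok] / dv) ** 2)
        rel[ok] = rel_ok
        err = np.where(bad, np.nan, np.abs(r) * rel)
    return Profile(z=K.z.copy(), values=r, errors=err, quantity="R", units="ps/nm^2")


def permeability(
    R: Profile,
    bounds: tuple[float, float] | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    n_boot: int = 200,
    seed: int | None = 0,
) -> PermeabilityResult:
    """Permeability from the resistance profile: 1/P = int R(z) dz.

    ``bounds`` defaults to the full profile span. The integral uses
    trapezoid quadrature on the tabulated grid (plus the exact bound
    positions if they fall between grid points). The uncertainty is a
    parametric bootstrap over the per-point resistance errors.
    """
    if bounds is None:
        bounds = R.span
    lo, hi = float(bounds[0]), float(bounds[1])
    if hi <= lo:
        raise ValueError("empty integration range")
    if lo < R.z[0] - 1e-9 or hi > R.z[-1] + 1e-9:
        raise ValueError("bounds must lie within the profile span")

    mask = (R.z >= lo - 1e-9) & (R.z <= hi + 1e-9)
    zs = R.z[mask]
    vs = R.values[mask]
    es = R.errors[mask]
    keep = np.isfinite(vs)
    zs, vs, es = zs[keep], vs[keep], es[keep]
    if zs.size < 2:
        raise ValueError("fewer than two usable resistance points in range")

    inv_p = float(np.trapezoid(vs, zs))  # ps/nm
    if inv_p <= 0:
        raise ValueError("non-positive resistance integral")
    p_nm_ps = 1.0 / inv_p

    err_cm_s = 0.0
    if n_boot > 0 and np.any(es > 0):
        rng = np.random.default_rng(seed)
        draws = vs + es * rng.standard_normal((n_boot, vs.size))
        inv_ps = np.trapezoid(draws, zs, axis=1)
        inv_ps = inv_ps[inv_ps > 0]
        if inv_ps.size >= 2:
            err_cm_s = float(np.std(1.0 / inv_ps, ddof=1)) * CM_PER_S_PER_NM_PER_PS

    return PermeabilityResult(
        P=p_nm_ps * CM_PER_S_PER_NM_PER_PS,
        error=err_cm_s,
        bounds=(lo, hi),
        thickness=hi - lo,
        temperature=temperature,
        P_nm_per_ps=p_nm_ps,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class ISDResult:
    """Bundle of symmetrized profiles and the permeability."""

    dG: Profile
    D: Profile
    K: Profile
    R: Profile
    perm: PermeabilityResult
    window_table: pd.DataFrame = field(repr=False, default=None)


def _interp_nan(z: np.ndarray, v: np.ndarray) -> np.ndarray:
    bad = ~np.isfinite(v)
    if bad.any():
        if bad.all():
            raise ValueError("no usable diffusion estimates in any window")
        v = v.copy()
        v[bad] = np.interp(z[bad], z[~bad], v[~bad])
    return v


def run_isd(
    windows: list[ForceWindow],
    temperature: float = DEFAULT_TEMPERATURE,
    discard_fraction: float = DEFAULT_DISCARD_FRACTION,
    bounds_mode: str = "full",
    bilayer_thickness: float | None = None,
    n_boot: int = 200,
    seed: int | None = 0,
) -> ISDResult:
    """Full pipeline: windows -> dG, D, K, R -> permeability.

    Windows cover one leaflet (z >= 0); profiles are mirrored to
    [-z_max, z_max] before integration. ``bounds_mode`` is "full"
    (integrate the whole sampled span, the default) or "bilayer"
    (integrate only [-d/2, +d/2] with d = ``bilayer_thickness``).
    The permeability uncertainty is a parametric bootstrap at the
    window level: per-window mean forces and diffusion coefficients are
    resampled within their standard errors and the whole profile chain
    is rebuilt for each draw.
    """
    if bounds_mode not in ("full", "bilayer"):
        raise ValueError("bounds_mode must be 'full' or 'bilayer'")
    if bounds_mode == "bilayer" and not bilayer_thickness:
        raise ValueError("bilayer_thickness required for bounds_mode='bilayer'")

    order = np.argsort([w.z for w in windows])
    ws = [windows[i] for i in order]
    zs = np.array([w.z for w in ws])
    if np.any(np.diff(zs) == 0):
        raise ValueError("duplicate window z values")

    mf = [mean_force(w, discard_fraction) for w in ws]
    df = [diffusion_from_facf(w, temperature, discard_fraction) for w in ws]
    f_mean = np.array([r.value for r in mf])
    f_se = np.array([r.se for r in mf])
    d_val = _interp_nan(zs, np.array([r.value for r in df]))
    d_se = np.array([r.se if np.isfinite(r.se) else 0.0 for r in df])

    def build(fm: np.ndarray, dv: np.ndarray):
        dG_half = integrate_mean_force(zs, fm, f_se)
        d_half = Profile(z=zs, values=dv, errors=d_se, quantity="D", units="nm^2/ps")
        dG_s = symmetrize(dG_half)
        d_s = symmetrize(d_half)
        k_s = partition_profile(dG_s, temperature)
        r_s = resistance_profile(k_s, d_s)
        return dG_s, d_s, k_s, r_s

    dG_s, d_s, k_s, r_s = build(f_mean, d_val)
    if bounds_mode == "bilayer":
        h = bilayer_thickness / 2.0
        bounds = (max(-h, r_s.z[0]), min(h, r_s.z[-1]))
    else:
        bounds = r_s.span
    perm = permeability(r_s, bounds, temperature, n_boot=0)

    # window-level parametric bootstrap of P
    p_err = 0.0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        p_draws = []
        for _ in range(n_boot):
            fm = f_mean + f_se * rng.standard_normal(f_mean.size)
            dv = d_val + d_se * rng.standard_normal(d_val.size)
            if np.any(dv <= 0):
                continue
            _, _, _, r_b = build(fm, dv)
            try:
                p_draws.append(permeability(r_b, bounds, temperature, n_boot=0).P)
            except ValueError:
                continue
        if len(p_draws) >= 2:
            p_err = float(np.std(p_draws, ddof=1))
    perm = PermeabilityResult(
        P=perm.P,
        error=p_err,
        bounds=perm.bounds,
        thickness=perm.thickness,
        temperature=temperature,
        P_nm_per_ps=perm.P_nm_per_ps,
    )

    table = pd.DataFrame(
        {
            "z_nm": zs,
            "mean_force": f_mean,
            "mean_force_se": f_se,
            "D_nm2_ps": d_val,
            "D_se": d_se,
            "tau_corr_ps": [r.tau_corr for r in df],
            "usable": [r.usable for r in df],
            "block_length": [r.block_length for r in mf],
        }
    )
    return ISDResult(dG=dG_s, D=d_s, K=k_s, R=r_s, perm=perm, window_table=table)
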