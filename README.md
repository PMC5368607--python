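# nanoperm

Permeability analysis of ligand-coated gold nanoparticles across a model
skin lipid bilayer, built around the inhomogeneous solubility-diffusion
(ISD) model.

The outermost skin layer (the stratum corneum) owes its barrier function
to a lipid matrix of ceramides, cholesterol and free fatty acids. Whether
a nanoparticle crosses that matrix is governed by its free energy of
permeation dG(z) and its local diffusion coefficient D(z) along the
bilayer normal z. In constrained coarse-grained simulations both are
estimated from the constraint-force time series F(z, t) recorded at a
ladder of fixed particle–bilayer separations ("windows"):

    dG(z)  = -∫ ⟨F⟩(z') dz'               (bulk water reference, dG = 0)
    D(z)   = (RT)² / ∫₀^∞ ⟨δF(z,t) δF(z,0)⟩ dt
    K(z)   = exp(-dG(z)/RT)
    R(z)   = 1 / (K(z) D(z))
    1/P    = ∫ R(z) dz                     (symmetric bilayer, P in cm/s)

`nanoperm` implements this chain with uncertainties (block averaging,
ACF segment resampling, window-level bootstrap), plus:

- **synthetic data** — Ornstein–Uhlenbeck constraint-force windows wired
  to analytic free-energy shapes and target diffusion profiles, so every
  estimator can be validated against known ground truth without
  microsecond MD runs;
- **nanoparticle builder** — FCC gold cores, coordination-based surface
  detection, farthest-point dodecanethiol grafting, terminal-bead
  charging (σ = Ne/S) and bilayer-box assembly with desolvation and
  counter-ions;
- **bilayer metrics** — projected area per lipid, area-compressibility
  modulus, chain order parameters Sz and ⟨Sn⟩, periodic minimum-image
  radial distribution functions, leaflet assignment;
- **Langevin oracle** — an independent overdamped Brownian-dynamics
  permeability estimate from steady-state flux, used to cross-check the
  ISD integral.

## Worked example

Recover the permeability of a 3 nm-like neutral hydrophobic particle
from synthetic constrained windows (135 kJ/mol interior well, bulk
diffusivity 0.08 nm²/ps, 40 windows at 0.2 nm spacing):

```python
import numpy as np
from nanoperm import PMFShapeSpec, OUDefaults, gen_window_set, run_isd

pmf = PMFShapeSpec("hydrophobic_well", depth=135.0)
windows = gen_window_set(
    pmf, d_true=0.08, ou=OUDefaults(n_steps=200_000), window_spacing=0.2, seed=1
)
result = run_isd(windows, temperature=310.0, seed=1)
dg_err = np.max(np.abs(result.dG.values - pmf.value(np.abs(result.dG.z))))
print(f"windows generated      : {len(windows)}")
print(f"dG at bilayer center   : {result.dG(0.0):.1f} kJ/mol")
print(f"max |dG - dG_true|     : {dg_err:.2f} kJ/mol")
print(f"D in bulk water        : {result.D(7.8):.4f} nm^2/ps")
print(f"permeability P         : {result.perm.P:.1f} +/- {result.perm.error:.1f} cm/s")
```

prints

```
windows generated      : 40
dG at bilayer center   : -134.7 kJ/mol
max |dG - dG_true|     : 0.32 kJ/mol
D in bulk water        : 0.0799 nm^2/ps
permeability P         : 1190.2 +/- 33.5 cm/s
```

The recovered free-energy profile matches the analytic ground truth to
a third of a kJ/mol, and the permeability is dominated by the water-
phase resistance (the deep hydrophobic well contributes almost none) —
the mechanism by which diffusivity, not well depth, sets the size
ordering of neutral-particle permeability. A charged-particle shape (a
headgroup minimum plus a +30 RT interior barrier) suppresses P by more
than ten orders of magnitude.

The same stages are scriptable from the shell:

```sh
nanoperm run-all --preset 3nm --seed 1 --out runs/3nm
nanoperm build-np --diameter 3 --charge +1 --out runs/np3
nanoperm oracle --profiles-dir runs/3nm --out runs/3nm/oracle
```

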