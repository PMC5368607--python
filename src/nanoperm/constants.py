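"""Physical constants and unit conversions used throughout the package.

Internal unit system: length nm, time ps, energy kJ/mol, temperature K,
force kJ/(mol nm), diffusion nm^2/ps, permeability reported in cm/s.
"""

#: Gas constant in kJ mol^-1 K^-1.
R_GAS = 8.314462618e-3

#: Boltzmann constant in J K^-1 (used for area compressibility in SI).
KB_J = 1.380649e-23

#: Conversion factor: 1 nm/ps = 1e5 cm/s.
CM_PER_S_PER_NM_PER_PS = 1.0e5

#: Default temperature (skin temperature), K.
DEFAULT_TEMPERATURE = 310.0


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT in kJ/mol at the given temperature."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return R_GAS * temperature
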