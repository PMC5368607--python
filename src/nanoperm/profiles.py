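"""Quantities tabulated on a z grid along the bilayer normal.

A :class:`Profile` holds one physical quantity -- free energy dG(z),
local diffusion D(z), partition coefficient K(z) or local resistance
R(z) -- on a strictly increasing grid of z positions (nm, measured from
the bilayer center of mass), together with a per-point 1-sigma
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Profile"]


@dataclass
class Profile:
    """A quantity tabulated on a z grid with per-point uncertainty.

    Parameters
    ----------
    z
        Grid positions in nm, strictly increasing.
    values
        Quantity values at each grid point.
    errors
        1-sigma uncertainties (>= 0); defaults to zeros.
    quantity
        Short tag identifying the quantity ("dG", "D", "K", "R", ...).
    units
        Unit string, e.g. "kJ/mol", "nm^2/ps", "ps/nm^2".
    """

    z: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None
    quantity: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.errors is None:
            self.errors = np.zeros_like(self.values)
        else:
            self.errors = np.asarray(self.errors, dtype=float)
        if self.z.ndim != 1:
            raise ValueError("z must be one-dimensional")
        if self.z.shape != self.values.shape or self.z.shape != self.errors.shape:
            raise ValueError("z, values and errors must have identical shapes")
        if self.z.size >= 2 and not np.all(np.diff(self.z) > 0):
            raise ValueError("z must be strictly increasing")
        if np.any(self.errors < 0):
            raise ValueError("errors must be >= 0")

    # -- convenience -------------------------------------------------
    def __len__(self) -> int:
        return self.z.size

    def __call__(self, zq) -> np.ndarray:
        """Linear interpolation of the values at query positions."""
        return np.interp(zq, self.z, self.values)

    def error_at(self, zq) -> np.ndarray:
        return np.interp(zq, self.z, self.errors)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.z[0]), float(self.z[-1])

    def with_values(self, values, errors=None, quantity=None, units=None) -> "Profile":
        return Profile(
            z=self.z.copy(),
            values=np.asarray(values, dtype=float),
            errors=None if errors is None else np.asarray(errors, dtype=float),
            quantity=self.quantity if quantity is None else quantity,
            units=self.units if units is None else units,
        )

    @classmethod
    def constant(cls, value: float, z, quantity: str = "", units: str = "") -> "Profile":
        z = np.asarray(z, dtype=float)
        return cls(z=z, values=np.full_like(z, float(value)), quantity=quantity, units=units)
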