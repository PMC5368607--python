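"""Text I/O: xvg-style force series, window manifests, profile tables.

Force series are two-column text (time in ps, force in kJ/(mol nm))
with '#' and '@' comment lines tolerated. A window set is one file per
window plus a TSV manifest (window index, z in nm, file name).
Profiles are written as TSV tables (z, value, error).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .isd import ForceWindow
from .profiles import Profile

__all__ = [
    "write_xvg",
    "read_xvg",
    "write_window_set",
    "read_window_set",
    "write_profile",
    "read_profile",
]


def write_xvg(path, times: np.ndarray, values: np.ndarray, title: str = "") -> None:
    path = Path(path)
    with path.open("w") as fh:
        if title:
            fh.write(f"# {title}\n")
        fh.write('@    xaxis  label "Time (ps)"\n')
        fh.write('@    yaxis  label "Force (kJ mol\\S-1\\N nm\\S-1\\N)"\n')
        for t, v in zip(times, values):
            fh.write(f"{t:.6g}\t{v:.8g}\n")


def read_xvg(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column time series, skipping '#'/'@' comment lines."""
    times, values = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line[0] in "#@":
            continue
        parts = line.split()
        times.append(float(parts[0]))
        values.append(float(parts[1]))
    if len(times) < 2:
        raise ValueError(f"{path}: fewer than two data rows")
    return np.asarray(times), np.asarray(values)


def write_window_set(outdir, windows: list[ForceWindow]) -> Path:
    """One xvg file per window plus a TSV manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.xvg"
        times = np.arange(w.forces.size) * w.dt
        write_xvg(outdir / fname, times, w.forces, title=f"constraint force, z = {w.z:.3f} nm")
        rows.append({"window": i, "z_nm": w.z, "file": fname})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_window_set(manifest_path) -> list[ForceWindow]:
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t")
    for col in ("z_nm", "file"):
        if col not in table.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    windows = []
    for _, row in table.iterrows():
        fpath = manifest_path.parent / str(row["file"])
        times, forces = read_xvg(fpath)
        dts = np.diff(times)
        if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6):
            raise ValueError(f"{fpath}: non-uniform or non-increasing time column")
        windows.append(
            ForceWindow(z=float(row["z_nm"]), forces=forces, dt=float(dts[0]), source=str(fpath))
        )
    return windows


def write_profile(path, profile: Profile) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# quantity: {profile.quantity}\n# units: {profile.units}\n")
        fh.write("z_nm\tvalue\terror\n")
        for z, v, e in zip(profile.z, profile.values, profile.errors):
            fh.write(f"{z:.6g}\t{v:.10g}\t{e:.6g}\n")


def read_profile(path) -> Profile:
    path = Path(path)
    quantity = units = ""
    for line in path.read_text().splitlines():
        if line.startswith("# quantity:"):
            quantity = line.split(":", 1)[1].strip()
        elif line.startswith("# units:"):
            units = line.split(":", 1)[1].strip()
    table = pd.read_csv(path, sep="\t", comment="#")
    return Profile(
        z=table["z_nm"].to_numpy(),
        values=table["value"].to_numpy(),
        errors=table["error"].to_numpy(),
        quantity=quantity,
        units=units,
    )
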