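"""Bead-configuration container and coordinate file I/O.

Coordinates are stored in nm inside an orthorhombic box with bead class
labels drawn from {head, tail, water, np, ion}. Reading and writing of
GRO (nm) and PDB (Angstrom) files goes through MDAnalysis; bead classes
are assigned from atom/residue names via a small mapping that can be
loaded from a two-column text file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

__all__ = [
    "BilayerFrame",
    "DEFAULT_CLASS_MAP",
    "load_class_map",
    "write_frame",
    "read_frame",
]

#: atom-name (first) or residue-name (fallback) -> bead class
DEFAULT_CLASS_MAP = {
    "HD": "head",
    "TL": "tail",
    "W": "water",
    "AU": "np",
    "SAU": "np",
    "CT": "np",
    "ION": "ion",
    "LIP": "tail",
    "AUN": "np",
    "AUC": "np",
}

_CLASS_TO_NAME = {"head": "HD", "tail": "TL", "water": "W", "np": "AU", "ion": "ION"}
_CLASS_TO_RESNAME = {"head": "LIP", "tail": "LIP", "water": "W", "np": "AUN", "ion": "ION"}


@dataclass
class BilayerFrame:
    """One bead configuration.

    Attributes
    ----------
    positions
        (N, 3) bead coordinates, nm.
    labels
        (N,) bead class labels: head / tail / water / np / ion.
    box
        Orthorhombic box edges (Lx, Ly, Lz), nm.
    chains
        Ordered bead-index arrays, one per lipid chain (head first).
    leaflets
        Optional per-chain leaflet labels (+1 upper / -1 lower).
    charges
        Optional per-bead charges in e.
    """

    positions: np.ndarray
    labels: np.ndarray
    box: np.ndarray
    chains: list = field(default_factory=list)
    leaflets: np.ndarray | None = None
    charges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.labels = np.asarray(self.labels)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.labels.shape[0] != self.positions.shape[0]:
            raise ValueError("labels and positions disagree in length")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        n = self.positions.shape[0]
        for c in self.chains:
            c = np.asarray(c)
            if c.min() < 0 or c.max() >= n:
                raise ValueError("chain topology references invalid bead ids")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def select(self, *classes: str) -> np.ndarray:
        """Positions of all beads whose class is in ``classes``."""
        mask = np.isin(self.labels, classes)
        return self.positions[mask]

    def wrapped(self) -> np.ndarray:
        """Positions wrapped into [0, box) under periodic boundaries."""
        return np.mod(self.positions, self.box)


def load_class_map(path) -> dict:
    """Read a name -> class mapping from two-column whitespace text."""
    mapping = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, cls = line.split()[:2]
        mapping[name] = cls
    return mapping


def _to_universe(frame: BilayerFrame) -> mda.Universe:
    n = frame.n_beads
    # residues: one per chain; every non-chain bead gets its own residue
    resindex = np.full(n, -1, dtype=int)
    res = 0
    for chain in frame.chains:
        resindex[np.asarray(chain)] = res
        res += 1
    for i in range(n):
        if resindex[i] < 0:
            resindex[i] = res
            res += 1
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=res,
        atom_resindex=resindex,
        residue_segindex=np.zeros(res, dtype=int),
        trajectory=True,
    )
    names = [_CLASS_TO_NAME.get(str(c), "X") for c in frame.labels]
    resnames = [""] * res
    for i in range(n):
        resnames[resindex[i]] = _CLASS_TO_RESNAME.get(str(frame.labels[i]), "UNK")
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, res + 1))
    u.atoms.positions = frame.positions * 10.0  # nm -> Angstrom
    u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
    return u


def write_frame(frame: BilayerFrame, path) -> None:
    """Write a frame to GRO (nm) or PDB (Angstrom), by file extension."""
    u = _to_universe(frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_frame(path, class_map: dict | None = None) -> BilayerFrame:
    """Read a GRO or PDB file into a :class:`BilayerFrame`.

    Bead classes come from ``class_map`` (atom name first, residue name
    as fallback; unknown names become "tail" with a warning). Chains
    are reconstructed from residues containing more than one head/tail
    bead, in atom order.
    """
    class_map = class_map or DEFAULT_CLASS_MAP
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    pos = u.atoms.positions / 10.0  # Angstrom -> nm
    if u.dimensions is None or np.any(u.dimensions[:3] <= 0):
        raise ValueError(f"{path}: no valid box found")
    box = np.asarray(u.dimensions[:3], dtype=float) / 10.0

    labels = []
    unknown = set()
    for atom in u.atoms:
        name = str(atom.name).strip()
        resname = str(atom.resname).strip()
        if name in class_map:
            labels.append(class_map[name])
        elif resname in class_map:
            labels.append(class_map[resname])
        else:
            unknown.add(name)
            labels.append("tail")
    if unknown:
        warnings.warn(f"unmapped bead names treated as tail: {sorted(unknown)}")
    labels = np.array(labels)

    chains = []
    for residue in u.residues:
        ids = residue.atoms.indices
        if ids.size > 1 and np.all(np.isin(labels[ids], ("head", "tail"))):
            chains.append(np.asarray(ids))
    return BilayerFrame(positions=pos, labels=labels, box=box, chains=chains)
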