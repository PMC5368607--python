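"""Structural observables of the bilayer from bead configurations.

Implements the projected area per lipid, the area-compressibility
modulus from box-area fluctuations, chain order parameters against the
bilayer normal, a periodic minimum-image radial distribution function,
and leaflet assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import KB_J
from .frames import BilayerFrame

__all__ = [
    "projected_area_per_lipid",
    "area_compressibility",
    "AreaCompressibility",
    "order_parameter",
    "OrderParameterResult",
    "rdf",
    "RDFResult",
    "leaflet_assign",
]


# ---------------------------------------------------------------------------
# Projected area and compressibility
# ---------------------------------------------------------------------------

def projected_area_per_lipid(
    frames: list[BilayerFrame], n_lipids_per_leaflet: int
) -> tuple[float, float]:
    """Time-averaged box XY area per leaflet lipid, (mean, SE) in nm^2.

    This is a projected (not tessellated) area: membrane area stored
    out of plane by undulation shrinks it relative to a flat bilayer
    of the same true area.
    """
    if not frames:
        raise ValueError("need at least one frame")
    if n_lipids_per_leaflet <= 0:
        raise ValueError("n_lipids_per_leaflet must be > 0")
    areas = np.array([f.box[0] * f.box[1] for f in frames]) / n_lipids_per_leaflet
    se = float(np.std(areas, ddof=1) / np.sqrt(areas.size)) if areas.size > 1 else 0.0
    return float(areas.mean()), se


@dataclass
class AreaCompressibility:
    value: float      # mN/m; meaningful only if defined
    defined: bool
    mean_area: float  # nm^2
    var_area: float   # nm^4


def area_compressibility(areas, temperature: float) -> AreaCompressibility:
    """Area-compressibility modulus from box-area fluctuations.

    K_A = k_B T <A> / Var(A), converted to mN/m (areas in nm^2). A
    vanishing variance makes the modulus undefined (infinitely stiff
    as measured); the result is flagged rather than raised.
    """
    a = np.asarray(areas, dtype=float)
    if a.size < 2:
        raise ValueError("need >= 2 area samples")
    if np.any(a <= 0):
        raise ValueError("areas must be > 0")
    mean = float(a.mean())
    var = float(a.var(ddof=1))
    if var == 0.0:
        return AreaCompressibility(value=np.inf, defined=False, mean_area=mean, var_area=0.0)
    # kB T [J] * <A>/Var(A) [1/nm^2] -> J/m^2 via 1e18, -> mN/m via 1e3
    ka = KB_J * temperature * mean / var * 1.0e21
    return AreaCompressibility(value=float(ka), defined=True, mean_area=mean, var_area=var)


# ---------------------------------------------------------------------------
# Order parameters
# ---------------------------------------------------------------------------

@dataclass
class OrderParameterResult:
    """Per-bond and overall chain order against the z axis.

    ``per_bond`` holds Sz = <(3 cos^2 theta - 1)/2> for each bond index
    along the chains (bond 0 joins the head bead to the first tail
    bead), averaged over lipids and frames; ``overall`` averages all
    tail--tail bonds (<Sn>). Values lie in [-0.5, 1].
    """

    per_bond: np.ndarray
    per_bond_counts: np.ndarray
    overall: float


def _min_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    return vec - box * np.round(vec / box)


def order_parameter(frames) -> OrderParameterResult:
    """Bond order parameters Sz and the overall tail order <Sn>.

    Each consecutive bond vector b along a chain contributes
    (3 cos^2 theta - 1)/2 with theta the angle between b (minimum
    image) and the z axis. Chains with fewer than two beads are
    skipped with a warning.
    """
    if isinstance(frames, BilayerFrame):
        frames = [frames]
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    tail_sum = 0.0
    tail_n = 0
    skipped = 0
    for frame in frames:
        for chain in frame.chains:
            chain = np.asarray(chain)
            if chain.size < 2:
                skipped += 1
                continue
            p = frame.positions[chain]
            bonds = _min_image(np.diff(p, axis=0), frame.box)
            norms = np.linalg.norm(bonds, axis=1)
            cos2 = (bonds[:, 2] / norms) ** 2
            sz = 1.5 * cos2 - 0.5
            both_tail = (frame.labels[chain[:-1]] == "tail") & (
                frame.labels[chain[1:]] == "tail"
            )
            for k, s in enumerate(sz):
                sums[k] = sums.get(k, 0.0) + s
                counts[k] = counts.get(k, 0) + 1
            tail_sum += float(sz[both_tail].sum())
            tail_n += int(both_tail.sum())
    if skipped:
        warnings.warn(f"{skipped} chains with < 2 beads skipped")
    if not counts:
        raise ValueError("no chains with >= 2 beads")
    nb = max(counts) + 1
    per_bond = np.array([sums[k] / counts[k] for k in range(nb)])
    per_counts = np.array([counts[k] for k in range(nb)])
    overall = tail_sum / tail_n if tail_n else float(per_bond.mean())
    return OrderParameterResult(per_bond=per_bond, per_bond_counts=per_counts, overall=overall)


# ---------------------------------------------------------------------------
# Radial distribution function
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    r: np.ndarray        # bin centers, nm
    g: np.ndarray
    counts: np.ndarray   # raw ordered-pair counts per shell
    edges: np.ndarray


def rdf(
    positions_a: np.ndarray,
    positions_b: np.ndarray,
    box,
    r_max: float,
    bin_width: float,
    same: bool | None = None,
) -> RDFResult:
    """3-D radial distribution function under the minimum-image convention.

    Pair distances between selections A and B (which may be identical,
    or A may be a single point such as a particle center of mass) are
    histogrammed and normalized by ideal-gas shell counts, so g -> 1
    for uncorrelated beads. ``r_max`` must not exceed half the
    smallest box edge.
    """
    box = np.asarray(box, dtype=float)
    a = np.atleast_2d(np.asarray(positions_a, dtype=float))
    b = np.atleast_2d(np.asarray(positions_b, dtype=float))
    if r_max > box.min() / 2.0 + 1e-9:
        raise ValueError("r_max must be <= half the smallest box edge")
    if bin_width <= 0 or bin_width > r_max:
        raise ValueError("bin_width must lie in (0, r_max]")
    if same is None:
        same = a.shape == b.shape and np.allclose(a, b)

    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    if edges[-1] < r_max - 1e-12:
        edges = np.append(edges, r_max)
    tree_a = cKDTree(np.mod(a, box), boxsize=box)
    tree_b = cKDTree(np.mod(b, box), boxsize=box)
    cum = tree_a.count_neighbors(tree_b, edges)
    counts = np.diff(cum).astype(float)  # ordered pairs per shell; self pairs sit at r=0

    volume = float(np.prod(box))
    n_pairs = a.shape[0] * b.shape[0] - (a.shape[0] if same else 0)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = n_pairs * shell_vol / volume
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(r=centers, g=g, counts=counts, edges=edges)


# ---------------------------------------------------------------------------
# Leaflets
# ---------------------------------------------------------------------------

def leaflet_assign(frame: BilayerFrame, tolerance: float = 0.1) -> np.ndarray:
    """Assign each lipid chain to a leaflet by its head-bead height.

    The midplane is the mean z of all lipid (head/tail) beads; chains
    whose head bead lies above it get +1, below -1, and chains within
    ``tolerance`` nm of the midplane are flagged 0 (ambiguous). The
    assignment is invariant under rigid z translation.
    """
    if not frame.chains:
        raise ValueError("frame has no chain topology")
    lipid_mask = np.isin(frame.labels, ("head", "tail"))
    midplane = frame.positions[lipid_mask, 2].mean()
    out = np.zeros(len(frame.chains), dtype=int)
    for i, chain in enumerate(frame.chains):
        chain = np.asarray(chain)
        head_ids = chain[frame.labels[chain] == "head"]
        zref = frame.positions[head_ids[0], 2] if head_ids.size else frame.positions[chain[0], 2]
        dz = zref - midplane
        if abs(dz) < tolerance:
            out[i] = 0
        else:
            out[i] = 1 if dz > 0 else -1
    return out
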