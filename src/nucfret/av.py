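"""Accessible-volume (AV) dye modelling.

The dye is a sphere of radius R_dye tethered to an attachment atom by a
flexible linker of length L_link and width w_link.  The accessible volume
is the set of grid points whose geodesic (flood-fill) distance from the
attachment -- through space left free by the structure inflated by the
linker half-width -- does not exceed the linker length, and whose dye
sphere does not clash with any atom.  Distances between two AV clouds are
summarized three ways, matching the experimental observables: the distance
between mean positions R_mp, the mean interdye distance <R_DA>, and the
FRET-averaged distance <R_DA>_E derived from the pairwise-mean efficiency.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .fret import FretPair

__all__ = [
    "DyeParams",
    "AVCloud",
    "VDW_RADII",
    "ALEXA_DYE",
    "CY5_DYE",
    "load_structure",
    "compute_av",
    "cloud_distances",
    "write_xyz",
]

#: van der Waals radii (A) by element symbol.
VDW_RADII = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "MN": 1.73, "ZN": 1.39, "NA": 2.27, "K": 2.75,
}
DEFAULT_VDW = 1.70


@dataclass(frozen=True)
class DyeParams:
    """Geometric dye/linker parameters (A)."""

    L_link: float
    w_link: float
    R_dye: float

    def __post_init__(self):
        if min(self.L_link, self.w_link, self.R_dye) <= 0:
            raise ValueError("dye parameters must be positive")


ALEXA_DYE = DyeParams(L_link=20.0, w_link=4.5, R_dye=1.5)
CY5_DYE = DyeParams(L_link=22.0, w_link=4.5, R_dye=3.5)


@dataclass
class AVCloud:
    """Accessible dye positions on a cubic lattice (uniform weights)."""

    points: np.ndarray
    spacing: float
    attachment: np.ndarray

    def __len__(self) -> int:
        return len(self.points)

    @property
    def empty(self) -> bool:
        return len(self.points) == 0

    @property
    def mean_position(self) -> np.ndarray:
        if self.empty:
            raise ValueError("empty accessible volume")
        return self.points.mean(axis=0)


def load_structure(path):
    """Heavy-atom coordinates, element symbols and vdW radii from a file.

    Understands PDB/mmCIF (via gemmi) and the plain-text CSV layout
    ``x,y,z,element`` used for packaged fixtures.  Hydrogens are dropped.
    """
    path = str(path)
    if path.endswith(".csv"):
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
        elements = df["element"].astype(str).str.upper().to_numpy()
    else:
        import gemmi

        st = gemmi.read_structure(path)
        st.setup_entities()
        coords, elements = [], []
        for model in st:
            for chain in model:
                for res in chain:
                    for atom in res:
                        el = atom.element.name.upper()
                        if el == "H":
                            continue
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        elements.append(el)
            break
        coords = np.asarray(coords, dtype=float)
        elements = np.asarray(elements)
    keep = elements != "H"
    coords, elements = coords[keep], elements[keep]
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements])
    return coords, elements, radii


_NEIGHBORS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)
_NEIGHBOR_COST = np.linalg.norm(_NEIGHBORS, axis=1)


def compute_av(
    coords,
    radii,
    attachment_xyz,
    dye: DyeParams,
    grid_spacing: float = 0.9,
    attachment_exclusion: float = 2.0,
) -> AVCloud:
    """Accessible volume of a tethered dye.

    Grid points within ``L_link`` geodesic distance of the attachment are
    found by Dijkstra flood-fill over the 26-connected lattice; a lattice
    node can be traversed when it clears every obstacle atom by
    ``vdW + w_link/2`` and is part of the cloud when the dye sphere clears
    ``vdW + R_dye``.  Atoms within ``attachment_exclusion`` of the
    attachment point (the attachment atom itself and its bonded neighbours)
    are not treated as obstacles.  An attachment buried so deeply that
    nothing is reachable yields an explicit empty cloud.
    """
    from scipy.spatial import cKDTree

    att = np.asarray(attachment_xyz, dtype=float)
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    if coords.shape[0] != radii.shape[0]:
        raise ValueError("coords and radii must match")

    L = dye.L_link
    n_side = int(np.ceil(L / grid_spacing))
    axis = np.arange(-n_side, n_side + 1) * grid_spacing
    shape = (axis.size,) * 3
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    nodes = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) + att

    # restrict to atoms that can matter
    if coords.size:
        reach = L + radii.max() + dye.R_dye + dye.w_link
        mask = np.linalg.norm(coords - att, axis=1) < reach
        mask &= np.linalg.norm(coords - att, axis=1) > attachment_exclusion
        near, near_r = coords[mask], radii[mask]
    else:
        near = np.empty((0, 3))
        near_r = np.empty(0)

    if near.size:
        tree = cKDTree(near)
        d_near, i_near = tree.query(nodes, k=1)
        clear_path = d_near >= near_r[i_near] + 0.5 * dye.w_link
        clear_dye = d_near >= near_r[i_near] + dye.R_dye
    else:
        clear_path = np.ones(len(nodes), dtype=bool)
        clear_dye = np.ones(len(nodes), dtype=bool)
    within = np.linalg.norm(nodes - att, axis=1) <= L
    clear_path &= within

    # Dijkstra over the lattice
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    start_idx = (n_side * strides).sum()
    if not clear_path[start_idx]:
        # attachment node itself blocked: allow starting there anyway
        clear_path[start_idx] = True
    dist = np.full(len(nodes), np.inf)
    dist[start_idx] = 0.0
    neighbor_offsets = _NEIGHBORS @ strides
    edge_costs = _NEIGHBOR_COST * grid_spacing
    coords3 = np.array(np.unravel_index(np.arange(len(nodes)), shape)).T
    heap = [(0.0, int(start_idx))]
    visited = np.zeros(len(nodes), dtype=bool)
    n_axis = axis.size
    while heap:
        d0, u = heapq.heappop(heap)
        if visited[u]:
            continue
        visited[u] = True
        cu = coords3[u]
        for off, cost, step in zip(neighbor_offsets, edge_costs, _NEIGHBORS):
            cv = cu + step
            if np.any(cv < 0) or np.any(cv >= n_axis):
                continue
            v = u + off
            if visited[v] or not clear_path[v]:
                continue
            nd = d0 + cost
            if nd <= L and nd < dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, int(v)))
    accessible = (dist <= L) & clear_dye & within
    return AVCloud(points=nodes[accessible], spacing=grid_spacing, attachment=att)


def cloud_distances(
    av_d: AVCloud,
    av_a: AVCloud,
    pair: FretPair,
    n_samples: int = 100_000,
    seed: int = 0,
) -> dict:
    """Distance observables between two dye clouds.

    R_mp is the distance between the mean positions; <R_DA> the mean
    pairwise distance and <R_DA>_E = R0 (1/<E> - 1)^(1/6) with <E> the
    pairwise-mean FRET efficiency, both estimated from ``n_samples``
    uniformly drawn point pairs (fixed seed).
    """
    if av_d.empty or av_a.empty:
        raise ValueError("cannot compute distances from an empty cloud")
    rng = np.random.default_rng(seed)
    r_mp = float(np.linalg.norm(av_d.mean_position - av_a.mean_position))
    i = rng.integers(0, len(av_d), n_samples)
    j = rng.integers(0, len(av_a), n_samples)
    r = np.linalg.norm(av_d.points[i] - av_a.points[j], axis=1)
    r = np.maximum(r, 1e-6)
    mean_r = float(np.mean(r))
    mean_e = float(np.mean(1.0 / (1.0 + (r / pair.R0) ** 6)))
    rda_e = float(pair.R0 * (1.0 / mean_e - 1.0) ** (1.0 / 6.0))
    return {"R_mp": r_mp, "mean_R_DA": mean_r, "Rda_E": rda_e}


def write_xyz(cloud: AVCloud, path, symbol: str = "D") -> None:
    """Write the cloud as an XYZ point file."""
    with open(path, "w") as f:
        f.write(f"{len(cloud)}\n")
        f.write(f"accessible volume, spacing {cloud.spacing} A\n")
        for p in cloud.points:
            f.write(f"{symbol} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")
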