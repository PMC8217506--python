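"""Voxel meshing of tissue volumes and beam discretization of vessel networks.

Builds 8-node hexahedral meshes from segmented intensity volumes (with
optional coarsening and outer-surface smoothing), splits vessel centreline
segments into two-node beam elements with per-node radii, and extracts
refined box submodels for microscale re-simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import hexutil
from .errors import MeshError, ConfigError
from .synthetic import VesselNetwork, VoxelImage

__all__ = [
    "HexMesh",
    "BeamMesh",
    "SubModelSpec",
    "SubModel",
    "segment_image",
    "voxelize",
    "smooth_outer_surface",
    "discretize_network",
    "extract_submodel",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class HexMesh:
    """Hexahedral tissue mesh (coordinates in µm, VTK corner ordering)."""

    nodes: np.ndarray  # (N, 3)
    elements: np.ndarray  # (E, 8)
    element_size: float | None = None  # µm, uniform voxel meshes only
    region_labels: np.ndarray | None = None  # (E,) int ROI tags

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.elements = np.asarray(self.elements, dtype=int).reshape(-1, 8)
        if self.region_labels is None:
            self.region_labels = np.zeros(len(self.elements), dtype=int)
        else:
            self.region_labels = np.asarray(self.region_labels, dtype=int).ravel()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_coords(self, nodes: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if nodes is None else nodes
        return x[self.elements]  # (E, 8, 3)

    def centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def volumes(self) -> np.ndarray:
        return hexutil.hex_volumes(self.element_coords())

    def min_jacobians(self) -> np.ndarray:
        return hexutil.det_jacobians_at_gauss(self.element_coords()).min(axis=1)

    def validate(self) -> None:
        if self.n_elements == 0:
            raise MeshError("empty mesh")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.elements.ravel()] = True
        if not used.all():
            raise MeshError("orphan nodes present")
        jmin = self.min_jacobians()
        if np.any(jmin <= 0):
            bad = int(np.argmin(jmin))
            raise MeshError(f"non-positive Jacobian in element {bad}")

    def boundary_faces(self) -> np.ndarray:
        """(F, 4) node quadruples of faces belonging to exactly one element."""
        faces = self.elements[:, hexutil.HEX_FACES]  # (E, 6, 4)
        flat = faces.reshape(-1, 4)
        key = np.sort(flat, axis=1)
        _, idx, inv, counts = np.unique(
            key, axis=0, return_index=True, return_inverse=True, return_counts=True
        )
        return flat[np.isin(inv, np.nonzero(counts == 1)[0])]

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_faces().ravel())


@dataclass
class BeamMesh:
    """Two-node beam discretization of a vessel network (µm)."""

    nodes: np.ndarray  # (N, 3)
    radii: np.ndarray  # (N,) per-node radius
    elements: np.ndarray  # (B, 2)
    source_segment: np.ndarray | None = None  # (B,) originating network segment

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.elements = np.asarray(self.elements, dtype=int).reshape(-1, 2)
        if self.source_segment is None:
            self.source_segment = np.full(len(self.elements), -1, dtype=int)
        else:
            self.source_segment = np.asarray(self.source_segment, dtype=int).ravel()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def lengths(self, nodes: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if nodes is None else nodes
        return np.linalg.norm(x[self.elements[:, 1]] - x[self.elements[:, 0]], axis=1)

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.nodes[self.elements[:, 0]] + self.nodes[self.elements[:, 1]])

    def element_radii(self) -> np.ndarray:
        """Mean of the two nodal radii per beam element."""
        return 0.5 * (self.radii[self.elements[:, 0]] + self.radii[self.elements[:, 1]])

    def total_volume(self) -> float:
        r0 = self.radii[self.elements[:, 0]]
        r1 = self.radii[self.elements[:, 1]]
        L = self.lengths()
        return float((np.pi * L / 3.0 * (r0**2 + r0 * r1 + r1**2)).sum())

    def validate(self) -> None:
        if np.any(self.radii <= 0):
            raise MeshError("non-positive beam radius")
        if np.any(self.lengths() <= 0):
            raise MeshError("zero-length beam element")


@dataclass
class SubModelSpec:
    """Axis-aligned box to re-mesh at higher resolution."""

    box_lo: np.ndarray
    box_hi: np.ndarray
    refinement: int = 2
    min_element_size: float = 20.0  # µm; finer triggers a warning

    def __post_init__(self) -> None:
        self.box_lo = np.asarray(self.box_lo, dtype=float).ravel()
        self.box_hi = np.asarray(self.box_hi, dtype=float).ravel()
        if np.any(self.box_hi <= self.box_lo):
            raise ConfigError("submodel box has non-positive extent")
        if self.refinement < 1:
            raise ConfigError("refinement factor must be >= 1")


@dataclass
class SubModel:
    """Refined region of interest with provenance into the parent mesh."""

    mesh: HexMesh
    beams: BeamMesh
    parent_elements: np.ndarray  # parent ids of the selected coarse elements
    node_parent_element: np.ndarray  # (Nn,) parent element per refined node
    node_parent_xi: np.ndarray  # (Nn, 3) natural coords in the parent element
    boundary_nodes: np.ndarray  # refined node ids on the submodel boundary
    spec: SubModelSpec = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def segment_image(img: VoxelImage, threshold: float) -> np.ndarray:
    """Binary mask: intensity >= threshold."""
    return img.intensities >= threshold


def voxelize(
    mask: np.ndarray,
    spacing: float | np.ndarray,
    coarsen: int = 1,
    origin: np.ndarray | None = None,
) -> HexMesh:
    """Turn a binary voxel mask into a hexahedral mesh.

    A coarse cell of ``coarsen``³ voxels becomes one element iff at least half
    of its voxels are foreground (majority vote).  Nodes shared between
    elements are merged exactly through integer lattice indexing.  Trailing
    voxels that do not fill a complete coarse cell are ignored.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise MeshError("mask must be 3D")
    if coarsen < 1:
        raise ConfigError("coarsen must be >= 1")
    sp = np.broadcast_to(np.asarray(spacing, dtype=float).ravel(), (3,)).copy()
    if np.any(sp <= 0):
        raise ConfigError("spacing must be positive")
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)

    c = coarsen
    nc = np.array(mask.shape) // c
    if np.any(nc < 1):
        raise MeshError("mask smaller than one coarse cell")
    trimmed = mask[: nc[0] * c, : nc[1] * c, : nc[2] * c]
    blocks = trimmed.reshape(nc[0], c, nc[1], c, nc[2], c)
    counts = blocks.sum(axis=(1, 3, 5))
    keep = counts >= (c**3) / 2.0
    if not keep.any():
        raise MeshError("empty mesh: no foreground coarse cell")

    ci, cj, ck = np.nonzero(keep)  # coarse cell indices
    nn = nc + 1  # node lattice dims
    # node lattice ids of the 8 corners, VTK order (z = axis 2 as "up")
    offs = np.array(
        [
            [0, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
            [1, 0, 1],
            [1, 1, 1],
            [0, 1, 1],
        ]
    )
    corners = np.stack([ci, cj, ck], axis=1)[:, None, :] + offs[None, :, :]  # (E,8,3)
    lattice_ids = np.ravel_multi_index(
        (corners[..., 0], corners[..., 1], corners[..., 2]), tuple(nn)
    )
    used, inverse = np.unique(lattice_ids, return_inverse=True)
    elements = inverse.reshape(lattice_ids.shape)
    ijk = np.stack(np.unravel_index(used, tuple(nn)), axis=1)
    nodes = origin + ijk * (sp * c)

    esize = float(sp[0] * c) if np.allclose(sp, sp[0]) else None
    return HexMesh(nodes=nodes, elements=elements, element_size=esize)


def smooth_outer_surface(
    mesh: HexMesh, iterations: int = 10, strength: float = 0.3
) -> HexMesh:
    """Laplacian smoothing restricted to the exterior surface.

    Each iteration moves every boundary node toward the mean of its
    surface-edge neighbours and then rescales the boundary about the volume
    centroid to keep the total volume (the smoothed surface would otherwise
    shrink).  Interior nodes and connectivity are untouched.  Raises
    ``MeshError`` if an element Jacobian turns non-positive or the total
    volume drifts by more than 5%.
    """
    if mesh.n_elements == 0:
        raise MeshError("empty mesh")
    if iterations == 0:
        return HexMesh(mesh.nodes.copy(), mesh.elements.copy(),
                       mesh.element_size, mesh.region_labels.copy())

    faces = mesh.boundary_faces()
    bnodes = np.unique(faces.ravel())
    # surface edges
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                        faces[:, [2, 3]], faces[:, [3, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    n = mesh.n_nodes
    deg = np.zeros(n)
    np.add.at(deg, e[:, 0], 1.0)
    np.add.at(deg, e[:, 1], 1.0)

    x = mesh.nodes.copy()
    vol0 = mesh.volumes().sum()
    for _ in range(iterations):
        acc = np.zeros_like(x)
        np.add.at(acc, e[:, 0], x[e[:, 1]])
        np.add.at(acc, e[:, 1], x[e[:, 0]])
        mean = acc[bnodes] / deg[bnodes, None]
        x[bnodes] = (1.0 - strength) * x[bnodes] + strength * mean
        # volume-preserving rescale of the boundary about the centroid
        smoothed = HexMesh(x, mesh.elements, mesh.element_size)
        vols = smoothed.volumes()
        centroid = (smoothed.centroids() * vols[:, None]).sum(axis=0) / vols.sum()
        f = (vol0 / vols.sum()) ** (1.0 / 3.0)
        x[bnodes] = centroid + f * (x[bnodes] - centroid)
        jmin = HexMesh(x, mesh.elements, mesh.element_size).min_jacobians()
        if np.any(jmin <= 0):
            bad = int(np.argmin(jmin))
            raise MeshError(
                f"surface smoothing inverted element {bad}; reduce strength"
            )
    out = HexMesh(x, mesh.elements.copy(), mesh.element_size,
                  mesh.region_labels.copy())
    drift = abs(out.volumes().sum() - vol0) / vol0
    if drift > 0.05:
        raise MeshError(f"smoothing changed total volume by {drift:.1%} (> 5%)")
    return out


def discretize_network(net: VesselNetwork, max_len: float) -> BeamMesh:
    """Split every network segment into beams no longer than ``max_len``.

    Interior nodes are equally spaced along the segment with linearly
    interpolated radii; original endpoints are shared between segments, so
    the beam mesh inherits the network connectivity.
    """
    if max_len <= 0:
        raise ConfigError("max_len must be positive")
    nodes = [net.nodes.copy()]
    radii = [net.radii.copy()]
    next_id = net.n_nodes
    elements = []
    source = []
    for s, (ia, ib) in enumerate(net.segments):
        pa, pb = net.nodes[ia], net.nodes[ib]
        ra, rb = net.radii[ia], net.radii[ib]
        L = float(np.linalg.norm(pb - pa))
        nbeam = max(int(np.ceil(L / max_len - 1e-12)), 1)
        if nbeam == 1:
            elements.append((ia, ib))
            source.append(s)
            continue
        ts = np.arange(1, nbeam) / nbeam
        nodes.append(pa[None, :] + ts[:, None] * (pb - pa)[None, :])
        radii.append(ra + ts * (rb - ra))
        ids = [ia] + list(range(next_id, next_id + nbeam - 1)) + [ib]
        next_id += nbeam - 1
        for k in range(nbeam):
            elements.append((ids[k], ids[k + 1]))
            source.append(s)
    bm = BeamMesh(
        nodes=np.concatenate(nodes),
        radii=np.concatenate(radii),
        elements=np.asarray(elements, dtype=int),
        source_segment=np.asarray(source, dtype=int),
    )
    bm.validate()
    return bm


def _clip_segment_to_box(p0, p1, lo, hi):
    """Liang-Barsky clip of segment p0->p1 to an AABB; (t0, t1) or None."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for k in range(3):
        if abs(d[k]) < 1e-300:
            if p0[k] < lo[k] or p0[k] > hi[k]:
                return None
            continue
        ta = (lo[k] - p0[k]) / d[k]
        tb = (hi[k] - p0[k]) / d[k]
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
        if t0 >= t1:
            return None
    return t0, t1


def extract_submodel(
    mesh: HexMesh, beams: BeamMesh | None, spec: SubModelSpec
) -> SubModel:
    """Refine the parent elements inside the box and clip the beams to it.

    Each selected parent element (all 8 corners inside the box, tolerance
    1e-9 µm) is split refinement³-fold in its natural coordinates; refined
    nodes carry their parent element id and natural coordinates, which later
    drive displacement interpolation at the submodel boundary.  Beams are
    clipped to the box with cut-point nodes (radius linearly interpolated).
    """
    lo, hi = spec.box_lo, spec.box_hi
    ec = mesh.element_coords()
    inside = np.all((ec >= lo - 1e-9) & (ec <= hi + 1e-9), axis=(1, 2))
    parent_ids = np.nonzero(inside)[0]
    if len(parent_ids) == 0:
        raise MeshError("submodel box contains no parent element")

    r = spec.refinement
    if mesh.element_size is not None and mesh.element_size / r < spec.min_element_size:
        warnings.warn(
            f"refined element size {mesh.element_size / r:.1f} µm below the "
            f"{spec.min_element_size:.0f} µm floor",
            stacklevel=2,
        )

    # sub-cell lattice in natural coordinates
    lin = -1.0 + 2.0 * np.arange(r + 1) / r
    XI, ETA, ZETA = np.meshgrid(lin, lin, lin, indexing="ij")
    lattice = np.stack([XI, ETA, ZETA], axis=-1).reshape(-1, 3)  # ((r+1)^3, 3)
    nl = r + 1

    def lat_id(i, j, k):
        return (i * nl + j) * nl + k

    sub_conn = []
    offs = hexutil.HEX_NATURAL  # corner offsets pattern
    for i in range(r):
        for j in range(r):
            for k in range(r):
                corner = [
                    lat_id(i + (o[0] > 0), j + (o[1] > 0), k + (o[2] > 0))
                    for o in offs
                ]
                sub_conn.append(corner)
    sub_conn = np.asarray(sub_conn, dtype=int)  # (r³, 8)

    all_coords = []
    all_xi = []
    all_parent = []
    all_elems = []
    offset = 0
    for pe in parent_ids:
        coords = hexutil.interpolate(
            np.broadcast_to(ec[pe], (len(lattice), 8, 3)), lattice
        )
        all_coords.append(coords)
        all_xi.append(lattice)
        all_parent.append(np.full(len(lattice), pe, dtype=int))
        all_elems.append(sub_conn + offset)
        offset += len(lattice)
    coords = np.concatenate(all_coords)
    xis = np.concatenate(all_xi)
    parents = np.concatenate(all_parent)
    elems = np.concatenate(all_elems)

    # merge coincident nodes (shared faces between parent elements)
    key = np.round(coords / 1e-6).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    merged_nodes = coords[first]
    merged_xi = xis[first]
    merged_parent = parents[first]
    merged_elems = inverse[elems]

    esize = mesh.element_size / r if mesh.element_size is not None else None
    sub_mesh = HexMesh(nodes=merged_nodes, elements=merged_elems, element_size=esize)
    bnodes = sub_mesh.boundary_nodes()

    # clip beams
    if beams is None:
        sub_beams = BeamMesh(np.zeros((0, 3)), np.zeros(0), np.zeros((0, 2), int))
    else:
        b_nodes, b_radii, b_elems, b_src = [], [], [], []
        for bi, (ia, ib) in enumerate(beams.elements):
            p0, p1 = beams.nodes[ia], beams.nodes[ib]
            clip = _clip_segment_to_box(p0, p1, lo, hi)
            if clip is None:
                continue
            t0, t1 = clip
            if t1 - t0 < 1e-12:
                continue
            q0 = p0 + t0 * (p1 - p0)
            q1 = p0 + t1 * (p1 - p0)
            r0 = beams.radii[ia] + t0 * (beams.radii[ib] - beams.radii[ia])
            r1 = beams.radii[ia] + t1 * (beams.radii[ib] - beams.radii[ia])
            b_elems.append((len(b_nodes), len(b_nodes) + 1))
            b_nodes.extend([q0, q1])
            b_radii.extend([r0, r1])
            b_src.append(beams.source_segment[bi])
        if b_nodes:
            bn = np.asarray(b_nodes)
            br = np.asarray(b_radii)
            be = np.asarray(b_elems, dtype=int)
            kk = np.round(bn / 1e-6).astype(np.int64)
            _, bf, binv = np.unique(kk, axis=0, return_index=True, return_inverse=True)
            sub_beams = BeamMesh(
                nodes=bn[bf], radii=br[bf], elements=binv[be],
                source_segment=np.asarray(b_src, dtype=int),
            )
        else:
            sub_beams = BeamMesh(np.zeros((0, 3)), np.zeros(0), np.zeros((0, 2), int))

    return SubModel(
        mesh=sub_mesh,
        beams=sub_beams,
        parent_elements=parent_ids,
        node_parent_element=merged_parent,
        node_parent_xi=merged_xi,
        boundary_nodes=bnodes,
        spec=spec,
    )
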