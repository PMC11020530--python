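"""Voxelized cardiac geometries and their hierarchical segmentation.

The package works on regular voxel grids.  Two synthetic geometries are
provided: a rectangular tissue slab (two opposite faces play the role of
endocardium and epicardium) and a truncated half-ellipsoid left-ventricle
shell with a rule-based helical fiber field.  The left ventricle is
partitioned following the American Heart Association 17-segment convention
and then refined twice: each of the 17 segments is split into four
sub-segments (68 total), and each of those into three transmural layers
(endocardial / mid-myocardial / epicardial, 204 total).

Conventions: 0-based node indices, node position = index * spacing, the
long axis is +Z with the base at z-max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelMesh",
    "SegmentHierarchy",
    "build_slab_mesh",
    "build_ellipsoid_lv",
    "segment_aha17",
    "single_segment_hierarchy",
    "subdivide_segments",
    "split_layers",
]

# transmural layer boundaries: equal thirds of the wall
LAYER_BOUNDS = (1.0 / 3.0, 2.0 / 3.0)
LAYER_NAMES = ("endo", "mid", "epi")


@dataclass
class VoxelMesh:
    """Regular 3D grid holding a myocardial mask, fibers and surfaces.

    Attributes
    ----------
    dims : tuple of int
        Nodes per axis ``(nx, ny, nz)``.
    spacing : float
        Edge length of one voxel in model space units.
    myocardium_mask : ndarray of bool, shape dims
        True where a node is myocardium.
    fibers : ndarray, shape dims + (3,)
        Unit fiber direction per myocardial node (zero outside).
    endo_surface, epi_surface : ndarray of int
        Flat node indices of the endocardial / epicardial surface sets.
    transmural_depth : ndarray, shape dims
        0 on the endocardial surface, 1 on the epicardial surface,
        NaN outside the myocardium.
    """

    dims: tuple[int, int, int]
    spacing: float
    myocardium_mask: np.ndarray
    fibers: np.ndarray
    endo_surface: np.ndarray
    epi_surface: np.ndarray
    transmural_depth: np.ndarray
    kind: str = "generic"
    long_axis_center: tuple[float, float] | None = None

    # -- derived helpers -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.dims))

    @property
    def myo_indices(self) -> np.ndarray:
        """Flat indices of all myocardial nodes (C order)."""
        return np.flatnonzero(self.myocardium_mask.ravel())

    def node_positions(self, flat_idx: np.ndarray) -> np.ndarray:
        """Cartesian positions (model units) of flat node indices."""
        ijk = np.column_stack(np.unravel_index(np.asarray(flat_idx), self.dims))
        return ijk * self.spacing

    def validate(self) -> None:
        myo = self.myocardium_mask
        if not np.all(myo.ravel()[self.endo_surface]):
            raise ValueError("endocardial surface nodes outside myocardium")
        if not np.all(myo.ravel()[self.epi_surface]):
            raise ValueError("epicardial surface nodes outside myocardium")
        if np.intersect1d(self.endo_surface, self.epi_surface).size:
            raise ValueError("endo and epi surface sets overlap")
        norms = np.linalg.norm(self.fibers[myo], axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("fiber vectors must have unit norm")
        lbl, n = ndimage.label(myo)
        if n != 1:
            raise ValueError(f"myocardium is not 6-connected (found {n} components)")


@dataclass
class SegmentHierarchy:
    """Per-node segment labels at up to four granularities.

    ``labels_17`` / ``labels_68`` / ``labels_204`` are integer arrays over
    the grid (0 outside the myocardium, labels start at 1).  ``parent_68``
    and ``parent_204`` map child label -> parent label.  ``layer_204``
    tags every 204-level label as 'endo', 'mid' or 'epi'.
    """

    labels_17: np.ndarray
    labels_68: np.ndarray | None = None
    labels_204: np.ndarray | None = None
    parent_68: dict[int, int] = field(default_factory=dict)
    parent_204: dict[int, int] = field(default_factory=dict)
    layer_204: dict[int, str] = field(default_factory=dict)

    def segment_ids(self, level: int) -> np.ndarray:
        lab = {17: self.labels_17, 68: self.labels_68, 204: self.labels_204}[level]
        if lab is None:
            raise ValueError(f"labels at level {level} not built yet")
        ids = np.unique(lab)
        return ids[ids > 0]

    def nodes_of(self, level: int, seg_id: int) -> np.ndarray:
        lab = {17: self.labels_17, 68: self.labels_68, 204: self.labels_204}[level]
        return np.flatnonzero(lab.ravel() == seg_id)


# ---------------------------------------------------------------------------
# slab fixture
# ---------------------------------------------------------------------------

def build_slab_mesh(
    dims: tuple[int, int, int],
    fiber_direction: tuple[float, float, float] = (1.0, 0.0, 0.0),
    spacing: float = 0.1,
) -> VoxelMesh:
    """Full-cuboid tissue slab; z-min face acts as endocardium, z-max as
    epicardium, transmural depth is linear in z."""
    dims = tuple(int(d) for d in dims)
    if any(d < 3 for d in dims):
        raise ValueError("slab dims must all be >= 3")
    f = np.asarray(fiber_direction, dtype=float)
    if abs(np.linalg.norm(f) - 1.0) > 1e-6:
        raise ValueError("fiber_direction must be a unit vector")

    nx, ny, nz = dims
    mask = np.ones(dims, dtype=bool)
    fibers = np.broadcast_to(f, dims + (3,)).copy()

    flat = np.arange(nx * ny * nz).reshape(dims)
    endo = flat[:, :, 0].ravel().copy()
    epi = flat[:, :, -1].ravel().copy()

    depth = np.broadcast_to(
        np.linspace(0.0, 1.0, nz)[None, None, :], dims
    ).astype(float).copy()

    return VoxelMesh(
        dims=dims,
        spacing=spacing,
        myocardium_mask=mask,
        fibers=fibers,
        endo_surface=endo,
        epi_surface=epi,
        transmural_depth=depth,
        kind="slab",
    )


# ---------------------------------------------------------------------------
# ellipsoidal left ventricle
# ---------------------------------------------------------------------------

def _surface_sets(myo: np.ndarray, cavity: np.ndarray, outside: np.ndarray):
    """Myocardial voxels 6-adjacent to the cavity (endo) or to the exterior
    (epi).  Endo membership wins if a voxel touches both."""
    struct = ndimage.generate_binary_structure(3, 1)
    near_cav = ndimage.binary_dilation(cavity, structure=struct) & myo
    near_out = ndimage.binary_dilation(outside, structure=struct) & myo
    endo = np.flatnonzero(near_cav.ravel())
    epi = np.flatnonzero((near_out & ~near_cav).ravel())
    return endo, epi


def _transmural_depth(myo: np.ndarray, endo: np.ndarray, epi: np.ndarray) -> np.ndarray:
    """Depth = d_endo / (d_endo + d_epi) from Euclidean distance transforms
    to each surface node set; resolution-robust and monotone across the wall."""
    shape = myo.shape
    seed_endo = np.ones(shape, dtype=bool)
    seed_endo.ravel()[endo] = False
    seed_epi = np.ones(shape, dtype=bool)
    seed_epi.ravel()[epi] = False
    d_endo = ndimage.distance_transform_edt(seed_endo)
    d_epi = ndimage.distance_transform_edt(seed_epi)
    with np.errstate(invalid="ignore", divide="ignore"):
        depth = d_endo / (d_endo + d_epi)
    depth[~myo] = np.nan
    # exact values on the surfaces themselves
    depth.ravel()[endo] = 0.0
    depth.ravel()[epi] = 1.0
    return depth


def build_ellipsoid_lv(
    outer_radii: tuple[float, float, float],
    wall_thickness: float,
    dims: tuple[int, int, int],
    base_cut: float = 0.0,
    spacing: float = 0.1,
    helix_angles: tuple[float, float] = (-60.0, 60.0),
) -> VoxelMesh:
    """Truncated half-ellipsoid LV shell with a linear helix-angle fiber rule.

    The shell is the set of voxels between the outer ellipsoid (semi-axes
    ``outer_radii``, model units) and the inner ellipsoid (each semi-axis
    shortened by ``wall_thickness``), kept below the base plane.  The long
    axis is +Z; the base plane sits at ``z_center + base_cut * rz`` so the
    default ``base_cut=0`` truncates the ellipsoid at its equator, giving a
    half-ellipsoid with the base parallel to the XY plane.

    Fibers: at transmural depth d the fiber is the circumferential unit
    vector rotated toward the long axis by the helix angle
    ``a(d) = a_endo + d * (a_epi - a_endo)`` (degrees); the default range
    (-60, +60) makes the midwall fiber purely circumferential.
    """
    dims = tuple(int(d) for d in dims)
    rx, ry, rz = (float(r) for r in outer_radii)
    wt = float(wall_thickness)
    if wt >= min(rx, ry, rz):
        raise ValueError("wall_thickness must be smaller than every outer radius")

    nx, ny, nz = dims
    # center the ellipsoid; apex toward z-min, base at z-max
    cx, cy = (nx - 1) / 2.0 * spacing, (ny - 1) / 2.0 * spacing
    z_base = (nz - 2) * spacing  # leave one exterior plane above the base
    cz = z_base - base_cut * rz

    x = np.arange(nx) * spacing
    y = np.arange(ny) * spacing
    z = np.arange(nz) * spacing
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    def inside(a, b, c):
        return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0

    in_outer = inside(rx, ry, rz)
    in_inner = inside(rx - wt, ry - wt, rz - wt)
    below_base = Z <= z_base

    myo = in_outer & ~in_inner & below_base
    cavity = in_inner & below_base
    outside = ~in_outer & below_base
    if not myo.any():
        raise ValueError("empty ellipsoid shell at the given resolution")

    # keep the largest 6-connected component (thin spurious voxels can detach)
    lbl, n = ndimage.label(myo)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
        myo = lbl == (1 + int(np.argmax(sizes)))
    if not myo.any():
        raise ValueError("empty ellipsoid shell at the given resolution")

    endo, epi = _surface_sets(myo, cavity, outside | ~below_base)
    if endo.size == 0 or epi.size == 0:
        raise ValueError("degenerate shell: missing endo or epi surface")
    depth = _transmural_depth(myo, endo, epi)

    # helical fiber field
    fibers = np.zeros(dims + (3,))
    ii, jj, kk = np.nonzero(myo)
    px, py = ii * spacing - cx, jj * spacing - cy
    r_xy = np.hypot(px, py)
    # circumferential unit vector; fall back to +x near the axis
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = np.where(r_xy > 1e-12, -py / r_xy, 1.0)
        ey = np.where(r_xy > 1e-12, px / r_xy, 0.0)
    d = depth[ii, jj, kk]
    a0, a1 = np.deg2rad(helix_angles[0]), np.deg2rad(helix_angles[1])
    alpha = a0 + d * (a1 - a0)
    fibers[ii, jj, kk, 0] = np.cos(alpha) * ex
    fibers[ii, jj, kk, 1] = np.cos(alpha) * ey
    fibers[ii, jj, kk, 2] = np.sin(alpha)

    mesh = VoxelMesh(
        dims=dims,
        spacing=spacing,
        myocardium_mask=myo,
        fibers=fibers,
        endo_surface=endo,
        epi_surface=epi,
        transmural_depth=depth,
        kind="lv",
        long_axis_center=(cx, cy),
    )
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# AHA segmentation hierarchy
# ---------------------------------------------------------------------------

def _angles(mesh: VoxelMesh, ii, jj, reference_angle: float) -> np.ndarray:
    cx, cy = mesh.long_axis_center
    theta = np.arctan2(jj * mesh.spacing - cy, ii * mesh.spacing - cx)
    return np.mod(theta - np.deg2rad(reference_angle), 2.0 * np.pi)


def segment_aha17(mesh: VoxelMesh, reference_angle: float = 0.0) -> SegmentHierarchy:
    """AHA 17-segment labelling of an LV-like mesh.

    The long axis (z, apex at z-min) is split into basal / mid / apical
    thirds above the apex cap; basal and mid rings get 6 circumferential
    sectors of 60 degrees, the apical ring 4 sectors of 90 degrees, and the
    cap below the cavity is segment 17.  ``reference_angle`` (degrees)
    fixes where sector 1 starts; rotating it by 360 leaves labels unchanged.
    """
    if mesh.kind != "lv" or mesh.long_axis_center is None:
        raise ValueError("AHA segmentation requires an LV geometry "
                         "(use single_segment_hierarchy for slabs)")
    myo = mesh.myocardium_mask
    ii, jj, kk = np.nonzero(myo)

    # apex cap = myocardium below the cavity's lowest extent
    depth = mesh.transmural_depth
    # cavity bottom: lowest z that contains an endocardial surface node
    endo_k = np.unravel_index(mesh.endo_surface, mesh.dims)[2]
    k_cap = endo_k.min()
    z_top = kk.max()

    labels = np.zeros(mesh.dims, dtype=np.int32)
    theta = _angles(mesh, ii, jj, reference_angle)

    cap = kk < k_cap
    span = max(z_top - k_cap, 1)
    frac = (kk - k_cap) / span  # 0 at cap top .. 1 at base
    ring = np.where(frac >= 2.0 / 3.0, 0, np.where(frac >= 1.0 / 3.0, 1, 2))
    # ring 0 = basal, 1 = mid, 2 = apical

    sec6 = np.floor(theta / (np.pi / 3.0)).astype(int) % 6
    sec4 = np.floor(theta / (np.pi / 2.0)).astype(int) % 4

    lab = np.where(ring == 0, 1 + sec6, np.where(ring == 1, 7 + sec6, 13 + sec4))
    lab = np.where(cap, 17, lab)
    labels[ii, jj, kk] = lab

    got = np.unique(lab)
    if got.size != 17:
        raise ValueError(f"expected 17 non-empty segments, got {got.size}")
    return SegmentHierarchy(labels_17=labels)


def single_segment_hierarchy(mesh: VoxelMesh) -> SegmentHierarchy:
    """Single-segment mode for slab fixtures: one segment covering the whole
    myocardium at the 17- and 68-levels, three equal-thickness layers at the
    204-level."""
    labels = np.zeros(mesh.dims, dtype=np.int32)
    labels[mesh.myocardium_mask] = 1
    h = SegmentHierarchy(labels_17=labels, labels_68=labels.copy())
    h.parent_68 = {1: 1}
    return split_layers(h, mesh)


def _median_split(values: np.ndarray) -> np.ndarray:
    """Boolean array: True for the upper half at the median (ties resolved
    by rank so the two halves are balanced)."""
    order = np.argsort(values, kind="stable")
    half = values.size // 2
    upper = np.zeros(values.size, dtype=bool)
    upper[order[half:]] = True
    return upper


def subdivide_segments(h: SegmentHierarchy, mesh: VoxelMesh) -> SegmentHierarchy:
    """Split every 17-segment into 4 children (2x2 along the segment's
    circumferential and longitudinal median planes) -> 68 segments."""
    labels17 = h.labels_17
    out = np.zeros_like(labels17)
    parent: dict[int, int] = {}
    for s in np.unique(labels17[labels17 > 0]):
        nodes = labels17 == s
        ii, jj, kk = np.nonzero(nodes)
        full_circle = False
        if mesh.long_axis_center is not None:
            theta = _angles(mesh, ii, jj, 0.0)
            # unwrap around the largest angular gap so segments touching the
            # branch cut split contiguously
            order = np.argsort(theta)
            gaps = np.diff(np.concatenate([theta[order], theta[order][:1] + 2 * np.pi]))
            biggest = gaps.max()
            full_circle = biggest < np.pi / 4  # apex cap wraps all the way round
            start = theta[order][(np.argmax(gaps) + 1) % theta.size]
            circ = np.mod(theta - start, 2 * np.pi)
        else:
            circ = ii.astype(float)
        if full_circle:
            # a longitudinal split of the cap would orphan children from the
            # endocardium; four circumferential quadrants keep every child
            # spanning the full wall depth
            quad = np.minimum((circ / (np.pi / 2)).astype(int), 3)
            child = 4 * (int(s) - 1) + 1 + quad
        else:
            upper_c = _median_split(circ)
            upper_z = _median_split(kk.astype(float))
            child = 4 * (int(s) - 1) + 1 + (upper_c.astype(int) * 2 + upper_z.astype(int))
        out[ii, jj, kk] = child
        for q in range(4):
            c = 4 * (int(s) - 1) + 1 + q
            if not np.any(child == c):
                raise ValueError(f"empty child {s}.{q + 1}: mesh too coarse")
            parent[c] = int(s)
    h2 = SegmentHierarchy(labels_17=labels17, labels_68=out, parent_68=parent)
    return h2


def split_layers(h: SegmentHierarchy, mesh: VoxelMesh) -> SegmentHierarchy:
    """Split every 68-segment into endo/mid/epi layers at transmural depth
    1/3 and 2/3 -> 204 segments."""
    if h.labels_68 is None:
        raise ValueError("labels_68 must be built first")
    depth = mesh.transmural_depth
    labels68 = h.labels_68
    out = np.zeros_like(labels68)
    parent: dict[int, int] = {}
    layer_tag: dict[int, str] = {}
    layer = np.where(depth < LAYER_BOUNDS[0], 0, np.where(depth <= LAYER_BOUNDS[1], 1, 2))
    for s in np.unique(labels68[labels68 > 0]):
        nodes = labels68 == s
        for li, name in enumerate(LAYER_NAMES):
            c = 3 * (int(s) - 1) + 1 + li
            sel = nodes & (layer == li)
            if not sel.any():
                raise ValueError(f"empty {name} layer in segment {s}: mesh too coarse")
            out[sel] = c
            parent[c] = int(s)
            layer_tag[c] = name
    return SegmentHierarchy(
        labels_17=h.labels_17,
        labels_68=labels68,
        labels_204=out,
        parent_68=h.parent_68,
        parent_204=parent,
        layer_204=layer_tag,
    )
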