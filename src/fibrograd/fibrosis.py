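"""Fibrosis density maps and their stochastic non-conductive realizations.

Fibrosis is modelled by knocking out mesh nodes: a node with local density
``D`` becomes non-conductive when ``D`` exceeds an independent uniform(0,1)
draw.  The uniform field is a pure function of (mesh shape, seed), so the
same seed yields a *common random field*: raising any density can only add
knocked-out nodes (monotone coupling), which keeps the optimizer's cost
curves quasi-monotone in density.

Density maps come from three sources: the four idealized transmural-layer
patterns, per-segment constants produced by the optimizer, or a
histology-like stack of per-slice 72x6 sector maps interpolated to 3D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .geometry import LAYER_BOUNDS, SegmentHierarchy, VoxelMesh

__all__ = [
    "PATTERNS",
    "FibrosisDensityMap",
    "FibrosisRealization",
    "SliceDensityMaps",
    "make_pattern",
    "density_from_segments",
    "uniform_field",
    "sample_fibrosis",
    "synth_histology_maps",
    "interpolate_density_3d",
]

# idealized per-layer densities (endo, mid, epi)
PATTERNS: dict[str, tuple[float, float, float]] = {
    "transmural": (0.25, 0.25, 0.25),
    "sub_endocardial": (0.35, 0.15, 0.02),
    "mid_myocardial": (0.10, 0.35, 0.15),
    "sub_epicardial": (0.02, 0.15, 0.35),
}


@dataclass
class FibrosisDensityMap:
    """Continuous fibrosis density in [0,1] per grid node (0 outside)."""

    values: np.ndarray  # shape = mesh.dims
    provenance: str = "unspecified"

    def validate(self, mesh: VoxelMesh) -> None:
        v = self.values
        if v.shape != tuple(mesh.dims):
            raise ValueError("density grid shape does not match mesh")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("density values outside [0, 1]")
        if np.any(v[~mesh.myocardium_mask] != 0):
            raise ValueError("nonzero density outside the myocardium")


@dataclass
class FibrosisRealization:
    """Seeded boolean knockout of a density map."""

    non_conductive_mask: np.ndarray  # bool, shape = mesh.dims
    seed: int
    density: FibrosisDensityMap


@dataclass
class SliceDensityMaps:
    """Stack of authored 2D density maps, 72 circumferential x 6 transmural
    sectors each, at given grid z-indices."""

    grids: np.ndarray      # (n_slices, 72, 6)
    slice_z: np.ndarray    # (n_slices,) int, ascending

    def __post_init__(self):
        self.grids = np.asarray(self.grids, dtype=float)
        self.slice_z = np.asarray(self.slice_z, dtype=int)
        if self.grids.ndim != 3 or self.grids.shape[1:] != (72, 6):
            raise ValueError("each slice map must be 72 x 6")
        if self.grids.shape[0] != self.slice_z.size:
            raise ValueError("slice_z length must match number of slices")
        if (self.grids < 0).any() or (self.grids > 1).any():
            raise ValueError("slice densities outside [0, 1]")


# ---------------------------------------------------------------------------
# idealized patterns
# ---------------------------------------------------------------------------

def make_pattern(
    segment_id: int,
    pattern: str,
    h: SegmentHierarchy,
    mesh: VoxelMesh,
) -> FibrosisDensityMap:
    """Constant per-layer density inside one 17-segment, zero elsewhere.

    The segment's wall is split into equal transmural thirds and each third
    gets the pattern's (endo, mid, epi) level.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {sorted(PATTERNS)}")
    seg = h.labels_17 == segment_id
    if not seg.any():
        raise ValueError(f"segment {segment_id} is empty")
    levels = PATTERNS[pattern]
    depth = mesh.transmural_depth
    layer = np.where(depth < LAYER_BOUNDS[0], 0, np.where(depth <= LAYER_BOUNDS[1], 1, 2))
    values = np.zeros(mesh.dims)
    for li in range(3):
        values[seg & (layer == li)] = levels[li]
    return FibrosisDensityMap(values=values, provenance=f"pattern:{pattern}")


def density_from_segments(
    values_by_segment: dict[int, float],
    labels: np.ndarray,
    provenance: str = "optimizer step",
) -> FibrosisDensityMap:
    """Expand per-segment constants to a per-node density grid."""
    out = np.zeros(labels.shape)
    for seg_id, d in values_by_segment.items():
        out[labels == seg_id] = d
    return FibrosisDensityMap(values=out, provenance=provenance)


# ---------------------------------------------------------------------------
# stochastic realization
# ---------------------------------------------------------------------------

def uniform_field(mesh: VoxelMesh, seed: int) -> np.ndarray:
    """The common uniform(0,1) comparison field for a mesh + seed."""
    rng = np.random.default_rng(seed)
    return rng.random(mesh.dims)


def sample_fibrosis(
    density: FibrosisDensityMap,
    seed: int,
    mesh: VoxelMesh,
    field: np.ndarray | None = None,
) -> FibrosisRealization:
    """Knock out node i iff ``density_i > u_i`` with u the seeded uniform
    field.  Passing a precomputed ``field`` (from :func:`uniform_field`)
    avoids re-drawing during optimization loops."""
    if field is None:
        field = uniform_field(mesh, seed)
    mask = (density.values > field) & mesh.myocardium_mask
    return FibrosisRealization(non_conductive_mask=mask, seed=seed, density=density)


# ---------------------------------------------------------------------------
# histology-like slice maps
# ---------------------------------------------------------------------------

def synth_histology_maps(
    n_slices: int = 20,
    roughness: float = 4.0,
    mean_level: float = 0.10,
    level_std: float = 0.125,
    seed: int = 0,
) -> "SliceDensityMaps":
    """Synthetic stand-in for per-slice histology density maps.

    Generates a spatially correlated random field over (slice,
    circumferential sector, transmural sector), periodic circumferentially,
    centred at ``mean_level`` with spread ``level_std`` and clipped to
    [0,1].  ``roughness`` is the Gaussian correlation length in sector
    units; as it tends to infinity every sector equals ``mean_level``.
    The default spread is calibrated so that roughly a fifth of sectors
    exceeds the 0.21 abnormality level, emulating diffuse non-ischemic
    fibrosis with focal denser pockets.

    Slice z-positions are left abstract here (indices 0..n-1); callers map
    them onto a mesh z-range when interpolating.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 authored slices")
    if not 0.0 <= mean_level <= 1.0:
        raise ValueError("mean_level must lie in [0, 1]")
    shape = (n_slices, 72, 6)
    if np.isinf(roughness):
        grids = np.full(shape, mean_level)
    else:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(shape)
        sm = ndimage.gaussian_filter(
            noise,
            sigma=(roughness / 2.0, roughness, roughness / 2.0),
            mode=("nearest", "wrap", "nearest"),
        )
        sm -= sm.mean()
        std = sm.std()
        if std > 0:
            sm /= std
        grids = np.clip(mean_level + level_std * sm, 0.0, 1.0)
    return SliceDensityMaps(grids=grids, slice_z=np.arange(n_slices))


def _sectorize(mesh: VoxelMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-myocardial-node (circumferential sector of 72, transmural sector
    of 6) indices."""
    if mesh.long_axis_center is None:
        raise ValueError("sectorization requires an LV-like mesh")
    cx, cy = mesh.long_axis_center
    ii, jj, kk = np.nonzero(mesh.myocardium_mask)
    theta = np.mod(np.arctan2(jj * mesh.spacing - cy, ii * mesh.spacing - cx), 2 * np.pi)
    c = np.minimum((theta / (2 * np.pi) * 72).astype(int), 71)
    d = mesh.transmural_depth[ii, jj, kk]
    t = np.minimum((d * 6).astype(int), 5)
    return c, t


def interpolate_density_3d(
    maps: SliceDensityMaps,
    mesh: VoxelMesh,
    smooth: bool = True,
) -> FibrosisDensityMap:
    """Expand authored per-slice sector maps to a full 3D density field.

    Every mesh XY slice is sectored 72x6 (circumferential x transmural);
    authored slices keep their values, in-between slices are filled by a
    natural cubic spline along z per sector label, out-of-range slices are
    clamped to the nearest authored value.  The per-node field is then
    averaged once over the 6-connected neighbourhood and clipped to [0,1].
    """
    if maps.slice_z.size < 2:
        raise ValueError("need at least 2 authored slices")
    zq = np.arange(mesh.dims[2])
    zq_cl = np.clip(zq, maps.slice_z.min(), maps.slice_z.max())
    # one natural cubic spline per (circ, trans) sector, vectorized over sectors
    flat = maps.grids.reshape(maps.grids.shape[0], -1)  # (n_slices, 432)
    spline = CubicSpline(maps.slice_z, flat, axis=0, bc_type="natural")
    per_z = spline(zq_cl).reshape(zq.size, 72, 6)

    ii, jj, kk = np.nonzero(mesh.myocardium_mask)
    c, t = _sectorize(mesh)
    values = np.zeros(mesh.dims)
    values[ii, jj, kk] = per_z[kk, c, t]

    if smooth:
        # one-pass arithmetic mean over the 6-neighbourhood, myocardium only
        kernel = np.zeros((3, 3, 3))
        kernel[1, 1, 1] = 1
        kernel[0, 1, 1] = kernel[2, 1, 1] = 1
        kernel[1, 0, 1] = kernel[1, 2, 1] = 1
        kernel[1, 1, 0] = kernel[1, 1, 2] = 1
        myo = mesh.myocardium_mask.astype(float)
        num = ndimage.convolve(values * myo, kernel, mode="constant")
        den = ndimage.convolve(myo, kernel, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(den > 0, num / den, 0.0)
        values = np.where(mesh.myocardium_mask, sm, 0.0)

    values = np.clip(values, 0.0, 1.0)
    values[~mesh.myocardium_mask] = 0.0
    return FibrosisDensityMap(values=values, provenance="histology-like")
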