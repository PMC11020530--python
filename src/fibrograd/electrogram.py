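"""Unipolar pseudo-electrogram synthesis and surface mapping.

An electrode at position x records the sum over all conductive myocardial
nodes of the transmembrane diffusion current weighted by the inverse
square of the distance:  EGM(t) = sum_i I_i(t) / r_i^2.  The transfer
constant is taken as 1; every downstream comparison is normalized by a
zero-fibrosis baseline, so the constant cancels.

From each trace two scalars are extracted: the local activation time
(LAT, time of the steepest downstroke, measured against a reference,
conventionally the simultaneous endocardial stimulation at t = 0) and the
peak-to-peak amplitude (PtP, max minus min).  Electrode values are spread
onto all surface nodes with a radius-limited inverse-distance-weighting
interpolator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import VoxelMesh
from .simulation import SimulationRecord

__all__ = [
    "ElectrodeSet",
    "EGMTrace",
    "SurfaceFieldMap",
    "place_electrodes",
    "transfer_matrix",
    "compute_egm",
    "compute_lat",
    "compute_ptp",
    "idw_interpolate",
    "surface_measurements",
]

BLOCK_LAT = np.inf  # sentinel for "wave never arrived"


@dataclass
class ElectrodeSet:
    """Electrodes one voxel off a tagged surface."""

    positions: np.ndarray      # (n, 3) model units
    surface: str               # 'endo' | 'epi'
    surface_nodes: np.ndarray  # flat grid index of the node each electrode sits on
    seed: int

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass
class EGMTrace:
    """Sampled potential at one electrode with derived scalars."""

    electrode: int
    times: np.ndarray
    potentials: np.ndarray
    lat: float | None = None
    ptp: float | None = None


@dataclass
class SurfaceFieldMap:
    """Per-surface-node LAT and PtP for both surfaces, plus the
    zero-fibrosis baseline used for cost normalization."""

    endo_nodes: np.ndarray
    epi_nodes: np.ndarray
    lat_endo: np.ndarray
    lat_epi: np.ndarray
    ptp_endo: np.ndarray
    ptp_epi: np.ndarray
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# electrode placement
# ---------------------------------------------------------------------------

def _outward_normals(mesh: VoxelMesh, nodes: np.ndarray, surface: str) -> np.ndarray:
    """Unit direction pointing away from the myocardium for each surface
    node: the mean of the 6-neighbour directions that leave the tissue."""
    dims = mesh.dims
    myo = mesh.myocardium_mask
    ijk = np.column_stack(np.unravel_index(nodes, dims))
    normals = np.zeros((nodes.size, 3))
    offs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    for off in offs:
        q = ijk + off
        inb = np.all((q >= 0) & (q < np.array(dims)), axis=1)
        # out-of-grid neighbours are the bounding box, not an anatomical
        # surface, so they do not contribute to the outward direction
        empty = np.zeros(nodes.size, dtype=bool)
        qin = q[inb]
        empty[inb] = ~myo[qin[:, 0], qin[:, 1], qin[:, 2]]
        normals[empty] += off
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    fallback = np.array([0.0, 0.0, -1.0]) if surface == "endo" else np.array([0.0, 0.0, 1.0])
    bad = norm[:, 0] < 1e-12
    normals[bad] = fallback
    norm[bad] = 1.0
    return normals / norm


def place_electrodes(
    mesh: VoxelMesh,
    surface: str,
    n: int,
    seed: int,
    stratify_labels: np.ndarray | None = None,
    offset_voxels: float = 2.0,
) -> ElectrodeSet:
    """Sample ``n`` distinct surface nodes uniformly (seeded) and offset
    each ``offset_voxels`` voxel spacings outward along the local surface
    normal.  The standoff keeps the recording away from the 1/r^2
    singularity; the default of two voxels widens each electrode's field
    of view to several wall nodes, which stabilizes PtP against the
    node-level granularity of the fibrosis knockout.

    With ``stratify_labels`` (a per-grid-node segment labelling), the n
    electrodes are allotted to segments proportionally to each segment's
    surface node count (largest-remainder rounding, so per-segment counts
    deviate from exact proportionality by at most 1).
    """
    nodes_all = mesh.endo_surface if surface == "endo" else mesh.epi_surface
    if n > nodes_all.size:
        raise ValueError(f"requested {n} electrodes but surface has {nodes_all.size} nodes")
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        chosen = rng.choice(nodes_all, size=n, replace=False)
    else:
        labels = stratify_labels.ravel()[nodes_all]
        chosen_parts = []
        segs = np.unique(labels)
        quota = n * np.array([(labels == s).sum() for s in segs]) / nodes_all.size
        counts = np.floor(quota).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(quota - counts))
        counts[order[:rem]] += 1
        for s, c in zip(segs, counts):
            pool = nodes_all[labels == s]
            if c > pool.size:
                c = pool.size
            chosen_parts.append(rng.choice(pool, size=c, replace=False))
        chosen = np.concatenate(chosen_parts)
    chosen = np.sort(chosen)
    normals = _outward_normals(mesh, chosen, surface)
    pos = mesh.node_positions(chosen) + offset_voxels * mesh.spacing * normals
    return ElectrodeSet(positions=pos, surface=surface, surface_nodes=chosen, seed=seed)


# ---------------------------------------------------------------------------
# EGM synthesis
# ---------------------------------------------------------------------------

def transfer_matrix(
    electrodes: ElectrodeSet,
    mesh: VoxelMesh,
    cond_idx: np.ndarray,
) -> np.ndarray:
    """Dense (n_electrodes x n_conductive) matrix of 1/r^2 weights, with r
    guarded below by half a voxel spacing."""
    src = mesh.node_positions(cond_idx)
    r = np.linalg.norm(
        electrodes.positions[:, None, :] - src[None, :, :], axis=-1)
    r = np.maximum(r, mesh.spacing / 2.0)
    return 1.0 / (r * r)


def compute_egm(
    record: SimulationRecord,
    electrodes: ElectrodeSet,
    Z: np.ndarray | None = None,
) -> list[EGMTrace]:
    """Pseudo-EGMs at every electrode from the sampled voltage fields.

    The transmembrane current is the diffusion term I = L u evaluated at
    the sampled times; the potential is the 1/r^2-weighted sum over all
    conductive nodes.  Pass a precomputed ``Z`` (from
    :func:`transfer_matrix`) to amortize the geometry cost across runs.
    """
    if Z is None:
        Z = transfer_matrix(electrodes, record.mesh, record.cond_idx)
    currents = record.operator @ record.u_samples.T      # (n_cond, n_t)
    pots = Z @ currents                                   # (n_e, n_t)
    return [
        EGMTrace(electrode=e, times=record.times, potentials=pots[e])
        for e in range(electrodes.n)
    ]


def compute_lat(
    trace: EGMTrace,
    reference_time: float = 0.0,
    noise_floor: float = 1e-12,
    blank_until: float = 0.0,
) -> float:
    """LAT = time of the steepest downstroke (most negative central-difference
    derivative) minus the reference time; ties resolve to the earliest
    sample; below ``noise_floor`` peak derivative magnitude the block
    sentinel (+inf) is returned.

    ``blank_until`` masks the initial part of the trace from the search:
    the injected stimulation current produces a large artifact whose decay
    at stimulus offset would otherwise be mistaken for the activation
    downstroke (the usual pacing-blanking practice).
    """
    x = np.asarray(trace.potentials, dtype=float)
    t = np.asarray(trace.times, dtype=float)
    if blank_until > 0.0:
        keep = t >= blank_until
        if keep.sum() < 3:
            raise ValueError("blanking removed almost the whole trace")
        x, t = x[keep], t[keep]
    if x.size < 3:
        raise ValueError("need at least 3 samples for a derivative")
    d = (x[2:] - x[:-2]) / (t[2:] - t[:-2])
    if np.max(np.abs(d)) < noise_floor:
        return BLOCK_LAT
    i = int(np.argmin(d))  # argmin returns the first minimum: earliest tie wins
    t_min = t[i + 1]
    # parabolic sub-sample refinement when the minimum is interior and strict
    if 0 < i < d.size - 1:
        y0, y1, y2 = d[i - 1], d[i], d[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            shift = 0.5 * (y0 - y2) / denom
            if abs(shift) <= 1.0:
                t_min = t_min + shift * (t[i + 2] - t[i + 1])
    return float(t_min - reference_time)


def compute_ptp(trace: EGMTrace, blank_until: float = 0.0) -> float:
    """Peak-to-peak amplitude: max minus min of the sampled potential.

    ``blank_until`` restricts the measurement window, used on the
    epicardium to score the transmural activation complex rather than the
    endocardial stimulation complex."""
    x = np.asarray(trace.potentials, dtype=float)
    if blank_until > 0.0:
        keep = np.asarray(trace.times, dtype=float) >= blank_until
        if keep.any():
            x = x[keep]
    if x.size < 1:
        raise ValueError("empty trace")
    return float(x.max() - x.min())


# ---------------------------------------------------------------------------
# IDW interpolation onto surface nodes
# ---------------------------------------------------------------------------

def idw_interpolate(
    values: np.ndarray,
    electrode_positions: np.ndarray,
    node_positions: np.ndarray,
    radius: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Radius-limited inverse-distance weighting.

    w_i(x) = (max(0, R - d_i) / (R d_i))^2; electrodes at or beyond R get
    zero weight; a node coincident with an electrode takes that
    electrode's value exactly.  Electrodes with non-finite values (blocked
    LAT) are ignored; a node with no finite electrode inside R falls back
    to its nearest finite electrode and is flagged in the returned mask.

    Returns (interpolated values, fallback_mask).
    """
    if radius <= 0:
        raise ValueError("IDW radius must be positive")
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    out = np.full(node_positions.shape[0], np.inf)
    fallback = np.zeros(node_positions.shape[0], dtype=bool)
    if not finite.any():
        fallback[:] = True
        return out, fallback
    pos = electrode_positions[finite]
    val = values[finite]
    tree = cKDTree(pos)
    neighbors = tree.query_ball_point(node_positions, r=radius)
    nn_d, nn_i = tree.query(node_positions)
    for m, idx in enumerate(neighbors):
        if not idx:
            out[m] = val[nn_i[m]]
            fallback[m] = True
            continue
        d = np.linalg.norm(pos[idx] - node_positions[m], axis=1)
        if d.min() < 1e-12:
            out[m] = val[idx[int(np.argmin(d))]]
            continue
        w = (np.maximum(0.0, radius - d) / (radius * d)) ** 2
        sw = w.sum()
        if sw <= 0:
            out[m] = val[nn_i[m]]
            fallback[m] = True
        else:
            out[m] = float(np.dot(w, val[np.asarray(idx)]) / sw)
    return out, fallback


def default_idw_radius(electrodes: ElectrodeSet) -> float:
    """Twice the mean nearest-neighbour electrode spacing."""
    tree = cKDTree(electrodes.positions)
    d, _ = tree.query(electrodes.positions, k=2)
    return float(2.0 * d[:, 1].mean())


# ---------------------------------------------------------------------------
# end-to-end surface measurement
# ---------------------------------------------------------------------------

def surface_measurements(
    record: SimulationRecord,
    endo_electrodes: ElectrodeSet,
    epi_electrodes: ElectrodeSet,
    radius: float | None = None,
    Z_endo: np.ndarray | None = None,
    Z_epi: np.ndarray | None = None,
    reference_time: float = 0.0,
    lat_blank: float | None = None,
    endo_lat_is_reference: bool = True,
) -> SurfaceFieldMap:
    """Run EGM synthesis + LAT/PtP extraction + IDW interpolation for both
    surfaces of one simulation.

    LAT detection is blanked until shortly after the first stimulus pulse
    ends (override with ``lat_blank``).  Peak-to-peak amplitudes are taken
    over the full trace on the endocardium — under the simultaneous
    endocardial stimulation model the stimulus complex *is* the
    endocardial activation complex — but over the post-blank window on the
    epicardium, so they score the transmural wave rather than the remote
    stimulation artifact.  An electrode whose nearest conductive tissue
    node never activated is marked blocked (LAT = +inf, PtP = 0)
    regardless of far-field deflections in its trace.
    """
    mesh = record.mesh
    if lat_blank is None:
        sample_dt = record.times[1] - record.times[0] if record.times.size > 1 else 0.0
        lat_blank = float(record.protocol.onsets[0] + record.protocol.duration
                          + 2.0 * sample_dt)
    maps: dict[str, np.ndarray] = {}
    nodes = {"endo": mesh.endo_surface, "epi": mesh.epi_surface}
    cond_tree = cKDTree(mesh.node_positions(record.cond_idx))
    for tag, electrodes, Z in (("endo", endo_electrodes, Z_endo),
                               ("epi", epi_electrodes, Z_epi)):
        traces = compute_egm(record, electrodes, Z=Z)
        if tag == "endo" and endo_lat_is_reference:
            # simultaneous endocardial stimulation: endocardial activation
            # coincides with the reference, so endocardial LATs are 0
            lat = np.zeros(electrodes.n)
        else:
            lat = np.array([compute_lat(tr, reference_time, blank_until=lat_blank)
                            for tr in traces])
        ptp_blank = lat_blank if tag == "epi" else 0.0
        ptp = np.array([compute_ptp(tr, blank_until=ptp_blank) for tr in traces])
        _, nearest = cond_tree.query(electrodes.positions)
        dead = ~np.isfinite(record.act_time[nearest])
        lat[dead] = BLOCK_LAT
        ptp[dead] = 0.0
        R = radius if radius is not None else default_idw_radius(electrodes)
        node_pos = mesh.node_positions(nodes[tag])
        lat_n, _ = idw_interpolate(lat, electrodes.positions, node_pos, R)
        ptp_n, _ = idw_interpolate(ptp, electrodes.positions, node_pos, R)
        maps[f"lat_{tag}"] = lat_n
        maps[f"ptp_{tag}"] = ptp_n
    return SurfaceFieldMap(
        endo_nodes=nodes["endo"],
        epi_nodes=nodes["epi"],
        lat_endo=maps["lat_endo"],
        lat_epi=maps["lat_epi"],
        ptp_endo=maps["ptp_endo"],
        ptp_epi=maps["ptp_epi"],
        meta={"radius": radius},
    )
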