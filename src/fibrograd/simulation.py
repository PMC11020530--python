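"""Monodomain simulation of cardiac excitation on a voxel mesh.

The tissue model is the two-variable Aliev-Panfilov system

    du/dt = div(D grad u) - k u (u - a)(u - 1) - u v
    dv/dt = -(eps + mu1 v / (u + mu2)) (v + k u (u - a - 1))

with u the dimensionless transmembrane voltage and v a recovery variable.
Integration is explicit forward Euler; the anisotropic Laplacian is a
19-point finite-difference stencil built per conductive node from the
local fiber direction (D = D_T I + (D_L - D_T) f f^T).  Fibrotic nodes and
the domain boundary carry homogeneous Neumann (zero-flux) conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.signal import find_peaks

from ._stencil import build_laplacian_csr, step_block
from .fibrosis import FibrosisRealization
from .geometry import VoxelMesh

__all__ = [
    "APParams",
    "StimulusProtocol",
    "SimulationRecord",
    "build_operator",
    "run_simulation",
    "sinus_protocol",
    "pacing_protocol",
    "measure_period",
    "conduction_velocity",
]


@dataclass(frozen=True)
class APParams:
    """Model and numerical parameters (dimensionless model units)."""

    k: float = 8.0
    a: float = 0.1
    eps: float = 0.01
    mu1: float = 0.2
    mu2: float = 0.3
    dt: float = 0.0015
    dr: float = 0.1
    d_long: float = 1.0
    d_trans: float = 0.25  # default 4:1 anisotropy; set equal for isotropic

    def __post_init__(self):
        if self.dt <= 0 or self.dr <= 0:
            raise ValueError("dt and dr must be positive")
        if not (self.d_long >= self.d_trans > 0):
            raise ValueError("need d_long >= d_trans > 0")
        trace = self.d_long + 2.0 * self.d_trans
        limit = self.dr ** 2 / (2.0 * trace)
        if self.dt > limit:
            raise ValueError(
                f"explicit stability violated: dt={self.dt} > dr^2/(2 tr D)={limit:.3g}")


@dataclass
class StimulusProtocol:
    """Current-injection protocol: same site set for every pulse."""

    sites: np.ndarray           # flat grid node indices
    onsets: np.ndarray          # model time units, sorted
    amplitude: float = 100.0
    duration: float = 0.2

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=np.int64)
        self.onsets = np.sort(np.asarray(self.onsets, dtype=float))
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.sites.size == 0:
            raise ValueError("stimulus site set is empty")


@dataclass
class SimulationRecord:
    """Time-sampled state of one forward run.

    ``u_samples`` holds u over conductive nodes at ``times`` (cadence
    ``sample_every`` steps).  ``act_time`` is the first upward crossing of
    u >= 0.5 per conductive node (+inf where tissue never activated).
    ``operator`` is the assembled Laplacian, used downstream to form the
    transmembrane diffusion current for electrogram synthesis.
    """

    times: np.ndarray
    u_samples: np.ndarray        # (n_samples, n_cond)
    act_time: np.ndarray         # (n_cond,)
    cond_idx: np.ndarray         # flat grid indices of conductive nodes
    operator: sparse.csr_matrix
    params: APParams
    protocol: StimulusProtocol
    mesh: VoxelMesh
    probe_traces: dict[int, np.ndarray] = field(default_factory=dict)
    blocked: bool = False

    def compact_of(self, flat_idx: np.ndarray) -> np.ndarray:
        """Map flat grid indices to compact conductive indices (-1 if not
        conductive)."""
        lookup = np.full(int(np.prod(self.mesh.dims)), -1, dtype=np.int64)
        lookup[self.cond_idx] = np.arange(self.cond_idx.size)
        return lookup[np.asarray(flat_idx)]


def _tensor_components(mesh: VoxelMesh, params: APParams) -> np.ndarray:
    """Per-node (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) from fibers."""
    f = mesh.fibers
    dT, dL = params.d_trans, params.d_long
    out = np.zeros((6,) + tuple(mesh.dims))
    out[0] = dT + (dL - dT) * f[..., 0] * f[..., 0]
    out[1] = dT + (dL - dT) * f[..., 1] * f[..., 1]
    out[2] = dT + (dL - dT) * f[..., 2] * f[..., 2]
    out[3] = (dL - dT) * f[..., 0] * f[..., 1]
    out[4] = (dL - dT) * f[..., 0] * f[..., 2]
    out[5] = (dL - dT) * f[..., 1] * f[..., 2]
    return out


def build_operator(
    mesh: VoxelMesh,
    realization: FibrosisRealization | None,
    params: APParams,
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Assemble the anisotropic Laplacian over conductive nodes.

    Returns (csr matrix over compact conductive indexing, flat grid indices
    of the conductive nodes).
    """
    cond = mesh.myocardium_mask.copy()
    if realization is not None:
        cond &= ~realization.non_conductive_mask
    cond_idx = np.flatnonzero(cond.ravel())
    cidx = np.full(mesh.dims, -1, dtype=np.int32)
    cidx.ravel()[cond_idx] = np.arange(cond_idx.size, dtype=np.int32)
    dcomp = _tensor_components(mesh, params)
    indptr, indices, data = build_laplacian_csr(cidx, dcomp, params.dr)
    n = cond_idx.size
    A = sparse.csr_matrix((data, indices, indptr), shape=(n, n))
    return A, cond_idx


def run_simulation(
    mesh: VoxelMesh,
    realization: FibrosisRealization | None,
    params: APParams,
    protocol: StimulusProtocol,
    t_end: float,
    sample_every: int = 50,
    probes: np.ndarray | None = None,
    act_thresh: float = 0.5,
) -> SimulationRecord:
    """Forward-Euler integration of the monodomain model until ``t_end``.

    Non-conductive (fibrotic) nodes are removed from the state entirely and
    hold u = 0 throughout.  The record flags ``blocked`` when no epicardial
    surface node activated within ``t_end``.
    """
    A, cond_idx = build_operator(mesh, realization, params)
    n = cond_idx.size
    lookup = np.full(mesh.n_nodes, -1, dtype=np.int64)
    lookup[cond_idx] = np.arange(n)

    sites = lookup[protocol.sites]
    sites = sites[sites >= 0]
    if sites.size == 0:
        raise ValueError("no conductive stimulus site")

    u = np.zeros(n)
    v = np.zeros(n)
    act = np.full(n, -1.0)
    stim_on = protocol.onsets
    stim_off = protocol.onsets + protocol.duration

    n_steps = int(round(t_end / params.dt))
    n_blocks = (n_steps + sample_every - 1) // sample_every
    times = [0.0]
    samples = [u.copy()]
    probe_idx = None
    probe_vals: list[np.ndarray] = []
    if probes is not None:
        probe_idx = lookup[np.asarray(probes)]
        if (probe_idx < 0).any():
            raise ValueError("probe on a non-conductive node")
        probe_vals.append(u[probe_idx].copy())

    done = 0
    for b in range(n_blocks):
        todo = min(sample_every, n_steps - done)
        step_block(
            u, v, A.indptr.astype(np.int64), A.indices.astype(np.int64), A.data,
            params.dt, params.k, params.a, params.eps, params.mu1, params.mu2,
            sites, protocol.amplitude, stim_on, stim_off,
            done * params.dt, todo, act, act_thresh)
        done += todo
        if not np.isfinite(u).all():
            raise FloatingPointError(
                f"simulation diverged at t={done * params.dt:.3f}")
        times.append(done * params.dt)
        samples.append(u.copy())
        if probe_idx is not None:
            probe_vals.append(u[probe_idx].copy())

    act_time = np.where(act < 0, np.inf, act)
    epi_compact = lookup[mesh.epi_surface]
    epi_compact = epi_compact[epi_compact >= 0]
    blocked = bool(epi_compact.size) and not np.isfinite(act_time[epi_compact]).any()

    probe_traces = {}
    if probe_idx is not None:
        arr = np.array(probe_vals)
        for m, g in enumerate(np.asarray(probes)):
            probe_traces[int(g)] = arr[:, m]

    return SimulationRecord(
        times=np.array(times),
        u_samples=np.array(samples),
        act_time=act_time,
        cond_idx=cond_idx,
        operator=A,
        params=params,
        protocol=protocol,
        mesh=mesh,
        probe_traces=probe_traces,
        blocked=blocked,
    )


def sinus_protocol(
    mesh: VoxelMesh,
    realization: FibrosisRealization | None = None,
    amplitude: float = 100.0,
    duration: float = 0.2,
) -> StimulusProtocol:
    """Sinus-rhythm surrogate: stimulate every conductive endocardial node
    simultaneously at t = 0 (the LAT reference time)."""
    sites = mesh.endo_surface
    if realization is not None:
        keep = ~realization.non_conductive_mask.ravel()[sites]
        sites = sites[keep]
    if sites.size == 0:
        raise ValueError("endocardial surface has no conductive node")
    return StimulusProtocol(sites=sites, onsets=np.array([0.0]),
                            amplitude=amplitude, duration=duration)


def pacing_protocol(
    apex_region: np.ndarray,
    count: int = 10,
    period: float = 28.5,
    amplitude: float = 100.0,
    duration: float = 0.2,
) -> StimulusProtocol:
    """High-frequency pacing train used for arrhythmia induction: ``count``
    pulses ``period`` time units apart delivered to the apex region."""
    apex_region = np.asarray(apex_region)
    if apex_region.size == 0:
        raise ValueError("apex region is empty")
    onsets = np.arange(count) * period
    return StimulusProtocol(sites=apex_region, onsets=onsets,
                            amplitude=amplitude, duration=duration)


def measure_period(times: np.ndarray, trace: np.ndarray,
                   prominence: float = 0.2, n_cycles: int = 10) -> float:
    """Mean cycle length over the last ``n_cycles`` peak-to-peak intervals
    of a voltage trace; raises if fewer than ``n_cycles``+1 peaks exist."""
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    peaks, _ = find_peaks(trace, prominence=prominence)
    if peaks.size < n_cycles + 1:
        raise ValueError(
            f"no sustained activity: found {peaks.size} peaks, need {n_cycles + 1}")
    t = times[peaks[-(n_cycles + 1):]]
    return float(np.mean(np.diff(t)))


def conduction_velocity(record: SimulationRecord, axis: int = 2) -> float:
    """Planar-front conduction velocity from tissue activation times along
    the central column of the given axis (least-squares slope of distance
    against activation time)."""
    mesh = record.mesh
    dims = mesh.dims
    ijk = np.column_stack(np.unravel_index(record.cond_idx, dims))
    center = [d // 2 for d in dims]
    other = [ax for ax in range(3) if ax != axis]
    sel = (ijk[:, other[0]] == center[other[0]]) & (ijk[:, other[1]] == center[other[1]])
    t = record.act_time[sel]
    pos = ijk[sel, axis]
    x = pos * mesh.spacing
    # fit only the settled central part of the column: the stimulated end
    # carries the source transient and the far end the boundary effect
    lo, hi = np.quantile(pos, [0.3, 0.9])
    ok = np.isfinite(t) & (pos >= lo) & (pos <= hi)
    if ok.sum() < 4:
        raise ValueError("front did not cross the probe column")
    slope = np.polyfit(t[ok], x[ok], 1)[0]
    return float(abs(slope))
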