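"""Hierarchical reconstruction of fibrosis density from surface maps.

The inverse method estimates per-segment fibrosis densities by driving a
normalized residual between target and simulated surface observables to
zero.  For an observable X (epicardial LAT, endocardial PtP or epicardial
PtP) over N surface nodes the cost is

    C = (1/N) * sum_n (x_n^target - x_n^estimate) / x_n^baseline

where the baseline is the zero-fibrosis run (shortest LAT, largest PtP).
C is signed: for LAT it starts non-negative at 0% density and turns
negative once the candidate over-slows (or blocks) the wave; for PtP the
signs are mirrored.  Each scalar density is found by a hybrid
bisection / modified false-position search on [0, 0.6] (above roughly 60%
density the wave no longer propagates, so the upper endpoint's cost is
known only by sign).

The pipeline refines in four steps: one global density, then the 17 AHA
segments, then 68 sub-segments, and finally three transmural layers per
68-segment (endocardial density fitted on endocardial PtP, epicardial on
epicardial PtP, mid-myocardial on LAT, cycled until all three costs
converge).  Segments are scheduled in four fixed groups of mutually
non-adjacent AHA segments; members of one group are fitted concurrently
within a shared forward simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .electrogram import (
    ElectrodeSet,
    SurfaceFieldMap,
    surface_measurements,
    transfer_matrix,
)
from .fibrosis import FibrosisDensityMap, sample_fibrosis, uniform_field
from .geometry import SegmentHierarchy, VoxelMesh
from .simulation import APParams, run_simulation, sinus_protocol

logger = logging.getLogger(__name__)

__all__ = [
    "CostEvaluation",
    "HybridRootFinder",
    "ReconstructionResult",
    "ForwardEvaluator",
    "cost",
    "hybrid_root_find",
    "schedule_groups",
    "prepare_baseline",
    "reconstruct",
    "evaluate_reconstruction",
]

D_MAX = 0.6           # upper end of the density search interval
BLOCK_RESIDUAL = 10.0  # collapsed |residual| for infinite-LAT sentinels
HIGH_DENSITY_CUT = 0.21  # abnormality threshold for detection counts


# ---------------------------------------------------------------------------
# cost function
# ---------------------------------------------------------------------------

@dataclass
class CostEvaluation:
    """Signed mean normalized residual over one node subset."""

    value: float
    residuals: np.ndarray
    kind: str
    n: int


def cost(
    target: np.ndarray,
    estimate: np.ndarray,
    baseline: np.ndarray,
    subset: np.ndarray | None = None,
    kind: str = "generic",
) -> CostEvaluation:
    """C = mean((target - estimate) / baseline) over the subset.

    Block sentinels collapse to large signed constants: an infinite
    estimate (wave never arrived in the candidate) contributes -10, an
    infinite target +10, both infinite 0.  Only the sign matters to the
    bisection phase of the search.
    """
    t = np.asarray(target, dtype=float)
    e = np.asarray(estimate, dtype=float)
    b = np.asarray(baseline, dtype=float)
    if subset is not None:
        t, e, b = t[subset], e[subset], b[subset]
    if t.size == 0:
        raise ValueError("empty node subset")
    if not np.all(np.isfinite(b) & (b > 0)):
        raise ValueError("baseline must be finite and positive on the subset")
    t_inf = ~np.isfinite(t)
    e_inf = ~np.isfinite(e)
    r = np.empty_like(b)
    ok = ~t_inf & ~e_inf
    r[ok] = (t[ok] - e[ok]) / b[ok]
    r[t_inf & ~e_inf] = BLOCK_RESIDUAL
    r[~t_inf & e_inf] = -BLOCK_RESIDUAL
    r[t_inf & e_inf] = 0.0
    return CostEvaluation(value=float(r.mean()), residuals=r, kind=kind, n=t.size)


# ---------------------------------------------------------------------------
# hybrid bisection / modified false-position search
# ---------------------------------------------------------------------------

class HybridRootFinder:
    """Stepwise scalar root search on [lo, hi] for a signed cost.

    Bisection runs from the assumed bracket (the cost is presumed to change
    sign somewhere in the interval; the value at the upper end is
    indeterminate when the wave blocks, so only its sign is assumed) until
    two evaluated points straddle the root; then the modified
    (Illinois-type) false-position rule takes over, halving the retained
    endpoint's stored value when it survives two iterations.  The search
    stops when |C| < eps, when the proposed density step falls below
    d_min, or at the evaluation cap.

    Drive it with :meth:`propose` / :meth:`update`; this stepping form lets
    several finders share one forward simulation per round.
    """

    def __init__(
        self,
        lo: float = 0.0,
        hi: float = D_MAX,
        eps: float = 0.01,
        d_min: float = 0.01,
        x0: float | None = None,
        sign_lo: int | None = None,
        max_evals: int = 30,
    ):
        if not lo < hi:
            raise ValueError("need lo < hi")
        self.lo, self.hi = lo, hi
        self.eps, self.d_min = eps, d_min
        self.sign_lo = sign_lo
        self.max_evals = max_evals
        self.a, self.b = lo, hi
        self.Ca: float | None = None
        self.Cb: float | None = None
        self._Ca_true: float | None = None  # undamped endpoint values for the
        self._Cb_true: float | None = None  # final secant projection
        self._last_side = 0
        self.history: list[tuple[float, float]] = []
        self.done = False
        self.root: float | None = None
        self.status = "running"
        if x0 is not None and lo < x0 < hi:
            self._pending = float(x0)
        elif sign_lo is None:
            self._pending = lo
        else:
            self._pending = 0.5 * (lo + hi)

    # -- stepping interface ---------------------------------------------
    def propose(self) -> float | None:
        return None if self.done else self._pending

    def _finish(self, root: float, status: str) -> None:
        # Shallow cost curves satisfy |C| < eps over a wide density band, so
        # the last probe can sit anywhere inside the tolerance ball.  When a
        # true bracket exists, the secant zero of its (undamped) endpoint
        # values is the better final estimate; it is exactly the next
        # false-position iterate, returned instead of evaluated.
        if status in ("converged", "step_below_d_min") and \
                self._Ca_true is not None and self._Cb_true is not None:
            denom = self._Cb_true - self._Ca_true
            if denom != 0:
                sec = (self.a * self._Cb_true - self.b * self._Ca_true) / denom
                if self.a <= sec <= self.b:
                    root = sec
        self.done = True
        self.root = float(np.clip(root, self.lo, self.hi))
        self.status = status

    def _best_evaluated(self) -> float:
        x, _ = min(self.history, key=lambda h: abs(h[1]))
        return x

    def update(self, C: float) -> None:
        if self.done:
            raise RuntimeError("root finder already finished")
        x = self._pending
        self.history.append((x, float(C)))
        if self.sign_lo is None:
            # first evaluation fixes the orientation; the opposite sign is
            # assumed at the far end of the interval
            self.sign_lo = 1 if C > 0 else -1
        if (C > 0) == (self.sign_lo > 0):
            self.a, self.Ca = x, float(C)
            self._Ca_true = float(C)
            side = -1
        else:
            self.b, self.Cb = x, float(C)
            self._Cb_true = float(C)
            side = +1
        if abs(C) < self.eps:
            self._finish(x, "converged")
            return
        if len(self.history) >= self.max_evals:
            self._finish(self._best_evaluated(), "max_evals")
            return

        if self.Ca is not None and self.Cb is not None:
            # modified false position (Illinois damping of the stale end)
            if side == self._last_side:
                if side == -1 and self.Cb is not None:
                    self.Cb *= 0.5
                elif side == +1 and self.Ca is not None:
                    self.Ca *= 0.5
            self._last_side = side
            denom = self.Cb - self.Ca
            if denom == 0:
                nxt = 0.5 * (self.a + self.b)
            else:
                nxt = (self.a * self.Cb - self.b * self.Ca) / denom
            nxt = float(np.clip(nxt, self.a, self.b))
        else:
            nxt = 0.5 * (self.a + self.b)

        bracketed = self.Ca is not None and self.Cb is not None
        if abs(nxt - x) < self.d_min:
            # a proposed step below resolution: converged if bracketed,
            # otherwise the cost kept one sign down to the boundary
            self._finish(nxt, "step_below_d_min" if bracketed else "no_root_in_interval")
            return
        if self.b - self.a < self.d_min:
            self._finish(self._best_evaluated(),
                         "step_below_d_min" if bracketed else "no_root_in_interval")
            return
        self._pending = nxt


def hybrid_root_find(
    evaluate,
    lo: float = 0.0,
    hi: float = D_MAX,
    eps: float = 0.01,
    d_min: float = 0.01,
    x0: float | None = None,
    sign_lo: int | None = None,
    max_evals: int = 30,
) -> tuple[float, HybridRootFinder]:
    """Run a :class:`HybridRootFinder` to completion against ``evaluate``
    (a density -> signed cost callable); returns (density, finder)."""
    f = HybridRootFinder(lo, hi, eps, d_min, x0, sign_lo, max_evals)
    while not f.done:
        x = f.propose()
        f.update(float(evaluate(x)))
    return f.root, f


# ---------------------------------------------------------------------------
# scheduling
# ---------------------------------------------------------------------------

#: Fixed groups of mutually non-adjacent AHA segments processed together.
GROUPS_17: tuple[tuple[int, ...], ...] = (
    (1, 3, 5, 14, 16),
    (2, 4, 6, 13, 15),
    (7, 9, 11, 17),
    (8, 10, 12),
)


def schedule_groups(h: SegmentHierarchy) -> list[list[int]]:
    """Ordered processing groups at the 17-segment level.

    For the full AHA layout these are the four fixed non-adjacent groups;
    for reduced hierarchies (e.g. a single-segment slab) every present
    segment forms its own group.
    """
    present = set(int(s) for s in h.segment_ids(17))
    if present == set(range(1, 18)):
        return [list(g) for g in GROUPS_17]
    return [[s] for s in sorted(present)]


def group_slots_68(group: list[int]) -> list[list[int]]:
    """Sub-segment slots: members' .1 children together, then .2, ..."""
    return [[4 * (s - 1) + 1 + q for s in group] for q in range(4)]


# ---------------------------------------------------------------------------
# forward evaluation machinery
# ---------------------------------------------------------------------------

class ForwardEvaluator:
    """Caches everything reusable across candidate evaluations of one
    reconstruction run: the common uniform comparison field, electrode
    transfer weights over the full myocardium, and completed forward
    evaluations keyed by the candidate density map."""

    def __init__(
        self,
        mesh: VoxelMesh,
        params: APParams,
        endo_electrodes: ElectrodeSet,
        epi_electrodes: ElectrodeSet,
        seed: int,
        t_end: float,
        idw_radius: float | None = None,
        sample_every: int = 50,
        resample_each_eval: bool = False,
        stim_amplitude: float = 100.0,
        stim_duration: float = 0.2,
        antithetic: bool = False,
        lat_blank: float | None = None,
    ):
        self.mesh = mesh
        self.params = params
        self.endo_electrodes = endo_electrodes
        self.epi_electrodes = epi_electrodes
        self.seed = int(seed)
        self.t_end = float(t_end)
        self.idw_radius = idw_radius
        self.sample_every = int(sample_every)
        self.resample_each_eval = resample_each_eval
        self.stim_amplitude = float(stim_amplitude)
        self.stim_duration = float(stim_duration)
        self.antithetic = antithetic
        self.lat_blank = lat_blank
        self.field = uniform_field(mesh, seed)
        self.myo_idx = mesh.myo_indices
        self._Z_endo_all = transfer_matrix(endo_electrodes, mesh, self.myo_idx)
        self._Z_epi_all = transfer_matrix(epi_electrodes, mesh, self.myo_idx)
        self.n_forward = 0
        self._cache: dict[bytes, SurfaceFieldMap] = {}

    def _key(self, density: np.ndarray) -> bytes:
        return np.round(density.ravel()[self.myo_idx], 6).tobytes()

    def __call__(self, density: FibrosisDensityMap) -> SurfaceFieldMap:
        key = self._key(density.values)
        if not self.resample_each_eval:
            hit = self._cache.get(key)
            if hit is not None:
                return hit
        if self.resample_each_eval:
            flds = [uniform_field(self.mesh, self.seed + 1 + self.n_forward)]
        elif self.antithetic:
            # antithetic pair: a knockout field and its mirror; the cost is
            # linear in the estimated fields, so averaging the two
            # measurements halves the realization variance of the estimator
            flds = [self.field, 1.0 - self.field]
        else:
            flds = [self.field]
        measured = []
        for fld in flds:
            realization = sample_fibrosis(density, self.seed, self.mesh, field=fld)
            protocol = sinus_protocol(self.mesh, realization,
                                      amplitude=self.stim_amplitude,
                                      duration=self.stim_duration)
            record = run_simulation(
                self.mesh, realization, self.params, protocol, self.t_end,
                sample_every=self.sample_every)
            cols = np.searchsorted(self.myo_idx, record.cond_idx)
            measured.append(surface_measurements(
                record, self.endo_electrodes, self.epi_electrodes,
                radius=self.idw_radius,
                Z_endo=self._Z_endo_all[:, cols],
                Z_epi=self._Z_epi_all[:, cols],
                lat_blank=self.lat_blank))
            self.n_forward += 1
        fields = measured[0] if len(measured) == 1 else _average_fields(measured)
        self._cache[key] = fields
        return fields


def _average_fields(maps: list[SurfaceFieldMap]) -> SurfaceFieldMap:
    """Elementwise mean of surface measurements over realizations; LAT
    block sentinels average over the finite subset and stay infinite only
    where every realization blocked."""

    def avg(arrs):
        a = np.stack(arrs)
        finite = np.isfinite(a)
        out = np.where(finite.any(axis=0),
                       np.nansum(np.where(finite, a, 0.0), axis=0)
                       / np.maximum(finite.sum(axis=0), 1),
                       np.inf)
        return out

    first = maps[0]
    return SurfaceFieldMap(
        endo_nodes=first.endo_nodes,
        epi_nodes=first.epi_nodes,
        lat_endo=avg([m.lat_endo for m in maps]),
        lat_epi=avg([m.lat_epi for m in maps]),
        ptp_endo=np.mean([m.ptp_endo for m in maps], axis=0),
        ptp_epi=np.mean([m.ptp_epi for m in maps], axis=0),
        meta=first.meta,
    )


def prepare_baseline(evaluator: ForwardEvaluator) -> SurfaceFieldMap:
    """One forward run at 0% fibrosis; its per-node LAT (the shortest) and
    PtP (the largest) normalize every subsequent cost."""
    zero = FibrosisDensityMap(values=np.zeros(evaluator.mesh.dims),
                              provenance="baseline")
    base = evaluator(zero)
    if not np.all(base.ptp_endo > 0) or not np.all(base.ptp_epi > 0):
        raise ValueError("baseline PtP vanishes somewhere: electrode coverage fault")
    if not np.all(np.isfinite(base.lat_epi)):
        raise ValueError("baseline wave never reached part of the epicardium")
    return base


# ---------------------------------------------------------------------------
# the multiscale pipeline
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionResult:
    """Estimated densities at every level plus bookkeeping."""

    d_lv: float = 0.0
    d17: dict[int, float] = field(default_factory=dict)
    d68: dict[int, float] = field(default_factory=dict)
    d204: dict[int, float] = field(default_factory=dict)
    convergence: list[dict] = field(default_factory=list)
    n_forward: int = 0
    flags: dict[str, str] = field(default_factory=dict)

    def density_map(self, h: SegmentHierarchy, level: int = 204) -> FibrosisDensityMap:
        from .fibrosis import density_from_segments
        values = {17: self.d17, 68: self.d68, 204: self.d204}[level]
        labels = {17: h.labels_17, 68: h.labels_68, 204: h.labels_204}[level]
        return density_from_segments(values, labels, provenance=f"reconstruction:{level}")


def _patches(h: SegmentHierarchy, mesh: VoxelMesh, level: int):
    """Per-segment index subsets into the endo/epi surface node lists."""
    labels = {17: h.labels_17, 68: h.labels_68}[level].ravel()
    endo_lab = labels[mesh.endo_surface]
    epi_lab = labels[mesh.epi_surface]
    return (
        {int(s): np.flatnonzero(endo_lab == s) for s in h.segment_ids(level)},
        {int(s): np.flatnonzero(epi_lab == s) for s in h.segment_ids(level)},
    )


def _concurrent_round(
    finders: dict[int, HybridRootFinder],
    set_density,
    evaluate_costs,
    log,
    stage: str,
):
    """Advance a set of root finders to completion, one shared forward
    simulation per round.  ``set_density(seg, D)`` writes a candidate into
    the working density assignment; ``evaluate_costs(active)`` runs the
    forward model once and returns {seg: C}."""
    while True:
        active = {s: f.propose() for s, f in finders.items() if not f.done}
        if not active:
            break
        for s, D in active.items():
            set_density(s, D)
        costs = evaluate_costs(list(active))
        for s in active:
            finders[s].update(costs[s])
            log.append({"stage": stage, "segment": s,
                        "density": active[s], "cost": costs[s]})
    for s, f in finders.items():
        set_density(s, f.root)


def reconstruct(
    target: SurfaceFieldMap,
    evaluator: ForwardEvaluator,
    h: SegmentHierarchy,
    baseline: SurfaceFieldMap | None = None,
    eps: float = 0.01,
    d_min: float = 0.01,
    max_cycles: int = 10,
    max_evals: int = 30,
    steps: tuple[int, ...] = (1, 2, 3, 4),
) -> ReconstructionResult:
    """Run the multiscale pipeline against target LAT/PtP surface fields.

    Step 1 fits one global density on the whole-epicardium LAT cost;
    steps 2 and 3 refine it over the 17- and 68-segment partitions (LAT
    cost restricted to each segment's epicardial patch, warm-started from
    the parent estimate); step 4 fits the three transmural layers of every
    68-segment on endocardial PtP, epicardial PtP and LAT respectively,
    cycling endo -> epi -> mid until all three costs satisfy the tolerance
    at the end of a cycle, the densities stop moving, or the cycle cap is
    reached.
    """
    mesh = evaluator.mesh
    if baseline is None:
        baseline = prepare_baseline(evaluator)
    result = ReconstructionResult()
    log = result.convergence

    seg17 = [int(s) for s in h.segment_ids(17)]
    multi = len(seg17) > 1
    density = np.zeros(mesh.dims)

    def evaluate_fields() -> SurfaceFieldMap:
        return evaluator(FibrosisDensityMap(values=density, provenance="optimizer step"))

    def lat_cost(fields: SurfaceFieldMap, subset=None) -> float:
        return cost(target.lat_epi, fields.lat_epi, baseline.lat_epi,
                    subset, kind="LAT").value

    # ---- step 1: global density ----------------------------------------
    if 1 in steps:
        def eval_global(D: float) -> float:
            density[mesh.myocardium_mask] = D
            return lat_cost(evaluate_fields())

        d_lv, finder = hybrid_root_find(
            eval_global, eps=eps, d_min=d_min, max_evals=max_evals)
        result.d_lv = d_lv
        result.flags["step1"] = finder.status
        for x, c in finder.history:
            log.append({"stage": "step1", "segment": 0, "density": x, "cost": c})
        density[mesh.myocardium_mask] = d_lv

    result.d17 = {s: result.d_lv for s in seg17}

    # ---- steps 2 and 3: per-segment LAT refinement ----------------------
    groups = schedule_groups(h)
    labels17 = h.labels_17
    if 2 in steps and multi:
        _, epi_patch = _patches(h, mesh, 17)

        def set17(s, D):
            density[labels17 == s] = D
            result.d17[s] = D

        for group in groups:
            finders = {
                s: HybridRootFinder(eps=eps, d_min=d_min, x0=result.d17[s],
                                    sign_lo=+1, max_evals=max_evals)
                for s in group if epi_patch[s].size > 0
            }

            def costs17(active):
                fields = evaluate_fields()
                return {s: lat_cost(fields, epi_patch[s]) for s in active}

            _concurrent_round(finders, set17, costs17, log, "step2")

    labels68 = h.labels_68
    result.d68 = {}
    if labels68 is not None:
        for c, p in (h.parent_68 or {1: 1}).items():
            result.d68[c] = result.d17.get(p, result.d_lv)
    if 3 in steps and multi and labels68 is not None:
        _, epi_patch68 = _patches(h, mesh, 68)

        def set68(s, D):
            density[labels68 == s] = D
            result.d68[s] = D

        for group in groups:
            for slot in group_slots_68(group):
                finders = {
                    s: HybridRootFinder(eps=eps, d_min=d_min, x0=result.d68[s],
                                        sign_lo=+1, max_evals=max_evals)
                    for s in slot if s in result.d68 and epi_patch68[s].size > 0
                }

                def costs68(active):
                    fields = evaluate_fields()
                    return {s: lat_cost(fields, epi_patch68[s]) for s in active}

                _concurrent_round(finders, set68, costs68, log, "step3")

    # ---- step 4: transmural layers --------------------------------------
    result.d204 = {}
    if h.labels_204 is not None:
        for c, p in h.parent_204.items():
            result.d204[c] = result.d68.get(p, result.d_lv)
    if 4 in steps and h.labels_204 is not None:
        labels204 = h.labels_204
        endo_patch68, epi_patch68 = _patches(h, mesh, 68)
        layer_of = h.layer_204  # 204-label -> 'endo'|'mid'|'epi'
        children = {}
        for c, p in h.parent_204.items():
            children.setdefault(p, {})[layer_of[c]] = c

        def set204(c, D):
            density[labels204 == c] = D
            result.d204[c] = D

        def layer_cost(fields: SurfaceFieldMap, seg68: int, layer: str) -> float:
            if layer == "endo":
                sub = endo_patch68[seg68]
                return cost(target.ptp_endo, fields.ptp_endo,
                            baseline.ptp_endo, sub, kind="PtP_endo").value
            if layer == "epi":
                sub = epi_patch68[seg68]
                return cost(target.ptp_epi, fields.ptp_epi,
                            baseline.ptp_epi, sub, kind="PtP_epi").value
            return lat_cost(fields, epi_patch68[seg68])

        sign = {"endo": -1, "epi": -1, "mid": +1}
        for group in groups:
            for slot in group_slots_68(group):
                segs = [s for s in slot
                        if s in children
                        and endo_patch68.get(s, np.empty(0)).size > 0
                        and epi_patch68.get(s, np.empty(0)).size > 0]
                if not segs:
                    continue
                for cycle in range(max_cycles):
                    before = {s: {ly: result.d204[children[s][ly]]
                                  for ly in ("endo", "epi", "mid")} for s in segs}
                    for layer in ("endo", "epi", "mid"):
                        finders = {
                            s: HybridRootFinder(
                                eps=eps, d_min=d_min,
                                x0=result.d204[children[s][layer]],
                                sign_lo=sign[layer], max_evals=max_evals)
                            for s in segs
                        }

                        def set_layer(s, D, layer=layer):
                            set204(children[s][layer], D)

                        def costs_layer(active, layer=layer):
                            fields = evaluate_fields()
                            return {s: layer_cost(fields, s, layer) for s in active}

                        _concurrent_round(finders, set_layer, costs_layer, log,
                                          f"step4:{layer}")
                    # cycle convergence: all three costs small at the final
                    # densities, or the densities stopped moving
                    fields = evaluate_fields()
                    max_c = max(abs(layer_cost(fields, s, ly))
                                for s in segs for ly in ("endo", "epi", "mid"))
                    max_move = max(
                        abs(result.d204[children[s][ly]] - before[s][ly])
                        for s in segs for ly in ("endo", "epi", "mid"))
                    log.append({"stage": "step4:cycle", "segment": -1,
                                "density": max_move, "cost": max_c})
                    if max_c < eps or max_move < d_min:
                        break
                else:
                    for s in segs:
                        result.flags[f"step4:{s}"] = "cycle_cap"

    result.n_forward = evaluator.n_forward
    return result


# ---------------------------------------------------------------------------
# evaluation against a known target map
# ---------------------------------------------------------------------------

def _pearson_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.polyfit(x, y, 1)[0])
    return r, slope


def evaluate_reconstruction(
    result: ReconstructionResult,
    target_density: FibrosisDensityMap,
    h: SegmentHierarchy,
    mesh: VoxelMesh,
) -> pd.DataFrame:
    """Per-group agreement between reconstructed and target densities.

    Groups: the three 204-level layers, all 204 segments, and the 68
    transmural segments (node-count-weighted layer average).  Reported per
    group: Pearson R, least-squares slope, mean and std of the signed
    error (estimate - target, percentage points), and detection counts at
    the 21% high-density threshold.
    """
    if h.labels_204 is None:
        raise ValueError("need a full 204-level hierarchy to evaluate")
    lab204 = h.labels_204.ravel()
    tvals = target_density.values.ravel()
    rows = []
    t204, e204, layer_tags, counts = [], [], [], []
    for c in sorted(result.d204):
        sel = lab204 == c
        t204.append(tvals[sel].mean())
        e204.append(result.d204[c])
        layer_tags.append(h.layer_204[c])
        counts.append(int(sel.sum()))
    t204 = np.array(t204)
    e204 = np.array(e204)
    layer_tags = np.array(layer_tags)
    counts = np.array(counts)

    def add_row(name, t, e):
        if t.size < 3:
            rows.append({"group": name, "n": int(t.size), "R": np.nan,
                         "slope": np.nan, "mean_error_pct": np.nan,
                         "std_error_pct": np.nan, "n_high_target": 0,
                         "n_high_detected": 0, "flag": "too_few_segments"})
            return
        r, slope = _pearson_slope(t, e)
        err = (e - t) * 100.0
        high = t > HIGH_DENSITY_CUT
        rows.append({
            "group": name, "n": int(t.size), "R": r, "slope": slope,
            "mean_error_pct": float(err.mean()),
            "std_error_pct": float(err.std()),
            "n_high_target": int(high.sum()),
            "n_high_detected": int((high & (e > HIGH_DENSITY_CUT)).sum()),
            "flag": "",
        })

    for name, tag in (("sub_endocardial", "endo"), ("mid_myocardial", "mid"),
                      ("sub_epicardial", "epi")):
        sel = layer_tags == tag
        add_row(name, t204[sel], e204[sel])
    add_row("all", t204, e204)

    # transmural 68: node-weighted mean of the three layers
    segs68 = sorted({p for p in h.parent_204.values()})
    t68, e68 = [], []
    lab68 = h.labels_68.ravel()
    for s in segs68:
        child = [c for c, p in h.parent_204.items() if p == s and c in result.d204]
        if not child:
            continue
        w = np.array([counts[sorted(result.d204).index(c)] for c in child], dtype=float)
        e68.append(float(np.average([result.d204[c] for c in child], weights=w)))
        t68.append(float(tvals[lab68 == s].mean()))
    add_row("transmural", np.array(t68), np.array(e68))
    return pd.DataFrame(rows)
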