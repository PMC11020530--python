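"""Electrode placement, pseudo-EGM synthesis, LAT/PtP, IDW interpolation."""

import numpy as np
import pytest
from scipy import sparse

from fibrograd.electrogram import (
    EGMTrace,
    compute_egm,
    compute_lat,
    compute_ptp,
    idw_interpolate,
    place_electrodes,
    surface_measurements,
    transfer_matrix,
)
from fibrograd.geometry import build_slab_mesh
from fibrograd.simulation import (
    APParams,
    SimulationRecord,
    StimulusProtocol,
    run_simulation,
    sinus_protocol,
)


def _fake_record(mesh, u_samples, times):
    """Record whose operator is the identity, so the 'diffusion current'
    equals the stored field — lets closed-form EGM sums be checked."""
    cond_idx = mesh.myo_indices
    n = cond_idx.size
    return SimulationRecord(
        times=np.asarray(times, dtype=float),
        u_samples=np.asarray(u_samples, dtype=float),
        act_time=np.zeros(n),
        cond_idx=cond_idx,
        operator=sparse.identity(n, format="csr"),
        params=APParams(d_long=1.0, d_trans=1.0),
        protocol=StimulusProtocol(sites=cond_idx[:1], onsets=np.array([0.0])),
        mesh=mesh,
    )


class TestPlacement:
    def test_seed_reproducible(self, slab_mesh):
        a = place_electrodes(slab_mesh, "epi", 30, seed=7)
        b = place_electrodes(slab_mesh, "epi", 30, seed=7)
        assert np.array_equal(a.positions, b.positions)

    def test_all_nodes_when_n_equals_surface(self, slab_mesh):
        n = slab_mesh.endo_surface.size
        es = place_electrodes(slab_mesh, "endo", n, seed=1)
        assert set(es.surface_nodes) == set(slab_mesh.endo_surface)

    def test_too_many_rejected(self, slab_mesh):
        with pytest.raises(ValueError):
            place_electrodes(slab_mesh, "endo", 10_000, seed=1)

    def test_offset_outward(self, slab_mesh):
        es = place_electrodes(slab_mesh, "epi", 10, seed=3, offset_voxels=1.0)
        zmax = (slab_mesh.dims[2] - 1) * slab_mesh.spacing
        assert np.allclose(es.positions[:, 2], zmax + slab_mesh.spacing)

    def test_stratified_counts_proportional(self, lv_mesh, lv_hierarchy):
        es = place_electrodes(lv_mesh, "epi", 100, seed=5,
                              stratify_labels=lv_hierarchy.labels_17)
        labels = lv_hierarchy.labels_17.ravel()[es.surface_nodes]
        surf_labels = lv_hierarchy.labels_17.ravel()[lv_mesh.epi_surface]
        for s in np.unique(surf_labels):
            quota = 100 * (surf_labels == s).sum() / surf_labels.size
            assert abs((labels == s).sum() - quota) <= 1.0


class TestEGMSynthesis:
    def test_single_source_inverse_square(self):
        """One source of current I at distance 2 gives EGM = I / 4."""
        mesh = build_slab_mesh((3, 3, 3), (1, 0, 0), spacing=1.0)
        rec = _fake_record(mesh, np.zeros((1, 27)), [0.0])
        src = 13  # center node (1,1,1)
        rec.u_samples[0, src] = 8.0
        es = place_electrodes(mesh, "epi", 1, seed=0, offset_voxels=0.0)
        # put the electrode exactly 2 length units above the source
        es.positions = np.array([[1.0, 1.0, 3.0]])
        traces = compute_egm(rec, es)
        assert traces[0].potentials[0] == pytest.approx(8.0 / 4.0)

    def test_two_sources_sum(self):
        """(I, r) pairs (1, 1) and (4, 2) sum to 1/1 + 4/4 = 2."""
        mesh = build_slab_mesh((3, 3, 5), (1, 0, 0), spacing=1.0)
        rec = _fake_record(mesh, np.zeros((1, 45)), [0.0])
        flat = np.arange(45).reshape(3, 3, 5)
        rec.u_samples[0, np.flatnonzero(mesh.myo_indices == flat[1, 1, 3])] = 1.0
        rec.u_samples[0, np.flatnonzero(mesh.myo_indices == flat[1, 1, 2])] = 4.0
        es = place_electrodes(mesh, "epi", 1, seed=0)
        es.positions = np.array([[1.0, 1.0, 4.0]])
        traces = compute_egm(rec, es)
        assert traces[0].potentials[0] == pytest.approx(2.0)

    def test_resting_tissue_silent(self):
        mesh = build_slab_mesh((3, 3, 3), (1, 0, 0))
        rec = _fake_record(mesh, np.zeros((4, 27)), np.linspace(0, 1, 4))
        es = place_electrodes(mesh, "endo", 2, seed=0)
        for tr in compute_egm(rec, es):
            assert np.all(tr.potentials == 0.0)

    def test_linearity_in_current_field(self, rng):
        mesh = build_slab_mesh((4, 4, 4), (1, 0, 0))
        u1 = rng.normal(size=(3, 64))
        u2 = rng.normal(size=(3, 64))
        es = place_electrodes(mesh, "epi", 3, seed=1)
        t = np.arange(3.0)
        p1 = compute_egm(_fake_record(mesh, u1, t), es)
        p2 = compute_egm(_fake_record(mesh, u2, t), es)
        p12 = compute_egm(_fake_record(mesh, u1 + u2, t), es)
        for a, b, c in zip(p1, p2, p12):
            assert np.allclose(a.potentials + b.potentials, c.potentials)

    def test_distance_guard(self, slab_mesh):
        """An electrode inside the tissue is guarded to half a voxel."""
        Z = transfer_matrix(
            place_electrodes(slab_mesh, "endo", 1, seed=0, offset_voxels=0.0),
            slab_mesh, slab_mesh.myo_indices)
        assert Z.max() <= (2.0 / slab_mesh.spacing) ** 2 + 1e-9


class TestLAT:
    def test_constant_downstroke_earliest_sample(self):
        t = np.linspace(0, 1, 11)
        tr = EGMTrace(0, t, -t)
        assert compute_lat(tr) == pytest.approx(t[1])

    def test_analytic_downstroke_location(self):
        """Sigmoid drop centered at t* = 7.2 has its steepest downstroke
        exactly there."""
        t = np.arange(0.0, 14.4001, 0.1)
        tr = EGMTrace(0, t, -np.tanh((t - 7.2) / 0.8))
        assert compute_lat(tr) == pytest.approx(7.2, abs=1e-9)
        assert compute_lat(tr, reference_time=2.0) == pytest.approx(5.2, abs=1e-9)

    def test_flat_trace_blocked(self):
        t = np.linspace(0, 1, 20)
        assert compute_lat(EGMTrace(0, t, np.zeros(20))) == np.inf

    def test_blanking_skips_early_artifact(self):
        t = np.arange(0.0, 10.0, 0.1)
        x = -5 * np.exp(-((t - 0.3) / 0.1) ** 2) - np.tanh((t - 6.0) / 0.5)
        assert compute_lat(EGMTrace(0, t, x)) < 1.0
        assert compute_lat(EGMTrace(0, t, x), blank_until=2.0) == pytest.approx(6.0, abs=0.1)


class TestPtP:
    @pytest.mark.parametrize("samples,want", [
        (np.zeros(5), 0.0),
        (np.array([3.2, -1.1, 0.0]), 4.3),
        (2.5 * np.sin(np.linspace(0, 4 * np.pi, 400)), 5.0),
    ])
    def test_examples(self, samples, want):
        tr = EGMTrace(0, np.linspace(0, 1, samples.size), samples)
        assert compute_ptp(tr) == pytest.approx(want, abs=1e-3)


class TestIDW:
    def test_weight_zero_at_radius(self):
        """An electrode exactly at distance R contributes nothing."""
        nodes = np.array([[0.0, 0.0, 0.0]])
        elec = np.array([[4.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        vals, _ = idw_interpolate(np.array([999.0, 5.0]), elec, nodes, radius=4.0)
        assert vals[0] == pytest.approx(5.0)

    def test_single_electrode_normalization(self):
        nodes = np.array([[0.0, 0.0, 0.0]])
        elec = np.array([[1.0, 1.0, 0.0]])
        vals, _ = idw_interpolate(np.array([5.0]), elec, nodes, radius=4.0)
        assert vals[0] == pytest.approx(5.0)

    def test_hand_worked_two_electrode_value(self):
        """Weights ((4-1)/(4*1))^2 and ((4-2)/(4*2))^2 give value 0.1."""
        nodes = np.array([[0.0, 0.0, 0.0]])
        elec = np.array([[1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        vals, _ = idw_interpolate(np.array([0.0, 1.0]), elec, nodes, radius=4.0)
        assert vals[0] == pytest.approx(0.1)

    def test_coincident_node_takes_exact_value(self):
        nodes = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        elec = np.array([[1.0, 2.0, 3.0], [0.5, 0.0, 0.0]])
        vals, _ = idw_interpolate(np.array([7.0, 1.0]), elec, nodes, radius=5.0)
        assert vals[0] == 7.0

    def test_fallback_flagged_outside_radius(self):
        nodes = np.array([[10.0, 0.0, 0.0]])
        elec = np.array([[0.0, 0.0, 0.0]])
        vals, fb = idw_interpolate(np.array([3.0]), elec, nodes, radius=1.0)
        assert vals[0] == 3.0 and fb[0]

    def test_convex_combination_bounds(self, rng):
        elec = rng.uniform(0, 2, size=(40, 3))
        vals = rng.normal(size=40)
        nodes = rng.uniform(0, 2, size=(100, 3))
        out, fb = idw_interpolate(vals, elec, nodes, radius=1.5)
        ok = ~fb
        assert np.all(out[ok] >= vals.min() - 1e-12)
        assert np.all(out[ok] <= vals.max() + 1e-12)


class TestSurfaceMeasurements:
    def test_endocardial_lat_zero_under_sinus(self, iso_params):
        """With simultaneous endocardial stimulation the endocardial LAT is
        the reference time: ~0 within the sampling resolution."""
        mesh = build_slab_mesh((12, 12, 14), (1, 0, 0))
        rec = run_simulation(mesh, None, iso_params, sinus_protocol(mesh),
                             t_end=3.0, sample_every=25)
        endo_e = place_electrodes(mesh, "endo", 20, seed=1)
        epi_e = place_electrodes(mesh, "epi", 20, seed=2)
        f = surface_measurements(rec, endo_e, epi_e)
        assert np.all(f.lat_endo == 0.0)
        # epicardial LAT is the transmural propagation time: strictly later
        assert np.all(f.lat_epi > 0)
        assert np.all(f.ptp_endo > 0) and np.all(f.ptp_epi > 0)
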