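"""Monodomain solver: stability guard, stencil correctness, wave physics."""

import numpy as np
import pytest
import sympy as sp

from fibrograd.fibrosis import FibrosisDensityMap, sample_fibrosis
from fibrograd.geometry import build_slab_mesh
from fibrograd.simulation import (
    APParams,
    StimulusProtocol,
    build_operator,
    conduction_velocity,
    measure_period,
    pacing_protocol,
    run_simulation,
    sinus_protocol,
)


class TestParams:
    def test_stability_guard(self):
        with pytest.raises(ValueError, match="stability"):
            APParams(d_long=4.0, d_trans=4.0)  # dt 0.0015 too big for D=4

    def test_anisotropy_ordering(self):
        with pytest.raises(ValueError):
            APParams(d_long=0.1, d_trans=0.5)

    def test_defaults_stable(self):
        APParams()
        APParams(d_long=1.0, d_trans=1.0)


class TestStencilOracle:
    """The 19-point anisotropic stencil against a symbolic divergence
    oracle: second-order interior convergence on a smooth field with a
    smoothly varying fiber tensor."""

    @staticmethod
    def _exact_lap(dL, dT):
        x, y, z = sp.symbols("x y z")
        u = sp.sin(1.3 * x + 0.4) * sp.cos(0.9 * y) * sp.sin(1.1 * z + 0.2)
        phi = 0.7 * x + 0.3 * y - 0.2 * z  # in-plane fiber angle
        psi = 0.4 * sp.sin(0.5 * x + 0.8 * z)  # elevation
        f = sp.Matrix([sp.cos(psi) * sp.cos(phi), sp.cos(psi) * sp.sin(phi),
                       sp.sin(psi)])
        D = dT * sp.eye(3) + (dL - dT) * f * f.T
        grad = sp.Matrix([sp.diff(u, v) for v in (x, y, z)])
        flux = D * grad
        div = sum(sp.diff(flux[i], v) for i, v in enumerate((x, y, z)))
        return (sp.lambdify((x, y, z), u, "numpy"),
                sp.lambdify((x, y, z), div, "numpy"),
                sp.lambdify((x, y, z), f.T, "numpy"))

    def test_second_order_convergence(self):
        dL, dT = 1.0, 0.25
        u_f, div_f, fib_f = self._exact_lap(dL, dT)
        errors = []
        for n, dr in ((17, 0.1), (33, 0.05)):
            mesh = build_slab_mesh((n, n, n), (1, 0, 0), spacing=dr)
            X, Y, Z = np.meshgrid(*(np.arange(n) * dr,) * 3, indexing="ij")
            fib = np.moveaxis(np.squeeze(np.array(fib_f(X, Y, Z))), 0, -1)
            mesh.fibers = fib / np.linalg.norm(fib, axis=-1, keepdims=True)
            params = APParams(dr=dr, dt=1e-4, d_long=dL, d_trans=dT)
            A, cond_idx = build_operator(mesh, None, params)
            u = u_f(X, Y, Z).ravel()
            got = (A @ u).reshape(n, n, n)
            want = div_f(X, Y, Z)
            interior = (slice(2, -2),) * 3
            errors.append(np.abs(got[interior] - want[interior]).max())
        rate = np.log2(errors[0] / errors[1])
        assert rate > 1.7, f"convergence rate {rate:.2f}, errors {errors}"

    def test_constant_field_in_kernel(self, slab_mesh, iso_params):
        """div(D grad const) = 0 including at no-flux boundaries."""
        A, _ = build_operator(slab_mesh, None, iso_params)
        const = np.full(A.shape[0], 0.7)
        assert np.abs(A @ const).max() < 1e-10


class TestDynamics:
    def test_rest_state_is_equilibrium(self, slab_mesh, iso_params):
        prot = StimulusProtocol(sites=slab_mesh.endo_surface,
                                onsets=np.array([0.0]), amplitude=0.0)
        rec = run_simulation(slab_mesh, None, iso_params, prot, t_end=1.0)
        assert np.all(rec.u_samples == 0.0)
        assert not np.isfinite(rec.act_time).any()
        assert rec.blocked

    def test_full_fibrosis_band_blocks(self, iso_params):
        """A 100% non-conductive band across the slab stops the wave."""
        mesh = build_slab_mesh((12, 12, 20), (1, 0, 0))
        vals = np.zeros(mesh.dims)
        vals[:, :, 9:12] = 1.0
        vals[~mesh.myocardium_mask] = 0.0
        r = sample_fibrosis(FibrosisDensityMap(vals), seed=1, mesh=mesh)
        rec = run_simulation(mesh, r, iso_params, sinus_protocol(mesh, r), t_end=12.0)
        ijk = np.column_stack(np.unravel_index(rec.cond_idx, mesh.dims))
        distal = ijk[:, 2] >= 12
        assert not np.isfinite(rec.act_time[distal]).any()
        assert rec.blocked
        proximal = ijk[:, 2] < 9
        assert np.isfinite(rec.act_time[proximal]).all()

    def test_cv_scales_with_sqrt_diffusivity(self):
        """Reaction-diffusion front speed is proportional to sqrt(D): a 4x
        diffusivity ratio gives a 2x velocity ratio within 5%."""
        mesh = build_slab_mesh((14, 14, 48), (1, 0, 0))
        cvs = {}
        for D in (0.25, 1.0):
            params = APParams(d_long=D, d_trans=D)
            rec = run_simulation(mesh, None, params, sinus_protocol(mesh),
                                 t_end=9.0, sample_every=200)
            cvs[D] = conduction_velocity(rec)
        assert cvs[1.0] / cvs[0.25] == pytest.approx(2.0, rel=0.05)

    def test_cv_consistent_under_mesh_refinement(self):
        """Halving the space step (with the time step rescaled to keep the
        explicit scheme stable) changes the slab conduction velocity by
        less than 5%."""
        cvs = []
        for dr, dt, nz in ((0.1, 0.0015, 40), (0.05, 0.0004, 80)):
            mesh = build_slab_mesh((9, 9, nz), (1, 0, 0), spacing=dr)
            params = APParams(d_long=1.0, d_trans=1.0, dr=dr, dt=dt)
            rec = run_simulation(mesh, None, params, sinus_protocol(mesh),
                                 t_end=4.0, sample_every=500)
            cvs.append(conduction_velocity(rec))
        assert cvs[1] == pytest.approx(cvs[0], rel=0.05)

    def test_activation_monotone_along_cable(self, iso_params):
        """Planar-front activation times increase monotonically with
        distance from the stimulated face."""
        mesh = build_slab_mesh((8, 8, 30), (1, 0, 0))
        rec = run_simulation(mesh, None, iso_params, sinus_protocol(mesh),
                             t_end=4.0, sample_every=200)
        ijk = np.column_stack(np.unravel_index(rec.cond_idx, mesh.dims))
        col = (ijk[:, 0] == 4) & (ijk[:, 1] == 4)
        act = rec.act_time[col][np.argsort(ijk[col, 2])]
        assert np.isfinite(act).all()
        assert np.all(np.diff(act) >= 0)

    def test_fibrosis_slows_conduction(self, iso_params):
        """Mean epicardial activation time rises monotonically with
        fibrosis density (Spearman rho > 0.9 over 0-50%)."""
        from scipy.stats import spearmanr
        mesh = build_slab_mesh((16, 16, 16), (1, 0, 0))
        densities = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
        t_end = 15.0
        mean_act = []
        for d in densities:
            per_seed = []
            for seed in (1, 2):
                dm = FibrosisDensityMap(np.where(mesh.myocardium_mask, d, 0.0))
                r = sample_fibrosis(dm, seed=seed, mesh=mesh)
                rec = run_simulation(mesh, r, iso_params, sinus_protocol(mesh, r),
                                     t_end=t_end, sample_every=400)
                epi = rec.compact_of(mesh.epi_surface)
                act = rec.act_time[epi[epi >= 0]]
                per_seed.append(np.where(np.isfinite(act), act, t_end).mean())
            mean_act.append(np.mean(per_seed))
        rho = spearmanr(densities, mean_act).statistic
        assert rho > 0.9
        assert np.all(np.diff(mean_act) > -1e-9)


class TestProtocols:
    def test_sinus_sites_are_endo_face(self, slab_mesh):
        prot = sinus_protocol(slab_mesh)
        assert set(prot.sites) == set(slab_mesh.endo_surface)
        assert prot.onsets[0] == 0.0

    def test_sinus_excludes_fibrotic_endo(self, slab_mesh):
        vals = np.zeros(slab_mesh.dims)
        vals[0, :, 0] = 1.0
        r = sample_fibrosis(FibrosisDensityMap(vals), seed=1, mesh=slab_mesh)
        prot = sinus_protocol(slab_mesh, r)
        knocked = np.flatnonzero(r.non_conductive_mask.ravel())
        assert not set(prot.sites) & set(knocked)

    def test_pacing_train(self):
        prot = pacing_protocol(np.array([5, 6, 7]))
        assert np.allclose(prot.onsets, np.arange(10) * 28.5)
        assert prot.onsets[-1] == pytest.approx(256.5)
        assert prot.onsets[-1] + prot.duration == pytest.approx(256.7)
        assert prot.amplitude == 100.0 and prot.duration == 0.2

    def test_empty_pacing_region(self):
        with pytest.raises(ValueError):
            pacing_protocol(np.array([], dtype=int))


class TestPeriodMeasurement:
    def test_uniform_peak_train(self):
        t = np.arange(0, 300, 0.05)
        trace = np.maximum(0.0, np.sin(2 * np.pi * (t - 10) / 25.77)) ** 2
        assert measure_period(t, trace) == pytest.approx(25.77, abs=0.06)

    def test_synthetic_period_within_cadence(self):
        t = np.arange(0, 400, 0.25)
        p = 31.4
        trace = np.cos(2 * np.pi * t / p)
        assert measure_period(t, trace) == pytest.approx(p, abs=0.25)

    def test_constant_trace_rejected(self):
        t = np.linspace(0, 100, 500)
        with pytest.raises(ValueError, match="sustained"):
            measure_period(t, np.ones_like(t))
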