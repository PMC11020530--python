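"""Numba kernels: anisotropic 19-point Laplacian assembly and explicit
time stepping of the two-variable excitable-tissue model.

The diffusion operator div(D grad u) is discretized in flux form on the
voxel grid.  Diagonal terms use face-averaged conductivities; mixed
(cross-derivative) terms average the flux D_ab * d_b u between the two
nodes sharing a face and difference it across the cell.  Any face whose
opposite node is non-conductive (fibrosis) or outside the domain carries
zero flux, which implements the homogeneous Neumann condition; transverse
derivatives fall back to one-sided differences where a neighbour is
missing, making the stencil asymmetric near boundaries.  The support is
the center, the 6 face neighbours and the 12 edge neighbours: 19 points.
"""

import numpy as np
from numba import njit

# local 3x3x3 offset -> slot
@njit(cache=True, inline="always")
def _slot(di, dj, dk):
    return 9 * (di + 1) + 3 * (dj + 1) + (dk + 1)


@njit(cache=True)
def _add_transverse_derivative(coeff, cidx, mi, mj, mk, beta, w, inv_dr, di0, dj0, dk0):
    """Accumulate w * (d_beta u at node m) into the local coefficient block.

    (di0, dj0, dk0) is m's offset from the stencil center; the beta-step
    must stay within the 3x3x3 block, which holds because mixed terms only
    ever move one step along each of two distinct axes.
    """
    nx, ny, nz = cidx.shape
    sbi = 1 if beta == 0 else 0
    sbj = 1 if beta == 1 else 0
    sbk = 1 if beta == 2 else 0
    # conductivity flags of m's +/- beta neighbours
    pi, pj, pk = mi + sbi, mj + sbj, mk + sbk
    ni, nj, nk = mi - sbi, mj - sbj, mk - sbk
    has_p = 0 <= pi < nx and 0 <= pj < ny and 0 <= pk < nz and cidx[pi, pj, pk] >= 0
    has_n = 0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz and cidx[ni, nj, nk] >= 0
    if has_p and has_n:
        coeff[_slot(di0 + sbi, dj0 + sbj, dk0 + sbk)] += w * 0.5 * inv_dr
        coeff[_slot(di0 - sbi, dj0 - sbj, dk0 - sbk)] -= w * 0.5 * inv_dr
    elif has_p:
        coeff[_slot(di0 + sbi, dj0 + sbj, dk0 + sbk)] += w * inv_dr
        coeff[_slot(di0, dj0, dk0)] -= w * inv_dr
    elif has_n:
        coeff[_slot(di0, dj0, dk0)] += w * inv_dr
        coeff[_slot(di0 - sbi, dj0 - sbj, dk0 - sbk)] -= w * inv_dr
    # neither neighbour: derivative taken as zero


@njit(cache=True)
def build_laplacian_csr(cidx, dcomp, dr):
    """Assemble the anisotropic Laplacian over conductive nodes as CSR.

    cidx : (nx,ny,nz) int32, compact index of each conductive node, -1 else
    dcomp : (6, nx,ny,nz) tensor components Dxx,Dyy,Dzz,Dxy,Dxz,Dyz
    returns (indptr, indices, data) with at most 19 entries per row
    """
    nx, ny, nz = cidx.shape
    n = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if cidx[i, j, k] >= 0:
                    n += 1
    indptr = np.empty(n + 1, dtype=np.int64)
    indices = np.empty(n * 19, dtype=np.int64)
    data = np.empty(n * 19, dtype=np.float64)
    inv_dr = 1.0 / dr
    inv_dr2 = inv_dr * inv_dr

    # mixed-term table: (alpha, beta, tensor-component slot)
    mixed = ((0, 1, 3), (1, 0, 3), (0, 2, 4), (2, 0, 4), (1, 2, 5), (2, 1, 5))

    nnz = 0
    indptr[0] = 0
    coeff = np.empty(27, dtype=np.float64)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p = cidx[i, j, k]
                if p < 0:
                    continue
                for s in range(27):
                    coeff[s] = 0.0
                # diagonal terms d_a (D_aa d_a u): face-averaged conductivity
                for axis in range(3):
                    sa_i = 1 if axis == 0 else 0
                    sa_j = 1 if axis == 1 else 0
                    sa_k = 1 if axis == 2 else 0
                    for s in (-1, 1):
                        qi, qj, qk = i + s * sa_i, j + s * sa_j, k + s * sa_k
                        if 0 <= qi < nx and 0 <= qj < ny and 0 <= qk < nz and cidx[qi, qj, qk] >= 0:
                            dface = 0.5 * (dcomp[axis, i, j, k] + dcomp[axis, qi, qj, qk])
                            w = dface * inv_dr2
                            coeff[_slot(s * sa_i, s * sa_j, s * sa_k)] += w
                            coeff[_slot(0, 0, 0)] -= w
                # mixed terms d_a (D_ab d_b u): flux averaged over the face,
                # zero across non-conductive faces
                for t in range(6):
                    alpha = mixed[t][0]
                    beta = mixed[t][1]
                    comp = mixed[t][2]
                    sa_i = 1 if alpha == 0 else 0
                    sa_j = 1 if alpha == 1 else 0
                    sa_k = 1 if alpha == 2 else 0
                    for s in (-1, 1):
                        qi, qj, qk = i + s * sa_i, j + s * sa_j, k + s * sa_k
                        if 0 <= qi < nx and 0 <= qj < ny and 0 <= qk < nz and cidx[qi, qj, qk] >= 0:
                            fac = s * 0.5 * inv_dr
                            _add_transverse_derivative(
                                coeff, cidx, i, j, k, beta,
                                fac * dcomp[comp, i, j, k], inv_dr, 0, 0, 0)
                            _add_transverse_derivative(
                                coeff, cidx, qi, qj, qk, beta,
                                fac * dcomp[comp, qi, qj, qk], inv_dr,
                                s * sa_i, s * sa_j, s * sa_k)
                # write the row
                for di in range(-1, 2):
                    for dj in range(-1, 2):
                        for dk in range(-1, 2):
                            c = coeff[_slot(di, dj, dk)]
                            if c != 0.0:
                                qi, qj, qk = i + di, j + dj, k + dk
                                q = cidx[qi, qj, qk]
                                indices[nnz] = q
                                data[nnz] = c
                                nnz += 1
                indptr[p + 1] = nnz
    return indptr, indices[:nnz].copy(), data[:nnz].copy()


@njit(cache=True)
def step_block(u, v, indptr, indices, data, dt, k, a, eps, mu1, mu2,
               stim_idx, stim_amp, stim_on, stim_off, t0, nsteps,
               act_time, act_thresh):
    """Advance the state ``nsteps`` forward-Euler steps in place.

    Stimulus windows are given as parallel (stim_on, stim_off) arrays; the
    current ``stim_amp`` is added to du/dt at ``stim_idx`` whenever the
    step time falls in any window.  ``act_time`` records the first upward
    crossing of ``act_thresh`` (-1 = not yet activated).
    """
    n = u.size
    unew = np.empty(n)
    for s in range(nsteps):
        t = t0 + s * dt
        active = False
        for w in range(stim_on.size):
            if stim_on[w] <= t < stim_off[w]:
                active = True
                break
        for p in range(n):
            lap = 0.0
            for e in range(indptr[p], indptr[p + 1]):
                lap += data[e] * u[indices[e]]
            up = u[p]
            vp = v[p]
            unew[p] = up + dt * (lap - k * up * (up - a) * (up - 1.0) - up * vp)
            v[p] = vp + dt * (-(eps + mu1 * vp / (up + mu2)) * (vp + k * up * (up - a - 1.0)))
        if active:
            for m in range(stim_idx.size):
                unew[stim_idx[m]] += dt * stim_amp
        tn = t + dt
        for p in range(n):
            if act_time[p] < 0.0 and u[p] < act_thresh <= unew[p]:
                act_time[p] = tn
            u[p] = unew[p]
    return u, v
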