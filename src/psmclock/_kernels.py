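"""Jit-compiled inner loops.

Fixed-radius neighbour interactions dominate the step cost, so binning,
pair scanning, repulsion, and phase-coupling accumulation are fused into one
kernel operating on caller-owned workspaces (no per-step allocation). The
boundary force and the spherical direction walk have jitted loop forms used
by the engine; the numpy implementations in :mod:`psmclock.geometry` and
:mod:`psmclock.motion` remain the reference versions and the test suite
checks the two paths against each other.

All kernels are pure functions of their array arguments; randomness stays
outside (pre-drawn normal deviates are passed in).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "StepWorkspace",
    "interactions",
    "neighbor_pairs",
    "brute_force_pairs",
    "boundary_force_kernel",
    "direction_step_kernel",
]


@njit(cache=True)
def _bin_points(pos, rcut, cidx, counts, order, spos):  # pragma: no cover - jitted
    """Uniform binning at pitch rcut; fills cell index, CSR offsets, the
    bin-sorted permutation, and bin-sorted coordinates. Returns (nx, ny, nz)
    or (-1, -1, -1) if the counts workspace is too small."""
    n = pos.shape[0]
    minx = pos[0, 0]
    miny = pos[0, 1]
    minz = pos[0, 2]
    maxx = minx
    maxy = miny
    maxz = minz
    for i in range(1, n):
        if pos[i, 0] < minx:
            minx = pos[i, 0]
        elif pos[i, 0] > maxx:
            maxx = pos[i, 0]
        if pos[i, 1] < miny:
            miny = pos[i, 1]
        elif pos[i, 1] > maxy:
            maxy = pos[i, 1]
        if pos[i, 2] < minz:
            minz = pos[i, 2]
        elif pos[i, 2] > maxz:
            maxz = pos[i, 2]
    inv = 1.0 / rcut
    nx = max(1, int((maxx - minx) * inv) + 1)
    ny = max(1, int((maxy - miny) * inv) + 1)
    nz = max(1, int((maxz - minz) * inv) + 1)
    ntot = nx * ny * nz
    if ntot + 1 > counts.shape[0]:
        return -1, -1, -1
    counts[: ntot + 1] = 0
    for i in range(n):
        a = min(int((pos[i, 0] - minx) * inv), nx - 1)
        b = min(int((pos[i, 1] - miny) * inv), ny - 1)
        c = min(int((pos[i, 2] - minz) * inv), nz - 1)
        ci = (a * ny + b) * nz + c
        cidx[i] = ci
        counts[ci + 1] += 1
    for c in range(ntot):
        counts[c + 1] += counts[c]
    fill = counts[:ntot].copy()
    for i in range(n):
        ci = cidx[i]
        k = fill[ci]
        order[k] = i
        spos[k, 0] = pos[i, 0]
        spos[k, 1] = pos[i, 1]
        spos[k, 2] = pos[i, 2]
        fill[ci] += 1
    return nx, ny, nz


@njit(cache=True)
def _interactions_core(  # pragma: no cover - jitted
    pos, dc, mu, sin_self, cos_self, sin_src, cos_src, src_ok,
    cidx, counts, order, spos,
    vrep, coup, ni, co_i, co_j,
):
    n = pos.shape[0]
    vrep[:n] = 0.0
    coup[:n] = 0.0
    ni[:n] = 0
    if n < 2:
        return 0
    nx, ny, nz = _bin_points(pos, dc, cidx, counts, order, spos)
    if nx < 0:
        return -1
    nyz = ny * nz
    r2 = dc * dc
    ncoin = 0
    for u in range(n):
        i = order[u]
        ci = cidx[i]
        a = ci // nyz
        rem = ci % nyz
        b = rem // nz
        c = rem % nz
        xu = spos[u, 0]
        yu = spos[u, 1]
        zu = spos[u, 2]
        lo_c = max(0, c - 1)
        hi_c = min(nz, c + 2)
        for ox in range(max(0, a - 1), min(nx, a + 2)):
            for oy in range(max(0, b - 1), min(ny, b + 2)):
                base = (ox * ny + oy) * nz
                for v in range(counts[base + lo_c], counts[base + hi_c]):
                    if v <= u:
                        continue
                    dx = spos[v, 0] - xu
                    dy = spos[v, 1] - yu
                    dz = spos[v, 2] - zu
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 > r2:
                        continue
                    j = order[v]
                    d = d2**0.5
                    if d < 1e-9:
                        if ncoin < co_i.shape[0]:
                            co_i[ncoin] = i
                            co_j[ncoin] = j
                            ncoin += 1
                    else:
                        f = mu * (d / dc - 1.0) / d
                        fx = f * dx
                        fy = f * dy
                        fz = f * dz
                        vrep[i, 0] += fx
                        vrep[i, 1] += fy
                        vrep[i, 2] += fz
                        vrep[j, 0] -= fx
                        vrep[j, 1] -= fy
                        vrep[j, 2] -= fz
                    # sin(theta_src[j] - theta[i]) via the difference identity
                    if src_ok[j]:
                        coup[i] += sin_src[j] * cos_self[i] - cos_src[j] * sin_self[i]
                        ni[i] += 1
                    if src_ok[i]:
                        coup[j] += sin_src[i] * cos_self[j] - cos_src[i] * sin_self[j]
                        ni[j] += 1
    return ncoin


class StepWorkspace:
    """Reusable buffers for the fused interaction kernel, grown on demand."""

    _COUNTS_CAP = 1 << 20

    def __init__(self) -> None:
        self.capacity = 0
        self.counts = np.zeros(self._COUNTS_CAP, np.int64)

    def ensure(self, n: int) -> None:
        if n <= self.capacity:
            return
        cap = max(256, 2 * n)
        self.capacity = cap
        self.cidx = np.empty(cap, np.int64)
        self.order = np.empty(cap, np.int64)
        self.spos = np.empty((cap, 3), float)
        self.vrep = np.zeros((cap, 3), float)
        self.coup = np.zeros(cap, float)
        self.ni = np.zeros(cap, np.int64)
        self.co_i = np.empty(cap, np.int64)
        self.co_j = np.empty(cap, np.int64)


_DEFAULT_WS: StepWorkspace | None = None


def _shared_ws() -> StepWorkspace:
    global _DEFAULT_WS
    if _DEFAULT_WS is None:
        _DEFAULT_WS = StepWorkspace()
    return _DEFAULT_WS


def interactions(
    pos: np.ndarray,
    dc: float,
    mu: float,
    theta: np.ndarray,
    theta_src: np.ndarray,
    src_ok: np.ndarray,
    ws: StepWorkspace | None = None,
):
    """Pairwise repulsion and phase-coupling sums over all closed-ball
    neighbour pairs (|xj - xi| <= dc).

    Returns views (vrep, coup, ni, co_i, co_j): summed repulsion velocities,
    sums of sin(theta_src[j] - theta[i]) over admissible sources, admissible
    neighbour counts, and the indices of coincident pairs (separation below
    1e-9, left for the caller to resolve with a random direction).
    """
    if ws is None:
        ws = _shared_ws()
    pos = np.ascontiguousarray(pos, dtype=float)
    n = pos.shape[0]
    ws.ensure(n)
    theta = np.asarray(theta, dtype=float)
    theta_src = np.asarray(theta_src, dtype=float)
    sin_self = np.sin(theta)
    cos_self = np.cos(theta)
    if theta_src is theta:
        sin_src, cos_src = sin_self, cos_self
    else:
        sin_src, cos_src = np.sin(theta_src), np.cos(theta_src)
    ncoin = _interactions_core(
        pos, dc, mu, sin_self, cos_self, sin_src, cos_src,
        np.ascontiguousarray(src_ok, dtype=np.bool_),
        ws.cidx, ws.counts, ws.order, ws.spos,
        ws.vrep, ws.coup, ws.ni, ws.co_i, ws.co_j,
    )
    if ncoin < 0:
        raise ValueError("interaction radius too small for the domain extent")
    return (
        ws.vrep[:n],
        ws.coup[:n],
        ws.ni[:n],
        ws.co_i[:ncoin].copy(),
        ws.co_j[:ncoin].copy(),
    )


@njit(cache=True)
def _pairs_core(pos, rcut, cidx, counts, order, spos, pi, pj):  # pragma: no cover
    n = pos.shape[0]
    if n < 2:
        return 0
    nx, ny, nz = _bin_points(pos, rcut, cidx, counts, order, spos)
    if nx < 0:
        return -1
    nyz = ny * nz
    r2 = rcut * rcut
    cap = pi.shape[0]
    m = 0
    for u in range(n):
        i = order[u]
        ci = cidx[i]
        a = ci // nyz
        rem = ci % nyz
        b = rem // nz
        c = rem % nz
        xu = spos[u, 0]
        yu = spos[u, 1]
        zu = spos[u, 2]
        lo_c = max(0, c - 1)
        hi_c = min(nz, c + 2)
        for ox in range(max(0, a - 1), min(nx, a + 2)):
            for oy in range(max(0, b - 1), min(ny, b + 2)):
                base = (ox * ny + oy) * nz
                for v in range(counts[base + lo_c], counts[base + hi_c]):
                    if v <= u:
                        continue
                    dx = spos[v, 0] - xu
                    dy = spos[v, 1] - yu
                    dz = spos[v, 2] - zu
                    if dx * dx + dy * dy + dz * dz <= r2:
                        if m < cap:
                            pi[m] = i
                            pj[m] = order[v]
                        m += 1
    return m


def neighbor_pairs(pos: np.ndarray, rcut: float):
    """All unordered index pairs with |xj - xi| <= rcut (closed ball)."""
    pos = np.ascontiguousarray(pos, dtype=float)
    n = pos.shape[0]
    if n < 2:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    span = pos.max(axis=0) - pos.min(axis=0)
    n_bins = np.prod(np.maximum(1, (span / rcut).astype(np.int64) + 1))
    if n_bins + 1 > StepWorkspace._COUNTS_CAP:
        return brute_force_pairs(pos, rcut)  # pathological radius; stay exact
    ws = _shared_ws()
    ws.ensure(n)
    cap = max(1024, 64 * n)
    while True:
        pi = np.empty(cap, np.int64)
        pj = np.empty(cap, np.int64)
        m = _pairs_core(pos, rcut, ws.cidx, ws.counts, ws.order, ws.spos, pi, pj)
        if m < 0:
            raise ValueError("interaction radius too small for the domain extent")
        if m <= cap:
            return pi[:m].copy(), pj[:m].copy()
        cap = 2 * m  # undersized output buffer: rerun with room to spare


def brute_force_pairs(pos: np.ndarray, rcut: float):
    """All-pairs oracle for the neighbour search (numpy, no spatial binning)."""
    pos = np.asarray(pos, dtype=float)
    n = pos.shape[0]
    if n < 2:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    diff = pos[:, None, :] - pos[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    iu, ju = np.triu_indices(n, k=1)
    mask = d2[iu, ju] <= rcut * rcut
    return iu[mask].astype(np.int64), ju[mask].astype(np.int64)


@njit(cache=True)
def boundary_force_kernel(  # pragma: no cover - jitted
    pos, out, Xc, Yc, Zc, R, rT, mu_b, r_b
):
    """Adds the confinement force into ``out`` (same expressions as
    geometry.boundary_force_many)."""
    n = pos.shape[0]
    for i in range(n):
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        if x > Xc:
            dx = x - Xc
            dy = y - Yc
            dz = z - Zc
            d = (dx * dx + dy * dy) ** 0.5
            u = d - R
            r = (u * u + dz * dz) ** 0.5
            if r > 0.0:
                cq = u / r
                sq = dz / r
            else:
                cq = 1.0
                sq = 0.0
            if d > 0.0:
                cp = dx / d
                sp = dy / d
            else:
                cp = 1.0
                sp = 0.0
            g = rT - r
            out[i, 0] += -mu_b * np.exp(-abs(g * cp * cq) / r_b) * cp * cq
            out[i, 1] += -mu_b * np.exp(-abs(g * sp * cq) / r_b) * sp * cq
            out[i, 2] += -mu_b * np.exp(-abs(g * sq) / r_b) * sq
        else:
            ay = rT if y < Yc else 2.0 * R + rT
            dy = y - ay
            dz = z - Zc
            r = (dy * dy + dz * dz) ** 0.5
            if r > 0.0:
                cq = dy / r
                sq = dz / r
            else:
                cq = 1.0
                sq = 0.0
            g = rT - r
            out[i, 1] += -mu_b * np.exp(-abs(g * cq) / r_b) * cq
            out[i, 2] += -mu_b * np.exp(-abs(g * sq) / r_b) * sq


@njit(cache=True)
def direction_step_kernel(n_vec, xi, amp, decay):  # pragma: no cover - jitted
    """Euler-Maruyama step of the unit-sphere direction walk, in place.

    ``xi`` is (N, 2) standard normal, ``amp = sqrt(2 D dt)``,
    ``decay = 2 D dt``; the tangent frame is (n x ez, (n x ez) x n)
    normalized, with the fixed frame (ex, ey) at the poles."""
    n = n_vec.shape[0]
    for i in range(n):
        a = n_vec[i, 0]
        b = n_vec[i, 1]
        c = n_vec[i, 2]
        # mx = n x ez = (b, -a, 0)
        nrm = (a * a + b * b) ** 0.5
        if nrm < 1e-12:
            mxx, mxy, mxz = 1.0, 0.0, 0.0
            myx, myy, myz = 0.0, 1.0, 0.0
        else:
            mxx = b / nrm
            mxy = -a / nrm
            mxz = 0.0
            # my = mx x n
            myx = mxy * c - mxz * b
            myy = mxz * a - mxx * c
            myz = mxx * b - mxy * a
            mn = (myx * myx + myy * myy + myz * myz) ** 0.5
            myx /= mn
            myy /= mn
            myz /= mn
        x1 = xi[i, 0]
        x2 = xi[i, 1]
        na = a + amp * (x1 * mxx + x2 * myx) - decay * a
        nb = b + amp * (x1 * mxy + x2 * myy) - decay * b
        nc = c + amp * (x1 * mxz + x2 * myz) - decay * c
        nn = (na * na + nb * nb + nc * nc) ** 0.5
        n_vec[i, 0] = na / nn
        n_vec[i, 1] = nb / nn
        n_vec[i, 2] = nc / nn
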