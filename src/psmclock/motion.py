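"""Cell velocity components: advection, intrinsic motility, directional random
walk on the unit sphere, and pairwise volume-exclusion repulsion.

The equation of motion for cell i is overdamped:

    dx_i/dt = v_d(x_i) + v0(x_i) n_i(t) + sum_j F(x_i, x_j) + F_b(x_i)

with anterior-directed advection v_d (the tailbud is the inertial frame, so
tissue elongation appears as cells drifting toward the anterior), a
posterior-biased intrinsic speed v0 along a persistent direction n_i that
diffuses on the unit sphere, soft linear repulsion F within one cell diameter
d_c, and the boundary confinement force F_b from :mod:`psmclock.geometry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import TissueGeometry, boundary_force_many

__all__ = [
    "MotionParams",
    "advection_speed",
    "advection_velocity",
    "motility_magnitude",
    "step_direction",
    "step_directions",
    "pair_repulsion",
]


@dataclass(frozen=True)
class MotionParams:
    """Motion parameters (defaults: zebrafish PSM).

    va, vp : advection speed at the anterior end and posterior scale (um/min)
    xq     : breakpoint of the piecewise-linear advection profile, in
             normalized AP position X = (x - xa)/L
    vs     : maximum intrinsic cell speed (um/min)
    Xv, h  : inflexion point and steepness of the motility profile
    D      : rotational diffusivity of the direction vector (1/min)
    mu     : repulsion strength (um/min); dc: cell diameter (um)
    mu_b, r_b : boundary force magnitude (um/min) and decay length (um)
    """

    va: float = 1.67
    vp: float = 3.0
    xq: float = 0.7
    vs: float = 1.0
    Xv: float = 0.4
    h: float = 3.0
    D: float = 0.026
    mu: float = 8.71
    dc: float = 11.0
    mu_b: float = 20.0
    r_b: float = 1.0


def _normalized_x(x, geom: TissueGeometry) -> np.ndarray:
    X = (np.asarray(x, dtype=float) - geom.xa) / geom.L
    return np.clip(X, 0.0, 1.0)


def advection_speed(x, geom: TissueGeometry, mp: MotionParams) -> np.ndarray:
    """Piecewise-linear advection speed profile v_d(X) >= 0.

    v_d(0) = va, v_d(xq) = vp (1 - xq), v_d(1) = 0, linear on both pieces;
    positions outside [0, 1] are clamped to the endpoint values.
    """
    X = _normalized_x(x, geom)
    anterior = mp.va + X * (mp.vp * (1.0 - mp.xq) - mp.va) / mp.xq
    posterior = mp.vp * (1.0 - X)
    return np.where(X <= mp.xq, anterior, posterior)


def advection_velocity(x, geom: TissueGeometry, mp: MotionParams) -> np.ndarray:
    """Advection velocity (-v_d, 0, 0): cells drift toward the anterior."""
    vd = np.atleast_1d(advection_speed(x, geom, mp))
    out = np.zeros(vd.shape + (3,))
    out[..., 0] = -vd
    return out if np.ndim(x) else out[0]


def motility_magnitude(x, geom: TissueGeometry, mp: MotionParams) -> np.ndarray:
    """Sigmoidal intrinsic speed v0(X) = vs / (1 + ((1-X)/Xv)^h), increasing
    toward the posterior; Xv = 0 degenerates to a step: vs at X=1, else 0."""
    X = _normalized_x(x, geom)
    if mp.Xv == 0.0:
        return np.where(X >= 1.0, mp.vs, 0.0)
    return mp.vs / (1.0 + ((1.0 - X) / mp.Xv) ** mp.h)


_EZ_TOL = 1e-12


def tangent_frame(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent pair (mx, my) at n: mx = n x ez / |n x ez|,
    my = mx x n. Near the poles (n ~ +-ez) any tangent pair works; use the
    fixed pair (ex, ey)."""
    n = np.atleast_2d(n)
    ez = np.array([0.0, 0.0, 1.0])
    mx = np.cross(n, ez)
    norm = np.linalg.norm(mx, axis=1)
    degen = norm < _EZ_TOL
    mx[degen] = (1.0, 0.0, 0.0)
    norm = np.where(degen, 1.0, norm)
    mx /= norm[:, None]
    my = np.cross(mx, n)
    my[degen] = (0.0, 1.0, 0.0)
    my /= np.linalg.norm(my, axis=1)[:, None]
    return mx, my


def step_directions(
    n: np.ndarray, dt: float, D: float, rng: np.random.Generator
) -> np.ndarray:
    """One Euler-Maruyama step of the directional random walk for an (N, 3)
    array of unit vectors; the result is renormalized onto the sphere."""
    n = np.atleast_2d(np.asarray(n, dtype=float))
    if D == 0.0:
        return n.copy()
    mx, my = tangent_frame(n)
    amp = math.sqrt(2.0 * D * dt)
    xi = rng.standard_normal((2, n.shape[0]))
    out = n + amp * (xi[0][:, None] * mx + xi[1][:, None] * my) - 2.0 * D * dt * n
    out /= np.linalg.norm(out, axis=1)[:, None]
    return out


def step_direction(n, dt: float, D: float, rng: np.random.Generator) -> np.ndarray:
    """Single-vector convenience wrapper around :func:`step_directions`."""
    return step_directions(np.asarray(n, float).reshape(1, 3), dt, D, rng)[0]


def pair_repulsion(xi, xj, mp: MotionParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Repulsion force on cell i from cell j: magnitude mu (d/dc - 1) (negative,
    i.e. repulsive) along the unit vector from i toward j; zero beyond dc.
    Coincident centres repel at full strength mu along a random direction."""
    xi = np.asarray(xi, float)
    xj = np.asarray(xj, float)
    dvec = xj - xi
    d = float(np.linalg.norm(dvec))
    if d > mp.dc:
        return np.zeros(3)
    if d < 1e-9:
        if rng is None:
            rng = np.random.default_rng()
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        return -mp.mu * u
    return mp.mu * (d / mp.dc - 1.0) * dvec / d


def net_velocity(
    cell_pos,
    cell_n,
    neighbor_pos: np.ndarray,
    geom: TissueGeometry,
    mp: MotionParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Reference (non-vectorized) assembly of the full equation of motion for a
    single cell given its neighbours' positions. The engine uses an equivalent
    batched path; this form exists for tests and small harnesses."""
    pos = np.asarray(cell_pos, float)
    v = advection_velocity(pos[0], geom, mp).copy()
    v += motility_magnitude(pos[0], geom, mp) * np.asarray(cell_n, float)
    for other in np.asarray(neighbor_pos, float).reshape(-1, 3):
        v += pair_repulsion(pos, other, mp, rng)
    v += boundary_force_many(pos.reshape(1, 3), geom, mp.mu_b, mp.r_b)[0]
    return v
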