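"""Horseshoe PSM tissue domain: two lateral cylinders joined by a half-torus tailbud.

The domain approximates the zebrafish pre-somitic mesoderm (PSM). The
anterior-posterior (AP) axis is x (increasing posteriorly), y is left-right,
z is dorsal-ventral. The two cylinders run along x with their axes at
``y = rT`` (left) and ``y = 2R + rT`` (right); the tailbud is the half-torus
(``p`` in [-pi/2, pi/2]) centred at ``(Xc, Yc, Zc)`` with major radius ``R``
and minor (tube) radius ``rT``. Cells leave the PSM anteriorly at ``x = xa``.

All lengths are in micrometres, times in minutes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TissueGeometry",
    "SubdomainId",
    "SampleRegion",
    "CoordTriple",
    "cylinder_polar",
    "torus_polar",
    "torus_embed",
    "subdomain_of",
    "boundary_force",
    "subdomain_volume",
    "subdomain_density",
    "sample_position",
]


class SubdomainId(enum.Enum):
    LEFT_CYLINDER = "left_cylinder"
    RIGHT_CYLINDER = "right_cylinder"
    TAILBUD = "tailbud"


class SampleRegion(enum.Enum):
    INTERIOR_RANDOM = "interior_random"
    DORSAL_SURFACE = "dorsal_surface"
    VENTRAL_SURFACE = "ventral_surface"


@dataclass(frozen=True)
class CoordTriple:
    """Local tube coordinates: radial distance ``r`` from the subdomain axis,
    toroidal angle ``p`` (tailbud only), and azimuthal angle ``q``."""

    r: float
    q: float
    p: float | None = None


@dataclass(frozen=True)
class TissueGeometry:
    """Parameters of the horseshoe domain.

    The derived AP length is ``L = rT + R + Xc - xa``; ``xd`` is the anterior
    limit of cell addition as an offset from ``xa``.
    """

    Xc: float = 300.0
    Yc: float = 85.0
    Zc: float = 25.0
    R: float = 60.0
    rT: float = 25.0
    xa: float = 0.0
    xd: float = 100.0

    def __post_init__(self) -> None:
        if self.rT <= 0 or self.R <= 0:
            raise ValueError("radii must be positive")
        if self.Xc <= self.xa:
            raise ValueError("Xc must be posterior to xa")
        if not math.isclose(self.Yc, self.rT + self.R, rel_tol=0, abs_tol=1e-9):
            raise ValueError("Yc must equal rT + R (cylinder axes at y=rT and y=2R+rT)")

    @property
    def L(self) -> float:
        return self.rT + self.R + self.Xc - self.xa

    def axis_y(self, side: SubdomainId) -> float:
        if side is SubdomainId.LEFT_CYLINDER:
            return self.rT
        if side is SubdomainId.RIGHT_CYLINDER:
            return 2.0 * self.R + self.rT
        raise ValueError("tailbud has no straight axis")

    def with_schedule(self, xa: float, rT: float) -> "TissueGeometry":
        """Return a copy with time-varying anterior limit and tube radius
        (compaction-extension); Yc tracks rT + R."""
        return replace(self, xa=xa, rT=rT, Yc=rT + self.R)


def cylinder_polar(pos, side: SubdomainId, geom: TissueGeometry) -> CoordTriple:
    """Polar coordinates about a cylinder axis; ``q = atan2(z-Zc, y-axis_y)``
    mapped to [0, 2pi). ``r = 0`` returns ``q = 0`` by convention."""
    x, y, z = pos
    ay = geom.axis_y(side)
    dy, dz = y - ay, z - geom.Zc
    r = math.hypot(dy, dz)
    q = math.atan2(dz, dy) % (2.0 * math.pi) if r > 0 else 0.0
    return CoordTriple(r=r, q=q)


def torus_polar(pos, geom: TissueGeometry) -> CoordTriple:
    """Toroidal coordinates in the tailbud: ``p`` about the torus centre,
    ``q`` about the centre circle of the tube."""
    x, y, z = pos
    dx, dy, dz = x - geom.Xc, y - geom.Yc, z - geom.Zc
    p = math.atan2(dy, dx)
    d = math.hypot(dx, dy)
    u = d - geom.R
    r = math.hypot(u, dz)
    q = math.atan2(dz, u) % (2.0 * math.pi) if r > 0 else 0.0
    return CoordTriple(r=r, q=q, p=p)


def torus_embed(c: CoordTriple, geom: TissueGeometry) -> np.ndarray:
    """Embed toroidal coordinates back to Cartesian (inverse of torus_polar)."""
    if c.p is None:
        raise ValueError("torus embedding needs the toroidal angle p")
    cp, sp = math.cos(c.p), math.sin(c.p)
    cq, sq = math.cos(c.q), math.sin(c.q)
    return np.array(
        [
            geom.Xc + geom.R * cp + c.r * cp * cq,
            geom.Yc + geom.R * sp + c.r * sp * cq,
            geom.Zc + c.r * sq,
        ]
    )


def cylinder_embed(c: CoordTriple, x: float, side: SubdomainId, geom: TissueGeometry) -> np.ndarray:
    ay = geom.axis_y(side)
    return np.array(
        [x, ay + c.r * math.cos(c.q), geom.Zc + c.r * math.sin(c.q)]
    )


def subdomain_of(pos, geom: TissueGeometry) -> SubdomainId:
    """Total partition of space: tailbud for ``x > Xc``, otherwise the cylinder
    on the cell's side of the midline ``y = Yc``."""
    x, y, _ = pos
    if x > geom.Xc:
        return SubdomainId.TAILBUD
    return SubdomainId.LEFT_CYLINDER if y < geom.Yc else SubdomainId.RIGHT_CYLINDER


def subdomain_volume(sub: SubdomainId, geom: TissueGeometry) -> float:
    if sub is SubdomainId.TAILBUD:
        v = math.pi**2 * geom.rT**2 * geom.R
    else:
        v = math.pi * geom.rT**2 * (geom.Xc - geom.xa)
    if v <= 0:
        raise ValueError("degenerate geometry: non-positive subdomain volume")
    return v


def subdomain_density(positions: np.ndarray, sub: SubdomainId, geom: TissueGeometry) -> float:
    """Number density (um^-3) of the given cells in one subdomain. Cells
    anterior of ``xa`` (already past the wavefront) are not counted."""
    vol = subdomain_volume(sub, geom)
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if positions.shape[0] == 0:
        return 0.0
    x, y = positions[:, 0], positions[:, 1]
    inside = x >= geom.xa
    if sub is SubdomainId.TAILBUD:
        mask = inside & (x > geom.Xc)
    elif sub is SubdomainId.LEFT_CYLINDER:
        mask = inside & (x <= geom.Xc) & (y < geom.Yc)
    else:
        mask = inside & (x <= geom.Xc) & (y >= geom.Yc)
    return float(np.count_nonzero(mask)) / vol


def all_subdomain_densities(positions: np.ndarray, geom: TissueGeometry) -> dict[SubdomainId, float]:
    return {sub: subdomain_density(positions, sub, geom) for sub in SubdomainId}


# -- boundary confinement force -------------------------------------------------

def boundary_force(pos, geom: TissueGeometry, mu_b: float, r_b: float) -> np.ndarray:
    """Confinement force (um/min) on a single cell; see boundary_force_many."""
    return boundary_force_many(np.asarray(pos, float).reshape(1, 3), geom, mu_b, r_b)[0]


def boundary_force_many(pos: np.ndarray, geom: TissueGeometry, mu_b: float, r_b: float) -> np.ndarray:
    """Vectorized boundary force for an (N, 3) position array.

    In the cylinders the force points toward the local axis with components
    ``-mu_b * exp(-dy/r_b) * cos q`` and ``-mu_b * exp(-dz/r_b) * sin q`` where
    ``dy = |(rT - r) cos q|``, ``dz = |(rT - r) sin q|``; in the tailbud the
    analogous expression uses the toroidal frame. The magnitude peaks at the
    tube surface ``r = rT`` and decays with length scale ``r_b`` on either
    side of it.
    """
    pos = np.asarray(pos, dtype=float)
    out = np.zeros_like(pos)
    x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
    tail = x > geom.Xc

    # cylinders
    cyl = ~tail
    if np.any(cyl):
        ay = np.where(y[cyl] < geom.Yc, geom.rT, 2.0 * geom.R + geom.rT)
        dy = y[cyl] - ay
        dz = z[cyl] - geom.Zc
        r = np.hypot(dy, dz)
        with np.errstate(invalid="ignore", divide="ignore"):
            cq = np.where(r > 0, dy / np.where(r > 0, r, 1.0), 1.0)
            sq = np.where(r > 0, dz / np.where(r > 0, r, 1.0), 0.0)
        dely = np.abs((geom.rT - r) * cq)
        delz = np.abs((geom.rT - r) * sq)
        out[cyl, 1] = -mu_b * np.exp(-dely / r_b) * cq
        out[cyl, 2] = -mu_b * np.exp(-delz / r_b) * sq

    if np.any(tail):
        dx = x[tail] - geom.Xc
        dyc = y[tail] - geom.Yc
        dzc = z[tail] - geom.Zc
        p = np.arctan2(dyc, dx)
        d = np.hypot(dx, dyc)
        u = d - geom.R
        r = np.hypot(u, dzc)
        with np.errstate(invalid="ignore", divide="ignore"):
            cq = np.where(r > 0, u / np.where(r > 0, r, 1.0), 1.0)
            sq = np.where(r > 0, dzc / np.where(r > 0, r, 1.0), 0.0)
        cp, sp = np.cos(p), np.sin(p)
        delx = np.abs((geom.rT - r) * cp * cq)
        dely = np.abs((geom.rT - r) * sp * cq)
        delz = np.abs((geom.rT - r) * sq)
        out[tail, 0] = -mu_b * np.exp(-delx / r_b) * cp * cq
        out[tail, 1] = -mu_b * np.exp(-dely / r_b) * sp * cq
        out[tail, 2] = -mu_b * np.exp(-delz / r_b) * sq
    return out


# -- sampling for ingression and initial placement ------------------------------

def sample_position(
    sub: SubdomainId,
    region: SampleRegion,
    geom: TissueGeometry,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one position in the named region of a subdomain.

    Draws are uniform in the tube parameters (x or p, r, q), matching how the
    ingression scenarios are defined; they are deliberately *not* uniform in
    volume or surface area. Dorsal-surface addition exists only on the tailbud
    (q in [pi/4, 3pi/4]); ventral-surface addition only on the cylinders
    (q in [5pi/4, 7pi/4], x in [xa + xd, Xc]).
    """
    two_pi = 2.0 * math.pi
    if sub is SubdomainId.TAILBUD:
        if region is SampleRegion.VENTRAL_SURFACE:
            raise ValueError("ventral-surface addition is defined on the cylinders only")
        p = rng.uniform(-math.pi / 2.0, math.pi / 2.0)
        if region is SampleRegion.DORSAL_SURFACE:
            r, q = geom.rT, rng.uniform(math.pi / 4.0, 3.0 * math.pi / 4.0)
        else:
            r, q = rng.uniform(0.0, geom.rT), rng.uniform(0.0, two_pi)
        return torus_embed(CoordTriple(r=r, q=q, p=p), geom)

    if region is SampleRegion.DORSAL_SURFACE:
        raise ValueError("dorsal-surface addition is defined on the tailbud only")
    # late in compaction the wavefront can overtake the cylinder addition
    # window (xa + xd > Xc); additions then collapse to the tailbud junction
    x = rng.uniform(min(geom.xa + geom.xd, geom.Xc), geom.Xc)
    if region is SampleRegion.VENTRAL_SURFACE:
        r, q = geom.rT, rng.uniform(5.0 * math.pi / 4.0, 7.0 * math.pi / 4.0)
    else:
        r, q = rng.uniform(0.0, geom.rT), rng.uniform(0.0, two_pi)
    return cylinder_embed(CoordTriple(r=r, q=q), x, sub, geom)
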