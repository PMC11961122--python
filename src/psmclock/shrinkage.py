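"""Compaction-extension of the late-somitogenesis PSM.

From the 16-somite stage onward the zebrafish PSM shrinks in length and
radius while its cell density rises and cell diameter falls. The schedules
are linear in somite stage s(t), itself a smooth interpolation of somite
count against time:

    s(t) = 6 + t / 24.7 - a e^{b (t - 300)}        (a = 0.5001, b = 0.0049)

Before s(t) = 16 all scheduled quantities hold their initial values. Length
shrinks by moving the wavefront xa posteriorly at rate ma per somite (the
posterior tip is the frame's origin and stays put); the tube radius follows
r0 - mr (s - 16), density rho_t0 + m_rho (s - 16) and cell diameter
dc0 - m_dc (s - 16). The anterior limit of cell addition tracks the
wavefront: xd(t) = xa(t) + 100 um.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ShrinkageParams",
    "GeometrySchedule",
    "TerminationReason",
    "somite_stage",
    "onset_time",
    "schedule_at",
]


@dataclass(frozen=True)
class ShrinkageParams:
    """Schedule constants (defaults: zebrafish, rates per somite stage)."""

    a: float = 0.5001
    b: float = 0.0049
    L0: float = 325.0
    ma: float = 14.1
    xa0: float = 0.0
    r0: float = 27.6
    mr: float = 1.1625
    rho_t0: float = 0.002123
    m_rho: float = 0.000121
    dc0: float = 9.2
    m_dc: float = 0.2
    enabled: bool = False
    stepwise_dc: bool = False  # quantize dc(t) to integer somite stages

    def __post_init__(self) -> None:
        if min(self.ma, self.mr, self.m_rho, self.m_dc) < 0:
            raise ValueError("shrink rates must be non-negative")


@dataclass(frozen=True)
class GeometrySchedule:
    """Scheduled tissue quantities at one instant."""

    L: float
    xa: float
    xd: float
    rT: float
    rho_target: float
    dc: float


class TerminationReason(enum.Enum):
    CONTINUE = "continue"
    LENGTH_EXHAUSTED = "length_exhausted"
    ANTERIOR_GAP = "anterior_gap"
    TIME_LIMIT = "time_limit"


def somite_stage(t, sp: ShrinkageParams) -> np.ndarray:
    """Interpolated somite count at time t (min)."""
    t = np.asarray(t, dtype=float)
    return 6.0 + t / 24.7 - sp.a * np.exp(sp.b * (t - 300.0))


@lru_cache(maxsize=8)
def _onset_time(a: float, b: float) -> float:
    sp = ShrinkageParams(a=a, b=b)
    return float(brentq(lambda t: somite_stage(t, sp) - 16.0, 0.0, 800.0, xtol=1e-6))


def onset_time(sp: ShrinkageParams) -> float:
    """Time (min) at which s(t) first reaches 16 somites; root-found once and
    cached."""
    return _onset_time(sp.a, sp.b)


def schedule_at(t: float, sp: ShrinkageParams) -> GeometrySchedule:
    """Scheduled L, xa, xd, rT, target density, and cell diameter at time t.

    Constant before the 16-somite stage; linear in (s - 16) after. Raises if
    any scheduled quantity has shrunk to zero or below (the run has outlived
    the model's validity).
    """
    s = float(somite_stage(t, sp))
    ds = max(0.0, s - 16.0)
    ds_dc = math.floor(ds) if sp.stepwise_dc else ds
    sched = GeometrySchedule(
        L=sp.L0 - sp.ma * ds,
        xa=sp.xa0 + sp.ma * ds,
        xd=100.0,
        rT=sp.r0 - sp.mr * ds,
        rho_target=sp.rho_t0 + sp.m_rho * ds,
        dc=sp.dc0 - sp.m_dc * ds_dc,
    )
    if min(sched.L, sched.rT, sched.rho_target, sched.dc) <= 0.0:
        raise ValueError(f"shrinkage schedule degenerate at t={t:.1f} min (s={s:.2f})")
    return sched


def termination_check(
    schedule: GeometrySchedule, n_anterior_cells: int
) -> TerminationReason:
    """LENGTH_EXHAUSTED once the tissue is shorter than the cell-addition
    offset (L(t) < xd); ANTERIOR_GAP when the anterior measurement window
    holds no cells; otherwise CONTINUE."""
    if schedule.L < schedule.xd:
        return TerminationReason.LENGTH_EXHAUSTED
    if n_anterior_cells == 0:
        return TerminationReason.ANTERIOR_GAP
    return TerminationReason.CONTINUE
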