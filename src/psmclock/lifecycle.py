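"""Cell turnover: density-triggered ingression, cell-cycle progression,
division with clock inheritance, and anterior culling.

Cells advect out of the PSM at the anterior, so the tissue is replenished by
adding cells wherever a subdomain's density drops below the target rho0. Three
ingression scenarios are modelled: RANDOM (random interior position, random
phase - a biologically implausible negative control), DP (dorso-posterior:
cells enter on the dorsal quarter of the tailbud surface with phase 0,
cylinders replenished randomly), and DP_LV (dorso-posterior plus
lateral-ventral: tailbud dorsal surface and cylinder ventral quarters, both
with phase 0). Ingressing progenitors do not yet express clock genes, hence
the constant phase theta = 0.

With division enabled each cell progresses through a cycle of length
TG + TM at unit rate; the clock arrests during M-phase (tau_cc in
[TG, TG + TM)), and on completion a daughter spawns d_new away sharing the
mother's phase and direction. Division can be restricted to the posterior of
x = xa + xdiv by pinning tau_cc to 0 anterior of that point.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    SampleRegion,
    SubdomainId,
    TissueGeometry,
    sample_position,
)

__all__ = [
    "IngressionScenario",
    "IngressedPhase",
    "LifecycleParams",
    "Cell",
    "advance_cycle",
    "divide",
    "make_ingressed_cell",
    "lowest_deficient_subdomain",
]


class IngressionScenario(enum.Enum):
    RANDOM = "random"
    DP = "dp"
    DP_LV = "dp_lv"


class IngressedPhase(enum.Enum):
    CONSTANT_ZERO = "constant_zero"
    RANDOM = "random"


@dataclass(frozen=True)
class LifecycleParams:
    """Turnover parameters (defaults: zebrafish).

    rho0   : target number density (um^-3)
    TG, TM : durations of G1+S+G2 and of M-phase (min); TG + TM = 187.5 min
             follows from M-phase lasting 15 min while ~8% of cells are in
             M-phase at any instant
    d_new  : mother-daughter spawn separation (um), dc/10
    xdiv   : division permitted only posterior of xa + xdiv (um); 0 means
             the whole PSM divides (the cycle is still halted in cells frozen
             anterior of the wavefront)
    """

    rho0: float = 0.0015
    scenario: IngressionScenario = IngressionScenario.RANDOM
    ingressed_phase: IngressedPhase = IngressedPhase.CONSTANT_ZERO
    additions_enabled: bool = True
    division_enabled: bool = False
    TG: float = 172.5
    TM: float = 15.0
    d_new: float = 1.1
    xdiv: float = 0.0

    def __post_init__(self) -> None:
        if self.TG < 0 or self.TM < 0 or self.d_new <= 0 or self.rho0 <= 0:
            raise ValueError("require TG, TM >= 0 and d_new, rho0 > 0")

    @property
    def cycle_length(self) -> float:
        return self.TG + self.TM


@dataclass
class Cell:
    """Single-cell record: position, motility direction, clock phase,
    cell-cycle phase, and addition time."""

    id: int
    position: np.ndarray
    n: np.ndarray
    theta: float
    tau_cc: float = 0.0
    t_add: float = 0.0
    history_fill: float = 0.0  # phase-history fill value (DELAYED mode)


def advance_cycle(
    tau_cc: float, x: float, dt: float, lp: LifecycleParams, geom: TissueGeometry
) -> tuple[float, bool]:
    """Advance a cell-cycle phase by dt at unit rate; anterior of xa + xdiv
    the cycle is halted with tau_cc pinned to 0. Returns (new tau_cc,
    division flag); the flag is set when tau_cc reaches TG + TM."""
    if x < geom.xa + lp.xdiv:
        return 0.0, False
    tau = tau_cc + dt
    if tau >= lp.cycle_length:
        return tau, True
    return tau, False


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction via phi in [0, pi], varphi in [0, 2 pi): the
    parameter-uniform polar draw used for spawn offsets and initial
    directions."""
    phi = rng.uniform(0.0, math.pi)
    varphi = rng.uniform(0.0, 2.0 * math.pi)
    sp = math.sin(phi)
    return np.array([math.cos(varphi) * sp, math.sin(varphi) * sp, math.cos(phi)])


def divide(
    mother: Cell, new_id: int, t: float, lp: LifecycleParams, rng: np.random.Generator
) -> Cell:
    """Spawn a daughter d_new away from the mother along a random direction.
    The daughter inherits the mother's clock phase and motility direction;
    both cells restart the cycle at tau_cc = 0."""
    offset = lp.d_new * random_unit_vector(rng)
    daughter = Cell(
        id=new_id,
        position=mother.position + offset,
        n=mother.n.copy(),
        theta=mother.theta,
        tau_cc=0.0,
        t_add=t,
        history_fill=mother.history_fill,
    )
    mother.tau_cc = 0.0
    return daughter


_SCENARIO_RULES = {
    # (region, constant-zero phase?) per subdomain kind
    IngressionScenario.RANDOM: {
        "tailbud": (SampleRegion.INTERIOR_RANDOM, False),
        "cylinder": (SampleRegion.INTERIOR_RANDOM, False),
    },
    IngressionScenario.DP: {
        "tailbud": (SampleRegion.DORSAL_SURFACE, True),
        "cylinder": (SampleRegion.INTERIOR_RANDOM, False),
    },
    IngressionScenario.DP_LV: {
        "tailbud": (SampleRegion.DORSAL_SURFACE, True),
        "cylinder": (SampleRegion.VENTRAL_SURFACE, True),
    },
}


def make_ingressed_cell(
    sub: SubdomainId,
    new_id: int,
    lp: LifecycleParams,
    geom: TissueGeometry,
    rng: np.random.Generator,
    t: float,
) -> Cell:
    """Create one ingressed cell in the given subdomain under the active
    scenario's position/phase rules (see module docstring)."""
    kind = "tailbud" if sub is SubdomainId.TAILBUD else "cylinder"
    region, zero_phase = _SCENARIO_RULES[lp.scenario][kind]
    pos = sample_position(sub, region, geom, rng)
    if zero_phase and lp.ingressed_phase is IngressedPhase.CONSTANT_ZERO:
        theta = 0.0
    else:
        theta = rng.uniform(0.0, 2.0 * math.pi)
    tau_cc = rng.uniform(0.0, lp.cycle_length) if lp.division_enabled else 0.0
    return Cell(
        id=new_id,
        position=pos,
        n=random_unit_vector(rng),
        theta=theta,
        tau_cc=tau_cc,
        t_add=t,
        history_fill=0.0,
    )


_TIE_ORDER = (SubdomainId.LEFT_CYLINDER, SubdomainId.RIGHT_CYLINDER, SubdomainId.TAILBUD)


def lowest_deficient_subdomain(
    densities: dict[SubdomainId, float], rho_target: float
) -> SubdomainId | None:
    """The subdomain to receive one new cell this step: the lowest-density
    subdomain among those below the target, ties broken in fixed order
    (left, right, tailbud); None when no subdomain is deficient."""
    best: SubdomainId | None = None
    best_rho = math.inf
    for sub in _TIE_ORDER:
        rho = densities[sub]
        if rho < rho_target and rho < best_rho:
            best, best_rho = sub, rho
    return best
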