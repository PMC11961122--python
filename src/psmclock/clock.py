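"""Segmentation-clock phase dynamics.

Each cell carries a single oscillator phase theta. Phases advance with a
spatially graded intrinsic frequency omega(x), Kuramoto-style sine coupling to
neighbours within one cell diameter, and additive white phase noise:

    dtheta_i/dt = omega(x_i) + (kappa / N_i) sum_j sin(theta_j* - theta_i)
                  + sqrt(2 D_theta) xi_i(t)

where theta_j* is the neighbour's current phase (instantaneous coupling) or
its phase tau minutes ago (delayed coupling, modelling delta-notch signal
transduction time). Oscillations arrest anterior of the wavefront (x < xa),
freezing the phase pattern that pre-patterns somites, and during M-phase of
the cell cycle (transcriptional arrest during mitosis).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .geometry import TissueGeometry

__all__ = [
    "CouplingMode",
    "MitoticCoupling",
    "ClockParams",
    "PhaseHistory",
    "intrinsic_frequency",
    "phase_increment",
    "delayed_neighbor_phase",
]


class CouplingMode(enum.Enum):
    INSTANT = "instant"
    DELAYED = "delayed"


class MitoticCoupling(enum.Enum):
    COUPLE_TO_MITOTIC = "couple_to_mitotic"
    EXCLUDE_MITOTIC = "exclude_mitotic"


@dataclass(frozen=True)
class ClockParams:
    """Clock parameters (defaults: zebrafish).

    omega0  : intrinsic frequency at the posterior tip (rad/min); the clock
              period is 2 pi / omega0 ~ 30 min
    sigma   : anterior:posterior frequency fold-change (anterior frequency is
              sigma * omega0)
    k       : shape of the exponential frequency gradient
    kappa   : phase coupling strength (1/min)
    D_theta : phase noise intensity (1/min)
    tau     : coupling delay (min); used only in DELAYED mode
    """

    omega0: float = 0.2094
    sigma: float = 0.66
    k: float = 3.07
    kappa: float = 0.07
    D_theta: float = 0.0013
    tau: float = 21.0
    coupling_mode: CouplingMode = CouplingMode.INSTANT
    mitotic_coupling: MitoticCoupling = MitoticCoupling.COUPLE_TO_MITOTIC

    def __post_init__(self) -> None:
        if self.omega0 <= 0 or not (0.0 < self.sigma <= 1.0) or self.k <= 0:
            raise ValueError("require omega0 > 0, sigma in (0, 1], k > 0")
        if self.kappa < 0 or self.D_theta < 0 or self.tau < 0:
            raise ValueError("kappa, D_theta, tau must be non-negative")

    @property
    def period(self) -> float:
        """Posterior clock period 2 pi / omega0 in minutes."""
        return 2.0 * math.pi / self.omega0


def intrinsic_frequency(x, geom: TissueGeometry, cp: ClockParams) -> np.ndarray:
    """Intrinsic frequency gradient

        omega(X) = omega0 (sigma + (1 - sigma) (1 - e^{-k X}) / (1 - e^{-k}))

    with X = (x - xa)/L clamped to [0, 1]; omega(0) = sigma omega0 at the
    anterior rising to omega0 at the posterior tip."""
    X = np.clip((np.asarray(x, dtype=float) - geom.xa) / geom.L, 0.0, 1.0)
    return cp.omega0 * (
        cp.sigma + (1.0 - cp.sigma) * (1.0 - np.exp(-cp.k * X)) / (1.0 - math.exp(-cp.k))
    )


class PhaseHistory:
    """Ring buffer of one cell's phase samples at step resolution, covering at
    least the coupling delay tau; lookups before the cell existed return the
    fill value (0 for ingressed cells, the global initial phase for founders).
    """

    def __init__(self, tau: float, dt: float, t_add: float, fill: float = 0.0):
        self.n_delay = int(round(tau / dt))
        self.dt = dt
        self.t_add = t_add
        self.fill = fill
        self.buf = np.full(self.n_delay + 1, fill, dtype=float)
        self._steps = 0  # samples recorded so far

    def record(self, theta: float) -> None:
        self._steps += 1
        self.buf[self._steps % len(self.buf)] = theta

    def lookup(self, t: float, tau: float) -> float:
        if int(round(tau / self.dt)) > self.n_delay:
            raise ValueError("delay exceeds history buffer capacity")
        # nearest stored sample to t - tau; samples live at t_add + k*dt
        k = int(round((t - tau - self.t_add) / self.dt))
        if k <= 0:
            return self.fill
        k = min(k, self._steps)
        if k == 0:
            return self.fill
        return float(self.buf[k % len(self.buf)])


def delayed_neighbor_phase(hist: PhaseHistory, t: float, tau: float) -> float:
    """Phase of a neighbour tau minutes ago, from its ring buffer; returns the
    fill value for times at or before the cell's addition."""
    return hist.lookup(t, tau)


def phase_increment(
    theta: float,
    x: float,
    neighbor_phases,
    dt: float,
    geom: TissueGeometry,
    cp: ClockParams,
    rng: np.random.Generator | None = None,
    *,
    arrested: bool = False,
) -> float:
    """Reference single-cell phase update (the engine uses a batched
    equivalent).

    ``neighbor_phases`` holds theta_j* for the Ni coupling neighbours (already
    delayed in DELAYED mode, already filtered in EXCLUDE_MITOTIC mode); the
    coupling term vanishes when there are none. ``arrested`` covers both the
    wavefront (x < xa) and M-phase, which zero the whole increment including
    the noise.
    """
    if arrested or x < geom.xa:
        return 0.0
    omega = float(intrinsic_frequency(x, geom, cp))
    nb = np.asarray(neighbor_phases, dtype=float)
    coupling = cp.kappa * float(np.mean(np.sin(nb - theta))) if nb.size else 0.0
    noise = 0.0
    if cp.D_theta > 0.0 and rng is not None:
        noise = math.sqrt(2.0 * cp.D_theta * dt) * float(rng.standard_normal())
    return (omega + coupling) * dt + noise
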