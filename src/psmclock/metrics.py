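"""Synchrony and frequency read-outs.

The phenotype proxies are measured in the anterior window: the left-hand
strip of tissue one cell diameter long at the wavefront (xa <= x <= xa + dc,
y < Yc), where arrested phases pattern somite boundaries. Synchrony is the
Kuramoto order parameter

    r e^{i psi} = (1/N) sum_j e^{i theta_j},

frequency is the mean of the deterministic part of each cell's instantaneous
dtheta/dt, and the excess frequency subtracts the strip average of the
intrinsic gradient:

    Delta dtheta/dt = dtheta/dt - (1/dc) int_{xa}^{xa+dc} omega(x) dx.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import fixed_quad

from ._kernels import interactions
from .clock import ClockParams, CouplingMode, MitoticCoupling, intrinsic_frequency
from .geometry import TissueGeometry
from .lifecycle import LifecycleParams

__all__ = [
    "OrderParameterResult",
    "order_parameter",
    "anterior_cells",
    "mean_frequency",
    "delta_frequency",
    "kymograph",
]


@dataclass(frozen=True)
class OrderParameterResult:
    r: float
    psi: float


def order_parameter(phases) -> OrderParameterResult:
    """Magnitude and argument of the population-mean unit phasor; an empty
    input yields NaN (missing), never zero."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        return OrderParameterResult(r=math.nan, psi=math.nan)
    z = np.exp(1j * phases).mean()
    return OrderParameterResult(r=float(abs(z)), psi=float(np.angle(z)))


def anterior_cells(
    state, geom: TissueGeometry, dc: float, lp: LifecycleParams
) -> np.ndarray:
    """Indices of cells in the anterior measurement window: the left-side
    strip xa <= x <= xa + dc, y < Yc; with division enabled, M-phase cells
    (tau_cc >= TG) are excluded so clock arrest is not counted trivially."""
    x, y = state.pos[:, 0], state.pos[:, 1]
    mask = (x >= geom.xa) & (x <= geom.xa + dc) & (y < geom.Yc)
    if lp.division_enabled:
        mask &= state.tau_cc < lp.TG
    return np.flatnonzero(mask)


def mean_frequency(
    state,
    subset: np.ndarray,
    geom: TissueGeometry,
    cp: ClockParams,
    dc: float,
    lp: LifecycleParams,
) -> float:
    """Mean deterministic phase velocity over a cell subset (rad/min).

    Recomputes the coupling term of each cell's current dtheta/dt (intrinsic
    frequency plus kappa/Ni weighted sine coupling; noise excluded) from the
    instantaneous neighbour graph, honouring the arrest rules: wavefront- or
    M-phase-arrested cells contribute 0."""
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size == 0:
        return math.nan
    n_cells = state.pos.shape[0]
    mitotic = (
        (state.tau_cc >= lp.TG) if lp.division_enabled else np.zeros(n_cells, np.bool_)
    )
    if cp.mitotic_coupling is MitoticCoupling.EXCLUDE_MITOTIC:
        src_ok = ~mitotic
    else:
        src_ok = np.ones(n_cells, dtype=np.bool_)
    if cp.coupling_mode is CouplingMode.DELAYED and state.history is not None:
        h = state.history.shape[1]
        theta_src = state.history[:, (state.step_index + 1) % h]
    else:
        theta_src = state.theta
    _, coup, ni, _, _ = interactions(
        state.pos, dc, 0.0, state.theta, np.asarray(theta_src), src_ok
    )
    omega = intrinsic_frequency(state.pos[:, 0], geom, cp)
    freq = omega + np.where(ni > 0, cp.kappa * coup / np.maximum(ni, 1), 0.0)
    arrested = (state.pos[:, 0] < geom.xa) | mitotic
    freq = np.where(arrested, 0.0, freq)
    return float(freq[subset].mean())


def strip_average_frequency(geom: TissueGeometry, cp: ClockParams, dc: float) -> float:
    """(1/dc) integral of omega(x) over [xa, xa + dc], 96-point Gauss."""
    val, _ = fixed_quad(
        lambda x: intrinsic_frequency(x, geom, cp), geom.xa, geom.xa + dc, n=96
    )
    return float(val) / dc


def delta_frequency(freq: float, geom: TissueGeometry, cp: ClockParams, dc: float) -> float:
    """Excess of a measured frequency over the anterior-strip average of the
    intrinsic gradient."""
    return freq - strip_average_frequency(geom, cp, dc)


def kymograph(
    snapshots: pd.DataFrame, geom: TissueGeometry, dc: float, x_max: float | None = None
) -> pd.DataFrame:
    """Long-format synchrony kymograph from per-cell snapshots.

    For each sample time and each AP bin [xa + k dc, xa + (k+1) dc) on the
    left-hand side (y < Yc), the Kuramoto r of the contained cells. Empty
    bins are absent (missing), never zero. Columns: t, bin_start, r, n_cells.
    """
    if x_max is None:
        x_max = geom.Xc + geom.R + geom.rT
    n_bins = math.ceil((x_max - geom.xa) / dc)
    edges = geom.xa + dc * np.arange(n_bins + 1)
    rows = []
    for t, grp in snapshots.groupby("t", sort=True):
        left = grp[(grp["y"] < geom.Yc) & (grp["x"] >= geom.xa) & (grp["x"] < x_max)]
        if left.empty:
            continue
        which = np.digitize(left["x"].to_numpy(), edges) - 1
        theta = left["theta"].to_numpy()
        for b in np.unique(which):
            sel = theta[which == b]
            rows.append(
                {
                    "t": t,
                    "bin_start": edges[b],
                    "r": order_parameter(sel).r,
                    "n_cells": int(sel.size),
                }
            )
    return pd.DataFrame(rows, columns=["t", "bin_start", "r", "n_cells"])
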