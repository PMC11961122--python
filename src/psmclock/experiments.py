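"""Scenario presets, the sweep runner, and desk-scale fixtures.

Presets bundle the parameter changes behind each study condition: the three
ingression scenarios, the motility-profile sweep, density/length variation,
compaction-extension, cell division (with and without the posterior
restriction xdiv), and instantaneous versus delayed coupling. Each preset
differs from the default configuration only in its documented keys, so sweeps
and controls stay comparable.

The fixtures are small, fast harnesses: ``two_cell`` isolates a coupled
oscillator pair whose phase difference has the closed form
phi(t) = 2 arctan(tan(phi0/2) e^{-2 kappa t}); ``mini_psm`` is a half-scale
tissue (~300 cells) that exercises every module in well under a minute.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import apply_overrides
from .engine import SimConfig, run
from .lifecycle import Cell

__all__ = ["PRESETS", "preset", "SweepSpec", "SweepResult", "run_sweep", "mini_fixture"]


_PRESET_OVERRIDES: dict[str, dict] = {
    "default": {},
    "fig2_random": {"lifecycle.scenario": "random"},
    "fig2_dp": {"lifecycle.scenario": "dp"},
    "fig2_dplv": {"lifecycle.scenario": "dp_lv"},
    # compaction-extension: initial values from the 16-somite-stage tissue
    # (rT = 27.6 um, rho = 0.002123 um^-3, dc = 9.2 um, L0 = 325 um, so the
    # wavefront starts at xa0 = rT + R + Xc - L0 = 62.6 um)
    "fig5_compaction": {
        "shrinkage.enabled": True,
        "shrinkage.xa0": 62.6,
        "geometry.xa": 62.6,
        "geometry.rT": 27.6,
        "motion.dc": 9.2,
        "lifecycle.rho0": 0.002123,
    },
    "fig5_control": {
        "geometry.xa": 62.6,
        "geometry.rT": 27.6,
        "motion.dc": 9.2,
        "lifecycle.rho0": 0.002123,
    },
    "fig6_division": {
        "lifecycle.division_enabled": True,
        "lifecycle.TM": 15.0,
        "lifecycle.TG": 172.5,
    },
    "fig8_delay": {"clock.coupling_mode": "delayed", "clock.tau": 21.0},
    "fig4_length_fixed_window": {},
}


def preset(name: str, **extra) -> SimConfig:
    """A complete configuration for a named study condition; ``extra`` dotted
    keys are applied on top."""
    if name not in _PRESET_OVERRIDES:
        raise KeyError(
            f"unknown preset '{name}'; available: {', '.join(sorted(_PRESET_OVERRIDES))}"
        )
    overrides = dict(_PRESET_OVERRIDES[name])
    overrides.update(extra)
    cfg = apply_overrides(SimConfig(), overrides)
    if name == "fig4_length_fixed_window":
        # cell addition confined to a posterior region of fixed extent
        # 100 + R + rT regardless of tissue length: xd = L - R - rT - 100
        cfg = apply_overrides(
            cfg, {"geometry.xd": cfg.geometry.Xc - cfg.geometry.xa - 100.0}
        )
    return cfg


PRESETS = tuple(sorted(_PRESET_OVERRIDES))


# sweep grids for the heat-map style experiments; the marked zebrafish values
# (Xv=0.4, h=3, kappa=0.07, vs=1, tau=21) all lie on these grids
SWEEP_GRIDS: dict[str, dict[str, list]] = {
    "fig3_motility_sweep": {
        "motion.Xv": [round(0.1 * i, 1) for i in range(11)],
        "motion.h": [0.5 * i for i in range(11)],
    },
    "fig4_density": {"lifecycle.rho0": [0.00075, 0.0015, 0.00225, 0.003]},
    "fig4_length": {"geometry.L": [200.0, 325.0, 385.0, 450.0]},
    "fig7_coupling_sweep": {
        "clock.kappa": [0.01 * i for i in range(21)],
        "motion.vs": [0.25 * i for i in range(13)],
    },
    "fig8_delay_sweep": {
        "clock.kappa": [0.01 * i for i in range(21)],
        "clock.tau": [3.0 * i for i in range(13)],
    },
}


@dataclass(frozen=True)
class SweepSpec:
    """A parameter grid crossed with replicates over a base preset."""

    preset: str = "default"
    grid: dict = field(default_factory=dict)
    replicates: int = 1
    base_seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.grid or self.replicates < 1:
            raise ValueError("grid must be non-empty and replicates >= 1")


@dataclass
class SweepResult:
    raw: pd.DataFrame  # one row per (grid point, replicate)
    summary: pd.DataFrame  # median/IQR per grid point


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run every grid point x replicate; replicate i uses seed base_seed + i
    offset by the grid-point index so no two runs share a seed. Individual
    failures are recorded per-row and the sweep continues."""
    names = list(spec.grid)
    rows = []
    for gp_index, values in enumerate(itertools.product(*(spec.grid[n] for n in names))):
        point = dict(zip(names, values))
        for rep in range(spec.replicates):
            seed = spec.base_seed + gp_index * spec.replicates + rep
            row = {**point, "replicate": rep, "seed": seed}
            try:
                cfg = preset(spec.preset, **spec.overrides, **point, seed=seed)
                traj = run(cfg)
                end = traj.metrics.iloc[-1]
                row.update(
                    r_anterior=end["r_anterior"],
                    mean_freq=end["mean_freq"],
                    delta_freq=end["delta_freq"],
                    t_end=end["t"],
                    termination=traj.termination.value,
                    error="",
                )
            except Exception as exc:  # noqa: BLE001 - per-row failure tolerance
                row.update(
                    r_anterior=math.nan,
                    mean_freq=math.nan,
                    delta_freq=math.nan,
                    t_end=math.nan,
                    termination="error",
                    error=str(exc),
                )
            rows.append(row)
    raw = pd.DataFrame(rows)
    grouped = raw.groupby(names, sort=True)
    summary = grouped.agg(
        median_r=("r_anterior", "median"),
        iqr_low_r=("r_anterior", lambda s: s.quantile(0.25)),
        iqr_high_r=("r_anterior", lambda s: s.quantile(0.75)),
        median_delta_freq=("delta_freq", "median"),
        n_runs=("r_anterior", "size"),
    ).reset_index()
    return SweepResult(raw=raw, summary=summary)


def mini_fixture(name: str, **extra) -> SimConfig:
    """Desk-scale harness configurations (see module docstring)."""
    if name == "two_cell":
        # inside the anterior measurement window so the metrics see the pair;
        # the flat frequency gradient (sigma = 1) makes position immaterial
        cells = (
            Cell(id=0, position=np.array([5.0, 25.0, 25.0]), n=np.array([1.0, 0.0, 0.0]),
                 theta=math.pi / 2.0),
            Cell(id=1, position=np.array([5.0, 30.0, 25.0]), n=np.array([1.0, 0.0, 0.0]),
                 theta=0.0),
        )
        overrides = {
            "motion.va": 0.0, "motion.vp": 0.0, "motion.vs": 0.0, "motion.D": 0.0,
            "motion.mu": 0.0, "motion.mu_b": 0.0,
            "clock.sigma": 1.0, "clock.D_theta": 0.0,
            "lifecycle.additions_enabled": False,
            "t_max": 10.0, "relax_duration": 0.0, "sample_interval": 1.0,
        }
        overrides.update(extra)
        cfg = apply_overrides(SimConfig(), overrides)
        return dataclasses.replace(cfg, initial_cells=cells)
    if name == "mini_psm":
        overrides = {
            "geometry.Xc": 150.0, "geometry.R": 30.0, "geometry.rT": 12.5,
            "dt": 0.02, "t_max": 200.0,
        }
        overrides.update(extra)
        return apply_overrides(SimConfig(), overrides)
    raise KeyError(f"unknown fixture '{name}'; available: two_cell, mini_psm")
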