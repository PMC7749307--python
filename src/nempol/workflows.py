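"""Configuration handling, seeded reproduction workflows and file output.

A run is described by a declarative :class:`RunConfig` (YAML on disk).
Workflows orchestrate the library modules at configurable scale: the
kinetic ``(rho_bar, psi)`` phase diagram, the hydrodynamic ``(rho_bar,
alpha2)`` phase diagram, and the coexistence demonstrations at the
reference parameter points of the two theories.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from nempol.boltzmann2d import SimConfig, band_seeded_condition, run_simulation
from nempol.diagnostics import classify_trajectory, global_order
from nempol.hydrodynamics import (
    HydroConfig,
    band_seeded_fields,
    default_coefficients,
    nematic_polar_threshold_hydro,
    phase_diagram_hydro,
    run_hydro,
)
from nempol.mode_system import ModelParams, critical_density, nematic_polar_threshold, table_for
from nempol.stability_phase import PhaseDiagram, phase_diagram

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "workflow_phase_diagram_kinetic",
    "workflow_phase_diagram_hydro",
    "workflow_coexistence_demo",
    "SCALE_PRESETS",
]

#: problem-size presets: quick checks ("ci"), interactive scale ("desk"),
#: and publication scale ("full")
SCALE_PRESETS = {
    "ci": {"N": 48, "L": 30.0, "n_theta": 16, "t_end": 1200.0, "grid": 8},
    "desk": {"N": 64, "L": 50.0, "n_theta": 16, "t_end": 2500.0, "grid": 12},
    "full": {"N": 128, "L": 100.0, "n_theta": 32, "t_end": 10000.0, "grid": 24},
}

_ALLOWED = {
    "workflow", "sigma", "psi", "rho_bar", "kc", "alpha2", "seed", "scale",
    "L", "N", "n_theta", "dt", "t_end", "out_every", "noise_eps",
    "band_seed", "band_amplitude",
    "coefficient_overrides", "rho_grid", "psi_grid", "alpha2_grid", "out",
}


@dataclass
class RunConfig:
    """Declarative, serializable description of a run."""

    workflow: str = "coexistence-kinetic"
    sigma: float = 0.2
    psi: float = 0.0
    rho_bar: float = 0.2
    kc: int = 10
    alpha2: float = 1.5
    seed: int = 0
    scale: str = "ci"
    L: Optional[float] = None
    N: Optional[int] = None
    n_theta: Optional[int] = None
    dt: Optional[float] = None
    t_end: Optional[float] = None
    out_every: Optional[float] = None
    noise_eps: float = 1e-2
    band_seed: bool = False  # start from a band-seeded state
    band_amplitude: float = 0.35
    coefficient_overrides: dict = field(default_factory=dict)
    rho_grid: Optional[list] = None
    psi_grid: Optional[list] = None
    alpha2_grid: Optional[list] = None
    out: Optional[str] = None

    def __post_init__(self):
        if not (0.0 <= self.psi <= np.pi / 2.0 + 1e-15):
            raise ValueError(f"psi={self.psi} outside [0, pi/2]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.rho_bar < 0:
            raise ValueError("rho_bar must be non-negative")
        if self.scale not in SCALE_PRESETS:
            raise ValueError(f"unknown scale {self.scale!r}")

    def resolved(self, key: str):
        v = getattr(self, key)
        if v is not None:
            return v
        preset = SCALE_PRESETS[self.scale]
        return preset.get(key)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    unknown = set(data) - _ALLOWED
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(asdict(cfg), f, sort_keys=True)


def workflow_phase_diagram_kinetic(cfg: RunConfig) -> PhaseDiagram:
    """Kinetic (rho_bar, psi) phase diagram at configurable resolution."""
    n = SCALE_PRESETS[cfg.scale]["grid"]
    rho_grid = np.asarray(cfg.rho_grid if cfg.rho_grid else np.linspace(0.05, 0.5, n))
    psi_grid = np.asarray(cfg.psi_grid if cfg.psi_grid
                          else np.linspace(0.0, 0.2 * np.pi, n))
    pd_ = phase_diagram(rho_grid, psi_grid, cfg.sigma, kc=cfg.kc)
    pd_.meta.update({"config_hash": cfg.config_hash(), "seed": cfg.seed})
    if cfg.out:
        pd_.to_csv(cfg.out)
    return pd_


def workflow_phase_diagram_hydro(cfg: RunConfig) -> PhaseDiagram:
    """Hydrodynamic (rho_bar, alpha2) phase diagram with derived defaults."""
    n = SCALE_PRESETS[cfg.scale]["grid"]
    rho_grid = np.asarray(cfg.rho_grid if cfg.rho_grid else np.linspace(0.12, 0.3, n))
    a2_grid = np.asarray(cfg.alpha2_grid if cfg.alpha2_grid else np.linspace(0.8, 2.0, n))
    pd_ = phase_diagram_hydro(rho_grid, a2_grid, sigma=cfg.sigma)
    pd_.meta.update({"config_hash": cfg.config_hash(), "seed": cfg.seed})
    if cfg.out:
        pd_.to_csv(cfg.out)
    return pd_


def workflow_coexistence_demo(cfg: RunConfig) -> dict:
    """Run a kinetic or hydrodynamic simulation and classify the trajectory.

    Returns a report dict with the regime label, the event log, the order
    time series, and the relevant threshold densities.
    """
    if cfg.workflow == "coexistence-kinetic":
        params = ModelParams(rho_bar=cfg.rho_bar, sigma=cfg.sigma, psi=cfg.psi, kc=cfg.kc)
        n_theta = int(cfg.resolved("n_theta"))
        table = table_for(params, kmax=min(n_theta // 2 - 1, 12))
        sim = SimConfig(params=params, L=float(cfg.resolved("L")),
                        N=int(cfg.resolved("N")), n_theta=n_theta,
                        dt=cfg.dt, t_end=float(cfg.resolved("t_end")),
                        out_every=cfg.out_every or float(cfg.resolved("t_end")) / 50.0,
                        seed=cfg.seed, noise_eps=cfg.noise_eps)
        fields = band_seeded_condition(sim, amplitude=cfg.band_amplitude) \
            if cfg.band_seed else None
        traj = run_simulation(sim, table=table, fields=fields)
        thr = nematic_polar_threshold(cfg.sigma, cfg.psi, table, kc=cfg.kc, rho_max=1.0)
        thresholds = {
            "rho_1c": critical_density(1, cfg.sigma, cfg.psi, table),
            "rho_2c": critical_density(2, cfg.sigma, cfg.psi, table),
            "rho_nem_pol": thr,
        }
    elif cfg.workflow == "coexistence-hydro":
        coeffs = default_coefficients(sigma=cfg.sigma, alpha2=cfg.alpha2,
                                      **cfg.coefficient_overrides)
        hc = HydroConfig(coeffs=coeffs, rho_bar=cfg.rho_bar,
                         L=float(cfg.resolved("L")), N=int(cfg.resolved("N")),
                         dt=cfg.dt or 0.1, t_end=float(cfg.resolved("t_end")),
                         out_every=cfg.out_every or float(cfg.resolved("t_end")) / 50.0,
                         seed=cfg.seed, noise_eps=cfg.noise_eps)
        fields = band_seeded_fields(hc, amplitude=cfg.band_amplitude) \
            if cfg.band_seed else None
        traj = run_hydro(hc, fields=fields)
        thresholds = {
            "rho_2c": coeffs.rho_2c,
            "rho_nem_pol": nematic_polar_threshold_hydro(coeffs),
        }
    else:
        raise ValueError(f"unknown workflow {cfg.workflow!r}")

    label, events = classify_trajectory(traj)
    series = pd.DataFrame(
        [{"t": s["t"], **dict(zip(("p1", "p2", "contrast"), global_order(s)))}
         for s in traj])
    report = {
        "label": label.label,
        "evidence": label.evidence,
        "events": events.events,
        "thresholds": thresholds,
        "order_series": series,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }
    if cfg.out:
        series.to_csv(str(cfg.out) + ".series.csv", index=False)
        with open(str(cfg.out) + ".report.json", "w") as f:
            json.dump({k: v for k, v in report.items() if k != "order_series"},
                      f, indent=2, default=float)
    return report
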