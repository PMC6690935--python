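"""Run configuration.

All tunable parameters of the simulator live in plain dataclasses that map
1:1 onto the TOML sections ``[vessels]``, ``[cells]``, ``[fields]``,
``[remodeling]``, ``[schedule]`` and ``[output]``.  Units follow the
package-wide convention: lengths in μm, blood pressure in kPa, oxygen
partial pressure in mmHg, concentrations in mM, flows in μm³/s, time in
hours at the schedule level and seconds at the cell level.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


@dataclass
class VesselConfig:
    """Geometry and hemodynamic boundary conditions of the capillary mesh."""

    nx: int = 9
    ny: int = 9
    nz: int = 9
    spacing: float = 80.0           # μm, inter-capillary lattice constant
    capillary_radius: float = 4.0   # μm
    radius_jitter: float = 0.1      # fractional radius heterogeneity
    inlet_pressure: float = 10.0    # kPa, arterial face
    outlet_pressure: float = 2.0    # kPa, venous face
    inlet_hematocrit: float = 0.45
    n_inlets: int | None = None     # None -> every node on the -x face
    n_outlets: int | None = None    # None -> every node on the +x face
    plasma_viscosity: float = 1.2e-3  # Pa·s
    arterial_po2: float = 80.0      # mmHg at inlets
    o2_carrying_capacity: float = 1.6e4  # mmHg-equivalent bound O2 per unit Hct
    p50: float = 27.0               # mmHg, hemoglobin half saturation
    hill_n: float = 2.7             # Hill exponent of the saturation curve
    gamma_o2: float = 30.0           # μm/s, transmural O2 transfer coefficient
    gamma_glucose: float = 10.0     # μm/s, transmural glucose transfer
    vessel_glucose: float = 5.0     # mM in plasma
    intravascular_ds: float = 40.0  # μm, marching substep along segments


@dataclass
class CellConfig:
    """Cell agent parameters: geometry, mechanics, metabolism, cycle."""

    # geometry
    r_div: float = 10.0         # μm, radius at mitosis
    r_checkpoint: float = 9.0   # μm, minimum radius for the G1p->S gate
    r_max: float = 11.0         # μm
    r_necrotic: float = 6.0     # μm, asymptotic radius of dead cells
    necrotic_shrink_rate: float = 0.1   # 1/h
    division_offset: float = 0.5        # fraction of daughter radius
    # mechanics (overdamped; spring constants folded with the drag)
    k_repulsion: float = 0.05   # 1/s
    k_adhesion: float = 0.01    # 1/s
    delta_adhesion: float = 2.0  # μm, adhesive shell thickness
    contact_cutoff: float = 30.0  # μm, Delaunay edge cutoff
    max_step_fraction: float = 0.1  # displacement cap per step, × radius
    # metabolism
    membrane_p_o2: float = 10.0     # μm/s, O2 membrane permeability
    q_o2_max: float = 2.0e5         # mmHg·μm³/s, maximal O2 consumption
    p50_consumption: float = 1.5    # mmHg
    hill_n_consumption: float = 2.0
    vmax_glucose: float = 20.0      # mM·μm/s, carrier capacity
    km_glucose: float = 1.0         # mM
    glucose_per_o2: float = 2.2e-4  # mM/mmHg, oxidative stoichiometry
    u_anaerobic_max: float = 60.0   # mM·μm³/s, glycolytic capacity
    p_lactate: float = 2.0          # μm/s, lactate export permeability
    ph_opt: float = 7.35
    ph_sigma: float = 0.8           # width of the bell-shaped pH modulation
    n_mito_ref: int = 100
    # cycle (nominal durations, hours)
    t_g1m: float = 6.0
    t_g1p: float = 5.0
    t_s: float = 8.0
    t_g2: float = 3.0
    t_m: float = 1.0
    p_cycle: float = 3.0    # mmHg, O2 half-point of the cycle stretch factor
    k_cycle: float = 0.05   # mM, glucose half-point
    # death
    p_death: float = 1.0    # mmHg
    t_starve: float = 8.0   # h of continuous anoxia before death
    ph_death: float = 6.1
    # hypoxia signalling
    p_hypoxia: float = 5.0  # mmHg; below this the cell emits VEGF
    vegf_rate: float = 1.0  # 1/s per hypoxic cell

    @property
    def cycle_time(self) -> float:
        """Nominal total cycle duration in hours."""
        return self.t_g1m + self.t_g1p + self.t_s + self.t_g2 + self.t_m


@dataclass
class FieldConfig:
    """Continuum tissue fields on the cubic grid."""

    spacing: float = 25.0       # μm
    margin: float = 60.0        # μm beyond the vessel mesh bounding box
    d_o2: float = 2000.0        # μm²/s
    o2_mm_half: float = 4.0     # mmHg, Michaelis constant of the tissue sink
    d_glucose: float = 600.0    # μm²/s
    glucose_mm_half: float = 0.5  # mM
    d_lactate: float = 800.0    # μm²/s
    lactate_decay: float = 3e-3  # 1/s, clearance
    d_vegf: float = 100.0       # μm²/s
    vegf_decay: float = 1e-2    # 1/s  (penetration depth 100 μm)
    ph0: float = 7.4
    beta_ph: float = 0.15       # pH units per mM lactate
    coupled_tol: float = 0.1    # mmHg, convergence of the O2 alternation
    coupled_max_iters: int = 30
    rd_tol: float = 1e-6
    rd_max_iters: int = 50


@dataclass
class RemodelingConfig:
    """Vascular remodeling thresholds and rates (per vessel tick)."""

    enabled: bool = True
    sprout_probability: float = 0.1     # 1/(site·h)
    sprout_max_length: float = 320.0    # μm
    anastomosis_radius: float = 45.0    # μm
    dilation_rate: float = 0.4          # μm per tick
    r_max: float = 10.0                 # μm, dilation cap
    tau_crit: float = 1.0               # Pa, shear below which collapse may fire
    collapse_probability: float = 0.25  # 1/tick for eligible segments
    vegf_regress_threshold: float = 2e-4
    regression_grace: float = 4.0       # h
    maturation_age: float = 20.0        # h, sprout -> capillary
    alpha_factor: float = 3.0           # alpha = (alpha_factor × mean radius)²


@dataclass
class ScheduleConfig:
    """Two-timescale main loop cadence.  dt_cell ≤ dt_fields ≤ 3600·dt_vessel."""

    dt_cell: float = 10.0       # s
    dt_fields: float = 600.0    # s
    dt_vessel: float = 1.0      # h
    t_end: float = 24.0         # h
    snapshot_every: float = 4.0  # h
    vegf_threshold: float = 1e-3  # remodeling switches on above this
    seed: int = 0
    seed_mode: str = "network_center"  # or near_arterial_bifurcation / near_venous_bifurcation
    n_seed_cells: int = 1
    rebuild_every: int = 10     # neighbor-graph refresh cadence (steps)

    def __post_init__(self) -> None:
        if not (0 < self.dt_cell <= self.dt_fields <= self.dt_vessel * 3600.0):
            raise ValueError(
                "schedule must satisfy 0 < dt_cell <= dt_fields <= dt_vessel*3600"
            )


@dataclass
class OutputConfig:
    out_dir: str | None = None
    write_events: bool = True


@dataclass
class SimulationConfig:
    vessels: VesselConfig = field(default_factory=VesselConfig)
    cells: CellConfig = field(default_factory=CellConfig)
    fields: FieldConfig = field(default_factory=FieldConfig)
    remodeling: RemodelingConfig = field(default_factory=RemodelingConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        sections = {
            "vessels": VesselConfig,
            "cells": CellConfig,
            "fields": FieldConfig,
            "remodeling": RemodelingConfig,
            "schedule": ScheduleConfig,
            "output": OutputConfig,
        }
        kwargs = {}
        for name, klass in sections.items():
            sub = dict(d.get(name, {}))
            valid = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - valid
            if unknown:
                raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
            kwargs[name] = klass(**sub)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, s: str) -> "SimulationConfig":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_toml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))
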