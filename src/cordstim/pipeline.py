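"""End-to-end pipeline: build the default model and compute study figures.

This module ties the layers together in one place so the command-line
interface, the acceptance script and the test suite all exercise the same
code path: geometry -> mesh -> basis fields -> activation grid -> sweeps.

The physics is deterministic; the only randomized modeling degree of freedom
is the axial alignment of fiber nodes relative to the array (nobody knows
where the nodes of Ranvier sit), so replicate runs draw a global alignment
offset per replicate from a seeded generator and the reported figures are
replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ExperimentConfig
from .field import BasisSet, Montage, solve_basis, superpose, \
    white_matter_inflow_fraction
from .geometry import CordGeometry, TArrayLayout, build_cord_geometry, \
    place_t_array
from .mapping import ActivationGrid, build_grid
from .mesh import Mesh, generate_mesh
from .montage import SweepResult, make_depth_schedule, make_lateral_schedule, \
    run_sweep, run_trial
from .safety import SiteElectricalSpec, charge_limit_per_phase, \
    max_phase_current


@dataclass
class Model:
    """Everything reusable across montages for one configuration."""
    config: ExperimentConfig
    geometry: CordGeometry
    layout: TArrayLayout
    mesh: Mesh
    basis: BasisSet
    grid: ActivationGrid

    @property
    def cond(self):
        return self.basis.cond


def build_model(config: ExperimentConfig | None = None,
                basis: BasisSet | None = None) -> Model:
    """Build the default cord + array model and solve its basis fields.

    Pass ``basis`` to reuse a previously solved (or loaded) basis set.
    """
    cfg = config or ExperimentConfig()
    geom = build_cord_geometry()
    layout = place_t_array(geom)
    if basis is None:
        mesh = generate_mesh(geom, layout,
                             resolution=cfg.mesh_resolution_mm)
        basis = solve_basis(mesh, cfg.conductivity_map())
    else:
        mesh = basis.mesh
    grid = build_grid(geom, cfg.map_spacing_mm)
    return Model(config=cfg, geometry=geom, layout=layout, mesh=mesh,
                 basis=basis, grid=grid)


def depth_sweep(model: Model, alignment: float = 0.0) -> SweepResult:
    sched = make_depth_schedule(model.layout, model.config.depth_trials)
    return run_sweep(model.basis, sched, model.grid, model.geometry,
                     stim_duration_ms=model.config.stim_duration_ms,
                     max_total_mA=model.config.max_total_mA,
                     dt_ms=model.config.axon_dt_ms, alignment=alignment)


def lateral_sweep(model: Model, alignment: float = 0.0) -> SweepResult:
    sched = make_lateral_schedule(model.layout, model.config.lateral_trials)
    return run_sweep(model.basis, sched, model.grid, model.geometry,
                     stim_duration_ms=model.config.stim_duration_ms,
                     max_total_mA=model.config.max_total_mA,
                     dt_ms=model.config.axon_dt_ms, alignment=alignment)


def max_depth_montage(model: Model) -> Montage:
    """Trial-1 depth shape (central cathodes, tip returns), unit cathodic."""
    sched = make_depth_schedule(model.layout, model.config.depth_trials)
    return sched.trials[0].montage


def inflow_fraction_at(model: Model, total_cathodic_mA: float = 4.0) -> float:
    """White-matter inflow, % of delivered current, for the max-depth shape."""
    m = max_depth_montage(model).scaled(total_cathodic_mA)
    sol = superpose(model.basis, m)
    return white_matter_inflow_fraction(sol, model.cond)


def charge_limited_depth(model: Model, alignment: float = 0.0) -> dict:
    """Recruitment depth of the max-depth shape at the electrode charge limit.

    The amplitude is the largest total cathodic current for which no single
    site exceeds the per-phase charge limit of its area.
    """
    spec = SiteElectricalSpec()
    shape = max_depth_montage(model)
    per_site_cap = max_phase_current(
        spec, model.config.stim_duration_ms * 1e3)
    amp = per_site_cap / np.abs(shape.site_currents).max()
    sched = make_depth_schedule(model.layout, model.config.depth_trials)
    res = run_trial(model.basis, sched.trials[0], model.grid, model.geometry,
                    amplitude_mA=amp,
                    stim_duration_ms=model.config.stim_duration_ms,
                    dt_ms=model.config.axon_dt_ms, alignment=alignment)
    return {"amplitude_mA": amp, "per_site_cap_mA": per_site_cap,
            "depth_mm": res.depth_mm,
            "charge_limit_uC": charge_limit_per_phase(spec)}


def compute_targets(config: ExperimentConfig | None = None,
                    model: Model | None = None,
                    progress=None) -> dict:
    """Compute the summary figures t4-t7 of the default study.

    * t4 - current entering the white matter as a percentage of a 4 mA
      delivered current, max-depth montage (field-level, deterministic).
    * t5 - power ratio of depth trial 1 (tip returns) to the last trial
      (stem returns) at gray-silent calibrated amplitudes.
    * t6 - power saving (%) of the last depth trial that preserves each of
      trial 1's three fiber-class recruited areas within 5%.
    * t7 - midline recruitment depth (mm) at the per-site charge limit.

    t5-t7 are means over ``config.n_replicates`` node-alignment replicates;
    returns ``{"t4": {"value": .., "n": ..}, ...}``.
    """
    cfg = config or ExperimentConfig()
    if model is None:
        model = build_model(cfg)
    rng = np.random.default_rng(cfg.seed)
    alignments = rng.uniform(-0.5, 0.5, size=cfg.n_replicates)
    t5s, t6s, t7s = [], [], []
    for rep, al in enumerate(alignments):
        sweep = depth_sweep(model, alignment=float(al))
        t5s.append(sweep.power_ratio(1, len(sweep.trials)))
        _, saving = sweep.area_preserving_power_saving()
        t6s.append(100.0 * saving)
        t7s.append(charge_limited_depth(model, alignment=float(al))["depth_mm"])
        if progress is not None:
            progress(rep, {"t5": t5s[-1], "t6": t6s[-1], "t7": t7s[-1]})
    n = cfg.n_replicates
    return {
        "t4": {"value": float(inflow_fraction_at(model)), "n": 1},
        "t5": {"value": float(np.mean(t5s)), "n": n},
        "t6": {"value": float(np.mean(t6s)), "n": n},
        "t7": {"value": float(np.mean(t7s)), "n": n},
    }
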