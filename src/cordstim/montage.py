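"""Montage steering sweeps: trial schedules, calibration, and execution.

A *sweep* is an ordered list of montage shapes (unit-amplitude current
patterns over the 12 sites).  Each trial is calibrated independently: its
amplitude is raised to the largest total cathodic current that still
produces zero gray-matter activation, then the activation map, power and
electrode-safety figures are computed at that amplitude.

Two canonical schedules:

* depth steering - cathodes fixed on the two central cross sites, the
  anodic return shifted linearly from the cross tips (trial 1) to the
  caudal stem sites (last trial), pushing recruitment depth against power;
* lateral steering - interpolation between a lateralized tip-cathode
  montage and the symmetric centered montage, sweeping the recruited
  territory across the midline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axon import DEFAULT_FIBER_CLASSES, FiberSpec, simulate_batch
from .field import BasisSet, FieldSolution, Montage, superpose
from .mapping import (ActivationGrid, ActivationMap, max_activation_depth,
                      node_potentials_at, scan)
from .safety import PulseWaveform, SiteElectricalSpec, waveform_safety_report


class ScheduleError(ValueError):
    pass


@dataclass(frozen=True)
class TrialSpec:
    """One montage shape, normalized to 1 mA total cathodic current."""
    name: str
    montage: Montage

    def __post_init__(self):
        if not self.montage.balanced:
            raise ScheduleError(f"trial {self.name}: montage is not balanced")
        tc = self.montage.total_cathodic_mA
        if abs(tc - 1.0) > 1e-9:
            raise ScheduleError(
                f"trial {self.name}: shape must be unit cathodic, got {tc}")


@dataclass(frozen=True)
class SweepSchedule:
    name: str
    trials: tuple[TrialSpec, ...]

    def __len__(self) -> int:
        return len(self.trials)


def _unit_shape(currents: np.ndarray) -> np.ndarray:
    c = np.asarray(currents, dtype=float)
    cath = -c[c < 0].sum()
    if cath <= 0:
        raise ScheduleError("montage shape has no cathodic current")
    return c / cath


def make_depth_schedule(layout, n_trials: int = 9) -> SweepSchedule:
    """Cathodes on the central cross pair; return shifted tips -> stem.

    Trial i in 1..n assigns a fraction f = 1 - (i-1)/(n-1) of the anodic
    return to the two cross tips and the rest evenly over the stem sites.
    """
    if n_trials < 2:
        raise ScheduleError("need at least 2 trials")
    cs = layout.group_ids("CS")
    tips = layout.tip_site_ids
    stem = layout.stem_site_ids
    trials = []
    for i in range(n_trials):
        f = 1.0 - i / (n_trials - 1)
        c = np.zeros(layout.n_sites)
        for sid in cs:
            c[sid] = -1.0 / len(cs)
        for sid in tips:
            c[sid] += f / len(tips)
        for sid in stem:
            c[sid] += (1.0 - f) / len(stem)
        trials.append(TrialSpec(f"depth_{i + 1:02d}", Montage(_unit_shape(c))))
    return SweepSchedule("depth", tuple(trials))


def make_lateral_schedule(layout, n_trials: int = 7) -> SweepSchedule:
    """Interpolate a lateralized tip montage into the centered montage.

    Endpoint A: cathode on the left tip, return split over its two cross
    neighbors.  Endpoint B: cathodes on the central pair, return split over
    the four lateral cross sites.  Intermediate shapes are linear blends,
    renormalized to unit cathodic current.
    """
    if n_trials < 2:
        raise ScheduleError("need at least 2 trials")
    cross = layout.cross_site_ids
    if len(cross) < 6:
        raise ScheduleError("lateral schedule needs a 6-site cross bar")
    left_tip, l1, c1, c2, r1, right_tip = cross
    a = np.zeros(layout.n_sites)
    a[left_tip] = -1.0
    a[l1] = a[c1] = 0.5
    b = np.zeros(layout.n_sites)
    b[c1] = b[c2] = -0.5
    for sid in (left_tip, l1, r1, right_tip):
        b[sid] = 0.25
    trials = []
    for i in range(n_trials):
        w = i / (n_trials - 1)
        c = (1.0 - w) * a + w * b
        trials.append(TrialSpec(f"lateral_{i + 1:02d}",
                                Montage(_unit_shape(c))))
    return SweepSchedule("lateral", tuple(trials))


# ---------------------------------------------------------------------------
# amplitude calibration
# ---------------------------------------------------------------------------

def calibrate_amplitude(basis: BasisSet, trial: TrialSpec,
                        grid: ActivationGrid,
                        fibers: tuple[FiberSpec, ...] = DEFAULT_FIBER_CLASSES,
                        stim_duration_ms: float = 0.2,
                        max_total_mA: float = 20.0, rel_tol: float = 0.01,
                        t_end_ms: float = 1.0, dt_ms: float = 1e-3,
                        alignment: float = 0.0) -> float:
    """Largest total cathodic amplitude (mA) with zero gray activation.

    The field is linear in amplitude, so the unit-montage node potentials at
    the gray grid points are computed once and rescaled inside the
    bisection; only the lowest-threshold (largest) fiber class is simulated,
    with early exit on the first gray crossing.  Returns ``max_total_mA``
    if even that amplitude is silent in gray matter.
    """
    if not len(grid.gray_points):
        return max_total_mA
    largest = tuple(fibers)[-1]
    sol_unit = superpose(basis, trial.montage)
    ve_unit = node_potentials_at(sol_unit, grid.gray_points, largest,
                                 alignment=alignment)

    def gray_fires(amp: float) -> bool:
        act, _, _ = simulate_batch(largest, ve_unit * amp, stim_duration_ms,
                                   t_end_ms, dt_ms, stop_on_first=True)
        return bool(act.any())

    if not gray_fires(max_total_mA):
        return max_total_mA
    lo, hi = 0.0, max_total_mA
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if gray_fires(mid):
            hi = mid
        else:
            lo = mid
    return lo


def recovery_phase_silent(basis: BasisSet, montage: Montage,
                          grid: ActivationGrid,
                          waveform: PulseWaveform,
                          fibers: tuple[FiberSpec, ...] = DEFAULT_FIBER_CLASSES,
                          dt_ms: float = 1e-3) -> bool:
    """True if the charge-recovery phase alone activates nothing.

    The recovery phase inverts the montage polarity at the waveform's
    recovery amplitude ratio for its (longer) duration; both white and gray
    points are checked with the lowest-threshold class.
    """
    largest = tuple(fibers)[-1]
    sol = superpose(basis, montage.scaled(-waveform.recovery_ratio))
    dur = waveform.recovery_duration * 1e-3
    for pts in (grid.gray_points, grid.white_points):
        if not len(pts):
            continue
        ve = node_potentials_at(sol, pts, largest)
        act, _, _ = simulate_batch(largest, ve, dur, dur + 0.8, dt_ms,
                                   stop_on_first=True)
        if act.any():
            return False
    return True


# ---------------------------------------------------------------------------
# sweep execution
# ---------------------------------------------------------------------------

@dataclass
class TrialResult:
    name: str
    montage: Montage              # at the calibrated amplitude
    amplitude_mA: float           # total cathodic current
    power_mW: float
    activation: ActivationMap
    depth_mm: float
    safety: dict

    @property
    def total_activated_area_mm2(self) -> float:
        return self.activation.total_activated_area_mm2

    def summary(self) -> dict:
        return {
            "name": self.name,
            "amplitude_mA": self.amplitude_mA,
            "power_mW": self.power_mW,
            "depth_mm": self.depth_mm,
            "site_currents_mA": self.montage.site_currents.tolist(),
            **self.activation.summary(),
            "safety": self.safety,
        }


@dataclass
class SweepResult:
    schedule: SweepSchedule
    trials: list[TrialResult]

    def power_ratio(self, i: int, j: int) -> float:
        """Power of trial ``i`` over trial ``j`` (1-based indices)."""
        return self.trials[i - 1].power_mW / self.trials[j - 1].power_mW

    def area_preserving_power_saving(self, area_tol: float = 0.05
                                     ) -> tuple[int, float]:
        """Last trial holding trial 1's recruitment profile, and its saving.

        A trial preserves the profile when each of the three fiber-class
        recruited areas is within ``area_tol`` (relative) of trial 1's;
        returns the (1-based) last such trial and the fractional power
        saving relative to trial 1.
        """
        a0 = self.trials[0].activation.class_areas_mm2()
        p0 = self.trials[0].power_mW
        best = 1
        for k, tr in enumerate(self.trials, start=1):
            ak = tr.activation.class_areas_mm2()
            ok = all(abs(a - b) <= area_tol * b if b > 0 else a == 0.0
                     for a, b in zip(ak, a0))
            if ok:
                best = k
        pk = self.trials[best - 1].power_mW
        saving = 1.0 - pk / p0 if p0 > 0 else 0.0
        return best, saving

    def summary(self) -> dict:
        return {"schedule": self.schedule.name,
                "trials": [t.summary() for t in self.trials]}


def run_trial(basis: BasisSet, trial: TrialSpec, grid: ActivationGrid,
              geometry, fibers: tuple[FiberSpec, ...] = DEFAULT_FIBER_CLASSES,
              amplitude_mA: float | None = None,
              stim_duration_ms: float = 0.2,
              electrical_spec: SiteElectricalSpec | None = None,
              max_total_mA: float = 20.0, dt_ms: float = 1e-3,
              alignment: float = 0.0) -> TrialResult:
    """Calibrate (unless ``amplitude_mA`` is given) and evaluate one trial."""
    if amplitude_mA is None:
        amplitude_mA = calibrate_amplitude(basis, trial, grid, fibers,
                                           stim_duration_ms, max_total_mA,
                                           dt_ms=dt_ms, alignment=alignment)
    montage = trial.montage.scaled(amplitude_mA)
    sol = superpose(basis, montage)
    amap = scan(sol, grid, fibers, stim_duration_ms, dt_ms=dt_ms,
                alignment=alignment)
    depth = max_activation_depth(amap, geometry)
    spec = electrical_spec or SiteElectricalSpec()
    wf = PulseWaveform(stim_amplitude=-amplitude_mA,
                       stim_duration=stim_duration_ms * 1e3)
    report = waveform_safety_report(wf, spec, montage.site_currents)
    return TrialResult(name=trial.name, montage=montage,
                       amplitude_mA=amplitude_mA, power_mW=sol.power_mW,
                       activation=amap, depth_mm=depth,
                       safety=report.to_dict())


def run_sweep(basis: BasisSet, schedule: SweepSchedule, grid: ActivationGrid,
              geometry, fibers: tuple[FiberSpec, ...] = DEFAULT_FIBER_CLASSES,
              stim_duration_ms: float = 0.2,
              electrical_spec: SiteElectricalSpec | None = None,
              max_total_mA: float = 20.0, dt_ms: float = 1e-3,
              progress=None, alignment: float = 0.0) -> SweepResult:
    """Calibrate and evaluate every trial of a schedule in order."""
    results = []
    for trial in schedule.trials:
        res = run_trial(basis, trial, grid, geometry, fibers,
                        None, stim_duration_ms, electrical_spec,
                        max_total_mA, dt_ms, alignment)
        results.append(res)
        if progress is not None:
            progress(res)
    return SweepResult(schedule=schedule, trials=results)
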