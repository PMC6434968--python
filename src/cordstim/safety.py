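"""Pulse-waveform bookkeeping and electrode/tissue charge-safety limits.

All limit computations are exact closed-form arithmetic on a per-site basis:
charge per phase against the platinum electrochemical limit (50 uC/cm^2) and
tissue current-density exposure against the accepted neural-damage boundary
(30 uC/cm^2).  Unit conventions: currents mA, durations us, areas mm^2,
charges uC, charge densities uC/cm^2, current densities mA/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MM2_PER_CM2 = 100.0


class WaveformError(ValueError):
    """Raised for invalid (e.g. charge-unbalanced) pulse waveforms."""


@dataclass(frozen=True)
class PulseWaveform:
    """Biphasic, per-site charge-balanced stimulation pulse.

    The recovery phase is opposite in polarity, lower in amplitude and longer
    in duration than the stimulation phase, restoring net-zero charge.
    """
    stim_amplitude: float            # mA (cathodic negative by convention)
    stim_duration: float = 200.0     # us
    recovery_amplitude: float | None = None   # mA, opposite sign
    recovery_duration: float | None = None    # us
    leading_edge_rise_time: float = 0.0       # us

    def __post_init__(self):
        if self.recovery_amplitude is None or self.recovery_duration is None:
            # default constructor: 1/4 amplitude over 4x duration
            object.__setattr__(self, "recovery_amplitude",
                               -self.stim_amplitude / 4.0)
            object.__setattr__(self, "recovery_duration",
                               4.0 * self.stim_duration)
        q = (self.stim_amplitude * self.stim_duration
             + self.recovery_amplitude * self.recovery_duration)
        scale = abs(self.stim_amplitude * self.stim_duration) or 1.0
        if abs(q) / scale > 1e-12:
            raise WaveformError(
                f"waveform is not charge balanced: residual {q} mA*us")

    @property
    def phase_charge(self) -> float:
        """Magnitude of the per-phase charge in uC (1 mA*us = 1e-3 uC)."""
        return abs(self.stim_amplitude) * self.stim_duration * 1e-3

    @property
    def recovery_ratio(self) -> float:
        """|recovery amplitude| / |stimulation amplitude|."""
        if self.stim_amplitude == 0.0:
            return 0.0
        return abs(self.recovery_amplitude / self.stim_amplitude)


@dataclass(frozen=True)
class SiteElectricalSpec:
    """Electrical/electrochemical ratings of one electrode site."""
    area: float = 1.72                        # mm^2
    charge_density_limit: float = 50.0        # uC/cm^2 (platinum)
    surface_capacitance: float = 0.45         # F/m^2
    tissue_charge_density_limit: float = 30.0  # uC/cm^2

    def __post_init__(self):
        for name in ("charge_density_limit", "surface_capacitance",
                     "tissue_charge_density_limit"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be positive")
        if self.area < 0.0:
            raise ValueError("area must be non-negative")


def charge_limit_per_phase(spec: SiteElectricalSpec) -> float:
    """Per-phase charge limit in uC: site area times the density limit."""
    return spec.area / MM2_PER_CM2 * spec.charge_density_limit


def max_phase_current(spec: SiteElectricalSpec, phase_duration: float) -> float:
    """Largest allowed phase current (mA) for a phase of ``phase_duration`` us."""
    if not phase_duration > 0.0:
        raise ValueError("phase_duration must be positive")
    return charge_limit_per_phase(spec) / phase_duration * 1e3


def site_capacitance(spec: SiteElectricalSpec) -> float:
    """Double-layer capacitance of one site in uF (secondary safety metric)."""
    return spec.surface_capacitance * spec.area * 1e-6 * 1e6  # F/m^2 * m^2 -> F -> uF


def tissue_charge_density(current_density: float,
                          phase_duration: float,
                          spec: SiteElectricalSpec | None = None
                          ) -> tuple[float, bool]:
    """Charge density (uC/cm^2) delivered to tissue and pass/fail vs limit.

    ``current_density`` in mA/cm^2, ``phase_duration`` in us.
    """
    if current_density < 0.0 or phase_duration < 0.0:
        raise ValueError("inputs must be non-negative")
    spec = spec or SiteElectricalSpec()
    q = current_density * phase_duration * 1e-3
    return q, q <= spec.tissue_charge_density_limit


@dataclass(frozen=True)
class SiteSafetyEntry:
    site_id: int
    current: float          # mA during the stimulation phase
    phase_charge: float     # uC
    fraction_of_limit: float


@dataclass(frozen=True)
class WaveformSafetyReport:
    entries: tuple[SiteSafetyEntry, ...]
    charge_limit: float          # uC per phase per site
    max_scale_factor: float      # montage multiplier before first violation

    @property
    def worst_fraction(self) -> float:
        return max((e.fraction_of_limit for e in self.entries), default=0.0)

    def to_dict(self) -> dict:
        return {
            "charge_limit_uC": self.charge_limit,
            "max_scale_factor": self.max_scale_factor,
            "sites": [
                {"site_id": e.site_id, "current_mA": e.current,
                 "phase_charge_uC": e.phase_charge,
                 "fraction_of_limit": e.fraction_of_limit}
                for e in self.entries],
        }


def waveform_safety_report(waveform: PulseWaveform,
                           spec: SiteElectricalSpec,
                           site_currents: np.ndarray) -> WaveformSafetyReport:
    """Per-site phase-charge audit of a montage driven by ``waveform``.

    ``site_currents`` are the per-site stimulation-phase currents in mA for a
    montage whose unit amplitude corresponds to ``waveform.stim_amplitude``;
    each site's delivered charge is ``|I_site| * stim_duration``.  The
    recovery phase carries the same charge magnitude by balance, so the
    per-phase audit covers both phases.
    """
    q = (waveform.stim_amplitude * waveform.stim_duration
         + waveform.recovery_amplitude * waveform.recovery_duration)
    if abs(q) > 1e-9:
        raise WaveformError("waveform is not charge balanced")
    limit = charge_limit_per_phase(spec)
    currents = np.asarray(site_currents, dtype=float)
    charges = np.abs(currents) * waveform.stim_duration * 1e-3
    entries = tuple(
        SiteSafetyEntry(i, float(currents[i]), float(charges[i]),
                        float(charges[i] / limit) if limit > 0 else np.inf)
        for i in range(len(currents)))
    nonzero = charges[charges > 0.0]
    scale = float(limit / nonzero.max()) if nonzero.size else np.inf
    return WaveformSafetyReport(entries, limit, scale)
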