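"""Electrode charge-safety arithmetic: limits, waveforms, montage audit."""

import numpy as np

from cordstim import (PulseWaveform, SiteElectricalSpec,
                      charge_limit_per_phase, max_phase_current,
                      tissue_charge_density, waveform_safety_report)

spec = SiteElectricalSpec()
print(f"site area                {spec.area} mm^2")
print(f"charge limit per phase   {charge_limit_per_phase(spec):.3f} uC")
print(f"max current, 200 us      {max_phase_current(spec, 200.0):.2f} mA")

q, ok = tissue_charge_density(1.33, 200.0)
print(f"tissue charge density    {q:.3f} uC/cm^2 (pass: {ok})")

wf = PulseWaveform(stim_amplitude=-4.3)
print(f"default waveform: {wf.stim_amplitude} mA x {wf.stim_duration} us, "
      f"recovery {wf.recovery_amplitude} mA x {wf.recovery_duration} us")

currents = np.zeros(12)
currents[[2, 3]] = -2.0
currents[[0, 5]] = 2.0
report = waveform_safety_report(wf, spec, currents)
print(f"worst site at {report.worst_fraction:.1%} of the charge limit; "
      f"montage could be scaled by {report.max_scale_factor:.2f}x")
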