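import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cordstim.safety import (PulseWaveform, SiteElectricalSpec, WaveformError,
                             charge_limit_per_phase, max_phase_current,
                             site_capacitance, tissue_charge_density,
                             waveform_safety_report)


def test_default_waveform_balance_and_ratio():
    wf = PulseWaveform(stim_amplitude=-4.3)
    assert wf.recovery_amplitude == pytest.approx(4.3 / 4)
    assert wf.recovery_duration == pytest.approx(800.0)
    assert wf.recovery_ratio == pytest.approx(0.25)
    assert wf.phase_charge == pytest.approx(0.86)


def test_unbalanced_waveform_rejected():
    with pytest.raises(WaveformError):
        PulseWaveform(stim_amplitude=-1.0, stim_duration=200.0,
                      recovery_amplitude=0.3, recovery_duration=200.0)


@given(amp=st.floats(0.01, 50.0), dur=st.floats(10.0, 1000.0),
       ratio=st.floats(0.05, 1.0))
@settings(max_examples=200, deadline=None)
def test_waveform_roundtrip_properties(amp, dur, ratio):
    wf = PulseWaveform(stim_amplitude=-amp, stim_duration=dur,
                       recovery_amplitude=amp * ratio,
                       recovery_duration=dur / ratio)
    assert wf.phase_charge == pytest.approx(amp * dur * 1e-3, rel=1e-9)
    assert wf.recovery_ratio == pytest.approx(ratio, rel=1e-9)
    # net charge is zero by construction
    assert (wf.stim_amplitude * wf.stim_duration
            + wf.recovery_amplitude * wf.recovery_duration
            ) == pytest.approx(0.0, abs=1e-9 * amp * dur)


def test_limits_scale_with_area():
    spec2 = SiteElectricalSpec(area=3.44)
    assert charge_limit_per_phase(spec2) == pytest.approx(1.72)
    assert max_phase_current(spec2, 200.0) == pytest.approx(8.6)


def test_site_capacitance_value():
    # 0.45 F/m^2 over 1.72 mm^2 = 0.774 uF
    assert site_capacitance(SiteElectricalSpec()) == pytest.approx(0.774)


def test_tissue_charge_density_pass_fail():
    q, ok = tissue_charge_density(1.33, 200.0)
    assert ok and q < 30.0
    q2, ok2 = tissue_charge_density(300.0, 1000.0)
    assert not ok2 and q2 > 30.0


def test_report_max_scale_factor_is_tight():
    wf = PulseWaveform(stim_amplitude=-2.0)
    spec = SiteElectricalSpec()
    currents = np.array([-2.0, 1.5, 0.5] + [0.0] * 9)
    rep = waveform_safety_report(wf, spec, currents)
    assert rep.worst_fraction == pytest.approx(
        2.0 * 200.0 * 1e-3 / rep.charge_limit)
    scaled = waveform_safety_report(wf, spec, currents * rep.max_scale_factor)
    assert scaled.worst_fraction == pytest.approx(1.0, rel=1e-9)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        SiteElectricalSpec(charge_density_limit=0.0)
    with pytest.raises(ValueError):
        max_phase_current(SiteElectricalSpec(), 0.0)
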