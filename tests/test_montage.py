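import numpy as np
import pytest

from cordstim.field import Montage, superpose
from cordstim.mapping import build_grid
from cordstim.montage import (ScheduleError, TrialSpec, calibrate_amplitude,
                              make_depth_schedule, make_lateral_schedule,
                              recovery_phase_silent, run_trial)
from cordstim.safety import PulseWaveform


def test_depth_schedule_structure(layout):
    sched = make_depth_schedule(layout)
    assert len(sched) == 9
    for t in sched.trials:
        c = t.montage.site_currents
        assert c.sum() == pytest.approx(0.0, abs=1e-12)
        assert t.montage.total_cathodic_mA == pytest.approx(1.0)
        assert np.all(c[[2, 3]] < 0)          # central cathodes throughout
    first, last = sched.trials[0], sched.trials[-1]
    assert np.all(first.montage.site_currents[6:] == 0.0)   # tips only
    assert np.all(last.montage.site_currents[[0, 5]] == 0.0)  # stem only
    # linear handoff of the return current
    tip_share = [t.montage.site_currents[[0, 5]].sum() for t in sched.trials]
    assert np.allclose(np.diff(tip_share), np.diff(tip_share)[0])


def test_lateral_schedule_endpoints(layout):
    sched = make_lateral_schedule(layout, n_trials=5)
    a = sched.trials[0].montage.site_currents
    b = sched.trials[-1].montage.site_currents
    assert a[0] == pytest.approx(-1.0)
    assert a[1] == pytest.approx(0.5) and a[2] == pytest.approx(0.5)
    assert b[2] == pytest.approx(-0.5) and b[3] == pytest.approx(-0.5)
    for t in sched.trials:
        assert t.montage.total_cathodic_mA == pytest.approx(1.0)
        assert t.montage.site_currents.sum() == pytest.approx(0.0, abs=1e-12)


def test_trialspec_validation():
    bad = np.zeros(12)
    bad[0] = -2.0
    bad[1] = 2.0
    with pytest.raises(ScheduleError):
        TrialSpec("x", Montage(bad))   # cathodic total is 2, not 1


def test_calibration_sits_on_gray_threshold(coarse_basis, geom, layout):
    grid = build_grid(geom, spacing=0.25)
    trial = make_depth_schedule(layout).trials[0]
    amp = calibrate_amplitude(coarse_basis, trial, grid, max_total_mA=40.0)
    from cordstim.mapping import any_gray_activation
    assert not any_gray_activation(
        superpose(coarse_basis, trial.montage.scaled(amp)), grid)
    assert any_gray_activation(
        superpose(coarse_basis, trial.montage.scaled(amp * 1.05)), grid)


def test_run_trial_fixed_amplitude(coarse_basis, geom, layout):
    grid = build_grid(geom, spacing=0.25)
    trial = make_depth_schedule(layout).trials[0]
    res = run_trial(coarse_basis, trial, grid, geom, amplitude_mA=2.0)
    assert res.amplitude_mA == 2.0
    assert res.montage.total_cathodic_mA == pytest.approx(2.0)
    ref = superpose(coarse_basis, trial.montage.scaled(2.0))
    assert res.power_mW == pytest.approx(ref.power_mW, rel=1e-9)
    assert res.safety["sites"][2]["current_mA"] == pytest.approx(-1.0)
    summary = res.summary()
    assert summary["name"] == trial.name


def test_recovery_phase_audit_both_branches(coarse_basis, geom, layout):
    # the audit must flag recovery-phase excitation at high amplitude and
    # clear it at low amplitude
    grid = build_grid(geom, spacing=0.25)
    trial = make_depth_schedule(layout).trials[0]
    wf = PulseWaveform(stim_amplitude=-1.0)
    assert recovery_phase_silent(coarse_basis, trial.montage.scaled(0.1),
                                 grid, wf)
    assert not recovery_phase_silent(coarse_basis, trial.montage.scaled(5.0),
                                     grid, wf)
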