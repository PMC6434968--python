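import numpy as np
import pytest

from cordstim.axon import (DEFAULT_FIBER_CLASSES, DomainError,
                           ExtracellularDrive, FiberSpec, activating_function,
                           alpha_m, alpha_s, beta_m, beta_s, drive_from_field,
                           gating_steady_state, leak_reversal, simulate_axon,
                           simulate_batch, threshold_search)

FIBER = DEFAULT_FIBER_CLASSES[1]


def _focal_drive(fiber, dist=2.0, dur=0.2):
    z = fiber.node_z_positions_mm()
    return ExtracellularDrive(-1.0 / np.sqrt(z ** 2 + dist ** 2), dur)


def test_fiber_table_monotone_dimensions():
    d = [f.diameter_um for f in DEFAULT_FIBER_CLASSES]
    s = [f.node_spacing_um for f in DEFAULT_FIBER_CLASSES]
    assert d == sorted(d) and s == sorted(s)
    for f in DEFAULT_FIBER_CLASSES:
        assert f.node_count == 21
        assert f.coupling_mS_per_cm2 > 0


def test_invalid_fiber_rejected():
    with pytest.raises(ValueError):
        FiberSpec(10.0, 1000.0, 3.0, 7.0, node_count=20)  # even node count


def test_rates_positive_and_continuous():
    v = np.linspace(-150.0, 100.0, 2001)
    for fn in (alpha_m, beta_m, alpha_s, beta_s):
        vals = fn(v)
        assert np.all(np.isfinite(vals)) and np.all(vals >= 0)
    # removable singularity of alpha_m at V = -20.4
    near = alpha_m(np.array([-20.4 - 1e-8, -20.4, -20.4 + 1e-8]))
    assert np.max(np.abs(near - near[1])) < 1e-4


def test_rest_is_exact_equilibrium():
    m, h, p, s = gating_steady_state(FIBER.v_rest)
    assert all(0.0 < g < 1.0 for g in (m, h, p, s))
    el = leak_reversal(FIBER)
    V = FIBER.v_rest
    i_total = (FIBER.g_naf * m ** 3 * h * (V - FIBER.e_na)
               + FIBER.g_nap * p ** 3 * (V - FIBER.e_na)
               + FIBER.g_ks * s * (V - FIBER.e_k)
               + FIBER.g_leak * (V - el))
    assert i_total == pytest.approx(0.0, abs=1e-9)
    resp = simulate_axon(FIBER, ExtracellularDrive(
        np.zeros(FIBER.node_count)), t_end_ms=5.0, early_stop=False)
    assert np.abs(resp.membrane_traces - FIBER.v_rest).max() < 1e-3


def test_activating_function_shape():
    v = np.array([0.0, -1.0, -4.0, -1.0, 0.0])
    d2 = activating_function(v)
    assert d2[2] > 0          # depolarizing at the cathode
    assert d2[1] < 0 and d2[3] < 0
    assert activating_function(np.full(7, 3.0)).max() == 0.0


def test_threshold_fixed_point():
    th = threshold_search(FIBER, _focal_drive(FIBER))
    assert th.excitable
    # drive scaled by its own threshold activates at scale 1.0
    scaled = ExtracellularDrive(
        _focal_drive(FIBER).node_potentials * th.threshold_scale, 0.2)
    again = threshold_search(FIBER, scaled)
    lo, hi = again.bracket
    assert lo <= 1.0 + 0.02 and hi >= 1.0 - 0.02


def test_engines_agree_within_2_percent():
    d = _focal_drive(FIBER)
    tb = threshold_search(FIBER, d, engine="batch", rel_tol=0.005)
    ti = threshold_search(FIBER, d, engine="ivp", rel_tol=0.005)
    assert tb.threshold_scale == pytest.approx(ti.threshold_scale, rel=0.02)


def test_tolerance_refinement_stability():
    d = _focal_drive(FIBER)

    def thr(rtol, atol):
        def act(scale):
            ve = d.node_potentials * scale
            return simulate_axon(FIBER, ExtracellularDrive(ve, 0.2),
                                 rtol=rtol, atol=atol).activated
        lo, hi = 1.0, 64.0
        while hi - lo > 1e-3 * hi:
            mid = 0.5 * (lo + hi)
            if act(mid):
                hi = mid
            else:
                lo = mid
        return hi

    t1 = thr(1e-6, 1e-8)
    t2 = thr(5e-7, 5e-9)
    assert abs(t1 - t2) / t1 < 0.005


def test_early_stop_equivalence():
    d = _focal_drive(FIBER)
    th = threshold_search(FIBER, d).threshold_scale
    for scale in (0.8 * th, 1.2 * th):
        ve = d.node_potentials * scale
        a = simulate_axon(FIBER, ExtracellularDrive(ve, 0.2),
                          early_stop=True)
        b = simulate_axon(FIBER, ExtracellularDrive(ve, 0.2),
                          early_stop=False)
        assert a.activated == b.activated


def test_batch_translation_equivariance():
    n = FIBER.node_count
    base = np.zeros(n)
    base[8:13] = np.array([-2.0, -6.0, -10.0, -6.0, -2.0]) * 40.0
    act0, node0, _ = simulate_batch(FIBER, base[None, :])
    act1, node1, _ = simulate_batch(FIBER, np.roll(base, 1)[None, :])
    assert act0[0] and act1[0]
    assert node1[0] == node0[0] + 1


def test_strong_ramp_excites_only_end_nodes():
    # a steep external gradient drives the sealed terminal nodes: the
    # interior activating function of a ramp is identically zero
    z = FIBER.node_z_positions_mm()
    ramp = -100.0 * z
    assert np.abs(activating_function(ramp)[1:-1]).max() < 1e-9
    act, node, _ = simulate_batch(FIBER, ramp[None, :])
    assert act[0] and node[0] in (0, FIBER.node_count - 1)


def test_drive_mismatch_rejected():
    with pytest.raises(ValueError):
        simulate_axon(FIBER, ExtracellularDrive(np.zeros(11)))


def test_drive_from_field_outside_cord_rejected(coarse_basis):
    from cordstim.field import Montage, superpose
    cur = np.zeros(12)
    cur[[2, 3]] = -0.5
    cur[[0, 5]] = 0.5
    sol = superpose(coarse_basis, Montage(cur))
    with pytest.raises(DomainError):
        drive_from_field(sol, FIBER, (7.5, 0.0))
    d = drive_from_field(sol, FIBER, (0.0, 2.0))
    assert d.node_potentials.shape == (FIBER.node_count,)
    assert np.any(d.node_potentials != 0.0)
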