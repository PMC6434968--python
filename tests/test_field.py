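import numpy as np
import pytest

from cordstim.field import (Montage, SolverError, direct_solve, load_basis,
                            site_surface_current_density, superpose,
                            white_matter_inflow_fraction)


def _montage(n=12, scale=1.0):
    cur = np.zeros(n)
    cur[[2, 3]] = -0.5 * scale
    cur[[0, 5]] = 0.5 * scale
    return Montage(cur)


def test_unbalanced_montage_rejected():
    with pytest.raises(ValueError):
        Montage(np.ones(12))
    Montage(np.ones(12), balanced=False)  # explicit opt-out allowed


def test_resistance_diagonal_dominant_positive(coarse_basis):
    R = coarse_basis.resistance_matrix
    d = np.diag(R)
    assert np.all(d > 0)
    assert np.all(d[:, None] >= R - 1e-9)


def test_inactive_sites_float_at_nonzero_potential(coarse_basis):
    sol = superpose(coarse_basis, _montage())
    inactive = [i for i in range(12) if i not in (0, 2, 3, 5)]
    # floating sites pick up a potential but carry no prescribed current
    assert np.all(np.abs(sol.site_voltages[inactive]) > 0)


def test_superposition_linearity(coarse_basis):
    s1 = superpose(coarse_basis, _montage())
    s2 = superpose(coarse_basis, _montage(scale=3.0))
    assert np.allclose(3.0 * s1.potential, s2.potential, rtol=0, atol=1e-12)
    assert s2.power == pytest.approx(9.0 * s1.power, rel=1e-9)


def test_direct_solve_matches_superposition_tightly(coarse_basis):
    m = _montage(scale=2.5)
    sup = superpose(coarse_basis, m)
    direct = direct_solve(coarse_basis.system, m)
    ref = np.abs(direct.potential).max()
    assert np.abs(sup.potential - direct.potential).max() < 1e-8 * ref
    assert sup.power == pytest.approx(direct.power, rel=1e-8)


def test_edge_current_density_exceeds_interior(coarse_basis):
    maps, _ = site_surface_current_density(coarse_basis, _montage(scale=4.0))
    m2 = maps[2]   # active cathode
    assert m2.mean_edge_density > m2.mean_interior_density


def test_inflow_fraction_scale_invariant(coarse_basis, cond):
    f1 = white_matter_inflow_fraction(superpose(coarse_basis, _montage()),
                                      cond)
    f2 = white_matter_inflow_fraction(
        superpose(coarse_basis, _montage(scale=7.0)), cond)
    assert 0.0 < f1 < 100.0
    assert f2 == pytest.approx(f1, rel=1e-9)


def test_basis_save_load_roundtrip(tmp_path, coarse_basis, coarse_mesh, cond):
    path = tmp_path / "basis.npz"
    coarse_basis.save(str(path))
    loaded = load_basis(str(path), coarse_mesh, cond)
    assert np.allclose(loaded.resistance_matrix,
                       coarse_basis.resistance_matrix)
    assert np.allclose(loaded.potentials, coarse_basis.potentials)
    assert (tmp_path / "basis.npz.json").exists()


def test_load_basis_rejects_wrong_mesh(tmp_path, coarse_basis, geom, layout,
                                       cond):
    from cordstim.mesh import generate_mesh
    path = tmp_path / "basis.npz"
    coarse_basis.save(str(path))
    other = generate_mesh(geom, layout, resolution=0.5)
    with pytest.raises(SolverError):
        load_basis(str(path), other, cond)
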