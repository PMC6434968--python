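import numpy as np
import pytest

from cordstim.mesh import (CSF_R, GRAY, SHELL, WHITE, MeshingError,
                           analytic_region_volume, generate_mesh)


def test_region_volumes_match_analytic(geom, layout, coarse_mesh):
    for code in (GRAY, WHITE, CSF_R, SHELL):
        exact = analytic_region_volume(geom, code)
        got = coarse_mesh.region_volume(code)
        assert got == pytest.approx(exact, rel=0.12)


def test_total_volume_additive_and_resolution_independent(geom, layout,
                                                          coarse_mesh):
    fine = generate_mesh(geom, layout, resolution=0.45)
    for mesh in (coarse_mesh, fine):
        total = sum(mesh.region_volume(c) for c in (GRAY, WHITE, CSF_R, SHELL))
        exact = sum(analytic_region_volume(geom, c)
                    for c in (GRAY, WHITE, CSF_R, SHELL))
        assert total == pytest.approx(exact, rel=0.02)


def test_site_facet_areas_exact_at_all_resolutions(geom, layout, coarse_mesh):
    fine = generate_mesh(geom, layout, resolution=0.45)
    for mesh in (coarse_mesh, fine):
        for k in range(mesh.n_sites):
            assert mesh.site_facet_area(k) == pytest.approx(1.72, rel=1e-9)


def test_grid_lines_snapped_to_site_edges(layout, coarse_mesh):
    for s in layout.sites:
        x0, z0, x1, z1 = s.outline.bounds
        for x in (x0, x1):
            assert np.min(np.abs(coarse_mesh.xs - x)) < 1e-9
        for z in (z0, z1):
            assert np.min(np.abs(coarse_mesh.zs - z)) < 1e-9


def test_every_site_has_csf_facing_facets(coarse_mesh):
    for k in range(coarse_mesh.n_sites):
        ii, jj, kk, areas = coarse_mesh.site_bottom_facets(k)
        assert len(areas) > 0
        assert np.all(areas > 0)


def test_vtk_export(tmp_path, coarse_mesh):
    path = tmp_path / "mesh.vtk"
    coarse_mesh.to_vtk(str(path))
    head = path.read_text().splitlines()[:10]
    assert head[0].startswith("# vtk DataFile")
    assert any("RECTILINEAR_GRID" in ln for ln in head)


def test_too_coarse_mesh_rejected(geom, layout):
    with pytest.raises(MeshingError):
        generate_mesh(geom, layout, resolution=5.0)
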