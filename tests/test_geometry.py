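import numpy as np
import pytest
import shapely

from cordstim.geometry import (ConductivityMap, ConfigurationError,
                               CordGeometryParams, TArrayParams,
                               build_cord_geometry, dorsal_surface_y,
                               ellipse_outline, flattened_ellipse_outline,
                               place_t_array)


def test_layer_nesting(geom):
    assert geom.white_matter_outline.contains(geom.gray_matter_outline)
    assert geom.csf_outer_outline.contains(geom.white_matter_outline)
    assert geom.outer_outline.contains(geom.csf_outer_outline)


def test_csf_to_white_ratio_within_band(cond):
    assert cond.csf_to_white_radial_ratio == pytest.approx(20.0, rel=0.25)


def test_conductivity_validation():
    with pytest.raises(ValueError):
        ConductivityMap(sigma_white_radial=0.7, sigma_white_longitudinal=0.6)
    with pytest.raises(ValueError):
        ConductivityMap(sigma_csf=-1.0)


def test_invalid_protrusion_names_constraint():
    with pytest.raises(ConfigurationError) as err:
        build_cord_geometry(CordGeometryParams(substrate_protrusion=5.0))
    assert "protrusion" in str(err.value).lower()


def test_site_count_areas_and_groups(layout):
    assert layout.n_sites == 12
    for s in layout.sites:
        assert s.area == pytest.approx(1.72, rel=1e-9)
        assert s.outline.area == pytest.approx(1.72, rel=1e-9)
    assert set(layout.group_ids("CS")) == {2, 3}
    assert set(layout.tip_site_ids) == {0, 5}
    assert set(layout.stem_site_ids) == {6, 7, 8, 9, 10, 11}
    assert set(layout.cross_site_ids) == {0, 1, 2, 3, 4, 5}


def test_sites_fit_under_dura(geom, layout):
    # every site must sit inside the CSF-facing footprint of the flat plate
    for s in layout.sites:
        x_min, _, x_max, _ = s.outline.bounds
        xmax = max(abs(x_min), abs(x_max))
        assert geom.inner_dura_y(xmax) > geom.plate_bottom_y


def test_mirrored_layout_is_x_symmetric(layout):
    mir = layout.mirrored()
    for a, b in zip(layout.sites, mir.sites):
        ax0, az0, ax1, az1 = a.outline.bounds
        bx0, bz0, bx1, bz1 = b.outline.bounds
        assert ax0 == pytest.approx(-bx1)
        assert az0 == pytest.approx(bz0) and az1 == pytest.approx(bz1)


def test_dorsal_surface_midline_height(geom):
    p = geom.params
    assert geom.dorsal_white_y(0.0) == pytest.approx(p.white_b)
    assert dorsal_surface_y(0.0, p.csf_a, p.csf_b,
                            p.dorsal_flatness) == pytest.approx(p.csf_b)


def test_flattened_ellipse_flatter_than_ellipse():
    e = ellipse_outline(8.0, 5.5)
    f = flattened_ellipse_outline(8.0, 5.5, 4.0)
    # at mid-lateral x, the flattened dorsal boundary is higher (flatter top)
    y_e = dorsal_surface_y(4.0, 8.0, 5.5, 2.0)
    y_f = dorsal_surface_y(4.0, 8.0, 5.5, 4.0)
    assert y_f > y_e
    assert f.area > e.area


def test_overlapping_sites_rejected(geom):
    with pytest.raises(ConfigurationError):
        place_t_array(geom, TArrayParams(cross_pitch=1.0))
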