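"""Shared fixtures.

Session-scoped fixtures hold the expensive artifacts: a coarse basis set
for fast field/mapping tests, a large graded homogeneous box for the
analytic point-source check, and the default-resolution model plus one
calibrated depth sweep for the acceptance criteria.
"""

from __future__ import annotations

import numpy as np
import pytest

from cordstim.config import ExperimentConfig
from cordstim.field import solve_basis
from cordstim.geometry import (ConductivityMap, build_cord_geometry,
                               place_t_array)
from cordstim.mapping import build_grid
from cordstim.mesh import CSF_R, SITE_BASE, Mesh, generate_mesh
from cordstim.pipeline import build_model, charge_limited_depth, depth_sweep


@pytest.fixture(scope="session")
def geom():
    return build_cord_geometry()


@pytest.fixture(scope="session")
def layout(geom):
    return place_t_array(geom)


@pytest.fixture(scope="session")
def cond():
    return ConductivityMap()


@pytest.fixture(scope="session")
def coarse_mesh(geom, layout):
    return generate_mesh(geom, layout, resolution=0.6)


@pytest.fixture(scope="session")
def coarse_basis(coarse_mesh, cond):
    return solve_basis(coarse_mesh, cond)


def _graded_half_axis(h0: float, growth: float, extent: float) -> np.ndarray:
    edges = [0.0, h0]
    h = h0
    while edges[-1] < extent:
        h *= growth
        edges.append(edges[-1] + h)
    return np.array(edges)


@pytest.fixture(scope="session")
def homogeneous_box():
    """Large graded uniform box with a small cubic electrode (4x4x4 cells,
    1 mm) at its center; approximates an infinite homogeneous medium.

    The site must span several cells: a one-cell site carries an O(h/2r)
    half-cell discretization artifact near the conductor that never meets
    a percent-level point-source comparison at a few site-diameters.
    """
    core = [0.25 * i for i in range(13)]          # uniform 0.25 mm core
    tail = _graded_half_axis(0.25 * 1.5, 1.5, 120.0 - 3.0) + 3.0
    half = np.concatenate([core, tail[1:]])
    edges = np.concatenate([-half[::-1], half[1:]])
    n = len(edges) - 1
    region = np.full((n, n, n), CSF_R, dtype=np.int16)
    c = n // 2
    region[c - 2:c + 2, c - 2:c + 2, c - 2:c + 2] = SITE_BASE
    mesh = Mesh(xs=edges, ys=edges, zs=edges, region=region, n_sites=1)
    sigma = ConductivityMap(sigma_white_radial=1.0 - 1e-9,
                            sigma_white_longitudinal=1.0, sigma_gray=1.0,
                            sigma_csf=1.0, sigma_extradural=1.0)
    return mesh, sigma, solve_basis(mesh, sigma)


@pytest.fixture(scope="session")
def default_model():
    return build_model(ExperimentConfig())


@pytest.fixture(scope="session")
def depth_sweep_result(default_model):
    """One calibrated depth sweep at zero node-alignment offset."""
    return depth_sweep(default_model, alignment=0.0)


@pytest.fixture(scope="session")
def charge_limited_result(default_model):
    return charge_limited_depth(default_model, alignment=0.0)
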