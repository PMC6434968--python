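"""Independent reference implementations used to cross-check the solvers.

Everything here is deliberately simple and slow: closed-form expressions or
the adaptive single-axon integrator, with none of the short-cuts the
production paths use (superposition, monotonicity short-circuiting, rate
tables).  Tests compare production output against these oracles.
"""

from __future__ import annotations

import numpy as np

from .axon import DEFAULT_FIBER_CLASSES, ExtracellularDrive, FiberSpec, simulate_axon
from .mapping import (ALL_SIZES, LARGE_ONLY, MEDIAL_AND_LARGE, NONE,
                      node_potentials_at)


def point_source_potential(current_mA: float, sigma_S_per_m: float,
                           distance_mm: float | np.ndarray) -> np.ndarray:
    """Potential (V) of a point current source in an infinite homogeneous
    medium: V = I / (4 pi sigma r)."""
    r = np.asarray(distance_mm, dtype=float) * 1e-3
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    return current_mA * 1e-3 / (4.0 * np.pi * sigma_S_per_m * r)


def dipole_potential(current_mA: float, sigma_S_per_m: float,
                     source_xyz_mm, sink_xyz_mm, points_xyz_mm) -> np.ndarray:
    """Potential (V) of a source/sink pair in an infinite homogeneous medium."""
    pts = np.atleast_2d(np.asarray(points_xyz_mm, dtype=float))
    rs = np.linalg.norm(pts - np.asarray(source_xyz_mm, float), axis=1)
    rk = np.linalg.norm(pts - np.asarray(sink_xyz_mm, float), axis=1)
    return (point_source_potential(current_mA, sigma_S_per_m, rs)
            - point_source_potential(current_mA, sigma_S_per_m, rk))


def brute_force_classify(solution, points: np.ndarray,
                         fibers: tuple[FiberSpec, ...] = DEFAULT_FIBER_CLASSES,
                         stim_duration_ms: float = 0.2,
                         t_end_ms: float = 1.0,
                         alignment: float = 0.0) -> np.ndarray:
    """Classify points by simulating every fiber class with the adaptive
    integrator — no monotonicity assumption, no rate tables.

    Returns the same label codes as :func:`cordstim.mapping.scan`: each
    point is labeled by the smallest recruited class.  (Strict pointwise
    diameter nesting is not assumed — classes sample the field at different
    node spacings, so a marginal point can recruit a smaller class only.)
    """
    fibers = tuple(fibers)
    pts = np.atleast_2d(points)
    fired = np.zeros((len(fibers), len(pts)), dtype=bool)
    for k, fiber in enumerate(fibers):
        ve = node_potentials_at(solution, pts, fiber, alignment=alignment)
        for i in range(len(pts)):
            resp = simulate_axon(
                fiber, ExtracellularDrive(ve[i], stim_duration_ms),
                t_end_ms=t_end_ms)
            fired[k, i] = resp.activated
    labels = np.full(len(pts), NONE, dtype=np.int8)
    codes_small_first = (ALL_SIZES, MEDIAL_AND_LARGE, LARGE_ONLY)[:len(fibers)]
    for i in range(len(pts)):
        col = fired[:, i]
        if col.any():
            # label = breadth implied by the smallest recruited class,
            # matching cordstim.mapping.scan
            labels[i] = codes_small_first[int(np.argmax(col))]
    return labels


def montage_power_mW(resistance_matrix_ohm: np.ndarray,
                     site_currents_mA: np.ndarray) -> float:
    """Quadratic-form power I^T R I, written out long-hand."""
    I = np.asarray(site_currents_mA, float) * 1e-3
    R = np.asarray(resistance_matrix_ohm, float)
    p = 0.0
    for j in range(len(I)):
        for k in range(len(I)):
            p += I[j] * R[j, k] * I[k]
    return p * 1e3
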