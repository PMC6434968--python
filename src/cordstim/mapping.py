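"""Activation mapping: fiber recruitment over the cord cross-section.

A regular grid of candidate fiber positions covers the cord cross-section.
At every grid point a longitudinal myelinated axon of each diameter class is
centered axially under the array, driven by the extracellular potential the
montage produces along its nodes, and integrated to a binary activated /
not-activated outcome.  White-matter points are classified by which diameter
classes fire; gray-matter points provide the off-target activation
constraint used for amplitude calibration.

Recruitment is monotone in fiber diameter for the smooth fields the array
produces at the cord (larger fibers have lower thresholds), which the
scanner exploits: if the smallest class fires at a point, the larger classes
are not re-simulated there.  The brute-force oracle in
:mod:`cordstim.oracles` checks this assumption point by point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .axon import DEFAULT_FIBER_CLASSES, FiberSpec, simulate_batch

# white-matter classification codes, ordered by recruitment breadth
NONE = 0
LARGE_ONLY = 1
MEDIAL_AND_LARGE = 2
ALL_SIZES = 3

LABEL_NAMES = {NONE: "none", LARGE_ONLY: "large_only",
               MEDIAL_AND_LARGE: "medial_and_large", ALL_SIZES: "all_sizes"}


@dataclass(frozen=True)
class ActivationGrid:
    """Candidate fiber positions in the transverse plane (mm)."""
    white_points: np.ndarray     # (Mw, 2)
    gray_points: np.ndarray      # (Mg, 2)
    spacing: float

    @property
    def cell_area_mm2(self) -> float:
        return self.spacing * self.spacing


def build_grid(geometry, spacing: float = 0.1,
               gray_margin: float | None = None) -> ActivationGrid:
    """Regular point grid over the cord cross-section.

    White-matter points carry fiber classification; gray-matter points carry
    the off-target constraint.  ``gray_margin`` (mm) optionally restricts
    gray points to a band inside the gray boundary; by default all gray
    points are kept.
    """
    white = geometry.white_matter_outline
    gray = geometry.gray_matter_outline
    minx, miny, maxx, maxy = white.bounds
    xs = np.arange(np.floor(minx / spacing), np.ceil(maxx / spacing) + 1) * spacing
    ys = np.arange(np.floor(miny / spacing), np.ceil(maxy / spacing) + 1) * spacing
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    in_white = shapely.contains_xy(white, pts[:, 0], pts[:, 1])
    in_gray = shapely.contains_xy(gray, pts[:, 0], pts[:, 1])
    gray_pts = pts[in_white & in_gray]
    if gray_margin is not None:
        band = gray.boundary.buffer(gray_margin)
        keep = shapely.contains_xy(band, gray_pts[:, 0], gray_pts[:, 1])
        gray_pts = gray_pts[keep]
    return ActivationGrid(white_points=pts[in_white & ~in_gray],
                          gray_points=gray_pts, spacing=spacing)


def node_potentials_at(solution, points: np.ndarray,
                       fiber: FiberSpec, center_mm: float = 0.0,
                       alignment: float = 0.0) -> np.ndarray:
    """External potential (mV) at every node of a fiber at each point.

    Returns (M, node_count); fibers run axially, centered at ``center_mm``,
    with nodes shifted by ``alignment`` internode fractions.
    """
    pts = np.atleast_2d(points)
    z = fiber.node_z_positions_mm(center_mm, alignment)
    M, N = len(pts), len(z)
    q = np.empty((M, N, 3))
    q[:, :, 0] = pts[:, 0][:, None]
    q[:, :, 1] = pts[:, 1][:, None]
    q[:, :, 2] = z[None, :]
    return solution.interpolator(q.reshape(-1, 3)).reshape(M, N) * 1e3


@dataclass
class ActivationMap:
    grid: ActivationGrid
    labels: np.ndarray            # (Mw,) classification codes
    gray_activated: np.ndarray    # (Mg,) bool
    fibers: tuple[FiberSpec, ...]

    @property
    def any_gray(self) -> bool:
        return bool(self.gray_activated.any())

    def area_mm2(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)
                     * self.grid.cell_area_mm2)

    def cumulative_area_mm2(self, min_label: int = LARGE_ONLY) -> float:
        """Area recruited at breadth >= ``min_label`` (nested by construction)."""
        return float(np.count_nonzero(self.labels >= min_label)
                     * self.grid.cell_area_mm2)

    @property
    def total_activated_area_mm2(self) -> float:
        return self.cumulative_area_mm2(LARGE_ONLY)

    def class_areas_mm2(self) -> np.ndarray:
        """Recruited area per fiber class, smallest to largest.

        Class k's area is the cumulative region where that class fires;
        with monotone recruitment these are nested (small <= medium <=
        large).
        """
        return np.array([self.cumulative_area_mm2(ALL_SIZES),
                         self.cumulative_area_mm2(MEDIAL_AND_LARGE),
                         self.cumulative_area_mm2(LARGE_ONLY)])

    @property
    def gray_area_mm2(self) -> float:
        return float(np.count_nonzero(self.gray_activated)
                     * self.grid.cell_area_mm2)

    def summary(self) -> dict:
        return {
            "areas_mm2": {LABEL_NAMES[k]: self.area_mm2(k)
                          for k in (NONE, LARGE_ONLY, MEDIAL_AND_LARGE,
                                    ALL_SIZES)},
            "total_activated_area_mm2": self.total_activated_area_mm2,
            "gray_area_mm2": self.gray_area_mm2,
            "any_gray": self.any_gray,
        }


def scan(solution, grid: ActivationGrid,
         fibers: tuple[FiberSpec, ...] = DEFAULT_FIBER_CLASSES,
         stim_duration_ms: float = 0.2, t_end_ms: float = 1.0,
         dt_ms: float = 1e-3, short_circuit: bool = True,
         alignment: float = 0.0) -> ActivationMap:
    """Classify every grid point under the field in ``solution``.

    ``fibers`` must be ordered by diameter ascending.  With
    ``short_circuit`` enabled, points recruited by a smaller class inherit
    recruitment of all larger classes (diameter monotonicity); disabling it
    simulates every class at every point.
    """
    fibers = tuple(fibers)
    if any(fibers[i].diameter_um >= fibers[i + 1].diameter_um
           for i in range(len(fibers) - 1)):
        raise ValueError("fibers must be ordered by diameter ascending")
    Mw = len(grid.white_points)
    labels = np.full(Mw, NONE, dtype=np.int8)
    # smallest class first: firing there implies the broadest label
    codes_small_first = (ALL_SIZES, MEDIAL_AND_LARGE, LARGE_ONLY)[:len(fibers)]
    pending = np.arange(Mw)
    per_class = {}
    for fiber, code in zip(fibers, codes_small_first):
        idx = pending if short_circuit else np.arange(Mw)
        if idx.size:
            ve = node_potentials_at(solution, grid.white_points[idx], fiber,
                                    alignment=alignment)
            act, _, _ = simulate_batch(fiber, ve, stim_duration_ms,
                                       t_end_ms, dt_ms)
        else:
            act = np.zeros(0, dtype=bool)
        per_class[fiber.diameter_um] = (idx, act)
        if short_circuit:
            labels[idx[act]] = code
            pending = idx[~act]
    if not short_circuit:
        # combine independently simulated classes: the label is the breadth
        # implied by the smallest recruited class, matching the short-circuit
        # definition (differing node placement can flip a marginal point's
        # outcome for one class, so strict pointwise nesting is not assumed)
        fired = np.zeros((len(fibers), Mw), dtype=bool)
        for k, fiber in enumerate(fibers):
            idx, act = per_class[fiber.diameter_um]
            fired[k, idx] = act
        labels[:] = NONE
        for k in range(len(fibers) - 1, -1, -1):
            labels[fired[k]] = codes_small_first[k]

    gray_act = np.zeros(len(grid.gray_points), dtype=bool)
    if len(grid.gray_points):
        largest = fibers[-1]
        ve = node_potentials_at(solution, grid.gray_points, largest,
                                alignment=alignment)
        gray_act, _, _ = simulate_batch(largest, ve, stim_duration_ms,
                                        t_end_ms, dt_ms)
    return ActivationMap(grid=grid, labels=labels, gray_activated=gray_act,
                         fibers=fibers)


def any_gray_activation(solution, grid: ActivationGrid,
                        fibers: tuple[FiberSpec, ...] = DEFAULT_FIBER_CLASSES,
                        stim_duration_ms: float = 0.2, t_end_ms: float = 1.0,
                        dt_ms: float = 1e-3) -> bool:
    """Fast off-target check: does any gray-matter point fire?

    Only the largest (lowest-threshold) class is simulated, with
    early exit on the first activation.
    """
    if not len(grid.gray_points):
        return False
    largest = tuple(fibers)[-1]
    ve = node_potentials_at(solution, grid.gray_points, largest)
    act, _, _ = simulate_batch(largest, ve, stim_duration_ms, t_end_ms,
                               dt_ms, stop_on_first=True)
    return bool(act.any())


def max_activation_depth(amap: ActivationMap, geometry,
                         half_width_mm: float = 1.0,
                         min_label: int = LARGE_ONLY) -> float:
    """Deepest recruitment below the dorsal white-matter surface (mm).

    Measured over a midline column of half-width ``half_width_mm``; depth of
    a point is the local dorsal surface height minus the point's y.  Returns
    0 when nothing in the column is recruited.
    """
    pts = amap.grid.white_points
    sel = (amap.labels >= min_label) & (np.abs(pts[:, 0]) <= half_width_mm)
    if not sel.any():
        return 0.0
    x, y = pts[sel, 0], pts[sel, 1]
    depth = geometry.dorsal_white_y(x) - y
    return float(depth.max())


def mirrored_map_labels(amap: ActivationMap) -> np.ndarray:
    """Labels reindexed onto the x-mirrored grid (for symmetry checks)."""
    pts = amap.grid.white_points
    order = np.lexsort((pts[:, 1], np.round(-pts[:, 0] / amap.grid.spacing)))
    direct = np.lexsort((pts[:, 1], np.round(pts[:, 0] / amap.grid.spacing)))
    out = np.empty_like(amap.labels)
    out[direct] = amap.labels[order]
    return out
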