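"""Nonuniform rectilinear (voxel) volume mesh with tissue-region tagging.

The cord cross-section is constant along z, so the mesh is a tensor-product
grid: edge arrays ``xs``, ``ys``, ``zs`` and an integer region code per cell.
Grid lines are snapped to every electrode-site edge and to the substrate
underside, so site surfaces are represented exactly (site facet areas are
exact, not staircase approximations).  Electrode sites are one-voxel-thick
perfect-conductor films at the bottom of the non-conductive substrate slab.

Region codes: 0 outside (grounded exterior), 1 gray, 2 white, 3 CSF,
4 dura/extradural shell, 5 substrate (non-conductive), 10+k site k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .geometry import CordGeometry, TArrayLayout

OUTSIDE, GRAY, WHITE, CSF_R, SHELL, SUBSTRATE = 0, 1, 2, 3, 4, 5
SITE_BASE = 10
REGION_NAMES = {OUTSIDE: "outside", GRAY: "gray", WHITE: "white",
                CSF_R: "csf", SHELL: "extradural", SUBSTRATE: "substrate"}


class MeshingError(ValueError):
    pass


def _fill_interval(a: float, b: float, h: float) -> np.ndarray:
    """Uniform edge coordinates from a to b at spacing <= h (excludes a)."""
    n = max(1, int(np.ceil((b - a) / h - 1e-9)))
    return a + (b - a) * np.arange(1, n + 1) / n


def graded_axis(breakpoints: list[float], h_of_x) -> np.ndarray:
    """Edge array through all ``breakpoints`` with local target spacing.

    ``h_of_x`` maps an interval midpoint to the target edge length there.
    Every breakpoint is an exact grid line (used to snap site edges).
    """
    bps = np.unique(np.asarray(breakpoints, dtype=float))
    edges = [bps[0]]
    for a, b in zip(bps[:-1], bps[1:]):
        if b - a < 1e-9:
            continue
        edges.extend(_fill_interval(a, b, float(h_of_x(0.5 * (a + b)))))
    return np.asarray(edges)


@dataclass
class Mesh:
    """Tagged rectilinear volume mesh."""
    xs: np.ndarray                 # x edge coordinates, mm  (nx+1)
    ys: np.ndarray                 # y edge coordinates, mm  (ny+1)
    zs: np.ndarray                 # z edge coordinates, mm  (nz+1)
    region: np.ndarray             # (nx, ny, nz) int16 region codes
    n_sites: int = 0
    geometry: CordGeometry | None = None
    layout: TArrayLayout | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, e in (("xs", self.xs), ("ys", self.ys), ("zs", self.zs)):
            if np.any(np.diff(e) <= 0.0):
                raise MeshingError(f"{name} edges must be strictly increasing")
        if self.region.shape != self.shape:
            raise MeshingError("region array shape does not match grid")

    # -- basic grid quantities ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.xs) - 1, len(self.ys) - 1, len(self.zs) - 1)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (0.5 * (self.xs[:-1] + self.xs[1:]),
                0.5 * (self.ys[:-1] + self.ys[1:]),
                0.5 * (self.zs[:-1] + self.zs[1:]))

    @property
    def widths(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (np.diff(self.xs), np.diff(self.ys), np.diff(self.zs))

    def cell_volumes(self) -> np.ndarray:
        hx, hy, hz = self.widths
        return hx[:, None, None] * hy[None, :, None] * hz[None, None, :]

    # -- region queries -------------------------------------------------------
    def site_code(self, k: int) -> int:
        return SITE_BASE + k

    def region_volume(self, code: int) -> float:
        """Total volume (mm^3) of cells carrying ``code``."""
        return float(self.cell_volumes()[self.region == code].sum())

    def site_cell_count(self, k: int) -> int:
        return int((self.region == self.site_code(k)).sum())

    def site_bottom_facets(self, k: int):
        """Facets of site k facing the CSF below (the stimulating surface).

        Returns (i, j, kz, area_mm2) arrays for cells of site k whose -y
        neighbor is CSF; the facet lies on the shared y grid line.
        """
        code = self.site_code(k)
        ii, jj, kk = np.nonzero(self.region == code)
        keep = (jj > 0) & (self.region[ii, np.maximum(jj - 1, 0), kk] == CSF_R)
        ii, jj, kk = ii[keep], jj[keep], kk[keep]
        hx, _, hz = self.widths
        areas = hx[ii] * hz[kk]
        return ii, jj, kk, areas

    def site_facet_area(self, k: int) -> float:
        """Stimulating-surface area of site k in mm^2."""
        return float(self.site_bottom_facets(k)[3].sum())

    # -- export ---------------------------------------------------------------
    def to_vtk(self, path: str, cell_data: dict | None = None) -> None:
        """Write the mesh (and optional per-cell fields) as legacy ASCII VTK."""
        nx, ny, nz = self.shape
        data = {"region": self.region.astype(float)}
        data.update(cell_data or {})
        with open(path, "w") as f:
            f.write("# vtk DataFile Version 3.0\ncordstim mesh\nASCII\n")
            f.write("DATASET RECTILINEAR_GRID\n")
            f.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
            for name, arr in (("X", self.xs), ("Y", self.ys), ("Z", self.zs)):
                f.write(f"{name}_COORDINATES {len(arr)} float\n")
                f.write(" ".join(f"{v:.6g}" for v in arr) + "\n")
            f.write(f"CELL_DATA {self.n_cells}\n")
            for name, arr in data.items():
                f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                flat = np.asarray(arr).transpose(2, 1, 0).ravel()
                f.write("\n".join(f"{v:.6g}" for v in flat) + "\n")


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

def _cross_section_codes(geom: CordGeometry, cx: np.ndarray,
                         cy: np.ndarray) -> np.ndarray:
    """Region code for every (x, y) cell center, before substrate overrides."""
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    pts_x, pts_y = X.ravel(), Y.ravel()
    code = np.zeros(pts_x.shape, dtype=np.int16)
    inside_outer = shapely.contains_xy(geom.outer_outline, pts_x, pts_y)
    code[inside_outer] = SHELL
    inside_csf = shapely.contains_xy(geom.csf_outer_outline, pts_x, pts_y)
    code[inside_csf] = CSF_R
    inside_white = shapely.contains_xy(geom.white_matter_outline, pts_x, pts_y)
    code[inside_white] = WHITE
    inside_gray = shapely.contains_xy(geom.gray_matter_outline, pts_x, pts_y)
    code[inside_gray] = GRAY
    return code.reshape(len(cx), len(cy))


def generate_mesh(geom: CordGeometry, layout: TArrayLayout | None = None,
                  resolution: float = 0.3) -> Mesh:
    """Voxelize the extruded cord geometry with the array in place.

    ``resolution`` is the target in-plane edge length (mm) near the array;
    spacing grades coarser with distance from the electrode region and
    toward the end caps.  Grid lines are snapped to all site edges and to
    the substrate underside.
    """
    if not resolution > 0.0:
        raise MeshingError("resolution must be positive")
    p = geom.params
    h = resolution
    y_plate = geom.plate_bottom_y
    film = min(0.15, 0.5 * geom.substrate_protrusion)

    outer_a = p.csf_a + p.dura_thickness
    outer_b = p.csf_b + p.dura_thickness
    pad = 0.4
    x_bp = [-outer_a - pad, outer_a + pad]
    z_half = p.segment_length / 2.0
    z_bp = [-z_half, z_half]
    y_bp = [-outer_b - pad, outer_b + pad, y_plate, y_plate + film]

    site_x_lo, site_x_hi = [], []
    if layout is not None:
        for s in layout.sites:
            x0, z0, x1, z1 = s.outline.bounds
            x_bp += [x0, x1]
            z_bp += [z0, z1]
            site_x_lo.append(x0); site_x_hi.append(x1)
        fx0, fz0, fx1, fz1 = layout.footprint.bounds
        x_bp += [fx0, fx1]
        z_bp += [fz0, fz1]

    arr_x = max((abs(v) for v in x_bp[2:]), default=4.5) if layout else 4.5
    arr_z_lo = min(z_bp[2:], default=-1.0) - 0.5 if layout else -1.0
    arr_z_hi = max(z_bp[2:], default=1.0) + 0.5 if layout else 1.0

    def hx(x):
        return h if abs(x) <= arr_x + 0.5 else min(3 * h, h + 0.35 * (abs(x) - arr_x))

    def hy(y):
        return h if 0.5 <= y <= y_plate + 0.5 else min(2.0 * h, 1.5 * h)

    def hz(z):
        if arr_z_lo <= z <= arr_z_hi:
            return 1.2 * h
        d = min(abs(z - arr_z_lo), abs(z - arr_z_hi))
        return min(12 * h, 1.2 * h + 0.28 * d)

    # intermediate breakpoints so spacing grades smoothly away from the array
    for d in (1.0, 2.5):
        for sgn in (-1.0, 1.0):
            x_bp.append(sgn * min(arr_x + d, outer_a + pad))
    for d in (1.0, 2.5, 5.0, 9.0, 15.0, 24.0):
        z_bp.append(max(arr_z_lo - d, -z_half))
        z_bp.append(min(arr_z_hi + d, z_half))

    xs = graded_axis(x_bp, hx)
    ys = graded_axis(y_bp, hy)
    zs = graded_axis(z_bp, hz)

    cx, cy, cz = (0.5 * (e[:-1] + e[1:]) for e in (xs, ys, zs))
    sec = _cross_section_codes(geom, cx, cy)           # (nx, ny)
    region = np.repeat(sec[:, :, None], len(cz), axis=2).astype(np.int16)

    if layout is not None:
        # substrate slab: between the plate underside and the inner dura,
        # over the T footprint, replacing CSF/shell cells only
        Xf, Zf = np.meshgrid(cx, cz, indexing="ij")
        in_fp = shapely.contains_xy(layout.footprint, Xf.ravel(), Zf.ravel())
        in_fp = in_fp.reshape(len(cx), len(cz))
        dura_y = geom.inner_dura_y(cx)                  # (nx,)
        y_ok = (cy[None, :] > y_plate) & (cy[None, :] < dura_y[:, None] + p.dura_thickness * 0.5)
        slab = in_fp[:, None, :] & y_ok[:, :, None]
        replace = np.isin(region, (CSF_R, SHELL))
        region[slab & replace] = SUBSTRATE

        # site films: first cell layer above the plate underside
        j_film = int(np.argmin(np.abs(ys - y_plate)))  # cell just above plate
        for s in layout.sites:
            x0, z0, x1, z1 = s.outline.bounds
            isel = (cx > x0) & (cx < x1)
            ksel = (cz > z0) & (cz < z1)
            blk = region[np.ix_(isel, [j_film], ksel)]
            if blk.size == 0:
                raise MeshingError(f"site {s.id} received no cells")
            region[np.ix_(isel, [j_film], ksel)] = SITE_BASE + s.id

    mesh = Mesh(xs, ys, zs, region,
                n_sites=(layout.n_sites if layout is not None else 0),
                geometry=geom, layout=layout,
                meta={"resolution": resolution})
    if layout is not None:
        for s in layout.sites:
            if mesh.site_cell_count(s.id) == 0:
                raise MeshingError(f"site {s.id} has no tagged cells")
            if mesh.site_bottom_facets(s.id)[3].size == 0:
                raise MeshingError(f"site {s.id} has no CSF-facing facets")
    return mesh


def analytic_region_volume(geom: CordGeometry, code: int) -> float:
    """Closed-form volume (mm^3) of an extruded tissue layer (no substrate)."""
    L = geom.segment_length
    g = geom.gray_matter_outline.area
    w = geom.white_matter_outline.area
    c = geom.csf_outer_outline.area
    o = geom.outer_outline.area
    return {GRAY: g, WHITE: w - g, CSF_R: c - w, SHELL: o - c}[code] * L
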