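"""Quasi-static volume-conductor solver and montage superposition.

Solves the continuity equation (zero charge creation) ``div(sigma grad V) = 0``
on the tagged voxel mesh by a cell-centered finite-volume discretization:
two-point flux with harmonic (series half-cell) face conductances, which
handles the anisotropic white-matter tensor exactly because the tensor axes
align with the grid.  Electrode sites are perfect-conductor supernodes with a
prescribed *total* current (the classic terminal constraint): the current
distribution over a site is then set by the surrounding electrical
environment and concentrates at the site edges.  Inactive sites float as
equipotential surfaces with zero net current.  The outer shell surface and
the end caps are held at 0 V.

Units: lengths mm (converted to SI inside the assembly), conductivities S/m,
currents A internally (montages expressed in mA at the API), potentials V.
The per-site basis fields are computed for a unit current of 1 mA, and any
montage field is the superposition of basis fields scaled by site currents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from . import mesh as meshmod
from .geometry import ConductivityMap
from .mesh import CSF_R, GRAY, OUTSIDE, SHELL, SITE_BASE, SUBSTRATE, WHITE, Mesh

GROUND_TAGS = ("outer_ground", "end_caps")


class SolverError(RuntimeError):
    pass


def _sigma_table(cond: ConductivityMap, n_sites: int) -> np.ndarray:
    """Per-region (sigma_x, sigma_y, sigma_z) lookup, S/m.

    ``inf`` marks perfect conductors (grounded exterior, metal sites) and
    0 marks the non-conductive substrate.
    """
    t = np.zeros((SITE_BASE + max(n_sites, 1), 3))
    t[OUTSIDE] = np.inf
    t[GRAY] = cond.sigma_gray
    t[WHITE] = (cond.sigma_white_radial, cond.sigma_white_radial,
                cond.sigma_white_longitudinal)
    t[CSF_R] = cond.sigma_csf
    t[SHELL] = cond.sigma_extradural
    t[SUBSTRATE] = 0.0
    t[SITE_BASE:SITE_BASE + n_sites] = np.inf
    return t


@dataclass
class AssembledSystem:
    """Discrete operator, unknown numbering, and reusable linear solver."""
    mesh: Mesh
    cond: ConductivityMap
    matrix: sp.csr_matrix
    idx: np.ndarray                   # cell -> unknown id (-1 excluded, -2 ground)
    n_tissue: int
    n_sites: int
    ground_idx: np.ndarray            # unknown ids with a ground face
    ground_g: np.ndarray              # face conductances (S)
    ground_tag: np.ndarray            # 0 outer_ground, 1 end_caps
    solver_meta: dict = field(default_factory=dict)
    _solve: object = None

    @property
    def n_unknowns(self) -> int:
        return self.n_tissue + self.n_sites

    def site_unknown(self, k: int) -> int:
        return self.n_tissue + k

    def _make_solver(self):
        # sparse direct factorization: exact to machine precision, reused
        # across all 12 basis right-hand sides
        if self._solve is not None:
            return self._solve
        lu = spla.splu(self.matrix.tocsc())
        self.solver_meta.update(method="splu", tolerance=0.0)
        self._solve = lu.solve
        return self._solve

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return self._make_solver()(rhs)

    def release_solver(self) -> None:
        """Drop the (memory-heavy) factorization; it is rebuilt on demand."""
        self._solve = None

    def potential_grid(self, v: np.ndarray) -> np.ndarray:
        """Scatter the unknown vector onto the full cell grid (V); excluded
        and grounded cells read 0."""
        grid = np.zeros(self.mesh.shape)
        m = self.idx >= 0
        grid[m] = v[self.idx[m]]
        return grid

    def boundary_currents(self, v: np.ndarray) -> dict[str, float]:
        """Net current (A) leaving through each grounded boundary."""
        cur = self.ground_g * v[self.ground_idx]
        return {tag: float(cur[self.ground_tag == i].sum())
                for i, tag in enumerate(GROUND_TAGS)}


def assemble(mesh: Mesh, cond: ConductivityMap,
             solver_opts: dict | None = None) -> AssembledSystem:
    """Assemble the finite-volume operator for the tagged mesh."""
    region = mesh.region
    shape = mesh.shape
    n_sites = mesh.n_sites
    sig = _sigma_table(cond, n_sites)[region]        # (nx,ny,nz,3)
    widths = mesh.widths

    # half-cell series resistance per unit area, per axis (ohm*m^2)
    Rh = []
    for ax in range(3):
        h = widths[ax].reshape([-1 if a == ax else 1 for a in range(3)])
        s = sig[..., ax]
        r = np.empty(shape)
        with np.errstate(divide="ignore"):
            r = (h * 0.5e-3) / s
        r[np.isinf(s)] = 0.0
        r[s == 0.0] = np.inf
        Rh.append(r)

    tissue = np.isin(region, (GRAY, WHITE, CSF_R, SHELL))
    idx = np.full(shape, -1, dtype=np.int64)
    idx[region == OUTSIDE] = -2
    nt = int(tissue.sum())
    idx[tissue] = np.arange(nt)
    for k in range(n_sites):
        idx[region == SITE_BASE + k] = nt + k
    n = nt + n_sites

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    g_idx, g_g, g_tag = [], [], []

    def face_areas(ax):
        # cross-sectional area (m^2) of faces normal to ax, broadcast shape
        other = [a for a in range(3) if a != ax]
        A = np.multiply.outer(widths[other[0]], widths[other[1]]) * 1e-6
        sh = [1, 1, 1]
        sh[other[0]] = len(widths[other[0]])
        sh[other[1]] = len(widths[other[1]])
        return A.reshape(sh)

    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        a, b = idx[tuple(sl_a)], idx[tuple(sl_b)]
        denom = Rh[ax][tuple(sl_a)] + Rh[ax][tuple(sl_b)]
        A = np.broadcast_to(face_areas(ax), a.shape)
        with np.errstate(divide="ignore"):
            g = A / denom
        both = (a >= 0) & (b >= 0) & (a != b)
        if np.any(both & np.isinf(g)):
            raise SolverError("adjacent distinct conductor regions (infinite "
                              "face conductance)")
        conn = both & (g > 0) & np.isfinite(g)
        ia, ib, gg = a[conn], b[conn], g[conn]
        rows.extend([ia, ib]); cols.extend([ib, ia]); vals.extend([-gg, -gg])
        np.add.at(diag, ia, gg)
        np.add.at(diag, ib, gg)

        # faces between an unknown and the grounded exterior region
        for u, o in ((a, b), (b, a)):
            gc = (u >= 0) & (o == -2) & (g > 0) & np.isfinite(g)
            if np.any(gc):
                np.add.at(diag, u[gc], g[gc])
                g_idx.append(u[gc]); g_g.append(g[gc])
                g_tag.append(np.zeros(int(gc.sum()), dtype=np.int8))

        # domain-boundary faces (half-cell conductance to 0 V)
        for side, z_end in ((0, False), (-1, True)):
            sl = [slice(None)] * 3
            sl[ax] = side
            u = idx[tuple(sl)]
            r = Rh[ax][tuple(sl)]
            A2 = np.broadcast_to(face_areas(ax), idx.shape)[tuple(sl)]
            with np.errstate(divide="ignore"):
                gb = A2 / r
            keep = (u >= 0) & (gb > 0) & np.isfinite(gb)
            if np.any(keep):
                np.add.at(diag, u[keep], gb[keep])
                g_idx.append(u[keep]); g_g.append(gb[keep])
                tag = 1 if ax == 2 else 0
                g_tag.append(np.full(int(keep.sum()), tag, dtype=np.int8))

    if not g_idx:
        raise SolverError("singular system: no grounded boundary")

    rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
    A = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n)).tocsr()
    return AssembledSystem(
        mesh=mesh, cond=cond, matrix=A, idx=idx, n_tissue=nt, n_sites=n_sites,
        ground_idx=np.concatenate(g_idx), ground_g=np.concatenate(g_g),
        ground_tag=np.concatenate(g_tag),
        solver_meta=dict(solver_opts or {}))


# ---------------------------------------------------------------------------
# basis set and superposition
# ---------------------------------------------------------------------------

UNIT_CURRENT_A = 1e-3   # basis fields are solved for 1 mA per site


@dataclass
class BasisSet:
    """Per-site unit-current (1 mA) potential fields and mutual resistances.

    ``resistance_matrix`` is in ohms: R[j, k] is the voltage on site j per
    ampere on site k.  By reciprocity of the (symmetric) discrete operator it
    is symmetric to solver tolerance, and passive (positive definite).
    """
    mesh: Mesh
    cond: ConductivityMap
    potentials: np.ndarray            # (n_sites, nx, ny, nz), V per 1 mA
    resistance_matrix: np.ndarray     # (n_sites, n_sites), ohm
    boundary_per_site: dict[str, np.ndarray]   # tag -> (n_sites,) A per 1 mA
    system: AssembledSystem | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.potentials.shape[0]

    @property
    def site_voltage_matrix_mV_per_mA(self) -> np.ndarray:
        """R expressed as mV per mA (numerically equal to ohms / 1000 * 1000,
        i.e. the same numbers as ohms; exposed for unit-explicit reporting)."""
        return self.resistance_matrix * 1e3 * 1e-3

    def save(self, path: str) -> None:
        import json
        np.savez_compressed(
            path, potentials=self.potentials, R=self.resistance_matrix,
            **{f"boundary_{k}": v for k, v in self.boundary_per_site.items()})
        sidecar = {
            "n_sites": int(self.n_sites),
            "conductivities": {k: float(v) for k, v in vars(self.cond).items()},
            "solver": {k: v for k, v in self.meta.items()
                       if isinstance(v, (int, float, str))},
        }
        with open(str(path) + ".json", "w") as f:
            json.dump(sidecar, f, indent=2)


def load_basis(path: str, mesh: Mesh, cond: ConductivityMap) -> BasisSet:
    """Load a basis saved by :meth:`BasisSet.save`.

    The mesh and conductivities are not stored in the archive; the caller
    must rebuild the same mesh (generation is deterministic for a given
    configuration).  A shape mismatch is rejected.
    """
    with np.load(path) as data:
        pots = data["potentials"]
        R = data["R"]
        boundary = {k[len("boundary_"):]: data[k]
                    for k in data.files if k.startswith("boundary_")}
    if pots.shape[1:] != mesh.shape:
        raise SolverError(
            f"basis grid {pots.shape[1:]} does not match mesh {mesh.shape}")
    return BasisSet(mesh=mesh, cond=cond, potentials=pots,
                    resistance_matrix=R, boundary_per_site=boundary)


def solve_basis(mesh: Mesh, cond: ConductivityMap,
                solver_opts: dict | None = None,
                keep_factorization: bool = False) -> BasisSet:
    """Solve the 12 unit-current basis problems and assemble R.

    Each site k is excited alone with 1 mA while the other sites carry zero
    net current (floating equipotentials); the grounded boundaries absorb the
    return current.
    """
    sys_ = assemble(mesh, cond, solver_opts)
    ns = sys_.n_sites
    if ns == 0:
        raise SolverError("mesh has no electrode sites")
    pots = np.empty((ns,) + mesh.shape)
    R = np.empty((ns, ns))
    boundary = {tag: np.empty(ns) for tag in GROUND_TAGS}
    for k in range(ns):
        rhs = np.zeros(sys_.n_unknowns)
        rhs[sys_.site_unknown(k)] = UNIT_CURRENT_A
        v = sys_.solve(rhs)
        pots[k] = sys_.potential_grid(v)
        R[:, k] = v[sys_.n_tissue:] / UNIT_CURRENT_A
        for tag, cur in sys_.boundary_currents(v).items():
            boundary[tag][k] = cur
    if not keep_factorization:
        sys_.release_solver()
    return BasisSet(mesh=mesh, cond=cond, potentials=pots,
                    resistance_matrix=R, boundary_per_site=boundary,
                    system=sys_, meta=dict(sys_.solver_meta))


@dataclass(frozen=True)
class Montage:
    """Vector of simultaneous per-site currents (mA, cathodic negative)."""
    site_currents: np.ndarray
    balanced: bool = True

    def __post_init__(self):
        c = np.asarray(self.site_currents, dtype=float)
        object.__setattr__(self, "site_currents", c)
        if self.balanced and abs(c.sum()) > 1e-9:
            raise ValueError(
                f"montage marked balanced but currents sum to {c.sum()} mA")

    def scaled(self, alpha: float) -> "Montage":
        return Montage(self.site_currents * alpha, self.balanced)

    def mirrored(self, layout) -> "Montage":
        """Currents remapped under the left<->right mirror of the layout."""
        cur = np.array(self.site_currents)
        out = np.empty_like(cur)
        centers = {s.id: s.center for s in layout.sites}
        for sid, (x, z) in centers.items():
            target = next(t for t, (x2, z2) in centers.items()
                          if abs(x2 + x) < 1e-9 and abs(z2 - z) < 1e-9)
            out[target] = cur[sid]
        return Montage(out, self.balanced)

    @property
    def total_cathodic_mA(self) -> float:
        c = self.site_currents
        return float(-c[c < 0].sum())


@dataclass
class FieldSolution:
    """A montage field: potential grid, site voltages, power, and audits."""
    mesh: Mesh
    potential: np.ndarray             # (nx, ny, nz) V
    site_currents: np.ndarray         # mA
    site_voltages: np.ndarray         # V
    power: float                      # W
    boundary_currents: dict[str, float] | None = None

    @property
    def power_mW(self) -> float:
        return self.power * 1e3

    @cached_property
    def interpolator(self) -> RegularGridInterpolator:
        cx, cy, cz = self.mesh.centers
        return RegularGridInterpolator((cx, cy, cz), self.potential,
                                       bounds_error=False, fill_value=0.0)

    def sample_line(self, point_xy: tuple[float, float],
                    z_positions: np.ndarray) -> np.ndarray:
        """Potential (V) along the axial line through ``point_xy``."""
        z = np.asarray(z_positions, dtype=float)
        pts = np.column_stack([np.full(z.shape, point_xy[0]),
                               np.full(z.shape, point_xy[1]), z])
        return self.interpolator(pts)


def superpose(basis: BasisSet, montage: Montage) -> FieldSolution:
    """Reconstruct the montage field as sum_k I_k * V_k.

    Site voltages follow as R I and power as the quadratic form I^T R I
    (power therefore scales with the square of any overall montage scale).
    """
    I_mA = np.asarray(montage.site_currents, dtype=float)
    if I_mA.shape[0] != basis.n_sites:
        raise ValueError("montage length does not match basis set")
    I_A = I_mA * 1e-3
    grid = np.tensordot(I_mA, basis.potentials, axes=(0, 0))
    v_sites = basis.resistance_matrix @ I_A
    power = float(I_A @ v_sites)
    boundary = {tag: float(per_site @ I_mA)
                for tag, per_site in basis.boundary_per_site.items()}
    return FieldSolution(mesh=basis.mesh, potential=grid,
                         site_currents=I_mA, site_voltages=v_sites,
                         power=power, boundary_currents=boundary)


def direct_solve(system: AssembledSystem, montage: Montage) -> FieldSolution:
    """Solve the full multi-site problem in one shot (superposition oracle)."""
    I_A = np.asarray(montage.site_currents, dtype=float) * 1e-3
    rhs = np.zeros(system.n_unknowns)
    rhs[system.n_tissue:] = I_A
    v = system.solve(rhs)
    v_sites = v[system.n_tissue:]
    return FieldSolution(mesh=system.mesh, potential=system.potential_grid(v),
                         site_currents=np.asarray(montage.site_currents),
                         site_voltages=v_sites,
                         power=float(I_A @ v_sites),
                         boundary_currents=system.boundary_currents(v))


# ---------------------------------------------------------------------------
# surface current densities and white-matter inflow
# ---------------------------------------------------------------------------

def _region_interface_faces(mesh: Mesh, cond: ConductivityMap,
                            code_a: int, code_b) -> list[tuple]:
    """Faces between cells of region ``code_a`` and neighbor regions
    ``code_b`` (int or set). Yields (cell_a multi-index, cell_b multi-index,
    axis, area_mm2)."""
    wanted = {code_b} if np.isscalar(code_b) else set(code_b)
    region = mesh.region
    widths = mesh.widths
    out = []
    for ax in range(3):
        other = [a for a in range(3) if a != ax]
        A2 = np.multiply.outer(widths[other[0]], widths[other[1]])
        sh = [1, 1, 1]
        sh[other[0]] = A2.shape[0]
        sh[other[1]] = A2.shape[1]
        A2 = np.broadcast_to(A2.reshape(sh), mesh.shape)
        sl_a = [slice(None)] * 3; sl_a[ax] = slice(None, -1)
        sl_b = [slice(None)] * 3; sl_b[ax] = slice(1, None)
        ra, rb = region[tuple(sl_a)], region[tuple(sl_b)]
        for flip in (False, True):
            src, dst = (ra, rb) if not flip else (rb, ra)
            hit = (src == code_a) & np.isin(dst, list(wanted))
            if not np.any(hit):
                continue
            ia = np.array(np.nonzero(hit)).T
            a_cells = ia.copy(); b_cells = ia.copy()
            if not flip:
                b_cells[:, ax] += 1
            else:
                a_cells[:, ax] += 1
            areas = A2[tuple(sl_a)][hit]
            out.append((a_cells, b_cells, ax, areas))
    return out


def _face_conductance(mesh: Mesh, cond: ConductivityMap, a_cells, b_cells,
                      ax, areas_mm2) -> np.ndarray:
    sig = _sigma_table(cond, mesh.n_sites)[mesh.region]
    widths = mesh.widths

    def half_r(cells):
        h = widths[ax][cells[:, ax]]
        s = sig[cells[:, 0], cells[:, 1], cells[:, 2], ax]
        with np.errstate(divide="ignore"):
            r = (h * 0.5e-3) / s
        r[np.isinf(s)] = 0.0
        return r
    return areas_mm2 * 1e-6 / (half_r(a_cells) + half_r(b_cells))


def white_matter_inflow_fraction(solution: FieldSolution,
                                 cond: ConductivityMap) -> float:
    """Percentage of the total cathodic site current entering the white
    matter through the pial (white/CSF) surface.

    Because of the shunting effect of the highly conductive CSF, this
    fraction is small; it is invariant to an overall montage scale.
    """
    mesh = solution.mesh
    total_cath = Montage(solution.site_currents,
                         balanced=False).total_cathodic_mA * 1e-3
    if total_cath == 0.0:
        return 0.0
    V = solution.potential
    inflow = 0.0
    for a_cells, b_cells, ax, areas in _region_interface_faces(
            mesh, cond, WHITE, CSF_R):
        g = _face_conductance(mesh, cond, a_cells, b_cells, ax, areas)
        va = V[a_cells[:, 0], a_cells[:, 1], a_cells[:, 2]]
        vb = V[b_cells[:, 0], b_cells[:, 1], b_cells[:, 2]]
        cur = g * (vb - va)          # positive = into the white-matter cell
        inflow += float(cur[cur > 0].sum())
    return 100.0 * inflow / total_cath


@dataclass
class SiteCurrentMap:
    site_id: int
    facet_centers: np.ndarray      # (n, 3) mm
    density: np.ndarray            # mA/cm^2, positive out of the site
    areas: np.ndarray              # mm^2
    is_edge: np.ndarray            # facet on the site-rectangle perimeter

    @property
    def mean_edge_density(self) -> float:
        d = np.abs(self.density[self.is_edge])
        return float(d.mean()) if d.size else 0.0

    @property
    def mean_interior_density(self) -> float:
        d = np.abs(self.density[~self.is_edge])
        return float(d.mean()) if d.size else 0.0


def site_surface_current_density(basis: BasisSet, montage: Montage
                                 ) -> tuple[list[SiteCurrentMap], dict]:
    """Per-site facet current densities and the pial inflow map.

    The equipotential-site boundary condition concentrates current on the
    site edges relative to the interior (the primary distribution of a disc
    electrode diverges at the rim).  Densities are per-facet averages in
    mA/cm^2 at the instant the cathodic phase starts.
    """
    mesh, cond = basis.mesh, basis.cond
    sol = superpose(basis, montage)
    v_site = sol.site_voltages
    V = sol.potential
    cx, cy, cz = mesh.centers
    hx, hy, hz = mesh.widths
    maps = []
    for k in range(basis.n_sites):
        ii, jj, kk, areas = mesh.site_bottom_facets(k)
        if ii.size == 0:
            maps.append(SiteCurrentMap(k, np.empty((0, 3)), np.empty(0),
                                       areas, np.empty(0, bool)))
            continue
        sig_csf = cond.sigma_csf
        g = areas * 1e-6 / ((hy[jj - 1] * 0.5e-3) / sig_csf)
        v_below = V[ii, jj - 1, kk]
        cur = g * (v_site[k] - v_below)               # A out of site
        dens = (cur / (areas * 1e-6)) * 0.1           # A/m^2 -> mA/cm^2
        # edge facets: on the perimeter of the site's (i, k) cell footprint
        iset = set(zip(ii.tolist(), kk.tolist()))
        is_edge = np.array([
            any((i + di, k2 + dk) not in iset
                for di, dk in ((1, 0), (-1, 0), (0, 1), (0, -1)))
            for i, k2 in zip(ii.tolist(), kk.tolist())])
        centers = np.column_stack([cx[ii], np.full(ii.shape, mesh.ys[jj[0]]),
                                   cz[kk]])
        maps.append(SiteCurrentMap(k, centers, dens, areas, is_edge))

    # pial inflow map: normal current density entering the white matter
    pial = {"centers": [], "density": []}
    for a_cells, b_cells, ax, areas in _region_interface_faces(
            mesh, cond, WHITE, CSF_R):
        g = _face_conductance(mesh, cond, a_cells, b_cells, ax, areas)
        va = V[a_cells[:, 0], a_cells[:, 1], a_cells[:, 2]]
        vb = V[b_cells[:, 0], b_cells[:, 1], b_cells[:, 2]]
        cur = g * (vb - va)
        dens = cur / (areas * 1e-6) * 0.1
        ctr = np.column_stack([cx[a_cells[:, 0]], cy[a_cells[:, 1]],
                               cz[a_cells[:, 2]]])
        pial["centers"].append(ctr)
        pial["density"].append(dens)
    pial = {"centers": (np.vstack(pial["centers"]) if pial["centers"]
                        else np.empty((0, 3))),
            "density": (np.concatenate(pial["density"]) if pial["density"]
                        else np.empty(0))}
    return maps, pial
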