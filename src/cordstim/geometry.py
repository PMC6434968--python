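"""Parametric cord cross-section, tissue conductivities, and T-array placement.

The model is an idealized thoracic (T8-T10) spinal cord segment: a gray-matter
"butterfly" core inside an elliptical white-matter boundary, surrounded by CSF,
all wrapped in a single merged dura + extradural low-conductivity shell that is
grounded on its outer surface.  The stimulator is a flat, non-conductive
substrate clamped to the dorsal dura whose underside (carrying 12 electrode
sites) projects ``substrate_protrusion`` millimetres below the inner dural
surface into the CSF.

Coordinate convention (all lengths mm):
    x  lateral, positive right
    y  dorsoventral, positive dorsal
    z  along the cord axis, origin mid-segment at the center of the T cross
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import Polygon, box
from shapely.ops import unary_union


class ConfigurationError(ValueError):
    """Raised when a geometry/layout configuration violates a model constraint."""


# ---------------------------------------------------------------------------
# outline helpers
# ---------------------------------------------------------------------------

def ellipse_outline(a: float, b: float, n: int = 256,
                    center: tuple[float, float] = (0.0, 0.0)) -> Polygon:
    """Closed elliptical outline with semi-axes ``a`` (x) and ``b`` (y)."""
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    x = center[0] + a * np.cos(t)
    y = center[1] + b * np.sin(t)
    return Polygon(np.column_stack([x, y]))


def flattened_ellipse_outline(a: float, b: float, dorsal_exponent: float = 4.0,
                              n: int = 256) -> Polygon:
    """Ellipse whose dorsal half (y > 0) is a superellipse of given exponent.

    Models the dorsal dural sac flattened locally by the clamped electrode
    plate; exponent 2 recovers a plain ellipse.  The curve is continuous at
    y = 0 (both halves pass through (+-a, 0)).
    """
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    c, s = np.cos(t), np.sin(t)
    p = np.where(s >= 0.0, dorsal_exponent, 2.0)
    x = a * np.sign(c) * np.abs(c) ** (2.0 / p)
    y = b * np.sign(s) * np.abs(s) ** (2.0 / p)
    return Polygon(np.column_stack([x, y]))


def dorsal_surface_y(x: np.ndarray | float, a: float, b: float,
                     exponent: float = 2.0) -> np.ndarray | float:
    """Height of the dorsal boundary y(x) for an (super)elliptic outline."""
    xa = np.clip(np.abs(np.asarray(x, dtype=float) / a), 0.0, 1.0)
    return b * (1.0 - xa ** exponent) ** (1.0 / exponent)


def butterfly_outline(commissure_ab: tuple[float, float] = (1.5, 0.75),
                      dorsal_ab: tuple[float, float] = (0.55, 1.5),
                      dorsal_center: tuple[float, float] = (1.0, 1.15),
                      dorsal_tilt_deg: float = -20.0,
                      ventral_ab: tuple[float, float] = (0.8, 1.3),
                      ventral_center: tuple[float, float] = (1.05, -1.1),
                      ventral_tilt_deg: float = 15.0,
                      n: int = 128) -> Polygon:
    """Two-lobed, mirror-symmetric gray-matter cross-section.

    Built as the union of a central commissural ellipse and mirrored dorsal /
    ventral horn ellipses.  The dorsal horns tilt laterally so their tips
    approach the dorsolateral pia, which is what makes guarded (anode-flanked)
    montages necessary to avoid gray-matter co-activation.
    """
    def lobe(abxy, cxy, tilt):
        e = ellipse_outline(abxy[0], abxy[1], n)
        e = shapely.affinity.rotate(e, tilt, origin=(0, 0))
        return shapely.affinity.translate(e, cxy[0], cxy[1])

    parts = [ellipse_outline(*commissure_ab, n)]
    for sign in (+1.0, -1.0):
        parts.append(lobe(dorsal_ab, (sign * dorsal_center[0], dorsal_center[1]),
                          sign * dorsal_tilt_deg))
        parts.append(lobe(ventral_ab, (sign * ventral_center[0], ventral_center[1]),
                          sign * ventral_tilt_deg))
    poly = unary_union(parts)
    if poly.geom_type != "Polygon":
        raise ConfigurationError("gray-matter lobes do not form a connected region")
    return Polygon(poly.exterior)  # drop interior holes, keep simply connected


# ---------------------------------------------------------------------------
# conductivities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConductivityMap:
    """Tissue conductivities in S/m.

    White matter is anisotropic (longitudinal along the cord axis, radial in
    the cross-sectional plane); all other media are scalar.  Defaults follow
    standard spinal-cord-stimulation modeling values; CSF is approximately
    20x the radial white-matter conductivity, which is what produces the
    strong CSF current shunting this model exhibits.
    """
    sigma_gray: float = 0.23
    sigma_white_longitudinal: float = 0.60
    sigma_white_radial: float = 0.083
    sigma_csf: float = 1.7
    sigma_extradural: float = 0.04

    def __post_init__(self):
        vals = dataclasses.asdict(self)
        for name, v in vals.items():
            if not v > 0.0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        if not self.sigma_white_longitudinal > self.sigma_white_radial:
            raise ConfigurationError(
                "white-matter longitudinal conductivity must exceed radial")

    @property
    def csf_to_white_radial_ratio(self) -> float:
        return self.sigma_csf / self.sigma_white_radial


# ---------------------------------------------------------------------------
# cord geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CordGeometryParams:
    """Tunable dimensions of the idealized cord segment (mm)."""
    white_a: float = 4.0            # white-matter semi-axis, lateral
    white_b: float = 3.25           # white-matter semi-axis, dorsoventral
    csf_a: float = 8.0              # inner-dura semi-axis, lateral
    csf_b: float = 5.5              # inner-dura semi-axis, dorsoventral
    dorsal_flatness: float = 4.0    # superellipse exponent of dorsal dura
    dura_thickness: float = 1.0     # merged dura + extradural fat shell
    segment_length: float = 80.0
    substrate_protrusion: float = 0.3
    gray_kwargs: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CordGeometry:
    """Layered cord cross-section extruded along z over ``segment_length``."""
    white_matter_outline: Polygon
    gray_matter_outline: Polygon
    csf_outer_outline: Polygon
    dura_thickness: float
    segment_length: float
    substrate_protrusion: float
    substrate_footprint: Polygon      # region in the (x, z) plane
    params: CordGeometryParams

    @property
    def outer_outline(self) -> Polygon:
        """Exterior (grounded) surface of the dura/extradural shell."""
        p = self.params
        return flattened_ellipse_outline(p.csf_a + self.dura_thickness,
                                         p.csf_b + self.dura_thickness,
                                         p.dorsal_flatness)

    @property
    def plate_bottom_y(self) -> float:
        """Dorsoventral level of the electrode-bearing substrate underside."""
        return self.params.csf_b - self.substrate_protrusion

    def inner_dura_y(self, x):
        p = self.params
        return dorsal_surface_y(x, p.csf_a, p.csf_b, p.dorsal_flatness)

    def dorsal_white_y(self, x):
        p = self.params
        return dorsal_surface_y(x, p.white_a, p.white_b, 2.0)


def _default_footprint(params: CordGeometryParams) -> Polygon:
    """T-shaped substrate footprint sized for the default 12-site layout."""
    lp = TArrayParams()
    m = lp.substrate_margin
    half_cross = lp.n_cross * lp.cross_pitch / 2.0 + m
    half_z = lp.site_length_z / 2.0 + m
    cross_bar = box(-half_cross, -half_z, half_cross, half_z)
    stem_end = lp.stem_start_z + (lp.n_stem - 1) * lp.stem_pitch + half_z
    stem = box(-(lp.site_width_x / 2.0 + m), 0.0,
               lp.site_width_x / 2.0 + m, stem_end)
    return unary_union([cross_bar, stem])


def build_cord_geometry(params: CordGeometryParams | None = None) -> CordGeometry:
    """Construct and validate the layered cord geometry.

    Raises :class:`ConfigurationError` naming the violated constraint when the
    layer ordering is unsatisfiable or the array would touch the cord.
    """
    p = params or CordGeometryParams()
    for name in ("white_a", "white_b", "csf_a", "csf_b", "dura_thickness",
                 "segment_length", "substrate_protrusion"):
        if not getattr(p, name) > 0.0:
            raise ConfigurationError(f"{name} must be positive")

    white = ellipse_outline(p.white_a, p.white_b)
    gray = butterfly_outline(**p.gray_kwargs)
    csf_outer = flattened_ellipse_outline(p.csf_a, p.csf_b, p.dorsal_flatness)

    if not white.contains(gray):
        raise ConfigurationError(
            "layer overlap: gray-matter outline is not strictly inside the "
            "white-matter outline")
    if not csf_outer.contains(white):
        raise ConfigurationError(
            "layer overlap: white-matter outline is not strictly inside the "
            "CSF outer outline")

    dorsal_csf_thickness = p.csf_b - p.white_b
    if not p.substrate_protrusion < dorsal_csf_thickness:
        raise ConfigurationError(
            f"substrate_protrusion {p.substrate_protrusion} mm exceeds the "
            f"dorsal CSF layer thickness {dorsal_csf_thickness} mm "
            "(array must not touch the cord)")

    return CordGeometry(
        white_matter_outline=white,
        gray_matter_outline=gray,
        csf_outer_outline=csf_outer,
        dura_thickness=p.dura_thickness,
        segment_length=p.segment_length,
        substrate_protrusion=p.substrate_protrusion,
        substrate_footprint=_default_footprint(p),
        params=p,
    )


# ---------------------------------------------------------------------------
# T-array layout
# ---------------------------------------------------------------------------

CS, TS, BS = "CS", "TS", "BS"


@dataclass(frozen=True)
class TArrayParams:
    """Site dimensions and pitches of the 12-site T layout (mm)."""
    site_area: float = 1.72          # per-site geometric area, mm^2
    site_width_x: float = 1.2        # lateral extent; z extent = area / width
    n_cross: int = 6
    n_stem: int = 6
    cross_pitch: float = 1.35        # center-to-center along the cross row
    stem_pitch: float = 1.65         # center-to-center along the stem column
    stem_start_z: float = 1.95       # first base-site center, caudal of cross
    substrate_margin: float = 0.35   # substrate border beyond site envelope

    @property
    def site_length_z(self) -> float:
        return self.site_area / self.site_width_x


@dataclass(frozen=True)
class Site:
    id: int
    group: str                    # one of CS / TS / BS
    outline: Polygon              # rectangle in the (x, z) plane
    area: float                   # mm^2
    center: tuple[float, float]   # (x, z)


@dataclass(frozen=True)
class TArrayLayout:
    """The 12 electrode sites: a 6-site cross row plus a 6-site stem column.

    Groups: CS = innermost cross pair straddling the midline, TS = the four
    lateral cross sites (the outermost pair are the tips of the T), BS = the
    six stem (base) sites caudal to the cross.
    """
    sites: tuple[Site, ...]
    params: TArrayParams

    @property
    def cross_site_ids(self) -> tuple[int, ...]:
        return tuple(s.id for s in self.sites if s.group in (CS, TS))

    @property
    def stem_site_ids(self) -> tuple[int, ...]:
        return tuple(s.id for s in self.sites if s.group == BS)

    @property
    def tip_site_ids(self) -> tuple[int, ...]:
        """The outermost (lateral extreme) pair of the cross."""
        cross = [s for s in self.sites if s.group in (CS, TS)]
        xs = sorted(cross, key=lambda s: s.center[0])
        return (xs[0].id, xs[-1].id)

    def group_ids(self, group: str) -> tuple[int, ...]:
        return tuple(s.id for s in self.sites if s.group == group)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def footprint(self) -> Polygon:
        """Substrate envelope: the site union plus the substrate margin."""
        m = self.params.substrate_margin
        return unary_union([s.outline.buffer(m, join_style="mitre")
                            for s in self.sites])

    def site(self, sid: int) -> Site:
        return self.sites[sid]

    def mirrored(self) -> "TArrayLayout":
        """Layout reflected left<->right about the cord midline."""
        sites = tuple(
            Site(s.id, s.group,
                 shapely.affinity.scale(s.outline, xfact=-1, yfact=1,
                                        origin=(0, 0)),
                 s.area, (-s.center[0], s.center[1]))
            for s in self.sites)
        return TArrayLayout(sites, self.params)


def place_t_array(geom: CordGeometry,
                  layout_params: TArrayParams | None = None) -> TArrayLayout:
    """Place the 12-site T array on the dorsal substrate.

    Site ids 0..5 run left-to-right across the cross, 6..11 near-to-far along
    the stem.  The layout is mirror-symmetric about the cord midline.
    """
    lp = layout_params or TArrayParams()
    w, l = lp.site_width_x, lp.site_length_z
    sites: list[Site] = []

    x0 = -(lp.n_cross - 1) * lp.cross_pitch / 2.0
    inner = sorted(range(lp.n_cross),
                   key=lambda i: abs(x0 + i * lp.cross_pitch))[:2]
    for i in range(lp.n_cross):
        cx = x0 + i * lp.cross_pitch
        group = CS if i in inner else TS
        outline = box(cx - w / 2, -l / 2, cx + w / 2, l / 2)
        sites.append(Site(len(sites), group, outline, lp.site_area, (cx, 0.0)))

    for j in range(lp.n_stem):
        cz = lp.stem_start_z + j * lp.stem_pitch
        outline = box(-w / 2, cz - l / 2, w / 2, cz + l / 2)
        sites.append(Site(len(sites), BS, outline, lp.site_area, (0.0, cz)))

    for a in range(len(sites)):
        for b in range(a + 1, len(sites)):
            if sites[a].outline.intersects(sites[b].outline):
                raise ConfigurationError(
                    f"layout error: sites {a} and {b} overlap")
    layout = TArrayLayout(tuple(sites), lp)
    xmax = max(abs(x) for x in layout.footprint.bounds[0::2])
    if not geom.inner_dura_y(xmax) > geom.plate_bottom_y:
        raise ConfigurationError(
            "layout error: substrate footprint extends laterally beyond the "
            "region where the plate underside remains inside the CSF space")
    return layout
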