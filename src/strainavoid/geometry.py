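"""Parametric grooved stretch-chamber geometry.

The device is a soft PDMS culture chamber whose floor carries an array of
square microgrooves (350 x 350 um cross-section, 350 um spacing by default).
Cells are seeded either as a thin 2D layer on the structured surface or
embedded in a dECM-fibrin hydrogel that fills the grooves (3D seeding).

Coordinate convention: ``x`` is the stretch axis, ``y`` the in-plane
transverse axis, ``z`` the height; all lengths in mm (groove dimensions are
specified in um and converted internally). Grooves run along ``x``
(``parallel_to_stretch``) or along ``y`` (``perpendicular_to_stretch``);
they are recessed into the top surface of the bottom wall.

Besides the full 3D chamber solid, the module builds the reduced 2D
sections (cross-sections perpendicular to the grooves and longitudinal
sections along the stretch axis) on which the orientation and
strain-transmission campaigns run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import Mesh, coords1d, structured_mesh

__all__ = [
    "GeometryError",
    "MaterialProps",
    "CELLS",
    "HYDROGEL",
    "PDMS",
    "default_materials",
    "ChamberGeometry",
    "ChamberSolid",
    "build_chamber_geometry",
    "mesh_geometry",
    "groove_hydrogel_section",
    "membrane_cross_section",
    "membrane_longitudinal_section",
]

UM = 1e-3  # um -> mm

GROOVE_REFINE_MM = 0.1  # max element size inside groove regions when refining


class GeometryError(ValueError):
    """Raised for geometrically infeasible chamber configurations."""


@dataclass(frozen=True)
class MaterialProps:
    """Linear isotropic elastic material (SI: Pa, kg/m^3)."""

    young_modulus: float
    poisson_ratio: float
    density: float = 1000.0

    def __post_init__(self):
        if self.young_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5) for computation")

    @property
    def lame_lambda(self) -> float:
        e, nu = self.young_modulus, self.poisson_ratio
        return e * nu / ((1 + nu) * (1 - 2 * nu))

    @property
    def lame_mu(self) -> float:
        return self.young_modulus / (2 * (1 + self.poisson_ratio))


# material presets: H9c2 cells, dECM-fibrin hydrogel, PDMS
CELLS = MaterialProps(young_modulus=30e3, poisson_ratio=0.49, density=1060.0)
HYDROGEL = MaterialProps(young_modulus=21e3, poisson_ratio=0.2, density=1000.0)
PDMS = MaterialProps(young_modulus=0.98e6, poisson_ratio=0.49, density=965.0)


def default_materials() -> dict[str, MaterialProps]:
    return {"pdms": PDMS, "hydrogel": HYDROGEL, "cell_layer": CELLS}


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber dimensions (mm) and groove layout (um).

    Defaults are the fabricated device: 20 x 10 x 10 mm chamber, 0.1 mm
    thin / 5 mm thick sidewalls, 2 mm bottom wall, and a 350 x 350 um
    groove array with 350 um spacing.
    """

    chamber_length: float = 20.0
    chamber_width: float = 10.0
    chamber_height: float = 10.0
    thin_sidewall: float = 0.1
    thick_sidewall: float = 5.0
    bottom_wall: float = 2.0
    groove_width: float = 350.0      # um
    groove_depth: float = 350.0      # um
    groove_spacing: float = 350.0    # um
    groove_axis: str = "none"        # parallel_to_stretch | perpendicular_to_stretch | none
    cell_layer_thickness: float = 10.0  # um, 2D monolayer film height

    def __post_init__(self):
        for name in (
            "chamber_length", "chamber_width", "chamber_height", "thin_sidewall",
            "thick_sidewall", "bottom_wall", "groove_width", "groove_depth",
            "groove_spacing", "cell_layer_thickness",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        if self.groove_axis not in ("parallel_to_stretch", "perpendicular_to_stretch", "none"):
            raise GeometryError(f"unknown groove_axis: {self.groove_axis!r}")
        if self.groove_depth * UM > self.bottom_wall:
            raise GeometryError("groove_depth exceeds the bottom-wall height budget")
        if self.thin_sidewall + self.thick_sidewall >= self.chamber_width:
            raise GeometryError("sidewalls leave no floor width")
        if self.bottom_wall >= self.chamber_height:
            raise GeometryError("bottom wall exceeds chamber height")

    # mm-converted groove dimensions
    @property
    def groove_width_mm(self) -> float:
        return self.groove_width * UM

    @property
    def groove_depth_mm(self) -> float:
        return self.groove_depth * UM

    @property
    def groove_pitch_mm(self) -> float:
        return (self.groove_width + self.groove_spacing) * UM

    @property
    def film_mm(self) -> float:
        return self.cell_layer_thickness * UM

    @property
    def floor_z(self) -> float:
        """Height of the groove floor above the chamber underside."""
        return self.bottom_wall - self.groove_depth_mm

    def groove_span(self) -> float:
        """Length available for the groove array along its distribution axis."""
        if self.groove_axis == "parallel_to_stretch":
            return self.chamber_width - self.thin_sidewall - self.thick_sidewall
        return self.chamber_length

    def groove_count(self) -> int:
        if self.groove_axis == "none":
            return 0
        return int(math.floor(self.groove_span() / self.groove_pitch_mm))

    def groove_intervals(self) -> list[tuple[float, float]]:
        """(lo, hi) extents of each groove along its distribution axis."""
        n = self.groove_count()
        if n == 0:
            return []
        if self.groove_axis == "parallel_to_stretch":
            start = self.thin_sidewall
        else:
            start = 0.0
        pitch, w, s = self.groove_pitch_mm, self.groove_width_mm, self.groove_spacing * UM
        # centre the array within the available span
        pad = 0.5 * (self.groove_span() - n * pitch) + 0.5 * s
        return [
            (start + pad + i * pitch, start + pad + i * pitch + w) for i in range(n)
        ]


@dataclass(frozen=True)
class ChamberSolid:
    """Watertight axis-aligned chamber solid with seeding-dependent regions."""

    config: ChamberGeometry
    seeding: str = "none"  # none | layer_2d | hydrogel_3d

    def __post_init__(self):
        if self.seeding not in ("none", "layer_2d", "hydrogel_3d"):
            raise GeometryError(f"unknown seeding mode: {self.seeding!r}")
        if self.config.groove_axis != "none" and self.config.groove_count() < 1:
            raise GeometryError(
                "grooves wider than the available chamber floor: no groove fits"
            )

    @property
    def bounding_box(self) -> tuple[float, float, float]:
        c = self.config
        return (c.chamber_length, c.chamber_width, c.chamber_height)

    def _in_groove(self, pts: np.ndarray) -> np.ndarray:
        c = self.config
        if c.groove_axis == "none":
            return np.zeros(len(pts), dtype=bool)
        axis = 1 if c.groove_axis == "parallel_to_stretch" else 0
        coord = pts[:, axis]
        hit = np.zeros(len(pts), dtype=bool)
        for lo, hi in c.groove_intervals():
            hit |= (coord >= lo) & (coord <= hi)
        return hit & (pts[:, 2] >= c.floor_z) & (pts[:, 2] <= c.bottom_wall)

    def region_of(self, pts: np.ndarray) -> np.ndarray:
        """Classify points (m, 3) into pdms/hydrogel/cell_layer/None (void)."""
        c = self.config
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        x, y, z = pts.T
        out = np.full(len(pts), None, dtype=object)
        groove = self._in_groove(pts)
        slab = (z >= 0) & (z <= c.bottom_wall)
        sidewall = (z > c.bottom_wall) & (z <= c.chamber_height) & (
            (y <= c.thin_sidewall) | (y >= c.chamber_width - c.thick_sidewall)
        )
        out[(slab & ~groove) | sidewall] = "pdms"
        if self.seeding == "hydrogel_3d":
            out[slab & groove] = "hydrogel"
        elif self.seeding == "layer_2d":
            film = groove & (z <= c.floor_z + c.film_mm)
            out[slab & groove & ~film] = None
            out[slab & film] = "cell_layer"
        inside = (x >= 0) & (x <= c.chamber_length) & (y >= 0) & (y <= c.chamber_width)
        out[~inside] = None
        return out

    def analytic_volume(self) -> float:
        """Exact solid volume in mm^3 (pdms + seeded material)."""
        c = self.config
        v = c.chamber_length * c.chamber_width * c.bottom_wall
        v += (c.chamber_height - c.bottom_wall) * c.chamber_length * (
            c.thin_sidewall + c.thick_sidewall
        )
        groove_len = (
            c.chamber_length if c.groove_axis == "parallel_to_stretch" else c.chamber_width
        )
        vg = c.groove_count() * c.groove_width_mm * c.groove_depth_mm * groove_len
        if self.seeding == "none":
            v -= vg
        elif self.seeding == "layer_2d":
            v -= vg
            v += c.groove_count() * c.groove_width_mm * c.film_mm * groove_len
        return v

    def breakpoints(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c = self.config
        xb = {0.0, c.chamber_length}
        yb = {0.0, c.thin_sidewall, c.chamber_width - c.thick_sidewall, c.chamber_width}
        zb = {0.0, c.floor_z, c.bottom_wall, c.chamber_height}
        if self.seeding == "layer_2d":
            zb.add(c.floor_z + c.film_mm)
        gb = {v for lohi in c.groove_intervals() for v in lohi}
        if c.groove_axis == "parallel_to_stretch":
            yb |= gb
        elif c.groove_axis == "perpendicular_to_stretch":
            xb |= gb
        return (
            np.array(sorted(xb)),
            np.array(sorted(yb)),
            np.array(sorted(zb)),
        )


def build_chamber_geometry(
    config: ChamberGeometry, seeding: str = "none"
) -> ChamberSolid:
    """Assemble the parametric chamber solid for a seeding mode.

    Raises :class:`GeometryError` for infeasible inputs (e.g. grooves that do
    not fit the chamber floor).
    """
    return ChamberSolid(config=config, seeding=seeding)


def _chamber_tagger(solid: ChamberSolid):
    c = solid.config
    tol = 1e-9

    def tag_of(cent: np.ndarray, normals: np.ndarray) -> np.ndarray:
        tags = np.full(len(cent), "free", dtype="<U24")
        tags[(np.abs(cent[:, 0]) < tol) & (normals[:, 0] < 0)] = "clamped_end"
        tags[(np.abs(cent[:, 0] - c.chamber_length) < tol) & (normals[:, 0] > 0)] = "moving_end"
        if c.groove_axis != "none" and solid.seeding != "hydrogel_3d":
            in_depth = (cent[:, 2] > c.floor_z + tol) & (cent[:, 2] < c.bottom_wall - tol)
            axis = 1 if c.groove_axis == "parallel_to_stretch" else 0
            side = np.zeros(len(cent), dtype=bool)
            for lo, hi in c.groove_intervals():
                side |= (np.abs(cent[:, axis] - lo) < tol) | (np.abs(cent[:, axis] - hi) < tol)
            tags[in_depth & side & (np.abs(normals[:, axis]) > 0.5)] = "groove_sidewall"
            bottom = np.zeros(len(cent), dtype=bool)
            for lo, hi in c.groove_intervals():
                bottom |= (cent[:, axis] > lo) & (cent[:, axis] < hi)
            floor_top = solid.seeding == "layer_2d" and c.film_mm or 0.0
            tags[
                bottom
                & (np.abs(cent[:, 2] - (c.floor_z + floor_top)) < tol)
                & (normals[:, 2] > 0)
            ] = "groove_bottom"
        return tags

    return tag_of


def mesh_geometry(
    solid: ChamberSolid, resolution: float, refine_grooves: bool = False
) -> Mesh:
    """Mesh the chamber solid with hexahedra of target edge ``resolution`` (mm).

    With ``refine_grooves`` the element size inside groove regions is capped
    at 0.1 mm (matching the refinement used for the device simulations).
    """
    if resolution <= 0:
        raise GeometryError("resolution must be positive")
    c = solid.config
    xb, yb, zb = solid.breakpoints()
    refine_x, refine_y = [], []
    refine_z = []
    if refine_grooves and c.groove_axis != "none":
        win = [(lo, hi, GROOVE_REFINE_MM) for lo, hi in c.groove_intervals()]
        if c.groove_axis == "parallel_to_stretch":
            refine_y = win
            # grooves run the full length: cap the along-groove spacing too
            refine_x = [(0.0, c.chamber_length, GROOVE_REFINE_MM)]
        else:
            refine_x = win
            refine_y = [(0.0, c.chamber_width, GROOVE_REFINE_MM)]
        refine_z = [(c.floor_z, c.bottom_wall, GROOVE_REFINE_MM)]
    axes = (
        coords1d(xb, resolution, refine_x),
        coords1d(yb, resolution, refine_y),
        coords1d(zb, resolution, refine_z),
    )
    return structured_mesh(axes, solid.region_of, _chamber_tagger(solid))


# ---------------------------------------------------------------------------
# reduced 2D sections used by the simulation campaigns
# ---------------------------------------------------------------------------

def groove_hydrogel_section(config: ChamberGeometry, h: float = 0.04375) -> Mesh:
    """Cross-section of the hydrogel filling one groove (plane ⟂ groove axis).

    The PDMS is treated as rigid relative to the 21 kPa gel: the groove
    floor is a bonded boundary (``groove_bottom``), the lateral walls carry
    the detachment springs (``groove_sidewall``), the top surface is free.
    Mesh coordinates: a = cross-groove direction, b = height, both from 0.
    """
    w, d = config.groove_width_mm, config.groove_depth_mm
    axes = (coords1d([0.0, w], h), coords1d([0.0, d], h))
    tol = 1e-9

    def tag_of(cent, normals):
        tags = np.full(len(cent), "free", dtype="<U24")
        tags[(np.abs(cent[:, 1]) < tol) & (normals[:, 1] < 0)] = "groove_bottom"
        side = (np.abs(cent[:, 0]) < tol) | (np.abs(cent[:, 0] - w) < tol)
        tags[side & (np.abs(normals[:, 0]) > 0.5)] = "groove_sidewall"
        return tags

    return structured_mesh(axes, lambda c: np.full(len(c), "hydrogel", dtype=object), tag_of)


def _grooved_profile_regions(config: ChamberGeometry, seeding: str, intervals):
    """Classifier for a grooved membrane profile in a 2D (a, z) plane."""
    c = config

    def region_of(cent: np.ndarray) -> np.ndarray:
        a, z = cent[:, 0], cent[:, 1]
        out = np.full(len(cent), None, dtype=object)
        out[(z >= 0) & (z <= c.bottom_wall)] = "pdms"
        in_a = np.zeros(len(cent), dtype=bool)
        for lo, hi in intervals:
            in_a |= (a >= lo) & (a <= hi)
        groove = in_a & (z >= c.floor_z) & (z <= c.bottom_wall)
        if seeding == "hydrogel_3d":
            out[groove] = "hydrogel"
        elif seeding == "layer_2d":
            film = groove & (z <= c.floor_z + c.film_mm)
            ridge_film = (
                ~in_a & (z > c.bottom_wall) & (z <= c.bottom_wall + c.film_mm)
            )
            out[groove] = None
            out[film] = "cell_layer"
            out[ridge_film] = "cell_layer"
        else:
            out[groove] = None
        return out

    return region_of


def _profile_breaks(config: ChamberGeometry, seeding: str, intervals, span: float):
    c = config
    ab = {0.0, span} | {v for lohi in intervals for v in lohi}
    zb = {0.0, c.floor_z, c.bottom_wall}
    if seeding == "layer_2d":
        zb |= {c.floor_z + c.film_mm, c.bottom_wall + c.film_mm}
    return np.array(sorted(ab)), np.array(sorted(zb))


def membrane_cross_section(
    config: ChamberGeometry,
    seeding: str = "hydrogel_3d",
    n_periods: int = 3,
    h: float = 0.0875,
    grooved: bool = True,
) -> Mesh:
    """Transverse section of the grooved membrane (plane ⟂ groove axis).

    Spans ``n_periods`` groove pitches; all exterior facets are tagged
    ``free`` (this section is driven by an out-of-plane stretch or by
    eigenstrain, with rigid-body pinning handled by the solver).
    """
    c = config
    pitch = c.groove_pitch_mm
    span = n_periods * pitch
    hz = min(h, c.groove_depth_mm / 4)
    ha = min(h, c.groove_width_mm / 4)
    if grooved:
        off = 0.5 * c.groove_spacing * UM
        intervals = [(off + i * pitch, off + i * pitch + c.groove_width_mm) for i in range(n_periods)]
        ab, zb = _profile_breaks(config, seeding, intervals, span)
        region_of = _grooved_profile_regions(config, seeding, intervals)
    else:
        # unstructured membrane: the seeded material lies as a uniform layer
        # on the flat top surface
        top = c.bottom_wall
        layer = c.groove_depth_mm if seeding == "hydrogel_3d" else c.film_mm
        name = {"hydrogel_3d": "hydrogel", "layer_2d": "cell_layer"}.get(seeding)

        def region_of(cent):
            z = cent[:, 1]
            out = np.full(len(cent), None, dtype=object)
            out[(z >= 0) & (z <= top)] = "pdms"
            if name is not None:
                out[(z > top) & (z <= top + layer)] = name
            return out

        zb = np.array(sorted({0.0, c.floor_z, top} | ({top + layer} if name else set())))
        ab = np.array([0.0, span])
    axes = (coords1d(ab, ha), coords1d(zb, hz))
    return structured_mesh(axes, region_of, None)


def membrane_longitudinal_section(
    config: ChamberGeometry,
    seeding: str = "none",
    grooved: bool = False,
    through_groove: bool = False,
    length: float | None = None,
    h: float = 0.25,
    h_groove: float = 0.0875,
) -> Mesh:
    """Longitudinal section of the membrane along the stretch axis (x-z plane).

    ``grooved=True`` carves the transverse groove array into the profile
    (grooves perpendicular to stretch). ``through_groove=True`` builds the
    layered section along the midline of a groove running parallel to
    stretch (thinned PDMS floor with the seeded material on top). The plain
    variant is the unstructured membrane with the seeded material layered on
    its top surface.

    Ends are tagged ``clamped_end`` (x=0) and ``moving_end`` (x=L).
    """
    c = config
    span = length if length is not None else c.chamber_length
    if grooved:
        cfg = replace(c, groove_axis="perpendicular_to_stretch")
        intervals = [(lo, hi) for lo, hi in cfg.groove_intervals() if hi <= span]
        region_of = _grooved_profile_regions(c, seeding, intervals)
        ab, zb = _profile_breaks(c, seeding, intervals, span)
        refine_a = [(lo, hi, h_groove) for lo, hi in intervals]
    else:
        intervals = []
        pdms_top = c.floor_z if through_groove else c.bottom_wall
        seeded_top = pdms_top + (
            c.groove_depth_mm if seeding == "hydrogel_3d" else c.film_mm
        )

        def region_of(cent):
            z = cent[:, 1]
            out = np.full(len(cent), None, dtype=object)
            out[(z >= 0) & (z <= pdms_top)] = "pdms"
            if seeding == "hydrogel_3d":
                out[(z > pdms_top) & (z <= seeded_top)] = "hydrogel"
            elif seeding == "layer_2d":
                out[(z > pdms_top) & (z <= seeded_top)] = "cell_layer"
            return out

        zb = {0.0, pdms_top}
        if seeding in ("hydrogel_3d", "layer_2d"):
            zb.add(seeded_top)
        ab = np.array([0.0, span])
        zb = np.array(sorted(zb))
        refine_a = []
    hz = min(h, c.groove_depth_mm / 4)
    axes = (coords1d(ab, h, refine_a), coords1d(zb, hz))
    tol = 1e-9

    def tag_of(cent, normals):
        tags = np.full(len(cent), "free", dtype="<U24")
        tags[(np.abs(cent[:, 0]) < tol) & (normals[:, 0] < 0)] = "clamped_end"
        tags[(np.abs(cent[:, 0] - span) < tol) & (normals[:, 0] > 0)] = "moving_end"
        return tags

    return structured_mesh(axes, region_of, tag_of)
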