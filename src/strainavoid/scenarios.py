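"""Canonical simulation scenarios and calibration.

The orientation campaign covers the seeding x topography grid
``{2D layer, 3D hydrogel} x {no grooves, grooves parallel to stretch,
grooves perpendicular to stretch}`` at 15% cyclic stretch amplitude, plus
``_static`` variants with the stretch switched off. The strain-transmission
campaign evaluates the axial strain reaching the cells for the nine
seeding x topography combinations at 36% applied stretch.

All solves run on reduced 2D sections of the grooved membrane:

* grooves parallel to stretch - a transverse (y-z) cross-section driven by
  the known axial strain as a generalized plane-strain condition;
* grooves perpendicular to stretch - a longitudinal (x-z) section through
  the groove profile, with the along-groove direction closed by the
  membrane's transverse Poisson contraction;
* hydrogel self-condensation - the groove cross-section of the gel alone
  (bonded floor, spring sidewalls, free top; the 47x stiffer PDMS is taken
  as rigid), in plane strain along the groove axis because adhesion to the
  floor suppresses longitudinal contraction far from the chamber ends.

Two quantities are calibrated rather than taken from measurements:

* the sidewall spring stiffness, set so the cross-groove contraction of the
  gel at the groove centre reaches a configurable fraction (default 50%) of
  its fully-detached value ("partial detachment");
* the cellular contraction eigenstrain, set so the peak in-plane
  self-elongation deficit of the 3D hydrogel at the probe equals the
  applied strain amplitude (cellular and applied strains are of similar
  magnitude in the soft gel). The same eigenstrain drives the 2D monolayer
  scenarios, where the stiff PDMS suppresses the resulting strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .elasticity import LoadCase, StrainField, effective_axial_strain, solve
from .geometry import (
    PDMS,
    ChamberGeometry,
    MaterialProps,
    default_materials,
    groove_hydrogel_section,
    membrane_cross_section,
    membrane_longitudinal_section,
)
from .orientation import (
    CombinationParams,
    OrientationPrediction,
    orientation_from_tensors,
)

__all__ = [
    "CANONICAL_SCENARIOS",
    "ScenarioResult",
    "run_scenario",
    "calibrate_spring_stiffness",
    "calibrated_self_tensor",
    "contraction_sweep",
    "strain_transmission_campaign",
    "TransmissionCase",
]

_BASE_SCENARIOS = (
    "flat_2d",
    "flat_3d",
    "2d_parallel",
    "2d_perpendicular",
    "3d_parallel",
    "3d_perpendicular",
)
CANONICAL_SCENARIOS = _BASE_SCENARIOS + tuple(f"{s}_static" for s in _BASE_SCENARIOS)

DEFAULT_APPLIED_STRAIN = 0.15   # cyclic stretch amplitude of the alignment protocol
DEFAULT_SPRING_FRACTION = 0.5   # residual cross-groove contraction vs fully detached
_CAL_SEED_CONTRACTION = 0.15    # initial eigenstrain before linear rescaling


def _parse_scenario(name: str) -> tuple[str, str, bool]:
    """-> (seeding, topography, stretch_on); raises for unknown names."""
    base = name
    static = name.endswith("_static")
    if static:
        base = name[: -len("_static")]
    table = {
        "flat_2d": ("layer_2d", "flat"),
        "flat_3d": ("hydrogel_3d", "flat"),
        "2d_parallel": ("layer_2d", "parallel"),
        "2d_perpendicular": ("layer_2d", "perpendicular"),
        "3d_parallel": ("hydrogel_3d", "parallel"),
        "3d_perpendicular": ("hydrogel_3d", "perpendicular"),
    }
    if base not in table:
        raise ValueError(
            f"unknown scenario {name!r}; canonical names: {', '.join(CANONICAL_SCENARIOS)}"
        )
    seeding, topo = table[base]
    return seeding, topo, not static


@dataclass
class ScenarioResult:
    """Orientation prediction plus the strain state behind it."""

    scenario: str
    prediction: OrientationPrediction
    eps_cyclic: np.ndarray | None   # lab-frame 3x3 peak-stretch strain at probe
    eps_self: np.ndarray | None     # lab-frame 3x3 condensation strain at probe
    applied_strain: float
    contraction_magnitude: float | None
    spring_stiffness: float | None  # Pa/m
    probe: dict
    fields: dict = field(default_factory=dict, repr=False)

    @property
    def angle(self) -> float:
        return self.prediction.angle


# ---------------------------------------------------------------------------
# hydrogel self-condensation on the groove unit cell, with calibration
# ---------------------------------------------------------------------------

_spring_cache: dict[tuple, float] = {}


def _groove_self_solve(
    config: ChamberGeometry,
    materials: dict[str, MaterialProps],
    contraction: float,
    spring_pa_per_m: float,
) -> tuple[StrainField, tuple[float, float]]:
    mesh = groove_hydrogel_section(config)
    load = LoadCase(
        kind="self_condensation",
        contraction_magnitude=contraction,
        sidewall_spring_stiffness=spring_pa_per_m,
        seeding_mode="hydrogel_3d",
    )
    # mesh coords: a = cross-groove, b = height; lab mapping applied later
    fld = solve(mesh, materials, load, plane_axes=("y", "z"))
    probe = (0.5 * config.groove_width_mm, 0.5 * config.groove_depth_mm)
    return fld, probe


def calibrate_spring_stiffness(
    config: ChamberGeometry | None = None,
    materials: dict[str, MaterialProps] | None = None,
    fraction: float = DEFAULT_SPRING_FRACTION,
) -> float:
    """Sidewall spring stiffness (Pa/m) matching a cross-groove contraction fraction.

    Finds k such that the transverse normal strain at the groove centre under
    unit-scale contraction equals ``fraction`` times its fully detached
    (k = 0) value. Monotone in k, solved by bracketed root finding; the
    result is cached per configuration.
    """
    config = config or ChamberGeometry()
    materials = materials or default_materials()
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    key = (config, fraction, materials["hydrogel"])
    if key in _spring_cache:
        return _spring_cache[key]

    def transverse(k: float) -> float:
        fld, probe = _groove_self_solve(config, materials, _CAL_SEED_CONTRACTION, k)
        return float(fld.strain_at(probe)[1, 1])  # cross-groove (lab y) component

    free = transverse(0.0)
    target = fraction * free

    def fun(log10k: float) -> float:
        return transverse(10.0**log10k) - target

    log10k = brentq(fun, 0.0, 14.0, xtol=1e-3)
    k_star = float(10.0**log10k)
    _spring_cache[key] = k_star
    return k_star


def calibrated_self_tensor(
    config: ChamberGeometry | None = None,
    materials: dict[str, MaterialProps] | None = None,
    *,
    groove_axis: str = "parallel_to_stretch",
    target_deficit: float = DEFAULT_APPLIED_STRAIN,
    spring_fraction: float = DEFAULT_SPRING_FRACTION,
) -> tuple[np.ndarray, float, float, StrainField]:
    """Calibrated hydrogel condensation strain at the groove-centre probe.

    Returns ``(eps_lab, contraction_magnitude, spring_stiffness, field)``
    where ``eps_lab`` is the 3x3 lab-frame tensor with the groove axis
    mapped onto x (parallel) or y (perpendicular). The eigenstrain magnitude
    is rescaled (exactly, by linearity) so the peak in-plane elongation
    deficit ``max_theta |1 - e_self(theta)|`` equals ``target_deficit``.
    """
    config = config or ChamberGeometry()
    materials = materials or default_materials()
    k_star = calibrate_spring_stiffness(config, materials, spring_fraction)
    fld, probe = _groove_self_solve(config, materials, _CAL_SEED_CONTRACTION, k_star)
    eps = fld.strain_at(probe)  # lab frame with groove axis = x (plane strain axis)
    # peak in-plane (x-y) deficit: with eps_xx = 0 and eps_xy = 0 this is |eps_yy|
    deficit = abs(min(eps[0, 0], eps[1, 1], 0.0))
    if deficit <= 0:
        raise RuntimeError("condensation solve produced no in-plane contraction")
    scale = target_deficit / deficit
    c_star = _CAL_SEED_CONTRACTION * scale
    eps = eps * scale
    if groove_axis == "perpendicular_to_stretch":
        # groove axis along y: swap the x and y roles of the tensor
        p = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        eps = p @ eps @ p
    return eps, c_star, k_star, fld


# ---------------------------------------------------------------------------
# cyclic-stretch solves on membrane sections
# ---------------------------------------------------------------------------

def _cyclic_parallel(config, materials, seeding, applied_strain):
    """Transverse cross-section driven by axial stretch (grooves along x)."""
    cfg = replace(config, groove_axis="parallel_to_stretch")
    mesh = membrane_cross_section(cfg, seeding=seeding)
    load = LoadCase(
        kind="applied_stretch", applied_strain=applied_strain, seeding_mode=seeding
    )
    fld = solve(
        mesh,
        materials,
        load,
        plane_axes=("y", "z"),
        out_of_plane_strain=applied_strain,
        pin_rigid_body=True,
    )
    a = 1.5 * cfg.groove_pitch_mm  # centre of the middle groove
    z = (
        cfg.floor_z + 0.5 * cfg.groove_depth_mm
        if seeding == "hydrogel_3d"
        else cfg.floor_z + 0.5 * cfg.film_mm
    )
    return fld, (a, z)


def _cyclic_perpendicular(config, materials, seeding, applied_strain):
    """Longitudinal section across the grooves (grooves along y)."""
    cfg = replace(config, groove_axis="perpendicular_to_stretch")
    mesh = membrane_longitudinal_section(cfg, seeding=seeding, grooved=True)
    load = LoadCase(
        kind="applied_stretch", applied_strain=applied_strain, seeding_mode=seeding
    )
    # along-groove (lab y) closure: transverse Poisson contraction of the membrane
    fld = solve(
        mesh,
        materials,
        load,
        plane_axes=("x", "z"),
        out_of_plane_strain=-materials["pdms"].poisson_ratio * applied_strain,
    )
    intervals = cfg.groove_intervals()
    centre = 0.5 * cfg.chamber_length
    lo, hi = min(intervals, key=lambda iv: abs(0.5 * (iv[0] + iv[1]) - centre))
    x = 0.5 * (lo + hi)
    if seeding == "hydrogel_3d":
        z = cfg.floor_z + 0.5 * cfg.groove_depth_mm
    elif seeding == "layer_2d":
        z = cfg.floor_z + 0.5 * cfg.film_mm
    else:
        z = cfg.floor_z - 0.02  # just below the groove floor surface
    return fld, (x, z)


def _cyclic_flat(config, materials, seeding, applied_strain):
    """Longitudinal section of the unstructured membrane."""
    cfg = replace(config, groove_axis="none")
    mesh = membrane_longitudinal_section(cfg, seeding=seeding, grooved=False)
    load = LoadCase(
        kind="applied_stretch", applied_strain=applied_strain, seeding_mode=seeding
    )
    fld = solve(
        mesh,
        materials,
        load,
        plane_axes=("x", "z"),
        out_of_plane_strain=-materials["pdms"].poisson_ratio * applied_strain,
    )
    x = 0.5 * cfg.chamber_length
    if seeding == "hydrogel_3d":
        z = cfg.bottom_wall + 0.5 * cfg.groove_depth_mm
    elif seeding == "layer_2d":
        z = cfg.bottom_wall + 0.5 * cfg.film_mm
    else:
        z = cfg.bottom_wall - 0.02
    return fld, (x, z)


def _self_film(config, materials, contraction, topography):
    """Monolayer self-condensation on the (grooved) PDMS surface.

    Transverse cross-section for grooves parallel to stretch, longitudinal
    grooved section for perpendicular grooves, flat layered section
    otherwise; plane strain along the remaining axis.
    """
    load = LoadCase(
        kind="self_condensation",
        contraction_magnitude=contraction,
        seeding_mode="layer_2d",
    )
    if topography == "parallel":
        cfg = replace(config, groove_axis="parallel_to_stretch")
        mesh = membrane_cross_section(cfg, seeding="layer_2d")
        plane_axes = ("y", "z")
        probe = (1.5 * cfg.groove_pitch_mm, cfg.floor_z + 0.5 * cfg.film_mm)
    elif topography == "perpendicular":
        cfg = replace(config, groove_axis="perpendicular_to_stretch")
        mesh = membrane_longitudinal_section(cfg, seeding="layer_2d", grooved=True)
        plane_axes = ("x", "z")
        intervals = cfg.groove_intervals()
        centre = 0.5 * cfg.chamber_length
        lo, hi = min(intervals, key=lambda iv: abs(0.5 * (iv[0] + iv[1]) - centre))
        probe = (0.5 * (lo + hi), cfg.floor_z + 0.5 * cfg.film_mm)
    else:
        cfg = replace(config, groove_axis="none")
        mesh = membrane_cross_section(cfg, seeding="layer_2d", grooved=False)
        plane_axes = ("y", "z")
        probe = (1.5 * cfg.groove_pitch_mm, cfg.bottom_wall + 0.5 * cfg.film_mm)
    fld = solve(mesh, materials, load, plane_axes=plane_axes, pin_rigid_body=True)
    return fld, probe


def _self_flat_hydrogel(config, materials, contraction):
    """Hydrogel layer condensing on the unstructured membrane.

    The strip spans 10 groove pitches so the probe sits many layer
    thicknesses away from the free lateral edges: near the chamber centre
    the bonded layer is almost fully constrained in both in-plane
    directions, matching the absence of a preferred direction on flat
    substrates.
    """
    cfg = replace(config, groove_axis="none")
    mesh = membrane_cross_section(cfg, seeding="hydrogel_3d", grooved=False, n_periods=10)
    load = LoadCase(
        kind="self_condensation",
        contraction_magnitude=contraction,
        seeding_mode="hydrogel_3d",
    )
    fld = solve(mesh, materials, load, plane_axes=("y", "z"), pin_rigid_body=True)
    probe = (5.0 * cfg.groove_pitch_mm, cfg.bottom_wall + 0.5 * cfg.groove_depth_mm)
    return fld, probe


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------

def run_scenario(
    name: str,
    *,
    config: ChamberGeometry | None = None,
    materials: dict[str, MaterialProps] | None = None,
    params: CombinationParams | None = None,
    applied_strain: float = DEFAULT_APPLIED_STRAIN,
    spring_fraction: float = DEFAULT_SPRING_FRACTION,
    contraction_scale: float = 1.0,
    keep_fields: bool = False,
) -> ScenarioResult:
    """Mesh, solve both load cases, combine the cues, and report the angle.

    Deterministic for a given configuration. ``contraction_scale``
    multiplies the calibrated contraction eigenstrain (1.0 = calibrated);
    ``name`` must be one of :data:`CANONICAL_SCENARIOS`.
    """
    seeding, topo, stretch_on = _parse_scenario(name)
    config = config or ChamberGeometry()
    materials = materials or default_materials()
    params = params or CombinationParams()

    fields: dict[str, StrainField] = {}
    probe_info: dict = {"seeding": seeding, "topography": topo}

    # --- static self-condensation cue --------------------------------------
    spring = None
    if seeding == "hydrogel_3d" and topo in ("parallel", "perpendicular"):
        axis = (
            "parallel_to_stretch" if topo == "parallel" else "perpendicular_to_stretch"
        )
        eps_self, c_star, spring, fld_self = calibrated_self_tensor(
            config,
            materials,
            groove_axis=axis,
            target_deficit=applied_strain,
            spring_fraction=spring_fraction,
        )
        eps_self = eps_self * contraction_scale
        c_star = c_star * contraction_scale
        fields["self"] = fld_self
    else:
        # calibrate the cellular eigenstrain on the 3D groove case, then let
        # the stiff substrate decide how much strain the monolayer achieves
        _, c_cal, spring, _ = calibrated_self_tensor(
            config,
            materials,
            target_deficit=applied_strain,
            spring_fraction=spring_fraction,
        )
        c_star = c_cal * contraction_scale
        if seeding == "layer_2d":
            fld_self, probe_self = _self_film(config, materials, c_star, topo)
        else:  # flat 3D hydrogel layer
            fld_self, probe_self = _self_flat_hydrogel(config, materials, c_star)
        eps_self = fld_self.strain_at(probe_self)
        if topo == "flat":
            # the unstructured chamber centre is in-plane symmetric under
            # homogeneous contraction; the reduced section breaks that
            # symmetry (plane constraint along x, free strip edges along y),
            # so restore it by in-plane isotropization of the self cue
            iso = 0.5 * (eps_self[0, 0] + eps_self[1, 1])
            eps_self = eps_self.copy()
            eps_self[0, 0] = eps_self[1, 1] = iso
            eps_self[0, 1] = eps_self[1, 0] = 0.0
        fields["self"] = fld_self
        probe_info["self_probe"] = probe_self

    # --- cyclic-stretch cue -------------------------------------------------
    eps_cyclic = None
    if stretch_on:
        if topo == "parallel":
            fld_cyc, probe_cyc = _cyclic_parallel(config, materials, seeding, applied_strain)
        elif topo == "perpendicular":
            fld_cyc, probe_cyc = _cyclic_perpendicular(config, materials, seeding, applied_strain)
        else:
            fld_cyc, probe_cyc = _cyclic_flat(config, materials, seeding, applied_strain)
        eps_cyclic = fld_cyc.strain_at(probe_cyc)
        fields["cyclic"] = fld_cyc
        probe_info["cyclic_probe"] = probe_cyc

    prediction = orientation_from_tensors(eps_cyclic, eps_self, params, scenario=name)
    return ScenarioResult(
        scenario=name,
        prediction=prediction,
        eps_cyclic=eps_cyclic,
        eps_self=eps_self,
        applied_strain=applied_strain if stretch_on else 0.0,
        contraction_magnitude=c_star,
        spring_stiffness=spring,
        probe=probe_info,
        fields=fields if keep_fields else {},
    )


def contraction_sweep(
    multipliers: Sequence[float],
    scenario: str = "3d_parallel",
    *,
    config: ChamberGeometry | None = None,
    materials: dict[str, MaterialProps] | None = None,
    params: CombinationParams | None = None,
    applied_strain: float = DEFAULT_APPLIED_STRAIN,
) -> list[tuple[float, float]]:
    """Predicted angle as the contraction magnitude sweeps from 0 to dominance.

    Exploits linearity: the condensation field is solved once at the
    calibrated magnitude and rescaled. Returns ``(multiplier, angle)`` pairs;
    the angle moves from 90 deg (stretch only) toward the groove direction
    as the contraction cue grows.
    """
    base = run_scenario(
        scenario,
        config=config,
        materials=materials,
        params=params,
        applied_strain=applied_strain,
    )
    params = params or CombinationParams()
    out = []
    for m in multipliers:
        eps_self = None if base.eps_self is None else base.eps_self * m
        pred = orientation_from_tensors(base.eps_cyclic, eps_self, params)
        out.append((float(m), pred.angle))
    return out


# ---------------------------------------------------------------------------
# strain-transmission campaign (nine seeding x topography cases)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransmissionCase:
    seeding: str      # none | layer_2d | hydrogel_3d
    topography: str   # flat | parallel | perpendicular
    axial_strain_pct: float
    probe: tuple


def strain_transmission_campaign(
    applied_strain: float = 0.36,
    *,
    config: ChamberGeometry | None = None,
    materials: dict[str, MaterialProps] | None = None,
    cases: Sequence[tuple[str, str]] | None = None,
) -> list[TransmissionCase]:
    """Axial strain at the representative cell location for each case.

    The probe sits near the chamber centre, on the groove midline, at the
    monolayer height (2D), the groove half-height (3D), or just below the
    membrane surface (no cells). Reported in percent of unit strain.
    """
    config = config or ChamberGeometry()
    materials = materials or default_materials()
    if cases is None:
        cases = [
            (s, t)
            for t in ("flat", "parallel", "perpendicular")
            for s in ("none", "layer_2d", "hydrogel_3d")
        ]
    results = []
    for seeding, topo in cases:
        if topo == "perpendicular":
            fld, probe = _cyclic_perpendicular(config, materials, seeding, applied_strain)
        elif topo == "parallel":
            # strain along the grooves is carried by the layered longitudinal
            # section through the groove midline
            cfg = replace(config, groove_axis="parallel_to_stretch")
            mesh = membrane_longitudinal_section(
                cfg, seeding=seeding, grooved=False, through_groove=True
            )
            load = LoadCase(
                kind="applied_stretch", applied_strain=applied_strain, seeding_mode=seeding
            )
            fld = solve(
                mesh,
                materials,
                load,
                plane_axes=("x", "z"),
                out_of_plane_strain=-materials["pdms"].poisson_ratio * applied_strain,
            )
            x = 0.5 * cfg.chamber_length
            if seeding == "hydrogel_3d":
                z = cfg.floor_z + 0.5 * cfg.groove_depth_mm
            elif seeding == "layer_2d":
                z = cfg.floor_z + 0.5 * cfg.film_mm
            else:
                z = cfg.floor_z - 0.02
            probe = (x, z)
        else:
            fld, probe = _cyclic_flat(config, materials, seeding, applied_strain)
        results.append(
            TransmissionCase(
                seeding=seeding,
                topography=topo,
                axial_strain_pct=effective_axial_strain(fld, probe),
                probe=tuple(probe),
            )
        )
    return results
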