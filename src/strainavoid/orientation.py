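"""Strain-avoidance orientation rule.

Cells align along the direction in which their stress fibers experience the
least compression. Each strain field contributes a directional elongation
``e(u) = 1 + u^T eps u`` (linearized stretch ratio of a fiber along the
unit direction ``u``; ``e < 1`` is compression). The cyclic-stretch cue is
evaluated on the *release* half-cycle, i.e. on the negated peak strain
tensor, because the net orienting effect of cyclic stretch comes from its
compressive phase. The static self-condensation cue uses the contraction
strain field directly.

The two cues combine through the nonlinear addition law

    e_tot = (e_cyclic^-n + e_self^-n)^(-1/n),    n = 4 by default,

which weights compression (e < 1) more heavily than extension, is symmetric
and homogeneous of degree one, is bounded above by min(e_cyclic, e_self),
and tends to the minimum as n -> infinity. The predicted orientation is the
direction maximising e_tot, reported as an angle in [0, 90] degrees from
the stretch axis (orientations are axial: theta and theta + 180 are the
same direction, and [90, 180) folds back onto [0, 90]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .elasticity import StrainField

__all__ = [
    "CombinationParams",
    "ElongationProfile",
    "OrientationPrediction",
    "directional_elongation",
    "combine_elongations",
    "elongation_profile",
    "cyclic_elongation_field",
    "self_elongation_field",
    "orientation_from_tensors",
    "predict_orientation",
]


@dataclass(frozen=True)
class CombinationParams:
    """Parameters of the nonlinear strain-addition law and direction search."""

    n: float = 4.0                 # addition-law exponent
    angle_grid: float = 0.5        # degrees between candidate directions
    search_space: str = "in_plane" # in_plane | full_3d

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("exponent n must be positive")
        if self.angle_grid <= 0 or abs(180.0 / self.angle_grid - round(180.0 / self.angle_grid)) > 1e-9:
            raise ValueError("angle_grid must divide 180 degrees")
        if self.search_space not in ("in_plane", "full_3d"):
            raise ValueError(f"unknown search_space: {self.search_space!r}")

    def angles(self) -> np.ndarray:
        """Axial candidate angles in degrees, [0, 180)."""
        return np.arange(0.0, 180.0, self.angle_grid)


@dataclass
class ElongationProfile:
    """Directional stress-fiber elongations over the axial angle grid."""

    angles: np.ndarray    # degrees in [0, 180)
    e_cyclic: np.ndarray  # elongation per angle (1 = no length change)
    e_self: np.ndarray
    e_tot: np.ndarray
    n: float

    def __post_init__(self):
        for name in ("e_cyclic", "e_self", "e_tot"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive everywhere")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "angle_deg": self.angles,
                "e_cyclic": self.e_cyclic,
                "e_self": self.e_self,
                "e_tot": self.e_tot,
            }
        )


@dataclass
class OrientationPrediction:
    """Predicted preferred alignment angle for one scenario."""

    angle: float                  # degrees in [0, 90] from the stretch axis (nan if degenerate)
    profile: ElongationProfile
    scenario: str = ""
    degenerate: bool = False      # flat profile: no preferred direction
    tie: bool = False             # multiple grid maxima; smaller angle reported


def directional_elongation(strain: np.ndarray, direction: Sequence[float]) -> float:
    """Relative length change of a stress fiber along a unit direction.

    Returns the linearized stretch ratio ``1 + u^T eps u``; raises for a
    non-unit direction.
    """
    u = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-8:
        raise ValueError("direction must be a unit vector")
    eps = np.asarray(strain, dtype=float)
    return float(1.0 + u @ eps @ u)


def combine_elongations(e_a, e_b, n: float = 4.0):
    """Nonlinear strain-avoidance addition ``(e_a^-n + e_b^-n)^(-1/n)``.

    Symmetric in its arguments, homogeneous of degree one, strictly
    increasing in each argument, bounded by ``min(e_a, e_b)``, and tends to
    the minimum as ``n -> inf``. Undefined (raises) for non-positive
    elongations.
    """
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    if n <= 0:
        raise ValueError("exponent n must be positive")
    if np.any(e_a <= 0) or np.any(e_b <= 0):
        raise ValueError("elongations must be strictly positive")
    out = (e_a ** (-n) + e_b ** (-n)) ** (-1.0 / n)
    return float(out) if out.ndim == 0 else out


def _directions(angles_deg: np.ndarray) -> np.ndarray:
    rad = np.deg2rad(angles_deg)
    return np.stack([np.cos(rad), np.sin(rad), np.zeros_like(rad)], axis=1)


def elongation_profile(strain: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """In-plane directional elongations ``1 + u^T eps u`` over an angle grid."""
    eps = np.asarray(strain, dtype=float)
    u = _directions(angles_deg)
    return 1.0 + np.einsum("ai,ij,aj->a", u, eps, u)


def _probe_tensor(fld: StrainField, probe: Sequence[float]) -> np.ndarray:
    return fld.strain_at(probe)


def cyclic_elongation_field(
    stretch_field: StrainField,
    probe: Sequence[float],
    angles_deg: np.ndarray | None = None,
) -> np.ndarray:
    """Directional elongations of the cyclic cue at a probe point.

    Computed from the *negated* peak-stretch strain (the release
    half-cycle): a pure uniaxial stretch therefore yields ``e_cyclic < 1``
    along the stretch axis and its maximum perpendicular to it.
    """
    if stretch_field.load.kind != "applied_stretch":
        raise ValueError("cyclic cue requires a field from an applied_stretch solve")
    if angles_deg is None:
        angles_deg = CombinationParams().angles()
    return elongation_profile(-_probe_tensor(stretch_field, probe), angles_deg)


def self_elongation_field(
    condensation_field: StrainField,
    probe: Sequence[float],
    angles_deg: np.ndarray | None = None,
) -> np.ndarray:
    """Directional elongations of the static self-condensation cue."""
    if condensation_field.load.kind != "self_condensation":
        raise ValueError("self cue requires a field from a self_condensation solve")
    if angles_deg is None:
        angles_deg = CombinationParams().angles()
    return elongation_profile(_probe_tensor(condensation_field, probe), angles_deg)


def fold_angle(angle_deg: float) -> float:
    """Fold an axial angle in [0, 180) onto [0, 90] from the stretch axis."""
    a = angle_deg % 180.0
    return 180.0 - a if a > 90.0 else a


def orientation_from_tensors(
    eps_cyclic_peak: np.ndarray | None,
    eps_self: np.ndarray | None,
    params: CombinationParams = CombinationParams(),
    scenario: str = "",
) -> OrientationPrediction:
    """Preferred orientation from the two probe strain tensors.

    Either tensor may be ``None`` (or zero), in which case that cue
    contributes a unit elongation in every direction (pure-cue limits).
    The cyclic tensor is the *peak stretch* strain; its negation (release
    half-cycle) is applied internally.
    """
    angles = params.angles()
    zero = np.zeros((3, 3))
    e_cyc = elongation_profile(
        -np.asarray(eps_cyclic_peak) if eps_cyclic_peak is not None else zero, angles
    )
    e_self = elongation_profile(
        np.asarray(eps_self) if eps_self is not None else zero, angles
    )
    e_tot = combine_elongations(e_cyc, e_self, params.n)
    profile = ElongationProfile(
        angles=angles, e_cyclic=e_cyc, e_self=e_self, e_tot=e_tot, n=params.n
    )

    spread = e_tot.max() - e_tot.min()
    if spread <= 1e-12 * max(1.0, abs(e_tot.max())):
        return OrientationPrediction(
            angle=float("nan"), profile=profile, scenario=scenario, degenerate=True
        )
    tol = 1e-12 * max(1.0, abs(e_tot.max()))
    at_max = np.nonzero(e_tot >= e_tot.max() - tol)[0]
    folded = np.array([fold_angle(a) for a in angles[at_max]])
    angle = float(folded.min())
    tie = len(np.unique(np.round(folded, 9))) > 1
    return OrientationPrediction(
        angle=angle, profile=profile, scenario=scenario, tie=tie
    )


def predict_orientation(
    stretch_field: StrainField | None,
    condensation_field: StrainField | None,
    params: CombinationParams,
    probe: Sequence[float],
    scenario: str = "",
) -> OrientationPrediction:
    """Combine the two solved fields at a probe point into an orientation.

    Ties between grid directions are broken toward the smaller folded angle
    and flagged; an exactly flat profile is reported as "no preferred
    direction" rather than an arbitrary angle.
    """
    eps_c = (
        _probe_tensor(stretch_field, probe) if stretch_field is not None else None
    )
    if stretch_field is not None and stretch_field.load.kind != "applied_stretch":
        raise ValueError("stretch_field must come from an applied_stretch solve")
    eps_s = (
        _probe_tensor(condensation_field, probe)
        if condensation_field is not None
        else None
    )
    if condensation_field is not None and condensation_field.load.kind != "self_condensation":
        raise ValueError("condensation_field must come from a self_condensation solve")
    return orientation_from_tensors(eps_c, eps_s, params, scenario=scenario)
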