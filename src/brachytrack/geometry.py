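"""Parametric geometry of the diverging-collimator gamma camera ring.

The system images a small, highly active Ir-192 brachytherapy source with six
compact detector panels arranged on a ring around the patient axis.  Each
panel carries a *diverging* collimator: a tungsten block whose square holes
all point at a single focal point located behind the detector, so the camera
sees a field of view larger than its own face (minification).  This module
holds the component specifications, the panel placement on the ring, and all
world <-> panel coordinate transforms.

Conventions
-----------
* Right-handed world frame, origin at the isocenter (center of the ring),
  ``z`` along the patient's longitudinal axis, units of mm throughout.
* Ring angles are measured counter-clockwise from ``+x`` in the ``xy`` plane.
* Panel-local coordinates put the origin at the collimator's focal point with
  ``+z_local`` pointing from the focal point toward the isocenter.  The
  detector-side collimator face then lies at ``z_local = F`` (the focal
  length) and the patient-side entrance face at ``z_local = F + h``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, GeometryError

__all__ = [
    "CollimatorSpec",
    "DetectorSpec",
    "PanelPose",
    "Panel",
    "SystemLayout",
    "SourceState",
    "Ray",
    "MCI_TO_BQ",
    "DEFAULT_RING_ANGLES",
    "DEFAULT_Z_OFFSETS",
    "focal_length",
    "hole_axis",
    "pixel_footprint",
    "build_layout",
    "default_layout",
]

#: Becquerel per millicurie.
MCI_TO_BQ = 3.7e7

#: Ring angles (degrees) of the six default panels.
DEFAULT_RING_ANGLES = (270.0, 306.0, 342.0, 18.0, 54.0, 90.0)

#: Default per-panel z staggering (mm), in ring-angle order.  Placing every
#: panel in one axial plane leaves the source's z coordinate poorly
#: constrained; an even stagger breaks that degeneracy while keeping each
#: panel within the effective field of view.
DEFAULT_Z_OFFSETS = (-25.0, -15.0, -5.0, 5.0, 15.0, 25.0)


@dataclass(frozen=True)
class CollimatorSpec:
    """Diverging tungsten collimator with a square hole array.

    Parameters
    ----------
    hole_size_d:
        Open hole width ``d`` (mm) on the detector-side face.
    septal_thickness_t:
        Tungsten wall width ``t`` (mm) between holes; the hole pitch is
        ``d + t`` and defaults to 0.6 mm.
    height_h:
        Collimator height ``h`` (mm) along the panel axis.
    holes_per_side:
        Holes per side of the square array (38 x 38 by default), matched 1:1
        to the detector pixel grid.
    acceptance_angle:
        Full field angle (degrees) subtended by the outermost hole axes; it
        fixes the focal length via :func:`focal_length`.
    attenuation_coeff:
        Linear attenuation coefficient of tungsten (1/mm) at the reference
        photon energy (default 0.625/mm, tungsten near 300 keV).
    focal_length_override:
        Explicit focal length (mm) that bypasses the acceptance-angle
        parameterization; use to realize alternative magnification
        conventions.
    """

    hole_size_d: float = 0.3
    septal_thickness_t: float = 0.3
    height_h: float = 30.0
    holes_per_side: int = 38
    acceptance_angle: float = 45.0
    attenuation_coeff: float = 0.625
    focal_length_override: float | None = None

    def __post_init__(self) -> None:
        if self.hole_size_d <= 0:
            raise ConfigurationError(f"hole size d must be > 0, got {self.hole_size_d}")
        if self.septal_thickness_t <= 0:
            raise ConfigurationError(
                f"septal thickness t must be > 0, got {self.septal_thickness_t}"
            )
        if self.height_h <= 0:
            raise ConfigurationError(f"collimator height must be > 0, got {self.height_h}")
        if self.holes_per_side < 1:
            raise ConfigurationError("holes_per_side must be >= 1")
        if not 0.0 < self.acceptance_angle < 180.0:
            raise ConfigurationError(
                f"acceptance angle must lie in (0, 180) degrees, got {self.acceptance_angle}"
            )
        if self.attenuation_coeff < 0:
            raise ConfigurationError("attenuation coefficient must be >= 0")

    @property
    def pitch(self) -> float:
        """Hole pitch ``d + t`` (mm)."""
        return self.hole_size_d + self.septal_thickness_t


@dataclass(frozen=True)
class DetectorSpec:
    """Pixelated scintillator panel (LYSO by default).

    The 38 x 38 pixel grid at 0.6 mm pitch spans 22.8 mm and sits centered on
    the 25.8 mm scintillator face; the 1.5 mm margins are dead area.  Each
    pixel has a 0.5 mm active aperture inside its 0.6 mm cell.
    """

    pixels_per_side: int = 38
    pixel_pitch: float = 0.6
    active_pixel_size: float = 0.5
    scintillator_thickness: float = 4.0
    face_size: float = 25.8

    def __post_init__(self) -> None:
        if self.pixels_per_side < 1:
            raise ConfigurationError("pixels_per_side must be >= 1")
        if self.active_pixel_size > self.pixel_pitch:
            raise ConfigurationError("active pixel size cannot exceed the pixel pitch")

    def pixel_offsets(self) -> np.ndarray:
        """1D pixel-center offsets (mm) from the panel axis, grid centered."""
        n = self.pixels_per_side
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch


@dataclass(frozen=True)
class PanelPose:
    """Placement of one panel on the detector ring.

    ``radius`` is the distance from the ring (z) axis to the collimator
    entrance face.  The panel normal points from the entrance face toward the
    z-shifted point ``(0, 0, z_offset)`` on the ring axis.
    """

    ring_angle: float
    radius: float = 500.0
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError(f"panel radius must be > 0, got {self.radius}")

    @property
    def orientation(self) -> np.ndarray:
        """Unit inward normal (toward the ring axis)."""
        th = math.radians(self.ring_angle)
        return np.array([-math.cos(th), -math.sin(th), 0.0])


def focal_length(collimator: CollimatorSpec, detector: DetectorSpec) -> float:
    """Distance F (mm) from the detector-side collimator face to the focal point.

    The acceptance angle is the full field angle spanned by the outermost hole
    axes across the detector face, so ``F = (face_size/2) / tan(angle/2)``.
    All hole axes pass through the focal point, which lies on the panel axis
    *behind* the detector.  ``focal_length_override`` on the collimator spec
    short-circuits this parameterization.
    """
    if collimator.focal_length_override is not None:
        return float(collimator.focal_length_override)
    half = math.radians(collimator.acceptance_angle) / 2.0
    return (detector.face_size / 2.0) / math.tan(half)


@dataclass(frozen=True)
class Ray:
    """A ray: world-frame point and unit direction."""

    point: np.ndarray
    direction: np.ndarray


@dataclass(frozen=True)
class Panel:
    """One detector + collimator assembly with its pose and local frame."""

    detector: DetectorSpec
    collimator: CollimatorSpec
    pose: PanelPose
    panel_id: int = 0

    # ---- derived frame ---------------------------------------------------

    @property
    def focal_len(self) -> float:
        return focal_length(self.collimator, self.detector)

    @property
    def axes(self) -> np.ndarray:
        """3x3 matrix whose columns are the local (u, v, n) axes in world frame.

        ``u`` is tangential in the ring plane, ``v`` is the world z axis and
        ``n`` the inward normal; (u, v, n) is right-handed.
        """
        th = math.radians(self.pose.ring_angle)
        u = np.array([math.sin(th), -math.cos(th), 0.0])
        v = np.array([0.0, 0.0, 1.0])
        n = np.array([-math.cos(th), -math.sin(th), 0.0])
        return np.column_stack([u, v, n])

    @property
    def entrance_center(self) -> np.ndarray:
        """World position of the collimator entrance-face center."""
        th = math.radians(self.pose.ring_angle)
        r = self.pose.radius
        return np.array([r * math.cos(th), r * math.sin(th), self.pose.z_offset])

    @property
    def focal_point(self) -> np.ndarray:
        """World position of the collimator focal point (behind the detector)."""
        out = -self.pose.orientation
        return self.entrance_center + (self.collimator.height_h + self.focal_len) * out

    # ---- transforms ------------------------------------------------------

    def to_panel(self, points: np.ndarray) -> np.ndarray:
        """World -> panel-local coordinates (origin at the focal point)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        local = (p - self.focal_point) @ self.axes
        return local.reshape(np.shape(points))

    def to_world(self, points: np.ndarray) -> np.ndarray:
        """Panel-local -> world coordinates."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        world = p @ self.axes.T + self.focal_point
        return world.reshape(np.shape(points))

    # ---- collimator/detector grids --------------------------------------

    def hole_offsets(self) -> np.ndarray:
        """1D hole-center offsets (mm) on the detector-side face."""
        n = self.collimator.holes_per_side
        return (np.arange(n) - (n - 1) / 2.0) * self.collimator.pitch


@dataclass(frozen=True)
class SystemLayout:
    """Ordered collection of panels sharing one world frame."""

    panels: tuple[Panel, ...]

    def __post_init__(self) -> None:
        angles = [p.pose.ring_angle for p in self.panels]
        if len(angles) > 1:
            diffs = [(b - a) % 360.0 for a, b in zip(angles, angles[1:])]
            if any(d <= 0.0 for d in diffs) or sum(diffs) >= 360.0:
                raise ConfigurationError(
                    "ring angles must be strictly increasing modulo 360"
                )

    def __len__(self) -> int:
        return len(self.panels)

    def __iter__(self):
        return iter(self.panels)

    def __getitem__(self, k: int) -> Panel:
        return self.panels[k]

    def with_collimator(self, collimator: CollimatorSpec) -> "SystemLayout":
        """Copy of the layout with every panel's collimator replaced."""
        return SystemLayout(
            tuple(replace(p, collimator=collimator) for p in self.panels)
        )


@dataclass(frozen=True)
class SourceState:
    """Cylindrical Ir-192 source capsule and its exposure.

    The default 0.6 mm diameter x 3.5 mm cylinder at 360 mCi matches a
    standard HDR afterloader source.
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    diameter: float = 0.6
    length: float = 3.5
    activity_bq: float = 360.0 * MCI_TO_BQ
    exposure_time: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ConfigurationError("source diameter and length must be > 0")
        if self.activity_bq < 0:
            raise ConfigurationError("source activity must be >= 0")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        ax = np.asarray(self.axis, dtype=float)
        nrm = np.linalg.norm(ax)
        if nrm == 0:
            raise ConfigurationError("source axis must be a nonzero vector")
        object.__setattr__(self, "axis", ax / nrm)

    def at(self, center: Sequence[float]) -> "SourceState":
        """Copy of this source moved to a new world position."""
        return replace(self, center=np.asarray(center, dtype=float))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_layout(
    radius: float,
    ring_angles: Sequence[float],
    z_offsets: Sequence[float],
    detector: DetectorSpec | None = None,
    collimator: CollimatorSpec | None = None,
) -> SystemLayout:
    """Place identical panels on a ring.

    Panel ``k`` has its collimator entrance-face center at
    ``(radius cos(theta_k), radius sin(theta_k), z_k)`` and its normal pointing
    at ``(0, 0, z_k)`` on the ring axis.
    """
    if len(ring_angles) != len(z_offsets):
        raise ConfigurationError(
            f"ring_angles ({len(ring_angles)}) and z_offsets ({len(z_offsets)}) "
            "must have the same length"
        )
    detector = detector or DetectorSpec()
    collimator = collimator or CollimatorSpec()
    panels = tuple(
        Panel(
            detector=detector,
            collimator=collimator,
            pose=PanelPose(ring_angle=float(a), radius=float(radius), z_offset=float(z)),
            panel_id=k,
        )
        for k, (a, z) in enumerate(zip(ring_angles, z_offsets))
    )
    return SystemLayout(panels)


def default_layout(
    detector: DetectorSpec | None = None,
    collimator: CollimatorSpec | None = None,
    radius: float = 500.0,
    z_offsets: Sequence[float] | None = None,
) -> SystemLayout:
    """The six-panel ring: 36-degree spacing from 270 to 90 degrees, staggered in z."""
    z = DEFAULT_Z_OFFSETS if z_offsets is None else z_offsets
    return build_layout(radius, DEFAULT_RING_ANGLES, z, detector, collimator)


def hole_axis(panel: Panel, i: int, j: int) -> Ray:
    """Axis of hole ``(i, j)``: through its center on the detector-side face
    and the focal point, directed away from the focal point into the FOV.

    ``i`` indexes the panel-local v (world z) direction, ``j`` the local u
    direction, matching image row/column order.
    """
    n = panel.collimator.holes_per_side
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"hole index ({i}, {j}) outside 0..{n - 1}")
    off = panel.hole_offsets()
    local = np.array([off[j], off[i], panel.focal_len])
    point = panel.to_world(local)
    direction = point - panel.focal_point
    direction = direction / np.linalg.norm(direction)
    return Ray(point=point, direction=direction)


def pixel_footprint(panel: Panel, i: int, j: int, distance_to_plane: float) -> np.ndarray:
    """Project pixel ``(i, j)``'s active area through its hole's acceptance
    cone onto a plane ``distance_to_plane`` mm in front of the detector face.

    Returns the 4x3 world-frame corner array of the (square) footprint.  At
    distance 0 the footprint is the pixel active area itself; it grows
    linearly with distance by the similar-triangles factor ``(F + D) / F``.
    """
    if distance_to_plane < 0:
        raise GeometryError("projection plane lies behind the detector")
    n = panel.detector.pixels_per_side
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"pixel index ({i}, {j}) outside 0..{n - 1}")
    off = panel.detector.pixel_offsets()
    half = panel.detector.active_pixel_size / 2.0
    cx, cy = off[j], off[i]
    corners = np.array(
        [[cx - half, cy - half], [cx + half, cy - half], [cx + half, cy + half], [cx - half, cy + half]]
    )
    F = panel.focal_len
    scale = (F + distance_to_plane) / F
    local = np.column_stack(
        [corners * scale, np.full(4, F + distance_to_plane)]
    )
    return panel.to_world(local)
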