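"""Landmark containers and slice geometry for scapular version measurement.

Glenoid version is measured on a *three-dimensionally corrected slice*: the
plane that contains the scapular axis (medial pole of the scapula to the
center of the glenoid surface) and is perpendicular to the scapular plane
(inferior tip of the scapular body, glenoid center, medial pole).  Working on
this reformatted plane removes scapular inclination and scanner gantry
effects from the measurement.

This module provides the :class:`LandmarkSet` container, the oriented
:class:`Plane` with an in-plane 2D frame, plane construction, orthogonal
projection into the slice, and the signed version angle primitive.  The sign
convention throughout is the clinical one: retroversion (posterior tilt of
the glenoid line) is positive, anteversion negative.

All coordinates are in millimetres in an arbitrary right-handed world frame;
anatomical orientation is resolved from the landmark labels, never from the
scanner axes, so every angle is invariant under rigid motion and uniform
scaling of the whole landmark set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .errors import DegenerateGeometryError, InputError, MissingLandmarkError

__all__ = [
    "REQUIRED_LANDMARKS",
    "OPTIONAL_LANDMARKS",
    "LandmarkSet",
    "Plane",
    "SlicePoint2D",
    "scapular_plane",
    "corrected_slice",
    "project",
    "signed_version_angle",
]

#: Landmarks every shoulder record must provide.
REQUIRED_LANDMARKS: tuple[str, ...] = (
    "inferior_angle",
    "glenoid_center",
    "medial_point",
    "medial_border_tip",
    "vault_tip",
    "anterior_rim",
    "posterior_rim",
)

#: Endpoints of the B2 intermediate glenoid line (biconcave glenoids).
OPTIONAL_LANDMARKS: tuple[str, ...] = (
    "anterior_rim_intermediate",
    "posterior_rim_intermediate",
)

SIDES = ("left", "right")
DOMINANCE = ("dominant", "nondominant", "unknown")

#: Collinearity threshold for the scapular-plane triangle (mm^2).
AREA_TOL_MM2 = 1e-6
#: Unit-length / orthogonality tolerance for plane frames.
UNIT_TOL = 1e-9
#: Minimum usable axis / chord length (mm).
LENGTH_TOL_MM = 1e-6


def _as_point(value, name: str) -> np.ndarray:
    p = np.asarray(value, dtype=float)
    if p.shape != (3,):
        raise InputError(f"landmark {name!r} must be a 3-vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise InputError(f"landmark {name!r} has non-finite coordinates: {p}")
    return p


def _triangle_area(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))


@dataclass(eq=False)
class LandmarkSet:
    """Named 3D anatomical landmarks for one shoulder (world mm).

    Parameters
    ----------
    shoulder_id : str
        Unique identifier of the shoulder record.
    side : {"left", "right"}
    dominance : {"dominant", "nondominant", "unknown"}
    points : mapping of landmark name to 3D coordinate (mm)
        Must contain all of :data:`REQUIRED_LANDMARKS`; may additionally
        contain the intermediate glenoid-line endpoints used for Walch B2
        glenoids.
    """

    shoulder_id: str
    side: str
    points: dict[str, np.ndarray]
    dominance: str = "unknown"

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise InputError(
                f"side must be one of {SIDES}, got {self.side!r} "
                f"(shoulder {self.shoulder_id!r})"
            )
        if self.dominance not in DOMINANCE:
            raise InputError(
                f"dominance must be one of {DOMINANCE}, got {self.dominance!r} "
                f"(shoulder {self.shoulder_id!r})"
            )
        known = set(REQUIRED_LANDMARKS) | set(OPTIONAL_LANDMARKS)
        unknown = sorted(set(self.points) - known)
        if unknown:
            raise InputError(
                f"unknown landmark name(s) {unknown} in shoulder "
                f"{self.shoulder_id!r}; known names are {sorted(known)}"
            )
        missing = [n for n in REQUIRED_LANDMARKS if n not in self.points]
        if missing:
            raise MissingLandmarkError(
                f"shoulder {self.shoulder_id!r} is missing required "
                f"landmark(s): {missing}"
            )
        self.points = {n: _as_point(p, n) for n, p in self.points.items()}

        area = _triangle_area(
            self.points["inferior_angle"],
            self.points["glenoid_center"],
            self.points["medial_point"],
        )
        if area < AREA_TOL_MM2:
            raise DegenerateGeometryError(
                "scapular-plane landmarks inferior_angle, glenoid_center and "
                f"medial_point are collinear (triangle area {area:.3g} mm^2) "
                f"in shoulder {self.shoulder_id!r}"
            )
        if (
            np.linalg.norm(self.points["anterior_rim"] - self.points["posterior_rim"])
            < LENGTH_TOL_MM
        ):
            raise DegenerateGeometryError(
                "anterior_rim and posterior_rim coincide in shoulder "
                f"{self.shoulder_id!r}"
            )

    def point(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(
                f"shoulder {self.shoulder_id!r} has no landmark {name!r}"
            ) from None

    def has(self, name: str) -> bool:
        return name in self.points

    def transformed(
        self, rotation: np.ndarray | None = None, translation=None, scale: float = 1.0
    ) -> "LandmarkSet":
        """Return a copy with ``p -> scale * R @ p + t`` applied to every
        landmark.  Used heavily in invariance tests and by the simulator."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        pts = {n: scale * (R @ p) + t for n, p in self.points.items()}
        return replace(self, points=pts)


@dataclass(frozen=True)
class SlicePoint2D:
    """In-slice coordinates (mm): x along medial→lateral, y posterior→anterior."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InputError(f"non-finite slice coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True, eq=False)
class Plane:
    """Oriented plane with a right-handed in-plane frame.

    ``normal = u_axis × v_axis`` holds to :data:`UNIT_TOL`; all three vectors
    are unit length and mutually orthogonal.
    """

    origin: np.ndarray
    normal: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "normal", "u_axis", "v_axis"):
            object.__setattr__(self, name, _as_point(getattr(self, name), name))
        for name in ("normal", "u_axis", "v_axis"):
            norm = float(np.linalg.norm(getattr(self, name)))
            if abs(norm - 1.0) > UNIT_TOL:
                raise DegenerateGeometryError(f"{name} is not unit length: |v|={norm!r}")
        for a, b in (("u_axis", "v_axis"), ("u_axis", "normal"), ("v_axis", "normal")):
            dot = abs(float(np.dot(getattr(self, a), getattr(self, b))))
            if dot > UNIT_TOL:
                raise DegenerateGeometryError(f"{a} and {b} are not orthogonal (|dot|={dot!r})")
        if np.linalg.norm(np.cross(self.u_axis, self.v_axis) - self.normal) > 1e-8:
            raise DegenerateGeometryError("plane frame is not right-handed (normal != u × v)")

    def signed_distance(self, point) -> float:
        return float(np.dot(np.asarray(point, float) - self.origin, self.normal))

    def contains(self, point, tol: float = 1e-6) -> bool:
        return abs(self.signed_distance(point)) < tol

    def to_world(self, p2d: SlicePoint2D) -> np.ndarray:
        """Map in-plane coordinates back to world coordinates."""
        return self.origin + p2d.x * self.u_axis + p2d.y * self.v_axis


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < LENGTH_TOL_MM:
        raise DegenerateGeometryError(f"{what} has (near-)zero length ({n:.3g} mm)")
    return v / n


def scapular_plane(landmarks: LandmarkSet) -> Plane:
    """Plane through the inferior tip of the scapular body, the glenoid
    center and the medial pole of the scapula.

    The returned plane's origin is the glenoid center; the in-plane frame is
    an arbitrary deterministic orthonormal pair (only the plane itself, not
    its frame, is consumed downstream).
    """
    gc = landmarks.point("glenoid_center")
    ia = landmarks.point("inferior_angle")
    mp = landmarks.point("medial_point")
    cr = np.cross(ia - gc, mp - gc)
    area = 0.5 * float(np.linalg.norm(cr))
    if area < AREA_TOL_MM2:
        raise DegenerateGeometryError(
            "cannot construct the scapular plane: inferior_angle, "
            "glenoid_center and medial_point are collinear or coincident "
            f"(triangle area {area:.3g} mm^2)"
        )
    normal = cr / np.linalg.norm(cr)
    u = _unit(ia - gc, "glenoid_center→inferior_angle")
    v = np.cross(normal, u)
    return Plane(origin=gc, normal=normal, u_axis=u, v_axis=v)


def corrected_slice(landmarks: LandmarkSet, scap_plane: Plane | None = None) -> Plane:
    """The three-dimensionally corrected measurement slice.

    The slice contains the scapular axis (medial_point → glenoid_center) and
    is perpendicular to the scapular plane.  Its 2D frame is anatomical:

    * ``u_axis`` points medial → lateral (from medial_point toward the
      glenoid center), so "the posterior rim is more medial" is a pure sign
      test on projected x;
    * ``v_axis`` points posterior → anterior, oriented so the projected
      anterior rim has y ≥ the projected posterior rim.

    Because the frame is anchored to the anatomical labels, the retroversion
    sign convention holds identically for left and right shoulders — a left
    scapula is implicitly mirrored by the label-resolved frame.
    """
    if scap_plane is None:
        scap_plane = scapular_plane(landmarks)
    gc = landmarks.point("glenoid_center")
    mp = landmarks.point("medial_point")
    axis = gc - mp
    if np.linalg.norm(axis) < LENGTH_TOL_MM:
        raise DegenerateGeometryError(
            "glenoid_center and medial_point coincide; the scapular axis is undefined"
        )
    u = axis / np.linalg.norm(axis)
    # The slice normal is perpendicular to the axis and lies in the scapular
    # plane, so the slice contains the scapular plane's normal direction.
    n = _unit(np.cross(u, scap_plane.normal), "slice normal")
    v = np.cross(n, u)
    plane = Plane(origin=mp, normal=n, u_axis=u, v_axis=v)
    y_ant = project(landmarks.point("anterior_rim"), plane).y
    y_post = project(landmarks.point("posterior_rim"), plane).y
    if y_ant < y_post:
        plane = Plane(origin=mp, normal=-n, u_axis=u, v_axis=-v)
    return plane


def project(point, plane: Plane) -> SlicePoint2D:
    """Orthogonal projection of a world point into the plane's 2D frame."""
    d = np.asarray(point, dtype=float) - plane.origin
    return SlicePoint2D(float(np.dot(d, plane.u_axis)), float(np.dot(d, plane.v_axis)))


def signed_version_angle(
    glenoid_ant: SlicePoint2D,
    glenoid_post: SlicePoint2D,
    axis_origin: SlicePoint2D,
    axis_end: SlicePoint2D,
) -> float:
    """Signed angle (degrees) between the glenoid line and the perpendicular
    to the reference axis, in the corrected slice.

    Positive = retroversion: the posterior rim lies medial to the anterior
    rim relative to the axis direction (axis_origin → axis_end, medial →
    lateral).  The magnitude is the acute angle between the glenoid *line*
    and the perpendicular line; the sign comes from the rim labels alone, so
    swapping which rim is called anterior negates the result, as does
    reflecting the configuration across the axis perpendicular (turning
    retroversion into anteversion).
    """
    g = glenoid_ant.as_array() - glenoid_post.as_array()
    a = axis_end.as_array() - axis_origin.as_array()
    if np.linalg.norm(g) < LENGTH_TOL_MM:
        raise DegenerateGeometryError("glenoid line has zero length")
    if np.linalg.norm(a) < LENGTH_TOL_MM:
        raise DegenerateGeometryError("reference axis has zero length")
    perp = np.array([-a[1], a[0]])  # axis rotated +90° (toward anterior)
    theta = math.degrees(math.atan2(g[0] * perp[1] - g[1] * perp[0], float(np.dot(g, perp))))
    # acute line-vs-line magnitude ...
    if theta > 90.0:
        theta -= 180.0
    elif theta <= -90.0:
        theta += 180.0
    # ... signed by the rim labels: positive exactly when the labelled
    # posterior rim sits medial to the anterior rim along the axis direction.
    # Swapping the labels, or reflecting across the axis perpendicular,
    # negates the angle; reflecting across the axis line itself leaves it
    # unchanged (the mirrored shoulder has the same retroversion).
    medial_lateral = float(np.dot(g, a))
    if medial_lateral > 0.0:
        return abs(theta)
    if medial_lateral < 0.0:
        return -abs(theta)
    return theta  # glenoid line exactly perpendicular to the axis: neutral
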