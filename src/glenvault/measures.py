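"""The two glenoid version measurements: conventional (Friedman) and vault.

Both methods share the *glenoid line* — the chord from the anterior to the
posterior rim of the glenoid on the corrected slice (for Walch B2 biconcave
glenoids, the *intermediate* line between the native and erosion surfaces is
used instead).  They differ only in the reference axis:

* **conventional** — the scapular axis, from the tip of the medial border of
  the scapula to the center of the glenoid line.  Sensitive to scapular body
  shape (flat, round or wavy bodies tilt this axis).
* **vault** — the glenoid vault axis, from the medial tip of the triangular
  scapular vault to the center of the glenoid line.  Independent of the
  scapular body, hence proposed as the more faithful "glenoid" version.

Version is the signed angle between the glenoid line and the perpendicular
to the chosen axis; retroversion positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError, MissingLandmarkError
from .geometry import (
    LandmarkSet,
    Plane,
    SlicePoint2D,
    corrected_slice,
    project,
    scapular_plane,
    signed_version_angle,
)

__all__ = [
    "METHODS",
    "VARIANTS",
    "VersionResult",
    "glenoid_line",
    "conventional_version",
    "vault_version",
    "measure",
    "measure_cohort",
    "method_difference",
]

METHODS = ("conventional", "vault")
VARIANTS = ("standard", "intermediate")

_VARIANT_RIMS = {
    "standard": ("anterior_rim", "posterior_rim"),
    "intermediate": ("anterior_rim_intermediate", "posterior_rim_intermediate"),
}

_AXIS_LANDMARK = {"conventional": "medial_border_tip", "vault": "vault_tip"}


@dataclass(frozen=True)
class VersionResult:
    """A single signed version angle with its provenance.

    ``version_deg`` is in degrees, retroversion positive, and lies in
    (−90°, 90°).  ``slice_coordinates`` optionally records the projected 2D
    landmarks (mm) used for the measurement, for auditing.
    """

    shoulder_id: str
    method: str
    glenoid_line_variant: str
    version_deg: float
    slice_coordinates: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InputError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.glenoid_line_variant not in VARIANTS:
            raise InputError(
                f"glenoid_line_variant must be one of {VARIANTS}, "
                f"got {self.glenoid_line_variant!r}"
            )
        if not -90.0 < self.version_deg < 90.0:
            raise InputError(
                f"version_deg must lie in (-90, 90), got {self.version_deg!r} "
                f"(shoulder {self.shoulder_id!r})"
            )


def glenoid_line(
    landmarks: LandmarkSet,
    variant: str = "standard",
    slice_plane: Plane | None = None,
) -> tuple[SlicePoint2D, SlicePoint2D, SlicePoint2D]:
    """Projected glenoid-line endpoints and their midpoint in the slice.

    Returns ``(anterior, posterior, center)`` where *center* is the midpoint
    of the chord ("the center of the glenoid line"), the distal endpoint of
    both measurement axes.
    """
    if variant not in VARIANTS:
        raise InputError(f"variant must be one of {VARIANTS}, got {variant!r}")
    ant_name, post_name = _VARIANT_RIMS[variant]
    for name in (ant_name, post_name):
        if not landmarks.has(name):
            raise MissingLandmarkError(
                f"glenoid-line variant {variant!r} requires landmark {name!r}, "
                f"absent from shoulder {landmarks.shoulder_id!r}"
            )
    if slice_plane is None:
        slice_plane = corrected_slice(landmarks)
    ant = project(landmarks.point(ant_name), slice_plane)
    post = project(landmarks.point(post_name), slice_plane)
    mid = SlicePoint2D(0.5 * (ant.x + post.x), 0.5 * (ant.y + post.y))
    return ant, post, mid


def _measure(
    landmarks: LandmarkSet,
    method: str,
    variant: str,
    audit: bool,
) -> VersionResult:
    axis_name = _AXIS_LANDMARK[method]
    if not landmarks.has(axis_name):
        raise MissingLandmarkError(
            f"{method} method requires landmark {axis_name!r}, absent from "
            f"shoulder {landmarks.shoulder_id!r}"
        )
    scap = scapular_plane(landmarks)
    slc = corrected_slice(landmarks, scap)
    ant, post, mid = glenoid_line(landmarks, variant, slc)
    axis_origin = project(landmarks.point(axis_name), slc)
    angle = signed_version_angle(ant, post, axis_origin, mid)
    coords = None
    if audit:
        coords = {n: (p2.x, p2.y) for n, p2 in
                  ((n, project(p, slc)) for n, p in landmarks.points.items())}
        coords["glenoid_line_center"] = (mid.x, mid.y)
    return VersionResult(
        shoulder_id=landmarks.shoulder_id,
        method=method,
        glenoid_line_variant=variant,
        version_deg=angle,
        slice_coordinates=coords,
    )


def conventional_version(
    landmarks: LandmarkSet, variant: str = "standard", audit: bool = False
) -> VersionResult:
    """Glenoid version by the conventional (Friedman) method: angle between
    the glenoid line and the perpendicular to the scapular axis
    (medial_border_tip → center of the glenoid line)."""
    return _measure(landmarks, "conventional", variant, audit)


def vault_version(
    landmarks: LandmarkSet, variant: str = "standard", audit: bool = False
) -> VersionResult:
    """Glenoid version by the vault method: angle between the glenoid line
    and the perpendicular to the glenoid vault axis (vault_tip → center of
    the glenoid line)."""
    return _measure(landmarks, "vault", variant, audit)


def measure(
    landmarks: LandmarkSet,
    method: str = "both",
    variant: str = "standard",
    audit: bool = False,
) -> list[VersionResult]:
    """Measure one shoulder with one or both methods."""
    if method == "both":
        wanted: Sequence[str] = METHODS
    elif method in METHODS:
        wanted = (method,)
    else:
        raise InputError(f"method must be 'both' or one of {METHODS}, got {method!r}")
    return [_measure(landmarks, m, variant, audit) for m in wanted]


def measure_cohort(
    landmark_sets: Iterable[LandmarkSet],
    method: str = "both",
    variant: str = "standard",
) -> pd.DataFrame:
    """Measure every shoulder and return a tidy results table.

    Columns: shoulder_id, side, dominance, method, variant, version_deg.
    """
    rows = []
    for lm in landmark_sets:
        for res in measure(lm, method=method, variant=variant):
            rows.append(
                {
                    "shoulder_id": res.shoulder_id,
                    "side": lm.side,
                    "dominance": lm.dominance,
                    "method": res.method,
                    "variant": res.glenoid_line_variant,
                    "version_deg": res.version_deg,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["shoulder_id", "side", "dominance", "method", "variant", "version_deg"],
    )


def method_difference(result_vault: VersionResult, result_conv: VersionResult) -> float:
    """Vault version minus conventional version (signed degrees) for one
    shoulder; positive when the vault method reads more retroverted."""
    if result_vault.shoulder_id != result_conv.shoulder_id:
        raise InputError(
            "method_difference requires results from the same shoulder, got "
            f"{result_vault.shoulder_id!r} and {result_conv.shoulder_id!r}"
        )
    if result_vault.method != "vault" or result_conv.method != "conventional":
        raise InputError(
            "method_difference expects (vault, conventional) results, got "
            f"({result_vault.method!r}, {result_conv.method!r})"
        )
    return result_vault.version_deg - result_conv.version_deg
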