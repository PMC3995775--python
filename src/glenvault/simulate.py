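"""Synthetic scapular landmark sets with known ground-truth version.

The generator inverts the measurement construction: a shoulder is laid out
in a canonical slice frame where every angle is exact, then embedded in 3D
with a labelled inclination tilt and an arbitrary rigid transform.  In the
canonical frame (x medial→lateral, y posterior→anterior, z inferior→superior):

* the glenoid-line center sits at the glenoid center (origin);
* the glenoid line of width *w* is rotated by the true vault version γ from
  the posterior→anterior direction;
* the vault tip lies on the medial axis at the vault depth, so the vault
  axis is exactly the +x direction and the measured vault version is γ;
* the tip of the medial border is placed so the conventional (scapular)
  axis makes the *body-shape offset* angle with the vault axis, giving
  conventional version = vault version − offset.  This single angle is the
  minimal parametrization of the claim that scapular body shape biases the
  conventional method but not the vault method;
* the medial pole and the inferior angle of the scapular body span the
  scapular plane; left shoulders mirror the construction's chirality.

Cohort presets (``normal``, ``arthritic``, ``paired``) carry Gaussian
ground-truth distributions emulating reported normal and arthritic shoulder
populations; observer noise is isotropic Gaussian displacement of every
landmark (mm), so rater error propagates through the true geometry rather
than being added to angles directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .errors import InputError
from .geometry import LandmarkSet
from .measures import measure, vault_version
from .reliability import RatingMatrix

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "PRESETS",
    "load_preset",
    "build_shoulder",
    "generate_cohort",
    "simulate_raters",
    "calibrate_landmark_noise",
    "ground_truth_frame",
]

PRESETS = ("normal", "arthritic", "paired")


@dataclass
class CohortSpec:
    """Generative parameters for a synthetic cohort.

    Ground-truth vault version and the body-shape offset (vault axis vs
    scapular axis, so conventional = vault − offset) are Gaussian; the
    dominance shift is added to the dominant side's vault version in paired
    mode.  Angles in degrees, lengths in mm.
    """

    n_shoulders: int = 150
    vault_version_mean_deg: float = 8.9
    vault_version_sd_deg: float = 2.7
    body_offset_mean_deg: float = 7.8
    body_offset_sd_deg: float = 1.718
    dominance_shift_deg: float = 0.0
    paired: bool = False
    inclination_range_deg: tuple[float, float] = (0.0, 30.0)
    landmark_noise_sd_mm: float = 0.0
    random_transform: bool = True
    glenoid_width_mm: float = 28.0
    vault_depth_mm: float = 30.0
    medial_border_mm: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_shoulders < 1:
            raise InputError(f"n_shoulders must be ≥ 1, got {self.n_shoulders}")
        for name in ("vault_version_sd_deg", "body_offset_sd_deg", "landmark_noise_sd_mm"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be ≥ 0, got {getattr(self, name)}")
        for name in ("glenoid_width_mm", "vault_depth_mm", "medial_border_mm"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0, got {getattr(self, name)}")
        lo, hi = self.inclination_range_deg
        if not (lo <= hi):
            raise InputError(f"invalid inclination range {self.inclination_range_deg}")
        if self.paired and self.n_shoulders % 2:
            raise InputError(
                f"paired mode needs an even n_shoulders, got {self.n_shoulders}"
            )


@dataclass(frozen=True)
class GroundTruth:
    """The generating angles behind one synthetic shoulder."""

    shoulder_id: str
    true_vault_version_deg: float
    true_conventional_version_deg: float
    body_offset_deg: float
    side: str
    dominance: str

    def __post_init__(self) -> None:
        resid = abs(
            self.true_conventional_version_deg
            - (self.true_vault_version_deg - self.body_offset_deg)
        )
        if resid > 1e-9:
            raise InputError(
                "ground truth inconsistent: conventional must equal "
                f"vault − offset (residual {resid:.3g}°)"
            )


def load_preset(name: str, **overrides) -> CohortSpec:
    """Load a shipped cohort preset (``normal``, ``arthritic``, ``paired``),
    optionally overriding fields (e.g. ``seed=...``, ``n_shoulders=...``)."""
    if name not in PRESETS:
        raise InputError(f"unknown preset {name!r}; available: {PRESETS}")
    text = resources.files("glenvault.presets").joinpath(f"{name}_cohort.yaml").read_text()
    cfg = yaml.safe_load(text)
    cfg.pop("description", None)
    if "inclination_range_deg" in cfg:
        cfg["inclination_range_deg"] = tuple(cfg["inclination_range_deg"])
    cfg.update(overrides)
    return CohortSpec(**cfg)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (normalized Gaussian quaternion)."""
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def build_shoulder(
    true_vault_deg: float,
    body_offset_deg: float,
    *,
    shoulder_id: str = "S0",
    side: str = "right",
    dominance: str = "unknown",
    inclination_deg: float = 0.0,
    glenoid_width_mm: float = 28.0,
    vault_depth_mm: float = 30.0,
    medial_border_mm: float = 100.0,
    intermediate_offset_deg: float | None = None,
    rotation: np.ndarray | None = None,
    translation: Sequence[float] | None = None,
) -> tuple[LandmarkSet, GroundTruth]:
    """Construct one synthetic shoulder realizing exact version angles.

    At zero landmark noise, measuring the returned :class:`LandmarkSet`
    recovers ``true_vault_deg`` (vault method) and
    ``true_vault_deg − body_offset_deg`` (conventional method) to well below
    1e-6°.  ``intermediate_offset_deg``, if given, adds an intermediate
    glenoid line rotated by that extra angle (Walch B2 emulation).
    ``rotation``/``translation`` place the shoulder in world coordinates;
    ``inclination_deg`` additionally tilts the scapular axis out of the
    reference axial plane (a labelled component of the placement to which
    all measurements are invariant by construction).
    """
    true_conv_deg = true_vault_deg - body_offset_deg
    if not abs(true_vault_deg) < 90:
        raise InputError(f"|true vault version| must be < 90°, got {true_vault_deg}")
    if not abs(true_conv_deg) < 90:
        raise InputError(
            f"implied conventional version {true_conv_deg}° out of range (−90°, 90°)"
        )
    gamma = math.radians(true_vault_deg)
    off = math.radians(body_offset_deg)
    w = glenoid_width_mm / 2.0

    line_dir = np.array([math.sin(gamma), math.cos(gamma), 0.0])
    pts = {
        "glenoid_center": np.zeros(3),
        "medial_point": np.array([-medial_border_mm, 0.0, 0.0]),
        "anterior_rim": w * line_dir,
        "posterior_rim": -w * line_dir,
        "vault_tip": np.array([-vault_depth_mm, 0.0, 0.0]),
        "medial_border_tip": np.array(
            [-medial_border_mm * math.cos(off), medial_border_mm * math.sin(off), 0.0]
        ),
        # scapular body: inferior angle below the axis, in the plane spanned
        # by the axis and the slice normal
        "inferior_angle": np.array([-0.7 * medial_border_mm, 0.0, -0.8 * medial_border_mm]),
    }
    if intermediate_offset_deg is not None:
        gi = gamma + math.radians(intermediate_offset_deg)
        idir = np.array([math.sin(gi), math.cos(gi), 0.0])
        pts["anterior_rim_intermediate"] = w * idir
        pts["posterior_rim_intermediate"] = -w * idir

    if side == "left":  # mirror chirality; label-anchored measurement is unaffected
        for p in pts.values():
            p[1] = -p[1]

    R_inc = Rotation.from_rotvec([0.0, math.radians(inclination_deg), 0.0]).as_matrix()
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    pts = {n: R @ (R_inc @ p) + t for n, p in pts.items()}

    lm = LandmarkSet(shoulder_id=shoulder_id, side=side, dominance=dominance, points=pts)
    gt = GroundTruth(
        shoulder_id=shoulder_id,
        true_vault_version_deg=float(true_vault_deg),
        true_conventional_version_deg=float(true_conv_deg),
        body_offset_deg=float(body_offset_deg),
        side=side,
        dominance=dominance,
    )
    return lm, gt


def _place(spec: CohortSpec, rng: np.random.Generator):
    lo, hi = spec.inclination_range_deg
    incl = float(rng.uniform(lo, hi))
    R = _random_rotation(rng) if spec.random_transform else None
    t = rng.uniform(-100.0, 100.0, size=3) if spec.random_transform else None
    return incl, R, t


def _maybe_noise(lm: LandmarkSet, sd: float, rng: np.random.Generator) -> LandmarkSet:
    if sd <= 0:
        return lm
    pts = {n: p + rng.normal(0.0, sd, size=3) for n, p in lm.points.items()}
    return LandmarkSet(lm.shoulder_id, lm.side, pts, lm.dominance)


def generate_cohort(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> tuple[list[LandmarkSet], list[GroundTruth]]:
    """Draw a synthetic cohort from a :class:`CohortSpec`.

    Unpaired mode emits ``spec.n_shoulders`` independent shoulders.  Paired
    mode emits dominant/nondominant pairs (``n_shoulders/2`` subjects,
    shoulder ids ``P####-R``/``P####-L``): both sides share the subject's
    baseline vault version, with ``dominance_shift_deg`` added on the
    dominant side.  Fixed ``spec.seed`` makes the output bit-reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    geom = dict(
        glenoid_width_mm=spec.glenoid_width_mm,
        vault_depth_mm=spec.vault_depth_mm,
        medial_border_mm=spec.medial_border_mm,
    )
    landmarks: list[LandmarkSet] = []
    truths: list[GroundTruth] = []

    if not spec.paired:
        for i in range(spec.n_shoulders):
            vault = float(rng.normal(spec.vault_version_mean_deg, spec.vault_version_sd_deg))
            offset = float(rng.normal(spec.body_offset_mean_deg, spec.body_offset_sd_deg))
            side = "right" if rng.random() < 0.5 else "left"
            incl, R, t = _place(spec, rng)
            lm, gt = build_shoulder(
                vault, offset, shoulder_id=f"S{i:04d}", side=side,
                dominance="unknown", inclination_deg=incl,
                rotation=R, translation=t, **geom,
            )
            landmarks.append(_maybe_noise(lm, spec.landmark_noise_sd_mm, rng))
            truths.append(gt)
        return landmarks, truths

    n_subjects = spec.n_shoulders // 2
    for i in range(n_subjects):
        baseline = float(rng.normal(spec.vault_version_mean_deg, spec.vault_version_sd_deg))
        dom_side = "right" if rng.random() < 0.92 else "left"  # most are right-dominant
        for dominance in ("dominant", "nondominant"):
            vault = baseline + (spec.dominance_shift_deg if dominance == "dominant" else 0.0)
            offset = float(rng.normal(spec.body_offset_mean_deg, spec.body_offset_sd_deg))
            side = dom_side if dominance == "dominant" else ("left" if dom_side == "right" else "right")
            incl, R, t = _place(spec, rng)
            lm, gt = build_shoulder(
                vault, offset,
                shoulder_id=f"P{i:04d}-{'R' if side == 'right' else 'L'}",
                side=side, dominance=dominance, inclination_deg=incl,
                rotation=R, translation=t, **geom,
            )
            landmarks.append(_maybe_noise(lm, spec.landmark_noise_sd_mm, rng))
            truths.append(gt)
    return landmarks, truths


def ground_truth_frame(truths: Iterable[GroundTruth]) -> pd.DataFrame:
    """Ground-truth records as a tidy table."""
    return pd.DataFrame([asdict(t) for t in truths])


def simulate_raters(
    cohort: Sequence[LandmarkSet],
    noise_sd_mm: float | Sequence[float],
    n_raters: int = 3,
    n_sessions: int = 2,
    rng: np.random.Generator | int | None = None,
    methods: Sequence[str] = ("conventional", "vault"),
    variant: str = "standard",
) -> dict[str, RatingMatrix]:
    """Emulate a multi-rater repeated-measurement study.

    Each rater, in each session, re-identifies every landmark with isotropic
    Gaussian error (``noise_sd_mm``; scalar, or one value per rater) and the
    measurement pipeline is re-run from the perturbed landmarks.  Returns
    one (subjects × raters × sessions) :class:`RatingMatrix` per method;
    both methods are measured from the *same* perturbed landmarks, as a real
    rater session would.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    sds = np.broadcast_to(np.asarray(noise_sd_mm, dtype=float), (n_raters,))
    if np.any(sds < 0):
        raise InputError("noise_sd_mm must be ≥ 0")
    n = len(cohort)
    values = {m: np.empty((n, n_raters, n_sessions)) for m in methods}
    for i, lm in enumerate(cohort):
        for j in range(n_raters):
            for s in range(n_sessions):
                noisy = _maybe_noise(lm, float(sds[j]), rng)
                for res in measure(noisy, method="both", variant=variant):
                    if res.method in values:
                        values[res.method][i, j, s] = res.version_deg
    subject_ids = [lm.shoulder_id for lm in cohort]
    rater_ids = [f"rater{j + 1}" for j in range(n_raters)]
    return {
        m: RatingMatrix(values=v, subject_ids=subject_ids, rater_ids=rater_ids)
        for m, v in values.items()
    }


def calibrate_landmark_noise(
    target_angle_sd_deg: float = 0.9,
    spec: CohortSpec | None = None,
    n_pilot: int = 200,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Landmark noise (mm) producing a given vault-angle measurement SD.

    Angle error is linear in landmark noise over the working range, so a
    single pilot run at 1 mm fixes the slope: perturb ``n_pilot`` preset
    shoulders once each, measure the vault version error SD, and rescale.
    Deterministic for a fixed ``rng`` seed.
    """
    if target_angle_sd_deg <= 0:
        raise InputError("target_angle_sd_deg must be > 0")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if spec is None:
        spec = load_preset("normal")
    pilot_spec = CohortSpec(**{**asdict(spec), "n_shoulders": n_pilot,
                               "landmark_noise_sd_mm": 0.0, "paired": False})
    landmarks, truths = generate_cohort(pilot_spec, rng=rng)
    sigma0 = 1.0
    errs = np.empty(n_pilot)
    for i, (lm, gt) in enumerate(zip(landmarks, truths)):
        noisy = _maybe_noise(lm, sigma0, rng)
        errs[i] = vault_version(noisy).version_deg - gt.true_vault_version_deg
    slope = float(errs.std(ddof=1)) / sigma0  # degrees of angle SD per mm of noise
    return target_angle_sd_deg / slope
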