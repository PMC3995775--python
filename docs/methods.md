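# Methods

## Measurement model

A shoulder is represented by named 3D anatomical landmarks in world
millimetres (an arbitrary right-handed scanner frame).  All constructions
are anchored to the landmark *labels*, never to scanner axes, so every
reported angle is invariant under rigid motion and uniform scaling of the
landmark set; tests verify this to 1e-6° under random rotations and
translations.

1. **Scapular plane** — the plane through the inferior tip of the scapular
   body, the center of the glenoid surface, and the medial pole of the
   scapula.
2. **Corrected slice** — the plane containing the scapular axis (medial
   pole → glenoid center) and perpendicular to the scapular plane.  Its 2D
   frame is anatomical: `u` runs medial → lateral along the axis; `v` is
   oriented so the projected anterior rim has the larger `y` than the
   posterior rim.  Because `v` is resolved from the rim labels, one sign
   convention (retroversion positive) holds for left and right shoulders
   alike — a left scapula is implicitly mirrored by its own labels, with no
   side-specific code path.
3. **Glenoid line** — the chord between the projected anterior and
   posterior rims (or the caller-supplied *intermediate* rims for biconcave
   B2 glenoids; the package never infers Walch morphology, the variant is an
   input).  Its midpoint is "the center of the glenoid line".
4. **Version** — the signed angle between the glenoid line and the
   perpendicular to the reference axis: the conventional method's axis runs
   from the tip of the medial border of the scapula to the glenoid-line
   center; the vault method's axis from the tip of the scapular vault to the
   same center.  Both methods share the identical glenoid line and differ
   only in the axis.

### Sign convention

Retroversion is positive: the angle is positive exactly when the labelled
posterior rim lies medial to the anterior rim along the axis direction.
The magnitude is the acute line-versus-line angle, so the value lies in
(−90°, 90°].  Consequences, encoded as tests: swapping the anterior and
posterior labels negates the angle (labels, not raw geometry, carry the
sign); reflecting the configuration across the axis perpendicular turns
retroversion into the same amount of anteversion; reflecting across the
axis line itself leaves the value unchanged (the mirrored shoulder — the
other-side anatomy — has the same retroversion).  These three properties
cannot all be antisymmetries simultaneously (their composition is the
identity up to relabelling), and this set is the one consistent with the
verbal definition above.

### Landmark vocabulary

The medial reference of the scapular axis is called the medial pole of the
scapula or the root of the scapular spine in different descriptions of the
same construction; the schema exposes a single `medial_point`.  The
conventional method's `medial_border_tip` is kept as a separate landmark —
some protocols use the same point for both — and callers may supply
identical coordinates to alias them.  `vault_tip` is a supplied landmark
(the medial apex of the triangular vault as seen on the corrected slice);
no vault segmentation is attempted.

### Numerical choices

Collinearity of the three scapular-plane landmarks is declared below a
triangle area of 1e-6 mm²; plane frames are orthonormal to 1e-9; axes and
chords shorter than 1e-6 mm are degenerate.  Angles are carried at full
double precision internally; the CLI rounds output to 0.1° by default
(`--round 0`, i.e. no rounding, for full precision), matching how such
angles are conventionally reported.

## Reliability statistics

Intrarater reliability is the one-way random-effects single-measure
ICC(1,1) per rater across sessions; interrater reliability is the two-way
random-effects absolute-agreement single-measure ICC(2,1) across raters.
Estimates come from the classical ANOVA mean squares; 95% confidence
intervals use the F-distribution-based Shrout–Fleiss formulation
(Satterthwaite degrees of freedom for ICC(2,1)), cross-checked in the test
suite against both an explicit sums-of-squares oracle and an independent
implementation (pingouin).  The interrater table uses each rater's session
means by default — symmetric in the raters and using all data — with a
first-session-only option, since a multi-session design does not dictate
which session enters the interrater analysis.  Negative estimates are
reported as computed (with a warning), not truncated; an all-constant table
is an error rather than a coefficient.

## Cohort statistics

Per-shoulder values are first averaged over raters and sessions (an explicit
aggregation step).  Method and side comparisons use the two-sided Wilcoxon
signed-rank test: zero differences are dropped before ranking (Wilcoxon's
original treatment; Pratt's is deliberately not used), the exact null
distribution is enumerated for ≤25 informative untied pairs, and the
tie-corrected normal approximation is used otherwise.  Distribution spreads
are compared with a two-sided variance-ratio F-test (larger variance over
smaller, doubling the upper tail), symmetric in its arguments.  α = 0.05
throughout; p-values print to three decimals.  No multiplicity correction
is applied.

## Synthetic scapula generator

The generator inverts the measurement: each shoulder is laid out in a
canonical slice frame where the vault axis is the medial-lateral direction,
the glenoid line (width 28 mm) is rotated by the true vault version, the
vault tip sits 30 mm medial of the glenoid-line center, and the medial
border tip (100 mm) is rotated off the vault axis by the **body-shape
offset**, so that conventional version = vault version − offset by
construction.  These lengths are plausible adult scapular dimensions; the
angles are scale-invariant, so the lengths matter only for how landmark
noise propagates into angle noise.  The configuration is then tilted by a
labelled **inclination** angle (rotation of the scapular axis out of the
reference axial plane — a controllable component of placement, to which the
corrected-slice construction is invariant by design) and embedded with a
uniform random rotation and translation.  Zero-noise round-trip identity —
measurement recovers the generating angles to 1e-6° across vault version
−20°…60°, offset −15°…15°, inclination 0°…30°, both sides, arbitrary
placement — is the generator's core guarantee and is enforced by tests.

The single-angle body-shape offset is the minimal parametrization of the
central claim that scapular body shape biases the conventional but not the
vault method; it does not model specific body morphologies (flat / round /
wavy) or glenoid surface shape, and the arthritic preset uses the standard
glenoid line for all shoulders rather than per-morphology intermediate
lines.  Passing tests therefore demonstrate correctness of the measurement
constructions and statistics under this idealized anatomy, not robustness
to real segmentation or landmark-identification error.

### Cohort presets

Ground-truth distributions are Gaussian (only means and SDs are specified
by the reference measurements the presets emulate).  With vault version and
offset independent, conventional variance = vault variance + offset
variance, which fixes the offset SD:

| preset    | vault (deg)   | offset (deg)        | implied conventional |
|-----------|---------------|---------------------|----------------------|
| normal    | 8.9 ± 2.7     | 7.8 ± √(3.2²−2.7²)=1.718 | 1.1 ± 3.2       |
| arthritic | 18.2 ± 9.1    | 7.4 ± √(9.3²−9.1²)=1.918 | 10.8 ± 9.3      |
| paired    | 8.2 ± 2.6 (nondominant baseline), +1.4 on the dominant side | 7.4 ± 1.688 | 0.8 ± 3.1 |

In paired mode both sides share the subject's baseline vault version; the
dominance shift applies to the vault (the side-to-side difference arises in
the vault, not the scapular body).  Sampling n = 150 shoulders at zero
landmark noise recovers the preset means within the 3-standard-error CLT
bound, end to end through the 3D pipeline.

### Observer noise and reliability simulation

Rater error is modelled as isotropic Gaussian displacement of every
landmark (mm) — noise propagates through the true geometry, not added to
angles.  `calibrate_landmark_noise` converts a target angle-error SD into a
landmark SD via a pilot simulation (angle error is linear in landmark noise
over the working range; the calibration is seeded and deterministic).  The
reliability simulation targets a 0.9° angle SD against the normal preset's
2.7° between-shoulder spread, i.e. a true vault-method reliability of
2.7²/(2.7²+0.9²) ≈ 0.90; on a 150-shoulder × 3-rater × 2-session design
every intra- and interrater coefficient then estimates above 0.85.  The
conventional method, with its longer axis, is less noise-sensitive per mm
and scores higher under the same landmark noise.

## Problem sizes

Simulated studies use 150 shoulders (75 pairs in paired mode), three raters
and two sessions — the design scale of the measurement studies this package
emulates; property sweeps use 1,000 random shoulders.  All simulations are
seeded and reproduce bitwise.

## Known limitations

- Landmarks are the input contract: no DICOM/NIfTI reading, segmentation,
  or automatic landmark detection.
- B2 intermediate-line endpoints must be supplied; they are not derived
  from paleo-/neoglenoid geometry.
- ICC estimators assume a complete balanced design; no missing-data forms,
  average-measure forms, or ICC(3,·).
- Real-cohort values (patient CTs) are not reproducible here; the synthetic
  cohorts are statistical surrogates with matched ground-truth moments.
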