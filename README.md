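# glenvault

Landmark-based CT morphometry of **glenoid version** for shoulder research:
the conventional (Friedman) method and the **glenoid-vault** method, measured
on three-dimensionally corrected slices, with the accompanying reliability
(intraclass correlation) and cohort statistics, and a synthetic scapula
generator with known ground truth.

## The problem

Glenoid version — the axial-plane tilt of the glenoid articular surface,
retroversion positive — guides glenoid component placement in shoulder
arthroplasty.  The conventional measurement references the *scapular axis*
(tip of the medial border of the scapula → center of the glenoid line), so
it is confounded by the shape of the scapular body, which varies widely
between patients (flat, round, wavy).  The vault method instead references
the *glenoid vault axis* (medial tip of the triangular scapular vault →
center of the glenoid line), a purely periglenoid structure, eliminating the
scapular-body effect.

Both methods measure on the three-dimensionally corrected slice: the plane
containing the scapular axis (medial pole → glenoid center) and
perpendicular to the scapular plane (inferior tip of scapular body, glenoid
center, medial pole), which removes scapular inclination and gantry-angle
effects.  With the glenoid line **g** (posterior rim → anterior rim) and
reference axis **a** projected into that slice, version is

&nbsp;&nbsp;&nbsp;&nbsp; α = ∠(**g**, **a**⊥) , signed positive when the
posterior rim lies medial to the anterior rim (retroversion).

This package takes *landmark coordinates* (JSON or CSV, world mm) as input —
not images: landmark identification is upstream of this tool.

## Worked example

Measuring a synthetic shoulder built with a true vault version of 9.7° and a
3.5° scapular-body offset:

```python
from glenvault import build_shoulder, vault_version, conventional_version, method_difference

lm, gt = build_shoulder(9.7, 3.5, shoulder_id="demo", inclination_deg=12.0)
rv, rc = vault_version(lm), conventional_version(lm)
print(f"vault {rv.version_deg:.1f}  conventional {rc.version_deg:.1f}  "
      f"difference {method_difference(rv, rc):.1f}")
```

prints

```
vault 9.7  conventional 6.2  difference 3.5
```

i.e. the vault method reads 9.7° retroversion, the conventional method reads
only 6.2° because the scapular body tilts its axis by 3.5°, and the
method difference is that body-shape offset.

The same pipeline from the shell, on a 150-shoulder synthetic normal cohort:

```bash
glenvault simulate --preset normal --seed 42 -n 150 --out cohort.json --truth truth.csv
glenvault measure cohort.json --round 0 --out results.csv
glenvault compare results.csv
```

```
Method comparison (vault vs conventional)
-----------------------------------------
cohort conventional: n=150, 1.3° ± 3.3° (range, -6.7° to 12.0°)
cohort vault: n=150, 9.0° ± 2.9° (range, 1.4° to 16.8°)
mean difference (vault − conventional): 7.7°
paired Wilcoxon signed-rank: W=0.0, p=0.000
variance-ratio F-test: F=1.330, p=0.083
(zeros dropped in Wilcoxon; two-sided tests, α = 0.05)
```

The normal glenoid vault is not neutral but retroverted (≈9°), while the
conventional method reads near-neutral (≈1°); the vault method reads
significantly larger retroversion.  `glenvault reliability` computes
per-rater ICC(1,1) and pooled ICC(2,1) from a ratings CSV, and
`glenvault sides` runs the paired dominant-versus-nondominant comparison.

## Layout

- `glenvault.geometry` — landmark sets, scapular plane, corrected slice,
  projection, signed version angle
- `glenvault.measures` — conventional and vault version, glenoid-line
  variants (standard / B2 intermediate), method difference
- `glenvault.reliability` — ICC(1,1), ICC(2,1) with Shrout–Fleiss CIs
- `glenvault.cohort` — summaries, paired Wilcoxon, variance F-test,
  method and side comparisons
- `glenvault.simulate` — synthetic scapulae, cohort presets, rater noise
- `glenvault.io` / `glenvault.cli` — file schemas and the `glenvault` CLI

See `docs/methods.md` for the model, conventions and limitations.
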