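# Methods

## Joint coordinate system

Tibiofemoral pose is a rigid transform (R, t) of a tibial body-fixed
frame relative to a femoral body-fixed frame, R proper orthonormal
(validated to 1e-9), t in mm.  Clinical coordinates use the
Grood–Suntay convention: femoral body-fixed flexion axis e1, tibial
body-fixed long axis e3, floating axis e2 = e3 × e1/|e3 × e1|.  With
the frame convention x = flexion axis (medial), z = long axis
(proximal), y = z × x (posterior for a right knee), the rotation of the
tibial *anatomical* frame relative to the femur factors as a Cardan
x–y–z product

    R_rel = Rx(flexion) · Ry(−varus) · Rz(−ext_rot),

which is exactly the body-fixed/floating-axis construction: flexion
about the femoral x, internal/external rotation about the tibial z,
varus/valgus about the intermediate floating axis.  Translations are
the components of the inter-origin displacement expanded on the
(generally non-orthogonal) basis (e1, e2, e3); the basis matrix has
determinant cos(varus) and is inverted exactly, so `pose_from_jcs` is
the exact inverse of `jcs_from_pose` on |varus| < 90°.

All six coordinates are reported relative to a per-specimen **zero
position** (the unloaded pose at 30° flexion).  The tibial anatomical
frame is defined to coincide with the femoral frame at that pose, i.e.
R_rel = R_pose · R_refᵀ and t_rel = t_pose − R_rel · t_ref; the
reference therefore maps to six zeros, and a pure rotation about the
femoral flexion axis applied on top of the reference changes flexion
only.  Reported flexion is relative to the 30° zero position
(`ReferencePose.flexion_at_zero` records the offset).

Numerical choices: the floating-axis singularity at |varus| = 90° is
guarded with a hard error at 89° (physiological varus here is < 10°);
arcsin/arccos arguments are clipped to [−1, 1]; round-trip accuracy is
better than 1e-9 over |varus| ≤ 60° (tested).  Left knees are handled
by a chirality flag that negates the varus angle and medial
translation.

## Superposition in situ force

`in_situ_force` is the Euclidean norm of the force-component difference
between a recorded trial and its path-identical replay; moments are
carried in the data model but excluded from F (an in situ moment norm
exists but is not part of the default report).  Pairing is enforced,
not assumed: same specimen/angle/state/cycle, equal sample counts, and
maximum pose discrepancy within 10× the robot's path-reproducibility
bounds, otherwise a `PairingError`.

## Synthetic rig

The generator emulates the full protocol (defaults: 14 specimens, 4
angles, 4 states, 3 cycles, 300 N target, plus a replayed counterpart
for every recorded trial → 1344 recordings).  Loading is a 2 s linear
force ramp followed by a 1 s hold, sampled at 100 Hz — a desk-scale
profile chosen by this package, since loading rate is not part of the
protocol description.

Tissue model (phenomenological, per specimen × angle × state × cycle):

| parameter | default | meaning / rationale |
|---|---|---|
| `intact_share` | 0.373 | fraction of axial load borne by the intact medial meniscus; 0.373 × 300 N = 111.9 N, the pilot's intact in situ force |
| `retention` | 1 / 0.85 / 0.50 / 0.20 | fraction of intact meniscal force remaining per state; the 0.20 anchor is the ~20 % residual reported after 90 % resection, the 0.85/0.50 values are interpolating configuration defaults |
| `varus_gain` | 2.0° | extra varus of the loaded tibia at zero retention; a state's increment is `varus_gain × (1 − retention)` |
| `extrot_offset` | 1.5° | width-independent external-rotation shift of any resected state (knees rotate externally once the meniscal restraint is cut, regardless of width) |
| `extrot_gain_30` | 1.0° | width-dependent external-rotation term active at 30° flexion only |
| `specimen_sd` | 0.10 | between-specimen log-normal SD on the load share; reproduces the ~10 % coefficient of variation of the pilot's intact force |
| `trial_sd` | 0.08 | within-specimen trial-to-trial log-normal SD on the meniscal force magnitude (biological variation, not rig noise) |
| `align_trial_sd` | 0.25 | multiplicative SD on the alignment increments |
| `conditioning_drift` | 0.004 | cycles 1/2 read high by 0.8 %/0.4 %; cycle 3 is the settled value, so third-cycle selection is observable and cycle-3 anchors are exact |
| `intact_varus`, `intact_extrot` | 6.7°, 7.4° | loaded intact alignment at full load (pilot values); intact medial/anterior translations 2.8/11.4 mm likewise |
| `force_direction` | (0.1, 0, −0.995) | direction cosines of the meniscal reaction; only the norm is consumed downstream, so direction is a free parameter |

All multiplicative effects are log-normal with unit mean, so expected
cell means equal the deterministic model.  Pose during the ramp scales
linearly with the commanded load fraction.

Noise model (bounds, not SDs): replay pose error is drawn with an
isotropic random direction and magnitude uniform on [0, bound]
(0.006 mm translation, 0.03° rotation), so the stated reproducibility
is never exceeded; recorded poses carry the same bounded measurement
noise.  Forces are quantized to the 0.02 N sensor resolution.  Axial
force-control error is uniform at 80 % of the <5 N fluctuation bound,
keeping the hold phase strictly inside it.  `no_noise()` on the rig
config and tissue model zeroes every stochastic term, making
superposition exact (recorded − replayed ≡ the injected meniscal
vector) and the pipeline's parameter recovery exact to machine
precision.

Randomness: one global seed; every trial draws from its own
seed-keyed generator (key = seed, specimen, angle, state, cycle,
phase), so identical seeds are bit-identical and enlarging the grid
never perturbs previously generated trials.

**What the generator does not emulate.**  Real menisci do not share
load through a fixed, angle-independent fraction; resection effects are
imposed directly through `retention` rather than emerging from contact
mechanics; force direction is fixed; cartilage, ligament and capsule
nonlinearity, specimen geometry, and flexion-angle dependence of the
intact share are absent.  Passing tests therefore demonstrate that the
*pipeline* recovers whatever structure the generator encodes — not that
the tissue model is biologically correct.  One concrete consequence:
with the calibrated ~10–13 % total variation, the intact-vs-30 %
comparison comes out clearly significant in default synthetic runs,
whereas real data of this kind can leave that smallest contrast
borderline; matching both the pilot's variance and a borderline
smallest contrast is impossible with a 15 % mean effect at n = 14, and
the variance calibration was kept.

## Pipeline

Only the third loading cycle is analyzed (protocol rule; missing cycle
3 is an error naming the group).  Outcomes are evaluated at the
**hold-phase midpoint**: the longest contiguous run of samples whose
axial force is within the controller fluctuation bound of the target,
midpoint index.  This is a design choice (robust to control
fluctuation) — the alternative conventions (ramp peak, hold average)
are not materially different on synthetic data but are not what this
package computes.  Alignment changes are computed from recorded
(pre-meniscectomy) paths only, each trial at its own peak-load sample,
as state minus intact.  The recording schema stores poses relative to
each specimen's zero position, so the analysis reference is the
identity pose.

## Statistics

* `rm_anova`: from-scratch partition SS_total = SS_subjects +
  SS_treatment + SS_error, F = MS_treat/MS_error on (k−1, (k−1)(n−1))
  df.  No sphericity correction by default (Greenhouse–Geisser is
  available as an option); a zero treatment SS returns F = 0, p = 1.
* `tukey_hsd`: q = |mean_i − mean_j| / √(MS_error/n) against the
  studentized-range distribution with k groups and the within-subject
  error df.  Using the repeated-measures MS_error (rather than a
  between-groups pooled variance) is deliberate: all comparisons are
  within-subject.  Verified against an R lmer/emmeans Tukey run frozen
  into the test suite, and against the paired-t identity q = t√2 at
  k = 2.
* `mann_whitney_u`: exact by complete enumeration (midranks under ties)
  for combined n ≤ 20, reporting the permutation probability of the
  folded statistic max(U, n₁n₂ − U) reaching its observed value — this
  equals the usual two-sided exact p for tie-free data and returns
  exactly 1 for identical samples; larger samples fall back to the
  tie-corrected normal approximation.
* `required_sample_size`: minimal n by iterating a noncentral power
  function.  The design (two-sided paired t, or repeated-measures
  ANOVA with stated condition count and within-subject correlation) is
  an explicit argument, because a bare "n to detect Δ with SD σ" is
  underdetermined; the helper makes no claim to reproduce any
  particular historical power analysis.

α = 0.05 in the default report.  Alignment comparisons use only the
three resection states — intact is the zero baseline of the change
scores, not a compared group.

## Problem sizes

The test suite runs reduced grids (2–3 specimens, 1–2 angles, 5–20 Hz
sampling) except where the full design matters: the type-I calibration
uses 10 000 simulated null datasets of 14 subjects × 4 states, and the
end-to-end check runs the complete default study (1344 recordings at
100 Hz) through analysis, statistics and report assembly.  The
acceptance script uses 5 specimens for the pilot-anchor quantities
(matching the pilot's n = 5) and the full 14-specimen grid for the
pooled-residual and noise-bound quantities.

## Known limitations

CSV recordings are large for the full grid (~150 MB); the format favors
inspectability over compactness.  The simulator's hold-window rule
means the reported maximal axial deviation sits at the window bound by
construction.  The JCS implementation targets the clinical envelope;
poses near |varus| = 90° are rejected rather than handled by an
alternative parameterization.
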