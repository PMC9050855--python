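# Methods

This note documents the models, numerical choices and limitations behind
`flowunwrap`. It is the design record a maintainer should read before
changing defaults.

## The wrap model

Phase-contrast velocimetry encodes velocity linearly in signal phase, so a
velocity outside the representable half-open interval `[-venc, +venc)`
aliases modularly. The simulator implements the symmetric fold

```
k   = floor((V_T + venc_sim) / (2 venc_sim))      # integer wrap count
V_A = V_T − 2 venc_sim · k
```

which reduces to the single-wrap relation `V_A = V_T − 2·venc_sim` for
`venc_sim < V_T < 3·venc_sim` and extends it consistently to negative
velocities and multiple wraps. Subtracting the exact multiple of
`2·venc_sim` leaves unwrapped voxels bit-identical, so the ground-truth mask
is simply `k ≠ 0` — no tolerance is involved.

**Boundary convention.** `V_T = +venc` wraps to `−venc`, mirroring the 2π
periodicity of phase. One consistent choice matters more than which choice.

**Mask-driven correction and its regime.** A binary mask carries no wrap
count, so `unwrap_with_mask` must infer the correction direction; it uses
the sign of the aliased value (negative values are shifted up by `2·venc`,
positive ones down; an exact 0 is shifted up and the case logged). The sign
flips under a single wrap only while `|V_T| < 2·venc`, so that is the regime
in which wrap → mask-unwrap is exactly invertible. For
`|V_T| ∈ (2·venc, 3·venc)` the aliased value keeps the sign of the true one
and the rule over-corrects; this is inherent to any single-label mask and is
the same limitation that multi-wrap data poses for the trained detector.
Tests and the acceptance script therefore exercise the round trip with
`peak_velocity < 2·venc_sim`.

## The phantom

Real aortic 4D-flow scans cannot be redistributed, so all study conditions
are generated:

- **Geometry.** A straight tube (for analytic checks) or a U-bend
  "candy-cane" — ascending limb, 180° arch, descending limb — with the bend
  plane tilted 20° about z so that the arch exercises all three velocity
  components. The vessel is all voxels within `vessel_radius` of the
  centerline; voxels must subtend at least 2 voxels of radius in-plane.
- **Flow.** Through-axis Poiseuille profile `v(r) = v_peak (1 − (r/R)²)`
  along the local tangent, scaled by a cardiac waveform: a raised-cosine
  systolic pulse over the first `systole_fraction` (default 0.35) of the
  cycle on a diastolic plateau of 0.08, sampled at frame centers and
  normalized to max 1. Womersley profiles, secondary/helical flow and wall
  motion are not modeled.
- **Noise.** Zero-mean Gaussian velocity noise, independent per
  voxel/frame/direction, with `σ_v = √2·venc/(π·SNR)` — the standard
  phase-contrast relation tying velocity noise to the chosen venc through
  the magnitude SNR. Default SNR 15, a mid-range value for contemporary
  aortic protocols.
- **Defaults.** 2.4×2.4×2.6 mm voxels, 40 ms frames, peak velocity
  150 cm/s (normal aortic peak), venc 170 cm/s (≈13 % above peak, the usual
  prescription headroom). Identical `PhantomSpec` (including `seed`)
  regenerates bit-identical data.

What passing on phantoms does *not* show: robustness to eddy-current
offsets, partial-volume averaging at the wall (voxels wrapped by less than
2π), scanner-specific noise structure, motion, or anatomic variety. The
phantom isolates the wrap arithmetic and the spatio-temporal signature of
aliasing, which is what both detectors consume.

## Conventional jump algorithm

Per slice and velocity direction the algorithm works on the `[X, Y, time]`
sub-array: nearest-neighbor differences along x, y and time; pairs with
`|Δ| > threshold` (threshold = `jump_threshold_factor × venc`, default
factor 1.0) are flagged; a flagged voxel is corrected by `−sign(V)·2·venc`.

Disambiguation of which voxel in a flagged pair is wrapped cannot be done
pairwise (the sign rule makes both ends of a wrap boundary look wrapped), so
the implementation relies on:

1. **Trusted references.** The first cardiac frame and the field borders are
   assumed unaliased (diastole and background rarely alias). Passes sweep
   sequentially away from them — temporal first (ascending frames), then x,
   then y (both directions) — each voxel judged against its already-resolved
   neighbor. Only values with `|V| ≤ venc` are correction candidates: an
   observed aliased value necessarily lies in `[-venc, venc)`, so anything
   beyond venc is already true or corrected.
2. **Sign consistency.** A correction is applied only when it reduces the
   jump (`sign(V) = sign(ΔV)`).
3. **Per-pass validation.** A sequential sweep can chain one mistaken
   correction through smooth data (each corrupted voxel becomes the next
   reference — the failure cascades along whole rows). After every pass,
   any voxel whose correction *increased* its count of `> threshold`
   neighbor pairs (over x, y and time) is reverted. Genuine wrap regions
   are corrected coherently within a single vectorized pass and stay
   consistent; chains do not. A reverted correction may validate in a later
   iteration once its context is resolved.

The schedule iterates to a fixpoint (no net corrections) or
`max_iterations` (default 10; non-convergence emits a `RuntimeWarning` and
returns the last iterate). On a converged output a second run changes
nothing. The detected mask is the set of voxels net-shifted by more than
venc, so transient corrections repaired within the run are not counted.

On noise-free phantoms whose true neighbor differences stay below the
threshold the algorithm is exact (Dice 1.0, field restored to float
rounding). Its characteristic failure appears when the venc is severely
reduced: the systolic upstroke between consecutive frames approaches
`venc_sim` itself, wraps stop producing super-threshold jumps, and the
algorithm under-detects — e.g. on the standard noisy phantom the in-vessel
Dice falls from 1.0 (at 0.6–0.7× venc) to ≈0.76 at 0.4× venc with the
detected count well below the truth count. This direction (missing voxels,
not inventing them) matches how such methods fail on heavily aliased
clinical data.

## Dense-block U-Net

**Task framing.** Every (cardiac frame, velocity direction) 3D volume is an
independent two-class segmentation problem; per-volume masks are compiled
into the 5-axis detection mask. Volumes are divided by their venc, mapping
them to `[-1, 1)`; the wrap signature is scale-free in these units, so one
model serves any venc. In-plane center-cropping (default 128×96; inputs
smaller than the crop are zero-padded and the padding forced to background
on output) bounds the field of view; the slab axis is untouched, and
pooling is in-plane only, so variable slab counts need no constraint.

**Architecture.** U-Net encoder–decoder in which each stage is a dense
block — `dense_layers` small convolutions, each emitting `growth` channels
concatenated onto everything before — followed by a 1×1 compression to
`width` channels; 2×2 in-plane max pooling / nearest upsampling between
levels; concatenation skip connections; a 1×1 two-channel softmax head. The
head is zero-initialized with a background-favoring bias `(+1, −1)`, so an
untrained model abstains (predicts no aliasing) rather than emitting noise.
All layers run on the package's own numpy engine (`flowunwrap.nn`):
convolutions as im2col + BLAS matrix products with analytic backward
passes, Adam optimization, inverted dropout. He-normal initialization from
a generator seeded by the config makes builds bit-reproducible.

**Loss.** Voxelwise softmax cross-entropy plus `1 − softDice`, with
`softDice = (2Σp·y + s)/(Σp + Σy + s)` and `s = 1` (the conventional unit
smooth term). Two numerical choices matter here:

- The *evaluation* Dice's 1e-5 stabilizer must not be reused as the loss
  smoothing: with `s = 1e-5`, volumes with empty truth (most diastolic
  frames) acquire a needle-sharp optimum at zero foreground mass whose
  gradient grows like `1/s` as `Σp → s`; those volumes dominate the
  training stream and collapse the network to all-background (observed
  empirically before the change: foreground logit margins pinned exactly at
  the head bias, zero detections).
- Even with `s = 1`, the dice gradient on an empty-truth volume only pushes
  the already-saturating background probability further down — a job
  cross-entropy already does with bounded gradients — so the dice term's
  gradient is applied only on volumes that contain aliasing. The dice term
  then does the work it is intended for: combating the ~1 % foreground
  class imbalance where the foreground exists. No other reweighting is
  used.

**Training schedule.** Per epoch every training field is wrapped
`wraps_per_dataset_per_epoch` (default 4) times at venc fractions drawn
uniformly from [0.40, 0.70] with a seeded generator, and every (frame,
direction) volume of every wrap is one sample; samples are shuffled and
optimized at batch size 1. Aliasing is thus never seen twice with the same
pattern. Fixed config seed ⇒ reproducible trajectory on one device.

**Desk-scale profile.** The full-scale profile (128×96 crops, 4 levels,
3×3×3 kernels, lr 1e-4, dropout 0.1, 400 epochs) is config-selectable but
takes days on CPU. Tests and the acceptance script use the `tiny` preset —
2 levels, growth 6, width 12, 3×3×1 kernels, lr 3e-3, 10 epochs — on
48×32×12-voxel, 8-frame phantoms (4 training, 1 held out), about 10–12
minutes on one core. The tiny preset holds the learning rate constant for
the first half of the run and then decays it on a cosine schedule to 10 %:
the network needs several epochs at full rate before its features cross the
detection boundary, and at a constant 3e-3 the last epochs oscillate around
that boundary instead of settling.
The in-plane 3×3×1 kernel reflects that both the wrap signature exploited
here and the conventional baseline operate in-plane; through-slab context
is config-restorable (`kernel=(3,3,3)`). At this scale
the held-out in-vessel Dice at half venc, and the monotone improvement of
Dice as the simulated venc decreases (more aliasing → easier detection),
are the quantities the acceptance checks assert.

## Metrics

- **Dice** `(2|X∩Y| + 1e-5)/(|X| + |Y| + 1e-5)`; the stabilizer makes
  empty-vs-empty score 1 (a correct "no aliasing" call on a diastolic
  frame). Restriction to a vessel mask is applied to both masks before
  counting.
- **Hausdorff** — symmetric max of directed min Euclidean distances between
  voxel-center point sets scaled by the voxel spacing (mm), computed per
  (frame, direction) volume; volumes where both masks are empty are
  skipped, and the data-set value is the maximum over volumes (per-volume
  values are retained). A volume with exactly one empty mask makes the
  distance undefined — an explicit `EmptyMaskError`, never a silent 0. Two
  code paths (brute-force O(|X||Y|) and a KD-tree) return identical values;
  the brute-force path is the reference.
- **Counts** — set voxels inside the vessel, over all frames and directions.

## Hemodynamics

Analysis planes are defined by an origin and unit normal; the plane is
rasterized at the finest voxel pitch with nearest-neighbor sampling (no
interpolation), and the ROI is taken from the vessel mask (or a circular
ROI). Per frame `Q = Σ_ROI (v·n̂) · pixel_area` (ml/s); net flow integrates
the series with the periodic rectangle rule `ΣQ·Δt` — exact for a constant
series and the natural choice for a cyclic signal; peak flow is `max_t Q`;
peak velocity is the maximum voxelwise speed (vector magnitude, not the
through-plane component — the reading a manual ROI yields) in m/s.
Bland–Altman: bias = mean(test − reference), LOA = 1.96·SD (n−1
denominator), LOA percent = 100·LOA / mean(reference), flagged undefined
when the reference mean is 0.

Dual-venc ground truth: voxels where the low-venc and high-venc scans
differ by more than the low venc, per direction and frame (a single wrap
shifts a value by exactly `2·venc_low`, so the threshold sits safely between
noise and wrap). On simulated pairs this reproduces the wrap simulator's
truth mask exactly; on real paired scans it additionally absorbs
inter-scan noise, motion and partial-volume differences, which the
simulated equivalence does not test.

## Known limitations

- Single-wrap correction only; wrap counts ≥ 2 (and `|V_T| > 2·venc` for
  the sign rule) need a multi-label formulation.
- The conventional algorithm's trusted-reference assumption fails if the
  first frame itself aliases (not the case for diastolic-start acquisitions).
- Oblique analysis planes use nearest-neighbor sampling; flux through
  strongly oblique planes carries staircase error at coarse resolution.
- The desk-scale network is intentionally small; its scores quantify the
  pipeline's behavior on phantoms, not expected clinical performance.
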