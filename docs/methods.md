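# Methods

This note documents the models, conventions and numerical choices behind
`dynaqa`, in the order the data flows through the pipeline.

## Geometry and conventions

The MLC is a Millennium-120-style collimator: two opposed banks (A, B) of 60
leaf pairs; projected leaf widths at isocenter are 5.0 mm for the central 40
pairs and 10.0 mm for the 10 outermost pairs on each side (400 mm total).
The leaf-travel axis is `x` (mm at isocenter); bank A approaches from −x,
bank B from +x, and the aperture of pair k is the open interval
`(tipA_k, tipB_k)` with `tipA ≤ tipB` enforced everywhere.  A closed pair is
`tipA == tipB` — no sentinel values.  The cross-pair axis is `y`, pair 0 at
the most negative y.  Gantry rotation is about y; at 0° the beam travels
along −z.

Positions live at three precision layers, coarsest wins on disk:

| layer | resolution | where |
|---|---|---|
| internal model | float64 | all in-memory arrays |
| sequence files (`dva`) | 0.01 mm (cm with 3 decimals) | `plan.py` |
| recorded log positions | 0.01 cm (0.1 mm) | `dynalog.py` |

Both text dialects (`dva` sequence files, `.dlg` per-bank logs) are defined
and documented in the owning modules' docstrings; they are self-contained
stand-ins for vendor formats, not reverse-engineered ones, and the writers
are canonical (write → read → write is byte-identical).

## Delivery simulation

The simulated controller is kinematic: leaves track the planned trajectory
exactly as a function of meterset fraction.  Every 55 ms it records dose
index (integer 0..25000, i.e. fractional MU × 25000), segment number (the
control-point interval containing the current fraction), a beam-on flag, and
planned plus recorded positions.  The dose index advances linearly at the
nominal dose rate (default 300 MU/min; 600 MU/min also used in tests, both
typical clinical settings).

Recorded positions = planned + systematic per-bank offset + zero-mean
Gaussian jitter (per leaf per sample) + 0.01 cm quantization.  Two rules make
the noise physical:

* **Abutting pairs move as a unit.**  Pairs whose planned gap is below
  0.5 mm receive common-mode jitter: opposed leaves in contact cannot
  interpenetrate, and independent noise on a closed pair would fabricate a
  fluence sliver (~0.1 mm × MU) at the parked position that no real machine
  produces.
* **Beam hold** when any leaf's error exceeds a tolerance (default 2 mm):
  the sample is flagged beam-off and the dose index does not advance.  A
  persistent hold (e.g. a systematic offset beyond tolerance) raises after
  20× the nominal delivery time.  Servo dynamics and gravity effects are not
  modelled.

The simulator returns both the log pair and the *true delivered motion*
(pre-quantization positions at every distinct fraction) — the ground truth
against which reconstructions are judged.

## Reconstruction

Control points are placed at segment boundaries seen in the segment-number
stream.  Two estimation problems are solved:

1. **Boundary meterset fraction.**  Within a segment each leaf moves linearly
   in fraction, so adjacent segments' planned-position lines intersect at the
   boundary.  The knot is the slope-change-weighted mean of the per-leaf
   intersections, clipped to the bracketing snapshot fractions, with the
   midpoint as fallback when no leaf changes slope (the boundary is then
   geometrically redundant).  The *planned* stream is used for this in both
   modes: it carries no recording noise and the controller switches segments
   at the same fraction for both streams.
2. **Tip positions.**  The full trajectory is a linear spline with the knots
   above; per leaf it is fitted by least squares to the snapshot stream (one
   shared hat-function design matrix for all 120 leaves).  This pools every
   sample of both adjacent segments per knot, suppressing quantization/jitter
   noise by the root of the per-segment sample count, and reduces to exact
   interpolation when a segment contributes a single snapshot.  Fitting
   across the knot, rather than interpolating between the two bracketing
   snapshots, also avoids cutting the trajectory corner (an
   O(|Δslope| × sample spacing) bias that would exceed the 0.01 mm file
   resolution at realistic leaf speeds).

Beam-hold samples (repeated fraction) are collapsed to the latest sample —
the delivery-resumed state.  Collisions created by noise are pinched to the
pair midpoint with a warning.  Accuracy, measured by the test suite:
planned-mode round trip ≤ 0.01 mm; actual-mode recovery of a systematic bank
offset ≤ 0.055 mm, i.e. the 0.05 mm quantization half-step (attained exactly
when a leaf's true position falls on a rounding boundary — information the
log does not carry) plus ~0.005 mm fit noise.

## Fluence

For one control-point interval the tips move linearly, so the time a tip
spends below a point x′ is the CDF of a uniform sweep over its range, and the
open-time fraction has the closed form

    T(x′) = clip((x′ − loA)/(hiA − loA), 0, 1) − clip((x′ − loB)/(hiB − loB), 0, 1),

valid because `A ≤ B` at all times makes "behind A" and "behind B" nested.
Pixel values are the exact integral of T over the pixel footprint (the
antiderivative of a clipped ramp is piecewise quadratic), weighted across
rows by pair/pixel overlap — per-pixel crossing-time integration with no time
subsampling.  The renderer agrees with an independent 1000-substep rendering
to < 0.1 % of the map maximum and is exactly invariant under control-point
refinement.  Leaf transmission is a uniform fraction of interval MU reaching
covered pixels (default 0).  Tongue-and-groove, rounded leaf ends and head
scatter are not modelled.  Default grid: 1.0 mm over ±200 mm.

## Gamma

Global-normalization gamma: dose criterion as a fraction of the reference
maximum, 10 % low-dose threshold (pixels below it are excluded from the
passing rate), pass when γ < 1.  The minimization searches a disc of radius
3 × DTA on a 0.1 mm grid with bilinear interpolation of the evaluated map,
walked in shells of increasing radius; a pixel leaves the search once no
farther displacement can improve its current best (the distance term alone
exceeds it), which makes the exhaustive search cheap for agreeing maps.  The
implementation matches a brute-force per-pixel search to < 0.01 in γ.
Normalization mode and threshold are configurable; global/10 % are the
declared defaults.

## Dose engine and DVH

The engine is a deliberately simple stand-in for a clinical algorithm:
parallel rays per beam, dose = MU-weighted fluence through the ray ×
exp(−μ·depth), with μ = 0.005/mm (a 6 MV-like effective attenuation) and
geometric depth from the phantom surface; no scatter, buildup or
heterogeneity.  Its adequacy rests on *differential* use only: the same
engine evaluates reference and reconstructed plans, so metric differences
isolate delivery effects — absolute dose accuracy is out of scope, and no
conclusion about absolute dosimetry should be drawn from it.  The reference
plan is scaled to 100 % at the isocenter voxel and the same factor is reused
for the reconstructed plan.

DVHs are cumulative (fraction of structure volume receiving ≥ dose,
default bin 0.05 %); D98 %/D2 % are read off by linear interpolation and
Dmean comes from the voxel mean.  Halving the bin width moves metrics by
< 0.05 %.  The chamber-dose operation averages voxels whose centre lies in a
sphere (a 0.125 cm³ chamber ≈ 3.1 mm radius) and errors below half a voxel.
The default phantom is a 200 mm water-equivalent cube at 2 mm voxels with a
25 mm-radius cylindrical target and two 12 mm-radius lateral OARs.

## Error injection

Three primitives build the ten systematic error classes used for
validation: opening expansion (total split equally per bank; 1/2/4 mm),
whole-bank outward shift (0.5/1/2 mm on A or B), and control-point removal
(transfer-failure surrogate).  Closed-pair handling is deliberate:
*expansion* skips closed pairs (expanding a zero gap would create apertures
the error class does not imply) while a *bank shift* moves every leaf of the
bank, closed pairs included.  Removed control points leave the surviving
meterset indices untouched — a controller skipping data does not renormalize
— so the aperture simply travels directly between the survivors; the dose
effect is correspondingly small and can go in either direction.

## QA statistics

* Per-leaf RMS of (planned − recorded) over beam-on samples; hold samples
  are excluded (there the discrepancy is controller state, not delivery
  error).
* Pearson product-moment correlation for paired dose ratios; both r and r²
  are of interest since near-unity values are conventionally quoted as R².
* Confidence limit CL = |mean Δ| + 1.96 × SD(Δ) with the sample (n−1) SD;
  at one-decimal reporting the n vs n−1 choice is immaterial.  For the
  bundled 20-case audit the 60 metric differences are pooled (3 metrics ×
  20 cases) into a single CL; per-metric CLs can be computed from the same
  table.
* Action level: a plan is flagged when any |ΔD98|, |ΔD2| or |ΔDmean|
  *exceeds* 1.0 % (strict inequality: a difference exactly at the level
  passes).

Two benchmark tables ship as package data: ten induced-error isocenter dose
ratios (reconstructed-calculated vs measured) and the 20-case DVH audit with
per-plan maximum leaf RMS.  They serve as fixtures for the statistics and as
a regression anchor: pooled CL 0.4 %, max |Δ| = 1.0 %, RMS range
0.07–0.59 mm.

## Synthetic data: what it does and does not emulate

The plan generator produces leaf-speed-feasible sliding-window sequences
(25 control points, 100 MU, five beams at 72° spacing by default) in three
presets: `ramp` (constant 12 mm gap swept over 120 mm — closed-form interior
fluence MU·gap/sweep), `pyramid`, and `random` (seeded smooth modulation of
window centre and gap).  These exercise every code path (modulation, closed
pairs, segment boundaries) but are not inverse-planned: target coverage and
OAR sparing are not clinically shaped, and passing tests on them shows the
*chain* is faithful, not that any clinical plan class is.  Likewise the
simulator's noise model (iid Gaussian jitter, constant offsets) omits
correlated servo lag, gravity dependence and dose-rate modulation, so
measured log feature distributions from real machines are outside what the
fixtures can validate.

## Validation experiments and problem sizes

`scripts/acceptance.py` runs two end-to-end experiments (sizes chosen to
keep a full run in well under a minute on one core):

* **Planned-mode round trip** — five-beam random plan, error-free delivery
  at 300 MU/min (~365 snapshots/beam), toy-engine dosimetry on the default
  phantom (10⁶ voxels): reports the maximum |ΔD98/ΔD2/ΔDmean| over target +
  two OARs.  Values land well below 0.1 %.
* **Fluence gamma** — ten random fields, 0.2 mm jitter + 0.01 cm recording
  quantization, actual-mode reconstruction, gamma 3 %/3 mm at 10 % threshold
  against the true delivered fluence: reports the mean passing rate,
  typically ≥ 99.95 %.

## Known limitations

* The dose engine is differential-only (see above); no absolute dosimetry.
* Only fractional MU is logged, so absolute-output (calibration) errors are
  invisible by construction, as are leaf-position errors introduced by a
  miscalibrated position encoder — the log believes the encoder.
* Patient/phantom setup error is explicitly out of scope.
* Fixed-gantry fields only; gantry angle is carried as metadata, not
  reconstructed.
* Binary trajectory-log formats and jaw/carriage tracking are not handled.
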