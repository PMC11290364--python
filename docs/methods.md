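# Methods

## Model and assumptions

Three rigid bodies — cranium, left hemimandible, right hemimandible —
move in a shared laboratory frame.  Each carries a constellation of
≥ 3 non-collinear markers whose positions are known in the bone's model
frame (from CT in a real experiment).  All lengths are millimetres and
all angles degrees in external interfaces; rotations are proper
orthonormal matrices validated to 1e-9 on construction.

**Pose estimation.**  Per frame and per bone, the rigid transform
minimising the sum of squared marker distances is the orthogonal
Procrustes solution via SVD of the cross-covariance of centred
coordinates.  If the optimal orthogonal matrix is a reflection
(det = −1) the smallest-singular-value axis is flipped — bone poses are
proper rotations.  Missing markers are excluded from the fit, never
imputed; frames with fewer than three usable markers, or a collinear
usable subset (smallest singular value of the centred reference
coordinates ≤ 0.1 mm), yield missing poses that propagate as missing
(NaN) through every downstream trace.

**Filtering.**  A zero-phase order-2 Butterworth low-pass (default
cutoff 20 Hz at 250 frames/s; both are config keys recorded in output
metadata) is applied to each raw marker coordinate component *before*
pose estimation, which keeps rotations exactly orthonormal and avoids
interpolating rotations.  Contiguous valid segments are filtered
independently with reflective end padding; segments shorter than the
padding length (3 × (order + 1) samples) pass through unfiltered and
are flagged.  Filtering can be disabled (`filter_cutoff_hz: null`),
which is appropriate for noise-free data.

**Coordinate systems.**  The cranial anatomical coordinate system (ACS)
derives from the occlusal plane: a total-least-squares plane through
the upper tooth-row cusp landmarks (normal = smallest-eigenvalue
direction of the centred scatter; sign fixed by an orientation hint).
X is the unit projection of the cranial long axis (anterior − posterior
landmark) into the plane; Z is the in-plane direction orthogonal to X
whose polarity is set by the left→right condyle direction; Y = Z × X
points superior.  Mandibular ACSs are clones: identical world
orientation at the reference frame, re-expressed in the hemimandible's
model frame, with origins at supplied landmarks (condyle centroid,
symphysis centroid).  Cloning at the zero frame makes the relative pose
there exactly the identity, so the zero frame decomposes to
(0, 0, 0, 0, 0, 0) by construction.

**Joint decomposition.**  For fixed-body ACS pose `W_f(t)` and mobile
`W_m(t)`, the relative pose is `P(t) = W_f(t)^-1 W_m(t)` and the
zero-referenced rotation `dR(t) = R_P(t) R_P(t0)^T` is factorised
intrinsically Z–Y′–X″ (`dR = Rz Ry Rx`): Rz about the fixed body's
lateral axis (pitch), Ry about the floating axis (yaw), Rx about the
mobile body's anterior axis (roll).  Translations are reported as the
components of the mobile origin's displacement from its zero position
**in the fixed body's ACS axes**, not along the time-varying floating
axes — this keeps Tx strictly anteroposterior and matches reporting
molar motion "relative to the cranium"; the choice is recorded in
output metadata.  Polarities follow the right-handed axes directly:
positive Rz pitches toward occlusion, positive Ry yaws toward the
animal's left, positive Rx rolls the right side inferior, positive
Tx/Ty/Tz are anterior/superior/right.  A reflection test (mirroring the
whole scene left↔right) pins these conventions: Rx, Ry and Tz flip,
Rz, Tx and Ty are preserved, and the two TMJs swap.  |yaw| within 0.5°
of 90° sets a gimbal flag but still returns values; rat jaw yaw stays
below ~3°, far from the singularity.

**Zero pose.**  The zero (centric occlusion) frame is the frame of
maximum pitch (minimum gape) inside a representative chew — the cycle
whose pitch amplitude is closest to the median across cycles — with
ties within 1e-9° broken to the earliest frame; a config key can pin an
explicit frame instead.

## Cycle statistics

Cycles run from one gape maximum to the next (peaks of −Rz with
prominence ≥ 2°).  Cycles with pitch amplitude below 5° (non-chew
wiggles) or above 25° (food-gathering, which pitches harder than
chewing) are discarded, as are the incomplete stretches before the
first and after the last maximum.  Each retained cycle is cubic-spline
interpolated onto 100 evenly spaced samples (endpoints preserved);
cycles with missing endpoints, fewer than 4 valid samples, or a missing
run longer than 10% of the segment are dropped with a logged reason.

*Absolute amplitude* of a variable is max − min over the normalised
cycle.  The *occlusal phase* is samples 31–70 of 1..100 (the middle
40%, configurable); occlusal metrics report end-minus-start
displacement and window range.  The *between-cycle 95% CI* is, by
default, the average over the 100 time points of the pointwise
across-cycle t-based CI of the mean (`t(0.975, n−1) · s(t) / sqrt(n)`) —
the band one would draw around a mean trace, then averaged; a CI of the
per-cycle amplitude distribution is available via `ci_mode:
amplitude`.  With a single cycle the CI is flagged undefined.  Report
rounding is decimal half-up at 2 decimals (1 decimal for the
translation grand mean); unrounded values are always emitted alongside.

**Workflow precision.**  Zero-relative-motion (frozen specimen) trials
run through the identical pipeline; per variable, frames are pooled
across trials and the reported CI is `t(0.975, N−1) · SD` of the
per-frame values about their pooled mean — a dispersion ("range of
apparent motion") measure, not a standard error of the mean.  This
reading makes the precision floor commensurate with the uncertainty of
a single recovered amplitude, which is what the parameter-recovery
tolerance `max(3%, 2 × workflow CI)` needs; the alternative SD/√N
reading shrinks without bound with trial length and bounds nothing.

## Synthetic data generator

The generator emulates the study conditions rather than any particular
recording: 250 frames/s, 5 Hz chew cycles, three bodies with 4/4/4
markers (optionally 3 on the right hemimandible, the minimal-marker
case), cusp landmarks exactly on the occlusal plane, and per-individual
amplitudes defaulting to the in vivo reference summary
(`chewkin.reference_data`), with 13/7/18 cycles for the three default
individuals.

Waveforms (cycle phase φ, gape maxima at integers):

- **Pitch** `Rz(φ)`: raised-cosine close/open flanks around an occlusal
  window occupying the middle 40% of the cycle; −amplitude at full
  gape.  Inside the window the jaw dips a shallow raised-cosine *dome*
  (default 1°, capped at 20% of the pitch amplitude) below centric and
  returns, so peak closure is unique at mid-cycle.  A perfectly flat
  plateau would leave the zero frame numerically undetermined; the dome
  pins it at centric occlusion, where every injected rotation is
  exactly zero — otherwise cloning axes at a rotated posture mixes a
  little of each DOF into the others.  The absolute amplitude is exact
  by construction.
- **Condylar Tx**: piecewise raised-cosine; posterior return during
  closing, anterior rise of `occlusal_tx_fraction` (default 0.55) of
  the excursion during occlusion, anterior continuation during opening
  — the condyle translates forward through both occlusion and opening,
  as observed in rats.
- **All other DOFs** (condylar roll/yaw/Ty/Tz, all six symphyseal):
  cycle-rate sinusoids with fixed per-DOF phases, offset to vanish
  exactly at centric occlusion; absolute amplitude equals the parameter
  exactly.

The left hemimandible is driven by the condylar waveform about the left
condyle centroid; the right hemimandible is the left composed with the
symphyseal waveform about the symphysis centroid.  Hence the left-TMJ
and symphyseal traces equal the injected waveforms exactly, and the
right-TMJ trace follows by composition (nearly identical to the left —
bilateral chewing — plus small symphyseal coupling).  Truly mirrored
left/right waveforms were rejected: they would force the symphyseal
amplitudes to be twice the condylar antisymmetric ones, contradicting
independently specified condylar and symphyseal amplitudes.  Condylar
report columns come from the left TMJ (configurable).  Molar-locator
translations are emergent (condylar translation plus pitch lever-arm
about the condyle, ~17 mm to the locator) rather than injected; their
ground truth is computed by running the trace machinery on the exact
generated poses.

Rendering maps each constellation through the per-frame poses and adds
i.i.d. isotropic Gaussian noise (default σ = 0.05 mm per coordinate)
and seeded dropouts (`missing_rate`, default 0).  Constellations are
jittered tetrahedra with 3.5 mm RMS spread about their centroid
(validated non-collinear).  Optional slow whole-scene "head" motion
(default 8° / 15 mm at 0.6 Hz) is superimposed; cadaver trials share
one such waving motion across all bodies with zero relative joint
motion.  All randomness derives from a single integer seed
(`SeedSequence([seed, stream])`); identical seeds give byte-identical
fixture files.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real recordings: 2-D tracking and
calibration artifacts (the noise is isotropic, white and homoscedastic,
whereas reprojection error is structured), bone deformation, marker
migration or contrast-dependent dropout patterns, food-item mechanics,
behavioural variability between cycles (injected cycles are identical
up to noise, so between-cycle CIs here reflect noise alone), and
aperiodic or drifting chew rhythm.

## Problem sizes and runtime defaults

The default synthetic study uses 13/7/18 cycles at 50 frames per cycle
(≈ 680/380/930 frames per individual) plus three 2 s (501-frame)
cadaver trials — matched to the reference study's cycle counts and
comfortably sized for routine re-running; the whole test suite and the
acceptance script each complete in well under a minute on one core.

## Known limitations

- The synthetic workflow CIs (~0.7° rotations, ~0.13 mm translations at
  the default noise and spread) are one to two orders larger than the
  in vivo reference workflow row (0.07° / 0.001 mm).  The reference
  values imply a substantially finer effective marker precision or a
  different CI estimator than the dispersion reading adopted here; the
  generator's σ is a free parameter, and no claim is made that the
  default reproduces the reference precision.
- The right-TMJ trace is derived, not independently injected; its
  amplitudes match the left's only up to symphyseal coupling.
- Gimbal proximity is flagged, not failed; the decomposition is not
  meaningful within ~0.5° of |yaw| = 90°.
- The between-cycle CI definition (pointwise-then-averaged vs
  amplitude-distribution) materially changes the reported CI; both are
  implemented and the choice is recorded in the config echo.
- Landmark digitisation (cusp points, centroids, the cranial long axis)
  is upstream of this package; the landmark file contract simply trusts
  the supplied coordinates.
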