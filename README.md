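# chewkin — marker-based 6-DOF jaw kinematics

`chewkin` quantifies chewing kinematics from implanted-marker motion
data of the kind produced by biplanar videoradiography (XROMM-style)
recordings of small mammals.  It was built around proal (posterior-to-
anterior power stroke) chewing in the brown rat — three rigid bodies
(cranium, left and right hemimandibles) carrying 3–4 radio-opaque
markers each — but the machinery is generic marker-based rigid-body
kinematics.

It is aimed at comparative biomechanists and clinical researchers who
need per-cycle, 6-degree-of-freedom joint motion at the
temporomandibular joint (TMJ) and the unfused mandibular symphysis,
together with honest estimates of measurement precision.

## What it computes

Given per-frame 3-D marker coordinates, per-bone reference marker
positions (e.g. from CT), and anatomical landmarks:

1. **Filtering** — zero-phase (forward–backward) low-pass Butterworth on
   raw marker coordinates (default 20 Hz at 250 frames/s), per
   contiguous valid segment, so estimated rotations stay exactly
   orthonormal.
2. **Pose estimation** — per-frame least-squares rigid transform per
   bone (orthogonal Procrustes, reflections excluded; missing markers
   excluded, never imputed; frames with < 3 usable markers propagate as
   missing).
3. **Anatomical coordinate systems** — the cranial ACS is anchored to
   the occlusal plane fitted (total least squares) to the upper
   tooth-row cusps: X anterior along the projected cranial long axis,
   Z lateral-right in the plane, Y superior.  Mandibular ACSs are
   clones (identical world orientation at the reference frame)
   translated to the condyle / symphysis centroids.
4. **Joint coordinate systems** — Grood–Suntay-style hierarchy with Z
   fixed to the proximal body and X to the distal body, equivalent to an
   intrinsic Z–Y′–X″ factorisation of the zero-referenced relative
   rotation:

       dR = Rz(pitch) · Ry(yaw) · Rx(roll)

   Translations are the mobile origin's displacement from its zero
   position along the fixed body's ACS axes.  The zero pose is centric
   occlusion at the midpoint of a representative chew (median pitch
   amplitude); a lower-molar locator is tracked relative to the cranial
   ACS translated to the maxillary occlusal centre.
5. **Cycle statistics** — chew cycles segmented between successive gape
   maxima (amplitude-gated to exclude non-chew and food-gathering
   cycles), spline-normalised to 100 samples; per-cycle absolute
   amplitude (max − min), occlusal-phase displacement (middle 40% of
   the cycle), and between-cycle 95% CIs.
6. **Workflow precision** — frozen-specimen (zero-relative-motion)
   trials run through the identical pipeline; the t-based 95%
   half-width of the pooled per-frame joint values isolates measurement
   error.

Because no public recordings accompany the study this package was built
around, a **synthetic proal-chewing generator**
(`chewkin.simulate`) produces ground-truth kinematics — pitch-dominated
gape cycles with anterior translation concentrated in the occlusal
phase, near-zero symphyseal motion, whole-head motion, marker noise and
dropouts, and cadaver trials — so every stage is validated end to end
by parameter recovery.

## Worked example

```sh
python analysis/01_simulate.py    # build the 3-individual synthetic study
python analysis/02_analyze.py    # full pipeline per individual
python analysis/03_precision.py  # cadaver workflow precision
python analysis/04_report.py     # merged summary-table report
```

The last step prints (seed 1):

```
total chew cycles analysed: 38
recovered vs injected amplitudes (largest variables):
  rat_A condylar_Rz  injected  18.10  recovered  17.95
  rat_A condylar_Tx  injected   2.13  recovered   2.18
  rat_B condylar_Rz  injected  11.60  recovered  11.73
  rat_B condylar_Tx  injected   2.08  recovered   2.10
  rat_C condylar_Rz  injected  10.00  recovered  10.10
  rat_C condylar_Tx  injected   2.31  recovered   2.35
```

38 cycles (13 + 7 + 18) are segmented and the injected condylar pitch
and anterior-translation amplitudes are recovered to within a few
percent under 0.05 mm marker noise; at zero noise recovery is exact to
about 2 × 10⁻⁴ relative.  `results/04_summary_table.csv` mirrors the
standard summary-table layout: one row per individual with
`mean (between-cycle CI)` per variable plus a workflow-CI row.

The same pipeline is scriptable through a CLI with the verbs
`chewkin simulate | analyze | precision | report` (see `chewkin --help`);
exit codes: 0 success, 2 validation error, 3 computation error.

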