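# cervitrack

Desk-scale toolkit for **cervical-spine range-of-motion (ROM) analysis from
head-mounted-display pose streams**. A VR headset worn during a guided
examination records the head's orientation as timestamped unit quaternions
at a nominal 60 Hz; `cervitrack` turns that stream into the quantities a
physiotherapist reads off a goniometer — and more:

* calibrated **signed anatomical angles** per sample: flexion–extension
  (flexion `+`, extension `−`), lateral flexion (left `+`, right `−`) and
  rotation (right `+`, left `−`);
* **segmentation** of the six-movement examination protocol (flexion,
  extension, left side bend, right side bend, left rotation, right
  rotation) into labelled episodes, with protocol-order validation;
* per-movement **signed ROM and duration**, left/right **asymmetry**,
  **compensatory co-movement** detection (off-plane peaks and coupling
  ratios), and norm-exceedance flags against user-supplied normative
  ranges;
* session **summaries** (min/max/mean per movement) and **between-session
  comparison** to track mobility over time;
* a **simulator** that generates full protocol sessions (minimum-jerk
  movement profiles, configurable couplings, Gaussian angle noise) and a
  **digital twin of a goniometer-equipped skull rig** for validation;
* session file I/O (lossless CSV + JSON), deterministic report export, and
  the posturographic-grid trajectory plot.

## The model in brief

With `q_ref` the neutral (starting-position) orientation estimated from a
still 1 s window, each sample's relative orientation `q_rel = q_ref⁻¹ q` is
decomposed intrinsically as yaw(Y) → pitch(X) → roll(Z) in a right-handed
frame (X = subject's right, Y = up, Z = posterior), then mapped to the
clinical signs above. This order puts each anatomical movement on a single
Euler axis and places gimbal lock at |flexion| = 90°, outside cervical ROM.
ROM is the signed extremum of the episode's primary channel — what a
goniometer's maximal-excursion reading measures — after a 0.25 s centred
smoothing that removes the upward bias of a raw noisy maximum.

## Worked example

```bash
python examples/01_rig_validation.py
```

```
             plane  commanded   app  gonio  verdict
 flexion_extension        0.0     0      0  identical
 flexion_extension       34.0    34     34  identical
          rotation       45.0    45     45  identical
   lateral_flexion      -30.0   -30    -30  identical
```

Each row is one simulated rig trial: a pure single-plane excursion of the
skull model to the commanded angle. `app` is the whole-degree ROM the full
pipeline reports; `gonio` is the goniometer twin (the true angle rounded to
the instrument's whole-degree scale). `identical` on every row means the
entire chain — calibration, quaternion decomposition, segmentation, ROM
extraction — adds less than half a degree of error. Note the sign
convention at work: right lateral flexion reads −30.

`examples/02_full_session.py` analyses a simulated six-movement session
(2250 samples, 37.5 s at 60 Hz) and recovers every commanded peak within a
degree under 0.5° sensor noise; `03_compensations.py` shows co-movement and
norm-exceedance flags; `04_compare_sessions.py` the longitudinal deltas;
`05_session_files_and_plot.py` file round-trips, report export and the
90°-grid trajectory plot.

The same operations are available from the shell:

```bash
cervitrack simulate --out session1 --seed 1
cervitrack analyze session1 --out report1 --norms norms.yaml
cervitrack rig-validate
cervitrack compare session1 session2
```

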