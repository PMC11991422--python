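# Methods

## Orientation model and angle decomposition

A head pose is a unit quaternion `q` mapping head-frame vectors to the
world frame, sampled at a nominal 60 Hz. The package never analyses
absolute orientation: everything is computed on `q_rel = q_ref⁻¹ q`, the
orientation relative to the calibrated neutral `q_ref`.

The working frame is right-handed with X = subject's right, Y = up,
Z = posterior. `q_rel` is factored intrinsically as yaw(Y) → pitch(X) →
roll(Z) and mapped to clinical signs afterwards:

| channel            | internal axis | sign map                      |
|--------------------|---------------|-------------------------------|
| flexion–extension  | pitch about X | flexion `+` = −pitch          |
| lateral flexion    | roll about Z  | left `+` = +roll              |
| rotation           | yaw about Y   | right `+` = −yaw              |

This order was chosen because it puts each anatomical movement on exactly
one Euler axis and moves the Euler singularity to |flexion–extension| = 90°,
outside physiological cervical ROM. Samples beyond 85° raise a
gimbal-proximity warning (never an error). Quaternions are held to unit
norm within 1e-6 (inputs further off are renormalised with a warning; a
zero quaternion is a hard error), and the hemisphere ambiguity `q ≡ −q`
is resolved by a canonical form with the first nonzero component
non-negative. Compose/decompose round-trips are exact to 1e-9 degrees over
the physiological range, and the decomposition matches an independent
rotation-matrix Euler extraction to 1e-6 degrees (both are test
invariants).

## Neutral calibration

`estimate_neutral` averages the hemisphere-aligned quaternion components
over the first 1 s (default) of the stream and renormalises. Component
averaging is adequate here because all samples in a still window lie within
a fraction of a degree of each other, where the chordal mean and the
geodesic mean coincide to far below the instrument's resolution. The window
must be still: the smoothed angular speed (below) must stay under
10 deg/s, otherwise a calibration error names the offending span. The
stillness check runs on the *smoothed* speed deliberately — the raw
sample-to-sample geodesic rate of a jittery-but-still sensor is a norm of
noise whose mean does not shrink with averaging, and would reject perfectly
usable calibration windows.

Calibration happens once per session; participants return to the indicated
starting position between movements, so per-movement re-zeroing is neither
needed nor attempted.

## Angular speed and segmentation

The speed track is the Euclidean norm of the three channel derivatives,
with a 0.25 s centred moving average applied to each channel before
differentiation and to each derivative after. Smoothing must precede the
norm: the norm of raw finite-difference noise has a positive mean
(~tens of deg/s at 60 Hz for sub-degree noise) that no amount of averaging
of the norm itself can remove. With the default window, white angle noise
of sd 1° leaves a resting speed floor near 2–3 deg/s, comfortably under
the thresholds.

Episodes are delimited by hysteresis: open when the speed exceeds
θ_hi = 10 deg/s, close when it drops below θ_lo = 5 deg/s **and** all
three channels are back inside the ±3° neutral band (so the hold at peak,
where speed is zero but angles are large, does not end the episode).
Episodes shorter than 0.3 s are discarded as noise blips (logged); an
episode still open at the end of the series is closed at the last sample,
which is what makes single-excursion rig trials segmentable. Each episode
is labelled by its dominant channel (largest |extremum| on the smoothed
channels) and the extremum's sign — by its data, never by its protocol
position; exact ties are broken by protocol order and logged.
`validate_protocol_order` then reports missing, duplicate and out-of-order
movements against the six-movement template, using a longest-increasing-
subsequence match so a single swapped pair yields a single flag. All five
thresholds are configuration, surfaced in the CLI config file.

## ROM, compensations, summaries

ROM is the signed extremum of the episode's primary channel — a
goniometer's maximal-excursion reading, not net displacement — taken on a
0.25 s-smoothed copy of the channel. The smoothing matters under noise:
the maximum of ~200 raw noisy samples is biased upward by roughly 2.5
standard deviations, which alone would exceed a 1° error budget at
σ = 0.5°; the centred average leaves a noise-free plateau untouched while
shrinking that bias several-fold.

Compensation reports give, per episode, the signed off-plane extrema and
their coupling ratios (off-plane peak / primary peak, signed throughout —
an injected simulator coupling is recovered with its sign). A co-movement
flag requires the off-plane peak to exceed a 5° band (small co-movements
are physiological); a norm-exceedance flag requires the primary |ROM| to
exceed the user-supplied normative limit for that movement. Normative
values are configuration only — published norm tables disagree across
sources and age bands, so the package ships none.

Session summaries are plain min/max/arithmetic-mean per movement with mean
durations and mean total procedure time; no trimming or outlier handling.
Between-session comparison is the elementwise difference of summary means
(second minus first), erroring on movement-set mismatch. Left/right
asymmetry returns signed left-minus-right differences of duration and of
|ROM| for a same-plane movement pair.

## Simulator

The simulator is first-class, tested code and defines the study conditions
for every recovery test. Voluntary movement is modelled with the
minimum-jerk polynomial θ(τ) = peak·(10τ³ − 15τ⁴ + 6τ⁵), the standard
smooth-reaching profile with zero endpoint velocity and acceleration; a
movement is rise–hold–mirrored return. A protocol session is a 1.5 s
neutral lead-in (the calibration window), then the six movements in
protocol order with 2 s rests. Defaults, chosen once as mid-range healthy
adult values and used unchanged by all tests: peaks 45° flexion, 55°
extension, 35° lateral each side, 65° rotation each side; rise 1.5 s,
hold 1 s; noise sd 0.5° per channel; 60 Hz.

Couplings are injected per movement as off-plane channel → signed ratio c,
adding c × the signed primary profile to that channel. Noise is Gaussian,
added in angle space *before* composing quaternions, so σ is directly in
degrees; the quaternion stream is then exactly the composition of the
noisy channels (decomposition recovers them to machine precision, which is
itself a test invariant). Generation is deterministic given the seed.

Rig trials are noise-free step-and-hold single-plane excursions; the
ground-truth goniometer reading is the commanded angle rounded to whole
degrees, the resolution of an analog goniometer scale. Ground truth
(windows, labels, signed peaks, couplings, goniometer reading) is saved as
a JSON sidecar next to simulated session files.

What the simulator does **not** emulate: headset tracking drift and optical
error models, biomechanical joint limits or muscle dynamics, fatigue, and
trunk substitution movements. Passing recovery tests therefore demonstrate
the correctness of the analysis chain under its stated noise model, not
clinical accuracy on human recordings.

## File formats and reporting

A session is two files: `samples.csv` (`t_s,qw,qx,qy,qz[,px,py,pz]`;
quaternion scalar-first, declared in the header and metadata to avoid the
w-last ambiguity) and `meta.json` (user, session, device, rate, seed).
Floats are written with 17 significant digits and parsed with round-trip
precision, so write→read reproduces the stream bit-for-bit and every
downstream result is identical across serialization; a stream whose
quaternions are already unit-norm is deliberately not renormalised on
load for the same reason. Malformed files raise format errors naming the
offending column/line; non-monotonic timestamps raise validation errors.

Reports export as schema-checked JSON (sorted keys, floats fixed to six
decimals — re-export is byte-identical) plus a summary CSV with one row
per movement (`movement,min_deg,max_deg,mean_deg,mean_duration_s`). The
trajectory plot draws the head trace in red over two fixed orthogonal
reference lines crossing at the neutral origin (the posturographic grid);
the 90° geometry is asserted on the plot *model*'s line directions —
pixel output is presentation, not contract.

## Problem sizes and numerical choices

Default sessions are ~37.5 s (2250 samples at 60 Hz); rig trials 4.5 s
(270 samples). Recovery tests use 20 seeded sessions per condition, the
matrix-oracle equivalence 1000 random orientations, and the
neutral-calibration Monte-Carlo 100 draws — sizes at which every quantity
under test is stable to well below its tolerance while the whole suite
runs in seconds. Tie-breaks, edge padding of the moving average (window
shrinks at the series ends), and the closing of the final open episode at
the last sample are the only boundary conventions; all are exercised
directly by tests.

## Known limitations

* Orientation only: the position channel is carried through I/O but not
  analysed.
* Offline segmentation of complete sessions; no streaming mode.
* Euler decomposition degrades near |flexion| = 90° (warned, not fixed) —
  irrelevant for cervical ROM but a caution for reuse elsewhere.
* One calibration per session; a drifting reference within a session is
  not corrected.
* The normative-range mechanism flags exceedance only; it performs no
  diagnostic classification.
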