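# Methods

## Scope and data model

The package processes recordings from a wearable four-sensor sEMG forearm
band: 12-bit ADC codes (0–4095 over 0–3 V, rest reference 1.5 V) sampled at
1000 Hz per sensor, streamed as fixed-width 17-character datagrams and stored
as semicolon-separated code streams. A *session* is one test of one forearm:
three cycles of six guided hand movements (M1 flexion, M2 extension, M3 ulnar
deviation, M4 radial deviation, M5 power grip, M6 lateral grip), each cycle
slot guided as 4 s cue display, 3 s preparation/execution, 3 s hold. The unit
of analysis is the *movement segment*: 4 sensors × 13,000 samples (13 s),
obtained by the segmentation stage below.

Slots are recorded as 14 s even though the guided part is 10 s: the analysis
length is fixed at 13,000 samples, so raw slots must exceed 13 s for the
symmetric-trim homogenization to be well defined. The 14 s default is the
package's reconciliation of the guided 10 s protocol with the 13,000-sample
analysis window.

## Synthetic cohort generator

The study cohort the pipeline was designed around is not publicly deposited,
so the generator emulates it and every downstream stage is validated against
generator ground truth. What it emulates:

* **Cohort structure** — 15 subjects × 2 forearms × 3 cycles × 6 movements =
  540 instances, 90 per class; 18 instances per session.
* **Signal model** — zero-mean Gaussian noise band-limited by a 4th-order
  Butterworth band-pass (applied forward-backward), scaled by a trapezoidal
  envelope: baseline during the cue, linear ramp over the 3 s preparation,
  plateau over the 3 s hold, 0.2 s fall, baseline for the slot remainder.
  Band-limited modulated Gaussian noise is the standard sEMG surrogate; it
  reproduces exactly the property the FFT features rely on (class-specific
  spectra) and nothing more.
* **Amplitude calibration** — the instantaneous noise std is envelope/3.5,
  chosen from extreme-value arithmetic: a burst has ~2·B·T ≈ 10³ effective
  samples, whose expected Gaussian extreme is σ·√(2 ln N) ≈ 3.5σ, so the
  realized peak excursion matches the stated envelope amplitude. Per-sensor
  plateau amplitudes follow the acquisition study's reported per-sensor
  maxima — sensor 1 ±0.90 V in extension, sensor 2 ±0.15 V in radial
  deviation, sensor 3 ±0.21 V in power grip, sensor 4 ±0.53 V in ulnar
  deviation (half the reported peak-to-peak ranges). Every non-dominant sensor
  carries a cross-talk floor of 25 % of its own reported maximum; scaling by
  the movement's dominant amplitude instead would make sensor 2 peak during
  extension, contradicting the reported per-sensor dominance. The two
  movements without reported amplitudes were assigned once on muscle-placement
  grounds (flexion → sensor 3 at 0.17 V, lateral grip → sensor 4 at 0.30 V),
  below their sensors' reported maxima.
* **Spectral signatures** — one band per movement (M1 40–80 Hz, M2 60–120,
  M3 100–160, M4 130–210, M5 180–280, M6 240–360), all inside the 10–500 Hz
  sEMG range. Distinct centers make classes separable by their spectra, which
  is the premise of the FFT features; ≥80 % of plateau power falls inside the
  stated band (periodogram check).
* **Inter-subject variability** — per-(movement, sensor) amplitude jitter
  ±10 % and per-movement spectral-center jitter ±5 %, drawn deterministically
  from the session seed. Baseline (cue/gap) noise amplitude 0.02 V; cycles
  are separated by 2 s baseline gaps.
* **Seeding** — one master seed; per-(subject, arm) and per-(cycle, movement)
  substreams are spawned by counter so any session or burst is reproducible
  in isolation. Identical specs produce bit-identical output.

What it does **not** emulate: motor-unit physiology, electrode-skin
impedance, motion artifacts, inter-session electrode shift, amplitude
non-stationarity within a hold, or class overlap between gestures. Passing
recovery tests therefore demonstrates that the pipeline's stages are correct
and internally consistent — not that real forearms achieve these accuracies.
The generator's class separation makes near-perfect classification the
*expected* outcome; the published real-data accuracies for this kind of
system (70–90 %) are context, not a target the synthetic experiment can
reproduce.

Ground truth per instance: the slot's half-open sample range, the ramp onset
(cue end), and the envelope-peak position defined as the half-maximum
midpoint of the noise-free envelope, display + 0.75·prepare + 0.5·hold into
the slot (7.75 s of 14 s, fraction ≈ 0.554).

## Segmentation

Five stages: (1) load the stream; (2) split into per-sensor voltage traces;
(3) locate the three cycles from sensor 1, which measures a higher amplitude
during extension than during any other movement and so serves as the division
reference; (4) cut each cycle into six equal-length slots in protocol order;
(5) homogenize each slot to 13,000 samples and store it labeled.

**Burst localization.** Candidate bursts are contiguous regions of the 200 ms
moving-RMS envelope above 50 % of its global maximum (regions separated by
dips shorter than 0.5 s are merged; the strongest `n_cycles` regions at least
0.6 expected-cycle-lengths apart qualify). Each burst is then localized by
correlating the envelope with the protocol's activation template (3 s ramp,
3 s plateau, 0.2 s fall) and reporting the template's half-maximum midpoint at
the best alignment. The naive alternative — the envelope argmax — is
ill-conditioned on plateaued bursts (the argmax of a noisy flat plateau is
uniform across it, ±1.5 s), and half-maximum threshold crossings inherit
~0.2 s noise from the slow ramp; matched filtering integrates over the whole
burst and localizes to tens of milliseconds (measured: mean +64 ms,
worst 98 ms over 60 bursts against generator ground truth).

**Cycle windows.** The cycle length C is the median inter-peak spacing minus
the known 2 s inter-cycle rest gap (the per-cycle count should exclude the
rest between repetitions); with a single peak, C is the distance from the
peak to the end of the record scaled by the slots remaining after the
reference peak. Windows are anchored so the detected peak sits at fraction
0.554 of slot 2 — the protocol-derived position of the extension envelope
peak — rather than at the slot midpoint, which would shift every slot by
~1.5 s. Windows are clipped to the record; overlapping windows are an error.

**Slots and homogenization.** Each window is divided into six contiguous
slots, equal length up to one sample with the remainder assigned to the last
slot(s); identical boundaries apply to all four sensors, so channels never
drift relative to each other. Homogenization trims the excess d symmetrically
— floor(d/2) from the front, ceil(d/2) from the back (the extra sample comes
off the back) — to exactly 13,000 samples. Coordinates are 0-based, half-open
throughout.

## FFT features

Per sensor of a 13,000-sample segment, the DFT has bin resolution
1000/13000 ≈ 0.0769 Hz and a 6,500-bin half spectrum.

* **Full mode**: magnitudes at transform positions 0–6,499 with positions 0–4
  zeroed (DC-region components carry no movement information; zeroing rather
  than dropping preserves the canonical 6,500/26,000 dimensions).
* **Average mode**: 50 bins, bin i (1-based) the mean of |FFT| at 0-based
  transform positions 5+130(i−1)..130·i inclusive — 126 magnitudes per bin,
  four positions skipped at each bin boundary, bin 50 ending at position
  6,500. This is a faithful rendering of the acquisition software's binning
  rule, whose stride arithmetic leaves the boundary gaps; a `clean_bins`
  option computes contiguous 130-wide bins for users who consider the gap an
  artifact. The binning is validated against an independent explicit-loop
  DFT oracle to 1e-9 relative tolerance.

No windowing, detrending or per-instance normalization is applied at the
feature stage; input scaling is the classifier's responsibility. Feature
matrices stack instances in deterministic (subject, arm, cycle, movement)
order with one-hot labels.

## Classifier

A two-layer feedforward network: one hidden layer of logistic sigmoid units
(34, 49 or 63 — the study's grid), softmax output over six classes, trained
with mini-batch Adam (batch 32, learning rate 1e-3, L2 penalty 1e-4) on
cross-entropy. The implementation wraps scikit-learn's `MLPClassifier`
driven by an explicit epoch loop so that early stopping monitors *this
pipeline's* validation partition: training stops after 6 consecutive epochs
without validation-loss improvement greater than 1e-3, or at 1000 epochs, and
the best-validation weights are restored. The 1e-3 improvement floor was
chosen for convergence behaviour — mini-batch Adam keeps creeping by
~1e-4/epoch long after the fit has converged, which would defeat a patience
rule — and stops typical runs at 80–260 epochs.

Splits are stratified by class with fixed sizes round(n·0.15) for test and
validation (540 → 378/81/81), seeded and reproducible. Inputs are min-max
scaled to [−1, 1] with parameters fitted on the training partition only
(toggleable). Reports follow the confusion-matrix conventions: per-class
sensitivity = diagonal / row sum, precision = diagonal / column sum (0 where
the denominator is 0), accuracy = trace / total, for train, validation, test
and pooled partitions. All randomness — split, initialization, batch order —
derives from the configuration seed; identical configurations give identical
fits. Wall times are reported but never asserted as values (hardware
dependent); the only timing claim tested is the ordering that 200-feature
training is faster than 26,000-feature training.

## Numerical and degenerate-input choices

* ADC round trip uses round-to-nearest; quantization error ≤ 0.37 mV.
* Voltages are clipped to ±1.5 V (the sensor's physical output range).
* A flat (all-zero) trace, too few qualifying bursts, overlapping cycle
  windows, a cycle window shorter than six samples, and a slot shorter than
  13,000 samples are all distinct, named segmentation errors; the failing
  stage and arm are identified in the message.
* Frame parsing distinguishes wrong length, wrong marker, non-digit payload
  and out-of-range value.
* Constant feature columns (e.g. zeroed DC bins) min-max scale to a constant;
  a 0-probability class in a partition yields 0 sensitivity/precision rather
  than NaN.

## Problem sizes

The canonical experiment (the default everywhere) is the full study geometry:
30 sessions of 256,000 samples × 4 channels, 540 segments, 540×200 and
540×26,000 matrices. The whole pipeline runs in a few minutes on one CPU;
unit tests use 1–6-session cohorts of the same timing so every stage is
exercised at full per-session scale throughout.

## Known limitations

* The segmentation's cycle-length rule is a reconstruction; the original
  description ("data between the last peak and the end of the vector") is
  ambiguous and is used here only as the single-peak fallback.
* The matched-filter locator assumes the guided protocol's envelope shape;
  strongly non-compliant executions (no hold, double bursts) would degrade
  localization, though label recovery tolerates ~1 s of misalignment.
* The classifier is deliberately the study's architecture family only — no
  convolutional or cross-subject transfer models.
* Left/right streams are treated as independent sessions; no frame-level
  synchronization between bands is assumed.
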