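"""Five-stage movement segmentation of multichannel sEMG sessions.

Stage 1 loads the semicolon-separated eight-sensor stream; stage 2 splits it
into per-sensor voltage traces; stage 3 locates the three test cycles from the
extension bursts on sensor 1 (the sensor on the upper forearm, which measures
a higher amplitude during extension than during any other movement and so
serves as the division reference); stage 4 cuts each cycle into six
equal-length movement slots in protocol order; stage 5 homogenizes every slot
to exactly 13,000 samples by symmetric trimming and stores it with its label.

Cycle references are found on a 200 ms moving-RMS envelope: candidate bursts
are the regions above half the global envelope maximum, and each burst is
then localized by correlating the envelope with the guided protocol's
activation template (ramp, plateau, fall), reporting the template's
half-maximum midpoint at the best alignment.  Matched filtering integrates
over the whole burst, so the locator is precise to tens of milliseconds
where a raw envelope argmax on a plateaued burst would be a coin toss across
the plateau.  The cycle length is the median inter-peak spacing (optionally
minus a known inter-cycle rest gap); a single detected peak falls back to
scaling the distance from the peak to the end of the record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import fftconvolve

from .protocol import SAMPLING_RATE_HZ, SessionRecord, adc_to_voltage

DEFAULT_MOVEMENT_ORDER = ("M1", "M2", "M3", "M4", "M5", "M6")
TARGET_SAMPLES = 13000
#: Fraction of a movement slot at which the reference (extension) envelope peaks
#: under the default 4 s display / 3 s prepare / 3 s hold protocol in a 14 s slot:
#: (display + 0.75*prepare + 0.5*hold) / slot = 7.75/14.
DEFAULT_PEAK_SLOT_FRACTION = 7.75 / 14.0


class SegmentationError(RuntimeError):
    """A stage of the division algorithm failed; the message names the stage."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the division algorithm."""

    n_cycles: int = 3
    smoothing_ms: float = 200.0
    threshold_frac: float = 0.5
    min_separation_frac: float = 0.6
    peak_slot_fraction: float = DEFAULT_PEAK_SLOT_FRACTION
    intercycle_gap_s: float = 2.0
    n_movements: int = 6
    target_samples: int = TARGET_SAMPLES
    movement_order: tuple = DEFAULT_MOVEMENT_ORDER
    # activation-template shape used by the matched-filter burst locator
    ramp_s: float = 3.0
    plateau_s: float = 3.0
    fall_s: float = 0.2

    @classmethod
    def from_timing(cls, timing, **kwargs) -> "SegmentationParams":
        """Derive the protocol-dependent parameters from a ProtocolTiming."""
        from .synth import TAPER_S

        return cls(n_cycles=timing.cycles, peak_slot_fraction=timing.peak_fraction,
                   intercycle_gap_s=timing.intercycle_gap_s, ramp_s=timing.prepare_s,
                   plateau_s=timing.hold_s, fall_s=TAPER_S, **kwargs)


@dataclass
class CycleWindows:
    """Detected cycles: reference peaks plus half-open per-cycle sample windows."""

    peak_indices: np.ndarray
    windows: list
    cycle_samples: float
    slot_samples: float


@dataclass
class MovementSegment:
    """One labeled movement instance: 4 sensors x 13,000 voltage samples."""

    subject_id: str
    arm: str
    cycle: int
    movement: str
    samples: np.ndarray
    source_range: tuple | None = None  # (start, end) in the original trace

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)


def split_channels(record: SessionRecord) -> np.ndarray:
    """Stage 2: per-sensor voltage traces, shape ``(n_channels, n_samples)``."""
    return adc_to_voltage(record.channels)


def moving_rms(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Moving-RMS envelope (uniform window, edge-replicated)."""
    w = max(1, int(round(window_samples)))
    return np.sqrt(uniform_filter1d(np.asarray(x, float) ** 2, size=w, mode="nearest"))


def activation_template(ramp_s: float = 3.0, plateau_s: float = 3.0, fall_s: float = 0.2,
                        fs: int = SAMPLING_RATE_HZ):
    """Unit-amplitude activation envelope (linear ramp, plateau, linear fall).

    Returns ``(template, midpoint)`` where ``midpoint`` is the index of the
    template's half-maximum midpoint — the point the burst locator reports.
    """
    template = np.concatenate([
        np.linspace(0.0, 1.0, int(round(ramp_s * fs)), endpoint=False),
        np.ones(int(round(plateau_s * fs))),
        np.linspace(1.0, 0.0, max(2, int(round(fall_s * fs)))),
    ])
    above = np.flatnonzero(template >= 0.5)
    return template, int((above[0] + above[-1]) // 2)


def detect_cycle_peaks(trace, n_cycles: int = 3, fs: int = SAMPLING_RATE_HZ,
                       smoothing_ms: float = 200.0, threshold_frac: float = 0.5,
                       min_separation: float | None = None,
                       template: np.ndarray | None = None,
                       template_midpoint: int | None = None) -> np.ndarray:
    """Stage 3: locate the reference (extension) burst of each cycle on sensor 1.

    Returns exactly ``n_cycles`` sample indices, sorted ascending.  Candidate
    bursts are the well-separated moving-RMS regions above ``threshold_frac``
    of the global envelope maximum; each is then localized by matched
    filtering against the activation template, reporting the template's
    half-maximum midpoint at the best alignment.
    """
    x = np.asarray(trace, dtype=float).ravel()
    if x.size == 0:
        raise SegmentationError("empty trace")
    env = moving_rms(x, smoothing_ms * fs / 1000.0)
    peak_env = env.max()
    if peak_env <= 0:
        raise SegmentationError("flat trace: no activity bursts to segment")
    above = env >= threshold_frac * peak_env

    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]

    # merge runs split by brief dips (shorter than 0.5 s) below threshold
    merge_gap = int(0.5 * fs)
    regions = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - regions[-1][1] < merge_gap:
            regions[-1][1] = int(e)
        else:
            regions.append([int(s), int(e)])

    mids = np.array([(s + e) // 2 for s, e in regions])
    scores = np.array([env[s:e].max() for s, e in regions])
    if min_separation is None:
        min_separation = 0.6 * x.size / n_cycles
    kept = []
    for i in np.argsort(scores)[::-1]:
        if all(abs(mids[i] - mids[j]) >= min_separation for j in kept):
            kept.append(i)
    if len(kept) < n_cycles:
        raise SegmentationError(
            f"found only {len(kept)} qualifying activity bursts "
            f"(threshold {threshold_frac:.0%} of max envelope, "
            f"min separation {min_separation:.0f} samples); need {n_cycles}")

    if template is None:
        template, template_midpoint = activation_template(fs=fs)
    elif template_midpoint is None:
        above2 = np.flatnonzero(np.asarray(template) >= 0.5 * np.max(template))
        template_midpoint = int((above2[0] + above2[-1]) // 2)
    template = np.asarray(template, dtype=float)
    corr = fftconvolve(env, template[::-1], mode="same")
    search = int(2.5 * fs)
    peaks = []
    for i in kept[:n_cycles]:
        mid = mids[i]
        lo, hi = max(0, mid - search), min(corr.size, mid + search)
        tau = lo + int(np.argmax(corr[lo:hi]))  # best template-center alignment
        peaks.append(int(np.clip(tau + template_midpoint - template.size // 2,
                                 0, env.size - 1)))
    return np.sort(np.asarray(peaks))


def derive_cycles(peaks, trace_length: int, fs: int = SAMPLING_RATE_HZ,
                  intercycle_gap_s: float = 0.0, peak_slot_fraction: float = 0.5,
                  n_slots: int = 6) -> CycleWindows:
    """Stage 3b: estimate the per-cycle sample count and anchor cycle windows.

    With two or more peaks the cycle length is the median inter-peak spacing
    minus the (optional) known inter-cycle rest gap; a single peak falls back
    to the distance from the peak to the end of the record, scaled by the
    number of slots remaining after the reference peak.  Each window is
    anchored so its peak sits at ``peak_slot_fraction`` of the reference slot
    (slot 2, extension) and clipped to the record.
    """
    peaks = np.sort(np.asarray(peaks, dtype=int).ravel())
    if peaks.size == 0:
        raise SegmentationError("no peaks supplied")
    if peaks.size >= 2:
        spacing = float(np.median(np.diff(peaks)))
        cycle = spacing - intercycle_gap_s * fs
    else:
        tail = float(trace_length - peaks[0])
        cycle = tail * n_slots / (n_slots - 1 - peak_slot_fraction)
    slot = cycle / n_slots
    if slot < 1:
        raise SegmentationError(f"estimated slot length {slot:.1f} samples is degenerate")

    windows = []
    for p in peaks:
        start = int(round(p - (1 + peak_slot_fraction) * slot))
        end = start + int(round(cycle))
        start, end = max(0, start), min(int(trace_length), end)
        if not start <= p < end:
            raise SegmentationError(f"cycle window [{start}, {end}) does not contain its peak {p}")
        windows.append((start, end))
    for (s0, e0), (s1, e1) in zip(windows, windows[1:]):
        if e0 > s1:
            raise SegmentationError(
                f"estimated cycle length {cycle:.0f} implies overlapping windows "
                f"[{s0}, {e0}) and [{s1}, {e1})")
    return CycleWindows(peaks, windows, cycle, slot)


def split_cycle_into_movements(samples, n_slots: int = 6) -> list:
    """Stage 4: divide one cycle window into ``n_slots`` contiguous slots.

    Slots are equal length up to one sample; the remainder goes to the last
    slot(s).  The same boundaries apply to every sensor row.
    """
    a = np.asarray(samples, dtype=float)
    width = a.shape[-1]
    if width < n_slots:
        raise SegmentationError(f"cycle window of {width} samples cannot hold {n_slots} slots")
    base, rem = divmod(width, n_slots)
    lengths = [base] * (n_slots - rem) + [base + 1] * rem
    bounds = np.cumsum([0] + lengths)
    return [a[..., bounds[i]:bounds[i + 1]] for i in range(n_slots)]


def homogenize(vector, target: int = TARGET_SAMPLES, pad: bool = False) -> np.ndarray:
    """Stage 5: symmetric trim to exactly ``target`` samples (last axis).

    With excess ``d``, ``floor(d/2)`` samples are dropped from the front and
    ``ceil(d/2)`` from the back.  Inputs shorter than the target raise unless
    ``pad=True``, which zero-pads symmetrically with the same tie-break.
    """
    a = np.asarray(vector)
    n = a.shape[-1]
    d = n - target
    if d < 0:
        if not pad:
            raise SegmentationError(f"vector of {n} samples shorter than target {target}")
        front = (-d) // 2
        back = -d - front
        pad_width = [(0, 0)] * (a.ndim - 1) + [(front, back)]
        return np.pad(a, pad_width)
    return a[..., d // 2: n - (d - d // 2)]


def segment_session(record: SessionRecord, params: SegmentationParams | None = None,
                    subject_id: str | None = None) -> list:
    """Run all five stages over a session; returns one segment per movement instance.

    An 8-channel record yields ``cycles x 6`` segments per arm (left = rows
    0-3, right = rows 4-7); a 4-channel record yields one arm.  Failures are
    re-raised with the failing stage and arm named.
    """
    params = params or SegmentationParams()
    volts = split_channels(record)
    subject = subject_id or record.subject_id
    n_ch = volts.shape[0]
    if n_ch == 8:
        groups = [("left", volts[:4]), ("right", volts[4:])]
    elif n_ch == 4:
        groups = [(str(record.metadata.get("arm", "left")), volts)]
    else:
        raise SegmentationError(f"expected 4 or 8 channels, got {n_ch}")

    fs = record.sampling_rate
    template, template_mid = activation_template(params.ramp_s, params.plateau_s,
                                                 params.fall_s, fs)
    segments = []
    for arm, g in groups:
        stage = "detect_cycle_peaks"
        try:
            peaks = detect_cycle_peaks(g[0], n_cycles=params.n_cycles, fs=fs,
                                       smoothing_ms=params.smoothing_ms,
                                       threshold_frac=params.threshold_frac,
                                       template=template, template_midpoint=template_mid)
            stage = "derive_cycles"
            cw = derive_cycles(peaks, g.shape[1], fs=fs,
                               intercycle_gap_s=params.intercycle_gap_s,
                               peak_slot_fraction=params.peak_slot_fraction,
                               n_slots=params.n_movements)
            for ci, (ws, we) in enumerate(cw.windows):
                stage = "split_cycle_into_movements"
                slots = split_cycle_into_movements(g[:, ws:we], params.n_movements)
                offset = ws
                for mi, slot in enumerate(slots):
                    stage = "homogenize"
                    width = slot.shape[-1]
                    trimmed = homogenize(slot, params.target_samples)
                    front = max(0, (width - params.target_samples) // 2)
                    segments.append(MovementSegment(
                        subject, arm, ci + 1, params.movement_order[mi], trimmed,
                        source_range=(offset + front, offset + front + trimmed.shape[-1])))
                    offset += width
        except SegmentationError as exc:
            raise SegmentationError(f"stage '{stage}' failed for arm '{arm}': {exc}") from exc
    return segments


def write_segments(segments, outdir) -> Path:
    """Store one CSV per segment plus a manifest; returns the manifest path.

    Each file holds a metadata header line and 4 semicolon-separated rows of
    13,000 voltages; the filename encodes subject, arm, cycle and movement.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for seg in segments:
        fname = f"{seg.subject_id}_{seg.arm}_c{seg.cycle}_{seg.movement}.csv"
        with open(outdir / fname, "w") as fh:
            fh.write(f"# subject={seg.subject_id} arm={seg.arm} cycle={seg.cycle} "
                     f"movement={seg.movement}\n")
            np.savetxt(fh, seg.samples, fmt="%.6f", delimiter=";")
        rows.append({"file": fname, "subject": seg.subject_id, "arm": seg.arm,
                     "cycle": seg.cycle, "movement": seg.movement})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_segment_csv(path) -> MovementSegment:
    """Read one segment CSV written by :func:`write_segments`."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        samples = np.loadtxt(fh, delimiter=";", ndmin=2)
    return MovementSegment(meta.get("subject", path.stem), meta.get("arm", "left"),
                           int(meta.get("cycle", 1)), meta.get("movement", "M1"), samples)


def read_segments(directory) -> list:
    """Read every segment listed in a directory's manifest."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {directory}")
    table = pd.read_csv(manifest)
    return [read_segment_csv(directory / fname) for fname in table["file"]]
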