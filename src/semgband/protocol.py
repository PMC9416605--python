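"""Wire protocol, ADC conversion and session storage for a four-sensor sEMG armband.

The acquisition hardware digitises each of the four forearm sensors with a
12-bit ADC (codes 0-4095 spanning 0-3 V around a 1.5 V rest reference) at
1000 Hz and streams one 17-character text datagram per sampling tick: a
start-marker character followed by four zero-padded 4-digit decimal ADC
fields, one per sensor.  Two bands (left and right forearm) each emit their
own stream; offline, a session is stored as a plain-text semicolon-separated
code stream, sample-major (one frame per line), with an optional ``#`` header
line recording subject, arm and sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ADC_BITS = 12
ADC_MAX = (1 << ADC_BITS) - 1  # 4095
V_SUPPLY = 3.0
V_REF = 1.5
SAMPLING_RATE_HZ = 1000
START_MARKER = "A"
SENSORS_PER_BAND = 4
FRAME_LENGTH = 17
_FIELD_WIDTH = 4


class FrameError(ValueError):
    """A datagram could not be encoded or decoded."""


class SessionFormatError(ValueError):
    """A session file violates the storage dialect."""


def encode_frame(codes, start_marker: str = START_MARKER) -> str:
    """Serialize four ADC counts into one 17-character datagram.

    Fields are zero-padded to 4 decimal digits so every frame is fixed-width
    and parseable by character offset.
    """
    arr = np.asarray(codes)
    if arr.shape != (SENSORS_PER_BAND,):
        raise FrameError(f"expected {SENSORS_PER_BAND} sensor codes, got shape {arr.shape}")
    if len(start_marker) != 1:
        raise FrameError("start marker must be a single character")
    fields = []
    for i, c in enumerate(arr):
        value = int(c)
        if value != c:
            raise FrameError(f"sensor {i + 1} code {c!r} is not an integer")
        if not 0 <= value <= ADC_MAX:
            raise FrameError(f"sensor {i + 1} code {value} outside [0, {ADC_MAX}]")
        fields.append(f"{value:0{_FIELD_WIDTH}d}")
    return start_marker + "".join(fields)


def decode_frame(message: str, start_marker: str = START_MARKER) -> np.ndarray:
    """Parse a 17-character datagram back into the four ADC counts.

    Raises :class:`FrameError` on wrong length, wrong start marker, non-digit
    payload or a decoded value above the 12-bit range.
    """
    if len(message) != FRAME_LENGTH:
        raise FrameError(f"frame length {len(message)} != {FRAME_LENGTH}")
    if message[0] != start_marker:
        raise FrameError(f"start marker {message[0]!r} != expected {start_marker!r}")
    payload = message[1:]
    if not payload.isdigit():
        raise FrameError(f"non-digit payload in frame {message!r}")
    codes = np.array(
        [int(payload[i * _FIELD_WIDTH:(i + 1) * _FIELD_WIDTH]) for i in range(SENSORS_PER_BAND)]
    )
    if codes.max() > ADC_MAX:
        bad = int(np.argmax(codes))
        raise FrameError(f"sensor {bad + 1} decoded value {codes[bad]} exceeds {ADC_MAX}")
    return codes


def adc_to_voltage(code):
    """Map ADC counts to volts centered on the 1.5 V reference.

    ``v = 3.0 * code / 4095 - 1.5``; accepts scalars or arrays.
    """
    arr = np.asarray(code)
    if arr.size and (arr.min() < 0 or arr.max() > ADC_MAX):
        raise ValueError(f"ADC code outside [0, {ADC_MAX}]")
    volts = V_SUPPLY * arr / ADC_MAX - V_REF
    return float(volts) if np.isscalar(code) else volts


def voltage_to_adc(volts):
    """Inverse of :func:`adc_to_voltage` with round-to-nearest quantization."""
    arr = np.asarray(volts, dtype=float)
    if arr.size and (arr.min() < -V_REF - 1e-9 or arr.max() > V_REF + 1e-9):
        raise ValueError(f"voltage outside [{-V_REF}, {V_REF}] V")
    codes = np.rint((arr + V_REF) / V_SUPPLY * ADC_MAX).astype(np.int64)
    codes = np.clip(codes, 0, ADC_MAX)
    return int(codes) if np.isscalar(volts) else codes


@dataclass
class SessionRecord:
    """One stored acquisition session: raw ADC code streams plus metadata.

    ``channels`` holds one row per sensor (4 rows for a single band, 8 for a
    two-band session: sensors 1-4 left then 1-4 right), all the same length.
    """

    channels: np.ndarray
    sampling_rate: int = SAMPLING_RATE_HZ
    subject_id: str = "S00"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ch = np.asarray(self.channels)
        if ch.ndim != 2:
            raise ValueError("channels must be a 2-D (sensors x samples) array")
        if not np.issubdtype(ch.dtype, np.integer):
            if ch.size and not np.all(np.mod(ch, 1) == 0):
                raise ValueError("ADC codes must be integers")
            ch = ch.astype(np.int64)
        if ch.size and (ch.min() < 0 or ch.max() > ADC_MAX):
            raise ValueError(f"ADC codes outside [0, {ADC_MAX}]")
        self.channels = ch

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    def voltages(self) -> np.ndarray:
        """Channels converted to volts centered on the reference."""
        return adc_to_voltage(self.channels)


def write_session_csv(record: SessionRecord, path) -> Path:
    """Write a session as a semicolon-separated code stream.

    Dialect: one ``#`` header line (``key=value`` pairs), then one frame per
    line, channels in sensor order separated by ``;`` (sample-major
    interleaving).  :func:`read_session_csv` inverts it losslessly.
    """
    path = Path(path)
    header = {
        "subject": record.subject_id,
        "sampling_rate": record.sampling_rate,
        "channels": record.n_channels,
    }
    for k, v in record.metadata.items():
        if isinstance(v, (str, int, float)) and k not in header:
            header[k] = v
    with open(path, "w") as fh:
        fh.write("# " + " ".join(f"{k}={v}" for k, v in header.items()) + "\n")
        np.savetxt(fh, record.channels.T, fmt="%d", delimiter=";")
    return path


def read_session_csv(path, n_channels: int | None = None) -> SessionRecord:
    """Read a session file written by :func:`write_session_csv`.

    Headerless files are accepted; the token count must then divide by
    ``n_channels`` (default 8, the two-band stream).
    """
    text = Path(path).read_text()
    meta: dict = {}
    tokens: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            continue
        tokens.extend(t for t in line.split(";") if t.strip())
    if not tokens:
        raise SessionFormatError(f"empty session file: no samples in {path}")
    k = int(n_channels or meta.get("channels", 2 * SENSORS_PER_BAND))
    if len(tokens) % k:
        raise SessionFormatError(f"token count {len(tokens)} not divisible by {k} channels")
    try:
        values = np.asarray(tokens).astype(np.int64)
    except ValueError as exc:
        raise SessionFormatError(f"non-integer token in session file: {exc}") from exc
    channels = values.reshape(-1, k).T
    sampling_rate = int(meta.pop("sampling_rate", SAMPLING_RATE_HZ))
    subject = meta.pop("subject", "S00")
    meta.pop("channels", None)
    try:
        return SessionRecord(channels, sampling_rate=sampling_rate, subject_id=subject, metadata=meta)
    except ValueError as exc:
        raise SessionFormatError(str(exc)) from exc
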