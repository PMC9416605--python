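"""Optional live UDP layer mirroring the acquisition firmware.

Each band streams one 17-character datagram per sampling tick over UDP
(conventionally port 3333 for the left forearm and 1812 for the right).  The
pipeline itself is offline-first and file-based; this module exists only for
demos and hardware bring-up.
"""

from __future__ import annotations

import socket
import time

from .protocol import SENSORS_PER_BAND, START_MARKER, SessionRecord, encode_frame

LEFT_PORT = 3333
RIGHT_PORT = 1812


def iter_frames(record: SessionRecord, channels=(0, 1, 2, 3), start_marker: str = START_MARKER):
    """Yield one datagram per sample for the selected four channels."""
    if len(channels) != SENSORS_PER_BAND:
        raise ValueError(f"need exactly {SENSORS_PER_BAND} channels")
    block = record.channels[list(channels)]
    for t in range(block.shape[1]):
        yield encode_frame(block[:, t], start_marker=start_marker)


def send_session(record: SessionRecord, host: str = "127.0.0.1", port: int = LEFT_PORT,
                 channels=(0, 1, 2, 3), rate_hz: float | None = None) -> int:
    """Send a session's frames over UDP; returns the number of datagrams sent.

    With ``rate_hz`` set, paces transmission to that frame rate; otherwise
    sends as fast as possible.
    """
    delay = 1.0 / rate_hz if rate_hz else 0.0
    sent = 0
    with socket.socket(socket.AF_INET, socket.SOCK_DGRAM) as sock:
        for frame in iter_frames(record, channels):
            sock.sendto(frame.encode("ascii"), (host, port))
            sent += 1
            if delay:
                time.sleep(delay)
    return sent
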