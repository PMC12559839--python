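"""EDF export/import for recording sessions.

Writing uses a minimal EDF implementation (16-bit samples, one-second data
records, per-channel physical scaling): no maintained writer is available
in this stack, and the format's fixed-width ASCII header plus int16 payload
is small enough to emit directly. Reading goes through MNE's EDF reader, so
everything we write is validated against an independent parser.

Channel labels are hemisphere-prefixed contact names ("L1".."L4", "R2A",
...). Signals are stored in microvolts; the last data record is
zero-padded, so a read-back signal may be up to one second longer than the
original (padding is trimmed by the reader here when the true length is
known from the header metadata).
"""

from __future__ import annotations

import datetime
import io
import struct

import numpy as np

from .containers import RecordingSession


def _ascii_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"EDF field {s!r} exceeds {width} ascii bytes")
    return s.ljust(width).encode("ascii")


def write_edf(session: RecordingSession, path) -> None:
    """Write one session to an EDF file (one signal per contact)."""
    rate = session.sampling_rate_hz
    spr = int(round(rate))
    if abs(spr - rate) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_sig = len(session.channels)
    n_records = int(np.ceil(session.n_samples / spr))
    prefix = "L" if session.hemisphere == "left" else "R"
    labels = [f"{prefix}{c}" for c in session.channels]

    data = session.data
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig_max = 32767
    scaled = np.round(data / phys_max[:, None] * dig_max).astype("<i2")

    buf = io.BytesIO()
    header_bytes = 256 * (1 + n_sig)
    now = datetime.datetime(2000, 1, 1)
    buf.write(_ascii_field("0", 8))
    buf.write(_ascii_field(f"{session.participant_id} hemisphere={session.hemisphere}", 80))
    buf.write(_ascii_field(f"lead={session.lead_model}", 80))
    buf.write(_ascii_field(now.strftime("%d.%m.%y"), 8))
    buf.write(_ascii_field(now.strftime("%H.%M.%S"), 8))
    buf.write(_ascii_field(header_bytes, 8))
    buf.write(_ascii_field(f"n_samples={session.n_samples}", 44))
    buf.write(_ascii_field(n_records, 8))
    buf.write(_ascii_field(1, 8))
    buf.write(_ascii_field(n_sig, 4))
    for lab in labels:
        buf.write(_ascii_field(lab, 16))
    for _ in labels:
        buf.write(_ascii_field("DBS lead contact", 80))
    for _ in labels:
        buf.write(_ascii_field("uV", 8))
    for pm in phys_max:
        buf.write(_ascii_field(f"{-pm:.6g}"[:8], 8))
    for pm in phys_max:
        buf.write(_ascii_field(f"{pm:.6g}"[:8], 8))
    for _ in labels:
        buf.write(_ascii_field(-dig_max, 8))
    for _ in labels:
        buf.write(_ascii_field(dig_max, 8))
    for _ in labels:
        buf.write(_ascii_field("", 80))
    for _ in labels:
        buf.write(_ascii_field(spr, 8))
    for _ in labels:
        buf.write(_ascii_field("", 32))

    pad = n_records * spr - session.n_samples
    if pad:
        scaled = np.concatenate([scaled, np.zeros((n_sig, pad), dtype="<i2")], axis=1)
    for r in range(n_records):
        block = scaled[:, r * spr:(r + 1) * spr]
        buf.write(block.astype("<i2").tobytes())
    with open(path, "wb") as f:
        f.write(buf.getvalue())


def read_edf(path) -> RecordingSession:
    """Read an EDF file into a RecordingSession via MNE.

    Hemisphere and contact labels are recovered from the channel-name
    prefix; the true sample count (stored in the header's reserved field by
    write_edf) trims the zero-padded final record when present.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data(units="uV")
    names = raw.ch_names
    prefixes = {n[0] for n in names}
    if prefixes <= {"L"}:
        hemisphere = "left"
    elif prefixes <= {"R"}:
        hemisphere = "right"
    else:
        raise ValueError(f"mixed or unknown hemisphere prefixes in channels {names}")
    contacts = [n[1:] for n in names]
    lead_model = "eight_contact_segmented" if len(contacts) == 8 else "four_contact"

    participant_id, n_samples = "unknown", None
    with open(path, "rb") as f:
        head = f.read(256)
    patient = head[8:88].decode("ascii", "replace").strip()
    if patient:
        participant_id = patient.split()[0]
    reserved = head[192:236].decode("ascii", "replace").strip()
    if reserved.startswith("n_samples="):
        n_samples = int(reserved.split("=", 1)[1])
    if n_samples is not None:
        data_uv = data_uv[:, :n_samples]
    return RecordingSession(participant_id, hemisphere, float(raw.info["sfreq"]),
                            lead_model, contacts, data_uv)
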