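"""Minimal Standard MIDI File (format 0/1) reader and writer.

Only note events are interpreted; everything else (meta events, controllers,
pitch bend, sysex) is parsed and skipped.  Times are expressed in beats
(quarter note = 1.0) at the module boundary; the on-disk representation uses
integer ticks at the file's ticks-per-quarter resolution.

The writer emits format-0 files at ``DEFAULT_TPQ`` ticks per quarter, chosen
as 2^11 * 3 * 5 = 30720 (below the 15-bit SMF limit) so that the metrical
grid used throughout this package — quarters, eighths, triplets, dotted
values and small rational tempo scalings thereof — maps to exactly integral
tick counts and beat values round-trip to float precision.
"""

from __future__ import annotations

import struct
from typing import List, Tuple

DEFAULT_TPQ = 30720

#: (onset_beats, duration_beats, pitch, channel)
RawNote = Tuple[float, float, int, int]

PERCUSSION_CHANNEL = 9  # MIDI channel 10, zero-based


class SMFError(ValueError):
    """Raised when a file cannot be parsed as a Standard MIDI File."""


def _read_varlen(data: bytes, pos: int) -> Tuple[int, int]:
    value = 0
    while True:
        if pos >= len(data):
            raise SMFError(f"truncated variable-length quantity at byte {pos}")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _write_varlen(value: int) -> bytes:
    if value < 0:
        raise SMFError("negative delta time")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def _parse_track(data: bytes, tpq: int) -> List[Tuple[int, int, int, int, bool]]:
    """Return (tick, channel, pitch, velocity, is_on) note events of one track."""
    events = []
    pos = 0
    tick = 0
    status = None
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        if pos >= len(data):
            raise SMFError(f"truncated event at byte {pos}")
        byte = data[pos]
        if byte & 0x80:
            status = byte
            pos += 1
        elif status is None:
            raise SMFError(f"running status with no prior status byte at byte {pos}")
        kind = status & 0xF0
        channel = status & 0x0F
        if kind in (0x80, 0x90):
            if pos + 2 > len(data):
                raise SMFError(f"truncated note event at byte {pos}")
            pitch, velocity = data[pos], data[pos + 1]
            pos += 2
            is_on = kind == 0x90 and velocity > 0
            events.append((tick, channel, pitch, velocity, is_on))
        elif kind in (0xA0, 0xB0, 0xE0):
            pos += 2
        elif kind in (0xC0, 0xD0):
            pos += 1
        elif status == 0xFF:
            if pos >= len(data):
                raise SMFError(f"truncated meta event at byte {pos}")
            meta_type = data[pos]
            pos += 1
            length, pos = _read_varlen(data, pos)
            pos += length
            if meta_type == 0x2F:  # end of track
                break
        elif status in (0xF0, 0xF7):
            length, pos = _read_varlen(data, pos)
            pos += length
        else:
            raise SMFError(f"unsupported status byte 0x{status:02X} at byte {pos}")
    return events


def read_smf(path: str) -> List[RawNote]:
    """Read a format 0/1 SMF and return notes as (onset, duration, pitch, channel).

    All tracks are merged; note-on/note-off pairing is per (channel, pitch),
    first-on/first-off.  Raises :class:`SMFError` on malformed input or
    unbalanced note events.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 14 or data[:4] != b"MThd":
        raise SMFError("not a Standard MIDI File: missing MThd chunk at byte 0")
    header_len, fmt, ntracks, division = struct.unpack(">IHHH", data[4:14])
    if header_len < 6:
        raise SMFError(f"bad MThd length {header_len}")
    if fmt not in (0, 1):
        raise SMFError(f"unsupported SMF format {fmt}")
    if division & 0x8000:
        raise SMFError("SMPTE time division is not supported")
    tpq = division
    if tpq == 0:
        raise SMFError("zero ticks-per-quarter division")

    pos = 8 + header_len
    events: List[Tuple[int, int, int, int, bool]] = []
    tracks_seen = 0
    while tracks_seen < ntracks and pos < len(data):
        if pos + 8 > len(data) or data[pos : pos + 4] != b"MTrk":
            raise SMFError(f"missing MTrk chunk at byte {pos}")
        (length,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        body = data[pos + 8 : pos + 8 + length]
        if len(body) < length:
            raise SMFError(f"truncated track chunk at byte {pos}")
        events.extend(_parse_track(body, tpq))
        pos += 8 + length
        tracks_seen += 1
    if tracks_seen != ntracks:
        raise SMFError(f"header declares {ntracks} tracks, found {tracks_seen}")

    events.sort(key=lambda ev: (ev[0], not ev[4]))  # offs before ons at equal tick
    pending: dict = {}
    notes: List[RawNote] = []
    for tick, channel, pitch, _velocity, is_on in events:
        key = (channel, pitch)
        if is_on:
            pending.setdefault(key, []).append(tick)
        else:
            stack = pending.get(key)
            if not stack:
                raise SMFError(f"note-off without matching note-on (ch {channel}, pitch {pitch})")
            on_tick = stack.pop(0)
            notes.append((on_tick / tpq, (tick - on_tick) / tpq, pitch, channel))
    dangling = sum(len(v) for v in pending.values())
    if dangling:
        raise SMFError(f"{dangling} note-on event(s) without matching note-off")
    notes.sort(key=lambda n: (n[0], -n[2]))
    return notes


def write_smf(path: str, notes: List[RawNote], tpq: int = DEFAULT_TPQ) -> None:
    """Write notes as a format-0 SMF, one track, channel taken from each note."""
    events: List[Tuple[int, int, bytes]] = []  # (tick, sort_rank, message)
    for onset, duration, pitch, channel in notes:
        if not 0 <= pitch <= 127:
            raise SMFError(f"pitch {pitch} out of MIDI range")
        on_tick = round(onset * tpq)
        off_tick = round((onset + duration) * tpq)
        if off_tick <= on_tick:
            off_tick = on_tick + 1
        events.append((on_tick, 1, bytes((0x90 | channel, pitch, 64))))
        events.append((off_tick, 0, bytes((0x80 | channel, pitch, 0))))
    events.sort(key=lambda ev: (ev[0], ev[1]))

    body = bytearray()
    prev_tick = 0
    for tick, _rank, message in events:
        body += _write_varlen(tick - prev_tick)
        body += message
        prev_tick = tick
    body += _write_varlen(0) + bytes((0xFF, 0x2F, 0x00))

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, tpq))
        fh.write(b"MTrk" + struct.pack(">I", len(body)) + bytes(body))
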