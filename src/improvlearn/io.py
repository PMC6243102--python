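"""Symbolic-music and tabular I/O.

Input formats:

* note-list CSV — header ``onset,duration,pitch,is_grace,slur_group``; onsets
  and durations in beats (quarter note = 1.0), pitch as a MIDI integer;
  ``is_grace``/``slur_group`` optional (default false / none);
* Standard MIDI File, format 0 or 1 — ticks are converted to beats using the
  file's ticks-per-quarter; channel 10 (percussion) is skipped and all other
  channels merged into one stream before skyline extraction.  MIDI carries no
  grace/slur annotation, so those fields are CSV-only.

Outputs are plain TSV with fixed column order, exact on read-back.

Onsets are kept in beats rather than seconds throughout, so tempo metadata
never enters the encodings: rhythm tokens are metrical ratios.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import pandas as pd

from . import _smf
from .encode import (
    SequenceType,
    format_context,
    format_continuation,
    parse_context,
    parse_continuation,
)

logger = logging.getLogger(__name__)

CSV_HEADER = ["onset", "duration", "pitch", "is_grace", "slur_group"]

TP_COLUMNS = [
    "piece_id", "musician_id", "order", "sequence_type",
    "context", "continuation", "count", "tp",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in its declared format."""


@dataclass(frozen=True)
class NoteEvent:
    """One timed pitched event."""

    onset: float
    duration: float
    pitch: int
    is_grace: bool = False
    slur_group: Optional[int] = None

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be non-negative, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch must be a MIDI integer 0..127, got {self.pitch}")


@dataclass(frozen=True)
class Piece:
    """A piece: ordered notes plus corpus identity."""

    piece_id: str
    musician_id: str
    chronological_index: int
    notes: tuple = field(default=())

    @staticmethod
    def from_notes(
        notes: Sequence[NoteEvent],
        piece_id: str = "",
        musician_id: str = "",
        chronological_index: int = 1,
    ) -> "Piece":
        """Build a Piece, sorting notes by (onset asc, pitch desc)."""
        ordered = tuple(sorted(notes, key=lambda n: (n.onset, -n.pitch)))
        return Piece(piece_id, musician_id, chronological_index, ordered)


@dataclass(frozen=True)
class ChronologyRecord:
    """Chronological rank of a piece within its musician's timeline."""

    piece_id: str
    musician_id: str
    chronological_index: int


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    piece_id: str
    musician_id: str
    chronological_index: int
    format: str = "csv"  # "csv" | "midi"


@dataclass(frozen=True)
class CorpusManifest:
    entries: tuple

    def validate(self, base_dir: Optional[Path] = None) -> None:
        seen = set()
        for entry in self.entries:
            if not entry.piece_id or not entry.musician_id:
                raise ValueError(f"empty id in manifest entry {entry}")
            key = (entry.musician_id, entry.chronological_index)
            if key in seen:
                raise ValueError(
                    f"duplicate chronological index {entry.chronological_index} "
                    f"for musician {entry.musician_id!r}"
                )
            seen.add(key)
            path = Path(entry.path)
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            if not path.exists():
                raise FileNotFoundError(f"manifest references missing file: {path}")


def load_manifest(path: Union[str, Path]) -> CorpusManifest:
    """Load a JSON corpus manifest: list of {path, piece_id, musician_id, chronological_index, format}."""
    path = Path(path)
    with open(path) as fh:
        rows = json.load(fh)
    entries = tuple(
        ManifestEntry(
            path=row["path"],
            piece_id=row["piece_id"],
            musician_id=row["musician_id"],
            chronological_index=int(row["chronological_index"]),
            format=row.get("format", "csv"),
        )
        for row in rows
    )
    manifest = CorpusManifest(entries)
    manifest.validate(base_dir=path.parent)
    return manifest


# ---------------------------------------------------------------------------
# note reading
# ---------------------------------------------------------------------------

def _read_notes_csv(path: Path) -> List[NoteEvent]:
    notes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "onset" not in reader.fieldnames:
            raise FormatError(f"{path}: line 1: missing CSV header with 'onset' column")
        for lineno, row in enumerate(reader, start=2):
            try:
                is_grace = str(row.get("is_grace") or "").strip().lower() in ("1", "true", "t", "yes")
                slur_raw = (row.get("slur_group") or "").strip()
                notes.append(
                    NoteEvent(
                        onset=float(row["onset"]),
                        duration=float(row["duration"]),
                        pitch=int(row["pitch"]),
                        is_grace=is_grace,
                        slur_group=int(slur_raw) if slur_raw else None,
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return notes


def _read_notes_midi(path: Path) -> List[NoteEvent]:
    try:
        raw = _smf.read_smf(str(path))
    except _smf.SMFError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return [
        NoteEvent(onset=onset, duration=duration, pitch=pitch)
        for onset, duration, pitch, channel in raw
        if channel != _smf.PERCUSSION_CHANNEL
    ]


def read_notes(
    path: Union[str, Path],
    format: str,
    piece_id: str = "",
    musician_id: str = "",
    chronological_index: int = 1,
) -> Piece:
    """Read one piece from a CSV note list or a Standard MIDI File.

    Exact duplicate attacks (same onset and pitch) are deduplicated with a
    warning, keeping the first occurrence.
    """
    path = Path(path)
    if format == "csv":
        notes = _read_notes_csv(path)
    elif format == "midi":
        notes = _read_notes_midi(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'midi'")

    seen = set()
    deduped = []
    for note in notes:
        key = (note.onset, note.pitch)
        if key in seen:
            logger.warning("%s: duplicate note at onset %s pitch %s dropped", path, *key)
            continue
        seen.add(key)
        deduped.append(note)

    return Piece.from_notes(
        deduped,
        piece_id=piece_id or path.stem,
        musician_id=musician_id,
        chronological_index=chronological_index,
    )


def read_corpus(manifest: CorpusManifest, base_dir: Union[str, Path, None] = None) -> List[Piece]:
    base = Path(base_dir) if base_dir is not None else None
    pieces = []
    for entry in manifest.entries:
        path = Path(entry.path)
        if base is not None and not path.is_absolute():
            path = base / path
        pieces.append(
            read_notes(
                path,
                entry.format,
                piece_id=entry.piece_id,
                musician_id=entry.musician_id,
                chronological_index=entry.chronological_index,
            )
        )
    return pieces


# ---------------------------------------------------------------------------
# note writing
# ---------------------------------------------------------------------------

def write_notes_csv(piece: Piece, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for note in piece.notes:
            writer.writerow([
                repr(note.onset), repr(note.duration), note.pitch,
                int(note.is_grace),
                note.slur_group if note.slur_group is not None else "",
            ])


def write_notes_midi(piece: Piece, path: Union[str, Path]) -> None:
    """Write the piece as a format-0 SMF (grace/slur annotations are lost)."""
    _smf.write_smf(
        str(path),
        [(n.onset, n.duration, n.pitch, 0) for n in piece.notes],
    )


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def tp_table_frame(table) -> pd.DataFrame:
    """Flatten a TPTable into a DataFrame with the fixed column order."""
    joint = SequenceType(table.sequence_type).is_joint
    rows = []
    for context, continuation, count, tp in table.items():
        rows.append({
            "piece_id": table.piece_id,
            "musician_id": table.musician_id,
            "order": table.order,
            "sequence_type": SequenceType(table.sequence_type).value,
            "context": format_context(context, joint),
            "continuation": format_continuation(continuation, joint),
            "count": count,
            "tp": tp,
        })
    return pd.DataFrame(rows, columns=TP_COLUMNS)


def write_tp_table(table, path: Union[str, Path]) -> None:
    """Write a TPTable as TSV; re-reading reproduces it exactly."""
    tp_table_frame(table).to_csv(path, sep="\t", index=False)


def read_tp_table(path: Union[str, Path]):
    """Read back a TSV written by :func:`write_tp_table`."""
    from .markov import TPTable  # local import to avoid a cycle

    frame = pd.read_csv(path, sep="\t", dtype={"piece_id": str, "musician_id": str},
                        keep_default_na=False)
    if frame.empty:
        raise FormatError(f"{path}: empty transition-probability table")
    first = frame.iloc[0]
    seq_type = SequenceType(first["sequence_type"])
    joint = seq_type.is_joint
    counts: dict = {}
    for _, row in frame.iterrows():
        context = parse_context(str(row["context"]), joint)
        continuation = parse_continuation(str(row["continuation"]), joint)
        counts.setdefault(context, {})[continuation] = int(row["count"])
    return TPTable(
        piece_id=str(first["piece_id"]),
        musician_id=str(first["musician_id"]),
        sequence_type=seq_type,
        order=int(first["order"]),
        counts=counts,
    )


def write_records(records: Sequence, path: Union[str, Path]) -> None:
    """Write a homogeneous list of record dataclasses (entropy/chronology) as TSV."""
    from dataclasses import asdict

    frame = pd.DataFrame([asdict(record) for record in records])
    frame.to_csv(path, sep="\t", index=False)
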