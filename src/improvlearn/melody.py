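"""Skyline reduction of a polyphonic piece to its highest-pitch line.

The melodic surface analyzed downstream is the monophonic sequence of the
highest pitch attacked at each distinct onset, after removing ornaments:

1. grace notes are dropped;
2. within each slur group only the first note is kept, so a slurred run
   counts as a single melodic event;
3. at each distinct onset, the highest pitch among the notes attacked there
   is kept (a chord reduces to its top note).

Note durations and rests play no further role: every downstream rhythm
quantity is computed from onsets alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

from .io import Piece


@dataclass(frozen=True)
class MelodyLine:
    """Monophonic (onset, pitch) line of a piece; onsets strictly increasing."""

    piece_id: str
    events: Tuple[Tuple[float, int], ...] = field(default=())

    def __post_init__(self) -> None:
        onsets = [onset for onset, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError(f"melody onsets not strictly increasing in {self.piece_id!r}")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> List[float]:
        return [onset for onset, _ in self.events]

    @property
    def pitches(self) -> List[int]:
        return [pitch for _, pitch in self.events]


def extract_melody(piece: Piece) -> MelodyLine:
    """Reduce ``piece`` to its skyline :class:`MelodyLine`.

    A piece with no surviving notes yields an empty melody, not an error.
    """
    notes = [note for note in piece.notes if not note.is_grace]

    seen_slurs = set()
    kept = []
    for note in notes:  # notes are sorted by onset, so "first of slur" is well defined
        if note.slur_group is not None:
            if note.slur_group in seen_slurs:
                continue
            seen_slurs.add(note.slur_group)
        kept.append(note)

    by_onset: dict = {}
    for note in kept:
        prev = by_onset.get(note.onset)
        if prev is None or note.pitch > prev:
            by_onset[note.onset] = note.pitch

    events = tuple(sorted(by_onset.items()))
    return MelodyLine(piece_id=piece.piece_id, events=events)
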