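"""Relative spectro-temporal n-gram encodings of a melody.

A melody is turned into overlapping windows (stride 1) of four sequence
types, for Markov orders 1-6:

* ``PITCH`` — relative pitch only: each window of n+1 notes is re-zeroed to
  its first pitch, so tokens are semitone offsets (0, p2-p1, ..., p_{n+1}-p1).
  Transposition-invariant by construction.
* ``RHYTHM`` — relative rhythm only: each window of n+1 inter-onset
  intervals (IOIs, hence n+2 notes) is expressed as ratios to the window's
  first IOI (1.0, d2/d1, ...).  Tempo-invariant by construction.
* ``PITCH_WITH_RHYTHM`` — pitch-led joint windows: the pitch tokens of a
  PITCH window paired with the rhythm ratios of the n IOIs inside that
  window.  At order 1 there is only a single IOI, so it is expressed as a
  ratio to the crotchet (quarter note = 1.0 beat) instead of a self-ratio.
* ``RHYTHM_WITH_PITCH`` — rhythm-led joint windows: the rhythm tokens of a
  RHYTHM window paired with the re-zeroed pitches of all n+2 notes spanned.

Rhythm ratios are rounded to 3 decimal places after division, so e.g. a
triplet eighth against a quarter always yields the token 0.333 and 1/3 and
2/6 collide onto the same token.  The window's continuation is its last
token (or last token pair for joint types); the context is everything else
in positional order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, List, Sequence, Tuple, Union

logger = logging.getLogger(__name__)

RATIO_DECIMALS = 3


class SequenceType(str, Enum):
    """The four relative sequence encodings."""

    PITCH = "pitch"
    RHYTHM = "rhythm"
    PITCH_WITH_RHYTHM = "pitch_rhythm"
    RHYTHM_WITH_PITCH = "rhythm_pitch"

    @property
    def is_joint(self) -> bool:
        return self in (SequenceType.PITCH_WITH_RHYTHM, SequenceType.RHYTHM_WITH_PITCH)


MIN_ORDER, MAX_ORDER = 1, 6

Token = Union[int, float]
#: context of a simple window: tuple of tokens; of a joint window: a pair
#: (primary-feature tokens, secondary-feature tokens), each a tuple.
Context = Union[Tuple[Token, ...], Tuple[Tuple[Token, ...], Tuple[Token, ...]]]
Continuation = Union[Token, Tuple[Token, Token]]


def check_order(n: int) -> int:
    if not MIN_ORDER <= n <= MAX_ORDER:
        raise ValueError(f"Markov order must be in {MIN_ORDER}..{MAX_ORDER}, got {n}")
    return int(n)


@dataclass(frozen=True)
class NGramWindow:
    """One relative-encoded window: context plus its continuation."""

    sequence_type: SequenceType
    order: int
    context: Context
    continuation: Continuation

    @property
    def pattern(self) -> Tuple[Context, Continuation]:
        return (self.context, self.continuation)


# ---------------------------------------------------------------------------
# token formatting (the field's bracketed serialization)
# ---------------------------------------------------------------------------

def format_token(token: Token) -> str:
    if isinstance(token, bool):
        raise TypeError("bool is not a token")
    if isinstance(token, int):
        return str(token)
    if float(token) == int(token):
        return str(int(token))
    return f"{token:.3f}".rstrip("0").rstrip(".")


def _parse_token(text: str) -> Token:
    try:
        return int(text)
    except ValueError:
        return float(text)


def format_tokens(tokens: Sequence[Token]) -> str:
    return ", ".join(format_token(t) for t in tokens)


def format_pattern(window: NGramWindow) -> str:
    """Serialize a full window in the field's bracketed style.

    Simple types read e.g. ``1, 0.333``; joint types read e.g.
    ``[0, -1, -2] with [1, 0.5]`` (primary feature first).
    """
    if window.sequence_type.is_joint:
        primary_ctx, secondary_ctx = window.context
        primary_cont, secondary_cont = window.continuation
        primary = (*primary_ctx, primary_cont)
        secondary = (*secondary_ctx, secondary_cont)
        return f"[{format_tokens(primary)}] with [{format_tokens(secondary)}]"
    return format_tokens((*window.context, window.continuation))


def format_context(context: Context, joint: bool) -> str:
    if joint:
        a, b = context
        return f"[{format_tokens(a)}] with [{format_tokens(b)}]"
    return format_tokens(context)


def format_continuation(continuation: Continuation, joint: bool) -> str:
    if joint:
        a, b = continuation
        return f"[{format_token(a)}] with [{format_token(b)}]"
    return format_token(continuation)


def _parse_token_list(text: str) -> Tuple[Token, ...]:
    text = text.strip()
    if not text:
        return ()
    return tuple(_parse_token(part.strip()) for part in text.split(","))


def parse_context(text: str, joint: bool) -> Context:
    if joint:
        left, _, right = text.partition(" with ")
        return (_parse_token_list(left.strip("[]")), _parse_token_list(right.strip("[]")))
    return _parse_token_list(text)


def parse_continuation(text: str, joint: bool) -> Continuation:
    if joint:
        left, _, right = text.partition(" with ")
        (a,) = _parse_token_list(left.strip("[]"))
        (b,) = _parse_token_list(right.strip("[]"))
        return (a, b)
    return _parse_token(text)


def pattern_sort_key(window_or_pattern) -> str:
    """Deterministic lexicographic key on the serialized pattern string."""
    if isinstance(window_or_pattern, NGramWindow):
        return format_pattern(window_or_pattern)
    return window_or_pattern


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

def _ratio(value: float, base: float) -> float:
    return round(value / base, RATIO_DECIMALS)


def _iois(onsets: Sequence[float]) -> List[float]:
    return [onsets[i + 1] - onsets[i] for i in range(len(onsets) - 1)]


def encode_pitch(melody, n: int) -> Iterator[NGramWindow]:
    """Relative-pitch windows of order ``n`` (n+1 notes per window)."""
    n = check_order(n)
    pitches = [pitch for _onset, pitch in melody.events]
    for i in range(len(pitches) - n):
        tokens = tuple(pitches[i + j] - pitches[i] for j in range(n + 1))
        yield NGramWindow(SequenceType.PITCH, n, tokens[:n], tokens[n])


def encode_rhythm(melody, n: int) -> Iterator[NGramWindow]:
    """Relative-rhythm (IOI-ratio) windows of order ``n`` (n+1 IOIs each)."""
    n = check_order(n)
    onsets = [onset for onset, _pitch in melody.events]
    iois = _iois(onsets)
    for i in range(len(iois) - n):
        run = iois[i : i + n + 1]
        if min(run) <= 0:
            logger.warning(
                "skipping rhythm window at index %d: non-positive IOI %s", i, run
            )
            continue
        tokens = tuple(_ratio(d, run[0]) for d in run)
        yield NGramWindow(SequenceType.RHYTHM, n, tokens[:n], tokens[n])


def encode_pitch_with_rhythm(melody, n: int) -> Iterator[NGramWindow]:
    """Pitch-led joint windows: n+1 pitch tokens with the run's n IOI tokens.

    At order 1 the single IOI has no reference interval inside the window,
    so it is expressed as a ratio to the crotchet (1.0 beat); from order 2
    upward rhythm tokens are self-ratios to the run's first IOI.
    """
    n = check_order(n)
    events = melody.events
    for i in range(len(events) - n):
        run = events[i : i + n + 1]
        pitches = [pitch for _o, pitch in run]
        iois = _iois([onset for onset, _p in run])
        if min(iois) <= 0:
            logger.warning(
                "skipping pitch-with-rhythm window at index %d: non-positive IOI %s",
                i, iois,
            )
            continue
        ptok = tuple(p - pitches[0] for p in pitches)
        if n == 1:
            rtok: Tuple[Token, ...] = (_ratio(iois[0], 1.0),)
        else:
            rtok = tuple(_ratio(d, iois[0]) for d in iois)
        yield NGramWindow(
            SequenceType.PITCH_WITH_RHYTHM,
            n,
            (ptok[:-1], rtok[:-1]),
            (ptok[-1], rtok[-1]),
        )


def encode_rhythm_with_pitch(melody, n: int) -> Iterator[NGramWindow]:
    """Rhythm-led joint windows: n+1 IOI tokens with all n+2 pitch tokens."""
    n = check_order(n)
    events = melody.events
    for i in range(len(events) - n - 1):
        run = events[i : i + n + 2]
        pitches = [pitch for _o, pitch in run]
        iois = _iois([onset for onset, _p in run])
        if min(iois) <= 0:
            logger.warning(
                "skipping rhythm-with-pitch window at index %d: non-positive IOI %s",
                i, iois,
            )
            continue
        rtok = tuple(_ratio(d, iois[0]) for d in iois)
        ptok = tuple(p - pitches[0] for p in pitches)
        yield NGramWindow(
            SequenceType.RHYTHM_WITH_PITCH,
            n,
            (rtok[:-1], ptok[:-1]),
            (rtok[-1], ptok[-1]),
        )


_ENCODERS = {
    SequenceType.PITCH: encode_pitch,
    SequenceType.RHYTHM: encode_rhythm,
    SequenceType.PITCH_WITH_RHYTHM: encode_pitch_with_rhythm,
    SequenceType.RHYTHM_WITH_PITCH: encode_rhythm_with_pitch,
}


def encode(melody, sequence_type: SequenceType, n: int) -> Iterator[NGramWindow]:
    """Dispatch to the encoder for ``sequence_type``."""
    return _ENCODERS[SequenceType(sequence_type)](melody, n)
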