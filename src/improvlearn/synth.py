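"""Synthetic improvisation corpora with known transition structure.

The generator emulates the structure of the study corpus — three musicians,
seven chronologically ordered pieces each — while keeping the underlying
statistics exactly known, so every pipeline stage can be validated by
parameter recovery instead of by undeposited recordings.

A musician is specified by:

* a pitch-interval process — either an explicit order-g Markov table over
  semitone-interval tokens, or a motif process (concatenation of fixed
  interval motifs sampled i.i.d. from a per-musician motif set).  The motif
  form makes "hierarchy" corpora easy: musicians whose motifs are
  permutations of one shared interval multiset have identical unigram
  (order-1 window) statistics but distinct high-order patterns;
* an i.i.d. inter-onset-interval (IOI) token distribution over a metrical
  grid (quarters, eighths, triplets, dotted values...);
* surface decorations: chord probability (extra pitches added below a
  melody note), grace-note probability, a per-piece transposition offset
  and a per-piece tempo scale, and optionally a linear chronological drift
  of one transition pattern's probability.

Decorations never touch the clean truth line: chords sit strictly below the
melody at the same onset, graces are flagged, transposition is a constant
pitch offset and tempo a constant onset scale, so the skyline reduction of
the decorated piece reproduces the truth line and all relative encodings
(except the order-1 crotchet-ratio token, which scales with tempo by
design) are unchanged.

Onsets are accumulated as integer ticks at 30720 per quarter so that every
IOI token and every tempo scale on the supported grid stays exactly
representable; beats are recovered by a single division.

Randomness: one corpus seed; per-piece substreams are derived from
(seed, musician id, chronological index), so pieces are reproducible and
independent of generation order, and the decoration stream is separate
from the core pitch/rhythm stream (toggling decorations does not change
the truth line).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._smf import DEFAULT_TPQ
from .io import ChronologyRecord, NoteEvent, Piece
from .melody import MelodyLine

TPQ = DEFAULT_TPQ

#: metrical IOI grid, in beats (exact rationals; 1/3 = triplet pair etc.)
IOI_TOKENS: Tuple[Fraction, ...] = (
    Fraction(1, 4), Fraction(1, 3), Fraction(1, 2), Fraction(2, 3),
    Fraction(1), Fraction(3, 2), Fraction(2), Fraction(3),
)
DEFAULT_IOI_DIST: Dict[Fraction, float] = {
    Fraction(1, 4): 0.10, Fraction(1, 3): 0.10, Fraction(1, 2): 0.25,
    Fraction(2, 3): 0.10, Fraction(1): 0.25, Fraction(3, 2): 0.08,
    Fraction(2): 0.08, Fraction(3): 0.04,
}

#: tempo scales that keep the tick grid integral
TEMPO_GRID: Tuple[float, ...] = (0.8, 0.9, 1.0, 1.1, 1.25)

PITCH_CENTER = 66
PITCH_LOW, PITCH_HIGH = 24, 108
CHORD_OFFSETS = (3, 4, 5, 7, 8, 9, 12)
GRACE_TICKS_MAX = TPQ // 8

IntervalContext = Tuple[int, ...]
IntervalTable = Dict[IntervalContext, Dict[int, float]]


@dataclass(frozen=True)
class DriftSpec:
    """Linear chronological drift of one transition's probability.

    tp at chronological index k is base + slope * (k - 1), clamped to
    [0, 1]; the remaining mass of the context is rescaled proportionally.
    """

    context: IntervalContext
    continuation: int
    slope: float


@dataclass(frozen=True)
class MusicianSpec:
    """Generator parameters of one synthetic musician."""

    musician_id: str
    order: int = 1
    pitch_tp: Optional[IntervalTable] = None
    motifs: Optional[Tuple[Tuple[int, ...], ...]] = None
    ioi_dist: Dict[Fraction, float] = field(
        default_factory=lambda: dict(DEFAULT_IOI_DIST)
    )
    chord_prob: float = 0.25
    grace_prob: float = 0.04
    transpositions: Optional[Tuple[int, ...]] = None  # per piece; random if None
    tempo_scales: Optional[Tuple[float, ...]] = None  # per piece; random if None
    drift: Optional[DriftSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.pitch_tp is None) == (self.motifs is None):
            raise ValueError("specify exactly one of pitch_tp or motifs")
        for prob in (self.chord_prob, self.grace_prob):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("decoration probabilities must be in [0, 1]")
        if self.pitch_tp is not None:
            for context, dist in self.pitch_tp.items():
                if len(context) != self.order:
                    raise ValueError(f"context {context} does not match order {self.order}")
                total = sum(dist.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"distribution for context {context} sums to {total}")
        total = sum(self.ioi_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"IOI distribution sums to {total}")


@dataclass
class SyntheticCorpus:
    """Pieces with manifest and the exact generating statistics."""

    pieces: List[Piece]
    truths: Dict[str, MelodyLine]
    chronology: List[ChronologyRecord]
    specs: Dict[str, MusicianSpec]

    @property
    def musician_of(self) -> Dict[str, str]:
        return {record.piece_id: record.musician_id for record in self.chronology}


def _substream(seed: int, musician_id: str, index: int, purpose: str) -> np.random.Generator:
    return np.random.default_rng(
        [seed, zlib.crc32(musician_id.encode()), index, zlib.crc32(purpose.encode())]
    )


def drifted_table(spec: MusicianSpec, chronological_index: int) -> IntervalTable:
    """The musician's interval table at a chronological index, drift applied."""
    if spec.pitch_tp is None:
        raise ValueError("drifted_table requires a Markov (pitch_tp) spec")
    table = {ctx: dict(dist) for ctx, dist in spec.pitch_tp.items()}
    if spec.drift is None:
        return table
    drift = spec.drift
    dist = table.get(drift.context)
    if dist is None or drift.continuation not in dist:
        raise ValueError(f"drift pattern {drift.context} -> {drift.continuation} not in table")
    base = dist[drift.continuation]
    target = min(max(base + drift.slope * (chronological_index - 1), 0.0), 1.0)
    rest = 1.0 - base
    scale = (1.0 - target) / rest if rest > 0 else 0.0
    for continuation in dist:
        dist[continuation] = dist[continuation] * scale
    dist[drift.continuation] = target
    return table


def _sample_markov_intervals(
    table: IntervalTable,
    n: int,
    rng: np.random.Generator,
    start_pitch: int = PITCH_CENTER,
    low: int = PITCH_LOW,
    high: int = PITCH_HIGH,
) -> List[int]:
    """Sample n intervals, keeping the integrated pitch inside [low, high].

    At the register boundary the conditional is restricted to inward steps
    and renormalized — the musician picks a playable note — so the emitted
    stream stays in the interval vocabulary; the distortion of the
    conditionals is proportional to the boundary-visit rate (a fraction of
    a percent at the default range).
    """
    contexts = sorted(table)
    context = contexts[rng.integers(len(contexts))]
    pitch = start_pitch
    intervals: List[int] = []
    for _ in range(n):
        dist = table.get(context)
        if dist is None:
            raise ValueError(f"generator table is not closed: context {context} unreachable")
        symbols = sorted(s for s in dist if low <= pitch + s <= high)
        if not symbols:
            raise ValueError(f"no playable continuation from pitch {pitch} in context {context}")
        probs = np.array([dist[s] for s in symbols])
        step = symbols[rng.choice(len(symbols), p=probs / probs.sum())]
        intervals.append(step)
        pitch += step
        context = (*context[1:], step)
    return intervals


def _sample_motif_intervals(
    motifs: Sequence[Tuple[int, ...]], n: int, rng: np.random.Generator
) -> List[int]:
    intervals: List[int] = []
    while len(intervals) < n:
        motif = motifs[rng.integers(len(motifs))]
        intervals.extend(motif)
    return intervals[:n]


def _integrate_pitches(intervals: Sequence[int]) -> List[int]:
    """Integrate intervals from the center pitch.

    Markov streams are range-bounded at sampling time; motif streams return
    to their start pitch after every motif (zero-sum multiset), so the walk
    stays well inside the MIDI range either way.
    """
    pitches = [PITCH_CENTER]
    for step in intervals:
        pitches.append(pitches[-1] + step)
    if min(pitches) < 0 or max(pitches) > 127:
        raise ValueError("pitch walk left the MIDI range; check the generator spec")
    return pitches


def sample_piece(
    spec: MusicianSpec,
    chronological_index: int,
    length: int,
    piece_id: Optional[str] = None,
) -> Tuple[Piece, MelodyLine]:
    """Sample one decorated piece and its clean monophonic truth line."""
    if length < spec.order + 2:
        raise ValueError(f"length {length} too small for order {spec.order} (need >= {spec.order + 2})")
    if piece_id is None:
        piece_id = f"{spec.musician_id}_p{chronological_index:02d}"

    rng_core = _substream(spec.seed, spec.musician_id, chronological_index, "core")
    rng_decor = _substream(spec.seed, spec.musician_id, chronological_index, "decor")

    if spec.pitch_tp is not None:
        table = drifted_table(spec, chronological_index)
        intervals = _sample_markov_intervals(table, length - 1, rng_core)
    else:
        intervals = _sample_motif_intervals(spec.motifs, length - 1, rng_core)

    if spec.transpositions is not None:
        transposition = spec.transpositions[chronological_index - 1]
    else:
        transposition = int(rng_decor.integers(-5, 7))
    if spec.tempo_scales is not None:
        tempo = spec.tempo_scales[chronological_index - 1]
    else:
        tempo = TEMPO_GRID[rng_decor.integers(len(TEMPO_GRID))]

    pitches = [p + transposition for p in _integrate_pitches(intervals)]

    tokens = sorted(spec.ioi_dist)
    probs = np.array([spec.ioi_dist[t] for t in tokens])
    ioi_choices = rng_core.choice(len(tokens), size=length - 1, p=probs / probs.sum())
    tempo_frac = Fraction(tempo).limit_denominator(100)
    tick_of = {t: t * TPQ * tempo_frac for t in tokens}
    ioi_ticks = [
        int(tick_of[tokens[i]]) if tick_of[tokens[i]].denominator == 1
        else round(float(tick_of[tokens[i]]))
        for i in ioi_choices
    ]

    onset_ticks = [0]
    for ticks in ioi_ticks:
        onset_ticks.append(onset_ticks[-1] + ticks)

    truth_events = tuple(
        (ticks / TPQ, pitch) for ticks, pitch in zip(onset_ticks, pitches)
    )
    truth = MelodyLine(piece_id=piece_id, events=truth_events)

    notes: List[NoteEvent] = []
    for i, (ticks, pitch) in enumerate(zip(onset_ticks, pitches)):
        onset = ticks / TPQ
        duration_ticks = ioi_ticks[i] if i < len(ioi_ticks) else TPQ
        duration = duration_ticks / TPQ
        notes.append(NoteEvent(onset=onset, duration=duration, pitch=pitch))
        if rng_decor.random() < spec.chord_prob:
            for offset in rng_decor.choice(
                CHORD_OFFSETS, size=rng_decor.integers(1, 3), replace=False
            ):
                low = pitch - int(offset)
                if low >= 0:
                    notes.append(NoteEvent(onset=onset, duration=duration, pitch=low))
        if i > 0 and rng_decor.random() < spec.grace_prob:
            gap = min(ioi_ticks[i - 1] // 2, GRACE_TICKS_MAX)
            if gap > 0:
                grace_pitch = pitch + int(rng_decor.choice([-2, -1, 1, 2]))
                if 0 <= grace_pitch <= 127:
                    notes.append(
                        NoteEvent(
                            onset=(ticks - gap) / TPQ,
                            duration=gap / TPQ,
                            pitch=grace_pitch,
                            is_grace=True,
                        )
                    )

    piece = Piece.from_notes(
        notes,
        piece_id=piece_id,
        musician_id=spec.musician_id,
        chronological_index=chronological_index,
    )
    return piece, truth


def make_corpus(
    specs: Sequence[MusicianSpec],
    pieces_per_musician: int = 7,
    length: int = 600,
) -> SyntheticCorpus:
    """Sample a full corpus (default 3 musicians x 7 chronological pieces)."""
    ids = [spec.musician_id for spec in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("musician ids must be distinct")
    pieces: List[Piece] = []
    truths: Dict[str, MelodyLine] = {}
    chronology: List[ChronologyRecord] = []
    for spec in specs:
        for k in range(1, pieces_per_musician + 1):
            piece, truth = sample_piece(spec, k, length)
            pieces.append(piece)
            truths[piece.piece_id] = truth
            chronology.append(
                ChronologyRecord(piece.piece_id, spec.musician_id, k)
            )
    return SyntheticCorpus(
        pieces=pieces,
        truths=truths,
        chronology=chronology,
        specs={spec.musician_id: spec for spec in specs},
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def stationary_context_distribution(
    table: IntervalTable, tol: float = 1e-12, max_iter: int = 100_000
) -> Dict[IntervalContext, float]:
    """Stationary distribution of the context chain of an interval table."""
    contexts = sorted(table)
    index = {ctx: i for i, ctx in enumerate(contexts)}
    n = len(contexts)
    P = np.zeros((n, n))
    for ctx, dist in table.items():
        for continuation, prob in dist.items():
            nxt = (*ctx[1:], continuation)
            if nxt not in index:
                raise ValueError(f"table is not closed: successor context {nxt} missing")
            P[index[ctx], index[nxt]] += prob
    pi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new = pi @ P
        if np.abs(new - pi).max() < tol:
            pi = new
            break
        pi = new
    pi = pi / pi.sum()
    return {ctx: float(pi[index[ctx]]) for ctx in contexts}


def generator_entropy(table: IntervalTable) -> float:
    """Conditional entropy (bits) of an interval table under its stationary law."""
    pi = stationary_context_distribution(table)
    h = 0.0
    for ctx, dist in table.items():
        for prob in dist.values():
            if prob > 0:
                h -= pi[ctx] * prob * np.log2(prob)
    return float(h)


def true_pitch_window_tps(table: IntervalTable) -> Dict[Tuple[Tuple[int, ...], int], float]:
    """Generator conditionals keyed by relative-pitch window tokens.

    An order-(g+1) PITCH window spans g+1 intervals; its context tokens are
    the cumulative sums (0, i1, i1+i2, ...) of the first g intervals and the
    continuation token adds the (g+1)th, so the window conditional equals
    the generator's P(next interval | last g intervals).
    """
    out = {}
    for ctx, dist in table.items():
        prefix = [0]
        for step in ctx:
            prefix.append(prefix[-1] + step)
        for continuation, prob in dist.items():
            out[(tuple(prefix), prefix[-1] + continuation)] = prob
    return out


# ---------------------------------------------------------------------------
# ready-made spec families
# ---------------------------------------------------------------------------

def random_markov_spec(
    musician_id: str,
    order: int,
    alphabet: Sequence[int] = (-2, -1, 1, 2),
    concentration: float = 3.0,
    uniform_mix: float = 0.5,
    symmetric: bool = True,
    seed: int = 0,
    **kwargs,
) -> MusicianSpec:
    """A closed order-g interval chain with Dirichlet-distributed rows.

    With ``symmetric=True`` (requires an alphabet closed under negation) the
    table satisfies P(-b | -ctx) = P(b | ctx), which makes the chain
    statistically invariant under pitch inversion and hence drift-free: the
    melodic random walk has exactly zero mean step.  ``uniform_mix`` blends
    each row with the uniform distribution, bounding directional persistence
    — melodies in a tonal idiom hold a stable register rather than running
    away, and a fast-mixing chain keeps the pitch walk diffusively slow so
    octave re-anchoring against the playable range stays rare even in very
    long pieces.
    """
    rng = np.random.default_rng([seed, zlib.crc32(musician_id.encode())])
    alphabet = sorted(alphabet)
    if symmetric and sorted(-a for a in alphabet) != alphabet:
        raise ValueError("symmetric chains need an alphabet closed under negation")
    contexts = [()]
    for _ in range(order):
        contexts = [(*ctx, a) for ctx in contexts for a in alphabet]
    table: IntervalTable = {}
    for ctx in contexts:
        mirror = tuple(-a for a in ctx)
        if symmetric and mirror in table:
            table[ctx] = {-b: p for b, p in table[mirror].items()}
            continue
        probs = rng.dirichlet(np.full(len(alphabet), concentration))
        probs = (1.0 - uniform_mix) * probs + uniform_mix / len(alphabet)
        row = {a: float(p) for a, p in zip(alphabet, probs)}
        total = sum(row.values())
        table[ctx] = {a: p / total for a, p in row.items()}
    return MusicianSpec(
        musician_id=musician_id, order=order, pitch_tp=table, seed=seed, **kwargs
    )


HIERARCHY_MULTISET: Tuple[int, ...] = (2, 2, -1, -3, 0)  # sums to zero: no pitch drift


def hierarchy_specs(
    seed: int = 0,
    motifs_per_musician: int = 4,
    musician_ids: Sequence[str] = ("evans", "hancock", "tyner"),
    **kwargs,
) -> List[MusicianSpec]:
    """Three musicians with shared shallow statistics, distinct deep patterns.

    All motifs are permutations of one interval multiset, so the order-1
    relative-pitch window distribution (the interval unigram) is identical
    across musicians, while order-4 windows trace musician-specific motifs.
    The IOI distribution is shared, so rhythm streams carry no musician
    signal at any order.
    """
    rng = np.random.default_rng([seed, 0x5EED])
    pool: List[Tuple[int, ...]] = []
    seen = set()
    while len(pool) < motifs_per_musician * len(musician_ids):
        motif = tuple(rng.permutation(HIERARCHY_MULTISET).tolist())
        if motif not in seen:
            seen.add(motif)
            pool.append(motif)
    specs = []
    for m, musician_id in enumerate(musician_ids):
        motifs = tuple(pool[m * motifs_per_musician : (m + 1) * motifs_per_musician])
        specs.append(
            MusicianSpec(
                musician_id=musician_id,
                order=4,
                motifs=motifs,
                seed=seed,
                **kwargs,
            )
        )
    return specs


def drift_spec(
    musician_id: str = "drifter",
    slope: float = 0.05,
    seed: int = 0,
    **kwargs,
) -> MusicianSpec:
    """An order-1 chain with one pattern drifting linearly across pieces."""
    base = random_markov_spec(musician_id, order=1, seed=seed, **kwargs)
    context = sorted(base.pitch_tp)[0]
    continuation = sorted(base.pitch_tp[context])[0]
    return replace(base, drift=DriftSpec(context, continuation, slope))
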