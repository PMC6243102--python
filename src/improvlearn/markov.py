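"""Transition-probability estimation and aggregation.

The nth-order transition probability (TP) is the relative-frequency
estimate of P(e_{n+1} | e_n, ..., e_1): window counts tallied per context,
normalized within each context.  No smoothing is applied — only observed
patterns carry probability mass; patterns a piece never produced enter the
downstream matrices as structural zeros.

Per-piece tables are estimated first; a musician's distribution is the mean
of the per-piece TPs over the union vocabulary (absent pattern = 0), not a
pooled-count refit, so each piece contributes equally regardless of length.
The mean of probabilities is not itself a normalized distribution and is
deliberately left unnormalized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import pandas as pd

from .encode import (
    Context,
    Continuation,
    NGramWindow,
    SequenceType,
    format_context,
    format_continuation,
)

logger = logging.getLogger(__name__)

Pattern = Tuple[Context, Continuation]

DEFAULT_LOGIT_EPS = 1e-6


def serialize_pattern(pattern: Pattern, sequence_type: SequenceType) -> str:
    """Deterministic string form of a (context, continuation) pattern."""
    joint = SequenceType(sequence_type).is_joint
    context, continuation = pattern
    ctx = format_context(context, joint)
    cont = format_continuation(continuation, joint)
    return f"{ctx} -> {cont}" if ctx else f"-> {cont}"


@dataclass
class TPTable:
    """Per-piece context -> continuation counts and MLE probabilities."""

    piece_id: str
    musician_id: str
    sequence_type: SequenceType
    order: int
    counts: Dict[Context, Dict[Continuation, int]] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return sum(sum(conts.values()) for conts in self.counts.values())

    def context_total(self, context: Context) -> int:
        return sum(self.counts[context].values())

    def tp(self, context: Context, continuation: Continuation) -> float:
        return self.counts[context][continuation] / self.context_total(context)

    def items(self) -> Iterator[Tuple[Context, Continuation, int, float]]:
        """Yield (context, continuation, count, tp), deterministically ordered."""
        joint = SequenceType(self.sequence_type).is_joint
        for context in sorted(self.counts, key=lambda c: format_context(c, joint)):
            total = self.context_total(context)
            conts = self.counts[context]
            for continuation in sorted(conts, key=lambda c: format_continuation(c, joint)):
                count = conts[continuation]
                yield context, continuation, count, count / total

    def pattern_tps(self) -> Dict[Pattern, float]:
        return {(ctx, cont): tp for ctx, cont, _count, tp in self.items()}

    def __len__(self) -> int:
        return sum(len(conts) for conts in self.counts.values())


def estimate_tp(
    windows: Iterable[NGramWindow],
    piece_id: str = "",
    musician_id: str = "",
) -> TPTable:
    """Tally windows into a :class:`TPTable` (maximum-likelihood, no smoothing).

    All windows must share one (sequence_type, order); a mixed stream is a
    contract violation.  An empty stream yields an empty table.
    """
    counts: Dict[Context, Dict[Continuation, int]] = {}
    sequence_type = None
    order = None
    for window in windows:
        if sequence_type is None:
            sequence_type, order = window.sequence_type, window.order
        elif (window.sequence_type, window.order) != (sequence_type, order):
            raise ValueError(
                "mixed window streams: expected "
                f"({sequence_type}, order {order}), got "
                f"({window.sequence_type}, order {window.order})"
            )
        conts = counts.setdefault(window.context, {})
        conts[window.continuation] = conts.get(window.continuation, 0) + 1
    return TPTable(
        piece_id=piece_id,
        musician_id=musician_id,
        sequence_type=sequence_type if sequence_type is not None else SequenceType.PITCH,
        order=order if order is not None else 1,
        counts=counts,
    )


@dataclass
class MeanTPTable:
    """Per-musician mean of per-piece TPs over the union vocabulary."""

    musician_id: str
    sequence_type: SequenceType
    order: int
    n_pieces: int
    mean_tp: Dict[Pattern, float] = field(default_factory=dict)


def average_tables(tables: Sequence[TPTable]) -> MeanTPTable:
    """Average per-piece TPs pattern-wise; a pattern absent from a piece counts 0."""
    if not tables:
        raise ValueError("cannot average zero tables")
    first = tables[0]
    for table in tables[1:]:
        if (table.sequence_type, table.order) != (first.sequence_type, first.order):
            raise ValueError("tables mix sequence types or orders")
    sums: Dict[Pattern, float] = {}
    for table in tables:
        for pattern, tp in table.pattern_tps().items():
            sums[pattern] = sums.get(pattern, 0.0) + tp
    n = len(tables)
    return MeanTPTable(
        musician_id=first.musician_id,
        sequence_type=first.sequence_type,
        order=first.order,
        n_pieces=n,
        mean_tp={pattern: total / n for pattern, total in sums.items()},
    )


@dataclass
class TPMatrix:
    """Pieces x pattern-vocabulary TP matrix for one (sequence_type, order)."""

    sequence_type: SequenceType
    order: int
    values: pd.DataFrame  # index = piece ids, columns = serialized patterns
    musician_ids: Dict[str, str]  # piece_id -> musician_id


def align_matrix(tables: Sequence[TPTable]) -> TPMatrix:
    """Align per-piece tables on the sorted union vocabulary (absent = 0)."""
    if len(tables) < 2:
        raise ValueError("need at least two tables to align")
    first = tables[0]
    for table in tables[1:]:
        if (table.sequence_type, table.order) != (first.sequence_type, first.order):
            raise ValueError("tables mix sequence types or orders")

    per_piece: Dict[str, Dict[str, float]] = {}
    vocabulary = set()
    for table in tables:
        row = {
            serialize_pattern(pattern, table.sequence_type): tp
            for pattern, tp in table.pattern_tps().items()
        }
        vocabulary.update(row)
        per_piece[table.piece_id] = row

    columns = sorted(vocabulary)
    frame = pd.DataFrame(
        [[per_piece[pid].get(col, 0.0) for col in columns] for pid in per_piece],
        index=list(per_piece),
        columns=columns,
        dtype=float,
    )
    return TPMatrix(
        sequence_type=first.sequence_type,
        order=first.order,
        values=frame,
        musician_ids={t.piece_id: t.musician_id for t in tables},
    )


@dataclass
class PatternRank:
    """A musician's k highest mean-TP patterns, non-increasing."""

    musician_id: str
    sequence_type: SequenceType
    order: int
    patterns: List[Tuple[Pattern, float]] = field(default_factory=list)


def top_k(mean_table: MeanTPTable, k: int = 5) -> PatternRank:
    """The k patterns with highest mean TP; ties broken lexicographically."""
    if not mean_table.mean_tp:
        raise ValueError("cannot rank an empty mean table")
    if len(mean_table.mean_tp) < k:
        logger.warning(
            "only %d patterns available for musician %s (requested top %d)",
            len(mean_table.mean_tp), mean_table.musician_id, k,
        )
    ranked = sorted(
        mean_table.mean_tp.items(),
        key=lambda item: (-item[1], serialize_pattern(item[0], mean_table.sequence_type)),
    )
    return PatternRank(
        musician_id=mean_table.musician_id,
        sequence_type=mean_table.sequence_type,
        order=mean_table.order,
        patterns=ranked[:k],
    )


def logit_tp(tp: float, eps: float = DEFAULT_LOGIT_EPS) -> float:
    """ln(p / (1-p)) with p clamped into [eps, 1-eps] so 0 and 1 stay finite."""
    if not 0.0 <= tp <= 1.0:
        raise ValueError(f"tp must be in [0, 1], got {tp}")
    p = min(max(tp, eps), 1.0 - eps)
    return math.log(p / (1.0 - p))
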