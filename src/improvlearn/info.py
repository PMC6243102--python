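"""Information content and conditional entropy of transition distributions.

Information content of an observed transition is the surprisal of its TP,
I = -log2(p) bits.  The conditional entropy of a piece's order-n table is
the context-weighted expected surprisal,

    H(B|A) = - sum_i P(a_i) sum_j P(b_j | a_i) log2 P(b_j | a_i),

with the context marginal P(a_i) taken as the empirical window frequency
(context count / total windows) — the plug-in estimate.  H therefore equals
the mean information content over all observed windows exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .encode import SequenceType
from .markov import Pattern, TPTable


@dataclass(frozen=True)
class InformationRecord:
    """Surprisal of one observed transition pattern."""

    pattern: Pattern
    tp: float
    information_content: float  # bits


@dataclass(frozen=True)
class EntropyRecord:
    """Plug-in conditional entropy of one piece x sequence type x order."""

    piece_id: str
    musician_id: str
    sequence_type: str
    order: int
    entropy: float  # bits


def information_content(tp: float) -> float:
    """-log2(tp) in bits; undefined at 0 (unobservable under MLE)."""
    if not 0.0 < tp <= 1.0:
        raise ValueError(f"information content requires 0 < tp <= 1, got {tp}")
    return -math.log2(tp)


def conditional_entropy(table: TPTable) -> EntropyRecord:
    """Conditional entropy of a per-piece TP table, in bits."""
    total = table.n_windows
    if total == 0:
        raise ValueError("conditional entropy of an empty table is undefined")
    h = 0.0
    for context, conts in table.counts.items():
        context_total = sum(conts.values())
        p_context = context_total / total
        for count in conts.values():
            if count == 0:
                continue  # 0 * log 0 := 0
            p = count / context_total
            h -= p_context * p * math.log2(p)
    return EntropyRecord(
        piece_id=table.piece_id,
        musician_id=table.musician_id,
        sequence_type=SequenceType(table.sequence_type).value,
        order=table.order,
        entropy=max(h, 0.0),
    )
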