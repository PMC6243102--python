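"""Independent brute-force oracles used by the test suite.

Each function reimplements a pipeline quantity in the most literal way
possible (explicit loops over slices, dictionary tallies, textbook sums of
squares) without touching the package's own code paths, so that agreement
is evidence of correctness rather than of shared implementation.
"""

import math

import numpy as np


def skyline_oracle(notes):
    """(onset, pitch) skyline by literal per-onset scan.

    notes: iterable of (onset, pitch, is_grace, slur_group).
    """
    kept = []
    seen_slur = set()
    for onset, pitch, is_grace, slur in sorted(notes, key=lambda n: (n[0], -n[1])):
        if is_grace:
            continue
        if slur is not None:
            if slur in seen_slur:
                continue
            seen_slur.add(slur)
        kept.append((onset, pitch))
    out = []
    for onset in sorted({o for o, _ in kept}):
        best = max(p for o, p in kept if o == onset)
        out.append((onset, best))
    return out


def pitch_windows_oracle(pitches, n):
    """All (n+1)-tuples re-zeroed to their first pitch."""
    out = []
    for i in range(len(pitches) - n):
        chunk = pitches[i : i + n + 1]
        out.append(tuple(p - chunk[0] for p in chunk))
    return out


def rhythm_windows_oracle(onsets, n):
    """All (n+1)-IOI runs as 3-decimal ratios to the run's first IOI."""
    iois = [b - a for a, b in zip(onsets, onsets[1:])]
    out = []
    for i in range(len(iois) - n):
        run = iois[i : i + n + 1]
        out.append(tuple(round(d / run[0], 3) for d in run))
    return out


def pitch_with_rhythm_windows_oracle(onsets, pitches, n):
    """(pitch tokens, rhythm tokens) per run of n+1 notes."""
    out = []
    for i in range(len(pitches) - n):
        p = pitches[i : i + n + 1]
        o = onsets[i : i + n + 1]
        iois = [b - a for a, b in zip(o, o[1:])]
        ptok = tuple(x - p[0] for x in p)
        if n == 1:
            rtok = (round(iois[0] / 1.0, 3),)
        else:
            rtok = tuple(round(d / iois[0], 3) for d in iois)
        out.append((ptok, rtok))
    return out


def rhythm_with_pitch_windows_oracle(onsets, pitches, n):
    """(rhythm tokens, pitch tokens) per run of n+2 notes."""
    out = []
    for i in range(len(pitches) - n - 1):
        p = pitches[i : i + n + 2]
        o = onsets[i : i + n + 2]
        iois = [b - a for a, b in zip(o, o[1:])]
        rtok = tuple(round(d / iois[0], 3) for d in iois)
        ptok = tuple(x - p[0] for x in p)
        out.append((rtok, ptok))
    return out


def tp_oracle(pairs):
    """Relative-frequency conditionals from (context, continuation) pairs."""
    counts = {}
    for context, continuation in pairs:
        counts.setdefault(context, {}).setdefault(continuation, 0)
        counts[context][continuation] += 1
    tps = {}
    for context, conts in counts.items():
        total = sum(conts.values())
        for continuation, count in conts.items():
            tps[(context, continuation)] = count / total
    return tps


def entropy_oracle(counts):
    """Double sum of Eq.-3 form over a {context: {continuation: count}} dict."""
    total = sum(sum(c.values()) for c in counts.values())
    h = 0.0
    for conts in counts.values():
        ctx_total = sum(conts.values())
        p_ctx = ctx_total / total
        for count in conts.values():
            if count:
                p = count / ctx_total
                h += -p_ctx * p * math.log2(p)
    return h


def mixed_anova_ss_oracle(Y, groups):
    """Textbook sums of squares for a balanced two-way mixed design.

    Y: subjects x within-levels array; groups: per-subject group labels.
    Returns dict of SS terms and partial eta squared per effect.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    a = len(levels)
    b = Y.shape[1]
    n = Y.shape[0] // a
    grand = Y.mean()
    grp_means = np.array([Y[groups == g].mean() for g in levels])
    ss_between = b * n * ((grp_means - grand) ** 2).sum()
    subj_means = Y.mean(axis=1)
    ss_subj = 0.0
    for g, gm in zip(levels, grp_means):
        ss_subj += b * ((subj_means[groups == g] - gm) ** 2).sum()
    w_means = Y.mean(axis=0)
    ss_within = a * n * ((w_means - grand) ** 2).sum()
    cell = np.array([[Y[groups == g][:, j].mean() for j in range(b)] for g in levels])
    ss_cells = n * ((cell - grand) ** 2).sum()
    ss_inter = ss_cells - ss_between - ss_within
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_between - ss_subj - ss_within - ss_inter
    return {
        "ss_between": ss_between,
        "ss_subj": ss_subj,
        "ss_within": ss_within,
        "ss_inter": ss_inter,
        "ss_err": ss_err,
        "np2_between": ss_between / (ss_between + ss_subj),
        "np2_within": ss_within / (ss_within + ss_err),
        "np2_inter": ss_inter / (ss_inter + ss_err),
    }
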