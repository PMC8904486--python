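"""Semi-global affine-gap alignment with a canonical traceback.

Amplicon reads are aligned against their reference with free end-gaps on
the reference (the read maps to a contiguous reference window; reference
overhangs cost nothing, read overhangs are penalized as insertions).
Scoring defaults: match +2, mismatch -3, gap open -5 (charged on the
first gap base), gap extend -2 (each further base).

Among co-optimal alignments the traceback returns a single canonical
one: the alignment whose operation string is lexicographically smallest
under the operation order ``D < I < M < S`` (D = gap in read consuming
reference, I = read base inserted relative to reference, M =
match/mismatch column, S = free reference skip at the read boundaries).
Preferring D and I over M in ties shifts every indel as far left as it
can go over equal bases, so indels are left-aligned by construction and
identical events from different reads compare equal.  The greedy
traceback is exact because it walks a table of suffix-optimal scores.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2

# operation codes (canonical lexicographic order)
OP_D = 0  # deletion from the read (consumes reference)
OP_I = 1  # insertion into the read (consumes read)
OP_M = 2  # match/mismatch column
OP_S = 3  # free reference skip (only at read boundaries)

_NEG = -(1 << 40)


@njit(cache=False)
def _dp_ops(read: np.ndarray, ref: np.ndarray,
            match: int, mismatch: int, gap_open: int, gap_extend: int):
    """Suffix DP + greedy canonical traceback.  Returns (ops, score)."""
    n = read.size
    m = ref.size
    # S[i, j, s] = best score aligning read[i:] vs ref[j:], where s is the
    # preceding operation state (0 = none/M/S, 1 = in deletion, 2 = in insertion)
    S = np.full((n + 1, m + 1, 3), _NEG, dtype=np.int64)
    for s in range(3):
        S[n, m, s] = 0
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            for s in range(3):
                best = _NEG
                if i < n and j < m:  # M
                    sc = match if read[i] == ref[j] else mismatch
                    v = sc + S[i + 1, j + 1, 0]
                    if v > best:
                        best = v
                if 0 < i < n and j < m:  # D (internal only; boundary = free skip)
                    sc = gap_extend if s == 1 else gap_open
                    v = sc + S[i, j + 1, 1]
                    if v > best:
                        best = v
                if i < n:  # I (read overhangs are penalized insertions)
                    sc = gap_extend if s == 2 else gap_open
                    v = sc + S[i + 1, j, 2]
                    if v > best:
                        best = v
                if (i == 0 or i == n) and j < m:  # S
                    v = S[i, j + 1, 0]
                    if v > best:
                        best = v
                S[i, j, s] = best

    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i = 0
    j = 0
    s = 0
    while not (i == n and j == m):
        cur = S[i, j, s]
        chosen = -1
        if 0 < i < n and j < m:
            sc = gap_extend if s == 1 else gap_open
            if sc + S[i, j + 1, 1] == cur:
                chosen = OP_D
        if chosen < 0 and i < n:
            sc = gap_extend if s == 2 else gap_open
            if sc + S[i + 1, j, 2] == cur:
                chosen = OP_I
        if chosen < 0 and i < n and j < m:
            sc = match if read[i] == ref[j] else mismatch
            if sc + S[i + 1, j + 1, 0] == cur:
                chosen = OP_M
        if chosen < 0 and (i == 0 or i == n) and j < m:
            if S[i, j + 1, 0] == cur:
                chosen = OP_S
        ops[k] = chosen
        k += 1
        if chosen == OP_M:
            i += 1
            j += 1
            s = 0
        elif chosen == OP_D:
            j += 1
            s = 1
        elif chosen == OP_I:
            i += 1
            s = 2
        else:  # OP_S
            j += 1
            s = 0
    return ops[:k], S[0, 0, 0]


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def align_ops(read: str, ref: str,
              match: int = MATCH, mismatch: int = MISMATCH,
              gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND):
    """Canonical op string (codes) and score for read vs reference."""
    ops, score = _dp_ops(encode(read), encode(ref),
                         match, mismatch, gap_open, gap_extend)
    return ops, int(score)


def ops_to_events(ops: np.ndarray, read: str, ref: str):
    """Decode an op string into (events, ref_span, n_matches, n_columns).

    Events are tuples ``("sub", pos, ref_base, read_base)``,
    ``("ins", pos, inserted_seq)`` (insertion before reference *pos*) and
    ``("del", pos, length)``, sorted by construction.  ``n_columns``
    counts aligned columns (M + D + I), the denominator of identity.
    """
    events = []
    i = j = 0
    span_start = None
    span_end = 0
    n_match = 0
    n_cols = 0
    k = 0
    L = len(ops)
    while k < L:
        op = ops[k]
        if op == OP_S:
            j += 1
            k += 1
            continue
        if span_start is None:
            span_start = j
        if op == OP_M:
            if read[i] != ref[j]:
                events.append(("sub", j, ref[j], read[i]))
            else:
                n_match += 1
            n_cols += 1
            i += 1
            j += 1
            span_end = j
            k += 1
        elif op == OP_D:
            start = j
            while k < L and ops[k] == OP_D:
                j += 1
                n_cols += 1
                k += 1
            events.append(("del", start, j - start))
            span_end = j
        else:  # OP_I
            start_i = i
            pos = j
            while k < L and ops[k] == OP_I:
                i += 1
                n_cols += 1
                k += 1
            events.append(("ins", pos, read[start_i:i]))
    if span_start is None:
        span_start = span_end = 0
    return events, (span_start, span_end), n_match, n_cols
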