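"""Independent exhaustive DP oracle for the semi-global affine aligner.

Computes, by memoized recursion over (read suffix, reference suffix, gap
state), the optimal alignment score together with the lexicographically
smallest optimal operation string under the canonical order
``D < I < M < S`` (which is plain ASCII order for those letters).  It is
deliberately written as a different mechanism from the package's
iterative table + greedy traceback: the recursion materializes whole
suffix operation strings and compares them, so it explores every optimal
alignment implicitly.  ``enumerate_optimal`` additionally lists *all*
optimal operation strings for tiny inputs.
"""

from __future__ import annotations

import sys
from functools import lru_cache

MATCH, MISMATCH, OPEN, EXT = 2, -3, -5, -2


def oracle_align(read: str, ref: str):
    """Return (score, canonical op string) for read vs reference."""
    n, m = len(read), len(ref)
    sys.setrecursionlimit(max(10_000, 10 * (n + m)))

    @lru_cache(maxsize=None)
    def best(i: int, j: int, s: int):
        if i == n and j == m:
            return (0, "")
        cands = []
        if 0 < i < n and j < m:  # D
            sc = EXT if s == 1 else OPEN
            sub_score, sub_ops = best(i, j + 1, 1)
            cands.append((sc + sub_score, "D" + sub_ops))
        if i < n:  # I
            sc = EXT if s == 2 else OPEN
            sub_score, sub_ops = best(i + 1, j, 2)
            cands.append((sc + sub_score, "I" + sub_ops))
        if i < n and j < m:  # M
            sc = MATCH if read[i] == ref[j] else MISMATCH
            sub_score, sub_ops = best(i + 1, j + 1, 0)
            cands.append((sc + sub_score, "M" + sub_ops))
        if (i == 0 or i == n) and j < m:  # S
            sub_score, sub_ops = best(i, j + 1, 0)
            cands.append((sub_score, "S" + sub_ops))
        top = max(c[0] for c in cands)
        return (top, min(ops for sc, ops in cands if sc == top))

    return best(0, 0, 0)


def enumerate_optimal(read: str, ref: str, cap: int = 50_000):
    """All optimal op strings (tiny inputs only)."""
    n, m = len(read), len(ref)

    @lru_cache(maxsize=None)
    def score(i, j, s):
        if i == n and j == m:
            return 0
        vals = []
        if 0 < i < n and j < m:
            vals.append((EXT if s == 1 else OPEN) + score(i, j + 1, 1))
        if i < n:
            vals.append((EXT if s == 2 else OPEN) + score(i + 1, j, 2))
        if i < n and j < m:
            vals.append((MATCH if read[i] == ref[j] else MISMATCH) + score(i + 1, j + 1, 0))
        if (i == 0 or i == n) and j < m:
            vals.append(score(i, j + 1, 0))
        return max(vals)

    out = []

    def walk(i, j, s, prefix):
        if len(out) >= cap:
            return
        if i == n and j == m:
            out.append(prefix)
            return
        cur = score(i, j, s)
        if 0 < i < n and j < m and (EXT if s == 1 else OPEN) + score(i, j + 1, 1) == cur:
            walk(i, j + 1, 1, prefix + "D")
        if i < n and (EXT if s == 2 else OPEN) + score(i + 1, j, 2) == cur:
            walk(i + 1, j, 2, prefix + "I")
        if i < n and j < m and (MATCH if read[i] == ref[j] else MISMATCH) + score(i + 1, j + 1, 0) == cur:
            walk(i + 1, j + 1, 0, prefix + "M")
        if (i == 0 or i == n) and j < m and score(i, j + 1, 0) == cur:
            walk(i, j + 1, 0, prefix + "S")

    walk(0, 0, 0, "")
    return out


def ops_to_events(opstring: str, read: str, ref: str):
    """Decode an op string into (sub/ins/del) events, independent of the package."""
    events = []
    i = j = 0
    k = 0
    L = len(opstring)
    while k < L:
        op = opstring[k]
        if op == "S":
            j += 1
            k += 1
        elif op == "M":
            if read[i] != ref[j]:
                events.append(("sub", j, ref[j], read[i]))
            i += 1
            j += 1
            k += 1
        elif op == "D":
            start = j
            while k < L and opstring[k] == "D":
                j += 1
                k += 1
            events.append(("del", start, j - start))
        else:  # I
            start_i, pos = i, j
            while k < L and opstring[k] == "I":
                i += 1
                k += 1
            events.append(("ins", pos, read[start_i:i]))
    return events


def mutate(rng, ref: str, n_sub=0, n_del=0, n_ins=0):
    """Derive a read from *ref* with random small edits (for test-case generation)."""
    bases = "ACGT"
    seq = list(ref)
    for _ in range(n_del):
        if len(seq) < 5:
            break
        p = rng.integers(1, len(seq) - 1)
        ln = int(rng.integers(1, 4))
        del seq[p:p + ln]
    for _ in range(n_ins):
        p = int(rng.integers(1, len(seq)))
        ins = "".join(bases[b] for b in rng.integers(0, 4, int(rng.integers(1, 4))))
        seq[p:p] = list(ins)
    for _ in range(n_sub):
        p = int(rng.integers(0, len(seq)))
        alt = bases[int(rng.integers(0, 4))]
        seq[p] = alt
    return "".join(seq)
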