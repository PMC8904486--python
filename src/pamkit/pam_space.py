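"""Algebra of concrete and degenerate (IUPAC) PAM sequences.

A protospacer adjacent motif (PAM) is the short sequence immediately
downstream of a Cas9 target that the nuclease must recognize before
unwinding the DNA.  The assays supported by this package interrogate an
8-bp randomized PAM region, so the module is built around the complete
space of ``4**8 = 65,536`` concrete 8-mers, indexed by a lexicographic
rank with the fixed base order ``A < C < G < T``.

Positions are 1-based; position 1 is the base immediately downstream of
the protospacer.  The functional consensus for CjCas9 discussed
throughout the docs, ``N3VRYAC``, constrains positions 4-8.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide codes (DNA only; U is deliberately rejected).
IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

#: Length of the randomized PAM region interrogated by the depletion assay.
PAM_LENGTH = 8
#: Number of concrete PAM patterns tracked by every count/score table.
N_PAMS = 4**PAM_LENGTH


def clean_concrete(seq: str, *, name: str = "sequence") -> str:
    """Upper-case and validate a concrete A/C/G/T sequence."""
    seq = str(seq).upper()
    for ch in seq:
        if ch not in _BASE_INDEX:
            raise ValueError(
                f"invalid base {ch!r} in {name} {seq!r}: expected only A/C/G/T"
            )
    return seq


def clean_pattern(pattern: str, *, name: str = "pattern") -> str:
    """Upper-case and validate an IUPAC degenerate pattern."""
    pattern = str(pattern).upper()
    if not pattern:
        raise ValueError(f"{name} must be non-empty")
    for ch in pattern:
        if ch not in IUPAC:
            raise ValueError(
                f"invalid IUPAC symbol {ch!r} in {name} {pattern!r}"
            )
    return pattern


def degeneracy(pattern: str) -> int:
    """Number of concrete sequences matching *pattern* (product of per-symbol set sizes)."""
    pattern = clean_pattern(pattern)
    n = 1
    for ch in pattern:
        n *= len(IUPAC[ch])
    return n


def expand_degenerate(pattern: str) -> list[str]:
    """Expand an IUPAC pattern into every matching concrete sequence.

    The result is in lexicographic order (``A < C < G < T``) and contains
    each matching sequence exactly once.
    """
    pattern = clean_pattern(pattern)
    out = [""]
    for ch in pattern:
        choices = IUPAC[ch]  # already lexicographically sorted
        out = [prefix + b for prefix in out for b in choices]
    return out


def matches(seq: str, pattern: str) -> bool:
    """True iff each base of *seq* is in the corresponding IUPAC class of *pattern*."""
    seq = clean_concrete(seq)
    pattern = clean_pattern(pattern)
    if len(seq) != len(pattern):
        raise ValueError(
            f"length mismatch: sequence has {len(seq)} bases, pattern has {len(pattern)}"
        )
    return all(b in IUPAC[p] for b, p in zip(seq, pattern))


def rank(seq: str) -> int:
    """Lexicographic rank of an 8-nt PAM (``AAAAAAAA`` -> 0, ``TTTTTTTT`` -> 65535)."""
    seq = clean_concrete(seq, name="PAM")
    if len(seq) != PAM_LENGTH:
        raise ValueError(f"PAM must have length {PAM_LENGTH}, got {len(seq)}")
    r = 0
    for ch in seq:
        r = r * 4 + _BASE_INDEX[ch]
    return r


def unrank(i: int) -> str:
    """Inverse of :func:`rank`."""
    i = int(i)
    if not 0 <= i < N_PAMS:
        raise ValueError(f"rank {i} out of range [0, {N_PAMS - 1}]")
    digits = []
    for _ in range(PAM_LENGTH):
        digits.append(BASES[i % 4])
        i //= 4
    return "".join(reversed(digits))


def rank_digits(ranks: np.ndarray | None = None) -> np.ndarray:
    """Base-4 digit matrix of PAM ranks, shape ``(n, 8)``, digit 0..3 = A..T.

    With no argument, returns the digits of all 65,536 ranks (cached).
    """
    global _ALL_DIGITS
    if ranks is None:
        if _ALL_DIGITS is None:
            _ALL_DIGITS = rank_digits(np.arange(N_PAMS))
        return _ALL_DIGITS
    ranks = np.asarray(ranks, dtype=np.int64)
    shifts = 4 ** np.arange(PAM_LENGTH - 1, -1, -1, dtype=np.int64)
    return (ranks[:, None] // shifts) % 4


_ALL_DIGITS: np.ndarray | None = None


def all_pams() -> list[str]:
    """All 65,536 concrete PAM sequences in rank order (cached)."""
    global _ALL_PAMS
    if _ALL_PAMS is None:
        _ALL_PAMS = expand_degenerate("N" * PAM_LENGTH)
    return _ALL_PAMS


_ALL_PAMS: list[str] | None = None


def pattern_ranks(pattern: str) -> np.ndarray:
    """Ranks of every 8-nt PAM matching *pattern*, in ascending order."""
    pattern = clean_pattern(pattern)
    if len(pattern) != PAM_LENGTH:
        raise ValueError(f"pattern must have length {PAM_LENGTH} to index PAM ranks")
    digits = rank_digits()
    keep = np.ones(N_PAMS, dtype=bool)
    for j, ch in enumerate(pattern):
        allowed = np.array([_BASE_INDEX[b] for b in IUPAC[ch]])
        keep &= np.isin(digits[:, j], allowed)
    return np.flatnonzero(keep)


def single_substitution_panel(canonical: str, positions: Iterable[int]) -> list[str]:
    """The canonical sequence plus every single-base substitution at *positions*.

    Mirrors the in vitro panel design in which the fourth to eighth
    nucleotides of the canonical PAM are individually substituted: the
    canonical ``TTTAACAC`` with positions ``{4..8}`` yields 16 sequences.
    Order is deterministic: canonical first, then by position, then base.
    """
    canonical = clean_concrete(canonical, name="canonical")
    positions = sorted(set(int(p) for p in positions))
    for p in positions:
        if not 1 <= p <= len(canonical):
            raise ValueError(
                f"position {p} outside sequence of length {len(canonical)}"
            )
    panel = [canonical]
    for p in positions:
        for b in BASES:
            if b == canonical[p - 1]:
                continue
            panel.append(canonical[: p - 1] + b + canonical[p:])
    return panel


def combination_panel(template: str, fixed_suffix: str | None = None) -> list[str]:
    """Enumerate every concrete combination of the degenerate template positions.

    E.g. ``TTTVRYAC`` (degenerate only at positions 4-6) expands to the 12
    targets covering all V x R x Y combinations.  If *fixed_suffix* is
    given it must be concrete and consistent with the template's trailing
    non-degenerate positions (it documents the invariant part of the
    panel); a conflicting suffix is rejected.
    """
    template = clean_pattern(template, name="template")
    if fixed_suffix is not None:
        fixed_suffix = clean_concrete(fixed_suffix, name="fixed_suffix")
        if len(fixed_suffix) > len(template):
            raise ValueError("fixed_suffix longer than template")
        tail = template[len(template) - len(fixed_suffix):]
        for i, (s, t) in enumerate(zip(fixed_suffix, tail)):
            if len(IUPAC[t]) > 1:
                raise ValueError(
                    f"fixed_suffix overlaps degenerate template position "
                    f"{len(template) - len(fixed_suffix) + i + 1}"
                )
            if s != t:
                raise ValueError(
                    f"fixed_suffix base {s!r} conflicts with template base {t!r} "
                    f"at position {len(template) - len(fixed_suffix) + i + 1}"
                )
    return expand_degenerate(template)


def write_panel(seqs: Sequence[str], path, *, fasta: bool = False, prefix: str = "pam") -> None:
    """Write a panel as one-sequence-per-line text or FASTA."""
    with open(path, "w") as fh:
        for i, s in enumerate(seqs, 1):
            if fasta:
                fh.write(f">{prefix}_{i:03d}\n{s}\n")
            else:
                fh.write(s + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a concrete DNA sequence."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq.upper()))
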