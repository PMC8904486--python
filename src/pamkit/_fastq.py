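"""Small FASTQ helpers shared by the counting and editing pipelines.

Parsing goes through Biopython's ``FastqGeneralIterator`` (the fast,
quality-string-preserving path).  Records are plain ``(title, seq, qual)``
tuples throughout the package; functions that accept "reads" take either
a path (``.gz`` transparently handled) or any iterable of such tuples.
"""

from __future__ import annotations

import gzip
import os
from typing import Iterable, Iterator, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

FastqRecord = Tuple[str, str, str]


def open_text(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(source) -> Iterator[FastqRecord]:
    """Iterate ``(title, seq, qual)`` from a path, handle, or pass through an iterable.

    A malformed record raises ``ValueError`` naming the index of the
    offending record.
    """
    if isinstance(source, (str, os.PathLike)):
        with open_text(source) as fh:
            yield from _iter_handle(fh)
    elif hasattr(source, "read"):
        yield from _iter_handle(source)
    else:  # already an iterable of records
        for rec in source:
            yield rec


def _iter_handle(fh) -> Iterator[FastqRecord]:
    it = FastqGeneralIterator(fh)
    i = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {i}: {exc}") from exc
        yield rec
        i += 1


def write_fastq(records: Iterable[FastqRecord], path) -> None:
    with open_text(path, "wt") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
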