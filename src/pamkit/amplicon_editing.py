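"""Amplicon deep-sequencing quantification of indels and C-to-T edits.

Reads from edited and matched control samples are aligned to reference
amplicons; indels and substitutions are called per read; recurrent
control artifacts (PCR errors, somatic variants) are blocklisted and the
reads carrying them removed from both samples; editing frequencies are
reported raw and control-subtracted (floored at zero).

Coordinates
-----------
Internally everything is 0-based half-open on the reference.  Externally
protospacer positions are numbered -22 (PAM-distal) .. -1 (PAM-proximal,
adjacent to the PAM) and PAM positions +1 .. +8, in protospacer
orientation; base-editing windows such as -21 .. -8 use this numbering.
For a site on the minus strand all per-position reporting is in the
protospacer frame (bases complemented), so plus- and minus-strand sites
with the same edit produce identical summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _align
from ._fastq import FastqRecord, read_fastq
from .pam_space import clean_concrete, reverse_complement

PROTOSPACER_LENGTH = 22
PAM_LENGTH = 8

#: Default control-artifact frequency threshold (exclusive: listed if > 1%).
DEFAULT_CONTROL_THRESHOLD = 0.01
#: Default flank (nt) around protospacer+PAM for indel window overlap.
DEFAULT_INDEL_FLANK = 3
#: Minimum read length accepted by the aligner.
MIN_READ_LENGTH = 30
#: Minimum identity over the aligned span; lower-identity reads are unmapped.
MIN_IDENTITY = 0.70


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationKey:
    """Canonical identity of one called event (post left-alignment).

    kind is ``sub`` / ``ins`` / ``del``; ``pos`` is the 0-based reference
    position (for insertions: the base before which the sequence is
    inserted); payload is the read base, inserted sequence, or deleted
    length.
    """

    kind: str
    pos: int
    payload: object


@dataclass
class ReadAlignment:
    """Called events of one read against its reference amplicon."""

    read_id: str
    ref_span: tuple  # 0-based half-open reference interval covered
    events: list     # as produced by pamkit._align.ops_to_events
    score: int
    identity: float

    def mutation_keys(self) -> tuple:
        out = []
        for ev in self.events:
            if ev[0] == "sub":
                out.append(MutationKey("sub", ev[1], ev[3]))
            elif ev[0] == "ins":
                out.append(MutationKey("ins", ev[1], ev[2]))
            else:
                out.append(MutationKey("del", ev[1], ev[2]))
        return tuple(out)

    def deleted_positions(self) -> set:
        if not hasattr(self, "_dels"):
            out = set()
            for ev in self.events:
                if ev[0] == "del":
                    out.update(range(ev[1], ev[1] + ev[2]))
            self._dels = out
        return self._dels

    def _sub_map(self) -> dict:
        if not hasattr(self, "_subs"):
            self._subs = {ev[1]: ev[3] for ev in self.events if ev[0] == "sub"}
        return self._subs

    def base_at(self, pos: int, ref: str) -> str | None:
        """Read base over reference position *pos*, or None if not covered."""
        if not (self.ref_span[0] <= pos < self.ref_span[1]):
            return None
        sub = self._sub_map().get(pos)
        if sub is not None:
            return sub
        if pos in self.deleted_positions():
            return None
        return ref[pos]


@dataclass
class AmpliconSite:
    """One target amplicon: reference, 22-nt protospacer and 8-nt PAM."""

    site_id: str
    reference: str
    protospacer: str
    pam: str
    strand: str  # protospacer strand on the reference: '+' or '-'
    protospacer_interval: tuple  # 0-based half-open on the reference

    def __post_init__(self):
        self.reference = clean_concrete(self.reference, name="reference")
        self.protospacer = clean_concrete(self.protospacer, name="protospacer")
        self.pam = clean_concrete(self.pam, name="pam")
        if len(self.protospacer) != PROTOSPACER_LENGTH:
            raise ValueError(f"protospacer must be {PROTOSPACER_LENGTH} nt")
        if len(self.pam) != PAM_LENGTH:
            raise ValueError(f"pam must be {PAM_LENGTH} nt")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        s, e = self.protospacer_interval
        if e - s != PROTOSPACER_LENGTH:
            raise ValueError("protospacer_interval length must be 22")
        if self.strand == "+":
            if self.reference[s:e] != self.protospacer:
                raise ValueError("protospacer not found at protospacer_interval")
            if self.reference[e:e + PAM_LENGTH] != self.pam:
                raise ValueError("pam does not follow the protospacer")
        else:
            if self.reference[s:e] != reverse_complement(self.protospacer):
                raise ValueError("protospacer (revcomp) not found at protospacer_interval")
            if self.reference[s - PAM_LENGTH:s] != reverse_complement(self.pam):
                raise ValueError("pam does not follow the protospacer")

    @classmethod
    def from_reference(cls, site_id: str, reference: str, protospacer: str,
                       pam: str, strand: str = "+") -> "AmpliconSite":
        """Locate the protospacer on the reference and build the site."""
        reference = clean_concrete(reference, name="reference")
        protospacer = clean_concrete(protospacer, name="protospacer")
        query = protospacer if strand == "+" else reverse_complement(protospacer)
        s = reference.find(query)
        if s < 0:
            raise ValueError(f"protospacer not found in reference for site {site_id}")
        return cls(site_id, reference, protospacer, pam, strand,
                   (s, s + len(protospacer)))

    # -- position mapping (protospacer frame <-> reference coordinates) ----

    def ref_pos(self, p: int) -> int:
        """Reference index of protospacer position p (-22..-1) or PAM position (+1..+8)."""
        s, e = self.protospacer_interval
        if -PROTOSPACER_LENGTH <= p <= -1:
            return e + p if self.strand == "+" else s - 1 - p
        if 1 <= p <= PAM_LENGTH:
            return e + p - 1 if self.strand == "+" else s - p
        raise ValueError(f"position {p} outside protospacer/PAM numbering")

    def base_at(self, p: int) -> str:
        """Protospacer-strand base at position p."""
        b = self.reference[self.ref_pos(p)]
        return b if self.strand == "+" else reverse_complement(b)

    def to_protospacer_frame(self, base: str) -> str:
        return base if self.strand == "+" else reverse_complement(base)

    def positions(self) -> list[int]:
        """All protospacer and PAM positions, PAM-distal to PAM-proximal to PAM."""
        return list(range(-PROTOSPACER_LENGTH, 0)) + list(range(1, PAM_LENGTH + 1))

    def cut_region(self, flank: int = DEFAULT_INDEL_FLANK) -> tuple:
        """Reference window [protospacer start - flank, PAM end + flank)."""
        s, e = self.protospacer_interval
        if self.strand == "+":
            return (s - flank, e + PAM_LENGTH + flank)
        return (s - PAM_LENGTH - flank, e + flank)


@dataclass
class EditingWindow:
    """Protospacer window where deaminase edits are scored (inclusive)."""

    start: int = -21
    end: int = -8

    def __post_init__(self):
        if not (-PROTOSPACER_LENGTH <= self.start <= self.end <= -1):
            raise ValueError("window must satisfy -22 <= start <= end <= -1")

    def positions(self) -> range:
        return range(self.start, self.end + 1)

    @classmethod
    def parse(cls, text: str) -> "EditingWindow":
        start, end = (int(x) for x in str(text).split(":"))
        return cls(start, end)


@dataclass
class SampleRecord:
    sample_id: str
    index: str
    fwd_primer: str
    rev_primer: str
    site_id: str
    role: str  # 'edited' or 'control'

    def __post_init__(self):
        if self.role not in ("edited", "control"):
            raise ValueError(f"role must be 'edited' or 'control', got {self.role!r}")
        self.index = clean_concrete(self.index, name="index")
        self.fwd_primer = clean_concrete(self.fwd_primer, name="fwd_primer")


@dataclass
class ControlBlocklist:
    """Recurrent control mutations with frequency above the threshold."""

    site_id: str
    frequencies: dict  # MutationKey -> control frequency (> threshold)
    threshold: float = DEFAULT_CONTROL_THRESHOLD

    def __contains__(self, key: MutationKey) -> bool:
        return key in self.frequencies

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass
class SiteEditingSummary:
    """Control-corrected editing summary for one amplicon site."""

    site_id: str
    window: EditingWindow
    n_aligned_edited: int
    n_retained_edited: int
    n_removed_edited: int
    n_aligned_control: int
    n_retained_control: int
    n_removed_control: int
    indel_frequency_raw: float
    indel_frequency_control: float
    indel_frequency_corrected: float
    ct_raw: dict        # protospacer position -> frequency in edited sample
    ct_control: dict
    ct_corrected: dict  # max(0, raw - control) per position
    site_ct_raw: float
    site_ct_corrected: float
    substitution_matrix: pd.DataFrame = field(repr=False, default=None)

    def to_row(self) -> dict:
        return {
            "site_id": self.site_id,
            "reads_edited": self.n_retained_edited,
            "reads_control": self.n_retained_control,
            "indel_raw": self.indel_frequency_raw,
            "indel_corrected": self.indel_frequency_corrected,
            "site_ct_raw": self.site_ct_raw,
            "site_ct_corrected": self.site_ct_corrected,
        }


# ---------------------------------------------------------------------------
# demultiplexing and pair merging
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def check_sample_sheet(samples: Sequence[SampleRecord], max_mismatch: int = 1) -> None:
    """Reject sheets whose index/primer combinations cannot be told apart."""
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            if a.sample_id == b.sample_id:
                raise ValueError(f"duplicate sample_id {a.sample_id!r}")
            if a.index != b.index:
                continue
            if len(a.fwd_primer) == len(b.fwd_primer) and \
                    _hamming(a.fwd_primer, b.fwd_primer) <= 2 * max_mismatch:
                raise ValueError(
                    f"samples {a.sample_id!r} and {b.sample_id!r} share index "
                    f"{a.index!r} and their primers are not distinguishable at "
                    f"> {max_mismatch} mismatches"
                )


def demultiplex(reads, samples: Sequence[SampleRecord], max_mismatch: int = 1):
    """Assign reads to samples by exact index match + mismatch-tolerant primer.

    Read layout: the sample index at the read start (exact match
    required) followed immediately by the forward primer (at most
    *max_mismatch* substitutions).  A read matching no sample, or two
    samples equally well, goes to the unassigned pool.  Returns
    ``(per_sample_records, unassigned_count)``; assigned reads keep their
    full sequence (the primer is part of the amplicon reference).
    """
    samples = list(samples)
    check_sample_sheet(samples, max_mismatch)
    out = {s.sample_id: [] for s in samples}
    unassigned = 0
    for rec in read_fastq(reads):
        seq = rec[1].upper()
        best_mm, best_sample, ties = max_mismatch + 1, None, 0
        for s in samples:
            if not seq.startswith(s.index):
                continue
            primer_region = seq[len(s.index):len(s.index) + len(s.fwd_primer)]
            if len(primer_region) < len(s.fwd_primer):
                continue
            mm = _hamming(primer_region, s.fwd_primer)
            if mm < best_mm:
                best_mm, best_sample, ties = mm, s, 1
            elif mm == best_mm:
                ties += 1
        if best_sample is None or best_mm > max_mismatch or ties > 1:
            unassigned += 1
        else:
            out[best_sample.sample_id].append(rec)
    return out, unassigned


def merge_pairs(r1: FastqRecord, r2: FastqRecord, min_overlap: int = 10,
                max_mismatch_rate: float = 0.1) -> FastqRecord | None:
    """Merge an inward-oriented read pair by its best ungapped overlap.

    R2 is reverse complemented, every overlap length >= *min_overlap* is
    scored (matches - mismatches), and the best-scoring overlap with
    mismatch rate <= *max_mismatch_rate* wins.  Disagreeing bases are
    resolved toward the higher base quality (R1 wins ties).  Returns None
    when no acceptable overlap exists.
    """
    t1, s1, q1 = r1
    _t2, s2, q2 = r2
    s1, s2 = s1.upper(), s2.upper()
    s2 = reverse_complement(s2)
    q2 = q2[::-1]
    best = None  # (score, olen)
    max_olen = min(len(s1), len(s2))
    for olen in range(max_olen, min_overlap - 1, -1):
        a = s1[len(s1) - olen:]
        b = s2[:olen]
        mm = _hamming(a, b)
        if mm / olen > max_mismatch_rate:
            continue
        score = olen - 2 * mm
        if best is None or score > best[0]:
            best = (score, olen)
    if best is None:
        return None
    olen = best[1]
    off = len(s1) - olen
    mid_seq = []
    mid_qual = []
    for i in range(olen):
        b1, b2 = s1[off + i], s2[i]
        c1, c2 = q1[off + i], q2[i]
        if b1 == b2:
            mid_seq.append(b1)
            mid_qual.append(max(c1, c2))
        elif c2 > c1:
            mid_seq.append(b2)
            mid_qual.append(c2)
        else:  # R1 wins ties
            mid_seq.append(b1)
            mid_qual.append(c1)
    seq = s1[:off] + "".join(mid_seq) + s2[olen:]
    qual = q1[:off] + "".join(mid_qual) + q2[olen:]
    return (t1 + " merged", seq, qual)


# ---------------------------------------------------------------------------
# alignment and event calling
# ---------------------------------------------------------------------------

def align_read(read, reference, *, read_id: str | None = None,
               min_identity: float = MIN_IDENTITY) -> ReadAlignment | None:
    """Align one read to a reference amplicon and call its events.

    *read* is a sequence string or a ``(title, seq, qual)`` record;
    *reference* an :class:`AmpliconSite` or a sequence string.  Returns
    None for unalignable reads (identity below *min_identity* over the
    aligned span) or reads shorter than 30 nt.
    """
    if isinstance(read, tuple):
        read_id = read_id or read[0]
        read = read[1]
    read = read.upper()
    ref = reference.reference if isinstance(reference, AmpliconSite) else reference.upper()
    if len(read) < MIN_READ_LENGTH:
        return None

    # fast path 1: exact substring (perfect alignment is uniquely optimal;
    # the leftmost occurrence matches the canonical traceback's preference
    # for starting the alignment as early as possible)
    pos = ref.find(read)
    if pos >= 0:
        return ReadAlignment(read_id or "", (pos, pos + len(read)), [],
                             _align.MATCH * len(read), 1.0)
    # fast path 2: equal length with <= 1 mismatch.  A single substitution
    # (-3) is strictly better than any gapped rearrangement, which needs a
    # read insertion (>= -5) plus either a deletion or a free end-skip and
    # can recoup at most +5 per mismatch fixed; the ungapped alignment is
    # therefore the unique optimum.
    if len(read) == len(ref):
        mm = [i for i, (a, b) in enumerate(zip(read, ref)) if a != b]
        if len(mm) <= 1:
            events = [("sub", i, ref[i], read[i]) for i in mm]
            score = _align.MATCH * (len(read) - len(mm)) + _align.MISMATCH * len(mm)
            identity = (len(read) - len(mm)) / len(read)
            if identity < min_identity:
                return None
            return ReadAlignment(read_id or "", (0, len(ref)), events, score, identity)

    ops, score = _align.align_ops(read, ref)
    events, span, n_match, n_cols = _align.ops_to_events(ops, read, ref)
    if n_cols == 0:
        return None
    identity = n_match / n_cols
    if identity < min_identity:
        return None
    return ReadAlignment(read_id or "", span, events, score, identity)


def align_sample(reads, site: AmpliconSite, **kwargs) -> list[ReadAlignment]:
    """Align every read of a FASTQ stream/iterable; unalignable reads dropped."""
    out = []
    for rec in read_fastq(reads):
        aln = align_read(rec, site, **kwargs)
        if aln is not None:
            out.append(aln)
    return out


# ---------------------------------------------------------------------------
# control-based filtering
# ---------------------------------------------------------------------------

def build_blocklist(control_alignments: Sequence[ReadAlignment],
                    threshold: float = DEFAULT_CONTROL_THRESHOLD,
                    *, site_id: str = "") -> ControlBlocklist:
    """Mutations observed in more than *threshold* of aligned control reads."""
    n = len(control_alignments)
    if n == 0:
        raise ValueError("cannot build a blocklist from zero aligned control reads")
    counts: dict = {}
    for aln in control_alignments:
        for key in set(aln.mutation_keys()):
            counts[key] = counts.get(key, 0) + 1
    freqs = {k: c / n for k, c in counts.items() if c / n > threshold}
    return ControlBlocklist(site_id=site_id, frequencies=freqs, threshold=threshold)


def filter_reads(alignments: Sequence[ReadAlignment], blocklist: ControlBlocklist):
    """Remove reads carrying any blocklisted mutation.  Returns (retained, removed)."""
    retained = []
    removed = 0
    for aln in alignments:
        if any(k in blocklist for k in aln.mutation_keys()):
            removed += 1
        else:
            retained.append(aln)
    return retained, removed


# ---------------------------------------------------------------------------
# editing quantification
# ---------------------------------------------------------------------------

def indel_frequency(alignments: Sequence[ReadAlignment], site: AmpliconSite,
                    flank: int = DEFAULT_INDEL_FLANK) -> float:
    """Fraction of reads with >= 1 indel overlapping the protospacer+PAM window."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if len(alignments) == 0:
        raise ValueError("cannot compute an indel frequency from zero retained reads")
    a, b = site.cut_region(flank)
    n_hit = 0
    for aln in alignments:
        for ev in aln.events:
            if ev[0] == "del":
                if ev[1] < b and ev[1] + ev[2] > a:
                    n_hit += 1
                    break
            elif ev[0] == "ins":
                if a <= ev[1] <= b:
                    n_hit += 1
                    break
    return n_hit / len(alignments)


def ct_profile(alignments: Sequence[ReadAlignment], site: AmpliconSite) -> dict:
    """Per-cytosine C-to-T frequency by protospacer position.

    For every protospacer position (-22..-1) whose protospacer-strand
    base is C, the frequency of reads showing T there (strand-aware)
    among reads covering the position.  Non-C positions are absent.
    """
    profile = {}
    for p in range(-PROTOSPACER_LENGTH, 0):
        if site.base_at(p) != "C":
            continue
        refpos = site.ref_pos(p)
        n_cov = n_t = 0
        for aln in alignments:
            base = aln.base_at(refpos, site.reference)
            if base is None:
                continue
            n_cov += 1
            if site.to_protospacer_frame(base) == "T":
                n_t += 1
        profile[p] = n_t / n_cov if n_cov else 0.0
    return profile


def substitution_matrix(alignments: Sequence[ReadAlignment], site: AmpliconSite) -> pd.DataFrame:
    """Per-position base frequencies over the protospacer+PAM region.

    One row per protospacer/PAM position with the protospacer-frame
    reference base, coverage and the frequency of each read base.
    """
    rows = []
    for p in site.positions():
        refpos = site.ref_pos(p)
        counts = {b: 0 for b in "ACGT"}
        n_cov = 0
        for aln in alignments:
            base = aln.base_at(refpos, site.reference)
            if base is None:
                continue
            base = site.to_protospacer_frame(base)
            if base in counts:
                counts[base] += 1
                n_cov += 1
        row = {"position": p, "ref_base": site.base_at(p), "coverage": n_cov}
        for b in "ACGT":
            row[b] = counts[b] / n_cov if n_cov else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_site(edited_alignments: Sequence[ReadAlignment],
                   control_alignments: Sequence[ReadAlignment],
                   site: AmpliconSite,
                   window: EditingWindow | None = None,
                   *,
                   control_threshold: float = DEFAULT_CONTROL_THRESHOLD,
                   flank: int = DEFAULT_INDEL_FLANK) -> SiteEditingSummary:
    """Control-corrected site summary.

    The blocklist is built from the control sample and applied to both
    samples, so recurrent artifacts are removed symmetrically; corrected
    frequencies are ``max(0, edited - control)`` for the indel frequency
    and each per-position C-to-T frequency.  The single per-site C-to-T
    statistic is the maximum corrected frequency within the editing
    window (default -21..-8), reported next to the full profile.
    """
    window = window or EditingWindow()
    blocklist = build_blocklist(control_alignments, control_threshold,
                                site_id=site.site_id)
    edited_kept, edited_removed = filter_reads(edited_alignments, blocklist)
    control_kept, control_removed = filter_reads(control_alignments, blocklist)
    if not edited_kept:
        raise ValueError(f"no edited reads retained for site {site.site_id}")
    if not control_kept:
        raise ValueError(f"no control reads retained for site {site.site_id}")

    indel_e = indel_frequency(edited_kept, site, flank)
    indel_c = indel_frequency(control_kept, site, flank)
    ct_e = ct_profile(edited_kept, site)
    ct_c = ct_profile(control_kept, site)
    ct_corr = {p: max(0.0, ct_e[p] - ct_c.get(p, 0.0)) for p in ct_e}

    window_positions = [p for p in ct_corr if window.start <= p <= window.end]
    site_ct_raw = max((ct_e[p] for p in window_positions), default=0.0)
    site_ct_corr = max((ct_corr[p] for p in window_positions), default=0.0)

    return SiteEditingSummary(
        site_id=site.site_id,
        window=window,
        n_aligned_edited=len(edited_alignments),
        n_retained_edited=len(edited_kept),
        n_removed_edited=edited_removed,
        n_aligned_control=len(control_alignments),
        n_retained_control=len(control_kept),
        n_removed_control=control_removed,
        indel_frequency_raw=indel_e,
        indel_frequency_control=indel_c,
        indel_frequency_corrected=max(0.0, indel_e - indel_c),
        ct_raw=ct_e,
        ct_control=ct_c,
        ct_corrected=ct_corr,
        site_ct_raw=site_ct_raw,
        site_ct_corrected=site_ct_corr,
        substitution_matrix=substitution_matrix(edited_kept, site),
    )


# ---------------------------------------------------------------------------
# table IO
# ---------------------------------------------------------------------------

def load_sites(sites_tsv, refs_fasta) -> dict:
    """Sites TSV (site_id, protospacer, pam, strand, reference_id) + FASTA refs."""
    from Bio import SeqIO

    refs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(refs_fasta, "fasta")}
    df = pd.read_csv(sites_tsv, sep="\t", dtype=str)
    sites = {}
    for row in df.itertuples(index=False):
        if row.reference_id not in refs:
            raise ValueError(f"reference {row.reference_id!r} missing from FASTA")
        sites[row.site_id] = AmpliconSite.from_reference(
            row.site_id, refs[row.reference_id], row.protospacer, row.pam, row.strand
        )
    return sites


def load_samples(samples_tsv) -> list[SampleRecord]:
    df = pd.read_csv(samples_tsv, sep="\t", dtype=str)
    records = [
        SampleRecord(row.sample_id, row.index_seq, row.fwd_primer,
                     getattr(row, "rev_primer", ""), row.site_id, row.role)
        for row in df.itertuples(index=False)
    ]
    for rec in records:
        if rec.role == "edited" and not any(
            r.role == "control" and r.site_id == rec.site_id for r in records
        ):
            raise ValueError(f"edited sample {rec.sample_id!r} has no same-site control")
    return records
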