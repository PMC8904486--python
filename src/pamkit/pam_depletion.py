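"""PAM discovery (library depletion) assay analysis.

A plasmid library carries a fixed protospacer followed by an 8-bp
randomized PAM region.  Cleavable PAMs are destroyed by the nuclease and
vanish from the sequenced survivor pool, so a PAM's activity shows up as
*negative* log2 enrichment of its read frequency in the treated sample
relative to the untreated library.  This module covers the full analysis:

1. extract the 8-bp randomized window from each read by anchoring on the
   constant sequence immediately upstream (:func:`extract_pam`),
2. count all ``4**8 = 65,536`` patterns densely (:func:`count_pams`),
3. score signed log2 enrichment against the untreated sample with a
   pseudocount (:func:`enrichment`),
4. threshold at ``-2.0`` enrichment for the functional/depleted set
   (:func:`depleted_set`), summarized as a sequence-logo matrix
   (:func:`logo_matrix`) and a 64 x 16 2D profile of mean scores over all
   1,024 position-4..8 five-mers (:func:`profile_2d`),
5. check library coverage of the untreated sample (:func:`coverage_qc`).

Scores are stored with the enrichment sign convention (depleted =
negative); any display of "depletion values" is the negation and is
flagged as such in output headers.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pam_space
from ._fastq import read_fastq
from .pam_space import BASES, N_PAMS, PAM_LENGTH

#: Default pseudocount added to every pattern in both samples.
#:
#: The scale matters because the assay's per-pattern coverage is low
#: (about 1.5 reads per pattern at 1e5 reads over 65,536 patterns).  With
#: a unit pseudocount a pure Poisson fluctuation (treated = 0 against
#: untreated = 3) already crosses the -2 enrichment threshold, so a few
#: percent of patterns would look "depleted" with no nuclease at all.
#: A pseudocount of 2 requires untreated >= 4 * treated + 6 to cross the
#: threshold, which pushes that null false-depletion rate well below 1%
#: at design coverage while leaving well-covered patterns essentially
#: unchanged.  It is exposed as a parameter everywhere for sensitivity
#: analysis.
DEFAULT_PSEUDOCOUNT = 2.0

#: Enrichment threshold defining the functional (depleted) PAM set.
DEFAULT_THRESHOLD = -2.0


@dataclass
class PamCountTable:
    """Dense read counts for all 65,536 8-nt PAM patterns of one sample."""

    sample_id: str
    counts: np.ndarray  # int64, length 65,536, indexed by PAM rank
    reads_used: int
    reads_discarded: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_PAMS,):
            raise ValueError(f"counts must have shape ({N_PAMS},)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != int(self.reads_used):
            raise ValueError("sum(counts) must equal reads_used")

    @property
    def total_reads(self) -> int:
        return self.reads_used + self.reads_discarded

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pam": pam_space.all_pams(), "count": self.counts})


@dataclass
class EnrichmentTable:
    """Signed log2 enrichment per PAM rank; negative = depleted (cleaved)."""

    scores: np.ndarray  # float64, length 65,536
    pseudocount: float
    treated_id: str
    untreated_id: str

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (N_PAMS,):
            raise ValueError(f"scores must have shape ({N_PAMS},)")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pam": pam_space.all_pams(), "score": self.scores})


@dataclass
class DepletedSet:
    """PAM ranks with enrichment score <= threshold (threshold inclusive)."""

    threshold: float
    members: np.ndarray  # sorted ranks

    def __post_init__(self):
        self.members = np.asarray(self.members, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.members)

    def sequences(self) -> list[str]:
        pams = pam_space.all_pams()
        return [pams[r] for r in self.members]


@dataclass
class LogoMatrix:
    """Per-position base frequencies and information content of a PAM set.

    ``frequencies`` is 8 positions x 4 bases (columns A, C, G, T), each
    row summing to 1.  ``information`` is the per-position information
    content in bits, ``IC_j = 2 + sum_b f_jb * log2(f_jb)``, without a
    small-sample correction.
    """

    frequencies: np.ndarray  # (8, 4)
    information: np.ndarray  # (8,)

    def modal_bases(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.frequencies, axis=1))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(BASES))
        df.insert(0, "position", np.arange(1, PAM_LENGTH + 1))
        df["bits"] = self.information
        return df


@dataclass
class Profile2D:
    """64 x 16 grid of mean scores for the 1,024 position-4..8 five-mers.

    Rows are the position 4-6 trimers, columns the position 7-8 dimers,
    both in lexicographic order (A < C < G < T).  Each cell is the
    arithmetic mean of the 64 scores sharing that 5-mer over the N3
    prefixes.
    """

    grid: np.ndarray  # (64, 16)
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.shape != (64, 16):
            raise ValueError("2D profile grid must be 64 x 16")
        if not self.row_labels:
            self.row_labels = pam_space.expand_degenerate("NNN")
        if not self.col_labels:
            self.col_labels = pam_space.expand_degenerate("NN")

    @property
    def n_cells(self) -> int:
        return self.grid.size

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, tri in enumerate(self.row_labels):
            for j, di in enumerate(self.col_labels):
                rows.append((tri, di, self.grid[i, j]))
        return pd.DataFrame(rows, columns=["row_trimer", "col_dimer", "mean_score"])


@dataclass
class CoverageReport:
    """Histogram/CDF of per-PAM read counts in the untreated library."""

    count_values: np.ndarray       # distinct per-PAM counts, ascending
    histogram: np.ndarray          # number of PAMs at each count value
    cumulative: np.ndarray         # CDF over count values, ends at 1
    fraction_covered: float        # fraction of patterns with count >= 1
    fraction_tenth_mean: float     # fraction with count >= mean/10

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": self.count_values,
                "n_pams": self.histogram,
                "cumulative_fraction": self.cumulative,
            }
        )


# ---------------------------------------------------------------------------
# read-level extraction and counting
# ---------------------------------------------------------------------------

def find_anchor(seq: str, anchor: str, max_mismatch: int) -> int | None:
    """Best substitution-only anchor placement, or None if absent/ambiguous.

    Scans every offset, scoring by Hamming mismatches (no indels).  If two
    offsets tie at the minimal mismatch count the read is ambiguous and
    None is returned.
    """
    n, m = len(seq), len(anchor)
    if m > n:
        return None
    # exact occurrences first (C-speed fast path; an exact hit is always best)
    first = seq.find(anchor)
    if first != -1:
        if seq.find(anchor, first + 1) != -1:
            return None  # two equally good (exact) placements
        return first
    if max_mismatch <= 0:
        return None
    best, best_pos, best_ties = max_mismatch + 1, None, 0
    for off in range(n - m + 1):
        mm = 0
        for i in range(m):
            if seq[off + i] != anchor[i]:
                mm += 1
                if mm > best:
                    break
        if mm < best:
            best, best_pos, best_ties = mm, off, 1
        elif mm == best:
            best_ties += 1
    if best_pos is None or best > max_mismatch or best_ties > 1:
        return None
    return best_pos


def extract_pam(seq: str, anchor: str, max_mismatch: int = 1) -> str | None:
    """Extract the 8-bp randomized window immediately after *anchor*.

    Returns None (the read is discarded) if the anchor is not found within
    *max_mismatch* substitutions, if its placement is ambiguous, if the
    window is truncated, or if the window contains an ambiguous base.
    Indels in the anchor are not tolerated: an indel shifts the randomized
    window and would corrupt the pattern.
    """
    if len(anchor) < 12:
        raise ValueError("anchor must be at least 12 nt to place the PAM window reliably")
    seq = seq.upper()
    pos = find_anchor(seq, anchor.upper(), max_mismatch)
    if pos is None:
        return None
    start = pos + len(anchor)
    window = seq[start:start + PAM_LENGTH]
    if len(window) < PAM_LENGTH:
        return None
    if any(b not in "ACGT" for b in window):
        return None
    return window


def count_pams(
    reads,
    anchor: str,
    max_mismatch: int = 1,
    *,
    sample_id: str = "sample",
    orientation: str = "as-read",
) -> PamCountTable:
    """Count all 65,536 PAM patterns in a FASTQ stream.

    *reads* may be a FASTQ(.gz) path or an iterable of ``(title, seq,
    qual)`` tuples.  ``orientation="reverse-complement"`` reverse
    complements each extracted window before counting (for samples
    sequenced from the opposite strand).
    """
    if orientation not in ("as-read", "reverse-complement"):
        raise ValueError(f"unknown orientation {orientation!r}")
    revcomp = orientation == "reverse-complement"
    counts = np.zeros(N_PAMS, dtype=np.int64)
    used = discarded = 0
    anchor = anchor.upper()
    for _title, seq, _qual in read_fastq(reads):
        pam = extract_pam(seq, anchor, max_mismatch)
        if pam is None:
            discarded += 1
            continue
        if revcomp:
            pam = pam_space.reverse_complement(pam)
        counts[pam_space.rank(pam)] += 1
        used += 1
    return PamCountTable(sample_id=sample_id, counts=counts,
                         reads_used=used, reads_discarded=discarded)


# ---------------------------------------------------------------------------
# scoring and summaries
# ---------------------------------------------------------------------------

def enrichment(
    treated: PamCountTable,
    untreated: PamCountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> EnrichmentTable:
    """Signed log2 enrichment of treated vs untreated read frequencies.

    ``score[p] = log2( ((t_p + a) / (T + Na)) / ((u_p + a) / (U + Na)) )``
    with ``a`` the pseudocount, ``T``/``U`` the total used reads and ``N``
    the number of patterns.  Depleted (cleaved) PAMs score negative.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = float(pseudocount)
    t = treated.counts + a
    u = untreated.counts + a
    t_norm = t / (treated.reads_used + N_PAMS * a)
    u_norm = u / (untreated.reads_used + N_PAMS * a)
    return EnrichmentTable(
        scores=np.log2(t_norm / u_norm),
        pseudocount=a,
        treated_id=treated.sample_id,
        untreated_id=untreated.sample_id,
    )


def depleted_set(scores: EnrichmentTable, threshold: float = DEFAULT_THRESHOLD) -> DepletedSet:
    """PAMs with enrichment score <= *threshold* (inclusive)."""
    threshold = float(threshold)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return DepletedSet(threshold=threshold,
                       members=np.flatnonzero(scores.scores <= threshold))


def logo_matrix(members) -> LogoMatrix:
    """Unweighted per-position base frequencies of a depleted PAM set.

    Every member sequence counts once regardless of its read count.
    Information content is in bits with no small-sample correction.
    """
    if isinstance(members, DepletedSet):
        ranks = members.members
    else:
        ranks = np.asarray(members, dtype=np.int64)
    if len(ranks) == 0:
        raise ValueError("cannot build a logo from an empty PAM set")
    digits = pam_space.rank_digits(ranks)
    freqs = np.empty((PAM_LENGTH, 4))
    for j in range(PAM_LENGTH):
        freqs[j] = np.bincount(digits[:, j], minlength=4) / len(ranks)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return LogoMatrix(frequencies=freqs, information=np.clip(info, 0.0, 2.0))


def profile_2d(scores: EnrichmentTable) -> Profile2D:
    """Mean score for each of the 1,024 position-4..8 five-mers.

    Averaging is over the 64 N3 prefixes (positions 1-3); the grid is
    64 rows (position 4-6 trimers) x 16 columns (position 7-8 dimers).
    """
    cube = scores.scores.reshape((4,) * PAM_LENGTH)
    grid = cube.mean(axis=(0, 1, 2)).reshape(64, 16)
    return Profile2D(grid=grid)


def coverage_qc(untreated: PamCountTable) -> CoverageReport:
    """Histogram/CDF of per-PAM counts plus simple coverage fractions."""
    counts = untreated.counts
    values, hist = np.unique(counts, return_counts=True)
    cdf = np.cumsum(hist) / N_PAMS
    mean = counts.mean()
    return CoverageReport(
        count_values=values,
        histogram=hist,
        cumulative=cdf,
        fraction_covered=float((counts >= 1).mean()),
        fraction_tenth_mean=float((counts >= mean / 10).mean()),
    )


# ---------------------------------------------------------------------------
# pipeline driver and outputs
# ---------------------------------------------------------------------------

def run_profile(
    treated_reads,
    untreated_reads,
    anchor: str,
    *,
    max_mismatch: int = 1,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    threshold: float = DEFAULT_THRESHOLD,
    orientation: str = "as-read",
    out_dir=None,
) -> dict:
    """Full depletion analysis; optionally writes the TSV/JSON outputs."""
    treated = count_pams(treated_reads, anchor, max_mismatch,
                         sample_id="treated", orientation=orientation)
    untreated = count_pams(untreated_reads, anchor, max_mismatch,
                           sample_id="untreated", orientation=orientation)
    scores = enrichment(treated, untreated, pseudocount)
    depleted = depleted_set(scores, threshold)
    result = {
        "treated": treated,
        "untreated": untreated,
        "scores": scores,
        "depleted": depleted,
        "logo": logo_matrix(depleted) if len(depleted) else None,
        "profile2d": profile_2d(scores),
        "coverage": coverage_qc(untreated),
    }
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: dict, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    p = lambda name: os.path.join(out_dir, name)
    for key in ("treated", "untreated"):
        result[key].to_frame().to_csv(p(f"counts_{key}.tsv"), sep="\t", index=False)
    result["scores"].to_frame().to_csv(p("scores.tsv"), sep="\t", index=False)
    dep = result["depleted"]
    pd.DataFrame({
        "pam": dep.sequences(),
        "score": result["scores"].scores[dep.members],
    }).to_csv(p("depleted.tsv"), sep="\t", index=False)
    if result["logo"] is not None:
        result["logo"].to_frame().to_csv(p("logo_matrix.tsv"), sep="\t", index=False)
    result["profile2d"].to_frame().to_csv(p("profile2d.tsv"), sep="\t", index=False)
    result["coverage"].to_frame().to_csv(p("coverage.tsv"), sep="\t", index=False)
    cov = result["coverage"]
    summary = {
        "reads_used": {k: int(result[k].reads_used) for k in ("treated", "untreated")},
        "reads_discarded": {k: int(result[k].reads_discarded) for k in ("treated", "untreated")},
        "pseudocount": result["scores"].pseudocount,
        "threshold": dep.threshold,
        "n_depleted": int(len(dep)),
        "fraction_patterns_covered": cov.fraction_covered,
        "fraction_patterns_ge_tenth_mean": cov.fraction_tenth_mean,
    }
    with open(p("run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)


def plot_profile_2d(profile: Profile2D, path, *, title: str = "2D PAM profile") -> None:
    """Heatmap of the 64 x 16 mean-score grid (depletion shown dark)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 12))
    im = ax.imshow(profile.grid, aspect="auto", cmap="RdBu_r",
                   vmin=-abs(profile.grid).max(), vmax=abs(profile.grid).max())
    ax.set_xticks(range(16), profile.col_labels, rotation=90, fontsize=6)
    ax.set_yticks(range(64), profile.row_labels, fontsize=4)
    ax.set_xlabel("PAM positions 7-8")
    ax.set_ylabel("PAM positions 4-6")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="mean log2 enrichment")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_logo(logo: LogoMatrix, path, *, title: str = "depleted-set logo") -> None:
    """Simple information-scaled letter logo rendered with matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#109648", "C": "#255c99", "G": "#f7b32b", "T": "#d62839"}
    fig, ax = plt.subplots(figsize=(6, 3))
    for j in range(PAM_LENGTH):
        y = 0.0
        order = np.argsort(logo.frequencies[j])
        for bi in order:
            h = logo.frequencies[j, bi] * logo.information[j]
            if h <= 0:
                continue
            ax.bar(j + 1, h, bottom=y, width=0.8, color=colors[BASES[bi]],
                   edgecolor="white", linewidth=0.5)
            if h > 0.08:
                ax.text(j + 1, y + h / 2, BASES[bi], ha="center", va="center",
                        fontsize=8 + 10 * h / 2, color="white", fontweight="bold")
            y += h
    ax.set_xticks(range(1, PAM_LENGTH + 1))
    ax.set_xlabel("PAM position")
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
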