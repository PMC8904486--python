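# Methods

This note documents the models implemented in `pamkit`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the package's known limitations.

## PAM depletion profiling

### Model

A cleavage-survivor library experiment is modeled as two multinomial
draws over the 65,536 8-nt PAM patterns. The untreated sample reflects
plasmid abundance alone; in the treated sample each pattern's abundance
is multiplied by its survival. The analysis makes no distributional
assumption: it simply compares normalized frequencies,

    score(p) = log2( f_treated(p) / f_untreated(p) ),

with pseudocount α added to every count in both samples. Scores are
stored with the enrichment sign convention (depleted = negative);
outputs that display depletion = −score say so in their headers.

### Pseudocount (α, default 2.0)

The α scale matters because per-pattern coverage is low: 10^5 reads over
65,536 patterns is λ ≈ 1.5 reads per pattern. Crossing the −2 threshold
requires (t+α)/(u+α) ≤ ~1/4, i.e. u ≥ 4t + 3α. With α = 1 the pure
Poisson fluctuation (t = 0, u ≥ 3) already qualifies and has probability
of a few percent, so a null experiment (no nuclease) would call a few
percent of all patterns "depleted". With α = 2 the requirement becomes
u ≥ 4t + 6, and the measured null false-depletion rate at design depth
is ≈ 0.1% across seeds. Well-covered patterns are essentially
unaffected. α is exposed on the API and CLI (`--pseudocount`) for
sensitivity analysis.

### PAM extraction

The 8-bp window is located by matching a constant ≥ 12-nt anchor
(the 3' end of the protospacer) with at most `max_mismatch`
substitutions and no indels. Reads with no anchor, two equally good
anchor placements, a truncated window, or an ambiguous base in the
window are discarded and counted. Indels are deliberately not tolerated
in the anchor: an indel shifts the randomized window and would corrupt
the pattern. Demultiplexing (where needed) uses the same
mismatch-tolerant exact-prefix logic as the amplicon pipeline rather
than an external aligner.

### Summaries

- **Depleted set**: score ≤ −2.0, threshold inclusive.
- **Logo**: unweighted per-position base frequencies over the member
  sequences (each member counts once regardless of read count — the
  set, not the reads, defines the motif), information content in bits
  with no small-sample correction.
- **2D profile**: for each of the 1,024 position-4–8 five-mers, the
  arithmetic mean of the 64 scores over the N3 prefixes, arranged as 64
  rows (position 4–6 trimers) × 16 columns (position 7–8 dimers), both
  axes lexicographic A<C<G<T. The axis arrangement is a rendering
  choice; the cell set is fixed by definition. The unweighted mean of
  all cells equals the mean of all 65,536 scores exactly (disjoint
  cover), which the tests assert to 1e-9.
- **Coverage QC**: histogram and CDF of untreated per-pattern counts,
  plus the fractions of patterns with count ≥ 1 and ≥ mean/10.

## Amplicon editing quantification

### Alignment

Reads are aligned to their reference amplicon with a semi-global
affine-gap DP (free end-gaps on the reference; read overhangs are
penalized insertions): match +2, mismatch −3, gap open −5 (first gap
base), extend −2 (each further base). Reads shorter than 30 nt or with
identity < 70% over the aligned columns are treated as unmapped — a
deterministic stand-in for E-value filtering in short-read mappers.

Among co-optimal alignments the traceback returns the alignment whose
operation string is lexicographically smallest under D < I < M < S
(deletion, insertion, match column, free end-skip). Preferring D and I
over M in ties shifts every indel maximally left over equal bases, so
indels are left-aligned *by construction* and event keys (kind,
position, payload) are canonical — a requirement for the control
blocklist, which matches events by exact key equality. The greedy
traceback over suffix-optimal scores provably yields that canonical
choice; the test suite verifies it against an independent exhaustive
oracle on hundreds of random instances and against full enumeration of
all optimal alignments on tiny ones. Two fast paths (exact substring;
equal-length with ≤ 1 mismatch) are used only where the ungapped
alignment is provably the unique optimum.

### Control correction

The blocklist contains every mutation key whose frequency among aligned
control reads exceeds the threshold (strictly greater than 1% by
default). It is built per site from that site's matched control.
Filtering removes blocklisted-read carriers from **both** samples —
symmetric treatment makes the self-control identity exact
(`summarize_site(X, X)` returns 0 corrected frequencies for any X) and
avoids denominators that differ between samples for reasons unrelated
to editing.

Corrected frequencies are floored at zero: subtraction can go negative
from sampling noise and negative editing is not meaningful.

- **Indel frequency**: fraction of retained reads with ≥ 1 insertion or
  deletion overlapping [protospacer start − 3, PAM end + 3).
- **C-to-T profile**: for each protospacer-strand C at positions
  −22…−1, the fraction of covering reads showing T (strand-aware:
  G-to-A in reference frame for minus-strand sites). C-to-G and C-to-A
  appear only in the substitution matrix.
- **Per-site C-to-T statistic**: the maximum corrected per-position
  frequency inside the editing window (default −21…−8). A single
  per-site number necessarily hides the profile shape, so the full
  profile is always reported next to it; maximum-over-window is the
  common convention for base-editor reporting.

Position numbering: 0-based half-open internally; externally protospacer
positions −22 (PAM-distal) … −1 (adjacent to the PAM) and PAM positions
+1…+8, which makes the −21…−8 base-editing window read the same on both
strands.

### Pair merging

`merge_pairs` is provided but optional (reads may arrive pre-merged):
best ungapped overlap ≥ 10 nt with mismatch rate ≤ 0.1, disagreements
resolved toward the higher base quality, R1 winning ties.

## Cleavage kinetics

One-phase exponential association, Y(t) = Ymax(1 − e^(−kt)), with no
intercept term because the substrate is uncleaved at t = 0. Bounds
Ymax ∈ [0, 1.05] (slack absorbs band-quantification noise above 1) and
k ∈ (0, 100] min⁻¹. Initialization: Ymax from the largest observed
fraction; k by inverting the model at the earliest nonzero point.
Replicates are pooled by default (fits to all points jointly);
per-replicate fits are a flag. The optimizer runs with tight tolerances
and an analytic Jacobian; the noiseless round trip over a 10×10
(Ymax, k) grid recovers both parameters to better than 1e-6 relative.
Degenerate inputs: all-zero fractions return Ymax = 0, not converged;
fewer than 3 points or fewer than 2 distinct nonzero times are rejected.

## Synthetic data generators

### Library simulator

Per-PAM plasmid abundance is log-normal (σ = 1.5 by default — randomized
oligo synthesis plus assembly yields order-of-magnitude abundance
spread) and normalized; untreated reads are a multinomial draw from it,
treated reads from abundance × survival with survival(p) = 1 − c·a(p),
c the cleavage extent. Linear survival is deliberately simple and
monotone in activity, which is what rank-recovery tests need; an
exposure model e^(−dose·a) can be substituted by a custom survival
array. Sequencing errors are independent per-base substitutions
(default 0.1%); indel errors can be enabled to stress the
anchor-discard path. Qualities are constant Q30 placeholders.

The default activity model a(p) is a product of per-position base
factors: consensus bases (N3VRYAC) have factor 1, positions 1–3 are
neutral, and off-consensus bases keep graded partial activity
(position 4 T is the most disfavored at 0.55; other penalties 0.60–0.95,
distinct per base), with an extra ×0.6 for the position-4 C ×
position-5 G combination — a weak class *inside* the consensus that the
2D profile should expose but a logo cannot. The grading reflects how a
promiscuous PAM reader behaves (near-consensus sequences retain partial
activity) and was fixed once by a design study balancing two
requirements at design depth: the depleted set must be
consensus-dominated, and activity ranks must be separable from counting
noise among well-covered patterns.

What it does not emulate: PCR duplicates and chimeras, quality decay,
position-dependent error, GC bias. Passing recovery tests therefore
demonstrates correctness of the analysis under multinomial sampling and
uniform substitution error, not robustness to amplification artifacts.

**A note on rank recovery.** At 10^5 reads per sample the per-pattern
coverage is λ ≈ 1.5; even among patterns with untreated count ≥ 10, the
Poisson standard deviation of the log2 ratio is ~0.5 while the linear
survival model caps the score range at −log2(1 − 0.95) ≈ 4.3. Spearman
correlation between depletion and true activity is therefore
noise-limited to roughly 0.8–0.9 even for a best-case continuous
activity distribution, and to ~0.6 for product-structured consensus
models; recovering the *consensus logo* is robust at this depth, but
fine activity *ranking* requires deeper sequencing or an exposure-style
survival model with a wider dynamic range.

### Amplicon simulator

Each edited read independently receives an indel at the cut region
(boundary between protospacer positions −4 and −3, the conventional
cleavage position; length from a configurable distribution, deletions
1–3 nt and 1-nt insertions by default) with the true frequency, and
independent per-position C-to-T conversions per the truth profile. Both
samples receive the recurrent control-artifact spectrum and random
substitution errors. Per-read labels are recorded as drawn, so
truth-table frequencies are the sampling record, not a re-estimate.

### Kinetics simulator

Exact curve values plus Gaussian noise, clipped to [0, 1]; t = 0 is
exactly zero before noise.

### Fixture bundle

`pamkit sim fixtures` writes a miniature end-to-end dataset (library
pair at depth 2×10^4, two amplicon sites on opposite strands, one
kinetics table) with truth files and a SHA-256 manifest; identical seed
and configuration give byte-identical output.

## Design choices where the design was open

- **One canonical score.** Only signed enrichment is stored; "depletion"
  displays negate it at the reporting layer. Avoids double-negation bugs.
- **Per-site controls** (not pooled across sites) for the blocklist:
  matched controls capture locus-specific PCR/somatic background.
- **Unweighted logo** over depleted sequences (not read-weighted): the
  threshold defines set membership; weighting would mix abundance back
  into a motif display.
- **Maximum-over-window** as the per-site C-to-T scalar, with the full
  profile always alongside.
- **Aligner replaces short-read BLAST mapping**: deterministic,
  dependency-free and testable against an exhaustive oracle, with the
  70% identity floor standing in for E-value filtering.

## Known limitations

- No statistical significance testing of per-PAM depletion; the −2.0
  threshold is a fixed operating point.
- No UMI handling, no SAM/BAM emission, no indel spectrum classification
  beyond presence/length, no off-target discovery (off-target sites are
  simply additional amplicon sites).
- The aligner is quadratic per read; adequate for amplicons (≤ ~500 nt),
  not a general-purpose mapper.
- Problem sizes in the test suite and acceptance script (10^5-read
  libraries, depth-5,000 amplicon replicates, 10×10 kinetics grids) were
  chosen as the smallest sizes at which the statistical guarantees are
  meaningful; all scale up linearly.
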