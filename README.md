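# pamkit

Analysis toolkit for characterizing compact Cas9 nucleases: PAM
specificity profiling from randomized-library depletion assays,
genome/base-editing quantification from amplicon deep sequencing, and
in vitro cleavage kinetics — with seeded ground-truth simulators so the
whole pipeline is testable end-to-end without any external sequencing
data.

## Who this is for

Groups characterizing Cas9 orthologs or engineered variants (e.g. the
compact *Campylobacter jejuni* Cas9 family, whose functional consensus
is N3VRYAC with a canonical T3AACAC PAM) typically run three assays:

1. **PAM discovery**: a plasmid library carrying a fixed 22-nt target
   followed by an 8-bp randomized PAM is cleaved in vitro; survivors are
   deep sequenced. Cleavable PAMs are depleted from the treated pool.
2. **Editing in cells**: amplicon deep sequencing of target loci in
   edited and control samples, quantifying indels (nuclease) and C-to-T
   conversions (cytosine base editor).
3. **Cleavage kinetics**: time courses of cleaved fraction fitted with a
   one-phase exponential association.

`pamkit` implements the computational side of all three as a tested,
reusable library with a thin CLI.

## The statistics at the core

**Depletion score.** For each of the 4^8 = 65,536 PAM patterns *p*, with
read counts *t_p* (treated) and *u_p* (untreated), totals *T*, *U* and
pseudocount α (default 2):

    score(p) = log2[ ((t_p + α)/(T + 65536·α)) / ((u_p + α)/(U + 65536·α)) ]

Negative scores mean depletion (cleavage). Patterns with score ≤ −2.0
form the functional set, summarized two ways: a sequence logo
(per-position base frequencies, information content IC_j = 2 + Σ_b
f_jb·log2 f_jb bits) and a **2D PAM profile** — the mean score for each
of the 1,024 concrete sequences at PAM positions 4–8, averaged over the
64 N3 prefixes and laid out as a 64×16 grid. The 2D profile resolves
preferences *within* a promiscuous consensus that a 1D logo hides.

**Editing frequencies.** Reads are aligned to their reference amplicon
with a semi-global affine-gap aligner (match +2, mismatch −3, gap open
−5, extend −2, free end-gaps on the reference; indels left-aligned so
identical events compare equal). Mutations above 1% frequency in the
matched control are blocklisted and reads carrying them removed from
both samples; corrected frequencies are `max(0, edited − control)` for
the indel frequency (any indel overlapping the protospacer+PAM ± 3 nt)
and for each per-position C-to-T frequency. Protospacer positions are
numbered −22 (PAM-distal) … −1 (PAM-proximal); base editing is scored in
the −21…−8 window by default.

**Kinetics.** Y(t) = Ymax·(1 − e^(−kt)), forced through 0 at t = 0,
fitted by bounded least squares.

## Worked example

```python
from pamkit import synthetic_data as sd, pam_depletion as pdp
from pamkit import cleavage_kinetics as ck

model = sd.default_activity_model(extent=0.95)          # N3VRYAC-like truth
cfg = sd.LibrarySimConfig(depth=100_000, seed=1)
lib = sd.simulate_library(model, cfg)

untreated = pdp.count_pams(lib.untreated_reads, cfg.anchor, sample_id="untreated")
treated = pdp.count_pams(lib.treated_reads, cfg.anchor, sample_id="treated")
scores = pdp.enrichment(treated, untreated)
dep = pdp.depleted_set(scores, threshold=-2.0)
print(f"depleted set: {len(dep)} PAMs at log2 enrichment <= -2.0")
print(f"logo modal bases: {pdp.logo_matrix(dep).modal_bases()}")

fit = ck.fit_association(
    sd.simulate_kinetics(0.8, 1.2, [0.5, 1, 2, 5], sigma=0.02, replicates=3, seed=1))
print(f"kinetics fit: y_max = {fit.y_max:.3f}, k = {fit.k:.3f} min^-1")
```

prints

```
depleted set: 85 PAMs at log2 enrichment <= -2.0
logo modal bases: TGAAACAC
kinetics fit: y_max = 0.796, k = 1.252 min^-1
```

The modal bases at PAM positions 4–8 read `AACAC` — the simulator's
planted consensus class (V R Y A C, ties resolved alphabetically at the
fully random positions 1–3, which carry ~0 bits). The kinetics fit
recovers the planted (0.8, 1.2 min⁻¹) within noise. The same analyses
are available from the shell:

```sh
pamkit sim library --depth 100000 --seed 1 --out sim/
pamkit pam profile --treated sim/treated.fastq.gz --untreated sim/untreated.fastq.gz \
    --anchor CAGGTTCACGATCCAG --out profile/
pamkit edit call --r1 pool.fastq --refs refs.fa --sites sites.tsv \
    --samples samples.tsv --out calls/
pamkit kinetics fit --in kinetics.tsv --out fits.tsv
```

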