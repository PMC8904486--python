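"""Seeded generators emulating the two sequencing assays and the kinetics assay.

Every generator records its ground truth (per-PAM activity, per-read edit
labels, true curve parameters), so each pipeline stage can be tested for
recovery without any external data.  All randomness flows from a single
integer seed through ``numpy.random.default_rng``; identical seed and
configuration give byte-identical output.

Library model
-------------
Plasmid abundances for the 65,536 PAM patterns are drawn log-normally
and normalized; the untreated sample is a multinomial draw from that
abundance, the treated sample a multinomial draw from abundance times
survival, ``survival(p) = 1 - c * activity(p)``, renormalized.  Survival
linear in activity is deliberately simple and monotone, which is all the
rank-recovery tests need; an exposure (exponential) model can be
substituted by passing a custom survival array.

Activity model
--------------
``activity(p)`` is a product of per-position, per-base factors.
Consensus-matching bases (``N3VRYAC``: positions 4-8) have factor 1 and
positions 1-3 are neutral; non-consensus bases carry partial penalties
(a promiscuous nuclease retains graded activity on near-consensus PAMs),
and an optional pairwise penalty reproduces sub-optimal combinations
inside the consensus, e.g. the weak position-4 C / position-5 G class.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pam_space
from ._fastq import FastqRecord, write_fastq
from .amplicon_editing import AmpliconSite, MutationKey, SampleRecord
from .cleavage_kinetics import CleavageTimeSeries, association
from .pam_space import BASES, N_PAMS, PAM_LENGTH, reverse_complement

# ---------------------------------------------------------------------------
# shared synthetic sequence context (synthetic stand-ins, not assay sequences)
# ---------------------------------------------------------------------------

#: Synthetic 22-nt protospacer used by the default simulations.
DEFAULT_PROTOSPACER = "ATGCTGCAGGTTCACGATCCAG"
#: Canonical PAM of the wild-type enzyme.
CANONICAL_PAM = "TTTAACAC"
#: Constant anchor used to locate the randomized PAM window: the 3' end
#: of the protospacer, immediately upstream of the window.
DEFAULT_ANCHOR = DEFAULT_PROTOSPACER[-16:]
#: Synthetic vector context flanking the library cassette.
LIBRARY_LEFT_FLANK = "GTTGTAAAACGACGGCCAGT"
LIBRARY_RIGHT_FLANK = "CAGGAAACAGCTATGACCATG"

_AMPLICON_LEFT = "TCTTGCGGTAACCTTACCTGGCAAAGTCCTGATCACGTGAT"
_AMPLICON_RIGHT = "GATCCTTAGGCACCAATGTGACCTTCAGGTCATAGCTGTTT"


# ---------------------------------------------------------------------------
# activity model
# ---------------------------------------------------------------------------

@dataclass
class ActivityModel:
    """Per-PAM cleavage activity as a product of per-position base factors."""

    factors: list  # 8 dicts, base -> factor in [0, 1]
    extent: float = 0.95  # overall cleavage completeness c
    pair_penalties: list = field(default_factory=list)
    # each pair penalty: (pos_a, base_a, pos_b, base_b, factor)

    def __post_init__(self):
        if len(self.factors) != PAM_LENGTH:
            raise ValueError(f"factors must list {PAM_LENGTH} positions")
        for j, d in enumerate(self.factors, 1):
            for b, f in d.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"factor {f} for base {b} at position {j} outside [0, 1]")
        if not 0.0 <= self.extent <= 1.0:
            raise ValueError("extent must be in [0, 1]")

    def activity(self, seq: str) -> float:
        a = 1.0
        for j, b in enumerate(seq.upper()):
            a *= self.factors[j][b]
        for (pa, ba, pb, bb, f) in self.pair_penalties:
            if seq[pa - 1] == ba and seq[pb - 1] == bb:
                a *= f
        return a

    def activity_table(self) -> np.ndarray:
        """Activity for all 65,536 PAMs in rank order (vectorized)."""
        digits = pam_space.rank_digits()
        act = np.ones(N_PAMS)
        for j in range(PAM_LENGTH):
            per_base = np.array([self.factors[j][b] for b in BASES])
            act *= per_base[digits[:, j]]
        for (pa, ba, pb, bb, f) in self.pair_penalties:
            mask = (digits[:, pa - 1] == BASES.index(ba)) & \
                   (digits[:, pb - 1] == BASES.index(bb))
            act[mask] *= f
        return act

    def survival_table(self) -> np.ndarray:
        return 1.0 - self.extent * self.activity_table()

    def consensus(self, tolerance: float = 0.05) -> str:
        """IUPAC consensus: per position, the bases within *tolerance* of the
        position's best factor (graded models keep near-maximal bases in the
        consensus class)."""
        inv = {frozenset(v): k for k, v in pam_space.IUPAC.items()}
        out = []
        for d in self.factors:
            top_f = max(d.values())
            top = frozenset(b for b in BASES if d[b] >= top_f * (1.0 - tolerance))
            out.append(inv.get(top, "N"))
        return "".join(out)


def default_activity_model(extent: float = 0.95) -> ActivityModel:
    """Default N3VRYAC-like model with graded off-consensus penalties.

    Consensus bases score 1.0; off-consensus bases keep substantial
    partial activity (distinct per base, emulating a promiscuous PAM
    reader); the position-4 C x position-5 G combination carries an extra
    penalty, reproducing a weak class of consensus-matching PAMs.  The
    numeric penalties were chosen once by a small design study so that
    the depletion assay at its design depth separates activity ranks
    from counting noise; see docs/methods.md.
    """
    neutral = {b: 1.0 for b in BASES}
    factors = [
        dict(neutral),  # position 1 (N)
        dict(neutral),  # position 2 (N)
        dict(neutral),  # position 3 (N)
        {"A": 1.0, "C": 1.0, "G": 1.0, "T": 0.55},              # 4: V (T strongly disfavored)
        {"A": 1.0, "G": 0.95, "C": 0.80, "T": 0.60},            # 5: R
        {"C": 1.0, "T": 0.95, "A": 0.80, "G": 0.60},            # 6: Y
        {"A": 1.0, "C": 0.90, "G": 0.80, "T": 0.65},            # 7: A
        {"C": 1.0, "A": 0.90, "T": 0.80, "G": 0.65},            # 8: C
    ]
    return ActivityModel(factors=factors, extent=extent,
                         pair_penalties=[(4, "C", 5, "G", 0.6)])


# ---------------------------------------------------------------------------
# PAM library simulation
# ---------------------------------------------------------------------------

@dataclass
class LibrarySimConfig:
    depth: int = 100_000            # reads per sample
    abundance_sigma: float = 1.5    # log-normal sigma of per-PAM plasmid abundance
    error_rate: float = 0.001       # per-base substitution error
    anchor: str = DEFAULT_ANCHOR
    left_flank: str = LIBRARY_LEFT_FLANK
    right_flank: str = LIBRARY_RIGHT_FLANK
    protect_pam_window: bool = False  # if True, no errors inside the PAM window
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error rate must be in [0, 0.05]")


@dataclass
class SimulatedLibrary:
    untreated_reads: list
    treated_reads: list
    truth: pd.DataFrame      # per-PAM abundance, activity, survival, true counts
    config: LibrarySimConfig

    def true_pam_counts(self, sample: str) -> np.ndarray:
        col = "count_untreated" if sample == "untreated" else "count_treated"
        return self.truth[col].to_numpy()


def _library_count_draw(model: ActivityModel, cfg: LibrarySimConfig, rng):
    abundance = rng.lognormal(0.0, cfg.abundance_sigma, N_PAMS)
    abundance /= abundance.sum()
    survival = model.survival_table()
    treated_p = abundance * survival
    treated_p /= treated_p.sum()
    untreated = rng.multinomial(cfg.depth, abundance)
    treated = rng.multinomial(cfg.depth, treated_p)
    return abundance, survival, untreated, treated


def _truth_frame(model, abundance, survival, untreated, treated) -> pd.DataFrame:
    return pd.DataFrame({
        "rank": np.arange(N_PAMS),
        "abundance": abundance,
        "activity": model.activity_table(),
        "survival": survival,
        "count_untreated": untreated,
        "count_treated": treated,
    })


def simulate_library_counts(model: ActivityModel, cfg: LibrarySimConfig):
    """Count-level library simulation (no read synthesis).

    Returns ``(untreated_counts, treated_counts, truth)`` as dense
    :class:`~pamkit.pam_depletion.PamCountTable` objects drawn from the
    same generative model as :func:`simulate_library`, for tests that
    only exercise the scoring stages.
    """
    from .pam_depletion import PamCountTable

    rng = np.random.default_rng(cfg.seed)
    abundance, survival, untreated, treated = _library_count_draw(model, cfg, rng)
    t_u = PamCountTable("untreated", untreated, int(untreated.sum()), 0)
    t_t = PamCountTable("treated", treated, int(treated.sum()), 0)
    return t_u, t_t, _truth_frame(model, abundance, survival, untreated, treated)


def _apply_errors(seqs: list, rng, error_rate: float, protected: tuple | None):
    """In-place per-base substitution errors; *protected* is a half-open window."""
    if error_rate <= 0:
        return
    for i, seq in enumerate(seqs):
        k = rng.binomial(len(seq), error_rate)
        if k == 0:
            continue
        positions = rng.choice(len(seq), size=k, replace=False)
        chars = list(seq)
        for p in positions:
            if protected and protected[0] <= p < protected[1]:
                continue
            alt = BASES[rng.integers(0, 4)]
            while alt == chars[p]:
                alt = BASES[rng.integers(0, 4)]
            chars[p] = alt
        seqs[i] = "".join(chars)


def _library_reads(tag: str, counts: np.ndarray, cfg: LibrarySimConfig, rng) -> list:
    pams = pam_space.all_pams()
    ranks = np.repeat(np.arange(N_PAMS), counts)
    rng.shuffle(ranks)
    prefix = cfg.left_flank + DEFAULT_PROTOSPACER
    # the anchor must sit immediately upstream of the window
    assert prefix.endswith(cfg.anchor)
    seqs = [prefix + pams[r] + cfg.right_flank for r in ranks]
    protected = (len(prefix), len(prefix) + PAM_LENGTH) if cfg.protect_pam_window else None
    _apply_errors(seqs, rng, cfg.error_rate, protected)
    qual = "?" * len(prefix + "N" * PAM_LENGTH + cfg.right_flank)  # constant Q30
    return [
        (f"{tag}_{i:07d} pam={pams[r]}", seq, qual)
        for i, (r, seq) in enumerate(zip(ranks, seqs))
    ]


def simulate_library(model: ActivityModel, cfg: LibrarySimConfig) -> SimulatedLibrary:
    """Full read-level library simulation (untreated + treated FASTQ records).

    Each read title records the true PAM drawn for that read (before
    sequencing errors), and the truth table records each PAM's abundance,
    activity, survival and true read counts.
    """
    rng = np.random.default_rng(cfg.seed)
    abundance, survival, untreated, treated = _library_count_draw(model, cfg, rng)
    reads_u = _library_reads("u", untreated, cfg, rng)
    reads_t = _library_reads("t", treated, cfg, rng)
    return SimulatedLibrary(
        untreated_reads=reads_u,
        treated_reads=reads_t,
        truth=_truth_frame(model, abundance, survival, untreated, treated),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# amplicon simulation
# ---------------------------------------------------------------------------

def make_test_site(site_id: str = "site1", strand: str = "+",
                   protospacer: str = DEFAULT_PROTOSPACER,
                   pam: str = CANONICAL_PAM) -> AmpliconSite:
    """Deterministic synthetic amplicon site on either strand."""
    cassette = protospacer + pam
    if strand == "-":
        cassette = reverse_complement(cassette)
    reference = _AMPLICON_LEFT + cassette + _AMPLICON_RIGHT
    return AmpliconSite.from_reference(site_id, reference, protospacer, pam, strand)


@dataclass
class AmpliconSimConfig:
    site: AmpliconSite
    indel_frequency: float = 0.0
    indel_lengths: dict = field(default_factory=lambda: {1: 0.45, 2: 0.25, 3: 0.15, -1: 0.15})
    # keys: deletion length (> 0) or insertion length (< 0); values: probabilities
    ct_truth: dict = field(default_factory=dict)   # protospacer position -> C-to-T frequency
    control_artifacts: list = field(default_factory=list)  # (MutationKey, frequency)
    error_rate: float = 0.001
    depth: int = 5000
    cut_offset: int = -3  # indels land at the boundary between cut_offset-1 and cut_offset
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.indel_frequency <= 1.0:
            raise ValueError("indel_frequency must be in [0, 1]")
        total = sum(self.indel_lengths.values())
        if self.indel_lengths and abs(total - 1.0) > 1e-9:
            raise ValueError("indel length probabilities must sum to 1")
        for p, f in self.ct_truth.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"C-to-T truth frequency {f} at position {p} outside [0, 1]")
            if self.site.base_at(p) != "C":
                raise ValueError(f"position {p} is not a protospacer-strand C")
        for _key, f in self.control_artifacts:
            if not 0.0 < f <= 1.0:
                raise ValueError("artifact frequencies must be in (0, 1]")


@dataclass
class SimulatedAmplicons:
    edited_reads: list
    control_reads: list
    site: AmpliconSite
    truth: pd.DataFrame  # one row per read with edit labels
    config: AmpliconSimConfig

    def true_fraction(self, label: str, sample: str = "edited") -> float:
        sub = self.truth[self.truth["sample"] == sample]
        return float(sub[label].mean())


def _indel_interval(site: AmpliconSite, cut_offset: int, length: int):
    """Reference interval removed (length > 0) or insertion point (length < 0)."""
    if length > 0:
        positions = sorted(site.ref_pos(p) for p in range(cut_offset - length + 1, cut_offset + 1))
        return positions[0], positions[0] + length
    ins_at = site.ref_pos(cut_offset) if site.strand == "+" else site.ref_pos(cut_offset - 1)
    return ins_at, ins_at


def _simulate_sample(tag: str, edited: bool, cfg: AmpliconSimConfig, rng):
    site = cfg.site
    ref = site.reference
    lengths = list(cfg.indel_lengths)
    length_p = np.array([cfg.indel_lengths[k] for k in lengths]) if lengths else None
    ct_positions = sorted(cfg.ct_truth)
    reads, labels = [], []
    for i in range(cfg.depth):
        subs = {}
        ct_hits = []
        has_indel = False
        indel_len = 0
        if edited:
            for p in ct_positions:
                if rng.random() < cfg.ct_truth[p]:
                    refpos = site.ref_pos(p)
                    # C-to-T on the protospacer strand; G-to-A in reference frame
                    subs[refpos] = "T" if site.strand == "+" else "A"
                    ct_hits.append(p)
            if cfg.indel_frequency and rng.random() < cfg.indel_frequency:
                has_indel = True
                indel_len = lengths[rng.choice(len(lengths), p=length_p)]
        artifact_hits = []
        indels = []
        for key, freq in cfg.control_artifacts:
            if rng.random() < freq:
                artifact_hits.append(key)
                if key.kind == "sub":
                    subs[key.pos] = key.payload
                elif key.kind == "del":
                    indels.append((key.pos, key.pos + key.payload, ""))
                else:
                    indels.append((key.pos, key.pos, key.payload))
        if has_indel:
            a, b = _indel_interval(site, cfg.cut_offset, indel_len)
            ins_seq = "".join(BASES[j] for j in rng.integers(0, 4, max(0, -indel_len)))
            indels.append((a, b, ins_seq))
        chars = list(ref)
        for pos, base in subs.items():
            chars[pos] = base
        for a, b, ins_seq in sorted(indels, reverse=True):
            chars[a:b] = list(ins_seq)
        seqs = ["".join(chars)]
        _apply_errors(seqs, rng, cfg.error_rate, None)
        seq = seqs[0]
        reads.append((f"{tag}_{i:06d}", seq, "?" * len(seq)))
        labels.append({
            "read_id": f"{tag}_{i:06d}",
            "sample": tag,
            "has_indel": has_indel,
            "indel_length": indel_len,
            "ct_positions": ",".join(str(p) for p in ct_hits),
            "n_artifacts": len(artifact_hits),
        })
        for p in ct_positions:
            labels[-1][f"ct_at_{p}"] = p in ct_hits
    return reads, labels


def simulate_amplicons(cfg: AmpliconSimConfig) -> SimulatedAmplicons:
    """Edited + control amplicon reads with per-read ground-truth labels.

    Edited reads carry indels at the cut region and independent
    per-position C-to-T conversions at the configured true frequencies;
    both samples carry the recurrent control-artifact spectrum and random
    substitution errors.  Truth frequencies are the exact means of the
    per-read labels (the sampling record, not a re-estimate).
    """
    rng = np.random.default_rng(cfg.seed)
    edited_reads, edited_labels = _simulate_sample("edited", True, cfg, rng)
    control_reads, control_labels = _simulate_sample("control", False, cfg, rng)
    truth = pd.DataFrame(edited_labels + control_labels)
    return SimulatedAmplicons(edited_reads, control_reads, cfg.site, truth, cfg)


# ---------------------------------------------------------------------------
# multiplexing and kinetics
# ---------------------------------------------------------------------------

def multiplex_reads(per_sample: dict, samples: list) -> list:
    """Interleave per-sample records into one pool, prepending index+primer.

    *per_sample* maps sample_id to records; *samples* is the sample sheet
    (:class:`~pamkit.amplicon_editing.SampleRecord`).  The true sample is
    recorded in each read title for label-consistency tests.
    """
    by_id = {s.sample_id: s for s in samples}
    pool = []
    for sample_id, records in per_sample.items():
        s = by_id[sample_id]
        for title, seq, qual in records:
            tagged = s.index + s.fwd_primer + seq
            pool.append((f"{title} sample={sample_id}", tagged,
                         "?" * (len(s.index) + len(s.fwd_primer)) + qual))
    pool.sort(key=lambda rec: rec[0])
    return pool


def simulate_kinetics(y_max: float, k: float, times, sigma: float = 0.0,
                      replicates: int = 3, seed: int = 0) -> list:
    """Noisy draws from Y(t) = y_max (1 - exp(-k t)), clipped to [0, 1]."""
    if not 0.0 <= y_max <= 1.0:
        raise ValueError("y_max must be in [0, 1]")
    if k <= 0:
        raise ValueError("k must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    out = []
    for r in range(replicates):
        y = association(times, y_max, k)
        if sigma > 0:
            y = y + rng.normal(0.0, sigma, size=times.shape)
        out.append(CleavageTimeSeries(times, np.clip(y, 0.0, 1.0),
                                      replicate_id=f"rep{r + 1}"))
    return out


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def fixture_bundle(out_dir, seed: int = 0) -> dict:
    """Write a miniature end-to-end dataset with truth files.

    Contents: a library pair at depth 2x10^4, two amplicon sites (one per
    strand) with edited/control samples, and one kinetics table, plus
    ground-truth tables and a checksum manifest.  Returns a dict of
    paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def path(name):
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    rng_seed = np.random.SeedSequence(seed).generate_state(4) % (2**31)

    # library pair
    model = default_activity_model()
    lib_cfg = LibrarySimConfig(depth=20_000, seed=int(rng_seed[0]))
    lib = simulate_library(model, lib_cfg)
    write_fastq(lib.untreated_reads, path("library_untreated.fastq"))
    write_fastq(lib.treated_reads, path("library_treated.fastq"))
    lib.truth.to_csv(path("library_truth.tsv"), sep="\t", index=False)

    # two amplicon sites, one per strand
    sites = [make_test_site("siteA_plus", "+"), make_test_site("siteB_minus", "-")]
    site_rows, sample_rows = [], []
    with open(path("refs.fa"), "w") as fh:
        for site in sites:
            fh.write(f">{site.site_id}_ref\n{site.reference}\n")
    for i, site in enumerate(sites):
        ct_pos = next(p for p in range(-21, -7) if site.base_at(p) == "C")
        cfg = AmpliconSimConfig(
            site=site,
            indel_frequency=0.40,
            ct_truth={ct_pos: 0.20},
            control_artifacts=[(MutationKey("sub", 5, "A" if site.reference[5] != "A" else "G"), 0.02)],
            depth=2000,
            seed=int(rng_seed[1]) + i,
        )
        sim = simulate_amplicons(cfg)
        write_fastq(sim.edited_reads, path(f"{site.site_id}_edited.fastq"))
        write_fastq(sim.control_reads, path(f"{site.site_id}_control.fastq"))
        sim.truth.to_csv(path(f"{site.site_id}_truth.tsv"), sep="\t", index=False)
        site_rows.append({
            "site_id": site.site_id, "protospacer": site.protospacer,
            "pam": site.pam, "strand": site.strand,
            "reference_id": f"{site.site_id}_ref",
        })
        for role in ("edited", "control"):
            sample_rows.append({
                "sample_id": f"{site.site_id}_{role}",
                "index_seq": ["ACGTACGT", "TGCATGCA", "GGTTAACC", "CCAATTGG"][2 * i + (role == "control")],
                "fwd_primer": site.reference[:20],
                "rev_primer": reverse_complement(site.reference[-20:]),
                "site_id": site.site_id,
                "role": role,
            })
    pd.DataFrame(site_rows).to_csv(path("sites.tsv"), sep="\t", index=False)
    pd.DataFrame(sample_rows).to_csv(path("samples.tsv"), sep="\t", index=False)

    # kinetics table
    series = simulate_kinetics(0.8, 1.2, [0.5, 1.0, 2.0, 5.0], sigma=0.02,
                               replicates=3, seed=int(rng_seed[2]))
    rows = []
    for s in series:
        for t, f in zip(s.times, s.fractions):
            rows.append({"replicate": s.replicate_id, "time_min": t, "fraction": f})
    pd.DataFrame(rows).to_csv(path("kinetics.tsv"), sep="\t", index=False)
    with open(path("kinetics_truth.json"), "w") as fh:
        json.dump({"y_max": 0.8, "k": 1.2, "sigma": 0.02}, fh)

    manifest = {
        name: hashlib.sha256(open(p, "rb").read()).hexdigest()
        for name, p in sorted(paths.items())
    }
    with open(os.path.join(out_dir, "checksums.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["checksums.json"] = os.path.join(out_dir, "checksums.json")
    return paths
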