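import json

import numpy as np
import pytest

from pamkit import pam_depletion as pdp
from pamkit import pam_space as ps
from pamkit import synthetic_data as sd


class TestActivityModel:
    def test_activity_is_product_of_factors(self, default_model):
        model = sd.ActivityModel(factors=default_model.factors, extent=0.9)
        for seq in ("TTTAACAC", "AAAAAAAA", "GGGCGCAC", "ACGTACGT"):
            expected = 1.0
            for j, b in enumerate(seq):
                expected *= model.factors[j][b]
            assert model.activity(seq) == pytest.approx(expected)
        table = model.activity_table()
        assert table[ps.rank("TTTAACAC")] == pytest.approx(model.activity("TTTAACAC"))

    def test_default_consensus_and_pair_penalty(self, default_model):
        assert default_model.consensus() == "NNNVRYAC"
        act = default_model.activity_table()
        assert act[ps.rank("TTTAACAC")] == 1.0
        # planted sub-optimal class: position-4 C with position-5 G
        assert default_model.activity("TTTCGCAC") < default_model.activity("TTTCACAC")

    def test_validation(self):
        with pytest.raises(ValueError, match="outside"):
            sd.ActivityModel(factors=[{b: 2.0 for b in "ACGT"}] * 8)
        with pytest.raises(ValueError, match="extent"):
            sd.ActivityModel(factors=[{b: 1.0 for b in "ACGT"}] * 8, extent=1.5)


class TestLibrarySimulation:
    def test_seeded_runs_are_identical(self, default_model):
        cfg = sd.LibrarySimConfig(depth=2000, seed=3)
        a = sd.simulate_library(default_model, cfg)
        b = sd.simulate_library(default_model, cfg)
        assert a.untreated_reads == b.untreated_reads
        assert a.treated_reads == b.treated_reads
        assert a.truth.equals(b.truth)

    def test_truth_counts_are_the_sampling_record(self, small_library):
        # per-read labels aggregate exactly to the truth-table counts
        from collections import Counter

        labels = Counter(t.split("pam=")[1] for t, _s, _q in small_library.treated_reads)
        counts = small_library.true_pam_counts("treated")
        for pam, n in labels.items():
            assert counts[ps.rank(pam)] == n
        assert counts.sum() == len(small_library.treated_reads)

    def test_extent_zero_scores_center_on_zero(self, default_model):
        model = sd.ActivityModel(factors=default_model.factors, extent=0.0,
                                 pair_penalties=default_model.pair_penalties)
        u, t, _ = sd.simulate_library_counts(
            model, sd.LibrarySimConfig(depth=100_000, seed=9))
        scores = pdp.enrichment(t, u).scores
        assert abs(np.mean(scores)) < 0.05
        assert (scores <= -2.0).mean() < 0.01

    def test_single_active_pam_strongly_depleted(self):
        # activity 1 for exactly one PAM via indicator factors; depth chosen so
        # the Poisson tail oracle puts its untreated count far above 4t + 3*alpha
        factors = [{b: (1.0 if b == c else 0.0) for b in "ACGT"} for c in "TTTAACAC"]
        model = sd.ActivityModel(factors=factors, extent=0.99)
        cfg = sd.LibrarySimConfig(depth=1_000_000, abundance_sigma=0.2, seed=1)
        u, t, truth = sd.simulate_library_counts(model, cfg)
        scores = pdp.enrichment(t, u).scores
        r = ps.rank("TTTAACAC")
        assert truth["activity"].sum() == 1.0
        assert scores[r] <= -2.0

    def test_counts_mode_matches_read_mode_distribution(self, default_model):
        cfg = sd.LibrarySimConfig(depth=20_000, error_rate=0.0, seed=7)
        u_counts, t_counts, truth = sd.simulate_library_counts(default_model, cfg)
        lib = sd.simulate_library(default_model, cfg)
        assert np.array_equal(u_counts.counts, lib.true_pam_counts("untreated"))
        assert np.array_equal(t_counts.counts, lib.true_pam_counts("treated"))


class TestAmpliconSimulation:
    def test_zero_truth_zero_error_reads_equal_reference(self, plus_site):
        cfg = sd.AmpliconSimConfig(site=plus_site, indel_frequency=0.0,
                                   error_rate=0.0, depth=50, seed=0)
        sim = sd.simulate_amplicons(cfg)
        assert all(seq == plus_site.reference for _t, seq, _q in sim.edited_reads)
        assert all(seq == plus_site.reference for _t, seq, _q in sim.control_reads)

    def test_realized_fraction_near_truth(self, plus_site):
        cfg = sd.AmpliconSimConfig(site=plus_site, indel_frequency=0.40,
                                   depth=5000, seed=4)
        sim = sd.simulate_amplicons(cfg)
        se = np.sqrt(0.4 * 0.6 / 5000)
        assert abs(sim.true_fraction("has_indel") - 0.40) < 3 * se

    def test_labels_are_the_sampling_record(self, plus_site, ct_position):
        cfg = sd.AmpliconSimConfig(site=plus_site, indel_frequency=0.3,
                                   ct_truth={ct_position: 0.2}, error_rate=0.0,
                                   depth=300, seed=6)
        sim = sd.simulate_amplicons(cfg)
        refpos = plus_site.ref_pos(ct_position)
        edited = sim.truth[sim.truth["sample"] == "edited"].to_dict("records")
        for (_t, seq, _q), row in zip(sim.edited_reads, edited):
            if not row["has_indel"]:
                assert (seq[refpos] == "T") == row[f"ct_at_{ct_position}"]

    def test_seeded_determinism(self, plus_site):
        cfg = sd.AmpliconSimConfig(site=plus_site, indel_frequency=0.2, depth=100, seed=8)
        assert sd.simulate_amplicons(cfg).edited_reads == sd.simulate_amplicons(cfg).edited_reads

    def test_truth_validation(self, plus_site):
        with pytest.raises(ValueError, match="not a protospacer-strand C"):
            sd.AmpliconSimConfig(site=plus_site, ct_truth={-1: 0.2}
                                 if plus_site.base_at(-1) != "C" else {-2: 0.2})
        with pytest.raises(ValueError, match="outside"):
            bad_pos = next(p for p in range(-21, -1) if plus_site.base_at(p) == "C")
            sd.AmpliconSimConfig(site=plus_site, ct_truth={bad_pos: 1.5})


class TestKineticsSimulation:
    def test_sigma_zero_gives_exact_curve(self):
        series = sd.simulate_kinetics(0.8, 1.2, [0.0, 0.5, 1, 2], sigma=0.0,
                                      replicates=1, seed=0)[0]
        from pamkit.cleavage_kinetics import association

        assert series.fractions[0] == 0.0  # t = 0 is exactly zero before noise
        assert np.allclose(series.fractions, association(series.times, 0.8, 1.2))

    def test_residual_spread_matches_sigma(self):
        from pamkit.cleavage_kinetics import association

        series = sd.simulate_kinetics(0.5, 1.0, [1.0, 2.0, 3.0], sigma=0.02,
                                      replicates=200, seed=1)
        resid = np.concatenate([
            s.fractions - association(s.times, 0.5, 1.0) for s in series
        ])
        assert np.std(resid) == pytest.approx(0.02, rel=0.15)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sd.simulate_kinetics(1.5, 1.0, [1, 2, 3])
        with pytest.raises(ValueError):
            sd.simulate_kinetics(0.5, -1.0, [1, 2, 3])


class TestFixtureBundle:
    def test_bundle_is_deterministic_and_complete(self, tmp_path):
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        p1 = sd.fixture_bundle(d1, seed=0)
        p2 = sd.fixture_bundle(d2, seed=0)
        m1 = json.load(open(p1["checksums.json"]))
        m2 = json.load(open(p2["checksums.json"]))
        assert m1 == m2
        for name in ("library_untreated.fastq", "refs.fa", "sites.tsv",
                     "samples.tsv", "kinetics.tsv"):
            assert name in m1

    def test_bundle_runs_through_all_pipelines(self, tmp_path):
        from pamkit import amplicon_editing as ae
        from pamkit import cleavage_kinetics as ck

        paths = sd.fixture_bundle(tmp_path / "bundle", seed=0)
        # depletion
        result = pdp.run_profile(paths["library_treated.fastq"],
                                 paths["library_untreated.fastq"],
                                 sd.DEFAULT_ANCHOR)
        assert result["untreated"].reads_used > 19_000
        # editing, both strands
        sites = ae.load_sites(paths["sites.tsv"], paths["refs.fa"])
        for site_id, site in sites.items():
            edited = ae.align_sample(paths[f"{site_id}_edited.fastq"], site)
            control = ae.align_sample(paths[f"{site_id}_control.fastq"], site)
            summary = ae.summarize_site(edited, control, site)
            assert abs(summary.indel_frequency_corrected - 0.40) < 0.05
            assert 0.1 < summary.site_ct_corrected < 0.3
        # kinetics
        fit = ck.fit_association(ck.read_table(paths["kinetics.tsv"]))
        assert fit.converged and abs(fit.k - 1.2) / 1.2 < 0.4
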