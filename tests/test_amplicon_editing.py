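import numpy as np
import pytest

from pamkit import amplicon_editing as ae
from pamkit import synthetic_data as sd


def rec(seq, qual=None, title="r"):
    return (title, seq, qual or "?" * len(seq))


class TestSiteGeometry:
    def test_position_mapping_plus(self, plus_site):
        s, e = plus_site.protospacer_interval
        assert plus_site.ref_pos(-1) == e - 1
        assert plus_site.ref_pos(-22) == s
        assert plus_site.ref_pos(1) == e
        assert plus_site.ref_pos(8) == e + 7
        assert plus_site.base_at(-1) == plus_site.protospacer[-1]
        assert plus_site.base_at(1) == plus_site.pam[0]

    def test_position_mapping_minus(self, minus_site):
        assert minus_site.base_at(-1) == minus_site.protospacer[-1]
        assert minus_site.base_at(-22) == minus_site.protospacer[0]
        assert "".join(minus_site.base_at(p) for p in range(1, 9)) == minus_site.pam

    def test_site_validation(self, plus_site):
        with pytest.raises(ValueError):
            ae.AmpliconSite("bad", plus_site.reference, plus_site.protospacer,
                            plus_site.pam, "+", (0, 22))

    def test_window_validation(self):
        assert list(ae.EditingWindow(-21, -8).positions()) == list(range(-21, -7))
        assert ae.EditingWindow.parse("-21:-8") == ae.EditingWindow(-21, -8)
        with pytest.raises(ValueError):
            ae.EditingWindow(-8, -21)
        with pytest.raises(ValueError):
            ae.EditingWindow(-30, -8)


class TestDemultiplex:
    def make_samples(self):
        return [
            ae.SampleRecord("s1", "ACGTACGT", "GGATCCAGTTACGGAT", "", "siteA", "edited"),
            ae.SampleRecord("s1c", "ACGTACGT", "CTTGACCAGTAAGGCT", "", "siteA", "control"),
            ae.SampleRecord("s2", "TGCATGCA", "GGATCCAGTTACGGAT", "", "siteA", "edited"),
        ]

    def test_exact_assignment(self):
        samples = self.make_samples()
        reads = [rec("ACGTACGT" + "GGATCCAGTTACGGAT" + "AAAA", title="x")]
        assigned, unassigned = ae.demultiplex(reads, samples)
        assert len(assigned["s1"]) == 1 and unassigned == 0

    def test_one_primer_mismatch_tolerated(self):
        samples = self.make_samples()
        reads = [rec("ACGTACGT" + "GGATCCAGTTACGGAA" + "AAAA")]
        assigned, unassigned = ae.demultiplex(reads, samples, max_mismatch=1)
        assert len(assigned["s1"]) == 1

    def test_index_must_be_exact(self):
        samples = self.make_samples()
        reads = [rec("ACGTACGA" + "GGATCCAGTTACGGAT" + "AAAA")]
        assigned, unassigned = ae.demultiplex(reads, samples)
        assert unassigned == 1

    def test_ambiguous_read_unassigned(self):
        samples = [
            ae.SampleRecord("a", "ACGTACGT", "GGATCCAGTTACGGAT", "", "s", "edited"),
            ae.SampleRecord("b", "ACGTACGT", "TTACGGATGGATCCAG", "", "s", "control"),
        ]
        # read whose primer region is 1 mismatch from both primers cannot exist
        # here (distance 12), so craft equal distance via max_mismatch bump
        reads = [rec("ACGTACGT" + "GGATCCAGTTACGGAT" + "AA")]
        assigned, unassigned = ae.demultiplex(reads, samples)
        assert len(assigned["a"]) == 1
        # identical primers would collide at load time instead
        with pytest.raises(ValueError, match="distinguishable"):
            ae.demultiplex(reads, [
                ae.SampleRecord("a", "ACGTACGT", "GGATCCAGTTACGGAT", "", "s", "edited"),
                ae.SampleRecord("b", "ACGTACGT", "GGATCCAGTTACGGAA", "", "s", "control"),
            ])

    def test_multiplexed_pool_recovers_simulator_labels(self, plus_site, minus_site):
        samples = [
            ae.SampleRecord("sampA", "ACGTACGT", plus_site.reference[:16], "", "p", "edited"),
            ae.SampleRecord("sampB", "TGCATGCA", minus_site.reference[:16], "", "m", "edited"),
        ]
        per_sample = {
            "sampA": [rec(plus_site.reference, title=f"a{i}") for i in range(20)],
            "sampB": [rec(minus_site.reference, title=f"b{i}") for i in range(20)],
        }
        pool = sd.multiplex_reads(per_sample, samples)
        assigned, unassigned = ae.demultiplex(pool, samples)
        assert unassigned == 0
        for sample_id, records in assigned.items():
            for title, _seq, _q in records:
                assert title.endswith(f"sample={sample_id}")


class TestMergePairs:
    def test_perfect_overlap_reconstructs_amplicon(self, plus_site):
        amp = plus_site.reference
        r1 = rec(amp[:70])
        r2 = rec(sd.reverse_complement(amp[40:]))
        merged = ae.merge_pairs(r1, r2, min_overlap=10)
        assert merged is not None and merged[1] == amp

    def test_non_overlapping_pair_is_null(self):
        assert ae.merge_pairs(rec("ACGTACGTACGTACG"), rec("TTTTGGGGCCCCAAA"),
                              min_overlap=10) is None

    def test_disagreement_resolved_by_quality(self, plus_site):
        amp = plus_site.reference
        s1 = amp[:70]
        s1 = s1[:60] + ("A" if s1[60] != "A" else "C") + s1[61:]
        r1_high = (("r1", s1, "I" * 70))
        r2 = ("r2", sd.reverse_complement(amp[40:]), "#" * len(amp[40:]))
        merged = ae.merge_pairs(r1_high, r2, min_overlap=10)
        assert merged[1][60] == s1[60]  # R1 base kept (higher quality)
        r1_low = (("r1", s1, "#" * 70))
        r2_high = ("r2", sd.reverse_complement(amp[40:]), "I" * len(amp[40:]))
        merged = ae.merge_pairs(r1_low, r2_high, min_overlap=10)
        assert merged[1] == amp  # R2 base corrects the error


class TestBlocklistAndFiltering:
    def test_blocklist_counts_directly(self, plus_site):
        ref = plus_site.reference
        sub_read = ref[:10] + ("A" if ref[10] != "A" else "G") + ref[11:]
        alns = [ae.align_read(ref, plus_site, read_id=f"c{i}") for i in range(98)]
        alns += [ae.align_read(sub_read, plus_site, read_id=f"m{i}") for i in range(2)]
        bl = ae.build_blocklist(alns, threshold=0.01)
        assert len(bl) == 1
        (key, freq), = bl.frequencies.items()
        assert key.kind == "sub" and key.pos == 10 and freq == pytest.approx(0.02)

    def test_clean_controls_give_empty_blocklist(self, plus_site):
        alns = [ae.align_read(plus_site.reference, plus_site) for _ in range(50)]
        assert len(ae.build_blocklist(alns)) == 0
        assert len(ae.build_blocklist(alns, threshold=1.0)) == 0

    def test_zero_control_reads_rejected(self):
        with pytest.raises(ValueError, match="zero aligned control"):
            ae.build_blocklist([])

    def test_filter_removes_only_blocklisted(self, plus_site):
        ref = plus_site.reference
        key = ae.MutationKey("sub", 10, "A" if ref[10] != "A" else "G")
        bl = ae.ControlBlocklist("s", {key: 0.02})
        carrier = ae.align_read(ref[:10] + key.payload + ref[11:], plus_site)
        clean = ae.align_read(ref, plus_site)
        retained, removed = ae.filter_reads([carrier, clean, clean], bl)
        assert removed == 1 and len(retained) == 2
        retained, removed = ae.filter_reads([carrier, clean], ae.ControlBlocklist("s", {}))
        assert removed == 0

    def test_enlarging_blocklist_never_retains_more(self, amplicon_run):
        alns = amplicon_run["edited"]
        bl_small = ae.build_blocklist(amplicon_run["control"], threshold=0.01)
        bl_big = ae.ControlBlocklist("s", dict(bl_small.frequencies))
        extra = ae.MutationKey("sub", 3, "T")
        bl_big.frequencies[extra] = 0.5
        kept_small, _ = ae.filter_reads(alns, bl_small)
        kept_big, _ = ae.filter_reads(alns, bl_big)
        assert len(kept_big) <= len(kept_small)


class TestQuantification:
    def test_event_free_reads_zero_indel(self, plus_site):
        alns = [ae.align_read(plus_site.reference, plus_site) for _ in range(10)]
        assert ae.indel_frequency(alns, plus_site) == 0.0

    def test_indel_frequency_direct_count(self, plus_site):
        ref = plus_site.reference
        cut = plus_site.ref_pos(-3)
        del_read = ref[:cut] + ref[cut + 2:]
        alns = [ae.align_read(ref, plus_site) for _ in range(90)]
        alns += [ae.align_read(del_read, plus_site) for _ in range(10)]
        assert ae.indel_frequency(alns, plus_site) == pytest.approx(0.10)

    def test_out_of_window_deletion_not_counted(self, plus_site):
        ref = plus_site.reference
        del_read = ref[:2] + ref[4:]  # far upstream of the protospacer
        alns = [ae.align_read(del_read, plus_site)]
        assert ae.indel_frequency(alns, plus_site) == 0.0

    def test_zero_retained_rejected(self, plus_site):
        with pytest.raises(ValueError, match="zero retained"):
            ae.indel_frequency([], plus_site)

    def test_ct_profile_positions_and_definition(self, plus_site, ct_position):
        ref = plus_site.reference
        refpos = plus_site.ref_pos(ct_position)
        ct_read = ref[:refpos] + "T" + ref[refpos + 1:]
        cg_read = ref[:refpos] + "G" + ref[refpos + 1:]
        alns = [ae.align_read(r, plus_site) for r in [ref] * 6 + [ct_read] * 3 + [cg_read]]
        prof = ae.ct_profile(alns, plus_site)
        assert set(prof) == {p for p in range(-22, 0) if plus_site.base_at(p) == "C"}
        assert prof[ct_position] == pytest.approx(0.3)  # C-to-G does not count
        clean = ae.ct_profile([ae.align_read(ref, plus_site)], plus_site)
        assert all(v == 0.0 for v in clean.values())

    def test_substitution_matrix_reports_cg(self, plus_site, ct_position):
        ref = plus_site.reference
        refpos = plus_site.ref_pos(ct_position)
        cg_read = ref[:refpos] + "G" + ref[refpos + 1:]
        alns = [ae.align_read(r, plus_site) for r in [ref, cg_read]]
        mat = ae.substitution_matrix(alns, plus_site)
        row = mat[mat["position"] == ct_position].iloc[0]
        assert row["G"] == pytest.approx(0.5) and row["ref_base"] == "C"


class TestSummarize:
    def test_self_control_identity(self, amplicon_run):
        alns = amplicon_run["edited"]
        summary = ae.summarize_site(alns, alns, amplicon_run["site"])
        assert summary.indel_frequency_corrected == 0.0
        assert summary.site_ct_corrected == 0.0
        assert all(v == 0.0 for v in summary.ct_corrected.values())

    def test_corrected_arithmetic(self, plus_site):
        ref = plus_site.reference
        cut = plus_site.ref_pos(-3)
        del_read = ref[:cut] + ref[cut + 2:]
        edited = [ae.align_read(r, plus_site) for r in [del_read] * 10 + [ref] * 90]
        control = [ae.align_read(r, plus_site) for r in [del_read] * 1 + [ref] * 99]
        summary = ae.summarize_site(edited, control, plus_site)
        assert summary.indel_frequency_raw == pytest.approx(0.10)
        assert summary.indel_frequency_corrected == pytest.approx(0.09)

    def test_recovers_simulated_truth(self, amplicon_run):
        sim = amplicon_run["sim"]
        p = amplicon_run["ct_position"]
        summary = ae.summarize_site(amplicon_run["edited"], amplicon_run["control"],
                                    amplicon_run["site"])
        true_indel = sim.true_fraction("has_indel")
        true_ct = sim.true_fraction(f"ct_at_{p}")
        n = sim.config.depth
        assert abs(summary.indel_frequency_corrected - true_indel) < 3 * np.sqrt(0.4 * 0.6 / n)
        assert abs(summary.ct_corrected[p] - true_ct) < 3 * np.sqrt(0.2 * 0.8 / n)
        # the planted 2% artifact must be blocklisted and removed
        bl = ae.build_blocklist(amplicon_run["control"])
        assert amplicon_run["artifact"] in bl
        assert summary.n_removed_edited > 0

    def test_strand_symmetric_summaries(self, plus_site, minus_site, ct_position):
        results = {}
        for site in (plus_site, minus_site):
            cfg = sd.AmpliconSimConfig(site=site, indel_frequency=0.3,
                                       ct_truth={ct_position: 0.25}, error_rate=0.0,
                                       depth=800, seed=42)
            sim = sd.simulate_amplicons(cfg)
            summary = ae.summarize_site(
                ae.align_sample(sim.edited_reads, site),
                ae.align_sample(sim.control_reads, site), site)
            results[site.strand] = summary
        # identical seed and protospacer-frame truth: summaries agree after
        # numbering translation (same positions, same statistics)
        assert results["+"].indel_frequency_corrected == pytest.approx(
            results["-"].indel_frequency_corrected)
        assert results["+"].ct_corrected[ct_position] == pytest.approx(
            results["-"].ct_corrected[ct_position])
        assert set(results["+"].ct_corrected) == set(results["-"].ct_corrected)


class TestTableIO:
    def test_site_and_sample_loading(self, tmp_path, plus_site):
        refs = tmp_path / "refs.fa"
        refs.write_text(f">ref1\n{plus_site.reference}\n")
        sites = tmp_path / "sites.tsv"
        sites.write_text(
            "site_id\tprotospacer\tpam\tstrand\treference_id\n"
            f"s1\t{plus_site.protospacer}\t{plus_site.pam}\t+\tref1\n"
        )
        loaded = ae.load_sites(sites, refs)
        assert loaded["s1"].protospacer_interval == plus_site.protospacer_interval
        samples = tmp_path / "samples.tsv"
        samples.write_text(
            "sample_id\tindex_seq\tfwd_primer\trev_primer\tsite_id\trole\n"
            "e1\tACGTACGT\tGGATCCAGTTACGGAT\t\ts1\tedited\n"
        )
        with pytest.raises(ValueError, match="no same-site control"):
            ae.load_samples(samples)
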