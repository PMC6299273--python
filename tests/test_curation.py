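"""Annotation curation rules and gene geometry."""

import pytest

from mitoarch.curation import (
    check_pcg_overlap_legality,
    compute_gene_geometry,
    curate_record,
    deduplicate_candidates,
    geometry_summary,
    resolve_stop_codon,
    select_start_codon,
)
from mitoarch.genome import FeatureKind, GeneFeature, GenomeRecord
from mitoarch.synthetic import SyntheticGenomeConfig, make_annotated_genome


def toy_record(seq, feats, circular=True):
    return GenomeRecord(id="toy", sequence=seq, circular=circular, features=feats)


class TestGeometry:
    def test_reference_annotation_gaps(self, reference_record):
        reports = compute_gene_geometry(reference_record)
        gaps = {(r.upstream, r.downstream): r.gap for r in reports}
        assert gaps[("nad4l", "nad4")] == -7
        assert gaps[("trnE(ttc)", "rrnS")] == 78
        assert gaps[("rrnL", "trnL2(taa)")] == -36

    def test_reference_annotation_summary(self, reference_record):
        s = geometry_summary(compute_gene_geometry(reference_record))
        assert s["n_spacers"] == 23
        assert s["total_spacer_bp"] == 250
        assert s["n_overlaps"] == 5
        assert s["max_overlap"] == 36

    def test_abutting_features_gap_zero(self):
        rec = toy_record(
            "A" * 30,
            [
                GeneFeature("x", FeatureKind.TRNA, "+", 1, 10),
                GeneFeature("y", FeatureKind.TRNA, "+", 11, 20),
            ],
        )
        reports = compute_gene_geometry(rec)
        assert reports[0].gap == 0
        # wrap-around junction y -> x spans positions 21..30
        assert reports[1].gap == 10

    @pytest.mark.parametrize("seed", range(5))
    def test_gap_length_conservation(self, seed):
        """Sum of gaps plus sum of feature lengths equals genome length."""
        rec = make_annotated_genome(SyntheticGenomeConfig(seed=seed)).truth
        reports = compute_gene_geometry(rec)
        assert len(reports) == len(rec.features)
        total = sum(r.gap for r in reports) + sum(
            f.length(len(rec.sequence)) for f in rec.features
        )
        assert total == len(rec.sequence)

    def test_reference_conservation(self, reference_record):
        reports = compute_gene_geometry(reference_record)
        total = sum(r.gap for r in reports) + sum(
            f.length(len(reference_record.sequence))
            for f in reference_record.features
        )
        assert total == len(reference_record.sequence)


class TestStartSelection:
    def build(self, spacer_codons, head_codons="GCA"):
        """Upstream tRNA, spacer, then a PCG; returns (record, pcg)."""
        upstream = "G" * 12
        cds = "ATG" + "GCTCAT" * 20 + "TAA"
        seq = upstream + spacer_codons + cds + "CC"
        pcg_start = len(upstream) + len(spacer_codons) + 1
        rec = toy_record(
            seq,
            [
                GeneFeature("trnX", FeatureKind.TRNA, "+", 1, 12),
                GeneFeature(
                    "pcg", FeatureKind.PCG, "+", pcg_start,
                    pcg_start + len(cds) - 1, "ATG", "TAA",
                ),
            ],
        )
        return rec, rec.features[1]

    def test_correct_start_is_fixed_point(self):
        rec, pcg = self.build("CCCGGG")
        new, diff, failed = select_start_codon(rec, pcg)
        assert not failed and diff is None and new == pcg

    def test_nearest_eligible_candidate_chosen(self):
        # annotated start sits 12 nt into the true ORF; the true ATG is the
        # first eligible candidate when scanning from the upstream gene
        rec, pcg = self.build("CCCGGG")
        from dataclasses import replace

        shifted = replace(pcg, start=pcg.start + 12, start_codon=None)
        rec.replace_feature(pcg, shifted)
        new, diff, failed = select_start_codon(rec, shifted)
        assert not failed
        assert new.start == pcg.start
        assert new.start_codon == "ATG"
        assert diff.rule == 1

    def test_overlapping_candidate_skipped(self):
        # an ATG exists upstream inside the tRNA; it must not be chosen
        rec, pcg = self.build("CCCGGG")
        seq = rec.sequence
        # plant an in-frame ATG 3 nt before the spacer (inside trnX)
        pos = pcg.start - 9 - 1
        rec2 = toy_record(
            seq[:pos] + "ATG" + seq[pos + 3 :],
            [f for f in rec.features],
        )
        new, diff, failed = select_start_codon(rec2, rec2.features[1])
        assert not failed and new.start == pcg.start

    def test_non_atg_start_reachable(self):
        # gene genuinely starts with ATT (as atp6 does): accepted unchanged
        upstream = "G" * 9
        cds = "ATT" + "GCTCAT" * 15 + "TAA"
        seq = upstream + "CCC" + cds
        rec = toy_record(
            seq,
            [
                GeneFeature("trnX", FeatureKind.TRNA, "+", 1, 9),
                GeneFeature("atp6", FeatureKind.PCG, "+", 13, len(seq), None, None),
            ],
        )
        new, diff, failed = select_start_codon(rec, rec.features[1])
        assert not failed
        assert new.start == 13
        assert new.start_codon == "ATT"

    def test_no_eligible_start_flags_unresolved(self):
        upstream = "G" * 9
        cds = "CCC" + "GCTCAT" * 10 + "TAA"  # no start codon anywhere
        seq = upstream + "CCC" + cds
        rec = toy_record(
            seq,
            [
                GeneFeature("trnX", FeatureKind.TRNA, "+", 1, 9),
                GeneFeature("pcg", FeatureKind.PCG, "+", 13, len(seq), None, None),
            ],
        )
        gene, diff, failed = select_start_codon(rec, rec.features[1])
        assert failed and diff is None and gene == rec.features[1]


class TestStopResolution:
    def test_first_full_stop_wins(self):
        # TAG at codon 5, TAA at codon 8: scanning stops at codon 5
        cds = "ATG" + "GCT" * 4 + "TAG" + "GCT" * 2 + "TAA"
        seq = "G" * 6 + cds + "CC" + "A" * 10
        rec = toy_record(
            seq,
            [
                GeneFeature("trnX", FeatureKind.TRNA, "+", 1, 6),
                GeneFeature(
                    "pcg", FeatureKind.PCG, "+", 7, 6 + len(cds), "ATG", None
                ),
                GeneFeature(
                    "trnY", FeatureKind.TRNA, "+", len(seq) - 9, len(seq)
                ),
            ],
        )
        new, diff, failed = resolve_stop_codon(rec, rec.features[1])
        assert not failed
        assert new.stop_codon == "TAG"
        assert new.end == 6 + 15 + 3  # start + 5 codons

    def test_abbreviated_stop_at_trna_boundary(self):
        # no in-frame stop before the tRNA; a single T remains -> T--
        cds_body = "ATG" + "GCT" * 5 + "T"
        seq = "G" * 6 + cds_body + "A" * 12
        rec = toy_record(
            seq,
            [
                GeneFeature("trnX", FeatureKind.TRNA, "+", 1, 6),
                GeneFeature(
                    "pcg", FeatureKind.PCG, "+", 7, 6 + len(cds_body) - 1,
                    "ATG", None,
                ),
                GeneFeature(
                    "trnY", FeatureKind.TRNA, "+", 6 + len(cds_body) + 1,
                    len(seq),
                ),
            ],
        )
        new, diff, failed = resolve_stop_codon(rec, rec.features[1])
        assert not failed
        assert new.stop_codon == "T--"
        assert new.end == 6 + len(cds_body)


class TestOverlapLegality:
    def make_overlap(self, offset_mod3):
        """Two plus-strand PCGs overlapping; frame congruence controlled."""
        a_cds = "ATG" + "GCT" * 8 + "TAA"  # 30 nt, 1..30
        # b overlaps a's tail; b.start = 25 shares a's frame (25 = 1 mod 3)
        b_start = 25 + offset_mod3
        seq = a_cds + "GCTCAT" * 10 + "TAA" + "CCC"
        return toy_record(
            seq,
            [
                GeneFeature("a", FeatureKind.PCG, "+", 1, 30),
                GeneFeature("b", FeatureKind.PCG, "+", b_start, len(seq) - 3),
            ],
        )

    def test_same_frame_overlap_is_violation(self):
        rec = self.make_overlap(offset_mod3=0)  # starts congruent mod 3
        assert (rec.features[1].start - rec.features[0].start) % 3 == 0
        assert len(check_pcg_overlap_legality(rec)) == 1

    def test_different_frame_overlap_legal(self):
        rec = self.make_overlap(offset_mod3=1)
        assert len(check_pcg_overlap_legality(rec)) == 0

    def test_opposite_strand_overlap_legal(self):
        rec = toy_record(
            "A" * 60,
            [
                GeneFeature("a", FeatureKind.PCG, "+", 1, 30),
                GeneFeature("b", FeatureKind.PCG, "-", 25, 54),
            ],
        )
        assert check_pcg_overlap_legality(rec) == []

    def test_seven_nt_overlap_like_nad4l_nad4_is_legal(self):
        # a 7-nt overlap forces different frames (7 mod 3 != 0)
        rec = toy_record(
            "A" * 90,
            [
                GeneFeature("nad4l", FeatureKind.PCG, "+", 1, 30),
                GeneFeature("nad4", FeatureKind.PCG, "+", 24, 80),
            ],
        )
        assert (30 - 24 + 1) == 7
        assert check_pcg_overlap_legality(rec) == []


class TestDeduplication:
    def feat(self, name, start, quality):
        return GeneFeature(name, FeatureKind.TRNA, "+", start, start + 60,
                           quality=quality)

    def test_highest_quality_kept(self):
        kept, diffs, warnings = deduplicate_candidates(
            [self.feat("trnL2", 10, 0.93), self.feat("trnL2", 200, 0.41)]
        )
        assert [f.quality for f in kept] == [0.93]
        assert len(diffs) == 1 and diffs[0].rule == 4
        assert not warnings

    def test_quality_tie_keeps_earliest_with_warning(self):
        kept, diffs, warnings = deduplicate_candidates(
            [
                self.feat("t", 300, 0.5),
                self.feat("t", 10, 0.5),
                self.feat("t", 100, 0.2),
            ]
        )
        assert len(kept) == 1 and kept[0].start == 10
        assert len(diffs) == 2
        assert len(warnings) == 1

    def test_no_duplicates_is_identity(self):
        feats = [self.feat("a", 10, 0.9), self.feat("b", 100, 0.8)]
        kept, diffs, warnings = deduplicate_candidates(feats)
        assert kept == feats and not diffs and not warnings


class TestCurateRecord:
    def test_clean_record_zero_diffs(self):
        sg = make_annotated_genome(SyntheticGenomeConfig(seed=5))
        res = curate_record(sg.corrupted)
        assert res.diffs == [] and res.unresolved == []

    @pytest.mark.parametrize("seed", range(12))
    def test_corrupted_record_recovers_ground_truth(self, seed):
        sg = make_annotated_genome(
            SyntheticGenomeConfig(
                seed=seed, p_start_shift=0.7, p_stop_shift=0.5, p_duplicate=0.4
            )
        )
        res = curate_record(sg.corrupted)
        assert res.record.features == sg.truth.features
        assert not res.unresolved

    def test_idempotence(self):
        sg = make_annotated_genome(
            SyntheticGenomeConfig(seed=8, p_start_shift=0.8, p_stop_shift=0.6)
        )
        first = curate_record(sg.corrupted)
        second = curate_record(first.record)
        assert second.diffs == []

    def test_duplicate_plus_stop_shift_yields_rules_4_and_3(self):
        sg = make_annotated_genome(
            SyntheticGenomeConfig(seed=13, p_stop_shift=1.0, p_duplicate=1.0)
        )
        res = curate_record(sg.corrupted)
        rules = {d.rule for d in res.diffs}
        assert rules == {3, 4}

    def test_pcgs_never_dropped(self):
        sg = make_annotated_genome(
            SyntheticGenomeConfig(seed=3, p_start_shift=1.0, p_stop_shift=1.0)
        )
        res = curate_record(sg.corrupted)
        truth_pcgs = {f.name for f in sg.truth.pcgs()}
        assert {f.name for f in res.record.pcgs()} == truth_pcgs

    def test_reference_report_lists_length_deltas(self):
        sg = make_annotated_genome(SyntheticGenomeConfig(seed=2))
        ref = make_annotated_genome(SyntheticGenomeConfig(seed=4)).truth
        res = curate_record(sg.corrupted, [ref])
        assert set(res.reference_report) == {f.name for f in sg.truth.pcgs()}
        for row in res.reference_report.values():
            assert row["delta"] == row["length"] - row["reference_mean_length"]
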