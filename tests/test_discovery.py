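"""Discovery-stage rules: segmentation, rescue, support, merging, boundary
refinement, classification and repeat flagging."""

import numpy as np
import pandas as pd
import pytest

from srna_seeker import discovery, synthdata
from srna_seeker.core import AnnotationRecord, CoverageTrack, SrnaInterval


def track(depths, replicon="chr"):
    return CoverageTrack(replicon, np.asarray(depths, dtype=float), normalized=True)


class TestSegmentation:
    def test_single_run_above_threshold(self):
        d = np.zeros(300)
        d[100:160] = 60.0  # positions 101..160
        assert discovery.segment_high_expression(track(d)) == [(101, 160)]

    def test_short_runs_are_still_emitted_here(self):
        d = np.zeros(300)
        d[100:140] = 60.0  # a 40 nt run: length filtering happens later
        assert discovery.segment_high_expression(track(d)) == [(101, 140)]

    def test_all_below_threshold_is_empty(self):
        assert discovery.segment_high_expression(track(np.full(100, 50.0))) == []

    def test_threshold_is_strict(self):
        d = np.full(100, 50.0)
        d[10:20] = 50.0001
        assert discovery.segment_high_expression(track(d)) == [(11, 20)]


class TestRescue:
    def make(self, inside, left, right):
        d = np.zeros(400)
        d[100:150] = left
        d[150:250] = inside
        d[250:300] = right
        return track(d)

    def test_clear_drop_on_both_flanks_retained(self):
        t = self.make(20.0, 2.0, 2.0)
        assert discovery.rescue_low_expression(t, [(151, 250)], flank=50, ratio=2.0) == [(151, 250)]

    def test_one_high_flank_rejected(self):
        t = self.make(20.0, 2.0, 15.0)
        assert discovery.rescue_low_expression(t, [(151, 250)], flank=50, ratio=2.0) == []

    def test_zero_inside_rejected(self):
        t = self.make(0.0, 0.0, 0.0)
        assert discovery.rescue_low_expression(t, [(151, 250)]) == []

    def test_out_of_bounds_reference_rejected(self):
        with pytest.raises(ValueError):
            discovery.rescue_low_expression(track(np.zeros(100)), [(50, 200)])


class TestSupport:
    def detections(self, samples_with_hit, interval=(101, 200), n_samples=18):
        per_sample = {}
        for i in range(n_samples):
            hits = [interval] if i in samples_with_hit else []
            per_sample[f"s{i}"] = {"chr": hits}
        return per_sample

    def test_three_of_eighteen_retained_with_support_three(self):
        out = discovery.retain_by_support(self.detections({0, 5, 9}), min_support=3)
        assert out["chr"] == [(101, 200, 3)]

    def test_two_samples_dropped(self):
        out = discovery.retain_by_support(self.detections({0, 5}), min_support=3)
        assert out["chr"] == []

    def test_full_support_counts_all_samples(self):
        out = discovery.retain_by_support(self.detections(set(range(18))), min_support=3)
        assert out["chr"] == [(101, 200, 18)]

    def test_consensus_is_positionwise_median(self):
        per_sample = {
            "a": {"chr": [(100, 200)]},
            "b": {"chr": [(104, 204)]},
            "c": {"chr": [(110, 210)]},
        }
        out = discovery.retain_by_support(per_sample, min_support=3)
        assert out["chr"] == [(104, 204, 3)]

    def test_poorly_overlapping_sample_does_not_count(self):
        # the fourth sample's interval touches the cluster but shares <50%
        per_sample = {
            "a": {"chr": [(100, 200)]},
            "b": {"chr": [(100, 200)]},
            "c": {"chr": [(180, 400)]},
        }
        out = discovery.retain_by_support(per_sample, min_support=3)
        assert out["chr"] == []  # only 2 samples overlap the consensus well

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            discovery.retain_by_support({})


class TestMerge:
    def test_small_gap_and_correlated_trend_merged(self):
        cands = [(100, 200, 5), (231, 300, 4)]  # gap 30
        v = np.arange(18, dtype=float)
        expr = {(100, 200): v, (231, 300): 2 * v + 1}
        out = discovery.merge_adjacent(cands, expr, merge_gap=50)
        assert out == [(100, 300, 5)]

    def test_gap_at_or_above_threshold_not_merged(self):
        cands = [(100, 200, 5), (261, 300, 4)]  # gap 60
        v = np.arange(18, dtype=float)
        expr = {(100, 200): v, (261, 300): v}
        assert discovery.merge_adjacent(cands, expr, merge_gap=50) == cands

    def test_anticorrelated_trend_not_merged(self):
        cands = [(100, 200, 5), (231, 300, 4)]
        v = np.arange(18, dtype=float)
        expr = {(100, 200): v, (231, 300): -v}
        assert discovery.merge_adjacent(cands, expr, merge_gap=50) == cands

    def test_chain_merges_to_fixpoint(self):
        v = np.arange(18, dtype=float)
        cands = [(100, 200, 3), (231, 300, 4), (331, 400, 5)]
        expr = {c[:2]: v for c in cands}
        assert discovery.merge_adjacent(cands, expr, merge_gap=50) == [(100, 400, 5)]


class TestRefineBoundaries:
    def test_sharp_cliff_found(self):
        d = np.zeros(400)
        d[99:220] = 100.0  # true feature 100..220
        t = track(d)
        assert discovery.refine_boundaries((105, 212), t, window=20) == (100, 220)

    def test_rectangular_signal_unchanged(self):
        d = np.zeros(400)
        d[99:220] = 100.0
        t = track(d)
        assert discovery.refine_boundaries((100, 220), t, window=20) == (100, 220)

    def test_flat_plateau_tie_keeps_original(self):
        t = track(np.full(400, 70.0))
        assert discovery.refine_boundaries((100, 220), t, window=20) == (100, 220)


class TestClassification:
    ann = [
        AnnotationRecord("geneA", "chr", 1000, 2000, "+", "CDS"),
        AnnotationRecord("geneB", "chr", 5000, 6000, "-", "CDS"),
    ]

    def test_inside_gene_body_is_asrna(self):
        assert discovery.classify_by_location(("chr", 1200, 1300), self.ann) == "asRNA"

    def test_within_upstream_window_is_utr(self):
        # 80 nt upstream of geneA's start, not overlapping any gene
        assert discovery.classify_by_location(("chr", 920, 990), self.ann) == "UTR"

    def test_minus_strand_upstream_window_placed_after_gene_end(self):
        assert discovery.classify_by_location(("chr", 6010, 6080), self.ann) == "UTR"

    def test_far_from_all_genes_is_ncrna(self):
        assert discovery.classify_by_location(("chr", 3000, 3100), self.ann) == "ncRNA"

    def test_gene_body_overlap_takes_precedence_over_window(self):
        # straddles geneA's start: both window and body overlap -> asRNA
        assert discovery.classify_by_location(("chr", 950, 1050), self.ann) == "asRNA"

    def test_classifier_is_order_independent(self):
        got = discovery.classify_by_location(("chr", 920, 990), list(reversed(self.ann)))
        assert got == "UTR"


class TestRepeatFlagging:
    def _genome_with_duplicate(self, identity=1.0, seed=31):
        g = synthdata.make_genome({"chr": 20_000}, seed=seed)
        seq = list(g.sequence("chr"))
        block = seq[1000:1080]  # the candidate's 80 bp sequence
        copy = list(block)
        if identity < 1.0:
            flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
            step = max(1, int(round(1 / (1 - identity))))
            for i in range(0, len(copy), step):
                copy[i] = flip[copy[i]]
        seq[10_000:10_080] = copy
        from srna_seeker.core import GenomeModel
        return GenomeModel((("chr", "".join(seq)),))

    def test_verbatim_duplicate_flagged(self):
        g = self._genome_with_duplicate(1.0)
        cand = SrnaInterval("nc1", "chr", 1001, 1080)
        (out,) = discovery.flag_repeats([cand], g)
        assert out.repeat_flag

    def test_unique_sequence_not_flagged(self):
        g = synthdata.make_genome({"chr": 20_000}, seed=32)
        cand = SrnaInterval("nc1", "chr", 1001, 1080)
        (out,) = discovery.flag_repeats([cand], g)
        assert not out.repeat_flag

    def test_seventy_percent_identity_not_flagged(self):
        g = self._genome_with_duplicate(0.7)
        cand = SrnaInterval("nc1", "chr", 1001, 1080)
        (out,) = discovery.flag_repeats([cand], g)
        assert not out.repeat_flag


class TestExternalAnnotations:
    def candidates(self):
        return [SrnaInterval("nc1", "chr", 100, 200), SrnaInterval("nc2", "chr", 400, 500)]

    def test_nr_hit_below_cutoff_attached(self):
        tables = {"nr": pd.DataFrame({"id": ["nc1"], "value": ["hypothetical"],
                                      "evalue": [1e-12]})}
        out = discovery.ingest_external_annotations(self.candidates(), tables)
        assert out[0].annotations["nr"] == "hypothetical"

    def test_nr_hit_above_cutoff_ignored(self):
        tables = {"nr": pd.DataFrame({"id": ["nc1"], "value": ["x"], "evalue": [1e-8]})}
        out = discovery.ingest_external_annotations(self.candidates(), tables)
        assert "nr" not in out[0].annotations

    def test_unknown_id_warns_and_skips(self, caplog):
        tables = {"rfam": pd.DataFrame({"id": ["ghost"], "value": ["RF00001"]})}
        out = discovery.ingest_external_annotations(self.candidates(), tables)
        assert all(not c.annotations for c in out)

    def test_empty_tables_leave_candidates_unchanged(self):
        out = discovery.ingest_external_annotations(self.candidates(), {})
        assert all(not c.annotations for c in out)

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            discovery.ingest_external_annotations(
                self.candidates(), {"orf": pd.DataFrame({"wrong": [1]})}
            )


class TestEndToEndCalling:
    def test_retained_intervals_satisfy_length_and_support(self, called_srnas):
        assert called_srnas, "caller returned nothing on the default study"
        for s in called_srnas:
            assert s.length >= 50
            assert s.support >= 3

    def test_categories_partition_candidates(self, called_srnas):
        assert all(s.category in ("ncRNA", "asRNA", "UTR") for s in called_srnas)

    def test_ids_carry_category_prefixes(self, called_srnas):
        for s in called_srnas:
            prefix = {"ncRNA": "nc", "asRNA": "as", "UTR": "U"}[s.category]
            assert s.id.startswith(prefix)
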