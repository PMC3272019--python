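"""Variant taxonomy: generic calls, isomiR offsets, novel miR*, e-miRs."""

import numpy as np
import pytest

from mircensus import synth
from mircensus.config import PipelineConfig
from mircensus.isomir import (GENERIC_LABELS, assign_feature, detect_emir,
                              detect_novel_star, finalize_taxonomy,
                              render_hairpin_alignment, summarize_hairpin)
from mircensus.pipeline import run_census
from mircensus.reference import MatureAnnotation
from mircensus.tagmap import SENSE, Tag, TagAlignment


def _placement(hairpin, start, end, count=1, weight=1.0):
    return TagAlignment(Tag(hairpin.sequence[start - 1:end], count),
                        hairpin.id, start, end, SENSE, weight=weight)


class TestAssignFeature:
    def test_canonical_start(self, toy70):
        h, ref = toy70
        call = assign_feature(_placement(h, 8, 29), ref)
        assert call.label == "generic_mature"
        assert call.five_prime_offset == 0
        assert call.three_prime_offset == 0

    def test_plus_one_isomir(self, toy70):
        h, ref = toy70
        call = assign_feature(_placement(h, 9, 29), ref)
        assert call.label == "generic_mature"
        assert call.five_prime_offset == 1

    @pytest.mark.parametrize("offset", range(-5, 6))
    def test_generic_window_boundary(self, toy70, offset):
        """Sweep 5' offsets -5..+5: generic iff |offset| <= 3."""
        h, ref = toy70
        call = assign_feature(_placement(h, 8 + offset, 29), ref)
        if abs(offset) <= 3:
            assert call.label == "generic_mature"
            assert call.five_prime_offset == offset
        else:
            assert call.label not in GENERIC_LABELS

    def test_three_prime_offset_against_anchor(self, toy70):
        h, ref = toy70
        call = assign_feature(_placement(h, 9, 27), ref)
        assert (call.five_prime_offset, call.three_prime_offset) == (1, -2)

    def test_loop_spanning_unassigned_with_ago2_flag(self, toy70):
        h, ref = toy70
        call = assign_feature(_placement(h, 25, 46), ref)
        assert call.label == "unassigned"
        assert "ago2_candidate" in call.flags

    def test_offset_antisymmetry_under_reannotation(self, toy70):
        """Shifting the annotated start by +1 shifts all 5' offsets by -1."""
        h, ref = toy70
        import copy
        ref2 = copy.deepcopy(ref)
        shifted = [MatureAnnotation(a.hairpin_id, a.name, a.start + 1, a.end,
                                    arm=a.arm,
                                    annotation_class=a.annotation_class)
                   for a in ref.annotations]
        ref2.annotations = shifted
        ref2._by_hairpin.clear()
        for a in shifted:
            ref2._by_hairpin.setdefault(a.hairpin_id, []).append(a)
        for start in range(6, 12):
            c1 = assign_feature(_placement(h, start, 29), ref)
            c2 = assign_feature(_placement(h, start, 29), ref2)
            if c1.five_prime_offset is not None and c2.five_prime_offset is not None:
                assert c2.five_prime_offset == c1.five_prime_offset - 1


class TestSummaries:
    def test_isomir_proportion_arithmetic(self, toy70):
        h, ref = toy70
        calls = ([assign_feature(_placement(h, 8, 29, count=1), ref)
                  for _ in range(60)]
                 + [assign_feature(_placement(h, 9, 29, count=1), ref)
                    for _ in range(40)])
        s = summarize_hairpin(calls)
        m = s.mirnas["toy-miR"]
        assert m.p5_isomir_fraction == pytest.approx(0.40)
        assert "high_5p_isomir" in m.flags

    def test_all_canonical_ends_give_zero_3p_isomir(self, toy70):
        h, ref = toy70
        calls = [assign_feature(_placement(h, 8, 29, count=5), ref)]
        s = summarize_hairpin(calls)
        assert s.mirnas["toy-miR"].p3_isomir_fraction == 0.0

    def test_length_histogram_sums_to_total(self, toy70):
        h, ref = toy70
        calls = [assign_feature(_placement(h, 8, 29, count=3), ref),
                 assign_feature(_placement(h, 8, 31, count=2), ref)]
        s = summarize_hairpin(calls)
        m = s.mirnas["toy-miR"]
        assert sum(m.length_hist.values()) == pytest.approx(m.total)

    def test_planted_50_1_percent_recovery(self):
        """A miRNA simulated with a 50.1% +1 5'-offset fraction on two
        identical loci is recovered within the binomial CI."""
        spec = synth.SimSpec(
            n_hairpins=2, n_reads=10_000, rng_seed=7,
            duplicate_of={1: 0},
            abundance_weights=(0.5, 0.5),
            hairpin_overrides={
                0: {"five_prime_dist": {0: 0.499, 1: 0.501},
                    "arm_fraction": 1.0},
                1: {"five_prime_dist": {0: 0.499, 1: 0.501},
                    "arm_fraction": 1.0}},
            nta_rate=0.0, error_rate=0.0,
            emir_plantings=(), antisense_plantings=(), novel_plantings=())
        synref = synth.build_reference(spec)
        reads, _ = synth.simulate_library(synref, spec)
        res = run_census(reads, synref.reference, run_discovery=False)
        fractions = [m.p5_isomir_fraction
                     for s in res.summaries.values()
                     for m in s.mirnas.values() if m.total > 100]
        assert fractions
        se = (0.501 * 0.499 / 10_000) ** 0.5
        for f in fractions:
            assert abs(f - 0.501) <= 3 * se

    def test_planted_recovery_across_replicates(self):
        """5'/3' isomiR proportions match planted values within 3 binomial
        SEs in >= 95% of 100 seeded replicates."""
        p5_dist = {0: 0.7, 1: 0.3}
        p3_dist = {0: 0.6, 1: 0.4}
        ok = 0
        for seed in range(100):
            spec = synth.SimSpec(
                n_hairpins=1, n_reads=600, rng_seed=seed,
                hairpin_overrides={0: {"five_prime_dist": p5_dist,
                                       "three_prime_dist": p3_dist,
                                       "arm_fraction": 1.0}},
                nta_rate=0.0, error_rate=0.0, genome_len=1000,
                emir_plantings=(), antisense_plantings=(),
                novel_plantings=())
            synref = synth.build_reference(spec)
            reads, _ = synth.simulate_library(synref, spec)
            res = run_census(reads, synref.reference, run_discovery=False)
            m = next(m for s in res.summaries.values()
                     for m in s.mirnas.values() if m.total > 100)
            n = m.total
            se5 = (0.3 * 0.7 / n) ** 0.5
            se3 = (0.4 * 0.6 / n) ** 0.5
            if (abs(m.p5_isomir_fraction - 0.3) <= 3 * se5
                    and abs(m.p3_isomir_fraction - 0.4) <= 3 * se3):
                ok += 1
        assert ok >= 95


class TestNovelStar:
    def _ref_without_star(self, toy70):
        import copy
        h, ref = toy70
        ref2 = copy.deepcopy(ref)
        keep = [a for a in ref.annotations if a.annotation_class == "mature"]
        ref2.annotations = keep
        ref2._by_hairpin.clear()
        for a in keep:
            ref2._by_hairpin.setdefault(a.hairpin_id, []).append(a)
        return h, ref2

    def test_juxtaposed_phased_set_is_generic_star(self, toy70):
        h, ref = self._ref_without_star(toy70)
        # canonical star position for mature (8,29): (44,65)
        calls = [assign_feature(_placement(h, 44, 65, count=20), ref)]
        final = detect_novel_star(calls, ref)
        assert final[0].label == "novel_generic_star"

    def test_displaced_set_is_non_generic_star(self, toy70):
        h, ref = self._ref_without_star(toy70)
        calls = [assign_feature(_placement(h, 50, 65, count=20), ref)]
        final = detect_novel_star(calls, ref)
        assert final[0].label == "novel_star"

    def test_diffuse_starts_give_no_call(self, toy70):
        h, ref = self._ref_without_star(toy70)
        calls = [assign_feature(_placement(h, s, 65, count=4), ref)
                 for s in (41, 44, 47, 50, 53)]
        final = detect_novel_star(calls, ref)
        assert all(c.label == "unassigned" for c in final)


class TestEmir:
    def test_dominant_non_generic_set_called(self, toy70):
        """A non-generic set carrying ~99.7% of hairpin tags is an e-miR."""
        h, ref = toy70
        calls = ([assign_feature(_placement(h, 13, 30, count=300), ref)]
                 + [assign_feature(_placement(h, 8, 29, count=1), ref)])
        final = detect_emir(calls, ref)
        emirs = [c for c in final if c.label == "e_miR"]
        assert len(emirs) == 1
        assert any(f.startswith("emir_name:e-miR-toy") for f in emirs[0].flags)

    def test_below_fraction_threshold_no_call(self, toy70):
        h, ref = toy70
        calls = ([assign_feature(_placement(h, 13, 30, count=20), ref)]
                 + [assign_feature(_placement(h, 8, 29, count=180), ref)])
        final = detect_emir(calls, ref)
        assert not [c for c in final if c.label == "e_miR"]

    def test_long_tags_rejected_by_length_filter(self, toy70):
        h, ref = toy70
        calls = ([assign_feature(_placement(h, 1, 30, count=120), ref)]  # 30 nt
                 + [assign_feature(_placement(h, 8, 29, count=180), ref)])
        final = detect_emir(calls, ref)
        assert not [c for c in final if c.label == "e_miR"]


class TestTaxonomyPartition:
    def test_every_placement_exactly_one_final_label(self, default_run):
        _, _, _, result = default_run
        allowed = GENERIC_LABELS | {"novel_generic_star", "novel_star",
                                    "e_miR", "unassigned"}
        assert all(c.label in allowed for c in result.calls)
        total_calls = sum(c.weighted_count for c in result.calls)
        total_summary = sum(s.total for s in result.summaries.values())
        assert total_calls == pytest.approx(total_summary, rel=1e-9)

    def test_label_weights_partition_hairpin_totals(self, default_run):
        _, _, _, result = default_run
        for s in result.summaries.values():
            assert sum(s.label_weight.values()) == pytest.approx(
                s.total, rel=1e-9)


class TestRendering:
    def test_block_layout_and_indent(self, toy70):
        h, ref = toy70
        calls = [assign_feature(_placement(h, 8, 29, count=3), ref)]
        block = render_hairpin_alignment(h, calls).splitlines()
        assert block[0] == h.sequence
        assert block[1] == h.structure
        assert block[2].startswith(" " * 7 + h.sequence[7:29])

    def test_mismatch_lowercased(self, toy70):
        h, ref = toy70
        ref_base = h.sequence[28]
        alt = "T" if ref_base != "T" else "A"
        tag_seq = h.sequence[7:28] + alt
        p = TagAlignment(Tag(tag_seq, 1), "toy", 8, 29, SENSE,
                         mismatches=((22, ref_base, alt),))
        call = assign_feature(p, ref)
        block = render_hairpin_alignment(h, [call]).splitlines()
        assert block[2].lstrip().startswith(tag_seq[:-1] + alt.lower())

    def test_sorted_by_weighted_count(self, toy70):
        h, ref = toy70
        rng = np.random.default_rng(2)
        calls = [assign_feature(_placement(h, 8, 29 - (i % 3), count=int(c)), ref)
                 for i, c in enumerate(rng.integers(1, 500, 30))]
        block = render_hairpin_alignment(h, calls).splitlines()[2:]
        counts = [int(line.split("[")[1].split("x")[0]) for line in block]
        assert counts == sorted(counts, reverse=True)
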