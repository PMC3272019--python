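"""Terminal composition, Welch tests, duplex geometry and distortions."""

import math

import numpy as np
import pytest

from mircensus import synth
from mircensus.config import PipelineConfig
from mircensus.isomir import assign_feature
from mircensus.procsites import (BASES, MAJOR, POSITIONS, DistortionClass,
                                 DuplexModel, assign_groups,
                                 background_frequencies,
                                 build_position_profiles, classify_distortions,
                                 composition_test, reconstruct_duplex,
                                 reconstruct_duplexes)
from mircensus.reference import (FIVE_PRIME, THREE_PRIME, HairpinRecord,
                                 Reference, pair_table)
from mircensus.tagmap import SENSE, Tag, TagAlignment


def _placement(hairpin, start, end, count=1):
    return TagAlignment(Tag(hairpin.sequence[start - 1:end], count),
                        hairpin.id, start, end, SENSE)


def welch_oracle(x, y):
    """Independent closed-form Welch t-test (two-sided)."""
    from scipy.stats import t as tdist
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    return 2.0 * tdist.sf(abs(t), df)


class TestPositionProfiles:
    def test_single_isomir_first_base(self, toy70):
        h, ref = toy70
        cfg = PipelineConfig(min_expression=1)
        calls = [assign_feature(_placement(h, 8, 29, count=5), ref)]
        profs = build_position_profiles(calls, ref, cfg)
        (p,) = [p for p in profs if p.arm == FIVE_PRIME]
        first = h.sequence[7].replace("T", "U")
        expected = np.array([1.0 if b == first else 0.0 for b in BASES])
        assert np.allclose(p.freq["first"], expected)

    def test_two_isomirs_weighted_70_30(self, toy70):
        h, ref = toy70
        cfg = PipelineConfig(min_expression=1)
        calls = [assign_feature(_placement(h, 8, 29, count=70), ref),
                 assign_feature(_placement(h, 9, 29, count=30), ref)]
        profs = build_position_profiles(calls, ref, cfg)
        (p,) = [p for p in profs if p.arm == FIVE_PRIME]
        b1 = h.sequence[7].replace("T", "U")
        b2 = h.sequence[8].replace("T", "U")
        assert b1 != b2  # fixture property
        expect = {b1: 0.7, b2: 0.3}
        got = dict(zip(BASES, p.freq["first"]))
        for b in BASES:
            assert got[b] == pytest.approx(expect.get(b, 0.0))

    def test_vectors_sum_to_one_and_background_is_exact_mean(self, toy70):
        h, ref = toy70
        cfg = PipelineConfig(min_expression=1)
        calls = [assign_feature(_placement(h, 8, 29, count=7), ref),
                 assign_feature(_placement(h, 44, 65, count=3), ref)]
        profs = build_position_profiles(calls, ref, cfg)
        vecs = []
        for p in profs:
            for v in p.freq.values():
                assert v.sum() == pytest.approx(1.0, abs=1e-9)
                vecs.append(v)
        assert np.allclose(background_frequencies(profs),
                           np.mean(vecs, axis=0))


class TestCompositionTest:
    def _toy_profiles(self, rng, n, first_u=0.25):
        from mircensus.procsites import PositionProfile
        profs = []
        for i in range(n):
            p = PositionProfile(f"m{i}", f"h{i}", FIVE_PRIME)
            for pos in POSITIONS:
                v = rng.dirichlet([5.0, 5.0, 5.0, 5.0])
                p.freq[pos] = v
            # plant U enrichment at the first position
            u = rng.beta(first_u * 40, (1 - first_u) * 40)
            rest = rng.dirichlet([5.0, 5.0, 5.0]) * (1 - u)
            p.freq["first"] = np.array([rest[0], rest[1], rest[2], u])
            profs.append(p)
        return profs

    def test_null_case_all_ns(self):
        from mircensus.procsites import PositionProfile
        profs = []
        for i in range(10):
            p = PositionProfile(f"m{i}", f"h{i}", FIVE_PRIME)
            for pos in POSITIONS:
                p.freq[pos] = np.full(4, 0.25)
            profs.append(p)
        results = composition_test(profs)
        assert all(r.status == "ns" for r in results)

    def test_planted_uridine_enrichment_detected(self):
        rng = np.random.default_rng(5)
        profs = self._toy_profiles(rng, 50, first_u=0.8)
        results = composition_test(profs)
        hit = [r for r in results
               if r.position == "first" and r.base == "U" and r.group == "total"]
        assert hit and hit[0].status == "enriched" and hit[0].p_value < 1e-6

    def test_welch_agrees_with_reference_formula(self):
        """Package Welch p-values match the closed form to 1e-9 on 100
        random datasets."""
        from scipy.stats import ttest_ind
        rng = np.random.default_rng(17)
        for _ in range(100):
            x = rng.normal(0, 1, int(rng.integers(4, 30)))
            y = rng.normal(rng.normal(), 2, int(rng.integers(4, 30)))
            p_pkg = float(ttest_ind(x, y, equal_var=False).pvalue)
            assert p_pkg == pytest.approx(welch_oracle(x, y), abs=1e-9)

    def test_group_assignment_by_arm_fraction(self):
        from mircensus.procsites import PositionProfile
        profs = [PositionProfile("a", "h", FIVE_PRIME),
                 PositionProfile("b", "h", FIVE_PRIME),
                 PositionProfile("c", "h", FIVE_PRIME)]
        groups = assign_groups(profs, {"a": 0.9, "b": 0.5, "c": 0.1})
        assert groups == {"a": "major", "b": "symmetric", "c": "minor"}


class TestDuplexGeometry:
    def test_canonical_two_nt_overhangs(self, toy70):
        h, ref = toy70
        d = reconstruct_duplex("toy", (8, 29), (44, 65),
                               ref.pair_table_of("toy"))
        assert (d.overhang_drosha, d.overhang_dicer) == (2, 2)

    def test_blunt_drosha_end(self, toy70):
        h, ref = toy70
        d = reconstruct_duplex("toy", (8, 29), (44, 63),
                               ref.pair_table_of("toy"))
        assert d.overhang_drosha == 0

    def test_unpaired_first_nt_reported(self):
        struct = "." + "(" * 29 + "." * 10 + ")" * 29 + "."
        seq = "A" * 70
        pt = pair_table(HairpinRecord("x", seq, struct))
        d = reconstruct_duplex("x", (1, 22), (47, 68), pt)
        assert not d.first_nt_paired_5p
        assert "unpaired_anchor" in d.flags

    def test_overhang_magnitudes_preserved_under_reverse_complement(self, toy70):
        """Reverse-complementing the hairpin description (arms swapped,
        intervals remapped x -> n+1-x) preserves each overhang's magnitude
        while flipping its sign: a 3' overhang on the sense hairpin is a 5'
        overhang on the antisense one."""
        h, ref = toy70
        n = len(h.sequence)
        flipped = h.structure[::-1].translate(str.maketrans("()", ")("))
        from mircensus.reference import revcomp
        h2 = HairpinRecord("flip", revcomp(h.sequence), flipped)
        pt2 = pair_table(h2)
        iv5 = (n + 1 - 65, n + 1 - 44)   # image of the 3p strand
        iv3 = (n + 1 - 29, n + 1 - 8)    # image of the 5p strand
        d1 = reconstruct_duplex("toy", (8, 29), (44, 65),
                                ref.pair_table_of("toy"))
        d2 = reconstruct_duplex("flip", iv5, iv3, pt2)
        assert (d2.overhang_drosha, d2.overhang_dicer) == (
            -d1.overhang_drosha, -d1.overhang_dicer)

    def test_synthetic_cohort_all_canonical(self):
        """On hairpins built with canonical geometry only, every duplex
        reconstructed from the annotated intervals has 2-nt overhangs."""
        spec = synth.SimSpec(n_hairpins=10, rng_seed=3, genome_len=1000,
                             novel_plantings=(), antisense_plantings=(),
                             emir_plantings=())
        synref = synth.build_reference(spec)
        for hid in synref.reference.hairpins:
            pt = synref.reference.pair_table_of(hid)
            d = reconstruct_duplex(hid, synth.MATURE_5P, synth.STAR_3P, pt)
            assert (d.overhang_drosha, d.overhang_dicer) == (2, 2)
            assert d.first_nt_paired_5p and d.first_nt_paired_3p


class TestDistortions:
    def test_fully_paired_drosha_window(self, toy70):
        h, ref = toy70
        d = reconstruct_duplex("toy", (8, 29), (44, 65),
                               ref.pair_table_of("toy"))
        drosha, dicer = classify_distortions(d, ref.pair_table_of("toy"))
        assert drosha.kind == "fully_paired"

    def test_dicer_adjacent_to_terminal_loop(self, toy70):
        h, ref = toy70
        pt = ref.pair_table_of("toy")
        d = reconstruct_duplex("toy", (8, 30), (42, 65), pt)
        _, dicer = classify_distortions(d, pt)
        assert dicer.kind == "terminal_loop_adjacent"
        assert dicer.offset == 0

    def test_planted_symmetric_internal_loop_recovered(self):
        """A 2-nt symmetrical internal loop planted at the Drosha boundary
        round-trips through the classifier."""
        spec = synth.SimSpec(n_hairpins=2, rng_seed=11, genome_len=1000,
                             novel_plantings=(), antisense_plantings=(),
                             emir_plantings=())
        synref = synth.build_reference(spec, distortions={0: 1})
        pt = synref.reference.pair_table_of("syn-mir-1")
        d = reconstruct_duplex("syn-mir-1", synth.MATURE_5P, synth.STAR_3P, pt)
        drosha, _ = classify_distortions(d, pt)
        assert drosha.kind == "sym_internal_loop_2"

    def test_bulge_on_one_strand(self, toy70):
        h, ref = toy70
        # position 6 bulged out of the 5' strand; the 3' strand stays paired
        struct = "(" * 5 + "." + "(" * 24 + "." * 10 + ")" * 29 + "."
        pt = pair_table(HairpinRecord("x", h.sequence, struct))
        d = reconstruct_duplex("x", (8, 29), (44, 65), pt)
        drosha, _ = classify_distortions(d, pt)
        assert drosha.kind == "bulge"


def test_planted_uridine_start_preference_detected_end_to_end():
    """Libraries whose mature products all start with U show first-position
    uridine enrichment over background after the full pipeline."""
    spec = synth.SimSpec(n_hairpins=24, n_reads=20_000, rng_seed=19,
                         first_base="T", genome_len=1000,
                         emir_plantings=(), antisense_plantings=(),
                         novel_plantings=())
    synref = synth.build_reference(spec)
    reads, _ = synth.simulate_library(synref, spec)
    from mircensus.pipeline import run_census
    result = run_census(reads, synref.reference, run_discovery=False)
    profs = build_position_profiles(result.calls, synref.reference)
    results = composition_test(profs)
    hit = [r for r in results
           if r.arm == FIVE_PRIME and r.group == "total"
           and r.position == "first" and r.base == "U"]
    assert hit and hit[0].status == "enriched"


def test_full_pipeline_profiles_on_default_library(default_run):
    """Profiles built from the default library are well-formed and the
    cohort shows the planted U-start preference machinery end to end."""
    _, synref, _, result = default_run
    profs = build_position_profiles(result.calls, synref.reference)
    assert profs
    for p in profs:
        for v in p.freq.values():
            assert v.sum() == pytest.approx(1.0, abs=1e-9)
    duplexes, single = reconstruct_duplexes(result.summaries, synref.reference)
    assert duplexes
    assert all(d.overhang_drosha == 2 and d.overhang_dicer == 2
               for d in duplexes if not d.flags)
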