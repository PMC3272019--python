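"""Novel-hairpin discovery, folding backend and the antisense screen."""

import numpy as np
import pytest

from mircensus import synth
from mircensus.discovery import (cluster_genome_tags, detect_antisense,
                                 discover_novel, evaluate_candidate,
                                 fold_window)
from mircensus.folding import fold_hairpin, paired_fraction
from mircensus.reference import HairpinRecord, revcomp
from mircensus.tagmap import ANTISENSE, SENSE, Tag, TagAlignment

BASES = "ACGT"


def _random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def _placement(chrom, start, end, count, strand=SENSE):
    return TagAlignment(Tag("A" * (end - start + 1), count),
                        chrom, start, end, strand)


class TestClustering:
    def test_single_start_perfect_phase(self):
        ps = [_placement("chr1", 1000, 1021, 1) for _ in range(100)]
        clusters = cluster_genome_tags(ps)
        assert len(clusters) == 1
        assert clusters[0].phase_fraction == pytest.approx(1.0)
        assert clusters[0].modal_start == 1000

    def test_diffuse_starts_discarded(self):
        ps = ([_placement("chr1", 1000, 1021, 40)]
              + [_placement("chr1", 1010, 1031, 30)]
              + [_placement("chr1", 1020, 1041, 30)])
        assert cluster_genome_tags(ps) == []

    def test_two_distant_clusters_both_retained(self):
        ps = ([_placement("chr1", 1000, 1021, 80)]
              + [_placement("chr1", 1060, 1081, 60)])
        clusters = cluster_genome_tags(ps)
        assert len(clusters) == 2
        assert {c.modal_start for c in clusters} == {1000, 1060}

    def test_size_selection(self):
        ps = [_placement("chr1", 1000, 1035, 500)]     # 36 nt
        assert cluster_genome_tags(ps) == []


class TestFolding:
    def _planted_window(self, rng, stem=24, loop=8, flank=20):
        side5 = _random_seq(rng, stem)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        hairpin = (side5 + _random_seq(rng, loop)
                   + "".join(comp[b] for b in reversed(side5)))
        return _random_seq(rng, flank) + hairpin + _random_seq(rng, flank)

    def test_planted_stem_recovered(self):
        rng = np.random.default_rng(31)
        window = self._planted_window(rng)
        db, score = fold_hairpin(window)
        # planted pairs: flank+i pairs flank+2*stem+loop+1-i (1-based)
        n_recovered = 0
        stack = []
        pairs = {}
        for i, c in enumerate(db, 1):
            if c == "(":
                stack.append(i)
            elif c == ")":
                pairs[stack.pop()] = i
        for i in range(1, 25):
            want = (20 + i, 20 + 2 * 24 + 8 + 1 - i)
            if pairs.get(want[0]) == want[1]:
                n_recovered += 1
        assert n_recovered >= 20

    def test_shuffled_control_below_stem_threshold(self):
        rng = np.random.default_rng(32)
        window = self._planted_window(rng)
        shuffled = "".join(rng.permutation(list(window)))
        db, _ = fold_hairpin(shuffled)
        assert sum(c == "(" for c in db) < 16

    def test_deterministic(self):
        rng = np.random.default_rng(33)
        w = self._planted_window(rng)
        assert fold_hairpin(w) == fold_hairpin(w)


class TestEvaluate:
    def _synthetic_scene(self, seed=5, n_mir=500, n_star=150):
        """Genome with one planted canonical hairpin and its tag clusters."""
        spec = synth.SimSpec(n_hairpins=2, rng_seed=seed, genome_len=20_000,
                             novel_plantings=(synth.NovelPlanting(),),
                             antisense_plantings=(), emir_plantings=())
        synref = synth.build_reference(spec)
        locus = synref.truth.novel_loci[0]
        g = synref.genome
        chrom = g["chr1"]
        mi, st = locus["mirna"], locus["star"]
        ps = ([TagAlignment(Tag(chrom[mi[0] - 1:mi[1]], n_mir), "chr1",
                            mi[0], mi[1], SENSE)]
              + [TagAlignment(Tag(chrom[st[0] - 1:st[1]], n_star), "chr1",
                              st[0], st[1], SENSE)])
        return g, ps, locus

    def test_planted_canonical_locus_accepted_with_star(self):
        genome, ps, locus = self._synthetic_scene()
        candidates = discover_novel(genome, ps)
        accepted = [c for c in candidates if c.accepted]
        assert len(accepted) == 1
        c = accepted[0]
        assert c.name == "miR-N1"
        assert c.star_support
        assert c.mirna_interval == locus["mirna"]

    def test_cluster_spanning_loop_rejected(self):
        genome, ps, locus = self._synthetic_scene()
        mi = locus["mirna"]
        # shift the cluster onto the loop (mature start +24 crosses it)
        bad = [TagAlignment(Tag("A" * 22, 500), "chr1",
                            mi[0] + 20, mi[1] + 20, SENSE)]
        clusters = cluster_genome_tags(bad)
        folded = fold_window(genome, clusters[0])
        cand = evaluate_candidate(clusters[0], folded)
        assert not cand.accepted
        assert not cand.criteria["on_one_arm"]

    def test_short_stem_rejected(self):
        rng = np.random.default_rng(8)
        side5 = _random_seq(rng, 14)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        hairpin = (side5 + _random_seq(rng, 8)
                   + "".join(comp[b] for b in reversed(side5)))
        genome = {"chr1": _random_seq(rng, 500) + hairpin
                  + _random_seq(rng, 500)}
        ps = [TagAlignment(Tag(genome["chr1"][500:522], 500), "chr1",
                           501, 522, SENSE)]
        candidates = discover_novel(genome, ps)
        assert candidates and not candidates[0].accepted

    def test_recall_and_false_positive_rates(self):
        """All easy planted loci are accepted; none of 100 shuffled-genome
        control windows yields an accepted candidate."""
        hits = 0
        for seed in range(5):
            genome, ps, locus = self._synthetic_scene(seed=40 + seed)
            accepted = [c for c in discover_novel(genome, ps) if c.accepted]
            hits += len(accepted) == 1
        assert hits == 5
        rng = np.random.default_rng(99)
        false_pos = 0
        for _ in range(100):
            g = {"chr1": _random_seq(rng, 400)}
            ps = [TagAlignment(Tag(g["chr1"][189:211], 500), "chr1",
                               190, 211, SENSE)]
            false_pos += sum(c.accepted for c in discover_novel(g, ps))
        assert false_pos == 0

    def test_verdicts_deterministic(self):
        genome, ps, _ = self._synthetic_scene()
        v1 = [(c.name, c.verdict) for c in discover_novel(genome, ps)]
        v2 = [(c.name, c.verdict) for c in discover_novel(genome, ps)]
        assert v1 == v2

    def test_accepted_interval_round_trips_through_genome(self):
        genome, ps, _ = self._synthetic_scene()
        for c in discover_novel(genome, ps):
            if not c.accepted:
                continue
            s, e = c.mirna_interval
            seg = genome[c.chrom][s - 1:e]
            if c.strand == ANTISENSE:
                seg = revcomp(seg)
            ci = c.window.cluster_interval
            assert c.window.sequence[ci[0] - 1:ci[1]] == seg


class TestAntisense:
    def _antisense_scene(self, both_arms=True):
        spec = synth.SimSpec(n_hairpins=2, rng_seed=21, genome_len=1000,
                             novel_plantings=(), emir_plantings=(),
                             antisense_plantings=())
        synref = synth.build_reference(spec)
        hid = "syn-mir-1"
        h = synref.reference.hairpins[hid]
        rc = revcomp(h.sequence)
        n = len(h.sequence)
        iv_major = (n - synth.STAR_3P[1] + 1, n - synth.STAR_3P[0] + 1)
        iv_minor = (n - synth.MATURE_5P[1] + 1, n - synth.MATURE_5P[0] + 1)
        ps = [TagAlignment(Tag(rc[iv_major[0] - 1:iv_major[1]], 400), hid,
                           synth.STAR_3P[0], synth.STAR_3P[1], ANTISENSE)]
        if both_arms:
            ps.append(TagAlignment(Tag(rc[iv_minor[0] - 1:iv_minor[1]], 90),
                                   hid, synth.MATURE_5P[0],
                                   synth.MATURE_5P[1], ANTISENSE))
        return synref, ps

    def test_planted_antisense_accepted_and_named(self):
        synref, ps = self._antisense_scene()
        cands = detect_antisense(ps, synref.reference.hairpins)
        accepted = [c for c in cands if c.accepted]
        assert [c.name for c in accepted] == ["syn-mir-1-as"]

    def test_one_arm_only_rejected(self):
        synref, ps = self._antisense_scene(both_arms=False)
        cands = detect_antisense(ps, synref.reference.hairpins)
        assert cands and cands[0].verdict == "rejected(no_opposing_tag)"

    def test_sense_only_placements_yield_no_candidate(self):
        synref, _ = self._antisense_scene()
        h = synref.reference.hairpins["syn-mir-1"]
        ps = [TagAlignment(Tag(h.sequence[7:29], 400), "syn-mir-1",
                           8, 29, SENSE)]
        assert detect_antisense(ps, synref.reference.hairpins) == []


def test_full_pipeline_discovery_on_default_library(default_run):
    """The default study's planted novel loci and antisense locus are all
    recovered by the end-to-end run."""
    _, synref, truth, result = default_run
    accepted = [c for c in result.novel_candidates if c.accepted]
    planted = {d["mirna"] for d in truth.novel_loci}
    assert {c.mirna_interval for c in accepted} == planted
    as_names = [c.name for c in result.antisense_candidates if c.accepted]
    assert as_names == [t["hairpin_id"] + "-as" for t in truth.antisense]
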