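"""Operational taxonomy of miRNA variants on annotated hairpins.

Every MMR-resolved sense placement on a hairpin receives exactly one label:

* ``generic_mature`` / ``generic_star`` / ``generic_p5`` / ``generic_p3`` —
  the tag's 5' start lies within +/- ``generic_window`` nt (default 3) of an
  annotated miRNA 5' end on the same arm; signed 5'/3' offsets are recorded
  relative to that anchor annotation.
* ``novel_star`` / ``novel_generic_star`` — a well-phased tag set on an arm
  without any annotation, opposite a known miRNA; upgraded to generic when
  its position matches canonical duplex geometry (2-nt 3' overhangs).
* ``e_miR`` — an extreme isomiR: a phased, credible tag set on an annotated
  hairpin outside every generic window.
* ``unassigned`` — loop-spanning placements (AGO2-processing candidates) and
  tag sets failing the phasing/credibility filters.

Per-hairpin summaries aggregate weighted counts, 5'/3' isomiR proportions,
length histograms and dominant isomiRs for the arm-bias, processing-site and
reporting stages.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .config import PipelineConfig, DEFAULT_CONFIG
from .reference import (FIVE_PRIME, LOOP_SPANNING, THREE_PRIME,
                        MatureAnnotation, PairTable, Reference, arm_of)
from .tagmap import SENSE, TagAlignment

logger = logging.getLogger(__name__)

GENERIC_LABELS = {"generic_mature", "generic_star", "generic_p5", "generic_p3"}
_CLASS_TO_LABEL = {"mature": "generic_mature", "star": "generic_star",
                   "p5": "generic_p5", "p3": "generic_p3",
                   "none": "generic_mature"}
# anchor-tie precedence: mature outranks star outranks -5p/-3p
_CLASS_RANK = {"mature": 0, "star": 1, "p5": 2, "p3": 2, "none": 3}


@dataclass(frozen=True)
class FeatureCall:
    """Taxonomy label of one placement (offsets relative to its anchor)."""

    placement: TagAlignment
    hairpin_id: str
    arm: str
    label: str
    anchor: MatureAnnotation | None = None
    five_prime_offset: int | None = None
    three_prime_offset: int | None = None
    flags: frozenset[str] = frozenset()

    @property
    def weighted_count(self) -> float:
        return self.placement.weighted_count

    @property
    def is_generic(self) -> bool:
        return self.label in GENERIC_LABELS or self.label == "novel_generic_star"


def assign_feature(placement: TagAlignment, reference: Reference,
                   cfg: PipelineConfig = DEFAULT_CONFIG) -> FeatureCall:
    """Label one sense hairpin placement against the annotations.

    The nearest same-arm annotation with |Delta5'| <= ``generic_window``
    anchors a generic call; ties go to the smaller |Delta5'|, then to the
    higher-precedence class (mature over star). Arms without any annotation
    yield ``novel_star_candidate``; annotated arms with no in-window anchor
    yield ``emir_candidate`` (both finalized by the set-level detectors).
    Loop-spanning placements are ``unassigned`` with an ``ago2_candidate``
    flag.
    """
    hid = placement.target_id
    pt = reference.pair_table_of(hid)
    arm = arm_of((placement.start, placement.end), pt)
    if arm == LOOP_SPANNING:
        return FeatureCall(placement, hid, arm, "unassigned",
                           flags=frozenset({"ago2_candidate"}))
    anns = reference.annotations_on_arm(hid, arm)
    if not anns:
        return FeatureCall(placement, hid, arm, "novel_star_candidate")
    best = None
    for a in anns:
        d5 = placement.start - a.start
        key = (abs(d5), _CLASS_RANK.get(a.annotation_class, 9), a.name)
        if best is None or key < best[0]:
            best = (key, a, d5)
    (_, anchor, d5) = best
    if abs(d5) <= cfg.generic_window:
        return FeatureCall(placement, hid, arm,
                           _CLASS_TO_LABEL[anchor.annotation_class],
                           anchor=anchor, five_prime_offset=d5,
                           three_prime_offset=placement.end - anchor.end)
    return FeatureCall(placement, hid, arm, "emir_candidate")


def assign_features(placements: Iterable[TagAlignment], reference: Reference,
                    cfg: PipelineConfig = DEFAULT_CONFIG) -> list[FeatureCall]:
    """Label every resolved sense placement lying on a known hairpin."""
    return [assign_feature(p, reference, cfg)
            for p in placements
            if p.strand == SENSE and p.target_id in reference.hairpins]


# --- phasing ----------------------------------------------------------------

def phase_stats(calls: Sequence[FeatureCall]) -> tuple[int | None, float, float]:
    """(modal 5' start, weighted share at modal +/- 1 nt, total weight)."""
    weight_at: dict[int, float] = defaultdict(float)
    for c in calls:
        weight_at[c.placement.start] += c.weighted_count
    total = sum(weight_at.values())
    if total == 0:
        return None, 0.0, 0.0
    modal = max(weight_at, key=lambda s: (weight_at[s], -s))
    phased = sum(w for s, w in weight_at.items() if abs(s - modal) <= 1)
    return modal, phased / total, total


def _modal_length(calls: Sequence[FeatureCall]) -> int | None:
    weight_at: dict[int, float] = defaultdict(float)
    for c in calls:
        weight_at[len(c.placement.tag)] += c.weighted_count
    if not weight_at:
        return None
    return max(weight_at, key=lambda n: (weight_at[n], -n))


# --- novel miR* -------------------------------------------------------------

def canonical_star_start(known: MatureAnnotation, pt: PairTable) -> int | None:
    """Expected 5' start of the passenger strand opposite ``known``.

    Canonical Drosha/Dicer geometry leaves 2-nt 3' overhangs on both duplex
    ends, so the star 5' start pairs with two nt inside the known miRNA's
    3' end: start* = partner(end_known - 2). Returns None when that anchor
    is unpaired.
    """
    anchor = known.end - 2
    if anchor < 1 or anchor > len(pt) or not pt.is_paired(anchor):
        return None
    return pt.partner_of(anchor)


def detect_novel_star(calls: Sequence[FeatureCall], reference: Reference,
                      cfg: PipelineConfig = DEFAULT_CONFIG) -> list[FeatureCall]:
    """Finalize ``novel_star_candidate`` calls per (hairpin, arm).

    A well-phased candidate set (modal 5' start +/- 1 nt holding >=
    ``phase_min_fraction`` of the set's weight, minimum ``phase_min_tags``
    weighted tags) on an arm opposite a known miRNA becomes ``novel_star``;
    if the modal start sits within 1 nt of the canonical 2-nt-overhang duplex
    position it is upgraded to ``novel_generic_star``. Other candidates
    become ``unassigned``.
    """
    out: list[FeatureCall] = []
    groups: dict[tuple[str, str], list[FeatureCall]] = defaultdict(list)
    rest: list[FeatureCall] = []
    for c in calls:
        if c.label == "novel_star_candidate":
            groups[(c.hairpin_id, c.arm)].append(c)
        else:
            rest.append(c)
    for (hid, arm), group in groups.items():
        other = FIVE_PRIME if arm == THREE_PRIME else THREE_PRIME
        known = reference.annotations_on_arm(hid, other)
        modal, frac, total = phase_stats(group)
        label = "unassigned"
        if (known and total >= cfg.phase_min_tags
                and frac >= cfg.phase_min_fraction):
            label = "novel_star"
            pt = reference.pair_table_of(hid)
            expected = [canonical_star_start(a, pt) for a in known]
            if any(e is not None and abs(modal - e) <= 1 for e in expected):
                label = "novel_generic_star"
        for c in group:
            out.append(replace(c, label=label))
    return rest + out


# --- extreme isomiRs (e-miRs) ----------------------------------------------

def detect_emir(calls: Sequence[FeatureCall], reference: Reference,
                cfg: PipelineConfig = DEFAULT_CONFIG) -> list[FeatureCall]:
    """Finalize ``emir_candidate`` calls per hairpin.

    Candidates are clustered around modal 5' starts (members within 5 nt).
    A cluster is reported as ``e_miR`` (named e-miR-<parent>) when the
    hairpin passes ``min_expression``, the cluster reaches
    ``emir_min_fraction`` of the hairpin's weighted tags, its modal length is
    credible (``emir_len_range``) and its phase fraction passes
    ``phase_min_fraction``. Loop-overlapping e-miRs carry an
    ``ago2_candidate`` flag. Failing candidates become ``unassigned``.
    """
    hairpin_total: dict[str, float] = defaultdict(float)
    for c in calls:
        hairpin_total[c.hairpin_id] += c.weighted_count
    groups: dict[str, list[FeatureCall]] = defaultdict(list)
    rest: list[FeatureCall] = []
    for c in calls:
        (groups[c.hairpin_id] if c.label == "emir_candidate"
         else rest).append(c)
    out: list[FeatureCall] = []
    for hid, group in groups.items():
        pt = reference.pair_table_of(hid)
        remaining = list(group)
        serial = 0
        while remaining:
            weight_at: dict[int, float] = defaultdict(float)
            for c in remaining:
                weight_at[c.placement.start] += c.weighted_count
            modal = max(weight_at, key=lambda s: (weight_at[s], -s))
            cluster = [c for c in remaining
                       if abs(c.placement.start - modal) <= 5]
            remaining = [c for c in remaining
                         if abs(c.placement.start - modal) > 5]
            _, frac, total = phase_stats(cluster)
            mlen = _modal_length(cluster)
            ok = (hairpin_total[hid] >= cfg.min_expression
                  and total >= cfg.emir_min_fraction * hairpin_total[hid]
                  and mlen is not None
                  and cfg.emir_len_range[0] <= mlen <= cfg.emir_len_range[1]
                  and frac >= cfg.phase_min_fraction)
            if ok:
                serial += 1
                name = f"e-miR-{hid}" + ("" if serial == 1 else f".{serial}")
                for c in cluster:
                    flags = set(c.flags)
                    if (pt.loop_interval is not None
                            and c.placement.start <= pt.loop_interval[1]
                            and c.placement.end >= pt.loop_interval[0]):
                        flags.add("ago2_candidate")
                    flags.add(f"emir_name:{name}")
                    out.append(replace(c, label="e_miR",
                                       flags=frozenset(flags)))
            else:
                out.extend(replace(c, label="unassigned") for c in cluster)
    return rest + out


def finalize_taxonomy(calls: Sequence[FeatureCall], reference: Reference,
                      cfg: PipelineConfig = DEFAULT_CONFIG) -> list[FeatureCall]:
    """Run the set-level detectors; afterwards no *_candidate labels remain."""
    return detect_emir(detect_novel_star(calls, reference, cfg),
                       reference, cfg)


# --- summaries ---------------------------------------------------------------

@dataclass
class MirnaSummary:
    """Aggregates for one annotated miRNA (weighted tags)."""

    annotation: MatureAnnotation
    total: float = 0.0
    p5_isomir: float = 0.0       # weight with five_prime_offset != 0
    p3_isomir: float = 0.0       # weight with three_prime_offset != 0
    length_hist: dict[int, float] = field(default_factory=dict)
    long_weight: float = 0.0
    dominant_interval: tuple[int, int] | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def p5_isomir_fraction(self) -> float:
        return self.p5_isomir / self.total if self.total else 0.0

    @property
    def p3_isomir_fraction(self) -> float:
        return self.p3_isomir / self.total if self.total else 0.0

    @property
    def long_fraction(self) -> float:
        return self.long_weight / self.total if self.total else 0.0


@dataclass
class HairpinSummary:
    """Per-hairpin aggregates over finalized calls."""

    hairpin_id: str
    arm_weight: dict[str, float] = field(default_factory=dict)
    mirnas: dict[str, MirnaSummary] = field(default_factory=dict)
    label_weight: dict[str, float] = field(default_factory=dict)
    total: float = 0.0

    def dominant_isomir(self, arm: str) -> tuple[int, int] | None:
        """Most abundant exact tag interval among generic calls on ``arm``."""
        best = None
        for m in self.mirnas.values():
            if m.annotation.arm == arm and m.dominant_interval is not None:
                if best is None or m.total > best[0]:
                    best = (m.total, m.dominant_interval)
        return best[1] if best else None


def summarize_hairpin(calls: Sequence[FeatureCall],
                      cfg: PipelineConfig = DEFAULT_CONFIG) -> HairpinSummary:
    """Summarize all finalized calls of one hairpin.

    5'/3' isomiR proportions are weighted fractions among each miRNA's
    generic tags; miRNAs get flagged ``high_5p_isomir`` (> 20%) /
    ``extreme_5p_isomir`` (> 80%), the 3' analogues, and ``long_mirna``
    when more than 20% of tags exceed ``long_tag_len`` nt.
    """
    if not calls:
        return HairpinSummary(hairpin_id="")
    s = HairpinSummary(hairpin_id=calls[0].hairpin_id)
    interval_weight: dict[str, dict[tuple[int, int], float]] = defaultdict(
        lambda: defaultdict(float))
    for c in calls:
        w = c.weighted_count
        s.total += w
        s.arm_weight[c.arm] = s.arm_weight.get(c.arm, 0.0) + w
        s.label_weight[c.label] = s.label_weight.get(c.label, 0.0) + w
        if c.label in GENERIC_LABELS and c.anchor is not None:
            m = s.mirnas.get(c.anchor.name)
            if m is None:
                m = s.mirnas[c.anchor.name] = MirnaSummary(c.anchor)
            m.total += w
            if c.five_prime_offset != 0:
                m.p5_isomir += w
            if c.three_prime_offset != 0:
                m.p3_isomir += w
            tlen = len(c.placement.tag)
            m.length_hist[tlen] = m.length_hist.get(tlen, 0.0) + w
            if tlen > cfg.long_tag_len:
                m.long_weight += w
            interval_weight[c.anchor.name][
                (c.placement.start, c.placement.end)] += w
    for name, m in s.mirnas.items():
        ivals = interval_weight[name]
        m.dominant_interval = max(ivals, key=lambda iv: (ivals[iv], -iv[0]))
        if m.p5_isomir_fraction > 0.8:
            m.flags.add("extreme_5p_isomir")
        elif m.p5_isomir_fraction > 0.2:
            m.flags.add("high_5p_isomir")
        if m.p3_isomir_fraction > 0.8:
            m.flags.add("extreme_3p_isomir")
        elif m.p3_isomir_fraction > 0.2:
            m.flags.add("high_3p_isomir")
        if m.long_fraction > 0.2:
            m.flags.add("long_mirna")
    return s


def summarize_all(calls: Sequence[FeatureCall],
                  cfg: PipelineConfig = DEFAULT_CONFIG
                  ) -> dict[str, HairpinSummary]:
    by_hairpin: dict[str, list[FeatureCall]] = defaultdict(list)
    for c in calls:
        by_hairpin[c.hairpin_id].append(c)
    return {hid: summarize_hairpin(cs, cfg)
            for hid, cs in sorted(by_hairpin.items())}


def global_isomir_rates(summaries: Mapping[str, HairpinSummary]
                        ) -> dict[str, float]:
    """Cohort-level isomiR statistics, both ways of computing them.

    ``p5_global``/``p3_global``: weighted share of generic tags that are
    5'/3' isomiRs pooled over all miRNAs. ``p5_mean``/``p3_mean``: unweighted
    per-miRNA means. Both are reported because either reading of a cohort
    rate is defensible; columns are labelled accordingly.
    """
    tot = p5 = p3 = 0.0
    fractions5: list[float] = []
    fractions3: list[float] = []
    for s in summaries.values():
        for m in s.mirnas.values():
            tot += m.total
            p5 += m.p5_isomir
            p3 += m.p3_isomir
            fractions5.append(m.p5_isomir_fraction)
            fractions3.append(m.p3_isomir_fraction)
    n = len(fractions5)
    return {
        "p5_global": p5 / tot if tot else 0.0,
        "p3_global": p3 / tot if tot else 0.0,
        "p5_mean": sum(fractions5) / n if n else 0.0,
        "p3_mean": sum(fractions3) / n if n else 0.0,
    }


# --- text rendering ----------------------------------------------------------

def render_hairpin_alignment(hairpin, calls: Sequence[FeatureCall]) -> str:
    """Plain-text stack of tags under a hairpin (counts, mismatches lowered).

    Line 1: hairpin sequence; line 2: dot-bracket; then one line per call,
    indented to its start column, sorted by weighted count descending.
    Mismatched tag bases (including non-templated 3' additions) are shown
    in lowercase.
    """
    lines = [hairpin.sequence, hairpin.structure]
    for c in sorted(calls, key=lambda c: (-c.weighted_count,
                                          c.placement.start,
                                          c.placement.tag.sequence)):
        p = c.placement
        seq = list(p.tag.sequence)
        for pos, _ref, _alt in p.mismatches:
            seq[pos - 1] = seq[pos - 1].lower()
        lines.append(" " * (p.start - 1) + "".join(seq)
                     + f"  [{p.tag.count}x w={p.weight:.3g} {c.label}]")
    return "\n".join(lines)
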