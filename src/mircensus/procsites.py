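"""Terminal composition and structure around Drosha/Dicer cleavage sites.

Two analyses over generic calls and the hairpin fold:

* **Terminal nucleoside composition** — per miRNA, isomiR-weighted base
  frequency vectors at four positions (one nt outside the 5' start, the
  first and last miRNA positions, one nt outside the 3' end), tested per
  (arm, expression group, position, base) against a pooled background with
  Welch's unequal-variance t-test.

* **Duplex geometry** — reconstructing the miRNA:miR* duplex from the
  dominant isomiR on each arm and the hairpin pair table gives the 3'
  overhang lengths left by Drosha (hairpin-base end) and Dicer (loop end),
  the pairing state of each 5' terminus (surrogate for thermodynamic-
  asymmetry strand selection), and a run-length classification of the
  structural distortions straddling each cleavage boundary.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .config import PipelineConfig, DEFAULT_CONFIG
from .isomir import GENERIC_LABELS, FeatureCall, HairpinSummary
from .reference import (FIVE_PRIME, THREE_PRIME, HairpinRecord, PairTable,
                        Reference, to_rna)

logger = logging.getLogger(__name__)

BASES = "ACGU"
POSITIONS = ("ext5", "first", "last", "ext3")
MAJOR, MINOR, SYMMETRIC, TOTAL = "major", "minor", "symmetric", "total"


# --- position profiles -------------------------------------------------------

@dataclass
class PositionProfile:
    """Per-miRNA isomiR-weighted base frequencies at the four positions.

    ``freq[position]`` is a length-4 vector over A,C,G,U summing to 1;
    positions falling outside the hairpin are absent.
    """

    mirna: str
    hairpin_id: str
    arm: str
    freq: dict[str, np.ndarray] = field(default_factory=dict)


def _base_index(b: str) -> int:
    return BASES.index(to_rna(b))


def build_position_profiles(calls: Sequence[FeatureCall],
                            reference: Reference,
                            cfg: PipelineConfig = DEFAULT_CONFIG,
                            ) -> list[PositionProfile]:
    """Isomir-weighted terminal composition per adequately expressed miRNA.

    Tag bases supply ``first``/``last`` (so non-templated additions count as
    read); the hairpin sequence supplies the external positions. miRNAs
    below ``min_expression`` are excluded; an external position outside the
    hairpin is dropped for that miRNA and logged.
    """
    acc: dict[tuple[str, str, str], dict[str, np.ndarray]] = {}
    totals: dict[tuple[str, str, str], float] = defaultdict(float)
    for c in calls:
        if c.label not in GENERIC_LABELS or c.anchor is None:
            continue
        key = (c.anchor.name, c.hairpin_id, c.arm)
        slot = acc.setdefault(key, {p: np.zeros(4) for p in POSITIONS})
        w = c.weighted_count
        totals[key] += w
        h = reference.hairpins[c.hairpin_id]
        p = c.placement
        slot["first"][_base_index(p.tag.sequence[0])] += w
        slot["last"][_base_index(p.tag.sequence[-1])] += w
        if p.start - 1 >= 1:
            slot["ext5"][_base_index(h.sequence[p.start - 2])] += w
        if p.end + 1 <= len(h):
            slot["ext3"][_base_index(h.sequence[p.end])] += w
    profiles = []
    for (name, hid, arm), slot in sorted(acc.items()):
        if totals[(name, hid, arm)] < cfg.min_expression:
            continue
        prof = PositionProfile(name, hid, arm)
        for pos, vec in slot.items():
            s = vec.sum()
            if s > 0:
                prof.freq[pos] = vec / s
            else:
                logger.info("%s: position %s outside hairpin, dropped",
                            name, pos)
        profiles.append(prof)
    return profiles


def background_frequencies(profiles: Sequence[PositionProfile]) -> np.ndarray:
    """Unweighted mean over every available position vector of every miRNA."""
    vecs = [v for p in profiles for v in p.freq.values()]
    if not vecs:
        return np.full(4, 0.25)
    return np.mean(vecs, axis=0)


# --- composition tests -------------------------------------------------------

@dataclass
class CompositionResult:
    arm: str
    group: str
    position: str
    base: str
    mean_freq: float
    background_freq: float
    p_value: float
    status: str  # enriched | depleted | ns
    n: int = 0
    flags: set[str] = field(default_factory=set)


def assign_groups(profiles: Sequence[PositionProfile],
                  arm_fraction: Mapping[str, float],
                  cfg: PipelineConfig = DEFAULT_CONFIG) -> dict[str, str]:
    """major / minor / symmetric per miRNA from its hairpin-arm fraction.

    ``arm_fraction[mirna]`` is the share of the hairpin's tags carried by
    that miRNA's own arm: >= bias_hi -> major, <= bias_lo -> minor, else
    symmetric.
    """
    groups = {}
    for p in profiles:
        f = arm_fraction.get(p.mirna)
        if f is None:
            groups[p.mirna] = SYMMETRIC
        elif f >= cfg.bias_hi:
            groups[p.mirna] = MAJOR
        elif f <= cfg.bias_lo:
            groups[p.mirna] = MINOR
        else:
            groups[p.mirna] = SYMMETRIC
    return groups


def composition_test(profiles: Sequence[PositionProfile],
                     groups: Mapping[str, str] | None = None,
                     cfg: PipelineConfig = DEFAULT_CONFIG,
                     ) -> list[CompositionResult]:
    """Welch t-tests of terminal base frequencies against pooled background.

    For each (arm, group, position, base): two-sample unequal-variance
    t-test of the group's per-miRNA frequencies at that position against the
    per-miRNA background frequencies (each miRNA's mean over its available
    positions), pooled over all included miRNAs. Status follows the sign of
    the mean difference at p < alpha; groups smaller than 3 are reported
    ``ns`` with a ``small_group`` flag.
    """
    if groups is None:
        groups = {p.mirna: TOTAL for p in profiles}
    # per-miRNA background: mean over its own available position vectors
    bg_rows = np.array([np.mean(list(p.freq.values()), axis=0)
                        for p in profiles])
    results: list[CompositionResult] = []
    group_names = sorted(set(groups.values()) | {TOTAL})
    for arm in (FIVE_PRIME, THREE_PRIME):
        for gname in group_names:
            members = [p for p in profiles if p.arm == arm
                       and (gname == TOTAL or groups.get(p.mirna) == gname)]
            for pos in POSITIONS:
                rows = np.array([p.freq[pos] for p in members
                                 if pos in p.freq])
                for bi, base in enumerate(BASES):
                    if len(rows) == 0:
                        continue
                    obs = rows[:, bi]
                    bg = bg_rows[:, bi]
                    res = CompositionResult(
                        arm, gname, pos, base,
                        float(obs.mean()), float(bg.mean()),
                        1.0, "ns", n=len(obs))
                    if len(obs) < 3:
                        res.flags.add("small_group")
                    elif np.var(obs) + np.var(bg) == 0:
                        res.p_value = 1.0
                    else:
                        t = stats.ttest_ind(obs, bg, equal_var=False)
                        res.p_value = float(t.pvalue)
                        if res.p_value < cfg.alpha:
                            res.status = ("enriched"
                                          if obs.mean() > bg.mean()
                                          else "depleted")
                    results.append(res)
    return results


# --- duplex reconstruction ---------------------------------------------------

@dataclass(frozen=True)
class DistortionClass:
    """Pairing pattern in the window straddling one cleavage boundary.

    ``kind``: fully_paired, sym_internal_loop_2/4/other, bulge,
    terminal_loop_adjacent (with ``offset`` 0 or 1 nt from the loop), other.
    """

    kind: str
    offset: int | None = None
    span: tuple[int, int] | None = None

    def __str__(self) -> str:
        if self.kind == "terminal_loop_adjacent":
            return f"terminal_loop_adjacent({self.offset})"
        return self.kind


@dataclass
class DuplexModel:
    """Reconstructed miRNA:miR* duplex of one hairpin."""

    hairpin_id: str
    interval_5p: tuple[int, int]
    interval_3p: tuple[int, int]
    overhang_drosha: int
    overhang_dicer: int
    first_nt_paired_5p: bool
    first_nt_paired_3p: bool
    distortion_drosha: DistortionClass | None = None
    distortion_dicer: DistortionClass | None = None
    flags: set[str] = field(default_factory=set)


def _effective_partner(pt: PairTable, anchor: int,
                       flags: set[str]) -> int | None:
    """Partner of ``anchor``; unpaired anchors step inward (higher position)
    to the nearest paired one, adding the gap back, and are flagged."""
    gap = 0
    pos = anchor
    while 1 <= pos <= len(pt) and not pt.is_paired(pos):
        pos += 1
        gap += 1
    if not (1 <= pos <= len(pt)):
        return None
    if gap:
        flags.add("unpaired_anchor")
    return pt.partner_of(pos) + gap


def reconstruct_duplex(hairpin_id: str,
                       interval_5p: tuple[int, int],
                       interval_3p: tuple[int, int],
                       pt: PairTable) -> DuplexModel:
    """Duplex overhangs and 5'-pairing states from dominant isomiR intervals.

    Drosha-end overhang = 3' end of the 3p strand minus the partner of the
    5p strand's 5' start; Dicer-end overhang = 3' end of the 5p strand minus
    the partner of the 3p strand's 5' start. Positive = 3' overhang (2 is
    the canonical value at both ends); 0 = blunt.
    """
    s5, e5 = interval_5p
    s3, e3 = interval_3p
    flags: set[str] = set()
    partner_s5 = _effective_partner(pt, s5, flags)
    partner_s3 = _effective_partner(pt, s3, flags)
    if partner_s5 is None or partner_s3 is None:
        raise ValueError(f"{hairpin_id}: cannot anchor duplex")
    return DuplexModel(
        hairpin_id, interval_5p, interval_3p,
        overhang_drosha=e3 - partner_s5,
        overhang_dicer=e5 - partner_s3,
        first_nt_paired_5p=pt.is_paired(s5),
        first_nt_paired_3p=pt.is_paired(s3),
        flags=flags)


def reconstruct_duplexes(summaries: Mapping[str, HairpinSummary],
                         reference: Reference,
                         cfg: PipelineConfig = DEFAULT_CONFIG
                         ) -> tuple[list[DuplexModel], int]:
    """Duplexes for every hairpin expressing both arms; also counts the
    single-arm hairpins skipped."""
    duplexes = []
    single_arm = 0
    for hid, s in summaries.items():
        i5 = s.dominant_isomir(FIVE_PRIME)
        i3 = s.dominant_isomir(THREE_PRIME)
        if i5 is None or i3 is None:
            single_arm += 1
            continue
        pt = reference.pair_table_of(hid)
        d = reconstruct_duplex(hid, i5, i3, pt)
        d.distortion_drosha, d.distortion_dicer = classify_distortions(
            d, pt, cfg.distortion_window)
        duplexes.append(d)
    return duplexes, single_arm


# --- distortion classification ----------------------------------------------

def _window_runs(pt: PairTable, positions: Sequence[int]) -> int:
    """Longest contiguous unpaired run within ``positions`` (clipped)."""
    best = run = 0
    for pos in positions:
        if 1 <= pos <= len(pt) and not pt.is_paired(pos):
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def classify_distortions(duplex: DuplexModel, pt: PairTable,
                         window: int = 4
                         ) -> tuple[DistortionClass, DistortionClass]:
    """Classify pairing around the Drosha and Dicer cleavage boundaries.

    ``window`` nt straddling each boundary are examined on both strands
    (half outside, half inside the miRNA). Equal unpaired runs on the two
    strands give a symmetrical internal loop (named by total size), a run on
    one strand only a bulge, none at all fully_paired. A Dicer boundary 0 or
    1 nt from the terminal loop is classed terminal_loop_adjacent first.
    """
    s5, e5 = duplex.interval_5p
    s3, e3 = duplex.interval_3p
    half = window // 2

    def classify(boundary_a: int, boundary_b: int) -> DistortionClass:
        # windows straddle the boundary: positions boundary-half+1..boundary+half
        win_a = range(boundary_a - half + 1, boundary_a + half + 1)
        win_b = range(boundary_b - half + 1, boundary_b + half + 1)
        run_a = _window_runs(pt, list(win_a))
        run_b = _window_runs(pt, list(win_b))
        if run_a == 0 and run_b == 0:
            return DistortionClass("fully_paired")
        if run_a == run_b:
            total = run_a + run_b
            if total == 2:
                return DistortionClass("sym_internal_loop_2")
            if total == 4:
                return DistortionClass("sym_internal_loop_4")
            return DistortionClass("sym_internal_loop_other")
        if run_a == 0 or run_b == 0:
            return DistortionClass("bulge")
        return DistortionClass("other")

    # Drosha boundary: outside the duplex base (5' of s5 / 3' of e3)
    drosha = classify(s5 - 1, e3)
    # Dicer boundary: loop side (3' of e5 / 5' of s3)
    if pt.loop_interval is not None:
        gap5 = pt.loop_interval[0] - e5 - 1
        gap3 = s3 - pt.loop_interval[1] - 1
        gap = min(g for g in (gap5, gap3) if g >= 0) if max(gap5, gap3) >= 0 \
            else -1
        if 0 <= gap <= 1:
            return drosha, DistortionClass("terminal_loop_adjacent",
                                           offset=gap)
    dicer = classify(e5, s3 - 1)
    return drosha, dicer
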