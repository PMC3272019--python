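"""Hairpin arm-strand bias categories and the M/A differential filter.

Strand selection during RISC loading is usually asymmetric: one duplex
strand (annotated ``mature``) accumulates, the passenger (``miR*``) decays.
Comparing observed per-arm tag weights with the annotation pattern yields
three unexpected-bias categories:

* ``strand_reversal``        — the miR* holds > bias_hi of the hairpin's tags;
* ``biased_to_symmetrical``  — the miR* holds between bias_lo and bias_hi;
* ``symmetrical_to_biased``  — a -5p/-3p pair (no annotated dominance) where
  one strand holds > bias_hi.

Fractions are computed on generic tags only so that bias reflects
annotated-species competition. Boundary values exactly at bias_hi/bias_lo
fall in the inner (symmetrical) class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .config import PipelineConfig, DEFAULT_CONFIG
from .isomir import GENERIC_LABELS, HairpinSummary
from .reference import FIVE_PRIME, THREE_PRIME, Reference

CONCORDANT = "concordant"
STRAND_REVERSAL = "strand_reversal"
BIASED_TO_SYMMETRICAL = "biased_to_symmetrical"
SYMMETRICAL_TO_BIASED = "symmetrical_to_biased"
NOT_ASSESSED = "not_assessed"


@dataclass
class ArmBiasRecord:
    hairpin_id: str
    count_5p: float
    count_3p: float
    annotation_pattern: str  # mature_star | p5_p3 | single
    category: str = NOT_ASSESSED
    flags: set[str] = field(default_factory=set)

    @property
    def total(self) -> float:
        return self.count_5p + self.count_3p

    @property
    def p5_fraction(self) -> float:
        return self.count_5p / self.total if self.total else 0.0


def _annotation_pattern(summary: HairpinSummary) -> str:
    classes = {m.annotation.annotation_class for m in summary.mirnas.values()}
    if {"p5", "p3"} & classes:
        return "p5_p3"
    if len(summary.mirnas) >= 2:
        return "mature_star"
    return "single"


def _generic_arm_weights(summary: HairpinSummary) -> tuple[float, float]:
    w5 = w3 = 0.0
    for m in summary.mirnas.values():
        if m.annotation.arm == FIVE_PRIME:
            w5 += m.total
        elif m.annotation.arm == THREE_PRIME:
            w3 += m.total
    return w5, w3


def compute_arm_bias(summaries: Mapping[str, HairpinSummary],
                     cfg: PipelineConfig = DEFAULT_CONFIG
                     ) -> dict[str, ArmBiasRecord]:
    """Arm fractions per hairpin; below ``min_expression`` -> not_assessed."""
    out: dict[str, ArmBiasRecord] = {}
    for hid, s in summaries.items():
        w5, w3 = _generic_arm_weights(s)
        rec = ArmBiasRecord(hid, w5, w3, _annotation_pattern(s))
        if rec.total >= cfg.min_expression:
            rec.category = "assessable"
        out[hid] = rec
    return out


def categorize_bias(record: ArmBiasRecord, summary: HairpinSummary,
                    cfg: PipelineConfig = DEFAULT_CONFIG) -> str:
    """Assign the unexpected-bias category of one assessable hairpin."""
    if record.total < cfg.min_expression or record.total == 0:
        record.category = NOT_ASSESSED
        return record.category
    if record.annotation_pattern == "p5_p3":
        frac = max(record.p5_fraction, 1.0 - record.p5_fraction)
        record.category = (SYMMETRICAL_TO_BIASED if frac > cfg.bias_hi
                           else CONCORDANT)
        return record.category
    if record.annotation_pattern == "single":
        record.category = CONCORDANT
        record.flags.add("single_annotation")
        return record.category
    star_weight = sum(m.total for m in summary.mirnas.values()
                      if m.annotation.annotation_class == "star")
    star_fraction = star_weight / record.total if record.total else 0.0
    if star_fraction > cfg.bias_hi:
        record.category = STRAND_REVERSAL
    elif star_fraction > cfg.bias_lo:
        record.category = BIASED_TO_SYMMETRICAL
    else:
        record.category = CONCORDANT
    return record.category


def categorize_all(summaries: Mapping[str, HairpinSummary],
                   cfg: PipelineConfig = DEFAULT_CONFIG
                   ) -> dict[str, ArmBiasRecord]:
    records = compute_arm_bias(summaries, cfg)
    for hid, rec in records.items():
        categorize_bias(rec, summaries[hid], cfg)
    return records


def global_arm_split(summaries: Mapping[str, HairpinSummary]
                     ) -> tuple[float, float]:
    """Cohort 5'/3' arm shares of generic tags (fractions summing to 1)."""
    w5 = w3 = 0.0
    for s in summaries.values():
        a, b = _generic_arm_weights(s)
        w5 += a
        w3 += b
    tot = w5 + w3
    return (w5 / tot, w3 / tot) if tot else (0.0, 0.0)


def expression_filter(totals: Mapping[str, float],
                      threshold: float) -> dict[str, float]:
    """Keep entries with weighted total >= threshold (boundary inclusive)."""
    return {k: v for k, v in totals.items() if v >= threshold}


# --- differential expression (M/A filter) -----------------------------------

@dataclass
class DiffExpRecord:
    """M/A record for one miRNA across two conditions with replicates.

    M = log2 fold (condition B over A) of replicate-averaged CPM;
    A = mean log2 CPM. ``significant`` requires the fold change to exceed
    ``de_fold`` in the same direction in every replicate pair and the raw
    count to exceed ``de_min_tags`` in every library.
    """

    mirna_id: str
    cpm_a: tuple[float, ...]
    cpm_b: tuple[float, ...]
    M: float = math.nan
    A: float = math.nan
    significant: bool = False
    evaluable: bool = True


def differential_expression(counts_a: Sequence[Mapping[str, float]],
                            counts_b: Sequence[Mapping[str, float]],
                            cfg: PipelineConfig = DEFAULT_CONFIG,
                            library_sizes_a: Sequence[float] | None = None,
                            library_sizes_b: Sequence[float] | None = None,
                            ) -> dict[str, DiffExpRecord]:
    """Two-condition differential filter on counts-per-million.

    ``counts_a``/``counts_b`` are per-replicate miRNA->tag-count mappings
    (replicate i of A pairs with replicate i of B). Library sizes default to
    the per-library count sums. A missing replicate pair marks records
    unevaluable rather than significant.
    """
    if not counts_a or not counts_b:
        raise ValueError("need at least one library per condition")
    sizes_a = list(library_sizes_a or [sum(c.values()) for c in counts_a])
    sizes_b = list(library_sizes_b or [sum(c.values()) for c in counts_b])
    cpm_a = [{k: 1e6 * v / s for k, v in c.items()}
             for c, s in zip(counts_a, sizes_a)]
    cpm_b = [{k: 1e6 * v / s for k, v in c.items()}
             for c, s in zip(counts_b, sizes_b)]
    ids = sorted(set().union(*counts_a, *counts_b))
    paired = min(len(counts_a), len(counts_b))
    out: dict[str, DiffExpRecord] = {}
    for mid in ids:
        ca = tuple(c.get(mid, 0.0) for c in cpm_a)
        cb = tuple(c.get(mid, 0.0) for c in cpm_b)
        rec = DiffExpRecord(mid, ca, cb)
        mean_a = sum(ca) / len(ca)
        mean_b = sum(cb) / len(cb)
        if mean_a > 0 and mean_b > 0:
            rec.M = math.log2(mean_b / mean_a)
            rec.A = 0.5 * (math.log2(mean_a) + math.log2(mean_b))
        if paired < 2:
            rec.evaluable = False
            out[mid] = rec
            continue
        raw = ([c.get(mid, 0.0) for c in counts_a]
               + [c.get(mid, 0.0) for c in counts_b])
        if min(raw) <= cfg.de_min_tags:
            out[mid] = rec
            continue
        folds = []
        for i in range(paired):
            if ca[i] <= 0 or cb[i] <= 0:
                folds = []
                break
            folds.append(cb[i] / ca[i])
        if folds:
            up = all(f > cfg.de_fold for f in folds)
            down = all(f < 1.0 / cfg.de_fold for f in folds)
            rec.significant = up or down
        out[mid] = rec
    return out
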