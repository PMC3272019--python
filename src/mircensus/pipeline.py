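"""End-to-end orchestration of the census over one library.

Ties the stages together in the canonical order: collapse reads to tags,
align to hairpins (both strands), MMR-resolve, apply the variant taxonomy,
summarize hairpins, categorize arm bias, then (optionally) send
hairpin-unmapped tags to the genome for discovery and run the antisense
screen. Each stage remains individually importable; this module only
removes the plumbing from scripts and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import armbias, discovery, isomir, tagmap
from .config import PipelineConfig, DEFAULT_CONFIG
from .reference import Reference
from .tagmap import ANTISENSE, SENSE, Tag, TagAlignment


@dataclass
class CensusResult:
    tags: list[Tag]
    dropped_reads: int
    placements: list[TagAlignment]          # all hairpin placements
    resolved: list[TagAlignment]            # MMR-weighted survivors
    antisense_placements: list[TagAlignment]
    calls: list[isomir.FeatureCall]
    summaries: dict[str, isomir.HairpinSummary]
    bias: dict[str, armbias.ArmBiasRecord]
    genome_placements: list[TagAlignment] = field(default_factory=list)
    novel_candidates: list[discovery.HairpinCandidate] = field(default_factory=list)
    antisense_candidates: list[discovery.HairpinCandidate] = field(default_factory=list)

    def mirna_totals(self) -> dict[str, float]:
        return {name: m.total
                for s in self.summaries.values()
                for name, m in s.mirnas.items()}


def run_census(reads, reference: Reference,
               genome: Mapping[str, str] | None = None,
               cfg: PipelineConfig = DEFAULT_CONFIG,
               min_len: int = 15, max_len: int = 35,
               run_discovery: bool = True,
               min_cluster_weight: float = discovery.MIN_CLUSTER_WEIGHT,
               ) -> CensusResult:
    """Run the full census on a read stream (sequences, records or path)."""
    tags, dropped = tagmap.collapse_reads(reads, min_len, max_len)
    placements = tagmap.align_to_hairpins(tags, reference.hairpins,
                                          cfg.max_mismatches)
    ref_seqs = {hid: h.sequence for hid, h in reference.hairpins.items()}
    resolved = tagmap.mmr_resolve(placements, ref_seqs)
    antisense = [p for p in resolved if p.strand == ANTISENSE]
    calls = isomir.finalize_taxonomy(
        isomir.assign_features(resolved, reference, cfg), reference, cfg)
    summaries = isomir.summarize_all(calls, cfg)
    bias = armbias.categorize_all(summaries, cfg)
    result = CensusResult(tags, dropped, placements, resolved, antisense,
                          calls, summaries, bias)
    if genome is not None and run_discovery:
        placed = {p.tag.sequence for p in resolved}
        unmapped = [t for t in tags if t.sequence not in placed]
        gplace, _rep = tagmap.align_to_genome(unmapped, genome,
                                              cfg.max_mismatches,
                                              cfg.multimap_cap)
        result.genome_placements = tagmap.mmr_resolve(gplace)
        result.novel_candidates = discovery.discover_novel(
            genome, result.genome_placements, cfg,
            min_cluster_weight=min_cluster_weight)
    if antisense:
        result.antisense_candidates = discovery.detect_antisense(
            antisense, reference.hairpins, cfg,
            min_cluster_weight=min_cluster_weight)
    return result


def modal_generic_length(result: CensusResult) -> int | None:
    """Modal tag length over generic calls, weighted by tag count."""
    weight: dict[int, float] = {}
    for c in result.calls:
        if c.is_generic:
            n = len(c.placement.tag)
            weight[n] = weight.get(n, 0.0) + c.weighted_count
    if not weight:
        return None
    return max(weight, key=lambda n: (weight[n], -n))
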