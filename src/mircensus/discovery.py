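"""De-novo miRNA discovery from genome tag clusters, and antisense calls.

Genome-placed tags (18-26 nt) are grouped into well-phased clusters; the
surrounding sequence is folded into a hairpin with the cluster placed on
the 5' arm and then the 3' arm, and each candidate is screened against a
set of structural criteria characteristic of genuine pri-miRNA precursors:

* the candidate interval lies entirely on one stem arm (no loop overlap);
* >= 60% of candidate bases are paired;
* terminal loop between 3 and 30 nt;
* stem of >= 16 base pairs;
* modal tag length 20-24 nt.

A second cluster at the 2-nt-overhang duplex position (a miR* form) is
recorded as a confidence bonus, not a requirement. Accepted candidates are
named miR-N<serial> in coordinate order so serials are stable across runs.

The antisense screen folds the reverse complement of each known hairpin
locus, applies the same criteria to its antisense tag clusters, and
additionally requires at least one tag on the opposing arm; accepted calls
are named <parent>-as.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .config import PipelineConfig, DEFAULT_CONFIG
from .folding import FoldFunc, fold_hairpin, paired_fraction
from .reference import (HairpinRecord, PairTable, normalize_seq, pair_table,
                        revcomp)
from .tagmap import ANTISENSE, SENSE, TagAlignment

logger = logging.getLogger(__name__)

CLUSTER_WINDOW = 30          # nt around the modal start grouped together
DEFAULT_WINDOW_LENGTHS = (100, 160)
MIN_CLUSTER_WEIGHT = 50.0
SIZE_RANGE = (18, 26)

MANDATORY_CRITERIA = ("on_one_arm", "paired_fraction", "loop_size",
                      "stem_pairs", "length_class")


@dataclass
class GenomicTagCluster:
    """A well-phased pile of genome-placed tags."""

    chrom: str
    strand: str
    modal_start: int
    span: tuple[int, int]
    members: list[TagAlignment]
    weighted_count: float
    phase_fraction: float

    @property
    def modal_length(self) -> int:
        weight: dict[int, float] = defaultdict(float)
        for p in self.members:
            weight[p.end - p.start + 1] += p.weighted_count
        return max(weight, key=lambda n: (weight[n], -n))


def cluster_genome_tags(placements: Sequence[TagAlignment],
                        cfg: PipelineConfig = DEFAULT_CONFIG,
                        min_weight: float = MIN_CLUSTER_WEIGHT,
                        size_range: tuple[int, int] = SIZE_RANGE,
                        ) -> list[GenomicTagCluster]:
    """Group size-selected genome placements into well-phased clusters.

    Tags are grouped per (chrom, strand) within ``CLUSTER_WINDOW`` nt of the
    (greedily chosen) modal biological 5' start. Clusters below
    ``min_weight`` weighted tags or with phase fraction below
    ``phase_min_fraction`` are discarded.
    """
    def start_of(p: TagAlignment) -> int:
        # biological 5' start in forward coordinates
        return p.start if p.strand == SENSE else p.end

    by_target: dict[tuple[str, str], list[TagAlignment]] = defaultdict(list)
    for p in placements:
        if size_range[0] <= (p.end - p.start + 1) <= size_range[1]:
            by_target[(p.target_id, p.strand)].append(p)
    clusters: list[GenomicTagCluster] = []
    for (chrom, strand), plist in sorted(by_target.items()):
        remaining = list(plist)
        while remaining:
            weight_at: dict[int, float] = defaultdict(float)
            for p in remaining:
                weight_at[start_of(p)] += p.weighted_count
            modal = max(weight_at, key=lambda s: (weight_at[s], -s))
            members = [p for p in remaining
                       if abs(start_of(p) - modal) <= CLUSTER_WINDOW]
            remaining = [p for p in remaining
                         if abs(start_of(p) - modal) > CLUSTER_WINDOW]
            total = sum(p.weighted_count for p in members)
            phased = sum(p.weighted_count for p in members
                         if abs(start_of(p) - modal) <= 1)
            if total < min_weight or phased / total < cfg.phase_min_fraction:
                continue
            span = (min(p.start for p in members),
                    max(p.end for p in members))
            clusters.append(GenomicTagCluster(
                chrom, strand, modal, span, members, total, phased / total))
    clusters.sort(key=lambda c: (c.chrom, c.strand, c.modal_start))
    return clusters


@dataclass
class FoldedWindow:
    chrom: str
    strand: str
    start: int                 # 1-based forward coords of the window
    end: int
    sequence: str              # strand-oriented (revcomp for antisense)
    structure: str
    score: float
    cluster_interval: tuple[int, int]   # 1-based within the window sequence
    truncated: bool = False


def _window_coords(cluster: GenomicTagCluster, length: int,
                   arm: str, chrom_len: int) -> tuple[int, int, bool]:
    """Window placement putting the cluster on the requested arm."""
    margin = 12
    lo, hi = cluster.span
    if (arm == "five_prime") == (cluster.strand == SENSE):
        start = lo - margin
        end = start + length - 1
    else:
        end = hi + margin
        start = end - length + 1
    truncated = False
    if start < 1:
        start, truncated = 1, True
    if end > chrom_len:
        end, truncated = chrom_len, True
    return start, end, truncated


def fold_window(genome: Mapping[str, str], cluster: GenomicTagCluster,
                window_lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
                fold: FoldFunc = fold_hairpin) -> FoldedWindow:
    """Fold candidate windows around a cluster; keep the best-scoring one.

    Windows of each configured length are positioned with the cluster on the
    5' arm and then on the 3' arm; the fold with the highest backend score
    wins. Windows running off the chromosome end are truncated and flagged.
    """
    chrom_seq = normalize_seq(genome[cluster.chrom])
    best: FoldedWindow | None = None
    for length in window_lengths:
        for arm in ("five_prime", "three_prime"):
            start, end, trunc = _window_coords(cluster, length, arm,
                                               len(chrom_seq))
            seq = chrom_seq[start - 1:end]
            if cluster.strand == ANTISENSE:
                seq = revcomp(seq)
            db, score = fold(seq)
            if cluster.strand == SENSE:
                ci = (cluster.span[0] - start + 1, cluster.span[1] - start + 1)
            else:
                ci = (end - cluster.span[1] + 1, end - cluster.span[0] + 1)
            fw = FoldedWindow(cluster.chrom, cluster.strand, start, end,
                              seq, db, score, ci, trunc)
            if best is None or fw.score > best.score:
                best = fw
    assert best is not None
    return best


@dataclass
class HairpinCandidate:
    """A candidate novel miRNA locus with its criteria audit trail."""

    name: str
    chrom: str
    strand: str
    window: FoldedWindow
    mirna_interval: tuple[int, int]       # genome coords (forward)
    star_interval: tuple[int, int] | None
    criteria: dict[str, bool]
    star_support: bool
    verdict: str                          # accepted | rejected(<reason>)
    cluster: "GenomicTagCluster | None" = None

    @property
    def accepted(self) -> bool:
        return self.verdict == "accepted"


def _stem_pairs_enclosing(pt: PairTable) -> int:
    """Number of base pairs in the structure (single-stem folds only have
    the terminal-loop stem, so the total pair count is the stem size)."""
    return sum(1 for i in range(1, len(pt) + 1) if pt.partner[i] > i)


def evaluate_candidate(cluster: GenomicTagCluster, folded: FoldedWindow,
                       cfg: PipelineConfig = DEFAULT_CONFIG,
                       other_clusters: Sequence[GenomicTagCluster] = (),
                       min_paired_fraction: float = 0.60,
                       loop_range: tuple[int, int] = (3, 30),
                       min_stem_pairs: int = 16,
                       length_range: tuple[int, int] = (20, 24),
                       ) -> HairpinCandidate:
    """Screen one folded cluster window against the pri-miRNA criteria.

    Each criterion is evaluated and reported individually; the verdict is
    ``accepted`` only when all mandatory criteria hold, otherwise
    ``rejected(<first failing criterion>)``. Star support (a second cluster
    whose 5' start matches the 2-nt-overhang duplex position within 2 nt)
    is recorded but never required.
    """
    h = HairpinRecord("window", folded.sequence, folded.structure)
    pt = pair_table(h)
    ci = folded.cluster_interval
    criteria: dict[str, bool] = {}
    if pt.loop_interval is None:
        criteria = {k: False for k in MANDATORY_CRITERIA}
        return HairpinCandidate("", cluster.chrom, cluster.strand, folded,
                                _to_genome(folded, ci), None, criteria,
                                False, "rejected(no_stem)", cluster)
    loop = pt.loop_interval
    criteria["on_one_arm"] = ci[1] < loop[0] or ci[0] > loop[1]
    criteria["paired_fraction"] = (
        paired_fraction(folded.structure, ci[0], ci[1]) >= min_paired_fraction)
    loop_len = loop[1] - loop[0] + 1
    criteria["loop_size"] = loop_range[0] <= loop_len <= loop_range[1]
    criteria["stem_pairs"] = _stem_pairs_enclosing(pt) >= min_stem_pairs
    criteria["length_class"] = (
        length_range[0] <= cluster.modal_length <= length_range[1])
    # star support: another cluster on the same strand at the duplex position
    star_iv = None
    support = False
    for other in other_clusters:
        if other is cluster or other.chrom != cluster.chrom \
                or other.strand != cluster.strand:
            continue
        oi = _to_window(folded, (other.span[0], other.span[1]))
        if oi is None:
            continue
        expected = _expected_star_start(pt, ci, cluster.modal_length)
        if expected is not None and abs(oi[0] - expected) <= 2:
            support = True
            star_iv = (other.span[0], other.span[1])
            break
    failing = [k for k in MANDATORY_CRITERIA if not criteria[k]]
    reasons = {"on_one_arm": "loop_overlap", "paired_fraction": "unpaired",
               "loop_size": "bad_loop", "stem_pairs": "short_stem",
               "length_class": "bad_length"}
    verdict = "accepted" if not failing else f"rejected({reasons[failing[0]]})"
    return HairpinCandidate("", cluster.chrom, cluster.strand, folded,
                            _to_genome(folded, ci), star_iv, criteria,
                            support, verdict, cluster)


def _expected_star_start(pt: PairTable, ci: tuple[int, int],
                         length: int) -> int | None:
    """Window coordinate of a canonical star cluster's 5' start.

    With 2-nt 3' overhangs the star's 5' start pairs two nt inside the
    candidate's 3' end, whichever arm the candidate occupies.
    """
    anchor = ci[1] - 2
    if not (1 <= anchor <= len(pt)) or not pt.is_paired(anchor):
        return None
    return pt.partner_of(anchor)


def _to_genome(folded: FoldedWindow, iv: tuple[int, int]) -> tuple[int, int]:
    """Window (strand-oriented) interval -> forward genome coordinates."""
    if folded.strand == SENSE:
        return folded.start + iv[0] - 1, folded.start + iv[1] - 1
    return folded.end - iv[1] + 1, folded.end - iv[0] + 1


def _to_window(folded: FoldedWindow, iv: tuple[int, int]
               ) -> tuple[int, int] | None:
    if folded.strand == SENSE:
        out = (iv[0] - folded.start + 1, iv[1] - folded.start + 1)
    else:
        out = (folded.end - iv[1] + 1, folded.end - iv[0] + 1)
    if out[0] < 1 or out[1] > len(folded.sequence):
        return None
    return out


def discover_novel(genome: Mapping[str, str],
                   genome_placements: Sequence[TagAlignment],
                   cfg: PipelineConfig = DEFAULT_CONFIG,
                   fold: FoldFunc = fold_hairpin,
                   min_cluster_weight: float = MIN_CLUSTER_WEIGHT,
                   ) -> list[HairpinCandidate]:
    """Full discovery pass: cluster, fold, evaluate, name accepted loci.

    Accepted candidates get serials miR-N1, miR-N2, ... in coordinate order.
    """
    clusters = cluster_genome_tags(genome_placements, cfg,
                                   min_weight=min_cluster_weight)
    candidates = []
    for c in clusters:
        folded = fold_window(genome, c, fold=fold)
        candidates.append(evaluate_candidate(c, folded, cfg,
                                             other_clusters=clusters))
    # one locus, one candidate: when the miR and its miR* both pass, keep
    # the heavier cluster as the miRNA and fold the lighter in as its star
    kept: list[HairpinCandidate] = []
    for cand in sorted(candidates,
                       key=lambda c: -(c.cluster.weighted_count
                                       if c.cluster else 0.0)):
        if not cand.accepted:
            continue
        for k in kept:
            if (k.chrom == cand.chrom and k.strand == cand.strand
                    and cand.mirna_interval[0] <= k.window.end
                    and cand.mirna_interval[1] >= k.window.start):
                cand.verdict = "rejected(duplex_partner)"
                if k.star_interval is None:
                    k.star_interval = cand.mirna_interval
                    k.star_support = True
                break
        else:
            kept.append(cand)
    serial = 0
    for cand in sorted(candidates,
                       key=lambda c: (c.chrom, c.mirna_interval[0])):
        if cand.accepted:
            serial += 1
            cand.name = f"miR-N{serial}"
    return candidates


def detect_antisense(antisense_placements: Sequence[TagAlignment],
                     hairpins: Mapping[str, HairpinRecord],
                     cfg: PipelineConfig = DEFAULT_CONFIG,
                     fold: FoldFunc = fold_hairpin,
                     min_cluster_weight: float = MIN_CLUSTER_WEIGHT,
                     ) -> list[HairpinCandidate]:
    """Antisense miRNA screen over known hairpin loci.

    The reverse complement of each hairpin with antisense tag clusters is
    folded and screened with the novel-locus criteria, plus the requirement
    of at least one tag on the opposing stem arm. Accepted candidates are
    named <parent>-as.
    """
    by_hairpin: dict[str, list[TagAlignment]] = defaultdict(list)
    for p in antisense_placements:
        if p.strand == ANTISENSE and p.target_id in hairpins:
            by_hairpin[p.target_id].append(p)
    out: list[HairpinCandidate] = []
    for hid, plist in sorted(by_hairpin.items()):
        h = hairpins[hid]
        genome_like = {hid: h.sequence}
        clusters = cluster_genome_tags(plist, cfg,
                                       min_weight=min_cluster_weight)
        if not clusters:
            continue
        main = max(clusters, key=lambda c: c.weighted_count)
        folded = fold_window(genome_like, main,
                             window_lengths=(len(h.sequence),), fold=fold)
        cand = evaluate_candidate(main, folded, cfg, other_clusters=clusters)
        # opposing-arm support: any antisense tag on the other side of the loop
        as_struct = HairpinRecord(hid + "-as", folded.sequence,
                                  folded.structure)
        pt = pair_table(as_struct)
        opposing = False
        if pt.loop_interval is not None:
            ci = folded.cluster_interval
            on_5p = ci[1] < pt.loop_interval[0]
            for p in plist:
                iv = _to_window(folded, (p.start, p.end))
                if iv is None:
                    continue
                if on_5p and iv[0] > pt.loop_interval[1]:
                    opposing = True
                elif not on_5p and iv[1] < pt.loop_interval[0]:
                    opposing = True
        cand.criteria["opposing_tag"] = opposing
        if cand.accepted and not opposing:
            cand.verdict = "rejected(no_opposing_tag)"
        if cand.accepted:
            cand.name = f"{hid}-as"
        out.append(cand)
    return out


def write_candidate_outputs(candidates: Sequence[HairpinCandidate],
                            bed_path, tsv_path, fasta_path=None,
                            structure_path=None) -> None:
    """BED of candidate loci + TSV criteria report (+ optional FASTA/fold)."""
    from pathlib import Path
    bed_lines, tsv_lines = [], []
    crit_names = sorted({k for c in candidates for k in c.criteria})
    tsv_lines.append("name\tchrom\tstart\tend\tstrand\tverdict\t"
                     "star_support\t" + "\t".join(crit_names))
    fa_lines, db_lines = [], []
    for c in candidates:
        s, e = c.mirna_interval
        strand = "+" if c.strand == SENSE else "-"
        name = c.name or "."
        if c.accepted:
            bed_lines.append(f"{c.chrom}\t{s - 1}\t{e}\t{name}\t0\t{strand}")
            fa_lines += [f">{name}", c.window.sequence]
            db_lines += [f">{name}", c.window.structure]
        tsv_lines.append("\t".join(
            [name, c.chrom, str(s), str(e), strand, c.verdict,
             str(c.star_support)]
            + [str(c.criteria.get(k, "")) for k in crit_names]))
    Path(bed_path).write_text("\n".join(bed_lines) + "\n")
    Path(tsv_path).write_text("\n".join(tsv_lines) + "\n")
    if fasta_path:
        Path(fasta_path).write_text("\n".join(fa_lines) + "\n")
    if structure_path:
        Path(structure_path).write_text("\n".join(db_lines) + "\n")
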