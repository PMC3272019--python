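"""Tag collapsing, alignment to hairpins/genome, and MMR resolution.

A *tag* is a unique read sequence; its count is the number of reads sharing
it. Tags are aligned in nucleotide space to both strands of every hairpin
(and, for the leftovers, to the genome) allowing up to ``max_mismatches``
substitutions. The Mismatch-and-Multimapping Resolver (MMR) then reduces
each tag's placement list to a weighted set:

1. placements with the fewest mismatches survive (a perfect hit silences
   all mismatch hits);
2. sense hairpin placements outrank antisense ones for weighting (antisense
   placements are kept unweighted for the antisense screen);
3. survivors share the tag's count in equal fractional weights 1/k;
4. survivors lying on hairpins that are sequence-identical over the placed
   interval are flagged ``identical-locus`` so reports can aggregate them.

The policy is deterministic; it is echoed into output headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

from .reference import HairpinRecord, normalize_seq, revcomp, to_rna

logger = logging.getLogger(__name__)

SENSE = "sense"
ANTISENSE = "antisense"

MMR_POLICY = ("min-mismatch wins; sense-over-antisense; equal weights 1/k; "
              "identical-locus ties flagged")


@dataclass(frozen=True)
class Tag:
    """A collapsed read: unique sequence plus its read count."""

    sequence: str
    count: int
    library_id: str = "lib1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))
        if self.count < 1:
            raise ValueError("tag count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TagAlignment:
    """One placement of a tag on a hairpin or chromosome.

    ``start``/``end`` are 1-based inclusive on the target's forward strand.
    ``mismatches`` lists (position_in_tag 1-based, ref_base, tag_base).
    ``weight`` is the fraction of the tag's count carried by this placement
    after MMR (1.0 before resolution).
    """

    tag: Tag
    target_id: str
    start: int
    end: int
    strand: str
    mismatches: tuple[tuple[int, str, str], ...] = ()
    weight: float = 1.0
    flags: frozenset[str] = frozenset()

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)

    @property
    def weighted_count(self) -> float:
        return self.weight * self.tag.count


def collapse_reads(reads: Iterable, min_len: int = 15, max_len: int = 35,
                   library_id: str = "lib1") -> tuple[list[Tag], int]:
    """Collapse a read stream to unique tags with summed counts.

    ``reads`` may be a path to FASTA/FASTQ, an iterable of sequence strings,
    or Bio.SeqRecord objects. Returns (tags sorted by descending count,
    number of reads dropped by the length filter).
    """
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
        reads = (str(rec.seq) for rec in SeqIO.parse(str(path), fmt))
    counts: dict[str, int] = {}
    dropped = 0
    total = 0
    for rec in reads:
        seq = normalize_seq(rec if isinstance(rec, str) else str(rec.seq))
        total += 1
        if not (min_len <= len(seq) <= max_len):
            dropped += 1
            continue
        counts[seq] = counts.get(seq, 0) + 1
    if total == 0:
        logger.warning("collapse_reads: empty input")
    tags = [Tag(seq, c, library_id) for seq, c in counts.items()]
    tags.sort(key=lambda t: (-t.count, t.sequence))
    return tags, dropped


def _occurrences(tag_seq: str, ref_seq: str, max_mm: int) -> list[tuple[int, tuple]]:
    """All placements of ``tag_seq`` in ``ref_seq`` with <= max_mm mismatches.

    Returns (0-based start, mismatch tuple) pairs. Exact hits come from
    substring search; 1-mismatch hits from single-substitution variant
    search (exact for max_mm == 1); higher allowances fall back to a sliding
    Hamming scan.
    """
    hits: dict[int, tuple] = {}
    pos = ref_seq.find(tag_seq)
    while pos != -1:
        hits[pos] = ()
        pos = ref_seq.find(tag_seq, pos + 1)
    if max_mm == 1:
        for i, base in enumerate(tag_seq):
            for alt in "ACGT":
                if alt == base:
                    continue
                var = tag_seq[:i] + alt + tag_seq[i + 1:]
                pos = ref_seq.find(var)
                while pos != -1:
                    if pos not in hits:
                        hits[pos] = ((i + 1, alt, base),)
                    pos = ref_seq.find(var, pos + 1)
    elif max_mm > 1:
        n, m = len(ref_seq), len(tag_seq)
        for pos in range(n - m + 1):
            if pos in hits:
                continue
            window = ref_seq[pos:pos + m]
            mm = [(k + 1, window[k], tag_seq[k])
                  for k in range(m) if window[k] != tag_seq[k]]
            if 0 < len(mm) <= max_mm:
                hits[pos] = tuple(mm)
    return sorted(hits.items())


def _place_on_target(tag: Tag, target_id: str, ref_seq: str,
                     max_mm: int) -> list[TagAlignment]:
    """Place a tag on both strands of one reference sequence.

    Antisense placements report forward-strand coordinates; the mismatch
    positions stay in tag coordinates (position 1 = tag 5' end).
    """
    out = []
    n = len(ref_seq)
    m = len(tag)
    if m > n:
        return out
    for pos0, mm in _occurrences(tag.sequence, ref_seq, max_mm):
        out.append(TagAlignment(tag, target_id, pos0 + 1, pos0 + m, SENSE,
                                mismatches=mm))
    rc = revcomp(ref_seq)
    for pos0, mm in _occurrences(tag.sequence, rc, max_mm):
        # position pos0 on the reverse strand maps to forward n-pos0-m+1
        out.append(TagAlignment(tag, target_id, n - pos0 - m + 1, n - pos0,
                                ANTISENSE, mismatches=mm))
    return out


def align_to_hairpins(tags: Sequence[Tag],
                      hairpins: Mapping[str, HairpinRecord],
                      max_mismatches: int = 1) -> list[TagAlignment]:
    """All placements of each tag on both strands of every hairpin."""
    placements = []
    for tag in tags:
        for hid, h in hairpins.items():
            placements.extend(_place_on_target(tag, hid, h.sequence,
                                               max_mismatches))
    return placements


def align_to_genome(tags_unmapped: Sequence[Tag],
                    genome: Mapping[str, str],
                    max_mismatches: int = 1,
                    multimap_cap: int = 10) -> tuple[list[TagAlignment], list[Tag]]:
    """Place hairpin-unmapped tags on the genome (both strands).

    Tags with more than ``multimap_cap`` placements are discarded as
    repetitive and returned separately.
    """
    placements: list[TagAlignment] = []
    repetitive: list[Tag] = []
    genome = {chrom: normalize_seq(seq) for chrom, seq in genome.items()}
    for tag in tags_unmapped:
        mine: list[TagAlignment] = []
        for chrom, seq in genome.items():
            mine.extend(_place_on_target(tag, chrom, seq, max_mismatches))
            if len(mine) > multimap_cap:
                break
        if len(mine) > multimap_cap:
            repetitive.append(tag)
            logger.info("discarding repetitive tag %s (> %d placements)",
                        tag.sequence, multimap_cap)
        else:
            placements.extend(mine)
    return placements, repetitive


def _identical_locus_groups(placements: list[TagAlignment],
                            refs: Mapping[str, str]) -> set[int]:
    """Indices of placements tied with another on an identical-sequence locus."""
    flagged: set[int] = set()
    segs = []
    for p in placements:
        seq = refs.get(p.target_id)
        if seq is None:
            segs.append(None)
            continue
        seg = seq[p.start - 1:p.end]
        segs.append(seg if p.strand == SENSE else revcomp(seg))
    for i in range(len(placements)):
        for j in range(i + 1, len(placements)):
            if (segs[i] is not None and segs[i] == segs[j]
                    and placements[i].target_id != placements[j].target_id):
                flagged.update((i, j))
    return flagged


def mmr_resolve(placements: Iterable[TagAlignment],
                reference_seqs: Mapping[str, str] | None = None,
                ) -> list[TagAlignment]:
    """Resolve per-tag placement lists into weighted survivors.

    See the module docstring for the policy. ``reference_seqs`` (target id ->
    sequence) enables the identical-locus flag; without it the flag is only
    set when tied placements share coordinates on equally named targets.
    Idempotent: resolving resolved placements changes nothing.
    """
    by_tag: dict[tuple[str, str], list[TagAlignment]] = {}
    for p in placements:
        by_tag.setdefault((p.tag.sequence, p.tag.library_id), []).append(p)
    resolved: list[TagAlignment] = []
    for plist in by_tag.values():
        candidates = [p for p in plist if p.strand == SENSE] or plist
        min_mm = min(p.n_mismatches for p in candidates)
        survivors = [p for p in candidates if p.n_mismatches == min_mm]
        k = len(survivors)
        flagged = (_identical_locus_groups(survivors, reference_seqs)
                   if reference_seqs and k > 1 else set())
        for i, p in enumerate(survivors):
            flags = set(p.flags)
            flags.discard("identical-locus")
            if i in flagged:
                flags.add("identical-locus")
            resolved.append(replace(p, weight=1.0 / k,
                                    flags=frozenset(flags)))
    resolved.sort(key=lambda p: (p.target_id, p.start, p.tag.sequence))
    return resolved


# --- mismatch classification -------------------------------------------------

CLEAN = "clean"


@dataclass(frozen=True)
class MismatchClass:
    """Mismatch category of one resolved placement.

    ``kind`` is ``clean``, ``nta`` (3'-terminal non-templated addition; the
    added base in ``detail``, RNA alphabet) or ``internal_mismatch``
    (``detail`` like ``A-to-G``, ref-to-tag in RNA alphabet; an A-to-I
    editing event manifests as A-to-G).
    """

    kind: str
    detail: str = ""

    def __str__(self) -> str:
        return self.kind if not self.detail else f"{self.kind}({self.detail})"


def classify_mismatch(placement: TagAlignment) -> MismatchClass:
    """Classify one placement: clean / nta(base) / internal substitution."""
    if not placement.mismatches:
        return MismatchClass(CLEAN)
    # single-mismatch regime: inspect the (first) mismatch
    pos, ref_base, tag_base = placement.mismatches[0]
    if pos == len(placement.tag):
        return MismatchClass("nta", to_rna(tag_base))
    return MismatchClass("internal_mismatch",
                         f"{to_rna(ref_base)}-to-{to_rna(tag_base)}")


def classify_mismatches(placements: Iterable[TagAlignment]
                        ) -> dict[str, MismatchClass]:
    """Per-tag mismatch class over resolved placements (keyed by sequence)."""
    out: dict[str, MismatchClass] = {}
    for p in placements:
        cls = classify_mismatch(p)
        prev = out.get(p.tag.sequence)
        if prev is None or (prev.kind != CLEAN and cls.kind == CLEAN):
            out[p.tag.sequence] = cls
    return out


def write_placement_table(placements: Sequence[TagAlignment],
                          path: str | Path,
                          header_lines: Sequence[str] = ()) -> None:
    """Write a TSV placement table (policy echoed in the header)."""
    lines = [f"# mmr_policy: {MMR_POLICY}"]
    lines += list(header_lines)
    lines.append("tag_seq\tcount\ttarget\tstart\tend\tstrand\t"
                 "n_mismatch\tweight\tflags")
    for p in placements:
        lines.append("\t".join(map(str, (
            p.tag.sequence, p.tag.count, p.target_id, p.start, p.end,
            p.strand, p.n_mismatches, f"{p.weight:.6g}",
            ",".join(sorted(p.flags)) or "."))))
    Path(path).write_text("\n".join(lines) + "\n")
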