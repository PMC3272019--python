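"""Seed extraction, simplified target scanning and set-overlap enrichment.

The seed (miRNA nucleotides 2-8) is the primary determinant of target
recognition, so a 5' isomiR — whose position-1 shifts by its offset —
carries a shifted seed and a potentially disjoint target repertoire.

The UTR scan here is an exact 7-mer reverse-complement match and is
labelled as such in all outputs: it is NOT TargetScan (no context scoring,
no conservation). Set-overlap (Venn) reports compare the target
repertoires of two variants, with optional per-term hypergeometric
enrichment within each subset, Benjamini-Hochberg corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig, DEFAULT_CONFIG
from .reference import normalize_seq, revcomp, to_rna

SCAN_METHOD = "exact 7-mer reverse-complement seed match (not TargetScan)"


@dataclass(frozen=True)
class SeedSequence:
    """Seed (positions 2-8) of one miRNA variant, RNA alphabet."""

    mirna_id: str
    bases: str
    variant_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.bases) != 7:
            raise ValueError("seed must be 7 nt")


def extract_seed(mature_sequence: str, variant_offset: int = 0,
                 mirna_id: str = "", seed_interval: tuple[int, int] = (2, 8),
                 ) -> SeedSequence:
    """Seed of the variant starting ``variant_offset`` nt into the canonical
    mature sequence (positive offsets shift the start 3'-ward)."""
    seq = to_rna(normalize_seq(mature_sequence))
    lo, hi = seed_interval
    start = lo - 1 + variant_offset
    end = hi + variant_offset
    if start < 0 or end > len(seq):
        raise ValueError(
            f"variant sequence too short for seed positions {lo}-{hi} "
            f"at offset {variant_offset:+d}")
    return SeedSequence(mirna_id, seq[start:end], variant_offset)


def scan_utrs(seed: SeedSequence, utrs: Mapping[str, str] | str | Path,
              ) -> set[str]:
    """Ids of UTR sequences containing >= 1 exact site for ``seed``.

    A site is the exact reverse complement of the seed (7-mer match between
    miRNA positions 2-8 and the mRNA). ``utrs`` is an id->sequence mapping
    or a FASTA path.
    """
    if isinstance(utrs, (str, Path)):
        utrs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(utrs), "fasta")}
    site = revcomp(normalize_seq(seed.bases))
    return {uid for uid, seq in utrs.items()
            if site in normalize_seq(seq)}


def expected_hit_rate(seed_len: int, utr_len: int) -> float:
    """Closed-form chance a random UTR contains >= 1 exact site:
    1 - (1 - 4^-k)^(L - k + 1)."""
    windows = max(utr_len - seed_len + 1, 0)
    return 1.0 - (1.0 - 4.0 ** -seed_len) ** windows


@dataclass
class TermEnrichment:
    term: str
    subset: str
    k: int          # annotated ids in subset
    n_subset: int
    K: int          # annotated ids in universe
    N: int
    p_value: float
    p_adjusted: float = 1.0
    significant: bool = False


@dataclass
class OverlapReport:
    """Venn counts of two id sets plus optional term enrichment."""

    a_only: set[str]
    b_only: set[str]
    shared: set[str]
    enrichment: list[TermEnrichment]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.a_only), len(self.b_only), len(self.shared)


def overlap_report(set_a: Iterable[str], set_b: Iterable[str],
                   annotation: Mapping[str, Iterable[str]] | None = None,
                   universe: Iterable[str] | None = None,
                   cfg: PipelineConfig = DEFAULT_CONFIG) -> OverlapReport:
    """Venn split of two target sets with per-term enrichment per subset.

    Enrichment: hypergeometric over-representation of each annotation term
    within each subset (A-only / B-only / shared) against the id universe
    (default: all annotated-or-member ids), BH-corrected across all
    (term, subset) tests, significant at ``cfg.alpha``.
    """
    A, B = set(set_a), set(set_b)
    report = OverlapReport(A - B, B - A, A & B, [])
    if annotation is None:
        return report
    if universe is None:
        universe = set(annotation) | A | B
    universe = set(universe)
    if not universe:
        raise ValueError("empty id universe")
    term_ids: dict[str, set[str]] = {}
    for uid, terms in annotation.items():
        if uid in universe:
            for t in terms:
                term_ids.setdefault(t, set()).add(uid)
    N = len(universe)
    tests: list[TermEnrichment] = []
    for sub_name, subset in (("A_only", report.a_only),
                             ("B_only", report.b_only),
                             ("shared", report.shared)):
        n = len(subset)
        for term, ids in sorted(term_ids.items()):
            K = len(ids)
            k = len(ids & subset)
            # P(X >= k) under sampling n of N with K marked
            p = float(hypergeom.sf(k - 1, N, K, n))
            tests.append(TermEnrichment(term, sub_name, k, n, K, N, p))
    if tests:
        rejected, adjusted, _, _ = multipletests(
            [t.p_value for t in tests], alpha=cfg.alpha, method="fdr_bh")
        for t, adj, rej in zip(tests, adjusted, rejected):
            t.p_adjusted = float(adj)
            t.significant = bool(rej)
    report.enrichment = tests
    return report
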