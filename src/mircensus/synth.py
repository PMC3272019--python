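"""Synthetic references and small-RNA libraries with planted ground truth.

The generator emulates the statistical structure of a deep small-RNA
library from a single cell type, as the census assumes it:

* precursor hairpins built as perfect stem-loops (30-bp stem, 10-nt loop)
  with mature/star or -5p/-3p products placed in canonical Drosha/Dicer
  geometry (2-nt 3' overhangs), optionally with planted structural
  distortions;
* log-normally distributed hairpin abundances with arm-biased expression;
* rare 5' offsets (default 95% canonical) and frequent 3' offsets
  (default 48% canonical, i.e. 52% 3' variability) giving a modal tag
  length of 22 nt;
* single-base non-templated 3' additions (A/U-rich) and uniform internal
  substitution errors;
* planted extreme-isomiR tag sets, antisense loci and novel genomic
  hairpins embedded in a random genome.

Everything is driven by one :class:`SimSpec` and a seed; outputs are
deterministic and the :class:`TruthTable` (written before reads are drawn)
records every planted parameter for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .reference import (HairpinRecord, MatureAnnotation, Reference, arm_of,
                        revcomp)

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# canonical geometry of the synthetic stem-loop (1-based, 76 nt).
# The stem leaves 4 nt between the mature 3' end and the loop so that 3'
# offsets up to +4 stay on the arm; the star interval realises 2-nt 3'
# overhangs against the mature product: star = (n+1-(e5-2), n+1-s5+2).
STEM = 33
LOOP = 10
MATURE_5P = (8, 29)
STAR_3P = (50, 71)
# G:U wobble pairs are planted at every third eligible stem position; they
# keep the declared fold fully paired while breaking the sequence symmetry
# between the two strands (so antisense transcripts are distinguishable
# from sense tags of the opposite arm, as they are on real hairpins).
WOBBLE_EVERY = 3


def _default_five_prime() -> dict[int, float]:
    return {-3: 0.002, -2: 0.004, -1: 0.009, 0: 0.950,
            1: 0.020, 2: 0.010, 3: 0.005}


def _default_three_prime() -> dict[int, float]:
    return {-4: 0.02, -3: 0.04, -2: 0.08, -1: 0.13, 0: 0.48,
            1: 0.13, 2: 0.07, 3: 0.03, 4: 0.02}


def _default_nta_bases() -> dict[str, float]:
    return {"A": 0.4, "T": 0.4, "C": 0.1, "G": 0.1}


@dataclass(frozen=True)
class EmirPlanting:
    """A planted extreme-isomiR tag set on a known hairpin."""
    hairpin_index: int
    interval: tuple[int, int] = (12, 30)   # on the 5' arm, outside +/-3 nt
    fraction: float = 0.30                 # share of the hairpin's reads


@dataclass(frozen=True)
class AntisensePlanting:
    """Reads transcribed antisense to a known hairpin (both arms covered)."""
    hairpin_index: int
    n_reads: int = 500
    major_arm_fraction: float = 0.8


@dataclass(frozen=True)
class NovelPlanting:
    """A novel hairpin embedded in the genome with miR and miR* reads."""
    n_reads: int = 400
    star_fraction: float = 0.30


@dataclass(frozen=True)
class SimSpec:
    """All knobs of the generator; defaults are the study conditions."""

    n_hairpins: int = 20
    n_reads: int = 50_000
    abundance_sigma: float = 1.0           # log-normal spread of hairpin use
    abundance_weights: tuple[float, ...] | None = None
    arm_fraction_biased: float = 0.85      # 5'-arm share, mature/star hairpins
    arm_fraction_symmetric: float = 0.5    # 5'-arm share, -5p/-3p hairpins
    five_prime_dist: dict[int, float] = field(default_factory=_default_five_prime)
    three_prime_dist: dict[int, float] = field(default_factory=_default_three_prime)
    nta_rate: float = 0.06
    nta_base_dist: dict[str, float] = field(default_factory=_default_nta_bases)
    error_rate: float = 0.01
    genome_len: int = 1_000_000
    emir_plantings: tuple[EmirPlanting, ...] = (EmirPlanting(0),)
    antisense_plantings: tuple[AntisensePlanting, ...] = (AntisensePlanting(1),)
    novel_plantings: tuple[NovelPlanting, ...] = (NovelPlanting(), NovelPlanting())
    hairpin_overrides: dict[int, dict] = field(default_factory=dict)
    duplicate_of: dict[int, int] = field(default_factory=dict)
    first_base: str | None = None          # plant the mature 5' base
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for dist in (self.five_prime_dist, self.three_prime_dist,
                     self.nta_base_dist):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("probability vectors must sum to 1")
        for p in self.emir_plantings:
            if not 0.0 <= p.fraction <= 1.0:
                raise ValueError("planting fractions must lie in [0, 1]")


@dataclass
class TruthRow:
    """Planted parameters of one hairpin (written before simulation)."""
    hairpin_id: str
    pattern: str                 # mature_star | p5_p3
    arm_fraction_5p: float
    five_prime_dist: dict[int, float]
    three_prime_dist: dict[int, float]
    nta_rate: float
    error_rate: float
    expected_reads: float


@dataclass
class TruthTable:
    hairpins: dict[str, TruthRow] = field(default_factory=dict)
    emirs: list[dict] = field(default_factory=list)
    antisense: list[dict] = field(default_factory=list)
    novel_loci: list[dict] = field(default_factory=list)
    provenance: list[tuple] = field(default_factory=list)  # per-read rows


@dataclass
class SyntheticReference:
    reference: Reference
    genome: dict[str, str]
    truth: TruthTable
    novel_records: list[HairpinRecord] = field(default_factory=list)


def _random_hairpin(rng: np.random.Generator,
                    first_base: str | None = None,
                    distort_drosha: int = 0) -> tuple[str, str]:
    """One 70-nt stem-loop (sequence, dot-bracket).

    ``distort_drosha`` = k plants a symmetrical internal loop of 2k nt
    straddling the Drosha cleavage boundary (positions just outside the
    mature 5' start and their partners).
    """
    side5 = [BASES[i] for i in rng.integers(0, 4, STEM)]
    if first_base is not None:
        side5[MATURE_5P[0] - 1] = first_base
    loop = [BASES[i] for i in rng.integers(0, 4, LOOP)]
    side3 = [_COMPLEMENT[b] for b in reversed(side5)]
    wobble = {"G": "T", "T": "G"}    # G:U pairs, declared paired
    n_eligible = 0
    for p in range(STEM):
        if side5[p] in wobble:
            n_eligible += 1
            if n_eligible % WOBBLE_EVERY == 1:
                side3[STEM - 1 - p] = wobble[side5[p]]
    seq = side5 + loop + side3
    struct = ["("] * STEM + ["."] * LOOP + [")"] * STEM
    n = len(seq)
    for k in range(distort_drosha):
        pos = MATURE_5P[0] - 1 - k          # 1-based, outside the mature 5' end
        partner = n + 1 - pos
        cur = seq[partner - 1]
        choices = [b for b in BASES if b != cur and _COMPLEMENT[seq[pos - 1]] != b]
        seq[partner - 1] = choices[rng.integers(0, len(choices))]
        struct[pos - 1] = "."
        struct[partner - 1] = "."
    return "".join(seq), "".join(struct)


def build_reference(spec: SimSpec,
                    distortions: Mapping[int, int] | None = None,
                    ) -> SyntheticReference:
    """Construct hairpins, annotations, genome and the truth table.

    Even-indexed hairpins carry a mature(5' arm)/star(3' arm) annotation
    pair, odd-indexed ones a -5p/-3p pair, both in canonical 2-nt-overhang
    geometry. ``distortions`` maps hairpin index -> symmetrical-loop half
    size planted at the Drosha boundary. Novel loci are embedded in a
    random genome at recorded coordinates.
    """
    rng = np.random.default_rng(spec.rng_seed)
    distortions = dict(distortions or {})
    if MATURE_5P[1] - MATURE_5P[0] + 1 > STEM:
        raise ValueError("miRNA longer than stem arm")
    hairpins: dict[str, HairpinRecord] = {}
    annotations: list[MatureAnnotation] = []
    truth = TruthTable()
    seqs: list[str] = []
    for i in range(spec.n_hairpins):
        hid = f"syn-mir-{i + 1}"
        if i in spec.duplicate_of:
            src = seqs[spec.duplicate_of[i]]
            structure = hairpins[f"syn-mir-{spec.duplicate_of[i] + 1}"].structure
            seq = src
        else:
            seq, structure = _random_hairpin(rng, spec.first_base,
                                             distortions.get(i, 0))
        seqs.append(seq)
        hairpins[hid] = HairpinRecord(hid, seq, structure)
        pattern = "mature_star" if i % 2 == 0 else "p5_p3"
        if pattern == "mature_star":
            annotations.append(MatureAnnotation(hid, f"miR-{i + 1}",
                                                *MATURE_5P,
                                                annotation_class="mature"))
            annotations.append(MatureAnnotation(hid, f"miR-{i + 1}*",
                                                *STAR_3P,
                                                annotation_class="star"))
        else:
            annotations.append(MatureAnnotation(hid, f"miR-{i + 1}-5p",
                                                *MATURE_5P,
                                                annotation_class="p5"))
            annotations.append(MatureAnnotation(hid, f"miR-{i + 1}-3p",
                                                *STAR_3P,
                                                annotation_class="p3"))
    genome_arr = rng.integers(0, 4, spec.genome_len)
    genome_seq = "".join(BASES[i] for i in genome_arr)
    novel_records: list[HairpinRecord] = []
    genome_list = list(genome_seq)
    n_novel = len(spec.novel_plantings)
    for j, planting in enumerate(spec.novel_plantings):
        seq, structure = _random_hairpin(rng)
        # one locus per equal genome segment, jittered, clear of the edges
        seg = max((spec.genome_len - 2000) // max(n_novel, 1), 200)
        start = 1000 + j * seg + int(rng.integers(0, max(seg - 200, 1)))
        genome_list[start - 1:start - 1 + len(seq)] = list(seq)
        rec = HairpinRecord(f"novel-{j + 1}", seq, structure)
        novel_records.append(rec)
        truth.novel_loci.append({
            "name": rec.id, "chrom": "chr1", "start": start,
            "end": start + len(seq) - 1,
            "mirna": (start + MATURE_5P[0] - 1, start + MATURE_5P[1] - 1),
            "star": (start + STAR_3P[0] - 1, start + STAR_3P[1] - 1),
            "n_reads": planting.n_reads,
            "star_fraction": planting.star_fraction})
    genome = {"chr1": "".join(genome_list)}

    if spec.abundance_weights is not None:
        weights = np.asarray(spec.abundance_weights, dtype=float)
    else:
        weights = rng.lognormal(0.0, spec.abundance_sigma, spec.n_hairpins)
    weights = weights / weights.sum()
    for i, hid in enumerate(hairpins):
        o = spec.hairpin_overrides.get(i, {})
        pattern = "mature_star" if i % 2 == 0 else "p5_p3"
        af = o.get("arm_fraction",
                   spec.arm_fraction_biased if pattern == "mature_star"
                   else spec.arm_fraction_symmetric)
        truth.hairpins[hid] = TruthRow(
            hid, pattern, af,
            dict(o.get("five_prime_dist", spec.five_prime_dist)),
            dict(o.get("three_prime_dist", spec.three_prime_dist)),
            o.get("nta_rate", spec.nta_rate),
            o.get("error_rate", spec.error_rate),
            float(weights[i] * spec.n_reads))
    for p in spec.emir_plantings:
        if p.hairpin_index < spec.n_hairpins:
            truth.emirs.append({"hairpin_id": f"syn-mir-{p.hairpin_index + 1}",
                                "interval": p.interval,
                                "fraction": p.fraction})
    for p in spec.antisense_plantings:
        if p.hairpin_index < spec.n_hairpins:
            truth.antisense.append({
                "hairpin_id": f"syn-mir-{p.hairpin_index + 1}",
                "n_reads": p.n_reads,
                "major_arm_fraction": p.major_arm_fraction})
    ref = Reference(hairpins, annotations)
    # resolve annotation arms as load_reference would
    resolved = []
    for a in ref.annotations:
        arm = arm_of((a.start, a.end), ref.pair_table_of(a.hairpin_id))
        resolved.append(MatureAnnotation(a.hairpin_id, a.name, a.start, a.end,
                                         arm=arm,
                                         annotation_class=a.annotation_class))
    ref.annotations = resolved
    ref._by_hairpin.clear()
    for a in resolved:
        ref._by_hairpin.setdefault(a.hairpin_id, []).append(a)
    return SyntheticReference(ref, genome, truth, novel_records)


def _draw(rng: np.random.Generator, dist: Mapping) -> object:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _mutate(read: str, rng: np.random.Generator) -> str:
    if len(read) < 2:
        return read
    pos = int(rng.integers(0, len(read) - 1))       # spare the 3' terminus
    alt = BASES[(BASES.index(read[pos]) + 1 + rng.integers(0, 3)) % 4]
    return read[:pos] + alt + read[pos + 1:]


def simulate_library(synref: SyntheticReference, spec: SimSpec,
                     ) -> tuple[list[str], TruthTable]:
    """Draw the read list (sequences) per the spec; fully deterministic.

    Per-read provenance rows (source, arm/interval, offsets, nta, error)
    are appended to the truth table. Planted antisense and novel-locus
    reads are drawn on top of ``n_reads`` hairpin reads.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    truth = synref.truth
    hairpin_ids = list(synref.reference.hairpins)
    weights = np.array([truth.hairpins[h].expected_reads
                        for h in hairpin_ids])
    weights = weights / weights.sum()
    reads: list[str] = []
    emir_by_hid = {e["hairpin_id"]: e for e in truth.emirs}
    counts = rng.multinomial(spec.n_reads, weights)
    for hid, n in zip(hairpin_ids, counts):
        row = truth.hairpins[hid]
        h = synref.reference.hairpins[hid]
        emir = emir_by_hid.get(hid)
        for _ in range(int(n)):
            if emir is not None and rng.random() < emir["fraction"]:
                s, e = emir["interval"]
                reads.append(h.sequence[s - 1:e])
                truth.provenance.append((hid, "emir", s, e, "", False))
                continue
            on_5p = rng.random() < row.arm_fraction_5p
            base_iv = MATURE_5P if on_5p else STAR_3P
            off5 = int(_draw(rng, row.five_prime_dist))
            off3 = int(_draw(rng, row.three_prime_dist))
            s = max(1, base_iv[0] + off5)
            e = min(len(h.sequence), base_iv[1] + off3)
            read = h.sequence[s - 1:e]
            nta = ""
            if rng.random() < row.nta_rate:
                templated = h.sequence[e] if e < len(h.sequence) else ""
                dist = {b: p for b, p in spec.nta_base_dist.items()
                        if b != templated and p > 0}
                nta = str(_draw(rng, dist))
                read += nta
            err = False
            if rng.random() < row.error_rate:
                read = _mutate(read, rng)
                err = True
            reads.append(read)
            truth.provenance.append((hid, "5p" if on_5p else "3p",
                                     off5, off3, nta, err))
    for planting in truth.antisense:
        h = synref.reference.hairpins[planting["hairpin_id"]]
        rc = revcomp(h.sequence)
        n = len(h.sequence)
        # antisense products mirror the sense intervals in rc coordinates
        iv_major = (n - STAR_3P[1] + 1, n - STAR_3P[0] + 1)
        iv_minor = (n - MATURE_5P[1] + 1, n - MATURE_5P[0] + 1)
        for _ in range(planting["n_reads"]):
            iv = (iv_major if rng.random() < planting["major_arm_fraction"]
                  else iv_minor)
            reads.append(rc[iv[0] - 1:iv[1]])
            truth.provenance.append((planting["hairpin_id"], "antisense",
                                     iv[0], iv[1], "", False))
    for locus in truth.novel_loci:
        chrom = synref.genome[locus["chrom"]]
        for _ in range(locus["n_reads"]):
            iv = (locus["star"] if rng.random() < locus["star_fraction"]
                  else locus["mirna"])
            reads.append(chrom[iv[0] - 1:iv[1]])
            truth.provenance.append((locus["name"], "novel",
                                     iv[0], iv[1], "", False))
    return reads, truth


def write_fastq(reads: Sequence[str], path: str | Path) -> None:
    lines = []
    for i, seq in enumerate(reads, start=1):
        lines += [f"@read{i}", seq, "+", "I" * len(seq)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_reference_files(synref: SyntheticReference, outdir: str | Path
                          ) -> dict[str, Path]:
    """Write hairpin FASTA, dot-bracket, annotation TSV, genome FASTA and
    truth TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = synref.reference
    paths = {
        "hairpins": outdir / "hairpins.fa",
        "structures": outdir / "hairpins.db",
        "annotations": outdir / "annotations.tsv",
        "genome": outdir / "genome.fa",
        "truth": outdir / "truth_hairpins.tsv",
        "truth_loci": outdir / "truth_loci.tsv",
    }
    paths["hairpins"].write_text("\n".join(
        f">{h.id}\n{h.sequence}" for h in ref.hairpins.values()) + "\n")
    paths["structures"].write_text("\n".join(
        f">{h.id}\n{h.structure}" for h in ref.hairpins.values()) + "\n")
    paths["annotations"].write_text("\n".join(
        f"{a.hairpin_id}\t{a.name}\t{a.start}\t{a.end}\t{a.annotation_class}"
        for a in ref.annotations) + "\n")
    paths["genome"].write_text(
        "\n".join(f">{c}\n{s}" for c, s in synref.genome.items()) + "\n")
    rows = ["hairpin_id\tpattern\tarm_fraction_5p\tnta_rate\terror_rate"
            "\texpected_reads\tfive_prime_dist\tthree_prime_dist"]
    for r in synref.truth.hairpins.values():
        rows.append("\t".join(map(str, (
            r.hairpin_id, r.pattern, r.arm_fraction_5p, r.nta_rate,
            r.error_rate, round(r.expected_reads, 3),
            r.five_prime_dist, r.three_prime_dist))))
    paths["truth"].write_text("\n".join(rows) + "\n")
    rows = ["kind\tname\tdetail"]
    for e in synref.truth.emirs:
        rows.append(f"emir\t{e['hairpin_id']}\t{e}")
    for a in synref.truth.antisense:
        rows.append(f"antisense\t{a['hairpin_id']}\t{a}")
    for n in synref.truth.novel_loci:
        rows.append(f"novel\t{n['name']}\t{n}")
    paths["truth_loci"].write_text("\n".join(rows) + "\n")
    return paths
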