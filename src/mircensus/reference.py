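"""Hairpin reference model: sequences, secondary structures, annotations.

Parses the precursor FASTA, the per-hairpin dot-bracket structure file and
the mature/star annotation table, validates them against each other, and
exposes the coordinate and base-pairing queries every downstream stage uses.

Coordinates are 1-based inclusive on the hairpin 5'->3' axis throughout.
Sequences are stored in the DNA alphabet (U -> T) and reported in RNA where
a display calls for it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
LOOP_SPANNING = "loop_spanning"

_ANNOTATION_CLASSES = ("mature", "star", "p5", "p3", "none")


def normalize_seq(seq: str) -> str:
    """Uppercase and map RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class ReferenceError(ValueError):
    """Raised when reference inputs are inconsistent."""


@dataclass(frozen=True)
class HairpinRecord:
    """A precursor hairpin: sequence, declared fold, optional genomic locus."""

    id: str
    sequence: str
    structure: str
    locus: tuple[str, int, int, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))
        if len(self.structure) != len(self.sequence):
            raise ReferenceError(
                f"{self.id}: structure length {len(self.structure)} != "
                f"sequence length {len(self.sequence)}")
        depth = 0
        for ch in self.structure:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ReferenceError(f"{self.id}: unbalanced brackets")
            elif ch != ".":
                raise ReferenceError(f"{self.id}: illegal structure char {ch!r}")
        if depth != 0:
            raise ReferenceError(f"{self.id}: unbalanced brackets")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairTable:
    """Base-pair partners of one hairpin (1-based; 0 = unpaired).

    ``loop_interval`` is the unpaired span enclosed by the innermost pair of
    the longest stem, i.e. the terminal loop. ``multi_loop`` marks structures
    containing more than one hairpin loop (tolerated with a warning).
    """

    partner: tuple[int, ...]  # index 0 unused; partner[i] for position i
    loop_interval: tuple[int, int] | None
    multi_loop: bool = False

    def __len__(self) -> int:
        return len(self.partner) - 1

    def partner_of(self, pos: int) -> int:
        return self.partner[pos]

    def is_paired(self, pos: int) -> bool:
        return self.partner[pos] != 0


@dataclass(frozen=True)
class MatureAnnotation:
    """One annotated product (mature/star/-5p/-3p) on a hairpin."""

    hairpin_id: str
    name: str
    start: int
    end: int
    arm: str = ""
    annotation_class: str = "none"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ReferenceError(
                f"{self.name}: bad interval ({self.start},{self.end})")
        if self.annotation_class not in _ANNOTATION_CLASSES:
            raise ReferenceError(
                f"{self.name}: unknown class {self.annotation_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Reference:
    """Validated hairpin set with annotation indices and cached pair tables."""

    hairpins: dict[str, HairpinRecord]
    annotations: list[MatureAnnotation]
    rejected: list[tuple[str, str]] = field(default_factory=list)
    _pair_tables: dict[str, PairTable] = field(default_factory=dict, repr=False)
    _by_hairpin: dict[str, list[MatureAnnotation]] = field(
        default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for a in self.annotations:
            self._by_hairpin.setdefault(a.hairpin_id, []).append(a)

    def pair_table_of(self, hairpin_id: str) -> PairTable:
        if hairpin_id not in self._pair_tables:
            self._pair_tables[hairpin_id] = pair_table(self.hairpins[hairpin_id])
        return self._pair_tables[hairpin_id]

    def annotations_of(self, hairpin_id: str) -> list[MatureAnnotation]:
        return self._by_hairpin.get(hairpin_id, [])

    def annotations_on_arm(self, hairpin_id: str, arm: str) -> list[MatureAnnotation]:
        pt = self.pair_table_of(hairpin_id)
        return [a for a in self.annotations_of(hairpin_id)
                if arm_of((a.start, a.end), pt) == arm]


def read_structures(path: str | Path) -> dict[str, str]:
    """Read a 2-line-per-record dot-bracket file (``>id`` then structure)."""
    structures: dict[str, str] = {}
    current: str | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            current = line[1:].split()[0]
        else:
            if current is None:
                raise ReferenceError(f"{path}: structure line before any id")
            # tolerate a trailing folding score in parentheses with spaces
            structures[current] = line.split(" ")[0]
            current = None
    return structures


def _read_annotation_tsv(path: str | Path) -> list[MatureAnnotation]:
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise ReferenceError(f"{path}: need 5 columns, got {line!r}")
        hid, name, start, end, cls = parts[:5]
        out.append(MatureAnnotation(hid, name, int(start), int(end),
                                    annotation_class=cls))
    return out


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def _read_annotation_gff3(path: str | Path) -> list[MatureAnnotation]:
    out = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 9 or cols[2] != "miRNA":
            continue
        attrs = dict(_GFF_ATTR.findall(cols[8]))
        hid = attrs.get("Derives_from", cols[0])
        name = attrs.get("Name", attrs.get("ID", "miRNA"))
        cls = attrs.get("Class", "none")
        if cls == "none":
            lname = name.lower()
            if lname.endswith("*"):
                cls = "star"
            elif lname.endswith("-5p"):
                cls = "p5"
            elif lname.endswith("-3p"):
                cls = "p3"
            else:
                cls = "mature"
        out.append(MatureAnnotation(hid, name, int(cols[3]), int(cols[4]),
                                    annotation_class=cls))
    return out


def load_reference(hairpin_fasta: str | Path,
                   structure_file: str | Path,
                   annotation_file: str | Path) -> Reference:
    """Load and cross-validate the hairpin reference.

    Records whose structure is missing, of mismatched length or with
    unbalanced brackets are rejected (collected in ``Reference.rejected``
    with a reason), as are annotations referencing unknown hairpins or
    exceeding hairpin bounds.
    """
    structures = read_structures(structure_file)
    hairpins: dict[str, HairpinRecord] = {}
    rejected: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(hairpin_fasta), "fasta"):
        sid = rec.id
        if sid not in structures:
            rejected.append((sid, "no structure"))
            continue
        try:
            hairpins[sid] = HairpinRecord(sid, str(rec.seq), structures[sid])
        except ReferenceError as exc:
            rejected.append((sid, str(exc)))
    path = str(annotation_file)
    if path.endswith((".gff", ".gff3")):
        raw_annotations = _read_annotation_gff3(path)
    else:
        raw_annotations = _read_annotation_tsv(path)
    annotations = []
    for a in raw_annotations:
        if a.hairpin_id not in hairpins:
            rejected.append((a.name, f"unknown hairpin {a.hairpin_id}"))
            continue
        if a.end > len(hairpins[a.hairpin_id]):
            rejected.append((a.name, "annotation outside hairpin"))
            continue
        annotations.append(a)
    for sid, reason in rejected:
        logger.warning("rejected %s: %s", sid, reason)
    ref = Reference(hairpins, annotations, rejected)
    # resolve annotation arms now so invalid structures surface early
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
    return ref


def pair_table(h: HairpinRecord) -> PairTable:
    """Build the base-pair partner table of a hairpin from its dot-bracket.

    The terminal loop is the unpaired span enclosed by the innermost pair of
    the longest stem; if the structure contains several hairpin loops the
    longest such span is chosen and the table flagged ``multi_loop``.
    """
    n = len(h)
    partner = [0] * (n + 1)
    stack: list[int] = []
    for i, ch in enumerate(h.structure, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            partner[i] = j
            partner[j] = i
    # hairpin loops: innermost pairs (i,j) with no paired position inside
    loops: list[tuple[int, int]] = []
    for i in range(1, n + 1):
        j = partner[i]
        if j > i and all(partner[k] == 0 for k in range(i + 1, j)):
            loops.append((i + 1, j - 1))
    if not loops:
        logger.warning("%s: no base pairs, loop undefined", h.id)
        return PairTable(tuple(partner), None)
    loops.sort(key=lambda iv: (iv[1] - iv[0], iv[0]))
    best = loops[-1]
    multi = len(loops) > 1
    if multi:
        logger.warning("%s: %d hairpin loops, keeping longest %s",
                       h.id, len(loops), best)
    return PairTable(tuple(partner), best, multi_loop=multi)


def arm_of(interval: tuple[int, int] | MatureAnnotation, pt: PairTable) -> str:
    """Assign an interval to the 5' arm, 3' arm, or call it loop-spanning."""
    if isinstance(interval, MatureAnnotation):
        start, end = interval.start, interval.end
    else:
        start, end = interval
    if pt.loop_interval is None:
        return LOOP_SPANNING
    loop_start, loop_end = pt.loop_interval
    if end < loop_start:
        return FIVE_PRIME
    if start > loop_end:
        return THREE_PRIME
    return LOOP_SPANNING
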