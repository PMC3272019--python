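"""Secondary-structure prediction behind a dot-bracket contract.

The contract: ``fold(sequence) -> (dot_bracket, score)`` with higher scores
better. Two backends satisfy it:

* :func:`fold_hairpin` (default, self-contained) — a single-stem base-pair
  maximizer: the sequence is locally aligned against its own reverse
  complement (affine-free Smith–Waterman where a "match" is a Watson–Crick
  or G:U pair), the best non-overlapping segment pair becomes the stem and
  everything between the terminal loop. This deliberately models exactly
  the structure class the discovery stage tests for (one stem, one loop);
  random sequences produce short stems, so it doubles as a stringent
  negative control.
* :func:`fold_rnafold` — shells out to the ViennaRNA ``RNAfold`` binary if
  present (minimum-free-energy, score = -energy).

Both are deterministic.
"""

from __future__ import annotations

import shutil
import subprocess
from typing import Callable

import numpy as np

from .reference import normalize_seq

# Watson-Crick + wobble pairs in DNA alphabet (U stored as T)
_PAIR_SCORE = {("A", "T"): 2, ("T", "A"): 2,
               ("G", "C"): 3, ("C", "G"): 3,
               ("G", "T"): 1, ("T", "G"): 1}
# Penalties are deliberately harsh: pri-miRNA stems are near-contiguous
# helices, so interrupting a stem must cost more than a few extra pairs can
# buy back. This keeps the best "stem" of a random sequence short, which the
# discovery criteria rely on.
_MISMATCH = -4
_GAP = -7
MIN_LOOP = 3

FoldFunc = Callable[[str], tuple[str, float]]


def _pair_score(a: str, b: str) -> int:
    return _PAIR_SCORE.get((a, b), _MISMATCH)


def fold_hairpin(sequence: str) -> tuple[str, float]:
    """Best single stem-loop fold of ``sequence`` (dot-bracket, score).

    Smith-Waterman of the sequence against itself where cell (i, j) scores
    pairing base i with base j (i < j), restricted to j - i > MIN_LOOP so
    the loop is at least MIN_LOOP nt. The traceback yields the stem pairs;
    score is the alignment score (GC=3, AU=2, GU=1, mismatch/gap penalised).
    """
    seq = normalize_seq(sequence)
    n = len(seq)
    if n < MIN_LOOP + 2:
        return "." * n, 0.0
    # H[i][j]: best local alignment score of prefix ending at i (5' side)
    # with suffix starting at j (3' side), pairing outward-in.
    # Work on index arrays: a = seq[0..n-1], align a against reverse of a.
    H = np.zeros((n + 1, n + 1), dtype=np.int32)
    # trace: 0 stop, 1 diag(pair/mismatch), 2 up(gap in 3' side), 3 left
    T = np.zeros((n + 1, n + 1), dtype=np.int8)
    best = 0
    best_ij = (0, 0)
    for i in range(1, n + 1):          # position i (1-based) on 5' side
        # j indexes the reversed sequence: r_j = seq[n - j]
        for j in range(1, n - i - MIN_LOOP + 1):
            if n - j + 1 - i <= MIN_LOOP:   # enforce loop size
                continue
            diag = H[i - 1][j - 1] + _pair_score(seq[i - 1], seq[n - j])
            up = H[i - 1][j] + _GAP
            left = H[i][j - 1] + _GAP
            m = max(0, diag, up, left)
            H[i][j] = m
            if m == 0:
                T[i][j] = 0
            elif m == diag:
                T[i][j] = 1
            elif m == up:
                T[i][j] = 2
            else:
                T[i][j] = 3
            if m > best:
                best = m
                best_ij = (i, j)
    structure = ["."] * n
    i, j = best_ij
    while i > 0 and j > 0 and T[i][j] != 0:
        if T[i][j] == 1:
            if _pair_score(seq[i - 1], seq[n - j]) > 0:
                structure[i - 1] = "("
                structure[n - j] = ")"
            i, j = i - 1, j - 1
        elif T[i][j] == 2:
            i -= 1
        else:
            j -= 1
    return "".join(structure), float(best)


def fold_rnafold(sequence: str) -> tuple[str, float]:
    """Minimum-free-energy fold via the ViennaRNA ``RNAfold`` binary."""
    if shutil.which("RNAfold") is None:
        raise RuntimeError("RNAfold not on PATH")
    out = subprocess.run(["RNAfold", "--noPS"],
                         input=sequence + "\n", text=True,
                         capture_output=True, check=True).stdout
    line = out.splitlines()[1]
    db = line.split(" ")[0]
    energy = float(line[line.rfind("(") + 1:line.rfind(")")])
    return db, -energy


def paired_fraction(structure: str, start: int = 1,
                    end: int | None = None) -> float:
    """Fraction of positions in [start, end] (1-based incl.) that are paired."""
    if end is None:
        end = len(structure)
    span = structure[start - 1:end]
    return sum(c != "." for c in span) / len(span) if span else 0.0
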