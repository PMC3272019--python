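#!/usr/bin/env python
"""Seed shift of a prevalent 5' isomiR and its target-set consequences.

Takes the most 5'-isomiR-rich miRNA of the default study, extracts the
seeds (positions 2-8) of its canonical and +1 variants, scans a synthetic
3'UTR set (2,000 random 1-kb UTRs, a subset annotated with a function
term and seeded with extra sites for each variant) with the exact
7-mer-complement scan, and reports the Venn split of the two target sets
with per-term hypergeometric enrichment (Benjamini-Hochberg, p < 0.01).
The scan is an explicit simplification: exact seed matches only.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mircensus import synth
from mircensus.pipeline import run_census
from mircensus.reference import revcomp, to_rna
from mircensus.seedscan import (SCAN_METHOD, extract_seed, overlap_report,
                                scan_utrs)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
BASES = "ACGT"


def main() -> None:
    spec = synth.SimSpec(rng_seed=SEED)
    synref = synth.build_reference(spec)
    reads, _ = synth.simulate_library(synref, spec)
    result = run_census(reads, synref.reference, run_discovery=False)

    best = max((m for s in result.summaries.values()
                for m in s.mirnas.values() if m.total >= 150),
               key=lambda m: m.p5_isomir_fraction)
    h = synref.reference.hairpins[best.annotation.hairpin_id]
    mature = h.sequence[best.annotation.start - 1:best.annotation.end]
    seed_can = extract_seed(mature, 0, best.annotation.name)
    seed_iso = extract_seed(mature, 1, best.annotation.name + "+1")
    print(f"{best.annotation.name}: 5' isomiR fraction "
          f"{100 * best.p5_isomir_fraction:.1f}%")
    print(f"  canonical seed {seed_can.bases}   +1 seed {seed_iso.bases}")

    rng = np.random.default_rng(SEED)
    utrs, annotation = {}, {}
    for i in range(2000):
        seq = "".join(BASES[j] for j in rng.integers(0, 4, 1000))
        uid = f"utr{i}"
        # seed extra sites so each variant has a solid planted target set
        if i % 20 == 0:
            seq = seq[:500] + revcomp(seed_can.bases.replace("U", "T")) \
                + seq[507:]
        if i % 20 == 10:
            seq = seq[:500] + revcomp(seed_iso.bases.replace("U", "T")) \
                + seq[507:]
        utrs[uid] = seq
        annotation[uid] = ["cardio"] if i % 20 == 0 else []
    targets_can = scan_utrs(seed_can, utrs)
    targets_iso = scan_utrs(seed_iso, utrs)
    report = overlap_report(targets_can, targets_iso, annotation, utrs)
    a, b, shared = report.counts
    print(f"targets ({SCAN_METHOD}):")
    print(f"  canonical-only {a}   +1-only {b}   shared {shared}")
    pd.DataFrame([{
        "term": t.term, "subset": t.subset, "k": t.k, "n": t.n_subset,
        "K": t.K, "N": t.N, "p": t.p_value, "p_bh": t.p_adjusted,
        "significant": t.significant,
    } for t in report.enrichment]).to_csv(OUT / "seed_enrichment.tsv",
                                          sep="\t", index=False)
    for t in report.enrichment:
        if t.significant:
            print(f"  enriched: {t.term} in {t.subset} "
                  f"(k={t.k}/{t.n_subset}, BH p={t.p_adjusted:.2e})")


if __name__ == "__main__":
    main()
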