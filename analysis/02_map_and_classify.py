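#!/usr/bin/env python
"""Map the library to the hairpin reference and classify every tag.

Reads the files written by 01_simulate_library.py, collapses reads to tags,
aligns them to both strands of every hairpin (one mismatch allowed),
resolves mismatch/multimapping placements (MMR), applies the variant
taxonomy and writes: the weighted placement table, the per-tag feature
table, the per-miRNA summary (counts, 5'/3' isomiR %, long-tag %, flags)
and plain-text per-hairpin tag alignments.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from mircensus import DEFAULT_CONFIG, load_reference
from mircensus.isomir import global_isomir_rates, render_hairpin_alignment
from mircensus.pipeline import modal_generic_length, run_census
from mircensus.tagmap import write_placement_table

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ref = load_reference(DATA / "hairpins.fa", DATA / "hairpins.db",
                         DATA / "annotations.tsv")
    result = run_census(DATA / "library.fastq", ref, run_discovery=False)
    print(f"{len(result.tags)} tags ({result.dropped_reads} reads outside "
          f"15-35 nt), {len(result.resolved)} resolved placements")

    write_placement_table(result.resolved, OUT / "placements.tsv",
                          DEFAULT_CONFIG.header_lines())

    rows = [{
        "tag": c.placement.tag.sequence,
        "count": c.placement.tag.count,
        "hairpin": c.hairpin_id,
        "arm": c.arm,
        "label": c.label,
        "anchor": c.anchor.name if c.anchor else ".",
        "offset5": c.five_prime_offset,
        "offset3": c.three_prime_offset,
        "weight": c.placement.weight,
    } for c in result.calls]
    pd.DataFrame(rows).to_csv(OUT / "feature_calls.tsv", sep="\t",
                              index=False)

    mir_rows = []
    for hid, s in result.summaries.items():
        for name, m in s.mirnas.items():
            mir_rows.append({
                "miRNA": name, "hairpin": hid, "arm": m.annotation.arm,
                "class": m.annotation.annotation_class,
                "tags": round(m.total, 2),
                "p5_isomir_pct": round(100 * m.p5_isomir_fraction, 2),
                "p3_isomir_pct": round(100 * m.p3_isomir_fraction, 2),
                "long_pct": round(100 * m.long_fraction, 2),
                "flags": ",".join(sorted(m.flags)) or ".",
            })
    per_mirna = pd.DataFrame(mir_rows).sort_values("tags", ascending=False)
    per_mirna.to_csv(OUT / "per_mirna_summary.tsv", sep="\t", index=False)

    with open(OUT / "hairpin_alignments.txt", "w") as fh:
        for hid, s in result.summaries.items():
            calls = [c for c in result.calls if c.hairpin_id == hid]
            fh.write(f"== {hid} ==\n")
            fh.write(render_hairpin_alignment(ref.hairpins[hid],
                                              calls[:40]) + "\n\n")

    labels = Counter()
    for c in result.calls:
        labels[c.label] += c.weighted_count
    total = sum(labels.values())
    print("taxonomy split (% of weighted hairpin tags):")
    for label, w in labels.most_common():
        print(f"  {label:20s} {100 * w / total:6.2f}")
    rates = global_isomir_rates(result.summaries)
    print(f"5' isomiR tags (global): {100 * rates['p5_global']:.1f}%  "
          f"3' isomiR tags (global): {100 * rates['p3_global']:.1f}%")
    print(f"modal generic tag length: {modal_generic_length(result)} nt")


if __name__ == "__main__":
    main()
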