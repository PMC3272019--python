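import numpy as np
import pytest

from mircensus import synth
from mircensus.pipeline import run_census
from mircensus.reference import HairpinRecord, MatureAnnotation, Reference, arm_of


def make_toy70() -> tuple[HairpinRecord, Reference]:
    """70-nt hairpin with pair table i<->(71-i), loop 31-40, canonical
    mature (8,29) / star (44,65) annotations."""
    rng = np.random.default_rng(42)
    bases = "ACGT"
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    side5 = [bases[i] for i in rng.integers(0, 4, 30)]
    loop = [bases[i] for i in rng.integers(0, 4, 10)]
    seq = "".join(side5 + loop + [comp[b] for b in reversed(side5)])
    struct = "(" * 30 + "." * 10 + ")" * 30
    h = HairpinRecord("toy", seq, struct)
    anns = [MatureAnnotation("toy", "toy-miR", 8, 29, annotation_class="mature"),
            MatureAnnotation("toy", "toy-miR*", 44, 65, annotation_class="star")]
    ref = Reference({"toy": h}, anns)
    resolved = [MatureAnnotation(a.hairpin_id, a.name, a.start, a.end,
                                 arm=arm_of((a.start, a.end),
                                            ref.pair_table_of("toy")),
                                 annotation_class=a.annotation_class)
                for a in anns]
    ref.annotations = resolved
    ref._by_hairpin.clear()
    for a in resolved:
        ref._by_hairpin.setdefault(a.hairpin_id, []).append(a)
    return h, ref


@pytest.fixture(scope="session")
def toy70():
    return make_toy70()


@pytest.fixture(scope="session")
def default_library():
    """Default synthetic study (20 hairpins, 50k reads, seed 1), simulated
    once per session."""
    spec = synth.SimSpec(rng_seed=1)
    synref = synth.build_reference(spec)
    reads, truth = synth.simulate_library(synref, spec)
    return spec, synref, reads, truth


@pytest.fixture(scope="session")
def default_run(default_library):
    """Full census over the default synthetic study."""
    spec, synref, reads, truth = default_library
    result = run_census(reads, synref.reference, genome=synref.genome)
    return spec, synref, truth, result
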