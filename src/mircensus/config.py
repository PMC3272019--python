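"""Pipeline-wide thresholds and switches.

Every tunable the census uses lives in :class:`PipelineConfig` so that the
thresholds applied at each stage (generic window, expression floors, arm-bias
bounds, e-miR fraction, ...) are declared once and echoed into output headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds governing classification, filtering and testing.

    Attributes
    ----------
    generic_window : int
        Maximum |5' start offset| (nt) from an annotated miRNA 5' end for a
        tag to be called generic.
    min_expression : int
        Weighted-tag floor for a miRNA/hairpin to enter the main analyses.
    low_expression : int
        Relaxed floor used for cross-study comparative mode.
    bias_hi, bias_lo : float
        Arm-fraction bounds separating biased from symmetrical hairpin
        expression (strictly greater / strictly smaller).
    emir_min_fraction : float
        Minimum share of a hairpin's tags a non-generic (extreme isomiR)
        tag set must reach to be reported.
    long_tag_len : int
        Tags strictly longer than this many nt count as "long".
    seed_interval : tuple[int, int]
        1-based inclusive positions of the seed on a mature sequence.
    alpha : float
        Significance threshold for composition and enrichment tests.
    de_min_tags : int
        Per-library tag floor for differential-expression calls.
    de_fold : float
        Fold change that must be exceeded in every replicate pair.
    max_mismatches : int
        Alignment mismatch allowance.
    phase_min_fraction : float
        Share of weighted count the modal 5' start (+/- 1 nt) must hold for a
        tag set to count as well-phased.
    phase_min_tags : float
        Minimum weighted tags in a phased set.
    emir_len_range : tuple[int, int]
        Credible modal-length window (nt, inclusive) for e-miR calls.
    multimap_cap : int
        Genome placements above this count mark a tag as repetitive.
    distortion_window : int
        Nucleotides examined on each side of a cleavage boundary when
        classifying structural distortions.
    rng_seed : int
        Seed for any stochastic step (the core pipeline is deterministic).
    """

    generic_window: int = 3
    min_expression: int = 150
    low_expression: int = 25
    bias_hi: float = 0.80
    bias_lo: float = 0.20
    emir_min_fraction: float = 0.20
    long_tag_len: int = 24
    seed_interval: tuple[int, int] = (2, 8)
    alpha: float = 0.01
    de_min_tags: int = 1000
    de_fold: float = 2.0
    max_mismatches: int = 1
    phase_min_fraction: float = 0.50
    phase_min_tags: float = 10.0
    emir_len_range: tuple[int, int] = (18, 26)
    multimap_cap: int = 10
    distortion_window: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.bias_lo < self.bias_hi < 1.0):
            raise ValueError("require 0 < bias_lo < bias_hi < 1")
        if self.generic_window < 0:
            raise ValueError("generic_window must be >= 0")
        for name in ("min_expression", "low_expression", "de_min_tags",
                     "long_tag_len", "max_mismatches", "multimap_cap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def header_lines(self) -> list[str]:
        """Config echo for TSV output headers (one '# key=value' per line)."""
        return [f"# {k}={v}" for k, v in asdict(self).items()]


DEFAULT_CONFIG = PipelineConfig()
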