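"""Detected repeat element records (shared by detection, I/O and association)."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class InvertedRepeat:
    """A small stem-loop: arm2 reverse-complement-aligns onto arm1.

    All coordinates 0-based half-open. `extent` (arm1.start -> arm2.end) is the
    footprint used for the <200 bp size limit and for redundancy resolution.
    """

    arm1_start: int
    arm1_end: int
    arm2_start: int
    arm2_end: int
    mismatches: int
    gaps: int
    score: int

    def __post_init__(self):
        if not (self.arm1_start < self.arm1_end <= self.arm2_start < self.arm2_end):
            raise ValueError("inverted repeat arms must be ordered and non-overlapping")

    @property
    def stem_len(self) -> int:
        """Stem length = longer arm (alignment columns minus gaps in the other arm)."""
        return max(self.arm1_end - self.arm1_start, self.arm2_end - self.arm2_start)

    @property
    def loop_len(self) -> int:
        return self.arm2_start - self.arm1_end

    @property
    def start(self) -> int:
        return self.arm1_start

    @property
    def end(self) -> int:
        return self.arm2_end

    @property
    def extent(self) -> int:
        return self.arm2_end - self.arm1_start


@dataclass(frozen=True)
class TandemRepeat:
    """An array of >=2 adjacent approximate copies of a unit (the period)."""

    start: int
    end: int
    period: int
    copies: float
    consensus: str
    score: int

    def __post_init__(self):
        if len(self.consensus) != self.period:
            raise ValueError("consensus length must equal period")
        if self.end - self.start < 2 * self.period:
            raise ValueError("tandem array must span at least two copies")

    @property
    def extent(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeRepeatProfile:
    """Per-genome repeat summary feeding the lineage statistics.

    mean/max repeat size and mean intergenic distance are None when undefined
    (no repeats / fewer than two features).
    """

    genome_id: str
    group: object  # Group enum; kept loose to avoid an import cycle
    n_inverted: int
    n_tandem: int
    mean_repeat_size: float | None
    max_repeat_size: int | None
    genome_size: int
    mean_intergenic: float | None

    def __post_init__(self):
        if self.n_inverted < 0 or self.n_tandem < 0:
            raise ValueError("repeat counts must be non-negative")
        if self.genome_size <= 0:
            raise ValueError("genome size must be positive")
        if self.mean_intergenic is not None and self.mean_intergenic < 0:
            raise ValueError("mean intergenic distance must be non-negative")

    @property
    def tandem_majority(self) -> bool:
        """Strictly more tandem than inverted repeats."""
        return self.n_tandem > self.n_inverted


Repeat = InvertedRepeat | TandemRepeat


def repeat_kind(r: Repeat) -> str:
    return "inverted_repeat" if isinstance(r, InvertedRepeat) else "tandem_repeat"
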