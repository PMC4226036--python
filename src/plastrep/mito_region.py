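"""Decomposition of large composite tandem-repeat regions.

Mitochondrial genomes of several algae carry multi-kilobase repeat regions
built from a small set of repeat-unit classes arranged in patterns (e.g. the
B-A-A-A-B flanking domains around three ~1.5 kb tandem repeats). Given a unit
library (or one derived from the region itself), the region is tiled greedily
left to right: each window is assigned to the best-matching class at >= 80%
identity, or to a spacer otherwise, and the resulting class pattern plus the
region's share of the genome is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import AnnotatedGenome
from .sequtils import encode

CLASS_IDENTITY = 0.80  # unit classes share "strong, but rarely perfect" identity


@dataclass
class RepeatRegionDecomposition:
    region: tuple[int, int]
    units: list[tuple[str, int, int]] = field(default_factory=list)  # (label, start, end)
    class_consensus: dict[str, str] = field(default_factory=dict)
    pattern: str = ""
    genome_fraction: float = 0.0  # percent


def region_fraction(region_len: int, genome_len: int) -> float:
    """Region share of the genome, in percent."""
    if not (0 < region_len <= genome_len):
        raise ValueError("need 0 < region_len <= genome_len")
    return 100.0 * region_len / genome_len


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    if a.size != b.size or a.size == 0:
        return 0.0
    return float(((a == b) & (a != 4)).sum()) / a.size


def _auto_unit_library(region_seq: str) -> dict[str, str]:
    """Derive unit classes from the region's own tandem structure: the
    consensus of every detected tandem array, merged at >= 80% identity,
    labelled A, B, C... by decreasing unit length."""
    from .small_repeats import TRParams, find_tandem_repeats

    params = TRParams(min_score=30, max_period=min(2000, len(region_seq) // 2))
    consensi: list[str] = []
    for tr in find_tandem_repeats(region_seq, params):
        cand = tr.consensus
        merged = False
        for known in consensi:
            if len(known) == len(cand) and _identity(encode(known), encode(cand)) >= CLASS_IDENTITY:
                merged = True
                break
        if not merged:
            consensi.append(cand)
    consensi.sort(key=lambda s: (-len(s), s))
    return {chr(ord("A") + i): s for i, s in enumerate(consensi)}


def decompose_repeat_region(
    g: AnnotatedGenome,
    region: tuple[int, int],
    unit_library: dict[str, str] | None = None,
) -> RepeatRegionDecomposition:
    """Tile [region) with repeat-unit classes; greedy left-to-right, longest
    unit preferred on ties, windows below 80% identity become spacers."""
    start, end = region
    if not (0 <= start < end <= g.length):
        raise ValueError(f"region [{start},{end}) outside genome of length {g.length}")
    seq = g.sequence[start:end]
    library = unit_library if unit_library is not None else _auto_unit_library(seq)
    if not library:
        raise ValueError("no unit classes available (empty library / no tandem structure)")
    if end - start < min(len(s) for s in library.values()):
        raise ValueError("region shorter than the smallest unit")
    codes = encode(seq)
    units_by_len = sorted(library.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    enc_lib = {label: encode(s) for label, s in library.items()}

    units: list[tuple[str, int, int]] = []
    pattern: list[str] = []
    pos = 0
    spacer_start: int | None = None

    def flush_spacer(upto):
        nonlocal spacer_start
        if spacer_start is not None:
            units.append(("spacer", spacer_start, upto))
            spacer_start = None

    n = len(seq)
    while pos < n:
        best = None  # (identity, -unit_len, label)
        for label, unit in units_by_len:
            L = len(unit)
            if pos + L > n:
                continue
            ident = _identity(codes[pos : pos + L], enc_lib[label])
            # classes are tried longest-first, so a strict improvement rule
            # gives the longest unit preference on identity ties
            if ident >= CLASS_IDENTITY and (best is None or ident > best[0]):
                best = (ident, L, label)
        if best is None:
            if spacer_start is None:
                spacer_start = pos
            pos += 1
            continue
        flush_spacer(pos)
        _, L, label = best
        units.append((label, pos, pos + L))
        pattern.append(label)
        pos += L
    flush_spacer(n)

    return RepeatRegionDecomposition(
        region=(start, end),
        units=[(lbl, s + start, e + start) for lbl, s, e in sorted(units, key=lambda u: u[1])],
        class_consensus=dict(library),
        pattern="".join(pattern),
        genome_fraction=region_fraction(end - start, g.length),
    )
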