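"""Core record types: annotated organellar genomes and their gene features.

Coordinates are 0-based half-open throughout the package; conversion to the
1-based inclusive GFF3 convention happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

from .sequtils import gc_percent, normalize, revcomp


class Group(str, Enum):
    """Taxon grouping used by the lineage statistics.

    CASH = cryptophyte/alveolate/stramenopile/haptophyte algae (red-derived
    secondary plastids); "green" pools chlorophytes, streptophytes and
    chlorophyte-derived euglenids.
    """

    CASH = "CASH"
    RHODOPHYTE = "rhodophyte"
    GREEN = "green"
    OTHER = "other"


FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "misc")


@dataclass(frozen=True)
class GeneFeature:
    name: str
    kind: str  # one of FEATURE_KINDS
    start: int  # 0-based
    end: int  # half-open
    strand: str  # "+" or "-"
    locus_tag: str | None = None  # shared by the two parts of a split wraparound feature

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid feature interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """A circular-or-linear genome sequence with typed gene features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    group: Group = Group.OTHER

    def __post_init__(self):
        self.sequence = normalize(self.sequence)
        if isinstance(self.group, str):
            self.group = Group(self.group)
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.name))
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = self.length
        for f in self.features:
            if f.end > n:
                raise ValueError(
                    f"feature {f.name} [{f.start},{f.end}) exceeds genome length {n}"
                )

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def subsequence(self, start: int, end: int) -> str:
        """Extract [start, end); wraps around the origin on circular genomes."""
        n = self.length
        if 0 <= start <= end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise IndexError(f"[{start},{end}) outside linear genome of length {n}")
        start %= n
        end %= n
        if start < end:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]

    def feature_sequence(self, f: GeneFeature) -> str:
        s = self.sequence[f.start:f.end]
        return revcomp(s) if f.strand == "-" else s

    def gc_percent(self) -> float:
        return gc_percent(self.sequence)

    def rotated(self, shift: int) -> "AnnotatedGenome":
        """Circularly rotate so old coordinate `shift` becomes coordinate 0.

        Features that would straddle the new origin are split into two parts
        sharing a locus tag, mirroring what ingest does with wraparound
        features in annotation files.
        """
        if not self.circular:
            raise ValueError("cannot rotate a linear genome")
        n = self.length
        shift %= n
        seq = self.sequence[shift:] + self.sequence[:shift]
        feats: list[GeneFeature] = []
        for f in self.features:
            s = (f.start - shift) % n
            e = s + f.length
            if e <= n:
                feats.append(replace(f, start=s, end=e))
            else:
                tag = f.locus_tag or f.name
                feats.append(replace(f, start=s, end=n, locus_tag=tag))
                feats.append(replace(f, start=0, end=e - n, locus_tag=tag))
        return AnnotatedGenome(
            id=self.id, sequence=seq, circular=True, features=feats, group=self.group
        )


def genome_summary(g: AnnotatedGenome) -> dict:
    """Per-genome tallies matching the comparison-table columns.

    gc_percent is reported to one decimal; an all-N sequence flags GC as None.
    """
    try:
        gc = round(g.gc_percent(), 1)
    except ValueError:
        gc = None
    return {
        "id": g.id,
        "length": g.length,
        "gc_percent": gc,
        "n_cds": len(g.features_of_kind("CDS")),
        "n_trna": len(g.features_of_kind("tRNA")),
        "n_rrna": len(g.features_of_kind("rRNA")),
    }


def merge_wraparound(features: Iterable[GeneFeature], length: int) -> list[GeneFeature]:
    """Sort features and validate they fit within [0, length)."""
    out = sorted(features, key=lambda f: (f.start, f.end, f.name))
    for f in out:
        if f.end > length:
            raise ValueError(f"feature {f.name} outside genome of length {length}")
    return out
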