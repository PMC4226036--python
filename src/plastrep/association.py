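"""Gene-repeat association and its conservation across a genome panel.

A repeat is associated with a gene when the nearest boundaries of the two lie
within a search distance (default 300 bp) of either gene end, with no other
annotated CDS/tRNA/rRNA feature strictly between them. Repeats overlapping the
gene body count as distance-0 associations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import AnnotatedGenome, GeneFeature
from .repeats import Repeat, repeat_kind

DEFAULT_SEARCH_DISTANCE = 300
# genes the comparative survey queries by default
DEFAULT_GENE_SET = ("clpC", "psaB", "rpoC", "atpA", "rps10", "rbcS", "psbC")


@dataclass(frozen=True)
class RepeatGeneAssociation:
    genome: str
    gene: str
    repeat_index: int  # index into the repeat list passed to associate()
    repeat_type: str
    distance: int  # gene boundary to nearest repeat boundary, bp
    gene_end: str  # "5'", "3'" or "overlap"


def _interval_distance(f_start, f_end, r_start, r_end, n, circular):
    """(distance, side): minimal boundary-to-boundary separation between the
    gene and repeat footprints; side says which gene flank the repeat is on."""
    candidates = [(0, 0)] if max(f_start, r_start) < min(f_end, r_end) else []
    # rightward: repeat after the gene
    gap = r_start - f_end
    if circular:
        gap %= n
    if gap >= 0:
        candidates.append((gap, +1))
    # leftward: repeat before the gene
    gap = f_start - r_end
    if circular:
        gap %= n
    if gap >= 0:
        candidates.append((gap, -1))
    if not candidates:
        return None, 0
    return min(candidates)


def _feature_between(g: AnnotatedGenome, lo: int, hi: int, exclude: GeneFeature) -> bool:
    """Is any annotated feature strictly inside the open gap (lo, hi)?"""
    n = g.length
    if hi < lo:
        hi += n
    if hi <= lo:
        return False
    for f in g.features:
        if f is exclude:
            continue
        for shift in (0, n):
            s, e = f.start + shift, f.end + shift
            if s < hi and e > lo and not (s >= hi or e <= lo):
                # overlap with the open gap counts only if some part is strictly inside
                if min(e, hi) - max(s, lo) > 0:
                    return True
    return False


def associate(
    g: AnnotatedGenome,
    repeats: list[Repeat],
    search_distance: int = DEFAULT_SEARCH_DISTANCE,
) -> list[RepeatGeneAssociation]:
    """All (gene, repeat) pairs within search_distance of either gene end with
    no intervening feature; ordered by gene position then distance."""
    n = g.length
    out: list[RepeatGeneAssociation] = []
    for f in g.features:
        for idx, r in enumerate(repeats):
            # canonicalise into [0, n) + unwrapped footprint length
            r_start = r.start % n
            r_end = r_start + (r.end - r.start)
            dist, side = _interval_distance(f.start, f.end, r_start, r_end, n, g.circular)
            if dist is None or dist > search_distance:
                continue
            if dist > 0:
                if side > 0:
                    lo, hi = f.end, r_start if r_start >= f.end else r_start + n
                else:
                    lo, hi = r_end, f.start if f.start >= r_end else f.start + n
                if _feature_between(g, lo, hi, f):
                    continue
            if side == 0:
                gene_end = "overlap"
            else:
                downstream = side > 0
                if f.strand == "-":
                    downstream = not downstream
                gene_end = "3'" if downstream else "5'"
            out.append(
                RepeatGeneAssociation(
                    genome=g.id,
                    gene=f.name,
                    repeat_index=idx,
                    repeat_type=repeat_kind(r),
                    distance=int(dist),
                    gene_end=gene_end,
                )
            )
    out.sort(key=lambda a: (a.gene, a.distance, a.repeat_index))
    return out


def conservation_table(
    panel: list[tuple[AnnotatedGenome, list[Repeat]]],
    gene_list: tuple[str, ...] = DEFAULT_GENE_SET,
    search_distance: int = DEFAULT_SEARCH_DISTANCE,
) -> dict[str, dict]:
    """Per queried gene: in how many panel genomes carrying the gene is a
    repeat associated with it? fraction = with_repeat / carrying; None (and
    flagged) when no genome carries the gene."""
    table: dict[str, dict] = {
        gene: {"carrying": 0, "with_repeat": 0} for gene in gene_list
    }
    for g, repeats in panel:
        assoc_genes = {a.gene.lower() for a in associate(g, repeats, search_distance)}
        present = {f.name.lower() for f in g.features}
        for gene in gene_list:
            key = gene.lower()
            if key in present:
                table[gene]["carrying"] += 1
                if key in assoc_genes:
                    table[gene]["with_repeat"] += 1
    for gene, row in table.items():
        row["fraction"] = (
            row["with_repeat"] / row["carrying"] if row["carrying"] else None
        )
        row["flag"] = "gene absent from panel" if row["carrying"] == 0 else ""
    return table
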