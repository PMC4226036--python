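"""Location and characterisation of the large ribosomal inverted repeat (IR).

A plastid IR is found by genome self-comparison: exact k-mer seeds between the
forward sequence and its reverse complement are chained along anti-diagonals,
the best chain spanning an rRNA operon is kept, and its boundaries are
extended outward until windowed identity between the two copies drops below
90%. Divergence between the duplicated rRNA genes is counted from a global
alignment, each SNP and each single-base inserted/deleted position counted
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .genome import AnnotatedGenome, GeneFeature
from .sequtils import revcomp

SEED_K = 21
MIN_IR_SPAN = 1000  # smallest self-match accepted as a large IR
WINDOW = 50  # extension stops when identity over this window drops
WINDOW_IDENTITY = 0.90
CHAIN_MAX_GAP = 500  # max unseeded stretch bridged within one chain
CHAIN_MAX_DRIFT = 100  # max anti-diagonal drift (absorbs indels)


@dataclass
class LargeIRReport:
    present: bool
    copy_a: tuple[int, int] | None = None  # [start, end), forward strand
    copy_b: tuple[int, int] | None = None
    ir_length: int = 0
    per_gene_divergence: dict[str, tuple[int, int]] = field(default_factory=dict)
    isr_trnas: dict[str, list[str]] = field(default_factory=dict)
    isr_label: str | None = None  # "canonical" / "non-canonical"
    note: str = ""


def _divergence_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def count_copy_divergence(copy_a_seq: str, copy_b_seq: str) -> tuple[int, int]:
    """(snps, indels) between two copies of the same gene, both already in the
    same orientation. A g-base gap contributes g to the indel count."""
    if not copy_a_seq or not copy_b_seq:
        raise ValueError("cannot align an empty sequence")
    aligner = _divergence_aligner()
    aln = aligner.align(copy_a_seq, copy_b_seq)[0]
    counts = aln.counts()
    return int(counts.mismatches), int(counts.gaps)


# ---------------------------------------------------------------------------
# IR location


def _seed_chains(seq: str, k: int = SEED_K):
    """Chains of exact k-mer matches between seq and its reverse complement.

    A seed (i, q) means seq[i:i+k] == revcomp(seq[q:q+k]). True inverted
    copies put seeds on a common anti-diagonal i + q; chaining tolerates small
    drift (indels) and unseeded gaps (local divergence).
    """
    n = len(seq)
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    rc = revcomp(seq)
    seeds = []
    for j in range(n - k + 1):
        positions = index.get(rc[j : j + k])
        if not positions:
            continue
        q = n - j - k  # seq[q:q+k] is the partner arm on the forward strand
        for i in positions:
            if i + k <= q:  # keep one orientation, arms non-overlapping
                seeds.append((i, q))
    seeds.sort()
    chains: list[dict] = []
    for i, q in seeds:
        placed = False
        for ch in chains:
            if (
                0 <= i - ch["i_max"] <= CHAIN_MAX_GAP
                and abs((i + q) - ch["diag"]) <= CHAIN_MAX_DRIFT
                and q <= ch["q_max"] + k + CHAIN_MAX_GAP
            ):
                ch["i_max"] = max(ch["i_max"], i)
                ch["q_min"] = min(ch["q_min"], q)
                ch["q_max"] = max(ch["q_max"], q)
                ch["diag"] = i + q
                placed = True
                break
        if not placed:
            chains.append({"i_min": i, "i_max": i, "q_min": q, "q_max": q, "diag": i + q})
    out = []
    for ch in chains:
        a = (ch["i_min"], ch["i_max"] + k)
        b = (ch["q_min"], ch["q_max"] + k)
        if a[1] <= b[0]:  # disjoint copies only
            out.append((a, b))
    return out


def _extend_boundary(seq, a0, a1, b0, b1, n):
    """Push copy boundaries outward base by base while identity over the last
    WINDOW comparisons stays >= WINDOW_IDENTITY; trim back to the outermost
    matching pair."""

    def walk(pos_a, pos_b, step_a, step_b):
        history = []
        best = None
        a, b = pos_a, pos_b
        while 0 <= a < n and 0 <= b < n and a < b:  # copies may not collide
            m = seq[a] == revcomp(seq[b]) and seq[a] in "ACGT"
            history.append(m)
            if m:
                best = (a, b)
            recent = history[-WINDOW:]
            if len(recent) >= WINDOW and sum(recent) / len(recent) < WINDOW_IDENTITY:
                break
            if not m and len(history) >= 3 and not any(history[-3:]):
                break  # three straight mismatches: past the repeat edge
            a += step_a
            b += step_b
        return best

    # copyA left edge pairs with copyB right edge
    hit = walk(a0 - 1, b1, -1, +1)
    if hit:
        a0, b1 = hit[0], hit[1] + 1
    # copyA right edge pairs with copyB left edge
    hit = walk(a1, b0 - 1, +1, -1)
    if hit:
        a1, b0 = hit[0] + 1, hit[1]
    return a0, a1, b0, b1


def _rrna_intervals(g: AnnotatedGenome) -> list[tuple[str, int, int]]:
    """(name, start, end) per rRNA gene; wraparound split parts reassembled
    into one unwrapped interval (end may exceed genome length)."""
    feats = g.features_of_kind("rRNA")
    by_tag: dict[str, list[GeneFeature]] = {}
    singles = []
    for f in feats:
        if f.locus_tag:
            by_tag.setdefault(f"{f.name}:{f.locus_tag}", []).append(f)
        else:
            singles.append((f.name, f.start, f.end))
    for parts in by_tag.values():
        parts = sorted(parts, key=lambda f: f.start)
        if len(parts) == 2 and parts[0].start == 0 and parts[1].end == g.length:
            singles.append((parts[1].name, parts[1].start, parts[0].end + g.length))
        else:
            singles.extend((p.name, p.start, p.end) for p in parts)
    return singles


def _overlaps(span: tuple[int, int], start: int, end: int, n: int) -> bool:
    """Does feature [start, end) overlap span, modulo a circle of size n?"""
    s0, s1 = span
    for shift in (-n, 0, n):
        if max(s0, start + shift) < min(s1, end + shift):
            return True
    return False


def locate_large_ir(g: AnnotatedGenome) -> LargeIRReport:
    """Boundaries of the large ribosomal inverted repeat, if present.

    The maximal inverted self-match containing the 16S-23S operon is reported;
    present=False when no disjoint inverted self-match >= 1 kb spans an rRNA
    operon (e.g. a genome with a single operon copy).
    """
    n = g.length
    seq = g.sequence + (g.sequence if g.circular else "")
    rrnas = _rrna_intervals(g)
    has_operon_genes = any("16S" in r[0] for r in rrnas) and any(
        "23S" in r[0] for r in rrnas
    )
    candidates = []
    for (a0, a1), (b0, b1) in _seed_chains(seq):
        if a0 >= n:  # doubled-sequence duplicate
            continue
        if min(a1 - a0, b1 - b0) < MIN_IR_SPAN - 2 * WINDOW:
            continue
        a0, a1, b0, b1 = _extend_boundary(seq, a0, a1, b0, b1, len(seq))
        if min(a1 - a0, b1 - b0) < MIN_IR_SPAN:
            continue
        spans_operon = (
            any(_overlaps((a0, a1), s, e, n) for name, s, e in rrnas if "16S" in name)
            and any(_overlaps((a0, a1), s, e, n) for name, s, e in rrnas if "23S" in name)
        ) or (
            any(_overlaps((b0, b1), s, e, n) for name, s, e in rrnas if "16S" in name)
            and any(_overlaps((b0, b1), s, e, n) for name, s, e in rrnas if "23S" in name)
        )
        if has_operon_genes and not spans_operon:
            continue
        if not has_operon_genes:
            continue
        candidates.append((a1 - a0, (a0, a1), (b0, b1)))
    if not candidates:
        return LargeIRReport(present=False, note="No Inverted Repeat")
    # longest span wins; ties resolve to the leftmost copyA, then leftmost copyB
    # (the doubled-sequence alias of the same IR has the larger coordinates)
    _, copy_a, copy_b = max(candidates, key=lambda c: (c[0], -c[1][0], -c[2][0]))
    return LargeIRReport(
        present=True,
        copy_a=copy_a,
        copy_b=copy_b,
        ir_length=copy_a[1] - copy_a[0],
    )


# ---------------------------------------------------------------------------
# per-gene divergence and ISR classification


def _genes_in_span(g: AnnotatedGenome, span, kind: str):
    n = g.length
    out = []
    intervals = (
        _rrna_intervals(g)
        if kind == "rRNA"
        else [(f.name, f.start, f.end) for f in g.features_of_kind(kind)]
    )
    for name, s, e in intervals:
        for shift in (-n, 0, n):
            if span[0] <= s + shift and e + shift <= span[1]:
                out.append((name, s + shift, e + shift))
                break
    return out


def _project_span(copy_a_seq: str, copy_b_seq: str, rel_start: int, rel_end: int):
    """Map a copyA-relative interval onto copyB through a global alignment of
    copyA against revcomp(copyB); used when copyB lacks its own annotation."""
    aligner = _divergence_aligner()
    aln = aligner.align(copy_a_seq, revcomp(copy_b_seq))[0]
    a_blocks, b_blocks = aln.aligned

    def a_to_b(pos, right):
        for (as_, ae), (bs, be) in zip(a_blocks, b_blocks):
            if as_ <= pos < ae:
                return bs + (pos - as_)
            if pos < as_:
                return bs if not right else bs
        return b_blocks[-1][1] if len(b_blocks) else 0

    s = a_to_b(rel_start, right=False)
    e = a_to_b(rel_end - 1, right=True) + 1
    # back to copyB forward-strand coordinates
    m = len(copy_b_seq)
    return m - e, m - s


def divergence_report(g: AnnotatedGenome, report: LargeIRReport) -> LargeIRReport:
    """Fill per-rRNA-gene (snps, indels) between the two IR copies.

    Gene copies come from the annotation when both copies are annotated, else
    copyA's genes are projected onto copyB through the IR alignment. copyB
    genes are reverse-complemented into copyA orientation before alignment.
    """
    if not report.present:
        return report
    a_genes = _genes_in_span(g, report.copy_a, "rRNA")
    b_genes = _genes_in_span(g, report.copy_b, "rRNA")
    b_by_name = {name: (s, e) for name, s, e in b_genes}
    copy_a_seq = g.subsequence(*report.copy_a)
    copy_b_seq = g.subsequence(*report.copy_b)
    for name, s, e in a_genes:
        if name in b_by_name:
            bs, be = b_by_name[name]
            b_seq = g.subsequence(bs, be)
        else:
            rel = (s - report.copy_a[0], e - report.copy_a[0])
            bs, be = _project_span(copy_a_seq, copy_b_seq, *rel)
            b_seq = copy_b_seq[bs:be]
        a_seq = g.subsequence(s, e)
        report.per_gene_divergence[name] = count_copy_divergence(a_seq, revcomp(b_seq))
    return report


def classify_isr(g: AnnotatedGenome, report: LargeIRReport) -> LargeIRReport:
    """List the tRNAs inside each copy's 16S-23S intergenic spacer region and
    label the arrangement: canonical means both copies carry both tRNA-Ile and
    tRNA-Ala."""
    if not report.present:
        return report
    for label, span in (("A", report.copy_a), ("B", report.copy_b)):
        rr = _genes_in_span(g, span, "rRNA")
        r16 = [iv for iv in rr if "16S" in iv[0]]
        r23 = [iv for iv in rr if "23S" in iv[0]]
        if not r16 or not r23:
            report.note = (report.note + " ISR classification skipped: missing rRNA annotation").strip()
            return report
        lo = min(r16[0][2], r23[0][2])
        hi = max(r16[0][1], r23[0][1])
        trnas = [
            name
            for name, s, e in _genes_in_span(g, span, "tRNA")
            if lo <= s and e <= hi
        ]
        report.isr_trnas[label] = sorted(trnas)
    both = all(
        any("Ile" in t for t in report.isr_trnas[c]) and any("Ala" in t for t in report.isr_trnas[c])
        for c in ("A", "B")
    )
    report.isr_label = "canonical" if both else "non-canonical"
    return report


def analyze_large_ir(g: AnnotatedGenome) -> LargeIRReport:
    """locate -> per-gene divergence -> ISR classification, in one call."""
    report = locate_large_ir(g)
    if report.present:
        divergence_report(g, report)
        classify_isr(g, report)
    return report
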