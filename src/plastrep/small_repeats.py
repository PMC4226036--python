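"""Detection of small (<200 bp) inverted and tandem repeats.

The inverted-repeat detector solves the einverted optimisation problem
exactly: a local alignment of the sequence against its own reverse complement
in which position i may pair with position q = i + o only for pairing offsets
0 < o < max_extent (the <200 bp footprint limit), and in which the innermost
aligned pair leaves a loop of at most max_loop bases.  Because the offset band
is narrow, the dynamic programme is vectorised over offsets with numpy and
runs in O(max_extent * n) time and memory.

The tandem-repeat detector follows the Tandem Repeats Finder scoring
convention: the whole array is scored against a rolling consensus (match +2,
mismatch -7 by default), with candidate arrays located by period-wise
self-comparison and trimmed by maximal-segment decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import AnnotatedGenome
from .repeats import GenomeRepeatProfile, InvertedRepeat, TandemRepeat
from .sequtils import complement_codes, encode

WRAP_WINDOW = 400  # bases appended virtually when scanning circular genomes


@dataclass(frozen=True)
class IRParams:
    """einverted-default scoring: match +3, mismatch -4, gap -12, threshold 50."""

    match: int = 3
    mismatch: int = -4
    gap: int = -12
    min_score: int = 50
    max_extent: int = 200  # total footprint (arm1.start -> arm2.end) must be < this
    max_loop: int = 30

    def validate(self):
        if self.max_extent <= 2:
            raise ValueError("max_extent must exceed 2")
        if self.match <= 0 or self.mismatch >= 0 or self.gap >= 0:
            raise ValueError("match must be positive; mismatch and gap negative")
        if self.max_loop < 0:
            raise ValueError("max_loop must be non-negative")


@dataclass(frozen=True)
class TRParams:
    """Tandem Repeats Finder-default weights: match 2, mismatch 7, indel 7,
    minimum alignment score 50, maximum period 200.

    mismatch/indel are penalty magnitudes (TRF convention). The indel weight is
    carried for interface compatibility; the detector is substitution-aware but
    does not model indels within copies.
    """

    match: int = 2
    mismatch: int = 7
    indel: int = 7
    min_score: int = 50
    max_period: int = 200

    def validate(self):
        if self.max_period < 1:
            raise ValueError("max_period must be >= 1")
        if self.match <= 0 or self.mismatch <= 0:
            raise ValueError("weights must be positive magnitudes")


# ---------------------------------------------------------------------------
# inverted repeats


def _ir_dp_matrix(codes: np.ndarray, comp: np.ndarray, p: IRParams) -> np.ndarray:
    """H[o, i] = best score of a palindrome alignment whose innermost aligned
    column pairs positions (i, i+o); filled outside-in (decreasing offset)."""
    n = codes.size
    max_o = min(p.max_extent - 2, n - 1)
    H = np.zeros((max_o + 3, n), dtype=np.int16)
    gap = np.int16(p.gap)
    for o in range(max_o, 0, -1):
        L = n - o
        if L <= 0:
            continue
        a = codes[:L]
        b = comp[o:]
        s = np.where((a == b) & (a != 4), p.match, p.mismatch).astype(np.int16)
        best = np.maximum(np.int16(0), s)  # alignment may start at this pair
        # rows above max_o are all zero, which encodes "no prior alignment"
        diag = H[o + 2, : L - 1] + s[1:]
        best[1:] = np.maximum(best[1:], diag)
        best[1:] = np.maximum(best[1:], H[o + 1, : L - 1] + gap)
        best = np.maximum(best, H[o + 1, :L] + gap)
        H[o, :L] = best
    return H


def _ir_traceback(H, codes, comp, p: IRParams, o: int, i: int):
    """Reconstruct the maximal-scoring path ending at cell (o, i).

    Returns None when the end cell's score is produced by a trailing gap move;
    the properly terminated (higher-scoring) cell is reported instead.
    """
    n = codes.size
    n_rows = H.shape[0]

    def sub(o_, i_):
        return p.match if (codes[i_] == comp[i_ + o_] and codes[i_] != 4) else p.mismatch

    def val(o_, i_):
        if o_ < 1 or o_ >= n_rows or i_ < 0 or i_ + o_ > n - 1:
            return None
        return int(H[o_, i_])

    score = int(H[o, i])
    s0 = sub(o, i)
    if s0 == p.mismatch:
        # a stem must close on a paired column: a terminal mismatch is loop,
        # and if trimming it violates the loop cap the candidate is invalid
        return None
    d = val(o + 2, i - 1)
    if not (score == (d or 0) + s0):
        return None  # innermost column is a gap
    inner_o, inner_i = o, i
    mismatches = 0
    gaps = 0
    cur_o, cur_i = o, i
    while True:
        v = int(H[cur_o, cur_i])
        s_here = sub(cur_o, cur_i)
        d = val(cur_o + 2, cur_i - 1)
        if d is not None and d > 0 and v == d + s_here:
            if s_here == p.mismatch:
                mismatches += 1
            cur_o, cur_i = cur_o + 2, cur_i - 1
            continue
        if v == s_here:  # the alignment starts with this pair
            break
        g1 = val(cur_o + 1, cur_i - 1)
        if g1 is not None and g1 > 0 and v == g1 + p.gap:
            gaps += 1
            cur_o, cur_i = cur_o + 1, cur_i - 1
            continue
        g2 = val(cur_o + 1, cur_i)
        if g2 is not None and g2 > 0 and v == g2 + p.gap:
            gaps += 1
            cur_o = cur_o + 1
            continue
        break  # defensive; every positive cell has a producing move
    outer_o, outer_i = cur_o, cur_i
    return InvertedRepeat(
        arm1_start=outer_i, arm1_end=inner_i + 1,
        arm2_start=inner_i + inner_o, arm2_end=outer_i + outer_o + 1,
        mismatches=mismatches, gaps=gaps, score=score,
    )


def _overlap_redundant(a, b) -> bool:
    """Hits sharing >= 50% of the smaller footprint are redundant."""
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    return ov >= 0.5 * min(a.extent, b.extent)


def _select_nonredundant(hits):
    """Keep highest score; ties broken by smaller start, then shorter extent."""
    hits = sorted(
        hits,
        key=lambda r: (-r.score, r.start, r.extent, r.end, getattr(r, "arm1_end", 0)),
    )
    kept = []
    for h in hits:
        if any(_overlap_redundant(h, k) for k in kept):
            continue
        kept.append(h)
    return sorted(kept, key=lambda r: (r.start, r.end))


def _remap_circular(hits, n, shift):
    """Remap hits found in the appended wraparound window and deduplicate."""
    seen = {}
    for h in hits:
        if h.start >= n:
            h = shift(h, -n)
        key = (h.start % n, h.end % n)
        cur = seen.get(key)
        if cur is None or (h.score, -h.start) > (cur.score, -cur.start):
            seen[key] = h
    return list(seen.values())


def find_inverted_repeats(
    g: AnnotatedGenome | str, params: IRParams | None = None
) -> list[InvertedRepeat]:
    """All maximal-scoring, mutually non-redundant small inverted repeats,
    sorted by arm1 start; deterministic for fixed input and parameters."""
    p = params or IRParams()
    p.validate()
    seq = g.sequence if isinstance(g, AnnotatedGenome) else g
    circular = g.circular if isinstance(g, AnnotatedGenome) else False
    if not seq:
        return []
    scan = seq + seq[: min(WRAP_WINDOW, len(seq))] if circular else seq
    codes = encode(scan)
    comp = complement_codes(codes)
    H = _ir_dp_matrix(codes, comp, p)
    max_end_o = min(p.max_loop + 1, H.shape[0] - 1)
    cand = np.argwhere(H[1 : max_end_o + 1] >= p.min_score)
    hits = []
    for o_idx, i in cand:
        hit = _ir_traceback(H, codes, comp, p, int(o_idx) + 1, int(i))
        if hit is not None and hit.extent < p.max_extent:
            hits.append(hit)
    if circular:
        n = len(seq)

        def shift(h, d):
            return InvertedRepeat(
                arm1_start=h.arm1_start + d, arm1_end=h.arm1_end + d,
                arm2_start=h.arm2_start + d, arm2_end=h.arm2_end + d,
                mismatches=h.mismatches, gaps=h.gaps, score=h.score,
            )

        hits = _remap_circular(hits, n, shift)
    return _select_nonredundant(set(hits))


def ir_alignment_score(seq: str, ir: InvertedRepeat, params: IRParams | None = None) -> int:
    """Optimal alignment score of arm1 vs revcomp(arm2) under the same scheme
    (self-consistency check for reported hits)."""
    from Bio import Align

    from .sequtils import revcomp

    p = params or IRParams()
    a = seq[ir.arm1_start:ir.arm1_end]
    b = revcomp(seq[ir.arm2_start:ir.arm2_end])
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = p.match
    aligner.mismatch_score = p.mismatch
    aligner.open_gap_score = p.gap
    aligner.extend_gap_score = p.gap
    aligner.end_gap_score = p.gap
    return int(aligner.score(a, b))


# ---------------------------------------------------------------------------
# tandem repeats


def _maximal_segments(w: np.ndarray, threshold: float):
    """All disjoint maximal-scoring segments of w with score >= threshold
    (recursive Kadane decomposition; deterministic)."""
    S = np.concatenate(([0.0], np.cumsum(w)))
    out = []
    # (min_lo, lo, hi): candidate ends e in (lo, hi], starts s in [min_lo, e)
    stack = [(0, 0, w.size)]
    while stack:
        min_lo, lo, hi = stack.pop()
        if hi <= lo:
            continue
        pm = np.minimum.accumulate(S[min_lo : hi])  # pm[k] = min S[min_lo..min_lo+k]
        ends = np.arange(lo + 1, hi + 1)
        scores = S[ends] - pm[ends - 1 - min_lo]
        k = int(np.argmax(scores))
        if scores[k] < threshold:
            continue
        e = int(ends[k])
        s = min_lo + int(np.argmin(S[min_lo:e]))
        out.append((s, e, float(scores[k])))
        stack.append((e, e, hi))
        if s > min_lo:
            stack.append((min_lo, lo, s))
    return sorted(out)


def _consensus(codes: np.ndarray, start: int, end: int, period: int, phase: int) -> np.ndarray:
    """Column-majority consensus of region [start, end) at the given period;
    `phase` anchors column 0; ties resolve to the alphabetically first base."""
    cols = (np.arange(start, end) - phase) % period
    cons = np.empty(period, dtype=np.int8)
    region = codes[start:end]
    for c in range(period):
        vals = region[cols == c]
        vals = vals[vals != 4]
        if vals.size == 0:
            cons[c] = 0
            continue
        cons[c] = int(np.argmax(np.bincount(vals, minlength=4)))
    return cons


_DECODE = np.array(list("ACGTN"))


def _refine_tandem(codes, start, end, period, p: TRParams):
    """Trim a candidate region against its own consensus and rescore."""
    n = codes.size
    lo = max(0, start - period)
    hi = min(n, end + period)
    cons = _consensus(codes, start, end, period, start)
    match0 = (codes[lo:hi] == cons[(np.arange(lo, hi) - start) % period]) & (codes[lo:hi] != 4)
    scores = np.where(match0, float(p.match), -float(p.mismatch))
    segs = [t for t in _maximal_segments(scores, p.min_score) if t[1] - t[0] >= 2 * period]
    if not segs:
        return None
    s_off, e_off, _ = max(segs, key=lambda t: (t[2], -t[0]))
    s, e = lo + s_off, lo + e_off
    cons = _consensus(codes, s, e, period, s)
    match = (codes[s:e] == cons[(np.arange(s, e) - s) % period]) & (codes[s:e] != 4)
    score = int(p.match * int(match.sum()) - p.mismatch * int((~match).sum()))
    if score < p.min_score:
        return None
    return TandemRepeat(
        start=int(s), end=int(e), period=int(period),
        copies=round((e - s) / period, 2),
        consensus="".join(_DECODE[cons]), score=score,
    )


def find_tandem_repeats(
    g: AnnotatedGenome | str, params: TRParams | None = None
) -> list[TandemRepeat]:
    """Non-redundant tandem arrays, minimal period preferred, sorted by start."""
    p = params or TRParams()
    p.validate()
    seq = g.sequence if isinstance(g, AnnotatedGenome) else g
    circular = g.circular if isinstance(g, AnnotatedGenome) else False
    if not seq:
        return []
    scan = seq + seq[: min(WRAP_WINDOW, len(seq))] if circular else seq
    codes = encode(scan)
    n = codes.size
    raw: list[TandemRepeat] = []
    for period in range(1, min(p.max_period, n // 2) + 1):
        a = codes[: n - period]
        b = codes[period:]
        # light-penalty self-match scan locates candidate arrays; real scoring
        # happens against the consensus during refinement
        w = np.where((a == b) & (a != 4), float(p.match), -float(p.match))
        t_cand = max(2.0 * p.match, 0.5 * p.match * period)
        for s_off, e_off, _sc in _maximal_segments(w, t_cand):
            region_start, region_end = s_off, min(e_off + period, n)
            if region_end - region_start < 2 * period:
                continue
            hit = _refine_tandem(codes, region_start, region_end, period, p)
            if hit is not None:
                raw.append(hit)
    if circular:
        m = len(seq)

        def shift(h, d):
            return TandemRepeat(start=h.start + d, end=h.end + d, period=h.period,
                                copies=h.copies, consensus=h.consensus, score=h.score)

        raw = _remap_circular(raw, m, shift)
    # two-stage redundancy resolution:
    # 1. alternative descriptions of the same locus (mutual overlap >= 70% of
    #    the larger footprint) collapse to the minimal period — a doubled
    #    period absorbs per-copy mutations into its consensus and would
    #    otherwise outscore the true unit;
    # 2. remaining overlaps (>= 50% of the smaller footprint) keep the score.
    def same_locus(a, b):
        ov = min(a.end, b.end) - max(a.start, b.start)
        return ov > 0 and ov >= 0.7 * max(a.extent, b.extent)

    stage1: list[TandemRepeat] = []
    for h in sorted(set(raw), key=lambda r: (r.period, -r.score, r.start, r.extent)):
        if any(same_locus(h, k) for k in stage1):
            continue
        stage1.append(h)
    kept: list[TandemRepeat] = []
    for h in sorted(stage1, key=lambda r: (-r.score, r.start, r.extent, r.period)):
        if any(_overlap_redundant(h, k) for k in kept):
            continue
        kept.append(h)
    return sorted(kept, key=lambda r: (r.start, r.end))


# ---------------------------------------------------------------------------
# per-genome profile


def repeat_profile(
    g: AnnotatedGenome,
    irs: list[InvertedRepeat],
    trs: list[TandemRepeat],
) -> GenomeRepeatProfile:
    """Summary feeding the lineage statistics. Mean/max repeat size are None
    when the genome carries no detected repeat."""
    from .lineage_stats import mean_intergenic_distance

    sizes = [r.extent for r in irs] + [r.extent for r in trs]
    try:
        mig = mean_intergenic_distance(g)
    except ValueError:
        mig = None
    return GenomeRepeatProfile(
        genome_id=g.id,
        group=g.group,
        n_inverted=len(irs),
        n_tandem=len(trs),
        mean_repeat_size=(sum(sizes) / len(sizes)) if sizes else None,
        max_repeat_size=max(sizes) if sizes else None,
        genome_size=g.length,
        mean_intergenic=mig,
    )
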