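"""Signed reversal distance between shared gene orders.

The minimum number of segment reversals (with strand flips) transforming one
signed gene order into another is computed exactly from the breakpoint graph:

    d = n + 1 - c + h + f

where c counts the graph's alternating cycles, h counts hurdles (unoriented
components that do not separate other unoriented components), and f is 1 for a
fortress (an odd number of hurdles, all of them superhurdles). A breadth-first
search over the reversal graph (`reversal_distance_bfs`) provides an exact
reference for small permutations.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .genome import AnnotatedGenome


@dataclass(frozen=True)
class GeneOrder:
    """Signed permutation of gene symbols shared by two genomes (sign = strand)."""

    genes: tuple[tuple[str, int], ...]  # (symbol, +1/-1)

    def __post_init__(self):
        symbols = [s for s, _ in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError("gene order contains duplicate symbols")
        if any(sign not in (1, -1) for _, sign in self.genes):
            raise ValueError("every gene must carry a strand sign")

    @property
    def symbols(self) -> frozenset:
        return frozenset(s for s, _ in self.genes)


@dataclass(frozen=True)
class RearrangementResult:
    distance: int
    breakpoints: int
    cycles: int
    hurdles: int
    fortress: bool
    n: int


# ---------------------------------------------------------------------------
# extracting shared signed orders from annotations

_SYNONYMS = {
    # common plastid gene-name variants normalised to one symbol
    "rbcl": "rbcL", "rbcs": "rbcS", "psba": "psbA", "psbc": "psbC",
    "psbd": "psbD", "psab": "psaB", "clpc": "clpC", "atpa": "atpA",
    "rpoc": "rpoC", "rps10": "rps10",
}


def _normalize_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    key = name.strip().lower()
    table = dict(_SYNONYMS)
    if synonyms:
        table.update({k.lower(): v for k, v in synonyms.items()})
    return table.get(key, key)


def extract_shared_order(
    g_a: AnnotatedGenome,
    g_b: AnnotatedGenome,
    synonyms: dict[str, str] | None = None,
) -> tuple[GeneOrder, GeneOrder]:
    """Signed orders over the genes shared by both genomes.

    Gene names are case-normalised (synonym table applied); genes duplicated
    within either genome are dropped from both; circular orders are linearised
    at the lexicographically smallest shared gene, oriented so that anchor is
    positive.
    """

    def named_features(g):
        out = []
        for f in g.features:
            if f.kind == "misc":
                continue
            out.append((_normalize_name(f.name, synonyms), f))
        return out

    fa, fb = named_features(g_a), named_features(g_b)

    def unique_names(feats):
        counts: dict[str, int] = {}
        seen_tags = set()
        for name, f in feats:
            if f.locus_tag:  # split parts of one wraparound feature count once
                key = (name, f.locus_tag)
                if key in seen_tags:
                    continue
                seen_tags.add(key)
            counts[name] = counts.get(name, 0) + 1
        return {n for n, c in counts.items() if c == 1}

    shared = unique_names(fa) & unique_names(fb)
    if len(shared) < 2:
        raise ValueError(f"need >= 2 shared single-copy genes, found {len(shared)}")

    def order(feats, g):
        seen = set()
        entries = []
        for name, f in sorted(feats, key=lambda t: (t[1].start, t[1].end)):
            if name in shared and name not in seen:
                seen.add(name)
                entries.append((name, 1 if f.strand == "+" else -1))
        if not g.circular:
            return entries
        anchor = min(e[0] for e in entries)
        idx = next(i for i, e in enumerate(entries) if e[0] == anchor)
        entries = entries[idx:] + entries[:idx]
        if entries[0][1] == -1:  # flip the whole circle so the anchor is +
            entries = [(n, -s) for n, s in reversed(entries[1:])]
            entries.insert(0, (anchor, 1))
        return entries

    return GeneOrder(tuple(order(fa, g_a))), GeneOrder(tuple(order(fb, g_b)))


# ---------------------------------------------------------------------------
# Hannenhalli-Pevzner distance


def _relabel(order_a: GeneOrder, order_b: GeneOrder) -> list[int]:
    """Express order_a in order_b's frame: order_b becomes identity 1..n."""
    if order_a.symbols != order_b.symbols:
        raise ValueError("gene orders must share the same symbol set")
    target = {name: (i + 1, sign) for i, (name, sign) in enumerate(order_b.genes)}
    perm = []
    for name, sign in order_a.genes:
        value, t_sign = target[name]
        perm.append(value * sign * t_sign)
    return perm


def _breakpoint_graph(perm: list[int]):
    """Doubled representation: +x -> (2x-1, 2x), -x -> (2x, 2x-1), framed by
    0 and 2n+1. Returns (v, cycles, cycle_id per vertex, trivial flags)."""
    n = len(perm)
    v = [0]
    for x in perm:
        if x > 0:
            v.extend((2 * x - 1, 2 * x))
        else:
            v.extend((-2 * x, -2 * x - 1))
    v.append(2 * n + 1)
    pos = {val: i for i, val in enumerate(v)}
    # black edges pair positions (2i, 2i+1); gray edges pair values (2i, 2i+1)
    black_partner = {}
    for i in range(n + 1):
        a, b = v[2 * i], v[2 * i + 1]
        black_partner[a] = b
        black_partner[b] = a
    gray_partner = {}
    for i in range(n + 1):
        gray_partner[2 * i] = 2 * i + 1
        gray_partner[2 * i + 1] = 2 * i
    cycle_id = {}
    cycles = []
    for start in v:
        if start in cycle_id:
            continue
        cid = len(cycles)
        members = []
        gray_edges = []
        cur = start
        while cur not in cycle_id:
            cycle_id[cur] = cid
            members.append(cur)
            nxt = black_partner[cur]
            if nxt not in cycle_id:
                cycle_id[nxt] = cid
                members.append(nxt)
            g = gray_partner[nxt]
            gray_edges.append((nxt, g))
            cur = g
        cycles.append({"members": members, "gray": gray_edges})
    return v, pos, cycles, cycle_id


def _components(perm: list[int]):
    """Interleaving components of the non-trivial cycles, each flagged
    oriented/unoriented, with its position span on the line."""
    v, pos, cycles, _ = _breakpoint_graph(perm)
    nontrivial = []
    for cyc in cycles:
        if len(cyc["members"]) <= 2:
            continue  # adjacency: one black + one gray edge, already sorted
        spans = []
        oriented = False
        for u, w in cyc["gray"]:
            pu, pw = pos[u], pos[w]
            if (pu - pw) % 2 == 0:
                oriented = True  # same-parity endpoints: reversal can resolve it
            spans.append((min(pu, pw), max(pu, pw)))
        nontrivial.append({"spans": spans, "oriented": oriented})
    # union cycles whose gray edges cross (interleave)
    m = len(nontrivial)
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i in range(m):
        for j in range(i + 1, m):
            if any(
                (a1 < a2 < b1 < b2) or (a2 < a1 < b2 < b1)
                for a1, b1 in nontrivial[i]["spans"]
                for a2, b2 in nontrivial[j]["spans"]
            ):
                union(i, j)
    comps: dict[int, dict] = {}
    for i, cyc in enumerate(nontrivial):
        root = find(i)
        comp = comps.setdefault(root, {"lo": 10 ** 9, "hi": -1, "oriented": False})
        comp["lo"] = min(comp["lo"], min(a for a, _ in cyc["spans"]))
        comp["hi"] = max(comp["hi"], max(b for _, b in cyc["spans"]))
        comp["oriented"] = comp["oriented"] or cyc["oriented"]
    return len(cycles), list(comps.values())


def _hurdles_and_fortress(components) -> tuple[int, bool]:
    """Count hurdles among the unoriented components and detect a fortress.

    Unoriented component spans nest or are disjoint. On the circle obtained by
    joining the line's ends, a component is a hurdle iff one of its two arcs
    contains no other unoriented component; a hurdle is a superhurdle iff
    deleting it would turn another unoriented component into a hurdle. A
    fortress has an odd number of hurdles, all superhurdles.
    """
    unoriented = sorted(
        (c for c in components if not c["oriented"]), key=lambda c: (c["lo"], -c["hi"])
    )
    k = len(unoriented)
    if k == 0:
        return 0, False
    if k == 1:
        return 1, False

    def contains(outer, inner):
        return outer["lo"] <= inner["lo"] and inner["hi"] <= outer["hi"]

    def is_hurdle(idx, comps):
        me = comps[idx]
        inside = [c for j, c in enumerate(comps) if j != idx and contains(me, c)]
        outside = [c for j, c in enumerate(comps) if j != idx and not contains(me, c)]
        return not inside or not outside

    hurdle_idx = [i for i in range(k) if is_hurdle(i, unoriented)]
    h = len(hurdle_idx)
    if h % 2 == 0:
        return h, False
    # fortress requires every hurdle to be a superhurdle
    for i in hurdle_idx:
        remaining = [c for j, c in enumerate(unoriented) if j != i]
        new_hurdles = [
            j for j in range(len(remaining)) if is_hurdle(j, remaining)
        ]
        protected = [
            remaining[j]
            for j in new_hurdles
            if not is_hurdle_in(remaining[j], unoriented)
        ]
        if not protected:
            return h, False
    return h, True


def is_hurdle_in(comp, comps) -> bool:
    idx = next(i for i, c in enumerate(comps) if c is comp)
    me = comps[idx]
    inside = [c for j, c in enumerate(comps) if j != idx and
              (me["lo"] <= c["lo"] and c["hi"] <= me["hi"])]
    outside = [c for j, c in enumerate(comps) if j != idx and not
               (me["lo"] <= c["lo"] and c["hi"] <= me["hi"])]
    return not inside or not outside


def count_breakpoints(perm: list[int]) -> int:
    """Adjacencies broken relative to the identity, frame elements included."""
    ext = [0] + perm + [len(perm) + 1]
    return sum(1 for a, b in zip(ext, ext[1:]) if b - a != 1)


def reversal_distance_perm(perm: list[int]) -> RearrangementResult:
    """Exact signed reversal distance of perm from the identity 1..n."""
    n = len(perm)
    if sorted(abs(x) for x in perm) != list(range(1, n + 1)):
        raise ValueError("input must be a signed permutation of 1..n")
    if perm == list(range(1, n + 1)):
        return RearrangementResult(0, 0, n + 1, 0, False, n)
    c, components = _components(perm)
    h, fortress = _hurdles_and_fortress(components)
    d = n + 1 - c + h + (1 if fortress else 0)
    return RearrangementResult(
        distance=d,
        breakpoints=count_breakpoints(perm),
        cycles=c,
        hurdles=h,
        fortress=fortress,
        n=n,
    )


def reversal_distance(order_a: GeneOrder, order_b: GeneOrder) -> RearrangementResult:
    """Exact signed reversal distance between two shared gene orders."""
    return reversal_distance_perm(_relabel(order_a, order_b))


def genome_rearrangement_distance(
    g_a: AnnotatedGenome, g_b: AnnotatedGenome, synonyms: dict[str, str] | None = None
) -> RearrangementResult:
    order_a, order_b = extract_shared_order(g_a, g_b, synonyms)
    return reversal_distance(order_a, order_b)


# ---------------------------------------------------------------------------
# exact reference by breadth-first search (small n only)


def reversal_distance_bfs(perm: list[int] | tuple[int, ...]) -> int:
    """Distance from the identity by BFS over the reversal graph; exact but
    exponential, intended for validating the breakpoint-graph computation."""
    n = len(perm)
    start = tuple(perm)
    target = tuple(range(1, n + 1))
    if start == target:
        return 0
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        cur, d = frontier.popleft()
        for i in range(n):
            for j in range(i + 1, n + 1):
                nxt = cur[:i] + tuple(-x for x in reversed(cur[i:j])) + cur[j:]
                if nxt == target:
                    return d + 1
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append((nxt, d + 1))
    raise RuntimeError("unreachable")


def bfs_distance_table(n: int) -> dict[tuple[int, ...], int]:
    """Distances from the identity to every signed permutation of 1..n, by one
    backward BFS (the reversal graph is undirected and vertex-transitive)."""
    from itertools import permutations

    target = tuple(range(1, n + 1))
    dist = {target: 0}
    frontier = deque([target])
    while frontier:
        cur = frontier.popleft()
        d = dist[cur]
        for i in range(n):
            for j in range(i + 1, n + 1):
                nxt = cur[:i] + tuple(-x for x in reversed(cur[i:j])) + cur[j:]
                if nxt not in dist:
                    dist[nxt] = d + 1
                    frontier.append(nxt)
    assert len(dist) == 2 ** n * len(list(permutations(range(1, n + 1))))
    return dist
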