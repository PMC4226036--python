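"""Synthetic annotated genomes with known ground truth.

Every pipeline stage is testable without downloads: genomes carry planted
small inverted repeats (stem/loop/mismatches), planted tandem arrays
(period/copies/per-copy substitutions), an optional large ribosomal inverted
repeat whose two copies differ by a configurable number of SNPs and
single-base indels, and gene features with configurable intergenic spacing.
Background sequence is i.i.d. per base at a target GC.

Planted elements are separated by >= 50 bp and flanked by guard tracts drawn
from a complement-free alphabet ({A,C} on both sides of an inverted pairing
can never base-pair), so the maximal-scoring detection alignment provably ends
exactly at the planted coordinates; without the guards, chance flanking
matches would stochastically extend hits past the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import AnnotatedGenome, GeneFeature, Group
from .repeats import GenomeRepeatProfile

_BASES = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}
MIN_SEPARATION = 50
GUARD = 12  # width of the complement-free guard tracts flanking planted elements

# default plastid-like gene names cycled through when planting CDS features
_GENE_NAMES = (
    "clpC", "psaB", "rpoC", "atpA", "rps10", "rbcS", "psbC", "rbcL", "psbA",
    "psbD", "psaA", "petB", "rpl2", "rps4", "atpB", "ycf39", "tufA", "rpoB",
)


class PackingError(ValueError):
    """Planted elements cannot fit in the requested genome length."""


@dataclass(frozen=True)
class PlantedIR:
    stem: int
    loop: int
    mismatches: int = 0
    position: int | None = None  # arm1 start; auto-placed when None
    after_gene: str | None = None  # plant downstream of this gene
    gene_distance: int = 100

    def __post_init__(self):
        if not (1 <= self.stem):
            raise ValueError("stem must be positive")
        if self.loop < 0 or self.mismatches < 0:
            raise ValueError("loop and mismatches must be non-negative")
        if self.mismatches and self.stem < 5:
            raise ValueError("mismatched stems must be >= 5 bp")

    @property
    def extent(self) -> int:
        return 2 * self.stem + self.loop


@dataclass(frozen=True)
class PlantedTR:
    period: int
    copies: float
    mutations_per_copy: int = 0
    position: int | None = None
    after_gene: str | None = None
    gene_distance: int = 100

    def __post_init__(self):
        if self.period < 1 or self.copies < 2:
            raise ValueError("period >= 1 and copies >= 2 required")

    @property
    def extent(self) -> int:
        return int(round(self.period * self.copies))


@dataclass(frozen=True)
class LargeIRSpec:
    """A 16S-ISR-23S-5S operon duplicated in inverted orientation.

    isr_layout: canonical (tRNA-Ile + tRNA-Ala in both copies), ctobin
    (Ala in copy A, Ile in copy B), phaeocystis (both tRNAs in copy A, none in
    copy B), none (no ISR tRNAs). single_copy plants only one operon, so no
    inverted repeat exists.
    """

    length: int = 4656
    snps_16s: int = 0
    snps_23s: int = 0
    indels_16s: int = 0
    indels_23s: int = 0
    isr_layout: str = "canonical"
    single_copy: bool = False

    LEN_16S = 1491
    LEN_23S = 2616
    LEN_5S = 119
    LEN_TRNA = 73

    def __post_init__(self):
        if self.isr_layout not in ("canonical", "ctobin", "phaeocystis", "none"):
            raise ValueError(f"unknown isr_layout {self.isr_layout!r}")
        core = self.LEN_16S + self.LEN_23S + self.LEN_5S
        if self.length < core + 2 * self.LEN_TRNA + 80:
            raise ValueError(f"large IR length {self.length} too small for the operon")


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    genome_length: int = 30000
    gc: float = 0.35
    planted_irs: tuple[PlantedIR, ...] = ()
    planted_trs: tuple[PlantedTR, ...] = ()
    large_ir: LargeIRSpec | None = None
    n_genes: int = 20
    mean_intergenic: float = 150.0
    circular: bool = True
    group: Group | str = Group.OTHER
    genome_id: str = "synthetic"

    def __post_init__(self):
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1 kb")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be a fraction in (0, 1)")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")


@dataclass
class TruthTable:
    """Exact coordinates and divergence of every planted element."""

    seed: int
    genome_id: str
    irs: list[dict] = field(default_factory=list)
    trs: list[dict] = field(default_factory=list)
    large_ir: dict | None = None
    genes: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sequence-level helpers (integer codes 0..3)


def _random_codes(rng, n, gc):
    return rng.choice(4, size=n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]).astype(
        np.int8
    )


def _revcomp_codes(codes):
    return np.array([_COMP[int(c)] for c in codes[::-1]], dtype=np.int8)


def _decode(codes):
    return "".join(_BASES[int(c)] for c in codes)


def _other_base(rng, *avoid):
    choices = [b for b in range(4) if b not in avoid]
    return int(rng.choice(choices))


# ---------------------------------------------------------------------------
# genome assembly


class _Assembler:
    def __init__(self, spec: SyntheticSpec, rng):
        self.spec = spec
        self.rng = rng
        self.codes = _random_codes(rng, spec.genome_length, spec.gc)
        self.cursor = MIN_SEPARATION
        self.features: list[GeneFeature] = []
        self.truth = TruthTable(seed=spec.seed, genome_id=spec.genome_id)

    def _advance(self, length, gap=None):
        if gap is None:
            gap = MIN_SEPARATION + int(
                self.rng.exponential(max(1.0, self.spec.mean_intergenic - MIN_SEPARATION))
            )
        start = self.cursor + gap
        if start + length > self.spec.genome_length - MIN_SEPARATION:
            raise PackingError(
                f"cannot fit element of {length} bp at {start} in genome of "
                f"{self.spec.genome_length} bp"
            )
        self.cursor = start + length
        return start

    def _ac_fill(self, lo, hi):
        """Overwrite [lo, hi) with A/C only: two positions both inside such
        tracts can never be reverse-complement partners, so no inverted
        alignment can extend through them."""
        lo = max(0, lo)
        hi = min(self.spec.genome_length, hi)
        if hi > lo:
            self.codes[lo:hi] = self.rng.choice(2, size=hi - lo).astype(np.int8)

    def _place(self, length, position, after_gene, gene_distance):
        if position is not None:
            if position + length > self.spec.genome_length - 1:
                raise PackingError(f"explicit position {position} overruns the genome")
            self.cursor = max(self.cursor, position + length)
            return position
        if after_gene is not None:
            gene = next(
                (f for f in reversed(self.features) if f.name == after_gene), None
            )
            if gene is None:
                raise ValueError(f"after_gene={after_gene!r}: gene not planted yet")
            start = gene.end + gene_distance
            if start + length > self.spec.genome_length - MIN_SEPARATION:
                raise PackingError("gene-adjacent repeat overruns the genome")
            self.cursor = max(self.cursor, start + length)
            return start
        return self._advance(length)

    # -- elements ----------------------------------------------------------

    def plant_gene(self, name, kind="CDS", length=None):
        if length is None:
            length = 72 if kind == "tRNA" else int(self.rng.integers(300, 1200))
        start = self._advance(length)
        f = GeneFeature(
            name=name, kind=kind, start=start, end=start + length,
            strand="+" if self.rng.random() < 0.7 else "-",
        )
        self.features.append(f)
        self.truth.genes.append(
            {"name": name, "kind": kind, "start": start, "end": start + length,
             "strand": f.strand}
        )
        return f

    def _ir_arm(self, ir: PlantedIR):
        """Draw an arm whose stem-loop footprint carries no tandem structure
        of its own (keeps planted tandem counts exact)."""
        from .small_repeats import TRParams, find_tandem_repeats

        probe = TRParams(min_score=40, max_period=max(1, ir.extent // 2))
        for _ in range(64):
            arm1 = _random_codes(self.rng, ir.stem, self.spec.gc)
            footprint = np.concatenate(
                (arm1, self.rng.choice(2, size=ir.loop).astype(np.int8), _revcomp_codes(arm1))
            )
            if not find_tandem_repeats(_decode(footprint), probe):
                return arm1
        raise ValueError("could not draw a tandem-free inverted-repeat arm")

    def plant_ir(self, ir: PlantedIR):
        start = self._place(ir.extent, ir.position, ir.after_gene, ir.gene_distance)
        rng = self.rng
        arm1 = self._ir_arm(ir)
        arm2 = _revcomp_codes(arm1)
        if ir.mismatches:
            if ir.stem < ir.mismatches * 3 + 4:
                raise ValueError("too many mismatches for this stem length")
            # interior positions >= 2 from each arm end keep the maximal
            # alignment pinned to the planted coordinates
            pos = rng.choice(np.arange(2, ir.stem - 2), size=ir.mismatches, replace=False)
            for p in sorted(int(x) for x in pos):
                arm2[p] = _other_base(rng, int(arm2[p]))
        a1s, a1e = start, start + ir.stem
        a2s = a1e + ir.loop
        a2e = a2s + ir.stem
        self.codes[a1s:a1e] = arm1
        self.codes[a2s:a2e] = arm2
        # complement-free guards: loop and outer flanks cannot base-pair, so
        # the planted stem is the unique maximal alignment
        self._ac_fill(a1e, a2s)
        self._ac_fill(a1s - GUARD, a1s)
        self._ac_fill(a2e, a2e + GUARD)
        self.truth.irs.append(
            {"arm1_start": a1s, "arm1_end": a1e, "arm2_start": a2s, "arm2_end": a2e,
             "stem": ir.stem, "loop": ir.loop, "mismatches": ir.mismatches}
        )

    def _tr_unit(self, tr: PlantedTR):
        """Draw a repeat unit whose array is not itself an inverted repeat
        (AT-rich periodic units can be self-reverse-complementary, which would
        add an unplanted inverted-repeat call on top of the tandem array)."""
        from .small_repeats import IRParams, find_inverted_repeats

        probe = IRParams(min_score=36)  # margin below the detection default
        for _ in range(64):
            unit = _random_codes(self.rng, tr.period, self.spec.gc)
            region = np.tile(unit, int(np.ceil(tr.copies)))[: tr.extent]
            if not find_inverted_repeats(_decode(region), probe):
                return unit
        raise ValueError("could not draw a non-palindromic tandem unit")

    def plant_tr(self, tr: PlantedTR):
        length = tr.extent
        start = self._place(length, tr.position, tr.after_gene, tr.gene_distance)
        rng = self.rng
        unit = self._tr_unit(tr)
        region = np.tile(unit, int(np.ceil(tr.copies)))[:length].copy()
        if tr.mutations_per_copy:
            n_full = length // tr.period
            for copy_i in range(1, n_full):
                lo = copy_i * tr.period
                hi = min(lo + tr.period, length)
                # keep 4 bp at the region edges pristine so trimming cannot
                # move the array boundary off the planted truth
                cand = [p for p in range(lo, hi) if 4 <= p < length - 4]
                if len(cand) < tr.mutations_per_copy:
                    continue
                pos = rng.choice(cand, size=tr.mutations_per_copy, replace=False)
                for p in sorted(int(x) for x in pos):
                    region[p] = _other_base(rng, int(region[p]))
        self.codes[start : start + length] = region
        # guard tract: 4 bases on each side that disagree with the consensus
        # at their phase, so consensus-scored trimming cannot move the edges
        for k in range(1, 5):
            if start - k >= 0:
                self.codes[start - k] = _other_base(rng, int(unit[(-k) % tr.period]))
            if start + length + k - 1 < self.spec.genome_length:
                self.codes[start + length + k - 1] = _other_base(
                    rng, int(unit[(length + k - 1) % tr.period])
                )
        self.truth.trs.append(
            {"start": start, "end": start + length, "period": tr.period,
             "copies": round(length / tr.period, 2),
             "mutations_per_copy": tr.mutations_per_copy,
             "consensus": _decode(unit)}
        )

    def _operon_codes(self, li: LargeIRSpec, trna_seqs):
        """One operon copy: margin-16S-ISR(with tRNAs)-23S-5S-margin, plus the
        relative feature layout. Returns (codes, features-relative)."""
        rng = self.rng
        core = li.LEN_16S + li.LEN_23S + li.LEN_5S
        isr_len = min(300, li.length - core - 60)
        margins = li.length - core - isr_len
        m_left = margins // 2
        parts = []
        feats = []
        pos = 0
        parts.append(_random_codes(rng, m_left, self.spec.gc))
        pos += m_left
        gene16 = _random_codes(rng, li.LEN_16S, self.spec.gc)
        feats.append(("16S", "rRNA", pos, pos + li.LEN_16S))
        parts.append(gene16)
        pos += li.LEN_16S
        # ISR: fixed background with tRNA slots at deterministic offsets
        isr = _random_codes(rng, isr_len, self.spec.gc)
        slot_ile = 40
        slot_ala = isr_len - li.LEN_TRNA - 40
        for name, slot in (("tRNA-Ile", slot_ile), ("tRNA-Ala", slot_ala)):
            isr[slot : slot + li.LEN_TRNA] = trna_seqs[name]
        feats.append(("tRNA-Ile", "tRNA", pos + slot_ile, pos + slot_ile + li.LEN_TRNA))
        feats.append(("tRNA-Ala", "tRNA", pos + slot_ala, pos + slot_ala + li.LEN_TRNA))
        parts.append(isr)
        pos += isr_len
        gene23 = _random_codes(rng, li.LEN_23S, self.spec.gc)
        feats.append(("23S", "rRNA", pos, pos + li.LEN_23S))
        parts.append(gene23)
        pos += li.LEN_23S
        gene5 = _random_codes(rng, li.LEN_5S, self.spec.gc)
        feats.append(("5S", "rRNA", pos, pos + li.LEN_5S))
        parts.append(gene5)
        pos += li.LEN_5S
        parts.append(_random_codes(rng, li.length - pos, self.spec.gc))
        return np.concatenate(parts), feats, (slot_ile, slot_ala, isr_len)

    def _mutate_copy(self, codes, feats, gene, n_snps, n_indels):
        """Apply SNPs then single-base deletions inside one gene of a copy;
        returns updated (codes, feats) with downstream coordinates shifted."""
        rng = self.rng
        name_to_iv = {f[0]: f for f in feats}
        _, _, gs, ge = name_to_iv[gene]
        interior = np.arange(gs + 30, ge - 30)
        take = n_snps + n_indels
        # >= 10 bp spacing keeps substitutions and indels from interacting in
        # the divergence alignment, so planted counts are recovered exactly
        picks: list[int] = []
        for p in rng.permutation(interior):
            if all(abs(int(p) - q) >= 10 for q in picks):
                picks.append(int(p))
            if len(picks) == take:
                break
        if len(picks) < take:
            raise ValueError(f"gene {gene} too short for {take} planted differences")
        snp_pos = sorted(picks[:n_snps])
        del_pos = sorted(picks[n_snps:])
        for p in snp_pos:
            codes[p] = _other_base(rng, int(codes[p]))
        keep = np.ones(codes.size, dtype=bool)
        keep[del_pos] = False
        codes = codes[keep]

        def shifted(x):
            return x - sum(1 for p in del_pos if p < x)

        new_feats = [(nm, kind, shifted(s), shifted(e)) for nm, kind, s, e in feats]
        return codes, new_feats

    def plant_large_ir(self, li: LargeIRSpec):
        rng = self.rng
        trna_seqs = {
            "tRNA-Ile": _random_codes(rng, li.LEN_TRNA, self.spec.gc),
            "tRNA-Ala": _random_codes(rng, li.LEN_TRNA, self.spec.gc),
        }
        copy_a, feats_a, (slot_ile, slot_ala, isr_len) = self._operon_codes(li, trna_seqs)
        copy_b = copy_a.copy()
        feats_b = list(feats_a)
        # divergence between the rRNA gene copies
        for gene, s, d in (("16S", li.snps_16s, li.indels_16s),
                           ("23S", li.snps_23s, li.indels_23s)):
            if s or d:
                copy_b, feats_b = self._mutate_copy(copy_b, feats_b, gene, s, d)
        # ISR tRNA layout (replace a slot with unrelated sequence = tRNA absent)
        def drop_trna(codes, feats, name):
            iv = next(f for f in feats if f[0] == name)
            codes = codes.copy()
            codes[iv[2] : iv[3]] = _random_codes(rng, iv[3] - iv[2], self.spec.gc)
            return codes, [f for f in feats if f[0] != name]

        if li.isr_layout == "ctobin":
            copy_a, feats_a = drop_trna(copy_a, feats_a, "tRNA-Ile")
            copy_b, feats_b = drop_trna(copy_b, feats_b, "tRNA-Ala")
        elif li.isr_layout == "phaeocystis":
            copy_b, feats_b = drop_trna(copy_b, feats_b, "tRNA-Ile")
            copy_b, feats_b = drop_trna(copy_b, feats_b, "tRNA-Ala")
        elif li.isr_layout == "none":
            copy_a, feats_a = drop_trna(copy_a, feats_a, "tRNA-Ile")
            copy_a, feats_a = drop_trna(copy_a, feats_a, "tRNA-Ala")
            copy_b, feats_b = drop_trna(copy_b, feats_b, "tRNA-Ile")
            copy_b, feats_b = drop_trna(copy_b, feats_b, "tRNA-Ala")

        a_start = self._advance(len(copy_a), gap=MIN_SEPARATION + 100)
        self.codes[a_start : a_start + len(copy_a)] = copy_a
        for nm, kind, s, e in feats_a:
            self.features.append(GeneFeature(nm, kind, a_start + s, a_start + e, "+"))

        b_interval = None
        if not li.single_copy:
            copy_b_rc = _revcomp_codes(copy_b)
            b_start = self._advance(len(copy_b_rc), gap=2 * MIN_SEPARATION + 400)
            self.codes[b_start : b_start + len(copy_b_rc)] = copy_b_rc
            m = len(copy_b)
            for nm, kind, s, e in feats_b:
                self.features.append(
                    GeneFeature(nm, kind, b_start + (m - e), b_start + (m - s), "-")
                )
            b_interval = (b_start, b_start + len(copy_b_rc))
            # complement-free guards on all four copy boundaries: boundary
            # extension stops exactly at the planted edges
            a0, a1 = a_start, a_start + len(copy_a)
            b0, b1 = b_interval
            self._ac_fill(a0 - GUARD, a0)
            self._ac_fill(b1, b1 + GUARD)
            self._ac_fill(a1, a1 + GUARD)
            self._ac_fill(b0 - GUARD, b0)
        self.truth.large_ir = {
            "copy_a": (a_start, a_start + len(copy_a)),
            "copy_b": b_interval,
            "ir_length": len(copy_a),
            "snps": {"16S": li.snps_16s, "23S": li.snps_23s},
            "indels": {"16S": li.indels_16s, "23S": li.indels_23s},
            "isr_layout": li.isr_layout,
        }

    # -- assembly order ----------------------------------------------------

    def build(self) -> tuple[AnnotatedGenome, TruthTable]:
        spec = self.spec
        gene_names = [
            _GENE_NAMES[i % len(_GENE_NAMES)]
            + ("" if i < len(_GENE_NAMES) else f"_{i // len(_GENE_NAMES)}")
            for i in range(spec.n_genes)
        ]
        # interleave genes with floating repeats; gene-attached repeats follow
        # their gene; the large IR splits the gene list plastid-style
        floating = [ir for ir in spec.planted_irs if ir.position is None and ir.after_gene is None]
        floating += [tr for tr in spec.planted_trs if tr.position is None and tr.after_gene is None]
        attached = [r for r in (*spec.planted_irs, *spec.planted_trs)
                    if r.after_gene is not None]
        positioned = [r for r in (*spec.planted_irs, *spec.planted_trs)
                      if r.position is not None and r.after_gene is None]
        by_gene: dict[str, list] = {}
        for r in attached:
            by_gene.setdefault(r.after_gene, []).append(r)

        items: list = []
        n_slots = max(len(gene_names), 1)
        per_slot = [[] for _ in range(n_slots)]
        for idx, r in enumerate(floating):
            per_slot[idx % n_slots].append(r)
        for i, name in enumerate(gene_names):
            kind = "tRNA" if (i % 5 == 4) else "CDS"
            items.append(("gene", name, kind))
            for r in by_gene.get(name, []):
                items.append(("repeat", r))
            for r in per_slot[i]:
                items.append(("repeat", r))
        if not gene_names:
            items = [("repeat", r) for r in floating]
        if spec.large_ir is not None:
            cut = int(len(items) * 0.6)
            items = items[:cut] + [("large_ir",)] + items[cut:]

        for item in items:
            if item[0] == "gene":
                self.plant_gene(item[1], item[2])
            elif item[0] == "repeat":
                r = item[1]
                self.plant_ir(r) if isinstance(r, PlantedIR) else self.plant_tr(r)
            elif item[0] == "large_ir":
                self.plant_large_ir(spec.large_ir)
        for r in positioned:
            self.plant_ir(r) if isinstance(r, PlantedIR) else self.plant_tr(r)

        genome = AnnotatedGenome(
            id=spec.genome_id,
            sequence=_decode(self.codes),
            circular=spec.circular,
            features=self.features,
            group=spec.group,
        )
        return genome, self.truth


def generate_genome(spec: SyntheticSpec) -> tuple[AnnotatedGenome, TruthTable]:
    """Deterministic for a fixed seed; raises PackingError before producing
    any output when the planted elements cannot fit."""
    rng = np.random.default_rng(spec.seed)
    return _Assembler(spec, rng).build()


# ---------------------------------------------------------------------------
# panels for the lineage statistics


@dataclass(frozen=True)
class GroupParams:
    """Per-lineage distributions for panel generation.

    Defaults mirror the comparative survey's descriptive numbers: CASH-like
    plastids average ~25 small repeats with inverted repeats predominating and
    repeat sizes capped near 65 bp; green-lineage plastids average ~80 repeats
    with tandem repeats predominating and no tight size cap; rhodophytes carry
    few repeats overall.
    """

    group: Group
    n_inverted_mean: float
    n_tandem_mean: float
    genome_size_range: tuple[int, int]
    repeat_size_range: tuple[int, int]
    repeat_size_cap: int
    mean_intergenic_range: tuple[float, float]


CASH_LIKE = GroupParams(Group.CASH, 17.0, 8.0, (90_000, 160_000), (18, 50), 65, (80.0, 200.0))
GREEN_LIKE = GroupParams(Group.GREEN, 30.0, 50.0, (100_000, 200_000), (25, 150), 200, (150.0, 400.0))
RHODOPHYTE_LIKE = GroupParams(Group.RHODOPHYTE, 8.0, 5.0, (150_000, 200_000), (18, 45), 65, (60.0, 150.0))

DEFAULT_GROUP_PARAMS = {
    Group.CASH: CASH_LIKE,
    Group.GREEN: GREEN_LIKE,
    Group.RHODOPHYTE: RHODOPHYTE_LIKE,
}


def sample_profile_panel(
    n_per_group: int,
    group_params: dict[Group, GroupParams] | None = None,
    seed: int = 0,
) -> list[GenomeRepeatProfile]:
    """Sample genome repeat profiles directly from the group distributions
    (no sequence realisation) — the fast path for power/type-I simulations."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    params = group_params or DEFAULT_GROUP_PARAMS
    rng = np.random.default_rng(seed)
    profiles = []
    for group in sorted(params, key=lambda g: g.value):
        gp = params[group]
        for i in range(n_per_group):
            n_inv = int(rng.poisson(gp.n_inverted_mean))
            n_tan = int(rng.poisson(gp.n_tandem_mean))
            size = int(rng.integers(*gp.genome_size_range))
            if n_inv + n_tan > 0:
                mean_sz = float(rng.uniform(*gp.repeat_size_range))
                max_sz = int(min(gp.repeat_size_cap, mean_sz * rng.uniform(1.0, 1.8)))
            else:
                mean_sz, max_sz = None, None
            profiles.append(
                GenomeRepeatProfile(
                    genome_id=f"{group.value}_{i}",
                    group=group,
                    n_inverted=n_inv,
                    n_tandem=n_tan,
                    mean_repeat_size=mean_sz,
                    max_repeat_size=max_sz,
                    genome_size=size,
                    mean_intergenic=float(rng.uniform(*gp.mean_intergenic_range)),
                )
            )
    return profiles


def generate_panel(
    n_per_group: int,
    group_params: dict[Group, GroupParams] | None = None,
    seed: int = 0,
    genome_length: int = 8000,
    repeats_per_genome: int = 4,
) -> list[tuple[AnnotatedGenome, TruthTable]]:
    """Fully realised panel: small genomes whose planted repeat mix follows
    each group's tandem/inverted balance; per-genome truth accompanies each."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    params = group_params or DEFAULT_GROUP_PARAMS
    rng = np.random.default_rng(seed)
    out = []
    for group in sorted(params, key=lambda g: g.value):
        gp = params[group]
        p_tandem = gp.n_tandem_mean / (gp.n_tandem_mean + gp.n_inverted_mean)
        for i in range(n_per_group):
            irs, trs = [], []
            for _ in range(repeats_per_genome):
                if rng.random() < p_tandem:
                    trs.append(PlantedTR(period=int(rng.integers(8, 16)), copies=4))
                else:
                    irs.append(PlantedIR(stem=int(rng.integers(18, 30)),
                                         loop=int(rng.integers(3, 9))))
            spec = SyntheticSpec(
                seed=int(rng.integers(0, 2**31 - 1)),
                genome_length=genome_length,
                planted_irs=tuple(irs),
                planted_trs=tuple(trs),
                n_genes=3,
                mean_intergenic=80.0,
                group=group,
                genome_id=f"{group.value}_{i}",
            )
            out.append(generate_genome(spec))
    return out


def profiles_with_slope(
    slope: float,
    intercept: float,
    noise_sd: float,
    n: int,
    seed: int,
    predictor: str = "genome_size",
    response: str = "n_repeats",
    x_range: tuple[float, float] = (50_000.0, 250_000.0),
) -> list[GenomeRepeatProfile]:
    """Profiles whose response depends linearly on the predictor with Gaussian
    noise — ground truth for regression parameter-recovery checks."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        x = float(int(rng.uniform(*x_range)))  # profile fields store integer sizes
        y = slope * x + intercept + rng.normal(0.0, noise_sd)
        genome_size = x if predictor == "genome_size" else 100_000
        mean_intergenic = x if predictor == "mean_intergenic" else 150.0
        if response == "n_repeats":
            n_inv = max(0, int(round(y)))
            n_tan = 0
            mean_sz = 30.0
        else:
            n_inv, n_tan = 1, 1
            mean_sz = max(1.0, y)
        profiles.append(
            GenomeRepeatProfile(
                genome_id=f"sim_{i}",
                group=Group.CASH,
                n_inverted=n_inv,
                n_tandem=n_tan,
                mean_repeat_size=mean_sz,
                max_repeat_size=int(mean_sz * 2),
                genome_size=int(genome_size),
                mean_intergenic=mean_intergenic,
            )
        )
    return profiles
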