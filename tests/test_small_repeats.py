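"""Small inverted/tandem repeat detection: planted truth, oracle equivalence,
strand symmetry and scoring self-consistency."""

import numpy as np
import pytest

from plastrep.repeats import InvertedRepeat
from plastrep.sequtils import revcomp
from plastrep.small_repeats import (
    IRParams,
    TRParams,
    _select_nonredundant,
    find_inverted_repeats,
    find_tandem_repeats,
    ir_alignment_score,
    repeat_profile,
)
from plastrep.synthetic import PlantedIR, PlantedTR, SyntheticSpec, generate_genome

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "?"}


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def gapless_oracle(seq, p: IRParams):
    """Enumerate every gapless stem placement: innermost pair (j, j+g+1) for
    each loop length g, grown outward column by column. Placements scoring
    >= min_score whose innermost and outermost columns are matches (an optimal
    alignment never starts or ends on a mismatch) enter the same redundancy
    resolution as the detector."""
    n = len(seq)
    hits = []
    for j in range(n):
        for g in range(p.max_loop + 1):
            score = 0
            mism = 0
            inner_match = False
            running_max = 0  # canonical local alignments are strict running maxima:
            # an extension whose added columns net <= 0 is trimmed by optimality
            k = 0
            while True:
                a, b = j - k, j + g + 1 + k
                if a < 0 or b >= n or (b + 1 - a) >= p.max_extent:
                    break
                m = seq[a] == COMP[seq[b]]
                if k == 0:
                    inner_match = m
                score += p.match if m else p.mismatch
                mism += 0 if m else 1
                if m and inner_match and score >= p.min_score and score > running_max:
                    hits.append(
                        InvertedRepeat(a, j + 1, j + g + 1, b + 1, mism, 0, score)
                    )
                running_max = max(running_max, score)
                k += 1
    return _select_nonredundant(set(hits))


class TestInvertedRepeats:
    def test_planted_perfect_palindrome(self):
        seq = "T" * 10 + "AAACCCGG" + "TTTT" + "CCGGGTTT" + "T" * 10
        hits = find_inverted_repeats(seq, IRParams(min_score=20))
        assert len(hits) == 1
        h = hits[0]
        assert (h.stem_len, h.loop_len, h.mismatches, h.gaps) == (8, 4, 0, 0)
        assert (h.arm1_start, h.arm1_end, h.arm2_start, h.arm2_end) == (10, 18, 22, 30)

    def test_homopolymer_has_no_inverted_repeat(self):
        assert find_inverted_repeats("A" * 100, IRParams(min_score=20)) == []

    def test_empty_sequence(self):
        assert find_inverted_repeats("") == []

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            find_inverted_repeats("ACGT", IRParams(max_extent=2))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle_gapless(self, seed):
        """Detector with a prohibitive gap penalty equals the brute-force scan
        over all arm-pair placements under the same scoring scheme."""
        rng = np.random.default_rng(seed)
        seq = _random_seq(rng, 300)
        p = IRParams(gap=-10_000, min_score=18)
        assert find_inverted_repeats(seq, p) == gapless_oracle(seq, p)

    @pytest.mark.parametrize("seed", range(6))
    def test_planted_recovery_exact(self, seed):
        spec = SyntheticSpec(
            seed=seed, genome_length=20000,
            planted_irs=tuple(PlantedIR(stem=20, loop=5) for _ in range(5)),
            n_genes=8,
        )
        g, truth = generate_genome(spec)
        det = find_inverted_repeats(g)
        got = sorted((h.arm1_start, h.arm1_end, h.arm2_start, h.arm2_end) for h in det)
        want = sorted(
            (t["arm1_start"], t["arm1_end"], t["arm2_start"], t["arm2_end"])
            for t in truth.irs
        )
        assert got == want  # recall 1.0, coordinates exact

    def test_strand_symmetry(self):
        rng = np.random.default_rng(17)
        spec = SyntheticSpec(
            seed=33, genome_length=8000, circular=False,
            planted_irs=(PlantedIR(stem=18, loop=4), PlantedIR(stem=24, loop=10)),
            n_genes=4,
        )
        g, _ = generate_genome(spec)
        n = g.length
        fwd = find_inverted_repeats(g.sequence)
        rev = find_inverted_repeats(revcomp(g.sequence))
        reflected = sorted(
            (n - h.arm2_end, n - h.arm2_start, n - h.arm1_end, n - h.arm1_start)
            for h in rev
        )
        assert reflected == sorted(
            (h.arm1_start, h.arm1_end, h.arm2_start, h.arm2_end) for h in fwd
        )

    def test_reported_score_is_self_consistent(self):
        spec = SyntheticSpec(
            seed=2, genome_length=10000,
            planted_irs=(PlantedIR(stem=30, loop=6, mismatches=2), PlantedIR(stem=20, loop=0)),
            n_genes=4,
        )
        g, _ = generate_genome(spec)
        for h in find_inverted_repeats(g):
            assert ir_alignment_score(g.sequence, h) == h.score

    def test_mismatch_count_matches_planted(self):
        spec = SyntheticSpec(
            seed=8, genome_length=6000,
            planted_irs=(PlantedIR(stem=30, loop=5, mismatches=3),), n_genes=2,
        )
        g, truth = generate_genome(spec)
        hits = find_inverted_repeats(g)
        assert len(hits) == 1
        assert hits[0].mismatches == 3
        assert hits[0].score == 27 * 3 + 3 * -4


class TestTandemRepeats:
    def test_planted_exact_array(self):
        rng = np.random.default_rng(5)
        seq = _random_seq(rng, 50) + "ACGTT" * 4 + _random_seq(rng, 50)
        hits = find_tandem_repeats(seq, TRParams(min_score=40))
        assert any(h.period == 5 and h.consensus == "ACGTT" for h in hits)

    def test_homopolymer_minimal_period(self):
        rng = np.random.default_rng(6)
        seq = "C" + "A" * 30 + "G" + _random_seq(rng, 40)
        hits = find_tandem_repeats(seq, TRParams(min_score=40))
        assert len(hits) == 1
        assert (hits[0].period, hits[0].copies) == (1, 30.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_mutated_array_period_and_copies(self, seed):
        spec = SyntheticSpec(
            seed=seed, genome_length=8000,
            planted_trs=(PlantedTR(period=12, copies=4, mutations_per_copy=1),),
            n_genes=3,
        )
        g, truth = generate_genome(spec)
        hits = find_tandem_repeats(g)
        assert len(hits) == 1
        assert hits[0].period == 12
        assert abs(hits[0].copies - truth.trs[0]["copies"]) <= 0.5

    def test_empty_sequence(self):
        assert find_tandem_repeats("") == []

    def test_exact_coordinates_for_clean_arrays(self):
        spec = SyntheticSpec(
            seed=3, genome_length=9000,
            planted_trs=(PlantedTR(period=15, copies=2), PlantedTR(period=7, copies=6)),
            n_genes=3,
        )
        g, truth = generate_genome(spec)
        got = sorted((h.start, h.end, h.period) for h in find_tandem_repeats(g))
        want = sorted((t["start"], t["end"], t["period"]) for t in truth.trs)
        assert got == want


class TestRepeatProfile:
    def test_empty_genome_profile_flags_undefined(self):
        spec = SyntheticSpec(seed=1, genome_length=5000, n_genes=4)
        g, _ = generate_genome(spec)
        prof = repeat_profile(g, [], [])
        assert prof.n_inverted == prof.n_tandem == 0
        assert prof.mean_repeat_size is None and prof.max_repeat_size is None

    def test_counts_and_sizes_from_planted(self):
        spec = SyntheticSpec(
            seed=4, genome_length=15000,
            planted_irs=tuple(PlantedIR(stem=20, loop=5) for _ in range(3)),
            planted_trs=(PlantedTR(period=10, copies=4),),
            n_genes=6,
        )
        g, _ = generate_genome(spec)
        irs, trs = find_inverted_repeats(g), find_tandem_repeats(g)
        prof = repeat_profile(g, irs, trs)
        assert (prof.n_inverted, prof.n_tandem) == (3, 1)
        assert prof.max_repeat_size == 45  # 2*20+5
        assert prof.genome_size == g.length
        assert prof.mean_intergenic is not None
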