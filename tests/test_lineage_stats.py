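"""Lineage statistics: intergenic distances, Fisher's exact test against an
enumeration oracle, and OLS regression properties."""

from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from plastrep.genome import AnnotatedGenome, GeneFeature, Group
from plastrep.lineage_stats import (
    fisher_exact_2x2,
    fisher_tandem_majority,
    mean_intergenic_distance,
    regress,
    tandem_majority_table,
)
from plastrep.repeats import GenomeRepeatProfile
from plastrep.synthetic import profiles_with_slope, sample_profile_panel


def fisher_enumeration(table):
    """Two-sided Fisher p by summing hypergeometric probabilities of every
    table with the observed margins whose probability <= the observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return sum(p for x in range(0, c1 + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))


def _profile(group, n_inv, n_tan, i=0, size=100_000, mig=150.0):
    return GenomeRepeatProfile(
        genome_id=f"{group}_{i}", group=Group(group), n_inverted=n_inv,
        n_tandem=n_tan, mean_repeat_size=30.0, max_repeat_size=60,
        genome_size=size, mean_intergenic=mig,
    )


class TestMeanIntergenic:
    def test_two_genes_on_circle(self):
        g = AnnotatedGenome(
            id="x", sequence="A" * 1000, circular=True,
            features=[GeneFeature("a", "CDS", 0, 100, "+"),
                      GeneFeature("b", "CDS", 500, 600, "+")],
        )
        assert mean_intergenic_distance(g) == 400.0

    def test_tiled_genes_zero(self):
        feats = [GeneFeature(f"g{i}", "CDS", i * 100, (i + 1) * 100, "+") for i in range(10)]
        g = AnnotatedGenome(id="x", sequence="A" * 1000, circular=True, features=feats)
        assert mean_intergenic_distance(g) == 0.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.choice(2000, size=12, replace=False)) * 5
        feats = [GeneFeature(f"g{i}", "CDS", int(s), int(s) + 40, "+") for i, s in enumerate(starts)]
        g = AnnotatedGenome(id="x", sequence="A" * 10000, circular=True, features=feats)
        gaps = []
        for i in range(len(feats)):
            nxt = feats[(i + 1) % len(feats)]
            gap = (nxt.start - feats[i].end) % 10000 if i == len(feats) - 1 else nxt.start - feats[i].end
            gaps.append(max(0, gap))
        assert mean_intergenic_distance(g) == pytest.approx(np.mean(gaps))

    def test_single_feature_undefined(self):
        g = AnnotatedGenome(id="x", sequence="A" * 1000, circular=True,
                            features=[GeneFeature("a", "CDS", 0, 100, "+")])
        with pytest.raises(ValueError):
            mean_intergenic_distance(g)


class TestFisher:
    def test_diagonal_table_closed_form(self):
        # P = 2 * C(5,5)C(5,0)/C(10,5) = 2/252
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_uniform_table(self):
        assert fisher_exact_2x2([[2, 2], [2, 2]]) == 1.0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 12, size=(2, 2))
        assert fisher_exact_2x2(table) == pytest.approx(fisher_enumeration(table.tolist()))

    def test_invariance_under_row_and_column_swap(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            t = rng.integers(0, 10, size=(2, 2))
            p = fisher_exact_2x2(t)
            assert fisher_exact_2x2(t[::-1]) == pytest.approx(p)
            assert fisher_exact_2x2(t[:, ::-1]) == pytest.approx(p)

    def test_tie_counts_as_not_tandem_majority(self):
        profiles = [_profile("CASH", 5, 5), _profile("green", 2, 8, i=1)]
        table = tandem_majority_table(profiles, "CASH", "green")
        assert table[0].tolist() == [0, 1]  # the tie is not tandem-majority
        assert table[1].tolist() == [1, 0]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fisher_tandem_majority([_profile("CASH", 5, 1)], "CASH", "green")


class TestRegression:
    def test_exact_line(self):
        profs = profiles_with_slope(0.002, 1.0, 0.0, 12, seed=0,
                                    response="mean_repeat_size")
        r = regress(profs, "mean_repeat_size", "genome_size")
        assert r.slope == pytest.approx(0.002)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        profs = [_profile("CASH", i, 0, i=i, size=100_000) for i in range(5)]
        with pytest.raises(ValueError, match="zero variance"):
            regress(profs, "n_repeats", "genome_size")

    def test_too_few_genomes_rejected(self):
        profs = [_profile("CASH", 1, 0, i=0, size=10), _profile("CASH", 2, 0, i=1, size=20)]
        with pytest.raises(ValueError, match=">= 3"):
            regress(profs, "n_repeats", "genome_size")

    def test_standardized_slope_equals_pearson_r(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 40)
        y = 0.6 * x + rng.normal(0, 0.2, 40)
        # standardize, then shift into the valid (non-negative) range; neither
        # the slope on standardized data nor Pearson r changes under a shift
        xs = (x - x.mean()) / x.std(ddof=1) + 10.0
        ys = (y - y.mean()) / y.std(ddof=1) + 10.0
        profs = [
            GenomeRepeatProfile(genome_id=str(i), group=Group.CASH, n_inverted=1,
                                n_tandem=0, mean_repeat_size=float(ys[i]),
                                max_repeat_size=1, genome_size=1 + i,
                                mean_intergenic=float(xs[i]))
            for i in range(40)
        ]
        r = regress(profs, "mean_repeat_size", "mean_intergenic")
        pearson = sps.pearsonr(xs, ys)
        assert r.slope == pytest.approx(pearson.statistic)
        assert r.r_squared == pytest.approx(pearson.statistic ** 2)
        assert r.p_value == pytest.approx(pearson.pvalue, rel=1e-6)

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        profs = profiles_with_slope(0.0004, 12.0, 6.0, 30, seed=5)
        r = regress(profs, "n_repeats", "genome_size")
        x = np.array([p.genome_size for p in profs], dtype=float)
        y = np.array([p.n_inverted + p.n_tandem for p in profs], dtype=float)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert r.slope == pytest.approx(fit.params[1])
        assert r.intercept == pytest.approx(fit.params[0])
        assert r.p_value == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_recovers_planted_slope_within_3_se(self):
        beta = 0.0003
        profs = profiles_with_slope(beta, 10.0, 4.0, 50, seed=11)
        r = regress(profs, "n_repeats", "genome_size")
        x = np.array([p.genome_size for p in profs], dtype=float)
        y = np.array([p.n_inverted + p.n_tandem for p in profs], dtype=float)
        se = sps.linregress(x, y).stderr
        assert abs(r.slope - beta) <= 3 * se


def test_group_pooling_in_panel_sampling():
    panel = sample_profile_panel(5, seed=0)
    groups = {p.group for p in panel}
    assert {Group.CASH, Group.GREEN, Group.RHODOPHYTE} <= groups
    with pytest.raises(ValueError):
        sample_profile_panel(0)
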