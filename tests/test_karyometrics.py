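import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import make_spread
from karyodiv import datasets
from karyodiv import karyometrics as km
from karyodiv.errors import InsufficientComplementError, ValidationError


class TestCentromericIndex:
    @pytest.mark.parametrize(
        "short,long,expected",
        [(2, 2, 50.0), (3, 5, 37.5), (1.5, 3.5, 30.0)],
    )
    def test_values(self, short, long, expected):
        assert km.centromeric_index(short, long) == pytest.approx(expected)

    def test_invalid_arms(self):
        with pytest.raises(ValidationError):
            km.centromeric_index(0, 2)
        with pytest.raises(ValidationError):
            km.centromeric_index(3, 2)


class TestTCL:
    def test_published_haploid_sums(self):
        sums = datasets.nucleus_karyotype_summaries()
        assert km.total_complement_length(sums["L"].abs_mean) == pytest.approx(79.34)
        assert km.total_complement_length(sums["S"].abs_mean) == pytest.approx(61.83)

    def test_single_pair_and_empty(self):
        assert km.total_complement_length([5]) == 5
        with pytest.raises(ValidationError):
            km.total_complement_length([])


class TestRelativeLength:
    def test_basic(self):
        assert km.relative_length(5, 100) == pytest.approx(5.0)

    def test_exceeding_tcl_rejected(self):
        with pytest.raises(ValidationError):
            km.relative_length(101, 100)

    @given(
        st.lists(st.floats(0.5, 20, allow_nan=False), min_size=2, max_size=20)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_metaphase_relative_lengths_sum_to_100(self, lengths):
        tcl = km.total_complement_length(lengths)
        assert sum(km.relative_length(x, tcl) for x in lengths) == pytest.approx(
            100.0, abs=1e-9
        )


class TestLevanClassification:
    @pytest.mark.parametrize(
        "ci,expected",
        [
            (32.19, "sm"),
            (50.0, "m"),
            (37.5, "sm"),   # boundary belongs to the lower class
            (37.6, "m"),
            (25.0, "st"),
            (12.5, "t"),
            (5.0, "t"),
        ],
    )
    def test_bands(self, ci, expected):
        assert km.classify_levan(ci) == expected

    @pytest.mark.parametrize("ci", [0.0, -1.0, 50.5])
    def test_domain(self, ci):
        with pytest.raises(ValidationError):
            km.classify_levan(ci)

    @pytest.mark.parametrize(
        "mean,sd,n,expected",
        [
            (38.84, 4.72, 10, "m-sm"),
            (48.06, 1.20, 10, "m"),
            (32.19, 3.50, 10, "sm"),
            (40.0, 0.0, 10, "m"),
            (36.60, 4.00, 10, "sm-m"),  # mean below the boundary leads
        ],
    )
    def test_ci_rule(self, mean, sd, n, expected):
        assert km.classify_with_ci_rule(mean, sd, n) == expected

    def test_ci_rule_needs_replication(self):
        with pytest.raises(ValidationError):
            km.classify_with_ci_rule(40.0, 1.0, 1)

    @given(st.floats(0.5, 50.0, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_degenerates_to_point_classification_as_sd_vanishes(self, mean):
        assert km.classify_with_ci_rule(mean, 0.0, 10) == km.classify_levan(mean)

    def test_interval_uses_t_quantile(self):
        lo, hi = km.ci_confidence_interval(40.0, 3.0, 10)
        half = stats.t.ppf(0.975, 9) * 3.0 / np.sqrt(10)
        assert (lo, hi) == pytest.approx((40 - half, 40 + half))

    def test_interval_clipped_to_valid_ci_range(self):
        _, hi = km.ci_confidence_interval(49.5, 3.0, 10)
        assert hi == 50.0


class TestPublishedClassificationColumns:
    def test_mamillanum_column(self):
        df = datasets.mamillanum_karyotype_summary()
        labels = [
            km.classify_with_ci_rule(r.ci_mean, r.ci_sd, datasets.N_KARYOTYPES)
            for r in df.itertuples()
        ]
        assert labels == list(df.printed_class)
        assert labels.count("m") == 13
        assert [i + 1 for i, l in enumerate(labels) if l == "m-sm"] == [4, 7]

    def test_nucleus_joint_column(self):
        sums = datasets.nucleus_karyotype_summaries()
        n = datasets.N_KARYOTYPES
        labels = [
            km.classify_joint(
                [(sums[p].ci_mean[i], sums[p].ci_sd[i], n) for p in ("S", "L", "C")]
            )
            for i in range(14)
        ]
        assert labels == list(sums["S"].printed_class)


def brute_force_min_weight(records):
    """Exhaustive minimum-weight perfect matching over all pairings."""
    scale = float(np.mean([r.total_length for r in records]))

    def all_matchings(idx):
        if not idx:
            yield []
            return
        first, rest = idx[0], idx[1:]
        for k, other in enumerate(rest):
            for sub in all_matchings(rest[:k] + rest[k + 1 :]):
                yield [(first, other)] + sub

    best = np.inf
    for matching in all_matchings(list(range(len(records)))):
        w = sum(
            km._pair_dissimilarity(records[i], records[j], scale)
            for i, j in matching
        )
        best = min(best, w)
    return best


class TestAssembleKaryotype:
    def test_equal_pairs_no_leftover(self):
        spread = make_spread([9, 9, 5, 5])
        pairs, leftover = km.assemble_karyotype(spread, 2)
        assert [round(p.mean_length, 6) for p in pairs] == [9, 5]
        assert leftover == []

    def test_small_supernumeraries_left_over(self):
        spread = make_spread([9, 9, 5, 5, 2.5, 2.5])
        pairs, leftover = km.assemble_karyotype(spread, 2)
        assert [round(p.mean_length, 6) for p in pairs] == [9, 5]
        assert sorted(r.total_length for r in leftover) == pytest.approx([2.5, 2.5])

    def test_insufficient_complement(self):
        with pytest.raises(InsufficientComplementError):
            km.assemble_karyotype(make_spread([5, 5]), 2)

    @pytest.mark.parametrize("n_chroms", [4, 6, 8])
    def test_matches_exhaustive_matching_oracle(self, n_chroms, rng):
        for _ in range(20):
            lengths = rng.uniform(1, 10, n_chroms)
            cis = rng.uniform(20, 50, n_chroms)
            spread = make_spread(lengths, cis)
            pairs, _ = km.assemble_karyotype(spread, n_chroms // 2)
            scale = float(np.mean(lengths))
            got = sum(
                km._pair_dissimilarity(p.first, p.second, scale) for p in pairs
            )
            assert got == pytest.approx(brute_force_min_weight(spread.records))

    def test_pairing_invariant_to_record_order(self, rng):
        lengths = [9.1, 9.0, 5.2, 5.0, 3.1, 3.0]
        spread = make_spread(lengths)
        perm = rng.permutation(6)
        shuffled = make_spread([lengths[i] for i in perm])
        p1, _ = km.assemble_karyotype(spread, 3)
        p2, _ = km.assemble_karyotype(shuffled, 3)
        assert [round(p.mean_length, 9) for p in p1] == [
            round(p.mean_length, 9) for p in p2
        ]


class TestSummarize:
    def test_identical_karyotypes_give_zero_sd(self):
        lengths = [9, 9, 6, 6, 4, 4, 2, 2]
        cis = [45, 45, 40, 40, 30, 30, 48, 48]
        spreads = [
            make_spread(lengths, cis, cell_id=f"c{i}", individual_id=f"i{i}")
            for i in range(10)
        ]
        table = km.summarize_population(spreads, 4)
        assert all(p.abs_len.sd == pytest.approx(0, abs=1e-12) for p in table.pairs)
        assert [p.abs_len.mean for p in table.pairs] == pytest.approx([9, 6, 4, 2])
        assert sum(p.rel_len.mean for p in table.pairs) == pytest.approx(100)
        assert table.tcl == pytest.approx(21)

    def test_requires_at_least_two_karyotypes(self):
        with pytest.raises(ValidationError):
            km.summarize_population([make_spread([9, 9, 5, 5])], 2)


class TestTwoSampleT:
    def test_identical_summaries(self):
        t, p, df = km.two_sample_t_from_stats(10, 1, 10, 10, 1, 10)
        assert (t, p, df) == (0.0, 1.0, 18)

    def test_zero_variance_equal_means(self):
        t, p, _ = km.two_sample_t_from_stats(10, 0, 10, 10, 0, 10)
        assert (t, p) == (0.0, 1.0)

    def test_published_pair1_ci_comparison_not_significant(self):
        # Lithuanian vs Czech pair-1 centromeric index; hand-computed
        # pooled-variance t = -0.292.
        t, p, df = km.two_sample_t_from_stats(44.90, 2.88, 10, 45.27, 2.78, 10)
        assert abs(t) == pytest.approx(0.292, abs=0.001)
        assert df == 18
        assert p > 0.05

    def test_extreme_separation_significant(self):
        _, p, _ = km.two_sample_t_from_stats(10, 1, 10, 20, 1, 10)
        assert p < 1e-6

    def test_agrees_with_scipy(self, rng):
        for _ in range(20):
            ma, mb = rng.normal(10, 2, 2)
            sa, sb = rng.uniform(0.5, 3, 2)
            na, nb = rng.integers(3, 15, 2)
            t, p, _ = km.two_sample_t_from_stats(ma, sa, na, mb, sb, nb)
            ref = stats.ttest_ind_from_stats(ma, sa, na, mb, sb, nb, equal_var=True)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    @given(
        st.floats(1, 50), st.floats(0.1, 5), st.integers(2, 20),
        st.floats(1, 50), st.floats(0.1, 5), st.integers(2, 20),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry(self, ma, sa, na, mb, sb, nb):
        t1, p1, _ = km.two_sample_t_from_stats(ma, sa, na, mb, sb, nb)
        t2, p2, _ = km.two_sample_t_from_stats(mb, sb, nb, ma, sa, na)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


def test_compare_populations_on_published_tables():
    """Pairwise comparison of the three published karyotype tables: right
    shape (14 pairs x 2 statistics) and the largest chromosome pair shows
    no significant CI difference between any two populations."""
    from karyodiv.karyometrics import KaryotypePairSummary, KaryotypeTable, MeanSD

    sums = datasets.nucleus_karyotype_summaries()
    tables = {}
    for pop, df in sums.items():
        pairs = tuple(
            KaryotypePairSummary(
                pair_index=r.pair,
                abs_len=MeanSD(r.abs_mean, r.abs_sd),
                rel_len=MeanSD(r.rel_mean, r.rel_sd),
                ci=MeanSD(r.ci_mean, r.ci_sd),
                n_karyotypes=datasets.N_KARYOTYPES,
                levan_class=km.classify_with_ci_rule(
                    r.ci_mean, r.ci_sd, datasets.N_KARYOTYPES
                ),
            )
            for r in df.itertuples()
        )
        tables[pop] = KaryotypeTable(pop, pairs, float(df.abs_mean.sum()))
    for a, b in itertools.combinations(tables, 2):
        result = km.compare_populations(tables[a], tables[b])
        assert len(result) == 14 * 2
        pair1_ci = result[(result.pair == 1) & (result.statistic == "ci")]
        assert not pair1_ci.significant.any(), f"{a} vs {b}"
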