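from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mastagree import (
    EmptyComparisonError,
    MatchedPair,
    PairedTable,
    UndefinedStatisticError,
    cohen_kappa,
    concordant_positive_rate,
    dichotomize,
    kappa_ci,
    kappa_se,
    summarize_agreement,
    summarize_table,
    tabulate,
    total_agreement,
)
from mastagree._format import round_half_up


def kappa_oracle(n_pp: int, n_pn: int, n_np: int, n_nn: int) -> float | None:
    """Independent brute-force kappa: expand to labeled pairs, count."""
    pairs = [(1, 1)] * n_pp + [(1, 0)] * n_pn + [(0, 1)] * n_np + [(0, 0)] * n_nn
    n = len(pairs)
    p_o = sum(a == b for a, b in pairs) / n
    p_e = 0.0
    for category in (0, 1):
        p_a = sum(a == category for a, _ in pairs) / n
        p_b = sum(b == category for _, b in pairs) / n
        p_e += p_a * p_b
    if p_e == 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def all_tables(max_n: int):
    for n in range(1, max_n + 1):
        for n_pp in range(n + 1):
            for n_pn in range(n - n_pp + 1):
                for n_np in range(n - n_pp - n_pn + 1):
                    yield (n_pp, n_pn, n_np, n - n_pp - n_pn - n_np)


tables_st = st.tuples(
    st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
).filter(lambda t: sum(t) > 0)


class TestDichotomize:
    def test_at_cutoff_is_positive(self):
        assert dichotomize(2, 2) is True

    def test_below_cutoff_is_negative(self):
        assert dichotomize(1, 2) is False

    def test_class_zero_never_positive(self):
        assert dichotomize(0, 1) is False

    @pytest.mark.parametrize("cutoff", [0, 7, "x"])
    def test_invalid_cutoff(self, cutoff):
        with pytest.raises(ValueError):
            dichotomize(2, cutoff)


class TestTabulate:
    PAIRS = [
        MatchedPair("P1", "cat", 3, 3),
        MatchedPair("P2", "cat", 0, 0),
        MatchedPair("P3", "cat", 2, 0),
    ]

    def test_counts_at_cutoff_2(self):
        t = tabulate(self.PAIRS, 2)
        assert (t.n_pp, t.n_pn, t.n_np, t.n_nn) == (1, 1, 0, 1)
        assert t.n == 3

    def test_counts_at_cutoff_3(self):
        t = tabulate(self.PAIRS, 3)
        assert (t.n_pp, t.n_nn, t.n) == (1, 2, 3)

    def test_empty_signals(self):
        with pytest.raises(EmptyComparisonError):
            tabulate([], 2)

    @given(
        st.lists(
            st.tuples(st.integers(0, 6), st.integers(0, 6)), min_size=1, max_size=200
        ),
        st.integers(1, 6),
    )
    @settings(deadline=None)
    def test_partition_property(self, class_pairs, cutoff):
        pairs = [
            MatchedPair(f"P{i}", "x", a, b) for i, (a, b) in enumerate(class_pairs)
        ]
        t = tabulate(pairs, cutoff)
        assert t.n == len(pairs)


class TestFormulas:
    def test_total_agreement_reconstruction(self):
        # 8 one-sided discordances among 30 pairs
        assert round_half_up(total_agreement(PairedTable(0, 8, 0, 22)), 1) == 73.3

    def test_total_agreement_no_discordance(self):
        assert total_agreement(PairedTable(5, 0, 0, 10)) == 100.0

    def test_total_agreement_dfarinae(self):
        assert round_half_up(total_agreement(PairedTable(21, 1, 1, 20)), 1) == 95.3

    def test_cpr_dpteronyssinus(self):
        assert round_half_up(concordant_positive_rate(PairedTable(22, 0, 0, 21)), 1) == 51.2

    def test_cpr_zero(self):
        assert concordant_positive_rate(PairedTable(0, 3, 2, 10)) == 0.0

    def test_cpr_protia_inhalant(self):
        assert round_half_up(concordant_positive_rate(PairedTable(11, 16, 0, 66)), 1) == 11.8

    def test_agreement_exact_complement(self):
        for table in all_tables(8):
            t = PairedTable(*table)
            discordant_pct = (t.n_pn + t.n_np) * 100.0 / t.n
            assert total_agreement(t) + discordant_pct == pytest.approx(100.0, abs=1e-9)


class TestKappa:
    def test_dfarinae_food(self):
        assert round_half_up(cohen_kappa(PairedTable(21, 1, 1, 20)), 2) == 0.91

    def test_all_negative_undefined(self):
        assert cohen_kappa(PairedTable(0, 0, 0, 43)) is None

    def test_all_positive_undefined(self):
        assert cohen_kappa(PairedTable(43, 0, 0, 0)) is None

    def test_single_one_sided_discordance_zero(self):
        # p_o = p_e = (N-1)/N symbolically
        assert cohen_kappa(PairedTable(0, 1, 0, 42)) == pytest.approx(0.0, abs=1e-12)

    def test_oracle_equivalence_exhaustive(self):
        # every 2x2 table with N <= 12 against the brute-force definition
        for table in all_tables(12):
            expected = kappa_oracle(*table)
            actual = cohen_kappa(PairedTable(*table))
            if expected is None:
                assert actual is None, table
            else:
                assert actual == pytest.approx(expected, abs=1e-12), table

    def test_sklearn_cross_check(self):
        # second, independent library implementation
        from sklearn.metrics import cohen_kappa_score

        for table in [(21, 1, 1, 20), (1, 1, 0, 41), (5, 3, 2, 30), (0, 1, 1, 88)]:
            n_pp, n_pn, n_np, n_nn = table
            a = [1] * (n_pp + n_pn) + [0] * (n_np + n_nn)
            b = [1] * n_pp + [0] * n_pn + [1] * n_np + [0] * n_nn
            assert cohen_kappa(PairedTable(*table)) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    @given(tables_st)
    def test_transposition_invariance(self, table):
        t = PairedTable(*table)
        k1, k2 = cohen_kappa(t), cohen_kappa(t.transposed())
        if k1 is None:
            assert k2 is None
        else:
            assert k1 == pytest.approx(k2, abs=1e-12)
            assert kappa_se(t) == pytest.approx(kappa_se(t.transposed()), abs=1e-12)

    @given(tables_st)
    def test_relabel_invariance(self, table):
        # swapping the positive/negative labels on both analyzers swaps
        # n_pp<->n_nn and n_pn<->n_np but leaves kappa unchanged
        n_pp, n_pn, n_np, n_nn = table
        k1 = cohen_kappa(PairedTable(n_pp, n_pn, n_np, n_nn))
        k2 = cohen_kappa(PairedTable(n_nn, n_np, n_pn, n_pp))
        if k1 is None:
            assert k2 is None
        else:
            assert k1 == pytest.approx(k2, abs=1e-12)

    @given(tables_st)
    def test_kappa_one_iff_perfect_nondegenerate(self, table):
        t = PairedTable(*table)
        k = cohen_kappa(t)
        if k is not None and t.n_pn == 0 and t.n_np == 0:
            assert k == pytest.approx(1.0, abs=1e-12)
        if k is not None and k == pytest.approx(1.0, abs=1e-12):
            assert t.n_pn == 0 and t.n_np == 0


class TestKappaSE:
    def test_barley_meal_se(self):
        # frozen from an independent evaluation of the three-term formula
        assert round_half_up(kappa_se(PairedTable(1, 1, 0, 41)), 3) == 0.319

    def test_barley_meal_ci(self):
        t = PairedTable(1, 1, 0, 41)
        k = cohen_kappa(t)
        lo, hi = kappa_ci(k, kappa_se(t))
        assert round_half_up(k, 2) == 0.66
        assert (round_half_up(lo, 2), round_half_up(hi, 2)) == (0.03, 1.28)

    def test_degenerate_discordance_zero_se(self):
        # symbolic cancellation T1 + T2 - T3 = 0, for every N >= 2
        for n in range(2, 101):
            t = PairedTable(0, 1, 0, n - 2)
            assert cohen_kappa(t) == pytest.approx(0.0, abs=1e-12)
            # sqrt of the cancellation residue leaves ~1e-7 in floats
            assert kappa_se(t) == pytest.approx(0.0, abs=1e-6)

    def test_se_undefined_when_kappa_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            kappa_se(PairedTable(0, 0, 0, 10))

    def test_balanced_symmetric_table_transpose_invariant(self):
        t = PairedTable(10, 3, 3, 10)
        assert kappa_se(t) == kappa_se(t.transposed())


class TestKappaCI:
    def test_dfarinae_ci(self):
        t = PairedTable(21, 1, 1, 20)
        lo, hi = kappa_ci(cohen_kappa(t), kappa_se(t))
        assert (round_half_up(lo, 2), round_half_up(hi, 2)) == (0.78, 1.03)

    def test_zero_se_zero_width(self):
        assert kappa_ci(0.5, 0.0) == (0.5, 0.5)

    def test_no_truncation_by_default(self):
        _, hi = kappa_ci(0.66, 0.32)
        assert hi > 1.0

    def test_clip_flag(self):
        lo, hi = kappa_ci(0.9, 0.2, clip=True)
        assert hi == 1.0
        assert lo == pytest.approx(0.9 - 1.959963984540054 * 0.2, abs=1e-9)

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            kappa_ci(0.5, 0.1, level=1.5)


class TestSummaries:
    def test_dfarinae_reconstruction(self):
        pairs = (
            [MatchedPair(f"P{i}", "x", 3, 3) for i in range(21)]
            + [MatchedPair("Q1", "x", 3, 0)]
            + [MatchedPair("Q2", "x", 0, 3)]
            + [MatchedPair(f"R{i}", "x", 0, 0) for i in range(20)]
        )
        s = summarize_agreement(pairs, 2)
        assert round_half_up(s.agreement_pct, 1) == 95.3
        assert round_half_up(s.concordant_positive_pct, 1) == 48.8
        assert round_half_up(s.kappa, 2) == 0.91
        assert (round_half_up(s.ci_low, 2), round_half_up(s.ci_high, 2)) == (0.78, 1.03)

    def test_all_negative_pairs(self):
        pairs = [MatchedPair(f"P{i}", "x", 0, 0) for i in range(43)]
        s = summarize_agreement(pairs, 2)
        assert s.agreement_pct == 100.0
        assert s.concordant_positive_pct == 0.0
        assert not s.kappa_defined
        assert s.kappa is None and s.kappa_se is None and s.ci_low is None

    @given(tables_st)
    def test_agreement_bounds_cpr(self, table):
        s = summarize_table(PairedTable(*table))
        assert 0.0 <= s.concordant_positive_pct <= s.agreement_pct <= 100.0
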