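import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcpin.io_formats import BenchmarkComplexSet
from tcpin.match_evaluation import (
    f_measure,
    match_all,
    overlap_score,
    round_half_up,
    size_distribution,
    threshold_sweep,
)


class TestOverlapScore:
    def test_regulator_complex_worked_example(self):
        # module of 19 proteins covering 17 of a 22-protein complex
        assert overlap_score(17, 19, 22) == pytest.approx(289 / 418)
        assert round_half_up(overlap_score(17, 19, 22)) == 0.69

    def test_eif3_worked_example(self):
        # 9-protein module covering 6 of the 7-protein eIF3 complex
        assert overlap_score(6, 9, 7) == pytest.approx(36 / 63)
        assert round_half_up(overlap_score(6, 9, 7)) == 0.57

    def test_identical_sets_score_one(self):
        assert overlap_score(5, 5, 5) == 1.0

    def test_disjoint_sets_score_zero(self):
        assert overlap_score(0, 4, 9) == 0.0

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            overlap_score(0, 0, 3)

    @given(
        st.integers(1, 40).flatmap(
            lambda g: st.integers(2, 40).flatmap(
                lambda h: st.tuples(
                    st.integers(0, min(g, h)), st.just(g), st.just(h)
                )
            )
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_symmetric_bounded_monotone(self, igh):
        i, g, h = igh
        score = overlap_score(i, g, h)
        assert 0 <= score <= 1
        assert score == overlap_score(i, h, g)
        if i >= 1:
            assert score >= overlap_score(i - 1, g, h)


class TestFMeasure:
    def test_static_network_worked_example(self):
        assert round_half_up(f_measure(0.45, 0.18)) == 0.26

    def test_equal_inputs_are_fixed_points(self):
        for x in (0.0, 0.3, 1.0):
            assert f_measure(x, x) == pytest.approx(x)

    def test_zero_component_gives_zero(self):
        assert f_measure(1.0, 0.0) == 0.0
        assert f_measure(0.0, 0.0) == 0.0


class TestMatchAll:
    @pytest.fixture
    def benchmark(self):
        return BenchmarkComplexSet({"K1": frozenset({"A", "B", "C"})})

    def test_perfect_match(self, benchmark):
        stats, _ = match_all([frozenset({"A", "B", "C"})], benchmark, 0.2)
        assert (stats.TP, stats.FP, stats.FN) == (1, 0, 0)
        assert stats.sensitivity == stats.specificity == stats.f_measure == 1.0

    def test_partial_match_counts(self, benchmark):
        stats, table = match_all(
            [frozenset({"A", "B"}), frozenset({"X", "Y"})], benchmark, 0.2
        )
        # OS({A,B}, K1) = 4/6 >= 0.2 -> one TP; {X,Y} unmatched -> FP
        assert (stats.TP, stats.FP, stats.FN) == (1, 1, 0)
        assert stats.sensitivity == 1.0
        assert stats.specificity == 0.5
        scores = {
            (row["module_index"], row["complex"]): row["os"] for row in table
        }
        assert scores[(0, "K1")] == pytest.approx(4 / 6)
        assert scores[(1, "K1")] == 0.0

    def test_zero_threshold_matches_everything(self, benchmark):
        modules = [frozenset({"Q", "R"}), frozenset({"S", "T"})]
        stats, _ = match_all(modules, benchmark, 0.0)
        assert stats.Mp == len(modules)
        assert stats.Mk == len(benchmark)
        assert stats.sensitivity == 1.0

    def test_empty_benchmark_rejected(self):
        with pytest.raises(ValueError):
            match_all([frozenset({"A", "B"})], BenchmarkComplexSet({}), 0.2)

    def test_agrees_with_brute_force(self, planted_modules, planted_complexes):
        tau = 0.2
        stats, _ = match_all(planted_modules, planted_complexes, tau)
        matched_modules = sum(
            1
            for module in planted_modules
            if any(
                len(module & members) ** 2 / (len(module) * len(members)) >= tau
                for members in planted_complexes.complexes.values()
            )
        )
        matched_complexes = sum(
            1
            for members in planted_complexes.complexes.values()
            if any(
                len(module & members) ** 2 / (len(module) * len(members)) >= tau
                for module in planted_modules
            )
        )
        assert stats.Mp == matched_modules
        assert stats.Mk == matched_complexes
        assert stats.FN == len(planted_complexes) - matched_complexes

    def test_mp_mk_nonincreasing_in_threshold(self, planted_modules, planted_complexes):
        sweep = threshold_sweep(planted_modules, planted_complexes)
        mps = [s.Mp for s in sweep]
        mks = [s.Mk for s in sweep]
        assert mps == sorted(mps, reverse=True)
        assert mks == sorted(mks, reverse=True)


class TestSizeDistribution:
    def test_small_histogram(self):
        histogram, n_large = size_distribution(
            [frozenset("AB"), frozenset("CD"), frozenset("EFG")]
        )
        assert histogram[2] == 2
        assert histogram[3] == 1
        assert n_large == 0

    def test_empty_set(self):
        histogram, n_large = size_distribution([])
        assert not histogram and n_large == 0

    def test_large_module_counted(self):
        big = frozenset(f"P{i}" for i in range(85))
        assert size_distribution([big])[1] == 1
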