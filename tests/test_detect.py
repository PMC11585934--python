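import numpy as np
import pytest

from termpeaks import (
    Parameters,
    benjamini_hochberg,
    compute_global_cutoff,
    poisson_upper_tail,
    scan_strand,
)

from conftest import make_coverage, random_sparse_coverage
from reference import bh_step_up, naive_scan, poisson_tail_direct


class TestParameters:
    def test_defaults_match_documented_values(self):
        p = Parameters()
        assert (p.readScoreMinimum, p.threshAdjust, p.highOutlierTrim) == (30, 0.75, 0.01)
        assert (p.slidingWindowSize, p.slidingWindowMovementDistance) == (51, 25)
        assert (p.user_pValue, p.adjacentPeakDistance, p.peakCondensingDistance) == (0.005, 2, 20)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"readScoreMinimum": -1},
            {"threshAdjust": 0.0},
            {"threshAdjust": 1.5},
            {"highOutlierTrim": 1.0},
            {"slidingWindowSize": 50},  # even
            {"slidingWindowSize": 11, "slidingWindowMovementDistance": 12},  # gap
            {"user_pValue": 0.0},
            {"adjacentPeakDistance": -1},
        ],
    )
    def test_out_of_range_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Parameters(**kwargs)


class TestGlobalCutoff:
    def _coverage_from_values(self, values, strand="+"):
        counts = {i + 1: v for i, v in enumerate(values)}
        return make_coverage(counts, genome_length=len(values) + 10, strand=strand)

    def test_worked_example(self, default_params):
        # values [100, 50, 30, 10, 5, 5]: prefix {100, 50} reaches 75% of 200,
        # trim floor(0.01 * 2) = 0, cutoff = mean(100, 50) = 75
        cov = self._coverage_from_values([100, 50, 30, 10, 5, 5])
        result = compute_global_cutoff([cov], default_params)
        assert result.cutoff == pytest.approx(75.0)
        assert result.n_selected == 2
        assert result.n_trimmed == 0
        assert result.total_coverage == 200

    def test_identical_values_give_that_value(self):
        cov = self._coverage_from_values([7] * 20)
        params = Parameters(threshAdjust=0.4, highOutlierTrim=0.0)
        assert compute_global_cutoff([cov], params).cutoff == pytest.approx(7.0)

    def test_full_prefix_no_trim_gives_overall_mean(self):
        values = [13, 8, 5, 2, 1, 1]
        cov = self._coverage_from_values(values)
        params = Parameters(threshAdjust=1.0, highOutlierTrim=0.0)
        assert compute_global_cutoff([cov], params).cutoff == pytest.approx(np.mean(values))

    def test_both_strands_are_pooled(self, default_params):
        plus = self._coverage_from_values([100, 5], strand="+")
        minus = self._coverage_from_values([50, 30, 10, 5], strand="-")
        result = compute_global_cutoff([plus, minus], default_params)
        assert result.cutoff == pytest.approx(75.0)

    def test_trim_count_uses_floor_of_prefix_size(self):
        # 20 equal values, threshAdjust=1 selects all, trim floor(0.1*20)=2
        cov = self._coverage_from_values(list(range(30, 10, -1)))
        params = Parameters(threshAdjust=1.0, highOutlierTrim=0.1)
        result = compute_global_cutoff([cov], params)
        assert result.n_trimmed == 2
        assert result.n_selected == 18
        assert result.cutoff == pytest.approx(np.mean(sorted(range(11, 31))[:-2]))

    def test_trimmed_prefix_never_exceeds_max_selected(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            values = rng.integers(1, 1000, size=rng.integers(2, 200)).tolist()
            cov = self._coverage_from_values(values)
            result = compute_global_cutoff([cov], Parameters())
            assert result.cutoff <= max(values)
            trim_base = result.n_selected + result.n_trimmed
            assert result.n_trimmed == int(np.floor(0.01 * trim_base))

    def test_all_zero_coverage_is_an_error(self, default_params):
        cov = make_coverage({}, genome_length=100)
        with pytest.raises(ValueError, match="no signal"):
            compute_global_cutoff([cov], default_params)

    def test_extreme_trim_never_empties_tiny_prefixes(self):
        # floor-based trimming removes floor(trim * k) < k values, so even a
        # trim fraction of 0.9 on a one-position prefix leaves the mean defined
        cov = self._coverage_from_values([100, 1, 1])
        params = Parameters(threshAdjust=0.9, highOutlierTrim=0.9)
        result = compute_global_cutoff([cov], params)
        assert result.n_selected >= 1
        assert result.cutoff == pytest.approx(100.0)


class TestPoissonUpperTail:
    def test_x_zero_is_one(self):
        assert poisson_upper_tail(0, 0.0) == 1.0
        assert poisson_upper_tail(0, 123.4) == 1.0

    def test_lambda_zero_is_degenerate(self):
        assert poisson_upper_tail(1, 0.0) == 0.0
        assert poisson_upper_tail(50, 0.0) == 0.0

    @pytest.mark.parametrize("lam", [0.1, 1.0, 5.0, 20.0, 100.0])
    def test_agrees_with_direct_summation(self, lam):
        for x in range(0, 301, 7):
            assert poisson_upper_tail(x, lam) == pytest.approx(
                poisson_tail_direct(x, lam), abs=1e-12
            )

    def test_worked_value_lambda_five(self):
        # independent series sum for P(X >= 10 | lam = 5)
        assert poisson_upper_tail(10, 5.0) == pytest.approx(
            poisson_tail_direct(10, 5.0), abs=1e-12
        )

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            poisson_upper_tail(-1, 1.0)
        with pytest.raises(ValueError):
            poisson_upper_tail(1, -0.5)


class TestBenjaminiHochberg:
    def test_worked_vector(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_textbook_step_up_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(1, 2000))
            p = rng.random(n) ** rng.uniform(0.5, 3.0)
            np.testing.assert_allclose(benjamini_hochberg(p), bh_step_up(p.tolist()), atol=1e-12)

    def test_never_decreases_p(self):
        rng = np.random.default_rng(7)
        p = rng.random(500)
        assert np.all(benjamini_hochberg(p) >= p - 1e-15)

    def test_empty_input(self):
        assert len(benjamini_hochberg([])) == 0


def scan_to_dict(result):
    return {sp.position: sp for sp in result}


class TestScanStrand:
    def test_empty_coverage_gives_empty_result(self, default_params):
        cov = make_coverage({}, genome_length=1000)
        assert scan_strand(cov, 5.0, default_params) == []

    def test_uniform_coverage_is_never_significant(self, default_params):
        c = 8
        cov = make_coverage({i: c for i in range(1, 501)}, genome_length=500)
        assert scan_strand(cov, float(c), default_params) == []

    def test_lone_spike_in_empty_window_is_significant(self, default_params):
        cov = make_coverage({300: 100}, genome_length=1000)
        result = scan_strand(cov, 10.0, default_params)
        assert [sp.position for sp in result] == [300]
        sp = result[0]
        assert sp.coverage == 100
        assert sp.window_lambda == pytest.approx(100 / 51)
        assert sp.p_adj < 1e-50

    def test_positions_below_cutoff_are_not_reported(self, default_params):
        cov = make_coverage({300: 100, 600: 9}, genome_length=1000)
        result = scan_strand(cov, 10.0, default_params)
        assert [sp.position for sp in result] == [300]

    def test_matches_naive_reference_on_random_maps(self, default_params):
        rng = np.random.default_rng(8)
        for _ in range(5):
            genome_length = int(rng.integers(200, 3000))
            counts = random_sparse_coverage(rng, genome_length, n_nonzero=genome_length // 10)
            cov = make_coverage(counts, genome_length)
            cutoff = float(rng.integers(1, 20))
            got = scan_to_dict(scan_strand(cov, cutoff, default_params))
            expected = naive_scan(
                counts, genome_length, cutoff,
                default_params.slidingWindowSize,
                default_params.slidingWindowMovementDistance,
                default_params.user_pValue,
            )
            assert set(got) == set(expected)
            for pos, (e_cov, e_lam, e_praw, e_padj) in expected.items():
                sp = got[pos]
                assert sp.coverage == e_cov
                assert sp.window_lambda == pytest.approx(e_lam, abs=1e-12)
                assert sp.p_adj == pytest.approx(e_padj, rel=1e-9, abs=1e-12)

    def test_raising_cutoff_never_adds_reported_positions(self, default_params):
        rng = np.random.default_rng(9)
        counts = random_sparse_coverage(rng, 2000, n_nonzero=150)
        cov = make_coverage(counts, 2000)
        previous = None
        for cutoff in (1.0, 5.0, 10.0, 20.0, 40.0):
            tested = {p for p, c in counts.items() if c >= cutoff}
            if previous is not None:
                assert tested <= previous
            previous = tested
            for sp in scan_strand(cov, cutoff, default_params):
                assert sp.coverage >= cutoff

    def test_emitted_records_satisfy_invariants(self, default_params):
        rng = np.random.default_rng(10)
        counts = random_sparse_coverage(rng, 3000, n_nonzero=300)
        cov = make_coverage(counts, 3000)
        for sp in scan_strand(cov, 3.0, default_params):
            assert sp.p_adj >= sp.p_raw - 1e-15
            assert sp.p_adj <= 1.0
            assert sp.p_adj < default_params.user_pValue
            assert sp.coverage == counts[sp.position]

    def test_local_spike_survives_distal_high_expression(self, default_params):
        # the motivating property of window-local normalization: a modest
        # spike over a quiet background is detected even when a distal
        # region of the same strand is three orders of magnitude hotter
        rng = np.random.default_rng(11)
        counts = {}
        for pos in range(1, 1001):
            c = int(rng.poisson(1.0))
            if c:
                counts[pos] = c
        counts[500] = 30
        for pos in range(3001, 4001):
            counts[pos] = int(rng.poisson(500.0))
        cov = make_coverage(counts, 5000)
        result = scan_to_dict(scan_strand(cov, 30.0, default_params))
        assert 500 in result
        assert result[500].window_lambda < 5  # judged against the local window
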