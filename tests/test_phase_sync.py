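import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from planksync import (
    PhaseUndefinedError,
    SynchronizationUndefinedError,
    ValidationError,
    detect_maxima,
    phase,
    pli,
    pli_pipeline,
    rank_correlation,
    surrogate_test,
)
from planksync.phase_sync import pli_from_phase_differences


class TestDetectMaxima:
    def test_two_peaks(self):
        assert detect_maxima([0, 1, 0, 2, 0]).tolist() == [1, 3]

    def test_plateau_first_index_wins(self):
        assert detect_maxima([0, 2, 2, 0]).tolist() == [1]

    def test_monotone_series_has_no_phase(self):
        with pytest.raises(PhaseUndefinedError):
            detect_maxima([3, 2, 1])

    def test_endpoints_are_never_maxima(self):
        # the leading 5 and trailing 0 are not candidates
        assert detect_maxima([5, 1, 2, 1, 0]).tolist() == [2]

    def test_single_maximum_cannot_carry_a_phase(self):
        maxima = detect_maxima([0, 1, 0])
        assert maxima.tolist() == [1]
        with pytest.raises(PhaseUndefinedError):
            phase([0, 1, 0], maxima=maxima)


class TestPhase:
    def test_midpoint_between_maxima_is_pi(self):
        x = np.zeros(10)
        ph = phase(x, maxima=np.array([2, 8]))
        j = np.flatnonzero(ph.indices == 5)[0]
        assert ph.phase[j] == pytest.approx(np.pi)

    def test_cycle_endpoints(self):
        ph = phase(np.zeros(10), maxima=np.array([2, 8]))
        assert ph.phase[0] == 0.0
        assert ph.phase[-1] == pytest.approx(2 * np.pi)

    def test_second_cycle_counts_from_m_equals_one(self):
        ph = phase(np.zeros(13), maxima=np.array([0, 6, 12]))
        j = np.flatnonzero(ph.indices == 9)[0]
        assert ph.phase[j] == pytest.approx(3 * np.pi)

    def test_phase_at_maxima_is_multiple_of_two_pi(self):
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * np.arange(60) / 7.3) + 0.1 * rng.normal(size=60)
        ph = phase(x)
        at_max = ph.phase[np.isin(ph.indices, ph.maxima)]
        np.testing.assert_allclose(at_max / (2 * np.pi),
                                   np.round(at_max / (2 * np.pi)), atol=1e-12)

    def test_phase_invariant_under_positive_affine_rescaling(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        ph1 = phase(x)
        ph2 = phase(3.5 * x + 100.0)
        np.testing.assert_array_equal(ph1.maxima, ph2.maxima)
        np.testing.assert_allclose(ph1.phase, ph2.phase)

    def test_phase_is_nondecreasing(self):
        rng = np.random.default_rng(2)
        ph = phase(rng.normal(size=80))
        assert np.all(np.diff(ph.phase) >= 0)


class TestPLI:
    @pytest.mark.parametrize(
        "dphi,expected",
        [
            (np.zeros(4), 1.0),
            (np.array([0.0, np.pi]), 0.0),
            (np.array([0.0, np.pi / 2]), np.sqrt(2) / 2),
        ],
    )
    def test_analytic_values(self, dphi, expected):
        assert pli_from_phase_differences(dphi) == pytest.approx(expected, abs=1e-12)

    def test_constant_nonzero_phase_difference_gives_one(self):
        assert pli_from_phase_differences(np.full(7, 1.234)) == pytest.approx(1.0, abs=1e-12)

    def test_common_domain_intersection(self):
        a = phase(np.zeros(10), maxima=np.array([1, 8]))
        b = phase(np.zeros(10), maxima=np.array([4, 9]))
        value, n = pli(a, b)
        assert n == 5  # indices 4..8
        assert 0.0 <= value <= 1.0

    def test_disjoint_domains_error(self):
        a = phase(np.zeros(20), maxima=np.array([1, 5]))
        b = phase(np.zeros(20), maxima=np.array([10, 15]))
        with pytest.raises(SynchronizationUndefinedError):
            pli(a, b)


class TestPliPipeline:
    def test_self_synchronization_is_one(self):
        x = np.sin(2 * np.pi * np.arange(24) / 12)
        value, _ = pli_pipeline(x, x)
        assert value == pytest.approx(1.0, abs=1e-12)

    def test_constant_lag_still_gives_one(self):
        t = np.arange(40)
        a = np.sin(2 * np.pi * t / 10)
        b = np.sin(2 * np.pi * (t - 3) / 10)
        value, _ = pli_pipeline(a, b)
        assert value == pytest.approx(1.0, abs=1e-9)

    def test_incommensurate_periods_below_one(self):
        t = np.arange(140)
        a = np.sin(2 * np.pi * t / 10)
        b = np.sin(2 * np.pi * t / 7)
        value, n = pli_pipeline(a, b)
        assert value < 0.99
        assert n > 100

    def test_calendar_time_axis_changes_phase_between_maxima(self):
        x = np.array([0, 1, 0, 0, 1, 0, 0, 1, 0], dtype=float)
        uniform = phase(x)
        stretched = phase(x, times=np.array([0, 1, 2, 3, 4, 5, 9, 10, 11.0]))
        assert not np.allclose(uniform.phase, stretched.phase)


class TestSurrogateTest:
    def test_fixed_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=60), rng.normal(size=60)
        r1 = surrogate_test(a, b, n_surrogates=50, seed=42)
        r2 = surrogate_test(a, b, n_surrogates=50, seed=42)
        assert np.array_equal(r1.surrogate_plis, r2.surrogate_plis)
        assert r1.significance == r2.significance

    def test_different_seeds_differ(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=60), rng.normal(size=60)
        r1 = surrogate_test(a, b, n_surrogates=50, seed=1)
        r2 = surrogate_test(a, b, n_surrogates=50, seed=2)
        assert not np.array_equal(r1.surrogate_plis, r2.surrogate_plis)

    def test_perfectly_locked_pair_beats_all_surrogates(self):
        t = np.arange(120)
        a = np.sin(2 * np.pi * t / 12 + 0.3)
        b = np.sin(2 * np.pi * t / 12 + 1.0)
        r = surrogate_test(a, b, n_surrogates=100, seed=0)
        assert r.pli == pytest.approx(1.0, abs=1e-9)
        assert r.significance == 100.0
        assert r.synchronized

    def test_single_series_shuffle_mode(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=60), rng.normal(size=60)
        r = surrogate_test(a, b, n_surrogates=30, seed=7, mode="a")
        assert r.mode == "a"
        assert len(r.surrogate_plis) == 30

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValidationError):
            surrogate_test(np.zeros(5), np.zeros(5), mode="neither")


def test_null_mean_squared_pli_matches_analytic_one_over_n():
    """For i.i.d. uniform phase differences, E[PLI²] = 1/N exactly."""
    rng = np.random.default_rng(2024)
    n_rep = 10_000
    for n in (25, 100, 400):
        dphi = rng.uniform(0, 2 * np.pi, size=(n_rep, n))
        plis2 = np.abs(np.exp(1j * dphi).mean(axis=1)) ** 2
        se = plis2.std(ddof=1) / np.sqrt(n_rep)
        assert abs(plis2.mean() - 1.0 / n) < 3 * se


@settings(max_examples=60, derandomize=True)
@given(
    dphi=st.lists(st.floats(-50, 50), min_size=1, max_size=30),
    offset=st.floats(-10, 10),
)
def test_pli_bounded_and_shift_invariant(dphi, offset):
    """PLI lies in [0,1] and only depends on phase differences mod a shift."""
    value = pli_from_phase_differences(dphi)
    assert 0.0 <= value <= 1.0 + 1e-12
    shifted = pli_from_phase_differences(np.asarray(dphi) + offset)
    assert shifted == pytest.approx(value, abs=1e-9)


class TestRankCorrelation:
    def test_perfect_monotone(self):
        rho, _ = rank_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_perfect_antitone(self):
        rho, _ = rank_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_rank_example(self):
        rho, _ = rank_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            rank_correlation([1.0, 1.0, 1.0], [1, 2, 3])
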