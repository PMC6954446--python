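import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaxl import mutsignal as ms
from rnaxl.mutsignal import (
    ConsensusSignal,
    SignalProfile,
    apply_coverage_mask,
    background_threshold,
    combine_replicates,
    filter_background,
    fold_change,
    ks_two_sample,
    replicate_correlation,
    sigma_sites,
    t_test_one_sample,
    t_test_two_sample,
    top_sites,
)
from tests.conftest import rate_profile


# ---------------------------------------------------------------------------
# independent oracles

def pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def ks_d_oracle(x, y):
    """sup |ECDF_x - ECDF_y| by brute-force evaluation at every sample point."""
    pts = sorted(set(x) | set(y))
    d = 0.0
    for t in pts:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        d = max(d, abs(fx - fy))
    return d


def welch_t_oracle(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    return (ma - mb) / math.sqrt(va / na + vb / nb)


def nearest_rank_oracle(values, pct):
    v = sorted(values)
    rank = math.ceil(pct * len(v))
    return v[max(rank, 1) - 1]


# ---------------------------------------------------------------------------


class TestCoverageMask:
    def test_strict_boundary(self):
        prof = rate_profile("g", [0.01, 0.01], coverage=[9_999, 10_000])
        out = apply_coverage_mask(prof, 10_000)
        assert np.isnan(out.rate[0])
        assert out.rate[1] == 0.01

    def test_min_cov_zero_is_identity(self):
        prof = rate_profile("g", [0.01, None, 0.02], coverage=[5, 0, 7])
        out = apply_coverage_mask(prof, 0)
        assert np.array_equal(out.present, prof.present)
        assert out.rate[0] == 0.01


class TestFoldChange:
    def test_simple_ratio(self):
        sig = fold_change(rate_profile("g", [0.003]), rate_profile("g", [0.001]))
        assert sig.signal[0] == pytest.approx(3.0)

    def test_zero_control_floored_by_coverage(self):
        test = rate_profile("g", [0.002], coverage=[10_000])
        ctrl = rate_profile("g", [0.0], coverage=[10_000])
        assert fold_change(test, ctrl).signal[0] == pytest.approx(20.0)

    def test_self_fold_change_is_one(self, small_pair_signal):
        prof = rate_profile("g", [0.001, 0.03, None, 0.5])
        sig = fold_change(prof, prof)
        present = sig.present
        assert present.tolist() == [True, True, False, True]
        assert np.allclose(sig.signal[present], 1.0)

    def test_absent_propagates(self):
        sig = fold_change(rate_profile("g", [None, 0.1]), rate_profile("g", [0.1, None]))
        assert not sig.present.any()

    def test_event_mismatch_rejected(self):
        with pytest.raises(ValueError, match="event"):
            fold_change(
                rate_profile("g", [0.1], event="T>C"),
                rate_profile("g", [0.1], event="mismatch:AC"),
            )

    def test_genome_mismatch_rejected(self):
        with pytest.raises(ValueError, match="genome"):
            fold_change(rate_profile("g1", [0.1]), rate_profile("g2", [0.1]))

    def test_rescaling_invariance(self):
        # common positive rescaling of both rates leaves the signal unchanged
        t = np.array([0.001, 0.004, 0.03])
        c = np.array([0.002, 0.001, 0.01])
        cov = [1_000_000] * 3  # floor far below every rate
        s1 = fold_change(rate_profile("g", t, cov), rate_profile("g", c, cov)).signal
        s2 = fold_change(rate_profile("g", 7 * t, cov), rate_profile("g", 7 * c, cov)).signal
        assert np.allclose(s1, s2)


class TestBackgroundThreshold:
    def test_nearest_rank_100(self):
        rates = [0.001 * i for i in range(1, 101)]
        assert background_threshold(rates, 0.05) == pytest.approx(0.095)

    def test_all_equal(self):
        assert background_threshold([0.4] * 17) == 0.4

    def test_single_value(self):
        assert background_threshold([0.123]) == 0.123

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            background_threshold([])

    def test_matches_nearest_rank_oracle(self):
        rng = np.random.default_rng(0)
        for n in (3, 10, 37, 101, 250):
            vals = rng.random(n).tolist()
            assert background_threshold(vals, 0.05) == pytest.approx(
                nearest_rank_oracle(vals, 0.95)
            )

    @pytest.mark.parametrize("n", [37, 41, 101, 103, 250, 999])
    def test_retains_ceil_top_frac(self, n):
        # for distinct rates with 0.05*n non-integral, exactly ceil(0.05*n)
        # control positions sit at or above the threshold
        rng = np.random.default_rng(n)
        vals = rng.permutation(np.linspace(0.001, 0.9, n))
        thr = background_threshold(vals, 0.05)
        assert (vals >= thr).sum() == math.ceil(0.05 * n)


class TestFilterBackground:
    def _signal(self, test_rates):
        test = rate_profile("g", test_rates)
        ctrl = rate_profile("g", [0.001] * len(test_rates))
        return fold_change(test, ctrl)

    def test_boundary_kept(self):
        sig = filter_background(self._signal([0.05]), 0.05)
        assert sig.passed_background[0]

    def test_below_removed(self):
        sig = filter_background(self._signal([0.05 - 1e-9]), 0.05)
        assert not sig.passed_background[0]

    def test_zero_threshold_passes_all_present(self):
        sig = filter_background(self._signal([0.0, 0.3]), 0.0)
        assert sig.passed_background.all()

    def test_absent_never_passes(self):
        sig = fold_change(rate_profile("g", [None]), rate_profile("g", [0.1]))
        assert not filter_background(sig, 0.0).passed_background[0]


def _profile_from_signals(signals, passed):
    signals = np.array([np.nan if s is None else s for s in signals], dtype=float)
    return SignalProfile(
        genome_id="g",
        event="T>C",
        signal=signals,
        passed_background=np.asarray(passed, dtype=bool) & ~np.isnan(signals),
        test_rate=np.where(np.isnan(signals), np.nan, 0.01),
        control_rate=np.where(np.isnan(signals), np.nan, 0.001),
    )


class TestCombineReplicates:
    def test_all_passing(self):
        reps = [_profile_from_signals([s], [True]) for s in (2.0, 3.0, 4.0)]
        cons = combine_replicates(reps)
        assert cons.mean_signal[0] == pytest.approx(3.0)
        assert cons.consistent[0]

    def test_two_of_three(self):
        reps = [
            _profile_from_signals([2.0], [True]),
            _profile_from_signals([4.0], [True]),
            _profile_from_signals([9.0], [False]),
        ]
        cons = combine_replicates(reps)
        assert cons.mean_signal[0] == pytest.approx(3.0)
        assert not cons.consistent[0]
        assert cons.n_passing[0] == 2

    def test_vacant_position(self):
        reps = [_profile_from_signals([5.0], [False]) for _ in range(3)]
        cons = combine_replicates(reps)
        assert np.isnan(cons.mean_signal[0])
        assert cons.n_passing[0] == 0

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            combine_replicates([_profile_from_signals([1.0], [True])])

    def test_genome_mismatch_rejected(self):
        a = _profile_from_signals([1.0], [True])
        b = _profile_from_signals([1.0], [True])
        b.genome_id = "other"
        with pytest.raises(ValueError):
            combine_replicates([a, b])


class TestSigmaSites:
    def test_single_outlier(self):
        # mean 2.8, sd 4.02 -> cutoff 6.82; only the 10 exceeds it
        assert list(sigma_sites([1, 1, 1, 1, 10], k=1)) == [5]

    def test_constant_vector_empty(self):
        assert len(sigma_sites([3.0] * 6, k=1)) == 0

    def test_k_zero_selects_above_mean(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        assert list(sigma_sites(vals, k=0)) == [3, 4]

    def test_nan_never_selected(self):
        assert list(sigma_sites([1, 1, np.nan, 50], k=1)) == [4]


class TestTopSites:
    def _consensus(self, means, consistent=None):
        means = np.asarray(means, dtype=float)
        k = 3
        if consistent is None:
            consistent = ~np.isnan(means)
        return ConsensusSignal(
            genome_id="g",
            event="T>C",
            replicate_signals=np.tile(means, (k, 1)),
            mean_signal=means,
            consistent=np.asarray(consistent, dtype=bool),
        )

    def test_tie_broken_by_position(self):
        means = np.full(10, np.nan)
        means[2] = 5.0  # pos 3
        means[9] = 5.0  # pos 10
        means[6] = 4.0  # pos 7
        assert top_sites(self._consensus(means), 2) == [3, 10]

    def test_fewer_candidates_than_n(self):
        means = np.array([np.nan, 2.0, 1.0])
        assert top_sites(self._consensus(means), 5) == [2, 3]

    def test_require_consistent_excludes_higher_singular(self):
        means = np.array([9.0, 2.0, 1.0])
        consistent = np.array([False, True, True])
        assert top_sites(self._consensus(means, consistent), 2) == [2, 3]
        assert top_sites(self._consensus(means, consistent), 2, require_consistent=False) == [1, 2]


class TestReplicateCorrelation:
    def _prof(self, vals):
        return _profile_from_signals(vals, [True] * len(vals))

    def test_identical_profiles(self):
        a = self._prof([1.0, 2.0, 5.0])
        assert replicate_correlation(a, a) == pytest.approx(1.0)

    def test_anticorrelated(self):
        a = self._prof([1.0, 2.0, 3.0])
        b = self._prof([9.0, 8.0, 7.0])
        assert replicate_correlation(a, b) == pytest.approx(-1.0)

    def test_closed_form_value(self):
        a = self._prof([1.0, 2.0, 3.0])
        b = self._prof([1.0, 2.0, 4.0])
        assert replicate_correlation(a, b) == pytest.approx(0.98198, abs=1e-5)

    def test_zero_variance_is_nan(self):
        a = self._prof([1.0, 1.0, 1.0])
        b = self._prof([1.0, 2.0, 3.0])
        assert math.isnan(replicate_correlation(a, b))

    def test_too_few_joint_positions(self):
        a = self._prof([1.0, 2.0])
        with pytest.raises(ValueError):
            replicate_correlation(a, a)

    @given(
        st.lists(st.floats(0, 10), min_size=4, max_size=6),
        st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_oracle(self, x, seed):
        rng = np.random.default_rng(seed)
        y = [v + rng.normal() for v in x]
        if np.std(x) == 0 or np.std(y) == 0:
            return
        a, b = self._prof(x), self._prof(y)
        assert replicate_correlation(a, b) == pytest.approx(pearson_oracle(x, y), abs=1e-9)


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        d, _ = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2], [3, 4])
        assert d == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1])

    def test_matches_brute_force_on_small_grid(self):
        grid = [0.0, 1.0, 2.0]
        for nx, ny in [(2, 2), (2, 3), (3, 3)]:
            for x in itertools.combinations_with_replacement(grid, nx):
                for y in itertools.combinations_with_replacement(grid, ny):
                    d, _ = ks_two_sample(list(x), list(y))
                    assert d == pytest.approx(ks_d_oracle(x, y), abs=1e-12)


class TestTTests:
    def test_identical_samples(self):
        t, p = t_test_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_constant_one_sample_at_mean(self):
        t, p = t_test_one_sample([3.0, 3.0, 3.0], 3.0)
        assert t == 0.0 and p == 1.0

    def test_one_sample_closed_form(self):
        t, _ = t_test_one_sample([4.0, 5.0, 6.0], 2.0)
        assert t == pytest.approx(3 * math.sqrt(3), abs=1e-6)
        assert t == pytest.approx(5.196, abs=1e-3)

    def test_welch_matches_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 7)).tolist()
            b = rng.normal(loc=0.5, size=rng.integers(2, 7)).tolist()
            t, _ = t_test_two_sample(a, b)
            assert t == pytest.approx(welch_t_oracle(a, b), abs=1e-9)


class TestMinorityVariantRobustness:
    def test_shared_variant_yields_flat_signal(self):
        # same elevated raw rate in test and control -> fold change near 1;
        # a test-arm-only elevation of the same size -> signal >= rate ratio
        cov = [100_000] * 3
        test = rate_profile("g", [0.05, 0.05, 0.001], coverage=cov)
        ctrl = rate_profile("g", [0.05, 0.001, 0.001], coverage=cov)
        sig = fold_change(test, ctrl)
        assert 0.5 <= sig.signal[0] <= 2.0  # both-arm variant cancels
        assert sig.signal[1] >= 0.05 / 0.001  # crosslink-only elevation
        assert sig.signal[2] == pytest.approx(1.0)


class TestTsvRoundtrip:
    def test_signal_profile(self, tmp_path, small_pair_signal):
        p = tmp_path / "sig.tsv"
        small_pair_signal.to_tsv(p)
        back = SignalProfile.from_tsv(p, small_pair_signal.genome_id, "T>C")
        assert np.array_equal(back.present, small_pair_signal.present)
        assert np.allclose(
            back.signal[back.present], small_pair_signal.signal[small_pair_signal.present]
        )
        assert np.array_equal(back.passed_background, small_pair_signal.passed_background)

    def test_consensus(self, tmp_path):
        reps = [
            _profile_from_signals([2.0, None], [True, False]),
            _profile_from_signals([4.0, 7.0], [True, True]),
        ]
        cons = combine_replicates(reps)
        p = tmp_path / "cons.tsv"
        cons.to_tsv(p)
        back = ConsensusSignal.from_tsv(p, "g", "T>C")
        assert np.array_equal(back.consistent, cons.consistent)
        assert back.mean_signal[0] == pytest.approx(3.0)
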