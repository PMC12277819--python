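"""Cross-correlogram coupling: binning against a brute-force oracle, mirror
symmetry, normalization, jitter surrogates, and significance verdicts."""

import numpy as np
import pytest

from meanet.coupling import (
    brute_force_ccg,
    ccg_lag_grid,
    coupling_strength,
    cross_correlogram,
    jitter_surrogates,
    normalize_ccg,
    session_coupling_distribution,
)
from meanet.types import CCGParams, ConfigurationError, SessionRecord, SpikeTrain

from conftest import poisson_train

P = CCGParams(bin_s=0.005, window_s=0.1, peak_search_s=0.05, n_surrogates=19,
              alpha=0.05, seed=0)


def _train(times, eid="E00"):
    return SpikeTrain(eid, np.asarray(times, dtype=float))


class TestCCG:
    def test_empty_train_all_zero(self):
        c = cross_correlogram(_train([]), _train([1.0, 2.0], "E01"), P)
        assert np.all(c == 0)

    def test_single_pair_lands_in_correct_bin(self):
        params = CCGParams(bin_s=0.001, window_s=0.01, peak_search_s=0.01,
                           n_surrogates=19, alpha=0.05, jitter_halfwidth_s=0.005)
        c = cross_correlogram(_train([0.0]), _train([0.003], "E01"), params)
        centers = ccg_lag_grid(params)
        assert c.sum() == 1
        assert centers[np.argmax(c)] == pytest.approx(0.003)

    @pytest.mark.parametrize("seed", range(10))
    def test_mirror_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = poisson_train(rng, 5.0, 30.0, "E00")
        b = poisson_train(rng, 5.0, 30.0, "E01")
        np.testing.assert_array_equal(
            cross_correlogram(a, b, P), cross_correlogram(b, a, P)[::-1]
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_and_conserves_pairs(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = poisson_train(rng, 8.0, 20.0, "E00")
        b = poisson_train(rng, 8.0, 20.0, "E01")
        fast = cross_correlogram(a, b, P)
        slow = brute_force_ccg(a, b, P)
        np.testing.assert_array_equal(fast, slow)
        # exact integer conservation over the histogram support
        half = P.window_s + P.bin_s / 2
        lags = b.times_s[None, :] - a.times_s[:, None]
        assert fast.sum() == np.sum((lags >= -half) & (lags < half))

    def test_brute_force_size_guard(self):
        t = _train(np.linspace(0.001, 10, 1100))
        with pytest.raises(ValueError):
            brute_force_ccg(t, _train(np.linspace(0.001, 10, 1100), "E01"), P)


class TestNormalize:
    def test_self_train_zero_lag_is_one(self):
        t = _train(np.arange(50) * 1.0 + 0.5)
        params = CCGParams(bin_s=0.01, window_s=0.05, peak_search_s=0.05,
                           n_surrogates=19, alpha=0.05)
        c = cross_correlogram(t, t, params)
        norm = normalize_ccg(c, t.n_spikes, t.n_spikes)
        assert norm[len(norm) // 2] == pytest.approx(1.0)

    def test_duplication_invariance(self):
        t = np.arange(30) * 1.0 + 0.5
        doubled = np.concatenate([t, t + 40.0])
        params = CCGParams(bin_s=0.01, window_s=0.05, peak_search_s=0.05,
                           n_surrogates=19, alpha=0.05)
        c1 = cross_correlogram(_train(t), _train(t, "E01"), params)
        c2 = cross_correlogram(_train(doubled), _train(doubled, "E01"), params)
        n1 = normalize_ccg(c1, 30, 30)
        n2 = normalize_ccg(c2, 60, 60)
        assert n2[len(n2) // 2] == pytest.approx(n1[len(n1) // 2])

    def test_zero_counts_and_zero_spikes(self):
        assert np.all(normalize_ccg(np.zeros(5), 10, 10) == 0)
        with pytest.raises(ValueError):
            normalize_ccg(np.zeros(5), 0, 10)


class TestSurrogates:
    def test_count_and_rate_preserved(self, rng):
        t = poisson_train(rng, 3.0, 60.0)
        for s in jitter_surrogates(t, P, duration_s=60.0):
            assert s.size == t.n_spikes
            assert s.min() >= 0 and s.max() <= 60.0

    def test_mean_abs_displacement(self):
        # E|U| for U ~ Uniform(-h, h) is h/2; regular train with ISIs wider
        # than the jitter range so sorting never reorders spikes
        t = SpikeTrain("E00", np.arange(1000) * 0.1 + 1.0)
        params = CCGParams(n_surrogates=50, jitter_halfwidth_s=0.02, alpha=0.05)
        disp = [
            np.mean(np.abs(np.sort(s) - t.times_s))
            for s in jitter_surrogates(t, params, duration_s=200.0)
        ]
        assert np.mean(disp) == pytest.approx(0.01, rel=0.05)

    def test_seeded_per_index(self, rng):
        t = poisson_train(rng, 3.0, 30.0)
        s1 = jitter_surrogates(t, P, entropy=(1, 2))
        s2 = jitter_surrogates(t, P, entropy=(1, 2))
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a, b)


class TestSignificance:
    def test_identical_trains_significant_at_zero_lag(self, rng):
        t = poisson_train(rng, 1.0, 60.0)
        assert t.n_spikes >= 20
        r = coupling_strength(t, _train(t.times_s, "E01"), CCGParams())
        assert r.peak_lag_s == 0.0
        assert r.coupling_strength == pytest.approx(1.0)
        assert r.significant

    def test_empty_train_untestable(self):
        r = coupling_strength(_train([]), _train([1.0], "E01"), P)
        assert not r.testable and not r.significant

    def test_verdict_deterministic(self, rng):
        a = poisson_train(rng, 2.0, 120.0, "E00")
        b = poisson_train(rng, 2.0, 120.0, "E01")
        r1 = coupling_strength(a, b, P)
        r2 = coupling_strength(a, b, P)
        assert r1.null_threshold == r2.null_threshold
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.counts, r2.counts)

    def test_alpha_unreachable_with_few_surrogates_rejected(self):
        with pytest.raises(ConfigurationError):
            CCGParams(n_surrogates=19, alpha=0.01)


class TestSessionDistribution:
    def _session(self, rng, n=5, rate=2.0, duration=60.0):
        trains = tuple(
            poisson_train(rng, rate, duration, f"E{i:02d}") for i in range(n)
        )
        return SessionRecord("a1", "APOE3", "BL", duration, trains)

    def test_pair_count_bound(self, rng):
        ses = self._session(rng, n=6)
        dist = session_coupling_distribution(ses, P, electrode_scope="all")
        assert dist.n_pairs_tested <= 6 * 5 // 2
        assert dist.n_significant == dist.strengths.size <= dist.n_pairs_tested

    def test_empty_session_warns(self):
        ses = SessionRecord("a1", "APOE3", "BL", 60.0,
                            (SpikeTrain("E00", np.empty(0)),
                             SpikeTrain("E01", np.empty(0))))
        with pytest.warns(UserWarning):
            dist = session_coupling_distribution(ses, P, electrode_scope="active")
        assert dist.n_pairs_tested == 0 and dist.n_significant == 0

    def test_scope_active_excludes_silent(self, rng):
        trains = (
            poisson_train(rng, 2.0, 60.0, "E00"),
            poisson_train(rng, 2.0, 60.0, "E01"),
            SpikeTrain("E02", np.array([1.0])),  # below 0.1 Hz
        )
        ses = SessionRecord("a1", "APOE3", "BL", 60.0, trains)
        dist = session_coupling_distribution(ses, P, electrode_scope="active")
        assert dist.n_pairs_tested == 1
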