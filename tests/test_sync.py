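"""Synchronization indices: calibration, oracles and invariances."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from swsync.sync import (
    SUBSETS,
    GridSearchResult,
    channel_gamma,
    get_subset,
    global_gamma,
    grid_search,
    pairwise_gamma,
    sync_matrix,
    window_global_gamma,
)
from swsync.wavelet import cwt, cwt_direct, phase

FS = 250.0


class TestPairwiseGamma:
    def test_constant_phase_difference_gives_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 250)
        assert pairwise_gamma(phi, phi - np.pi / 3) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_phase_difference_grid_gives_zero(self):
        n = 250
        delta = 2 * np.pi * np.arange(n) / n
        assert pairwise_gamma(delta, np.zeros(n)) == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_mean_matches_direct_convolution_oracle(self, rng):
        """Mean gamma of independent 1-s noise pairs at (fc=1, fa=12): the
        FFT pipeline must agree with an oracle built from the time-domain
        convolution path, within Monte-Carlo error."""
        n = int(FS)

        def gamma_fft():
            a = phase(cwt(rng.standard_normal(n), FS, 1.0, 12.0))
            b = phase(cwt(rng.standard_normal(n), FS, 1.0, 12.0))
            return pairwise_gamma(a, b)

        def gamma_oracle():
            pa = np.angle(cwt_direct(rng.standard_normal(n), FS, 1.0, 12.0))
            pb = np.angle(cwt_direct(rng.standard_normal(n), FS, 1.0, 12.0))
            d = pa - pb
            return np.hypot(np.mean(np.sin(d)), np.mean(np.cos(d)))

        main = np.array([gamma_fft() for _ in range(300)])
        oracle = np.array([gamma_oracle() for _ in range(100)])
        se = np.hypot(main.std() / np.sqrt(main.size), oracle.std() / np.sqrt(oracle.size))
        assert abs(main.mean() - oracle.mean()) < 3 * se

    def test_bounds_over_many_random_windows(self, rng):
        for _ in range(10_000):
            a = rng.uniform(-np.pi, np.pi, 20)
            b = rng.uniform(-np.pi, np.pi, 20)
            g = pairwise_gamma(a, b)
            assert 0.0 <= g <= 1.0

    def test_invariant_under_common_phase_offset(self, rng):
        a = rng.uniform(-np.pi, np.pi, 100)
        b = rng.uniform(-np.pi, np.pi, 100)
        for c in (0.5, -2.0, np.pi):
            assert pairwise_gamma(a + c, b + c) == pytest.approx(pairwise_gamma(a, b))

    def test_decreases_with_noise_on_locked_sinusoids(self, rng):
        t = np.arange(int(FS)) / FS
        base = 2 * np.pi * 12.0 * t
        means = []
        for amp in (0.1, 0.5, 2.0):
            g = [
                pairwise_gamma(
                    base + amp * rng.standard_normal(t.size),
                    base + amp * rng.standard_normal(t.size),
                )
                for _ in range(200)
            ]
            means.append(np.mean(g))
        assert means[0] > means[1] > means[2]

    def test_all_invalid_samples_rejected(self):
        with pytest.raises(ValueError, match="valid"):
            pairwise_gamma(np.full(10, np.nan), np.zeros(10))

    @settings(derandomize=True, max_examples=200)
    @given(
        phases=hnp.arrays(
            float,
            st.tuples(st.just(2), st.integers(2, 64)),
            elements=st.floats(-np.pi, np.pi),
        ),
        offset=st.floats(-10.0, 10.0),
    )
    def test_bounds_and_offset_invariance_property(self, phases, offset):
        g = pairwise_gamma(phases[0], phases[1])
        assert 0.0 <= g <= 1.0
        shifted = pairwise_gamma(phases[0] + offset, phases[1] + offset)
        assert shifted == pytest.approx(g, abs=1e-9)


class TestSyncMatrix:
    def test_identical_channels_fully_locked(self, rng):
        sig = rng.standard_normal(int(2 * FS))
        phi = phase(cwt(sig, FS, 1.0, 12.0))
        phases = {c: phi for c in SUBSETS["S4"]}
        m = sync_matrix(phases, SUBSETS["S4"])
        off = m.values[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-9)

    def test_symmetric_for_random_input(self, rng):
        phases = {c: rng.uniform(-np.pi, np.pi, 200) for c in SUBSETS["S6"]}
        m = sync_matrix(phases, SUBSETS["S6"])
        np.testing.assert_allclose(m.values, m.values.T)

    def test_s19_has_171_pairs(self):
        n = len(get_subset("S19"))
        assert n * (n - 1) // 2 == 171

    def test_missing_channel_rejected(self, rng):
        phases = {c: rng.uniform(-np.pi, np.pi, 100) for c in ("Fp1", "Fp2", "T5")}
        with pytest.raises(KeyError, match="T6"):
            sync_matrix(phases, SUBSETS["S4"])

    def test_unknown_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            get_subset("S7")


class TestAggregates:
    def _random_matrix(self, rng, n):
        m = np.eye(n)
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(0, 1, iu[0].size)
        m[iu] = vals
        m[(iu[1], iu[0])] = vals
        return m

    def test_constant_offdiagonal(self):
        m = np.full((5, 5), 0.5)
        np.fill_diagonal(m, 1.0)
        assert global_gamma(m) == pytest.approx(0.5)
        assert all(channel_gamma(m, k) == pytest.approx(0.5) for k in range(5))

    def test_all_ones(self):
        assert global_gamma(np.ones((4, 4))) == 1.0

    @pytest.mark.parametrize("subset", ["S4", "S6", "S12", "S19"])
    def test_agree_with_enumeration_oracle(self, rng, subset):
        n = len(SUBSETS[subset])
        m = self._random_matrix(rng, n)
        pairs = list(combinations(range(n), 2))
        brute_global = sum(m[k, l] for k, l in pairs) / len(pairs)
        assert global_gamma(m) == pytest.approx(brute_global, abs=1e-12)
        for k in range(n):
            brute_k = sum(m[k, l] for l in range(n) if l != k) / (n - 1)
            assert channel_gamma(m, k) == pytest.approx(brute_k, abs=1e-12)

    def test_mean_channel_gamma_equals_global_gamma(self, rng):
        m = self._random_matrix(rng, 6)
        chan = [channel_gamma(m, k) for k in range(6)]
        assert np.mean(chan) == pytest.approx(global_gamma(m), abs=1e-12)

    def test_channel_outside_subset_rejected(self, rng):
        m = self._random_matrix(rng, 4)
        with pytest.raises(ValueError):
            channel_gamma(m, 7)


class TestWindowedGamma:
    def test_matches_per_window_matrix_computation(self, rng):
        """The cumulative-sum fast path equals windowed sync_matrix +
        global_gamma evaluated one window at a time."""
        n_ch, dur = 4, 6.0
        x = rng.standard_normal((n_ch, int(dur * FS)))
        phi = phase(cwt(x, FS, 1.0, 12.0))
        starts = np.arange(0.0, dur - 1.0 + 1e-9, 0.5)
        fast = window_global_gamma(phi, FS, starts)
        labels = ("a", "b", "c", "d")
        phases = dict(zip(labels, phi))
        slow = [
            global_gamma(sync_matrix(phases, labels, window=(s, s + 1.0), fs=FS))
            for s in starts
        ]
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_nan_samples_excluded(self, rng):
        phi = rng.uniform(-np.pi, np.pi, size=(2, 250))
        phi_nan = phi.copy()
        phi_nan[0, :50] = np.nan
        g_full = window_global_gamma(phi[:, 50:], FS, np.array([0.0]), window_s=0.8)
        g_nan = window_global_gamma(phi_nan, FS, np.array([0.0]), window_s=1.0)
        # same valid samples enter both averages
        assert g_nan[0] == pytest.approx(
            pairwise_gamma(phi[0, 50:], phi[1, 50:]), abs=1e-12
        )


class TestGridSearch:
    def _segments(self, rng, n_per_class=6):
        t = np.arange(int(FS)) / FS
        segments, labels = [], []
        for _ in range(n_per_class):  # phase-locked 3.5-Hz spike-train stand-ins
            shared = np.sign(np.sin(2 * np.pi * 3.5 * t + rng.uniform(0, 2 * np.pi)))
            segments.append(np.vstack([shared + 0.2 * rng.standard_normal(t.size) for _ in range(3)]))
            labels.append(True)
        for _ in range(n_per_class):
            segments.append(rng.standard_normal((3, t.size)))
            labels.append(False)
        return segments, labels

    def test_matches_exhaustive_scripted_evaluation(self, rng):
        segments, labels = self._segments(rng)
        fc_grid, fa_grid = [1.0], [7.0, 10.5, 14.0]
        res = grid_search(segments, labels, FS, fc_grid, fa_grid)
        assert isinstance(res, GridSearchResult)
        # scripted re-evaluation of the same objective
        labels = np.asarray(labels)
        for j, fa in enumerate(fa_grid):
            gbar = []
            for seg in segments:
                phi = phase(cwt(seg, FS, 1.0, fa))
                gbar.append(window_global_gamma(phi, FS, np.array([0.0]))[0])
            gbar = np.asarray(gbar)
            obj = 100 * (gbar[labels].mean() - gbar[~labels].mean()) / gbar[~labels].mean()
            assert res.objective[0, j] == pytest.approx(obj, abs=1e-9)
        i, j = np.unravel_index(np.argmax(res.objective), res.objective.shape)
        assert res.best == (fc_grid[i], fa_grid[j])

    def test_deterministic(self, rng):
        segments, labels = self._segments(rng, n_per_class=3)
        a = grid_search(segments, labels, FS, [1.0], [10.0, 12.0])
        b = grid_search(segments, labels, FS, [1.0], [10.0, 12.0])
        np.testing.assert_array_equal(a.objective, b.objective)

    def test_single_class_rejected(self, rng):
        segments, _ = self._segments(rng, n_per_class=2)
        with pytest.raises(ValueError, match="both"):
            grid_search(segments, [True] * 4, FS)
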