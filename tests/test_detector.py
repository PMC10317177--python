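"""Training-set construction, k-NN classification, LOOCV and post-processing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swsync.config import RunConfig
from swsync.detector import (
    KnnDetector,
    TrainingSet,
    build_training_set,
    fit,
    interictal_threshold,
    load_model,
    loocv,
    postprocess,
    save_model,
)


class TestThreshold:
    def test_linear_interpolation_quantile(self):
        values = np.arange(1, 101) / 100.0  # 0.01 .. 1.00
        assert interictal_threshold(values) == pytest.approx(0.9505)

    def test_constant_values(self):
        assert interictal_threshold(np.full(30, 0.37)) == pytest.approx(0.37)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            interictal_threshold(np.linspace(0, 1, 10))


def synthetic_frame(rng, subjects=("A", "B", "C"), n_inter=200, n_ictal=30):
    """Feature frame with separated ictal/interictal clusters per subject."""
    frames = []
    for s in subjects:
        start = 0.0
        rows = []
        for _ in range(n_inter):
            rows.append((s, start, rng.normal(0.3, 0.05), rng.normal(1.0, 0.1), 0, False))
            start += 0.5
        for i in range(n_ictal):
            code = 3 if i % 10 == 0 else (5 if i % 10 == 9 else 4)
            rows.append((s, start, rng.normal(0.9, 0.03), rng.normal(4.0, 0.3), code, True))
            start += 0.5
        frames.append(
            pd.DataFrame(
                rows,
                columns=["subject_id", "start_s", "gamma", "amp_norm", "taxonomy", "label"],
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestTrainingSet:
    def test_held_out_subject_absent(self, rng):
        frame = synthetic_frame(rng)
        ts = build_training_set(frame, held_out="C", seed=0)
        assert "C" not in set(ts.subjects)

    def test_class_ratio(self, rng):
        frame = synthetic_frame(rng)
        ts = build_training_set(frame, seed=0)
        assert ts.n_interictal == 3 * ts.n_ictal

    def test_ictal_rows_embedded_and_above_threshold(self, rng):
        frame = synthetic_frame(rng)
        ts = build_training_set(frame, seed=0)
        assert np.all(ts.X[ts.y, 0] > ts.threshold)

    def test_seeded_sampling_contract(self, rng):
        frame = synthetic_frame(rng)
        a = build_training_set(frame, seed=1)
        b = build_training_set(frame, seed=1)
        c = build_training_set(frame, seed=2)
        np.testing.assert_array_equal(a.X, b.X)
        assert not np.array_equal(a.X[~a.y], c.X[~c.y])  # interictal sample differs
        np.testing.assert_array_equal(a.X[a.y], c.X[c.y])  # ictal rows identical

    def test_scarce_interictal_takes_all_and_warns(self, rng):
        frame = synthetic_frame(rng, n_inter=40, n_ictal=30)
        with pytest.warns(UserWarning, match="interictal"):
            ts = build_training_set(frame, seed=0)
        assert ts.n_interictal == 3 * 40  # all interictal rows of 3 subjects

    def test_no_qualifying_ictal_rejected(self, rng):
        frame = synthetic_frame(rng)
        frame.loc[frame.taxonomy > 0, "gamma"] = 0.0  # below any threshold
        with pytest.raises(ValueError, match="ictal"):
            build_training_set(frame, seed=0)


class TestKnn:
    def _training(self, rng, sep=10.0, n=200):
        X = np.vstack(
            [
                rng.normal([0.0, 0.0], 1.0, size=(n, 2)),
                rng.normal([sep, sep], 1.0, size=(n, 2)),
            ]
        )
        y = np.concatenate([np.zeros(n, bool), np.ones(n, bool)])
        mean, scale = X.mean(0), X.std(0)
        return TrainingSet(X, y, np.array(["s"] * 2 * n), mean, scale, threshold=0.0)

    def test_query_inside_pure_ictal_cluster(self, rng):
        ts = self._training(rng)
        model = fit(ts)
        assert model.predict([[10.0, 10.0]])[0]

    def test_separated_clusters_self_prediction_perfect(self, rng):
        ts = self._training(rng)
        model = fit(ts)
        pred = model.predict(ts.X)
        np.testing.assert_array_equal(pred, ts.y)

    def test_matches_brute_force_distance_oracle(self, rng):
        ts = self._training(rng, sep=1.5)  # overlapping clusters: hard queries
        model = fit(ts, k=10)
        queries = rng.normal(0.75, 2.0, size=(50, 2))
        pred = model.predict(queries)
        Xs = (ts.X - ts.mean) / ts.scale
        Qs = (queries - ts.mean) / ts.scale
        for q, p in zip(Qs, pred):
            d = np.linalg.norm(Xs - q, axis=1)
            votes = ts.y[np.argsort(d, kind="stable")[:10]].sum()
            assert p == (votes > 5)

    def test_tie_resolves_to_interictal(self):
        # k=2, one training point per class, query equidistant
        X = np.array([[0.0, -1.0], [0.0, 1.0]])
        y = np.array([False, True])
        ts = TrainingSet(X, y, np.array(["s", "s"]), np.zeros(2), np.ones(2), 0.0)
        model = fit(ts, k=2)
        assert not model.predict([[5.0, 0.0]])[0]

    def test_k_exceeding_rows_rejected(self, rng):
        ts = self._training(rng, n=4)
        with pytest.raises(ValueError, match="exceeds"):
            fit(ts, k=10)

    def test_archive_round_trip(self, rng, tmp_path):
        ts = self._training(rng, sep=2.0)
        model = fit(ts)
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        queries = rng.normal(1.0, 2.0, size=(40, 2))
        np.testing.assert_array_equal(model.predict(queries), back.predict(queries))

    def test_bad_archive_rejected(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="archive"):
            load_model(p)


class TestLoocv:
    def test_one_fold_per_subject(self, rng):
        frame = synthetic_frame(rng, subjects=("A", "B", "C", "D", "E"))
        decisions = loocv(frame, RunConfig(seed=0))
        assert sorted(decisions) == ["A", "B", "C", "D", "E"]
        for sid, d in decisions.items():
            assert d.size == (frame.subject_id == sid).sum()

    def test_fold_training_sets_differ(self, rng):
        frame = synthetic_frame(rng)
        ts_a = build_training_set(frame, held_out="A", seed=0)
        ts_b = build_training_set(frame, held_out="B", seed=0)
        assert set(ts_a.subjects) != set(ts_b.subjects)

    def test_seeded_end_to_end_determinism(self, rng):
        frame = synthetic_frame(rng)
        d1 = loocv(frame, RunConfig(seed=5))
        d2 = loocv(frame, RunConfig(seed=5))
        for sid in d1:
            np.testing.assert_array_equal(d1[sid], d2[sid])

    def test_single_subject_rejected(self, rng):
        frame = synthetic_frame(rng, subjects=("A",))
        with pytest.raises(ValueError, match="two subjects"):
            loocv(frame)


def oracle_postprocess(seq):
    """Run-length oracle: drop ictal runs of length exactly 1."""
    seq = list(seq)
    out = list(seq)
    i = 0
    while i < len(seq):
        if seq[i]:
            j = i
            while j < len(seq) and seq[j]:
                j += 1
            if j - i == 1:
                out[i] = False
            i = j
        else:
            i += 1
    return out


class TestPostprocess:
    def test_isolated_window_removed(self):
        np.testing.assert_array_equal(
            postprocess([False, True, False]), [False, False, False]
        )

    def test_adjacent_pair_survives(self):
        d = [False, True, True, False]
        np.testing.assert_array_equal(postprocess(d), d)

    def test_all_negative_unchanged(self):
        d = np.zeros(10, bool)
        np.testing.assert_array_equal(postprocess(d), d)

    def test_exhaustive_against_run_length_oracle(self):
        for n in range(0, 13):
            for bits in itertools.product([False, True], repeat=n):
                got = postprocess(np.array(bits, dtype=bool))
                np.testing.assert_array_equal(got, oracle_postprocess(bits))

    def test_idempotent_and_non_increasing(self, rng):
        for _ in range(500):
            d = rng.random(rng.integers(1, 40)) < 0.4
            once = postprocess(d)
            twice = postprocess(once)
            np.testing.assert_array_equal(once, twice)
            assert once.sum() <= d.sum()

    @settings(derandomize=True, max_examples=300)
    @given(st.lists(st.booleans(), max_size=60))
    def test_oracle_agreement_property(self, bits):
        d = np.array(bits, dtype=bool)
        np.testing.assert_array_equal(postprocess(d), oracle_postprocess(bits))
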