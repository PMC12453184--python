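"""Sliding windows, electrode screening, pairwise spectral similarity, and
the Same/Different contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from navrsa.rsa import (ContrastSeries, SimilarityTensor, WindowScheme,
                        build_vectors, contrast, pairwise_similarity, rsm4,
                        select_task_electrodes, window_matrix)


class TestWindowScheme:
    def test_default_bookkeeping(self):
        s = WindowScheme()
        assert s.n_windows == 31
        assert s.win_samples == 250
        assert s.step_samples == 25
        assert s.centers_s[0] == pytest.approx(0.25)
        assert s.centers_s[-1] == pytest.approx(1.75)

    @pytest.mark.parametrize("width, step, n_expected, samp_expected", [
        (200.0, 20.0, 91, 100),
        (100.0, 10.0, 191, 50),
    ])
    def test_alternative_schemes(self, width, step, n_expected, samp_expected):
        s = WindowScheme(width_ms=width, step_ms=step)
        assert s.n_windows == n_expected
        assert s.win_samples == samp_expected

    def test_window_interval(self):
        s = WindowScheme()
        idx = s.window_interval(0.65, 0.80)
        assert np.allclose(s.centers_s[idx], [0.65, 0.70, 0.75, 0.80])


class TestVectors:
    def test_vector_length(self):
        z = np.random.default_rng(0).normal(size=(3, 2, 50, 1000)).astype(np.float32)
        s = WindowScheme()
        assert window_matrix(z, s, 0).shape == (3, 50 * 250 * 2)
        v = build_vectors(z, s)
        assert v.shape == (3, 31, 50 * 250 * 2)

    def test_single_channel_single_window_length(self):
        z = np.zeros((2, 1, 50, 1000), dtype=np.float32)
        assert window_matrix(z, WindowScheme(), 5).shape[1] == 12500

    def test_empty_channels_rejected(self):
        with pytest.raises(ValueError):
            build_vectors(np.zeros((2, 0, 50, 1000)), WindowScheme())


class TestScreening:
    def _epochs(self, n_ep=12, n_ch=3, n_samp=200, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(n_ep, n_ch, n_samp))
        ctx = np.array(["a", "b"] * (n_ep // 2))
        obj = np.array(["x"] * (n_ep // 2) + ["y"] * (n_ep // 2))
        return data, ctx, obj

    def test_offset_channel_selected(self):
        data, ctx, obj = self._epochs()
        data[ctx == "a", 0, :] += 10.0
        data[obj == "x", 0, :] += 10.0
        flags = select_task_electrodes(data, ctx, obj)
        assert flags[0]
        assert not flags[1:].any()

    def test_alpha_one_selects_everything(self):
        data, ctx, obj = self._epochs()
        assert select_task_electrodes(data, ctx, obj, alpha=1.0).all()

    def test_null_selection_rate_near_alpha_squared(self):
        rng = np.random.default_rng(1)
        n_ch = 300
        data = rng.normal(size=(12, n_ch, 100))
        ctx = np.array(["a", "b"] * 6)
        obj = np.array(["x"] * 6 + ["y"] * 6)
        rate = select_task_electrodes(data, ctx, obj, alpha=0.5).mean()
        # two independent tests at alpha=0.5 -> ~25% conjunction rate
        assert 0.15 < rate < 0.35

    def test_single_label_level_rejected(self):
        data, ctx, obj = self._epochs()
        with pytest.raises(ValueError):
            select_task_electrodes(data, np.array(["a"] * 12), obj)


def _toy_sim(z_pairs, labels, sessions=None):
    """SimilarityTensor from an explicit pair->z mapping on one session."""
    n = len(labels)
    pi, pj = np.triu_indices(n, k=1)
    z = np.array([[z_pairs.get((i, j), np.nan)] for i, j in zip(pi, pj)],
                 dtype=float)
    epochs = pd.DataFrame({
        "session": sessions if sessions is not None else [1] * n,
        "environment": labels, "object": labels,
        "trial_id": np.arange(n), "is_good": [True] * n,
    })
    sess = epochs["session"].to_numpy()
    keep = sess[pi] == sess[pj]
    return SimilarityTensor(z=z[keep], pair_i=pi[keep], pair_j=pj[keep],
                            session=sess[pi][keep], epochs=epochs,
                            scheme=WindowScheme())


class TestPairwiseSimilarity:
    def test_known_spearman_value(self):
        # vectors [1,2,3,4] vs [1,3,2,4]: rho = 1 - 6*2/60 = 0.8
        z_power = np.zeros((2, 1, 1, 8), dtype=np.float32)
        z_power[0, 0, 0] = [1, 2, 3, 4, 1, 2, 3, 4]
        z_power[1, 0, 0] = [1, 3, 2, 4, 1, 3, 2, 4]
        scheme = WindowScheme(width_ms=1000, step_ms=1000, epoch_s=2.0, rate=4.0)
        epochs = pd.DataFrame({"session": [1, 1], "environment": ["a", "b"],
                               "object": ["x", "y"]})
        sim = pairwise_similarity(z_power, epochs, scheme)
        assert sim.z.shape == (1, 2)
        assert sim.z[0, 0] == pytest.approx(np.arctanh(0.8), abs=1e-6)
        assert sim.z[0, 0] == pytest.approx(1.0986, abs=1e-4)

    def test_identical_vectors_clipped(self):
        z_power = np.tile(np.arange(8, dtype=np.float32), (2, 1, 1, 1))
        scheme = WindowScheme(width_ms=2000, step_ms=2000, epoch_s=2.0, rate=4.0)
        epochs = pd.DataFrame({"session": [1, 1], "environment": ["a", "b"],
                               "object": ["x", "y"]})
        sim = pairwise_similarity(z_power, epochs, scheme)
        assert sim.z[0, 0] == pytest.approx(np.arctanh(1 - 1e-10), rel=1e-5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(2, 1, 4, 100)).astype(np.float64)
        warped = base.copy()
        warped[1] = np.exp(0.5 * warped[1]) + 3.0  # strictly increasing map
        scheme = WindowScheme(width_ms=200, step_ms=200, epoch_s=0.2, rate=500.0)
        epochs = pd.DataFrame({"session": [1, 1], "environment": ["a", "b"],
                               "object": ["x", "y"]})
        s1 = pairwise_similarity(base, epochs, scheme)
        s2 = pairwise_similarity(warped, epochs, scheme)
        assert np.allclose(s1.z, s2.z, atol=1e-6)

    def test_matches_scipy_spearman(self):
        rng = np.random.default_rng(1)
        z_power = rng.normal(size=(4, 2, 3, 40))
        scheme = WindowScheme(width_ms=40, step_ms=20, epoch_s=0.08, rate=500.0)
        epochs = pd.DataFrame({"session": [1, 1, 1, 1],
                               "environment": list("abab"),
                               "object": list("xxyy")})
        sim = pairwise_similarity(z_power, epochs, scheme)
        for p, (i, j) in enumerate(zip(sim.pair_i, sim.pair_j)):
            for w in range(scheme.n_windows):
                vi = window_matrix(z_power, scheme, w)[i]
                vj = window_matrix(z_power, scheme, w)[j]
                rho = sstats.spearmanr(vi, vj).statistic
                assert sim.z[p, w] == pytest.approx(np.arctanh(rho), abs=1e-6)

    def test_constant_vector_flagged_nan(self):
        z_power = np.zeros((3, 1, 2, 20))
        z_power[0] = np.random.default_rng(2).normal(size=(1, 2, 20))
        z_power[2] = np.random.default_rng(3).normal(size=(1, 2, 20))
        scheme = WindowScheme(width_ms=40, step_ms=40, epoch_s=0.04, rate=500.0)
        epochs = pd.DataFrame({"session": [1] * 3, "environment": list("aba"),
                               "object": list("xyx")})
        sim = pairwise_similarity(z_power, epochs, scheme)
        flat = {(i, j): k for k, (i, j) in enumerate(zip(sim.pair_i, sim.pair_j))}
        assert np.isnan(sim.z[flat[(0, 1)]]).all()
        assert np.isfinite(sim.z[flat[(0, 2)]]).all()

    def test_no_cross_session_pairs(self):
        rng = np.random.default_rng(4)
        z_power = rng.normal(size=(4, 1, 2, 20))
        scheme = WindowScheme(width_ms=40, step_ms=40, epoch_s=0.04, rate=500.0)
        epochs = pd.DataFrame({"session": [1, 1, 2, 2],
                               "environment": list("abab"),
                               "object": list("xyxy")})
        sim = pairwise_similarity(z_power, epochs, scheme)
        assert sim.n_pairs == 2
        assert all(epochs["session"][i] == epochs["session"][j]
                   for i, j in zip(sim.pair_i, sim.pair_j))


class TestContrast:
    def test_toy_example(self):
        z_pairs = {(0, 1): 0.6, (2, 3): 0.5, (0, 2): 0.1, (0, 3): 0.2,
                   (1, 2): 0.3, (1, 3): 0.1}
        sim = _toy_sim(z_pairs, ["A", "A", "B", "B"])
        c = contrast(sim, "context")
        assert c.mean_same[0] == pytest.approx(0.55)
        assert c.mean_diff[0] == pytest.approx(0.175)
        assert c.difference[0] == pytest.approx(0.375)

    def test_constant_z_gives_expected_difference(self):
        z_pairs = {(0, 1): 1.0, (2, 3): 1.0, (0, 2): 0.0, (0, 3): 0.0,
                   (1, 2): 0.0, (1, 3): 0.0}
        sim = _toy_sim(z_pairs, ["A", "A", "B", "B"])
        assert contrast(sim, "context").difference[0] == pytest.approx(1.0)

    def test_shuffled_labels_centered_on_zero(self):
        rng = np.random.default_rng(5)
        diffs = []
        for _ in range(200):
            labels = rng.permutation(["A", "A", "B", "B"])
            z_pairs = {(i, j): rng.normal() for i in range(4)
                       for j in range(i + 1, 4)}
            sim = _toy_sim(z_pairs, list(labels))
            diffs.append(contrast(sim, "context").difference[0])
        assert abs(np.mean(diffs)) < 0.1

    def test_sessionwise_averaging(self):
        # session 1 difference 1.0, session 2 difference 0.0 -> average 0.5
        labels = ["A", "A", "B", "B"] * 2
        sessions = [1] * 4 + [2] * 4
        z_pairs = {}
        for i in range(8):
            for j in range(i + 1, 8):
                if sessions[i] != sessions[j]:
                    continue
                same = labels[i] == labels[j]
                z_pairs[(i, j)] = (1.0 if same else 0.0) if sessions[i] == 1 else 0.3
        sim = _toy_sim(z_pairs, labels, sessions)
        assert contrast(sim, "context").difference[0] == pytest.approx(0.5)


class TestRsm:
    def _block_sim(self):
        labels_env = ["sq", "sq", "ci", "ci"]
        labels_obj = ["o1", "o2", "o1", "o2"]
        n = 4
        pi, pj = np.triu_indices(n, k=1)
        z = np.array([[0.5 if labels_env[i] == labels_env[j] else 0.1]
                      for i, j in zip(pi, pj)])
        epochs = pd.DataFrame({"session": [1] * n, "environment": labels_env,
                               "object": labels_obj, "trial_id": range(n),
                               "is_good": [True] * n})
        return SimilarityTensor(z=z, pair_i=pi, pair_j=pj,
                                session=np.ones(len(pi), dtype=int),
                                epochs=epochs, scheme=WindowScheme())

    def test_block_structure_and_symmetry(self):
        m = rsm4(self._block_sim(), np.array([0]))
        arr = m.to_numpy(dtype=float)
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert m.loc[("ci", "o1"), ("ci", "o2")] == pytest.approx(0.5)
        assert m.loc[("ci", "o1"), ("sq", "o1")] == pytest.approx(0.1)

    def test_constant_z(self):
        sim = self._block_sim()
        sim.z[:] = 0.3
        m = rsm4(sim, np.array([0]))
        vals = m.to_numpy(dtype=float)
        assert np.allclose(vals[np.isfinite(vals)], 0.3)
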