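"""Task schedule, trajectories/movement states, behavior link, and the
synthetic LFP."""

import numpy as np
import pytest
from scipy import signal as sps

from navrsa.synth import (ArenaGeometry, BehaviorLink, NeuralSimConfig,
                          TaskConfig, draw_trial_latents, generate_schedule,
                          simulate_ieeg, simulate_subject,
                          simulate_trajectories)


def _run_lengths(envs):
    """Lengths of maximal constant-environment runs."""
    runs, cur = [], 1
    for a, b in zip(envs[:-1], envs[1:]):
        if a == b:
            cur += 1
        else:
            runs.append(cur)
            cur = 1
    runs.append(cur)
    return runs


class TestSchedule:
    def test_default_counts(self):
        s = generate_schedule(TaskConfig())
        assert len(s) == 140
        assert (s["block"] == "test").sum() == 100
        counts = s.groupby(["session", "block", "environment"]).size()
        assert (counts.loc[(slice(None), "test")] == 25).all()
        assert (counts.loc[(slice(None), "learning")] == 10).all()

    def test_runs_alternate_within_range(self):
        s = generate_schedule(TaskConfig(seed=11))
        for (_, _), block in s.groupby(["session", "block"]):
            runs = _run_lengths(block["environment"].tolist())
            assert all(3 <= r <= 5 for r in runs)

    def test_fixed_run_length_five_accepted(self):
        s = generate_schedule(TaskConfig(run_length_range=(5, 5)))
        test = s[s["block"] == "test"]
        for _, block in test.groupby("session"):
            assert set(_run_lengths(block["environment"].tolist())) == {5}

    def test_untileable_run_length_rejected(self):
        with pytest.raises(ValueError):
            generate_schedule(TaskConfig(run_length_range=(4, 4)))

    def test_deterministic_under_seed(self):
        a = generate_schedule(TaskConfig(seed=3))
        b = generate_schedule(TaskConfig(seed=3))
        assert a.equals(b)

    def test_objects_inside_arena_validated(self):
        bad = dict(TaskConfig().object_positions)
        bad[(1, "circle", "cone")] = (20.0, 0.0)
        with pytest.raises(ValueError):
            TaskConfig(object_positions=bad)


class TestArena:
    def test_contains(self):
        sq = ArenaGeometry("square")
        ci = ArenaGeometry("circle")
        assert sq.contains((14.0, 14.0))[0]
        assert not ci.contains((14.0, 14.0))[0]
        assert ci.contains((10.0, 0.0))[0]

    def test_interior_sampling_respects_wall(self):
        ci = ArenaGeometry("circle")
        pts = ci.sample_uniform(np.random.default_rng(0), 5000, mode="interior")
        assert ci.contains(pts).all()

    def test_square_extent_sampling_covers_corners(self):
        ci = ArenaGeometry("circle")
        pts = ci.sample_uniform(np.random.default_rng(1), 5000,
                                mode="square_extent")
        assert (~ci.contains(pts)).mean() > 0.1  # corners outside the wall


class TestTrajectories:
    def setup_method(self):
        self.task = TaskConfig(seed=5)
        self.schedule = generate_schedule(self.task)

    def test_zero_behavior_link_gives_zero_errors(self):
        cfg = NeuralSimConfig(behavior_link=BehaviorLink.zero())
        _, trials = simulate_trajectories(self.schedule, self.task, cfg, seed=1)
        test = trials[trials["block"] == "test"]
        assert np.allclose(test["drop_error"], 0.0)

    def test_segments_partition_each_trial(self):
        cfg = NeuralSimConfig()
        segments, trials = simulate_trajectories(self.schedule, self.task,
                                                 cfg, seed=2)
        for tid, seg in segments.groupby("trial_id"):
            onsets = seg["onset"].to_numpy()
            durs = seg["duration"].to_numpy()
            assert np.allclose(onsets[1:], onsets[:-1] + durs[:-1])
            row = trials.set_index("trial_id").loc[tid]
            assert onsets[0] == pytest.approx(row["trial_onset_s"])
            assert onsets[-1] + durs[-1] == pytest.approx(row["trial_end_s"])

    def test_every_test_trial_has_long_translation(self):
        cfg = NeuralSimConfig()
        segments, trials = simulate_trajectories(self.schedule, self.task,
                                                 cfg, seed=3)
        trans = segments[segments["state"] == "translation"]
        per_trial_max = trans.groupby("trial_id")["duration"].max()
        n_test = (trials["block"] == "test").sum()
        assert len(per_trial_max) == n_test
        assert (per_trial_max >= 1.0).all()
        assert (per_trial_max >= 2.0).mean() >= 0.7

    def test_interaction_shows_up_in_cell_means(self):
        """With noise off, the high/high cell sits delta below the others."""
        delta = 3.0
        cfg = NeuralSimConfig(behavior_link=BehaviorLink(
            base_error=8.0, subject_sd=0.0, first_half_penalty=(0.0, 0.0),
            delta=delta, noise_sd=0.0))
        _, trials = simulate_trajectories(self.schedule, self.task, cfg, seed=4)
        t = trials[trials["block"] == "test"]
        hi_c = t["s_context"] > t["s_context"].median()
        hi_o = t["s_object"] > t["s_object"].median()
        cell_hh = t.loc[hi_c & hi_o, "drop_error"].mean()
        cell_ll = t.loc[~hi_c & ~hi_o, "drop_error"].mean()
        assert cell_ll - cell_hh == pytest.approx(delta, abs=1e-9)

    def test_latents_centered(self):
        lat = draw_trial_latents(5000, NeuralSimConfig(), np.random.default_rng(0))
        assert abs(lat["g"].mean()) < 0.05
        assert abs(lat["c"].mean()) < 0.05
        assert (lat["s_context"] > 0).all()


class TestIeeg:
    def setup_method(self):
        self.task = TaskConfig(test_trials_per_session=10,
                               learning_trials_per_session=6, seed=9)
        self.schedule = generate_schedule(self.task)
        self.cfg = NeuralSimConfig()
        self.segments, self.trials = simulate_trajectories(
            self.schedule, self.task, self.cfg, seed=10)

    def test_bit_identical_under_seed(self):
        a = simulate_ieeg(self.trials, self.segments, self.cfg, seed=5)
        b = simulate_ieeg(self.trials, self.segments, self.cfg, seed=5)
        assert np.array_equal(a.voltage, b.voltage)
        c = simulate_ieeg(self.trials, self.segments, self.cfg, seed=6)
        assert not np.array_equal(a.voltage, c.voltage)

    def test_channel_metadata(self):
        rec = simulate_ieeg(self.trials, self.segments, self.cfg, seed=5)
        regions = rec.channels["region"].value_counts()
        assert regions["HC"] == 4 and regions["EC"] == 4
        assert set(rec.channels["hemisphere"]) <= {"L", "R"}
        assert rec.rate == 500.0

    def test_zero_roi_channels_rejected(self):
        with pytest.raises(ValueError, match="EC"):
            NeuralSimConfig(channels_per_region={"HC": 4, "EC": 0})

    def test_translation_band_power_exceeds_stationary(self):
        """Injected 2-8 Hz codes raise band power during translation."""
        rec = simulate_ieeg(self.trials, self.segments, self.cfg, seed=7)
        sos = sps.butter(4, (2, 8), btype="bandpass", fs=rec.rate, output="sos")
        ch = rec.channel_indices("HC")[0]
        bp = sps.sosfiltfilt(sos, rec.voltage[ch])
        pad = rec.meta["head_pad_s"]
        var = {"translation": [], "stationary": []}
        for _, seg in self.segments.iterrows():
            if seg["state"] not in var:
                continue
            i0 = int((seg["onset"] + pad) * rec.rate)
            i1 = i0 + int(seg["duration"] * rec.rate)
            var[seg["state"]].append(bp[i0:i1].var())
        assert np.mean(var["translation"]) > 1.5 * np.mean(var["stationary"])

    def test_invariants_of_config(self):
        with pytest.raises(ValueError):
            NeuralSimConfig(coupling_strength=1.5)
        with pytest.raises(ValueError):
            NeuralSimConfig(context_code_snr=-0.1)

    def test_simulate_subject_bundle(self):
        sub = simulate_subject(self.task, self.cfg, "s01", 77,
                               schedule=self.schedule)
        assert sub.recording.n_samples > 0
        assert "config_digest" in sub.recording.meta
        test = sub.trials[sub.trials["block"] == "test"]
        assert test["drop_error"].notna().all()
        assert (sub.trials["subject_id"] == "s01").all()
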