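import numpy as np
import pytest

import scenemeg as sm
from scenemeg.stats import rms_timecourse


class TestTopographies:
    def test_unit_norm_and_bipolar(self, sensors):
        for name, v in sensors.topographies.items():
            assert np.linalg.norm(v) == pytest.approx(1.0)
            assert (v > 0).any() and (v < 0).any(), name

    def test_m50_m100_opposite_polarity(self, sensors):
        proj = sensors.topographies["M50"] @ sensors.topographies["M100"]
        assert proj < -0.9

    def test_deterministic_given_seed(self):
        s1 = sm.make_sensor_topographies(32, np.random.default_rng(3))
        s2 = sm.make_sensor_topographies(32, np.random.default_rng(3))
        for k in s1.topographies:
            assert np.array_equal(s1.topographies[k], s2.topographies[k])
        assert np.array_equal(s1.noise_maps, s2.noise_maps)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            sm.make_sensor_topographies(4, np.random.default_rng(0))

    def test_noise_subspace_distinct_from_auditory_map(self, sensors):
        # background sources (beyond the shared effect-map source) are
        # orthogonal to the auditory evoked map
        leak = np.abs(sensors.noise_maps[1:] @ sensors.topographies["M50"]).max()
        assert leak < 1e-9


class TestSubjectEvoked:
    def test_zero_amplitudes_give_zero_evoked(self, sensors):
        fx = sm.EffectConfig(
            scene_components=tuple(
                sm.simulate.Component(c.latency_ms, 0.0, c.fwhm_ms)
                for c in sm.EffectConfig().scene_components
            ),
            sustained_level=0.0,
        )
        ev = sm.simulate_subject_evoked("scene", True, "Passive", fx, sensors)
        assert not ev.data.any()

    def test_epoch_sample_counts(self, fx, sensors):
        scene = sm.simulate_subject_evoked("scene", True, "Passive", fx, sensors)
        app = sm.simulate_subject_evoked("appearance", True, "Passive", fx, sensors)
        assert scene.data.shape[1] == 250  # (-200, 800) at 250 Hz, half-open
        assert app.data.shape[1] == 150    # (-200, 400)

    def test_m50_rms_ratio_is_planted_gain(self, fx, sensors):
        reg = sm.simulate_subject_evoked("appearance", True, "Passive", fx, sensors)
        rand = sm.simulate_subject_evoked("appearance", False, "Passive", fx, sensors)
        t = reg.times_ms
        i = int(np.argmin(np.abs(t - 90.0)))  # M50 peak
        ratio = rms_timecourse(reg).values[i] / rms_timecourse(rand).values[i]
        assert ratio == pytest.approx(1.22, abs=0.01)

    def test_scene_difference_zero_before_group_onset(self, fx, sensors):
        reg = sm.simulate_subject_evoked("scene", True, "Passive", fx, sensors)
        rand = sm.simulate_subject_evoked("scene", False, "Passive", fx, sensors)
        t = reg.times_ms
        pre = t < fx.scene_reg_onset_ms[0]
        assert np.abs(reg.data[:, pre] - rand.data[:, pre]).max() < 1e-12
        post = t > fx.scene_reg_onset_ms[0] + 50
        assert np.abs(reg.data[:, post] - rand.data[:, post]).max() > 0.1

    def test_active_appearance_effect_gated_later(self, fx, sensors):
        reg = sm.simulate_subject_evoked("appearance", True, "Active", fx, sensors)
        rand = sm.simulate_subject_evoked("appearance", False, "Active", fx, sensors)
        t = reg.times_ms
        pre = (t >= 0) & (t < fx.appearance_reg_onset_ms[1])
        assert np.abs(reg.data[:, pre] - rand.data[:, pre]).max() < 1e-12

    def test_passive_m100_absent(self, fx, sensors):
        ev = sm.simulate_subject_evoked("appearance", False, "Passive", fx, sensors)
        t = ev.times_ms
        rms = rms_timecourse(ev).values
        i100 = int(np.argmin(np.abs(t - 150.0)))
        i50 = int(np.argmin(np.abs(t - 90.0)))
        assert rms[i100] < 0.5 * rms[i50]

    def test_nochange_appearance_evoked_is_flat(self, fx, sensors):
        ev = sm.simulate_subject_evoked(
            "appearance", True, "Passive", fx, sensors, has_change=False
        )
        assert not ev.data.any()


class TestSimulateTrials:
    def test_zero_noise_reproduces_evoked(self, fx, sensors, rng):
        ev = sm.simulate_subject_evoked("scene", True, "Passive", fx, sensors)
        quiet = sm.NoiseConfig(spatial_sd=0.0, sensor_sd=0.0,
                               effect_dir_noise_sd=0.0, outlier_fraction=0.0)
        tt = sm.simulate_trials(ev, sensors, quiet, 4, rng)
        for k in range(4):
            assert np.allclose(tt.data[:, :, k], ev.data)

    def test_trial_mean_converges_to_evoked(self, fx, sensors):
        ev = sm.simulate_subject_evoked("scene", True, "Passive", fx, sensors)
        noise = sm.NoiseConfig(outlier_fraction=0.0)
        rng = np.random.default_rng(0)
        err = []
        for n in (25, 400):
            tt = sm.simulate_trials(ev, sensors, noise, n, rng)
            err.append(np.abs(tt.data.mean(axis=2) - ev.data).mean())
        # SE shrinks ~ 1/sqrt(n): x16 trials -> ~x4 error reduction
        assert err[1] < err[0] / 2.5

    def test_outlier_count_matches_fraction(self, fx, sensors):
        ev = sm.simulate_subject_evoked("scene", True, "Passive", fx, sensors)
        noise = sm.NoiseConfig(outlier_fraction=0.02)
        rng = np.random.default_rng(123)
        counts = [
            len(sm.simulate_trials(ev, sensors, noise, 100, rng).labels["outlier_true"])
            for _ in range(30)
        ]
        assert np.mean(counts) == pytest.approx(2.0, abs=1.0)

    def test_determinism(self, fx, sensors):
        ev = sm.simulate_subject_evoked("scene", True, "Passive", fx, sensors)
        t1 = sm.simulate_trials(ev, sensors, sm.NoiseConfig(), 8, np.random.default_rng(5))
        t2 = sm.simulate_trials(ev, sensors, sm.NoiseConfig(), 8, np.random.default_rng(5))
        assert np.array_equal(t1.data, t2.data)


class TestSimulateDataset:
    def test_default_group_sizes(self, fx):
        ds = sm.simulate_dataset(
            fx, np.random.default_rng(1), n_channels=32, trials_per_cond=4,
            noise=sm.NoiseConfig(outlier_fraction=0.0),
        )
        groups = [s["group"] for s in ds["subjects"]]
        assert groups.count("Passive") == 14
        assert groups.count("Active") == 13

    def test_conditions_present(self, small_dataset):
        subj = small_dataset["subjects"][0]
        assert set(subj["scene"]) == {"REG", "RAND"}
        assert set(subj["appearance"]) == {
            "REG", "RAND", "REG_nochange", "RAND_nochange"
        }

    def test_zero_jitter_gives_identical_subjects(self, fx):
        noise = sm.NoiseConfig(subject_gain_sd=0.0, subject_latency_sd_ms=0.0,
                               spatial_sd=0.0, sensor_sd=0.0,
                               effect_dir_noise_sd=0.0, outlier_fraction=0.0)
        ds = sm.simulate_dataset(fx, np.random.default_rng(2), n_passive=2,
                                 n_active=2, n_channels=32, trials_per_cond=2,
                                 noise=noise)
        a, b = ds["subjects"][0], ds["subjects"][1]
        assert np.array_equal(a["scene"]["REG"].data, b["scene"]["REG"].data)

    def test_nochange_tensors_lack_appearance_components(self, small_dataset):
        subj = small_dataset["subjects"][0]
        nochange = subj["appearance"]["REG_nochange"].data.mean(axis=2)
        change = subj["appearance"]["REG"].data.mean(axis=2)
        t = subj["appearance"]["REG"].times_ms
        win = (t >= 60) & (t <= 120)
        rms_nc = np.sqrt((nochange[:, win] ** 2).mean())
        rms_ch = np.sqrt((change[:, win] ** 2).mean())
        assert rms_ch > 2.5 * rms_nc


class TestSimulateBehavior:
    def test_group_mean_hit_rate(self, fx):
        table = sm.simulate_behavior(fx, np.random.default_rng(0),
                                     n_subjects=200, trials_per_cond=96)
        hit_rate = table.hits.sum() / table.n_change.sum()
        assert hit_rate == pytest.approx(0.761, abs=0.02)

    def test_false_alarm_rate(self, fx):
        table = sm.simulate_behavior(fx, np.random.default_rng(1),
                                     n_subjects=200, trials_per_cond=96)
        per = table.drop_duplicates(["subject", "scene_regularity"])
        fa = per.false_alarms.sum() / per.n_nochange.sum()
        assert fa == pytest.approx(0.0625, abs=0.01)

    def test_regular_appearing_rt_advantage(self, fx):
        table = sm.simulate_behavior(fx, np.random.default_rng(2),
                                     n_subjects=300, trials_per_cond=96)
        mean_rt = table.groupby("appearing_regular").detection_times_ms.apply(
            lambda col: np.concatenate(col.values).mean()
        )
        assert mean_rt[True] - mean_rt[False] == pytest.approx(-27.0, abs=5.0)

    def test_counts_within_bounds(self, fx):
        table = sm.simulate_behavior(fx, np.random.default_rng(3), n_subjects=10)
        assert (table.hits <= table.n_change).all()
        assert (table.false_alarms <= table.n_nochange).all()
        assert all(all(t > 0 for t in row) for row in table.detection_times_ms)

    def test_determinism(self, fx):
        t1 = sm.simulate_behavior(fx, np.random.default_rng(7), n_subjects=5)
        t2 = sm.simulate_behavior(fx, np.random.default_rng(7), n_subjects=5)
        assert t1.drop(columns="detection_times_ms").equals(
            t2.drop(columns="detection_times_ms")
        )
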