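import numpy as np
import pytest
from scipy import optimize, special
from scipy import stats as sps

import scenemeg as sm
from scenemeg.stats import (
    OnsetNotCrossedError,
    cluster_permutation_test,
    channel_subset_means,
    dprime,
    jackknife_onset,
    jackknife_two_sample_test,
    rm_anova_2x2,
    rms_timecourse,
)


class TestRms:
    def test_zero_input(self):
        out = rms_timecourse(np.zeros((4, 10)))
        assert not out.values.any()

    def test_single_channel_is_absolute_value(self):
        out = rms_timecourse(np.array([[-3.0, 2.0]]))
        assert np.allclose(out.values, [3.0, 2.0])

    def test_hand_computed_value(self):
        out = rms_timecourse(np.array([[3.0], [4.0]]))
        assert out.values[0] == pytest.approx(np.sqrt(12.5))

    def test_nonnegative(self, rng):
        out = rms_timecourse(rng.normal(size=(6, 40)))
        assert (out.values >= 0).all()


def _null_series(rng, n_subj=8, n_t=60):
    return rng.normal(size=(n_subj, n_t)), rng.normal(size=(n_subj, n_t))


class TestClusterPermutation:
    def test_identical_conditions_no_clusters(self, rng):
        a = rng.normal(size=(6, 40))
        res = cluster_permutation_test(a, a.copy(), n_perm=200, rng=rng)
        assert res.clusters == []

    def test_planted_effect_detected_and_located(self, rng):
        n_subj, n_t = 10, 100
        b = rng.normal(size=(n_subj, n_t))
        a = b + rng.normal(size=(n_subj, n_t)) * 0.3
        a[:, 40:70] += 2.0
        res = cluster_permutation_test(a, b, n_perm=500, rng=rng,
                                       rate_hz=1000.0, t0_ms=0.0)
        sig = res.significant()
        assert sig
        best = max(sig, key=lambda c: c.stat)
        assert best.start_ms < 45 and best.end_ms > 60

    def test_permutation_count_invariance(self, rng):
        b = rng.normal(size=(8, 80))
        a = b + 0.8 + rng.normal(size=(8, 80)) * 0.5
        p1 = cluster_permutation_test(
            a, b, n_perm=1000, rng=np.random.default_rng(0)
        ).clusters[0].p_fwe
        p2 = cluster_permutation_test(
            a, b, n_perm=2000, rng=np.random.default_rng(1)
        ).clusters[0].p_fwe
        assert abs(p1 - p2) < 3 * np.sqrt(p1 * (1 - p1) / 1000) + 1e-3

    def test_monotone_in_effect_size(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(8, 80))
        noise = rng.normal(size=(8, 80))
        stats = []
        for gain in (0.0, 0.5, 1.0, 2.0):
            a = base + noise * 0.5
            a[:, 30:50] += gain
            res = cluster_permutation_test(
                a, base, n_perm=200, rng=np.random.default_rng(0)
            )
            stats.append(max((c.stat for c in res.clusters), default=0.0))
        assert all(s2 >= s1 - 1e-9 for s1, s2 in zip(stats, stats[1:]))

    def test_exhaustive_enumeration_matches_oracle(self):
        """For n=8 the Monte-Carlo null converges on the exact 2^8 sign-flip
        null, and full enumeration is deterministic."""
        rng = np.random.default_rng(42)
        a, b = _null_series(rng)
        a[:, 20:35] += 1.2
        exact1 = cluster_permutation_test(a, b, exhaustive=True, n_perm=0)
        exact2 = cluster_permutation_test(a, b, exhaustive=True, n_perm=0)
        assert [c.p_fwe for c in exact1.clusters] == [c.p_fwe for c in exact2.clusters]
        assert np.array_equal(np.sort(exact1.null_max), np.sort(exact2.null_max))
        mc = cluster_permutation_test(
            a, b, n_perm=4000, rng=np.random.default_rng(1)
        )
        for ce, cm in zip(exact1.clusters, mc.clusters):
            se = np.sqrt(ce.p_fwe * (1 - ce.p_fwe) / 4000)
            assert cm.p_fwe == pytest.approx(ce.p_fwe, abs=4 * se + 2e-3)

    def test_two_sample_design(self, rng):
        a = rng.normal(size=(9, 60)) + 1.5
        b = rng.normal(size=(8, 60))
        res = cluster_permutation_test(a, b, design="two_sample",
                                       n_perm=300, rng=rng)
        assert res.significant()

    def test_too_few_subjects_rejected(self, rng):
        a = rng.normal(size=(2, 30))
        with pytest.raises(ValueError):
            cluster_permutation_test(a, a + 1, n_perm=200, rng=rng)

    def test_fwe_calibration_fast(self):
        """Null rejection rate stays near the nominal level (coarse check;
        the full calibration lives in the acceptance suite)."""
        rej = 0
        n_rep = 60
        for i in range(n_rep):
            rng = np.random.default_rng(1000 + i)
            a, b = _null_series(rng, n_subj=8, n_t=50)
            res = cluster_permutation_test(a, b, n_perm=300, rng=rng)
            rej += bool(res.significant())
        assert rej / n_rep < 0.15


class TestJackknifeOnset:
    def test_noiseless_step_recovered_exactly(self):
        n_subj, n_t = 6, 100
        d = np.zeros((n_subj, n_t))
        d[:, 60:] = 5.0  # step at sample 60 -> 40 ms before... t0=-200: 4ms step
        est = jackknife_onset(d, rate_hz=250.0, t0_ms=-200.0)
        expected = -200.0 + 60 * 4.0
        assert est.mean_ms == pytest.approx(expected, abs=4.0)
        assert est.corrected_se_ms == pytest.approx(0.0, abs=1e-9)
        assert est.n == n_subj

    def test_all_zero_difference_flagged(self):
        d = np.zeros((5, 80))
        with pytest.raises(OnsetNotCrossedError):
            jackknife_onset(d, rate_hz=250.0, t0_ms=-200.0)
        est = jackknife_onset(d, rate_hz=250.0, t0_ms=-200.0, errors="flag")
        assert np.isnan(est.subsample_latencies_ms).all()

    def test_corrected_se_is_inflated_jackknife_se(self, rng):
        n = 9
        d = rng.normal(size=(n, 120)) * 0.1
        d[:, 80:] += 4.0 + rng.normal(size=(n, 1))
        est = jackknife_onset(d, rate_hz=250.0, t0_ms=-200.0)
        lats = est.subsample_latencies_ms
        expected = np.std(lats, ddof=1) * (n - 1) / np.sqrt(n)
        assert est.corrected_se_ms == pytest.approx(expected)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            jackknife_onset(np.zeros((2, 50)), rate_hz=250.0, t0_ms=-200.0)


class TestJackknifeTwoSample:
    def _est(self, lats):
        lats = np.asarray(lats, dtype=float)
        n = lats.size
        se = float(np.std(lats, ddof=1) * (n - 1) / np.sqrt(n))
        from scenemeg.stats import LatencyEstimate

        return LatencyEstimate(lats, float(lats.mean()), se, n, "test")

    def test_identical_groups_null(self):
        a = self._est([100, 104, 102, 98, 101])
        t, df, p, degen = jackknife_two_sample_test(a, a)
        assert t == 0.0 and p == pytest.approx(1.0) and not degen
        assert df == 8

    def test_zero_variance_unequal_means_flagged(self):
        a = self._est([100, 100, 100])
        b = self._est([150, 150, 150])
        t, df, p, degen = jackknife_two_sample_test(a, b)
        assert degen and np.isinf(t) and p == 0.0

    def test_known_difference_significant(self):
        a = self._est([100.0, 100.5, 99.5, 100.2, 99.8])
        b = self._est([155.0, 155.5, 154.5, 155.2, 154.8])
        t, df, p, _ = jackknife_two_sample_test(a, b)
        assert p < 0.01 and t < 0


class TestChannelSubsets:
    def test_dipolar_antisymmetry(self, rng):
        n_subj, n_ch, n_t = 5, 20, 40
        pattern = np.concatenate([np.ones(10), -np.ones(10)])
        sig = np.abs(rng.normal(size=(n_subj, 1, n_t)))
        data = pattern[None, :, None] * sig
        times = np.arange(n_t) * 4.0
        pos, neg, pidx, nidx = channel_subset_means(data, times, (0, 80), 10)
        assert np.allclose(pos, -neg)
        assert set(pidx) == set(range(10))

    def test_half_split_partitions_array(self, rng):
        data = rng.normal(size=(4, 12, 30))
        times = np.arange(30) * 4.0
        _, _, pidx, nidx = channel_subset_means(data, times, (20, 60), 6)
        assert len(set(pidx) | set(nidx)) == 12

    def test_planted_gain_preserved_with_sign(self, fx, sensors):
        reg = sm.simulate_subject_evoked("appearance", True, "Passive", fx, sensors)
        rand = sm.simulate_subject_evoked("appearance", False, "Passive", fx, sensors)
        data = np.stack([rand.data])  # rank channels on the RAND response
        t = rand.times_ms
        posR, negR, pidx, nidx = channel_subset_means(
            np.stack([reg.data]), t, (72, 112), 8
        )
        posN, negN, _, _ = channel_subset_means(
            np.stack([rand.data]), t, (72, 112), 8
        )
        w = (t >= 72) & (t <= 112)
        assert posR[0, w].mean() > posN[0, w].mean() > 0
        assert negR[0, w].mean() < negN[0, w].mean() < 0

    def test_window_outside_epoch_rejected(self, rng):
        data = rng.normal(size=(3, 10, 20))
        with pytest.raises(ValueError):
            channel_subset_means(data, np.arange(20) * 4.0, (500, 600), 5)

    def test_oversized_selection_rejected(self, rng):
        data = rng.normal(size=(3, 10, 20))
        with pytest.raises(ValueError):
            channel_subset_means(data, np.arange(20) * 4.0, (0, 40), 6)


def _ndtri_oracle(p):
    # independent inverse-normal: root-find on the CDF instead of using ndtri
    return optimize.brentq(lambda z: special.ndtr(z) - p, -10, 10, xtol=1e-12)


class TestDprime:
    def test_equal_rates_zero(self):
        assert dprime(50, 100, 25, 50) == pytest.approx(0.0)

    def test_printed_group_rates_match_oracle(self):
        d = dprime(761, 1000, 625, 10000)
        expected = _ndtri_oracle(0.761) - _ndtri_oracle(0.0625)
        assert d == pytest.approx(expected, abs=1e-6)
        assert d == pytest.approx(2.244, abs=0.005)

    def test_extreme_rates_clamped_finite(self):
        d = dprime(100, 100, 0, 100)
        assert np.isfinite(d)
        assert d == pytest.approx(2 * -_ndtri_oracle(1 / 200), abs=1e-9)

    def test_antisymmetry(self, rng):
        for _ in range(10):
            h = int(rng.integers(0, 51))
            f = int(rng.integers(0, 51))
            assert dprime(h, 50, f, 50) == pytest.approx(-dprime(f, 50, h, 50))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            dprime(5, 0, 1, 10)
        with pytest.raises(ValueError):
            dprime(11, 10, 1, 10)


class TestBehaviorSummary:
    def test_anova_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        n = 12
        y = rng.normal(size=(n, 2, 2))
        y[:, 0, :] += 0.8  # factor-A effect
        ours = rm_anova_2x2(y)
        long = pd.DataFrame(
            dict(
                subject=np.repeat(np.arange(n), 4),
                A=np.tile([0, 0, 1, 1], n),
                B=np.tile([0, 1, 0, 1], n),
                y=y.reshape(-1),
            )
        )
        ref = pg.rm_anova(data=long, dv="y", within=["A", "B"],
                          subject="subject", detailed=True)
        for name, key in (("A", "A"), ("B", "B"), ("A * B", "AxB")):
            row = ref[ref.Source == name].iloc[0]
            assert ours[key]["F"] == pytest.approx(row.F, rel=1e-6)
            assert ours[key]["p"] == pytest.approx(row["p_unc"], rel=1e-6)

    def test_identical_subjects_zero_within_se(self, fx):
        table = sm.simulate_behavior(
            fx, np.random.default_rng(0), n_subjects=1, trials_per_cond=96
        )
        table = (
            __import__("pandas").concat([table.assign(subject=i) for i in range(4)])
        )
        out = sm.behavior_summary(table)
        assert np.allclose(out["dprime_within_se"], 0.0)

    def test_planted_scene_effect_significant(self, fx):
        hits = 0
        for rep in range(8):
            table = sm.simulate_behavior(
                fx, np.random.default_rng(100 + rep), n_subjects=13,
                trials_per_cond=96,
            )
            out = sm.behavior_summary(table)
            hits += out["dprime_anova"]["A"]["p"] < 0.05
        assert hits >= 7

    def test_null_behavior_calibrated(self):
        fx0 = sm.EffectConfig(
            hit_rate_reg=0.75, hit_rate_rand=0.75,
            rt_scene_reg_shift_ms=0.0, rt_appearing_regular_shift_ms=0.0,
        )
        rej = 0
        n_rep = 60
        for rep in range(n_rep):
            table = sm.simulate_behavior(
                fx0, np.random.default_rng(rep), n_subjects=13,
                trials_per_cond=48,
            )
            out = sm.behavior_summary(table)
            rej += out["dprime_anova"]["A"]["p"] < 0.05
        assert rej / n_rep < 0.15

    def test_empty_rt_cell_excluded_with_warning(self, fx):
        table = sm.simulate_behavior(fx, np.random.default_rng(1), n_subjects=3)
        table.at[0, "hits"] = 0
        table.at[0, "detection_times_ms"] = []
        with pytest.warns(UserWarning):
            out = sm.behavior_summary(table)
        assert out["n_subjects_rt"] == 2
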