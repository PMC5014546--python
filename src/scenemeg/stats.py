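"""Statistical procedures for evoked time-series and behaviour.

* RMS-across-sensors time-courses (polarity-free response magnitude);
* cluster-based permutation tests on 1-D time-courses with family-wise
  error control via the max-cluster-statistic null (sign flips for paired
  designs, group-label shuffles for two-sample designs);
* jackknife (leave-one-participant-out) onset-latency estimation on the
  grand-average difference waveform, with the (n-1) standard-error
  correction, and the corresponding corrected two-sample latency test;
* polarity-preserving channel-subset averages around a chosen deflection;
* signal-detection d' and 2x2 repeated-measures behavioural summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

__all__ = [
    "RmsSeries",
    "rms_timecourse",
    "Cluster",
    "ClusterResult",
    "cluster_permutation_test",
    "LatencyEstimate",
    "OnsetNotCrossedError",
    "jackknife_onset",
    "jackknife_two_sample_test",
    "channel_subset_means",
    "dprime",
    "rm_anova_2x2",
    "behavior_summary",
]


@dataclass
class RmsSeries:
    """Per-time-sample RMS across sensors."""

    values: np.ndarray
    rate_hz: float
    t0_ms: float

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.values.size) * 1000.0 / self.rate_hz


def rms_timecourse(evoked) -> RmsSeries:
    """v(t) = sqrt(mean over channels of x(c, t)^2)."""
    x = evoked.data if hasattr(evoked, "rate_hz") else np.asarray(evoked, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("expected a channels x time array")
    v = np.sqrt((x**2).mean(axis=0))
    rate = getattr(evoked, "rate_hz", 1000.0)
    t0 = getattr(evoked, "t0_ms", 0.0)
    return RmsSeries(v, rate, t0)


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    stat: float
    p_fwe: float
    sign: int  # +1 / -1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    height_p: float
    n_perm: int
    design: str
    threshold_t: float
    t_obs: np.ndarray
    times_ms: np.ndarray
    null_max: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_fwe <= alpha]


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs; stop is exclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _max_cluster_stat(t: np.ndarray, tcrit: float) -> float:
    best = 0.0
    at = np.abs(t)
    for sgn in (1, -1):
        for a, b in _runs(sgn * t > tcrit):
            s = at[a:b].sum()
            if s > best:
                best = s
    return best


def _paired_t_perm(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t time-series for each sign-flip row. d: (n, T); signs: (P, n)."""
    n = d.shape[0]
    means = signs @ d / n
    ssq = (d**2).sum(axis=0)  # invariant under sign flips
    var = (ssq - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(0), b.mean(0)
    sp = ((a - ma) ** 2).sum(0) + ((b - mb) ** 2).sum(0)
    sp = sp / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp * (1 / na + 1 / nb))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def cluster_permutation_test(
    series_a,
    series_b,
    design: str = "paired",
    height_p: float = 0.05,
    n_perm: int = 5000,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
    rate_hz: float | None = None,
    t0_ms: float = 0.0,
) -> ClusterResult:
    """Cluster-based permutation test on per-subject 1-D time-courses.

    ``series_a``/``series_b`` are (subjects x time) arrays (or lists of
    :class:`RmsSeries`).  Per-sample t statistics above the two-tailed
    critical value at ``height_p`` form temporally contiguous clusters
    whose statistic is the sum of |t|; the null is the distribution of the
    maximum cluster statistic over permutations (per-subject sign flips of
    the paired difference, or group-label shuffles), pooling positive and
    negative clusters.  FWE p-values use the (1 + exceedances)/(1 + n_perm)
    convention so they are never zero; with ``exhaustive=True`` (paired
    design) all 2^n sign patterns are enumerated and the p-value is the
    exact proportion ``#(null >= observed) / 2^n``.
    """

    def _as_matrix(s):
        nonlocal rate_hz, t0_ms
        if isinstance(s, np.ndarray):
            return np.atleast_2d(np.asarray(s, dtype=float))
        rate_hz = s[0].rate_hz
        t0_ms = s[0].t0_ms
        return np.stack([x.values for x in s])

    a = _as_matrix(series_a)
    b = _as_matrix(series_b)
    if rate_hz is None:
        rate_hz = 1000.0
    if a.shape[1] != b.shape[1]:
        raise ValueError("time axes differ between conditions")
    if n_perm < 100 and not exhaustive:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng() if rng is None else rng

    if design == "paired":
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired design needs equal, matched subject sets")
        n = a.shape[0]
        if n < 3:
            raise ValueError("need at least 3 subjects")
        d = a - b
        tcrit = float(sps.t.ppf(1 - height_p / 2, n - 1))
        t_obs = _paired_t_perm(d, np.ones((1, n)))[0]
        if exhaustive:
            if n > 20:
                raise ValueError("exhaustive enumeration limited to n <= 20")
            bits = np.arange(2**n)
            signs = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)) & 1)
        else:
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        t_null = _paired_t_perm(d, signs)
    elif design == "two_sample":
        na, nb = a.shape[0], b.shape[0]
        if min(na, nb) < 3:
            raise ValueError("need at least 3 subjects per group")
        pooled = np.vstack([a, b])
        tcrit = float(sps.t.ppf(1 - height_p / 2, na + nb - 2))
        t_obs = _two_sample_t(a, b)
        if exhaustive:
            raise NotImplementedError("exhaustive null implemented for paired design only")
        t_null = np.empty((n_perm, a.shape[1]))
        for p in range(n_perm):
            idx = rng.permutation(na + nb)
            t_null[p] = _two_sample_t(pooled[idx[:na]], pooled[idx[na:]])
    else:
        raise ValueError("design must be 'paired' or 'two_sample'")

    null_max = np.array([_max_cluster_stat(t, tcrit) for t in t_null])
    n_eff = null_max.size
    step = 1000.0 / rate_hz
    clusters = []
    at = np.abs(t_obs)
    for sgn in (1, -1):
        for i0, i1 in _runs(sgn * t_obs > tcrit):
            stat = float(at[i0:i1].sum())
            if exhaustive:
                p = float((null_max >= stat - 1e-12).sum() / n_eff)
            else:
                p = float((1 + (null_max >= stat - 1e-12).sum()) / (1 + n_eff))
            clusters.append(
                Cluster(t0_ms + i0 * step, t0_ms + (i1 - 1) * step, stat, p, sgn)
            )
    clusters.sort(key=lambda c: c.start_ms)
    times = t0_ms + np.arange(a.shape[1]) * step
    return ClusterResult(clusters, height_p, n_eff, design, tcrit, t_obs, times, null_max)


class OnsetNotCrossedError(RuntimeError):
    """Raised when a jackknife subsample never crosses the onset criterion."""

    def __init__(self, latencies_ms):
        self.latencies_ms = latencies_ms
        n_missing = int(np.sum(np.isnan(latencies_ms)))
        super().__init__(
            f"onset criterion never crossed in {n_missing}/{len(latencies_ms)} "
            "jackknife subsamples"
        )


@dataclass
class LatencyEstimate:
    """Leave-one-out onset-latency estimate with corrected standard error."""

    subsample_latencies_ms: np.ndarray
    mean_ms: float
    corrected_se_ms: float
    n: int
    criterion: str


def _first_crossing(ga, times, centre, thr):
    """First post-zero time where |ga - centre| exceeds thr.

    The crossing is linearly interpolated between the last sub-threshold
    and the first supra-threshold sample, so latencies vary continuously
    rather than being quantised to the sampling grid.
    """
    dev = np.abs(ga - centre)
    post = times >= 0
    idx = np.flatnonzero(post & (dev > thr))
    if not idx.size:
        return np.nan
    i = idx[0]
    if i == 0 or not post[i - 1] or dev[i] == dev[i - 1]:
        return float(times[i])
    frac = (thr - dev[i - 1]) / (dev[i] - dev[i - 1])
    frac = min(max(frac, 0.0), 1.0)
    return float(times[i - 1] + frac * (times[i] - times[i - 1]))


def jackknife_onset(
    subject_diffs,
    rate_hz: float | None = None,
    t0_ms: float | None = None,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
    k_sd: float = 3.0,
    errors: str = "raise",
) -> LatencyEstimate:
    """Jackknife onset latency of a difference waveform.

    For each leave-one-participant-out subsample, the remaining subjects'
    difference series are grand-averaged; the onset is the first post-zero
    latency at which the average deviates from its baseline mean by more
    than ``k_sd`` x the SD of the baseline samples.  The corrected
    standard error is the jackknife SE inflated by (n - 1), i.e. SD of the
    subsample latencies x (n - 1) / sqrt(n).

    ``subject_diffs`` is a (subjects x time) array (with ``rate_hz`` and
    ``t0_ms``) or a list of :class:`RmsSeries`.  With ``errors="flag"``
    missing subsample latencies are returned as NaN instead of raising.
    """
    if not isinstance(subject_diffs, np.ndarray):
        rate_hz = subject_diffs[0].rate_hz
        t0_ms = subject_diffs[0].t0_ms
        subject_diffs = np.stack([s.values for s in subject_diffs])
    if rate_hz is None or t0_ms is None:
        raise ValueError("rate_hz and t0_ms required for array input")
    d = np.asarray(subject_diffs, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    times = t0_ms + np.arange(d.shape[1]) * 1000.0 / rate_hz
    b0, b1 = baseline_ms
    bmask = (times >= b0) & (times < b1)
    if not bmask.any() or b0 < times[0] - 1e-9:
        raise ValueError("baseline window outside the epoch")
    total = d.sum(axis=0)
    lat = np.empty(n)
    for i in range(n):
        ga = (total - d[i]) / (n - 1)
        base = ga[bmask]
        lat[i] = _first_crossing(ga, times, base.mean(), k_sd * base.std(ddof=1))
    criterion = (
        f"|grand-average - baseline mean| > {k_sd}*baseline SD, searched from t=0"
    )
    if np.isnan(lat).any():
        if errors == "flag":
            se = np.nan
            return LatencyEstimate(lat, float(np.nanmean(lat)), se, n, criterion)
        raise OnsetNotCrossedError(lat)
    se = float(np.std(lat, ddof=1) * (n - 1) / np.sqrt(n))
    return LatencyEstimate(lat, float(lat.mean()), se, n, criterion)


def jackknife_two_sample_test(
    est_a: LatencyEstimate, est_b: LatencyEstimate
) -> tuple[float, int, float, bool]:
    """Corrected two-sample t-test on jackknife latency estimates.

    Each group's jackknife variance is inflated by (n_g - 1)^2 (already
    folded into ``corrected_se_ms``); df = n_a + n_b - 2.  Returns
    ``(t, df, p, degenerate)`` where ``degenerate`` flags a zero-variance
    comparison with unequal means (t = +/-inf).
    """
    if np.isnan(est_a.mean_ms) or np.isnan(est_b.mean_ms):
        raise ValueError("incomplete latency estimate")
    df = est_a.n + est_b.n - 2
    delta = est_a.mean_ms - est_b.mean_ms
    denom = np.hypot(est_a.corrected_se_ms, est_b.corrected_se_ms)
    if denom == 0:
        if delta == 0:
            return 0.0, df, 1.0, False
        return float(np.sign(delta) * np.inf), df, 0.0, True
    t = float(delta / denom)
    p = float(2 * sps.t.sf(abs(t), df))
    return t, df, p, False


def channel_subset_means(
    subject_evokeds: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
    n_select: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Polarity-preserving means over the most positive/negative channels.

    Channels are ranked by their mean signal inside ``window_ms`` on the
    group average of ``subject_evokeds`` (subjects x channels x time; pool
    conditions before calling).  Returns ``(pos_mean, neg_mean, pos_idx,
    neg_idx)`` where the means are (subjects x time) averages over the
    ``n_select`` most positive and most negative channels.
    """
    x = np.asarray(subject_evokeds, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected subjects x channels x time")
    n_ch = x.shape[1]
    if n_select > n_ch // 2:
        raise ValueError("n_select exceeds half the channel count")
    w0, w1 = window_ms
    mask = (times_ms >= w0) & (times_ms <= w1)
    if not mask.any():
        raise ValueError("window outside the epoch")
    ranking = x.mean(axis=0)[:, mask].mean(axis=1)
    order = np.argsort(ranking)
    neg_idx = np.sort(order[:n_select])
    pos_idx = np.sort(order[-n_select:])
    pos_mean = x[:, pos_idx, :].mean(axis=1)
    neg_mean = x[:, neg_idx, :].mean(axis=1)
    return pos_mean, neg_mean, pos_idx, neg_idx


def dprime(hits: int, n_change: int, fas: int, n_nochange: int) -> float:
    """Signal-detection sensitivity d' = z(hit rate) - z(false-alarm rate).

    Rates are clamped to [1/(2N), 1 - 1/(2N)] of their respective trial
    counts so extreme counts stay finite.
    """
    if n_change <= 0 or n_nochange <= 0:
        raise ValueError("trial totals must be positive")
    if not 0 <= hits <= n_change or not 0 <= fas <= n_nochange:
        raise ValueError("counts outside their totals")
    h = np.clip(hits / n_change, 1 / (2 * n_change), 1 - 1 / (2 * n_change))
    f = np.clip(fas / n_nochange, 1 / (2 * n_nochange), 1 - 1 / (2 * n_nochange))
    return float(special.ndtri(h) - special.ndtri(f))


def rm_anova_2x2(y: np.ndarray) -> dict:
    """Classical 2x2 repeated-measures ANOVA.

    ``y`` is (subjects, 2, 2) with axis 1 = factor A and axis 2 = factor B.
    For two-level factors each F(1, n-1) is exactly the squared paired t of
    the corresponding within-subject contrast.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValueError("expected subjects x 2 x 2")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")

    def _contrast_F(c):
        t, p = sps.ttest_1samp(c, 0.0)
        return dict(F=float(t**2), df1=1, df2=n - 1, p=float(p))

    return {
        "A": _contrast_F(y[:, 0, :].mean(axis=1) - y[:, 1, :].mean(axis=1)),
        "B": _contrast_F(y[:, :, 0].mean(axis=1) - y[:, :, 1].mean(axis=1)),
        "AxB": _contrast_F(y[:, 0, 0] - y[:, 0, 1] - y[:, 1, 0] + y[:, 1, 1]),
    }


def _within_subject_se(cells: np.ndarray) -> np.ndarray:
    """Cousineau-Morey within-subject SEM per cell. cells: (subjects, k)."""
    n, k = cells.shape
    centred = cells - cells.mean(axis=1, keepdims=True) + cells.mean()
    return centred.std(axis=0, ddof=1) / np.sqrt(n) * np.sqrt(k / (k - 1))


def behavior_summary(table: pd.DataFrame) -> dict:
    """Condition-wise d' and detection-time summaries with 2x2 RM ANOVAs.

    Expects the long-format table produced by
    :func:`scenemeg.simulate.simulate_behavior` (one row per subject x
    scene regularity x appearing-source regularity).  Factor A is scene
    regularity (REG vs RAND), factor B the appearing source's regularity.
    Subjects with no hits in some cell are excluded from the detection-time
    ANOVA with a warning.
    """
    subjects = sorted(table["subject"].unique())
    scenes = ("REG", "RAND")
    apps = (True, False)
    n = len(subjects)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    dp = np.full((n, 2, 2), np.nan)
    rt = np.full((n, 2, 2), np.nan)
    for si, ai in product(range(2), range(2)):
        for k, subj in enumerate(subjects):
            row = table[
                (table.subject == subj)
                & (table.scene_regularity == scenes[si])
                & (table.appearing_regular == apps[ai])
            ].iloc[0]
            dp[k, si, ai] = dprime(
                row.hits, row.n_change, row.false_alarms, row.n_nochange
            )
            times = np.asarray(row.detection_times_ms, dtype=float)
            rt[k, si, ai] = times.mean() if times.size else np.nan
    rt_ok = ~np.isnan(rt).any(axis=(1, 2))
    if not rt_ok.all():
        warnings.warn(
            f"excluding {int((~rt_ok).sum())} subject(s) with empty detection-time "
            "cells from the RT ANOVA"
        )
    out = {
        "cells": {"scene": scenes, "appearing_regular": apps},
        "dprime_mean": dp.mean(axis=0),
        "dprime_within_se": _within_subject_se(dp.reshape(n, 4)).reshape(2, 2),
        "dprime_anova": rm_anova_2x2(dp),
        "rt_mean_ms": np.nanmean(rt, axis=0),
        "n_subjects": n,
        "n_subjects_rt": int(rt_ok.sum()),
    }
    if rt_ok.sum() >= 2:
        out["rt_within_se_ms"] = _within_subject_se(rt[rt_ok].reshape(-1, 4)).reshape(2, 2)
        out["rt_anova"] = rm_anova_2x2(rt[rt_ok])
    return out
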