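"""End-to-end orchestration: synthesize -> simulate -> preprocess -> analyze.

A single YAML-able configuration drives every stage.  One master seed
spawns independent per-stage child streams through
``numpy.random.SeedSequence(master).spawn()``, so the stimulus draw, the
MEG noise, the behavioural draw and the permutation stream are mutually
independent but individually reproducible; every artifact is stamped with
the seed and a hash of the resolved configuration.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np

from . import simulate as sim
from .preprocessing import dss_apply, dss_fit, reject_outlier_trials
from .scenes import StimulusParams, make_trial_sequence
from .simulate import EffectConfig, NoiseConfig, TrialTensor
from .stats import (
    LatencyEstimate,
    OnsetNotCrossedError,
    behavior_summary,
    channel_subset_means,
    cluster_permutation_test,
    jackknife_onset,
    jackknife_two_sample_test,
    rms_timecourse,
)

__all__ = [
    "DEFAULT_CONFIG",
    "PROFILES",
    "resolve_config",
    "validate_config",
    "run_experiment",
    "preprocess_dataset",
    "analyze_dataset",
]

DEFAULT_CONFIG: dict = {
    "seed": None,  # mandatory
    "profile": None,  # optional: "fast" | "study"
    "stimulus": {
        "n_blocks": 8,
        "trials_per_block": 96,
        "isi_range_ms": [900.0, 1100.0],
    },
    "simulation": {
        "n_passive": 14,
        "n_active": 13,
        "n_channels": 274,
        "trials_per_cond": 96,
        "rate_hz": 250.0,
        "behavior_trials_per_cond": 96,
        "behavior_nochange_per_scene": 192,
        "noise": {},   # NoiseConfig overrides
        "effects": {},  # EffectConfig overrides (scalar fields)
    },
    "preprocessing": {
        "k_sd": 3.0,
        "n_keep": 2,
        "lowpass_hz": 30.0,
    },
    "stats": {
        "height_p": 0.05,
        "n_perm": 5000,
        "baseline_ms": [-200.0, 0.0],
        "m50_window_ms": [72.0, 112.0],
        "n_select": 20,
    },
}

# "fast" is for smoke runs; "study" mirrors the modelled study dimensions.
PROFILES: dict[str, dict] = {
    "fast": {
        "simulation": {"n_passive": 6, "n_active": 6, "n_channels": 32,
                       "trials_per_cond": 24},
        "stats": {"n_perm": 200},
    },
    "study": {
        "simulation": {"n_passive": 14, "n_active": 13, "n_channels": 274,
                       "trials_per_cond": 96},
        "stats": {"n_perm": 5000},
    },
}


def _deep_update(base: dict, upd: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (upd or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def resolve_config(cfg: dict | None) -> dict:
    """Fill defaults, then apply the named profile, then explicit overrides."""
    cfg = cfg or {}
    profile = cfg.get("profile", None)
    resolved = DEFAULT_CONFIG
    if profile:
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}")
        resolved = _deep_update(resolved, PROFILES[profile])
    return _deep_update(resolved, cfg)


def validate_config(cfg: dict | None) -> tuple[dict, list[str]]:
    """Resolve a (possibly partial) config and report violations by field path."""
    r = resolve_config(cfg)
    diags: list[str] = []
    if r["seed"] is None:
        diags.append("seed: a seed is mandatory")
    elif not isinstance(r["seed"], (int, np.integer)) or r["seed"] < 0:
        diags.append("seed: must be a non-negative integer")
    s = r["simulation"]
    if s["n_passive"] < 2 or s["n_active"] < 2:
        diags.append("simulation.n_passive/n_active: need >= 2 subjects per group")
    if s["n_channels"] < 8:
        diags.append("simulation.n_channels: need >= 8 channels")
    if s["trials_per_cond"] < 4:
        diags.append("simulation.trials_per_cond: need >= 4 trials for rejection")
    p = r["preprocessing"]
    if p["lowpass_hz"] >= s["rate_hz"] / 2:
        diags.append("preprocessing.lowpass_hz: cutoff at or above Nyquist of simulation.rate_hz")
    if p["n_keep"] < 1:
        diags.append("preprocessing.n_keep: must be >= 1")
    st = r["stats"]
    if not 0 < st["height_p"] < 1:
        diags.append("stats.height_p: must be in (0, 1)")
    if st["n_perm"] < 100:
        diags.append("stats.n_perm: need at least 100 permutations")
    b0, b1 = st["baseline_ms"]
    for lock, win in (("scene", sim.SCENE_WINDOW_MS), ("appearance", sim.APPEARANCE_WINDOW_MS)):
        if not (win[0] <= b0 < b1 <= win[1]):
            diags.append(
                f"stats.baseline_ms: [{b0}, {b1}] not contained in the {lock} "
                f"epoch window {list(win)}"
            )
    w0, w1 = st["m50_window_ms"]
    if not (sim.APPEARANCE_WINDOW_MS[0] <= w0 < w1 <= sim.APPEARANCE_WINDOW_MS[1]):
        diags.append("stats.m50_window_ms: outside the appearance epoch window")
    try:
        _effect_config(r)
    except TypeError as e:
        diags.append(f"simulation.effects: {e}")
    try:
        _noise_config(r)
    except TypeError as e:
        diags.append(f"simulation.noise: {e}")
    return r, diags


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _effect_config(cfg: dict) -> EffectConfig:
    over = dict(cfg["simulation"]["effects"])
    for key in ("scene_reg_onset_ms", "appearance_reg_onset_ms"):
        if key in over:
            over[key] = tuple(over[key])
    return EffectConfig(**over)


def _noise_config(cfg: dict) -> NoiseConfig:
    return NoiseConfig(**cfg["simulation"]["noise"])


def _pool_scene_trials(subj: dict) -> TrialTensor:
    reg, rand = subj["scene"]["REG"], subj["scene"]["RAND"]
    data = np.concatenate([reg.data, rand.data], axis=2)
    return TrialTensor(data, reg.rate_hz, reg.t0_ms, "scene", {"pooled": True})


def preprocess_subject(subj: dict, cfg: dict) -> tuple[dict, list[dict]]:
    """Outlier rejection + DSS denoising + trial averaging for one subject.

    The DSS model is fitted on the pooled scene-locked epochs (REG and
    RAND together, after rejection) and its top ``n_keep`` components are
    used to denoise every condition of both locks, matching a bias window
    locked to scene onset.  Returns the per-subject evoked record and the
    rejection-log entries.
    """
    k_sd = cfg["preprocessing"]["k_sd"]
    n_keep = cfg["preprocessing"]["n_keep"]
    log = []
    clean: dict = {"scene": {}, "appearance": {}}
    for lock in ("scene", "appearance"):
        for cond, tt in subj[lock].items():
            kept, rejected = reject_outlier_trials(tt, k_sd)
            clean[lock][cond] = kept
            log.append(
                dict(subject=subj["id"], lock=lock, condition=cond,
                     rejected=rejected, n_trials=tt.n_trials)
            )
    model = dss_fit(_pool_scene_trials(clean))
    evoked = {"scene": {}, "appearance": {}}
    for lock in ("scene", "appearance"):
        for cond, tt in clean[lock].items():
            evoked[lock][cond] = dss_apply(model, tt, n_keep).average()
    record = dict(id=subj["id"], group=subj["group"], evoked=evoked,
                  dss_eigenvalues=model.eigenvalues[: max(4, n_keep)].tolist())
    return record, log


def preprocess_dataset(dataset: dict, cfg: dict) -> dict:
    """Apply :func:`preprocess_subject` to every subject of a dataset."""
    out = {"subjects": [], "rejection_log": []}
    for subj in dataset["subjects"]:
        record, log = preprocess_subject(subj, cfg)
        out["subjects"].append(record)
        out["rejection_log"].extend(log)
    return out


def _group_rms(processed: dict, group: str, lock: str, cond: str) -> np.ndarray:
    rows = [
        rms_timecourse(s["evoked"][lock][cond]).values
        for s in processed["subjects"]
        if s["group"] == group and cond in s["evoked"][lock]
    ]
    return np.stack(rows)


def _cluster_to_dict(c) -> dict:
    return dict(start_ms=c.start_ms, end_ms=c.end_ms, stat=c.stat,
                p_fwe=c.p_fwe, sign=c.sign)


def _latency_to_dict(est: LatencyEstimate | None) -> dict | None:
    if est is None:
        return None
    return dict(mean_ms=est.mean_ms, corrected_se_ms=est.corrected_se_ms,
                n=est.n, subsample_latencies_ms=est.subsample_latencies_ms.tolist())


def analyze_dataset(processed: dict, cfg: dict, rng: np.random.Generator) -> dict:
    """Cluster permutation tests, jackknife latencies, channel subsets, per group."""
    st = cfg["stats"]
    any_subject = processed["subjects"][0]
    rate = any_subject["evoked"]["scene"]["REG"].rate_hz
    results: dict = {"groups": {}}
    onsets: dict[str, dict[str, LatencyEstimate | None]] = {}
    has_nochange = "REG_nochange" in any_subject["evoked"]["appearance"]
    for group in sim.GROUPS:
        gres: dict = {}
        contrasts = [("scene", "REG", "RAND", "scene_reg_vs_rand"),
                     ("appearance", "REG", "RAND", "appearance_reg_vs_rand")]
        if has_nochange:
            contrasts.append(
                ("appearance", "REG_nochange", "RAND_nochange", "nochange_reg_vs_rand")
            )
        onsets[group] = {}
        for lock, ca, cb, name in contrasts:
            a = _group_rms(processed, group, lock, ca)
            b = _group_rms(processed, group, lock, cb)
            t0 = sim.SCENE_WINDOW_MS[0] if lock == "scene" else sim.APPEARANCE_WINDOW_MS[0]
            res = cluster_permutation_test(
                a, b, design="paired", height_p=st["height_p"],
                n_perm=st["n_perm"], rng=rng, rate_hz=rate, t0_ms=t0,
            )
            gres[name] = {
                "clusters": [_cluster_to_dict(c) for c in res.clusters],
                "significant": [_cluster_to_dict(c) for c in res.significant()],
            }
            if name.endswith("reg_vs_rand") and not name.startswith("nochange"):
                try:
                    est = jackknife_onset(
                        a - b, rate_hz=rate, t0_ms=t0,
                        baseline_ms=tuple(st["baseline_ms"]),
                    )
                except OnsetNotCrossedError as e:
                    warnings.warn(f"{group}/{name}: {e}")
                    est = None
                onsets[group][lock] = est
                gres[name]["onset"] = _latency_to_dict(est)
        results["groups"][group] = gres
    for lock in ("scene", "appearance"):
        ea, eb = onsets["Passive"].get(lock), onsets["Active"].get(lock)
        if ea is not None and eb is not None:
            t, df, p, degen = jackknife_two_sample_test(ea, eb)
            results[f"{lock}_onset_group_test"] = dict(t=t, df=df, p=p, degenerate=degen)
    # polarity-preserving channel subsets around the appearance-evoked M50
    subset = {}
    for group in sim.GROUPS:
        evs = [
            np.stack([s["evoked"]["appearance"]["REG"].data,
                      s["evoked"]["appearance"]["RAND"].data]).mean(axis=0)
            for s in processed["subjects"] if s["group"] == group
        ]
        pooled = np.stack(evs)
        times = any_subject["evoked"]["appearance"]["REG"].times_ms
        n_sel = min(st["n_select"], pooled.shape[1] // 2)
        per_cond = {}
        for cond in ("REG", "RAND"):
            data = np.stack([
                s["evoked"]["appearance"][cond].data
                for s in processed["subjects"] if s["group"] == group
            ])
            pos, neg, pidx, nidx = channel_subset_means(
                pooled, times, tuple(st["m50_window_ms"]), n_sel
            )
            wmask = (times >= st["m50_window_ms"][0]) & (times <= st["m50_window_ms"][1])
            per_cond[cond] = dict(
                pos_window_mean=float(data[:, pidx, :][:, :, wmask].mean()),
                neg_window_mean=float(data[:, nidx, :][:, :, wmask].mean()),
            )
        subset[group] = per_cond
    results["m50_channel_subsets"] = subset
    return results


def run_experiment(cfg: dict | None, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and return (and optionally write) the run report."""
    resolved, diags = validate_config(cfg)
    if diags:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(diags))
    seed = int(resolved["seed"])
    ss = np.random.SeedSequence(seed)
    rng_stim, rng_data, rng_behavior, rng_perm = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    timings: dict[str, float] = {}
    report: dict = {
        "seed": seed,
        "config": resolved,
        "config_hash": config_hash(resolved),
    }

    t0 = time.perf_counter()
    stim = resolved["stimulus"]
    manifest = make_trial_sequence(
        rng_stim, stim["n_blocks"], stim["trials_per_block"],
        tuple(stim["isi_range_ms"]),
    )
    report["stimulus"] = {
        "n_trials": int(len(manifest)),
        "n_change_trials": int(manifest.has_change.sum()),
        "conditions": sorted(manifest.scene_regularity.unique().tolist()),
    }
    timings["synthesize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    s = resolved["simulation"]
    fx = _effect_config(resolved)
    noise = _noise_config(resolved)
    behavior = sim.simulate_behavior(
        fx, rng_behavior, n_subjects=s["n_active"],
        trials_per_cond=s["behavior_trials_per_cond"],
        nochange_per_scene=s["behavior_nochange_per_scene"],
    )
    # subjects are simulated and preprocessed one at a time so that peak
    # memory stays at a single subject's epochs even at study scale
    sensors = sim.make_sensor_topographies(
        s["n_channels"], rng_data, noise.n_noise_sources
    )
    processed: dict = {"subjects": [], "rejection_log": []}
    t_sim = 0.0
    t_prep = 0.0
    t1 = time.perf_counter()
    for subj in sim.iter_subject_datasets(
        fx, rng_data, n_passive=s["n_passive"], n_active=s["n_active"],
        sensors=sensors, trials_per_cond=s["trials_per_cond"],
        noise=noise, rate_hz=s["rate_hz"],
    ):
        t2 = time.perf_counter()
        t_sim += t2 - t1
        record, log = preprocess_subject(subj, resolved)
        processed["subjects"].append(record)
        processed["rejection_log"].extend(log)
        t1 = time.perf_counter()
        t_prep += t1 - t2
    report["rejection_log"] = processed["rejection_log"]
    timings["simulate"] = t_sim
    timings["preprocess"] = t_prep

    t0 = time.perf_counter()
    results = analyze_dataset(processed, resolved, rng_perm)
    bsum = behavior_summary(behavior)
    results["behavior"] = _json_safe(bsum)
    report["results"] = _json_safe(results)
    timings["analyze"] = time.perf_counter() - t0
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        # timings are run-specific and stay out of the persisted report,
        # which is byte-identical for a fixed (config, seed)
        persisted = {k: v for k, v in report.items() if k != "timings_s"}
        (out_dir / "report.json").write_text(
            json.dumps(persisted, indent=1, sort_keys=True)
        )
        manifest.to_csv(out_dir / "trial_manifest.csv", index=False)
        from .io import behavior_to_csv

        behavior_to_csv(out_dir / "behavior.csv", behavior)
    return report


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _json_safe(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else str(f)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def default_stimulus_params() -> StimulusParams:
    return StimulusParams()
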