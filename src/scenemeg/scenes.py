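"""Synthesis of multi-source tone-pip "scenes".

A scene is a 2.5-3.5 s mixture of 7-8 concurrent pure-tone sources.  Each
source is a train of tone-pips at a unique carrier frequency drawn from an
ERB-spaced pool.  In REG scenes every source repeats with a fixed
tone/silence cycle; in RAND scenes the tone duration is fixed but every
silent interval is drawn anew from the same uniform distribution, so the
long-term statistics match while the temporal pattern is unpredictable.
On change trials a new source appears 1000-2000 ms into the scene and the
scene always continues for exactly 1500 ms after the appearance.  Change
and no-change stimuli are rendered from the same symbolic configuration so
their waveforms are sample-identical before the appearance time.

Everything is generated from an explicit symbolic :class:`SceneSpec`, so a
spec renders to the same waveform bit-for-bit on every call.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .erb import CarrierPool, build_carrier_pool, erb_bandwidth

__all__ = [
    "StimulusParams",
    "SourceSpec",
    "SceneSpec",
    "Waveform",
    "draw_scene_spec",
    "make_matched_pair",
    "render_source",
    "render_scene",
    "render_matched_pair",
    "auditory_spectrogram",
    "make_trial_sequence",
]


@dataclass(frozen=True)
class StimulusParams:
    """Stimulus-generation parameters (defaults are the experiment's values)."""

    duration_range_ms: tuple[float, float] = (2500.0, 3500.0)
    n_sources_choices: tuple[int, ...] = (7, 8)
    tone_dur_range_ms: tuple[float, float] = (22.0, 167.0)
    gap_range_ms: tuple[float, float] = (1.0, 167.0)
    appearance_range_ms: tuple[float, float] = (1000.0, 2000.0)
    post_change_ms: float = 1500.0
    fmin_hz: float = 200.0
    fmax_hz: float = 2800.0
    step_erb: float = 2.0
    rate_hz: int = 44100
    scene_ramp_ms: float = 30.0
    pip_ramp_ms: float = 5.0
    norm_peak: float = 0.9


@dataclass(frozen=True)
class SourceSpec:
    """One tone-pip source.

    ``gap_mode`` is ``"regular"`` (every silent interval equals ``gap_ms``)
    or ``"random"`` (intervals follow the realised ``gap_sequence_ms``,
    drawn from ``gap_range_ms`` when the scene was drawn).  ``onset_ms`` is
    when the source enters the scene (0 for original sources, the
    appearance time for an appearing source); ``start_offset_ms`` delays
    the first pip relative to the onset so sources are desynchronised.
    """

    carrier_hz: float
    tone_dur_ms: float
    gap_mode: str
    gap_ms: float | None = None
    gap_range_ms: tuple[float, float] | None = None
    gap_sequence_ms: tuple[float, ...] = ()
    start_offset_ms: float = 0.0
    onset_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.carrier_hz <= 0:
            raise ValueError("carrier_hz must be positive")
        if not 22.0 <= self.tone_dur_ms <= 167.0:
            raise ValueError("tone_dur_ms outside [22, 167] ms")
        if self.gap_mode not in ("regular", "random"):
            raise ValueError("gap_mode must be 'regular' or 'random'")
        if self.gap_mode == "regular":
            if self.gap_ms is None or not 1.0 <= self.gap_ms <= 167.0:
                raise ValueError("regular source needs gap_ms in [1, 167] ms")
        else:
            if not self.gap_sequence_ms:
                raise ValueError("random source needs a realised gap_sequence_ms")
            g = np.asarray(self.gap_sequence_ms)
            if g.min() < 1.0 or g.max() > 167.0:
                raise ValueError("gap values outside [1, 167] ms")

    def gaps(self):
        """Iterator over successive inter-tone silent intervals (ms)."""
        if self.gap_mode == "regular":
            while True:
                yield self.gap_ms
        else:
            yield from self.gap_sequence_ms


@dataclass(frozen=True)
class SceneSpec:
    """Complete symbolic description of one stimulus."""

    duration_ms: float
    sources: tuple[SourceSpec, ...]
    scene_regularity: str  # "REG" | "RAND"
    has_change: bool = False
    appearing_source: SourceSpec | None = None
    appearance_time_ms: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.scene_regularity not in ("REG", "RAND"):
            raise ValueError("scene_regularity must be 'REG' or 'RAND'")
        if self.has_change:
            if self.appearing_source is None or self.appearance_time_ms is None:
                raise ValueError("change scene needs appearing_source and appearance_time_ms")
            if abs(self.duration_ms - self.appearance_time_ms - 1500.0) > 1e-6:
                raise ValueError("appearance-to-offset interval must be exactly 1500 ms")
        carriers = [s.carrier_hz for s in self.sources]
        if self.has_change:
            carriers.append(self.appearing_source.carrier_hz)
        if len(set(carriers)) != len(carriers):
            raise ValueError("carrier frequencies must be distinct")


@dataclass
class Waveform:
    """Rendered audio with labelled event markers (times in ms)."""

    samples: np.ndarray
    rate_hz: int
    events: dict[str, float] = field(default_factory=dict)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.rate_hz


def _round_sample(t_ms: float, rate_hz: float) -> int:
    return int(round(t_ms * rate_hz / 1000.0))


def _draw_source(
    rng: np.random.Generator,
    carrier_hz: float,
    regular: bool,
    params: StimulusParams,
    span_ms: float,
    onset_ms: float,
    desync: bool,
) -> SourceSpec:
    tone = float(rng.uniform(*params.tone_dur_range_ms))
    lo, hi = params.gap_range_ms
    if regular:
        gap = float(rng.uniform(lo, hi))
        cycle = tone + gap
        offset = float(rng.uniform(0.0, cycle)) if desync else 0.0
        return SourceSpec(carrier_hz, tone, "regular", gap_ms=gap,
                          start_offset_ms=offset, onset_ms=onset_ms)
    # random mode: realise enough gaps to cover the span with shortest cycles
    n_gaps = int(np.ceil(span_ms / (tone + lo))) + 2
    seq = tuple(float(g) for g in rng.uniform(lo, hi, size=n_gaps))
    offset = float(rng.uniform(0.0, tone + 0.5 * (lo + hi))) if desync else 0.0
    return SourceSpec(carrier_hz, tone, "random", gap_range_ms=(lo, hi),
                      gap_sequence_ms=seq, start_offset_ms=offset, onset_ms=onset_ms)


def draw_scene_spec(
    rng: np.random.Generator,
    params: StimulusParams = StimulusParams(),
    scene_regularity: str = "REG",
    has_change: bool = True,
    appearing_regular: bool = True,
    pool: CarrierPool | None = None,
) -> SceneSpec:
    """Draw one random scene configuration.

    Change scenes draw the appearance time uniformly (rounded to the nearest
    audio sample) and set the total duration to appearance + 1500 ms, which
    keeps durations on the stated 2500-3500 ms support.
    """
    if scene_regularity not in ("REG", "RAND"):
        raise ValueError("scene_regularity must be 'REG' or 'RAND'")
    if pool is None:
        pool = build_carrier_pool(params.fmin_hz, params.fmax_hz, params.step_erb)
    n_src = int(rng.choice(params.n_sources_choices))
    need = n_src + (1 if has_change else 0)
    if len(pool) < need:
        raise ValueError(f"carrier pool ({len(pool)}) smaller than required sources ({need})")
    carriers = rng.choice(np.asarray(pool.freqs_hz), size=need, replace=False)

    if has_change:
        appearance = float(rng.uniform(*params.appearance_range_ms))
        appearance = _round_sample(appearance, params.rate_hz) * 1000.0 / params.rate_hz
        duration = appearance + params.post_change_ms
    else:
        appearance = None
        duration = float(rng.uniform(*params.duration_range_ms))

    regular_scene = scene_regularity == "REG"
    sources = tuple(
        _draw_source(rng, float(c), regular_scene, params, duration, 0.0, desync=True)
        for c in carriers[:n_src]
    )
    appearing = None
    if has_change:
        appearing = _draw_source(
            rng, float(carriers[-1]), appearing_regular, params,
            params.post_change_ms, appearance, desync=False,
        )
    return SceneSpec(
        duration_ms=duration,
        sources=sources,
        scene_regularity=scene_regularity,
        has_change=has_change,
        appearing_source=appearing,
        appearance_time_ms=appearance,
        seed=int(rng.integers(2**31)),
    )


def make_matched_pair(spec: SceneSpec) -> tuple[SceneSpec, SceneSpec]:
    """Return (change, no-change) scenes sharing every original source.

    The no-change member is the same configuration with the appearing source
    removed; ``appearance_time_ms`` is kept as metadata so matched no-change
    epochs can be locked to the same time point.
    """
    if not spec.has_change:
        raise ValueError("make_matched_pair requires a change scene")
    nochange = dataclasses.replace(spec, has_change=False, appearing_source=None)
    return spec, nochange


def _cosine_ramp(n: int) -> np.ndarray:
    # raised-cosine (hann-edge) ramp from 0 to 1 over n samples
    return 0.5 * (1.0 - np.cos(np.pi * np.arange(1, n + 1) / (n + 1)))


def render_source(
    src: SourceSpec,
    duration_ms: float,
    rate_hz: int,
    pip_ramp_ms: float = 5.0,
    amplitude: float = 1.0,
) -> Waveform:
    """Render one source as a train of ramped pure-tone pips.

    Pips start at ``onset_ms + start_offset_ms`` and repeat with the source's
    tone/gap cycle; the final pip is truncated at the scene end.  Each pip
    carries a short cosine on/off ramp to avoid spectral splatter (the pips
    can be as short as 22 ms, so the ramp is deliberately brief).
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    if src.carrier_hz >= rate_hz / 2:
        raise ValueError("carrier at or above Nyquist")
    n = _round_sample(duration_ms, rate_hz)
    out = np.zeros(n)
    pip_len = _round_sample(src.tone_dur_ms, rate_hz)
    ramp_len = min(_round_sample(pip_ramp_ms, rate_hz), pip_len // 2)
    env = np.ones(pip_len)
    if ramp_len > 0:
        r = _cosine_ramp(ramp_len)
        env[:ramp_len] *= r
        env[-ramp_len:] *= r[::-1]
    pip = amplitude * env * np.sin(
        2 * np.pi * src.carrier_hz * np.arange(pip_len) / rate_hz
    )
    t = src.onset_ms + src.start_offset_ms
    gaps = src.gaps()
    while True:
        i0 = _round_sample(t, rate_hz)
        if i0 >= n:
            break
        seg = pip[: n - i0]
        out[i0 : i0 + len(seg)] += seg
        try:
            t += src.tone_dur_ms + next(gaps)
        except StopIteration:
            break
    return Waveform(out, rate_hz, events={"source_onset": src.onset_ms})


def _mix_sources(spec: SceneSpec, rate_hz: int, pip_ramp_ms: float) -> np.ndarray:
    n = _round_sample(spec.duration_ms, rate_hz)
    mix = np.zeros(n)
    for src in spec.sources:
        mix += render_source(src, spec.duration_ms, rate_hz, pip_ramp_ms).samples
    return mix


def _finalise(mix: np.ndarray, spec: SceneSpec, rate_hz: int,
              scale: float, ramp_ms: float) -> Waveform:
    out = mix * scale
    ramp_len = min(_round_sample(ramp_ms, rate_hz), len(out) // 2)
    if ramp_len > 0:
        r = _cosine_ramp(ramp_len)
        out[:ramp_len] *= r
        out[-ramp_len:] *= r[::-1]
    if np.max(np.abs(out)) > 1.0 + 1e-12:
        raise RuntimeError("scene clipped after normalisation")
    events = {"scene_onset": 0.0, "scene_offset": spec.duration_ms}
    if spec.appearance_time_ms is not None:
        events["appearance"] = spec.appearance_time_ms
    return Waveform(out, rate_hz, events=events)


def render_scene(
    spec: SceneSpec,
    rate_hz: int = 44100,
    norm_peak: float = 0.9,
    scene_ramp_ms: float = 30.0,
    pip_ramp_ms: float = 5.0,
) -> Waveform:
    """Render a full scene: sum of sources, peak-normalised, 30 ms scene ramps."""
    mix = _mix_sources(spec, rate_hz, pip_ramp_ms)
    if spec.has_change:
        mix = mix + render_source(
            spec.appearing_source, spec.duration_ms, rate_hz, pip_ramp_ms
        ).samples
    peak = np.max(np.abs(mix))
    scale = norm_peak / peak if peak > 0 else 1.0
    return _finalise(mix, spec, rate_hz, scale, scene_ramp_ms)


def render_matched_pair(
    change_spec: SceneSpec,
    rate_hz: int = 44100,
    norm_peak: float = 0.9,
    scene_ramp_ms: float = 30.0,
    pip_ramp_ms: float = 5.0,
) -> tuple[Waveform, Waveform]:
    """Render a matched change/no-change pair with a shared normalisation.

    Both members are scaled by the change member's peak so the waveforms are
    bit-identical before the appearance time.
    """
    change_spec, nochange_spec = make_matched_pair(change_spec)
    base = _mix_sources(change_spec, rate_hz, pip_ramp_ms)
    full = base + render_source(
        change_spec.appearing_source, change_spec.duration_ms, rate_hz, pip_ramp_ms
    ).samples
    peak = np.max(np.abs(full))
    scale = norm_peak / peak if peak > 0 else 1.0
    w_change = _finalise(full, change_spec, rate_hz, scale, scene_ramp_ms)
    w_nochange = _finalise(base, nochange_spec, rate_hz, scale, scene_ramp_ms)
    return w_change, w_nochange


def auditory_spectrogram(
    w: Waveform,
    pool: CarrierPool | None = None,
    smooth_ms: float = 8.0,
    hop_ms: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bandpass energy per ERB-spaced channel, temporally smoothed.

    Visualisation aid: one 1-ERB-wide channel per pool carrier, envelope
    smoothed over ``smooth_ms`` and sampled every ``hop_ms``.  Returns
    ``(spec, freqs_hz, frame_times_ms)`` with rows ordered by ERB-number.
    """
    if pool is None:
        pool = build_carrier_pool()
    x = np.asarray(w.samples, dtype=float)
    hop = max(1, _round_sample(hop_ms, w.rate_hz))
    win = max(1, _round_sample(smooth_ms, w.rate_hz))
    kernel = np.ones(win) / win
    rows = []
    for f in pool.freqs_hz:
        bw = erb_bandwidth(f)
        lo, hi = max(1.0, f - bw / 2), min(w.rate_hz / 2 - 1.0, f + bw / 2)
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=w.rate_hz, output="sos")
        env = np.abs(signal.sosfiltfilt(sos, x)) if x.size else x
        if x.size:
            env = signal.fftconvolve(env, kernel, mode="same")
        rows.append(env[::hop])
    spec = np.asarray(rows)
    frame_times = np.arange(spec.shape[1]) * hop * 1000.0 / w.rate_hz
    return spec, np.asarray(pool.freqs_hz), frame_times


def make_trial_sequence(
    rng: np.random.Generator,
    n_blocks: int = 8,
    trials_per_block: int = 96,
    isi_range_ms: tuple[float, float] = (900.0, 1100.0),
):
    """Balanced trial sequencing metadata (no audio concatenation).

    Returns a pandas DataFrame with one row per trial: block, trial index,
    scene regularity, change flag, appearing-source regularity (NA on
    no-change trials), ISI and a per-trial child seed.
    """
    import pandas as pd

    if trials_per_block % 8:
        raise ValueError("trials_per_block must be divisible by 8 for a balanced design")
    rows = []
    for block in range(n_blocks):
        cells = []
        per = trials_per_block // 8
        for scene in ("REG", "RAND"):
            for change in (True, False):
                for app_reg in (True, False):
                    cells += [(scene, change, app_reg if change else None)] * per
        order = rng.permutation(len(cells))
        for k, idx in enumerate(order):
            scene, change, app_reg = cells[idx]
            rows.append(
                dict(
                    block=block,
                    trial=k,
                    scene_regularity=scene,
                    has_change=change,
                    appearing_regular=app_reg,
                    isi_ms=float(rng.uniform(*isi_range_ms)),
                    seed=int(rng.integers(2**31)),
                )
            )
    return pd.DataFrame(rows)
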