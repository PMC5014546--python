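"""Plotting helpers: RMS time-courses with cluster shading, spectrograms."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_rms_with_clusters", "plot_auditory_spectrogram"]


def plot_rms_with_clusters(times_ms, rms_a, rms_b, result, labels=("REG", "RAND"),
                           ax=None, alpha: float = 0.05):
    """Group-mean RMS per condition with significant clusters shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(times_ms, np.mean(rms_a, axis=0), label=labels[0])
    ax.plot(times_ms, np.mean(rms_b, axis=0), label=labels[1])
    for c in result.clusters:
        sig = c.p_fwe <= alpha
        ax.axvspan(c.start_ms, c.end_ms, color="green" if sig else "lightgreen",
                   alpha=0.5 if sig else 0.25, lw=0)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("RMS (a.u.)")
    ax.legend(frameon=False)
    return ax


def plot_auditory_spectrogram(spec, freqs_hz, frame_times_ms, ax=None):
    """ERB-channel energy matrix as an image, rows ordered by ERB-number."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.imshow(spec, aspect="auto", origin="lower", cmap="magma",
              extent=[frame_times_ms[0], frame_times_ms[-1], 0, spec.shape[0]])
    ax.set_yticks(np.arange(len(freqs_hz)) + 0.5)
    ax.set_yticklabels([f"{f:.0f}" for f in freqs_hz])
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("carrier (Hz)")
    return ax
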