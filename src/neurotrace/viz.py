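"""Convenience plots. These are inspection aids, not analyzed outputs."""

from __future__ import annotations

import numpy as np

from .prep import EpochSet


def plot_grand_average(epochs: EpochSet, channel: str = "Pz", ax=None):
    """Grand-average ERP per class at one channel.

    Returns the matplotlib axes. With the default generator settings the
    target trace shows the late parietal positivity (delayed by the stimulus
    pipeline lag) that the decoder exploits; all classes share the early
    negativity.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if epochs.channel_labels and channel in epochs.channel_labels:
        ci = epochs.channel_labels.index(channel)
    else:
        ci = 0
        channel = (epochs.channel_labels or ["ch0"])[0]
    t = epochs.window[0] + np.arange(epochs.n_samples) / epochs.fs_hz
    for lab in np.unique(epochs.labels):
        mask = epochs.labels == lab
        ax.plot(t, epochs.epochs[mask, ci, :].mean(axis=0), label=f"class {lab} (n={mask.sum()})")
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time from marker (s)")
    ax.set_ylabel("amplitude (uV)")
    ax.set_title(f"grand average at {channel}")
    ax.legend()
    return ax
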