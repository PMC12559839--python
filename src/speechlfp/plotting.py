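"""Basic time-frequency map rendering (log frequency axis, onset line)."""

from __future__ import annotations

import numpy as np

from .surrogate import ThresholdedTFMap


def plot_tfmap(tfmap, channel: int = 0, ax=None, vlim: float | None = None,
               masked: bool = False, title: str | None = None):
    """Render one contact's dB map; returns the matplotlib Axes.

    With masked=True a ThresholdedTFMap shows non-significant pixels as
    0 dB, mirroring the thresholded group figures.
    """
    import matplotlib.pyplot as plt

    if isinstance(tfmap, ThresholdedTFMap):
        data = tfmap.masked_data() if masked else tfmap.map.data
        m = tfmap.map
    else:
        data, m = tfmap.data, tfmap
    if ax is None:
        _, ax = plt.subplots()
    v = vlim if vlim is not None else float(np.abs(data[channel]).max()) or 1.0
    mesh = ax.pcolormesh(m.times_ms, m.freqs_hz, data[channel], cmap="RdBu_r",
                         vmin=-v, vmax=v, shading="nearest")
    ax.set_yscale("log")
    ax.set_ylabel("frequency (Hz)")
    ax.set_xlabel("time from speech onset (ms)")
    ax.axvline(0.0, color="k", lw=1)
    ax.set_title(title or f"{m.condition} (contact {m.channels[channel]})")
    ax.figure.colorbar(mesh, ax=ax, label="power (dB)")
    return ax
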