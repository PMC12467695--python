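"""Simple validation figures: Bland-Altman and error-distribution plots."""

from __future__ import annotations

import numpy as np

from .stats import AgreementStats


def bland_altman_plot(values, reference, stats: AgreementStats, ax=None):
    """Scatter of differences against means with bias and LoA lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    values = np.asarray(values, dtype=float)
    ref = np.broadcast_to(np.asarray(reference, dtype=float), values.shape)
    mean = (values + ref) / 2.0
    diff = values - ref
    ax.scatter(mean, diff, s=14, alpha=0.7)
    ax.axhline(stats.bias, color="k", label=f"bias {stats.bias:.1f}")
    for y, lbl in [(stats.loa_lower, "LoA low"), (stats.loa_upper, "LoA high")]:
        ax.axhline(y, color="r", linestyle="--", label=f"{lbl} {y:.1f}")
    ax.set_xlabel("mean of measurement and reference (deg)")
    ax.set_ylabel("measurement - reference (deg)")
    ax.legend(fontsize=8)
    return ax


def error_distribution_plot(values, reference, ax=None):
    """Histogram of measurement errors about the reference."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    err = np.asarray(values, dtype=float) - np.asarray(reference, dtype=float)
    ax.hist(err, bins="auto", edgecolor="k")
    ax.axvline(0.0, color="r")
    ax.set_xlabel("error (deg)")
    ax.set_ylabel("count")
    return ax
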