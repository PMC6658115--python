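"""Diagnostic plots (requires matplotlib)."""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["qq_plot"]


def qq_plot(p_values: Sequence[float], ax=None, label: str | None = None):
    """Quantile-quantile plot of observed versus expected -log10 p-values.

    Points above the diagonal indicate inflation of the test statistic.
    Returns the matplotlib axis.
    """
    import matplotlib.pyplot as plt

    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    if n == 0:
        raise ValueError("no p-values to plot")
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(expected, observed, "o", ms=3, alpha=0.7, label=label)
    lim = max(expected.max(), observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    if label:
        ax.legend()
    return ax
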