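"""Optional matplotlib figures: tornado diagram, CEAC, cost-effectiveness plane."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .psa import CEACCurve, Ellipse
from .sensitivity import TornadoEntry


def tornado_plot(entries: Sequence[TornadoEntry], base_value: float, output: str):
    """Horizontal tornado bars around the base-case output value."""
    import matplotlib.pyplot as plt

    shown = [e for e in entries if e.spread > 0] or list(entries)
    fig, ax = plt.subplots(figsize=(7, 0.5 * max(4, len(shown))))
    ypos = np.arange(len(shown))[::-1]
    for y, e in zip(ypos, shown):
        lo, hi = sorted((e.output_low, e.output_high))
        ax.barh(y, hi - lo, left=lo, height=0.6, color="#4878d0", edgecolor="none")
    ax.axvline(base_value, color="black", lw=1, label="base case")
    ax.set_yticks(ypos)
    ax.set_yticklabels([e.parameter for e in shown])
    ax.set_xlabel(output)
    ax.legend(loc="lower right")
    fig.tight_layout()
    return fig


def ceac_plot(curve: CEACCurve):
    """Acceptability curves: probability cost-effective versus willingness-to-pay."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for strategy in curve.probabilities.columns:
        ax.plot(curve.wtp, curve.probabilities[strategy], label=strategy)
    ax.axhline(0.5, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("willingness-to-pay (US$/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    return fig


def ce_plane_plot(cloud, ellipse: Ellipse, wtp: float):
    """Incremental cost-effectiveness scatter with the confidence ellipse and WTP line."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6.5, 6))
    ax.scatter(cloud["delta_effect"], cloud["delta_cost"], s=4, alpha=0.3, color="#4878d0")
    if ellipse is not None and not ellipse.degenerate:
        theta = np.linspace(0, 2 * np.pi, 200)
        circle = np.stack([ellipse.semi_axes[0] * np.cos(theta),
                           ellipse.semi_axes[1] * np.sin(theta)])
        c, s = np.cos(ellipse.orientation), np.sin(ellipse.orientation)
        rot = np.array([[c, -s], [s, c]]) @ circle
        ax.plot(rot[0] + ellipse.center[0], rot[1] + ellipse.center[1],
                color="crimson", lw=1.5, label=f"{ellipse.level:.0%} ellipse")
    xs = np.array(ax.get_xlim())
    ax.plot(xs, wtp * xs, color="grey", lw=0.8, ls="--", label="WTP")
    ax.axhline(0, color="black", lw=0.6)
    ax.axvline(0, color="black", lw=0.6)
    ax.set_xlabel("incremental effect (QALY)")
    ax.set_ylabel("incremental cost (US$)")
    ax.legend()
    fig.tight_layout()
    return fig
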