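"""Quick-look plots for simulation traces and adaptation fields."""

from __future__ import annotations

import numpy as np

from .protocol import AdaptationFieldResult, SimulationTrace

__all__ = ["plot_adaptation_field", "plot_trial_course"]


def plot_adaptation_field(
    fields: AdaptationFieldResult, signal: str = "M", ax=None, scale: float = 1.0
):
    """Arrow plot of the per-probe change of a signal (the adaptation field)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    probes = np.vstack(fields.probes)
    delta = fields.delta[signal]
    ax.quiver(
        probes[:, 0], probes[:, 1], delta[:, 0], delta[:, 1],
        angles="xy", scale_units="xy", scale=1.0 / scale, color="tab:blue",
    )
    ax.plot(probes[:, 0], probes[:, 1], "k.", ms=4)
    ax.set_xlabel("x (dva)")
    ax.set_ylabel("y (dva)")
    ax.set_title(f"$\\Delta${signal} adaptation field")
    ax.set_aspect("equal")
    return ax


def plot_trial_course(trace: SimulationTrace, ax=None):
    """Amplitude of V1, M and CDV across adaptation trials."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    frame = trace.to_frame()
    for sig, color in (("V1", "tab:green"), ("M", "tab:blue"), ("CDV", "tab:orange")):
        amp = np.hypot(frame[f"{sig}_x"], frame[f"{sig}_y"])
        ax.plot(frame["trial"], amp, color=color, label=sig)
    ax.set_xlabel("trial")
    ax.set_ylabel("amplitude (dva)")
    ax.legend()
    return ax
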