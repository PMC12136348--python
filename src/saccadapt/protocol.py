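"""Full experiment simulation and adaptation-field construction.

The simulated protocol mirrors a classic intra-saccadic step experiment: a
pre-adaptation readout of saccades and localizations at 11 probe positions,
a block of adaptation trials at a single target with a peri-saccadic step, a
fractional decay (kappa) of the acquired gain-field changes, and a
post-adaptation readout at the same probes.  The adaptation field is the
per-probe change (post minus pre) of the visual target estimate V1, the
saccade vector M, the internal saccade estimate CDV and the predicted
post-saccadic target Vhat2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import FieldGrid, TEST_GRID
from .gainfields import (
    GainFieldSet,
    ModelParams,
    apply_adaptation_drop,
    build_learning_distributions,
    init_gain_fields,
)
from .engine import TrialInput, TrialOutcome, forward_pre_saccadic, run_trial

__all__ = [
    "ExperimentDesign",
    "AdaptationFieldResult",
    "SimulationTrace",
    "default_probe_set",
    "probe_readout",
    "run_adaptation_experiment",
    "compute_cdv_from_behavior",
]

PROBE_SIGNALS = ("V1", "M", "CDV", "Vhat2")


def default_probe_set(adaptation_target: np.ndarray) -> list[np.ndarray]:
    """The 11 standard probe positions around an adaptation target.

    The target itself, four positions on a 3 dva circle (0, 90, 180, 270 deg)
    and six on a 6 dva circle (30, 90, 150, 210, 270, 330 deg); angles in
    screen polar coordinates (0 deg rightward, counterclockwise positive).
    """
    target = np.asarray(adaptation_target, dtype=float)
    if target[0] == 0.0 and target[1] == 0.0:
        raise ValueError("adaptation target must not be at the fovea")
    probes = [target.copy()]
    for radius, angles in ((3.0, (0, 90, 180, 270)), (6.0, (30, 90, 150, 210, 270, 330))):
        for ang in angles:
            theta = np.deg2rad(ang)
            probes.append(target + radius * np.array([np.cos(theta), np.sin(theta)]))
    return probes


@dataclass(frozen=True)
class ExperimentDesign:
    """Adaptation-experiment layout: target, intra-saccadic step, trial count,
    probe positions and the adaptation drop factor applied before the
    post-adaptation readout."""

    adaptation_target: np.ndarray
    step: np.ndarray
    n_adapt_trials: int = 200
    probe_set: tuple = None  # type: ignore[assignment]
    kappa: float | None = None  # None -> take kappa from ModelParams

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "adaptation_target", np.asarray(self.adaptation_target, dtype=float)
        )
        object.__setattr__(self, "step", np.asarray(self.step, dtype=float))
        if self.n_adapt_trials < 1:
            raise ValueError("n_adapt_trials must be >= 1")
        probes = self.probe_set
        if probes is None:
            probes = default_probe_set(self.adaptation_target)
        probes = tuple(np.asarray(p, dtype=float) for p in probes)
        if not probes:
            raise ValueError("probe_set must be non-empty")
        if not any(np.allclose(p, self.adaptation_target) for p in probes):
            raise ValueError("probe_set must include the adaptation target")
        object.__setattr__(self, "probe_set", probes)

    @classmethod
    def standard(cls, **kwargs) -> "ExperimentDesign":
        """The reference design: 12 dva rightward target, 3 dva inward step,
        200 adaptation trials, 11 probes."""
        defaults = dict(adaptation_target=(12.0, 0.0), step=(-3.0, 0.0))
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass
class SimulationTrace:
    """Per-trial record of an adaptation run."""

    outcomes: list[TrialOutcome]
    gain_at_target: list[dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (out, g) in enumerate(zip(self.outcomes, self.gain_at_target), start=1):
            row = {"trial": i}
            row.update(out.as_row())
            row.update({f"{k}_at_target": v for k, v in g.items()})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class AdaptationFieldResult:
    """Per-probe pre/post readouts and their change (the adaptation field)."""

    probes: list[np.ndarray]
    pre: dict[str, np.ndarray]  # signal -> (n_probes, 2)
    post: dict[str, np.ndarray]

    @property
    def delta(self) -> dict[str, np.ndarray]:
        return {sig: self.post[sig] - self.pre[sig] for sig in self.pre}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, probe in enumerate(self.probes):
            for sig in self.pre:
                for phase, table in (("pre", self.pre), ("post", self.post)):
                    rows.append(
                        {
                            "probe_x": probe[0],
                            "probe_y": probe[1],
                            "signal": sig,
                            "phase": phase,
                            "value_x": table[sig][i, 0],
                            "value_y": table[sig][i, 1],
                        }
                    )
        return pd.DataFrame(rows)

    def amplitude_change(self, signal: str = "M") -> np.ndarray:
        """Per-probe change in readout amplitude, |post| - |pre| (dva)."""
        pre = np.linalg.norm(self.pre[signal], axis=1)
        post = np.linalg.norm(self.post[signal], axis=1)
        return post - pre


def probe_readout(
    gains: GainFieldSet, probe_set, grid: FieldGrid | None = None
) -> dict[str, np.ndarray]:
    """Pre-saccadic readouts (V1, M, CDV, Vhat2) at each probe; never learns."""
    grid = grid or gains.grid
    out = {sig: np.empty((len(probe_set), 2)) for sig in PROBE_SIGNALS}
    for i, probe in enumerate(probe_set):
        pre = forward_pre_saccadic(np.asarray(probe, dtype=float), gains, grid)
        for sig in PROBE_SIGNALS:
            out[sig][i] = pre[sig]
    return out


def run_adaptation_experiment(
    design: ExperimentDesign,
    params: ModelParams,
    grid: FieldGrid = TEST_GRID,
    seed: int | None = None,
    motor_noise_sd: float = 0.0,
    initial_gains: GainFieldSet | None = None,
) -> tuple[SimulationTrace, AdaptationFieldResult, GainFieldSet]:
    """Simulate a complete adaptation experiment.

    Pipeline: flat gains at the pre-adaptation constants -> pre-adaptation
    probe readout -> ``n_adapt_trials`` learning trials at the adaptation
    target with the design's intra-saccadic step -> fractional decay kappa
    toward the pre-adaptation state -> post-adaptation probe readout.  Probe
    readouts never update the gains.

    Motor noise defaults to zero (the fitting regime); with
    ``motor_noise_sd > 0`` iid isotropic Gaussian noise is drawn per trial
    from a generator seeded with ``seed`` (mandatory in that case).

    Returns the trial trace, the adaptation-field result and the final
    (post-drop) gain fields, so multiple designs can share gain state.
    """
    if motor_noise_sd > 0.0 and seed is None:
        raise ValueError("motor noise requested without a seed")
    rng = np.random.default_rng(seed)
    kappa = design.kappa if design.kappa is not None else params.kappa

    gains_pre = initial_gains if initial_gains is not None else init_gain_fields(params, grid)
    alphas = build_learning_distributions(params, design.adaptation_target, grid)

    pre = probe_readout(gains_pre, design.probe_set, grid)

    gains = gains_pre.copy()
    outcomes: list[TrialOutcome] = []
    gain_trace: list[dict[str, float]] = []
    for _ in range(design.n_adapt_trials):
        eps = (
            rng.normal(0.0, motor_noise_sd, size=2)
            if motor_noise_sd > 0.0
            else np.zeros(2)
        )
        trial = TrialInput.make(design.adaptation_target, design.step, eps, learn=True)
        outcome, gains = run_trial(trial, gains, alphas)
        outcomes.append(outcome)
        gain_trace.append(gains.value_at(design.adaptation_target))

    gains_post = apply_adaptation_drop(gains, gains_pre, kappa)
    post = probe_readout(gains_post, design.probe_set, grid)

    trace = SimulationTrace(outcomes, gain_trace)
    fields = AdaptationFieldResult(
        probes=[np.asarray(p) for p in design.probe_set], pre=pre, post=post
    )
    return trace, fields, gains_post


def compute_cdv_from_behavior(
    V1: np.ndarray, V2f: np.ndarray, M: np.ndarray
) -> np.ndarray:
    """Behavioral estimate of the computed displacement of visual space.

    ``CDV = V1 - V2f + M`` with the pre-saccadic localization V1, the
    post-saccadic localization re fixation V2f and the saccade vector M.  If
    pre- and post-saccadic localizations agree (V2f = V1), CDV equals the
    saccade vector: trans-saccadic space is integrated correctly.
    """
    return np.asarray(V1, float) - np.asarray(V2f, float) + np.asarray(M, float)
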