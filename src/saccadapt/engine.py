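"""Forward pass of a single adaptation trial.

A trial proceeds in four stages: (1) pre-saccadic computations — the input
response to the target is routed through the visual, motor and CD gain
fields, yielding the visual target estimate V1, the motor command M and the
internally computed displacement of visual space CDV, plus the predicted
post-saccadic target (forward shift of the visual map by CDV); (2) saccade
execution with optional motor noise, placing the post-saccadic target at P2
relative to the landing position; (3) post-saccadic computations — the
response to P2 is routed through the visual gain field and postdicted back to
pre-saccadic coordinates (backward shift by CDV), giving the postdicted
target Vhat1 and the postdictive motor error E = Vhat1 - M; (4) learning —
E is encoded as a directed amplitude error and applied to the gain fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import (
    FieldGrid,
    PopulationMap,
    apply_gain,
    gaussian_population_response,
    population_vector,
    shift_map,
)
from .gainfields import (
    GainFieldSet,
    LearningDistributionSet,
    directed_amplitude_error,
    update_gain_fields,
)

__all__ = [
    "POST_SACCADIC_SIGMA_FLOOR",
    "TrialInput",
    "TrialOutcome",
    "forward_pre_saccadic",
    "execute_saccade",
    "forward_post_saccadic",
    "run_trial",
]

#: Lower bound on the post-saccadic input width (dva); keeps the response to
#: near-foveal post-saccadic targets well-defined.
POST_SACCADIC_SIGMA_FLOOR = 0.5


@dataclass(frozen=True)
class TrialInput:
    """One trial's externally controlled quantities (all dva)."""

    P1: np.ndarray  # pre-saccadic target
    Ps: np.ndarray  # peri-saccadic target step
    epsilon_M: np.ndarray  # motor noise
    learn: bool = True

    @classmethod
    def make(cls, P1, Ps=(0.0, 0.0), epsilon_M=(0.0, 0.0), learn=True) -> "TrialInput":
        return cls(
            np.asarray(P1, dtype=float),
            np.asarray(Ps, dtype=float),
            np.asarray(epsilon_M, dtype=float),
            learn,
        )


@dataclass
class TrialOutcome:
    """All per-trial signal vectors (dva) and the scalar directed error."""

    V1: np.ndarray
    M: np.ndarray
    CDV: np.ndarray
    Vhat2: np.ndarray
    PM: np.ndarray
    Pd: np.ndarray
    P2: np.ndarray
    V2: np.ndarray
    Vhat1: np.ndarray
    E: np.ndarray
    delta_E: float
    maps: dict[str, PopulationMap] = field(default_factory=dict, repr=False)

    def as_row(self) -> dict[str, float]:
        """Flatten to one tidy-CSV row (x, y columns per vector)."""
        row: dict[str, float] = {}
        for name in ("V1", "M", "CDV", "Vhat2", "PM", "Pd", "P2", "V2", "Vhat1", "E"):
            vec = getattr(self, name)
            row[f"{name}_x"] = float(vec[0])
            row[f"{name}_y"] = float(vec[1])
        row["delta_E"] = float(self.delta_E)
        return row


def forward_pre_saccadic(
    P1: np.ndarray,
    gains: GainFieldSet,
    grid: FieldGrid | None = None,
    keep_maps: bool = False,
) -> dict:
    """Pre-saccadic pass: input -> visual -> motor -> CDV maps and readouts.

    Returns a dict with vectors ``V1, M, CDV, Vhat2``, the visual-map mass
    ``m1`` and, if ``keep_maps``, the intermediate population maps.
    """
    grid = grid or gains.grid
    if grid != gains.grid:
        raise ValueError("grid does not match the gain fields' grid")
    r_i1 = gaussian_population_response(P1, grid)
    r_v1 = apply_gain(r_i1, gains.omega_v)
    r_m = apply_gain(r_v1, gains.omega_m)
    r_cdv = apply_gain(r_m, gains.omega_cd)
    V1 = population_vector(r_v1)
    M = population_vector(r_m)
    CDV = population_vector(r_cdv)
    r_vhat2 = shift_map(r_v1, CDV, "forward")
    Vhat2 = population_vector(r_vhat2)
    out = {
        "V1": V1,
        "M": M,
        "CDV": CDV,
        "Vhat2": Vhat2,
        "m1": r_v1.mass,
    }
    if keep_maps:
        out["maps"] = {"rI1": r_i1, "rV1": r_v1, "rM": r_m, "rCDV": r_cdv,
                       "rVhat2": r_vhat2}
    return out


def execute_saccade(
    M: np.ndarray, epsilon_M: np.ndarray, Ps: np.ndarray, P1: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Saccade execution: landing vector, physical disruption, and the
    post-saccadic target position relative to saccade landing.

    ``PM = M + eps``; ``Pd = Ps - eps``; ``P2 = P1 + Pd - PM``.
    """
    M = np.asarray(M, dtype=float)
    epsilon_M = np.asarray(epsilon_M, dtype=float)
    Ps = np.asarray(Ps, dtype=float)
    P1 = np.asarray(P1, dtype=float)
    PM = M + epsilon_M
    Pd = Ps - epsilon_M
    P2 = P1 + Pd - PM
    return PM, Pd, P2


def forward_post_saccadic(
    P2: np.ndarray,
    gains: GainFieldSet,
    CDV: np.ndarray,
    M: np.ndarray,
    grid: FieldGrid | None = None,
    keep_maps: bool = False,
) -> dict:
    """Post-saccadic pass: input response to P2, visual gain, postdiction.

    The backward shift by CDV maps the post-saccadic visual response into
    pre-saccadic coordinates; the postdictive motor error is
    ``E = Vhat1 - M``.
    """
    grid = grid or gains.grid
    if grid != gains.grid:
        raise ValueError("grid does not match the gain fields' grid")
    r_i2 = gaussian_population_response(
        P2, grid, sigma_floor=POST_SACCADIC_SIGMA_FLOOR
    )
    r_v2 = apply_gain(r_i2, gains.omega_v)
    r_vhat1 = shift_map(r_v2, CDV, "backward")
    V2 = population_vector(r_v2)
    Vhat1 = population_vector(r_vhat1)
    E = Vhat1 - np.asarray(M, dtype=float)
    out = {"V2": V2, "Vhat1": Vhat1, "E": E, "m2": r_v2.mass}
    if keep_maps:
        out["maps"] = {"rI2": r_i2, "rV2": r_v2, "rVhat1": r_vhat1}
    return out


def run_trial(
    trial: TrialInput,
    gains: GainFieldSet,
    alphas: LearningDistributionSet | None = None,
    keep_maps: bool = False,
) -> tuple[TrialOutcome, GainFieldSet]:
    """Execute one full trial; returns the outcome and (possibly updated) gains.

    Learning applies the same-trial directed amplitude error once, after the
    post-saccadic pass.  Deterministic given its inputs; the gain fields are
    the only state carried from trial to trial.
    """
    pre = forward_pre_saccadic(trial.P1, gains, keep_maps=keep_maps)
    PM, Pd, P2 = execute_saccade(pre["M"], trial.epsilon_M, trial.Ps, trial.P1)
    post = forward_post_saccadic(P2, gains, pre["CDV"], pre["M"], keep_maps=keep_maps)
    delta_e = directed_amplitude_error(post["E"], trial.P1)
    outcome = TrialOutcome(
        V1=pre["V1"], M=pre["M"], CDV=pre["CDV"], Vhat2=pre["Vhat2"],
        PM=PM, Pd=Pd, P2=P2,
        V2=post["V2"], Vhat1=post["Vhat1"], E=post["E"], delta_E=delta_e,
        maps={**pre.get("maps", {}), **post.get("maps", {})} if keep_maps else {},
    )
    if trial.learn:
        if alphas is None:
            raise ValueError("learning requested but no learning distributions given")
        gains = update_gain_fields(gains, alphas, delta_e)
    return outcome, gains
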