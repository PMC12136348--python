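"""Gain-field state, asymmetric learning distributions, and the learning rule.

Three multiplicative gain fields act on the population responses: the visual
gain field ``omega_v`` (visual localization), the motor gain field ``omega_m``
(the inverse model mapping visual to motor coordinates) and the CD gain field
``omega_cd`` (the forward dynamics model mapping the motor command back to an
internal visual estimate of saccade size).  Each field starts as a flat plane
at a fitted constant and adapts additively, trial by trial, in proportion to
a signed learning-rate map (the learning distribution) times the directed
amplitude error of that trial.

The learning distributions are piecewise Gaussians in coordinates rotated to
the adaptation target's direction: a foveal-side width for positions inward
of the target along the amplitude axis, a peripheral-side width outward, and
a symmetric orthogonal width.  They are evaluated analytically per cell (no
raster rotation) and scaled so that the peak learning rate, at the
adaptation target itself, equals phi.  The peak convention makes the
trial-by-trial dynamics independent of the grid step: gain-field changes are
per-position rates, not rates shared out over however many cells the grid
happens to contain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .grid import FieldGrid, PopulationMap

__all__ = [
    "GainFieldSet",
    "LearningParams",
    "LearningDistributionSet",
    "ModelParams",
    "TABLE1_PARAMS",
    "FIG2_PARAMS",
    "FIG3_PARAMS",
    "NegativeGainError",
    "NegativeGainWarning",
    "init_gain_fields",
    "build_learning_distribution",
    "build_learning_distributions",
    "directed_amplitude_error",
    "update_gain_fields",
    "apply_adaptation_drop",
]


class NegativeGainError(RuntimeError):
    """Raised when a learning update drives a gain field to zero or below."""


class NegativeGainWarning(RuntimeWarning):
    """A learning update drove a gain field to zero or below.

    Deep local indentations are intrinsic to this model: a learning dip much
    narrower than the population response must be deep to move the
    mass-weighted readout by degrees, and realistic adaptation magnitudes can
    push the motor gain at the target below zero.  The dynamics remain
    well-defined (the readout polynomials do not require positivity), but the
    map loses its interpretation as a nonnegative rate, so the event is
    flagged."""


@dataclass
class GainFieldSet:
    """The three multiplicative gain fields on a common grid."""

    omega_v: np.ndarray
    omega_m: np.ndarray
    omega_cd: np.ndarray
    grid: FieldGrid

    def __post_init__(self) -> None:
        n = self.grid.n
        for name in ("omega_v", "omega_m", "omega_cd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, n):
                raise ValueError(f"{name} shape {arr.shape} != grid ({n}, {n})")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, arr)

    def copy(self) -> "GainFieldSet":
        return GainFieldSet(
            self.omega_v.copy(), self.omega_m.copy(), self.omega_cd.copy(), self.grid
        )

    def value_at(self, position: np.ndarray) -> dict[str, float]:
        """Gain values at the grid cell nearest ``position`` (dva)."""
        ax = self.grid.axis
        i = int(np.argmin(np.abs(ax - position[0])))
        j = int(np.argmin(np.abs(ax - position[1])))
        return {
            "omega_v": float(self.omega_v[i, j]),
            "omega_m": float(self.omega_m[i, j]),
            "omega_cd": float(self.omega_cd[i, j]),
        }


@dataclass(frozen=True)
class LearningParams:
    """Shape parameters of the three learning distributions.

    ``phi_*`` are the signed peak learning rates (the rate-map value at the
    adaptation target); ``sigma_*F/P/O`` are the foveal-side, peripheral-side
    and orthogonal Gaussian widths in dva.
    """

    phi_v: float
    phi_m: float
    phi_cd: float
    sigma_vF: float
    sigma_mF: float
    sigma_cdF: float
    sigma_vP: float
    sigma_mP: float
    sigma_cdP: float
    sigma_vO: float
    sigma_mO: float
    sigma_cdO: float

    def __post_init__(self) -> None:
        for name in (
            "sigma_vF", "sigma_mF", "sigma_cdF",
            "sigma_vP", "sigma_mP", "sigma_cdP",
            "sigma_vO", "sigma_mO", "sigma_cdO",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def validate_for_target(self, target: np.ndarray) -> None:
        """Enforce the foveal-extent constraint ``sigma_xF <= |target| / 3``.

        The foveal half-widths may not let learning extend past the fovea.
        Violations raise rather than clip, so fitted bounds stay explicit.
        """
        delta1 = float(np.hypot(*np.asarray(target, dtype=float)))
        limit = delta1 / 3.0
        for name in ("sigma_vF", "sigma_mF", "sigma_cdF"):
            val = getattr(self, name)
            if val > limit + 1e-12:
                raise ValueError(
                    f"{name} = {val} violates the foveal constraint "
                    f"{name} <= |target|/3 = {limit:.4g}"
                )


@dataclass
class LearningDistributionSet:
    """Signed per-cell learning rates for the three gain fields."""

    alpha_v: np.ndarray
    alpha_m: np.ndarray
    alpha_cd: np.ndarray
    grid: FieldGrid
    target: np.ndarray


@dataclass(frozen=True)
class ModelParams:
    """The complete 16-parameter model: three pre-adaptation gain constants,
    twelve learning-distribution parameters and the adaptation drop factor
    kappa (fractional decay of adaptation from the end of the adaptation
    phase to the post-adaptation measurement)."""

    omega_vC: float
    omega_mC: float
    omega_cdC: float
    learning: LearningParams
    kappa: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must lie in [0, 1]")

    # -- flat JSON round trip -------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        d = {
            "omega_vC": self.omega_vC,
            "omega_mC": self.omega_mC,
            "omega_cdC": self.omega_cdC,
        }
        d.update(asdict(self.learning))
        d["kappa"] = self.kappa
        return d

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParams":
        d = dict(d)
        constants = {k: d.pop(k) for k in ("omega_vC", "omega_mC", "omega_cdC")}
        kappa = d.pop("kappa")
        return cls(**constants, learning=LearningParams(**d), kappa=kappa)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def with_learning(self, **kwargs) -> "ModelParams":
        return replace(self, learning=replace(self.learning, **kwargs))


#: Parameters fitted to the grand-mean behavioral data (inward adaptation of a
#: 12 dva rightward saccade with a 3 dva intra-saccadic inward step).
TABLE1_PARAMS = ModelParams(
    omega_vC=0.978,
    omega_mC=0.962,
    omega_cdC=1.020,
    learning=LearningParams(
        phi_v=0.005, phi_m=0.008, phi_cd=-0.003,
        sigma_vF=0.55, sigma_mF=0.48, sigma_cdF=1.10,
        sigma_vP=2.01, sigma_mP=2.66, sigma_cdP=1.18,
        sigma_vO=1.04, sigma_mO=1.06, sigma_cdO=1.13,
    ),
    kappa=0.334,
)

#: Illustrative configuration: inward adaptation of an oblique saccade
#: (12.7 dva at 45 deg) with a 3 dva inward step.
FIG2_PARAMS = ModelParams(
    omega_vC=0.900,
    omega_mC=1.050,
    omega_cdC=1.020,
    learning=LearningParams(
        phi_v=0.002, phi_m=0.002, phi_cd=-0.002,
        sigma_vF=1.00, sigma_mF=2.00, sigma_cdF=1.50,
        sigma_vP=3.50, sigma_mP=7.00, sigma_cdP=6.00,
        sigma_vO=2.00, sigma_mO=4.00, sigma_cdO=3.00,
    ),
    kappa=0.0,
)

#: Illustrative configuration: outward adaptation of a horizontal leftward
#: saccade (9 dva) with a 3 dva outward step.
FIG3_PARAMS = ModelParams(
    omega_vC=0.900,
    omega_mC=1.050,
    omega_cdC=1.020,
    learning=LearningParams(
        phi_v=0.002, phi_m=0.001, phi_cd=-0.001,
        sigma_vF=1.50, sigma_mF=3.00, sigma_cdF=2.00,
        sigma_vP=3.00, sigma_mP=6.00, sigma_cdP=4.00,
        sigma_vO=2.00, sigma_mO=4.00, sigma_cdO=3.00,
    ),
    kappa=0.0,
)


def init_gain_fields(
    constants: tuple[float, float, float] | ModelParams, grid: FieldGrid
) -> GainFieldSet:
    """Flat gain fields at the pre-adaptation constants."""
    if isinstance(constants, ModelParams):
        cv, cm, ccd = constants.omega_vC, constants.omega_mC, constants.omega_cdC
    else:
        cv, cm, ccd = constants
    n = grid.n
    return GainFieldSet(
        np.full((n, n), float(cv)),
        np.full((n, n), float(cm)),
        np.full((n, n), float(ccd)),
        grid,
    )


def build_learning_distribution(
    phi: float,
    sigma_f: float,
    sigma_p: float,
    sigma_o: float,
    target: np.ndarray,
    grid: FieldGrid,
) -> np.ndarray:
    """Signed learning-rate map: rotated piecewise Gaussian with peak ``phi``.

    Cell coordinates are rotated into the target's frame: ``u`` along the
    amplitude axis (unit vector toward the target), ``w`` orthogonal.  The
    shape uses width ``sigma_f`` for ``u < 0`` (inward / toward the fovea),
    ``sigma_p`` for ``u >= 0`` (outward) and ``sigma_o`` along ``w``; both
    halves share the peak at the target, so the map is continuous with a kink
    there.  The map value at the target is exactly ``phi`` (the peak learning
    rate), independent of grid resolution.  Analytic evaluation in rotated
    coordinates keeps the construction exactly rotation-equivariant up to
    grid sampling.
    """
    target = np.asarray(target, dtype=float)
    delta1 = float(np.hypot(*target))
    if delta1 == 0.0:
        raise ValueError("amplitude axis undefined for a target at the fovea")
    u_hat = target / delta1
    X, Y = grid.mesh()
    dx = X - target[0]
    dy = Y - target[1]
    u = dx * u_hat[0] + dy * u_hat[1]
    w = -dx * u_hat[1] + dy * u_hat[0]
    sigma_u = np.where(u < 0.0, sigma_f, sigma_p)
    shape = np.exp(-(u**2 / (2.0 * sigma_u**2) + w**2 / (2.0 * sigma_o**2)))
    return phi * shape


def build_learning_distributions(
    params: LearningParams | ModelParams, target: np.ndarray, grid: FieldGrid
) -> LearningDistributionSet:
    """All three learning distributions for one adaptation target."""
    lp = params.learning if isinstance(params, ModelParams) else params
    lp.validate_for_target(target)
    target = np.asarray(target, dtype=float)
    return LearningDistributionSet(
        alpha_v=build_learning_distribution(
            lp.phi_v, lp.sigma_vF, lp.sigma_vP, lp.sigma_vO, target, grid
        ),
        alpha_m=build_learning_distribution(
            lp.phi_m, lp.sigma_mF, lp.sigma_mP, lp.sigma_mO, target, grid
        ),
        alpha_cd=build_learning_distribution(
            lp.phi_cd, lp.sigma_cdF, lp.sigma_cdP, lp.sigma_cdO, target, grid
        ),
        grid=grid,
        target=target,
    )


def directed_amplitude_error(E: np.ndarray, target: np.ndarray) -> float:
    """Encode a 2D postdictive motor error as a signed amplitude error (dva).

    The magnitude is ``|E|``; the sign comes from the horizontal error
    component relative to the target's hemifield (or the vertical component
    for targets on the vertical meridian), so that inward errors are negative
    and outward errors positive regardless of hemifield.  If the
    sign-determining product is exactly zero while ``|E| > 0`` the error is
    returned as 0, the unique continuous tie-break.
    """
    E = np.asarray(E, dtype=float)
    target = np.asarray(target, dtype=float)
    if target[0] == 0.0 and target[1] == 0.0:
        raise ValueError("directed amplitude error undefined for a foveal target")
    norm = float(np.hypot(*E))
    if norm == 0.0:
        return 0.0
    if target[0] != 0.0:
        prod = E[0] * target[0]
    else:
        prod = E[1] * target[1]
    if prod == 0.0:
        return 0.0
    return float(np.sign(prod)) * norm


def update_gain_fields(
    gains: GainFieldSet,
    alphas: LearningDistributionSet,
    delta_e: float,
    on_nonpositive: str = "warn",
) -> GainFieldSet:
    """One additive learning step, ``omega_x <- omega_x + alpha_x * delta_e``.

    A field driven to zero or below is flagged: warned by default
    (:class:`NegativeGainWarning`), raised as :class:`NegativeGainError` with
    ``on_nonpositive='raise'``; never silently ignored.
    """
    if alphas.grid != gains.grid:
        raise ValueError("gain fields and learning distributions on different grids")
    out = GainFieldSet(
        gains.omega_v + alphas.alpha_v * delta_e,
        gains.omega_m + alphas.alpha_m * delta_e,
        gains.omega_cd + alphas.alpha_cd * delta_e,
        gains.grid,
    )
    for name in ("omega_v", "omega_m", "omega_cd"):
        if np.any(getattr(out, name) <= 0.0):
            msg = f"learning update drove {name} to a non-positive value"
            if on_nonpositive == "raise":
                raise NegativeGainError(msg)
            warnings.warn(msg, NegativeGainWarning, stacklevel=2)
    return out


def apply_adaptation_drop(
    gains_end: GainFieldSet, gains_pre: GainFieldSet, kappa: float
) -> GainFieldSet:
    """Decay adaptation by a fraction ``kappa`` toward the pre-adaptation state,
    ``omega_post = omega_end + kappa * (omega_pre - omega_end)`` cellwise."""
    if not (0.0 <= kappa <= 1.0):
        raise ValueError("kappa must lie in [0, 1]")
    if gains_end.grid != gains_pre.grid:
        raise ValueError("gain field sets on different grids")
    return GainFieldSet(
        gains_end.omega_v + kappa * (gains_pre.omega_v - gains_end.omega_v),
        gains_end.omega_m + kappa * (gains_pre.omega_m - gains_end.omega_m),
        gains_end.omega_cd + kappa * (gains_pre.omega_cd - gains_end.omega_cd),
        gains_end.grid,
    )
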