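"""Retinocentric 2D field grid, Gaussian population responses and readouts.

All signals in the model live on a square grid of cell centers spanning
``[-half_extent, +half_extent]`` degrees of visual angle (dva) in both x
(rightward positive) and y (upward positive), with the fovea at the origin.
A :class:`PopulationMap` holds nonnegative activity per cell; the encoded
location is read out as the population vector, i.e. the activity-weighted sum
of cell positions *without* dividing by total mass.  Because the readout is
mass-weighted, multiplicative gain fields change readout length — this is the
mechanism by which the model adapts saccade amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FieldGrid",
    "PopulationMap",
    "PAPER_GRID",
    "TEST_GRID",
    "gaussian_population_response",
    "apply_gain",
    "population_vector",
    "shift_map",
]


@dataclass(frozen=True)
class FieldGrid:
    """Square retinocentric grid of cell centers.

    Parameters
    ----------
    half_extent : float
        The field spans ``[-half_extent, +half_extent]`` dva in x and y.
    step : float
        Cell spacing in dva.  ``half_extent`` must be an integer multiple of
        ``step`` so that the origin (fovea) is a cell center.
    """

    half_extent: float
    step: float

    def __post_init__(self) -> None:
        if self.half_extent <= 0 or self.step <= 0:
            raise ValueError("half_extent and step must be positive")
        ratio = self.half_extent / self.step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "half_extent must be an integer multiple of step so that the "
                "origin is a cell center"
            )

    @property
    def n(self) -> int:
        """Number of cells along each axis."""
        return 2 * int(round(self.half_extent / self.step)) + 1

    @property
    def axis(self) -> np.ndarray:
        """1D array of cell-center coordinates along one axis (dva)."""
        half = int(round(self.half_extent / self.step))
        return np.arange(-half, half + 1, dtype=float) * self.step

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinate arrays ``(X, Y)`` with ``indexing='ij'`` (x first axis)."""
        ax = self.axis
        return np.meshgrid(ax, ax, indexing="ij")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FieldGrid):
            return NotImplemented
        return (
            abs(self.half_extent - other.half_extent) < 1e-12
            and abs(self.step - other.step) < 1e-12
        )

    def __hash__(self) -> int:
        return hash((round(self.half_extent, 12), round(self.step, 12)))


#: Grid used for publication-grade runs (±48 dva at 0.05 dva; ~1921² cells).
PAPER_GRID = FieldGrid(half_extent=48.0, step=0.05)
#: Fast default grid for tests and exploratory runs (±24 dva at 0.25 dva).
TEST_GRID = FieldGrid(half_extent=24.0, step=0.25)


@dataclass
class PopulationMap:
    """Nonnegative activity over a :class:`FieldGrid`.

    ``activity[i, j]`` is the activity of the cell at
    ``(grid.axis[i], grid.axis[j])`` (x index first).
    """

    activity: np.ndarray
    grid: FieldGrid = field(repr=False)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        n = self.grid.n
        if self.activity.shape != (n, n):
            raise ValueError(
                f"activity shape {self.activity.shape} does not match grid ({n}, {n})"
            )
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity must be finite everywhere")

    @property
    def mass(self) -> float:
        """Total activity over the grid."""
        return float(self.activity.sum())

    def copy(self) -> "PopulationMap":
        return PopulationMap(self.activity.copy(), self.grid)


def gaussian_population_response(
    center: np.ndarray,
    grid: FieldGrid,
    eccentricity_fraction: float = 1.0 / 3.0,
    sigma_floor: float = 0.0,
) -> PopulationMap:
    """Normalized isotropic Gaussian population response to a target.

    The Gaussian width scales with target eccentricity,
    ``sigma = max(eccentricity_fraction * |center|, sigma_floor)``, so more
    peripheral targets produce broader but flatter responses.  The map is
    normalized by its sum over the grid (total mass 1).  The pre-saccadic
    input uses ``sigma_floor = 0``; the post-saccadic input uses 0.5 dva to
    keep the response well-defined for foveal targets.
    """
    center = np.asarray(center, dtype=float)
    sigma = max(eccentricity_fraction * float(np.hypot(*center)), sigma_floor)
    if sigma <= 0:
        raise ValueError(
            "Gaussian width is zero (target at the fovea with sigma_floor 0)"
        )
    X, Y = grid.mesh()
    act = np.exp(-(((X - center[0]) ** 2) + ((Y - center[1]) ** 2)) / (2.0 * sigma**2))
    total = act.sum()
    if total <= 0:
        raise ValueError("Gaussian has no mass on the grid (center off-field?)")
    return PopulationMap(act / total, grid)


def apply_gain(pop: PopulationMap, gain: np.ndarray | PopulationMap) -> PopulationMap:
    """Cellwise product of a population map with a multiplicative gain field.

    No renormalization: the gain deliberately changes total mass, and through
    the mass-weighted readout, the encoded vector length.
    """
    if isinstance(gain, PopulationMap):
        if gain.grid != pop.grid:
            raise ValueError("map and gain are defined on different grids")
        gain = gain.activity
    gain = np.asarray(gain, dtype=float)
    if gain.shape != pop.activity.shape:
        raise ValueError("map and gain shapes differ")
    return PopulationMap(pop.activity * gain, pop.grid)


def population_vector(pop: PopulationMap) -> np.ndarray:
    """Activity-weighted sum of cell positions, ``sum_p r(p) p`` (dva 2-vector).

    Deliberately not divided by total mass: a map of mass ``c`` centered at
    ``P`` reads out as ``c * P``.
    """
    ax = pop.grid.axis
    vx = float(pop.activity.sum(axis=1) @ ax)
    vy = float(pop.activity.sum(axis=0) @ ax)
    return np.array([vx, vy])


def shift_map(
    pop: PopulationMap, shift: np.ndarray, direction: str = "forward"
) -> PopulationMap:
    """Uniform coordinate shift of a map with bilinear interpolation.

    ``forward`` returns ``q -> map(q + shift)`` (the map content moves by
    ``-shift``); ``backward`` returns ``q -> map(q - shift)``.  Sample points
    falling outside the field contribute zero, so mass may be lost at the
    boundary.  Up to interpolation error the readout obeys the exact
    change-of-variables identity
    ``pv(backward shift by s) = pv(map) + mass(map) * s``.
    """
    shift = np.asarray(shift, dtype=float)
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    s_idx = shift / pop.grid.step
    if direction == "forward":
        offset = -s_idx
    else:
        offset = s_idx
    out = ndimage.shift(
        pop.activity, offset, order=1, mode="constant", cval=0.0, prefilter=False
    )
    # bilinear weights can produce tiny negative round-off
    np.clip(out, 0.0, None, out=out)
    return PopulationMap(out, pop.grid)
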