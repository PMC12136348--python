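"""Model fitting: balanced weighted-SSE objective and the two-stage estimator.

The observable surfaces are (a) the pre- and post-adaptation per-probe
readouts — the visual estimate V1 against pre-saccadic localizations, the
motor command M against saccade vectors, and the internal saccade estimate
CDV against the behavioral CDV derived from the pre/post-saccadic
localization pair and the saccade vector (``CDV = V1 - V2f + M``) — and
(b) the per-trial saccade vectors at the adaptation target during the
adaptation phase.  Entering the post-saccadic localization channel in CDV
space (rather than as raw localizations re saccade landing) makes the
channel an exact linear recombination of the same per-probe medians while
keeping the comparison free of the response-mass factor that the
prediction-map readout carries; with noiseless self-generated data the
generating parameters are then an exact zero of the objective.  Because the
two surfaces contribute unequal numbers of data points, the objective
balances them:

``SSE_weighted = eta_prepost * SSE_prepost + eta_adapt * SSE_adapt``

with ``eta_prepost = (q_adapt + q_prepost) / q_prepost * 0.6`` and
``eta_adapt = (q_adapt + q_prepost) / q_adapt * 0.4``, where the q's count
scalar residuals (2 coordinates per entry).  Goodness of fit is reported as
residual standard errors ``RSE = sqrt(SSE / (q - 1))`` per surface.

Estimation is two-stage: the three pre-adaptation gain constants are
identified from the pre-adaptation probe data alone (closed-form
initialization, local refinement), then the twelve learning-distribution
parameters and the adaptation drop factor kappa are estimated by
bound-constrained minimization of the weighted SSE from multiple seeded
starts, with the constants held fixed and zero motor noise.

Usage follows the Model/Results convention::

    model = SaccadeAdaptationModel.from_trial_table(table, design)
    res = model.fit(seed=7)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .grid import FieldGrid, TEST_GRID
from .gainfields import LearningParams, ModelParams
from .protocol import ExperimentDesign
from .fastsim import FastAdaptationSimulator, SimulationDiverged
from .behavior import filter_trials, summarize_probes

__all__ = [
    "FitTargets",
    "AdaptationFitResult",
    "SaccadeAdaptationModel",
    "compute_weights",
    "weighted_sse",
    "rse",
    "fit_model",
]

PREPOST_SIGNALS = ("V1", "M", "CDV")

#: Stage-2 parameter order.
STAGE2_NAMES = (
    "phi_v", "phi_m", "phi_cd",
    "sigma_vF", "sigma_mF", "sigma_cdF",
    "sigma_vP", "sigma_mP", "sigma_cdP",
    "sigma_vO", "sigma_mO", "sigma_cdO",
    "kappa",
)


def compute_weights(q_adapt: int, q_prepost: int) -> tuple[float, float]:
    """Balanced objective weights ``(eta_prepost, eta_adapt)``.

    Chosen so that with unit residuals everywhere the weighted SSE equals the
    total number of data points (0.6/0.4 split between the surfaces).
    """
    if q_adapt <= 0 or q_prepost <= 0:
        raise ValueError("both data-point counts must be positive")
    total = q_adapt + q_prepost
    return total / q_prepost * 0.6, total / q_adapt * 0.4


def weighted_sse(
    residuals_prepost: np.ndarray,
    residuals_adapt: np.ndarray,
    weights: tuple[float, float],
) -> tuple[float, float, float]:
    """Plain sums of squared residuals per surface and their weighted sum."""
    res_pp = np.asarray(residuals_prepost, dtype=float).ravel()
    res_a = np.asarray(residuals_adapt, dtype=float).ravel()
    sse_pp = float(np.sum(res_pp**2))
    sse_a = float(np.sum(res_a**2))
    eta_pp, eta_a = weights
    return sse_pp, sse_a, eta_pp * sse_pp + eta_a * sse_a


def rse(sse: float, q: int) -> float:
    """Residual standard error ``sqrt(sse / (q - 1))``."""
    if q < 2:
        raise ValueError("residual standard error requires q >= 2")
    return float(np.sqrt(sse / (q - 1)))


@dataclass
class FitTargets:
    """Per-probe pre/post data and the adaptation-phase saccade trace.

    Arrays may contain NaN for missing cells; those entries are excluded from
    both the residuals and the data-point counts.
    """

    probes: np.ndarray  # (n_probes, 2)
    pre: dict[str, np.ndarray]  # signal -> (n_probes, 2)
    post: dict[str, np.ndarray]
    adapt_M: np.ndarray  # (n_trials, 2)

    @property
    def q_prepost(self) -> int:
        return int(
            sum(np.isfinite(tab[sig]).sum() for tab in (self.pre, self.post)
                for sig in PREPOST_SIGNALS)
        )

    @property
    def q_adapt(self) -> int:
        return int(np.isfinite(self.adapt_M).sum())

    @classmethod
    def from_summary(
        cls,
        summary: pd.DataFrame,
        adapt_trace: np.ndarray,
        design: ExperimentDesign,
    ) -> "FitTargets":
        """Build targets from a probe summary table (see ``summarize_probes``).

        The post-saccadic localization channel is carried as the behavioral
        CDV derived from the three medians, ``CDV = V1 - V2f + M``.
        """
        probes = np.asarray(design.probe_set, dtype=float)
        out = {
            phase: {sig: np.full((len(probes), 2), np.nan) for sig in PREPOST_SIGNALS}
            for phase in ("pre", "post")
        }
        for phase in ("pre", "post"):
            sub = summary[summary["phase"] == phase]
            for i, probe in enumerate(probes):
                match = sub[
                    (np.isclose(sub["probe_x"], probe[0], atol=1e-6))
                    & (np.isclose(sub["probe_y"], probe[1], atol=1e-6))
                ]
                if match.empty:
                    continue
                row = match.iloc[0]
                out[phase]["V1"][i] = (row["V1_x"], row["V1_y"])
                out[phase]["M"][i] = (row["M_x"], row["M_y"])
                out[phase]["CDV"][i] = (
                    row["V1_x"] - row["V2f_x"] + row["M_x"],
                    row["V1_y"] - row["V2f_y"] + row["M_y"],
                )
        adapt_M = np.full((design.n_adapt_trials, 2), np.nan)
        adapt_trace = np.asarray(adapt_trace, dtype=float)
        n = min(len(adapt_trace), design.n_adapt_trials)
        adapt_M[:n] = adapt_trace[:n]
        return cls(probes=probes, pre=out["pre"], post=out["post"], adapt_M=adapt_M)

    @classmethod
    def from_trial_table(
        cls, table: pd.DataFrame, design: ExperimentDesign, prefiltered: bool = False
    ) -> "FitTargets":
        if not prefiltered:
            table, _ = filter_trials(table)
        summary = summarize_probes(table)
        adapt = table[
            (table["phase"] == "adapt") & (table["trial_type"] == "saccade")
        ]
        trace = (
            adapt.groupby("trial_index")[["sacc_x", "sacc_y"]]
            .median()
            .reindex(range(1, design.n_adapt_trials + 1))
            .to_numpy()
        )
        return cls.from_summary(summary, trace, design)


@dataclass
class AdaptationFitResult:
    """Estimates, goodness of fit and optimizer diagnostics."""

    params: ModelParams
    sse_prepost: float
    sse_adapt: float
    sse_weighted: float
    rse_prepost: float
    rse_adapt: float
    q_prepost: int
    q_adapt: int
    weights: tuple[float, float]
    grid: FieldGrid
    seed: int
    n_starts: int
    converged: bool
    start_values: list[float] = field(default_factory=list, repr=False)
    message: str = ""

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(
            sse_prepost=self.sse_prepost,
            sse_adapt=self.sse_adapt,
            sse_weighted=self.sse_weighted,
            rse_prepost=self.rse_prepost,
            rse_adapt=self.rse_adapt,
            q_prepost=self.q_prepost,
            q_adapt=self.q_adapt,
            eta_prepost=self.weights[0],
            eta_adapt=self.weights[1],
            grid_half_extent=self.grid.half_extent,
            grid_step=self.grid.step,
            seed=self.seed,
            n_starts=self.n_starts,
            converged=self.converged,
        )
        return d

    def summary(self) -> str:
        p = self.params.to_dict()
        lines = [
            "Saccadic adaptation gain-field model fit",
            "=" * 46,
            f"grid: +-{self.grid.half_extent:g} dva @ {self.grid.step:g} dva",
            f"data points: q_prepost={self.q_prepost}  q_adapt={self.q_adapt}",
            f"weights: eta_prepost={self.weights[0]:.2f}  eta_adapt={self.weights[1]:.2f}",
            "-" * 46,
        ]
        for name in (
            "omega_vC", "omega_mC", "omega_cdC",
            "phi_v", "phi_m", "phi_cd",
            "sigma_vF", "sigma_mF", "sigma_cdF",
            "sigma_vP", "sigma_mP", "sigma_cdP",
            "sigma_vO", "sigma_mO", "sigma_cdO",
            "kappa",
        ):
            lines.append(f"{name:>12s}  {p[name]: .4f}")
        lines += [
            "-" * 46,
            f"SSE_prepost={self.sse_prepost:.4f}  SSE_adapt={self.sse_adapt:.4f}  "
            f"SSE_weighted={self.sse_weighted:.4f}",
            f"RSE_prepost={self.rse_prepost:.3f} dva  RSE_adapt={self.rse_adapt:.3f} dva",
            f"multi-start: {self.n_starts} starts, seed {self.seed}, "
            f"converged={self.converged}",
        ]
        return "\n".join(lines)


class SaccadeAdaptationModel:
    """Gain-field adaptation model bound to one dataset and design.

    Parameters
    ----------
    targets : FitTargets
        The fitting surfaces (pre/post per-probe readouts and the
        adaptation-phase saccade trace).
    design : ExperimentDesign
        Adaptation target, intra-saccadic step, trial count and probe set.
    grid : FieldGrid
        Field geometry used for all model evaluations during the fit.
    """

    #: bound-constrained search box for stage 2 (sigma bounds additionally
    #: capped by the foveal constraint sigma_xF <= |target|/3)
    PHI_BOUND = 0.05
    SIGMA_BOUNDS = (0.1, 10.0)
    CONST_BOUNDS = (0.5, 1.5)

    def __init__(
        self,
        targets: FitTargets,
        design: ExperimentDesign,
        grid: FieldGrid = TEST_GRID,
    ):
        self.targets = targets
        self.design = design
        self.grid = grid
        self.sim = FastAdaptationSimulator(design, grid)
        self.q_prepost = targets.q_prepost
        self.q_adapt = targets.q_adapt
        self.weights = compute_weights(self.q_adapt, self.q_prepost)
        delta1 = float(np.hypot(*design.adaptation_target))
        lo, hi = self.SIGMA_BOUNDS
        hi_f = min(hi, delta1 / 3.0)
        self._bounds = (
            [(-self.PHI_BOUND, self.PHI_BOUND)] * 3
            + [(lo, hi_f)] * 3
            + [(lo, hi)] * 6
            + [(0.0, 1.0)]
        )

    @classmethod
    def from_trial_table(
        cls,
        table: pd.DataFrame,
        design: ExperimentDesign,
        grid: FieldGrid = TEST_GRID,
    ) -> "SaccadeAdaptationModel":
        return cls(FitTargets.from_trial_table(table, design), design, grid)

    # -- residuals / objective -------------------------------------------------

    def residuals(self, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
        sim = self.sim.run(params)
        res_pp = []
        for phase, model_tab in (("pre", sim.pre), ("post", sim.post)):
            data_tab = getattr(self.targets, phase)
            for sig in PREPOST_SIGNALS:
                diff = model_tab[sig] - data_tab[sig]
                res_pp.append(diff[np.isfinite(diff)])
        res_pp = np.concatenate(res_pp) if res_pp else np.empty(0)
        diff_a = sim.trial_M - self.targets.adapt_M
        res_a = diff_a[np.isfinite(diff_a)]
        return res_pp, res_a

    def evaluate(self, params: ModelParams) -> tuple[float, float, float]:
        """``(SSE_prepost, SSE_adapt, SSE_weighted)`` at a parameter vector."""
        res_pp, res_a = self.residuals(params)
        return weighted_sse(res_pp, res_a, self.weights)

    def objective(self, params: ModelParams) -> float:
        return self.evaluate(params)[2]

    def _make_params(self, constants: np.ndarray, theta: np.ndarray) -> ModelParams:
        kw = dict(zip(STAGE2_NAMES[:-1], theta[:-1]))
        return ModelParams(
            omega_vC=float(constants[0]),
            omega_mC=float(constants[1]),
            omega_cdC=float(constants[2]),
            learning=LearningParams(**kw),
            kappa=float(theta[-1]),
        )

    # -- stage 1: gain constants from the pre-adaptation state ----------------

    def _prepost_sse_constants(self, constants: np.ndarray) -> float:
        """Pre-adaptation SSE; the pre-phase readouts depend only on the
        constants (flat fields, no learning yet)."""
        cv, cm, ccd = constants
        T = np.vstack([self.sim._pv(A) for A in self.sim._probe_maps])
        model = {"V1": cv * T, "M": cv * cm * T, "CDV": cv * cm * ccd * T}
        sse = 0.0
        for sig in PREPOST_SIGNALS:
            diff = model[sig] - self.targets.pre[sig]
            sse += float(np.nansum(diff**2))
        return sse

    def fit_constants(self) -> np.ndarray:
        """Closed-form least squares on the pre-adaptation probe data,
        followed by a local simplex refinement."""
        T = np.vstack([self.sim._pv(A) for A in self.sim._probe_maps])

        def ls_scale(data: np.ndarray) -> float:
            mask = np.isfinite(data).all(axis=1)
            num = float(np.sum(data[mask] * T[mask]))
            den = float(np.sum(T[mask] ** 2))
            return num / den

        cv = ls_scale(self.targets.pre["V1"])
        cvcm = ls_scale(self.targets.pre["M"])
        cm = cvcm / cv
        ccd = ls_scale(self.targets.pre["CDV"]) / (cv * cm)
        x0 = np.clip([cv, cm, ccd], *zip(*[self.CONST_BOUNDS] * 3))
        res = optimize.minimize(
            self._prepost_sse_constants,
            x0,
            method="Nelder-Mead",
            bounds=[self.CONST_BOUNDS] * 3,
            options={"xatol": 1e-6, "fatol": 1e-12},
        )
        return res.x

    # -- stage 2: learning parameters + kappa ----------------------------------

    def _stage2_starts(self, seed: int, n_starts: int) -> np.ndarray:
        delta1 = float(np.hypot(*self.design.adaptation_target))
        heuristic = np.array(
            [0.004, 0.004, -0.002]
            + [min(1.0, delta1 / 3.0)] * 3
            + [3.0] * 3
            + [2.0] * 3
            + [0.3]
        )
        starts = [heuristic]
        if n_starts > 1:
            sampler = qmc.LatinHypercube(d=len(self._bounds), seed=seed)
            lo = np.array([b[0] for b in self._bounds])
            hi = np.array([b[1] for b in self._bounds])
            pts = lo + sampler.random(n_starts - 1) * (hi - lo)
            starts.extend(pts)
        return np.array(starts)

    def fit(
        self,
        seed: int = 0,
        n_starts: int = 8,
        max_nfev: int = 2000,
        xtol: float = 1e-10,
        ftol: float = 1e-12,
    ) -> AdaptationFitResult:
        """Two-stage fit; returns an :class:`AdaptationFitResult`.

        Stage 2 runs a bound-constrained trust-region least-squares solver on
        the weight-scaled residual vector from each of ``n_starts`` seeded
        starting points and keeps the lowest weighted SSE.  ``seed`` controls
        the multi-start sampling (and is recorded).  The objective is
        deterministic (zero motor noise), so identical inputs give identical
        results regardless of data row order.
        """
        constants = self.fit_constants()
        sqrt_w = (np.sqrt(self.weights[0]), np.sqrt(self.weights[1]))
        n_res = self.q_prepost + self.q_adapt

        def resid(theta: np.ndarray) -> np.ndarray:
            try:
                params = self._make_params(constants, theta)
                res_pp, res_a = self.residuals(params)
            except (ValueError, SimulationDiverged):
                return np.full(n_res, 1e6)
            return np.concatenate([sqrt_w[0] * res_pp, sqrt_w[1] * res_a])

        lo = np.array([b[0] for b in self._bounds])
        hi = np.array([b[1] for b in self._bounds])
        # characteristic parameter scales (peak rates ~5e-3, widths ~1 dva)
        x_scale = np.array([0.005] * 3 + [1.0] * 9 + [0.3])
        best = None
        start_values = []
        for x0 in self._stage2_starts(seed, n_starts):
            res = optimize.least_squares(
                resid,
                np.clip(x0, lo, hi),
                bounds=(lo, hi),
                method="trf",
                x_scale=x_scale,
                max_nfev=max_nfev,
                xtol=xtol,
                ftol=ftol,
                gtol=1e-12,
            )
            start_values.append(float(2.0 * res.cost))
            if best is None or res.cost < best.cost:
                best = res

        params = self._make_params(constants, best.x)
        sse_pp, sse_a, sse_w = self.evaluate(params)
        return AdaptationFitResult(
            params=params,
            sse_prepost=sse_pp,
            sse_adapt=sse_a,
            sse_weighted=sse_w,
            rse_prepost=rse(sse_pp, self.q_prepost),
            rse_adapt=rse(sse_a, self.q_adapt),
            q_prepost=self.q_prepost,
            q_adapt=self.q_adapt,
            weights=self.weights,
            grid=self.grid,
            seed=seed,
            n_starts=n_starts,
            converged=bool(best.status > 0),
            start_values=start_values,
            message=str(best.message),
        )


def fit_model(
    targets: FitTargets,
    design: ExperimentDesign,
    grid: FieldGrid = TEST_GRID,
    **fit_kwargs,
) -> AdaptationFitResult:
    """Functional wrapper around :class:`SaccadeAdaptationModel`."""
    return SaccadeAdaptationModel(targets, design, grid).fit(**fit_kwargs)
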