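"""Exact moment-based recursion for the adaptation protocol.

Because the learning rule is additive and the learning distributions are
fixed maps, every gain field stays of the form
``omega_x(n) = omega_xC + alpha_x * S(n)`` with a single scalar state
``S(n) = sum_{k<n} delta_E(k)`` (the cumulative directed amplitude error).
Pre-saccadic readouts are therefore low-order polynomials in ``S`` whose
coefficients are grid moments of the probe response against products of the
learning distributions, computable once per parameter vector:

``V1(S)  = cv*T + S*Uv``                               (degree 1)
``M(S)   = cv*cm*T + S*(cv*Um + cm*Uv) + S^2*Wvm``     (degree 2)
``CDV(S)``                                             (degree 3)

with ``T = sum A p``, ``Ux = sum A alpha_x p``, ``Wxy = sum A alpha_x
alpha_y p`` for the normalized input response ``A``.  Shift readouts use the
exact change-of-variables identities ``Vhat2 = V1 - m1*CDV`` and
``Vhat1 = V2 + m2*CDV`` (the identities the interpolating grid engine obeys
up to bilinear error).  The post-saccadic input response is re-evaluated per
trial on a subwindow covering its support.

This path exists for the fitter, where the objective is evaluated thousands
of times; tests verify it against the reference grid engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import hypot

import numpy as np

from .grid import FieldGrid, TEST_GRID, gaussian_population_response
from .gainfields import ModelParams, build_learning_distributions
from .engine import POST_SACCADIC_SIGMA_FLOOR
from .protocol import ExperimentDesign

__all__ = ["FastAdaptationSimulator", "FastSimResult", "SimulationDiverged"]


class SimulationDiverged(RuntimeError):
    """The trial recursion left the field (runaway positive feedback).

    Raised when the simulated post-saccadic target lands far outside the
    grid; occurs only for parameter vectors in unstable regions of the
    search space."""

#: Half-width of the post-saccadic evaluation window in units of sigma.
_WINDOW_NSIGMA = 8.0


@dataclass
class FastSimResult:
    """Arrays produced by one fast protocol run."""

    trial_V1: np.ndarray  # (n_trials, 2)
    trial_M: np.ndarray
    trial_CDV: np.ndarray
    trial_Vhat2: np.ndarray
    trial_delta_E: np.ndarray  # (n_trials,)
    S: np.ndarray  # cumulative error before each trial, (n_trials,)
    S_end: float
    S_post: float
    pre: dict[str, np.ndarray]  # signal -> (n_probes, 2)
    post: dict[str, np.ndarray]


class FastAdaptationSimulator:
    """Moment-based simulator for one experiment design on one grid.

    Probe input responses are precomputed at construction; :meth:`run` then
    costs milliseconds per parameter vector.  The inner recursion is plain
    scalar arithmetic (the state is one float), so it carries no per-trial
    array overhead.
    """

    def __init__(self, design: ExperimentDesign, grid: FieldGrid = TEST_GRID):
        self.design = design
        self.grid = grid
        self._axis = grid.axis
        self._probe_maps = [
            gaussian_population_response(p, grid).activity for p in design.probe_set
        ]
        self._target_idx = next(
            i
            for i, p in enumerate(design.probe_set)
            if np.allclose(p, design.adaptation_target)
        )

    # -- moments ---------------------------------------------------------------

    def _pv(self, arr: np.ndarray) -> np.ndarray:
        return np.array(
            [arr.sum(axis=1) @ self._axis, arr.sum(axis=0) @ self._axis]
        )

    def _probe_moments(self, alphas) -> list[dict[str, float]]:
        av, am, acd = alphas.alpha_v, alphas.alpha_m, alphas.alpha_cd
        ax = self._axis
        moments = []
        for A in self._probe_maps:
            b_v = A * av
            b_m = A * am
            b_cd = A * acd
            b_vm = b_v * am

            def pv(arr):
                return float(arr.sum(axis=1) @ ax), float(arr.sum(axis=0) @ ax)

            mom: dict[str, float] = {}
            for name, arr in (
                ("T", A), ("Uv", b_v), ("Um", b_m), ("Ucd", b_cd),
                ("Wvm", b_vm), ("Wvcd", b_v * acd), ("Wmcd", b_m * acd),
                ("Wvmcd", b_vm * acd),
            ):
                mom[name + "x"], mom[name + "y"] = pv(arr)
            mom["Uv1"] = float(b_v.sum())
            moments.append(mom)
        return moments

    @staticmethod
    def _readout(
        mom: dict[str, float], cv: float, cm: float, ccd: float, S: float
    ) -> tuple:
        """``(V1, M, CDV, Vhat2, m1)`` as flat floats at cumulative error S."""
        S2 = S * S
        S3 = S2 * S
        V1x = cv * mom["Tx"] + S * mom["Uvx"]
        V1y = cv * mom["Ty"] + S * mom["Uvy"]
        Mx = cv * cm * mom["Tx"] + S * (cv * mom["Umx"] + cm * mom["Uvx"]) + S2 * mom["Wvmx"]
        My = cv * cm * mom["Ty"] + S * (cv * mom["Umy"] + cm * mom["Uvy"]) + S2 * mom["Wvmy"]
        CDVx = (
            cv * cm * ccd * mom["Tx"]
            + S * (cv * cm * mom["Ucdx"] + cv * ccd * mom["Umx"] + cm * ccd * mom["Uvx"])
            + S2 * (cv * mom["Wmcdx"] + cm * mom["Wvcdx"] + ccd * mom["Wvmx"])
            + S3 * mom["Wvmcdx"]
        )
        CDVy = (
            cv * cm * ccd * mom["Ty"]
            + S * (cv * cm * mom["Ucdy"] + cv * ccd * mom["Umy"] + cm * ccd * mom["Uvy"])
            + S2 * (cv * mom["Wmcdy"] + cm * mom["Wvcdy"] + ccd * mom["Wvmy"])
            + S3 * mom["Wvmcdy"]
        )
        m1 = cv + S * mom["Uv1"]
        return (
            V1x, V1y, Mx, My, CDVx, CDVy,
            V1x - m1 * CDVx, V1y - m1 * CDVy, m1,
        )

    # -- post-saccadic window evaluation ---------------------------------------

    def _post_moments(self, p2x: float, p2y: float, alpha_v: np.ndarray):
        """(sum rI2 p, sum rI2 alpha_v p, sum rI2 alpha_v) on a subwindow."""
        sigma = max(hypot(p2x, p2y) / 3.0, POST_SACCADIC_SIGMA_FLOOR)
        step = self.grid.step
        half = self.grid.half_extent
        r = _WINDOW_NSIGMA * sigma
        n = self.grid.n
        i0 = max(int((p2x - r + half) / step), 0)
        i1 = min(int((p2x + r + half) / step) + 2, n)
        j0 = max(int((p2y - r + half) / step), 0)
        j1 = min(int((p2y + r + half) / step) + 2, n)
        ax_x = self._axis[i0:i1]
        ax_y = self._axis[j0:j1]
        inv = 1.0 / (2.0 * sigma * sigma)
        gx = np.exp(-((ax_x - p2x) ** 2) * inv)
        gy = np.exp(-((ax_y - p2y) ** 2) * inv)
        # separable Gaussian: all plain moments factorize
        sx = gx.sum()
        sy = gy.sum()
        tot = sx * sy
        T2x = float((gx @ ax_x) * sy / tot)
        T2y = float(sx * (gy @ ax_y) / tot)
        ga = (gx[:, None] * gy[None, :]) * alpha_v[i0:i1, j0:j1]
        U2x = float((ga.sum(axis=1) @ ax_x) / tot)
        U2y = float((ga.sum(axis=0) @ ax_y) / tot)
        return T2x, T2y, U2x, U2y, float(ga.sum() / tot)

    # -- full protocol ---------------------------------------------------------

    def run(self, params: ModelParams, kappa: float | None = None) -> FastSimResult:
        design = self.design
        alphas = build_learning_distributions(params, design.adaptation_target, self.grid)
        moments = self._probe_moments(alphas)
        mom_t = moments[self._target_idx]
        kappa = kappa if kappa is not None else (
            design.kappa if design.kappa is not None else params.kappa
        )

        n = design.n_adapt_trials
        trial = np.empty((n, 8))
        delta_e = np.empty(n)
        S_arr = np.empty(n)
        cv, cm, ccd = params.omega_vC, params.omega_mC, params.omega_cdC
        p1x, p1y = design.adaptation_target
        psx, psy = design.step
        alpha_v = alphas.alpha_v
        vertical = p1x == 0.0
        S = 0.0
        for k in range(n):
            S_arr[k] = S
            ro = self._readout(mom_t, cv, cm, ccd, S)
            trial[k] = ro[:8]
            mx, my, cdvx, cdvy = ro[2], ro[3], ro[4], ro[5]
            p2x = p1x + psx - mx
            p2y = p1y + psy - my
            if not (abs(p2x) < 4.0 * self.grid.half_extent
                    and abs(p2y) < 4.0 * self.grid.half_extent):
                raise SimulationDiverged(
                    f"post-saccadic target left the field at trial {k + 1}"
                )
            T2x, T2y, U2x, U2y, u2s = self._post_moments(p2x, p2y, alpha_v)
            m2 = cv + S * u2s
            ex = cv * T2x + S * U2x + m2 * cdvx - mx
            ey = cv * T2y + S * U2y + m2 * cdvy - my
            norm = hypot(ex, ey)
            prod = ey * p1y if vertical else ex * p1x
            de = 0.0 if (norm == 0.0 or prod == 0.0) else (norm if prod > 0 else -norm)
            delta_e[k] = de
            S += de

        S_end = S
        S_post = (1.0 - kappa) * S_end

        def probe_table(S_val: float) -> dict[str, np.ndarray]:
            rows = np.array(
                [self._readout(m, cv, cm, ccd, S_val)[:8] for m in moments]
            )
            return {
                "V1": rows[:, 0:2],
                "M": rows[:, 2:4],
                "CDV": rows[:, 4:6],
                "Vhat2": rows[:, 6:8],
            }

        return FastSimResult(
            trial_V1=trial[:, 0:2],
            trial_M=trial[:, 2:4],
            trial_CDV=trial[:, 4:6],
            trial_Vhat2=trial[:, 6:8],
            trial_delta_E=delta_e,
            S=S_arr,
            S_end=S_end,
            S_post=S_post,
            pre=probe_table(0.0),
            post=probe_table(S_post),
        )
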