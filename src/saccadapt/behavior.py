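"""Behavioral trial tables: schema, offline filters, probe summaries, and a
synthetic dataset generator.

A trial table is a tidy :class:`pandas.DataFrame` with one row per trial:

======================  =====================================================
column                  meaning
======================  =====================================================
``session``             session identifier (int)
``phase``               ``pre`` | ``adapt`` | ``post``
``trial_type``          ``saccade`` | ``pre_loc`` | ``post_loc``
``trial_index``         running index within phase (orders the adapt trace)
``probe_x, probe_y``    probe / saccade target position (dva re fixation)
``sacc_x, sacc_y``      primary saccade vector (dva; NaN for pre_loc)
``latency_ms``          saccade latency (ms; NaN for pre_loc)
``loc_x, loc_y``        localization response re fixation (dva; NaN for
                        saccade trials)
``fix_dev``             maximal fixation deviation during the trial (dva)
======================  =====================================================

Missing values are empty (NaN), never zero.  In the pre/post phases, plain
saccade trials go to the adaptation target only; the per-probe saccade
vectors come from the post-saccadic localization trials, which require a
primary saccade to the probe.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grid import FieldGrid, TEST_GRID
from .gainfields import ModelParams
from .protocol import ExperimentDesign, run_adaptation_experiment

__all__ = [
    "TABLE_COLUMNS",
    "TABLE_VERSION",
    "read_trial_table",
    "write_trial_table",
    "filter_trials",
    "summarize_probes",
    "generate_synthetic_dataset",
    "DEFAULT_NOISE_SD",
]

TABLE_VERSION = "saccadapt-trial-table-v1"
TABLE_COLUMNS = [
    "session", "phase", "trial_type", "trial_index",
    "probe_x", "probe_y", "sacc_x", "sacc_y", "latency_ms",
    "loc_x", "loc_y", "fix_dev",
]

LATENCY_WINDOW_MS = (100.0, 400.0)
LANDING_WINDOW_DVA = 5.0  # per-axis window around the saccade target
FIXATION_LIMIT_DVA = 2.0

#: Response-noise defaults (dva SD).  Measurement noise magnitudes are free
#: choices: saccadic endpoint scatter is typically about half a degree and
#: mouse localization of a brief flash about a degree.
DEFAULT_NOISE_SD = {"saccade": 0.5, "pre_loc": 1.0, "post_loc": 1.0}


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    """CSV with a versioned header comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {TABLE_VERSION}\n")
        table.to_csv(fh, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, comment="#")
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    return table


def _valid_saccade(table: pd.DataFrame) -> pd.Series:
    lat_ok = table["latency_ms"].between(*LATENCY_WINDOW_MS)
    land_ok = (
        (table["sacc_x"] - table["probe_x"]).abs() <= LANDING_WINDOW_DVA
    ) & ((table["sacc_y"] - table["probe_y"]).abs() <= LANDING_WINDOW_DVA)
    return lat_ok & land_ok


def filter_trials(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the offline acceptance rules; returns the kept rows and a report.

    Saccades (including the primary saccades of post-saccadic localization
    trials) are accepted with a latency of 100-400 ms and a landing within
    +-5 dva per axis of the trial's saccade target.  Localizations are
    accepted only if fixation was held within +-2 dva; post-saccadic
    localizations additionally require a valid primary saccade.  The filter
    is idempotent.
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")

    report = {
        "n_input": len(table),
        "saccade_invalid": 0,
        "fixation_invalid": 0,
        "post_loc_without_valid_saccade": 0,
    }
    keep = pd.Series(True, index=table.index)

    is_sacc = table["trial_type"] == "saccade"
    is_pre_loc = table["trial_type"] == "pre_loc"
    is_post_loc = table["trial_type"] == "post_loc"
    sacc_ok = _valid_saccade(table)
    fix_ok = table["fix_dev"] <= FIXATION_LIMIT_DVA

    bad = is_sacc & ~sacc_ok
    report["saccade_invalid"] = int(bad.sum())
    keep &= ~bad

    bad = (is_pre_loc | is_post_loc) & ~fix_ok
    report["fixation_invalid"] = int(bad.sum())
    keep &= ~bad

    bad = is_post_loc & fix_ok & ~sacc_ok
    report["post_loc_without_valid_saccade"] = int(bad.sum())
    keep &= ~bad

    kept = table.loc[keep].copy()
    report["n_kept"] = len(kept)
    return kept, report


def _session_summary(table: pd.DataFrame) -> pd.DataFrame:
    pieces = []
    # per-probe saccade vector: adapt phase from saccade trials, pre/post from
    # the primary saccades of post-saccadic localization trials
    for phase in table["phase"].unique():
        sub = table[table["phase"] == phase]
        src = sub[sub["trial_type"] == ("saccade" if phase == "adapt" else "post_loc")]
        m = src.groupby(["probe_x", "probe_y"])[["sacc_x", "sacc_y"]].median()
        m.columns = ["M_x", "M_y"]
        v1 = (
            sub[sub["trial_type"] == "pre_loc"]
            .groupby(["probe_x", "probe_y"])[["loc_x", "loc_y"]]
            .median()
        )
        v1.columns = ["V1_x", "V1_y"]
        v2f = (
            sub[sub["trial_type"] == "post_loc"]
            .groupby(["probe_x", "probe_y"])[["loc_x", "loc_y"]]
            .median()
        )
        v2f.columns = ["V2f_x", "V2f_y"]
        merged = m.join(v1, how="outer").join(v2f, how="outer").reset_index()
        merged.insert(0, "phase", phase)
        pieces.append(merged)
    return pd.concat(pieces, ignore_index=True)


def summarize_probes(table: pd.DataFrame) -> pd.DataFrame:
    """Componentwise per-probe, per-phase medians and the derived CDV.

    Medians are taken per session first and averaged across sessions (the
    even-count median uses the midpoint convention).  CDV is derived from the
    three medians as ``CDV = V1 - V2f + M``.  A probe/phase cell without any
    valid trial stays NaN and is flagged in the ``complete`` column.
    """
    per_session = [
        _session_summary(sub) for _, sub in table.groupby("session")
    ]
    stacked = pd.concat(per_session, ignore_index=True)
    summary = (
        stacked.groupby(["phase", "probe_x", "probe_y"], as_index=False)
        .mean()
    )
    summary["CDV_x"] = summary["V1_x"] - summary["V2f_x"] + summary["M_x"]
    summary["CDV_y"] = summary["V1_y"] - summary["V2f_y"] + summary["M_y"]
    value_cols = ["M_x", "M_y", "V1_x", "V1_y", "V2f_x", "V2f_y"]
    summary["complete"] = summary[value_cols].notna().all(axis=1)
    return summary


def generate_synthetic_dataset(
    true_params: ModelParams,
    design: ExperimentDesign,
    noise_sd: dict[str, float] | float | None = None,
    n_repeats: int = 5,
    seed: int = 0,
    violation_fraction: float = 0.0,
    n_sessions: int = 1,
    grid: FieldGrid = TEST_GRID,
) -> pd.DataFrame:
    """Simulate the full experiment and emit a noisy behavioral trial table.

    Measured quantities are model signals plus iid Gaussian noise: saccade
    vectors scatter around the model's motor command M, pre-saccadic
    localizations around the visual estimate V1, and post-saccadic
    localizations re fixation are constructed as
    ``V2f = V1 - CDV + M + noise`` so that the behavioral identity
    ``CDV = V1 - V2f + M`` inverts the construction exactly in the noiseless
    case.  Latencies and fixation deviations are drawn inside the acceptance
    windows except for an injected ``violation_fraction`` of trials that
    exercise the offline filters.
    """
    if seed is None:
        raise ValueError("a seed is mandatory")
    if noise_sd is None:
        noise = dict(DEFAULT_NOISE_SD)
    elif np.isscalar(noise_sd):
        noise = {k: float(noise_sd) for k in DEFAULT_NOISE_SD}
    else:
        noise = {**DEFAULT_NOISE_SD, **noise_sd}

    rng = np.random.default_rng(seed)
    trace, fields, _ = run_adaptation_experiment(design, true_params, grid)
    adapt_M = np.array([o.M for o in trace.outcomes])
    target = design.adaptation_target

    rows: list[dict] = []

    def draw_latency() -> float:
        if rng.random() < violation_fraction:
            return float(rng.choice([rng.uniform(20, 95), rng.uniform(405, 600)]))
        return float(rng.uniform(150, 350))

    def draw_fix_dev() -> float:
        if rng.random() < violation_fraction:
            return float(rng.uniform(2.05, 4.0))
        return float(rng.uniform(0.0, 1.5))

    def noisy(vec: np.ndarray, sd: float) -> np.ndarray:
        return np.asarray(vec, float) + rng.normal(0.0, sd, size=2)

    for session in range(1, n_sessions + 1):
        for phase, table in (("pre", fields.pre), ("post", fields.post)):
            idx = 0
            target_i = next(
                i for i, p in enumerate(fields.probes) if np.allclose(p, target)
            )
            for rep in range(n_repeats):
                # plain saccade trials (adaptation target only)
                M = noisy(table["M"][target_i], noise["saccade"])
                rows.append(
                    dict(
                        session=session, phase=phase, trial_type="saccade",
                        trial_index=(idx := idx + 1),
                        probe_x=target[0], probe_y=target[1],
                        sacc_x=M[0], sacc_y=M[1], latency_ms=draw_latency(),
                        loc_x=np.nan, loc_y=np.nan, fix_dev=draw_fix_dev(),
                    )
                )
                for i, probe in enumerate(fields.probes):
                    V1 = table["V1"][i]
                    Mi = table["M"][i]
                    CDVi = table["CDV"][i]
                    loc_pre = noisy(V1, noise["pre_loc"])
                    rows.append(
                        dict(
                            session=session, phase=phase, trial_type="pre_loc",
                            trial_index=(idx := idx + 1),
                            probe_x=probe[0], probe_y=probe[1],
                            sacc_x=np.nan, sacc_y=np.nan, latency_ms=np.nan,
                            loc_x=loc_pre[0], loc_y=loc_pre[1],
                            fix_dev=draw_fix_dev(),
                        )
                    )
                    sacc = noisy(Mi, noise["saccade"])
                    v2f = noisy(V1 - CDVi + Mi, noise["post_loc"])
                    rows.append(
                        dict(
                            session=session, phase=phase, trial_type="post_loc",
                            trial_index=(idx := idx + 1),
                            probe_x=probe[0], probe_y=probe[1],
                            sacc_x=sacc[0], sacc_y=sacc[1],
                            latency_ms=draw_latency(),
                            loc_x=v2f[0], loc_y=v2f[1], fix_dev=draw_fix_dev(),
                        )
                    )
        for k in range(design.n_adapt_trials):
            M = noisy(adapt_M[k], noise["saccade"])
            rows.append(
                dict(
                    session=session, phase="adapt", trial_type="saccade",
                    trial_index=k + 1,
                    probe_x=target[0], probe_y=target[1],
                    sacc_x=M[0], sacc_y=M[1], latency_ms=draw_latency(),
                    loc_x=np.nan, loc_y=np.nan, fix_dev=draw_fix_dev(),
                )
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
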