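"""Trial tables: filters, medians, synthetic generation, round trips."""

import numpy as np
import pandas as pd
import pytest

from saccadapt import (
    ExperimentDesign,
    TABLE1_PARAMS,
    compute_cdv_from_behavior,
    filter_trials,
    generate_synthetic_dataset,
    read_trial_table,
    run_adaptation_experiment,
    summarize_probes,
    write_trial_table,
)
from saccadapt.behavior import TABLE_COLUMNS


def make_rows(**overrides):
    base = dict(
        session=1, phase="pre", trial_type="saccade", trial_index=1,
        probe_x=12.0, probe_y=0.0, sacc_x=11.8, sacc_y=0.1, latency_ms=200.0,
        loc_x=np.nan, loc_y=np.nan, fix_dev=0.5,
    )
    base.update(overrides)
    return base


@pytest.fixture(scope="module")
def small_design():
    return ExperimentDesign.standard(n_adapt_trials=25)


@pytest.fixture(scope="module")
def noiseless(small_design, grid):
    table = generate_synthetic_dataset(
        TABLE1_PARAMS, small_design, noise_sd=0.0, n_repeats=3, seed=11, grid=grid
    )
    _, fields, _ = run_adaptation_experiment(small_design, TABLE1_PARAMS, grid)
    return table, fields


class TestFilterTrials:
    def test_latency_window(self):
        rows = [make_rows(latency_ms=l, trial_index=i)
                for i, l in enumerate([90, 150, 250, 410, 300])]
        kept, report = filter_trials(pd.DataFrame(rows))
        assert len(kept) == 3
        assert report["saccade_invalid"] == 2

    def test_landing_window_is_per_axis(self):
        ok = make_rows(sacc_x=12.0 + 4.9, sacc_y=4.9)
        bad = make_rows(sacc_x=12.0 + 5.1, sacc_y=0.0, trial_index=2)
        kept, report = filter_trials(pd.DataFrame([ok, bad]))
        assert len(kept) == 1
        assert kept.iloc[0]["trial_index"] == 1

    def test_fixation_limit_for_localizations(self):
        ok = make_rows(trial_type="pre_loc", sacc_x=np.nan, sacc_y=np.nan,
                       latency_ms=np.nan, loc_x=11.0, loc_y=0.0, fix_dev=1.9)
        bad = make_rows(trial_type="pre_loc", sacc_x=np.nan, sacc_y=np.nan,
                        latency_ms=np.nan, loc_x=11.0, loc_y=0.0, fix_dev=2.5,
                        trial_index=2)
        kept, report = filter_trials(pd.DataFrame([ok, bad]))
        assert len(kept) == 1
        assert report["fixation_invalid"] == 1

    def test_post_loc_requires_valid_primary_saccade(self):
        row = make_rows(trial_type="post_loc", loc_x=9.0, loc_y=0.0,
                        latency_ms=90.0)  # invalid primary saccade
        kept, report = filter_trials(pd.DataFrame([row]))
        assert kept.empty
        assert report["post_loc_without_valid_saccade"] == 1

    def test_idempotent(self, noiseless):
        table, _ = noiseless
        once, _ = filter_trials(table)
        twice, report = filter_trials(once)
        assert len(once) == len(twice)
        assert report["n_input"] == report["n_kept"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing required columns"):
            filter_trials(pd.DataFrame({"phase": ["pre"]}))


class TestSummarizeProbes:
    def test_identical_rows_give_that_row(self):
        rows = [make_rows(trial_type="post_loc", loc_x=9.5, loc_y=0.2)] * 3
        summary = summarize_probes(pd.DataFrame(rows))
        row = summary.iloc[0]
        assert row["V2f_x"] == 9.5 and row["M_x"] == 11.8

    def test_median_is_robust_to_outliers(self):
        rows = [
            make_rows(trial_type="post_loc", loc_x=v, loc_y=0.0, trial_index=i)
            for i, v in enumerate([1.0, 2.0, 100.0])
        ]
        summary = summarize_probes(pd.DataFrame(rows))
        assert summary.iloc[0]["V2f_x"] == 2.0

    def test_median_invariant_to_odd_duplication(self):
        # replicating every row an odd number of times preserves the median
        rows = [
            make_rows(trial_type="post_loc", loc_x=v, loc_y=0.0, trial_index=i)
            for i, v in enumerate([1.0, 2.0, 5.0, 7.0])
        ]
        base = summarize_probes(pd.DataFrame(rows))
        tripled = summarize_probes(pd.DataFrame(rows * 3))
        assert base.iloc[0]["V2f_x"] == tripled.iloc[0]["V2f_x"]

    def test_incomplete_cells_flagged_not_imputed(self):
        rows = [make_rows(trial_type="pre_loc", sacc_x=np.nan, sacc_y=np.nan,
                          latency_ms=np.nan, loc_x=11.0, loc_y=0.0)]
        summary = summarize_probes(pd.DataFrame(rows))
        assert not summary.iloc[0]["complete"]
        assert np.isnan(summary.iloc[0]["M_x"])


class TestSyntheticDataset:
    def test_noiseless_summaries_reproduce_model_signals(self, noiseless):
        table, fields = noiseless
        summary = summarize_probes(table)
        for phase, tab in (("pre", fields.pre), ("post", fields.post)):
            sub = summary[summary["phase"] == phase]
            for i, p in enumerate(fields.probes):
                row = sub[
                    np.isclose(sub["probe_x"], p[0]) & np.isclose(sub["probe_y"], p[1])
                ].iloc[0]
                assert row["M_x"] == pytest.approx(tab["M"][i, 0], abs=1e-12)
                assert row["V1_x"] == pytest.approx(tab["V1"][i, 0], abs=1e-12)

    def test_noiseless_cdv_recovery_is_exact(self, noiseless):
        table, fields = noiseless
        summary = summarize_probes(table)
        for phase, tab in (("pre", fields.pre), ("post", fields.post)):
            sub = summary[summary["phase"] == phase]
            for i, p in enumerate(fields.probes):
                row = sub[
                    np.isclose(sub["probe_x"], p[0]) & np.isclose(sub["probe_y"], p[1])
                ].iloc[0]
                cdv = compute_cdv_from_behavior(
                    (row["V1_x"], row["V1_y"]),
                    (row["V2f_x"], row["V2f_y"]),
                    (row["M_x"], row["M_y"]),
                )
                assert np.abs(cdv - tab["CDV"][i]).max() < 1e-12

    def test_injected_violations_are_deterministic_and_near_rate(
        self, small_design, grid
    ):
        t1 = generate_synthetic_dataset(
            TABLE1_PARAMS, small_design, noise_sd=0.0, n_repeats=2, seed=5,
            violation_fraction=0.2, grid=grid,
        )
        t2 = generate_synthetic_dataset(
            TABLE1_PARAMS, small_design, noise_sd=0.0, n_repeats=2, seed=5,
            violation_fraction=0.2, grid=grid,
        )
        _, r1 = filter_trials(t1)
        _, r2 = filter_trials(t2)
        assert r1 == r2
        removed = r1["n_input"] - r1["n_kept"]
        assert 0.1 < removed / r1["n_input"] < 0.45

    def test_seed_is_mandatory(self, small_design, grid):
        with pytest.raises(ValueError):
            generate_synthetic_dataset(TABLE1_PARAMS, small_design, seed=None, grid=grid)

    def test_adapt_phase_is_saccades_only(self, noiseless):
        table, _ = noiseless
        adapt = table[table["phase"] == "adapt"]
        assert set(adapt["trial_type"]) == {"saccade"}
        assert len(adapt) == 25


class TestCsvRoundTrip:
    def test_write_read_preserves_table(self, noiseless, tmp_path):
        table, _ = noiseless
        path = tmp_path / "trials.csv"
        write_trial_table(table, path)
        assert path.read_text().startswith("# saccadapt-trial-table-v1")
        loaded = read_trial_table(path)
        assert list(loaded.columns) == TABLE_COLUMNS
        pd.testing.assert_frame_equal(
            loaded.reset_index(drop=True), table.reset_index(drop=True),
            check_dtype=False,
        )
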