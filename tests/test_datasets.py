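"""Generator contracts: design arithmetic, determinism, model faithfulness."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from lipidrhythm import (
    KernelParams,
    SimulationConfig,
    make_null_dataset,
    parse_ceramide_name,
    periodic_kernel,
    simulate_dataset,
)
from lipidrhythm.datasets import build_analyte_names


class TestDesignArithmetic:
    def test_clinical_design_row_counts(self):
        """10 subjects x 5 six-hourly samples from 18:00 -> 50 rows/analyte/group."""
        cfg = SimulationConfig(n_subjects_per_group=10, sample_times=(18.0, 6.0, 5),
                               n_analytes=2, missing_rate=0.0, seed=0)
        ds = simulate_dataset(cfg)
        counts = ds.table.groupby(["analyte", "group"], observed=True).size()
        assert (counts == 50).all()
        assert len(ds.table) == 2 * 2 * 50
        assert sorted(ds.table["time_h"].unique()) == [18.0, 24.0, 30.0, 36.0, 42.0]

    def test_missing_cells_flagged_not_dropped(self):
        cfg = SimulationConfig(n_analytes=4, missing_rate=0.3, seed=3)
        ds = simulate_dataset(cfg)
        assert len(ds.table) == 2 * 10 * 5 * 4  # full grid retained
        assert ds.table["value"].isna().any()

    def test_missing_rate_within_binomial_ci(self):
        rate = 0.1
        cfg = SimulationConfig(n_analytes=20, missing_rate=rate, seed=11)
        ds = simulate_dataset(cfg)
        n = len(ds.table)
        observed = ds.table["value"].isna().mean()
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(observed - rate) < 4 * se


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_config):
        a = simulate_dataset(small_config)
        b = simulate_dataset(small_config)
        pd.testing.assert_frame_equal(a.table, b.table)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self, small_config):
        a = simulate_dataset(small_config)
        b = simulate_dataset(replace(small_config, seed=small_config.seed + 1))
        assert not a.table["value"].equals(b.table["value"])


class TestGroundTruth:
    def test_truth_is_side_channel_not_columns(self, small_dataset):
        assert set(small_dataset.table.columns) == {
            "subject", "group", "time_h", "analyte", "value"
        }
        assert {"rhythmic", "acrophase_h", "amplitude"} <= set(small_dataset.truth.columns)

    def test_null_dataset_has_no_rhythmic_analytes(self, small_config):
        ds = make_null_dataset(small_config)
        assert not ds.truth["rhythmic"].any()
        assert (ds.truth["amplitude"] == 0).all()

    def test_cosinor_truth_records_injected_acrophase(self):
        cfg = SimulationConfig(n_analytes=3, acrophases=23.0, missing_rate=0.0,
                               fraction_rhythmic_per_group=(1.0, 1.0), seed=5)
        ds = simulate_dataset(cfg)
        assert (ds.truth["acrophase_h"] == 23.0).all()


class TestAnalyteNaming:
    def test_study_size_roster_is_valid_and_unique(self):
        names = build_analyte_names(116)
        assert len(names) == len(set(names)) == 116
        ceramides = [n for n in names if parse_ceramide_name(n, lenient=True) is not None]
        assert len(ceramides) >= 90  # ceramide-dominated panel
        assert "9-HODE" in names

    def test_roster_matches_dataset(self):
        cfg = SimulationConfig(n_analytes=116, seed=1)
        ds = simulate_dataset(cfg)
        assert ds.table["analyte"].nunique() == 116


class TestStatisticalStructure:
    def test_degenerate_config_gives_iid_noise(self):
        """amplitude=0, subject_dev_sd=0 -> values are i.i.d. N(0, noise_sd^2)."""
        cfg = SimulationConfig(n_subjects_per_group=25, n_analytes=20, amplitude=0.0,
                               subject_dev_sd=0.0, noise_sd=1.0, missing_rate=0.0, seed=13)
        ds = simulate_dataset(cfg)
        v = ds.table["value"].to_numpy()
        n = v.size
        assert abs(v.mean()) < 4 / np.sqrt(n)
        assert abs(v.std(ddof=1) - 1.0) < 4 / np.sqrt(2 * n)

    def test_null_without_subject_dev_is_white_across_time(self):
        """Lag-1 autocorrelation over many replicate traces is ~0."""
        cfg = SimulationConfig(n_subjects_per_group=40, n_analytes=10, subject_dev_sd=0.0,
                               noise_sd=1.0, missing_rate=0.0, seed=17)
        ds = make_null_dataset(cfg)
        wide = ds.table.pivot_table(index=["analyte", "subject"], columns="time_h",
                                    values="value").to_numpy()
        x, y = wide[:, :-1].ravel(), wide[:, 1:].ravel()
        r = np.corrcoef(x, y)[0, 1]
        assert abs(r) < 4 / np.sqrt(x.size)

    def test_gp_mode_shared_covariance_matches_periodic_kernel(self):
        """Empirical covariance of g across draws matches the kernel on the grid."""
        n_draws = 3000
        cfg = SimulationConfig(n_subjects_per_group=1, n_analytes=n_draws, amplitude=1.0,
                               subject_dev_sd=0.0, noise_sd=1e-4, missing_rate=0.0,
                               fraction_rhythmic_per_group=(1.0, 0.0), seed=23,
                               signal_mode="gp")
        ds = simulate_dataset(cfg)
        healthy = ds.table[ds.table["group"] == "healthy"]
        wide = healthy.pivot_table(index="analyte", columns="time_h", values="value").to_numpy()
        emp = np.cov(wide, rowvar=False)
        times = cfg.resolved_sample_times()
        theory = periodic_kernel(times, times, KernelParams(sigma2_p=1.0, ell_p=1.0))
        # entrywise Monte-Carlo SE of a covariance of N(0,1)-scale variables
        se = 3.0 / np.sqrt(n_draws)
        assert np.max(np.abs(emp - theory)) < 3 * se


class TestValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_subjects_per_group", 0),
            ("n_analytes", 0),
            ("fraction_rhythmic_per_group", (1.5, 0.0)),
            ("amplitude", -1.0),
            ("subject_dev_sd", -0.1),
            ("subject_dev_lengthscale", 0.0),
            ("noise_sd", 0.0),
            ("missing_rate", 1.0),
            ("signal_mode", "sine"),
            ("sample_times", (10.0, 5.0, 5.0, 1.0)),  # not increasing
        ],
    )
    def test_invalid_config_names_the_field(self, field, value):
        cfg = replace(SimulationConfig(), **{field: value})
        with pytest.raises(ValueError, match=field.split("_")[0]):
            cfg.validate()

    def test_triple_vs_explicit_times(self):
        triple = SimulationConfig(sample_times=(18.0, 6.0, 5))
        assert list(triple.resolved_sample_times()) == [18.0, 24.0, 30.0, 36.0, 42.0]
        explicit = SimulationConfig(sample_times=(0.0, 6.0, 12.0))
        assert list(explicit.resolved_sample_times()) == [0.0, 6.0, 12.0]
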