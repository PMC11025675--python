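"""Synthetic cohort generator: target structure, sampling, round-trip IO."""

import numpy as np
import pytest

from hofcnet import synthio
from hofcnet.synthio import (
    CohortValidationError,
    GeneratorConfig,
    build_group_covariance,
    generate_cohort,
    nearest_positive_definite,
    read_cohort,
    sample_timeseries,
    write_cohort,
)

SIZES_10 = {"SMN": 2, "DMN": 2, "FPN": 2, "VN": 2, "SN": 2}


def _blocks(sizes):
    labels, partition = synthio.default_partition(sizes)
    out = {}
    for mod in synthio.MODULE_NAMES:
        out[mod] = np.array([i for i, r in enumerate(labels)
                             if partition[r] == mod])
    return out


class TestBuildGroupCovariance:
    def test_baseline_block_structure(self):
        cfg = GeneratorConfig(n_regions=10, r_within=0.4, r_between=0.1,
                              effects=(), module_sizes=SIZES_10)
        cov = build_group_covariance(cfg, "control")
        blocks = _blocks(SIZES_10)
        assert np.allclose(np.diag(cov), 1.0)
        for mod, idx in blocks.items():
            block = cov[np.ix_(idx, idx)]
            off = block[~np.eye(idx.size, dtype=bool)]
            assert np.allclose(off, 0.4)
        assert np.allclose(cov[np.ix_(blocks["SMN"], blocks["DMN"])], 0.1)

    def test_effect_applies_to_named_group_and_block_only(self):
        cfg = GeneratorConfig(n_regions=10, r_within=0.4, r_between=0.1,
                              effects=(("SMN", "DMN", 0.15, "patient"),),
                              module_sizes=SIZES_10)
        pat = build_group_covariance(cfg, "patient")
        ctl = build_group_covariance(cfg, "control")
        blocks = _blocks(SIZES_10)
        smn, dmn = blocks["SMN"], blocks["DMN"]
        assert np.allclose(pat[np.ix_(smn, dmn)], 0.25)
        assert np.allclose(ctl[np.ix_(smn, dmn)], 0.10)
        mask = np.ones((10, 10), dtype=bool)
        mask[np.ix_(smn, dmn)] = False
        mask[np.ix_(dmn, smn)] = False
        assert np.array_equal(pat[mask], ctl[mask])

    def test_delta_out_of_range_rejected_with_block_name(self):
        cfg = GeneratorConfig(n_regions=10, r_within=0.4, r_between=0.1,
                              effects=(("SMN", "DMN", 0.95, "patient"),),
                              module_sizes=SIZES_10)
        with pytest.raises(ValueError, match="SMN-DMN"):
            build_group_covariance(cfg, "patient")

    def test_indefinite_target_repaired_to_pd(self):
        # deliberately indefinite: strong between-block, zero within-block
        cfg = GeneratorConfig(n_regions=10, r_within=0.0, r_between=0.9,
                              effects=(("SMN", "DMN", -0.5, "patient"),),
                              module_sizes=SIZES_10)
        cov = build_group_covariance(cfg, "patient")
        vals = np.linalg.eigvalsh(cov)
        assert vals.min() >= 1e-6 - 1e-12
        assert np.allclose(np.diag(cov), 1.0)

    def test_repair_distance_reported_by_eigen_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 6))
        target = np.clip((a + a.T) / 2, -0.9, 0.9)
        np.fill_diagonal(target, 1.0)
        repaired, dist = nearest_positive_definite(target)
        # independent eigendecomposition oracle for the clamp step
        vals, vecs = np.linalg.eigh(target)
        clamped = (vecs * np.maximum(vals, 1e-6)) @ vecs.T
        d = np.sqrt(np.diag(clamped))
        expected = clamped / np.outer(d, d)
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(repaired, expected, atol=1e-12)
        assert dist == pytest.approx(np.max(np.abs(expected - target)))


class TestSampleTimeseries:
    def test_sample_correlation_converges_to_target(self):
        cfg = GeneratorConfig(n_regions=10, r_within=0.4, r_between=0.1,
                              effects=(), module_sizes=SIZES_10)
        cov = build_group_covariance(cfg, "control")
        ts = sample_timeseries(cov, 20_000, ar_coef=0.0, seed=7)
        sample_corr = np.corrcoef(ts, rowvar=False)
        assert np.max(np.abs(sample_corr - cov)) < 0.03

    def test_specific_entry_recovered_at_large_t(self):
        cov = np.array([[1.0, 0.4], [0.4, 1.0]])
        ts = sample_timeseries(cov, 50_000, ar_coef=0.0, seed=1)
        r = np.corrcoef(ts[:, 0], ts[:, 1])[0, 1]
        assert r == pytest.approx(0.4, abs=0.02)

    def test_lag1_autocorrelation_matches_ar_coefficient(self):
        cov = np.eye(5)
        ts = sample_timeseries(cov, 10_000, ar_coef=0.3, seed=2)
        acs = [np.corrcoef(ts[:-1, j], ts[1:, j])[0, 1] for j in range(5)]
        assert np.mean(acs) == pytest.approx(0.3, abs=0.05)

    def test_same_seed_bitwise_identical(self):
        cov = np.eye(4)
        a = sample_timeseries(cov, 100, 0.2, seed=5)
        b = sample_timeseries(cov, 100, 0.2, seed=5)
        assert np.array_equal(a, b)

    def test_non_pd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="build_group_covariance"):
            sample_timeseries(bad, 50, 0.0, seed=0)


class TestGenerateCohort:
    def test_default_cohort_matches_study_design(self):
        ds = generate_cohort(GeneratorConfig(seed=3))
        assert len(ds.subjects) == 110
        assert ds.n_regions == 90
        assert ds.n_timepoints == 239
        patients = [s for s in ds.subjects if s.group == "patient"]
        assert len(patients) == 60
        pta = np.mean([s.pta_mean for s in patients])
        assert pta == pytest.approx(33.22, abs=2.0)

    def test_pta_mean_is_average_of_ears(self, tiny_cohort):
        for s in tiny_cohort.subjects:
            assert s.pta_mean == pytest.approx((s.pta_left + s.pta_right) / 2)

    def test_miniature_cohort_shapes(self, tiny_cohort, tiny_config):
        assert len(tiny_cohort.subjects) == 8
        assert tiny_cohort.subjects[0].timeseries.shape == (80, 15)
        assert set(tiny_cohort.partition.values()) <= set(synthio.MODULE_NAMES)

    def test_seed_controls_everything(self, tiny_config):
        import dataclasses
        a = generate_cohort(tiny_config)
        b = generate_cohort(tiny_config)
        c = generate_cohort(dataclasses.replace(tiny_config, seed=99))
        assert np.array_equal(a.subjects[0].timeseries, b.subjects[0].timeseries)
        assert not np.array_equal(a.subjects[0].timeseries,
                                  c.subjects[0].timeseries)
        assert [s.subject_id for s in a.subjects] == [s.subject_id
                                                      for s in c.subjects]

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            generate_cohort(GeneratorConfig(n_patient=1))


class TestCohortIO:
    def test_round_trip_reproduces_values(self, tiny_cohort, tmp_path):
        write_cohort(tiny_cohort, tmp_path / "cohort")
        back = read_cohort(tmp_path / "cohort")
        assert back.region_labels == tiny_cohort.region_labels
        assert back.partition == tiny_cohort.partition
        for a, b in zip(tiny_cohort.subjects, back.subjects):
            assert a.subject_id == b.subject_id
            assert np.max(np.abs(a.timeseries - b.timeseries)) < 1e-12
            assert a.age == pytest.approx(b.age, abs=1e-12)

    def test_wrong_column_count_names_subject(self, tiny_cohort, tmp_path):
        import pandas as pd
        write_cohort(tiny_cohort, tmp_path / "cohort")
        bad_id = tiny_cohort.subjects[2].subject_id
        path = tmp_path / "cohort" / "ts" / f"{bad_id}.csv"
        df = pd.read_csv(path)
        df.drop(columns=df.columns[-1]).to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match=bad_id):
            read_cohort(tmp_path / "cohort")

    def test_partition_omitting_region_lists_it(self, tiny_cohort, tmp_path):
        import pandas as pd
        write_cohort(tiny_cohort, tmp_path / "cohort")
        path = tmp_path / "cohort" / "partition.csv"
        pd.read_csv(path).iloc[:-1].to_csv(path, index=False)
        last = tiny_cohort.region_labels[-1]
        with pytest.raises(CohortValidationError, match=last):
            read_cohort(tmp_path / "cohort")

    def test_missing_covariate_named(self, tiny_cohort, tmp_path):
        import pandas as pd
        write_cohort(tiny_cohort, tmp_path / "cohort")
        path = tmp_path / "cohort" / "subjects.csv"
        df = pd.read_csv(path)
        df.loc[0, "age"] = np.nan
        df.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match="age"):
            read_cohort(tmp_path / "cohort")
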