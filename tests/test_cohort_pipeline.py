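from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from vesselrep import T1W_GATED, StudyConfig
from vesselrep.cohort import CohortConfig, simulate_cohort
from vesselrep.exceptions import PairingError
from vesselrep.pipeline import (
    AREA_METRICS,
    INTENSITY_METRICS,
    build_synthetic_rois,
    quantify_cohort,
    run_calibration,
    run_study,
)
from vesselrep.stats import build_comparison_table, build_repeatability_table


class TestSimulateCohort:
    def test_cohort_size_and_layout(self, small_cohort_metrics):
        metrics, truth = small_cohort_metrics
        # 6 subjects x 1 weighting x 2 sequences x 2 repeats
        assert len(metrics) == 24
        assert set(metrics["sequence"]) == {"gated", "ungated"}
        counts = metrics.groupby(["sequence", "repeat"]).size()
        assert (counts == 6).all()

    def test_determinism(self):
        config = CohortConfig(n_subjects=2, weightings=("T1W",), matrix=(96, 96), seed=5)
        _, t1 = simulate_cohort(config)
        _, t2 = simulate_cohort(config)
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_subject_degenerate_variances(self):
        config = CohortConfig(
            n_subjects=1, weightings=("T1W",), matrix=(96, 96),
            lumen_area_cm2_sd=0.0, wall_area_cm2_sd=0.0, mean_rr_ms_sd=0.0,
            sd_rr_ms=0.0, pulsation_amplitude_mm=0.0, seed=1,
        )
        records, truth = simulate_cohort(config)
        ungated = [r for r in records if r.sequence == "ungated"]
        # both ungated repeats share geometry and amplitudes exactly
        assert ungated[0].acq.truth["amplitudes"] == ungated[1].acq.truth["amplitudes"]
        assert (
            ungated[0].acq.truth["lumen_radius_mm"]
            == ungated[1].acq.truth["lumen_radius_mm"]
        )

    def test_ground_truth_areas_match_radii(self, small_cohort_metrics):
        _, truth = small_cohort_metrics
        areas = np.pi * truth["lumen_radius_mm"] ** 2 / 100.0
        assert np.allclose(areas, truth["true_lumen_area_cm2"])


class TestStatsTables:
    def test_comparison_table_shape(self, small_cohort_metrics):
        metrics, _ = small_cohort_metrics
        table = build_comparison_table(metrics, INTENSITY_METRICS + AREA_METRICS)
        assert len(table) == 7
        assert set(table.columns) >= {"gated_median", "ungated_median", "wilcoxon_p"}

    def test_repeatability_table_shape(self, small_cohort_metrics):
        metrics, _ = small_cohort_metrics
        table = build_repeatability_table(
            metrics, ["snr_wall", "lumen_area_cm2"], n_perm=500, seed=0
        )
        assert len(table) == 2
        assert (table["gated_loa_range"] >= 0).all()
        assert ((table["permutation_p"] > 0) & (table["permutation_p"] <= 1)).all()

    def test_single_subject_input_raises(self):
        config = CohortConfig(n_subjects=1, weightings=("T1W",), matrix=(96, 96), seed=3)
        records, _ = simulate_cohort(config)
        metrics = quantify_cohort(records)
        with pytest.raises(PairingError):
            build_comparison_table(metrics, ["snr_wall"])

    def test_scaled_ungated_amplitude_separates_snr(self):
        """An ungated amplitude penalty shows up as gated > ungated SNR."""
        config = CohortConfig(n_subjects=8, weightings=("T2W",), matrix=(96, 96), seed=21)
        records, _ = simulate_cohort(config)  # T2W ungated scale 0.65 by default
        metrics = quantify_cohort(records)
        table = build_comparison_table(metrics, ["snr_wall"])
        row = table.iloc[0]
        assert row["gated_median"] > row["ungated_median"]
        assert row["wilcoxon_p"] < 0.05


@pytest.fixture(scope="module")
def study_config():
    cohort = CohortConfig(n_subjects=6, weightings=("T1W",), matrix=(96, 96))
    return StudyConfig(cohort=cohort, n_perm=500, seed=17)


class TestRunStudy:
    def test_full_run_determinism(self, study_config, tmp_path_factory):
        m1 = run_study(study_config, tmp_path_factory.mktemp("run1"))
        m2 = run_study(study_config, tmp_path_factory.mktemp("run2"))
        assert m1.checksums == m2.checksums
        assert m1.config_hash == m2.config_hash

    def test_outputs_exist(self, study_config, tmp_path):
        run_study(study_config, tmp_path)
        for name in ("metrics.csv", "comparison.csv", "repeatability.csv",
                     "ground_truth.csv", "manifest.json", "config.yaml"):
            assert (tmp_path / name).exists()
        metrics = pd.read_csv(tmp_path / "metrics.csv")
        assert len(metrics) == 24

    def test_config_round_trip(self, study_config):
        doc = study_config.to_dict()
        restored = StudyConfig.from_dict(doc)
        assert restored == study_config
        assert restored.to_dict() == doc


class TestNullCohortCalibration:
    def test_exchangeable_arms_do_not_reject(self):
        """With HRV off and matched protocols the permutation test stays null."""
        ungated_twin = replace(
            T1W_GATED, name="T1W-ungated", gated=False, tr_ms=1000.0, signal_scale=1.0
        )
        rejections = 0
        ps = []
        for i in range(30):
            config = CohortConfig(
                n_subjects=13, weightings=("T1W",), matrix=(96, 96),
                sd_rr_ms=0.0, pulsation_amplitude_mm=0.0, seed=1000 + i,
                protocols={"T1W-gated": T1W_GATED, "T1W-ungated": ungated_twin},
            )
            records, _ = simulate_cohort(config)
            metrics = quantify_cohort(records)
            table = build_repeatability_table(metrics, ["snr_wall"], n_perm=2000, seed=i)
            p = table["permutation_p"].iloc[0]
            ps.append(p)
            rejections += p <= 0.05
        assert rejections <= 5
        assert 0.25 < np.mean(ps) < 0.75


def test_calibration_report_passes():
    report = run_calibration(seed=0, n_replicates=200, n_perm=1000)
    assert report["passed"]["noise_factor_within_2pct"]
    assert report["passed"]["area_error_below_5pct"]
    assert report["passed"]["power_exceeds_size"]
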