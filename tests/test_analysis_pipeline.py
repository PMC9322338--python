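"""Tests for quantification maps, paired statistics and the full study."""

import numpy as np
import pytest

from hp13c import (
    PhantomConfig,
    ROIQuant,
    StudyConfig,
    auc_map,
    crossover_compare,
    generate_subject,
    make_masks,
    quantify_subject,
    roi_auc_snr,
    run_study,
)
from hp13c.analysis_pipeline import report_to_json, tidy_long_table
from hp13c.synthetic_data import ARM_SATURATED, ARM_SPARED
from hp13c.exceptions import InferenceImpossibleError, ValidationError


def _pair(subject, value_spared, value_saturated, metric="bicarbonate"):
    def q(arm, v):
        return ROIQuant(subject_id=subject, arm=arm, region="organ",
                        auc_snr={metric: v})
    return {ARM_SPARED: q(ARM_SPARED, value_spared),
            ARM_SATURATED: q(ARM_SATURATED, value_saturated)}


class TestAUCMap:
    def test_zero_series_gives_zero_map(self):
        cfg = PhantomConfig.brain(noise_sd=0.0, roi_spec=(), kinetics_by_region={})
        series = generate_subject(cfg, ARM_SPARED)
        assert np.all(auc_map(series, "bicarbonate") == 0)

    def test_sum_convention_no_dt_weighting(self):
        cfg = PhantomConfig.brain(noise_sd=0.0)
        series = generate_subject(cfg, ARM_SPARED)
        series.voxels[...] = 0.0
        series.voxels[3, 4, 0, 0, 7] = 2.5
        m = auc_map(series, "pyruvate")
        assert m[3, 4, 0] == 2.5 and m.sum() == 2.5

    def test_noise_free_voxel_auc_equals_summed_signal(self):
        from hp13c import simulate_pools, summed_signal

        cfg = PhantomConfig.brain(noise_sd=0.0)
        series = generate_subject(cfg, ARM_SPARED)
        labels = make_masks(cfg)
        tc = simulate_pools(cfg.kinetics_by_region["brain"],
                            cfg.scheme_for_arm(ARM_SPARED), cfg.input_fn)
        vox = np.argwhere(labels == 1)[0]
        assert auc_map(series, "bicarbonate")[tuple(vox)] == pytest.approx(
            summed_signal(tc, "bicarbonate"), rel=1e-12)


class TestROIAucSNR:
    def test_degenerate_background_flagged_infinite(self):
        auc = np.zeros((4, 4, 1))
        auc[1, 1, 0] = 1.0
        roi = auc > 0
        assert roi_auc_snr(auc, roi, ~roi) == np.inf

    def test_disjointness_enforced(self):
        auc = np.random.default_rng(0).normal(size=(4, 4, 1))
        mask = np.ones_like(auc, dtype=bool)
        with pytest.raises(ValidationError):
            roi_auc_snr(auc, mask, mask)

    def test_pure_noise_snr_centred_on_zero(self):
        rng = np.random.default_rng(1)
        roi = np.zeros((8, 8, 1), dtype=bool)
        roi[2:5, 2:5, 0] = True
        vals = [roi_auc_snr(rng.normal(size=(8, 8, 1)), roi, ~roi)
                for _ in range(200)]
        assert abs(np.mean(vals)) < 3 / np.sqrt(200) * 3

    def test_calibration_brackets_reported_organ_values(self):
        """Default-noise brain datasets put the spared-arm bicarbonate ROI
        AUC-SNR in a band bracketing 5.8 and the saturated arm bracketing
        3.6 (generator calibration, not an in vivo reproduction)."""
        from hp13c import generate_crossover

        cfg = PhantomConfig.brain()
        ds = generate_crossover(cfg, n_subjects=8, seed=11)
        labels = make_masks(cfg)
        roi, bg = labels == 1, labels == 0
        spared = [roi_auc_snr(auc_map(s["series"][ARM_SPARED], "bicarbonate"), roi, bg)
                  for s in ds.subjects]
        sat = [roi_auc_snr(auc_map(s["series"][ARM_SATURATED], "bicarbonate"), roi, bg)
               for s in ds.subjects]
        assert 4.3 < np.mean(spared) < 7.3
        assert 2.2 < np.mean(sat) < 5.0
        assert np.mean(spared) > np.mean(sat)


class TestQuantifySubject:
    @pytest.fixture
    def brain_pair(self):
        from hp13c import generate_crossover

        cfg = PhantomConfig.brain()
        ds = generate_crossover(cfg, n_subjects=2, seed=4)
        labels = make_masks(cfg)
        return ds.subjects[0]["series"], labels == 1, labels == 0

    def test_lactate_only_detectable_in_saturated_arm(self, brain_pair):
        series, roi, bg = brain_pair
        q = quantify_subject(series, roi, bg)
        assert (q[ARM_SATURATED].auc_snr["lactate"]
                > q[ARM_SPARED].auc_snr["lactate"])
        assert abs(q[ARM_SPARED].auc_snr["lactate"]) < 3

    def test_no_lactate_fit_when_never_excited(self, brain_pair):
        series, roi, bg = brain_pair
        q = quantify_subject(series, roi, bg)
        assert q[ARM_SPARED].kPL is None
        assert q[ARM_SATURATED].kPL is None  # 90 deg: fit refused

    def test_noise_free_pair_kpb_direction(self):
        cfg = PhantomConfig.brain(noise_sd=0.0)
        series = {arm: generate_subject(cfg, arm) for arm in (ARM_SPARED, ARM_SATURATED)}
        labels = make_masks(cfg)
        q = quantify_subject(series, labels == 1, labels == 0)
        assert q[ARM_SPARED].kPB > q[ARM_SATURATED].kPB

    def test_missing_arm_rejected(self, brain_pair):
        series, roi, bg = brain_pair
        with pytest.raises(ValidationError):
            quantify_subject({ARM_SPARED: series[ARM_SPARED]}, roi, bg)


class TestCrossoverCompare:
    def test_null_coverage_of_the_paired_ci(self):
        """Under the null (identical arms up to noise) the 95% CI covers
        zero in 95 +/- 3 percent of replicate datasets."""
        rng = np.random.default_rng(12345)
        covered = 0
        n_rep = 500
        for _ in range(n_rep):
            quants = [_pair(f"S{i}", rng.normal(), rng.normal()) for i in range(8)]
            res = crossover_compare(quants, "bicarbonate_auc_snr")
            covered += res.ci_low <= 0 <= res.ci_high
        assert covered / n_rep == pytest.approx(0.95, abs=0.03)

    def test_constant_shift_recovered_exactly(self):
        quants = [_pair(f"S{i}", 5.0 + 0.7, 5.0) for i in range(6)]
        res = crossover_compare(quants, "bicarbonate_auc_snr")
        assert res.mean_diff == pytest.approx(0.7)
        assert res.degenerate and res.ci_low == res.ci_high == res.mean_diff

    def test_exclusions_counted_not_dropped(self):
        quants = [_pair(f"S{i}", 5.0 + i * 0.1, 4.0) for i in range(5)]
        quants.append(_pair("S5", np.nan, 4.0))
        res = crossover_compare(quants, "bicarbonate_auc_snr")
        assert res.n_pairs == 5 and res.n_excluded == 1

    def test_too_few_pairs_raises(self):
        quants = [_pair("S0", 1.0, 2.0), _pair("S1", np.nan, 2.0)]
        with pytest.raises(InferenceImpossibleError):
            crossover_compare(quants, "bicarbonate_auc_snr")


@pytest.fixture(scope="module")
def brain_report():
    return run_study(StudyConfig(protocol="brain", n_subjects=8, seed=11))


@pytest.fixture(scope="module")
def body_report():
    return run_study(StudyConfig(protocol="body", n_subjects=5, seed=11))


class TestRunStudy:
    def test_deterministic_given_seed(self, brain_report):
        again = run_study(StudyConfig(protocol="brain", n_subjects=8, seed=11))
        assert report_to_json(brain_report) == report_to_json(again)

    def test_brain_bicarbonate_effect_detected(self, brain_report):
        res = brain_report["comparisons"]["brain"]["bicarbonate_auc_snr"]
        assert res["mean_diff"] > 0 and res["ci_low"] > 0

    def test_brain_ttp_shows_no_delivery_effect(self, brain_report):
        res = brain_report["comparisons"]["brain"]["ttp_s"]
        assert res["ci_low"] <= 0 <= res["ci_high"]

    def test_body_bicarbonate_null_in_every_organ(self, body_report):
        for organ in ("heart", "kidney", "liver"):
            res = body_report["comparisons"][organ]["bicarbonate_auc_snr"]
            assert res["ci_low"] <= 0 <= res["ci_high"]

    def test_exclusion_bookkeeping_adds_up(self, brain_report):
        for metrics in brain_report["comparisons"].values():
            for res in metrics.values():
                if "n_pairs" in res:
                    assert res["n_pairs"] + res["n_excluded"] == 8

    def test_ground_truth_echoed(self, brain_report):
        gt = brain_report["ground_truth"]
        assert gt["kinetics_by_region"]["brain"]["kLB"] == 0.001
        assert len(gt["effects"]) == 8

    def test_subject_rows_cover_all_arms_and_regions(self):
        report = run_study(StudyConfig(protocol="brain", n_subjects=2, seed=1))
        assert len(report["subjects"]) == 2 * 2  # subjects x arms x one region


def test_tidy_long_table_is_one_row_per_arm():
    quants = {"organ": [_pair("S0", 5.0, 4.0), _pair("S1", 6.0, 4.5)]}
    df = tidy_long_table(quants)
    assert len(df) == 4
    assert set(df["arm"]) == {ARM_SPARED, ARM_SATURATED}
    assert "bicarbonate_auc_snr" in df.columns
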