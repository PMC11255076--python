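"""Decomposition pipeline: gain fitting, correction, onset, LTF fit, bookkeeping."""

import numpy as np
import pytest

import ventltf as v
from ventltf.decompose import (
    augmentation_estimate,
    detect_onset,
    extrapolate,
    fit_chemo_gains,
    fit_ltf,
    neural_component,
    rebaseline,
)

from conftest import recovery_series

TRUTH = v.CanonicalParams(wn=0.375, zeta=0.7, A=0.0, B=9.0, baseline=7.6, onset_delay=2.0)


class TestFitChemoGains:
    def test_noiseless_pure_chemoreflex_recovers_true_gains(self, noiseless_config):
        """With the exercise drive off, the 40 W fit must recover the
        generator's gains essentially exactly (self-consistency)."""
        cfg = noiseless_config.with_(
            drive_amplitude_lpm={"rest": 0.0, "w40": 0.0, "light45": 0.0, "heavy80": 0.0}
        )
        tr = v.generate_subject(cfg, v.CO2_3PCT, 1)
        fit = fit_chemo_gains(tr.ve_lpm, tr.petco2_mmhg, tr.time_min, tr.segments)
        assert fit.identifiable and fit.converged
        assert fit.Gc == pytest.approx(cfg.chemo_truth.Gc, rel=0.01)
        assert fit.Gp == pytest.approx(cfg.chemo_truth.Gp, rel=0.01)
        assert fit.residual_sd < 1e-6

    def test_flat_petco2_flagged_unidentifiable(self):
        grid = v.build_protocol(v.default_protocol())
        rng = np.random.default_rng(0)
        ve = 10 + rng.normal(0, 1.0, len(grid.time_min))
        pet = np.full(len(grid.time_min), 40.0)
        fit = fit_chemo_gains(ve, pet, grid.time_min, grid.labels)
        assert not fit.identifiable
        assert (fit.Gc, fit.Gp) == (0.0, 0.0)
        fit_idx = grid.labels == "w40_1"
        dve = ve - ve[np.flatnonzero(fit_idx)[0]]
        assert fit.residual_sd == pytest.approx(np.std(dve[fit_idx], ddof=1))

    def test_air_condition_flagged(self):
        traces, group = v.generate_group(v.GeneratorConfig(seed=3), v.AIR)
        fit = fit_chemo_gains(group.ve_lpm, group.petco2_mmhg, group.time_min, group.segments)
        assert not fit.identifiable

    def test_group_average_residual_sd_below_printed_order(self):
        """Group averaging n=7 shrinks the 1.7 L/min per-sample noise; the
        residual SD must stay below the study's printed 1.73 group value."""
        sds = []
        for seed in range(5):
            traces, group = v.generate_group(v.GeneratorConfig(seed=seed))
            fit = fit_chemo_gains(
                group.ve_lpm, group.petco2_mmhg, group.time_min, group.segments
            )
            sds.append(fit.residual_sd)
        assert np.mean(sds) < 1.73


class TestNeuralComponent:
    def test_perfect_prediction_gives_zero_series(self, noiseless_config):
        cfg = noiseless_config.with_(
            drive_amplitude_lpm={"rest": 0.0, "w40": 0.0, "light45": 0.0, "heavy80": 0.0},
            ltf_truth=v.CanonicalParams(wn=0.375, zeta=0.7, B=0.0, onset_delay=2.0),
        )
        tr = v.generate_subject(cfg, v.CO2_3PCT, 1)
        fit = fit_chemo_gains(tr.ve_lpm, tr.petco2_mmhg, tr.time_min, tr.segments)
        neural = neural_component(tr.ve_lpm, fit, tr.petco2_mmhg)
        assert np.allclose(neural, 0.0, atol=1e-6)

    def test_correction_leaves_drive_plus_ltf(self, noiseless_config):
        """With true gains recovered, the corrected series equals the stored
        exercise-drive + LTF components exactly."""
        cfg = noiseless_config.with_(
            drive_amplitude_lpm={"rest": 0.0, "w40": 0.0, "light45": 0.0, "heavy80": 0.0}
        )
        tr = v.generate_subject(cfg, v.CO2_3PCT, 1)
        fit = fit_chemo_gains(tr.ve_lpm, tr.petco2_mmhg, tr.time_min, tr.segments)
        neural = neural_component(tr.ve_lpm, fit, tr.petco2_mmhg)
        expected = tr.components["drive"] + tr.components["ltf"]
        assert np.allclose(neural, expected, atol=1e-6)

    def test_grid_mismatch_rejected(self, noiseless_config):
        tr = v.generate_subject(noiseless_config, v.CO2_3PCT, 1)
        fit = fit_chemo_gains(tr.ve_lpm, tr.petco2_mmhg, tr.time_min, tr.segments)
        with pytest.raises(ValueError):
            neural_component(tr.ve_lpm[:-1], fit, tr.petco2_mmhg[:-1])


class TestRebaseline:
    def test_reference_at_start_zeroes_start(self):
        t = np.arange(0, 5, 0.5)
        y = np.sin(t) + 3
        out = rebaseline(y, t, 0.0)
        assert out[0] == 0.0

    def test_constant_series_becomes_zero(self):
        t = np.arange(0, 5, 0.5)
        assert np.all(rebaseline(np.full_like(t, 7.7), t, 2.0) == 0.0)

    def test_linear_ramp_shifts_by_reference_value(self):
        t = np.arange(0, 5, 0.5)
        assert np.allclose(rebaseline(t.copy(), t, 2.0), t - 2.0)

    def test_off_grid_reference_rejected(self):
        t = np.arange(0, 5, 0.5)
        with pytest.raises(ValueError):
            rebaseline(t.copy(), t, 0.3)


class TestDetectOnset:
    def test_noiseless_rise_detected_near_true_delay(self):
        y, t, segs = recovery_series(
            v.CanonicalParams(wn=0.375, zeta=0.7, B=9.0, baseline=0.0, onset_delay=2.0)
        )
        onset = detect_onset(y, t, segs, noise_sd=0.05)
        assert onset is not None and 2.0 <= onset <= 2.5

    def test_single_sample_spike_not_an_onset(self):
        grid = v.build_protocol(v.default_protocol())
        y = np.zeros(len(grid.time_min))
        y[grid.segment_index("w40_2")[8]] = 10.0
        assert detect_onset(y, grid.time_min, grid.labels, noise_sd=0.5) is None

    def test_flat_noisy_series_rarely_triggers(self):
        grid = v.build_protocol(v.default_protocol())
        hits = 0
        n = 200
        for seed in range(n):
            y = np.random.default_rng(seed).normal(0.0, 0.64, len(grid.time_min))
            if detect_onset(y, grid.time_min, grid.labels, noise_sd=0.64) is not None:
                hits += 1
        assert hits / n <= 0.05

    def test_short_recovery_segment_rejected(self):
        spec = v.ProtocolSpec(
            segments=(v.Segment("a", 5.0, "rest"), v.Segment("w40_2", 1.0, "w40"))
        )
        grid = v.build_protocol(spec)
        with pytest.raises(ValueError):
            detect_onset(np.zeros(len(grid.time_min)), grid.time_min, grid.labels, noise_sd=1.0)


class TestFitLTF:
    def test_noiseless_free_fit_recovers_all_parameters(self):
        y, t, segs = recovery_series(TRUTH)
        fit = fit_ltf(y, t, segs, onset=2.5)
        p = fit.params
        assert p.wn == pytest.approx(TRUTH.wn, rel=1e-3)
        assert p.zeta == pytest.approx(TRUTH.zeta, rel=1e-3)
        assert p.B == pytest.approx(TRUTH.B, rel=1e-3)
        assert p.baseline == pytest.approx(TRUTH.baseline, rel=1e-3)
        assert p.onset_delay == pytest.approx(TRUTH.onset_delay, rel=1e-3)

    def test_flat_series_fits_zero_amplitude(self):
        grid = v.build_protocol(v.default_protocol())
        y = np.full(len(grid.time_min), 3.0)
        fit = fit_ltf(y, grid.time_min, grid.labels, onset=2.0, fix_wn=0.375, fix_zeta=0.7)
        assert fit.params.B == pytest.approx(0.0, abs=1e-4)
        assert fit.params.baseline == pytest.approx(3.0, abs=1e-4)

    def test_amplitude_recovery_on_noisy_group_averages(self):
        """Pipeline-default fit (published dynamics held fixed) keeps the
        amplitude within a couple of L/min of the generator truth."""
        errs = []
        for seed in range(1, 11):
            traces, group = v.generate_group(v.GeneratorConfig(seed=seed))
            res = v.run_pipeline(traces, group)
            errs.append(res.ltf.params.B - 9.0)
        assert abs(np.mean(errs)) < 2.0

    def test_too_short_window_rejected(self):
        spec = v.ProtocolSpec(
            segments=(v.Segment("a", 5.0, "rest"), v.Segment("w40_2", 2.0, "w40"))
        )
        grid = v.build_protocol(spec)
        with pytest.raises(ValueError):
            fit_ltf(np.zeros(len(grid.time_min)), grid.time_min, grid.labels)


class TestExtrapolateAndEstimate:
    def test_extrapolation_asymptotes(self):
        fit = fit_ltf(*recovery_series(TRUTH), onset=2.0)
        ex = extrapolate(fit, horizon_min=60.0)
        assert ex.asymptote_above_initial_lpm == pytest.approx(9.0, abs=1e-2)
        assert ex.asymptote_above_control_lpm == pytest.approx(16.6, abs=1e-2)
        assert ex.value_lpm[-1] == pytest.approx(ex.asymptote_above_control_lpm, abs=1e-3)

    def test_zero_amplitude_extrapolates_flat(self):
        grid = v.build_protocol(v.default_protocol())
        fit = fit_ltf(
            np.full(len(grid.time_min), 2.0),
            grid.time_min,
            grid.labels,
            fix_wn=0.375,
            fix_zeta=0.7,
        )
        ex = extrapolate(fit)
        assert np.allclose(ex.value_lpm, ex.value_lpm[0], atol=1e-3)

    def test_variance_combination_matches_printed_arithmetic(self):
        rng = np.random.default_rng(0)
        finals = 16.6 + 6.32 * rng.standard_normal(7)
        est = augmentation_estimate(finals, fit_sd=1.73)
        assert est.combined_sd_lpm == pytest.approx(
            np.sqrt(np.var(finals, ddof=1) + 1.73**2)
        )
        assert est.se_lpm == pytest.approx(est.combined_sd_lpm / np.sqrt(7))

    def test_zero_fit_sd_keeps_group_sd(self):
        est = augmentation_estimate([10.0, 12.0, 14.0], fit_sd=0.0)
        assert est.combined_sd_lpm == pytest.approx(est.group_sd_lpm)

    def test_equal_finals_give_zero_se(self):
        est = augmentation_estimate([5.0, 5.0, 5.0], fit_sd=0.0)
        assert est.estimate_lpm == 5.0 and est.se_lpm == 0.0

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            augmentation_estimate([5.0], fit_sd=1.0)


class TestPipelineInvariants:
    def test_rebaseline_commutes_with_fit_offset(self):
        """Rebaselining before the fit only shifts the fitted baseline."""
        y, t, segs = recovery_series(TRUTH)
        shifted = y + 4.0
        f1 = fit_ltf(y, t, segs, onset=2.0, fix_wn=0.375, fix_zeta=0.7, fix_onset=2.0)
        f2 = fit_ltf(shifted, t, segs, onset=2.0, fix_wn=0.375, fix_zeta=0.7, fix_onset=2.0)
        assert f2.params.B == pytest.approx(f1.params.B, abs=1e-6)
        assert f2.params.baseline - f1.params.baseline == pytest.approx(4.0, abs=1e-6)

    def test_end_to_end_recovery_of_final_augmentation(self):
        """Over 20 synthetic groups the mean recovered asymptote above
        control must lie within one printed SE (2.48) of the truth 16.6."""
        finals = []
        for seed in range(1, 21):
            traces, group = v.generate_group(v.GeneratorConfig(seed=seed))
            res = v.run_pipeline(traces, group)
            finals.append(res.final_augmentation_lpm)
        assert abs(np.mean(finals) - 16.6) < 2.48

    def test_pipeline_reports_finite_estimates_and_diagnostics(self, default_group):
        traces, group = default_group
        res = v.run_pipeline(traces, group)
        assert np.isfinite(res.final_augmentation_lpm)
        assert np.isfinite(res.final_augmentation_se_lpm)
        assert res.augmentation.p_value < 0.001  # strong augmentation at defaults
        assert set(res.diagnostics["onset_multiplier_sensitivity_min"]) == {1.5, 2.0, 2.5, 3.0}
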