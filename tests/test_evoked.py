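"""Preprocessing operators, GLM, ROI rules, gas summary, evoked measures."""

import numpy as np
import pytest

from vecmro.davis import compute_delta_cmro2
from vecmro.evoked import (
    CalibrationFailure,
    DualEchoSeries,
    EmptyROIError,
    GasProtocol,
    TaskDesign,
    bold_pair_average,
    boxcar_regressor,
    despike,
    evoked_measures,
    functional_roi,
    gas_roi_and_summary,
    glm_percent_change,
    grey_matter_mask,
    highpass,
    pair_average_regressor,
    process_participant,
    smooth_gaussian,
    surround_regressor,
    surround_subtract,
)
from vecmro.synth import make_gas_run, make_task_design, make_task_run


def _pair_amplitude(x, f, tr):
    t = np.arange(x.size) * tr
    design = np.stack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t), np.ones_like(t)], 1)
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(np.hypot(beta[0], beta[1]))


class TestDespike:
    def test_constant_series_unchanged(self):
        x = np.full(20, 7.0)
        assert np.array_equal(despike(x), x)

    def test_isolated_spike_replaced_by_neighbor_mean(self):
        out = despike(np.array([100.0, 100, 500, 100, 100]))
        assert np.array_equal(out, [100.0, 100, 100, 100, 100])

    def test_non_spike_points_pass_through(self):
        """Only points beyond k robust SDs of the running median change,
        and they become their neighbour mean (independent re-derivation)."""
        rng = np.random.default_rng(4)
        x = 100 + rng.normal(0.0, 1.0, 200)
        x[[30, 90, 150]] += [15.0, -12.0, 20.0]
        med = np.array(
            [np.median(x[max(i - 1, 0) : i + 2]) if 0 < i < 199 else np.mean(x[max(i - 1, 0) : i + 2]) for i in range(200)]
        )
        resid = x - med
        flagged = np.abs(resid) > 3 * 1.4826 * np.median(np.abs(resid))
        out = despike(x)
        assert np.array_equal(out[~flagged], x[~flagged])
        inner = flagged.copy()
        inner[[0, -1]] = False
        idx = np.flatnonzero(inner)
        assert np.allclose(out[idx], 0.5 * (x[idx - 1] + x[idx + 1]))
        assert flagged[[30, 90, 150]].all()

    def test_clean_boxcar_and_alternating_pass_through(self):
        boxcar = np.repeat([100.0, 102, 100, 102, 100], 15)
        assert np.array_equal(despike(boxcar), boxcar)
        alt = np.tile([1000.0, 990.0], 30)  # control/label alternation
        assert np.array_equal(despike(alt), alt)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            despike(np.array([1.0, 2.0]))


class TestSurroundSubtract:
    def test_constant_control_label(self):
        c, l = 1000.0, 990.0
        x = np.tile([l, c], 10)  # label first
        out = surround_subtract(x, label_first=True)
        assert np.allclose(out, c - l)

    def test_zero_perfusion(self):
        x = np.full(12, 500.0)
        assert np.allclose(surround_subtract(x), 0.0)

    def test_linear_drift_cancels_interior(self):
        t = np.arange(20, dtype=float)
        drift = 3.0 * t
        d = 10.0
        x = drift.copy()
        x[0::2] -= d  # labels
        out = surround_subtract(x, label_first=True)
        assert np.allclose(out[1:-1], d)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            surround_subtract(np.array([1.0, 2.0]))


class TestPairAverage:
    def test_constant(self):
        x = np.full(10, 5.0)
        assert np.array_equal(bold_pair_average(x), x)

    def test_alternating(self):
        x = np.tile([2.0, 8.0], 6)
        out = bold_pair_average(x)
        assert np.allclose(out[:-1], 5.0)

    def test_ramp_midpoints(self):
        x = np.arange(10.0)
        out = bold_pair_average(x)
        assert np.allclose(out[:-1], x[:-1] + 0.5)
        assert out[-1] == x[-1]


class TestSmoothing:
    def test_zero_fwhm_identity(self):
        rng = np.random.default_rng(0)
        vol = rng.random((6, 6, 3))
        assert np.array_equal(smooth_gaussian(vol, 0.0), vol)

    def test_constant_volume_unchanged(self):
        vol = np.full((8, 8, 4), 3.3)
        assert np.allclose(smooth_gaussian(vol, 8.0), 3.3)

    def test_kernel_mass_preserved_on_delta(self):
        vol = np.zeros((21, 21, 11))
        vol[10, 10, 5] = 1.0
        out = smooth_gaussian(vol, 6.0, voxel_size_mm=(2.0, 2.0, 2.0))
        assert out.sum() == pytest.approx(1.0, abs=1e-6)


class TestHighpass:
    TR = 4.0
    N = 150

    def _sine(self, f, phase=0.7):
        t = np.arange(self.N) * self.TR
        return np.sin(2 * np.pi * f * t + phase)

    def test_slow_drift_strongly_attenuated(self):
        s = self._sine(0.001)
        out = highpass(s, 0.0039, self.TR)
        ratio = _pair_amplitude(out, 0.001, self.TR) / _pair_amplitude(s, 0.001, self.TR)
        assert ratio <= 0.1  # >= 10x reduction

    @pytest.mark.parametrize("f", [0.0106, 0.02])
    def test_task_band_passes(self, f):
        s = self._sine(f)
        out = highpass(s, 0.0039, self.TR)
        ratio = _pair_amplitude(out, f, self.TR) / _pair_amplitude(s, f, self.TR)
        assert ratio >= 0.95  # attenuation < 5 %

    def test_constant_preserved_exactly(self):
        c = np.full(self.N, 123.4)
        assert np.allclose(highpass(c, 0.0039, self.TR), c, atol=1e-10)

    def test_mean_preserved(self):
        rng = np.random.default_rng(1)
        x = 50 + rng.normal(0, 1, self.N)
        assert highpass(x, 0.0039, self.TR).mean() == pytest.approx(x.mean())

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass(np.ones(50), 0.2, self.TR)


class TestGlm:
    def test_noiseless_two_level_fit(self):
        design = TaskDesign(block_onsets=[40.0, 160.0], block_duration=60.0, total_duration=280.0)
        u = boxcar_regressor(design, 70, 4.0)
        series = 100.0 + 2.0 * u
        pct, t = glm_percent_change(series, u)
        assert pct == pytest.approx(2.0, abs=1e-10)
        assert t > 1e6  # zero-residual fit: t is numerically unbounded

    def test_constant_series_zero_effect(self):
        u = np.zeros(50)
        u[10:20] = 1.0
        pct, t = glm_percent_change(np.full(50, 100.0), u)
        assert pct == pytest.approx(0.0, abs=1e-12)
        assert t == 0.0

    def test_noisy_recovery_within_half_percent(self):
        """True +5% at contrast SNR 20: mean estimate within +/-0.5 over 100 seeds."""
        design = make_task_design(seed=2)
        n = int(design.total_duration / 4.0)
        u = boxcar_regressor(design, n, 4.0)
        ests = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            series = 100.0 * (1 + 0.05 * u) + rng.normal(0, 100.0 * 0.05 / 20, n)
            ests.append(glm_percent_change(series, u)[0])
        assert np.mean(ests) == pytest.approx(5.0, abs=0.5)

    def test_zero_variance_regressor_rejected(self):
        with pytest.raises(ValueError):
            glm_percent_change(np.ones(20), np.ones(20))


class TestRois:
    def test_gm_threshold_inclusive(self):
        pve = np.array([[[0.80, 0.79, 1.0, 0.0]]])
        assert np.array_equal(grey_matter_mask(pve)[0, 0], [True, False, True, False])
        assert not grey_matter_mask(np.zeros((2, 2, 2))).any()

    def test_constructed_overlap_size(self):
        """Top-50 sets of two maps sharing exactly 20 voxels -> ROI of 20."""
        mask = np.ones((10, 10, 10), bool)
        t_bold = np.arange(1000, dtype=float)  # top 50 = indices 950..999
        t_cbf = np.arange(1000, dtype=float) / 10.0
        t_cbf[950:970] = 2000 + np.arange(20)  # 20 shared top voxels
        t_cbf[:30] = 3000 + np.arange(30)  # 30 top-CBF voxels outside top-BOLD
        roi = functional_roi(
            t_bold.reshape(10, 10, 10), t_cbf.reshape(10, 10, 10), mask, 0.05
        )
        assert roi.sum() == 20

    def test_identical_maps_self_overlap(self):
        vals = np.arange(1000, dtype=float).reshape(10, 10, 10)
        roi = functional_roi(vals, vals, np.ones(vals.shape, bool), 0.05)
        assert roi.sum() == int(np.ceil(0.05 * 1000))

    def test_disjoint_top_sets_raise(self):
        vals = np.arange(1000, dtype=float).reshape(10, 10, 10)
        with pytest.raises(EmptyROIError):
            functional_roi(vals, -vals, np.ones(vals.shape, bool), 0.05)

    def test_roi_is_subset_of_mask(self):
        rng = np.random.default_rng(9)
        mask = rng.random((8, 8, 8)) > 0.4
        roi = functional_roi(rng.random((8, 8, 8)), rng.random((8, 8, 8)), mask, 0.15)
        assert not (roi & ~mask).any()


class TestGasSummary:
    def test_noiseless_m_recovery(self):
        gas, truth = make_gas_run(m=0.05, delta_cbf_hc=1.0, seed=0)
        summary = gas_roi_and_summary(gas, np.ones(gas.perfusion.shape[:3], bool))
        assert summary.m == pytest.approx(0.05, abs=1e-6)
        assert summary.top_fraction_used == 0.15

    def test_printed_hc_mean_m_recovery(self):
        gas, _ = make_gas_run(m=0.0511, delta_cbf_hc=1.469, seed=1)
        summary = gas_roi_and_summary(gas, np.ones(gas.perfusion.shape[:3], bool))
        assert summary.m_percent == pytest.approx(5.11, abs=1e-4)

    def test_transition_window_discarded(self):
        gas, _ = make_gas_run(m=0.05, delta_cbf_hc=1.0, seed=0)
        mask = np.ones(gas.perfusion.shape[:3], bool)
        base = gas_roi_and_summary(gas, mask)
        # garble the discarded post-switch window in both echoes
        t = gas.frame_times
        garble = (t >= 244.0) & (t < 356.0)  # inside discard, clear of guards
        rng = np.random.default_rng(2)
        gas.bold[..., garble] = rng.uniform(0, 2000, gas.bold[..., garble].shape)
        gas.perfusion[..., garble] = rng.uniform(0, 2000, gas.perfusion[..., garble].shape)
        after = gas_roi_and_summary(gas, mask)
        assert after.m == pytest.approx(base.m, rel=1e-9)
        assert after.roi_voxels == base.roi_voxels

    def test_fallback_fraction_escalation(self):
        """Anti-aligned change maps: top-15% overlap too small -> use 20%."""
        shape = (8, 8, 4)
        n = np.prod(shape)
        rank = np.arange(n, dtype=float)
        d_bold_rank = rank.reshape(shape)
        # CBF ranks shifted so top-15% sets share only 5 voxels, top-20% more
        n15 = int(np.ceil(0.15 * n))
        shift = n15 - 5
        d_cbf_rank = np.roll(rank, shift).reshape(shape)
        m, d_cbf_amp = 0.05, 1.0
        db_map = 0.02 + 1e-6 * d_bold_rank
        dc_map = d_cbf_amp + 1e-4 * d_cbf_rank

        protocol = GasProtocol()
        tr = 4.0
        n_vols = int((protocol.baseline_s + protocol.hypercapnia_s) / tr)
        t = np.arange(n_vols) * tr
        g = (t >= protocol.baseline_s).astype(float)
        bold = 1000.0 * (1.0 + db_map[..., None] * g)
        diff = 10.0 * (1.0 + dc_map[..., None] * g)
        perf = np.where(np.arange(n_vols) % 2 == 0, 1000.0 - diff, 1000.0)
        gas = DualEchoSeries(perf, bold, tr=tr, label_first=True)
        summary = gas_roi_and_summary(gas, np.ones(shape, bool), protocol, fwhm_mm=0.0)
        assert summary.top_fraction_used == 0.20
        assert summary.roi_voxels >= 10

    def test_short_run_rejected(self):
        gas, _ = make_gas_run(m=0.05, seed=0)
        short = DualEchoSeries(gas.perfusion[..., :50], gas.bold[..., :50], tr=4.0)
        with pytest.raises(ValueError):
            gas_roi_and_summary(short, np.ones(gas.perfusion.shape[:3], bool))


class TestEvokedMeasures:
    def test_uniform_maps_match_scalar_oracle(self):
        shape = (4, 4, 2)
        roi = np.ones(shape, bool)
        db = np.full(shape, 0.01)
        dc = np.full(shape, 0.50)
        vox = evoked_measures(db, dc, roi, 0.05, averaging_mode="voxelwise")
        roi_mean = evoked_measures(db, dc, roi, 0.05, averaging_mode="roi_mean")
        expected = 100 * compute_delta_cmro2(0.01, 0.50, 0.05)  # 12.2205...
        assert vox.ve_cmro2 == pytest.approx(expected, abs=1e-9)
        assert roi_mean.ve_cmro2 == pytest.approx(expected, abs=1e-9)
        assert vox.ve_bold == pytest.approx(1.0) and vox.ve_cbf == pytest.approx(50.0)

    def test_single_voxel_modes_identical(self):
        roi = np.zeros((3, 3, 1), bool)
        roi[1, 1, 0] = True
        db = np.full((3, 3, 1), 0.008)
        dc = np.full((3, 3, 1), 0.4)
        vox = evoked_measures(db, dc, roi, 0.05, averaging_mode="voxelwise")
        rm = evoked_measures(db, dc, roi, 0.05, averaging_mode="roi_mean")
        assert vox.ve_cmro2 == pytest.approx(rm.ve_cmro2)
        assert vox.ve_n == pytest.approx(rm.ve_n)

    def test_two_voxel_mean_of_ratios_differs(self):
        """Mean of voxelwise n differs from the ratio computed on means."""
        roi = np.ones((2, 1, 1), bool)
        db = np.array([0.005, 0.02]).reshape(2, 1, 1)
        dc = np.array([0.2, 0.9]).reshape(2, 1, 1)
        vox = evoked_measures(db, dc, roi, 0.05, averaging_mode="voxelwise")
        rm = evoked_measures(db, dc, roi, 0.05, averaging_mode="roi_mean")
        d1 = compute_delta_cmro2(0.005, 0.2, 0.05)
        d2 = compute_delta_cmro2(0.02, 0.9, 0.05)
        assert vox.ve_n == pytest.approx((0.2 / d1 + 0.9 / d2) / 2)
        assert vox.ve_n != pytest.approx(rm.ve_n)

    def test_invalid_voxels_skipped_with_count(self):
        roi = np.ones((2, 1, 1), bool)
        db = np.array([0.01, 0.08]).reshape(2, 1, 1)  # second exceeds M
        dc = np.full((2, 1, 1), 0.5)
        res = evoked_measures(db, dc, roi, 0.05)
        assert res.n_skipped == 1
        assert res.ve_cmro2 == pytest.approx(100 * compute_delta_cmro2(0.01, 0.5, 0.05))


class TestEndToEnd:
    def test_noiseless_participant_recovery(self):
        design = make_task_design(seed=1)
        task, _ = make_task_run(delta_bold=0.01, delta_cbf=0.5, design=design, seed=1)
        gas, _ = make_gas_run(m=0.05, delta_cbf_hc=1.0, seed=1)
        shape = task.perfusion.shape[:3]
        meas, gsum = process_participant(
            task, gas, np.ones(shape), np.ones(shape, bool), design
        )
        assert gsum.m == pytest.approx(0.05, abs=1e-6)
        assert meas.ve_bold == pytest.approx(1.0, abs=1e-6)
        assert meas.ve_cbf == pytest.approx(50.0, abs=1e-6)
        assert meas.ve_cmro2 == pytest.approx(
            100 * compute_delta_cmro2(0.01, 0.5, 0.05), abs=1e-6
        )

    def test_zero_perfusion_constant_bold_phantom(self):
        """Surround subtraction and pair averaging leave it at (0, constant)."""
        perf = np.full((4, 4, 2, 20), 800.0)
        bold = np.full((4, 4, 2, 20), 1200.0)
        assert np.allclose(surround_subtract(perf), 0.0)
        assert np.allclose(bold_pair_average(bold), 1200.0)

    def test_grid_mismatch_rejected(self):
        design = make_task_design(seed=1)
        task, _ = make_task_run(design=design, seed=1)
        gas, _ = make_gas_run(seed=1)
        shape = task.perfusion.shape[:3]
        with pytest.raises(ValueError, match="grid"):
            process_participant(
                task, gas, np.ones((2, 2, 2)), np.ones(shape, bool), design
            )

    def test_matched_regressors_follow_data_operators(self):
        """Surround/pair-average regressors equal the operators applied to
        a unit-modulated series, so noiseless GLM recovery is exact."""
        design = make_task_design(seed=3)
        n = int(design.total_duration / 4.0)
        u = boxcar_regressor(design, n, 4.0)
        pa = pair_average_regressor(u)
        assert np.allclose(pa[:-1], 0.5 * (u[:-1] + u[1:]))
        sr = surround_regressor(u, label_first=True)
        # label positions carry u_t, control positions the neighbour mean
        assert np.allclose(sr[0::2][1:-1], u[0::2][1:-1])
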