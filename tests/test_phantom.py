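"""Phantom generator tests: geometry, masks, simulated acquisitions, M0."""

import numpy as np
import pytest

from ossasl.config import AcquisitionConfig, FitConfig, PhantomSpec
from ossasl.fitting import MissingROIError, calibrate_m0_blood, \
    pairwise_subtract
from ossasl.kinetic import KineticParams, delta_m, peak_ti2
from ossasl.phantom import (_R_GM, _R_WM, make_phantom, simulate_acquisition,
                            simulate_m0, simulate_masks, slice_scales)
from ossasl.scheduler import initial_schedule


class TestGeometry:
    def test_fractions_sum_to_one_inside_head(self, default_phantom):
        total = sum(default_phantom.pv[t] for t in ("gm", "wm", "csf"))
        inside = total > 0
        assert np.allclose(total[inside], 1.0)

    def test_zero_boundary_width_gives_pure_voxels(self, acq, fitcfg):
        ph = make_phantom(PhantomSpec(pv_boundary_width=0), acq, fitcfg)
        for t in ("gm", "wm", "csf"):
            assert set(np.unique(ph.pv[t])) <= {0.0, 1.0}
        masks = simulate_masks(ph)
        assert np.array_equal(masks["wm-gm"], masks["wm"])

    def test_boundary_shell_count_matches_enumeration(self, default_phantom):
        # independent enumeration of the GM/WM interface shell
        spec = default_phantom.spec
        m = spec.matrix
        centre = (m - 1) / 2.0
        x, y = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
        r_xy = np.hypot(x - centre, y - centre)
        expected = 0
        for s in slice_scales(spec.n_slices):
            r = r_xy / s
            expected += int(((r >= _R_WM * m - 0.5) & (r < _R_WM * m + 0.5)).sum())
        mixed = (default_phantom.pv["gm"] > 0) & (default_phantom.pv["gm"] < 1)
        assert int(mixed.sum()) == expected

    def test_deterministic_given_spec(self, acq, fitcfg):
        a = make_phantom(PhantomSpec(seed=3), acq, fitcfg)
        b = make_phantom(PhantomSpec(seed=3), acq, fitcfg)
        for key in a.truth:
            assert np.array_equal(a.truth[key], b.truth[key])

    def test_mixed_voxel_truth_between_pure_tissues(self, default_phantom):
        ph = default_phantom
        mixed = (ph.pv["gm"] > 0) & (ph.pv["gm"] < 1)
        wm_cbf = ph.spec.tissue_params["wm"].cbf
        gm_cbf = ph.spec.tissue_params["gm"].cbf
        vals = ph.truth["cbf"][mixed]
        assert np.all(vals > wm_cbf) and np.all(vals < gm_cbf)
        # fraction-weighted mixture, exactly
        expected = (ph.pv["gm"][mixed] * gm_cbf + ph.pv["wm"][mixed] * wm_cbf)
        assert np.allclose(vals, expected)

    def test_geometry_impossible_raises(self, acq, fitcfg):
        with pytest.raises(ValueError):
            PhantomSpec(matrix=8)


class TestMasks:
    def test_threshold_half_on_pure_phantom_equals_tissue_maps(self, acq, fitcfg):
        ph = make_phantom(PhantomSpec(pv_boundary_width=0), acq, fitcfg)
        masks = simulate_masks(ph, 0.5)
        for t in ("gm", "wm", "csf"):
            assert np.array_equal(masks[t], ph.pv[t] == 1.0)

    def test_wm_minus_gm_excludes_mixed_voxels(self, default_phantom):
        masks = simulate_masks(default_phantom, 0.5)
        # brute-force check voxel by voxel
        pv = default_phantom.pv
        expected = (pv["wm"] >= 0.5) & ~(pv["gm"] >= 0.5)
        assert np.array_equal(masks["wm-gm"], expected)
        mixed = (pv["gm"] > 0) & (pv["gm"] < 1)
        assert not (masks["wm-gm"] & mixed).any()

    def test_masks_shrink_monotonically_with_threshold(self, default_phantom):
        prev = None
        for thr in (0.25, 0.5, 0.75, 0.99):
            masks = simulate_masks(default_phantom, thr)
            if prev is not None:
                for t in ("gm", "wm", "csf"):
                    assert not (masks[t] & ~prev[t]).any()  # set inclusion
            prev = masks

    def test_invalid_threshold(self, default_phantom):
        with pytest.raises(ValueError):
            simulate_masks(default_phantom, 1.0)


class TestAcquisition:
    def test_noiseless_subtraction_equals_model(self, noiseless_phantom, acq,
                                                fitcfg):
        sched = initial_schedule(4, (0.8, 2.0))
        series = simulate_acquisition(noiseless_phantom, sched, acq, fitcfg,
                                      seed=0)
        dm = pairwise_subtract(series)
        ph = noiseless_phantom
        for z in (0, 3):
            sel = ph.pv["wm"][:, :, z] == 1.0
            i, j = np.argwhere(sel)[0]
            p = KineticParams(
                f=ph.truth["cbf"][i, j, z], delta_t=ph.truth["att"][i, j, z],
                tau=acq.ti1, t1_blood=fitcfg.t1_blood,
                t1_tissue=ph.truth["t1"][i, j, z], alpha=fitcfg.alpha,
                m0_blood=ph.spec.m0_blood, lam=fitcfg.lam)
            expected = delta_m(dm.effective_ti2(z), p)
            assert np.allclose(dm.dm[i, j, z, :], expected, rtol=1e-12)

    def test_effective_ti2_increases_with_slice(self, noiseless_phantom, acq,
                                                fitcfg):
        sched = initial_schedule(3, (0.8, 2.0))
        series = simulate_acquisition(noiseless_phantom, sched, acq, fitcfg)
        eff = series.effective_ti2()
        assert np.all(np.diff(eff, axis=1) > 0)

    def test_gm_wm_peak_signal_ratio_about_three(self, acq, fitcfg):
        # the reported GM:WM contrast ratio at max signal is ~3:1 and
        # literature spans 2.5:1 to 5:1
        spec = PhantomSpec()
        gm, wm = spec.tissue_params["gm"], spec.tissue_params["wm"]
        common = dict(tau=acq.ti1, t1_blood=fitcfg.t1_blood,
                      alpha=fitcfg.alpha, m0_blood=spec.m0_blood,
                      lam=fitcfg.lam)
        p_gm = KineticParams(f=gm.cbf, delta_t=gm.att, t1_tissue=gm.t1,
                             **common)
        p_wm = KineticParams(f=wm.cbf, delta_t=wm.att, t1_tissue=wm.t1,
                             **common)
        ratio = (delta_m(peak_ti2(p_gm, acq.window), p_gm)
                 / delta_m(peak_ti2(p_wm, acq.window), p_wm))
        assert 2.5 < ratio < 5.0

    def test_same_seed_identical_different_seed_same_truth(
            self, default_phantom, acq, fitcfg):
        sched = initial_schedule(3, (0.8, 2.0))
        a = simulate_acquisition(default_phantom, sched, acq, fitcfg, seed=7)
        b = simulate_acquisition(default_phantom, sched, acq, fitcfg, seed=7)
        c = simulate_acquisition(default_phantom, sched, acq, fitcfg, seed=8)
        assert np.array_equal(a.images, b.images)
        assert not np.array_equal(a.images, c.images)
        # noiseless component identical: many-pair averages agree loosely
        assert np.allclose(a.images.mean(), c.images.mean(), atol=1e-2)

    def test_schedule_outside_window_raises(self, default_phantom, acq,
                                            fitcfg):
        sched = initial_schedule(3, (0.5, 3.0))
        with pytest.raises(ValueError):
            simulate_acquisition(default_phantom, sched, acq, fitcfg)

    def test_mean_difference_converges_to_kinetic_curve(self, acq, fitcfg):
        # law of large numbers over 200 noise seeds on a small phantom
        spec = PhantomSpec(matrix=16, n_slices=1)
        ph = make_phantom(spec, acq, fitcfg)
        sched = initial_schedule(4, (0.8, 2.0))
        sel = ph.pv["wm"][:, :, 0] == 1.0
        i, j = np.argwhere(sel)[0]
        n_seeds = 200
        acc = np.zeros(4)
        for s in range(n_seeds):
            series = simulate_acquisition(ph, sched, acq, fitcfg, seed=s)
            acc += pairwise_subtract(series).dm[i, j, 0, :]
        mean = acc / n_seeds
        p = KineticParams(f=ph.truth["cbf"][i, j, 0],
                          delta_t=ph.truth["att"][i, j, 0], tau=acq.ti1,
                          t1_blood=fitcfg.t1_blood,
                          t1_tissue=ph.truth["t1"][i, j, 0],
                          alpha=fitcfg.alpha, m0_blood=spec.m0_blood,
                          lam=fitcfg.lam)
        expected = delta_m(sched.ti2_values, p)
        se = spec.noise_sigma * np.sqrt(2) / np.sqrt(n_seeds)
        assert np.all(np.abs(mean - expected) < 3 * se)


class TestM0Calibration:
    def test_noiseless_round_trip_exact(self, noiseless_phantom, acq, fitcfg):
        vol, roi = simulate_m0(noiseless_phantom, acq, fitcfg)
        m0b = calibrate_m0_blood(vol, roi, acq.te, fitcfg.t2star_csf,
                                 fitcfg.lam)
        assert m0b == pytest.approx(noiseless_phantom.spec.m0_blood,
                                    rel=1e-10)

    def test_identity_case_returns_raw_csf_mean(self, noiseless_phantom, acq,
                                                fitcfg):
        vol, roi = simulate_m0(noiseless_phantom, acq, fitcfg)
        assert calibrate_m0_blood(vol, roi, te=0.0, t2star_csf=1.0, lam=1.0) \
            == pytest.approx(vol[roi].mean())

    def test_noisy_calibration_bias_below_one_percent(self, default_phantom,
                                                      acq, fitcfg):
        truth = default_phantom.spec.m0_blood
        estimates = [
            calibrate_m0_blood(*simulate_m0(default_phantom, acq, fitcfg,
                                            seed=s),
                               acq.te, fitcfg.t2star_csf, fitcfg.lam)
            for s in range(100)]
        assert abs(np.mean(estimates) / truth - 1) < 0.01

    def test_zero_csf_phantom_raises_missing_roi(self, default_phantom, acq,
                                                 fitcfg):
        vol, _ = simulate_m0(default_phantom, acq, fitcfg)
        empty = np.zeros_like(vol, dtype=bool)
        with pytest.raises(MissingROIError):
            calibrate_m0_blood(vol, empty, acq.te, fitcfg.t2star_csf,
                               fitcfg.lam)
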