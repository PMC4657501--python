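"""Fitting tests: subtraction, calibration, voxel/volume fits, uncertainty."""

import numpy as np
import pandas as pd
import pytest

from ossasl.config import AcquisitionConfig, FitConfig, PhantomSpec
from ossasl.fitting import (DeltaMSeries, PairingError, _batch_fit,
                            fit_volume, fit_voxel, pairwise_subtract)
from ossasl.kinetic import KineticParams, delta_m
from ossasl.phantom import AcquisitionSeries, make_phantom, \
    simulate_acquisition, simulate_masks
from ossasl.scheduler import initial_schedule


def forward(ti2, f, att, t1_tissue=1.4, m0_blood=110.0, fit=None):
    fit = fit or FitConfig()
    p = KineticParams(f=f, delta_t=att, tau=0.7, t1_blood=fit.t1_blood,
                      t1_tissue=t1_tissue, alpha=fit.alpha,
                      m0_blood=m0_blood, lam=fit.lam)
    return delta_m(ti2, p)


@pytest.fixture(scope="module")
def wm_design():
    """An 80-point multi-TI design: 10 evenly spaced blocks, slice 2."""
    even = initial_schedule(8, (0.8, 2.55)).ti2_values
    return np.tile(even, 10) + 2 * 0.045


class TestPairwiseSubtract:
    def _series(self, images, conditions, ti2s):
        meta = pd.DataFrame({"volume": np.arange(len(conditions)),
                             "block": 0, "ti2": ti2s,
                             "condition": conditions})
        return AcquisitionSeries(images=images, meta=meta,
                                 slice_delay=0.045, affine=np.eye(4))

    def test_identical_control_tag_gives_zero(self):
        vol = np.random.default_rng(0).normal(size=(4, 4, 2, 1))
        images = np.concatenate([vol, vol], axis=3)
        s = self._series(images, ["control", "tag"], [1.3, 1.3])
        assert np.all(pairwise_subtract(s).dm == 0)

    def test_noiseless_pair_matches_model_with_slice_delay(self, acq, fitcfg):
        ph = make_phantom(PhantomSpec(noise_sigma=0.0), acq, fitcfg)
        from ossasl.scheduler import TISchedule
        series = simulate_acquisition(ph, TISchedule([1.3]), acq, fitcfg)
        dm = pairwise_subtract(series)
        z = 5
        sel = ph.pv["wm"][:, :, z] == 1.0
        i, j = np.argwhere(sel)[0]
        expected = forward(1.3 + z * acq.slice_delay,
                           ph.truth["cbf"][i, j, z],
                           ph.truth["att"][i, j, z],
                           t1_tissue=ph.truth["t1"][i, j, z],
                           m0_blood=ph.spec.m0_blood)
        assert dm.dm[i, j, z, 0] == pytest.approx(expected, rel=1e-12)

    def test_swapped_condition_metadata_flips_sign(self):
        rng = np.random.default_rng(1)
        images = rng.normal(size=(3, 3, 1, 2))
        fwd = self._series(images, ["control", "tag"], [1.0, 1.0])
        rev = self._series(images, ["tag", "control"], [1.0, 1.0])
        assert np.allclose(pairwise_subtract(fwd).dm,
                           -pairwise_subtract(rev).dm)

    def test_unpaired_image_raises(self):
        images = np.zeros((2, 2, 1, 3))
        s = self._series(images, ["control", "tag", "control"],
                         [1.0, 1.0, 1.2])
        with pytest.raises(PairingError):
            pairwise_subtract(s)
        s2 = self._series(np.zeros((2, 2, 1, 2)), ["control", "control"],
                          [1.0, 1.0])
        with pytest.raises(PairingError):
            pairwise_subtract(s2)


class TestFitVoxel:
    def test_noiseless_wm_recovery(self, wm_design):
        y = forward(wm_design, 16.3, 0.89)
        res = fit_voxel(wm_design, y, t1_tissue=1.4, m0_blood=110.0)
        assert res.f_hat == pytest.approx(16.3, rel=1e-3)
        assert res.att_hat == pytest.approx(0.89, rel=1e-3)
        assert res.converged and res.z > 10

    def test_null_signal_rarely_significant(self, wm_design):
        # under the null (zero perfusion) the bulk of fits stay below z = 2.
        # The rate is slightly above the nominal 5% (measured ~5.5%) because
        # z is effectively maximised over the transit-time search, so the
        # derived bound is 92%, not the nominal 95%.
        rng = np.random.default_rng(2024)
        sigma = 0.05 * np.sqrt(2)
        Y = rng.normal(0.0, sigma, (len(wm_design), 200))
        res = _batch_fit(wm_design, Y, 1.4, 110.0, FitConfig(), 0.7)
        assert np.mean(np.abs(res["z"]) < 2) >= 0.92
        assert np.median(res["cbf"]) < 2.0
        assert np.median(res["z"]) < 1.0

    def test_curvature_se_close_to_bootstrap_se(self, wm_design):
        # parametric bootstrap at WM-like contrast-to-noise
        fit = FitConfig()
        truth = forward(wm_design, 16.3, 0.89)
        sigma = 0.05 * np.sqrt(2)
        rng = np.random.default_rng(99)
        Y = truth[:, None] + rng.normal(0, sigma, (len(wm_design), 200))
        res = _batch_fit(wm_design, Y, 1.4, 110.0, fit, 0.7)
        bootstrap_se = res["cbf"].std(ddof=1)
        curvature_se = np.median(res["se_f"])
        assert curvature_se / bootstrap_se < 1.5
        assert bootstrap_se / curvature_se < 1.5

    def test_estimator_bias_below_five_percent(self, wm_design):
        # 200 Monte-Carlo repetitions at WM-like CNR, 80 observations
        truth = forward(wm_design, 16.3, 0.89)
        sigma = 0.05 * np.sqrt(2)
        rng = np.random.default_rng(7)
        Y = truth[:, None] + rng.normal(0, sigma, (len(wm_design), 200))
        res = _batch_fit(wm_design, Y, 1.4, 110.0, FitConfig(), 0.7)
        assert abs(res["cbf"].mean() - 16.3) / 16.3 < 0.05

    def test_too_few_observations_refused(self):
        with pytest.raises(ValueError, match="observations"):
            fit_voxel(np.array([1.0, 1.5]), np.array([0.1, 0.2]),
                      t1_tissue=1.4, m0_blood=110.0)

    def test_batch_fit_agrees_with_scipy_path(self, wm_design):
        rng = np.random.default_rng(31)
        truth = forward(wm_design, 16.3, 0.89)
        Y = truth[:, None] + rng.normal(0, 0.05 * np.sqrt(2),
                                        (len(wm_design), 30))
        batch = _batch_fit(wm_design, Y, 1.4, 110.0, FitConfig(), 0.7)
        close = 0
        for v in range(30):
            ref = fit_voxel(wm_design, Y[:, v], 1.4, 110.0)
            if (abs(ref.f_hat - batch["cbf"][v]) < 1e-3 * max(ref.f_hat, 1)
                    and abs(ref.att_hat - batch["att"][v]) < 1e-3):
                close += 1
        # allow a couple of draws where the two optimisers pick different
        # (equal-cost) local solutions
        assert close >= 28

    def test_forward_fit_identity_random_draws(self):
        # noiseless forward-simulate -> fit is the identity inside bounds
        rng = np.random.default_rng(42)
        even = initial_schedule(8, (0.8, 2.55)).ti2_values
        design = np.tile(even, 10)
        n = 100
        f_true = rng.uniform(5, 120, n)
        att_true = rng.uniform(0.2, 1.6, n)
        Y = np.stack([forward(design, f, a) for f, a in
                      zip(f_true, att_true)], axis=1)
        res = _batch_fit(design, Y, 1.4, 110.0, FitConfig(), 0.7)
        assert np.all(np.abs(res["cbf"] - f_true) <= 1e-3 * f_true)
        assert np.all(np.abs(res["att"] - att_true) <= 2e-3)

    def test_z_monotone_in_noise(self, wm_design):
        # four-point noise ladder on a fixed voxel, fixed noise shape
        truth = forward(wm_design, 16.3, 0.89)
        rng = np.random.default_rng(5)
        shape = rng.normal(0, 1, (len(wm_design), 50))
        z_by_sigma = []
        for sigma in (0.02, 0.05, 0.1, 0.2):
            Y = truth[:, None] + sigma * np.sqrt(2) * shape
            res = _batch_fit(wm_design, Y, 1.4, 110.0, FitConfig(), 0.7)
            z_by_sigma.append(res["z"].mean())
        assert np.all(np.diff(z_by_sigma) < 0)

    def test_wrong_slice_delay_shifts_transit_by_five_delays(self):
        # slice 5 data fitted with the uncorrected nominal TI2s: the label
        # had 5 * slice_delay more travel time than assumed, so the apparent
        # arrival moves EARLIER by that amount (ATT biased downward)
        even = initial_schedule(8, (0.8, 2.55)).ti2_values
        design5 = np.tile(even, 10) + 5 * 0.045
        y = forward(design5, 16.3, 0.89)
        wrong = fit_voxel(np.tile(even, 10), y, 1.4, 110.0)
        right = fit_voxel(design5, y, 1.4, 110.0)
        assert right.att_hat - wrong.att_hat == pytest.approx(5 * 0.045,
                                                              abs=0.05)


class TestFitVolume:
    def test_noiseless_phantom_recovers_truth_maps(self, acq, fitcfg):
        spec = PhantomSpec(matrix=32, n_slices=2, noise_sigma=0.0,
                           pv_boundary_width=0)
        ph = make_phantom(spec, acq, fitcfg)
        masks = simulate_masks(ph)
        sched = initial_schedule(8, acq.window)
        parts = [simulate_acquisition(ph, sched, acq, fitcfg)]
        from ossasl.phantom import AcquisitionSeries as AS
        maps = fit_volume(AS.concat(parts), masks, spec.m0_blood, fitcfg,
                          tau=acq.ti1)
        tissue = masks["gm"] | masks["wm"]
        err = (np.abs(maps.cbf - ph.truth["cbf"])[tissue]
               / ph.truth["cbf"][tissue])
        assert np.all(err < 0.005)
        assert np.all(np.abs(maps.att - ph.truth["att"])[tissue] < 0.005)

    def test_gm_exceeds_wm_and_att_ordering(self, acq, fitcfg):
        spec = PhantomSpec(matrix=32, n_slices=2)
        ph = make_phantom(spec, acq, fitcfg)
        masks = simulate_masks(ph)
        sched = initial_schedule(8, acq.window)
        series = simulate_acquisition(ph, sched, acq, fitcfg, seed=0)
        maps = fit_volume(series, masks, spec.m0_blood, fitcfg, tau=acq.ti1)
        assert maps.cbf[masks["gm"]].mean() > maps.cbf[masks["wm-gm"]].mean()
        assert maps.att[masks["wm-gm"]].mean() > maps.att[masks["gm"]].mean()

    def test_grid_mismatch_raises(self, acq, fitcfg):
        spec = PhantomSpec(matrix=16, n_slices=1, noise_sigma=0.0)
        ph = make_phantom(spec, acq, fitcfg)
        masks = simulate_masks(ph)
        sched = initial_schedule(8, acq.window)
        series = simulate_acquisition(ph, sched, acq, fitcfg)
        bad = {k: v[:8, :8, :] for k, v in masks.items()}
        with pytest.raises(ValueError, match="mask"):
            fit_volume(series, bad, spec.m0_blood, fitcfg)

    def test_single_ti_refused(self, acq, fitcfg):
        spec = PhantomSpec(matrix=16, n_slices=1, noise_sigma=0.0)
        ph = make_phantom(spec, acq, fitcfg)
        masks = simulate_masks(ph)
        from ossasl.scheduler import TISchedule
        series = simulate_acquisition(ph, TISchedule([1.3]), acq, fitcfg)
        with pytest.raises(ValueError, match="TI2"):
            fit_volume(series, masks, spec.m0_blood, fitcfg)
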