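"""Phantom, time-series, retention and calibration-set generators: voxelized
ground truth, seeded reproducibility, blur conservation, FOV presets."""

import numpy as np
import pytest

from iodose import (
    AcquisitionSpec,
    OrganSpec,
    PhantomSpec,
    RetentionSpec,
    make_calibration_set,
    make_phantom,
    make_retention_series,
    make_timeseries,
)
from iodose.synthdata import ABDOMINAL_ORGANS

LN2 = np.log(2)


def sphere_spec(conc=0.1, radius=10.0, half_life=24.0, spacing=2.0, n=25):
    # odd n puts the sphere centre on a voxel centre
    c = (n - 1) / 2 * spacing
    return PhantomSpec(
        shape=(n, n, n),
        spacing_mm=(spacing,) * 3,
        organs=[OrganSpec("neck_uptake", "sphere", (c, c, c), (radius,) * 3, conc, half_life)],
    )


class TestMakePhantom:
    def test_voxelized_sphere_volume_and_activity(self):
        """A 10-mm sphere at 0.1 MBq/mL holds ~4/3 pi (1 cm)^3 x 0.1 MBq."""
        ph = make_phantom(sphere_spec())
        analytic_ml = 4.0 / 3.0 * np.pi * 1.0**3  # cm^3 = mL
        tr = ph.truth["neck_uptake"]
        assert tr.volume_ml == pytest.approx(analytic_ml, rel=0.05)
        assert tr.activity0_mbq == pytest.approx(0.1 * analytic_ml, rel=0.05)
        # voxelized truth is exactly concentration x voxelized volume
        assert tr.activity0_mbq == pytest.approx(0.1 * tr.volume_ml, rel=1e-12)

    def test_zero_concentration_gives_zero_truth(self):
        ph = make_phantom(sphere_spec(conc=0.0))
        assert ph.truth["neck_uptake"].activity0_mbq == 0.0

    def test_masks_are_disjoint(self, two_organ_phantom):
        total = sum(m.data.astype(int) for m in two_organ_phantom.masks.values())
        assert total.max() <= 1

    def test_head_neck_fov_drops_abdominal_organs(self):
        organs = [
            OrganSpec("neck_uptake", "sphere", (40, 40, 20), (10,) * 3, 0.1, 68.0),
            OrganSpec("liver", "sphere", (40, 40, 60), (10,) * 3, 0.02, 24.0),
            OrganSpec("spleen", "sphere", (18, 18, 60), (6,) * 3, 0.01, 18.0),
        ]
        spec = PhantomSpec((40, 40, 40), 2.0, organs, fov="head-neck-only")
        ph = make_phantom(spec)
        assert set(ph.masks) == {"neck_uptake"}
        assert not set(ph.masks) & ABDOMINAL_ORGANS

    def test_organ_outside_grid_rejected_by_name(self):
        spec = sphere_spec()
        spec.organs[0].center_mm = (2.0, 2.0, 2.0)
        with pytest.raises(ValueError, match="neck_uptake"):
            make_phantom(spec)

    def test_overlapping_organs_rejected(self):
        c = 23.0
        organs = [
            OrganSpec("neck_uptake", "sphere", (c, c, c), (10,) * 3, 0.1, 24.0),
            OrganSpec("salivary_glands", "sphere", (c + 5, c, c), (10,) * 3, 0.1, 9.3),
        ]
        with pytest.raises(ValueError, match="overlap"):
            make_phantom(PhantomSpec((24, 24, 24), 2.0, organs))

    def test_invalid_half_life_rejected(self):
        with pytest.raises(ValueError, match="half-life"):
            sphere_spec(half_life=500.0)


class TestMakeTimeseries:
    def test_noise_free_halving_per_half_life(self, noise_free_acq):
        ph = make_phantom(sphere_spec(half_life=24.0))
        series = make_timeseries(ph, noise_free_acq)
        a0 = ph.truth["neck_uptake"].activity0_mbq
        cf = noise_free_acq.calibration_factor_cps_per_mbq
        mask = ph.masks["neck_uptake"].data
        for img, expect in zip(series, (0.5 * a0, 0.25 * a0)):
            assert img.data[mask].sum() / cf == pytest.approx(expect, rel=1e-12)

    def test_poisson_seed_reproducibility(self):
        ph = make_phantom(sphere_spec())
        acq = AcquisitionSpec(times_h=(24.0,), noise="poisson", seed=42)
        s1 = make_timeseries(ph, acq)
        s2 = make_timeseries(ph, acq)
        assert np.array_equal(s1[0].data, s2[0].data)
        s3 = make_timeseries(ph, AcquisitionSpec(times_h=(24.0,), noise="poisson", seed=43))
        assert not np.array_equal(s1[0].data, s3[0].data)

    def test_blur_conserves_totals_but_loses_voi_activity(self):
        # grid large enough that the 8-mm blur tails stay > 3 sigma inside
        ph = make_phantom(sphere_spec(radius=8.0, n=41))
        sharp = make_timeseries(ph, AcquisitionSpec(times_h=(24.0,)))[0]
        blurred = make_timeseries(ph, AcquisitionSpec(times_h=(24.0,), blur_sigma_mm=8.0))[0]
        assert blurred.data.sum() == pytest.approx(sharp.data.sum(), rel=1e-6)
        mask = ph.masks["neck_uptake"].data
        assert blurred.data[mask].sum() < sharp.data[mask].sum()

    def test_time_outside_window_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 360\]"):
            AcquisitionSpec(times_h=(24.0, 400.0))


class TestMakeRetentionSeries:
    def test_biexponential_true_tiac(self):
        spec = RetentionSpec(
            fractions=(0.6, 0.4), half_lives_h=(5.0, 24.0),
            times_h=(2, 24, 48), administered_mbq=1.0,
        )
        assert spec.true_tiac_h == pytest.approx((0.6 * 5 + 0.4 * 24) / LN2, rel=1e-12)
        assert spec.true_tiac_h == pytest.approx(18.178, abs=5e-4)

    def test_noise_free_series_on_model_and_anchored_at_a0(self):
        spec = RetentionSpec(
            fractions=(0.6, 0.4), half_lives_h=(5.0, 24.0),
            times_h=(0.0, 24.0, 48.0), administered_mbq=3700.0,
        )
        table, meta = make_retention_series(spec)
        assert table.retained_MBq.iloc[0] == pytest.approx(3700.0)
        expect = 3700.0 * (0.6 * 2.0 ** (-48 / 5.0) + 0.4 * 2.0 ** (-48 / 24.0))
        assert table.retained_MBq.iloc[2] == pytest.approx(expect, rel=1e-12)

    def test_physical_decay_limit(self):
        spec = RetentionSpec(
            fractions=(1.0,), half_lives_h=(192.5,),
            times_h=(24.0, 96.0), administered_mbq=1.0,
        )
        table, _ = make_retention_series(spec)
        assert np.allclose(table.retained_MBq, 2.0 ** (-table.time_h / 192.5))

    def test_truncated_schedules_share_truth(self):
        kw = dict(fractions=(0.6, 0.4), half_lives_h=(5.0, 24.0), administered_mbq=1.0)
        short = RetentionSpec(times_h=(2, 20, 44), **kw)
        long = RetentionSpec(times_h=(2, 48, 167), **kw)
        assert short.true_tiac_h == long.true_tiac_h

    def test_noise_reproducible_by_seed(self):
        kw = dict(fractions=(1.0,), half_lives_h=(16.0,), times_h=(2, 24, 48),
                  relative_noise=0.05, administered_mbq=1.0)
        t1, _ = make_retention_series(RetentionSpec(seed=5, **kw))
        t2, _ = make_retention_series(RetentionSpec(seed=5, **kw))
        assert np.array_equal(t1.retained_MBq, t2.retained_MBq)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            RetentionSpec(fractions=(0.6, 0.3), half_lives_h=(5.0, 24.0),
                          times_h=(2.0,), administered_mbq=1.0)


class TestMakeCalibrationSet:
    def test_noise_free_counts_are_activity_times_cf(self):
        cs = make_calibration_set(120.0, 5000.0, [10.0, 100.0])
        assert cs.calibration_image.data.sum() == pytest.approx(6.0e5, rel=1e-9)

    def test_no_blur_means_unit_recovery(self):
        cs = make_calibration_set(120.0, 5000.0, [1.0, 10.0, 100.0], blur_sigma_mm=0.0)
        ratios = cs.sphere_table.measured_MBq / cs.sphere_table.true_MBq
        assert np.allclose(ratios, 1.0, rtol=1e-9)

    def test_blur_recovery_increases_with_volume(self):
        cs = make_calibration_set(120.0, 5000.0, [1.0, 10.0, 100.0], blur_sigma_mm=8.0)
        ratios = (cs.sphere_table.measured_MBq / cs.sphere_table.true_MBq).to_numpy()
        assert np.all(np.diff(ratios) > 0)
        assert np.all(ratios < 1.0)

    def test_nonpositive_activity_rejected(self):
        with pytest.raises(ValueError, match="activity"):
            make_calibration_set(0.0, 5000.0, [1.0, 10.0])
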