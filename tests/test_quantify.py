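import numpy as np
import pytest

from quickdwi.acquisition import AcquisitionProtocol, acquire, average_acquisitions, trace_weighted
from quickdwi.phantom import generate_phantom, noiseless_signal, random_phantom_spec
from quickdwi.quantify import ADCMap, fit_adc, mavd, rdm, roi_stats

B_VALUES = (50.0, 600.0, 900.0)


def _ols_slope(b, logs):
    """Independent normal-equations oracle for the log-linear slope."""
    b = np.asarray(b, float)
    n = b.size
    sx, sy = b.sum(), logs.sum()
    sxx, sxy = (b * b).sum(), (b * logs).sum()
    return (n * sxy - sx * sy) / (n * sxx - sx * sx)


class TestFitAdc:
    def test_exact_on_noiseless_signals(self):
        s0, adc = 1000.0, 1.0e-3
        imgs = np.stack([np.full((8, 8), s0 * np.exp(-b * adc)) for b in B_VALUES])
        out = fit_adc(imgs, B_VALUES)
        assert np.allclose(out.data, adc, rtol=1e-12)

    def test_recovers_phantom_ground_truth(self, simple_gt):
        imgs = np.stack([noiseless_signal(simple_gt, b) for b in B_VALUES])
        # restrict to voxels with signal (background s0 = 0 is flagged invalid)
        out = fit_adc(imgs, B_VALUES)
        tissue = simple_gt.s0_map > 0
        assert np.abs(out.data[tissue] - simple_gt.adc_map[tissue]).max() < 1e-10
        assert out.valid[tissue].all()
        assert not out.valid[~tissue].any()
        assert np.all(out.data[~tissue] == 0.0)

    def test_default_b_values_accepted(self):
        imgs = np.ones((3, 4, 4))
        out = fit_adc(imgs, B_VALUES)
        assert out.b_values_used == B_VALUES

    def test_matches_normal_equations_oracle(self, rng):
        imgs = rng.random((3, 6, 6)) * 1000 + 1.0
        out = fit_adc(imgs, B_VALUES)
        for r in range(6):
            for c in range(6):
                slope = _ols_slope(B_VALUES, np.log(imgs[:, r, c]))
                assert out.data[r, c] == pytest.approx(-slope, rel=1e-10)

    def test_negative_adcs_preserved(self):
        # signal increasing with b => negative fitted ADC, kept as-is
        imgs = np.stack([np.full((4, 4), 100.0 * np.exp(+1e-3 * b)) for b in B_VALUES])
        out = fit_adc(imgs, B_VALUES)
        assert np.all(out.data < 0)
        assert out.valid.all()

    def test_fewer_than_two_b_values_rejected(self):
        with pytest.raises(ValueError):
            fit_adc(np.ones((1, 4, 4)), (500.0,))
        with pytest.raises(ValueError):
            fit_adc(np.ones((2, 4, 4)), (500.0, 500.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_adc(np.ones((2, 4, 4)), B_VALUES)

    def test_weighted_fit_exact_on_noiseless(self):
        s0, adc = 900.0, 1.3e-3
        imgs = np.stack([np.full((4, 4), s0 * np.exp(-b * adc)) for b in B_VALUES])
        out = fit_adc(imgs, B_VALUES, weighted=True)
        assert np.allclose(out.data, adc, rtol=1e-10)


class TestRoiStats:
    def test_constant_field(self):
        amap = ADCMap(data=np.full((4, 4), 1.0e-3), b_values_used=B_VALUES)
        s = roi_stats(amap, np.ones((4, 4), bool))
        assert s.mean_adc == pytest.approx(1.0e-3)
        assert s.std_adc == 0.0
        assert s.cov == 0.0
        assert s.n_voxels == 16

    def test_two_voxel_closed_form(self):
        data = np.zeros((1, 2))
        data[0] = [0.5e-3, 1.5e-3]
        s = roi_stats(ADCMap(data=data, b_values_used=B_VALUES), np.ones((1, 2), bool))
        assert s.mean_adc == pytest.approx(1.0e-3)
        assert s.std_adc == pytest.approx(0.5e-3)
        assert s.cov == pytest.approx(0.5)

    def test_matches_loop_oracle(self, rng):
        data = rng.standard_normal((8, 8)) * 1e-3
        mask = rng.random((8, 8)) > 0.4
        s = roi_stats(ADCMap(data=data, b_values_used=B_VALUES), mask)
        vals = [data[r, c] for r in range(8) for c in range(8) if mask[r, c]]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / len(vals)
        assert s.mean_adc == pytest.approx(mean, rel=1e-12)
        assert s.std_adc == pytest.approx(var**0.5, rel=1e-12)

    def test_empty_mask_rejected(self):
        amap = ADCMap(data=np.ones((4, 4)), b_values_used=B_VALUES)
        with pytest.raises(ValueError):
            roi_stats(amap, np.zeros((4, 4), bool))


class TestRdm:
    def _map(self, value):
        return ADCMap(data=np.full((4, 4), value), b_values_used=B_VALUES)

    def test_identity_zero(self):
        m = self._map(1.0e-3)
        assert rdm(m, m, np.ones((4, 4), bool)) == 0.0

    def test_closed_form_two_percent(self):
        assert rdm(self._map(1.02e-3), self._map(1.00e-3), np.ones((4, 4), bool)) == pytest.approx(2.0)

    def test_compositional_oracle(self, rng):
        a = ADCMap(data=rng.random((6, 6)) * 1e-3 + 1e-4, b_values_used=B_VALUES)
        b = ADCMap(data=rng.random((6, 6)) * 1e-3 + 1e-4, b_values_used=B_VALUES)
        mask = rng.random((6, 6)) > 0.3
        expected = (
            abs(roi_stats(a, mask).mean_adc - roi_stats(b, mask).mean_adc)
            / roi_stats(b, mask).mean_adc
            * 100
        )
        assert rdm(a, b, mask) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance(self, rng):
        a = ADCMap(data=rng.random((6, 6)) + 0.1, b_values_used=B_VALUES)
        b = ADCMap(data=rng.random((6, 6)) + 0.1, b_values_used=B_VALUES)
        mask = np.ones((6, 6), bool)
        base = rdm(a, b, mask)
        for c in (0.5, 3.0, 1e-3):
            sa = ADCMap(data=a.data * c, b_values_used=B_VALUES)
            sb = ADCMap(data=b.data * c, b_values_used=B_VALUES)
            assert rdm(sa, sb, mask) == pytest.approx(base, rel=1e-10)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rdm(self._map(1e-3), self._map(0.0), np.ones((4, 4), bool))


class TestMavd:
    def _map(self, data):
        return ADCMap(data=data, b_values_used=B_VALUES)

    def test_identity_zero(self, rng):
        data = rng.random((4, 4))
        assert mavd(self._map(data), self._map(data.copy()), np.ones((4, 4), bool)) == 0.0

    def test_constant_difference(self):
        a = self._map(np.full((4, 4), 1.1e-3))
        b = self._map(np.full((4, 4), 1.0e-3))
        assert mavd(a, b, np.ones((4, 4), bool)) == pytest.approx(1e-4)

    def test_matches_loop_oracle(self, rng):
        da, db = rng.random((5, 5)), rng.random((5, 5))
        mask = rng.random((5, 5)) > 0.5
        vals = [abs(da[r, c] - db[r, c]) for r in range(5) for c in range(5) if mask[r, c]]
        assert mavd(self._map(da), self._map(db), mask) == pytest.approx(
            sum(vals) / len(vals), rel=1e-12
        )


class TestNoiseBehaviour:
    def test_noa9_roi_mean_close_to_truth(self):
        """ROI-mean ADC from clinical images stays within 3% of ground truth
        when the lesion SNR at b=50 is high."""
        spec = random_phantom_spec(21, lesion_radius=8.0)
        gt = generate_phantom(spec)
        mask = gt.roi_masks["lesion"]
        s0_lesion = gt.s0_map[mask].mean()
        sigma = s0_lesion / 40.0  # SNR 40 at b=0, > 20 at b=50
        p = AcquisitionProtocol(noise_sigma=sigma, seed=17)
        clin = average_acquisitions(trace_weighted(acquire(gt, p)))
        amap = fit_adc(clin.data, p.b_values, source="noa_n")
        mean_fit = roi_stats(amap, mask).mean_adc
        mean_true = gt.adc_map[mask].mean()
        assert abs(mean_fit - mean_true) / mean_true < 0.03
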