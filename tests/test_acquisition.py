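import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from quickdwi.acquisition import (
    AcquisitionProtocol,
    DWIStack,
    TraceStack,
    acquire,
    average_acquisitions,
    denormalize,
    normalize,
    trace_weighted,
)
from quickdwi.phantom import noiseless_signal


def _protocol(**kw):
    defaults = dict(noise_sigma=20.0, seed=0)
    defaults.update(kw)
    return AcquisitionProtocol(**defaults)


def _stack_from_array(data, **kw):
    protocol = _protocol(
        b_values=tuple(range(1, data.shape[0] + 1)),
        n_directions=data.shape[1],
        n_acquisitions=data.shape[2],
        **kw,
    )
    return DWIStack(data=data, protocol=protocol)


class TestProtocolValidation:
    def test_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            _protocol(noise_sigma=0.0)

    def test_rejects_bad_directions(self):
        with pytest.raises(ValueError):
            _protocol(n_directions=2)

    def test_noa(self):
        assert _protocol(n_directions=3, n_acquisitions=3).noa == 9
        assert _protocol(n_directions=3, n_acquisitions=4).noa == 12


class TestAcquire:
    def test_sigma_to_zero_limit(self, simple_gt):
        p = _protocol(noise_sigma=1e-12)
        stack = acquire(simple_gt, p)
        for ib, b in enumerate(p.b_values):
            clean = np.clip(noiseless_signal(simple_gt, b), 0, p.intensity_ceiling)
            for j in range(3):
                for a in range(3):
                    assert np.allclose(stack.data[ib, j, a], clean, atol=1e-9)

    def test_deterministic(self, simple_gt):
        p = _protocol(seed=99)
        a = acquire(simple_gt, p)
        b = acquire(simple_gt, p)
        assert np.array_equal(a.data, b.data)

    def test_background_rayleigh_mean(self, simple_gt):
        # S = 0 voxels follow a Rayleigh law with mean sigma * sqrt(pi/2)
        sigma = 25.0
        p = _protocol(noise_sigma=sigma, n_acquisitions=16, seed=5)
        stack = acquire(simple_gt, p)
        background = simple_gt.s0_map == 0
        draws = stack.data[:, :, :, background]
        assert draws.size >= 1e5
        assert draws.mean() == pytest.approx(sigma * math.sqrt(math.pi / 2), rel=0.01)

    def test_nonnegative_and_clipped(self, simple_gt):
        p = _protocol(noise_sigma=3000.0, seed=2)
        stack = acquire(simple_gt, p)
        assert stack.data.min() >= 0
        assert stack.data.max() <= p.intensity_ceiling


class TestTraceWeighted:
    def test_geometric_sequence(self):
        data = np.zeros((1, 3, 1, 4, 4))
        data[0, 0], data[0, 1], data[0, 2] = 2.0, 4.0, 8.0
        out = trace_weighted(_stack_from_array(data))
        assert np.allclose(out.data, 4.0, rtol=1e-12)

    def test_identity_when_equal(self, rng):
        img = rng.random((1, 1, 2, 8, 8)) * 100
        data = np.repeat(img, 3, axis=1)
        out = trace_weighted(_stack_from_array(data))
        assert np.allclose(out.data, img[:, 0], rtol=1e-10)

    def test_single_direction_identity(self, rng):
        data = rng.random((2, 1, 3, 8, 8))
        out = trace_weighted(_stack_from_array(data))
        assert np.array_equal(out.data, data[:, 0])

    def test_matches_exp_mean_log_oracle(self, rng):
        data = rng.random((3, 3, 2, 8, 8)) * 1000 + 1.0
        out = trace_weighted(_stack_from_array(data))
        oracle = np.exp(np.mean(np.log(data), axis=1))
        assert np.allclose(out.data, oracle, rtol=1e-12)

    def test_zero_voxels_give_zero(self):
        data = np.ones((1, 3, 1, 4, 4))
        data[0, 1, 0, 2, 2] = 0.0
        out = trace_weighted(_stack_from_array(data))
        assert out.data[0, 0, 2, 2] == pytest.approx(0.0, abs=1e-3)

    @given(arrays(np.float64, (1, 3, 1, 6, 6), elements=st.floats(0.0, 1000.0)))
    @settings(max_examples=50, deadline=None)
    def test_am_gm_inequality(self, data):
        out = trace_weighted(_stack_from_array(data))
        am = data.mean(axis=1)
        assert np.all(out.data <= am + 1e-8)


class TestAverageAcquisitions:
    def test_identical_traces(self, rng):
        img = rng.random((2, 1, 8, 8))
        data = np.repeat(img, 3, axis=1)
        traces = TraceStack(data=data, protocol=_protocol(b_values=(1.0, 2.0)))
        out = average_acquisitions(traces)
        assert np.allclose(out.data, img[:, 0], rtol=1e-12)

    def test_noa_nine(self, rng):
        p = _protocol(n_directions=3, n_acquisitions=3)
        traces = TraceStack(data=rng.random((3, 3, 8, 8)), protocol=p)
        assert average_acquisitions(traces).noa == 9

    def test_matches_loop_oracle(self, rng):
        p = _protocol()
        data = rng.random((3, 3, 8, 8))
        out = average_acquisitions(TraceStack(data=data, protocol=p))
        oracle = np.zeros((3, 8, 8))
        for ib in range(3):
            for r in range(8):
                for c in range(8):
                    oracle[ib, r, c] = sum(data[ib, a, r, c] for a in range(3)) / 3
        assert np.allclose(out.data, oracle, rtol=1e-12)


class TestNormalize:
    @pytest.mark.parametrize("value,ceiling", [(4095, 4095), (939, 939)])
    def test_ceiling_maps_to_one(self, value, ceiling):
        assert normalize(np.array([float(value)]), ceiling)[0] == 1.0

    def test_zero(self):
        assert normalize(np.array([0.0]), 4095)[0] == 0.0

    def test_roundtrip_on_integer_images(self, rng):
        img = rng.integers(0, 4096, size=(32, 32)).astype(float)
        assert np.array_equal(denormalize(normalize(img, 4095), 4095), img)

    def test_clips_before_scaling(self):
        assert normalize(np.array([5000.0]), 4095)[0] == 1.0

    def test_bad_ceiling(self):
        with pytest.raises(ValueError):
            normalize(np.zeros(3), 0)


class TestNoiseAveragingLaw:
    def test_noa9_noise_std_one_third(self):
        """Empirical NOA_9 noise std ~ 1/3 of NOA_1 in high-SNR voxels."""
        from quickdwi.phantom import Compartment, PhantomSpec, generate_phantom

        spec = PhantomSpec(
            grid_shape=(128, 128),
            compartments=(
                Compartment(
                    "t", "rectangle", (64.0, 64.0), (64.0, 64.0), s0=2000.0, adc=1.0e-3
                ),
            ),
        )
        gt = generate_phantom(spec)
        sigma = 60.0  # SNR at b=50: ~2000*exp(-0.05)/60 > 10
        n_rep = 40
        noa1 = np.empty((n_rep, 128, 128))
        noa9 = np.empty((n_rep, 128, 128))
        for r in range(n_rep):
            p = _protocol(b_values=(50.0,), noise_sigma=sigma, seed=1000 + r)
            stack = acquire(gt, p)
            noa1[r] = stack.data[0, 0, 0]
            noa9[r] = average_acquisitions(trace_weighted(stack)).data[0]
        ratio = noa9.std(axis=0) / noa1.std(axis=0)
        assert ratio.size >= 1e4
        assert 0.28 < ratio.mean() < 0.39

    def test_rician_bias_survives_averaging(self, simple_gt):
        """Averaging magnitude images does not remove the noise floor.

        The NOA_1 background mean is the Rayleigh mean sigma*sqrt(pi/2).
        The geometric mean over 3 directions shifts it to the exact value
        sigma * sqrt(2) * Gamma(7/6)^3 (~1.129 sigma, about 10% below the
        Rayleigh mean); the arithmetic mean over acquisitions preserves
        the expectation.
        """
        from scipy.special import gamma

        sigma = 25.0
        p = _protocol(noise_sigma=sigma, n_acquisitions=3, seed=11)
        stack = acquire(simple_gt, p)
        clin = average_acquisitions(trace_weighted(stack))
        background = simple_gt.s0_map == 0
        assert stack.data[:, :, :, background].mean() == pytest.approx(
            sigma * math.sqrt(math.pi / 2), rel=0.02
        )
        mean_bg = clin.data[:, background].mean()
        assert mean_bg > 0
        expected = sigma * math.sqrt(2.0) * gamma(7.0 / 6.0) ** 3
        assert mean_bg == pytest.approx(expected, rel=0.02)
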