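"""Funnel sizing, forward/backward pass, kernel cross-check, end-to-end runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dnfilter as dn
from dnfilter import _kernel
from dnfilter.dnf_core import (
    NetworkState,
    compute_layer_sizes,
    dnf_step,
    init_network,
    suggested_ntaps,
)
from dnfilter.preprocessing import DelayLine


class TestLayerSizing:
    @pytest.mark.parametrize(
        "ntaps,nlayers,expected",
        [
            (50, 6, (50, 22, 10, 4, 2, 1)),   # the operating configuration
            (1, 6, (1, 1, 1, 1, 1, 1)),
            (16, 5, (16, 8, 4, 2, 1)),        # b = 2 exactly
            (100, 6, (100, 39, 15, 6, 2, 1)),
        ],
    )
    def test_funnel_examples(self, ntaps, nlayers, expected):
        assert compute_layer_sizes(ntaps, nlayers) == expected

    @given(ntaps=st.integers(1, 400), nlayers=st.integers(1, 12))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_funnel_properties(self, ntaps, nlayers):
        sizes = compute_layer_sizes(ntaps, nlayers)
        assert len(sizes) == nlayers
        assert sizes[-1] == 1
        if nlayers > 1:
            assert sizes[0] == ntaps
        assert all(a >= b >= 1 for a, b in zip(sizes, sizes[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            compute_layer_sizes(0, 6)
        with pytest.raises(ValueError):
            compute_layer_sizes(50, 0)

    def test_suggested_ntaps_from_reference_highpass(self):
        assert suggested_ntaps(500, 5.0) == 100


class TestInit:
    def test_same_seed_identical(self):
        a = init_network((4, 2, 1), seed=3)
        b = init_network((4, 2, 1), seed=3)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_published_init_range(self):
        net = init_network((50, 22, 10, 4, 2, 1), seed=0, init_scale=1.0)
        for w in net.weights:
            assert np.all(w > 0) and np.all(w <= 1)

    def test_fanin_init_range(self):
        net = init_network((50, 22, 10, 4, 2, 1), seed=0)
        fan_in = [50, 50, 22, 10, 4, 2]
        for w, f in zip(net.weights, fan_in):
            assert np.all(w > 0) and np.all(w <= 2.0 / f)

    def test_fresh_network_distance_zero(self):
        net = init_network((8, 3, 1), seed=1)
        assert np.array_equal(net.weight_distance(), np.zeros(3))


class TestForward:
    def test_zero_taps_zero_output(self):
        net = init_network((6, 3, 1), seed=0)
        assert net.forward(np.zeros(6)) == 0.0
        assert all(np.all(a == 0) for a in net._acts[1:])

    def test_odd_symmetry(self, rng):
        net = init_network((10, 4, 1), seed=2)
        taps = rng.standard_normal(10)
        assert net.forward(-taps) == pytest.approx(-net.forward(taps), rel=1e-12)

    def test_small_signal_linearisation(self, rng):
        # at tiny amplitudes tanh is identity: y -> (prod of W) @ taps
        net = init_network((10, 4, 2, 1), seed=5)
        taps = 1e-6 * rng.standard_normal(10)
        linear = taps
        for w in net.weights:
            linear = w @ linear
        assert net.forward(taps) == pytest.approx(float(linear[0]), rel=1e-6)

    def test_remover_bounded(self, rng):
        net = init_network((5, 2, 1), seed=0, init_scale=1.0)
        for _ in range(50):
            y = net.forward(100 * rng.standard_normal(5))
            assert abs(y) < 1


class TestBackward:
    def test_zero_error_no_update(self, rng):
        net = init_network((6, 3, 1), seed=0)
        before = [w.copy() for w in net.weights]
        net.forward(rng.standard_normal(6))
        net.backward(0.0)
        for w, w0 in zip(net.weights, before):
            assert np.array_equal(w, w0)

    def test_zero_eta_no_update(self, rng):
        net = init_network((6, 3, 1), seed=0)
        before = [w.copy() for w in net.weights]
        net.forward(rng.standard_normal(6))
        net.backward(1.7, eta=0.0)
        for w, w0 in zip(net.weights, before):
            assert np.array_equal(w, w0)

    def test_backward_without_forward_rejected(self):
        net = init_network((4, 1), seed=0)
        with pytest.raises(RuntimeError):
            net.backward(0.5)

    def test_deltas_match_central_differences(self, rng):
        # the update with e=1 must equal d z_L / d w for every weight
        sizes = compute_layer_sizes(4, 3)
        for trial in range(10):
            net = init_network(sizes, seed=trial, n_inputs=4, init_scale=0.5)
            taps = rng.standard_normal(4)
            net.forward(taps)
            ref = [w.copy() for w in net.weights]
            net.backward(1.0, eta=1.0)
            h = 1e-6
            for l, w0 in enumerate(ref):
                for j in range(w0.shape[0]):
                    for i in range(w0.shape[1]):
                        grads = []
                        for sgn in (+1, -1):
                            ws = [w.copy() for w in ref]
                            ws[l][j, i] += sgn * h
                            a = taps
                            for w in ws[:-1]:
                                a = np.tanh(w @ a)
                            z = float((ws[-1] @ a)[0])  # output pre-activation
                            grads.append(z)
                        fd = (grads[0] - grads[1]) / (2 * h)
                        analytic = net.weights[l][j, i] - w0[j, i]
                        assert analytic == pytest.approx(fd, rel=1e-5, abs=1e-9)


class TestStepAndRun:
    def test_zero_taps_pass_through(self):
        net = init_network((3, 1), seed=0)
        line = DelayLine(3)
        # first sample with x=0: taps all zero, y=0, e = d
        e = dnf_step(net, 0.42, 0.0, line)
        assert e == 0.42

    def test_identical_seeds_identical_streams(self, short_session):
        rec, _ = short_session
        cfg = dn.RunConfig(seed=9)
        r1 = dn.run_dnf(rec, cfg)
        r2 = dn.run_dnf(rec, cfg)
        assert np.array_equal(r1.e, r2.e)
        assert np.array_equal(r1.weight_distance, r2.weight_distance)

    def test_kernel_matches_reference_network(self, rng):
        # jitted padded-array loop vs the plain-numpy sample loop
        sizes = compute_layer_sizes(8, 4)
        net = init_network(sizes, seed=11, n_inputs=8)
        d = 0.1 * rng.standard_normal(300)
        x = 0.1 * rng.standard_normal(300)
        line = DelayLine(8)
        e_ref = np.array([dnf_step(net, dv, xv, line, eta=2.5) for dv, xv in zip(d, x)])
        packed = _kernel.pack_weights(init_network(sizes, seed=11, n_inputs=8).weights)
        sizes_ext = np.asarray((8,) + sizes, dtype=np.int64)
        e_k, y_k, wdist, _ = _kernel.dnf_loop(
            d, x, packed, sizes_ext, 2.5, False, 1, np.zeros(8)
        )
        assert np.allclose(e_k, e_ref, atol=1e-10)
        assert wdist[0] == pytest.approx(0.0)
        final = _kernel.unpack_weights(packed, sizes_ext)
        for wk, wr in zip(final, net.weights):
            assert np.allclose(wk, wr, atol=1e-10)

    def test_run_conserves_length_and_bounds(self, short_session):
        rec, _ = short_session
        res = dn.run_dnf(rec, dn.RunConfig(seed=0))
        assert res.e.size == res.y.size == rec.n_samples
        assert np.all(np.abs(res.y) < 1)
        assert np.all(np.isfinite(res.weight_distance))
        assert np.all(res.weight_distance[0] == 0)

    def test_zero_input_dc_free(self):
        rec = dn.Recording(np.zeros(2000), np.zeros(2000), fs=500)
        res = dn.run_dnf(rec, dn.RunConfig(seed=0))
        assert np.all(res.e == 0) and np.all(res.y == 0)

    def test_error_amplitude_shrinks_on_stationary_noise(self):
        # correlated stationary noise: the filter learns to cancel it
        spec = dn.session1_spec(seed=3)
        spec.duration_s = 60.0
        spec.emg_burst_rms = spec.emg_tonic_rms  # no bursts: stationary
        rec, _ = dn.synthesize_recording(spec)
        res = dn.run_dnf(rec, dn.RunConfig(seed=3))
        n = res.e.size
        first = np.mean(np.abs(res.e[: n // 10]))
        last = np.mean(np.abs(res.e[-n // 10:]))
        assert last < first


class TestEstimatorSurface:
    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone

        est = dn.DeepNeuralFilter(fs=250, eta=10, random_state=4)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()

    def test_fit_transform_shape_and_attributes(self, short_session):
        rec, _ = short_session
        est = dn.DeepNeuralFilter(fs=rec.fs, random_state=0)
        out = est.fit_transform(rec.as_array())
        assert out.shape == (rec.n_samples, 1)
        assert est.layer_sizes_ == (50, 22, 10, 4, 2, 1)
        assert est.delay_ == 25
        assert len(est.weights_) == 6

    def test_transform_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            dn.DeepNeuralFilter().transform(np.zeros((10, 2)))

    def test_transform_continues_stream(self, short_session):
        # filtering a record whole or in two chunks is identical
        rec, _ = short_session
        X = rec.as_array()
        whole = dn.DeepNeuralFilter(fs=rec.fs, random_state=1).fit(X).output_
        est = dn.DeepNeuralFilter(fs=rec.fs, random_state=1)
        half = X.shape[0] // 2
        part1 = est.fit(X[:half]).output_
        part2 = est.transform(X[half:])[:, 0]
        assert np.allclose(np.concatenate([part1, part2]), whole, atol=1e-12)
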