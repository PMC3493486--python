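"""Two-stage optimization, decoding, Fisher information, calibration."""

import numpy as np
import pytest

from ctcsim import (
    GDConfig,
    band_rates,
    biological_gain_baseline,
    build_condition,
    calibrate_delta,
    decode,
    direct_gain_single,
    evaluate_estimates,
    fisher_info,
    fit_decoder,
    gain_from_filter,
    generate_batch,
    hann_window,
    stage1_fit,
    stage2_fit,
)
from ctcsim.population import THETA_REF, SampleBatch
from ctcsim.receiving import freq_weights, n_freqs
from ctcsim.training import DecoderModel, _bilinear_descend


def _noise_free_batch(n_samples=64, n_bins=40, delta=4.0, modulated=False, seed=0,
                      windowed=True):
    """Deterministic batch: counts equal the target rate times dt exactly.

    With ``modulated`` a shared 75 Hz sinusoidal modulation multiplies the
    rates (and is stored as the reference); otherwise M = 1.
    """
    rng = np.random.default_rng(seed)
    spec = build_condition("asynchronous").networks[0]
    labels = np.concatenate([
        np.full(n_samples // 2, THETA_REF - delta / 2),
        np.full(n_samples // 2, THETA_REF + delta / 2),
    ])
    rng.shuffle(labels)
    rates = band_rates(spec, labels)  # (S, 8)
    if modulated:
        t = np.arange(n_bins) * 1e-3
        m = 1.0 + 0.8 * np.cos(2 * np.pi * 75.0 * t)
        modulation = np.tile(m, (n_samples, 1))
    else:
        modulation = np.ones((n_samples, n_bins))
    traces = rates[:, :, None] * modulation[:, None, :]
    batch = SampleBatch(
        counts=traces * 1e-3,
        target_modulation=modulation,
        target_band_rates=traces,
        labels=labels,
        delta_theta=delta,
        dt=1e-3,
    )
    return hann_window(batch) if windowed else batch


class TestStage1:
    def test_constant_modulation_yields_dc_filter(self):
        # target-only counts with M = 1: the matched filter is a constant
        # gain, i.e. the response concentrates at DC
        batch = _noise_free_batch()
        h, report = stage1_fit(batch)
        energy = np.abs(h.coefficients) ** 2 * freq_weights(batch.n_bins)
        assert energy[0] / energy.sum() > 0.9
        g = gain_from_filter(h, batch.target_modulation_raw[0])
        assert g.std() / max(abs(g.mean()), 1e-12) < 0.1

    def test_zero_targets_leave_filter_at_zero(self):
        batch = _noise_free_batch()
        batch.target_band_rates = np.zeros_like(batch.target_band_rates)
        h, _ = stage1_fit(batch)
        assert np.allclose(h.coefficients, 0.0)

    def test_training_cost_monotone(self, async_batches):
        _, train, test = async_batches
        _, report = stage1_fit(train, test)
        mse = np.asarray(report.train_mse)
        assert np.all(np.diff(mse) <= 1e-12)

    def test_unwindowed_batch_rejected(self):
        cond = build_condition("asynchronous")
        raw = generate_batch(cond, 4.0, 20, 3)
        with pytest.raises(ValueError):
            stage1_fit(raw)


class TestStage2:
    def test_zero_separation_drives_estimates_to_reference(self):
        batch = _noise_free_batch(delta=0.0)
        h0, _ = stage1_fit(batch)
        model, _ = stage2_fit(batch, batch, h0)
        est = decode(model, batch)
        np.testing.assert_allclose(est, THETA_REF, atol=1e-6)

    def test_estimates_invariant_to_count_scaling(self, async_batches):
        _, train, test = async_batches
        model, _, _ = fit_decoder(train, test)
        est = decode(model, test)
        scaled_train = SampleBatch(
            counts=2.0 * train.counts, target_modulation=train.target_modulation,
            target_band_rates=train.target_band_rates, labels=train.labels,
            delta_theta=train.delta_theta, dt=train.dt, windowed=True,
            target_modulation_raw=train.target_modulation_raw,
            counts_raw=2.0 * train.counts_raw,
        )
        scaled_test = SampleBatch(
            counts=2.0 * test.counts, target_modulation=test.target_modulation,
            target_band_rates=test.target_band_rates, labels=test.labels,
            delta_theta=test.delta_theta, dt=test.dt, windowed=True,
            target_modulation_raw=test.target_modulation_raw,
            counts_raw=2.0 * test.counts_raw,
        )
        model2, _, _ = fit_decoder(scaled_train, scaled_test)
        est2 = decode(model2, scaled_test)
        # the bilinear estimator is invariant to a global count rescaling
        np.testing.assert_allclose(est2, est, atol=0.05 * est.std() + 1e-6)

    def test_fitted_gain_near_sinusoidal_at_target_frequency(self, async_batches):
        # asynchronous condition: the optimized gain concentrates its energy
        # at the 50 Hz target band (+/- 2 DFT bins)
        _, train, test = async_batches
        model, _, _ = fit_decoder(train, test)
        gains = gain_from_filter(model.h, train.target_modulation_raw)
        gains = gains - gains.mean(axis=1, keepdims=True)
        spec = np.abs(np.fft.rfft(gains, axis=1)) ** 2 * freq_weights(train.n_bins)
        frac = spec[:, 3:8].sum() / spec.sum()  # 50 Hz = bin 5 at T = 100 ms
        assert frac > 0.7

    def test_early_stopping_returns_running_minimum(self, async_batches):
        _, train, test = async_batches
        h0, rep1 = stage1_fit(train, test)
        _, rep2 = stage2_fit(train, test, h0)
        # the reported model corresponds to the minimum test MSE seen
        assert min(rep1.test_mse) <= rep1.test_mse[-1]
        assert rep2.test_mse[rep2.stopping_iteration - 1] == min(rep2.test_mse)
        assert rep2.stopping_iteration <= rep2.n_iterations

    def test_freq_cap_zeroes_high_frequencies(self, async_batches):
        _, train, test = async_batches
        model, _, _ = fit_decoder(train, test, freq_cap=150.0)
        freqs = np.arange(n_freqs(train.n_bins)) / (train.n_bins * train.dt)
        assert np.all(model.h.coefficients[freqs > 150.0] == 0)
        assert np.any(model.h.coefficients[freqs <= 150.0] != 0)


class TestFilterStructure:
    def test_known_modulation_frequency_recovered(self):
        # single sinusoidally modulated input, no distractors: the fitted
        # filter passes the true modulation frequency (within one DFT bin)
        from dataclasses import replace
        cond = build_condition("asynchronous", n_networks=1, sync_strength=0.4)
        net = cond.networks[0]
        net = replace(net, oscillation=replace(
            net.oscillation, waveform="sinusoidal", mean_frequency=80.0))
        cond = replace(cond, networks=(net,))
        train = hann_window(generate_batch(cond, 2.0, 800, 70))
        test = hann_window(generate_batch(cond, 2.0, 800, 71))
        model, _, _ = fit_decoder(train, test)
        h = np.abs(model.h.coefficients)
        true_bin = int(round(80.0 * train.n_bins * train.dt))
        assert abs(int(np.argmax(h[1:])) + 1 - true_bin) <= 1

    def test_incoherent_filter_suppresses_shared_band(self):
        # same-band incoherent distractors: the optimized response is small
        # at the shared 50 Hz band relative to its low/high-frequency flanks
        cond = build_condition("incoherent_same_band")
        train = hann_window(generate_batch(cond, 7.0, 1200, 72))
        test = hann_window(generate_batch(cond, 7.0, 1200, 73))
        model, _, _ = fit_decoder(train, test)
        h = np.abs(model.h.coefficients)
        band = h[4:7].mean()  # 40-60 Hz at T = 100 ms
        flanks = np.r_[h[2:4], h[7:10]].mean()
        assert band < flanks


class TestOptimizerOracle:
    def test_als_matches_long_run_gradient_descent(self):
        # tiny bilinear instance: block-coordinate optimum vs an independent
        # plain steepest-descent run agree in training cost within 1%
        rng = np.random.default_rng(4)
        z = rng.standard_normal((200, 2, 8))
        w_true, u_true = rng.standard_normal(2), rng.standard_normal(8)
        y = np.einsum("sju,u,j->s", z, u_true, w_true) + 0.1 * rng.standard_normal(200)
        u0 = rng.standard_normal(8) * 0.1
        als_cfg = GDConfig(max_rounds_als=200, patience=10**6, rel_tol=1e-15)
        gd_cfg = GDConfig(stage2_method="gd", max_iter_stage2=30000,
                          patience=10**6, eval_every=1000, rel_tol=1e-15)
        w_a, c_a, u_a, rep_a = _bilinear_descend(z, y, z, y, u0, als_cfg, None, "als")
        w_g, c_g, u_g, rep_g = _bilinear_descend(z, y, z, y, u0, gd_cfg, None, "gd")
        cost_a = np.mean((np.einsum("sju,u,j->s", z, u_a, w_a) + c_a - y) ** 2)
        cost_g = np.mean((np.einsum("sju,u,j->s", z, u_g, w_g) + c_g - y) ** 2)
        assert cost_a <= cost_g * 1.01
        assert cost_g <= cost_a * 1.01


class TestDecode:
    def test_zero_weights_give_constant_offset(self, async_batches):
        _, _, test = async_batches
        model = DecoderModel(
            weights=np.zeros(8), offset=42.0, g_direct=np.ones(test.n_bins)
        )
        assert np.all(decode(model, test) == 42.0)

    def test_affine_consistency(self, async_batches):
        _, train, test = async_batches
        model, _, _ = fit_decoder(train, test)
        doubled = DecoderModel(
            weights=2.0 * model.weights, offset=model.offset, h=model.h,
            reference=model.reference, dt=model.dt,
        )
        est, est2 = decode(model, test), decode(doubled, test)
        np.testing.assert_allclose(est2 - model.offset, 2.0 * (est - model.offset),
                                   rtol=1e-9)

    def test_fit_then_decode_brackets_labels(self, async_batches):
        # held-out estimates bracket the two orientations with small bias
        _, train, test = async_batches
        model, _, _ = fit_decoder(train, test)
        res = evaluate_estimates(decode(model, test), test.labels, test.delta_theta)
        delta = test.delta_theta
        assert abs(res.mean_low - (THETA_REF - delta / 2)) < delta / 4
        assert abs(res.mean_high - (THETA_REF + delta / 2)) < delta / 4


class TestFisherInfo:
    def test_unit_slope_unit_variance(self, rng):
        delta = 2.0
        labels = np.repeat([THETA_REF - 1.0, THETA_REF + 1.0], 3000)
        est = labels + rng.standard_normal(6000)
        assert fisher_info(est, labels, delta) == pytest.approx(1.0, rel=0.1)

    def test_gaussian_toy_with_known_slope(self):
        # slope 0.8, sd 2 deg: FI = 0.8^2 / 2^2 = 0.16
        rng = np.random.default_rng(2)
        delta = 2.0
        labels = np.repeat([THETA_REF - 1.0, THETA_REF + 1.0], 20_000)
        est = THETA_REF + 0.8 * (labels - THETA_REF) + 2.0 * rng.standard_normal(40_000)
        assert fisher_info(est, labels, delta) == pytest.approx(0.16, rel=0.1)

    def test_constant_estimates_give_zero(self):
        labels = np.repeat([89.0, 91.0], 10)
        assert fisher_info(np.full(20, 90.0), labels, 2.0) == 0.0

    def test_zero_variance_with_separation_is_infinite(self):
        labels = np.repeat([89.0, 91.0], 10)
        est = np.repeat([80.0, 100.0], 10)
        assert fisher_info(est, labels, 2.0) == np.inf

    def test_invariance_to_shift_and_relabel(self, rng):
        labels = np.repeat([89.0, 91.0], 500)
        est = labels + rng.standard_normal(1000)
        fi = fisher_info(est, labels, 2.0)
        assert fisher_info(est + 17.0, labels, 2.0) == pytest.approx(fi)
        assert fisher_info(-est, labels, 2.0) == pytest.approx(fi)
        assert fisher_info(est, 180.0 - labels, 2.0) == pytest.approx(fi)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            fisher_info(np.array([1.0, 2.0]), np.array([89.0, 91.0]), 2.0)


class TestCalibration:
    def test_fraction_lands_in_band(self):
        cond = build_condition("asynchronous")
        delta, frac, trace = calibrate_delta(cond, 31, n_samples=600)
        assert 0.75 <= frac <= 0.80
        assert delta > 0
        assert len(trace) >= 1

    def test_tiny_separation_classifies_at_chance(self):
        from ctcsim import fit_and_evaluate
        cond = build_condition("asynchronous")
        res, _ = fit_and_evaluate(cond, 0.02, 600, 32)
        # binomial 4-sigma band around chance at n = 600
        assert abs(res.fraction_correct - 0.5) < 4 * 0.5 / np.sqrt(600)


class TestDirectGain:
    def test_noise_free_gain_matches_modulation_waveform(self):
        # without noise the informative temporal direction is the modulation
        # itself; the ridge u-step selects (a scaling of) that direction
        batch = _noise_free_batch(modulated=True, n_samples=128, windowed=False)
        model, _ = direct_gain_single(batch, batch)
        g = model.g_direct - model.g_direct.mean()
        m = batch.target_modulation_raw[0] - batch.target_modulation_raw[0].mean()
        corr = abs(np.corrcoef(g, m)[0, 1])
        assert corr > 0.9


class TestBiologicalGainBaseline:
    def test_gain_is_mean_free_and_loses_to_optimized(self):
        cond = build_condition("incoherent_same_band")
        train = hann_window(generate_batch(cond, 7.0, 900, 61))
        test = hann_window(generate_batch(cond, 7.0, 900, 62))
        result, model = biological_gain_baseline(train, test)
        m = train.target_modulation_raw
        g = m - m.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(g.mean(axis=1), 0.0, atol=1e-9)
        full, _, _ = fit_decoder(train, test)
        fi_opt = evaluate_estimates(decode(full, test), test.labels, 7.0).fisher_info
        assert result.fisher_info < fi_opt

    def test_flat_modulation_gives_zero_information(self):
        from dataclasses import replace
        from ctcsim import OscillationParams
        cond = build_condition("asynchronous")
        nets = tuple(
            replace(n, oscillation=OscillationParams(waveform="none", sync_strength=0.0))
            for n in cond.networks
        )
        cond = replace(cond, networks=nets)
        train = hann_window(generate_batch(cond, 5.0, 200, 63))
        test = hann_window(generate_batch(cond, 5.0, 200, 64))
        result, _ = biological_gain_baseline(train, test)
        assert result.fisher_info == 0.0
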