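"""Feature bank: registry contract, analytic signals, oracle equivalence."""

import numpy as np
import pytest

from neobg.core import EPOCH_SAMPLES
from neobg.features import (FEATURE_REGISTRY, activation_synchrony_index,
                            amplitude_modulation_stats, band_power,
                            compute_feature_table, multiscale_entropy_slope,
                            sample_entropy)
from neobg.features.engine import ChannelContext
from neobg.features.measures import multiscale_entropy_curve
from neobg.features.registry import NAMED_TOP5
from oracles import (median_aggregate_bruteforce, sample_entropy_bruteforce,
                     welch_band_power_bruteforce)


class TestRegistry:
    def test_exactly_98_features(self):
        assert len(FEATURE_REGISTRY) == 98
        assert len(set(FEATURE_REGISTRY.ids)) == 98

    def test_named_top5_present(self):
        for fid in NAMED_TOP5:
            assert fid in FEATURE_REGISTRY.ids

    def test_every_feature_computable_on_every_class(self):
        """All 98 features yield finite values on a clean epoch of every
        background grade (at least one channel pair available)."""
        from neobg.simulate import DEFAULT_CLASS_PARAMS, simulate_epoch
        from conftest import make_epochset

        for score in range(7):
            x = simulate_epoch(DEFAULT_CLASS_PARAMS[score], 2, 64, 300,
                               seed=score)
            es = make_epochset(x[None])
            ft = compute_feature_table(es)
            bad = [fid for fid, v in zip(ft.feature_ids, ft.values[0])
                   if not np.isfinite(v)]
            assert not bad, f"score {score}: non-finite {bad}"


class TestBandPower:
    def test_10hz_10uv_sine_concentrates_50uv2_in_9_11(self, sine_epoch):
        p_band = band_power(sine_epoch, (9.0, 11.0))
        p_total = band_power(sine_epoch, (0.5, 30.0))
        assert abs(p_band - 50.0) / 50.0 < 0.05
        assert p_band / p_total > 0.99

    def test_5hz_sine_has_no_9_11_power(self):
        t = np.arange(EPOCH_SAMPLES) / 64.0
        x = 10.0 * np.sin(2 * np.pi * 5.0 * t)
        assert band_power(x, (9.0, 11.0)) <= 0.01 * band_power(x, (0.5, 30.0))

    def test_matches_bruteforce_welch_on_noise(self, rng):
        for _ in range(5):
            x = rng.normal(size=4096)
            for band in ((0.5, 3.0), (9.0, 11.0), (15.0, 30.0)):
                mine = band_power(x, band)
                ref = welch_band_power_bruteforce(x, band)
                assert abs(mine - ref) / ref < 0.01

    def test_white_noise_power_proportional_to_bandwidth(self, rng):
        x = rng.normal(size=EPOCH_SAMPLES)
        p1 = np.mean([band_power(x, (5.0, 10.0))])
        p2 = np.mean([band_power(x, (15.0, 25.0))])
        assert abs(p2 / p1 - 2.0) < 0.3  # 10 Hz vs 5 Hz of flat spectrum


class TestAmplitudeModulation:
    def test_unmodulated_sine(self, sine_epoch):
        mean, sd = amplitude_modulation_stats(sine_epoch)
        assert abs(mean - 10.0) / 10.0 < 0.05
        assert sd < 0.05 * mean

    def test_two_level_envelope_sd_over_mean_near_one(self):
        t = np.arange(EPOCH_SAMPLES) / 64.0
        gate = (np.floor(t / 10.0) % 2).astype(float)  # 10 s on / 10 s off
        x = gate * np.sin(2 * np.pi * 10 * t) * 20.0
        mean, sd = amplitude_modulation_stats(x)
        assert abs(sd / mean - 1.0) < 0.10

    def test_zero_signal(self):
        mean, sd = amplitude_modulation_stats(np.zeros(EPOCH_SAMPLES))
        assert mean == 0.0 and sd == 0.0


class TestSynchrony:
    def _gated(self, gate, seed):
        rng = np.random.default_rng(seed)
        return gate * rng.normal(size=len(gate)) * 30.0

    def test_self_synchrony_is_maximal(self):
        t = np.arange(EPOCH_SAMPLES) / 64.0
        gate = (np.sin(2 * np.pi * t / 20) > 0).astype(float)
        a = self._gated(gate, 0)
        assert activation_synchrony_index(a, a) == pytest.approx(1.0)

    def test_shared_gate_beats_shuffled_gate(self):
        """Permutation oracle: ASI with the true shared gate exceeds the null
        distribution of gate-shuffled channels."""
        rng = np.random.default_rng(0)
        n_blocks = 60
        block = EPOCH_SAMPLES // n_blocks
        states = rng.random(n_blocks) < 0.5
        gate = np.repeat(states, block).astype(float)
        a, b = self._gated(gate, 1), self._gated(gate, 2)
        observed = activation_synchrony_index(a, b)
        null = []
        for k in range(200):
            perm = rng.permutation(n_blocks)
            g2 = np.repeat(states[perm], block).astype(float)
            null.append(activation_synchrony_index(a, self._gated(g2, 100 + k)))
        assert observed > np.percentile(null, 99)

    def test_zero_channels_fallback(self):
        z = np.zeros(EPOCH_SAMPLES)
        assert activation_synchrony_index(z, z) == 0.0


class TestEntropy:
    def test_sample_entropy_matches_bruteforce(self, rng):
        for _ in range(10):
            x = rng.normal(size=120)
            mine = sample_entropy(x)
            ref = sample_entropy_bruteforce(x)
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_constant_signal_is_missing(self):
        assert np.isnan(sample_entropy(np.ones(500)))

    def test_white_noise_slope_negative(self):
        rng = np.random.default_rng(0)
        slopes = [multiscale_entropy_slope(rng.standard_normal(1200))
                  for _ in range(5)]
        assert all(s < 0 for s in slopes)

    def test_white_vs_one_over_f_slope_ordering(self):
        """1/f noise keeps its entropy across scales; white noise loses it,
        so the white-noise slope is more negative (20 seeds)."""
        from neobg.simulate import colored_noise

        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w = rng.standard_normal(1200)
            pink = colored_noise(1200, 64, 1.0, np.random.default_rng(seed + 1),
                                 band=(0.5, 32.0))
            s_w = multiscale_entropy_slope(w)
            s_p = multiscale_entropy_slope(pink)
            diffs.append(s_p - s_w)
        assert np.mean(diffs) > 0
        assert np.mean([d > 0 for d in diffs]) >= 0.9

    def test_determinism(self):
        x = np.random.default_rng(5).normal(size=800)
        assert multiscale_entropy_slope(x) == multiscale_entropy_slope(x.copy())


class TestAggregation:
    def _es_with_values(self, per_channel_signals, rejected=None):
        from conftest import make_epochset

        epochs = np.stack(per_channel_signals)[None]
        es = make_epochset(epochs)
        if rejected:
            for c in rejected:
                es.channel_rejected[0, c] = True
        return es

    def test_median_of_three_channels(self):
        t = np.arange(EPOCH_SAMPLES) / 64.0
        sigs = [a * np.sin(2 * np.pi * 10 * t) for a in (1.0, 2.0, 9.0)]
        ft = compute_feature_table(self._es_with_values(sigs))
        j = ft.feature_ids.index("am_mean")
        assert ft.values[0, j] == pytest.approx(2.0, rel=0.05)

    def test_median_of_survivors_after_rejection(self):
        t = np.arange(EPOCH_SAMPLES) / 64.0
        sigs = [a * np.sin(2 * np.pi * 10 * t) for a in (1.0, 2.0, 9.0)]
        ft = compute_feature_table(self._es_with_values(sigs, rejected=[2]))
        j = ft.feature_ids.index("am_mean")
        assert ft.values[0, j] == pytest.approx(1.5, rel=0.05)

    def test_identical_channels_equal_single_channel(self):
        from neobg.simulate import DEFAULT_CLASS_PARAMS, simulate_epoch

        x = simulate_epoch(DEFAULT_CLASS_PARAMS[3], 1, 64, 300, seed=0)[0]
        es3 = self._es_with_values([x, x, x])
        ft = compute_feature_table(es3)
        ctx = ChannelContext(x)
        for entry, v in zip(FEATURE_REGISTRY, ft.values[0]):
            if entry.pairwise:
                continue
            assert v == pytest.approx(entry.func(ctx), nan_ok=True, abs=1e-12)

    def test_rejected_epoch_is_missing(self):
        t = np.arange(EPOCH_SAMPLES) / 64.0
        es = self._es_with_values([np.sin(t), np.cos(t)])
        es.epoch_rejected[0] = True
        ft = compute_feature_table(es)
        assert ft.missing[0].all()
        assert np.isnan(ft.values[0]).all()

    def test_median_aggregation_matches_bruteforce(self, rng):
        for _ in range(20):
            vals = rng.normal(size=rng.integers(1, 9))
            assert np.nanmedian(vals) == pytest.approx(
                median_aggregate_bruteforce(vals))


class TestScalingContract:
    def test_declared_gain_behaviour(self):
        """Amplitude features scale linearly, power features quadratically,
        dimensionless features are invariant under gains 0.5x and 2x."""
        from neobg.simulate import DEFAULT_CLASS_PARAMS, simulate_epoch

        x = simulate_epoch(DEFAULT_CLASS_PARAMS[1], 2, 64, 300, seed=4)
        base = [ChannelContext(x[0]), ChannelContext(x[1])]
        for gain in (0.5, 2.0):
            scaled = [ChannelContext(gain * x[0]), ChannelContext(gain * x[1])]
            for entry in FEATURE_REGISTRY:
                if entry.scaling == "other":
                    continue
                if entry.pairwise:
                    v0 = entry.func(base[0], base[1])
                    v1 = entry.func(scaled[0], scaled[1])
                else:
                    v0 = entry.func(base[0])
                    v1 = entry.func(scaled[0])
                if not np.isfinite(v0):
                    continue
                expected = {"linear": gain * v0, "quadratic": gain ** 2 * v0,
                            "invariant": v0}[entry.scaling]
                assert v1 == pytest.approx(expected, rel=1e-6, abs=1e-9), \
                    entry.feature_id


class TestMonotoneDiscrimination:
    def test_envelope_amplitude_ordered_across_amplitude_classes(self):
        """Mean envelope amplitude strictly ordered 0 > 4 > 6 (20 seeds)."""
        from neobg.simulate import DEFAULT_CLASS_PARAMS, simulate_epoch

        for seed in range(20):
            means = {}
            for score in (0, 4, 6):
                x = simulate_epoch(DEFAULT_CLASS_PARAMS[score], 1, 64, 60,
                                   seed=seed)[0]
                means[score] = amplitude_modulation_stats(x)[0]
            assert means[0] > means[4] > means[6]
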