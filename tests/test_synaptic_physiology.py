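"""IPSP extraction, receptor classification, mixture fit, rundown and
gap-junction measurement."""

import numpy as np
import pytest

from l1census import synaptic_physiology as sp
from l1census import synthetic_data as sd
from l1census.ephys_features import VoltageTrace

from oracles import biexp_crossings


def _sweeps(voltages, t=None):
    t = t if t is not None else np.arange(0.0, 600.0, 0.1)
    return [VoltageTrace(t, v, np.zeros_like(t), {}) for v in voltages]


class TestAverageSweeps:
    def test_identical_sweeps_mean_equals_either(self):
        t = np.arange(0.0, 600.0, 0.1)
        v = -57.0 - np.exp(-((t - 200) ** 2) / 500.0)
        rec = sp.PairedRecording(np.array([150.0]), _sweeps([v, v.copy()]))
        mean = sp.average_sweeps(rec)
        base = v - v[(t >= 100) & (t < 150)].mean()
        np.testing.assert_allclose(mean.voltage, base, atol=1e-9)

    def test_antisymmetric_sweeps_cancel(self):
        t = np.arange(0.0, 600.0, 0.1)
        bump = np.exp(-((t - 300) ** 2) / 800.0)
        rec = sp.PairedRecording(np.array([150.0]),
                                 _sweeps([-57.0 + bump, -57.0 - bump]))
        mean = sp.average_sweeps(rec)
        np.testing.assert_allclose(mean.voltage, 0.0, atol=1e-9)

    def test_residual_noise_shrinks_with_sweep_count(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 600.0, 0.1)
        sigma = 0.5
        n = 25
        rec = sp.PairedRecording(
            np.array([150.0]),
            _sweeps([-57.0 + rng.normal(0, sigma, len(t)) for _ in range(n)]))
        mean = sp.average_sweeps(rec)
        assert np.std(mean.voltage) == pytest.approx(sigma / np.sqrt(n), rel=0.2)

    def test_mismatched_lengths_rejected(self):
        t1 = np.arange(0.0, 600.0, 0.1)
        t2 = np.arange(0.0, 500.0, 0.1)
        with pytest.raises(ValueError):
            sp.PairedRecording(np.array([150.0]), [
                VoltageTrace(t1, np.full_like(t1, -57.0), np.zeros_like(t1), {}),
                VoltageTrace(t2, np.full_like(t2, -57.0), np.zeros_like(t2), {}),
            ])


class TestExtractIpsp:
    def test_rise_time_matches_analytic_biexponential(self):
        spec = sd.SynapseGenSpec.for_receptor("GABA_A", seed=0, noise_sd=0.0,
                                              tau_rise_A=5.0, tau_decay_A=40.0)
        rec = sd.generate_paired_recording(spec, [100.0])
        feats = sp.extract_ipsp(rec)
        t20, t80 = biexp_crossings(5.0, 40.0)
        assert feats.rise_time_2080 == pytest.approx(
            t80 - t20, abs=rec.post_sweeps[0].dt)

    def test_constant_sweep_amplitudes_zero_cv(self):
        spec = sd.SynapseGenSpec.for_receptor("GABA_A", seed=0, noise_sd=0.0,
                                              n_repetitions=3)
        feats = sp.extract_ipsp(sd.generate_paired_recording(spec, [100.0]))
        assert feats.cv == pytest.approx(0.0, abs=1e-9)

    def test_flat_trace_below_detection(self):
        t = np.arange(0.0, 600.0, 0.1)
        rec = sp.PairedRecording(np.array([150.0]),
                                 _sweeps([np.full_like(t, -57.0)]))
        with pytest.raises(sp.BelowDetection):
            sp.extract_ipsp(rec)

    def test_amplitude_invariant_under_baseline_offset(self):
        spec = sd.SynapseGenSpec.for_receptor("GABA_A", seed=1, noise_sd=0.0)
        rec = sd.generate_paired_recording(spec, [100.0])
        shifted = sp.PairedRecording(
            rec.pre_spike_times,
            [VoltageTrace(s.time, s.voltage + 11.0, s.stimulus, s.metadata)
             for s in rec.post_sweeps])
        a = sp.extract_ipsp(rec).amplitude
        b = sp.extract_ipsp(shifted).amplitude
        assert a == pytest.approx(b, rel=1e-9)

    def test_latency_invariant_under_time_shift(self):
        spec = sd.SynapseGenSpec.for_receptor("GABA_A", seed=1, noise_sd=0.0)
        rec = sd.generate_paired_recording(spec, [100.0])
        shift = 50.0
        shifted = sp.PairedRecording(
            rec.pre_spike_times + shift,
            [VoltageTrace(s.time + shift, s.voltage, s.stimulus, s.metadata)
             for s in rec.post_sweeps])
        assert sp.extract_ipsp(rec).latency == pytest.approx(
            sp.extract_ipsp(shifted).latency, abs=1e-9)

    def test_cv_estimates_relative_amplitude_jitter(self):
        # per-sweep amplitude scatter dominated by injected noise at trough
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 600.0, 0.1)
        kernel = -4.0 * np.exp(-((t - 250.0) ** 2) / (2 * 25.0**2))
        sweeps = []
        for _ in range(200):
            scale = rng.normal(1.0, 0.2)
            sweeps.append(-57.0 + scale * kernel)
        rec = sp.PairedRecording(np.array([150.0]), _sweeps(sweeps))
        feats = sp.extract_ipsp(rec)
        assert feats.cv == pytest.approx(0.2, rel=0.2)


class TestClassifyReceptor:
    def test_fast_single_ap_response_is_gaba_a(self):
        fake_single = sp.IpspFeatures(2.0, 20.0, 50.0, 4.0, 60.0, 0.3,
                                      np.array([2.0]), 104.0, 0.005)
        fake_train = sp.IpspFeatures(6.0, 55.0, 60.0, 4.0, 200.0, 0.3,
                                     np.array([6.0]), 104.0, 0.01)
        assert sp.classify_receptor(fake_single, fake_train).label == "GABA_A"

    def test_train_only_slow_response_is_gaba_b(self):
        fake_train = sp.IpspFeatures(1.5, 160.0, 250.0, 14.0, 300.0, 0.4,
                                     np.array([1.5]), 400.0, 0.2)
        assert sp.classify_receptor(None, fake_train).label == "GABA_B"

    def test_no_response_at_all_unclassified(self):
        out = sp.classify_receptor(None, None)
        assert out.label == "unclassified"
        assert "reason" in out.evidence

    def test_generator_round_trip_all_three_classes_low_noise(self):
        single = np.array([100.0])
        train = 100.0 + np.arange(15) * 20.0
        for receptor in ("GABA_A", "GABA_B", "GABA_AB"):
            spec = sd.SynapseGenSpec.for_receptor(receptor, seed=3,
                                                  noise_sd=0.1)
            feats = {}
            for name, spikes in (("single", single), ("train", train)):
                try:
                    feats[name] = sp.extract_ipsp(
                        sd.generate_paired_recording(spec, spikes))
                except sp.BelowDetection:
                    feats[name] = None
            got = sp.classify_receptor(feats["single"], feats["train"])
            assert got.label == receptor

    def test_deterministic_on_complete_features(self):
        fake_single = sp.IpspFeatures(2.0, 20.0, 50.0, 4.0, 60.0, 0.3,
                                      np.array([2.0]), 104.0, 0.005)
        fake_train = sp.IpspFeatures(6.0, 90.0, 200.0, 4.0, 300.0, 0.3,
                                     np.array([6.0]), 104.0, 0.10)
        labels = {sp.classify_receptor(fake_single, fake_train).label
                  for _ in range(5)}
        assert labels == {"GABA_AB"}


class TestRiseTimeMixture:
    def test_two_population_recovery(self):
        rng = np.random.default_rng(4)
        data = np.concatenate([rng.normal(20, 3, 100), rng.normal(160, 30, 100)])
        res = sp.fit_rise_time_mixture(data, seed=0)
        assert res["means"][0] == pytest.approx(20.0, rel=0.10)
        assert res["means"][1] == pytest.approx(160.0, rel=0.10)

    def test_identical_values_flagged_degenerate(self):
        res = sp.fit_rise_time_mixture(np.full(20, 25.0))
        assert res["degenerate"]

    def test_single_population_small_likelihood_gain(self):
        rng = np.random.default_rng(5)
        one_pop = rng.normal(50, 5, 200)
        res = sp.fit_rise_time_mixture(one_pop, seed=0)
        two_pop = np.concatenate([rng.normal(20, 3, 100),
                                  rng.normal(160, 30, 100)])
        res2 = sp.fit_rise_time_mixture(two_pop, seed=0)
        assert res["lrt_statistic"] < res2["lrt_statistic"]
        assert res["lrt_statistic"] < 20.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            sp.fit_rise_time_mixture([1.0, 2.0, 3.0])


class TestRundown:
    def test_exact_geometric_sequence(self):
        res = sp.measure_rundown([4.0, 2.0, 1.0])
        assert res["ratio"] == pytest.approx(0.5, abs=1e-9)
        assert res["rundown_rate"] == pytest.approx(0.5, abs=1e-9)

    def test_constant_amplitudes_no_decay(self):
        res = sp.measure_rundown([3.0, 3.0, 3.0, 3.0])
        assert res["ratio"] == pytest.approx(1.0, abs=1e-12)

    def test_generator_rundown_recovered_within_ci(self):
        spec = sd.SynapseGenSpec.for_receptor("GABA_A", seed=6, noise_sd=0.05,
                                              rundown_rate=0.1,
                                              n_repetitions=10)
        feats = sp.extract_ipsp(sd.generate_paired_recording(spec, [100.0]))
        res = sp.measure_rundown(feats.sweep_amplitudes)
        assert abs(res["rundown_rate"] - 0.1) <= 2 * res["ratio_se"] + 0.01

    def test_perforated_patch_rate_near_zero(self):
        spec = sd.SynapseGenSpec.for_receptor("GABA_A", seed=7, noise_sd=0.02,
                                              rundown_rate=0.0,
                                              patch_mode="perforated",
                                              n_repetitions=10)
        feats = sp.extract_ipsp(sd.generate_paired_recording(spec, [100.0]))
        res = sp.measure_rundown(feats.sweep_amplitudes)
        assert abs(res["rundown_rate"]) < 0.02


class TestGapJunction:
    def test_ratio_of_deflections(self):
        assert sp.coupling_coefficient(-10.0, -0.5) == pytest.approx(0.05)
        with pytest.raises(ValueError):
            sp.coupling_coefficient(0.0, -0.5)

    def test_symmetric_resistive_pair_equal_coefficients(self):
        pre, post = sd.generate_gj_recording(cc=0.06, noise_sd=0.0, seed=0)
        m = sp.gj_analyze(pre, post, pre, post)
        assert m.cc_12 == pytest.approx(m.cc_21, abs=1e-12)
        assert m.symmetric

    def test_generator_coefficient_recovered(self):
        ccs = []
        for seed in range(10):
            pre, post = sd.generate_gj_recording(cc=0.054, noise_sd=0.05,
                                                 seed=seed)
            m = sp.gj_analyze(pre, post, pre, post)
            ccs.append(m.cc_12)
        mean = np.mean(ccs)
        se = np.std(ccs, ddof=1) / np.sqrt(len(ccs))
        assert abs(mean - 0.054) <= max(2 * se, 0.002)


class TestPharmacology:
    def test_blocker_epoch_arithmetic(self):
        ledger = sp.PharmacologyLedger(4.83, 1.66, 0.64, 3.27)
        res = sp.pharmacology_account(ledger)
        assert res["fast_component"] == pytest.approx(3.17)
        assert res["slow_component"] == pytest.approx(1.02)
        assert res["residual"] == pytest.approx(0.64)
        assert res["recovery_fraction"] == pytest.approx(3.27 / 4.83)

    def test_equal_epochs_no_components(self):
        res = sp.pharmacology_account(sp.PharmacologyLedger(2.0, 2.0, 2.0, 2.0))
        assert res["fast_component"] == 0.0
        assert res["slow_component"] == 0.0

    def test_missing_washout_flagged(self):
        res = sp.pharmacology_account(sp.PharmacologyLedger(2.0, 1.0, 0.5))
        assert np.isnan(res["recovery_fraction"])
        assert res["flags"]

    def test_generator_components_recovered_via_block_simulation(self):
        # blocking a component = regenerating without it
        train = 100.0 + np.arange(15) * 20.0
        full = sd.SynapseGenSpec.for_receptor("GABA_AB", seed=8, noise_sd=0.0)
        b_only = sd.SynapseGenSpec.for_receptor("GABA_AB", seed=8, noise_sd=0.0,
                                                gA_amp=0.0)
        amp = {}
        amp["baseline"] = sp.extract_ipsp(
            sd.generate_paired_recording(full, train)).amplitude
        amp["gabazine"] = sp.extract_ipsp(
            sd.generate_paired_recording(b_only, train)).amplitude
        res = sp.pharmacology_account(sp.PharmacologyLedger(
            amp["baseline"], amp["gabazine"], 0.0, amp["baseline"]))
        # fast component should carry most of the compound amplitude
        assert res["fast_component"] > res["slow_component"] > 0
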