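"""Morpho-electric feature extraction from current-clamp sweeps."""

import math

import numpy as np
import pytest

from hippoexc.ephys import (RampProtocol, StepProtocol, Sweep, SweepSet,
                            build_if_curve, classify_dgc_type,
                            compute_gain, compute_inactivation_threshold,
                            compute_passive, compute_rheobase, compute_secondary,
                            compute_spike_latency, detect_spikes, extract_features,
                            percent_of_control, predict_soma_volume)
from hippoexc.simulate import (NeuronModelParams, lif_spike_count,
                               simulate_current_clamp)

DT = 1e-4


def stamp_spikes(times_s, duration_s=1.2, v_rest=-70.0):
    """Synthetic trace with sharp 1-ms APs at given times."""
    n = int(duration_s / DT)
    v = np.full(n, v_rest)
    for t in times_s:
        i = int(t / DT)
        v[i : i + 5] = [-45.0, 20.0, 40.0, -20.0, -60.0][: max(0, min(5, n - i))]
    return Sweep(voltage=v, current=np.zeros(n))


class TestDetectSpikes:
    def test_subthreshold_sweep_empty(self):
        sw = Sweep(np.full(10000, -70.0), np.zeros(10000))
        assert detect_spikes(sw, DT) == []

    def test_recovers_stamped_lif_spikes(self, lif_params, lif_step_set):
        for sweep, truth in zip(lif_step_set.sweeps, lif_step_set.truth["spike_times"]):
            spikes = detect_spikes(sweep, lif_step_set.dt)
            assert len(spikes) == len(truth)
            for s, t in zip(spikes, truth):
                assert abs(s.t_s - t) <= 2 * lif_step_set.dt

    def test_count_nonincreasing_in_threshold(self):
        sw = stamp_spikes([0.2, 0.5, 0.8])
        n_low = len(detect_spikes(sw, DT, dvdt_threshold=20.0))
        n_high = len(detect_spikes(sw, DT, dvdt_threshold=40.0))
        assert n_high <= n_low

    def test_waveform_metrics_sensible(self, lif_step_set):
        spikes = detect_spikes(lif_step_set.sweeps[-1], lif_step_set.dt)
        s = spikes[0]
        assert s.peak_mv > s.threshold_mv
        assert s.amplitude_mv == pytest.approx(s.peak_mv - s.threshold_mv)
        assert s.half_width_ms > 0
        assert s.fahp_mv > 0


class TestIfCurve:
    def test_all_subthreshold(self):
        p = NeuronModelParams(r_in_mohm=100.0, c_m_pf=100.0)
        ss = simulate_current_clamp(p, StepProtocol(10.0, 10.0, 5))
        assert all(n == 0 for _, n in build_if_curve(ss))

    def test_matches_closed_form_lif_rate(self, lif_params, lif_step_set):
        curve = build_if_curve(lif_step_set)
        for i_pa, n in curve:
            expect = lif_spike_count(lif_params, i_pa, 1.0)
            assert abs(n - expect) <= 1

    def test_duplicate_currents_rejected(self):
        p = NeuronModelParams()
        ss = simulate_current_clamp(p, StepProtocol(50.0, 0.0, 2))
        with pytest.raises(ValueError, match="duplicate"):
            build_if_curve(ss)

    def test_ramp_input_rejected(self, lif_ramp_set):
        with pytest.raises(ValueError):
            build_if_curve(lif_ramp_set)


class TestGainRheobase:
    def test_exact_linear_gain(self):
        curve = [(0.0, 0), (50.0, 2), (100.0, 4), (150.0, 6)]
        assert compute_gain(curve) == pytest.approx(0.04)

    def test_flat_curve_zero_slope(self):
        assert compute_gain([(50.0, 3), (100.0, 3), (150.0, 3), (200.0, 3)]) == \
            pytest.approx(0.0)

    def test_too_few_points_missing(self):
        assert compute_gain([(50.0, 0), (100.0, 5)]) is None

    def test_descending_limb_excluded(self):
        # depolarization block after 150 pA must not drag the slope down
        curve = [(50.0, 2), (100.0, 4), (150.0, 6), (200.0, 1), (250.0, 0)]
        assert compute_gain(curve) == pytest.approx(0.04)

    def test_rheobase_first_suprathreshold(self):
        assert compute_rheobase([(50.0, 0), (100.0, 0), (150.0, 2)]) == 150.0
        assert compute_rheobase([(50.0, 0), (100.0, 0)]) is None

    def test_lif_rheobase_within_one_step(self, lif_params, lif_step_set):
        # analytic rheobase: (V_thresh - V_rest)/R_in = 100 pA
        curve = build_if_curve(lif_step_set)
        assert abs(compute_rheobase(curve) - lif_params.rheobase_pa) <= 10.0

    def test_gain_monotone_in_r_in_at_fixed_tau(self):
        # higher R_in at fixed membrane time constant (smaller cell) means a
        # steeper I-F curve; at fixed C_m the refractory-saturated region
        # would instead flatten the fit for high-R_in neurons
        gains = []
        for r in (100.0, 150.0, 200.0, 250.0):
            p = NeuronModelParams(r_in_mohm=r, c_m_pf=20000.0 / r)
            ss = simulate_current_clamp(p, StepProtocol(20.0, 20.0, 15))
            gains.append(compute_gain(build_if_curve(ss)))
        assert all(b > a for a, b in zip(gains, gains[1:]))


class TestSpikeLatency:
    def test_no_spike_missing(self):
        p = NeuronModelParams(r_in_mohm=100.0, c_m_pf=100.0)
        ss = simulate_current_clamp(p, RampProtocol(peak_pa=10.0))
        assert compute_spike_latency(ss) is None

    def test_matches_fine_grid_integration(self, lif_params, lif_ramp_set):
        latency = compute_spike_latency(lif_ramp_set)
        # independent oracle: brute-force Euler integration at 10x resolution
        dt = 1e-5
        tau = lif_params.tau_s
        v = lif_params.v_rest_mv
        t_first = None
        for j in range(int(1.0 / dt)):
            i_pa = 800.0 * j * dt / 1.0
            v += dt / tau * (-(v - lif_params.v_rest_mv) + i_pa * lif_params.r_in_mohm * 1e-3)
            if v >= lif_params.v_thresh_mv:
                t_first = j * dt
                break
        assert t_first is not None
        assert abs(latency - t_first * 1e3) <= 2 * lif_ramp_set.dt * 1e3

    def test_latency_increases_when_r_in_halved(self):
        lat = []
        for r in (200.0, 100.0):
            p = NeuronModelParams(r_in_mohm=r, c_m_pf=100.0)
            lat.append(compute_spike_latency(simulate_current_clamp(p, RampProtocol())))
        assert lat[1] > lat[0]


class TestPassive:
    def test_recovers_rc_parameters(self, lif_passive_set):
        params, ss = lif_passive_set
        r_in, c_m, rmp = compute_passive(ss)
        assert abs(r_in - 150.0) / 150.0 < 0.05
        assert abs(c_m - 120.0) / 120.0 < 0.05
        assert rmp == pytest.approx(params.v_rest_mv, abs=0.1)

    def test_steady_state_deflection_closed_form(self, lif_passive_set):
        # R=150 MOhm, I=-50 pA: steady-state dV = -7.5 mV; tau = RC = 18 ms
        _, ss = lif_passive_set
        proto = ss.protocol
        sw = ss.sweeps[0]
        i1 = int((proto.pre_s + proto.duration_s) / ss.dt)
        dv = sw.voltage[i1 - 100 : i1].mean() - sw.voltage[: int(proto.pre_s / ss.dt)].mean()
        assert dv == pytest.approx(-7.5, abs=0.05)
        r_in, c_m, _ = compute_passive(ss)
        assert r_in * c_m * 1e-3 == pytest.approx(18.0, rel=0.05)  # tau in ms

    def test_zero_current_returns_rmp_only(self):
        p = NeuronModelParams(v_rest_mv=-68.0)
        ss = simulate_current_clamp(p, StepProtocol(0.0, 0.0, 1))
        r_in, c_m, rmp = compute_passive(ss)
        assert math.isnan(r_in) and math.isnan(c_m)
        assert rmp == pytest.approx(-68.0, abs=0.01)

    def test_doubling_c_doubles_tau(self):
        taus = []
        for c in (100.0, 200.0):
            p = NeuronModelParams(r_in_mohm=150.0, c_m_pf=c)
            ss = simulate_current_clamp(p, StepProtocol(-50.0, 0.0, 1))
            r_in, c_m, _ = compute_passive(ss)
            taus.append(r_in * c_m)
        assert taus[1] / taus[0] == pytest.approx(2.0, rel=0.05)

    def test_spiking_step_rejected(self, lif_params):
        ss = simulate_current_clamp(lif_params, StepProtocol(300.0, 0.0, 1))
        with pytest.raises(ValueError, match="spikes"):
            compute_passive(ss)


class TestSecondaryAndInactivation:
    def test_max_rate_is_max_count(self):
        assert compute_secondary([(50.0, 0), (100.0, 3), (150.0, 7), (200.0, 5)])[0] == 7.0

    def test_accommodation_from_isi_sequence(self):
        times = [0.2, 0.21, 0.23, 0.27, 0.35]  # ISIs 10, 20, 40, 80 ms
        sw = stamp_spikes(times)
        ss = SweepSet([sw], DT, StepProtocol(100.0, 0.0, 1))
        ss.sweeps[0].current[int(0.1 / DT) : int(1.1 / DT)] = 100.0
        _, acc = compute_secondary([(100.0, 5)], ss)
        assert acc == pytest.approx(8.0, rel=0.01)

    def test_regular_train_accommodation_one(self, lif_params):
        ss = simulate_current_clamp(lif_params, StepProtocol(150.0, 0.0, 1))
        curve = build_if_curve(ss)
        _, acc = compute_secondary(curve, ss)
        assert acc == pytest.approx(1.0, abs=0.05)

    def test_monotone_counts_no_inactivation(self):
        assert compute_inactivation_threshold([(50.0, 1), (100.0, 3), (150.0, 6)]) is None

    def test_block_pattern_enumeration(self):
        curve = [(100.0, 2), (200.0, 8), (300.0, 10), (400.0, 3), (500.0, 0)]
        # rule by rule: max 10 at 300; first later step with count < 50% of max is 400
        assert compute_inactivation_threshold(curve) == 400.0

    def test_sustained_firing_lif_no_block(self, lif_step_set):
        assert compute_inactivation_threshold(build_if_curve(lif_step_set),
                                              lif_step_set) is None


class TestDgcClassification:
    def test_all_none_all_type_ii(self):
        labels, cut = classify_dgc_type([None, None, None])
        assert labels == ["II", "II", "II"]

    def test_bimodal_mixture_recovery(self):
        rng = np.random.default_rng(0)
        low = rng.normal(150.0, 30.0, 60)
        high = rng.normal(400.0, 30.0, 60)
        thresholds = list(np.r_[low, high])
        labels, cut = classify_dgc_type(thresholds)
        truth = ["I"] * 60 + ["II"] * 60
        agree = np.mean([a == b for a, b in zip(labels, truth)])
        assert agree >= 0.95
        assert 200.0 < cut < 350.0

    def test_manual_cutoff_respected(self):
        labels, cut = classify_dgc_type([100.0, 300.0, None], cutoff=200.0)
        assert labels == ["I", "II", "II"]
        assert cut == 200.0

    def test_unimodal_warns(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="unimodal"):
            labels, _ = classify_dgc_type(list(rng.normal(200.0, 5.0, 50)))
        assert set(labels) == {"I"}


class TestSomaVolume:
    def test_hand_computed_reference(self):
        # C_m = 90 pF at 0.9 µF/cm²: A = 1e4 µm², V = 9.40e4 µm³
        v = predict_soma_volume(90.0)
        assert v == pytest.approx(9.40e4, rel=0.005)

    def test_scaling_law(self):
        assert predict_soma_volume(180.0) / predict_soma_volume(90.0) == \
            pytest.approx(2 ** 1.5, rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            predict_soma_volume(0.0)


class TestPercentOfControl:
    def test_reference_cases(self):
        assert percent_of_control([20.0], [10.0, 20.0, 30.0])[0] == pytest.approx(100.0)
        assert percent_of_control([40.0], [10.0, 20.0, 30.0])[0] == pytest.approx(200.0)

    def test_permutation_invariant(self):
        a = percent_of_control([15.0], [1.0, 2.0, 3.0])
        b = percent_of_control([15.0], [3.0, 1.0, 2.0])
        assert a[0] == b[0]

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_of_control([1.0], [-1.0, 1.0])


class TestFeatureRelations:
    def test_cm_rin_inverse_at_fixed_tau(self):
        # family with constant tau = R*C: fitted C_m anticorrelates with R_in
        rs = np.linspace(100.0, 300.0, 8)
        feats = []
        for r in rs:
            c = 24000.0 / r  # tau fixed at 24 ms
            p = NeuronModelParams(r_in_mohm=r, c_m_pf=c)
            ss = simulate_current_clamp(p, StepProtocol(-50.0, 0.0, 1))
            r_fit, c_fit, _ = compute_passive(ss)
            feats.append((r_fit, c_fit))
        r_fit = np.array([f[0] for f in feats])
        c_fit = np.array([f[1] for f in feats])
        assert np.corrcoef(r_fit, c_fit)[0, 1] < -0.9

    def test_extract_features_deterministic(self, lif_params, lif_step_set,
                                            lif_ramp_set, lif_passive_set):
        f1 = extract_features(lif_step_set, lif_ramp_set, lif_passive_set[1])
        f2 = extract_features(lif_step_set, lif_ramp_set, lif_passive_set[1])
        assert f1.as_dict() == f2.as_dict()
        assert f1.rheobase_pa is not None and f1.gain is not None
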