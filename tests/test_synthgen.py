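"""Generators: closed-form fidelity, determinism and planted ground truth."""

import json
import math

import numpy as np
import pytest

from nocistudy.iolib import ValidationError
from nocistudy.study import DEV_CONTROL_AP_TARGETS
from nocistudy.synthgen import (
    APTemplateParams,
    DegGeneratorSpec,
    HeatCurrentParams,
    InfeasibleTemplateError,
    PassiveCellParams,
    SpikingCellParams,
    generate_deg_tables,
    generate_variant_table,
    heat_activation_threshold_analytic,
    lif_first_spike_latency,
    random_feasible_ap_params,
    simulate_heat_sweep,
    simulate_ir_protocol,
    simulate_spiking_protocol,
    solve_ap_template,
    synth_ap_waveform,
)


class TestIrProtocol:
    def test_steady_state_deflection_is_ohmic(self):
        p = PassiveCellParams(R=1.0, tau=1.0, V_rest=-60.0, noise_sd=0.0)
        sweeps = simulate_ir_protocol(p, (-5.0, -10.0, -15.0, -20.0),
                                      step_dur=200.0)
        for sw, amp in zip(sweeps, (-5, -10, -15, -20)):
            on = sw.stimulus != 0
            assert sw.response[on][-1] == pytest.approx(-60.0 + amp, abs=1e-6)

    def test_matches_rc_closed_form_to_1e9(self):
        p = PassiveCellParams(R=1.53, tau=15.0, V_rest=-56.0, noise_sd=0.0)
        (sw,) = simulate_ir_protocol(p, (-10.0,), step_dur=200.0, baseline=50.0)
        on = (sw.time >= 50.0) & (sw.time < 250.0)
        expected = -56.0 - 10.0 * 1.53 * (1 - np.exp(-(sw.time[on] - 50.0) / 15.0))
        np.testing.assert_allclose(sw.response[on], expected, atol=1e-9)

    def test_same_seed_identical_traces(self):
        p = PassiveCellParams(R=1.0, tau=10.0, V_rest=-60.0, noise_sd=0.5)
        a = simulate_ir_protocol(p, seed=42)
        b = simulate_ir_protocol(p, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.response, y.response)

    def test_zero_amplitude_rejected(self):
        p = PassiveCellParams(R=1.0, tau=10.0, V_rest=-60.0)
        with pytest.raises(ValidationError):
            simulate_ir_protocol(p, (-5.0, 0.0))


class TestSpikingProtocol:
    P = SpikingCellParams(R=1.0, tau=30.0, V_rest=-60.0, spike_threshold=-40.0)

    def test_subthreshold_step_gives_zero_spikes(self):
        stim = np.full(2000, 15.0)  # 15 pA * 1 GOhm = 15 mV < 20 mV gap
        sw = simulate_spiking_protocol(self.P, stim, fs=20000.0)
        assert json.loads(sw.metadata["spike_times_ms"]) == []

    def test_first_spike_latency_matches_closed_form(self):
        for amp in (25.0, 40.0, 80.0):
            stim = np.full(4000, amp)
            sw = simulate_spiking_protocol(self.P, stim, fs=20000.0)
            (first, *_ ) = json.loads(sw.metadata["spike_times_ms"])
            analytic = lif_first_spike_latency(self.P, amp)
            assert 0 <= first - analytic <= sw.dt + 1e-12

    def test_adaptation_makes_isis_non_decreasing(self):
        p = SpikingCellParams(R=1.0, tau=30.0, V_rest=-60.0,
                              spike_threshold=-40.0,
                              adaptation_increment=5.0, adaptation_tau=10000.0)
        stim = np.full(50000, 60.0)
        sw = simulate_spiking_protocol(p, stim, fs=5000.0)
        times = np.array(json.loads(sw.metadata["spike_times_ms"]))
        assert len(times) > 3
        isis = np.diff(times)
        assert np.all(np.diff(isis) >= -1e-9)

    def test_fs_below_refractory_rejected(self):
        with pytest.raises(ValidationError, match="refractory"):
            simulate_spiking_protocol(self.P, np.full(100, 50.0), fs=100.0)

    def test_jit_and_pure_python_integrators_agree(self):
        from nocistudy.synthgen import _lif_core, _lif_core_py

        stim = np.concatenate([np.zeros(100), np.full(4000, 45.0),
                               np.linspace(0, 120.0, 4000)])
        args = (stim, 0.05, -60.0, 1.0, 30.0, -40.0, 44, 5.0, 800.0)
        v_jit, spk_jit = _lif_core(*args)
        v_py, spk_py = _lif_core_py(*args)
        np.testing.assert_array_equal(np.asarray(spk_jit), np.asarray(spk_py))
        np.testing.assert_allclose(np.asarray(v_jit), np.asarray(v_py),
                                   atol=1e-12)


class TestApTemplate:
    def test_control_column_extrema_equal_targets(self):
        """The solved template's analytic derivative extrema are the
        requested control-group waveform targets, exactly."""
        model = solve_ap_template(DEV_CONTROL_AP_TARGETS)
        truth = model.truth()
        assert truth["S1"] == DEV_CONTROL_AP_TARGETS.S1_target
        assert truth["S2"] == DEV_CONTROL_AP_TARGETS.S2_target
        assert truth["S3"] == DEV_CONTROL_AP_TARGETS.S3_target
        assert truth["t13"] == pytest.approx(4.21, abs=1e-12)
        # evaluate the analytic derivative on a fine grid: extrema match
        t = np.linspace(0, model.duration, 400001)
        dv = model.dvdt(t)
        assert dv.max() == pytest.approx(127.64, rel=1e-9)
        assert dv.min() == pytest.approx(-38.80, rel=1e-9)

    def test_voltage_hits_os_and_ahp(self):
        model = solve_ap_template(DEV_CONTROL_AP_TARGETS)
        t = np.linspace(0, model.duration, 200001)
        v = model.voltage(t)
        assert v.max() == pytest.approx(68.97, abs=1e-6)
        assert v.min() == pytest.approx(-66.66, abs=1e-6)
        assert v[0] == pytest.approx(-56.28, abs=1e-12)

    def test_monophasic_has_single_repolarization_minimum(self):
        p = APTemplateParams(
            V_rest=-56.0, threshold=-31.0, OS_target=50.0, AHP_target=-66.0,
            S1_target=117.0, S2_target=-93.0, S3_target=-93.0,
            t12_target=1.3, t23_target=0.0, biphasic=False,
        )
        model = solve_ap_template(p)
        t = np.linspace(0, model.duration, 200001)
        dv = model.dvdt(t)
        # only one contiguous region attains the repolarization minimum
        deep = np.flatnonzero(dv < 0.5 * dv.min())
        assert deep.size > 0
        assert (np.diff(deep) > 1).sum() == 0
        assert model.t2 == model.t3

    def test_doubling_fs_leaves_analytic_truth_unchanged(self):
        p = DEV_CONTROL_AP_TARGETS
        sw20 = synth_ap_waveform(p, fs=20000.0)
        sw40 = synth_ap_waveform(p, fs=40000.0)
        assert sw20.metadata["truth"] == sw40.metadata["truth"]
        # sampled derivative extremum converges to the analytic value
        d20 = np.gradient(sw20.response, sw20.dt).max()
        d40 = np.gradient(sw40.response, sw40.dt).max()
        assert abs(d40 - 127.64) <= abs(d20 - 127.64) + 1e-9
        assert abs(d40 - 127.64) / 127.64 < 0.01

    def test_infeasible_targets_raise(self):
        with pytest.raises(ValidationError):
            # overshoot below threshold is not a valid waveform
            APTemplateParams(
                V_rest=-56.0, threshold=-29.0, OS_target=-35.0,
                AHP_target=-66.0, S1_target=120.0, S2_target=-40.0,
                S3_target=-30.0, t12_target=1.6, t23_target=2.5,
            )
        with pytest.raises(InfeasibleTemplateError):
            # speeds far too small to cover the excursion in the phase gaps
            solve_ap_template(APTemplateParams(
                V_rest=-56.0, threshold=-29.0, OS_target=69.0,
                AHP_target=-66.0, S1_target=120.0, S2_target=-10.0,
                S3_target=-10.0, t12_target=1.0, t23_target=1.0,
            ))

    def test_low_sampling_rate_refused(self):
        with pytest.raises(ValidationError):
            synth_ap_waveform(DEV_CONTROL_AP_TARGETS, fs=5000.0)

    def test_random_feasible_draws_solve(self, rng):
        for _ in range(20):
            p = random_feasible_ap_params(rng)
            model = solve_ap_template(p)
            assert model.truth()["S1"] == p.S1_target


class TestHeatSweep:
    def test_unresponsive_cell_is_exactly_linear(self):
        p = HeatCurrentParams(responsive=False, leak_slope=-0.01, noise_sd=0.0)
        sw = simulate_heat_sweep(p)
        expected = -0.01 * (sw.stimulus - sw.stimulus[0])
        np.testing.assert_allclose(sw.response, expected, atol=1e-12)

    def test_boltzmann_crossing_closed_form(self):
        p = HeatCurrentParams(T_half=41.0, slope=1.0, g_max=-1.0,
                              leak_slope=0.0, responsive=True, noise_sd=0.0)
        assert heat_activation_threshold_analytic(p, -0.2) == pytest.approx(
            41.0 - math.log(4.0), abs=1e-12
        )

    def test_same_seed_identical_noise(self):
        p = HeatCurrentParams(noise_sd=0.02)
        a = simulate_heat_sweep(p, seed=9)
        b = simulate_heat_sweep(p, seed=9)
        np.testing.assert_array_equal(a.response, b.response)

    def test_nonpositive_ramp_duration_rejected(self):
        with pytest.raises(ValidationError):
            simulate_heat_sweep(HeatCurrentParams(), ramp_dur=0.0)


class TestDegGenerator:
    def test_planted_counts_recovered_structurally(self):
        spec = DegGeneratorSpec(n_genes=3000, n_deg_A=600, n_deg_A_strong=90,
                                n_deg_B=40, n_core_overlap=12, seed=0)
        a, b, truth = generate_deg_tables(spec)
        sig_a = {r.gene for r in a if r.qvalue < 0.05}
        strong_a = {r.gene for r in a if r.qvalue < 0.05 and abs(r.log2fc) > 1}
        sig_b = {r.gene for r in b if r.qvalue < 0.05}
        assert len(sig_a) == 600 and len(strong_a) == 90 and len(sig_b) == 40
        assert sorted(strong_a & sig_b) == truth["core"]
        assert len(truth["core"]) == 12

    def test_zero_overlap_gives_empty_intersection(self):
        spec = DegGeneratorSpec(n_genes=1000, n_deg_A=100, n_deg_A_strong=30,
                                n_deg_B=20, n_core_overlap=0, seed=1)
        a, b, truth = generate_deg_tables(spec)
        strong_a = {r.gene for r in a if r.qvalue < 0.05 and abs(r.log2fc) > 1}
        sig_b = {r.gene for r in b if r.qvalue < 0.05}
        assert strong_a & sig_b == set()

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ValidationError):
            DegGeneratorSpec(n_genes=100, n_deg_A=50, n_deg_A_strong=10,
                             n_deg_B=5, n_core_overlap=8)

    def test_pvalues_never_exceed_qvalues(self):
        spec = DegGeneratorSpec(n_genes=500, n_deg_A=100, n_deg_A_strong=20,
                                n_deg_B=10, n_core_overlap=5, seed=2)
        a, b, _ = generate_deg_tables(spec)
        assert all(r.pvalue <= r.qvalue for r in a + b)


class TestVariantGenerator:
    def test_all_planted_all_retained(self):
        from nocistudy.varseg import segregation_filter

        recs, planted = generate_variant_table(6, planted_shared=6, seed=0)
        calls = segregation_filter(recs)
        assert all(c.retained for c in calls)
        assert sorted(planted) == sorted(c.gene for c in calls)

    def test_none_planted_none_retained(self):
        from nocistudy.varseg import segregation_filter

        recs, planted = generate_variant_table(9, planted_shared=0, seed=1)
        assert planted == []
        assert not any(c.retained for c in segregation_filter(recs))

    def test_planted_exceeding_candidates_rejected(self):
        with pytest.raises(ValidationError):
            generate_variant_table(3, planted_shared=4)
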