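"""Per-cell analysis operations against analytic and construction oracles."""

import math

import numpy as np
import pytest

from nocistudy import ephys
from nocistudy.iolib import CURRENT_CLAMP, VOLTAGE_CLAMP, SweepRecording, ValidationError
from nocistudy.study import DEV_CONTROL_AP_TARGETS
from nocistudy.synthgen import (
    APTemplateParams,
    HeatCurrentParams,
    PassiveCellParams,
    SpikingCellParams,
    heat_activation_threshold_analytic,
    lif_first_spike_latency,
    make_lif_cell,
    simulate_heat_sweep,
    simulate_ir_protocol,
    solve_ap_template,
    stamp_peak_delay,
    synth_ap_waveform,
    synth_prepulse_pair,
)


def _flat_sweep(n=1000, fs=20000.0, level=-60.0):
    t = np.arange(n) * (1000.0 / fs)
    return SweepRecording(fs, CURRENT_CLAMP, t, np.full(n, level), np.zeros(n))


class TestInputResistance:
    def test_exact_on_ideal_resistor(self):
        # tau much shorter than a sample: the cell is an ideal resistor
        p = PassiveCellParams(R=1.0, tau=1e-4, V_rest=-60.0, noise_sd=0.0)
        sweeps = simulate_ir_protocol(p, (-5.0, -10.0, -15.0, -20.0),
                                      step_dur=100.0, fs=1000.0)
        assert ephys.input_resistance(sweeps) == pytest.approx(1.0, rel=1e-6)

    def test_rc_cell_recovered_within_one_percent(self):
        p = PassiveCellParams(R=1.53, tau=15.0, V_rest=-56.0, noise_sd=0.0)
        sweeps = simulate_ir_protocol(p, step_dur=200.0)
        assert ephys.input_resistance(sweeps) == pytest.approx(1.53, abs=0.01)

    def test_depolarizing_steps_rejected(self):
        p = PassiveCellParams(R=1.0, tau=10.0, V_rest=-60.0)
        sweeps = simulate_ir_protocol(p, (-5.0, -10.0))
        flipped = [
            SweepRecording(s.sample_rate, s.clamp_mode, s.time, s.response,
                           -s.stimulus)
            for s in sweeps
        ]
        with pytest.raises(ValidationError, match="hyperpolarizing"):
            ephys.input_resistance(flipped)


class TestDetectAps:
    def test_flat_trace_has_no_spikes(self):
        assert len(ephys.detect_aps(_flat_sweep())) == 0

    def test_inserted_template_found_at_crossing(self):
        sw = synth_ap_waveform(DEV_CONTROL_AP_TARGETS, fs=20000.0)
        spikes = ephys.detect_aps(sw)
        assert len(spikes) == 1
        # the analytic waveform crosses 0 mV on the upstroke
        model = solve_ap_template(DEV_CONTROL_AP_TARGETS)
        above = sw.time[sw.response >= 0.0]
        assert abs(spikes[0] - above[0]) <= sw.dt + 1e-12
        assert model.t1 - 1.0 < spikes[0] < model.t2

    def test_lockout_merges_nearby_crossings(self):
        fs = 20000.0
        n = 2000
        t = np.arange(n) * (1000.0 / fs)
        v = np.full(n, -60.0)
        for t0 in (50.0, 51.0):  # two crossings 1 ms apart
            k = int(t0 * fs / 1000.0)
            v[k : k + 6] = 20.0
        sw = SweepRecording(fs, CURRENT_CLAMP, t, v, np.zeros(n))
        assert len(ephys.detect_aps(sw, lockout=2.0)) == 1
        assert len(ephys.detect_aps(sw, lockout=0.5)) == 2


class TestFindRheobase:
    def test_within_one_increment_of_effective_analytic(self, rng):
        """Grid search lands within one 5-pA increment above the
        closed-form threshold current for the effective step duration
        (the stamped AP peak must still fall inside the step)."""
        delay = stamp_peak_delay(2.2, 20000.0)
        for _ in range(25):
            p = SpikingCellParams(
                R=rng.uniform(0.5, 2.0), tau=rng.uniform(20.0, 200.0),
                V_rest=-60.0, spike_threshold=rng.uniform(-45.0, -25.0),
            )
            t_eff = 50.0 - delay
            i_eff = (p.spike_threshold - p.V_rest) / (
                p.R * (1.0 - math.exp(-t_eff / p.tau))
            )
            got = ephys.find_rheobase(make_lif_cell(p), i_max=800.0)
            assert got is not None
            assert i_eff - 5.0 - 0.2 <= got <= i_eff + 5.0 + 0.2

    def test_discrete_oracle_equality(self, rng):
        """The search equals a closed-form enumeration of the discrete
        crossing-plus-peak criterion on the same 5-pA grid."""
        fs, dt = 20000.0, 0.05
        delay = stamp_peak_delay(2.2, fs)
        for _ in range(25):
            p = SpikingCellParams(
                R=rng.uniform(0.5, 2.0), tau=rng.uniform(20.0, 200.0),
                V_rest=-60.0, spike_threshold=rng.uniform(-45.0, -25.0),
            )
            expect = None
            for k in range(1, 200):
                amp = 5.0 * k
                lat = lif_first_spike_latency(p, amp)
                if math.isfinite(lat) and math.ceil(lat / dt) * dt + delay <= 50.0:
                    expect = amp
                    break
            got = ephys.find_rheobase(make_lif_cell(p), i_max=1000.0, fs=fs)
            assert got == expect

    def test_passive_cell_reported_non_excitable(self):
        p = SpikingCellParams(R=0.1, tau=20.0, V_rest=-60.0,
                              spike_threshold=30.0)
        assert ephys.find_rheobase(make_lif_cell(p), i_max=500.0) is None


class TestExtractApFeatures:
    def test_table_control_template_recovered(self):
        """Control-column waveform targets: S1 within 2% of 127.64
        mV/ms and AP width t1-t3 within 5% of 4.21 ms at 20 kHz."""
        sw = synth_ap_waveform(DEV_CONTROL_AP_TARGETS, fs=20000.0)
        f = ephys.extract_ap_features(sw)
        assert f.S1 == pytest.approx(127.64, rel=0.02)
        assert f.t13 == pytest.approx(4.21, rel=0.05)
        assert f.biphasic

    def test_monophasic_template_flagged(self):
        p = APTemplateParams(
            V_rest=-56.29, threshold=-30.89, OS_target=49.89,
            AHP_target=-66.66, S1_target=116.94, S2_target=-92.89,
            S3_target=-92.89, t12_target=1.3, t23_target=0.0, biphasic=False,
        )
        f = ephys.extract_ap_features(synth_ap_waveform(p, fs=20000.0))
        assert not f.biphasic
        assert f.t23 == 0.0
        assert f.S3 == f.S2

    def test_low_sample_rate_refused(self):
        sw = _flat_sweep(fs=5000.0)
        with pytest.warns(UserWarning):
            with pytest.raises(ValidationError):
                ephys.extract_ap_features(sw, spike_time=10.0)

    def test_fs_consistency_40_vs_20_khz(self):
        f20 = ephys.extract_ap_features(
            synth_ap_waveform(DEV_CONTROL_AP_TARGETS, fs=20000.0))
        f40 = ephys.extract_ap_features(
            synth_ap_waveform(DEV_CONTROL_AP_TARGETS, fs=40000.0))
        for k in ("S1", "S2", "S3", "OS", "AHP", "ap_threshold"):
            assert getattr(f20, k) == pytest.approx(getattr(f40, k), rel=0.01)
        assert f20.t13 == pytest.approx(f40.t13, rel=0.01)


class TestCounting:
    CELL = SpikingCellParams(R=1.0, tau=30.0, V_rest=-60.0,
                             spike_threshold=-40.0)

    def test_passive_ramps_count_zero(self):
        p = SpikingCellParams(R=0.05, tau=20.0, V_rest=-60.0,
                              spike_threshold=0.0)
        counts = ephys.count_ramp_aps(make_lif_cell(p), I_AP=10.0,
                                      ramp_dur=500.0)
        assert counts == (0, 0, 0)

    def test_ramp_counts_match_fine_timestep_refinement(self):
        # adapting cell with well-separated spikes: counts are invariant
        # to a 10x-finer integration step
        cell = make_lif_cell(
            SpikingCellParams(R=1.0, tau=30.0, V_rest=-60.0,
                              spike_threshold=-40.0,
                              adaptation_increment=4.0,
                              adaptation_tau=3000.0))
        coarse = ephys.count_ramp_aps(cell, I_AP=30.0, ramp_dur=1000.0,
                                      fs=2000.0)
        fine = ephys.count_ramp_aps(cell, I_AP=30.0, ramp_dur=1000.0,
                                    fs=20000.0)
        assert coarse == fine == (3, 10, 17)

    def test_ramp_counts_monotone_in_amplitude(self):
        cell = make_lif_cell(self.CELL)
        counts = ephys.count_ramp_aps(cell, I_AP=25.0,
                                      multiples=(1, 2, 3, 4), ramp_dur=1000.0)
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_block_bins_half_open_and_conserving(self):
        fs = 1000.0
        spikes_at = (0.0, 2500.0, 5000.0)

        def fake_cell(stim, fs_):
            n = len(stim)
            t = np.arange(n) * (1000.0 / fs_)
            v = np.full(n, -60.0)
            for s in spikes_at:
                # a crossing needs one sub-level sample before it
                k = max(1, int(s * fs_ / 1000.0))
                v[k : k + 4] = 20.0
            return SweepRecording(fs_, CURRENT_CLAMP, t, v, stim)

        bins, total = ephys.count_block_aps(fake_cell, I_AP=10.0,
                                            dur=20000.0, bin_width=2500.0,
                                            fs=fs)
        # a spike exactly on a boundary belongs to the later bin
        assert bins == (1, 1, 1, 0, 0, 0, 0, 0)
        assert total == sum(bins) == 3

    def test_block_total_equals_detected_spikes(self):
        cell = make_lif_cell(
            SpikingCellParams(R=1.0, tau=30.0, V_rest=-60.0,
                              spike_threshold=-40.0,
                              adaptation_increment=3.0, adaptation_tau=500.0))
        bins, total = ephys.count_block_aps(cell, I_AP=30.0, dur=5000.0,
                                            bin_width=2500.0, fs=5000.0)
        assert total == sum(bins) > 0

    def test_non_divisible_duration_rejected(self):
        with pytest.raises(ValidationError):
            ephys.count_block_aps(make_lif_cell(self.CELL), I_AP=30.0,
                                  dur=20000.0, bin_width=3000.0)


class TestHeatClassification:
    def test_pure_leak_not_responsive(self):
        p = HeatCurrentParams(responsive=False, leak_slope=-0.01)
        hr = ephys.classify_heat_response(simulate_heat_sweep(p))
        assert not hr.responsive and hr.T_act is None

    def test_boltzmann_threshold_within_one_sample(self):
        p = HeatCurrentParams(T_half=41.0, slope=1.0, g_max=-1.0,
                              leak_slope=-0.002, responsive=True)
        sw = simulate_heat_sweep(p, T_start=22.0, T_end=50.0,
                                 ramp_dur=5000.0, fs=1000.0)
        hr = ephys.classify_heat_response(sw)
        analytic = heat_activation_threshold_analytic(p, -0.2)
        dT = np.diff(sw.stimulus)[0]
        assert hr.responsive
        assert abs(hr.T_act - analytic) <= dT + 1e-12

    def test_non_monotone_temperature_rejected(self):
        sw = simulate_heat_sweep(HeatCurrentParams())
        bad = SweepRecording(sw.sample_rate, VOLTAGE_CLAMP, sw.time,
                             sw.response, sw.stimulus[::-1].copy())
        with pytest.raises(ValidationError):
            ephys.classify_heat_response(bad)


class TestPrepulse:
    def test_identical_sweeps_give_zero_fraction(self):
        a, _ = synth_prepulse_pair(-2.0, 0.5)
        assert ephys.prepulse_fractions(a, a).ttx_s_fraction == 0.0

    def test_mixture_fraction_recovered(self):
        a, b = synth_prepulse_pair(-2.0, 0.6, fs=20000.0)
        res = ephys.prepulse_fractions(a, b)
        assert res.ttx_s_fraction == pytest.approx(0.60, abs=0.01)

    def test_pure_sensitive_current_gives_fraction_one(self):
        a, b = synth_prepulse_pair(-2.0, 1.0)
        assert ephys.prepulse_fractions(a, b).ttx_s_fraction == pytest.approx(1.0)

    def test_excess_resistant_current_clamped_with_warning(self):
        a, b = synth_prepulse_pair(-2.0, 0.0)
        bigger = SweepRecording(b.sample_rate, b.clamp_mode, b.time,
                                b.response * 1.5, b.stimulus)
        with pytest.warns(UserWarning):
            res = ephys.prepulse_fractions(a, bigger)
        assert res.ttx_s_fraction == 0.0
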