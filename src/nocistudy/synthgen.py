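"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure each analysis stage
assumes, not the biophysics of real sensory neurons:

* passive RC responses to hyperpolarizing current steps (input
  resistance via Ohm's law);
* a leaky integrate-and-fire neuron with spike-frequency adaptation for
  the excitability protocols (rheobase search, 5-s ramps, 20-s block);
* a piecewise-analytic action-potential template whose first-derivative
  extrema (maximal depolarization speed S1, repolarization speeds S2 and
  S3 of the biphasic "shoulder") and their times are known in closed
  form, so the waveform-decomposition code can be tested against exact
  targets;
* Boltzmann-activated inward currents riding on a linear leak for the
  heat-ramp responsiveness classifier;
* planted-effect differential-expression tables and candidate-variant
  tables with known segregation ground truth.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .iolib import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    DegRecord,
    SweepRecording,
    ValidationError,
    VariantRecord,
)

__all__ = [
    "PassiveCellParams",
    "SpikingCellParams",
    "APTemplateParams",
    "HeatCurrentParams",
    "DegGeneratorSpec",
    "InfeasibleTemplateError",
    "APTemplateModel",
    "simulate_ir_protocol",
    "simulate_spiking_protocol",
    "make_lif_cell",
    "stamp_peak_delay",
    "lif_rheobase_analytic",
    "lif_first_spike_latency",
    "solve_ap_template",
    "synth_ap_waveform",
    "random_feasible_ap_params",
    "simulate_heat_sweep",
    "heat_activation_threshold_analytic",
    "synth_prepulse_pair",
    "generate_deg_tables",
    "generate_variant_table",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PassiveCellParams:
    """Passive membrane: resistance (GOhm), time constant (ms), rest (mV)."""

    R: float
    tau: float
    V_rest: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.R <= 0 or self.tau <= 0 or self.noise_sd < 0:
            raise ValidationError("require R > 0, tau > 0, noise_sd >= 0")


@dataclass(frozen=True)
class SpikingCellParams:
    """Leaky integrate-and-fire neuron with spike-frequency adaptation.

    Between spikes the membrane follows
    ``tau dV/dt = -(V - V_rest) + R (I_stim - I_adapt)``; a spike is
    emitted when V reaches ``spike_threshold``, the adaptation current
    increments by ``adaptation_increment`` (pA) and decays with
    ``adaptation_tau`` (ms), and the voltage is reset after an absolute
    ``refractory`` period during which a stereotyped AP shape is stamped
    into the trace.
    """

    R: float
    tau: float
    V_rest: float
    spike_threshold: float
    refractory: float = 2.2
    adaptation_increment: float = 0.0
    adaptation_tau: float = 1000.0

    def __post_init__(self) -> None:
        if self.spike_threshold <= self.V_rest:
            raise ValidationError("spike_threshold must exceed V_rest")
        if self.refractory <= 0 or self.adaptation_tau <= 0:
            raise ValidationError("refractory and adaptation_tau must be > 0")
        if self.R <= 0 or self.tau <= 0:
            raise ValidationError("require R > 0 and tau > 0")


@dataclass(frozen=True)
class APTemplateParams:
    """Targets for the analytic action-potential template.

    ``S1_target`` is the maximal depolarization speed (mV/ms, positive);
    ``S2_target``/``S3_target`` the repolarization-phase derivative
    minima (negative, either magnitude ordering); ``t12_target`` and
    ``t23_target`` the time separations between the extrema.  With
    ``biphasic=False`` the repolarization collapses to a single phase
    (S3 = S2, t23 = 0).
    """

    V_rest: float
    threshold: float
    OS_target: float
    AHP_target: float
    S1_target: float
    S2_target: float
    S3_target: float
    t12_target: float
    t23_target: float
    biphasic: bool = True

    def __post_init__(self) -> None:
        if not (self.OS_target > self.threshold > self.V_rest > self.AHP_target):
            raise ValidationError(
                "require OS > threshold > V_rest > AHP "
                f"(got {self.OS_target}, {self.threshold}, {self.V_rest}, "
                f"{self.AHP_target})"
            )
        if self.S1_target <= 0:
            raise ValidationError("S1_target must be positive")
        if self.S2_target >= 0 or (self.biphasic and self.S3_target >= 0):
            raise ValidationError("S2_target and S3_target must be negative")
        if self.t12_target <= 0:
            raise ValidationError("t12_target must be positive")
        if self.biphasic and self.t23_target <= 0:
            raise ValidationError("t23_target must be positive when biphasic")


@dataclass(frozen=True)
class HeatCurrentParams:
    """Boltzmann-activated inward current on a linear leak.

    ``current(T) = leak_slope * (T - T_start) + g_max / (1 + exp((T_half - T)/slope))``
    with the second term present only when ``responsive``.  ``g_max`` is
    negative (inward convention).
    """

    T_half: float = 41.0
    slope: float = 1.0
    g_max: float = -1.0
    leak_slope: float = -0.002
    responsive: bool = True
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("slope must be positive")
        if self.responsive and self.g_max > 0:
            raise ValidationError("g_max must be <= 0 (inward) when responsive")


@dataclass(frozen=True)
class DegGeneratorSpec:
    """Planted structure for a pair of DE tables A (developmental-like)
    and B (adult-like) over a shared gene universe.

    Defaults mirror the study conditions this pipeline targets: 5,851
    significant genes in A, 868 of them with |log2FC| > 1, 67
    significant genes in B, and 35 genes planted in both the strong-A
    and the B lists.
    """

    n_genes: int = 15000
    n_deg_A: int = 5851
    n_deg_A_strong: int = 868
    n_deg_B: int = 67
    n_core_overlap: int = 35
    strong_lfc_range: tuple[float, float] = (1.05, 3.5)
    weak_lfc_range: tuple[float, float] = (0.1, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core_overlap > min(self.n_deg_A_strong, self.n_deg_B):
            raise ValidationError(
                "n_core_overlap exceeds min(n_deg_A_strong, n_deg_B)"
            )
        if self.n_deg_A_strong > self.n_deg_A or self.n_deg_A > self.n_genes:
            raise ValidationError("require n_deg_A_strong <= n_deg_A <= n_genes")
        if self.n_deg_B > self.n_genes:
            raise ValidationError("n_deg_B exceeds n_genes")
        # non-overlap B genes must avoid the strong-A list
        if self.n_deg_B - self.n_core_overlap > self.n_genes - self.n_deg_A_strong:
            raise ValidationError("not enough genes outside strong-A for B")
        if not self.weak_lfc_range[1] < 1.0 < self.strong_lfc_range[0]:
            raise ValidationError("lfc ranges must straddle the |log2FC|=1 cut")


# ---------------------------------------------------------------------------
# passive RC protocol
# ---------------------------------------------------------------------------


def _rc_step_response(
    params: PassiveCellParams,
    amplitude: float,
    t: np.ndarray,
    onset: float,
    offset: float,
) -> np.ndarray:
    """Closed-form RC response to a current step of ``amplitude`` pA."""
    v = np.full_like(t, params.V_rest)
    on = (t >= onset) & (t < offset)
    v[on] += amplitude * params.R * (1.0 - np.exp(-(t[on] - onset) / params.tau))
    after = t >= offset
    v_off = amplitude * params.R * (1.0 - math.exp(-(offset - onset) / params.tau))
    v[after] += v_off * np.exp(-(t[after] - offset) / params.tau)
    return v


def simulate_ir_protocol(
    params: PassiveCellParams,
    step_amplitudes: Sequence[float] = (-5.0, -10.0, -15.0, -20.0),
    step_dur: float = 200.0,
    fs: float = 5000.0,
    seed: int = 0,
    baseline: float = 50.0,
    tail: float = 100.0,
) -> list[SweepRecording]:
    """Hyperpolarizing-step sweeps of a passive cell (one per amplitude).

    The noiseless response follows the RC closed form
    ``V(t) = V_rest + I R (1 - exp(-t/tau))`` during the step; Gaussian
    noise of sd ``noise_sd`` is added on top, seeded.
    """
    if any(a == 0 for a in step_amplitudes):
        raise ValidationError("zero step amplitude in sequence")
    rng = np.random.default_rng(seed)
    dt = 1000.0 / fs
    n = int(round((baseline + step_dur + tail) / dt))
    t = np.arange(n) * dt
    sweeps = []
    for amp in step_amplitudes:
        v = _rc_step_response(params, amp, t, baseline, baseline + step_dur)
        if params.noise_sd > 0:
            v = v + rng.normal(0.0, params.noise_sd, size=n)
        stim = np.where((t >= baseline) & (t < baseline + step_dur), amp, 0.0)
        sweeps.append(
            SweepRecording(
                sample_rate=fs,
                clamp_mode=CURRENT_CLAMP,
                time=t,
                response=v,
                stimulus=stim,
                metadata={"step_pa": repr(float(amp)), "true_R_gohm": repr(params.R)},
            )
        )
    return sweeps


# ---------------------------------------------------------------------------
# leaky integrate-and-fire with adaptation
# ---------------------------------------------------------------------------


def _lif_core_py(stim, dt, v_rest, R, tau, theta, refr_steps, inc, tau_a):
    n = stim.shape[0]
    v = np.empty(n)
    spikes = np.empty(n, dtype=np.int64)
    n_spk = 0
    decay_v = math.exp(-dt / tau)
    decay_a = math.exp(-dt / tau_a)
    state = v_rest
    i_a = 0.0
    k = 0
    while k < n:
        v_inf = v_rest + R * (stim[k] - i_a)
        state = v_inf + (state - v_inf) * decay_v if k > 0 else v_rest
        i_a *= decay_a
        if state >= theta:
            spikes[n_spk] = k
            n_spk += 1
            i_a += inc
            stop = min(k + refr_steps, n)
            for j in range(k, stop):
                v[j] = v_rest
                i_a *= decay_a
            i_a /= decay_a  # the spike sample's decay was already applied
            k = stop
            state = v_rest
            continue
        v[k] = state
        k += 1
    return v, spikes[:n_spk]


try:  # optional JIT of the integrator hot loop
    from numba import njit as _njit

    _lif_core = _njit(cache=False)(_lif_core_py)
except Exception:  # pragma: no cover - numba present in the supported env
    _lif_core = _lif_core_py


def stamp_peak_delay(refractory: float, fs: float) -> float:
    """Delay (ms) from threshold crossing to the stamped AP's peak.

    The stereotyped AP shape peaks one third of the way into the
    refractory window; protocol criteria that gate on the AP *peak*
    time (the rheobase step criterion) see crossings this much earlier.
    """
    dt = 1000.0 / fs
    refr_steps = max(1, int(round(refractory / dt)))
    return max(1, refr_steps // 3) * dt


def _ap_stamp(dt: float, refr_steps: int, theta: float, v_rest: float) -> np.ndarray:
    """Stereotyped AP shape covering the refractory window.

    Piecewise linear: threshold -> +40 mV peak in the first third,
    decay to 5 mV below rest by the end (detection level 0 mV is
    crossed exactly once on the way up).
    """
    k_peak = max(1, refr_steps // 3)
    rise = np.linspace(theta, 40.0, k_peak, endpoint=False)
    fall = np.linspace(40.0, v_rest - 5.0, refr_steps - k_peak)
    return np.concatenate([rise, fall])


def simulate_spiking_protocol(
    params: SpikingCellParams,
    stimulus: np.ndarray | SweepRecording,
    fs: float,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> SweepRecording:
    """Simulate the adapting LIF response to an arbitrary stimulus.

    ``stimulus`` is a pA array on a uniform grid at ``fs`` (or a
    current-clamp :class:`SweepRecording` whose stimulus channel is
    used).  Spikes are stamped as a stereotyped AP template at the
    threshold-crossing sample; spike times (ms) are reported in
    ``metadata["spike_times_ms"]``.
    """
    if isinstance(stimulus, SweepRecording):
        stim = np.asarray(stimulus.stimulus, dtype=float)
        fs = stimulus.sample_rate
    else:
        stim = np.asarray(stimulus, dtype=float)
    dt = 1000.0 / fs
    if dt > params.refractory:
        raise ValidationError(
            f"sampling interval {dt} ms cannot honor refractory "
            f"{params.refractory} ms"
        )
    refr_steps = max(1, int(round(params.refractory / dt)))
    v, spk = _lif_core(
        stim, dt, params.V_rest, params.R, params.tau,
        params.spike_threshold, refr_steps, params.adaptation_increment,
        params.adaptation_tau,
    )
    v = np.array(v, copy=True)
    stamp = _ap_stamp(dt, refr_steps, params.spike_threshold, params.V_rest)
    for k in spk:
        seg = stamp[: len(v) - k]
        v[k : k + len(seg)] = seg
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=len(v))
    t = np.arange(len(stim)) * dt
    spike_times = (np.asarray(spk, dtype=float) * dt).tolist()
    return SweepRecording(
        sample_rate=fs,
        clamp_mode=CURRENT_CLAMP,
        time=t,
        response=v,
        stimulus=stim,
        metadata={"spike_times_ms": json.dumps(spike_times)},
    )


def make_lif_cell(
    params: SpikingCellParams, seed: int = 0, noise_sd: float = 0.0
) -> Callable[[np.ndarray, float], SweepRecording]:
    """Adapter: a cell-response closure ``fn(stimulus_pA, fs) -> sweep``.

    This is the interface the protocol drivers (rheobase search, ramp
    and block counting) consume; a recorded-sweep lookup can implement
    the same signature.
    """

    def cell(stimulus: np.ndarray, fs: float) -> SweepRecording:
        return simulate_spiking_protocol(params, stimulus, fs, seed=seed,
                                         noise_sd=noise_sd)

    return cell


def lif_rheobase_analytic(params: SpikingCellParams, step_dur: float = 50.0) -> float:
    """Minimal constant current (pA) reaching threshold within ``step_dur``.

    From the closed-form step response:
    ``I = (theta - V_rest) / (R (1 - exp(-step_dur/tau)))``.
    """
    return (params.spike_threshold - params.V_rest) / (
        params.R * (1.0 - math.exp(-step_dur / params.tau))
    )


def lif_first_spike_latency(params: SpikingCellParams, amplitude: float) -> float:
    """Closed-form latency ``-tau ln(1 - (theta - V_rest)/(I R))`` in ms.

    Returns ``inf`` for subthreshold amplitudes.
    """
    drive = amplitude * params.R
    gap = params.spike_threshold - params.V_rest
    if drive <= gap:
        return math.inf
    return -params.tau * math.log(1.0 - gap / drive)


# ---------------------------------------------------------------------------
# analytic action-potential template
# ---------------------------------------------------------------------------


class InfeasibleTemplateError(ValidationError):
    """The requested extrema/timing targets cannot coexist."""


@dataclass(frozen=True)
class _Bump:
    """A C1 plateau bump in dV/dt: sin^2 ramps of width ``r`` flanking a
    flat top of width ``p`` at amplitude ``A``, centered at ``tc``.

    The bump integrates to ``A (p + r)`` and its extremum is exactly
    ``A`` over the plateau (a strict extremum at ``tc`` when p = 0).
    """

    tc: float
    A: float
    p: float
    r: float

    @property
    def area(self) -> float:
        return self.A * (self.p + self.r)

    @property
    def half_width(self) -> float:
        return self.p / 2.0 + self.r

    def dvdt(self, t: np.ndarray) -> np.ndarray:
        x = np.abs(np.asarray(t, dtype=float) - self.tc)
        out = np.zeros_like(x)
        out[x <= self.p / 2.0] = self.A
        edge = (x > self.p / 2.0) & (x < self.half_width)
        d = x[edge] - self.p / 2.0
        out[edge] = self.A * np.cos(np.pi * d / (2.0 * self.r)) ** 2
        return out

    def integral(self, t: np.ndarray) -> np.ndarray:
        """Closed-form cumulative integral from -inf to t."""
        t = np.asarray(t, dtype=float)
        a0 = self.tc - self.half_width        # left edge start
        a1 = self.tc - self.p / 2.0           # plateau start
        a2 = self.tc + self.p / 2.0           # plateau end
        A, r = self.A, self.r
        out = np.zeros_like(t)

        def ramp_up(u):  # integral of A sin^2(pi u / 2r) on [0, u]
            return A * (u / 2.0 - (r / (2.0 * np.pi)) * np.sin(np.pi * u / r))

        def ramp_down(u):  # integral of A cos^2(pi u / 2r) on [0, u]
            return A * (u / 2.0 + (r / (2.0 * np.pi)) * np.sin(np.pi * u / r))

        m = (t > a0) & (t <= a1)
        out[m] = ramp_up(t[m] - a0)
        m = (t > a1) & (t <= a2)
        out[m] = ramp_up(r) + A * (t[m] - a1)
        m = (t > a2) & (t <= a2 + r)
        out[m] = ramp_up(r) + A * self.p + ramp_down(t[m] - a2)
        out[t > a2 + r] = self.area
        return out


def _bump_for(area: float, amp: float, tc: float, r_pref: float) -> _Bump:
    """Bump with requested signed area and peak amplitude ``amp``."""
    q = area / amp  # net duration p + r, positive by construction
    if q <= 0:
        raise InfeasibleTemplateError("phase area and amplitude disagree in sign")
    r = min(r_pref, q)
    return _Bump(tc=tc, A=amp, p=q - r, r=r)


def _bump_width(area: float, amp: float, r_pref: float) -> float:
    q = area / amp
    return q + min(r_pref, q)


@dataclass(frozen=True)
class APTemplateModel:
    """Solved piecewise-analytic AP waveform.

    ``bumps`` are the dV/dt segments in temporal order (foot, upstroke,
    one or two repolarization phases, AHP recovery); the derivative
    extrema of the waveform equal the construction targets exactly.
    """

    params: APTemplateParams
    bumps: tuple[_Bump, ...]
    t1: float
    t2: float
    t3: float
    stim_onset: float
    duration: float

    def voltage(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        v = np.full_like(t, self.params.V_rest)
        for b in self.bumps:
            v = v + b.integral(t)
        return v

    def dvdt(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for b in self.bumps:
            out = out + b.dvdt(t)
        return out

    def truth(self) -> dict[str, float]:
        """Closed-form extrema of the constructed waveform."""
        p = self.params
        return {
            "V_mem": p.V_rest,
            "ap_threshold": p.threshold,
            "OS": p.OS_target,
            "AHP": p.AHP_target,
            "S1": p.S1_target,
            "S2": p.S2_target,
            "S3": p.S3_target if p.biphasic else p.S2_target,
            "t1": self.t1,
            "t2": self.t2,
            "t3": self.t3,
            "t12": self.t2 - self.t1,
            "t23": self.t3 - self.t2,
            "t13": self.t3 - self.t1,
            "biphasic": float(p.biphasic),
        }


def solve_ap_template(
    params: APTemplateParams,
    baseline: float = 20.0,
    foot_slope: float = 4.0,
    recovery_slope: float = 1.5,
    edge_ms: float = 0.15,
    gap_ms: float = 0.08,
    min_phase_ms: float = 0.3,
) -> APTemplateModel:
    """Map waveform targets to analytic dV/dt segments.

    Segments in order: a slow sub-threshold foot (V_rest -> threshold at
    ``foot_slope`` mV/ms), the upstroke plateau bump peaking exactly at
    S1, one or two repolarization bumps peaking at S2 (and S3), and a
    slow AHP recovery back to rest.  Segment supports must not overlap;
    an infeasible target combination (speeds too small to cover the
    voltage excursions in the requested phase separations) raises
    :class:`InfeasibleTemplateError`.
    """
    p = params
    rise = p.OS_target - p.threshold
    drop = p.OS_target - p.AHP_target
    if rise / p.S1_target < min_phase_ms:
        raise InfeasibleTemplateError(
            "upstroke too brief: the rise cannot sustain S1 for the "
            f"minimum phase duration {min_phase_ms} ms"
        )
    w1 = _bump_width(rise, p.S1_target, edge_ms)

    if p.biphasic:
        # Split the total repolarization drop between the S2 and S3
        # phases so that neither support collides with its neighbors.
        # Feasible split fractions are found by scanning; the middle of
        # the feasible interval is used (no tuning knob).
        cand = np.linspace(0.02, 0.98, 241)
        feasible = []
        for f in cand:
            d2, d3 = f * drop, (1.0 - f) * drop
            # each phase must sustain its peak speed for a minimum time,
            # otherwise the extremum degenerates to an unresolvable blip
            if (-d2 / p.S2_target < min_phase_ms
                    or -d3 / p.S3_target < min_phase_ms):
                continue
            w2 = _bump_width(-d2, p.S2_target, edge_ms)
            w3 = _bump_width(-d3, p.S3_target, edge_ms)
            ok_a = w1 / 2.0 + gap_ms + w2 / 2.0 <= p.t12_target
            ok_b = w2 / 2.0 + gap_ms + w3 / 2.0 <= p.t23_target
            if ok_a and ok_b:
                feasible.append(f)
        if not feasible:
            raise InfeasibleTemplateError(
                "no feasible S2/S3 drop split: phase speeds too small for "
                "the requested OS-AHP excursion within t12/t23"
            )
        f = feasible[len(feasible) // 2]
        d2, d3 = f * drop, (1.0 - f) * drop
    else:
        d2, d3 = drop, 0.0
        if -d2 / p.S2_target < min_phase_ms:
            raise InfeasibleTemplateError(
                "repolarization too brief to sustain S2 for the minimum "
                "phase duration"
            )
        w2 = _bump_width(-d2, p.S2_target, edge_ms)
        if w1 / 2.0 + gap_ms + w2 / 2.0 > p.t12_target:
            raise InfeasibleTemplateError(
                "monophasic repolarization cannot cover OS-AHP at S2 "
                "within t12"
            )

    foot_area = p.threshold - p.V_rest
    w_foot = _bump_width(foot_area, foot_slope, 4 * edge_ms)
    t1 = baseline + gap_ms + w_foot + gap_ms + w1 / 2.0
    t2 = t1 + p.t12_target
    t3 = t2 + p.t23_target if p.biphasic else t2

    bumps = [
        _bump_for(foot_area, foot_slope, baseline + gap_ms + w_foot / 2.0,
                  4 * edge_ms),
        _bump_for(rise, p.S1_target, t1, edge_ms),
        _bump_for(-d2, p.S2_target, t2, edge_ms),
    ]
    last_end = t2 + bumps[-1].half_width
    if p.biphasic:
        bumps.append(_bump_for(-d3, p.S3_target, t3, edge_ms))
        last_end = t3 + bumps[-1].half_width

    rec_area = p.V_rest - p.AHP_target
    w_rec = _bump_width(rec_area, recovery_slope, 4 * edge_ms)
    bumps.append(
        _bump_for(rec_area, recovery_slope, last_end + gap_ms + w_rec / 2.0,
                  4 * edge_ms)
    )
    duration = max(last_end + gap_ms + w_rec, t1 + 55.0) + 5.0
    return APTemplateModel(
        params=p, bumps=tuple(bumps), t1=t1, t2=t2, t3=t3,
        stim_onset=baseline, duration=duration,
    )


def synth_ap_waveform(
    params: APTemplateParams,
    fs: float = 20000.0,
    stim_amplitude: float = 100.0,
    **solver_kwargs,
) -> SweepRecording:
    """Sample the analytic AP template on a uniform grid at ``fs``.

    Requires ``fs >= 20000`` Hz (the rate the waveform-decomposition
    stage assumes); the stimulus channel carries a nominal depolarizing
    step from ``stim_onset`` so a pre-stimulus baseline exists for the
    resting-potential estimate.  Ground-truth extrema are stored as JSON
    in the sweep metadata.
    """
    if fs < 20000.0:
        raise ValidationError("AP templates must be sampled at >= 20 kHz")
    model = solve_ap_template(params, **solver_kwargs)
    dt = 1000.0 / fs
    n = int(round(model.duration / dt))
    t = np.arange(n) * dt
    v = model.voltage(t)
    stim = np.where(t >= model.stim_onset, stim_amplitude, 0.0)
    return SweepRecording(
        sample_rate=fs,
        clamp_mode=CURRENT_CLAMP,
        time=t,
        response=v,
        stimulus=stim,
        metadata={"truth": json.dumps(model.truth())},
    )


def random_feasible_ap_params(
    rng: np.random.Generator, biphasic: bool = True, max_tries: int = 200
) -> APTemplateParams:
    """Draw template targets from plausible nociceptor ranges, retrying
    until the solver accepts them (guaranteed-feasible fixture source)."""
    for _ in range(max_tries):
        v_rest = rng.uniform(-62.0, -52.0)
        thr = rng.uniform(-34.0, -24.0)
        os_ = rng.uniform(45.0, 72.0)
        ahp = rng.uniform(-72.0, v_rest - 4.0)
        s1 = rng.uniform(70.0, 140.0)
        s2 = -rng.uniform(25.0, 95.0)
        s3 = -rng.uniform(20.0, 90.0)
        t12 = rng.uniform(1.0, 2.6)
        t23 = rng.uniform(1.8, 6.0)
        try:
            p = APTemplateParams(
                V_rest=v_rest, threshold=thr, OS_target=os_, AHP_target=ahp,
                S1_target=s1, S2_target=s2, S3_target=s3,
                t12_target=t12, t23_target=t23 if biphasic else 0.0,
                biphasic=biphasic,
            )
            solve_ap_template(p)
            return p
        except ValidationError:
            continue
    raise RuntimeError("could not draw feasible AP template parameters")


# ---------------------------------------------------------------------------
# heat-ramp inward currents
# ---------------------------------------------------------------------------


def simulate_heat_sweep(
    params: HeatCurrentParams,
    T_start: float = 22.0,
    T_end: float = 50.0,
    ramp_dur: float = 5000.0,
    fs: float = 1000.0,
    seed: int = 0,
) -> SweepRecording:
    """Voltage-clamp sweep of a heat ramp; stimulus channel carries T(t).

    Temperature rises linearly from ``T_start`` (room temperature) to
    ``T_end`` over ``ramp_dur`` ms.  The recorded current (nA) is a
    linear leak plus, for responsive cells, a Boltzmann activation term.
    """
    if ramp_dur <= 0:
        raise ValidationError("ramp_dur must be positive")
    if T_end <= T_start:
        raise ValidationError("T_end must exceed T_start")
    dt = 1000.0 / fs
    n = int(round(ramp_dur / dt)) + 1
    t = np.arange(n) * dt
    temp = T_start + (T_end - T_start) * t / ramp_dur
    current = params.leak_slope * (temp - T_start)
    if params.responsive:
        current = current + params.g_max / (
            1.0 + np.exp((params.T_half - temp) / params.slope)
        )
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, params.noise_sd, size=n)
    return SweepRecording(
        sample_rate=fs,
        clamp_mode=VOLTAGE_CLAMP,
        time=t,
        response=current,
        stimulus=temp,
        metadata={"true_T_half": repr(params.T_half)},
    )


def heat_activation_threshold_analytic(
    params: HeatCurrentParams, threshold: float = -0.2
) -> float:
    """Temperature where the Boltzmann term alone crosses ``threshold``:
    ``T_half - slope * ln(g_max/threshold - 1)``."""
    ratio = params.g_max / threshold
    if not params.responsive or ratio <= 1.0:
        return math.inf
    return params.T_half - params.slope * math.log(ratio - 1.0)


# ---------------------------------------------------------------------------
# prepulse sodium-current fractionation
# ---------------------------------------------------------------------------


def synth_prepulse_pair(
    i_total: float = -2.0,
    ttx_s_fraction: float = 0.6,
    fs: float = 20000.0,
    prepulse_dur: float = 250.0,
    test_dur: float = 50.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[SweepRecording, SweepRecording]:
    """Two voltage-clamp sweeps mimicking conditioning-prepulse runs.

    After a -120 mV prepulse the full sodium current is available (peak
    inward ``i_total`` nA, negative); after a -40 mV prepulse only the
    TTX-resistant component ``(1 - ttx_s_fraction) * i_total`` remains.
    The transient is an alpha function at the test-pulse onset.
    """
    if not -1e-9 <= ttx_s_fraction <= 1 + 1e-9:
        raise ValidationError("ttx_s_fraction must lie in [0, 1]")
    if i_total >= 0:
        raise ValidationError("i_total is an inward (negative) peak")
    dt = 1000.0 / fs
    n = int(round((prepulse_dur + test_dur) / dt))
    t = np.arange(n) * dt
    rng = np.random.default_rng(seed)
    out = []
    for hold, frac in ((-120.0, 1.0), (-40.0, 1.0 - ttx_s_fraction)):
        stim = np.where(t < prepulse_dur, hold, -10.0)
        rel = np.clip(t - prepulse_dur, 0.0, None)
        tau = 1.0  # ms; alpha-function kinetics
        shape = (rel / tau) * np.exp(1.0 - rel / tau)  # peaks at 1.0
        shape[t < prepulse_dur] = 0.0
        current = frac * i_total * shape
        if noise_sd > 0:
            current = current + rng.normal(0.0, noise_sd, size=n)
        out.append(
            SweepRecording(
                sample_rate=fs,
                clamp_mode=VOLTAGE_CLAMP,
                time=t,
                response=current,
                stimulus=stim,
                metadata={"prepulse_mv": repr(hold)},
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# planted differential-expression tables
# ---------------------------------------------------------------------------


def generate_deg_tables(
    spec: DegGeneratorSpec,
) -> tuple[list[DegRecord], list[DegRecord], dict[str, list[str]]]:
    """Two DE tables with planted significant genes and a known core.

    Table A carries ``n_deg_A`` genes with q < 0.05, of which
    ``n_deg_A_strong`` also have |log2FC| > 1; table B carries
    ``n_deg_B`` significant genes; exactly ``n_core_overlap`` genes are
    planted in both the strong-A and B lists.  Null genes receive
    q >= 0.05 strictly, so downstream thresholding recovers the planted
    counts exactly for every seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"G{i:06d}" for i in range(spec.n_genes)])
    perm = rng.permutation(spec.n_genes)
    a_idx = perm[: spec.n_deg_A]
    strong_idx = a_idx[: spec.n_deg_A_strong]
    core_idx = strong_idx[: spec.n_core_overlap]
    outside_strong = np.setdiff1d(perm, strong_idx, assume_unique=True)
    extra_b = rng.choice(
        outside_strong, size=spec.n_deg_B - spec.n_core_overlap, replace=False
    )
    b_idx = np.concatenate([core_idx, extra_b])

    def build(idx_sig: np.ndarray, idx_strong: np.ndarray) -> list[DegRecord]:
        sig = np.zeros(spec.n_genes, dtype=bool)
        sig[idx_sig] = True
        strong = np.zeros(spec.n_genes, dtype=bool)
        strong[idx_strong] = True
        q = rng.uniform(0.0501, 1.0, size=spec.n_genes)
        q[sig] = rng.uniform(1e-8, 0.0499, size=sig.sum())
        pv = q * rng.uniform(0.05, 1.0, size=spec.n_genes)
        sign = rng.choice([-1.0, 1.0], size=spec.n_genes)
        lo_w, hi_w = spec.weak_lfc_range
        lo_s, hi_s = spec.strong_lfc_range
        lfc = sign * rng.uniform(lo_w, hi_w, size=spec.n_genes)
        lfc[strong] = sign[strong] * rng.uniform(lo_s, hi_s, size=strong.sum())
        return [
            DegRecord(g, float(f), float(p), float(qq))
            for g, f, p, qq in zip(genes, lfc, pv, q)
        ]

    # B "strong" genes: the planted core keeps |log2FC| > 1 in B as well,
    # matching genes dysregulated strongly in both conditions.
    table_a = build(a_idx, strong_idx)
    table_b = build(b_idx, core_idx)
    truth = {
        "deg_a": sorted(genes[a_idx].tolist()),
        "deg_a_strong": sorted(genes[strong_idx].tolist()),
        "deg_b": sorted(genes[b_idx].tolist()),
        "core": sorted(genes[core_idx].tolist()),
    }
    return table_a, table_b, truth


# ---------------------------------------------------------------------------
# planted candidate-variant tables
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


def generate_variant_table(
    n_candidates: int,
    affected: Sequence[str] = ("P1", "P2"),
    planted_shared: int = 0,
    seed: int = 0,
    carriers: Sequence[str] = (),
) -> tuple[list[VariantRecord], list[str]]:
    """Candidate variants with a known set of truly segregating records.

    Exactly ``planted_shared`` records carry the alternate allele in the
    required state (homozygous, or hemizygous on the male X) in every
    affected individual; the remainder mimic exclusion patterns seen in
    consanguineous-family exome screens (the second affected
    heterozygous or homozygous reference).  Returns the records and the
    list of planted genes.
    """
    if planted_shared > n_candidates:
        raise ValidationError("planted_shared exceeds n_candidates")
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    planted: list[str] = []
    index = affected[0]
    for i in range(n_candidates):
        gene = f"CAND{i + 1}"
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        ref, alt = _BASES[ref], _BASES[alt]
        x_linked = rng.random() < 0.2
        mode = "XLR" if x_linked else "AR"
        chrom = "chrX" if x_linked else f"chr{rng.integers(1, 23)}"
        pos = int(rng.integers(1_000_000, 200_000_000))
        shared = i < planted_shared
        genotypes: dict[str, str] = {}
        for j, ind in enumerate(affected):
            if x_linked:  # male X: single allele
                if shared or ind == index:
                    genotypes[ind] = alt
                else:
                    genotypes[ind] = ref
            else:
                if shared or ind == index:
                    genotypes[ind] = f"{alt}/{alt}"
                else:
                    genotypes[ind] = (
                        f"{ref}/{alt}" if rng.random() < 0.6 else f"{ref}/{ref}"
                    )
        for ind in carriers:
            genotypes[ind] = alt if x_linked else f"{ref}/{alt}"
        if shared:
            planted.append(gene)
        records.append(
            VariantRecord(
                gene=gene,
                genomic_change=f"{chrom}:g.{pos}{ref}>{alt}",
                zygosity_claimed="homozygous",
                inheritance=mode,
                genotypes=genotypes,
                panel="ID" if rng.random() < 0.5 else "Autism candidate",
                cadd=float(np.round(rng.uniform(15.0, 35.0), 1)),
                population_freq=float(10 ** rng.uniform(-6.0, -3.2)),
            )
        )
    order = rng.permutation(n_candidates)
    return [records[k] for k in order], sorted(planted)
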