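"""Single-neuron phenotyping from raw current/voltage-clamp sweeps.

Implements the full per-cell readout set of the patch-clamp protocols:

* passive input resistance by Ohm's law from hyperpolarizing steps;
* rheobase (I_AP): the minimal 50-ms block-pulse amplitude, on a 5-pA
  grid, that evokes a single action potential within the step;
* AP waveform decomposition from the first derivative of the evoked
  spike -- maximal depolarization speed S1 and the two repolarization
  speeds S2/S3 of the biphasic "shoulder", their times t1/t2/t3,
  threshold, overshoot (OS) and afterhyperpolarization (AHP);
* AP counting under 5-s ramps at 1x/2x/3x rheobase and a 20-s block at
  2x rheobase binned in 2.5-s windows;
* heat-ramp responsiveness classification (non-linear inward current
  crossing -0.2 nA over the linear baseline) with activation
  temperature T_act;
* TTX-sensitive current fractionation from conditioning-prepulse pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .iolib import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    SweepRecording,
    ValidationError,
)

__all__ = [
    "APFeatureSet",
    "ProtocolSummary",
    "HeatResponse",
    "PrepulseResult",
    "input_resistance",
    "detect_aps",
    "find_rheobase",
    "extract_ap_features",
    "count_ramp_aps",
    "count_block_aps",
    "classify_heat_response",
    "prepulse_fractions",
    "step_stimulus",
    "ramp_stimulus",
]

CellResponseFn = Callable[[np.ndarray, float], SweepRecording]


@dataclass(frozen=True)
class APFeatureSet:
    """Waveform quantities of one action potential.

    Times are absolute sweep times (ms); ``t12``/``t23``/``t13`` are the
    pairwise differences.  For a monophasic repolarization S3 = S2,
    t3 = t2 and ``biphasic`` is False.
    """

    V_mem: float
    ap_threshold: float
    OS: float
    AHP: float
    S1: float
    S2: float
    S3: float
    t1: float
    t2: float
    t3: float
    biphasic: bool

    @property
    def t12(self) -> float:
        return self.t2 - self.t1

    @property
    def t23(self) -> float:
        return self.t3 - self.t2

    @property
    def t13(self) -> float:
        return self.t3 - self.t1

    def __post_init__(self) -> None:
        if not self.t1 <= self.t2 <= self.t3:
            raise ValidationError("require t1 <= t2 <= t3")
        if self.S1 <= 0 or self.S2 >= 0 or self.S3 >= 0:
            raise ValidationError("require S1 > 0 and S2, S3 < 0")
        if not self.OS > self.ap_threshold > self.AHP:
            raise ValidationError("require OS > threshold > AHP")


@dataclass(frozen=True)
class ProtocolSummary:
    """Per-cell excitability summary across the stimulation protocols."""

    IR: float
    I_AP: float | None
    ramp_counts: tuple[int, ...]
    block_bins: tuple[int, ...]
    total_aps: int

    def __post_init__(self) -> None:
        if self.IR <= 0:
            raise ValidationError("IR must be positive")
        if self.total_aps != sum(self.block_bins):
            raise ValidationError("total_aps must equal sum(block_bins)")
        if any(c < 0 for c in self.ramp_counts + self.block_bins):
            raise ValidationError("counts must be non-negative")


@dataclass(frozen=True)
class HeatResponse:
    """Heat-ramp classification of one voltage-clamped neuron."""

    responsive: bool
    T_act: float | None
    baseline_slope: float
    peak_subtracted_current: float

    def __post_init__(self) -> None:
        if self.responsive != (self.T_act is not None):
            raise ValidationError("responsive iff T_act present")


@dataclass(frozen=True)
class PrepulseResult:
    """Peak inward currents after -120/-40 mV conditioning prepulses."""

    I_total: float
    I_resistant: float
    ttx_s_fraction: float


# ---------------------------------------------------------------------------
# passive properties
# ---------------------------------------------------------------------------


def _step_window(sweep: SweepRecording) -> tuple[int, int, float]:
    """Locate the constant nonzero stimulus step; returns (i0, i1, amp)."""
    nz = np.flatnonzero(sweep.stimulus != 0.0)
    if nz.size == 0:
        raise ValidationError("sweep has no stimulus step")
    i0, i1 = nz[0], nz[-1] + 1
    amp = sweep.stimulus[i0]
    if not np.all(sweep.stimulus[i0:i1] == amp):
        raise ValidationError("stimulus step is not constant")
    return int(i0), int(i1), float(amp)


def input_resistance(
    sweeps: Sequence[SweepRecording],
    settle_fraction: float = 0.2,
) -> float:
    """Input resistance (GOhm) by Ohm's law from hyperpolarizing steps.

    The steady-state deflection of each sweep (mean over the final
    ``settle_fraction`` of the step, relative to the pre-step baseline)
    is regressed against the injected current through the origin: the
    slope, in mV/pA = GOhm, is the input resistance.  A zero deflection
    at zero current is physically forced, hence the origin constraint.
    """
    if len(sweeps) < 2:
        raise ValidationError("need >= 2 step sweeps")
    dv, di = [], []
    for sw in sweeps:
        if sw.clamp_mode != CURRENT_CLAMP:
            raise ValidationError("input resistance needs current-clamp sweeps")
        i0, i1, amp = _step_window(sw)
        if amp >= 0:
            raise ValidationError("steps must be hyperpolarizing (negative)")
        n_step = i1 - i0
        n_settle = max(1, int(round(settle_fraction * n_step)))
        if n_settle >= n_step:
            raise ValidationError("step shorter than the settle window")
        baseline = float(np.mean(sw.response[:i0])) if i0 > 0 else float(sw.response[0])
        steady = float(np.mean(sw.response[i1 - n_settle : i1]))
        dv.append(steady - baseline)
        di.append(amp)
    dv_arr, di_arr = np.asarray(dv), np.asarray(di)
    return float(np.dot(dv_arr, di_arr) / np.dot(di_arr, di_arr))


# ---------------------------------------------------------------------------
# spike detection and protocol drivers
# ---------------------------------------------------------------------------


def detect_aps(
    sweep: SweepRecording,
    level: float = 0.0,
    lockout: float = 2.0,
) -> np.ndarray:
    """Spike times (ms): upward crossings of ``level`` with a refractory
    lockout -- a crossing within ``lockout`` ms of the previous accepted
    spike is ignored."""
    if sweep.clamp_mode != CURRENT_CLAMP:
        raise ValidationError("spike detection needs a current-clamp sweep")
    v = sweep.response
    up = np.flatnonzero((v[:-1] < level) & (v[1:] >= level)) + 1
    if up.size == 0:
        return np.empty(0)
    times = sweep.time[up]
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= lockout:
            kept.append(t)
    return np.asarray(kept)


def step_stimulus(amplitude: float, dur: float, fs: float,
                  tail: float = 10.0) -> np.ndarray:
    """Instantaneous block pulse of ``amplitude`` pA for ``dur`` ms."""
    dt = 1000.0 / fs
    n_on = int(round(dur / dt))
    n_tail = int(round(tail / dt))
    return np.concatenate([np.full(n_on, amplitude), np.zeros(n_tail)])


def ramp_stimulus(amplitude: float, dur: float, fs: float) -> np.ndarray:
    """Linear ramp from 0 to ``amplitude`` pA over ``dur`` ms."""
    n = int(round(dur * fs / 1000.0))
    return np.linspace(0.0, amplitude, n)


def _peak_time_after(sweep: SweepRecording, spike_time: float,
                     horizon: float = 5.0) -> float:
    """Time of the voltage maximum within ``horizon`` ms of a crossing."""
    i0 = int(np.searchsorted(sweep.time, spike_time))
    i1 = int(np.searchsorted(sweep.time, spike_time + horizon))
    i1 = max(i1, i0 + 1)
    return float(sweep.time[i0 + int(np.argmax(sweep.response[i0:i1]))])


def find_rheobase(
    cell_response_fn: CellResponseFn,
    step_dur: float = 50.0,
    increment: float = 5.0,
    i_max: float = 500.0,
    fs: float = 20000.0,
    detect_level: float = 0.0,
    lockout: float = 2.0,
) -> float | None:
    """Rheobase search on the grid increment, 2*increment, ..., <= i_max.

    Returns the smallest tested amplitude whose response contains at
    least one action potential whose *peak* falls within the step, or
    ``None`` when the cell is non-excitable up to ``i_max`` (a
    distinguished outcome, not an error).
    """
    amp = increment
    while amp <= i_max + 1e-9:
        sweep = cell_response_fn(step_stimulus(amp, step_dur, fs), fs)
        spikes = detect_aps(sweep, level=detect_level, lockout=lockout)
        for st in spikes:
            if _peak_time_after(sweep, st) <= step_dur:
                return float(amp)
        amp += increment
    return None


def count_ramp_aps(
    cell_response_fn: CellResponseFn,
    I_AP: float,
    multiples: Sequence[float] = (1.0, 2.0, 3.0),
    ramp_dur: float = 5000.0,
    fs: float = 5000.0,
    detect_level: float = 0.0,
    lockout: float = 2.0,
) -> tuple[int, ...]:
    """AP count for each 5-s ramp at the given multiples of rheobase."""
    counts = []
    for m in multiples:
        sweep = cell_response_fn(ramp_stimulus(m * I_AP, ramp_dur, fs), fs)
        counts.append(len(detect_aps(sweep, level=detect_level, lockout=lockout)))
    return tuple(counts)


def count_block_aps(
    cell_response_fn: CellResponseFn,
    I_AP: float,
    dur: float = 20000.0,
    bin_width: float = 2500.0,
    amplitude_factor: float = 2.0,
    fs: float = 5000.0,
    detect_level: float = 0.0,
    lockout: float = 2.0,
) -> tuple[tuple[int, ...], int]:
    """Spike counts of a long block depolarization at 2x rheobase, binned
    into half-open windows [k*w, (k+1)*w) -- a boundary spike belongs to
    the later bin.  Returns (bins, total); total always equals the
    number of detected spikes."""
    n_bins = dur / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValidationError("dur must be divisible by bin_width")
    n_bins = int(round(n_bins))
    sweep = cell_response_fn(
        step_stimulus(amplitude_factor * I_AP, dur, fs, tail=0.0), fs
    )
    spikes = detect_aps(sweep, level=detect_level, lockout=lockout)
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(spikes, bins=edges)
    bins = tuple(int(c) for c in hist)
    return bins, int(len(spikes))


# ---------------------------------------------------------------------------
# AP waveform decomposition
# ---------------------------------------------------------------------------


def _smooth_derivatives(
    v: np.ndarray, dt: float, window_ms: float, polyorder: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Polynomial-window smoothing, then central-difference derivatives."""
    win = max(polyorder + 2, int(round(window_ms / dt)))
    if win % 2 == 0:
        win += 1
    win = min(win, len(v) - 1 if (len(v) - 1) % 2 else len(v) - 2)
    vs = savgol_filter(v, win, polyorder) if win > polyorder else v.copy()
    dvdt = np.gradient(vs, dt)
    d2 = np.gradient(dvdt, dt)
    return vs, dvdt, d2


def _refine_extremum(raw: np.ndarray, center: float) -> tuple[float, float]:
    """Sub-sample peak (index, height) by a 3-point parabola on ``raw``.

    Exact on plateaus (the parabola degenerates to a constant) and
    accurate to fourth order on smooth strict peaks; falls back to the
    center sample when the local quadratic is not concave.
    """
    c = int(round(center))
    if c < 1 or c > len(raw) - 2:
        return center, float(raw[min(max(c, 0), len(raw) - 1)])
    y1, y2, y3 = float(raw[c - 1]), float(raw[c]), float(raw[c + 1])
    denom = y1 - 2.0 * y2 + y3
    if denom >= -(1e-6 * abs(y2) + 1e-9):
        return center, y2
    delta = 0.5 * (y1 - y3) / denom
    if abs(delta) > 1.0:
        return center, y2
    height = y2 - 0.25 * (y1 - y3) * delta
    return c + delta, height


def _derivative_extrema(
    signal: np.ndarray, time: np.ndarray, prominence: float,
    raw: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Locate maxima of ``signal`` robustly for flat and strict peaks.

    A derivative extremum of a spike waveform may be a plateau (the
    phase speed is sustained) rather than a point, and smoothing can
    ripple a plateau's edges.  Candidate peaks from a prominence-gated
    search are therefore expanded to the contiguous region within a
    small tolerance band of the peak height; overlapping regions are
    merged; each merged region reports its center time and the signal
    value at that center (the band is kept below the prominence gate so
    distinct phases never merge).

    Returns (times, heights, prominences) in temporal order.
    """
    idx, props = find_peaks(signal, prominence=prominence, plateau_size=1)
    if idx.size == 0:
        return np.empty(0), np.empty(0), np.empty(0)
    regions: list[list[float]] = []  # [start, end, prominence]
    n = len(signal)
    for pk, le, re, pr in zip(
        idx, props["left_edges"], props["right_edges"], props["prominences"]
    ):
        h = signal[pk]
        band = min(max(0.25, 0.04 * abs(h)), 0.8 * prominence)
        lo = int(le)
        while lo > 0 and signal[lo - 1] >= h - band:
            lo -= 1
        hi = int(re)
        while hi < n - 1 and signal[hi + 1] >= h - band:
            hi += 1
        if regions and lo <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], hi)
            regions[-1][2] = max(regions[-1][2], pr)
        else:
            regions.append([lo, hi, pr])
    if raw is None:
        raw = signal
    centers, heights, proms = [], [], []
    for lo, hi, pr in regions:
        h = float(np.max(signal[lo : hi + 1]))
        level = h - 0.5 * pr
        # sub-sample center: midpoint of the half-prominence crossings
        j = lo
        while j > 0 and signal[j - 1] >= level:
            j -= 1
        if j > 0 and signal[j] != signal[j - 1]:
            x_left = j - 1 + (level - signal[j - 1]) / (signal[j] - signal[j - 1])
        else:
            x_left = float(j)
        k = hi
        while k < n - 1 and signal[k + 1] >= level:
            k += 1
        if k < n - 1 and signal[k] != signal[k + 1]:
            x_right = k + (signal[k] - level) / (signal[k] - signal[k + 1])
        else:
            x_right = float(k)
        center, height = _refine_extremum(raw, (x_left + x_right) / 2.0)
        centers.append(center)
        heights.append(height)
        proms.append(pr)
    t = np.interp(np.array(centers), np.arange(len(time)), time)
    return t, np.array(heights), np.array(proms)


def extract_ap_features(
    sweep: SweepRecording,
    spike_time: float | None = None,
    smooth_window_ms: float = 0.35,
    prominence: float = 5.0,
    ahp_window_ms: float = 50.0,
    dvdt_threshold_fallback: float = 10.0,
    min_fs: float = 20000.0,
) -> APFeatureSet:
    """Decompose a single evoked AP via its first derivative.

    dV/dt is computed by central differences after polynomial-window
    smoothing.  S1 is the maximal dV/dt before the voltage peak (time
    t1); S2 and S3 are the two most prominent local minima of dV/dt
    after the peak, ordered by time (one qualifying minimum means a
    monophasic repolarization: S3 = S2, ``biphasic=False``).  The AP
    threshold is the membrane voltage at the last negative-to-positive
    sign change of d2V/dt2 preceding t1 (fallback: first sample with
    dV/dt >= 10 mV/ms).  OS is the voltage maximum, AHP the minimum
    within ``ahp_window_ms`` after the peak, V_mem the pre-stimulus
    baseline mean.
    """
    if sweep.clamp_mode != CURRENT_CLAMP:
        raise ValidationError("AP extraction needs a current-clamp sweep")
    if sweep.sample_rate < min_fs:
        warnings.warn(
            f"sample rate {sweep.sample_rate} Hz below the {min_fs} Hz the "
            "derivative decomposition assumes; refusing"
        )
        raise ValidationError("sample rate too low for AP decomposition")
    t = sweep.time
    dt = sweep.dt
    v = sweep.response

    # pre-stimulus baseline for the resting potential
    stim_on = np.flatnonzero(sweep.stimulus != 0.0)
    i_base = int(stim_on[0]) if stim_on.size else max(1, int(0.05 * len(v)))
    v_mem = float(np.mean(v[: max(1, i_base)]))

    if spike_time is None:
        spikes = detect_aps(sweep)
        if spikes.size != 1:
            raise ValidationError(
                f"expected exactly one AP in the sweep, found {spikes.size}"
            )
        spike_time = float(spikes[0])
    vs, dvdt, d2 = _smooth_derivatives(v, dt, smooth_window_ms)

    i_peak = int(np.argmax(v))
    os_ = float(np.max(v))
    t_peak = float(t[i_peak])
    if not (spike_time - 10.0 <= t_peak):
        raise ValidationError("no AP near the requested spike time")

    dvdt_raw = np.gradient(v, dt)

    # S1: maximal depolarization speed before the peak
    pre = slice(0, i_peak + 1)
    t1_cand, h1, _ = _derivative_extrema(dvdt[pre], t[pre], prominence,
                                         raw=dvdt_raw[pre])
    if t1_cand.size:
        j = int(np.argmax(h1))
        t1, s1 = float(t1_cand[j]), float(h1[j])
    else:
        j = int(np.argmax(dvdt[pre]))
        t1, s1 = float(t[j]), float(dvdt[j])
    if s1 <= 0:
        raise ValidationError("no depolarizing upstroke found")

    # S2/S3: prominence-ranked minima of dV/dt after the peak
    post = slice(i_peak, len(v))
    tmins, depths, proms = _derivative_extrema(-dvdt[post], t[post], prominence,
                                               raw=-dvdt_raw[post])
    if tmins.size == 0:
        raise ValidationError("no repolarization phase found")
    top = np.argsort(proms)[::-1][:2]
    top = np.sort(top)  # temporal order
    if top.size == 2:
        t2, t3 = float(tmins[top[0]]), float(tmins[top[1]])
        s2, s3 = float(-depths[top[0]]), float(-depths[top[1]])
        biphasic = True
    else:
        t2 = t3 = float(tmins[top[0]])
        s2 = s3 = float(-depths[top[0]])
        biphasic = False

    # threshold: last - -> + sign change of d2V/dt2 before the upstroke
    i1 = int(np.searchsorted(t, t1))
    thr = None
    eps = 1e-3 * float(np.max(np.abs(d2[: i1 + 1]))) if i1 > 0 else 0.0
    signs = np.where(d2[:i1] > eps, 1, np.where(d2[:i1] < -eps, -1, 0))
    nz = np.flatnonzero(signs)
    for a, b in zip(nz[:-1][::-1], nz[1:][::-1]):
        if signs[a] == -1 and signs[b] == 1:
            thr = float(vs[b])
            break
    if thr is None:
        above = np.flatnonzero(dvdt[: i_peak + 1] >= dvdt_threshold_fallback)
        if above.size == 0:
            raise ValidationError("could not locate the AP threshold")
        thr = float(vs[above[0]])

    i_ahp1 = min(len(v), i_peak + int(round(ahp_window_ms / dt)))
    ahp = float(np.min(v[i_peak:i_ahp1]))
    return APFeatureSet(
        V_mem=v_mem, ap_threshold=thr, OS=os_, AHP=ahp,
        S1=s1, S2=s2, S3=s3, t1=t1, t2=t2, t3=t3, biphasic=biphasic,
    )


# ---------------------------------------------------------------------------
# heat-ramp classification
# ---------------------------------------------------------------------------


def classify_heat_response(
    sweep: SweepRecording,
    threshold: float = -0.2,
    baseline_fraction: float = 0.2,
) -> HeatResponse:
    """Classify a heat-ramp sweep as responsive or not.

    The baseline is a linear fit of current against temperature over the
    first ``baseline_fraction`` of the ramp; a neuron is heat responsive
    when the baseline-subtracted current dips to ``threshold`` (-0.2 nA)
    or below.  T_act is the temperature at the first crossing.
    """
    if sweep.clamp_mode != VOLTAGE_CLAMP:
        raise ValidationError("heat classification needs a voltage-clamp sweep")
    temp = sweep.stimulus
    if np.any(np.diff(temp) < 0):
        raise ValidationError("temperature ramp must be monotone increasing")
    n0 = max(2, int(round(baseline_fraction * len(temp))))
    slope, intercept = np.polyfit(temp[:n0], sweep.response[:n0], 1)
    subtracted = sweep.response - (slope * temp + intercept)
    peak = float(np.min(subtracted))
    if peak > threshold:
        return HeatResponse(
            responsive=False, T_act=None,
            baseline_slope=float(slope), peak_subtracted_current=peak,
        )
    first = int(np.flatnonzero(subtracted <= threshold)[0])
    return HeatResponse(
        responsive=True, T_act=float(temp[first]),
        baseline_slope=float(slope), peak_subtracted_current=peak,
    )


# ---------------------------------------------------------------------------
# prepulse current fractionation
# ---------------------------------------------------------------------------


def _test_window(sweep: SweepRecording) -> slice:
    """Samples after the last stimulus level change (the test pulse)."""
    changes = np.flatnonzero(np.diff(sweep.stimulus) != 0.0)
    start = int(changes[-1]) + 1 if changes.size else 0
    return slice(start, len(sweep.stimulus))


def prepulse_fractions(
    sweep_minus120: SweepRecording,
    sweep_minus40: SweepRecording,
    tolerance: float = 0.02,
) -> PrepulseResult:
    """TTX-sensitive fraction from a conditioning-prepulse sweep pair.

    The -120 mV prepulse makes the full sodium current available
    (I_total); the -40 mV prepulse inactivates the TTX-sensitive
    component, leaving I_resistant.  Both peaks are the most negative
    current in the shared test-pulse window;
    ``ttx_s_fraction = 1 - |I_resistant| / |I_total|``, clamped to 0
    (with a warning) if the resistant peak exceeds the total beyond
    ``tolerance``.
    """
    for sw in (sweep_minus120, sweep_minus40):
        if sw.clamp_mode != VOLTAGE_CLAMP:
            raise ValidationError("prepulse sweeps must be voltage clamp")
    w1, w2 = _test_window(sweep_minus120), _test_window(sweep_minus40)
    i_total = float(np.min(sweep_minus120.response[w1]))
    i_res = float(np.min(sweep_minus40.response[w2]))
    if i_total >= 0:
        raise ValidationError("no inward current after the -120 mV prepulse")
    frac = 1.0 - abs(i_res) / abs(i_total)
    if frac < -tolerance:
        warnings.warn(
            "resistant current exceeds total beyond tolerance; "
            "fraction clamped to 0"
        )
    return PrepulseResult(
        I_total=i_total, I_resistant=i_res,
        ttx_s_fraction=float(np.clip(frac, 0.0, 1.0)),
    )
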