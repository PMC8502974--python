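# Methods

This note documents the models behind `nocistudy`, the choices made
where the design was genuinely open, and what the synthetic data do and
do not establish about real recordings.

## Synthetic neurons are per-protocol generators, not one biophysical cell

Each synthetic cell is a bundle of protocol-specific generators that
share the drawn input resistance and resting/threshold voltages but are
otherwise independent layers:

* **Passive layer** (input-resistance protocol): the RC closed form
  V(t) = V_rest + I·R·(1 − e^(−t/τ)) with additive Gaussian noise
  (default SD 0.3 mV), membrane τ ≈ 15 ms. Units are ms, mV, pA and
  GΩ throughout, so Ohm's-law code is unit-free (GΩ × pA = mV).
* **Excitability layer**: a leaky integrate-and-fire neuron with
  spike-frequency adaptation, τ dV/dt = −(V − V_rest) + R(I − I_a),
  dI_a/dt = −I_a/τ_a, I_a ← I_a + Δa at each spike, absolute
  refractory period 2.2 ms during which a stereotyped AP shape is
  stamped into the trace (peaking one third into the refractory
  window). Integration uses the exact exponential update per sample,
  so constant-step threshold crossings match the closed form
  −τ·ln(1 − (θ−V_rest)/(IR)) to within one sample. The LIF membrane
  constant is *solved from the drawn rheobase* (τ = −T/ln(1 −
  (θ−V_rest)/(I_AP·R)) with T = 50 ms), which decouples the
  excitability calibration from the passive layer's τ — a LIF cannot
  reproduce a nociceptor's rheobase and its passive time constant
  simultaneously, and the rheobase is the protocol readout being
  tested. The hot loop is JIT-compiled with numba when available; a
  bit-identical pure-Python path is kept and tested against it.
* **Waveform layer**: the AP template is a sum of C¹ plateau bumps in
  dV/dt — sin²-ramped flat-topped segments for the sub-threshold foot,
  the upstroke (peak exactly S1), one or two repolarization phases
  (peaks exactly S2, S3) and the afterhyperpolarization recovery —
  integrated in closed form. An internal solver maps user targets
  (S1–S3, t1-t2, t2-t3, overshoot, AHP, threshold) to segment areas
  and widths, splitting the overshoot-to-AHP drop between the S2 and
  S3 phases at the middle of the feasible interval. Each phase must
  sustain its peak speed for ≥ 0.3 ms; target combinations whose
  speeds cannot cover the voltage excursions inside the requested
  phase separations raise an infeasibility error rather than being
  silently adjusted. Flat-topped derivative extrema are deliberate:
  at the published repolarization speeds the overshoot-to-AHP drop
  *requires* near-peak speeds to be sustained, which is also what the
  repolarization shoulder of real nociceptor APs looks like in dV/dt.
* **Heat layer**: current(T) = leak_slope·(T − T_start) +
  g_max/(1 + e^((T_half − T)/slope)) on a linear 22 → 50 °C, 5-s ramp.
  Room temperature is fixed at 22 °C by convention (configurable). The
  −0.2 nA criterion crossing has the closed form
  T_half − slope·ln(g_max/(−0.2) − 1), valid when the Boltzmann tail is
  negligible inside the baseline-fit window.

## Feature extraction choices

* dV/dt is computed by central differences after Savitzky–Golay
  smoothing (0.35 ms window, order 3; configurable). Derivative
  extrema are localized robustly for both flat and strict peaks:
  prominence-gated candidate peaks (default gate 5 mV/ms) are expanded
  to the contiguous region within a small tolerance band of the peak,
  overlapping regions are merged, the time is the midpoint of the
  half-prominence flank crossings (sub-sample, by linear
  interpolation), and the value comes from a 3-point parabola on the
  *unsmoothed* derivative at that center — exact on plateaus,
  fourth-order accurate on strict peaks, and immune to the edge
  ripples smoothing introduces on flat tops.
* The AP threshold is the voltage at the last negative-to-positive
  sign change of d²V/dt² before the upstroke maximum (with a small
  dead band around zero), falling back to the first sample with
  dV/dt ≥ 10 mV/ms. This operationalizes the standard
  derivative-method reading; the smoothing filter of the original
  acquisition software is not published, so the window is a parameter.
* S2/S3 are the two most prominent post-peak minima ordered by time;
  when only one passes the prominence gate the AP is monophasic and
  S3 = S2, t3 = t2. The gate (5 mV/ms) is the exposed boundary between
  "biphasic" and "two nearby minima"; no published criterion exists.
* Overshoot and AHP are the raw trace extrema (AHP within 50 ms after
  the peak); the resting potential is the pre-stimulus baseline mean.
* Rheobase counts an AP only if its *peak* falls inside the 50-ms
  step, so the effective analytic threshold current corresponds to the
  step duration minus the stamped peak delay (~0.73 ms at 20 kHz).
* Spike counting uses upward 0-mV crossings with a 2-ms lockout;
  block-depolarization bins are half-open [k·w, (k+1)·w), boundary
  spikes to the later bin, and the bin total always equals the
  detected spike count.
* The steady-state window for IR is the last 20% of each step, and the
  ΔV–ΔI regression is constrained through the origin (zero current
  forces zero deflection).

## Population calibration

The group tables of the source study give a center and a spread per
quantity; the spread is used as the **per-cell SD** of the generating
distributions. Group means: control IR 1.53 GΩ, I_AP 69.84 pA, S1
127.64 mV/ms, biphasic (t1-t2 1.66 ms, width 4.21 ms); knockout-like
IR 0.81 GΩ, I_AP 162.4 pA, monophasic with S2 −92.89 mV/ms and lower
overshoot (49.89 mV). The published phase-time means are mutually
inconsistent as a single-cell parameter set (they average different
cell subsets), so t1-t2 and t2-t3 are the primitive targets, with
t2-t3 = 4.21 − 1.66 = 2.55 ms for the control template, and the
knockout template width raised to the solver's feasibility minimum
(≈1.25 ms) when the drawn value cannot sustain the published speeds.
Adaptation parameters (control Δa = 25 pA, τ_a = 4 s; knockout
Δa = 15 pA, τ_a = 2 s) were chosen so control firing collapses within
the first block bins while knockout-like firing is sustained — the
published direction — without targeting exact bin counts. The
adult-onset model showed no group differences, so both adult arms draw
from one pooled distribution. Heat responsiveness: 38% of control-like
cells respond, T_half placed so the mean activation threshold is
40.0 °C; knockout-like cells respond with probability 1/42 at a high
threshold.

The end-to-end directional check calls each developmental-model
difference and each adult-model "no difference" at α = 0.001 — the
level at which the source tables mark their developmental-model rows.
At a looser level the joint probability of zero false positives across
the adult null comparisons would cap the attainable per-run pattern
rate below the 95% requirement regardless of implementation quality.

## Statistics

Two-sample comparisons gate on Shapiro–Wilk (both p > α → unpaired
two-sided t-test, Welch by default since the original's equal-variance
assumption is unstated; otherwise Mann–Whitney U with exact
small-sample p where ties permit). Constant groups route to
Mann–Whitney with a note. Fisher's exact uses the probability-ordering
two-sided definition with a 1e-12 relative slack for floating-point
ties (the "double the one-sided p" alternative differs and is not
used). BH is the definitional step-up; it is a fixed point on flat
adjusted vectors but not idempotent on arbitrary adjusted outputs.

GSEA permutes gene labels, not phenotypes: the pipeline consumes
ranked lists, and at desk scale a sample-permutation null is not
available. NES divides ES by the mean magnitude of same-sign
permutation scores; the FDR pools sign-matched permutation NES values
across sets (add-one smoothing on nominal p). Default 1000
permutations; Monte-Carlo SE on a nominal p of 0.05 is then ≈ 0.007.
Gene symbols are upper-cased before set operations (mouse/human casing
differs). The enrichment-map cutoff 0.375 on k·O + (1−k)·J with
k = 0.5 is inclusive; the alternative reading of the combined-score
constant as a second threshold is not adopted, but k is configurable.

Variant segregation infers the alternate allele as the allele
homozygous in the index patient, because candidate tables of this kind
print genotypes without ref/alt annotation. Single-allele male X
genotypes are treated as hemizygous even when the table labels them
homozygous; X-linked dominant and recessive modes are handled
identically for male affecteds (female carrier logic is out of scope).
Mode "NA" is treated as autosomal recessive.

## Problem sizes

The default test and acceptance runs use the published group sizes
(32/38 developmental, 37/29 adult), 200 seeded end-to-end runs for the
stochastic pattern rate, 2,000 null draws for type-I calibration,
exhaustive Fisher enumeration to total count 40 and ORA enumeration to
universe 30, and 100-draw analytic-recovery sweeps; the acceptance
script reports the sizes alongside each value.

## Limitations

* The LIF reproduces counts and latencies, not conductances; waveform
  morphology lives entirely in the template layer, so waveform and
  excitability readouts of a synthetic cell are consistent only by
  calibration, not by dynamics.
* Noise is additive Gaussian; heavier-tailed measurement noise, drift,
  series-resistance artifacts and liquid-junction potentials are not
  modeled, so passing tests demonstrate correctness of the estimators
  on clean structure, not robustness to every recording pathology.
* The DE generator plants q-values directly rather than modeling
  counts; it validates thresholding/intersection logic, not
  differential-expression inference itself.
* Real MSigDB collections and the study's actual DEG lists are not
  shipped; enrichment results on synthetic sets validate the
  statistics, not biological conclusions.
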