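# nocistudy

A tested, reusable implementation of the analysis computations behind a
study of PRDM12-dependent nociceptor function. PRDM12 is a
transcription factor required for the development of nociceptors — the
peripheral sensory neurons that detect painful stimuli — and biallelic
*PRDM12* variants cause congenital insensitivity to pain (CIP). The
study this package models compared a developmental and an adult-onset
*Prdm12* deletion mouse model by single-neuron patch clamp,
exome-candidate segregation in a consanguineous CIP family, and bulk
dorsal-root-ganglion (DRG) transcriptomics. `nocistudy` re-implements
that analysis chain end to end at desk scale, for electrophysiologists
and computational biologists who want the individual stages as callable,
tested functions:

* **`synthgen`** — synthetic inputs with known ground truth: passive RC
  sweeps, a leaky integrate-and-fire (LIF) neuron with spike-frequency
  adaptation, a piecewise-analytic action-potential (AP) template whose
  derivative extrema are known in closed form, Boltzmann heat-activated
  currents, planted differential-expression (DE) tables and
  candidate-variant tables.
* **`ephys`** — per-cell phenotyping: input resistance (IR) by Ohm's
  law, rheobase (I_AP) on a 5-pA grid, AP waveform decomposition
  (S1/S2/S3, t1–t3, threshold, overshoot, afterhyperpolarization), ramp
  and 20-s block spike counting, heat-response classification,
  TTX-sensitive current fractionation.
* **`stats`** — Shapiro–Wilk-gated t / Mann–Whitney comparisons,
  Fisher's exact test, Benjamini–Hochberg FDR.
* **`varseg`** — rare-variant filtering and pedigree segregation testing
  under recessive and X-linked models.
* **`enrich`** — DEG thresholding, core-DEG intersection,
  hypergeometric overrepresentation (ORA), GSEA, and enrichment-map
  networks.
* **`study`** — calibrated population generators and the end-to-end
  two-model comparison.

## The quantities at the core

**AP waveform decomposition.** From the first derivative of an evoked
AP, S1 = max dV/dt (depolarization speed), and S2, S3 are the two
prominence-ranked minima of dV/dt after the peak — the two phases of
the biphasic repolarization "shoulder" typical of nociceptors; t1–t3
are their times, and t1-t3 is the AP width. The AP threshold is the
voltage at the last negative-to-positive sign change of d²V/dt² before
the upstroke.

**Input resistance and rheobase.** IR is the origin-constrained slope
of steady-state ΔV against ΔI over four hyperpolarizing −5 pA-increment
steps (GΩ, since GΩ × pA = mV); I_AP is the smallest 5-pA-grid
amplitude of a 50-ms block pulse whose response contains an AP peaking
within the step.

**Heat responsiveness.** A neuron is heat responsive when, during a
linear ramp from room temperature to 50 °C, its baseline-subtracted
inward current crosses −0.2 nA; T_act is the temperature at the first
crossing.

**Enrichment.** ORA uses the upper-tail hypergeometric probability
P(X ≥ k | N, K, n) with BH adjustment across gene sets. GSEA is the
weighted Kolmogorov–Smirnov running sum (hit increments ∝ |score|^p
normalized over hits; miss decrement 1/(N−N_h)); ES is the
maximum-magnitude deviation, NES the ES normalized by the mean
same-sign gene-label-permutation ES, with permutation nominal p and
FDR. Enrichment maps join significant sets whose combined similarity
k·O + (1−k)·J ≥ 0.375 (J Jaccard, O overlap coefficient, k = 0.5).

## Worked example

Decompose the control-group AP template and run the family segregation
screen:

```sh
nocistudy simulate --out demo --seed 3
nocistudy ephys --sweeps demo/ap_sweep.csv --protocol ap
nocistudy segregate --variants demo/variants.tsv --affected P1,P2
```

The `ephys` call prints (abridged):

```json
{
  "ap_threshold": -29.09,
  "OS": 68.97,
  "AHP": -66.66,
  "S1": 127.64,
  "t13": 4.21,
  "biphasic": true
}
```

i.e. the waveform reaches its maximal depolarization speed of
127.64 mV/ms, peaks at +68.97 mV, repolarizes through two phases to an
afterhyperpolarization of −66.66 mV, and spans 4.21 ms between the
first and last derivative extremum — a wide, biphasic, control-like
nociceptor AP. The `segregate` call reports `retained 0 of 9
candidates`: none of the nine autism/ID candidate variants is shared by
both affected individuals in the required homozygous (or hemizygous)
state. Running `nocistudy enrich` on the simulated DE tables reports
`strong A: 868; B: 67; core: 35` — the planted significant, strong and
shared gene counts recovered by thresholding (q < 0.05, |log2FC| > 1)
and exact intersection.

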