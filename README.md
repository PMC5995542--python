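# termfret

Simulation and kinetic analysis of single-molecule FRET (smFRET) traces
of bacterial translation termination.

When a ribosome reaches a stop codon, class-I release factors (RF1/RF2)
hydrolyze the peptidyl-tRNA and the GTPase RF3 recycles them. TIRF
microscopy of surface-immobilized ribosomes reports these events as
two-channel (donor Cy3 / acceptor Cy5) intensity time traces sampled at
30 frames/s: an S6/L9 dye pair reads out rotation between the
non-rotated (N, ~0.7 FRET) and rotated (R, ~0.5 FRET) subunit
conformations, an L1–tRNA pair reads out the L1 stalk, and labeled
factors binding to L11-labeled ribosomes appear as discrete FRET events
whose durations measure factor residence. `termfret` implements the
full desk-scale analysis chain for such experiments — and, because raw
experimental traces of this kind are rarely deposited, a synthetic trace
generator whose named scenarios carry published kinetic parameters as
ground truth, so every estimator can be validated by parameter recovery.

The package is aimed at single-molecule biophysicists who want a tested,
scriptable version of the standard smFRET workflow: trace quality
control, hidden-Markov idealization, dwell-time kinetics with censoring,
and population analysis.

## The analysis chain

1. **Trace QC** (`termfret.qc`) — donor bleed-through correction
   A′ = A − β·D (β ≈ 0.13, calibrated from donor-only segments after
   acceptor photobleach), FRET efficiency E = A′/(D + A′), 3-point
   smoothing, photobleach step detection by penalized changepoint
   fitting, and selection of single-molecule traces (channel Pearson
   r < 0.1, single bleach step per dye, single-fluorophore intensity).
2. **Idealization** (`termfret.idealize`) — per-trace Gaussian-emission
   HMM fit by maximum-likelihood EM with BIC state-number selection,
   Viterbi decoding, merging of states separated by ΔE < 0.1, exclusion
   of traces with ≤ 1 transition from kinetics, and extraction of a
   dwell table with left/right censoring flags.
3. **Kinetics** (`termfret.kinetics`) — maximum-likelihood one- or
   two-exponential dwell fits in the frame domain (geometric likelihood
   with survival terms for right-censored dwells and left truncation at
   the detection floor), a dead-time correction for sojourns too short
   to decode, photobleach subtraction for dissociation rates
   (k_off = k_obs − k_bleach, reported as a ≤ 0.2 s⁻¹ bound when
   indistinguishable from bleaching), molecule-level resolution of
   biphasic dwell distributions, and mean ± sd aggregation over three
   independent replicate datasets.
4. **Populations** (`termfret.populations`) — Gaussian-mixture fits of
   pooled FRET values with population fractions p, and the fraction of
   dynamic (fluctuating) traces.
5. **Synchronized densities** (`termfret.syncdensity`) — contour plots
   of FRET probability versus time after synchronization to a binding
   event or conformational transition.

`termfret.synthetic` generates the inputs: continuous-time Markov
(Gillespie) state paths rendered into noisy two-channel counts with
exact per-frame occupancy averaging, per-dye exponential photobleaching,
bleed-through, and mixtures of kinetic subpopulations. Scenarios cover
subunit rotation with and without factors, L1–tRNA dynamics, and
RF1/RF2/RF3 binding kinetics from stable (photobleach-limited) to fast
(~6 s⁻¹) dissociation.

## Worked example

Simulate the PreHC + RF3–GTP rotation experiment (truth: E_N = 0.73,
E_R = 0.52, k_N→R = 4.4 s⁻¹, k_R→N = 2.2 s⁻¹) and recover the kinetics:

```python
from termfret.pipeline import PipelineConfig, run_scenario

cfg = PipelineConfig(seeds=(0, 1, 2))
summary = run_scenario("rf3_prehc_rotation", cfg, n_traces=100)
m, sd, w = summary.gmm_means, summary.gmm_means_sd, summary.gmm_weights
print(f"FRET states: R = {m[0]:.3f} +/- {sd[0]:.3f} (p = {w[0]:.2f}), "
      f"N = {m[1]:.3f} +/- {sd[1]:.3f} (p = {w[1]:.2f})")
for key in ("k_N_to_R", "k_R_to_N"):
    est = summary.rates[key]
    print(f"{key}: {est.value:.2f} +/- {est.sd:.2f} 1/s  (3 replicates)")
print(f"fraction of dynamic traces: {summary.dynamic[0]:.2f} +/- {summary.dynamic[1]:.2f}")
```

prints

```
FRET states: R = 0.528 +/- 0.002 (p = 0.66), N = 0.708 +/- 0.002 (p = 0.34)
k_N_to_R: 4.28 +/- 0.02 1/s  (3 replicates)
k_R_to_N: 2.29 +/- 0.10 1/s  (3 replicates)
fraction of dynamic traces: 0.97 +/- 0.00
```

The two rotation rates come back within a few percent of the generating
values; the R state dominates (p ≈ 2/3 = k_N→R/(k_N→R + k_R→N)) and
nearly all traces fluctuate, as expected for this regime. The N-state
mean is pulled slightly below 0.73 by frame-averaging blur of its short
dwells — a real feature of frame-limited smFRET data, discussed in
`docs/methods.md`.

The same pipeline is available from the shell:

```bash
termfret simulate --fixture l11_rf3_prehc --n 300 --seed 1 --out sim/
termfret qc --in sim/ --beta auto --out qc/
termfret idealize --in qc/ --kmax 2 --out ideal/
termfret run --scenario l11_rf3_prehc --n 300 --out results/
```

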