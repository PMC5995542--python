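# Methods

This note documents the models, estimators, and design choices behind
`termfret`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Synthetic trace model

**Kinetics.** Each molecule follows a continuous-time Markov chain over
conformational or binding states (`KineticScheme`): sojourns in state i
are exponential with the total exit rate Σⱼ k_ij, successors drawn
proportionally to k_ij (exact Gillespie sampling, no time
discretization). Kinetic heterogeneity is modeled as a mixture of
schemes with molecule-level weights; subpopulation membership is drawn
per trace and recorded in the truth manifest.

**Emission.** A frame integrates the emitted FRET efficiency over its
exposure window with exact occupancy fractions, so a transition
mid-frame produces one frame of intermediate intensity — the averaging
blur a frame-rate-limited detector actually sees and the idealizer must
tolerate. Pre-bleach, donor = I·(1−E̅) and acceptor = I·E̅ + β·donor,
with β the donor→acceptor bleed-through. Gaussian read noise is added
per channel. Defaults: I = 1000 counts/frame, noise sd 65 counts per
channel (FRET histogram width ≈ 0.05, matching the reported Gaussian
widths), β = 0.13, backgrounds 0 (background subtraction is assumed to
have happened at spot extraction). Each state also carries a small
molecule-to-molecule FRET jitter (sd 0.02), so state means vary between
molecules as they do between real ribosomes.

**Photobleaching.** Each dye bleaches with an exponential wall-clock
hazard (0.05 s⁻¹ per dye; first-bleach hazard 0.1 s⁻¹, inside the
0.07–0.19 s⁻¹ range estimated for these imaging conditions). After
acceptor bleach the donor recovers its full intensity (the donor-only
tail used to calibrate β); after donor bleach both channels fall to
background. In factor-binding scenarios every binding event carries a
fresh acceptor-labeled factor, so a wall-clock acceptor bleach would be
the wrong physics; instead acceptor photobleach of the bound factor is
folded into the scheme as an additional bound→dark hazard
(0.05 s⁻¹) — indistinguishable from dissociation at the trace level,
which is precisely the confound the photobleach correction addresses.
Bleach takes effect at frame granularity (the frame containing the
bleach time is dark).

**Scenario parameters.** Scenario fixtures carry the published values
of the experiments they emulate (state FRET means, dissociation and
rotation rates, subpopulation fractions). Rates the source experiments
could not resolve or did not print are design values, flagged in each
fixture's `design_values`: baseline PreHC exchange k_N→R = 0.02,
k_R→N = 0.08 s⁻¹ (sum 0.1 s⁻¹; keeps the fraction of visibly
fluctuating traces under ~20 %, as observed), k_N→R = 4.4 s⁻¹ for the
RF3-rotation scenario (makes R twice as occupied as N),
k_open→closed = 1.5 s⁻¹ for the L1–tRNA pair (closed state transient),
apparent binding rate 0.3 s⁻¹ for all 10 nM factor-binding scenarios,
and a true RF1 k_off of 0.01 s⁻¹ (stable on the experimental timescale;
its observed disappearance is photobleach-limited). The RF3–GDPNP
scenario uses a single bound state at E = 0.71; the secondary ~0.40
engaged state seen in that complex is not simulated because the target
quantity there is the dissociation rate. Trace durations are 20 s
(FRET-pair scenarios) and 40 s (binding scenarios) at 30 frames/s.

## Trace QC

β is estimated as the median of (A − bg_A)/(D − bg_D) over frames where
the acceptor has bleached and the donor survives. Traces are selected
by three rules with documented, configurable thresholds:

* **Anticorrelation.** Pearson r of donor vs corrected acceptor over
  the pre-bleach window must be < 0.1. Static traces sit near r = 0 and
  pass (intended: stably bound factors produce static traces). The
  correlation is computed on the raw channels — smoothing first would
  autocorrelate the noise and roughly double the variance of r — and
  windows shorter than 40 frames are treated as carrying no correlation
  evidence rather than as rejections.
* **Single bleach steps.** Changepoints are found by penalized
  (SIC-type) least-squares piecewise-constant fitting. A donor
  photobleach must be mirrored by a comparable drop in the corrected
  total intensity D + A′ (FRET transitions move intensity between
  channels but conserve the total; bleaching removes it) and be
  permanent; an acceptor photobleach is a permanent corrected-acceptor
  step down to background. Exactly one such step per channel is
  allowed (none, for traces that outlive the movie). In binding mode
  the acceptor rule is skipped: factor arrivals and departures are
  signal, not bleaching.
* **Intensity band.** The pre-bleach median total must lie within
  [0.5, 1.5]× the set median — the operational meaning of
  "characteristic single-fluorophore intensity". Aggregates (two
  molecules per spot) double the total and fail this band; with their
  co-moving intensity envelope and double bleach steps they are
  rejected at ≥ 95 % in the doped-set test.

FRET is computed as E = A′/(D + A′) on bleed-through-corrected traces;
frames after the first bleach and frames whose total falls below a
quarter of the trace's upper-decile total (both dyes dark — the ratio
is pure noise) are masked from all statistics. The 3-point running
average is applied for histograms, density maps and display, but **not**
before idealization: smoothing smears transitions across neighbouring
frames and at rates of a few s⁻¹ biases dwell-derived rates downward by
15–30 %.

## Idealization

Each masked FRET series is fit with a Gaussian-emission HMM by
maximum-likelihood EM: deterministic quantile initialization plus five
seeded restarts, convergence at relative log-likelihood change < 1e-6
or 500 iterations, emission sd floored at 1e-3. The variational-Bayes
machinery of the commonly used HMM package is intentionally not
reproduced: downstream analysis depends only on the idealized paths,
and an ML fit with explicit BIC model selection over K = 1..K_max has
the same output surface with fewer moving parts. In pipeline runs the
state count is fixed to the scenario's known value (as an experimenter
would); per-trace BIC selection is available (`fix_K=False`).

Decoding is exact Viterbi; ties break toward the lower-mean state (the
suite verifies equality with exhaustive path enumeration for short
traces). The exclusion rules then (i) merge fitted states whose means
differ by < 0.1 (closest pair first, occupancy-weighted; idempotent)
and (ii) drop traces with ≤ 1 surviving transition from kinetics while
keeping them for histograms and the dynamic-trace fraction. Dwells are
extracted with the first sojourn left-censored, the last right-censored
(cause: bleach or trace end), and dwell frames summing exactly to the
unmasked frame count.

## Dwell-time kinetics

Dwells are whole frames, so rates are estimated in the frame domain: a
sojourn of n frames follows a geometric law with per-frame survival
q = exp(−k/f). Uncensored dwells contribute the mass function,
right-censored dwells the survival function; the one-component MLE is
closed-form, the two-component mixture is fit by bounded quasi-Newton
from multiple starts, and models are compared by BIC (a two-component
fit falls back to one below 50 dwells).

Two detection artifacts of frame-limited idealization are handled
explicitly rather than left as bias:

* **Left truncation.** A sojourn must dominate at least one frame to be
  decoded at all, so the observed dwell distribution is effectively
  conditioned on n ≥ 2; the likelihood is left-truncated at
  `n_min = 2` frames (the ignore-the-first-histogram-bin rule; by
  memorylessness this is harmless when no truncation is present).
* **Missed-event (dead-time) correction.** A sojourn of the *other*
  state shorter than the detection floor merges its two flanking
  dwells, thinning the observed exit rate to k·P(partner dwell ≥ t_d).
  With random frame phase the decodability threshold falls uniformly
  between one and two frames, giving t_d = 1.5 frames by construction.
  The corrected rate pair solves the fixed point
  k_a = k_a,obs·exp(k_b·t_d) (and symmetrically), the first-order
  missed-event correction familiar from single-channel kinetics; it is
  skipped for rates beyond twice the frame rate, where no correction is
  meaningful. At the fixture rates (2–6 s⁻¹ at 30 frames/s) this
  correction is worth 5–15 % and brings recovery within a few percent.

**Photobleaching.** The bleach rate of a FRET pair is fit from the
signal durations of non-fluctuating traces (censored MLE; an upper
bound is reported if nothing bleaches). For binding experiments the
event-ending bleach hazard is calibrated from the stably bound RF1
scenario, whose FRET-event disappearance is photobleach-limited —
mirroring how the experimental detection limit was defined. Observed
dissociation rates are corrected as k_off = k_obs − k_bleach with
propagated uncertainty; when k_obs is within two combined standard
deviations of k_bleach only a bound (default 0.2 s⁻¹, configurable) is
reported, never a negative rate. Both corrected and uncorrected values
are kept.

**Biphasic dwell distributions.** Pooled two-exponential amplitudes are
dwell-count fractions and overweight fast molecules, which cycle more
often per trace (70 % fast molecules contribute ~90 % of dwells at the
fixture rates). Molecule fractions are therefore estimated by a
trace-level two-class EM over per-trace dwell likelihoods
(`classify_subpopulations`), which recovers the 0.70 fast-molecule
fraction within ±0.05 at 300 traces.

Replicate aggregation is the unweighted mean ± sample sd over (by
default three) independently seeded datasets, matching the
three-independent-datasets convention of the experimental tables; any
bound among replicates makes the aggregate a bound.

## Populations and synchronized densities

Gaussian mixtures are fit by EM on the raw pooled (smoothed) FRET
values — bin-width independent — with quantile initialization and
seeded restarts; a least-squares fit to the binned histogram
(0.02 FRET units over [−0.1, 1.1]) is provided as a fidelity mode and
agrees with EM on clean data within the test tolerances. For binding
experiments the pool is taken from the first 10–30 frames after
synchronization to the FRET-event start; because short-lived events
leave part of that window dark, the pool is fit as a dark/bound mixture
(component count by BIC) and the bound state is the highest-mean
component. Density maps are per-time-column 2-D histograms normalized
over the traces still contributing in each column (survivor
normalization), at 1-frame × 0.02-FRET default bins.

## Numerical and reproducibility choices

All randomness descends from a single integer seed via spawned
`SeedSequence`s (one per trace), so trace sets are bit-reproducible and
parallelizable. EM and Viterbi inner loops are numba-compiled. GMM
fitting uses scikit-learn with fixed random state. The pipeline's
written tables are byte-identical across reruns of the same config.
Degenerate inputs (all-equal pools, all-censored dwell sets, traces too
short to fit) raise descriptive errors rather than returning numbers.

Problem sizes in the validation suite and the acceptance script — 300
traces × 3 replicate seeds per scenario, 20–40 s traces at 30 frames/s —
are the package's desk-scale working point: large enough that recovery
error is dominated by method bias rather than sampling noise, small
enough to run interactively.

## What the synthetic validation does not show

The generator draws Gaussian channel noise (no Poisson shot noise or
EMCCD gain statistics), single-step bleaching (no triplet blinking or
partial quenching), flat backgrounds (no drift), and exponential dwells
(no non-Markovian memory). Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to every artifact of real movies; the QC layer addresses the
main trace-level artifacts (aggregates, correlated envelopes, multistep
bleaching) but, e.g., baseline drift correction is out of scope. Bound
FRET means of very short-lived binding events (mean dwell ≈ 5 frames)
are biased low by frame-averaging and smoothing blur — visible in the
fast RF3 scenarios — which is a property of frame-limited data itself;
the dwell-time machinery, not the histogram mean, is the reliable
estimator in that regime.
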