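# Methods

## 1. The clustering feasibility model

**Question.** During a typical odor, does random glomerulus-to-neuron
connectivity place enough co-active LOT synapses on one terminal apical
branch to initiate a local NMDA-spike?

**Model.** Each of `n_glomeruli` activated glomeruli (default 110)
contributes synapses to the recorded neuron; the activated-synapse count N
follows one of three models:

- `fixed`: N = round(n_glomeruli × mean_syn_per_glom) = 70.  This mirrors
  the back-of-envelope arithmetic 110 × 0.64 → 70.
- `bernoulli_per_glomerulus` (default): N = Σ Bernoulli(0.64) over 110
  glomeruli, i.e. N ~ Binomial(110, 0.64).  Chosen as the default because
  0.64 < 1 reads naturally as a per-glomerulus connection probability and
  at most one synapse per glomerulus is the sparsest consistent reading.
- `poisson`: N ~ Poisson(70.4), for sensitivity analysis.

Each synapse is then allocated independently among `n_branches` terminal
branches (default 10) with weights `branch_weights` (default uniform).  A
branch "clusters" when it receives at least `nmda_threshold` synapses
(default 10, the estimated NMDA-spike initiation number).  The spine
capacity (≥ 1 spine/µm × ~100 µm LOT band → ≥ 100 spines/branch) is far
above the mean load of 7 synapses/branch, so the capacity cap is disabled
by default; it can be enabled for sweeps, in which case only the
Monte-Carlo path applies (overflow synapses are re-drawn among non-full
branches).

**Per-branch probability (exact).**  For fixed N the designated branch
count is Binomial(N, w_b) and the answer is its upper tail at k.  For the
Bernoulli model the thinning identity gives the count directly as
Binomial(n_glomeruli, mean × w_b); for Poisson, Poisson(λ w_b).  Under the
defaults: fixed 0.1586, Bernoulli 0.1668, Poisson 0.1736.  The per-branch
reading is the quantity numerically consistent with the published ~15%
feasibility figure and is flagged as such in all outputs.

**Any-branch probability (exact).**  P(max branch count ≥ k) = 1 − P(all
counts ≤ k−1).  The truncated-multinomial mass is computed by sequential
binomial conditioning: processing branches in order, branch b receives
Binomial(m, w_b / W_remaining) synapses given m remain.  One backward pass
over remaining-count m yields the probability for every total
simultaneously, all intermediates being probabilities (numerically stable
for any N; validated against exhaustive Bᴺ enumeration for all N ≤ 8,
B ≤ 4, all k, at 1e-10 absolute).  Stochastic N is handled by exact
mixture over the count pmf (Poisson support truncated at upper-tail mass
1e-12).  Under the defaults the any-branch probability is 0.916 (fixed N:
0.9162; i.e. some branch is primed in >90% of neurons) — an order of
magnitude closer to certainty than the per-branch 0.16, which is why both
interpretations are always reported side by side rather than silently
choosing one.

**Monte Carlo.**  `estimate_clustering_mc` simulates neurons in vectorised
chunks (count draw → multinomial allocation), reporting both probabilities
with binomial-proportion standard errors; a designated branch is index 0
(branches are exchangeable under uniform weights, which is tested).  All
randomness flows from one integer seed.

## 2. Synthetic electrophysiology

The generator emulates what the downstream feature extractors and
statistics consume; it does not attempt biophysics.

- **EPSP**: difference of exponentials with rise τ 2 ms, decay τ 20 ms,
  normalised so the noiseless peak equals the nominal amplitude
  (default 1.88 mV, the typical focal test-pulse EPSP).  Additive white
  recording noise.  Only the peak statistic is consumed downstream, so the
  waveform shape is minimal phenomenology.
- **NMDA-spike plateau**: amplitude drawn N(27.2, 2.5²) mV and area
  N(2999.5, 434.7²) mV·ms; the waveform is a flat plateau with half-cosine
  ramps (4 ms) whose flat-top duration is derived as area/amplitude − ramp,
  so the noiseless integral reproduces the drawn area exactly.  The
  classification threshold is 10.2 mV somatic depolarisation.
- **Input–output curves**: below the stimulus-intensity threshold,
  responses are graded EPSPs scaled linearly up to 80% of the
  classification threshold; at and above it, plateau spikes — producing
  the all-or-none jump at a known intensity.
- **Protocols**: STDP = EPSP followed 8 ms later by three BAPs at 150 Hz,
  triplets at 20 Hz, 40 sweeps at 5 s intervals (a 30-sweep variant is
  retained as a configuration switch; both repetition counts are in
  circulation and the discrepancy is preserved, not resolved).  NMDA
  train = three pulses at 50 Hz per spike, repeated at 4 Hz; admissible
  burst counts 2–23, with condition presets using 2–7 (distal LOT),
  4–10 (proximal IC) midpoints.  Test pulses at 0.033 Hz for 10–15 min per
  phase → default 24 pulses per phase (12 min).
- **LTP cohorts**: per cell, a lognormal baseline amplitude (CV 0.35
  across cells around 1.88 mV); pre amplitudes lognormal around the
  baseline with trial-to-trial CV `within_cell_cv`; a per-cell potentiation
  factor drawn normal around the condition's true factor (truncated > 0);
  post amplitudes lognormal around baseline × factor — a step change that
  persists to the end of the series.  Optional linear resting-potential
  drift of configurable amplitude.  Ground truth (baseline, cell factor,
  condition factor) is stored on each record.
- **Line scans**: 500 Hz, two channels (spine, shaft); baseline at F₀ then
  an instant-rise, exponential-decay transient peaking at F₀(1 + ΔF/F);
  multiplicative per-sample noise.

**Condition presets.**  The per-condition generator defaults are the
published potentiation point estimates (percent of control, cohort size,
printed SEM): LOT Ia STDP 103.06% (n=11), LOT Ia NMDA 213.98% (n=26),
IC Ib STDP 168.93% (n=6), IC Ib NMDA 148.48% (n=9; the figure legend's
3.85% SEM variant is noted, the running-text 4.1% is used), basal STDP
137.12% (n=8), basal NMDA 140.64% (n=6), APV 95.06% (n=5), sub-NMDA
106.79% (n=5), baclofen NMDA 236.57% (n=5), optogenetic NMDA 232.45%
(n=11), EPSP+BAP pairing at 4 Hz 97.31% (n=4).

**Variance calibration.**  The sources give no trial-to-trial EPSP
variability, only cohort SEMs.  The per-cell ratio variance decomposes into
a between-cell term (factor variability) and an analytic trial-noise term
factor² · CV² · (1/n_pre + 1/n_post).  The default trial CV is 0.15: for
the tightest printed SEM (2.81% at n=11, implying a per-cell ratio SD of
~9.3%) this attributes less than a quarter of the ratio variance to trial
noise, leaving between-cell differences dominant, which matches the
qualitative observation that per-cell averages differ far more than
repeated trials within a cell.  The between-cell SD is then set per
condition so the total per-cell ratio SD equals SEM × √n — making the
simulated cohort SEM match the printed one by construction.  Because
percent of control is a ratio of means, its expectation carries a small
finite-sample inflation ≈ factor × CV²/n_pre (≈ 0.1% of the mean at the
defaults); this is a property of the estimator, not of the generator.

**What the generator does not emulate** — and hence what passing recovery
tests do not establish about real recordings: synaptic failures and
quantal structure, slow rundown or drift in EPSP amplitude (other than the
optional RMP drift), series-resistance artefacts, temporal correlation of
trial noise, gradual (non-step) expression of potentiation, and any
mechanistic difference between conditions beyond the potentiation factor
and spike availability.

## 3. Feature extraction

Measurement windows are explicit parameters because the original analysis
software windows are not documented: baseline 0–50 ms, EPSP response
50–150 ms, spike epoch = everything after the baseline window.  EPSP
amplitude = response-window maximum minus baseline mean (the windowed max
has a small positive bias under noise; tests quantify it against a
brute-force oracle rather than pretending it away).  Spike area integrates
the positive part of the baseline-subtracted trace with the trapezoidal
rule.  The all-or-none detector declares a threshold at the largest
adjacent-peak jump when it is at least 40% of the maximum peak (robust
given ~27 mV spikes vs < 10 mV sub-threshold EPSPs); otherwise none.
Spike counting uses upward threshold crossings separated by a 100 ms
refractory (below the 250 ms inter-burst interval of a 4 Hz train).
ΔF/F = (F − F₀)/F₀ with F₀ the baseline-window mean per structure, exactly
invariant under multiplicative gain.

## 4. Statistics

Percent of control is the ratio of per-cell means (post/pre) × 100, then
averaged across cells; SEM uses the n−1 denominator.  The within-condition
test is the classical two-tailed paired Student's t on per-cell pre/post
means, implemented directly so degenerate inputs have defined behaviour
(identical pairs → t=0, p=1; nonzero constant differences → p=0 with a
degeneracy flag) and verified against scipy to 1e-10 on random inputs.
Cross-condition comparisons use Welch's unpaired t (different cells cannot
be paired; equal variances are not assumed).  No multiple-testing
correction is applied, and the summary table says so.  The stability rule
excludes cells whose resting potential moved more than 3 mV from its
initial value at any point; records lacking an RMP series pass with a
warning (missing monitoring is a data gap, not a failure).

## 5. Problem sizes and numerical choices

Exact-vs-enumeration agreement is asserted at 1e-10 absolute.  The exact
any-branch solver accepts counts up to 5000 by default before deferring to
Monte Carlo (a runtime guard, not a validity limit).  Monte-Carlo checks in
the test suite use 10⁶ neurons against 4·SE bands; parameter recovery uses
500 replicate cohorts per condition at the published cohort sizes (3·SE
grand-mean bands) and 1000 null cohorts at n=11 for the type-I error check
(3·binomial-SE band around 0.05).  The acceptance script simulates 10⁶
neurons with the fixed-70 count model — the model matching the published
arithmetic — and cross-checks the exact tail.  Seeds: every stochastic
entry point takes a single integer seed or a numpy Generator; cohort and
pipeline seeds are derived via `SeedSequence` spawning so results are
independent of execution order.

## 6. Known limitations

- The feasibility model has no within-branch spatial window (synapses on
  the same branch are assumed co-clustered) and no release-probability or
  temporal-jitter model; both would lower the effective clustering
  probability.
- The any-branch/per-branch ambiguity is inherent to the verbal statement
  of the published 15% figure; this package computes both and labels the
  per-branch reading as the arithmetically consistent one rather than
  resolving the wording.
- Condition presets treat each experiment as a clean step potentiation;
  real induction failures, partial expression and washout are not modelled.
- The paired t-test assumes approximately normal per-cell differences;
  with n as low as 4–6 cells this is an approximation inherited from the
  original analysis procedure, not a recommendation.
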