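# Methods

## Signal model and conventions

Traces are whole-cell voltage-clamp currents in pA at a nominally −65 mV
holding potential, sampled at 20 kHz; excitatory (inward) currents are
negative.  Raw traces keep their sign; every reported *amplitude* and *slope*
is a positive magnitude.  Slopes are in pA/ms, numerically identical to
nA·s⁻¹, so instrument-style thresholds (−50 nA·s⁻¹) carry over unchanged.

Synaptic events are modeled as dual-exponential kernels

    k(t) = −A · (e^(−t/τ_d) − e^(−t/τ_r)) / norm,   t ≥ 0

normalised so min k = −A, with defaults τ_r = 0.5 ms, τ_d = 5 ms (typical
AMPA-receptor kinetics at physiological temperature).  Closed forms used as
oracles: peak time t_pk = τ_rτ_d/(τ_d−τ_r)·ln(τ_d/τ_r) ≈ 1.279 ms, and the
analytic derivative k′(t).  Note k′ is discontinuous at onset — its supremum
is at t → 0⁺ — so no sampled estimate can attain it.  Ground-truth "peak
slope" is therefore defined as |k′(Δt)| one sample after onset, the steepest
slope resolvable on the grid; a central-difference derivative agrees with
that value to ≈0.2% at 20 kHz.

## Preprocessing

* **QC**: a cell passes when every series-resistance reading is below
  `rs_max` (default 10 MΩ) and the relative increase over the reference sweep
  is at most `increase_max` (default 0.20).  The reference defaults to the
  set's first sweep and is exposed as a parameter so the rule can be anchored
  to the first passing baseline sweep of a cell; missing Rs data yield a
  "not assessable" report rather than a silent pass.
* **Baseline subtraction** uses the mean over a pre-stimulus window, by
  default the 50 ms ending 1 ms before the flash (the window is not stated in
  the usual acquisition conventions, so it is configurable); the operation is
  idempotent.
* **Low-pass filtering** is Gaussian with the −3 dB convention:
  σ_t = √(ln 2)/(2π·f_c), so the transfer function e^(−2π²σ²f²) is exactly
  half-power at the named cutoff (default 1 kHz).  Edges are handled by
  reflection; DC gain is 1.
* **Averaging** omits the first 4 sweeps of agonist/antagonist conditions
  (drug equilibration) and none otherwise; filtering and averaging commute,
  and the default order is filter-then-average.
* **Peak amplitude** is the magnitude of the trace minimum in a post-stimulus
  search window (default flash to +50 ms, the positive half of the detection
  window).  **Onset latency** is the flash-to-10%-of-peak time, linearly
  interpolated between samples, with ties resolved to the earliest crossing;
  because the threshold is a fraction of the peak, it is amplitude-invariant.

## Event deconvolution

The first temporal derivative (central differences; one-sided at endpoints)
of each filtered sweep is scanned inside the detection window (default −50 to
+50 ms around the flash).  An event opens when dI/dt crosses below the
threshold (default −50 pA/ms) and closes on return; with the default minimum
event separation of 0 ms every re-crossing is a new event, otherwise runs
closer than the separation merge.  The event's latency is the time of its
most-negative derivative sample — the maximum-slope point, which is what the
latency histograms use — and its reported slope is that magnitude, which by
construction is at least |threshold|.  A capture window (1 ms before to 5 ms
after the opening crossing) is retained for inspection.  Two settings kept
for provenance with acquisition-software defaults ("time to peak for typical
event", "peak measurement interval") do not affect threshold-crossing
results; they are logged so runs are auditable.  Known limitation: events
whose derivative excursions overlap (separations ≲1–2 ms) merge into one
detection, and an event riding on another kernel's decay has its slope biased
by the underlying decay slope (a few %); the oracle for noise-free recovery
is therefore the closed-form derivative of the injected *compound* waveform.

## Latency split

Latencies over 0–10 ms are binned at 0.5 ms by default (bin width is exposed
and `trough_sensitivity` reports the trough across {0.25, 0.5, 1.0} ms, since
histogram conventions are not standardised).  The fit minimises squared error
of a two-Gaussian curve against bin-center/count pairs (counts, not density).
Initialisation: the two highest local maxima of a 3-bin moving average seed
the means/amplitudes, σ starts at the bin width, and 10 jittered restarts
(fixed restart seed) keep the best SSE.  Fewer than two smoothed local maxima
raises a "no bimodality" error; fewer than 30 in-range events refuses to fit.
The trough is the argmin of the fitted curve on [μ₁, μ₂], located on a 1 µs
grid and refined by bounded scalar minimisation; a curve monotone between the
means (overlapped components) has no trough and says so.  Classification:
latency < trough → early, otherwise late (ties late); the default counting
window for early/late rates is 0–20 ms, configurable, since events beyond the
histogram range still belong to the late population.

## Drug-effect quantification

% reduction is computed within a cell from condition-averaged traces and only
then aggregated across cells — never from pooled traces.  Early/late event
rates divide classified event counts by the number of episodes (all sweeps
used for detection).  Slope summaries pool events within a cell (per-event
aggregation) by default, matching how event-level comparisons are usually
presented.  The latency–inhibition relationship is ordinary least squares of
per-cell % reduction on baseline onset latency (scipy's linregress; the
two-sided slope test is the t-test).  The Kruskal–Wallis H (with tie
correction) and Dunn pairwise z statistics with Bonferroni adjustment are
implemented directly from the rank formulas — only the χ²/normal tail
probabilities come from scipy — because group screening is part of this
pipeline's surface; mixed-effects ANOVA and multiple-comparison frameworks
are deliberately out of scope, served instead by the exported tidy tables.

## The generative circuit model

The simulator is phenomenological rather than conductance-based: it exists to
produce compound sweeps with exactly known event content, not to model
membranes.

* **Monosynaptic pathway**: per sweep, release occurs with probability
  `mono.prob` (default 0.9); latency ~ Normal(2.5, 0.4) ms truncated at
  ≥0.5 ms (causality; minimal synaptic delay), amplitude ~ Normal(200, 40) pA
  clipped positive.
* **Recurrent pathway**: the event count is Poisson with rate
  `poly.rate × poly_scale × drive^coupling`, where drive is the sweep's drawn
  monosynaptic amplitude normalised by its mean and scaled by `mono_scale`
  (coupling exponent default 1; the real circuit's coupling is unknown, so no
  validated quantity depends on its exact value).  The drawn amplitude enters
  the drive whether or not release occurred — the recurrent network responds
  to population drive, not to the single recorded synapse — which keeps the
  baseline expectation at prob + rate = 0.9 + 1.9 = 2.8 events/episode, the
  observed scale for this preparation.  Latencies ~ Normal(6.5, 1.5) ms
  truncated after the sweep's monosynaptic latency; amplitudes ~ Normal(80,
  25) pA.
* **Pharmacology presets**: KOR mono_scale = 0.2 (≈80% peak suppression,
  propagating to the recurrent rate through the drive term); MOR poly_scale
  = 0.5 and DOR poly_scale = 0.55 (compromise between reported late
  events/episode ratios ≈0.6 and late-cell amplitude ratios ≈0.45);
  TTX removes all events; TTX+4-AP removes recurrent events and scales the
  monosynaptic amplitude by 0.3 (the observed partial recovery).  These are
  fixed calibration points, not fitted quantities.
* **Noise**: additive Gaussian, default SD 8 pA, with an optional 1/f
  fraction (FFT-shaped) for more realistic drift.
* **Reproducibility**: all randomness flows from one seed through a spawned
  stream per sweep, so per-sweep draws are stable under reordering and the
  same seed is bit-identical.  A `snap_latencies_to_grid` flag aligns onsets
  to sample times for exactness oracles.
* **Cohorts** (`preset_cohort`): cells carry random effects on amplitudes,
  latencies, and rates; half of each cohort is generated with weak direct
  connectivity (monosynaptic weight 0.02–0.2 applied to both amplitude and
  release probability), yielding recurrent-dominated cells whose 10%-rise
  onset falls in the late window.  That spread is what gives the
  latency–reduction regression support: under a mu/delta-type drug the
  recurrent-dominated cells lose most of their peak (positive slope), while
  a kappa-type drug suppresses every cell's drive uniformly (flat).

### What the simulator does not emulate

Stimulus artifacts, short-term plasticity across the sweep train, GABAergic
currents, postsynaptic conductance changes (e.g. GIRK), space-clamp
distortion, and electrode drift.  Tests passing on this generator therefore
validate the *analysis* — detection, classification, and effect estimation
under the stated event statistics — not robustness to every artifact of real
recordings; the QC and baseline-subtraction stages exist precisely because
real data need them.

## Validation sizes and numerical choices

The validation suite uses: 50 noise-free compound sweeps for the detection
oracle; 1,000 pure-noise sweeps at slope SD = |threshold|/10 for the
false-positive control; 100 replicates of 400-event mixtures for trough
recovery (the analytic minimum of the default mixture is ≈4.26 ms); 20
replicates of 16-cell cohorts (30 sweeps/condition) per receptor for the
early/late dissociation — cells in this preparation typically yield ~10
sweeps per condition, and 30 keeps rate estimates stable at desk scale; and
1,000 null replicates (3 × 10 values) for rank-test calibration.  Per-replicate
regression R² on a 16-cell cohort is Beta(1/2, 7)-distributed under the null
(median ≈0.03, but exceeding 0.1 with probability ≈0.2), so latency
independence is asserted on the median across replicates, the robust
summary at this n.  Tolerances: detection latency within one sample; slope
within 1% of the compound closed form; trough within 0.5 ms of the analytic
minimum in ≥90% of replicates; type-I error within [0.03, 0.07].

## Known limitations

* Threshold-crossing detection cannot separate events whose derivative
  excursions overlap; amplitudes (pA) of individual overlapping events are
  not estimated — only slopes, which is why the event statistics are built on
  slopes in the first place.
* The double-Gaussian fit requires visible bimodality; strongly unbalanced or
  merged mixtures are reported as errors rather than silently split.
* NWB I/O requires the optional pynwb dependency; the native HDF5/CSV layouts
  are self-describing and round-trip exactly.
* The transcript module consumes pre-exported cell tables; it performs no
  atlas API access or spatial statistics.
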