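# oepsc

Analysis of compound **optically evoked EPSCs** (oEPSCs): deconvolution into
discrete synaptic events, early/late latency classification, and
receptor-specific drug-effect quantification — with a generative simulator of
the underlying recurrent circuit for validation.

## The scientific problem

Light-activating long-range axon terminals (e.g. claustral inputs to cortex
expressing channelrhodopsin) in a voltage-clamped pyramidal neuron evokes a
*compound* inward current: a stimulus-locked **monosynaptic** EPSC with short
latency and little jitter, followed by **polysynaptic** EPSCs generated by
recurrent local excitation, at longer and more variable latencies.
Presynaptic neuromodulators act on these pathways selectively — kappa opioid
receptor (KOR) agonists suppress the direct input (and thereby everything
downstream of it), while mu/delta (MOR/DOR) agonists suppress only the
recurrent component.  Resolving *which* pathway a drug acts on requires taking
the compound current apart.

This package implements that decomposition:

1. **QC and preprocessing** — series-resistance inclusion rule (Rs < 10 MΩ,
   increase ≤ 20%), baseline subtraction, 1 kHz low-pass Gaussian filtering,
   per-condition sweep averaging (omitting the first four sweeps of a drug
   wash), peak amplitude and 10%-rise onset latency of the averaged trace.
2. **Derivative deconvolution** — the first temporal derivative dI/dt (pA/ms ≡
   nA·s⁻¹) of each sweep is scanned for excursions below a −50 pA/ms
   threshold in a −50…+50 ms window around the flash; each excursion is one
   synaptic event, timestamped at its maximum-slope point.
3. **Latency split** — event latencies over 0–10 ms are binned and fitted with
   a double Gaussian f(t) = a₁e^{−(t−μ₁)²/2σ₁²} + a₂e^{−(t−μ₂)²/2σ₂²}; the
   trough of f between μ₁ and μ₂ is the early/late classification boundary.
4. **Drug effects** — per-cell % peak reduction (100 × (1 − peak_drug /
   peak_baseline)), early/late events/episode and mean event slopes,
   cumulative latency distributions, and simple linear regression of %
   reduction on onset latency (flat for pathway-independent suppression,
   positive for recurrent-selective suppression).  A hand-implemented
   Kruskal–Wallis/Dunn rank comparison covers group screening; tidy per-cell
   tables are exported for any richer external modeling.
5. **Synthetic circuit** (`oepsc.synth`) — dual-exponential EPSC kernels
   (τ_rise 0.5 ms, τ_decay 5 ms), Bernoulli monosynaptic release, Poisson
   recurrent events whose rate is coupled to the realized monosynaptic drive,
   receptor-specific scaling, TTX / TTX+4-AP condition presets, Gaussian
   noise, and exact per-event ground truth.
6. A MERFISH-style **transcript query** (`oepsc.transcripts`) summarising
   region/class-filtered gene expression quartiles (log2(CPM+1)).

## Worked example

Simulate a baseline recording, deconvolve it, and fit the latency split:

```bash
$ oepsc simulate --seed 7 --n-sweeps 60 --out baseline.h5
60 sweeps -> baseline.h5; 168 true events -> baseline.ground_truth.csv

$ oepsc detect baseline.h5 --out events.csv
151 events over 60 episodes -> events.csv

$ oepsc split events.csv
a1 = 23.8338
mu1_ms = 2.80405
sigma1_ms = 0.453928
a2 = 9.3299
mu2_ms = 7.08201
sigma2_ms = 1.78328
trough_ms = 4.1264694801535775
...
```

The two fitted components sit at ≈2.8 ms (monosynaptic, narrow) and ≈7.1 ms
(recurrent, broad); the trough at ≈4.1 ms is the boundary used to label each
event early or late.  151 of 168 injected events are recovered — the misses
are overlapping recurrent events whose derivative excursions merge.

The same steps run as one pipeline from a config file:

```bash
$ cat pipeline.yaml
seed: 7
out_dir: run
simulate: {receptor: KOR, n_cells: 6, n_sweeps: 20}

$ oepsc run --config pipeline.yaml
trough_ms = 3.674
324 events across 12 sweep sets
outputs in run: events.csv, split_model.txt, summaries.csv, effects.csv, regression.txt
```

`effects.csv` then holds one row per cell with the % oEPSC reduction and the
early/late event-rate deltas; for a KOR cohort both populations collapse and
the reduction is independent of onset latency, whereas a MOR/DOR cohort loses
only late events and shows reduction growing with latency.

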