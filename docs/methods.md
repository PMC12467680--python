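# Methods

This note documents the models and numerical choices behind `p300select`:
the task-schedule generator, the synthetic-EEG model, the preprocessing
chain, the three decoders, and the cohort statistics.  It also states what
the simulations can and cannot establish about real recordings.

## Task schedules

A task is `n_games` games × `n_blocks` blocks × `n_slots` slots (defaults
8 × 6 × 8).  Stimulus cycle: 375 ms stimulus + 250 ms inter-stimulus
interval = 625 ms (1.6 Hz); 10 s breaks between games only.  With defaults,
one game lasts 30 s, a task 310 s, and there are 48 target trials
(6 blocks × 8 games).

Per block the target slot is drawn uniformly from slots `2..n_slots-1`
(the target never occupies the first two slots), independently across
blocks — resampling rather than balancing, a deliberate choice: balancing
would correlate blocks and complicate the null distribution, and nothing in
the paradigm requires it.  Every block also carries a pseudorandom bijection
of abstract *candidate labels* onto slots with the game's target label
pinned to the target slot.  This device makes all three task variants the
same 8-alternative decision problem (chance 12.5 %) even where non-targets
are physically identical (oddball) or absent (target-only dummy slots); in
target-selection the label simply coincides with the shape identity.
Stimulus identities come from a fixed inventory of 8 abstract shape ids —
rendering is out of scope.

All randomisation uses `numpy.random.default_rng(seed)`; equal seeds give
byte-identical schedules.

## Synthetic EEG

**What it emulates.**  Eight channels (FC1, FC2, C3, Cz, C4, CP1, CP2, Pz)
at 256 Hz, in µV, already referenced.  Each real (non-dummy) stimulus adds
an early visual component: a positive half-cosine bump centred at 188 ms,
full width 100 ms, scaled by `nontarget_early_scale` (default 0.5) on
non-targets.  Each *target* additionally adds a late P300-like component: a
positive Gaussian bump (SD 60 ms) centred at a task-dependent latency with
per-trial Gaussian jitter.  Both components multiply a per-subject
centro-parietal topography (8 non-negative gains, max 1 at Pz).  Dummy
slots add nothing.  Background noise is pink (1/f), generated by spectral
shaping of seeded white noise, normalised to a per-sample SD of
`noise_sd`, independent across channels.

The component shapes (half-cosine / Gaussian) are smooth unimodal positives
chosen for morphological plausibility; nothing downstream depends on their
exact form, and all widths/centres are configurable.

**Cohort distributions (defaults).**  Subjects are drawn with truncated
Gaussian variation around cohort means; per-task means encode the
difficulty gradient — discriminability decreases from target-only through
oddball to target-selection:

| parameter | target_only | oddball | selection | between-subject SD |
|---|---|---|---|---|
| early amplitude (µV) | 6 | 5 | 4 | 1 |
| late amplitude (µV) | 8 | 6 | 4 | 1.5 |
| late latency (ms) | 360 | 420 | 500 | 40 (truncated 300–550) |

plus latency jitter SD 25 ± 8 ms, noise SD 9 ± 2 µV, non-target early scale
0.5 ± 0.1, topography gains ± 0.06 (Pz fixed at 1).  No quantitative µV
norms exist for this paradigm's cohort, so these are calibration choices,
set once so that the default 40-subject cohort lands target-selection
final-block pattern-matching accuracy in a 40–85 % band — clearly above
chance, clearly below ceiling — while preserving the difficulty gradient.
They live in `CohortParams`, not in code paths.

**Seeding and linearity.**  Each recording spawns separate child streams
for noise and latency jitter, and jitter is drawn for every trial whether
or not a component is added.  Consequently
`recording(profile) − recording(zero-amplitude profile)` at the same seed
is exactly the deterministic evoked part — the superposition property the
tests exploit.

**What it does not emulate.**  Volume conduction and realistic source
mixing (channels share a gain vector, not a forward model), ocular/muscle
artifacts, amplifier drift or line noise, non-stationarity, habituation or
fatigue across games, and any dependence of the ERP on stimulus *identity*
(only target status and task matter).  Passing tests therefore show the
pipeline is correct and well-calibrated under this generative model — not
that real cohorts would reach any particular accuracy.

## Preprocessing

0.2–30 Hz band-pass → decimation to 64 Hz → 1 s epochs (−200…800 ms) →
baseline correction.  Numerical choices:

* **Filter realisation:** 4th-order Butterworth, applied forward–backward
  (`sosfiltfilt`) per channel.  Zero phase matters because peak latency is
  itself a decoding feature; a causal filter would bias it.
* **Decimation:** plain sample dropping by the integer factor (4), with
  event indices rescaled by `round(i/4)`.  The band-pass already confines
  content below 30 Hz < 32 Hz target Nyquist, so no second anti-alias
  filter is applied.
* **Epoch grid:** sample k of an epoch sits at `(k − 13)/64` s relative to
  onset — 64 samples, 13 pre-stimulus.  Filtering is done once on the
  continuous signal, never per epoch; epoching is pure slicing and commutes
  with it.
* **Baseline:** mean of the 13 pre-stimulus samples subtracted per channel.
  Default on, toggleable, since it shifts mean-amplitude summaries.

## Decoders

* **Features:** 15 time points × 8 channels = 120 features, channel-major.
  Default indices 15, 18, …, 57 of the epoch grid = 31.25–687.5 ms
  post-stimulus, covering both components and the 100–700 ms analysis span;
  configurable and stored in the model.
* **Discriminant:** pooled within-class covariance with the unbiased n−2
  denominator; `pinv(S, rcond=1e-10)` handles rank deficiency without
  shrinkage.  Class imbalance (1:7) is left as-is — the standard
  formulation.  Identical class means yield a degenerate model (zero
  weights) with a warning rather than an error.
* **±1 calibration:** gain `a = 2/(s₊ − s₋)` and offset mapping the
  training-mean raw scores s₊, s₋ to +1/−1.  The identity holds exactly
  (to ~1e-12) after every CV fold and is re-verified in the tests.
* **Cumulative selection:** per game, candidate scores are summed over
  blocks 1..k; prediction is `argmax` with ties broken to the lowest label
  (deterministic and test-stable).  Evidence is nested: block k+1 equals
  block k plus that block's contribution.
* **Peak baselines:** the literature gives no canonical selection rule for
  the single-feature methods, so the package defines them explicitly —
  amplitude: maximum voltage of the channel-averaged, cumulatively averaged
  candidate waveform in 200–700 ms; latency: negative distance between the
  candidate's peak latency and a reference latency taken from the peak of
  the training games' mean target waveform.  Both windows are parameters.
* **Cross-validation:** leave-one-game-out; the peak-amplitude rule has no
  trainable part but is evaluated through the same folds so the three
  methods are compared on identical held-out data.

## Cohort statistics

Grand averages weight subjects equally (subject means first).  Mean ERP
amplitude is the time-mean of the channel-averaged waveform over
100–700 ms.  Per (task, method) cell the final success rates are tested
against chance with a one-sample two-sided t-test, df = n−1; a
zero-variance cell reports an infinite t with a note instead of failing.
Repeated-measures ANOVA and normality testing are intentionally out of
scope: the CSV outputs are flat so any statistics package can consume them.

The label-shuffling null (`shuffle_candidate_labels`) permutes candidate
labels within blocks while keeping target flags and the games' true labels,
reducing decoding to a uniform 1-in-8 guess; the test suite verifies the
mean accuracy over 200 simulated subjects sits within 3 SE of 12.5 % and
that the t-test's type-I error is ≈5 % over 500 null cohorts (simulated as
Binomial(8, 1/8)/8 per-subject accuracies, which the shuffling result
justifies).

## Problem sizes and determinism

Default study size: 40 subjects × 3 tasks × 3 methods with 8×6×8 schedules;
a full cohort simulates, preprocesses and cross-validates in well under a
minute per ten subjects on one core.  Monotonicity checks use 12-subject
cohorts at three noise levels (4.5/9/18 µV) and three late-amplitude levels
(1/4/8 µV) with common seeds so the comparison is paired.  The master seed
derives all per-subject and per-purpose streams through
`numpy.random.SeedSequence` spawn keys; identical configs produce
byte-identical output tables.

## Known limitations

* The generator's realism caveats above; in particular, no artifact model
  means preprocessing is never stress-tested against ocular contamination.
* EDF recordings are read (via mne) but continuous output is written in the
  package's npz+JSON sidecar format; EDF export requires an optional
  exporter backend.
* Epochs overlap neighbouring stimulus cycles (1 s window vs 625 ms cycle);
  this is faithful to the paradigm but means adjacent trials are not
  statistically independent, and a dummy epoch adjacent to a target carries
  real evoked signal.
* The peak-method definitions, while reasonable, are this package's own;
  absolute baseline-method accuracies should be read as properties of these
  definitions.
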